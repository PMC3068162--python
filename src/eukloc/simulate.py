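"""Synthetic localization worlds with the statistical structure the
classifier assumes.

A world is a complete, self-contained dataset — labels, GO annotations,
homology sets, PSSMs, sequences — generated from one seed, so every other
module is testable without any database download.  The generative model:

* each protein draws a label-set size from the benchmark multiplicity
  distribution (proportions 6687 : 1029 : 48 : 2 for 1..4 sites) and its
  sites uniformly without replacement;
* each site owns a disjoint set of signature GO terms; a protein's homology
  representatives carry each signature term of the protein's sites with
  probability p_sig and every other term with background probability p_bg,
  so encoded GO vectors concentrate near p_sig on the true signatures;
* each site owns a fixed direction in the 20-dimensional residue-type
  space; a protein's PSSM rows are that direction (summed over its sites)
  modulated by an independent per-position amplitude, plus noise.  The
  amplitude modulation puts the site signal into the between-column
  correlation structure — the part of a PSSM that survives column
  standardization and is measured by the transpose-product features.

One seed drives a single generator stream with a fixed draw order
(signature permutation, site directions, then per protein: multiplicity,
sites, orphan flag, homology size, per-representative annotations, PSSM
length/amplitudes/noise, residues), so bundles are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as eio
from .dataset import Dataset
from .go import build_go_index
from .io import CANONICAL_AA

__all__ = ["WorldConfig", "World", "simulate_world", "make_tie_fixture"]

#: benchmark label-multiplicity composition: proteins with 1, 2, 3, 4 sites
MULTIPLICITY_COUNTS = (6687, 1029, 48, 2)


@dataclass(frozen=True)
class WorldConfig:
    """Generator parameters; defaults define the standard study conditions."""

    n: int = 500
    C: int = 22
    G: int = 500
    signature_terms_per_site: int = 10
    multiplicity_probs: tuple[float, ...] = tuple(
        c / sum(MULTIPLICITY_COUNTS) for c in MULTIPLICITY_COUNTS
    )
    homology_mean_size: float = 8.0
    p_sig: float = 0.8
    p_bg: float = 0.02
    pssm_length_range: tuple[int, int] = (50, 400)
    pssm_effect: float = 3.0
    pssm_noise: float = 1.0
    orphan_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2 or self.C < 2:
            raise ValueError("need n >= 2 proteins and C >= 2 sites")
        if self.C * self.signature_terms_per_site > self.G:
            raise ValueError("signature sets exceed the GO term universe")
        if abs(sum(self.multiplicity_probs) - 1.0) > 1e-9:
            raise ValueError("multiplicity probabilities must sum to 1")
        if not all(0.0 <= p <= 1.0 for p in (self.p_sig, self.p_bg, self.orphan_fraction)):
            raise ValueError("probabilities must lie in [0, 1]")
        if len(self.multiplicity_probs) > self.C:
            raise ValueError("multiplicity support exceeds the number of sites")
        lo, hi = self.pssm_length_range
        if lo < 2 or hi < lo:
            raise ValueError("PSSM length range must satisfy 2 <= lo <= hi")


@dataclass
class World:
    """A simulated dataset plus the ground-truth generative structure."""

    dataset: Dataset
    signatures: dict[int, tuple[str, ...]]  # site code -> its signature GO ids
    site_directions: np.ndarray  # C x 20
    config: WorldConfig

    def write(self, path: str | Path) -> None:
        path = Path(path)
        self.dataset.to_directory(path)
        with open(path / "world_config.json", "w", encoding="utf-8") as fh:
            cfg = {k: v for k, v in vars(self.config).items()}
            json.dump(cfg, fh, indent=2, sort_keys=True, default=list)
            fh.write("\n")


def _go_universe(G: int) -> list[str]:
    # deliberately non-consecutive ids so compression is exercised
    return [f"GO:{3 * i + 1:07d}" for i in range(G)]


def simulate_world(cfg: WorldConfig) -> World:
    """Generate one world; fully determined by ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    go_ids = _go_universe(cfg.G)
    go_index = build_go_index(go_ids)

    s = cfg.signature_terms_per_site
    perm = rng.permutation(cfg.G)
    signatures = {
        u: tuple(go_ids[j] for j in perm[(u - 1) * s : u * s])
        for u in range(1, cfg.C + 1)
    }
    sig_positions = {
        u: np.array([go_index.compress(g) - 1 for g in signatures[u]])
        for u in signatures
    }

    directions = rng.normal(size=(cfg.C, 20))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    directions *= cfg.pssm_effect

    multiplicities = np.arange(1, len(cfg.multiplicity_probs) + 1)
    records: list[eio.SequenceRecord] = []
    site_map: dict[str, frozenset[int]] = {}
    homology: dict[str, tuple[tuple[str, None], ...]] = {}
    annotations: dict[str, frozenset[str]] = {}
    pssms: dict[str, np.ndarray] = {}
    rep_counter = 0
    lo, hi = cfg.pssm_length_range
    aa = np.frombuffer(CANONICAL_AA.encode(), dtype=np.uint8)

    for i in range(cfg.n):
        acc = f"SYN{i + 1:06d}"
        m = int(rng.choice(multiplicities, p=cfg.multiplicity_probs))
        sites = frozenset(int(u) + 1 for u in rng.choice(cfg.C, size=m, replace=False))
        site_map[acc] = sites
        orphan = rng.random() < cfg.orphan_fraction

        # homology set and representative annotations (drawn even for
        # orphans to keep the stream layout independent of the orphan flag)
        n_reps = 1 + int(rng.poisson(max(cfg.homology_mean_size - 1.0, 0.0)))
        sig_idx = np.concatenate([sig_positions[u] for u in sorted(sites)])
        reps: list[tuple[str, None]] = []
        for _ in range(n_reps):
            rep_counter += 1
            rep = f"SYNH{rep_counter:06d}"
            hit = rng.random(cfg.G) < cfg.p_bg
            hit[sig_idx] = rng.random(sig_idx.size) < cfg.p_sig
            terms = frozenset(go_ids[j] for j in np.flatnonzero(hit))
            reps.append((rep, None))
            if terms and not orphan:
                annotations[rep] = terms
        if not orphan:
            homology[acc] = tuple(reps)

        L = int(rng.integers(lo, hi + 1))
        w = directions[[u - 1 for u in sorted(sites)]].sum(axis=0)
        amplitude = rng.normal(size=L)
        noise = rng.normal(size=(L, 20))
        pssms[acc] = np.outer(amplitude, w) + cfg.pssm_noise * noise

        residues = rng.integers(0, 20, size=L)
        records.append(
            eio.SequenceRecord(acc, "synthetic", aa[residues].tobytes().decode())
        )

    dataset = Dataset(
        accessions=[r.accession for r in records],
        records=records,
        homology=eio.HomologyTable(homology),
        annotations=eio.AnnotationTable(annotations),
        go_index=go_index,
        pssms=pssms,
        truths=eio.SiteTable(site_map, C=cfg.C),
        C=cfg.C,
    )
    return World(dataset, signatures, directions, cfg)


def make_tie_fixture() -> World:
    """A handcrafted 4-protein world with exact distance ties.

    Each protein has one homology representative annotated with 0/1 term
    hits, so encoded GO vectors are exactly binary: with the first protein
    held out as the query, the second and third training vectors are
    bitwise-equidistant from it, exercising the deterministic tie-break
    policies.
    """
    go_ids = [f"GO:{j:07d}" for j in range(1, 5)]
    ann = {
        "SYNH000001": frozenset({go_ids[0]}),
        "SYNH000002": frozenset({go_ids[0], go_ids[1]}),
        "SYNH000003": frozenset({go_ids[0], go_ids[2]}),
        "SYNH000004": frozenset({go_ids[1], go_ids[2], go_ids[3]}),
    }
    labels = {
        "SYN000001": frozenset({1}),
        "SYN000002": frozenset({1}),
        "SYN000003": frozenset({2}),
        "SYN000004": frozenset({1, 2}),
    }
    homology = {
        f"SYN{i:06d}": ((f"SYNH{i:06d}", None),) for i in range(1, 5)
    }
    base = (np.arange(60, dtype=float).reshape(3, 20) % 7.0) - 3.0
    pssms = {f"SYN{i:06d}": base + float(i) for i in range(1, 5)}
    records = [
        eio.SequenceRecord(f"SYN{i:06d}", "tie fixture", "ACD") for i in range(1, 5)
    ]
    dataset = Dataset(
        accessions=[r.accession for r in records],
        records=records,
        homology=eio.HomologyTable(homology),
        annotations=eio.AnnotationTable(ann),
        go_index=build_go_index(go_ids),
        pssms=pssms,
        truths=eio.SiteTable(labels, C=22),
        C=22,
    )
    cfg = WorldConfig(n=4)  # nominal echo; vectors above are handcrafted
    return World(dataset, {}, np.zeros((22, 20)), cfg)
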