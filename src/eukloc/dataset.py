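"""A self-contained localization dataset and its two feature-space models.

A dataset bundles everything one benchmark needs: the ordered protein
accessions, their sequences, the homology table, the GO annotation table,
the GO term universe, per-protein PSSMs and the true site labels.  Datasets
round-trip through a directory of the plain-text formats in :mod:`eukloc.io`,
so simulated worlds and real inputs are interchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as eio
from .go import GOIndex, build_go_index, encode_go
from .knn import TrainingSet
from .seqevo import seqevo_features
from .sites import DEFAULT_C

__all__ = ["Dataset", "build_models"]

FASTA_NAME = "sequences.fasta"
ANNOTATIONS_NAME = "annotations.tsv"
HOMOLOGY_NAME = "homology.tsv"
SITES_NAME = "sites.tsv"
GO_TERMS_NAME = "go_terms.txt"
PSSM_DIR = "pssm"


@dataclass
class Dataset:
    accessions: list[str]
    records: list[eio.SequenceRecord]
    homology: eio.HomologyTable
    annotations: eio.AnnotationTable
    go_index: GOIndex
    pssms: dict[str, np.ndarray]
    truths: eio.SiteTable
    C: int = DEFAULT_C

    def __post_init__(self) -> None:
        for acc in self.accessions:
            if acc not in self.truths:
                raise eio.ValidationError(f"protein {acc!r} missing from the site table")

    def __len__(self) -> int:
        return len(self.accessions)

    def to_directory(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        eio.write_fasta(self.records, path / FASTA_NAME)
        eio.write_annotations(self.annotations, path / ANNOTATIONS_NAME)
        eio.write_homology(self.homology, path / HOMOLOGY_NAME)
        eio.write_sites(self.truths, path / SITES_NAME)
        eio.write_go_terms(self.go_index.ids, path / GO_TERMS_NAME)
        pssm_dir = path / PSSM_DIR
        pssm_dir.mkdir(exist_ok=True)
        for acc in sorted(self.pssms):
            eio.write_pssm(self.pssms[acc], pssm_dir / f"{acc}.pssm")

    @classmethod
    def from_directory(cls, path: str | Path, C: int = DEFAULT_C) -> "Dataset":
        path = Path(path)
        records = eio.read_fasta(path / FASTA_NAME)
        truths = eio.read_sites(path / SITES_NAME, C=C)
        pssms: dict[str, np.ndarray] = {}
        pssm_dir = path / PSSM_DIR
        if pssm_dir.is_dir():
            for f in sorted(pssm_dir.glob("*.pssm")):
                pssms[f.stem] = eio.read_pssm(f)
        return cls(
            accessions=[r.accession for r in records],
            records=records,
            homology=eio.read_homology(path / HOMOLOGY_NAME),
            annotations=eio.read_annotations(path / ANNOTATIONS_NAME),
            go_index=build_go_index(eio.read_go_terms(path / GO_TERMS_NAME)),
            pssms=pssms,
            truths=truths,
            C=C,
        )


def build_models(
    dataset: Dataset,
    length_normalize: bool = True,
) -> tuple[TrainingSet, TrainingSet | None]:
    """Encode every protein in both feature spaces and build the two models.

    The GO model covers all proteins (naught vectors included, so the two
    models describe the same population); the SeqEvo model covers the
    proteins that have a PSSM, or is None when none does.
    """
    go_X = np.stack(
        [
            encode_go(acc, dataset.homology, dataset.annotations, dataset.go_index)
            for acc in dataset.accessions
        ]
    )
    go_model = TrainingSet(
        space="GO",
        accessions=list(dataset.accessions),
        X=go_X,
        labels=[dataset.truths.labels(acc) for acc in dataset.accessions],
        C=dataset.C,
    )
    with_pssm = [acc for acc in dataset.accessions if acc in dataset.pssms]
    seqevo_model = None
    if with_pssm:
        se_X = np.stack(
            [
                seqevo_features(dataset.pssms[acc], length_normalize=length_normalize)
                for acc in with_pssm
            ]
        )
        seqevo_model = TrainingSet(
            space="SeqEvo",
            accessions=with_pssm,
            X=se_X,
            labels=[dataset.truths.labels(acc) for acc in with_pssm],
            C=dataset.C,
        )
    return go_model, seqevo_model
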