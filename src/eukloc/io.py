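"""Readers and writers for every external file the tool touches.

All tabular formats are tab-delimited UTF-8 text; lines starting with ``#``
are comments.  Accession matching is case-sensitive exact string match
throughout.  FASTA parsing is delegated to Bio.SeqIO with strict validation
layered on top; the PSI-BLAST ASCII PSSM dialect has no reader in the
installed libraries and is parsed here directly.
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .sites import DEFAULT_C, site_name

__all__ = [
    "ParseError",
    "ValidationError",
    "SequenceRecord",
    "AnnotationTable",
    "HomologyTable",
    "SiteTable",
    "read_fasta",
    "write_fasta",
    "read_pssm",
    "write_pssm",
    "read_annotations",
    "write_annotations",
    "read_homology",
    "write_homology",
    "read_sites",
    "write_sites",
    "read_go_terms",
    "write_go_terms",
    "write_predictions",
]


class ParseError(ValueError):
    """A file does not conform to its expected dialect."""


class ValidationError(ValueError):
    """A file parses but violates a semantic invariant."""


# the 20 canonical residues, alphabetical single-letter order
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
# tolerated ambiguity / non-standard codes, flagged but never dropped
AMBIGUOUS_AA = "BJOUXZ"
# PSI-BLAST prints PSSM columns in this native order
PSIBLAST_ORDER = "ARNDCQEGHILKMFPSTWYV"

_GO_ID_RE = re.compile(r"^GO:\d{7}$")
_FRAGMENT_LENGTH = 50


@dataclass(frozen=True)
class SequenceRecord:
    """One protein chain: accession, free-text description, residue string."""

    accession: str
    description: str
    residues: str

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValidationError("empty accession")
        if not self.residues:
            raise ValidationError(f"record {self.accession!r} has an empty sequence")
        bad = set(self.residues) - set(CANONICAL_AA) - set(AMBIGUOUS_AA)
        if bad:
            raise ValidationError(
                f"record {self.accession!r} contains invalid residue code(s) "
                f"{''.join(sorted(bad))!r}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def is_fragment(self) -> bool:
        """Chains shorter than 50 residues are deemed fragments."""
        return self.length < _FRAGMENT_LENGTH

    @property
    def has_ambiguous(self) -> bool:
        return any(c in AMBIGUOUS_AA for c in self.residues)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-record FASTA file with strict validation.

    The accession is the first whitespace-delimited token of the header;
    the remainder is the description.  Duplicate accessions are rejected.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise ParseError(
                    f"{path}: line {lineno}: expected a '>' header, got {line[:40]!r}"
                )
            break
    else:
        raise ParseError(f"{path}: no records found")

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
        residues = "".join(str(rec.seq).split()).upper()
        if not residues:
            raise ParseError(f"{path}: record {rec.id!r} has an empty sequence body")
        if rec.id in seen:
            raise ValidationError(f"{path}: duplicate accession {rec.id!r}")
        seen.add(rec.id)
        description = rec.description[len(rec.id):].strip()
        records.append(SequenceRecord(rec.id, description, residues))
    if not records:
        raise ParseError(f"{path}: no records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records in FASTA format, wrapping sequence lines at `width` ≤ 120."""
    width = min(width, 120)
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            header = rec.accession if not rec.description else f"{rec.accession} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.residues[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM


def read_pssm(path: str | Path) -> np.ndarray:
    """Parse the first score block of a PSI-BLAST ASCII PSSM.

    Returns an L x 20 float array with columns in alphabetical single-letter
    order (A, C, D, ..., Y), re-ordering the file's native column order as
    dictated by its header line.  Only the first 20-column log-odds block is
    read; a trailing frequency block, if present, is ignored.
    """
    path = Path(path)
    header_order: list[str] | None = None
    rows: list[list[float]] = []
    positions: list[int] = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        tokens = line.split()
        if not tokens:
            if rows:
                break  # blank line ends the matrix block
            continue
        if header_order is None:
            letters = [t for t in tokens if len(t) == 1 and t.isalpha()]
            if len(letters) >= 20 and set(letters[:20]) == set(CANONICAL_AA):
                header_order = [t.upper() for t in letters[:20]]
            continue
        # data row: position index, residue letter, then scores
        if not tokens[0].lstrip("-").isdigit():
            if rows:
                break  # footer (Lambda/K statistics) ends the block
            continue
        if len(tokens) < 2 or not (len(tokens[1]) == 1 and tokens[1].isalpha()):
            raise ParseError(f"{path}: line {lineno}: expected 'pos residue scores...'")
        scores: list[float] = []
        for tok in tokens[2:]:
            try:
                scores.append(float(tok))
            except ValueError:
                break
            if len(scores) == 20:
                break
        if len(scores) != 20:
            raise ParseError(
                f"{path}: line {lineno}: expected 20 scores, found {len(scores)}"
            )
        positions.append(int(tokens[0]))
        rows.append(scores)
    if header_order is None:
        raise ParseError(f"{path}: no column-header line with the 20 residue letters")
    if not rows:
        raise ParseError(f"{path}: no matrix rows found")
    if positions != list(range(positions[0], positions[0] + len(positions))):
        raise ParseError(f"{path}: position indices are not contiguous")

    matrix = np.asarray(rows, dtype=float)
    # permute columns from the file's native order to alphabetical order
    perm = [header_order.index(aa) for aa in CANONICAL_AA]
    return matrix[:, perm]


def write_pssm(matrix: np.ndarray, path: str | Path, residues: str | None = None) -> None:
    """Write an L x 20 score matrix in the PSI-BLAST ASCII dialect.

    Columns are written in alphabetical order with a residue-letter header
    so that :func:`read_pssm` round-trips the matrix exactly (2-decimal
    score precision).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] != 20:
        raise ValidationError(f"PSSM must be L x 20, got {matrix.shape}")
    L = matrix.shape[0]
    if residues is not None and len(residues) != L:
        raise ValidationError("residue string length does not match matrix rows")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# position-specific scoring matrix, alphabetical column order\n\n")
        fh.write("      " + "  ".join(f"{aa:>7s}" for aa in CANONICAL_AA) + "\n")
        for i in range(L):
            aa = residues[i] if residues is not None else "X"
            row = "  ".join(f"{v:7.2f}" for v in matrix[i])
            fh.write(f"{i + 1:4d} {aa}  {row}\n")


# ---------------------------------------------------------------------------
# tab-delimited tables


def _data_lines(path: Path) -> Iterable[tuple[int, str]]:
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        yield lineno, line.rstrip("\n")


def _validate_go_id(token: str, context: str) -> str:
    token = token.strip()
    if not _GO_ID_RE.match(token):
        raise ValidationError(f"{context}: malformed GO identifier {token!r}")
    return token


@dataclass(frozen=True)
class AnnotationTable:
    """Mapping accession -> non-empty set of GO identifiers."""

    mapping: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for acc, terms in self.mapping.items():
            if not terms:
                raise ValidationError(f"accession {acc!r} has an empty GO set")
            for t in terms:
                _validate_go_id(t, f"accession {acc!r}")

    def terms(self, accession: str) -> frozenset[str]:
        return self.mapping.get(accession, frozenset())

    def __contains__(self, accession: str) -> bool:
        return accession in self.mapping

    def __len__(self) -> int:
        return len(self.mapping)


@dataclass(frozen=True)
class HomologyTable:
    """Mapping query accession -> ordered representatives (optional %identity)."""

    mapping: Mapping[str, tuple[tuple[str, float | None], ...]]

    def __post_init__(self) -> None:
        for query, reps in self.mapping.items():
            names = [r for r, _ in reps]
            if len(names) != len(set(names)):
                raise ValidationError(f"query {query!r}: representative listed twice")
            for rep, ident in reps:
                if ident is not None and not (0.0 <= ident <= 100.0):
                    raise ValidationError(
                        f"query {query!r}: identity {ident} for {rep!r} outside [0, 100]"
                    )

    def representatives(self, query: str) -> list[str]:
        """Representative accessions for `query`; empty list if absent."""
        return [rep for rep, _ in self.mapping.get(query, ())]

    def filtered(self, min_identity: float) -> "HomologyTable":
        """Drop representatives whose identity is known and below the cutoff."""
        out = {
            q: tuple((r, i) for r, i in reps if i is None or i >= min_identity)
            for q, reps in self.mapping.items()
        }
        return HomologyTable({q: reps for q, reps in out.items() if reps})

    def without_representative(self, query: str, representative: str) -> "HomologyTable":
        """Return a copy with one representative dropped from one query's set."""
        if query not in self.mapping:
            return self
        reps = tuple(
            (r, i) for r, i in self.mapping[query] if r != representative
        )
        out = dict(self.mapping)
        if reps:
            out[query] = reps
        else:
            del out[query]
        return HomologyTable(out)

    def __contains__(self, query: str) -> bool:
        return query in self.mapping


@dataclass(frozen=True)
class SiteTable:
    """Mapping accession -> non-empty set of site codes in 1..C."""

    mapping: Mapping[str, frozenset[int]]
    C: int = DEFAULT_C

    def __post_init__(self) -> None:
        for acc, labels in self.mapping.items():
            if not labels:
                raise ValidationError(f"accession {acc!r} has an empty label set")
            for code in labels:
                if not (1 <= code <= self.C):
                    raise ValidationError(
                        f"accession {acc!r}: site code {code} outside 1..{self.C}"
                    )

    def labels(self, accession: str) -> frozenset[int]:
        if accession not in self.mapping:
            raise KeyError(accession)
        return self.mapping[accession]

    def __contains__(self, accession: str) -> bool:
        return accession in self.mapping

    def __len__(self) -> int:
        return len(self.mapping)


def read_annotations(path: str | Path) -> AnnotationTable:
    """Read `accession <TAB> GO:...,GO:...`; duplicate lines are unioned."""
    path = Path(path)
    mapping: dict[str, set[str]] = {}
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 tab-delimited fields")
        acc, terms = parts[0].strip(), parts[1]
        ids = {
            _validate_go_id(tok, f"{path}: line {lineno}")
            for tok in terms.split(",")
            if tok.strip()
        }
        if not ids:
            raise ParseError(f"{path}: line {lineno}: no GO identifiers")
        mapping.setdefault(acc, set()).update(ids)
    return AnnotationTable({acc: frozenset(v) for acc, v in mapping.items()})


def write_annotations(table: AnnotationTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# accession\tgo_ids\n")
        for acc in sorted(table.mapping):
            fh.write(f"{acc}\t{','.join(sorted(table.mapping[acc]))}\n")


def read_homology(path: str | Path, min_identity: float | None = None) -> HomologyTable:
    """Read `query <TAB> rep[,rep:identity,...]` homology sets.

    Representatives keep file order; `rep:97.5` attaches a percent identity.
    An optional `min_identity` filter drops representatives with a known
    identity below the cutoff while reading.
    """
    path = Path(path)
    mapping: dict[str, tuple[tuple[str, float | None], ...]] = {}
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 tab-delimited fields")
        query = parts[0].strip()
        if query in mapping:
            raise ValidationError(f"{path}: line {lineno}: duplicate query {query!r}")
        reps: list[tuple[str, float | None]] = []
        for tok in parts[1].split(","):
            tok = tok.strip()
            if not tok:
                continue
            if ":" in tok:
                name, ident_s = tok.rsplit(":", 1)
                try:
                    ident = float(ident_s)
                except ValueError:
                    raise ParseError(
                        f"{path}: line {lineno}: bad identity value {ident_s!r}"
                    ) from None
                reps.append((name.strip(), ident))
            else:
                reps.append((tok, None))
        mapping[query] = tuple(reps)
    table = HomologyTable(mapping)
    if min_identity is not None:
        table = table.filtered(min_identity)
    return table


def write_homology(table: HomologyTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# query\trepresentatives\n")
        for query in sorted(table.mapping):
            items = [
                rep if ident is None else f"{rep}:{ident:g}"
                for rep, ident in table.mapping[query]
            ]
            fh.write(f"{query}\t{','.join(items)}\n")


def read_sites(path: str | Path, C: int = DEFAULT_C) -> SiteTable:
    """Read `accession <TAB> code[,code...]` multi-label site assignments."""
    path = Path(path)
    mapping: dict[str, frozenset[int]] = {}
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 tab-delimited fields")
        acc = parts[0].strip()
        if acc in mapping:
            raise ValidationError(f"{path}: line {lineno}: duplicate accession {acc!r}")
        try:
            codes = frozenset(int(tok) for tok in parts[1].split(",") if tok.strip())
        except ValueError:
            raise ParseError(f"{path}: line {lineno}: non-integer site code") from None
        if not codes:
            raise ParseError(f"{path}: line {lineno}: empty label set")
        mapping[acc] = codes
    return SiteTable(mapping, C=C)


def write_sites(table: SiteTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# accession\tsite_codes\n")
        for acc in sorted(table.mapping):
            fh.write(f"{acc}\t{','.join(str(c) for c in sorted(table.mapping[acc]))}\n")


def read_go_terms(path: str | Path) -> list[str]:
    """Read a GO term-universe file, one GO identifier per line."""
    path = Path(path)
    return [
        _validate_go_id(line.strip(), f"{path}: line {lineno}")
        for lineno, line in _data_lines(path)
    ]


def write_go_terms(go_ids: Sequence[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# GO term universe, one identifier per line\n")
        for gid in go_ids:
            fh.write(gid + "\n")


def write_predictions(predictions: Sequence, path: str | Path, C: int = DEFAULT_C) -> None:
    """Write a prediction table: accession, site names, space, status, scores.

    Site names are semicolon-joined in ascending code order; scores are
    `code:value` pairs for the predicted sites only.  Abstained rows carry
    '-' placeholders.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# accession\tsites\tspace\tstatus\tscores\n")
        for pred in predictions:
            if pred.status == "abstained" or not pred.labels:
                fh.write(f"{pred.accession}\t-\t-\tabstained\t-\n")
                continue
            codes = sorted(pred.labels)
            names = "; ".join(site_name(c, C) for c in codes)
            scores = ",".join(f"{c}:{pred.scores[c - 1]:g}" for c in codes)
            fh.write(f"{pred.accession}\t{names}\t{pred.space}\t{pred.status}\t{scores}\n")
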