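"""Jackknife cross-validation and multi-label success metrics.

Two complementary scales measure a multi-label localization predictor:

* the locative success rate works on "virtual proteins" — one (protein,
  site) pair each, so a protein at three sites counts three times.  Per
  site, it is the fraction of proteins truly carrying the site whose
  predicted set recalls it; over-predicted sites never add to a numerator.
* the absolute-true success rate is far stricter: a protein scores 1 only
  when its predicted set equals the true set exactly, with no under- or
  over-prediction, and the rate is averaged over proteins.

The jackknife (leave-one-out) test predicts each protein with the model
restricted to the other N-1, also stripping the held-out protein from its
own homology set before re-encoding its GO vector, so no self-information
leaks into the prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np

from .dataset import Dataset, build_models
from .go import encode_go
from .io import SiteTable
from .knn import Prediction, predict
from .sites import DEFAULT_C, site_name

__all__ = [
    "EvaluationReport",
    "count_virtual",
    "absolute_true_rate",
    "locative_rates",
    "jackknife",
    "format_rate",
    "format_report",
]


def count_virtual(truths: SiteTable) -> int:
    """Total virtual proteins: the sum of label-set sizes over all proteins."""
    if len(truths) == 0:
        raise ValueError("site table is empty")
    return sum(len(labels) for labels in truths.mapping.values())


def absolute_true_rate(preds: Sequence[Prediction], truths: SiteTable) -> float:
    """Fraction of proteins whose predicted set equals the true set exactly.

    Abstentions (empty predicted sets) score 0.  Every predicted accession
    must be present in the truth table.
    """
    if not preds:
        raise ValueError("no predictions")
    hits = 0
    for p in preds:
        true = truths.labels(p.accession)  # KeyError on accession mismatch
        if p.labels and p.labels == true:
            hits += 1
    return hits / len(preds)


def locative_rates(
    preds: Sequence[Prediction],
    truths: SiteTable,
    C: int = DEFAULT_C,
) -> tuple[list[tuple[int, int, int]], float]:
    """Per-site (code, correct, total) counts and the overall locative rate.

    total(u) counts predicted proteins truly carrying site u; correct(u)
    counts those whose predicted set contains u.  Overall = sum of correct
    over sum of totals (virtual-protein accounting).
    """
    if not preds:
        raise ValueError("no predictions")
    correct = np.zeros(C + 1, dtype=int)
    total = np.zeros(C + 1, dtype=int)
    for p in preds:
        true = truths.labels(p.accession)
        for u in true:
            total[u] += 1
            if u in p.labels:
                correct[u] += 1
    per_site = [(u, int(correct[u]), int(total[u])) for u in range(1, C + 1)]
    overall = correct.sum() / total.sum()
    return per_site, float(overall)


@dataclass(frozen=True)
class EvaluationReport:
    """All counts and rates from one jackknife run."""

    per_site: tuple[tuple[int, str, int, int], ...]  # code, name, correct, total
    locative_correct: int
    locative_total: int
    overall_locative: float
    absolute_true_correct: int
    absolute_true: float
    n_proteins: int
    n_virtual: int
    K: int
    space_counts: tuple[tuple[str, int], ...]  # ("GO", n), ("SeqEvo", n)
    abstained: int


def jackknife(
    dataset: Dataset,
    K: int = 10,
    length_normalize: bool = True,
) -> EvaluationReport:
    """Leave-one-out evaluation of the full pipeline on one dataset.

    Each protein is re-encoded in GO space with itself removed from its own
    homology set, then predicted with itself excluded from the neighbor
    pool.  Deterministic for fixed inputs and configuration.
    """
    n = len(dataset)
    if n < 2:
        raise ValueError("jackknife needs at least 2 proteins")
    if K > n - 1:
        raise ValueError(f"K={K} too large for {n} proteins (leave-one-out pool is N-1)")

    go_model, seqevo_model = build_models(dataset, length_normalize=length_normalize)
    se_index = (
        {acc: i for i, acc in enumerate(seqevo_model.accessions)}
        if seqevo_model is not None
        else {}
    )

    preds: list[Prediction] = []
    for i, acc in enumerate(dataset.accessions):
        # leakage control: drop the held-out protein from its own homology set
        if acc in dataset.homology.representatives(acc):
            homology = dataset.homology.without_representative(acc, acc)
            q_go = encode_go(acc, homology, dataset.annotations, dataset.go_index)
        else:
            q_go = go_model.X[i]
        q_se = seqevo_model.X[se_index[acc]] if acc in se_index else None
        preds.append(
            predict(go_model, seqevo_model, acc, q_go, q_se, K, exclude=acc)
        )

    per_site_counts, overall = locative_rates(preds, dataset.truths, C=dataset.C)
    abs_hits = sum(
        1
        for p in preds
        if p.labels and p.labels == dataset.truths.labels(p.accession)
    )
    space_counts = {"GO": 0, "SeqEvo": 0}
    abstained = 0
    for p in preds:
        if p.status == "abstained":
            abstained += 1
        elif p.space is not None:
            space_counts[p.space] += 1
    return EvaluationReport(
        per_site=tuple(
            (u, site_name(u, dataset.C), c, t) for u, c, t in per_site_counts
        ),
        locative_correct=sum(c for _, c, _ in per_site_counts),
        locative_total=sum(t for _, _, t in per_site_counts),
        overall_locative=overall,
        absolute_true_correct=abs_hits,
        absolute_true=abs_hits / n,
        n_proteins=n,
        n_virtual=count_virtual(dataset.truths),
        K=K,
        space_counts=tuple(sorted(space_counts.items())),
        abstained=abstained,
    )


def format_rate(correct: int, total: int) -> str:
    """Render a success fraction as `correct/total = XX.XX%` (half-up)."""
    if total <= 0:
        raise ValueError("total must be positive")
    pct = (Decimal(correct) * 100 / Decimal(total)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP
    )
    return f"{correct}/{total} = {pct}%"


def format_report(report: EvaluationReport) -> str:
    """Render a report as a human-readable text table.

    Sites with no true carriers (total = 0) are omitted from the per-site
    rows; all rates are formatted half-up to two decimals at presentation
    only.
    """
    lines = [
        "Code\tSubcellular location site\tSuccess rate (jackknife)",
    ]
    for code, name, correct, total in report.per_site:
        if total == 0:
            continue
        lines.append(f"{code}\t{name}\t{format_rate(correct, total)}")
    lines.append(
        f"Overall\tlocative\t{format_rate(report.locative_correct, report.locative_total)}"
    )
    lines.append(
        "Overall\tabsolute-true\t"
        + format_rate(report.absolute_true_correct, report.n_proteins)
    )
    lines.append(f"# proteins: {report.n_proteins}")
    lines.append(f"# virtual proteins: {report.n_virtual}")
    lines.append(f"# K: {report.K}")
    for space, count in report.space_counts:
        lines.append(f"# predicted in {space} space: {count}")
    lines.append(f"# abstained: {report.abstained}")
    return "\n".join(lines) + "\n"


def report_to_tsv(report: EvaluationReport) -> str:
    """Machine-readable twin of :func:`format_report`."""
    lines = ["code\tname\tcorrect\ttotal"]
    for code, name, correct, total in report.per_site:
        lines.append(f"{code}\t{name}\t{correct}\t{total}")
    lines.append(
        f"overall_locative\t\t{report.locative_correct}\t{report.locative_total}"
    )
    lines.append(
        f"absolute_true\t\t{report.absolute_true_correct}\t{report.n_proteins}"
    )
    return "\n".join(lines) + "\n"
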