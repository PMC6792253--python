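"""Classifier- and ranking-level evaluation.

A fitted model is scored two ways: as a binary classifier (ROC and
precision-recall curves with their areas) and as a per-case prioritization
system.  For the latter, each proband's filtered variants are sorted by
descending predicted reported-probability; the 1-based positions of the
clinically reported variants yield median/mean rank and top-1/10/20
percentages, stratified by ACMG class (VUS / likely pathogenic /
pathogenic).  Two single-feature baselines (predicted deleteriousness and
phenotype-cosine) give a floor any useful model must beat.

Ties in probability break by variant key, making every ranking
deterministic; a pessimistic mode assigning tied variants their worst
possible rank is available for sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_curve

from .features import FeatureMatrix

logger = logging.getLogger(__name__)

STRATA = ("All", "VUS", "LP", "Path")

#: ACMG class labels as stored on variants -> stratum names used in reports.
ACMG_TO_STRATUM = {"VUS": "VUS", "likely_pathogenic": "LP", "pathogenic": "Path"}


# ---------------------------------------------------------------------------
# per-case ranking
# ---------------------------------------------------------------------------

@dataclass
class CaseRanking:
    case_id: str
    ordered_keys: List[str]                    # descending probability
    reported_ranks: Dict[str, int]             # reported variant -> 1-based rank

    def __post_init__(self) -> None:
        n = len(self.ordered_keys)
        for key, rank in self.reported_ranks.items():
            if not (1 <= rank <= n):
                raise ValueError(f"rank {rank} of {key!r} outside 1..{n}")


def rank_case(
    case_id: str,
    probabilities: Mapping[str, float],
    reported: Iterable[str] = (),
    *,
    pessimistic_ties: bool = False,
) -> CaseRanking:
    """Sort a case's variants by descending probability; ties break by key.

    With ``pessimistic_ties=True`` every reported variant instead receives
    the worst rank within its probability tie group.
    """
    if not probabilities:
        raise ValueError(f"case {case_id!r} has no variants")
    ordered = sorted(probabilities, key=lambda k: (-probabilities[k], k))
    pos = {k: i + 1 for i, k in enumerate(ordered)}
    reported = [k for k in reported if k in probabilities]
    if pessimistic_ties:
        ranks = {
            k: sum(1 for p in probabilities.values() if p >= probabilities[k])
            for k in reported
        }
    else:
        ranks = {k: pos[k] for k in reported}
    return CaseRanking(case_id=case_id, ordered_keys=ordered, reported_ranks=ranks)


@dataclass
class RankSummary:
    stratum: str
    n: int
    median_rank: Optional[float]
    mean_rank: Optional[float]
    top1_pct: Optional[float]
    top10_pct: Optional[float]
    top20_pct: Optional[float]

    def __post_init__(self) -> None:
        tops = [self.top1_pct, self.top10_pct, self.top20_pct]
        if all(t is not None for t in tops):
            if not (tops[0] <= tops[1] + 1e-9 and tops[1] <= tops[2] + 1e-9):
                raise AssertionError(f"top-X not monotone in {self.stratum}: {tops}")


def _summarize(stratum: str, ranks: Sequence[int]) -> RankSummary:
    if not ranks:
        return RankSummary(stratum, 0, None, None, None, None, None)
    arr = np.asarray(ranks, dtype=float)
    return RankSummary(
        stratum=stratum,
        n=len(arr),
        median_rank=float(np.median(arr)),   # even n: mean of central pair
        mean_rank=float(arr.mean()),
        top1_pct=float((arr <= 1).mean() * 100),
        top10_pct=float((arr <= 10).mean() * 100),
        top20_pct=float((arr <= 20).mean() * 100),
    )


def rank_metrics(
    rankings: Sequence[CaseRanking],
    acmg_by_key: Mapping[str, str],
) -> List[RankSummary]:
    """Rank summaries overall and per ACMG stratum.

    *acmg_by_key* maps each reported variant key to its ACMG class
    (``VUS`` / ``likely_pathogenic`` / ``pathogenic``).  Reported variants
    without a class raise, since stratification would silently lose them.
    """
    all_ranks: List[int] = []
    by_stratum: Dict[str, List[int]] = {s: [] for s in STRATA[1:]}
    for ranking in rankings:
        for key, rank in ranking.reported_ranks.items():
            cls = acmg_by_key.get(key)
            if cls not in ACMG_TO_STRATUM:
                raise KeyError(f"reported variant {key!r} lacks a valid ACMG class")
            all_ranks.append(rank)
            by_stratum[ACMG_TO_STRATUM[cls]].append(rank)
    out = [_summarize("All", all_ranks)]
    out.extend(_summarize(s, by_stratum[s]) for s in STRATA[1:])
    return out


# ---------------------------------------------------------------------------
# classifier curves
# ---------------------------------------------------------------------------

@dataclass
class CurveSummary:
    roc_points: np.ndarray = field(repr=False)   # (fpr, tpr) rows
    pr_points: np.ndarray = field(repr=False)    # (recall, precision) rows
    auroc: float = 0.0
    auprc: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.auroc <= 1.0 and 0.0 <= self.auprc <= 1.0):
            raise AssertionError("curve areas must lie in [0,1]")


def curves(scores: Sequence[float], labels: Sequence[int]) -> CurveSummary:
    """ROC (trapezoidal area) and PR (average-precision step area) curves.

    The step-wise average-precision estimator is used for the PR area
    because trapezoidal interpolation of precision is optimistically
    biased.  Single-class label vectors raise.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    fpr, tpr, _ = roc_curve(y, s)
    auroc = float(np.trapezoid(tpr, fpr))
    precision, recall, _ = precision_recall_curve(y, s)
    auprc = float(average_precision_score(y, s))
    return CurveSummary(
        roc_points=np.column_stack([fpr, tpr]),
        pr_points=np.column_stack([recall, precision]),
        auroc=auroc,
        auprc=auprc,
    )


# ---------------------------------------------------------------------------
# baselines and external score files
# ---------------------------------------------------------------------------

def baseline_rankers(
    matrix: FeatureMatrix,
    feature: str,
    reported_keys: Iterable[str] = (),
    *,
    pessimistic_ties: bool = False,
) -> List[CaseRanking]:
    """Per-case rankings using one raw feature column as the score."""
    if feature not in matrix.X.columns:
        raise KeyError(f"feature column {feature!r} not in matrix")
    reported = set(reported_keys)
    values = matrix.X[feature].to_numpy()
    by_case: Dict[str, Dict[str, float]] = {}
    for case_id, key, val in zip(matrix.case_ids, matrix.variant_keys, values):
        by_case.setdefault(case_id, {})[key] = float(val)
    return [
        rank_case(
            case_id,
            probs,
            [k for k in probs if k in reported],
            pessimistic_ties=pessimistic_ties,
        )
        for case_id, probs in sorted(by_case.items())
    ]


def rankings_from_probabilities(
    matrix: FeatureMatrix,
    probabilities: Sequence[float],
    reported_keys: Iterable[str],
    *,
    pessimistic_ties: bool = False,
) -> List[CaseRanking]:
    """Group model probabilities by case and rank each case."""
    reported = set(reported_keys)
    by_case: Dict[str, Dict[str, float]] = {}
    for case_id, key, p in zip(matrix.case_ids, matrix.variant_keys, probabilities):
        by_case.setdefault(case_id, {})[key] = float(p)
    return [
        rank_case(
            case_id,
            probs,
            [k for k in probs if k in reported],
            pessimistic_ties=pessimistic_ties,
        )
        for case_id, probs in sorted(by_case.items())
    ]


def conservative_unranked_fill(
    scored_order: Sequence[str], all_keys: Iterable[str]
) -> List[str]:
    """Complete a partial ranking: unscored variants follow the last scored
    one, in key order (the most favorable rank they could still take)."""
    scored = list(scored_order)
    seen = set(scored)
    return scored + sorted(k for k in all_keys if k not in seen)


# ---------------------------------------------------------------------------
# report writers (table-shaped TSVs)
# ---------------------------------------------------------------------------

def format_rank_cell(s: RankSummary) -> str:
    if s.n == 0:
        return "n/a"
    return f"{s.median_rank:.1f} ({s.mean_rank:.2f})"


def format_topx_cell(s: RankSummary) -> str:
    if s.n == 0:
        return "n/a"
    return f"{s.top1_pct:.0f}, {s.top10_pct:.0f}, {s.top20_pct:.0f}"


def write_classifier_table(
    rows: Sequence[Tuple[str, Tuple[float, float], float, float]], stream
) -> None:
    """One row per method: CV10 balanced accuracy 'mean+-std', AUROC, AUPRC."""
    stream.write("Classifier\tCV10 Acc.\tAUROC\tAUPRC\n")
    for name, (mean, std), auroc, auprc in rows:
        stream.write(f"{name}\t{mean:.2f}+-{std:.2f}\t{auroc:.4f}\t{auprc:.4f}\n")


def write_rank_table(rows: Sequence[Tuple[str, List[RankSummary]]], stream) -> None:
    """One row per ranking system: 'median (mean)' per stratum."""
    header = ["Ranking System"] + [
        f"{s} (n={rows[0][1][i].n})" if rows else s for i, s in enumerate(STRATA)
    ]
    stream.write("\t".join(header) + "\n")
    for name, summaries in rows:
        stream.write(
            "\t".join([name] + [format_rank_cell(s) for s in summaries]) + "\n"
        )


def write_topx_table(rows: Sequence[Tuple[str, List[RankSummary]]], stream) -> None:
    """One row per ranking system: 'top1, top10, top20' percentages per stratum."""
    header = ["Ranking System"] + [
        f"{s} (n={rows[0][1][i].n})" if rows else s for i, s in enumerate(STRATA)
    ]
    stream.write("\t".join(header) + "\n")
    for name, summaries in rows:
        stream.write(
            "\t".join([name] + [format_topx_cell(s) for s in summaries]) + "\n"
        )


def write_curve_points(summary: CurveSummary, roc_stream, pr_stream) -> None:
    roc_stream.write("fpr\ttpr\n")
    for fpr, tpr in summary.roc_points:
        roc_stream.write(f"{fpr:.6f}\t{tpr:.6f}\n")
    pr_stream.write("recall\tprecision\n")
    for rec, prec in summary.pr_points:
        pr_stream.write(f"{rec:.6f}\t{prec:.6f}\n")
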