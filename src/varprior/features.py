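"""Annotation-to-feature encoding and univariate feature selection.

Raw variant annotations come in three shapes: single numeric values
(copied through; missing values take a fixed default chosen OUTSIDE the
expected range on the less-impactful side, except allele frequencies
which default to 0.0), multi-value numerics (reduced with min or max to
the single "worst" — most deleterious / most conserved — value), and
multi-label categoricals (bin-count encoded: one integer column per
vocabulary label counting its occurrences, plus an ``_other`` bucket for
labels outside the declared vocabulary).

The reference spec set shipped with the package encodes to 95 columns;
univariate screening (ANOVA F by default, chi-square for count columns as
an alternative) on the TRAINING rows only prunes those to the top 20.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, TextIO, Tuple

import numpy as np
import pandas as pd
import yaml
from sklearn.feature_selection import chi2, f_classif

from .clinfilter import AnnotatedVariant

logger = logging.getLogger(__name__)

OTHER_BUCKET = "_other"


class EncodingError(ValueError):
    pass


class SpecError(ValueError):
    pass


@dataclass
class FeatureSpec:
    """How one raw annotation becomes numeric feature column(s)."""

    name: str
    kind: str                                   # numeric_single | numeric_multi | categorical
    default_value: Optional[float] = None       # numeric kinds
    worst_direction: Optional[str] = None       # numeric_multi: 'min' | 'max'
    vocabulary: Optional[List[str]] = None      # categorical
    is_allele_freq: bool = False
    expected_range: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.kind not in ("numeric_single", "numeric_multi", "categorical"):
            raise SpecError(f"{self.name}: unknown kind {self.kind!r}")
        if self.kind == "categorical":
            if not self.vocabulary:
                raise SpecError(f"{self.name}: categorical spec needs a vocabulary")
        else:
            if self.is_allele_freq:
                if self.default_value not in (None, 0.0):
                    raise SpecError(f"{self.name}: allele-frequency default must be 0.0")
                self.default_value = 0.0
            if self.default_value is None:
                raise SpecError(f"{self.name}: numeric spec needs default_value")
            if self.kind == "numeric_multi" and self.worst_direction not in ("min", "max"):
                raise SpecError(f"{self.name}: numeric_multi needs worst_direction min|max")
            # Defaults must sit outside the declared expected range (on the
            # less-impactful side, which the range cannot orient by itself —
            # we enforce exteriority; the side is the spec author's call).
            if self.expected_range is not None and not self.is_allele_freq:
                lo, hi = self.expected_range
                if lo <= self.default_value <= hi:
                    raise SpecError(
                        f"{self.name}: default {self.default_value} lies inside "
                        f"expected range [{lo}, {hi}]"
                    )

    def columns(self) -> List[str]:
        """Names of the matrix columns this spec produces."""
        if self.kind == "categorical":
            return [f"{self.name}_{label}" for label in self.vocabulary] + [
                f"{self.name}{OTHER_BUCKET}"
            ]
        return [self.name]


def load_feature_specs(stream: TextIO | str) -> List[FeatureSpec]:
    """Load a YAML list of feature specs; duplicate names or columns raise."""
    raw = yaml.safe_load(stream)
    if not isinstance(raw, list):
        raise SpecError("feature spec file must be a YAML list")
    specs: List[FeatureSpec] = []
    for entry in raw:
        if "expected_range" in entry and entry["expected_range"] is not None:
            entry["expected_range"] = tuple(entry["expected_range"])
        specs.append(FeatureSpec(**entry))
    names = [s.name for s in specs]
    if len(names) != len(set(names)):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise SpecError(f"duplicate feature names: {dupes}")
    cols = [c for s in specs for c in s.columns()]
    if len(cols) != len(set(cols)):
        dupes = sorted({c for c in cols if cols.count(c) > 1})
        raise SpecError(f"duplicate feature columns: {dupes}")
    return specs


def reference_specs() -> List[FeatureSpec]:
    """The packaged reference spec set (95 encoded columns)."""
    text = (
        importlib.resources.files("varprior.data")
        .joinpath("feature_specs.yaml")
        .read_text()
    )
    return load_feature_specs(text)


# ---------------------------------------------------------------------------
# per-annotation encoders
# ---------------------------------------------------------------------------

def _as_float(value: object, spec: FeatureSpec, variant_key: str) -> float:
    try:
        out = float(value)  # type: ignore[arg-type]
    except (TypeError, ValueError) as exc:
        raise EncodingError(
            f"variant {variant_key!r}, feature {spec.name!r}: "
            f"non-numeric payload {value!r}"
        ) from exc
    if math.isnan(out):
        raise EncodingError(
            f"variant {variant_key!r}, feature {spec.name!r}: NaN payload"
        )
    return out


def encode_numeric_single(
    value: object, spec: FeatureSpec, *, variant_key: str = "?"
) -> float:
    """Pass a numeric annotation through; missing takes the spec default."""
    if value is None:
        return float(spec.default_value)
    return _as_float(value, spec, variant_key)


def reduce_multi_value(
    values: Optional[Iterable[object]], spec: FeatureSpec, *, variant_key: str = "?"
) -> float:
    """Reduce a multi-value numeric annotation to its worst single value."""
    vals = [] if values is None else [_as_float(v, spec, variant_key) for v in values]
    if not vals:
        return float(spec.default_value)
    return max(vals) if spec.worst_direction == "max" else min(vals)


def bin_count_encode(
    labels: Optional[Iterable[str]], spec: FeatureSpec
) -> np.ndarray:
    """Count each vocabulary label (whitespace-trimmed, case-sensitive).

    Labels outside the vocabulary fall into the trailing ``_other`` bucket.
    """
    vocab_index = {label: i for i, label in enumerate(spec.vocabulary)}
    counts = np.zeros(len(spec.vocabulary) + 1, dtype=np.int64)
    for label in labels or ():
        idx = vocab_index.get(str(label).strip(), len(spec.vocabulary))
        counts[idx] += 1
    return counts


# ---------------------------------------------------------------------------
# matrix assembly
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Variants × numeric features, with labels and case membership."""

    X: pd.DataFrame                 # rows in input order; columns in spec order
    labels: np.ndarray              # 1 = reported
    case_ids: List[str]
    variant_keys: List[str]

    def __post_init__(self) -> None:
        if self.X.isna().any().any():
            bad = self.X.columns[self.X.isna().any()].tolist()
            raise EncodingError(f"NaN survived assembly in columns {bad}")

    @property
    def n_rows(self) -> int:
        return len(self.X)

    def rows_for_cases(self, case_ids: Iterable[str]) -> "FeatureMatrix":
        wanted = set(case_ids)
        mask = np.array([c in wanted for c in self.case_ids])
        return FeatureMatrix(
            X=self.X.loc[mask].reset_index(drop=True),
            labels=self.labels[mask],
            case_ids=[c for c, m in zip(self.case_ids, mask) if m],
            variant_keys=[k for k, m in zip(self.variant_keys, mask) if m],
        )

    def to_tsv(self, matrix_stream: TextIO, sidecar_stream: TextIO) -> None:
        self.X.to_csv(matrix_stream, sep="\t", index=False, float_format="%.10g")
        json.dump(
            {
                "labels": self.labels.tolist(),
                "case_ids": self.case_ids,
                "variant_keys": self.variant_keys,
            },
            sidecar_stream,
        )

    @classmethod
    def from_tsv(cls, matrix_stream: TextIO, sidecar_stream: TextIO) -> "FeatureMatrix":
        X = pd.read_csv(matrix_stream, sep="\t", dtype=np.float64)
        meta = json.load(sidecar_stream)
        return cls(
            X=X,
            labels=np.asarray(meta["labels"], dtype=np.int64),
            case_ids=meta["case_ids"],
            variant_keys=meta["variant_keys"],
        )


def assemble_feature_matrix(
    variants: Sequence[AnnotatedVariant], specs: Sequence[FeatureSpec]
) -> FeatureMatrix:
    """Encode every variant against every spec into one dense float matrix.

    Column order follows spec order (deterministic); row order preserves
    input order.  Annotations not covered by any spec are logged once and
    dropped.
    """
    names = [s.name for s in specs]
    if len(names) != len(set(names)):
        raise SpecError("duplicate feature names in spec list")
    known = set(names)
    unknown_seen: set = set()

    columns = [c for s in specs for c in s.columns()]
    data = np.empty((len(variants), len(columns)), dtype=np.float64)

    for i, v in enumerate(variants):
        j = 0
        ann = v.annotations
        for s in specs:
            value = ann.get(s.name)
            if s.kind == "numeric_single":
                data[i, j] = encode_numeric_single(value, s, variant_key=v.key)
                j += 1
            elif s.kind == "numeric_multi":
                if value is not None and not isinstance(value, (list, tuple)):
                    value = [value]
                data[i, j] = reduce_multi_value(value, s, variant_key=v.key)
                j += 1
            else:
                if value is not None and not isinstance(value, (list, tuple)):
                    value = [value]
                w = len(s.vocabulary) + 1
                data[i, j : j + w] = bin_count_encode(value, s)
                j += w
        for extra in ann.keys() - known:
            if extra not in unknown_seen:
                unknown_seen.add(extra)
                logger.warning("annotation %r not covered by any spec; dropped", extra)

    return FeatureMatrix(
        X=pd.DataFrame(data, columns=columns),
        labels=np.array([1 if v.is_reported else 0 for v in variants], dtype=np.int64),
        case_ids=[v.case_id for v in variants],
        variant_keys=[v.key for v in variants],
    )


# ---------------------------------------------------------------------------
# univariate selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    """Top-k univariate screen, fitted on training rows only."""

    selected: List[str]
    scores: Dict[str, float]
    fitted_on: List[str] = field(default_factory=list)  # training case IDs


def select_top_k(
    matrix: FeatureMatrix, k: int, *, method: str = "f_classif"
) -> SelectionResult:
    """Score each column independently against the label; keep the top *k*.

    Ties (and NaN scores from zero-variance columns) break by column
    order.  ``method`` is the ANOVA F statistic by default, with a
    chi-square alternative suited to count columns.  When *k* exceeds the
    column count, all columns are returned with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = matrix.X.to_numpy()
    y = matrix.labels
    if method == "f_classif":
        with np.errstate(divide="ignore", invalid="ignore"):
            scores, _ = f_classif(X, y)
    elif method == "chi2":
        scores, _ = chi2(X, y)
    else:
        raise ValueError(f"unknown selection method {method!r}")
    scores = np.nan_to_num(scores, nan=-np.inf)
    ncols = X.shape[1]
    if k > ncols:
        logger.warning("select_top_k: k=%d > %d columns; returning all", k, ncols)
        k = ncols
    order = np.argsort(-scores, kind="stable")  # stable => ties keep column order
    top = sorted(order[:k])                     # selected columns in matrix order
    cols = list(matrix.X.columns)
    return SelectionResult(
        selected=[cols[i] for i in top],
        scores={cols[i]: float(scores[i]) for i in range(ncols)},
        fitted_on=sorted(set(matrix.case_ids)),
    )


def report_feature_importance(model, selection: SelectionResult) -> Dict[str, float]:
    """Per-feature importances of a fitted forest-style model, sorted descending.

    The importances cover the selected features and sum to 1.  Model kinds
    without ``feature_importances_`` raise.
    """
    imp = getattr(model, "feature_importances_", None)
    if imp is None:
        raise TypeError(f"model {type(model).__name__} does not expose feature importances")
    imp = np.asarray(imp, dtype=float)
    if len(imp) != len(selection.selected):
        raise ValueError("importance length does not match selected features")
    total = imp.sum()
    if total > 0 and abs(total - 1.0) > 1e-6:
        imp = imp / total
    pairs = sorted(zip(selection.selected, imp), key=lambda kv: (-kv[1], kv[0]))
    return {name: float(val) for name, val in pairs}


def average_importances(maps: Sequence[Dict[str, float]]) -> Dict[str, float]:
    """Average several importance maps and re-sort descending (report style)."""
    keys = sorted({k for m in maps for k in m})
    avg = {k: float(np.mean([m.get(k, 0.0) for m in maps])) for k in keys}
    return dict(sorted(avg.items(), key=lambda kv: (-kv[1], kv[0])))
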