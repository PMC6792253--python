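"""The six-criterion clinical variant filter.

Clinical analysis pipelines reduce the millions of called variants in a
genome to the few hundred a human analyst can review.  The screen applied
here requires, per variant:

1. sufficient total read depth,
2. sufficient alternate-allele read depth,
3. low population allele frequency (a variant absent from the frequency
   database is treated as frequency 0.0),
4. at least one predicted effect on a transcript,
5. at least one gene-disease association, and
6. absence from a blacklist of known, common sequencing false positives.

Variants with missing depth fields fail the depth criteria (conservative);
variants with no gene links fail the gene-disease-association criterion.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Dict, Iterable, List, Optional, Sequence, Set, TextIO, Tuple

import yaml

logger = logging.getLogger(__name__)

ACMG_CLASSES = ("VUS", "likely_pathogenic", "pathogenic")


@dataclass
class AnnotatedVariant:
    """One annotated variant in one proband."""

    key: str                                  # chrom-pos-ref-alt identifier
    case_id: str
    genes: List[str] = field(default_factory=list)
    total_depth: Optional[int] = None
    alt_depth: Optional[int] = None
    pop_freq: Optional[float] = None          # None = absent from databases
    transcript_effects: List[str] = field(default_factory=list)
    gene_disease_assocs: List[str] = field(default_factory=list)
    annotations: Dict[str, object] = field(default_factory=dict)
    label: str = "not_reported"               # 'reported' | 'not_reported'
    acmg_class: Optional[str] = None          # present iff reported

    def __post_init__(self) -> None:
        if self.label not in ("reported", "not_reported"):
            raise ValueError(f"bad label {self.label!r} for variant {self.key}")
        if (self.acmg_class is not None) != (self.label == "reported"):
            raise ValueError(
                f"variant {self.key}: acmg_class must be present iff reported"
            )
        if self.acmg_class is not None and self.acmg_class not in ACMG_CLASSES:
            raise ValueError(f"variant {self.key}: unknown ACMG class {self.acmg_class!r}")
        if (
            self.total_depth is not None
            and self.alt_depth is not None
            and self.alt_depth > self.total_depth
        ):
            raise ValueError(f"variant {self.key}: alt_depth > total_depth")
        if self.pop_freq is not None and not (0.0 <= self.pop_freq <= 1.0):
            raise ValueError(f"variant {self.key}: pop_freq out of [0,1]")

    @property
    def is_reported(self) -> bool:
        return self.label == "reported"

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, line: str) -> "AnnotatedVariant":
        return cls(**json.loads(line))


def read_jsonl(stream: TextIO | Iterable[str]) -> List[AnnotatedVariant]:
    """Read JSON-lines variant records."""
    return [
        AnnotatedVariant.from_json(line)
        for line in stream
        if line.strip() and not line.lstrip().startswith("#")
    ]


def write_jsonl(variants: Iterable[AnnotatedVariant], stream: TextIO) -> None:
    for v in variants:
        stream.write(v.to_json())
        stream.write("\n")


@dataclass
class FilterConfig:
    """Thresholds and switches of the clinical filter.

    Defaults are configurable placeholders in the realistic range for a
    rare-disease screen; the test suite never depends on them.
    """

    min_total_depth: int = 8
    min_alt_depth: int = 4
    max_pop_freq: float = 0.01
    require_transcript_effect: bool = True
    require_gene_disease_assoc: bool = True
    blacklist: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.min_alt_depth > self.min_total_depth:
            raise ValueError("min_alt_depth must be <= min_total_depth")
        if not (0.0 <= self.max_pop_freq <= 1.0) and not math.isinf(self.max_pop_freq):
            raise ValueError("max_pop_freq must be in [0,1]")

    @classmethod
    def from_yaml(cls, stream: TextIO | str) -> "FilterConfig":
        data = yaml.safe_load(stream) or {}
        if "blacklist" in data:
            data["blacklist"] = set(data["blacklist"])
        return cls(**data)

    def to_yaml(self) -> str:
        d = asdict(self)
        d["blacklist"] = sorted(self.blacklist)
        return yaml.safe_dump(d, sort_keys=True)


#: Criterion names in evaluation order, as reported in the rejection tally.
CRITERIA = ("depth", "alt_depth", "freq", "effect", "assoc", "blacklist")


def _failed_criterion(v: AnnotatedVariant, cfg: FilterConfig) -> Optional[str]:
    """Name of the first criterion the variant fails, or None if it passes."""
    if v.total_depth is None or v.total_depth < cfg.min_total_depth:
        return "depth"
    if v.alt_depth is None or v.alt_depth < cfg.min_alt_depth:
        return "alt_depth"
    freq = 0.0 if v.pop_freq is None else v.pop_freq
    if freq > cfg.max_pop_freq:
        return "freq"
    if cfg.require_transcript_effect and not v.transcript_effects:
        return "effect"
    if cfg.require_gene_disease_assoc and not (v.genes and v.gene_disease_assocs):
        return "assoc"
    if v.key in cfg.blacklist:
        return "blacklist"
    return None


def apply_clinical_filter(
    variants: Sequence[AnnotatedVariant],
    cfg: FilterConfig,
    *,
    return_tally: bool = False,
) -> List[AnnotatedVariant] | Tuple[List[AnnotatedVariant], Dict[str, int]]:
    """Return the variants passing all six criteria, order preserved.

    Per-criterion rejection counts (first failed criterion per rejected
    variant) are logged, and returned too when ``return_tally=True``.
    """
    passed: List[AnnotatedVariant] = []
    tally: Dict[str, int] = {c: 0 for c in CRITERIA}
    for v in variants:
        failed = _failed_criterion(v, cfg)
        if failed is None:
            passed.append(v)
        else:
            tally[failed] += 1
    logger.info(
        "clinical filter: %d in, %d out, rejections %s",
        len(variants), len(passed), tally,
    )
    if return_tally:
        return passed, tally
    return passed
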