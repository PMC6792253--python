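"""Seeded synthetic cohorts with the statistical structure the pipeline assumes.

Real rare-disease cohorts of this kind are controlled-access, so the
generator builds fully self-contained stand-ins end to end: a random
rooted phenotype DAG, gene-to-term annotations sampled as coherent
subtrees, and per-proband annotated variant tables with 1-3 planted
reported positives among a few hundred filter-passing negatives (plus a
handful of designed filter failures).

What the generator emulates:

* patient phenotype terms drawn from the causal gene's annotations, with
  noise (spurious terms added, true terms dropped) mimicking the
  variability of real phenotype collection;
* positives mean-shifted on a designated set of signal features, with the
  shift growing with ACMG class (pathogenic > likely pathogenic > VUS) —
  the designated columns plus the two phenotype scores form 20 signal
  columns among the 95 encoded features, the rest being pure noise;
* per-annotation missingness, multi-gene variants, and the filter fields
  (read depths, population frequency, effects, disease links, blacklist).

All randomness flows from one master seed through named substreams, so
ontology, cohort and noise are independently reproducible and the same
seed yields byte-identical outputs.
"""

from __future__ import annotations

import io
import zlib
from dataclasses import dataclass, field, asdict
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import yaml

from .clinfilter import AnnotatedVariant
from .features import FeatureMatrix, FeatureSpec, reference_specs
from .ontology import GeneAnnotationMap, OntologyGraph


def substream(seed: int, name: str) -> np.random.Generator:
    """A named, independent random substream of the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


@dataclass
class CohortSpec:
    """Study conditions of a synthetic cohort.

    The defaults reproduce the shape of a realistic rare-disease cohort:
    237 probands, 200-400 filter-passing variants each, 1-3 reported
    positives per case with a VUS-heavy class mix, and ~1:230 overall
    class imbalance.
    """

    seed: int = 0
    n_terms: int = 400
    branching: float = 0.2          # probability a term gets a second parent
    n_genes: int = 800
    annotations_per_gene: float = 8.0
    n_cases: int = 237
    variants_per_case: Tuple[int, int] = (200, 400)
    positives_per_case_probs: Dict[int, float] = field(
        default_factory=lambda: {1: 0.55, 2: 0.30, 3: 0.15}
    )
    class_mix: Dict[str, float] = field(
        default_factory=lambda: {"VUS": 0.59, "likely_pathogenic": 0.22, "pathogenic": 0.19}
    )
    signal_strength: float = 1.0    # base positive shift, in SD units
    class_signal_scale: Dict[str, float] = field(
        default_factory=lambda: {"VUS": 1.0, "likely_pathogenic": 1.3, "pathogenic": 1.6}
    )
    phenotype_spurious_terms: int = 3
    phenotype_dropped_terms: int = 2
    missingness: float = 0.10
    prefilter_failures_per_case: int = 24

    def __post_init__(self) -> None:
        if self.n_terms < 3 or self.n_genes < 1 or self.n_cases < 1:
            raise ValueError("counts must be positive")
        for mix in (self.positives_per_case_probs, self.class_mix):
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"probabilities must sum to 1, got {total}")
        lo, hi = self.variants_per_case
        if not (0 < lo <= hi):
            raise ValueError("variants_per_case range invalid")

    @classmethod
    def from_yaml(cls, stream) -> "CohortSpec":
        data = yaml.safe_load(stream) or {}
        if "variants_per_case" in data:
            data["variants_per_case"] = tuple(data["variants_per_case"])
        if "positives_per_case_probs" in data:
            data["positives_per_case_probs"] = {
                int(k): v for k, v in data["positives_per_case_probs"].items()
            }
        return cls(**data)

    def to_yaml(self) -> str:
        d = asdict(self)
        d["variants_per_case"] = list(self.variants_per_case)
        return yaml.safe_dump(d, sort_keys=True)


# ---------------------------------------------------------------------------
# ontology + annotations
# ---------------------------------------------------------------------------

def _term_id(i: int) -> str:
    return f"HP:{i:07d}"


def generate_ontology(spec: CohortSpec) -> Tuple[OntologyGraph, GeneAnnotationMap]:
    """Random rooted DAG plus per-gene coherent-subtree annotations.

    Term i attaches to one uniformly chosen earlier term (two with
    probability ``branching``), so every term reaches the root.  Each gene
    anchors at a random non-root term and annotates a sample of the
    anchor's descendant neighborhood, giving genes locally coherent --- and
    partially overlapping --- phenotype profiles.
    """
    rng = substream(spec.seed, "ontology")
    parents: Dict[str, Set[str]] = {_term_id(1): set()}
    terms = [_term_id(1)]
    for i in range(2, spec.n_terms + 1):
        t = _term_id(i)
        ps = {terms[rng.integers(0, len(terms))]}
        if len(terms) > 1 and rng.random() < spec.branching:
            ps.add(terms[rng.integers(0, len(terms))])
        parents[t] = ps
        terms.append(t)
    graph = OntologyGraph(terms=set(terms), parents=parents)

    rng_ann = substream(spec.seed, "annotations")
    non_root = sorted(graph.terms - graph.roots)
    annotations: Dict[str, Set[str]] = {}
    for g in range(1, spec.n_genes + 1):
        gene = f"GENE{g:04d}"
        anchor = non_root[rng_ann.integers(0, len(non_root))]
        k = max(1, int(rng_ann.poisson(spec.annotations_per_gene)))

        def descendants(start: str, cap: int = 60) -> List[str]:
            pool = [start]
            frontier = [start]
            while frontier and len(pool) < cap:
                nxt: List[str] = []
                for t in frontier:
                    for c in sorted(graph.children.get(t, ())):
                        if c not in pool:
                            pool.append(c)
                            nxt.append(c)
                frontier = nxt
            return pool

        # descendant neighborhood of the anchor; if the anchor sits near a
        # leaf, ascend toward the root until the neighborhood can support k
        pool = descendants(anchor)
        node = anchor
        while len(pool) < k:
            ps = sorted(graph.parents.get(node, ()) - graph.roots)
            if not ps:
                break
            node = ps[int(rng_ann.integers(0, len(ps)))]
            pool = sorted(set(pool) | set(descendants(node)))
        k = min(k, len(pool))
        chosen = rng_ann.choice(len(pool), size=k, replace=False)
        annotations[gene] = {pool[i] for i in chosen}
    return graph, GeneAnnotationMap(annotations=annotations)


def ontology_to_obo(graph: OntologyGraph) -> str:
    """Serialize the DAG to OBO text (deterministic term order)."""
    out = io.StringIO()
    out.write("format-version: 1.2\n")
    for t in sorted(graph.terms):
        out.write(f"\n[Term]\nid: {t}\nname: synthetic phenotype {t}\n")
        for p in sorted(graph.parents.get(t, ())):
            out.write(f"is_a: {p}\n")
    return out.getvalue()


def annotations_to_tsv(annotations: GeneAnnotationMap) -> str:
    out = io.StringIO()
    out.write("#gene-symbol\thpo-term-id\n")
    for gene in sorted(annotations.annotations):
        for term in sorted(annotations.annotations[gene]):
            out.write(f"{gene}\t{term}\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# annotation background model
# ---------------------------------------------------------------------------

#: Numeric signal features planted on positives: name -> direction of the
#: impactful side (+1 higher is worse for the patient, -1 lower).  Together
#: with the six tilted categorical columns below and the two phenotype
#: scores these form 20 signal columns among the 95 encoded features.
SIGNAL_NUMERIC: Dict[str, int] = {
    "CADD Scaled": +1,
    "phylop100 conservation": +1,
    "phylop conservation": +1,
    "phastcon100 conservation": +1,
    "GERP rsScore": +1,
    "ADA Boost Splice Prediction": +1,
    "Random Forest Splice Prediction": +1,
    "Gnomad Genome total allele count": -1,
    "SIFT score": -1,
    "PolyPhen HV score": +1,
    "PolyPhen HD score": +1,
    "Meta SVM score": +1,
}

#: Categorical signal: feature name -> label whose frequency is tilted up
#: for positives (one encoded column each).
SIGNAL_CATEGORICAL: Dict[str, str] = {
    "HGMD assessment type": "DM",
    "HGMD association confidence": "High",
    "ClinVar Classification": "Pathogenic",
    "Meta Svm Prediction": "D",
    "PolyPhen HV Prediction": "D",
    "Effects": "Premature stop",
}

#: Encoded signal columns (for selection-recovery bookkeeping).
SIGNAL_COLUMNS: Tuple[str, ...] = (
    "HPO-cosine",
    "PyxisMap",
    *SIGNAL_NUMERIC.keys(),
    *(f"{name}_{label}" for name, label in SIGNAL_CATEGORICAL.items()),
)

# background (mu, sd) per numeric feature; anything unlisted is N(0, 1)
_NUMERIC_BG: Dict[str, Tuple[float, float]] = {
    "CADD Scaled": (12.0, 6.0),
    "phylop100 conservation": (0.5, 1.5),
    "phylop conservation": (0.5, 1.5),
    "phastcon100 conservation": (0.45, 0.25),
    "phastcon conservation": (0.45, 0.25),
    "GERP rsScore": (0.0, 2.5),
    "GERP element score": (200.0, 120.0),
    "ADA Boost Splice Prediction": (0.3, 0.2),
    "Random Forest Splice Prediction": (0.3, 0.2),
    "Splice site distance": (5000.0, 4000.0),
    "Haploinsufficiency score": (0.5, 0.2),
    "Gene intolerance percentile": (50.0, 25.0),
    "Missense Z-score": (1.0, 2.0),
    "pLI score": (0.4, 0.3),
    "CCR percentile": (50.0, 25.0),
    "LoFtool percentile": (50.0, 25.0),
    "Gene damage index": (5.0, 3.0),
    "S-het score": (0.1, 0.08),
    "Regulatory element score": (0.3, 0.2),
    "Segmental duplication fraction": (0.1, 0.1),
    "Repeat overlap fraction": (0.15, 0.12),
    "Mappability score": (0.9, 0.1),
    "Distance to gene boundary": (20000.0, 15000.0),
    "Transcript percentile": (50.0, 25.0),
    "SIFT score": (0.5, 0.25),
    "PolyPhen HV score": (0.45, 0.25),
    "PolyPhen HD score": (0.45, 0.25),
    "Meta SVM score": (0.0, 0.8),
    "Exon distance": (800.0, 600.0),
}

# categorical backgrounds: mean label count per variant, label weights
_CAT_BG: Dict[str, Tuple[float, Optional[List[float]]]] = {
    "HGMD assessment type": (0.3, [0.25, 0.2, 0.2, 0.2, 0.15]),
    "HGMD association confidence": (0.3, [0.3, 0.4, 0.3]),
    "ClinVar Classification": (0.5, [0.08, 0.10, 0.45, 0.20, 0.17]),
    "Meta Svm Prediction": (0.8, [0.3, 0.7]),
    "PolyPhen HV Prediction": (0.8, [0.3, 0.35, 0.35]),
    "PolyPhen HD Prediction": (0.8, [0.3, 0.35, 0.35]),
    "SIFT Prediction": (0.8, [0.35, 0.65]),
    "Effects": (1.4, [0.02, 0.04, 0.40, 0.18, 0.04, 0.05, 0.05, 0.14, 0.08]),
    "Gene disease association source": (1.2, [0.4, 0.2, 0.2, 0.2]),
    "Inheritance mode": (1.0, [0.45, 0.40, 0.10, 0.05]),
    "Variant impact": (1.0, [0.1, 0.45, 0.25, 0.2]),
    "Zygosity": (1.0, [0.75, 0.2, 0.05]),
}

ACMG_KEYS = ("VUS", "likely_pathogenic", "pathogenic")


@dataclass
class CohortData:
    """A generated cohort plus its ground truth."""

    variants: List[AnnotatedVariant]
    patient_terms: Dict[str, List[str]]        # case -> HPO terms
    truth: pd.DataFrame                        # planted positives + chronology
    blacklist: Set[str]
    cases: List[str]                           # chronological order

    def case_positive_counts(self) -> List[Tuple[str, int]]:
        counts = self.truth.groupby("case_id").size().to_dict()
        return [(c, int(counts.get(c, 0))) for c in self.cases]


def _draw_annotations(
    rng: np.random.Generator,
    specs: Sequence[FeatureSpec],
    is_positive: bool,
    shift: float,
    missingness: float,
) -> Dict[str, object]:
    """Raw annotation dict for one variant under the background model."""
    ann: Dict[str, object] = {}
    for s in specs:
        if s.name in ("HPO-cosine", "PyxisMap"):
            continue  # computed downstream by the phenoscore stage
        if rng.random() < missingness:
            continue
        if s.kind == "categorical":
            mean_count, weights = _CAT_BG.get(s.name, (0.8, None))
            vocab = list(s.vocabulary)
            p = np.asarray(weights) if weights is not None else np.full(len(vocab), 1 / len(vocab))
            p = p / p.sum()
            k = int(rng.poisson(mean_count))
            labels = [vocab[i] for i in rng.choice(len(vocab), size=k, p=p)] if k else []
            sig = SIGNAL_CATEGORICAL.get(s.name)
            if sig is not None and is_positive:
                extra = int(rng.binomial(2, min(0.95, 0.35 * shift)))
                labels.extend([sig] * extra)
            ann[s.name] = labels
            continue
        mu, sd = _NUMERIC_BG.get(s.name, (0.0, 1.0))
        direction = SIGNAL_NUMERIC.get(s.name, 0)
        if is_positive and direction:
            mu = mu + direction * shift * sd
        if s.is_allele_freq:
            # counts for rare variants: low Poisson, lower still for positives
            lam = 3.0 if not (is_positive and direction) else 3.0 * float(np.exp(-0.7 * shift))
            ann[s.name] = int(rng.poisson(lam))
            continue
        if s.kind == "numeric_multi":
            k = int(rng.integers(1, 4))
            vals = rng.normal(mu, sd, size=k)
            if s.expected_range is not None:
                vals = np.clip(vals, *s.expected_range)
            ann[s.name] = [float(v) for v in vals]
        else:
            v = float(rng.normal(mu, sd))
            if s.expected_range is not None:
                lo, hi = s.expected_range
                v = float(np.clip(v, lo, hi))
            ann[s.name] = v
    return ann


EFFECT_LABELS = [
    "Missense", "Synonymous", "Intronic", "UTR", "In-frame indel",
    "Canonical splice site", "Frameshift",
]


def generate_cohort(
    spec: CohortSpec,
    graph: OntologyGraph,
    annotations: GeneAnnotationMap,
    specs: Optional[Sequence[FeatureSpec]] = None,
) -> CohortData:
    """Generate probands, variants, planted positives and ground truth."""
    specs = list(specs) if specs is not None else reference_specs()
    rng = substream(spec.seed, "cohort")
    noise_rng = substream(spec.seed, "noise")
    genes = sorted(annotations.annotations)
    non_root = sorted(graph.terms - graph.roots)
    pos_counts = sorted(spec.positives_per_case_probs)
    pos_probs = [spec.positives_per_case_probs[k] for k in pos_counts]
    class_probs = [spec.class_mix[k] for k in ACMG_KEYS]

    variants: List[AnnotatedVariant] = []
    truth_rows: List[Dict[str, object]] = []
    patient_terms: Dict[str, List[str]] = {}
    blacklist: Set[str] = set()
    cases: List[str] = []
    key_counter = 0

    def next_key() -> str:
        nonlocal key_counter
        key_counter += 1
        chrom = 1 + (key_counter % 22)
        ref, alt = "AG"[key_counter % 2], "CT"[key_counter % 2]
        return f"chr{chrom}-{100000 + key_counter * 7}-{ref}-{alt}"

    def passing_fields() -> Dict[str, object]:
        total = int(rng.integers(20, 80))
        return {
            "total_depth": total,
            "alt_depth": int(rng.integers(max(8, total // 4), total + 1)),
            "pop_freq": (None if rng.random() < 0.5
                         else float(rng.uniform(0.0, 0.008))),
        }

    for ci in range(1, spec.n_cases + 1):
        case_id = f"case_{ci:04d}"
        cases.append(case_id)
        n_variants = int(rng.integers(spec.variants_per_case[0],
                                      spec.variants_per_case[1] + 1))
        n_pos = int(rng.choice(pos_counts, p=pos_probs))
        causal_genes = [genes[i] for i in rng.choice(len(genes), size=n_pos, replace=False)]

        # patient phenotype from causal-gene annotations, with noise
        terms: Set[str] = set()
        for g in causal_genes:
            terms |= annotations.annotations[g]
        n_drop = int(noise_rng.integers(0, spec.phenotype_dropped_terms + 1))
        if terms and n_drop:
            droppable = sorted(terms)
            drop = noise_rng.choice(len(droppable), size=min(n_drop, len(droppable) - 1),
                                    replace=False)
            terms -= {droppable[i] for i in drop}
        n_spur = int(noise_rng.integers(0, spec.phenotype_spurious_terms + 1))
        for i in noise_rng.choice(len(non_root), size=n_spur, replace=False):
            terms.add(non_root[i])
        if not terms:
            terms = {non_root[int(noise_rng.integers(0, len(non_root)))]}
        patient_terms[case_id] = sorted(terms)

        # planted positives
        for g in causal_genes:
            acmg = ACMG_KEYS[int(rng.choice(3, p=class_probs))]
            shift = spec.signal_strength * spec.class_signal_scale[acmg]
            key = next_key()
            vgenes = [g]
            if rng.random() < 0.15:
                vgenes.append(genes[int(rng.integers(0, len(genes)))])
            ann = _draw_annotations(rng, specs, True, shift, spec.missingness)
            effects = list(ann.get("Effects") or []) or ["Missense"]
            variants.append(AnnotatedVariant(
                key=key, case_id=case_id, genes=vgenes,
                transcript_effects=effects,
                gene_disease_assocs=["OMIM"],
                annotations=ann, label="reported", acmg_class=acmg,
                **passing_fields(),
            ))
            truth_rows.append({
                "case_id": case_id, "variant_key": key, "gene": g,
                "acmg_class": acmg, "chronology": ci,
            })

        # filter-passing negatives
        for _ in range(n_variants - n_pos):
            ann = _draw_annotations(rng, specs, False, 0.0, spec.missingness)
            vgenes = [genes[int(rng.integers(0, len(genes)))]]
            if rng.random() < 0.10:
                vgenes.append(genes[int(rng.integers(0, len(genes)))])
            effects = list(ann.get("Effects") or []) or \
                [EFFECT_LABELS[int(rng.integers(0, len(EFFECT_LABELS)))]]
            variants.append(AnnotatedVariant(
                key=next_key(), case_id=case_id, genes=vgenes,
                transcript_effects=effects,
                gene_disease_assocs=["OMIM"] if rng.random() < 0.9 else ["Orphanet"],
                annotations=ann, label="not_reported",
                **passing_fields(),
            ))

        # designed pre-filter failures, one failure mode each
        for _ in range(spec.prefilter_failures_per_case):
            mode = int(rng.integers(0, 6))
            fields = passing_fields()
            ann = _draw_annotations(rng, specs, False, 0.0, spec.missingness)
            effects = ["Missense"]
            assocs = ["OMIM"]
            key = next_key()
            if mode == 0:
                fields["total_depth"] = int(rng.integers(0, 8))
                fields["alt_depth"] = min(fields["alt_depth"], fields["total_depth"])
            elif mode == 1:
                fields["alt_depth"] = int(rng.integers(0, 4))
            elif mode == 2:
                fields["pop_freq"] = float(rng.uniform(0.05, 0.5))
            elif mode == 3:
                effects = []
            elif mode == 4:
                assocs = []
            else:
                blacklist.add(key)
            variants.append(AnnotatedVariant(
                key=key, case_id=case_id,
                genes=[genes[int(rng.integers(0, len(genes)))]],
                transcript_effects=effects, gene_disease_assocs=assocs,
                annotations=ann, label="not_reported", **fields,
            ))

    truth = pd.DataFrame(truth_rows,
                         columns=["case_id", "variant_key", "gene",
                                  "acmg_class", "chronology"])
    return CohortData(variants=variants, patient_terms=patient_terms,
                      truth=truth, blacklist=blacklist, cases=cases)


def truth_to_tsv(truth: pd.DataFrame) -> str:
    return truth.to_csv(sep="\t", index=False)


# ---------------------------------------------------------------------------
# focused benchmarks (matrix-level, bypassing the cohort machinery)
# ---------------------------------------------------------------------------

def make_selection_benchmark(
    seed: int,
    n_rows: int = 40_000,
    n_cols: int = 95,
    n_signal: int = 20,
    shift: float = 0.25,
    positive_rate: float = 0.10,
) -> Tuple[FeatureMatrix, List[str]]:
    """A matrix with ``n_signal`` label-shifted columns among pure noise.

    Returns the matrix and the names of the planted signal columns
    (every 5th column by construction).
    """
    rng = np.random.default_rng(seed)
    y = (rng.random(n_rows) < positive_rate).astype(np.int64)
    X = rng.normal(size=(n_rows, n_cols))
    signal_idx = list(range(0, n_cols, max(1, n_cols // n_signal)))[:n_signal]
    for j in signal_idx:
        X[y == 1, j] += shift
    cols = [f"f{j:03d}" for j in range(n_cols)]
    matrix = FeatureMatrix(
        X=pd.DataFrame(X, columns=cols),
        labels=y,
        case_ids=[f"case_{i % 40:03d}" for i in range(n_rows)],
        variant_keys=[f"v{i:06d}" for i in range(n_rows)],
    )
    return matrix, [cols[j] for j in signal_idx]


def make_imbalanced_training(
    seed: int,
    n_positive: int = 100,
    imbalance: int = 200,
    n_features: int = 20,
    n_informative: int = 10,
    shift: float = 1.0,
) -> FeatureMatrix:
    """A 1:``imbalance`` binary problem with informative features.

    Positives are mean-shifted by ``shift`` SDs on the first
    ``n_informative`` features; the rest are noise.
    """
    rng = np.random.default_rng(seed)
    n_neg = n_positive * imbalance
    n = n_positive + n_neg
    y = np.zeros(n, dtype=np.int64)
    y[:n_positive] = 1
    X = rng.normal(size=(n, n_features))
    X[:n_positive, :n_informative] += shift
    perm = rng.permutation(n)
    X, y = X[perm], y[perm]
    return FeatureMatrix(
        X=pd.DataFrame(X, columns=[f"f{j:02d}" for j in range(n_features)]),
        labels=y,
        case_ids=[f"case_{i % 50:03d}" for i in range(n)],
        variant_keys=[f"v{i:06d}" for i in range(n)],
    )
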