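"""Phenotype-driven gene scoring.

Two scores relate a patient's HPO term set to candidate genes:

* **cosine** — patient and gene are each represented as a binary
  P-dimensional vector over the non-root ontology terms, with bits set on
  the ancestor closure of their annotated terms; the score is the cosine
  of the angle between the two vectors.  For binary vectors this is
  ``|A ∩ B| / sqrt(|A| |B|)`` on the closed term sets.
* **rwr** — a random walk with restart diffuses probability mass from the
  patient's (closed) term nodes over the joint term∪gene graph (undirected
  ontology edges plus weighted gene–annotation edges); the stationary mass
  landing on gene nodes ranks genes by graph proximity to the phenotype.

Each variant then inherits the best score over the genes it overlaps.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np
import scipy.sparse as sp

from .ontology import GeneAnnotationMap, OntologyGraph, ancestor_closure

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# binary phenotype vectors and cosine similarity
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeVector:
    """Binary indicator vector over the graph's fixed non-root dims."""

    dims: Tuple[str, ...]
    bits: np.ndarray  # uint8, length P

    def __post_init__(self) -> None:
        if len(self.bits) != len(self.dims):
            raise ValueError("bits length does not match dims")

    @property
    def set_terms(self) -> Set[str]:
        return {d for d, b in zip(self.dims, self.bits) if b}


def build_term_vector(graph: OntologyGraph, terms: Iterable[str]) -> PhenotypeVector:
    """Binary vector with bits on the ancestor closure of *terms* (roots excluded).

    An empty term set yields the zero vector; cosine against it is 0 by
    convention.
    """
    bits = np.zeros(graph.P, dtype=np.uint8)
    for t in ancestor_closure(graph, terms):
        bits[graph.dim_index[t]] = 1
    return PhenotypeVector(dims=graph.dims, bits=bits)


def cosine_score(u: PhenotypeVector, v: PhenotypeVector) -> float:
    """Cosine of the angle between two phenotype vectors, 0 for zero vectors."""
    if u.dims != v.dims:
        raise ValueError("vectors built over different ontologies")
    nu = int(u.bits.sum())
    nv = int(v.bits.sum())
    if nu == 0 or nv == 0:
        return 0.0
    dot = int((u.bits & v.bits).sum())
    return min(1.0, dot / float(np.sqrt(nu) * np.sqrt(nv)))


@dataclass
class GeneScoreTable:
    """One score per gene from a single method ('cosine' or 'rwr')."""

    method: str
    scores: Dict[str, float]

    def ranked(self) -> List[Tuple[str, float]]:
        """Genes sorted by descending score, ties broken by gene name."""
        return sorted(self.scores.items(), key=lambda kv: (-kv[1], kv[0]))


def gene_closures(graph: OntologyGraph, annotations: GeneAnnotationMap) -> Dict[str, Set[str]]:
    """Ancestor closures of every gene's annotation set (cached per call site)."""
    return {g: ancestor_closure(graph, ts) for g, ts in annotations.annotations.items()}


def score_genes_cosine(
    graph: OntologyGraph,
    annotations: GeneAnnotationMap,
    patient_terms: Iterable[str],
    *,
    closures: Dict[str, Set[str]] | None = None,
) -> GeneScoreTable:
    """Cosine score of every annotated gene against the patient's phenotype.

    Works on closed term sets directly (equivalent to the binary-vector dot
    product, but sparse).  Pass precomputed *closures* when scoring many
    patients on the same annotation set.
    """
    patient = ancestor_closure(graph, patient_terms)
    np_pat = np.sqrt(len(patient)) if patient else 0.0
    if closures is None:
        closures = gene_closures(graph, annotations)
    scores: Dict[str, float] = {}
    for gene, closed in closures.items():
        if not patient or not closed:
            scores[gene] = 0.0
            continue
        overlap = len(patient & closed)
        scores[gene] = min(1.0, overlap / (np_pat * np.sqrt(len(closed))))
    return GeneScoreTable(method="cosine", scores=scores)


# ---------------------------------------------------------------------------
# random walk with restart
# ---------------------------------------------------------------------------

@dataclass
class RWRConfig:
    """Random-walk-with-restart parameters.

    restart_prob:
        Probability of jumping back to the patient's term nodes at each
        step; default 0.1.
    tol:
        L1 convergence tolerance on successive iterates.
    max_iter:
        Iteration cap; non-convergence warns and returns the best iterate.
    gene_edge_weight:
        Weight of gene–term annotation edges relative to ontology edges
        (which have weight 1).
    restart_on_closure:
        Spread the restart mass over the patient's closed term set
        (default) or only over the directly given terms.
    """

    restart_prob: float = 0.1
    tol: float = 1e-10
    max_iter: int = 1000
    gene_edge_weight: float = 1.0
    restart_on_closure: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.restart_prob <= 1.0):
            raise ValueError("restart_prob must be in (0, 1]")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class RWRGraph:
    """Column-stochastic transition structure over term ∪ gene nodes."""

    nodes: Tuple[str, ...]           # terms first, then gene nodes ("gene:" prefix)
    node_index: Dict[str, int]
    W: sp.csc_matrix                 # column-stochastic transition matrix
    gene_slice: slice                # rows holding gene nodes
    gene_names: Tuple[str, ...]


GENE_PREFIX = "gene:"


def build_rwr_graph(
    graph: OntologyGraph,
    annotations: GeneAnnotationMap,
    cfg: RWRConfig | None = None,
) -> RWRGraph:
    """Build the undirected term∪gene walk graph and column-normalize it.

    Edges: term–parent (weight 1) and gene–term (weight
    ``cfg.gene_edge_weight``).  Isolated nodes get a self-loop so every
    column sums to exactly 1.
    """
    cfg = cfg or RWRConfig()
    if not annotations.annotations:
        raise ValueError("annotations must be non-empty")
    terms = sorted(graph.terms)
    genes = sorted(annotations.annotations)
    nodes = tuple(terms) + tuple(GENE_PREFIX + g for g in genes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)

    rows: List[int] = []
    cols: List[int] = []
    vals: List[float] = []

    def add_undirected(i: int, j: int, w: float) -> None:
        rows.extend((i, j))
        cols.extend((j, i))
        vals.extend((w, w))

    for t in terms:
        for p in graph.parents.get(t, ()):
            if p in index:
                add_undirected(index[t], index[p], 1.0)
    for g, ts in annotations.annotations.items():
        gi = index[GENE_PREFIX + g]
        for t in ts:
            if t in index:
                add_undirected(gi, index[t], cfg.gene_edge_weight)

    A = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()
    colsum = np.asarray(A.sum(axis=0)).ravel()
    isolated = np.where(colsum == 0)[0]
    if isolated.size:
        A = A + sp.coo_matrix(
            (np.ones(isolated.size), (isolated, isolated)), shape=(n, n)
        ).tocsc()
        colsum[isolated] = 1.0
    # Column normalization makes each column a probability distribution.
    W = A @ sp.diags(1.0 / colsum)
    return RWRGraph(
        nodes=nodes,
        node_index=index,
        W=W.tocsc(),
        gene_slice=slice(len(terms), n),
        gene_names=tuple(genes),
    )


def rwr_stationary(
    rwr: RWRGraph, restart: np.ndarray, cfg: RWRConfig
) -> np.ndarray:
    """Iterate ``p <- (1-r) W p + r p0`` to the stationary distribution."""
    r = cfg.restart_prob
    p = restart.copy()
    W = rwr.W
    for _ in range(cfg.max_iter):
        p_next = (1.0 - r) * (W @ p) + r * restart
        delta = float(np.abs(p_next - p).sum())
        p = p_next
        if delta < cfg.tol:
            break
    else:
        warnings.warn(
            f"RWR did not converge within {cfg.max_iter} iterations "
            f"(last L1 change {delta:.3g}); returning best iterate"
        )
    total = float(p.sum())
    if abs(total - 1.0) > 1e-10:
        raise AssertionError(f"RWR mass not conserved: sum={total!r}")
    return p


def rwr_scores(
    rwr: RWRGraph,
    graph: OntologyGraph,
    patient_terms: Iterable[str],
    cfg: RWRConfig | None = None,
) -> GeneScoreTable:
    """Stationary RWR mass on gene nodes, restarting from the patient's terms.

    The restart vector is uniform over the patient's closed term set (or the
    directly given terms when ``cfg.restart_on_closure`` is False).  Terms
    absent from the walk graph are ignored; an empty restart set raises.
    """
    cfg = cfg or RWRConfig()
    patient_terms = list(patient_terms)
    if not patient_terms:
        raise ValueError("patient_terms must be non-empty")
    if cfg.restart_on_closure:
        restart_terms = ancestor_closure(graph, patient_terms) or set(patient_terms)
    else:
        restart_terms = set(patient_terms)
    idx = [rwr.node_index[t] for t in restart_terms if t in rwr.node_index]
    if not idx:
        raise ValueError("no patient term maps to a walk-graph node")
    p0 = np.zeros(len(rwr.nodes))
    p0[idx] = 1.0 / len(idx)
    p = rwr_stationary(rwr, p0, cfg)
    gene_mass = p[rwr.gene_slice]
    return GeneScoreTable(
        method="rwr",
        scores={g: float(s) for g, s in zip(rwr.gene_names, gene_mass)},
    )


def annotate_phenotype_scores(
    variants,
    graph: OntologyGraph,
    annotations: GeneAnnotationMap,
    patient_terms: Dict[str, Sequence[str]],
    cfg: RWRConfig | None = None,
    *,
    cosine_feature: str = "HPO-cosine",
    rwr_feature: str = "PyxisMap",
) -> None:
    """Attach the two per-variant phenotype scores as raw annotations.

    For every case, scores all genes once (cosine and RWR) against the
    case's term list, then writes each variant's best-gene score into its
    ``annotations`` map under *cosine_feature* / *rwr_feature*.  Cases
    without a term list leave their variants unannotated (the encoder's
    default applies downstream).
    """
    cfg = cfg or RWRConfig()
    closures = gene_closures(graph, annotations)
    rwr = build_rwr_graph(graph, annotations, cfg)
    by_case: Dict[str, list] = {}
    for v in variants:
        by_case.setdefault(v.case_id, []).append(v)
    for case_id in sorted(by_case):
        terms = list(patient_terms.get(case_id, ()))
        if not terms:
            logger.warning("case %s has no phenotype terms; scores left missing", case_id)
            continue
        cos = score_genes_cosine(graph, annotations, terms, closures=closures)
        walk = rwr_scores(rwr, graph, terms, cfg)
        for v in by_case[case_id]:
            v.annotations[cosine_feature] = best_gene_score_per_variant(v.genes, cos)
            v.annotations[rwr_feature] = best_gene_score_per_variant(v.genes, walk)


def best_gene_score_per_variant(
    variant_genes: Sequence[str], table: GeneScoreTable
) -> float:
    """Maximum score over the variant's genes; unscored genes floor at 0."""
    best = 0.0
    for g in variant_genes:
        best = max(best, table.scores.get(g, 0.0))
    return best
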