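"""Shared fixtures: toy ontologies, small cohorts, random-DAG helpers."""

from __future__ import annotations

import io
from typing import Dict, List, Set, Tuple

import numpy as np
import pytest

from varprior.ontology import OntologyGraph, parse_obo
from varprior.synthetic import CohortSpec, generate_cohort, generate_ontology

CHAIN_OBO = """\
format-version: 1.2

[Term]
id: HP:A
name: root

[Term]
id: HP:B
name: mid
is_a: HP:A

[Term]
id: HP:C
name: leaf
is_a: HP:B
"""

DIAMOND_OBO = """\
format-version: 1.2

[Term]
id: HP:A

[Term]
id: HP:B
is_a: HP:A

[Term]
id: HP:C
is_a: HP:A

[Term]
id: HP:D
is_a: HP:B
is_a: HP:C
"""


@pytest.fixture
def chain_graph() -> OntologyGraph:
    return parse_obo(io.StringIO(CHAIN_OBO))


@pytest.fixture
def diamond_graph() -> OntologyGraph:
    return parse_obo(io.StringIO(DIAMOND_OBO))


def random_dag(
    rng: np.random.Generator, n_terms: int, second_parent_prob: float = 0.2
) -> OntologyGraph:
    """Random rooted DAG: term i attaches to earlier terms only (acyclic)."""
    terms = [f"T{i:03d}" for i in range(n_terms)]
    parents: Dict[str, Set[str]] = {terms[0]: set()}
    for i in range(1, n_terms):
        ps = {terms[int(rng.integers(0, i))]}
        if i > 1 and rng.random() < second_parent_prob:
            ps.add(terms[int(rng.integers(0, i))])
        parents[terms[i]] = ps
    return OntologyGraph(terms=set(terms), parents=parents)


def brute_force_closure(graph: OntologyGraph, terms) -> Set[str]:
    """Independent oracle: DFS reachability over parent edges, roots dropped."""
    reached: Set[str] = set()

    def visit(t: str) -> None:
        if t in reached:
            return
        reached.add(t)
        for p in graph.parents.get(t, ()):
            visit(p)

    for t in terms:
        visit(t)
    return reached - graph.roots


SMALL_SPEC = CohortSpec(
    seed=7, n_cases=20, variants_per_case=(60, 100),
    n_terms=150, n_genes=200, prefilter_failures_per_case=12,
)


@pytest.fixture(scope="session")
def small_cohort():
    """One small generated cohort shared across tests (read-only)."""
    graph, gam = generate_ontology(SMALL_SPEC)
    cohort = generate_cohort(SMALL_SPEC, graph, gam)
    return SMALL_SPEC, graph, gam, cohort
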