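"""Phenotype-ontology ingestion and ancestor closure.

Parses the OBO flat-file dialect used by the Human Phenotype Ontology
(``[Term]`` stanzas with ``id``/``is_a``/``is_obsolete`` lines) into a
lightweight DAG, and loads gene-to-phenotype annotation tables.  The
ancestor closure over ``is_a`` edges is the primitive every phenotype
vector is built from: a patient (or gene) annotated with a specific term
is implicitly annotated with every more general ancestor of that term.

The root term carries no phenotype information — every closed set would
contain it — so it is excluded from closures and from the vector
dimensions.  With multiple roots, all roots are excluded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Set, TextIO, Tuple, Union

logger = logging.getLogger(__name__)


class OboParseError(ValueError):
    """Raised for malformed OBO input, naming the offending line."""


class OntologyCycleError(ValueError):
    """Raised when the is_a graph contains a cycle; carries one witness cycle."""

    def __init__(self, cycle: List[str]):
        self.cycle = cycle
        super().__init__("cycle in is_a graph: " + " -> ".join(cycle + [cycle[0]]))


@dataclass
class OntologyGraph:
    """A rooted DAG of phenotype terms linked by ``is_a`` edges.

    Attributes
    ----------
    terms:
        All non-obsolete term IDs.
    parents:
        Map from term to its set of direct ``is_a`` parents.
    roots:
        Terms with no parents.  A well-formed HPO has exactly one.
    """

    terms: Set[str]
    parents: Dict[str, Set[str]]
    roots: Set[str] = field(init=False)
    children: Dict[str, Set[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.roots = {t for t in self.terms if not self.parents.get(t)}
        self.children = {t: set() for t in self.terms}
        for child, ps in self.parents.items():
            for p in ps:
                self.children[p].add(child)
        self._check_acyclic()
        # Fixed, sorted dimension order so patient and gene vectors built on
        # the same graph are always comparable.
        self.dims: Tuple[str, ...] = tuple(sorted(self.terms - self.roots))
        self.dim_index: Dict[str, int] = {t: i for i, t in enumerate(self.dims)}

    @property
    def root(self) -> str:
        """The unique root; raises if the graph has several."""
        if len(self.roots) != 1:
            raise ValueError(f"graph has {len(self.roots)} roots, not 1")
        return next(iter(self.roots))

    @property
    def P(self) -> int:
        """Vector dimensionality: number of non-root terms."""
        return len(self.dims)

    def _check_acyclic(self) -> None:
        # Iterative three-color DFS over parent edges; recursion-free so deep
        # ontologies do not hit the interpreter stack limit.
        WHITE, GRAY, BLACK = 0, 1, 2
        color = {t: WHITE for t in self.terms}
        for start in self.terms:
            if color[start] != WHITE:
                continue
            stack: List[Tuple[str, Iterable[str]]] = [(start, iter(self.parents.get(start, ())))]
            color[start] = GRAY
            path = [start]
            while stack:
                node, it = stack[-1]
                advanced = False
                for nxt in it:
                    if nxt not in self.terms:
                        continue
                    if color[nxt] == GRAY:
                        raise OntologyCycleError(path[path.index(nxt):])
                    if color[nxt] == WHITE:
                        color[nxt] = GRAY
                        stack.append((nxt, iter(self.parents.get(nxt, ()))))
                        path.append(nxt)
                        advanced = True
                        break
                if not advanced:
                    color[node] = BLACK
                    stack.pop()
                    path.pop()


def parse_obo(stream: Union[TextIO, Iterable[str]]) -> OntologyGraph:
    """Parse OBO text into an :class:`OntologyGraph`.

    Only ``[Term]`` stanzas are interpreted, and within them only ``id:``,
    ``is_a:`` and ``is_obsolete:`` lines.  Obsolete terms are dropped
    (``replaced_by`` is not followed).  Parent references to terms that do
    not appear in the file raise, as do stanzas without an ``id``.
    """
    terms: Set[str] = set()
    parents: Dict[str, Set[str]] = {}
    cur_id: str | None = None
    cur_parents: Set[str] = set()
    cur_obsolete = False
    in_term = False
    stanza_line = 0

    def flush() -> None:
        nonlocal cur_id, cur_parents, cur_obsolete
        if in_term:
            if cur_id is None:
                raise OboParseError(f"[Term] stanza starting at line {stanza_line} has no id:")
            if not cur_obsolete:
                terms.add(cur_id)
                parents[cur_id] = cur_parents
        cur_id, cur_parents, cur_obsolete = None, set(), False

    for lineno, raw in enumerate(stream, start=1):
        line = raw.split("!", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            flush()
            in_term = line == "[Term]"
            stanza_line = lineno
            continue
        if not in_term:
            continue
        if ":" not in line:
            raise OboParseError(f"line {lineno}: malformed tag-value line: {raw.strip()!r}")
        tag, value = line.split(":", 1)
        tag = tag.strip()
        value = value.strip()
        if tag == "id":
            if cur_id is not None:
                raise OboParseError(f"line {lineno}: duplicate id: in stanza")
            cur_id = value
        elif tag == "is_a":
            cur_parents.add(value.split()[0])
        elif tag == "is_obsolete":
            cur_obsolete = value.lower() == "true"
    flush()

    # Drop edges into obsolete (absent) parents rather than resurrecting them.
    for t in terms:
        missing = parents[t] - terms
        if missing:
            parents[t] = parents[t] - missing
    return OntologyGraph(terms=terms, parents=parents)


@dataclass
class GeneAnnotationMap:
    """Map from gene symbol to its directly annotated term IDs."""

    annotations: Dict[str, Set[str]]

    def __getitem__(self, gene: str) -> Set[str]:
        return self.annotations[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self.annotations

    def __len__(self) -> int:
        return len(self.annotations)

    def genes(self) -> List[str]:
        return sorted(self.annotations)


def load_gene_annotations(
    stream: Union[TextIO, Iterable[str]],
    graph: OntologyGraph,
    *,
    gene_col: int = 0,
    term_col: int = 1,
    strict: bool = False,
) -> GeneAnnotationMap:
    """Load a gene-to-phenotype TSV (gene symbol, HPO term ID per row).

    Comment lines start with ``#``.  Column indices are configurable to
    accommodate the different layouts of HPO ``genes_to_phenotype.txt``
    releases.  Rows referencing terms absent from *graph* are skipped with
    a warning, or raise when ``strict=True``.  Duplicate rows collapse.
    """
    out: Dict[str, Set[str]] = {}
    ncols = max(gene_col, term_col) + 1
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < ncols:
            raise OboParseError(f"line {lineno}: expected >= {ncols} columns, got {len(fields)}")
        gene, term = fields[gene_col].strip(), fields[term_col].strip()
        if term not in graph.terms:
            msg = f"line {lineno}: term {term!r} (gene {gene!r}) not in ontology"
            if strict:
                raise KeyError(msg)
            warnings.warn(msg)
            logger.warning("skipping annotation row: %s", msg)
            continue
        out.setdefault(gene, set()).add(term)
    return GeneAnnotationMap(annotations=out)


def ancestor_closure(graph: OntologyGraph, terms: Iterable[str]) -> Set[str]:
    """Input terms plus all transitive ``is_a`` ancestors, roots excluded.

    Raises ``KeyError`` naming the first unknown term.
    """
    closed: Set[str] = set()
    stack: List[str] = []
    for t in terms:
        if t not in graph.terms:
            raise KeyError(f"unknown term: {t!r}")
        if t not in graph.roots:
            closed.add(t)
        stack.append(t)
    seen = set(stack)
    while stack:
        node = stack.pop()
        for p in graph.parents.get(node, ()):
            if p in seen:
                continue
            seen.add(p)
            if p not in graph.roots:
                closed.add(p)
            stack.append(p)
    return closed
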