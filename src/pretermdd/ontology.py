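"""Ontology-aware phenotype derivation.

Prematurity classification under the WHO rule, Human Phenotype Ontology
(HPO) descendant-closure queries, non-redundant organ-system counting,
and LMS-based birthweight z-scores.

The ontology is held as a directed acyclic graph with ``is_a`` edges
pointing child -> parent (the orientation OBO files use); a term's
*descendant closure* is itself plus everything that can reach it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .exceptions import ConfigurationError, DataError, OntologyLookupError

logger = logging.getLogger(__name__)

WHO_BOUNDS = {"extreme": (22, 27), "very": (28, 31), "moderate": (32, 36), "term": (37, 44)}


def classify_prematurity(gestational_weeks: float) -> str:
    """WHO gestational-age category from completed weeks.

    Half-open boundaries: extreme < 28, very 28 to < 32, moderate 32 to
    < 37, term >= 37 completed weeks. Fractional input floors to
    completed weeks (with a warning); out-of-range input raises.
    """
    w = float(gestational_weeks)
    if w != int(w):
        logger.warning("fractional gestational weeks %s floored to completed weeks", w)
    w = math.floor(w)
    if not 22 <= w <= 44:
        raise DataError(f"gestational weeks {gestational_weeks!r} outside [22, 44]")
    if w >= 37:
        return "term"
    if w >= 32:
        return "moderate"
    if w >= 28:
        return "very"
    return "extreme"


class OntologyGraph:
    """A rooted DAG of phenotype terms with is_a edges (child -> parent)."""

    def __init__(self, graph: nx.DiGraph, root: str):
        if root not in graph:
            raise ConfigurationError(f"root {root!r} not in graph")
        if not nx.is_directed_acyclic_graph(graph):
            raise DataError("ontology graph contains a cycle")
        unreachable = [
            t for t in graph.nodes if t != root and not nx.has_path(graph, t, root)
        ]
        if unreachable:
            raise DataError(
                f"{len(unreachable)} terms cannot reach the root "
                f"(e.g. {unreachable[:3]})"
            )
        self.graph = graph
        self.root = root
        self._closure_cache: dict[str, frozenset[str]] = {}

    @classmethod
    def from_edges(cls, edges, root: str, extra_terms=()) -> "OntologyGraph":
        """Build from (child, parent) pairs."""
        g = nx.DiGraph()
        g.add_node(root)
        g.add_nodes_from(extra_terms)
        g.add_edges_from(edges)
        return cls(g, root)

    @classmethod
    def from_obo(cls, path, root: str | None = None) -> "OntologyGraph":
        """Read an OBO file, keeping only non-obsolete terms and is_a edges."""
        import obonet

        multi = obonet.read_obo(path)  # skips obsolete stanzas by default
        g = nx.DiGraph()
        g.add_nodes_from(multi.nodes(data=True))
        for u, v, key in multi.edges(keys=True):
            if key == "is_a":
                g.add_edge(u, v)
        if root is None:
            roots = [t for t in g.nodes if g.out_degree(t) == 0]
            if len(roots) != 1:
                raise DataError(f"cannot infer a unique root; candidates: {roots[:5]}")
            root = roots[0]
        return cls(g, root)

    @property
    def terms(self):
        return set(self.graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def label(self, term: str) -> str:
        if term not in self.graph:
            raise OntologyLookupError(term)
        return self.graph.nodes[term].get("name", term)

    def descendant_closure(self, term: str) -> frozenset[str]:
        """The term plus all transitive descendants, as a set."""
        if term not in self.graph:
            raise OntologyLookupError(term)
        cached = self._closure_cache.get(term)
        if cached is None:
            cached = frozenset(nx.ancestors(self.graph, term)) | {term}
            self._closure_cache[term] = cached
        return cached


def descendant_closure(graph: OntologyGraph, term: str) -> frozenset[str]:
    return graph.descendant_closure(term)


def has_phenotype(proband_terms, graph: OntologyGraph, query_term: str) -> bool:
    """True iff the proband carries the query term or any descendant of it."""
    return bool(set(proband_terms) & graph.descendant_closure(query_term))


@dataclass
class OrganSystemMap:
    """Many-to-one assignment of terms to top-level organ-system roots."""

    system_roots: list[str]
    assignment: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, term: str) -> str:
        return self.assignment[term]

    def get(self, term: str, default=None):
        return self.assignment.get(term, default)


def assign_organ_systems(
    graph: OntologyGraph,
    system_roots,
    priority: list[str] | None = None,
) -> OrganSystemMap:
    """Assign each term under >=1 system root to exactly one root.

    A term belonging to several systems goes to the root with the
    smallest descendant closure (the most specific system); residual
    ties break lexicographically on root ID. A ``priority`` list, if
    given, overrides the rule: the earliest listed root containing the
    term wins.
    """
    system_roots = list(system_roots)
    for r in system_roots:
        if r not in graph:
            raise ConfigurationError(f"system root {r!r} not in ontology")
    closures = {r: graph.descendant_closure(r) for r in system_roots}
    assignment: dict[str, str] = {}
    all_terms = set().union(*closures.values()) if closures else set()
    for term in all_terms:
        candidates = [r for r in system_roots if term in closures[r]]
        if priority:
            ordered = [r for r in priority if r in candidates]
            chosen = ordered[0] if ordered else min(
                candidates, key=lambda r: (len(closures[r]), r)
            )
        else:
            chosen = min(candidates, key=lambda r: (len(closures[r]), r))
        assignment[term] = chosen
    return OrganSystemMap(system_roots=system_roots, assignment=assignment)


def count_affected_systems(proband_terms, mapping: OrganSystemMap) -> int:
    """Number of distinct organ systems a proband's terms map to.

    A term and its same-system ancestor count once; terms outside every
    system are ignored (a warning is logged for unknown terms).
    """
    systems = set()
    for t in set(proband_terms):
        root = mapping.get(t)
        if root is None:
            logger.debug("term %s not assigned to any organ system; ignored", t)
        else:
            systems.add(root)
    return len(systems)


class LmsReference:
    """LMS (skewness / median / coefficient-of-variation) growth reference.

    Exact lookup on (sex, completed week) - no interpolation.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"sex", "gestational_weeks", "L", "M", "S"}
        if not required.issubset(table.columns):
            raise DataError(f"LMS reference needs columns {sorted(required)}")
        if (table["M"] <= 0).any() or (table["S"] <= 0).any():
            raise DataError("LMS reference requires M > 0 and S > 0")
        if table.duplicated(["sex", "gestational_weeks"]).any():
            raise DataError("duplicate (sex, week) keys in LMS reference")
        self._lookup = {
            (int(r.sex), int(r.gestational_weeks)): (float(r.L), float(r.M), float(r.S))
            for r in table.itertuples()
        }

    @classmethod
    def from_tsv(cls, path) -> "LmsReference":
        return cls(pd.read_csv(path, sep="\t"))

    def params(self, sex: int, weeks: int) -> tuple[float, float, float]:
        key = (int(sex), int(weeks))
        if key not in self._lookup:
            raise DataError(f"no LMS reference row for sex={sex}, weeks={weeks}")
        return self._lookup[key]


def birthweight_zscore(
    weight_g: float, sex: int, gestational_weeks: int, ref: LmsReference
) -> float:
    """LMS z-score: ((x/M)^L - 1)/(L*S), or ln(x/M)/S in the L -> 0 limit."""
    if not weight_g > 0:
        raise DataError(f"birthweight must be positive, got {weight_g!r}")
    L, M, S = ref.params(sex, gestational_weeks)
    ratio = weight_g / M
    if abs(L) > 1e-8:
        return (ratio**L - 1.0) / (L * S)
    return math.log(ratio) / S


def filter_birthweight_outliers(
    cohort: pd.DataFrame, ref: LmsReference, threshold: float = 5.0
) -> pd.DataFrame:
    """Drop probands with |birthweight z| above ``threshold`` (default 5 SD)."""
    z = cohort.apply(
        lambda r: birthweight_zscore(
            r["birthweight_g"], r["sex"], r["gestational_weeks"], ref
        ),
        axis=1,
    ) if len(cohort) else pd.Series(dtype=float)
    keep = z.abs() <= threshold
    removed = int((~keep).sum())
    if removed:
        logger.info("removed %d probands with |birthweight z| > %s", removed, threshold)
    return cohort[keep].copy() if len(cohort) else cohort.copy()


def toy_ontology(
    n_systems: int = 5, depth: int = 2, branching: int = 3
) -> tuple[OntologyGraph, list[str]]:
    """Deterministic small phenotype DAG for demos and fixtures.

    Returns the graph and the list of system roots (direct children of
    the global root), each carrying a ``branching``-ary subtree of the
    given depth.
    """
    edges = []
    roots = []
    for s in range(n_systems):
        sr = f"SYS:{s + 1:03d}"
        roots.append(sr)
        edges.append((sr, "ROOT:000"))
        frontier = [sr]
        for d in range(depth):
            nxt = []
            for i, parent in enumerate(frontier):
                for b in range(branching):
                    child = f"T:{s + 1:02d}{d + 1:01d}{i:02d}{b:01d}"
                    edges.append((child, parent))
                    nxt.append(child)
            frontier = nxt
    return OntologyGraph.from_edges(edges, root="ROOT:000"), roots
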