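import numpy as np
import pandas as pd
import pytest

from pretermdd import SimConfig
from pretermdd import ontology as ont
from pretermdd import simulate as sim


@pytest.fixture(scope="session")
def small_cohort():
    """A 3000-proband synthetic cohort shared by read-only tests."""
    return sim.simulate_cohort(SimConfig(n_probands=3000, seed=11))


@pytest.fixture(scope="session")
def rate_table():
    return sim.synthetic_gene_rate_table(n_genes=40, seed=11)


@pytest.fixture(scope="session")
def toy_graph():
    graph, roots = ont.toy_ontology(n_systems=4, depth=2, branching=3)
    return graph, roots


def random_dag(n_terms: int, seed: int, extra_edge_prob: float = 0.25):
    """Random rooted DAG: node i attaches to one parent j < i, plus
    occasional extra parents (multiple parentage)."""
    rng = np.random.default_rng(seed)
    nodes = [f"N{i:03d}" for i in range(n_terms)]
    edges = []
    for i in range(1, n_terms):
        j = int(rng.integers(0, i))
        edges.append((nodes[i], nodes[j]))
        if i > 1 and rng.random() < extra_edge_prob:
            k = int(rng.integers(0, i))
            if k != j:
                edges.append((nodes[i], nodes[k]))
    return ont.OntologyGraph.from_edges(edges, root=nodes[0]), nodes


def brute_force_closure(graph: ont.OntologyGraph, term: str) -> set:
    """Exhaustive DFS over child->parent edges reversed (independent of
    the networkx-based implementation)."""
    children = {}
    for u, v in graph.graph.edges:
        children.setdefault(v, []).append(u)
    seen, stack = set(), [term]
    while stack:
        t = stack.pop()
        if t in seen:
            continue
        seen.add(t)
        stack.extend(children.get(t, []))
    return seen


@pytest.fixture
def diagnosis_table():
    """Deterministic single-gene diagnosis table for enrichment tests."""
    rng = np.random.default_rng(17)
    n = 1200
    genes = rng.choice(["GENE_A", "GENE_B", "GENE_C", "GENE_D", "GENE_E"],
                       size=n, p=[0.35, 0.25, 0.2, 0.15, 0.05])
    cat = rng.choice(["term", "moderate", "very", "extreme"], size=n,
                     p=[0.8, 0.14, 0.04, 0.02])
    return pd.DataFrame({
        "proband_id": [f"D{i:05d}" for i in range(n)],
        "diagnosed_gene": genes,
        "tier": rng.choice(["P/LP", "broader"], size=n, p=[0.8, 0.2]),
        "preterm": (cat != "term").astype(int),
        "gestational_category": cat,
    })
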