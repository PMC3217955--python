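import numpy as np
import pytest

from orthogo.ontology import OntologyGraph, OntologyTerm


def go(i: int) -> str:
    return f"GO:{i:07d}"


def build_dag(parents, namespace="biological_process", relation="is_a"):
    """Build an OntologyGraph from {name: [parent names]}; returns (graph, ids).

    Names are mapped to sequential GO ids in sorted order.
    """
    names = sorted(set(parents) | {p for ps in parents.values() for p in ps})
    ids = {name: go(i + 1) for i, name in enumerate(names)}
    terms = [
        OntologyTerm(
            id=ids[name],
            name=name,
            namespace=namespace,
            parents=frozenset((ids[p], relation) for p in parents.get(name, [])),
        )
        for name in names
    ]
    return OntologyGraph(terms), ids


def random_dag(rng: np.random.Generator, n_nodes: int) -> OntologyGraph:
    """A random single-namespace DAG: node 0 is the root, node i draws 1-2
    parents among nodes 0..i-1."""
    terms = [OntologyTerm(go(1), "root", "biological_process")]
    for i in range(1, n_nodes):
        k = int(rng.integers(1, min(3, i + 1)))
        parents = rng.choice(i, size=k, replace=False)
        terms.append(
            OntologyTerm(
                go(i + 1),
                f"node {i}",
                "biological_process",
                frozenset((go(int(p) + 1), "is_a") for p in parents),
            )
        )
    return OntologyGraph(terms)


def ancestors_oracle(graph: OntologyGraph, term: str, relations) -> set:
    """Reachability by exhaustive DFS over the selected relations."""
    out, stack = set(), [term]
    while stack:
        node = stack.pop()
        for parent, relation in graph.terms[node].parents:
            if relation in relations and parent not in out:
                out.add(parent)
                stack.append(parent)
    return out


@pytest.fixture
def chain_graph():
    """a -> b -> root (is_a chain)."""
    return build_dag({"root": [], "b": ["root"], "a": ["b"]})


@pytest.fixture
def diamond_graph():
    """a below both b and c, which are both below d (the root)."""
    return build_dag({"d": [], "b": ["d"], "c": ["d"], "a": ["b", "c"]})
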