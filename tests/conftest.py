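import networkx as nx
import pytest

from gofunc.ontology import AnnotationTable, OntologyGraph


def build_graph(edges, namespace=None, obsolete=None):
    """Hand-build an OntologyGraph from (child, parent[, relation]) tuples."""
    g = nx.DiGraph()
    nodes = set()
    for e in edges:
        child, parent = e[0], e[1]
        rel = e[2] if len(e) > 2 else "is_a"
        g.add_edge(child, parent, relation=rel)
        nodes |= {child, parent}
    ns = namespace or {t: "MFO" for t in nodes}
    for t in ns:
        g.add_node(t)
    return OntologyGraph(graph=g, namespace=ns, obsolete=set(obsolete or ()))


@pytest.fixture
def chain_graph():
    """a -> b -> c with c the root."""
    return build_graph([("a", "b"), ("b", "c")])


@pytest.fixture
def diamond_graph():
    """a -> {b, d} -> c: two paths to the root c."""
    return build_graph([("a", "b"), ("a", "d"), ("b", "c"), ("d", "c")])


@pytest.fixture
def toy_obo(tmp_path):
    """A 6-term OBO file exercising namespaces, part_of, obsolete, alt_id."""
    text = """format-version: 1.2
ontology: toy

[Term]
id: GO:0000001
name: mf root
namespace: molecular_function

[Term]
id: GO:0000002
name: bp root
namespace: biological_process

[Term]
id: GO:0000003
name: binding
namespace: molecular_function
alt_id: GO:0000113
is_a: GO:0000001 ! mf root

[Term]
id: GO:0000004
name: ion binding
namespace: molecular_function
is_a: GO:0000003 ! binding

[Term]
id: GO:0000005
name: some process part
namespace: biological_process
relationship: part_of GO:0000002 ! bp root

[Term]
id: GO:0000099
name: gone
namespace: molecular_function
is_obsolete: true
"""
    path = tmp_path / "toy.obo"
    path.write_text(text)
    return str(path)


def table(records, propagated=False):
    """AnnotationTable from {protein: iterable of terms}."""
    return AnnotationTable(
        records={p: set(ts) for p, ts in records.items()}, propagated=propagated
    )
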