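"""Gene Ontology DAG handling.

The Gene Ontology (GO) organises terms for gene-product function into three
rooted directed acyclic graphs (namespaces): biological_process,
molecular_function and cellular_component.  Annotation obeys the true-path
rule: a gene annotated to a term is implicitly annotated to every ancestor
of that term.  This module parses OBO 1.2 ontologies, computes ancestor
closures over a configurable set of relations (``is_a`` and ``part_of`` by
default), propagates annotation tables to their closures, reduces term sets
to their most-specific antichain, and counts occurrences of GO-slim terms.

Obsolete terms are retained (so identifiers still resolve) but carry no
edges and never receive or propagate annotation.  Secondary identifiers
(``alt_id``) are resolved to their primary term at parse time; every
downstream operation sees primary identifiers only.
"""

from __future__ import annotations

import io
import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

import networkx as nx
import obonet

from .errors import ParseError, UnknownTermError, UsageError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .transfer import AnnotationTable

TERM_ID_PATTERN = re.compile(r"^GO:\d{7}$")

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")

#: GAF "aspect" letter for each namespace.
NAMESPACE_ASPECT = {
    "biological_process": "P",
    "molecular_function": "F",
    "cellular_component": "C",
}
ASPECT_NAMESPACE = {v: k for k, v in NAMESPACE_ASPECT.items()}

#: Relations traversed for the true-path closure unless overridden.
DEFAULT_RELATIONS = frozenset({"is_a", "part_of"})


def is_term_id(value: str) -> bool:
    """True if *value* is a syntactically valid GO identifier (GO:0000000)."""
    return bool(TERM_ID_PATTERN.match(value))


@dataclass(frozen=True)
class OntologyTerm:
    """A single GO term.

    ``parents`` holds ``(parent_id, relation)`` pairs; only ``is_a`` and
    ``part_of`` relations are retained at parse time.  Obsolete terms are
    flagged and edge-less.
    """

    id: str
    name: str
    namespace: str
    parents: frozenset[tuple[str, str]] = frozenset()
    obsolete: bool = False
    alt_ids: frozenset[str] = frozenset()
    subsets: frozenset[str] = frozenset()


@dataclass(frozen=True)
class SlimSet:
    """A named GO-slim: a small, high-level subset of ontology terms."""

    name: str
    members: frozenset[str]


class OntologyGraph:
    """The GO DAG: terms indexed by primary id, with per-namespace roots.

    Parameters
    ----------
    terms:
        The ontology terms.  Parent references must stay inside the term set.
    validate:
        When true (default) the constructor checks identifier syntax,
        acyclicity, namespace consistency of edges, uniqueness of alt_id
        resolution and reachability of each namespace root.
    """

    def __init__(self, terms: Iterable[OntologyTerm], validate: bool = True):
        self.terms: dict[str, OntologyTerm] = {}
        for term in terms:
            if term.id in self.terms:
                raise ValidationError(f"duplicate term id {term.id}")
            self.terms[term.id] = term
        self._alt: dict[str, str] = {}
        for term in self.terms.values():
            for alt in term.alt_ids:
                if alt in self.terms or self._alt.get(alt, term.id) != term.id:
                    raise ValidationError(
                        f"alt_id {alt} does not resolve to exactly one primary id"
                    )
                self._alt[alt] = term.id
        self.roots: dict[str, str] = {}
        for term in self.terms.values():
            if not term.obsolete and not term.parents:
                if term.namespace in self.roots:
                    raise ValidationError(
                        f"namespace {term.namespace} has multiple roots: "
                        f"{self.roots[term.namespace]}, {term.id}"
                    )
                self.roots[term.namespace] = term.id
        self._ancestor_cache: dict[frozenset[str], dict[str, frozenset[str]]] = {}
        if validate:
            self._validate()

    # -- lookup ------------------------------------------------------------

    def __contains__(self, term: str) -> bool:
        return term in self.terms or term in self._alt

    def __len__(self) -> int:
        return len(self.terms)

    def __getitem__(self, term: str) -> OntologyTerm:
        return self.terms[self.resolve(term)]

    def resolve(self, term: str) -> str:
        """Map a primary or secondary identifier to its primary id."""
        if term in self.terms:
            return term
        if term in self._alt:
            return self._alt[term]
        raise UnknownTermError(term)

    # -- closure -----------------------------------------------------------

    def ancestors(
        self, term: str, relations: Iterable[str] = DEFAULT_RELATIONS
    ) -> frozenset[str]:
        """All terms reachable from *term* via >=1 edge of the selected
        relations.  Excludes *term* itself.  Memoised per relation set."""
        rel = frozenset(relations)
        cache = self._ancestor_cache.setdefault(rel, {})
        start = self.resolve(term)
        if start in cache:
            return cache[start]
        stack = [start]
        while stack:
            node = stack[-1]
            if node in cache:
                stack.pop()
                continue
            parents = [p for p, r in self.terms[node].parents if r in rel]
            pending = [p for p in parents if p not in cache]
            if pending:
                stack.extend(pending)
                continue
            closure: set[str] = set()
            for p in parents:
                closure.add(p)
                closure |= cache[p]
            cache[node] = frozenset(closure)
            stack.pop()
        return cache[start]

    def leaves(self, namespace: str | None = None) -> frozenset[str]:
        """Non-obsolete terms that are nobody's parent."""
        parent_ids = {
            p for t in self.terms.values() if not t.obsolete for p, _ in t.parents
        }
        return frozenset(
            t.id
            for t in self.terms.values()
            if not t.obsolete
            and t.id not in parent_ids
            and (namespace is None or t.namespace == namespace)
        )

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        dag = nx.DiGraph()
        for term in self.terms.values():
            if not is_term_id(term.id):
                raise ValidationError(f"invalid term id {term.id!r}")
            if term.namespace not in NAMESPACES:
                raise ValidationError(
                    f"{term.id}: unknown namespace {term.namespace!r}"
                )
            if term.obsolete and term.parents:
                raise ValidationError(f"obsolete term {term.id} has parents")
            dag.add_node(term.id)
            for parent, relation in term.parents:
                if parent not in self.terms:
                    raise ValidationError(
                        f"{term.id}: parent {parent} is not in the ontology"
                    )
                if self.terms[parent].namespace != term.namespace:
                    raise ValidationError(
                        f"{term.id}: {relation} parent {parent} crosses namespaces"
                    )
                dag.add_edge(term.id, parent)
        if not nx.is_directed_acyclic_graph(dag):
            cycle = nx.find_cycle(dag)
            raise ValidationError(f"ontology contains a cycle: {cycle}")
        for term in self.terms.values():
            if term.obsolete:
                continue
            root = self.roots.get(term.namespace)
            if root is None:
                raise ValidationError(f"namespace {term.namespace} has no root")
            if term.id != root and root not in self.ancestors(term.id):
                raise ValidationError(
                    f"{term.id} does not reach its namespace root {root}"
                )


# -- OBO parsing -------------------------------------------------------------


def _as_text(source) -> str:
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        return Path(source).read_text()
    if isinstance(source, str):
        return source
    return source.read()


def _prescan_obo(text: str) -> None:
    """Cheap structural check so malformed stanzas fail with a line number."""
    in_term = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("!"):
            continue
        if line.startswith("["):
            if not line.endswith("]"):
                raise ParseError(f"line {lineno}: malformed stanza header {line!r}")
            in_term = line == "[Term]"
            continue
        if in_term and ":" not in line:
            raise ParseError(
                f"line {lineno}: expected 'tag: value' inside [Term] stanza, "
                f"got {line!r}"
            )


def parse_obo(source) -> OntologyGraph:
    """Parse an OBO 1.2 ontology into an :class:`OntologyGraph`.

    *source* may be a path or an open text stream.  Non-obsolete terms keep
    their ``is_a`` and ``relationship: part_of`` edges; other relationship
    types (``regulates`` etc.) are dropped.  Obsolete terms are retained,
    flagged and edge-less.
    """
    text = _as_text(source)
    _prescan_obo(text)
    try:
        net = obonet.read_obo(io.StringIO(text), ignore_obsolete=False)
    except ValueError as exc:  # pragma: no cover - obonet-level failure
        raise ParseError(f"OBO parse failure: {exc}") from exc
    default_ns = net.graph.get("default-namespace", [None])
    default_ns = default_ns[0] if isinstance(default_ns, list) else default_ns

    terms = []
    for node, data in net.nodes(data=True):
        obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        parents: set[tuple[str, str]] = set()
        if not obsolete:
            for _, parent, relation in net.out_edges(node, keys=True):
                if relation in ("is_a", "part_of"):
                    parents.add((parent, relation))
        namespace = data.get("namespace", default_ns)
        if namespace is None:
            raise ParseError(f"term {node} has no namespace and no default")
        terms.append(
            OntologyTerm(
                id=node,
                name=data.get("name", ""),
                namespace=namespace,
                parents=frozenset(parents),
                obsolete=obsolete,
                alt_ids=frozenset(data.get("alt_id", [])),
                subsets=frozenset(data.get("subset", [])),
            )
        )
    return OntologyGraph(terms)


# -- slim sets ---------------------------------------------------------------


def slim_from_subset(graph: OntologyGraph, subset_name: str) -> SlimSet:
    """Collect the terms tagged ``subset: <subset_name>`` in the ontology."""
    members = frozenset(
        t.id for t in graph.terms.values() if subset_name in t.subsets and not t.obsolete
    )
    return SlimSet(name=subset_name, members=members)


def read_slim_ids(source, graph: OntologyGraph, name: str = "slim") -> SlimSet:
    """Read a slim as a plain one-id-per-line file ('#' starts a comment)."""
    text = _as_text(source)
    members = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            members.add(graph.resolve(line))
        except UnknownTermError as exc:
            raise ValidationError(
                f"line {lineno}: slim term {line} is not in the ontology"
            ) from exc
    return SlimSet(name=name, members=frozenset(members))


# -- annotation-level operations ---------------------------------------------


def propagate(
    table: "AnnotationTable",
    graph: OntologyGraph,
    relations: Iterable[str] = DEFAULT_RELATIONS,
    on_missing: str = "error",
) -> "AnnotationTable":
    """Replace each gene's term set by its ancestor closure (true-path rule).

    Each propagated ancestor inherits the evidence code of the annotation it
    was implied by.  Terms absent from the graph (or obsolete) either raise
    or are skipped with a warning, per *on_missing* ('error' | 'skip').
    Idempotent: re-applying to an already-closed table is a no-op.
    """
    if on_missing not in ("error", "skip"):
        raise UsageError(f"on_missing must be 'error' or 'skip', got {on_missing!r}")
    rel = frozenset(relations)
    closed: dict[str, frozenset[tuple[str, str]]] = {}
    for gene, pairs in table.direct.items():
        out: set[tuple[str, str]] = set()
        for term, evidence in pairs:
            try:
                primary = graph.resolve(term)
                if graph.terms[primary].obsolete:
                    raise UnknownTermError(term)
            except UnknownTermError:
                if on_missing == "skip":
                    warnings.warn(
                        f"{gene}: term {term} missing or obsolete; skipped",
                        stacklevel=2,
                    )
                    continue
                raise UnknownTermError(
                    f"{gene}: annotated term {term} is missing or obsolete"
                ) from None
            out.add((primary, evidence))
            for ancestor in graph.ancestors(primary, rel):
                out.add((ancestor, evidence))
        closed[gene] = frozenset(out)
    return table.with_direct(closed)


def reduce_to_most_specific(
    terms: Iterable[str],
    graph: OntologyGraph,
    relations: Iterable[str] = DEFAULT_RELATIONS,
) -> frozenset[str]:
    """Drop every term that is an ancestor of another term in the input.

    The result is an antichain: no remaining term is reachable from another
    via the selected relations.
    """
    resolved = {graph.resolve(t) for t in terms}
    covered: set[str] = set()
    for term in resolved:
        covered |= graph.ancestors(term, relations)
    return frozenset(t for t in resolved if t not in covered)


def slim_count(
    terms: Iterable[str],
    slim: SlimSet,
    graph: OntologyGraph,
    relations: Iterable[str] = DEFAULT_RELATIONS,
) -> dict[str, int]:
    """Occurrences of slim terms over the input terms (single occurrence).

    For each input term, every slim term equal to it or among its ancestors
    is credited exactly once regardless of how many paths lead there; the
    returned counts are sums over input terms.
    """
    if not slim.members:
        return {}
    counts: Counter[str] = Counter()
    for term in terms:
        primary = graph.resolve(term)
        hits = ({primary} | set(graph.ancestors(primary, relations))) & slim.members
        counts.update(hits)
    return dict(counts)
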