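"""GO term over-representation analysis.

For a study set of n genes drawn from a universe of N annotated genes, a GO
term carried (after true-path propagation) by K universe genes and k study
genes is scored with the one-tailed Fisher's exact test, i.e. the
hypergeometric upper tail

    p = sum_{i=k}^{min(n,K)} C(K,i) C(N-K, n-i) / C(N,n),

testing over-representation only.  P-values are corrected across all
candidate terms (those with k >= min_study_count) with the Benjamini-
Hochberg step-up procedure; terms with q <= alpha are significant.  Among
the significant terms, the most-specific subset (no significant descendant)
is flagged to suppress redundant high-level ancestors.  Multi-set summaries
map significant terms onto a GO slim and count single occurrences.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import UsageError, ValidationError
from .ontology import (
    DEFAULT_RELATIONS,
    NAMESPACES,
    OntologyGraph,
    SlimSet,
    propagate,
    reduce_to_most_specific,
    slim_count,
)
from .transfer import AnnotationTable

UNIVERSE_POLICIES = ("annotated_only", "all_predicted")

#: Smallest positive double; p-values are clipped into (0, 1].
_TINY = 5e-324


@dataclass(frozen=True)
class EnrichmentParams:
    """Knobs of the enrichment procedure.

    alpha:
        FDR threshold; a term is significant when q <= alpha.
    relations:
        Edge types traversed during propagation (is_a + part_of by default).
    universe:
        'annotated_only' restricts the background to genes with >= 1
        propagated term; 'all_predicted' uses a caller-supplied gene roster.
    min_study_count:
        Candidate terms must be carried by at least this many study genes.
    per_namespace:
        Correct within each GO namespace separately instead of jointly.
    """

    alpha: float = 0.05
    relations: frozenset[str] = DEFAULT_RELATIONS
    universe: str = "annotated_only"
    min_study_count: int = 1
    per_namespace: bool = False

    def __post_init__(self):
        if not 0 < self.alpha <= 1:
            raise UsageError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.universe not in UNIVERSE_POLICIES:
            raise UsageError(
                f"universe must be one of {UNIVERSE_POLICIES}, got {self.universe!r}"
            )
        if self.min_study_count < 1:
            raise UsageError("min_study_count must be >= 1")


@dataclass(frozen=True)
class ContingencyCounts:
    """2x2 table margins: k of n study genes vs K of N universe genes."""

    k: int
    n: int
    K: int
    N: int

    def __post_init__(self):
        if not (
            0 <= self.k <= min(self.n, self.K)
            and 0 <= self.n <= self.N
            and 0 <= self.K <= self.N
        ):
            raise ValidationError(
                f"invalid contingency counts k={self.k} n={self.n} "
                f"K={self.K} N={self.N}"
            )


@dataclass(frozen=True)
class EnrichmentRecord:
    term: str
    name: str
    namespace: str
    counts: ContingencyCounts
    p: float
    q: float
    significant: bool
    most_specific: bool


@dataclass(frozen=True)
class EnrichmentResult:
    """Full outcome of one enrichment run."""

    records: tuple[EnrichmentRecord, ...]
    n_study: int
    universe_size: int
    unknown_ids: tuple[str, ...]

    @property
    def n_candidates(self) -> int:
        return len(self.records)

    def significant_terms(self) -> frozenset[str]:
        return frozenset(r.term for r in self.records if r.significant)

    def most_specific_terms(self) -> frozenset[str]:
        return frozenset(
            r.term for r in self.records if r.significant and r.most_specific
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (
                    r.term,
                    r.name,
                    r.namespace,
                    r.counts.k,
                    r.counts.n,
                    r.counts.K,
                    r.counts.N,
                    r.p,
                    r.q,
                    r.significant,
                    r.most_specific,
                )
                for r in self.records
            ],
            columns=[
                "term",
                "name",
                "namespace",
                "k",
                "n",
                "K",
                "N",
                "p",
                "q",
                "significant",
                "most_specific",
            ],
        )


def one_tailed_fisher(counts: ContingencyCounts) -> float:
    """Hypergeometric upper-tail probability of >= k successes.

    Equivalent to the one-tailed (over-representation) Fisher's exact test
    on the 2x2 table.  k=0 gives p=1 (the whole distribution).
    """
    p = float(hypergeom.sf(counts.k - 1, counts.N, counts.K, counts.n))
    return min(max(p, _TINY), 1.0)


def benjamini_hochberg(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    With order statistics p_(1) <= ... <= p_(m):
    q_(i) = min_{j >= i} min(1, m * p_(j) / j).
    """
    arr = np.asarray(list(pvalues), dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1) | np.isnan(arr)):
        raise ValidationError("p-values must lie in [0, 1]")
    q = multipletests(arr, alpha=0.05, method="fdr_bh")[1]
    return [float(v) for v in q]


class EnrichmentAnalysis:
    """Reusable enrichment engine over a fixed background annotation.

    Propagating the background and counting per-term universe frequencies is
    the expensive part; building the engine once and calling :meth:`run` for
    many study sets amortises it.
    """

    def __init__(
        self,
        background: AnnotationTable,
        graph: OntologyGraph,
        params: EnrichmentParams | None = None,
        universe_genes: Iterable[str] | None = None,
        assume_propagated: bool = False,
    ):
        self.graph = graph
        self.params = params or EnrichmentParams()
        table = (
            background
            if assume_propagated
            else propagate(background, graph, self.params.relations)
        )
        self.gene_terms: dict[str, frozenset[str]] = {
            gene: frozenset(t for t, _ in pairs)
            for gene, pairs in table.direct.items()
            if pairs
        }
        if self.params.universe == "all_predicted":
            if universe_genes is None:
                raise UsageError(
                    "universe='all_predicted' needs an explicit gene roster"
                )
            self.universe: frozenset[str] = frozenset(universe_genes)
        else:
            self.universe = frozenset(self.gene_terms)
        self.N = len(self.universe)
        term_K: Counter[str] = Counter()
        for gene in self.universe:
            term_K.update(self.gene_terms.get(gene, ()))
        self.term_K: dict[str, int] = dict(term_K)

    def run(self, study_genes: Iterable[str]) -> EnrichmentResult:
        """Score every candidate term for one study set."""
        seen: dict[str, None] = {}
        for gene in study_genes:
            seen.setdefault(gene)
        in_universe = [g for g in seen if g in self.universe]
        unknown = tuple(g for g in seen if g not in self.universe)
        if not in_universe:
            raise UsageError(
                f"no study gene maps to the universe "
                f"({len(unknown)} unknown identifiers)"
            )
        n = len(in_universe)
        k_counts: Counter[str] = Counter()
        for gene in in_universe:
            k_counts.update(self.gene_terms.get(gene, ()))
        candidates = sorted(
            t for t, k in k_counts.items() if k >= self.params.min_study_count
        )
        if not candidates:
            return EnrichmentResult(
                records=(), n_study=n, universe_size=self.N, unknown_ids=unknown
            )
        k = np.array([k_counts[t] for t in candidates])
        K = np.array([self.term_K[t] for t in candidates])
        p = hypergeom.sf(k - 1, self.N, K, n)
        p = np.clip(p, _TINY, 1.0)
        q = np.empty_like(p)
        if self.params.per_namespace:
            namespaces = np.array(
                [self.graph[t].namespace for t in candidates]
            )
            for ns in NAMESPACES:
                mask = namespaces == ns
                if mask.any():
                    q[mask] = benjamini_hochberg(p[mask])
        else:
            q[:] = benjamini_hochberg(p)
        significant = q <= self.params.alpha
        sig_terms = {t for t, s in zip(candidates, significant) if s}
        most_specific = (
            reduce_to_most_specific(sig_terms, self.graph, self.params.relations)
            if sig_terms
            else frozenset()
        )
        records = []
        for i, term in enumerate(candidates):
            node = self.graph[term]
            records.append(
                EnrichmentRecord(
                    term=term,
                    name=node.name,
                    namespace=node.namespace,
                    counts=ContingencyCounts(
                        k=int(k[i]), n=n, K=int(K[i]), N=self.N
                    ),
                    p=float(p[i]),
                    q=float(q[i]),
                    significant=bool(significant[i]),
                    most_specific=term in most_specific,
                )
            )
        records.sort(key=lambda r: (r.q, r.p, r.term))
        return EnrichmentResult(
            records=tuple(records),
            n_study=n,
            universe_size=self.N,
            unknown_ids=unknown,
        )


def enrich(
    study_genes: Iterable[str],
    background: AnnotationTable,
    graph: OntologyGraph,
    params: EnrichmentParams | None = None,
    universe_genes: Iterable[str] | None = None,
) -> EnrichmentResult:
    """One-shot enrichment of a study set against a background annotation."""
    engine = EnrichmentAnalysis(
        background, graph, params=params, universe_genes=universe_genes
    )
    return engine.run(study_genes)


def read_study_set(source) -> list[str]:
    """Read gene ids, one per line; '#' starts a comment."""
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        text = Path(source).read_text()
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()
    genes = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            genes.append(line)
    return genes


def slim_comparison(
    term_sets: Mapping[str, Iterable[str]],
    slim: SlimSet,
    graph: OntologyGraph,
    relations: Iterable[str] = DEFAULT_RELATIONS,
) -> pd.DataFrame:
    """Slim-occurrence matrix: rows = slim terms, columns = labelled sets.

    Every slim member appears as a row even when its count is zero, so that
    columns from different runs line up.
    """
    if not term_sets:
        raise UsageError("slim_comparison needs at least one term set")
    index = sorted(slim.members)
    data = {}
    for label, terms in term_sets.items():
        counts = slim_count(terms, slim, graph, relations)
        data[label] = [counts.get(t, 0) for t in index]
    return pd.DataFrame(data, index=pd.Index(index, name="slim_term"))


# -- export --------------------------------------------------------------------

_NS_FILE_TAG = {
    "biological_process": "bp",
    "molecular_function": "mf",
    "cellular_component": "cc",
}


def _dot_escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"')


def _dot_graph(
    result: EnrichmentResult,
    graph: OntologyGraph,
    namespace: str,
    relations: Iterable[str],
) -> str:
    """DOT text of the significant terms of one namespace plus ancestors.

    Significant nodes are filled; edges are the induced parent edges of the
    sub-DAG, drawn child -> parent (part_of edges dashed).
    """
    significant = sorted(
        r.term for r in result.records if r.significant and r.namespace == namespace
    )
    nodes: set[str] = set(significant)
    for term in significant:
        nodes |= graph.ancestors(term, relations)
    by_q = {r.term: r.q for r in result.records}
    lines = [f'digraph "{namespace}" {{', "  rankdir=BT;", '  node [shape=box];']
    for term in sorted(nodes):
        node = graph[term]
        label = _dot_escape(f"{term}\\n{node.name}")
        if term in by_q and term in set(significant):
            label += _dot_escape(f"\\nq={by_q[term]:.3g}")
            lines.append(
                f'  "{term}" [label="{label}", style=filled, '
                f'fillcolor=lightsalmon];'
            )
        else:
            lines.append(f'  "{term}" [label="{label}"];')
    rel = frozenset(relations)
    for term in sorted(nodes):
        for parent, relation in sorted(graph[term].parents):
            if relation in rel and parent in nodes:
                style = ', style=dashed' if relation == "part_of" else ""
                lines.append(
                    f'  "{term}" -> "{parent}" [label="{relation}"{style}];'
                )
    lines.append("}")
    return "\n".join(lines) + "\n"


def export_results(
    result: EnrichmentResult,
    graph: OntologyGraph,
    out_prefix,
    relations: Iterable[str] = DEFAULT_RELATIONS,
) -> dict[str, Path]:
    """Write TSV, plain-text summary and one DOT graph per namespace.

    Returns the mapping of artefact kind to path.  The DOT files contain the
    significant terms plus all their ancestors up to the namespace root and
    are valid input for standard DOT -> SVG renderers.
    """
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    tsv_path = prefix.with_name(prefix.name + ".tsv")
    result.to_frame().to_csv(tsv_path, sep="\t", index=False)
    paths["tsv"] = tsv_path

    txt_path = prefix.with_name(prefix.name + ".txt")
    sig = [r for r in result.records if r.significant]
    lines = [
        f"study genes in universe: {result.n_study}",
        f"universe size: {result.universe_size}",
        f"unknown identifiers: {len(result.unknown_ids)}",
        f"candidate terms: {result.n_candidates}",
        f"significant terms: {len(sig)}",
        f"most-specific significant terms: "
        f"{sum(1 for r in sig if r.most_specific)}",
        "",
    ]
    for r in sig:
        marker = "*" if r.most_specific else " "
        lines.append(
            f"{marker} {r.term}  q={r.q:.3g}  {r.counts.k}/{r.counts.n} vs "
            f"{r.counts.K}/{r.counts.N}  [{r.namespace}] {r.name}"
        )
    txt_path.write_text("\n".join(lines) + "\n")
    paths["txt"] = txt_path

    for namespace, tag in _NS_FILE_TAG.items():
        dot_path = prefix.with_name(f"{prefix.name}.{tag}.dot")
        dot_path.write_text(_dot_graph(result, graph, namespace, relations))
        paths[f"dot_{tag}"] = dot_path
    return paths
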