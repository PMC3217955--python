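"""Two-step Jaccard / reciprocal-best-hit ortholog clustering.

Starting from an all-vs-all protein similarity table (BLASTP-style 12-column
tabular output), the method first clusters each genome's proteins
independently: hits are filtered (E-value <= 1e-5, identity >= 80%), a match
set is formed per protein, and two proteins are connected when the Jaccard
coefficient of their match sets strictly exceeds 0.6.  Connected components
of that graph are *Jaccard clusters* (paralog families; singletons allowed).

In the second step, clusters from different genomes are linked when at least
one member of each cluster has its highest-bitscore cross-genome hit inside
the other cluster, in both directions (cluster-level reciprocal best hits).
Connected components spanning >= 2 Jaccard clusters are *Jaccard orthologous
clusters*; they may mix orthologs with close paralogs.
"""

from __future__ import annotations

import itertools
import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .errors import ParseError, UnknownProteinError, UsageError, ValidationError

#: Standard 12-column tabular similarity-search output.
BLAST_TAB_COLUMNS = (
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
)


@dataclass(frozen=True)
class Proteome:
    """A genome's predicted protein roster."""

    genome_id: str
    proteins: frozenset[str]


@dataclass(frozen=True)
class SimilarityHit:
    """One pairwise similarity hit (directional: query -> subject)."""

    query: str
    subject: str
    percent_identity: float
    evalue: float
    bitscore: float


@dataclass(frozen=True)
class ClusteringParams:
    """Filtering and graph thresholds for the two clustering stages.

    Defaults: E-value cut-off 1e-5 (kept when <=), identity at least 80%
    (kept when >=), and a Jaccard edge only when J strictly exceeds 0.6.
    """

    max_evalue: float = 1e-5
    min_identity_percent: float = 80.0
    jaccard_threshold: float = 0.6

    def __post_init__(self):
        if self.max_evalue < 0:
            raise UsageError("max_evalue must be non-negative")
        if not 0 <= self.min_identity_percent <= 100:
            raise UsageError("min_identity_percent must be in [0, 100]")
        if not 0 <= self.jaccard_threshold <= 1:
            raise UsageError("jaccard_threshold must be in [0, 1]")


@dataclass(frozen=True)
class MatchSet:
    """A protein plus its same-genome match neighbourhood (self included)."""

    protein: str
    matches: frozenset[str]


@dataclass(frozen=True)
class JaccardCluster:
    """A within-genome paralog cluster (connected component of the J-graph)."""

    cluster_id: str
    genome_id: str
    members: frozenset[str]


@dataclass(frozen=True)
class OrthologCluster:
    """A cross-genome component of reciprocally best-matching Jaccard clusters."""

    cluster_id: str
    members: frozenset[tuple[str, str]]  # (genome_id, protein)
    source_jaccard_clusters: frozenset[str]


def round_half_up(x: float) -> int:
    """Round to the nearest integer, ties away from zero for positive x."""
    return int(math.floor(x + 0.5))


def genome_index(proteomes: Iterable[Proteome]) -> dict[str, str]:
    """Map protein id -> genome id; protein ids must be globally unique."""
    index: dict[str, str] = {}
    for proteome in proteomes:
        for protein in proteome.proteins:
            if protein in index:
                raise ValidationError(
                    f"protein id {protein} occurs in both {index[protein]} "
                    f"and {proteome.genome_id}"
                )
            index[protein] = proteome.genome_id
    return index


# -- I/O ----------------------------------------------------------------------


def read_hits(source) -> list[SimilarityHit]:
    """Read similarity hits from 12-column tab-separated tabular output."""
    try:
        frame = pd.read_csv(
            source, sep="\t", header=None, comment="#", dtype=str,
            skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        return []
    if frame.shape[1] != len(BLAST_TAB_COLUMNS):
        raise ParseError(
            f"expected {len(BLAST_TAB_COLUMNS)} tab-separated columns, "
            f"got {frame.shape[1]}"
        )
    frame.columns = list(BLAST_TAB_COLUMNS)
    return [
        SimilarityHit(
            query=row.qseqid,
            subject=row.sseqid,
            percent_identity=float(row.pident),
            evalue=float(row.evalue),
            bitscore=float(row.bitscore),
        )
        for row in frame.itertuples(index=False)
    ]


def write_hits(hits: Iterable[SimilarityHit], path) -> None:
    """Write hits as 12-column tabular text (unused coordinates zeroed)."""
    with open(path, "w") as handle:
        for h in hits:
            handle.write(
                f"{h.query}\t{h.subject}\t{h.percent_identity:g}\t0\t0\t0\t"
                f"0\t0\t0\t0\t{h.evalue:g}\t{h.bitscore:g}\n"
            )


def read_proteome(source, genome_id: str) -> Proteome:
    """Read a proteome from FASTA (ids only) or a one-id-per-line list."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    stripped = text.lstrip()
    proteins: set[str] = set()
    if stripped.startswith(">"):
        from Bio import SeqIO
        import io as _io

        for record in SeqIO.parse(_io.StringIO(text), "fasta"):
            proteins.add(record.id)
    else:
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if line:
                proteins.add(line)
    return Proteome(genome_id=genome_id, proteins=frozenset(proteins))


# -- stage 1: within-genome Jaccard clustering --------------------------------


def dedupe_hits(hits: Iterable[SimilarityHit]) -> list[SimilarityHit]:
    """Keep the best hit per ordered (query, subject) pair.

    Best = highest bitscore, then lowest E-value, then highest identity.
    """
    best: dict[tuple[str, str], SimilarityHit] = {}
    for hit in hits:
        key = (hit.query, hit.subject)
        cur = best.get(key)
        if cur is None or (
            (hit.bitscore, -hit.evalue, hit.percent_identity)
            > (cur.bitscore, -cur.evalue, cur.percent_identity)
        ):
            best[key] = hit
    return list(best.values())


def filter_hits(
    hits: Iterable[SimilarityHit],
    params: ClusteringParams,
    stage: str,
    genome_of: Mapping[str, str],
) -> list[SimilarityHit]:
    """Apply the stage-specific filters.

    ``paralog``: same-genome, non-self hits with E-value <= max_evalue and
    identity >= min_identity_percent.  ``ortholog``: cross-genome hits with
    E-value <= max_evalue (no identity filter).
    """
    if stage not in ("paralog", "ortholog"):
        raise UsageError(f"stage must be 'paralog' or 'ortholog', got {stage!r}")
    kept = []
    for hit in hits:
        for protein in (hit.query, hit.subject):
            if protein not in genome_of:
                raise UnknownProteinError(
                    f"hit references unknown protein {protein}"
                )
        if hit.evalue > params.max_evalue:
            continue
        same_genome = genome_of[hit.query] == genome_of[hit.subject]
        if stage == "paralog":
            if (
                same_genome
                and hit.query != hit.subject
                and hit.percent_identity >= params.min_identity_percent
            ):
                kept.append(hit)
        else:
            if not same_genome:
                kept.append(hit)
    return kept


def match_sets(
    proteome: Proteome, filtered_hits: Iterable[SimilarityHit]
) -> dict[str, MatchSet]:
    """Per-protein match sets from paralog-stage hits, symmetrised.

    The match set of P is {P} plus every same-genome protein linked to P by
    a kept hit in either direction.
    """
    neighbours: dict[str, set[str]] = {p: {p} for p in proteome.proteins}
    for hit in filtered_hits:
        if hit.query in neighbours and hit.subject in neighbours:
            neighbours[hit.query].add(hit.subject)
            neighbours[hit.subject].add(hit.query)
    return {
        protein: MatchSet(protein=protein, matches=frozenset(members))
        for protein, members in neighbours.items()
    }


def jaccard_coefficient(m1: MatchSet, m2: MatchSet) -> float:
    """|m1 & m2| / |m1 | m2|; 0.0 when the union is empty."""
    union = m1.matches | m2.matches
    if not union:
        return 0.0
    return len(m1.matches & m2.matches) / len(union)


def build_jaccard_clusters(
    proteome: Proteome,
    filtered_hits: Iterable[SimilarityHit],
    params: ClusteringParams | None = None,
) -> list[JaccardCluster]:
    """Connected components of the J > threshold graph over one genome.

    Every protein lands in exactly one cluster; proteins without qualifying
    edges form singletons.  Candidate pairs are generated from co-occurrence
    within a match set, which is exactly the set of pairs with non-empty
    match-set intersection.
    """
    params = params or ClusteringParams()
    sets = match_sets(proteome, filtered_hits)
    graph = nx.Graph()
    graph.add_nodes_from(proteome.proteins)
    candidates: set[tuple[str, str]] = set()
    for mset in sets.values():
        for a, b in itertools.combinations(sorted(mset.matches), 2):
            candidates.add((a, b))
    for a, b in candidates:
        if jaccard_coefficient(sets[a], sets[b]) > params.jaccard_threshold:
            graph.add_edge(a, b)
    components = sorted(nx.connected_components(graph), key=min)
    return [
        JaccardCluster(
            cluster_id=f"{proteome.genome_id}|JC{i:05d}",
            genome_id=proteome.genome_id,
            members=frozenset(component),
        )
        for i, component in enumerate(components, start=1)
    ]


# -- stage 2: cross-genome reciprocal best hits -------------------------------


class BestHitIndex:
    """Per (protein, target genome): the set of maximal-bitscore subjects.

    All subjects tied at the top bitscore are retained, which keeps the
    result independent of input order.
    """

    def __init__(self, best: dict[tuple[str, str], frozenset[str]]):
        self._best = best

    @classmethod
    def from_hits(
        cls, ortholog_hits: Iterable[SimilarityHit], genome_of: Mapping[str, str]
    ) -> "BestHitIndex":
        best: dict[tuple[str, str], tuple[float, set[str]]] = {}
        for hit in ortholog_hits:
            key = (hit.query, genome_of[hit.subject])
            score, subjects = best.get(key, (-math.inf, set()))
            if hit.bitscore > score:
                best[key] = (hit.bitscore, {hit.subject})
            elif hit.bitscore == score:
                subjects.add(hit.subject)
        return cls({k: frozenset(v) for k, (_, v) in best.items()})

    def best_subjects(self, protein: str, genome: str) -> frozenset[str]:
        return self._best.get((protein, genome), frozenset())


def best_hits(
    cluster: JaccardCluster, genome_b: str, index: BestHitIndex
) -> frozenset[str]:
    """Union over cluster members of their top-bitscore subjects in genome_b."""
    out: set[str] = set()
    for protein in cluster.members:
        out |= index.best_subjects(protein, genome_b)
    return frozenset(out)


def rbh_cluster_edges(
    clusters: Sequence[JaccardCluster],
    ortholog_hits: Iterable[SimilarityHit],
    genome_of: Mapping[str, str],
) -> set[tuple[str, str]]:
    """Unordered cluster-id pairs linked by cluster-level reciprocal best hits.

    Clusters A (genome GA) and B (genome GB != GA) are linked iff some member
    of A has its best hit in GB inside B, and some member of B has its best
    hit in GA inside A.
    """
    index = BestHitIndex.from_hits(ortholog_hits, genome_of)
    cluster_of: dict[str, str] = {}
    by_id: dict[str, JaccardCluster] = {}
    for cluster in clusters:
        by_id[cluster.cluster_id] = cluster
        for protein in cluster.members:
            cluster_of[protein] = cluster.cluster_id
    genomes = sorted({c.genome_id for c in clusters})
    forward: dict[str, set[str]] = defaultdict(set)
    for cluster in clusters:
        for genome in genomes:
            if genome == cluster.genome_id:
                continue
            for subject in best_hits(cluster, genome, index):
                target = cluster_of.get(subject)
                if target is not None:
                    forward[cluster.cluster_id].add(target)
    edges: set[tuple[str, str]] = set()
    for a, targets in forward.items():
        for b in targets:
            if a in forward.get(b, ()):  # reciprocal
                edges.add((min(a, b), max(a, b)))
    return edges


def build_ortholog_clusters(
    clusters: Sequence[JaccardCluster], edges: Iterable[tuple[str, str]]
) -> list[OrthologCluster]:
    """Connected components of the cluster graph spanning >= 2 Jaccard clusters.

    Isolated Jaccard clusters are left out (reported as unclustered by the
    summary).  Components may contain several clusters from one genome.
    """
    by_id = {c.cluster_id: c for c in clusters}
    graph = nx.Graph()
    graph.add_nodes_from(by_id)
    graph.add_edges_from(edges)
    components = sorted(
        (c for c in nx.connected_components(graph) if len(c) >= 2), key=min
    )
    out = []
    for i, component in enumerate(components, start=1):
        members = frozenset(
            (by_id[cid].genome_id, protein)
            for cid in component
            for protein in by_id[cid].members
        )
        out.append(
            OrthologCluster(
                cluster_id=f"JOC{i:05d}",
                members=members,
                source_jaccard_clusters=frozenset(component),
            )
        )
    return out


# -- end-to-end convenience ----------------------------------------------------


@dataclass
class ClusteringResult:
    params: ClusteringParams
    jaccard_clusters: dict[str, list[JaccardCluster]]
    ortholog_clusters: list[OrthologCluster]

    @property
    def all_jaccard_clusters(self) -> list[JaccardCluster]:
        return [c for group in self.jaccard_clusters.values() for c in group]

    @property
    def unclustered_jaccard_ids(self) -> frozenset[str]:
        used = {
            cid
            for oc in self.ortholog_clusters
            for cid in oc.source_jaccard_clusters
        }
        return frozenset(
            c.cluster_id for c in self.all_jaccard_clusters if c.cluster_id not in used
        )


def cluster_genomes(
    proteomes: Sequence[Proteome],
    hits: Iterable[SimilarityHit],
    params: ClusteringParams | None = None,
) -> ClusteringResult:
    """Run both clustering stages over all genomes."""
    params = params or ClusteringParams()
    genome_of = genome_index(proteomes)
    unique_hits = dedupe_hits(hits)
    paralog_hits = filter_hits(unique_hits, params, "paralog", genome_of)
    jaccard: dict[str, list[JaccardCluster]] = {}
    for proteome in proteomes:
        own = [
            h for h in paralog_hits if genome_of[h.query] == proteome.genome_id
        ]
        jaccard[proteome.genome_id] = build_jaccard_clusters(proteome, own, params)
    all_clusters = [c for group in jaccard.values() for c in group]
    ortholog_hits = filter_hits(unique_hits, params, "ortholog", genome_of)
    edges = rbh_cluster_edges(all_clusters, ortholog_hits, genome_of)
    ortholog_clusters = build_ortholog_clusters(all_clusters, edges)
    return ClusteringResult(
        params=params, jaccard_clusters=jaccard, ortholog_clusters=ortholog_clusters
    )


# -- summary -------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeClusteringRow:
    genome_id: str
    n_proteins: int
    n_clustered: int
    percent_clustered: int


@dataclass(frozen=True)
class ClusteringSummary:
    rows: tuple[GenomeClusteringRow, ...]
    total_proteins: int
    total_clustered: int
    percent_clustered: int
    n_ortholog_clusters: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.genome_id, r.n_proteins, r.n_clustered, r.percent_clustered)
                for r in self.rows
            ],
            columns=["genome", "proteins", "in_ortholog_clusters", "percent"],
        )

    def to_text(self) -> str:
        lines = [
            f"{r.genome_id}: {r.n_clustered}/{r.n_proteins} proteins in "
            f"ortholog clusters ({r.percent_clustered}%)"
            for r in self.rows
        ]
        lines.append(
            f"total: {self.total_clustered}/{self.total_proteins} "
            f"({self.percent_clustered}%) in {self.n_ortholog_clusters} "
            f"Jaccard orthologous clusters"
        )
        return "\n".join(lines)


def clustering_summary(
    ortholog_clusters: Sequence[OrthologCluster], proteomes: Sequence[Proteome]
) -> ClusteringSummary:
    """Per-genome and total counts of proteins inside ortholog clusters.

    Percentages are rounded to the nearest integer.
    """
    clustered: dict[str, set[str]] = defaultdict(set)
    for oc in ortholog_clusters:
        for genome, protein in oc.members:
            clustered[genome].add(protein)
    rows = []
    total = 0
    total_clustered = 0
    for proteome in proteomes:
        n = len(proteome.proteins)
        c = len(clustered.get(proteome.genome_id, set()) & proteome.proteins)
        rows.append(
            GenomeClusteringRow(
                genome_id=proteome.genome_id,
                n_proteins=n,
                n_clustered=c,
                percent_clustered=round_half_up(100 * c / n) if n else 0,
            )
        )
        total += n
        total_clustered += c
    return ClusteringSummary(
        rows=tuple(rows),
        total_proteins=total,
        total_clustered=total_clustered,
        percent_clustered=round_half_up(100 * total_clustered / total) if total else 0,
        n_ortholog_clusters=len(ortholog_clusters),
    )


# -- cluster table I/O ----------------------------------------------------------


def write_jaccard_clusters(clusters: Iterable[JaccardCluster], path) -> None:
    with open(path, "w") as handle:
        handle.write("cluster_id\tgenome\tprotein\n")
        for cluster in sorted(clusters, key=lambda c: c.cluster_id):
            for protein in sorted(cluster.members):
                handle.write(f"{cluster.cluster_id}\t{cluster.genome_id}\t{protein}\n")


def write_ortholog_clusters(clusters: Iterable[OrthologCluster], path) -> None:
    with open(path, "w") as handle:
        handle.write("cluster_id\tgenome\tprotein\n")
        for cluster in sorted(clusters, key=lambda c: c.cluster_id):
            for genome, protein in sorted(cluster.members):
                handle.write(f"{cluster.cluster_id}\t{genome}\t{protein}\n")


def read_ortholog_clusters(source) -> list[OrthologCluster]:
    """Read ortholog clusters from the 3-column TSV written above.

    The Jaccard-cluster provenance is not stored in the file, so the
    ``source_jaccard_clusters`` field comes back empty.
    """
    frame = pd.read_csv(source, sep="\t", dtype=str)
    expected = ["cluster_id", "genome", "protein"]
    if list(frame.columns) != expected:
        raise ParseError(f"expected columns {expected}, got {list(frame.columns)}")
    grouped: dict[str, set[tuple[str, str]]] = defaultdict(set)
    for row in frame.itertuples(index=False):
        grouped[row.cluster_id].add((row.genome, row.protein))
    return [
        OrthologCluster(
            cluster_id=cid,
            members=frozenset(members),
            source_jaccard_clusters=frozenset(),
        )
        for cid, members in sorted(grouped.items())
    ]
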