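"""Deterministic synthetic data for every pipeline stage.

Generators produce toy ontologies, proteomes, similarity-hit tables with
planted ortholog groups and paralog families, and annotation tables with a
planted enrichment signal, together with the ground truth needed to verify
recovery.  All generators are pure functions of ``(spec, seed)``: a single
integer seed drives independent sub-streams via numpy's SeedSequence
spawning scheme (stream 0: ontology, 1: hits, 2: annotation).

Planted similarity structure is margin-separated: reciprocal best hits of
ortholog groups carry bitscores >= 400 while noise hits stay <= 200, so at
zero noise the clustering stages recover the planted groups exactly and no
accidental bitscore ties arise.

A printed-data fixture reproduces a published ten-strain mapping summary
(predicted transcripts, GO-annotated transcripts, distinct propagated GO
terms per strain) for arithmetic checks that need realistic magnitudes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .clustering import Proteome, SimilarityHit
from .errors import UsageError
from .ontology import NAMESPACES, OntologyGraph, OntologyTerm
from .transfer import AnnotationTable

#: Subset tag attached to the first tier below each synthetic root.
SLIM_SUBSET = "goslim_synthetic"

_STREAM_ONTOLOGY = 0
_STREAM_HITS = 1
_STREAM_ANNOTATION = 2

#: Planted ortholog-group hits dominate noise by at least this margin.
_ORTHOLOG_BITSCORE_BASE = 400.0
_NOISE_BITSCORE_MAX = 200.0


@dataclass(frozen=True)
class FixtureSpec:
    """Shape of one synthetic dataset.

    Defaults model a small multi-genome comparison: a handful of related
    genomes with one-to-one ortholog groups, a couple of within-genome
    paralog families, a three-namespace ontology and a sparse background
    annotation with one planted enrichment signal.
    """

    seed: int = 0
    n_genomes: int = 3
    proteins_per_genome: int = 20
    n_ortholog_groups: int = 8
    paralog_family_sizes: tuple[int, ...] = (3, 2)
    noise_hit_rate: float = 0.0
    depth: int = 4
    branching: int = 2
    diamond_fraction: float = 0.0
    background_term_rate: float = 0.05
    planted_carriers: int = 0

    def __post_init__(self):
        if self.n_genomes < 1 or self.proteins_per_genome < 1:
            raise UsageError("genome and proteome sizes must be positive")
        if self.n_ortholog_groups < 0 or self.planted_carriers < 0:
            raise UsageError("counts must be non-negative")
        if any(size < 1 for size in self.paralog_family_sizes):
            raise UsageError("paralog family sizes must be positive")
        for rate in (
            self.noise_hit_rate,
            self.diamond_fraction,
            self.background_term_rate,
        ):
            if not 0 <= rate <= 1:
                raise UsageError("rates must lie in [0, 1]")
        if self.depth < 1 or self.branching < 1:
            raise UsageError("ontology depth and branching must be >= 1")
        occupied = sum(self.paralog_family_sizes) + self.n_ortholog_groups
        if occupied > self.proteins_per_genome:
            raise UsageError(
                f"paralog families plus ortholog groups need {occupied} "
                f"proteins per genome, only {self.proteins_per_genome} available"
            )


def _rng(spec: FixtureSpec, stream: int, extra: int | None = None):
    key = [spec.seed, stream] if extra is None else [spec.seed, stream, extra]
    return np.random.default_rng(key)


# -- ontology ------------------------------------------------------------------


def make_ontology(spec: FixtureSpec) -> OntologyGraph:
    """A three-namespace DAG of the given depth and branching factor.

    Each namespace is a rooted tree where every node has ``branching``
    children down to ``depth`` levels; with probability ``diamond_fraction``
    a node below the second level gains an extra parent from the previous
    level (a multi-parent 'diamond').  Depth 1 yields roots only.  Nodes
    directly below a root carry the ``goslim_synthetic`` subset tag.
    """
    terms: list[OntologyTerm] = []
    counter = 1
    for ns_index, namespace in enumerate(NAMESPACES):
        rng = _rng(spec, _STREAM_ONTOLOGY, ns_index)
        root_id = f"GO:{counter:07d}"
        counter += 1
        terms.append(
            OntologyTerm(
                id=root_id, name=f"{namespace} root", namespace=namespace
            )
        )
        previous = [root_id]
        for level in range(1, spec.depth):
            current = []
            for parent in previous:
                for _ in range(spec.branching):
                    term_id = f"GO:{counter:07d}"
                    counter += 1
                    parents = {(parent, "is_a")}
                    if level >= 2 and rng.random() < spec.diamond_fraction:
                        extra = previous[rng.integers(len(previous))]
                        if extra != parent:
                            parents.add((extra, "is_a"))
                    terms.append(
                        OntologyTerm(
                            id=term_id,
                            name=f"synthetic {namespace} term {term_id[3:]}",
                            namespace=namespace,
                            parents=frozenset(parents),
                            subsets=frozenset(
                                {SLIM_SUBSET} if level == 1 else ()
                            ),
                        )
                    )
                    current.append(term_id)
            previous = current
    return OntologyGraph(terms)


def write_obo(graph: OntologyGraph, path) -> None:
    """Serialise an ontology as OBO 1.2 text (sorted, byte-deterministic)."""
    lines = ["format-version: 1.2", "ontology: go", ""]
    for term_id in sorted(graph.terms):
        term = graph.terms[term_id]
        lines.append("[Term]")
        lines.append(f"id: {term.id}")
        lines.append(f"name: {term.name}")
        lines.append(f"namespace: {term.namespace}")
        for alt in sorted(term.alt_ids):
            lines.append(f"alt_id: {alt}")
        for subset in sorted(term.subsets):
            lines.append(f"subset: {subset}")
        for parent, relation in sorted(term.parents):
            if relation == "is_a":
                lines.append(f"is_a: {parent}")
            else:
                lines.append(f"relationship: {relation} {parent}")
        if term.obsolete:
            lines.append("is_obsolete: true")
        lines.append("")
    Path(path).write_text("\n".join(lines))


# -- proteomes and similarity hits ----------------------------------------------


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure returned alongside generated hits."""

    ortholog_groups: tuple[frozenset[tuple[str, str]], ...]
    paralog_families: dict[str, tuple[frozenset[str], ...]]


def make_proteomes_hits(
    spec: FixtureSpec,
) -> tuple[list[Proteome], list[SimilarityHit], GroundTruth]:
    """Proteomes plus an all-vs-all style hit table with planted structure.

    Per genome, the first proteins form the paralog families (intra-genome
    cliques: identity 95%, E-value 1e-50, bitscore 300, giving pairwise
    J = 1 within a family); the next ``n_ortholog_groups`` proteins are the
    one-per-genome members of the ortholog groups, connected by reciprocal
    cross-genome hits whose bitscores (>= 400, decreasing per group) strictly
    dominate everything else.  Noise hits (identity 40-75%, bitscore 50-200)
    are added at ``noise_hit_rate`` times the number of planted hits.
    """
    genomes = [f"g{i + 1}" for i in range(spec.n_genomes)]
    proteins = {
        g: [f"{g}_p{j:03d}" for j in range(spec.proteins_per_genome)]
        for g in genomes
    }
    proteomes = [Proteome(g, frozenset(proteins[g])) for g in genomes]

    hits: list[SimilarityHit] = []
    families: dict[str, list[frozenset[str]]] = {g: [] for g in genomes}
    for g in genomes:
        offset = 0
        for size in spec.paralog_family_sizes:
            members = proteins[g][offset : offset + size]
            offset += size
            families[g].append(frozenset(members))
            for a in members:
                for b in members:
                    if a != b:
                        hits.append(
                            SimilarityHit(a, b, 95.0, 1e-50, 300.0)
                        )
    family_offset = sum(spec.paralog_family_sizes)

    groups: list[frozenset[tuple[str, str]]] = []
    for i in range(spec.n_ortholog_groups):
        members = {g: proteins[g][family_offset + i] for g in genomes}
        groups.append(frozenset((g, p) for g, p in members.items()))
        score = _ORTHOLOG_BITSCORE_BASE + spec.n_ortholog_groups - i
        for ga in genomes:
            for gb in genomes:
                if ga != gb:
                    hits.append(
                        SimilarityHit(members[ga], members[gb], 90.0, 1e-80, score)
                    )

    rng = _rng(spec, _STREAM_HITS)
    n_noise = int(round(spec.noise_hit_rate * len(hits)))
    flat = [p for g in genomes for p in proteins[g]]
    for _ in range(n_noise):
        query, subject = rng.choice(len(flat), size=2, replace=False)
        hits.append(
            SimilarityHit(
                flat[int(query)],
                flat[int(subject)],
                float(rng.uniform(40.0, 75.0)),
                1e-6,
                float(rng.uniform(50.0, _NOISE_BITSCORE_MAX)),
            )
        )
    truth = GroundTruth(
        ortholog_groups=tuple(groups),
        paralog_families={g: tuple(f) for g, f in families.items()},
    )
    return proteomes, hits, truth


# -- annotation -----------------------------------------------------------------


@dataclass(frozen=True)
class AnnotationFixture:
    """Generated annotation plus its planted enrichment signal."""

    table: AnnotationTable
    planted_term: str | None
    carriers: tuple[str, ...]


def make_annotation(
    spec: FixtureSpec, graph: OntologyGraph, proteome: Proteome
) -> AnnotationFixture:
    """Background annotation with an optional planted enrichment signal.

    Every gene receives each leaf term independently with probability
    ``background_term_rate``.  When ``planted_carriers`` > 0, the first
    biological_process leaf is additionally assigned to that many randomly
    chosen carrier genes, creating a known over-representation signal once a
    study set is built around the carriers.  Genes left without any term are
    omitted from the table.
    """
    rng = _rng(spec, _STREAM_ANNOTATION)
    genes = sorted(proteome.proteins)
    leaves = sorted(graph.leaves())
    planted_term: str | None = None
    carriers: tuple[str, ...] = ()
    if spec.planted_carriers > 0:
        bp_leaves = sorted(graph.leaves("biological_process"))
        if not bp_leaves:
            raise UsageError("ontology has no biological_process leaf to plant")
        planted_term = bp_leaves[0]
        if spec.planted_carriers > len(genes):
            raise UsageError("more planted carriers than genes")
        chosen = rng.choice(len(genes), size=spec.planted_carriers, replace=False)
        carriers = tuple(sorted(genes[int(i)] for i in chosen))
    direct: dict[str, frozenset[tuple[str, str]]] = {}
    if leaves and spec.background_term_rate > 0:
        mask = rng.random((len(genes), len(leaves))) < spec.background_term_rate
    else:
        mask = np.zeros((len(genes), max(len(leaves), 1)), dtype=bool)
    carrier_set = set(carriers)
    for gi, gene in enumerate(genes):
        pairs = {
            (leaves[ti], "IEA")
            for ti in np.nonzero(mask[gi])[0]
        }
        if gene in carrier_set and planted_term is not None:
            pairs.add((planted_term, "IEA"))
        if pairs:
            direct[gene] = frozenset(pairs)
    table = AnnotationTable(
        genome_id=proteome.genome_id, direct=direct, source=f"synthetic:{spec.seed}"
    )
    return AnnotationFixture(table=table, planted_term=planted_term, carriers=carriers)


# -- printed mapping-summary fixture ---------------------------------------------


@dataclass(frozen=True)
class Table1Row:
    species: str
    strain: str
    genome_id: str
    predicted: int
    annotated: int
    go_terms: int


@dataclass(frozen=True)
class Table1Fixture:
    """Published ten-strain mapping summary used for arithmetic checks.

    ``annotated_and_clustered`` is the number of reference transcripts that
    are both GO-annotated and members of an ortholog cluster; the namespace
    counts partition the reference genome's propagated term list.
    """

    rows: tuple[Table1Row, ...]
    reference_genome: str
    annotated_and_clustered: int
    reference_namespace_counts: dict[str, int]
    total_clustered_proteins: int
    n_ortholog_clusters: int
    reference_clustered_proteins: int

    @property
    def reference_row(self) -> Table1Row:
        return next(r for r in self.rows if r.genome_id == self.reference_genome)

    @property
    def total_predicted(self) -> int:
        return sum(r.predicted for r in self.rows)


def table1_fixture() -> Table1Fixture:
    """The printed ten-strain GO-annotation mapping summary, verbatim."""
    rows = (
        Table1Row("A. nidulans", "FGSC A4", "Anid_FGSC_A4", 10546, 3498, 5508),
        Table1Row("A. fumigatus", "AF2937", "Afum_AF293", 9846, 3443, 5445),
        Table1Row("A. fumigatus", "A1163", "Afum_A1163", 10109, 3450, 5446),
        Table1Row("A. flavus", "NRRL 3357", "Afla_NRRL3357", 13487, 3574, 5463),
        Table1Row("A. niger", "CBS 513.88", "Anig_CBS513", 14366, 3540, 5430),
        Table1Row("A. niger", "ATCC 1015", "Anig_ATCC1015", 11200, 3487, 5412),
        Table1Row("A. oryzae", "RIB40", "Aory_RIB40", 12319, 3502, 5434),
        Table1Row("A. terreus", "NIH 2624", "Ater_NIH2624", 10402, 3414, 5406),
        Table1Row("A. clavatus", "NRRL 1", "Acla_NRRL1", 9379, 3403, 5449),
        Table1Row("N. fischeri", "NRRL 181", "Nfis_NRRL181", 10728, 3543, 5445),
    )
    return Table1Fixture(
        rows=rows,
        reference_genome="Anid_FGSC_A4",
        annotated_and_clustered=3405,
        reference_namespace_counts={
            "biological_process": 3061,
            "molecular_function": 1753,
            "cellular_component": 694,
        },
        total_clustered_proteins=99679,
        n_ortholog_clusters=13179,
        reference_clustered_proteins=9250,
    )


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Dump planted structure as JSON for end-to-end runs."""
    payload = {
        "ortholog_groups": [sorted(map(list, g)) for g in truth.ortholog_groups],
        "paralog_families": {
            g: [sorted(f) for f in fams] for g, fams in truth.paralog_families.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
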