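"""Annotation projection across ortholog clusters, plus GAF/GMT/gene2terms I/O.

A well-annotated reference genome's GO annotation is projected onto every
member of each Jaccard orthologous cluster: the cluster-level term set is the
union of the direct terms of the cluster's annotated reference members, and
every member protein (reference proteins included, by default) receives
exactly that set.  Transferred records carry a computational evidence code
(IEA) and name the contributing reference gene(s) in their provenance.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .clustering import OrthologCluster, Proteome, round_half_up
from .errors import ParseError, UsageError
from .ontology import (
    ASPECT_NAMESPACE,
    DEFAULT_RELATIONS,
    NAMESPACE_ASPECT,
    NAMESPACES,
    OntologyGraph,
    propagate,
)

#: Evidence code for annotations inferred from orthology without curation.
TRANSFER_EVIDENCE = "IEA"

#: Fixed date stamp so written GAF files are byte-deterministic.
GAF_DATE = "20110101"
GAF_DB = "orthogo"
ANNOTATION_FORMATS = ("gaf", "gmt", "gene2terms")


@dataclass(frozen=True)
class AnnotationTable:
    """Gene -> direct GO annotation for one genome.

    ``direct`` maps each annotated gene to a set of ``(term, evidence)``
    pairs.  ``provenance`` optionally maps a gene to the reference gene(s)
    its annotation was transferred from (GAF With/From column).
    """

    genome_id: str
    direct: Mapping[str, frozenset[tuple[str, str]]]
    source: str = ""
    provenance: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def with_direct(
        self, direct: Mapping[str, frozenset[tuple[str, str]]]
    ) -> "AnnotationTable":
        return replace(self, direct=dict(direct))

    def terms_of(self, gene: str) -> frozenset[str]:
        return frozenset(t for t, _ in self.direct.get(gene, ()))

    def annotated_genes(self) -> frozenset[str]:
        return frozenset(g for g, pairs in self.direct.items() if pairs)

    def all_terms(self) -> frozenset[str]:
        return frozenset(t for pairs in self.direct.values() for t, _ in pairs)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AnnotationTable):
            return NotImplemented
        return (
            self.genome_id == other.genome_id
            and dict(self.direct) == dict(other.direct)
            and dict(self.provenance) == dict(other.provenance)
        )


# -- transfer ------------------------------------------------------------------


def transfer_annotations(
    ortholog_clusters: Sequence[OrthologCluster],
    reference: AnnotationTable,
    target_proteomes: Sequence[Proteome],
    evidence_code: str = TRANSFER_EVIDENCE,
    keep_reference_direct: bool = False,
) -> dict[str, AnnotationTable]:
    """Project the reference annotation onto every clustered protein.

    Each cluster's term set is the union of the direct terms of its
    reference-genome annotated members; all members of the cluster receive
    that identical set.  Proteins whose cluster contains no annotated
    reference member, and unclustered proteins, receive nothing.

    With ``keep_reference_direct`` the reference genome's own genes retain
    their original direct annotation instead of the (possibly larger)
    cluster-level union.
    """
    reference_genome = reference.genome_id
    if not any(p.genome_id == reference_genome for p in target_proteomes):
        raise UsageError(
            f"reference genome {reference_genome} is not among the proteomes"
        )
    direct: dict[str, dict[str, frozenset[tuple[str, str]]]] = {
        p.genome_id: {} for p in target_proteomes
    }
    provenance: dict[str, dict[str, frozenset[str]]] = {
        p.genome_id: {} for p in target_proteomes
    }
    for cluster in ortholog_clusters:
        annotated_refs = sorted(
            protein
            for genome, protein in cluster.members
            if genome == reference_genome and reference.direct.get(protein)
        )
        if not annotated_refs:
            continue
        terms = sorted(
            {t for p in annotated_refs for t, _ in reference.direct[p]}
        )
        pairs = frozenset((t, evidence_code) for t in terms)
        sources = frozenset(annotated_refs)
        for genome, protein in cluster.members:
            if genome not in direct:
                continue
            direct[genome][protein] = pairs
            provenance[genome][protein] = sources
    if keep_reference_direct and reference_genome in direct:
        for gene in list(direct[reference_genome]):
            if gene in reference.direct:
                direct[reference_genome][gene] = frozenset(reference.direct[gene])
                provenance[reference_genome].pop(gene, None)
    return {
        genome: AnnotationTable(
            genome_id=genome,
            direct=direct[genome],
            source=f"transfer:{reference_genome}",
            provenance=provenance[genome],
        )
        for genome in direct
    }


def unmapped_reference_genes(
    ortholog_clusters: Sequence[OrthologCluster], reference: AnnotationTable
) -> frozenset[str]:
    """Annotated reference genes contained in no ortholog cluster."""
    clustered = {
        protein
        for cluster in ortholog_clusters
        for genome, protein in cluster.members
        if genome == reference.genome_id
    }
    return frozenset(g for g in reference.annotated_genes() if g not in clustered)


# -- summary -------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeMappingRow:
    genome_id: str
    predicted: int
    annotated: int
    percent_annotated: int
    n_terms: int


@dataclass(frozen=True)
class MappingSummary:
    """Per-genome annotation coverage plus cross-genome aggregates.

    ``mean_annotated`` / ``mean_terms`` average over the non-reference
    genomes; ``namespace_counts`` and ``namespace_percents`` describe the
    reference genome's propagated distinct-term list.
    """

    rows: tuple[GenomeMappingRow, ...]
    reference_genome: str
    mean_annotated: float
    min_annotated: int
    max_annotated: int
    mean_terms: float
    namespace_counts: dict[str, int]
    namespace_percents: dict[str, int]

    @classmethod
    def from_counts(
        cls,
        rows: Sequence[GenomeMappingRow],
        reference_genome: str,
        namespace_counts: Mapping[str, int] | None = None,
    ) -> "MappingSummary":
        others = [r for r in rows if r.genome_id != reference_genome]
        if not others:  # single-genome table: aggregate over what we have
            others = list(rows)
        annotated = [r.annotated for r in others]
        terms = [r.n_terms for r in others]
        ns_counts = dict(namespace_counts or {})
        total_terms = sum(ns_counts.values())
        ns_percents = {
            ns: round_half_up(100 * ns_counts.get(ns, 0) / total_terms)
            if total_terms
            else 0
            for ns in NAMESPACES
        }
        return cls(
            rows=tuple(rows),
            reference_genome=reference_genome,
            mean_annotated=sum(annotated) / len(annotated) if annotated else 0.0,
            min_annotated=min(annotated) if annotated else 0,
            max_annotated=max(annotated) if annotated else 0,
            mean_terms=sum(terms) / len(terms) if terms else 0.0,
            namespace_counts=ns_counts,
            namespace_percents=ns_percents,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.genome_id, r.predicted, r.annotated, r.percent_annotated, r.n_terms)
                for r in self.rows
            ],
            columns=["genome", "predicted", "annotated", "percent", "go_terms"],
        )

    def to_text(self) -> str:
        lines = [
            f"{r.genome_id}: {r.annotated}/{r.predicted} transcripts GO-annotated "
            f"({r.percent_annotated}%), {r.n_terms} distinct propagated terms"
            for r in self.rows
        ]
        lines.append(
            f"mean annotated transcripts over non-reference genomes: "
            f"{self.mean_annotated:.1f} "
            f"(range {self.min_annotated}-{self.max_annotated}); "
            f"mean distinct terms: {self.mean_terms:.1f}"
        )
        if self.namespace_counts:
            parts = [
                f"{ns}: {self.namespace_counts.get(ns, 0)} "
                f"({self.namespace_percents.get(ns, 0)}%)"
                for ns in NAMESPACES
            ]
            lines.append(
                f"reference ({self.reference_genome}) propagated terms by "
                f"namespace: " + ", ".join(parts)
            )
        return "\n".join(lines)


def mapping_summary(
    tables: Mapping[str, AnnotationTable],
    proteomes: Sequence[Proteome],
    graph: OntologyGraph,
    reference_genome: str,
    relations: Iterable[str] = DEFAULT_RELATIONS,
    include_roots: bool = True,
) -> MappingSummary:
    """Compute coverage rows and aggregates from annotation tables.

    Distinct-term counts are over the ancestor-closed (propagated) term set
    of each genome; ``include_roots=False`` excludes the three namespace
    roots from those counts.
    """
    roots = set(graph.roots.values())
    rows = []
    reference_ns_counts: dict[str, int] = {}
    for proteome in proteomes:
        table = tables.get(proteome.genome_id)
        if table is None:
            continue
        closed = propagate(table, graph, relations)
        terms = set(closed.all_terms())
        if not include_roots:
            terms -= roots
        annotated = len(closed.annotated_genes())
        predicted = len(proteome.proteins)
        rows.append(
            GenomeMappingRow(
                genome_id=proteome.genome_id,
                predicted=predicted,
                annotated=annotated,
                percent_annotated=round_half_up(100 * annotated / predicted)
                if predicted
                else 0,
                n_terms=len(terms),
            )
        )
        if proteome.genome_id == reference_genome:
            reference_ns_counts = {
                ns: sum(1 for t in terms if graph[t].namespace == ns)
                for ns in NAMESPACES
            }
    return MappingSummary.from_counts(rows, reference_genome, reference_ns_counts)


# -- annotation file formats -----------------------------------------------------


def write_annotation(
    table: AnnotationTable,
    path,
    fmt: str,
    graph: OntologyGraph | None = None,
    date: str = GAF_DATE,
    db: str = GAF_DB,
) -> None:
    """Write an annotation table as GAF 2.x, GMT or gene2terms.

    Output is byte-deterministic: genes and terms are emitted sorted.
    GMT descriptions and GAF aspect letters require *graph*; without it the
    description falls back to the term id and the aspect is left blank.
    """
    if fmt not in ANNOTATION_FORMATS:
        raise UsageError(
            f"unknown annotation format {fmt!r}; expected one of {ANNOTATION_FORMATS}"
        )
    if not table.direct:
        raise UsageError("refusing to write an empty annotation table")
    writer = {"gaf": _write_gaf, "gmt": _write_gmt, "gene2terms": _write_gene2terms}[
        fmt
    ]
    with open(path, "w") as handle:
        writer(table, handle, graph=graph, date=date, db=db)


def _write_gaf(table, handle, graph=None, date=GAF_DATE, db=GAF_DB) -> None:
    handle.write("!gaf-version: 2.1\n")
    handle.write(f"!genome: {table.genome_id}\n")
    if table.source:
        handle.write(f"!source: {table.source}\n")
    for gene in sorted(table.direct):
        with_from = "|".join(sorted(table.provenance.get(gene, ())))
        for term, evidence in sorted(table.direct[gene]):
            aspect = ""
            if graph is not None:
                aspect = NAMESPACE_ASPECT.get(graph[term].namespace, "")
            fields = [
                db,  # 1 DB
                gene,  # 2 DB Object ID
                gene,  # 3 Symbol
                "",  # 4 Qualifier
                term,  # 5 GO ID
                f"{db}:transfer",  # 6 DB:Reference
                evidence,  # 7 Evidence
                with_from,  # 8 With/From
                aspect,  # 9 Aspect
                "",  # 10 Name
                "",  # 11 Synonym
                "protein",  # 12 Type
                "taxon:0",  # 13 Taxon
                date,  # 14 Date
                db,  # 15 Assigned by
                "",  # 16 Annotation extension
                "",  # 17 Gene product form
            ]
            handle.write("\t".join(fields) + "\n")


def _write_gmt(table, handle, graph=None, **_) -> None:
    by_term: dict[str, list[str]] = defaultdict(list)
    for gene in table.direct:
        for term, _ev in table.direct[gene]:
            by_term[term].append(gene)
    for term in sorted(by_term):
        description = term
        if graph is not None:
            description = graph[term].name or term
        genes = "\t".join(sorted(set(by_term[term])))
        handle.write(f"{term}\t{description}\t{genes}\n")


def _write_gene2terms(table, handle, **_) -> None:
    for gene in sorted(table.direct):
        terms = ",".join(sorted({t for t, _ in table.direct[gene]}))
        handle.write(f"{gene}\t{terms}\n")


def parse_gaf(source) -> AnnotationTable:
    """Parse a GAF 2.x file into an annotation table.

    Rows whose qualifier contains ``NOT`` are excluded.  Column 2 is the
    gene id, column 5 the term id, column 7 the evidence code and column 8
    the With/From provenance.  Wrong column counts raise a
    :class:`~orthogo.errors.ParseError` naming the line.
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        text = Path(source).read_text()
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()
    genome_id = ""
    table_source = ""
    direct: dict[str, set[tuple[str, str]]] = defaultdict(set)
    provenance: dict[str, frozenset[str]] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip():
            continue
        if raw.startswith("!"):
            header = raw[1:].strip()
            if header.startswith("genome:"):
                genome_id = header.split(":", 1)[1].strip()
            elif header.startswith("source:"):
                table_source = header.split(":", 1)[1].strip()
            continue
        fields = raw.split("\t")
        if len(fields) != 17:
            raise ParseError(
                f"line {lineno}: expected 17 tab-separated columns, "
                f"got {len(fields)}"
            )
        qualifier = fields[3]
        if "NOT" in qualifier.split("|"):
            continue
        gene, term, evidence, with_from = (
            fields[1],
            fields[4],
            fields[6],
            fields[7],
        )
        direct[gene].add((term, evidence))
        if with_from:
            provenance[gene] = frozenset(with_from.split("|"))
    return AnnotationTable(
        genome_id=genome_id,
        direct={g: frozenset(pairs) for g, pairs in direct.items()},
        source=table_source,
        provenance=provenance,
    )


def parse_gmt(source, genome_id: str = "", evidence: str = TRANSFER_EVIDENCE) -> AnnotationTable:
    """Parse a GMT file (term, description, member genes per line)."""
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        text = Path(source).read_text()
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()
    direct: dict[str, set[tuple[str, str]]] = defaultdict(set)
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) < 3:
            raise ParseError(
                f"line {lineno}: GMT lines need term, description and >=1 gene"
            )
        term = fields[0]
        for gene in fields[2:]:
            if gene:
                direct[gene].add((term, evidence))
    return AnnotationTable(
        genome_id=genome_id,
        direct={g: frozenset(pairs) for g, pairs in direct.items()},
    )


def parse_gene2terms(
    source, genome_id: str = "", evidence: str = TRANSFER_EVIDENCE
) -> AnnotationTable:
    """Parse a gene2terms file (gene TAB comma-separated term ids)."""
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        text = Path(source).read_text()
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()
    direct: dict[str, frozenset[tuple[str, str]]] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) != 2:
            raise ParseError(
                f"line {lineno}: expected 'gene<TAB>term,term,...', got "
                f"{len(fields)} columns"
            )
        gene, terms = fields
        direct[gene] = frozenset(
            (t, evidence) for t in terms.split(",") if t
        )
    return AnnotationTable(genome_id=genome_id, direct=direct)
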