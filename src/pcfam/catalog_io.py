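"""Readers and writers for the formats the pipeline touches.

Sequences travel as FASTA, gene models as GFF3, trees as Newick and
per-protein feature annotations (signal peptide, GPI-anchor signal,
plastocyanin-like-domain spans) as tab-separated tables.  Genomic
coordinates are 1-based inclusive throughout (GFF3 convention); protein
domain spans are 0-based half-open.  These two conventions meet only in
the converters of this module and :mod:`pcfam.phylo`.
"""

from __future__ import annotations

import io
import os
import tempfile
from dataclasses import dataclass, field

import dendropy
import gffutils
from Bio import SeqIO

__all__ = [
    "FormatError",
    "SequenceRecord",
    "GeneModel",
    "FeatureAnnotation",
    "Catalog",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_feature_table",
    "write_feature_table",
    "read_newick",
    "write_newick",
]

# IUPAC alphabets (uppercase); '*' permitted in proteins as a terminal stop.
_NUC = set("ACGTUNRYSWKMBDHV-")
_AA = set("ACDEFGHIKLMNPQRSTVWYBXZJUO*-")


class FormatError(ValueError):
    """Malformed or internally inconsistent input file."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single named sequence, either protein or CDS."""

    id: str
    residues: str
    kind: str = "protein"  # "protein" | "cds"


@dataclass
class GeneModel:
    """A gene's placement and exon-intron architecture.

    ``exons`` are 1-based inclusive (start, end) pairs sorted by start;
    ``introns`` are derived as the gaps between consecutive exons, each
    carrying the intron phase: the cumulative coding length upstream of
    the intron modulo 3, computed on the spliced 5'->3' coding
    orientation (so minus-strand genes are phased on the reverse
    complement order of their exons).
    """

    gene_id: str
    species: str
    chromosome: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    ordinal: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.start > self.end:
            raise FormatError(f"{self.gene_id}: start > end")
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise FormatError(f"{self.gene_id}: overlapping exons")
        for s, e in self.exons:
            if s > e:
                raise FormatError(f"{self.gene_id}: exon start > end")

    @property
    def n_introns(self) -> int:
        return max(len(self.exons) - 1, 0)

    @property
    def coding_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def introns(self) -> list[tuple[int, int, int]]:
        """(start, end, phase) of each intron, genomic coordinates.

        Phase is cumulative coding length upstream of the intron mod 3,
        counted along the coding direction.
        """
        if len(self.exons) < 2:
            return []
        gaps = [
            (e1 + 1, s2 - 1)
            for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]
        lengths = [e - s + 1 for s, e in self.exons]
        if self.strand == "+":
            upstream = [sum(lengths[: i + 1]) for i in range(len(gaps))]
            return [(g[0], g[1], u % 3) for g, u in zip(gaps, upstream)]
        # minus strand: coding order is reversed, intron i (genomic) is
        # preceded (in coding order) by the exons genomically after it
        upstream = [sum(lengths[i + 1 :]) for i in range(len(gaps))]
        return [(g[0], g[1], u % 3) for g, u in zip(gaps, upstream)]

    def intron_phases(self) -> list[int]:
        """Phases in coding (5'->3') order."""
        phases = [p for _, _, p in self.introns]
        return phases if self.strand == "+" else phases[::-1]


@dataclass
class FeatureAnnotation:
    """Externally predicted per-protein features.

    Flags come from upstream predictors (secretion signal, GPI-anchor
    signal) and domain searches (plastocyanin-like-domain spans); this
    package consumes them, it does not predict them.  Spans are 0-based
    half-open on the protein.
    """

    gene_id: str
    has_sp: bool
    has_gas: bool
    pcld_spans: list[tuple[int, int]] = field(default_factory=list)
    alr_spans: list[tuple[int, int]] = field(default_factory=list)
    n_glyc_sites: int | None = None

    def __post_init__(self) -> None:
        for s, e in self.pcld_spans:
            if s >= e:
                raise FormatError(
                    f"{self.gene_id}: malformed span {s}-{e} (start >= end)"
                )
        spans = sorted(self.pcld_spans)
        for (_, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 < e1:
                raise FormatError(f"{self.gene_id}: overlapping PCLD spans")

    @property
    def pcld_count(self) -> int:
        return len(self.pcld_spans)


@dataclass
class Catalog:
    """Per-species census plus the gene records behind it."""

    species: dict[str, dict] = field(default_factory=dict)
    genes: list[GeneModel] = field(default_factory=list)

    def validate(self) -> None:
        counts: dict[str, int] = {}
        for g in self.genes:
            counts[g.species] = counts.get(g.species, 0) + 1
        for name, row in self.species.items():
            expect = row.get("n_pc_genes")
            if expect is not None and counts.get(name, 0) != expect:
                raise FormatError(
                    f"{name}: catalog claims {expect} family genes, "
                    f"records hold {counts.get(name, 0)}"
                )


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path, kind: str = "protein") -> list[SequenceRecord]:
    """Read FASTA into order-preserving records with uppercased residues.

    Duplicate ids, empty files and non-IUPAC characters raise
    :class:`FormatError`.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    alphabet = _NUC if kind == "cds" else _AA
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id: {rec.id}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        bad = set(residues) - alphabet
        if bad:
            raise FormatError(
                f"{rec.id}: non-IUPAC characters {sorted(bad)!r}"
            )
        records.append(SequenceRecord(id=rec.id, residues=residues, kind=kind))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

def read_gff3(path, species: str | None = None) -> list[GeneModel]:
    """Parse gene/mRNA/exon features into :class:`GeneModel` records.

    One mRNA per gene is assumed (the first encountered is used).
    Ordinals are assigned by sorted start position within each
    chromosome, counting every gene present in the file.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        exons: list[tuple[int, int]] = []
        mrnas = list(db.children(gene, featuretype="mRNA", level=1))
        parent = mrnas[0] if mrnas else gene
        for ex in db.children(parent, featuretype="exon"):
            exons.append((ex.start, ex.end))
        if not exons:
            exons = [(gene.start, gene.end)]
        sp = species or gene.attributes.get("species", [""])[0] or "unknown"
        model = GeneModel(
            gene_id=gene.id,
            species=sp,
            chromosome=gene.seqid,
            strand=gene.strand,
            start=gene.start,
            end=gene.end,
            exons=exons,
        )
        if model.coding_length % 3 != 0:
            raise FormatError(
                f"{model.gene_id}: coding length {model.coding_length} "
                "not a multiple of 3"
            )
        models.append(model)
    _assign_ordinals(models)
    return models


def _assign_ordinals(models: list[GeneModel]) -> None:
    by_chrom: dict[tuple[str, str], list[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault((m.species, m.chromosome), []).append(m)
    for group in by_chrom.values():
        for rank, m in enumerate(sorted(group, key=lambda g: g.start), 1):
            m.ordinal = rank


def write_gff3(models, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in sorted(models, key=lambda g: (g.chromosome, g.start)):
            attrs = f"ID={m.gene_id};species={m.species}"
            fh.write(
                f"{m.chromosome}\tpcfam\tgene\t{m.start}\t{m.end}\t.\t"
                f"{m.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{m.chromosome}\tpcfam\tmRNA\t{m.start}\t{m.end}\t.\t"
                f"{m.strand}\t.\tID={m.gene_id}.1;Parent={m.gene_id}\n"
            )
            for s, e in m.exons:
                fh.write(
                    f"{m.chromosome}\tpcfam\texon\t{s}\t{e}\t.\t"
                    f"{m.strand}\t.\tParent={m.gene_id}.1\n"
                )


# ---------------------------------------------------------------------------
# feature table

def _parse_spans(text: str) -> list[tuple[int, int]]:
    spans = []
    text = text.strip()
    if not text or text == ".":
        return spans
    for part in text.split(";"):
        a, b = part.split("-")
        spans.append((int(a), int(b)))
    return spans


def read_feature_table(path, known_ids=None):
    """Read the feature TSV into ``gene_id -> FeatureAnnotation``.

    Columns: gene_id, has_sp, has_gas, pcld_spans (``;``-separated
    ``start-end`` in 0-based half-open protein coordinates), optional
    alr_spans and n_glyc.  When ``known_ids`` is given, rows whose
    gene_id is not in it are skipped and reported.

    Returns ``(annotations, skipped_ids)``.
    """
    annos: dict[str, FeatureAnnotation] = {}
    skipped: list[str] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col = {name: i for i, name in enumerate(header)}
        for need in ("gene_id", "has_sp", "has_gas", "pcld_spans"):
            if need not in col:
                raise FormatError(f"feature table missing column {need!r}")
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            gid = f[col["gene_id"]]
            if known_ids is not None and gid not in known_ids:
                skipped.append(gid)
                continue
            anno = FeatureAnnotation(
                gene_id=gid,
                has_sp=f[col["has_sp"]] in ("1", "true", "True"),
                has_gas=f[col["has_gas"]] in ("1", "true", "True"),
                pcld_spans=_parse_spans(f[col["pcld_spans"]]),
                alr_spans=_parse_spans(f[col["alr_spans"]])
                if "alr_spans" in col and len(f) > col["alr_spans"]
                else [],
            )
            annos[gid] = anno
    return annos, skipped


def write_feature_table(annos, path) -> None:
    def fmt(spans):
        return ";".join(f"{s}-{e}" for s, e in spans) or "."

    with open(path, "w") as fh:
        fh.write("gene_id\thas_sp\thas_gas\tpcld_spans\talr_spans\n")
        for anno in annos.values() if isinstance(annos, dict) else annos:
            fh.write(
                f"{anno.gene_id}\t{int(anno.has_sp)}\t{int(anno.has_gas)}\t"
                f"{fmt(anno.pcld_spans)}\t{fmt(anno.alr_spans)}\n"
            )


# ---------------------------------------------------------------------------
# Newick

def read_newick(source) -> dendropy.Tree:
    """Read a Newick tree, keeping internal node labels (V, E, T, ...)."""
    if isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
        with open(source) as fh:
            text = fh.read()
    else:
        text = str(source)
    if text.count("(") != text.count(")"):
        raise FormatError("unbalanced parentheses in Newick input")
    tree = dendropy.Tree.get(
        data=text,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    return tree


def tree_to_newick(tree: dendropy.Tree) -> str:
    """Serialize with branch lengths at 6 significant digits."""
    out = io.StringIO()
    tree.write(
        file=out,
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".6g",
    )
    return out.getvalue().strip() + ("" if out.getvalue().strip().endswith(";") else ";")


def write_newick(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree_to_newick(tree) + "\n")
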