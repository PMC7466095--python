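"""Readers, writers and coordinate conventions shared by every other module.

All coordinates are 1-based and inclusive on both ends, the native convention
of GFF3 and VCF. No half-open representation is exposed anywhere in the
package; :func:`interval_span` is the one place interval arithmetic happens.

Formats handled here:

* FASTA (wrapped at 60 columns) via Biopython,
* GFF3 restricted to ``gene`` / ``five_prime_UTR`` / ``CDS`` /
  ``three_prime_UTR`` / ``exon`` features,
* single-sample VCF v4.2 with ``DP`` in INFO and a ``GT`` genotype,
* 12-column tab-separated protein similarity hits (the de-facto standard
  tabular dialect emitted by protein search tools).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FEATURE_KINDS = ("five_prime_UTR", "CDS", "three_prime_UTR", "exon")


class FormatError(ValueError):
    """A file did not conform to its stated dialect."""


# ---------------------------------------------------------------------------
# coordinate arithmetic


def interval_span(start: int, end: int) -> int:
    """Length in bp of the 1-based inclusive interval ``[start, end]``.

    ``interval_span(70111740, 70120667) == 8928``: both endpoints count.
    """
    if start > end:
        raise ValueError(f"interval start {start} > end {end}")
    return end - start + 1


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Feature:
    kind: str
    start: int
    end: int

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.start > self.end:
            raise ValueError(f"feature start {self.start} > end {self.end}")


@dataclass
class GeneModel:
    """A gene with an ordered, non-overlapping feature layout."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        for f in self.features:
            if f.start < self.start or f.end > self.end:
                raise ValueError(
                    f"gene {self.gene_id}: feature {f.kind} "
                    f"[{f.start},{f.end}] outside gene span"
                )

    @property
    def span(self) -> int:
        return interval_span(self.start, self.end)

    def feature_of(self, kind: str) -> Feature | None:
        for f in self.features:
            if f.kind == kind:
                return f
        return None


@dataclass(frozen=True)
class VariantRecord:
    """One filtered variant call against a single reference genome."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotype_class: str = "homozygous"  # or "heterozygous"
    mean_depth: float = 0.0

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"variant position {self.pos} < 1")
        if not self.ref or not self.alt:
            raise ValueError("empty REF or ALT allele")

    @property
    def var_class(self) -> str:
        """``SNP`` iff both alleles are single bases, ``INDEL`` otherwise."""
        return "SNP" if len(self.ref) == 1 and len(self.alt) == 1 else "INDEL"


@dataclass(frozen=True)
class HitRecord:
    """One pairwise protein similarity hit (one row of the tabular dialect)."""

    query_id: str
    subject_id: str
    identity_pct: float
    aln_length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    score: float

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError("negative e-value")
        if not 0 <= self.identity_pct <= 100:
            raise ValueError(f"identity {self.identity_pct} outside [0, 100]")


# ---------------------------------------------------------------------------
# FASTA


def read_genome(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into a ``{chrom: sequence}`` mapping."""
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        genome[rec.id] = str(rec.seq).upper()
    if not genome:
        raise FormatError(f"{path}: no FASTA records found")
    return genome


def write_genome(genome: dict[str, str], path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="")
        for chrom, seq in genome.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3


def write_annotation(genes: list[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            fh.write(
                f"{g.chrom}\tintrodissect\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for i, f in enumerate(g.features):
                fh.write(
                    f"{g.chrom}\tintrodissect\t{f.kind}\t{f.start}\t{f.end}"
                    f"\t.\t{g.strand}\t{'0' if f.kind == 'CDS' else '.'}\t"
                    f"ID={g.gene_id}.{f.kind}.{i};Parent={g.gene_id}\n"
                )


def read_annotation(path: str | os.PathLike) -> list[GeneModel]:
    """Parse a GFF3 file into :class:`GeneModel` records.

    Only ``gene`` features and their UTR/CDS/exon children are retained.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise FormatError(f"{path}: not parseable as GFF3 ({exc})") from exc
    genes = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        feats = [
            Feature(child.featuretype, child.start, child.end)
            for child in db.children(
                g, featuretype=FEATURE_KINDS, order_by="start"
            )
        ]
        genes.append(
            GeneModel(
                gene_id=g.attributes.get("ID", [g.id])[0],
                chrom=g.seqid,
                start=g.start,
                end=g.end,
                strand=g.strand if g.strand in "+-" else "+",
                features=feats,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# VCF v4.2 (single sample, DP in INFO)


def write_variants(
    variants: list[VariantRecord],
    path: str | os.PathLike,
    contigs: dict[str, int] | None = None,
    sample: str = "line",
) -> None:
    gt = {"homozygous": "1/1", "heterozygous": "0/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,'
                 'Description="Mean depth of coverage">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{sample}\n"
        )
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t"
                f"DP={round(v.mean_depth)}\tGT\t{gt[v.genotype_class]}\n"
            )


def read_variants(path: str | os.PathLike) -> list[VariantRecord]:
    """Read a VCF into :class:`VariantRecord` list.

    INDELs are kept left-anchored as given; no re-normalization is done.
    """
    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise FormatError(
                    f"{path}: position {rec.chrom}:{rec.pos} is not "
                    "bi-allelic single-ALT"
                )
            depth = float(rec.info.get("DP", 0.0))
            gclass = "homozygous"
            if rec.samples:
                gt = rec.samples[0].get("GT")
                if gt is not None and len(set(a for a in gt if a is not None)) > 1:
                    gclass = "heterozygous"
            out.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    genotype_class=gclass,
                    mean_depth=depth,
                )
            )
    return out


# ---------------------------------------------------------------------------
# 12-column tabular hits

HIT_COLUMNS = (
    "query_id", "subject_id", "identity_pct", "aln_length", "mismatches",
    "gap_opens", "qstart", "qend", "sstart", "send", "evalue", "score",
)


def read_hits(path: str | os.PathLike) -> list[HitRecord]:
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(parts)}"
                )
            try:
                hits.append(
                    HitRecord(
                        query_id=parts[0],
                        subject_id=parts[1],
                        identity_pct=float(parts[2]),
                        aln_length=int(parts[3]),
                        mismatches=int(parts[4]),
                        gap_opens=int(parts[5]),
                        qstart=int(parts[6]),
                        qend=int(parts[7]),
                        sstart=int(parts[8]),
                        send=int(parts[9]),
                        evalue=float(parts[10]),
                        score=float(parts[11]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_hits(hits: list[HitRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(getattr(h, col)) for col in HIT_COLUMNS
                )
                + "\n"
            )
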