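"""Accessors for the packaged fixture tables.

The fixtures transcribe the three printed summary tables of the tomato
chromosome-7 introgression sub-line study this package models: the
per-chromosome DEG counts, the common-DEG list, and the donor/background
homology table — plus a synthetic hit table that encodes the hit structure
the homology table implies, a small restriction-enzyme resource and a
(synthetic-boundaries) gene model for the border gene Sopen07g024640.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io_formats import GeneModel, HitRecord, read_annotation, read_hits
from .orthology import OrthologyRelation

DONOR_CHROM = "Spenn-ch07"
BACKGROUND_CHROM = "SL4.0ch07"

#: Replaced background segment, iTAG4.1 coordinates (homology-table endpoints:
#: start of Solyc07g047990 to end of Solyc07g049310).
REPLACED_REGION_ITAG41 = (BACKGROUND_CHROM, 59_085_047, 59_488_648)

#: The same replaced segment in SL3.0 coordinates, the system the common-DEG
#: table prints. Start as in the homology table; end = SL3.0 end of the last
#: replaced gene (Solyc07g049310).
REPLACED_REGION_SL30 = ("7", 59_085_047, 59_695_592)

#: The donor border gene carrying the intra-gene crossover.
BORDER_GENE_ID = "Sopen07g024640"


def _path(name: str):
    return resources.files("introdissect").joinpath("data", name)


def _parse_pos(text: str) -> tuple[int, int, str]:
    """Parse a printed ``a-b`` position; reversed order encodes strand '-'."""
    a, b = (int(x) for x in text.split("-"))
    return (a, b, "+") if a <= b else (b, a, "-")


def load_table3(
) -> tuple[list[OrthologyRelation], list[GeneModel], list[GeneModel], dict]:
    """The printed homology table.

    Returns ``(relations, donor_genes, background_genes, flags)`` where
    ``flags`` maps a gene id to the printed flag (currently only
    ``partner_unlisted`` on the Sopen07g024590 row, whose background partner
    the source never names — it is preserved empty, not invented).
    """
    relations: list[OrthologyRelation] = []
    donor: dict[str, GeneModel] = {}
    background: dict[str, GeneModel] = {}
    flags: dict[str, str] = {}
    with _path("table3_relations.tsv").open() as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                continue
            d_id, d_pos, b_id, b_pos, relation, flag = line.split("\t")
            d_id = "" if d_id == "." else d_id
            b_id = "" if b_id == "." else b_id
            if relation in ("donor_specific", "background_specific"):
                relation = "species_specific_" + relation.split("_")[0]
            elif relation == "Homology":
                relation = "homology"
            if d_id and d_pos != ".":
                s, e, strand = _parse_pos(d_pos)
                # a gene printed twice keeps its first (non-repeated) span
                if d_id not in donor or donor[d_id].span < e - s + 1:
                    donor[d_id] = GeneModel(d_id, DONOR_CHROM, s, e, strand)
            if b_id and b_pos != ".":
                s, e, strand = _parse_pos(b_pos)
                background.setdefault(
                    b_id, GeneModel(b_id, BACKGROUND_CHROM, s, e, strand)
                )
            if flag != ".":
                flags[d_id or b_id] = flag
            relations.append(OrthologyRelation(d_id, b_id, relation))
    return (
        relations,
        sorted(donor.values(), key=lambda g: g.start),
        sorted(background.values(), key=lambda g: g.start),
        flags,
    )


def load_table3_hits() -> list[HitRecord]:
    """Synthetic hit table encoding the structure the homology table implies."""
    return read_hits(_path("table3_hits.tsv"))


def load_table1() -> pd.DataFrame:
    """Per-chromosome up/down DEG counts for the BR and MR contrasts."""
    with _path("table1_deg_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#", dtype={"chrom": str})


def load_table2() -> pd.DataFrame:
    """Common DEGs across the BR and MR stages, with SL3.0 coordinates."""
    with _path("table2_common_degs.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#", dtype={"chrom": str})


def load_enzymes():
    """Packaged restriction enzyme table as :class:`markers.Enzyme` records."""
    from .markers import Enzyme

    enzymes = []
    with _path("enzymes.tsv").open() as fh:
        header_seen = False
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if not header_seen:
                header_seen = True
                continue
            name, site, off = line.split("\t")
            enzymes.append(Enzyme(name, site, int(off)))
    return enzymes


def load_border_gene_model() -> GeneModel:
    """Border gene model (published span, synthetic feature boundaries)."""
    with resources.as_file(
        _path("sopen07g024640_model_synthetic.gff3")
    ) as p:
        genes = read_annotation(p)
    (gene,) = genes
    return gene
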