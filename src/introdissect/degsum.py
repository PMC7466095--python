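"""Differential-expression table summaries.

DEG tables are consumed, not computed — the upstream count modelling lives in
dedicated expression pipelines. Here they are reduced to the summaries an
introgression study reports: per-chromosome up/down counts per contrast,
genes significant in both developmental stages (split by concordant
direction), and the intersection with the introgressed region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

log = logging.getLogger(__name__)

DEG_COLUMNS = ("gene_id", "chrom", "start", "end", "logFC", "fdr")


@dataclass(frozen=True)
class DEGRecord:
    gene_id: str
    chrom: str
    start: int
    end: int
    logFC: float
    fdr: float
    contrast: str = ""

    def __post_init__(self):
        if not 0 <= self.fdr <= 1:
            raise ValueError(f"{self.gene_id}: FDR {self.fdr} outside [0, 1]")


def read_deg_table(path, contrast: str = "") -> list[DEGRecord]:
    """Read a delimited DEG table (gene_id, chrom, start, end, logFC, fdr)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    missing = set(DEG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        DEGRecord(
            gene_id=r.gene_id, chrom=str(r.chrom), start=int(r.start),
            end=int(r.end), logFC=float(r.logFC), fdr=float(r.fdr),
            contrast=contrast,
        )
        for r in df.itertuples()
    ]


def significant(
    records: list[DEGRecord], fdr_threshold: float = 0.05
) -> list[DEGRecord]:
    """Records with ``fdr < threshold`` (strict); direction = sign(logFC).

    A record with logFC exactly 0 passing the FDR cut has no direction; it is
    flagged and excluded.
    """
    out = []
    for r in records:
        if r.fdr >= fdr_threshold:
            continue
        if r.logFC == 0:
            log.warning(
                "%s: significant (FDR %g) but logFC 0 — direction "
                "ambiguous, excluded", r.gene_id, r.fdr,
            )
            continue
        out.append(r)
    return out


def direction(r: DEGRecord) -> str:
    return "up" if r.logFC > 0 else "down"


def per_chromosome_counts(
    by_contrast: dict[str, list[DEGRecord]]
) -> pd.DataFrame:
    """Up/down counts per chromosome and contrast, with a Total row.

    Input records must already be significance-filtered; the counts partition
    each contrast's set.
    """
    rows: dict[str, dict[str, int]] = {}
    columns = []
    for contrast, records in by_contrast.items():
        for dirn in ("up", "down"):
            columns.append(f"{contrast}_{dirn}")
        for r in records:
            key = f"{contrast}_{direction(r)}"
            rows.setdefault(r.chrom, {}).setdefault(key, 0)
            rows[r.chrom][key] += 1
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    df = df.reindex(columns=columns, fill_value=0)
    df = df.sort_index(key=lambda idx: [
        (0, int(c)) if str(c).isdigit() else (1, str(c)) for c in idx
    ])
    df.loc["Total"] = df.sum()
    df.index.name = "chrom"
    return df


def common_degs(
    records_a: list[DEGRecord], records_b: list[DEGRecord]
) -> tuple[set[str], set[str], set[str]]:
    """Genes significant in both contrasts, split by direction.

    Returns ``(common_up, common_down, discordant)``; discordant genes are
    significant in both but with opposite signs and belong to neither common
    set.
    """
    dir_a = {r.gene_id: direction(r) for r in records_a}
    dir_b = {r.gene_id: direction(r) for r in records_b}
    both = set(dir_a) & set(dir_b)
    up = {g for g in both if dir_a[g] == dir_b[g] == "up"}
    down = {g for g in both if dir_a[g] == dir_b[g] == "down"}
    return up, down, both - up - down


def intersect_region(
    records: list[DEGRecord], region: tuple[str, int, int]
) -> list[DEGRecord]:
    """Records whose gene span overlaps the region (1-based inclusive)."""
    chrom, start, end = region
    if start > end:
        return []
    return [
        r for r in records
        if r.chrom == chrom and r.start <= end and r.end >= start
    ]
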