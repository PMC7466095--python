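"""Breakpoint inference, genome merging, annotation lift-over and gene order.

The introgression line's genome is background outside the donor block and
donor inside it. Variant data bounds each breakpoint only to an open
uncertainty interval: between the last background-diagnostic position before
the block and the first donor-diagnostic variant inside it (and mirrored at
the upper edge). The merge places its cut inside that interval (midpoint by
default) and records a piecewise, invertible coordinate map from both
parental genomes into the reconstructed one.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

from .ancestry import AncestryCall
from .io_formats import Feature, GeneModel, VariantRecord


class NoIntrogressionError(ValueError):
    pass


class MultipleBlocksError(ValueError):
    pass


@dataclass
class BreakpointInterval:
    """Open uncertainty intervals around one donor block.

    ``None`` bounds mean the block runs into a chromosome edge.
    Lower edge: ``(last_background_pos, first_donor_pos)``;
    upper edge: ``(last_donor_pos, first_background_pos)``.
    All positions are background-genome coordinates.
    """

    chrom: str
    last_background_pos: int | None
    first_donor_pos: int
    last_donor_pos: int
    first_background_pos: int | None
    block_gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if (
            self.last_background_pos is not None
            and self.last_background_pos >= self.first_donor_pos
        ):
            raise ValueError("lower uncertainty interval is empty")
        if (
            self.first_background_pos is not None
            and self.last_donor_pos >= self.first_background_pos
        ):
            raise ValueError("upper uncertainty interval is empty")

    def cut_points(self, chrom_len: int, placement: str = "midpoint"
                   ) -> tuple[int, int]:
        """Concrete cut positions (last background base kept on each side)."""
        lo = 0 if self.last_background_pos is None else self.last_background_pos
        hi = (
            chrom_len + 1
            if self.first_background_pos is None
            else self.first_background_pos
        )
        if placement == "midpoint":
            return (lo + self.first_donor_pos) // 2, (self.last_donor_pos + hi) // 2
        if placement == "last_donor":
            return self.first_donor_pos - 1, self.last_donor_pos
        if placement == "first_background":
            return lo, hi - 1
        raise ValueError(f"unknown cut placement {placement!r}")


@dataclass(frozen=True)
class MapSegment:
    source: str  # background | donor
    source_chrom: str
    source_start: int
    source_end: int
    target_chrom: str
    target_start: int
    target_end: int

    def __post_init__(self):
        if (self.source_end - self.source_start) != (
            self.target_end - self.target_start
        ):
            raise ValueError("segment source/target lengths differ")


class ReconstructionMap:
    """Piecewise coordinate map from the parental genomes into the target.

    Target segments are contiguous and non-overlapping per target chromosome;
    every segment preserves length, so the map is invertible per source.
    """

    def __init__(self, segments: list[MapSegment]):
        by_target: dict[str, list[MapSegment]] = {}
        for s in segments:
            by_target.setdefault(s.target_chrom, []).append(s)
        for chrom, segs in by_target.items():
            segs.sort(key=lambda s: s.target_start)
            pos = 1
            for s in segs:
                if s.target_start != pos:
                    raise ValueError(
                        f"target {chrom}: segments not contiguous at {pos}"
                    )
                pos = s.target_end + 1
        self.segments = sorted(
            segments, key=lambda s: (s.target_chrom, s.target_start)
        )

    def __iter__(self):
        return iter(self.segments)

    def __len__(self):
        return len(self.segments)

    def segment_for(
        self, source: str, chrom: str, pos: int
    ) -> MapSegment | None:
        for s in self.segments:
            if (
                s.source == source
                and s.source_chrom == chrom
                and s.source_start <= pos <= s.source_end
            ):
                return s
        return None

    def lift(self, source: str, chrom: str, pos: int) -> tuple[str, int]:
        s = self.segment_for(source, chrom, pos)
        if s is None:
            raise KeyError(f"{source} {chrom}:{pos} not covered by the map")
        return s.target_chrom, s.target_start + (pos - s.source_start)

    def invert(self, target_chrom: str, pos: int) -> tuple[str, str, int]:
        """Map a target position back to ``(source, chrom, pos)``."""
        for s in self.segments:
            if s.target_chrom == target_chrom and (
                s.target_start <= pos <= s.target_end
            ):
                return (
                    s.source,
                    s.source_chrom,
                    s.source_start + (pos - s.target_start),
                )
        raise KeyError(f"target {target_chrom}:{pos} not covered")


@dataclass
class LiftoverResult:
    lifted: list[GeneModel]
    chimeric_candidates: list[GeneModel]
    unmapped: list[GeneModel]


@dataclass
class SegmentOrderReport:
    pairs: list[tuple[int, int]]  # (background rank, donor rank)
    collinear: list[tuple[int, int]]
    translocated_blocks: list[list[str]]  # donor gene ids per block


@dataclass
class GeneAccounting:
    n_donor: int
    n_background: int
    donor_segment_sizes: list[int]
    donor_segments: list[tuple[int, int]]  # donor-coordinate spans


# ---------------------------------------------------------------------------
# breakpoint inference


def infer_breakpoints(
    calls: list[AncestryCall],
    genes: list[GeneModel],
    variants_vs_background: list[VariantRecord],
    max_bridged_unknowns: int = 3,
    strict_single_block: bool = True,
) -> list[BreakpointInterval]:
    """Locate donor blocks in coordinate-ordered ancestry calls.

    A donor block is a maximal run of donor calls; interleaved unknown calls
    (unexpressed genes) bridge the run up to ``max_bridged_unknowns`` in a
    row — real pipelines bridge such gaps with markers. A background call
    always ends the block. Donor-diagnostic positions are the
    variants-vs-background inside block gene spans; background-side bounds
    use the flanking background-called gene ends (background coordinates).
    """
    gene_by_id = {g.gene_id: g for g in genes}
    ordered = sorted(
        (c for c in calls if c.gene_id in gene_by_id),
        key=lambda c: (gene_by_id[c.gene_id].chrom, gene_by_id[c.gene_id].start),
    )
    if not any(c.call == "donor" for c in ordered):
        raise NoIntrogressionError("no introgression detected: zero donor calls")

    var_by_chrom: dict[str, list[int]] = {}
    for v in sorted(variants_vs_background, key=lambda v: (v.chrom, v.pos)):
        var_by_chrom.setdefault(v.chrom, []).append(v.pos)

    blocks: list[tuple[str, list[AncestryCall]]] = []  # (chrom, donor/unknown calls)
    cur: list[AncestryCall] = []
    pending_unknowns: list[AncestryCall] = []
    cur_chrom: str | None = None

    def close():
        nonlocal cur, pending_unknowns
        if cur:
            blocks.append((cur_chrom, cur))
        cur, pending_unknowns = [], []

    for c in ordered:
        chrom = gene_by_id[c.gene_id].chrom
        if chrom != cur_chrom:
            close()
            cur_chrom = chrom
        if c.call == "donor":
            if cur and len(pending_unknowns) <= max_bridged_unknowns:
                cur.extend(pending_unknowns)
            elif cur:
                close()
            pending_unknowns = []
            cur.append(c)
        elif c.call == "unknown":
            if cur:
                pending_unknowns.append(c)
        else:  # background
            close()
    close()

    if strict_single_block and len(blocks) > 1:
        desc = "; ".join(
            f"{chrom}:{b[0].gene_id}..{b[-1].gene_id}" for chrom, b in blocks
        )
        raise MultipleBlocksError(
            f"{len(blocks)} donor blocks found in strict mode: {desc}"
        )

    intervals = []
    for chrom, block in blocks:
        block_ids = [c.gene_id for c in block]
        first_gene = gene_by_id[block_ids[0]]
        last_gene = gene_by_id[block_ids[-1]]
        chrom_calls = [
            c for c in ordered if gene_by_id[c.gene_id].chrom == chrom
        ]
        bg_before = [
            gene_by_id[c.gene_id].end
            for c in chrom_calls
            if c.call == "background"
            and gene_by_id[c.gene_id].end < first_gene.start
        ]
        bg_after = [
            gene_by_id[c.gene_id].start
            for c in chrom_calls
            if c.call == "background"
            and gene_by_id[c.gene_id].start > last_gene.end
        ]
        positions = var_by_chrom.get(chrom, [])
        lo = bisect.bisect_left(positions, first_gene.start)
        hi = bisect.bisect_right(positions, last_gene.end)
        in_block = positions[lo:hi]
        if not in_block:
            raise NoIntrogressionError(
                f"donor block {block_ids[0]}..{block_ids[-1]} has no "
                "diagnostic variants against the background reference"
            )
        intervals.append(
            BreakpointInterval(
                chrom=chrom,
                last_background_pos=max(bg_before) if bg_before else None,
                first_donor_pos=in_block[0],
                last_donor_pos=in_block[-1],
                first_background_pos=min(bg_after) if bg_after else None,
                block_gene_ids=block_ids,
            )
        )
    return intervals


# ---------------------------------------------------------------------------
# genome merge


def merge_genomes(
    background: dict[str, str],
    donor: dict[str, str],
    donor_source_span: tuple[str, int, int],
    interval: BreakpointInterval,
    cut_placement: str = "midpoint",
    target_suffix: str = "",
) -> tuple[dict[str, str], ReconstructionMap]:
    """Merge the parental genomes into the reconstructed line genome.

    Target = background up to the lower cut + the donor span + background
    from after the upper cut. Chromosomes without a breakpoint pass through
    unchanged. Length conservation holds by construction:
    ``|target| = |background| - replaced + inserted``.
    """
    d_chrom, d_start, d_end = donor_source_span
    if d_start > d_end + 1:
        raise ValueError("invalid donor span")
    segments: list[MapSegment] = []
    target: dict[str, str] = {}
    for chrom, seq in background.items():
        tchrom = chrom + target_suffix
        if chrom != interval.chrom or d_start > d_end:
            target[tchrom] = seq
            segments.append(
                MapSegment("background", chrom, 1, len(seq), tchrom, 1, len(seq))
            )
            continue
        lower_cut, upper_cut = interval.cut_points(len(seq), cut_placement)
        if not 0 <= lower_cut < upper_cut <= len(seq):
            raise ValueError(
                f"overlapping or out-of-range cuts ({lower_cut}, {upper_cut})"
            )
        dseq = donor[d_chrom][d_start - 1: d_end]
        target[tchrom] = seq[:lower_cut] + dseq + seq[upper_cut:]
        pos = 1
        if lower_cut >= 1:
            segments.append(
                MapSegment("background", chrom, 1, lower_cut, tchrom, 1,
                           lower_cut)
            )
            pos = lower_cut + 1
        segments.append(
            MapSegment("donor", d_chrom, d_start, d_end, tchrom, pos,
                       pos + len(dseq) - 1)
        )
        pos += len(dseq)
        if upper_cut < len(seq):
            segments.append(
                MapSegment("background", chrom, upper_cut + 1, len(seq),
                           tchrom, pos, pos + (len(seq) - upper_cut) - 1)
            )
    return target, ReconstructionMap(segments)


def liftover(
    rmap: ReconstructionMap, genes: list[GeneModel], source: str
) -> LiftoverResult:
    """Transfer gene models onto the reconstructed genome.

    Genes fully inside one map segment are shifted by the segment offset.
    Genes spanning a junction land in ``chimeric_candidates`` (never lifted
    silently); genes outside every segment of their source are ``unmapped``.
    """
    lifted, chimeric, unmapped = [], [], []
    for g in genes:
        s = rmap.segment_for(source, g.chrom, g.start)
        if s is None:
            s_end = rmap.segment_for(source, g.chrom, g.end)
            (chimeric if s_end is not None else unmapped).append(g)
            continue
        if g.end > s.source_end:
            chimeric.append(g)
            continue
        delta = s.target_start - s.source_start
        lifted.append(
            GeneModel(
                gene_id=g.gene_id,
                chrom=s.target_chrom,
                start=g.start + delta,
                end=g.end + delta,
                strand=g.strand,
                features=[
                    Feature(f.kind, f.start + delta, f.end + delta)
                    for f in g.features
                ],
            )
        )
    return LiftoverResult(lifted, chimeric, unmapped)


# ---------------------------------------------------------------------------
# gene order / synteny check


def longest_increasing_subsequence(seq: list[int]) -> list[int]:
    """Indices of one longest strictly-increasing subsequence (O(n log n)).

    Among equally long subsequences the lexicographically earliest index set
    produced by the patience construction is returned — deterministic.
    """
    if not seq:
        return []
    tails: list[int] = []  # index of smallest tail of each length
    prev = [-1] * len(seq)
    for i, x in enumerate(seq):
        lo = bisect.bisect_left([seq[t] for t in tails], x)
        if lo == len(tails):
            tails.append(i)
        else:
            tails[lo] = i
        prev[i] = tails[lo - 1] if lo > 0 else -1
    out = []
    i = tails[-1]
    while i != -1:
        out.append(i)
        i = prev[i]
    return out[::-1]


def segment_order_check(
    pairs: list[tuple[str, str]],
    donor_order: list[str],
    background_order: list[str],
) -> SegmentOrderReport:
    """Collinearity of one-to-one ortholog pairs between the parents.

    ``pairs`` are (donor_gene_id, background_gene_id); duplications must be
    collapsed to their best pair beforehand. The collinear subset is a
    longest strictly-increasing subsequence over rank pairs; each maximal
    excluded run is a translocated block.
    """
    if not pairs:
        return SegmentOrderReport([], [], [])
    d_rank = {g: i for i, g in enumerate(donor_order)}
    b_rank = {g: i for i, g in enumerate(background_order)}
    rank_pairs = sorted(
        ((b_rank[b], d_rank[d], d) for d, b in pairs
         if d in d_rank and b in b_rank)
    )
    donor_ranks = [p[1] for p in rank_pairs]
    keep = set(longest_increasing_subsequence(donor_ranks))
    collinear = [rank_pairs[i][:2] for i in sorted(keep)]
    blocks: list[list[str]] = []
    run: list[str] = []
    for i, (_, _, d_id) in enumerate(rank_pairs):
        if i in keep:
            if run:
                blocks.append(run)
                run = []
        else:
            run.append(d_id)
    if run:
        blocks.append(run)
    return SegmentOrderReport(
        pairs=[p[:2] for p in rank_pairs],
        collinear=collinear,
        translocated_blocks=blocks,
    )


def one_to_one_pairs(relations) -> list[tuple[str, str]]:
    """BBH and homology pairs plus each duplicated group's best pair.

    Relations with an empty partner id (species-specific or an unlisted
    partner) are excluded.
    """
    pairs = []
    best_dup: dict[tuple[str, str], tuple[float, str, str]] = {}
    for r in relations:
        if not r.donor_gene_id or not r.background_gene_id:
            continue
        if r.relation in ("BBH", "homology"):
            pairs.append((r.donor_gene_id, r.background_gene_id))
        elif r.relation.startswith("duplicated"):
            # group key: the shared partner side
            key = (
                ("b", r.background_gene_id)
                if r.relation == "duplicated_donor"
                else ("d", r.donor_gene_id)
            )
            cand = (r.score, r.donor_gene_id, r.background_gene_id)
            cur = best_dup.get(key)
            # higher score wins; on equal score keep first-listed member
            if cur is None or cand[0] > cur[0]:
                best_dup.setdefault(key, cand)
                if cur is not None and cand[0] > cur[0]:
                    best_dup[key] = cand
    pairs.extend((d, b) for _, d, b in best_dup.values())
    return sorted(pairs)


def gene_accounting(
    donor_genes: list[GeneModel],
    background_genes: list[GeneModel],
    max_gap: int = 300_000,
) -> GeneAccounting:
    """Count the introgressed and replaced genes and the donor segments.

    Donor genes are clustered into segments by coordinate: a gap larger than
    ``max_gap`` between consecutive genes starts a new segment (the donor
    assembly may split one introgression into distant segments).
    """
    donor_sorted = sorted(donor_genes, key=lambda g: (g.chrom, g.start))
    segments: list[list[GeneModel]] = []
    for g in donor_sorted:
        if (
            segments
            and segments[-1][-1].chrom == g.chrom
            and g.start - segments[-1][-1].end <= max_gap
        ):
            segments[-1].append(g)
        else:
            segments.append([g])
    return GeneAccounting(
        n_donor=len({g.gene_id for g in donor_genes}),
        n_background=len({g.gene_id for g in background_genes}),
        donor_segment_sizes=[len(s) for s in segments],
        donor_segments=[(s[0].start, s[-1].end) for s in segments],
    )
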