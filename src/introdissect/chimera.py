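"""Intra-gene recombination localization from a three-way alignment.

A border gene crossed by the introgression breakpoint is chimeric: part of
its sequence follows the donor allele, the rest the background allele. Given
an alignment of the line's sequence with both parental alleles, every column
where the parents differ is a diagnostic site; the crossover is localized to
the open interval between the last donor-supporting and the first
background-supporting site, by maximizing concordance on each side of a
split (equivalently, minimizing misclassified sites — robust to single
sequencing errors, unlike a first-discordant-site rule).
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import GeneModel


class NoChimeraError(ValueError):
    """No split with the required support on both sides."""


@dataclass(frozen=True)
class DiagnosticSite:
    """One position where the parental alleles differ."""

    pos: int  # anchored reference coordinate (1-based)
    background_allele: str
    donor_allele: str
    line_allele: str
    support: str  # matches_donor | matches_background | matches_neither

    def __post_init__(self):
        if self.background_allele == self.donor_allele:
            raise ValueError(
                f"site at {self.pos} is not diagnostic: parents agree"
            )


@dataclass
class ChimeraReport:
    gene_id: str
    last_donor_site: int
    first_background_site: int
    n_donor_side: int
    n_background_side: int
    n_mismatched: int  # sites misclassified by the best split
    n_sites_total: int

    @property
    def interval(self) -> tuple[int, int]:
        """Open recombination interval (exclusive bounds)."""
        return (self.last_donor_site, self.first_background_site)


# ---------------------------------------------------------------------------


def call_diagnostic_sites(
    line: str,
    donor: str,
    background: str,
    anchor: int = 1,
) -> list[DiagnosticSite]:
    """Extract diagnostic sites from three equal-length aligned rows.

    ``anchor`` is the reference coordinate of the first non-gap base of the
    anchor row (the background row by default convention; pass the donor
    allele's coordinate when the alignment is anchored on the donor genome —
    the caller must be explicit, coordinates are never guessed). A run of
    alignment columns in which any row is gapped is treated as a single
    site at its anchored position.
    """
    if not (len(line) == len(donor) == len(background)):
        raise ValueError("aligned rows have unequal lengths")
    sites: list[DiagnosticSite] = []
    ref_pos = anchor - 1  # last consumed reference position
    i = 0
    n = len(line)
    while i < n:
        gapped = "-" in (line[i], donor[i], background[i])
        if gapped:
            j = i
            while j < n and "-" in (line[j], donor[j], background[j]):
                j += 1
            b = background[i:j].replace("-", "")
            d = donor[i:j].replace("-", "")
            l_ = line[i:j].replace("-", "")
            site_pos = ref_pos if background[i] == "-" else ref_pos + 1
            if b != d:
                sites.append(_site(site_pos, b or "-", d or "-", l_ or "-"))
            ref_pos += len(b)
            i = j
            continue
        if background[i] != "-":
            ref_pos += 1
        if donor[i] != background[i]:
            sites.append(_site(ref_pos, background[i], donor[i], line[i]))
        i += 1
    return sites


def _site(pos: int, b: str, d: str, l_: str) -> DiagnosticSite:
    if l_ == d:
        support = "matches_donor"
    elif l_ == b:
        support = "matches_background"
    else:
        support = "matches_neither"
    return DiagnosticSite(pos, b, d, l_, support)


def locate_recombination(
    sites: list[DiagnosticSite],
    gene_id: str = "",
    min_run: int = 3,
) -> ChimeraReport:
    """Best single-crossover split of an ordered diagnostic-site list.

    Finds the split index maximizing (donor-supporting sites before) +
    (background-supporting sites after). ``matches_neither`` sites are
    excluded from the objective but counted in ``n_sites_total``. Requires at
    least ``min_run`` supporting sites on each side of the best split, else
    :class:`NoChimeraError` — a handful of discordant calls must not fake a
    crossover.
    """
    ordered = sorted(sites, key=lambda s: s.pos)
    informative = [
        s for s in ordered if s.support in ("matches_donor", "matches_background")
    ]
    n = len(informative)
    best_score, best_split = -1, None
    donor_prefix = 0
    bg_total = sum(1 for s in informative if s.support == "matches_background")
    bg_after = bg_total
    # split k: sites [0,k) on the donor side, [k,n) on the background side
    for k in range(n + 1):
        score = donor_prefix + bg_after
        if score > best_score:
            best_score, best_split = score, k
        if k < n:
            if informative[k].support == "matches_donor":
                donor_prefix += 1
            else:
                bg_after -= 1
    k = best_split
    donor_side = [
        s for s in informative[:k] if s.support == "matches_donor"
    ]
    bg_side = [
        s for s in informative[k:] if s.support == "matches_background"
    ]
    if len(donor_side) < min_run or len(bg_side) < min_run:
        raise NoChimeraError(
            "no chimera detected: best split has "
            f"{len(donor_side)} donor-side and {len(bg_side)} "
            f"background-side supporting sites (min_run={min_run})"
        )
    return ChimeraReport(
        gene_id=gene_id,
        last_donor_site=donor_side[-1].pos,
        first_background_site=bg_side[0].pos,
        n_donor_side=len(donor_side),
        n_background_side=len(bg_side),
        n_mismatched=n - best_score,
        n_sites_total=len(ordered),
    )


def annotate_interval(
    report: ChimeraReport, gene: GeneModel
) -> list[str]:
    """Feature kinds overlapping the open recombination interval.

    Returns ``["intergenic"]`` when the interval falls between features.
    An interval outside the gene span is an error.
    """
    a, b = report.interval
    if b <= gene.start or a >= gene.end:
        raise ValueError(
            f"interval ({a}, {b}) outside gene {gene.gene_id} span "
            f"[{gene.start}, {gene.end}]"
        )
    # a feature overlaps the OPEN interval (a, b) iff it covers some
    # position strictly between the bounds
    kinds = [
        f.kind
        for f in gene.features
        if max(f.start, a + 1) <= min(f.end, b - 1)
    ]
    return kinds if kinds else ["intergenic"]


def count_residual_differences(
    seg_a: str, seg_b: str
) -> tuple[int, int]:
    """Substitutions and indel runs between two aligned segments.

    One maximal gap run counts as one INDEL regardless of length.
    """
    if len(seg_a) != len(seg_b):
        raise ValueError("aligned segments have unequal lengths")
    n_snp = n_indel = 0
    in_gap = False
    for x, y in zip(seg_a, seg_b):
        if x == "-" or y == "-":
            if x != y and not in_gap:
                n_indel += 1
            in_gap = x != y
        else:
            in_gap = False
            if x != y:
                n_snp += 1
    return n_snp, n_indel
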