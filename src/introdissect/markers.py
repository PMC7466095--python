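"""In-silico SCAR/CAPS marker evaluation.

Genes the variant data leaves unknown (typically unexpressed, so no
RNA-derived variants exist) are genotyped with sequence markers instead:
a PCR amplicon is located by exact primer matching (SCAR: presence/size),
digested with a restriction enzyme whose fragment pattern differs between the
parental alleles (CAPS), and the line's pattern is matched against both
parents. Informative marker genotypes then resolve the unknown ancestry
calls — never overriding variant evidence silently.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace

from .ancestry import AncestryCall

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class AmbiguousAmpliconError(ValueError):
    """The primer pair amplifies more than one locus."""


@dataclass(frozen=True)
class PrimerPair:
    forward: str
    reverse: str
    max_product_length: int = 10_000

    def __post_init__(self):
        for name, p in (("forward", self.forward), ("reverse", self.reverse)):
            if len(p) < 15:
                raise ValueError(f"{name} primer shorter than 15 bp")
            if set(p) - set("ACGT"):
                raise ValueError(f"{name} primer not over ACGT")


@dataclass(frozen=True)
class Enzyme:
    name: str
    site: str
    cut_offset: int  # 0-based offset within the site; 0 cuts 5' of the site

    def __post_init__(self):
        if len(self.site) < 4:
            raise ValueError("recognition sequence shorter than 4 bp")
        if set(self.site) - set("ACGT"):
            raise ValueError("recognition sequence not over ACGT")
        if not 0 <= self.cut_offset <= len(self.site):
            raise ValueError("cut offset outside recognition site")


@dataclass
class CapsAssay:
    marker_id: str
    gene_id: str
    primers: PrimerPair
    enzyme: Enzyme
    expected_background: Counter
    expected_donor: Counter

    def informative(self) -> bool:
        return self.expected_background != self.expected_donor


@dataclass(frozen=True)
class Amplicon:
    chrom: str
    start: int
    end: int
    sequence: str


# ---------------------------------------------------------------------------


def _find_all(haystack: str, needle: str) -> list[int]:
    """All (possibly overlapping) 0-based occurrences."""
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def find_amplicon(
    genome: dict[str, str], primers: PrimerPair
) -> Amplicon | None:
    """Locate the unique PCR product of an exactly matching primer pair.

    The forward primer must match the plus strand and the reverse primer's
    reverse complement must occur downstream within the size limit. Returns
    ``None`` when nothing amplifies (itself a SCAR genotype signal); raises
    :class:`AmbiguousAmpliconError` when several loci would amplify.
    """
    rc = revcomp(primers.reverse)
    products: list[Amplicon] = []
    for chrom, seq in genome.items():
        for f in _find_all(seq, primers.forward):
            limit = f + primers.max_product_length
            for r in _find_all(seq[f: limit], rc):
                end = f + r + len(rc)
                products.append(Amplicon(chrom, f + 1, end, seq[f:end]))
    # a fwd site with several rev sites yields nested products; also check
    # the opposite orientation is NOT accepted: rc search is downstream only
    if not products:
        return None
    if len(products) > 1:
        loci = ", ".join(f"{p.chrom}:{p.start}-{p.end}" for p in products)
        raise AmbiguousAmpliconError(f"multiple products: {loci}")
    return products[0]


def digest(sequence: str, enzyme: Enzyme) -> Counter:
    """Fragment-length multiset after complete digestion.

    Cuts at every (overlapping occurrences included) recognition site, at the
    enzyme's cut offset; fragment lengths always sum to the input length.
    """
    cuts = sorted(
        {
            i + enzyme.cut_offset
            for i in _find_all(sequence, enzyme.site)
            if 0 < i + enzyme.cut_offset < len(sequence)
        }
    )
    bounds = [0] + cuts + [len(sequence)]
    return Counter(
        b - a for a, b in zip(bounds, bounds[1:])
    )


def caps_genotype(
    line_fragments: Counter,
    background_fragments: Counter,
    donor_fragments: Counter,
) -> str:
    """Call a line's genotype from digestion fragment patterns.

    Patterns are compared as exact length multisets. Equal parental patterns
    make the assay uninformative regardless of the line.
    """
    if background_fragments == donor_fragments:
        return "uninformative"
    if line_fragments == background_fragments:
        return "background"
    if line_fragments == donor_fragments:
        return "donor"
    union = background_fragments | donor_fragments  # co-migrating bands merge
    combined = background_fragments + donor_fragments
    if line_fragments in (union, combined):
        return "heterozygous"
    return "uninformative"


def design_caps(
    background_amplicon: str,
    donor_amplicon: str,
    enzymes: list[Enzyme],
) -> list[tuple[Enzyme, Counter, Counter]]:
    """Enzymes whose digestion patterns distinguish the two amplicons.

    Returns ``(enzyme, background_pattern, donor_pattern)`` triples; every
    returned enzyme is informative by construction (patterns differ).
    """
    if not enzymes:
        raise ValueError("empty enzyme table")
    out = []
    for e in enzymes:
        pb = digest(background_amplicon, e)
        pd = digest(donor_amplicon, e)
        if pb != pd:
            out.append((e, pb, pd))
    return out


def resolve_unknowns(
    calls: list[AncestryCall],
    marker_genotypes: dict[str, str],
) -> list[AncestryCall]:
    """Fill unknown ancestry calls from marker genotypes.

    Unknown calls with an informative marker genotype (``donor`` or
    ``background``) become that genotype with provenance ``marker``. A marker
    contradicting existing variant evidence raises the call's ``conflict``
    flag but never overwrites it.
    """
    out = []
    for c in calls:
        geno = marker_genotypes.get(c.gene_id)
        if geno not in ("donor", "background"):
            out.append(c)
        elif c.call == "unknown":
            out.append(replace(c, call=geno, provenance="marker"))
        elif c.call != geno:
            out.append(replace(c, conflict=True))
        else:
            out.append(c)
    return out


# ---------------------------------------------------------------------------
# assay design against two parental genomes


def _occurrences(genome: dict[str, str], kmer: str) -> int:
    return sum(len(_find_all(seq, kmer)) for seq in genome.values())


def _conserved_unique_kmer(
    background: dict[str, str],
    donor: dict[str, str],
    chrom: str,
    lo: int,
    hi: int,
    k: int,
    step: int = 7,
) -> str | None:
    """A k-mer from background[chrom][lo:hi] present exactly once in both
    parental genomes (0-based half-open window)."""
    seq = background[chrom]
    for p in range(max(0, lo), min(hi, len(seq)) - k, step):
        kmer = seq[p: p + k]
        if set(kmer) - set("ACGT"):
            continue
        if _occurrences(background, kmer) == 1 and _occurrences(donor, kmer) == 1:
            return kmer
    return None


def design_gene_assay(
    background: dict[str, str],
    donor: dict[str, str],
    bg_gene,
    enzymes: list[Enzyme],
    primer_len: int = 20,
    flank: int = 400,
) -> CapsAssay | None:
    """Design a CAPS assay spanning one gene.

    Primers are picked from flanking sequence conserved between the parents
    (a k-mer occurring exactly once in each genome), so the assay amplifies
    regardless of the locus ancestry; the first enzyme whose fragment
    pattern differs between the two parental amplicons makes it a CAPS
    marker. Returns ``None`` when no conserved primer pair or no informative
    enzyme exists.
    """
    chrom = bg_gene.chrom
    fwd = _conserved_unique_kmer(
        background, donor, chrom,
        bg_gene.start - 1 - flank, bg_gene.start - 1 - primer_len,
        primer_len,
    )
    rev_site = _conserved_unique_kmer(
        background, donor, chrom,
        bg_gene.end + primer_len, bg_gene.end + flank,
        primer_len,
    )
    if fwd is None or rev_site is None:
        return None
    primers = PrimerPair(
        fwd, revcomp(rev_site),
        max_product_length=(bg_gene.end - bg_gene.start + 1) + 2 * flank + 200,
    )
    try:
        amp_bg = find_amplicon(background, primers)
        amp_dn = find_amplicon(donor, primers)
    except AmbiguousAmpliconError:
        return None
    if amp_bg is None or amp_dn is None:
        return None
    informative = design_caps(amp_bg.sequence, amp_dn.sequence, enzymes)
    if not informative:
        return None
    enzyme, pat_bg, pat_dn = informative[0]
    return CapsAssay(
        marker_id=f"caps_{bg_gene.gene_id}",
        gene_id=bg_gene.gene_id,
        primers=primers,
        enzyme=enzyme,
        expected_background=pat_bg,
        expected_donor=pat_dn,
    )


def genotype_with_assay(
    line_genome: dict[str, str], assay: CapsAssay
) -> str:
    """Apply a CAPS assay to a genome in silico.

    ``no_amplification`` is itself a SCAR-style signal and is returned as
    such rather than guessed into a parental call.
    """
    try:
        amp = find_amplicon(line_genome, assay.primers)
    except AmbiguousAmpliconError:
        return "uninformative"
    if amp is None:
        return "no_amplification"
    return caps_genotype(
        digest(amp.sequence, assay.enzyme),
        assay.expected_background,
        assay.expected_donor,
    )
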