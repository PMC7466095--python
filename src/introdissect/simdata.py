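"""Synthetic parental genomes, a planted introgression line, and its data.

The generator emulates the statistical structure of an introgression
sub-line experiment: two divergent parental genomes (a cultivated background
and a wild donor) sharing most genes, a homozygous introgressed block on one
chromosome whose lower crossover can fall inside the 3'UTR of the last block
gene (producing a chimeric border gene), RNA-derived variant calls whose
visibility depends on gene expression, and differential-expression tables
with planted truth sets. Everything is emitted together with a
machine-readable :class:`TruthRecord` so downstream inference can be scored.

Default rates are calibrated to the regime published for the system this
package models: an ~80:20 SNP:indel mixture and an average of ~17 variants
per gene between the parental alleles. Two floors are part of the generator
contract (not tunable noise): every shared gene carries at least a handful
of substitutions (all wild genes in the emulated study were diagnosable),
and the chimeric border gene carries exactly 6 substitutions + 3 indels in
its background-derived 3' tail — the published residual divergence — with a
guaranteed excess of donor-derived variants ahead of the crossover.

Determinism: all draws come from ``numpy`` generators seeded from
``SimConfig.seed`` (separate fixed streams for genome generation, planting,
each variant set, and the DEG tables), consumed in a fixed documented order,
so identical configs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import Feature, GeneModel, VariantRecord

BASES = np.frombuffer(b"ACGT", dtype="S1")

UTR5_LEN = 150
CDS_LEN = 1200
UTR3_LEN = 450
UTR3A_LEN = 250  # donor-derived part of the chimeric gene's 3'UTR
GENE_LEN = UTR5_LEN + CDS_LEN + UTR3_LEN
MIN_GAP = 1000

# generator contract floors (see module docstring)
MIN_SUBS_CDS = 4
MIN_SUBS_CDS_CHIMERIC = 12
MIN_SUBS_UTR3A = 4
TAIL_SUBS = 6
TAIL_INDELS = 3
INDEL_CAP = 50


class SimConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for one simulated introgression line."""

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 120_000
    n_genes_per_chromosome: int = 20
    snp_rate: float = 0.007           # substitutions per bp between parents
    indel_rate: float = 0.00175       # ~80:20 SNP:indel mixture
    indel_len_geometric_p: float = 0.5
    n_species_specific_donor: int = 2
    n_species_specific_background: int = 2
    n_duplicated: int = 1
    introgression_chromosome: int = 0
    introgression_gene_span: tuple[int, int] = (6, 13)
    breakpoint_in_utr: bool = True
    expression_dropout: float = 0.0   # fraction of genes emitting no variants
    variant_error_rate: float = 0.0   # spurious variants per bp per callset
    n_deg_up: int = 7                 # planted common up/downregulated sets
    n_deg_down: int = 8

    def validate(self) -> None:
        for name in ("snp_rate", "indel_rate", "indel_len_geometric_p",
                     "expression_dropout", "variant_error_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SimConfigError(f"{name} must be in [0, 1], got {v}")
        if self.indel_len_geometric_p == 0:
            raise SimConfigError("indel_len_geometric_p must be > 0")
        if self.n_chromosomes < 1:
            raise SimConfigError("n_chromosomes must be >= 1")
        n = self.n_genes_per_chromosome
        if n < 1:
            raise SimConfigError("n_genes_per_chromosome must be >= 1")
        min_len = n * GENE_LEN + (n + 1) * MIN_GAP
        if self.chromosome_length < min_len:
            raise SimConfigError(
                f"chromosome_length {self.chromosome_length} below the "
                f"minimal footprint {min_len} for {n} genes"
            )
        if not 0 <= self.introgression_chromosome < self.n_chromosomes:
            raise SimConfigError(
                "introgression_chromosome outside chromosome count"
            )
        i0, i1 = self.introgression_gene_span
        if i1 >= i0 and not (0 <= i0 <= i1 < n):
            raise SimConfigError(
                f"introgression_gene_span {self.introgression_gene_span} "
                f"outside the gene count {n}"
            )
        if i1 >= i0 and not self.breakpoint_in_utr and i1 >= n - 1:
            raise SimConfigError(
                "introgression_gene_span must end before the last gene "
                "when the upper crossover falls in intergenic space"
            )
        specials = (self.n_species_specific_donor
                    + self.n_species_specific_background + self.n_duplicated)
        if specials > n:
            raise SimConfigError(
                "more special genes requested than slots per chromosome"
            )
        if self.n_chromosomes == 1 and specials and i1 >= i0:
            if i1 >= n - specials:
                raise SimConfigError(
                    "introgression span overlaps special gene slots on the "
                    "single chromosome"
                )


@dataclass
class TruthRecord:
    """Ground truth for one simulated line."""

    gene_ancestry: dict[str, str] = field(default_factory=dict)
    donor_block_genes: list[str] = field(default_factory=list)
    chrom: str | None = None
    lower_breakpoint: int | None = None   # last background bp before donor
    upper_breakpoint: int | None = None   # last donor-derived bp (bg coords)
    chimeric_gene: str | None = None
    crossover_feature: str | None = None
    species_specific_donor: list[str] = field(default_factory=list)
    species_specific_background: list[str] = field(default_factory=list)
    duplicated: list[tuple[str, str]] = field(default_factory=list)
    unexpressed: set[str] = field(default_factory=set)
    deg_up: dict[str, set[str]] = field(default_factory=dict)
    deg_down: dict[str, set[str]] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        d = self.__dict__.copy()
        d["unexpressed"] = sorted(self.unexpressed)
        d["deg_up"] = {k: sorted(v) for k, v in self.deg_up.items()}
        d["deg_down"] = {k: sorted(v) for k, v in self.deg_down.items()}
        d["duplicated"] = [list(t) for t in self.duplicated]
        return d


@dataclass
class Segment:
    """One mutation unit: an intergenic stretch or one gene feature part.

    ``ops`` are atomic background→donor edits ``(p0, ref, alt)`` with
    0-based segment-local anchor ``p0``; ``ref`` starts at that background
    position (indels carry their anchor base, VCF-style).
    """

    kind: str                  # intergenic | five_prime_UTR | CDS | ...
    part: str                  # layout label (gapA, gapB, utr3a, ...)
    gene_slot: int | None
    bg_seq: str
    donor_seq: str = ""
    ops: list[tuple[int, str, str]] = field(default_factory=list)
    in_block: bool = False
    bg_start: int = 0          # 1-based global, filled at assembly
    donor_start: int = 0

    def donor_local(self, p0: int) -> int:
        """Donor-local coordinate of a background-local op anchor."""
        off = 0
        for p, ref, alt in self.ops:
            if p >= p0:
                break
            off += len(alt) - len(ref)
        return p0 + off


@dataclass
class SimGene:
    gene_id: str
    chrom: str
    slot: int
    role: str                  # shared | donor_only | background_only | duplicated_donor
    seg_indices: list[int]


@dataclass
class SimChromosome:
    name: str
    segments: list[Segment]
    genes: list[SimGene]


@dataclass
class ParentalPair:
    config: SimConfig
    chroms: list[SimChromosome]
    truth: TruthRecord
    background_genome: dict[str, str]
    donor_genome: dict[str, str]
    background_genes: list[GeneModel]
    donor_genes: list[GeneModel]

    def gene(self, gene_id: str) -> tuple[SimChromosome, SimGene]:
        for c in self.chroms:
            for g in c.genes:
                if g.gene_id == gene_id:
                    return c, g
        raise KeyError(gene_id)


@dataclass
class LineSim:
    parents: ParentalPair
    genome: dict[str, str]
    truth: TruthRecord

    @property
    def config(self) -> SimConfig:
        return self.parents.config


# ---------------------------------------------------------------------------
# low-level draws


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(BASES, size=n).tobytes().decode()


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(0, 3)]


def _sample_ops(
    seq: str,
    rng: np.random.Generator,
    snp_rate: float,
    indel_rate: float,
    geom_p: float,
    min_subs: int = 0,
    exact: tuple[int, int] | None = None,
) -> list[tuple[int, str, str]]:
    """Draw non-overlapping background→donor edits for one segment.

    Draw order (fixed for reproducibility): indel count, then per indel its
    length, type and anchor; then substitution count and positions; then the
    substituted bases. ``exact=(n_subs, n_indels)`` overrides both counts
    (used for the chimeric tail); ``min_subs`` is a floor on the
    substitution count.
    """
    m = len(seq)
    blocked = np.zeros(m, dtype=bool)
    ops: list[tuple[int, str, str]] = []

    if exact is not None:
        n_sub, n_ind = exact
    else:
        n_ind = rng.binomial(m, indel_rate)
        n_sub = None  # drawn after indels, keeping stream order fixed

    for _ in range(n_ind):
        length = int(min(rng.geometric(geom_p), INDEL_CAP))
        is_ins = rng.random() < 0.5
        foot = 2 if is_ins else length + 1
        if m < foot + 4:
            continue
        for _try in range(10):
            p0 = int(rng.integers(1, m - foot))
            window = blocked[max(0, p0 - 1): p0 + foot + 1]
            if not window.any():
                break
        else:
            continue
        if is_ins:
            ins = _random_seq(rng, length)
            ops.append((p0, seq[p0], seq[p0] + ins))
        else:
            ops.append((p0, seq[p0: p0 + length + 1], seq[p0]))
        blocked[p0: p0 + foot] = True

    if n_sub is None:
        n_sub = int(rng.binomial(m, snp_rate))
        n_sub = max(n_sub, min_subs)
    free = np.flatnonzero(~blocked)
    n_sub = min(n_sub, len(free))
    if n_sub:
        pos = rng.choice(free, size=n_sub, replace=False)
        for p0 in sorted(int(p) for p in pos):
            ops.append((p0, seq[p0], _other_base(rng, seq[p0])))
    return sorted(ops)


def _apply_ops(seq: str, ops: list[tuple[int, str, str]]) -> str:
    out = []
    cursor = 0
    for p0, ref, alt in ops:
        out.append(seq[cursor:p0])
        out.append(alt)
        cursor = p0 + len(ref)
    out.append(seq[cursor:])
    return "".join(out)


# ---------------------------------------------------------------------------
# generation


def generate_parents(config: SimConfig) -> ParentalPair:
    """Build the two parental genomes, annotations and the truth skeleton."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes_per_chromosome
    i0, i1 = config.introgression_gene_span
    has_block = i1 >= i0
    gap_total = config.chromosome_length - n * GENE_LEN
    gap = gap_total // (n + 1)
    last_gap = gap_total - n * gap

    # assign special roles to the tail slots of one non-introgression
    # chromosome (or the tail of the single chromosome)
    special_chrom = (
        (config.introgression_chromosome + 1) % config.n_chromosomes
    )
    roles_by_slot: dict[tuple[int, int], str] = {}
    slot = n - 1
    for role, count in (
        ("donor_only", config.n_species_specific_donor),
        ("background_only", config.n_species_specific_background),
        ("duplicated_donor", config.n_duplicated),
    ):
        for _ in range(count):
            roles_by_slot[(special_chrom, slot)] = role
            slot -= 1

    truth = TruthRecord()
    chroms: list[SimChromosome] = []
    for ci in range(config.n_chromosomes):
        name = f"chr{ci + 1}"
        is_intro = has_block and ci == config.introgression_chromosome
        segments: list[Segment] = []
        genes: list[SimGene] = []
        for slot in range(n):
            glen = gap if slot < n else last_gap
            # split the gaps flanking the block so each half is its own
            # mutation unit and the cut falls exactly on a segment boundary
            if is_intro and slot == i0:
                segments.append(Segment("intergenic", "gapA", None,
                                        _random_seq(rng, glen // 2)))
                segments.append(Segment("intergenic", "gapB", None,
                                        _random_seq(rng, glen - glen // 2),
                                        in_block=True))
            elif is_intro and slot == i1 + 1 and not config.breakpoint_in_utr:
                segments.append(Segment("intergenic", "gapC1", None,
                                        _random_seq(rng, glen // 2),
                                        in_block=True))
                segments.append(Segment("intergenic", "gapC2", None,
                                        _random_seq(rng, glen - glen // 2)))
            else:
                # gaps between block genes travel with the block
                gap_in_block = is_intro and i0 < slot <= i1
                segments.append(Segment("intergenic", "gap", None,
                                        _random_seq(rng, glen),
                                        in_block=gap_in_block))
            role = roles_by_slot.get((ci, slot), "shared")
            gene_id = f"g{ci + 1:02d}_{slot:03d}"
            in_block = is_intro and i0 <= slot <= i1
            chimeric = (
                is_intro and config.breakpoint_in_utr and slot == i1
            )
            first = len(segments)
            segments.append(Segment("five_prime_UTR", "utr5", slot,
                                    _random_seq(rng, UTR5_LEN),
                                    in_block=in_block))
            segments.append(Segment("CDS", "cds", slot,
                                    _random_seq(rng, CDS_LEN),
                                    in_block=in_block))
            if chimeric:
                segments.append(Segment("three_prime_UTR", "utr3a", slot,
                                        _random_seq(rng, UTR3A_LEN),
                                        in_block=True))
                segments.append(Segment("three_prime_UTR", "utr3b", slot,
                                        _random_seq(rng,
                                                    UTR3_LEN - UTR3A_LEN)))
            else:
                segments.append(Segment("three_prime_UTR", "utr3", slot,
                                        _random_seq(rng, UTR3_LEN),
                                        in_block=in_block))
            genes.append(SimGene(gene_id, name, slot, role,
                                 list(range(first, len(segments)))))
            if role == "donor_only":
                truth.species_specific_donor.append(gene_id)
            elif role == "background_only":
                truth.species_specific_background.append(gene_id)
        tail = last_gap if n else gap_total
        segments.append(Segment("intergenic", "gap", None,
                                _random_seq(rng, tail)))
        chroms.append(SimChromosome(name, segments, genes))

    # mutate: derive the donor allele of every segment (fixed order);
    # the contract floors only apply when there is divergence at all, so a
    # zero-rate config yields two identical genomes
    diverged = config.snp_rate > 0 or config.indel_rate > 0
    for ci, chrom in enumerate(chroms):
        gene_by_seg: dict[int, SimGene] = {}
        for g in chrom.genes:
            for si in g.seg_indices:
                gene_by_seg[si] = g
        for si, seg in enumerate(chrom.segments):
            g = gene_by_seg.get(si)
            if g is not None and g.role != "shared":
                # species-specific / duplicated loci: donor side is an
                # unrelated sequence (no homology), no alignable ops
                seg.donor_seq = _random_seq(rng, len(seg.bg_seq))
                seg.ops = []
                continue
            if not diverged:
                seg.ops = []
                seg.donor_seq = seg.bg_seq
                continue
            if seg.part == "utr3b":
                # the fixed residual-tail counts only make sense for the
                # variant classes the config actually generates
                exact = (TAIL_SUBS if config.snp_rate > 0 else 0,
                         TAIL_INDELS if config.indel_rate > 0 else 0)
                seg.ops = _sample_ops(
                    seg.bg_seq, rng, config.snp_rate, config.indel_rate,
                    config.indel_len_geometric_p, exact=exact,
                )
            else:
                min_subs = 0
                if g is not None and seg.kind == "CDS":
                    is_chimeric_cds = any(
                        chrom.segments[j].part == "utr3a"
                        for j in g.seg_indices
                    )
                    min_subs = (MIN_SUBS_CDS_CHIMERIC if is_chimeric_cds
                                else MIN_SUBS_CDS)
                elif seg.part == "utr3a":
                    min_subs = MIN_SUBS_UTR3A
                seg.ops = _sample_ops(
                    seg.bg_seq, rng, config.snp_rate, config.indel_rate,
                    config.indel_len_geometric_p, min_subs=min_subs,
                )
            seg.donor_seq = _apply_ops(seg.bg_seq, seg.ops)

    # duplicated donor genes copy a neighbouring shared gene's donor CDS
    for chrom in chroms:
        for g in chrom.genes:
            if g.role != "duplicated_donor":
                continue
            source = next(
                (s for s in reversed(chrom.genes[:g.slot]) if s.role == "shared"),
                None,
            )
            if source is None:
                continue
            src_cds = next(
                chrom.segments[j] for j in source.seg_indices
                if chrom.segments[j].kind == "CDS"
            )
            cds = next(
                chrom.segments[j] for j in g.seg_indices
                if chrom.segments[j].kind == "CDS"
            )
            light = _sample_ops(src_cds.donor_seq, rng, 0.01, 0.0,
                                config.indel_len_geometric_p)
            cds.donor_seq = _apply_ops(src_cds.donor_seq, light)
            truth.duplicated.append((g.gene_id, source.gene_id))

    # planted DEG truth over shared background-annotation genes
    shared = [
        g.gene_id for c in chroms for g in c.genes if g.role == "shared"
    ]
    k = config.n_deg_up + config.n_deg_down
    picked = [shared[int(i)] for i in
              rng.choice(len(shared), size=min(k, len(shared)),
                         replace=False)]
    up = set(picked[: config.n_deg_up])
    down = set(picked[config.n_deg_up:])
    truth.deg_up = {"BR": set(up), "MR": set(up)}
    truth.deg_down = {"BR": set(down), "MR": set(down)}

    _assemble_coordinates(chroms)
    bg_genome = {
        c.name: "".join(s.bg_seq for s in c.segments) for c in chroms
    }
    dn_genome = {
        c.name: "".join(s.donor_seq for s in c.segments) for c in chroms
    }
    bg_genes = _gene_models(chroms, "background")
    dn_genes = _gene_models(chroms, "donor")
    return ParentalPair(config, chroms, truth, bg_genome, dn_genome,
                        bg_genes, dn_genes)


def _assemble_coordinates(chroms: list[SimChromosome]) -> None:
    for chrom in chroms:
        bg_pos = dn_pos = 1
        for seg in chrom.segments:
            seg.bg_start = bg_pos
            seg.donor_start = dn_pos
            bg_pos += len(seg.bg_seq)
            dn_pos += len(seg.donor_seq)


def _gene_models(chroms: list[SimChromosome], which: str) -> list[GeneModel]:
    """Gene models in background or donor coordinates.

    Shared genes keep one id in both annotations (real data would add an
    ortholog map between the two species' id namespaces).
    """
    out: list[GeneModel] = []
    for chrom in chroms:
        for g in chrom.genes:
            if which == "background" and g.role in ("donor_only",
                                                    "duplicated_donor"):
                continue
            if which == "donor" and g.role == "background_only":
                continue
            feats: list[Feature] = []
            for si in g.seg_indices:
                seg = chrom.segments[si]
                if which == "background":
                    s, length = seg.bg_start, len(seg.bg_seq)
                else:
                    s, length = seg.donor_start, len(seg.donor_seq)
                if length == 0:
                    continue
                if feats and feats[-1].kind == seg.kind:
                    feats[-1] = Feature(seg.kind, feats[-1].start,
                                        s + length - 1)
                else:
                    feats.append(Feature(seg.kind, s, s + length - 1))
            out.append(
                GeneModel(g.gene_id, chrom.name, feats[0].start,
                          feats[-1].end, "+", feats)
            )
    return out


# ---------------------------------------------------------------------------
# planting


def plant_introgression(parents: ParentalPair) -> LineSim:
    """Replace the configured block of the background with donor sequence.

    The line equals the background outside the block and the donor inside;
    with ``breakpoint_in_utr`` the upper crossover falls at the utr3a/utr3b
    boundary inside the last block gene, making it chimeric. Expression
    dropout is drawn here (stream ``[seed, 1]``) so both variant sets see
    the same unexpressed genes.
    """
    config = parents.config
    rng = np.random.default_rng([config.seed, 1])
    truth = parents.truth
    i0, i1 = config.introgression_gene_span
    has_block = i1 >= i0

    genome: dict[str, str] = {}
    for chrom in parents.chroms:
        genome[chrom.name] = "".join(
            seg.donor_seq if seg.in_block else seg.bg_seq
            for seg in chrom.segments
        )

    for chrom in parents.chroms:
        for g in chrom.genes:
            if g.role != "shared":
                continue
            in_block = any(
                chrom.segments[si].in_block for si in g.seg_indices
            )
            truth.gene_ancestry[g.gene_id] = (
                "donor" if in_block else "background"
            )
            if in_block:
                truth.donor_block_genes.append(g.gene_id)

    if has_block:
        intro = parents.chroms[config.introgression_chromosome]
        truth.chrom = intro.name
        gapA = next(s for s in intro.segments if s.part == "gapA")
        truth.lower_breakpoint = gapA.bg_start + len(gapA.bg_seq) - 1
        if config.breakpoint_in_utr:
            utr3a = next(s for s in intro.segments if s.part == "utr3a")
            truth.upper_breakpoint = utr3a.bg_start + len(utr3a.bg_seq) - 1
            truth.chimeric_gene = truth.donor_block_genes[-1]
            truth.crossover_feature = "three_prime_UTR"
        else:
            gapC1 = next(s for s in intro.segments if s.part == "gapC1")
            truth.upper_breakpoint = gapC1.bg_start + len(gapC1.bg_seq) - 1

    # expression dropout over shared genes (fixed iteration order)
    truth.unexpressed = set()
    for chrom in parents.chroms:
        for g in chrom.genes:
            if g.role == "shared" and rng.random() < config.expression_dropout:
                truth.unexpressed.add(g.gene_id)
    return LineSim(parents, genome, truth)


# ---------------------------------------------------------------------------
# variant simulation


def simulate_variant_calls(
    line: LineSim, reference: str
) -> list[VariantRecord]:
    """Variant calls of the line against one parental reference.

    For every expressed gene of that reference's annotation, every
    line-vs-reference mismatch inside the gene span is emitted as a
    homozygous variant (positions in reference coordinates); unexpressed
    genes emit nothing; spurious variants are added at
    ``variant_error_rate`` per bp as isolated singletons, at most one per
    gene, so they can never mimic a donor block.

    Streams: ``[seed, 2]`` for the background callset, ``[seed, 3]`` for the
    donor callset.
    """
    if reference not in ("background", "donor"):
        raise ValueError("reference must be 'background' or 'donor'")
    parents = line.parents
    config = parents.config
    rng = np.random.default_rng(
        [config.seed, 2 if reference == "background" else 3]
    )
    truth = line.truth
    variants: list[VariantRecord] = []
    used_positions: set[tuple[str, int]] = set()

    for chrom in parents.chroms:
        for g in chrom.genes:
            if g.gene_id in truth.unexpressed:
                continue
            if reference == "background" and g.role in (
                "donor_only", "duplicated_donor",
            ):
                continue
            if reference == "donor" and g.role == "background_only":
                continue
            if g.role != "shared":
                # species-specific loci have no alignable counterpart in
                # the line (outside the block the line is background)
                continue
            for si in g.seg_indices:
                seg = chrom.segments[si]
                line_is_donor = seg.in_block
                if reference == "background" and line_is_donor:
                    for p0, ref, alt in seg.ops:
                        pos = seg.bg_start + p0
                        variants.append(VariantRecord(
                            chrom.name, pos, ref, alt,
                            "homozygous",
                            float(rng.poisson(25) + 1),
                        ))
                        used_positions.add((chrom.name, pos))
                elif reference == "donor" and not line_is_donor:
                    for p0, ref, alt in seg.ops:
                        pos = seg.donor_start + seg.donor_local(p0)
                        variants.append(VariantRecord(
                            chrom.name, pos, alt, ref,
                            "homozygous",
                            float(rng.poisson(25) + 1),
                        ))
                        used_positions.add((chrom.name, pos))

    # spurious singleton calls in expressed genes
    if config.variant_error_rate > 0:
        ref_genome = (
            parents.background_genome if reference == "background"
            else parents.donor_genome
        )
        genes = [
            (c, g) for c in parents.chroms for g in c.genes
            if g.role == "shared" and g.gene_id not in truth.unexpressed
        ]
        total = sum(len(s) for s in ref_genome.values())
        n_spurious = rng.binomial(total, config.variant_error_rate)
        order = rng.permutation(len(genes))
        for k in range(min(int(n_spurious), len(genes))):
            chrom, g = genes[int(order[k])]
            segs = [chrom.segments[si] for si in g.seg_indices]
            if reference == "background":
                start = segs[0].bg_start
                end = segs[-1].bg_start + len(segs[-1].bg_seq) - 1
            else:
                start = segs[0].donor_start
                end = segs[-1].donor_start + len(segs[-1].donor_seq) - 1
            for _try in range(10):
                pos = int(rng.integers(start, end + 1))
                if (chrom.name, pos) not in used_positions:
                    break
            else:
                continue
            base = ref_genome[chrom.name][pos - 1]
            het = rng.random() < 0.3
            variants.append(VariantRecord(
                chrom.name, pos, base, _other_base(rng, base),
                "heterozygous" if het else "homozygous",
                float(rng.poisson(12) + 1),
            ))
            used_positions.add((chrom.name, pos))

    return sorted(variants, key=lambda v: (v.chrom, v.pos))


# ---------------------------------------------------------------------------
# DEG tables


def simulate_deg_tables(parents: ParentalPair):
    """BR-like and MR-like DEG tables with the planted truth sets.

    Truth genes draw |logFC| in [1.5, 8] with FDR < 0.05; null genes draw
    FDR >= 0.05. Stream ``[seed, 4]``.
    """
    from .degsum import DEGRecord

    config = parents.config
    rng = np.random.default_rng([config.seed, 4])
    truth = parents.truth
    tables = []
    for stage in ("BR", "MR"):
        rows = []
        ups = truth.deg_up.get(stage, set())
        downs = truth.deg_down.get(stage, set())
        for gene in parents.background_genes:
            gid = gene.gene_id
            if gid in ups or gid in downs:
                lfc = float(rng.uniform(1.5, 8.0))
                if gid in downs:
                    lfc = -lfc
                fdr = float(rng.uniform(1e-6, 0.049))
            else:
                lfc = float(rng.normal(0.0, 0.5))
                fdr = float(rng.uniform(0.05, 1.0))
            rows.append(DEGRecord(
                gene_id=gid, chrom=gene.chrom, start=gene.start,
                end=gene.end, logFC=lfc, fdr=fdr, contrast=stage,
            ))
        tables.append(rows)
    return tables[0], tables[1]


# ---------------------------------------------------------------------------
# aligned alleles (for the chimera module)


def aligned_gene_triple(
    line: LineSim, gene_id: str
) -> tuple[str, str, str, int]:
    """Line / donor / background alleles of a gene as aligned rows.

    Returns ``(line_row, donor_row, background_row, anchor)`` where rows are
    gap-padded to equal length and ``anchor`` is the background coordinate
    of the first column — the exact input a three-way multiple alignment of
    the sequenced border gene would provide.
    """
    chrom, g = line.parents.gene(gene_id)
    line_parts, donor_parts, bg_parts = [], [], []
    anchor = None
    for si in g.seg_indices:
        seg = chrom.segments[si]
        if anchor is None:
            anchor = seg.bg_start
        b_row, d_row = [], []
        cursor = 0
        for p0, ref, alt in seg.ops:
            b_row.append(seg.bg_seq[cursor:p0])
            d_row.append(seg.bg_seq[cursor:p0])
            if len(ref) == len(alt) == 1:
                b_row.append(ref)
                d_row.append(alt)
            elif len(alt) > len(ref):  # insertion in donor
                b_row.append(ref + "-" * (len(alt) - len(ref)))
                d_row.append(alt)
            else:                      # deletion in donor
                b_row.append(ref)
                d_row.append(alt + "-" * (len(ref) - len(alt)))
            cursor = p0 + len(ref)
        b_row.append(seg.bg_seq[cursor:])
        d_row.append(seg.bg_seq[cursor:])
        b = "".join(b_row)
        d = "".join(d_row)
        bg_parts.append(b)
        donor_parts.append(d)
        line_parts.append(d if seg.in_block else b)
    return (
        "".join(line_parts), "".join(donor_parts), "".join(bg_parts),
        int(anchor),
    )
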