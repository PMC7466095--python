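"""Generator invariants: determinism, divergence calibration, conservation
and expression-dependent variant visibility."""

import numpy as np
import pytest

from introdissect.simdata import (
    GENE_LEN,
    SimConfig,
    SimConfigError,
    generate_parents,
    plant_introgression,
    simulate_deg_tables,
    simulate_variant_calls,
)


def no_specials(**kw):
    return SimConfig(
        n_species_specific_donor=0, n_species_specific_background=0,
        n_duplicated=0, **kw,
    )


class TestConfigValidation:
    def test_rates_outside_unit_interval_rejected_by_name(self):
        with pytest.raises(SimConfigError, match="snp_rate"):
            SimConfig(snp_rate=1.5).validate()
        with pytest.raises(SimConfigError, match="expression_dropout"):
            SimConfig(expression_dropout=-0.1).validate()

    def test_span_outside_gene_count_rejected(self):
        with pytest.raises(SimConfigError, match="introgression_gene_span"):
            SimConfig(introgression_gene_span=(5, 25)).validate()

    def test_chromosome_too_short_rejected(self):
        with pytest.raises(SimConfigError, match="chromosome_length"):
            SimConfig(chromosome_length=GENE_LEN * 5).validate()


class TestGenerateParents:
    def test_zero_divergence_yields_identical_genomes(self):
        cfg = no_specials(seed=3, snp_rate=0.0, indel_rate=0.0)
        parents = generate_parents(cfg)
        assert parents.background_genome == parents.donor_genome
        assert parents.truth.species_specific_donor == []
        assert parents.truth.species_specific_background == []
        assert parents.truth.duplicated == []

    def test_same_seed_is_byte_identical(self):
        a = generate_parents(SimConfig(seed=5))
        b = generate_parents(SimConfig(seed=5))
        assert a.background_genome == b.background_genome
        assert a.donor_genome == b.donor_genome
        assert [g.__dict__ for g in a.donor_genes] == [
            g.__dict__ for g in b.donor_genes
        ]
        la, lb = plant_introgression(a), plant_introgression(b)
        assert la.genome == lb.genome
        for ref in ("background", "donor"):
            assert simulate_variant_calls(la, ref) == (
                simulate_variant_calls(lb, ref)
            )
        assert simulate_deg_tables(a) == simulate_deg_tables(b)

    def test_substitution_count_within_three_binomial_sd(self):
        # indels off so the genomes stay alignable position-by-position
        cfg = no_specials(seed=7, snp_rate=0.01, indel_rate=0.0)
        parents = generate_parents(cfg)
        observed = total = 0
        for chrom, bg in parents.background_genome.items():
            dn = parents.donor_genome[chrom]
            assert len(bg) == len(dn)
            observed += sum(1 for x, y in zip(bg, dn) if x != y)
            total += len(bg)
        mean = total * 0.01
        sd = np.sqrt(total * 0.01 * 0.99)
        assert abs(observed - mean) <= 3 * sd

    def test_annotations_cover_both_namespaces(self):
        parents = generate_parents(SimConfig(seed=1))
        bg_ids = {g.gene_id for g in parents.background_genes}
        dn_ids = {g.gene_id for g in parents.donor_genes}
        for gid in parents.truth.species_specific_donor:
            assert gid in dn_ids and gid not in bg_ids
        for gid in parents.truth.species_specific_background:
            assert gid in bg_ids and gid not in dn_ids
        for dup, src in parents.truth.duplicated:
            assert dup in dn_ids and dup not in bg_ids and src in dn_ids

    def test_gene_models_have_the_fixed_feature_layout(self):
        parents = generate_parents(SimConfig(seed=1))
        for g in parents.background_genes:
            assert [f.kind for f in g.features] == [
                "five_prime_UTR", "CDS", "three_prime_UTR",
            ]
            for f, nxt in zip(g.features, g.features[1:]):
                assert nxt.start == f.end + 1


class TestPlantIntrogression:
    def test_zero_gene_span_returns_background(self):
        cfg = no_specials(seed=2, introgression_gene_span=(6, 5))
        line = plant_introgression(generate_parents(cfg))
        assert line.genome == line.parents.background_genome
        assert line.truth.donor_block_genes == []
        assert line.truth.lower_breakpoint is None

    def test_truth_ancestry_by_construction(self, default_line):
        truth = default_line.truth
        i0, i1 = default_line.config.introgression_gene_span
        for gid, anc in truth.gene_ancestry.items():
            chrom_no = int(gid[1:3])
            slot = int(gid.split("_")[1])
            in_block = chrom_no == 1 and i0 <= slot <= i1
            assert anc == ("donor" if in_block else "background")

    def test_line_matches_background_outside_the_block(self, default_line):
        line = default_line
        parents = line.parents
        truth = line.truth
        bg = parents.background_genome[truth.chrom]
        ln = line.genome[truth.chrom]
        p, q = truth.lower_breakpoint, truth.upper_breakpoint
        assert ln[:p] == bg[:p]
        tail = len(bg) - q
        assert ln[-tail:] == bg[q:]
        assert line.genome["chr2"] == parents.background_genome["chr2"]

    def test_length_conservation(self, default_line):
        line = default_line
        truth = line.truth
        bg = line.parents.background_genome[truth.chrom]
        ln = line.genome[truth.chrom]
        replaced = truth.upper_breakpoint - truth.lower_breakpoint
        inserted = len(ln) - (len(bg) - replaced)
        assert len(ln) == len(bg) - replaced + inserted
        assert inserted > 0

    def test_chimeric_gene_matches_donor_then_background(self, default_line):
        from introdissect.simdata import aligned_gene_triple

        line = default_line
        truth = line.truth
        lr, dr, br, anchor = aligned_gene_triple(line, truth.chimeric_gene)
        ref_pos = anchor - 1
        for col, (l_, d, b) in enumerate(zip(lr, dr, br)):
            if b != "-":
                ref_pos += 1
            if ref_pos <= truth.upper_breakpoint:
                assert l_ == d
            elif b != "-":  # strictly past the crossover
                assert l_ == b

    def test_span_overlapping_special_slots_rejected(self):
        cfg = SimConfig(seed=1, n_chromosomes=1,
                        introgression_gene_span=(14, 19))
        with pytest.raises(SimConfigError):
            generate_parents(cfg)


class TestVariantVisibility:
    def test_identical_genomes_emit_no_variants(self):
        cfg = no_specials(seed=3, snp_rate=0.0, indel_rate=0.0)
        line = plant_introgression(generate_parents(cfg))
        assert simulate_variant_calls(line, "background") == []
        assert simulate_variant_calls(line, "donor") == []

    def test_full_dropout_silences_everything(self):
        cfg = no_specials(seed=3, expression_dropout=1.0)
        line = plant_introgression(generate_parents(cfg))
        assert simulate_variant_calls(line, "background") == []
        assert simulate_variant_calls(line, "donor") == []

    def test_unexpressed_gene_contributes_zero_variants(self, noisy_line):
        parents = noisy_line.parents
        by_id = {g.gene_id: g for g in parents.background_genes}
        for ref in ("background", "donor"):
            genes = parents.background_genes if ref == "background" else (
                parents.donor_genes
            )
            by_id = {g.gene_id: g for g in genes}
            for v in simulate_variant_calls(noisy_line, ref):
                for gid in noisy_line.truth.unexpressed:
                    g = by_id.get(gid)
                    if g is not None and g.chrom == v.chrom:
                        assert not g.start <= v.pos <= g.end

    def test_block_variant_count_equals_planted_divergence(self,
                                                           default_line):
        line = default_line
        parents = line.parents
        truth = line.truth
        variants = simulate_variant_calls(line, "background")
        by_id = {g.gene_id: g for g in parents.background_genes}
        n_in_block_genes = sum(
            1 for v in variants
            if any(
                by_id[gid].chrom == v.chrom
                and by_id[gid].start <= v.pos <= by_id[gid].end
                for gid in truth.donor_block_genes
            )
        )
        # planted divergence: donor-derived ops inside block gene spans
        planted = 0
        chrom = parents.chroms[line.config.introgression_chromosome]
        for g in chrom.genes:
            if g.gene_id not in truth.donor_block_genes:
                continue
            for si in g.seg_indices:
                seg = chrom.segments[si]
                if seg.in_block:
                    planted += len(seg.ops)
        assert len(variants) == n_in_block_genes == planted

    def test_variant_class_mixture_is_near_80_20(self, default_line):
        variants = simulate_variant_calls(default_line, "background")
        n_snp = sum(1 for v in variants if v.var_class == "SNP")
        frac = n_snp / len(variants)
        assert 0.68 <= frac <= 0.92
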