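"""Protein alignment, reciprocal best hits and relationship typing."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from introdissect import fixtures
from introdissect.io_formats import HitRecord
from introdissect.orthology import (
    align_proteins,
    best_bidirectional_hits,
    classify_relationships,
)

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def hit(q, s, score, evalue=1e-60):
    return HitRecord(q, s, 90.0, 100, 10, 0, 1, 100, 1, 100, evalue, score)


def sw_oracle(a, b, gap_open=11.0, gap_extend=1.0):
    """Independent affine-gap Smith-Waterman (Gotoh) for tiny sequences."""
    n, m = len(a), len(b)
    NEG = -1e9
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(M[i - 1][j] - gap_open - gap_extend,
                          X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - gap_open - gap_extend,
                          Y[i][j - 1] - gap_extend)
            sub = BLOSUM62[a[i - 1], b[j - 1]]
            M[i][j] = max(0.0,
                          M[i - 1][j - 1] + sub,
                          X[i - 1][j - 1] + sub,
                          Y[i - 1][j - 1] + sub)
            best = max(best, M[i][j], X[i][j], Y[i][j])
    return best


class TestAlignProteins:
    def test_identical_sequences_score_sum_of_diagonal(self):
        seq = "MKVLAWT"
        score, identity, evalue = align_proteins(seq, seq)
        assert identity == 100.0
        assert score == sum(float(BLOSUM62[c, c]) for c in seq)
        assert evalue < 1e-3

    def test_score_is_symmetric(self):
        a, b = "MKVLAWTGHR", "MKVIAWSGHR"
        assert align_proteins(a, b)[0] == align_proteins(b, a)[0]

    def test_matches_exhaustive_dp_on_tiny_pairs(self):
        rng = np.random.default_rng(11)
        alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(30):
            a = "".join(rng.choice(alphabet, size=rng.integers(3, 9)))
            b = "".join(rng.choice(alphabet, size=rng.integers(3, 9)))
            score, _, _ = align_proteins(a, b)
            assert score == pytest.approx(sw_oracle(a, b))

    def test_invalid_residue_rejected(self):
        with pytest.raises(ValueError):
            align_proteins("MKV1", "MKV")
        with pytest.raises(ValueError):
            align_proteins("", "MKV")


class TestBBH:
    def test_mutual_best_pair(self):
        hits = [hit("a", "b", 100), hit("b", "a", 100)]
        assert best_bidirectional_hits(hits) == [("a", "b", 100, 1e-60)]

    def test_non_reciprocal_best_is_not_bbh(self):
        hits = [hit("a", "b", 100), hit("b", "a", 50), hit("b", "c", 90),
                hit("c", "b", 90)]
        pairs = best_bidirectional_hits(hits)
        assert [(p[0], p[1]) for p in pairs] == [("b", "c")]

    def test_evalue_threshold_applies_to_both_directions(self):
        hits = [hit("a", "b", 100), hit("b", "a", 100, evalue=1e-5)]
        assert best_bidirectional_hits(hits) == []

    def test_matches_brute_force_on_random_score_matrices(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            na, nb = rng.integers(2, 7), rng.integers(2, 7)
            scores = rng.integers(10, 1000, size=(na, nb))
            a_ids = [f"a{i}" for i in range(na)]
            b_ids = [f"b{j}" for j in range(nb)]
            hits = []
            for i in range(na):
                for j in range(nb):
                    hits.append(hit(a_ids[i], b_ids[j], float(scores[i, j])))
                    hits.append(hit(b_ids[j], a_ids[i], float(scores[i, j])))
            got = {(p[0], p[1]) for p in best_bidirectional_hits(hits)}
            expected = set()
            for i in range(na):
                for j in range(nb):
                    if (
                        scores[i, j] == scores[i].max()
                        and scores[i, j] == scores[:, j].max()
                        # unique maxima only: ties are broken by id and
                        # checked separately
                        and (scores[i] == scores[i].max()).sum() == 1
                        and (scores[:, j] == scores[:, j].max()).sum() == 1
                    ):
                        expected.add((a_ids[i], b_ids[j]))
            assert expected <= got  # every unambiguous pair is found
            for a, b in got - expected:  # extras must still be mutual best
                i, j = int(a[1:]), int(b[1:])
                assert scores[i, j] == scores[i].max() == scores[:, j].max()


@pytest.fixture(scope="module")
def typed():
    relations, donor_genes, background_genes, _ = fixtures.load_table3()
    hits = fixtures.load_table3_hits()
    donor_ids = {g.gene_id for g in donor_genes}
    background_ids = {g.gene_id for g in background_genes} | {
        "SolycUnlisted01"
    }
    return relations, classify_relationships(hits, donor_ids, background_ids)


class TestClassifyRelationships:

    def test_published_relation_counts(self, typed):
        _, got = typed
        by_kind = {}
        for r in got:
            by_kind.setdefault(r.relation, []).append(r)
        assert len(by_kind["BBH"]) == 22
        assert len(by_kind["homology"]) == 5
        assert len(by_kind["species_specific_background"]) == 3
        assert len(by_kind["species_specific_donor"]) == 7
        assert len(by_kind["duplicated_donor"]) == 4
        assert len(by_kind["duplicated_background"]) == 2

    def test_reproduces_printed_table_row_for_row(self, typed):
        relations, got = typed

        def key(r):
            b = r.background_gene_id.replace("SolycUnlisted01", "")
            return (r.donor_gene_id, b, r.relation)

        assert sorted(key(r) for r in got) == sorted(
            key(r) for r in relations
        )

    def test_one_to_many_groups(self, typed):
        _, got = typed
        lyc_dup = {
            r.background_gene_id for r in got
            if r.relation == "duplicated_background"
        }
        assert lyc_dup == {"Solyc07g049120", "Solyc07g049130"}
        assert all(
            r.donor_gene_id == "Sopen07g024560" for r in got
            if r.relation == "duplicated_background"
        )
        pen_groups = {}
        for r in got:
            if r.relation == "duplicated_donor":
                pen_groups.setdefault(r.background_gene_id, set()).add(
                    r.donor_gene_id
                )
        assert pen_groups["Solyc07g049240"] == {
            "Sopen07g025260", "Sopen07g025270",
        }
        assert pen_groups["Solyc07g048100"] == {
            "Sopen07g024520", "Sopen07g024530",
        }

    def test_every_gene_in_exactly_one_relation_group(self, typed):
        _, got = typed
        donor_seen, background_seen = [], []
        for r in got:
            if r.donor_gene_id and r.relation != "duplicated_background":
                donor_seen.append(r.donor_gene_id)
            if r.background_gene_id and r.relation != "duplicated_donor":
                background_seen.append(r.background_gene_id)
        # duplicated groups share the partner side by design; the member
        # side must still be unique
        assert len(donor_seen) == len(set(donor_seen))
        assert len(background_seen) == len(set(background_seen))

    def test_bbh_is_one_to_one(self, typed):
        _, got = typed
        bbh = [r for r in got if r.relation == "BBH"]
        for side in ("donor_gene_id", "background_gene_id"):
            ids = [getattr(r, side) for r in bbh]
            assert len(ids) == len(set(ids))
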