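import pytest

from fragani import (
    BackendSpec,
    FragmentationParams,
    Hit,
    MutationSpec,
    NoOrthologousFragmentsError,
    OrthologPair,
    best_hit_per_query,
    compute_ani,
    mutate_genome,
    orthoani,
    random_genome,
    reciprocal_orthologs,
)
from fragani.orthoani_core import DegenerateGenomeError


def hit(q, s, bits=1000.0, evalue=0.0, ident=99.0, length=1020):
    return Hit(
        query_id=q,
        subject_id=s,
        percent_identity=ident,
        alignment_length=length,
        mismatches=0,
        gap_opens=0,
        evalue=evalue,
        bit_score=bits,
    )


class TestBestHitPerQuery:
    def test_highest_bit_score_wins(self):
        best = best_hit_per_query([hit("q1", "s1", bits=1800), hit("q1", "s2", bits=1700)])
        assert best["q1"].subject_id == "s1"

    def test_empty_input(self):
        assert best_hit_per_query([]) == {}

    def test_full_tie_break_chain(self):
        # equal bits -> lower evalue; equal again -> higher identity;
        # equal again -> lexicographically smallest subject
        best = best_hit_per_query(
            [hit("q", "s9"), hit("q", "s2")]
        )
        assert best["q"].subject_id == "s2"
        best = best_hit_per_query(
            [hit("q", "s9", ident=99.5), hit("q", "s2", ident=99.0)]
        )
        assert best["q"].subject_id == "s9"
        best = best_hit_per_query(
            [hit("q", "s9", evalue=1e-60), hit("q", "s2", evalue=1e-50)]
        )
        assert best["q"].subject_id == "s9"

    def test_order_independence(self):
        hits = [hit("q", "s9"), hit("q", "s2"), hit("q", "s5", bits=900)]
        assert best_hit_per_query(hits) == best_hit_per_query(hits[::-1])


class TestReciprocalOrthologs:
    def test_mutual_best_pair_emitted_with_both_identities(self):
        fwd = {"q1": hit("q1", "s5", ident=98.2, length=1020)}
        rev = {"s5": hit("s5", "q1", ident=98.1, length=1018)}
        (pair,) = reciprocal_orthologs(fwd, rev)
        assert (pair.forward_identity, pair.reverse_identity) == (98.2, 98.1)

    def test_non_reciprocal_pair_dropped(self):
        fwd = {"q1": hit("q1", "s5")}
        rev = {"s5": hit("s5", "q2")}
        assert reciprocal_orthologs(fwd, rev) == []

    @pytest.mark.parametrize("length,kept", [(356, False), (357, True)])
    def test_coverage_boundary_at_357(self, length, kept):
        fwd = {"q1": hit("q1", "s5", length=1020)}
        rev = {"s5": hit("s5", "q1", length=length)}
        pairs = reciprocal_orthologs(fwd, rev)
        assert bool(pairs) is kept

    def test_coverage_applies_to_both_directions(self):
        fwd = {"q1": hit("q1", "s5", length=356)}
        rev = {"s5": hit("s5", "q1", length=1020)}
        assert reciprocal_orthologs(fwd, rev) == []

    def test_output_sorted_by_query_id(self):
        fwd = {"qB": hit("qB", "sB"), "qA": hit("qA", "sA")}
        rev = {"sB": hit("sB", "qB"), "sA": hit("sA", "qA")}
        pairs = reciprocal_orthologs(fwd, rev)
        assert [p.query_fragment for p in pairs] == ["qA", "qB"]


class TestComputeAni:
    def pair(self, f, r):
        return OrthologPair("q", "s", f, r, 1020, 1020)

    def test_both_directional_identities_enter_mean(self):
        pairs = [self.pair(100.0, 100.0), self.pair(98.0, 96.0)]
        assert compute_ani(pairs) == pytest.approx(98.5)

    def test_single_perfect_pair(self):
        assert compute_ani([self.pair(100.0, 100.0)]) == 100.0

    def test_empty_is_an_error_not_zero(self):
        with pytest.raises(NoOrthologousFragmentsError):
            compute_ani([])

    def test_per_hit_not_per_pair_averaging(self):
        # asymmetric pair counts would hide the distinction; a single
        # lopsided pair plus a balanced one pins the 2n-value convention
        pairs = [self.pair(100.0, 90.0), self.pair(80.0, 80.0)]
        assert compute_ani(pairs) == pytest.approx((100 + 90 + 80 + 80) / 4)


class TestOrthoaniPipeline:
    def test_self_comparison_is_exactly_100(self):
        g = random_genome(1, [5100], seed=3, genome_id="g")
        res = orthoani(g, g)
        assert res.ani == 100.0
        assert res.n_pairs == 5
        assert res.n_query_fragments == res.n_reference_fragments == 5

    def test_too_short_genome_raises_degenerate(self):
        g = random_genome(1, [900], seed=4)
        other = random_genome(1, [2040], seed=5)
        with pytest.raises(DegenerateGenomeError, match="synthetic-4"):
            orthoani(g, other)

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_unrelated_genomes_have_no_orthologs(self, seed):
        a = random_genome(1, [10200], seed=seed, genome_id="a")
        b = random_genome(1, [10200], seed=seed + 100, genome_id="b")
        with pytest.raises(NoOrthologousFragmentsError):
            orthoani(a, b)

    def test_symmetry_on_small_mutant_pair(self):
        g = random_genome(1, [8160], seed=21, genome_id="g")
        m = mutate_genome(g, MutationSpec(substitution_rate=0.03, seed=22))
        assert orthoani(g, m).ani == orthoani(m, g).ani

    def test_result_range_and_bookkeeping(self):
        g = random_genome(2, [4080, 3060], seed=31, genome_id="g")
        m = mutate_genome(g, MutationSpec(substitution_rate=0.05, seed=32))
        res = orthoani(g, m)
        assert 0.0 <= res.ani <= 100.0
        assert res.ani < 100.0  # some directional identity is below 100
        assert res.n_pairs <= min(res.n_query_fragments, res.n_reference_fragments)
        assert res.params["fragment_length"] == 1020
        assert res.params["min_coverage"] == 0.35

    def test_pipeline_matches_brute_force_oracle(self, ani_oracle):
        g = random_genome(1, [6120], seed=41, genome_id="g")
        m = mutate_genome(g, MutationSpec(substitution_rate=0.02, seed=42))
        assert orthoani(g, m).ani == ani_oracle(g, m)

    def test_workers_do_not_change_result(self):
        g = random_genome(1, [6120], seed=51, genome_id="g")
        m = mutate_genome(g, MutationSpec(substitution_rate=0.02, seed=52))
        assert orthoani(g, m, backend=BackendSpec(workers=1)) == orthoani(
            g, m, backend=BackendSpec(workers=4)
        )
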