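import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agosort.io import MatureStrand, MiRNALocus, pair_table
from agosort.simulate import SimulationParams, generate_loci, simulate
from agosort.pipeline import run_synthetic_pipeline, star_fraction_by_pool
from agosort import sorting
from oracles import fisher_greater_oracle


def _tpm(rows):
    return pd.DataFrame(rows).T.astype(float)  # rows: strand -> {lib: tpm}


class TestCurateStrands:
    LOCUS = {"m-5p": "m", "m-3p": "m"}

    def test_more_abundant_is_mir(self):
        tpm = _tpm({"m-5p": {"l1": 100, "l2": 100}, "m-3p": {"l1": 10, "l2": 10}})
        labels = sorting.curate_strands(tpm, self.LOCUS)
        assert labels == {"m-5p": "miR", "m-3p": "miR*"}

    def test_single_detected_strand_is_mir(self):
        tpm = _tpm({"m-3p": {"l1": 5.0}})
        assert sorting.curate_strands(tpm, {"m-3p": "m"}) == {"m-3p": "miR"}

    def test_exact_tie_5p_wins(self):
        tpm = _tpm({"m-5p": {"l1": 7.0}, "m-3p": {"l1": 7.0}})
        labels = sorting.curate_strands(tpm, self.LOCUS)
        assert labels["m-5p"] == "miR" and labels["m-3p"] == "miR*"

    @given(st.floats(0.1, 100), st.floats(0.1, 100),
           st.floats(0.5, 10), st.booleans())
    @settings(max_examples=50, deadline=None)
    def test_invariant_to_scaling_and_order(self, a, b, scale, flip):
        cols = {"l1": a, "l2": b}
        if flip:
            cols = dict(reversed(list(cols.items())))
        tpm = _tpm({"m-5p": cols, "m-3p": {k: v * 0.37 for k, v in cols.items()}})
        base = sorting.curate_strands(tpm, self.LOCUS)
        scaled = sorting.curate_strands(tpm * scale, self.LOCUS)
        assert base == scaled


class TestPartitionFractions:
    def _run(self, a1, a2):
        t1 = _tpm({"s": {"l1": a1}})
        t2 = _tpm({"s": {"l1": a2}})
        return sorting.partition_fractions(t1, t2, {"s": "miR"}).loc["s"]

    def test_ago1_biased(self):
        row = self._run(80, 20)
        assert row["ago1_fraction"] == pytest.approx(0.8) and row["bias"] == "ago1"

    def test_balanced_no_bias(self):
        row = self._run(50, 50)
        assert row["ago1_fraction"] == pytest.approx(0.5) and row["bias"] == "none"

    def test_both_zero_absent(self):
        row = self._run(0, 0)
        assert np.isnan(row["ago1_fraction"]) and row["bias"] == "none"

    def test_ago2_boundary_strict(self):
        assert self._run(30, 70)["bias"] == "none"   # exactly 0.30 is not < 0.30
        assert self._run(29, 71)["bias"] == "ago2"


class TestFisher:
    def test_oracle_example(self):
        p = sorting.star_enrichment_test(8, 12, 2, 48)
        assert p == pytest.approx(fisher_greater_oracle(8, 12, 2, 48), abs=1e-10)

    def test_no_stars_anywhere(self):
        assert sorting.star_enrichment_test(0, 10, 0, 20) == pytest.approx(1.0)

    def test_identical_proportions(self):
        p = sorting.star_enrichment_test(5, 45, 10, 90)
        assert p > 0.5
        assert p == pytest.approx(fisher_greater_oracle(5, 45, 10, 90), abs=1e-10)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            sorting.star_enrichment_test(-1, 5, 5, 5)

    @given(st.integers(0, 60), st.integers(0, 60), st.integers(0, 60),
           st.integers(0, 60))
    @settings(max_examples=200, deadline=None)
    def test_matches_enumeration_oracle(self, a, b, c, d):
        if (a + b == 0) or (c + d == 0) or (a + b + c + d == 0):
            return
        p = sorting.star_enrichment_test(a, b, c, d)
        assert p == pytest.approx(fisher_greater_oracle(a, b, c, d), abs=1e-10)
        assert 0.0 <= p <= 1.0


class TestBenjaminiHochberg:
    def test_monotone_and_bounded(self):
        p = np.array([0.001, 0.02, 0.8, 0.04, 0.5])
        q = sorting.benjamini_hochberg(p)
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_empty(self):
        assert len(sorting.benjamini_hochberg([])) == 0


class TestNtComposition:
    def test_position1_all_u(self):
        comp = sorting.nt_composition(["UGAGG", "UCAGG"])
        assert comp.loc[1, "U"] == 1.0

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACGU"), 22)) for _ in range(50)]
        comp = sorting.nt_composition(seqs)
        assert np.allclose(comp[list("ACGU")].sum(axis=1), 1.0)

    def test_uniform_random_near_quarter(self):
        rng = np.random.default_rng(1)
        n = 4000
        seqs = ["".join(rng.choice(list("ACGU"), 22)) for _ in range(n)]
        comp = sorting.nt_composition(seqs)
        sigma = (0.25 * 0.75 / n) ** 0.5
        assert (np.abs(comp[list("ACGU")] - 0.25) < 3.5 * sigma).all().all()

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            sorting.nt_composition([])


class TestPosition1BiasTest:
    def test_detects_planted_u_bias(self):
        biased = ["U" + "ACG" * 7] * 40 + ["A" + "ACG" * 7] * 10
        background = [b + "ACG" * 7 for b in "ACGU" * 25]
        freq, bg, p = sorting.position1_bias_test(biased, background, "U")
        assert freq > bg and p < 1e-4

    def test_no_bias_high_p(self):
        seqs = [b + "ACG" * 7 for b in "ACGU" * 10]
        freq, bg, p = sorting.position1_bias_test(seqs, seqs, "U")
        assert freq == bg and p == pytest.approx(1.0)


class TestPairingProfile:
    def test_fully_paired_duplex_all_ones(self):
        params = SimulationParams(n_loci=3, seed=2, structure_feature_prob={
            "mismatch_pos9": 0.0, "mismatch_3prime_end": 0.0})
        loci, strands, _ = generate_loci(params)
        v = sorting.duplex_pairing_vector(loci[0], strands[0])
        assert (v[:20] == 1.0).all() and (v[20:] == 0.0).all()

    def test_planted_mismatch_position9(self):
        params = SimulationParams(n_loci=3, seed=2, structure_feature_prob={
            "mismatch_pos9": 1.0, "mismatch_3prime_end": 0.0})
        loci, strands, _ = generate_loci(params)
        v = sorting.duplex_pairing_vector(loci[0], strands[0])
        assert v[8] == 0.0 and v[0] == 1.0

    def test_median_profile(self):
        params = SimulationParams(n_loci=1, seed=2, structure_feature_prob={
            "mismatch_pos9": 0.0, "mismatch_3prime_end": 0.0})
        loci, strands, _ = generate_loci(params)
        params_mm = SimulationParams(n_loci=1, seed=4, structure_feature_prob={
            "mismatch_pos9": 1.0, "mismatch_3prime_end": 0.0})
        loci_mm, strands_mm, _ = generate_loci(params_mm)
        pairs = [(loci[0], strands[0]), (loci[0], strands[0]),
                 (loci_mm[0], strands_mm[0])]
        prof = sorting.median_pairing_profile(pairs)
        assert prof.loc[9, "median_paired"] == 1.0  # median over {1,1,0}
        assert (prof.loc[1:20, "median_paired"] == 1.0).all()

    def test_structure_absent_raises(self):
        locus = MiRNALocus("x", "c", 0, 20, "+", "ACGU" * 5, None, arm5p=(0, 18))
        strand = MatureStrand("x-5p", "x", "5p", ("ACGU" * 5)[:18])
        with pytest.raises(ValueError, match="structure"):
            sorting.duplex_pairing_vector(locus, strand)


class TestNussinov:
    def test_returns_valid_balanced_structure(self):
        s = sorting.nussinov_fold("GGGAAAUCCC")
        assert len(s) == 10
        pt = pair_table(s)  # raises if unbalanced
        seq = "GGGAAAUCCC"
        for i, j in enumerate(pt):
            if j is not None and i < j:
                assert (seq[i], seq[j]) in sorting._CAN_PAIR
                assert j - i > 3  # min loop respected

    def test_hairpin_gets_mostly_paired(self):
        arm = "GCGCGCGCGC"
        seq = arm + "AAAA" + "GCGCGCGCGC"
        s = sorting.nussinov_fold(seq)
        assert s.count("(") >= 8

    def test_ensure_structures_fills_missing(self):
        locus = MiRNALocus("x", "c", 0, 24, "+", "GGGGGGAAAACCCCCCAAAAAAAA",
                           None, arm5p=(0, 16))
        sorting.ensure_structures([locus])
        assert locus.structure is not None and len(locus.structure) == 24

    def test_ensure_structures_disabled_raises(self):
        locus = MiRNALocus("x", "c", 0, 24, "+", "GGGGGGAAAACCCCCCAAAAAAAA",
                           None, arm5p=(0, 16))
        with pytest.raises(ValueError):
            sorting.ensure_structures([locus], allow_fold=False)


class TestRecoveryProperties:
    def test_star_overrepresented_in_ago2(self, paper_pipeline):
        f_total = star_fraction_by_pool(paper_pipeline, "total")
        f_ago2 = star_fraction_by_pool(paper_pipeline, "ago2")
        assert f_ago2 > f_total

    def test_first_nt_biases_recovered(self, paper_pipeline):
        from agosort.pipeline import ago_bias_sign_recovery
        checks = ago_bias_sign_recovery(paper_pipeline)
        assert checks["ago1_5prime_U"] and checks["ago2_5prime_C"]

    @pytest.mark.parametrize("bias_sweep", [(-0.5, -1.5, -3.0)])
    def test_star_fraction_monotone_in_is_star_logit(self, bias_sweep):
        from agosort.simulate import paper_like_config
        means = []
        for b in bias_sweep:
            params = paper_like_config(n_loci=40, library_depth=60_000, seed=9)
            params.ago1_logit_bias["is_star"] = b
            res = run_synthetic_pipeline(params)
            tab = res.sorting_table
            stars = tab[(tab["star"] == "miR*") & tab["ago1_fraction"].notna()]
            means.append(stars["ago1_fraction"].mean())
        assert means[0] > means[1] > means[2]
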