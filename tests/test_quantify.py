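import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agosort import quantify
from agosort.io import MatureStrand, MiRNALocus
from agosort.quantify import (
    AlignPolicy,
    align_to_hairpins,
    annotate_categories,
    brute_force_align,
    compute_tpm,
    filter_low_abundance,
    length_histogram,
    mirna_percent,
    size_select,
    trim_adapter,
)
from agosort.simulate import SimulationParams, generate_loci, simulate

ADAPTER = "AGAUCGGAAGAGC"


class TestTrimAdapter:
    def test_insert_plus_full_adapter(self):
        reads = {"UGAGGUAGUAGG" + ADAPTER: 4}
        assert trim_adapter(reads, ADAPTER) == {"UGAGGUAGUAGG": 4}

    def test_no_adapter_unchanged(self):
        reads = {"UGAGGUAGUAGGUUGUAUAGUU": 2}
        assert trim_adapter(reads, ADAPTER) == reads

    def test_adapter_only_becomes_empty(self):
        out = trim_adapter({ADAPTER: 3}, ADAPTER)
        assert out == {"": 3}
        assert size_select(out, 15, 30) == {}

    def test_partial_adapter_at_end(self):
        # 6-nt adapter prefix at the read end is enough
        reads = {"UGAGGUAGUAGGUUGUAUAGUU" + ADAPTER[:6]: 1}
        assert trim_adapter(reads, ADAPTER) == {"UGAGGUAGUAGGUUGUAUAGUU": 1}

    def test_five_nt_suffix_not_trimmed(self):
        reads = {"UGAGGUAGUAGGUUGUAUAGUU" + ADAPTER[:5]: 1}
        assert trim_adapter(reads, ADAPTER) == reads

    def test_leftmost_occurrence_wins(self):
        read = "CCCCCC" + ADAPTER + "GGG" + ADAPTER
        assert trim_adapter({read: 1}, ADAPTER) == {"CCCCCC": 1}


class TestSizeSelect:
    def test_boundaries_inclusive(self):
        reads = {"A" * 14: 5, "C" * 15: 5, "G" * 30: 2, "U" * 31: 2}
        assert size_select(reads, 15, 30) == {"C" * 15: 5, "G" * 30: 2}

    def test_empty_input(self):
        assert size_select({}, 15, 30) == {}

    def test_all_in_range_identity(self):
        reads = {"ACGU" * 5: 7}
        assert size_select(reads, 15, 30) == reads

    def test_invalid_range(self):
        with pytest.raises(ValueError):
            size_select({}, 20, 10)


@pytest.fixture(scope="module")
def toy():
    """One locus whose next template base after the 5p arm is known."""
    # 5p arm (22) + loop + 3p arm; loop starts with G
    arm5 = "UGAGGUAGUAGGUUGUAUAGUU"
    loop = "GCGAAAGCUU"
    arm3 = "AACUAUACAACCUACUACCUCA"
    hp = arm5 + loop + arm3
    locus = MiRNALocus("toy", "chr1", 0, len(hp), "+", hp,
                       arm5p=(0, 22), arm3p=(len(hp) - 22, len(hp)))
    strands = [MatureStrand("toy-5p", "toy", "5p", arm5),
               MatureStrand("toy-3p", "toy", "3p", arm3)]
    return locus, strands


class TestAlign:
    def test_exact_mature_read(self, toy):
        locus, strands = toy
        assignments, un = align_to_hairpins({strands[0].sequence: 3}, [locus], strands)
        (a,) = assignments
        assert (a.strand_id, a.offset5, a.tail, a.weight) == ("toy-5p", 0, "", 1.0)
        assert a.templated_len == 22 and not un

    def test_forced_nontemplate_tail(self, toy):
        locus, strands = toy
        # next template base after the 5p arm is G; appending A forces a tail
        read = strands[0].sequence + "A"
        (a,), _ = align_to_hairpins({read: 1}, [locus], strands)
        assert a.tail == "A" and a.templated_len == 22

    def test_template_extension_precedence(self, toy):
        locus, strands = toy
        read = strands[0].sequence + "G"  # matches the template
        (a,), _ = align_to_hairpins({read: 1}, [locus], strands)
        assert a.tail == "" and a.templated_len == 23

    def test_long_tail_unassigned(self, toy):
        locus, strands = toy
        read = strands[0].sequence + "AAAA"  # tail of 4 > max_tail 3
        assignments, un = align_to_hairpins({read: 2}, [locus], strands)
        assert not assignments and un == {read: 2}

    def test_offset_window(self, toy):
        locus, strands = toy
        read = locus.hairpin_seq[2:24]  # starts +2 from the 5p arm
        (a,), _ = align_to_hairpins({read: 1}, [locus], strands)
        assert a.offset5 == 2

    def test_multimapper_weights_sum_to_one(self):
        # two loci sharing an identical 5p arm
        arm = "UGAGGUAGUAGGUUGUAUAGUU"
        loci, strands = [], []
        for i in (1, 2):
            hp = arm + "GCGAAAGCUU" + "AACUAUACAACCUACUACCUCA"
            loci.append(MiRNALocus(f"L{i}", "c", 0, len(hp), "+", hp,
                                   arm5p=(0, 22), arm3p=(len(hp) - 22, len(hp))))
            strands += [MatureStrand(f"L{i}-5p", f"L{i}", "5p", arm),
                        MatureStrand(f"L{i}-3p", f"L{i}", "3p",
                                     "AACUAUACAACCUACUACCUCA")]
        assignments, _ = align_to_hairpins({arm: 10}, loci, strands)
        by_seq = {}
        for a in assignments:
            by_seq.setdefault(a.sequence, 0.0)
            by_seq[a.sequence] += a.weight
        assert all(abs(w - 1.0) < 1e-12 for w in by_seq.values())


class TestAlignOracle:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        params = SimulationParams(n_loci=3, seed=seed,
                                  mono_addition_prob={"total": 0.3, "ago1": 0.3, "ago2": 0.3},
                                  trim_prob=0.3, library_depth=2000)
        loci, strands, libraries, _ = simulate(params)
        pool = list(libraries[0].reads)
        picks = rng.choice(len(pool), size=min(50, len(pool)), replace=False)
        reads = {pool[i]: 1 for i in picks}
        # add adversarial reads: shifted, mutated, random
        arm = strands[0].sequence
        reads[arm[3:] + "AC"] = 1
        reads["".join(rng.choice(list("ACGU"), 22))] = 1
        fast, un_fast = align_to_hairpins(reads, loci, strands)
        slow, un_slow = brute_force_align(reads, loci, strands)
        key = lambda a: (a.sequence, a.strand_id, a.offset5, a.templated_len, a.tail,
                         round(a.weight, 12))
        assert sorted(map(key, fast)) == sorted(map(key, slow))
        assert un_fast == un_slow


class TestCategories:
    def test_cascade_priority(self):
        tracks = {"repeats": {"AAAA"}, "mRNA": {"AAAA", "CCCC"}}
        out = annotate_categories({"AAAA": 5, "CCCC": 2}, tracks)
        assert out["repeats"] == 5 and out["mRNA"] == 2

    def test_unmatched_is_unannotated(self):
        out = annotate_categories({"GGGG": 3}, {"repeats": {"AAAA"}})
        assert out["unannotated"] == 3

    def test_no_tracks(self):
        out = annotate_categories({"GGGG": 3, "AAAA": 1})
        assert out["unannotated"] == 4


def _matrix(raw_rows, cats):
    import pandas as pd
    raw = pd.DataFrame(raw_rows)
    cat = pd.DataFrame(cats).T.reindex(raw.columns).fillna(0).astype(int)
    return quantify.CountMatrix(raw=raw, category_totals=cat)


class TestTpm:
    def test_single_strand_all_reads(self):
        m = _matrix({"lib1": {"s1": 10.0}}, {"lib1": {"unannotated": 0}})
        compute_tpm(m)
        assert m.tpm.loc["s1", "lib1"] == 1_000_000

    def test_even_split(self):
        m = _matrix({"lib1": {"s1": 5.0, "s2": 5.0}}, {"lib1": {"unannotated": 0}})
        compute_tpm(m)
        assert (m.tpm["lib1"] == 500_000).all()

    def test_zero_raw_zero_tpm(self):
        m = _matrix({"lib1": {"s1": 10.0, "s2": 0.0}}, {"lib1": {"unannotated": 0}})
        compute_tpm(m)
        assert m.tpm.loc["s2", "lib1"] == 0.0

    def test_other_categories_in_denominator(self):
        m = _matrix({"lib1": {"s1": 10.0}}, {"lib1": {"unannotated": 90}})
        compute_tpm(m)
        assert m.tpm.loc["s1", "lib1"] == pytest.approx(100_000)

    def test_zero_mapped_total_errors(self):
        m = _matrix({"lib1": {"s1": 0.0}}, {"lib1": {"unannotated": 0}})
        with pytest.raises(ValueError, match="zero"):
            compute_tpm(m)

    def test_conservation_invariant(self, small_pipeline):
        m = small_pipeline.matrix
        strand_tpm = m.tpm.sum(axis=0)
        cat_tpm = m.category_totals.div(m.mapped_totals(), axis=0) * 1e6
        total = strand_tpm + cat_tpm.sum(axis=1)
        assert np.allclose(total, 1e6, rtol=1e-6)


class TestFilter:
    def _tpm_matrix(self, values):
        import pandas as pd
        raw = pd.DataFrame(values).astype(float)
        m = quantify.CountMatrix(raw=raw, category_totals=pd.DataFrame(
            0, index=raw.columns, columns=["unannotated"]))
        m.tpm = raw
        return m

    def test_below_threshold_everywhere_discarded(self):
        m = self._tpm_matrix({"l1": {"s1": 19.9}, "l2": {"s1": 15.0}})
        assert len(filter_low_abundance(m, 20.0).raw) == 0

    def test_exactly_20_retained(self):
        m = self._tpm_matrix({"l1": {"s1": 20.0}, "l2": {"s1": 0.0}})
        assert list(filter_low_abundance(m, 20.0).raw.index) == ["s1"]

    def test_threshold_zero_identity(self):
        m = self._tpm_matrix({"l1": {"s1": 0.5, "s2": 1000.0}})
        assert len(filter_low_abundance(m, 0.0).raw) == 2

    @given(st.lists(st.floats(0, 100), min_size=1, max_size=8),
           st.floats(0, 50), st.floats(0, 50))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_threshold(self, tpms, t1, t2):
        import pandas as pd
        lo, hi = sorted([t1, t2])
        m = self._tpm_matrix({"l1": {f"s{i}": v for i, v in enumerate(tpms)}})
        kept_hi = set(filter_low_abundance(m, hi).raw.index)
        kept_lo = set(filter_low_abundance(m, lo).raw.index)
        assert kept_hi <= kept_lo


class TestLengthHistogram:
    def test_single_length(self):
        assert length_histogram({"A" * 22: 5}) == {22: 1.0}

    def test_even_split(self):
        h = length_histogram({"A" * 21: 5, "C" * 22: 5})
        assert h == {21: 0.5, 22: 0.5}

    def test_empty(self):
        assert length_histogram({}) == {}

    def test_synthetic_mirna_modal_length_22(self):
        params = SimulationParams(n_loci=10, seed=6, library_depth=20_000)
        _, _, libraries, _ = simulate(params)
        lib = next(l for l in libraries if l.pool == "total")
        h = length_histogram(lib.reads)
        # oracle: direct count over generated reads (no background, no mods)
        assert max(h, key=h.get) == 22

    def test_fractions_sum_to_one(self, small_pipeline):
        for lib in small_pipeline.libraries:
            assert sum(length_histogram(lib.reads).values()) == pytest.approx(1.0)


def test_mirna_percent_columns_sum_to_100(small_pipeline):
    pct = mirna_percent(small_pipeline.matrix.raw)
    assert np.allclose(pct.sum(axis=0), 100.0)
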