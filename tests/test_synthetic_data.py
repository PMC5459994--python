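"""Unit and property tests for the hybrid-clone generator."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allelochoice import (
    ActivationModelParams,
    CountNoiseParams,
    category_probs,
    make_locus,
    make_snps,
    simulate_clone,
    simulate_counts,
    simulate_pool,
    simulate_reads,
    simulate_repertoire,
)
from allelochoice.allelic_assignment import assignment_window


class TestMakeLocus:
    def test_study_scale_locus(self):
        locus = make_locus(96, 60, seed=1)
        assert len(locus) == 96
        assert len(locus.potential_set) == 60
        assert len(set(locus.segment_ids)) == 96

    def test_degenerate_locus(self):
        locus = make_locus(1, 0, seed=1)
        assert len(locus) == 1
        assert locus.potential_set == frozenset()

    def test_windows_pairwise_disjoint_brute_force(self):
        locus = make_locus(5, 5, seed=7)
        assert locus.potential_set == frozenset(locus.segment_ids)
        windows = [assignment_window(s) for s in locus]
        for i in range(len(windows)):
            for j in range(i + 1, len(windows)):
                lo_i, hi_i = windows[i]
                lo_j, hi_j = windows[j]
                assert hi_i <= lo_j or hi_j <= lo_i, "windows overlap"

    def test_gap_exceeds_windowing_requirement(self):
        locus = make_locus(20, 10, seed=3)
        segs = sorted(locus, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            assert b.start - a.end > 10_500

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            make_locus(-1, 0, seed=0)
        with pytest.raises(ValueError):
            make_locus(5, 6, seed=0)

    def test_bit_reproducible(self):
        a = make_locus(30, 10, seed=42)
        b = make_locus(30, 10, seed=42)
        assert a == b


class TestSimulateClone:
    def test_zero_probability_all_silent(self, full_locus):
        clone = simulate_clone(full_locus, ActivationModelParams(0, 0, 60, 96), seed=1)
        assert all(v == (False, False) for v in clone.activation.values())

    def test_certainty_all_potential_biallelic(self, full_locus):
        clone = simulate_clone(full_locus, ActivationModelParams(1, 1, 60, 96), seed=1)
        for sid, (b6, cast) in clone.activation.items():
            if sid in full_locus.potential_set:
                assert b6 and cast
            else:
                assert not b6 and not cast

    def test_category_frequencies_match_analytic_probs(self, full_locus, study_params):
        """Simulated category frequencies converge to the analytic distribution
        within 3 Monte-Carlo standard errors."""
        n_clones = 3000
        probs = category_probs(study_params)["potential"]
        counts = {c: 0 for c in probs.index}
        for i in range(n_clones):
            clone = simulate_clone(full_locus, study_params, seed=(500_000 + i))
            for sid in full_locus.potential_set:
                counts[clone.category(sid)] += 1
        n = n_clones * len(full_locus.potential_set)
        for cat, p in probs.items():
            freq = counts[cat] / n
            se = np.sqrt(p * (1 - p) / n)
            assert abs(freq - p) < 3 * se + 1e-9

    def test_mean_active_fraction_near_analytic(self, full_locus, study_params):
        """At the study parameters ~35.8% of the 96 segments are active on >=1 allele."""
        fracs = []
        for i in range(2000):
            clone = simulate_clone(full_locus, study_params, seed=(900_000 + i))
            active = sum(b or c for b, c in clone.activation.values())
            fracs.append(active / 96)
        assert abs(np.mean(fracs) - 0.3578125) < 0.005


class TestSimulateCounts:
    def test_zero_leak_gives_exact_zeros(self, small_locus):
        clone = simulate_clone(small_locus, ActivationModelParams(0, 0, 6, 8), seed=1)
        noise = CountNoiseParams(mu_active=50, mu_leak=0.0, dispersion=0.1, n_replicates=4)
        t = simulate_counts(clone, noise, seed=2)
        assert (t[["b6", "cast"]] == 0).all().all()

    def test_biallelic_ratio_near_half(self, small_locus):
        clone = simulate_clone(small_locus, ActivationModelParams(1, 1, 6, 8), seed=1)
        noise = CountNoiseParams(mu_active=100, mu_leak=1, dispersion=0.1, n_replicates=1000)
        t = simulate_counts(clone, noise, seed=3)
        active = t[t["feature_id"].isin(small_locus.potential_set)]
        ratio = active["b6"].sum() / (active["b6"].sum() + active["cast"].sum())
        assert abs(ratio - 0.5) < 0.02

    def test_monoallelic_ratio_matches_leak_expectation(self, small_locus):
        """A mono-B6 segment at mu_active=50, mu_leak=1 has mean B6 ratio ~ 50/51."""
        clone = simulate_clone(small_locus, ActivationModelParams(1, 0, 6, 8), seed=1)
        noise = CountNoiseParams(mu_active=50, mu_leak=1, dispersion=0.05, n_replicates=2000)
        t = simulate_counts(clone, noise, seed=4)
        active = t[t["feature_id"].isin(small_locus.potential_set)]
        ratio = active["b6"].sum() / (active["b6"].sum() + active["cast"].sum())
        assert abs(ratio - 50 / 51) < 0.01

    def test_counts_are_nonnegative_integers(self, small_locus, study_params, default_noise):
        clone = simulate_clone(small_locus, ActivationModelParams(0.5, 0.5, 6, 8), seed=5)
        t = simulate_counts(clone, default_noise, seed=6)
        assert np.issubdtype(t["b6"].dtype, np.integer)
        assert np.issubdtype(t["cast"].dtype, np.integer)
        assert (t[["b6", "cast"]] >= 0).all().all()

    def test_unknown_bias_segment_rejected(self, small_locus, default_noise):
        clone = simulate_clone(small_locus, ActivationModelParams(0.5, 0.5, 6, 8), seed=5)
        with pytest.raises(ValueError, match="unknown segments"):
            simulate_counts(clone, default_noise, bias={"nope": 2.0}, seed=1)

    def test_bit_reproducible(self, small_locus, default_noise):
        clone = simulate_clone(small_locus, ActivationModelParams(0.5, 0.5, 6, 8), seed=5)
        a = simulate_counts(clone, default_noise, seed=9)
        b = simulate_counts(clone, default_noise, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestSimulatePool:
    def test_singleton_pool_equals_single_clone(self, small_locus, default_noise):
        params = ActivationModelParams(0.4, 0.4, 6, 8)
        pool = simulate_pool(small_locus, params, 1, default_noise, seed=17)
        ss = np.random.SeedSequence(17)
        c_seed, k_seed = ss.spawn(2)
        clone = simulate_clone(small_locus, params, c_seed, clone_id="pool_clone0")
        single = simulate_counts(clone, default_noise, seed=k_seed, sample_prefix="pool")
        pd.testing.assert_frame_equal(pool, single)

    def test_large_symmetric_pool_is_biallelic(self, full_locus, default_noise):
        """Pooling many clones with symmetric activation yields balanced segments."""
        from allelochoice.monoallelic_calling import call_with_replicates, split_by_sample

        params = ActivationModelParams(0.4, 0.4, 60, 96)
        pool = simulate_pool(full_locus, params, 500, default_noise, seed=23)
        calls = call_with_replicates(split_by_sample(pool), min_depth=20)
        callable_ = calls[calls["category"] != "insufficient"]
        assert len(callable_) >= 50
        assert (callable_["category"] == "biallelic").all()

    def test_genetic_bias_skews_pooled_ratio(self, full_locus, default_noise):
        params = ActivationModelParams(0.4, 0.4, 60, 96)
        target = sorted(full_locus.potential_set)[0]
        pool = simulate_pool(full_locus, params, 500, default_noise,
                             bias={target: 10.0}, seed=29)
        seg = pool[pool["feature_id"] == target]
        ratio = seg["b6"].sum() / (seg["b6"].sum() + seg["cast"].sum())
        assert ratio < 0.2

    def test_pool_requires_clones(self, full_locus, study_params, default_noise):
        with pytest.raises(ValueError):
            simulate_pool(full_locus, study_params, 0, default_noise, seed=1)


class TestSimulateReads:
    def test_reads_carry_parental_bases(self, small_locus, default_noise):
        from allelochoice.allelic_assignment import AlleleTag, build_snp_index, tag_allele

        params = ActivationModelParams(1, 0, 6, 8)
        clone = simulate_clone(small_locus, params, seed=31)
        snps = make_snps(small_locus, per_segment=5, seed=32)
        reads = simulate_reads(clone, small_locus, snps, default_noise, seed=33)
        index = build_snp_index(snps)
        tags = [tag_allele(r, index) for r in reads if r.snp_observations]
        assert tags, "no informative reads generated"
        assert all(t in (AlleleTag.B6, AlleleTag.CAST) for t in tags)

    def test_snpless_window_warns(self, small_locus, default_noise):
        clone = simulate_clone(small_locus, ActivationModelParams(1, 1, 6, 8), seed=35)
        with pytest.warns(UserWarning, match="no SNP"):
            simulate_reads(clone, small_locus, [], default_noise, seed=36)

    def test_round_trip_matches_count_marginals(self, small_locus, default_noise):
        """simulate_reads -> assign_reads reproduces the per-segment allele
        count distribution of simulate_counts within sampling error."""
        from allelochoice.allelic_assignment import assign_reads

        params = ActivationModelParams(1, 0, 6, 8)
        clone = simulate_clone(small_locus, params, seed=41)
        snps = make_snps(small_locus, per_segment=40, seed=42)
        noise = CountNoiseParams(mu_active=400, mu_leak=2, dispersion=0.05, n_replicates=1)
        reads = simulate_reads(clone, small_locus, snps, noise, seed=43, read_span=600)
        table, tallies = assign_reads(reads, small_locus, snps)
        assert tallies["ambiguous"] == 0
        totals = table.groupby("feature_id")[["b6", "cast"]].sum()
        for sid in small_locus.potential_set:
            b6, cast = totals.loc[sid, "b6"], totals.loc[sid, "cast"]
            # active B6 allele ~ NB(400); most reads cover >=1 window SNP
            assert b6 > 150
            assert cast < 50

    def test_reads_reproducible(self, small_locus, default_noise):
        clone = simulate_clone(small_locus, ActivationModelParams(0.5, 0.5, 6, 8), seed=51)
        snps = make_snps(small_locus, seed=52)
        a = simulate_reads(clone, small_locus, snps, default_noise, seed=53)
        b = simulate_reads(clone, small_locus, snps, default_noise, seed=53)
        assert a == b


class TestSimulateRepertoire:
    def _mono_b6_clone(self, locus):
        params = ActivationModelParams(1, 0, 6, 8)
        return simulate_clone(locus, params, seed=61)

    def test_single_active_segment_takes_whole_repertoire(self, small_locus, default_noise):
        clone = self._mono_b6_clone(small_locus)
        one = sorted(clone.potential_set)[0]
        activation = {sid: (sid == one, False) for sid in clone.activation}
        clone = type(clone)(clone_id="c", activation=activation, potential_set=clone.potential_set)
        ncrna = simulate_counts(clone, default_noise, seed=62)
        with pytest.warns(UserWarning, match="Cast"):
            rep = simulate_repertoire(clone, ncrna, coupling=1.0, time_fraction=0.0, seed=63)
        b6 = rep[rep["allele"] == "B6"]
        assert b6.loc[b6["v_id"] == one, "percent"].iloc[0] == pytest.approx(100.0)

    def test_time_zero_puts_all_events_on_early_allele(self, small_locus, default_noise):
        clone = simulate_clone(small_locus, ActivationModelParams(1, 1, 6, 8), seed=64)
        ncrna = simulate_counts(clone, default_noise, seed=65)
        rep = simulate_repertoire(clone, ncrna, coupling=0.5, early_allele="B6",
                                  time_fraction=0.0, n_events=5000, seed=66)
        assert rep.loc[rep["allele"] == "Cast", "count"].sum() == 0
        assert rep.loc[rep["allele"] == "B6", "count"].sum() == 5000

    def test_percent_sums_to_100_per_allele(self, small_locus, default_noise):
        clone = simulate_clone(small_locus, ActivationModelParams(1, 1, 6, 8), seed=67)
        ncrna = simulate_counts(clone, default_noise, seed=68)
        rep = simulate_repertoire(clone, ncrna, coupling=0.7, seed=69)
        sums = rep.groupby("allele")["percent"].sum()
        assert np.allclose(sums, 100.0, rtol=1e-6)

    @given(coupling=st.floats(-2, 2), tf=st.floats(-2, 2))
    def test_out_of_range_mixing_rejected(self, small_locus, default_noise, coupling, tf):
        if 0 <= coupling <= 1 and 0 <= tf <= 1:
            return
        clone = simulate_clone(small_locus, ActivationModelParams(1, 1, 6, 8), seed=70)
        ncrna = simulate_counts(clone, default_noise, seed=71)
        with pytest.raises(ValueError):
            simulate_repertoire(clone, ncrna, coupling=coupling, time_fraction=tf, seed=72)
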