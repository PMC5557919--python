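"""Gating, well means, strain summaries and induction classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alascan.errors import GatingError, SummarizationError, ThresholdError, UndefinedFoldError
from alascan.flow import (
    EventTable,
    InductionClass,
    LibraryThresholds,
    StrainInductionSummary,
    classify_induction,
    compute_library_thresholds,
    gate_events,
    secondary_impairment_flag,
    summarize_strain,
    well_mean,
)
from alascan.synth import MutantTruth, SimulationConfig, simulate_events


def _table(scatter, fluor, well="w1"):
    return EventTable(well, np.asarray(scatter, float), np.asarray(fluor, float))


def _well(mean, condition, rep=1, strain="s", n=3):
    return summarize_wells_input(mean, condition, rep, strain, n)


def summarize_wells_input(mean, condition, rep, strain, n):
    from alascan.flow import WellMeasurement

    return WellMeasurement(
        strain_id=strain, condition=condition, replicate=rep,
        gated_mean_fluorescence=float(mean), n_gated=n * 100,
    )


def _summary(strain, mean_u, sd_u, mean_i, sd_i):
    return StrainInductionSummary(
        strain_id=strain, mean_uninduced=mean_u, sd_uninduced=sd_u,
        mean_induced=mean_i, sd_induced=sd_i, fold_induction=mean_i / mean_u, n_replicates=3,
    )


class TestGating:
    def test_threshold_below_all_is_identity(self):
        t = _table([100, 200, 300], [1, 2, 3])
        g = gate_events(t, threshold=50)
        assert len(g) == 3
        np.testing.assert_array_equal(g.fluorescence, t.fluorescence)

    def test_threshold_above_all_raises_naming_well(self):
        t = _table([100, 200], [1, 2], well="plateA_w7")
        with pytest.raises(GatingError, match="plateA_w7"):
            gate_events(t, threshold=1e6)

    def test_planted_background_fraction_removed_exactly(self):
        """A well with 10% sub-gate particles loses exactly that 10%."""
        cfg = SimulationConfig(seed=11, background_fraction=0.10, event_count_per_well=1000)
        truth = MutantTruth(
            mutant_id="m1A", position=1, induction_class_true="wild_type_like",
            fold_true=8.3, abundance_multiplier_true=1.0, category_true="no_effect",
            uninduced_mean_true=2500.0, fluorescence_ratio_true=1.0,
        )
        tab = simulate_events(truth, "uninduced", cfg, replicate=1)
        gated = gate_events(tab, threshold=200.0)  # between background and cell scatter
        assert len(gated) == 900

    def test_percentile_gate_removes_lower_tail(self):
        t = _table(np.arange(1, 101), np.ones(100))
        g = gate_events(t, percentile=5.0)
        assert len(g) == 95  # scatter >= the 5th-percentile value (5.95)


class TestWellMean:
    def test_constant_events(self):
        m = well_mean(_table([1, 1, 1], [500, 500, 500]), "s", "induced", 1, min_events=1)
        assert m.gated_mean_fluorescence == 500

    def test_arithmetic_mean(self):
        m = well_mean(_table([1, 1, 1], [100, 200, 300]), "s", "uninduced", 1, min_events=1)
        assert m.gated_mean_fluorescence == 200
        assert m.n_gated == 3

    def test_below_minimum_is_flagged(self):
        m = well_mean(_table([1, 1], [10, 20]), "s", "induced", 1, min_events=100)
        assert m.flagged

    def test_lognormal_well_matches_closed_form_mean(self):
        """Simulated event means agree with the analytic log-normal mean."""
        sd = 0.4
        cfg = SimulationConfig(
            seed=5, background_fraction=0.0, well_log_jitter=0.0,
            event_log_sd=sd, event_count_per_well=50_000,
        )
        truth = MutantTruth(
            mutant_id="m2A", position=2, induction_class_true="wild_type_like",
            fold_true=8.3, abundance_multiplier_true=1.0, category_true="no_effect",
            uninduced_mean_true=2500.0, fluorescence_ratio_true=1.0,
        )
        tab = simulate_events(truth, "uninduced", cfg, replicate=1)
        m = well_mean(tab, "m2A", "uninduced", 1)
        analytic_mean = 2500.0  # generator parameterizes the arithmetic mean directly
        se = analytic_mean * np.sqrt(np.exp(sd**2) - 1) / np.sqrt(len(tab))
        assert abs(m.gated_mean_fluorescence - analytic_mean) < 3 * se


class TestSummarize:
    def test_published_wild_type_fold(self):
        """Identical triplicates at the printed means give the printed fold."""
        wells = [_well(2851, "uninduced", r) for r in (1, 2, 3)] + [
            _well(23663, "induced", r) for r in (1, 2, 3)
        ]
        s = summarize_strain(wells)
        assert s.mean_uninduced == 2851 and s.mean_induced == 23663
        assert s.sd_uninduced == 0 and s.sd_induced == 0
        assert round(s.fold_induction, 2) == 8.30

    def test_hand_arithmetic(self):
        wells = [_well(v, "uninduced", r) for r, v in enumerate([2, 4, 6], 1)] + [
            _well(v, "induced", r) for r, v in enumerate([8, 8, 8], 1)
        ]
        s = summarize_strain(wells)
        assert s.mean_uninduced == 4 and s.sd_uninduced == 2
        assert s.fold_induction == 2.0

    def test_missing_condition_raises(self):
        wells = [_well(2, "uninduced", r) for r in (1, 2, 3)]
        with pytest.raises(SummarizationError, match="induced"):
            summarize_strain(wells)

    def test_zero_uninduced_mean_raises(self):
        wells = [_well(0, "uninduced", r) for r in (1, 2)] + [
            _well(5, "induced", r) for r in (1, 2)
        ]
        with pytest.raises(UndefinedFoldError):
            summarize_strain(wells)

    def test_fold_is_exactly_ratio_of_means(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            u = rng.uniform(100, 5000, 3)
            i = rng.uniform(100, 50000, 3)
            wells = [_well(v, "uninduced", r) for r, v in enumerate(u, 1)] + [
                _well(v, "induced", r) for r, v in enumerate(i, 1)
            ]
            s = summarize_strain(wells)
            assert s.fold_induction == pytest.approx(np.mean(i) / np.mean(u), rel=1e-12)


class TestThresholds:
    def test_direct_formula(self):
        summaries = [_summary(f"s{k}", u, 0.0, 10 * u, 0.0) for k, u in enumerate([1, 2, 3, 4, 5])]
        th = compute_library_thresholds(summaries, min_strains=5)
        assert th.mean_uninduced_all == 3
        assert th.sd_uninduced_all == pytest.approx(1.5811388, abs=1e-6)
        assert th.upper_uninduced == pytest.approx(6.1622777, abs=1e-6)

    def test_identical_strains_zero_sd(self):
        summaries = [_summary(f"s{k}", 100, 0, 1000, 0) for k in range(12)]
        th = compute_library_thresholds(summaries)
        assert th.upper_uninduced == 100 and th.lower_induced == 1000

    def test_too_few_strains(self):
        with pytest.raises(ThresholdError):
            compute_library_thresholds([_summary("a", 1, 0, 2, 0)])


#: thresholds making the published worked examples classifiable
_TH = LibraryThresholds(
    mean_uninduced_all=2500, sd_uninduced_all=1000,
    mean_induced_all=20000, sd_induced_all=5000,
)  # upper_uninduced 4500, lower_induced 10000


class TestClassify:
    @pytest.mark.parametrize(
        "summary, expected",
        [
            (_summary("L6A", 2293, 107, 1495, 34), InductionClass.NON_INDUCIBLE),
            (_summary("P262A", 1906, 418, 6004, 1649), InductionClass.POORLY_INDUCIBLE),
            (_summary("N105A", 8344, 171, 35539, 219), InductionClass.SEMI_CONSTITUTIVE),
            (_summary("wt-like", 2500, 100, 21000, 900), InductionClass.WILD_TYPE_LIKE),
        ],
    )
    def test_published_like_examples(self, summary, expected):
        assert classify_induction(summary, _TH) is expected

    def test_semi_constitutive_precedence_with_secondary_flag(self):
        s = _summary("odd", 8000, 100, 9000, 100)  # elevated baseline AND impaired induction
        assert classify_induction(s, _TH) is InductionClass.SEMI_CONSTITUTIVE
        assert secondary_impairment_flag(s, _TH)

    @settings(max_examples=50, deadline=None)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, scale):
        """A common rescaling of all fluorescence values changes no label."""
        for s in [
            _summary("a", 2293, 107, 1495, 34),
            _summary("b", 1906, 418, 6004, 1649),
            _summary("c", 8344, 171, 35539, 219),
            _summary("d", 2500, 100, 21000, 900),
        ]:
            scaled = _summary(
                s.strain_id, s.mean_uninduced * scale, s.sd_uninduced * scale,
                s.mean_induced * scale, s.sd_induced * scale,
            )
            th_scaled = LibraryThresholds(
                _TH.mean_uninduced_all * scale, _TH.sd_uninduced_all * scale,
                _TH.mean_induced_all * scale, _TH.sd_induced_all * scale,
            )
            assert classify_induction(scaled, th_scaled) is classify_induction(s, _TH)

    @settings(max_examples=100, deadline=None)
    @given(
        mean_u=st.floats(min_value=1, max_value=1e5),
        sd_u=st.floats(min_value=0, max_value=1e4),
        fold=st.floats(min_value=1e-2, max_value=50),
    )
    def test_rules_are_total_and_exclusive(self, mean_u, sd_u, fold):
        s = _summary("x", mean_u, sd_u, mean_u * fold, 0.0)
        label = classify_induction(s, _TH)
        assert label in InductionClass
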