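"""Survival normalisation, slope fitting, and context-rate deconvolution."""

import numpy as np
import pytest

from uvchron import (
    ContextRateTable,
    DamageRateModel,
    RandomerDesign,
    ReadCountTable,
    SurvivalCurve,
    aggregate_kmer_survival,
    compute_survival,
    deconvolve_context_rates,
    fit_initial_slope,
    make_synthetic_context_rates,
    simulate_randomer_counts,
)
from uvchron.damage_rates import _fit_rates_log


def _uniform_counts(design, per_cell=100):
    return ReadCountTable(
        design=design,
        counts=np.full((design.n_randomers, design.n_doses), per_cell, dtype=np.int64),
    )


class TestComputeSurvival:
    def test_unchanged_composition_gives_unit_survival(self, tiny_design):
        surv = compute_survival(_uniform_counts(tiny_design))
        assert np.allclose(surv.survival, 1.0)
        assert surv.usable.all()

    def test_zero_count_at_positive_dose_gives_zero_survival(self, tiny_design):
        counts = _uniform_counts(tiny_design)
        counts.counts[3, 2] = 0
        surv = compute_survival(counts)
        assert surv.survival[3, 2] == 0.0
        assert surv.survival[3, 0] == 1.0

    def test_invariant_under_column_rescaling(self, tiny_design):
        rng = np.random.default_rng(0)
        counts = ReadCountTable(
            design=tiny_design,
            counts=rng.integers(1, 500, (tiny_design.n_randomers, tiny_design.n_doses)),
        )
        scaled = ReadCountTable(design=tiny_design, counts=counts.counts.copy())
        scaled.counts[:, 3] *= 7
        a = compute_survival(counts).survival
        b = compute_survival(scaled).survival
        assert np.allclose(a, b)

    def test_zero_total_column_raises_naming_dose(self, tiny_design):
        counts = _uniform_counts(tiny_design)
        counts.counts[:, 5] = 0
        with pytest.raises(ValueError, match="1.25"):
            compute_survival(counts)

    def test_zero_control_marks_curve_unusable(self, tiny_design):
        counts = _uniform_counts(tiny_design)
        counts.counts[7, 0] = 0
        surv = compute_survival(counts)
        assert not surv.usable[7]
        assert np.isnan(surv.survival[7, 1])
        seq = tiny_design.randomer_sequences()[7]
        with pytest.raises(ValueError, match="control"):
            surv.curve(seq)

    def test_survival_matches_generating_exponential(self, default_table):
        """Simulated counts reproduce exp(-mu_j D)/Z(D) within sampling error."""
        design = RandomerDesign(random_length=4, doses=(0.0, 1.0, 2.0))
        counts = simulate_randomer_counts(
            default_table, design, depth=2_000_000, rng=np.random.default_rng(5)
        )
        surv = compute_survival(counts)
        mu = design.full_strand_rates(default_table)
        for col, dose in enumerate(design.doses):
            p = np.exp(-mu * dose)
            expected = p / p.mean()  # per-dose multinomial renormalisation
            err = surv.survival[:, col] - expected
            # ~7800 control reads per cell -> relative sampling sd ~1.6%
            assert np.abs(err).mean() < 0.05
            assert abs(np.median(err)) < 0.01


class TestAggregateKmerSurvival:
    def test_degenerate_aggregation_equals_single_curve(self, tiny_design):
        rng = np.random.default_rng(1)
        counts = ReadCountTable(
            design=tiny_design,
            counts=rng.integers(50, 500, (tiny_design.n_randomers, tiny_design.n_doses)),
        )
        # a 4-mer core matched core-only aggregates exactly one sequence
        seq = "TTGA"
        agg = aggregate_kmer_survival(counts, seq, include_tags=False)
        single = compute_survival(counts).curve(seq)
        assert np.allclose(agg.survival, single.survival)

    def test_two_sequence_toy_matches_hand_enumeration(self):
        design = RandomerDesign(random_length=4, doses=(0.0, 1.0))
        counts = np.zeros((256, 2), dtype=np.int64)
        j_tta = design.sequence_index("TTAG")
        j_other = design.sequence_index("GGCC")
        counts[j_tta] = [100, 40]
        counts[j_other] = [100, 90]
        table = ReadCountTable(design=design, counts=counts)
        agg = aggregate_kmer_survival(table, "TTA", include_tags=False)
        # only TTAG contains TTA: S = (40/130)/(100/200)
        assert np.isclose(agg.survival[1], (40 / 130) / (100 / 200))

    def test_dipyrimidine_aggregate_decays_faster_than_purine(self, default_table):
        design = RandomerDesign(random_length=4, doses=(0.0, 0.5, 1.0, 2.0))
        counts = simulate_randomer_counts(
            default_table, design, depth=2_000_000, rng=np.random.default_rng(3)
        )
        s_tt = aggregate_kmer_survival(counts, "TTT").survival
        s_gg = aggregate_kmer_survival(counts, "GGC").survival
        assert (s_tt[1:] < s_gg[1:]).all()

    def test_invalid_kmer_rejected(self, tiny_design):
        counts = _uniform_counts(tiny_design)
        with pytest.raises(ValueError, match="non-ACGT"):
            aggregate_kmer_survival(counts, "TNT")
        with pytest.raises(ValueError, match="length"):
            aggregate_kmer_survival(counts, "TTTTT")


class TestFitInitialSlope:
    def test_constant_survival_gives_zero_rate(self):
        curve = SurvivalCurve("flat", np.linspace(0, 2, 9), np.ones(9))
        assert fit_initial_slope(curve) == 0.0

    def test_exponential_curve_recovered_within_5_percent(self):
        D = np.arange(0, 2.25, 0.25)
        curve = SurvivalCurve("exp", D, np.exp(-0.03 * D))
        mu = fit_initial_slope(curve)
        assert abs(mu - 0.03) / 0.03 < 0.05

    def test_low_dose_restriction_applied(self):
        D = np.array([0, 0.5, 1.0, 2.0, 10.0, 20.0])
        curve = SurvivalCurve("exp", D, np.exp(-0.05 * D))
        mu = fit_initial_slope(curve, max_dose=2.0)
        # the far-out points would otherwise drag the linear slope down badly
        assert abs(mu - 0.05) / 0.05 < 0.1

    def test_too_few_points_raises(self):
        curve = SurvivalCurve("short", np.array([0.0, 1.0]), np.array([1.0, 0.9]))
        with pytest.raises(ValueError, match="3 dose points"):
            fit_initial_slope(curve)

    def test_negative_estimate_clamped_with_warning(self):
        D = np.linspace(0, 2, 9)
        curve = SurvivalCurve("up", D, 1 + 0.05 * D)
        with pytest.warns(UserWarning, match="clamped"):
            assert fit_initial_slope(curve) == 0.0


class TestDeconvolution:
    def test_noiseless_recovery_of_identifiable_part(self, default_table):
        """Exact additive rates return the generating table's identifiable part."""
        design = RandomerDesign()
        mu = design.full_strand_rates(default_table)
        res = deconvolve_context_rates(mu, design)
        proj_err = res.project_identifiable(res.context_rates) - res.project_identifiable(
            default_table
        )
        assert np.linalg.norm(proj_err) < 1e-6
        assert res.residual_norm < 1e-6

    def test_all_zero_rates_give_zero_table(self):
        design = RandomerDesign(random_length=4)
        res = deconvolve_context_rates(np.zeros(256), design)
        assert np.allclose(res.context_rates.rates, 0.0)

    def test_pushback_reproduces_input_rates(self, jittered_table):
        """Pipeline consistency: additive data has ~zero pushback residual."""
        design = RandomerDesign()
        mu = design.full_strand_rates(jittered_table)
        res = deconvolve_context_rates(mu, design)
        pushback = design.full_strand_rates(res.context_rates) + res.intercept
        assert np.linalg.norm(pushback - mu) < 1e-6

    def test_g_masking_recovered_through_strand_predictions(self):
        """5-fold-per-flank guanine masking survives deconvolution.

        Individual context rates are gauged (see DeconvolutionResult), so
        the masking is asserted on interior strand rates: TT flanked by A
        versus by G at both sides differs 25-fold under the generator.
        """
        from uvchron import SyntheticRateModel

        base = {d: 0.0 for d in SyntheticRateModel().base_rates}
        base["TT"] = 0.03
        table = make_synthetic_context_rates(
            SyntheticRateModel(base_rates=base, a_enhancement=1.0)
        )
        design = RandomerDesign()
        res = deconvolve_context_rates(design.full_strand_rates(table), design)
        est = res.context_rates

        def interior_rate(t, unit):
            # doubling the repeat cancels both strand-end contexts and the
            # telescoping gauge boundary terms exactly
            return t.sequence_rate(unit * 60) - t.sequence_rate(unit * 30)

        ratio_true = interior_rate(table, "AATT") / interior_rate(table, "GGTT")
        ratio_est = interior_rate(est, "AATT") / interior_rate(est, "GGTT")
        assert np.isclose(ratio_true, 25.0, rtol=1e-9)
        assert np.isclose(ratio_est, 25.0, rtol=0.01)

    def test_short_random_core_rejected(self):
        design = RandomerDesign(random_length=3)
        with pytest.raises(ValueError, match="rank-deficient"):
            deconvolve_context_rates(np.zeros(64), design)

    def test_homogeneous_table_kmer_marginals(self):
        table = ContextRateTable.homogeneous(0.01)
        assert np.isclose(table.kmer_rates(2)["TT"], 0.01)
        assert np.isclose(table.kmer_rates(3)["GTC"], 0.02)
        assert np.isclose(table.kmer_rates(4)["ACGT"], 0.03)


@pytest.fixture(scope="module")
def fitted(default_table):
    design = RandomerDesign()
    counts = simulate_randomer_counts(
        default_table, design, depth=2_000_000, rng=np.random.default_rng(8)
    )
    return DamageRateModel(counts).fit(), default_table


class TestDamageRateModel:
    def test_recovery_at_moderate_depth(self, fitted):
        res, table = fitted
        d = res.deconvolution
        pt = d.project_identifiable(table)
        pe = d.project_identifiable(res.context_rates)
        assert np.linalg.norm(pe - pt) / np.linalg.norm(pt) < 0.25

    def test_trimer_rates_track_generator(self, fitted):
        res, table = fitted
        est = res.kmer_rates(3).as_series()
        true = table.kmer_rates(3).as_series()
        assert np.corrcoef(est, true)[0, 1] > 0.9

    def test_summary_reports_fit(self, fitted):
        res, _ = fitted
        text = res.summary()
        assert "rate estimator:    log" in text
        assert "TTT" in text
        assert "residual norm" in text

    def test_linear_method_matches_curvewise_fit(self, default_table):
        design = RandomerDesign(random_length=4, doses=tuple(0.25 * k for k in range(9)))
        counts = simulate_randomer_counts(
            default_table, design, depth=500_000, rng=np.random.default_rng(4)
        )
        res = DamageRateModel(counts).fit(method="linear")
        surv = compute_survival(counts)
        j = design.sequence_index("TTTT")
        mu_j = fit_initial_slope(surv.curve("TTTT"), max_dose=2.0)
        assert np.isclose(max(res.full_rates[j], 0.0), mu_j, atol=1e-9)

    def test_log_estimator_unbiased_on_exact_curves(self):
        """-log S regression returns mu exactly on noiseless exponentials."""
        doses = np.array([0.0, 0.5, 1.0, 2.0, 4.0])
        mu_true = np.array([0.0, 0.01, 0.1, 0.4])
        S = np.exp(-mu_true[:, None] * doses)
        counts = np.full_like(S, 10**12)
        mu_hat = _fit_rates_log(S, doses, counts)
        assert np.allclose(mu_hat, mu_true, atol=1e-9)
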