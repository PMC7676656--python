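"""Treated fraction, expected ORR, and classification agreement metrics."""

import math

import numpy as np
import pytest

import tmbsim as tm
from tmbsim.errors import ZeroSelectionError
from tmbsim.panel_noise import ClassifierSpec, PanelModel
from tmbsim.response import ResponseFunction


class TestTreatedFraction:
    def test_select_everyone(self, luad_dist):
        wes = PanelModel.noiseless()
        assert tm.treated_fraction(luad_dist, wes, ClassifierSpec(0.0)) == pytest.approx(1.0, abs=1e-9)

    def test_noiseless_reduces_to_tail_mass(self, uniform_dist):
        wes = PanelModel.noiseless()
        z = tm.treated_fraction(uniform_dist, wes, ClassifierSpec(16.0))
        assert z == pytest.approx(0.2, abs=1e-6)

    def test_decreasing_in_threshold(self, luad_dist):
        panel = PanelModel(panel_size=1.0, discretize=False)
        taus = np.linspace(0.5, 25, 30)
        zs = [tm.treated_fraction(luad_dist, panel, ClassifierSpec(t)) for t in taus]
        assert np.all(np.diff(zs) < 0)

    def test_small_panel_inflates_market_size(self, luad_dist):
        """Smaller panels select more patients at a fixed threshold."""
        spec = ClassifierSpec(10.0)
        z_small = tm.treated_fraction(luad_dist, PanelModel(panel_size=1.0), spec)
        z_wes = tm.treated_fraction(luad_dist, PanelModel(panel_size=35.6), spec)
        assert z_small > z_wes

    def test_quadrature_matches_monte_carlo(self, luad_dist):
        panel = PanelModel(panel_size=1.33)
        spec = ClassifierSpec(10.0)
        z = tm.treated_fraction(luad_dist, panel, spec)
        n = 100_000
        rng = np.random.default_rng(31)
        T = tm.sample_tmb(luad_dist, n, rng)
        calls = tm.simulate_cohort_readouts(panel, T, rng) > spec.threshold_tau
        se = np.sqrt(z * (1 - z) / n)
        assert abs(calls.mean() - z) < 3 * se


class TestExpectedOrr:
    def test_constant_response_factors_out(self, luad_dist, uniform_dist):
        """Psi == c implies ORR == c; the Bayes-ratio normalization identity."""
        psi = ResponseFunction.two_level(5.0, 0.37, 0.37)
        for dist in (luad_dist, uniform_dist):
            for panel in (PanelModel(panel_size=1.0), PanelModel.noiseless()):
                orr = tm.expected_orr(dist, psi, panel, ClassifierSpec(8.0))
                assert orr == pytest.approx(0.37, abs=1e-9)

    def test_unit_response_gives_unit_orr(self, luad_dist):
        psi = ResponseFunction.two_level(1.0, 1.0, 1.0)
        orr = tm.expected_orr(luad_dist, psi, PanelModel(panel_size=2.0), ClassifierSpec(6.0))
        assert orr == 1.0

    def test_noiseless_matched_step_is_certain_response(self, luad_dist):
        tau = tm.quantile_threshold(luad_dist, 0.2)
        orr = tm.expected_orr(
            luad_dist, ResponseFunction.step(tau), PanelModel.noiseless(), ClassifierSpec(tau)
        )
        assert orr == 1.0

    def test_unstratified_perfect_predictor_gives_prevalence(self, luad_dist):
        """Without TMB selection, a perfect top-20% predictor responds 20%."""
        tau = tm.quantile_threshold(luad_dist, 0.2)
        orr = tm.expected_orr(
            luad_dist, ResponseFunction.step(tau), PanelModel.noiseless(), ClassifierSpec(0.0)
        )
        assert orr == pytest.approx(0.2, abs=0.001)

    def test_orr_within_response_range(self, luad_dist):
        psi = ResponseFunction.two_level(8.0, 0.8, 0.2)
        orr = tm.expected_orr(luad_dist, psi, PanelModel(panel_size=1.0), ClassifierSpec(8.0))
        assert 0.2 <= orr <= 0.8

    def test_empty_selection_is_error(self, uniform_dist):
        wes = PanelModel.noiseless()
        with pytest.raises(ZeroSelectionError):
            tm.expected_orr(uniform_dist, ResponseFunction.step(5.0), wes, ClassifierSpec(25.0))


class TestClassificationMetrics:
    def test_zero_noise_panel_agrees_perfectly(self, luad_dist):
        wes = PanelModel.noiseless()
        m = tm.classification_metrics(luad_dist, wes, ClassifierSpec(8.0), n_mc=5000, seed=1)
        assert (m.ppa, m.npa, m.opa, m.ppv, m.npv) == (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_pure_noise_ppv_equals_prevalence(self, luad_dist):
        """A call independent of T has PPV equal to the true-high prevalence."""
        panel = PanelModel(panel_size=0.01, c0=50.0, lambda_driver=0.0)
        tau_truth = 8.0
        m = tm.classification_metrics(
            luad_dist, panel, ClassifierSpec(tau_truth), n_mc=200_000, seed=2
        )
        prevalence = float(luad_dist.sf(tau_truth))
        assert m.ppv == pytest.approx(prevalence, abs=0.01)

    def test_two_point_distribution_against_exhaustive_table(self):
        """Brute-force oracle: discrete truth at {2, 10} with equal mass and a
        hand-computed noise table."""
        # near-discrete density: two narrow spikes at 2 and 10
        grid = np.linspace(0, 14, 14001)
        density = np.zeros_like(grid)
        for center in (2.0, 10.0):
            density += np.exp(-0.5 * ((grid - center) / 0.01) ** 2)
        dist = tm.HistologyDistribution.from_grid("TWO", grid, density)
        panel = PanelModel(panel_size=1.0, c0=1.0, lambda_driver=0.0)
        tau = 6.0
        spec = ClassifierSpec(tau)

        # oracle: exhaustive 2x2 from the analytic exceedance at each atom
        p_hi = tm.selection_probability(panel, spec, 10.0)
        p_lo = tm.selection_probability(panel, spec, 2.0)
        tp, fn = 0.5 * p_hi, 0.5 * (1 - p_hi)
        fp, tn = 0.5 * p_lo, 0.5 * (1 - p_lo)
        m = tm.classification_metrics(dist, panel, spec, n_mc=400_000, seed=3)
        assert m.ppa == pytest.approx(tp / (tp + fn), abs=0.01)
        assert m.npa == pytest.approx(tn / (tn + fp), abs=0.01)
        assert m.opa == pytest.approx(tp + tn, abs=0.01)
        assert m.ppv == pytest.approx(tp / (tp + fp), abs=0.01)
        assert m.npv == pytest.approx(tn / (tn + fn), abs=0.01)

    def test_empty_stratum_reported_as_nan(self, uniform_dist):
        panel = PanelModel(panel_size=1.0)
        m = tm.classification_metrics(
            uniform_dist, panel, ClassifierSpec(10.0), ClassifierSpec(30.0),
            n_mc=2000, seed=4,
        )
        assert math.isnan(m.ppa)  # nobody is truly high above the support


@pytest.fixture(scope="module")
def grid(luad_dist, brca_dist):
    psi = ResponseFunction.gamma(1, 0.08)
    return tm.outcome_grid(
        [luad_dist, brca_dist], psi,
        panel_sizes=[0.5, 1.0, 2.0, 35.6],
        thresholds=[10.0, {"top_fraction": 0.2}],
        n_mc=20_000, seed=7,
    )


class TestOutcomeGrid:

    def test_shape_and_determinism(self, grid, luad_dist, brca_dist):
        assert len(grid) == 2 * 4 * 2
        again = tm.outcome_grid(
            [luad_dist, brca_dist], ResponseFunction.gamma(1, 0.08),
            panel_sizes=[0.5, 1.0, 2.0, 35.6],
            thresholds=[10.0, {"top_fraction": 0.2}],
            n_mc=20_000, seed=7,
        )
        assert grid.equals(again)

    def test_top_fraction_resolved_per_histology(self, grid, luad_dist, brca_dist):
        taus = grid[grid["threshold_tau"] != 10.0]
        luad_tau = taus[taus["histology"] == "LUAD"]["threshold_tau"].iloc[0]
        brca_tau = taus[taus["histology"] == "BRCA"]["threshold_tau"].iloc[0]
        assert luad_tau == pytest.approx(tm.quantile_threshold(luad_dist, 0.2))
        assert brca_tau == pytest.approx(tm.quantile_threshold(brca_dist, 0.2))
        assert luad_tau > brca_tau

    def test_opa_nondecreasing_in_panel_size(self, grid):
        """Larger panels are less noisy, so overall agreement improves."""
        sub = grid[(grid["histology"] == "LUAD") & (grid["threshold_tau"] == 10.0)]
        opa = sub.sort_values("panel_size")["opa"].to_numpy()
        assert np.all(np.diff(opa) >= -0.01)  # Monte-Carlo wiggle allowance

    def test_performance_plateaus_near_one_mbp(self, luad_dist):
        """At the per-histology top-20% cutoff, OPA improves by < 0.03 from
        1 to 2 Mbp on the heavy-tailed preset (exact quadrature)."""
        tau = ClassifierSpec(tm.quantile_threshold(luad_dist, 0.2))
        opa = {
            L: tm.classification_metrics(
                luad_dist, PanelModel(panel_size=L), tau, method="quadrature"
            ).opa
            for L in (1.0, 2.0)
        }
        assert abs(opa[1.0] - opa[2.0]) < 0.03

    def test_quadrature_metrics_match_monte_carlo(self, luad_dist):
        panel = PanelModel(panel_size=1.0)
        spec = ClassifierSpec(10.0)
        mc = tm.classification_metrics(luad_dist, panel, spec, n_mc=200_000, seed=1)
        qd = tm.classification_metrics(luad_dist, panel, spec, method="quadrature")
        for field in ("ppa", "npa", "opa", "ppv", "npv"):
            assert getattr(mc, field) == pytest.approx(getattr(qd, field), abs=0.01)

    def test_low_tmb_histology_has_lower_ppv_higher_opa(self, grid):
        sub = grid[grid["threshold_tau"] == 10.0]
        sub = sub[sub["panel_size"] == 1.0]
        luad = sub[sub["histology"] == "LUAD"].iloc[0]
        brca = sub[sub["histology"] == "BRCA"].iloc[0]
        assert brca["ppv"] < luad["ppv"]
        assert brca["opa"] > luad["opa"]

    def test_cell_errors_recorded_not_raised(self, uniform_dist):
        table = tm.outcome_grid(
            [uniform_dist], ResponseFunction.step(5.0),
            panel_sizes=[35.6], thresholds=[25.0], n_mc=2000, seed=1,
        )
        assert len(table) == 1
        # threshold beyond the support: fraction ~0 on a noisy panel is fine,
        # but if ORR is undefined the cell must carry the error string
        row = table.iloc[0]
        assert row["error"] == "" or "ZeroSelection" in row["error"]
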