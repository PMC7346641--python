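"""Power-law fitting, model comparison, group summaries, diameter trend."""

import math

import numpy as np
import pytest

from hgtnet.errors import (
    DegenerateDataError,
    FitError,
    InsufficientDataError,
)
from hgtnet.scalefree import (
    alt_log_pmf,
    compare_fits,
    diameter_lnlnN_trend,
    fit_alternative,
    fit_power_law,
    powerlaw_log_pmf,
    sample_discrete_powerlaw,
    summarize_group_fits,
    vuong_ratio,
)
from hgtnet.synthetic_cohort import preferential_attachment_graph
from .conftest import make_network


def pa_degrees(n, seed, alpha_target=3.0):
    rng = np.random.default_rng(seed)
    g = preferential_attachment_graph(n, m=2, alpha_target=alpha_target, rng=rng)
    return [d for _, d in g.degree()]


class TestPowerLawFit:
    def test_continuous_closed_form_oracle(self):
        # α̂ = 1 + n / Σ ln(x/xmin) on (2,4,8) with xmin=2: 1 + 3/ln(8) ≈ 2.4427
        fit = fit_power_law([2, 4, 8], xmin_policy=2, method="continuous",
                            allow_small=True)
        assert fit.alpha == pytest.approx(1 + 3 / math.log(8), abs=1e-12)
        assert fit.alpha == pytest.approx(2.4427, abs=1e-3)

    def test_discrete_mle_recovers_alpha(self):
        rng = np.random.default_rng(42)
        x = sample_discrete_powerlaw(2.5, 1, 10_000, rng)
        fit = fit_power_law(x)
        assert 2.40 <= fit.alpha <= 2.60
        assert fit.n_tail >= 2

    def test_consistency_improves_with_n(self):
        # |α̂ − α| shrinks in median as n grows 10^3 -> 10^5
        errs = {}
        for n in (1_000, 10_000, 100_000):
            errs[n] = np.median([
                abs(fit_power_law(
                    sample_discrete_powerlaw(2.5, 1, n, np.random.default_rng(s)),
                    xmin_policy=1,
                ).alpha - 2.5)
                for s in range(10)
            ])
        assert errs[100_000] < errs[1_000]

    def test_degenerate_distribution_rejected(self):
        with pytest.raises(DegenerateDataError):
            fit_power_law([3] * 200)

    def test_small_network_guard_with_override(self):
        degrees = [1, 1, 2, 3, 5, 8]
        with pytest.raises(InsufficientDataError):
            fit_power_law(degrees)
        fit = fit_power_law(degrees, allow_small=True)
        assert fit.alpha > 1


class TestAlternatives:
    def test_exponential_rate_recovery(self):
        rng = np.random.default_rng(0)
        draws = np.maximum(1, np.ceil(rng.exponential(1 / 0.3, 10_000)).astype(int))
        fit = fit_alternative(draws, "exponential", xmin=1)
        assert 0.27 <= fit.params["lam"] <= 0.33

    def test_lognormal_mu_constraint_binds(self):
        # data concentrated below 1 in log-space: unconstrained μ̂ < 0
        rng = np.random.default_rng(1)
        draws = np.maximum(1, np.round(rng.lognormal(-0.5, 0.8, 2000)).astype(int))
        fit = fit_alternative(draws, "lognormal_positive", xmin=1)
        assert fit.params["mu"] == 0.0
        assert fit.constraint_bound

    def test_lognormal_positive_mu_unconstrained(self):
        rng = np.random.default_rng(2)
        draws = np.round(rng.lognormal(2.0, 0.5, 5000)).astype(int)
        draws = draws[draws >= 1]
        fit = fit_alternative(draws, "lognormal_positive", xmin=1)
        assert fit.params["mu"] == pytest.approx(2.0, abs=0.2)
        assert not fit.constraint_bound

    def test_weibull_on_constant_data_fails(self):
        with pytest.raises(FitError):
            fit_alternative([4] * 100, "weibull", xmin=4)


class TestLLRComparison:
    def test_self_comparison_is_zero_and_undecided(self):
        rng = np.random.default_rng(5)
        x = sample_discrete_powerlaw(2.5, 1, 500, rng).astype(float)
        ll = powerlaw_log_pmf(x, 2.5, 1)
        R, v, p = vuong_ratio(ll, ll)
        assert (R, v, p) == (0.0, 0.0, 1.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(6)
        x = sample_discrete_powerlaw(2.3, 1, 1000, rng)
        pl = powerlaw_log_pmf(x.astype(float), 2.3, 1)
        alt = alt_log_pmf(fit_alternative(x, "exponential", 1), x)
        R1, v1, _ = vuong_ratio(pl, alt)
        R2, v2, _ = vuong_ratio(alt, pl)
        assert R1 == pytest.approx(-R2) and v1 == pytest.approx(-v2)

    def test_heavy_tail_beats_exponential_on_pa_graphs(self):
        wins = 0
        for seed in range(20):
            degrees = pa_degrees(2000, seed)
            if compare_fits(degrees, "exponential").ratio > 0:
                wins += 1
        assert wins >= 19

    def test_exponential_data_prefers_exponential(self):
        rng = np.random.default_rng(9)
        draws = np.maximum(1, np.ceil(rng.exponential(1 / 0.3, 10_000)).astype(int))
        res = compare_fits(draws, "exponential", allow_small=True)
        assert res.ratio < 0 and res.winner == "alternative"

    def test_short_tail_is_undecided(self):
        rng = np.random.default_rng(10)
        x = sample_discrete_powerlaw(2.5, 1, 2000, rng)
        fit = fit_power_law(x)
        res = compare_fits(x, "exponential", power_fit=fit, min_tail=10**6)
        assert res.winner == "undecided"


class TestGroupSummaries:
    def test_identical_groups_give_p_one(self):
        fits = {"A": [2.1, 2.5, 2.9], "B": [2.1, 2.5, 2.9]}
        summaries = summarize_group_fits(fits)
        for s in summaries:
            assert s.pairwise_p[("B" if s.group == "A" else "A")] == pytest.approx(1.0)

    def test_separated_groups_with_jitter(self):
        # ε jitter breaks zero variance; oracle = direct pooled-t computation
        eps = 1e-6
        a = [2.1 - eps, 2.1 + eps, 2.1 - eps, 2.1 + eps]
        b = [2.9 - eps, 2.9 + eps, 2.9 - eps, 2.9 + eps]
        summaries = {s.group: s for s in summarize_group_fits({"A": a, "B": b})}
        assert summaries["B"].mean_alpha > summaries["A"].mean_alpha
        assert summaries["A"].pairwise_p["B"] < 1e-3
        lo, hi = summaries["A"].ci95
        assert lo < 2.1 < hi

    def test_cohort_alpha_ordering_recovered(self):
        rng = np.random.default_rng(0)
        def alphas(target, n_nets):
            out = []
            for _ in range(n_nets):
                g = preferential_attachment_graph(2000, m=2, alpha_target=target,
                                                  rng=rng)
                out.append(fit_power_law([d for _, d in g.degree()]).alpha)
            return out
        mother = alphas(2.8, 8)
        child = alphas(2.4, 8)
        summaries = {s.group: s
                     for s in summarize_group_fits({"Mother": mother, "Child": child})}
        assert summaries["Mother"].mean_alpha > summaries["Child"].mean_alpha

    def test_small_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            summarize_group_fits({"A": [2.0], "B": [2.1, 2.2]})


class TestDiameterTrend:
    def test_monotone_points_give_positive_slope(self):
        nets = [
            make_network("a", [(i, i + 1) for i in range(3)]),  # N=4, d=3
            make_network("b", [(0, i) for i in range(1, 9)]),   # star N=9, d=2
        ]
        # hand-built third network: two stars joined => d=3, N=11
        nets.append(make_network("c", [(0, i) for i in range(1, 6)]
                                 + [(5, i) for i in range(6, 11)]))
        trend = diameter_lnlnN_trend(nets)
        assert len(trend.points) == 3
        assert -1 <= trend.r <= 1

    def test_all_equal_sizes_degenerate(self):
        nets = [make_network(s, [("a", "b"), ("b", "c")]) for s in "xyz"]
        with pytest.raises(DegenerateDataError):
            diameter_lnlnN_trend(nets)

    def test_too_few_networks(self):
        with pytest.raises(InsufficientDataError):
            diameter_lnlnN_trend([make_network("a", [("a", "b"), ("b", "c")])])

    def test_pa_networks_show_lnlnN_scaling(self):
        from hgtnet.data_model import HGTNetwork

        rng = np.random.default_rng(4)
        nets = []
        for i in range(15):
            n = int(rng.integers(200, 4000))
            g = preferential_attachment_graph(n, m=2, alpha_target=3.0, rng=rng)
            nets.append(HGTNetwork(f"n{i}", g))
        trend = diameter_lnlnN_trend(nets)
        assert trend.slope > 0
        assert trend.r > 0.5
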