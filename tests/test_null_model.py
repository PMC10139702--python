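"""Expected-count null model and Poisson testing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from convscan import (
    FocalBranchSet,
    contrast_branch_sets,
    count_observed,
    expected_counts,
    genome_wide_test,
    marginal_posteriors,
    poisson_tail,
)
from convscan.null_model import ConvergenceResult, make_result, site_expectations
from convscan.simulate import FOCAL_TIPS, SimulationConfig, default_tree, simulate_gene


def _point_mass(state: int) -> np.ndarray:
    q = np.zeros((1, 20))
    q[0, state] = 1.0
    return q


def _p_change(t: float) -> float:
    """Equal-rates per-target substitution probability."""
    return (1 / 20) * (1 - np.exp(-20 * t / 19))


class TestSiteExpectations:
    def test_zero_length_branch_contributes_nothing(self, eq_model, rng):
        q1 = rng.dirichlet(np.ones(20))[None, :]
        q2 = rng.dirichlet(np.ones(20))[None, :]
        Ps = [eq_model.transition_probs(0.0), eq_model.transition_probs(0.4)]
        conv, par = site_expectations([q1, q2], Ps, "pairwise")
        assert conv[0] == 0.0 and par[0] == 0.0

    @pytest.mark.parametrize("t1, t2", [(0.1, 0.2), (0.05, 0.5), (1.0, 1.0)])
    def test_point_mass_closed_form_convergent(self, eq_model, t1, t2):
        """Distinct fixed ancestors under equal rates: 18 * p(t1) * p(t2)."""
        qs = [_point_mass(0), _point_mass(5)]
        Ps = [eq_model.transition_probs(t1), eq_model.transition_probs(t2)]
        conv, par = site_expectations(qs, Ps, "pairwise")
        assert conv[0] == pytest.approx(18 * _p_change(t1) * _p_change(t2), abs=1e-8)
        assert par[0] == 0.0

    def test_point_mass_closed_form_parallel(self, eq_model):
        """Identical fixed ancestors: 19 shared targets, all parallel."""
        t1, t2 = 0.15, 0.3
        qs = [_point_mass(4), _point_mass(4)]
        Ps = [eq_model.transition_probs(t1), eq_model.transition_probs(t2)]
        conv, par = site_expectations(qs, Ps, "pairwise")
        assert par[0] == pytest.approx(19 * _p_change(t1) * _p_change(t2), abs=1e-8)
        assert conv[0] == 0.0

    def test_combined_is_convergent_plus_parallel(self, jtt, rng):
        qs = [rng.dirichlet(np.ones(20), size=7) for _ in range(3)]
        Ps = [jtt.transition_probs(t) for t in (0.1, 0.3, 0.2)]
        for mode in ("all-branches", "pairwise"):
            conv, par = site_expectations(qs, Ps, mode)
            assert (conv >= 0).all() and (par >= 0).all()

    def test_expectation_monotone_in_branch_length(self, jtt, rng):
        q1 = rng.dirichlet(np.ones(20))[None, :]
        q2 = rng.dirichlet(np.ones(20))[None, :]
        P2 = jtt.transition_probs(0.2)
        totals = []
        for t in (0.01, 0.05, 0.1, 0.3, 0.6):
            conv, par = site_expectations(
                [q1, q2], [jtt.transition_probs(t), P2], "pairwise"
            )
            totals.append(conv[0] + par[0])
        assert all(a < b for a, b in zip(totals, totals[1:]))


class TestExpectedCountsOnTree:
    def test_zero_length_focal_branches_give_zero(self, jtt):
        tree = default_tree()
        for tip in FOCAL_TIPS:
            tree.lengths[tree.tip_index(tip)] = 0.0
        cfg = SimulationConfig(seed=8, n_genes=1, sites_per_gene=60, tree=tree)
        aln, _ = simulate_gene(cfg, 0)
        post = marginal_posteriors(tree, aln, jtt)
        bset = FocalBranchSet("myr", FOCAL_TIPS, "all-branches")
        exp = expected_counts(tree, aln, post, jtt, bset)
        assert exp.combined == 0.0

    def test_mean_observed_matches_mean_expected_under_null(self, jtt):
        """Aggregated over many null genes, observed and expected combined
        counts agree within 10% (pairwise mode, 3 focal branches)."""
        tree = default_tree()
        bset = FocalBranchSet("myr", FOCAL_TIPS, "pairwise")
        cfg = SimulationConfig(seed=55, n_genes=500, sites_per_gene=300)
        obs = exp = 0.0
        for g in range(cfg.n_genes):
            aln, _ = simulate_gene(cfg, g)
            post = marginal_posteriors(tree, aln, jtt)
            counts, usable = count_observed(tree, aln, post, bset)
            e = expected_counts(tree, aln, post, jtt, bset, usable=usable)
            obs += counts.combined
            exp += e.combined
        assert exp > 0
        assert abs(obs - exp) / exp < 0.10


class TestPoissonTail:
    def test_zero_observed_upper_tail_is_one(self):
        for lam in (0.0, 0.3, 5.0):
            p_upper, _ = poisson_tail(0, lam)
            assert p_upper == 1.0

    def test_small_count_closed_form(self):
        p_upper, _ = poisson_tail(3, 0.5)
        assert p_upper == pytest.approx(
            1 - np.exp(-0.5) * (1 + 0.5 + 0.125), abs=1e-12
        )

    @pytest.mark.parametrize("obs, lam", [(0, 0.1), (2, 1.3), (7, 3.0), (15, 20.0)])
    def test_tails_overlap_by_exactly_the_pmf(self, obs, lam):
        p_upper, p_lower = poisson_tail(obs, lam)
        assert p_upper + p_lower == pytest.approx(
            1 + stats.poisson.pmf(obs, lam), abs=1e-12
        )

    def test_degenerate_zero_mean(self):
        assert poisson_tail(0, 0.0) == (1.0, 1.0)
        assert poisson_tail(2, 0.0) == (0.0, 1.0)

    @pytest.mark.parametrize("obs, lam", [(-1, 1.0), (2, -0.5), (1.5, 1.0)])
    def test_invalid_inputs_rejected(self, obs, lam):
        with pytest.raises(ValueError):
            poisson_tail(obs, lam)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        obs=st.integers(min_value=0, max_value=200),
        lam=st.floats(min_value=1e-6, max_value=100.0),
    )
    def test_tail_identity_holds_everywhere(self, obs, lam):
        p_upper, p_lower = poisson_tail(obs, lam)
        assert 0.0 <= p_upper <= 1.0 and 0.0 <= p_lower <= 1.0
        assert p_upper + p_lower == pytest.approx(
            1 + stats.poisson.pmf(obs, lam), rel=1e-9, abs=1e-12
        )


def _result(gene, obs, exp, branch_set="myr", mode="all-branches"):
    p_upper, p_lower = poisson_tail(obs, exp)
    return ConvergenceResult(
        gene=gene, branch_set=branch_set, mode=mode,
        obs_convergent=obs, obs_parallel=0,
        exp_convergent=exp, exp_parallel=0.0,
        p_upper=p_upper, p_lower=p_lower, n_usable_sites=300,
    )


class TestGenomeWide:
    def test_single_gene_aggregate_is_that_gene(self):
        r = _result("g1", 2, 0.4)
        agg, q = genome_wide_test([r])
        assert (agg.obs_combined, agg.exp_combined) == (2, 0.4)
        assert agg.p_upper == pytest.approx(r.p_upper)
        assert q[0] == pytest.approx(r.p_upper)

    def test_expectations_add_across_genes(self):
        agg, _ = genome_wide_test([_result("g1", 1, 0.2), _result("g2", 2, 0.3)])
        assert agg.obs_combined == 3
        assert agg.exp_combined == pytest.approx(0.5)
        assert agg.p_upper == pytest.approx(poisson_tail(3, 0.5)[0])

    def test_mixed_branch_sets_rejected(self):
        with pytest.raises(ValueError, match="branch sets"):
            genome_wide_test(
                [_result("g1", 1, 0.2), _result("g2", 1, 0.2, branch_set="other")]
            )

    def test_bh_adjustment_is_monotone_and_bounded(self):
        results = [_result(f"g{i}", i % 3, 0.2 + 0.1 * i) for i in range(10)]
        _, q = genome_wide_test(results)
        assert ((q >= 0) & (q <= 1)).all()
        p = np.array([r.p_upper for r in results])
        assert (q >= p - 1e-12).all()


class TestContrast:
    def test_identical_inputs_have_equal_ratios_and_no_flags(self):
        focal = _result("GENOME_WIDE", 3, 3.0)
        contrast = contrast_branch_sets(focal, focal)
        assert contrast.focal_ratio == pytest.approx(contrast.control_ratio)
        assert not contrast.focal_excess
        assert not contrast.control_deficit

    def test_silent_control_with_large_expectation_is_a_deficit(self):
        control = _result("GENOME_WIDE", 0, 3.5)
        focal = _result("GENOME_WIDE", 9, 1.0)
        contrast = contrast_branch_sets(focal, control)
        assert control.p_lower == pytest.approx(np.exp(-3.5))
        assert contrast.control_deficit
        assert contrast.focal_excess
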