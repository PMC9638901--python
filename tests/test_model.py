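"""Mixture likelihood, posterior fitting and the grid-integration oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import poisson

from tilac.core import Combination, MutationType, SampleDesign
from tilac.model import (
    GeneTheta,
    GlobalRates,
    PriorConfig,
    SamplerConfig,
    dataset_log_likelihood,
    fit_posterior,
    grid_posterior_oracle,
    read_log_likelihood,
    tilac_ratio,
)

from conftest import mixture_counts

TC = MutationType.TC
GA = MutationType.GA


class TestReadLogLikelihood:
    def test_pure_background_zero_count(self):
        r = GlobalRates(lambda_u=0.05, tl=2.45)
        assert read_log_likelihood(0, theta=0.0, rates=r) == pytest.approx(-0.05)

    def test_degenerate_mixture_is_labelled_poisson(self):
        r = GlobalRates(lambda_u=0.05, tl=2.45)
        assert read_log_likelihood(3, theta=1.0, rates=r) == pytest.approx(
            poisson.logpmf(3, 2.5)
        )

    def test_matches_direct_pmf_summation(self):
        # lambda values = generative per-base rates x 50 expected sites
        r = GlobalRates(lambda_u=0.05, tl=2.45)
        expected = np.log(0.5 * poisson.pmf(2, 2.5) + 0.5 * poisson.pmf(2, 0.05))
        assert read_log_likelihood(2, theta=0.5, rates=r) == pytest.approx(expected)

    def test_unlabelled_indicator_forces_background(self):
        r = GlobalRates(lambda_u=0.2, tl=0.8)
        assert read_log_likelihood(1, theta=0.9, rates=r, labelled_indicator=0) == (
            pytest.approx(poisson.logpmf(1, 0.2))
        )

    def test_domain_errors(self):
        r = GlobalRates(lambda_u=0.05, tl=1.0)
        with pytest.raises(ValueError):
            read_log_likelihood(1, theta=1.5, rates=r)
        with pytest.raises(ValueError):
            read_log_likelihood(-1, theta=0.5, rates=r)


def _one_gene_table(groups):
    """groups: list of (sample, channel, y, k)."""
    return pd.DataFrame(
        [("g0", s, m, y, k, 50.0) for s, m, y, k in groups],
        columns=["gene_id", "sample_id", "mutation_type", "n_mut", "n_reads", "mean_bases"],
    )


class TestDatasetLogLikelihood:
    def test_empty_table_is_zero(self, derived_rates, design3):
        empty = _one_gene_table([]).iloc[:0]
        assert dataset_log_likelihood(empty, design3, {}, derived_rates) == 0.0

    def test_group_weighting_identity(self, derived_rates, design3):
        thetas = {"g0": GeneTheta(0.6, 0.3)}
        one = _one_gene_table([("fwd1", "TC", 2, 1)])
        k = _one_gene_table([("fwd1", "TC", 2, 7)])
        a = dataset_log_likelihood(one, design3, thetas, derived_rates)
        b = dataset_log_likelihood(k, design3, thetas, derived_rates)
        assert b == pytest.approx(7 * a)

    def test_forward_reverse_routing_swaps_thetas(self, derived_rates):
        fwd = [SampleDesign("s1", Combination.FORWARD), SampleDesign("c", Combination.UNLABELLED)]
        rev = [SampleDesign("s1", Combination.REVERSE), SampleDesign("c", Combination.UNLABELLED)]
        table = _one_gene_table([("s1", "TC", 3, 10), ("s1", "GA", 1, 10)])
        t = {"g0": GeneTheta(0.6, 0.3)}
        t_swapped = {"g0": GeneTheta(0.3, 0.6)}
        ll_fwd = dataset_log_likelihood(table, fwd, t, derived_rates)
        ll_rev = dataset_log_likelihood(table, rev, t, derived_rates)
        assert ll_fwd != pytest.approx(ll_rev)
        assert ll_fwd == pytest.approx(
            dataset_log_likelihood(table, rev, t_swapped, derived_rates)
        )

    def test_unknown_sample_is_hard_error(self, derived_rates, design3):
        table = _one_gene_table([("mystery", "TC", 0, 5)])
        with pytest.raises(ValueError, match="mystery"):
            dataset_log_likelihood(table, design3, {"g0": GeneTheta(0.5, 0.5)}, derived_rates)

    def test_maximized_near_simulation_truth(self, derived_rates, design3):
        """The likelihood profile over theta peaks near the generating values."""
        rng = np.random.default_rng(42)
        table = mixture_counts(rng, 4000, 0.6, 0.3, derived_rates, design3)
        grid = np.linspace(0.05, 0.95, 19)
        best, best_ll = None, -np.inf
        for te in grid:
            for tc in grid:
                ll = dataset_log_likelihood(
                    table, design3, {"g0": GeneTheta(te, tc)}, derived_rates
                )
                if ll > best_ll:
                    best, best_ll = (te, tc), ll
        assert best[0] == pytest.approx(0.6, abs=0.05)
        assert best[1] == pytest.approx(0.3, abs=0.05)


class TestTilacRatio:
    def test_arithmetic(self):
        assert tilac_ratio(GeneTheta(0.5, 0.5)) == (1.0, 0.0)
        ratio, log2r = tilac_ratio(GeneTheta(0.6, 0.3))
        assert ratio == pytest.approx(2.0)
        assert log2r == pytest.approx(1.0)

    def test_interior_constraint(self):
        with pytest.raises(ValueError):
            GeneTheta(0.5, 0.0)


class TestGridOracle:
    def test_zero_reads_returns_symmetric_prior(self, derived_rates, design3):
        empty = _one_gene_table([("fwd1", "TC", 0, 0)]).iloc[:0]
        empty = pd.concat([empty, _one_gene_table([])]).iloc[:0]
        table = _one_gene_table([("ctl1", "TC", 0, 1)])  # unlabelled only: no theta info
        res = grid_posterior_oracle(table, design3, derived_rates)
        assert res.log2_ratio_mean == pytest.approx(0.0, abs=1e-6)
        assert res.log2_ratio_sd > 0.5

    def test_grid_refinement_converges(self, derived_rates, design3):
        rng = np.random.default_rng(1)
        table = mixture_counts(rng, 500, 0.6, 0.3, derived_rates, design3)
        a = grid_posterior_oracle(table, design3, derived_rates, tol=1e-3)
        b = grid_posterior_oracle(table, design3, derived_rates, n_start=2 * a.grid_size - 1,
                                  tol=np.inf)
        assert abs(a.log2_ratio_mean - b.log2_ratio_mean) < 1e-3

    def test_rejects_multi_gene_tables(self, derived_rates, design3):
        table = _one_gene_table([("fwd1", "TC", 0, 1)])
        other = table.assign(gene_id="g1")
        with pytest.raises(ValueError, match="single gene"):
            grid_posterior_oracle(pd.concat([table, other]), design3, derived_rates)


class TestFitPosterior:
    def test_recovers_known_ratio_and_matches_oracle(self, derived_rates, design3,
                                                     quick_sampler):
        """2000 mixture reads at theta (0.6, 0.3): posterior ratio ~= 2, agreeing
        with the independent quadrature oracle within Monte-Carlo error."""
        rng = np.random.default_rng(7)
        table = mixture_counts(rng, 2000, 0.6, 0.3, derived_rates, design3)
        post = fit_posterior(table, design3, seed=1, fixed_rates=derived_rates,
                             sampler=quick_sampler)
        row = post.genes.iloc[0]
        oracle = grid_posterior_oracle(table, design3, derived_rates)
        assert 2 ** row["log2_ratio_mean"] == pytest.approx(2.0, rel=0.15)
        assert abs(row["log2_ratio_mean"] - oracle.log2_ratio_mean) <= (
            3 * row["log2_ratio_mcse"]
        )

    def test_symmetric_gene_centers_on_zero(self, derived_rates, design3, quick_sampler):
        rng = np.random.default_rng(3)
        table = mixture_counts(rng, 1500, 0.45, 0.45, derived_rates, design3)
        post = fit_posterior(table, design3, seed=2, fixed_rates=derived_rates,
                             sampler=quick_sampler)
        row = post.genes.iloc[0]
        assert abs(row["log2_ratio_mean"]) < 3 * row["log2_ratio_sd"]

    def test_background_identified_from_unlabelled(self, design3):
        """Fitted lambda_u should sit near the unlabelled samples' empirical rate."""
        from tilac.simulate import SimConfig, simulate_reads

        cfg = SimConfig(ratio_mode="constant", ratio_constant=1.0, n_transcripts=8,
                        read_count=400, seed=9)
        sim = simulate_reads(cfg, seed=9)
        post = fit_posterior(sim.counts, sim.design, seed=3)
        ctl = sim.tallies[sim.tallies.sample_id == "ctl1"]
        for chan, ycol in (("TC", "y_TC"), ("GA", "y_GA")):
            empirical = ctl[ycol].mean()
            row = post.rate_summary.set_index("parameter").loc[f"lambda_u_{chan}"]
            assert abs(row["mean"] - empirical) < 3 * max(row["sd"], 1e-3)

    def test_refuses_without_background_information(self, derived_rates):
        design = [SampleDesign("fwd1", Combination.FORWARD)]
        table = _one_gene_table([("fwd1", "TC", 0, 300), ("fwd1", "GA", 0, 300)])
        with pytest.raises(ValueError, match="unlabelled"):
            fit_posterior(table, design, seed=0)

    def test_posterior_tsv_round_trip(self, derived_rates, design3, quick_sampler, tmp_path):
        from tilac.model import read_posterior, write_posterior

        rng = np.random.default_rng(5)
        table = mixture_counts(rng, 400, 0.5, 0.25, derived_rates, design3)
        post = fit_posterior(table, design3, seed=4, fixed_rates=derived_rates,
                             sampler=quick_sampler)
        path = tmp_path / "posterior.tsv"
        meta = tmp_path / "meta.json"
        write_posterior(post, path, meta)
        loaded = read_posterior(path)
        assert loaded.loc[0, "log2_ratio_mean"] == pytest.approx(
            post.genes.loc[0, "log2_ratio_mean"]
        )
        assert meta.exists()
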