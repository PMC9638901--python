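"""Bayesian Poisson-mixture model for dual-label RNA-seq ratio estimation.

Each read's per-channel mutation count y is modelled as a two-component
Poisson mixture: with probability I_s * theta the read is labelled and
y ~ Poisson(lambda_l,m); otherwise y ~ Poisson(lambda_u,m), the background
(sequencing-error) rate.  The mixing fraction theta is the per-gene fraction
of labelled transcripts for the condition (experimental or control) that the
channel reads out, routed through the sample's label combination: in a
forward sample T-to-C mutations inform theta_exp and G-to-A inform
theta_cntl; a reverse sample swaps them; an unlabelled control (I_s = 0)
contributes pure background and anchors lambda_u,m.

Priors (weakly informative): log(lambda_u,m) ~ Normal(-2, 2);
lambda_l,m = lambda_u,m + TL_m with TL_m ~ Exponential(rate 0.5);
logit(theta) ~ Normal(0, 1.5) per gene and condition.

The quantity of interest is the internally normalized abundance ratio
theta_exp / theta_cntl per gene, reported on the log2 scale.

Fitting is two-stage empirical Bayes: the global mutation-rate posterior is
sampled first by Metropolis-within-Gibbs jointly with the thetas of a
high-coverage gene subset (the background rate is additionally informed by
every unlabelled read in the dataset), then each gene's two-dimensional
theta posterior is sampled with the rates fixed at their posterior means.  Both stages use
adaptive random-walk Metropolis MCMC with four independent chains per target
(the per-gene stage updates every gene's chains simultaneously in one
vectorised sweep); convergence is gated on split R-hat and bulk effective
sample size.  A deterministic two-dimensional grid-integration posterior is
provided as an independent verification oracle for the sampler.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logit, logsumexp, xlogy
from scipy.stats import norm, poisson

from .core import MutationType, SampleDesign

__all__ = [
    "GlobalRates",
    "GeneTheta",
    "PriorConfig",
    "SamplerConfig",
    "PosteriorSummary",
    "read_log_likelihood",
    "dataset_log_likelihood",
    "fit_posterior",
    "grid_posterior_oracle",
    "tilac_ratio",
    "write_posterior",
    "read_posterior",
]

THETA_FLOOR = 1e-6  # theta constrained to (1e-6, 1 - 1e-6) via the logit scale
_LOGIT_BOUND = float(logit(1.0 - THETA_FLOOR))


@dataclass(frozen=True)
class GlobalRates:
    """Per-read Poisson mutation rates for one mutation channel.

    ``lambda_u`` is the background (unlabelled / sequencing-error) rate and
    ``tl`` the labelling increment, both in mutations per read, so the
    labelled rate is ``lambda_l = lambda_u + tl``.
    """

    lambda_u: float
    tl: float

    def __post_init__(self) -> None:
        if not (self.lambda_u > 0):
            raise ValueError(f"lambda_u must be > 0, got {self.lambda_u}")
        if self.tl < 0:
            raise ValueError(f"TL must be >= 0, got {self.tl}")

    @property
    def lambda_l(self) -> float:
        return self.lambda_u + self.tl


@dataclass(frozen=True)
class GeneTheta:
    """Labelled fractions of one gene's reads in each condition."""

    theta_exp: float
    theta_cntl: float

    def __post_init__(self) -> None:
        for name in ("theta_exp", "theta_cntl"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be strictly inside (0, 1), got {v}")


@dataclass(frozen=True)
class PriorConfig:
    """Weakly informative priors on the global rates and per-gene fractions."""

    mu_log_lambda_u: float = -2.0
    sd_log_lambda_u: float = 2.0
    tl_rate: float = 0.5  # Exponential rate on TL_m (prior mean 2 mutations/read)
    theta_logit_sd: float = 1.5

    def __post_init__(self) -> None:
        if self.sd_log_lambda_u <= 0 or self.tl_rate <= 0 or self.theta_logit_sd <= 0:
            raise ValueError("prior scales must be positive")


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC settings shared by the global-rate and per-gene stages.

    Four independent chains with 1000 warm-up sweeps (step-size and
    per-parameter scale adaptation) and 2000 kept sweeps each.  The global
    stage samples the joint (rates, theta) posterior on at most
    ``global_gene_cap`` highest-coverage genes by Metropolis-within-Gibbs.  Convergence
    gates: split R-hat <= ``rhat_max`` and bulk ESS >= ``min_ess`` for every
    reported quantity.
    """

    n_chains: int = 4
    n_warmup: int = 1000
    n_keep: int = 2000
    global_gene_cap: int = 25
    rhat_max: float = 1.01
    min_ess: float = 100.0
    target_accept: float = 0.4


@dataclass
class PosteriorSummary:
    """Posterior draws, summaries and diagnostics from a model fit.

    ``genes`` has one row per gene: posterior mean/sd of theta_exp,
    theta_cntl and log2(theta_exp/theta_cntl), split R-hat, minimum bulk
    effective sample size, a Monte-Carlo standard error for the mean log2
    ratio, divergence count (identically 0 for the Metropolis sampler) and a
    convergence flag.  ``log2_draws`` maps gene_id to that gene's posterior
    draws of the log2 ratio, shape (chains, draws).  ``rates`` holds the
    posterior-mean global rates per mutation channel and ``rate_summary``
    their full summaries.
    """

    genes: pd.DataFrame
    log2_draws: dict[str, np.ndarray]
    rates: dict[MutationType, GlobalRates]
    rate_summary: pd.DataFrame
    priors: PriorConfig
    sampler: SamplerConfig
    seed: int
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Likelihood kernels


def _pois_logpmf(y, lam):
    return xlogy(y, lam) - lam - gammaln(np.asarray(y, dtype=float) + 1.0)


def read_log_likelihood(
    y: int,
    theta: float,
    rates: GlobalRates,
    labelled_indicator: int = 1,
) -> float:
    """Log-probability of one read's mutation count under the mixture.

    log[ I*theta * Pois(y; lambda_l) + (1 - I*theta) * Pois(y; lambda_u) ],
    computed by log-space summation.  With ``labelled_indicator`` = 0 the
    read comes from an unlabelled control and the result is the pure
    background Poisson log-pmf.
    """
    if y < 0:
        raise ValueError(f"mutation count must be >= 0, got {y}")
    if not (0.0 <= theta <= 1.0):
        raise ValueError(f"theta must lie in [0, 1], got {theta}")
    if labelled_indicator not in (0, 1):
        raise ValueError(f"labelled_indicator must be 0 or 1, got {labelled_indicator}")
    w = labelled_indicator * theta
    if w == 0.0:
        return float(_pois_logpmf(y, rates.lambda_u))
    if w == 1.0:
        return float(_pois_logpmf(y, rates.lambda_l))
    return float(
        np.logaddexp(
            np.log(w) + _pois_logpmf(y, rates.lambda_l),
            np.log1p(-w) + _pois_logpmf(y, rates.lambda_u),
        )
    )


@dataclass
class _GeneGroups:
    """Flattened likelihood groups of one gene.

    One entry per (sample, channel, mutations-per-read) group: the mutation
    count ``y``, the number of reads ``k``, the channel index (0 = TC,
    1 = GA), the condition the channel reads out (0 = experimental,
    1 = control, -1 = unlabelled) and the labelled indicator I_s.
    """

    y: np.ndarray
    k: np.ndarray
    ch: np.ndarray
    cond: np.ndarray
    labelled: np.ndarray


_CH_INDEX = {MutationType.TC.value: 0, MutationType.GA.value: 1}
_COND_INDEX = {"experimental": 0, "control": 1, None: -1}


def _build_groups(table: pd.DataFrame, design: Sequence[SampleDesign]) -> dict[str, _GeneGroups]:
    design_map = {d.sample_id: d for d in design}
    unknown = set(table["sample_id"]) - set(design_map)
    if unknown:
        raise ValueError(f"samples not in design: {sorted(unknown)}")
    ch = table["mutation_type"].map(_CH_INDEX).to_numpy()
    cond = np.array(
        [
            _COND_INDEX[design_map[s].condition_for(MutationType(m))]
            for s, m in zip(table["sample_id"], table["mutation_type"])
        ],
        dtype=np.int64,
    )
    lab = np.array(
        [design_map[s].labelled_indicator for s in table["sample_id"]], dtype=np.int64
    )
    y = table["n_mut"].to_numpy(dtype=np.int64)
    k = table["n_reads"].to_numpy(dtype=np.int64)
    out: dict[str, _GeneGroups] = {}
    for gene, idx in table.groupby("gene_id", sort=True).indices.items():
        out[str(gene)] = _GeneGroups(y[idx], k[idx], ch[idx], cond[idx], lab[idx])
    return out


def _groups_loglik(
    g: _GeneGroups,
    theta_exp: np.ndarray,
    theta_cntl: np.ndarray,
    lam_u: np.ndarray,
    lam_l: np.ndarray,
) -> np.ndarray:
    """Vectorised gene log-likelihood.

    ``theta_exp``/``theta_cntl`` may be any broadcastable shape; ``lam_u``/
    ``lam_l`` are length-2 arrays indexed by channel.  Returns the
    log-likelihood with the leading theta shape.
    """
    theta_exp = np.asarray(theta_exp, dtype=float)[..., None]
    theta_cntl = np.asarray(theta_cntl, dtype=float)[..., None]
    lp_l = _pois_logpmf(g.y, lam_l[g.ch])
    lp_u = _pois_logpmf(g.y, lam_u[g.ch])
    theta = np.where(g.cond == 0, theta_exp, theta_cntl)
    w = np.where(g.labelled == 1, theta, 0.0)
    w = np.clip(w, THETA_FLOOR, 1.0 - THETA_FLOOR)
    mix = np.logaddexp(np.log(w) + lp_l, np.log1p(-w) + lp_u)
    # unlabelled groups are pure background, not a degenerate mixture
    mix = np.where(g.labelled == 1, mix, lp_u)
    return (g.k * mix).sum(axis=-1)


def dataset_log_likelihood(
    table: pd.DataFrame,
    design: Sequence[SampleDesign],
    thetas: Mapping[str, GeneTheta],
    rates: Mapping[MutationType, GlobalRates],
) -> float:
    """Total log-likelihood of a grouped count table.

    Sums the per-read mixture log-likelihood over both channels of every
    group (weighted by group read count), routing theta by each sample's
    label combination.
    """
    if table.empty:
        return 0.0
    lam_u = np.array([rates[MutationType.TC].lambda_u, rates[MutationType.GA].lambda_u])
    lam_l = np.array([rates[MutationType.TC].lambda_l, rates[MutationType.GA].lambda_l])
    total = 0.0
    for gene, groups in _build_groups(table, design).items():
        if gene not in thetas:
            raise ValueError(f"no theta provided for gene {gene}")
        th = thetas[gene]
        total += float(
            _groups_loglik(
                groups,
                np.asarray(th.theta_exp),
                np.asarray(th.theta_cntl),
                lam_u,
                lam_l,
            )
        )
    return total


def tilac_ratio(theta: GeneTheta) -> tuple[float, float]:
    """Internally normalized abundance ratio theta_exp / theta_cntl and its log2."""
    if theta.theta_cntl <= 0:
        raise ValueError("ratio undefined for theta_cntl <= 0")
    ratio = theta.theta_exp / theta.theta_cntl
    return ratio, float(np.log2(ratio))


# ---------------------------------------------------------------------------
# Adaptive random-walk Metropolis, batched over independent targets


def _adaptive_rwm(
    logpost,
    x0: np.ndarray,
    rng: np.random.Generator,
    n_warmup: int,
    n_keep: int,
    target_accept: float = 0.4,
) -> np.ndarray:
    """Sample a batch of independent targets with adaptive RWM.

    ``x0`` has shape (batch, chains, dim); ``logpost`` maps such an array to
    log-densities of shape (batch, chains).  Warm-up adapts a per-target
    scalar step size toward ``target_accept`` (Robbins-Monro on the log
    scale) and, halfway through, rescales proposals by the empirical
    per-parameter posterior spread.  Returns kept draws of shape
    (batch, chains, n_keep, dim); adaptation is frozen during the kept phase.
    """
    x = np.array(x0, dtype=float)
    b, c, d = x.shape
    lp = logpost(x)
    log_scale = np.full((b, 1, 1), np.log(0.5))
    step_sd = np.ones((b, 1, d))
    half = n_warmup // 2
    warm_buf = np.empty((half, b, c, d))
    draws = np.empty((b, c, n_keep, d))
    for t in range(n_warmup + n_keep):
        prop = x + np.exp(log_scale) * step_sd * rng.standard_normal(x.shape)
        lp_prop = logpost(prop)
        accept = np.log(rng.random((b, c))) < (lp_prop - lp)
        x = np.where(accept[..., None], prop, x)
        lp = np.where(accept, lp_prop, lp)
        if t < n_warmup:
            acc_rate = accept.mean(axis=1)  # (b,)
            gain = 1.0 / (1.0 + 0.1 * t) ** 0.6
            log_scale += gain * (acc_rate - target_accept)[:, None, None]
            if t < half:
                warm_buf[t] = x
            if t == half:
                sd = warm_buf[half // 2 :].std(axis=(0, 2))  # (b, d)
                sd = np.maximum(sd, 1e-3)
                step_sd = (sd / sd.mean(axis=1, keepdims=True))[:, None, :]
        else:
            draws[:, :, t - n_warmup, :] = x
    return draws


def _diagnostics(per_gene_draws: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split R-hat and bulk ESS for draws of shape (batch, chains, draws, q)."""
    arr = np.moveaxis(per_gene_draws, (1, 2), (0, 1))  # (chains, draws, batch, q)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset(arr)
        rhat = az.rhat(ds)["x"].to_numpy()
        ess = az.ess(ds, method="bulk")["x"].to_numpy()
    return rhat, ess  # each (batch, q)


# ---------------------------------------------------------------------------
# Stage A: global mutation-rate posterior


def _unlabelled_histogram(
    groups: Mapping[str, _GeneGroups]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pooled (y, channel) -> read-count histogram over all unlabelled groups."""
    agg: dict[tuple[int, int], int] = {}
    for g in groups.values():
        m = g.labelled == 0
        for yi, ci, ki in zip(g.y[m], g.ch[m], g.k[m]):
            agg[(int(yi), int(ci))] = agg.get((int(yi), int(ci)), 0) + int(ki)
    if not agg:
        return (np.empty(0, dtype=np.int64),) * 3
    keys = sorted(agg)
    return (
        np.array([k[0] for k in keys]),
        np.array([k[1] for k in keys]),
        np.array([agg[k] for k in keys]),
    )


class _JointGlobalModel:
    """Joint posterior pieces for (global rates, subset-gene thetas).

    Rate parameters are p = (log lambda_u,TC, log lambda_u,GA, log TL_TC,
    log TL_GA) per chain.  The unlabelled-read histogram (pooled over all
    genes) informs lambda_u directly; the labelled groups of the gene subset
    inform the labelled rates through the mixture, with the subset thetas
    sampled alongside by Metropolis-within-Gibbs.
    """

    def __init__(
        self,
        groups: Mapping[str, _GeneGroups],
        subset: Sequence[str],
        priors: PriorConfig,
    ):
        self.priors = priors
        self.y_u, self.ch_u, self.k_u = _unlabelled_histogram(groups)
        self.lgam_u = gammaln(self.y_u + 1.0)
        ys, ks, chs, conds, gidx, seg = [], [], [], [], [], [0]
        for i, gene in enumerate(subset):
            g = groups[gene]
            m = g.labelled == 1
            ys.append(g.y[m])
            ks.append(g.k[m])
            chs.append(g.ch[m])
            conds.append(g.cond[m])
            gidx.append(np.full(int(m.sum()), i))
            seg.append(seg[-1] + int(m.sum()))
        self.y = np.concatenate(ys) if ys else np.empty(0, dtype=np.int64)
        self.k = np.concatenate(ks) if ks else np.empty(0, dtype=np.int64)
        self.ch = np.concatenate(chs) if chs else np.empty(0, dtype=np.int64)
        self.cond = np.concatenate(conds) if conds else np.empty(0, dtype=np.int64)
        self.gidx = np.concatenate(gidx) if gidx else np.empty(0, dtype=np.int64)
        self.seg = np.asarray(seg[:-1])
        self.empty = np.diff(seg) == 0
        self.lgam = gammaln(self.y + 1.0)
        self.n_genes = len(subset)

    @staticmethod
    def rates_from_params(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lam_u = np.exp(p[:, 0:2])
        lam_l = lam_u + np.exp(p[:, 2:4])
        return lam_u, lam_l

    def _group_mix(self, t: np.ndarray, lam_u: np.ndarray, lam_l: np.ndarray) -> np.ndarray:
        """Per-group weighted mixture log-likelihood, shape (n_groups, chains)."""
        theta = expit(np.clip(t, -_LOGIT_BOUND, _LOGIT_BOUND))
        sel = theta[self.gidx]  # (n_groups, chains, 2)
        w = np.where(self.cond[:, None] == 0, sel[..., 0], sel[..., 1])
        w = np.clip(w, THETA_FLOOR, 1.0 - THETA_FLOOR)
        ll = lam_l[:, self.ch].T  # (n_groups, chains)
        lu = lam_u[:, self.ch].T
        lp_l = xlogy(self.y[:, None], ll) - ll - self.lgam[:, None]
        lp_u = xlogy(self.y[:, None], lu) - lu - self.lgam[:, None]
        return self.k[:, None] * np.logaddexp(
            np.log(w) + lp_l, np.log1p(-w) + lp_u
        )

    def theta_logpost(self, t: np.ndarray, lam_u: np.ndarray, lam_l: np.ndarray) -> np.ndarray:
        lp = norm.logpdf(
            np.clip(t, -_LOGIT_BOUND, _LOGIT_BOUND), 0.0, self.priors.theta_logit_sd
        ).sum(axis=-1)
        lp = np.where(np.any(np.abs(t) > _LOGIT_BOUND + 1e-9, axis=-1), -np.inf, lp)
        if self.gidx.size == 0:
            return lp
        contrib = np.add.reduceat(self._group_mix(t, lam_u, lam_l), self.seg, axis=0)
        if self.empty.any():
            contrib[self.empty] = 0.0
        return lp + contrib

    def rates_logpost(self, p: np.ndarray, t: np.ndarray) -> np.ndarray:
        pr = self.priors
        lp = norm.logpdf(p[:, 0:2], pr.mu_log_lambda_u, pr.sd_log_lambda_u).sum(axis=1)
        # Exponential(rate) prior on TL with the log-transform Jacobian
        lp += (np.log(pr.tl_rate) - pr.tl_rate * np.exp(p[:, 2:4]) + p[:, 2:4]).sum(axis=1)
        lam_u, lam_l = self.rates_from_params(p)
        if self.y_u.size:
            lam = lam_u[:, self.ch_u]  # (chains, n_u_groups)
            lp += (self.k_u * (xlogy(self.y_u, lam) - lam - self.lgam_u)).sum(axis=1)
        if self.y.size:
            lp += self._group_mix(t, lam_u, lam_l).sum(axis=0)
        return lp


def _fit_global_rates(
    groups: Mapping[str, _GeneGroups],
    priors: PriorConfig,
    cfg: SamplerConfig,
    rng: np.random.Generator,
    fixed_background: Mapping[MutationType, float] | None,
) -> tuple[dict[MutationType, GlobalRates], pd.DataFrame]:
    has_unlabelled = any((g.labelled == 0).any() for g in groups.values())
    if not has_unlabelled and fixed_background is None:
        raise ValueError(
            "no unlabelled control sample in the design and no fixed background rates "
            "provided; the background mutation rate is unidentifiable"
        )
    by_depth = sorted(groups, key=lambda g: (-int(groups[g].k[groups[g].labelled == 1].sum()), g))
    subset = by_depth[: cfg.global_gene_cap]
    model = _JointGlobalModel(groups, subset, priors)

    # moment-based initial rates: unlabelled mean for lambda_u, labelled mean for TL
    lu0 = np.full(2, np.exp(priors.mu_log_lambda_u))
    if fixed_background is not None:
        lu0 = np.array([fixed_background[MutationType.TC], fixed_background[MutationType.GA]])
    elif model.y_u.size:
        for cnd in (0, 1):
            m = model.ch_u == cnd
            if m.any() and model.k_u[m].sum() > 0:
                lu0[cnd] = max(
                    (model.y_u[m] * model.k_u[m]).sum() / model.k_u[m].sum(), 1e-4
                )
    tl0 = np.full(2, 1.0)
    for cnd in (0, 1):
        m = model.ch == cnd
        if m.any() and model.k[m].sum() > 0:
            ybar = (model.y[m] * model.k[m]).sum() / model.k[m].sum()
            tl0[cnd] = max(2.0 * (ybar - lu0[cnd]), 0.2)
    p0 = np.concatenate([np.log(lu0), np.log(tl0)])
    c = cfg.n_chains
    p = p0[None, :] + 0.05 * rng.standard_normal((c, 4))  # (chains, 4)
    t = np.zeros((model.n_genes, c, 2)) + 0.2 * rng.standard_normal((model.n_genes, c, 2))

    n_warm, n_keep = cfg.n_warmup, cfg.n_keep
    rate_ls = np.log(0.1)
    rate_sd = np.ones(4)
    theta_ls = np.full((model.n_genes, 1, 1), np.log(0.3))
    half = n_warm // 2
    warm_buf = np.empty((half, c, 4))
    draws = np.empty((c, n_keep, 4))
    lam_u, lam_l = model.rates_from_params(p)
    for step in range(n_warm + n_keep):
        # theta block (all subset genes, all chains at once)
        lp_t = model.theta_logpost(t, lam_u, lam_l)
        prop_t = t + np.exp(theta_ls) * rng.standard_normal(t.shape)
        lp_t_prop = model.theta_logpost(prop_t, lam_u, lam_l)
        acc_t = np.log(rng.random(lp_t.shape)) < (lp_t_prop - lp_t)
        t = np.where(acc_t[..., None], prop_t, t)
        # rates block
        lp_p = model.rates_logpost(p, t)
        prop_p = p + np.exp(rate_ls) * rate_sd * rng.standard_normal(p.shape)
        lp_p_prop = model.rates_logpost(prop_p, t)
        acc_p = np.log(rng.random(c)) < (lp_p_prop - lp_p)
        p = np.where(acc_p[:, None], prop_p, p)
        lam_u, lam_l = model.rates_from_params(p)
        if step < n_warm:
            gain = 1.0 / (1.0 + 0.1 * step) ** 0.6
            theta_ls += gain * (acc_t.mean(axis=1) - cfg.target_accept)[:, None, None]
            rate_ls += gain * (acc_p.mean() - cfg.target_accept)
            if step < half:
                warm_buf[step] = p
            if step == half:
                sd = np.maximum(warm_buf[half // 2 :].std(axis=(0, 1)), 1e-4)
                rate_sd = sd / sd.mean()
        else:
            draws[:, step - n_warm, :] = p

    lu = np.exp(draws[..., 0:2])
    tl = np.exp(draws[..., 2:4])
    natural = np.concatenate([lu, tl, lu + tl], axis=-1)  # (chains, n_keep, 6)
    rhat, ess = _diagnostics(natural[None, ...])
    names = ["lambda_u_TC", "lambda_u_GA", "TL_TC", "TL_GA", "lambda_l_TC", "lambda_l_GA"]
    summary = pd.DataFrame(
        dict(
            parameter=names,
            mean=natural.mean(axis=(0, 1)),
            sd=natural.std(axis=(0, 1), ddof=1),
            rhat=rhat[0],
            ess=ess[0],
        )
    )
    means = dict(zip(names, summary["mean"]))
    rates = {
        MutationType.TC: GlobalRates(means["lambda_u_TC"], means["TL_TC"]),
        MutationType.GA: GlobalRates(means["lambda_u_GA"], means["TL_GA"]),
    }
    return rates, summary


# ---------------------------------------------------------------------------
# Stage B: per-gene theta posteriors, all genes swept together


class _BatchedGenePosterior:
    """Joint evaluation of every gene's (logit theta_exp, logit theta_cntl) posterior.

    With the global rates fixed, the per-group Poisson pmfs are constants;
    only the mixing weights depend on theta, so one sweep over the
    concatenated group arrays evaluates all genes' log-posteriors at once.
    """

    def __init__(
        self,
        groups: Mapping[str, _GeneGroups],
        gene_order: Sequence[str],
        lam_u: np.ndarray,
        lam_l: np.ndarray,
        prior_sd: float,
    ):
        self.prior_sd = prior_sd
        ys, ks, chs, conds, gidx, seg = [], [], [], [], [], [0]
        for i, gene in enumerate(gene_order):
            g = groups[gene]
            m = g.labelled == 1
            ys.append(g.y[m])
            ks.append(g.k[m])
            chs.append(g.ch[m])
            conds.append(g.cond[m])
            gidx.append(np.full(int(m.sum()), i))
            seg.append(seg[-1] + int(m.sum()))
        y = np.concatenate(ys) if ys else np.empty(0, dtype=np.int64)
        self.k = np.concatenate(ks) if ks else np.empty(0, dtype=np.int64)
        ch = np.concatenate(chs) if chs else np.empty(0, dtype=np.int64)
        self.cond = np.concatenate(conds) if conds else np.empty(0, dtype=np.int64)
        self.gidx = np.concatenate(gidx) if gidx else np.empty(0, dtype=np.int64)
        self.seg = np.asarray(seg[:-1])
        self.empty = np.diff(seg) == 0
        self.lp_l = _pois_logpmf(y, lam_l[ch])
        self.lp_u = _pois_logpmf(y, lam_u[ch])
        self.n_genes = len(gene_order)

    def __call__(self, t: np.ndarray) -> np.ndarray:
        # t: (n_genes, chains, 2) on the logit scale
        lp = norm.logpdf(np.clip(t, -_LOGIT_BOUND, _LOGIT_BOUND), 0.0, self.prior_sd).sum(axis=-1)
        lp = np.where(np.any(np.abs(t) > _LOGIT_BOUND + 1e-9, axis=-1), -np.inf, lp)
        if self.gidx.size == 0:
            return lp
        theta = expit(t)  # (n_genes, chains, 2)
        sel = theta[self.gidx, :, :]  # (G, chains, 2)
        w = np.where(self.cond[:, None] == 0, sel[:, :, 0], sel[:, :, 1])  # (G, chains)
        w = np.clip(w, THETA_FLOOR, 1.0 - THETA_FLOOR)
        mix = np.logaddexp(np.log(w) + self.lp_l[:, None], np.log1p(-w) + self.lp_u[:, None])
        contrib = np.add.reduceat(self.k[:, None] * mix, self.seg, axis=0)  # (n_genes, chains)
        if self.empty.any():
            contrib[self.empty] = 0.0
        return lp + contrib


def _moment_start(
    groups: Mapping[str, _GeneGroups],
    gene_order: Sequence[str],
    lam_u: np.ndarray,
    lam_l: np.ndarray,
) -> np.ndarray:
    """Method-of-moments logit-theta starting points, shape (n_genes, 2)."""
    start = np.zeros((len(gene_order), 2))
    for i, gene in enumerate(gene_order):
        g = groups[gene]
        for cnd in (0, 1):
            m = (g.labelled == 1) & (g.cond == cnd)
            if not m.any() or g.k[m].sum() == 0:
                continue
            k = g.k[m]
            ybar = (g.y[m] * k).sum() / k.sum()
            base = (k * lam_u[g.ch[m]]).sum() / k.sum()
            span = (k * (lam_l - lam_u)[g.ch[m]]).sum() / k.sum()
            theta_hat = np.clip((ybar - base) / max(span, 1e-8), 1e-3, 1 - 1e-3)
            start[i, cnd] = logit(theta_hat)
    return start


def fit_posterior(
    table: pd.DataFrame,
    design: Sequence[SampleDesign],
    priors: PriorConfig | None = None,
    *,
    seed: int = 0,
    sampler: SamplerConfig | None = None,
    fixed_rates: Mapping[MutationType, GlobalRates] | None = None,
    fixed_background: Mapping[MutationType, float] | None = None,
) -> PosteriorSummary:
    """Fit the mixture model to a grouped count table.

    Parameters
    ----------
    table
        Grouped count table (see :func:`tilac.core.aggregate_reads`),
        already coverage-filtered.
    design
        Sample design records covering every sample in the table.  At least
        one unlabelled control is required unless ``fixed_rates`` or
        ``fixed_background`` pins the background rate.
    seed
        Master seed; all sampler randomness derives from it.
    fixed_rates
        Skip the global stage entirely and use these rates.
    fixed_background
        Fix lambda_u per channel but still infer the labelling increments.

    Returns a :class:`PosteriorSummary`.  Genes whose chains fail the
    convergence gates are flagged (``converged`` = False), never silently
    accepted.
    """
    priors = priors or PriorConfig()
    cfg = sampler or SamplerConfig()
    rng = np.random.default_rng(seed)
    groups = _build_groups(table, design)

    if fixed_rates is not None:
        rates = dict(fixed_rates)
        rate_summary = pd.DataFrame(
            dict(
                parameter=[f"lambda_u_{m.value}" for m in MutationType]
                + [f"lambda_l_{m.value}" for m in MutationType],
                mean=[rates[m].lambda_u for m in MutationType]
                + [rates[m].lambda_l for m in MutationType],
                sd=0.0,
                rhat=np.nan,
                ess=np.nan,
            )
        )
    else:
        rates, rate_summary = _fit_global_rates(groups, priors, cfg, rng, fixed_background)

    lam_u = np.array([rates[MutationType.TC].lambda_u, rates[MutationType.GA].lambda_u])
    lam_l = np.array([rates[MutationType.TC].lambda_l, rates[MutationType.GA].lambda_l])

    gene_order = sorted(groups)
    logpost = _BatchedGenePosterior(groups, gene_order, lam_u, lam_l, priors.theta_logit_sd)
    start = _moment_start(groups, gene_order, lam_u, lam_l)
    x0 = start[:, None, :] + 0.1 * rng.standard_normal((len(gene_order), cfg.n_chains, 2))
    draws = _adaptive_rwm(logpost, x0, rng, cfg.n_warmup, cfg.n_keep, cfg.target_accept)

    t = np.clip(draws, -_LOGIT_BOUND, _LOGIT_BOUND)
    theta_e, theta_c = expit(t[..., 0]), expit(t[..., 1])  # (genes, chains, keep)
    log2r = np.log2(theta_e / theta_c)
    stacked = np.stack([log2r, theta_e, theta_c], axis=-1)  # (genes, chains, keep, 3)
    rhat, ess = _diagnostics(stacked)  # (genes, 3)
    rhat_max = rhat.max(axis=1)
    ess_min = ess.min(axis=1)
    mc_se = log2r.std(axis=(1, 2), ddof=1) / np.sqrt(np.maximum(ess[:, 0], 1.0))

    genes = pd.DataFrame(
        dict(
            gene_id=gene_order,
            theta_exp_mean=theta_e.mean(axis=(1, 2)),
            theta_exp_sd=theta_e.std(axis=(1, 2), ddof=1),
            theta_cntl_mean=theta_c.mean(axis=(1, 2)),
            theta_cntl_sd=theta_c.std(axis=(1, 2), ddof=1),
            log2_ratio_mean=log2r.mean(axis=(1, 2)),
            log2_ratio_sd=log2r.std(axis=(1, 2), ddof=1),
            log2_ratio_mcse=mc_se,
            rhat_max=rhat_max,
            n_eff_min=ess_min,
            n_divergent=0,
            converged=(rhat_max <= cfg.rhat_max) & (ess_min >= cfg.min_ess),
        )
    )
    n_fail = int((~genes["converged"]).sum())
    if n_fail:
        warnings.warn(
            f"{n_fail}/{len(genes)} genes failed convergence gates "
            f"(R-hat <= {cfg.rhat_max}, ESS >= {cfg.min_ess}); flagged in output",
            stacklevel=2,
        )
    log2_draws = {gene: log2r[i] for i, gene in enumerate(gene_order)}
    return PosteriorSummary(
        genes=genes,
        log2_draws=log2_draws,
        rates=rates,
        rate_summary=rate_summary,
        priors=priors,
        sampler=cfg,
        seed=seed,
        metadata={"sampler": "adaptive random-walk Metropolis", "n_genes": len(genes)},
    )


# ---------------------------------------------------------------------------
# Independent grid-integration oracle


@dataclass(frozen=True)
class OracleResult:
    log2_ratio_mean: float
    log2_ratio_sd: float
    theta_exp_mean: float
    theta_cntl_mean: float
    grid_size: int


def grid_posterior_oracle(
    table: pd.DataFrame,
    design: Sequence[SampleDesign],
    rates: Mapping[MutationType, GlobalRates],
    prior_logit_sd: float = 1.5,
    *,
    span: float = 9.0,
    n_start: int = 121,
    tol: float = 1e-3,
    max_n: int = 1000,
) -> OracleResult:
    """Deterministic 2-D quadrature posterior for one gene, rates fixed.

    Evaluates the exact unnormalised posterior of (logit theta_exp,
    logit theta_cntl) on a trapezoid grid over [-span, span]^2 and refines
    (doubling the resolution) until the posterior mean log2 ratio changes by
    less than ``tol``.  Independent of the MCMC path: the likelihood is
    spelled out directly from the scipy Poisson pmf, row by row.
    """
    genes = table["gene_id"].unique()
    if len(genes) > 1:
        raise ValueError(f"oracle expects a single gene, got {len(genes)}")
    design_map = {d.sample_id: d for d in design}

    def log_post(te: np.ndarray, tc: np.ndarray) -> np.ndarray:
        lp = norm.logpdf(te, 0, prior_logit_sd) + norm.logpdf(tc, 0, prior_logit_sd)
        th_e, th_c = expit(te), expit(tc)
        for _, row in table.iterrows():
            d = design_map[row["sample_id"]]
            mt = MutationType(row["mutation_type"])
            r = rates[mt]
            cond = d.condition_for(mt)
            if d.labelled_indicator == 0:
                lp = lp + row["n_reads"] * poisson.logpmf(row["n_mut"], r.lambda_u)
                continue
            th = th_e if cond == "experimental" else th_c
            like = th * poisson.pmf(row["n_mut"], r.lambda_l) + (1 - th) * poisson.pmf(
                row["n_mut"], r.lambda_u
            )
            lp = lp + row["n_reads"] * np.log(like)
        return lp

    prev_mean = None
    n = n_start
    while True:
        t = np.linspace(-span, span, n)
        te, tc = np.meshgrid(t, t, indexing="ij")
        lp = log_post(te, tc)
        w = np.exp(lp - lp.max())
        w /= w.sum()
        log2r = np.log2(expit(te) / expit(tc))
        mean = float((w * log2r).sum())
        sd = float(np.sqrt((w * (log2r - mean) ** 2).sum()))
        if prev_mean is not None and abs(mean - prev_mean) < tol:
            return OracleResult(
                log2_ratio_mean=mean,
                log2_ratio_sd=sd,
                theta_exp_mean=float((w * expit(te)).sum()),
                theta_cntl_mean=float((w * expit(tc)).sum()),
                grid_size=n,
            )
        if 2 * n - 1 > max_n:
            raise RuntimeError(
                f"grid posterior did not converge to {tol} by n = {n} "
                f"(last change {abs(mean - prev_mean) if prev_mean is not None else np.inf:.2e})"
            )
        prev_mean = mean
        n = 2 * n - 1


# ---------------------------------------------------------------------------
# Posterior TSV + metadata I/O

POSTERIOR_COLUMNS = [
    "gene_id",
    "theta_exp_mean",
    "theta_exp_sd",
    "theta_cntl_mean",
    "theta_cntl_sd",
    "log2_ratio_mean",
    "log2_ratio_sd",
    "log2_ratio_mcse",
    "rhat_max",
    "n_eff_min",
    "n_divergent",
    "converged",
]


def write_posterior(
    summary: PosteriorSummary, path: str | Path, metadata_path: str | Path | None = None
) -> None:
    """Write the per-gene posterior table; optionally a JSON run-metadata file."""
    summary.genes[POSTERIOR_COLUMNS].to_csv(path, sep="\t", index=False)
    if metadata_path is not None:
        meta = {
            "seed": summary.seed,
            "priors": asdict(summary.priors),
            "sampler": asdict(summary.sampler),
            "rates": {
                m.value: {"lambda_u": r.lambda_u, "tl": r.tl, "lambda_l": r.lambda_l}
                for m, r in summary.rates.items()
            },
            **summary.metadata,
        }
        Path(metadata_path).write_text(json.dumps(meta, indent=2) + "\n")


def read_posterior(path: str | Path) -> pd.DataFrame:
    genes = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    missing = [c for c in ("gene_id", "log2_ratio_mean", "log2_ratio_sd") if c not in genes.columns]
    if missing:
        raise ValueError(f"posterior table {path} missing columns: {missing}")
    if "converged" not in genes.columns:
        genes["converged"] = True
    return genes
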