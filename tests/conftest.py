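import numpy as np
import pytest

from tilac.core import Combination, SampleDesign
from tilac.model import GlobalRates, SamplerConfig
from tilac.core import MutationType
from tilac.simulate import SimConfig, simulate_reads


@pytest.fixture(scope="session")
def derived_rates():
    """Per-read rates implied by the generative per-base rates at 50 expected sites.

    200-base reads with quarter-U / quarter-G composition carry ~50 U and
    ~50 G sites, so per-read Poisson rates are 50x the per-base rates:
    lambda_l,TC = 2.5, lambda_u,TC = 0.05, lambda_l,GA = 1.0, lambda_u,GA = 0.2.
    """
    return {
        MutationType.TC: GlobalRates(lambda_u=0.05, tl=2.45),
        MutationType.GA: GlobalRates(lambda_u=0.2, tl=0.8),
    }


@pytest.fixture(scope="session")
def design3():
    return [
        SampleDesign("fwd1", Combination.FORWARD, 1),
        SampleDesign("rev1", Combination.REVERSE, 1),
        SampleDesign("ctl1", Combination.UNLABELLED, 1),
    ]


@pytest.fixture(scope="session")
def small_sim():
    """A 12-gene experiment spanning depletion, null and enrichment."""
    cfg = SimConfig(
        ratio_mode="grid",
        ratio_grid=(0.25, 1.0, 4.0),
        transcripts_per_ratio=4,
        read_count=300,
        seed=5,
    )
    return simulate_reads(cfg, seed=5)


@pytest.fixture(scope="session")
def quick_sampler():
    """Smaller sampler for tests that do not assert convergence diagnostics."""
    return SamplerConfig(n_warmup=500, n_keep=800)


def mixture_counts(rng, n_reads, theta_exp, theta_cntl, rates, design):
    """Draw a single-gene count table directly from the Poisson mixture model."""
    import pandas as pd
    from tilac.core import aggregate_reads, ReadTally

    rows = []
    for d in design:
        for mt in MutationType:
            r = rates[mt]
            cond = d.condition_for(mt)
            if d.labelled_indicator == 0:
                lam = np.full(n_reads, r.lambda_u)
            else:
                theta = theta_exp if cond == "experimental" else theta_cntl
                labelled = rng.random(n_reads) < theta
                lam = np.where(labelled, r.lambda_l, r.lambda_u)
            y = rng.poisson(lam)
            vals, counts = np.unique(y, return_counts=True)
            for v, c in zip(vals, counts):
                rows.append(("g0", d.sample_id, mt.value, int(v), int(c), 50.0))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "sample_id", "mutation_type", "n_mut", "n_reads", "mean_bases"],
    )
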