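"""Composite-null testing of log2 abundance ratios.

Rather than testing whether a gene's log2 ratio differs from zero, the test
asks whether its magnitude exceeds a threshold mu_cutoff (default 0.5):
the composite null is |mu| <= mu_cutoff, evaluated at its boundary under a
normal approximation to the ratio posterior (the construction used by the
fold-change-threshold test TREAT).  P-values are corrected across genes by
Benjamini-Hochberg at FDR level alpha (default 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

__all__ = ["TestConfig", "treat_pvalue", "bh_adjust", "call_significance", "write_results"]


@dataclass(frozen=True)
class TestConfig:
    """Composite-null test settings.

    ``mu_cutoff`` is the log2-ratio magnitude below which a change is
    considered uninteresting; ``alpha`` the FDR level for BH correction.
    """

    mu_cutoff: float = 0.5
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.mu_cutoff < 0:
            raise ValueError(f"mu_cutoff must be >= 0, got {self.mu_cutoff}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")


RESULT_COLUMNS = [
    "gene_id",
    "log2_ratio_mean",
    "log2_ratio_sd",
    "p_value",
    "p_adjusted",
    "significant",
    "direction",
]


def treat_pvalue(mean, sd, mu_cutoff: float = 0.5):
    """P-value for the composite null |mu| <= mu_cutoff.

    With the posterior approximated as Normal(mean, sd), the two-boundary
    tail sum is p = S((|mean| - c)/sd) + S((|mean| + c)/sd) where S is the
    standard-normal survival function and c = mu_cutoff; capped at 1.
    At mean = 0 the two tails are complementary and p = 1 exactly.
    Accepts scalars or arrays.
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if np.any(sd <= 0):
        raise ValueError("posterior sd must be > 0")
    a = np.abs(mean)
    p = norm.sf((a - mu_cutoff) / sd) + norm.sf((a + mu_cutoff) / sd)
    p = np.minimum(p, 1.0)
    return float(p) if p.ndim == 0 else p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_significance(
    posterior: pd.DataFrame,
    config: TestConfig | None = None,
) -> pd.DataFrame:
    """Test every converged gene and correct across the tested family.

    ``posterior`` needs columns gene_id, log2_ratio_mean, log2_ratio_sd and
    (optionally) converged.  Genes failing convergence are excluded from the
    BH family — their rows carry NaN p-values and ``significant`` = False —
    and their exclusion is reported via a warning.  Direction is the sign of
    the posterior mean for significant genes, 'none' otherwise.
    """
    config = config or TestConfig()
    if posterior.empty:
        warnings.warn("empty posterior table: no genes to test", stacklevel=2)
        return pd.DataFrame(columns=RESULT_COLUMNS)
    out = posterior[["gene_id", "log2_ratio_mean", "log2_ratio_sd"]].copy()
    converged = (
        posterior["converged"].astype(bool)
        if "converged" in posterior.columns
        else pd.Series(True, index=posterior.index)
    )
    n_excluded = int((~converged).sum())
    if n_excluded:
        warnings.warn(
            f"excluding {n_excluded} non-converged genes from the testing family",
            stacklevel=2,
        )
    out["p_value"] = np.nan
    out["p_adjusted"] = np.nan
    tested = converged.to_numpy()
    p = treat_pvalue(
        out.loc[tested, "log2_ratio_mean"].to_numpy(),
        out.loc[tested, "log2_ratio_sd"].to_numpy(),
        config.mu_cutoff,
    )
    out.loc[tested, "p_value"] = p
    out.loc[tested, "p_adjusted"] = bh_adjust(np.atleast_1d(p)) if np.size(p) else p
    out["significant"] = (out["p_adjusted"] < config.alpha).fillna(False)
    out["direction"] = np.where(
        ~out["significant"], "none", np.where(out["log2_ratio_mean"] > 0, "up", "down")
    )
    return out[RESULT_COLUMNS]


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    results[RESULT_COLUMNS].to_csv(path, sep="\t", index=False)
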