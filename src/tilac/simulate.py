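"""Generative simulator for dual-label recoding RNA-seq experiments.

A simulated experiment consists of a forward sample (experimental condition
fed s4U, control fed s6G), a reverse sample (labels swapped) and an
unlabelled control.  Per transcript, a true abundance ratio determines the
labelled fractions (theta_exp, theta_cntl); each read is assigned to the
experimental-labelled, control-labelled or unlabelled pool by a multinomial
draw, its U/G content is drawn as Multinomial(read_length; p_U, p_G), and
its T-to-C / G-to-A mutation counts are Binomial in the per-base labelled or
background rate for its pool.  Mutation counts are generated Binomially even
though the inference model is Poisson; this mild misspecification is
deliberate and mirrors how real per-read counts arise from finite site
counts.

The module doubles as the repository's fixture generator: it can emit the
simulated reads as SAM + FASTA + GTF so the alignment-tallying front end can
be round-tripped against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam
from scipy.special import expit, logit

from .core import Combination, SampleDesign, aggregate_reads

__all__ = [
    "SimConfig",
    "SimResult",
    "default_design",
    "draw_thetas",
    "simulate_reads",
    "apply_regulation_mode",
    "synthetic_template",
    "sweep",
    "emit_synthetic_sam",
]

#: abundance-ratio grid used for dynamic-range assessment
RATIO_GRID = (0.01, 0.1, 0.5, 1.0, 1.5, 2.0, 10.0, 100.0)


@dataclass(frozen=True)
class SimConfig:
    """Generative settings for one simulated experiment.

    Defaults follow the standard experimental regime: 200-base reads with a
    quarter-U / quarter-G composition; per-base labelled mutation rates of
    0.05 (T-to-C, s4U) and 0.02 (G-to-A, s6G) over backgrounds of 0.001 and
    0.004; logit-scale noise of 0.5 on the control labelled fraction.

    Ratio modes: ``grid`` cycles ``ratio_grid`` with ``transcripts_per_ratio``
    transcripts each; ``constant`` uses ``ratio_constant`` for every
    transcript; ``template`` takes per-transcript ratios (and, with
    read_count_mode ``template``, Poisson read-count means) from
    ``template`` — a DataFrame with columns log2_ratio and read_count_mean.
    """

    n_transcripts: int | None = None
    read_count_mode: str = "fixed"  # fixed | template
    read_count: int = 200
    ratio_mode: str = "grid"  # grid | constant | template
    ratio_grid: tuple[float, ...] = RATIO_GRID
    transcripts_per_ratio: int = 300
    ratio_constant: float = 1.0
    template: pd.DataFrame | None = None
    min_template_reads: int = 15  # template transcripts below this mean are dropped
    read_length: int = 200
    p_U: float = 0.25
    p_G: float = 0.25
    rate_TC_labelled: float = 0.05
    rate_TC_background: float = 0.001
    rate_GA_labelled: float = 0.02
    rate_GA_background: float = 0.004
    theta_logit_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_U", "p_G", "rate_TC_labelled", "rate_TC_background",
                     "rate_GA_labelled", "rate_GA_background"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.p_U + self.p_G > 1.0:
            raise ValueError("p_U + p_G must not exceed 1")
        if self.rate_TC_labelled < self.rate_TC_background:
            raise ValueError("labelled T-to-C rate below background")
        if self.rate_GA_labelled < self.rate_GA_background:
            raise ValueError("labelled G-to-A rate below background")
        if self.read_count_mode not in ("fixed", "template"):
            raise ValueError(f"unknown read_count_mode {self.read_count_mode!r}")
        if self.ratio_mode not in ("grid", "constant", "template"):
            raise ValueError(f"unknown ratio_mode {self.ratio_mode!r}")

    def resolve_ratios(self) -> np.ndarray:
        """True per-transcript abundance ratios implied by the configuration."""
        if self.ratio_mode == "grid":
            base = np.repeat(self.ratio_grid, self.transcripts_per_ratio)
            if self.n_transcripts is not None:
                base = np.resize(
                    np.repeat(self.ratio_grid, max(1, self.n_transcripts // len(self.ratio_grid))),
                    self.n_transcripts,
                )
            return np.asarray(base, dtype=float)
        if self.ratio_mode == "constant":
            n = self.n_transcripts if self.n_transcripts is not None else 300
            return np.full(n, self.ratio_constant, dtype=float)
        if self.template is None:
            raise ValueError("ratio_mode='template' requires a template DataFrame")
        tpl = self.template
        if self.min_template_reads and "read_count_mean" in tpl.columns:
            tpl = tpl[tpl["read_count_mean"] >= self.min_template_reads]
        ratios = 2.0 ** tpl["log2_ratio"].to_numpy(dtype=float)
        if self.n_transcripts is not None:
            ratios = ratios[: self.n_transcripts]
        return ratios


@dataclass
class SimResult:
    """Simulator output: read-level tallies, grouped counts, truth and design."""

    tallies: pd.DataFrame
    counts: pd.DataFrame
    truth: pd.DataFrame
    design: list[SampleDesign]
    config: SimConfig = field(repr=False, default=None)


def default_design(
    n_forward: int = 1, n_reverse: int = 1, n_unlabelled: int = 1
) -> list[SampleDesign]:
    """One-replicate forward + reverse + unlabelled design (extendable)."""
    design = []
    for i in range(n_forward):
        design.append(SampleDesign(f"fwd{i + 1}", Combination.FORWARD, i + 1))
    for i in range(n_reverse):
        design.append(SampleDesign(f"rev{i + 1}", Combination.REVERSE, i + 1))
    for i in range(n_unlabelled):
        design.append(SampleDesign(f"ctl{i + 1}", Combination.UNLABELLED, i + 1))
    return design


def draw_thetas(
    ratio, noise_sd: float = 0.5, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw labelled fractions consistent with the requested true ratio.

    logit(theta_cntl) ~ Normal(logit(1 / (1 + ratio)), noise_sd) and
    theta_exp = ratio * theta_cntl, so theta_exp / theta_cntl equals the
    requested ratio exactly and, at zero noise, the two fractions sum to 1.
    Pairs whose sum exceeds 1 (possible for noisy draws at extreme ratios)
    are rescaled to sum to 1 - 1e-9, preserving the ratio.
    """
    ratio = np.asarray(ratio, dtype=float)
    if np.any(ratio <= 0):
        raise ValueError("true ratio must be > 0")
    rng = rng or np.random.default_rng()
    center = logit(1.0 / (1.0 + ratio))
    t = center + noise_sd * rng.standard_normal(ratio.shape)
    theta_cntl = expit(t)
    theta_exp = ratio * theta_cntl
    s = theta_exp + theta_cntl
    scale = np.where(s > 1.0, (1.0 - 1e-9) / s, 1.0)
    return theta_exp * scale, theta_cntl * scale


def _read_counts(config: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    if config.read_count_mode == "fixed":
        return np.full(n, config.read_count, dtype=np.int64)
    tpl = config.template
    if tpl is None or "read_count_mean" not in tpl.columns:
        raise ValueError("read_count_mode='template' requires template.read_count_mean")
    means = tpl["read_count_mean"].to_numpy(dtype=float)
    if config.min_template_reads:
        means = means[means >= config.min_template_reads]
    means = np.resize(means, n)
    return rng.poisson(means)


def simulate_reads(
    config: SimConfig,
    design: Sequence[SampleDesign] | None = None,
    seed: int | None = None,
) -> SimResult:
    """Simulate a full experiment: per-read tallies, grouped counts and truth.

    Reproducible: identical config + seed give identical output tables.
    """
    import warnings

    design = list(design) if design is not None else default_design()
    combos = {d.combination for d in design}
    if not {Combination.FORWARD, Combination.REVERSE} & combos:
        warnings.warn("design has neither forward nor reverse sample", stacklevel=2)
    elif Combination.FORWARD not in combos or Combination.REVERSE not in combos:
        warnings.warn(
            "design lacks one of forward/reverse: the fit is unbalanced", stacklevel=2
        )
    rng = np.random.default_rng(config.seed if seed is None else seed)
    ratios = config.resolve_ratios()
    n_tx = len(ratios)
    genes = np.array([f"g{i:05d}" for i in range(n_tx)])
    theta_exp, theta_cntl = draw_thetas(ratios, config.theta_logit_noise_sd, rng)

    p_rest = 1.0 - config.p_U - config.p_G
    frames = []
    truth_counts = {d.sample_id: np.zeros(n_tx, dtype=np.int64) for d in design}
    for d in design:
        counts = _read_counts(config, n_tx, rng)
        truth_counts[d.sample_id] = counts
        for i in range(n_tx):
            n = int(counts[i])
            if n == 0:
                continue
            if d.combination is Combination.UNLABELLED:
                n_exp = n_cntl = 0
            else:
                p_u = max(0.0, 1.0 - theta_exp[i] - theta_cntl[i])
                n_exp, n_cntl, _ = rng.multinomial(
                    n, [theta_exp[i], theta_cntl[i], p_u]
                )
            # pool membership -> which label the read carries
            if d.combination is Combination.FORWARD:
                s4u = np.r_[np.ones(n_exp, bool), np.zeros(n - n_exp, bool)]
                s6g = np.r_[np.zeros(n_exp, bool), np.ones(n_cntl, bool),
                            np.zeros(n - n_exp - n_cntl, bool)]
            elif d.combination is Combination.REVERSE:
                s6g = np.r_[np.ones(n_exp, bool), np.zeros(n - n_exp, bool)]
                s4u = np.r_[np.zeros(n_exp, bool), np.ones(n_cntl, bool),
                            np.zeros(n - n_exp - n_cntl, bool)]
            else:
                s4u = s6g = np.zeros(n, bool)
            comp = rng.multinomial(config.read_length, [config.p_U, config.p_G, p_rest], size=n)
            n_U, n_G = comp[:, 0], comp[:, 1]
            y_TC = rng.binomial(
                n_U, np.where(s4u, config.rate_TC_labelled, config.rate_TC_background)
            )
            y_GA = rng.binomial(
                n_G, np.where(s6g, config.rate_GA_labelled, config.rate_GA_background)
            )
            frames.append(
                pd.DataFrame(
                    {
                        "read_id": [f"{d.sample_id}|{genes[i]}|{j}" for j in range(n)],
                        "sample_id": d.sample_id,
                        "gene_id": genes[i],
                        "feature_class": "exonic",
                        "n_U": n_U,
                        "n_G": n_G,
                        "y_TC": y_TC,
                        "y_GA": y_GA,
                    }
                )
            )
    tallies = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["read_id", "sample_id", "gene_id", "feature_class",
                                   "n_U", "n_G", "y_TC", "y_GA"])
    )
    counts_table = aggregate_reads(tallies) if len(tallies) else tallies.iloc[:0]
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "true_ratio": ratios,
            "true_log2_ratio": np.log2(ratios),
            "theta_exp": theta_exp,
            "theta_cntl": theta_cntl,
        }
    )
    for d in design:
        truth[f"n_reads_{d.sample_id}"] = truth_counts[d.sample_id]
    return SimResult(tallies=tallies, counts=counts_table, truth=truth,
                     design=design, config=config)


def apply_regulation_mode(log2_ratios, mode: str) -> np.ndarray:
    """Recast a template's log-scale ratios as one of three regulation regimes.

    ``down``: unchanged (the template regime — global repression/depletion);
    ``up``: every log-scale ratio negated (global enrichment); ``symmetric``:
    the mean log-scale ratio subtracted, balancing up- and downregulation.
    """
    x = np.asarray(log2_ratios, dtype=float)
    if x.size == 0:
        raise ValueError("empty ratio template")
    if mode == "down":
        return x.copy()
    if mode == "up":
        return -x
    if mode == "symmetric":
        return x - x.mean()
    raise ValueError(f"unknown regulation mode {mode!r}")


def synthetic_template(n: int = 5000, seed: int = 0) -> pd.DataFrame:
    """Synthetic stand-in for a transcription-inhibition template dataset.

    Emulates the shape of a real experiment in which transcription is
    globally repressed: most transcripts strongly depleted (log2 ratios
    centred near -2.5) with a minority of stable transcripts near 0, and
    log-normal per-transcript read depths.  Entirely synthetic — generated
    from the seed, standing in for per-transcript estimates from real data.
    """
    rng = np.random.default_rng(seed)
    stable = rng.random(n) < 0.15
    log2_ratio = np.where(
        stable,
        rng.normal(0.0, 0.4, n),
        rng.normal(-2.5, 1.0, n),
    )
    read_count_mean = np.exp(rng.normal(np.log(250.0), 1.1, n))
    return pd.DataFrame({"log2_ratio": log2_ratio, "read_count_mean": read_count_mean})


def sweep(
    read_counts: Sequence[int] = (50, 200, 500),
    ratio_grid: Sequence[float] = (0.1, 1.0, 10.0),
    transcripts_per_ratio: int = 5,
    *,
    vary_rate: str | None = None,
    rate_values: Sequence[float] = (),
    config: SimConfig | None = None,
    seed: int = 0,
    fit_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Accuracy sweep over read depths (and optionally one label's mutation rate).

    Each cell simulates a grid experiment at one fixed read depth, fits the
    model, and compares posterior mean log2 ratios with truth, reporting
    bias, RMSE and 95% interval coverage.  With ``vary_rate`` = 'TC' or 'GA'
    the corresponding labelled per-base rate additionally sweeps over
    ``rate_values`` while the other label stays at its default.  Cell sizes
    default to desk scale; pass larger grids to reproduce full-scale sweeps.
    """
    from .model import fit_posterior

    base = config or SimConfig()
    fit_kwargs = dict(fit_kwargs or {})
    if vary_rate not in (None, "TC", "GA"):
        raise ValueError(f"vary_rate must be None, 'TC' or 'GA', got {vary_rate!r}")
    rate_cells = list(rate_values) if vary_rate else [None]
    rows = []
    for ci, (rc, rate) in enumerate(
        (rc, rate) for rc in read_counts for rate in rate_cells
    ):
        overrides = {}
        if rate is not None:
            overrides[f"rate_{vary_rate}_labelled"] = float(rate)
        cfg = replace(
            base,
            read_count_mode="fixed",
            read_count=int(rc),
            ratio_mode="grid",
            ratio_grid=tuple(ratio_grid),
            transcripts_per_ratio=transcripts_per_ratio,
            n_transcripts=None,
            **overrides,
        )
        sim = simulate_reads(cfg, seed=seed + ci)
        post = fit_posterior(sim.counts, sim.design, seed=seed + ci, **fit_kwargs)
        merged = post.genes.merge(sim.truth, on="gene_id")
        err = merged["log2_ratio_mean"] - merged["true_log2_ratio"]
        lo = merged["log2_ratio_mean"] - 1.96 * merged["log2_ratio_sd"]
        hi = merged["log2_ratio_mean"] + 1.96 * merged["log2_ratio_sd"]
        covered = (merged["true_log2_ratio"] >= lo) & (merged["true_log2_ratio"] <= hi)
        row = dict(
            read_count=int(rc),
            n_transcripts=len(merged),
            bias=float(err.mean()),
            rmse=float(np.sqrt((err**2).mean())),
            coverage_95=float(covered.mean()),
        )
        if rate is not None:
            row[f"rate_{vary_rate}_labelled"] = float(rate)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# SAM/FASTA/GTF fixture emission


def _window(n_U: int, n_G: int, read_length: int) -> str:
    rest = read_length - n_U - n_G
    return "T" * n_U + "G" * n_G + "A" * rest


def _read_seq(n_U: int, n_G: int, y_TC: int, y_GA: int, read_length: int) -> str:
    rest = read_length - n_U - n_G
    return (
        "C" * y_TC
        + "T" * (n_U - y_TC)
        + "A" * y_GA
        + "G" * (n_G - y_GA)
        + "A" * rest
    )


def _md_tag(ref: str, read: str) -> str:
    out, run = [], 0
    for r, q in zip(ref, read):
        if r == q:
            run += 1
        else:
            out.append(str(run))
            out.append(r)
            run = 0
    out.append(str(run))
    return "".join(out)


def emit_synthetic_sam(
    tallies: pd.DataFrame,
    out_dir: str | Path,
    read_length: int = 200,
    prefix: str = "sim",
) -> dict[str, Path]:
    """Materialise simulated tallies as SAM reads over a synthetic reference.

    Builds one synthetic contig per gene by concatenating a 200-base window
    per read (n_U leading T sites, n_G G sites, filler A); each read aligns
    full-length to its own window with its first y_TC T positions recoded to
    C and first y_GA G positions to A, so re-tallying the SAM against the
    FASTA recovers the input counts exactly.  Reads carry MD/NM tags, flag 99
    and MAPQ 60, so the standard alignment filters keep them.  Emits one SAM
    per sample plus the shared FASTA reference and a single-exon + strand GTF.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tallies = tallies.sort_values(["gene_id", "sample_id", "read_id"], kind="mergesort")
    if ((tallies["n_U"] + tallies["n_G"]) > read_length).any():
        raise ValueError("n_U + n_G exceeds the read length")

    offsets = tallies.groupby("gene_id", sort=True).cumcount() * read_length
    tallies = tallies.assign(offset=offsets)
    contigs: dict[str, list[str]] = {}
    for gene, sub in tallies.groupby("gene_id", sort=True):
        contigs[gene] = [
            _window(int(r.n_U), int(r.n_G), read_length) for r in sub.itertuples()
        ]
    fasta_path = out_dir / f"{prefix}_reference.fa"
    with open(fasta_path, "w") as fh:
        for gene, windows in contigs.items():
            fh.write(f">{gene}\n")
            seq = "".join(windows)
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")

    gtf_path = out_dir / f"{prefix}_genes.gtf"
    with open(gtf_path, "w") as fh:
        for gene, windows in contigs.items():
            length = len(windows) * read_length
            attrs = f'gene_id "{gene}";'
            fh.write(f"{gene}\tsim\tgene\t1\t{length}\t.\t+\t.\t{attrs}\n")
            fh.write(f"{gene}\tsim\texon\t1\t{length}\t.\t+\t.\t{attrs}\n")

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": gene, "LN": len(w) * read_length}
            for gene, w in contigs.items()
        ],
    }
    paths = {"fasta": fasta_path, "gtf": gtf_path}
    for sample, sub in tallies.groupby("sample_id", sort=True):
        sam_path = out_dir / f"{prefix}_{sample}.sam"
        with pysam.AlignmentFile(str(sam_path), "w", header=header) as sam:
            for r in sub.itertuples():
                ref = _window(int(r.n_U), int(r.n_G), read_length)
                seq = _read_seq(int(r.n_U), int(r.n_G), int(r.y_TC), int(r.y_GA), read_length)
                a = pysam.AlignedSegment(sam.header)
                a.query_name = str(r.read_id)
                a.query_sequence = seq
                a.flag = 99
                a.reference_id = sam.header.references.index(r.gene_id)
                a.reference_start = int(r.offset)
                a.mapping_quality = 60
                a.cigarstring = f"{read_length}M"
                a.next_reference_id = a.reference_id
                a.next_reference_start = a.reference_start
                a.template_length = read_length
                a.query_qualities = pysam.qualitystring_to_array("I" * read_length)
                a.set_tag("MD", _md_tag(ref, seq))
                a.set_tag("NM", int(r.y_TC + r.y_GA))
                sam.write(a)
        paths[f"sam:{sample}"] = sam_path
    return paths
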