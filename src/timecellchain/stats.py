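"""Scalar-variability statistics and the independent-interval null models.

The scalar property (Weber's law for timing) requires the SD of a timed
response to grow in proportion to its mean — a constant coefficient of
variation.  Summing k independent interval distributions cannot produce it:
the mean grows like k but the SD only like sqrt(k), so the CV of the
cumulative time falls as 1/sqrt(k).  The functions here measure what the
chain simulator actually produces (per-cell first-spike mean, SD, CV,
mean-normalized histograms and their superposition) and provide the
analytic/Monte-Carlo null models the mechanism has to beat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ScalarStats",
    "NormalizedHistogram",
    "scalar_stats",
    "normalized_histograms",
    "superposition_ks",
    "sum_of_normals_null",
    "increasing_isi_null",
]


@dataclass
class ScalarStats:
    """Per-cell-index spike-time summary across trials.

    ``per_cell`` has one row per cell index (1-based) with columns
    mean_ms, sd_ms, cv, n.  ``slope``/``intercept``/``r_squared`` describe
    the least-squares fit of SD on mean over the cells used for the fit.
    """

    per_cell: pd.DataFrame
    slope: float
    intercept: float
    r_squared: float
    n_trials: int
    n_excluded: int

    def cv(self, cell: int) -> float:
        return float(self.per_cell.loc[cell, "cv"])

    def cv_flatness(self, cell_lo: int, cell_hi: int) -> tuple[float, float]:
        """(max - min, median) of CV over the inclusive cell range."""
        sel = self.per_cell.loc[cell_lo:cell_hi, "cv"].dropna()
        return float(sel.max() - sel.min()), float(sel.median())

    def refit(self, cell_lo: int, cell_hi: int) -> tuple[float, float, float]:
        """Slope, intercept, R^2 of SD vs mean over a cell range."""
        sel = self.per_cell.loc[cell_lo:cell_hi].dropna(subset=["mean_ms", "sd_ms"])
        return _sd_mean_fit(sel["mean_ms"].values, sel["sd_ms"].values)


@dataclass
class NormalizedHistogram:
    """Mean-normalized spike-time distribution of one cell index."""

    cell: int
    edges: np.ndarray    # bin edges on the spike_time / mean axis
    masses: np.ndarray   # probability masses, sum to 1
    sample: np.ndarray   # the normalized sample itself


def _first_spike_matrix(records, up_to_cell=None):
    """Stack completed trials' first-spike vectors; also count exclusions."""
    if hasattr(records, "records"):  # TrialsResult
        recs = records.records
        up_to = up_to_cell or records.up_to_cell
    else:
        recs = list(records)
        up_to = up_to_cell or min(r.first_spike.size for r in recs)
    rows, excluded = [], 0
    for r in recs:
        fs = r.first_spike[:up_to]
        if getattr(r, "status", "completed") == "completed" and np.isfinite(fs).all():
            rows.append(fs)
        else:
            excluded += 1
    return np.array(rows), excluded


def _sd_mean_fit(mean, sd):
    if mean.size < 2:
        return np.nan, np.nan, np.nan
    fit = sps.linregress(mean, sd)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def scalar_stats(records, up_to_cell=None, fit_from_cell: int = 10) -> ScalarStats:
    """Mean, SD and CV of FIRST-spike times per cell index across trials.

    Trials flagged as stalled or truncated are excluded (their count is
    reported).  The SD-on-mean line is fit over cells >= ``fit_from_cell``
    (the first few cells are dominated by the stimulus onset transient).
    """
    mat, excluded = _first_spike_matrix(records, up_to_cell)
    if mat.size == 0 or mat.shape[0] < 2:
        raise ValueError("need >= 2 completed trials for spike-time statistics")
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    cv = np.divide(sd, mean, out=np.full_like(sd, np.nan), where=mean > 0)
    cells = np.arange(1, mat.shape[1] + 1)
    per_cell = pd.DataFrame(
        {"mean_ms": mean, "sd_ms": sd, "cv": cv, "n": mat.shape[0]}, index=cells
    )
    per_cell.index.name = "cell"
    lo = min(fit_from_cell, mat.shape[1])
    slope, intercept, r2 = _sd_mean_fit(mean[lo - 1:], sd[lo - 1:])
    return ScalarStats(
        per_cell=per_cell,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        n_trials=mat.shape[0] + excluded,
        n_excluded=excluded,
    )


def normalized_histograms(
    records, cells, n_bins: int = 20, bin_range=(0.0, 2.0)
) -> list[NormalizedHistogram]:
    """Histogram each cell's spike times divided by that cell's mean.

    All histograms share one grid on the normalized axis so they can be
    superposed; masses sum to 1.
    """
    mat, _ = _first_spike_matrix(records)
    edges = np.linspace(bin_range[0], bin_range[1], n_bins + 1)
    out = []
    for cell in cells:
        if not 1 <= cell <= mat.shape[1]:
            raise ValueError(f"cell {cell} not present in the records")
        sample = mat[:, cell - 1]
        if sample.size == 0:
            raise ValueError(f"empty spike-time sample for cell {cell}")
        norm = sample / sample.mean()
        counts, _ = np.histogram(norm, bins=edges)
        masses = counts / counts.sum()
        out.append(
            NormalizedHistogram(cell=cell, edges=edges, masses=masses, sample=norm)
        )
    return out


def superposition_ks(hists) -> pd.DataFrame:
    """Two-sample Kolmogorov–Smirnov distance between every pair of
    mean-normalized samples; a non-rejection (p above the chosen alpha)
    is the statistical reading of 'the distributions superpose'."""
    rows = []
    for i in range(len(hists)):
        for j in range(i + 1, len(hists)):
            ks = sps.ks_2samp(hists[i].sample, hists[j].sample)
            rows.append(
                {
                    "cell_a": hists[i].cell,
                    "cell_b": hists[j].cell,
                    "ks_stat": float(ks.statistic),
                    "p_value": float(ks.pvalue),
                }
            )
    return pd.DataFrame(rows)


def sum_of_normals_null(n_terms: int, mu_isi: float, sd_isi: float):
    """Mean, SD and CV of a sum of n independent Normal(mu, sd) intervals.

    The closed form (n*mu, sqrt(n)*sd, sd/(mu*sqrt(n))) is the square-root
    compression argument: CV shrinks as 1/sqrt(n), so independent identical
    intervals cannot give the scalar property.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    if sd_isi < 0:
        raise ValueError("sd_isi must be >= 0")
    mean = n_terms * mu_isi
    sd = np.sqrt(n_terms) * sd_isi
    return mean, sd, sd / mean if mean != 0 else np.nan


def increasing_isi_null(
    isi_means,
    cv_per_isi: float,
    n_draws: int = 10_000,
    rng=None,
):
    """Cumulative-time CV under independent scalar-noise intervals.

    Draws interval k from Normal(mu_k, cv*mu_k) independently and returns a
    DataFrame with the Monte-Carlo mean, SD and CV of the k-th cumulative
    time, plus the closed form cv*sqrt(sum mu^2)/sum mu.  Even though every
    single interval has the scalar property (SD proportional to its own
    mean), the cumulative CV still falls with k — lengthening intervals
    alone do not rescue Weber's law.
    """
    mu = np.asarray(isi_means, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("interval means must be positive")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    draws = rng.normal(mu, cv_per_isi * mu, size=(n_draws, mu.size))
    cum = draws.cumsum(axis=1)
    mean = cum.mean(axis=0)
    sd = cum.std(axis=0, ddof=1)
    closed = cv_per_isi * np.sqrt(np.cumsum(mu**2)) / np.cumsum(mu)
    return pd.DataFrame(
        {
            "k": np.arange(1, mu.size + 1),
            "mean": mean,
            "sd": sd,
            "cv": sd / mean,
            "cv_closed_form": closed,
        }
    )
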