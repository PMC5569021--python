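"""Relative qPCR quantification (ddCt) and growth-curve doubling time.

ddCt uses the arithmetic mean of three endogenous reference controls
(default GUSB, PPIA, 18S) as the per-sample normalizer — equivalent to a
geometric mean of their expression levels — with amplification efficiency
fixed at 2 and relative quantity RQ = 2^(-ddCt) against a calibrator
sample (default U-CH1). Doubling time is estimated on the exponential part
of a growth curve as DT = dt / dlog2(N), either from the window endpoints
(two_point) or from the reciprocal slope of a least-squares fit of
log2(count) on time (regression).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import linregress

DEFAULT_REFERENCE_GENES = ("GUSB", "PPIA", "18S")
DEFAULT_CALIBRATOR = "U-CH1"


def delta_delta_ct(
    ct: pd.DataFrame,
    reference_genes: tuple[str, ...] = DEFAULT_REFERENCE_GENES,
    calibrator: str = DEFAULT_CALIBRATOR,
) -> pd.DataFrame:
    """Relative expression of each target gene in each sample vs a calibrator.

    Parameters
    ----------
    ct : DataFrame
        Long format with columns (sample, gene, replicate, ct); replicate
        Ct values are averaged per (sample, gene) first.

    Returns
    -------
    DataFrame with one row per (sample, target gene) carrying delta_ct,
    delta_delta_ct and rq = 2^(-delta_delta_ct). The calibrator's rq is 1
    for every target by construction, and any per-sample additive Ct
    offset cancels in delta_ct.
    """
    required = {"sample", "gene", "replicate", "ct"}
    if not required <= set(ct.columns):
        raise ValueError(f"ct table needs columns {sorted(required)}")
    if (ct["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")

    mean_ct = ct.groupby(["sample", "gene"])["ct"].mean().unstack()
    if calibrator not in mean_ct.index:
        raise ValueError(f"calibrator sample {calibrator!r} not found")
    missing_refs = [g for g in reference_genes if g not in mean_ct.columns
                    or mean_ct[g].isna().any()]
    if missing_refs:
        raise ValueError(f"reference genes missing in some sample: {missing_refs}")

    ref_mean = mean_ct[list(reference_genes)].mean(axis=1)
    targets = [g for g in mean_ct.columns if g not in reference_genes]
    rows = []
    for gene in targets:
        d_ct = mean_ct[gene] - ref_mean
        dd_ct = d_ct - d_ct.loc[calibrator]
        for sample in mean_ct.index:
            rows.append({
                "sample": sample, "gene": gene,
                "delta_ct": d_ct.loc[sample],
                "delta_delta_ct": dd_ct.loc[sample],
                "rq": 2.0 ** (-dd_ct.loc[sample]),
            })
    return pd.DataFrame(rows)


class GrowthSeries:
    """Cell counts over time with an optional exponential-phase window."""

    def __init__(self, times_hr, counts, window: tuple[float, float] | None = None):
        self.times = np.asarray(times_hr, dtype=float)
        self.counts = np.asarray(counts, dtype=float)
        if len(self.times) != len(self.counts):
            raise ValueError("times and counts must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.counts <= 0):
            raise ValueError("counts must be positive")
        self.window = window

    def in_window(self) -> tuple[np.ndarray, np.ndarray]:
        if self.window is None:
            return self.times, self.counts
        lo, hi = self.window
        mask = (self.times >= lo) & (self.times <= hi)
        return self.times[mask], self.counts[mask]


def doubling_time(series: GrowthSeries, method: str = "regression") -> dict:
    """Estimate population doubling time in hours (and days).

    two_point uses the window endpoints: DT = (Tx - T0) / (log2 N(Tx) -
    log2 N(T0)). regression fits log2(count) on time by least squares and
    returns the reciprocal slope; both agree exactly on noiseless
    exponential growth. A non-positive growth slope raises.
    """
    if method not in ("regression", "two_point"):
        raise ValueError(f"unknown method {method!r}")
    t, n = series.in_window()
    if len(t) < 2:
        raise ValueError("need at least 2 points in the exponential window")
    log2n = np.log2(n)
    if method == "two_point":
        dlog = log2n[-1] - log2n[0]
        if dlog <= 0:
            raise ValueError("no exponential growth in window")
        dt_hr = (t[-1] - t[0]) / dlog
    else:
        fit = linregress(t, log2n)
        if fit.slope <= 0:
            raise ValueError("no exponential growth in window")
        dt_hr = 1.0 / fit.slope
    return {"dt_hours": float(dt_hr), "dt_days": float(dt_hr) / 24.0,
            "method": method, "n_points": int(len(t))}
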