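"""Paired nonparametric tests and the habituation check.

Concession pairs are the experimental blocks, so site-level summaries
(hunting signs, site covariates) are compared with two-sided Wilcoxon
signed-rank tests on the seven pair differences.  With so few pairs the
exact null distribution matters: p-values are computed by full enumeration
of sign assignments (via an equivalent rank-sum convolution) whenever the
number of non-zero differences is small, with zero differences dropped
(Wilcoxon's convention) and ties mid-ranked.

The habituation check asks whether detection rates trend upward over a
deployment — as trap-shy animals would produce — differentially between
certified and non-certified concessions, by regressing log-transformed
daily observation counts on deployment day, certification status and their
interaction over the first weeks common to all deployments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.formula.api as smf

__all__ = [
    "WilcoxonResult",
    "HabituationResult",
    "wilcoxon_signed_rank",
    "paired_proportions",
    "hunting_sign_pairs",
    "daily_observation_counts",
    "habituation_test",
]

DEFAULT_HABITUATION_WINDOW = 68  # days; shortest deployment in the target design


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W, sum of ranks of positive differences
    p_value: float
    n_used: int
    n_zero: int
    method: str  # "exact" or "normal"


@dataclass(frozen=True)
class HabituationResult:
    estimate: float  # day x certification interaction on the log scale
    se: float
    t: float
    p_value: float
    n_obs: int
    window_days: int


def wilcoxon_signed_rank(x, y=None, exact_threshold: int = 25) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test.

    ``x`` may be paired differences, or ``x, y`` two paired samples.  Zero
    differences are dropped; absolute differences are mid-ranked; W is the
    rank sum over positive differences.  For ``n <= exact_threshold``
    non-zero differences the p-value is exact over all 2^n sign
    assignments (computed by convolution over the — possibly tied — rank
    multiset, which enumerates the same distribution); beyond that a
    normal approximation with tie-corrected variance and continuity
    correction is used.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    if d.size == 0:
        raise ValueError("no paired differences")
    if not np.all(np.isfinite(d)):
        raise ValueError("differences must be finite")

    nz = d[d != 0]
    n_zero = int(d.size - nz.size)
    n = nz.size
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return WilcoxonResult(0.0, 1.0, 0, n_zero, "degenerate")

    ranks = st.rankdata(np.abs(nz))
    w = float(ranks[nz > 0].sum())
    total = n * (n + 1) / 2.0

    if n <= exact_threshold:
        # distribution of W over all 2^n sign flips; scale mid-ranks (k/2)
        # to integers so the convolution is exact
        scaled = np.round(ranks * 2).astype(int)
        dist = np.zeros(scaled.sum() + 1)
        dist[0] = 1.0
        for r in scaled:
            shifted = np.zeros_like(dist)
            shifted[r:] = dist[: dist.size - r]
            dist = dist + shifted
        dist /= 2.0**n
        ws = int(round(w * 2))
        p_ge = dist[ws:].sum()
        p_le = dist[: ws + 1].sum()
        p = min(1.0, 2.0 * min(p_ge, p_le))
        return WilcoxonResult(w, float(p), n, n_zero, "exact")

    mean = total / 2.0
    _, counts = np.unique(np.abs(nz), return_counts=True)
    tie_term = (counts**3 - counts).sum() / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    diff = w - mean
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
    p = min(1.0, 2.0 * st.norm.sf(abs(z)))
    return WilcoxonResult(w, float(p), n, n_zero, "normal")


def paired_proportions(
    deployments: pd.DataFrame, flag: pd.Series, name: str = "proportion"
) -> pd.DataFrame:
    """Per-pair proportions of cameras with ``flag`` true, by status.

    Returns one row per pair with columns ``certified`` and ``noncert`` —
    the shape consumed by :func:`wilcoxon_signed_rank`.
    """
    df = deployments[["pair_id", "certified"]].copy()
    df[name] = np.asarray(flag, dtype=bool)
    agg = df.groupby(["pair_id", "certified"])[name].mean().unstack("certified")
    out = pd.DataFrame(
        {"pair_id": agg.index, "certified": agg[True], "noncert": agg[False]}
    ).reset_index(drop=True)
    return out


def hunting_sign_pairs(deployments: pd.DataFrame) -> pd.DataFrame:
    """Proportion of camera locations with at least one hunting sign, per pair."""
    return paired_proportions(
        deployments, deployments["hunting_signs"] >= 1, name="hunting_signs"
    )


def daily_observation_counts(events: pd.DataFrame, deployments: pd.DataFrame) -> pd.DataFrame:
    """Observations per concession-day, aligned to deployment day 1.

    Days with no events are kept as zero counts up to each concession's
    deployment span, so downward or upward trends are not censored.
    """
    dep = deployments.set_index("camera_id")
    ev = events.copy()
    ev["concession_id"] = ev["camera_id"].map(dep["concession_id"])
    ev["day"] = (
        (ev["start_time"] - ev["camera_id"].map(dep["start"])).dt.total_seconds() / 86400.0
    ).astype(int) + 1

    span = (
        deployments.assign(
            span=((deployments["end"] - deployments["start"]).dt.total_seconds() // 86400).astype(int)
        )
        .groupby(["concession_id", "certified"], as_index=False)["span"]
        .max()
    )
    counts = ev.groupby(["concession_id", "day"]).size().rename("n_obs")
    frames = []
    for _, row in span.iterrows():
        days = np.arange(1, row["span"] + 1)
        idx = pd.MultiIndex.from_product([[row["concession_id"]], days])
        n = counts.reindex(idx, fill_value=0).to_numpy()
        frames.append(
            pd.DataFrame(
                {
                    "concession_id": row["concession_id"],
                    "certified": row["certified"],
                    "day": days,
                    "n_obs": n,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def habituation_test(
    daily_counts: pd.DataFrame, window_days: int = DEFAULT_HABITUATION_WINDOW
) -> HabituationResult:
    """Trap-shyness check: does the detection trend differ by status?

    Fits ``log(n_obs + 1) ~ day * certified + concession`` by OLS on the
    first ``window_days`` of each deployment (the window is truncated to
    the shortest deployment with a warning) and reports the
    day-by-certification interaction.  A positive, significant interaction
    would mean detections rise faster over time where hunting pressure is
    lower — the habituation signature the analysis must rule out.
    """
    for col in ("concession_id", "certified", "day", "n_obs"):
        if col not in daily_counts.columns:
            raise ValueError(f"daily_counts is missing column {col!r}")
    shortest = int(daily_counts.groupby("concession_id")["day"].max().min())
    if window_days > shortest:
        warnings.warn(
            f"window of {window_days} d exceeds the shortest deployment; truncating to {shortest} d",
            stacklevel=2,
        )
        window_days = shortest
    df = daily_counts[daily_counts["day"] <= window_days].copy()
    for status in (True, False):
        if df.loc[df["certified"] == status, "concession_id"].nunique() < 2:
            raise ValueError("need at least 2 concessions per certification status")
    df["logn"] = np.log1p(df["n_obs"].astype(float))
    df["cert"] = df["certified"].astype(int)
    # the certification main effect is absorbed by the concession intercepts
    # (status is constant within a concession), so only its slope enters
    res = smf.ols("logn ~ day + day:cert + C(concession_id)", df).fit()
    name = "day:cert"
    return HabituationResult(
        estimate=float(res.params[name]),
        se=float(res.bse[name]),
        t=float(res.tvalues[name]),
        p_value=float(res.pvalues[name]),
        n_obs=int(res.nobs),
        window_days=window_days,
    )
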