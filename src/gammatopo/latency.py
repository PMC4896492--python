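"""Selectivity onset-latency detection from BGA time series.

Onset is the first post-stimulus time point at which one category's
percent-change BGA differs from the pooled other categories (two-tailed
two-sample t-test per time point, FDR-corrected across time points at
alpha = 0.05) and stays significant over a run of consecutive samples
spanning more than 100 ms. Trials have unequal counts across categories,
so the contrast is an unpaired Welch test by default (a pooled-variance
Student option is provided).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from gammatopo.bga import BGASeries
from gammatopo.selectivity import fdr_correct

__all__ = ["LatencyResult", "pointwise_contrast", "onset_latency",
           "latency_summary"]

#: run of corrected-significant samples must span strictly more than this
PERSISTENCE_S = 0.100
#: corrected pointwise significance level
ALPHA = 0.05
#: time window over which the pointwise tests (and their FDR family) run
SEARCH_WINDOW_S = (0.0, 0.700)


@dataclass
class LatencyResult:
    electrode_id: str
    category: str
    onset_latency_s: float | None
    p_trace: np.ndarray          # corrected-family p-values over search window
    time_axis: np.ndarray        # matching times (s)
    alpha: float = ALPHA
    persistence_s: float = PERSISTENCE_S

    @property
    def onset_latency_ms(self) -> float | None:
        return None if self.onset_latency_s is None else 1e3 * self.onset_latency_s


def pointwise_contrast(bga: BGASeries, target: str,
                       equal_var: bool = False) -> np.ndarray:
    """Per-time-point p-values, target trials vs pooled other-category trials.

    Two-tailed two-sample t-test at every sample (Welch by default). Time
    points where both groups have zero variance are assigned p = 1.
    """
    labels = np.asarray(bga.categories)[bga.retained]
    x = bga.percent_change[bga.retained]
    tgt = x[labels == target]
    oth = x[labels != target]
    if tgt.shape[0] < 2 or oth.shape[0] < 2:
        raise ValueError("need >= 2 trials in target and pooled-other groups")
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(tgt, oth, axis=0, equal_var=equal_var)
        p = np.asarray(res.pvalue, float)
    degenerate = (tgt.var(axis=0) == 0) & (oth.var(axis=0) == 0)
    p[degenerate | ~np.isfinite(p)] = 1.0
    return p


def onset_latency(bga: BGASeries, target: str, alpha: float = ALPHA,
                  persistence_s: float = PERSISTENCE_S,
                  search_window_s: tuple[float, float] = SEARCH_WINDOW_S,
                  equal_var: bool = False) -> LatencyResult:
    """Earliest sustained FDR-corrected significant contrast for one category.

    BH correction is applied across all time points inside the search
    window; the onset is the start of the first run of corrected-significant
    samples whose duration strictly exceeds ``persistence_s``; ``None`` if
    no such run exists.
    """
    t = bga.time_axis
    lo, hi = search_window_s
    mask = (t >= lo) & (t <= hi)
    tw = t[mask]
    dt = 1.0 / bga.sampling_rate_hz
    need = int(np.floor(persistence_s / dt)) + 1   # samples spanning > persistence
    if need > tw.size:
        raise ValueError("persistence requirement longer than p-trace")
    p = pointwise_contrast(bga, target, equal_var=equal_var)[mask]
    flags, _ = fdr_correct(p, q=alpha)

    onset = None
    run = 0
    for i, sig in enumerate(flags):
        run = run + 1 if sig else 0
        if run * dt > persistence_s:
            onset = tw[i - run + 1]
            break
    return LatencyResult(electrode_id=bga.electrode_id, category=target,
                         onset_latency_s=None if onset is None else float(onset),
                         p_trace=p, time_axis=tw, alpha=alpha,
                         persistence_s=persistence_s)


def latency_summary(onsets: pd.DataFrame, q: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summaries and pairwise category comparisons of detected onsets.

    Parameters
    ----------
    onsets : DataFrame with columns region, hemisphere, category, onset_ms
        (one row per electrode with a detected onset).
    q : FDR level for the pairwise rank tests.

    Returns
    -------
    (summary, pairwise): per region x hemisphere x category median/SD/count,
    and Wilcoxon rank-sum tests (asymptotic; onsets come from distinct
    electrodes, so pairing is not available) between categories within each
    region x hemisphere, BH-corrected together. Cells with no onsets are
    simply absent from the output.
    """
    onsets = onsets.dropna(subset=["onset_ms"])
    rows = []
    for (reg, hemi, cat), grp in onsets.groupby(["region", "hemisphere", "category"]):
        v = grp["onset_ms"].to_numpy(float)
        rows.append({"region": reg, "hemisphere": hemi, "category": cat,
                     "n": v.size, "median_ms": float(np.median(v)),
                     "sd_ms": float(v.std(ddof=1)) if v.size > 1 else 0.0})
    summary = pd.DataFrame(rows)

    pair_rows = []
    for (reg, hemi), grp in onsets.groupby(["region", "hemisphere"]):
        cats = sorted(grp["category"].unique())
        for a, b in combinations(cats, 2):
            va = grp.loc[grp["category"] == a, "onset_ms"].to_numpy(float)
            vb = grp.loc[grp["category"] == b, "onset_ms"].to_numpy(float)
            if va.size == 0 or vb.size == 0:
                continue
            stat = stats.ranksums(va, vb, alternative="two-sided")
            pair_rows.append({"region": reg, "hemisphere": hemi,
                              "category_a": a, "category_b": b,
                              "n_a": va.size, "n_b": vb.size,
                              "p": float(stat.pvalue)})
    pairwise = pd.DataFrame(pair_rows)
    if len(pairwise):
        flags, _ = fdr_correct(pairwise["p"].to_numpy(), q=q)
        pairwise["significant"] = flags
    return summary, pairwise
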