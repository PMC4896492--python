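"""Category-selectivity statistics: multi-category d', permutation null, FDR.

For each electrode the response to each of the five stimulus categories is
summarized as the per-trial window-mean BGA. The d' sensitivity index for
target category j against the N other categories is

    d' = (u_j - mean_i(u_i)) / sqrt( 0.5 * (o_j^2 + mean_i(o_i^2)) ),  i != j

with u the per-category trial means and o the across-trial sample SDs
(ddof=1). Significance comes from a label-permutation null (category labels
shuffled jointly across all trials, preserving per-category counts) and the
one-sided strictly-greater exceedance fraction; group-level control uses
Benjamini-Hochberg FDR within region x hemisphere families, pooling
categories and electrodes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "dprime", "dprime_all", "permutation_null", "permutation_pvalue",
    "fdr_correct", "selectivity_table",
]


def dprime(means: np.ndarray, sds: np.ndarray, target: int) -> float:
    """d' for one target category given per-category means and SDs.

    Parameters
    ----------
    means, sds : ndarray, shape (n_categories,)
        Per-category trial means and across-trial sample SDs of the scalar
        response.
    target : int
        Index j of the target category.
    """
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)
    k = means.size
    if k < 2:
        raise ValueError("d' requires at least 2 categories")
    if not (np.all(np.isfinite(means)) and np.all(np.isfinite(sds))):
        raise ValueError("non-finite category summaries")
    others = np.arange(k) != target
    pooled = 0.5 * (sds[target] ** 2 + np.mean(sds[others] ** 2))
    if pooled <= 0:
        raise ValueError("zero pooled variance: d' undefined")
    return float((means[target] - np.mean(means[others])) / np.sqrt(pooled))


def _category_summaries(values: np.ndarray, labels: np.ndarray,
                        categories: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    means = np.empty(categories.size)
    sds = np.empty(categories.size)
    ns = np.empty(categories.size, dtype=int)
    for c, cat in enumerate(categories):
        v = values[labels == cat]
        ns[c] = v.size
        if v.size < 2:
            raise ValueError(f"category {cat!r} has fewer than 2 trials")
        means[c] = v.mean()
        sds[c] = v.std(ddof=1)
    return means, sds, ns


def dprime_all(values: np.ndarray, labels: np.ndarray,
               categories: np.ndarray | None = None) -> np.ndarray:
    """All per-category d' values for one electrode's per-trial scalars."""
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    if categories is None:
        categories = np.unique(labels)
    else:
        categories = np.asarray(categories)
    means, sds, _ = _category_summaries(values, labels, categories)
    return np.array([dprime(means, sds, j) for j in range(categories.size)])


def permutation_null(values: np.ndarray, labels: np.ndarray,
                     n_perm: int = 10_000,
                     seed: int | np.random.Generator = 0,
                     categories: np.ndarray | None = None) -> np.ndarray:
    """Null d' distribution from joint label shuffles.

    Each permutation shuffles category labels across all trials (which
    preserves per-category trial counts) and recomputes every category's
    d'. Returns an (n_perm, n_categories) matrix.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    if categories is None:
        categories = np.unique(labels)
    else:
        categories = np.asarray(categories)
    n = values.size
    if n < 2 * categories.size:
        raise ValueError("need at least 2 trials per category overall")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # Shuffling labels with fixed values is equivalent to shuffling values
    # with fixed label blocks; the latter vectorizes across permutations.
    order = np.argsort(labels, kind="stable")
    sorted_labels = labels[order]
    boundaries = np.flatnonzero(np.r_[True, sorted_labels[1:] != sorted_labels[:-1], True])
    block_cats = sorted_labels[boundaries[:-1]]

    keys = rng.random((n_perm, n))
    idx = np.argsort(keys, axis=1)
    perm_vals = values[idx]                      # (n_perm, n)

    k = categories.size
    means = np.empty((n_perm, k))
    var = np.empty((n_perm, k))
    for cat, lo, hi in zip(block_cats, boundaries[:-1], boundaries[1:]):
        c = int(np.flatnonzero(categories == cat)[0])
        block = perm_vals[:, lo:hi]
        means[:, c] = block.mean(axis=1)
        var[:, c] = block.var(axis=1, ddof=1)

    null = np.empty((n_perm, k))
    for j in range(k):
        others = np.arange(k) != j
        pooled = 0.5 * (var[:, j] + var[:, others].mean(axis=1))
        null[:, j] = (means[:, j] - means[:, others].mean(axis=1)) / np.sqrt(pooled)
    return null


def permutation_pvalue(observed: float | np.ndarray, null: np.ndarray,
                       conservative: bool = False) -> float | np.ndarray:
    """One-sided permutation p: fraction of null draws strictly greater.

    Ties count as not-greater; p = 0 is permitted. ``conservative`` applies
    the (+1)/(n+1) small-sample correction instead.
    """
    null = np.asarray(null, float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    observed = np.asarray(observed, float)
    if not (np.all(np.isfinite(observed)) and np.all(np.isfinite(null))):
        raise ValueError("non-finite inputs to permutation p-value")
    n_perm = null.shape[0]
    greater = (null > observed).sum(axis=0)
    if conservative:
        p = np.asarray((greater + 1) / (n_perm + 1))
    else:
        p = np.asarray(greater / n_perm)
    if observed.ndim == 0 and p.size == 1:
        return float(p.reshape(()))
    return p


def fdr_correct(pvalues: pd.Series | np.ndarray,
                families: pd.Series | np.ndarray | None = None,
                q: float = 0.01) -> tuple[np.ndarray, dict]:
    """Benjamini-Hochberg step-up within each correction family.

    Parameters
    ----------
    pvalues : array-like of float in [0, 1]
    families : array-like of hashable, optional
        Family label per p-value (e.g. region x hemisphere tuples); all
        p-values within a family are corrected together, pooling categories
        and electrodes. ``None`` treats everything as one family.
    q : float
        Controlled false-discovery rate.

    Returns
    -------
    flags : ndarray of bool
    cutoffs : dict mapping family -> largest rejected p (NaN if none rejected)
    """
    p = np.asarray(pvalues, float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if families is None:
        families = np.zeros(p.size, dtype=int)
    fam = np.asarray(families, dtype=object)
    codes, uniques = pd.factorize(fam)
    flags = np.zeros(p.size, dtype=bool)
    cutoffs: dict = {}
    for ci, f in enumerate(uniques):
        m = codes == ci
        rej = multipletests(p[m], alpha=q, method="fdr_bh")[0]
        flags[m] = rej
        cutoffs[f] = float(p[m][rej].max()) if rej.any() else float("nan")
    return flags, cutoffs


def selectivity_table(trial_values: dict[str, tuple[np.ndarray, np.ndarray]],
                      geometry: pd.DataFrame,
                      categories: np.ndarray | list[str],
                      n_perm: int = 10_000, q: float = 0.01,
                      seed: int = 0,
                      conservative: bool = False) -> pd.DataFrame:
    """Full per-electrode x per-category d' table with grouped FDR.

    Parameters
    ----------
    trial_values : dict electrode_id -> (values, labels)
        Per-trial scalar BGA (retained trials only) with category labels.
    geometry : DataFrame indexed by electrode id with columns
        subject, hemisphere, region, x, y, z.
    categories : full ordered category list; electrodes missing a category
        are recorded with NaN for it and excluded from that family entry.
    n_perm, q, seed : permutation and FDR parameters.

    Returns
    -------
    DataFrame with one row per electrode x category: d_prime, p_perm,
    fdr_flag, fdr_cutoff plus the geometry columns.
    """
    categories = np.asarray(categories)
    rows = []
    root = np.random.default_rng(seed)
    for eid, (values, labels) in trial_values.items():
        geo = geometry.loc[eid]
        present = np.array([c for c in categories if (np.asarray(labels) == c).sum() >= 2])
        missing = [c for c in categories if c not in present]
        if missing:
            log.warning("electrode %s missing categories %s; excluded from "
                        "their families", eid, missing)
        d = dprime_all(values, labels, present)
        null = permutation_null(values, labels, n_perm=n_perm,
                                seed=np.random.default_rng(root.integers(2**31)),
                                categories=present)
        p = permutation_pvalue(d, null, conservative=conservative)
        lookup = {c: (d[i], p[i]) for i, c in enumerate(present)}
        for cat in categories:
            dv, pv = lookup.get(cat, (np.nan, np.nan))
            rows.append({
                "electrode": eid, "subject": geo["subject"],
                "hemisphere": geo["hemisphere"], "region": geo["region"],
                "x": geo["x"], "y": geo["y"], "z": geo["z"],
                "category": cat, "d_prime": dv, "p_perm": pv,
            })
    table = pd.DataFrame(rows)
    table["fdr_flag"] = False
    table["fdr_cutoff"] = np.nan
    valid = table["p_perm"].notna()
    fams = list(zip(table.loc[valid, "region"], table.loc[valid, "hemisphere"]))
    flags, cutoffs = fdr_correct(table.loc[valid, "p_perm"].to_numpy(),
                                 pd.Series(fams, dtype=object).to_numpy(), q=q)
    table.loc[valid, "fdr_flag"] = flags
    table.loc[valid, "fdr_cutoff"] = [cutoffs[f] for f in fams]
    table.attrs["n_perm"] = n_perm
    table.attrs["q"] = q
    return table
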