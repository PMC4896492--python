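"""Reader for the deposited electrode-level supplementary matrices.

The deposited archives are MAT-files, one per cohort file, holding for each
region/hemisphere cohort: per-category BGA mean and SD matrices, per-category
d' matrices, an electrode-coordinate matrix (group/Talairach space), and a
per-subject cell of 10,000 label-shuffled d' indices per electrode. Exact
variable names are only documented for the left-VTC file
(``Pt_Coords_LH_VTC``, ``pt_dprime_final_shuf_LH_VTC``, ``Categories``), so
variables are discovered by name pattern rather than assumed, and electrode
counts are cross-checked across variables and against the published
per-subject electrode tallies. Both MAT v5 and v7.3 (HDF5) containers are
supported.

``reproduce_selectivity`` recomputes permutation p-values from the stored
shuffles and re-applies grouped BH control; ``reproduce_topology`` refits
the coordinate mixed models from the stored d' and coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from gammatopo.selectivity import fdr_correct
from gammatopo.topology import REGION_AXES, center_coordinates, fit_lme

__all__ = ["SupplementaryCohort", "read_supplementary",
           "reproduce_selectivity", "reproduce_topology",
           "TABLE1_SDE_COUNTS"]

#: published per-subject electrode tallies (cohort -> list per subject)
TABLE1_SDE_COUNTS = {
    ("VTC", "L"): [10, 3, 1, 1, 9, 4, 4, 9, 8, 3, 3, 5, 5, 8, 13, 8],
    ("VTC", "R"): [3, 4, 5, 8, 4, 4, 4, 22, 5, 5],
    ("LOC", "L"): [1, 1, 4, 1, 3, 0, 0, 7, 3, 0, 0, 0, 0, 12, 9, 7],
    ("LOC", "R"): [0, 10, 0, 2, 0, 0, 0, 13, 7, 3],
}

CATEGORY_ORDER = ("face", "animate", "place", "tool", "word")


@dataclass
class SupplementaryCohort:
    """One region x hemisphere cohort extracted from a MAT-file."""

    region: str
    hemisphere: str
    coords: np.ndarray              # (n_electrodes, 3) x/y/z
    dprime: np.ndarray              # (n_electrodes, n_categories)
    bga_mean: np.ndarray | None     # (n_electrodes, n_categories)
    bga_sd: np.ndarray | None
    shuffles: list[np.ndarray]      # per subject: (n_e, n_cat, n_perm) or (n_e, n_perm)
    subjects: np.ndarray            # subject index per electrode
    categories: tuple[str, ...] = CATEGORY_ORDER

    @property
    def n_electrodes(self) -> int:
        return self.coords.shape[0]

    def geometry(self) -> pd.DataFrame:
        eids = [f"{self.hemisphere}{self.region}-{i:03d}"
                for i in range(self.n_electrodes)]
        return pd.DataFrame({
            "subject": [f"S{self.hemisphere}{s:02d}" for s in self.subjects],
            "hemisphere": self.hemisphere, "region": self.region,
            "x": self.coords[:, 0], "y": self.coords[:, 1],
            "z": self.coords[:, 2]}, index=pd.Index(eids, name="electrode"))


def _load_mat(path: str) -> dict:
    """Load a MAT-file (v5 via scipy, v7.3 via h5py) into plain arrays."""
    from scipy import io as sio
    try:
        # no squeeze: keeps (1, k, n) cell entries unambiguous
        raw = sio.loadmat(path, squeeze_me=False)
        return {k: v for k, v in raw.items() if not k.startswith("__")}
    except NotImplementedError:
        pass  # v7.3: HDF5 container
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read MAT-file {path!r}: {exc}") from exc
    import h5py

    def deref(obj, f):
        if isinstance(obj, h5py.Dataset):
            data = obj[()]
            if data.dtype == object or data.dtype.kind == "O":
                return np.array([deref(f[r], f) for r in data.ravel()],
                                dtype=object).reshape(data.shape)
            if data.dtype.kind == "u" and obj.attrs.get("MATLAB_class") == b"char":
                return "".join(chr(c) for c in data.ravel())
            return np.asarray(data).T   # MATLAB column-major
        return obj

    out = {}
    with h5py.File(path, "r") as f:
        for k in f:
            if k.startswith("#"):
                continue
            out[k] = deref(f[k], f)
    return out


_COHORT_RE = re.compile(r"([LR])H?_?(VTC|LOC)", re.IGNORECASE)


def _cohort_key(name: str) -> tuple[str, str] | None:
    m = _COHORT_RE.search(name)
    if not m:
        return None
    return m.group(2).upper(), m.group(1).upper()


def _orient(mat: np.ndarray, n_electrodes: int) -> np.ndarray:
    """Return matrix as (n_electrodes, k), transposing if needed."""
    mat = np.atleast_2d(np.asarray(mat, float))
    if mat.shape[0] == n_electrodes:
        return mat
    if mat.shape[1] == n_electrodes:
        return mat.T
    raise ValueError(f"matrix shape {mat.shape} inconsistent with "
                     f"{n_electrodes} electrodes")


def _orient_shuffle(arr: np.ndarray, n_cat: int) -> np.ndarray:
    """Orient one subject's shuffle block to (n_e, [n_cat,] n_perm).

    The permutation axis is taken as the largest axis (10,000 dominates any
    electrode or category count); a leading category axis is moved to the
    middle. A 2-D block of shape (n_cat, n_perm) is a single electrode's
    per-category null.
    """
    arr = np.asarray(arr, float)
    if arr.ndim == 1:
        return arr[None, :]
    perm_axis = int(np.argmax(arr.shape))   # the 10,000 axis is the largest
    arr = np.moveaxis(arr, perm_axis, -1)
    if arr.ndim == 2 and arr.shape[0] == n_cat:
        arr = arr[None, :, :]
    elif arr.ndim == 3 and arr.shape[0] == n_cat and arr.shape[1] != n_cat:
        arr = np.moveaxis(arr, 0, 1)
    return arr


def read_supplementary(path: str) -> dict[tuple[str, str], SupplementaryCohort]:
    """Read one deposited MAT-file into its region x hemisphere cohorts.

    Variables are grouped by the ``{L,R}H_{VTC,LOC}`` tag in their names and
    classified by pattern: coordinates (``coord``), shuffled d' cells
    (``shuf``), observed d' (``dprime`` without ``shuf``), BGA mean/SD
    (``mean``/``std``). Electrode counts must agree across variables;
    subject attribution comes from the shuffle cell lengths and is
    cross-checked against the published per-subject tallies.
    """
    variables = _load_mat(str(path))
    groups: dict[tuple[str, str], dict[str, object]] = {}
    categories = None
    for name, value in variables.items():
        low = name.lower()
        if "categor" in low:
            cats = []
            for c in np.ravel(np.asarray(value, dtype=object)):
                c = np.ravel(c)
                if c.size:
                    cats.append(str(c[0]).strip().lower())
            if cats:
                categories = tuple(cats)
            continue
        key = _cohort_key(name)
        if key is None:
            continue
        slot = groups.setdefault(key, {})
        if "coord" in low:
            slot["coords"] = value
        elif "shuf" in low:
            slot["shuffles"] = value
        elif "dprime" in low or "d_prime" in low:
            slot["dprime"] = value
        elif "mean" in low:
            slot["bga_mean"] = value
        elif "std" in low or re.search(r"\bsd\b|_sd", low):
            slot["bga_sd"] = value

    if not groups:
        raise ValueError(f"no cohort-tagged variables found in {path!r}")
    cats = categories or CATEGORY_ORDER
    out = {}
    for (region, hemi), slot in sorted(groups.items()):
        missing = [k for k in ("coords", "dprime", "shuffles") if k not in slot]
        if missing:
            raise ValueError(f"cohort {region}/{hemi} in {path!r} is missing "
                             f"variables: {missing}")
        coords = np.atleast_2d(np.asarray(slot["coords"], float))
        if coords.shape[1] != 3:
            if coords.shape[0] == 3:
                coords = coords.T
            else:
                raise ValueError(f"coordinate matrix for {region}/{hemi} has "
                                 f"shape {coords.shape}, expected (n, 3)")
        n_e = coords.shape[0]
        dprime = _orient(slot["dprime"], n_e)
        cell = [np.asarray(c, float) for c in np.ravel(slot["shuffles"])
                if np.asarray(c).size]
        shuffles = [_orient_shuffle(c, len(cats)) for c in cell]
        cell_counts = [s.shape[0] for s in shuffles]
        if sum(cell_counts) != n_e:
            raise ValueError(
                f"cohort {region}/{hemi}: shuffle cells account for "
                f"{sum(cell_counts)} electrodes but coordinates list {n_e}")
        expected = [c for c in TABLE1_SDE_COUNTS.get((region, hemi), []) if c > 0]
        if expected and cell_counts != expected:
            raise ValueError(
                f"cohort {region}/{hemi}: per-subject electrode counts "
                f"{cell_counts} do not match the published tallies {expected}")
        subjects = np.concatenate([
            np.full(c, i, dtype=int) for i, c in enumerate(cell_counts)])
        bga_mean = slot.get("bga_mean")
        bga_sd = slot.get("bga_sd")
        out[(region, hemi)] = SupplementaryCohort(
            region=region, hemisphere=hemi, coords=coords, dprime=dprime,
            bga_mean=None if bga_mean is None else _orient(bga_mean, n_e),
            bga_sd=None if bga_sd is None else _orient(bga_sd, n_e),
            shuffles=shuffles, subjects=subjects, categories=cats)
    return out


def _cohort_pvalues(cohort: SupplementaryCohort) -> np.ndarray:
    """Permutation p per electrode x category from the stored shuffles."""
    n_cat = cohort.dprime.shape[1]
    p = np.full((cohort.n_electrodes, n_cat), np.nan)
    row = 0
    for block in cohort.shuffles:
        for e in range(block.shape[0]):
            for c in range(n_cat):
                obs = cohort.dprime[row, c]
                if not np.isfinite(obs):
                    continue
                null = block[e, c] if block.ndim == 3 else block[e]
                null = null[np.isfinite(null)]
                p[row, c] = np.mean(null > obs)
            row += 1
    return p


def reproduce_selectivity(cohorts: dict[tuple[str, str], SupplementaryCohort],
                          q: float = 0.01) -> tuple[pd.DataFrame, dict]:
    """Recompute p-values from stored shuffles and re-apply grouped FDR.

    Returns the long-format table (one row per electrode x category) and a
    summary dict with the per-cohort and overall significant-electrode
    counts, the dual-selectivity count, and the left-VTC word-selective
    count.
    """
    frames = []
    for (region, hemi), cohort in cohorts.items():
        p = _cohort_pvalues(cohort)
        geo = cohort.geometry()
        for ci, cat in enumerate(cohort.categories):
            frames.append(pd.DataFrame({
                "electrode": geo.index, "subject": geo["subject"].to_numpy(),
                "region": region, "hemisphere": hemi, "category": cat,
                "d_prime": cohort.dprime[:, ci], "p_perm": p[:, ci],
                "x": cohort.coords[:, 0], "y": cohort.coords[:, 1],
                "z": cohort.coords[:, 2]}))
    table = pd.concat(frames, ignore_index=True)
    table["fdr_flag"] = False
    valid = table["p_perm"].notna()
    fams = list(zip(table.loc[valid, "region"], table.loc[valid, "hemisphere"]))
    flags, _ = fdr_correct(table.loc[valid, "p_perm"].to_numpy(),
                           pd.Series(fams, dtype=object).to_numpy(), q=q)
    table.loc[valid, "fdr_flag"] = flags

    sig = table[table["fdr_flag"]]
    per_elec = sig.groupby("electrode")["category"].nunique()
    counts = {
        f"{r}_{h}": int(sig[(sig["region"] == r) & (sig["hemisphere"] == h)]
                        ["electrode"].nunique())
        for (r, h) in cohorts}
    summary = {
        "per_cohort": counts,
        "total_significant": int(per_elec.size),
        "total_electrodes": int(table["electrode"].nunique()),
        "dual_selective": int((per_elec >= 2).sum()),
        "word_selective_left_vtc": int(
            sig[(sig["category"] == "word") & (sig["region"] == "VTC")
                & (sig["hemisphere"] == "L")]["electrode"].nunique()),
    }
    return table, summary


def reproduce_topology(cohorts: dict[tuple[str, str], SupplementaryCohort]
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collinearity screen and per-category mixed models from stored data.

    Returns (spearman table, coefficient table) in the same layout as the
    in-package topology report.
    """
    from gammatopo.topology import collinearity_screen

    geo = pd.concat([c.geometry() for c in cohorts.values()])
    screen = collinearity_screen(geo)

    rows = []
    for (region, hemi), cohort in cohorts.items():
        geometry = center_coordinates(cohort.geometry())
        axes = REGION_AXES[region]
        coords = geometry[["c" + axes[0], "c" + axes[1]]].to_numpy(float)
        for ci, cat in enumerate(cohort.categories):
            if cat == "word" and hemi != "L":
                continue
            y = cohort.dprime[:, ci]
            ok = np.isfinite(y)
            if ok.sum() < 8 or len(np.unique(cohort.subjects[ok])) < 2:
                continue
            fit = fit_lme(y[ok], coords[ok], cohort.subjects[ok],
                          terms=["intercept", axes[0], axes[1],
                                 f"{axes[0]}:{axes[1]}"],
                          category=cat, region=region, hemisphere=hemi)
            for i, term in enumerate(fit.terms):
                rows.append({"category": cat, "region": region,
                             "hemisphere": hemi, "term": term,
                             "estimate": fit.beta[i], "se": fit.se[i],
                             "p": fit.pvalues[i], "n_obs": fit.n_obs})
    return screen, pd.DataFrame(rows)
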