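"""Synthetic stand-in for the deposited supplementary MAT-files.

Builds a MAT-file with the documented variable layout (coordinate matrix,
per-category d' matrix, BGA mean/SD, per-subject cell of shuffled d') and
a planted selectivity/topology structure, so the reader and reproduction
routines can be exercised without the real deposit. Entirely synthetic:
the numbers share only the schema with the published datasets.
"""

import numpy as np
from scipy import io as sio

from gammatopo.supplementary import TABLE1_SDE_COUNTS

CATS = ("face", "animate", "place", "tool", "word")


def build_cohort_mat(path, region="VTC", hemi="L", n_perm=500, seed=0,
                     n_planted=12, face_slope=0.035, coords_rows=None):
    """Write one synthetic cohort MAT-file; returns the planted truth."""
    rng = np.random.default_rng(seed)
    counts = [c for c in TABLE1_SDE_COUNTS[(region, hemi)] if c > 0]
    n_e = sum(counts)
    sign = -1.0 if hemi == "L" else 1.0
    x = sign * rng.uniform(25, 45, n_e)
    y = rng.uniform(-75, -30, n_e)
    z = 5 - 0.55 * x * sign + rng.normal(0, 1.5, n_e)
    coords = np.column_stack([x, y, z])

    subjects = np.concatenate([np.full(c, i) for i, c in enumerate(counts)])
    dprime = rng.normal(0, 0.8, (n_e, 5))
    # planted gradient: face d' rises with |x| plus a subject offset
    offs = rng.normal(0, 0.3, len(counts))
    dprime[:, 0] = face_slope * np.abs(x) + offs[subjects] \
        + rng.normal(0, 0.4, n_e)
    planted = rng.choice(n_e, size=n_planted, replace=False)
    # planted atoms avoid the face column, which carries the smooth gradient
    planted_cat = rng.integers(1, 5, size=n_planted)
    for e, c in zip(planted, planted_cat):
        dprime[e, c] = rng.uniform(5.0, 6.0)
    # one deliberately dual-selective electrode
    dual = planted[0]
    dual_second = 1 + (planted_cat[0] % 4)
    dprime[dual, dual_second] = rng.uniform(5.0, 6.0)

    shuf_cell = np.empty((len(counts), 1), dtype=object)
    start = 0
    for i, c in enumerate(counts):
        shuf_cell[i, 0] = rng.normal(0, 1, (c, 5, n_perm))
        start += c

    cats_cell = np.empty((5, 1), dtype=object)
    for i, c in enumerate(CATS):
        cats_cell[i, 0] = c

    tag = f"{hemi}H_{region}"
    variables = {
        f"Pt_Coords_{tag}": coords if coords_rows is None
        else coords[:coords_rows],
        f"pt_dprime_final_{tag}": dprime,
        f"pt_BGA_mean_{tag}": rng.uniform(10, 80, (n_e, 5)),
        f"pt_BGA_std_{tag}": rng.uniform(5, 20, (n_e, 5)),
        f"pt_dprime_final_shuf_{tag}": shuf_cell,
        "Categories": cats_cell,
    }
    sio.savemat(str(path), variables)
    return {"n_electrodes": n_e, "counts": counts,
            "planted": {(int(e), CATS[c]) for e, c in zip(planted, planted_cat)}
        | {(int(dual), CATS[dual_second])},
            "dual_electrode": int(dual), "face_slope": face_slope,
            "coords": coords, "subjects": subjects, "dprime": dprime}
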