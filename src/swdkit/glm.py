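"""Mass-univariate GLM analysis of (synthetic) fMRI runs.

Classified stimulation blocks and seizure periods are turned into a
design matrix by convolving each condition's boxcar with the
third-order gamma basis (three regressors per condition).  Effects of
interest are interictal stimulation, stimulation fully inside a
seizure, stimulation that ended a seizure, and seizures without
stimulation; intermediate timing categories and the six motion
parameters enter as confounds of no interest.  Voxel-wise OLS provides
beta maps; F-contrasts test a condition's three basis coefficients
jointly (optionally as an interictal-minus-ictal difference), and
significance is assessed with cluster-level correction against a
circular-shift permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sstats

from .signals import HRFBasis, extreme_beta

__all__ = [
    "DesignMatrix",
    "GLMFit",
    "ContrastResult",
    "condition_regressors",
    "build_design",
    "fit_glm",
    "f_contrast",
    "cluster_correct",
    "mask_f_with_t",
    "framewise_displacement",
    "scrub_stimulations",
    "roi_extreme_beta_test",
]

# stimulation-block label -> modeled condition of interest
EFFECT_CONDITIONS = {
    "baseline": "interictal_stim",
    "fully_inside": "ictal_stim",
    "ended_seizure": "stim_ended_seizure",
}
SEIZURE_CONDITION = "seizure"


def condition_regressors(events, basis: HRFBasis, frame_times,
                         oversample: int = 50) -> np.ndarray:
    """Convolve a condition's boxcar with each basis column.

    The boxcar (one entry per event ``(onset_s, duration_s)``) is built
    on a dense grid of ``TR / oversample`` resolution, convolved with
    the basis functions evaluated on the same grid, and decimated at the
    frame times.  Returns a (n_frames, n_basis) array.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    TR = basis.TR
    dt = TR / oversample
    t_end = frame_times[-1] + TR
    n_dense = int(np.ceil(t_end / dt)) + 1
    dense_t = np.arange(n_dense) * dt
    boxcar = np.zeros(n_dense)
    for onset, dur in events:
        boxcar[(dense_t >= onset) & (dense_t < onset + dur)] = 1.0
    from .signals import gamma_basis
    dense_basis = gamma_basis(TR=TR, duration=basis.duration,
                              shapes=basis.shapes, t_grid=np.arange(
                                  0.0, basis.duration + dt, dt)).matrix
    out = np.empty((frame_times.size, dense_basis.shape[1]))
    idx = np.round(frame_times / dt).astype(int)
    for k in range(dense_basis.shape[1]):
        conv = np.convolve(boxcar, dense_basis[:, k])[:n_dense] * dt
        out[:, k] = conv[idx]
    return out


@dataclass
class DesignMatrix:
    """frames x regressors design with column metadata."""

    matrix: np.ndarray
    columns: pd.DataFrame      # name, condition, basis_index, confound
    frame_times: np.ndarray
    basis: HRFBasis

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]

    def condition_columns(self, condition: str) -> np.ndarray:
        sel = np.flatnonzero((self.columns["condition"] == condition).to_numpy())
        if sel.size == 0:
            raise ValueError(f"condition '{condition}' not present in the design")
        return sel

    @property
    def effect_conditions(self) -> list:
        eff = self.columns.loc[~self.columns["confound"], "condition"]
        return [c for c in dict.fromkeys(eff) if c is not None]


def build_design(classified_blocks, seizure_intervals, motion,
                 basis: HRFBasis, frame_times) -> DesignMatrix:
    """Design matrix from classified events.

    Effects of interest: interictal stimulation (``baseline`` blocks),
    ictal stimulation (``fully_inside``), stimulation that ended a
    seizure, and seizures without stimulation — three gamma regressors
    each.  All remaining block categories are modeled identically but
    flagged as confounds, alongside the six motion parameters and an
    intercept.  Conditions without events are omitted with a warning.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    steps = np.diff(frame_times)
    if steps.size and not np.allclose(steps, steps[0]):
        raise ValueError("frame times must be uniform")

    events_by_cond: dict = {}
    for blk in classified_blocks:
        if blk.label is None:
            raise ValueError("blocks must be classified before design construction")
        cond = EFFECT_CONDITIONS.get(blk.label, f"confound_{blk.label}")
        events_by_cond.setdefault(cond, []).append((blk.onset, blk.duration))

    # seizures with no overlapping stimulation block
    solo = []
    for iv in seizure_intervals:
        if not any(b.onset < iv.end and iv.start < b.end for b in classified_blocks):
            solo.append((iv.start, iv.duration))
    if solo:
        events_by_cond[SEIZURE_CONDITION] = solo

    mats, meta = [], []
    order = list(EFFECT_CONDITIONS.values()) + [SEIZURE_CONDITION]
    ordered = [c for c in order if c in events_by_cond] + sorted(
        c for c in events_by_cond if c not in order
    )
    for cond in ordered:
        reg = condition_regressors(events_by_cond[cond], basis, frame_times)
        if not np.any(np.abs(reg) > 1e-12):
            warnings.warn(f"condition '{cond}' produced an all-zero regressor; omitted")
            continue
        confound = cond.startswith("confound_")
        for k in range(reg.shape[1]):
            mats.append(reg[:, k])
            meta.append((f"{cond}_b{k}", cond, k, confound))

    motion_arr = np.asarray(motion, dtype=float) if motion is not None else None
    if motion_arr is not None:
        if motion_arr.shape[0] != frame_times.size:
            raise ValueError("motion parameters must have one row per frame")
        motion_arr = motion_arr - motion_arr.mean(axis=0)
        for j in range(motion_arr.shape[1]):
            mats.append(motion_arr[:, j])
            meta.append((f"motion_{j}", None, None, True))
    mats.append(np.ones(frame_times.size))
    meta.append(("intercept", None, None, True))

    columns = pd.DataFrame(meta, columns=["name", "condition", "basis_index", "confound"])
    return DesignMatrix(matrix=np.column_stack(mats), columns=columns,
                        frame_times=frame_times, basis=basis)


@dataclass
class GLMFit:
    """Voxel-wise OLS estimates (statsmodels-flavoured results object)."""

    betas: np.ndarray          # (n_regressors, n_voxels)
    resid_var: np.ndarray      # (n_voxels,) unbiased
    dof: int
    design: DesignMatrix
    xtx_inv: np.ndarray = field(repr=False)

    def summary(self, voxel: int | None = None) -> pd.DataFrame:
        """Per-regressor beta, standard error and t for one voxel
        (or averaged betas across voxels when ``voxel`` is None)."""
        if voxel is None:
            beta = self.betas.mean(axis=1)
            var = float(self.resid_var.mean())
        else:
            beta = self.betas[:, voxel]
            var = float(self.resid_var[voxel])
        se = np.sqrt(np.diag(self.xtx_inv) * var)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = beta / se
        return pd.DataFrame({
            "regressor": self.design.columns["name"],
            "beta": beta, "se": se, "t": t,
        })

    def condition_betas(self, condition: str) -> np.ndarray:
        return self.betas[self.design.condition_columns(condition)]


def fit_glm(data: np.ndarray, design: DesignMatrix) -> GLMFit:
    """Mass-univariate OLS: ``data`` is frames x voxels."""
    data = np.asarray(data, dtype=float)
    X = design.matrix
    if data.shape[0] != X.shape[0]:
        raise ValueError("data frames do not match the design")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns via tiny singular vectors
        _, s, vt = np.linalg.svd(X, full_matrices=False)
        bad = np.abs(vt[s < s.max() * 1e-10]).sum(axis=0) > 1e-8
        names = design.columns["name"][bad].tolist()
        raise ValueError(f"rank-deficient design; collinear columns: {names}")
    xtx_inv = np.linalg.inv(X.T @ X)
    betas = xtx_inv @ X.T @ data
    resid = data - X @ betas
    dof = X.shape[0] - rank
    resid_var = (resid**2).sum(axis=0) / dof
    return GLMFit(betas=betas, resid_var=resid_var, dof=dof,
                  design=design, xtx_inv=xtx_inv)


@dataclass
class ContrastResult:
    F: np.ndarray              # (n_voxels,)
    t_first: np.ndarray        # t map of the first-basis row
    df: tuple                  # (q, dof)
    p: np.ndarray              # voxel-wise F p-values

    @property
    def q(self) -> int:
        return self.df[0]


def _contrast_matrix(design: DesignMatrix, condition) -> np.ndarray:
    P = design.matrix.shape[1]
    if isinstance(condition, str):
        cols = design.condition_columns(condition)
        C = np.zeros((cols.size, P))
        C[np.arange(cols.size), cols] = 1.0
    else:  # difference contrast, +1 on A's basis columns, -1 on B's
        a, b = condition
        ca, cb = design.condition_columns(a), design.condition_columns(b)
        if ca.size != cb.size:
            raise ValueError("difference contrast needs matching basis columns")
        C = np.zeros((ca.size, P))
        C[np.arange(ca.size), ca] = 1.0
        C[np.arange(cb.size), cb] = -1.0
    return C


def f_contrast(fit: GLMFit, condition) -> ContrastResult:
    """F test over a condition's basis coefficients.

    ``condition`` may be a name (joint test of its three betas) or a
    pair ``(A, B)`` for the A-minus-B difference contrast with +1/-1
    weights on matched basis columns.  The returned ``t_first`` map is
    the signed t of the contrast's first-basis row.
    """
    C = _contrast_matrix(fit.design, condition)
    q = C.shape[0]
    cb = C @ fit.betas                                   # (q, V)
    M = C @ fit.xtx_inv @ C.T
    Minv = np.linalg.inv(M)
    quad = np.einsum("qv,qr,rv->v", cb, Minv, cb)
    with np.errstate(invalid="ignore", divide="ignore"):
        F = quad / (q * fit.resid_var)
        t_first = cb[0] / np.sqrt(M[0, 0] * fit.resid_var)
    F = np.where(fit.resid_var > 0, F, 0.0)
    t_first = np.where(fit.resid_var > 0, t_first, 0.0)
    p = sstats.f.sf(F, q, fit.dof)
    return ContrastResult(F=F, t_first=t_first, df=(q, fit.dof), p=p)


def _cluster_sizes(binary3d: np.ndarray):
    labels, n = ndimage.label(binary3d, structure=np.ones((3, 3, 3), dtype=int))
    if n == 0:
        return labels, np.array([], dtype=int)
    sizes = np.bincount(labels.ravel())[1:]
    return labels, sizes


def cluster_correct(stat_map, voxel_p_threshold: float, n_permutations: int,
                    alpha: float, *, data, design: DesignMatrix, condition,
                    mask=None, seed: int = 0):
    """Cluster-level correction by circular-shift permutation.

    ``stat_map`` is the observed 3D F map (``condition`` must match the
    contrast it came from).  Clusters are 26-connected components above
    the voxel threshold; a cluster survives if its size exceeds the
    (1-alpha) quantile of the maximal cluster size over permutations in
    which the effect regressors are jointly circularly shifted in time
    (preserving autocorrelation).  Returns ``(mask3d, table)``.
    """
    if n_permutations < 20:
        raise ValueError("need >= 20 permutations")
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations; cluster p-values are coarse")
    stat_map = np.asarray(stat_map)
    dims = stat_map.shape
    brain = np.ones(dims, dtype=bool) if mask is None else np.asarray(mask, bool)

    fit = fit_glm(data, design)
    q = _contrast_matrix(design, condition).shape[0]
    f_crit = sstats.f.isf(voxel_p_threshold, q, fit.dof)

    obs_bin = (stat_map > f_crit) & brain
    labels, sizes = _cluster_sizes(obs_bin)

    rng = np.random.default_rng(seed)
    eff_cols = design.columns.index[~design.columns["confound"]].to_numpy()
    n_frames = design.n_frames
    null_max = np.empty(n_permutations)
    for i in range(n_permutations):
        shift = int(rng.integers(1, n_frames))
        Xp = design.matrix.copy()
        Xp[:, eff_cols] = np.roll(Xp[:, eff_cols], shift, axis=0)
        dperm = DesignMatrix(matrix=Xp, columns=design.columns,
                             frame_times=design.frame_times, basis=design.basis)
        fperm = f_contrast(fit_glm(data, dperm), condition)
        perm_bin = (fperm.F.reshape(dims) > f_crit) & brain
        _, psizes = _cluster_sizes(perm_bin)
        null_max[i] = psizes.max() if psizes.size else 0
    crit_size = float(np.quantile(null_max, 1.0 - alpha))

    keep = np.zeros(dims, dtype=bool)
    rows = []
    for cid, size in enumerate(sizes, start=1):
        cluster_p = float((1 + np.sum(null_max >= size)) / (1 + n_permutations))
        retained = size > crit_size
        if retained:
            keep |= labels == cid
        rows.append({"cluster": cid, "size": int(size),
                     "max_stat": float(stat_map[labels == cid].max()),
                     "p": cluster_p, "significant": retained})
    table = pd.DataFrame(rows, columns=["cluster", "size", "max_stat", "p", "significant"])
    return keep, table


def mask_f_with_t(f_mask, t_map_first_basis):
    """Directional mask: F-significant AND positive first-basis t."""
    f_mask = np.asarray(f_mask, dtype=bool)
    t_map = np.asarray(t_map_first_basis)
    if f_mask.shape != t_map.shape:
        raise ValueError("F mask and t map grids do not match")
    return f_mask & (t_map > 0)


def framewise_displacement(motion, radius_mm: float = 5.0,
                           mode: str = "standard") -> np.ndarray:
    """Scalar head-motion series (mm) from 6 rigid-body parameters.

    ``motion`` is (n_frames, 6): translations x/y/z in mm then
    rotations in degrees.  Differentials of successive parameters are
    summed after converting rotations: ``standard`` multiplies the
    rotation in radians by ``radius_mm`` (arc length on a sphere of the
    brain's radius); ``divide_by_radius`` divides the rotation in
    degrees by ``radius_mm`` — a dimensionally anomalous convention that
    nonetheless appears in some processing pipelines, kept for
    comparability.  First frame is 0.
    """
    arr = np.asarray(motion, dtype=float)
    if isinstance(motion, pd.DataFrame):
        arr = motion.to_numpy(dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 6 or arr.shape[0] < 2:
        raise ValueError("motion must be (n_frames >= 2, 6)")
    d = np.abs(np.diff(arr, axis=0))
    trans = d[:, :3].sum(axis=1)
    if mode == "standard":
        rot = (np.deg2rad(d[:, 3:]) * radius_mm).sum(axis=1)
    elif mode == "divide_by_radius":
        rot = (d[:, 3:] / radius_mm).sum(axis=1)
    else:
        raise ValueError(f"unknown FD mode '{mode}'")
    return np.concatenate([[0.0], trans + rot])


def scrub_stimulations(blocks, motion_metric, TR: float, voxel_size_mm: float,
                       threshold_fraction: float = 0.003):
    """Drop stimulation blocks coinciding with motion above threshold.

    A block is removed when any frame within it has
    ``motion_metric > threshold_fraction * voxel_size_mm`` (the 0.3 %
    of-voxel-size criterion; with 0.5 mm voxels this is 1.5 um).
    """
    metric = np.asarray(motion_metric, dtype=float)
    thr = threshold_fraction * voxel_size_mm
    kept = []
    for blk in blocks:
        frames = np.flatnonzero(
            (np.arange(metric.size) * TR >= blk.onset)
            & (np.arange(metric.size) * TR < blk.end)
        )
        if not np.any(metric[frames] > thr):
            kept.append(blk)
    return kept


def roi_extreme_beta_test(hrfs_condition_a, hrfs_condition_b):
    """Two-sample two-tailed t-test on per-session extreme beta values.

    Inputs are sequences of per-session HRF curves (or directly their
    extreme values); the extreme (max-or-min by magnitude) of each
    session enters the test.  Returns a dict with t, p and group
    mean +/- SD.
    """
    def extremes(group):
        return np.array([
            extreme_beta(h) if np.ndim(h) else float(h) for h in group
        ])

    a, b = extremes(hrfs_condition_a), extremes(hrfs_condition_b)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 sessions per condition")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.allclose(a.mean(), b.mean()):
            return {"t": 0.0, "p": 1.0,
                    "mean_a": float(a.mean()), "sd_a": 0.0,
                    "mean_b": float(b.mean()), "sd_b": 0.0}
        raise ValueError("zero within-group variance in both groups")
    t, p = sstats.ttest_ind(a, b)
    return {"t": float(t), "p": float(p),
            "mean_a": float(a.mean()), "sd_a": float(a.std(ddof=1)),
            "mean_b": float(b.mean()), "sd_b": float(b.std(ddof=1))}
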