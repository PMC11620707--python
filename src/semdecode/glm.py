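"""First- and second-level GLM analysis of simulated BOLD runs.

Design matrices convolve condition boxcars with the canonical double-gamma
HRF; voxelwise ordinary least squares yields beta, residual-variance and t
maps; group inference is a voxelwise one-sample t on per-subject contrast
maps (exact for the 1-df within-subject contrasts reported here), followed
by cluster-extent thresholding with optional exclusive masking.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

# Canonical double-gamma HRF: peak delay 6 s, undershoot delay 16 s, unit
# dispersions, peak:undershoot ratio 6, 32 s support, peak-normalized.
HRF_PEAK_DELAY = 6.0
HRF_UNDERSHOOT_DELAY = 16.0
HRF_PEAK_DISP = 1.0
HRF_UNDERSHOOT_DISP = 1.0
HRF_RATIO = 6.0
HRF_LENGTH_S = 32.0

DEFAULT_OVERSAMPLING = 24  # micro-time resolution tr/oversampling (0.1 s at TR 2.4)

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def canonical_hrf(tr: float, oversampling: int = DEFAULT_OVERSAMPLING) -> np.ndarray:
    """Canonical HRF sampled at ``tr / oversampling`` over 32 s of support,
    peak-normalized to a maximum of 1. The value at t=0 is exactly 0."""
    if tr <= 0:
        raise ValueError("tr must be positive")
    dt = tr / oversampling
    t = np.arange(0.0, HRF_LENGTH_S, dt)
    h = (stats.gamma.pdf(t, HRF_PEAK_DELAY / HRF_PEAK_DISP, scale=HRF_PEAK_DISP)
         - stats.gamma.pdf(t, HRF_UNDERSHOOT_DELAY / HRF_UNDERSHOOT_DISP,
                           scale=HRF_UNDERSHOOT_DISP) / HRF_RATIO)
    return h / h.max()


def condition_regressors(events: pd.DataFrame, tr: float, n_volumes: int,
                         conditions: Sequence[str] | None = None,
                         oversampling: int = DEFAULT_OVERSAMPLING,
                         ) -> tuple[np.ndarray, list[str]]:
    """HRF-convolved boxcar regressors sampled at the frame times i*tr.

    One column per condition label. When ``conditions`` is given it fixes
    the column order and any event with a label outside it is an error;
    otherwise labels are taken in sorted order.
    """
    if n_volumes < 1:
        raise ValueError("n_volumes must be >= 1")
    present = list(pd.unique(events["trial_type"])) if len(events) else []
    if conditions is None:
        conditions = sorted(present)
    else:
        unknown = sorted(set(present) - set(conditions))
        if unknown:
            raise ValueError(f"unknown condition label(s): {unknown}")
        conditions = list(conditions)
    if len(events):
        if events["onset"].min() < -1e-9:
            raise ValueError("event beyond run end: negative onset")
        if (events["onset"] + events["duration"]).max() > n_volumes * tr + 1e-9:
            raise ValueError("event beyond run end: event exceeds run duration")

    dt = tr / oversampling
    n_fine = n_volumes * oversampling
    kernel = canonical_hrf(tr, oversampling)
    out = np.zeros((n_volumes, len(conditions)))
    for j, cond in enumerate(conditions):
        sub = events[events["trial_type"] == cond]
        if not len(sub):
            continue
        box = np.zeros(n_fine)
        for onset, dur in zip(sub["onset"], sub["duration"]):
            a = int(round(onset / dt))
            b = max(a + 1, int(round((onset + dur) / dt)))
            box[a:min(b, n_fine)] = 1.0
        conv = np.convolve(box, kernel)[:n_fine]
        out[:, j] = conv[::oversampling]
    return out, list(conditions)


@dataclass
class DesignMatrix:
    """T x P design with named columns; the intercept is always last."""

    matrix: np.ndarray
    column_names: list[str]
    tr: float
    frame_times: np.ndarray

    def __post_init__(self) -> None:
        if len(self.column_names) != self.matrix.shape[1]:
            raise ValueError("column_names length must match design width")
        if len(set(self.column_names)) != len(self.column_names):
            raise ValueError("column names must be unique")

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]


def _cosine_drift(n_volumes: int, order: int) -> np.ndarray:
    t = np.arange(n_volumes)
    return np.column_stack([
        np.cos(math.pi * (t + 0.5) * k / n_volumes) for k in range(1, order + 1)
    ])


def build_design_matrix(events: pd.DataFrame, tr: float, n_volumes: int,
                        nuisance: pd.DataFrame | np.ndarray | None = None,
                        conditions: Sequence[str] | None = None,
                        oversampling: int = DEFAULT_OVERSAMPLING,
                        drift_order: int = 0) -> DesignMatrix:
    """Build a first-level design: one HRF-convolved boxcar regressor per
    condition, optional nuisance columns and cosine drift, intercept last."""
    regs, names = condition_regressors(events, tr, n_volumes,
                                       conditions=conditions,
                                       oversampling=oversampling)
    for j, name in enumerate(names):
        if len(events) and not np.any(regs[:, j]):
            raise ValueError(f"all-zero task regressor for condition {name!r}")
    cols = [regs] if regs.shape[1] else []
    if nuisance is not None:
        if isinstance(nuisance, pd.DataFrame):
            nuis_names = [str(c) for c in nuisance.columns]
            nuis = nuisance.to_numpy(dtype=float)
        else:
            nuis = np.atleast_2d(np.asarray(nuisance, dtype=float))
            if nuis.shape[0] != n_volumes:
                nuis = nuis.T
            nuis_names = [f"nuisance_{k}" for k in range(nuis.shape[1])]
        if nuis.shape[0] != n_volumes:
            raise ValueError("nuisance regressors must have T rows")
        cols.append(nuis)
        names = names + nuis_names
    if drift_order > 0:
        cols.append(_cosine_drift(n_volumes, drift_order))
        names = names + [f"drift_{k}" for k in range(1, drift_order + 1)]
    cols.append(np.ones((n_volumes, 1)))
    names = names + ["intercept"]
    matrix = np.hstack(cols) if cols else np.ones((n_volumes, 1))
    return DesignMatrix(matrix=matrix, column_names=names, tr=tr,
                        frame_times=np.arange(n_volumes) * tr)


@dataclass
class GLMResult:
    """Voxelwise OLS fit: betas, residual variance, dof and t-map access."""

    beta: np.ndarray             # (P, X, Y, Z)
    column_names: list[str]
    sigma2: np.ndarray           # (X, Y, Z) residual variance
    dof: int
    xtx_inv: np.ndarray          # (P, P)
    degenerate: np.ndarray = field(repr=False)  # (X, Y, Z) zero-variance flag

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.sigma2.shape

    def _index(self, name: str) -> int:
        try:
            return self.column_names.index(name)
        except ValueError:
            raise KeyError(f"no regressor named {name!r}") from None

    def beta_map(self, name: str) -> np.ndarray:
        return self.beta[self._index(name)]

    def contrast(self, weights) -> tuple[np.ndarray, np.ndarray]:
        """Effect and t maps for a weight vector over the design columns
        (or a mapping name -> weight). Degenerate voxels get t = 0."""
        if isinstance(weights, dict):
            w = np.zeros(len(self.column_names))
            for name, val in weights.items():
                w[self._index(name)] = val
        else:
            w = np.asarray(weights, dtype=float)
            if w.shape != (len(self.column_names),):
                raise ValueError("weights length must match design columns")
        effect = np.tensordot(w, self.beta, axes=1)
        var_factor = float(w @ self.xtx_inv @ w)
        se = np.sqrt(self.sigma2 * var_factor)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, effect / np.where(se > 0, se, 1.0), 0.0)
        return effect, t

    def t_map(self, name: str) -> np.ndarray:
        w = np.zeros(len(self.column_names))
        w[self._index(name)] = 1.0
        return self.contrast(w)[1]


def fit_glm(run, design: DesignMatrix) -> GLMResult:
    """Ordinary least squares per voxel.

    ``run`` is a SubjectRun or a 4D array (X, Y, Z, T). Raises on a
    rank-deficient design, naming the collinear columns; voxels with zero
    residual variance are flagged degenerate (their t values are 0).
    """
    data = np.asarray(run) if isinstance(run, np.ndarray) else np.asarray(run.data)
    if data.ndim != 4:
        raise ValueError("run data must be 4D (X, Y, Z, T)")
    x = design.matrix
    t_len, p = x.shape
    if data.shape[-1] != t_len:
        raise ValueError(
            f"run has {data.shape[-1]} volumes but design has {t_len}")
    r_diag = np.abs(np.diag(np.linalg.qr(x, mode="r")))
    bad = r_diag < 1e-8 * max(r_diag.max(), 1.0)
    if bad.any():
        names = [design.column_names[i] for i in np.flatnonzero(bad)]
        raise ValueError(f"rank-deficient design; collinear columns: {names}")
    shape = data.shape[:3]
    y = data.reshape(-1, t_len).T
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    dof = t_len - p
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = (resid ** 2).sum(axis=0) / dof
    scale = max(float(np.abs(y).max()), 1.0)
    degenerate = sigma2 <= (1e-12 * scale) ** 2
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} voxel(s) with zero residual "
                      "variance; their t values are set to 0", stacklevel=2)
    return GLMResult(beta=beta.reshape(p, *shape), column_names=list(design.column_names),
                     sigma2=sigma2.reshape(shape), dof=dof, xtx_inv=xtx_inv,
                     degenerate=degenerate.reshape(shape))


def smooth_volume(volume: np.ndarray, fwhm_mm: float | Sequence[float],
                  voxel_size_mm: Sequence[float] = (3.0, 3.0, 3.0)) -> np.ndarray:
    """Separable Gaussian smoothing of a 3D map or 4D run (spatial axes
    only), sigma = FWHM / (2 sqrt(2 ln 2)) per axis; FWHM 0 is the identity."""
    fwhm = np.broadcast_to(np.asarray(fwhm_mm, dtype=float), (3,))
    if (fwhm < 0).any():
        raise ValueError("fwhm must be >= 0")
    out = np.asarray(volume, dtype=float).copy()
    for axis in range(3):
        sigma = fwhm[axis] * FWHM_TO_SIGMA / voxel_size_mm[axis]
        if sigma > 0:
            out = ndimage.gaussian_filter1d(out, sigma, axis=axis, mode="constant")
    return out


def second_level_contrast(subject_maps: Sequence[np.ndarray],
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise one-sample t across subjects with a right-tailed p map.

    Zero between-subject variance is flagged: t is +/-inf where the mean is
    nonzero (p 0 or 1) and 0 where the mean is zero (p 1).
    """
    maps = np.stack(subject_maps)
    n = maps.shape[0]
    if n < 2:
        raise ValueError("second-level analysis requires >= 2 subjects")
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0) * math.sqrt(n), 0.0)
    p = stats.t.sf(t, df=n - 1)
    zero_var = sd == 0
    t = np.where(zero_var & (mean > 0), np.inf, t)
    t = np.where(zero_var & (mean < 0), -np.inf, t)
    p = np.where(zero_var, np.where(mean > 0, 0.0, 1.0), p)
    return t, p


@dataclass(frozen=True)
class Cluster:
    id: int
    size: int
    voxels: np.ndarray          # (size, 3) integer coordinates
    peak_coordinate: tuple[int, int, int]
    peak_stat: float


@dataclass
class ClusterTable:
    clusters: list[Cluster]

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def __getitem__(self, i: int) -> Cluster:
        return self.clusters[i]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [{"cluster_id": c.id, "size": c.size,
                 "peak_x": c.peak_coordinate[0], "peak_y": c.peak_coordinate[1],
                 "peak_z": c.peak_coordinate[2], "peak_stat": c.peak_stat}
                for c in self.clusters]
        return pd.DataFrame(rows, columns=["cluster_id", "size", "peak_x",
                                           "peak_y", "peak_z", "peak_stat"])


_CONNECTIVITY = {6: 1, 18: 2, 26: 3}


def extract_clusters(stat_map: np.ndarray, p_map: np.ndarray,
                     cluster_p: float = 0.001, extent: int = 10,
                     exclusive_mask: tuple[np.ndarray, float] | None = None,
                     connectivity: int = 18) -> ClusterTable:
    """Group suprathreshold voxels (p < cluster_p) into connected components
    and keep those with strictly more than ``extent`` voxels, sorted by size.

    ``exclusive_mask`` is an optional (p_map, mask_p) pair: voxels significant
    in the competing contrast at ``mask_p`` are removed before labeling.
    """
    if stat_map.shape != p_map.shape:
        raise ValueError("stat and p maps must share a grid")
    if connectivity not in _CONNECTIVITY:
        raise ValueError("connectivity must be one of 6, 18, 26")
    mask = p_map < cluster_p
    if exclusive_mask is not None:
        excl_p, mask_p = exclusive_mask
        if excl_p.shape != p_map.shape:
            raise ValueError("exclusive mask must share the grid")
        mask &= ~(excl_p < mask_p)
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY[connectivity])
    labels, n_labels = ndimage.label(mask, structure=structure)
    clusters: list[Cluster] = []
    for lab in range(1, n_labels + 1):
        voxels = np.argwhere(labels == lab)
        if len(voxels) <= extent:
            continue
        stats_here = stat_map[tuple(voxels.T)]
        peak = voxels[int(np.argmax(stats_here))]
        clusters.append(Cluster(id=0, size=len(voxels), voxels=voxels,
                                peak_coordinate=tuple(int(v) for v in peak),
                                peak_stat=float(stats_here.max())))
    clusters.sort(key=lambda c: (-c.size, -c.peak_stat, c.peak_coordinate))
    clusters = [Cluster(id=i + 1, size=c.size, voxels=c.voxels,
                        peak_coordinate=c.peak_coordinate, peak_stat=c.peak_stat)
                for i, c in enumerate(clusters)]
    return ClusterTable(clusters)
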