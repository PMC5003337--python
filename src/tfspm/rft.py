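"""Random-field-theory cluster-level inference for 1-D and 2-D T maps.

Suprathreshold clusters of the statistic image (height threshold: the
T value with upper-tail probability ``height_p`` under Student t) are
assigned family-wise-error corrected p-values from the expected Euler
characteristic of a T random field and the Poisson clumping heuristic for
cluster extents.  Field smoothness (FWHM per dimension) is estimated from
the spatial partial derivatives of the standardized GLM residuals, and the
search region is expressed in resels (resolution elements).

A label-permutation oracle over the same cluster statistics is provided as
an independent, assumption-light check of the analytic p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import gammaln
from scipy.stats import t as tdist

__all__ = [
    "SmoothnessEstimate", "estimate_smoothness", "resel_counts",
    "ec_density_t", "cluster_p_fwe", "cluster_inference", "ClusterTable",
    "format_cluster_report", "permutation_oracle",
]

def empty_cluster_table() -> "ClusterTable":
    return ClusterTable(pd.DataFrame(columns=CLUSTER_COLUMNS))


CLUSTER_COLUMNS = [
    "peak_time_ms", "peak_freq_hz", "peak_T",
    "extent_time_lo_ms", "extent_time_hi_ms",
    "extent_freq_lo_hz", "extent_freq_hi_hz",
    "n_pixels", "cluster_size_ms_hz", "p_fwe_cluster",
]


@dataclass
class SmoothnessEstimate:
    """Estimated field smoothness.

    ``fwhm_px`` / ``fwhm_physical`` are global per-dimension FWHM values
    (from the mean residual-gradient roughness).  ``rpv`` is the
    resels-per-pixel image, the local resel density prod_d sqrt(lambda_d /
    (4 ln 2)); its sum over the search region gives ``resel_count``.
    Wavelet decompositions make smoothness strongly nonstationary over the
    time-frequency plane, so cluster extents are measured in resels by
    summing ``rpv`` over the cluster rather than dividing pixel counts by a
    global FWHM (the standard nonstationarity correction)."""

    fwhm_px: tuple[float, ...]
    fwhm_physical: tuple[float, ...]
    resel_count: float
    rpv: np.ndarray | None = None
    method: str = "residual-gradient"


class ClusterTable(pd.DataFrame):
    """Suprathreshold clusters sorted by corrected p (a plain DataFrame
    with the columns in ``CLUSTER_COLUMNS``)."""

    @property
    def _constructor(self):
        return ClusterTable


def estimate_smoothness(resid_std: np.ndarray,
                        pixel_size: tuple[float, ...] = (1.0,),
                        mask: np.ndarray | None = None,
                        search_shape: tuple[int, ...] | None = None,
                        ) -> SmoothnessEstimate:
    """FWHM per dimension from standardized residual images.

    ``resid_std`` is (n_images, *grid); images must be unit-normalized per
    pixel (sum of squares over images = 1), as stored by the GLM fit.  The
    roughness of each dimension is the mean over pixels of the squared
    forward difference, summed over images; FWHM = sqrt(4 ln 2 / lambda),
    clamped below at 1 pixel.  ``pixel_size`` converts to physical units
    (ms, Hz).  ``search_shape`` (default: the grid shape) sets the region
    whose resel count is reported.
    """
    u = np.asarray(resid_std, float)
    if u.ndim < 2:
        raise ValueError("need (n_images, grid...) residuals")
    grid_ndim = u.ndim - 1
    if np.allclose(u.std(axis=0), 0):
        raise ValueError("constant residuals: smoothness undefined")
    # re-standardize within the provided image set so a subsample of the
    # full residual stack still has unit sum of squares per pixel
    sumsq = (u ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(sumsq > 0, u / np.sqrt(sumsq), 0.0)
    a = 4 * np.log(2)
    fwhm_px = []
    lam_maps = []
    for d in range(grid_ndim):
        diff = np.diff(u, axis=d + 1)
        lam_map = (diff ** 2).sum(axis=0)
        # map the edge-to-edge roughness back onto the pixel grid by
        # averaging the one-sided estimates (edge pixels use one side)
        grid = np.empty(u.shape[1:])
        sl_lo = [slice(None)] * grid_ndim
        sl_hi = [slice(None)] * grid_ndim
        sl_lo[d] = slice(0, -1)
        sl_hi[d] = slice(1, None)
        cnt = np.zeros(u.shape[1:])
        grid[...] = 0.0
        grid[tuple(sl_lo)] += lam_map
        grid[tuple(sl_hi)] += lam_map
        cnt[tuple(sl_lo)] += 1
        cnt[tuple(sl_hi)] += 1
        grid /= cnt
        # FWHM below 1 pixel is not resolvable: clamp the local roughness
        grid = np.minimum(grid, a)
        lam_maps.append(grid)
        if mask is not None:
            m = np.minimum(mask.take(range(diff.shape[d + 1]), axis=d),
                           mask.take(range(1, diff.shape[d + 1] + 1), axis=d))
            lam = lam_map[m].mean() if m.any() else lam_map.mean()
        else:
            lam = lam_map.mean()
        if lam <= 0:
            fwhm_px.append(float(u.shape[d + 1]))
        else:
            fwhm_px.append(max(1.0, float(np.sqrt(a / lam))))
    if len(pixel_size) != grid_ndim:
        raise ValueError("pixel_size does not match grid dimensions")
    rpv = np.ones(u.shape[1:])
    for grid in lam_maps:
        rpv *= np.sqrt(grid / a)
    shape = search_shape if search_shape is not None else u.shape[1:]
    if mask is not None:
        resels = float(rpv[mask].sum())
    else:
        resels = float(rpv.sum())
    return SmoothnessEstimate(
        fwhm_px=tuple(fwhm_px),
        fwhm_physical=tuple(f * s for f, s in zip(fwhm_px, pixel_size)),
        resel_count=resels, rpv=rpv)


def resel_counts(shape: tuple[int, ...], fwhm_px: tuple[float, ...],
                 ) -> np.ndarray:
    """Resel counts [R_0 .. R_D] of a box-shaped search region.

    For a box with sides of n_d pixels and smoothness f_d, side lengths in
    resels are L_d = (n_d - 1) / f_d; R_0 = 1, R_1 = sum L_d,
    R_2 = prod L_d (D = 2).
    """
    L = [(n - 1) / f for n, f in zip(shape, fwhm_px)]
    if len(L) == 1:
        return np.array([1.0, L[0]])
    if len(L) == 2:
        return np.array([1.0, L[0] + L[1], L[0] * L[1]])
    raise NotImplementedError("only 1-D and 2-D fields are supported")


def ec_density_t(u: float, df: float, d: int) -> float:
    """Euler characteristic density rho_d(u) of a Student-T field."""
    v = df
    if d == 0:
        return float(tdist.sf(u, v))
    c = (1 + u ** 2 / v) ** ((1 - v) / 2)
    a = 4 * np.log(2)
    if d == 1:
        return float(np.sqrt(a) / (2 * np.pi) * c)
    if d == 2:
        b = np.exp(gammaln((v + 1) / 2) - gammaln(v / 2))
        return float(a / (2 * np.pi) ** 1.5 * c * u * b / np.sqrt(v / 2))
    raise NotImplementedError("EC density implemented for d <= 2")


def cluster_p_fwe(k_resels: float, u: float, df: float,
                  resels: np.ndarray) -> float:
    """Cluster-level FWE p for an extent of ``k_resels`` at threshold u.

    Expected number of clusters Em = sum_d R_d rho_d(u); expected cluster
    size in resels En = rho_0 / rho_D; the extent survivor function is
    exp(-beta k^(2/D)) with beta = (Gamma(D/2 + 1) / En)^(2/D); the FWE p
    follows from Poisson clumping: 1 - exp(-Em * P(extent >= k)).
    """
    D = len(resels) - 1
    if k_resels <= 0:
        return 1.0
    Em = sum(resels[d] * ec_density_t(u, df, d) for d in range(D + 1))
    rho_D = ec_density_t(u, df, D)
    if rho_D <= 0 or Em <= 0:
        return 1.0
    En = ec_density_t(u, df, 0) / rho_D  # resels per cluster
    beta = (np.exp(gammaln(D / 2 + 1)) / En) ** (2.0 / D)
    p_k = np.exp(-beta * k_resels ** (2.0 / D))
    return float(1 - np.exp(-Em * p_k))


def _connectivity_structure(ndim: int, connectivity: int) -> np.ndarray:
    if ndim == 1:
        return np.ones(3, bool)
    if connectivity == 8:
        return np.ones((3, 3), bool)
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    raise ValueError("connectivity must be 4 or 8")


def cluster_inference(t_map: np.ndarray, df: float,
                      smoothness: SmoothnessEstimate,
                      times_ms: np.ndarray, freqs_hz: np.ndarray | None,
                      height_p: float = 0.001, extent_fwe_p: float = 0.05,
                      connectivity: int = 8,
                      mask: np.ndarray | None = None,
                      keep_all: bool = False) -> ClusterTable:
    """Threshold a T map and assign cluster-level FWE p-values.

    ``t_map`` is (freqs, times) or (times,).  Only pixels inside ``mask``
    enter the search region.  Clusters with p_fwe < ``extent_fwe_p`` are
    retained unless ``keep_all``.  Peaks break ties toward earlier time,
    then lower frequency.
    """
    if df <= 2:
        raise ValueError(f"df = {df} too small for T-field inference")
    t_map = np.asarray(t_map, float)
    is2d = t_map.ndim == 2
    if is2d and (freqs_hz is None or t_map.shape != (len(freqs_hz), len(times_ms))):
        raise ValueError("t_map shape does not match axes")
    u = float(tdist.isf(height_p, df))
    sup = t_map > u
    if mask is not None:
        sup &= mask
    shape = (t_map.shape if mask is None else
             tuple(int(mask.any(axis=tuple(j for j in range(t_map.ndim) if j != d)).sum())
                   for d in range(t_map.ndim)))
    resels = resel_counts(shape, smoothness.fwhm_px)
    rpv = smoothness.rpv
    if rpv is not None:
        # nonstationarity correction: local resel density replaces the
        # global-volume top resel count and measures cluster extents
        resels[-1] = float(rpv[mask].sum() if mask is not None else rpv.sum())

    labels, n_lab = ndimage.label(sup, structure=_connectivity_structure(t_map.ndim, connectivity))
    dt = float(times_ms[1] - times_ms[0]) if len(times_ms) > 1 else 1.0
    dfreq = (float(freqs_hz[1] - freqs_hz[0])
             if (freqs_hz is not None and len(freqs_hz) > 1) else 1.0)
    rows = []
    for lab in range(1, n_lab + 1):
        where = np.nonzero(labels == lab)
        k = where[0].size
        vals = t_map[where]
        best = np.argmax(vals)
        peak_val = vals[best]
        # tie-break: earliest time, then lowest frequency
        ties = np.nonzero(vals == peak_val)[0]
        if is2d:
            tsel = where[1][ties]
            order = np.lexsort((where[0][ties], tsel))
            best = ties[order[0]]
            fi, ti = where[0][best], where[1][best]
            peak_freq = float(freqs_hz[fi])
            ext_f = (float(freqs_hz[where[0].min()]), float(freqs_hz[where[0].max()]))
        else:
            best = ties[np.argsort(where[0][ties])[0]]
            ti = where[0][best]
            peak_freq = np.nan
            ext_f = (np.nan, np.nan)
        if rpv is not None:
            k_res = float(rpv[where].sum())
        else:
            k_res = k / float(np.prod(smoothness.fwhm_px))
        p = cluster_p_fwe(k_res, u, df, resels)
        rows.append(dict(peak_time_ms=float(times_ms[ti]), peak_freq_hz=peak_freq,
                         peak_T=float(peak_val),
                         extent_time_lo_ms=float(times_ms[where[-1].min()]),
                         extent_time_hi_ms=float(times_ms[where[-1].max()]),
                         extent_freq_lo_hz=ext_f[0], extent_freq_hi_hz=ext_f[1],
                         n_pixels=int(k),
                         cluster_size_ms_hz=float(k * dt * dfreq),
                         p_fwe_cluster=float(p)))
    table = pd.DataFrame(rows, columns=CLUSTER_COLUMNS)
    if not keep_all:
        table = table[table["p_fwe_cluster"] < extent_fwe_p]
    table = table.sort_values("p_fwe_cluster", kind="stable").reset_index(drop=True)
    return ClusterTable(table)


def _fast_t_map(Y, cell_of_obs, n_cells, c):
    """OLS cell-means T map (identity covariance), vectorized over pixels."""
    N = Y.shape[0]
    counts = np.bincount(cell_of_obs, minlength=n_cells).astype(float)
    sums = np.zeros((n_cells, Y.shape[1]))
    np.add.at(sums, cell_of_obs, Y)
    means = sums / counts[:, None]
    rss = (Y ** 2).sum(axis=0) - (counts[:, None] * means ** 2).sum(axis=0)
    df = N - n_cells
    sigma2 = np.maximum(rss, 0) / df
    var_c = float(((np.asarray(c) ** 2) / counts).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(sigma2 > 0, (np.asarray(c) @ means) / np.sqrt(sigma2 * var_c), 0.0)
    return t, df


def permutation_oracle(Y: np.ndarray, design, contrast_weights: np.ndarray,
                       grid_shape: tuple[int, ...], n_perm: int, seed: int,
                       height_p: float = 0.001,
                       mask: np.ndarray | None = None,
                       connectivity: int = 8) -> dict:
    """Trial-label permutation null of the maximum cluster extent.

    Under the null of no condition effect, the (type, direction) labels of
    trials are exchangeable within participant; hemisphere stays attached
    to its channel.  T maps are recomputed per permutation with the OLS
    cell-means fit (identity covariance), clusters formed at the same
    height threshold, and the maximum cluster pixel count recorded.  The
    p-value of an observed cluster of k pixels is
    (1 + #{perm max >= k}) / (n_perm + 1).

    Returns a dict with ``null_max_extent``, ``observed_extents``,
    ``cluster_p`` and ``threshold``.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm = {n_perm} < 100: permutation p-values are coarse")
    rng = np.random.default_rng(seed)
    Y = np.asarray(Y, float)
    cell_of_obs = design.cell_of_obs
    n_cells = design.n_cells
    struct = _connectivity_structure(len(grid_shape), connectivity)

    t_obs, df = _fast_t_map(Y, cell_of_obs, n_cells, contrast_weights)
    u = float(tdist.isf(height_p, df))

    def max_extent_and_sizes(cells_idx):
        t, _ = _fast_t_map(Y, cells_idx, n_cells, contrast_weights)
        sup = t.reshape(grid_shape) > u
        if mask is not None:
            sup &= mask
        labels, n_lab = ndimage.label(sup, structure=struct)
        if n_lab == 0:
            return 0, []
        sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                   np.arange(1, n_lab + 1)).astype(int)
        return int(sizes.max()), sizes.tolist()

    _, obs_sizes = max_extent_and_sizes(cell_of_obs)

    # permute the trial-level condition labels within participant: trial b
    # takes the (type, direction) cell pair of another trial of the same
    # participant, keeping each observation's hemisphere
    blocks = design.blocks
    part_of_block = design.obs["participant"].values[blocks[:, 0]]
    cell_b = cell_of_obs[blocks]  # (B, s)
    null_max = np.empty(n_perm, int)
    for pnum in range(n_perm):
        perm_cell = cell_b.copy()
        for part in np.unique(part_of_block):
            rows = np.nonzero(part_of_block == part)[0]
            perm_cell[rows] = perm_cell[rows[rng.permutation(len(rows))]]
        new_cells = np.empty_like(cell_of_obs)
        new_cells[blocks.ravel()] = perm_cell.ravel()
        null_max[pnum], _ = max_extent_and_sizes(new_cells)

    cluster_p = [(1 + int((null_max >= k).sum())) / (n_perm + 1)
                 for k in obs_sizes]
    return dict(null_max_extent=null_max, observed_extents=obs_sizes,
                cluster_p=cluster_p, threshold=u, df=df, t_obs=t_obs)


def format_cluster_report(table: ClusterTable, contrast_label: str) -> str:
    """Human-readable cluster report in the style of a peak/extent table.

    Columns: peak time (ms), peak frequency (Hz), peak T, extent ranges and
    cluster size (ms x Hz); an empty table renders a single "none" row.
    """
    header = (f"{contrast_label}\n"
              f"{'----- Peak -----':^23s} {'------- Extent -------':^42s}\n"
              f"{'Time':>7s} {'Freq':>7s} {'T':>7s} "
              f"{'Time (ms)':>13s} {'Freq (Hz)':>13s} {'Size (ms x Hz)':>14s} "
              f"{'p(FWE)':>8s}")
    if len(table) == 0:
        return header + "\n    none"
    lines = [header]
    for _, r in table.iterrows():
        if np.isnan(r["peak_freq_hz"]):
            freq, fext = "-", "-"
        else:
            freq = f"{r['peak_freq_hz']:.0f}"
            fext = f"{r['extent_freq_lo_hz']:.0f}–{r['extent_freq_hi_hz']:.0f}"
        text = f"{r['extent_time_lo_ms']:.0f}–{r['extent_time_hi_ms']:.0f}"
        lines.append(f"{r['peak_time_ms']:7.0f} {freq:>7s} {r['peak_T']:7.2f} "
                     f"{text:>13s} {fext:>13s} "
                     f"{r['cluster_size_ms_hz']:14.0f} "
                     f"{r['p_fwe_cluster']:8.3f}")
    return "\n".join(lines)
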