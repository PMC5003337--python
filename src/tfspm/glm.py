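"""Mass-univariate factorial GLM with ReML non-sphericity correction.

Single-trial time-frequency (or time-only) images from every trial,
electrode and participant are stacked into one fixed-effects model with a
cell-means design over stimulus type x direction x hemisphere.  Errors are
not assumed i.i.d.: each factor cell may have its own variance and the two
hemisphere observations from the same trial may covary.  The error
covariance is modelled as V = sum_i lambda_i Q_i over user-visible
covariance components, with the hyperparameters lambda estimated once for
the whole image by restricted maximum likelihood (ReML, Fisher scoring),
pooling over in-mask pixels.  Data and design are then whitened by
W = V^(-1/2) and ordinary least squares is run per pixel; contrast T maps
follow from the whitened normal equations.

The trial structure makes every covariance component block-diagonal over
trials (at most 2 x 2 blocks), which the ReML implementation exploits: no
operation scales worse than O(N) in the number of observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DesignMatrix", "NonSphericity", "GLMFit", "Contrast", "MaskSpec",
    "build_design", "covariance_components", "estimate_nonsphericity",
    "fit", "contrast_map", "explicit_mask", "factorial_weights",
    "satterthwaite_df", "observations_table",
]

FACTORS = ("stimulus_type", "direction", "hemisphere")


class DesignError(ValueError):
    pass


class ReMLError(RuntimeError):
    pass


@dataclass
class DesignMatrix:
    """Cell-means design: X is observations x cells, one 1 per row."""

    X: np.ndarray
    cells: list[tuple]                # (stimulus_type, direction, hemisphere)
    cell_of_obs: np.ndarray           # (N,) int
    obs: pd.DataFrame                 # participant, trial_id, factor columns
    blocks: np.ndarray                # (B, s) observation indices per trial

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_cells(self) -> int:
        return self.X.shape[1]

    def cell_counts(self) -> np.ndarray:
        return self.X.sum(axis=0).astype(int)


def observations_table(epochs_list, presentation: str = "first") -> pd.DataFrame:
    """One row per (participant, analysed trial, electrode).

    The direction factor is the first- or second-stimulus direction
    depending on ``presentation``; target trials are excluded.  Row order
    matches ``TFStack.images()`` applied per participant and concatenated.
    """
    col = {"first": "first_direction", "second": "second_direction"}[presentation]
    rows = []
    for ep in epochs_list:
        for _, ev in ep.events.df.iterrows():
            for ch, hemi in zip(ep.channels, ep.hemispheres):
                rows.append(dict(participant=ep.participant_id,
                                 trial_id=int(ev["trial_id"]),
                                 stimulus_type=ev["stimulus_type"],
                                 direction=ev[col], hemisphere=hemi,
                                 is_target=bool(ev["is_target"])))
    return pd.DataFrame.from_records(rows)


def build_design(obs: pd.DataFrame) -> DesignMatrix:
    """Build the 8-cell (or fewer, with one hemisphere) cell-means design.

    Raises :class:`DesignError` listing any empty cell.
    """
    obs = obs[~obs.get("is_target", pd.Series(False, index=obs.index))]
    obs = obs.reset_index(drop=True)
    if len(obs) == 0:
        raise DesignError("no analysable observations")
    levels = [tuple(lv for lv in canon
                    if lv in set(obs[fac]))
              for fac, canon in zip(FACTORS, (("eyes", "mosaic"),
                                              ("averted", "straight"),
                                              ("left", "right")))]
    for fac, lv in zip(FACTORS, levels):
        if len(lv) == 0:
            raise DesignError(f"factor {fac} has no observed levels")
    if len(levels[0]) < 2:
        missing = set(("eyes", "mosaic")) - set(levels[0])
        raise DesignError(
            f"stimulus type has a single observed level; empty cells for "
            f"{sorted(missing)}")
    cells = [(t, d, h) for t in levels[0] for d in levels[1] for h in levels[2]]
    index = {c: k for k, c in enumerate(cells)}
    keys = list(zip(obs["stimulus_type"], obs["direction"], obs["hemisphere"]))
    unknown = [k for k in keys if k not in index]
    if unknown:
        raise DesignError(f"observations outside the factor space: {set(unknown)}")
    cell_of_obs = np.array([index[k] for k in keys])
    counts = np.bincount(cell_of_obs, minlength=len(cells))
    empty = [cells[k] for k in np.where(counts == 0)[0]]
    if empty:
        raise DesignError(f"empty design cells: {empty}")
    X = np.zeros((len(obs), len(cells)))
    X[np.arange(len(obs)), cell_of_obs] = 1.0

    grp = obs.groupby(["participant", "trial_id"], sort=False).indices
    sizes = {len(v) for v in grp.values()}
    if len(sizes) != 1:
        raise DesignError(f"unequal observations per trial: sizes {sorted(sizes)}")
    blocks = np.array([np.sort(v) for v in grp.values()])
    return DesignMatrix(X=X, cells=cells, cell_of_obs=cell_of_obs, obs=obs,
                        blocks=blocks)


def covariance_components(design: DesignMatrix) -> list[tuple[str, np.ndarray]]:
    """Default covariance component set.

    One variance component per design cell plus, when trials contribute two
    hemisphere observations, a single dependence component coupling the two
    observations of each trial.  Returned as (name, Qb) with Qb of shape
    (n_blocks, s, s).
    """
    B, s = design.blocks.shape
    comps = []
    cell_b = design.cell_of_obs[design.blocks]  # (B, s)
    for k, cell in enumerate(design.cells):
        Q = np.zeros((B, s, s))
        for j in range(s):
            Q[:, j, j] = (cell_b[:, j] == k)
        comps.append(("var:" + "/".join(cell), Q))
    if s == 2:
        Q = np.zeros((B, s, s))
        Q[:, 0, 1] = Q[:, 1, 0] = 1.0
        comps.append(("cov:within-trial-hemisphere", Q))
    return comps


def identity_component(design: DesignMatrix) -> list[tuple[str, np.ndarray]]:
    B, s = design.blocks.shape
    Q = np.broadcast_to(np.eye(s), (B, s, s)).copy()
    return [("var:iid", Q)]


@dataclass
class NonSphericity:
    """ReML-estimated error covariance and its whitening transform.

    ``Vb``/``Wb`` hold the per-trial-block covariance and whitening blocks;
    V is normalized so tr(V) = N (the per-pixel residual variance carries
    the overall scale).  ``df_effective`` is the Satterthwaite effective
    error df of the whitened model.
    """

    component_names: list[str]
    lambdas: np.ndarray
    Vb: np.ndarray
    Wb: np.ndarray
    df_effective: float
    n_iter: int
    converged: bool

    def cell_variances(self, design: DesignMatrix) -> dict[tuple, float]:
        out = {}
        for name, lam in zip(self.component_names, self.lambdas):
            if name.startswith("var:") and name != "var:iid":
                out[tuple(name[4:].split("/"))] = float(lam)
        return out


def _is_pd(Vb: np.ndarray) -> bool:
    return bool(np.linalg.eigvalsh(Vb).min() > 0)


def _reml(Yb, Xb, Qs, n_pix, max_iter=200, tol=1e-6):
    """Fisher-scoring ReML on block-structured covariance components.

    Yb: (B, s, n_pix) data gathered by block; Xb: (B, s, p); Qs: list of
    (B, s, s).  Returns (lambdas, n_iter, converged, grad_norm).
    """
    B, s, p = Xb.shape
    n_q = len(Qs)
    N = B * s

    # start from the pooled OLS variance on variance-like components
    X = Xb.reshape(N, p)
    Y = Yb.reshape(N, n_pix)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    res = Y - X @ beta
    s2 = float((res ** 2).sum() / ((N - np.linalg.matrix_rank(X)) * n_pix))
    lam = np.array([s2 if np.trace(Q.sum(axis=0)) > 0 else 0.0 for Q in Qs])

    scale = max(s2, np.finfo(float).tiny)
    converged = False
    g = np.zeros(n_q)
    it = 0
    for it in range(1, max_iter + 1):
        Vb = sum(l * Q for l, Q in zip(lam, Qs))
        Vib = np.linalg.inv(Vb)
        Ab = Vib @ Xb
        M = np.einsum("bsp,bsq->pq", Xb, Ab)
        Minv = np.linalg.inv(M)
        ViY = Vib @ Yb
        AtY = np.einsum("bsp,bsn->pn", Xb, ViY)
        PYb = ViY - Ab @ (Minv @ AtY)

        QA = [Q @ Ab for Q in Qs]
        Nmat = [np.einsum("bsp,bsq->pq", Ab, qa) for qa in QA]
        D = [Vib @ Q for Q in Qs]
        for i, Q in enumerate(Qs):
            trPQ = np.einsum("bst,bts->", Vib, Q) - np.trace(Minv @ Nmat[i])
            q_dat = np.einsum("bsn,bst,btn->", PYb, Q, PYb)
            g[i] = -0.5 * n_pix * trPQ + 0.5 * q_dat
        H = np.empty((n_q, n_q))
        for i in range(n_q):
            for j in range(i, n_q):
                t1 = np.einsum("bst,bts->", D[i], D[j])
                U = np.einsum("bsp,bst,btq->pq", QA[i], Vib, QA[j])
                t3 = np.trace(Minv @ Nmat[i] @ Minv @ Nmat[j])
                H[i, j] = H[j, i] = 0.5 * n_pix * (t1 - 2 * np.trace(Minv @ U) + t3)

        try:
            dlam = np.linalg.solve(H + 1e-8 * np.eye(n_q) * H.diagonal().max(),
                                   g)
        except np.linalg.LinAlgError as exc:
            raise ReMLError(f"singular Fisher information at iter {it}: {exc}")
        step = 1.0
        for _ in range(40):
            trial = lam + step * dlam
            if _is_pd(sum(l * Q for l, Q in zip(trial, Qs))):
                break
            step /= 2
        else:
            raise ReMLError(f"cannot keep V positive definite at iter {it}")
        lam = lam + step * dlam
        if np.max(np.abs(step * dlam)) < tol * scale:
            converged = True
            break
    return lam, it, converged, float(np.linalg.norm(g) / (n_pix * scale))


def estimate_nonsphericity(Y: np.ndarray, design: DesignMatrix,
                           components: list[tuple[str, np.ndarray]] | None = None,
                           max_pixels: int = 2000, max_iter: int = 200,
                           ) -> NonSphericity:
    """ReML hyperparameter estimation pooled over (a subsample of) pixels.

    Parameters
    ----------
    Y : ndarray, shape (N, n_pixels)
        In-mask image data aligned with the design rows.
    design : DesignMatrix
    components : optional component list from :func:`covariance_components`.
    max_pixels : int
        Pixels are subsampled (evenly spaced) beyond this count; the
        pooled second moments are what ReML sees, so a few thousand pixels
        determine lambda to well under a percent.
    """
    if components is None:
        components = covariance_components(design)
    counts = design.cell_counts()
    if counts.min() < 2:
        raise DesignError("need >= 2 observations per cell for ReML")
    Y = np.atleast_2d(np.asarray(Y, float))
    if Y.shape[0] != design.n_obs:
        raise DesignError("data rows do not match design")
    if Y.shape[1] > max_pixels:
        sel = np.linspace(0, Y.shape[1] - 1, max_pixels).astype(int)
        Y = Y[:, sel]
    names = [c[0] for c in components]
    Qs = [np.asarray(c[1], float) for c in components]
    Xb = design.X[design.blocks]
    Yb = Y[design.blocks]

    lam, n_iter, converged, gnorm = _reml(Yb, Xb, Qs, Y.shape[1],
                                          max_iter=max_iter)
    if not converged:
        raise ReMLError(
            f"ReML did not converge in {n_iter} iterations "
            f"(|grad| = {gnorm:.3g}); check the component set")

    Vb = sum(l * Q for l, Q in zip(lam, Qs))
    N = design.n_obs
    tr = np.einsum("bss->", Vb)
    Vb = Vb * (N / tr)
    vals, vecs = np.linalg.eigh(Vb)
    Wb = (vecs * (1.0 / np.sqrt(vals))[:, None, :]) @ np.swapaxes(vecs, 1, 2)
    # whitened V is the identity by construction, so the Satterthwaite
    # effective df of the whitened model is N - rank(X)
    df_eff = float(N - np.linalg.matrix_rank(design.X))
    return NonSphericity(component_names=names, lambdas=lam, Vb=Vb, Wb=Wb,
                         df_effective=df_eff, n_iter=n_iter, converged=converged)


def _apply_blocks(Wb: np.ndarray, blocks: np.ndarray, Y: np.ndarray) -> np.ndarray:
    out = np.empty_like(Y, dtype=float)
    Yb = Y[blocks]
    Zb = Wb @ Yb if Y.ndim == 1 else np.einsum("bst,btn->bsn", Wb, Yb)
    out[blocks.ravel()] = Zb.reshape(-1, *Y.shape[1:])
    return out


@dataclass
class GLMFit:
    """Whitened least-squares fit of an image stack."""

    betas: np.ndarray          # (p, n_pixels)
    sigma2: np.ndarray         # (n_pixels,)
    xtx_inv: np.ndarray        # (p, p) of the whitened design
    df: float
    design: DesignMatrix
    nonsphericity: NonSphericity | None
    resid_std: np.ndarray | None = None   # standardized whitened residuals
    resid_rows: np.ndarray | None = None


def fit(Y: np.ndarray, design: DesignMatrix,
        nonsphericity: NonSphericity | None = None,
        n_resid_images: int = 64) -> GLMFit:
    """Per-pixel whitened least squares.

    ``n_resid_images`` whitened residual images (unit-normalized per pixel)
    are retained for smoothness estimation; pass ``-1`` to keep all.
    """
    Y = np.atleast_2d(np.asarray(Y, float))
    if Y.shape[0] != design.n_obs:
        raise DesignError("data rows do not match design")
    if nonsphericity is not None:
        Yw = _apply_blocks(nonsphericity.Wb, design.blocks, Y)
        Xw = _apply_blocks(nonsphericity.Wb, design.blocks, design.X)
        df = nonsphericity.df_effective
    else:
        Yw, Xw = Y, design.X
        df = design.n_obs - np.linalg.matrix_rank(design.X)
    rank = np.linalg.matrix_rank(Xw)
    if rank < Xw.shape[1]:
        raise DesignError("whitened design is rank deficient")
    xtx_inv = np.linalg.inv(Xw.T @ Xw)
    betas = xtx_inv @ (Xw.T @ Yw)
    res = Yw - Xw @ betas
    rss = (res ** 2).sum(axis=0)
    sigma2 = rss / df

    if n_resid_images == -1 or n_resid_images >= design.n_obs:
        rows = np.arange(design.n_obs)
    else:
        rows = np.linspace(0, design.n_obs - 1, n_resid_images).astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        rstd = np.where(rss > 0, res[rows] / np.sqrt(rss), 0.0)
    return GLMFit(betas=betas, sigma2=sigma2, xtx_inv=xtx_inv, df=df,
                  design=design, nonsphericity=nonsphericity,
                  resid_std=rstd.astype(np.float32), resid_rows=rows)


@dataclass(frozen=True)
class MaskSpec:
    """Inclusive mask: restrict the search region to pixels where the
    masking contrast is significant at ``p_unc`` with the given sign."""

    weights: np.ndarray
    p_unc: float = 0.05
    sign: int = 1


@dataclass(frozen=True)
class Contrast:
    weights: np.ndarray
    label: str
    mask: MaskSpec | None = None


@dataclass
class ContrastResult:
    t: np.ndarray
    df: float
    label: str
    inclusive_mask: np.ndarray | None = None
    n_zero_variance: int = 0


def contrast_map(fit_: GLMFit, contrast: Contrast) -> ContrastResult:
    """T statistic image for a cell-means contrast.

    T = c'beta / sqrt(sigma^2 c'(X'X)^-1 c) on the whitened model.  Pixels
    with zero residual variance get T = 0 and are counted in
    ``n_zero_variance``.  If the contrast carries an inclusive mask, the
    returned boolean mask marks pixels passing the mask test.
    """
    c = np.asarray(contrast.weights, float)
    if c.shape != (fit_.design.n_cells,):
        raise DesignError(
            f"contrast length {c.shape} != number of cells {fit_.design.n_cells}")
    t = _t_stat(fit_, c)
    n_zero = int((fit_.sigma2 == 0).sum())
    res = ContrastResult(t=t, df=fit_.df, label=contrast.label,
                         n_zero_variance=n_zero)
    if contrast.mask is not None:
        from scipy.stats import t as tdist
        tm = _t_stat(fit_, np.asarray(contrast.mask.weights, float))
        thr = tdist.isf(contrast.mask.p_unc, fit_.df)
        res.inclusive_mask = (contrast.mask.sign * tm) > thr
    return res


def _t_stat(fit_: GLMFit, c: np.ndarray) -> np.ndarray:
    num = c @ fit_.betas
    var_c = float(c @ fit_.xtx_inv @ c)
    if var_c == 0:
        return np.zeros_like(fit_.sigma2)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(fit_.sigma2 > 0, num / np.sqrt(fit_.sigma2 * var_c), 0.0)
    return t


def factorial_weights(cells: list[tuple], terms: dict[str, tuple[str, str]],
                      ) -> np.ndarray:
    """Main-effect / interaction weights over cell means.

    ``terms`` maps factor name to (positive level, negative level); the
    weight of a cell is the product of signs over the named factors,
    normalized by the cell count.  One factor gives a main effect, two or
    three the corresponding interaction.
    """
    fac_idx = {f: i for i, f in enumerate(FACTORS)}
    w = np.ones(len(cells))
    for fac, (pos, neg) in terms.items():
        sgn = []
        for cell in cells:
            lv = cell[fac_idx[fac]]
            if lv == pos:
                sgn.append(1.0)
            elif lv == neg:
                sgn.append(-1.0)
            else:
                sgn.append(0.0)
        w = w * np.array(sgn)
    return w / len(cells)


def explicit_mask(times_ms: np.ndarray, freqs_hz: np.ndarray | None,
                  t_window: tuple[float, float] = (0.0, 500.0),
                  f_window: tuple[float, float] = (4.0, 300.0)) -> np.ndarray:
    """Boolean search-region mask over the (frequency, time) grid.

    For time-only (ERP) images pass ``freqs_hz=None`` to get a 1-D mask.
    """
    tsel = (times_ms >= t_window[0] - 1e-9) & (times_ms <= t_window[1] + 1e-9)
    if freqs_hz is None:
        mask = tsel
    else:
        fsel = (freqs_hz >= f_window[0] - 1e-9) & (freqs_hz <= f_window[1] + 1e-9)
        mask = fsel[:, None] & tsel[None, :]
    if not mask.any():
        raise ValueError("explicit mask is empty")
    return mask


def satterthwaite_df(X: np.ndarray, V: np.ndarray) -> float:
    """Satterthwaite effective df tr(RV)^2 / tr(RVRV) of an OLS fit under
    error covariance V (dense; for cross-checks at small N)."""
    X = np.asarray(X, float)
    R = np.eye(X.shape[0]) - X @ np.linalg.pinv(X)
    RV = R @ V
    return float(np.trace(RV) ** 2 / np.trace(RV @ RV))
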