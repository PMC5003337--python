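"""1-D sensor-time SPM on event-related potentials.

Single-trial voltage traces are baseline-corrected (mean over -200..0 ms
subtracted) and entered, as one-dimensional line images, into the same
factorial GLM / non-sphericity / RFT machinery as the time-frequency maps,
with the search region restricted to 0..500 ms.  Because the ERP average
only retains phase-locked activity, random-phase (induced) oscillatory
effects present in the time-frequency arm are expected to vanish here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import glm as _glm
from . import rft as _rft
from .simulate import Epochs

__all__ = ["erp_images", "erp_spm_pipeline", "grand_averages"]


def erp_images(epochs: Epochs,
               baseline_ms: tuple[float, float] = (-200.0, 0.0),
               ) -> tuple[np.ndarray, np.ndarray]:
    """Baseline-corrected per-trial voltage traces.

    Returns (images, times_ms) with images of shape
    (trials, channels, samples); each trace has zero mean over the baseline
    window.
    """
    t = epochs.times_ms
    lo, hi = baseline_ms
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
        raise ValueError(f"baseline ({lo}, {hi}) outside epoch ({t[0]}, {t[-1]})")
    sel = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    base = epochs.data[..., sel].mean(axis=-1, keepdims=True)
    return epochs.data - base, t


def grand_averages(epochs: Epochs,
                   baseline_ms: tuple[float, float] = (-200.0, 0.0),
                   ) -> pd.DataFrame:
    """Per-condition grand-average traces (long format, per channel)."""
    imgs, t = erp_images(epochs, baseline_ms)
    rows = []
    ev = epochs.events.df
    for (stype, fdir), grp in ev.groupby(["stimulus_type", "first_direction"]):
        mean = imgs[grp.index.values].mean(axis=0)  # channels x samples
        for c, ch in enumerate(epochs.channels):
            rows.append(pd.DataFrame(dict(
                time_ms=t, amplitude_uv=mean[c], channel=ch,
                stimulus_type=stype, first_direction=fdir)))
    return pd.concat(rows, ignore_index=True)


def erp_spm_pipeline(epochs_list: list[Epochs], presentation: str = "first",
                     baseline_ms: tuple[float, float] = (-200.0, 0.0),
                     crop_ms: tuple[float, float] = (-200.0, 500.0),
                     mask_ms: tuple[float, float] = (0.0, 500.0),
                     contrasts: list[_glm.Contrast] | None = None,
                     height_p: float = 0.001, extent_fwe_p: float = 0.05,
                     use_nonsphericity: bool = True,
                     ) -> dict[str, _rft.ClusterTable]:
    """Full 1-D ERP SPM: images -> GLM -> 1-D RFT cluster tables.

    ``epochs_list`` holds (artifact-free) epochs per participant, already
    locked to the presentation of interest.  Returns one cluster table per
    contrast label.
    """
    obs = _glm.observations_table(epochs_list, presentation)
    stacks, times = [], None
    for ep in epochs_list:
        imgs, t = erp_images(ep, baseline_ms)
        sel = (t >= crop_ms[0] - 1e-9) & (t <= crop_ms[1] + 1e-9)
        stacks.append(imgs[..., sel].reshape(-1, sel.sum()))
        times = t[sel]
    Y_all = np.concatenate(stacks, axis=0)
    keep = ~obs["is_target"].values
    Y = Y_all[keep]
    design = _glm.build_design(obs)

    mask = _glm.explicit_mask(times, None, t_window=mask_ms)
    if contrasts is None:
        contrasts = default_contrasts(design)
    if not Y.any():
        return {con.label: _rft.empty_cluster_table() for con in contrasts}
    nonsph = (_glm.estimate_nonsphericity(Y[:, mask], design)
              if use_nonsphericity else None)
    fit_ = _glm.fit(Y, design, nonsph)
    resid = fit_.resid_std.reshape(fit_.resid_std.shape[0], len(times))
    smooth = _rft.estimate_smoothness(resid, pixel_size=(times[1] - times[0],),
                                      mask=mask)
    out = {}
    for con in contrasts:
        res = _glm.contrast_map(fit_, con)
        m = mask if res.inclusive_mask is None else \
            mask & res.inclusive_mask.reshape(mask.shape)
        out[con.label] = _rft.cluster_inference(
            res.t.reshape(len(times)), res.df, smooth, times, None,
            height_p=height_p, extent_fwe_p=extent_fwe_p, mask=m)
    return out


def default_contrasts(design: _glm.DesignMatrix) -> list[_glm.Contrast]:
    """The analysed contrast set: positive main effect of stimulus type and
    the interactions involving stimulus type (type x hemisphere inclusively
    masked by the positive main effect of type)."""
    cells = design.cells
    w_type = _glm.factorial_weights(cells, {"stimulus_type": ("eyes", "mosaic")})
    cons = [_glm.Contrast(w_type, "main_effect_stimulus_type")]
    cons.append(_glm.Contrast(
        _glm.factorial_weights(cells, {"stimulus_type": ("eyes", "mosaic"),
                                       "direction": ("averted", "straight")}),
        "type_x_direction"))
    hemis = {c[2] for c in cells}
    if len(hemis) == 2:
        w_th = _glm.factorial_weights(cells, {"stimulus_type": ("eyes", "mosaic"),
                                              "hemisphere": ("right", "left")})
        cons.append(_glm.Contrast(w_th, "type_x_hemisphere",
                                  mask=_glm.MaskSpec(w_type)))
        cons.append(_glm.Contrast(
            _glm.factorial_weights(cells, {"stimulus_type": ("eyes", "mosaic"),
                                           "direction": ("averted", "straight"),
                                           "hemisphere": ("right", "left")}),
            "type_x_direction_x_hemisphere"))
    return cons
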