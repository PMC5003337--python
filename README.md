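# tfspm

Time–frequency statistical parametric mapping for intracranial EEG.

`tfspm` implements the analysis chain used to ask *when* and *in which
frequency band* a cortical site responds to an experimental manipulation,
for paradigms where single-trial iEEG epochs from a small set of electrodes
are pooled across participants:

1. **Morlet decomposition** — single-trial power maps from 7-cycle complex
   Morlet wavelets (σ_t = n/2πf), computed over the full epoch, cropped to
   −200…500 ms to discard wavelet edge effects, log-transformed and
   baseline-corrected per frequency against the mean power of the −200…0 ms
   window.
2. **Mass-univariate factorial GLM** — every pixel of every trial image
   enters one fixed-effects cell-means model over stimulus type ×
   direction × hemisphere, with the pooled error from all trials of all
   participants. Error non-sphericity (unequal cell variances, within-trial
   dependence between the two hemisphere electrodes) is modelled as
   V = Σᵢ λᵢQᵢ with λ estimated by restricted maximum likelihood; data and
   design are whitened by W = V^(−1/2) before per-pixel least squares.
3. **Random-field-theory cluster inference** — SPM{T} maps are thresholded
   at p < 0.001 (uncorrected) and clusters receive family-wise-error
   corrected p-values from the expected Euler characteristic of a T field
   and the Poisson clumping heuristic, with a resels-per-pixel
   nonstationarity correction (wavelet smoothness varies strongly over the
   time–frequency plane). A trial-label permutation oracle provides an
   assumption-light cross-check.
4. **ERP arm** — the same GLM/RFT machinery on baseline-corrected 1-D
   voltage traces. Because averages only keep phase-locked activity,
   induced (random-phase) oscillatory effects appear in the TF arm but not
   here.
5. **Synthetic iEEG** — a generator emulating a two-stimulus gaze paradigm
   (eyes vs. mosaic × averted vs. straight, first/second presentation,
   1000 Hz, −1000…2000 ms epochs, one temporal-pole electrode per
   hemisphere): 1/f background, condition-dependent gamma bursts with
   per-trial random carrier phase, optional evoked deflections, and
   injectable high-amplitude artifacts. It drives every calibration and
   recovery test without requiring patient data.

Preprocessing implements the two epoch-rejection rules: any sample
exceeding ±800 μV, and per-electrode distributional outliers whose
per-trial peak amplitude exceeds the mean-or-median + 5 SD of its
across-trial distribution.

## Worked example

```python
import dataclasses
from tfspm import AnalysisConfig, default_effects, run

cfg = AnalysisConfig(seed=42, freq_step_hz=8.0, time_decim=8,
                     single_precision=True, presentations=("first",))
# eyes-only induced gamma burst at 226 ms / 121 Hz, calibrated to a
# log-power effect of 0.5 at its locus under the 1/f background
cfg = dataclasses.replace(cfg, effects=default_effects(cfg, 0.5))
results = run(cfg, "out_demo")
print(open("out_demo/report.txt").read())
```

The report renders one peak/extent table per contrast. On this seed the
main effect of stimulus type (eyes − mosaics) prints

```
[first presentation] main_effect_stimulus_type
   ----- Peak -----               ------- Extent -------
   Time    Freq       T     Time (ms)     Freq (Hz) Size (ms x Hz)   p(FWE)
    224     124    6.49       216–232       108–156           1280    0.000
```

an FWE-significant gamma-band cluster whose peak (224 ms, 124 Hz,
T ≈ 6.5) sits on the injected locus and whose extent (216–232 ms,
108–156 Hz) brackets it, while the interaction contrasts on the same data
print `none`. With `run_erp: true` the ERP tables also stay at `none` —
the induced/evoked dissociation the pipeline is designed to expose. The
same pipeline is available from the shell via `tfspm simulate /
preprocess / tfr / glm / report / run / calibrate`.

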