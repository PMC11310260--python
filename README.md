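# musuppress

A tested, reusable pipeline for mu-suppression EEG analysis:

- **synthetic** — forward-simulated EEG studies with known ground truth:
  band-limited oscillatory sources on a hemispherical mesh, an analytic
  spherical lead field, 1/f background and white sensor noise, per-condition
  amplitude gains (a gain `a` vs a gain-1 baseline implies a true
  suppression index of `2*log10(a)`), and the study block structure
  (five 24-s action clips per condition, 120-s resting blocks).
- **preprocessing** — DC removal, average reference, per-clip edge trimming
  (2 s for action clips, 10 s for rest) and concatenation into 100-s
  per-condition segments.
- **spectral** — Welch PSD (2-s Hamming windows, 50% overlap, one-sided
  density normalization) and mean band power over 8–13 Hz.
- **msi** — the Mu Suppression Index `log10(P_condition / P_baseline)`
  (negative = suppression), one-sample t-tests against zero with Cohen's d
  and 95% CIs, a fully-within-subject repeated-measures ANOVA with
  Greenhouse–Geisser correction, partial eta², a Mauchly sphericity flag,
  and the suppresser/non-suppresser median split.
- **inverse** — weighted minimum-norm source estimation with identity noise
  covariance, depth weighting, and an SNR-based default regularization.
- **clusterperm** — per-vertex paired t-maps, adjacency-based same-sign
  cluster formation at a two-sided threshold, and the sign-flip permutation
  test on the extreme cluster sum with 2.5/97.5-percentile decisions.
- **nft** — the four-band neurofeedback threshold protocol: band amplitudes
  (zero-phase band-pass + sliding RMS), the ≥1-s hold success rule,
  quantile-bisection threshold calibration to a target success range, and
  feedback-minus-baseline session summaries.
- **io / pipeline / cli** — EDF/BDF and HDF5 readers/writers, montage and
  study-manifest handling, and seeded end-to-end runs.

## Command line

```sh
# simulate a ground-truth-known study (writes recordings + manifest + model)
musuppress simulate --out study/ --subjects 16 --sessions 2 \
    --gain post/complex=0.8 --seed 1

# run the full analysis
musuppress run --manifest study/manifest.csv --model study/source_model.h5 \
    --out results/ --electrodes all --seed 1

# individual stages
musuppress preprocess --manifest study/manifest.csv --trim-action 2 \
    --trim-rest 10 --out segments/
musuppress psd --input segments/sub00_pre_balls_seg.h5 --out psd.csv
musuppress stats ttest --msi results/sensor_msi.csv --condition social
musuppress stats anova --msi results/sensor_msi.csv
musuppress stats split --msi results/sensor_msi.csv --session pre
musuppress cluster --msi results/source_msi.csv \
    --model study/source_model.h5 --condition complex --nperm 1000 --seed 7
musuppress nft calibrate --amplitudes baseline.csv --fs 256 \
    --target 0.75 0.80
```

## Conventions

Times are in seconds, sample indices are 0-based, and intervals are
half-open `[start, stop)`. EDF export is lossy by format (16-bit against a
per-channel physical range); the internal HDF5 container preserves float64
and is the format of record for intermediate artifacts.
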