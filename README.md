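# itpcdecode

Time-resolved decoding of **intertrial phase coherence (ITPC)** in
electrophysiological (MEG/EEG-style) epoch data, with LCMV beamformer
source projection, an L1-sparsified logistic-regression MVPA pipeline,
and threshold-gated permutation statistics with cluster-duration
correction.

The package is aimed at researchers who want to ask, for a binary
stimulus contrast (e.g. word vs pseudoword), *when*, *in which frequency
band*, and *where* stimulus-locked phase alignment carries enough
information to classify single conditions across subjects — without
pre-selecting regions or time windows of interest.

## The method

1. **Spectral decomposition.** Single-trial epochs are band-passed into
   five canonical bands (α 8–12, β 13–30, γ-low 30–45, γ-mid 55–70,
   γ-high 70–90 Hz) with a zero-phase FIR, and Hilbert-transformed into
   complex analytic signals. The evoked component is deliberately not
   subtracted — stimulus-locked phase alignment is the signal of
   interest.
2. **Source projection (optional).** An adaptive LCMV spatial filter is
   built from the unregularized covariance of all trials and timepoints
   (`w = (lᵀC⁻¹l)⁻¹ lᵀC⁻¹`), with per-source max-power orientation and
   neural-activity-index (NAI) weight normalization, and applied to the
   complex single-trial data.
3. **ITPC.** Per location and timepoint,
   `ITPC = |n⁻¹ Σ_r exp(i k_r)|` over the n trials of a condition —
   amplitude never enters. Per-subject, per-condition maps are smoothed
   with a 10-ms rolling mean and stacked into an across-subject dataset
   (one row per subject × condition), time-referenced to the contrast's
   divergence point (DP).
4. **Decoding over time.** Independently at each timepoint, inside
   stratified 5-fold cross-validation: z-score on the training fold,
   select features with a cross-validated Lasso (4 stratified inner
   folds over a 25-step logarithmic penalty path), fit logistic
   regression (C = 1), and score the held-out fold by ROC-AUC.
5. **Inference.** Timepoints whose mean AUC exceeds
   `baseline mean + 1.5·SD` are tested with m = 2000 label
   permutations of the full pipeline; `p = (b+1)/(m+1)`. Runs of
   consecutive significant timepoints shorter than 10 ms are discarded;
   surviving clusters are tabulated (peak %, peak SD, peak time, start,
   end, length, cluster mean, cluster SD). Haufe patterns
   (`a ∝ Cov(X)·w`) localize each cluster, with top/bottom-5% masks.

No public recordings accompany the original study design, so the
package ships a first-class synthetic-data generator that emulates its
structure — 17 subjects, stimulus conditions with 100 repetitions,
epochs −100..900 ms at 500 Hz — and injects class-conditional "phase
resetting": within a chosen band/location/window, the carrier's phase
at window onset is drawn von Mises(0, κ_class), so the expected ITPC is
the Bessel ratio I₁(κ)/I₀(κ) and every downstream stage can be checked
against ground truth.

## Worked example

```python
import numpy as np
from itpcdecode import (EffectSpec, GeneratorConfig, PipelineConfig,
                        PermutationConfig, RunConfig, run_pipeline,
                        noise_sd_for_band_snr, semantic_contrast)

gen = GeneratorConfig(
    conditions={"action_verb": "action_verb", "object_noun": "object_noun"},
    n_subjects=8, n_trials_per_condition=30, n_locations=20,
    sampling_rate=500.0, epoch_span_ms=(-100.0, 500.0),
    effects=(EffectSpec(band="gamma_low", locations=(0, 1, 2, 3, 4),
                        window_ms=(400.0, 450.0),        # 100-150 ms post-DP
                        kappa_by_class={"action_verb": 4.0},
                        carrier_freq=40.0),),
    noise_sd=noise_sd_for_band_snr("gamma_low", 500.0),  # ~0 dB in-band SNR
    seed=7)
cfg = RunConfig(seed=7, out_dir="runs/demo", bands=("gamma_low",),
                contrast=semantic_contrast(dp_ms=300.0), generator=gen,
                decim=5, pipeline=PipelineConfig(n_alphas=10, seed=7),
                permutation=PermutationConfig(n_perm=200, seed=7))
print(run_pipeline(cfg)["clusters"].to_string(index=False))
```

prints a cluster table such as

```
     Band  Peak (%)  Peak SD (%)  Peak time (ms)  Cluster start (ms)  Cluster end (ms)  Cluster length (ms)  Cluster mean (%)  Cluster SD (%)
gamma_low     100.0          0.0           110.0                90.0             160.0                 70.0            98.125        2.795085
```

i.e. the injected 100–150 ms post-DP phase reset in the low-gamma band
is recovered as a significant decoding cluster around 90–160 ms (the
10-ms feature smoothing and band-filter ringing widen it slightly);
`Peak (%)` is the cross-validated ROC-AUC at the best timepoint and the
SD columns summarize variability across the five folds. The run
directory additionally holds the AUC/p curves (`curve_<band>.tsv`),
per-cluster Haufe pattern maps (`patterns_<band>_<k>.tsv`), a `run.log`,
and a `manifest.json` from which `itpcdecode run-all manifest.json`
reproduces every table bit-identically.

The same pipeline is available from the shell:

```bash
itpcdecode run-all config.yaml          # simulate/load -> decode -> clusters
itpcdecode simulate config.yaml --out sim/
itpcdecode decode config.yaml --band gamma_low
itpcdecode report runs/demo
```

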