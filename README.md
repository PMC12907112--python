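# tgdecode

Cross-task temporal-generalization decoding for epoched EEG, built around
the question of whether the P300 elicited by oddball target detection and
the P300 elicited by n-back working-memory updating reflect a shared neural
representation.  A linear classifier trained to separate rare targets from
frequent standards at each time point of one task is tested at every time
point of the other; above-chance transfer, concentrated in the P300 window
and over parietal/occipital sensors, is the signature of a shared code.

The package is aimed at EEG researchers who want this analysis as tested,
reusable, seedable code: a synthetic epoched-EEG generator that emulates
the two-task study design stands in for the original recordings, so the
entire chain — preprocessing, decoding, cluster statistics, ERP layer — is
verifiable end to end without any download.

## What it computes

- **Time-resolved decoding** per subject: under-sample to balance classes,
  average every k = 4 trials into pseudo-trials, 4-fold stratified CV with
  a linear SVM (C = 1) on z-scored channel patterns at each time point,
  averaged over 100 repetitions; chance = 0.5.
- **Temporal generalization**: the train × test time accuracy matrix; its
  diagonal reproduces the time course exactly under a shared seed.
- **Cross-task transfer**: train on all pseudo-trials of one task, test on
  the other, both directions; the shared-representation matrix is
  `(A + Bᵀ)/2`.
- **Cluster-based permutation tests**: max-statistic sign-flip null for
  time courses (1-D), generalization matrices (2-D, orthogonal adjacency)
  and sensor space (Delaunay-triangulation adjacency, ≥2 electrodes,
  two-sided); Bonferroni α/6 for the six electrode networks.
- **ERP statistics**: P300 window means (oddball 250–650 ms, n-back
  300–750 ms), paired t with Cohen's d = t/√n and 95% CI
  d ± t₀.₉₇₅,ₙ₋₁/√n, one-way repeated-measures ANOVA with
  Greenhouse–Geisser correction and Bonferroni post hocs.
- **Synthetic study generator**: 26 subjects, 28-channel 10-5 montage,
  −200..1000 ms epochs at 200 Hz, exact-count 30% target allocation per
  20-trial series, planted P300-like component (400 ms oddball / 550 ms
  n-back latency), AR(1) × spatially correlated noise, and a matched null
  mode for type-I-error calibration.

## Worked example

Simulate two subjects, preprocess, and decode the oddball contrast:

```python
import numpy as np
import tgdecode as tg
from tgdecode.epochs import (baseline_correct, common_average_reference,
                             downsample_pairs, EpochsSet)

cfg = tg.default_sim_config(seed=7, n_subjects=2)
cfg.trial_counts = {"oddball": {"oddball": 107, "standard": 249}}
study = tg.simulate_dataset(cfg)

e = study["sub-01"]["oddball"]
e = downsample_pairs(common_average_reference(baseline_correct(e)))

def cond(e, name):
    d = e.select(name)
    return EpochsSet(d, e.times, e.sfreq, e.channels,
                     np.full(len(d), name, dtype=object), e.subject)

res = tg.decode_timecourse(cond(e, "oddball"), cond(e, "standard"),
                           tg.DecodingConfig(n_reps=20, seed=1))
peak = res.accuracy.argmax()
print(f"peak accuracy {res.accuracy[peak]:.3f} at {res.times[peak]:.0f} ms")
```

```
peak accuracy 0.736 at 402 ms
```

The planted P300-like component (amplitude 3.536 µV for targets vs
1.250 µV for standards, centred at 400 ms) is recovered as a decoding peak
of ~0.74 at 402 ms — inside the 0.7–0.9 single-subject range the
generator is calibrated to (individual subjects vary with their simulated
component gain).  Group-level significance of such curves (or
of cross-task shared matrices) is then assessed with
`tg.one_sample_cbpt(stacked_accuracies, chance=0.5, config)`, and peaks
are extracted from the largest significant cluster with
`tg.peak_accuracy_latency`.

The full configuration-driven pipeline (simulate → preprocess → within-task
→ cross-task over 6 condition pairs × 7 electrode sets → cluster stats →
ERP tables → hashed manifest) runs from the shell:

```bash
tgdecode all -c config.yaml     # subcommands: simulate, preprocess,
                                # decode, tga, crosstask, cbpt, erp,
                                # report, all
```

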