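# eegnda

Noise data augmentation for multi-label EEG action classification — and
what it does to the metrics.

Brain–computer interfaces record multi-channel EEG (here: 32 channels at
500 Hz, grasp-and-lift style) in which six hand-action events
(`HandStart`, `FirstDigitTouch`, `BothStartLoadPhase`, `LiftOff`,
`Replace`, `BothReleased`) are marked by binary trigger series of ~0.3 s
(150 samples) per event, partially overlapping. This package implements,
as a tested and reusable pipeline, a study of two noise-augmentation
mechanisms for classifying those events:

- **Natural noise augmentation**: each training example is a window of
  *N* samples drawn at a random position of the timeline; its 6-bit label
  is the trigger state at one index inside the window,
  `start + ⌊offset·(N−1)⌋` with offset ∈ {0, 0.5, 1}. Growing *N* dilutes
  the action signal with neighboring, action-irrelevant EEG; edge offsets
  (0 and 1) additionally cut off part of the action-related activity.
- **Synthetic noise augmentation**: additive i.i.d. Gaussian noise
  ε ~ N(0, σ²) on the normalized signal, X̃(t) = X(t) + ε(t), with
  σ ∈ {0.001, 0.01, 0.1, 0.2}.

For every (N, offset, σ) cell a small CNN — three conv stages of
32/64/128 filters with kernels 3/5/7 along time, batch norm, max pooling
and dropout 0.1, then dense layers into 6 sigmoid outputs — is trained
for a single epoch with best-loss/best-accuracy checkpointing, and scored
by per-class, micro and macro ROC-AUC. AUC-vs-N curves are summarized by
steady-region statistics (mean ± std, max, range) and LOWESS smoothing,
and their fluctuation structure is characterized by detrended fluctuation
analysis: F(n) ∝ n^H, with Hurst exponents H_full, H_low (scales
< 1000 samples ≈ 2 s) and H_high (scales > 1000). A synthetic generator
reproduces the structural facts of the real data (event durations,
overlap of FirstDigitTouch/BothStartLoadPhase, anticipatory pre-onset
activity, 1/f background), so every claim is testable end to end without
the external dataset; an exact fractional-Gaussian-noise generator
validates the Hurst estimator.

The CNN, including backward passes and Adam, is implemented directly on
numpy arrays and verified by numerical gradient checks.

## Worked example

```python
from dataclasses import replace
import numpy as np
from eegnda import demo_config, run_sweep, run_dfa_stage

cfg = replace(demo_config(master_seed=1), n_grid=(300, 600), sigmas=(0.0,))
records = run_sweep(cfg)
for offset in cfg.offsets:
    aucs = [r.macro_auc for r in records
            if r.checkpoint == "best_loss" and r.offset == offset]
    print(f"offset {offset:>3}: macro AUC {np.mean(aucs):.3f} "
          f"(N=300: {aucs[0]:.3f}, N=600: {aucs[1]:.3f})")

table, _ = run_dfa_stage(cfg, sigmas=(0.0, 0.2))
print(table.to_string(index=False))
```

Output (a few minutes on one CPU):

```
offset 0.0: macro AUC 0.886 (N=300: 0.921, N=600: 0.852)
offset 0.5: macro AUC 0.948 (N=300: 0.932, N=600: 0.965)
offset 1.0: macro AUC 0.847 (N=300: 0.923, N=600: 0.771)

             class  sigma  hurst_full  hurst_low  hurst_high
         HandStart    0.0        0.87       0.94        0.71
         HandStart    0.2        0.77       0.83        0.74
   FirstDigitTouch    0.0        0.75       0.76        0.72
   FirstDigitTouch    0.2        0.72       0.72        0.77
BothStartLoadPhase    0.0        0.75       0.76        0.72
BothStartLoadPhase    0.2        0.72       0.72        0.72
           LiftOff    0.0        0.93       0.94        0.80
           LiftOff    0.2        0.83       0.83        0.77
           Replace    0.0        0.87       0.91        0.62
           Replace    0.2        0.77       0.79        0.72
      BothReleased    0.0        0.94       0.98        0.95
      BothReleased    0.2        0.82       0.82        0.88
```

Reading it: labeling windows at their midpoint (offset 0.5) yields the
highest macro AUC, and the gap to the edge offsets widens with N — at
N = 600 an edge-labeled window carries up to 0.6 s of signal-free
neighborhood on the labeled side. In the DFA table, per-action series are
more complex at short scales than long ones (H_low > H_high for most
rows), and σ = 0.2 noise pulls the short-scale exponents down toward the
uncorrelated value 0.5.

The same stages are scriptable from a shell:

```sh
eegnda simulate --out-prefix /tmp/toy --seed 3 --duration 90 --trials-per-class 12
eegnda sweep --data-csv /tmp/toy_data.csv --events-csv /tmp/toy_events.csv \
             --demo-scale --out /tmp/results.csv
eegnda summarize --records /tmp/results.csv --out-dir /tmp/tables
eegnda dfa --synthetic --seed 3 --out /tmp/dfa.csv
eegnda demo --seed 1 --out-dir /tmp/demo   # end-to-end reduced-scale run
```

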