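# lotra

**Local Topological Recurrence Analysis for biomedical time series.**

Recurrence analysis asks when the trajectory of a dynamical system returns
near a previous state. The classical tool thresholds the phase-space
distance matrix, `R_ij = Θ(ε − ‖V_i − V_j‖)`, which throws away every
distance relation except "closer than ε" — a real loss when the
discriminating signal lives in the *shape* of the trajectory (curvature,
directionality) rather than in raw proximity. LoTRA keeps that information:
each cell of the distance matrix is replaced by an 8-bit local-binary-pattern
code,

    code(i,j) = Σ_{n=1..8} s(g_n − g_0) · 2^(n−1),   s(u) = 1 iff u ≥ 0,

comparing the cell `g_0 = D_ij` with its eight neighbors in the 3×3
neighborhood. The 256 codes grade the local topology of the trajectory
without any threshold; the middle code band (64–191) marks high-curvature
structure and yields a binary sparse matrix from which the classical
recurrence statistics (RR, DET, L, Lmax, DIV, ENT, LAM, TT, Vmax) are
extracted.

The package is aimed at people analyzing physiological time series —
digitized handwriting/drawing tests, wearable gait sensors, fiber
photometry — and provides:

* time-delay embedding with AMI/FNN parameter selection (`lotra.embedding`),
* distance matrices, the LoTRA code transform, code-band masks, classical
  recurrence matrices and recurrence-rate-targeted threshold calibration
  (`lotra.core`),
* recurrence quantification of any binary matrix (`lotra.rqa`),
* benchmark simulators: sine, Lorenz attractor, and a synthetic labeled
  spiral-drawing cohort (`lotra.simulate`),
* an end-to-end nested-LOOCV SVM classifier over the 9-feature recurrence
  vector (`lotra.ml`),
* readers, preprocessing, plotting and a CLI (`lotra.io`, `lotra.cli`).

## Worked example

```python
import numpy as np
from lotra import (
    CohortSpec, EmbeddingParams, build_feature_table, calibrate_epsilon,
    code_band_mask, delay_embed, distance_matrix, lotra_transform,
    nested_loocv, recurrence_matrix, rqa_features, sine_series,
    synthetic_cohort,
)

sine = sine_series()                       # 300 samples of sin(u), u = 0.1..30
traj = delay_embed(sine, EmbeddingParams(delay=15, dimension=2))
D = distance_matrix(traj)
codes = lotra_transform(D)
print("trajectory:", traj.points.shape, "codes:", codes.codes.shape)

band = code_band_mask(codes)               # high-curvature codes 64..191
print("band occupancy: %.4f" % band.entries.mean())

cal = calibrate_epsilon(D, target_rr=0.045)
feats = rqa_features(recurrence_matrix(D, cal.epsilon))
print("epsilon=%.4f  RR=%.4f  DET=%.4f  ENT=%.4f"
      % (cal.epsilon, feats.rr, feats.det, feats.ent))

series, labels = synthetic_cohort(CohortSpec(n_per_class=10, seed=7))
table = build_feature_table(series, labels)
report = nested_loocv(table, seed=7)
print("cohort accuracy=%.3f  sensitivity=%.3f  specificity=%.3f"
      % (report.accuracy, report.sensitivity, report.specificity))
```

prints

```
trajectory: (285, 2) codes: (283, 283)
band occupancy: 0.0248
epsilon=0.1371  RR=0.0450  DET=1.0000  ENT=2.7073
cohort accuracy=1.000  sensitivity=1.000  specificity=1.000
```

Reading the numbers: the 300-sample sine embedded at delay 15 gives a
285-point planar trajectory and a 283×283 code matrix (borders have no full
3×3 neighborhood). Only ~2.5% of codes fall in the high-curvature band —
this embedding is nearly circular, so vertices are rare; the same signal
embedded at delay 3 puts ~23% of codes there, which is how LoTRA separates
trajectories that calibrated recurrence plots cannot (their RR is pinned to
4.5% by construction). The calibrated threshold 0.1371 achieves RR = 0.0450
exactly; DET = 1 and a moderate line-length entropy are what a noiseless
periodic signal should give. On a synthetic 20-subject drawing cohort with a
visible planted tremor, the nested leave-one-out SVM recovers every subject.

The same pipeline from a shell:

```sh
lotra simulate sine -o sine.csv
lotra embed -i sine.csv --delay 15 --dimension 2 -o traj.csv
lotra transform -i traj.csv -o codes.csv --mask-output mask.txt
lotra rqa -i codes.csv --codes -o features.csv
lotra plot --codes codes.csv -o codes.png
```

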