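# Methods

## The LoTRA transform

Classical recurrence analysis embeds a scalar series
`x = (x_1, …, x_n)` in an m-dimensional phase space
(`V_i = (x_i, x_{i+t}, …, x_{i+(m−1)t})`), computes the pairwise Euclidean
distance matrix `D_ij = ‖V_i − V_j‖`, and thresholds it:
`R_ij = Θ(ε − D_ij)`. The threshold discards everything about the local
geometry of the trajectory except "closer than ε".

Local Topological Recurrence Analysis (LoTRA) replaces the threshold with a
local-binary-pattern code. Each interior cell of `D` is compared with its
3×3 neighborhood and assigned

    code(i, j) = Σ_{n=1..8} s(g_n − g_0) · 2^(n−1),   s(u) = 1 iff u ≥ 0,

where `g_0 = D_ij` and `g_1..g_8` are the eight connected neighbors. The
256 possible codes encode the inequality pattern of the neighborhood —
curvature and directionality of the trajectory around the point pair —
without discarding any cell. Ties count as ≥ (so a constant neighborhood
codes as 255, and the line of identity always codes as 255: its center
distance is 0 and no distance is negative).

**Neighbor order.** "Circling the center" fixes the code only up to the
starting corner and the direction of travel, and axis conventions (matrix
rows grow downward, plot axes grow upward) make a verbal rotation direction
ambiguous. We fix, once, the enumeration

    g1=(i−1,j−1), g2=(i−1,j), g3=(i−1,j+1), g4=(i,j+1),
    g5=(i+1,j+1), g6=(i+1,j), g7=(i+1,j−1), g8=(i,j−1)

starting at the preceding-time corner, bit `n` weighted `2^(n−1)`. Any
other circular enumeration is a fixed permutation of the bit positions;
aggregate statistics built from code bands and masks are unchanged up to
relabelling of band boundaries, but exact code values depend on this
choice, which is why it is pinned and exported as
`lotra.core.NEIGHBOR_OFFSETS`. A useful consequence that the test-suite
checks: for symmetric `D`, `code(j, i)` is `code(i, j)` with each
neighbor offset transposed (bits 0..7 permuted to 0,7,6,5,4,3,2,1).

**Border policy.** Codes are computed only where the full 3×3 neighborhood
exists, so an `N×N` distance matrix yields an `(N−2)×(N−2)` code matrix;
no padding distances are invented. The stored `index_offset = 1` aligns
code cell `(i, j)` with distance cell `(i+1, j+1)`.

**High-curvature band.** Codes 64–191 (the middle two quartiles: bit 7 and
bit 6 disagree about the neighborhood) concentrate at trajectory vertices.
`code_band_mask` with this default band turns a code matrix into a binary
sparse matrix used for feature extraction. The quartile rendering maps
the outer quartiles ([0,63], [192,255] — shallow curvature and
directionality ribboning) to black/blue and the inner band to red/green by
default; the palette is a parameter.

## Recurrence quantification

`rqa_features` reduces any binary matrix to nine statistics, the classical
RQA set:

| statistic | definition |
|---|---|
| RR | density of ones, `(1/N²) Σ R_ij` |
| DET | fraction of run points on diagonal lines of length ≥ `l_min` |
| mean L, Lmax | mean/max diagonal line length (lines ≥ `l_min`) |
| DIV | `1/Lmax` |
| ENT | Shannon entropy `−Σ p(l) ln p(l)` of the diagonal-line length distribution, `p(l) = P(l)/N_l` over `l ≥ l_min`, in nats |
| LAM, TT, Vmax | the analogous vertical-run statistics (laminarity, trapping time, longest vertical) |

`l_min = v_min = 2` by default (two points define a line). Maximal runs
are counted on every diagonal of both triangles; the line of identity is
excluded by default for thresholded matrices (standard practice — its
trivial self-recurrences would dominate the line statistics) and is absent
from high-curvature band masks anyway, since the diagonal codes are all
255. Runs touching the matrix border count at their observed length; no
censoring correction is applied. Degenerate cases are defined to keep
feature vectors finite: ENT = 0 when no line reaches `l_min` or all lines
share one length, and every ratio with an empty denominator is reported as
0 with a note on the feature object. A corollary worth knowing: an
all-ones `N×N` matrix has DET = (N²−2)/N², not 1, because the two corner
diagonals are single cells.

## Threshold calibration

For comparisons against classical recurrence plots the threshold ε is not
set by hand but calibrated to a target recurrence rate: 4–5% for
periodic/gait-like signals, ~2% for aperiodic physiological signals.
`calibrate_epsilon` searches the sorted unique off-diagonal distances and
returns the smallest ε whose RR (diagonal included) reaches the target —
exact on the empirical distance spectrum, no bisection error; the achieved
rate is returned alongside and recomputing the recurrence matrix at the
returned ε reproduces it exactly. The achievable rates are discrete
(steps of `2·multiplicity/N²`), so the achieved rate can exceed the target
by up to one spectrum step; with a few hundred points the granularity is
far below a percentage point. An optional Theiler window excludes the
near-diagonal band from the candidate pool (default off).

## Embedding parameter selection

Delay `t`: first strict local minimum of the average mutual information
profile, falling back to the first lag whose relative change drops below
`level_off_frac` (default 0.05). AMI is estimated with an equal-width 2-D
histogram; the default bin count is `max(8, ⌊n^{1/3}⌋)`. The cube-root
rule is deliberate: the plug-in MI estimate has positive bias of order
`bins²/(2n)`, and a √n rule would put ~0.5 nats of bias on a
10 000-sample series — larger than the structure being measured — whereas
the cube-root rule keeps it near 0.02 nats. Scores are in nats; lag 0
equals the marginal-entropy estimate and bounds the profile.

Dimension `m`: the fraction of false nearest neighbors per dimension with
the classical criteria — distance-ratio tolerance `r_tol = 15` and
attractor-size tolerance `a_tol = 2` (attractor size = series standard
deviation) — choosing the first `m` below the floor (default 0.05), else
the first level-off. Neighbor searches use a k-d tree; only points that
remain valid in dimension `m+1` enter the dimension-`m` census. Which
rule fired is recorded on the returned `EmbeddingParams`.

Multi-channel series that are already a state-space sample (tablet x/y/
pressure) are used as-is (`dimension = 1` returns channels unchanged);
AMI/FNN operate on a selectable single channel (first by default).

## Simulators and what they stand for

* **Sine** — 300 samples of `sin(u)`, `u = 0.1, 0.2, …, 30`. The three
  benchmark 2-D embeddings `t = 15, 20, 3` give trajectories of
  increasing eccentricity; their LoTRA code histograms separate cleanly
  (high-curvature band occupancy ≈ 2.5%, 9.4%, 23.5%) while their
  calibrated recurrence matrices are pinned to the same RR by
  construction — the core of the claim that the codes retain information
  thresholding destroys.
* **Lorenz** — `dx = σ(y−x), dy = x(r−z)−y, dz = xy−βz` with `r = 28,
  σ = 15, β = 8/3` (σ as printed, not the classical 10), integrated by
  fixed-step RK4 at `Δt = 0.025`. The integrator is chosen for bit-exact
  determinism at the stated step; the convergence test verifies 4th-order
  behavior. Initial state and duration are not pinned by the benchmark
  description; defaults are `(1, 1, 1)` and 4000 steps with an optional
  burn-in discard. Analyses here use 1500 steps with a 200-step burn-in
  (N = 1300), enough for both attractor wings to be visited while keeping
  the N² distance matrix small.
* **Synthetic cohort** — a stand-in for digitized spiral-drawing tests
  (real cohorts are human data and not redistributable). Controls trace
  an Archimedean spiral `r = aθ` (3 turns, 256 samples ≈ 10 s) in x/y
  with a smooth pressure plateau and Gaussian jitter (σ = 0.05 tablet
  units). Patients add an action-tremor oscillation — 5 Hz, amplitude
  0.5 units ≈ 2.6% of the spiral extent, i.e. a clearly visible tremor
  at the 4–6 Hz band typical of parkinsonian action tremor — and
  intermittent pressure drops whose depth scales with the tremor
  amplitude, so a zero-amplitude cohort is distributionally identical to
  controls. The generator reproduces the *feature geometry* the pipeline
  exploits (extra vertices in phase space, laminar pressure episodes),
  not the kinematics of real handwriting: passing the end-to-end test
  shows the pipeline recovers a planted effect of realistic size, not
  that it reaches any particular accuracy on clinical data.

## Classifier

Per subject: per-channel z-score → distance matrix → LoTRA → band mask
(64–191) → 9 features. Channel z-scoring makes features invariant to
device gain/offset per channel. Evaluation is nested leave-one-out: the
outer loop holds out one subject; the inner leave-one-out over the rest
scores every `(C, γ)` of an RBF SVM grid (`C ∈ {0.1, 1, 10, 100}`,
`γ ∈ {0.01, 0.1, 1, 10}`, applied to feature vectors standardized inside
each training split); ties break toward the smallest `C`, then smallest
`γ`; the winner is refitted on the outer-training set to predict the
held-out subject. The held-out subject influences neither scaling nor
selection — the suite checks this by corrupting a held-out row and
asserting the fold's chosen hyperparameters do not move. Classes are
unweighted. The kernel and grid are package defaults, exposed as
parameters.

One evaluation caveat is documented rather than hidden: under the null
(no class signal), leave-one-out accuracy is biased *below* chance on
balanced labels (the anti-learning artifact), so permutation controls are
asserted one-sided (no significant skill) at the unit level, while the
zero-effect cohort check uses the two-sided binomial 95% interval and
passes.

The headline diagnostic rates of the published spiral-test classifier
follow algebraically from a single confusion matrix. Exhaustive search
over all matrices with ≤ 100 subjects that reproduce all five printed
rates (accuracy 98.6, sensitivity 100, specificity 93.3, precision 98.2,
F1 99) pins the control side exactly — FN = 0, FP = 1, TN = 14 — and
determines TP to within printed rounding ({54, 55, 56}); TP = 55
(70 subjects) is used. `classification_metrics` reproduces all five rates
from it.

## Preprocessing utilities

* Spiral-file reader: semicolon-delimited
  `X;Y;Z;Pressure;GripAngle;Timestamp;TestID` by default, schema fully
  remappable; strict mode raises on a malformed line with its line
  number, lenient mode skips and logs; optional filtering to the dynamic
  test via the test-id column.
* `standardize_series`: keep every k-th sample (k = 3 or 4 to equalize
  heterogeneous sampling rates; the per-file assignment is configuration,
  not inference), then per-channel z-score.
* `detrend_photometry`: per channel, subtract a least-squares quadratic in
  time (bleaching correction), then z-score by the baseline window's mean
  and standard deviation. A channel fitted exactly (e.g. constant) leaves
  only rounding noise; a relative floor on the baseline standard
  deviation turns that into an error instead of a division by ~1e−16.

## Numerical choices

* Distance matrices mirror the computed upper triangle, so symmetry is
  bit-exact and the code-transpose permutation property holds exactly.
* Codes are small integers (`int16`); band masks are `uint8`.
* The tie rule `s(0) = 1` is applied literally; with continuous-valued
  signals ties off the diagonal have measure zero, but constant segments
  make them real, and the rule keeps those cases deterministic.
* All randomness flows from explicit integer seeds
  (`numpy.random.default_rng`); simulators are bit-reproducible per seed.

## Known limitations

* Exact code values depend on the pinned neighbor enumeration; compare
  code matrices across implementations only after matching it.
* AMI/FNN defaults (histogram bins, Kennel constants, level-off
  thresholds) are standard but not canonical; embedding parameters chosen
  for borderline signals can move with them.
* The 9-feature composition is the classical RQA set; other reasonable
  sets exist and the extraction is parameterized accordingly.
* The cohort generator is synthetic; results on it bound nothing about
  clinical data (see above).
* No windowed/epoch RQA, recurrence networks, rotation-invariant LBP
  variants or multi-class classification.
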