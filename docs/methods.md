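# Methods

This note documents the models, parameter choices and numerical decisions
behind `gaitspm`, and what the synthetic-data experiments do and do not
demonstrate about real recordings.

## Signal model and processing chain

Surface EMG is treated as an amplitude-modulated broadband carrier: the
quantity of physiological interest is the low-frequency modulation (the
"linear envelope"), not the carrier. The chain is:

1. **Band-pass 20–500 Hz**, Butterworth, design order 5, applied
   forward–backward. Zero-phase application is chosen because burst
   timing is an endpoint of the analysis; a causal filter would delay
   onsets by several milliseconds. Forward–backward filtering doubles the
   effective order; "order 5" names the per-pass design.
2. **Rectification** as the magnitude of the analytic signal
   (Hilbert transform). For a pure tone this equals the instantaneous
   amplitude exactly, which is what makes the envelope examples testable
   against closed forms.
3. **Envelope smoothing**: low-pass Butterworth at 6 Hz, order 4,
   zero-phase. Gait EMG modulation lives below ~6 Hz at ordinary walking
   speeds. Zero-phase smoothing can produce tiny negative excursions next
   to sharp transients; these are clipped to 0 to preserve the envelope's
   non-negativity invariant (the clipped magnitudes are ~1e-15 of signal
   scale and do not affect results).
4. **Cycle segmentation** at heel strikes (footswitch rising edges for
   EMG; shank-gyro events for kinematics). Cycle k is `[HS_k, HS_{k+1})`.
5. **Time normalization** to a fixed 101-node grid (0, 1, …, 100 % of the
   cycle) by linear interpolation, the convention of 1D SPM gait
   analyses: node counts must agree across subjects for waveform-level
   inference, and 101 nodes keeps node index = % cycle.
6. **Amplitude normalization** per subject, per muscle, across that
   subject's included cycles (default 20): divide by the single maximum
   over all cycles (`max` mode), or by the median of per-cycle maxima
   (`median` mode, robust to a single outlier cycle inflating the
   reference). Normalization is per subject rather than pooled across a
   group: pooling would let one subject's gain determine every subject's
   scale, and relative (within-subject) intensity is the interpretable
   quantity under surface-EMG gain uncertainty.

## Co-contraction

`CCI_i = (LEMG_i / HEMG_i) (LEMG_i + HEMG_i)` on amplitude-normalized
curves; the less/more-active roles are resolved **per node**, because the
formula indexes by node — a pair can swap dominance within the cycle.
When both inputs are zero at a node the formula is 0/0; the limit of
`L/H·(L+H)` as both go to zero with `L ≤ H` is 0, so CCI is defined as 0
there. Inputs outside [0, 1] (beyond 1e-9) raise, signalling
un-normalized data rather than silently producing out-of-range indices.

The SOL/LG slope ratio fits least-squares lines to both mean envelopes
over cycle nodes `[0, stance_end/2]` and reports the slope quotient. It
is computed on the subject's mean cycle (not per cycle then averaged):
the mean-curve slope is the per-cycle average of slopes up to cycle-time
weighting, and the mean curve is the representation used everywhere else.

## Burst detection

The detector clusters the **rectified, unsmoothed** amplitude series into
k = 3 clusters; the lowest cluster is inactivity, and maximal runs of
samples in the two upper clusters form bursts. Operating on the
unsmoothed series is deliberate: the 5 ms discard rule below is
meaningless on a 6 Hz-smoothed envelope (whose fluctuations are two
orders of magnitude slower), and only the unsmoothed series can produce
the sub-10 ms spurious bursts the rule exists to remove. The 6 Hz
envelope can be substituted via configuration.

The 1D k-means is solved **exactly**: optimal k-means clusters in one
dimension are contiguous in sorted order, so the minimum
within-cluster sum of squares is found by dynamic programming over split
positions (divide-and-conquer on the monotone optimal-split structure,
O(k n log n)). This is deterministic by construction — no random
initialization, no local optima — and agrees with exhaustive search on
small instances by theorem, which the test suite verifies empirically.

Cleaning applies two rules in a fixed order: (1) discard bursts
shorter than 5 ms; (2) merge bursts separated by gaps shorter than
125 ms. The order matters — a 4 ms blip between two long bursts is
removed before it can bridge them — and the operation is idempotent.

Per cycle, the **primary burst** is the longest interval overlapping the
cycle; a burst that spans heel strike reports its onset in late % and
offset in early %, and means over cycles use circular statistics with
period 100 % so (95 %, 10 %) averages do not collapse to ~50 %. Duration
is averaged linearly. Rectus femoris optionally reports a second burst:
a distinct interval whose midpoint falls in the stance-to-swing
transition window (default 45–75 % of the cycle).

## Kinematics

Segment orientations are unit quaternions; the ISB axis convention is
used (x anteroposterior, y vertical, z mediolateral), so the sagittal
segment angle is the z rotation of an intrinsic Z–Y–X Euler
decomposition. Neutral-stance calibration takes the quaternion mean
(eigenvector method) over a 10 s quiet-standing window. The stillness
check compares the mean orientations of the two window halves and
rejects drifts above 5°/s: a per-sample angular-velocity check would
false-alarm on sensor noise (1° sample noise at 75 Hz looks like 75°/s),
whereas half-window means average it away.

Joint angle = distal minus proximal sagittal segment angle, sign-fixed
per joint (hip/knee flexion and ankle dorsiflexion positive; signs in
`kinematics.JOINT_SIGNS`), low-passed at 10 Hz (order 4, zero phase).

Gait events come from the shank angular velocity about z: mid-swing is a
prominent positive peak (height and prominence ≥ 50°/s, minimum
separation 0.5 s — suited to 0.8–1.4 m/s walking); heel strike is the
deepest local minimum within the separation window after each peak, and
toe-off the deepest local minimum between the preceding heel strike and
the peak. Height is required in addition to prominence because the
stance plateau between the two dips is itself "prominent" without being
a swing peak; "deepest in window" is preferred over "first after peak"
because the latter is fragile against small ripples.

Temporal parameters: mean velocity = distance / total time; cycle-time
CV uses the sample SD (ddof = 1, configurable); stance % is the toe-off
position within its cycle; ROM is max − min of the mean normalized
angle cycle (invariant to additive offsets by construction).

The flexion-plane identification maneuver used with real sensors
(a sequence of independent segment flexions) is not modelled: synthetic
streams are generated with rotation confined to the mediolateral axis,
and calibration reduces to static axis reset. Analyses of real IMU data
would need that functional alignment step before this chain applies.

## Waveform inference

Two-sample pointwise t with pooled variance, df = nA + nB − 2. The
family-wise error over the correlated 101-node curve is controlled with
1D random field theory:

- Smoothness (FWHM in nodes) is estimated from the variance-normalized
  residual gradients (the standard gradient estimator); resels
  R = (Q − 1)/FWHM.
- The critical threshold solves
  `P(T > u) + R·ρ₁(u) = α/2` per tail (two-tailed on |t|), with ρ₁ the
  1D EC density of a t field. As R → 0 this reduces to the ordinary t
  quantile (verified to 1e-3), and the threshold is monotone decreasing
  in FWHM.
- Cluster p-values use the standard exponential approximation: expected
  cluster count `E[m] = R·ρ₁(u)`, expected supra-threshold extent
  `E[N] = Q·P(T > u)`, extent survival `exp(−k·E[m]/E[N])`, and
  `p = 1 − exp(−E[m]·P(extent ≥ k))`. Interpolated (sub-node) cluster
  extents are not used.
- Per cluster, the mean pointwise Cohen's d over the cluster's nodes is
  reported as the effect-size summary.
- Degenerate inputs: identical groups return a flat zero field with no
  clusters; zero-variance nodes are masked with a warning; a residual
  field too rough for any threshold below t = 50 disables supra-threshold
  inference with a warning rather than failing the whole comparison.

Calibration was checked by simulation: on 1000 null datasets (n = 13 vs
14 subjects, smooth Gaussian fields of FWHM 20 nodes) the family-wise
supra-threshold rate is 0.049 at α = 0.05; the test suite re-runs this
check. Detection of a +1 SD difference injected over 20–40 % of the
cycle at the same group sizes runs at ≈ 0.79 one-tailed (consistent with
the 0.80 design power of the scalar noncentral-t computation) and ≈ 0.68
two-tailed — waveform-level RFT correction costs power relative to an
uncorrected scalar test, which is the price of curve-wide error control.

Scalar statistics: Cohen's d from summary statistics with the pooled SD;
a priori per-group n as the smallest integer whose noncentral-t power
(ncp = d√(n/2), df = 2n − 2) reaches the target — the number of tails is
an explicit argument because one- and two-tailed designs give different
n (13 vs 16 at d = 1.03, α = 0.05, power 0.80) and conventions differ
between studies. Group scalar tests gate t vs Wilcoxon rank-sum on
Shapiro–Wilk normality at 0.05 per group; 2×2 frequency tables use the
continuity-corrected chi-squared.

## Synthetic data

The generator emulates the *study conditions*, not muscle physiology:

- **EMG**: band-limited Gaussian noise (20–450 Hz) multiplied by an
  amplitude template — noise floor plus per-burst plateaus with
  raised-cosine ramps (default 20 ms). The carrier band sits inside the
  analysis band so the band-pass is near-transparent and envelope logic
  is tested in isolation from carrier spectral effects; raised-cosine
  ramps avoid step edges that would make "onset" ill-defined at the
  sample level. Typical templates use peak 1.0 over floor 0.05 (20:1).
- **Footswitch**: per-cycle durations drawn i.i.d. normal around the
  plan mean with the plan CV (clipped at 0.3× the mean), heel strikes at
  the cumulative sums; contact high for the stance fraction of each
  cycle.
- **IMU**: all rotations are confined to the mediolateral z-axis. The
  shank angle integrates a per-cycle angular-velocity template with a
  +300°/s mid-swing peak, a −150°/s toe-off dip at the plan's stance
  fraction and a −120°/s heel-strike dip at the cycle boundary (zero
  mean per cycle, so the shank orientation is periodic); thigh, pelvis
  and foot angles are chained off the shank so the hip/knee/ankle
  relative angles reproduce the requested waveforms. A 10 s identity
  lead-in provides the calibration window.
- **Group datasets**: per-subject mean curves are the group template
  plus a smooth unit-variance Gaussian field (FWHM 10 nodes) scaled by
  the between-subject SD — matching the smooth-field assumption under
  which the RFT threshold is exact. Per-subject *session* simulation
  additionally jitters cycle time (SD 0.1 s), its CV (SD 0.5–0.7 %),
  stance (SD 3–3.8 %), joint ROMs (SD 5–7°) and burst timing (SD 2 %),
  magnitudes typical of small adult cohorts. The study does not report
  its variance components, so these are free, fixed choices of the
  generator, not estimates of any dataset.

Default gait plans: cycle time 1.1 s; CV 1.7 % (control) / 2.6 %
(patient); stance 57.3 % / 62.4 %; hip/knee/ankle ROM 35.4/53.7/27.3°
(control) and 29.8/39.3/19.8° (patient); 22 cycles generated, 20
analyzed; 30 m walks.

What passing tests therefore show: the chain recovers known burst
timing to < 2 % of the cycle at 20:1 SNR, joint ROM to < 0.5°, stance to
< 1 %, cycle CV to the generator's realization, and the SPM layer
controls its error rate on fields satisfying its assumptions. What they
do not show: robustness to motion artifact, electrode lift-off,
crosstalk, soft-tissue wobble, magnetometer drift, non-sagittal motion,
or EMG whose inactivity level is not well separated from activity —
real-data performance on those axes is untested by construction.

## Numerical and interface choices

- Filters are SOS Butterworth via `scipy.signal`, `sosfiltfilt` for zero
  phase. RFT root-finding uses Brent's method on (0, 50] with 1e-10
  tolerance; k-means uses exact integer DP with prefix-sum costs.
- All generators take explicit integer seeds (`numpy` Generator); equal
  seeds give byte-identical outputs.
- On-disk formats are plain text: EMG CSV (`time_s`, one column per
  muscle, `footswitch`), quaternion CSV (`time_s`, `<site>_w/x/y/z` for
  pelvis/thigh/shank/foot), JSON sidecars with sampling rate and channel
  mapping, YAML analysis configuration whose defaults equal the protocol
  constants (20–500 Hz order 5; 6 Hz; 10 Hz; 5 ms; 125 ms; k = 3;
  α = 0.05; 20 cycles).
- Problem sizes in the test and acceptance runs are chosen to finish in
  minutes on one CPU: 1000-replicate null calibration, 100-replicate
  detection runs, 200-instance clustering oracle comparisons, 20-cycle
  sessions; larger runs change only the Monte-Carlo error of the checks.

## Known limitations

- Cluster p-values use the exponential extent approximation; very small
  resel counts (extremely smooth fields) push it toward conservatism.
- The burst detector assumes three amplitude regimes; muscles with
  graded, plateau-free activity can split one physiological burst
  across clusters (the 125 ms merge rule absorbs most such splits).
- Amplitude normalization to the within-subject maximum caps between-
  group intensity interpretation: a group difference in normalized
  amplitude is a difference in *relative* activation shape, not in
  absolute drive. The median mode mitigates single-cycle outliers only.
- One-dimensional SPM assumes residual fields that are approximately
  Gaussian and stationary in smoothness; heavy-tailed or spike-like
  residuals call for the nonparametric (permutation) variant, which this
  package does not implement.
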