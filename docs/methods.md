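# Methods

`fosemg` implements an EMG-driven force-estimation framework for static
isometric contractions: high-density surface EMG (HD-SEMG) from an agonist
and an antagonist grid is reduced to one activation signal per muscle, and
a sparse nonlinear model built by fast orthogonal search (FOS) maps the two
activation signals to the measured force. This note documents the models,
the numerical choices, and what the synthetic data do and do not establish.

## Signal model and preprocessing

Each 4 x 8 electrode grid (32 channels, 1000 Hz) records interference EMG.
The amplitude envelope of a channel is obtained by full-wave rectification
followed by a zero-phase low-pass FIR filter: 51 taps, Hanning (raised
cosine, endpoints included) window, 5 Hz cutoff, unit DC gain. The filter
is applied forward-backward; offline analysis needs envelopes aligned with
the simultaneously sampled force trace, and the squared-magnitude response
of the applied filter attenuates 50 Hz by about 66 dB (33 dB single-pass).
Whether to use zero-phase filtering was a genuinely open choice; zero lag
against the force trace decided it.

Bad channels are repaired by copying the nearest good electrode in the grid
4-neighborhood, ties broken by the smallest channel index. "50th order" is
read as 51 taps. All force-model inputs and the measured force are
normalized to their per-trial maximum, so errors are percentages of full
scale.

## Activation extraction

Four reductions from a 32 x T grid to one activation signal:

* **AVG-ENVLP** — mean of all 32 channel envelopes (the conventional
  baseline).
* **PCA** — eigendecomposition of the channel covariance of the raw
  (channel-mean-centered) signals; patterns are unit-norm eigenvectors in
  decreasing eigenvalue order, each oriented so its largest-magnitude
  weight is positive; curves are rectified, low-pass-filtered score series.
* **ICA** — FastICA (log-cosh negentropy contrast, symmetric decorrelation)
  after whitening to the requested dimension; patterns are mixing-matrix
  columns, curves are source envelopes. The contrast function is a choice;
  log-cosh is the standard robust negentropy proxy.
* **NMF** — Lee-Seung multiplicative updates minimizing the squared
  Frobenius error of the *envelope* matrix (nonnegativity requires
  envelope-domain input), seeded uniform random initialization, stopping at
  1e-6 relative improvement or 2000 sweeps. The W/H scale indeterminacy is
  fixed by normalizing each pattern column to unit maximum. The objective
  is non-increasing at every sweep by construction.

Component counts default to 2 (agonist) and 3 (antagonist), matching the
two heads of the biceps brachii and three of the triceps brachii. The
per-muscle activation signal is the unweighted sum of the activation
curves, normalized to its maximum. Summation is deliberately unweighted:
curves carry the component amplitudes under each method's scale convention.

## Fast orthogonal search

The force model is y(t) = Σ a_m p_m(t) + e(t) with p_m drawn from a fixed
candidate pool: a bias plus 13 functions of (H_BI, H_TR) — the fundamental
terms {H_BI, H_TR, H_BI·H_TR}, polynomials {H_BI², H_TR², H_BI³, H_TR³},
square roots {√H_BI, √H_TR, √(H_BI·H_TR)} and sigmoids {σ(H_BI), σ(H_TR),
σ(H_BI)·σ(H_TR)}; 14 functions total. The single-grid variant uses bias +
{H, H², H³, √H, σ(H)}. σ is the logistic sigmoid 1/(1+e^{-x}); inputs are
already max-normalized to [0, 1]. The sigmoid was never pinned down by the
problem statement; logistic is the standard choice.

Selection is greedy: at each step every unselected candidate is
orthogonalized (modified Gram-Schmidt, time-average inner products) against
the already-selected orthogonal functions, and the candidate with the
largest mean-square-error reduction g²·mean(q²) is added. Candidates whose
orthogonalized power falls below 1e-12 of their own power are skipped as
collinear; ties break toward the lower pool index. The search stops at 7
functions (configurable) or when the best remaining candidate would lower
the normalized RMSD by less than 0.2 percentage points. The threshold is
applied to RMSD, not MSE, which departs from some of the
system-identification literature but follows the framework being
implemented; both are configurable.

Original-basis coefficients come from the standard back-substitution
a_m = Σ_{i=m}^{M} g_i v_i with v_m = 1 and
v_i = -Σ_{r=m}^{i-1} α_ir v_r, where α_ir projects candidate i on
orthogonal function r. For a fixed selected set this is algebra, not
approximation: fitted values must agree with a QR/normal-equations
least-squares projection to 1e-8 relative, and the test suite enforces
exactly that, plus per-step greedy optimality against an exhaustive refit
oracle.

Implementation note: explicit modified Gram-Schmidt on stored columns is
used rather than the classical correlation-table recursion; the results
are algebraically identical and the OLS-equivalence contract pins
correctness.

## Evaluation

RMSD = sqrt(Σ(ŷ-y)²/T)·100% on the normalized scale; R² = 1 - Σ(ŷ-y)²/Σ(ȳ-y)².
Cross-validation follows a deliberately pessimistic protocol: one
repetition trains the model, the remaining repetitions are test sets, and
the training repetition cycles (7 repetitions -> 42 folds). Folds are
aggregated by simple mean ± sd. Pearson correlation quantifies how well an
activation signal tracks the force before any model fitting.

## Synthetic data

No public recordings exist for this protocol, so the generator emulates it:
6 s trials at 1000 Hz — a 3 s linear ramp to 20/40/60% MVC followed by a
3 s hold — 7 repetitions per level, two 4 x 8 grids. Surface EMG is
modelled as amplitude modulation: each latent component has a 2-D Gaussian
spatial footprint over the grid (peak 1, small positive floor of 0.02 for
crosstalk, per-electrode gain jitter of ±30%) and modulates its own
independent Gaussian carrier band-passed to 20-500 Hz with a zero-phase
FIR and scaled to unit variance; white measurement noise (sd 0.02) is
added per channel. Independent carriers per component make ICA's
assumption satisfiable by construction; the carrier model itself is a
convention — the modelled experiments use real EMG, which has no closed
generative form. The grid flattens row-major (channel = row·8 + col), so
pattern images round-trip.

Trial-to-trial structure follows force-feedback physiology: the *net* drive
of each muscle tracks the ramp-and-hold target (with 5% smooth
multiplicative jitter), while the *split* of that drive across the
muscle's components is redrawn every repetition — per-component shares
uniform in [0.25, 0.75], renormalized to sum to one, drifting linearly by
up to 0.25 within a trial. The summed drive (and hence the force) is
reproducible across repetitions; the regional contributions are not. This
is the mechanism that separates the methods: averaging all channels weighs
each region by its footprint size, so the share variation contaminates the
averaged envelope across repetitions, while it cancels in the sum of
separated activation curves.

Force is synthesized from the true (normalized) drives through candidate-
pool functions — defaults 0.6·H_BI + 0.3·H_BI² + 0.1·H_TR — plus white
sensor noise (sd 0.01, 1% of full scale), which guarantees the force model
is realizable and gives every downstream test a ground truth. The static
lever relation F_wrist·L_wrist + F_elbow·L_elbow = 0 converts elbow to
wrist force when lever arms are supplied.

The default benchmark scenario uses disjoint footprints of unequal width —
agonist σ of 0.7 and 1.5 electrode pitches at opposite ends of the grid,
antagonist components of σ 0.7-1.1 at half the agonist drive with a 0.3 s
recruitment delay. All randomness descends from a single seed through a
documented SeedSequence splitting scheme; identical seeds give bit-identical
sessions.

**What the generator does not emulate:** motor-unit action potentials,
firing statistics and volume conduction; fatigue; dynamic contractions;
electrode-skin impedance drift; movement artifacts. Passing benchmarks here
show the pipeline behaves correctly under the amplitude-modulation model
with variable load sharing — they do not certify performance on recorded
EMG.

## Benchmark findings and known limitations

On the packaged 20-seed benchmark (7 repetitions, 1-train/6-test
cross-validation, 840 folds per method) the factorization pipelines beat
channel averaging: mean RMSD ≈ 7.1% (AVG-ENVLP), 5.7% (PCA), 5.6% (ICA),
with NMF ≈ 7.1%, statistically tied with the baseline (its median fold is
better, 6.5% vs 6.7%, but its spread is three times larger).

The NMF tie is a real and instructive limitation, not an implementation
defect: when a muscle's component curves are nearly proportional within a
trial (load shares roughly constant over 6 s), the envelope matrix is close
to rank one and its exact nonnegative factorization is not unique — many
factorizations reach near-identical reconstruction error with very
different curve sums. Restart selection by reconstruction error cannot
distinguish them (8 restarts span activation fidelity of 16-23% RMSD while
reconstruction error varies by less than 0.01%), and SVD-based
initialization, tighter tolerances and larger iteration budgets do not
help. PCA and ICA resolve the same ambiguity through eigenstructure and
carrier independence respectively. On recordings with richer within-trial
temporal structure NMF is known to behave better; curve-level recovery is
guaranteed here only for genuinely separated components (pure channels or
pure epochs), and the test suite demonstrates both the success and the
failure mode.

Other numerical choices: envelopes are clipped at zero after filtering
(the FIR can undershoot); NMF denominators carry a 1e-12 epsilon guard;
degenerate inputs (constant force, all-zero curves, all-bad channels,
zero-maximum signals) raise typed errors rather than propagating NaNs.

## Problem sizes

The default test and benchmark sizes — full 6000-sample trials, 20
benchmark seeds, 50-seed recovery and greedy-optimality checks — were
chosen so the complete suite exercises the pipeline at the protocol's
native scale while remaining comfortable to run on a single CPU.
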