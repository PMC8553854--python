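# Methods

## Model and procedure

The package treats stimulus-locked EEG as a piecewise-stationary sequence
of scalp topographies. The analysis chain is:

1. **ERP and normalization.** Per subject × condition cell, epochs
   (epochs × channels × timepoints, µV) are averaged elementwise. GFP is
   the population standard deviation across channels at one timepoint,
   with the spatial mean subtracted (the standard Lehmann–Skrandies field
   power); every timepoint of the ERP is divided by its own GFP, making
   between-condition differences interpretable as changes in the spatial
   *distribution* of activity, never overall amplitude. A timepoint with
   GFP ≤ 1e−12 is degenerate and raises, naming the timepoint.
2. **Grand–grandmean.** Normalized subject ERPs of all conditions are
   pooled and averaged; this single matrix is the clustering substrate.
   It is *not* re-normalized by default — averaging unit-GFP maps yields
   GFP ≤ 1 wherever subjects disagree, which is informative; a
   `renormalize` flag restores unit GFP for users who prefer it. (Whether
   to re-normalize here is genuinely open; both behaviors are selectable
   and tested.)
3. **Clustering and segmentation.** Timepoint topographies are clustered
   with polarity-sensitive squared-Euclidean k-means. ERPs are
   phase-locked and the post-hoc tests interpret signed amplitudes, so a
   polarity reversal is a real difference here — deliberately unlike the
   polarity-invariant "modified k-means" of resting-state practice.
   Maximal runs of equal labels are microstates; no minimum duration is
   enforced (task microstates legitimately undercut the 60–120 ms
   resting-state convention), though `merge_short_microstates` offers an
   optional floor.
4. **TANOVA.** Per microstate, each condition is reduced to one
   channel-space vector (epoch mean → GFP normalization → mean over the
   microstate's timepoints); the statistic is the cosine of the angle
   between the two vectors. The null distribution pools the epochs of both
   conditions, shuffles, relabels the first n_A as condition A, and
   reruns the full averaging/normalizing/reducing chain, 3000 times by
   default. Significance is Bonferroni-adjusted over microstates.
5. **Post-hoc localization.** For TANOVA-significant microstates only,
   epoch counts are equalized by seeded subsampling of the larger
   condition, epochs are averaged over the microstate's timepoints, and a
   two-sided paired t-test runs per channel at α divided by the channel
   count. Pairing is by epoch index after equalization — preserved for
   fidelity to the analysis design this package operationalizes, although
   the pairing is statistically arbitrary (the epochs are unrelated); an
   unpaired option is provided.

## Numerical conventions

- **cos θ** divides the dot product by the product of Euclidean norms
  (the inner product is the only reading that keeps the quotient in
  [−1, 1] in 30 dimensions) and clips to [−1, 1] against roundoff; zero
  vectors raise.
- **Permutation p** uses the add-one convention
  `(1 + #{null ≤ obs})/(n_perm + 1)`, so p is never 0 and the floor at
  3000 permutations is 1/3001 ≈ 3.3e−4 (reported as p < 0.001). Ties
  count as ≤ observed (conservative). A plain `rank` convention
  (`#{null ≤ obs}/n_perm`, which can reach 0) is available, since rank-based
  descriptions leave this choice open.
- **k-means** initializes each restart with k distinct timepoint
  topographies drawn without replacement (seeded); assignment ties break
  toward the lowest cluster id; a restart converging with an empty
  cluster is re-seeded (counted in `n_reseeds`, hard cap per restart);
  the best of 50 restarts by inner-distance sum wins, and clusters are
  renumbered by first temporal appearance so runs are comparable. 50
  restarts (not 20) is the default because fewer restarts are not robust
  across runs at the k values of interest; a robustness test asserts two
  different seeds reach the same optimum within 1e−6.
- **k selection is not automated.** The sweep emits elbow and
  stacked-duration tables; an optional knee heuristic (maximum second
  difference of the inner-distance curve) is provided for orientation and
  never applied silently.
- **Power analysis** models the paired t-test as a one-sample t on
  differences (n − 1 df, noncentrality d√n) and solves for d by Brent
  root-finding to |Δpower| < 1e−8.
- **Median split:** items strictly above the median go high, items at or
  below go low. The tie convention is arbitrary and documented; an
  all-equal input yields an empty high group and is flagged.

## Synthetic data: what it emulates and what it does not

The generator mirrors a 107-participant picture-viewing design: 30 scalp
channels (10–20 montage, mastoid reference excluded) on a 4 ms grid
(250 Hz), a half-open 0–600 ms window of 150 samples (an exploratory
600–2000 ms window of 350 samples is equally supported), subjects ×
conditions cells of epochs. Scalp activity is a fixed timeline of
unit-GFP template topographies scaled by a GFP envelope, plus iid Gaussian
channel noise; per-subject topographic jitter adds between-subject
variability; condition B rotates the template of selected segments by a
controlled angle within the plane spanned by the template and a
dataset-level random orthogonal direction, so the angle between noiseless
condition means is exact (tested to 1e−6 degrees) and TANOVA power studies
have a known effect size on the statistic's own scale.

Defaults, chosen once as plausible for this design and not revisited:
16 epochs per cell (≈ 128 retained epochs over 8 cells per participant),
noise_sd 15 µV against a ~10 µV envelope peak (single-trial SNR < 1, as in
raw EEG; averaging restores it), subject_sd 0.2, segment durations
defaulting inside 60–120 ms. No published SNR or epoch-count variability
model exists for this design, so these are conventions. Tests and examples
use smaller studies (3–8 subjects, 6–16 channels where topography size is
irrelevant, 100–3000 permutations) chosen so each check still exercises
the full code path at informative power.

The generator does **not** emulate: volume-conducted dipole sources,
spatially correlated sensor noise (available via an explicit channel
covariance, off by default), ocular/muscle artifacts, latency jitter
across epochs, or non-stationary switching. Passing tests therefore show
the *pipeline* is correct under its own assumptions, not that real EEG
satisfies those assumptions.

## Statistical behavior of the pooled shuffle

The TANOVA's permutation scheme pools epochs of all participants without
subject stratification. When epochs are exchangeable (no subject-level
correlation), the test is exactly calibrated: over 200 synthetic null
replicates the rejection rate at nominal α = 0.05 sits inside the exact
binomial 95% interval (with 399 permutations the attainable rate under the
add-one convention is 19/400 = 0.0475, a discreteness effect, not a bias).
When epochs are correlated within subjects, the observed condition split
is subject-balanced while shuffled splits are not, so the null is
stochastically more dissimilar and the test becomes *conservative* — a
property of the pooled design itself, reproduced and asserted by a
dedicated test (≈1% empirical rejection at nominal 5% under moderate
jitter). A subject-stratified shuffle is provided as an option for users
who want exactness under subject variability; the pooled scheme remains
the default for fidelity.

## Known limitations

- Timepoint-wise TANOVA (testing every sample rather than microstate
  averages) is out of scope.
- The ASCII/BrainVision readers map data into `EpochSet`s but perform no
  preprocessing (filtering, re-referencing, artifact rejection are the
  user's responsibility upstream).
- The equalization subsample and the epoch-index pairing make post-hoc
  results depend on the post-hoc seed; the seed is recorded in every
  results bundle.
- k-means finds local optima; the brute-force-equivalence guarantee is
  only verified at enumeration-tractable sizes, and the restart-robustness
  test covers the default fixture, not every dataset.
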