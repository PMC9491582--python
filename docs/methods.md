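# Methods

This note documents the models, estimators, numerical choices, and known
limitations behind `idpdyn`. Units throughout: coordinates in Å, time in
ps, rates in s⁻¹, residues numbered 1..N contiguously.

## Gyration-tensor shape statistics

The per-snapshot gyration tensor is computed in its central second-moment
form about the unweighted centroid, which is algebraically identical to
the pairwise-difference form (1/2N²)Σᵢⱼ(rᵢ−rⱼ)(rᵢ−rⱼ)ᵀ; the identity is
asserted numerically in the tests. No mass weighting enters: the tensor is
a geometric descriptor, and the atom subset defaults to all protein atoms
(CA-only and heavy-atom modes are available for sensitivity checks since
the convention varies across the literature).

From ascending eigenvalues λ₁ ≤ λ₂ ≤ λ₃:

* Rg² = λ₁+λ₂+λ₃ (trace identity, checked per frame);
* asphericity A = [(λ₃−λ₂)² + (λ₃−λ₁)² + (λ₂−λ₁)²] / [2(λ₁+λ₂+λ₃)²],
  0 for a sphere, 1 for a rod;
* prolateness P = (2λ₃−λ₂−λ₁)(2λ₂−λ₃−λ₁)(2λ₁−λ₂−λ₃) /
  [2(λ₁²+λ₂²+λ₃²−λ₁λ₂−λ₁λ₃−λ₂λ₃)^{3/2}], +1 fully prolate, −1 fully
  oblate. At exact sphericity the denominator vanishes; P is defined as 0
  there (measure-zero case; any fixed finite value keeps ensemble means
  defined) and the event is logged.

A scientific caveat worth stating plainly: freely-jointed Gaussian chains
are *not* nearly spherical on a per-conformer basis. Under the definitions
above an ideal 73-bead chain gives ⟨A⟩ ≈ 0.40 with the asphericity mode
near 0.22, and ⟨P⟩ ≈ 0.71 — strongly prolate. These values are
scale-invariant (independent of bond length) and essentially independent
of chain length; claims that random-coil references peak at A = 0 or show
⟨P⟩ ≈ 0.3 correspond to some other construction (an uncorrelated Gaussian
point cloud does peak at A = 0, but yields ⟨P⟩ ≈ 0.10). The package
reports what its simulation yields and does not force agreement with any
external number.

Ensemble summaries pool frames with equal weight; histogram bin widths
default to 0.02 for A, 0.04 for P (fixed ranges [0,1] and [−1,1]) and
0.5 Å for Rg (range adapted to the data). The defaults are conventional
round numbers; nothing downstream depends on them.

## Rg fluctuation dynamics

The normalized variance σ² = 1 − ⟨Rg⟩²/⟨Rg²⟩ uses plain frame averages; a
constant series returns 0 rather than erroring.

The offset-free autocorrelation subtracts one mean and divides the lag-t
sum by the number of contributing pairs (unbiased per-lag counts), is
evaluated by zero-padded FFT (identical to the direct double loop; the
tests assert the identity to 1e-10), and is reported for lags up to T/3 —
the truncation that keeps only the statistically converged initial part
of the estimate; it is applied uniformly to the scalar and orientational
estimators.

Two mean conventions are provided:

* `rg_autocorrelation` (single series) subtracts the series' own sample
  mean — the literal reading of an offset-free estimator.
* `rg_autocorrelation_ensemble` (replicate trajectories) subtracts the
  *pooled* mean and normalizes by the pooled variance before averaging
  the per-replicate functions with equal weight. Subtracting each
  replicate's own mean biases its ACF downward by ≈ 2τ_corr/T, which is
  material when a trajectory spans only tens of correlation lengths
  (≈ 0.06 at 10 replicas × 1 μs with a 62 ns slow mode) and visibly
  shortens fitted timescales. The pooled mean removes that bias.

The biexponential fit a·e^(−t/τ_a) + (1−a)·e^(−t/τ_b) parameterizes the
amplitude split through a logistic (sum-to-one exact by construction) and
τ in log space, with a deterministic multi-start over log-spaced τ pairs;
ties break by lowest residual then smallest τ_b.

## Correlation-function fitting on logarithmic lag grids

Both the biexponential and the n-mode fits operate by default on a
deterministic log-spaced subsample of the lag grid (~100 points per
decade, always including lag 0 and the last lag). Rationale: a
multi-exponential decay spans decades, but on a uniform lag grid ~97% of
the points of a T/3-truncated estimate sit in the final decade where the
estimator is pure correlated noise. A least-squares fit over the uniform
grid buys residual there with spurious slow modes, which is fatal for
R₂ (see below). Equal weight per decade is the standard practice for
multi-decade decays; `lag_sampling="uniform"` restores the uniform grid.

## ¹⁵N R₁/R₂ back-calculation

N→H unit vectors are taken from the frames as stored — deliberately *not*
superimposed on a reference — because for a freely reorienting disordered
chain the overall tumbling cannot be separated from internal motion and
must stay in the correlation function. Prolines and the N-terminal
residue carry no amide proton and are excluded (and listed); other
residues missing N or H are excluded with a warning.

The P₂ autocorrelation uses the quadratic-component expansion
(e·e′)² = Σₖ qₖqₖ′ with q = (x², y², z², √2xy, √2xz, √2yz): six scalar FFT
autocorrelations whose sum is ⟨(e(τ)·e(τ+t))²⟩, again with unbiased
per-lag counts and T/3 truncation.

The multiexponential model C(t) = Σᵢ Aᵢ e^(−t/τᵢ) (default 6 modes)
enforces Σ Aᵢ = 1 and Aᵢ ≥ 0 exactly through the parameterization
Aᵢ = wᵢ²/Σwⱼ², with τ in log space, analytic Jacobians, and a
deterministic multi-start (log-spaced τ grids shifted by factors 0.3, 1,
3). After fitting, modes are pruned if their amplitude is below 1e-6 or
below the fit's rms residual: an amplitude smaller than the noise floor of
the correlation estimate is statistically unidentified, and — paired with
a long τ — would otherwise corrupt J(0) and hence R₂ arbitrarily
(observed +56%…+137% R₂ errors on rotor oracles before pruning; ±3%
after). Surviving amplitudes are renormalized, so conservation holds
through fit, pruning, and the timescale summary. Noise-free inputs have
rms residual ≈ 0 and are never pruned.

The spectral density J(ω) = Σᵢ 2Aᵢτᵢ/(1+(ωτᵢ)²) (τ in seconds) follows
analytically; with C(0) = 1 it obeys (1/π)∫₀^∞ J dω = 1. Rates:

    R1 = d00 [3J(ωN) + J(ωH−ωN) + 6J(ωH+ωN)] + c00 ωN² J(ωN)
    R2 = d00/2 [4J(0) + 3J(ωN) + J(ωH−ωN) + 6J(ωH) + 6J(ωH+ωN)]
         + c00 ωN²/6 [4J(0) + 3J(ωN)]

with d00 = (1/20)(μ₀/4π)² ħ² γH² γN² ⟨r_NH⁻³⟩², r_NH fixed at 1.02 Å (no
vibrational averaging), and c00 = Δσ²/15 at Δσ = −160 ppm. Because γN < 0,
frequency arguments use magnitudes; J is even, so results are unaffected —
stated to preclude sign bugs. R₂ ≥ R₁ holds for any non-increasing J and
is asserted on all computed results. The spectrometer field has no
universal default in file-driven runs: the CLI refuses to guess
(`--field-mhz` required); the library function `field_constants(600.0)`
carries the conventional 600 MHz default for interactive use.

Per-residue pipeline: correlation functions are computed per trajectory,
averaged with equal weight, and the averaged function is fitted for the
reported rates; the per-residue spread is the standard deviation of rates
from each trajectory's own fit (zero for a single trajectory). Outlier
trajectories are removed only by an explicit label list — removal against
experiment is a diagnostic, not a default. The timescale summary lists
modes with τ ≥ 100 ps individually and aggregates the faster (librational)
amplitude into one number per residue.

## Contact graphs

A contact exists when the nearest distance between atoms of two residues
is strictly below the cutoff (default 4 Å); (i,i±1) and (i,i±2) pairs are
excluded as trivially present. Atom modes: all atoms (default, the literal
convention), heavy-only, and sidechain-only. Neighbor search uses a
KD-tree with an exact strict-< post-filter, making it bit-identical to the
all-pairs scan (asserted against a brute-force oracle).

Occupancy is the fraction of frames containing a pair. Per-residue rates
count both members of each pair and divide by frames; band edges 0.5 /
1.5 / 2.0 contacts-per-snapshot assign boundary values upward (the prose
brackets in common use are ambiguous at the boundaries). Residue-type
propensities average over residues of a 3-letter type with *population*
standard deviation; singleton types are flagged rather than given a
meaningless spread.

Snapshot graphs take residues as nodes and contacts as edges; clusters
are connected components with ≥ 2 nodes (isolated residues are not
clusters — this choice sets the scale of "clusters per snapshot").
Cluster statistics report per-frame counts, the size histogram, and
(n_nodes, n_edges) per observed cluster. The "average edge-to-node ratio"
is ambiguous between a per-cluster mean and a pooled regression slope;
the per-cluster mean of n_edges/n_nodes is primary and the zero-intercept
slope of edges on nodes is reported alongside. Occupancy networks keep
edges strictly above the threshold (default 0.2) and export as plain edge
list and GraphML.

## Synthetic data: what it emulates and what it does not

All generators are pure functions of (parameters, seed):

* `gaussian_chain_ensemble` — freely-jointed ideal chains, i.i.d.
  isotropic Gaussian bonds of rms length b (default 1 Å; A and P are
  scale-invariant so the value is immaterial). Closed form
  ⟨Rg²⟩ = b²(N²−1)/(6N); Flory exponent 0.5. Deliberately *not*
  self-avoiding: it is the random-coil reference, not a realistic IDP.
* `rotor_vector_series` — isotropic rotational diffusion with
  D_r = 1/(6τ_c), stepped by SO(3) random rotations with rotation-vector
  components N(0, 2D_r·dt); P₂ autocorrelation e^(−t/τ_c) in the
  small-angle regime. dt ≤ τ_c/10 is the documented regime; coarser steps
  are allowed with a logged discretization-bias warning.
* `multi_ou_series` — sums of independent stationary Ornstein–Uhlenbeck
  modes with the exact update x ← x·e^(−dt/τ) + ξσ√(1−e^(−2dt/τ)), so the
  population ACF Σᵢ Aᵢe^(−t/τᵢ) holds without Euler bias.
* `harmonic_chain_trajectory` — a discrete Rouse chain evolved *exactly*
  in normal-mode space: mode p is an OU process with
  τ_p = τ₁·sin²(π/2N)/sin²(pπ/2N) and equilibrium variance
  b²/(24N sin²(pπ/2N)) per component, which reproduces ideal-chain
  statistics identically (verified against the closed form). The center
  of mass is held fixed; it carries no shape or contact information.
* `rotor_nh_trajectory` — a pseudo-peptide with one N–H pair per residue,
  H at N + 1.02 Å·e(t); gives the relaxation pipeline a per-residue
  single-Lorentzian oracle.
* `synthetic_contact_frames` — independent Bernoulli contact streams.

None of these reproduce excluded volume, hydrodynamics, side-chain
packing, secondary structure, or rugged free-energy landscapes. Passing
tests therefore demonstrate the *estimators and formulas* are correct on
signals with known structure — not that any particular force field or
real protein behaves this way.

## Statistical limits worth knowing

Two honest limitations surfaced during validation:

* A biexponential decomposition with a τ ratio of ~5 is sloppy: with 10
  replicas of 1 μs and a 62 ns slow mode (~16 correlation lengths per
  replica), the averaged ACF tail carries coherent noise of order 25%
  relative to the slow amplitude, and fitted τ_b values scatter by
  30–50% across replicate sets. Fitted reconfiguration times at such data
  sizes should be quoted with that uncertainty in mind.
* R₂ is proportional to J(0), the *integral* of C(t): any unidentified
  slow amplitude maps directly into R₂ error. The log-grid fitting and
  noise-floor pruning above exist to keep such amplitudes out of the
  model; single-trajectory R₂ values without them (uniform grid, no
  pruning) can be wrong by a factor of two while R₁ stays accurate.

## Problem sizes

The test and validation runs use chains of 2–128 beads, ensembles of
10⁴–10⁵ conformers, and series of 10⁵–10⁶ frames — sizes at which the
closed-form comparisons above have adequate statistical power while a
full suite run stays in the minutes range on one CPU.
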