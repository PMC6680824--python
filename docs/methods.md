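# Methods

## Scope

`smburst` simulates confocal single-molecule fluorescence detection (SMFD) of
freely diffusing fluorophores and asks a question an experiment cannot:
which photons of which molecules survive the burst analysis?  Every simulated
photon carries its emitting molecule's identity and position, so burst
*impurity* — photons from more than one molecule inside one burst — and the
*molecular position dispersion* — the sub-volume of the detection volume
sampled by accepted photons — can be measured exactly as a function of the
burst-analysis parameters (window size m, rate threshold F, burst-size
threshold sz, burst-width threshold w) and of the experimental conditions
(concentration, diffusion coefficient, detection-volume shape).

## Physical model and default conditions

**Diffusion.**  Point molecules perform free 3D Brownian motion with
per-axis, per-step displacements N(0, 2·D·dt), D = 90 μm²/s and dt = 200 ns
by default (22.5 and 5.625 μm²/s are the standard alternatives).  The box is
periodic; its volume encodes the molar concentration, V = n/(c·N_A), with
n = 15 molecules and c = 62 pM by default (31 and 15.5 pM standard
alternatives; ~402 μm³ at 62 pM).  Periodic boundaries preserve the uniform
stationary distribution, so concentration never drifts.  The box aspect is
(1, 1, 2) by default: the axial σ of the detection volume is ~5× the lateral
one, and the elongated box keeps every box dimension ≥ 10× the corresponding
detection-volume σ (a cube at 62 pM would violate this on z).

**Detection volume.**  Either a separable Gaussian with σx = σy = 180 nm and
σz = 880 nm, or any tabulated non-negative 3D intensity grid evaluated by
trilinear interpolation (zero outside support).  The package ships a
generator for a surrogate numerical model — the square of a Gaussian, i.e.
the product of identical excitation and detection profiles — which is
narrower than its Gaussian parent.  Alternative models are compared at equal
*energies* (volume integrals), not equal widths: the peak-normalized field is
kept and the molecular brightness is multiplied by the energy ratio, so a
uniformly distributed emitter population yields the same total detected flux
under either model.  The surrogate grid's extent (±2 μm laterally, ±6 μm
axially, 81³ nodes) is a package choice; beyond ~6σ the intensity is
negligible at double precision.

**Photon generation.**  Emission is an inhomogeneous Poisson process with
instantaneous rate = brightness × PSF(r), brightness 200 kHz at the peak,
realized by Bernoulli thinning with at most one photon per molecule per step
(peak per-step probability 0.04, so the approximation error is O(p²) ≈
10⁻³ of the rate).  Background is homogeneous Poisson at 2.3 kHz
(single-channel) or 1.5/0.8 kHz (donor/acceptor); background photons carry
molecule id −1 and no position.  Timestamps are integer step indices with the
step duration as metadata: exact arithmetic and bit-stable sorting.
Diffusion, emission, background and channel splitting draw from independent
named RNG substreams of one master seed; a given configuration (including
its chunk size, which fixes the layout of the random stream) reproduces
bit-identical output.

**smFRET.**  For two-population simulations, 10 molecules carry E = 0.75 and
5 carry E = 0.50; each signal photon is routed to the acceptor channel with
probability E(molecule).  No gamma, leakage or direct-excitation corrections
are applied anywhere — the burst proximity ratio n_A/(n_A+n_D) is used
uncorrected, with background photons included, as in the analysis this
package emulates.

## Burst analysis

The background rate is estimated from the slow tail of the inter-photon
delay distribution: delays exceeding 5× the median are treated as draws from
the background exponential, whose excess over the cutoff is again
exponential by memorylessness, giving the MLE rate n/Σ(dᵢ−c).  On a pure
2.3 kHz stream the estimator lands within a few percent; on bursty streams
it is far less biased than total-count/duration.  The known simulated rate
can be injected instead (a config switch used when tests must isolate search
behaviour from estimator error).

The sliding-window search uses the m/Δt rate convention: window i spans
photons i..i+m−1 and qualifies when m/(t[i+m−1]−t[i]) ≥ F·BG; a burst is a
maximal run of photons covered by at least one qualifying window, with no
additional gap-merging.  The (m−1)/Δt convention found elsewhere in the
literature shifts F-sweep results slightly; the convention here is fixed and
tested against an exhaustive window-enumeration oracle.  Burst sizes count
all photons including (indistinguishable) background; selection keeps bursts
with size ≥ sz and width ≥ w.

A note on false positives: with m = 10, F = 6 on pure 2.3 kHz background the
per-window qualifying probability is P(Gamma(9) ≤ 10/6) ≈ 6×10⁻⁵, i.e. ≈1.4
expected qualifying windows per 10 s — background alone *does* produce
occasional bursts at F = 6.  At F = 11 the expectation drops to ~0.01 per
10 s.

## Purity and dispersion statistics

Burst impurity is f = 1 − (modal-molecule photons)/(signal photons), with
background discarded from both counts; bursts containing only background
photons have undefined impurity and are excluded from aggregates (counted
separately).  The three aggregates are: fraction of bursts with f > 0
(Wilson 95% CI), mean per-burst impurity (standard error), and the pooled
photon-level impurity (no error bar; it is identically the size-weighted
mean of per-burst impurities, an identity asserted in the tests).  Photon
classes for position histograms: impure photons, photons of impure bursts,
photons of pure bursts, all burst photons; modal-molecule ties break toward
the lower molecule id (the impurity value itself is tie-invariant).

Position dispersion pools the emission positions of all signal photons of
all selected bursts and reports per-axis sample sds.  The stated uncertainty
s/√(2(n−1)) assumes independent photons; photons within one crossing are
strongly correlated, so this understates the true sampling error by a factor
of ~3–5 at these conditions.  Where a calibrated uncertainty matters (the
recovery checks in the test suite), the spread of independent per-molecule
sds is used instead.

## FCS surrogate

The burst-photon autocorrelation is estimated from pair counts on log-spaced
lag bins with the exact finite-record edge correction,
G = C/(λ²[TΔτ − (e₂²−e₁²)/2]) − 1, so a Poisson stream gives G ≈ 0 and the
amplitude convention G(τ→0) = 1/⟨N⟩ holds.  An O(n²) pair-count correlator
serves as the test oracle.  Fits use the standard single-component 3D
diffusion model G(τ) = ⟨N⟩⁻¹(1+τ/τ_D)⁻¹(1+τ/(κ²τ_D))^(−1/2) with κ fixed
at 7, unweighted least squares, initial ⟨N⟩ from the small-lag amplitude and
initial τ_D at the half-amplitude lag.  Restricting the correlation to burst
photons biases the curve shape — the effective volume after burst selection
is neither constant nor Gaussian — so ⟨N⟩-derived multi-occupancy
probabilities (1 − e⁻ᴺ − Ne⁻ᴺ, and the same conditioned on ≥1 molecule) are
treated as qualitative surrogates; τ_D from these fits carries large errors
and is not relied on.  Mean burst width is the robust dwell-time measure.

## FRET histogram fitting

Proximity ratios of all selected bursts are histogrammed in 41 bins over
[0, 1] (odd count centres a bin on 0.5) and fitted with
A·[f·N(μ₁,σ₁) + (1−f)·N(μ₂,σ₂)] by least squares on the binned counts (the
histogram, not an unbinned likelihood, is what is fitted in practice).
Initial means come from splitting the sample at its median; populations are
reported high-FRET first; f may be fixed (e.g. to the simulated 2/3) or
left free.  Collapsed components (σ → 0) and degenerate samples raise
explicit fit failures.

## Trend checks

The headline qualitative findings — mean impurity falls with F and rises
with m and sz; dispersion falls with F and sz; the deviation of fitted FRET
means from truth falls with F — are asserted as monotone trends.  Because
every point is a stochastic estimate, "monotone allowing ties" is
formalized as: no consecutive step may move against the trend by more than
one combined standard error, and the trend must hold in at least 2 of 3
independent seeds.

## Problem sizes

Desk-scale runs are used throughout: the default simulation duration is 5 s
(configurable), the test-suite recovery checks use 2 s single-channel runs
and a 10 s smFRET mixture, and trend sweeps use 3 s (impurity/dispersion)
and 6 s (FRET) per seed.  The reproduction script uses longer records where
a quantity's sampling scatter demands it: 16 s for the detected-photon
dispersion (the axial sd has ~8% scatter per 2 s record) and four averaged
20 s replicates for the two-Gaussian FRET fit, whose free-fraction estimate
carries a ~0.05 single-fit error.  All asserted quantities are distributional and converge
well below a 60 s acquisition; trajectories stream through fixed-size chunks
(3×10⁵ steps) so no full position history is ever materialized (~50 GB for
60 s at 200 ns would otherwise be required).

## Known limitations

No photophysics (blinking, bleaching, triplet states), no detector dead
time, afterpulsing or crosstalk, no flow or 2D/1D diffusion, no
alternating-laser excitation or dual-channel search.  The Gaussian component
model for FRET peaks ignores shot-noise skew toward 0.5 — deliberately,
since reproducing that common approximation is part of the exercise.
Passing tests demonstrate correctness of the simulation and analysis
machinery under these idealized conditions, not the behaviour of any real
instrument.
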