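# Methods

## Scope and data model

The pipeline takes region-level multichannel time series (one
`regions × samples` matrix per subject × condition, with sampling rate
and labels), or alternatively precomputed symmetric connectivity
matrices or a long-format measure table, and produces a three-way
equivalence verdict per stimulus, per band, per network measure. The
default region fixture is a 61-label emotion-processing parcellation;
the published region table contains two duplicated labels and is shipped
verbatim alongside a deduplicated canonical list that restores the two
missing contralateral labels (`L Hippocampus`, `R Ant OFC`). Matrices
are dimensioned by the canonical list.

The default condition scheme is seven recordings per subject: a pre-rest
baseline, five auditory stimuli, and a post-rest recording. The count is
configurable (the source protocol is ambiguous about additional stimulus
slots, with one condition recorded for fewer subjects; the generator
defaults to the seven-condition main design and complete cases).

## Envelope extraction

Band-pass filtering uses a linear-phase FIR (Hamming window, odd tap
count, transition width `min(2 Hz, low_edge / 2)`), applied with its
integer group delay compensated so the output is zero-phase; the Hamming
design gives > 50 dB stop-band attenuation one transition width beyond
the edges. The analytic signal is built by one-sided spectrum doubling
(`scipy.signal.hilbert`); the principal-value integral defining the
Hilbert transform is a definition, not an algorithm. The first and last
filter-length samples are transient-contaminated and are excluded from
every downstream correlation. No time–frequency decomposition and no
resampling are performed.

## Connectivity

Orthogonalization removes, at each sample, the component of one analytic
signal collinear with the instantaneous phase of the other:
y⊥x = ℑ(x*/|x| · y), with samples where |x| falls below 1e−12 of its
maximum set to 0. The operation is asymmetric, so both directions are
computed and the undirected weight is their arithmetic mean — the
established convention for this estimator. A residual whose amplitude is
below 1e−10 of the orthogonalized signal's own amplitude is treated as
exactly zero (collinear channels leave only rounding noise, whose
envelope would otherwise correlate spuriously with the reference).
Correlation between a constant envelope and anything is reported as 0
with a warning. One static estimate is made per recording; windowed
estimation (split + average) exists behind `n_windows` but defaults off.
Negative correlations are retained at this stage; their handling is
deferred to thresholding.

## Thresholding and graph metrics

The cutoff is the median (midpoint interpolation) of all upper-triangle
weights pooled over every recording of a band — by default including
the two resting recordings; `exclude_conditions` restricts the pool.
Entries strictly below the cutoff are zeroed, entries at or above it are
retained unchanged (no binarization); a nonnegative cutoff therefore
also removes negative correlations, and the metrics reject negative
inputs rather than silently taking absolute values, because cube roots
of triangle products and inverse-weight lengths are undefined for them.

Weighted transitivity is computed as T = Σᵢ 2tᵢ / Σᵢ kᵢ(kᵢ−1) with
tᵢ = ½ Σ_{j,h} (w_ij w_ih w_jh)^{1/3} over ordered pairs (evaluated as
the diagonal of the elementwise-cube-root matrix cubed), and T = 0 by
convention when no node has degree ≥ 2. Weighted global efficiency maps
weights to lengths by f(w) = 1/w (−log w available for weights ≤ 1),
runs Dijkstra on the sparse length graph, and counts unreachable pairs
as zero inverse distance, so disconnected graphs are well defined; a
single-node graph has E = 0. Both implementations are checked against
exhaustive triangle enumeration and Floyd–Warshall oracles on hundreds
of random graphs to 1e−10.

## Hierarchical model

For each measure × band, observations y (strictly positive) follow

    y_{i|s} ~ LogNormal(μ_s, σ),   μ_s = α_s + Σ_j β_{s,j} Stimuli_j

with the pre-rest condition absorbed into α_s and every other condition,
including post-rest, carrying a slope. Subject-level deviations are
jointly Gaussian with a 2×2 covariance diag(σ_α, σ_β) R diag(σ_α, σ_β).
A 2×2 covariance implies **one** slope deviation per subject shared
across its condition slopes (β_{s,j} = β̄_j + b_s); this is the default
reading and the single most consequential modelling choice, so it is
recorded in the fitted object. A per-condition-deviation variant exists
behind `slope_structure="per_condition"`.

Priors: ᾱ ~ N(μ̄_k, 0.2) with μ̄_k the mean of the log measure values in
the analysed table (the prior is on the log-scale location, so "measure
mean" is read on the model's scale); β̄_j ~ N(0, 0.2); σ_α, σ_β, σ ~
half-N(0, 0.1); R ~ LKJ(2). A non-informative sensitivity variant widens
the scales to 10/100/10/10/10. A Student-t likelihood on the log values
(fixed, configurable ν, default 4) is available as a robustness variant;
ν is not estimated because the variant exists only to check sign and
ROPE stability of conclusions.

Before fitting, each measure × band × condition cell is screened once
(not iterated) with the 1.5·IQR boxplot rule. The quartile interpolation
rule is declared (`midpoint` default, `linear` available) so screening is
bit-reproducible; cells with fewer than four values pass through with a
warning. Screening is per cell rather than pooled across conditions —
the stricter reading when conditions may differ in level.

## Sampling

No general-purpose gradient-based MCMC engine is part of the
dependencies; the model is sampled by a compact adaptive Hamiltonian
Monte Carlo sampler written for this package: leapfrog integration with
a jittered trajectory length (default 3.0 in mass-normalized units),
dual-averaging step-size adaptation toward 0.85 acceptance, and a
diagonal mass matrix estimated in two expanding warmup windows with the
step size re-adapted after each update. The posterior is parameterized
on the unconstrained scale — log scales for σ_α, σ_β, σ (half-normal
priors plus Jacobians) and atanh for the correlation (LKJ(2) density
plus tanh Jacobian) — with non-centered random effects, which is what
makes the half-N(0, 0.1) hierarchy geometrically tractable. Transitions
with energy error beyond 1000 are rejected and counted; a fit dominated
by divergences warns loudly rather than failing silently. The analytic
gradient is verified against central finite differences in the test
suite. Convergence is assessed with rank-normalized split-chain R-hat
and bulk ESS (arviz) over every sampled and derived parameter;
the conventional thresholds are R-hat < 1.1 and, at publication scale,
ESS > 10,000.

Desk-scale defaults are 4 chains × 2,500 iterations with 500 warm-up
(8,000 retained draws); `paper_scale=True` (CLI `--paper-chains`)
restores the publication-scale 4 × 14,000 with 4,000 warm-up, i.e.
40,000 retained draws. The acceptance checks use 4 × 700/400 per
replicate fit — enough for stable 90% HDIs (1,200 pooled draws) while
keeping twenty replicate fits to a few minutes.

## Equivalence

Contrasts are reported on the response scale as the difference of
population medians, exp(ᾱ + β̄_j) − exp(ᾱ), per draw. The 90% credible
intervals are highest-density intervals computed by the sorted-window
(narrowest-interval) estimator, which is declared unreliable for
multimodal posteriors. The ROPE is the HDI of the post-rest − pre-rest
contrast; "the total credible interval" is not a defined estimator, so
the ROPE mass is configurable with a default of 0.99 (covering
essentially the whole interval of the resting difference), 0.90
available to mirror the contrast CIs, and the chosen mass is flagged in
every report. %-in-ROPE is interval overlap (length of CI ∩ ROPE over
CI length), matching table semantics where containment reads 100%; a
posterior-mass variant (`mass_in_rope`) exists behind its own function.
Decisions are three-way and exactly consistent with the percentage:
equivalent ⟺ 100, different ⟺ 0 for nondegenerate intervals.

The 50 published contrast rows (5 stimuli × 5 bands × 2 measures) ship
as a worked-example fixture; two printed intervals had inverted bounds
from a dropped minus sign and are stored sign-restored (documented in
the loader). Replaying every row's printed CI and ROPE through the
decision arithmetic reproduces 100% / equivalent in all 50 rows.

## Synthetic data

The oscillation generator produces channels x_k(t) = e_k(t) cos(2π f_c t
+ φ_k + ψ_k(t)) with f_c the band center: Rayleigh envelopes
e_k = |v_k + i w_k| from two independent low-pass-filtered correlated
Gaussian fields, and carrier phases independent across channels (a fixed
random offset plus slow drift, default 0.5 rad). Envelope coupling built
this way is *not* phase coherent, so it survives orthogonalization the
way genuine neural envelope coupling does — a phase-coherent
construction (correlated complex amplitudes) was rejected because
orthogonalization removes exactly the phase-coherent part. An optional
mixing matrix adds instantaneous leakage on top. The map from latent
Gaussian correlation r to Rayleigh envelope correlation is the closed
form (π/2)(₂F₁(−½, −½; 1; r²) − 1)/(2 − π/2), evaluated on a dense grid
and inverted by monotone PCHIP interpolation; it is exact at 0 and 1 and
verified against Monte Carlo. Envelope correlations are representable in
[0, 1) only — negative targets are rejected — and the target matrix must
map to a positive-semidefinite latent correlation. Defaults emulate the
study recording geometry (1000 Hz, 180 s); tests use shorter, slower
recordings where only the contract, not the scale, matters.

Whole-study simulations default to a two-module coupling topology
(0.6 within each half of the regions, 0.15 between). Absolute
thresholding presumes heterogeneous edge weights: a uniform coupling
target would place every edge at the pooled median, making threshold
survival a coin flip and occasionally leaving recordings with no
triangles at all (T = 0, which the log-normal likelihood rightly
rejects). The modular structure mirrors real functional networks and
guarantees each recording keeps a stable above-threshold core.

The generator does **not** emulate sensor-space physics: no forward
fields, no 1/f background, no cardiac or movement artifacts, and its
narrow-band spectrum is symmetric around the band center. Passing tests
therefore demonstrate correctness of the estimators under controlled
coupling, not robustness to real MEG noise.

The measure-table generator draws directly from the hierarchical model
above (shared slope deviation, log-normal or Student-t likelihood), and
is the forward half of the parameter-recovery checks: fitting the model
to its own simulations at the study design size (30 subjects, 7
conditions) recovers the slopes with ≥ 80% empirical 90%-HDI coverage
over 20 replicates, with R-hat < 1.1 in at least 19 of them.

## Determinism

Every source of randomness descends from explicit integer seeds; a
master seed spawns independent substreams per subject × condition so
partial re-runs reproduce exactly. Matrices and measure tables are
written with 17-significant-digit formatting and round-trip
bit-identically; identical config + seed reproduces them byte-for-byte.
Sampler draws are reproducible given the seed on a fixed platform and
numpy version.

## Known limitations

- Ensemble behaviour of the HMC sampler is tuned for this model family
  (a few hundred dimensions, mild hierarchy); it is not a general PPL.
- The HDI estimator assumes unimodality.
- The interval-overlap %-in-ROPE ignores the posterior's shape inside
  the interval; the mass-based variant is provided for sensitivity.
- Orthogonalized AEC attenuates genuine coupling (it discards the
  phase-aligned component); values are comparable across conditions, not
  unbiased estimates of envelope correlation.
- The generator's envelope correlation calibration is exact for the
  latent construction, but band-pass filtering at analysis time clips
  envelope sidebands slightly, so measured plain AEC is recovered within
  about ±0.05 of the target rather than exactly.
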