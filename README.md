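# aecnet

Orthogonalized amplitude-envelope-correlation (AEC) brain networks with
weighted-topology metrics and Bayesian ROPE equivalence testing.

## The problem

MEG/EEG studies of auditory or musical intervention often ask whether a
stimulus *changes* the topology of a functional brain network — and,
just as importantly, whether it demonstrably does *not*. This package
implements that full analysis as a tested, reusable pipeline:

1. **Envelope connectivity.** Region-level time series are band-pass
   filtered into the five canonical bands (δ 2–4, θ 5–7, α 8–12,
   β 15–29, γ 30–59 Hz), the amplitude envelope a(t) = |x(t) + i H[x(t)]|
   is extracted with the Hilbert transform, and connectivity between
   regions i and j is the Pearson correlation of their envelopes. To
   remove source-leakage artifacts, each pair is first orthogonalized:
   y⊥x(t) = ℑ(x*(t)/|x(t)| · y(t)), computed in both directions and
   averaged, giving a symmetric weighted adjacency matrix **A** with zero
   diagonal per subject × condition × band.
2. **Network topology.** Matrices are thresholded with an absolute
   cutoff — the median of connectivity pooled over all recordings of a
   band — and summarized by weighted transitivity
   T = Σᵢ2tᵢ / Σᵢkᵢ(kᵢ−1) (functional segregation) and weighted global
   efficiency E = ⟨1/d_ij⟩ with lengths f(w) = 1/w (functional
   integration).
3. **Bayesian equivalence.** Each measure is modelled hierarchically:
   y ~ LogNormal(α_s + Σⱼ β_{s,j}·Stimuliⱼ, σ) with correlated
   subject-level intercept and slope deviations
   (LKJ(2) prior on the 2×2 correlation), weakly informative priors
   (N(μ̄_k, 0.2), N(0, 0.2), half-N(0, 0.1)), sampled with an adaptive
   Hamiltonian Monte Carlo sampler written for this model. The region of
   practical equivalence (ROPE) is the credible interval of the
   post-rest − pre-rest contrast; a stimulus is *equivalent* to rest iff
   the 90% HDI of its contrast lies entirely inside the ROPE, *different*
   iff entirely outside, otherwise *undecidable*.

A synthetic-data generator produces narrow-band oscillations with an
exactly calibrated envelope-correlation structure (plus optional
instantaneous mixing to emulate leakage) and forward-simulates the
hierarchical generative model, so every stage is verifiable without any
recording.

## Worked example

```python
import numpy as np
from aecnet import (
    SimulationConfig, simulate_coupled_oscillations,
    plain_aec_matrix, orthogonalized_aec_matrix,
)

# two regions whose envelopes are coupled at 0.8, plus a leaky pair
cfg = SimulationConfig(
    n_regions=2, fs=1000.0, duration=180.0,
    target_aec=np.array([[1.0, 0.8], [0.8, 1.0]]), seed=3,
)
ts = simulate_coupled_oscillations(cfg)
print("plain AEC:", round(plain_aec_matrix(ts, "alpha").weights[0, 1], 3))
print("orth AEC: ", round(orthogonalized_aec_matrix(ts, "alpha").weights[0, 1], 3))
```

prints

```
plain AEC: 0.805
orth AEC:  0.628
```

— the plain AEC recovers the 0.8 target within estimation error, and
genuine (non-phase-coherent) coupling survives orthogonalization, while a
rank-1 mixed pair (`mixing=[[1, 1], [1, 1]]`) gives plain AEC 1.0 and
orthogonalized AEC 0.0.

The full pipeline, from synthetic recordings to the equivalence report:

```sh
aecnet all --seed 1 --out results/demo
```

which writes the measure table, per-band connectivity matrices, posterior
summaries and a report with one row per stimulus contrast
(`median, ci_low, ci_high, rope_low, rope_high, percent_in_rope,
decision, rhat, ess`). Every output directory embeds the resolved
configuration and its hash; identical config + seed reproduces matrices
and measure tables byte-for-byte.

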