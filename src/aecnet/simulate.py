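"""Synthetic inputs for every pipeline stage.

Two generators live here:

* :func:`simulate_coupled_oscillations` — narrow-band multichannel
  oscillations with a *known* amplitude-envelope correlation structure.
  Each channel is a Rayleigh envelope modulating a carrier at the band
  center. The envelopes are |v + i w| with v, w slow correlated Gaussian
  fields, so the envelope correlation is an exact, monotone function of
  the latent Gaussian correlation (closed form via the Gauss
  hypergeometric function) and can be dialled precisely. Carrier phases
  are independent across channels: envelope coupling built this way is
  *not* phase coherent, so it survives leakage orthogonalization — while
  an optional instantaneous mixing matrix adds the phase-coherent leakage
  that orthogonalization is designed to remove.

* :func:`simulate_measure_table` — forward simulation of the hierarchical
  log-normal generative model for the network measures: one observation
  per subject x condition, log-location alpha_s for the reference (rest)
  condition plus a per-condition slope, with correlated subject-level
  intercept and slope deviations.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal
from scipy.interpolate import PchipInterpolator
from scipy.special import hyp2f1

from .bands import BandSpec
from .tables import validate_measure_table
from .timeseries import RegionTimeSeries

# --------------------------------------------------------------------------
# envelope-correlation calibration
# --------------------------------------------------------------------------


def envelope_corr_from_latent(r: np.ndarray | float) -> np.ndarray | float:
    """Pearson correlation of two Rayleigh envelopes |v1+iw1|, |v2+iw2|.

    v and w are unit Gaussians with corr(v1, v2) = corr(w1, w2) = r and
    all other cross-correlations zero. Closed form:

        corr = (pi/2) * (2F1(-1/2, -1/2; 1; r^2) - 1) / (2 - pi/2)

    which is 0 at r = 0 and 1 at |r| = 1, and strictly increasing in |r|.
    """
    r = np.asarray(r, dtype=float)
    val = (np.pi / 2) * (hyp2f1(-0.5, -0.5, 1.0, r**2) - 1.0) / (2.0 - np.pi / 2)
    return val if val.ndim else float(val)


_GRID = np.linspace(0.0, 1.0, 201)
_ENV_OF_LATENT = np.asarray(envelope_corr_from_latent(_GRID))
# monotone interpolant of the inverse map (envelope corr -> latent corr)
_LATENT_OF_ENV = PchipInterpolator(_ENV_OF_LATENT, _GRID)


def latent_corr_for_envelope(rho_env: np.ndarray | float) -> np.ndarray | float:
    """Latent Gaussian correlation producing a target envelope correlation."""
    rho_env = np.asarray(rho_env, dtype=float)
    if (rho_env < 0).any() or (rho_env > 1).any():
        raise ValueError(
            "this generator represents envelope correlations in [0, 1] only"
        )
    val = _LATENT_OF_ENV(rho_env)
    return val if val.ndim else float(val)


# --------------------------------------------------------------------------
# coupled narrow-band oscillations
# --------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Recording geometry and coupling targets for the oscillation generator.

    Defaults emulate the study conditions this pipeline is built around:
    1000 Hz sampling and 180 s (3 min) recordings.
    """

    n_regions: int = 2
    fs: float = 1000.0
    duration: float = 180.0
    band: BandSpec = field(default_factory=lambda: BandSpec("alpha", 8.0, 12.0))
    target_aec: np.ndarray | None = None  # defaults to identity
    envelope_bandwidth: float = 1.0
    phase_jitter: float = 0.5  # rad std of slow independent phase drift
    mixing: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_aec is None:
            self.target_aec = np.eye(self.n_regions)
        self.target_aec = np.asarray(self.target_aec, dtype=float)
        C = self.target_aec
        if C.shape != (self.n_regions, self.n_regions):
            raise ValueError("target_aec shape must be n_regions x n_regions")
        if not np.allclose(C, C.T, atol=1e-12):
            raise ValueError("target_aec must be symmetric")
        if not np.allclose(np.diag(C), 1.0):
            raise ValueError("target_aec diagonal must be exactly 1")
        if self.fs <= 2 * self.band.high:
            raise ValueError("sampling rate must exceed twice the band top edge")
        n = self.duration * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration x fs must be an integer sample count")
        if not (0 < self.envelope_bandwidth < self.band.span):
            raise ValueError("envelope bandwidth must lie in (0, band span)")
        if self.mixing is not None:
            self.mixing = np.asarray(self.mixing, dtype=float)
            if self.mixing.shape != (self.n_regions, self.n_regions):
                raise ValueError("mixing matrix shape must be n_regions x n_regions")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


def _slow_field(
    rng: np.random.Generator, chol: np.ndarray, n: int, fs: float, bw: float
) -> np.ndarray:
    """Correlated channels of low-pass Gaussian noise, unit variance each."""
    white = rng.standard_normal((chol.shape[0], n))
    corr = chol @ white
    numtaps = min(int(np.ceil(3.3 * fs / bw)) | 1, (n - 1) | 1)
    taps = signal.firwin(numtaps, bw, fs=fs)
    half = numtaps // 2
    padded = np.pad(corr, [(0, 0), (half, half)], mode="reflect")
    out = signal.fftconvolve(padded, taps[None, :], mode="valid", axes=-1)
    out -= out.mean(axis=1, keepdims=True)
    out /= out.std(axis=1, keepdims=True)
    return out


def simulate_coupled_oscillations(
    cfg: SimulationConfig, subject: str = "sub01", condition: str = "rest"
) -> RegionTimeSeries:
    """Generate narrow-band channels with the configured AEC structure."""
    G = latent_corr_for_envelope(np.clip(cfg.target_aec, 0.0, 1.0))
    G = np.asarray(G)
    np.fill_diagonal(G, 1.0)
    eigmin = float(np.linalg.eigvalsh(G).min())
    if eigmin < -1e-10:
        raise ValueError(
            "target AEC maps to a non-positive-semidefinite latent covariance"
        )
    jitter = max(0.0, -eigmin) + 1e-12
    chol = np.linalg.cholesky(G + jitter * np.eye(len(G)))

    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    v = _slow_field(rng, chol, n, cfg.fs, cfg.envelope_bandwidth)
    w = _slow_field(rng, chol, n, cfg.fs, cfg.envelope_bandwidth)
    env = np.hypot(v, w)

    t = np.arange(n) / cfg.fs
    phi0 = rng.uniform(0, 2 * np.pi, size=cfg.n_regions)
    if cfg.phase_jitter > 0:
        ident = np.eye(cfg.n_regions)
        drift = cfg.phase_jitter * _slow_field(
            rng, ident, n, cfg.fs, cfg.envelope_bandwidth
        )
    else:
        drift = np.zeros((cfg.n_regions, n))
    phase = 2 * np.pi * cfg.band.center * t[None, :] + phi0[:, None] + drift
    data = env * np.cos(phase)
    if cfg.mixing is not None:
        data = cfg.mixing @ data
    return RegionTimeSeries(
        data=data, fs=cfg.fs, subject=subject, condition=condition
    )


# --------------------------------------------------------------------------
# generative model for measure tables
# --------------------------------------------------------------------------


@dataclass
class GenerativeParams:
    """Population parameters of the hierarchical log-normal model.

    ``beta_bar`` maps each non-reference condition label to its overall
    slope on the log scale; the reference (first) condition is absorbed
    into the intercept. Subject-level intercept and (shared) slope
    deviations are jointly Gaussian with scales ``sigma_alpha``,
    ``sigma_beta`` and 2x2 correlation ``R_corr``.
    """

    alpha_bar: float
    beta_bar: Mapping[str, float]
    sigma_alpha: float = 0.05
    sigma_beta: float = 0.05
    sigma: float = 0.05
    R_corr: np.ndarray = field(default_factory=lambda: np.eye(2))
    n_subjects: int = 30
    likelihood: str = "lognormal"
    student_df: float = 4.0

    def __post_init__(self) -> None:
        for name in ("sigma_alpha", "sigma_beta", "sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        R = np.asarray(self.R_corr, dtype=float)
        if R.shape != (2, 2) or not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1):
            raise ValueError("R_corr must be a symmetric 2x2 unit-diagonal matrix")
        if np.linalg.eigvalsh(R).min() <= -1e-12:
            raise ValueError("R_corr must be positive (semi)definite")
        self.R_corr = R
        if self.likelihood not in ("lognormal", "student_t"):
            raise ValueError("likelihood must be 'lognormal' or 'student_t'")


def simulate_measure_table(
    gp: GenerativeParams,
    conditions: Sequence[str],
    seed: int,
    band: str = "sim",
    measure: str = "T",
) -> pd.DataFrame:
    """Forward-simulate one observation per subject x condition.

    The first condition label is the reference (pre-rest); every other
    condition, including a post-rest, carries a slope from
    ``gp.beta_bar`` (conditions absent from the map get slope 0).
    """
    conditions = list(conditions)
    if len(conditions) < 1:
        raise ValueError("need at least one condition")
    reference, others = conditions[0], conditions[1:]
    rng = np.random.default_rng(seed)

    scale = np.diag([gp.sigma_alpha, gp.sigma_beta])
    cov = scale @ gp.R_corr @ scale
    dev = rng.multivariate_normal(np.zeros(2), cov, size=gp.n_subjects)

    rows = []
    for s in range(gp.n_subjects):
        subject = f"sub{s + 1:02d}"
        alpha_s = gp.alpha_bar + dev[s, 0]
        for cond in conditions:
            mu = alpha_s
            if cond != reference:
                mu += gp.beta_bar.get(cond, 0.0) + dev[s, 1]
            if gp.likelihood == "lognormal":
                logy = rng.normal(mu, gp.sigma) if gp.sigma > 0 else mu
            else:
                draw = rng.standard_t(gp.student_df) if gp.sigma > 0 else 0.0
                logy = mu + gp.sigma * draw
            rows.append((subject, cond, band, measure, float(np.exp(logy))))
    table = pd.DataFrame(
        rows, columns=["subject", "condition", "band", "measure", "value"]
    )
    return validate_measure_table(table)


#: Default condition scheme: pre-rest, five stimuli, post-rest.
DEFAULT_CONDITIONS = (
    "Pre", "Stim01", "Stim02", "Stim03", "Stim04", "Stim05", "Post"
)


def modular_target(n_regions: int, coupling: float, background: float) -> np.ndarray:
    """Two-module envelope-correlation target.

    Strong coupling within each half, weak background between halves —
    the heterogeneous edge-weight structure that absolute thresholding
    presumes (a uniform target would put every edge at the pooled
    median, making threshold survival a coin flip).
    """
    target = np.full((n_regions, n_regions), float(background))
    half = n_regions // 2
    target[:half, :half] = coupling
    target[half:, half:] = coupling
    np.fill_diagonal(target, 1.0)
    return target


def simulate_study_dataset(
    n_subjects: int = 30,
    conditions: Sequence[str] = DEFAULT_CONDITIONS,
    n_regions: int = 8,
    fs: float = 1000.0,
    duration: float = 30.0,
    band: BandSpec | None = None,
    coupling: float = 0.6,
    background: float = 0.15,
    seed: int = 0,
) -> list[RegionTimeSeries]:
    """Recordings for a whole study, one per subject x condition.

    A single master seed spawns independent substreams per recording so
    partial re-runs reproduce exactly. The envelope-correlation target is
    the two-module structure of :func:`modular_target`.
    """
    band = band or BandSpec("alpha", 8.0, 12.0)
    target = modular_target(n_regions, coupling, background)
    children = np.random.SeedSequence(seed).spawn(n_subjects * len(conditions))
    out = []
    k = 0
    for s in range(n_subjects):
        for cond in conditions:
            sub_seed = int(children[k].generate_state(1)[0] % (2**31))
            k += 1
            cfg = SimulationConfig(
                n_regions=n_regions,
                fs=fs,
                duration=duration,
                band=band,
                target_aec=target,
                seed=sub_seed,
            )
            out.append(
                simulate_coupled_oscillations(
                    cfg, subject=f"sub{s + 1:02d}", condition=cond
                )
            )
    return out
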