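"""Synthetic repeated-session resting EEG with known reliability structure.

The generator stands in for the study population whose recordings are not
distributable. Each subject-session signal is built per channel as

* a 1/f^chi-shaped Gaussian background (subject-specific exponent chi),
* five band-limited noise components (delta..gamma) whose standard
  deviations are ``exp`` of realised log-amplitudes, and
* a narrowband oscillation at the subject's individual alpha peak
  frequency, its amplitude tied to the realised alpha log-amplitude,

plus optional artifacts (60 Hz line sinusoid, flat or noisy bad channels,
low-frequency blink-like transients on frontal channels).

Reliability is controlled at the level of the log band amplitudes: for
each band the realised value for subject i at session j is

    mu_band + u_i + v_ij + e_ij,
    u ~ N(0, sigma2_subject), v ~ N(0, sigma2_session), e ~ N(0, sigma2_error)

so the true intraclass correlation of the latent amplitude is
sigma2_subject / (sigma2_subject + sigma2_session + sigma2_error). Acting on
log-amplitudes keeps power positive (log-normal across subjects); the ICC
of the *extracted* relative-power feature differs slightly from the latent
target because relative power is a nonlinear function of all bands — tests
at the latent level are exact, end-to-end recovery is tolerance-banded.

Band-limited components are produced by spectral-domain shaping of white
Gaussian noise (multiply the FFT by a band mask and invert): exact band
control with no filter ringing. Randomness is counter-based: every
(subject, session) pair draws from its own ``default_rng([stream, seed,
i, j])`` stream, so enlarging the design never perturbs existing subjects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from ._exceptions import ConfigurationError, ValidationError
from .edf import Recording
from .montage import Montage, default_montage, fibonacci_montage
from .tables import INTERVAL_LABELS

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "variance_components_for_icc",
    "sample_subject_profiles",
    "synthesize_session",
    "generate_dataset",
    "BAND_ORDER",
]

BAND_ORDER = ("delta", "theta", "alpha", "beta", "gamma")

# latent log-amplitude means (log uV) giving a plausible resting spectrum:
# delta/theta-dominant low frequencies, modest beta, weak gamma
_DEFAULT_BAND_LOG_AMP = {
    "delta": math.log(8.0),
    "theta": math.log(5.0),
    "alpha": math.log(6.0),
    "beta": math.log(3.0),
    "gamma": math.log(1.5),
}

# same-day reliability targets used as the generator's default latent ICCs
_DEFAULT_BAND_ICC = {
    "delta": 0.810,
    "theta": 0.875,
    "alpha": 0.959,
    "beta": 0.840,
    "gamma": 0.814,
}

_INTERVAL_OFFSETS = {
    "baseline": timedelta(0),
    "same_day": timedelta(hours=5),
    "2wk": timedelta(days=14),
    "4wk": timedelta(days=28),
    "6wk": timedelta(days=42),
}


def variance_components_for_icc(
    target_icc: float, total_var: float, session_share: float = 0.5
) -> tuple[float, float, float]:
    """Split a total variance into (subject, session, error) components.

    ``sigma2_subject = target_icc * total_var``; the remainder is divided
    between the session and error components in proportion
    ``session_share : (1 - session_share)``. The three components sum to
    ``total_var`` and realise a latent intraclass correlation of exactly
    ``target_icc``.
    """
    if not 0.0 <= target_icc <= 1.0:
        raise ConfigurationError("target_icc must lie in [0, 1]")
    if total_var <= 0.0:
        raise ConfigurationError("total_var must be positive")
    if not 0.0 <= session_share <= 1.0:
        raise ConfigurationError("session_share must lie in [0, 1]")
    s2_subject = target_icc * total_var
    rest = total_var - s2_subject
    s2_session = session_share * rest
    s2_error = rest - s2_session
    return s2_subject, s2_session, s2_error


def _default_variance_components() -> dict[str, tuple[float, float, float]]:
    return {
        band: variance_components_for_icc(icc, total_var=0.04, session_share=0.3)
        for band, icc in _DEFAULT_BAND_ICC.items()
    }


@dataclass
class SimulationSpec:
    """Parameters of one synthetic test-retest study.

    Defaults emulate the acquisition this package models: 128 channels at
    1000 Hz, five-minute sessions, a 1/f aperiodic background with a
    subject-specific alpha peak near 10 Hz, and latent band-amplitude
    ICCs at the same-day reliability level. ``alpha_peak_jitter_sd`` is 0
    by default, making individual peak frequency a subject-level constant
    (true ICC ~ 1); set it positive to inject session-to-session peak
    wander.
    """

    n_subjects: int = 30
    sessions_per_subject: int = 2
    fs: float = 1000.0
    duration: float = 300.0
    n_channels: int = 128
    aperiodic_exponent_mean: float = 1.5
    aperiodic_exponent_sd: float = 0.1
    background_amp_uv: float = 10.0
    alpha_peak_freq_mean: float = 10.0
    alpha_peak_freq_sd: float = 1.0
    alpha_peak_jitter_sd: float = 0.0
    alpha_peak_amp_uv: float = 6.0
    alpha_peak_halfwidth_hz: float = 0.25
    band_log_amp_mean: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_BAND_LOG_AMP)
    )
    variance_components: dict[str, tuple[float, float, float]] = field(
        default_factory=_default_variance_components
    )
    line_noise_60hz: bool = False
    line_noise_amp_uv: float = 20.0
    n_bad_channels: int = 0
    blink_rate_per_min: float = 0.0
    blink_amp_uv: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.sessions_per_subject < 1:
            raise ConfigurationError("need at least one subject and one session")
        if self.sessions_per_subject > len(INTERVAL_LABELS):
            raise ConfigurationError(
                f"at most {len(INTERVAL_LABELS)} sessions per subject are labelled"
            )
        if self.fs <= 0 or self.duration <= 0:
            raise ConfigurationError("fs and duration must be positive")
        n_samp = self.fs * self.duration
        if abs(n_samp - round(n_samp)) > 1e-6:
            raise ConfigurationError("duration x fs must be an integer sample count")
        if not 8.0 <= self.alpha_peak_freq_mean <= 12.5:
            raise ConfigurationError("alpha_peak_freq_mean must lie in [8, 12.5] Hz")
        if set(self.band_log_amp_mean) != set(BAND_ORDER):
            raise ConfigurationError(f"band_log_amp_mean must cover {BAND_ORDER}")
        if set(self.variance_components) != set(BAND_ORDER):
            raise ConfigurationError(f"variance_components must cover {BAND_ORDER}")
        for band, comps in self.variance_components.items():
            if len(comps) != 3 or any(c < 0 for c in comps):
                raise ConfigurationError(
                    f"variance components for {band} must be 3 non-negative numbers"
                )
        if self.alpha_peak_jitter_sd < 0 or self.alpha_peak_freq_sd < 0:
            raise ConfigurationError("alpha peak SDs must be non-negative")
        if self.n_bad_channels < 0 or self.n_bad_channels >= self.n_channels:
            raise ConfigurationError("n_bad_channels must be in [0, n_channels)")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))

    @property
    def interval_labels(self) -> tuple[str, ...]:
        """Session labels in visit order: baseline then increasing interval."""
        return INTERVAL_LABELS[: self.sessions_per_subject]

    def montage(self) -> Montage:
        if self.n_channels == 128:
            return default_montage()
        return fibonacci_montage(self.n_channels)

    def true_icc(self) -> dict[str, float]:
        """Latent intraclass correlation per feature implied by the spec."""
        out = {}
        for band in BAND_ORDER:
            s2s, s2v, s2e = self.variance_components[band]
            total = s2s + s2v + s2e
            out[f"rbp_{band}"] = s2s / total if total > 0 else 1.0
        s2s = self.alpha_peak_freq_sd**2
        s2e = self.alpha_peak_jitter_sd**2
        out["ipf"] = s2s / (s2s + s2e) if (s2s + s2e) > 0 else 1.0
        return out


@dataclass
class GroundTruth:
    """Realised latent quantities for every subject-session.

    band_log_amp has shape (n_subjects, n_sessions, 5) in BAND_ORDER;
    alpha_peak_hz has shape (n_subjects, n_sessions); exponent is one chi
    per subject. true_icc maps feature name to the latent intraclass
    correlation implied by the generating variance components.
    """

    band_log_amp: np.ndarray
    alpha_peak_hz: np.ndarray
    exponent: np.ndarray
    true_icc: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        n_sub, n_ses, _ = self.band_log_amp.shape
        rows = []
        for i in range(n_sub):
            for j in range(n_ses):
                row = {"subject": i, "session": j}
                for b, band in enumerate(BAND_ORDER):
                    row[f"log_amp_{band}"] = self.band_log_amp[i, j, b]
                row["alpha_peak_hz"] = self.alpha_peak_hz[i, j]
                row["exponent"] = self.exponent[i]
                rows.append(row)
        return pd.DataFrame(rows)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Rejection-sampled truncated normal (narrow truncation, cheap)."""
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def sample_subject_profiles(spec: SimulationSpec) -> GroundTruth:
    """Draw the latent per-subject / per-session quantities.

    Deterministic given ``spec.seed``; independent of the signal-synthesis
    random streams.
    """
    n, k = spec.n_subjects, spec.sessions_per_subject
    n_bands = len(BAND_ORDER)
    sd_subject = np.array(
        [math.sqrt(spec.variance_components[b][0]) for b in BAND_ORDER]
    )
    sd_session = np.array(
        [math.sqrt(spec.variance_components[b][1]) for b in BAND_ORDER]
    )
    sd_error = np.array(
        [math.sqrt(spec.variance_components[b][2]) for b in BAND_ORDER]
    )
    mu = np.array([spec.band_log_amp_mean[b] for b in BAND_ORDER])

    band_log_amp = np.empty((n, k, n_bands))
    alpha_peak = np.empty((n, k))
    exponent = np.empty(n)
    # one stream per subject and one per subject-session, keyed by index:
    # enlarging the design never perturbs earlier subjects' draws
    for i in range(n):
        ri = np.random.default_rng([1, spec.seed, i])
        u = ri.standard_normal(n_bands) * sd_subject
        peak_i = float(
            _truncated_normal(
                ri, spec.alpha_peak_freq_mean, spec.alpha_peak_freq_sd, 8.0, 12.5, 1
            )[0]
        )
        exponent[i] = _truncated_normal(
            ri, spec.aperiodic_exponent_mean, spec.aperiodic_exponent_sd, 0.5, 3.0, 1
        )[0]
        for j in range(k):
            rij = np.random.default_rng([3, spec.seed, i, j])
            v = rij.standard_normal(n_bands) * sd_session
            e = rij.standard_normal(n_bands) * sd_error
            band_log_amp[i, j] = mu + u + v + e
            peak_ij = peak_i
            if spec.alpha_peak_jitter_sd > 0:
                peak_ij = float(
                    np.clip(
                        peak_ij + rij.normal(0.0, spec.alpha_peak_jitter_sd), 8.0, 12.5
                    )
                )
            alpha_peak[i, j] = peak_ij
    return GroundTruth(band_log_amp, alpha_peak, exponent, spec.true_icc())


_BAND_EDGES = {
    "delta": (2.0, 3.5),
    "theta": (4.0, 7.5),
    "alpha": (8.0, 12.5),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 80.0),
}


def _shaped_noise(rng, n_samples, fs, n_channels, mask_fn):
    """White Gaussian noise spectrally shaped by mask_fn(freqs) -> weights."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    weights = mask_fn(freqs)
    white = rng.standard_normal((n_channels, n_samples))
    spectrum = np.fft.rfft(white, axis=1) * weights[None, :]
    x = np.fft.irfft(spectrum, n=n_samples, axis=1)
    return x


def _unit_std(x):
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def synthesize_session(
    truth: GroundTruth,
    subject: int,
    session: int,
    spec: SimulationSpec,
) -> Recording:
    """Render the multichannel time series for one subject-session.

    Channels are independent realisations sharing the session's latent
    band amplitudes. Artifacts are added per ``spec``: a 60 Hz sinusoid on
    every channel, ``n_bad_channels`` channels overwritten (alternately
    flat and 20x-noise), and blink-like Gaussian transients on the frontal
    third of the montage.
    """
    n_sub, n_ses, _ = truth.band_log_amp.shape
    if not (0 <= subject < n_sub and 0 <= session < n_ses):
        raise ValidationError("subject/session index outside the simulated design")
    rng = np.random.default_rng([2, spec.seed, subject, session])
    n = spec.n_samples
    n_ch = spec.n_channels
    chi = truth.exponent[subject]

    # aperiodic background: amplitude ~ f^(-chi/2), flattened below 1 Hz
    def aperiodic(freqs):
        w = np.zeros_like(freqs)
        nz = freqs > 0
        w[nz] = np.maximum(freqs[nz], 1.0) ** (-chi / 2.0)
        return w

    data = _unit_std(_shaped_noise(rng, n, spec.fs, n_ch, aperiodic))
    data *= spec.background_amp_uv

    for b, band in enumerate(BAND_ORDER):
        lo, hi = _BAND_EDGES[band]
        amp = math.exp(truth.band_log_amp[subject, session, b])
        comp = _shaped_noise(
            rng, n, spec.fs, n_ch, lambda f: ((f >= lo) & (f <= hi)).astype(float)
        )
        data += amp * _unit_std(comp)

    # narrowband alpha oscillation at the subject's peak frequency; its
    # amplitude covaries with the realised alpha log-amplitude so that the
    # peak strengthens and weakens with the band it lives in
    f_peak = truth.alpha_peak_hz[subject, session]
    rel = math.exp(
        truth.band_log_amp[subject, session, BAND_ORDER.index("alpha")]
        - spec.band_log_amp_mean["alpha"]
    )
    peak_amp = spec.alpha_peak_amp_uv * rel
    if peak_amp > 0:
        hw = spec.alpha_peak_halfwidth_hz
        comp = _shaped_noise(
            rng, n, spec.fs, n_ch,
            lambda f: ((f >= f_peak - hw) & (f <= f_peak + hw)).astype(float),
        )
        data += peak_amp * _unit_std(comp)

    if spec.line_noise_60hz:
        t = np.arange(n) / spec.fs
        phase = rng.uniform(0, 2 * np.pi)
        data += spec.line_noise_amp_uv * np.sin(2 * np.pi * 60.0 * t + phase)[None, :]

    if spec.blink_rate_per_min > 0:
        montage = spec.montage()
        frontal = np.where(montage.positions[:n_ch, 1] > 0.55)[0]
        n_blinks = rng.poisson(spec.blink_rate_per_min * spec.duration / 60.0)
        t = np.arange(n) / spec.fs
        for _ in range(n_blinks):
            centre = rng.uniform(0.5, spec.duration - 0.5)
            pulse = spec.blink_amp_uv * np.exp(-0.5 * ((t - centre) / 0.15) ** 2)
            data[frontal] += pulse[None, :]

    for idx in range(spec.n_bad_channels):
        ch = idx  # deterministic: first channels are the bad ones
        if idx % 2 == 0:
            data[ch] = 0.0  # flat
        else:
            data[ch] = rng.standard_normal(n) * 20.0 * spec.background_amp_uv

    montage = spec.montage()
    labels = montage.labels[:n_ch]
    base_dt = datetime(2024, 1, 8, 9, 0) + timedelta(minutes=7 * subject)
    label = spec.interval_labels[session]
    return Recording(
        data=data,
        fs=spec.fs,
        channel_labels=labels,
        subject_id=f"sub{subject + 1:03d}",
        session_id=f"ses{session + 1:02d}",
        session_datetime=base_dt + _INTERVAL_OFFSETS[label],
    )


def generate_dataset(
    spec: SimulationSpec,
) -> tuple[list[Recording], pd.DataFrame, GroundTruth]:
    """Generate all recordings plus the session table and ground truth.

    Sessions are labelled in visit order baseline, same_day, 2wk, 4wk,
    6wk (truncated to ``sessions_per_subject``): each post-baseline visit
    pairs with baseline to form one test-retest interval. Fully
    reproducible from ``spec.seed``.
    """
    truth = sample_subject_profiles(spec)
    recordings = []
    rows = []
    for i in range(spec.n_subjects):
        for j in range(spec.sessions_per_subject):
            rec = synthesize_session(truth, i, j, spec)
            recordings.append(rec)
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "session_id": rec.session_id,
                    "session_datetime": rec.session_datetime.isoformat(),
                    "interval_label": spec.interval_labels[j],
                }
            )
    sessions = pd.DataFrame(rows)
    return recordings, sessions, truth
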