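"""Signal conditioning: zero-phase filtering, epoching, artifact rejection,
bad-channel detection and spherical-spline interpolation.

The chain mirrors a conventional resting-EEG pipeline: a 2 Hz highpass and
80 Hz lowpass zero-phase digital filter with a 55-65 Hz line-noise bandstop
(harmonics removed up to the Nyquist frequency of the original sampling
rate), segmentation into 2 s epochs, deterministic threshold-based epoch
rejection standing in for manual artifact inspection, and Perrin-style
spherical-spline interpolation of bad channels capped at 5% of the montage.

The filter is a single symmetric (linear-phase) windowed-sinc FIR kernel
designed over the combined highpass/lowpass/bandstop amplitude response and
applied once with reflection edge-padding; trimming the constant group
delay makes the overall response zero-phase.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy.special import eval_legendre

from ._exceptions import ConfigurationError, EmptyResultError, ValidationError
from .edf import Recording
from .montage import Montage

__all__ = [
    "FilterSpec",
    "EpochSet",
    "design_fir_kernel",
    "apply_filters",
    "segment_epochs",
    "reject_epochs",
    "detect_bad_channels",
    "spherical_spline_interpolate",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterSpec:
    """Passband 2-80 Hz with 55-65 Hz bandstop and its harmonics.

    ``bandstops`` defaults to (55, 65) plus harmonic images (115, 125),
    (175, 185), ... up to the Nyquist frequency of the original sampling
    rate, as computed by :meth:`for_fs`. Transition widths: 25% of each
    corner frequency for highpass/lowpass, a fixed 2.5 Hz for bandstop
    edges.
    """

    highpass_hz: float = 2.0
    lowpass_hz: float = 80.0
    bandstops: tuple[tuple[float, float], ...] = ((55.0, 65.0),)
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.highpass_hz >= self.lowpass_hz:
            raise ConfigurationError("highpass must be below lowpass")
        stops = sorted(self.bandstops)
        for (l1, h1), (l2, h2) in zip(stops, stops[1:]):
            if h1 > l2:
                raise ConfigurationError("bandstop intervals must not overlap")
        for lo, hi in stops:
            if not 0 < lo < hi:
                raise ConfigurationError("bandstop edges must be positive and ordered")

    @classmethod
    def for_fs(
        cls,
        fs: float,
        highpass_hz: float = 2.0,
        lowpass_hz: float = 80.0,
        stop_center: float = 60.0,
        stop_halfwidth: float = 5.0,
    ) -> "FilterSpec":
        """Build the spec with line-noise harmonics up to Nyquist of ``fs``."""
        nyq = fs / 2.0
        stops = []
        h = stop_center
        while h - stop_halfwidth < nyq:
            stops.append((h - stop_halfwidth, min(h + stop_halfwidth, nyq)))
            h += stop_center
        return cls(highpass_hz, lowpass_hz, tuple(stops))


@dataclass
class EpochSet:
    """Fixed-length epochs of one recording.

    ``data`` is epochs x channels x samples; ``kept_mask`` aligns with the
    original epoch order and marks epochs surviving rejection.
    """

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    epoch_length_s: float = 2.0
    kept_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    interpolated_channels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError("epochs must be 3-D (epochs x channels x samples)")
        expected = self.epoch_length_s * self.fs
        if abs(self.data.shape[2] - expected) > 1e-9:
            raise ValidationError(
                f"epoch length {self.data.shape[2]} samples != "
                f"{self.epoch_length_s} s x {self.fs} Hz"
            )
        if self.kept_mask is None:
            self.kept_mask = np.ones(self.data.shape[0], dtype=bool)
        self.kept_mask = np.asarray(self.kept_mask, dtype=bool)
        if self.kept_mask.shape != (self.data.shape[0],):
            raise ValidationError("kept_mask must have one entry per epoch")
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != self.data.shape[1]:
            raise ValidationError("one label per channel required")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_kept(self) -> int:
        return int(self.kept_mask.sum())

    def kept_data(self) -> np.ndarray:
        return self.data[self.kept_mask]


def design_fir_kernel(fspec: FilterSpec, fs: float) -> np.ndarray:
    """Design the combined symmetric FIR kernel for ``fspec`` at rate ``fs``.

    Windowed (Hamming) frequency-sampling design over the piecewise-linear
    amplitude response: 0 below the highpass transition, 1 in the passband,
    0 inside each bandstop and above the lowpass transition. Kernel length
    scales with the sharpest transition so every stopband reaches the
    window's ~50 dB floor.
    """
    nyq = fs / 2.0
    if nyq <= fspec.lowpass_hz:
        raise ConfigurationError(
            f"sampling rate {fs} Hz too low for lowpass {fspec.lowpass_hz} Hz"
        )
    hp_tw = 0.25 * fspec.highpass_hz
    lp_tw = 0.25 * fspec.lowpass_hz
    stop_tw = 2.5

    # breakpoints as (freq, gain); kept strictly increasing afterwards
    pts: list[tuple[float, float]] = [(0.0, 0.0), (fspec.highpass_hz - hp_tw / 2, 0.0),
                                      (fspec.highpass_hz + hp_tw / 2, 1.0)]
    for lo, hi in sorted(fspec.bandstops):
        if lo - stop_tw >= nyq:
            continue
        pts.append((max(lo - stop_tw, 0.0), 1.0))
        pts.append((lo, 0.0))
        pts.append((min(hi, nyq), 0.0))
        if hi + stop_tw < nyq:
            pts.append((hi + stop_tw, 1.0))
    pts.append((fspec.lowpass_hz - lp_tw / 2, 1.0))
    pts.append((fspec.lowpass_hz + lp_tw / 2, 0.0))
    pts.append((nyq, 0.0))

    pts.sort(key=lambda p: p[0])
    freqs: list[float] = []
    gains: list[float] = []
    for f, g in pts:
        if f >= nyq:
            continue
        if freqs and f <= freqs[-1]:
            f = np.nextafter(freqs[-1], np.inf)
        # inside any stopband or above the lowpass edge the gain is 0
        g_eff = g
        for lo, hi in fspec.bandstops:
            if lo <= f <= hi:
                g_eff = 0.0
        if f >= fspec.lowpass_hz + lp_tw / 2:
            g_eff = 0.0
        freqs.append(f)
        gains.append(g_eff)
    freqs[0] = 0.0
    freqs.append(nyq)
    gains.append(0.0)  # everything above the lowpass edge is stopband

    min_tw = min(hp_tw, stop_tw)
    numtaps = int(np.ceil(6.6 * fs / min_tw))
    numtaps += 1 - numtaps % 2  # odd -> type-I linear phase
    return signal.firwin2(numtaps, freqs, gains, fs=fs)


def apply_filters(rec: Recording, fspec: FilterSpec | None = None) -> Recording:
    """Zero-phase filter a recording with the combined FIR kernel.

    The symmetric kernel is applied once after reflecting the signal by
    half a kernel length at each edge; the 'valid' part of the convolution
    restores the original length with zero group delay.
    """
    if fspec is None:
        fspec = FilterSpec.for_fs(rec.fs)
    kernel = design_fir_kernel(fspec, rec.fs)
    half = len(kernel) // 2
    data = rec.data
    if data.shape[1] < 2:
        raise ValidationError("recording too short to filter")
    pad = min(half, data.shape[1] - 1)
    padded = np.pad(data, ((0, 0), (pad, pad)), mode="reflect")
    if pad < half:  # very short recording: extend with edge values
        padded = np.pad(padded, ((0, 0), (half - pad, half - pad)), mode="edge")
    out = signal.fftconvolve(padded, kernel[None, :], mode="valid", axes=1)
    assert out.shape == data.shape
    return rec.copy_with(data=out)


def segment_epochs(rec: Recording, epoch_length_s: float = 2.0) -> EpochSet:
    """Cut a recording into consecutive non-overlapping fixed-length epochs.

    A trailing partial epoch is discarded. Raises ValidationError when the
    recording is shorter than one epoch.
    """
    spe = int(round(epoch_length_s * rec.fs))
    if abs(spe - epoch_length_s * rec.fs) > 1e-9:
        raise ValidationError("epoch length times fs must be an integer")
    n_epochs = rec.n_samples // spe
    if n_epochs < 1:
        raise ValidationError(
            f"recording of {rec.n_samples} samples shorter than one "
            f"{epoch_length_s} s epoch at {rec.fs} Hz"
        )
    trimmed = rec.data[:, : n_epochs * spe]
    epochs = trimmed.reshape(rec.n_channels, n_epochs, spe).transpose(1, 0, 2).copy()
    return EpochSet(
        data=epochs,
        fs=rec.fs,
        channel_labels=rec.channel_labels,
        epoch_length_s=epoch_length_s,
    )


def _robust_z(x: np.ndarray) -> np.ndarray:
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    scale = 1.4826 * mad
    if scale == 0:
        scale = np.std(x) or 1.0
    return (x - med) / scale


def reject_epochs(
    es: EpochSet,
    abs_thresh_uv: float = 150.0,
    z_thresh: float = 4.0,
    montage: Montage | None = None,
) -> EpochSet:
    """Drop artifact epochs by amplitude and robust-variance criteria.

    An epoch is rejected when any analysis channel's half peak-to-peak
    amplitude exceeds ``abs_thresh_uv`` within it, or when its log total
    variance lies more than ``z_thresh`` robust z-units above the
    across-epoch median. Raises EmptyResultError (with counts in the
    message) when nothing survives.
    """
    if es.n_epochs < 1:
        raise ValidationError("need at least one epoch")
    if montage is not None:
        keep_ch = [
            i for i, l in enumerate(es.channel_labels)
            if l in set(montage.analysis_labels)
        ]
        data = es.data[:, keep_ch, :]
    else:
        data = es.data
    half_pp = (data.max(axis=2) - data.min(axis=2)) / 2.0  # epochs x channels
    amp_bad = (half_pp > abs_thresh_uv).any(axis=1)
    total_var = data.var(axis=2).sum(axis=1)
    with np.errstate(divide="ignore"):
        log_var = np.log(np.maximum(total_var, np.finfo(float).tiny))
    var_bad = _robust_z(log_var) > z_thresh
    keep = es.kept_mask & ~amp_bad & ~var_bad
    if not keep.any():
        raise EmptyResultError(
            f"all {es.n_epochs} epochs rejected "
            f"(amplitude: {int(amp_bad.sum())}, variance: {int(var_bad.sum())})"
        )
    dropped = int(es.kept_mask.sum() - keep.sum())
    if dropped:
        logger.info("rejected %d/%d epochs", dropped, es.n_epochs)
    return replace(es, kept_mask=keep)


def detect_bad_channels(
    es: EpochSet, z_thresh: float = 5.0, max_frac: float = 0.05
) -> list[str]:
    """Flag channels with aberrant log variance, capped at ``max_frac``.

    A channel is a candidate when it is exactly flat or when the robust
    z-score of its log variance across the recording exceeds ``z_thresh``
    in magnitude. At most ``floor(max_frac * n_channels)`` labels are
    returned, worst first (flat channels outrank everything); a warning is
    emitted when candidates exceed the cap.
    """
    if es.data.shape[1] < 2:
        raise ValidationError("need at least two channels")
    flat = np.ptp(es.data, axis=(0, 2)) == 0.0
    ch_var = es.data.var(axis=2).mean(axis=0)
    with np.errstate(divide="ignore"):
        log_var = np.log(np.maximum(ch_var, np.finfo(float).tiny))
    z = _robust_z(log_var)
    badness = np.where(flat, np.inf, np.abs(z))
    candidates = np.where(flat | (np.abs(z) > z_thresh))[0]
    cap = int(np.floor(max_frac * es.data.shape[1]))
    order = candidates[np.argsort(-badness[candidates], kind="stable")]
    if len(order) > cap:
        warnings.warn(
            f"{len(order)} bad-channel candidates exceed the "
            f"{max_frac:.0%} cap ({cap}); keeping the worst {cap}",
            stacklevel=2,
        )
        order = order[:cap]
    return [es.channel_labels[i] for i in order]


def _spline_g(cosang: np.ndarray, m: int, n_legendre: int) -> np.ndarray:
    """Perrin spherical-spline kernel: truncated Legendre series of cos(angle)."""
    g = np.zeros_like(cosang, dtype=float)
    for deg in range(1, n_legendre + 1):
        g += (2 * deg + 1) / (deg**m * (deg + 1) ** m) * eval_legendre(deg, cosang)
    return g / (4.0 * np.pi)


def spherical_spline_interpolate(
    es: EpochSet,
    bad: list[str],
    montage: Montage,
    m: int = 4,
    n_legendre: int = 7,
    reg: float = 1e-5,
) -> EpochSet:
    """Replace bad channels by their spherical-spline estimate.

    Solves the Perrin interpolation system on the good channels (spline
    order ``m``, Legendre series truncated at ``n_legendre``, Tikhonov
    regularisation ``reg`` on the kernel matrix) and evaluates the spline
    at the bad sites. Good channels are untouched; the mapping is linear
    and time-independent, so one matrix multiply handles every sample.
    """
    if not bad:
        return es
    labels = list(es.channel_labels)
    for b in bad:
        if b not in labels:
            raise ValidationError(f"bad-channel label {b!r} not in the recording")
    bad_idx = np.array([labels.index(b) for b in bad])
    good_idx = np.array([i for i in range(len(labels)) if labels[i] not in set(bad)])
    if len(good_idx) < 4:
        raise ValidationError(
            f"spherical spline needs >= 4 good channels, have {len(good_idx)}"
        )
    pos = np.array([montage.positions[montage.index_of(l)] for l in labels])
    pg, pb = pos[good_idx], pos[bad_idx]

    G = _spline_g(np.clip(pg @ pg.T, -1.0, 1.0), m, n_legendre)
    Gb = _spline_g(np.clip(pb @ pg.T, -1.0, 1.0), m, n_legendre)
    n_good = len(good_idx)
    A = np.zeros((n_good + 1, n_good + 1))
    A[:n_good, :n_good] = G + reg * np.eye(n_good)
    A[:n_good, n_good] = 1.0
    A[n_good, :n_good] = 1.0

    # linear operator bad <- good: y_bad = Gb c + d with [c; d] = A^-1 [y; 0]
    inv = np.linalg.solve(A, np.eye(n_good + 1))
    W = np.hstack([Gb, np.ones((len(bad_idx), 1))]) @ inv[:, :n_good]

    data = es.data.copy()
    flat = data[:, good_idx, :].transpose(1, 0, 2).reshape(n_good, -1)
    est = W @ flat
    data[:, bad_idx, :] = est.reshape(len(bad_idx), es.n_epochs, -1).transpose(1, 0, 2)
    interp = tuple(dict.fromkeys(es.interpolated_channels + tuple(bad)))
    return replace(es, data=data, interpolated_channels=interp)
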