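"""Spectral features: Welch relative band power and individual peak frequency.

Six features per recording: the mean relative power in delta (2-3.5 Hz),
theta (4-7.5 Hz), alpha (8-12.5 Hz), beta (13-30 Hz) and gamma (30-80 Hz,
excluding the 55-65 Hz line-noise stopband from the band average), plus the
individual peak frequency (IPF) — the frequency of the maximum log-scaled
relative power within 5-14 Hz. Relative power at a frequency is the
absolute Welch power there divided by the channel's total power over
2-80 Hz. Features are computed per channel and then averaged, unweighted,
over the non-excluded channels of the analysis montage.

The Welch estimate uses 2 s Hann windows with 50% overlap (0.5 Hz
resolution) drawn from the kept epochs only: overlapping segments slide
within each contiguous run of kept epochs but never span a rejection gap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import get_window

from ._exceptions import EmptyResultError, ValidationError
from .montage import Montage
from .preprocess import EpochSet
from .tables import FEATURE_NAMES

__all__ = [
    "BandScheme",
    "PowerSpectrum",
    "welch_psd",
    "relative_power",
    "band_powers",
    "individual_peak_frequency",
    "montage_average",
    "compute_features",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BandScheme:
    """Band edges in Hz plus the gamma stopband and total-power range.

    Bin assignment: a bin at frequency f belongs to band [lo, hi] iff
    lo <= f <= hi; a bin on a shared boundary (30 Hz between beta and
    gamma) goes to the lower band. Gamma's band average excludes bins
    inside the 55-65 Hz stopband; the 2-80 Hz total-power denominator
    keeps them (their post-filter power is ~0).
    """

    bands: tuple[tuple[str, float, float], ...] = (
        ("delta", 2.0, 3.5),
        ("theta", 4.0, 7.5),
        ("alpha", 8.0, 12.5),
        ("beta", 13.0, 30.0),
        ("gamma", 30.0, 80.0),
    )
    gamma_stopband: tuple[float, float] = (55.0, 65.0)
    total_range: tuple[float, float] = (2.0, 80.0)
    ipf_window: tuple[float, float] = (5.0, 14.0)

    def __post_init__(self) -> None:
        lo_t, hi_t = self.total_range
        for name, lo, hi in self.bands:
            if not (lo_t <= lo < hi <= hi_t):
                raise ValidationError(f"band {name} [{lo}, {hi}] outside total range")

    def band_masks(self, freqs: np.ndarray) -> dict[str, np.ndarray]:
        """Unique bin-to-band assignment on a frequency grid."""
        taken = np.zeros(freqs.shape, dtype=bool)
        masks: dict[str, np.ndarray] = {}
        for name, lo, hi in self.bands:
            mask = (freqs >= lo) & (freqs <= hi) & ~taken
            if name == "gamma":
                s_lo, s_hi = self.gamma_stopband
                mask &= ~((freqs >= s_lo) & (freqs <= s_hi))
            masks[name] = mask
            taken |= mask
        return masks


@dataclass
class PowerSpectrum:
    """Per-channel absolute and relative power on a regular frequency grid.

    ``relative`` is defined on the total-range bins only (NaN outside);
    each defined channel row sums to 1 over those bins. ``undefined``
    flags channels whose total in-range power was zero (flat channels).
    """

    freqs: np.ndarray
    absolute: np.ndarray
    channel_labels: tuple[str, ...]
    relative: np.ndarray | None = None
    undefined: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.absolute = np.asarray(self.absolute, dtype=float)
        if self.absolute.shape != (len(self.channel_labels), self.freqs.size):
            raise ValidationError("absolute must be channels x freqs")
        if np.any(self.absolute < 0):
            raise ValidationError("absolute power must be non-negative")
        if self.undefined is None:
            self.undefined = np.zeros(len(self.channel_labels), dtype=bool)


def welch_psd(es: EpochSet, scheme: BandScheme | None = None) -> PowerSpectrum:
    """Welch power spectral density over the kept epochs of a recording.

    Mean of Hann-windowed, 50%-overlapping 2 s segment periodograms with
    window power normalisation (density scaling, one-sided). Segments are
    taken inside contiguous runs of kept epochs, so no segment straddles a
    rejected epoch. Frequency resolution is 1/(2 s) = 0.5 Hz.
    """
    if es.n_kept < 1:
        raise EmptyResultError("no kept epochs to estimate a spectrum from")
    fs = es.fs
    nperseg = int(round(2.0 * fs))
    step = nperseg // 2
    window = get_window("hann", nperseg, fftbins=True)
    norm = fs * (window**2).sum()
    n_ch = es.data.shape[1]
    spe = es.data.shape[2]

    psd = np.zeros((n_ch, nperseg // 2 + 1))
    n_segments = 0
    # contiguous runs of kept epochs
    kept = es.kept_mask
    boundaries = np.flatnonzero(np.diff(kept.astype(int)) != 0) + 1
    runs = np.split(np.arange(es.n_epochs), boundaries)
    for run in runs:
        if run.size == 0 or not kept[run[0]]:
            continue
        chunk = es.data[run].transpose(1, 0, 2).reshape(n_ch, run.size * spe)
        n_samp = chunk.shape[1]
        for start in range(0, n_samp - nperseg + 1, step):
            seg = chunk[:, start : start + nperseg] * window[None, :]
            spec = np.fft.rfft(seg, axis=1)
            p = (spec.real**2 + spec.imag**2) / norm
            p[:, 1:-1] *= 2.0  # one-sided
            psd += p
            n_segments += 1
    if n_segments == 0:
        raise EmptyResultError("kept data shorter than one Welch segment")
    psd /= n_segments
    freqs = np.fft.rfftfreq(nperseg, 1.0 / fs)
    return PowerSpectrum(freqs=freqs, absolute=psd, channel_labels=es.channel_labels)


def relative_power(
    ps: PowerSpectrum, scheme: BandScheme | None = None
) -> PowerSpectrum:
    """Fill the relative part: per-bin power / total 2-80 Hz power.

    Bins outside the total range are excluded from both the numerator
    pool and the denominator (NaN in the relative spectrum). Channels
    with zero in-range total power are flagged undefined and excluded
    from downstream montage averages with a warning.
    """
    scheme = scheme or BandScheme()
    lo, hi = scheme.total_range
    in_range = (ps.freqs >= lo) & (ps.freqs <= hi)
    if not in_range.any():
        raise ValidationError("frequency grid has no bins inside the total range")
    total = ps.absolute[:, in_range].sum(axis=1)
    undefined = total <= 0.0
    if undefined.any():
        bad = [ps.channel_labels[i] for i in np.flatnonzero(undefined)]
        logger.warning("channels with zero total power marked undefined: %s", bad)
    rel = np.full_like(ps.absolute, np.nan)
    safe_total = np.where(undefined, 1.0, total)
    rel[:, in_range] = ps.absolute[:, in_range] / safe_total[:, None]
    rel[undefined, :] = np.nan
    ps.relative = rel
    ps.undefined = undefined
    return ps


def band_powers(
    ps: PowerSpectrum, scheme: BandScheme | None = None
) -> dict[str, np.ndarray]:
    """Per-channel relative band power: mean of relative bins in each band."""
    scheme = scheme or BandScheme()
    if ps.relative is None:
        raise ValidationError("relative power not computed; call relative_power first")
    masks = scheme.band_masks(ps.freqs)
    out = {}
    for name, mask in masks.items():
        if not mask.any():
            raise ValidationError(f"band {name} has no bins on this grid")
        out[f"rbp_{name}"] = ps.relative[:, mask].mean(axis=1)
    return out


def individual_peak_frequency(
    ps: PowerSpectrum, scheme: BandScheme | None = None
) -> np.ndarray:
    """Per-channel frequency of maximal log10 relative power in 5-14 Hz.

    The global in-window maximum is used; ties break toward the lower
    frequency. Monotone (peakless) spectra therefore return a window edge
    — logged as a quality flag.
    """
    scheme = scheme or BandScheme()
    if ps.relative is None:
        raise ValidationError("relative power not computed; call relative_power first")
    lo, hi = scheme.ipf_window
    win = (ps.freqs >= lo) & (ps.freqs <= hi)
    if not win.any():
        raise ValidationError("IPF window empty on this frequency grid")
    wfreqs = ps.freqs[win]
    with np.errstate(divide="ignore"):
        logrel = np.log10(ps.relative[:, win])
    idx = np.nanargmax(
        np.where(np.isnan(logrel), -np.inf, logrel), axis=1
    )  # argmax takes the first (lowest-frequency) maximum
    ipf = wfreqs[idx]
    ipf = np.where(ps.undefined, np.nan, ipf)
    at_edge = np.isin(ipf, [wfreqs[0], wfreqs[-1]])
    if at_edge.any():
        labels = [ps.channel_labels[i] for i in np.flatnonzero(at_edge)]
        logger.info("IPF at window edge (no interior peak) for channels %s", labels)
    return ipf


def montage_average(
    per_channel: dict[str, np.ndarray],
    ps: PowerSpectrum,
    montage: Montage,
) -> dict[str, float]:
    """Unweighted mean of per-channel features over analysis channels.

    Excluded-montage and undefined channels are dropped; dropping any
    defined analysis channel is logged. Raises EmptyResultError when no
    channel remains.
    """
    analysis = set(montage.analysis_labels)
    keep = np.array(
        [
            (l in analysis) and not u
            for l, u in zip(ps.channel_labels, ps.undefined)
        ]
    )
    n_excluded_undefined = sum(
        1 for l, u in zip(ps.channel_labels, ps.undefined) if l in analysis and u
    )
    if n_excluded_undefined:
        logger.warning(
            "%d undefined analysis channels excluded from the montage average",
            n_excluded_undefined,
        )
    if not keep.any():
        raise EmptyResultError("no defined analysis channels to average")
    return {name: float(np.mean(vals[keep])) for name, vals in per_channel.items()}


def compute_features(
    es: EpochSet, montage: Montage, scheme: BandScheme | None = None
) -> dict[str, float]:
    """Full feature extraction for one recording's epochs.

    Returns the six montage-averaged features keyed by the canonical
    feature names.
    """
    scheme = scheme or BandScheme()
    ps = relative_power(welch_psd(es), scheme)
    per_channel = band_powers(ps, scheme)
    per_channel["ipf"] = individual_peak_frequency(ps, scheme)
    feats = montage_average(per_channel, ps, montage)
    return {name: feats[name] for name in FEATURE_NAMES}
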