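"""Electrode montages on the unit sphere.

A montage is an ordered list of labelled scalp positions, each carrying an
``excluded`` flag. The packaged default is a synthetic 128-channel layout
standing in for a high-density geodesic sensor net: positions are placed
deterministically on a spherical cap by a Fibonacci spiral, and the 20
lowest positions (the outermost ring below the equator, where face and neck
electrodes sit) are flagged excluded, leaving the 108-channel whole-brain
analysis subset over which spectral features are averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from ._exceptions import ValidationError

__all__ = [
    "Montage",
    "load_montage",
    "save_montage",
    "default_montage",
    "fibonacci_montage",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class Montage:
    """Ordered electrode layout on the unit sphere.

    Parameters
    ----------
    labels : list of str
        Unique channel labels, in recording order.
    positions : ndarray, shape (n_channels, 3)
        Cartesian unit vectors (head-centred sphere, z up, y anterior).
    excluded : ndarray of bool, shape (n_channels,)
        True for channels dropped from the whole-brain analysis subset.
    """

    labels: tuple[str, ...]
    positions: np.ndarray
    excluded: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        positions = np.asarray(self.positions, dtype=float)
        if positions.ndim != 2 or positions.shape[1] != 3:
            raise ValidationError("positions must have shape (n_channels, 3)")
        if len(self.labels) != positions.shape[0]:
            raise ValidationError(
                f"{len(self.labels)} labels for {positions.shape[0]} positions"
            )
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({l for l in self.labels if list(self.labels).count(l) > 1})
            raise ValidationError(f"duplicate channel labels: {dupes}")
        norms = np.linalg.norm(positions, axis=1)
        if np.any(norms <= 0) or not np.all(np.isfinite(norms)):
            raise ValidationError("positions must be finite and non-zero")
        if np.any(np.abs(norms - 1.0) > 1e-6):
            positions = positions / norms[:, None]
        excluded = self.excluded
        if excluded is None:
            excluded = np.zeros(positions.shape[0], dtype=bool)
        excluded = np.asarray(excluded, dtype=bool)
        if excluded.shape != (positions.shape[0],):
            raise ValidationError("excluded flag must have one entry per channel")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "positions", positions)
        object.__setattr__(self, "excluded", excluded)

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    @property
    def analysis_labels(self) -> tuple[str, ...]:
        """Labels of the non-excluded (analysis) channels, in montage order."""
        return tuple(l for l, e in zip(self.labels, self.excluded) if not e)

    @property
    def n_analysis(self) -> int:
        return int((~self.excluded).sum())

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ValidationError(f"unknown channel label: {label!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": list(self.labels),
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
                "excluded": self.excluded.astype(int),
            }
        )


def load_montage(path: str | Path) -> Montage:
    """Read a montage from delimited text with columns label, x, y, z, excluded.

    Positions are renormalised onto the unit sphere; exclusion flags are
    read verbatim. Duplicate labels raise :class:`ValidationError`.
    """
    df = pd.read_csv(path)
    required = {"label", "x", "y", "z", "excluded"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"montage file missing columns: {sorted(missing)}")
    labels = [str(l) for l in df["label"]]
    positions = df[["x", "y", "z"]].to_numpy(dtype=float)
    excluded = df["excluded"].to_numpy().astype(bool)
    return Montage(tuple(labels), positions, excluded)


def save_montage(montage: Montage, path: str | Path) -> None:
    """Write a montage as CSV (label, x, y, z, excluded) at full precision."""
    montage.to_frame().to_csv(path, index=False, float_format="%.17g")


def fibonacci_montage(
    n_channels: int,
    n_excluded: int = 0,
    z_min: float = -0.45,
    prefix: str = "E",
) -> Montage:
    """Deterministic Fibonacci-spiral layout on the spherical cap z >= z_min.

    Channels are labelled ``E1..En`` from vertex to rim; when ``n_excluded``
    is positive the lowest ``n_excluded`` positions (largest polar angle,
    i.e. the face/neck ring) are flagged excluded.
    """
    if not 0 <= n_excluded < n_channels:
        raise ValidationError("n_excluded must be in [0, n_channels)")
    i = np.arange(n_channels)
    z = 1.0 - (1.0 - z_min) * (i + 0.5) / n_channels
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    theta = _GOLDEN_ANGLE * i
    positions = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    excluded = np.zeros(n_channels, dtype=bool)
    if n_excluded:
        excluded[np.argsort(z)[:n_excluded]] = True
    labels = tuple(f"{prefix}{k + 1}" for k in i)
    return Montage(labels, positions, excluded)


def default_montage() -> Montage:
    """The packaged 128-channel montage with the 108-channel analysis subset.

    Synthetic layout: an idealised unit-sphere approximation of a
    128-channel geodesic net; exactly 20 face/neck channels are excluded.
    """
    with resources.files("eegretest.data").joinpath("montage128.csv").open("rb") as fh:
        return load_montage(fh)
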