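"""Pulse-height and binned spectra: calibration, rebinning, subtraction.

A multichannel analyzer delivers raw channel counts (8 keV per channel in the
modelled setup).  Channels are calibrated against radioisotope photopeaks,
summed in groups of 25 to 0.2 MeV bins, and the shielded-beam background is
subtracted before unfolding.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError
from .grids import EnergyGrid

__all__ = [
    "PulseHeightSpectrum",
    "BinnedSpectrum",
    "CalibrationModel",
    "calibrate_channels",
    "rebin_channels",
    "subtract_background",
    "mean_energy",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PulseHeightSpectrum:
    """Raw MCA channel counts."""

    counts: np.ndarray  # non-negative integers, one per channel
    channel_kev: float = 8.0  # energy width per channel (keV)
    live_time: float | None = None  # seconds
    label: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if np.any(counts < 0):
            raise ValidationError("channel counts must be non-negative")
        if self.channel_kev <= 0:
            raise ValidationError("channel width must be > 0")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def n_channels(self) -> int:
        return len(self.counts)

    @property
    def total_counts(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class BinnedSpectrum:
    """Counts or relative fluence on a uniform energy grid."""

    grid: EnergyGrid
    values: np.ndarray
    uncertainty: np.ndarray | None = None
    normalized: bool = False
    live_time: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, float)
        if len(values) != self.grid.n_bins:
            raise ValidationError("value count does not match grid")
        if np.any(values < 0):
            raise ValidationError("binned values must be non-negative")
        if self.normalized and abs(values.sum() - 1.0) > 1e-9:
            raise ValidationError("normalized spectrum must sum to 1")
        object.__setattr__(self, "values", values)
        if self.uncertainty is not None:
            unc = np.asarray(self.uncertainty, float)
            if unc.shape != values.shape:
                raise ValidationError("uncertainty shape mismatch")
            object.__setattr__(self, "uncertainty", unc)

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def normalize(self) -> "BinnedSpectrum":
        """Return a copy scaled to unit total (relative fluence)."""
        total = self.total
        if total <= 0:
            raise ValidationError("cannot normalize an empty spectrum")
        unc = self.uncertainty / total if self.uncertainty is not None else None
        vals = self.values / total
        vals = vals / vals.sum()  # exact renormalization
        return replace(self, values=vals, uncertainty=unc, normalized=True)

    def with_poisson_uncertainty(self) -> "BinnedSpectrum":
        return replace(self, uncertainty=np.sqrt(self.values))


@dataclass(frozen=True)
class CalibrationModel:
    """Linear channel -> energy map: E(keV) = slope * channel + offset."""

    slope_kev_per_channel: float
    offset_kev: float = 0.0

    def __post_init__(self) -> None:
        if self.slope_kev_per_channel <= 0:
            raise ValidationError("calibration slope must be > 0")

    def energy_kev(self, channel) -> np.ndarray:
        return self.slope_kev_per_channel * np.asarray(channel, float) + self.offset_kev


def calibrate_channels(
    peaks: list[tuple[float, float]], *, force_zero_offset: bool = False
) -> CalibrationModel:
    """Least-squares linear channel calibration.

    Parameters
    ----------
    peaks : list of (channel, energy_MeV)
        Located photopeak channels with their known emission energies, e.g.
        137Cs at 0.662 MeV and the two 60Co lines at 1.173 and 1.332 MeV.
    force_zero_offset : bool
        Fit slope only, pinning the offset at 0 keV.  Required when a single
        peak is supplied.
    """
    if not peaks:
        raise ValidationError("need at least one calibration peak")
    ch = np.array([p[0] for p in peaks], float)
    e_kev = np.array([p[1] for p in peaks], float) * 1000.0
    if len(np.unique(ch)) != len(ch):
        raise ValidationError("duplicate calibration channels")
    if len(peaks) == 1 and not force_zero_offset:
        raise ValidationError(
            "a single peak is underdetermined; pass force_zero_offset=True")
    if force_zero_offset:
        slope = float(np.dot(ch, e_kev) / np.dot(ch, ch))
        offset = 0.0
    else:
        slope, offset = np.polyfit(ch, e_kev, 1)
    if slope <= 0:
        raise ValidationError("calibration slope is non-positive")
    return CalibrationModel(float(slope), float(offset))


def rebin_channels(raw: PulseHeightSpectrum, factor: int = 25) -> BinnedSpectrum:
    """Sum consecutive groups of ``factor`` channels into coarse energy bins.

    With 8 keV channels and the default factor 25 the result has 0.2 MeV
    bins.  A trailing partial group is dropped with a warning.
    """
    if factor < 1:
        raise ValidationError("rebin factor must be >= 1")
    counts = raw.counts
    n_full = len(counts) // factor
    if n_full == 0:
        raise ValidationError("fewer channels than one rebin group")
    if len(counts) % factor:
        log.warning("dropping %d trailing channels not filling a %d-channel group",
                    len(counts) % factor, factor)
    summed = counts[: n_full * factor].reshape(n_full, factor).sum(axis=1)
    width_mev = factor * raw.channel_kev / 1000.0
    grid = EnergyGrid(lower=0.0, width=width_mev, n_bins=n_full)
    return BinnedSpectrum(grid=grid, values=summed.astype(float),
                          uncertainty=np.sqrt(summed), live_time=raw.live_time,
                          label=raw.label)


def subtract_background(
    c_a: BinnedSpectrum, c_b: BinnedSpectrum, *, live_time_rtol: float = 1e-3
) -> BinnedSpectrum:
    """Net spectrum c = c_a - c_b, clamped at zero.

    ``c_a`` is the open-beam measurement, ``c_b`` the shielded (leakage and
    room-scatter) background.  If both carry live times differing by more
    than ``live_time_rtol``, the background is scaled to the signal live time
    first.  Uncertainties combine in quadrature.
    """
    if c_a.grid != c_b.grid:
        raise ValidationError("background grid does not match signal grid")
    scale = 1.0
    if (c_a.live_time is not None and c_b.live_time is not None
            and abs(c_a.live_time - c_b.live_time) > live_time_rtol * c_a.live_time):
        scale = c_a.live_time / c_b.live_time
        log.info("scaling background by live-time ratio %.6g", scale)
    diff = c_a.values - scale * c_b.values
    if np.any(diff < 0):
        warnings.warn("negative net counts clamped to zero", stacklevel=2)
    ua = c_a.uncertainty if c_a.uncertainty is not None else np.sqrt(c_a.values)
    ub = c_b.uncertainty if c_b.uncertainty is not None else np.sqrt(c_b.values)
    unc = np.hypot(ua, scale * ub)
    return BinnedSpectrum(grid=c_a.grid, values=np.clip(diff, 0.0, None),
                          uncertainty=unc, live_time=c_a.live_time,
                          label=c_a.label or "net")


def mean_energy(s: BinnedSpectrum) -> float:
    """Value-weighted mean of bin-center energies (MeV)."""
    total = s.total
    if total <= 0:
        raise ValidationError("mean energy of an empty spectrum is undefined")
    return float(np.dot(s.values, s.grid.centers) / total)
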