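"""Uniform energy grids for binned spectra and response matrices."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = ["EnergyGrid", "DEFAULT_GRID"]


@dataclass(frozen=True)
class EnergyGrid:
    """Uniform deposited/incident energy binning.

    The default mirrors the spectrometry setup this package models: 40 bins of
    0.2 MeV spanning 0-8 MeV, so bin centers fall on 0.1, 0.3, ..., 7.9 MeV
    and the 0.1 MeV transport threshold sits in the middle of the first bin.

    Parameters
    ----------
    lower : float
        Lower edge of the first bin (MeV).
    width : float
        Bin width (MeV).
    n_bins : int
        Number of bins.
    """

    lower: float = 0.0
    width: float = 0.2
    n_bins: int = 40

    def __post_init__(self) -> None:
        if self.lower < 0:
            raise ValidationError("grid lower edge must be >= 0")
        if self.width <= 0:
            raise ValidationError("grid bin width must be > 0")
        if self.n_bins < 1:
            raise ValidationError("grid needs at least one bin")

    @property
    def edges(self) -> np.ndarray:
        return self.lower + self.width * np.arange(self.n_bins + 1)

    @property
    def centers(self) -> np.ndarray:
        return self.lower + self.width * (np.arange(self.n_bins) + 0.5)

    @property
    def upper(self) -> float:
        return self.lower + self.width * self.n_bins

    def index_of(self, energy: float) -> int:
        """Index of the bin containing ``energy`` (half-open bins)."""
        i = int(np.floor((energy - self.lower) / self.width))
        if not 0 <= i < self.n_bins:
            raise ValidationError(f"{energy} MeV outside grid [{self.lower}, {self.upper}]")
        return i

    @classmethod
    def from_edges(cls, edges: np.ndarray) -> "EnergyGrid":
        edges = np.asarray(edges, float)
        widths = np.diff(edges)
        if len(widths) < 1 or np.any(widths <= 0):
            raise ValidationError("grid edges must be strictly ascending")
        if not np.allclose(widths, widths[0], rtol=1e-6, atol=1e-12):
            raise ValidationError("grid must be uniform")
        return cls(lower=float(edges[0]), width=float(widths[0]), n_bins=len(widths))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EnergyGrid):
            return NotImplemented
        return (
            np.isclose(self.lower, other.lower, atol=1e-9)
            and np.isclose(self.width, other.width, rtol=1e-9)
            and self.n_bins == other.n_bins
        )

    def __hash__(self) -> int:  # frozen dataclass with custom __eq__
        return hash((round(self.lower, 9), round(self.width, 9), self.n_bins))


DEFAULT_GRID = EnergyGrid()
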