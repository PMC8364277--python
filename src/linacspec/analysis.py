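"""Validation and planning statistics.

Spectrum-comparison tests (Wilcoxon rank-sum, chi-square, two-sample
Kolmogorov-Smirnov), relative RMS deviation between depth-dose curves,
dose-rate budgeting for pile-up-free spectrometry, and the TPR20,10 beam
quality index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError
from .materials import load_material
from .spectra import BinnedSpectrum

__all__ = [
    "PDDCurve",
    "TPRMeasurement",
    "LinacPulseConfig",
    "ComparisonReport",
    "compare_spectra_tests",
    "rrmsd",
    "plan_dose_rate",
    "fluence_rate_for_dose_rate",
    "tpr_20_10",
    "tpr_consistent",
    "GRAY_PER_MEV_PER_GRAM",
]

#: MeV/g -> Gy (J/kg): 1 MeV = 1.602176634e-13 J, 1 g = 1e-3 kg.
GRAY_PER_MEV_PER_GRAM = 1.602176634e-10


@dataclass(frozen=True)
class PDDCurve:
    """Percent depth dose versus depth in water."""

    depths: np.ndarray  # cm, strictly ascending
    values: np.ndarray  # percent of maximum, > 0

    def __post_init__(self) -> None:
        d = np.asarray(self.depths, float)
        v = np.asarray(self.values, float)
        if d.shape != v.shape or d.ndim != 1 or len(d) < 2:
            raise ValidationError("PDD needs matching 1-D depth/value arrays")
        if np.any(np.diff(d) <= 0):
            raise ValidationError("PDD depths must be strictly ascending")
        if np.any(v <= 0):
            raise ValidationError("PDD values must be positive")
        object.__setattr__(self, "depths", d)
        object.__setattr__(self, "values", v)

    def interpolate_to(self, depths: np.ndarray) -> np.ndarray:
        depths = np.asarray(depths, float)
        if depths.min() < self.depths[0] or depths.max() > self.depths[-1]:
            raise ValidationError("requested depths outside curve range")
        return np.interp(depths, self.depths, self.values)


@dataclass(frozen=True)
class TPRMeasurement:
    """Electrometer readings at 20 and 10 g/cm^2 depth, same field size."""

    m20: float
    m10: float
    field_cm2: float = 100.0

    def __post_init__(self) -> None:
        if self.m20 <= 0 or self.m10 <= 0:
            raise ValidationError("electrometer readings must be positive")


@dataclass(frozen=True)
class LinacPulseConfig:
    """Pulsed-beam description for the dose-rate budget."""

    pulse_rate: float = 180.0  # pulses per second
    fluence_per_pulse: float = 1.0  # primary photons per cm^2 per pulse

    def __post_init__(self) -> None:
        if self.pulse_rate <= 0:
            raise ValidationError("pulse repetition frequency must be > 0")
        if self.fluence_per_pulse < 0:
            raise ValidationError("fluence per pulse must be >= 0")


@dataclass(frozen=True)
class ComparisonReport:
    """p-values of the three nonparametric spectrum comparisons."""

    p_ranksum: float
    p_chi2: float
    p_ks: float
    ks_statistic: float
    level: float = 0.05

    def __post_init__(self) -> None:
        for p in (self.p_ranksum, self.p_chi2, self.p_ks):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("p-values must lie in [0, 1]")

    @property
    def significant(self) -> dict[str, bool]:
        return {
            "ranksum": self.p_ranksum < self.level,
            "chi2": self.p_chi2 < self.level,
            "ks": self.p_ks < self.level,
        }

    @property
    def any_significant(self) -> bool:
        return any(self.significant.values())


def _weighted_ks(s1: np.ndarray, s2: np.ndarray, centers: np.ndarray,
                 n_eff: float) -> tuple[float, float]:
    """Two-sample KS on weighted empirical CDFs of bin centers.

    The statistic is the max CDF gap; the p-value uses the asymptotic
    two-sample Kolmogorov distribution with ``n_eff`` per sample, the
    resampling size standing in for the unavailable event lists.
    """
    c1 = np.cumsum(s1) / s1.sum()
    c2 = np.cumsum(s2) / s2.sum()
    d = float(np.max(np.abs(c1 - c2)))
    en = np.sqrt(n_eff / 2.0)
    p = float(stats.kstwobign.sf(max((en + 0.12 + 0.11 / en) * d, 0.0)))
    return d, min(max(p, 0.0), 1.0)


def compare_spectra_tests(
    s1: BinnedSpectrum, s2: BinnedSpectrum, level: float = 0.05,
    n_eff: int = 100,
) -> ComparisonReport:
    """Nonparametric comparison of two binned spectra.

    Both spectra are normalized to unit fluence first, so only their shapes
    are compared.  Wilcoxon rank-sum compares the per-bin normalized values;
    the two-sample chi-square and KS tests treat each distribution as
    ``n_eff`` weighted draws of the bin centers (binned spectra carry no
    event list, so an effective sample size stands in for one).  All three
    tests are symmetric in the two spectra.
    """
    if s1.grid != s2.grid:
        raise ValidationError("spectra must share a grid")
    if s1.total <= 0 or s2.total <= 0:
        raise ValidationError("cannot compare empty spectra")
    v1 = s1.values / s1.total
    v2 = s2.values / s2.total
    p_rs = float(stats.ranksums(v1, v2).pvalue)
    # two-sample chi-square on the n_eff-scaled distributions
    obs = np.vstack([v1, v2]) * n_eff
    keep = obs.sum(axis=0) > 0
    chi2 = ((obs[0, keep] - obs[1, keep]) ** 2 / (obs[0, keep] + obs[1, keep])).sum()
    dof = int(keep.sum()) - 1
    p_chi2 = float(stats.chi2.sf(chi2, dof)) if dof > 0 else 1.0
    d, p_ks = _weighted_ks(v1, v2, s1.grid.centers, n_eff)
    return ComparisonReport(p_ranksum=p_rs, p_chi2=p_chi2, p_ks=p_ks,
                            ks_statistic=d, level=level)


def rrmsd(calc: PDDCurve, meas: PDDCurve) -> float:
    """Relative root-mean-square deviation (percent) between two curves.

    The calculated curve is linearly interpolated onto the measured depths;
    rRMSD = 100 * sqrt(mean(((calc - meas)/meas)^2)).
    """
    calc_v = calc.interpolate_to(meas.depths)
    rel = (calc_v - meas.values) / meas.values
    return float(100.0 * np.sqrt(np.mean(rel**2)))


def plan_dose_rate(spectrum: BinnedSpectrum, config: LinacPulseConfig) -> float:
    """Absorbed dose rate in water (Gy/s) for a pile-up-free measurement.

    D = Phi_prim * f_p * sum_bins p(hv) * hv * mu_en/rho(hv), converted from
    MeV cm^2/g to Gy cm^2.  ``spectrum`` must be normalized fluence p(hv).
    """
    if not spectrum.normalized:
        raise ValidationError("dose-rate budget needs a normalized spectrum")
    water = load_material("water")
    support = spectrum.values > 0
    centers = spectrum.grid.centers[support]
    mu_en = water.mu_en_over_rho(centers)
    kerma_per_fluence = float(np.dot(spectrum.values[support], centers * mu_en))
    return (config.fluence_per_pulse * config.pulse_rate
            * kerma_per_fluence * GRAY_PER_MEV_PER_GRAM)


def fluence_rate_for_dose_rate(spectrum: BinnedSpectrum,
                               config: LinacPulseConfig,
                               target_dose_rate: float) -> float:
    """Primary fluence per pulse (photons/cm^2/pulse) giving a target dose
    rate (Gy/s): the inverse of `plan_dose_rate` at fixed pulse rate."""
    if target_dose_rate < 0:
        raise ValidationError("target dose rate must be >= 0")
    unit = plan_dose_rate(
        spectrum, LinacPulseConfig(config.pulse_rate, 1.0))
    return target_dose_rate / unit


def tpr_20_10(m: TPRMeasurement) -> float:
    """Tissue-phantom ratio TPR20,10 = M(20 g/cm^2) / M(10 g/cm^2)."""
    return m.m20 / m.m10


def tpr_consistent(a: float, b: float, tolerance: float = 0.004) -> bool:
    """Whether two TPR20,10 values agree within a stated tolerance."""
    if tolerance < 0:
        raise ValidationError("tolerance must be >= 0")
    return abs(a - b) <= tolerance
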