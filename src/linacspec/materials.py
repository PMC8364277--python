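"""Bundled photon-interaction and energy-absorption coefficient tables.

Coefficients are mass attenuation coefficients mu/rho in cm^2/g on a dense
energy grid (0.01-30 MeV), split by process: photoelectric absorption,
incoherent (Compton) scattering and pair production.  The ``total`` column is
the sum of the three and deliberately *excludes* coherent (Rayleigh)
scattering: a coherent event deposits no energy and never registers as a
count in a scintillation spectrum, so it plays no role in detection
efficiency.  Values between knots are interpolated log-log, the standard
choice for smooth photon cross sections.

The incoherent column is the integrated Klein-Nishina cross section per
electron scaled by the material's electron density, which keeps the sampled
transport kinematics exactly consistent with the attenuation data.
Photoelectric, pair and (for water) mass energy-absorption values derive from
NIST XCOM / Hubbell & Seltzer reference tabulations (see
``tools/make_material_tables.py``).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .errors import ValidationError

__all__ = [
    "MaterialTable",
    "load_material",
    "mu_over_rho",
    "mu_en_over_rho",
    "PAIR_THRESHOLD_MEV",
    "MATERIAL_ALIASES",
]

PAIR_THRESHOLD_MEV = 1.021998  # 2 * m_e c^2

PROCESSES = ("photoelectric", "incoherent", "pair", "total")

#: Accepted material names -> bundled table file stem.
MATERIAL_ALIASES = {
    "nai": "nai",
    "NaI": "nai",
    "water": "water",
    "Pb": "lead",
    "pb": "lead",
    "lead": "lead",
}


@dataclass(frozen=True)
class MaterialTable:
    """Per-process mass attenuation data for one material."""

    name: str
    density: float  # g/cm^3
    energies: np.ndarray  # MeV, strictly ascending
    photoelectric: np.ndarray
    incoherent: np.ndarray
    pair: np.ndarray
    total: np.ndarray
    mu_en: np.ndarray | None  # None where not tabulated

    def __post_init__(self) -> None:
        if np.any(np.diff(self.energies) <= 0):
            raise ValidationError(f"{self.name}: energies not strictly ascending")

    @property
    def energy_range(self) -> tuple[float, float]:
        return float(self.energies[0]), float(self.energies[-1])

    def _interp(self, column: np.ndarray, energy) -> np.ndarray:
        e = np.asarray(energy, float)
        lo, hi = self.energy_range
        if np.any(e < lo) or np.any(e > hi):
            raise ValidationError(
                f"energy outside {self.name} table range [{lo}, {hi}] MeV")
        with np.errstate(divide="ignore"):
            logv = np.log(column)
        out = np.exp(np.interp(np.log(e), np.log(self.energies), logv))
        return out

    def mu_over_rho(self, energy, process: str = "total") -> np.ndarray:
        """Interpolated mu/rho (cm^2/g) for one interaction process."""
        if process not in PROCESSES:
            raise ValidationError(f"unknown process {process!r}; one of {PROCESSES}")
        if process == "pair":
            e = np.asarray(energy, float)
            out = np.zeros_like(e, dtype=float)
            above = e > PAIR_THRESHOLD_MEV
            if np.any(above):
                # log-log interpolation only over the region where the
                # tabulated coefficient is non-zero
                nz = self.pair > 0
                sub = MaterialTable(self.name, self.density,
                                    self.energies[nz], self.photoelectric[nz],
                                    self.incoherent[nz], self.pair[nz],
                                    self.total[nz], None)
                lo, hi = self.energy_range
                if np.any(e < lo) or np.any(e > hi):
                    raise ValidationError(
                        f"energy outside {self.name} table range [{lo}, {hi}] MeV")
                first = sub.energies[0]
                ramp = above & (e < first)
                interp = above & ~ramp
                if np.any(interp):
                    out[interp] = sub._interp(sub.pair, e[interp])
                if np.any(ramp):
                    out[ramp] = sub.pair[0] * (e[ramp] - PAIR_THRESHOLD_MEV) / (
                        first - PAIR_THRESHOLD_MEV)
            else:
                # still validate range
                self._interp(self.total, e)
            return out if out.shape else float(out)
        col = getattr(self, process)
        out = self._interp(col, energy)
        return out if out.shape else float(out)

    def mu_en_over_rho(self, energy) -> np.ndarray:
        """Interpolated mass energy-absorption coefficient (cm^2/g)."""
        if self.mu_en is None:
            raise ValidationError(f"no mu_en/rho table bundled for {self.name}")
        out = self._interp(self.mu_en, energy)
        return out if out.shape else float(out)


def _read_table(stem: str) -> MaterialTable:
    text = (resources.files("linacspec") / "data" / f"{stem}.tsv").read_text()
    density = None
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "density_g_cm3:" in line:
                density = float(line.split(":")[1])
            continue
        rows.append(line.split("\t"))
    if density is None:
        raise ValidationError(f"{stem}.tsv: missing density metadata")
    arr = np.array([[np.nan if v == "-" else float(v) for v in r] for r in rows])
    mu_en = arr[:, 5]
    return MaterialTable(
        name=stem,
        density=density,
        energies=arr[:, 0],
        photoelectric=arr[:, 1],
        incoherent=arr[:, 2],
        pair=arr[:, 3],
        total=arr[:, 4],
        mu_en=None if np.all(np.isnan(mu_en)) else mu_en,
    )


@functools.lru_cache(maxsize=None)
def load_material(name: str) -> MaterialTable:
    """Load a bundled material table (``NaI``, ``water`` or ``Pb``)."""
    stem = MATERIAL_ALIASES.get(name) or MATERIAL_ALIASES.get(name.lower())
    if stem is None:
        raise ValidationError(
            f"unknown material {name!r}; bundled: {sorted(set(MATERIAL_ALIASES))}")
    return _read_table(stem)


def mu_over_rho(material: str, energy, process: str = "total"):
    """Mass attenuation coefficient (cm^2/g); ``total`` excludes coherent."""
    return load_material(material).mu_over_rho(energy, process)


def mu_en_over_rho(material: str, energy):
    """Mass energy-absorption coefficient (cm^2/g)."""
    return load_material(material).mu_en_over_rho(energy)
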