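"""Delimited-text readers and writers for spectra and depth-dose curves.

Two spectrum dialects are supported:

``channels``
    Raw MCA output: two columns (channel index, counts) with ``#``-prefixed
    metadata lines ``# live_time <s>`` and ``# channel_kev <keV>``.
``binned``
    Three columns (bin_low_MeV, bin_high_MeV, value) for spectra on a
    uniform energy grid.

PDD files are two columns (depth_cm, percent) with optional ``#`` metadata.
All writers round-trip losslessly through their readers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .analysis import PDDCurve
from .errors import ValidationError
from .grids import EnergyGrid
from .spectra import BinnedSpectrum, PulseHeightSpectrum

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_pdd",
    "write_pdd",
]


def _parse(path) -> tuple[dict[str, str], list[tuple[int, list[str]]]]:
    meta: dict[str, str] = {}
    rows: list[tuple[int, list[str]]] = []
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line.lstrip("# ").split(None, 1)
            if len(parts) == 2:
                meta[parts[0]] = parts[1]
            continue
        rows.append((lineno, line.replace(",", " ").split()))
    return meta, rows


def read_spectrum(path, dialect: str = "channels"):
    """Read a spectrum file.

    Returns a `PulseHeightSpectrum` for the ``channels`` dialect and a
    `BinnedSpectrum` for the ``binned`` dialect.  Malformed rows and
    negative counts raise `ValidationError` naming the offending line.
    """
    meta, rows = _parse(path)
    if not rows:
        raise ValidationError(f"{path}: no data rows")
    if dialect == "channels":
        counts = np.zeros(len(rows), dtype=np.int64)
        for i, (lineno, fields) in enumerate(rows):
            if len(fields) != 2:
                raise ValidationError(f"{path}:{lineno}: expected 2 columns")
            try:
                ch, ct = int(float(fields[0])), float(fields[1])
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            if ct < 0:
                raise ValidationError(f"{path}:{lineno}: negative count {ct}")
            if ch != i:
                raise ValidationError(f"{path}:{lineno}: non-contiguous channel {ch}")
            counts[i] = round(ct)
        return PulseHeightSpectrum(
            counts=counts,
            channel_kev=float(meta.get("channel_kev", 8.0)),
            live_time=float(meta["live_time"]) if "live_time" in meta else None,
            label=meta.get("label", Path(path).stem),
        )
    if dialect == "binned":
        lows, highs, vals = [], [], []
        for lineno, fields in rows:
            if len(fields) != 3:
                raise ValidationError(f"{path}:{lineno}: expected 3 columns")
            try:
                lo, hi, v = (float(f) for f in fields)
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            if v < 0:
                raise ValidationError(f"{path}:{lineno}: negative value {v}")
            lows.append(lo)
            highs.append(hi)
            vals.append(v)
        edges = np.array(lows + [highs[-1]])
        if not np.allclose(edges[1:-1], np.array(highs[:-1]), rtol=1e-9):
            raise ValidationError(f"{path}: bins are not contiguous")
        try:
            grid = EnergyGrid.from_edges(edges)
        except ValidationError as exc:
            raise ValidationError(f"{path}: {exc}") from exc
        values = np.array(vals)
        normalized = abs(values.sum() - 1.0) <= 1e-9
        return BinnedSpectrum(
            grid=grid, values=values, normalized=normalized,
            live_time=float(meta["live_time"]) if "live_time" in meta else None,
            label=meta.get("label", Path(path).stem),
        )
    raise ValidationError(f"unknown spectrum dialect {dialect!r}")


def write_spectrum(spectrum, path) -> None:
    """Write a spectrum in the dialect matching its type."""
    lines = []
    if spectrum.label:
        lines.append(f"# label {spectrum.label}")
    if spectrum.live_time is not None:
        lines.append(f"# live_time {spectrum.live_time:.10g}")
    if isinstance(spectrum, PulseHeightSpectrum):
        lines.append(f"# channel_kev {spectrum.channel_kev:.10g}")
        lines += [f"{i}\t{c}" for i, c in enumerate(spectrum.counts)]
    elif isinstance(spectrum, BinnedSpectrum):
        edges = spectrum.grid.edges
        lines += [
            f"{edges[i]:.9g}\t{edges[i + 1]:.9g}\t{v:.10e}"
            for i, v in enumerate(spectrum.values)
        ]
    else:
        raise ValidationError(f"cannot write {type(spectrum).__name__}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pdd(path) -> PDDCurve:
    """Read a two-column depth (cm) / PDD (percent) file."""
    _, rows = _parse(path)
    depths, values = [], []
    for lineno, fields in rows:
        if len(fields) != 2:
            raise ValidationError(f"{path}:{lineno}: expected 2 columns")
        try:
            d, v = float(fields[0]), float(fields[1])
        except ValueError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
        depths.append(d)
        values.append(v)
    return PDDCurve(depths=np.array(depths), values=np.array(values))


def write_pdd(curve: PDDCurve, path) -> None:
    lines = ["# depth_cm percent"]
    lines += [f"{d:.9g}\t{v:.9g}" for d, v in zip(curve.depths, curve.values)]
    Path(path).write_text("\n".join(lines) + "\n")
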