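"""Two-column delimited text format for (relative) reflectance spectra.

Header ``wavelength_nm,<value-name>``; one ``wavelength,value`` pair per
line; wavelengths strictly increasing.  Write/read round trips are lossless
to 1e-9.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .optics import RelativeSpectrum, Spectrum

__all__ = ["read_spectrum", "write_spectrum"]


def write_spectrum(spectrum: Spectrum, path: str | Path, value_name: str | None = None) -> None:
    if value_name is None:
        value_name = ("relative_reflectance" if isinstance(spectrum, RelativeSpectrum)
                      else "reflectance")
    lines = [f"wavelength_nm,{value_name}"]
    for wl, v in zip(spectrum.wavelengths, spectrum.values):
        lines.append(f"{wl:.10g},{v:.12g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_spectrum(path: str | Path, relative: bool = False) -> Spectrum:
    """Read a spectrum file, reporting the offending line on malformed input."""
    path = Path(path)
    raw = path.read_text().splitlines()
    if not raw:
        raise ValueError(f"{path}: empty file")
    header = raw[0].strip().split(",")
    if len(header) != 2 or header[0] != "wavelength_nm":
        raise ValueError(
            f"{path}:1: expected header 'wavelength_nm,<value-name>', got {raw[0]!r}"
        )
    wl, vals = [], []
    for lineno, line in enumerate(raw[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        try:
            if len(parts) != 2:
                raise ValueError
            w, v = float(parts[0]), float(parts[1])
        except ValueError:
            raise ValueError(f"{path}:{lineno}: malformed row {line!r}") from None
        if wl and w <= wl[-1]:
            raise ValueError(
                f"{path}:{lineno}: wavelengths must be strictly increasing "
                f"({w} after {wl[-1]})"
            )
        wl.append(w)
        vals.append(v)
    cls = RelativeSpectrum if relative else Spectrum
    return cls(np.asarray(wl), np.asarray(vals))
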