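"""Plain-text readers and writers for spectra, chromatograms and activities.

Spectra and chromatograms travel as two-column delimited text with a
``# key: value`` metadata header.  A minimal JCAMP-DX-style dialect
(``##TITLE=``, ``##XUNITS=PPM``, ``##XYPOINTS=(XY..XY)`` with one ``x, y``
pair per line) is supported read-only for spectra.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .ionex import Chromatogram
from .spectra import Spectrum

__all__ = [
    "write_spectrum",
    "read_spectrum",
    "write_chromatogram",
    "read_chromatogram",
    "write_activities",
    "read_activities",
]


def write_spectrum(s: Spectrum, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seq_id: {s.seq_id}\n")
        fh.write(f"# timepoint: {s.timepoint}\n")
        for key, val in s.meta.items():
            fh.write(f"# {key}: {val}\n")
        fh.write("# columns: ppm\tintensity\n")
        for x, y in zip(s.ppm, s.intensity):
            fh.write(f"{x:.6f}\t{y:.8g}\n")


def _read_jcamp(lines: list[str]) -> Spectrum:
    meta: dict[str, str] = {}
    xs: list[float] = []
    ys: list[float] = []
    in_data = False
    for line in lines:
        line = line.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, val = line[2:].partition("=")
            key = key.strip().upper()
            if key == "XYPOINTS":
                in_data = True
                continue
            if key == "END":
                break
            meta[key] = val.strip()
            if key == "XUNITS" and val.strip().upper() != "PPM":
                raise ValueError(f"unsupported XUNITS {val.strip()!r}; expected PPM")
            continue
        if in_data:
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise ValueError(f"malformed XY line: {line!r}")
            xs.append(float(parts[0]))
            ys.append(float(parts[1]))
    if not xs:
        raise ValueError("JCAMP file contains no XY data")
    return Spectrum(
        ppm=np.array(xs),
        intensity=np.array(ys),
        seq_id=meta.get("TITLE", ""),
        timepoint=meta.get("TIMEPOINT", "t0"),
        meta=meta,
    )


def read_spectrum(path) -> Spectrum:
    """Read either the native two-column dialect or JCAMP-DX-style text."""
    lines = Path(path).read_text().splitlines()
    if any(ln.lstrip().startswith("##TITLE") for ln in lines[:5]):
        return _read_jcamp(lines)
    meta: dict[str, str] = {}
    xs: list[float] = []
    ys: list[float] = []
    for line in lines:
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 2:
            raise ValueError(f"malformed data line: {line!r}")
        xs.append(float(parts[0]))
        ys.append(float(parts[1]))
    return Spectrum(
        ppm=np.array(xs),
        intensity=np.array(ys),
        seq_id=meta.get("seq_id", ""),
        timepoint=meta.get("timepoint", "t0"),
        meta={k: v for k, v in meta.items()
              if k not in {"seq_id", "timepoint", "columns"}},
    )


def write_chromatogram(c: Chromatogram, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seq_id: {c.seq_id}\n")
        fh.write("# columns: volume_ml\tabsorbance\n")
        for x, y in zip(c.volume_ml, c.absorbance):
            fh.write(f"{x:.5f}\t{y:.8g}\n")


def read_chromatogram(path) -> Chromatogram:
    meta: dict[str, str] = {}
    xs: list[float] = []
    ys: list[float] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 2:
            raise ValueError(f"malformed data line: {line!r}")
        xs.append(float(parts[0]))
        ys.append(float(parts[1]))
    return Chromatogram(
        volume_ml=np.array(xs), absorbance=np.array(ys),
        seq_id=meta.get("seq_id", ""),
    )


def write_activities(t: pd.DataFrame, path) -> None:
    t.to_csv(path, sep="\t", index=False)


def read_activities(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
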