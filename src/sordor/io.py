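"""Shape-file I/O: Bruker-dialect JCAMP-DX and CSV waveforms.

The JCAMP-DX dialect stores each slice as an (amplitude percent of maximum,
phase degrees) pair; absolute scaling therefore lives outside the file, and
reading one back into a :class:`~sordor.propagation.PulseShape` requires the
peak rf amplitude in Hz and the total pulse duration.  Round trips are
lossless to the six decimal digits written.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np
import pandas as pd

from .propagation import PulseShape

__all__ = ["read_shape", "write_shape", "read_shape_csv", "write_shape_csv"]


class ShapeParseError(ValueError):
    """Malformed shape file; the message names the offending line."""


def write_shape(path, pulse: PulseShape, title: str | None = None) -> None:
    """Write a pulse as a Bruker-style JCAMP-DX shape file.

    Amplitudes are stored as percent of the pulse maximum, phases as degrees
    in [0, 360).
    """
    path = Path(path)
    peak = float(pulse.amplitudes.max())
    percent = 100.0 * pulse.amplitudes / peak if peak > 0 else \
        np.zeros_like(pulse.amplitudes)
    degrees = np.degrees(pulse.phases) % 360.0
    integfac = float(np.mean((percent / 100.0) * np.exp(1j * pulse.phases)).real)
    lines = [
        f"##TITLE= {title or pulse.label or 'sordor shape'}",
        "##JCAMP-DX= 5.00 Bruker JCAMP library",
        "##DATA TYPE= Shape Data",
        "##ORIGIN= sordor",
        f"##DATE= {_dt.date.today().isoformat()}",
        f"##MINX= {percent.min():.6e}",
        f"##MAXX= {percent.max():.6e}",
        f"##MINY= {degrees.min():.6e}",
        f"##MAXY= {degrees.max():.6e}",
        "##$SHAPE_EXMODE= Universal",
        "##$SHAPE_TOTROT= 9.000000e+01",
        "##$SHAPE_BWFAC= 0.000000e+00",
        f"##$SHAPE_INTEGFAC= {integfac:.6e}",
        "##$SHAPE_MODE= 1",
        f"##NPOINTS= {pulse.n_slices}",
        "##XYPOINTS= (XY..XY)",
    ]
    lines += [f"{p:.6e}, {d:.6e}" for p, d in zip(percent, degrees)]
    lines.append("##END=")
    path.write_text("\n".join(lines) + "\n")


def read_shape(path, peak_amplitude_hz: float, duration: float) -> PulseShape:
    """Read a Bruker-style JCAMP-DX shape file.

    ``peak_amplitude_hz`` maps the stored percent amplitudes to Hz;
    ``duration`` is the total pulse length in seconds (the dialect does not
    store time).
    """
    path = Path(path)
    text = path.read_text().splitlines()
    if not text:
        raise ShapeParseError(f"{path}: empty file")
    npoints = None
    title = ""
    points: list[tuple[float, float]] = []
    in_points = False
    for lineno, raw in enumerate(text, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            if line.startswith("##TITLE="):
                title = line.split("=", 1)[1].strip()
            elif line.startswith("##NPOINTS="):
                try:
                    npoints = int(line.split("=", 1)[1])
                except ValueError as exc:
                    raise ShapeParseError(
                        f"{path}:{lineno}: bad NPOINTS value") from exc
            elif line.startswith("##XYPOINTS="):
                in_points = True
            elif line.startswith("##END"):
                in_points = False
            continue
        if not in_points:
            raise ShapeParseError(f"{path}:{lineno}: data outside XYPOINTS block")
        parts = line.split(",")
        if len(parts) != 2:
            raise ShapeParseError(f"{path}:{lineno}: expected 'amp, phase'")
        try:
            amp, ph = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise ShapeParseError(f"{path}:{lineno}: non-numeric point") from exc
        if not (0.0 <= amp <= 100.0 + 1e-9):
            raise ShapeParseError(
                f"{path}:{lineno}: amplitude {amp} outside [0, 100] percent")
        points.append((amp, ph))
    if npoints is None:
        raise ShapeParseError(f"{path}: missing ##NPOINTS=")
    if len(points) != npoints:
        raise ShapeParseError(
            f"{path}: NPOINTS={npoints} but {len(points)} points present")
    if npoints == 0:
        raise ShapeParseError(f"{path}: shape has no points")
    arr = np.asarray(points)
    amplitudes = peak_amplitude_hz * arr[:, 0] / 100.0
    phases = np.radians(arr[:, 1])
    return PulseShape(duration / npoints, amplitudes, phases, label=title)


def write_shape_csv(path, pulse: PulseShape) -> None:
    """CSV waveform: absolute amplitudes (Hz) and phases (degrees).

    The slice duration travels in a comment header line so the CSV is
    self-contained, unlike the JCAMP percent dialect.
    """
    path = Path(path)
    df = pd.DataFrame(dict(amplitude_hz=pulse.amplitudes,
                           phase_deg=np.degrees(pulse.phases) % 360.0))
    with open(path, "w") as fh:
        fh.write(f"# slice_duration_s= {pulse.slice_duration:.9e}\n")
        fh.write(f"# label= {pulse.label}\n")
        df.to_csv(fh, index=False, float_format="%.6e")


def read_shape_csv(path) -> PulseShape:
    path = Path(path)
    dt = None
    label = ""
    with open(path) as fh:
        lines = fh.readlines()
    if not lines:
        raise ShapeParseError(f"{path}: empty file")
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line.lstrip("#").partition("=")
            if key.strip() == "slice_duration_s":
                dt = float(val)
            elif key.strip() == "label":
                label = val.strip()
            body_start = i + 1
        else:
            break
    if dt is None:
        raise ShapeParseError(f"{path}: missing '# slice_duration_s=' header")
    try:
        df = pd.read_csv(path, skiprows=body_start)
    except Exception as exc:
        raise ShapeParseError(f"{path}: unreadable CSV body") from exc
    for col in ("amplitude_hz", "phase_deg"):
        if col not in df.columns:
            raise ShapeParseError(f"{path}: missing column {col!r}")
    return PulseShape(dt, df["amplitude_hz"].to_numpy(),
                      np.radians(df["phase_deg"].to_numpy()), label=label)
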