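"""Contour file I/O.

The contour dialect is two-column delimited text (comma or tab,
auto-detected) with one ``x,y`` header row, preceded by ``# key=value``
comment lines declaring metadata:

    # smartegg contour v1
    # units=px
    # orientation=pointed_negative_x
    # scale=0.265116
    # closed=false
    x,y
    -199.0,0
    ...

``closed=true`` marks a full outline (both branches, signed y), which is
folded to a half-profile on read.  Numbers are written with 17 significant
digits so write/read round trips are lossless.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .geometry import Orientation
from .measure import DigitizedProfile, fold_closed_outline

__all__ = ["FormatError", "read_contour", "write_contour"]

MAGIC = "# smartegg contour v1"


class FormatError(ValueError):
    """Malformed contour file; the message carries the offending line number."""


def _parse_meta(lines: list[str]) -> tuple[dict[str, str], int]:
    meta: dict[str, str] = {}
    i = 0
    for i, line in enumerate(lines):
        s = line.strip()
        if not s.startswith("#"):
            break
        body = s.lstrip("#").strip()
        if "=" in body:
            k, _, v = body.partition("=")
            meta[k.strip()] = v.strip()
    else:
        i = len(lines)
    return meta, i


def read_contour(path: str | Path) -> DigitizedProfile:
    """Parse a contour file into a :class:`DigitizedProfile`.

    Raises :class:`FormatError` with a 1-based line number on missing
    columns, non-numeric cells, or duplicate x values (beyond 1e-9 of the
    x span).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    meta, start = _parse_meta(lines)

    if start >= len(lines):
        raise FormatError(f"{path}: no data rows")
    header = lines[start]
    delim = "\t" if "\t" in header else ","
    cols = [c.strip().lower() for c in header.split(delim)]
    if len(cols) < 2 or cols[0] != "x" or cols[1] != "y":
        raise FormatError(
            f"{path}:{start + 1}: expected header 'x{delim}y', got {header!r}"
        )

    xs: list[float] = []
    ys: list[float] = []
    for lineno, line in enumerate(lines[start + 1 :], start=start + 2):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        parts = s.split(delim)
        if len(parts) < 2:
            raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        try:
            xs.append(float(parts[0]))
            ys.append(float(parts[1]))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric cell ({exc})") from None

    x = np.asarray(xs)
    y = np.asarray(ys)
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]

    closed = meta.get("closed", "false").lower() in ("true", "1", "yes")
    span = float(x.max() - x.min()) if len(x) else 0.0
    if not closed and np.any(np.diff(x) <= 1e-9 * max(span, 1.0)):
        i = int(np.argmin(np.diff(x)))
        raise FormatError(
            f"{path}: duplicate x value near x = {x[i]!r} (data row {i + 1})"
        )

    kwargs = dict(
        units=meta.get("units", "px"),
        scale=float(meta["scale"]) if "scale" in meta else None,
        orientation=Orientation(meta.get("orientation", "pointed_negative_x")),
    )
    if closed:
        return fold_closed_outline(x, y, **kwargs)
    return DigitizedProfile(x=x, y=y, **kwargs)


def write_contour(profile: DigitizedProfile, path: str | Path, delim: str = ",") -> Path:
    """Write a profile in the contour dialect (lossless round trip)."""
    path = Path(path)
    lines = [
        MAGIC,
        f"# units={profile.units}",
        f"# orientation={profile.orientation.value}",
    ]
    if profile.scale is not None:
        lines.append(f"# scale={profile.scale:.17g}")
    lines.append("# closed=false")
    lines.append(f"x{delim}y")
    lines += [
        f"{x:.17g}{delim}{y:.17g}" for x, y in zip(profile.x, profile.y)
    ]
    path.write_text("\n".join(lines) + "\n")
    return path
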