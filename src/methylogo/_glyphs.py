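"""Unit-box letter outlines for logo glyphs.

Letter outlines are taken once from the bundled DejaVu Sans Bold font via
matplotlib's TextPath, normalised so each letter exactly fills the box
[0,1] x [0,1] with y pointing *down* (SVG convention).  A glyph drawn with
``translate(x y) scale(w h)`` then occupies exactly the rectangle
(x, y, w, h), which is what makes rendered letter heights machine-checkable.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from matplotlib.font_manager import FontProperties
from matplotlib.path import Path
from matplotlib.textpath import TextPath

__all__ = ["glyph_svg_path", "glyph_mpl_path"]

_FONT = FontProperties(family="DejaVu Sans", weight="bold")


@lru_cache(maxsize=None)
def _unit_path(letter: str) -> Path:
    tp = TextPath((0, 0), letter, size=100, prop=_FONT)
    verts = tp.vertices.copy()
    lo = verts.min(axis=0)
    hi = verts.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    verts = (verts - lo) / span
    verts[:, 1] = 1.0 - verts[:, 1]  # flip to y-down
    return Path(verts, tp.codes.copy())


@lru_cache(maxsize=None)
def glyph_svg_path(letter: str, decimals: int = 4) -> str:
    """SVG path data ('d' attribute) of the unit-box letter."""
    path = _unit_path(letter)
    fmt = f"%.{decimals}f"
    out: list[str] = []
    i = 0
    verts, codes = path.vertices, path.codes
    while i < len(codes):
        code = codes[i]
        if code == Path.MOVETO:
            x, y = verts[i]
            out.append(f"M {fmt % x} {fmt % y}")
            i += 1
        elif code == Path.LINETO:
            x, y = verts[i]
            out.append(f"L {fmt % x} {fmt % y}")
            i += 1
        elif code == Path.CURVE3:
            (cx, cy), (x, y) = verts[i], verts[i + 1]
            out.append(f"Q {fmt % cx} {fmt % cy} {fmt % x} {fmt % y}")
            i += 2
        elif code == Path.CURVE4:
            (c1x, c1y), (c2x, c2y), (x, y) = verts[i], verts[i + 1], verts[i + 2]
            out.append(
                f"C {fmt % c1x} {fmt % c1y} {fmt % c2x} {fmt % c2y} "
                f"{fmt % x} {fmt % y}"
            )
            i += 3
        elif code == Path.CLOSEPOLY:
            out.append("Z")
            i += 1
        else:  # pragma: no cover - STOP
            i += 1
    return " ".join(out)


def glyph_mpl_path(letter: str) -> Path:
    """The unit-box letter as a matplotlib Path (y-down coordinates)."""
    return _unit_path(letter)
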