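"""Vector rendering of methylation logos and the flanking scape panel.

The renderer builds a backend-independent list of primitives (rectangles,
letter glyphs, lines, text) in figure points with y pointing down, then
writes them either as hand-assembled SVG 1.1 (the primary, byte-
deterministic output whose geometry tests can read back) or through
matplotlib for PDF/PNG.

Geometry conventions that make figures machine-checkable:

* a letter glyph is emitted as a unit-box path under
  ``translate(x y) scale(w h)``, so its rendered height in points is the
  ``scale`` y-factor, and heights in bits are points / points_per_bit;
* methylation shading of C and G glyphs is a clipped overlay rectangle in
  glyph-local units whose height *is* the methylation fraction;
* every data-bearing element carries a ``class`` attribute
  (seq-letter, meth-comp, dimer-bar, ...) plus ``data-*`` indices.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path as _P

import numpy as np

from ._glyphs import glyph_mpl_path, glyph_svg_path
from .genome import CONTEXTS
from .models import BASES, MethylationBackground, MotifModel, ZeroOrderBackground
from .sites import CONTEXT_CODE
from .tracks import ScapeProfile, TrackSet

__all__ = ["RenderConfig", "render_logo", "render_methylscape"]


# ----------------------------------------------------------------- scene

def _f(x: float) -> str:
    return f"{x:.6f}"


@dataclass(frozen=True)
class Rect:
    x: float
    y: float
    w: float
    h: float
    fill: str
    opacity: float = 1.0
    stroke: str | None = None
    stroke_width: float = 0.75
    class_: str = ""
    data: tuple = ()


@dataclass(frozen=True)
class Glyph:
    letter: str
    x: float
    y: float  # top of the glyph box
    w: float
    h: float
    fill: str
    shade_fraction: float | None = None  # methylation fill from baseline up
    shade_color: str = "#00000080"
    class_: str = ""
    data: tuple = ()


@dataclass(frozen=True)
class Line:
    x1: float
    y1: float
    x2: float
    y2: float
    stroke: str = "#000000"
    width: float = 1.0
    dash: str | None = None
    class_: str = ""
    data: tuple = ()


@dataclass(frozen=True)
class Polyline:
    points: tuple
    stroke: str
    width: float = 1.25
    class_: str = ""


@dataclass(frozen=True)
class Text:
    x: float
    y: float
    s: str
    size: float = 9.0
    anchor: str = "start"
    fill: str = "#000000"
    rotate: float | None = None
    class_: str = ""


@dataclass
class Scene:
    width: float
    height: float
    items: list = field(default_factory=list)

    def add(self, *prims) -> None:
        self.items.extend(prims)


# ------------------------------------------------------------ config

DEFAULT_BASE_COLORS = {"A": "#109648", "C": "#255C99", "G": "#F7B32B", "T": "#D62839"}
# one hue per context; lighter tint for the reverse strand so the six
# (context, strand) classes stay visually distinct
DEFAULT_METH_COLORS = {
    ("CG", "+"): "#7B3294", ("CG", "-"): "#C2A5CF",
    ("CHG", "+"): "#008837", ("CHG", "-"): "#A6DBA0",
    ("CHH", "+"): "#E66101", ("CHH", "-"): "#FDB863",
}


@dataclass
class RenderConfig:
    """Figure geometry, palette and labelling knobs."""

    fmt: str = "svg"  # svg | pdf | png
    col_width: float = 42.0
    points_per_bit: float = 55.0  # sequence + dimer tracks
    points_per_bit_meth: float = 110.0  # methylation components are small
    margin: float = 46.0
    key_width: float = 120.0
    track_gap: float = 26.0
    base_colors: dict = field(default_factory=lambda: dict(DEFAULT_BASE_COLORS))
    meth_colors: dict = field(default_factory=lambda: dict(DEFAULT_METH_COLORS))
    shade_opacity: float = 0.45
    dash: str = "4,3"
    font_size: float = 9.0
    title: str = ""
    background_label: str = "WG"  # figure annotation: whole-genome / promoter
    show_axis_labels: bool = True
    min_letter_bits: float = 1e-9

    # methylscape panel geometry
    panel_w: float = 190.0
    panel_h: float = 92.0
    panel_gap: float = 26.0


# ------------------------------------------------------------ logo layout

def _stack_letters(scene, cfg, tracks, x0, baseline, col):
    """One sequence-logo column: letters stacked, most probable on top."""
    heights = tracks.letter_heights[col]
    order = np.argsort(heights, kind="stable")  # ascending: smallest at bottom
    y = baseline
    for k in order:
        h_bits = float(heights[k])
        if h_bits < cfg.min_letter_bits:
            continue
        base = BASES[k]
        h_pts = h_bits * cfg.points_per_bit
        y -= h_pts
        shade = None
        strand = None
        if base == "C":
            strand = 0
        elif base == "G":
            strand = 1
        if strand is not None:
            frac = tracks.observed_meth[col, strand]
            if not np.isnan(frac):
                shade = float(frac)
        scene.add(
            Glyph(
                base, x0 + 2.0, y, cfg.col_width - 4.0, h_pts,
                cfg.base_colors[base],
                shade_fraction=shade,
                shade_color="#333333",
                class_="seq-letter",
                data=(("col", col), ("base", base), ("bits", _f(h_bits))),
            )
        )
        if strand is not None:
            exp = tracks.expected_meth[col, strand]
            if not np.isnan(exp):
                ye = y + h_pts - float(exp) * h_pts
                scene.add(
                    Line(
                        x0 + 2.0, ye, x0 + cfg.col_width - 2.0, ye,
                        stroke="#000000", width=0.9, dash="3,2",
                        class_="expected-meth",
                        data=(("col", col), ("strand", "+-"[strand]),
                              ("level", _f(float(exp)))),
                    )
                )


def _axis(scene, cfg, x0, x1, y, label=""):
    scene.add(Line(x0, y, x1, y, stroke="#000000", width=1.0, class_="axis"))
    if label and cfg.show_axis_labels:
        scene.add(Text(x0 - 6.0, y - 2.0, label, size=cfg.font_size,
                       anchor="end", class_="axis-label"))


def render_logo(
    tracks: TrackSet,
    motif: MotifModel,
    mbg: MethylationBackground,
    bg0: ZeroOrderBackground,
    cfg: RenderConfig | None = None,
    out=None,
):
    """Draw the three-track methylation logo; returns the Scene.

    Top: stacked methylation components per (context, strand), reverse
    strand downward.  Middle: the sequence logo with shaded C/G glyphs
    and dashed expected-methylation segments.  Bottom: signed dimer bars
    between columns with the theoretical max/min reference lines.  A key
    box at lower right lists the background methylation probabilities and
    base frequencies.
    """
    cfg = cfg or RenderConfig()
    L = tracks.length
    if L == 0:
        raise ValueError("zero-length motif")
    x_left = cfg.margin
    x_right = x_left + L * cfg.col_width
    width = x_right + cfg.key_width + cfg.margin

    meth_up = float(tracks.meth_components[:, :, 0].sum(axis=1).max(initial=0.0))
    meth_dn = float(tracks.meth_components[:, :, 1].sum(axis=1).max(initial=0.0))
    meth_up_pts = max(meth_up * cfg.points_per_bit_meth, 8.0)
    meth_dn_pts = max(meth_dn * cfg.points_per_bit_meth, 8.0)
    seq_pts = max(float(tracks.seq_heights.max(initial=0.0)) * cfg.points_per_bit, 10.0)
    dim_up = max(tracks.dimer_bound_max, 0.0) * cfg.points_per_bit
    dim_dn = max(-min(tracks.dimer_bound_min, 0.0) * cfg.points_per_bit, 8.0)

    y = cfg.margin
    meth_axis = y + meth_up_pts
    y = meth_axis + meth_dn_pts + cfg.track_gap
    seq_base = y + seq_pts
    y = seq_base + cfg.track_gap
    dim_axis = y + dim_up
    height = dim_axis + dim_dn + cfg.margin

    scene = Scene(width, height)
    if cfg.title:
        scene.add(Text(x_left, cfg.margin - 14.0,
                       f"{cfg.title}  [{cfg.background_label}]",
                       size=cfg.font_size + 2, class_="title"))

    # --- methylation track (top) ---
    _axis(scene, cfg, x_left, x_right, meth_axis, "meth (bits)")
    for i in range(L):
        x0 = x_left + i * cfg.col_width
        yp = meth_axis
        yn = meth_axis
        for ctx in CONTEXTS:
            c = CONTEXT_CODE[ctx]
            up = float(tracks.meth_components[i, c, 0])
            dn = float(tracks.meth_components[i, c, 1])
            if up > 0:
                h = up * cfg.points_per_bit_meth
                yp -= h
                scene.add(Rect(x0 + 6.0, yp, cfg.col_width - 12.0, h,
                               cfg.meth_colors[(str(ctx), "+")],
                               class_="meth-comp",
                               data=(("col", i), ("ctx", str(ctx)),
                                     ("strand", "+"), ("bits", _f(up)))))
            if dn > 0:
                h = dn * cfg.points_per_bit_meth
                scene.add(Rect(x0 + 6.0, yn, cfg.col_width - 12.0, h,
                               cfg.meth_colors[(str(ctx), "-")],
                               class_="meth-comp",
                               data=(("col", i), ("ctx", str(ctx)),
                                     ("strand", "-"), ("bits", _f(dn)))))
                yn += h

    # --- sequence track (middle) ---
    _axis(scene, cfg, x_left, x_right, seq_base, "bits")
    for i in range(L):
        _stack_letters(scene, cfg, tracks, x_left + i * cfg.col_width, seq_base, i)
        scene.add(Text(x_left + (i + 0.5) * cfg.col_width, seq_base + 11.0,
                       str(i + 1), size=cfg.font_size, anchor="middle",
                       class_="col-label"))

    # --- dimer track (bottom) ---
    _axis(scene, cfg, x_left, x_right, dim_axis, "dimer (bits)")
    for ref, name in ((tracks.dimer_bound_max, "max"),
                      (tracks.dimer_bound_min, "min")):
        yy = dim_axis - ref * cfg.points_per_bit
        scene.add(Line(x_left, yy, x_right, yy, stroke="#888888",
                       width=0.8, dash=cfg.dash, class_="dimer-bound",
                       data=(("which", name), ("bits", _f(float(ref))))))
    bar_w = cfg.col_width * 0.45
    for j in range(L - 1):
        v = float(tracks.dimer_heights[j])
        xc = x_left + (j + 1) * cfg.col_width
        h = abs(v) * cfg.points_per_bit
        ytop = dim_axis - h if v >= 0 else dim_axis
        scene.add(Rect(xc - bar_w / 2, ytop, bar_w, h, "#666666",
                       class_="dimer-bar",
                       data=(("pair", j), ("bits", _f(v)))))

    # --- key box (lower right) ---
    kx = x_right + 14.0
    ky = seq_base - 86.0
    scene.add(Rect(kx, ky, cfg.key_width - 8.0, 92.0, "#FFFFFF",
                   stroke="#000000", class_="key-box"))
    lines = [f"m({ctx}) = {mbg.prob(ctx):.3f}" for ctx in CONTEXTS]
    lines += [f"q({b}) = {bg0.prob(b):.3f}" for b in BASES]
    for k, s in enumerate(lines):
        scene.add(Text(kx + 7.0, ky + 14.0 + 12.0 * k, s,
                       size=cfg.font_size, class_="key-entry"))

    if out is not None:
        _write(scene, out, cfg)
    return scene


# ------------------------------------------------------------ methylscape

def render_methylscape(profile: ScapeProfile, cfg: RenderConfig | None = None, out=None):
    """Draw the 3x3 flanking-profile panel; returns the Scene.

    Columns are the contexts CG / CHG / CHH; rows are methylation relative
    entropy, methylation probability (with a translucent band at the
    background level), and context probability.  All panels share the
    offset axis, with the motif span marked by vertical dashed lines.
    """
    cfg = cfg or RenderConfig()
    offs = profile.offsets
    n = len(offs)
    rows = ("entropy", "methylation", "context probability")
    e_max = max(float(np.nanmax(profile.entropy, initial=0.0)), 1e-6)
    p_max = max(float(profile.ctx_prob.max(initial=0.0)), 1e-6)

    width = cfg.margin * 2 + 3 * cfg.panel_w + 2 * cfg.panel_gap
    height = cfg.margin * 2 + 3 * cfg.panel_h + 2 * cfg.panel_gap + 16.0
    scene = Scene(width, height)
    if cfg.title:
        scene.add(Text(cfg.margin, cfg.margin - 14.0,
                       f"{cfg.title}  [{cfg.background_label}]",
                       size=cfg.font_size + 2, class_="title"))

    def xmap(px, off_idx):
        return px + (off_idx / max(n - 1, 1)) * cfg.panel_w

    for ci, ctx in enumerate(CONTEXTS):
        c = CONTEXT_CODE[ctx]
        has_content = float(profile.ctx_prob[c].max(initial=0.0)) > 0.0
        px = cfg.margin + ci * (cfg.panel_w + cfg.panel_gap)
        scene.add(Text(px + cfg.panel_w / 2, cfg.margin - 2.0, str(ctx),
                       size=cfg.font_size + 1, anchor="middle",
                       class_="panel-title"))
        for ri, row in enumerate(rows):
            py = cfg.margin + ri * (cfg.panel_h + cfg.panel_gap) + 8.0
            scene.add(Rect(px, py, cfg.panel_w, cfg.panel_h, "#FFFFFF",
                           stroke="#000000", stroke_width=0.8,
                           class_="panel",
                           data=(("ctx", str(ctx)), ("row", row))))
            if row == "entropy":
                vals, vmax = profile.entropy[c], e_max
            elif row == "methylation":
                vals, vmax = profile.meth[c], 1.0
                mb = profile.m_bg.get(str(ctx))
                if mb is not None:
                    band_h = 0.04 * cfg.panel_h
                    yb = py + cfg.panel_h * (1.0 - float(mb)) - band_h / 2
                    scene.add(Rect(px, yb, cfg.panel_w, band_h,
                                   cfg.meth_colors[(str(ctx), "+")],
                                   opacity=0.25, class_="bg-band",
                                   data=(("ctx", str(ctx)),
                                         ("level", _f(float(mb))))))
            else:
                vals, vmax = profile.ctx_prob[c], p_max
            # motif span demarcation
            core0 = int(np.searchsorted(offs, 0))
            core1 = int(np.searchsorted(offs, profile.motif_length - 1))
            for idx in (core0, core1):
                xx = xmap(px, idx)
                scene.add(Line(xx, py, xx, py + cfg.panel_h, stroke="#999999",
                               width=0.7, dash=cfg.dash, class_="motif-span"))
            # the curve, broken at NaNs; a context absent everywhere gets
            # an empty-but-labeled panel
            seg: list[tuple[float, float]] = []
            for k in range(n if has_content else 0):
                v = vals[k]
                if np.isnan(v):
                    if len(seg) > 1:
                        scene.add(Polyline(tuple(seg), "#333333",
                                           class_=f"curve-{row.split()[0]}"))
                    seg = []
                    continue
                yy = py + cfg.panel_h * (1.0 - float(v) / vmax)
                seg.append((xmap(px, k), yy))
            if len(seg) > 1:
                scene.add(Polyline(tuple(seg), "#333333",
                                   class_=f"curve-{row.split()[0]}"))
            if ci == 0 and cfg.show_axis_labels:
                scene.add(Text(px - 6.0, py + cfg.panel_h / 2, row,
                               size=cfg.font_size - 1, anchor="end",
                               rotate=-90.0, class_="row-label"))
    if out is not None:
        _write(scene, out, cfg)
    return scene


# ------------------------------------------------------------ backends

def _write(scene: Scene, out, cfg: RenderConfig) -> None:
    out = _P(out)
    fmt = out.suffix.lstrip(".").lower() or cfg.fmt
    if fmt == "svg":
        write_svg(scene, out)
    elif fmt in ("pdf", "png"):
        write_mpl(scene, out)
    else:
        raise ValueError(f"unsupported output format {fmt!r}")


def write_svg(scene: Scene, path) -> None:
    """Serialize the scene as standalone SVG 1.1 (byte-deterministic)."""
    root = ET.Element("svg", {
        "xmlns": "http://www.w3.org/2000/svg",
        "version": "1.1",
        "width": _f(scene.width),
        "height": _f(scene.height),
        "viewBox": f"0 0 {_f(scene.width)} {_f(scene.height)}",
    })
    defs = ET.SubElement(root, "defs")
    clip_n = 0
    for item in scene.items:
        if isinstance(item, Rect):
            attrs = {
                "x": _f(item.x), "y": _f(item.y),
                "width": _f(item.w), "height": _f(item.h),
                "fill": item.fill,
            }
            if item.opacity != 1.0:
                attrs["fill-opacity"] = _f(item.opacity)
            if item.stroke:
                attrs["stroke"] = item.stroke
                attrs["stroke-width"] = _f(item.stroke_width)
            _decorate(attrs, item)
            ET.SubElement(root, "rect", attrs)
        elif isinstance(item, Glyph):
            g_attrs = {
                "transform": (
                    f"translate({_f(item.x)} {_f(item.y)}) "
                    f"scale({_f(item.w)} {_f(item.h)})"
                ),
            }
            _decorate(g_attrs, item)
            g = ET.SubElement(root, "g", g_attrs)
            d = glyph_svg_path(item.letter)
            ET.SubElement(g, "path", {"d": d, "fill": item.fill})
            if item.shade_fraction is not None:
                cid = f"clip{clip_n}"
                clip_n += 1
                cp = ET.SubElement(defs, "clipPath", {"id": cid,
                                                      "clipPathUnits": "userSpaceOnUse"})
                ET.SubElement(cp, "path", {"d": d})
                frac = min(max(item.shade_fraction, 0.0), 1.0)
                ET.SubElement(g, "rect", {
                    "x": "0", "y": _f(1.0 - frac), "width": "1",
                    "height": _f(frac),
                    "fill": item.shade_color,
                    "fill-opacity": _f(0.45),
                    "clip-path": f"url(#{cid})",
                    "class": "meth-shade",
                    "data-fraction": _f(frac),
                })
        elif isinstance(item, Line):
            attrs = {
                "x1": _f(item.x1), "y1": _f(item.y1),
                "x2": _f(item.x2), "y2": _f(item.y2),
                "stroke": item.stroke, "stroke-width": _f(item.width),
            }
            if item.dash:
                attrs["stroke-dasharray"] = item.dash
            _decorate(attrs, item)
            ET.SubElement(root, "line", attrs)
        elif isinstance(item, Polyline):
            pts = " ".join(f"{_f(x)},{_f(y)}" for x, y in item.points)
            attrs = {"points": pts, "fill": "none", "stroke": item.stroke,
                     "stroke-width": _f(item.width)}
            if item.class_:
                attrs["class"] = item.class_
            ET.SubElement(root, "polyline", attrs)
        elif isinstance(item, Text):
            attrs = {
                "x": _f(item.x), "y": _f(item.y),
                "font-size": _f(item.size),
                "font-family": "DejaVu Sans, sans-serif",
                "text-anchor": {"start": "start", "middle": "middle",
                                "end": "end"}[item.anchor],
                "fill": item.fill,
            }
            if item.rotate is not None:
                attrs["transform"] = (
                    f"rotate({_f(item.rotate)} {_f(item.x)} {_f(item.y)})"
                )
            if item.class_:
                attrs["class"] = item.class_
            el = ET.SubElement(root, "text", attrs)
            el.text = item.s
    data = ET.tostring(root, encoding="unicode")
    with open(path, "w", newline="\n") as fh:
        fh.write('<?xml version="1.0" encoding="UTF-8"?>\n')
        fh.write(data)
        fh.write("\n")


def _decorate(attrs: dict, item) -> None:
    if item.class_:
        attrs["class"] = item.class_
    for k, v in item.data:
        attrs[f"data-{k}"] = str(v)


def write_mpl(scene: Scene, path) -> None:
    """Draw the scene through matplotlib (PDF/PNG backends)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib import patches, transforms

    fig = plt.figure(figsize=(scene.width / 72.0, scene.height / 72.0))
    ax = fig.add_axes([0, 0, 1, 1])
    ax.set_xlim(0, scene.width)
    ax.set_ylim(scene.height, 0)  # y-down to match the scene
    ax.axis("off")
    for item in scene.items:
        if isinstance(item, Rect):
            ax.add_patch(patches.Rectangle(
                (item.x, item.y), item.w, item.h,
                facecolor=item.fill, alpha=item.opacity,
                edgecolor=item.stroke or "none",
                linewidth=item.stroke_width))
        elif isinstance(item, Glyph):
            tr = (transforms.Affine2D().scale(item.w, item.h)
                  .translate(item.x, item.y) + ax.transData)
            ax.add_patch(patches.PathPatch(
                glyph_mpl_path(item.letter), facecolor=item.fill,
                edgecolor="none", transform=tr))
            if item.shade_fraction is not None:
                frac = min(max(item.shade_fraction, 0.0), 1.0)
                shade = patches.Rectangle(
                    (0.0, 1.0 - frac), 1.0, frac, facecolor=item.shade_color,
                    alpha=0.45, edgecolor="none", transform=tr)
                shade.set_clip_path(patches.PathPatch(
                    glyph_mpl_path(item.letter), transform=tr))
                ax.add_patch(shade)
        elif isinstance(item, Line):
            style = {}
            if item.dash:
                style["linestyle"] = (0, tuple(float(d) for d in item.dash.split(",")))
            ax.plot([item.x1, item.x2], [item.y1, item.y2],
                    color=item.stroke, linewidth=item.width, **style)
        elif isinstance(item, Polyline):
            xs, ys = zip(*item.points)
            ax.plot(xs, ys, color=item.stroke, linewidth=item.width)
        elif isinstance(item, Text):
            ax.text(item.x, item.y, item.s, fontsize=item.size,
                    ha={"start": "left", "middle": "center",
                        "end": "right"}[item.anchor],
                    va="baseline", color=item.fill,
                    rotation=item.rotate or 0)
    fig.savefig(path)
    plt.close(fig)
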