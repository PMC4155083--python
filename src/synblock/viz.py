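"""SVG dot-plot rendering of an MHP with synteny block rectangles.

Vector output only (infinite zoom, no pixelisation).  Each block gets a
deterministic colour (hash of its id into a fixed palette) and a black
bounding rectangle.  In zoom-detail mode the hp signs, tb orientations and
tb sizes are drawn on the axes, and tbs without any hp in this MHP are
greyed out (they may still have hps in other chromosome pairs).
"""

from __future__ import annotations

from dataclasses import dataclass
from xml.sax.saxutils import escape

from .core_model import SyntenyBlock
from .tandem_mhp import MHP

__all__ = ["ViewSpec", "render_mhp_svg"]

_PALETTE = [
    "#e41a1c", "#377eb8", "#4daf4a", "#984ea3", "#ff7f00",
    "#a65628", "#f781bf", "#17becf", "#bcbd22", "#2ca02c",
]

_CELL = 20  # px per tb
_MARGIN = 70


@dataclass
class ViewSpec:
    """Window of an MHP to draw.

    Ranges are half-open tb index ranges; None means the full axis.
    ``detail`` switches on per-tb annotations.
    """

    range_a: tuple[int, int] | None = None
    range_b: tuple[int, int] | None = None
    detail: bool = False
    label_a: str = ""
    label_b: str = ""


def _color(sb_id: int) -> str:
    return _PALETTE[sb_id % len(_PALETTE)]


def _orient_glyph(orientation: int | None) -> str:
    if orientation == 1:
        return ">"
    if orientation == -1:
        return "<"
    return "#"


def render_mhp_svg(
    mhp: MHP,
    blocks: list[SyntenyBlock],
    spec: ViewSpec,
    path,
) -> None:
    """Write an SVG 1.1 image of the MHP window described by ``spec``."""
    a0, a1 = spec.range_a if spec.range_a else (0, mhp.n_a)
    b0, b1 = spec.range_b if spec.range_b else (0, mhp.n_b)
    if not (0 <= a0 < a1 <= mhp.n_a and 0 <= b0 < b1 <= mhp.n_b):
        raise ValueError(
            f"view range ({a0},{a1})x({b0},{b1}) outside MHP "
            f"{mhp.n_a}x{mhp.n_b}"
        )
    na, nb = a1 - a0, b1 - b0
    width = 2 * _MARGIN + na * _CELL
    height = 2 * _MARGIN + nb * _CELL

    def cx(x: int) -> float:
        return _MARGIN + (x - a0) * _CELL

    def cy(y: int) -> float:
        # y axis points up: tb index b0 sits at the bottom
        return height - _MARGIN - (y - b0 + 1) * _CELL

    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{width}" height="{height}" '
        f'viewBox="0 0 {width} {height}">',
        f'<rect x="0" y="0" width="{width}" height="{height}" fill="white"/>',
        f'<rect x="{_MARGIN}" y="{_MARGIN}" width="{na * _CELL}" '
        f'height="{nb * _CELL}" fill="none" stroke="black"/>',
    ]
    # axis labels: input identity, chromosome names, window ranges
    label_a = escape(
        f"{spec.label_a} {mhp.chrom_a.name} [{a0}:{a1}]".strip()
    )
    label_b = escape(
        f"{spec.label_b} {mhp.chrom_b.name} [{b0}:{b1}]".strip()
    )
    parts.append(
        f'<text x="{width / 2}" y="{height - 8}" text-anchor="middle" '
        f'font-size="12">{label_a}</text>'
    )
    parts.append(
        f'<text x="14" y="{height / 2}" text-anchor="middle" font-size="12" '
        f'transform="rotate(-90 14 {height / 2})">{label_b}</text>'
    )

    block_of_cell = {}
    for sb in blocks:
        for hp in sb.hps:
            block_of_cell[(hp.x, hp.y)] = sb.id

    if spec.detail:
        used_a = {x for (x, _) in mhp.cells}
        used_b = {y for (_, y) in mhp.cells}
        for x in range(a0, a1):
            tb = mhp.chrom_a.tbs[x]
            grey = x not in used_a
            fill = "#999999" if grey else "#333333"
            glyph = escape(f"{_orient_glyph(tb.orientation)}{tb.size}")
            parts.append(
                f'<text x="{cx(x) + _CELL / 2}" y="{_MARGIN - 6}" '
                f'text-anchor="middle" font-size="9" fill="{fill}">'
                f"{glyph}</text>"
            )
        for y in range(b0, b1):
            tb = mhp.chrom_b.tbs[y]
            grey = y not in used_b
            fill = "#999999" if grey else "#333333"
            glyph = escape(f"{_orient_glyph(tb.orientation)}{tb.size}")
            parts.append(
                f'<text x="{_MARGIN - 14}" y="{cy(y) + _CELL / 2 + 4}" '
                f'text-anchor="middle" font-size="9" fill="{fill}">'
                f"{glyph}</text>"
            )

    for (x, y), sign in sorted(mhp.cells.items()):
        if not (a0 <= x < a1 and b0 <= y < b1):
            continue
        sb_id = block_of_cell.get((x, y))
        fill = _color(sb_id) if sb_id is not None else "#555555"
        parts.append(
            f'<rect x="{cx(x) + 3}" y="{cy(y) + 3}" width="{_CELL - 6}" '
            f'height="{_CELL - 6}" fill="{fill}"/>'
        )
        if spec.detail:
            glyph = "+" if sign == 1 else ("-" if sign == -1 else "?")
            parts.append(
                f'<text x="{cx(x) + _CELL / 2}" y="{cy(y) + _CELL / 2 + 4}" '
                f'text-anchor="middle" font-size="10" fill="white">'
                f"{glyph}</text>"
            )

    for sb in blocks:
        xs = [hp.x for hp in sb.hps]
        ys = [hp.y for hp in sb.hps]
        if max(xs) < a0 or min(xs) >= a1 or max(ys) < b0 or min(ys) >= b1:
            continue
        x_lo, x_hi = max(min(xs), a0), min(max(xs), a1 - 1)
        y_lo, y_hi = max(min(ys), b0), min(max(ys), b1 - 1)
        parts.append(
            f'<rect x="{cx(x_lo)}" y="{cy(y_hi)}" '
            f'width="{(x_hi - x_lo + 1) * _CELL}" '
            f'height="{(y_hi - y_lo + 1) * _CELL}" '
            f'fill="none" stroke="black" stroke-width="2" '
            f'class="sb-box" data-sb="{sb.id}"/>'
        )
    parts.append("</svg>")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(parts) + "\n")
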