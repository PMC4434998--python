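"""Two-chromosome ideogram rendering (SVG 1.1).

The reference is drawn as the left vertical bar and the target as the
right one, both to a common base-pairs-per-pixel scale.  Each region
pair gets one hue, spread uniformly around the HSV circle with fixed
saturation and value; inverted pairs additionally carry a diagonal-hatch
overlay so orientation does not rely on colour alone.  Unpaired
stretches stay uncoloured.  Output is plain-text SVG, byte-deterministic
for a fixed map and style.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass

from .mapping import RearrangementMap
from .profile import INVERTED


@dataclass
class IdeogramStyle:
    """Geometry and colour constants of the ideogram.

    ``scale`` is in base pairs per pixel; when None it is chosen so the
    longer chromosome is ``target_bar_px`` tall.
    """

    width: int = 460
    bar_width: int = 70
    margin: int = 45
    target_bar_px: int = 600
    saturation: float = 0.65
    value: float = 0.95
    scale: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.saturation <= 1.0 and 0.0 < self.value <= 1.0):
            raise ValueError("saturation and value must be in (0,1]")
        if self.scale is not None and self.scale <= 0:
            raise ValueError("scale must be positive")


def assign_hues(n_pairs: int) -> list[float]:
    """Uniformly spaced hues in degrees: i * 360 / n, all distinct."""
    if n_pairs < 0:
        raise ValueError("n_pairs must be >= 0")
    return [i * 360.0 / n_pairs for i in range(n_pairs)]


def _hsv_hex(hue_deg: float, s: float, v: float) -> str:
    r, g, b = colorsys.hsv_to_rgb((hue_deg % 360.0) / 360.0, s, v)
    return f"#{round(r * 255):02x}{round(g * 255):02x}{round(b * 255):02x}"


def _f(x: float) -> str:
    """Fixed two-decimal formatting keeps the document byte-stable."""
    return f"{x:.2f}"


def render_svg(m: RearrangementMap, style: IdeogramStyle | None = None,
               out: str | None = None) -> str:
    """Render the map as an SVG ideogram; optionally write it to ``out``."""
    style = style or IdeogramStyle()
    longest = max(m.reference_length, m.target_length, 1)
    scale = style.scale or longest / style.target_bar_px
    mg, bw = style.margin, style.bar_width
    x_ref = mg
    x_tgt = style.width - mg - bw
    h_ref = m.reference_length / scale
    h_tgt = m.target_length / scale
    height = int(max(h_ref, h_tgt)) + 2 * mg

    e: list[str] = []
    e.append('<?xml version="1.0" encoding="UTF-8"?>')
    e.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{style.width}" height="{height}" '
        f'viewBox="0 0 {style.width} {height}">'
    )
    e.append(
        '<defs><pattern id="hatch" width="6" height="6" '
        'patternUnits="userSpaceOnUse" patternTransform="rotate(45)">'
        '<line x1="0" y1="0" x2="0" y2="6" stroke="#000000" '
        'stroke-width="1.2" stroke-opacity="0.35"/></pattern></defs>'
    )
    for x, h, name in ((x_ref, h_ref, m.reference_name), (x_tgt, h_tgt, m.target_name)):
        e.append(
            f'<rect x="{x}" y="{mg}" width="{bw}" height="{_f(h)}" rx="8" '
            f'fill="#f2f2f2" stroke="#555555" stroke-width="1"/>'
        )
        e.append(
            f'<text x="{x + bw / 2:.1f}" y="{mg - 12}" text-anchor="middle" '
            f'font-family="sans-serif" font-size="13">{name}</text>'
        )

    def block(x: int, start: int, end: int, fill: str) -> str:
        y0 = mg + start / scale
        h = (end - start) / scale
        return (
            f'<rect x="{x}" y="{_f(y0)}" width="{bw}" height="{_f(h)}" '
            f'fill="{fill}"/>'
        )

    for pair in m.pairs:
        fill = _hsv_hex(pair.colour_hue, style.saturation, style.value)
        t = pair.target_region
        e.append(block(x_tgt, t.start, t.end, fill))
        if pair.orientation == INVERTED:
            e.append(block(x_tgt, t.start, t.end, "url(#hatch)"))
        for r in pair.reference_regions:
            e.append(block(x_ref, r.start, r.end, fill))
            if pair.orientation == INVERTED:
                e.append(block(x_ref, r.start, r.end, "url(#hatch)"))
    e.append("</svg>")
    doc = "\n".join(e) + "\n"
    if out is not None:
        with open(out, "w") as fh:
            fh.write(doc)
    return doc
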