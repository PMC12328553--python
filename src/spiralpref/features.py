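"""Rasterization and image-level stimulus features.

Stimuli are drawn as 1-px black curves on a white square canvas (500 x 500 by
default), centered by bounding box and, for balance measurement, fitted to the
canvas with a 12.5% margin per side emulating the axis padding of a line-graph
rendering.  The perceptual-balance feature is the DCM ("deviation of the
center of mass"): the Euclidean distance between the centroid of the ink
pixels and the canvas center, as a percentage of the half canvas side (the
maximal axis-aligned deviation).  A perfectly balanced pattern (ink centroid
at the center) scores 0; larger values mean a more lopsided figure.  The
margin and normalization are calibrated once against the published balance
scores of the three four-turn stimuli; every correlation-based statistic is
invariant to this affine choice.

``feature_table`` assembles the full per-stimulus feature set used to explain
beauty ratings: width, height, width-to-height ratio, path length, curvature
mean/variance, and DCM.  DCM is a within-spiral balance (each spiral fitted to
its own canvas); the three-turn "normal" versions inherit the value of their
family's size-matched version 2 (substitution rule), which shares their shape
and whose footprint matches the whole image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from .geometry import (
    Polyline,
    SpiralSpec,
    arc_length_numeric,
    curvature_stats,
    sample_polyline,
)

#: fraction of the canvas side left blank on each side when fitting a curve
DEFAULT_MARGIN = 0.125

FEATURE_COLUMNS = [
    "mean_curvature",
    "var_curvature",
    "width",
    "width_to_height",
    "path_length",
    "dcm",
]


@dataclass(frozen=True)
class RasterStimulus:
    """Black-on-white raster of one stimulus plus its rendering scale."""

    pixels: np.ndarray  # (side, side) uint8, 255 = background
    scale: float  # pixels per plot unit

    @property
    def canvas_side(self) -> int:
        return self.pixels.shape[0]

    @property
    def ink_mask(self) -> np.ndarray:
        return self.pixels < 128


def bounding_box(p: Polyline) -> tuple[float, float]:
    """Axis-aligned (width, height) of the vertex set, in plot units."""
    lo = p.vertices.min(axis=0)
    hi = p.vertices.max(axis=0)
    return float(hi[0] - lo[0]), float(hi[1] - lo[1])


def _fit_scale(p: Polyline, canvas_side: int, margin_frac: float) -> float:
    w, h = bounding_box(p)
    return canvas_side * (1.0 - 2.0 * margin_frac) / max(w, h)


def render(
    p: Polyline,
    canvas_side: int = 500,
    margin_frac: float = DEFAULT_MARGIN,
    scale: float | None = None,
) -> RasterStimulus:
    """Draw the polyline as a 1-px, non-anti-aliased curve, bbox-centered.

    With ``scale=None`` the curve is fitted to the canvas (largest bounding-box
    extent fills the canvas minus the margin).  Passing an explicit ``scale``
    (pixels per plot unit) renders a whole stimulus set at a common size.
    """
    if canvas_side < 16:
        raise ValueError("canvas_side must be at least 16 pixels")
    if scale is None:
        scale = _fit_scale(p, canvas_side, margin_frac)
    lo = p.vertices.min(axis=0)
    hi = p.vertices.max(axis=0)
    bbox_center = (lo + hi) / 2.0
    center_px = (canvas_side - 1) / 2.0
    xy = (p.vertices - bbox_center) * scale
    # image rows grow downward; flip y so the plot orientation is preserved
    px = xy[:, 0] + center_px
    py = center_px - xy[:, 1]
    img = Image.new("L", (canvas_side, canvas_side), color=255)
    draw = ImageDraw.Draw(img)
    draw.line(list(zip(px.tolist(), py.tolist())), fill=0, width=1)
    pixels = np.asarray(img, dtype=np.uint8)
    if not (pixels < 128).any():
        raise ValueError("rendered stimulus contains no ink")
    return RasterStimulus(pixels=pixels, scale=float(scale))


def dcm(r: RasterStimulus) -> float:
    """Balance score: 100 x (ink-centroid deviation from canvas center) / (side/2)."""
    rows, cols = np.nonzero(r.ink_mask)
    if len(rows) == 0:
        raise ValueError("no ink pixels")
    center = (r.canvas_side - 1) / 2.0
    dy = rows.mean() - center
    dx = cols.mean() - center
    return float(100.0 * np.hypot(dx, dy) / (r.canvas_side / 2.0))


def feature_table(
    specs: list[SpiralSpec],
    canvas_side: int = 500,
    margin_frac: float = DEFAULT_MARGIN,
    substitute_v1_dcm: bool = True,
) -> pd.DataFrame:
    """Per-stimulus feature table (one row per stimulus_id).

    Width/height/path length are measured on the continuous polyline in plot
    units (a scale common to all stimuli by construction, so width
    discriminates the deliberately size-manipulated versions); DCM is a
    within-spiral balance measured on a per-stimulus canvas-fitted raster.
    ``substitute_v1_dcm`` overwrites each version-1 DCM with the same family's
    version-2 value, whose shape it shares.
    """
    polylines = {s.stimulus_id: sample_polyline(s) for s in specs}
    rows = []
    for spec in specs:
        p = polylines[spec.stimulus_id]
        w, h = bounding_box(p)
        mean_k, var_k = curvature_stats(spec)
        raster = render(p, canvas_side=canvas_side, margin_frac=margin_frac)
        rows.append(
            {
                "stimulus_id": spec.stimulus_id,
                "family": spec.family.value,
                "version": spec.version,
                "width": w,
                "height": h,
                "width_to_height": w / h,
                "path_length": arc_length_numeric(p),
                "mean_curvature": mean_k,
                "var_curvature": var_k,
                "dcm": dcm(raster),
            }
        )
    table = pd.DataFrame(rows).set_index("stimulus_id")
    if substitute_v1_dcm:
        for fam in table["family"].unique():
            fam_rows = table.index[table["family"] == fam]
            v1 = [i for i in fam_rows if table.loc[i, "version"] == 1]
            v2 = [i for i in fam_rows if table.loc[i, "version"] == 2]
            if v1 and v2:
                table.loc[v1[0], "dcm"] = table.loc[v2[0], "dcm"]
    return table


def feature_correlations(table: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Pearson correlation matrix over the six feature columns."""
    if len(table) < 3:
        raise ValueError("need at least 3 stimuli for correlations")
    cols = [c for c in FEATURE_COLUMNS if c in table.columns]
    sub = table[cols].astype(float)
    degenerate = [c for c in cols if sub[c].std() == 0]
    corr = sub.corr(method="pearson")
    for c in degenerate:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
        corr.loc[c, c] = np.nan
    return corr
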