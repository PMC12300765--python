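"""Heatmap coloring of relative mutation scores and ROI report rendering.

The relative mutation score in [0, 1] maps to a green-yellow-red scale:
green at 0, yellow near 0.5, red at 1, via piecewise-linear RGB
interpolation (r = 255*min(2v, 1), g = 255*min(2(1-v), 1), b = 0). An
ROI whose DNA has not been sequenced yet has no score and stays fully
transparent. Overlays are alpha-composited over the slide raster.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from typing import Mapping, Optional

import numpy as np
from skimage import draw

from .burden import ROISummary
from .morphometry import MorphometryResult
from .registration import ROIArchive

logger = logging.getLogger(__name__)

#: default overlay opacity (fraction of 255)
DEFAULT_OPACITY = 0.4


@dataclass(frozen=True)
class HeatColor:
    r: int
    g: int
    b: int
    alpha: int

    def __post_init__(self) -> None:
        for ch in (self.r, self.g, self.b, self.alpha):
            if not 0 <= ch <= 255:
                raise ValueError("color channels must be in [0, 255]")


def score_to_color(score: Optional[float], opacity: float = DEFAULT_OPACITY) -> HeatColor:
    """Map a relative mutation score onto the green→yellow→red scale.

    ``None`` (unsequenced ROI) yields a fully transparent color. The
    mapping is piecewise linear with anchors green (0, 255, 0) at 0,
    yellow (255, 255, 0) at 0.5 and red (255, 0, 0) at 1.
    """
    if score is None:
        return HeatColor(0, 0, 0, 0)
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score must be in [0, 1], got {score}")
    r = int(round(255 * min(2.0 * score, 1.0)))
    g = int(round(255 * min(2.0 * (1.0 - score), 1.0)))
    return HeatColor(r, g, 0, int(round(255 * opacity)))


def _shape_interior(shape, image_shape) -> tuple[np.ndarray, np.ndarray]:
    h, w = image_shape[:2]
    if shape.kind in ("rectangle", "square"):
        rr, cc = draw.rectangle(
            start=(shape.y, shape.x),
            extent=(shape.height, shape.width),
            shape=(h, w),
        )
        return rr.astype(int).ravel(), cc.astype(int).ravel()
    if shape.kind in ("circle", "ellipse"):
        return draw.ellipse(shape.y, shape.x, shape.b, shape.a, shape=(h, w))
    return draw.line(
        int(round(np.clip(shape.y, 0, h - 1))), int(round(np.clip(shape.x, 0, w - 1))),
        int(round(np.clip(shape.y2, 0, h - 1))), int(round(np.clip(shape.x2, 0, w - 1))),
    )


def render_overlay(
    image: np.ndarray,
    archive: ROIArchive,
    scores: Mapping[str, float],
    opacity: float = DEFAULT_OPACITY,
) -> np.ndarray:
    """Alpha-composite heatmap fills over ROI interiors.

    ROIs without a score stay untouched (transparent convention).
    Shapes partly outside the raster are clipped with a warning. The
    output is a uint8 RGB array of the input dimensions; the blend is
    out = (1 - alpha) * src + alpha * fill, rounded per channel.
    """
    img = np.asarray(image)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    out = img[..., :3].astype(float)
    h, w = out.shape[:2]
    for entry in archive.rois:
        if entry.roi_id not in scores:
            continue
        color = score_to_color(scores[entry.roi_id], opacity=opacity)
        if color.alpha == 0:
            continue
        s = entry.shape
        x_max = s.x + (s.width or 0) + (s.a or 0)
        y_max = s.y + (s.height or 0) + (s.b or 0)
        if s.x < 0 or s.y < 0 or x_max > w or y_max > h:
            logger.warning("ROI %s extends outside the image; clipping", entry.roi_id)
        rr, cc = _shape_interior(s, out.shape)
        a = color.alpha / 255.0
        fill = np.array([color.r, color.g, color.b], dtype=float)
        out[rr, cc] = (1.0 - a) * out[rr, cc] + a * fill
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def render_annotation(
    summary: Optional[ROISummary],
    morpho: MorphometryResult,
    roi_id: Optional[str] = None,
) -> dict:
    """Structured annotation report for one ROI (JSON-serializable).

    Contains the morphometry, the mutation totals, the relative score
    and the top-gene blocks with their variant types, pathways and drug
    targets. An unsequenced ROI (``summary=None``) carries only the
    morphometry with the genomic block marked pending.
    """
    report: dict = {
        "roi_id": roi_id if roi_id is not None else (summary.roi_id if summary else ""),
        "perimeter_um": morpho.perimeter_um,
        "area_um2": morpho.area_um2,
    }
    if summary is None:
        report["genomics"] = {"status": "pending"}
        return report
    report["genomics"] = {
        "status": "analyzed",
        "total_mutations": summary.total_mutations,
        "affected_genes": summary.total_affected_genes,
        "relative_mutation_score": summary.relative_mutation_score,
        "top_genes": [
            {
                "symbol": g.symbol,
                "mutations": g.count,
                "variant_types": list(g.variant_types),
                "pathways": list(g.pathways),
                "drug_targets": list(g.drugs),
                "annotated": g.annotated,
            }
            for g in summary.top_genes
        ],
    }
    return report


def annotation_text(report: dict) -> str:
    """Plain-text rendering of an annotation report."""
    lines = [
        f"ROI {report['roi_id']}",
        f"  perimeter: {report['perimeter_um']:.3f} um",
        f"  area:      {report['area_um2']:.3f} um^2",
    ]
    gen = report["genomics"]
    if gen["status"] == "pending":
        lines.append("  genomics:  pending (not sequenced)")
        return "\n".join(lines)
    lines += [
        f"  mutations: {gen['total_mutations']} on {gen['affected_genes']} genes",
        f"  relative mutation score: {gen['relative_mutation_score']:.4f}",
    ]
    for g in gen["top_genes"]:
        lines.append(f"  {g['symbol']}: {g['mutations']} mutation(s) "
                     f"[{', '.join(g['variant_types'])}]")
        if g["pathways"]:
            lines.append(f"    pathways: {'; '.join(g['pathways'])}")
        if g["drug_targets"]:
            lines.append(f"    drugs:    {'; '.join(g['drug_targets'])}")
    return "\n".join(lines)


def report_roundtrip_json(report: dict) -> dict:
    """Serialize and re-load a report; loss-free by construction."""
    return json.loads(json.dumps(report))
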