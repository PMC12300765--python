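"""Pixel-to-stage registration, ROI archives and microdissector export.

Before ROIs drawn on a digital slide can be laser-cut, reference points
recorded both in image pixels and in the microdissector's stage
coordinate system anchor a 2D affine transform (least squares over at
least three non-collinear correspondences). A full affine is fitted —
rather than a similarity — because the scanner stage has independent
mechanisms, hence independent scales, along the two axes.

ROIs, their morphometry and genomic summaries are persisted in a
versioned JSON archive; for cutting, shapes are exported to an XML
file in stage coordinates. The vendor's XML schema is not public, so a
documented schema (see ``LMD_XML_VERSION``) is written here, isolated
behind one writer/reader pair so a vendor-exact writer can be swapped
in. Stage coordinates are kept in μm internally and exported in mm to
4 decimal places.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from lxml import etree

from .burden import ChromosomeStat, ROISummary, TopGene
from .morphometry import MorphometryResult, ROIShape

ARCHIVE_VERSION = "1"
LMD_XML_VERSION = "1"

#: empirically set dissection parameters, carried as export metadata only
DISSECTION_PARAMS = {
    "cut_velocity_um_per_s": 30.0,
    "laser_focus_um": 533.0,
    "laser_power_fraction": 0.8,
    "laser_power_total_mw": 10.0,
    "cutting_repeats": 2,
    "z_drill_um": 0.1,
    "focus_check_s": 1.0,
}


class RegistrationError(ValueError):
    """Degenerate reference-point geometry or unfitted frame."""


@dataclass
class ReferenceFrame:
    """Fitted pixel → stage (μm) affine: ``stage = A @ pixel + t``."""

    matrix: np.ndarray  # 2x2 linear part
    translation: np.ndarray  # length-2, μm
    rms_residual_um: float = 0.0
    pairs: tuple[tuple[tuple[float, float], tuple[float, float]], ...] = ()

    def to_dict(self) -> dict:
        return {
            "matrix": self.matrix.tolist(),
            "translation": self.translation.tolist(),
            "rms_residual_um": self.rms_residual_um,
            "pairs": [list(map(list, p)) for p in self.pairs],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReferenceFrame":
        return cls(
            matrix=np.asarray(d["matrix"], dtype=float),
            translation=np.asarray(d["translation"], dtype=float),
            rms_residual_um=float(d.get("rms_residual_um", 0.0)),
            pairs=tuple((tuple(p[0]), tuple(p[1])) for p in d.get("pairs", ())),
        )


def fit_affine(
    pairs: Sequence[tuple[tuple[float, float], tuple[float, float]]],
) -> ReferenceFrame:
    """Least-squares 2D affine from (pixel, stage μm) correspondences.

    Requires at least three pairs with non-collinear pixel points.
    Stores the RMS residual in stage space.
    """
    if len(pairs) < 3:
        raise RegistrationError(f"need >= 3 reference pairs, got {len(pairs)}")
    px = np.asarray([p for p, _ in pairs], dtype=float)
    st = np.asarray([s for _, s in pairs], dtype=float)
    # collinearity check on pixel points: rank of centered coordinates
    centered = px - px.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(px).max())) < 2:
        raise RegistrationError("reference pixel points are collinear")
    design = np.hstack([px, np.ones((len(pairs), 1))])
    coef, *_ = np.linalg.lstsq(design, st, rcond=None)
    matrix = coef[:2].T
    translation = coef[2]
    residuals = design @ coef - st
    rms = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    return ReferenceFrame(
        matrix=matrix,
        translation=translation,
        rms_residual_um=rms,
        pairs=tuple((tuple(p), tuple(s)) for p, s in pairs),
    )


def map_point(frame: ReferenceFrame, p: tuple[float, float]) -> tuple[float, float]:
    """Apply the fitted affine to a pixel point; returns stage μm."""
    out = frame.matrix @ np.asarray(p, dtype=float) + frame.translation
    return (float(out[0]), float(out[1]))


def inverse_map_point(frame: ReferenceFrame, s: tuple[float, float]) -> tuple[float, float]:
    """Stage μm → pixel, using the algebraic inverse of the affine."""
    det = np.linalg.det(frame.matrix)
    if abs(det) < 1e-300:
        raise RegistrationError("singular linear part; frame is not invertible")
    out = np.linalg.solve(frame.matrix, np.asarray(s, dtype=float) - frame.translation)
    return (float(out[0]), float(out[1]))


# ---------------------------------------------------------------------------
# ROI archive (JSON)
# ---------------------------------------------------------------------------

@dataclass
class ROIEntry:
    roi_id: str
    shape: ROIShape
    morphometry: Optional[MorphometryResult] = None
    summary: Optional[ROISummary] = None


@dataclass
class ROIArchive:
    """Everything persisted about a slide's ROIs, restorable later."""

    slide_id: str
    rois: list[ROIEntry] = field(default_factory=list)
    frame: Optional[ReferenceFrame] = None

    def __post_init__(self) -> None:
        ids = [r.roi_id for r in self.rois]
        if len(ids) != len(set(ids)):
            raise ValueError("roi_id values must be unique within an archive")


def _summary_to_dict(s: ROISummary) -> dict:
    return {
        "roi_id": s.roi_id,
        "per_chromosome": [asdict(c) for c in s.per_chromosome],
        "total_mutations": s.total_mutations,
        "total_affected_genes": s.total_affected_genes,
        "relative_mutation_score": s.relative_mutation_score,
        "top_genes": [asdict(g) for g in s.top_genes],
    }


def _summary_from_dict(d: dict) -> ROISummary:
    return ROISummary(
        roi_id=d["roi_id"],
        per_chromosome=tuple(ChromosomeStat(**c) for c in d["per_chromosome"]),
        total_mutations=d["total_mutations"],
        total_affected_genes=d["total_affected_genes"],
        relative_mutation_score=d["relative_mutation_score"],
        top_genes=tuple(
            TopGene(
                symbol=g["symbol"],
                count=g["count"],
                variant_types=tuple(g["variant_types"]),
                pathways=tuple(g.get("pathways", ())),
                drugs=tuple(g.get("drugs", ())),
                annotated=g.get("annotated", False),
            )
            for g in d["top_genes"]
        ),
    )


def save_archive(archive: ROIArchive, path: str | Path) -> None:
    """Lossless JSON persistence of shapes, morphometry, summaries, frame."""
    doc = {
        "format": "roifuse-archive",
        "version": ARCHIVE_VERSION,
        "slide_id": archive.slide_id,
        "frame": archive.frame.to_dict() if archive.frame is not None else None,
        "rois": [
            {
                "roi_id": e.roi_id,
                "shape": {k: v for k, v in asdict(e.shape).items() if v is not None},
                "morphometry": asdict(e.morphometry) if e.morphometry else None,
                "summary": _summary_to_dict(e.summary) if e.summary else None,
            }
            for e in archive.rois
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_archive(path: str | Path) -> ROIArchive:
    """Restore an archive; version mismatch raises with the version found."""
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "roifuse-archive":
        raise ValueError(f"{path} is not a ROI archive")
    version = doc.get("version")
    if version != ARCHIVE_VERSION:
        raise ValueError(
            f"archive version {version!r} not supported (expected {ARCHIVE_VERSION!r})"
        )
    rois = [
        ROIEntry(
            roi_id=e["roi_id"],
            shape=ROIShape(**e["shape"]),
            morphometry=MorphometryResult(**e["morphometry"]) if e["morphometry"] else None,
            summary=_summary_from_dict(e["summary"]) if e["summary"] else None,
        )
        for e in doc["rois"]
    ]
    frame = ReferenceFrame.from_dict(doc["frame"]) if doc["frame"] is not None else None
    return ROIArchive(slide_id=doc["slide_id"], rois=rois, frame=frame)


# ---------------------------------------------------------------------------
# Microdissector XML export
# ---------------------------------------------------------------------------

def _mm(um: float) -> str:
    return f"{um / 1000.0:.4f}"


def _shape_stage_geometry(shape: ROIShape, frame: ReferenceFrame) -> dict:
    """Stage-space geometry of one shape, values in μm.

    Rectangles and lines map their vertices through the affine exactly.
    Circles/ellipses export their mapped center plus semi-axes scaled by
    the per-axis magnification (norm of each transformed unit axis);
    under a shearing affine this is the axis-aligned approximation.
    """
    if shape.kind in ("rectangle", "square"):
        corners = [
            (shape.x, shape.y),
            (shape.x + shape.width, shape.y),
            (shape.x + shape.width, shape.y + shape.height),
            (shape.x, shape.y + shape.height),
        ]
        return {"vertices": [map_point(frame, c) for c in corners]}
    if shape.kind in ("circle", "ellipse"):
        center = map_point(frame, (shape.x, shape.y))
        sx = float(np.linalg.norm(frame.matrix[:, 0]))
        sy = float(np.linalg.norm(frame.matrix[:, 1]))
        return {"center": center, "semi_axes": (shape.a * sx, shape.b * sy)}
    return {"vertices": [map_point(frame, (shape.x, shape.y)),
                         map_point(frame, (shape.x2, shape.y2))]}


def export_lmd_xml(archive: ROIArchive, path: str | Path) -> None:
    """Write the archive's ROIs as microdissector-import XML.

    One ``<shape>`` element per ROI with its stage-space geometry in mm
    to 4 decimals; the dissection parameter block is attached as
    metadata. Requires a fitted reference frame.
    """
    if archive.frame is None:
        raise RegistrationError("archive has no reference frame; fit one before export")
    root = etree.Element(
        "lmd_export", version=LMD_XML_VERSION, slide=archive.slide_id, units="mm"
    )
    params = etree.SubElement(root, "dissection_parameters")
    for k, v in DISSECTION_PARAMS.items():
        etree.SubElement(params, "param", name=k, value=str(v))
    shapes = etree.SubElement(root, "shapes")
    for e in archive.rois:
        el = etree.SubElement(shapes, "shape", id=e.roi_id, kind=e.shape.kind)
        geom = _shape_stage_geometry(e.shape, archive.frame)
        if "vertices" in geom:
            for vx, vy in geom["vertices"]:
                etree.SubElement(el, "vertex", x=_mm(vx), y=_mm(vy))
        else:
            cx, cy = geom["center"]
            a, b = geom["semi_axes"]
            etree.SubElement(el, "center", x=_mm(cx), y=_mm(cy))
            etree.SubElement(el, "semi_axes", a=_mm(a), b=_mm(b))
    _validate_lmd_tree(root)
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


def _validate_lmd_tree(root: etree._Element) -> None:
    if root.tag != "lmd_export" or root.get("version") != LMD_XML_VERSION:
        raise ValueError("invalid LMD export document")
    for el in root.iter("vertex", "center", "semi_axes"):
        for attr in el.attrib.values():
            float(attr)  # every coordinate must be numeric


def import_lmd_xml(path: str | Path) -> list[dict]:
    """Read back an exported XML; returns per-shape stage geometry in mm.

    Each dict has ``id``, ``kind`` and either ``vertices`` (list of
    (x, y) mm tuples) or ``center``/``semi_axes``.
    """
    root = etree.parse(str(path)).getroot()
    _validate_lmd_tree(root)
    out = []
    for el in root.iter("shape"):
        entry: dict = {"id": el.get("id"), "kind": el.get("kind")}
        verts = [(float(v.get("x")), float(v.get("y"))) for v in el.iter("vertex")]
        if verts:
            entry["vertices"] = verts
        else:
            c = el.find("center")
            s = el.find("semi_axes")
            entry["center"] = (float(c.get("x")), float(c.get("y")))
            entry["semi_axes"] = (float(s.get("a")), float(s.get("b")))
        out.append(entry)
    return out
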