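"""Facial landmark handling and analysis-region derivation.

The analysis regions follow the layout used in UV-photography coverage
studies: an axis-aligned *face* box spanning forehead to chin, one *eyelid*
box per eye (periocular skin up to the brow line), and a small *medial
canthus* box at each inner eye corner — the facial area with the highest
per-unit-area skin-cancer incidence.  All regions are binary pixel masks
derived from a 68-point landmark annotation.

Landmark semantics use the standard 68-point scheme (1-based): jaw 1-17,
brows 18-27, nose 28-36, eyes 37-48 and mouth 49-68.  Storage is 0-based.
Coordinates are image-frame pixels: origin top-left, x rightward,
y downward; "left"/"right" mean image-frame left/right, not anatomical.
Boxes are half-open ``[x0, x1) x [y0, y1)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "LandmarkError",
    "LandmarkFormatError",
    "LandmarkSet",
    "RegionParams",
    "RegionSet",
    "load_landmarks",
    "write_landmarks_pts",
    "regions_from_landmarks",
    "split_face_halves",
    "JAW",
    "LEFT_BROW",
    "RIGHT_BROW",
    "NOSE_BRIDGE",
    "NOSE_BASE",
    "LEFT_EYE",
    "RIGHT_EYE",
    "MOUTH",
    "LEFT_EYE_INNER",
    "RIGHT_EYE_INNER",
    "LEFT_EYE_OUTER",
    "RIGHT_EYE_OUTER",
]

N_LANDMARKS = 68

# 0-based index groups of the 68-point scheme ("left" = image-left).
JAW = slice(0, 17)
LEFT_BROW = slice(17, 22)
RIGHT_BROW = slice(22, 27)
NOSE_BRIDGE = slice(27, 31)
NOSE_BASE = slice(31, 36)
LEFT_EYE = slice(36, 42)
RIGHT_EYE = slice(42, 48)
MOUTH = slice(48, 68)

LEFT_EYE_OUTER = 36   # point 37
LEFT_EYE_INNER = 39   # point 40
RIGHT_EYE_INNER = 42  # point 43
RIGHT_EYE_OUTER = 45  # point 46
CHIN = 8              # point 9


class LandmarkError(ValueError):
    """A landmark set violates a geometric or semantic invariant."""


class LandmarkFormatError(LandmarkError):
    """A landmark file could not be parsed as a 68-point annotation."""


@dataclass(frozen=True)
class LandmarkSet:
    """68 labelled facial points in image pixel coordinates.

    Parameters
    ----------
    points:
        ``(68, 2)`` float array of ``(x, y)`` pixel coordinates.
    source_image_dims:
        ``(height, width)`` of the image the landmarks were detected on,
        or ``None`` if unknown (bounds validation is then skipped).
    """

    points: np.ndarray
    source_image_dims: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (N_LANDMARKS, 2):
            raise LandmarkFormatError(
                f"expected {N_LANDMARKS} landmark points, found {pts.shape[0]}"
            )
        if not np.all(np.isfinite(pts)):
            raise LandmarkError("landmark coordinates must be finite")
        object.__setattr__(self, "points", pts)
        if self.source_image_dims is not None:
            h, w = self.source_image_dims
            if np.any(pts[:, 0] < 0) or np.any(pts[:, 0] > w - 1) or \
                    np.any(pts[:, 1] < 0) or np.any(pts[:, 1] > h - 1):
                raise LandmarkError(
                    f"landmark points fall outside image bounds {h}x{w}"
                )
        for a, b in ((LEFT_EYE_OUTER, LEFT_EYE_INNER),
                     (RIGHT_EYE_INNER, RIGHT_EYE_OUTER)):
            if np.hypot(*(pts[a] - pts[b])) <= 0:
                raise LandmarkError(
                    f"degenerate eye landmarks: points {a + 1} and {b + 1} coincide"
                )

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    def scaled(self, s: float) -> "LandmarkSet":
        """Return a copy with coordinates (and dims, if set) scaled by ``s``."""
        dims = self.source_image_dims
        new_dims = None if dims is None else (int(round(dims[0] * s)),
                                              int(round(dims[1] * s)))
        return LandmarkSet(self.points * s, new_dims)


def _parse_pts(text: str) -> np.ndarray:
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    n_declared = None
    coords: list[tuple[float, float]] = []
    in_body = False
    for ln in lines:
        low = ln.lower()
        if low.startswith("version:"):
            continue
        if low.startswith("n_points:"):
            n_declared = int(ln.split(":", 1)[1])
            continue
        if ln == "{":
            in_body = True
            continue
        if ln == "}":
            in_body = False
            continue
        if in_body:
            parts = ln.split()
            if len(parts) != 2:
                raise LandmarkFormatError(f"malformed PTS coordinate line: {ln!r}")
            coords.append((float(parts[0]), float(parts[1])))
    if n_declared is not None and n_declared != len(coords):
        raise LandmarkFormatError(
            f"PTS header declares {n_declared} points but body has {len(coords)}"
        )
    return np.asarray(coords, dtype=float).reshape(-1, 2)


def load_landmarks(path: str | Path, fmt: str | None = None,
                   image_dims: tuple[int, int] | None = None) -> LandmarkSet:
    """Read a 68-point landmark file in PTS or JSON format.

    ``fmt`` is inferred from the file extension when omitted.  JSON files
    are objects with a ``points`` list of ``[x, y]`` pairs and an optional
    ``image_dims`` ``[height, width]`` entry; an explicit ``image_dims``
    argument overrides the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"landmark file not found: {path}")
    if fmt is None:
        fmt = path.suffix.lower().lstrip(".")
    if fmt == "pts":
        pts = _parse_pts(path.read_text())
        dims = image_dims
    elif fmt == "json":
        payload = json.loads(path.read_text())
        pts = np.asarray(payload["points"], dtype=float).reshape(-1, 2)
        dims = image_dims
        if dims is None and payload.get("image_dims") is not None:
            dims = tuple(int(v) for v in payload["image_dims"])
    else:
        raise LandmarkFormatError(f"unsupported landmark format: {fmt!r}")
    if pts.shape[0] != N_LANDMARKS:
        raise LandmarkFormatError(
            f"expected {N_LANDMARKS} landmark points, found {pts.shape[0]} in {path}"
        )
    return LandmarkSet(pts, dims)


def write_landmarks_pts(lm: LandmarkSet, path: str | Path) -> None:
    """Write a landmark set as a PTS file (coordinates to 3 decimals)."""
    lines = ["version: 1", f"n_points: {N_LANDMARKS}", "{"]
    lines += [f"{x:.3f} {y:.3f}" for x, y in lm.points]
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class RegionParams:
    """Tunable margins of the region geometry.

    forehead_margin:
        Forehead extension above the brow line, in units of the vertical
        eye-to-brow distance.
    lateral_margin_frac:
        Lateral expansion of each eyelid box, as a fraction of eye width.
    canthus_inner_frac:
        Canthus box side as a fraction of the inter-inner-corner distance.
    canthus_eye_cap_frac:
        Upper cap on the canthus box side, as a fraction of eye width.
    nasal_offset_frac:
        Nasal (toward-midline) shift of the canthus box centre, as a
        fraction of the canthus box side.
    """

    forehead_margin: float = 1.0
    lateral_margin_frac: float = 0.10
    canthus_inner_frac: float = 0.60
    canthus_eye_cap_frac: float = 0.25
    nasal_offset_frac: float = 0.25


@dataclass
class RegionSet:
    """Named binary masks over one image, plus derivation provenance.

    Region names: ``face``, ``eyelid_left``, ``eyelid_right``,
    ``canthus_left``, ``canthus_right``, ``eyelid`` (union of both eyelid
    boxes) and ``non_eyelid`` (face minus eyelid).  Invariants: every
    region is a subset of ``face``; eyelid and non_eyelid partition face.
    """

    masks: dict[str, np.ndarray]
    provenance: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def area(self, name: str) -> int:
        return int(self.masks[name].sum())


def _box_mask(dims: tuple[int, int], x0: float, x1: float,
              y0: float, y1: float) -> np.ndarray:
    """Rasterize a half-open box, clipped to the image.

    Edges round to the nearest pixel boundary, which keeps rasterized
    areas unbiased under rescaling of the landmark geometry.
    """
    h, w = dims
    xi0 = max(0, int(np.floor(x0 + 0.5)))
    yi0 = max(0, int(np.floor(y0 + 0.5)))
    xi1 = min(w, int(np.floor(x1 + 0.5)))
    yi1 = min(h, int(np.floor(y1 + 0.5)))
    mask = np.zeros((h, w), dtype=bool)
    if xi1 > xi0 and yi1 > yi0:
        mask[yi0:yi1, xi0:xi1] = True
    return mask


def regions_from_landmarks(lm: LandmarkSet,
                           params: RegionParams | None = None,
                           image_dims: tuple[int, int] | None = None) -> RegionSet:
    """Derive the analysis regions from a 68-point landmark set.

    The face box runs laterally between the outermost jaw points, from an
    extrapolated forehead line (brow top minus ``forehead_margin`` times
    the eye-to-brow distance) down to the chin point.  Each eyelid box is
    the bounding box of that eye's six points, raised to the brow line and
    widened laterally; each canthus box is a small square at the inner eye
    corner, shifted nasally.  All regions are clipped to the face box.
    """
    params = params or RegionParams()
    dims = image_dims or lm.source_image_dims
    if dims is None:
        raise LandmarkError("image_dims required (landmark set carries none)")
    pts = lm.points

    brow_top = float(pts[17:27, 1].min())
    eye_y = float(pts[36:48, 1].mean())
    eye_to_brow = max(eye_y - brow_top, 1.0)

    face_x0 = float(pts[JAW][:, 0].min())
    face_x1 = float(pts[JAW][:, 0].max()) + 1.0
    face_y0 = brow_top - params.forehead_margin * eye_to_brow
    face_y1 = float(pts[CHIN, 1]) + 1.0
    face = _box_mask(dims, face_x0, face_x1, face_y0, face_y1)
    if not face.any():
        raise LandmarkError("face region is empty after clipping to image")

    inner_dist = float(np.hypot(*(pts[RIGHT_EYE_INNER] - pts[LEFT_EYE_INNER])))

    eyelids: dict[str, np.ndarray] = {}
    canthi: dict[str, np.ndarray] = {}
    boxes: dict[str, tuple[float, float, float, float]] = {
        "face": (face_x0, face_x1, face_y0, face_y1),
    }
    for side, eye_sl, brow_sl, inner, outer in (
        ("left", LEFT_EYE, LEFT_BROW, LEFT_EYE_INNER, LEFT_EYE_OUTER),
        ("right", RIGHT_EYE, RIGHT_BROW, RIGHT_EYE_INNER, RIGHT_EYE_OUTER),
    ):
        eye = pts[eye_sl]
        eye_width = max(abs(float(pts[outer, 0] - pts[inner, 0])), 1.0)
        margin = params.lateral_margin_frac * eye_width
        ex0 = float(eye[:, 0].min()) - margin
        ex1 = float(eye[:, 0].max()) + 1.0 + margin
        ey0 = float(pts[brow_sl][:, 1].min())
        ey1 = float(eye[:, 1].max()) + 1.0
        eyelids[side] = _box_mask(dims, ex0, ex1, ey0, ey1) & face
        boxes[f"eyelid_{side}"] = (ex0, ex1, ey0, ey1)

        size = min(params.canthus_inner_frac * inner_dist,
                   params.canthus_eye_cap_frac * eye_width)
        size = max(size, 2.0)
        nasal = 1.0 if side == "left" else -1.0
        cx = float(pts[inner, 0]) + nasal * params.nasal_offset_frac * size
        cy = float(pts[inner, 1])
        canthi[side] = _box_mask(dims, cx - size / 2, cx + size / 2,
                                 cy - size / 2, cy + size / 2) & face
        boxes[f"canthus_{side}"] = (cx - size / 2, cx + size / 2,
                                    cy - size / 2, cy + size / 2)

    eyelid = eyelids["left"] | eyelids["right"]
    masks = {
        "face": face,
        "eyelid_left": eyelids["left"],
        "eyelid_right": eyelids["right"],
        "canthus_left": canthi["left"],
        "canthus_right": canthi["right"],
        "eyelid": eyelid,
        "non_eyelid": face & ~eyelid,
    }
    provenance = {
        "params": params,
        "boxes": boxes,
        "landmark_indices": {
            "face_lateral": [1, 17], "chin": 9,
            "eyes": "37-48", "inner_corners": [40, 43],
        },
        "note": "left/right are image-frame, not anatomical",
    }
    return RegionSet(masks=masks, provenance=provenance)


def split_face_halves(lm: LandmarkSet,
                      face: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split the face mask vertically at the nose-bridge midline.

    The midline x is the mean x of the four nose-bridge points (28-31).
    Returns ``(left, right)`` masks that exactly partition ``face``:
    pixels with column index strictly below the midline go left.
    """
    midline_x = float(lm.points[NOSE_BRIDGE, 0].mean())
    cols = np.arange(face.shape[1])[None, :]
    left = face & (cols < midline_x)
    right = face & ~(cols < midline_x)
    return left, right
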