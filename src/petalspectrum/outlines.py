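"""Outline containers and I/O: raster tracing, tables, landmarks, resampling.

An :class:`Outline` is an ordered closed 2D polyline (implicitly closed,
counter-clockwise) for one specimen and view, with landmarks stored as vertex
indices.  Coordinates are continuous planar units with no physical scale — the
downstream Procrustes alignment removes scale anyway.

Raster masks follow the image convention (origin top-left, y down); the y axis
is flipped on ingestion so the mathematical counter-clockwise convention holds
internally.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage import measure

from .exceptions import DegeneracyError, FormatError, InputError, MappingError

LANDMARK_COUNT = {"front": 4, "side": 3}
#: index (0-based) of the landmark that anchors the traversal start
START_LANDMARK = {"front": 2, "side": 0}  # front: top; side: tube base


@dataclass
class Outline:
    """Closed polyline for one specimen/view with attached landmarks."""

    specimen_id: str
    taxon_id: str
    view: str
    points: np.ndarray
    landmarks: list[int] = field(default_factory=list)
    clade: str | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise InputError("points must be an (n, 2) array")
        if self.view not in ("front", "side"):
            raise InputError(f"view must be 'front' or 'side', got {self.view!r}")
        n = len(self.points)
        if n < 3:
            raise InputError("an outline needs at least 3 points")
        self.landmarks = [int(i) for i in self.landmarks]
        if any(i < 0 or i >= n for i in self.landmarks):
            raise InputError("landmark index out of range")
        if len(set(self.landmarks)) != len(self.landmarks):
            raise InputError("landmark indices must be unique")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def signed_area(self) -> float:
        x, y = self.points[:, 0], self.points[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def perimeter(self) -> float:
        closed = np.vstack([self.points, self.points[:1]])
        return float(np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1)))

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def centroid_size(self) -> float:
        return float(np.sqrt(np.sum((self.points - self.centroid()) ** 2)))

    def landmark_coords(self) -> np.ndarray:
        return self.points[self.landmarks]

    def with_points(self, points, landmarks=None) -> "Outline":
        """Copy carrying all metadata; optionally new landmark indices."""
        return replace(
            self,
            points=np.asarray(points, dtype=float),
            landmarks=self.landmarks if landmarks is None else list(landmarks),
        )


@dataclass
class SpecimenTable:
    """Inventory of outlines: one row per (specimen, view) with taxon and clade."""

    frame: pd.DataFrame

    REQUIRED = ("specimen_id", "taxon_id", "clade", "view")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise FormatError(f"specimen table missing columns: {missing}")
        dup = self.frame.duplicated(subset=["specimen_id", "view"])
        if dup.any():
            raise FormatError(
                f"duplicate (specimen_id, view) rows: {self.frame.loc[dup, 'specimen_id'].tolist()}"
            )

    @classmethod
    def from_csv(cls, path) -> "SpecimenTable":
        return cls(pd.read_csv(path, dtype=str))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def taxon_of(self, specimen_id: str) -> str:
        rows = self.frame[self.frame["specimen_id"] == specimen_id]
        if rows.empty:
            raise MappingError(f"specimen {specimen_id!r} not in specimen table")
        return str(rows["taxon_id"].iloc[0])

    def clade_of_taxon(self, taxon_id: str) -> str:
        rows = self.frame[self.frame["taxon_id"] == taxon_id]
        if rows.empty:
            raise MappingError(f"taxon {taxon_id!r} not in specimen table")
        return str(rows["clade"].iloc[0])


# ------------------------------------------------------------------- raster


def trace_mask(image, min_area: int = 1, specimen_id: str = "traced",
               taxon_id: str = "traced", view: str = "front",
               smooth_sigma: float = 1.0) -> Outline:
    """Trace the boundary of the largest foreground component of a binary mask.

    Marching squares at level 0.5 on the (zero-padded) component; a light
    Gaussian smoothing (``smooth_sigma`` pixels) suppresses the staircase bias
    marching squares has on hard binary data, keeping traced perimeters close
    to the true boundary length.  Pixel rows are flipped to y-up so the
    returned outline is counter-clockwise.
    """
    arr = np.asarray(image)
    if arr.dtype != bool:
        arr = arr.astype(float)
        if arr.max() > 1:
            arr = arr / 255.0
        arr = arr > 0.5
    labels = measure.label(arr, connectivity=1)
    if labels.max() == 0:
        raise InputError("mask contains no foreground component")
    areas = np.bincount(labels.ravel())[1:]
    big = areas.max()
    if big < min_area:
        raise InputError(f"largest component has area {big} < min_area={min_area}")
    winners = np.flatnonzero(areas == big)
    if winners.size > 1:
        raise DegeneracyError(f"{winners.size} equal-largest components (area {big})")
    comp = np.pad(labels == winners[0] + 1, 2).astype(float)
    if smooth_sigma > 0:
        from scipy.ndimage import gaussian_filter

        comp = gaussian_filter(comp, smooth_sigma)
    contours = measure.find_contours(comp, 0.5)
    contour = max(contours, key=len)
    if np.allclose(contour[0], contour[-1]):
        contour = contour[:-1]
    # (row, col) -> (x, y) with y flipped; undo the 2-pixel pad
    pts = np.column_stack([contour[:, 1] - 2, -(contour[:, 0] - 2)])
    out = Outline(specimen_id, taxon_id, view, pts)
    if out.signed_area() < 0:
        out = out.with_points(out.points[::-1])
    return out


# -------------------------------------------------------------------- tables

_OUTLINE_COLS = ["specimen_id", "taxon_id", "clade", "view", "point_index", "x", "y"]
_LANDMARK_COLS = ["specimen_id", "view", "landmark_index", "x", "y"]


def write_outline_table(outlines, path, landmark_path=None) -> None:
    """Write outlines (and optionally landmark coordinates) as CSV.

    Coordinates are written with full repr precision so that write-then-read is
    an exact round trip.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_OUTLINE_COLS)
        for o in outlines:
            clade = "" if o.clade is None else o.clade
            for i, (x, y) in enumerate(o.points):
                w.writerow([o.specimen_id, o.taxon_id, clade, o.view, i, repr(float(x)), repr(float(y))])
    if landmark_path is not None:
        with open(landmark_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(_LANDMARK_COLS)
            for o in outlines:
                for j, (x, y) in enumerate(o.landmark_coords()):
                    w.writerow([o.specimen_id, o.view, j, repr(float(x)), repr(float(y))])


def read_outline_table(path, landmark_path=None) -> list[Outline]:
    """Read outlines from CSV; if a landmark CSV is given, attach landmarks.

    Points are re-ordered by ``point_index``; gaps or duplicate indices raise a
    :class:`FormatError` naming the offending index/row.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file without header")
        missing = [c for c in _OUTLINE_COLS if c not in header]
        if missing:
            raise FormatError(f"{path}: missing columns {missing}")
        col = {c: header.index(c) for c in _OUTLINE_COLS}
        rows: dict[tuple[str, str], dict] = {}
        for lineno, rec in enumerate(reader, start=2):
            if not rec:
                continue
            key = (rec[col["specimen_id"]], rec[col["view"]])
            entry = rows.setdefault(
                key,
                {
                    "taxon_id": rec[col["taxon_id"]],
                    "clade": rec[col["clade"]] or None,
                    "points": {},
                },
            )
            try:
                idx = int(rec[col["point_index"]])
                xy = (float(rec[col["x"]]), float(rec[col["y"]]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if idx in entry["points"]:
                raise FormatError(
                    f"{path}:{lineno}: duplicate point_index {idx} for specimen "
                    f"{key[0]!r} view {key[1]!r}"
                )
            entry["points"][idx] = xy
    outlines = []
    for (sid, view), entry in rows.items():
        idxs = sorted(entry["points"])
        if idxs != list(range(len(idxs))):
            gap = next(i for i in range(len(idxs)) if i not in entry["points"])
            raise FormatError(
                f"{path}: specimen {sid!r} view {view!r}: point_index not "
                f"contiguous, missing index {gap}"
            )
        pts = np.array([entry["points"][i] for i in idxs])
        outlines.append(
            Outline(sid, entry["taxon_id"], view, pts, landmarks=[], clade=entry["clade"])
        )
    if landmark_path is not None:
        lm = pd.read_csv(landmark_path)
        miss = [c for c in _LANDMARK_COLS if c not in lm.columns]
        if miss:
            raise FormatError(f"{landmark_path}: missing columns {miss}")
        by_spec = {
            key: grp.sort_values("landmark_index")[["x", "y"]].to_numpy()
            for key, grp in lm.groupby(["specimen_id", "view"])
        }
        outlines = [
            attach_landmarks(o, by_spec[(o.specimen_id, o.view)])
            if (o.specimen_id, o.view) in by_spec
            else o
            for o in outlines
        ]
    return outlines


# ----------------------------------------------------------------- landmarks


def attach_landmarks(outline: Outline, landmark_coords) -> Outline:
    """Snap landmark coordinates to the nearest outline vertices.

    Landmark order is preserved (front: left-mid, right-mid, top, bottom;
    side: tube base, upper-lip tip, lower-lip tip).  Ties snap to the lower
    vertex index.
    """
    coords = np.asarray(landmark_coords, dtype=float).reshape(-1, 2)
    want = LANDMARK_COUNT[outline.view]
    if len(coords) != want:
        raise InputError(
            f"{outline.view} view needs {want} landmarks, got {len(coords)}"
        )
    idxs = []
    for c in coords:
        d2 = np.sum((outline.points - c) ** 2, axis=1)
        idxs.append(int(np.argmin(d2)))  # argmin takes the lowest index on ties
    if len(set(idxs)) != len(idxs):
        raise DegeneracyError(f"two landmarks snapped to the same vertex: {idxs}")
    return outline.with_points(outline.points, landmarks=idxs)


# ---------------------------------------------------------------- resampling


def _arc_params(points: np.ndarray):
    closed = np.vstack([points, points[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    return closed, t


def resample_uniform(outline: Outline, n_points: int = 300) -> Outline:
    """Resample to ``n_points`` vertices equally spaced by arc length.

    The start vertex is the one nearest the view's anchor landmark (front:
    top; side: tube base); landmarks are re-snapped to the new vertices.
    """
    if n_points < 64:
        raise InputError("n_points must be >= 64")
    if outline.perimeter() <= 0:
        raise InputError("degenerate outline with zero perimeter")
    pts = outline.points
    if outline.landmarks:
        anchor = outline.landmarks[START_LANDMARK[outline.view]]
        pts = np.roll(pts, -anchor, axis=0)
    closed, t = _arc_params(pts)
    total = t[-1]
    new_t = np.linspace(0.0, total, n_points, endpoint=False)
    x = np.interp(new_t, t, closed[:, 0])
    y = np.interp(new_t, t, closed[:, 1])
    new_pts = np.column_stack([x, y])
    # drop any consecutive duplicates created by coincident input vertices
    keep = np.ones(len(new_pts), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(new_pts, axis=0), axis=1) > 1e-14
    new_pts = new_pts[keep]
    new = outline.with_points(new_pts, landmarks=[])
    if outline.landmarks:
        return attach_landmarks(new, outline.landmark_coords())
    return new


def canonicalize_orientation(outline: Outline) -> Outline:
    """Force counter-clockwise traversal and the canonical start vertex.

    Idempotent; landmark indices are remapped under reversal/rotation.
    """
    area = outline.signed_area()
    if area == 0:
        raise InputError("outline has zero signed area")
    pts = outline.points
    lms = list(outline.landmarks)
    n = len(pts)
    if area < 0:
        pts = pts[::-1].copy()
        lms = [(n - 1 - i) for i in lms]
    if lms:
        anchor = lms[START_LANDMARK[outline.view]]
        pts = np.roll(pts, -anchor, axis=0)
        lms = [(i - anchor) % n for i in lms]
    return outline.with_points(pts, landmarks=lms)
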