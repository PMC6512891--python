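"""Face normalization, grid-cell intensity extraction, and the facial partition.

The video descriptor used throughout the pipeline is the matrix ``X[r][n]``:
the mean gray level of grid cell *r* in frame *n* of a landmark-normalized
face video.  This module provides

* :func:`normalize_face` — least-squares similarity alignment of a frame
  onto canonical landmark positions, cropped to a fixed-size face box;
* :func:`cell_intensity_series` — division of each normalized frame into a
  grid of equally sized cells and recording of the per-cell mean intensity;
* :func:`partition_faceparts` — assignment of grid cells to the six facial
  parts (left/right eye, left/right cheek, mouth, nose) and their composite
  groups (eyes, mouth_and_nose, cheeks, all_parts).

Conventions: pixel coordinates are 0-based with origin at the top-left,
x rightward and y downward; cells are indexed row-major with the top-left
cell at index 0; color input is converted to gray as 0.299R+0.587G+0.114B.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.transform import SimilarityTransform, warp

from .errors import ConfigurationError

LANDMARK_NAMES: tuple[str, ...] = (
    "left_eye",
    "right_eye",
    "nose_tip",
    "mouth_left",
    "mouth_right",
    "chin",
)

#: Canonical landmark positions as fractions of the normalized face box.
CANONICAL_LANDMARK_FRACTIONS: dict[str, tuple[float, float]] = {
    "left_eye": (0.28, 0.28),
    "right_eye": (0.72, 0.28),
    "nose_tip": (0.50, 0.64),
    "mouth_left": (0.32, 0.82),
    "mouth_right": (0.68, 0.82),
    "chin": (0.50, 0.94),
}

PART_NAMES: tuple[str, ...] = (
    "left_eye",
    "right_eye",
    "left_cheek",
    "right_cheek",
    "mouth",
    "nose",
)

GROUP_NAMES: tuple[str, ...] = ("eyes", "mouth_and_nose", "cheeks", "all_parts")

#: Table-3-style region column order: four composite groups then six parts.
REGION_NAMES: tuple[str, ...] = (
    "eyes",
    "mouth_and_nose",
    "cheeks",
    "all_parts",
    "left_eye",
    "right_eye",
    "nose",
    "mouth",
    "left_cheek",
    "right_cheek",
)

#: Default part rectangles (x0, y0, x1, y1) in normalized [0,1]^2 face
#: coordinates.  Edges sit on eighth-gridlines so that on the default 8x8
#: grid every part is an exact union of whole cells.  Eyes occupy the upper
#: third, nose the center, mouth the lower third, cheeks the lateral halves.
DEFAULT_PART_LAYOUT: dict[str, tuple[float, float, float, float]] = {
    "left_eye": (0.125, 0.125, 0.500, 0.375),
    "right_eye": (0.500, 0.125, 0.875, 0.375),
    "nose": (0.375, 0.500, 0.625, 0.750),
    "mouth": (0.250, 0.750, 0.750, 1.000),
    "left_cheek": (0.000, 0.500, 0.250, 1.000),
    "right_cheek": (0.750, 0.500, 1.000, 1.000),
}

DEFAULT_OUT_SIZE = 96
DEFAULT_GRID = (8, 8)


def to_gray(img: np.ndarray) -> np.ndarray:
    """Convert an image to float gray levels (luma weights for color input)."""
    img = np.asarray(img, dtype=float)
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[2] in (3, 4):
        return img[..., 0] * 0.299 + img[..., 1] * 0.587 + img[..., 2] * 0.114
    raise ValueError(f"unsupported image shape {img.shape}")


@dataclass(frozen=True)
class LandmarkSet:
    """Named facial landmark coordinates (x, y) for a single frame."""

    points: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (x, y) in self.points.items():
            if not (np.isfinite(x) and np.isfinite(y)):
                raise ValueError(f"non-finite coordinate for landmark {name!r}")
        if "left_eye" in self.points and "right_eye" in self.points:
            if not self.points["left_eye"][0] < self.points["right_eye"][0]:
                raise ValueError("left_eye must lie left of right_eye in image coordinates")

    def as_array(self, names: tuple[str, ...] | None = None) -> np.ndarray:
        names = names or tuple(self.points)
        return np.array([self.points[n] for n in names], dtype=float)

    def names(self) -> tuple[str, ...]:
        return tuple(self.points)


def template_landmarks(out_size: int = DEFAULT_OUT_SIZE) -> LandmarkSet:
    """Canonical landmark positions scaled to an ``out_size`` face box."""
    return LandmarkSet(
        {n: (x * out_size, y * out_size) for n, (x, y) in CANONICAL_LANDMARK_FRACTIONS.items()}
    )


@dataclass
class NormalizedFaceSequence:
    """A stack of aligned, cropped, fixed-size grayscale face frames."""

    frames: np.ndarray  # (n_frames, out_size, out_size)
    patient_id: str | None = None
    fps: float = 30.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != self.frames.shape[2]:
            raise ValueError("frames must be a (n, size, size) stack")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def out_size(self) -> int:
        return self.frames.shape[1]


def estimate_alignment(landmarks: LandmarkSet, template: LandmarkSet) -> SimilarityTransform:
    """Least-squares similarity transform mapping template onto frame landmarks.

    The returned transform maps canonical (output) coordinates to source-frame
    coordinates, i.e. it is the inverse map used for resampling.
    """
    common = [n for n in template.names() if n in landmarks.points]
    if len(common) < 2:
        raise ValueError("need at least 2 landmarks shared with the template")
    src = template.as_array(tuple(common))
    dst = landmarks.as_array(tuple(common))
    if np.allclose(dst, dst[0], atol=1e-9) or np.allclose(src, src[0], atol=1e-9):
        raise ValueError("degenerate landmarks: all points coincide")
    tform = SimilarityTransform.from_estimate(src, dst)
    if not tform or not np.all(np.isfinite(tform.params)) or abs(tform.scale) < 1e-8:
        raise ValueError("degenerate landmark configuration: alignment is rank-deficient")
    return tform


def normalize_face(
    frame: np.ndarray,
    landmarks: LandmarkSet,
    template: LandmarkSet | None = None,
    out_size: int = DEFAULT_OUT_SIZE,
) -> np.ndarray:
    """Align and crop one frame to the canonical ``out_size`` face box.

    The similarity transform (rotation, isotropic scale, translation) is the
    least-squares fit of the frame landmarks onto the template; resampling is
    bilinear with out-of-source samples filled with 0.
    """
    template = template or template_landmarks(out_size)
    gray = to_gray(frame)
    tform = estimate_alignment(landmarks, template)
    return warp(
        gray,
        tform,
        output_shape=(out_size, out_size),
        order=1,
        cval=0.0,
        preserve_range=True,
    )


def normalize_sequence(
    frames: np.ndarray,
    landmarks_per_frame: list[LandmarkSet],
    out_size: int = DEFAULT_OUT_SIZE,
    patient_id: str | None = None,
    fps: float = 30.0,
) -> NormalizedFaceSequence:
    """Normalize every frame of a video against the canonical template."""
    if len(frames) != len(landmarks_per_frame):
        raise ValueError("one LandmarkSet required per frame")
    template = template_landmarks(out_size)
    out = np.stack(
        [normalize_face(f, lm, template, out_size) for f, lm in zip(frames, landmarks_per_frame)]
    )
    return NormalizedFaceSequence(out, patient_id=patient_id, fps=fps)


# ---------------------------------------------------------------------------
# Grid cells


@dataclass
class CellIntensitySeries:
    """The matrix X[r][n]: mean gray level of cell r at frame n."""

    X: np.ndarray  # (n_cells, n_frames)
    grid: tuple[int, int]  # (rows, cols)
    out_size: int
    patient_id: str | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        g_r, g_c = self.grid
        if self.X.shape[0] != g_r * g_c:
            raise ValueError("number of cells must equal grid rows x cols")
        if self.X.shape[1] < 2:
            raise ValueError("a cell-intensity series needs at least 2 frames")

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_frames(self) -> int:
        return self.X.shape[1]

    def cell_rect(self, r: int) -> tuple[int, int, int, int]:
        """Pixel rectangle (row0, col0, row1, col1) of cell ``r`` (row-major)."""
        g_r, g_c = self.grid
        ch, cw = self.out_size // g_r, self.out_size // g_c
        i, j = divmod(r, g_c)
        return (i * ch, j * cw, (i + 1) * ch, (j + 1) * cw)


def _check_grid(out_size: int, grid: tuple[int, int]) -> None:
    g_r, g_c = grid
    if g_r < 1 or g_c < 1:
        raise ConfigurationError("grid dimensions must be positive")
    if out_size % g_r or out_size % g_c:
        raise ConfigurationError(
            f"out_size {out_size} not divisible by grid {grid}: cells would be unequal"
        )


def cell_means(frame: np.ndarray, grid: tuple[int, int]) -> np.ndarray:
    """Per-cell mean gray level of one frame, row-major (length g_r * g_c)."""
    frame = np.asarray(frame, dtype=float)
    size = frame.shape[0]
    if frame.shape != (size, size):
        raise ValueError("frame must be square")
    _check_grid(size, grid)
    g_r, g_c = grid
    ch, cw = size // g_r, size // g_c
    return frame.reshape(g_r, ch, g_c, cw).mean(axis=(1, 3)).reshape(-1)


def cell_intensity_series(
    seq: NormalizedFaceSequence | np.ndarray,
    grid: tuple[int, int] = DEFAULT_GRID,
    patient_id: str | None = None,
) -> CellIntensitySeries:
    """Record X[r][n] for every grid cell r and frame n of a normalized video."""
    if isinstance(seq, NormalizedFaceSequence):
        frames, size = seq.frames, seq.out_size
        patient_id = patient_id or seq.patient_id
    else:
        frames = np.asarray(seq, dtype=float)
        if frames.ndim != 3 or frames.shape[1] != frames.shape[2]:
            raise ValueError("frames must be a (n, size, size) stack")
        size = frames.shape[1]
    if frames.shape[0] < 2:
        raise ValueError("a video needs at least 2 frames")
    _check_grid(size, grid)
    g_r, g_c = grid
    ch, cw = size // g_r, size // g_c
    X = frames.reshape(-1, g_r, ch, g_c, cw).mean(axis=(2, 4)).reshape(len(frames), g_r * g_c).T
    return CellIntensitySeries(X, grid, size, patient_id=patient_id)


# ---------------------------------------------------------------------------
# Facial partition


@dataclass
class FacePartition:
    """Assignment of grid cells to the six facial parts and composite groups."""

    grid: tuple[int, int]
    parts: dict[str, frozenset[int]]
    groups: dict[str, frozenset[int]] = field(default_factory=dict)

    def cells(self, region: str) -> frozenset[int]:
        if region in self.parts:
            return self.parts[region]
        if region in self.groups:
            return self.groups[region]
        raise KeyError(f"unknown face region {region!r}")

    @property
    def region_names(self) -> tuple[str, ...]:
        return tuple(self.parts) + tuple(self.groups)


def _rects_overlap(a: tuple[float, ...], b: tuple[float, ...]) -> bool:
    ax0, ay0, ax1, ay1 = a
    bx0, by0, bx1, by1 = b
    return ax0 < bx1 and bx0 < ax1 and ay0 < by1 and by0 < ay1


def partition_faceparts(
    grid: tuple[int, int] = DEFAULT_GRID,
    layout: dict[str, tuple[float, float, float, float]] | None = None,
) -> FacePartition:
    """Assign each grid cell whose center lies inside a part rectangle to that part.

    ``layout`` maps part names to (x0, y0, x1, y1) rectangles in normalized
    [0,1]^2 face coordinates; rectangles must be pairwise non-overlapping
    (shared edges allowed).  Composite groups are exact unions of their parts.
    """
    layout = layout if layout is not None else DEFAULT_PART_LAYOUT
    names = list(layout)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if _rects_overlap(layout[a], layout[b]):
                raise ConfigurationError(f"part rectangles {a!r} and {b!r} overlap")
    g_r, g_c = grid
    if g_r < 1 or g_c < 1:
        raise ConfigurationError("grid dimensions must be positive")
    parts: dict[str, frozenset[int]] = {}
    for name, (x0, y0, x1, y1) in layout.items():
        members = []
        for r in range(g_r * g_c):
            i, j = divmod(r, g_c)
            cx, cy = (j + 0.5) / g_c, (i + 0.5) / g_r
            if x0 <= cx <= x1 and y0 <= cy <= y1:
                members.append(r)
        parts[name] = frozenset(members)
    groups: dict[str, frozenset[int]] = {}
    if {"left_eye", "right_eye"} <= set(parts):
        groups["eyes"] = parts["left_eye"] | parts["right_eye"]
    if {"mouth", "nose"} <= set(parts):
        groups["mouth_and_nose"] = parts["mouth"] | parts["nose"]
    if {"left_cheek", "right_cheek"} <= set(parts):
        groups["cheeks"] = parts["left_cheek"] | parts["right_cheek"]
    groups["all_parts"] = frozenset().union(*parts.values())
    return FacePartition(grid=grid, parts=parts, groups=groups)


# ---------------------------------------------------------------------------
# IO: PNG frame directories, landmark CSV, series CSV + JSON sidecar


def read_frames_dir(path: str | Path) -> np.ndarray:
    """Read a directory of numbered grayscale PNG frames into an (n, h, w) stack."""
    files = sorted(Path(path).glob("*.png"))
    if not files:
        raise FileNotFoundError(f"no PNG frames found under {path}")
    return np.stack([to_gray(iio.imread(f)) for f in files])


def write_frames_dir(frames: np.ndarray, path: str | Path) -> list[Path]:
    """Write frames as zero-padded numbered 8-bit grayscale PNGs."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    out = []
    for i, f in enumerate(np.asarray(frames)):
        p = path / f"{i:06d}.png"
        iio.imwrite(p, np.clip(np.round(f), 0, 255).astype(np.uint8))
        out.append(p)
    return out


def read_landmarks_csv(path: str | Path) -> list[LandmarkSet]:
    """Read per-frame landmarks (columns frame_index, landmark_name, x, y)."""
    df = pd.read_csv(path)
    out = []
    for _, grp in df.groupby("frame_index", sort=True):
        out.append(
            LandmarkSet({row.landmark_name: (row.x, row.y) for row in grp.itertuples()})
        )
    return out


def write_landmarks_csv(landmarks: list[LandmarkSet], path: str | Path) -> None:
    rows = [
        {"frame_index": i, "landmark_name": name, "x": x, "y": y}
        for i, lm in enumerate(landmarks)
        for name, (x, y) in lm.points.items()
    ]
    pd.DataFrame(rows, columns=["frame_index", "landmark_name", "x", "y"]).to_csv(
        path, index=False
    )


def write_series(
    series: CellIntensitySeries,
    csv_path: str | Path,
    partition: FacePartition | None = None,
) -> None:
    """Write X as CSV (rows = cells, columns = frames) plus a JSON sidecar."""
    csv_path = Path(csv_path)
    cols = [f"frame_{n:06d}" for n in range(series.n_frames)]
    pd.DataFrame(series.X, columns=cols).to_csv(csv_path, index_label="cell")
    meta = {
        "grid": list(series.grid),
        "out_size": series.out_size,
        "patient_id": series.patient_id,
    }
    if partition is not None:
        meta["partition"] = {k: sorted(v) for k, v in partition.parts.items()}
        meta["groups"] = {k: sorted(v) for k, v in partition.groups.items()}
    csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_series(csv_path: str | Path) -> CellIntensitySeries:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path, index_col="cell")
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    return CellIntensitySeries(
        df.to_numpy(), tuple(meta["grid"]), meta["out_size"], patient_id=meta.get("patient_id")
    )
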