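"""Landmark-track and bite-table input/output.

Strike videos are landmarked with five points per frame (a SLEAP-style
pose-estimation export): premaxilla anterior tip, dentary anterior tip,
pupil center, quadrate-articular jaw joint, and an anteroventral point on
the preopercle.  Tracks arrive in pixel coordinates with a per-landmark
confidence score and are calibrated to millimetres with a per-session
ruler scale.  Bite outcomes (length/width/depth of the gelatin divot per
strike) arrive as a CSV table.

HDF5 layout (one file per strike)
---------------------------------
``tracks``        float array, frames x 5 x 2 (x, y image coordinates,
                  origin top-left, y increasing downward) or
                  frames x instances x 5 x 2 for multi-instance exports
``point_scores``  float array, frames x 5 (or frames x instances x 5),
                  confidence in [0, 1]; 0 or NaN marks a missing point
``node_names``    length-5 string array naming the landmarks in order
plus file attributes ``strike_id``, ``individual_id``, ``species``,
``frame_rate`` and ``units``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

#: canonical landmark order; indices are used throughout the package
NODE_NAMES = (
    "premaxilla_tip",
    "dentary_tip",
    "pupil_center",
    "quadrate_articular",
    "preopercle_anteroventral",
)
PREMAX, DENTARY, PUPIL, QUADRATE, PREOPERCLE = range(5)

SPECIES = ("generalist", "molluscivore", "scale_eater", "hybrid")
STRIKE_TYPES = ("edge", "corner", "scrape", "miss")


@dataclass
class StrikeTrack:
    """One strike's landmark coordinate time series.

    ``coords`` is frames x 5 x 2; missing observations are NaN in both
    coordinates (and carry confidence 0).  ``units`` is ``"px"`` until
    :func:`calibrate_track` converts to ``"mm"``.
    """

    strike_id: str
    individual_id: str
    species: str
    frame_rate: float
    coords: np.ndarray
    confidence: np.ndarray
    units: str = "px"
    strike_type: str | None = None
    imputed: np.ndarray = field(default=None)  # frames x 5 bool

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise ValidationError(
                f"coords must be frames x landmarks x 2, got {self.coords.shape}"
            )
        if self.coords.shape[1] != 5:
            raise ValidationError(
                f"expected exactly 5 landmarks, got {self.coords.shape[1]}"
            )
        if self.coords.shape[0] < 2:
            raise ValidationError("a track needs at least 2 frames")
        if self.confidence.shape != self.coords.shape[:2]:
            raise ValidationError("confidence must be frames x landmarks")
        if self.units not in ("px", "mm"):
            raise ValidationError(f"units must be 'px' or 'mm', got {self.units!r}")
        if self.species not in SPECIES:
            raise ValidationError(f"unknown species {self.species!r}")
        if self.frame_rate <= 0:
            raise ValidationError("frame_rate must be positive")
        # normalize: zero/NaN confidence means the point is missing
        missing = ~np.isfinite(self.confidence) | (self.confidence <= 0)
        self.coords = self.coords.copy()
        self.coords[missing] = np.nan
        coord_missing = ~np.isfinite(self.coords).all(axis=2)
        if np.any(coord_missing & ~missing):
            # non-finite coords with positive confidence violate the contract
            raise ValidationError("non-finite coordinates with positive confidence")
        if self.imputed is None:
            self.imputed = np.zeros(self.coords.shape[:2], dtype=bool)
        else:
            self.imputed = np.asarray(self.imputed, dtype=bool)
            if self.imputed.shape != self.coords.shape[:2]:
                raise ValidationError("imputed mask must be frames x landmarks")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def missing(self) -> np.ndarray:
        """Boolean frames x 5 mask of missing observations."""
        return ~np.isfinite(self.coords).all(axis=2)

    def copy(self) -> "StrikeTrack":
        return replace(
            self,
            coords=self.coords.copy(),
            confidence=self.confidence.copy(),
            imputed=self.imputed.copy(),
        )


@dataclass(frozen=True)
class CalibrationScale:
    """Pixels-per-millimetre scale from a photographed ruler."""

    px_per_mm: float
    session_id: str = ""

    def __post_init__(self):
        if not np.isfinite(self.px_per_mm) or self.px_per_mm <= 0:
            raise ValidationError("px_per_mm must be a positive real")


@dataclass(frozen=True)
class BiteRecord:
    """Dimensions of the gelatin divot removed by one strike."""

    strike_id: str
    individual_id: str
    species: str
    strike_type: str
    length_mm: float
    width_mm: float
    depth_mm: float

    def __post_init__(self):
        if self.species not in SPECIES:
            raise ValidationError(f"unknown species {self.species!r}")
        if self.strike_type not in STRIKE_TYPES:
            raise ValidationError(f"unknown strike type {self.strike_type!r}")
        for name in ("length_mm", "width_mm", "depth_mm"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be nonnegative, got {v}")
        if self.strike_type == "miss" and self.volume_mm3 != 0:
            raise ValidationError("miss strikes must have zero bite dimensions")

    @property
    def volume_mm3(self) -> float:
        return self.length_mm * self.width_mm * self.depth_mm


# ---------------------------------------------------------------------------
# HDF5 track round-trip


def write_track(path, track: StrikeTrack) -> None:
    """Write a StrikeTrack to the documented HDF5 layout."""
    with h5py.File(path, "w") as f:
        f.create_dataset("tracks", data=track.coords)
        f.create_dataset("point_scores", data=track.confidence)
        f.create_dataset(
            "node_names", data=np.array(NODE_NAMES, dtype=h5py.string_dtype())
        )
        f.create_dataset("imputed", data=track.imputed)
        f.attrs["strike_id"] = track.strike_id
        f.attrs["individual_id"] = track.individual_id
        f.attrs["species"] = track.species
        f.attrs["frame_rate"] = track.frame_rate
        f.attrs["units"] = track.units
        if track.strike_type is not None:
            f.attrs["strike_type"] = track.strike_type


def _cull_instances(coords: np.ndarray, scores: np.ndarray):
    """Reduce a multi-instance export to one instance per frame.

    Fish were filmed individually, so extra instances are spurious
    detections; keep, per frame, the instance with the highest mean
    confidence.
    """
    n_frames = coords.shape[0]
    out_c = np.full(coords.shape[0:1] + coords.shape[2:], np.nan)
    out_s = np.zeros((n_frames, coords.shape[2]))
    mean_scores = np.where(np.isfinite(scores), scores, 0.0).mean(axis=2)
    best = np.argmax(mean_scores, axis=1)
    idx = np.arange(n_frames)
    out_c = coords[idx, best]
    out_s = scores[idx, best]
    return out_c, out_s


def read_track(path, metadata: dict | None = None) -> StrikeTrack:
    """Read a StrikeTrack from HDF5; ``metadata`` overrides file attributes."""
    metadata = metadata or {}
    with h5py.File(path, "r") as f:
        for name in ("tracks", "point_scores", "node_names"):
            if name not in f:
                raise FormatError(f"{path}: missing required dataset {name!r}")
        coords = np.asarray(f["tracks"], dtype=float)
        scores = np.asarray(f["point_scores"], dtype=float)
        names = [
            n.decode() if isinstance(n, bytes) else str(n) for n in f["node_names"][()]
        ]
        imputed = np.asarray(f["imputed"], dtype=bool) if "imputed" in f else None
        attrs = dict(f.attrs)
    if coords.ndim == 4:  # frames x instances x nodes x 2
        coords, scores = _cull_instances(coords, scores)
    if coords.ndim != 3:
        raise FormatError(f"{path}: 'tracks' must be frames x landmarks x 2")
    if len(names) != coords.shape[1]:
        raise FormatError(f"{path}: node_names length does not match tracks")
    if tuple(names) != NODE_NAMES:
        if len(names) != 5:
            raise ValidationError(
                f"{path}: expected 5 landmarks {NODE_NAMES}, got {names}"
            )
        raise ValidationError(f"{path}: unexpected landmark names/order: {names}")

    def _get(key, default=None):
        if key in metadata:
            return metadata[key]
        v = attrs.get(key, default)
        return v.item() if hasattr(v, "item") and not isinstance(v, str) else v

    return StrikeTrack(
        strike_id=str(_get("strike_id", Path(path).stem)),
        individual_id=str(_get("individual_id", "unknown")),
        species=str(_get("species", "generalist")),
        frame_rate=float(_get("frame_rate", 1100.0)),
        coords=coords,
        confidence=scores,
        units=str(_get("units", "px")),
        strike_type=_get("strike_type"),
        imputed=imputed,
    )


# ---------------------------------------------------------------------------
# calibration and gap repair


def calibrate_track(track: StrikeTrack, scale: CalibrationScale) -> StrikeTrack:
    """Convert a pixel-space track to millimetres (divide by px/mm).

    Calibrating an already-calibrated track is an error rather than a
    silent double division.
    """
    if track.units == "mm":
        raise ValidationError("track is already calibrated to mm")
    out = track.copy()
    out.coords = out.coords / scale.px_per_mm
    out.units = "mm"
    return out


def interpolate_gaps(track: StrikeTrack, max_gap: int = 5) -> StrikeTrack:
    """Fill short missing runs per landmark by linear interpolation.

    Runs of at most ``max_gap`` consecutive missing frames that are
    flanked by observations on both sides are filled linearly; longer
    runs and gaps touching either end of the track are left missing.
    Filled frames are flagged in ``imputed``; observed frames are never
    altered.
    """
    if max_gap < 0:
        raise ValidationError("max_gap must be >= 0")
    out = track.copy()
    missing = track.missing
    for lm in range(track.coords.shape[1]):
        m = missing[:, lm]
        if not m.any():
            continue
        obs_idx = np.flatnonzero(~m)
        if obs_idx.size < 2:
            continue
        # walk runs of missing frames
        i = 0
        n = m.size
        while i < n:
            if not m[i]:
                i += 1
                continue
            j = i
            while j < n and m[j]:
                j += 1
            run = j - i
            if run <= max_gap and i > 0 and j < n and not m[i - 1] and not m[j]:
                t0, t1 = i - 1, j
                for t in range(i, j):
                    w = (t - t0) / (t1 - t0)
                    out.coords[t, lm] = (1 - w) * track.coords[t0, lm] + w * track.coords[t1, lm]
                    out.imputed[t, lm] = True
            i = j
    return out


# ---------------------------------------------------------------------------
# bite table

BITE_COLUMNS = [
    "strike_id",
    "individual_id",
    "species",
    "strike_type",
    "length_mm",
    "width_mm",
    "depth_mm",
]


def load_bite_table(path) -> list[BiteRecord]:
    """Load per-strike bite dimensions from CSV.

    Misses leave no mark, so blank or zero dimensions on a ``miss`` row
    are coerced to 0; any other blank dimension is a validation error.
    """
    df = pd.read_csv(path)
    missing_cols = [c for c in BITE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"{path}: bite table missing columns {missing_cols}")
    records = []
    for _, row in df.iterrows():
        st = str(row["strike_type"])
        dims = {}
        for c in ("length_mm", "width_mm", "depth_mm"):
            v = row[c]
            if pd.isna(v):
                if st == "miss":
                    v = 0.0
                else:
                    raise ValidationError(
                        f"{path}: blank {c} on non-miss strike {row['strike_id']!r}"
                    )
            dims[c] = float(v)
        if st == "miss":
            dims = {c: 0.0 for c in dims}
        records.append(
            BiteRecord(
                strike_id=str(row["strike_id"]),
                individual_id=str(row["individual_id"]),
                species=str(row["species"]),
                strike_type=st,
                **dims,
            )
        )
    return records


def bite_table_frame(records: list[BiteRecord]) -> pd.DataFrame:
    """Tidy DataFrame view of bite records, with derived volume."""
    return pd.DataFrame(
        {
            "strike_id": [r.strike_id for r in records],
            "individual_id": [r.individual_id for r in records],
            "species": [r.species for r in records],
            "strike_type": [r.strike_type for r in records],
            "length_mm": [r.length_mm for r in records],
            "width_mm": [r.width_mm for r in records],
            "depth_mm": [r.depth_mm for r in records],
            "volume_mm3": [r.volume_mm3 for r in records],
        }
    )


def save_bite_table(path, records: list[BiteRecord]) -> None:
    bite_table_frame(records)[BITE_COLUMNS].to_csv(path, index=False)
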