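"""Synthetic feeding strikes with a known two-peak performance surface.

The generator emits the same artifacts a filming + pose-estimation
session would: per-strike landmark tracks (HDF5, pixel units, with
detector jitter), a bite-dimension CSV, and — unlike real data — a
ground-truth table of the kinematics and expected bite size each strike
was built from.

Trajectory model
----------------
The head (pupil, quadrate, preopercle) translates as a rigid triad
toward a virtual gel along a logistic approach; total travel is scaled
so the pupil displacement between gape onset (20% of peak) and peak gape
equals ``rs * TTPG`` exactly.  Gape and premaxilla protrusion rise along
a smoothstep from onset to peak, then hold at their peaks until impact
(fish reach peak gape well before contact) and relax afterwards while
the head retreats.  The dentary opens ventrally from the premaxilla tip,
and the preopercle landmark is placed so the dentary-quadrate-preopercle
angle at the peak-gape frame equals the injected minimum jaw angle.

Bite model
----------
Expected bite length is a deterministic two-bump performance surface in
(g, jp) — one optimum at small gape/protrusion and one at large
gape/protrusion with a valley between — plus species and strike-type
offsets and a per-individual random intercept.  Width tracks jaw size
(weak dependence on gape), depth is near-constant with a scrape
reduction, misses have all dimensions zero, and each dimension receives
independent Gaussian measurement noise truncated at zero before volume
is formed.  Species kinematic means follow the qualitative ordering seen
in this system (scale-eaters largest gape and protrusion, > 6.5 mm
protrusion reachable only with scale-eater ancestry) without asserting
any measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import (
    SPECIES,
    STRIKE_TYPES,
    BiteRecord,
    StrikeTrack,
    bite_table_frame,
    save_bite_table,
    write_track,
)

KIN_VARS = ("g", "jp", "ja", "ttpg", "rs")


@dataclass(frozen=True)
class SurfaceParams:
    """Two-bump Gaussian performance surface over (g, jp), in mm."""

    centers: tuple = ((3.0, 2.8), (5.5, 7.5))
    amplitudes: tuple = (3.0, 2.5)
    widths: tuple = ((0.9, 0.9), (1.1, 1.2))  # (sd_g, sd_jp) per bump
    baseline: float = 0.8

    def __post_init__(self):
        if len(self.centers) != len(self.amplitudes) or len(self.centers) != len(
            self.widths
        ):
            raise ValidationError("centers, amplitudes, widths must align")
        if any(a < 0 for a in self.amplitudes) or self.baseline < 0:
            raise ValidationError("amplitudes and baseline must be nonnegative")
        if any(w <= 0 for pair in self.widths for w in pair):
            raise ValidationError("bump widths must be positive")


def true_performance(g, jp, params: SurfaceParams = SurfaceParams()):
    """Expected bite length (mm) at kinematics (g, jp); vectorized."""
    g = np.asarray(g, dtype=float)
    jp = np.asarray(jp, dtype=float)
    out = np.full(np.broadcast(g, jp).shape, params.baseline, dtype=float)
    for (cg, cj), amp, (sg, sj) in zip(
        params.centers, params.amplitudes, params.widths
    ):
        out = out + amp * np.exp(
            -0.5 * (((g - cg) / sg) ** 2 + ((jp - cj) / sj) ** 2)
        )
    return out if out.shape else float(out)


# species kinematic targets: mean and SD of (g, jp, ja, ttpg, rs)
# (mm, mm, degrees, ms, m/s); synthetic values chosen to straddle the
# two surface optima with hybrids spanning the valley
_DEFAULT_MEANS = {
    "generalist": {"g": 3.2, "jp": 3.0, "ja": 28.0, "ttpg": 6.0, "rs": 0.6},
    "molluscivore": {"g": 2.8, "jp": 2.6, "ja": 25.0, "ttpg": 5.5, "rs": 0.5},
    "scale_eater": {"g": 5.5, "jp": 7.5, "ja": 35.0, "ttpg": 8.0, "rs": 0.9},
    "hybrid": {"g": 4.2, "jp": 5.0, "ja": 30.0, "ttpg": 7.0, "rs": 0.7},
}
_DEFAULT_SDS = {
    "generalist": {"g": 0.55, "jp": 0.55, "ja": 4.0, "ttpg": 1.5, "rs": 0.18},
    "molluscivore": {"g": 0.5, "jp": 0.5, "ja": 4.0, "ttpg": 1.5, "rs": 0.15},
    "scale_eater": {"g": 0.7, "jp": 0.8, "ja": 5.0, "ttpg": 2.0, "rs": 0.25},
    "hybrid": {"g": 0.9, "jp": 1.1, "ja": 5.0, "ttpg": 2.0, "rs": 0.2},
}


@dataclass
class GeneratorConfig:
    n_individuals: int = 5  # per species group
    strikes_per_individual: int = 8  # filming sessions capped at 16
    species: tuple = SPECIES
    kinematic_means: dict = field(default_factory=lambda: dict(_DEFAULT_MEANS))
    kinematic_sds: dict = field(default_factory=lambda: dict(_DEFAULT_SDS))
    g_jp_corr: float = 0.4
    between_individual_sd_kin: float = 0.3  # mm, shifts g and jp per fish
    between_individual_sd_bite: float = 0.3  # mm, bite-length intercept
    landmark_jitter_px: float = 5.0
    dropout_rate: float = 0.01
    px_per_mm: float = 10.0
    frame_rate: float = 1100.0
    strike_type_probs: dict = field(
        default_factory=lambda: {"edge": 0.55, "corner": 0.15, "scrape": 0.15, "miss": 0.15}
    )
    surface: SurfaceParams = field(default_factory=SurfaceParams)
    species_length_offsets: dict = field(
        default_factory=lambda: {
            "generalist": 0.0,
            "molluscivore": -0.2,
            "scale_eater": 0.5,
            "hybrid": 0.0,
        }
    )
    strike_type_length_offsets: dict = field(
        default_factory=lambda: {"edge": 0.0, "corner": -0.3, "scrape": -1.0, "miss": 0.0}
    )
    bite_noise_sd: float = 0.5  # mm, on length
    dim_noise_sd: float = 0.15  # mm, on width and depth
    scrape_depth_factor: float = 0.4

    def __post_init__(self):
        if self.strikes_per_individual < 1 or self.strikes_per_individual > 16:
            raise ValidationError("strikes_per_individual must be in 1..16")
        probs = self.strike_type_probs
        if set(probs) - set(STRIKE_TYPES):
            raise ValidationError(f"unknown strike types in probs: {probs}")
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValidationError("strike_type_probs must sum to 1")
        for sd in (
            self.between_individual_sd_kin,
            self.between_individual_sd_bite,
            self.landmark_jitter_px,
            self.bite_noise_sd,
            self.dim_noise_sd,
        ):
            if sd < 0:
                raise ValidationError("all SDs must be nonnegative")
        if not (0 <= self.dropout_rate < 1):
            raise ValidationError("dropout_rate must be in [0, 1)")
        if self.px_per_mm <= 0 or self.frame_rate <= 0:
            raise ValidationError("px_per_mm and frame_rate must be positive")
        # protrusion > 6.5 mm is the scale-eater regime in this system
        if "scale_eater" in self.kinematic_means:
            if self.kinematic_means["scale_eater"]["jp"] <= 6.5:
                raise ValidationError("scale_eater mean jp must exceed 6.5 mm")
        for sp in ("generalist", "molluscivore"):
            if sp in self.kinematic_means and self.kinematic_means[sp]["jp"] > 6.5:
                raise ValidationError(f"{sp} mean jp must be below 6.5 mm")


@dataclass
class SyntheticDataset:
    tracks: list
    bites: list
    ground_truth: pd.DataFrame
    config: GeneratorConfig


def sample_kinematics(
    config: GeneratorConfig, species: str, n: int, rng, indiv_offset: float = 0.0
) -> pd.DataFrame:
    """Draw n strike-level kinematic targets for one individual.

    (g, jp) are correlated Gaussian; remaining variables independent.
    Values are clipped to feasible ranges and TTPG is snapped to a whole
    number of frames (timing is counted in frames downstream).
    """
    mu = config.kinematic_means[species]
    sd = config.kinematic_sds[species]
    cov = np.diag([sd[v] ** 2 for v in KIN_VARS])
    cov[0, 1] = cov[1, 0] = config.g_jp_corr * sd["g"] * sd["jp"]
    draw = rng.multivariate_normal(
        [mu[v] for v in KIN_VARS], cov, size=n, method="cholesky"
    )
    df = pd.DataFrame(draw, columns=list(KIN_VARS))
    df["g"] = np.clip(df["g"] + indiv_offset, 0.8, None)
    df["jp"] = np.clip(df["jp"] + indiv_offset, 1.2, None)
    df["ja"] = np.clip(df["ja"], 8.0, 75.0)
    mpf = 1000.0 / config.frame_rate
    n_frames = np.clip(np.round(df["ttpg"] / mpf), 2, None)
    df["ttpg"] = n_frames * mpf
    df["rs"] = np.clip(df["rs"], 0.1, None)
    return df


def _sample_plan(config: GeneratorConfig, rng) -> pd.DataFrame:
    """Strike-level ground truth: kinematic targets and bite dimensions."""
    types = list(config.strike_type_probs)
    type_p = np.array([config.strike_type_probs[t] for t in types])
    rows = []
    for species in config.species:
        for i in range(config.n_individuals):
            indiv = f"{species[:3]}_{i:02d}"
            kin_off = rng.normal(0, config.between_individual_sd_kin)
            bite_int = rng.normal(0, config.between_individual_sd_bite)
            kin = sample_kinematics(
                config, species, config.strikes_per_individual, rng, kin_off
            )
            for s in range(config.strikes_per_individual):
                st = types[rng.choice(len(types), p=type_p)]
                row = kin.iloc[s].to_dict()
                g, jp = row["g"], row["jp"]
                exp_len = (
                    true_performance(g, jp, config.surface)
                    + config.species_length_offsets[species]
                    + config.strike_type_length_offsets[st]
                    + bite_int
                )
                if st == "miss":
                    length = width = depth = 0.0
                else:
                    length = max(0.0, exp_len + rng.normal(0, config.bite_noise_sd))
                    width = max(0.0, 1.8 + 0.25 * g + rng.normal(0, config.dim_noise_sd))
                    depth = max(0.0, 1.3 + 0.05 * g + rng.normal(0, config.dim_noise_sd))
                    if st == "scrape":
                        depth *= config.scrape_depth_factor
                rows.append(
                    {
                        "strike_id": f"{indiv}_s{s:02d}",
                        "individual_id": indiv,
                        "species": species,
                        "strike_type": st,
                        **row,
                        "individual_intercept": bite_int,
                        "individual_kin_offset": kin_off,
                        "expected_length_mm": float(exp_len),
                        "length_mm": length,
                        "width_mm": width,
                        "depth_mm": depth,
                    }
                )
    return pd.DataFrame(rows)


def _rot(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3 - 2 * u)


# fixed head geometry (mm, image coords: +x anterior, +y ventral)
_QUADRATE_OFFSET = np.array([-2.0, 2.5])  # from pupil
_PROT_DIR = np.array([np.cos(np.radians(10.0)), np.sin(np.radians(10.0))])
_REST_PROTRUSION = 0.8
_GAPE_DIR = np.array([np.sin(np.radians(18.0)), np.cos(np.radians(18.0))])
_PREOPERCLE_LEN = 2.2
_PRE_FRAMES = 15
_HOLD_FRAMES = 25
_RETREAT_FRAMES = 10
# strict per-frame decay on the held peak so argmax/threshold crossings
# are unambiguous after the pixel round trip (values ~1e9 x float eps)
_PLATEAU_DECAY = 1e-5


def simulate_strike(
    row: dict, config: GeneratorConfig, rng
) -> tuple[StrikeTrack, dict]:
    """Render one strike's landmark track from its kinematic targets.

    Returns the pixel-space track (with jitter/dropout applied) and the
    realized noiseless kinematics.
    """
    mpf = 1000.0 / config.frame_rate
    g, jp, ja, ttpg, rs = (row[v] for v in KIN_VARS)
    n_ttpg = int(round(ttpg / mpf))
    if n_ttpg < 1:
        raise ValidationError("TTPG shorter than one frame")
    t_on = _PRE_FRAMES
    t_peak = t_on + n_ttpg
    t_impact = t_peak + _HOLD_FRAMES
    n_frames = t_impact + _RETREAT_FRAMES + 1
    t = np.arange(n_frames)

    # gape profile: below 20% of peak before onset, smoothstep rise whose
    # first frame sits strictly above the 20% threshold, peak held until
    # impact with a tiny strict decay, relaxation afterwards
    gape = np.empty(n_frames)
    pre = t < t_on
    # jaws essentially closed before the strike, with a slight drift
    gape[pre] = g * (0.06 + 0.03 * t[pre] / t_on)
    rise = (t >= t_on) & (t <= t_peak)
    u = (t[rise] - t_on + 1.0) / (n_ttpg + 1.0)
    gape[rise] = g * (0.2 + 0.8 * _smoothstep(u))
    hold = (t > t_peak) & (t <= t_impact)
    gape[hold] = g * (1.0 - _PLATEAU_DECAY * (t[hold] - t_peak))
    post = t > t_impact
    gape[post] = g * (1 - 0.5 * (t[post] - t_impact) / _RETREAT_FRAMES)

    prot = np.empty(n_frames)
    prot[pre] = _REST_PROTRUSION
    prot[rise] = _REST_PROTRUSION + (jp - _REST_PROTRUSION) * _smoothstep(u)
    prot[hold] = jp * (1.0 - _PLATEAU_DECAY * (t[hold] - t_peak))
    prot[post] = jp - 0.3 * (jp - _REST_PROTRUSION) * (t[post] - t_impact) / _RETREAT_FRAMES

    # logistic approach; scale total travel so displacement between
    # onset and peak equals rs * TTPG (mm)
    tm = 0.5 * (t_on + t_peak)
    rate = 4.0 / n_ttpg
    s_raw = 1.0 / (1.0 + np.exp(-rate * (np.minimum(t, t_impact) - tm)))
    s = (s_raw - s_raw[0]) / (s_raw[t_impact] - s_raw[0])
    ttpg_ms = n_ttpg * mpf
    d_window = s[t_peak] - s[t_on]
    travel = rs * ttpg_ms / d_window
    start = np.array([6.0, 6.0]) + rng.uniform(-0.5, 0.5, size=2)
    pupil = start + np.outer(travel * s, np.array([1.0, 0.0]))
    pupil[post] -= np.outer(0.15 * (t[post] - t_impact), np.array([1.0, 0.0]))

    premax = pupil + np.outer(prot, _PROT_DIR)
    quadrate = pupil + _QUADRATE_OFFSET
    dentary = premax + np.outer(gape, _GAPE_DIR)

    # place the preopercle so the jaw angle at peak gape equals ja
    u_pk = dentary[t_peak] - quadrate[t_peak]
    u_pk = u_pk / np.linalg.norm(u_pk)
    preop_offset = _PREOPERCLE_LEN * (_rot(np.radians(ja)) @ u_pk)
    preop = quadrate + preop_offset

    coords_mm = np.stack([premax, dentary, pupil, quadrate, preop], axis=1)

    # realized noiseless kinematics (jaw angle min over onset..peak)
    u = dentary - quadrate
    v = preop - quadrate
    cosang = (u * v).sum(axis=1) / (
        np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
    )
    ja_series = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
    realized = {
        "g": g,
        "jp": jp,
        "ja": float(ja_series[t_on : t_peak + 1].min()),
        "ttpg": ttpg_ms,
        "rs": rs,
        "onset_frame": t_on,
        "peak_gape_frame": t_peak,
        "impact_frame": t_impact,
    }

    coords_px = coords_mm * config.px_per_mm
    if config.landmark_jitter_px > 0:
        coords_px = coords_px + rng.normal(
            0, config.landmark_jitter_px, size=coords_px.shape
        )
    confidence = np.ones((n_frames, 5))
    if config.dropout_rate > 0:
        drop = rng.random((n_frames, 5)) < config.dropout_rate
        confidence[drop] = 0.0

    track = StrikeTrack(
        strike_id=row["strike_id"],
        individual_id=row["individual_id"],
        species=row["species"],
        frame_rate=config.frame_rate,
        coords=coords_px,
        confidence=confidence,
        units="px",
        strike_type=row["strike_type"],
    )
    return track, realized


def generate_dataset(
    config: GeneratorConfig | None = None,
    seed: int = 0,
    out_dir=None,
    render_tracks: bool = True,
) -> SyntheticDataset:
    """Generate a full synthetic study: tracks, bite table, ground truth.

    Randomness comes from ``numpy.random.default_rng(seed)`` (PCG64), so
    a fixed seed reproduces the dataset bit-for-bit across runs.  With
    ``render_tracks=False`` only the strike-level table is produced
    (useful for statistics-only simulations).  With ``out_dir`` set, the
    HDF5 tracks, bite CSV, and ground-truth CSV are written there.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    plan = _sample_plan(config, rng)

    tracks = []
    if render_tracks:
        realized_rows = []
        for _, row in plan.iterrows():
            track, realized = simulate_strike(row.to_dict(), config, rng)
            tracks.append(track)
            realized_rows.append(realized)
        realized_df = pd.DataFrame(realized_rows)
        for col in ("ja",):  # ja is realized from geometry, not the raw draw
            plan[col] = realized_df[col].to_numpy()
        for col in ("onset_frame", "peak_gape_frame", "impact_frame"):
            plan[col] = realized_df[col].to_numpy()

    bites = [
        BiteRecord(
            strike_id=r.strike_id,
            individual_id=r.individual_id,
            species=r.species,
            strike_type=r.strike_type,
            length_mm=r.length_mm,
            width_mm=r.width_mm,
            depth_mm=r.depth_mm,
        )
        for r in plan.itertuples()
    ]

    ds = SyntheticDataset(tracks=tracks, bites=bites, ground_truth=plan, config=config)
    if out_dir is not None:
        out = Path(out_dir)
        (out / "tracks").mkdir(parents=True, exist_ok=True)
        for track in tracks:
            write_track(out / "tracks" / f"{track.strike_id}.h5", track)
        save_bite_table(out / "bites.csv", bites)
        plan.to_csv(out / "ground_truth.csv", index=False)
    return ds


def kinematic_table(ds: SyntheticDataset) -> pd.DataFrame:
    """Ground-truth kinematics joined with bite dimensions (no extraction)."""
    df = ds.ground_truth.copy()
    df["volume_mm3"] = df["length_mm"] * df["width_mm"] * df["depth_mm"]
    return df[
        [
            "strike_id",
            "individual_id",
            "species",
            "strike_type",
            *KIN_VARS,
            "length_mm",
            "width_mm",
            "depth_mm",
            "volume_mm3",
        ]
    ]


def merge_kinematics_bites(kin: pd.DataFrame, bites: pd.DataFrame) -> pd.DataFrame:
    """Join an extracted kinematics table with a bite table on strike_id."""
    if not isinstance(bites, pd.DataFrame):
        bites = bite_table_frame(bites)
    bite_cols = ["strike_id", "length_mm", "width_mm", "depth_mm", "volume_mm3"]
    return kin.merge(bites[bite_cols], on="strike_id", how="inner")
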