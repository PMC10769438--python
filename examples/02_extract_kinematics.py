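"""Extract the five kinematic variables from landmark tracks.

Tracks are calibrated from pixels to millimetres with the session's
ruler scale, short detector dropouts are bridged, coordinates are
smoothed (21-frame moving average), and each strike is summarized inside
its window from strike start to gel impact.
"""

from bitescape import (
    CalibrationScale,
    GeneratorConfig,
    calibrate_track,
    generate_dataset,
    summarize_dataset,
)

config = GeneratorConfig()
ds = generate_dataset(config, seed=1)
scale = CalibrationScale(px_per_mm=config.px_per_mm)

kin = summarize_dataset(
    (calibrate_track(t, scale) for t in ds.tracks), smooth_window=21
)
print(f"extracted {len(kin)} strikes; columns: {list(kin.columns)}")
print("\nper-species means (g/jp in mm, ja in degrees, ttpg in ms, rs in m/s):")
print(kin.groupby("species")[["g", "jp", "ja", "ttpg", "rs"]].mean().round(2))

# how close is extraction to the generator's truth under 5 px jitter?
m = kin.merge(
    ds.ground_truth[["strike_id", "g", "jp"]], on="strike_id", suffixes=("_rec", "_true")
)
print(
    f"\npeak gape recovery: bias {(m.g_rec - m.g_true).mean():+.3f} mm, "
    f"SD {(m.g_rec - m.g_true).std():.3f} mm"
)
# A bias well under 0.1 mm means the noisy-landmark estimator is close to
# unbiased at the detector's 5-pixel error level.
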