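"""Synthetic validation cohorts with known generative ground truth.

Emulates the design of a two-observer repeatability study: each subject is
measured three times by each of two independent observers (six scan pairs
per subject), with the observers' camera placement jittered around the
nominal rig and sensor noise applied, while reference body volume (three
replicate measurements), reference fat mass and the camera system's raw
volume are drawn from a documented generative rule so that every
downstream estimate can be checked against the rule that produced it.

Generative rule (per subject i):
  * sex balanced; age ~ N(28, 6) clipped to [20, 42]
  * height ~ N(1.65, 0.08) m, weight ~ N(67.5, 12.2) kg (clipped to sane
    adult ranges); physical activity: ~45 % sedentary (< 150 min/week)
  * true BV_i = weight_i / density_i with density ~ N(1.035, 0.015) kg/L
  * the phantom is the humanoid preset scaled uniformly so its ground-truth
    volume equals BV_i (volume scales exactly with the cube of the factor)
  * reference replicates: BV_i + N(0, 0.05 L), three draws
  * reference FM: the fat-mass equation evaluated at (sex, PA, height,
    BV_i) plus N(0, 1.4 kg) measurement error
  * camera raw BV: 1.078 * BV_i + N(0, 0.9 L) — a multiplicative volume
    overestimate of the kind lateral in-filling produces, which the linear
    calibration must remove.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .camera import CameraModel, look_at
from .densitometry import predict_fat_mass
from .errors import InputError
from .phantoms import humanoid_phantom
from .pipeline import PipelineConfig
from .render import render_views
from .sceneio import write_scene

__all__ = ["make_fixture_cohort", "COHORT_COLUMNS"]

COHORT_COLUMNS = [
    "subject_id",
    "sex_code",
    "age_years",
    "height_m",
    "weight_kg",
    "pa_min_week",
    "bodpod_bv_l_1",
    "bodpod_bv_l_2",
    "bodpod_bv_l_3",
    "dxa_fm_kg",
    "kinect_raw_bv_l",
    "true_bv_l",
]

RAW_BV_SLOPE = 1.078
RAW_BV_NOISE_SD_L = 0.9
REPLICATE_NOISE_SD_L = 0.05
FM_NOISE_SD_KG = 1.4


def _jittered_rig(config: PipelineConfig, rng) -> tuple[CameraModel, CameraModel]:
    """Nominal rig with operator placement jitter (per observer/repeat)."""
    c = config.camera
    d = c["distance_m"] + rng.normal(0, 0.03)
    h = c["height_m"] + rng.normal(0, 0.02)
    yaw = rng.normal(0, np.deg2rad(1.0))
    front_eye = np.array([d * np.sin(yaw), h, -d * np.cos(yaw)])
    back_eye = np.array([-d * np.sin(yaw), h, d * np.cos(yaw)])
    target = np.array([0.0, h, 0.0])
    base_front, base_back = config.rig()
    front = dataclasses.replace(base_front, pose=look_at(front_eye, target))
    back = dataclasses.replace(base_back, pose=look_at(back_eye, target))
    return front, back


def make_fixture_cohort(
    n_subjects: int,
    seed: int,
    out_dir,
    config: PipelineConfig | None = None,
    observers: int = 2,
    repeats: int = 3,
    render: bool = True,
) -> tuple[pd.DataFrame, list]:
    """Generate a cohort CSV and (optionally) its rendered scene files.

    Returns ``(cohort_dataframe, scene_pair_stems)`` where the stems are
    ``out_dir/subjectID/obsO_repR`` with ``_anterior``/``_posterior`` views
    written next to them.  Identical ``(n_subjects, seed)`` give identical
    CSVs; all randomness flows from the single seed.
    """
    if n_subjects < 3:
        raise InputError("need at least 3 subjects")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = config or PipelineConfig()
    rng = np.random.default_rng([int(seed), 0xC0F0])

    base = humanoid_phantom(voxel_resolution_m=0.004)
    rows = []
    stems = []
    for i in range(n_subjects):
        sex = 1 if i % 2 == 0 else 2
        height = float(np.clip(rng.normal(1.65, 0.08), 1.45, 1.90))
        weight = float(np.clip(rng.normal(67.5, 12.2), 45.0, 115.0))
        age = float(np.clip(rng.normal(28.3, 6.0), 20.0, 42.0))
        sedentary = rng.random() < 0.45
        pa = float(rng.uniform(0, 140)) if sedentary else float(rng.uniform(150, 600))
        density = float(np.clip(rng.normal(1.035, 0.015), 0.99, 1.09))
        true_bv = weight / density

        scale = (true_bv / base.reference_volume_liters) ** (1.0 / 3.0)
        phantom = base.scaled(scale, label=f"subject{i:02d}")

        reps = true_bv + rng.normal(0, REPLICATE_NOISE_SD_L, size=3)
        fm_true = predict_fat_mass(
            None, true_bv, sex_code=sex, pa_min_week=pa, height_m=height
        ).fm_kg
        dxa_fm = fm_true + float(rng.normal(0, FM_NOISE_SD_KG))
        raw_bv = RAW_BV_SLOPE * true_bv + float(rng.normal(0, RAW_BV_NOISE_SD_L))

        rows.append(
            {
                "subject_id": f"S{i:03d}",
                "sex_code": sex,
                "age_years": round(age, 1),
                "height_m": round(height, 4),
                "weight_kg": round(weight, 2),
                "pa_min_week": round(pa, 1),
                "bodpod_bv_l_1": round(float(reps[0]), 4),
                "bodpod_bv_l_2": round(float(reps[1]), 4),
                "bodpod_bv_l_3": round(float(reps[2]), 4),
                "dxa_fm_kg": round(dxa_fm, 3),
                "kinect_raw_bv_l": round(raw_bv, 4),
                "true_bv_l": round(true_bv, 6),
            }
        )

        if render:
            for o in range(1, observers + 1):
                for r in range(1, repeats + 1):
                    sub_rng = np.random.default_rng([int(seed), i, o, r])
                    front, back = _jittered_rig(config, sub_rng)
                    scene_seed = int(
                        np.random.default_rng([int(seed), i, o, r, 1]).integers(2**31)
                    )
                    ant, post = render_views(
                        phantom,
                        front,
                        back,
                        platform_height_m=config.platform_height_m,
                        seed=scene_seed,
                    )
                    stem = out_dir / f"S{i:03d}" / f"obs{o}_rep{r}"
                    write_scene(ant, f"{stem}_anterior")
                    write_scene(post, f"{stem}_posterior")
                    stems.append(str(stem))

    df = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    df.to_csv(out_dir / "cohort.csv", index=False)
    return df, stems
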