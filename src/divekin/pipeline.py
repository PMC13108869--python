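"""End-to-end convenience: native diary -> model-ready dive feature table."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import behavior as bh
from . import dives as dv
from . import features as ft
from . import fluke as fl
from . import signal as sg
from .io import BehaviorEvent, DiarySeries, resample_diary

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    diary: DiarySeries                 # working-rate diary
    orientation: sg.OrientationSeries
    kinematics: sg.KinematicSeries
    dives: list
    strokes: fl.FlukeStrokeSet
    stroke_table: pd.DataFrame
    labels: pd.DataFrame | None
    features: pd.DataFrame
    speed: sg.SpeedResult | None


def run_pipeline(
    diary_native: DiarySeries,
    events: list[BehaviorEvent] | None = None,
    fs_working: float = 10.0,
    rules: dv.DiveRules | None = None,
    speed_cfg: sg.SpeedConfig | None = None,
    amplitude_gate: float = 5.0,
) -> PipelineResult:
    """Run downsampling, filtering, segmentation, stroke detection, behavior
    labeling and feature extraction in the standard order.

    Speed calibration needs steep-pitch samples; if the deployment has none
    (all-horizontal swimming) speed stays missing and speed-based features
    are NaN rather than failing the whole pipeline.
    """
    diary = resample_diary(diary_native, fs_working)

    static, _ = sg.static_dynamic_split(diary.accel, diary.fs)
    mag_static = sg.butterworth_zero_lag(diary.mag, diary.fs, "lowpass")
    orient = sg.compute_orientation(static, mag_static, diary.t, diary.fs)

    speed = None
    try:
        speed = sg.estimate_speed(
            diary_native.accel, diary_native.fs, diary.depth, orient.pitch,
            diary.fs, speed_cfg,
        )
    except sg.CalibrationError:
        pass
    kin = sg.compute_kinematics(diary, orient, speed)

    dives = dv.detect_dives(diary.depth, t=diary.t, rules=rules,
                            deployment_id=diary.deployment_id)
    for d in dives:
        dv.segment_phases(d, diary.depth, diary.t, rules)
        dv.classify_shape(d)

    strokes = fl.detect_fluke_strokes(
        kin.gyro_y_band, diary.depth, t=diary.t,
        amplitude_gate=amplitude_gate, deployment_id=diary.deployment_id,
    )
    stroke_table = fl.per_stroke_frequency(strokes)

    labels = bh.label_table(dives, events) if events is not None else None
    features = ft.feature_table(
        dives, kin, orient, strokes, depth=diary.depth, labels=labels,
        start_time_utc=diary.start_time_utc,
    )
    return PipelineResult(
        diary=diary, orientation=orient, kinematics=kin, dives=dives,
        strokes=strokes, stroke_table=stroke_table, labels=labels,
        features=features, speed=speed,
    )
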