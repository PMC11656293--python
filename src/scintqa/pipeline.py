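"""End-to-end orchestration: simulate, measure, calibrate and verify.

These functions chain the stages the way a physicist would run the physical
device: a calibration grid irradiation (recorded twice, at a high and a low
spot intensity, to span the pulse-intensity range) trains the polynomial
maps; a verification irradiation is then measured, its pulses calibrated and
regrouped into pencil beams, and the delivery is checked against the plan
with 3-sigma confidence intervals.

The default problem sizes are scaled-down versions of a clinical session (a
few hundred spots, half-resolution sensor) so a full run completes in
minutes on one CPU; every stage accepts the full-size geometry unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import calibrate as cal
from . import verify as ver
from .localize import extract_features_stack
from .preprocess import DarkModel, preprocess_stack
from .reconstruct import ReconstructedPB, reconstruct_all
from .simulate import (
    DeliveryConfig,
    GeometryConfig,
    Misalignment,
    SpotPlan,
    deliver,
    make_calibration_plan,
    render,
)

__all__ = [
    "Measurement",
    "measure_delivery",
    "run_calibration",
    "full_run",
    "PRESETS",
]


@dataclass
class Measurement:
    """Everything measured from one simulated irradiation."""

    plan: SpotPlan
    log: list
    features: list
    pairs: list
    pulses: pd.DataFrame  # calibrated pulses (or raw features if no model)
    pbs: list[ReconstructedPB] = field(default_factory=list)
    dark: DarkModel | None = None
    n_frames: int = 0


def measure_delivery(
    plan: SpotPlan,
    geom: GeometryConfig,
    cfg: DeliveryConfig,
    model: cal.CalibrationModel | None = None,
    table_misalignment: Misalignment | None = None,
    kernel_sd: float = 6.0,
    kernel_sd_px_mm: bool = True,
    sync_tolerance: float = 0.4,
) -> Measurement:
    """Simulate, acquire, preprocess, localize and (optionally) calibrate one
    delivery.

    ``table_misalignment`` displaces the scene seen by the camera while the
    log stays nominal — the signature of a table positioning error.  The
    localization kernel sd is given in full-resolution pixels and rescaled
    with the sensor so the kernel's physical footprint is resolution
    independent.
    """
    geom_use = replace(geom, range_shifter_wet_cm=plan.range_shifter_wet_cm)
    log = deliver(plan, cfg)
    stack = render(log, geom_use, cfg, mis=table_misalignment)
    cleaned, manifest, dark = preprocess_stack(stack, geom_use)
    ksd = kernel_sd
    if kernel_sd_px_mm:
        # keep the kernel's footprint fixed in mm across sensor scales
        ksd = kernel_sd * geom_use.direct_view_pixels / 230.0
    features = extract_features_stack(cleaned, kernel_sd=max(ksd, 1.0), dark_sd=dark.sd)
    pairs, unmatched_f, unmatched_l = cal.synchronize(
        features, log, tolerance=sync_tolerance
    )
    if model is not None:
        pulses = cal.apply_model(model, [p.features for p in pairs],
                                 warn_extrapolation=False)
        pulses["pb_id"] = [p.pulse.pb_id for p in pairs]
        pbs = reconstruct_all(pulses)
    else:
        pulses = pd.DataFrame(
            [
                (p.features.timestamp, p.features.i_Dc, p.features.j_Dc,
                 p.features.j_Mc, p.features.PI_Dmax, p.pulse.pb_id)
                for p in pairs
            ],
            columns=["timestamp", "i_Dc", "j_Dc", "j_Mc", "PI_Dmax", "pb_id"],
        )
        pbs = []
    return Measurement(
        plan=plan, log=log, features=features, pairs=pairs,
        pulses=pulses, pbs=pbs, dark=dark, n_frames=len(stack),
    )


def run_calibration(
    geom: GeometryConfig,
    seed: int = 0,
    n_layers: int = 7,
    spots_per_side: int = 5,
    extent: float = 40.0,
    energy_range: tuple[float, float] = (121.0, 156.0),
    intensities: tuple[float, float] = (1.0, 0.1),
    f_max_power: int = 5,
    g_max_power: int = 4,
    delivery: DeliveryConfig | None = None,
) -> cal.CalibrationModel:
    """Train the calibration maps on a grid irradiation recorded at two spot
    intensities (pooled into one fit), mirroring the physical procedure."""
    pairs = []
    for k, intensity in enumerate(intensities):
        plan = make_calibration_plan(
            n_layers, spots_per_side, extent, energy_range,
            intensity=intensity, name=f"cal-{intensity}MU",
        )
        cfg = delivery or DeliveryConfig()
        cfg = replace(cfg, rng_seed=int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % 2**31))
        meas = measure_delivery(plan, geom, cfg)
        pairs.extend(meas.pairs)
    return cal.fit_all(pairs, rng_seed=seed,
                       f_max_power=f_max_power, g_max_power=g_max_power)


PRESETS: dict[str, Misalignment] = {
    "nominal": Misalignment(),
    "rotate1deg": Misalignment(rotation_deg=1.0),
    "pitch1deg": Misalignment(pitch_deg=1.0),
    "translate2mm": Misalignment(translation=(0.0, 2.0, 0.0)),
}


def full_run(
    preset: str = "nominal",
    seed: int = 0,
    geom: GeometryConfig | None = None,
    scale: float = 0.5,
    model: cal.CalibrationModel | None = None,
    ci: ver.ConfidenceIntervals | None = None,
    verification_plan: SpotPlan | None = None,
    joint_threshold: float = 0.95,
    calibration_kwargs: dict | None = None,
) -> tuple[ver.QAReport, cal.CalibrationModel, Measurement]:
    """Run the complete QA chain on synthetic data for one delivery preset.

    Calibrates (unless a model is given), measures a verification grid
    delivered with the preset's table misalignment, reconstructs the pencil
    beams and verifies them against the plan.  When no confidence intervals
    are supplied they are derived from a nominal delivery of the same plan
    (the reference irradiation set).
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    geom = (geom or GeometryConfig()).scaled(scale) if scale != 1.0 else (
        geom or GeometryConfig()
    )
    if model is None:
        model = run_calibration(geom, seed=seed, **(calibration_kwargs or {}))
    if verification_plan is None:
        verification_plan = make_calibration_plan(
            5, 6, 30.0, (122.0, 154.0), intensity=0.3, name="verification-grid"
        )
    base_cfg = DeliveryConfig()

    def run_one(mis: Misalignment, sub_seed: int) -> Measurement:
        cfg = replace(base_cfg, rng_seed=int(
            np.random.SeedSequence([seed, 100 + sub_seed]).generate_state(1)[0] % 2**31
        ))
        return measure_delivery(
            verification_plan, geom, cfg, model=model, table_misalignment=mis
        )

    if ci is None:
        nominal = run_one(Misalignment(), 0)
        d_nom = ver.discrepancies(nominal.pbs, verification_plan, level="pb")
        ci = ver.confidence_intervals(d_nom)
        meas = nominal if preset == "nominal" else run_one(PRESETS[preset], 1)
    else:
        meas = run_one(PRESETS[preset], 1)

    report = ver.verify_delivery(
        verification_plan, meas.pbs, ci, joint_threshold=joint_threshold,
        parameters={
            "preset": preset, "seed": seed, "scale": scale,
            "n_frames": meas.n_frames,
            "n_pulses": len(meas.pairs),
            "geometry_hash": geom.hash(),
        },
    )
    return report, model, meas
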