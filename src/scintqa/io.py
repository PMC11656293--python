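"""Readers and writers for the plan, log-file, frame-stack, calibration-model
and report formats.

Formats
-------
Spot plan (``.pld``-like text)::

    PLAN <name> <range_shifter_wet_cm>
    LAYER <E_MeV> <n_spots>
    <spot_id> <X_mm> <Y_mm> <I_MU>
    ...

Log-file: CSV with columns
``timestamp_ms,X_mm,Y_mm,E_MeV,I_MU,pb_id,layer_index,scan_index``.

Frame stack: multi-page 16-bit grayscale TIFF plus a ``.json`` sidecar holding
timestamps, exposure and geometry metadata.

Calibration model and QA report: JSON (numbers survive round-trip exactly:
Python's JSON writer emits shortest-repr floats).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .simulate import FrameStack, Layer, PulseRecord, Spot, SpotPlan

__all__ = [
    "PlanFormatError",
    "LogFormatError",
    "read_plan",
    "write_plan",
    "read_logfile",
    "write_logfile",
    "read_frames",
    "write_frames",
    "write_report",
    "read_report",
]

LOG_COLUMNS = [
    "timestamp_ms", "X_mm", "Y_mm", "E_MeV", "I_MU",
    "pb_id", "layer_index", "scan_index",
]


class PlanFormatError(ValueError):
    """Malformed spot-plan file; message carries the offending line number."""


class LogFormatError(ValueError):
    """Malformed or inconsistent log-file."""


# ---------------------------------------------------------------------------
# spot plan
# ---------------------------------------------------------------------------

def write_plan(plan: SpotPlan, path: str | Path) -> None:
    plan.validate()
    lines = [f"PLAN {plan.name} {plan.range_shifter_wet_cm!r}"]
    by_id = {s.spot_id: s for s in plan.spots}
    for layer in plan.layers:
        lines.append(f"LAYER {layer.E!r} {len(layer.spot_ids)}")
        for sid in layer.spot_ids:
            s = by_id[sid]
            lines.append(f"{s.spot_id} {s.X!r} {s.Y!r} {s.I!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_plan(path: str | Path) -> SpotPlan:
    text = Path(path).read_text().splitlines()
    rows = [(i + 1, ln.strip()) for i, ln in enumerate(text) if ln.strip()]
    if not rows or not rows[0][1].startswith("PLAN"):
        raise PlanFormatError("line 1: expected 'PLAN <name> <wet_cm>' header")
    head = rows[0][1].split()
    if len(head) != 3:
        raise PlanFormatError("line 1: malformed PLAN header")
    try:
        wet = float(head[2])
    except ValueError as exc:
        raise PlanFormatError("line 1: non-numeric range-shifter WET") from exc

    spots: list[Spot] = []
    layers: list[Layer] = []
    seen: set[int] = set()
    i = 1
    while i < len(rows):
        lineno, ln = rows[i]
        parts = ln.split()
        if parts[0] != "LAYER":
            raise PlanFormatError(f"line {lineno}: expected LAYER block")
        try:
            E = float(parts[1])
            n = int(parts[2])
        except (IndexError, ValueError) as exc:
            raise PlanFormatError(f"line {lineno}: malformed LAYER line") from exc
        if n < 1:
            raise PlanFormatError(f"line {lineno}: empty layer block")
        ids: list[int] = []
        for k in range(n):
            if i + 1 + k >= len(rows):
                raise PlanFormatError(f"line {lineno}: layer truncated")
            sl, sline = rows[i + 1 + k]
            sp = sline.split()
            try:
                sid = int(sp[0])
                x, y, intensity = float(sp[1]), float(sp[2]), float(sp[3])
            except (IndexError, ValueError) as exc:
                raise PlanFormatError(f"line {sl}: non-numeric spot field") from exc
            if sid in seen:
                raise PlanFormatError(f"line {sl}: duplicate spot_id {sid}")
            seen.add(sid)
            spots.append(Spot(sid, x, y, E, intensity))
            ids.append(sid)
        layers.append(Layer(E, tuple(ids)))
        i += 1 + n
    plan = SpotPlan(head[1], wet, spots, layers)
    try:
        plan.validate()
    except ValueError as exc:
        raise PlanFormatError(str(exc)) from exc
    return plan


# ---------------------------------------------------------------------------
# machine log-file
# ---------------------------------------------------------------------------

def pulses_to_frame(pulses: list[PulseRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (p.timestamp, p.X, p.Y, p.E, p.I, p.pb_id, p.layer_index, p.scan_index)
            for p in pulses
        ],
        columns=LOG_COLUMNS,
    )


def write_logfile(pulses: list[PulseRecord], path: str | Path) -> None:
    """Write the per-pulse machine log as CSV (header always present)."""
    df = pulses_to_frame(pulses)
    df.to_csv(path, index=False)  # pandas writes shortest round-trip floats


def read_logfile(path: str | Path) -> list[PulseRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise LogFormatError(f"log-file missing columns: {missing}")
    ts = df["timestamp_ms"].to_numpy()
    if len(ts) > 1 and not np.all(np.diff(ts) > 0):
        bad = int(np.argmin(np.diff(ts))) + 1
        raise LogFormatError(f"timestamp regression at data row {bad}")
    return [
        PulseRecord(
            timestamp=float(r.timestamp_ms), X=float(r.X_mm), Y=float(r.Y_mm),
            E=float(r.E_MeV), I=float(r.I_MU), pb_id=int(r.pb_id),
            layer_index=int(r.layer_index), scan_index=int(r.scan_index),
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# frame stacks
# ---------------------------------------------------------------------------

def write_frames(stack: FrameStack, path: str | Path) -> None:
    """Multi-page 16-bit TIFF + JSON sidecar (timestamps and metadata)."""
    path = Path(path)
    tifffile.imwrite(path, stack.pixels, photometric="minisblack")
    sidecar = {
        "timestamps_ms": [float(t) for t in stack.timestamps],
        "exposure_us": stack.exposure_us,
        "frequency_hz": stack.frequency_hz,
        "metadata": stack.metadata,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_frames(path: str | Path) -> FrameStack:
    path = Path(path)
    pixels = tifffile.imread(path)
    if pixels.ndim == 2:
        pixels = pixels[None]
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return FrameStack(
        pixels=pixels,
        timestamps=np.asarray(sidecar["timestamps_ms"], dtype=float),
        exposure_us=sidecar["exposure_us"],
        frequency_hz=sidecar["frequency_hz"],
        metadata=sidecar.get("metadata", {}),
    )


# ---------------------------------------------------------------------------
# QA report
# ---------------------------------------------------------------------------

def write_report(report: "QAReport", path: str | Path) -> None:
    """Write a QA report as JSON; per-PB rows additionally as a CSV twin."""
    from .verify import QAReport  # local import to avoid a cycle

    assert isinstance(report, QAReport)
    path = Path(path)
    path.write_text(json.dumps(report.to_dict(), indent=1))
    if report.rows is not None:
        report.rows.to_csv(path.with_suffix(".csv"), index=False)


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
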