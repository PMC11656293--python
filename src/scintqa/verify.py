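"""QA verification: discrepancies, 3-sigma confidence intervals, in-CI
proportions and the delivery verdict.

Discrepancies are reference minus measured (reference = machine log on a
pulse-by-pulse basis, or the plan on a PB-by-PB basis).  Their pooled mean
and standard deviation define per-feature 3-sigma confidence intervals
(99.7% coverage for normal scatter); a delivery is verified by the fraction
of pencil beams falling inside every interval simultaneously.  A rigid table
misplacement pushes position discrepancies out of their interval, so the
joint proportion collapses and the report names the offending axis.

Reporting units: position in um, energy in keV, intensity in 1e-3 MU and in
percent of the planned PB intensity.  The intensity interval is taken on the
relative (percent) scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reconstruct import ReconstructedPB
from .simulate import SpotPlan

__all__ = [
    "DiscrepancySet",
    "ConfidenceIntervals",
    "QAReport",
    "discrepancies",
    "discrepancies_pulses",
    "confidence_intervals",
    "proportion_in_ci",
    "verify_delivery",
]

FEATURES = ("X", "Y", "E", "I")
REPORT_UNITS = {"X": "um", "Y": "um", "E": "keV", "I": "%"}
# internal (mm, MeV, relative) -> reporting scale
_SCALE = {"X": 1e3, "Y": 1e3, "E": 1e3, "I": 100.0}


@dataclass
class DiscrepancySet:
    """Per-item discrepancies dP = reference - measured, on the reporting
    scale (um / keV / percent for I; dI in 1e-3 MU carried alongside)."""

    table: pd.DataFrame  # columns: id, dX, dY, dE, dI (%), dI_mMU
    reference_kind: str  # "log" | "plan"
    level: str  # "pulse" | "pb"

    def __post_init__(self) -> None:
        vals = self.table[["dX", "dY", "dE", "dI"]].to_numpy()
        if not np.all(np.isfinite(vals)):
            raise ValueError("discrepancies must be finite")

    def __len__(self) -> int:
        return len(self.table)

    def values(self, feature: str) -> np.ndarray:
        return self.table[f"d{feature}"].to_numpy(dtype=float)

    def summary(self) -> pd.DataFrame:
        rows = []
        for f in FEATURES:
            v = self.values(f)
            rows.append((f, REPORT_UNITS[f], len(v), float(v.mean()),
                         float(v.std(ddof=1)) if len(v) > 1 else 0.0))
        out = pd.DataFrame(rows, columns=["feature", "unit", "n", "mean", "sd"])
        v = self.table["dI_mMU"].to_numpy(dtype=float)
        out.loc[len(out)] = ("I_abs", "1e-3 MU", len(v), float(v.mean()),
                             float(v.std(ddof=1)) if len(v) > 1 else 0.0)
        return out


@dataclass(frozen=True)
class ConfidenceIntervals:
    """Per-feature [mean - 3 sd, mean + 3 sd] tolerance bands."""

    intervals: dict  # feature -> (lo, hi)
    source: dict  # feature -> {n, mean, sd}
    degenerate: tuple[str, ...] = field(default_factory=tuple)

    def __getitem__(self, feature: str) -> tuple[float, float]:
        return self.intervals[feature]

    def to_dict(self) -> dict:
        return {
            "intervals": {k: list(v) for k, v in self.intervals.items()},
            "source": self.source,
            "degenerate": list(self.degenerate),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConfidenceIntervals":
        return cls(
            intervals={k: tuple(v) for k, v in d["intervals"].items()},
            source=d["source"],
            degenerate=tuple(d.get("degenerate", ())),
        )


@dataclass
class QAReport:
    """Per-PB verification rows plus the summary and proportion tables."""

    rows: pd.DataFrame
    summary: pd.DataFrame
    proportions: dict
    ci: ConfidenceIntervals
    verdict: str
    joint_threshold: float
    unplanned_pb_ids: list[int] = field(default_factory=list)
    missing_planned_pb_ids: list[int] = field(default_factory=list)
    offending_features: list[str] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "joint_threshold": self.joint_threshold,
            "proportions": self.proportions,
            "offending_features": self.offending_features,
            "unplanned_pb_ids": self.unplanned_pb_ids,
            "missing_planned_pb_ids": self.missing_planned_pb_ids,
            "ci": self.ci.to_dict(),
            "summary": self.summary.to_dict(orient="records"),
            "rows": self.rows.to_dict(orient="records"),
            "parameters": self.parameters,
        }


# ---------------------------------------------------------------------------
# discrepancies
# ---------------------------------------------------------------------------

def _diff_table(ref: pd.DataFrame, meas: pd.DataFrame, id_col: str) -> pd.DataFrame:
    merged = ref.merge(meas, on=id_col, suffixes=("_ref", "_meas"), how="inner")
    out = pd.DataFrame({"id": merged[id_col]})
    for f in ("X", "Y", "E"):
        out[f"d{f}"] = (merged[f"{f}_ref"] - merged[f"{f}_meas"]) * _SCALE[f]
    dI = merged["I_ref"] - merged["I_meas"]
    out["dI"] = dI / merged["I_ref"] * 100.0  # percent of planned/logged I
    out["dI_mMU"] = dI * 1e3
    return out


def discrepancies(
    measured: list[ReconstructedPB] | pd.DataFrame,
    reference: SpotPlan | list | pd.DataFrame,
    level: str = "pb",
) -> DiscrepancySet:
    """Element-wise reference-minus-measured discrepancies joined by pb_id.

    ``reference`` may be a SpotPlan (plan-level verification) or any table /
    record list with pb_id, X, Y, E, I (log-level).  Items present on one
    side only raise an error naming them.
    """
    meas_df = _as_frame(measured)
    ref_df = _as_frame(reference)
    only_meas = set(meas_df["pb_id"]) - set(ref_df["pb_id"])
    only_ref = set(ref_df["pb_id"]) - set(meas_df["pb_id"])
    if only_meas or only_ref:
        raise ValueError(
            f"unmatched items: measured-only {sorted(only_meas)[:10]}, "
            f"reference-only {sorted(only_ref)[:10]}"
        )
    table = _diff_table(ref_df, meas_df, "pb_id")
    kind = "plan" if isinstance(reference, SpotPlan) else "log"
    return DiscrepancySet(table=table, reference_kind=kind, level=level)


def discrepancies_pulses(
    measured: pd.DataFrame, log: pd.DataFrame
) -> DiscrepancySet:
    """Pulse-level discrepancies, joined one-to-one by pulse index/timestamp."""
    if len(measured) != len(log):
        raise ValueError("pulse tables must align one-to-one")
    m = measured.reset_index(drop=True).copy()
    r = log.reset_index(drop=True).copy()
    m["pb_id"] = np.arange(len(m))
    r["pb_id"] = np.arange(len(r))
    table = _diff_table(r, m, "pb_id")
    return DiscrepancySet(table=table, reference_kind="log", level="pulse")


def _as_frame(obj) -> pd.DataFrame:
    if isinstance(obj, SpotPlan):
        return pd.DataFrame(
            [(s.spot_id, s.X, s.Y, s.E, s.I) for s in obj.spots],
            columns=["pb_id", "X", "Y", "E", "I"],
        )
    if isinstance(obj, pd.DataFrame):
        return obj
    rows = []
    for p in obj:
        rows.append((p.pb_id, p.X, p.Y, p.E, p.I))
    return pd.DataFrame(rows, columns=["pb_id", "X", "Y", "E", "I"])


# ---------------------------------------------------------------------------
# confidence intervals and proportions
# ---------------------------------------------------------------------------

def confidence_intervals(d: DiscrepancySet) -> ConfidenceIntervals:
    """Per-feature [mean - 3 sd, mean + 3 sd] from a discrepancy set (n >= 2)."""
    if len(d) < 2:
        raise ValueError("need at least 2 items for a confidence interval")
    intervals, source = {}, {}
    degenerate = []
    for f in FEATURES:
        v = d.values(f)
        mean, sd = float(v.mean()), float(v.std(ddof=1))
        if sd == 0.0:
            degenerate.append(f)
        intervals[f] = (mean - 3.0 * sd, mean + 3.0 * sd)
        source[f] = {"n": len(v), "mean": mean, "sd": sd}
    return ConfidenceIntervals(intervals, source, tuple(degenerate))


def proportion_in_ci(d: DiscrepancySet, ci: ConfidenceIntervals) -> dict:
    """Fraction of items inside each feature interval (closed bounds) and
    inside the intersection of all four."""
    if len(d) == 0:
        raise ValueError("empty discrepancy set")
    inside_all = np.ones(len(d), dtype=bool)
    out: dict = {}
    for f in FEATURES:
        lo, hi = ci[f]
        if not (np.isfinite(lo) and np.isfinite(hi)):
            raise ValueError(f"non-finite interval for {f}")
        v = d.values(f)
        inside = (v >= lo) & (v <= hi)
        out[f] = float(inside.mean())
        inside_all &= inside
    out["joint"] = float(inside_all.mean())
    return out


# ---------------------------------------------------------------------------
# delivery verdict
# ---------------------------------------------------------------------------

def verify_delivery(
    plan: SpotPlan,
    pbs: list[ReconstructedPB],
    ci: ConfidenceIntervals,
    joint_threshold: float = 0.95,
    parameters: dict | None = None,
) -> QAReport:
    """Verify a reconstructed delivery against its plan.

    Reconstructed PBs absent from the plan are listed as unplanned and
    excluded from the proportions; planned spots never reconstructed are
    listed as missing (both are reported so a QA reviewer sees them).
    """
    if not pbs:
        raise ValueError("empty PB list")
    plan_ids = {s.spot_id for s in plan.spots}
    unplanned = sorted(pb.pb_id for pb in pbs if pb.pb_id not in plan_ids)
    missing = sorted(plan_ids - {pb.pb_id for pb in pbs})
    planned_pbs = [pb for pb in pbs if pb.pb_id in plan_ids]
    if not planned_pbs:
        raise ValueError("no reconstructed PB matches the plan")
    plan_sub = _as_frame(plan)
    plan_sub = plan_sub[plan_sub["pb_id"].isin([pb.pb_id for pb in planned_pbs])]
    d = DiscrepancySet(
        table=_diff_table(plan_sub, _as_frame(planned_pbs), "pb_id"),
        reference_kind="plan",
        level="pb",
    )
    props = proportion_in_ci(d, ci)
    rows = d.table.copy()
    for f in FEATURES:
        lo, hi = ci[f]
        rows[f"in_CI{f}"] = (rows[f"d{f}"] >= lo) & (rows[f"d{f}"] <= hi)
    rows["in_CI_joint"] = rows[[f"in_CI{f}" for f in FEATURES]].all(axis=1)
    offending = [f for f in FEATURES if props[f] < joint_threshold]
    verdict = "pass" if props["joint"] >= joint_threshold else (
        "fail: " + (", ".join(f"{f} out of tolerance" for f in offending)
                    if offending else "joint proportion below threshold")
    )
    return QAReport(
        rows=rows,
        summary=d.summary(),
        proportions=props,
        ci=ci,
        verdict=verdict,
        joint_threshold=joint_threshold,
        unplanned_pb_ids=unplanned,
        missing_planned_pb_ids=missing,
        offending_features=offending,
        parameters=parameters or {},
    )
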