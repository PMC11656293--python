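"""Pencil-beam reconstruction from calibrated pulses.

A pencil beam's intensity is the sum of its pulses' intensities; its other
characteristics (position, energy) are the intensity-weighted means of the
per-pulse values.  Pulses are grouped by the pencil-beam identification
number carried by the machine log; an optional log-free spatial grouping
(grid snap of the calibrated positions) is provided behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ReconstructedPB", "group_pulses", "reconstruct", "reconstruct_all"]


@dataclass(frozen=True)
class ReconstructedPB:
    pb_id: int
    X: float
    Y: float
    E: float
    I: float
    n_pulses: int
    member_indices: tuple[int, ...]


def group_pulses(pulses: pd.DataFrame, spatial: bool = False,
                 grid_pitch: float = 2.5) -> dict[int, np.ndarray]:
    """Partition calibrated pulses (rows of a DataFrame) by pb_id.

    With ``spatial=True`` the pb_id column is ignored and pulses are grouped
    by snapping (X, Y, E) to a grid of ``grid_pitch`` mm laterally (1 MeV in
    energy) — the log-file-free mode.  Returns {group id: row indices}.
    """
    if spatial:
        gx = np.round(pulses["X"].to_numpy() / grid_pitch).astype(int)
        gy = np.round(pulses["Y"].to_numpy() / grid_pitch).astype(int)
        ge = np.round(pulses["E"].to_numpy()).astype(int)
        keys = pd.Series(list(zip(gx, gy, ge)))
        groups: dict[int, np.ndarray] = {}
        for gid, (_, idx) in enumerate(keys.groupby(keys).groups.items()):
            groups[gid] = np.asarray(idx)
        return groups
    if "pb_id" not in pulses.columns:
        raise ValueError("pulses carry no pb_id column")
    if pulses["pb_id"].isna().any():
        bad = pulses.index[pulses["pb_id"].isna()].tolist()
        raise ValueError(f"pulses without pb_id at rows {bad}")
    return {
        int(pb): np.asarray(idx)
        for pb, idx in pulses.groupby("pb_id").groups.items()
    }


def reconstruct(group: pd.DataFrame, pb_id: int,
                member_indices: tuple[int, ...] = ()) -> ReconstructedPB:
    """Intensity-weighted aggregate of one pencil beam's pulses."""
    if len(group) == 0:
        raise ValueError("empty pulse group")
    I = group["I"].to_numpy(dtype=float)
    if np.any(I <= 0):
        raise ValueError("pulse intensities must be > 0")
    I_pb = float(I.sum())
    if I_pb <= 0:
        raise ValueError("zero total intensity: cannot weight")
    w = I / I_pb
    return ReconstructedPB(
        pb_id=pb_id,
        X=float(w @ group["X"].to_numpy(dtype=float)),
        Y=float(w @ group["Y"].to_numpy(dtype=float)),
        E=float(w @ group["E"].to_numpy(dtype=float)),
        I=I_pb,
        n_pulses=len(group),
        member_indices=member_indices,
    )


def reconstruct_all(pulses: pd.DataFrame, spatial: bool = False) -> list[ReconstructedPB]:
    """Group and reconstruct every pencil beam of a calibrated-pulse table.

    Unusable pulses (NaN characteristics) are dropped before grouping.
    """
    ok = pulses
    if "usable" in pulses.columns:
        ok = pulses[pulses["usable"].astype(bool)]
    ok = ok.dropna(subset=["X", "Y", "E", "I"]).reset_index(drop=True)
    groups = group_pulses(ok, spatial=spatial)
    pbs = [
        reconstruct(ok.iloc[idx], pb_id, tuple(int(i) for i in idx))
        for pb_id, idx in sorted(groups.items())
    ]
    return pbs
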