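"""Polynomial calibration from image features to physical pulse characteristics.

Positions and energy are modelled as linear combinations of monomials (powers
up to 5 per predictor) of the image features (i_Dc, j_Dc, j_Mc); intensity
adds PI_Dmax as a fourth predictor with powers up to 4.  The full tensor
candidate bases therefore hold 6^3 - 1 = 215 and 5^4 - 1 = 624 non-constant
terms; an explicit intercept is carried separately.

Fitting is ordinary least squares on the full basis followed by greedy
backward deletion: at each step the term whose removal most decreases the
Bayesian Information Criterion

    BIC = n * ln(RSS / n) + k * ln(n),   k = #terms + intercept + variance,

is dropped, until no single removal decreases BIC.  Predictors are
standardized (training mean/sd) before monomials are built, which keeps the
degree-5 design matrices well conditioned; collinear columns are dropped up
front by pivoted QR and reported.

One independent scalar map is fitted per target (X, Y, E, I).  The
calibration absorbs perspective, vignetting and any smooth spatially varying
response of the optical chain, so no separate flat-field step is needed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .localize import ViewFeatures
from .simulate import PulseRecord

__all__ = [
    "BasisTerm",
    "MatchedPair",
    "FittedMap",
    "CalibrationModel",
    "SynchronizationError",
    "candidate_basis",
    "synchronize",
    "fit_map",
    "fit",
    "fit_all",
    "apply_map",
    "apply_model",
]

F_PREDICTORS = ("i_Dc", "j_Dc", "j_Mc")
G_PREDICTORS = ("i_Dc", "j_Dc", "j_Mc", "PI_Dmax")
F_MAX_POWER = 5
G_MAX_POWER = 4

BasisTerm = tuple[int, ...]


class SynchronizationError(ValueError):
    """Ambiguous frame/log matching; message lists the offending entries."""


@dataclass(frozen=True)
class MatchedPair:
    features: ViewFeatures
    pulse: PulseRecord

    @property
    def time_offset(self) -> float:
        return self.features.timestamp - self.pulse.timestamp


@dataclass
class FittedMap:
    """One fitted polynomial map: selected basis terms, coefficients, intercept,
    plus the predictor standardization and fit diagnostics."""

    predictors: tuple[str, ...]
    terms: list[BasisTerm]
    coefficients: np.ndarray
    intercept: float
    center: np.ndarray  # training predictor means
    scale: np.ndarray  # training predictor sds
    residual_sd: float
    bic: float
    bic_trace: list[float] = field(default_factory=list)
    n_points: int = 0
    dropped_collinear: list[BasisTerm] = field(default_factory=list)
    train_min: np.ndarray | None = None
    train_max: np.ndarray | None = None

    def design(self, P: np.ndarray) -> np.ndarray:
        Z = (np.asarray(P, dtype=np.float64) - self.center) / self.scale
        return _monomials(Z, self.terms)

    def predict(self, P: np.ndarray) -> np.ndarray:
        return self.design(P) @ self.coefficients + self.intercept


@dataclass
class CalibrationModel:
    """The four fitted maps (f_X, f_Y, f_E, g_I) plus fit metadata."""

    maps: dict[str, FittedMap]
    rng_seed: int | None = None

    def __getitem__(self, target: str) -> FittedMap:
        return self.maps[target]

    def to_dict(self) -> dict:
        out: dict = {"rng_seed": self.rng_seed, "maps": {}}
        for target, m in self.maps.items():
            out["maps"][target] = {
                "predictors": list(m.predictors),
                "terms": [list(t) for t in m.terms],
                "coefficients": [float(c) for c in m.coefficients],
                "intercept": m.intercept,
                "center": [float(c) for c in m.center],
                "scale": [float(s) for s in m.scale],
                "residual_sd": m.residual_sd,
                "bic": m.bic,
                "bic_trace": [float(b) for b in m.bic_trace],
                "n_points": m.n_points,
                "dropped_collinear": [list(t) for t in m.dropped_collinear],
                "train_min": None if m.train_min is None else [float(v) for v in m.train_min],
                "train_max": None if m.train_max is None else [float(v) for v in m.train_max],
            }
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        maps = {}
        for target, m in d["maps"].items():
            maps[target] = FittedMap(
                predictors=tuple(m["predictors"]),
                terms=[tuple(t) for t in m["terms"]],
                coefficients=np.asarray(m["coefficients"], dtype=float),
                intercept=float(m["intercept"]),
                center=np.asarray(m["center"], dtype=float),
                scale=np.asarray(m["scale"], dtype=float),
                residual_sd=float(m["residual_sd"]),
                bic=float(m["bic"]),
                bic_trace=list(m.get("bic_trace", [])),
                n_points=int(m.get("n_points", 0)),
                dropped_collinear=[tuple(t) for t in m.get("dropped_collinear", [])],
                train_min=None if m.get("train_min") is None else np.asarray(m["train_min"]),
                train_max=None if m.get("train_max") is None else np.asarray(m["train_max"]),
            )
        return cls(maps=maps, rng_seed=d.get("rng_seed"))


# ---------------------------------------------------------------------------
# candidate basis
# ---------------------------------------------------------------------------

def candidate_basis(n_predictors: int, max_power: int) -> list[BasisTerm]:
    """All exponent tuples with each exponent in [0, max_power], excluding the
    all-zero tuple; count = (max_power + 1)**n_predictors - 1."""
    if n_predictors < 1 or max_power < 1:
        raise ValueError("need n_predictors >= 1 and max_power >= 1")
    terms = [
        t
        for t in itertools.product(range(max_power + 1), repeat=n_predictors)
        if any(t)
    ]
    return terms


def _monomials(Z: np.ndarray, terms: list[BasisTerm]) -> np.ndarray:
    Z = np.atleast_2d(np.asarray(Z, dtype=np.float64))
    n, p = Z.shape
    max_pow = max((max(t) for t in terms), default=0)
    # precompute powers of each predictor
    powers = np.ones((max_pow + 1, n, p))
    for e in range(1, max_pow + 1):
        powers[e] = powers[e - 1] * Z
    X = np.empty((n, len(terms)))
    for j, t in enumerate(terms):
        col = np.ones(n)
        for pi, e in enumerate(t):
            if e:
                col = col * powers[e, :, pi]
        X[:, j] = col
    return X


# ---------------------------------------------------------------------------
# synchronization
# ---------------------------------------------------------------------------

def synchronize(
    features: list[ViewFeatures],
    log: list[PulseRecord],
    tolerance: float = 0.5,
) -> tuple[list[MatchedPair], list[ViewFeatures], list[PulseRecord]]:
    """Greedy nearest-timestamp one-to-one matching within ``tolerance`` ms.

    Returns (matched pairs, unmatched features, unmatched log records).  Two
    log entries both within tolerance of one frame is an ambiguity error.
    """
    if any(
        features[i].timestamp > features[i + 1].timestamp
        for i in range(len(features) - 1)
    ) or any(log[i].timestamp > log[i + 1].timestamp for i in range(len(log) - 1)):
        raise ValueError("inputs must be timestamp-sorted")
    log_ts = np.array([p.timestamp for p in log])
    for f in features:
        close = np.flatnonzero(np.abs(log_ts - f.timestamp) <= tolerance)
        if len(close) > 1:
            raise SynchronizationError(
                f"frame at t={f.timestamp} ms matches log entries "
                f"{[log[i].timestamp for i in close]} within {tolerance} ms"
            )
    # candidate (|dt|, feature idx, log idx) pairs, assigned greedily
    cands = []
    for i, f in enumerate(features):
        close = np.flatnonzero(np.abs(log_ts - f.timestamp) <= tolerance)
        for j in close:
            cands.append((abs(f.timestamp - log_ts[j]), i, int(j)))
    cands.sort()
    used_f: set[int] = set()
    used_l: set[int] = set()
    pairs: list[MatchedPair] = []
    for _, i, j in cands:
        if i in used_f or j in used_l:
            continue
        used_f.add(i)
        used_l.add(j)
        pairs.append(MatchedPair(features[i], log[j]))
    pairs.sort(key=lambda p: p.pulse.timestamp)
    unmatched_f = [f for i, f in enumerate(features) if i not in used_f]
    unmatched_l = [p for j, p in enumerate(log) if j not in used_l]
    return pairs, unmatched_f, unmatched_l


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _bic(n: int, rss: float, n_terms: int, rss_floor: float = 1e-300) -> float:
    # the floor makes numerically-zero residuals (exact interpolation)
    # compare as equal instead of as spurious likelihood gains
    k = n_terms + 2  # coefficients + intercept + variance
    return n * np.log(max(rss, rss_floor) / n) + k * np.log(n)


def fit_map(
    P: np.ndarray,
    y: np.ndarray,
    max_power: int,
    predictors: tuple[str, ...] | None = None,
) -> FittedMap:
    """Fit one polynomial map by OLS + greedy backward BIC deletion.

    ``P`` is (n, n_predictors) raw predictor values, ``y`` the target.  The
    design is built from standardized predictors; rank-deficient columns are
    dropped by pivoted QR before selection and reported on the fitted map.
    """
    P = np.atleast_2d(np.asarray(P, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64)
    n, p = P.shape
    terms = candidate_basis(p, max_power)
    if n <= len(terms) + 1:
        raise ValueError(
            f"need more points ({n}) than candidate terms + 1 ({len(terms) + 1})"
        )
    center = P.mean(axis=0)
    scale = P.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (P - center) / scale
    X = _monomials(Z, terms)

    # drop collinear columns (pivoted QR on the centered design)
    Xc = X - X.mean(axis=0)
    _, R, piv = linalg.qr(Xc, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag[0] * max(Xc.shape) * np.finfo(float).eps if diag[0] > 0 else 0.0
    keep_rank = int(np.sum(diag > tol))
    kept_idx = sorted(piv[:keep_rank])
    dropped = [terms[j] for j in sorted(piv[keep_rank:])]
    terms = [terms[j] for j in kept_idx]
    X = X[:, kept_idx]

    # Gram-matrix OLS with intercept; backward deletion via the exact
    # single-column RSS update RSS_-j = RSS + beta_j^2 / (X'X)^-1_jj.
    ones = np.ones((n, 1))
    A = np.hstack([ones, X])
    G = A.T @ A
    b = A.T @ y
    yty = float(y @ y)
    rss_floor = max(yty, 1e-30) * (100 * np.finfo(float).eps) ** 2

    active = list(range(len(terms)))  # indices into terms/X (intercept pinned)

    def solve(active_idx: list[int]) -> tuple[np.ndarray, np.ndarray, float]:
        sel = [0] + [j + 1 for j in active_idx]
        Gs = G[np.ix_(sel, sel)]
        bs = b[sel]
        try:
            cho = linalg.cho_factor(Gs)
            beta = linalg.cho_solve(cho, bs)
            Ginv = linalg.cho_solve(cho, np.eye(len(sel)))
        except linalg.LinAlgError:
            Ginv = np.linalg.pinv(Gs)
            beta = Ginv @ bs
        rss = max(yty - float(bs @ beta), 0.0)
        return beta, Ginv, rss

    beta, Ginv, rss = solve(active)
    bic = _bic(n, rss, len(active), rss_floor)
    trace = [bic]

    while active:
        # RSS increase from deleting each active term
        d = np.diag(Ginv)[1:]
        with np.errstate(divide="ignore", invalid="ignore"):
            rss_inc = np.where(d > 0, beta[1:] ** 2 / d, np.inf)
        order = np.argsort(rss_inc)
        j_best = int(order[0])
        cand_rss = rss + float(rss_inc[j_best])
        cand_bic = _bic(n, cand_rss, len(active) - 1, rss_floor)
        if cand_bic >= bic:
            break
        del active[j_best]
        beta, Ginv, rss = solve(active)
        bic = _bic(n, rss, len(active), rss_floor)
        trace.append(bic)

    sel_terms = [terms[j] for j in active]
    dof = max(n - len(active) - 1, 1)
    residual_sd = float(np.sqrt(rss / dof))
    return FittedMap(
        predictors=predictors or tuple(f"p{i}" for i in range(p)),
        terms=sel_terms,
        coefficients=np.asarray(beta[1:], dtype=float),
        intercept=float(beta[0]),
        center=center,
        scale=scale,
        residual_sd=residual_sd,
        bic=bic,
        bic_trace=trace,
        n_points=n,
        dropped_collinear=dropped,
        train_min=P.min(axis=0),
        train_max=P.max(axis=0),
    )


def _pairs_to_arrays(pairs: list[MatchedPair]) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    F = np.array(
        [[p.features.i_Dc, p.features.j_Dc, p.features.j_Mc, p.features.PI_Dmax]
         for p in pairs]
    )
    targets = {
        "X": np.array([p.pulse.X for p in pairs]),
        "Y": np.array([p.pulse.Y for p in pairs]),
        "E": np.array([p.pulse.E for p in pairs]),
        "I": np.array([p.pulse.I for p in pairs]),
    }
    return F, targets


def fit(pairs: list[MatchedPair], target: str) -> FittedMap:
    """Fit the calibration map for one target (X, Y or E use the three
    geometric predictors with powers up to 5; I adds PI_Dmax, powers up to 4)."""
    if target not in ("X", "Y", "E", "I"):
        raise ValueError("target must be one of X, Y, E, I")
    F, targets = _pairs_to_arrays(pairs)
    if target == "I":
        return fit_map(F, targets["I"], G_MAX_POWER, G_PREDICTORS)
    return fit_map(F[:, :3], targets[target], F_MAX_POWER, F_PREDICTORS)


def fit_all(pairs: list[MatchedPair], rng_seed: int | None = None,
            f_max_power: int = F_MAX_POWER, g_max_power: int = G_MAX_POWER) -> CalibrationModel:
    """Fit all four maps; ``f_max_power``/``g_max_power`` allow reduced bases
    for quick runs."""
    F, targets = _pairs_to_arrays(pairs)
    maps = {
        t: fit_map(F[:, :3], targets[t], f_max_power, F_PREDICTORS)
        for t in ("X", "Y", "E")
    }
    maps["I"] = fit_map(F, targets["I"], g_max_power, G_PREDICTORS)
    return CalibrationModel(maps=maps, rng_seed=rng_seed)


# ---------------------------------------------------------------------------
# application
# ---------------------------------------------------------------------------

def apply_map(m: FittedMap, features: ViewFeatures) -> float:
    row = [getattr(features, name) for name in m.predictors]
    return float(m.predict(np.asarray(row)[None, :])[0])


def apply_model(
    model: CalibrationModel,
    features: list[ViewFeatures],
    warn_extrapolation: bool = True,
) -> pd.DataFrame:
    """Calibrate a list of pulse features into physical characteristics.

    Returns a DataFrame with columns timestamp, X, Y, E, I, usable,
    extrapolated.  Unusable features propagate their flag and emit NaNs.
    """
    import warnings

    rows = []
    n_extrap = 0
    for f in features:
        if not f.usable:
            rows.append((f.timestamp, np.nan, np.nan, np.nan, np.nan, False, False))
            continue
        extrap = False
        vals = {}
        for target in ("X", "Y", "E", "I"):
            m = model[target]
            p = np.array([getattr(f, name) for name in m.predictors])
            if m.train_min is not None and (
                np.any(p < m.train_min) or np.any(p > m.train_max)
            ):
                extrap = True
            vals[target] = float(m.predict(p[None, :])[0])
        n_extrap += extrap
        rows.append(
            (f.timestamp, vals["X"], vals["Y"], vals["E"], vals["I"], True, extrap)
        )
    if warn_extrapolation and n_extrap:
        warnings.warn(
            f"{n_extrap} pulses lie outside the calibration predictor hull",
            stacklevel=2,
        )
    return pd.DataFrame(
        rows, columns=["timestamp", "X", "Y", "E", "I", "usable", "extrapolated"]
    )
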