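"""BRET saturation-curve quantification and AUC/fold-of-change PPI scoring.

The live-cell BRET assay titrates an acceptor (Venus-tagged prey) against
a fixed donor (NLuc-tagged bait).  Each well yields

* the BRET ratio  F535 / L460,
* net BRET        = pair ratio - donor-only control ratio,
* the acceptor/donor expression ratio X = Venus FI / L460.

Net BRET (Y) versus X follows a one-site hyperbolic saturation model

    Y = Bmax * X / (B50 + X)

with plateau ``Bmax`` (interaction amplitude) and half-saturation ``B50``
(inverse relative affinity).  Points with negative X or Y (instrument
noise around zero signal) are excluded before fitting.  Each candidate
interaction is scored by the area under its fitted curve over a common
[0, x_max] window, compared against two empty-vector control series:

    FOC   = mean AUC_ppi / max(mean AUC_ctrl1, mean AUC_ctrl2)
    P_FOC = two-sided equal-variance t-test, replicate PPI AUCs vs the
            pooled ctrl1+ctrl2 replicate AUCs

A pair is a hit when FOC >= 4.0 and P_FOC <= 0.001 (both inclusive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import (
    DegenerateSignalError,
    InsufficientDataError,
    InsufficientReplicatesError,
)

DEFAULT_FOC_CUTOFF = 4.0
DEFAULT_P_CUTOFF = 0.001


# ---------------------------------------------------------------------------
# elementary ratios
# ---------------------------------------------------------------------------

def bret_ratio(f535, l460):
    """BRET ratio: acceptor emission over donor luminescence (F535/L460)."""
    f535 = np.asarray(f535, dtype=float)
    l460 = np.asarray(l460, dtype=float)
    if np.any(l460 <= 0):
        raise DegenerateSignalError("L460 must be positive to form a BRET ratio")
    out = f535 / l460
    return float(out) if out.ndim == 0 else out


def net_bret(ratio_pair, ratio_donor_only_ctrl):
    """Specific BRET signal: pair ratio minus donor-only control ratio.

    May be negative; negative values are excluded at the fitting stage,
    not here.
    """
    a = np.asarray(ratio_pair, dtype=float)
    b = np.asarray(ratio_donor_only_ctrl, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("net BRET requires finite ratios")
    out = a - b
    return float(out) if out.ndim == 0 else out


def acceptor_donor_ratio(venus_fi, l460):
    """Acceptor/donor expression ratio X = Venus FI / L460.

    Venus fluorescence comes from a black plate seeded and transfected
    side-by-side with the white (luminescence) plate; callers pair wells
    by identical plate position before taking the ratio.
    """
    venus_fi = np.asarray(venus_fi, dtype=float)
    l460 = np.asarray(l460, dtype=float)
    if np.any(l460 <= 0):
        raise DegenerateSignalError("L460 must be positive to form an acceptor/donor ratio")
    out = venus_fi / l460
    return float(out) if out.ndim == 0 else out


def trfret_ratio(f665, f620):
    """TR-FRET signal: (F665 / F620) x 10^4."""
    f665 = np.asarray(f665, dtype=float)
    f620 = np.asarray(f620, dtype=float)
    if np.any(f620 <= 0):
        raise DegenerateSignalError("F620 must be positive to form a TR-FRET ratio")
    out = f665 / f620 * 1e4
    return float(out) if out.ndim == 0 else out


def trfret_foc(signal, empty_vector_signal):
    """Fold-of-change of a TR-FRET signal over the empty-vector control."""
    ev = float(empty_vector_signal)
    if ev <= 0:
        raise DegenerateSignalError("empty-vector TR-FRET signal must be positive")
    return float(signal) / ev


# ---------------------------------------------------------------------------
# saturation model
# ---------------------------------------------------------------------------

@dataclass
class SaturationPoint:
    """One titration point of a saturation curve.

    ``excluded`` is derived from the exclusion rule (negative X or Y
    never enter a fit) unless set explicitly.
    """

    x: float
    y: float
    replicate: int = 1
    excluded: bool | None = None

    def __post_init__(self):
        if self.excluded is None:
            self.excluded = bool(self.x < 0 or self.y < 0)


@dataclass
class SaturationFit:
    """Fitted hyperbolic saturation parameters for one replicate curve."""

    bret_max: float
    bret50: float
    n_points_used: int
    rss: float
    converged: bool


def saturation_model(x, bret_max, bret50):
    """Hyperbolic one-site saturation: Y = Bmax * X / (B50 + X)."""
    x = np.asarray(x, dtype=float)
    return bret_max * x / (bret50 + x)


class SaturationCurve(RegressorMixin, BaseEstimator):
    """Least-squares estimator of the hyperbolic BRET saturation model.

    Parameters
    ----------
    tol : float
        Convergence tolerance on the relative change of the residual sum
        of squares.
    max_iter : int
        Iteration cap for the trust-region solver.

    Attributes
    ----------
    bret_max_ : float
        Fitted plateau (>= 0).
    bret50_ : float
        Fitted half-saturation ratio (> 0 when converged; NaN for the
        degenerate all-zero-response case where it is unidentifiable).
    rss_ : float
        Residual sum of squares at the solution.
    converged_ : bool
        Whether the solver reported convergence.
    n_points_used_ : int
        Number of points the fit used.
    """

    def __init__(self, tol: float = 1e-10, max_iter: int = 1000):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.shape != y.shape:
            raise ValueError("X and y must have the same length")
        if x.size < 3 or np.unique(x).size < 2:
            raise InsufficientDataError(
                f"saturation fit needs >= 3 points with >= 2 distinct x values, got {x.size}"
            )
        self.n_points_used_ = int(x.size)

        ymax = float(np.max(y))
        if ymax <= 0.0:
            # no positive response: plateau pinned at 0, B50 unidentifiable
            self.bret_max_ = 0.0
            self.bret50_ = float("nan")
            self.rss_ = float(np.sum(y**2))
            self.converged_ = False
            return self

        # half-saturation guess: first x whose response reaches half the plateau
        above = x[y >= ymax / 2.0]
        b50_0 = float(np.min(above)) if above.size else float(np.median(x))
        b50_0 = max(b50_0, 1e-6)

        def residuals(p):
            return saturation_model(x, p[0], p[1]) - y

        def jac(p):
            w = x / (p[1] + x)
            return np.column_stack([w, -p[0] * w / (p[1] + x)])

        res = optimize.least_squares(
            residuals,
            jac=jac,
            x0=[ymax, b50_0],
            bounds=([0.0, 1e-12], [np.inf, np.inf]),
            ftol=self.tol,
            xtol=self.tol,
            gtol=self.tol,
            max_nfev=self.max_iter,
        )
        self.bret_max_ = float(res.x[0])
        self.bret50_ = float(res.x[1])
        self.rss_ = float(np.sum(res.fun**2))
        self.converged_ = bool(res.success)
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).ravel()
        return saturation_model(x, self.bret_max_, self.bret50_)


def _as_xy(points):
    """Coerce a curve (SaturationPoints, (x, y) pair, or (n,2) array) to arrays."""
    if isinstance(points, (tuple, list)) and len(points) == 2 and np.ndim(points[0]) >= 1:
        x = np.asarray(points[0], dtype=float)
        y = np.asarray(points[1], dtype=float)
    elif len(points) and isinstance(points[0], SaturationPoint):
        x = np.array([p.x for p in points], dtype=float)
        y = np.array([p.y for p in points], dtype=float)
    else:
        arr = np.asarray(points, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("curve must be SaturationPoints, (x, y) arrays, or an (n, 2) array")
        x, y = arr[:, 0], arr[:, 1]
    return x, y


def fit_saturation(points) -> SaturationFit:
    """Fit one replicate saturation curve, applying the exclusion rule.

    Points with negative X or negative Y are excluded before fitting;
    ``n_points_used`` reflects the exclusion.  Fewer than 3 usable points
    (or < 2 distinct x) raises :class:`InsufficientDataError`.
    Non-convergence is reported via ``converged=False``, not an exception.
    """
    x, y = _as_xy(points)
    usable = (x >= 0) & (y >= 0)
    x, y = x[usable], y[usable]
    if x.size < 3 or np.unique(x).size < 2:
        raise InsufficientDataError(
            f"only {x.size} usable point(s) after excluding negative X/Y values"
        )
    est = SaturationCurve().fit(x, y)
    return SaturationFit(
        bret_max=est.bret_max_,
        bret50=est.bret50_,
        n_points_used=est.n_points_used_,
        rss=est.rss_,
        converged=est.converged_,
    )


def hyperbolic_auc(bret_max: float, bret50: float, x_max: float) -> float:
    """Exact integral of the saturation model over [0, x_max].

    closed form: Bmax * (x_max - B50 * ln((B50 + x_max) / B50)).
    """
    if x_max <= 0:
        raise ValueError("x_max must be positive")
    if bret_max == 0.0:
        return 0.0
    if bret50 <= 0:
        # B50 -> 0+ limit: rectangle Bmax * x_max
        return float(bret_max * x_max)
    return float(bret_max * (x_max - bret50 * math.log((bret50 + x_max) / bret50)))


def saturation_auc(fit: SaturationFit, x_max: float) -> float:
    """AUC of a fitted saturation curve over the common window [0, x_max]."""
    if fit.bret_max == 0.0:
        return 0.0
    if not fit.converged:
        raise InsufficientDataError("cannot integrate a non-converged saturation fit")
    return hyperbolic_auc(fit.bret_max, fit.bret50, x_max)


# ---------------------------------------------------------------------------
# PPI scoring
# ---------------------------------------------------------------------------

@dataclass
class PPIScore:
    """AUC-based score for one donor-acceptor pair against dual controls."""

    donor: str
    acceptor: str
    auc_ppi: list = field(default_factory=list)
    auc_ctrl1: list = field(default_factory=list)
    auc_ctrl2: list = field(default_factory=list)
    x_max: float = float("nan")
    foc: float = float("nan")
    p_foc: float = float("nan")
    is_hit: bool = False
    callable: bool = True  # False when the control AUC scale is nonpositive


def _curve_aucs(curves, x_max):
    aucs = []
    for curve in curves:
        try:
            fit = fit_saturation(curve)
        except InsufficientDataError:
            continue  # replicate lost to the negative-value exclusion rule
        if fit.converged or fit.bret_max == 0.0:
            aucs.append(saturation_auc(fit, x_max) if fit.bret_max != 0.0 else 0.0)
    return aucs


def _common_x_max(curve_sets):
    """Common integration bound: min over curves of each curve's max usable x."""
    bounds = []
    for curves in curve_sets:
        for curve in curves:
            x, y = _as_xy(curve)
            usable = (x >= 0) & (y >= 0)
            if usable.any():
                bounds.append(float(np.max(x[usable])))
    if not bounds:
        raise InsufficientDataError("no usable points in any curve")
    return min(bounds)


def score_from_aucs(
    auc_ppi,
    auc_ctrl1,
    auc_ctrl2,
    *,
    donor: str = "",
    acceptor: str = "",
    x_max: float = float("nan"),
    foc_cutoff: float = DEFAULT_FOC_CUTOFF,
    p_cutoff: float = DEFAULT_P_CUTOFF,
) -> PPIScore:
    """Score a pair from precomputed replicate AUCs (fold-of-change + t-test)."""
    auc_ppi = [float(a) for a in auc_ppi]
    auc_ctrl1 = [float(a) for a in auc_ctrl1]
    auc_ctrl2 = [float(a) for a in auc_ctrl2]
    for name, aucs in (("ppi", auc_ppi), ("ctrl1", auc_ctrl1), ("ctrl2", auc_ctrl2)):
        if len(aucs) < 2:
            raise InsufficientReplicatesError(
                f"condition {name!r} has {len(aucs)} usable replicate AUC(s); need >= 2"
            )
    denom = max(float(np.mean(auc_ctrl1)), float(np.mean(auc_ctrl2)))
    pooled_ctrl = auc_ctrl1 + auc_ctrl2
    t = stats.ttest_ind(auc_ppi, pooled_ctrl, equal_var=True)
    p_foc = float(t.pvalue)
    if denom <= 0:
        # FOC undefined against a nonpositive control scale: flag, don't guess
        return PPIScore(
            donor, acceptor, auc_ppi, auc_ctrl1, auc_ctrl2, x_max,
            float("nan"), p_foc, False, callable=False,
        )
    foc = float(np.mean(auc_ppi)) / denom
    is_hit = bool(foc >= foc_cutoff and p_foc <= p_cutoff)
    return PPIScore(donor, acceptor, auc_ppi, auc_ctrl1, auc_ctrl2, x_max, foc, p_foc, is_hit)


def score_ppi(
    ppi_curves,
    ctrl1_curves,
    ctrl2_curves,
    foc_cutoff: float = DEFAULT_FOC_CUTOFF,
    p_cutoff: float = DEFAULT_P_CUTOFF,
    *,
    donor: str = "",
    acceptor: str = "",
    x_max: float | None = None,
) -> PPIScore:
    """Fit replicate curves, integrate over a common window, and score the pair.

    Each ``*_curves`` argument is a sequence of replicate curves (each a
    (x, y) array pair, (n, 2) array, or list of :class:`SaturationPoint`).
    The integration bound defaults to the smallest per-curve maximum
    usable x across all three conditions, so every AUC covers the same
    acceptor/donor window.
    """
    if x_max is None:
        x_max = _common_x_max([ppi_curves, ctrl1_curves, ctrl2_curves])
    return score_from_aucs(
        _curve_aucs(ppi_curves, x_max),
        _curve_aucs(ctrl1_curves, x_max),
        _curve_aucs(ctrl2_curves, x_max),
        donor=donor,
        acceptor=acceptor,
        x_max=x_max,
        foc_cutoff=foc_cutoff,
        p_cutoff=p_cutoff,
    )


def scores_to_frame(scores) -> pd.DataFrame:
    """Flatten PPIScores to a results table (one row per pair)."""
    rows = []
    for s in scores:
        rows.append(
            {
                "donor": s.donor,
                "acceptor": s.acceptor,
                "mean_auc_ppi": float(np.mean(s.auc_ppi)) if s.auc_ppi else float("nan"),
                "mean_auc_ctrl1": float(np.mean(s.auc_ctrl1)) if s.auc_ctrl1 else float("nan"),
                "mean_auc_ctrl2": float(np.mean(s.auc_ctrl2)) if s.auc_ctrl2 else float("nan"),
                "x_max": s.x_max,
                "foc": s.foc,
                "p_foc": s.p_foc,
                "is_hit": bool(s.is_hit),
                "callable": bool(s.callable),
            }
        )
    return pd.DataFrame(rows)


def call_hits(scores) -> pd.DataFrame:
    """Hit table: rows with ``is_hit``, sorted by FOC descending.

    Ties in FOC break by smaller P_FOC, then acceptor name, so the order
    is deterministic.
    """
    df = scores if isinstance(scores, pd.DataFrame) else scores_to_frame(scores)
    if len(df) == 0:
        raise ValueError("call_hits requires a nonempty score collection")
    hits = df[df["is_hit"]].copy()
    hits = hits.sort_values(
        ["foc", "p_foc", "acceptor"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    return hits
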