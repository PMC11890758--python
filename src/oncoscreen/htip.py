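"""Immune co-culture (HTiP) screen statistics.

The screen runs every compound in two parallel arms — cancer cells alone
(-PBMC) and cancer cells co-cultured with activated PBMCs (+PBMC) — and
normalizes each viability signal to percent of control,

    %C = 100 * (S_compound - S_blank) / (S_positive - S_blank)

where S_blank averages PBMC/medium-only DMSO wells and S_positive
averages DMSO wells containing cancer cells.  Immune-dependent killers
are ranked by the selectivity index

    SI = %C(-PBMC) / %C(+PBMC)

(>1 means the compound kills only when immune cells are present; a
nonpositive +PBMC %C is flagged as saturated killing and ranks above all
finite indices).  Potency comes from a variable-slope sigmoidal
(four-parameter logistic, 4PL) fit on a log10 dose axis,

    y = bottom + (top - bottom) / (1 + 10^((log10(IC50) - log10(d)) * hill)).

PBMC-dose killing curves are summarized by a normalized trapezoidal AUC
of viability against log effector dose (1 = no killing, 0 = complete).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import DegenerateControlError, InsufficientDataError

DEFAULT_SI_CUTOFF = 2.0
DEFAULT_AREA_THRESHOLD_UM2 = 400.0


def percent_of_control(s_compound, s_blank, s_positive):
    """Percent of control for a viability signal; may leave [0, 100] (reported as-is)."""
    s_blank = float(s_blank)
    s_positive = float(s_positive)
    if s_positive == s_blank:
        raise DegenerateControlError("S_positive equals S_blank; percent-of-control undefined")
    out = 100.0 * (np.asarray(s_compound, dtype=float) - s_blank) / (s_positive - s_blank)
    return float(out) if out.ndim == 0 else out


def selectivity_index(pc_minus: float, pc_plus: float) -> float:
    """Immune-killing selectivity %C(-PBMC)/%C(+PBMC).

    Returns ``inf`` (the saturated-killing sentinel, ranked above all
    finite values) when the +PBMC percent of control is nonpositive.
    A negative -PBMC percent (compound toxic even without immune cells)
    floors the numerator at 0: such a compound is not immune-selective.
    """
    pc_plus = float(pc_plus)
    if pc_plus <= 0:
        return float("inf")
    return max(float(pc_minus), 0.0) / pc_plus


def cancer_viability(total_signal, pbmc_alone_signal):
    """Cancer-cell viability: total signal minus the PBMC-alone background, floored at 0."""
    out = np.asarray(total_signal, dtype=float) - np.asarray(pbmc_alone_signal, dtype=float)
    out = np.maximum(out, 0.0)
    return float(out) if out.ndim == 0 else out


def filter_objects_by_area(
    objects: pd.DataFrame,
    threshold: float = DEFAULT_AREA_THRESHOLD_UM2,
    area_column: str = "area",
) -> pd.DataFrame:
    """Keep segmented objects strictly larger than ``threshold`` um^2.

    Separates the larger cancer cells from effector immune cells in
    co-culture images; operates on the segmentation's tabular output.
    """
    areas = objects[area_column].astype(float)
    if (areas < 0).any():
        raise ValueError("object areas must be nonnegative")
    return objects[areas > threshold].copy()


# ---------------------------------------------------------------------------
# 4PL dose-response
# ---------------------------------------------------------------------------

@dataclass
class DoseResponseFit:
    """Variable-slope sigmoidal fit; hill > 0 ascending (EC50), < 0 descending (IC50)."""

    top: float
    bottom: float
    hill: float
    ic50: float
    r2: float
    converged: bool


def four_pl(dose, top, bottom, hill, ic50):
    """4PL response at ``dose`` (same parameterization as variable-slope sigmoid fits)."""
    logd = np.log10(np.asarray(dose, dtype=float))
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((np.log10(ic50) - logd) * hill))


class FourParamLogistic(RegressorMixin, BaseEstimator):
    """Least-squares four-parameter logistic (variable-slope sigmoidal) estimator.

    Fits ``log10(IC50)`` internally so the midpoint stays positive.

    Attributes
    ----------
    top_, bottom_, hill_, ic50_ : float
        Fitted plateau, floor, slope factor and midpoint concentration.
    r2_ : float
        Coefficient of determination of the fit.
    converged_ : bool
    """

    #: minimum dose span (log10 units) for an identifiable sigmoid
    MIN_LOG_SPAN = 2.0

    def __init__(self, max_iter: int = 10000):
        self.max_iter = max_iter

    def fit(self, X, y):
        d = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if d.shape != y.shape:
            raise ValueError("doses and responses must have the same length")
        if np.any(d <= 0):
            raise ValueError("doses must be positive concentrations")
        if d.size < 4:
            raise InsufficientDataError(f"4PL fit needs >= 4 points, got {d.size}")
        logd = np.log10(d)
        span = float(logd.max() - logd.min())
        if span < self.MIN_LOG_SPAN:
            raise InsufficientDataError(
                f"4PL fit needs a dose span >= {self.MIN_LOG_SPAN} log10 units, got {span:.2f}"
            )

        top0, bottom0 = float(y.max()), float(y.min())
        slope = np.polyfit(logd, y, 1)[0]
        hill0 = 1.0 if slope >= 0 else -1.0
        mid = (top0 + bottom0) / 2.0
        logec0 = float(logd[np.argmin(np.abs(y - mid))])

        def model(logd, top, bottom, hill, logec):
            return bottom + (top - bottom) / (1.0 + 10.0 ** ((logec - logd) * hill))

        try:
            popt, _ = optimize.curve_fit(
                model, logd, y, p0=[top0, bottom0, hill0, logec0], maxfev=self.max_iter
            )
            self.converged_ = True
        except RuntimeError:
            popt = [top0, bottom0, hill0, logec0]
            self.converged_ = False
        self.top_, self.bottom_, self.hill_ = map(float, popt[:3])
        self.ic50_ = float(10.0 ** popt[3])
        resid = y - model(logd, *popt)
        tss = float(np.sum((y - y.mean()) ** 2))
        self.r2_ = 1.0 - float(np.sum(resid**2)) / tss if tss > 0 else float("nan")
        return self

    def predict(self, X):
        return four_pl(X, self.top_, self.bottom_, self.hill_, self.ic50_)


def fit_4pl(doses, responses) -> DoseResponseFit:
    """Fit a variable-slope sigmoidal dose-response curve.

    Requires >= 4 points spanning >= 2 log10 units of dose;
    non-convergence is reported via ``converged=False``.
    """
    est = FourParamLogistic().fit(doses, responses)
    return DoseResponseFit(
        top=est.top_,
        bottom=est.bottom_,
        hill=est.hill_,
        ic50=est.ic50_,
        r2=est.r2_,
        converged=est.converged_,
    )


def killing_curve_auc(effector_doses, viabilities) -> float:
    """Normalized AUC of a viability-vs-effector-dose killing curve.

    Viability is integrated by trapezoid against log10 effector dose and
    divided by the AUC of a flat 100%-viability curve over the same span,
    so 1.0 means no killing and values near 0 complete killing.
    """
    d = np.asarray(effector_doses, dtype=float)
    v = np.asarray(viabilities, dtype=float)
    if d.size < 3:
        raise ValueError("killing-curve AUC needs >= 3 points")
    if np.any(np.diff(d) <= 0):
        raise ValueError("effector doses must be strictly increasing")
    if np.any(d <= 0):
        raise ValueError("effector doses must be positive for log scaling")
    x = np.log10(d)
    return float(np.trapezoid(v, x) / (100.0 * (x[-1] - x[0])))


# ---------------------------------------------------------------------------
# screen-level results
# ---------------------------------------------------------------------------

@dataclass
class CompoundResult:
    """Per-compound percent-of-control in both arms and selectivity index."""

    compound: str
    pc_minus: float
    pc_plus: float
    selectivity: float
    rank: int | None = None

    @property
    def saturated(self) -> bool:
        return not np.isfinite(self.selectivity)


def compound_results_frame(results) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        df = results.copy()
    else:
        df = pd.DataFrame(
            {
                "compound": [r.compound for r in results],
                "pc_minus": [r.pc_minus for r in results],
                "pc_plus": [r.pc_plus for r in results],
                "selectivity": [r.selectivity for r in results],
            }
        )
    df["saturated_killing"] = ~np.isfinite(df["selectivity"].astype(float))
    return df


def nominate_sensitizers(results, si_cutoff: float = DEFAULT_SI_CUTOFF) -> pd.DataFrame:
    """Ranked immune-sensitizer table.

    Keeps compounds with selectivity >= ``si_cutoff`` (saturated-killing
    flags always qualify and rank first), sorted by selectivity
    descending with deterministic name tie-break, and assigns 1-based
    ranks.
    """
    df = compound_results_frame(results)
    if len(df) == 0:
        raise ValueError("nominate_sensitizers requires nonempty results")
    keep = df[(df["selectivity"] >= si_cutoff) | df["saturated_killing"]].copy()
    keep = keep.sort_values(
        ["selectivity", "compound"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    keep["rank"] = np.arange(1, len(keep) + 1)
    return keep
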