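"""Univariate linear pKa models and their diagnostics.

The calibration model is an ordinary least-squares line

    pKa = slope · ΔE + intercept

fitted per dissociation step to (ΔE, experimental pKa) pairs.  All
diagnostics are computed from the closed-form simple-regression formulas
(not delegated to a statistics library, which instead serves as an
independent cross-check in the test suite):

    slope       = Sxy / Sxx
    intercept   = ȳ − slope·x̄
    s           = sqrt(SSE / (n − 2))          residual standard error
    SE(slope)   = s / sqrt(Sxx)
    SE(intcpt)  = s · sqrt(1/n + x̄²/Sxx)
    R²          = 1 − SSE/SST
    F           = (n − 2)·R²/(1 − R²)          one-regressor ANOVA F(1, n−2)

The same machinery measures agreement between an external commercial
predictor and experiment (external value as regressor).

A fitted slope of a pKa-vs-ΔE model cannot exceed the thermodynamic limit
1/(RT·ln 10) ≈ 0.175 mol/kJ at 298.15 K in magnitude, the slope a perfect
free-energy relationship would have; the reference calibrations (−0.131 and
−0.141) respect it comfortably.

Estimates in the negative pKa range are poorly characterised experimentally;
instead of a numeric value such predictions are reported qualitatively as
modestly negative (``"<0"``, down to −7) or strongly negative (``"<<0"``,
below −7).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chem_data import Step, round_half_up
from .tautomers import DEFAULT_TEMPERATURE_K, R_KJ_PER_MOL_K

__all__ = [
    "QsarModel",
    "Prediction",
    "FitError",
    "InsufficientDataError",
    "DegenerateInputError",
    "QUALITATIVE_CUT",
    "THERMODYNAMIC_SLOPE_LIMIT",
    "REFERENCE_COEFFICIENTS",
    "reference_model",
    "fit",
    "predict",
    "residual",
    "external_agreement",
    "build_report",
    "report_to_csv",
    "calibrate",
    "loo_residuals",
    "studentized_residuals",
]


class FitError(ValueError):
    """The regression could not be computed."""


class InsufficientDataError(FitError):
    """Fewer than three points were supplied."""


class DegenerateInputError(FitError):
    """The regressor has zero variance."""


#: Predictions below this value are labelled "<<0" rather than "<0".
QUALITATIVE_CUT = -7.0

#: |slope| upper bound for any pKa-vs-ΔE fit: 1/(RT ln 10) at 298.15 K.
THERMODYNAMIC_SLOPE_LIMIT = 1.0 / (
    R_KJ_PER_MOL_K * DEFAULT_TEMPERATURE_K * math.log(10.0))

#: Published reference calibration (slope per kJ/mol, intercept) per step.
REFERENCE_COEFFICIENTS: dict[Step, tuple[float, float]] = {
    Step.PKA1: (-0.131, -151.54),
    Step.PKA2: (-0.141, -159.42),
}


@dataclass(frozen=True)
class QsarModel:
    """A fitted (or externally supplied) univariate linear pKa model."""

    slope: float
    intercept: float
    step: Step | None = None
    slope_se: float = float("nan")
    intercept_se: float = float("nan")
    n: int = 0
    r_squared: float = float("nan")
    s: float = float("nan")
    f_stat: float = float("nan")

    def to_json(self, path: str | Path | None = None) -> str:
        d = asdict(self)
        d["step"] = None if self.step is None else Step(self.step).value
        text = json.dumps(d, indent=1)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "QsarModel":
        try:
            is_file = Path(source).exists()
        except (OSError, ValueError):
            is_file = False
        text = Path(source).read_text(encoding="utf-8") if is_file else str(source)
        d = json.loads(text)
        if d.get("step") is not None:
            d["step"] = Step(d["step"])
        return cls(**d)

    def summary(self) -> str:
        step = "" if self.step is None else f" [{self.step.value}]"
        return (f"pKa{step} = {self.slope:.3f}·x + {self.intercept:.3f}   "
                f"(n={self.n}, R²={self.r_squared:.3f}, s={self.s:.3f}, "
                f"F={self.f_stat:.1f}; SE slope {self.slope_se:.3f}, "
                f"SE intercept {self.intercept_se:.3f})")


def reference_model(step: Step) -> QsarModel:
    """The published reference calibration for ``step`` (coefficients only)."""
    slope, intercept = REFERENCE_COEFFICIENTS[Step(step)]
    return QsarModel(slope, intercept, Step(step))


@dataclass(frozen=True)
class Prediction:
    """A model estimate for one compound: numeric, or qualitative when the
    underlying value is negative."""

    compound_id: str | None
    step: Step | None
    delta_e: float
    pka_value: float        # rounded to 2 decimals for reporting
    raw_value: float        # unrounded slope·ΔE + intercept
    qualitative: str        # "numeric", "<0", or "<<0"
    residual: float | None = None


def fit(points: Iterable[tuple[float, float]],
        step: Step | None = None) -> QsarModel:
    """Ordinary least squares on (x, y) pairs with closed-form diagnostics."""
    pts = [(float(x), float(y)) for x, y in points]
    n = len(pts)
    if n < 3:
        raise InsufficientDataError(
            f"need at least 3 points to fit, got {n}")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    xbar, ybar = x.mean(), y.mean()
    sxx = float(((x - xbar) ** 2).sum())
    if sxx == 0.0:
        raise DegenerateInputError("regressor has zero variance")
    sxy = float(((x - xbar) * (y - ybar)).sum())
    sst = float(((y - ybar) ** 2).sum())
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - (intercept + slope * x)
    sse = float((resid ** 2).sum())
    s = math.sqrt(sse / (n - 2))
    r_squared = 1.0 - sse / sst if sst > 0 else float("nan")
    f_stat = ((n - 2) * r_squared / (1.0 - r_squared)
              if 0 <= r_squared < 1 else float("inf"))
    return QsarModel(
        slope=slope, intercept=intercept, step=None if step is None else Step(step),
        slope_se=s / math.sqrt(sxx),
        intercept_se=s * math.sqrt(1.0 / n + xbar ** 2 / sxx),
        n=n, r_squared=r_squared, s=s, f_stat=f_stat)


def predict(model: QsarModel, delta_e: float, *,
            compound_id: str | None = None,
            qualitative_cut: float = QUALITATIVE_CUT) -> Prediction:
    """Apply the linear model to one ΔE value.

    The reported value is rounded to two decimals.  Negative estimates are
    flagged qualitatively: ``"<0"`` for ``qualitative_cut ≤ value < 0`` and
    ``"<<0"`` below the cut.
    """
    raw = model.slope * float(delta_e) + model.intercept
    if raw >= 0:
        qualitative = "numeric"
    elif raw >= qualitative_cut:
        qualitative = "<0"
    else:
        qualitative = "<<0"
    return Prediction(compound_id, model.step, float(delta_e),
                      round_half_up(raw, 2), raw, qualitative)


def residual(prediction: Prediction, experimental: float | None) -> float | None:
    """Residual = experimental − predicted, to 2 decimals.

    Returns None (absent, not zero) when the experimental value is missing
    or the prediction is qualitative.
    """
    if experimental is None or prediction.qualitative != "numeric":
        return None
    return round_half_up(float(experimental) - prediction.pka_value, 2)


def external_agreement(pairs: Iterable[tuple[float, float]],
                       step: Step | None = None) -> QsarModel:
    """Regress experimental pKa on an external predictor's values.

    ``pairs`` are (external, experimental); the fitted line measures how
    faithfully the external predictor tracks experiment (slope 1, intercept
    0, R² 1 for a perfect predictor).
    """
    return fit(pairs, step)


def build_report(entries: Iterable[tuple[str, float, float | None]],
                 model: QsarModel, *,
                 qualitative_cut: float = QUALITATIVE_CUT,
                 flag_outliers: bool = False) -> pd.DataFrame:
    """One row per compound: ΔE, experimental value, estimate, residual.

    ``entries`` are (compound_id, delta_e, experimental-or-None).  The
    estimate column holds a float or a qualitative string; residuals are
    absent (None) where either value is.  With ``flag_outliers`` an extra
    boolean column marks calibration points whose studentized residual
    exceeds 2.5 in magnitude — digressions worth a second look, not
    exclusions.
    """
    rows = []
    for compound_id, delta_e, exp in entries:
        p = predict(model, delta_e, compound_id=compound_id,
                    qualitative_cut=qualitative_cut)
        calc = p.pka_value if p.qualitative == "numeric" else p.qualitative
        rows.append({"compound": compound_id, "delta_e": float(delta_e),
                     "exp": exp, "calc": calc,
                     "residual": residual(p, exp)})
    report = pd.DataFrame(rows, columns=["compound", "delta_e", "exp",
                                         "calc", "residual"])
    if flag_outliers and len(report):
        fitted = report[report["residual"].notna()]
        flags = pd.Series(False, index=report.index)
        if len(fitted) >= 4:
            t = studentized_residuals(
                list(zip(fitted["delta_e"], fitted["exp"])))
            flags.loc[fitted.index] = np.abs(t) > 2.5
        report["outlier_flag"] = flags
    return report


def report_to_csv(report: pd.DataFrame, path: str | Path) -> None:
    """Write a report with ``-`` for absent cells and 2-decimal estimates."""
    out = report.copy()

    def fmt(v, nd=2):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return "-"
        if isinstance(v, str):
            return v
        return f"{v:.{nd}f}"

    out["calc"] = [fmt(v) for v in out["calc"]]
    out["residual"] = [fmt(v) for v in out["residual"]]
    out["exp"] = [("-" if v is None or (isinstance(v, float) and math.isnan(v))
                   else repr(float(v))) for v in out["exp"]]
    out["delta_e"] = [f"{v:.0f}" for v in out["delta_e"]]
    out.to_csv(path, index=False)


def calibrate(records, step: Step, *, phase=None, policy=None,
              consolidation_policy: str = "mean",
              temperature: float = DEFAULT_TEMPERATURE_K,
              round_de_for_fit: bool = False) -> QsarModel:
    """End-to-end calibration from compound records.

    Consolidates literature values, resolves tautomer states, builds ΔE
    descriptors, and fits the model.  Compounds lacking an experimental
    value or a computable descriptor for the step are excluded from the fit
    (prediction reports still include them).  ``round_de_for_fit`` rounds
    each ΔE to the nearest integer kJ/mol before fitting, reproducing fits
    done from display-rounded tables.
    """
    from .chem_data import Phase
    from .consolidation import consolidate
    from .descriptors import compute_delta_e
    from .tautomers import TautomerPolicy

    phase = Phase.AQUEOUS if phase is None else Phase(phase)
    policy = TautomerPolicy.MOST_STABLE if policy is None else TautomerPolicy(policy)
    step = Step(step)
    points = []
    for record in records:
        values = record.literature_values(step)
        if not values or not record.has_step(step, phase):
            continue
        de = compute_delta_e(record, step, phase, policy, temperature).delta_e
        if round_de_for_fit:
            de = round_half_up(de, 0)
        points.append((de, consolidate(values, consolidation_policy,
                                       ndigits=None)))
    return fit(points, step)


def loo_residuals(points: Sequence[tuple[float, float]]) -> list[float]:
    """Leave-one-out prediction residuals y_i − ŷ_(−i), a small utility for
    judging calibration robustness."""
    pts = list(points)
    out = []
    for i in range(len(pts)):
        rest = pts[:i] + pts[i + 1:]
        m = fit(rest)
        out.append(pts[i][1] - (m.slope * pts[i][0] + m.intercept))
    return out


def studentized_residuals(points: Sequence[tuple[float, float]]) -> np.ndarray:
    """Internally studentized residuals e_i / (s·sqrt(1 − h_i))."""
    m = fit(points)
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    e = y - (m.intercept + m.slope * x)
    sxx = float(((x - x.mean()) ** 2).sum())
    h = 1.0 / len(x) + (x - x.mean()) ** 2 / sxx
    denom = m.s * np.sqrt(1.0 - h)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom > 0, e / denom, 0.0)
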