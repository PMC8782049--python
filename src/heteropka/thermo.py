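"""Gas-phase thermochemical validation.

Before trusting solution-phase energy differences as a pKa descriptor, the
underlying level of theory is checked against experimental gas-phase
deprotonation thermochemistry: the standard Gibbs energy change of
AH → A⁻ + H⁺ in vacuum (the gas-phase acidity).  From computed free
energies of the neutral and the anion,

    ΔrG° = |G°(A⁻) + G°(H⁺) − G°(AH)|,   G°(H⁺) = −26.3 kJ/mol at 298.15 K.

The magnitude is reported because tabulated gas-phase acidities are quoted
as positive ~1400–1600 kJ/mol values regardless of the direction in which
the reaction is written.  Agreement with experiment is summarised by the
squared Pearson correlation and a per-compound deviation report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chem_data import ThermoRecord

__all__ = ["G_PROTON_GAS_KJ", "UndefinedStatisticError", "reaction_drG",
           "agreement_r2", "DeviationReport", "deviation_report"]

#: Standard gas-phase Gibbs free energy of the proton at 298.15 K, kJ/mol.
G_PROTON_GAS_KJ = -26.3


class UndefinedStatisticError(ValueError):
    """Correlation is undefined (zero variance in a column)."""


def reaction_drG(g_neutral: float, g_anion: float, *,
                 g_proton: float = G_PROTON_GAS_KJ) -> float:
    """Gas-phase acidity magnitude |G°(A⁻) + G°(H⁺) − G°(AH)| in kJ/mol.

    Translation-invariant: adding any constant to both free energies leaves
    the result unchanged.
    """
    if not (math.isfinite(g_neutral) and math.isfinite(g_anion)):
        raise ValueError("free energies must be finite")
    return abs(g_anion + g_proton - g_neutral)


def agreement_r2(pairs: Iterable[tuple[float, float]]) -> float:
    """Squared Pearson correlation between experimental and calculated
    columns; scale- and shift-invariant in each column."""
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (experimental, calculated) pairs")
    x, y = arr[:, 0], arr[:, 1]
    sx = float(((x - x.mean()) ** 2).sum())
    sy = float(((y - y.mean()) ** 2).sum())
    if sx == 0.0 or sy == 0.0:
        raise UndefinedStatisticError("zero variance in one of the columns")
    sxy = float(((x - x.mean()) * (y - y.mean())).sum())
    return sxy * sxy / (sx * sy)


@dataclass(frozen=True)
class DeviationReport:
    """Signed per-compound differences calc − exp, and the worst case."""

    table: pd.DataFrame
    max_compound: str | None
    max_abs_difference: float


def deviation_report(records: Sequence[ThermoRecord]) -> DeviationReport:
    """Per-compound ΔrG° differences (calculated − experimental)."""
    rows = [{"compound": r.compound_id, "exp_drg": r.exp_drG,
             "calc_drg": r.calc_drG,
             "difference": r.calc_drG - r.exp_drG} for r in records]
    table = pd.DataFrame(rows, columns=["compound", "exp_drg", "calc_drg",
                                        "difference"])
    if not rows:
        return DeviationReport(table, None, float("nan"))
    worst = max(rows, key=lambda r: abs(r["difference"]))
    return DeviationReport(table, worst["compound"], abs(worst["difference"]))
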