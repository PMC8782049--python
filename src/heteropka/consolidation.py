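"""Consolidation of multiple literature pKa reports into one value.

Different literature sources frequently report slightly different pKa values
for the same compound and step.  Calibration needs a single experimental
value per compound, so the reports are collapsed — by default to the
arithmetic mean of the *distinct* reported numbers (the same number cited
twice counts once), computed in exact decimal arithmetic and rounded
half-up to two decimals, which is how the shipped reference tables were
assembled from their underlying literature lists.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from statistics import median
from typing import Sequence

from .chem_data import LiteraturePka

__all__ = ["ConsolidationPolicy", "consolidate"]

#: Supported consolidation policies.
ConsolidationPolicy = ("mean", "median", "first")


def _as_floats(values: Sequence[LiteraturePka] | Sequence[float]) -> list[float]:
    return [v.value if isinstance(v, LiteraturePka) else float(v)
            for v in values]


def consolidate(values: Sequence[LiteraturePka] | Sequence[float],
                policy: str = "mean", ndigits: int | None = 2) -> float | None:
    """Collapse literature pKa reports for one compound/step to one number.

    Parameters
    ----------
    values
        Literature entries (or raw floats).  An empty list returns ``None``
        (the no-data sentinel).
    policy
        ``"mean"`` (default) — arithmetic mean of the distinct values;
        ``"median"`` — median of the distinct values;
        ``"first"`` — the first value in citation order.
    ndigits
        Decimals to keep, rounding exact decimal ties half-up (away from
        zero).  ``None`` keeps full precision — used inside the calibration
        pipeline, where rounding is a display concern only.

    The result always lies within [min, max] of the inputs and does not
    depend on their order (except under ``policy="first"``).
    """
    floats = _as_floats(values)
    if not floats:
        return None
    if policy == "first":
        out = Decimal(repr(floats[0]))
    else:
        # Exact decimal arithmetic on the printed numbers: 9.755-type ties
        # must be genuine ties, not float artefacts.
        distinct = sorted({repr(v) for v in floats}, key=float)
        decimals = [Decimal(d) for d in distinct]
        if policy == "mean":
            out = sum(decimals) / len(decimals)
        elif policy == "median":
            out = median(decimals)
        else:
            raise ValueError(f"unknown consolidation policy {policy!r}")
    if ndigits is not None:
        out = out.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP)
    return float(out)
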