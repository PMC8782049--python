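"""Tautomer-state resolution.

Many of the heterocycles treated here exist in solution as an ensemble of
tautomers for each charge state (uracil, for instance, has three cationic,
six neutral, and two anionic forms).  The default protocol represents each
compound/charge state by its single most stable tautomer — justified when
the energy gap to the next tautomer is large (the working threshold is
25 kJ/mol).  A Boltzmann-weighted effective energy is available as an
opt-in alternative for sensitivity analysis of that approximation.
"""

from __future__ import annotations

import math
import warnings
from enum import Enum
from typing import Sequence

from .chem_data import Microstate

__all__ = [
    "R_KJ_PER_MOL_K",
    "DEFAULT_TEMPERATURE_K",
    "GAP_WARNING_THRESHOLD_KJ",
    "TautomerPolicy",
    "MissingStateError",
    "SmallGapWarning",
    "select_representative",
    "energy_gap",
    "boltzmann_effective_energy",
    "effective_energy",
]

#: Molar gas constant, kJ/(mol K).
R_KJ_PER_MOL_K = 8.31446e-3
#: Default thermodynamic temperature, K.
DEFAULT_TEMPERATURE_K = 298.15
#: Gap below which the most-stable-tautomer approximation is flagged.
GAP_WARNING_THRESHOLD_KJ = 25.0


class TautomerPolicy(str, Enum):
    """How a tautomer ensemble is collapsed to one energy."""

    MOST_STABLE = "most_stable"
    BOLTZMANN = "boltzmann"


class MissingStateError(ValueError):
    """Raised when a required compound/charge state has no microstates."""


class SmallGapWarning(UserWarning):
    """The gap between the two lowest tautomers is below the threshold, so
    the most-stable-tautomer approximation may be questionable."""


def _validate_ensemble(microstates: Sequence[Microstate]) -> None:
    if not microstates:
        raise MissingStateError("empty tautomer ensemble")
    first = microstates[0]
    for m in microstates[1:]:
        if (m.compound_id, m.charge, m.phase) != (
                first.compound_id, first.charge, first.phase):
            raise ValueError(
                "ensemble mixes compounds/charges/phases: "
                f"{(m.compound_id, m.charge, m.phase)} vs "
                f"{(first.compound_id, first.charge, first.phase)}")


def select_representative(microstates: Sequence[Microstate]) -> Microstate:
    """Return the most stable tautomer of one compound/charge/phase ensemble.

    Exact energy ties are broken by the lexicographically smallest
    ``tautomer_id`` so the choice is deterministic and independent of input
    order.
    """
    _validate_ensemble(microstates)
    return min(microstates, key=lambda m: (m.energy, m.tautomer_id))


def energy_gap(microstates: Sequence[Microstate], *,
               warn_threshold: float = GAP_WARNING_THRESHOLD_KJ) -> float:
    """Energy gap (kJ/mol) between the two most stable tautomers.

    Returns ``math.inf`` for a single-tautomer ensemble.  Emits
    :class:`SmallGapWarning` when the gap is at or below ``warn_threshold``.
    """
    _validate_ensemble(microstates)
    if len(microstates) == 1:
        return math.inf
    energies = sorted(m.energy for m in microstates)
    gap = energies[1] - energies[0]
    if gap <= warn_threshold:
        m = microstates[0]
        warnings.warn(
            f"{m.compound_id} (charge {m.charge:+d}, {m.phase.value}): "
            f"tautomer gap {gap:.1f} kJ/mol <= {warn_threshold:g} kJ/mol; "
            "the most-stable-tautomer approximation may be inaccurate",
            SmallGapWarning, stacklevel=2)
    return gap


def boltzmann_effective_energy(
        microstates: Sequence[Microstate],
        temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """Ensemble free energy −RT·ln Σᵢ exp(−Eᵢ/RT), in kJ/mol.

    Computed with the energies shifted by their minimum for numerical
    stability; always ≤ the minimum energy, approaching it as the gaps to
    the higher tautomers grow.
    """
    _validate_ensemble(microstates)
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    rt = R_KJ_PER_MOL_K * temperature
    e_min = min(m.energy for m in microstates)
    z = sum(math.exp(-(m.energy - e_min) / rt) for m in microstates)
    return e_min - rt * math.log(z)


def effective_energy(microstates: Sequence[Microstate],
                     policy: TautomerPolicy = TautomerPolicy.MOST_STABLE,
                     temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """Collapse an ensemble to one energy under the given policy."""
    policy = TautomerPolicy(policy)
    if policy is TautomerPolicy.MOST_STABLE:
        return select_representative(microstates).energy
    return boltzmann_effective_energy(microstates, temperature)
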