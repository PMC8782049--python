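"""The ΔE dissociation descriptor.

The single regression descriptor of the model is the electronic energy
difference between a compound's deprotonated product and its parent species,
both represented by their resolved tautomer state in the same phase:

* pKa1 (cation → neutral):  ΔE = E(AH) − E(AH₂⁺)
* pKa2 (neutral → anion):   ΔE = E(A⁻) − E(AH)

In aqueous solution (continuum solvent energies) this quantity correlates
linearly with the measured pKa; in the gas phase the same construction is
available via the phase flag for comparison.  Full floating-point precision
is carried internally; ΔE is rounded to whole kJ/mol only for display.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .chem_data import (DEPROTONATED_CHARGE, PROTONATED_CHARGE,
                        CompoundRecord, Phase, Step)
from .tautomers import (DEFAULT_TEMPERATURE_K, MissingStateError,
                        TautomerPolicy, effective_energy,
                        select_representative)

__all__ = ["DissociationDescriptor", "compute_delta_e",
           "write_descriptors", "read_descriptors"]


@dataclass(frozen=True)
class DissociationDescriptor:
    """ΔE (kJ/mol) for one dissociation step of one compound in one phase."""

    compound_id: str
    step: Step
    phase: Phase
    delta_e: float
    parent_tautomer: str
    product_tautomer: str


def compute_delta_e(record: CompoundRecord, step: Step,
                    phase: Phase = Phase.AQUEOUS,
                    policy: TautomerPolicy = TautomerPolicy.MOST_STABLE,
                    temperature: float = DEFAULT_TEMPERATURE_K,
                    ) -> DissociationDescriptor:
    """Build the ΔE descriptor for ``record`` and ``step``.

    Both charge states required by the step must have at least one
    microstate in ``phase``; otherwise :class:`MissingStateError` is raised
    (a compound is never silently dropped).  The parent/product tautomer ids
    recorded are the most stable tautomer of each state; under the Boltzmann
    policy the *energies* are ensemble-effective while the labels still name
    the dominant form.
    """
    step, phase = Step(step), Phase(phase)
    parent = record.microstates_for(PROTONATED_CHARGE[step], phase)
    product = record.microstates_for(DEPROTONATED_CHARGE[step], phase)
    for states, charge in ((parent, PROTONATED_CHARGE[step]),
                           (product, DEPROTONATED_CHARGE[step])):
        if not states:
            raise MissingStateError(
                f"{record.compound_id}: no {phase.value} microstate with "
                f"charge {charge:+d} (required for {step.value})")
    delta = (effective_energy(product, policy, temperature)
             - effective_energy(parent, policy, temperature))
    return DissociationDescriptor(
        record.compound_id, step, phase, delta,
        select_representative(parent).tautomer_id,
        select_representative(product).tautomer_id)


DESCRIPTOR_COLUMNS = ["compound_id", "step", "phase", "delta_e",
                      "parent_tautomer", "product_tautomer"]


def write_descriptors(descriptors: Sequence[DissociationDescriptor],
                      path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(DESCRIPTOR_COLUMNS)
        for d in descriptors:
            w.writerow([d.compound_id, d.step.value, d.phase.value,
                        repr(d.delta_e), d.parent_tautomer,
                        d.product_tautomer])


def read_descriptors(path: str | Path) -> list[DissociationDescriptor]:
    with open(path, newline="", encoding="utf-8") as fh:
        return [DissociationDescriptor(
            row["compound_id"], Step(row["step"]), Phase(row["phase"]),
            float(row["delta_e"]), row["parent_tautomer"],
            row["product_tautomer"]) for row in csv.DictReader(fh)]
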