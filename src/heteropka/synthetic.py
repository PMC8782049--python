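"""Synthetic compound datasets with the statistical structure the analysis
assumes.

No energies or raw measurements are deposited with the reference tables, so
every pipeline stage must be testable on generated data.  The generator
emulates exactly the structure the method relies on:

* a true linear free-energy relationship pKa = slope·ΔE + intercept, with
  ΔE drawn uniformly over the aqueous descriptor range of the reference
  tables (default −1254 … −872 kJ/mol);
* Gaussian observation noise on the "true" pKa (default sd 1.25, the
  residual scatter of the reference pKa1 calibration);
* tautomer ensembles per charge state whose representative-state energy
  difference equals the drawn ΔE exactly, with the remaining tautomers
  offset upward by exponential gaps (default mean 30 kJ/mol, consistent
  with the >25 kJ/mol gaps typical of these compounds);
* 1–3 literature replicates per compound scattered around the observed
  value (default sd 0.1, the spread of repeated literature reports).

Energy baselines are drawn in an arbitrary window since only differences
enter the analysis — the pipeline is translation-invariant in the energies.
All randomness flows from a single seeded generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .chem_data import (DEPROTONATED_CHARGE, PROTONATED_CHARGE,
                        CompoundRecord, LiteraturePka, Microstate, Phase,
                        Step)

__all__ = ["SimulationParams", "SimulatedDataset", "simulate_dataset",
           "perturb_tautomer_gap"]


@dataclass(frozen=True)
class SimulationParams:
    n_compounds: int = 17
    slope: float = -0.131
    intercept: float = -151.54
    noise_sd: float = 1.25
    de_range: tuple[float, float] = (-1254.0, -872.0)
    n_tautomers: tuple[int, int] = (1, 4)
    gap_scale: float = 30.0
    replicate_sd: float = 0.1
    seed: int = 0
    step: Step = Step.PKA1
    phase: Phase = Phase.AQUEOUS


@dataclass(frozen=True)
class SimulatedDataset:
    """Generated records plus the ground truth they were built from."""

    records: list[CompoundRecord]
    truth: pd.DataFrame  # compound_id, delta_e, pka_true, pka_observed
    params: SimulationParams


def _ensemble(rng: np.random.Generator, compound_id: str, charge: int,
              phase: Phase, e_representative: float, k: int,
              gap_scale: float) -> list[Microstate]:
    """Build k tautomers whose minimum energy is exactly e_representative."""
    states = [Microstate(compound_id, charge, "t01", phase, e_representative)]
    if k > 1:
        offsets = rng.exponential(gap_scale, size=k - 1)
        states += [Microstate(compound_id, charge, f"t{j + 2:02d}", phase,
                              e_representative + float(off))
                   for j, off in enumerate(offsets)]
    return states


def simulate_dataset(n_compounds: int = 17, slope: float = -0.131,
                     intercept: float = -151.54, noise_sd: float = 1.25,
                     de_range: tuple[float, float] = (-1254.0, -872.0),
                     n_tautomers: tuple[int, int] = (1, 4),
                     gap_scale: float = 30.0, replicate_sd: float = 0.1,
                     seed: int | None = None, step: Step = Step.PKA1,
                     phase: Phase = Phase.AQUEOUS) -> SimulatedDataset:
    """Generate a synthetic compound dataset; fully reproducible per seed."""
    if seed is None:
        raise ValueError("a seed is required; the generator has no global state")
    if n_compounds < 3:
        raise ValueError("need at least 3 compounds")
    lo, hi = de_range
    if not (lo < hi):
        raise ValueError(f"invalid de_range {de_range}")
    if noise_sd < 0 or replicate_sd < 0:
        raise ValueError("noise_sd and replicate_sd must be non-negative")
    kmin, kmax = n_tautomers
    if not (1 <= kmin <= kmax):
        raise ValueError(f"invalid n_tautomers {n_tautomers}")
    if gap_scale <= 0:
        raise ValueError("gap_scale must be positive")
    step, phase = Step(step), Phase(phase)
    params = SimulationParams(n_compounds, slope, intercept, noise_sd,
                              (float(lo), float(hi)), (kmin, kmax),
                              gap_scale, replicate_sd, seed, step, phase)
    rng = np.random.default_rng(seed)
    width = max(3, len(str(n_compounds)))
    records, truth_rows = [], []
    for i in range(n_compounds):
        cid = f"cmpd-{i:0{width}d}"
        de = float(rng.uniform(lo, hi))
        e_parent = float(rng.uniform(-6000.0, -4000.0))
        e_product = e_parent + de  # ΔE = E(product) − E(parent)
        k_parent, k_product = rng.integers(kmin, kmax + 1, size=2)
        microstates = (
            _ensemble(rng, cid, PROTONATED_CHARGE[step], phase, e_parent,
                      int(k_parent), gap_scale)
            + _ensemble(rng, cid, DEPROTONATED_CHARGE[step], phase, e_product,
                        int(k_product), gap_scale))
        pka_true = slope * de + intercept
        pka_obs = pka_true + float(rng.normal(0.0, noise_sd)) if noise_sd else pka_true
        n_rep = int(rng.integers(1, 4))
        reps = [pka_obs + (float(rng.normal(0.0, replicate_sd))
                           if replicate_sd else 0.0) for _ in range(n_rep)]
        literature = [LiteraturePka(cid, step, v, f"sim-{j + 1}")
                      for j, v in enumerate(reps)]
        records.append(CompoundRecord(cid, microstates=microstates,
                                      literature=literature))
        truth_rows.append({"compound_id": cid, "delta_e": de,
                           "pka_true": pka_true, "pka_observed": pka_obs})
    return SimulatedDataset(records, pd.DataFrame(truth_rows), params)


def perturb_tautomer_gap(dataset: SimulatedDataset,
                         new_gap_scale: float) -> SimulatedDataset:
    """Rescale all inter-tautomer gaps to a new mean gap scale.

    Representative (minimum) energies are untouched, so descriptors under
    the most-stable policy are invariant; Boltzmann-policy descriptors shift
    by a bounded amount that vanishes as the gaps grow.  ``math.inf``
    pushes every non-representative tautomer infinitely high (the
    most-stable limit).
    """
    if not (new_gap_scale > 0):
        raise ValueError("gap scale must be positive")
    factor = new_gap_scale / dataset.params.gap_scale
    records = []
    for record in dataset.records:
        groups: dict[tuple[int, Phase], list[Microstate]] = {}
        for m in record.microstates:
            groups.setdefault((m.charge, m.phase), []).append(m)
        new_states = []
        for states in groups.values():
            e_min = min(s.energy for s in states)
            for s in states:
                offset = s.energy - e_min
                if offset == 0.0:
                    new_states.append(s)
                else:
                    new_e = e_min + offset * factor
                    if math.isinf(new_e):  # most-stable limit: weight 0
                        new_e = e_min + 1e9
                    new_states.append(replace(s, energy=new_e))
        records.append(replace_record(record, new_states))
    params = replace(dataset.params, gap_scale=(
        new_gap_scale if math.isfinite(new_gap_scale) else new_gap_scale))
    return SimulatedDataset(records, dataset.truth, params)


def replace_record(record: CompoundRecord,
                   microstates: Sequence[Microstate]) -> CompoundRecord:
    return CompoundRecord(record.compound_id, record.name, record.formula,
                          list(microstates), list(record.literature),
                          list(record.external), dict(record.availability))
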