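"""Discrete-time simulation of a virtual (predicted) control arm.

Each enrolled patient's corrected 15-year survival prediction is spread over
years by a reference mortality fraction, giving conditional death
probabilities q_1..q_H.  The patient is then simulated forward one year at a
time: draw X_t ~ Uniform(0,1); death in year t if X_t < q_t, otherwise
continue; surviving all H years yields administrative censoring at the
horizon.  Pooling the simulated times over the cohort gives the virtual
arm, which is analysed with the same Kaplan-Meier machinery as the observed
arm.

Randomness is reproducible and order-invariant: one master seed spawns a
substream per (replicate, patient), keyed by a stable hash of the patient id,
so permuting the cohort does not change any patient's simulated outcome.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .calibration import CorrectionTable, apply_correction
from .cohort import EVENT_CENSORED, EVENT_DEATH, PatientRecord
from .fractions import MortalityFraction, YearlySchedule, allocate_schedule


@dataclass(frozen=True)
class SimulatedOutcome:
    """One simulated follow-up: death in year ``sim_time`` or censoring at H."""

    patient_id: str
    sim_time: int
    sim_event: int  # 1 = death, 0 = censored (only at the horizon)
    replicate_id: int = 0


def _patient_key(patient_id: str) -> int:
    """Stable 64-bit key for a patient id (independent of PYTHONHASHSEED)."""
    digest = hashlib.sha256(patient_id.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "big")


def patient_rng(seed: int, patient_id: str, replicate: int = 0) -> np.random.Generator:
    """Per-patient random stream derived from the master seed."""
    ss = np.random.SeedSequence([int(seed), int(replicate), _patient_key(patient_id)])
    return np.random.default_rng(ss)


def simulate_patient(
    schedule: YearlySchedule, rng: np.random.Generator
) -> tuple[int, int]:
    """Simulate one patient's survival time against a yearly schedule.

    Returns ``(time, event)``: death in the first year t with X_t < q_t, or
    censoring at the horizon.  Exactly min(time, H) uniforms are consumed.
    """
    for t in range(1, schedule.horizon + 1):
        if rng.random() < schedule.q[t - 1]:
            return t, EVENT_DEATH
    return schedule.horizon, EVENT_CENSORED


def simulate_arm(
    cohort: Sequence[PatientRecord],
    table: CorrectionTable,
    mf: MortalityFraction,
    seed: int,
    replicates: int = 1,
    fallback_overall: bool = False,
) -> list[SimulatedOutcome]:
    """Simulate the virtual control arm for a cohort.

    One outcome per patient per replicate, in cohort order within each
    replicate.  Deterministic given the seed, and each patient's outcome is
    invariant to the cohort's row order (per-patient substreams).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    schedules = {}
    outcomes: list[SimulatedOutcome] = []
    for rep in range(replicates):
        for rec in cohort:
            s15 = apply_correction(rec, table, fallback_overall=fallback_overall)
            key = round(s15, 15)
            sched = schedules.get(key)
            if sched is None:
                sched = allocate_schedule(s15, mf)
                schedules[key] = sched
            rng = patient_rng(seed, rec.patient_id, replicate=rep)
            time, event = simulate_patient(sched, rng)
            outcomes.append(
                SimulatedOutcome(
                    patient_id=rec.patient_id,
                    sim_time=time,
                    sim_event=event,
                    replicate_id=rep,
                )
            )
    return outcomes


def outcomes_to_records(
    outcomes: Sequence[SimulatedOutcome],
    cohort: Sequence[PatientRecord],
    replicate: int = 0,
) -> list[PatientRecord]:
    """Cast one replicate's simulated outcomes into the cohort record schema.

    The virtual arm then flows through the same I/O and Kaplan-Meier code
    paths as an observed arm (followup_years = sim_time, event = sim_event).
    """
    by_id = {rec.patient_id: rec for rec in cohort}
    records = []
    for out in outcomes:
        if out.replicate_id != replicate:
            continue
        src = by_id[out.patient_id]
        records.append(
            replace(
                src,
                followup_years=float(out.sim_time),
                event=out.sim_event,
            )
        )
    return records
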