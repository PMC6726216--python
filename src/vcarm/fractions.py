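"""Yearly mortality fractions and allocation of a 15-year survival prediction.

A mortality fraction f_1..f_H distributes a cohort's total horizon mortality
over the years of follow-up: f_t is the share of all deaths through year H
that occur in year t, computed from a reference yearly survival curve as

    f_t = (S_ref(t-1) - S_ref(t)) / (1 - S_ref(H)),

so the fractions are nonnegative and sum to 1.  Given a patient's corrected
horizon survival probability s15, the allocated yearly survival is

    S_t = 1 - (1 - s15) * sum_{i<=t} f_i,

with S_H = s15 exactly, and the conditional death probabilities
q_t = (S_{t-1} - S_t) / S_{t-1} drive the discrete-time simulation.

Two reference fixtures ship with the package, both derived from the SEER
breast-cancer cohort diagnosed 1993-1996: all cases, and the subset matching
the analysis population (non-ER+/PR+, ages 20-60, stage II/III).  The subset
is the pipeline default.  The printed subset fractions sum to 1.001 under
rounding and are renormalised on load (logged); the raw printed values stay
available as ``raw_fractions``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .km import km_curve

logger = logging.getLogger(__name__)

_SUM_TOL = 1e-9


class FractionError(Exception):
    """Invalid reference curve or fraction vector."""


@dataclass
class MortalityFraction:
    """Yearly shares of total horizon mortality, summing to 1.

    ``fractions`` has length ``horizon`` (f_1..f_H).  ``raw_fractions``
    preserves pre-renormalisation values when the vector was loaded from a
    rounded published table.
    """

    fractions: np.ndarray
    provenance: str = ""
    raw_fractions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if np.any(self.fractions < 0):
            raise FractionError("mortality fractions must be nonnegative")
        if abs(self.fractions.sum() - 1.0) > _SUM_TOL:
            raise FractionError(
                f"fractions sum to {self.fractions.sum():.6f}, expected 1"
            )

    @property
    def horizon(self) -> int:
        return int(self.fractions.size)

    @property
    def cumulative(self) -> np.ndarray:
        """Cumulative shares F_0..F_H with F_0 = 0, F_H = 1."""
        return np.concatenate([[0.0], np.cumsum(self.fractions)])

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            if self.provenance:
                fh.write(f"# provenance: {self.provenance}\n")
            pd.DataFrame(
                {"year": np.arange(1, self.horizon + 1), "fraction": self.fractions}
            ).to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "MortalityFraction":
        frame = pd.read_csv(path, comment="#")
        frame = frame.sort_values("year")
        return from_values(frame["fraction"].to_numpy(), provenance=str(path))


def from_values(
    values, provenance: str = "", renormalize: bool = True
) -> MortalityFraction:
    """Build a :class:`MortalityFraction` from (possibly rounded) values.

    Published tables print rounded fractions whose sum can miss 1 by a few
    thousandths; with ``renormalize`` the vector is rescaled to sum exactly
    to 1 (required for the allocation identity S_H = s15) and the event is
    logged.  Without it, an off-by-rounding sum raises.
    """
    raw = np.asarray(values, dtype=float)
    if np.any(raw < 0):
        raise FractionError("mortality fractions must be nonnegative")
    total = raw.sum()
    if total <= 0:
        raise FractionError("fractions sum to zero")
    if abs(total - 1.0) <= _SUM_TOL:
        return MortalityFraction(raw, provenance=provenance)
    if not renormalize:
        raise FractionError(f"fractions sum to {total:.6f} and renormalize=False")
    logger.info(
        "renormalising mortality fractions (%s): printed sum %.4f -> 1",
        provenance or "unnamed", total,
    )
    return MortalityFraction(raw / total, provenance=provenance, raw_fractions=raw)


def compute_fractions(
    reference_survival, provenance: str = ""
) -> MortalityFraction:
    """Mortality fractions from a reference yearly survival curve S(0..H).

    Requires S(0) = 1, S nonincreasing, S(H) < 1.  The result satisfies
    sum f_t = 1 exactly and, composed with :func:`allocate_schedule` at
    s15 = S(H), reproduces the reference curve.
    """
    s = np.asarray(reference_survival, dtype=float)
    if s.ndim != 1 or s.size < 2:
        raise FractionError("reference curve needs S(0)..S(H), H >= 1")
    if s[0] != 1.0:
        raise FractionError(f"S(0) must be 1, got {s[0]}")
    if np.any(np.diff(s) > 0):
        raise FractionError("reference survival must be nonincreasing")
    total_mortality = 1.0 - s[-1]
    if total_mortality <= 0.0:
        raise FractionError("reference cohort has zero mortality at the horizon")
    fractions = -np.diff(s) / total_mortality
    return MortalityFraction(fractions, provenance=provenance)


def fractions_from_cohort(
    times, events, horizon: int = 15, provenance: str = ""
) -> MortalityFraction:
    """Mortality fractions from patient-level reference follow-up data.

    Fits a Kaplan-Meier curve on the yearly grid 0..horizon and applies
    :func:`compute_fractions`.
    """
    curve = km_curve(times, events, eval_times=np.arange(0.0, horizon + 1.0))
    return compute_fractions(curve.estimates, provenance=provenance)


# ---------------------------------------------------------------------------
# Allocation
# ---------------------------------------------------------------------------

@dataclass
class YearlySchedule:
    """Allocated yearly survival S_0..S_H and conditional death probabilities.

    q_t is the probability of death in year t given survival to year t-1;
    reconstructing S from q recovers S exactly.
    """

    survival: np.ndarray  # length H + 1, S_0 = 1
    q: np.ndarray = field(init=False)  # length H

    def __post_init__(self) -> None:
        s = np.asarray(self.survival, dtype=float)
        prev = s[:-1]
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.where(prev > 0, (prev - s[1:]) / prev, 1.0)
        self.survival = s
        self.q = np.clip(q, 0.0, 1.0)

    @property
    def horizon(self) -> int:
        return int(self.q.size)


def allocate_schedule(corrected_s15: float, mf: MortalityFraction) -> YearlySchedule:
    """Spread a corrected horizon survival over years via a mortality fraction.

    S_t = 1 - (1 - corrected_s15) * F_t with F_t the cumulative fraction;
    S_H equals ``corrected_s15`` exactly.
    """
    if not 0.0 <= corrected_s15 <= 1.0:
        raise FractionError(f"corrected_s15 {corrected_s15} outside [0, 1]")
    survival = 1.0 - (1.0 - corrected_s15) * mf.cumulative
    survival[-1] = corrected_s15  # exact despite floating accumulation
    return YearlySchedule(survival=survival)


# ---------------------------------------------------------------------------
# Packaged SEER reference fixtures (breast cancer, diagnosed 1993-1996)
# ---------------------------------------------------------------------------

#: all SEER breast-cancer cases (n = 92,701); 15-year KM survival 0.478
SEER_ALL_CASES_FRACTIONS = (
    0.103, 0.103, 0.095, 0.086, 0.077, 0.067, 0.064, 0.060,
    0.056, 0.054, 0.053, 0.049, 0.047, 0.044, 0.042,
)
SEER_ALL_CASES_S15 = 0.478

#: non-ER+/PR+, ages 20-60, stage II/III subset (n = 7,139); 15-year KM 0.556
SEER_SUBSET_FRACTIONS = (
    0.064, 0.198, 0.155, 0.128, 0.084, 0.065, 0.050, 0.045,
    0.036, 0.032, 0.029, 0.030, 0.036, 0.025, 0.024,
)
SEER_SUBSET_S15 = 0.556


def seer_all_cases() -> MortalityFraction:
    """Reference fractions for all SEER 1993-1996 breast-cancer cases."""
    return from_values(
        SEER_ALL_CASES_FRACTIONS,
        provenance="SEER 1993-1996 breast cancer, all cases (n=92701)",
    )


def seer_subset() -> MortalityFraction:
    """Reference fractions for the analysis-matched SEER subset (default).

    Non-ER+/PR+, ages 20-60, stage II/III.  The printed values sum to 1.001
    and are renormalised on load.
    """
    return from_values(
        SEER_SUBSET_FRACTIONS,
        provenance=(
            "SEER 1993-1996 breast cancer, non-ER+/PR+ ages 20-60 "
            "stage II/III subset (n=7139)"
        ),
    )
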