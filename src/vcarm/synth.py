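"""Synthetic two-arm trial generator with known ground truth.

Emulates the structure of large adjuvant breast-cancer trials used for
virtual-control-arm studies: ages 20-59, hormone-receptor combinations
excluding ER+/PR+, a standard-of-care arm ("AC") and an experimental arm
("AC+P"), 15 years of follow-up with yearly dropout, and a deliberately
miscalibrated baseline predictor.

Ground truth is discrete-time: each subgroup g has a true 15-year survival
s_g spread over years by a mortality-fraction vector, giving conditional
death probabilities q_{g,t}.  The experimental arm applies a discrete-time
proportional-hazards multiplier, q'_t = 1 - (1 - q_t)^hr, so a virtual
control built from standard-of-care predictions is wrong for that arm in
exactly the way the design exploits.  The baseline predictor emits
clip(s_g / c_g + eps, 0, 1) with eps ~ Normal(0, sigma): dividing by the
subgroup miscalibration factor c_g makes c_g the correction a calibration
stage should recover.

Defaults mirror the training trial's published subgroup sizes and observed
15-year survival and the SEER-subset mortality fractions; arm size defaults
to the validation trial's ~680 per arm.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cohort import ALL_SUBGROUPS, EVENT_CENSORED, EVENT_DEATH, PatientRecord, Subgroup
from .fractions import MortalityFraction, allocate_schedule, seer_subset

#: published training-trial subgroup sizes, in ALL_SUBGROUPS order
#: (20-39 then 40-59; ER-/PR-, ER+/PR-, ER-/PR+ within each band)
DEFAULT_SUBGROUP_N = (250, 70, 61, 634, 295, 140)
#: observed 15-year survival per subgroup in the training trial
DEFAULT_S_TRUE = (0.527, 0.337, 0.508, 0.488, 0.413, 0.529)
#: published multiplier corrections, reused as true miscalibration factors
DEFAULT_C_G = (0.808, 0.540, 0.755, 0.809, 0.723, 0.791)

_TOTAL_N = sum(DEFAULT_SUBGROUP_N)


class SynthError(Exception):
    """Invalid ground-truth configuration."""


@dataclass
class TruthConfig:
    """Ground truth for a synthetic trial.

    hr is the experimental arm's discrete-time hazard multiplier (1 = no
    treatment effect; 0.7 mirrors a paclitaxel-sized benefit).  dropout is a
    yearly independent censoring probability; 0.03/year reproduces the
    published at-risk attrition beyond deaths.  sigma is the predictor's
    additive per-patient noise SD.
    """

    n_per_arm: int = 680
    n_training: int = 1450
    mix: tuple = tuple(n / _TOTAL_N for n in DEFAULT_SUBGROUP_N)
    s_true: tuple = DEFAULT_S_TRUE
    fractions: MortalityFraction = field(default_factory=seer_subset)
    hr: float = 0.7
    c_g: tuple = DEFAULT_C_G
    sigma: float = 0.02
    dropout: float = 0.03
    seed: int = 0
    control_arm: str = "AC"
    experimental_arm: str = "AC+P"
    horizon: int = 15

    def __post_init__(self) -> None:
        if abs(sum(self.mix) - 1.0) > 1e-9:
            raise SynthError("subgroup mixing proportions must sum to 1")
        if len(self.mix) != 6 or len(self.s_true) != 6 or len(self.c_g) != 6:
            raise SynthError("mix, s_true and c_g must have one entry per subgroup")
        if not all(0.0 < s < 1.0 for s in self.s_true):
            raise SynthError("s_true values must lie in (0, 1)")
        if self.hr <= 0:
            raise SynthError("hr must be positive")
        if not all(c > 0 for c in self.c_g):
            raise SynthError("miscalibration factors must be positive")
        if not 0.0 <= self.dropout <= 1.0:
            raise SynthError("dropout must be a probability")
        if self.fractions.horizon != self.horizon:
            raise SynthError("mortality-fraction horizon does not match config")


_BANDS = {"20-39": (20, 39), "40-59": (40, 59)}


def _true_q(config: TruthConfig, arm: str) -> np.ndarray:
    """Conditional yearly death probabilities, one row per subgroup."""
    q = np.empty((6, config.horizon))
    for g, s in enumerate(config.s_true):
        q[g] = allocate_schedule(s, config.fractions).q
    if arm == config.experimental_arm:
        q = 1.0 - (1.0 - q) ** config.hr
    return q


def _stream(config: TruthConfig, arm: str, label: str) -> np.random.Generator:
    key = int.from_bytes(
        hashlib.sha256(f"{arm}|{label}".encode("utf-8")).digest()[:8], "big"
    )
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), key]))


def generate_cohort(
    config: TruthConfig,
    arm: str,
    n: int | None = None,
    label: str = "",
) -> list[PatientRecord]:
    """Draw a synthetic cohort for one arm.

    Subgroups follow the mixing proportions; ages are uniform integers within
    the subgroup's band; the true death year comes from the same sequential
    yearly mechanism as the virtual-arm simulator using the arm-adjusted
    q'_t; dropout censors independently each year (deaths within a year take
    precedence over end-of-year dropout); survivors are censored at the
    horizon.  ``label`` separates random streams of otherwise identical
    cohorts (e.g. training vs validation).
    """
    if arm not in (config.control_arm, config.experimental_arm):
        raise SynthError(f"unknown arm {arm!r}")
    if n is None:
        n = config.n_per_arm
    rng = _stream(config, arm, label)
    q = _true_q(config, arm)

    g = rng.choice(6, size=n, p=np.asarray(config.mix))
    lows = np.array([_BANDS[sg.age_band][0] for sg in ALL_SUBGROUPS])
    highs = np.array([_BANDS[sg.age_band][1] for sg in ALL_SUBGROUPS])
    ages = rng.integers(lows[g], highs[g] + 1)

    H = config.horizon
    u_death = rng.random((n, H))
    death_hit = u_death < q[g]
    any_death = death_hit.any(axis=1)
    death_year = np.where(any_death, death_hit.argmax(axis=1) + 1, H + 1)

    u_drop = rng.random((n, H))
    drop_hit = u_drop < config.dropout
    any_drop = drop_hit.any(axis=1)
    drop_year = np.where(any_drop, drop_hit.argmax(axis=1) + 1, H + 1)

    # death during year t precedes that year's end-of-year dropout
    died = any_death & (death_year <= drop_year) & (death_year <= H)
    followup = np.minimum(np.minimum(death_year, drop_year), H)

    eps = rng.normal(0.0, config.sigma, size=n)
    s_true = np.asarray(config.s_true)[g]
    c = np.asarray(config.c_g)[g]
    predicted = np.clip(s_true / c + eps, 0.0, 1.0)

    prefix = f"{label}-" if label else ""
    records = []
    for i in range(n):
        sg: Subgroup = ALL_SUBGROUPS[g[i]]
        er = "positive" if sg.receptor_class.startswith("ER+") else "negative"
        pr = "positive" if sg.receptor_class.endswith("PR+") else "negative"
        records.append(
            PatientRecord(
                patient_id=f"{prefix}{arm}-{i:06d}",
                age=int(ages[i]),
                er_status=er,
                pr_status=pr,
                arm=arm,
                followup_years=float(followup[i]),
                event=EVENT_DEATH if died[i] else EVENT_CENSORED,
                predicted_s15=float(predicted[i]),
            )
        )
    return records


def true_curve(config: TruthConfig, arm: str) -> dict:
    """Analytic yearly survival per subgroup and pooled (no sampling).

    Returns ``{"subgroups": {Subgroup: S_0..S_H}, "pooled": S_0..S_H}`` where
    the pooled curve is the mixing-proportion-weighted average of the
    subgroup curves.
    """
    if arm not in (config.control_arm, config.experimental_arm):
        raise SynthError(f"unknown arm {arm!r}")
    q = _true_q(config, arm)
    surv = np.concatenate(
        [np.ones((6, 1)), np.cumprod(1.0 - q, axis=1)], axis=1
    )
    pooled = np.asarray(config.mix) @ surv
    return {
        "subgroups": {sg: surv[i] for i, sg in enumerate(ALL_SUBGROUPS)},
        "pooled": pooled,
    }


def generate_trial(
    config: TruthConfig,
) -> tuple[list[PatientRecord], list[PatientRecord]]:
    """Training cohort (standard of care) plus two-arm validation cohort.

    The training cohort has ``n_training`` patients, all under standard of
    care; the validation cohort pools ``n_per_arm`` patients per arm.
    """
    training = generate_cohort(
        config, config.control_arm, n=config.n_training, label="train"
    )
    validation = generate_cohort(
        config, config.control_arm, label="valid"
    ) + generate_cohort(config, config.experimental_arm, label="valid")
    return training, validation
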