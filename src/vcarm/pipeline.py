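"""End-to-end library pipeline helpers.

`run_synthetic_trial` wires the full method together on generated data:
draw a training trial and a two-arm validation trial from a ground-truth
config, fit subgroup corrections on the training cohort, simulate each
validation arm's virtual control, and compare observed vs virtual
Kaplan-Meier curves year by year.  Used for operating-characteristic
studies (type-I error and power of the yearly Z comparisons) and as the
worked example of the library API.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calibration import fit_corrections
from .cohort import apply_exclusions, split_by_arm
from .km import compare_arms_by_year, km_curve
from .simulate import outcomes_to_records, simulate_arm
from .synth import TruthConfig, generate_trial


def compare_observed_vs_virtual(
    patients,
    table,
    mf,
    seed: int,
    horizon: int = 15,
    z_crit: float = 1.96,
) -> pd.DataFrame:
    """Simulate the virtual arm for ``patients`` and compare per year."""
    outcomes = simulate_arm(patients, table, mf, seed=seed)
    virtual = outcomes_to_records(outcomes, patients)
    grid = np.arange(0.0, horizon + 1.0)
    observed_curve = km_curve(
        [p.followup_years for p in patients],
        [p.event for p in patients],
        eval_times=grid,
        z_crit=z_crit,
    )
    virtual_curve = km_curve(
        [p.followup_years for p in virtual],
        [p.event for p in virtual],
        eval_times=grid,
        z_crit=z_crit,
    )
    return compare_arms_by_year(observed_curve, virtual_curve, horizon=horizon)


def run_synthetic_trial(truth: TruthConfig) -> dict[str, pd.DataFrame]:
    """Generate, calibrate, simulate and compare one synthetic trial.

    Returns one yearly comparison table per validation arm, keyed by arm
    label.  All randomness derives from ``truth.seed``.
    """
    training, validation = generate_trial(truth)
    training = apply_exclusions(training)
    table = fit_corrections(training, horizon=truth.horizon)
    results: dict[str, pd.DataFrame] = {}
    for arm, patients in sorted(split_by_arm(apply_exclusions(validation)).items()):
        results[arm] = compare_observed_vs_virtual(
            patients, table, truth.fractions, seed=truth.seed, horizon=truth.horizon
        )
    return results


def rejection_rates(
    comparisons: list[pd.DataFrame], alpha: float = 0.05
) -> np.ndarray:
    """Per-year fraction of comparison tables with p < alpha."""
    flags = np.stack([(c["p_value"] < alpha).to_numpy() for c in comparisons])
    return flags.mean(axis=0)
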