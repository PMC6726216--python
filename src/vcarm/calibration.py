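"""Subgroup multiplier corrections: observed / predicted survival at horizon.

A baseline survival predictor is recalibrated against a training trial by an
observed-over-expected ratio per subgroup: the Kaplan-Meier 15-year survival
of the subgroup's training patients divided by the mean of their baseline
predictions.  New patients' predictions are multiplied by their subgroup's
correction (clipped to [0, 1]).  Corrections are stored and applied at full
precision; rounding is display-only, since ratios of rounded table entries
do not reproduce full-precision multipliers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import ALL_SUBGROUPS, PatientRecord, Subgroup, assign_subgroup, split_by_subgroup
from .km import km_curve

logger = logging.getLogger(__name__)


class CalibrationError(Exception):
    """Correction cannot be fitted or applied."""


class MissingSubgroupError(CalibrationError):
    """A record's subgroup has no fitted correction."""


@dataclass
class CorrectionRow:
    n: int
    observed_s15: float
    predicted_s15_mean: float
    correction: float


@dataclass
class CorrectionTable:
    """Per-subgroup multiplier corrections plus a pooled (overall) row."""

    rows: dict[Subgroup, CorrectionRow]
    overall: CorrectionRow
    horizon: int = 15

    def correction_for(self, subgroup: Subgroup, fallback_overall: bool = False) -> float:
        row = self.rows.get(subgroup)
        if row is None:
            if fallback_overall:
                logger.warning(
                    "subgroup %s missing from correction table; using the "
                    "overall correction %.4f", subgroup, self.overall.correction,
                )
                return self.overall.correction
            raise MissingSubgroupError(f"no correction fitted for subgroup {subgroup}")
        return row.correction

    def to_frame(self) -> pd.DataFrame:
        records = [
            {
                "category": "overall",
                "n": self.overall.n,
                "observed_s15": self.overall.observed_s15,
                "predicted_s15_mean": self.overall.predicted_s15_mean,
                "correction": self.overall.correction,
            }
        ]
        for sg in ALL_SUBGROUPS:
            if sg in self.rows:
                row = self.rows[sg]
                records.append(
                    {
                        "category": str(sg),
                        "n": row.n,
                        "observed_s15": row.observed_s15,
                        "predicted_s15_mean": row.predicted_s15_mean,
                        "correction": row.correction,
                    }
                )
        return pd.DataFrame(records)

    def to_csv(self, path: str | Path, header_comments: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            fh.write(f"# horizon: {self.horizon}\n")
            for line in header_comments:
                fh.write(f"# {line}\n")
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CorrectionTable":
        horizon = 15
        with open(path) as fh:
            for line in fh:
                if line.startswith("# horizon:"):
                    horizon = int(line.split(":", 1)[1])
                if not line.startswith("#"):
                    break
        frame = pd.read_csv(path, comment="#")
        rows: dict[Subgroup, CorrectionRow] = {}
        overall = None
        for rec in frame.itertuples():
            row = CorrectionRow(
                n=int(rec.n),
                observed_s15=float(rec.observed_s15),
                predicted_s15_mean=float(rec.predicted_s15_mean),
                correction=float(rec.correction),
            )
            if rec.category == "overall":
                overall = row
            else:
                band, receptor = str(rec.category).split(" ", 1)
                rows[Subgroup(band, receptor)] = row
        if overall is None:
            raise CalibrationError(f"{path}: no overall row")
        return cls(rows=rows, overall=overall, horizon=horizon)


def _observed_km_at_horizon(
    patients: Sequence[PatientRecord], horizon: int, label: str
) -> float:
    times = [p.followup_years for p in patients]
    events = [p.event for p in patients]
    curve = km_curve(times, events, eval_times=np.arange(0.0, horizon + 1.0))
    if max(times) < horizon:
        logger.warning(
            "%s: no subject under observation at year %d; carrying the last "
            "KM value (%.3f) forward", label, horizon, curve.estimates[-1],
        )
    return float(curve.estimates[-1])


def fit_corrections(
    training: Sequence[PatientRecord], horizon: int = 15
) -> CorrectionTable:
    """Fit per-subgroup multiplier corrections on a filtered training cohort.

    For each subgroup present: observed KM survival at the horizon divided by
    the arithmetic mean of the baseline predictions (averaged across the
    subgroup's patients).  Empty subgroups are flagged and omitted; a pooled
    row over the whole cohort is always produced.
    """
    if not training:
        raise CalibrationError("empty training cohort")
    for rec in training:
        if rec.predicted_s15 is None:
            raise CalibrationError(
                f"{rec.patient_id}: missing baseline prediction in training cohort"
            )
    groups = split_by_subgroup(training)
    rows: dict[Subgroup, CorrectionRow] = {}
    for sg, members in groups.items():
        if not members:
            logger.warning("subgroup %s empty in training cohort; no correction", sg)
            continue
        observed = _observed_km_at_horizon(members, horizon, str(sg))
        predicted = float(np.mean([p.predicted_s15 for p in members]))
        if predicted == 0.0:
            raise CalibrationError(f"subgroup {sg}: mean predicted survival is 0")
        rows[sg] = CorrectionRow(
            n=len(members),
            observed_s15=observed,
            predicted_s15_mean=predicted,
            correction=observed / predicted,
        )
    observed_all = _observed_km_at_horizon(training, horizon, "overall")
    predicted_all = float(np.mean([p.predicted_s15 for p in training]))
    if predicted_all == 0.0:
        raise CalibrationError("overall mean predicted survival is 0")
    overall = CorrectionRow(
        n=len(training),
        observed_s15=observed_all,
        predicted_s15_mean=predicted_all,
        correction=observed_all / predicted_all,
    )
    logger.info(
        "fitted corrections for %d subgroup(s); overall %.4f = %.3f / %.3f",
        len(rows), overall.correction, observed_all, predicted_all,
    )
    return CorrectionTable(rows=rows, overall=overall, horizon=horizon)


def correction_ratio(observed_s15: float, predicted_s15_mean: float) -> float:
    """The multiplier correction: observed over mean-predicted survival."""
    if predicted_s15_mean <= 0:
        raise CalibrationError("mean predicted survival must be positive")
    if observed_s15 < 0:
        raise CalibrationError("observed survival must be nonnegative")
    return observed_s15 / predicted_s15_mean


def apply_correction(
    record: PatientRecord,
    table: CorrectionTable,
    fallback_overall: bool = False,
) -> float:
    """Corrected 15-year survival: prediction x subgroup correction, in [0, 1].

    Corrections above 1 (an under-predicting baseline) are allowed; the
    product is clipped to keep probability semantics.
    """
    if record.predicted_s15 is None:
        raise CalibrationError(f"{record.patient_id}: missing baseline prediction")
    c = table.correction_for(assign_subgroup(record), fallback_overall=fallback_overall)
    return float(np.clip(record.predicted_s15 * c, 0.0, 1.0))


def apply_corrections(
    cohort: Iterable[PatientRecord],
    table: CorrectionTable,
    fallback_overall: bool = False,
) -> np.ndarray:
    """Vector of corrected predictions for a cohort (order preserved)."""
    return np.array(
        [apply_correction(rec, table, fallback_overall=fallback_overall) for rec in cohort]
    )
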