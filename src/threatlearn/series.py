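"""In-memory containers for trial-level SCR data and subject covariates.

A :class:`TrialSeries` holds one subject's square-root-transformed SCR
amplitude per scheduled CS trial (aligned with a :class:`~threatlearn.task.
TaskSchedule`), the UCS-response amplitude on reinforced trials, and a
missingness mask.  A :class:`SubjectRecord` adds demographic, clinical and
structural covariates plus (for synthetic subjects) the generating
ground-truth parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .task import TaskSchedule

TRIAL_COLUMNS = ["subject_id", "phase", "cs", "trial", "reinforced",
                 "scr", "ucs_scr", "missing"]


@dataclass
class TrialSeries:
    """One subject's observed SCR values on the task schedule.

    ``trials`` has one row per scheduled trial, in presentation order, with
    columns phase, cs, trial (1-based within-phase per-CS index),
    reinforced, scr (NaN when missing), ucs_scr (NaN on unreinforced
    trials) and missing (bool).
    """

    subject_id: str
    trials: pd.DataFrame
    order_id: str = "A"

    def __post_init__(self) -> None:
        self.trials = self.trials.reset_index(drop=True)
        valid = self.trials["scr"].to_numpy(dtype=float)
        miss = self.trials["missing"].to_numpy(dtype=bool)
        if np.any(valid[~miss] < 0):
            raise ValueError("non-missing SCR values must be >= 0")

    def copy(self) -> "TrialSeries":
        return TrialSeries(self.subject_id, self.trials.copy(), self.order_id)

    def phase_frame(self, phase: str, cs: str | None = None) -> pd.DataFrame:
        m = self.trials["phase"] == phase
        if cs is not None:
            m &= self.trials["cs"] == cs
        return self.trials.loc[m]

    def phase_values(self, phase: str) -> np.ndarray:
        """Observed SCR over the phase's trials, in presentation order."""
        return self.phase_frame(phase)["scr"].to_numpy(dtype=float)

    def ucs_values(self) -> np.ndarray:
        """UCS-response amplitudes on reinforced trials, in order."""
        m = self.trials["reinforced"].astype(bool)
        return self.trials.loc[m, "ucs_scr"].to_numpy(dtype=float)

    def matches_schedule(self, schedule: TaskSchedule) -> bool:
        if len(self.trials) != len(schedule):
            return False
        for row, trial in zip(self.trials.itertuples(index=False), schedule):
            if (row.phase, row.cs, row.trial) != (trial.phase, trial.cs,
                                                  trial.index):
                return False
        return True


@dataclass
class SubjectRecord:
    """TrialSeries plus covariates and (optionally) generating truth."""

    series: TrialSeries
    age: float
    sex: int                      # 0 = female, 1 = male
    group: str = "healthy"        # 'healthy' | 'anxiety'
    anxiety_z: float = 0.0
    icv: float = float("nan")     # intracranial volume, mm^3
    gmv: dict[str, float] = field(default_factory=dict)  # structure -> mm^3
    true_params: dict[str, float] = field(default_factory=dict)
    true_model_id: int | None = None

    @property
    def subject_id(self) -> str:
        return self.series.subject_id


def cohort_to_frames(records: list[SubjectRecord]
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten a cohort into (trials, subjects) data frames."""
    trial_parts = []
    subj_rows = []
    for rec in records:
        t = rec.series.trials.copy()
        t.insert(0, "subject_id", rec.subject_id)
        trial_parts.append(t[TRIAL_COLUMNS])
        row: dict[str, object] = {
            "subject_id": rec.subject_id,
            "order_id": rec.series.order_id,
            "age": rec.age,
            "sex": rec.sex,
            "group": rec.group,
            "anxiety_z": rec.anxiety_z,
            "icv": rec.icv,
        }
        row.update(rec.gmv)
        if rec.true_model_id is not None:
            row["true_model_id"] = rec.true_model_id
        row.update({f"true_{k}": v for k, v in rec.true_params.items()})
        subj_rows.append(row)
    return pd.concat(trial_parts, ignore_index=True), pd.DataFrame(subj_rows)


def write_cohort(records: list[SubjectRecord], out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trials, subjects = cohort_to_frames(records)
    trials.to_csv(out / "trials.csv", index=False)
    subjects.to_csv(out / "subjects.csv", index=False)


def read_trials(path: str | Path) -> dict[str, TrialSeries]:
    """Load a trials.csv into per-subject TrialSeries, preserving order."""
    df = pd.read_csv(path)
    out: dict[str, TrialSeries] = {}
    for sid, grp in df.groupby("subject_id", sort=False):
        out[str(sid)] = TrialSeries(str(sid),
                                    grp.drop(columns="subject_id"))
    return out
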