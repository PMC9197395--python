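"""Threat conditioning and extinction task schedules.

The task has three phases: a *pre-conditioning* (habituation) phase in which
the two conditioned stimuli (CS+ and CS-) are shown 4 times each without
reinforcement, a *conditioning* phase with 10 presentations per CS in which
80% of the CS+ presentations co-terminate with the aversive unconditioned
stimulus (UCS), and an *extinction* phase with 8 unreinforced presentations
per CS.  CS+/CS- presentations are interleaved pseudo-randomly in one of two
counterbalanced orders (A / B).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterator

import numpy as np

PHASES = ("pre", "conditioning", "extinction")
CS_TYPES = ("CS+", "CS-")

#: presentations per CS in each phase
PHASE_LENGTHS = {"pre": 4, "conditioning": 10, "extinction": 8}

#: number of reinforced CS+ presentations during conditioning (80% of 10)
N_REINFORCED = 8

#: maximum run of consecutive same-CS presentations in the pseudo-random order
MAX_RUN = 2


@dataclass(frozen=True)
class Trial:
    phase: str          # 'pre' | 'conditioning' | 'extinction'
    cs: str             # 'CS+' | 'CS-'
    index: int          # 1-based within-phase presentation index for this CS
    reinforced: bool    # UCS delivered on this trial


@dataclass
class TaskSchedule:
    """Ordered list of trials for one counterbalance order."""

    trials: list[Trial]
    order_id: str

    def __iter__(self) -> Iterator[Trial]:
        return iter(self.trials)

    def __len__(self) -> int:
        return len(self.trials)

    def phase_trials(self, phase: str) -> list[Trial]:
        if phase not in PHASES:
            raise ValueError(f"unknown phase {phase!r}")
        return [t for t in self.trials if t.phase == phase]

    def n_trials(self, phase: str, cs: str | None = None) -> int:
        return sum(
            1 for t in self.trials
            if t.phase == phase and (cs is None or t.cs == cs)
        )

    def reinforced_trials(self) -> list[Trial]:
        return [t for t in self.trials if t.reinforced]

    def to_json(self) -> str:
        return json.dumps(
            {
                "order_id": self.order_id,
                "trials": [
                    {"phase": t.phase, "cs": t.cs, "index": t.index,
                     "reinforced": t.reinforced}
                    for t in self.trials
                ],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "TaskSchedule":
        obj = json.loads(text)
        trials = [Trial(d["phase"], d["cs"], d["index"], d["reinforced"])
                  for d in obj["trials"]]
        return cls(trials=trials, order_id=obj["order_id"])


def schedule_from_frame(df, order_id: str = "?") -> TaskSchedule:
    """Reconstruct a TaskSchedule from a trial table.

    Any frame with phase / cs / trial / reinforced columns in
    presentation order defines a schedule; this lets fits align with the
    exact sequence a subject actually saw.
    """
    trials = [Trial(str(r.phase), str(r.cs), int(r.trial), bool(r.reinforced))
              for r in df.itertuples(index=False)]
    return TaskSchedule(trials=trials, order_id=order_id)


def _interleave(rng: np.random.Generator, n_per_cs: int) -> list[str]:
    """Pseudo-random CS sequence with at most MAX_RUN consecutive repeats."""
    base = ["CS+"] * n_per_cs + ["CS-"] * n_per_cs
    while True:  # rejection sampling; acceptance probability is high
        seq = list(rng.permutation(base))
        run, ok = 1, True
        for a, b in zip(seq, seq[1:]):
            run = run + 1 if a == b else 1
            if run > MAX_RUN:
                ok = False
                break
        if ok:
            return seq


def build_task_schedule(order_id: str, seed: int) -> TaskSchedule:
    """Build one counterbalance order of the task.

    Deterministic given ``(order_id, seed)``: the two orders derive from
    independent substreams of the same seed, so A and B differ from each
    other but are each reproducible.  The set of unreinforced CS+
    conditioning positions is fixed per order (the first CS+ conditioning
    trial is always reinforced, as is conventional so that the contingency
    can be acquired from the outset).
    """
    if order_id not in ("A", "B"):
        raise ValueError(f"order_id must be 'A' or 'B', got {order_id!r}")
    sub = 0 if order_id == "A" else 1
    rng = np.random.default_rng([int(seed), sub])

    trials: list[Trial] = []
    # unreinforced CS+ conditioning positions (1-based), drawn once per order
    unreinforced = set(
        rng.choice(np.arange(2, PHASE_LENGTHS["conditioning"] + 1),
                   size=PHASE_LENGTHS["conditioning"] - N_REINFORCED,
                   replace=False).tolist()
    )
    for phase in PHASES:
        seq = _interleave(rng, PHASE_LENGTHS[phase])
        counts = {"CS+": 0, "CS-": 0}
        for cs in seq:
            counts[cs] += 1
            reinforced = (
                phase == "conditioning"
                and cs == "CS+"
                and counts[cs] not in unreinforced
            )
            trials.append(Trial(phase, cs, counts[cs], reinforced))
    return TaskSchedule(trials=trials, order_id=order_id)
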