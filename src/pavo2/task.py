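"""Probabilistic Pavlovian task structure.

Each session presents 56 ten-second auditory cues (28 per cue). CS_High is
rewarded on exactly 75% of its presentations (21/28) and CS_Low on exactly
25% (7/28); reward or omission follows immediately at cue offset. Intertrial
intervals are drawn uniformly from [30, 60] s (mean 45 s). The mapping from
cue role (CS_High/CS_Low) to physical sound (clicker/tone) is set by the
counterbalance group.

Reward proportions are enforced exactly per session rather than sampled
Bernoulli, so per-session reward counts are deterministic properties of the
design and not of the seed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeds import child_rng

__all__ = [
    "Counterbalance",
    "Regime",
    "Cue",
    "Sound",
    "TrialRecord",
    "SessionSchedule",
    "generate_schedule",
    "N_TRIALS",
    "N_PER_CUE",
    "N_REWARDED_HIGH",
    "N_REWARDED_LOW",
    "CUE_DURATION_S",
    "ITI_RANGE_S",
]

N_TRIALS = 56
N_PER_CUE = 28
N_REWARDED_HIGH = 21   # 0.75 * 28
N_REWARDED_LOW = 7     # 0.25 * 28
CUE_DURATION_S = 10.0
ITI_RANGE_S = (30.0, 60.0)


class Cue(str, enum.Enum):
    CS_HIGH = "CS_High"
    CS_LOW = "CS_Low"


class Sound(str, enum.Enum):
    CLICKER = "clicker"
    TONE = "tone"


class Counterbalance(str, enum.Enum):
    """Cue-identity group: which sound carries the high reward probability."""

    CL1_T2 = "CL1_T2"   # clicker = CS_High, tone = CS_Low
    T1_CL2 = "T1_CL2"   # tone = CS_High, clicker = CS_Low

    def sound_for(self, cue: Cue) -> Sound:
        if self is Counterbalance.CL1_T2:
            return Sound.CLICKER if cue is Cue.CS_HIGH else Sound.TONE
        return Sound.TONE if cue is Cue.CS_HIGH else Sound.CLICKER


class Regime(str, enum.Enum):
    TRAINING = "training"
    PRE_DRUG = "pre_drug"
    VEHICLE = "vehicle"
    AMPHETAMINE = "amphetamine"


@dataclass(frozen=True)
class TrialRecord:
    trial_index: int            # 1-based within session
    cue: Cue
    sound: Sound
    rewarded: bool
    iti_s: float
    cue_onset_s: float          # seconds from session start
    outcome_onset_s: float      # cue_onset_s + 10 exactly


@dataclass
class SessionSchedule:
    trials: list[TrialRecord]
    session_index: int          # 1..10
    counterbalance: Counterbalance
    regime: Regime
    animal_id: str | None = field(default=None)

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def duration_s(self) -> float:
        """Session clock value at the last outcome."""
        return self.trials[-1].outcome_onset_s

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": [t.trial_index for t in self.trials],
                "cue": [t.cue.value for t in self.trials],
                "sound": [t.sound.value for t in self.trials],
                "rewarded": [int(t.rewarded) for t in self.trials],
                "iti_s": [t.iti_s for t in self.trials],
                "cue_onset_s": [t.cue_onset_s for t in self.trials],
                "outcome_onset_s": [t.outcome_onset_s for t in self.trials],
            }
        )


def generate_schedule(
    session_index: int,
    counterbalance: Counterbalance | str,
    regime: Regime | str,
    seed: int,
) -> SessionSchedule:
    """Generate one seeded session schedule.

    Cue order and the positions of rewarded trials within each cue are a
    seeded random permutation; reward counts per cue are exact (21/28 for
    CS_High, 7/28 for CS_Low). The same ``(session_index, counterbalance,
    regime, seed)`` always yields the identical schedule.
    """
    try:
        counterbalance = Counterbalance(counterbalance)
    except ValueError as exc:
        raise ValueError(f"unknown counterbalance {counterbalance!r}") from exc
    try:
        regime = Regime(regime)
    except ValueError as exc:
        raise ValueError(f"unknown regime {regime!r}") from exc
    if not isinstance(session_index, (int, np.integer)) or not 1 <= session_index <= 10:
        raise ValueError(f"session_index must be in 1..10, got {session_index}")

    rng = child_rng(seed, "schedule", session_index, counterbalance.value, regime.value)

    cues = np.array([0] * N_PER_CUE + [1] * N_PER_CUE)  # 0=CS_High, 1=CS_Low
    rng.shuffle(cues)
    rewarded = np.zeros(N_TRIALS, dtype=bool)
    for code, n_rew in ((0, N_REWARDED_HIGH), (1, N_REWARDED_LOW)):
        idx = np.flatnonzero(cues == code)
        rewarded[rng.choice(idx, size=n_rew, replace=False)] = True
    itis = rng.uniform(*ITI_RANGE_S, size=N_TRIALS)

    trials: list[TrialRecord] = []
    clock = 0.0
    for i in range(N_TRIALS):
        cue = Cue.CS_HIGH if cues[i] == 0 else Cue.CS_LOW
        cue_onset = clock + itis[i]
        trials.append(
            TrialRecord(
                trial_index=i + 1,
                cue=cue,
                sound=counterbalance.sound_for(cue),
                rewarded=bool(rewarded[i]),
                iti_s=float(itis[i]),
                cue_onset_s=cue_onset,
                outcome_onset_s=cue_onset + CUE_DURATION_S,
            )
        )
        clock = cue_onset + CUE_DURATION_S

    return SessionSchedule(
        trials=trials,
        session_index=int(session_index),
        counterbalance=counterbalance,
        regime=regime,
    )
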