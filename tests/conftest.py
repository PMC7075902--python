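import numpy as np
import pandas as pd
import pytest

from pavo2.cohort import CohortConfig, simulate_cohort
from pavo2.task import Counterbalance, Regime, SessionSchedule, TrialRecord, Cue, Sound


@pytest.fixture(scope="session")
def small_cohort():
    """Four animals, behaviour only — shared across read-only tests."""
    return simulate_cohort(4, CohortConfig(include_o2=False), seed=42)


@pytest.fixture(scope="session")
def o2_cohort():
    """Four animals with one NAc and one OFC electrode each."""
    return simulate_cohort(4, CohortConfig(), seed=7)


def make_single_trial_schedule(
    cue=Cue.CS_HIGH, rewarded=True, cue_onset=40.0, regime=Regime.TRAINING
) -> SessionSchedule:
    """Minimal hand-built schedule for kernel-level trace tests."""
    tr = TrialRecord(
        trial_index=1, cue=cue, sound=Sound.CLICKER, rewarded=rewarded,
        iti_s=cue_onset, cue_onset_s=cue_onset, outcome_onset_s=cue_onset + 10.0,
    )
    return SessionSchedule(
        trials=[tr], session_index=1,
        counterbalance=Counterbalance.CL1_T2, regime=regime,
    )


def make_latents(schedule, v_emit, rewarded=None) -> pd.DataFrame:
    rew = rewarded if rewarded is not None else [int(t.rewarded) for t in schedule.trials]
    v = np.broadcast_to(np.asarray(v_emit, dtype=float), (len(schedule.trials),))
    return pd.DataFrame(
        {
            "trial": [t.trial_index for t in schedule.trials],
            "rewarded": rew,
            "v_emit": v,
            "delta_emit": np.asarray(rew, dtype=float) - v,
        }
    )
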