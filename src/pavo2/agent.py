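"""Rescorla-Wagner agent generating magazine head-entry rates.

The generative model mirrors the fitted behavioural model family: cue value V
is updated trial by trial as V <- V + alpha_eff * (r - V) with an effective
learning rate alpha * beta_sound (beta_tone fixed at 1, so beta_clicker is a
relative salience of the clicker). The emitted cue-period response rate is

    rate(t) = gain * V_cue(t) + k_sound + b(t) + noise,   truncated at 0,

where k_sound is cue-specific unconditioned magazine responding and b(t) is a
recency-weighted smoothing of observed pre-cue rates. Pre-cue rates come from
a stationary Gaussian baseline process truncated at 0.

Values carry over across sessions (one continuous learning history per
animal). On an amphetamine session the expressed values are shrunk toward
their mean by ``drug_effect`` — learning itself is untouched, but cue
discrimination in behaviour (and, downstream, in simulated neural amplitudes)
collapses. The shrunk value and its prediction error are recorded as
``v_emit`` / ``delta_emit`` alongside the true latents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seeds import child_rng
from .task import Cue, Regime, SessionSchedule, Sound

__all__ = ["AgentParams", "simulate_agent"]


@dataclass
class AgentParams:
    alpha: float = 0.1              # learning rate, in (0, 1)
    beta_clicker: float = 1.5       # clicker salience multiplier (> 0); beta_tone = 1
    k_clicker: float = 1.5          # unconditioned responding, clicker trials (>= 0)
    k_tone: float = 0.25            # unconditioned responding, tone trials (>= 0)
    gamma_recency: float = 0.7      # baseline smoothing weight, in [0, 1]
    response_gain: float = 6.0      # head entries per unit value
    noise_sd: float = 1.0           # emission noise on cue-period rates
    drug_effect: float = 0.9        # fraction of cue discrimination collapsed, [0, 1]
    baseline_mean: float = 1.0      # stationary pre-cue rate level
    baseline_sd: float = 0.5        # pre-cue rate noise

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.beta_clicker <= 0.0:
            raise ValueError(f"beta_clicker must be > 0, got {self.beta_clicker}")
        if self.k_clicker < 0.0 or self.k_tone < 0.0:
            raise ValueError("k_clicker and k_tone must be >= 0")
        if not 0.0 <= self.gamma_recency <= 1.0:
            raise ValueError(f"gamma_recency must be in [0,1], got {self.gamma_recency}")
        if self.response_gain < 0.0:
            raise ValueError("response_gain must be >= 0")
        if self.noise_sd < 0.0 or self.baseline_sd < 0.0:
            raise ValueError("noise sds must be >= 0")
        if not 0.0 <= self.drug_effect <= 1.0:
            raise ValueError(f"drug_effect must be in [0,1], got {self.drug_effect}")
        if self.baseline_mean < 0.0:
            raise ValueError("baseline_mean must be >= 0")


def simulate_agent(
    schedules: list[SessionSchedule],
    params: AgentParams,
    seed: int,
) -> pd.DataFrame:
    """Simulate head-entry behaviour over an ordered list of sessions.

    Returns one row per trial with the schedule columns, the emitted
    ``pre_cue_rate`` and ``cue_rate``, and the latent trajectory: ``v_high``
    and ``v_low`` (both cues' values at cue onset), ``v_pre`` (presented cue's
    value before the update), ``delta`` (r - v_pre), ``v_post``, and the
    drug-adjusted ``v_emit`` / ``delta_emit`` actually expressed.
    """
    params.validate()
    if any(
        schedules[i].session_index >= schedules[i + 1].session_index
        for i in range(len(schedules) - 1)
    ):
        raise ValueError("schedules must be ordered by ascending session_index")

    rng = child_rng(seed, "agent")
    v = {Cue.CS_HIGH: 0.0, Cue.CS_LOW: 0.0}   # naive animal, V0 = 0
    b = params.baseline_mean                   # recency-weighted baseline
    rows = []
    for sched in schedules:
        on_drug = sched.regime is Regime.AMPHETAMINE
        for tr in sched.trials:
            pre_rate = max(
                0.0, params.baseline_mean + params.baseline_sd * rng.standard_normal()
            )
            shrink = params.drug_effect if on_drug else 0.0
            m = 0.5 * (v[Cue.CS_HIGH] + v[Cue.CS_LOW])
            v_emit = m + (1.0 - shrink) * (v[tr.cue] - m)
            k = params.k_clicker if tr.sound is Sound.CLICKER else params.k_tone
            rate = (
                params.response_gain * v_emit
                + k
                + b
                + params.noise_sd * rng.standard_normal()
            )
            r = 1.0 if tr.rewarded else 0.0
            v_pre = v[tr.cue]
            beta = params.beta_clicker if tr.sound is Sound.CLICKER else 1.0
            alpha_eff = min(params.alpha * beta, 1.0)
            v[tr.cue] = v_pre + alpha_eff * (r - v_pre)
            rows.append(
                {
                    "session": sched.session_index,
                    "regime": sched.regime.value,
                    "trial": tr.trial_index,
                    "cue": tr.cue.value,
                    "sound": tr.sound.value,
                    "rewarded": int(tr.rewarded),
                    "iti_s": tr.iti_s,
                    "cue_onset_s": tr.cue_onset_s,
                    "outcome_onset_s": tr.outcome_onset_s,
                    "pre_cue_rate": pre_rate,
                    "cue_rate": max(0.0, rate),
                    "v_high": v[Cue.CS_HIGH] if tr.cue is Cue.CS_LOW else v_pre,
                    "v_low": v[Cue.CS_LOW] if tr.cue is Cue.CS_HIGH else v_pre,
                    "v_pre": v_pre,
                    "v_post": v[tr.cue],
                    "delta": r - v_pre,
                    "v_emit": v_emit,
                    "delta_emit": r - v_emit,
                }
            )
            # baseline smoother consumes the just-observed pre-cue rate
            b = params.gamma_recency * b + (1.0 - params.gamma_recency) * pre_rate
    return pd.DataFrame(rows)
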