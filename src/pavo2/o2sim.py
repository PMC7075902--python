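"""Generative model for tissue-oxygen traces.

Each session's trace is a sum of haemodynamic impulse responses placed at the
behavioural events, plus a slow linear drift and AR(1) noise:

    trace(t) = sum_events a_e * HRF(t - t_e) + drift_slope * t + noise(t)

The HRF is a gamma-shaped kernel with unit peak amplitude (default peak 4 s,
FWHM 4 s, 25-s support, sampled at 1 Hz) — rodent haemodynamics peak faster
than the canonical human response.

Event amplitudes come from the agent's latent learning variables:

- cue onset:  ``w_cue_value * V(t)``
- outcome:    ``w_outcome * r(t) + w_value_at_outcome * V(t)
              + w_unsigned_pe * |r(t) - V(t)|``

where V(t) is the presented cue's value before the outcome's update. The two
region profiles encode the distinct signatures the analyses are designed to
detect: an NAc-like channel carries a signed reward prediction error at
outcome (amplitude r - V, i.e. positive outcome weight and negative value
weight), an OFC-like channel carries an unsigned prediction error (surprise)
plus a *positive* value contribution at outcome. On an amphetamine session
the latents are already discrimination-collapsed (``v_emit``), and outcome
amplitudes on CS_Low trials are additionally blunted toward 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._seeds import child_rng
from .signals import O2Trace
from .task import Regime, SessionSchedule

__all__ = ["O2SimParams", "REGION_PROFILES", "gamma_hrf", "simulate_o2"]


@dataclass
class O2SimParams:
    sample_rate_hz: float = 1.0
    hrf_peak_s: float = 4.0
    hrf_fwhm_s: float = 4.0
    hrf_support_s: float = 25.0
    w_cue_value: float = 1.0
    w_outcome: float = 1.0
    w_value_at_outcome: float = -1.0
    w_unsigned_pe: float = 0.0
    ar1_coef: float = 0.8           # noise autocorrelation, [0, 1)
    noise_sd: float = 0.3           # stationary noise sd
    drift_slope: float = 1e-4       # signal units per second
    tail_s: float = 35.0            # recording continued past the last outcome

    def validate(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError(f"sample_rate_hz must be > 0, got {self.sample_rate_hz}")
        if not 0.0 <= self.ar1_coef < 1.0:
            raise ValueError(f"ar1_coef must be in [0,1), got {self.ar1_coef}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name in ("w_cue_value", "w_outcome", "w_value_at_outcome", "w_unsigned_pe"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


#: Default regressor-weight presets per recorded region.
REGION_PROFILES: dict[str, O2SimParams] = {
    # outcome amplitude = r - V : signed reward prediction error
    "NAc": O2SimParams(w_cue_value=1.0, w_outcome=1.0,
                       w_value_at_outcome=-1.0, w_unsigned_pe=0.0),
    # outcome amplitude = 0.5 r + 1.0 V + 1.5 |r - V| : salience + positive value
    "OFC": O2SimParams(w_cue_value=1.0, w_outcome=0.5,
                       w_value_at_outcome=1.0, w_unsigned_pe=1.5),
}


def gamma_hrf(
    dt: float, peak_s: float = 4.0, fwhm_s: float = 4.0, support_s: float = 25.0
) -> np.ndarray:
    """Gamma-shaped haemodynamic kernel, unit peak, sampled every ``dt`` s.

    Shape and scale are chosen so the mode sits at ``peak_s`` and the spread
    matches ``fwhm_s`` through the Gaussian relation sd = FWHM / 2.355.
    """
    if dt <= 0 or peak_s <= 0 or fwhm_s <= 0:
        raise ValueError("dt, peak_s and fwhm_s must all be > 0")
    var = (fwhm_s / 2.355) ** 2
    # mode = (k-1)*theta, var = k*theta^2  =>  quadratic in theta
    theta = (-peak_s + np.sqrt(peak_s**2 + 4 * var)) / 2
    k = peak_s / theta + 1.0
    t = np.arange(0.0, support_s + dt / 2, dt)
    h = t ** (k - 1) * np.exp(-t / theta)
    peak = peak_s ** (k - 1) * np.exp(-peak_s / theta)
    return h / peak


def event_amplitudes(
    schedule: SessionSchedule,
    latents: pd.DataFrame,
    params: O2SimParams,
    drug_effect: float = 0.0,
) -> pd.DataFrame:
    """Per-trial (cue, outcome) event times and amplitudes.

    ``latents`` is the agent's output for this session, aligned to the
    schedule trials; ``v_emit``/``delta_emit`` already reflect any drug-induced
    collapse of cue discrimination. ``drug_effect`` additionally scales down
    outcome amplitudes on CS_Low trials during an amphetamine session.
    """
    if len(latents) != len(schedule.trials):
        raise ValueError(
            f"latents ({len(latents)} rows) not aligned to schedule "
            f"({len(schedule.trials)} trials)"
        )
    on_drug = schedule.regime is Regime.AMPHETAMINE
    rows = []
    for tr, (_, lat) in zip(schedule.trials, latents.iterrows()):
        v = float(lat["v_emit"])
        r = float(lat["rewarded"])
        a_out = (
            params.w_outcome * r
            + params.w_value_at_outcome * v
            + params.w_unsigned_pe * abs(r - v)
        )
        if on_drug and tr.cue.value == "CS_Low":
            a_out *= 1.0 - drug_effect
        rows.append(
            {
                "trial": tr.trial_index,
                "cue": tr.cue.value,
                "rewarded": int(tr.rewarded),
                "cue_time_s": tr.cue_onset_s,
                "cue_amplitude": params.w_cue_value * v,
                "outcome_time_s": tr.outcome_onset_s,
                "outcome_amplitude": a_out,
            }
        )
    return pd.DataFrame(rows)


def simulate_o2(
    schedule: SessionSchedule,
    latents: pd.DataFrame,
    region_profile: str,
    o2_params: O2SimParams | None = None,
    seed: int = 0,
    electrode_id: str = "e0",
    animal_id: str = "a0",
    drug_effect: float = 0.0,
    kernel: np.ndarray | None = None,
) -> O2Trace:
    """Simulate one electrode's oxygen trace for one session.

    ``region_profile`` selects the NAc or OFC weight preset; an explicit
    ``o2_params`` overrides it entirely. ``kernel`` replaces the gamma HRF
    with an arbitrary impulse response (e.g. a unit impulse in tests).
    Identical seed gives an identical trace.
    """
    if o2_params is None:
        if region_profile not in REGION_PROFILES:
            raise ValueError(
                f"unknown region_profile {region_profile!r}; "
                f"known: {sorted(REGION_PROFILES)}"
            )
        o2_params = replace(REGION_PROFILES[region_profile])
    o2_params.validate()

    dt = 1.0 / o2_params.sample_rate_hz
    t_end = schedule.duration_s + o2_params.tail_s
    time_s = np.arange(0.0, t_end + dt / 2, dt)
    sig = np.zeros_like(time_s)

    if kernel is None:
        kernel = gamma_hrf(dt, o2_params.hrf_peak_s, o2_params.hrf_fwhm_s,
                           o2_params.hrf_support_s)
    else:
        kernel = np.asarray(kernel, dtype=float)
    amps = event_amplitudes(schedule, latents, o2_params, drug_effect=drug_effect)
    for _, ev in amps.iterrows():
        for t_ev, a in ((ev["cue_time_s"], ev["cue_amplitude"]),
                        (ev["outcome_time_s"], ev["outcome_amplitude"])):
            if a == 0.0:
                continue
            i0 = int(round(t_ev / dt))
            i1 = min(i0 + len(kernel), len(sig))
            if i0 < len(sig):
                sig[i0:i1] += a * kernel[: i1 - i0]

    sig += o2_params.drift_slope * time_s
    if o2_params.noise_sd > 0:
        rng = child_rng(
            seed, "o2", animal_id, electrode_id, schedule.session_index
        )
        innov_sd = o2_params.noise_sd * np.sqrt(1.0 - o2_params.ar1_coef**2)
        eps = innov_sd * rng.standard_normal(len(sig))
        noise = np.empty_like(sig)
        noise[0] = o2_params.noise_sd * rng.standard_normal()
        for i in range(1, len(sig)):
            noise[i] = o2_params.ar1_coef * noise[i - 1] + eps[i]
        sig += noise

    return O2Trace(
        time_s=time_s,
        signal=sig,
        region=region_profile,
        electrode_id=electrode_id,
        animal_id=animal_id,
        session=schedule.session_index,
    )
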