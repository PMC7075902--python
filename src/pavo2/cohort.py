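"""Whole-study simulation: animals, sessions, behaviour and electrodes.

Each simulated animal runs nine training sessions (session 9 doubling as the
pre-drug session) plus a tenth drug-challenge session under vehicle or
amphetamine. Animals are assigned round-robin to the two cue-identity
counterbalance groups and, orthogonally, to the vehicle/amphetamine groups.
Per-animal learning parameters are drawn from configured population
distributions and recorded as ground truth, so recovery analyses can compare
fitted against generating values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeds import child_rng
from .agent import AgentParams, simulate_agent
from .o2sim import O2SimParams, REGION_PROFILES, simulate_o2
from .signals import O2Trace
from .task import Counterbalance, Regime, SessionSchedule, generate_schedule

__all__ = ["CohortConfig", "Cohort", "simulate_cohort", "draw_agent_params"]

N_TRAINING_SESSIONS = 9
DRUG_SESSION = 10


@dataclass
class CohortConfig:
    """Population-level simulation settings.

    Learning-rate spread is wide enough that individual differences dominate
    fitting noise; clicker parameters are larger than tone parameters,
    reflecting stronger unconditioned responding to the clicker.
    """

    # population distributions for AgentParams
    alpha_range: tuple[float, float] = (0.05, 0.30)        # uniform
    beta_clicker_logmean: float = float(np.log(1.5))       # lognormal
    beta_clicker_logsd: float = 0.2
    k_clicker_mean: float = 1.5
    k_clicker_sd: float = 0.3
    k_tone_mean: float = 0.25
    k_tone_sd: float = 0.1
    gamma_range: tuple[float, float] = (0.5, 0.9)          # uniform
    gain_mean: float = 6.0
    gain_sd: float = 1.0
    noise_sd: float = 1.0
    baseline_mean: float = 1.0
    baseline_sd: float = 0.5
    drug_effect: float = 0.9       # applied to amphetamine animals

    # electrodes and signal simulation
    n_nac_electrodes: int = 1
    n_ofc_electrodes: int = 1
    include_o2: bool = True
    o2_overrides: dict = field(default_factory=dict)   # field -> value, both regions


@dataclass
class Cohort:
    trials: pd.DataFrame                    # all animals, all sessions, + latents
    traces: list[O2Trace]
    ground_truth: pd.DataFrame              # one row per animal
    schedules: dict[tuple[str, int], SessionSchedule]
    config: CohortConfig
    seed: int

    def animal_trials(self, animal_id: str) -> pd.DataFrame:
        return self.trials[self.trials["animal_id"] == animal_id].reset_index(drop=True)


def draw_agent_params(config: CohortConfig, rng: np.random.Generator,
                      drug_group: str) -> AgentParams:
    """One animal's parameters from the population distributions."""
    return AgentParams(
        alpha=float(rng.uniform(*config.alpha_range)),
        beta_clicker=float(np.exp(rng.normal(config.beta_clicker_logmean,
                                             config.beta_clicker_logsd))),
        k_clicker=float(max(0.0, rng.normal(config.k_clicker_mean,
                                            config.k_clicker_sd))),
        k_tone=float(max(0.0, rng.normal(config.k_tone_mean, config.k_tone_sd))),
        gamma_recency=float(rng.uniform(*config.gamma_range)),
        response_gain=float(max(0.1, rng.normal(config.gain_mean, config.gain_sd))),
        noise_sd=config.noise_sd,
        drug_effect=config.drug_effect if drug_group == "amphetamine" else 0.0,
        baseline_mean=config.baseline_mean,
        baseline_sd=config.baseline_sd,
    )


def _session_regime(session: int, drug_group: str) -> Regime:
    if session < N_TRAINING_SESSIONS:
        return Regime.TRAINING
    if session == N_TRAINING_SESSIONS:
        return Regime.PRE_DRUG
    return Regime(drug_group)


def simulate_cohort(
    n_animals: int,
    config: CohortConfig | None = None,
    seed: int = 0,
) -> Cohort:
    """Simulate a full cohort: schedules, behaviour, and (optionally) O2 traces."""
    if n_animals < 2:
        raise ValueError(f"n_animals must be >= 2, got {n_animals}")
    config = config or CohortConfig()

    trials_frames = []
    traces: list[O2Trace] = []
    schedules: dict[tuple[str, int], SessionSchedule] = {}
    gt_rows = []
    for i in range(n_animals):
        animal_id = f"rat{i:02d}"
        counterbalance = (
            Counterbalance.CL1_T2 if i % 2 == 0 else Counterbalance.T1_CL2
        )
        drug_group = "vehicle" if (i // 2) % 2 == 0 else "amphetamine"
        rng = child_rng(seed, "animal_params", i)
        params = draw_agent_params(config, rng, drug_group)

        animal_scheds = []
        for session in range(1, DRUG_SESSION + 1):
            regime = _session_regime(session, drug_group)
            sched = generate_schedule(
                session, counterbalance, regime,
                seed=int(child_rng(seed, "schedule_seed", i).integers(2**31)) + session,
            )
            sched.animal_id = animal_id
            animal_scheds.append(sched)
            schedules[(animal_id, session)] = sched

        behaviour = simulate_agent(
            animal_scheds, params, seed=int(child_rng(seed, "agent_seed", i).integers(2**31))
        )
        behaviour.insert(0, "animal_id", animal_id)
        behaviour.insert(1, "counterbalance", counterbalance.value)
        behaviour.insert(2, "drug_group", drug_group)
        trials_frames.append(behaviour)

        if config.include_o2:
            o2_seed = int(child_rng(seed, "o2_seed", i).integers(2**31))
            electrode_plan = [
                ("NAc", f"{animal_id}_NAc{j}") for j in range(config.n_nac_electrodes)
            ] + [
                ("OFC", f"{animal_id}_OFC{j}") for j in range(config.n_ofc_electrodes)
            ]
            for region, electrode_id in electrode_plan:
                o2p = O2SimParams(**{
                    **REGION_PROFILES[region].__dict__, **config.o2_overrides
                })
                for sched in animal_scheds:
                    lat = behaviour[
                        behaviour["session"] == sched.session_index
                    ].reset_index(drop=True)
                    traces.append(
                        simulate_o2(
                            sched, lat, region_profile=region, o2_params=o2p,
                            seed=o2_seed, electrode_id=electrode_id,
                            animal_id=animal_id, drug_effect=params.drug_effect,
                        )
                    )

        gt_rows.append(
            {
                "animal_id": animal_id,
                "counterbalance": counterbalance.value,
                "drug_group": drug_group,
                **{k: getattr(params, k) for k in (
                    "alpha", "beta_clicker", "k_clicker", "k_tone",
                    "gamma_recency", "response_gain", "noise_sd",
                    "drug_effect", "baseline_mean", "baseline_sd",
                )},
            }
        )

    return Cohort(
        trials=pd.concat(trials_frames, ignore_index=True),
        traces=traces,
        ground_truth=pd.DataFrame(gt_rows),
        schedules=schedules,
        config=config,
        seed=int(seed),
    )
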