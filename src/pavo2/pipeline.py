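"""End-to-end pipeline: simulate -> fit -> epoch -> GLM -> drug contrast.

A run is reproducible from the config plus master seed alone; every JSON
artifact is stamped with the config hash and seed, and a manifest lists all
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import behaviour, glm as glm_mod, io as io_mod
from .cohort import Cohort, CohortConfig, simulate_cohort
from .drug import pre_post_contrast
from .signals import (
    CUE_AUC_WINDOW_S,
    OUTCOME_AUC_WINDOW_S,
    extract_epochs,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "read_config", "config_hash", "run_pipeline",
            "cohort_auc_tables", "fit_cohort_behaviour"]


@dataclass
class PipelineConfig:
    n_animals: int = 4
    seed: int = 0
    n_restarts: int = 5
    n_perm: int = 10_000
    cue_auc_window_s: tuple[float, float] = CUE_AUC_WINDOW_S
    outcome_auc_window_s: tuple[float, float] = OUTCOME_AUC_WINDOW_S
    cohort: CohortConfig = field(default_factory=CohortConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            d["cohort"] = CohortConfig(**d["cohort"])
        cfg = cls(**d)
        for name in ("cue_auc_window_s", "outcome_auc_window_s"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def read_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(raw)


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=list)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def fit_cohort_behaviour(
    cohort: Cohort,
    spec_grid: list[behaviour.ModelSpec] | None = None,
    n_restarts: int = 5,
    seed: int = 0,
) -> dict:
    """Fit the model grid to every animal's training behaviour (sessions 1-9)."""
    grid = spec_grid or behaviour.default_grid()
    traces = {
        a: cohort.animal_trials(a).query("session <= 9").reset_index(drop=True)
        for a in cohort.ground_truth["animal_id"]
    }
    return behaviour.compare_models(traces, grid, n_restarts=n_restarts, seed=seed)


def _outcome_events(session_df: pd.DataFrame, window_hi: float) -> pd.DataFrame:
    """Outcome event table, excluding trials whose window crosses the next cue."""
    ev = session_df[["trial", "cue", "rewarded", "outcome_onset_s",
                     "cue_onset_s", "session"]].copy()
    next_cue = ev["cue_onset_s"].shift(-1)
    crosses = next_cue.notna() & (next_cue < ev["outcome_onset_s"] + window_hi)
    if crosses.any():
        logger.info("excluding %d outcome trials crossing the next cue",
                    int(crosses.sum()))
    ev = ev[~crosses]
    return ev.rename(columns={"outcome_onset_s": "time_s"})[
        ["time_s", "session", "trial", "cue", "rewarded"]
    ]


def cohort_auc_tables(
    cohort: Cohort,
    cue_window: tuple[float, float] = CUE_AUC_WINDOW_S,
    outcome_window: tuple[float, float] = OUTCOME_AUC_WINDOW_S,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-trial cue and outcome AUC for every electrode-session trace.

    Cue epochs are baseline-corrected to the pre-cue mean ([-5, 0) s);
    outcome epochs are normalised to the signal value at the outcome.
    """
    cue_rows, out_rows = [], []
    for trace in cohort.traces:
        sess = cohort.trials[
            (cohort.trials["animal_id"] == trace.animal_id)
            & (cohort.trials["session"] == trace.session)
        ].reset_index(drop=True)
        ident = {
            "animal_id": trace.animal_id,
            "electrode_id": trace.electrode_id,
            "region": trace.region,
        }
        cue_ev = sess.rename(columns={"cue_onset_s": "time_s"})[
            ["time_s", "session", "trial", "cue", "rewarded"]
        ]
        eps = extract_epochs(
            trace, cue_ev, window_s=(-5.0, cue_window[1]),
            baseline_policy="subtract_pre_event_mean", alignment="cue_onset",
        )
        tab = eps.auc_table(*cue_window).assign(**ident)
        cue_rows.append(tab)

        out_ev = _outcome_events(sess, outcome_window[1])
        eps = extract_epochs(
            trace, out_ev, window_s=(0.0, outcome_window[1]),
            baseline_policy="subtract_value_at_event", alignment="outcome",
        )
        tab = eps.auc_table(*outcome_window).assign(**ident)
        out_rows.append(tab)
    cols = ["animal_id", "electrode_id", "region", "session", "trial",
            "cue", "rewarded", "auc"]
    return (
        pd.concat(cue_rows, ignore_index=True)[cols],
        pd.concat(out_rows, ignore_index=True)[cols],
    )


def electrode_glms(
    cohort: Cohort,
    fits: dict,
    cue_auc: pd.DataFrame,
    outcome_auc: pd.DataFrame,
    sessions: tuple[int, ...] = tuple(range(1, 10)),
) -> list[glm_mod.GlmResult]:
    """cue_value / outcome_rpe / outcome_unsigned GLMs per electrode.

    Latents come from each animal's best-BIC behavioural fit.
    """
    results = []
    best = fits["best_per_animal"]
    for (animal, electrode, region), _ in cue_auc.groupby(
        ["animal_id", "electrode_id", "region"], observed=True
    ):
        lat = fits["fits"][animal][best[animal].label].latents
        lat = lat[lat["session"].isin(sessions)]
        trials = cohort.animal_trials(animal)
        lat = lat.merge(
            trials[["session", "trial", "rewarded"]], on=["session", "trial"]
        )
        for kind, table in (
            ("cue_value", cue_auc), ("outcome_rpe", outcome_auc),
            ("outcome_unsigned", outcome_auc),
        ):
            sub = table[
                (table["electrode_id"] == electrode)
                & table["session"].isin(sessions)
            ]
            X, y = glm_mod.build_design(lat, sub, kind)
            results.append(
                glm_mod.fit_glm(X, y, electrode_id=electrode, region=region,
                                design_kind=kind)
            )
    return results


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage in order, writing the result bundle to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    stamp = {"config_hash": chash, "seed": config.seed}
    artifacts: list[str] = []

    def _fail(stage: str, exc: Exception):
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # -- simulate ----------------------------------------------------------
    try:
        cohort = simulate_cohort(config.n_animals, config.cohort, seed=config.seed)
        io_mod.write_trials(cohort.trials[list(io_mod.TRIAL_COLUMNS)],
                            outdir / "trials.csv")
        cohort.ground_truth.to_csv(outdir / "ground_truth.csv", index=False)
        artifacts += ["trials.csv", "ground_truth.csv"]
    except Exception as exc:
        _fail("simulate", exc)

    # -- fit behaviour -----------------------------------------------------
    try:
        fits = fit_cohort_behaviour(cohort, n_restarts=config.n_restarts,
                                    seed=config.seed)
        fits["bic_table"].to_csv(outdir / "bic_table.csv")
        records = {
            animal: {lab: fr.to_record() for lab, fr in by_spec.items()}
            for animal, by_spec in fits["fits"].items()
        }
        (outdir / "fits.json").write_text(json.dumps(
            {**stamp, "best_per_animal":
                {a: s.label for a, s in fits["best_per_animal"].items()},
             "population_preferred": fits["population_preferred"].label,
             "fits": records}, indent=1))
        artifacts += ["bic_table.csv", "fits.json"]
    except Exception as exc:
        _fail("fit-behaviour", exc)

    # -- epoch -------------------------------------------------------------
    try:
        cue_auc, outcome_auc = cohort_auc_tables(
            cohort, config.cue_auc_window_s, config.outcome_auc_window_s
        )
        cue_auc.to_csv(outdir / "auc_cue.csv", index=False)
        outcome_auc.to_csv(outdir / "auc_outcome.csv", index=False)
        artifacts += ["auc_cue.csv", "auc_outcome.csv"]
    except Exception as exc:
        _fail("epoch", exc)

    # -- glm ---------------------------------------------------------------
    try:
        glms = electrode_glms(cohort, fits, cue_auc, outcome_auc)
        pd.DataFrame([g.to_record() for g in glms]).to_csv(
            outdir / "glm.csv", index=False
        )
        artifacts.append("glm.csv")
    except Exception as exc:
        _fail("glm", exc)

    # -- drug contrast -----------------------------------------------------
    contrast_out = {}
    try:
        groups = dict(zip(cohort.ground_truth["animal_id"],
                          cohort.ground_truth["drug_group"]))
        pre = cohort.trials[cohort.trials["session"] == 9]
        drg = cohort.trials[cohort.trials["session"] == 10]
        try:
            res = pre_post_contrast(pre, drg, groups, n_perm=config.n_perm,
                                    seed=config.seed)
            contrast_out["head_entries"] = dataclasses.asdict(res)
        except ValueError as exc:
            contrast_out["head_entries"] = {"error": f"insufficient-n: {exc}"}
        (outdir / "contrast.json").write_text(
            json.dumps({**stamp, **contrast_out}, indent=1)
        )
        artifacts.append("contrast.json")
    except Exception as exc:
        _fail("drug-contrast", exc)

    manifest = {**stamp, "n_animals": config.n_animals, "artifacts": artifacts}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return {"cohort": cohort, "fits": fits, "cue_auc": cue_auc,
            "outcome_auc": outcome_auc, "glms": glms,
            "contrast": contrast_out, "manifest": manifest}
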