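"""Trial-by-trial regression of T_O2 responses on model-derived latents.

Three designs, all ordinary least squares with an intercept on regressors and
response z-scored within each electrode-session (so coefficients are
standardized effect sizes):

- ``cue_value``:        cue-period AUC ~ 1 + V(t)
- ``outcome_rpe``:      outcome AUC   ~ 1 + r(t) + V(t-1)
                        (the reward-prediction-error decomposition: an RPE
                        signal shows a positive r weight and a *negative*
                        V(t-1) weight)
- ``outcome_unsigned``: outcome AUC   ~ 1 + |r(t) - V(t-1)|  (salience)
- ``outcome_printed_delta``: outcome AUC ~ 1 + (V(t) + r(t) - V(t-1)),
                        an alternative single-regressor PE form.

V(t-1) denotes the presented cue's value before the current outcome's update
(column ``v_pre`` in the latents). The group level treats the electrode as
the unit of analysis: a two-sided one-sample t test of the per-electrode
standardized betas against zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "GlmResult",
    "RankDeficientDesignError",
    "build_design",
    "fit_glm",
    "group_effects",
    "rpe_criteria_check",
    "value_vs_behaviour_comparison",
    "DESIGN_KINDS",
]

DESIGN_KINDS = ("cue_value", "outcome_rpe", "outcome_unsigned",
                "outcome_printed_delta")


class RankDeficientDesignError(ValueError):
    """Design matrix is not full rank (e.g. a constant regressor)."""


@dataclass
class GlmResult:
    electrode_id: str
    region: str
    design_kind: str
    betas: dict = field(default_factory=dict)       # standardized coefficients
    se: dict = field(default_factory=dict)
    pvalues: dict = field(default_factory=dict)
    n_trials: int = 0
    r2: float = float("nan")

    def to_record(self) -> dict:
        rec = {
            "electrode_id": self.electrode_id,
            "region": self.region,
            "design_kind": self.design_kind,
            "n_trials": self.n_trials,
            "r2": self.r2,
        }
        for k, v in self.betas.items():
            rec[f"beta_{k}"] = v
            rec[f"se_{k}"] = self.se[k]
            rec[f"p_{k}"] = self.pvalues[k]
        return rec


def _zscore_by_session(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    out = df.copy()
    for col in cols:
        def z(x):
            sd = x.std(ddof=0)
            if sd < 1e-12:
                raise RankDeficientDesignError(
                    f"regressor {col!r} is constant within a session; "
                    "design is rank deficient after z-scoring"
                )
            return (x - x.mean()) / sd
        if "session" in out.columns:
            out[col] = out.groupby("session", observed=True)[col].transform(z)
        else:
            out[col] = z(out[col])
    return out


_KIND_COLUMNS = {
    "cue_value": ["v"],
    "outcome_rpe": ["r", "v_prev"],
    "outcome_unsigned": ["unsigned_pe"],
    "outcome_printed_delta": ["printed_delta"],
}


def build_design(
    latents: pd.DataFrame,
    auc_table: pd.DataFrame,
    kind: str,
) -> tuple[pd.DataFrame, pd.Series]:
    """Assemble the z-scored design matrix and response for one electrode.

    ``latents`` (from the best-BIC behavioural fit, columns v_pre, v_post and
    the trial table's rewarded flag) is merged to ``auc_table`` on
    (session, trial). Returns (X, y) with X carrying a ``const`` column and
    the kind's regressors, everything z-scored per session.
    """
    if kind not in DESIGN_KINDS:
        raise ValueError(f"kind must be one of {DESIGN_KINDS}, got {kind!r}")
    keys = [k for k in ("session", "trial") if
            k in latents.columns and k in auc_table.columns]
    if not keys:
        raise ValueError("latents and auc_table share no merge keys (session/trial)")
    lat_cols = keys + [c for c in ("v_pre", "v_post", "rewarded") if c in latents.columns]
    merged = auc_table.merge(latents[lat_cols], on=keys, how="inner",
                             suffixes=("", "_lat"))
    if len(merged) == 0:
        raise ValueError("no overlapping trials between latents and auc_table")
    if "rewarded_lat" in merged.columns:
        merged = merged.drop(columns="rewarded_lat")

    r = merged["rewarded"].astype(float)
    v = merged["v_pre"].astype(float)
    merged = merged.assign(
        v=v, v_prev=v, r=r, unsigned_pe=(r - v).abs(),
        printed_delta=merged["v_post"].astype(float) + r - v,
    )
    cols = _KIND_COLUMNS[kind]
    merged = _zscore_by_session(merged, cols + ["auc"])
    X = merged[cols].copy()
    X.insert(0, "const", 1.0)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise RankDeficientDesignError(
            f"design for kind={kind!r} has rank {rank} < {X.shape[1]}"
        )
    return X, merged["auc"]


def fit_glm(
    X: pd.DataFrame,
    y: pd.Series,
    electrode_id: str = "",
    region: str = "",
    design_kind: str = "",
) -> GlmResult:
    """Ordinary least squares on a prepared design; betas are standardized."""
    n, p = X.shape
    if n <= p + 2:
        raise ValueError(f"need n_trials > n_columns + 2, got n={n}, p={p}")
    if np.linalg.matrix_rank(X.to_numpy()) < p:
        raise RankDeficientDesignError("singular design matrix")
    res = sm.OLS(np.asarray(y, dtype=float), X).fit()
    return GlmResult(
        electrode_id=electrode_id,
        region=region,
        design_kind=design_kind,
        betas={k: float(v) for k, v in res.params.items()},
        se={k: float(v) for k, v in res.bse.items()},
        pvalues={k: float(v) for k, v in res.pvalues.items()},
        n_trials=int(n),
        r2=float(res.rsquared),
    )


def group_effects(
    glm_results: list[GlmResult],
    coef: str,
    min_electrodes: int = 3,
) -> pd.DataFrame:
    """Per-region mean effect size +/- SEM and one-sample two-sided t test.

    The electrode is the unit of analysis; electrodes from the same animal are
    not pooled.
    """
    rows = []
    by_region: dict[str, list[float]] = {}
    for g in glm_results:
        if coef not in g.betas:
            raise KeyError(f"coefficient {coef!r} absent from {g.design_kind} fit")
        by_region.setdefault(g.region, []).append(g.betas[coef])
    for region, betas in sorted(by_region.items()):
        if len(betas) < min_electrodes:
            raise ValueError(
                f"region {region!r} has {len(betas)} electrodes; "
                f"need >= {min_electrodes} for the group test"
            )
        arr = np.asarray(betas)
        t, p = stats.ttest_1samp(arr, 0.0)
        rows.append(
            {
                "region": region,
                "coef": coef,
                "mean_beta": float(arr.mean()),
                "sem": float(stats.sem(arr, ddof=1)),
                "t": float(t),
                "p": float(p),
                "n_electrodes": len(arr),
            }
        )
    return pd.DataFrame(rows)


def rpe_criteria_check(
    cue_glms: list[GlmResult],
    outcome_glms: list[GlmResult],
    alpha: float = 0.05,
) -> dict[str, bool]:
    """The three cardinal reward-prediction-error criteria at the group level.

    1. positive influence of expected value on the cue-elicited signal;
    2. positive influence of delivered reward on the outcome signal;
    3. negative influence of expected value on the outcome signal.

    Each criterion requires the correct group-level sign *and* a significant
    two-sided t test across electrodes. Inputs must cover one electrode set
    (one region).
    """
    regions = {g.region for g in cue_glms} | {g.region for g in outcome_glms}
    if len(regions) != 1:
        raise ValueError(f"expected a single region, got {sorted(regions)}")
    cue_v = group_effects(cue_glms, "v").iloc[0]
    out_r = group_effects(outcome_glms, "r").iloc[0]
    out_v = group_effects(outcome_glms, "v_prev").iloc[0]
    return {
        "positive_cue_value": bool(cue_v["mean_beta"] > 0 and cue_v["p"] < alpha),
        "positive_outcome": bool(out_r["mean_beta"] > 0 and out_r["p"] < alpha),
        "negative_value_at_outcome": bool(
            out_v["mean_beta"] < 0 and out_v["p"] < alpha
        ),
    }


def value_vs_behaviour_comparison(
    auc_table: pd.DataFrame,
    latents: pd.DataFrame,
    head_entries: pd.DataFrame,
) -> pd.DataFrame:
    """BIC contest: does cue value or raw behaviour predict the cue signal?

    Fits, per electrode table, two single-regressor models of cue-period AUC
    — one on model-derived V(t), one on the trial's observed cue-period
    head-entry rate — and reports delta_bic = BIC(V) - BIC(head entries).
    Negative favours value.
    """
    keys = [k for k in ("session", "trial") if k in auc_table.columns]
    merged = auc_table.merge(
        latents[keys + ["v_pre"]], on=keys
    ).merge(head_entries[keys + ["cue_rate"]], on=keys)
    merged = _zscore_by_session(merged, ["v_pre", "cue_rate", "auc"])
    y = merged["auc"].to_numpy(dtype=float)
    out = {}
    for name, col in (("value", "v_pre"), ("behaviour", "cue_rate")):
        X = sm.add_constant(merged[col].to_numpy(dtype=float))
        out[name] = sm.OLS(y, X).fit()
    return pd.DataFrame(
        [
            {
                "bic_value": float(out["value"].bic),
                "bic_behaviour": float(out["behaviour"].bic),
                "delta_bic": float(out["value"].bic - out["behaviour"].bic),
                "n_trials": len(y),
            }
        ]
    )
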