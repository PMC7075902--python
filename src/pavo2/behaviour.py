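"""Rescorla-Wagner model grid, maximum-likelihood fitting and BIC comparison.

The model family starts from a single-learning-rate Rescorla-Wagner model of
cue-period head-entry rates and optionally adds

- a cue salience term ``beta`` (cue-specific learning rates; beta_tone = 1,
  beta_clicker free),
- separate learning rates for rewarded (``alpha_pos``) and non-rewarded
  (``alpha_neg``) trials,
- unconditioned magazine responding, either shared (``k``) or cue-specific
  (``k_clicker``, ``k_tone``),
- a pre-cue baseline term, either the trial's observed pre-cue rate with a
  fitted coefficient or a recency-weighted (exponentially smoothed) pre-cue
  rate.

Predicted cue-period rate:

    rate(t) = gain * V_cue(t) + k_term(sound) + baseline_term(t)

with V updated by V <- V + alpha_eff * (r - V), alpha_eff = alpha * beta_sound
(clipped to (0, 1]), carried across sessions, V0 = 0.

Observed rates are modelled as Gaussian around the prediction with free sigma;
models are compared by BIC = n_params * ln(n_obs) + 2 * NLL, where n_obs is
the number of cue presentations fitted and n_params counts every free
parameter including gain and sigma.

Fitting is bounded multi-start local optimisation. Internally, parameters
that enter the prediction linearly (gain, k, baseline coefficient) are
profiled out at each evaluation of the nonlinear parameters via bounded least
squares, and sigma by its closed-form MLE; this is exactly the joint maximum
but searches only the 1-4 nonlinear dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc

__all__ = [
    "ModelSpec",
    "FitResult",
    "rw_update",
    "recency_baseline",
    "predict_responses",
    "negloglik",
    "fit_model",
    "compare_models",
    "default_grid",
    "STANDARD_SPEC",
    "FULL_SPEC",
    "BOUNDS",
]

K_MODES = ("none", "shared", "cue_specific")
BASELINE_MODES = ("none", "trial_specific", "recency_weighted")

#: Optimisation bounds per parameter.
BOUNDS: dict[str, tuple[float, float]] = {
    "alpha": (0.001, 0.999),
    "alpha_pos": (0.001, 0.999),
    "alpha_neg": (0.001, 0.999),
    "beta_clicker": (0.01, 10.0),
    "gamma_recency": (0.001, 0.999),
    "gain": (0.0, 20.0),
    "k": (0.0, 20.0),
    "k_clicker": (0.0, 20.0),
    "k_tone": (0.0, 20.0),
    "w_pre": (0.0, 20.0),
    "sigma": (1e-3, 50.0),
}


class FitError(RuntimeError):
    """Raised when every optimisation restart fails."""


@dataclass(frozen=True)
class ModelSpec:
    """One member of the model grid, identified by its component flags."""

    salience: bool = False
    split_alpha: bool = False
    k_mode: str = "none"
    baseline_mode: str = "none"

    def __post_init__(self) -> None:
        if self.k_mode not in K_MODES:
            raise ValueError(f"k_mode must be one of {K_MODES}, got {self.k_mode!r}")
        if self.baseline_mode not in BASELINE_MODES:
            raise ValueError(
                f"baseline_mode must be one of {BASELINE_MODES}, "
                f"got {self.baseline_mode!r}"
            )

    @property
    def nonlinear_params(self) -> list[str]:
        names = ["alpha_pos", "alpha_neg"] if self.split_alpha else ["alpha"]
        if self.salience:
            names.append("beta_clicker")
        if self.baseline_mode == "recency_weighted":
            names.append("gamma_recency")
        return names

    @property
    def linear_params(self) -> list[str]:
        names = ["gain"]
        if self.k_mode == "shared":
            names.append("k")
        elif self.k_mode == "cue_specific":
            names += ["k_clicker", "k_tone"]
        if self.baseline_mode == "trial_specific":
            names.append("w_pre")
        return names

    @property
    def param_names(self) -> list[str]:
        return self.nonlinear_params + self.linear_params + ["sigma"]

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def label(self) -> str:
        parts = []
        parts.append("salience" if self.salience else None)
        parts.append("split_alpha" if self.split_alpha else None)
        parts.append(f"k_{self.k_mode}" if self.k_mode != "none" else None)
        parts.append(self.baseline_mode if self.baseline_mode != "none" else None)
        parts = [p for p in parts if p]
        return "+".join(parts) if parts else "standard"


STANDARD_SPEC = ModelSpec()
FULL_SPEC = ModelSpec(salience=True, k_mode="cue_specific",
                      baseline_mode="recency_weighted")


def default_grid() -> list[ModelSpec]:
    """Standard model, each single-component variant, and the full model."""
    return [
        STANDARD_SPEC,
        ModelSpec(salience=True),
        ModelSpec(split_alpha=True),
        ModelSpec(k_mode="shared"),
        ModelSpec(k_mode="cue_specific"),
        ModelSpec(baseline_mode="trial_specific"),
        ModelSpec(baseline_mode="recency_weighted"),
        FULL_SPEC,
    ]


def rw_update(v: float, r: float, alpha_eff: float) -> float:
    """One Rescorla-Wagner step: v + alpha_eff * (r - v)."""
    if not 0.0 < alpha_eff <= 1.0:
        raise ValueError(f"alpha_eff must be in (0,1], got {alpha_eff}")
    if not 0.0 <= v <= 1.0:
        raise ValueError(f"v must be in [0,1], got {v}")
    if r not in (0, 1, 0.0, 1.0):
        raise ValueError(f"r must be 0 or 1, got {r}")
    return v + alpha_eff * (r - v)


def recency_baseline(pre_cue_rates: np.ndarray, gamma: float, b0: float) -> np.ndarray:
    """Exponentially smoothed pre-cue rates: b(1)=b0, b(t)=g*b(t-1)+(1-g)*rate(t-1)."""
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must be in [0,1], got {gamma}")
    rates = np.asarray(pre_cue_rates, dtype=float)
    if (rates < 0).any():
        raise ValueError("pre-cue rates must be non-negative")
    b = np.empty(len(rates))
    if len(rates) == 0:
        return b
    b[0] = b0
    for t in range(1, len(rates)):
        b[t] = gamma * b[t - 1] + (1.0 - gamma) * rates[t - 1]
    return b


_REQUIRED_COLS = ("cue", "sound", "rewarded", "pre_cue_rate")


def _value_trajectory(trace: pd.DataFrame, params: dict, spec: ModelSpec) -> np.ndarray:
    """Presented cue's value at each cue onset (before that trial's update)."""
    is_high = (trace["cue"].to_numpy() == "CS_High")
    is_clicker = (trace["sound"].to_numpy() == "clicker")
    r = trace["rewarded"].to_numpy().astype(float)
    if spec.split_alpha:
        a_pos, a_neg = params["alpha_pos"], params["alpha_neg"]
    else:
        a_pos = a_neg = params["alpha"]
    beta_c = params["beta_clicker"] if spec.salience else 1.0
    v = np.zeros(2)  # [CS_High, CS_Low]
    out = np.empty(len(trace))
    for t in range(len(trace)):
        c = 0 if is_high[t] else 1
        out[t] = v[c]
        alpha = a_pos if r[t] else a_neg
        alpha_eff = min(alpha * (beta_c if is_clicker[t] else 1.0), 1.0)
        v[c] += alpha_eff * (r[t] - v[c])
    return out


def _design_columns(
    trace: pd.DataFrame, params: dict, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Linear design (columns ordered as spec.linear_params) and fixed offset."""
    n = len(trace)
    v = _value_trajectory(trace, params, spec)
    cols = [v]
    is_clicker = (trace["sound"].to_numpy() == "clicker").astype(float)
    if spec.k_mode == "shared":
        cols.append(np.ones(n))
    elif spec.k_mode == "cue_specific":
        cols += [is_clicker, 1.0 - is_clicker]
    offset = np.zeros(n)
    if spec.baseline_mode == "trial_specific":
        cols.append(trace["pre_cue_rate"].to_numpy().astype(float))
    elif spec.baseline_mode == "recency_weighted":
        rates = trace["pre_cue_rate"].to_numpy().astype(float)
        if "session" in trace.columns:
            sess = trace["session"].to_numpy()
            b0 = float(rates[sess == sess[0]].mean())
        else:
            b0 = float(rates.mean())
        offset = recency_baseline(rates, params["gamma_recency"], b0)
    return np.column_stack(cols), offset


def predict_responses(
    trace: pd.DataFrame, params: dict, spec: ModelSpec
) -> tuple[np.ndarray, pd.DataFrame]:
    """Predicted cue-period rate per trial plus latent trajectories.

    ``trace`` holds the (possibly multi-session) trial table with columns
    cue, sound, rewarded, pre_cue_rate and session. Returns the prediction
    vector and a latents frame with v_pre, v_post, delta and predicted_rate.
    """
    for col in _REQUIRED_COLS:
        if col not in trace.columns:
            raise ValueError(f"trace is missing required column {col!r}")
    missing = [p for p in spec.param_names if p != "sigma" and p not in params]
    if missing:
        raise KeyError(f"missing parameter(s) {missing} for spec {spec.label}")
    X, offset = _design_columns(trace, params, spec)
    theta = np.array([params[name] for name in spec.linear_params])
    pred = X @ theta + offset
    r = trace["rewarded"].to_numpy().astype(float)
    v_pre = X[:, 0]
    latents = pd.DataFrame(
        {
            "v_pre": v_pre,
            "delta": r - v_pre,
            "v_post": _post_values(trace, params, spec, v_pre, r),
            "predicted_rate": pred,
        }
    )
    if "session" in trace.columns:
        latents.insert(0, "session", trace["session"].to_numpy())
    if "trial" in trace.columns:
        latents.insert(1, "trial", trace["trial"].to_numpy())
    return pred, latents


def _post_values(trace, params, spec, v_pre, r):
    if spec.split_alpha:
        alpha = np.where(r > 0, params["alpha_pos"], params["alpha_neg"])
    else:
        alpha = np.full(len(r), params["alpha"])
    beta_c = params["beta_clicker"] if spec.salience else 1.0
    is_clicker = (trace["sound"].to_numpy() == "clicker")
    alpha_eff = np.minimum(alpha * np.where(is_clicker, beta_c, 1.0), 1.0)
    return v_pre + alpha_eff * (r - v_pre)


def negloglik(trace: pd.DataFrame, params: dict, spec: ModelSpec) -> float:
    """Gaussian negative log-likelihood of observed cue_rate around predictions."""
    sigma = params.get("sigma")
    if sigma is None or sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    pred, _ = predict_responses(trace, params, spec)
    resid = trace["cue_rate"].to_numpy().astype(float) - pred
    n = len(resid)
    return float(
        0.5 * n * np.log(2 * np.pi * sigma**2) + (resid @ resid) / (2 * sigma**2)
    )


@dataclass
class FitResult:
    spec: ModelSpec
    params: dict
    nll: float
    bic: float
    n_obs: int
    n_params: int
    latents: pd.DataFrame = field(repr=False)

    def to_record(self) -> dict:
        return {
            "model": self.spec.label,
            "params": {k: float(v) for k, v in self.params.items()},
            "nll": float(self.nll),
            "bic": float(self.bic),
            "n_obs": int(self.n_obs),
            "n_params": int(self.n_params),
        }


def _profiled_nll(trace: pd.DataFrame, theta: np.ndarray, spec: ModelSpec):
    """NLL at nonlinear params ``theta`` with linear params and sigma profiled."""
    params = dict(zip(spec.nonlinear_params, theta))
    X, offset = _design_columns(trace, params, spec)
    y = trace["cue_rate"].to_numpy().astype(float) - offset
    lb = np.array([BOUNDS[p][0] for p in spec.linear_params])
    ub = np.array([BOUNDS[p][1] for p in spec.linear_params])
    sol = optimize.lsq_linear(X, y, bounds=(lb, ub), method="bvls")
    coef = sol.x
    resid = y - X @ coef
    n = len(y)
    sigma = float(np.clip(np.sqrt((resid @ resid) / n), *BOUNDS["sigma"]))
    nll = 0.5 * n * np.log(2 * np.pi * sigma**2) + (resid @ resid) / (2 * sigma**2)
    params.update(dict(zip(spec.linear_params, coef)))
    params["sigma"] = sigma
    return float(nll), params


def fit_model(
    trace: pd.DataFrame,
    spec: ModelSpec,
    n_restarts: int = 20,
    seed: int = 0,
) -> FitResult:
    """Fit one model by bounded multi-start maximum likelihood.

    Restarts are Latin-hypercube draws over the nonlinear parameters;
    the restart with the lowest NLL wins. Deterministic given the seed.
    """
    if n_restarts < 1:
        raise ValueError(f"n_restarts must be >= 1, got {n_restarts}")
    nl = spec.nonlinear_params
    lb = np.array([BOUNDS[p][0] for p in nl])
    ub = np.array([BOUNDS[p][1] for p in nl])
    sampler = qmc.LatinHypercube(d=len(nl), seed=int(seed) & 0x7FFFFFFF)
    starts = lb + sampler.random(n_restarts) * (ub - lb)

    def objective(theta: np.ndarray) -> float:
        return _profiled_nll(trace, theta, spec)[0]

    best = None
    n_failed = 0
    for x0 in starts:
        try:
            res = optimize.minimize(
                objective, x0, method="L-BFGS-B",
                bounds=list(zip(lb, ub)),
                options={"maxiter": 200},
            )
        except Exception:
            n_failed += 1
            continue
        if not np.isfinite(res.fun):
            n_failed += 1
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise FitError(
            f"all {n_restarts} restarts failed for model {spec.label!r} "
            f"({n_failed} optimizer failures)"
        )

    nll, params = _profiled_nll(trace, best.x, spec)
    _, latents = predict_responses(trace, params, spec)
    n_obs = len(trace)
    bic = spec.n_params * np.log(n_obs) + 2.0 * nll
    return FitResult(
        spec=spec, params=params, nll=nll, bic=float(bic),
        n_obs=n_obs, n_params=spec.n_params, latents=latents,
    )


def compare_models(
    traces_per_animal: dict[str, pd.DataFrame],
    spec_grid: list[ModelSpec],
    n_restarts: int = 20,
    seed: int = 0,
) -> dict:
    """Fit the grid to every animal and tabulate BIC.

    Returns a dict with:
      ``bic_table``  — DataFrame animals x model labels of BIC values;
      ``fits``       — {animal: {label: FitResult}};
      ``best_per_animal`` — {animal: winning ModelSpec} (ties to the spec with
      fewer parameters, then grid order);
      ``win_counts`` — {label: number of animals for which it is best};
      ``population_preferred`` — spec with the lowest BIC summed over animals.
    """
    if len(traces_per_animal) < 1:
        raise ValueError("need at least one animal")
    if len(spec_grid) < 2:
        raise ValueError("need at least two model specs to compare")
    fits: dict[str, dict[str, FitResult]] = {}
    for a_idx, (animal, trace) in enumerate(sorted(traces_per_animal.items())):
        fits[animal] = {}
        for s_idx, spec in enumerate(spec_grid):
            fits[animal][spec.label] = fit_model(
                trace, spec, n_restarts=n_restarts,
                seed=int(seed) + 1000 * a_idx + s_idx,
            )
    labels = [s.label for s in spec_grid]
    bic_table = pd.DataFrame(
        {lab: [fits[a][lab].bic for a in sorted(fits)] for lab in labels},
        index=sorted(fits),
    )

    def _winner(bics: pd.Series) -> ModelSpec:
        best_bic = bics.min()
        tied = [
            s for s in spec_grid if abs(fits_row[s.label].bic - best_bic) <= 1e-9
        ]
        tied.sort(key=lambda s: (s.n_params, spec_grid.index(s)))
        return tied[0]

    best_per_animal = {}
    for animal in sorted(fits):
        fits_row = fits[animal]
        best_per_animal[animal] = _winner(bic_table.loc[animal])
    win_counts = {lab: 0 for lab in labels}
    for spec in best_per_animal.values():
        win_counts[spec.label] += 1
    summed = bic_table.sum(axis=0)
    best_sum = summed.min()
    tied = [s for s in spec_grid if abs(summed[s.label] - best_sum) <= 1e-9]
    tied.sort(key=lambda s: (s.n_params, spec_grid.index(s)))
    return {
        "bic_table": bic_table,
        "fits": fits,
        "best_per_animal": best_per_animal,
        "win_counts": win_counts,
        "population_preferred": tied[0],
    }
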