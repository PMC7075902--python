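"""Pre-drug vs drug-session contrasts.

The amphetamine question — does the drug abolish cue discrimination over and
above any session-to-session change seen under vehicle? — is answered with a
permutation difference-of-differences test: the statistic is

    [mean over amphetamine animals of (drug - pre) discrimination]
  - [mean over vehicle animals of (drug - pre) discrimination]

and the null distribution permutes the drug-group labels across animals
(exact enumeration of label assignments whenever feasible). This preserves
the cue x session x drug interaction logic of a mixed ANOVA while being fully
reproducible from the seed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seeds import child_rng

__all__ = [
    "ContrastResult",
    "discrimination_index",
    "pre_post_contrast",
    "outcome_blunting",
]

_MEASURE_COLS = {"head_entries": "cue_rate", "cue_auc": "auc"}


@dataclass
class ContrastResult:
    metric: str
    pre_value: dict                 # group -> mean pre-session index
    drug_value: dict                # group -> mean drug-session index
    interaction_estimate: float     # difference of differences
    permutation_p: float
    n_permutations: int
    exact: bool
    seed: int


def discrimination_index(session_table: pd.DataFrame, measure: str) -> float:
    """mean(CS_High) - mean(CS_Low) of the chosen per-trial measure."""
    if measure not in _MEASURE_COLS:
        raise ValueError(
            f"measure must be one of {sorted(_MEASURE_COLS)}, got {measure!r}"
        )
    col = _MEASURE_COLS[measure]
    if col not in session_table.columns:
        raise ValueError(f"session table lacks column {col!r} for measure {measure!r}")
    by_cue = session_table.groupby("cue", observed=True)[col].mean()
    for cue in ("CS_High", "CS_Low"):
        if cue not in by_cue.index:
            raise ValueError(f"cue {cue!r} missing from session table")
    return float(by_cue["CS_High"] - by_cue["CS_Low"])


def _per_animal_delta(
    pre_tables: pd.DataFrame, drug_tables: pd.DataFrame, measure: str
) -> pd.Series:
    deltas = {}
    pre_by = dict(tuple(pre_tables.groupby("animal_id", observed=True)))
    drug_by = dict(tuple(drug_tables.groupby("animal_id", observed=True)))
    animals = sorted(pre_by)
    if sorted(drug_by) != animals:
        raise ValueError("every animal needs both a pre and a drug session")
    for animal in animals:
        deltas[animal] = discrimination_index(
            drug_by[animal], measure
        ) - discrimination_index(pre_by[animal], measure)
    return pd.Series(deltas)


def pre_post_contrast(
    pre_tables: pd.DataFrame,
    drug_tables: pd.DataFrame,
    groups: dict[str, str],
    n_perm: int = 10_000,
    seed: int = 0,
    measure: str = "head_entries",
) -> ContrastResult:
    """Permutation difference-of-differences test of the drug effect.

    ``pre_tables``/``drug_tables`` are trial tables with an ``animal_id``
    column; ``groups`` maps animal_id -> "vehicle" | "amphetamine". When the
    number of distinct label assignments is at most ``n_perm`` the null is
    enumerated exactly (p = proportion of assignments with |null| >= |obs|,
    which includes the observed one, so p > 0); otherwise ``n_perm`` random
    label permutations are drawn and p = (1 + #{|null| >= |obs|}) / (n_perm + 1).
    """
    bad = set(groups.values()) - {"vehicle", "amphetamine"}
    if bad:
        raise ValueError(f"unknown group label(s) {sorted(bad)}")
    deltas = _per_animal_delta(pre_tables, drug_tables, measure)
    animals = list(deltas.index)
    labels = np.array([groups[a] for a in animals])
    n_amph = int((labels == "amphetamine").sum())
    n_veh = int((labels == "vehicle").sum())
    if min(n_amph, n_veh) < 2:
        raise ValueError(
            f"each group needs >= 2 animals, got amphetamine={n_amph}, "
            f"vehicle={n_veh}"
        )
    d = deltas.to_numpy()

    def stat(is_amph: np.ndarray) -> float:
        return float(d[is_amph].mean() - d[~is_amph].mean())

    obs = stat(labels == "amphetamine")
    n_total = math.comb(len(animals), n_amph)
    if n_total <= n_perm:
        null = np.array([
            stat(np.isin(np.arange(len(animals)), combo))
            for combo in itertools.combinations(range(len(animals)), n_amph)
        ])
        p = float((np.abs(null) >= abs(obs) - 1e-12).sum() / n_total)
        n_used, exact = n_total, True
    else:
        rng = child_rng(seed, "drug_perm")
        count = 0
        base = np.zeros(len(animals), dtype=bool)
        base[:n_amph] = True
        for _ in range(n_perm):
            perm = rng.permutation(base)
            if abs(stat(perm)) >= abs(obs) - 1e-12:
                count += 1
        p = float((1 + count) / (n_perm + 1))
        n_used, exact = n_perm, False

    def _group_means(tables: pd.DataFrame) -> dict:
        out: dict[str, float] = {}
        for grp in ("vehicle", "amphetamine"):
            sel = [a for a in animals if groups[a] == grp]
            idxs = [
                discrimination_index(
                    tables[tables["animal_id"] == a], measure
                )
                for a in sel
            ]
            out[grp] = float(np.mean(idxs))
        return out

    return ContrastResult(
        metric=measure,
        pre_value=_group_means(pre_tables),
        drug_value=_group_means(drug_tables),
        interaction_estimate=obs,
        permutation_p=p,
        n_permutations=n_used,
        exact=exact,
        seed=int(seed),
    )


def outcome_blunting(
    pre_auc: pd.DataFrame, drug_auc: pd.DataFrame
) -> pd.DataFrame:
    """Drug-minus-pre change in outcome AUC per (region, cue, outcome) cell."""
    keys = [k for k in ("region", "cue", "rewarded") if
            k in pre_auc.columns and k in drug_auc.columns]
    if "cue" not in keys or "rewarded" not in keys:
        raise ValueError("AUC tables need 'cue' and 'rewarded' columns")
    pre = pre_auc.groupby(keys, observed=True)["auc"].mean().rename("pre_mean")
    drug = drug_auc.groupby(keys, observed=True)["auc"].mean().rename("drug_mean")
    out = pd.concat([pre, drug], axis=1).reset_index()
    out["change"] = out["drug_mean"] - out["pre_mean"]
    return out
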