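"""Event-locked analysis of tissue-oxygen (T_O2) traces.

Model-free summaries of amperometric oxygen signals: epoch extraction
time-locked to cue or outcome, area-under-the-curve (AUC) in fixed windows
(5-10 s after cue onset; 0-30 s after outcome), training-stage averages, and
cross-region correlation of per-trial responses.

Epoching never interpolates: event times snap to the trace's sample grid.
AUC is a trapezoidal integral on the native grid, in units of signal x s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "O2Trace",
    "EpochSet",
    "extract_epochs",
    "auc",
    "stage_summaries",
    "cross_region_correlation",
    "DEFAULT_STAGES",
    "CUE_AUC_WINDOW_S",
    "OUTCOME_AUC_WINDOW_S",
]

# AUC windows used throughout: cue-period response 5-10 s after cue onset,
# outcome response over the 30 s following the outcome.
CUE_AUC_WINDOW_S = (5.0, 10.0)
OUTCOME_AUC_WINDOW_S = (0.0, 30.0)

#: Training-stage partition: nine sessions in three equal stages.
DEFAULT_STAGES = {1: (1, 2, 3), 2: (4, 5, 6), 3: (7, 8, 9)}

_BASELINE_POLICIES = ("none", "subtract_pre_event_mean", "subtract_value_at_event")


@dataclass
class O2Trace:
    """Uniformly sampled oxygen signal from one electrode in one session."""

    time_s: np.ndarray
    signal: np.ndarray
    region: str                     # "NAc" or "OFC"
    electrode_id: str
    animal_id: str
    session: int

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time_s.shape != self.signal.shape or self.time_s.ndim != 1:
            raise ValueError("time_s and signal must be 1-D arrays of equal length")
        if len(self.time_s) < 2:
            raise ValueError("trace must contain at least two samples")
        dts = np.diff(self.time_s)
        if dts.min() <= 0:
            raise ValueError("sample times must be strictly increasing")
        if dts.max() - dts.min() > 1e-9:
            raise ValueError(
                "non-uniform sampling: dt range "
                f"[{dts.min():.6g}, {dts.max():.6g}] s exceeds 1e-9 tolerance"
            )

    @property
    def dt(self) -> float:
        return float(self.time_s[1] - self.time_s[0])


@dataclass
class EpochSet:
    """Per-trial windows aligned to an event (relative time 0 at the event)."""

    rel_time_s: np.ndarray          # (n_samples,)
    data: np.ndarray                # (n_epochs, n_samples)
    meta: pd.DataFrame              # one row per kept epoch (event metadata)
    alignment: str                  # "cue_onset" or "outcome"
    excluded: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return self.data.shape[0]

    def auc_table(self, from_s: float, to_s: float) -> pd.DataFrame:
        """Meta table with one trapezoidal AUC per epoch over [from_s, to_s]."""
        out = self.meta.copy()
        out["auc"] = [auc(self.rel_time_s, row, from_s, to_s) for row in self.data]
        return out


def extract_epochs(
    trace: O2Trace,
    events: pd.DataFrame,
    window_s: tuple[float, float],
    baseline_policy: str = "none",
    alignment: str = "cue_onset",
    pre_event_window_s: tuple[float, float] = (-5.0, 0.0),
) -> EpochSet:
    """Cut event-locked windows out of a trace.

    ``events`` needs a ``time_s`` column; all other columns are carried into
    the epoch metadata. Windows snap to the sample grid (nearest sample to the
    event defines relative time 0). Baseline policies:

    - ``none``: raw signal.
    - ``subtract_pre_event_mean``: subtract the mean over the half-open
      pre-event window (default [-5, 0) s).
    - ``subtract_value_at_event``: subtract the sample at the event, so every
      epoch is 0 at relative time 0 (the outcome analyses normalise this way).

    Events whose window (or required baseline window) falls outside the trace
    are excluded and logged, not an error.
    """
    if baseline_policy not in _BASELINE_POLICIES:
        raise ValueError(
            f"baseline_policy must be one of {_BASELINE_POLICIES}, got {baseline_policy!r}"
        )
    if "time_s" not in events.columns:
        raise ValueError("events frame must contain a 'time_s' column")
    lo, hi = window_s
    if not hi > lo:
        raise ValueError(f"empty window {window_s}")

    dt = trace.dt
    t0 = trace.time_s[0]
    n = len(trace.time_s)
    off_lo = int(round(lo / dt))
    off_hi = int(round(hi / dt))
    offsets = np.arange(off_lo, off_hi + 1)
    rel_time = offsets * dt
    base_lo = int(round(pre_event_window_s[0] / dt))
    base_hi = int(round(pre_event_window_s[1] / dt))   # half-open: excludes this offset

    rows, meta_rows, excluded = [], [], []
    for pos, (_, ev) in enumerate(events.iterrows()):
        i_ev = int(round((float(ev["time_s"]) - t0) / dt))
        need_lo = i_ev + off_lo
        need_hi = i_ev + off_hi
        if baseline_policy == "subtract_pre_event_mean":
            need_lo = min(need_lo, i_ev + base_lo)
        if need_lo < 0 or need_hi >= n or not 0 <= i_ev < n:
            excluded.append(pos)
            continue
        seg = trace.signal[i_ev + off_lo : i_ev + off_hi + 1].copy()
        if baseline_policy == "subtract_pre_event_mean":
            seg -= trace.signal[i_ev + base_lo : i_ev + base_hi].mean()
        elif baseline_policy == "subtract_value_at_event":
            seg -= trace.signal[i_ev]
        rows.append(seg)
        meta_rows.append(ev)

    if excluded:
        logger.info(
            "extract_epochs: excluded %d/%d events outside trace bounds "
            "(electrode %s, session %s): positions %s",
            len(excluded), len(events), trace.electrode_id, trace.session, excluded,
        )
    data = np.vstack(rows) if rows else np.empty((0, len(rel_time)))
    meta = pd.DataFrame(meta_rows).reset_index(drop=True)
    return EpochSet(rel_time_s=rel_time, data=data, meta=meta,
                    alignment=alignment, excluded=excluded)


def auc(rel_time_s: np.ndarray, values: np.ndarray, from_s: float, to_s: float) -> float:
    """Trapezoidal area under ``values`` over [from_s, to_s] on the sample grid."""
    rel_time_s = np.asarray(rel_time_s, dtype=float)
    values = np.asarray(values, dtype=float)
    if not to_s > from_s:
        raise ValueError(f"empty AUC window [{from_s}, {to_s}]")
    eps = 1e-9
    mask = (rel_time_s >= from_s - eps) & (rel_time_s <= to_s + eps)
    if mask.sum() < 2:
        raise ValueError(
            f"AUC window [{from_s}, {to_s}] s contains fewer than two samples"
        )
    return float(np.trapezoid(values[mask], rel_time_s[mask]))


def stage_summaries(
    auc_table: pd.DataFrame,
    stages: dict[int, tuple[int, ...]] | None = None,
    by_outcome: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean +/- SEM of AUC per cue x session and per cue x training stage.

    With ``by_outcome`` the grouping additionally splits rewarded vs omitted
    trials (used for outcome-aligned responses).
    """
    if "session" not in auc_table.columns:
        raise ValueError("auc_table must carry a 'session' column")
    stages = DEFAULT_STAGES if stages is None else stages
    keys = ["cue", "session"] + (["rewarded"] if by_outcome else [])
    per_session = (
        auc_table.groupby(keys, observed=True)["auc"]
        .agg(mean="mean", sem=lambda x: stats.sem(x, ddof=1) if len(x) > 1 else 0.0,
             n="count")
        .reset_index()
    )
    session_to_stage = {s: k for k, ss in stages.items() for s in ss}
    staged = auc_table[auc_table["session"].isin(session_to_stage)].copy()
    staged["stage"] = staged["session"].map(session_to_stage)
    keys = ["cue", "stage"] + (["rewarded"] if by_outcome else [])
    per_stage = (
        staged.groupby(keys, observed=True)["auc"]
        .agg(mean="mean", sem=lambda x: stats.sem(x, ddof=1) if len(x) > 1 else 0.0,
             n="count")
        .reset_index()
    )
    return per_session, per_stage


def cross_region_correlation(nac_auc: np.ndarray, ofc_auc: np.ndarray) -> float:
    """Squared Pearson correlation between trial-aligned NAc and OFC AUC series."""
    x = np.asarray(nac_auc, dtype=float)
    y = np.asarray(ofc_auc, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must be aligned (equal length)")
    if len(x) < 3:
        raise ValueError(f"need at least 3 paired points, got {len(x)}")
    r = stats.pearsonr(x, y).statistic
    return float(r * r)
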