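"""From transaction records to windowed supervised samples.

The pipeline is: aggregate transactions to a weekly demand panel (zero-filled
over the full span, a week with no sales meaning zero demand), drop drugs with
fewer than 40 valid sales weeks, correct 3-sigma outliers against sliding
window statistics, split chronologically (last 8 weeks test, preceding 4
validation), min-max scale on training weeks only, and slide a 16-week window
one week at a time to produce graph-window samples whose target is the next
week's demand of one target drug.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.preprocessing import MinMaxScaler

from .knowledge_graph import KnowledgeGraph, khop_subgraph

__all__ = [
    "DemandPanel",
    "SplitSpec",
    "GraphWindowSample",
    "aggregate_weekly",
    "filter_min_history",
    "clip_outliers",
    "chronological_split",
    "scale_series",
    "scale_panel",
    "assemble_windows",
    "stack_samples",
]

#: sliding-window length in weeks; one sample spans this many weeks of history
WINDOW = 16
#: minimum number of valid (>=1 transaction) weeks for a drug to be retained
MIN_VALID_WEEKS = 40
#: outlier threshold in standard deviations
OUTLIER_SIGMA = 3.0
TEST_WEEKS = 8
VAL_WEEKS = 4


@dataclass
class DemandPanel:
    """Drugs x weeks demand matrix with a transaction-presence mask."""

    drug_ids: list[str]
    week_index: list[str]  # consecutive ISO week labels "YYYY-Www"
    demand: np.ndarray  # (n_drugs, n_weeks), non-negative
    valid_week_mask: np.ndarray  # (n_drugs, n_weeks) 0/1

    def __post_init__(self) -> None:
        self.demand = np.asarray(self.demand, dtype=float)
        self.valid_week_mask = np.asarray(self.valid_week_mask)
        d, w = len(self.drug_ids), len(self.week_index)
        if self.demand.shape != (d, w) or self.valid_week_mask.shape != (d, w):
            raise ValueError("demand/mask shape does not match drug and week counts")
        if (self.demand < 0).any():
            raise ValueError("demand must be non-negative")
        if ((self.valid_week_mask == 0) & (self.demand != 0)).any():
            raise ValueError("mask=0 cells must have zero demand")

    @property
    def n_weeks(self) -> int:
        return len(self.week_index)

    def valid_weeks(self) -> np.ndarray:
        """Valid-week count per drug."""
        return self.valid_week_mask.sum(axis=1).astype(int)

    def series(self, drug_id: str) -> np.ndarray:
        return self.demand[self.drug_ids.index(drug_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.demand, index=self.drug_ids, columns=self.week_index)


@dataclass(frozen=True)
class SplitSpec:
    """Chronological week-index partition: train < validation < test."""

    train_weeks: range
    val_weeks: range
    test_weeks: range

    def __post_init__(self) -> None:
        t, v, s = self.train_weeks, self.val_weeks, self.test_weeks
        if not (t.stop == v.start and v.stop == s.start):
            raise ValueError("ranges must be contiguous and ordered train<val<test")

    def region(self, week: int) -> str:
        for name, rng in (("train", self.train_weeks), ("val", self.val_weeks), ("test", self.test_weeks)):
            if week in rng:
                return name
        raise ValueError(f"week {week} outside the panel")


@dataclass
class GraphWindowSample:
    """One supervised instance for one target drug.

    ``snapshot_features`` is (T_w, N_sub, F): for each of the T_w=16 weekly
    snapshots, every subgraph node carries its demand over the 16 weeks ending
    at that snapshot (zero-padded on the left). ``target_value`` is the
    target drug's demand the week after the window.
    """

    snapshot_features: np.ndarray  # (T_w, N_sub, F)
    target_value: float
    target_position: int
    adjacency_ref: np.ndarray  # (N_sub, N_sub) induced adjacency
    week_of_target: str
    target_week_index: int = field(default=-1)


def _week_start(dates: pd.Series) -> pd.Series:
    """Monday of the ISO week of each date."""
    dates = pd.to_datetime(dates)
    return dates - pd.to_timedelta(dates.dt.weekday, unit="D")


def _iso_label(monday: pd.Timestamp) -> str:
    iso = monday.isocalendar()
    return f"{iso.year}-W{iso.week:02d}"


def aggregate_weekly(transactions: pd.DataFrame) -> DemandPanel:
    """Sum transaction quantities per drug and ISO week.

    The panel spans every week from the first to the last transaction week;
    weeks without transactions are zero-filled (absence of sales means zero
    demand, not missing data) and flagged 0 in the validity mask.
    """
    required = {"drug_id", "date", "quantity"}
    missing = required - set(transactions.columns)
    if missing:
        raise ValueError(f"transactions table missing columns {sorted(missing)}")
    if transactions.empty:
        raise ValueError("transactions table is empty")
    if (transactions["quantity"] < 0).any():
        raise ValueError("negative quantity in transactions")

    tx = transactions.copy()
    tx["week_start"] = _week_start(tx["date"])
    mondays = pd.date_range(tx["week_start"].min(), tx["week_start"].max(), freq="7D")
    drug_ids = sorted(tx["drug_id"].unique())
    grouped = tx.groupby(["drug_id", "week_start"])["quantity"].sum()

    demand = np.zeros((len(drug_ids), len(mondays)))
    mask = np.zeros_like(demand, dtype=int)
    col = {m: j for j, m in enumerate(mondays)}
    row = {d: i for i, d in enumerate(drug_ids)}
    for (drug, week), q in grouped.items():
        demand[row[drug], col[week]] = q
        mask[row[drug], col[week]] = 1
    return DemandPanel(
        drug_ids=drug_ids,
        week_index=[_iso_label(m) for m in mondays],
        demand=demand,
        valid_week_mask=mask,
    )


def filter_min_history(panel: DemandPanel, min_valid_weeks: int = MIN_VALID_WEEKS) -> DemandPanel:
    """Keep drugs with at least ``min_valid_weeks`` weeks of recorded sales.

    A valid week has at least one transaction. The week axis is unchanged.
    """
    keep = panel.valid_weeks() >= min_valid_weeks
    if not keep.any():
        warnings.warn("all drugs fall below the history floor; panel is empty", stacklevel=2)
    idx = np.flatnonzero(keep)
    return DemandPanel(
        drug_ids=[panel.drug_ids[i] for i in idx],
        week_index=list(panel.week_index),
        demand=panel.demand[idx],
        valid_week_mask=panel.valid_week_mask[idx],
    )


def clip_outliers(
    series: np.ndarray,
    window_length: int = WINDOW,
    n_sigma: float = OUTLIER_SIGMA,
) -> np.ndarray:
    """Replace values deviating more than ``n_sigma`` standard deviations
    from their sliding-window mean with that window mean.

    Windows slide with stride 1 over the *original* values in a single
    left-to-right sweep; the replacement for a flagged value is the mean of
    the first window that flags it. The standard deviation is the population
    form, so a constant window (sd = 0) never fires.
    """
    if window_length < 2:
        raise ValueError("window_length must be >= 2")
    x = np.asarray(series, dtype=float)
    out = x.copy()
    n = x.size
    if n < window_length:
        warnings.warn("series shorter than the outlier window; returned unchanged", stacklevel=2)
        return out
    replaced = np.zeros(n, dtype=bool)
    for start in range(n - window_length + 1):
        win = x[start : start + window_length]
        mean = win.mean()
        sd = win.std()  # population
        if sd == 0:
            continue
        dev = np.abs(win - mean)
        for k in np.flatnonzero(dev > n_sigma * sd):
            if not replaced[start + k]:
                out[start + k] = mean
                replaced[start + k] = True
    return out


def chronological_split(
    panel: DemandPanel,
    test_weeks: int = TEST_WEEKS,
    val_weeks: int = VAL_WEEKS,
    window: int = WINDOW,
) -> SplitSpec:
    """Reserve the final ``test_weeks`` for testing and the ``val_weeks``
    immediately preceding them for validation; everything earlier trains.

    Requires enough training weeks for at least one sliding-window sample
    (window + 1 weeks, the +1 being the forecast target).
    """
    minimum = window + 1 + val_weeks + test_weeks
    n = panel.n_weeks
    if n < minimum:
        raise ValueError(
            f"panel has {n} weeks; at least {minimum} needed "
            f"(window {window} + target 1 + val {val_weeks} + test {test_weeks})"
        )
    return SplitSpec(
        train_weeks=range(0, n - val_weeks - test_weeks),
        val_weeks=range(n - val_weeks - test_weeks, n - test_weeks),
        test_weeks=range(n - test_weeks, n),
    )


def scale_series(
    series: np.ndarray, fit_range: range
) -> tuple[np.ndarray, Callable[[np.ndarray], np.ndarray]]:
    """Min-max scale a series with statistics fitted on ``fit_range`` only.

    Returns the transformed series and the inverse transform. Values outside
    the fitted range may scale beyond [0, 1]; a constant fit range maps to
    all-zeros (and the inverse restores the constant).
    """
    if len(fit_range) == 0:
        raise ValueError("fit_range must be non-empty")
    x = np.asarray(series, dtype=float).reshape(-1, 1)
    scaler = MinMaxScaler().fit(x[list(fit_range)])

    def inverse(values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        return scaler.inverse_transform(v.reshape(-1, 1)).reshape(v.shape)

    return scaler.transform(x).reshape(-1), inverse


def scale_panel(
    panel: DemandPanel, fit_range: range
) -> tuple[np.ndarray, dict[str, Callable[[np.ndarray], np.ndarray]]]:
    """Per-drug min-max scaling of the whole panel on the training weeks.

    Returns the scaled demand matrix and one inverse transform per drug.
    Metrics must always be computed after applying the inverse.
    """
    scaled = np.empty_like(panel.demand)
    inverses: dict[str, Callable[[np.ndarray], np.ndarray]] = {}
    for i, drug in enumerate(panel.drug_ids):
        scaled[i], inverses[drug] = scale_series(panel.demand[i], fit_range)
    return scaled, inverses


def _snapshot_tensor(span: np.ndarray, window: int) -> np.ndarray:
    """(T_w, N, F) tensor of causally padded per-node windows.

    ``span`` is (N, L) with L >= window; snapshot ``s`` holds, per node, the
    ``window`` values ending at span column ``L - window + s``, zero-padded
    where the window reaches before the span start.
    """
    n, length = span.shape
    feats = np.zeros((window, n, window))
    for s in range(window):
        end = length - window + s + 1  # exclusive
        start = end - window
        lo = max(start, 0)
        feats[s, :, lo - start :] = span[:, lo:end]
    return feats


def assemble_windows(
    panel: DemandPanel,
    graph: KnowledgeGraph,
    target: str,
    window: int = WINDOW,
    hop: int = 2,
    *,
    demand: np.ndarray | None = None,
    outlier_correct: bool = True,
    causal_padding: bool = True,
) -> list[GraphWindowSample]:
    """Build sliding-window samples for one target drug.

    The target's ``hop``-neighbourhood subgraph is extracted once; for every
    anchor week ``t`` (window end) a sample carries T_w = ``window`` snapshots
    of per-node 16-week histories and the target's week ``t+1`` demand. With
    ``causal_padding`` (default) snapshot histories are zero-padded to the
    left within the sample; otherwise they reach back into the raw series
    (the sample then spans ``2*window - 1`` raw weeks). Outlier correction
    applies the 3-sigma rule to the sample's raw span at assembly time, so
    window statistics never leak across the train/test boundary.

    The sample count for an L-week panel is exactly L - window.
    """
    if target not in panel.drug_ids:
        raise ValueError(f"target {target!r} not in panel (filtered out?)")
    if window < 1:
        raise ValueError("window must be >= 1")
    nodes, induced, target_pos = khop_subgraph(graph, target, k=hop)
    present = [d for d in nodes if d in panel.drug_ids]
    if present != nodes:
        # neighbours dropped by the history filter leave the subgraph
        keep = np.array([i for i, d in enumerate(nodes) if d in panel.drug_ids])
        induced = induced[np.ix_(keep, keep)]
        nodes = present
        target_pos = nodes.index(target)
    # raw demand is non-negative by construction; an override (e.g. min-max
    # scaled values) may legitimately dip below zero outside the fit range
    if demand is None:
        values = panel.demand
    else:
        values = np.asarray(demand, dtype=float)
        if values.shape != panel.demand.shape:
            raise ValueError("demand override shape must match the panel")
    rows = np.array([panel.drug_ids.index(d) for d in nodes])
    series = values[rows]  # (N_sub, L)
    length = series.shape[1]

    samples: list[GraphWindowSample] = []
    if length <= window:
        warnings.warn("no admissible windows: panel no longer than the window", stacklevel=2)
        return samples
    lookback = window if causal_padding else 2 * window - 1
    for t in range(window - 1, length - 1):
        start = t + 1 - lookback
        span = np.zeros((len(nodes), lookback))
        lo = max(start, 0)
        span[:, lo - start :] = series[:, lo : t + 1]
        if outlier_correct:
            span = np.vstack([clip_outliers(s, window) for s in span])
        samples.append(
            GraphWindowSample(
                snapshot_features=_snapshot_tensor(span, window),
                target_value=float(values[panel.drug_ids.index(target), t + 1]),
                target_position=target_pos,
                adjacency_ref=induced,
                week_of_target=panel.week_index[t + 1],
                target_week_index=t + 1,
            )
        )
    return samples


def stack_samples(samples: list[GraphWindowSample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack same-subgraph samples into (B, T_w, N, F) features and (B,) targets."""
    if not samples:
        raise ValueError("no samples to stack")
    shapes = {s.snapshot_features.shape for s in samples}
    if len(shapes) != 1:
        raise ValueError("samples come from different subgraphs")
    X = np.stack([s.snapshot_features for s in samples])
    y = np.array([s.target_value for s in samples])
    return X, y
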