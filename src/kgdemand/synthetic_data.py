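"""Synthetic pharmacy-sales generator.

Emulates the statistical structure the knowledge graph is meant to exploit,
without any external data:

* **group seasonality** — each ATC level-4 group follows a 52-week sinusoid
  with its own amplitude, phase and multiplicative noise;
* **substitution** — drugs in a group compete for the group's demand through
  market shares following a logistic-normal random walk (one drug's gain is
  its substitutes' loss);
* **co-prescription** — each DDI pair shares an additive latent demand
  component, scaled by the coupling strength ``kappa``, inducing positive
  cross-correlation between the endpoints;
* **count noise** — negative-binomial observation noise (demand is a count);
* **data defects** — multiplicative outliers, zeroed "missing" weeks, and a
  late-launch drug that falls below the 40-valid-week history floor;
* **devices** — independent seasonal AR(1) count series, isolated in the
  graph.

Defaults are the reference study conditions: 12 items (2 of them devices),
3 ATC groups, 2 cross-group DDI pairs, 120 weeks, kappa = 2.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .knowledge_graph import DrugRecord
from .preprocessing import DemandPanel

__all__ = ["SimConfig", "GroundTruth", "SimulatedDataset", "gen_catalog", "simulate_demand", "emit_transactions", "generate_dataset"]

_ALPHA = "ABCDEFGHJLMNPRSV"


@dataclass(frozen=True)
class SimConfig:
    n_drugs: int = 12
    n_atc_groups: int = 3
    device_fraction: float = 1 / 6  # ~16% devices, as in real pharmacy catalogs
    n_ddi_pairs: int = 2
    weeks: int = 120
    seasonal_amplitude: float = 0.3
    group_noise_sigma: float = 0.08
    share_drift_scale: float = 0.06
    coupling_strength: float = 2.0  # kappa
    noise_dispersion: float = 8.0  # negative-binomial r; larger = less noise, 0 = noise off
    outlier_prob: float = 0.01
    outlier_multiplier: tuple[float, float] = (3.0, 6.0)
    missing_week_prob: float = 0.02
    n_short_history: int = 1  # drugs launching too late to pass the 40-week floor
    #: when True, every pharmaceutical drug gets its own independent seasonal
    #: curve: the catalog still defines ATC groups (so the graph has edges)
    #: but demand carries no relational signal at all
    independent_demand: bool = False
    base_demand_range: tuple[float, float] = (120.0, 320.0)
    start_date: str = "2022-01-03"  # a Monday
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("device_fraction", "outlier_prob", "missing_week_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.coupling_strength < 0:
            raise ValueError("coupling_strength must be >= 0")
        if self.n_drugs < self.n_atc_groups:
            raise ValueError("need at least one drug per ATC group")


@dataclass
class GroundTruth:
    groups: dict[str, list[str]]  # atc level-4 prefix -> drug ids
    shares: dict[str, np.ndarray] = field(default_factory=dict)  # drug -> weekly share
    group_curves: dict[str, np.ndarray] = field(default_factory=dict)
    coupling_pairs: list[tuple[str, str, float]] = field(default_factory=list)


@dataclass
class SimulatedDataset:
    records: list[DrugRecord]
    ddi_pairs: pd.DataFrame
    panel: DemandPanel
    transactions: pd.DataFrame
    truth: GroundTruth
    inn_map: pd.DataFrame
    drug_db: pd.DataFrame


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(c) for c in np.random.SeedSequence(seed).spawn(n)]


def gen_catalog(config: SimConfig) -> tuple[list[DrugRecord], GroundTruth]:
    """Deterministic synthetic catalog with shared-prefix ATC groups.

    Pharmaceutical drugs in the same group share a 5-character ATC prefix and
    differ only in the final two characters; devices carry no code. Raw names
    include dosage tokens so that name cleaning is exercised downstream.
    """
    rng = _rngs(config.seed, 4)[0]
    n_devices = int(round(config.device_fraction * config.n_drugs))
    n_pharma = config.n_drugs - n_devices
    if 0 < n_pharma < config.n_atc_groups:
        raise ValueError("not enough pharmaceutical drugs for the requested ATC groups")

    prefixes = []
    while len(prefixes) < config.n_atc_groups:
        p = (
            rng.choice(list(_ALPHA))
            + f"{rng.integers(1, 17):02d}"
            + rng.choice(list(_ALPHA))
            + rng.choice(list(_ALPHA))
        )
        if p not in prefixes:
            prefixes.append(p)

    syllables = ["lor", "vax", "cil", "pra", "dex", "mab", "tol", "zin", "fen", "mir", "cor", "nal"]
    records: list[DrugRecord] = []
    groups: dict[str, list[str]] = {p: [] for p in prefixes}
    used_names: set[str] = set()
    for i in range(n_pharma):
        prefix = prefixes[i % config.n_atc_groups]
        drug_id = f"D{i + 1:04d}"
        core = "".join(rng.choice(syllables, size=3))
        while core in used_names:
            core = "".join(rng.choice(syllables, size=3))
        used_names.add(core)
        dose = int(rng.choice([50, 100, 250, 500]))
        records.append(
            DrugRecord(
                drug_id=drug_id,
                raw_name=f"{core.capitalize()} {dose} mg",
                core_name=core,
                item_type="pharmaceutical",
                inn_name=core,
                atc_code=f"{prefix}{len(groups[prefix]) + 1:02d}",
            )
        )
        groups[prefix].append(drug_id)
    device_names = ["mask", "syringe", "thermometer", "glove", "bandage", "test strip"]
    for j in range(n_devices):
        records.append(
            DrugRecord(
                drug_id=f"D{n_pharma + j + 1:04d}",
                raw_name=device_names[j % len(device_names)],
                core_name=device_names[j % len(device_names)],
                item_type="device",
            )
        )
    return records, GroundTruth(groups=groups)


def _ddi_table(records: list[DrugRecord], truth: GroundTruth, config: SimConfig) -> pd.DataFrame:
    """Cross-group DDI pairs, so combination edges add information that
    substitution edges do not already encode."""
    rng = _rngs(config.seed, 4)[1]
    prefixes = list(truth.groups)
    pairs: set[tuple[str, str]] = set()
    guard = 0
    while len(pairs) < config.n_ddi_pairs and guard < 1000:
        guard += 1
        g1, g2 = rng.choice(len(prefixes), size=2, replace=False)
        a = rng.choice(truth.groups[prefixes[g1]])
        b = rng.choice(truth.groups[prefixes[g2]])
        pairs.add(tuple(sorted((a, b))))
    rows = sorted(pairs)
    return pd.DataFrame(rows, columns=["drug_id_a", "drug_id_b"])


def simulate_demand(
    records: list[DrugRecord],
    truth: GroundTruth,
    ddi_pairs: pd.DataFrame,
    config: SimConfig,
) -> tuple[DemandPanel, GroundTruth]:
    """Weekly demand panel with substitution, coupling, noise and defects."""
    rng = _rngs(config.seed, 4)[2]
    weeks = config.weeks
    t = np.arange(weeks)
    drug_ids = [r.drug_id for r in records]
    mean = np.zeros((len(records), weeks))
    row = {d: i for i, d in enumerate(drug_ids)}

    lo, hi = config.base_demand_range
    if config.independent_demand:
        # no relational signal: per-drug independent seasonal curves
        for prefix, members in truth.groups.items():
            for drug in members:
                base = rng.uniform(lo, hi) / 3
                phase = rng.uniform(0, 2 * np.pi)
                eps = rng.normal(0, config.group_noise_sigma, size=weeks)
                mean[row[drug]] = base * (
                    1 + config.seasonal_amplitude * np.sin(2 * np.pi * t / 52 + phase)
                ) * np.exp(eps)
                truth.shares[drug] = np.full(weeks, 1.0)
        truth.group_curves = {}
    else:
        for prefix, members in truth.groups.items():
            base = rng.uniform(lo, hi)
            phase = rng.uniform(0, 2 * np.pi)
            eps = rng.normal(0, config.group_noise_sigma, size=weeks)
            curve = base * (1 + config.seasonal_amplitude * np.sin(2 * np.pi * t / 52 + phase)) * np.exp(eps)
            truth.group_curves[prefix] = curve
            # logistic-normal random walk over within-group market shares
            z = rng.normal(0, 0.5, size=len(members))[:, None] + np.cumsum(
                rng.normal(0, config.share_drift_scale, size=(len(members), weeks)), axis=1
            )
            shares = np.exp(z) / np.exp(z).sum(axis=0, keepdims=True)
            for k, drug in enumerate(members):
                truth.shares[drug] = shares[k]
                mean[row[drug]] = curve * shares[k]

    # shared latent co-prescription demand per DDI pair
    for _, pair in ddi_pairs.iterrows():
        a, b = pair["drug_id_a"], pair["drug_id_b"]
        pair_base = 0.25 * (mean[row[a]].mean() + mean[row[b]].mean()) / 2
        phase = rng.uniform(0, 2 * np.pi)
        shared = (
            config.coupling_strength
            * pair_base
            * (1 + 0.5 * np.sin(2 * np.pi * t / 52 + phase))
            * np.exp(rng.normal(0, 0.3, size=weeks))
        )
        mean[row[a]] += shared
        mean[row[b]] += shared
        truth.coupling_pairs.append((a, b, config.coupling_strength))

    # devices: independent seasonal AR(1) counts, isolated from the graph
    for r in records:
        if r.item_type != "device":
            continue
        base = rng.uniform(lo, hi) / 4
        phase = rng.uniform(0, 2 * np.pi)
        level = np.empty(weeks)
        prev = base
        for w in range(weeks):
            target = base * (1 + config.seasonal_amplitude * np.sin(2 * np.pi * w / 52 + phase))
            prev = target + 0.6 * (prev - target) + rng.normal(0, base * 0.1)
            level[w] = max(prev, 0.0)
        mean[row[r.drug_id]] = level

    # negative-binomial observation: demand is a count (dispersion 0 = noise off)
    r_disp = config.noise_dispersion
    if r_disp > 0:
        positive = mean > 0
        observed = np.zeros_like(mean)
        p = r_disp / (r_disp + mean[positive])
        observed[positive] = rng.negative_binomial(r_disp, p)
    else:
        observed = mean.copy()

    # injected outliers
    hits = rng.random(observed.shape) < config.outlier_prob
    mult = rng.uniform(*config.outlier_multiplier, size=observed.shape)
    observed = np.where(hits & (observed > 0), np.round(observed * mult), observed)

    # missing weeks
    observed[rng.random(observed.shape) < config.missing_week_prob] = 0

    # late-launch drugs: too little history to pass the 40-week floor
    pharma = [r.drug_id for r in records if r.item_type == "pharmaceutical"]
    for drug in pharma[-config.n_short_history :] if config.n_short_history else []:
        launch = max(weeks - 30, 0)
        observed[row[drug], :launch] = 0

    start = pd.Timestamp(config.start_date)
    mondays = pd.date_range(start, periods=weeks, freq="7D")
    labels = [f"{m.isocalendar().year}-W{m.isocalendar().week:02d}" for m in mondays]
    panel = DemandPanel(
        drug_ids=drug_ids,
        week_index=labels,
        demand=observed,
        valid_week_mask=(observed > 0).astype(int),
    )
    return panel, truth


def emit_transactions(panel: DemandPanel, config: SimConfig, max_per_week: int = 4) -> pd.DataFrame:
    """Decompose weekly quantities into dated transactions.

    Each positive cell becomes 1..``max_per_week`` transactions with positive
    integer quantities summing exactly to the cell, dated within the ISO
    week, so ``aggregate_weekly`` reproduces the panel.
    """
    rng = _rngs(config.seed, 4)[3]
    rows = []
    for i, drug in enumerate(panel.drug_ids):
        for j, label in enumerate(panel.week_index):
            q = int(round(panel.demand[i, j]))
            if q <= 0:
                continue
            year, week = int(label[:4]), int(label[-2:])
            monday = datetime.date.fromisocalendar(year, week, 1)
            m = int(rng.integers(1, min(q, max_per_week) + 1))
            parts = rng.multinomial(q - m, np.full(m, 1.0 / m)) + 1
            for part in parts:
                day = monday + datetime.timedelta(days=int(rng.integers(0, 7)))
                rows.append({"drug_id": drug, "date": day.isoformat(), "quantity": int(part)})
    return pd.DataFrame(rows, columns=["drug_id", "date", "quantity"])


def generate_dataset(config: SimConfig = SimConfig()) -> SimulatedDataset:
    """End-to-end fixture set: catalog, DDI table, panel, transactions,
    ground truth, and the INN/ATC lookup tables the matching step reads."""
    records, truth = gen_catalog(config)
    ddi = _ddi_table(records, truth, config)
    panel, truth = simulate_demand(records, truth, ddi, config)
    transactions = emit_transactions(panel, config)
    inn_map = pd.DataFrame(
        [{"core_name": r.core_name, "inn": r.inn_name} for r in records if r.inn_name],
    )
    drug_db = pd.DataFrame(
        [{"inn": r.inn_name, "atc_code": r.atc_code} for r in records if r.atc_code],
    )
    return SimulatedDataset(
        records=records,
        ddi_pairs=ddi,
        panel=panel,
        transactions=transactions,
        truth=truth,
        inn_map=inn_map,
        drug_db=drug_db,
    )
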