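"""Replication engine: runs study conditions and aggregates flag rates.

A replication of a condition draws fresh attribute profiles and responses for
a reference and a focal group (N = 1000 each by default), applies the
condition's DIF pattern to the focal parameters on the six frozen DIF items,
generates each group's data under its *generating* Q-matrix (the flipped one
for groups impacted by misspecification), and runs the DIF tests conditioning
on the original Q.  Flags are aggregated into per-item flag proportions and
rolled up into Type I error (mean over the 25 non-DIF items) and power (mean
over the 6 DIF items), overall and by item-complexity stratum.

Seeding: replication ``r`` of condition ``c`` uses a seed derived from
(base seed, CRC-32 of the condition id, r), so any single replication can be
regenerated in isolation and results do not depend on execution order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import (
    StudyCondition,
    apply_dif,
    build_study_qmatrix,
    load_baseline_parameters,
    load_study_dif_items,
    misspecify_qmatrix,
)
from .detection import METHODS, run_all_methods
from .dina import ItemParameterSet, QMatrix, draw_attribute_profiles, simulate_responses
from .estimation import FitOptions

__all__ = [
    "StudyFixtures",
    "ReplicationRecord",
    "DifResultTable",
    "replication_seed",
    "run_replication",
    "run_condition",
    "aggregate_by_complexity",
    "aggregate_overall",
    "cli_run",
]

DEFAULT_N_PER_GROUP = 1000
DEFAULT_ALPHA = 0.05
# Engine-level EM settings for the per-item Wald fits: warm-started from a
# pooled fit, a few hundred iterations at 1e-4 suffice.
ENGINE_FIT_OPTIONS = FitOptions(max_iter=400, tol=1e-4)


@dataclass(frozen=True)
class StudyFixtures:
    """The frozen study inputs shared by every condition."""

    qmatrix: QMatrix
    dif_items: tuple[int, ...]
    baseline_params: ItemParameterSet

    @classmethod
    def packaged(cls) -> "StudyFixtures":
        return cls(
            qmatrix=build_study_qmatrix(),
            dif_items=load_study_dif_items(),
            baseline_params=load_baseline_parameters(),
        )


@dataclass
class ReplicationRecord:
    """Per-item, per-method flags of one replication."""

    condition_id: str
    replication: int
    flags: pd.DataFrame  # item_id, method, statistic, df, p_value, flagged, note

    @property
    def n_failures(self) -> int:
        return int(self.flags["flagged"].isna().sum())


@dataclass
class DifResultTable:
    """Flag proportions of one condition across replications, with roll-ups."""

    condition: StudyCondition
    n_replications: int
    per_item: pd.DataFrame  # item_id, method, prop_flagged, n_valid, role, stratum
    failure_rate: float = 0.0
    records: list[ReplicationRecord] | None = None

    def replication_frame(self) -> pd.DataFrame:
        """Raw per-replication flags: condition_id, replication, item_id,
        method, statistic, df, p_value, flagged."""
        if not self.records:
            raise ValueError("replication records were not retained for this table")
        return pd.concat(
            [
                r.flags.assign(
                    condition_id=r.condition_id, replication=r.replication
                )
                for r in self.records
            ],
            ignore_index=True,
        )[
            [
                "condition_id",
                "replication",
                "item_id",
                "method",
                "statistic",
                "df",
                "p_value",
                "flagged",
                "note",
            ]
        ]

    def _mask(self, method: str, role: str, stratum: str | None = None) -> pd.Series:
        m = (self.per_item["method"] == method) & (self.per_item["role"] == role)
        if stratum is not None:
            m &= self.per_item["stratum"] == stratum
        return m

    def type_i_error(self, method: str, stratum: str | None = None) -> float:
        """Mean flag proportion over non-DIF items (optionally one stratum)."""
        return float(self.per_item.loc[self._mask(method, "non-dif", stratum), "prop_flagged"].mean())

    def power(self, method: str, stratum: str | None = None) -> float:
        """Mean flag proportion over DIF items (optionally one stratum)."""
        return float(self.per_item.loc[self._mask(method, "dif", stratum), "prop_flagged"].mean())


def replication_seed(base_seed: int, condition_id: str, replication: int) -> np.random.SeedSequence:
    """Deterministic seed for one (condition, replication) cell."""
    digest = zlib.crc32(condition_id.encode("utf-8")) & 0x7FFFFFFF
    return np.random.SeedSequence([int(base_seed) & 0x7FFFFFFF, digest, int(replication)])


def _generating_qmatrices(
    condition: StudyCondition, q: QMatrix, rng: np.random.Generator
) -> tuple[QMatrix, QMatrix]:
    """(reference Q, focal Q) used for data generation under this condition."""
    mis = condition.misspec
    if mis.is_none:
        return q, q
    flipped = misspecify_qmatrix(q, mis, rng)
    if mis.impacted_group == "both":
        return flipped, flipped
    return q, flipped


def run_replication(
    condition: StudyCondition,
    rep_index: int,
    fixtures: StudyFixtures | None = None,
    base_seed: int = 0,
    n_per_group: int = DEFAULT_N_PER_GROUP,
    alpha: float = DEFAULT_ALPHA,
    methods: tuple[str, ...] = METHODS,
    fit_options: FitOptions | None = None,
) -> ReplicationRecord:
    """Generate one replication's two-group data and run the DIF tests."""
    fx = fixtures or StudyFixtures.packaged()
    q = fx.qmatrix
    ss = replication_seed(base_seed, condition.condition_id, rep_index)
    rng_flip, rng_ref_prof, rng_foc_prof, rng_ref_resp, rng_foc_resp = (
        np.random.default_rng(child) for child in ss.spawn(5)
    )
    q_ref, q_foc = _generating_qmatrices(condition, q, rng_flip)
    rho = condition.attribute_correlation
    prof_ref = draw_attribute_profiles(n_per_group, q.n_attributes, rho, rng_ref_prof)
    prof_foc = draw_attribute_profiles(n_per_group, q.n_attributes, rho, rng_foc_prof)
    params_ref = fx.baseline_params
    params_foc = apply_dif(params_ref, fx.dif_items, condition.dif_pattern, q.item_ids)
    x_ref = simulate_responses(prof_ref, q_ref, params_ref, rng_ref_resp, "reference")
    x_foc = simulate_responses(prof_foc, q_foc, params_foc, rng_foc_resp, "focal")
    flags = run_all_methods(
        x_ref,
        x_foc,
        q,  # analyses always condition on the original Q
        alpha=alpha,
        methods=methods,
        fit_options=fit_options or ENGINE_FIT_OPTIONS,
    )
    return ReplicationRecord(condition.condition_id, rep_index, flags)


def _summarize(
    condition: StudyCondition,
    records: list[ReplicationRecord],
    fixtures: StudyFixtures,
) -> DifResultTable:
    q = fixtures.qmatrix
    stacked = pd.concat(
        [r.flags.assign(replication=r.replication) for r in records], ignore_index=True
    )
    flagged = stacked["flagged"].astype("float")  # NA -> NaN, excluded from means
    per_item = (
        stacked.assign(flagged_f=flagged)
        .groupby(["item_id", "method"], as_index=False)
        .agg(prop_flagged=("flagged_f", "mean"), n_valid=("flagged_f", "count"))
    )
    low = dict(zip(q.item_ids, q.low_complexity_mask()))
    per_item["stratum"] = per_item["item_id"].map(
        lambda i: "low" if low[i] else "high"
    )
    per_item["role"] = per_item["item_id"].map(
        lambda i: "dif" if i in fixtures.dif_items else "non-dif"
    )
    n_cells = len(stacked)
    fail = float(stacked["flagged"].isna().sum() / n_cells) if n_cells else 0.0
    return DifResultTable(
        condition=condition,
        n_replications=len(records),
        per_item=per_item,
        failure_rate=fail,
    )


def run_condition(
    condition: StudyCondition,
    n_reps: int,
    fixtures: StudyFixtures | None = None,
    base_seed: int = 0,
    n_per_group: int = DEFAULT_N_PER_GROUP,
    alpha: float = DEFAULT_ALPHA,
    methods: tuple[str, ...] = METHODS,
    fit_options: FitOptions | None = None,
    keep_records: bool = False,
) -> DifResultTable:
    """Replicate a condition and average flags into per-item proportions."""
    if n_reps < 1:
        raise ValueError("need at least one replication")
    fx = fixtures or StudyFixtures.packaged()
    records = [
        run_replication(
            condition, r, fx, base_seed, n_per_group, alpha, methods, fit_options
        )
        for r in range(n_reps)
    ]
    table = _summarize(condition, records, fx)
    if keep_records:
        table.records = records
    return table


def aggregate_by_complexity(tables: list[DifResultTable]) -> pd.DataFrame:
    """Mean Type I error and power per method x stratum x misspecification cell.

    Rows are indexed by the 7 (impacted group, position) combinations;
    averages pool every supplied condition table falling in a cell (e.g. over
    attribute correlations or DIF patterns).
    """
    if not tables:
        raise ValueError("no condition tables supplied")
    rows = []
    for t in tables:
        mis = t.condition.misspec
        for method in t.per_item["method"].unique():
            for stratum in ("low", "high"):
                rows.append(
                    {
                        "impacted_group": mis.impacted_group,
                        "position": mis.position,
                        "method": method,
                        "stratum": stratum,
                        "type_i_error": t.type_i_error(method, stratum),
                        "power": t.power(method, stratum),
                    }
                )
    frame = pd.DataFrame(rows)
    out = (
        frame.groupby(["impacted_group", "position", "method", "stratum"], as_index=False)
        .agg(type_i_error=("type_i_error", "mean"), power=("power", "mean"))
    )
    if out[["type_i_error", "power"]].isna().all(axis=None):
        raise ValueError("empty stratum: no items contribute to any cell")
    return out


def aggregate_overall(tables: list[DifResultTable]) -> pd.DataFrame:
    """Overall Type I error / power per condition and method.

    Overall power is the mean of the six DIF items' flag proportions; overall
    Type I error the mean of the 25 non-DIF items' proportions (averaging
    over items and replications commutes).
    """
    rows = []
    for t in tables:
        for method in t.per_item["method"].unique():
            rows.append(
                {
                    "condition_id": t.condition.condition_id,
                    "dif_type": t.condition.dif_pattern.dif_type,
                    "dif_size": t.condition.dif_pattern.dif_size,
                    "impacted_group": t.condition.misspec.impacted_group,
                    "position": t.condition.misspec.position,
                    "rho": t.condition.attribute_correlation,
                    "method": method,
                    "type_i_error": t.type_i_error(method),
                    "power": t.power(method),
                    "n_replications": t.n_replications,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# config-driven runs
# --------------------------------------------------------------------------


def _select_conditions(config: dict) -> list[StudyCondition]:
    from .design import build_condition_grid

    grid = build_condition_grid()
    wanted = config.get("conditions", "all")
    if wanted != "all":
        wanted = set(wanted)
        grid = [c for c in grid if c.condition_id in wanted]
        missing = wanted - {c.condition_id for c in grid}
        if missing:
            raise ValueError(f"unknown condition ids: {sorted(missing)}")
    filters = config.get("filters", {}) or {}
    if "dif_type" in filters:
        grid = [c for c in grid if c.dif_pattern.dif_type == filters["dif_type"]]
    if "dif_size" in filters:
        grid = [c for c in grid if c.dif_pattern.dif_size == filters["dif_size"]]
    if "impacted_group" in filters:
        grid = [c for c in grid if c.misspec.impacted_group == filters["impacted_group"]]
    if "position" in filters:
        grid = [c for c in grid if c.misspec.position == filters["position"]]
    if "rhos" in filters:
        keep = {float(r) for r in filters["rhos"]}
        grid = [c for c in grid if c.attribute_correlation in keep]
    return grid


def cli_run(config_path: str, log=print) -> pd.DataFrame:
    """Run the conditions described by a YAML config; write tidy CSVs.

    Config keys: conditions ("all" or a list of ids), filters (dif_type,
    dif_size, impacted_group, position, rhos), reps, seed, alpha, methods,
    n_per_group, output, write_replications (also dump the raw
    per-replication flag tables).  Per-condition CSVs make partial runs
    resumable: an existing file is loaded instead of recomputed.
    """
    import os

    import yaml

    with open(config_path) as fh:
        config = yaml.safe_load(fh)
    for key in ("reps", "seed", "output"):
        if key not in config:
            raise ValueError(f"config is missing required key {key!r}")
    out_dir = config["output"]
    os.makedirs(out_dir, exist_ok=True)
    reps = int(config["reps"])
    seed = int(config["seed"])
    alpha = float(config.get("alpha", DEFAULT_ALPHA))
    methods = tuple(config.get("methods", list(METHODS)))
    n_per_group = int(config.get("n_per_group", DEFAULT_N_PER_GROUP))
    write_replications = bool(config.get("write_replications", False))
    conditions = _select_conditions(config)
    if not conditions:
        raise ValueError("config selects no conditions")
    fx = StudyFixtures.packaged()
    tables = []
    for i, cond in enumerate(conditions, 1):
        safe = cond.condition_id.replace("[", "_").replace("]", "").replace("/", "-")
        path = os.path.join(out_dir, f"condition_{safe}.csv")
        if os.path.exists(path):
            log(f"[{i}/{len(conditions)}] {cond.condition_id}: cached")
            per_item = pd.read_csv(path, comment="#")
            tables.append(
                DifResultTable(condition=cond, n_replications=reps, per_item=per_item)
            )
            continue
        log(f"[{i}/{len(conditions)}] {cond.condition_id}: running {reps} reps")
        table = run_condition(
            cond, reps, fx, seed, n_per_group, alpha, methods,
            keep_records=write_replications,
        )
        if write_replications:
            rep_path = os.path.join(out_dir, f"replications_{safe}.csv")
            with open(rep_path, "w") as fh:
                fh.write(f"# condition_id={cond.condition_id} seed={seed}\n")
                table.replication_frame().to_csv(fh, index=False)
        with open(path, "w") as fh:
            fh.write(
                f"# condition_id={cond.condition_id} seed={seed} reps={reps} "
                f"alpha={alpha} methods={','.join(methods)}\n"
            )
            table.per_item.to_csv(fh, index=False)
        tables.append(table)
    summary = aggregate_overall(tables)
    summary.to_csv(os.path.join(out_dir, "summary_overall.csv"), index=False)
    strata = aggregate_by_complexity(tables)
    strata.to_csv(os.path.join(out_dir, "summary_by_complexity.csv"), index=False)
    return summary
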