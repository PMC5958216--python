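"""Factorial study design: DIF patterns, the study Q-matrix, misspecification.

The Monte-Carlo design crosses DIF-related factors with Q-matrix-related
("CDM") factors:

* DIF pattern — signed shifts (delta_g, delta_s) applied to the focal group's
  guessing/slipping parameters on the DIF items.  Shifts of magnitude 0.075
  are "moderate", 0.10 "large".  Same-sign shifts are labelled uniform DIF,
  any other nonnull combination nonuniform; 8 patterns per size, 16 in all,
  plus a no-DIF baseline.
* Q-matrix misspecification — a fixed proportion of Q entries flipped
  (0 -> 1 or 1 -> 0), positioned either at random, only among low-complexity
  items (<= 2 required attributes) or only among high-complexity items
  (>= 3), and impacting either both groups or only the focal group.
* Attribute correlation — the equicorrelation of the latent normal behind the
  attribute profiles, at 0.3 / 0.5 / 0.8.

(16 + 1 baseline) DIF patterns x (6 + 1 none) misspecification combinations
x 3 correlations = 357 study conditions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .dina import ItemParameterSet, QMatrix, as_rng

__all__ = [
    "DifPattern",
    "MisspecificationSpec",
    "StudyCondition",
    "MODERATE_DIF",
    "LARGE_DIF",
    "ATTRIBUTE_CORRELATIONS",
    "MISSPECIFICATION_RATE",
    "N_DIF_ITEMS",
    "build_study_qmatrix",
    "dif_condition_table",
    "select_dif_items",
    "load_study_dif_items",
    "load_baseline_parameters",
    "apply_dif",
    "misspecify_qmatrix",
    "build_condition_grid",
]

MODERATE_DIF = 0.075
LARGE_DIF = 0.10
_ALLOWED_DELTAS = (0.0, MODERATE_DIF, LARGE_DIF)
ATTRIBUTE_CORRELATIONS = (0.3, 0.5, 0.8)
MISSPECIFICATION_RATE = 0.10
N_DIF_ITEMS = 6
LOW_COMPLEXITY_CUTOFF = 2


@dataclass(frozen=True)
class DifPattern:
    """Signed focal-minus-reference parameter shifts (delta_g, delta_s)."""

    delta_g: float
    delta_s: float

    def __post_init__(self) -> None:
        for name, d in (("delta_g", self.delta_g), ("delta_s", self.delta_s)):
            if not any(math.isclose(abs(d), a, abs_tol=1e-12) for a in _ALLOWED_DELTAS):
                raise ValueError(f"|{name}| must be one of {_ALLOWED_DELTAS}, got {d}")
        sizes = {abs(d) for d in (self.delta_g, self.delta_s) if d != 0.0}
        if len(sizes) > 1:
            raise ValueError("mixed-magnitude DIF patterns are not part of the design")

    @property
    def dif_type(self) -> str:
        if self.delta_g == 0.0 and self.delta_s == 0.0:
            return "none"
        if self.delta_g != 0.0 and self.delta_s != 0.0 and (
            np.sign(self.delta_g) == np.sign(self.delta_s)
        ):
            return "uniform"
        return "nonuniform"

    @property
    def dif_size(self) -> str:
        mag = max(abs(self.delta_g), abs(self.delta_s))
        if mag == 0.0:
            return "none"
        return "moderate" if math.isclose(mag, MODERATE_DIF) else "large"

    @property
    def label(self) -> str:
        if self.dif_type == "none":
            return "none"
        return f"g{self.delta_g:+.3f}_s{self.delta_s:+.3f}"


NO_DIF = DifPattern(0.0, 0.0)

_POSITIONS = ("random", "low_complexity", "high_complexity")
_GROUPS = ("both", "focal_only")


@dataclass(frozen=True)
class MisspecificationSpec:
    """Where Q-entry flips land and which group's generating Q they affect."""

    position: str = "none"
    impacted_group: str = "none"
    rate: float = MISSPECIFICATION_RATE

    def __post_init__(self) -> None:
        if self.position not in _POSITIONS + ("none",):
            raise ValueError(f"unknown position {self.position!r}")
        if self.impacted_group not in _GROUPS + ("none",):
            raise ValueError(f"unknown impacted_group {self.impacted_group!r}")
        if (self.position == "none") != (self.impacted_group == "none"):
            raise ValueError("position is 'none' iff impacted_group is 'none'")
        if not (0.0 <= self.rate <= 1.0):
            raise ValueError("flip rate must lie in [0, 1]")

    @property
    def is_none(self) -> bool:
        return self.position == "none"

    @property
    def label(self) -> str:
        if self.is_none:
            return "none"
        return f"{self.impacted_group}-{self.position}"


NO_MISSPECIFICATION = MisspecificationSpec()


@dataclass(frozen=True)
class StudyCondition:
    """One cell of the 357-condition factorial design."""

    dif_pattern: DifPattern
    misspec: MisspecificationSpec
    attribute_correlation: float

    def __post_init__(self) -> None:
        if not any(
            math.isclose(self.attribute_correlation, r) for r in ATTRIBUTE_CORRELATIONS
        ):
            raise ValueError(
                f"attribute correlation must be one of {ATTRIBUTE_CORRELATIONS}, "
                f"got {self.attribute_correlation}"
            )

    @property
    def condition_id(self) -> str:
        return (
            f"dif[{self.dif_pattern.label}]"
            f"__mis[{self.misspec.label}]"
            f"__rho[{self.attribute_correlation:.1f}]"
        )


def _fixture_text(name: str) -> str:
    return resources.files("dinadif.fixtures").joinpath(name).read_text()


def build_study_qmatrix() -> QMatrix:
    """The fixed 31-item, 5-attribute study Q-matrix.

    The fixture enumerates every nonempty subset of the five attributes
    (ordered by number of required attributes, then lexicographically), so the
    test contains items measuring one to five attributes, a single-attribute
    anchor for each attribute (completeness / identifiability), 15 items in
    the low-complexity stratum (<= 2 attributes) and 16 in the high-complexity
    stratum.  It is a versioned fixture, never re-randomized.
    """
    rows = []
    for line in _fixture_text("study_qmatrix.csv").splitlines():
        if not line or line.startswith("#") or line.startswith("item_id"):
            continue
        parts = line.split(",")
        rows.append([int(v) for v in parts[1:]])
    return QMatrix(np.array(rows, dtype=np.int8))


def load_study_dif_items() -> tuple[int, ...]:
    """The six frozen DIF item ids (three per complexity stratum)."""
    payload = json.loads(_fixture_text("study_dif_items.json"))
    return tuple(int(i) for i in payload["dif_items"])


def load_baseline_parameters() -> ItemParameterSet:
    """The frozen baseline (reference-group) slipping/guessing draw."""
    s, g = [], []
    for line in _fixture_text("baseline_item_parameters.csv").splitlines():
        if not line or line.startswith("#") or line.startswith("item_id"):
            continue
        _, sj, gj = line.split(",")
        s.append(float(sj))
        g.append(float(gj))
    return ItemParameterSet(np.array(s), np.array(g))


def dif_condition_table() -> list[DifPattern]:
    """The no-DIF baseline followed by the 16 DIF patterns, in design order.

    Per size (moderate 0.075, large 0.10): two uniform patterns (both deltas
    positive / both negative) and six nonuniform ones (opposite signs or one
    delta zero).
    """
    patterns = [NO_DIF]
    for d in (MODERATE_DIF, LARGE_DIF):
        patterns.append(DifPattern(+d, +d))
        patterns.append(DifPattern(-d, -d))
    for d in (MODERATE_DIF, LARGE_DIF):
        patterns.extend(
            [
                DifPattern(+d, -d),
                DifPattern(+d, 0.0),
                DifPattern(-d, +d),
                DifPattern(-d, 0.0),
                DifPattern(0.0, -d),
                DifPattern(0.0, +d),
            ]
        )
    return patterns


def select_dif_items(
    q: QMatrix, n_dif: int = N_DIF_ITEMS, seed: int | np.random.Generator = 0
) -> tuple[int, ...]:
    """Select DIF items at random, stratified over both complexity strata.

    Half the items (rounded down) come from the low-complexity stratum
    (<= 2 required attributes), the rest from the high-complexity stratum, so
    per-stratum power summaries are always defined.
    """
    if n_dif > q.n_items:
        raise ValueError("cannot select more DIF items than there are items")
    rng = as_rng(seed)
    low_mask = q.low_complexity_mask(LOW_COMPLEXITY_CUTOFF)
    ids = np.asarray(q.item_ids)
    low_ids, high_ids = ids[low_mask], ids[~low_mask]
    n_low = n_dif // 2
    n_high = n_dif - n_low
    if n_low > low_ids.size or n_high > high_ids.size:
        raise ValueError(
            f"stratified selection needs {n_low} low- and {n_high} high-complexity "
            f"items but only {low_ids.size}/{high_ids.size} are available"
        )
    chosen = np.concatenate(
        [
            rng.choice(low_ids, size=n_low, replace=False),
            rng.choice(high_ids, size=n_high, replace=False),
        ]
    )
    return tuple(sorted(int(i) for i in chosen))


def apply_dif(
    params: ItemParameterSet,
    dif_items: tuple[int, ...] | list[int],
    pattern: DifPattern,
    item_ids: tuple[int, ...] | None = None,
) -> ItemParameterSet:
    """Focal-group parameters: shift g and s on DIF items, leave the rest.

    g_Fj = g_Rj + delta_g and s_Fj = s_Rj + delta_s for DIF items; the
    reference parameter set is never modified.  Any shifted parameter landing
    outside [0, 1) (or violating g < 1 - s) is rejected by the container.
    """
    ids = item_ids or tuple(range(1, params.n_items + 1))
    s = params.slipping.copy()
    g = params.guessing.copy()
    for item in dif_items:
        try:
            idx = ids.index(item)
        except ValueError:
            raise KeyError(f"DIF item id {item} not present") from None
        g[idx] += pattern.delta_g
        s[idx] += pattern.delta_s
    return ItemParameterSet(s, g)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def misspecify_qmatrix(
    q: QMatrix,
    spec: MisspecificationSpec,
    seed: int | np.random.Generator,
    max_redraws: int = 1000,
) -> QMatrix:
    """Flip round(rate * J * K) Q entries inside the eligible pool.

    The pool is every entry for position='random', entries of items with true
    row-sum <= 2 for 'low_complexity', and row-sum >= 3 for 'high_complexity'
    (complexity judged on the input Q).  Flip sets producing an all-zero row
    are re-drawn.  The input matrix is left unmodified.
    """
    if spec.is_none:
        raise ValueError("misspecify_qmatrix requires a non-null specification")
    j, k = q.entries.shape
    n_flips = _round_half_up(spec.rate * j * k)
    if spec.position == "random":
        eligible_rows = np.arange(j)
    elif spec.position == "low_complexity":
        eligible_rows = np.flatnonzero(q.low_complexity_mask(LOW_COMPLEXITY_CUTOFF))
    else:
        eligible_rows = np.flatnonzero(~q.low_complexity_mask(LOW_COMPLEXITY_CUTOFF))
    pool = np.array([(r, c) for r in eligible_rows for c in range(k)])
    if pool.shape[0] < n_flips:
        raise ValueError(
            f"eligible pool has {pool.shape[0]} entries, fewer than the "
            f"{n_flips} required flips"
        )
    rng = as_rng(seed)
    for _ in range(max_redraws):
        pick = rng.choice(pool.shape[0], size=n_flips, replace=False)
        entries = q.entries.copy()
        rows, cols = pool[pick, 0], pool[pick, 1]
        entries[rows, cols] ^= 1
        if entries.sum(axis=1).min() >= 1:
            return QMatrix(entries, q.item_ids, q.attribute_ids)
    raise RuntimeError("could not draw a flip set without an all-zero row")


def misspecification_table() -> list[MisspecificationSpec]:
    """The no-misspecification baseline plus the 6 position x group combinations."""
    specs = [NO_MISSPECIFICATION]
    for group in _GROUPS:
        for position in _POSITIONS:
            specs.append(MisspecificationSpec(position=position, impacted_group=group))
    return specs


def condition_grid_frame():
    """The full grid as a tidy table, one row per condition (CSV-ready)."""
    import pandas as pd

    rows = []
    for c in build_condition_grid():
        rows.append(
            {
                "condition_id": c.condition_id,
                "dif_type": c.dif_pattern.dif_type,
                "dif_size": c.dif_pattern.dif_size,
                "delta_g": c.dif_pattern.delta_g,
                "delta_s": c.dif_pattern.delta_s,
                "impacted_group": c.misspec.impacted_group,
                "position": c.misspec.position,
                "flip_rate": c.misspec.rate if not c.misspec.is_none else 0.0,
                "rho": c.attribute_correlation,
            }
        )
    return pd.DataFrame(rows)


def build_condition_grid() -> list[StudyCondition]:
    """All 357 study conditions: 17 DIF patterns x 7 misspecifications x 3 rho."""
    grid = []
    for pattern in dif_condition_table():
        for misspec in misspecification_table():
            for rho in ATTRIBUTE_CORRELATIONS:
                grid.append(
                    StudyCondition(
                        dif_pattern=pattern,
                        misspec=misspec,
                        attribute_correlation=rho,
                    )
                )
    return grid
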