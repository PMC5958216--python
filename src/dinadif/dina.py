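"""DINA model primitives and the synthetic response generator.

The DINA ("deterministic inputs, noisy AND-gate") model is a conjunctive
cognitive diagnostic model for dichotomous item responses.  Each item ``j``
requires the subset of latent binary attributes given by row ``j`` of a
Q-matrix; an examinee ``i`` with attribute profile ``alpha_i`` has the ideal
response

    eta_ij = prod_k alpha_ik ** q_jk,

i.e. ``eta_ij = 1`` iff every required attribute is mastered.  The observed
response is a noisy version of ``eta``:

    P(X_ij = 1 | alpha_i) = (1 - s_j) ** eta_ij * g_j ** (1 - eta_ij),

where ``s_j`` is the slipping probability (failing despite full mastery) and
``g_j`` the guessing probability (succeeding without it).

This module provides the typed containers (Q-matrix, attribute profiles, item
parameters, responses) and the stochastic generators used by the simulation
study: correlated attribute profiles from a thresholded equicorrelated
multivariate normal, uniform item-parameter draws, and Bernoulli response
simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "QMatrix",
    "AttributeProfileMatrix",
    "ItemParameterSet",
    "ResponseMatrix",
    "EtaMatrix",
    "compute_eta",
    "response_probability",
    "draw_attribute_profiles",
    "draw_item_parameters",
    "simulate_responses",
]


def as_rng(seed: int | np.random.Generator | np.random.SeedSequence) -> np.random.Generator:
    """Return a numpy Generator for an int seed, SeedSequence, or pass one through."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _require_binary(arr: np.ndarray, name: str) -> np.ndarray:
    out = np.asarray(arr)
    if out.ndim != 2:
        raise ValueError(f"{name} must be a 2-D array, got shape {out.shape}")
    if not np.isin(out, (0, 1)).all():
        raise ValueError(f"{name} entries must all be 0 or 1")
    return out.astype(np.int8)


@dataclass
class QMatrix:
    """Binary J x K loading structure mapping items to required attributes."""

    entries: np.ndarray
    item_ids: tuple[int, ...] = ()
    attribute_ids: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.entries = _require_binary(self.entries, "Q-matrix")
        j, k = self.entries.shape
        rs = self.entries.sum(axis=1)
        if (rs < 1).any():
            bad = [int(i) for i in np.flatnonzero(rs < 1)]
            raise ValueError(f"every item must require >= 1 attribute; rows {bad} are all zero")
        if not self.item_ids:
            self.item_ids = tuple(range(1, j + 1))
        if not self.attribute_ids:
            self.attribute_ids = tuple(range(1, k + 1))
        if len(self.item_ids) != j or len(self.attribute_ids) != k:
            raise ValueError("item_ids / attribute_ids lengths must match the matrix shape")

    @property
    def n_items(self) -> int:
        return self.entries.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.entries.shape[1]

    @property
    def row_sums(self) -> np.ndarray:
        return self.entries.sum(axis=1)

    def item_index(self, item_id: int) -> int:
        """0-based row index of a (1-based) item id."""
        try:
            return self.item_ids.index(item_id)
        except ValueError:
            raise KeyError(f"unknown item id {item_id}") from None

    def low_complexity_mask(self, cutoff: int = 2) -> np.ndarray:
        """Boolean mask of items requiring ``cutoff`` or fewer attributes."""
        return self.row_sums <= cutoff

    def copy(self) -> "QMatrix":
        return QMatrix(self.entries.copy(), self.item_ids, self.attribute_ids)


@dataclass
class AttributeProfileMatrix:
    """N x K binary mastery indicators, with the correlation that generated them."""

    profiles: np.ndarray
    generating_correlation: float = float("nan")

    def __post_init__(self) -> None:
        self.profiles = _require_binary(self.profiles, "attribute profiles")

    @property
    def n_examinees(self) -> int:
        return self.profiles.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.profiles.shape[1]


@dataclass
class ItemParameterSet:
    """Per-item slipping (s) and guessing (g) probabilities.

    Invariants: s_j, g_j in [0, 1) and g_j < 1 - s_j (an examinee who has
    mastered everything an item requires is never less likely to succeed than
    one who has not).
    """

    slipping: np.ndarray
    guessing: np.ndarray

    def __post_init__(self) -> None:
        self.slipping = np.atleast_1d(np.asarray(self.slipping, dtype=float))
        self.guessing = np.atleast_1d(np.asarray(self.guessing, dtype=float))
        if self.slipping.shape != self.guessing.shape or self.slipping.ndim != 1:
            raise ValueError("slipping and guessing must be 1-D vectors of equal length")
        for name, v in (("slipping", self.slipping), ("guessing", self.guessing)):
            if ((v < 0) | (v >= 1)).any():
                raise ValueError(f"{name} parameters must lie in [0, 1)")
        if (self.guessing > 1 - self.slipping).any():
            bad = np.flatnonzero(self.guessing > 1 - self.slipping)
            raise ValueError(
                f"monotonicity g <= 1 - s violated at item index(es) {bad.tolist()}"
            )

    @property
    def n_items(self) -> int:
        return self.slipping.shape[0]

    def copy(self) -> "ItemParameterSet":
        return ItemParameterSet(self.slipping.copy(), self.guessing.copy())


@dataclass
class ResponseMatrix:
    """N x J dichotomous responses for one examinee group."""

    responses: np.ndarray
    group_label: str = "reference"

    def __post_init__(self) -> None:
        self.responses = _require_binary(self.responses, "responses")

    @property
    def n_examinees(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    def total_scores(self) -> np.ndarray:
        """Number-correct total score per examinee (includes every item)."""
        return self.responses.sum(axis=1)


@dataclass
class EtaMatrix:
    """N x J ideal-response ("AND"-gate) indicators."""

    eta: np.ndarray

    def __post_init__(self) -> None:
        self.eta = _require_binary(self.eta, "eta")


def compute_eta(profiles: AttributeProfileMatrix | np.ndarray, q: QMatrix) -> EtaMatrix:
    """Ideal responses eta_ij = prod_k alpha_ik ** q_jk.

    eta_ij = 1 iff examinee i masters every attribute required by item j.
    """
    alpha = profiles.profiles if isinstance(profiles, AttributeProfileMatrix) else np.asarray(profiles)
    if alpha.shape[1] != q.n_attributes:
        raise ValueError(
            f"attribute count mismatch: profiles have {alpha.shape[1]} columns, "
            f"Q-matrix has {q.n_attributes}"
        )
    # alpha @ q_j counts mastered-and-required attributes; equality with the row
    # sum means every required attribute is mastered.
    hits = alpha.astype(np.int64) @ q.entries.T.astype(np.int64)
    eta = (hits == q.row_sums[None, :]).astype(np.int8)
    return EtaMatrix(eta)


def response_probability(
    eta: np.ndarray | int, slipping: np.ndarray | float, guessing: np.ndarray | float
) -> np.ndarray | float:
    """P(X=1) = 1 - s where eta = 1, g where eta = 0 (broadcasting elementwise)."""
    e = np.asarray(eta)
    s = np.asarray(slipping, dtype=float)
    g = np.asarray(guessing, dtype=float)
    if ((s < 0) | (s >= 1)).any() or ((g < 0) | (g >= 1)).any():
        raise ValueError("slipping and guessing must lie in [0, 1)")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("eta must be binary")
    p = np.where(e == 1, 1.0 - s, g)
    return float(p) if p.ndim == 0 else p


def draw_attribute_profiles(
    n: int,
    k: int,
    rho: float,
    seed: int | np.random.Generator,
    threshold: float = 0.0,
) -> AttributeProfileMatrix:
    """Draw N correlated binary attribute profiles.

    Each profile comes from a k-variate standard normal with all pairwise
    correlations ``rho``, dichotomized at ``threshold`` (mastery iff the latent
    coordinate is >= threshold).  Threshold 0 gives marginal mastery rate 0.5.
    """
    if n < 0 or k < 1:
        raise ValueError("need n >= 0 and k >= 1")
    if not (0.0 <= rho < 1.0):
        raise ValueError(f"attribute correlation must satisfy 0 <= rho < 1, got {rho}")
    rng = as_rng(seed)
    cov = np.full((k, k), rho)
    np.fill_diagonal(cov, 1.0)
    chol = np.linalg.cholesky(cov)
    z = rng.standard_normal((n, k)) @ chol.T
    profiles = (z >= threshold).astype(np.int8)
    return AttributeProfileMatrix(profiles, generating_correlation=rho)


def draw_item_parameters(
    j_items: int,
    lower: float = 0.1,
    upper: float = 0.3,
    seed: int | np.random.Generator = 0,
) -> ItemParameterSet:
    """Draw slipping and guessing independently uniform on [lower, upper].

    ``upper <= 0.5`` guarantees the monotonicity invariant g < 1 - s by
    construction.
    """
    if not (0.0 <= lower < upper <= 0.5):
        raise ValueError(
            f"need 0 <= lower < upper <= 0.5 for valid DINA parameters, got [{lower}, {upper}]"
        )
    rng = as_rng(seed)
    s = rng.uniform(lower, upper, size=j_items)
    g = rng.uniform(lower, upper, size=j_items)
    return ItemParameterSet(s, g)


def simulate_responses(
    profiles: AttributeProfileMatrix,
    q: QMatrix,
    params: ItemParameterSet,
    seed: int | np.random.Generator,
    group_label: str = "reference",
) -> ResponseMatrix:
    """Simulate X_ij ~ Bernoulli((1-s_j)^eta_ij g_j^(1-eta_ij)) independently."""
    if params.n_items != q.n_items:
        raise ValueError(
            f"parameter count ({params.n_items}) does not match item count ({q.n_items})"
        )
    eta = compute_eta(profiles, q).eta
    p = response_probability(eta, params.slipping[None, :], params.guessing[None, :])
    rng = as_rng(seed)
    x = (rng.random(eta.shape) < p).astype(np.int8)
    return ResponseMatrix(x, group_label=group_label)
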