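"""Marginal maximum-likelihood estimation of the DINA model by EM.

The latent attribute profile alpha_i is unobserved; the marginal likelihood of
a response vector x_i sums over the C = 2^K latent classes:

    L_i = sum_c pi_c * prod_j P(x_ij | eta_jc),

with P(x=1 | eta) = (1-s)^eta g^(1-eta).  The EM algorithm alternates

* E-step: class posteriors  post_ic  proportional to  pi_c prod_j P(x_ij|eta_jc),
* M-step: closed-form updates of each item's (s_j, g_j) from expected
  correct/incorrect counts split by eta, and of pi from posterior mass,

which never decreases the marginal log-likelihood.  A multigroup variant fits
two groups jointly with all items shared except one studied item, whose
(s, g) are group-specific, together with group-specific mixing proportions —
the fitting scheme behind the Wald test of item-parameter invariance.

Parameter covariance is estimated by the outer product of per-examinee score
vectors (OPG / cross-product of gradients) of the marginal log-likelihood at
the estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import pinvh

from .dina import ItemParameterSet, QMatrix, ResponseMatrix, compute_eta

__all__ = [
    "FitOptions",
    "LatentClassSpace",
    "FittedDina",
    "MultiGroupFit",
    "EstimationError",
    "em_fit",
    "class_posteriors",
    "parameter_covariance",
    "studied_item_covariance",
    "multigroup_em_fit",
    "marginal_loglik_naive",
]


class EstimationError(RuntimeError):
    """Raised when an estimation step cannot produce a usable result."""


@dataclass(frozen=True)
class FitOptions:
    """EM control knobs.

    ``tol`` is the convergence threshold on the maximum absolute change of any
    parameter (s, g, or a mixing proportion) between iterations; bounds keep
    M-step updates strictly interior, preventing boundary collapse and label
    switching (with both bounds below 0.5 the monotonicity g < 1 - s holds
    automatically).
    """

    max_iter: int = 1000
    tol: float = 1e-4
    param_min: float = 0.001
    param_max: float = 0.5
    init_slipping: float = 0.2
    init_guessing: float = 0.2


@dataclass
class LatentClassSpace:
    """All 2^K attribute patterns with their mixing proportions pi_c."""

    profiles: np.ndarray  # (C, K) binary
    mixing: np.ndarray  # (C,) simplex

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=np.int8)
        self.mixing = np.asarray(self.mixing, dtype=float)
        if self.mixing.shape != (self.profiles.shape[0],):
            raise ValueError("mixing length must equal the number of classes")
        if (self.mixing < 0).any() or not np.isclose(self.mixing.sum(), 1.0):
            raise ValueError("mixing proportions must be a probability simplex")

    @classmethod
    def full(cls, k: int, mixing: np.ndarray | None = None) -> "LatentClassSpace":
        c = 1 << k
        profiles = ((np.arange(c)[:, None] >> np.arange(k)[None, :]) & 1).astype(np.int8)
        if mixing is None:
            mixing = np.full(c, 1.0 / c)
        return cls(profiles, np.asarray(mixing, dtype=float))

    @property
    def n_classes(self) -> int:
        return self.profiles.shape[0]


def _class_eta(q: QMatrix, space: LatentClassSpace) -> np.ndarray:
    """(C, J) ideal responses of every latent class to every item."""
    return compute_eta(space.profiles, q).eta


# Finite sentinel for log(0): keeps 0 * log(0) = 0 inside the matmul (a
# response cannot "see" an impossible outcome it did not produce) while a
# produced impossible outcome drives the class weight to exp(-1e15) = 0.
_NEG_BIG = -1e15


def _safe_log(v: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        out = np.log(v)
    out[np.isneginf(out)] = _NEG_BIG
    return out


def _class_logprobs(eta_c: np.ndarray, s: np.ndarray, g: np.ndarray):
    p = np.where(eta_c == 1, 1.0 - s[None, :], g[None, :])
    return _safe_log(p), _safe_log(1.0 - p)


def _estep(x: np.ndarray, eta_c: np.ndarray, s, g, pi):
    """Total marginal log-likelihood and (N, C) class posteriors.

    Uses the single-matmul identity
    sum_j [x log p + (1-x) log(1-p)] = x @ (log p - log(1-p)).T + sum_j log(1-p).
    """
    logp, log1mp = _class_logprobs(eta_c, s, g)
    joint = x @ (logp - log1mp).T
    joint += (log1mp.sum(axis=1) + _safe_log(np.asarray(pi, dtype=float)))[None, :]
    best = joint.max(axis=1)
    if (best < -1e12).any():
        bad = np.flatnonzero(best < -1e12).tolist()
        raise EstimationError(
            f"zero marginal likelihood for examinee row(s) {bad[:10]}; "
            "responses are impossible under the supplied parameters"
        )
    w = np.exp(joint - best[:, None])
    tot = w.sum(axis=1)
    post = w / tot[:, None]
    return float((best + np.log(tot)).sum()), post


@dataclass
class FittedDina:
    """Converged (or flagged) single-group marginal ML fit."""

    params: ItemParameterSet
    class_space: LatentClassSpace
    loglik: float
    loglik_history: np.ndarray
    converged: bool
    n_iterations: int
    q: QMatrix
    responses: np.ndarray = field(repr=False)
    options: FitOptions = field(default_factory=FitOptions)


@dataclass
class MultiGroupFit:
    """Two-group joint fit with one studied item's (s, g) group-specific.

    All other items share parameters across groups by construction; mixing
    proportions are group-specific.
    """

    q: QMatrix
    studied_item: int
    slipping_ref: np.ndarray
    guessing_ref: np.ndarray
    slipping_foc: np.ndarray
    guessing_foc: np.ndarray
    space_ref: LatentClassSpace
    space_foc: LatentClassSpace
    loglik: float
    loglik_history: np.ndarray
    converged: bool
    n_iterations: int
    responses_ref: np.ndarray = field(repr=False)
    responses_foc: np.ndarray = field(repr=False)
    options: FitOptions = field(default_factory=FitOptions)

    @property
    def studied_index(self) -> int:
        return self.q.item_index(self.studied_item)

    def studied_estimates(self) -> np.ndarray:
        """(s_R, g_R, s_F, g_F) for the studied item."""
        j0 = self.studied_index
        return np.array(
            [
                self.slipping_ref[j0],
                self.guessing_ref[j0],
                self.slipping_foc[j0],
                self.guessing_foc[j0],
            ]
        )


def _mstep_counts(post: np.ndarray, x: np.ndarray, eta_c: np.ndarray):
    """Class masses (C,), expected correct counts (C, J)."""
    return post.sum(axis=0), post.T @ x


def _update_sg(mass, corr, eta_c, s_old, g_old, opts):
    tot1 = (mass[:, None] * eta_c).sum(axis=0)
    tot0 = mass.sum() - tot1
    corr1 = (corr * eta_c).sum(axis=0)
    corr0 = corr.sum(axis=0) - corr1
    with np.errstate(invalid="ignore", divide="ignore"):
        s_new = np.where(tot1 > 0, 1.0 - corr1 / np.maximum(tot1, 1e-300), s_old)
        g_new = np.where(tot0 > 0, corr0 / np.maximum(tot0, 1e-300), g_old)
    return (
        np.clip(s_new, opts.param_min, opts.param_max),
        np.clip(g_new, opts.param_min, opts.param_max),
    )


def _update_pi(mass: np.ndarray) -> np.ndarray:
    pi = np.maximum(mass / mass.sum(), 1e-12)
    return pi / pi.sum()


def em_fit(
    x: ResponseMatrix | np.ndarray,
    q: QMatrix,
    options: FitOptions | None = None,
) -> FittedDina:
    """Single-group marginal ML fit of the DINA model by EM.

    Starting values are s = g = 0.2 with uniform mixing proportions;
    convergence is declared when the largest absolute parameter change drops
    below ``options.tol``.  A fit hitting ``max_iter`` is returned with
    ``converged=False`` rather than silently accepted.
    """
    opts = options or FitOptions()
    xm = x.responses if isinstance(x, ResponseMatrix) else np.asarray(x)
    if xm.shape[1] != q.n_items:
        raise ValueError("response columns must match Q-matrix rows")
    xf = xm.astype(float)
    space = LatentClassSpace.full(q.n_attributes)
    eta_c = _class_eta(q, space)
    j = q.n_items
    s = np.full(j, opts.init_slipping)
    g = np.full(j, opts.init_guessing)
    pi = space.mixing.copy()
    history = []
    converged = False
    it = 0
    for it in range(1, opts.max_iter + 1):
        ll, post = _estep(xf, eta_c, s, g, pi)
        history.append(ll)
        mass, corr = _mstep_counts(post, xf, eta_c)
        s_new, g_new = _update_sg(mass, corr, eta_c, s, g, opts)
        pi_new = _update_pi(mass)
        delta = max(
            np.abs(s_new - s).max(), np.abs(g_new - g).max(), np.abs(pi_new - pi).max()
        )
        s, g, pi = s_new, g_new, pi_new
        if delta < opts.tol:
            converged = True
            break
    ll_final, _ = _estep(xf, eta_c, s, g, pi)
    history.append(ll_final)
    return FittedDina(
        params=ItemParameterSet(s, g),
        class_space=LatentClassSpace(space.profiles, pi),
        loglik=ll_final,
        loglik_history=np.asarray(history),
        converged=converged,
        n_iterations=it,
        q=q,
        responses=xm,
        options=opts,
    )


def class_posteriors(
    x: ResponseMatrix | np.ndarray,
    q: QMatrix,
    params: ItemParameterSet,
    space: LatentClassSpace,
) -> np.ndarray:
    """(N, C) posterior class memberships under the supplied parameters.

    Rows normalize to one and are proportional to pi_c prod_j P(x_ij|eta_jc);
    an examinee whose responses have zero likelihood under every class is
    rejected with diagnostics.
    """
    xm = x.responses if isinstance(x, ResponseMatrix) else np.asarray(x)
    eta_c = _class_eta(q, space)
    _, post = _estep(xm.astype(float), eta_c, params.slipping, params.guessing, space.mixing)
    return post


def marginal_loglik_naive(
    x: np.ndarray, q: QMatrix, params: ItemParameterSet, space: LatentClassSpace
) -> float:
    """Direct summation over all 2^K classes, one examinee and class at a time.

    Deliberately loop-based and independent of the vectorized E-step; used as
    an oracle for the EM internals.
    """
    xm = np.asarray(x)
    eta_c = _class_eta(q, space)
    total = 0.0
    for i in range(xm.shape[0]):
        li = 0.0
        for c in range(space.n_classes):
            pc = space.mixing[c]
            for j in range(q.n_items):
                p1 = 1.0 - params.slipping[j] if eta_c[c, j] else params.guessing[j]
                pc *= p1 if xm[i, j] == 1 else 1.0 - p1
            li += pc
        total += np.log(li)
    return float(total)


# --------------------------------------------------------------------------
# multigroup fit (Wald plumbing)
# --------------------------------------------------------------------------


def multigroup_em_fit(
    x_ref: ResponseMatrix | np.ndarray,
    x_foc: ResponseMatrix | np.ndarray,
    q: QMatrix,
    studied_item: int | None,
    options: FitOptions | None = None,
    init: "FittedDina | MultiGroupFit | None" = None,
) -> MultiGroupFit:
    """Joint two-group EM with only the studied item's (s, g) group-specific.

    Shared items are updated from pooled expected counts; the studied item
    from each group's own counts; mixing proportions per group.
    ``studied_item=None`` fits the fully shared model (all item parameters
    equal across groups, mixing proportions still group-specific) — useful as
    a warm start.  ``init`` may supply that shared fit (or a pooled
    single-group fit), which greatly shortens the per-item fits inside the
    Wald test.
    """
    opts = options or FitOptions()
    xr = (x_ref.responses if isinstance(x_ref, ResponseMatrix) else np.asarray(x_ref)).astype(float)
    xf = (x_foc.responses if isinstance(x_foc, ResponseMatrix) else np.asarray(x_foc)).astype(float)
    if xr.shape[1] != q.n_items or xf.shape[1] != q.n_items:
        raise ValueError("both groups must respond to the Q-matrix's items")
    j0 = None if studied_item is None else q.item_index(studied_item)
    space = LatentClassSpace.full(q.n_attributes)
    eta_c = _class_eta(q, space)
    j = q.n_items
    if isinstance(init, MultiGroupFit):
        s_r = init.slipping_ref.copy()
        g_r = init.guessing_ref.copy()
        pi_r = init.space_ref.mixing.copy()
        pi_f = init.space_foc.mixing.copy()
    elif init is not None:
        s_r = np.clip(init.params.slipping.copy(), opts.param_min, opts.param_max)
        g_r = np.clip(init.params.guessing.copy(), opts.param_min, opts.param_max)
        pi_r = init.class_space.mixing.copy()
        pi_f = init.class_space.mixing.copy()
    else:
        s_r = np.full(j, opts.init_slipping)
        g_r = np.full(j, opts.init_guessing)
        pi_r = space.mixing.copy()
        pi_f = space.mixing.copy()
    # studied-item focal parameters start at the shared values
    s_f0 = s_r[j0] if j0 is not None else np.nan
    g_f0 = g_r[j0] if j0 is not None else np.nan
    history = []
    converged = False
    it = 0
    for it in range(1, opts.max_iter + 1):
        s_f = s_r.copy()
        g_f = g_r.copy()
        if j0 is not None:
            s_f[j0], g_f[j0] = s_f0, g_f0
        ll_r, post_r = _estep(xr, eta_c, s_r, g_r, pi_r)
        ll_f, post_f = _estep(xf, eta_c, s_f, g_f, pi_f)
        history.append(ll_r + ll_f)
        mass_r, corr_r = _mstep_counts(post_r, xr, eta_c)
        mass_f, corr_f = _mstep_counts(post_f, xf, eta_c)
        # shared items: pooled counts
        s_new, g_new = _update_sg(mass_r + mass_f, corr_r + corr_f, eta_c, s_r, g_r, opts)
        delta_studied = 0.0
        if j0 is not None:
            # studied item: per-group counts
            s_ro, g_ro = _update_sg(mass_r, corr_r, eta_c, s_r, g_r, opts)
            s_fo, g_fo = _update_sg(mass_f, corr_f, eta_c, s_f, g_f, opts)
            s_new[j0], g_new[j0] = s_ro[j0], g_ro[j0]
            delta_studied = max(abs(s_fo[j0] - s_f0), abs(g_fo[j0] - g_f0))
            s_f0, g_f0 = s_fo[j0], g_fo[j0]
        pi_r_new, pi_f_new = _update_pi(mass_r), _update_pi(mass_f)
        delta = max(
            np.abs(s_new - s_r).max(),
            np.abs(g_new - g_r).max(),
            delta_studied,
            np.abs(pi_r_new - pi_r).max(),
            np.abs(pi_f_new - pi_f).max(),
        )
        s_r, g_r, pi_r, pi_f = s_new, g_new, pi_r_new, pi_f_new
        if delta < opts.tol:
            converged = True
            break
    s_f = s_r.copy()
    g_f = g_r.copy()
    if j0 is not None:
        s_f[j0], g_f[j0] = s_f0, g_f0
    ll_r, _ = _estep(xr, eta_c, s_r, g_r, pi_r)
    ll_f, _ = _estep(xf, eta_c, s_f, g_f, pi_f)
    history.append(ll_r + ll_f)
    return MultiGroupFit(
        q=q,
        studied_item=studied_item if studied_item is not None else -1,
        slipping_ref=s_r,
        guessing_ref=g_r,
        slipping_foc=s_f,
        guessing_foc=g_f,
        space_ref=LatentClassSpace(space.profiles, pi_r),
        space_foc=LatentClassSpace(space.profiles, pi_f),
        loglik=ll_r + ll_f,
        loglik_history=np.asarray(history),
        converged=converged,
        n_iterations=it,
        responses_ref=xr.astype(np.int8),
        responses_foc=xf.astype(np.int8),
        options=opts,
    )


# --------------------------------------------------------------------------
# OPG covariance
# --------------------------------------------------------------------------


def _sg_scores(x: np.ndarray, post: np.ndarray, eta_c: np.ndarray, s, g):
    """Per-examinee scores w.r.t. every item's s and g.

    d log L_i / d s_j = h_ij * (-x_ij/(1-s_j) + (1-x_ij)/s_j) with
    h_ij = P(eta_ij = 1 | x_i) the posterior AND-gate probability; the g score
    mirrors it on the 1 - h side.
    """
    h = post @ eta_c  # (N, J)
    sc_s = h * (-x / (1.0 - s[None, :]) + (1.0 - x) / s[None, :])
    sc_g = (1.0 - h) * (x / g[None, :] - (1.0 - x) / (1.0 - g[None, :]))
    return sc_s, sc_g


def _pi_scores(post: np.ndarray, pi: np.ndarray):
    """Scores w.r.t. the C-1 free mixing proportions (last class eliminated)."""
    return post[:, :-1] / pi[None, :-1] - post[:, -1:] / pi[-1]


def _single_group_score_matrix(fit: FittedDina, free_mixing: bool) -> np.ndarray:
    x = fit.responses.astype(float)
    eta_c = _class_eta(fit.q, fit.class_space)
    _, post = _estep(
        x, eta_c, fit.params.slipping, fit.params.guessing, fit.class_space.mixing
    )
    sc_s, sc_g = _sg_scores(x, post, eta_c, fit.params.slipping, fit.params.guessing)
    blocks = [sc_s, sc_g]
    if free_mixing:
        blocks.append(_pi_scores(post, fit.class_space.mixing))
    return np.hstack(blocks)


def _multigroup_score_matrix(fit: MultiGroupFit) -> np.ndarray:
    """Scores over [s_1..s_J (studied=ref), g_1..g_J, s_F*, g_F*, pi_R, pi_F]."""
    q, j0 = fit.q, fit.studied_index
    jj = q.n_items
    eta_c = _class_eta(q, fit.space_ref)
    c1 = fit.space_ref.n_classes - 1

    xr = fit.responses_ref.astype(float)
    _, post_r = _estep(xr, eta_c, fit.slipping_ref, fit.guessing_ref, fit.space_ref.mixing)
    sc_s_r, sc_g_r = _sg_scores(xr, post_r, eta_c, fit.slipping_ref, fit.guessing_ref)
    n_r = xr.shape[0]
    block_r = np.hstack(
        [
            sc_s_r,
            sc_g_r,
            np.zeros((n_r, 2)),
            _pi_scores(post_r, fit.space_ref.mixing),
            np.zeros((n_r, c1)),
        ]
    )

    xf = fit.responses_foc.astype(float)
    _, post_f = _estep(xf, eta_c, fit.slipping_foc, fit.guessing_foc, fit.space_foc.mixing)
    sc_s_f, sc_g_f = _sg_scores(xf, post_f, eta_c, fit.slipping_foc, fit.guessing_foc)
    st_s, st_g = sc_s_f[:, j0].copy(), sc_g_f[:, j0].copy()
    sc_s_f[:, j0] = 0.0
    sc_g_f[:, j0] = 0.0
    n_f = xf.shape[0]
    block_f = np.hstack(
        [
            sc_s_f,
            sc_g_f,
            st_s[:, None],
            st_g[:, None],
            np.zeros((n_f, c1)),
            _pi_scores(post_f, fit.space_foc.mixing),
        ]
    )
    return np.vstack([block_r, block_f])


def parameter_covariance(
    fit: FittedDina | MultiGroupFit,
    free_mixing: bool = True,
    allow_singular: bool = False,
) -> np.ndarray:
    """OPG covariance of the parameter estimates.

    The information matrix is the empirical cross-product of per-examinee
    score vectors at the estimates; its (pseudo-)inverse is the covariance.
    Parameter order: all slipping, all guessing, then free mixing proportions
    (for the multigroup fit: shared s and g with the studied slot holding the
    reference values, then the studied item's focal (s, g), then both groups'
    mixing proportions).  Singular information is rejected with a
    condition-number diagnostic unless ``allow_singular`` requests a
    pseudo-inverse.
    """
    if isinstance(fit, MultiGroupFit):
        scores = _multigroup_score_matrix(fit)
    else:
        scores = _single_group_score_matrix(fit, free_mixing)
    info = scores.T @ scores
    if not np.isfinite(info).all():
        raise EstimationError("non-finite entries in the information matrix")
    if not allow_singular:
        cond = np.linalg.cond(info)
        if not np.isfinite(cond) or cond > 1e12:
            raise EstimationError(
                f"information matrix is numerically singular (condition number {cond:.3e})"
            )
        cov = np.linalg.inv(info)
        return (cov + cov.T) / 2.0
    cov = pinvh(info)
    return (cov + cov.T) / 2.0


def fit_summary(fit: FittedDina):
    """Per-item estimate/SE table plus fit diagnostics (CSV-ready).

    SEs come from the OPG covariance (pseudo-inverted if ill-conditioned).
    """
    import pandas as pd

    cov = parameter_covariance(fit, allow_singular=True)
    j = fit.q.n_items
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    frame = pd.DataFrame(
        {
            "item_id": list(fit.q.item_ids),
            "slipping": fit.params.slipping,
            "guessing": fit.params.guessing,
            "se_slipping": se[:j],
            "se_guessing": se[j : 2 * j],
        }
    )
    frame["loglik"] = fit.loglik
    frame["converged"] = fit.converged
    frame["n_iterations"] = fit.n_iterations
    return frame


def studied_item_covariance(fit: MultiGroupFit, information: str = "item_block") -> np.ndarray:
    """4x4 covariance of the studied item's (s_R, g_R, s_F, g_F).

    ``information='item_block'`` (the default) inverts only the studied
    item's own 4x4 OPG cross-product — the item-wise incomplete-information
    convention of the standard CDM software implementations of this test.
    It ignores cross-parameter covariance and therefore understates sampling
    variance, which is what gives the classical Wald DIF test its inflated
    Type I error.  ``information='full'`` uses the studied block of the
    pseudo-inverted full-parameter OPG information instead (the corrected,
    better-calibrated variant; pseudo-inverted because mixing-direction
    information is routinely ill-conditioned at high attribute correlation).
    """
    jj, j0 = fit.q.n_items, fit.studied_index
    idx = np.array([j0, jj + j0, 2 * jj, 2 * jj + 1])
    if information == "full":
        cov = parameter_covariance(fit, allow_singular=True)
        return cov[np.ix_(idx, idx)]
    if information != "item_block":
        raise ValueError("information must be 'item_block' or 'full'")
    scores = _multigroup_score_matrix(fit)[:, idx]
    info4 = scores.T @ scores
    if not np.isfinite(info4).all():
        raise EstimationError("non-finite entries in the studied item's information")
    cov4 = pinvh(info4)
    return (cov4 + cov4.T) / 2.0
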