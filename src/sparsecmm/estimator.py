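"""Constrained multinomial estimation of CMMs: ML, MEL and MAEL.

All three methods maximize the multinomial log-likelihood sum(n_i log m_i)
subject to the model constraint g(m) = 0 and the sum constraint sum(m) = N;
they differ only in the support over which m lives:

* ML   — all L cells of the table (guarded: L must be materializable);
* MEL  — the observed cells only (zero cells become structural zeros);
* MAEL — the observed cells plus a small set of deliberately added
  zero-count cells chosen so that (i) every model margin has at least one
  contributing support cell and (ii) the covariance matrix of the margin
  statistics is nonsingular on the support.

The solver is Aitchison–Silvey/Lang-style Fisher scoring on the Lagrangian.
At iterate m, with G̃ the constraint Jacobian with the sum-constraint row
appended and D_m = diag(m):

    solve (G̃ D_m G̃ᵀ) λ = g̃(m) + G̃ (n − m),   m⁺ = n − D_m G̃ᵀ λ,

followed by a damped, floor-projected step.  Fixed points satisfy the
Lagrangian stationarity n_i/m̂_i = μ + (Gᵀλ)_i on interior cells; boundary
cells (m̂ at the floor) are flagged.  When the restricted support makes the
constraint-covariance matrix singular the fit aborts with a second-order
problem error; when the constraint set itself is infeasible on the support
(the empty-set problem) a first-order problem error is raised.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.linalg
from scipy import optimize, stats

from .contingency import (
    DEFAULT_DENSE_CAP,
    MarginSpec,
    SparseTable,
    full_support,
    index_to_pattern,
    margin_matrix,
    pattern_index,
)
from .models import (
    CMModel,
    ConstraintEvaluator,
    EvaluationError,
    IdentityLink,
    ModelError,
)

__all__ = [
    "SolverOptions",
    "FitResult",
    "AugmentationPlan",
    "GofStats",
    "EstimationProblem",
    "FirstOrderProblem",
    "SecondOrderProblem",
    "AugmentationFailure",
    "ProblemStatus",
    "fit",
    "augment_support",
    "detect_first_order_problem",
    "detect_second_order_problem",
    "goodness_of_fit",
    "beta_se",
]


class EstimationProblem(RuntimeError):
    """Base class for support-induced estimation failures."""

    exit_code = 2


class FirstOrderProblem(EstimationProblem):
    """The constraint set has no solution on the support (empty-set problem)."""

    exit_code = 3


class SecondOrderProblem(EstimationProblem):
    """The support makes the constraint covariance singular; augment the
    support (MAEL) to restore inference."""

    exit_code = 4


class AugmentationFailure(EstimationProblem):
    """Support augmentation hit its cap with the covariance still singular."""

    def __init__(self, message, coverage_report=None):
        super().__init__(message)
        self.coverage_report = coverage_report or {}


class ProblemStatus(enum.Enum):
    ABSENT = "absent"
    PRESENT = "present"
    UNDETERMINED = "undetermined"


@dataclass
class SolverOptions:
    """Tunable solver knobs.

    max_iter=1000 and uniform starting values match the reference defaults;
    convergence requires both max|g̃| < tol·N and max|Δm| < tol·N.  The floor
    (floor_scale·N) keeps D_m invertible while letting cells sit numerically
    at zero; rank deficiency below rank_tol (smallest/largest eigenvalue)
    triggers the second-order error.
    """

    max_iter: int = 1000
    tol: float = 1e-8
    floor_scale: float = 1e-12
    max_halvings: int = 30
    rank_tol: float = 1e-10
    dense_cap: int = DEFAULT_DENSE_CAP
    start: Optional[np.ndarray] = None


@dataclass
class AugmentationPlan:
    """Zero-count cells added to the observed support for a MAEL fit."""

    added_cells: list
    seed: Optional[int]
    level: str
    coverage_report: dict = field(default_factory=dict)


@dataclass
class GofStats:
    G2: float
    X2: float
    p_value: float
    G2_truncated: Optional[float] = None


@dataclass
class FitResult:
    """A fitted CMM on a support.

    ``m_hat`` sums to N and satisfies g within tolerance when ``converged``.
    ``lam`` holds the D+1 Lagrange multipliers (model constraints, then the
    sum constraint).  ``boundary_cells`` are support indices where the fitted
    expectation sits at the numerical floor; a positive count facing a
    floored expectation makes G2 = +inf, with the pre-truncation value kept
    in ``G2_truncated``.
    """

    method: str
    model_name: str
    support: list
    n: np.ndarray
    m_hat: np.ndarray
    lam: np.ndarray
    G2: float
    X2: float
    df: int
    p_value: float
    beta: Optional[np.ndarray]
    beta_se: Optional[np.ndarray]
    iterations: int
    converged: bool
    boundary_cells: list
    N: float
    G2_truncated: Optional[float] = None
    overall_mean: Optional[float] = None
    overall_mean_se: Optional[float] = None
    plan: Optional[AugmentationPlan] = None
    seed: Optional[int] = None
    max_constraint: float = math.inf


# ---------------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------------


def goodness_of_fit(n, m_hat, df: int, N: float = None, zero_tol: float = None) -> GofStats:
    """Likelihood-ratio G² and Pearson X² with upper-tail chi-square p.

    G² = 2 Σ_{n_i>0} n_i log(n_i/m̂_i) with 0·log 0 = 0; a positive count
    facing an (effectively) zero expectation — m̂_i at or below ``zero_tol``
    — gives G² = +inf, and the value computed at the floored expectation is
    reported alongside.
    """
    n = np.asarray(n, dtype=float)
    m_hat = np.asarray(m_hat, dtype=float)
    if np.any(n < 0) or np.any(m_hat < 0):
        raise ValueError("negative frequencies")
    if N is None:
        N = float(n.sum())
    if abs(n.sum() - m_hat.sum()) > 1e-6 * max(N, 1.0):
        raise ValueError("observed and expected totals differ")
    if zero_tol is None:
        zero_tol = 1e-10 * max(N, 1.0)
    floor = 1e-12 * max(N, 1.0)
    pos = n > 0
    clipped = np.maximum(m_hat, floor)
    G2_trunc = float(2.0 * np.sum(n[pos] * np.log(n[pos] / clipped[pos])))
    if np.any(pos & (m_hat <= zero_tol)):
        G2 = math.inf
    else:
        G2 = G2_trunc
        G2_trunc = None
    mask = m_hat > zero_tol
    X2 = float(np.sum((n[mask] - m_hat[mask]) ** 2 / m_hat[mask]))
    p = 0.0 if math.isinf(G2) else float(stats.chi2.sf(max(G2, 0.0), df)) if df > 0 else 1.0
    if df > 0 and not math.isinf(G2) and G2 <= 0:
        p = 1.0
    return GofStats(G2=max(G2, 0.0) if not math.isinf(G2) else G2, X2=X2, p_value=p,
                    G2_truncated=G2_trunc)


# ---------------------------------------------------------------------------
# problem detectors
# ---------------------------------------------------------------------------


def _support_patterns(support):
    if isinstance(support, SparseTable):
        return support.pattern_array()
    return np.asarray(support, dtype=np.int64)


def detect_first_order_problem(
    model: CMModel, support, N: float, seed: int = None, restarts: int = 5
) -> ProblemStatus:
    """Is {m >= 0, sum(m) = N, g(m) = 0} empty on this support?

    Identity-link models are linear, so feasibility is settled exactly by
    linear programming.  For nonlinear links the check is a heuristic: the
    squared constraint residual is minimized over the simplex from several
    random starts; a residual that cannot be driven to zero reports the
    problem as present.
    """
    ev = model.evaluator(support)
    S = ev.support_size
    if isinstance(model.link, IdentityLink):
        # g(m) = (Bᵀ·collapse·Aᵀ) m − criterion is linear in m
        G = model.B_t @ ev.A
        A_eq = np.vstack([G, np.ones(S)])
        b_eq = np.concatenate([model.criterion, [N]])
        res = optimize.linprog(
            np.zeros(S), A_eq=A_eq, b_eq=b_eq, bounds=(0, None), method="highs"
        )
        if res.status == 2:
            return ProblemStatus.PRESENT
        if res.status == 0:
            return ProblemStatus.ABSENT
        return ProblemStatus.UNDETERMINED

    rng = np.random.default_rng(seed)
    cons = [{"type": "eq", "fun": lambda m: np.sum(m) - N}]
    bounds = [(0.0, N)] * S

    def residual(m):
        try:
            g = ev.g(np.maximum(m, 1e-12 * N), N)
        except EvaluationError:
            return 1e6
        return float(g @ g)

    best = math.inf
    starts = [np.full(S, N / S)] + [
        N * rng.dirichlet(np.ones(S)) for _ in range(restarts - 1)
    ]
    for x0 in starts:
        res = optimize.minimize(
            residual, x0, method="SLSQP", bounds=bounds, constraints=cons,
            options={"maxiter": 200, "ftol": 1e-14},
        )
        if res.fun < best:
            best = res.fun
        if best < (1e-6 * N) ** 2:
            return ProblemStatus.ABSENT
    if best > (1e-4 * N) ** 2:
        return ProblemStatus.PRESENT
    return ProblemStatus.UNDETERMINED


def detect_second_order_problem(model: CMModel, support, N: float = 1.0) -> ProblemStatus:
    """Is the covariance of the constraint statistics singular on the support?

    Evaluates V = G Σ₀ Gᵀ at the uniform distribution over the support,
    where Σ₀ = D_m − m mᵀ/N is the multinomial covariance and G the
    constraint Jacobian.  Rank deficiency (smallest eigenvalue below
    rank_tol × largest) reports the problem; inference is then impossible
    because the variance of some constraint statistic is identically zero.
    """
    ev = model.evaluator(support)
    S = ev.support_size
    m = np.full(S, N / S)
    try:
        _, G = ev.g_and_G(m, N)
    except EvaluationError:
        return ProblemStatus.PRESENT
    Gm = G @ m
    V = (G * m) @ G.T - np.outer(Gm, Gm) / N
    return _rank_status(V)


def _rank_status(V: np.ndarray, rank_tol: float = 1e-10) -> ProblemStatus:
    if V.size == 0:
        return ProblemStatus.ABSENT
    w = np.linalg.eigvalsh((V + V.T) / 2.0)
    largest = float(w[-1])
    if largest <= 0:
        return ProblemStatus.PRESENT
    return ProblemStatus.PRESENT if w[0] < rank_tol * largest else ProblemStatus.ABSENT


# ---------------------------------------------------------------------------
# support augmentation
# ---------------------------------------------------------------------------

_PAIR_COVERAGE_LIMIT = 200  # beyond this many margin rows, go straight to random


def _random_cell_for_spec(spec, cats, rng, taken, tries=200):
    free = [j for j in range(len(cats)) if j not in spec.variables]
    fixed = dict(zip(spec.variables, spec.values))
    for _ in range(tries):
        p = tuple(
            fixed[j] if j in fixed else int(rng.integers(cats[j]))
            for j in range(len(cats))
        )
        if p not in taken:
            return p
    # tiny tables: enumerate the consistent cells and pick a missing one
    n_free = math.prod(cats[j] for j in free)
    if n_free <= 4096:
        for r in range(n_free):
            sub = index_to_pattern(r, [cats[j] for j in free])
            p = tuple(
                fixed[j] if j in fixed else sub[free.index(j)]
                for j in range(len(cats))
            )
            if p not in taken:
                return p
    return None


def augment_support(
    table: SparseTable,
    model: CMModel,
    seed: int = None,
    level: str = "second",
    extra: int = 0,
    cap: int = None,
) -> AugmentationPlan:
    """Choose zero-count cells to add to the observed support (MAEL).

    level="first" guarantees every model margin cell at least one
    contributing support cell (one uniformly random consistent pattern per
    uncovered margin).  level="second" additionally covers the pairwise
    joint margin cells that drive the margin covariances (skipping
    incompatible pairs, and skipped wholesale for models with very many
    margin rows) and then adds random zero cells until the covariance rank
    test passes or the cap (default 50·D + 100) is hit.  Deterministic given
    the seed.
    """
    if level not in ("first", "second"):
        raise ValueError(f"unknown augmentation level {level!r}")
    rng = np.random.default_rng(seed)
    cats = table.cats
    if cap is None:
        cap = 50 * model.D + 100
    arr = table.pattern_array()
    taken = set(table.patterns)
    added: list = []
    report: dict = {}

    def covered(spec, extra_cells):
        mask = np.ones(arr.shape[0], dtype=bool)
        for v, x in zip(spec.variables, spec.values):
            mask &= arr[:, v] == x
        if mask.any():
            return True
        return any(spec.matches(p) for p in extra_cells)

    for spec in model.margins:
        if covered(spec, added):
            report[spec] = "covered"
            continue
        cell = _random_cell_for_spec(spec, cats, rng, taken)
        if cell is None:
            raise AugmentationFailure(
                f"no free cell available to cover margin {spec}", report
            )
        added.append(cell)
        taken.add(cell)
        report[spec] = cell

    if level == "second":
        specs = model.margins
        if len(specs) <= _PAIR_COVERAGE_LIMIT:
            for i in range(len(specs)):
                for j in range(i + 1, len(specs)):
                    if not specs[i].compatible(specs[j]):
                        continue  # conflicting overlap: this covariance term vanishes
                    merged = specs[i].merged(specs[j])
                    if covered(merged, added):
                        continue
                    cell = _random_cell_for_spec(merged, cats, rng, taken)
                    if cell is not None:
                        added.append(cell)
                        taken.add(cell)
                        report[merged] = cell
        L = table.n_cells
        anything_free = (table.support_size + len(added)) < L
        while anything_free and len(added) < cap:
            status = detect_second_order_problem(
                model, table.patterns + added, N=table.N
            )
            if status is not ProblemStatus.ABSENT:
                batch = max(4, model.D)
                filler = MarginSpec((), ())
                got_any = False
                for _ in range(batch):
                    if table.support_size + len(added) >= L or len(added) >= cap:
                        break
                    cell = _random_cell_for_spec(filler, cats, rng, taken)
                    if cell is None:
                        break
                    added.append(cell)
                    taken.add(cell)
                    got_any = True
                if not got_any:
                    break
            else:
                break
        status = detect_second_order_problem(model, table.patterns + added, N=table.N)
        if status is not ProblemStatus.ABSENT and len(added) >= cap:
            raise AugmentationFailure(
                f"augmentation cap of {cap} cells reached with the constraint "
                "covariance still singular",
                report,
            )

    filler = MarginSpec((), ())
    for _ in range(int(extra)):
        cell = _random_cell_for_spec(filler, cats, rng, taken)
        if cell is None:
            break
        added.append(cell)
        taken.add(cell)
    return AugmentationPlan(added_cells=added, seed=seed, level=level,
                            coverage_report=report)


# ---------------------------------------------------------------------------
# structural zeros on a restricted support (identity links: exact, via LP)
# ---------------------------------------------------------------------------


def _forced_zero_cells(model: CMModel, ev: ConstraintEvaluator, N: float) -> list:
    """Support cells that every feasible m pins to zero (identity link only).

    On restricted supports, linear constraints can force cells to zero even
    when the constraint set is nonempty; if such a cell carries observations
    the constrained likelihood is unbounded below (G² = +inf) and plain
    Fisher scoring creeps.  A max-min LP certifies an interior feasible
    point; failing that, per-cell LPs identify the forced zeros exactly.
    """
    G = model.B_t @ ev.A
    D, S = G.shape
    A_eq = np.vstack([G, np.ones(S)])
    b_eq = np.concatenate([model.criterion, [N]])
    tol = 1e-9 * N
    # stage 1: maximize t subject to m_i >= t for all i (interior certificate)
    c = np.zeros(S + 1)
    c[-1] = -1.0
    A_eq1 = np.hstack([A_eq, np.zeros((D + 1, 1))])
    A_ub = np.hstack([-np.eye(S), np.ones((S, 1))])
    res = optimize.linprog(
        c, A_ub=A_ub, b_ub=np.zeros(S), A_eq=A_eq1, b_eq=b_eq,
        bounds=[(0, None)] * S + [(0, N)], method="highs",
    )
    if res.status != 0:
        return []  # infeasibility is handled by the first-order check
    if -res.fun > tol:
        return []
    candidates = [i for i in range(S) if res.x[i] <= tol]
    forced = []
    for i in candidates:
        ci = np.zeros(S)
        ci[i] = -1.0  # maximize m_i
        ri = optimize.linprog(
            ci, A_eq=A_eq, b_eq=b_eq, bounds=(0, None), method="highs"
        )
        if ri.status == 0 and -ri.fun <= tol:
            forced.append(i)
    return forced


# ---------------------------------------------------------------------------
# core solver
# ---------------------------------------------------------------------------


def _merit(n, m, g_tilde, floor, kappa):
    pos = n > 0
    return float(-np.sum(n[pos] * np.log(np.maximum(m[pos], floor)))
                 + kappa * np.abs(g_tilde).sum())


def _solve_on_support(ev: ConstraintEvaluator, n, N, options: SolverOptions,
                      strict_rank: bool = True):
    S = ev.support_size
    floor = options.floor_scale * N
    m = (np.maximum(np.asarray(options.start, dtype=float), floor)
         if options.start is not None else np.full(S, N / S))
    m = m * (N / m.sum())
    lam = np.zeros(ev.model.D + 1)
    converged = False
    it = 0
    max_g = math.inf
    ll_window: list = []
    for it in range(1, options.max_iter + 1):
        g, G = ev.g_and_G(m, N)
        g_tilde = np.concatenate([g, [m.sum() - N]])
        Gt = np.vstack([G, np.ones(S)])
        Dm = np.maximum(m, floor)
        M = (Gt * Dm) @ Gt.T
        rhs = g_tilde + Gt @ (n - m)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", scipy.linalg.LinAlgWarning)
                lam = scipy.linalg.solve(M, rhs, assume_a="pos")
        except (scipy.linalg.LinAlgError, np.linalg.LinAlgError, ValueError):
            if strict_rank and _rank_status(M, options.rank_tol) is ProblemStatus.PRESENT:
                raise SecondOrderProblem(
                    "constraint covariance singular on this support; "
                    "augment the support (MAEL)"
                ) from None
            lam = np.linalg.lstsq(M, rhs, rcond=None)[0]
        m_plus = n - Dm * (Gt.T @ lam)
        delta = m_plus - m
        kappa = max(1.0, 2.0 * float(np.abs(lam).max(initial=0.0)))
        merit0 = _merit(n, m, g_tilde, floor, kappa)
        s = 1.0
        m_new, g_new = None, None
        for _ in range(options.max_halvings):
            cand = np.maximum(m + s * delta, floor)
            try:
                g_c = ev.g(cand, N)
            except EvaluationError:
                s *= 0.5
                continue
            gt_c = np.concatenate([g_c, [cand.sum() - N]])
            if _merit(n, cand, gt_c, floor, kappa) <= merit0 + 1e-9 * (1 + abs(merit0)):
                m_new, g_new = cand, gt_c
                break
            s *= 0.5
        if m_new is None:  # no improving step: take the smallest trial anyway
            m_new = np.maximum(m + s * delta, floor)
            try:
                g_c = ev.g(m_new, N)
            except EvaluationError:
                break
            g_new = np.concatenate([g_c, [m_new.sum() - N]])
        step = float(np.max(np.abs(m_new - m)))
        max_g = float(np.max(np.abs(g_new)))
        m = m_new
        if max_g < options.tol * N and step < options.tol * N:
            converged = True
            break
        # secondary rule: constraints met and the likelihood resolved — the
        # iterate can keep bouncing tangentially in directions the
        # likelihood is flat in, so stagnation is judged on the range of
        # the log-likelihood over a window of iterations, not on step size
        pos = n > 0
        ll = float(np.sum(n[pos] * np.log(np.maximum(m[pos], floor))))
        ll_window.append(ll)
        if len(ll_window) > 20:
            ll_window.pop(0)
            if (
                max_g < options.tol * N
                and max(ll_window) - min(ll_window) < 1e-8 * (1.0 + abs(ll))
            ):
                converged = True
                break
    return m, lam, it, converged, max_g


# ---------------------------------------------------------------------------
# covariance / standard errors
# ---------------------------------------------------------------------------


def _mhat_covariance(ev: ConstraintEvaluator, m_hat, N, rank_tol=1e-10):
    """Asymptotic covariance of m̂ on the support (Aitchison–Silvey form):
    D − D G̃ᵀ (G̃ D G̃ᵀ)⁻¹ G̃ D with the sum-constraint row in G̃; reduces to
    the multinomial D − m mᵀ/N for the saturated model."""
    S = ev.support_size
    floor = 1e-12 * N
    Dm = np.maximum(m_hat, floor)
    _, G = ev.g_and_G(np.maximum(m_hat, floor), N)
    Gt = np.vstack([G, np.ones(S)])
    M = (Gt * Dm) @ Gt.T
    if _rank_status(M, rank_tol) is ProblemStatus.PRESENT:
        raise SecondOrderProblem(
            "constraint covariance singular at the fitted point"
        )
    GD = Gt * Dm  # rows of G̃ scaled by D
    return np.diag(Dm) - GD.T @ scipy.linalg.solve(M, GD, assume_a="pos")


def beta_se(model: CMModel, fit_result: FitResult, N: float = None) -> np.ndarray:
    """Delta-method standard errors of β̂ = (ZᵀZ)⁻¹ Zᵀ f(Aᵀ m̂)."""
    if model.Z is None:
        raise ModelError("model carries no design matrix Z")
    if not fit_result.converged:
        raise EstimationProblem("fit did not converge; no standard errors")
    if N is None:
        N = fit_result.N
    ev = model.evaluator(np.asarray(fit_result.support, dtype=np.int64))
    m_hat = fit_result.m_hat
    cov_m = _mhat_covariance(ev, m_hat, N)
    t = ev.margins(np.maximum(m_hat, 1e-12 * N))
    Jf = model.link.jacobian(t, N)
    Z = model.Z
    Jbeta = np.linalg.solve(Z.T @ Z, Z.T @ Jf @ ev.A)
    cov_b = Jbeta @ cov_m @ Jbeta.T
    return np.sqrt(np.maximum(np.diag(cov_b), 0.0))


# ---------------------------------------------------------------------------
# the front door
# ---------------------------------------------------------------------------


def fit(
    model: CMModel,
    table: SparseTable,
    method: str = "ml",
    options: SolverOptions = None,
    seed: int = None,
    augment_level: str = "second",
    extra_cells: int = 0,
    plan: AugmentationPlan = None,
) -> FitResult:
    """Fit a CMM by ML, MEL or MAEL and compute fit statistics.

    ML uses the full table (refused above ``options.dense_cap`` cells); MEL
    the observed support; MAEL the observed support plus an augmentation
    plan (computed from ``seed``/``augment_level``/``extra_cells`` unless an
    explicit ``plan`` is given).  Raises :class:`FirstOrderProblem` when the
    constraint set is infeasible on the support and :class:`SecondOrderProblem`
    when the constraint covariance is singular there.
    """
    options = options or SolverOptions()
    method = method.lower()
    if tuple(table.cats) != tuple(model.cats):
        raise ValueError("table and model disagree on category counts")
    N = table.N
    used_plan = None
    if method == "ml":
        patterns = full_support(table.cats, cap=options.dense_cap)
        n = table.dense_counts(cap=options.dense_cap)
    elif method == "mel":
        patterns = list(table.patterns)
        n = table.counts.astype(float)
    elif method == "mael":
        used_plan = plan if plan is not None else augment_support(
            table, model, seed=seed, level=augment_level, extra=extra_cells
        )
        aug = table.add_zero_cells(used_plan.added_cells)
        patterns = list(aug.patterns)
        n = aug.counts.astype(float)
    else:
        raise ValueError(f"unknown method {method!r}")

    ev = model.evaluator(np.asarray(patterns, dtype=np.int64))

    # linear models: settle feasibility exactly before iterating
    if method != "ml" and isinstance(model.link, IdentityLink):
        if detect_first_order_problem(model, patterns, N) is ProblemStatus.PRESENT:
            raise FirstOrderProblem(
                "the constraint set has no solution on this support "
                "(empty-set problem); augment the support"
            )
    # the covariance rank check at the uniform start doubles as the
    # second-order screen (cheap: D+1 squared); a first-order problem is the
    # more fundamental diagnosis (it implies the second-order one), so when
    # the screen fails, feasibility is checked before deciding which to raise
    if method != "ml":
        S = ev.support_size
        m0 = np.full(S, N / S)
        singular = False
        try:
            _, G0 = ev.g_and_G(m0, N)
            Gt0 = np.vstack([G0, np.ones(S)])
            M0 = (Gt0 * m0) @ Gt0.T
            singular = _rank_status(M0, options.rank_tol) is ProblemStatus.PRESENT
        except EvaluationError:
            singular = True
        if singular:
            if (
                detect_first_order_problem(model, patterns, N, seed=seed)
                is ProblemStatus.PRESENT
            ):
                raise FirstOrderProblem(
                    "the constraint set has no solution on this support "
                    "(empty-set problem); augment the support"
                )
            raise SecondOrderProblem(
                "constraint covariance singular on this support; "
                "augment the support (MAEL)"
            )

    # identity links: constraints on a restricted support can pin cells to
    # exact zero; solve on the free cells and report the pinned ones at the
    # floor (an observation on a pinned cell makes the deviance infinite)
    forced: list = []
    if isinstance(model.link, IdentityLink):
        forced = _forced_zero_cells(model, ev, N)
    try:
        if forced:
            keep = np.setdiff1d(np.arange(len(patterns)), forced)
            parr = np.asarray(patterns, dtype=np.int64)
            ev_red = model.evaluator(parr[keep])
            m_red, lam, iterations, converged, max_g = _solve_on_support(
                ev_red, n[keep], N, options, strict_rank=False
            )
            m_hat = np.full(len(patterns), options.floor_scale * N)
            m_hat[keep] = m_red
        else:
            m_hat, lam, iterations, converged, max_g = _solve_on_support(
                ev, n, N, options
            )
    except EvaluationError as exc:
        raise SecondOrderProblem(f"link undefined during iteration: {exc}") from exc

    if not converged and not isinstance(model.link, IdentityLink):
        if detect_first_order_problem(model, patterns, N, seed=seed) is ProblemStatus.PRESENT:
            raise FirstOrderProblem(
                "the constraint set has no solution on this support "
                "(empty-set problem); augment the support"
            )

    floor = options.floor_scale * N
    # a fitted expectation this small is a boundary cell: the exact
    # constrained optimum has it at zero, the solver at the floor
    zero_tol = 1e-6 * N
    boundary = [int(i) for i in np.flatnonzero(m_hat <= zero_tol)]
    if converged or abs(m_hat.sum() - N) <= 1e-6 * N:
        gof = goodness_of_fit(n, m_hat, model.D, N=N, zero_tol=zero_tol)
    else:  # diverged iterate: fit statistics are meaningless
        gof = GofStats(G2=math.nan, X2=math.nan, p_value=math.nan)
    beta_vec = overall = None
    if model.Z is not None and converged:
        t = ev.margins(np.maximum(m_hat, floor))
        f = model.link.value(t, N)
        beta_vec = np.linalg.solve(model.Z.T @ model.Z, model.Z.T @ f)
        if model.name == "mean":
            overall = float(np.sum(f) / (model.J * N))
    result = FitResult(
        method=method,
        model_name=model.name,
        support=[tuple(p) for p in patterns],
        n=n,
        m_hat=m_hat,
        lam=lam,
        G2=gof.G2,
        X2=gof.X2,
        df=model.D,
        p_value=gof.p_value,
        beta=beta_vec,
        beta_se=None,
        iterations=iterations,
        converged=converged,
        boundary_cells=boundary,
        N=N,
        G2_truncated=gof.G2_truncated,
        overall_mean=overall,
        plan=used_plan,
        seed=seed,
        max_constraint=max_g,
    )
    if model.Z is not None and converged:
        try:
            result.beta_se = beta_se(model, result, N)
            if model.name == "mean" and result.beta_se is not None:
                # overall mean = β / (√J · N)
                result.overall_mean_se = float(
                    result.beta_se[0] / (math.sqrt(model.J) * N)
                )
        except EstimationProblem:
            result.beta_se = None
    return result
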