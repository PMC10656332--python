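"""Null-population construction and simulation harnesses.

Populations that satisfy a CMM exactly are built in two steps: (1) draw a
base table of response patterns from a two-parameter logistic IRT model
(2PLM) — success probability 1/(1 + exp(−a_j(θ − b_j))) with a standard
normal latent trait θ — and (2) fit the CMM of interest to that base table;
the fitted probabilities π̂ = m̂/N satisfy the model constraints to solver
tolerance and become the data-generating distribution.  The particular 2PLM
parameters therefore only shape *where* in the null hypothesis the
population sits, not whether it sits there, which is what makes the Type-I
error harness a genuine null experiment.

Two harnesses mirror the two kinds of questions asked of the estimators:

* :func:`run_convergence_study` — small tables, ML vs MEL vs MAEL, with a
  controlled fraction U of population cells forced to zero (the thinned
  population need no longer satisfy the model; only convergence is scored);
* :func:`run_type1_study` — MAEL only, null populations, rejection rate of
  the G² test at the 5% level plus bias and SD of the mean-model parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .contingency import SparseTable, build_table
from .estimator import (
    EstimationProblem,
    FirstOrderProblem,
    SecondOrderProblem,
    SolverOptions,
    fit,
)
from .models import (
    CMModel,
    ModelError,
    alpha_model,
    coefficient_alpha,
    hj_model,
    item_scalability,
    mean_model,
)

__all__ = [
    "IRTItem",
    "PopulationModel",
    "StudyConfig",
    "StudyResult",
    "default_items",
    "twopl_sample",
    "build_population",
    "thin_zeros",
    "run_type1_study",
    "run_convergence_study",
    "results_frame",
    "load_study_config",
]

#: base-table size used when constructing populations
BASE_TABLE_SIZE = 1000


@dataclass(frozen=True)
class IRTItem:
    """2PLM item: discrimination a > 0, location b."""

    a: float
    b: float

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError("discrimination must be positive")

    def prob(self, theta):
        # logistic item characteristic curve, overflow-safe
        from scipy.special import expit

        return expit(self.a * (np.asarray(theta) - self.b))


def default_items(J: int, a: float = 1.5, b_range: float = 1.5) -> list:
    """Default item bank: common discrimination, locations equally spaced
    in [−b_range, b_range]."""
    bs = np.linspace(-b_range, b_range, J) if J > 1 else np.array([0.0])
    return [IRTItem(a=a, b=float(b)) for b in bs]


@dataclass
class PopulationModel:
    """A probability vector π on a sparse support."""

    cats: tuple
    support: list
    pi: np.ndarray

    def __post_init__(self):
        self.cats = tuple(int(c) for c in self.cats)
        self.support = [tuple(int(x) for x in p) for p in self.support]
        self.pi = np.asarray(self.pi, dtype=float)
        if np.any(self.pi < 0):
            raise ValueError("negative probabilities")
        s = self.pi.sum()
        if not math.isclose(s, 1.0, rel_tol=0, abs_tol=1e-8):
            raise ValueError(f"probabilities sum to {s}, not 1")

    @property
    def support_size(self) -> int:
        return len(self.support)

    def sample(self, N: int, seed=None) -> SparseTable:
        """Multinomial sample of size N from π, as a sparse table."""
        rng = np.random.default_rng(seed)
        counts = rng.multinomial(N, self.pi / self.pi.sum())
        pairs = [(p, int(c)) for p, c in zip(self.support, counts) if c > 0]
        return build_table(pairs, cats=self.cats)


def twopl_sample(items: Sequence[IRTItem], n: int, seed=None) -> SparseTable:
    """Draw n response patterns from the 2PLM with θ ~ N(0, 1)."""
    if n < 1:
        raise ValueError("need at least one respondent")
    rng = np.random.default_rng(seed)
    theta = rng.standard_normal(n)
    probs = np.column_stack([item.prob(theta) for item in items])
    scores = (rng.random(probs.shape) < probs).astype(np.int64)
    return build_table([tuple(row) for row in scores],
                       cats=(2,) * len(items))


def build_population(
    model: CMModel,
    base: SparseTable,
    method: str = "ml",
    seed=None,
    options: SolverOptions = None,
) -> PopulationModel:
    """Fit the CMM to a base table; π = m̂/N on the fitted support.

    The returned population satisfies the model constraints to solver
    tolerance, whatever the base table looked like.
    """
    result = fit(model, base, method=method, seed=seed, options=options)
    if not result.converged:
        raise EstimationProblem(
            "population fit did not converge; adjust the base table or model"
        )
    pi = np.maximum(result.m_hat, 0.0)
    pi = pi / pi.sum()
    return PopulationModel(cats=base.cats, support=list(result.support), pi=pi)


def thin_zeros(pop: PopulationModel, U: float, seed=None) -> PopulationModel:
    """Force a uniformly random fraction U of support cells to zero, rescale.

    The thinned population need no longer satisfy the CMM; it is used only
    to study convergence under unobservable response patterns.
    """
    if not 0 <= U < 1:
        raise ValueError("U must be in [0, 1)")
    if U == 0:
        return pop
    rng = np.random.default_rng(seed)
    k = math.ceil(U * pop.support_size)
    idx = rng.choice(pop.support_size, size=k, replace=False)
    pi = pop.pi.copy()
    pi[idx] = 0.0
    total = pi.sum()
    if total <= 0:
        raise ValueError("thinning removed all probability mass")
    return PopulationModel(cats=pop.cats, support=list(pop.support), pi=pi / total)


# ---------------------------------------------------------------------------
# study harnesses
# ---------------------------------------------------------------------------


@dataclass
class StudyResult:
    """One experimental cell of a simulation study."""

    study: str
    model: str
    method: str
    J: int
    N: int
    U: float
    replications: int
    converged: int
    convergence_rate: float
    rejection_rate: Optional[float] = None
    rejection_rate_converged: Optional[float] = None
    first_order_failures: int = 0
    second_order_failures: int = 0
    nonconvergence_failures: int = 0
    beta_true: Optional[float] = None
    beta_bias: Optional[float] = None
    beta_sd: Optional[float] = None
    mc_se_rate: Optional[float] = None
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def results_frame(results: Sequence[StudyResult]) -> pd.DataFrame:
    """Tidy one-row-per-cell frame of study results."""
    return pd.DataFrame([r.to_dict() for r in results])


def _make_model(family: str, J: int, criterion=None, item_order=None) -> CMModel:
    family = family.lower()
    if family == "mean":
        return mean_model(J)
    if family == "alpha":
        return alpha_model(J, criterion=0.8 if criterion is None else criterion)
    if family == "hj":
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return hj_model(J, criterion=0.3 if criterion is None else criterion,
                            item_order=item_order)
    raise ModelError(f"unknown model family {family!r}")


def _population_method(J: int, cats_per_item: int = 2) -> str:
    return "ml" if cats_per_item**J <= 4096 else "mael"


def run_type1_study(
    model_family: str,
    J: int,
    N: int,
    replications: int,
    seed: int,
    criterion: float = None,
    alpha_level: float = 0.05,
    base_size: int = BASE_TABLE_SIZE,
    items: Sequence[IRTItem] = None,
    options: SolverOptions = None,
) -> StudyResult:
    """Type-I-error experiment for one (model family, J, N) cell.

    Builds one null population (2PLM base of ``base_size`` patterns, CMM fit
    imposed), then draws ``replications`` multinomial samples of size N and
    fits each by MAEL with a fresh derived seed.  Rejection is p < 0.05 for
    the G² test; non-converged replications count as non-rejections and are
    reported separately.  For the mean model the parameter tracked is the
    overall mean item score.
    """
    ss = np.random.SeedSequence(seed)
    base_seed, pop_seed, rep_root = ss.spawn(3)
    model = _make_model(model_family, J, criterion)
    items = items if items is not None else default_items(J)
    base = twopl_sample(items, base_size, seed=base_seed)
    pop_method = _population_method(J)
    pop = build_population(model, base, method=pop_method, seed=pop_seed,
                           options=options)

    beta_true = None
    if model.name == "mean":
        # overall mean item score of the population
        arr = np.asarray(pop.support, dtype=np.int64)
        beta_true = float((arr * pop.pi[:, None]).sum() / J)

    rejects = converged = first = second = nonconv = 0
    betas = []
    rep_seeds = rep_root.spawn(replications)
    for r in range(replications):
        child = rep_seeds[r]
        sample_seed, fit_seed = child.spawn(2)
        table = pop.sample(N, seed=sample_seed)
        try:
            res = fit(model, table, method="mael",
                      seed=int(fit_seed.generate_state(1)[0] % (2**31)),
                      options=options)
        except FirstOrderProblem:
            first += 1
            continue
        except SecondOrderProblem:
            second += 1
            continue
        except EstimationProblem:
            nonconv += 1
            continue
        if not res.converged:
            nonconv += 1
            continue
        converged += 1
        if res.p_value < alpha_level:
            rejects += 1
        if model.name == "mean" and res.overall_mean is not None:
            betas.append(res.overall_mean)

    rate = rejects / replications
    return StudyResult(
        study="type1",
        model=model_family,
        method="mael",
        J=J,
        N=N,
        U=0.0,
        replications=replications,
        converged=converged,
        convergence_rate=converged / replications,
        rejection_rate=rate,
        rejection_rate_converged=(rejects / converged) if converged else None,
        first_order_failures=first,
        second_order_failures=second,
        nonconvergence_failures=nonconv,
        beta_true=beta_true,
        beta_bias=(float(np.mean(betas)) - beta_true) if betas else None,
        beta_sd=float(np.std(betas, ddof=1)) if len(betas) > 1 else None,
        mc_se_rate=math.sqrt(alpha_level * (1 - alpha_level) / replications),
        seed=seed,
    )


@dataclass
class StudyConfig:
    """Configuration of a convergence study grid (YAML-loadable).

    ``criterion`` may be a number, None (family default), or one of the
    sample-dependent rules "sample+0.2" (alpha: sample value plus 0.2) and
    "sample_mean" (H_j: average of the sample coefficients), resolved per
    replication.
    """

    model: str
    J: int = 4
    N: int = 50
    U_levels: tuple = (0.0, 0.25, 0.75)
    methods: tuple = ("ml", "mel", "mael")
    replications: int = 100
    seed: int = None
    criterion: object = None
    base_size: int = BASE_TABLE_SIZE
    item_a: float = 1.5
    item_b_range: float = 1.5

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory for simulation studies")
        self.U_levels = tuple(float(u) for u in self.U_levels)
        self.methods = tuple(str(m).lower() for m in self.methods)


def load_study_config(source) -> StudyConfig:
    """Load a study config from a YAML path, stream, or string."""
    import os

    if hasattr(source, "read"):
        doc = yaml.safe_load(source)
    elif isinstance(source, (str, os.PathLike)) and os.path.exists(source):
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = yaml.safe_load(str(source))
    if not isinstance(doc, dict):
        raise ValueError("study config must be a mapping")
    known = {f for f in StudyConfig.__dataclass_fields__}
    bad = sorted(set(doc) - known)
    if bad:
        raise ValueError(f"unknown study config key(s): {bad}")
    return StudyConfig(**doc)


def _resolve_criterion(config: StudyConfig, family: str, table: SparseTable):
    crit = config.criterion
    if crit is None or isinstance(crit, (int, float)):
        return crit
    rule = str(crit).lower()
    if rule in ("sample+0.2", "sample_plus_0.2") and family == "alpha":
        return float(np.clip(coefficient_alpha(table) + 0.2, 0.01, 0.97))
    if rule in ("sample_mean", "sample_mean_hj") and family == "hj":
        return float(np.clip(np.mean(item_scalability(table)), 0.01, 0.97))
    raise ValueError(f"criterion rule {crit!r} not valid for model {family!r}")


def run_convergence_study(config: StudyConfig) -> list:
    """Convergence-rate grid over estimation method × zero-cell fraction U.

    One population per (U) level (fresh seeded 2PLM base, CMM imposed, then
    thinned); each replication samples N respondents and attempts a fit with
    every requested method.  Failures are data, classified as first-order,
    second-order or plain non-convergence.
    """
    family = config.model.lower()
    results = []
    for iu, U in enumerate(config.U_levels):
        cell = np.random.SeedSequence((config.seed, iu))
        base_seed, pop_seed, thin_seed, rep_root = cell.spawn(4)
        items = default_items(config.J, a=config.item_a, b_range=config.item_b_range)
        base = twopl_sample(items, config.base_size, seed=base_seed)
        pop_crit = config.criterion
        if pop_crit is not None and not isinstance(pop_crit, (int, float)):
            # population fit uses the base sample's own value: always feasible
            if family == "alpha":
                pop_crit = float(np.clip(coefficient_alpha(base), 0.01, 0.97))
            elif family == "hj":
                pop_crit = float(np.clip(np.mean(item_scalability(base)), 0.01, 0.97))
        model_pop = _make_model(family, config.J, pop_crit)
        pop = build_population(model_pop, base,
                               method=_population_method(config.J), seed=pop_seed)
        pop = thin_zeros(pop, U, seed=thin_seed)
        tallies = {
            m: {"converged": 0, "first": 0, "second": 0, "nonconv": 0}
            for m in config.methods
        }
        rep_seeds = rep_root.spawn(config.replications)
        for r in range(config.replications):
            sample_seed, fit_root = rep_seeds[r].spawn(2)
            table = pop.sample(config.N, seed=sample_seed)
            crit = _resolve_criterion(config, family, table)
            try:
                model = _make_model(family, config.J, crit)
            except ModelError:
                for m in config.methods:
                    tallies[m]["nonconv"] += 1
                continue
            for im, method in enumerate(config.methods):
                fseed = int(
                    np.random.SeedSequence((config.seed, iu, r, im))
                    .generate_state(1)[0] % (2**31)
                )
                try:
                    res = fit(model, table, method=method, seed=fseed)
                except FirstOrderProblem:
                    tallies[method]["first"] += 1
                except SecondOrderProblem:
                    tallies[method]["second"] += 1
                except EstimationProblem:
                    tallies[method]["nonconv"] += 1
                else:
                    if res.converged:
                        tallies[method]["converged"] += 1
                    else:
                        tallies[method]["nonconv"] += 1
        for method in config.methods:
            t = tallies[method]
            results.append(
                StudyResult(
                    study="convergence",
                    model=family,
                    method=method,
                    J=config.J,
                    N=config.N,
                    U=U,
                    replications=config.replications,
                    converged=t["converged"],
                    convergence_rate=t["converged"] / config.replications,
                    first_order_failures=t["first"],
                    second_order_failures=t["second"],
                    nonconvergence_failures=t["nonconv"],
                    seed=config.seed,
                )
            )
    return results
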