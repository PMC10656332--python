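"""Categorical marginal model (CMM) specification and builders.

A CMM constrains a multinomial expected-frequency vector m through its
margins only:  g(m) = Bᵀ f(Aᵀ m) − c = 0,  where Aᵀ picks marginal cells,
f is a smooth link with analytic Jacobian, Bᵀ is a full-row-rank constraint
matrix and c a criterion vector.  The joint dependence structure is left
free, which is the point: hypotheses about means, Cronbach's alpha or Mokken
scalability coefficients are tested without any parametric model for the
item dependencies.

Builders cover the families exercised in the estimation and simulation
harnesses:

* :func:`mean_model` — equality of the J item means (marginal homogeneity of
  the item margins), identity link, J−1 constraints;
* :func:`alpha_model` — Cronbach's alpha equal to a benchmark, 1 constraint;
* :func:`hj_model` — every Mokken item-scalability coefficient H_j equal to
  a lower bound, J constraints (dichotomous items).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

from .contingency import MarginSpec, SparseTable, margin_matrix

__all__ = [
    "CMModel",
    "ModelError",
    "EvaluationError",
    "IdentityLink",
    "AlphaLink",
    "HjLink",
    "CustomLink",
    "mean_model",
    "alpha_model",
    "hj_model",
    "alpha_from_margins",
    "hj_from_margins",
    "coefficient_alpha",
    "item_scalability",
    "evaluate_constraints",
    "beta_from_margins",
    "ConstraintEvaluator",
    "model_to_yaml",
    "model_from_yaml",
]


class ModelError(ValueError):
    """Invalid model specification."""


class EvaluationError(RuntimeError):
    """The link is undefined at the supplied margin values."""

    def __init__(self, message, margin=None):
        super().__init__(message)
        self.margin = margin


# ---------------------------------------------------------------------------
# links: f and its analytic Jacobian, as functions of the raw margin vector t
# ---------------------------------------------------------------------------


class IdentityLink:
    """f(t) = t; constant Jacobian."""

    name = "identity"

    def value(self, t: np.ndarray, N: float) -> np.ndarray:
        return np.asarray(t, dtype=float)

    def jacobian(self, t: np.ndarray, N: float) -> np.ndarray:
        return np.eye(len(t))


class AlphaLink:
    """Cronbach's alpha from first- and second-order marginal moments.

    Margin layout (produced by :func:`alpha_model`): for each item j the
    univariate cells {j = x}, x = 1..c_j−1, then for each pair j < k the
    bivariate cells {j = x, k = y} with x, y >= 1.  Cells at score 0 are
    recovered through complements, so no redundant margin rows are carried.

    With divisor-N moments mu_j = E[X_j], s_j = E[X_j^2], c_jk = E[X_j X_k]:
    sigma_jj = s_j − mu_j², sigma_jk = c_jk − mu_j mu_k, and

        alpha = J/(J−1) · (1 − Σ_j sigma_jj / Σ_{jk} sigma_jk).
    """

    name = "alpha"

    def __init__(self, J: int, cats: Sequence[int]):
        self.J = int(J)
        self.cats = tuple(int(c) for c in cats)
        self.uni_slices = []
        pos = 0
        for c in self.cats:
            self.uni_slices.append(slice(pos, pos + c - 1))
            pos += c - 1
        self.pair_slices = {}
        self.pair_scores = {}
        for j in range(self.J):
            for k in range(j + 1, self.J):
                n = (self.cats[j] - 1) * (self.cats[k] - 1)
                self.pair_slices[(j, k)] = slice(pos, pos + n)
                xy = [
                    x * y
                    for x in range(1, self.cats[j])
                    for y in range(1, self.cats[k])
                ]
                self.pair_scores[(j, k)] = np.array(xy, dtype=float)
                pos += n
        self.dim_in = pos
        self.scores = [np.arange(1, c, dtype=float) for c in self.cats]

    def _moments(self, t, N):
        mu = np.empty(self.J)
        s = np.empty(self.J)
        for j in range(self.J):
            tj = t[self.uni_slices[j]]
            mu[j] = self.scores[j] @ tj / N
            s[j] = (self.scores[j] ** 2) @ tj / N
        c = {}
        for (j, k), sl in self.pair_slices.items():
            c[(j, k)] = self.pair_scores[(j, k)] @ t[sl] / N
        return mu, s, c

    def _totals(self, mu, s, c):
        trace = float(np.sum(s - mu**2))
        off = sum(c[(j, k)] - mu[j] * mu[k] for (j, k) in c)
        total = trace + 2.0 * off
        return trace, total

    def value(self, t, N):
        mu, s, c = self._moments(np.asarray(t, dtype=float), N)
        trace, total = self._totals(mu, s, c)
        if total <= 0:
            raise EvaluationError(
                "total-score variance is not positive; alpha undefined",
                margin="total variance",
            )
        K = self.J / (self.J - 1)
        return np.array([K * (1.0 - trace / total)])

    def jacobian(self, t, N):
        t = np.asarray(t, dtype=float)
        mu, s, c = self._moments(t, N)
        trace, total = self._totals(mu, s, c)
        if total <= 0:
            raise EvaluationError(
                "total-score variance is not positive; alpha undefined",
                margin="total variance",
            )
        K = self.J / (self.J - 1)
        # d alpha = K (trace dTotal − total dTrace) / total², chained to t
        grad = np.zeros(self.dim_in)
        musum = mu.sum()
        for j in range(self.J):
            dtr_dmu = -2.0 * mu[j]
            dtot_dmu = dtr_dmu - 2.0 * (musum - mu[j])
            da_dmu = K * (trace * dtot_dmu - total * dtr_dmu) / total**2
            da_ds = K * (trace - total) / total**2  # dTr/ds = dTot/ds = 1
            sl = self.uni_slices[j]
            grad[sl] += da_dmu * self.scores[j] / N
            grad[sl] += da_ds * (self.scores[j] ** 2) / N
        da_dc = K * (trace * 2.0) / total**2  # dTot/dc_jk = 2
        for (j, k), sl in self.pair_slices.items():
            grad[sl] += da_dc * self.pair_scores[(j, k)] / N
        return grad[np.newaxis, :]


class HjLink:
    """Mokken item-scalability coefficients H_j for dichotomous items.

    Margin layout (produced by :func:`hj_model`): first the univariate cells
    {o_p = 1} for the items in scale order o_1..o_J, then the Guttman-error
    cells {o_p = 0, o_q = 1} for ordered pairs p < q.  With u_p = m^{o_p}_1
    and w_pq the pair cell,

        H_p = 1 − N·(Σ_{q<p} w_qp + Σ_{q>p} w_pq)
                  / (Σ_{q<p} (N−u_q) u_p + Σ_{q>p} (N−u_p) u_q).

    The denominator is the expected count of those cells under independence;
    H_p = 0 at independence, 1 when no pair cell carries mass.
    """

    name = "hj"

    def __init__(self, J: int):
        if J < 2:
            raise ModelError("H_j link needs at least 2 items")
        self.J = int(J)
        self.pair_pos = {}
        pos = self.J
        for p in range(self.J):
            for q in range(p + 1, self.J):
                self.pair_pos[(p, q)] = pos
                pos += 1
        self.dim_in = pos

    def _parts(self, t, N):
        u = np.asarray(t[: self.J], dtype=float)
        if np.any(u <= 0) or np.any(u >= N):
            raise EvaluationError(
                "a univariate margin is at 0 or N; H_j denominator degenerates",
                margin="univariate",
            )
        num = np.zeros(self.J)
        den = np.zeros(self.J)
        for (p, q), pos in self.pair_pos.items():
            w = float(t[pos])
            num[p] += w
            num[q] += w
            den[q] += (N - u[p]) * u[q]
            den[p] += (N - u[p]) * u[q]
        if np.any(den <= 0):
            raise EvaluationError("zero H_j denominator", margin="pairwise")
        return u, num, den

    def value(self, t, N):
        u, num, den = self._parts(np.asarray(t, dtype=float), N)
        return 1.0 - N * num / den

    def jacobian(self, t, N):
        t = np.asarray(t, dtype=float)
        u, num, den = self._parts(t, N)
        Jm = np.zeros((self.J, self.dim_in))
        # pair cells enter num_p and num_q linearly
        for (p, q), pos in self.pair_pos.items():
            Jm[p, pos] = -N / den[p]
            Jm[q, pos] = -N / den[q]
        # univariate margins enter through the denominators only
        dden = np.zeros((self.J, self.J))  # dden[j, i] = d den_j / d u_i
        for (p, q) in self.pair_pos:
            # den_p and den_q both contain (N − u_p)·u_q
            dden[p, p] += -u[q]
            dden[p, q] += N - u[p]
            dden[q, p] += -u[q]
            dden[q, q] += N - u[p]
        for j in range(self.J):
            Jm[j, : self.J] += N * num[j] / den[j] ** 2 * dden[j]
        return Jm


class CustomLink:
    """User-supplied f and Jacobian, both functions of (t, N)."""

    name = "custom"

    def __init__(self, value_fn, jacobian_fn):
        self._value = value_fn
        self._jacobian = jacobian_fn

    def value(self, t, N):
        return np.atleast_1d(np.asarray(self._value(t, N), dtype=float))

    def jacobian(self, t, N):
        return np.atleast_2d(np.asarray(self._jacobian(t, N), dtype=float))


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------


@dataclass
class CMModel:
    """A categorical marginal model g(m) = Bᵀ f(Aᵀ m) − criterion = 0.

    ``margins`` are the rows of Aᵀ; ``collapse`` (optional) linearly maps raw
    margin values to the link inputs (used to form score-weighted mean
    numerators for polytomous items; identity when None).  ``Z``, when
    present, is the design matrix whose orthogonal complement is B, giving
    the parameter β = (ZᵀZ)⁻¹ Zᵀ f(Aᵀm).
    """

    name: str
    cats: tuple
    margins: list
    link: object
    B_t: np.ndarray
    criterion: np.ndarray
    Z: Optional[np.ndarray] = None
    collapse: Optional[np.ndarray] = None
    item_order: Optional[tuple] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.cats = tuple(int(c) for c in self.cats)
        self.B_t = np.atleast_2d(np.asarray(self.B_t, dtype=float))
        self.criterion = np.atleast_1d(np.asarray(self.criterion, dtype=float))
        if self.B_t.shape[0] != len(self.criterion):
            raise ModelError("criterion length does not match constraint count")
        if np.linalg.matrix_rank(self.B_t) < self.B_t.shape[0] and self.B_t.size:
            raise ModelError("Bᵀ does not have full row rank")
        for spec in self.margins:
            spec.validate(self.cats)
        if self.Z is not None:
            self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
            if self.Z.shape[0] == 1 and self.B_t.shape[1] > 1:
                self.Z = self.Z.T
            if np.linalg.matrix_rank(self.Z) < self.Z.shape[1]:
                raise ModelError("Z is not of full column rank")

    @property
    def J(self) -> int:
        return len(self.cats)

    @property
    def D(self) -> int:
        """Number of constraints = model degrees of freedom."""
        return self.B_t.shape[0]

    def evaluator(self, support) -> "ConstraintEvaluator":
        return ConstraintEvaluator(self, support)


class ConstraintEvaluator:
    """Binds a model to a support, caching the incidence matrix Aᵀ."""

    def __init__(self, model: CMModel, support):
        self.model = model
        if isinstance(support, SparseTable):
            arr = support.pattern_array()
        else:
            arr = np.asarray(support, dtype=np.int64)
        self.pattern_array = arr
        A = margin_matrix(model.margins, arr)
        self.A = model.collapse @ A if model.collapse is not None else A

    @property
    def support_size(self) -> int:
        return self.A.shape[1]

    def margins(self, m) -> np.ndarray:
        """Link inputs t = (collapse·)Aᵀ m."""
        return self.A @ np.asarray(m, dtype=float)

    def g(self, m, N) -> np.ndarray:
        t = self.margins(m)
        return self.model.B_t @ self.model.link.value(t, N) - self.model.criterion

    def g_and_G(self, m, N):
        """Constraint values and Jacobian G = Bᵀ (∂f/∂t) Aᵀ on the support."""
        t = self.margins(m)
        link = self.model.link
        g = self.model.B_t @ link.value(t, N) - self.model.criterion
        G = self.model.B_t @ link.jacobian(t, N) @ self.A
        return g, G


def evaluate_constraints(model: CMModel, support, m, N: float):
    """Evaluate (g, G) for weights ``m`` over a support (table or patterns)."""
    ev = model.evaluator(support)
    m = np.asarray(m, dtype=float)
    if np.any(m < 0):
        raise ModelError("negative weights")
    return ev.g_and_G(m, N)


def beta_from_margins(model: CMModel, support, m, N: float = None) -> np.ndarray:
    """β = (ZᵀZ)⁻¹ Zᵀ f(Aᵀm) for models carrying a design matrix Z."""
    if model.Z is None:
        raise ModelError(f"model {model.name!r} is constraint-only (no Z)")
    ev = model.evaluator(support)
    if N is None:
        N = float(np.sum(m))
    f = model.link.value(ev.margins(m), N)
    Z = model.Z
    return np.linalg.solve(Z.T @ Z, Z.T @ f)


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------


def _successive_differences(J: int) -> np.ndarray:
    B = np.zeros((J - 1, J))
    for r in range(J - 1):
        B[r, r] = 1.0
        B[r, r + 1] = -1.0
    return B


def mean_model(J: int, cats: Sequence[int] = None) -> CMModel:
    """Equality of the J item means (marginal homogeneity of item margins).

    For binary items the mean numerator is the single margin cell {j = 1};
    for polytomous items it is the score-weighted sum over {j = x}, carried
    by the ``collapse`` matrix.  f is the identity on the J numerators,
    Bᵀ the successive-difference matrix, so D = J − 1.  Z is the normalized
    constant column, giving β = Σ_j m^j_1 / √J.
    """
    if J < 2:
        raise ModelError("mean model needs at least 2 variables")
    cats = tuple(int(c) for c in cats) if cats is not None else (2,) * J
    if len(cats) != J:
        raise ModelError("cats length does not match J")
    margins, collapse_rows = [], []
    pos = 0
    for j, c in enumerate(cats):
        for x in range(1, c):
            margins.append(MarginSpec((j,), (x,)))
        collapse_rows.append((pos, c - 1))
        pos += c - 1
    collapse = np.zeros((J, pos))
    for j, (start, width) in enumerate(collapse_rows):
        collapse[j, start : start + width] = np.arange(1, width + 1)
    if all(c == 2 for c in cats):
        collapse = None  # identity: margins are already the numerators
    return CMModel(
        name="mean",
        cats=cats,
        margins=margins,
        link=IdentityLink(),
        B_t=_successive_differences(J),
        criterion=np.zeros(J - 1),
        Z=np.full((J, 1), 1.0 / np.sqrt(J)),
        collapse=collapse,
    )


def alpha_model(J: int, cats: Sequence[int] = None, criterion: float = 0.8) -> CMModel:
    """Cronbach's alpha equal to a benchmark: α(m) − criterion = 0, D = 1."""
    if J < 2:
        raise ModelError("alpha model needs at least 2 items")
    if not 0 < criterion < 1:
        raise ModelError(f"alpha criterion {criterion} outside (0, 1)")
    cats = tuple(int(c) for c in cats) if cats is not None else (2,) * J
    if len(cats) != J:
        raise ModelError("cats length does not match J")
    link = AlphaLink(J, cats)
    margins = []
    for j, c in enumerate(cats):
        for x in range(1, c):
            margins.append(MarginSpec((j,), (x,)))
    for j in range(J):
        for k in range(j + 1, J):
            for x in range(1, cats[j]):
                for y in range(1, cats[k]):
                    margins.append(MarginSpec((j, k), (x, y)))
    return CMModel(
        name="alpha",
        cats=cats,
        margins=margins,
        link=link,
        B_t=np.eye(1),
        criterion=np.array([criterion]),
        meta={"benchmark": float(criterion)},
    )


def hj_model(
    J: int, criterion: float = 0.3, item_order: Sequence[int] = None
) -> CMModel:
    """All item-scalability coefficients equal to a lower bound c.

    Items are dichotomous.  ``item_order`` is the scale order used in the
    H_j definition; the default is the order the items are given, which
    reproduces sample coefficients computed on tables in their printed item
    order.  Passing an order sorted by ascending sample popularity gives the
    textbook convention.  For J = 2 the two coefficients coincide, so the
    duplicate constraint is collapsed (D = 1) with a warning.
    """
    if J < 2:
        raise ModelError("H_j model needs at least 2 items")
    if not 0 < criterion < 1:
        raise ModelError(f"H_j criterion {criterion} outside (0, 1)")
    cats = (2,) * J
    order = tuple(range(J)) if item_order is None else tuple(int(i) for i in item_order)
    if sorted(order) != list(range(J)):
        raise ModelError(f"item_order {order} is not a permutation of 0..{J - 1}")
    link = HjLink(J)
    margins = [MarginSpec((o,), (1,)) for o in order]
    for p in range(J):
        for q in range(p + 1, J):
            a, b = order[p], order[q]
            lo, hi = min(a, b), max(a, b)
            # Guttman-error cell {o_p = 0, o_q = 1}, variables stored sorted
            vals = (0, 1) if a < b else (1, 0)
            margins.append(MarginSpec((lo, hi), vals))
    if J == 2:
        warnings.warn(
            "H_1 and H_2 coincide for two items; duplicate constraint collapsed, D = 1",
            stacklevel=2,
        )
        B_t = np.array([[1.0, 0.0]])
        crit = np.array([criterion])
    else:
        B_t = np.eye(J)
        crit = np.full(J, criterion)
    return CMModel(
        name="hj",
        cats=cats,
        margins=margins,
        link=link,
        B_t=B_t,
        criterion=crit,
        item_order=order,
        meta={"lower_bound": float(criterion)},
    )


# ---------------------------------------------------------------------------
# coefficient helpers (margin-vector and table front doors)
# ---------------------------------------------------------------------------


def alpha_from_margins(margin_values, J: int, cats: Sequence[int], N: float) -> float:
    """Cronbach's alpha from the margin layout of :func:`alpha_model`."""
    cats = tuple(int(c) for c in cats) if cats is not None else (2,) * J
    return float(AlphaLink(J, cats).value(np.asarray(margin_values, float), N)[0])


def hj_from_margins(margin_values, J: int, N: float, item_order=None) -> np.ndarray:
    """H_j vector from the margin layout of :func:`hj_model`.

    ``item_order`` fixes the interpretation of the layout positions; the
    values returned are in item (not position) order.
    """
    order = tuple(range(J)) if item_order is None else tuple(item_order)
    h_by_pos = HjLink(J).value(np.asarray(margin_values, float), N)
    out = np.empty(J)
    for pos, item in enumerate(order):
        out[item] = h_by_pos[pos]
    return out


def _margin_values(model: CMModel, table: SparseTable) -> np.ndarray:
    A = margin_matrix(model.margins, table.pattern_array())
    return A @ table.counts


def coefficient_alpha(table: SparseTable) -> float:
    """Sample Cronbach's alpha of a table (divisor-N covariances)."""
    model = alpha_model(table.J, table.cats, criterion=0.5)
    return alpha_from_margins(_margin_values(model, table), table.J, table.cats, table.N)


def item_scalability(table: SparseTable, item_order=None) -> np.ndarray:
    """Sample Mokken H_j coefficients of a dichotomous-item table."""
    if any(c != 2 for c in table.cats):
        raise ModelError("item-scalability coefficients require dichotomous items")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # J=2 duplicate-constraint note
        model = hj_model(table.J, criterion=0.5, item_order=item_order)
    t = _margin_values(model, table)
    return hj_from_margins(t, table.J, table.N, item_order=model.item_order)


# ---------------------------------------------------------------------------
# YAML serialization
# ---------------------------------------------------------------------------


def model_to_yaml(model: CMModel, path=None) -> str:
    """Serialize a builder-produced (or identity-link custom) model."""
    doc = {
        "name": model.name,
        "link": model.link.name,
        "J": model.J,
        "cats": list(model.cats),
    }
    if model.name == "alpha":
        doc["criterion"] = float(model.criterion[0])
    elif model.name == "hj":
        doc["criterion"] = float(model.criterion[0])
        doc["item_order"] = list(model.item_order)
    elif model.name != "mean":
        if model.link.name != "identity":
            raise ModelError("only identity-link custom models serialize to YAML")
        doc["B_t"] = model.B_t.tolist()
        doc["criterion"] = model.criterion.tolist()
        doc["margins"] = [
            {"variables": list(s.variables), "values": list(s.values)}
            for s in model.margins
        ]
        if model.Z is not None:
            doc["Z"] = model.Z.tolist()
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def model_from_yaml(source) -> CMModel:
    if hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        text = str(source)
        if "\n" not in text and text.endswith((".yml", ".yaml")):
            with open(text) as fh:
                doc = yaml.safe_load(fh)
        else:
            doc = yaml.safe_load(text)
    name, J = doc["name"], int(doc["J"])
    cats = tuple(doc.get("cats", [2] * J))
    if name == "mean":
        return mean_model(J, cats)
    if name == "alpha":
        return alpha_model(J, cats, float(doc["criterion"]))
    if name == "hj":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return hj_model(J, float(doc["criterion"]), doc.get("item_order"))
    margins = [
        MarginSpec(tuple(m["variables"]), tuple(m["values"])) for m in doc["margins"]
    ]
    return CMModel(
        name=name,
        cats=cats,
        margins=margins,
        link=IdentityLink(),
        B_t=np.array(doc["B_t"], dtype=float),
        criterion=np.array(doc["criterion"], dtype=float),
        Z=np.array(doc["Z"], dtype=float) if "Z" in doc else None,
    )
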