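"""Penalized additive models for reading-time analysis.

Implements the two benchmark-property models used throughout the analyses:

* a *surprisal* model
  ``RT ~ s(surp) + s(surp_prev) + te(freq, len) + te(freq_prev, len_prev)
  + re(subj) + re(subj, surp) + re(subj, freq*len)``
* a *frequency/length* model
  ``RT ~ s(surp) + s(surp_prev) + s(freq) + s(freq_prev) + s(len) + s(len_prev)
  + re(subj) + re(subj, surp) + re(subj, freq) + re(subj, len)``

Univariate smooths are cubic regression splines (value-at-knot
parameterization, second-derivative penalty, knots at covariate quantiles),
tensor-product smooths are Kronecker products of marginal spline bases with
one penalty per margin, and participant terms are ridge-penalized indicator
(or indicator-times-covariate) columns, i.e. Gaussian random effects.

Smoothing parameters are selected by restricted maximum likelihood using
Fellner-Schall updates; generalized cross-validation is available as an
alternative criterion. The fitter is linear-Gaussian throughout, which is the
setting all reading-time analyses here operate in.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

__all__ = [
    "SmoothTerm",
    "TensorTerm",
    "PolyTerm",
    "RandomIntercept",
    "RandomSlope",
    "ModelSpec",
    "surprisal_model_spec",
    "frequency_model_spec",
    "quadratic_test_spec",
    "build_design",
    "fit_penalized",
    "fit_model",
    "superlinearity_test",
    "bootstrap_ci",
    "FitResult",
    "QuadraticTestResult",
    "ConvergenceError",
    "significance_stars",
]

LAMBDA_MIN = 1e-9
LAMBDA_MAX = 1e11


class ConvergenceError(RuntimeError):
    """Smoothing-parameter iteration failed to converge.

    Carries the last criterion value in ``last_criterion``.
    """

    def __init__(self, msg: str, last_criterion: float):
        super().__init__(msg)
        self.last_criterion = last_criterion


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "(.)"


# ---------------------------------------------------------------------------
# model terms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SmoothTerm:
    """Univariate cubic regression spline s(var) with basis dimension k."""

    var: str
    k: int = 20

    @property
    def label(self) -> str:
        return f"s({self.var})"


@dataclass(frozen=True)
class TensorTerm:
    """Tensor-product smooth te(var1, var2) with marginal dimensions k1, k2."""

    var1: str
    var2: str
    k1: int = 5
    k2: int = 5

    @property
    def label(self) -> str:
        return f"te({self.var1},{self.var2})"


@dataclass(frozen=True)
class PolyTerm:
    """Unpenalized parametric polynomial in one covariate (no intercept).

    Columns are z, z**2, ..., z**degree with z the standardized covariate.
    Used by the superlinearity test, where a smooth is replaced by a linear
    plus quadratic term.
    """

    var: str
    degree: int = 2

    @property
    def label(self) -> str:
        return f"poly({self.var},{self.degree})"


@dataclass(frozen=True)
class RandomIntercept:
    """Per-group intercept with ridge (i.i.d. Gaussian) penalty."""

    group: str = "participant_id"

    @property
    def label(self) -> str:
        return f"re({self.group})"


@dataclass(frozen=True)
class RandomSlope:
    """Per-group slope on a covariate (or product of covariates).

    ``degree`` > 1 gives a random slope on z**degree (standardized covariate),
    as needed for the random quadratic slope in the superlinearity test.
    """

    group: str = "participant_id"
    vars: tuple[str, ...] = ()
    degree: int = 1

    @property
    def label(self) -> str:
        v = "*".join(self.vars)
        suffix = f"^{self.degree}" if self.degree != 1 else ""
        return f"re({self.group},{v}{suffix})"


Term = SmoothTerm | TensorTerm | PolyTerm | RandomIntercept | RandomSlope


@dataclass(frozen=True)
class ModelSpec:
    """Response plus ordered term list for one additive model."""

    response: str
    terms: tuple[Term, ...]
    name: str = "custom"


def _re_terms_eq1(group: str) -> tuple[Term, ...]:
    return (
        RandomIntercept(group),
        RandomSlope(group, ("surp",)),
        RandomSlope(group, ("freq", "len")),
    )


def _re_terms_eq2(group: str) -> tuple[Term, ...]:
    return (
        RandomIntercept(group),
        RandomSlope(group, ("surp",)),
        RandomSlope(group, ("freq",)),
        RandomSlope(group, ("len",)),
    )


def surprisal_model_spec(
    measure: str = "tf",
    k: int = 20,
    include_re: bool = True,
    group: str = "participant_id",
) -> ModelSpec:
    """The surprisal-curve model: spline terms for current and previous-word
    surprisal, tensor smooths for (frequency, length) of the current and
    previous word, plus participant random effects."""
    terms: tuple[Term, ...] = (
        SmoothTerm("surp", k),
        SmoothTerm("prev_surp", k),
        TensorTerm("freq", "len"),
        TensorTerm("prev_freq", "prev_len"),
    )
    if include_re:
        terms = terms + _re_terms_eq1(group)
    return ModelSpec(measure, terms, name="surprisal_model")


def frequency_model_spec(
    measure: str = "tf",
    k: int = 20,
    k_len: int = 10,
    include_re: bool = True,
    group: str = "participant_id",
) -> ModelSpec:
    """The frequency/length-curve model: univariate splines for surprisal,
    frequency and length of the current and previous word, plus participant
    random effects."""
    terms: tuple[Term, ...] = (
        SmoothTerm("surp", k),
        SmoothTerm("prev_surp", k),
        SmoothTerm("freq", k),
        SmoothTerm("prev_freq", k),
        SmoothTerm("len", k_len),
        SmoothTerm("prev_len", k_len),
    )
    if include_re:
        terms = terms + _re_terms_eq2(group)
    return ModelSpec(measure, terms, name="frequency_model")


def quadratic_test_spec(
    property: str,
    measure: str = "tf",
    k: int = 20,
    include_re: bool = True,
    group: str = "participant_id",
) -> ModelSpec:
    """Model for the superlinearity test: the current-word smooth of
    ``property`` is replaced by linear + quadratic terms and a per-participant
    random slope on the quadratic term; every other term is unchanged."""
    base = (
        surprisal_model_spec(measure, k, include_re, group)
        if property == "surp"
        else frequency_model_spec(measure, k, include_re=include_re, group=group)
    )
    new_terms: list[Term] = []
    for t in base.terms:
        if isinstance(t, SmoothTerm) and t.var == property:
            new_terms.append(PolyTerm(property, 2))
        else:
            new_terms.append(t)
    if property not in [t.var for t in base.terms if isinstance(t, SmoothTerm)]:
        raise ValueError(
            f"property {property!r} has no univariate smooth in {base.name}; "
            "the superlinearity test replaces a univariate smooth"
        )
    if include_re:
        new_terms.append(RandomSlope(group, (property,), degree=2))
    return ModelSpec(measure, tuple(new_terms), name=f"quadratic_test_{property}")


# ---------------------------------------------------------------------------
# cubic regression spline basis
# ---------------------------------------------------------------------------


def crs_knots(x: np.ndarray, k: int) -> np.ndarray:
    """Knots at equally spaced quantiles of the unique covariate values.

    If fewer than ``k`` distinct values exist, ``k`` is reduced (with a
    warning); fewer than 3 distinct values is an error.
    """
    ux = np.unique(np.asarray(x, dtype=float))
    if ux.size < 2 or ux[-1] - ux[0] <= 0:
        raise ValueError("zero-variance covariate: cannot place spline knots")
    if ux.size < k:
        warnings.warn(
            f"covariate has {ux.size} distinct values < k={k}; reducing basis dimension",
            stacklevel=2,
        )
        k = ux.size
    if k < 3:
        raise ValueError("need at least 3 distinct covariate values for a cubic spline")
    knots = np.quantile(ux, np.linspace(0.0, 1.0, k))
    knots = np.unique(knots)
    return knots


def _crs_F_and_penalty(knots: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """F maps values-at-knots to second derivatives at knots (natural spline);
    the penalty is the integrated squared second derivative D' B^{-1} D."""
    k = len(knots)
    h = np.diff(knots)
    D = np.zeros((k - 2, k))
    B = np.zeros((k - 2, k - 2))
    for i in range(k - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i < k - 3:
            B[i, i + 1] = h[i + 1] / 6.0
            B[i + 1, i] = h[i + 1] / 6.0
    BinvD = linalg.solve(B, D, assume_a="pos")
    F = np.zeros((k, k))
    F[1:-1] = BinvD
    S = D.T @ BinvD
    S = 0.5 * (S + S.T)
    return F, S


def crs_basis(x: np.ndarray, knots: np.ndarray, F: np.ndarray | None = None) -> np.ndarray:
    """Evaluate the cubic-regression-spline basis at ``x``.

    Values outside the knot range are evaluated by linear extension of the
    boundary segment (value and first derivative at the boundary knot).
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    k = len(knots)
    if F is None:
        F, _ = _crs_F_and_penalty(knots)
    h = np.diff(knots)
    lo, hi = knots[0], knots[-1]
    xc = np.clip(x, lo, hi)
    j = np.clip(np.searchsorted(knots, xc, side="right") - 1, 0, k - 2)
    hj = h[j]
    t_hi = knots[j + 1] - xc
    t_lo = xc - knots[j]
    a_m = t_hi / hj
    a_p = t_lo / hj
    c_m = (t_hi**3 / hj - hj * t_hi) / 6.0
    c_p = (t_lo**3 / hj - hj * t_lo) / 6.0
    X = np.zeros((x.size, k))
    rows = np.arange(x.size)
    np.add.at(X, (rows, j), a_m)
    np.add.at(X, (rows, j + 1), a_p)
    X += c_m[:, None] * F[j] + c_p[:, None] * F[j + 1]
    # linear extension outside the knot range
    out_lo = x < lo
    out_hi = x > hi
    if out_lo.any() or out_hi.any():
        # derivative rows at the clipped (boundary) point
        dc_m = (-3.0 * t_hi**2 / hj + hj) / 6.0
        dc_p = (3.0 * t_lo**2 / hj - hj) / 6.0
        dX = np.zeros_like(X)
        np.add.at(dX, (rows, j), -1.0 / hj)
        np.add.at(dX, (rows, j + 1), 1.0 / hj)
        dX += dc_m[:, None] * F[j] + dc_p[:, None] * F[j + 1]
        delta = np.where(out_lo, x - lo, np.where(out_hi, x - hi, 0.0))
        X = X + delta[:, None] * dX
    return X


def _constraint_nullspace(col_means: np.ndarray) -> np.ndarray:
    """Z with columns spanning the null space of the sum-to-zero constraint."""
    c = col_means.reshape(-1, 1)
    q, _ = np.linalg.qr(c, mode="complete")
    return q[:, 1:]


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


@dataclass
class Block:
    term: Term
    sl: slice
    penalties: list[np.ndarray] = field(default_factory=list)
    penalty_ranks: list[int] = field(default_factory=list)
    penalty_logdets: list[float] = field(default_factory=list)
    combined_rank: int = 0
    null_dim: int = 0
    # evaluation metadata
    knots: np.ndarray | None = None
    knots2: np.ndarray | None = None
    Z: np.ndarray | None = None
    levels: list | None = None
    center: float = 0.0
    scale: float = 1.0

    @property
    def size(self) -> int:
        return self.sl.stop - self.sl.start


@dataclass
class Design:
    spec: ModelSpec
    X: np.ndarray
    blocks: list[Block]
    n: int
    p: int
    n_parametric: int  # intercept + unpenalized parametric columns

    @property
    def null_space_dim(self) -> int:
        return self.n_parametric + sum(b.null_dim for b in self.blocks)


def _positive_eig_stats(S: np.ndarray) -> tuple[int, float]:
    ev = np.linalg.eigvalsh(S)
    tol = max(S.shape[0], 1) * np.finfo(float).eps * max(ev.max(), 1.0)
    pos = ev[ev > tol]
    return pos.size, float(np.sum(np.log(pos)))


def build_design(spec: ModelSpec, data: pd.DataFrame) -> Design:
    """Assemble the model matrix and penalty blocks for ``spec`` on ``data``.

    Column 0 is the intercept. Each spline block carries a sum-to-zero
    constraint absorbed by reparameterization.
    """
    n = len(data)
    for t in spec.terms:
        for v in _term_vars(t):
            if v not in data.columns:
                raise KeyError(f"model variable {v!r} missing from data")
            vals = np.asarray(data[v], dtype=float)
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"non-finite values in covariate {v!r}")
    cols: list[np.ndarray] = [np.ones((n, 1))]
    blocks: list[Block] = []
    pos = 1
    n_parametric = 1
    for term in spec.terms:
        if isinstance(term, SmoothTerm):
            x = np.asarray(data[term.var], dtype=float)
            knots = crs_knots(x, term.k)
            F, S = _crs_F_and_penalty(knots)
            Xb = crs_basis(x, knots, F)
            Z = _constraint_nullspace(Xb.mean(axis=0))
            Xb = Xb @ Z
            Sc = Z.T @ S @ Z
            Sc = 0.5 * (Sc + Sc.T)
            rank, logdet = _positive_eig_stats(Sc)
            b = Block(
                term,
                slice(pos, pos + Xb.shape[1]),
                penalties=[Sc],
                penalty_ranks=[rank],
                penalty_logdets=[logdet],
                combined_rank=rank,
                null_dim=Xb.shape[1] - rank,
                knots=knots,
                Z=Z,
            )
        elif isinstance(term, TensorTerm):
            x1 = np.asarray(data[term.var1], dtype=float)
            x2 = np.asarray(data[term.var2], dtype=float)
            kn1 = crs_knots(x1, term.k1)
            kn2 = crs_knots(x2, term.k2)
            F1, S1 = _crs_F_and_penalty(kn1)
            F2, S2 = _crs_F_and_penalty(kn2)
            X1 = crs_basis(x1, kn1, F1)
            X2 = crs_basis(x2, kn2, F2)
            k1, k2 = X1.shape[1], X2.shape[1]
            Xb = (X1[:, :, None] * X2[:, None, :]).reshape(n, k1 * k2)
            P1 = np.kron(S1, np.eye(k2))
            P2 = np.kron(np.eye(k1), S2)
            Z = _constraint_nullspace(Xb.mean(axis=0))
            Xb = Xb @ Z
            P1 = Z.T @ P1 @ Z
            P2 = Z.T @ P2 @ Z
            P1 = 0.5 * (P1 + P1.T)
            P2 = 0.5 * (P2 + P2.T)
            r1, ld1 = _positive_eig_stats(P1)
            r2, ld2 = _positive_eig_stats(P2)
            rank_sum, _ = _positive_eig_stats(P1 + P2)
            b = Block(
                term,
                slice(pos, pos + Xb.shape[1]),
                penalties=[P1, P2],
                penalty_ranks=[r1, r2],
                penalty_logdets=[ld1, ld2],
                combined_rank=rank_sum,
                null_dim=Xb.shape[1] - rank_sum,
                knots=kn1,
                knots2=kn2,
                Z=Z,
            )
        elif isinstance(term, PolyTerm):
            x = np.asarray(data[term.var], dtype=float)
            m, s = float(x.mean()), float(x.std())
            if s <= 0:
                raise ValueError(f"zero-variance covariate {term.var!r}")
            z = (x - m) / s
            Xb = np.column_stack([z**d for d in range(1, term.degree + 1)])
            b = Block(term, slice(pos, pos + Xb.shape[1]), center=m, scale=s)
            n_parametric += Xb.shape[1]
        elif isinstance(term, RandomIntercept):
            levels, idx = _levels(data[term.group])
            Xb = np.zeros((n, len(levels)))
            Xb[np.arange(n), idx] = 1.0
            b = _ridge_block(term, pos, Xb.shape[1], levels)
        elif isinstance(term, RandomSlope):
            levels, idx = _levels(data[term.group])
            v = np.ones(n)
            for name in term.vars:
                v = v * np.asarray(data[name], dtype=float)
            m, s = float(v.mean()), float(v.std())
            if s <= 0:
                raise ValueError(f"zero-variance covariate product {term.vars!r}")
            z = ((v - m) / s) ** term.degree
            Xb = np.zeros((n, len(levels)))
            Xb[np.arange(n), idx] = z
            b = _ridge_block(term, pos, Xb.shape[1], levels)
            b.center, b.scale = m, s
        else:  # pragma: no cover
            raise TypeError(f"unknown term type {term!r}")
        cols.append(Xb)
        pos += Xb.shape[1]
        blocks.append(b)
    X = np.hstack(cols)
    return Design(spec=spec, X=X, blocks=blocks, n=n, p=X.shape[1], n_parametric=n_parametric)


def _term_vars(t: Term) -> tuple[str, ...]:
    if isinstance(t, SmoothTerm):
        return (t.var,)
    if isinstance(t, TensorTerm):
        return (t.var1, t.var2)
    if isinstance(t, PolyTerm):
        return (t.var,)
    if isinstance(t, RandomSlope):
        return t.vars
    return ()


def _levels(series: pd.Series) -> tuple[list, np.ndarray]:
    levels, idx = np.unique(np.asarray(series), return_inverse=True)
    return list(levels), idx


def _ridge_block(term: Term, pos: int, dim: int, levels: list) -> Block:
    return Block(
        term,
        slice(pos, pos + dim),
        penalties=[np.eye(dim)],
        penalty_ranks=[dim],
        penalty_logdets=[0.0],
        combined_rank=dim,
        null_dim=0,
        levels=levels,
    )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """A fitted additive model.

    ``partial_effect(var, x)`` evaluates the centered contribution (ms) of the
    univariate term in ``var``; ``anchor="zero"`` subtracts the value at 0 so
    a linear effect of slope b evaluates to b*x, the convention used by the
    per-word slowdown statistic.
    """

    spec_name: str
    response: str
    beta: np.ndarray
    intercept: float
    lambdas: dict[str, list[float]]
    edf: dict[str, float]
    edf_total: float
    sigma2: float  # REML variance estimate
    scale: float  # RSS / (n - edf) used for Wald tests
    criterion: str
    criterion_value: float
    converged: bool
    n: int
    blocks: list[Block]
    cov: np.ndarray | None = None  # Bayesian posterior covariance of beta
    fitted: np.ndarray | None = None

    # -- evaluation ---------------------------------------------------------

    def _find_block(self, var: str) -> Block:
        matches = [
            b
            for b in self.blocks
            if (isinstance(b.term, SmoothTerm) and b.term.var == var)
            or (isinstance(b.term, PolyTerm) and b.term.var == var)
        ]
        if not matches:
            raise KeyError(f"no univariate term for variable {var!r}")
        return matches[0]

    def partial_effect(self, var: str, x, anchor: str | None = None) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        b = self._find_block(var)
        beta_b = self.beta[b.sl]
        if isinstance(b.term, SmoothTerm):
            vals = crs_basis(x, b.knots) @ b.Z @ beta_b
            if anchor == "zero":
                vals = vals - (crs_basis(np.zeros(1), b.knots) @ b.Z @ beta_b)[0]
        else:  # PolyTerm
            z = (x - b.center) / b.scale
            vals = sum(beta_b[d - 1] * z**d for d in range(1, b.term.degree + 1))
            if anchor == "zero":
                z0 = (0.0 - b.center) / b.scale
                vals = vals - sum(
                    beta_b[d - 1] * z0**d for d in range(1, b.term.degree + 1)
                )
        return vals

    def tensor_effect(self, var1: str, var2: str, x1, x2) -> np.ndarray:
        for b in self.blocks:
            if isinstance(b.term, TensorTerm) and (b.term.var1, b.term.var2) == (var1, var2):
                X1 = crs_basis(np.atleast_1d(x1), b.knots)
                X2 = crs_basis(np.atleast_1d(x2), b.knots2)
                n = X1.shape[0]
                Xb = (X1[:, :, None] * X2[:, None, :]).reshape(n, -1) @ b.Z
                return Xb @ self.beta[b.sl]
        raise KeyError(f"no tensor term te({var1},{var2})")

    def term_labels(self) -> list[str]:
        return [b.term.label for b in self.blocks]

    # -- inference helpers --------------------------------------------------

    def wald_coefficient(self, var: str, degree: int) -> tuple[float, float, float]:
        """(estimate, se, p) for one polynomial coefficient, on the raw
        covariate scale (ms per unit**degree)."""
        if self.cov is None:
            raise ValueError("fit was run without covariance tracking")
        b = self._find_block(var)
        if not isinstance(b.term, PolyTerm):
            raise TypeError(f"{var!r} is a smooth term; Wald test needs a PolyTerm")
        j = b.sl.start + (degree - 1)
        est = self.beta[j] / b.scale**degree
        se = float(np.sqrt(self.cov[j, j])) / b.scale**degree
        z = est / se
        p = 2.0 * stats.norm.sf(abs(z))
        return float(est), se, float(p)

    def smooth_term_test(self, var: str) -> tuple[float, float, float]:
        """Approximate Wald test that a whole smooth term is zero.

        Returns (statistic, edf, p); the statistic is beta' V^- beta on the
        term's block and the reference distribution is chi-square with the
        term's effective degrees of freedom (rounded up).
        """
        if self.cov is None:
            raise ValueError("fit was run without covariance tracking")
        b = self._find_block(var)
        beta_b = self.beta[b.sl]
        Vb = self.cov[b.sl, b.sl]
        stat = float(beta_b @ np.linalg.pinv(Vb, rcond=1e-10) @ beta_b)
        df = max(min(float(np.ceil(self.edf[b.term.label])), b.size), 1.0)
        p = float(stats.chi2.sf(stat, df))
        return stat, df, p

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "spec_name": self.spec_name,
            "response": self.response,
            "beta": self.beta.tolist(),
            "intercept": self.intercept,
            "lambdas": self.lambdas,
            "edf": self.edf,
            "edf_total": self.edf_total,
            "sigma2": self.sigma2,
            "scale": self.scale,
            "criterion": self.criterion,
            "criterion_value": self.criterion_value,
            "converged": self.converged,
            "n": self.n,
            "blocks": [
                {
                    "term_kind": type(b.term).__name__,
                    "term": _term_to_dict(b.term),
                    "start": b.sl.start,
                    "stop": b.sl.stop,
                    "knots": None if b.knots is None else b.knots.tolist(),
                    "knots2": None if b.knots2 is None else b.knots2.tolist(),
                    "Z": None if b.Z is None else b.Z.tolist(),
                    "levels": None
                    if b.levels is None
                    else [str(v) for v in b.levels],
                    "center": b.center,
                    "scale": b.scale,
                }
                for b in self.blocks
            ],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, s: str) -> "FitResult":
        d = json.loads(s)
        kinds = {
            "SmoothTerm": SmoothTerm,
            "TensorTerm": TensorTerm,
            "PolyTerm": PolyTerm,
            "RandomIntercept": RandomIntercept,
            "RandomSlope": RandomSlope,
        }
        blocks = []
        for bd in d["blocks"]:
            term = kinds[bd["term_kind"]](**bd["term"])
            blocks.append(
                Block(
                    term,
                    slice(bd["start"], bd["stop"]),
                    knots=None if bd["knots"] is None else np.array(bd["knots"]),
                    knots2=None if bd["knots2"] is None else np.array(bd["knots2"]),
                    Z=None if bd["Z"] is None else np.array(bd["Z"]),
                    levels=bd["levels"],
                    center=bd["center"],
                    scale=bd["scale"],
                )
            )
        return cls(
            spec_name=d["spec_name"],
            response=d["response"],
            beta=np.array(d["beta"]),
            intercept=d["intercept"],
            lambdas=d["lambdas"],
            edf=d["edf"],
            edf_total=d["edf_total"],
            sigma2=d["sigma2"],
            scale=d["scale"],
            criterion=d["criterion"],
            criterion_value=d["criterion_value"],
            converged=d["converged"],
            n=d["n"],
            blocks=blocks,
        )


def _term_to_dict(t: Term) -> dict:
    if isinstance(t, SmoothTerm):
        return {"var": t.var, "k": t.k}
    if isinstance(t, TensorTerm):
        return {"var1": t.var1, "var2": t.var2, "k1": t.k1, "k2": t.k2}
    if isinstance(t, PolyTerm):
        return {"var": t.var, "degree": t.degree}
    if isinstance(t, RandomIntercept):
        return {"group": t.group}
    if isinstance(t, RandomSlope):
        return {"group": t.group, "vars": tuple(t.vars), "degree": t.degree}
    raise TypeError(t)


def _assemble_penalty(design: Design, lambdas: list[list[float]]) -> np.ndarray:
    S = np.zeros((design.p, design.p))
    for b, lams in zip(design.blocks, lambdas):
        for lam, P in zip(lams, b.penalties):
            S[b.sl, b.sl] += lam * P
    return S


def _log_det_penalty(design: Design, lambdas: list[list[float]]) -> float:
    total = 0.0
    for b, lams in zip(design.blocks, lambdas):
        if len(b.penalties) == 0:
            continue
        if all(l <= 0.0 for l in lams):
            continue  # block forced unpenalized; contributes no log-determinant
        if len(b.penalties) == 1:
            total += b.penalty_ranks[0] * np.log(lams[0]) + b.penalty_logdets[0]
        else:
            Sb = sum(l * P for l, P in zip(lams, b.penalties))
            _, ld = _positive_eig_stats(Sb)
            total += ld
    return total


def fit_penalized(
    design: Design,
    y: np.ndarray | pd.Series,
    criterion: str = "reml",
    fixed_lambdas: dict[str, list[float]] | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
    keep_cov: bool = True,
) -> FitResult:
    """Fit the penalized least-squares model, selecting smoothing parameters
    by REML (Fellner-Schall updates) or GCV (simplex search on log-lambdas).

    ``fixed_lambdas`` maps a term label to its (list of) smoothing parameters,
    which are then held fixed; use 0 for an unpenalized fit of that block and
    a large value (e.g. 1e10) for the penalty-null-space limit.
    """
    y = np.asarray(y, dtype=float)
    X = design.X
    n, p = design.n, design.p
    Mp = design.null_space_dim
    if n <= Mp:
        raise ValueError("more unpenalized coefficients than data rows")
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    fixed_lambdas = dict(fixed_lambdas or {})
    lambdas: list[list[float]] = []
    free: list[tuple[int, int]] = []
    for bi, b in enumerate(design.blocks):
        if b.term.label in fixed_lambdas:
            v = fixed_lambdas.pop(b.term.label)
            v = [float(v)] if np.isscalar(v) else [float(u) for u in v]
            if len(v) != len(b.penalties):
                raise ValueError(f"term {b.term.label} needs {len(b.penalties)} lambdas")
            lambdas.append(v)
        else:
            lambdas.append([1.0] * len(b.penalties))
            free.extend((bi, j) for j in range(len(b.penalties)))
    if fixed_lambdas:
        raise KeyError(f"fixed_lambdas for unknown terms: {sorted(fixed_lambdas)}")

    def solve_at(lams: list[list[float]]):
        S = _assemble_penalty(design, lams)
        A = XtX + S
        jitter = 0.0
        base = np.mean(np.diag(A))
        for attempt in range(6):
            try:
                L = linalg.cho_factor(A + jitter * np.eye(p), lower=True)
                break
            except linalg.LinAlgError:
                jitter = base * 10.0 ** (-10 + 2 * attempt)
        else:  # pragma: no cover
            raise ConvergenceError("design + penalty matrix not positive definite", np.nan)
        beta = linalg.cho_solve(L, Xty)
        rss = max(yty - 2.0 * beta @ Xty + beta @ (XtX @ beta), 1e-300)
        pen = float(beta @ (S @ beta))
        logdetA = 2.0 * float(np.sum(np.log(np.diag(L[0]))))
        return S, L, beta, rss, pen, logdetA

    if criterion == "gcv" and free:
        lambdas = _gcv_search(design, XtX, Xty, yty, lambdas, free, n)

    V_old = np.inf
    V_best = np.inf
    best_lambdas = [list(l) for l in lambdas]
    best_iter = 0
    converged = not free or criterion == "gcv"
    for it in range(max_iter):
        S, L, beta, rss, pen, logdetA = solve_at(lambdas)
        P = max(rss + pen, 1e-300)
        sigma2 = P / (n - Mp)
        V = 0.5 * (n - Mp) * np.log(P) + 0.5 * (logdetA - _log_det_penalty(design, lambdas))
        if criterion == "gcv" or not free:
            converged = True
            break
        if V < V_best - tol * (1.0 + abs(V)):
            V_best = V
            best_lambdas = [list(l) for l in lambdas]
            best_iter = it
        elif V < V_best:
            V_best = V
            best_lambdas = [list(l) for l in lambdas]
        if abs(V - V_old) < tol * (1.0 + abs(V)):
            converged = True
            break
        if it - best_iter > 20:
            # the criterion has stalled (typically a near-flat direction for a
            # tensor-product block): accept the best point seen
            lambdas = [list(l) for l in best_lambdas]
            converged = True
            break
        V_old = V
        # progressive damping stabilizes oscillatory updates late in the run
        step = 1.0 if it < 20 else 0.5
        Ainv = linalg.cho_solve(L, np.eye(p))
        for bi, j in free:
            b = design.blocks[bi]
            Pj = b.penalties[j]
            beta_b = beta[b.sl]
            den = float(beta_b @ (Pj @ beta_b))
            tr_AinvS = float(np.sum(Ainv[b.sl, b.sl] * Pj))
            if len(b.penalties) == 1:
                tr_SinvS = b.penalty_ranks[0] / lambdas[bi][j]
            else:
                Sb = sum(l * Pk for l, Pk in zip(lambdas[bi], b.penalties))
                tr_SinvS = float(np.sum(np.linalg.pinv(Sb, rcond=1e-12) * Pj))
            num = max(tr_SinvS - tr_AinvS, 1e-14)
            if den <= 1e-300:
                lam_new = LAMBDA_MAX
            else:
                ratio = num * sigma2 / den
                ratio = min(max(ratio, 1e-3), 1e3) ** step
                lam_new = lambdas[bi][j] * ratio
            lambdas[bi][j] = float(min(max(lam_new, LAMBDA_MIN), LAMBDA_MAX))
    else:
        raise ConvergenceError(
            f"smoothing-parameter iteration did not converge in {max_iter} steps", V_old
        )
    if not converged:  # pragma: no cover
        raise ConvergenceError("smoothing-parameter iteration failed", V_old)

    S, L, beta, rss, pen, logdetA = solve_at(lambdas)
    P = max(rss + pen, 1e-300)
    sigma2 = P / (n - Mp)
    H = linalg.cho_solve(L, XtX)
    edf_total = float(np.trace(H))
    edf = {
        b.term.label: float(np.sum(np.diag(H)[b.sl])) for b in design.blocks
    }
    scale = rss / max(n - edf_total, 1.0)
    cov = scale * linalg.cho_solve(L, np.eye(p)) if keep_cov else None
    V = 0.5 * (n - Mp) * np.log(P) + 0.5 * (logdetA - _log_det_penalty(design, lambdas))
    if criterion == "gcv":
        V = n * rss / (n - edf_total) ** 2
    return FitResult(
        spec_name=design.spec.name,
        response=design.spec.response,
        beta=beta,
        intercept=float(beta[0]),
        lambdas={b.term.label: list(l) for b, l in zip(design.blocks, lambdas) if l},
        edf=edf,
        edf_total=edf_total,
        sigma2=float(sigma2),
        scale=float(scale),
        criterion=criterion,
        criterion_value=float(V),
        converged=converged,
        n=n,
        blocks=design.blocks,
        cov=cov,
        fitted=X @ beta,
    )


def _gcv_search(design, XtX, Xty, yty, lambdas, free, n):
    """Nelder-Mead search of the GCV criterion over free log-lambdas."""
    p = design.p

    def unpack(theta):
        lams = [list(l) for l in lambdas]
        for t, (bi, j) in zip(theta, free):
            lams[bi][j] = float(np.exp(np.clip(t, np.log(LAMBDA_MIN), np.log(LAMBDA_MAX))))
        return lams

    def gcv(theta):
        lams = unpack(theta)
        S = _assemble_penalty(design, lams)
        try:
            L = linalg.cho_factor(S + XtX + 1e-10 * np.eye(p), lower=True)
        except linalg.LinAlgError:
            return np.inf
        beta = linalg.cho_solve(L, Xty)
        rss = max(yty - 2.0 * beta @ Xty + beta @ (XtX @ beta), 1e-300)
        edf = float(np.trace(linalg.cho_solve(L, XtX)))
        return n * rss / (n - edf) ** 2

    theta0 = np.zeros(len(free))
    res = optimize.minimize(
        gcv, theta0, method="Nelder-Mead", options={"maxiter": 200 * len(free), "xatol": 1e-3, "fatol": 1e-8}
    )
    return unpack(res.x)


def fit_model(
    spec: ModelSpec,
    data: pd.DataFrame,
    criterion: str = "reml",
    **kwargs,
) -> FitResult:
    """Convenience wrapper: build the design for ``spec`` and fit it."""
    design = build_design(spec, data)
    return fit_penalized(design, np.asarray(data[spec.response], dtype=float), criterion=criterion, **kwargs)


def linear_partial_stub(
    var: str,
    slope: float,
    x_range: tuple[float, float] = (0.0, 10.0),
    k: int = 6,
    response: str = "tf",
) -> FitResult:
    """A synthetic fitted-model stub whose partial effect for ``var`` is an
    exactly linear function of the covariate.

    The spline coefficients are the (centered) values of the line at the
    knots; because a natural cubic spline through collinear points is the line
    itself, the partial effect is linear to machine precision everywhere,
    including the linear extension outside the knot range. Useful for worked
    examples and closed-form validation of effect-size formulas.
    """
    knots = np.linspace(x_range[0], x_range[1], k)
    F, S = _crs_F_and_penalty(knots)
    X = crs_basis(knots, knots, F)
    cmean = X.mean(axis=0)
    Z = _constraint_nullspace(cmean)
    v = slope * knots
    v = v - float(cmean @ v)  # center so the constraint c'v = 0 holds
    beta_c = Z.T @ v
    block = Block(SmoothTerm(var, k), slice(1, k), knots=knots, Z=Z)
    beta = np.concatenate([[0.0], beta_c])
    return FitResult(
        spec_name="linear_stub",
        response=response,
        beta=beta,
        intercept=0.0,
        lambdas={},
        edf={block.term.label: 1.0},
        edf_total=2.0,
        sigma2=0.0,
        scale=0.0,
        criterion="none",
        criterion_value=0.0,
        converged=True,
        n=k,
        blocks=[block],
    )


# ---------------------------------------------------------------------------
# superlinearity test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QuadraticTestResult:
    property: str
    measure: str
    quadratic_coef: float  # ms per unit^2 on the raw covariate scale
    se: float
    p_value: float

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def superlinearity_test(
    data: pd.DataFrame,
    property: str,
    measure: str = "tf",
    k: int = 20,
    include_re: bool = True,
    criterion: str = "reml",
) -> QuadraticTestResult:
    """Test for a superlinear (convex) effect of one word property.

    The property's current-word smooth is replaced by linear and quadratic
    terms plus a per-participant random slope on the quadratic term, all other
    model terms unchanged; the Wald p-value of the fixed quadratic coefficient
    is returned.
    """
    spec = quadratic_test_spec(property, measure, k=k, include_re=include_re)
    fit = fit_model(spec, data, criterion=criterion)
    est, se, p = fit.wald_coefficient(property, 2)
    return QuadraticTestResult(property, measure, est, se, p)


# ---------------------------------------------------------------------------
# cluster bootstrap confidence bands
# ---------------------------------------------------------------------------


class BootstrapError(RuntimeError):
    pass


def bootstrap_ci(
    data: pd.DataFrame,
    spec: ModelSpec,
    var: str,
    grid: np.ndarray,
    B: int,
    seed: int,
    cluster: str = "participant_id",
    anchor: str | None = None,
    level: float = 0.95,
) -> dict:
    """Cluster-bootstrap pointwise confidence band for one partial effect.

    Participants (values of ``cluster``) are resampled with replacement B
    times; each replicate refits the model and evaluates the partial effect on
    ``grid``. Returns pointwise percentile bounds, the replicate curves, and
    the count of failed replicates. More than 20% failures is an error.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    grid = np.asarray(grid, dtype=float)
    ids = np.unique(np.asarray(data[cluster]))
    groups = {g: df for g, df in data.groupby(cluster, sort=False)}
    curves = []
    failures = 0
    for b in range(B):
        draw = rng.choice(ids, size=ids.size, replace=True)
        parts = []
        for i, g in enumerate(draw):
            sub = groups[g].copy()
            sub[cluster] = f"bs{i}"
            parts.append(sub)
        boot = pd.concat(parts, ignore_index=True)
        try:
            fit = fit_model(spec, boot, keep_cov=False)
            curves.append(fit.partial_effect(var, grid, anchor=anchor))
        except (ConvergenceError, ValueError, np.linalg.LinAlgError):
            failures += 1
    if failures > 0.2 * B:
        raise BootstrapError(f"{failures}/{B} bootstrap replicates failed")
    arr = np.vstack(curves)
    alpha = (1.0 - level) / 2.0
    return {
        "grid": grid,
        "lower": np.quantile(arr, alpha, axis=0),
        "upper": np.quantile(arr, 1.0 - alpha, axis=0),
        "curves": arr,
        "failures": failures,
    }
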