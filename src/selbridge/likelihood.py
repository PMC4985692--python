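"""Trajectory likelihoods for the selection coefficient, and their maximizers.

For a single observed trajectory with per-step transitions ``i(t) -> j(t)``:

* unconditioned likelihood
  ``log L(s) = sum_{i,j} n({i,j}) log P_ij(s)`` — the classical choice,
  appropriate for ensembles of freely evolving replicates (experimental
  evolution);
* conditional likelihood
  ``log L_c(s) = sum_t log P_{i(t) j(t)|k}(s, T_F - t)`` — the
  endpoint-conditioned (Doob h-transform) likelihood, appropriate for a
  single historical trajectory whose final frequency is known;
* their ratio ``R(s) = L_c(s) / L(s) = Phi(s)``, the cumulative transform
  factor along the trajectory.

A transition that is impossible under the model at a candidate ``s`` makes
the log-likelihood ``-inf`` (a value, not an exception), so grid searches
survive partial infeasibility.  Maximization runs a log-spaced grid scan
followed by golden-section refinement around the best interior grid point;
multiple local maxima (the conditional likelihood can be bimodal when the
trajectory ends at fixation) are detected and retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .conditioning import (
    ConditioningSpec,
    Horizon,
    absorption_probs,
    asymptotic_conditional_matrix,
    asymptotic_conditional_row,
    conditional_transition_row,
)
from .models import Family, ModelSpec, build_transition_matrix
from .simulate import TransitionData, Trajectory, encode_transitions

logger = logging.getLogger(__name__)

_MAX_CACHED_S = 256


class EstimationError(RuntimeError):
    """The likelihood carries no information about s (flat or all -inf)."""


def _safe_log(x: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(x)


class UnconditionalLikelihood:
    """Evaluator for ``log L(s)`` with per-``s`` caching of ``log P(s)``."""

    def __init__(self, family: Family, N: int):
        self.family = family
        self.N = N
        self._cache: dict[float, np.ndarray] = {}

    def _logP(self, s: float) -> np.ndarray:
        logP = self._cache.get(s)
        if logP is None:
            tm = build_transition_matrix(ModelSpec(self.family, self.N, s))
            logP = _safe_log(tm.P)
            if len(self._cache) < _MAX_CACHED_S:
                self._cache[s] = logP
        return logP

    def loglik(self, data: TransitionData, s: float) -> float:
        terms = self._logP(s)[data.i_steps, data.j_steps]
        total = terms.sum()
        return float(total) if np.isfinite(total) else -np.inf


class ConditionalLikelihood:
    """Evaluator for ``log L_c(s)`` under a fixed conditioning specification.

    For finite horizons the backward hitting recursion is run once per
    ``s`` up to ``T_F`` and shared across all trajectories and steps; the
    per-step conditioned probability is read off as
    ``P_ij h_{m-1}(j) / (P h_{m-1})(i)`` with ``m = T_F - t``.
    For asymptotic horizons the time-homogeneous transformed matrix is built
    once per ``s``.
    """

    def __init__(self, family: Family, N: int, cond: ConditioningSpec):
        self.family = family
        self.N = N
        self.cond = cond
        self._cache: dict[float, tuple] = {}

    def _finite_tables(self, s: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        tm = build_transition_matrix(ModelSpec(self.family, self.N, s))
        T_F = self.cond.T_F
        n = tm.n_states
        logH = np.full((T_F + 1, n), -np.inf)
        logG = np.full((T_F + 1, n), -np.inf)
        h = np.zeros(n)
        h[self.cond.k] = 1.0
        logH[0, self.cond.k] = 0.0
        for m in range(1, T_F + 1):
            g = tm.P @ h
            logG[m] = _safe_log(g)
            top = g.max()
            h = g / top if top > 0.0 else g
            logH[m] = _safe_log(h)
        return _safe_log(tm.P), logH, logG

    def _tables(self, s: float):
        tables = self._cache.get(s)
        if tables is None:
            if self.cond.horizon is Horizon.FINITE:
                tables = self._finite_tables(s)
            else:
                tm = build_transition_matrix(ModelSpec(self.family, self.N, s))
                logM = _safe_log(asymptotic_conditional_matrix(tm, self.cond.k))
                if self.cond.k in (0, self.N):
                    feasible = absorption_probs(tm, self.cond.k).u > 0.0
                else:
                    feasible = np.zeros(tm.n_states, dtype=bool)
                    feasible[1:-1] = True
                logM[~feasible] = -np.inf
                tables = (logM,)
            if len(self._cache) < _MAX_CACHED_S:
                self._cache[s] = tables
        return tables

    def loglik(self, data: TransitionData, s: float) -> float:
        if self.cond.horizon is Horizon.FINITE:
            logP, logH, logG = self._tables(s)
            T_F = self.cond.T_F
            t = np.arange(data.T)
            m = T_F - t
            if data.T and m.min() < 1:
                raise ValueError("trajectory longer than the conditioning horizon")
            terms = (
                logP[data.i_steps, data.j_steps]
                + logH[m - 1, data.j_steps]
                - logG[m, data.i_steps]
            )
        else:
            (logM,) = self._tables(s)
            terms = logM[data.i_steps, data.j_steps]
        total = terms.sum()
        return float(total) if np.isfinite(total) else -np.inf


def _resolve(traj: Trajectory, family, N) -> tuple[Family, int, TransitionData]:
    fam = family if family is not None else traj.family
    n_alleles = N if N is not None else traj.N
    return fam, n_alleles, encode_transitions(traj)


def loglik_unconditional(
    traj: Trajectory, s: float, family: Family | None = None, N: int | None = None
) -> float:
    """``log L(s)`` over the trajectory's consecutive transitions."""
    fam, n, data = _resolve(traj, family, N)
    return UnconditionalLikelihood(fam, n).loglik(data, s)


def loglik_conditional(
    traj: Trajectory,
    s: float,
    cond: ConditioningSpec | None = None,
    family: Family | None = None,
    N: int | None = None,
) -> float:
    """``log L_c(s)`` over the trajectory's consecutive transitions."""
    fam, n, data = _resolve(traj, family, N)
    spec = cond if cond is not None else traj.conditioning()
    return ConditionalLikelihood(fam, n, spec).loglik(data, s)


def log_phi_product(
    traj: Trajectory,
    s: float,
    cond: ConditioningSpec | None = None,
    family: Family | None = None,
    N: int | None = None,
) -> float:
    """``log Phi(s)``: per-step transform factors multiplied along the path.

    Computed directly from the conditioning rows (``phi = P_{ij|k} / P_ij``
    step by step), independently of the likelihood evaluators; satisfies
    ``L_c(s) = Phi(s) L(s)``.
    """
    fam, n, data = _resolve(traj, family, N)
    spec = cond if cond is not None else traj.conditioning()
    tm = build_transition_matrix(ModelSpec(fam, n, s))
    total = 0.0
    for t in range(data.T):
        i, j = int(data.i_steps[t]), int(data.j_steps[t])
        if spec.horizon is Horizon.FINITE:
            row = conditional_transition_row(tm, i, spec.k, spec.T_F - t)
        else:
            row = asymptotic_conditional_row(tm, i, spec.k)
        p_cond = row[j]
        p_free = tm.P[i, j]
        if p_cond <= 0.0 or p_free <= 0.0:
            return -np.inf
        total += np.log(p_cond) - np.log(p_free)
    return total


@dataclass(frozen=True)
class LikelihoodCurve:
    """Log-likelihood (or log-ratio) evaluated on a grid of ``s`` values."""

    s: np.ndarray = field(repr=False)
    loglik: np.ndarray = field(repr=False)
    kind: str


@dataclass(frozen=True)
class MLEResult:
    """Maximizer of one likelihood curve for one trajectory."""

    s_hat: float
    loglik: float
    boundary: bool
    multimodal: bool
    local_maxima: tuple
    kind: str


def maximize(
    fun,
    s_min: float = 0.05,
    s_max: float = 20.0,
    n_grid: int = 200,
    kind: str = "likelihood",
) -> MLEResult:
    """Maximize ``fun(s)`` over ``[s_min, s_max]``.

    Scans a log-spaced grid, flags boundary maxima and multimodality, and
    refines the best interior grid point by golden-section search on
    ``log s`` to relative tolerance 1e-5.
    """
    if not 0 < s_min < s_max:
        raise ValueError("need 0 < s_min < s_max")
    grid = np.geomspace(s_min, s_max, n_grid)
    vals = np.array([fun(s) for s in grid])
    finite = np.isfinite(vals)
    if not finite.any():
        raise EstimationError("likelihood is -inf everywhere on the search grid")
    fvals = vals[finite]
    if fvals.max() - fvals.min() < 1e-12:
        raise EstimationError("likelihood is flat: trajectory carries no information")
    best = int(np.nanargmax(np.where(finite, vals, -np.inf)))

    maxima = []
    for idx in range(n_grid):
        if not finite[idx]:
            continue
        left = vals[idx - 1] if idx > 0 else -np.inf
        right = vals[idx + 1] if idx < n_grid - 1 else -np.inf
        if vals[idx] > left and vals[idx] > right:
            maxima.append((float(grid[idx]), float(vals[idx])))
    multimodal = len(maxima) > 1
    boundary = best in (0, n_grid - 1)

    s_hat, ll_hat = float(grid[best]), float(vals[best])
    if not boundary and vals[best] > vals[best - 1] and vals[best] > vals[best + 1]:
        u = np.log(grid)
        try:
            res = optimize.minimize_scalar(
                lambda x: -fun(float(np.exp(x))),
                bracket=(u[best - 1], u[best], u[best + 1]),
                method="golden",
                options={"xtol": 1e-5},
            )
            if np.isfinite(res.fun) and -res.fun >= ll_hat:
                s_hat = float(np.clip(np.exp(res.x), s_min, s_max))
                ll_hat = float(-res.fun)
        except Exception:  # refinement is best-effort; the grid point stands
            logger.warning("golden-section refinement failed; keeping grid maximum")
    return MLEResult(
        s_hat=s_hat, loglik=ll_hat, boundary=boundary,
        multimodal=multimodal, local_maxima=tuple(maxima), kind=kind,
    )


def likelihood_curve(
    traj: Trajectory,
    kind: str,
    grid: np.ndarray,
    cond: ConditioningSpec | None = None,
) -> LikelihoodCurve:
    """Evaluate ``log L``, ``log L_c`` or ``log R`` on an ``s`` grid."""
    fam, n, data = _resolve(traj, None, None)
    if kind == "unconditional":
        ev = UnconditionalLikelihood(fam, n)
        vals = np.array([ev.loglik(data, s) for s in grid])
    elif kind == "conditional":
        spec = cond if cond is not None else traj.conditioning()
        ev = ConditionalLikelihood(fam, n, spec)
        vals = np.array([ev.loglik(data, s) for s in grid])
    elif kind == "ratio":
        spec = cond if cond is not None else traj.conditioning()
        ev_c = ConditionalLikelihood(fam, n, spec)
        ev_u = UnconditionalLikelihood(fam, n)
        lc = np.array([ev_c.loglik(data, s) for s in grid])
        lu = np.array([ev_u.loglik(data, s) for s in grid])
        with np.errstate(invalid="ignore"):
            vals = lc - lu
        vals[~np.isfinite(vals)] = -np.inf
    else:
        raise ValueError(f"unknown likelihood kind {kind!r}")
    return LikelihoodCurve(s=np.asarray(grid, dtype=float), loglik=vals, kind=kind)


def likelihood_ratio_curve(
    traj: Trajectory, grid: np.ndarray, cond: ConditioningSpec | None = None
) -> LikelihoodCurve:
    """``log R(s) = log L_c(s) - log L(s)`` on a grid (exploratory estimator)."""
    return likelihood_curve(traj, "ratio", grid, cond=cond)


def fit_mle(
    traj: Trajectory,
    kind: str,
    cond: ConditioningSpec | None = None,
    s_min: float = 0.05,
    s_max: float = 20.0,
    n_grid: int = 200,
) -> MLEResult:
    """Convenience wrapper: maximize one likelihood kind for one trajectory."""
    fam, n, data = _resolve(traj, None, None)
    if kind == "unconditional":
        ev = UnconditionalLikelihood(fam, n)
        fun = lambda s: ev.loglik(data, s)  # noqa: E731
    elif kind == "conditional":
        spec = cond if cond is not None else traj.conditioning()
        ev = ConditionalLikelihood(fam, n, spec)
        fun = lambda s: ev.loglik(data, s)  # noqa: E731
    elif kind == "ratio":
        spec = cond if cond is not None else traj.conditioning()
        ev_c = ConditionalLikelihood(fam, n, spec)
        ev_u = UnconditionalLikelihood(fam, n)
        fun = lambda s: ev_c.loglik(data, s) - ev_u.loglik(data, s)  # noqa: E731
    else:
        raise ValueError(f"unknown likelihood kind {kind!r}")
    return maximize(fun, s_min=s_min, s_max=s_max, n_grid=n_grid, kind=kind)
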