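"""Endpoint conditioning of the allele-frequency chains (Doob h-transform).

Conditioning a Markov chain on a future observation ``X_{T_F} = k`` yields a
new Markov chain whose one-step probabilities are re-weighted by hitting
probabilities of ``k``:

    P_{ij|k}(m) = P_ij * h_{m-1}(j) / h_m(i),      h_m(i) = (P^m)_{ik},

where ``m = T_F - t`` is the time remaining.  The weights are computed by the
backward recursion ``h_m = P h_{m-1}`` with ``h_0`` the indicator of ``k``,
rescaled by its maximum at every step so that horizons of hundreds of
generations do not underflow (only ratios within a step enter the transform,
so the rescaling is exact).

In the limit ``T_F -> infinity`` the factors become time-homogeneous:

* transient ``k`` (0 < k < N): quasi-stationary conditioning through the
  Perron eigenpair (``lambda_0``, ``w_0``) of the transient submatrix,
  ``phi_ij = w_0(j) / (lambda_0 w_0(i))``;
* absorbing ``k`` (0 or N): ``phi_ij = u_jk / u_ik`` with ``u_ik`` the
  probability of eventual absorption in ``k`` from ``i``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .models import TransitionMatrix

logger = logging.getLogger(__name__)

_POWER_ITER_TOL = 1e-12
_POWER_ITER_MAX = 200_000


class InfeasibleBridgeError(ValueError):
    """The conditioning event has probability zero from the given state."""


class Horizon(str, Enum):
    FINITE = "finite"
    ASYMPTOTIC = "asymptotic"


@dataclass(frozen=True)
class ConditioningSpec:
    """Final observation to condition on: state ``k`` and horizon mode.

    ``finite`` horizons carry the generation ``T_F`` of the final
    observation; the per-step transform then depends on the remaining time
    ``m = T_F - t``.  ``asymptotic`` horizons use the ``T_F -> infinity``
    limit (spectral for transient ``k``, absorption-probability for
    absorbing ``k``) and are time-homogeneous.
    """

    k: int
    horizon: Horizon
    T_F: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "horizon", Horizon(self.horizon))
        if self.horizon is Horizon.FINITE:
            if self.T_F is None or self.T_F < 1:
                raise ValueError("finite horizon requires T_F >= 1")
        elif self.T_F is not None:
            raise ValueError("asymptotic horizon takes no T_F")

    @classmethod
    def finite(cls, k: int, T_F: int) -> "ConditioningSpec":
        return cls(k=k, horizon=Horizon.FINITE, T_F=T_F)

    @classmethod
    def asymptotic(cls, k: int) -> "ConditioningSpec":
        return cls(k=k, horizon=Horizon.ASYMPTOTIC)


@dataclass(frozen=True)
class HittingProfile:
    """Rescaled hitting probabilities ``h(i) ∝ Pr(X after m steps = k | X = i)``.

    ``h`` is the backward-recursion vector after ``m`` steps, rescaled by its
    running maximum; ``log_scale`` restores the absolute scale:
    ``(P^m)_{ik} = h(i) * exp(log_scale)``.
    """

    h: np.ndarray = field(repr=False)
    m: int
    k: int
    log_scale: float


def hitting_profile(P: TransitionMatrix, k: int, m: int) -> HittingProfile:
    """Backward recursion ``h_m = P h_{m-1}`` from ``h_0 = indicator(k)``."""
    if m < 0:
        raise ValueError("m must be >= 0")
    if not 0 <= k <= P.N:
        raise ValueError(f"k={k} outside 0..{P.N}")
    h = np.zeros(P.n_states)
    h[k] = 1.0
    log_scale = 0.0
    for _ in range(m):
        h = P.P @ h
        top = h.max()
        if top <= 0.0:
            # k unreachable from every state at this depth
            return HittingProfile(h=h, m=m, k=k, log_scale=-np.inf)
        h = h / top
        log_scale += np.log(top)
    return HittingProfile(h=h, m=m, k=k, log_scale=log_scale)


def conditional_transition_row(
    P: TransitionMatrix, i: int, k: int, m: int
) -> np.ndarray:
    """Finite-horizon conditioned row ``P_{ij|k}`` with ``m`` steps remaining.

    ``P_{ij|k} = P_ij (P^{m-1})_{jk} / (P^m)_{ik}``; the Doob normalization
    ``sum_j P_ij h_{m-1}(j) = h_m(i)`` makes the row sum to one.  At
    ``m = 1`` the row is the indicator of ``j = k``.
    """
    if m < 1:
        raise ValueError("conditioned step needs m >= 1 remaining steps")
    if not 0 <= i <= P.N:
        raise ValueError(f"state i={i} outside 0..{P.N}")
    prof = hitting_profile(P, k, m - 1)
    weights = P.P[i] * prof.h
    total = weights.sum()
    if total <= 0.0:
        raise InfeasibleBridgeError(
            f"state k={k} is unreachable from i={i} in m={m} steps"
        )
    return weights / total


@dataclass(frozen=True)
class SpectralData:
    """Perron eigenpair of the transient submatrix (states ``1..N-1``).

    ``lam0`` is the largest non-trivial eigenvalue of the chain (the leading
    eigenvalue of the transient block, strictly between 0 and 1); ``w`` is the
    corresponding right eigenvector padded with zeros at the absorbing states
    and normalized positive.
    """

    lam0: float
    w: np.ndarray = field(repr=False)


def _power_iteration(Q: np.ndarray) -> tuple[float, np.ndarray]:
    v = np.ones(Q.shape[0])
    v /= v.sum()
    lam = 0.0
    for _ in range(_POWER_ITER_MAX):
        nv = Q @ v
        lam_new = nv.max()
        nv /= lam_new
        if np.max(np.abs(nv - v)) < _POWER_ITER_TOL:
            return lam_new, nv
        v, lam = nv, lam_new
    logger.warning("power iteration hit the iteration cap; returning best pair")
    return lam, v


def spectral_data(P: TransitionMatrix) -> SpectralData:
    """Leading eigenpair of the transient block, with power-iteration fallback."""
    Q = P.P[1:-1, 1:-1]
    vals, vecs = np.linalg.eig(Q)
    idx = int(np.argmax(vals.real))
    lam0 = vals[idx]
    w = vecs[:, idx]
    degenerate = (
        abs(lam0.imag) > 1e-10
        or np.max(np.abs(w.imag)) > 1e-8
        or np.count_nonzero(np.isclose(vals.real, lam0.real, rtol=1e-10, atol=1e-14)) > 1
    )
    lam0 = float(lam0.real)
    w = w.real
    w = w * np.sign(w[np.argmax(np.abs(w))])
    if degenerate or w.min() <= 0.0:
        logger.warning("leading eigenpair degenerate or non-positive; "
                       "falling back to power iteration")
        lam0, w = _power_iteration(Q)
    if not 0.0 < lam0 < 1.0:
        raise ArithmeticError(f"leading transient eigenvalue {lam0} outside (0, 1)")
    if w.min() <= 0.0:
        raise ArithmeticError("Perron eigenvector has non-positive components")
    w = w / w.max()
    full = np.zeros(P.n_states)
    full[1:-1] = w
    return SpectralData(lam0=lam0, w=full)


def spectral_phi(
    P: TransitionMatrix, i: int, j: int, data: SpectralData | None = None
) -> float:
    """Asymptotic transform factor ``phi_ij = w_0(j) / (lambda_0 w_0(i))``.

    Valid for transient ``i, j``; independent of which transient endpoint the
    chain is conditioned on, and of time.
    """
    if not (0 < i < P.N and 0 < j < P.N):
        raise ValueError("spectral phi is defined for transient states only")
    sd = data if data is not None else spectral_data(P)
    return sd.w[j] / (sd.lam0 * sd.w[i])


@dataclass(frozen=True)
class AbsorptionProfile:
    """Absorption probabilities ``u_ik`` into a boundary ``k in {0, N}``."""

    u: np.ndarray = field(repr=False)
    k: int


def absorption_probs(P: TransitionMatrix, k: int) -> AbsorptionProfile:
    """Solve the first-step system ``(I - Q) u = r_k`` on transient states."""
    if k not in (0, P.N):
        raise ValueError(f"k={k} is not an absorbing state (0 or {P.N})")
    Q = P.P[1:-1, 1:-1]
    r = P.P[1:-1, k]
    u_trans = np.linalg.solve(np.eye(P.N - 1) - Q, r)
    u = np.empty(P.n_states)
    u[0] = 1.0 if k == 0 else 0.0
    u[P.N] = 1.0 if k == P.N else 0.0
    u[1:-1] = np.clip(u_trans, 0.0, 1.0)
    return AbsorptionProfile(u=u, k=k)


def asymptotic_conditional_row(P: TransitionMatrix, i: int, k: int) -> np.ndarray:
    """Time-homogeneous conditioned row in the ``T_F -> infinity`` limit."""
    if not 0 <= i <= P.N:
        raise ValueError(f"state i={i} outside 0..{P.N}")
    if k in (0, P.N):
        u = absorption_probs(P, k).u
        if u[i] <= 0.0:
            raise InfeasibleBridgeError(
                f"absorption in k={k} has probability zero from i={i}"
            )
        weights = P.P[i] * u
    else:
        if i in (0, P.N):
            raise InfeasibleBridgeError(
                f"conditioning on transient k={k} is infeasible from absorbing i={i}"
            )
        sd = spectral_data(P)
        weights = P.P[i] * sd.w
    total = weights.sum()
    return weights / total


def asymptotic_conditional_matrix(P: TransitionMatrix, k: int) -> np.ndarray:
    """Full transition matrix of the asymptotically conditioned chain.

    Rows from which the conditioning is infeasible (probability-zero states
    the conditioned chain can never visit) are left as indicator rows so the
    matrix stays row-stochastic.
    """
    n = P.n_states
    M = np.eye(n)
    if k in (0, P.N):
        u = absorption_probs(P, k).u
        for i in range(n):
            if u[i] > 0.0:
                row = P.P[i] * u
                M[i] = row / row.sum()
    else:
        sd = spectral_data(P)
        for i in range(1, P.N):
            row = P.P[i] * sd.w
            M[i] = row / row.sum()
    return M
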