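"""Trajectory simulation: free chains and endpoint-conditioned bridges.

A recorded trajectory consists of ``T + 1`` strictly consecutive
measurements ``N_B(0..T)`` plus one final observation, giving ``T + 2``
measurements in total.  Four observation schemes are distinguished:

* case I  — final observation one generation after the block
  (``T_F = T + 1``) at an intermediate frequency ``0 < k < N``;
* case II — ``T_F = T + 1`` with *B* fixed (or nearly fixed) at ``T_F``;
* case III — final observation in the distant future (``T_F >> T``,
  treated as the ``T_F -> infinity`` limit) at an intermediate frequency;
* case IV — distant-future observation at (near-)fixation.

Cases I/II are simulated from the time-dependent bridge transform, cases
III/IV from the time-homogeneous asymptotic transform.  The gap between
generation ``T`` and the final observation carries conditioning information
only; it is never counted as an observed transition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .conditioning import (
    ConditioningSpec,
    Horizon,
    InfeasibleBridgeError,
    asymptotic_conditional_matrix,
)
from .models import Family, ModelSpec, TransitionMatrix, build_transition_matrix

CASES = ("I", "II", "III", "IV")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class Trajectory:
    """Observed B-allele counts at generations ``0..T`` plus a final record.

    ``final_state`` / ``T_F`` describe the extra observation; ``T_F`` is
    ``None`` when the final record sits in the asymptotic future (cases
    III/IV) or when there is no final record at all (free simulation).
    """

    states: np.ndarray = field(repr=False)
    family: Family
    N: int
    final_state: int | None = None
    horizon: Horizon | None = None
    T_F: int | None = None
    case: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        from .models import _as_family

        object.__setattr__(self, "family", _as_family(self.family))
        if self.horizon is not None:
            object.__setattr__(self, "horizon", Horizon(self.horizon))
        states = np.asarray(self.states, dtype=np.int64)
        object.__setattr__(self, "states", states)
        states.setflags(write=False)
        if states.ndim != 1 or states.size < 1:
            raise ValueError("states must be a non-empty 1-d sequence")
        if states.min() < 0 or states.max() > self.N:
            raise ValueError("states outside 0..N")
        steps = np.diff(states)
        if self.family is Family.MORAN and steps.size and np.abs(steps).max() > 1:
            raise ValueError("Moran states must change by at most 1 per step")
        for a in (0, self.N):
            hits = np.flatnonzero(states == a)
            if hits.size and not np.all(states[hits[0]:] == a):
                raise ValueError("chain left an absorbing state")
        if self.horizon is Horizon.FINITE and self.T_F != self.T + 1:
            raise ValueError("finite-horizon record must sit at T_F = T + 1")

    @property
    def T(self) -> int:
        """Number of consecutive transitions in the observed block."""
        return self.states.size - 1

    def conditioning(self) -> ConditioningSpec:
        if self.final_state is None:
            raise ValueError("trajectory carries no final observation")
        if self.horizon is Horizon.FINITE:
            return ConditioningSpec.finite(self.final_state, self.T_F)
        return ConditioningSpec.asymptotic(self.final_state)


@dataclass(frozen=True)
class CaseSpec:
    """One of the four observation schemes with its concrete parameters."""

    case: str
    N_B0: int
    T: int
    k: int

    def __post_init__(self) -> None:
        if self.case not in CASES:
            raise ValueError(f"case must be one of {CASES}, got {self.case!r}")
        if self.T < 0:
            raise ValueError("T must be >= 0")

    @property
    def horizon(self) -> Horizon:
        return Horizon.FINITE if self.case in ("I", "II") else Horizon.ASYMPTOTIC

    def conditioning(self) -> ConditioningSpec:
        if self.horizon is Horizon.FINITE:
            return ConditioningSpec.finite(self.k, self.T + 1)
        return ConditioningSpec.asymptotic(self.k)

    def validate_against(self, N: int) -> None:
        if not 0 <= self.N_B0 <= N or not 0 <= self.k <= N:
            raise ValueError("N_B0 and k must lie in 0..N")
        if self.case in ("I", "III") and self.k in (0, N):
            raise ValueError(f"case {self.case} needs an intermediate final state")
        if self.case in ("II", "IV") and self.k not in (N, N - 1):
            raise ValueError(f"case {self.case} needs k = N (or N-1 near fixation)")


def _sample_rows(cum_rows: np.ndarray, states: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Vectorized categorical draw: next state per trajectory from cum rows."""
    return (cum_rows[states] < u[:, None]).sum(axis=1)


def simulate_unconditioned(
    spec: ModelSpec, N_B0: int, T: int, seed=None
) -> Trajectory:
    """Simulate ``T`` free steps of the chain from ``N_B(0) = N_B0``."""
    rng = _as_rng(seed)
    tm = build_transition_matrix(spec)
    cum = np.cumsum(tm.P, axis=1)
    states = np.empty(T + 1, dtype=np.int64)
    states[0] = N_B0
    for t in range(T):
        states[t + 1] = np.searchsorted(cum[states[t]], rng.random(), side="right")
    return Trajectory(states=states, family=spec.family, N=spec.N)


def simulate_unconditioned_ensemble(
    spec: ModelSpec, N_B0: int, T: int, n: int, seed=None
) -> np.ndarray:
    """``(n, T+1)`` array of free trajectories, vectorized across replicates."""
    rng = _as_rng(seed)
    tm = build_transition_matrix(spec)
    cum = np.cumsum(tm.P, axis=1)
    out = np.empty((n, T + 1), dtype=np.int64)
    out[:, 0] = N_B0
    for t in range(T):
        out[:, t + 1] = _sample_rows(cum, out[:, t], rng.random(n))
    return out


def _hitting_stack(tm: TransitionMatrix, k: int, m_max: int) -> np.ndarray:
    """Max-rescaled backward-recursion vectors ``h_m`` for ``m = 0..m_max``."""
    n = tm.n_states
    H = np.zeros((m_max + 1, n))
    H[0, k] = 1.0
    for m in range(1, m_max + 1):
        v = tm.P @ H[m - 1]
        top = v.max()
        H[m] = v / top if top > 0.0 else v
    return H


def _bridge_row_weights(tm: TransitionMatrix, H: np.ndarray, i: int, m: int) -> np.ndarray:
    w = tm.P[i] * H[m - 1]
    total = w.sum()
    if total <= 0.0:
        raise InfeasibleBridgeError(
            f"endpoint unreachable from state {i} in {m} remaining steps"
        )
    return w / total


def simulate_conditioned(spec: ModelSpec, case: CaseSpec, seed=None) -> Trajectory:
    """Simulate one endpoint-conditioned trajectory for the given case.

    Cases I/II draw every step from the finite-horizon bridge transform with
    remaining time ``m = T_F - t`` (the last step into ``T_F = T + 1`` is
    forced to ``k``); cases III/IV draw from the time-homogeneous asymptotic
    transform and record ``k`` as the present-time observation.
    """
    case.validate_against(spec.N)
    rng = _as_rng(seed)
    tm = build_transition_matrix(spec)
    states = np.empty(case.T + 1, dtype=np.int64)
    states[0] = case.N_B0
    if case.horizon is Horizon.FINITE:
        T_F = case.T + 1
        H = _hitting_stack(tm, case.k, T_F)
        if H[T_F, case.N_B0] <= 0.0:
            raise InfeasibleBridgeError(
                f"bridge from {case.N_B0} to {case.k} in {T_F} steps is infeasible"
            )
        for t in range(case.T):
            row = _bridge_row_weights(tm, H, int(states[t]), T_F - t)
            states[t + 1] = np.searchsorted(np.cumsum(row), rng.random(), side="right")
        return Trajectory(
            states=states, family=spec.family, N=spec.N, final_state=case.k,
            horizon=Horizon.FINITE, T_F=T_F, case=case.case,
        )
    M = asymptotic_conditional_matrix(tm, case.k)
    if 0 < case.k < spec.N:
        if not 0 < case.N_B0 < spec.N:
            raise InfeasibleBridgeError("transient conditioning from absorbing start")
    else:
        from .conditioning import absorption_probs

        if absorption_probs(tm, case.k).u[case.N_B0] <= 0.0:
            raise InfeasibleBridgeError(
                f"absorption in {case.k} has probability zero from {case.N_B0}"
            )
    cum = np.cumsum(M, axis=1)
    for t in range(case.T):
        states[t + 1] = np.searchsorted(cum[states[t]], rng.random(), side="right")
    return Trajectory(
        states=states, family=spec.family, N=spec.N, final_state=case.k,
        horizon=Horizon.ASYMPTOTIC, T_F=None, case=case.case,
    )


def simulate_conditioned_ensemble(
    spec: ModelSpec, case: CaseSpec, n: int, seed=None
) -> np.ndarray:
    """``(n, T+1)`` array of conditioned trajectories (states only)."""
    case.validate_against(spec.N)
    rng = _as_rng(seed)
    tm = build_transition_matrix(spec)
    out = np.empty((n, case.T + 1), dtype=np.int64)
    out[:, 0] = case.N_B0
    if case.horizon is Horizon.FINITE:
        T_F = case.T + 1
        H = _hitting_stack(tm, case.k, T_F)
        if H[T_F, case.N_B0] <= 0.0:
            raise InfeasibleBridgeError("infeasible bridge")
        for t in range(case.T):
            m = T_F - t
            rows = tm.P * H[m - 1][None, :]
            totals = rows.sum(axis=1, keepdims=True)
            safe = np.where(totals > 0.0, totals, 1.0)
            cum = np.cumsum(rows / safe, axis=1)
            out[:, t + 1] = _sample_rows(cum, out[:, t], rng.random(n))
    else:
        M = asymptotic_conditional_matrix(tm, case.k)
        cum = np.cumsum(M, axis=1)
        for t in range(case.T):
            out[:, t + 1] = _sample_rows(cum, out[:, t], rng.random(n))
    return out


@dataclass(frozen=True)
class TransitionData:
    """Per-step transitions of the consecutive block, plus counts.

    ``i_steps[t] -> j_steps[t]`` is the transition at step ``t`` (the index
    functional: exactly one (i, j) pair fires per step).  ``counts`` maps
    each observed ordered pair to its number of occurrences ``n({i, j})``;
    counts sum to ``T``.  The (T, T_F) gap transition, when a final record
    exists, is kept separate and never enters the counts.
    """

    i_steps: np.ndarray = field(repr=False)
    j_steps: np.ndarray = field(repr=False)
    counts: dict
    gap: tuple | None

    @property
    def T(self) -> int:
        return self.i_steps.size


def encode_transitions(traj: Trajectory) -> TransitionData:
    """Encode a trajectory as transition indicators and pair counts."""
    if traj.states.size < 2 and traj.final_state is None:
        raise ValueError("need at least two measurements to encode transitions")
    i_steps = traj.states[:-1].copy()
    j_steps = traj.states[1:].copy()
    if traj.family is Family.MORAN and i_steps.size:
        if np.abs(j_steps - i_steps).max() > 1:
            raise ValueError("non-consecutive Moran states in the observed block")
    counts: dict = {}
    for a, b in zip(i_steps.tolist(), j_steps.tolist()):
        counts[(a, b)] = counts.get((a, b), 0) + 1
    gap = None
    if traj.final_state is not None:
        gap = (int(traj.states[-1]), int(traj.final_state))
    return TransitionData(i_steps=i_steps, j_steps=j_steps, counts=counts, gap=gap)


# ---------------------------------------------------------------------------
# TSV interchange format
# ---------------------------------------------------------------------------

def write_trajectory_tsv(traj: Trajectory, path) -> None:
    """Write a trajectory in the two-column TSV interchange format.

    Metadata travels in ``# key=value`` header lines; the final observation
    row carries generation ``T+1`` (finite horizon) or the token ``present``
    (asymptotic horizon).
    """
    lines = [
        f"# family={traj.family.value}",
        f"# N={traj.N}",
        f"# T={traj.T}",
    ]
    if traj.case is not None:
        lines.append(f"# case={traj.case}")
    if traj.seed is not None:
        lines.append(f"# seed={traj.seed}")
    if traj.horizon is not None:
        lines.append(f"# horizon={traj.horizon.value}")
    lines.append("generation\tn_B")
    for t, x in enumerate(traj.states.tolist()):
        lines.append(f"{t}\t{x}")
    if traj.final_state is not None:
        gen = str(traj.T_F) if traj.horizon is Horizon.FINITE else "present"
        lines.append(f"{gen}\t{traj.final_state}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_trajectory_tsv(path) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory_tsv`."""
    meta: dict = {}
    rows: list[tuple[str, int]] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line.lstrip("# ").partition("=")
            meta[key.strip()] = val.strip()
            continue
        gen, _, val = line.partition("\t")
        if gen == "generation":
            continue
        rows.append((gen, int(val)))
    if "family" not in meta or "N" not in meta:
        raise ValueError(f"{path}: missing family/N metadata headers")
    family = Family(meta["family"])
    N = int(meta["N"])
    T = int(meta["T"]) if "T" in meta else None
    final_state: int | None = None
    horizon: Horizon | None = None
    T_F: int | None = None
    if rows and rows[-1][0] == "present":
        final_state = rows[-1][1]
        horizon = Horizon.ASYMPTOTIC
        rows = rows[:-1]
    elif T is not None and len(rows) == T + 2:
        final_state = rows[-1][1]
        horizon = Horizon.FINITE
        T_F = int(rows[-1][0])
        rows = rows[:-1]
    gens = [int(g) for g, _ in rows]
    if gens != list(range(len(rows))):
        raise ValueError(f"{path}: consecutive block generations must be 0..T")
    states = np.array([v for _, v in rows], dtype=np.int64)
    return Trajectory(
        states=states, family=family, N=N, final_state=final_state,
        horizon=horizon, T_F=T_F, case=meta.get("case"),
        seed=int(meta["seed"]) if "seed" in meta else None,
    )
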