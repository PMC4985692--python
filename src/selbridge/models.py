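"""Two-allele population-genetic Markov chains (Moran and Wright–Fisher).

Both models track the count ``N_B`` of *B* alleles in a population of ``N``
alleles as a discrete-time Markov chain on ``{0, ..., N}`` with absorbing
boundaries at 0 (loss of *B*, fixation of *A*) and ``N`` (fixation of *B*).

The selection coefficient ``s`` is a fitness ratio of the *A* class over the
*B* class:

* Moran (haploid): ``s = W_A / W_B``.  One fitness-weighted birth and one
  uniform death per time step, so ``N_B`` changes by at most one.
* Wright–Fisher (diploid, one autosomal locus, codominance):
  ``s = W_AA / W_BB`` with ``W_AB / W_BB = (1 + s) / 2``.  The next adult
  generation is a binomial sample of size ``N`` from the selection-weighted
  gamete pool.

``s = 1`` is neutrality; ``s > 1`` favours *A* (drives *B* toward loss);
``0 <= s < 1`` favours *B*.  Only fitness ratios matter, so fitnesses are
normalized internally to ``W_B = 1`` (Moran) and ``W_BB = 1`` (WF).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import stats


class Family(str, Enum):
    """Which Markov chain generates the allele-frequency dynamics."""

    MORAN = "moran"
    WRIGHT_FISHER = "wright_fisher"


def _as_family(family: "Family | str") -> Family:
    if isinstance(family, Family):
        return family
    key = str(family).lower().replace("-", "_")
    aliases = {"wf": Family.WRIGHT_FISHER, "wright_fisher": Family.WRIGHT_FISHER,
               "moran": Family.MORAN}
    if key in aliases:
        return aliases[key]
    raise ValueError(f"unknown model family: {family!r}")


@dataclass(frozen=True)
class ModelSpec:
    """A fully specified chain: family, population size in alleles, selection.

    Parameters
    ----------
    family:
        ``Family.MORAN`` or ``Family.WRIGHT_FISHER`` (strings accepted).
    N:
        Number of alleles (even, >= 2).  For the diploid WF model this is
        twice the number of individuals.
    s:
        Selection coefficient (A over B), non-negative.  ``s = 0`` means the
        *A* class never reproduces.
    """

    family: Family
    N: int
    s: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", _as_family(self.family))
        if int(self.N) != self.N or self.N < 2 or self.N % 2 != 0:
            raise ValueError(f"N must be an even integer >= 2, got {self.N}")
        object.__setattr__(self, "N", int(self.N))
        if not np.isfinite(self.s) or self.s < 0:
            raise ValueError(f"selection coefficient must be finite and >= 0, got {self.s}")
        object.__setattr__(self, "s", float(self.s))


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic one-step matrix over B-allele counts ``0..N``.

    Rows 0 and ``N`` are absorbing.  Entries are time-independent.
    """

    P: np.ndarray = field(repr=False)
    family: Family
    N: int
    s: float

    def __post_init__(self) -> None:
        self.P.setflags(write=False)

    @property
    def n_states(self) -> int:
        return self.N + 1


def _check_state(N: int, i: int) -> None:
    if not 0 <= i <= N:
        raise ValueError(f"state i={i} outside 0..{N}")


def moran_step_probs(N: int, s: float, i: int) -> tuple[float, float, float]:
    """One-step (up, down, stay) probabilities of the Moran chain at ``N_B = i``.

    Each *A* individual contributes weight ``s`` and each *B* individual
    weight 1 to the offspring pool; one offspring is drawn from the pool and
    replaces a uniformly chosen parent.  ``N_B`` goes up when a *B* reproduces
    and an *A* dies, down when an *A* reproduces and a *B* dies:

    ``P_i = [i / ((N-i) s + i)] * (N-i)/N``
    ``Q_i = [(N-i) s / ((N-i) s + i)] * i/N``

    For ``0 <= s < 1`` the *B* class is advantaged (``P_i > Q_i``), and vice
    versa for ``s > 1``; ``s = 1`` is neutral.
    """
    if s < 0 or not np.isfinite(s):
        raise ValueError(f"selection coefficient must be finite and >= 0, got {s}")
    _check_state(N, i)
    if i == 0 or i == N:
        return 0.0, 0.0, 1.0
    pool = (N - i) * s + i
    up = (i / pool) * ((N - i) / N)
    down = ((N - i) * s / pool) * (i / N)
    return up, down, 1.0 - up - down


def wf_gamete_freq(N: int, s: float, i: int) -> float:
    """B-allele frequency in the gamete pool produced by ``i`` adult B alleles.

    With codominant fitnesses ``W_BB = 1``, ``W_AB = (1+s)/2``, ``W_AA = s``
    and adult frequencies ``p_B = i/N``, ``p_A = 1 - p_B``::

        p'_B = p_B (p_B W_BB + p_A W_AB) / W_O
        W_O  = p_A^2 W_AA + 2 p_A p_B W_AB + p_B^2 W_BB

    where ``W_O`` is the mean fitness of the adult population.
    """
    if s < 0 or not np.isfinite(s):
        raise ValueError(f"selection coefficient must be finite and >= 0, got {s}")
    _check_state(N, i)
    if i == 0:
        return 0.0
    if i == N:
        return 1.0
    p_b = i / N
    p_a = 1.0 - p_b
    w_ab = (1.0 + s) / 2.0
    w_mean = p_a * p_a * s + 2.0 * p_a * p_b * w_ab + p_b * p_b
    return p_b * (p_b + p_a * w_ab) / w_mean


def _moran_matrix(N: int, s: float) -> np.ndarray:
    P = np.zeros((N + 1, N + 1))
    for i in range(N + 1):
        up, down, stay = moran_step_probs(N, s, i)
        if i > 0:
            P[i, i - 1] = down
        P[i, i] = stay
        if i < N:
            P[i, i + 1] = up
    return P


def _wf_matrix(N: int, s: float) -> np.ndarray:
    p = np.array([wf_gamete_freq(N, s, i) for i in range(N + 1)])
    j = np.arange(N + 1)
    P = stats.binom.pmf(j[None, :], N, p[:, None])
    # exact absorbing rows (binom.pmf already gives indicators at p=0,1)
    P[0] = 0.0
    P[0, 0] = 1.0
    P[N] = 0.0
    P[N, N] = 1.0
    return P


def build_transition_matrix(spec: ModelSpec) -> TransitionMatrix:
    """Build the one-step transition matrix for a :class:`ModelSpec`.

    Moran matrices are tridiagonal; Wright–Fisher rows are
    ``Binomial(N, p'_B(i))`` probability mass functions.
    """
    if spec.family is Family.MORAN:
        P = _moran_matrix(spec.N, spec.s)
    else:
        P = _wf_matrix(spec.N, spec.s)
    return TransitionMatrix(P=P, family=spec.family, N=spec.N, s=spec.s)
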