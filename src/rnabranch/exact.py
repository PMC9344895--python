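"""Exact small-instance oracles: enumerated Gibbs distribution, the full
transition matrix of the path chain, and reversibility / stationarity /
spectral diagnostics.

Everything here is brute force over the Catalan-sized state space and is
only feasible for short paths (the default caps are m <= 10 for
distributions and m <= 8 for matrices, i.e. up to C_9 = 4862 states).  It
serves as the independent check that the production sampler targets the
intended Gibbs distribution: detailed balance to machine precision, the
leading eigenvector of the matrix against the enumerated distribution, and
a positive spectral gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eig
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.special import expit, logsumexp

from .trees import TwoMotzkinPath, enumerate_paths, validate_path

__all__ = [
    "ExactDistribution",
    "TransitionMatrix",
    "DiagnosticsReport",
    "exact_distribution",
    "transition_matrix",
    "verify_detailed_balance",
    "stationary_from_matrix",
    "total_variation",
    "spectral_diagnostics",
]

DISTRIBUTION_CAP = 10
MATRIX_CAP = 8


@dataclass(frozen=True)
class ExactDistribution:
    """Gibbs distribution over all valid paths of one length, by enumeration."""

    states: tuple  # ordered TwoMotzkinPath enumeration
    weights: np.ndarray  # probabilities, same order
    log_z: float
    alpha: float
    beta: float

    @property
    def m(self) -> int:
        return len(self.states[0]) if self.states else 0

    def as_dict(self) -> dict[str, float]:
        return {str(s): float(p) for s, p in zip(self.states, self.weights)}


@dataclass(frozen=True)
class TransitionMatrix:
    """One-step transition probabilities of the chain on a full enumeration."""

    states: tuple
    P: np.ndarray
    alpha: float
    beta: float

    @property
    def index(self) -> dict[str, int]:
        return {str(s): i for i, s in enumerate(self.states)}


@dataclass(frozen=True)
class DiagnosticsReport:
    max_detailed_balance_violation: float
    tv_to_target: float
    second_eigenvalue_modulus: float
    spectral_gap: float
    irreducible: bool

    def as_dict(self) -> dict:
        return {
            "max_detailed_balance_violation": self.max_detailed_balance_violation,
            "tv_to_target": self.tv_to_target,
            "second_eigenvalue_modulus": self.second_eigenvalue_modulus,
            "spectral_gap": self.spectral_gap,
            "irreducible": self.irreducible,
        }


def _path_log_weight(path: TwoMotzkinPath, alpha: float, beta: float) -> float:
    s = path.symbols
    return -(alpha * (s.count("U") + s.count("H") + 1) + beta * s.count("I"))


def exact_distribution(
    m: int, alpha: float, beta: float, cap: int = DISTRIBUTION_CAP
) -> ExactDistribution:
    """Enumerate all paths of length m and normalize exp(-E) in log space."""
    if m > cap:
        raise ValueError(f"m={m} exceeds the distribution cap {cap}")
    states = tuple(enumerate_paths(m, cap=cap))
    log_w = np.array([_path_log_weight(x, alpha, beta) for x in states])
    log_z = logsumexp(log_w)
    return ExactDistribution(
        states=states,
        weights=np.exp(log_w - log_z),
        log_z=float(log_z),
        alpha=alpha,
        beta=beta,
    )


def move_probabilities(alpha: float, beta: float) -> dict[str, float]:
    """The four Bernoulli acceptance probabilities of the chain, with the
    embedded 1/2 laziness, computed in logistic form for stability."""
    return {
        "UD->HH": 0.5 * expit(-alpha),      # e^-a / (2 (1 + e^-a))
        "HH->UD": 0.5 * expit(alpha),       # 1 / (2 (1 + e^-a))
        "I->H": 0.5 * expit(beta - alpha),  # e^-a / (2 (e^-a + e^-b))
        "H->I": 0.5 * expit(alpha - beta),  # e^-b / (2 (e^-a + e^-b))
    }


def transition_matrix(
    m: int, alpha: float, beta: float, cap: int = MATRIX_CAP
) -> TransitionMatrix:
    """Exact one-step kernel by summing over move types and index choices.

    Each of the four move types carries probability 1/4; pair moves pick one
    of the m-1 adjacent pairs, symbol moves one (or an ordered pair) of the
    m positions; the move-specific Bernoulli supplies the laziness.  For
    m = 1 the pair moves have no pair to pick and are no-ops.  The diagonal
    absorbs all rejected and identity proposals.
    """
    if m > cap:
        raise ValueError(f"m={m} exceeds the matrix cap {cap}")
    states = tuple(enumerate_paths(m, cap=max(cap, DISTRIBUTION_CAP)))
    index = {str(s): i for i, s in enumerate(states)}
    size = len(states)
    P = np.zeros((size, size))
    probs = move_probabilities(alpha, beta)

    for si, state in enumerate(states):
        s = state.symbols

        def add(target: str, p: float) -> None:
            P[si, index[target]] += p

        # l = 1: adjacent pair, UD <-> HH
        if m >= 2:
            per_pair = 0.25 / (m - 1)
            for i in range(m - 1):
                pair = s[i : i + 2]
                if pair == "UD":
                    add(s[:i] + "HH" + s[i + 2 :], per_pair * probs["UD->HH"])
                elif pair == "HH":
                    add(s[:i] + "UD" + s[i + 2 :], per_pair * probs["HH->UD"])
        # l = 2: single position, H <-> I
        per_pos = 0.25 / m
        for i in range(m):
            if s[i] == "I":
                add(s[:i] + "H" + s[i + 1 :], per_pos * probs["I->H"])
            elif s[i] == "H":
                add(s[:i] + "I" + s[i + 1 :], per_pos * probs["H->I"])
        # l = 3: ordered index pair, swap two U/D symbols, revert if invalid
        per_ordered_pair = 0.25 / (m * m)
        for i in range(m):
            if s[i] not in "UD":
                continue
            for j in range(m):
                if s[j] not in "UD" or i == j or s[i] == s[j]:
                    continue  # i=j or equal symbols: identity swap -> diagonal
                lst = list(s)
                lst[i], lst[j] = lst[j], lst[i]
                y = "".join(lst)
                if validate_path(y):
                    add(y, per_ordered_pair * 0.5)
        # l = 4: adjacent pair, swap a U/D with an H/I (always stays valid)
        if m >= 2:
            per_pair = 0.25 / (m - 1)
            for i in range(m - 1):
                a, b = s[i], s[i + 1]
                if (a in "UD") != (b in "UD"):
                    add(s[:i] + b + a + s[i + 2 :], per_pair * 0.5)

        P[si, si] = 0.0
        P[si, si] = 1.0 - P[si].sum()

    return TransitionMatrix(states=states, P=P, alpha=alpha, beta=beta)


def verify_detailed_balance(tm: TransitionMatrix, dist: ExactDistribution) -> float:
    """max over state pairs of |pi(x) P(x,y) - pi(y) P(y,x)|."""
    if tuple(map(str, tm.states)) != tuple(map(str, dist.states)):
        raise ValueError("transition matrix and distribution order their states differently")
    pi = dist.weights
    flow = pi[:, None] * tm.P
    return float(np.abs(flow - flow.T).max())


def _is_ergodic(P: np.ndarray) -> bool:
    graph = csr_matrix(P > 0)
    n_comp, _ = connected_components(graph, directed=True, connection="strong")
    aperiodic = bool(np.any(P.diagonal() > 0))
    return n_comp == 1 and aperiodic


def stationary_from_matrix(tm: TransitionMatrix) -> np.ndarray:
    """Leading left eigenvector of P, normalized to a distribution.

    Requires ergodicity (strongly connected transition graph plus self
    loops); otherwise the stationary vector is not unique and an error is
    raised.
    """
    P = tm.P
    if not _is_ergodic(P):
        raise ValueError("transition matrix is not ergodic; stationary vector not unique")
    values, vectors = eig(P.T)
    lead = int(np.argmin(np.abs(values - 1.0)))
    v = np.real(vectors[:, lead])
    v = np.abs(v)
    return v / v.sum()


def total_variation(p, q) -> float:
    """TV(p, q) = (1/2) sum |p - q| over a shared support ordering."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"distribution length mismatch: {p.shape} vs {q.shape}")
    return float(0.5 * np.abs(p - q).sum())


def spectral_diagnostics(
    tm: TransitionMatrix, dist: ExactDistribution | None = None
) -> DiagnosticsReport:
    """Second-eigenvalue modulus, spectral gap, and the other health checks.

    The gap 1 - |lambda_1| is positive exactly when the chain is ergodic;
    its inverse is the relaxation time that controls mixing.
    """
    P = tm.P
    if dist is None:
        dist = exact_distribution(len(tm.states[0]), tm.alpha, tm.beta)
    values = np.linalg.eigvals(P)
    moduli = np.sort(np.abs(values))[::-1]
    lam1 = float(moduli[1]) if len(moduli) > 1 else 0.0
    pi_eig = stationary_from_matrix(tm)
    return DiagnosticsReport(
        max_detailed_balance_violation=verify_detailed_balance(tm, dist),
        tv_to_target=total_variation(pi_eig, dist.weights),
        second_eigenvalue_modulus=lam1,
        spectral_gap=1.0 - lam1,
        irreducible=_is_ergodic(P),
    )
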