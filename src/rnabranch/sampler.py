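"""The production Markov chain on 2-Motzkin paths.

One step: draw a move type l uniformly from {1, 2, 3, 4}, then

  l=1  pick an adjacent pair; UD -> HH with probability e^-a/(2(1+e^-a)),
       HH -> UD with probability 1/(2(1+e^-a));
  l=2  pick a position; I -> H with probability e^-a/(2(e^-a+e^-b)),
       H -> I with probability e^-b/(2(e^-a+e^-b));
  l=3  pick two positions independently; if both hold U or D, swap them
       with probability 1/2, reverting if the result dips below the axis;
  l=4  pick an adjacent pair; if exactly one symbol is U/D and the other
       H/I, swap them with probability 1/2.

(a, b above are the energy coefficients alpha, beta.)  The chain is lazy,
aperiodic through its self-loops, irreducible via the all-H path, and
reversible with respect to the Gibbs distribution pi(x) ~ exp(-E(x)) with
E(x) = alpha*(|x|_U + |x|_H + 1) + beta*|x|_I.

Randomness contract (within one build): ``chain_step`` draws, per step, the
move type, then a fixed block of three floats (two index draws and the
Bernoulli).  ``run_chain`` consumes the same per-step layout but draws it
in chunks of arrays (one integer array, then a 3-by-chunk float array), so
its stream differs from repeated ``chain_step`` calls; each entry point is
individually bit-reproducible given its seed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np

from .exact import move_probabilities
from .trees import PlaneTree, TwoMotzkinPath, path_to_tree, validate_path

__all__ = [
    "ChainConfig",
    "SampleSet",
    "chain_step",
    "run_chain",
    "sample_trees",
    "empirical_step_distribution",
    "random_initial_path",
]

_CHUNK = 65536


@dataclass(frozen=True)
class ChainConfig:
    """Configuration of one seeded run.

    ``alpha`` and ``beta`` are the energy coefficients in kcal/mol (the
    exterior-loop coefficient gamma is fixed at 0 in the sampled
    distribution).  ``initial`` defaults to the all-H path, the hub state
    every path can reach.
    """

    m: int
    alpha: float
    beta: float
    steps: int
    burn_in: int = 0
    thinning: int = 1
    seed: int = 0
    initial: str | None = None

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("path length m must be >= 1")
        if self.steps <= 0:
            raise ValueError("steps must be positive")
        if not 0 <= self.burn_in <= self.steps:
            raise ValueError("need steps >= burn_in >= 0")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        start = self.resolved_initial()
        if len(start) != self.m or not validate_path(start):
            raise ValueError(f"initial state {start!r} is not a valid path of length {self.m}")

    def resolved_initial(self) -> str:
        return "H" * self.m if self.initial is None else self.initial


@dataclass(frozen=True)
class SampleSet:
    """Thinned output of one run plus its provenance."""

    paths: tuple  # kept states as strings, post burn-in, every thinning-th
    config: ChainConfig
    move_attempts: dict = field(default_factory=dict)  # move type -> draws
    move_accepts: dict = field(default_factory=dict)  # move type -> state changes
    final_state: str = ""

    def trees(self) -> list[PlaneTree]:
        return [path_to_tree(TwoMotzkinPath(p)) for p in self.paths]


def _step_core(s: list, l: int, r1: float, r2: float, u: float, probs: dict) -> bool:
    """Apply one move in place; return True if the state changed.

    ``r1``, ``r2`` select indices (scaled to the relevant range), ``u`` is
    the Bernoulli uniform.  Validity re-check is needed only for l=3; the
    other moves provably preserve validity.
    """
    m = len(s)
    if l == 1:
        if m < 2:
            return False  # no adjacent pair to pick: no-op
        i = int(r1 * (m - 1))
        a, b = s[i], s[i + 1]
        if a == "U" and b == "D":
            if u < probs["UD->HH"]:
                s[i] = "H"
                s[i + 1] = "H"
                return True
        elif a == "H" and b == "H":
            if u < probs["HH->UD"]:
                s[i] = "U"
                s[i + 1] = "D"
                return True
        return False
    if l == 2:
        i = int(r1 * m)
        if s[i] == "I":
            if u < probs["I->H"]:
                s[i] = "H"
                return True
        elif s[i] == "H":
            if u < probs["H->I"]:
                s[i] = "I"
                return True
        return False
    if l == 3:
        i = int(r1 * m)
        j = int(r2 * m)
        a, b = s[i], s[j]
        if a in "UD" and b in "UD" and u < 0.5:
            if i == j or a == b:
                return False  # identity swap, still lazy
            s[i], s[j] = b, a
            height = 0
            for ch in s:  # full prefix scan; O(m)
                if ch == "U":
                    height += 1
                elif ch == "D":
                    height -= 1
                    if height < 0:
                        s[i], s[j] = a, b  # revert
                        return False
            return True
        return False
    # l == 4
    if m < 2:
        return False
    i = int(r1 * (m - 1))
    a, b = s[i], s[i + 1]
    if ((a in "UD") != (b in "UD")) and u < 0.5:
        s[i], s[i + 1] = b, a
        return True
    return False


def chain_step(
    x: TwoMotzkinPath | str,
    rng: np.random.Generator,
    alpha: float,
    beta: float,
) -> TwoMotzkinPath:
    """One step of the chain from state ``x`` using ``rng``."""
    symbols = x.symbols if isinstance(x, TwoMotzkinPath) else x
    if not isinstance(x, TwoMotzkinPath) and not validate_path(symbols):
        raise ValueError(f"{symbols!r} is not a valid 2-Motzkin path")
    probs = move_probabilities(alpha, beta)
    s = list(symbols)
    l = int(rng.integers(1, 5))
    r1, r2, u = rng.random(3)
    _step_core(s, l, r1, r2, u, probs)
    return TwoMotzkinPath("".join(s))


def run_chain(config: ChainConfig) -> SampleSet:
    """Run the chain for ``config.steps`` steps; keep every ``thinning``-th
    state after ``burn_in``.  Deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    probs = move_probabilities(config.alpha, config.beta)
    s = list(config.resolved_initial())
    kept: list[str] = []
    attempts: Counter = Counter()
    accepts: Counter = Counter()

    done = 0
    since_keep = 0
    while done < config.steps:
        block = min(_CHUNK, config.steps - done)
        ls = rng.integers(1, 5, size=block)
        floats = rng.random((3, block))
        for k in range(block):
            l = int(ls[k])
            attempts[l] += 1
            if _step_core(s, l, floats[0, k], floats[1, k], floats[2, k], probs):
                accepts[l] += 1
            done += 1
            if done > config.burn_in:
                since_keep += 1
                if since_keep == config.thinning:
                    kept.append("".join(s))
                    since_keep = 0

    return SampleSet(
        paths=tuple(kept),
        config=config,
        move_attempts=dict(sorted(attempts.items())),
        move_accepts=dict(sorted(accepts.items())),
        final_state="".join(s),
    )


def sample_trees(config: ChainConfig) -> list[PlaneTree]:
    """Run the chain and convert every kept path to its plane tree."""
    return run_chain(config).trees()


def empirical_step_distribution(
    x: TwoMotzkinPath | str,
    alpha: float,
    beta: float,
    n_trials: int,
    seed: int = 0,
) -> Counter:
    """Counts of the state after a single step from ``x``, over independent
    trials — the empirical one-step kernel row used to cross-check the
    exact transition matrix."""
    symbols = x.symbols if isinstance(x, TwoMotzkinPath) else x
    if not validate_path(symbols):
        raise ValueError(f"{symbols!r} is not a valid 2-Motzkin path")
    rng = np.random.default_rng(seed)
    probs = move_probabilities(alpha, beta)
    start = list(symbols)
    tally: Counter = Counter()
    done = 0
    while done < n_trials:
        block = min(_CHUNK, n_trials - done)
        ls = rng.integers(1, 5, size=block)
        floats = rng.random((3, block))
        for k in range(block):
            s = start.copy()
            _step_core(s, int(ls[k]), floats[0, k], floats[1, k], floats[2, k], probs)
            tally["".join(s)] += 1
        done += block
    return tally


def random_initial_path(m: int, seed: int = 0, warmup_steps: int | None = None) -> str:
    """A near-uniform random valid path of length m, produced by a warm-up
    chain at alpha = beta = 0 started from the all-H hub."""
    if warmup_steps is None:
        warmup_steps = max(10_000, 100 * m * m)
    cfg = ChainConfig(
        m=m, alpha=0.0, beta=0.0, steps=warmup_steps,
        burn_in=warmup_steps - 1, thinning=1, seed=seed,
    )
    return run_chain(cfg).final_state
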