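"""Exact (non-Monte-Carlo) computation of design properties.

Two complementary machineries:

* reference-set enumeration for small trials (``n <= 16``): every feasible
  sequence together with its probability, the support of exact
  randomization-based inference;
* forward dynamic programming over the imbalance Markov chain for any
  ``n``: per-step expected absolute imbalance, loss, forcing-index
  increments, deterministic-assignment probability, and correct-guess
  probability, computed exactly.

All supported designs have conditional assignment rules that depend on the
history only through ``(i, D(i))`` (see :mod:`randkit.designs`), so the
probability distribution of ``D(i)`` can be propagated step by step on the
lattice ``D in {-i, -i+2, ..., i}``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .designs import (
    DesignSpec,
    MTI_DESIGNS,
    conditional_prob_array,
)

__all__ = [
    "ReferenceSet",
    "enumerate_reference_set",
    "exact_step_metrics",
    "long_run_predictability",
    "stationary_imbalance_distribution",
]

MAX_ENUM_N = 16


@dataclass
class ReferenceSet:
    """The enumerated set of feasible sequences of length ``n``."""

    spec: DesignSpec
    n: int
    sequences: np.ndarray  # (m, n) int8
    probs: np.ndarray  # (m,)

    def __post_init__(self) -> None:
        total = float(self.probs.sum())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"reference-set probabilities sum to {total}, not 1")

    @property
    def size(self) -> int:
        return self.sequences.shape[0]

    def index_of(self, assignments: np.ndarray) -> int:
        arr = np.asarray(assignments, dtype=np.int8)
        hits = np.nonzero((self.sequences == arr).all(axis=1))[0]
        if hits.size == 0:
            raise ValueError("sequence is not in the reference set (design violation)")
        return int(hits[0])

    def to_frame(self) -> pd.DataFrame:
        strings = ["".join("E" if a else "C" for a in row) for row in self.sequences]
        return pd.DataFrame({"sequence": strings, "probability": self.probs})


def enumerate_reference_set(spec: DesignSpec, n: int) -> ReferenceSet:
    """Enumerate all feasible sequences of length ``n`` with their probabilities.

    Depth-first search over the binary tree of assignments; branches with
    conditional probability 0 are pruned, so only feasible sequences are
    visited and each appears exactly once.
    """
    n = spec.resolve_n(n) or n
    if n > MAX_ENUM_N:
        raise ValueError(f"n={n} too large for exhaustive enumeration (max {MAX_ENUM_N})")
    sequences: list[list[int]] = []
    probs: list[float] = []
    prefix = np.empty(n, dtype=np.int8)

    def descend(i: int, d: int, prob: float) -> None:
        if i == n:
            sequences.append(prefix.tolist())
            probs.append(prob)
            return
        phi = float(conditional_prob_array(spec, i, d, n))
        if phi > 0.0:
            prefix[i] = 1
            descend(i + 1, d + 1, prob * phi)
        if phi < 1.0:
            prefix[i] = 0
            descend(i + 1, d - 1, prob * (1.0 - phi))

    descend(0, 0, 1.0)
    return ReferenceSet(spec, n, np.array(sequences, dtype=np.int8), np.array(probs))


# -- forward DP over the imbalance chain ---------------------------------------

def _step_distributions(spec: DesignSpec, n: int):
    """Yield ``(i, d_values, mass, phi)`` for i = 0..n-1.

    ``mass`` is the exact distribution of ``D(i)`` *before* assignment
    ``i + 1`` and ``phi`` the conditional E-probability at each support
    point.
    """
    d_values = np.array([0], dtype=np.int64)
    mass = np.array([1.0])
    for i in range(n):
        phi = conditional_prob_array(spec, i, d_values, n)
        yield i, d_values, mass, phi
        # propagate: d -> d+1 with prob phi, d -> d-1 with prob 1-phi
        lo, hi = d_values[0] - 1, d_values[-1] + 1
        new_values = np.arange(lo, hi + 1, 2, dtype=np.int64)
        new_mass = np.zeros(new_values.size)
        up = (d_values + 1 - lo) // 2
        down = (d_values - 1 - lo) // 2
        np.add.at(new_mass, up, mass * phi)
        np.add.at(new_mass, down, mass * (1.0 - phi))
        keep = new_mass > 0.0
        d_values, mass = new_values[keep], new_mass[keep]
        mass = mass / mass.sum()


def _guess_correct_prob(
    d: np.ndarray, phi: np.ndarray, strategy: str
) -> np.ndarray:
    """P(correct guess | D = d) for the chosen guessing strategy.

    ``convergence`` guesses the under-represented arm (random at a tie);
    ``optimal`` guesses the arm whose conditional probability exceeds 1/2
    (random when phi = 1/2).
    """
    if strategy == "convergence":
        return np.where(d < 0, phi, np.where(d > 0, 1.0 - phi, 0.5))
    if strategy == "optimal":
        # at phi = 1/2 a random guess is correct with probability 1/2,
        # which coincides with max(phi, 1 - phi)
        return np.maximum(phi, 1.0 - phi)
    raise ValueError(f"unknown guessing strategy {strategy!r}")


def exact_step_metrics(
    spec: DesignSpec, n: int, strategy: str = "convergence"
) -> pd.DataFrame:
    """Exact per-step balance and randomness summaries for steps 1..n.

    Columns: ``exp_abs_imbalance`` E|D(i)|, ``exp_loss`` E[L_i] with
    L_i = D(i)^2 / i, ``cum_imb`` Imb(i), ``exp_phi_dev`` E|phi_i - 1/2|,
    ``forcing_index`` FI(i), ``p_deterministic`` P(phi_i in {0, 1}),
    ``p_correct_guess`` P(G_i = 1), ``pcg`` PCG(i).
    """
    n = spec.resolve_n(n) or n
    rows = np.empty((n, 4))  # phi_dev, p_det, p_guess, (placeholder)
    exp_abs = np.empty(n)
    exp_sq = np.empty(n)
    for i, d, mass, phi in _step_distributions(spec, n):
        rows[i, 0] = float(np.sum(mass * np.abs(phi - 0.5)))
        rows[i, 1] = float(np.sum(mass * ((phi == 0.0) | (phi == 1.0))))
        rows[i, 2] = float(np.sum(mass * _guess_correct_prob(d, phi, strategy)))
        # distribution of D(i+1) from the pre-assignment distribution
        succ_abs = mass * (phi * np.abs(d + 1) + (1.0 - phi) * np.abs(d - 1))
        succ_sq = mass * (phi * (d + 1.0) ** 2 + (1.0 - phi) * (d - 1.0) ** 2)
        exp_abs[i] = float(succ_abs.sum())
        exp_sq[i] = float(succ_sq.sum())
    steps = np.arange(1, n + 1)
    exp_loss = exp_sq / steps
    out = pd.DataFrame(
        {
            "step": steps,
            "exp_abs_imbalance": exp_abs,
            "exp_loss": exp_loss,
            "cum_imb": np.cumsum(exp_loss) / steps,
            "exp_phi_dev": rows[:, 0],
            "forcing_index": np.cumsum(rows[:, 0]) / (steps / 4.0),
            "p_deterministic": rows[:, 1],
            "p_correct_guess": rows[:, 2],
            "pcg": np.cumsum(rows[:, 2]) / steps,
        }
    )
    out.attrs["design"] = spec.label
    out.attrs["strategy"] = strategy
    return out


# -- long-run (stationary) predictability --------------------------------------

def _d_markov_transition(spec: DesignSpec, d_values: np.ndarray) -> np.ndarray:
    """Transition matrix of the imbalance walk for rules that depend on D only."""
    phi = conditional_prob_array(spec, 0, d_values)
    k = d_values.size
    P = np.zeros((k, k))
    for j, d in enumerate(d_values):
        up = np.searchsorted(d_values, d + 1)
        down = np.searchsorted(d_values, d - 1)
        if up < k and d_values[up] == d + 1:
            P[j, up] = phi[j]
        else:
            P[j, j] += phi[j]  # mass would leave the truncation window
        if 0 <= down < k and d_values[down] == d - 1:
            P[j, down] = 1.0 - phi[j]
        else:
            P[j, j] += 1.0 - phi[j]
    return P


def stationary_imbalance_distribution(
    spec: DesignSpec, truncation: int = 400
) -> tuple[np.ndarray, np.ndarray]:
    """Time-average stationary distribution of the imbalance chain.

    For MTI designs the walk lives on ``|D| <= mti``; for the unbounded
    biased-coin rules the drift toward 0 makes the chain positive
    recurrent and the state space is truncated at ``|D| = truncation``
    (the tail mass is geometrically small).  The chain has period 2; the
    returned vector is the unique solution of ``pi P = pi``, i.e. the
    long-run time average over consecutive steps.
    """
    if spec.name in MTI_DESIGNS:
        bound = spec.mti
    elif spec.name in ("BCD", "ABCD"):
        bound = truncation
    else:
        raise ValueError(f"{spec.label} has no stationary imbalance distribution")
    d_values = np.arange(-bound, bound + 1, dtype=np.int64)
    P = _d_markov_transition(spec, d_values)
    # solve pi (P - I) = 0 with sum(pi) = 1
    A = np.vstack([P.T - np.eye(d_values.size), np.ones(d_values.size)])
    b = np.zeros(d_values.size + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    return d_values, pi


def _pbd_block_average(spec: DesignSpec, strategy: str) -> tuple[float, float]:
    """Exact per-block averages of P(deterministic) and P(correct guess)."""
    bs = spec.block_size
    df = exact_step_metrics(spec, bs, strategy=strategy)
    return float(df["p_deterministic"].mean()), float(df["p_correct_guess"].mean())


def long_run_predictability(
    spec: DesignSpec,
    strategy: str = "optimal",
    method: str = "stationary",
    n_steps: int = 10_000,
) -> tuple[float, float]:
    """Long-run proportion of deterministic assignments and excess correct-guess
    probability (the increase over the 1/2 achieved against complete
    randomization), both as fractions in [0, 1].

    ``method='stationary'`` uses the closed-form stationary distribution of
    the imbalance walk (MTI and biased-coin designs) or the exact per-block
    average (PBD).  ``method='average'`` averages the exact per-step values
    over ``n_steps`` allocations, which serves as an independent
    cross-check of the stationary computation.
    """
    if spec.name == "CRD":
        return 0.0, 0.0
    if method == "average":
        if spec.name == "PBD":
            n_steps -= n_steps % spec.block_size
        df = exact_step_metrics(spec, n_steps, strategy=strategy)
        return (
            float(df["p_deterministic"].mean()),
            float(df["p_correct_guess"].mean()) - 0.5,
        )
    if method != "stationary":
        raise ValueError(f"unknown method {method!r}")
    if spec.name == "PBD":
        p_det, p_guess = _pbd_block_average(spec, strategy)
        return p_det, p_guess - 0.5
    d_values, pi = stationary_imbalance_distribution(spec)
    phi = conditional_prob_array(spec, 0, d_values)
    p_det = float(np.sum(pi * ((phi == 0.0) | (phi == 1.0))))
    p_guess = float(np.sum(pi * _guess_correct_prob(d_values, phi, strategy)))
    return p_det, p_guess - 0.5
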