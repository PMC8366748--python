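"""Simulation-based balance and randomness metrics.

The per-step summaries mirror the standard evaluation of restricted
randomization procedures:

* expected absolute imbalance ``E|D(i)|`` and expected loss
  ``E[L_i]``, ``L_i = |D(i)|^2 / i`` (the efficiency penalty of imbalance);
* cumulative average loss ``Imb(i) = (1/i) sum_{j<=i} E[L_j]``;
* the forcing index
  ``FI(i) = sum_{j<=i} E|phi_j - 1/2| / (i/4)``, which is 0 for complete
  randomization and 1 for the permuted block design with blocks of two;
* the expected proportion of correct guesses
  ``PCG(i) = (1/i) sum_{j<=i} P(G_j = 1)`` under the Blackwell-Hodges
  guessing model;
* the balance/randomness tradeoff distance
  ``d(i) = sqrt(Imb(i)^2 + FI(i)^2)`` (smaller is better).

All quantities are estimated from independent simulated sequences with
Monte Carlo standard errors; :mod:`randkit.exact_engine` provides the
matching exact values for cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .designs import (
    AllocationState,
    DesignSpec,
    allocation_probability,
    generate_sequences,
)

__all__ = [
    "MetricsTable",
    "guess_next",
    "convergence_guesses",
    "simulate_balance_metrics",
    "variance_of_difference",
]


def guess_next(
    strategy: str,
    spec: DesignSpec,
    state: AllocationState,
    rng: np.random.Generator,
    n: int | None = None,
) -> int:
    """Guess the next assignment (1 = E, 0 = C).

    ``convergence``: guess the arm assigned less frequently so far, at
    random on a tie.  ``optimal``: guess the arm whose conditional
    assignment probability exceeds 1/2, at random when it equals 1/2.
    """
    if strategy == "convergence":
        d = state.imbalance
        if d == 0:
            return int(rng.random() < 0.5)
        return int(d < 0)
    if strategy == "optimal":
        phi = allocation_probability(spec, state, n)
        if phi == 0.5:
            return int(rng.random() < 0.5)
        return int(phi > 0.5)
    raise ValueError(f"unknown guessing strategy {strategy!r}")


def convergence_guesses(
    assignments: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized convergence-strategy guesses for a batch of sequences.

    ``assignments`` has shape ``(reps, n)``; the guess at step ``j`` uses
    the imbalance after ``j - 1`` assignments.
    """
    d_prev = np.zeros_like(assignments, dtype=np.int64)
    d_prev[:, 1:] = np.cumsum(2 * assignments[:, :-1].astype(np.int64) - 1, axis=1)
    ties = rng.random(assignments.shape) < 0.5
    return np.where(d_prev == 0, ties, d_prev < 0).astype(np.int8)


def _optimal_guesses(
    probs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    ties = rng.random(probs.shape) < 0.5
    return np.where(probs == 0.5, ties, probs > 0.5).astype(np.int8)


@dataclass
class MetricsTable:
    """Per-step metric estimates for one design."""

    spec: DesignSpec
    table: pd.DataFrame
    replicates: int
    strategy: str
    expected_bias_factor: float

    @property
    def n(self) -> int:
        return len(self.table)

    def final(self, column: str) -> float:
        return float(self.table[column].iloc[-1])

    @property
    def imb(self) -> float:
        return self.final("cum_imb")

    @property
    def forcing_index(self) -> float:
        return self.final("forcing_index")

    @property
    def tradeoff(self) -> float:
        return self.final("tradeoff")


def simulate_balance_metrics(
    spec: DesignSpec,
    n: int,
    reps: int,
    strategy: str = "convergence",
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> MetricsTable:
    """Monte Carlo estimates of all per-step metrics from ``reps`` sequences.

    The forcing-index increments ``|phi_j - 1/2|`` are taken from the
    realized conditional-probability paths, so designs whose increments
    are non-random (CRD, PBD(2)) produce FI exactly.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    assignments, probs = generate_sequences(spec, n, reps, rng)
    steps = np.arange(1, n + 1)

    d_path = np.cumsum(2 * assignments.astype(np.int64) - 1, axis=1)
    abs_d = np.abs(d_path)
    loss = abs_d.astype(float) ** 2 / steps
    cum_loss = np.cumsum(loss, axis=1) / steps  # per-rep Imb(i) path

    phi_dev = np.abs(probs - 0.5)
    fi = np.cumsum(phi_dev, axis=1) / (steps / 4.0)  # per-rep FI(i) path

    if strategy == "convergence":
        guesses = convergence_guesses(assignments, rng)
    elif strategy == "optimal":
        guesses = _optimal_guesses(probs, rng)
    else:
        raise ValueError(f"unknown guessing strategy {strategy!r}")
    correct = (guesses == assignments).astype(float)
    pcg = np.cumsum(correct, axis=1) / steps

    def mean_se(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return x.mean(axis=0), x.std(axis=0, ddof=1) / np.sqrt(reps)

    abs_mean, abs_se = mean_se(abs_d.astype(float))
    loss_mean, loss_se = mean_se(loss)
    imb_mean, imb_se = mean_se(cum_loss)
    fi_mean, fi_se = mean_se(fi)
    pcg_mean, pcg_se = mean_se(pcg)
    phi_dev_mean, _ = mean_se(phi_dev)

    table = pd.DataFrame(
        {
            "step": steps,
            "exp_abs_imbalance": abs_mean,
            "exp_abs_imbalance_se": abs_se,
            "exp_loss": loss_mean,
            "exp_loss_se": loss_se,
            "cum_imb": imb_mean,
            "cum_imb_se": imb_se,
            "exp_phi_dev": phi_dev_mean,
            "forcing_index": fi_mean,
            "forcing_index_se": fi_se,
            "pcg": pcg_mean,
            "pcg_se": pcg_se,
            "tradeoff": np.sqrt(imb_mean**2 + fi_mean**2),
        }
    )
    bias_factor = float(correct.sum(axis=1).mean() - n / 2.0)
    return MetricsTable(spec, table, reps, strategy, bias_factor)


def variance_of_difference(sigma: float, n: int, final_imbalance: int) -> float:
    """Variance of the efficient estimator of the treatment difference,
    ``V = 4 sigma^2 / (n - L_n)`` with ``L_n = |D(n)|^2 / n``.

    ``V`` is minimized at ``D(n) = 0`` (the balanced trial); a one-arm
    trial (``|D(n)| = n``) leaves the difference inestimable.
    """
    if abs(final_imbalance) >= n:
        raise ValueError("|D(n)| = n: one-arm trial, treatment difference inestimable")
    loss = final_imbalance**2 / n
    return 4.0 * sigma**2 / (n - loss)
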