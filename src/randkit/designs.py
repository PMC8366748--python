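"""Restricted randomization procedures for two-arm 1:1 clinical trials.

A randomization sequence is a vector ``delta`` in {0, 1}^n, with 1 coding
the experimental arm E and 0 the control arm C.  Every procedure here is a
sequential rule: given the allocation history, the (i+1)st subject is
assigned to E with some conditional probability ``phi``.  For all supported
procedures ``phi`` depends on the history only through the step index ``i``
and the treatment imbalance ``D(i) = N_E(i) - N_C(i)`` (for the permuted
block design the block position is a function of ``i``; for the quota
designs the group counts are recovered from ``(i, D)``), which is what makes
exact dynamic-programming computations possible (see
:mod:`randkit.exact_engine`).

Supported procedures
--------------------
CRD
    Complete randomization: a fair coin at every step.
RAND
    Random allocation rule: uniform distribution over all sequences with
    exactly n/2 assignments per arm; sequentially,
    ``phi = (n/2 - N_E(i)) / (n - i)``.
TBD
    Truncated binomial design: a fair coin until one arm reaches its quota
    n/2, deterministic completion thereafter.
PBD
    Permuted block design with even block size 2b: the random allocation
    rule applied independently within consecutive blocks.
BSD
    Big stick design: a fair coin while ``|D| < mti``; at the maximum
    tolerated imbalance the next assignment is forced toward balance.
BCD
    Efron's biased coin: a fair coin at ``D = 0``; otherwise probability
    ``p > 1/2`` for the under-represented arm.
BCDWIT
    Biased coin design with imbalance tolerance: Efron's rule with a
    deterministic correction at ``|D| = mti``.
ABCD
    Adjustable biased coin design with exponent ``a``:
    ``phi = 1 / (1 + D^a)`` for ``D >= 1`` and symmetrically for ``D <= -1``.
GBCD
    Generalized (adaptive) biased coin design with exponent ``gamma``:
    ``phi = N_C^gamma / (N_E^gamma + N_C^gamma)``, 1/2 at the first step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = [
    "DesignSpec",
    "AllocationState",
    "AllocationSequence",
    "crd",
    "rand_rule",
    "tbd",
    "pbd",
    "bsd",
    "bcd",
    "bcdwit",
    "abcd",
    "gbcd",
    "allocation_probability",
    "conditional_prob_array",
    "generate_sequence",
    "generate_sequences",
    "sequence_probability",
]

DESIGN_NAMES = ("CRD", "RAND", "TBD", "PBD", "BSD", "BCDWIT", "BCD", "ABCD", "GBCD")

#: designs that guarantee N_E(n) = N_C(n) = n/2 whenever n is a multiple of
#: the block size (the block size of RAND/TBD being n itself)
QUOTA_DESIGNS = ("RAND", "TBD", "PBD")

#: designs with a hard bound on |D(i)|
MTI_DESIGNS = ("BSD", "BCDWIT")


@dataclass(frozen=True)
class DesignSpec:
    """A named restricted randomization procedure and its tuning parameters.

    Parameters not used by the named procedure must be left as ``None``;
    parameters the procedure requires are validated on construction.
    ``n`` (the total sample size) is required by RAND and TBD, whose rules
    depend on the quota ``n/2``.
    """

    name: str
    block_size: int | None = None
    mti: int | None = None
    coin_p: float | None = None
    exponent_a: float | None = None
    gamma: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.name not in DESIGN_NAMES:
            raise ValueError(f"unknown design {self.name!r}; expected one of {DESIGN_NAMES}")
        if self.name == "PBD":
            if self.block_size is None or self.block_size < 2 or self.block_size % 2:
                raise ValueError("PBD requires a positive even block_size")
        if self.name in MTI_DESIGNS:
            if self.mti is None or self.mti < 1:
                raise ValueError(f"{self.name} requires a positive integer mti")
        if self.name in ("BCD", "BCDWIT"):
            if self.coin_p is None or not (0.5 < self.coin_p <= 1.0):
                raise ValueError(f"{self.name} requires coin_p in (0.5, 1]")
        if self.name == "ABCD" and (self.exponent_a is None or self.exponent_a <= 0):
            raise ValueError("ABCD requires a positive exponent_a")
        if self.name == "GBCD" and (self.gamma is None or self.gamma <= 0):
            raise ValueError("GBCD requires a positive gamma")
        if self.name in ("RAND", "TBD"):
            if self.n is None or self.n < 2 or self.n % 2:
                raise ValueError(f"{self.name} requires an even total sample size n")

    @property
    def label(self) -> str:
        """Short display label, e.g. ``BSD(3)`` or ``BCDWIT(2/3, 3)``."""
        if self.name == "PBD":
            return f"PBD({self.block_size})"
        if self.name == "BSD":
            return f"BSD({self.mti})"
        if self.name == "BCD":
            return f"BCD({_fmt_p(self.coin_p)})"
        if self.name == "BCDWIT":
            return f"BCDWIT({_fmt_p(self.coin_p)}, {self.mti})"
        if self.name == "ABCD":
            return f"ABCD({_fmt_num(self.exponent_a)})"
        if self.name == "GBCD":
            return f"GBCD({_fmt_num(self.gamma)})"
        if self.name == "RAND":
            return "Rand"
        return self.name

    def resolve_n(self, n: int | None) -> int | None:
        """Reconcile the spec's sample size with an explicitly passed one."""
        if self.n is not None and n is not None and self.n != n:
            raise ValueError(f"design fixes n={self.n} but n={n} was requested")
        return self.n if n is None else n


def _fmt_p(p: float) -> str:
    return "2/3" if abs(p - 2.0 / 3.0) < 1e-12 else f"{p:g}"


def _fmt_num(x: float) -> str:
    return f"{int(x)}" if float(x).is_integer() else f"{x:g}"


# -- convenience constructors -------------------------------------------------

def crd() -> DesignSpec:
    return DesignSpec("CRD")


def rand_rule(n: int) -> DesignSpec:
    return DesignSpec("RAND", n=n)


def tbd(n: int) -> DesignSpec:
    return DesignSpec("TBD", n=n)


def pbd(block_size: int) -> DesignSpec:
    return DesignSpec("PBD", block_size=block_size)


def bsd(mti: int) -> DesignSpec:
    return DesignSpec("BSD", mti=mti)


def bcd(coin_p: float) -> DesignSpec:
    return DesignSpec("BCD", coin_p=coin_p)


def bcdwit(coin_p: float, mti: int) -> DesignSpec:
    return DesignSpec("BCDWIT", coin_p=coin_p, mti=mti)


def abcd(exponent_a: float) -> DesignSpec:
    return DesignSpec("ABCD", exponent_a=exponent_a)


def gbcd(gamma: float) -> DesignSpec:
    return DesignSpec("GBCD", gamma=gamma)


@dataclass
class AllocationState:
    """Running allocation history after ``step`` assignments."""

    step: int
    n_e: int
    n_c: int
    assignments: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_e < 0 or self.n_c < 0 or self.n_e + self.n_c != self.step:
            raise ValueError("inconsistent state: n_e + n_c must equal step")

    @property
    def imbalance(self) -> int:
        return self.n_e - self.n_c

    @classmethod
    def from_assignments(cls, assignments: Iterable[int]) -> "AllocationState":
        arr = np.asarray(list(assignments), dtype=np.int8)
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise ValueError("assignments must be 0/1")
        n_e = int(arr.sum())
        return cls(step=arr.size, n_e=n_e, n_c=arr.size - n_e, assignments=arr)


@dataclass
class AllocationSequence:
    """A realized randomization sequence with its conditional probabilities.

    ``conditional_probs[j]`` is the probability of assigning E that was in
    force at step ``j + 1`` (i.e. the realized ``phi_{j+1}``), regardless of
    which arm was actually assigned.
    """

    spec: DesignSpec
    assignments: np.ndarray
    conditional_probs: np.ndarray

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, dtype=np.int8)
        self.conditional_probs = np.asarray(self.conditional_probs, dtype=float)
        if self.assignments.shape != self.conditional_probs.shape:
            raise ValueError("assignments and conditional_probs must align")

    @property
    def n(self) -> int:
        return self.assignments.size

    @property
    def n_e(self) -> int:
        return int(self.assignments.sum())

    @property
    def n_c(self) -> int:
        return self.n - self.n_e

    @property
    def imbalance_path(self) -> np.ndarray:
        """D(i) for i = 1..n."""
        return np.cumsum(2 * self.assignments.astype(np.int64) - 1)

    def to_string(self) -> str:
        return "".join("E" if a else "C" for a in self.assignments)

    @classmethod
    def from_string(
        cls, spec: DesignSpec, s: str, n: int | None = None
    ) -> "AllocationSequence":
        """Build a sequence from an "E"/"C" (or "1"/"0") string, recomputing
        the conditional probabilities the design would have used."""
        arr = np.array([1 if ch in "E1" else 0 for ch in s], dtype=np.int8)
        probs = _conditional_path(spec, arr, spec.resolve_n(n if n is not None else arr.size))
        return cls(spec, arr, probs)


# -- the conditional assignment rule ------------------------------------------

def conditional_prob_array(
    spec: DesignSpec, i: int, d: np.ndarray | int, n: int | None = None
) -> np.ndarray:
    """Probability of assigning E at step ``i + 1`` given imbalance ``D(i) = d``.

    Vectorized over ``d`` (history enters only through ``(i, d)``; for PBD
    the block position is ``i mod block_size``, and for the quota designs
    the group counts are ``N_E = (i + d) / 2``, ``N_C = (i - d) / 2``).
    """
    d = np.asarray(d, dtype=float)
    name = spec.name

    if name == "CRD":
        return np.full_like(d, 0.5)

    if name == "RAND":
        n = spec.resolve_n(n)
        if i >= n:
            raise ValueError(f"step {i} beyond the design horizon n={n}")
        n_e = (i + d) / 2.0
        return np.clip((n / 2.0 - n_e) / (n - i), 0.0, 1.0)

    if name == "TBD":
        n = spec.resolve_n(n)
        if i >= n:
            raise ValueError(f"step {i} beyond the design horizon n={n}")
        n_e = (i + d) / 2.0
        n_c = (i - d) / 2.0
        phi = np.full_like(d, 0.5)
        phi = np.where(n_e >= n / 2.0, 0.0, phi)
        phi = np.where(n_c >= n / 2.0, 1.0, phi)
        return phi

    if name == "PBD":
        bs = spec.block_size
        k = i % bs
        # blocks restore perfect balance, so the within-block E count is
        # (position + current total imbalance) / 2
        e_blk = (k + d) / 2.0
        return np.clip((bs / 2.0 - e_blk) / (bs - k), 0.0, 1.0)

    if name == "BSD":
        m = spec.mti
        phi = np.full_like(d, 0.5)
        phi = np.where(d >= m, 0.0, phi)
        phi = np.where(d <= -m, 1.0, phi)
        return phi

    if name == "BCD":
        p = spec.coin_p
        phi = np.full_like(d, 0.5)
        phi = np.where(d > 0, 1.0 - p, phi)
        phi = np.where(d < 0, p, phi)
        return phi

    if name == "BCDWIT":
        p, m = spec.coin_p, spec.mti
        phi = np.full_like(d, 0.5)
        phi = np.where(d > 0, 1.0 - p, phi)
        phi = np.where(d < 0, p, phi)
        phi = np.where(d >= m, 0.0, phi)
        phi = np.where(d <= -m, 1.0, phi)
        return phi

    if name == "ABCD":
        a = spec.exponent_a
        absd = np.abs(d)
        with np.errstate(over="ignore"):
            pw = np.where(absd > 0, absd, 1.0) ** a
        phi = np.full_like(d, 0.5)
        phi = np.where(d >= 1, 1.0 / (1.0 + pw), phi)
        phi = np.where(d <= -1, pw / (1.0 + pw), phi)
        return phi

    if name == "GBCD":
        g = spec.gamma
        n_e = (i + d) / 2.0
        n_c = (i - d) / 2.0
        with np.errstate(divide="ignore", invalid="ignore"):
            num = n_c**g
            den = n_e**g + n_c**g
            phi = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.5)
        return phi

    raise AssertionError("unreachable")


def allocation_probability(
    spec: DesignSpec, state: AllocationState, n: int | None = None
) -> float:
    """Conditional probability of assigning E to the next subject.

    Raises if the state violates the design's invariants (e.g. an imbalance
    beyond the maximum tolerated imbalance, or a quota already exceeded).
    """
    d = state.imbalance
    if spec.name in MTI_DESIGNS and abs(d) > spec.mti:
        raise ValueError(f"|D|={abs(d)} exceeds the MTI bound {spec.mti}")
    if spec.name == "PBD":
        k = state.step % spec.block_size
        if abs(d) > min(k, spec.block_size - k) or (k + d) % 2:
            raise ValueError("state inconsistent with the block structure")
    if spec.name in ("RAND", "TBD"):
        nn = spec.resolve_n(n)
        if max(state.n_e, state.n_c) > nn // 2:
            raise ValueError("a group quota has been exceeded")
    return float(conditional_prob_array(spec, state.step, d, n))


def _conditional_path(
    spec: DesignSpec, assignments: np.ndarray, n: int | None
) -> np.ndarray:
    n_total = assignments.size if n is None else n
    probs = np.empty(assignments.size)
    d = 0
    for i, a in enumerate(assignments):
        probs[i] = conditional_prob_array(spec, i, d, n_total)
        d += 1 if a else -1
    return probs


# -- sequence generation -------------------------------------------------------

def generate_sequence(
    spec: DesignSpec, n: int, rng: np.random.Generator
) -> AllocationSequence:
    """Draw one allocation sequence of length ``n`` step by step."""
    assignments, probs = generate_sequences(spec, n, 1, rng)
    return AllocationSequence(spec, assignments[0], probs[0])


def generate_sequences(
    spec: DesignSpec, n: int, reps: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``reps`` independent sequences at once.

    Returns ``(assignments, conditional_probs)``, both of shape
    ``(reps, n)``.  The generation loop is over allocation steps, with all
    replicates advanced in parallel; this is the workhorse behind the
    Monte Carlo metrics and the re-randomization tests.
    """
    n = spec.resolve_n(n) or n
    if n < 1:
        raise ValueError("n must be >= 1")
    if spec.name in QUOTA_DESIGNS:
        block = n if spec.name in ("RAND", "TBD") else spec.block_size
        if spec.name in ("RAND", "TBD") and n % 2:
            raise ValueError(f"{spec.name} requires even n")
    assignments = np.empty((reps, n), dtype=np.int8)
    probs = np.empty((reps, n), dtype=float)
    d = np.zeros(reps, dtype=np.int64)
    for i in range(n):
        phi = conditional_prob_array(spec, i, d, n)
        a = (rng.random(reps) < phi).astype(np.int8)
        assignments[:, i] = a
        probs[:, i] = phi
        d += 2 * a.astype(np.int64) - 1
    return assignments, probs


def sequence_probability(
    spec: DesignSpec, assignments: Iterable[int], n: int | None = None
) -> float:
    """Probability of observing a given sequence under the design.

    The probability is the product over steps of the conditional
    probability of the realized assignment; it is 0 for sequences that are
    infeasible under the design.
    """
    arr = np.asarray(list(assignments) if not isinstance(assignments, np.ndarray) else assignments, dtype=np.int8)
    n_total = spec.resolve_n(n)
    if n_total is not None and arr.size != n_total:
        raise ValueError(f"sequence length {arr.size} != design n {n_total}")
    n_total = arr.size if n_total is None else n_total
    prob = 1.0
    d = 0
    for i, a in enumerate(arr):
        if spec.name in MTI_DESIGNS and abs(d) > spec.mti:
            return 0.0
        phi = float(conditional_prob_array(spec, i, d, n_total))
        prob *= phi if a else 1.0 - phi
        if prob == 0.0:
            return 0.0
        d += 1 if a else -1
    return prob
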