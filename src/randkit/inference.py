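"""Population-model and randomization-model tests for two-arm trials.

Population-model tests treat the data as random samples: the pooled
two-sample t-test and Wald tests from Cox proportional-hazards fits.
Randomization-model tests condition on the observed responses and refer
the observed statistic to its distribution over re-randomized allocation
sequences drawn from (or enumerated over) the design's reference set —
no distributional assumptions on the outcomes are needed, only that the
trial actually used the stated randomization procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .designs import AllocationSequence, DesignSpec, generate_sequences
from .exact_engine import ReferenceSet

__all__ = [
    "TestResult",
    "t_test_pooled",
    "linear_rank_statistic",
    "mean_difference",
    "mc_randomization_test",
    "exact_randomization_pvalue",
    "fisher_exact_1sided",
    "ph_test",
    "power_ttest",
    "effect_for_power",
]

_REL_TOL = 1e-12  # tie tolerance when comparing re-randomized statistics


@dataclass
class TestResult:
    method: str
    statistic: float
    p_value: float
    sided: str
    n_resamples: int | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _split(y: np.ndarray, delta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    delta = np.asarray(delta)
    if y.shape != delta.shape:
        raise ValueError("responses and assignments must have equal length")
    return y[delta == 1], y[delta == 0]


def mean_difference(y: np.ndarray, delta: np.ndarray) -> float:
    """Observed mean difference ``Ybar_E - Ybar_C``."""
    ye, yc = _split(y, delta)
    if ye.size == 0 or yc.size == 0:
        raise ValueError("mean difference undefined with an empty arm")
    return float(ye.mean() - yc.mean())


def t_test_pooled(y: np.ndarray, delta: np.ndarray) -> TestResult:
    """Classical equal-variance two-sample t-test (two-sided).

    The statistic uses the pooled variance with ``n - 2`` degrees of
    freedom.  With zero pooled variance the statistic is defined as 0 when
    the arm means are also equal (p = 1), and an error otherwise.
    """
    ye, yc = _split(y, delta)
    n = ye.size + yc.size
    if ye.size == 0 or yc.size == 0:
        raise ValueError("t-test requires both arms nonempty")
    if n < 3:
        raise ValueError("t-test requires n >= 3")
    sp2 = (np.sum((ye - ye.mean()) ** 2) + np.sum((yc - yc.mean()) ** 2)) / (n - 2)
    diff = ye.mean() - yc.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            return TestResult("t_test", 0.0, 1.0, "two")
        raise ValueError("zero pooled variance with unequal means")
    t = diff / np.sqrt(sp2 * (1.0 / ye.size + 1.0 / yc.size))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return TestResult("t_test", float(t), float(p), "two", extras={"df": n - 2})


def linear_rank_statistic(y: np.ndarray, delta: np.ndarray) -> float:
    """Linear rank statistic ``S = sum_i delta_i (a_i - abar)`` with
    mid-ranks for ties."""
    y = np.asarray(y, dtype=float)
    delta = np.asarray(delta)
    a = stats.rankdata(y)
    return float(np.sum(delta * (a - a.mean())))


def _centered_ranks(y: np.ndarray) -> np.ndarray:
    a = stats.rankdata(y)
    return a - a.mean()


def mc_randomization_test(
    spec: DesignSpec,
    observed: AllocationSequence | np.ndarray,
    y: np.ndarray,
    statistic: str = "mean_diff",
    L: int = 10_000,
    sided: str = "two",
    rng: np.random.Generator | None = None,
    conservative: bool = False,
) -> TestResult:
    """Monte Carlo randomization test.

    Draws ``L`` fresh sequences from the design, recomputes the statistic
    on each with the responses held fixed, and reports the proportion at
    least as extreme as observed: ``P = (1/L) sum 1{|S_l| >= |S_obs|}``
    (two-sided) or the one-sided analog.  ``conservative=True`` applies
    the ``(1 + count) / (1 + L)`` variant instead of the plain proportion.

    Re-randomized sequences with an empty arm (possible under CRD at small
    n) leave the mean difference undefined; such draws are replaced by
    fresh ones and their number is reported in ``extras``.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    y = np.asarray(y, dtype=float)
    n = y.size
    delta_obs = (
        observed.assignments
        if isinstance(observed, AllocationSequence)
        else np.asarray(observed, dtype=np.int8)
    )

    if statistic == "mean_diff":
        s_obs = mean_difference(y, delta_obs)
        values = y
        use_weights = True
    elif statistic == "rank":
        s_obs = linear_rank_statistic(y, delta_obs)
        values = _centered_ranks(y)
        use_weights = False
    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    seqs, _ = generate_sequences(spec, n, L, rng)
    n_resampled = 0
    if use_weights:
        ne = seqs.sum(axis=1)
        bad = (ne == 0) | (ne == n)
        while bad.any():
            n_resampled += int(bad.sum())
            fresh, _ = generate_sequences(spec, n, int(bad.sum()), rng)
            seqs[bad] = fresh
            ne = seqs.sum(axis=1)
            bad = (ne == 0) | (ne == n)
        w = seqs / ne[:, None] - (1 - seqs) / (n - ne)[:, None]
        s = w @ values
    else:
        s = seqs @ values

    tol = _REL_TOL * max(1.0, abs(s_obs))
    if sided == "two":
        count = int(np.sum(np.abs(s) >= abs(s_obs) - tol))
    elif sided == "one_favor_E":
        count = int(np.sum(s >= s_obs - tol))
    else:
        raise ValueError(f"unknown sided {sided!r}")
    p = (1 + count) / (1 + L) if conservative else count / L
    return TestResult(
        f"rand_{statistic}",
        s_obs,
        float(p),
        sided,
        n_resamples=L,
        extras={"n_resampled_empty_arm": n_resampled},
    )


def exact_randomization_pvalue(
    ref: ReferenceSet,
    observed: AllocationSequence | np.ndarray,
    y: np.ndarray,
    statistic: str = "prop_diff",
    direction: str = "one_favor_E",
) -> TestResult:
    """Exact randomization p-value by reference-set enumeration.

    The p-value is the sum of probabilities of all sequences in the
    reference set whose statistic is at least as large in favor of E as
    the observed one.  For binary responses the statistic is the
    difference in success proportions; for continuous responses the mean
    difference; ``rank`` uses the linear rank statistic.  The observed
    sequence must belong to the reference set.
    """
    y = np.asarray(y, dtype=float)
    delta_obs = (
        observed.assignments
        if isinstance(observed, AllocationSequence)
        else np.asarray(observed, dtype=np.int8)
    )
    idx = ref.index_of(delta_obs)  # design-violation check
    seqs = ref.sequences
    ne = seqs.sum(axis=1)
    if statistic in ("prop_diff", "mean_diff"):
        if np.any(ne == 0) or np.any(ne == ref.n):
            raise ValueError("reference set contains a one-arm sequence; use rank")
        s = seqs @ y / ne - (y.sum() - seqs @ y) / (ref.n - ne)
    elif statistic == "rank":
        s = seqs @ _centered_ranks(y)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    s_obs = float(s[idx])
    tol = _REL_TOL * max(1.0, abs(s_obs))
    if direction == "one_favor_E":
        p = float(ref.probs[s >= s_obs - tol].sum())
    elif direction == "two":
        p = float(ref.probs[np.abs(s) >= abs(s_obs) - tol].sum())
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return TestResult(
        f"exact_rand_{statistic}", s_obs, min(p, 1.0), direction, n_resamples=ref.size
    )


def fisher_exact_1sided(
    succ_e: int, n_e: int, succ_c: int, n_c: int
) -> TestResult:
    """One-sided Fisher exact test of H1: p_E > p_C (hypergeometric tail)."""
    for v, total in ((succ_e, n_e), (succ_c, n_c)):
        if v < 0 or total < 0 or v > total:
            raise ValueError("counts must satisfy 0 <= successes <= group size")
    table = np.array([[succ_e, n_e - succ_e], [succ_c, n_c - succ_c]])
    odds, p = stats.fisher_exact(table, alternative="greater")
    return TestResult(
        "fisher_1sided",
        float(succ_e / n_e - succ_c / n_c) if n_e and n_c else float("nan"),
        float(p),
        "one_favor_E",
        extras={"odds_ratio": float(odds)},
    )


def ph_test(
    times: np.ndarray,
    events: np.ndarray | None,
    delta: np.ndarray,
    covariate_u: np.ndarray | None = None,
    adjust: bool = False,
) -> TestResult:
    """Cox proportional-hazards Wald test for the treatment effect.

    Fits the partial likelihood (Breslow tie handling) with the treatment
    indicator, plus the covariate when ``adjust`` is true, and reports the
    Wald p-value for the treatment coefficient.  Convergence failures are
    raised, not silenced.
    """
    import pandas as pd
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    times = np.asarray(times, dtype=float)
    delta = np.asarray(delta)
    if times.size < 10:
        raise ValueError("ph_test requires n >= 10")
    data = {"time": times, "event": np.ones_like(times) if events is None else np.asarray(events), "treatment": delta.astype(float)}
    cols = ["treatment"]
    if adjust:
        if covariate_u is None:
            raise ValueError("adjust=True requires covariate_u")
        data["u"] = np.asarray(covariate_u, dtype=float)
        cols.append("u")
    df = pd.DataFrame(data)
    fitter = CoxPHFitter()
    try:
        fitter.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as err:  # pragma: no cover - rare
        raise RuntimeError(f"Cox model failed to converge: {err}") from err
    coef = float(fitter.params_["treatment"])
    se = float(fitter.standard_errors_["treatment"])
    z = coef / se
    p = 2.0 * stats.norm.sf(abs(z))
    return TestResult(
        "ph_wald_adjusted" if adjust else "ph_wald",
        z,
        float(p),
        "two",
        extras={"log_hr": coef, "se": se},
    )


def power_ttest(n: int, effect: float, alpha: float = 0.05) -> float:
    """Exact power of the balanced two-sample t-test (noncentral t).

    ``effect`` is the standardized difference Delta/sigma; ``n`` the total
    sample size split equally between arms.
    """
    from statsmodels.stats.power import TTestIndPower

    if n % 2:
        raise ValueError("n must be even for the balanced design")
    return float(
        TTestIndPower().power(
            effect_size=effect, nobs1=n // 2, alpha=alpha, ratio=1.0
        )
    )


def effect_for_power(n: int, power: float, alpha: float = 0.05) -> float:
    """Standardized effect size Delta/sigma giving the target power."""
    from statsmodels.stats.power import TTestIndPower

    return float(
        TTestIndPower().solve_power(
            nobs1=n // 2, power=power, alpha=alpha, ratio=1.0
        )
    )
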