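"""The hierarchical randomization test and its inversion into intervals.

The test proceeds by (1) aggregating observations to one mean per treated
entity and computing the observed statistic; (2) hierarchically bootstrapping
the entities' nested observations, re-aggregating, and permuting treatment
labels within blocks, recording the statistic for every
(bootstrap replicate, permutation) pair; (3) reporting the fraction of the
resulting null distribution as or more extreme (in absolute value) than the
observed statistic — the two-tailed p-value.

Confidence intervals come from test inversion: a candidate effect size
``b`` is rejected when the test of H0: beta = b (run on the data with
``b * x`` subtracted) rejects; the interval collects the non-rejected
values.  The rejection boundary is located iteratively and unstudentized
back to the units of the beta coefficient.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as _st
from .design import ClusterIndex, DesignError, DesignSpec, DesignTable, encode_design
from .resampling import (
    BootstrapPlan,
    PermutationPlan,
    aggregate_treated_means,
    bootstrap_resample,
    build_permutation_plan,
    count_permutations,
    enumerate_bootstrap_resamples,
    permutation_matrix,
    sample_permutation_matrix,
)

__all__ = [
    "NullDistribution",
    "TestResult",
    "ConfidenceInterval",
    "ConvergenceError",
    "hypothesis_test",
    "empirical_p_value",
    "confidence_interval",
    "achievable_alpha",
]


class ConvergenceError(RuntimeError):
    """Interval bound search failed to converge; carries the last bracket."""

    def __init__(self, message, bracket):
        super().__init__(message)
        self.bracket = bracket


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NullDistribution:
    values: np.ndarray
    n_bootstraps: int
    n_permutations_per_bootstrap: int
    exhaustive: bool

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float).ravel()
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class TestResult:
    observed: float
    p_two_tailed: float
    effect: _st.EffectEstimate
    statistic: str
    null: NullDistribution
    total_permutations: int
    seed: object

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "observed": self.observed,
            "p_two_tailed": self.p_two_tailed,
            "beta_hat": self.effect.beta_hat,
            "se_beta": self.effect.se_beta,
            "n_bootstraps": self.null.n_bootstraps,
            "n_permutations_per_bootstrap": self.null.n_permutations_per_bootstrap,
            "n_null": len(self.null),
            "exhaustive_permutations": self.null.exhaustive,
            "total_distinct_permutations": self.total_permutations,
            "achievable_alpha": 2.0 / self.total_permutations,
            "seed": self.seed,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


@dataclass(frozen=True)
class ConfidenceInterval:
    lower: float
    upper: float
    level: float
    beta_hat: float
    iterations_used: int
    achieved_resolution: float
    seed: object = None

    def __contains__(self, value) -> bool:
        return self.lower <= float(value) <= self.upper

    def to_dict(self) -> dict:
        return {
            "lower": self.lower,
            "upper": self.upper,
            "level": self.level,
            "beta_hat": self.beta_hat,
            "iterations_used": self.iterations_used,
            "achieved_resolution": self.achieved_resolution,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# Internals
# ---------------------------------------------------------------------------

def _as_table(table) -> DesignTable:
    if isinstance(table, DesignTable):
        return table
    if isinstance(table, pd.DataFrame):
        return DesignTable(table)
    raise TypeError("expected a DesignTable or pandas DataFrame")


def _resolve_statistic(statistic: str, index: ClusterIndex) -> str:
    n_labels = len(index.treatment_label_names)
    if statistic == "auto":
        statistic = "t" if n_labels == 2 else "corr"
    if statistic == "t" and n_labels != 2:
        raise DesignError(
            f"the t statistic needs exactly two treatment groups, got {n_labels}; "
            "use statistic='corr'"
        )
    if statistic == "corr" and index.n_entities < 4:
        raise DesignError("the studentized covariance statistic needs >= 4 treated entities")
    if statistic not in ("t", "corr"):
        raise ValueError(f"unknown statistic {statistic!r} (use 't', 'corr' or 'auto')")
    return statistic


def _observed_statistic(statistic: str, index: ClusterIndex, response=None) -> tuple[float, np.ndarray]:
    # computed through the same batch kernels as the null distribution so
    # that exact ties (identity permutation in pure permutation tests) are
    # reproduced bit-for-bit and the >= tie rule counts them
    means = _agg_means(index, response, rows=None)
    codes = index.entity_label[None, :].astype(float)
    return float(_batch(statistic, codes, means)[0]), means


def _agg_means(index: ClusterIndex, response, rows) -> np.ndarray:
    if response is None:
        return aggregate_treated_means(index, rows)
    E = index.n_entities
    ent = index.entity_of_row if rows is None else index.entity_of_row[rows]
    y = response if rows is None else response[rows]
    counts = np.bincount(ent, minlength=E)
    sums = np.bincount(ent, weights=y, minlength=E)
    return sums / counts


def _batch(statistic: str, codes: np.ndarray, y: np.ndarray) -> np.ndarray:
    if statistic == "t":
        return _st.batch_welch_t(codes, y)
    return _st.batch_studentized_covariance(codes, y)


def _null_statistics(
    statistic: str,
    spec: DesignSpec,
    index: ClusterIndex,
    plan: PermutationPlan,
    bootstraps,
    rng: np.random.Generator,
    response=None,
    boot_cap: int = 20_000,
) -> NullDistribution:
    """Resampled statistics for every (bootstrap replicate, permutation)."""
    pure_permutation = not spec.resample_levels
    if pure_permutation:
        replicate_rows = [None]
    elif bootstraps == "all":
        replicate_rows = enumerate_bootstrap_resamples(spec, index, cap=boot_cap)
    else:
        bplan = BootstrapPlan(int(bootstraps), spec.resample_levels)
        replicate_rows = [bootstrap_resample(index, bplan, rng) for _ in range(int(bootstraps))]
    n_boot = len(replicate_rows)
    means = np.empty((index.n_entities, n_boot))
    for j, rows in enumerate(replicate_rows):
        means[:, j] = _agg_means(index, response, rows)

    if plan.mode == "exhaustive":
        codes = permutation_matrix(plan)
        values = _batch(statistic, codes, means)  # (P, B)
        n_perm = codes.shape[0]
    else:
        n_perm = int(plan.requested)
        values = np.empty((n_perm, n_boot))
        for j in range(n_boot):
            codes = sample_permutation_matrix(plan, n_perm, rng)
            values[:, j] = _batch(statistic, codes, means[:, j])
    return NullDistribution(
        values=values.ravel(),
        n_bootstraps=n_boot,
        n_permutations_per_bootstrap=n_perm,
        exhaustive=plan.mode == "exhaustive",
    )


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def empirical_p_value(null, observed: float, plus_one: bool = False) -> float:
    """Two-tailed p: fraction of null values with \\|v\\| >= \\|observed\\|.

    Ties count as extreme.  ``plus_one`` applies the conservative
    (count + 1) / (N + 1) correction that treats the observed statistic as
    one more draw from the null.
    """
    values = null.values if isinstance(null, NullDistribution) else np.asarray(null, dtype=float)
    if values.size == 0:
        raise ValueError("empty null distribution")
    count = int(np.count_nonzero(np.abs(values) >= abs(observed)))
    if plus_one:
        return (count + 1) / (values.size + 1)
    return count / values.size


def achievable_alpha(spec: DesignSpec, index: ClusterIndex) -> float:
    """Smallest two-tailed level resolvable by the finite permutation set.

    Equal to 2 divided by the number of distinct label arrangements: with
    3 entities per group this is 2/20 = 0.1; with 4 per group, 2/70.
    """
    return 2.0 / count_permutations(spec, index)


def hypothesis_test(
    table,
    treatment_level: int = 1,
    statistic: str = "auto",
    bootstraps=100,
    permutations=1000,
    skip_levels=(),
    seed=None,
    interaction: bool | None = None,
    plus_one: bool = False,
    permutation_cap: int = 100_000,
) -> TestResult:
    """Run the full hierarchical randomization test.

    Parameters
    ----------
    table:
        :class:`DesignTable` or long-format DataFrame (levels outermost to
        innermost, response last).
    treatment_level:
        1-based index of the treatment column.
    statistic:
        ``"t"`` (Welch-form, two groups), ``"corr"`` (studentized
        covariance, any number of groups with linear dose coding), or
        ``"auto"``.
    bootstraps:
        Number of bootstrap replicates, or ``"all"`` to enumerate every
        ordered bootstrap outcome (tiny designs only).  Ignored (single
        pass) when the design has no bootstrappable level, in which case
        the procedure degrades to a pure block permutation test.
    permutations:
        Number of sampled label arrangements per bootstrap replicate, or
        ``"all"`` to enumerate the distinct set once per replicate.
    """
    dt = _as_table(table)
    spec, index = encode_design(dt, treatment_level, skip_levels, interaction)
    statistic = _resolve_statistic(statistic, index)
    plan = build_permutation_plan(spec, index, permutations, cap=permutation_cap)
    rng = np.random.default_rng(seed)

    if np.ptp(index.response) == 0:
        warnings.warn("constant response; p-value is 1 by construction", stacklevel=2)
        x = index.entity_label.astype(float)
        effect = _st.EffectEstimate(0.0, float("inf"), 0.0)
        null = NullDistribution(np.zeros(1), 0, 0, plan.mode == "exhaustive")
        return TestResult(0.0, 1.0, effect, statistic, null, plan.total_distinct, seed)

    observed, means = _observed_statistic(statistic, index)
    null = _null_statistics(statistic, spec, index, plan, bootstraps, rng)
    p = empirical_p_value(null, observed, plus_one=plus_one)
    effect = _st.beta_and_se(index.entity_label.astype(float), means, statistic)
    return TestResult(
        observed=float(observed),
        p_two_tailed=float(p),
        effect=effect,
        statistic=statistic,
        null=null,
        total_permutations=plan.total_distinct,
        seed=seed,
    )


def confidence_interval(
    table,
    treatment_level: int = 1,
    statistic: str = "auto",
    level: float = 0.95,
    bootstraps=100,
    permutations=1000,
    skip_levels=(),
    seed=None,
    interaction: bool | None = None,
    max_iterations: int = 10,
    rtol: float = 0.02,
    permutation_cap: int = 100_000,
) -> ConfidenceInterval:
    """Effect-size confidence interval by test inversion.

    A candidate effect ``b`` lies outside the interval when the test of
    H0: beta = b rejects, i.e. when the observed statistic on the shifted
    data ``y - b * x`` exceeds the interpolated ``level`` quantile of the
    absolute resampled statistics under that shift.  Each bound is the root
    of that (deterministic, seeded) margin curve, located by bisection from
    a starting bracket of ``beta_hat +/- 4 * se`` (expanded if needed) and
    refined until the bracket is narrower than ``rtol * se`` or
    ``max_iterations`` resampling rounds have been spent per bound; the
    result is already in beta units (the quantile is unstudentized through
    ``se(beta_hat)`` implicitly by the shift construction).
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    dt = _as_table(table)
    spec, index = encode_design(dt, treatment_level, skip_levels, interaction)
    statistic = _resolve_statistic(statistic, index)
    plan = build_permutation_plan(spec, index, permutations, cap=permutation_cap)
    resolution = 2.0 / plan.total_distinct
    alpha = 1.0 - level
    if alpha < resolution - 1e-12:
        best = 1.0 - resolution
        raise DesignError(
            f"a {level:.0%} interval needs a two-tailed tail probability of "
            f"{alpha:.4g}, below the smallest achievable level {resolution:.4g} "
            f"for {plan.total_distinct} permutations; the best achievable "
            f"confidence level is {best:.4g}"
        )

    observed, means = _observed_statistic(statistic, index)
    effect = _st.beta_and_se(index.entity_label.astype(float), means, statistic)
    beta_hat, se = effect.beta_hat, effect.se_beta
    x_row = index.entity_label[index.entity_of_row].astype(float)
    y = index.response
    tol = rtol * max(se, 1e-12)

    root = np.random.SeedSequence(seed)
    side_seeds = root.spawn(2)
    bounds = {}
    iterations_used = 0
    for side, child in zip((-1.0, 1.0), side_seeds):
        def margin(b):
            """|T_obs| minus the interpolated null quantile, both at shift b.

            Negative inside the acceptance region, positive outside; the
            rejection boundary is its root.  The resample stream is frozen
            per bound so the curve is a deterministic function of b.
            """
            shifted = y - b * x_row
            rng = np.random.default_rng(child)
            null = _null_statistics(
                statistic, spec, index, plan, bootstraps, rng, response=shifted
            )
            finite = null.values[np.isfinite(null.values)]
            q = float(np.quantile(np.abs(finite), level))
            t_obs, _ = _observed_statistic(statistic, index, response=shifted)
            return abs(t_obs) - q

        inner, outer = beta_hat, beta_hat + side * 4.0 * se
        f_outer = margin(outer)
        evals = 1
        while f_outer < 0 and evals < max_iterations:
            inner, outer = outer, beta_hat + 2.0 * (outer - beta_hat)
            f_outer = margin(outer)
            evals += 1
        if f_outer < 0:
            raise ConvergenceError(
                f"could not bracket the rejection boundary within "
                f"{max_iterations} refinements",
                bracket=(inner, outer),
            )
        while evals < max_iterations and abs(outer - inner) > tol:
            mid = 0.5 * (inner + outer)
            if margin(mid) < 0:
                inner = mid
            else:
                outer = mid
            evals += 1
        iterations_used = max(iterations_used, evals)
        bounds[side] = 0.5 * (inner + outer)
    return ConfidenceInterval(
        lower=float(min(bounds[-1.0], beta_hat)),
        upper=float(max(bounds[1.0], beta_hat)),
        level=level,
        beta_hat=float(beta_hat),
        iterations_used=iterations_used,
        achieved_resolution=resolution,
        seed=seed,
    )
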