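"""Test statistics for randomization tests on aggregated cluster means.

Two approximately pivotal statistics are provided.  The Welch-form t
statistic handles the two-group difference of means.  For multi-group or
regression-style nulls (H0: slope beta = 0) the studentized covariance
statistic T = Q / sqrt(S2(Q)) is used, where Q is the sample covariance of
the treatment codes X and responses Y, and S2(Q) is a bias-corrected
estimate of the variance of Q built from product central moments.  Dividing
by an estimated standard error makes both statistics asymptotically valid
under unequal variances between treatment groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GroupSummary",
    "MomentSet",
    "EffectEstimate",
    "DegenerateStatisticError",
    "welch_t",
    "product_central_moment",
    "compute_moments",
    "sample_covariance",
    "var_sample_covariance_population",
    "var_sample_covariance_corrected",
    "studentized_covariance",
    "beta_and_se",
]


class DegenerateStatisticError(ZeroDivisionError):
    """Raised when a statistic's denominator vanishes (constant data)."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSummary:
    """Sufficient statistics for the two-group t statistic."""

    mean_a: float
    mean_b: float
    var_a: float
    var_b: float
    n_a: int
    n_b: int

    @classmethod
    def from_samples(cls, a, b) -> "GroupSummary":
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        return cls(
            mean_a=float(a.mean()),
            mean_b=float(b.mean()),
            var_a=float(a.var(ddof=1)) if a.size > 1 else 0.0,
            var_b=float(b.var(ddof=1)) if b.size > 1 else 0.0,
            n_a=int(a.size),
            n_b=int(b.size),
        )


@dataclass(frozen=True)
class MomentSet:
    """Product central moments of a paired sample (X, Y)."""

    n: int
    mu_11: float
    mu_20: float
    mu_02: float
    mu_22: float
    x_bar: float
    y_bar: float

    def __post_init__(self):
        if self.mu_20 < 0 or self.mu_02 < 0:
            raise ValueError("second moments cannot be negative")
        # Cauchy-Schwarz with a little numerical headroom
        bound = self.mu_20 * self.mu_02
        if self.mu_11 ** 2 > bound * (1 + 1e-9) + 1e-30:
            raise ValueError("mu_11^2 exceeds mu_20 * mu_02 (Cauchy-Schwarz)")


@dataclass(frozen=True)
class EffectEstimate:
    """Slope estimate with its standard error and pivotal statistic value."""

    beta_hat: float
    se_beta: float
    statistic: float


# ---------------------------------------------------------------------------
# Moments and covariance
# ---------------------------------------------------------------------------

def product_central_moment(x, y, r: int, t: int) -> float:
    """Plug-in product central moment mu_{r,t} = mean((X-Xbar)^r (Y-Ybar)^t)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 1:
        raise ValueError("need at least one observation")
    xc = x - x.mean()
    yc = y - y.mean()
    return float(np.mean(xc ** r * yc ** t))


def compute_moments(x, y) -> MomentSet:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    xc = x - x.mean()
    yc = y - y.mean()
    return MomentSet(
        n=int(x.size),
        mu_11=float(np.mean(xc * yc)),
        mu_20=float(np.mean(xc ** 2)),
        mu_02=float(np.mean(yc ** 2)),
        mu_22=float(np.mean(xc ** 2 * yc ** 2)),
        x_bar=float(x.mean()),
        y_bar=float(y.mean()),
    )


def sample_covariance(x, y) -> float:
    """Q = n * mu_{1,1} / (n - 1), the usual (n-1)-denominator covariance."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("sample covariance needs n >= 2")
    return n * product_central_moment(x, y, 1, 1) / (n - 1)


def var_sample_covariance_population(m: MomentSet) -> float:
    """Plug-in (population-moment) variance of the sample covariance.

    Biased downwards in small samples; kept for reference and as the
    large-n limit of the corrected estimator.
    """
    n = m.n
    if n < 2:
        raise ValueError("needs n >= 2")
    return (
        -(n - 2) * m.mu_11 ** 2 / ((n - 1) * n)
        + m.mu_02 * m.mu_20 / ((n - 1) * n)
        + m.mu_22 / n
    )


def var_sample_covariance_corrected(m: MomentSet, clip: bool = True) -> float:
    """Bias-corrected approximation S2(Q) to the variance of Q.

    Requires n >= 4.  The exact unbiased estimator is numerically unstable;
    this corrected approximation is nearly unbiased for n as small as 8.  A
    negative value (possible for extreme small-n inputs) is clipped to 0,
    signalling an unusable denominator.
    """
    n = m.n
    if n < 4:
        raise ValueError(
            "the corrected variance of Q needs n >= 4; "
            "use the two-sample t statistic for smaller designs"
        )
    s2 = (1.0 / (n - 1.5)) * (
        -(n ** 2) * (n - 2) * m.mu_11 ** 2 / ((n - 1) * (n - 1.75) ** 2)
        + n ** 2 * m.mu_02 * m.mu_20 / (n - 1) ** 3
        + n * m.mu_22 / (n - 2)
    )
    if clip and s2 < 0:
        return 0.0
    return float(s2)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def welch_t(summary: GroupSummary) -> float:
    """t = (Bbar - Abar) / sqrt(s2_B/n_B + s2_A/n_A)."""
    denom = summary.var_b / summary.n_b + summary.var_a / summary.n_a
    if denom <= 0:
        raise DegenerateStatisticError(
            "both group variances are zero; the data are constant"
        )
    return (summary.mean_b - summary.mean_a) / float(np.sqrt(denom))


def studentized_covariance(x, y) -> float:
    """T = Q / sqrt(S2(Q)); the pivotal statistic for H0: beta = 0.

    ``x`` holds numeric treatment codes (e.g. 0, 1, 2, ... in dose order)
    and ``y`` the responses (typically aggregated cluster means).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("treatment codes are constant")
    m = compute_moments(x, y)
    q = m.n * m.mu_11 / (m.n - 1)
    s2 = var_sample_covariance_corrected(m)
    if s2 <= 0:
        if q == 0:
            return 0.0
        raise DegenerateStatisticError("S2(Q) is zero while Q is not")
    return float(q / np.sqrt(s2))


def beta_and_se(x, y, statistic: str = "corr") -> EffectEstimate:
    """Slope beta_hat = Q(X, Y) / Var(X) with its standard error.

    Equals the ordinary least-squares slope; with two groups coded 0/1 it is
    the difference of group means.  ``statistic`` selects the pivot used for
    the standard error: ``"corr"`` (studentized covariance) or ``"t"``
    (Welch t on the two groups).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("treatment codes are constant")
    var_x = x.var(ddof=1)
    beta = sample_covariance(x, y) / var_x
    if statistic == "t":
        codes = np.unique(x)
        if codes.size != 2:
            raise ValueError("the t statistic needs exactly two groups")
        summ = GroupSummary.from_samples(y[x == codes[0]], y[x == codes[1]])
        stat = welch_t(summ)
    elif statistic == "corr":
        stat = studentized_covariance(x, y)
    else:
        raise ValueError(f"unknown statistic {statistic!r} (use 't' or 'corr')")
    se = abs(beta / stat) if stat != 0 else float("inf")
    return EffectEstimate(beta_hat=float(beta), se_beta=float(se), statistic=float(stat))


# ---------------------------------------------------------------------------
# Vectorized batch forms (hot path of the randomization loop)
# ---------------------------------------------------------------------------

def batch_welch_t(codes: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Welch t for every row of a (P, E) 0/1 label matrix against y (E,) or (E, B).

    Returns (P,) or (P, B).  Zero denominators yield 0 (the corresponding
    label arrangement carries no evidence either way).
    """
    L = np.asarray(codes, dtype=float)
    y = np.asarray(y, dtype=float)
    one_d = y.ndim == 1
    Y = y[:, None] if one_d else y
    E = L.shape[1]
    # both groups are reduced through identical matmul kernels so that a
    # full label swap negates the statistic bit-for-bit (exact tie counting)
    M = 1.0 - L
    n_b = L.sum(axis=1, keepdims=True)
    n_a = E - n_b
    Ysq = Y ** 2
    m_b = (L @ Y) / n_b
    m_a = (M @ Y) / n_a
    var_b = (L @ Ysq - n_b * m_b ** 2) / (n_b - 1)
    var_a = (M @ Ysq - n_a * m_a ** 2) / (n_a - 1)
    denom = np.sqrt(np.maximum(var_b / n_b + var_a / n_a, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (m_b - m_a) / denom, 0.0)
    return t[:, 0] if one_d else t


def batch_studentized_covariance(codes: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Studentized covariance for every row of a (P, E) code matrix.

    ``y`` may be (E,) or (E, B) for B bootstrap replicates; returns (P,) or
    (P, B).  Non-positive S2(Q) yields 0 when Q is 0 and +/-inf otherwise
    (maximally extreme, counted against the observed statistic).
    """
    X = np.asarray(codes, dtype=float)
    y = np.asarray(y, dtype=float)
    one_d = y.ndim == 1
    Y = y[:, None] if one_d else y
    P, E = X.shape
    n = E
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=0, keepdims=True)
    mu11 = (Xc @ Yc) / n
    mu20 = (Xc ** 2).mean(axis=1, keepdims=True)
    mu02 = (Yc ** 2).mean(axis=0, keepdims=True)
    mu22 = (Xc ** 2 @ Yc ** 2) / n
    q = n * mu11 / (n - 1)
    s2 = (1.0 / (n - 1.5)) * (
        -(n ** 2) * (n - 2) * mu11 ** 2 / ((n - 1) * (n - 1.75) ** 2)
        + n ** 2 * mu02 * mu20 / (n - 1) ** 3
        + n * mu22 / (n - 2)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(s2 > 0, q / np.sqrt(np.maximum(s2, 0.0)), np.where(q == 0, 0.0, np.inf * np.sign(q)))
    return t[:, 0] if one_d else t
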