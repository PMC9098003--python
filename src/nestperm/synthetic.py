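"""Synthetic hierarchical datasets and the validation simulation studies.

Two additive data-generating models are provided, mirroring common nested
experimental designs:

* three-level: ``y = treatment * beta + cluster + individual`` — treatments
  assigned to clusters (e.g. mice), each measured repeatedly;
* four-level: ``y = block + treatment * beta + cluster + individual`` —
  treatments assigned to clusters (e.g. wells) within blocks (e.g. mice),
  each cluster measured repeatedly.

Random terms can be drawn from normal, lognormal, Pareto, or gamma families;
every family is centered and scaled to unit variance before use, so that
``beta`` is the only systematic difference between treatment groups and the
intraclass correlation is controlled exactly.  The ``icc`` parameter is the
conventional intraclass correlation: the share of the total (cluster +
individual) noise variance attributable to cluster membership.  An optional
variance ratio scales the noise of the later treatment groups (e.g. 1:1.5)
to emulate heteroscedasticity.

The study harnesses estimate the Type I error rate of the hierarchical
randomization test (against closed-form Student/Welch t comparators on
cluster means) and the coverage probability of inverted-test confidence
intervals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import DesignTable
from .inference import confidence_interval, hypothesis_test

__all__ = [
    "SimulationModel",
    "StudyResult",
    "DISTRIBUTION_FAMILIES",
    "generate_dataset",
    "type_i_error_study",
    "coverage_study",
    "student_t_comparators",
]


# ---------------------------------------------------------------------------
# Standardized random families
# ---------------------------------------------------------------------------

def _draw_normal(rng, size, params):
    return rng.standard_normal(size)


def _draw_lognormal(rng, size, params):
    sigma = float(params.get("lognormal_sigma", 0.75))
    if sigma <= 0:
        raise ValueError("lognormal sigma must be positive")
    z = rng.lognormal(0.0, sigma, size)
    mean = np.exp(sigma ** 2 / 2)
    var = (np.exp(sigma ** 2) - 1) * np.exp(sigma ** 2)
    return (z - mean) / np.sqrt(var)


def _draw_pareto(rng, size, params):
    shape = float(params.get("pareto_shape", 3.0))
    if shape <= 2:
        raise ValueError("Pareto shape must exceed 2 for a finite variance")
    z = rng.pareto(shape, size) + 1.0  # Pareto with scale 1
    mean = shape / (shape - 1)
    var = shape / ((shape - 1) ** 2 * (shape - 2))
    return (z - mean) / np.sqrt(var)


def _draw_gamma(rng, size, params):
    shape = float(params.get("gamma_shape", 2.0))
    if shape <= 0:
        raise ValueError("gamma shape must be positive")
    z = rng.gamma(shape, 1.0, size)
    return (z - shape) / np.sqrt(shape)


DISTRIBUTION_FAMILIES = {
    "normal": _draw_normal,
    "lognormal": _draw_lognormal,
    "pareto": _draw_pareto,
    "gamma": _draw_gamma,
}


def _sampler(name: str):
    try:
        return DISTRIBUTION_FAMILIES[name]
    except KeyError:
        raise ValueError(
            f"unknown distribution family {name!r}; "
            f"valid families: {sorted(DISTRIBUTION_FAMILIES)}"
        ) from None


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationModel:
    """Data-generating configuration for one simulated experiment.

    ``n_blocks = 0`` selects the three-level model (treatment assigned to
    clusters); ``n_blocks >= 1`` the four-level model (treatment assigned to
    clusters within blocks).  ``total_variance`` is the per-observation noise
    variance (cluster + individual); ``icc`` its cluster share.
    ``variance_ratio`` is the total-noise-variance ratio of the last
    treatment group to the first, interpolated linearly in between.
    """

    n_treatment_groups: int = 2
    clusters_per_group: int = 4
    obs_per_cluster: int = 3
    n_blocks: int = 0
    beta: float = 0.0
    cluster_dist: str = "normal"
    individual_dist: str = "normal"
    block_dist: str = "normal"
    icc: float = 0.5
    total_variance: float = 1.0
    block_variance: float = 1.0
    variance_ratio: float = 1.0
    dist_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.icc <= 1.0:
            raise ValueError("icc must be in [0, 1]")
        if not 2 <= self.n_treatment_groups:
            raise ValueError("need at least 2 treatment groups")
        if min(self.clusters_per_group, self.obs_per_cluster) < 1:
            raise ValueError("all level sizes must be >= 1")
        if self.variance_ratio <= 0:
            raise ValueError("variance_ratio must be positive")
        for fam in (self.cluster_dist, self.individual_dist, self.block_dist):
            _sampler(fam)

    @property
    def treatment_level(self) -> int:
        """1-based treatment column index in the generated table."""
        return 2 if self.n_blocks else 1

    def with_beta(self, beta: float) -> "SimulationModel":
        return replace(self, beta=beta)


def generate_dataset(model: SimulationModel, seed=None) -> DesignTable:
    """Draw one long-format dataset from the model.

    Three-level layout: ``Treatment, Cluster, Obs, y`` (treatment level 1).
    Four-level layout: ``Block, Treatment, Cluster, Obs, y`` (treatment
    level 2).  Treatment groups appear in dose order g0, g1, ... so that
    first-appearance integer coding matches the generating code.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    G = model.n_treatment_groups
    C = model.clusters_per_group
    m = model.obs_per_cluster
    B = max(model.n_blocks, 1)
    n_clusters = B * G * C
    n = n_clusters * m

    sd_cluster = np.sqrt(model.icc * model.total_variance)
    sd_indiv = np.sqrt((1.0 - model.icc) * model.total_variance)
    if G > 1:
        group_scale = np.sqrt(
            1.0 + (model.variance_ratio - 1.0) * np.arange(G) / (G - 1)
        )
    else:
        group_scale = np.ones(1)

    block_of_cluster = np.repeat(np.arange(B), G * C)
    group_of_cluster = np.tile(np.repeat(np.arange(G), C), B)
    cluster_of_obs = np.repeat(np.arange(n_clusters), m)
    group_of_obs = group_of_cluster[cluster_of_obs]

    cluster_eff = _sampler(model.cluster_dist)(rng, n_clusters, model.dist_params)
    indiv_eff = _sampler(model.individual_dist)(rng, n, model.dist_params)
    y = (
        model.beta * group_of_obs
        + sd_cluster * group_scale[group_of_obs] * cluster_eff[cluster_of_obs]
        + sd_indiv * group_scale[group_of_obs] * indiv_eff
    )
    if model.n_blocks:
        block_eff = _sampler(model.block_dist)(rng, B, model.dist_params)
        y = y + np.sqrt(model.block_variance) * block_eff[block_of_cluster[cluster_of_obs]]

    cols = {}
    if model.n_blocks:
        cols["Block"] = [f"b{b}" for b in block_of_cluster[cluster_of_obs]]
    cols["Treatment"] = [f"g{g}" for g in group_of_obs]
    cols["Cluster"] = [f"c{c % (G * C)}" for c in cluster_of_obs]
    cols["Obs"] = [f"o{i % m}" for i in range(n)]
    cols["y"] = y
    return DesignTable(pd.DataFrame(cols))


# ---------------------------------------------------------------------------
# Comparators
# ---------------------------------------------------------------------------

def student_t_comparators(groups, paired: bool = False) -> dict:
    """Closed-form two-sample p-values on per-cluster means.

    ``groups`` is a sequence of two arrays of cluster means.  Returns
    two-tailed p-values for the pooled-variance Student t test and for the
    Welch t test (Welch-Satterthwaite degrees of freedom); with
    ``paired=True`` a paired t test on within-pair differences instead of
    the pooled test.
    """
    a, b = (np.asarray(g, dtype=float) for g in groups)
    if min(a.size, b.size) < 2:
        raise ValueError("need at least 2 clusters per group")
    out = {}
    if paired:
        out["paired_t"] = float(sps.ttest_rel(b, a).pvalue)
    else:
        out["student_t"] = float(sps.ttest_ind(b, a, equal_var=True).pvalue)
    out["welch_t"] = float(sps.ttest_ind(b, a, equal_var=False).pvalue)
    return out


def _cluster_means(table: DesignTable, model: SimulationModel, paired: bool = False):
    """Per-group arrays of summary means for the closed-form comparators.

    Unpaired: one mean per cluster.  Paired (blocked designs): one mean per
    (block, group), so the paired t test differences whole blocks.
    """
    df = table.data
    tcol = df.columns[model.treatment_level - 1]
    if paired:
        keys = [df.columns[0], tcol]
    else:
        keys = list(df.columns[: model.treatment_level + 1])
    means = df.groupby(keys, sort=False)[df.columns[-1]].mean()
    by_group = means.groupby(level=tcol, sort=False)
    return [g.to_numpy() for _, g in by_group]


# ---------------------------------------------------------------------------
# Studies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyResult:
    """Aggregate outcome of a simulation study (one row per method)."""

    kind: str                      # "type_i" | "coverage"
    nominal: float                 # alpha or confidence level
    n_datasets: int
    counts: dict                   # method -> number of rejections / covers
    seed: object = None

    @property
    def rates(self) -> dict:
        return {k: v / self.n_datasets for k, v in self.counts.items()}

    def nominal_band(self, confidence: float = 0.95) -> tuple[float, float]:
        """Binomial band around the nominal rate at the study's sample size."""
        z = sps.norm.ppf(0.5 + confidence / 2)
        half = z * np.sqrt(self.nominal * (1 - self.nominal) / self.n_datasets)
        return (self.nominal - half, self.nominal + half)

    def rate_interval(self, method: str, confidence: float = 0.95) -> tuple[float, float]:
        from statsmodels.stats.proportion import proportion_confint

        lo, hi = proportion_confint(
            self.counts[method], self.n_datasets, alpha=1 - confidence, method="wilson"
        )
        return (float(lo), float(hi))

    def to_frame(self) -> pd.DataFrame:
        lo, hi = self.nominal_band()
        rows = []
        for method, count in self.counts.items():
            rlo, rhi = self.rate_interval(method)
            rows.append(
                {
                    "study": self.kind,
                    "method": method,
                    "nominal": self.nominal,
                    "n_datasets": self.n_datasets,
                    "count": count,
                    "rate": count / self.n_datasets,
                    "rate_ci_low": rlo,
                    "rate_ci_high": rhi,
                    "nominal_band_low": lo,
                    "nominal_band_high": hi,
                }
            )
        return pd.DataFrame(rows)

    def to_json(self, **kw) -> str:
        lo, hi = self.nominal_band()
        return json.dumps(
            {
                "study": self.kind,
                "nominal": self.nominal,
                "n_datasets": self.n_datasets,
                "rates": self.rates,
                "nominal_band": [lo, hi],
                "seed": self.seed,
            },
            **kw,
        )


def _child_seeds(seed, n) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.integers(0, 2 ** 31 - 1, size=n)


def type_i_error_study(
    model: SimulationModel,
    n_datasets: int = 2000,
    alpha: float = 0.05,
    statistic: str = "auto",
    bootstraps=100,
    permutations="all",
    seed=None,
    comparators: bool = True,
    external_p: dict | None = None,
) -> StudyResult:
    """Null rejection rate of the hierarchical test (and t comparators).

    Requires ``model.beta == 0``.  Each simulated dataset is tested at
    ``alpha``; a rejection is a p-value at or below ``alpha``.  Closed-form
    Student and Welch t tests on cluster means run alongside for reference
    (paired Student variant on blocked designs).  ``external_p`` may supply
    extra methods' p-value vectors (length ``n_datasets``) for side-by-side
    tabulation.
    """
    if model.beta != 0:
        raise ValueError("a Type I error study needs beta = 0")
    seeds = _child_seeds(seed, 2 * n_datasets)
    counts: dict = {"hierarchical": 0}
    paired = bool(model.n_blocks) and model.n_treatment_groups == 2
    for i in range(n_datasets):
        table = generate_dataset(model, seed=int(seeds[2 * i]))
        res = hypothesis_test(
            table,
            treatment_level=model.treatment_level,
            statistic=statistic,
            bootstraps=bootstraps,
            permutations=permutations,
            seed=int(seeds[2 * i + 1]),
        )
        counts["hierarchical"] += res.p_two_tailed <= alpha
        if comparators and model.n_treatment_groups == 2:
            groups = _cluster_means(table, model, paired=paired)
            for name, p in student_t_comparators(groups, paired=paired).items():
                counts[name] = counts.get(name, 0) + (p <= alpha)
    if external_p:
        for name, pvec in external_p.items():
            pvec = np.asarray(pvec, dtype=float)
            if pvec.size != n_datasets:
                raise ValueError(f"external p-values for {name!r} have wrong length")
            counts[name] = int(np.count_nonzero(pvec <= alpha))
    return StudyResult("type_i", alpha, n_datasets, counts, seed)


def coverage_study(
    model: SimulationModel,
    n_datasets: int = 1000,
    level: float = 0.95,
    statistic: str = "auto",
    bootstraps=50,
    permutations="all",
    seed=None,
) -> StudyResult:
    """Fraction of inverted-test intervals containing the true beta."""
    seeds = _child_seeds(seed, 2 * n_datasets)
    covered = 0
    for i in range(n_datasets):
        table = generate_dataset(model, seed=int(seeds[2 * i]))
        ci = confidence_interval(
            table,
            treatment_level=model.treatment_level,
            statistic=statistic,
            level=level,
            bootstraps=bootstraps,
            permutations=permutations,
            seed=int(seeds[2 * i + 1]),
        )
        covered += model.beta in ci
    return StudyResult("coverage", level, n_datasets, {"hierarchical": covered}, seed)
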