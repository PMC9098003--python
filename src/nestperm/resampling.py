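"""Block-restricted permutations and hierarchical bootstrap resampling.

Treatment labels are only exchangeable at the level where treatment was
randomized, so permutations shuffle the labels attached to the treated
entities *within* each block (the joint labels of the columns left of the
treatment column).  Uncertainty in each treated entity's mean is represented
by hierarchically resampling its nested observations with replacement.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
from sympy.utilities.iterables import multiset_permutations

from .design import ClusterIndex, DesignError, DesignSpec

__all__ = [
    "PermutationPlan",
    "BootstrapPlan",
    "count_permutations",
    "build_permutation_plan",
    "iter_permutations",
    "permutation_matrix",
    "sample_permutation_matrix",
    "count_bootstrap_resamples",
    "bootstrap_resample",
    "enumerate_bootstrap_resamples",
    "aggregate_treated_means",
]

ENUMERATION_CAP = 100_000


def _multinomial(counts) -> int:
    total, out = 0, 1
    for c in counts:
        total += int(c)
        out *= math.comb(total, int(c))
    return out


def _block_items(spec: DesignSpec, index: ClusterIndex):
    """Per block: (items, membership) where items are the labels permuted.

    Without an interaction the items are the treated entities' label codes.
    With an interaction whole treatment groups move together, so the items
    are the distinct group labels and ``membership`` maps each item to the
    entity positions it covers.
    """
    blocks = []
    eb, el, eg = index.entity_block, index.entity_label, index.entity_group
    for b in range(index.n_blocks):
        in_b = np.flatnonzero(eb == b)
        if spec.has_interaction:
            groups = np.unique(eg[in_b])
            labels = np.array([el[eg == g][0] for g in groups], dtype=np.int64)
            members = [np.flatnonzero(eg == g) for g in groups]
            blocks.append((labels, members))
        else:
            blocks.append((el[in_b].copy(), [np.array([i]) for i in in_b]))
    return blocks


# ---------------------------------------------------------------------------
# Permutations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermutationPlan:
    """A resolved permutation scheme for one encoded design."""

    blocks: tuple                      # per block: (label codes, member index lists)
    mode: str                          # "exhaustive" | "sampled"
    requested: object                  # int or "all"
    total_distinct: int
    n_entities: int
    has_interaction: bool

    @property
    def n_exhaustive(self) -> int:
        return self.total_distinct


def count_permutations(spec: DesignSpec, index: ClusterIndex) -> int:
    """Exact count of distinct within-block label arrangements.

    The count is the product over blocks of the multinomial coefficient of
    that block's label multiset; under an interaction restriction whole
    treatment groups are exchanged, collapsing the count (e.g. 20^3 -> 2^3).
    """
    total = 1
    for labels, _members in _block_items(spec, index):
        _, counts = np.unique(labels, return_counts=True)
        total *= _multinomial(counts)
    return total


def build_permutation_plan(
    spec: DesignSpec,
    index: ClusterIndex,
    permutations="all",
    cap: int = ENUMERATION_CAP,
) -> PermutationPlan:
    blocks = tuple(_block_items(spec, index))
    total = count_permutations(spec, index)
    if permutations == "all":
        if total > cap:
            raise DesignError(
                f"{total} distinct permutations exceed the enumeration cap "
                f"({cap}); pass an integer count to sample instead"
            )
        mode = "exhaustive"
    else:
        permutations = int(permutations)
        if permutations < 1:
            raise DesignError("permutation count must be >= 1")
        mode = "sampled"
    return PermutationPlan(
        blocks=blocks,
        mode=mode,
        requested=permutations,
        total_distinct=total,
        n_entities=index.n_entities,
        has_interaction=spec.has_interaction,
    )


def _expand(plan: PermutationPlan, per_block_labels) -> np.ndarray:
    out = np.empty(plan.n_entities, dtype=np.int64)
    for (labels, members), arrangement in zip(plan.blocks, per_block_labels):
        for lab, mem in zip(arrangement, members):
            out[mem] = lab
    return out


def iter_permutations(plan: PermutationPlan, seed=None):
    """Yield entity-level label arrangements.

    Exhaustive mode yields each distinct arrangement exactly once (identity
    included).  Sampled mode yields ``plan.requested`` arrangements drawn
    uniformly at random with replacement from the distinct set; the stream is
    reproducible under ``seed``.
    """
    if plan.mode == "exhaustive":
        per_block = [list(multiset_permutations(list(labels))) for labels, _ in plan.blocks]
        for combo in itertools.product(*per_block):
            yield _expand(plan, combo)
    else:
        rng = np.random.default_rng(seed)
        for _ in range(int(plan.requested)):
            combo = [rng.permutation(labels) for labels, _ in plan.blocks]
            yield _expand(plan, combo)


def permutation_matrix(plan: PermutationPlan) -> np.ndarray:
    """All distinct arrangements as a ``(total_distinct, n_entities)`` array."""
    if plan.mode != "exhaustive":
        raise DesignError("permutation_matrix requires an exhaustive plan")
    return np.stack(list(iter_permutations(plan)))


def sample_permutation_matrix(plan: PermutationPlan, n: int, rng: np.random.Generator) -> np.ndarray:
    """``n`` uniformly sampled arrangements as an ``(n, n_entities)`` array.

    A uniform random shuffle of each block's label multiset gives every
    distinct arrangement equal probability, so draws are i.i.d. uniform with
    replacement over the distinct set.
    """
    out = np.empty((n, plan.n_entities), dtype=np.int64)
    for labels, members in plan.blocks:
        k = len(labels)
        keys = rng.random((n, k))
        shuffled = np.asarray(labels)[np.argsort(keys, axis=1)]
        for j, mem in enumerate(members):
            out[:, mem] = shuffled[:, j][:, None]
    return out


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BootstrapPlan:
    """Hierarchical bootstrap configuration for an encoded design."""

    n_bootstraps: int
    resample_levels: tuple[int, ...]
    seed: object = None


def build_bootstrap_plan(
    spec: DesignSpec, index: ClusterIndex, n_bootstraps: int, seed=None
) -> BootstrapPlan:
    levels = spec.resample_levels
    for lev in levels:
        parent_of_cluster = (
            index.row_codes[lev - 1][index.cluster_starts[lev]]
            if lev > 1
            else np.zeros(len(index.cluster_starts[lev]), dtype=np.int64)
        )
        children_per_parent = np.bincount(parent_of_cluster)
        if children_per_parent.max(initial=0) <= 1:
            warnings.warn(
                f"every cluster at level {lev} has a single child; "
                "resampling this level is a no-op",
                stacklevel=2,
            )
    return BootstrapPlan(n_bootstraps=int(n_bootstraps), resample_levels=levels, seed=seed)


def _spans_within(index: ClusterIndex, level: int, lo: int, hi: int):
    starts = index.cluster_starts[level]
    sizes = index.cluster_sizes[level]
    a = int(np.searchsorted(starts, lo))
    b = int(np.searchsorted(starts, hi))
    return [(int(starts[i]), int(starts[i] + sizes[i])) for i in range(a, b)]


def _resample_span(rng, index, lo, hi, levels):
    if not levels:
        return np.arange(lo, hi)
    lev = levels[0]
    out = []
    parents = _spans_within(index, lev - 1, lo, hi) if lev > 1 else [(lo, hi)]
    for plo, phi in parents:
        children = _spans_within(index, lev, plo, phi)
        k = len(children)
        for d in rng.integers(0, k, size=k):
            clo, chi = children[d]
            out.append(_resample_span(rng, index, clo, chi, levels[1:]))
    return np.concatenate(out) if out else np.empty(0, dtype=np.int64)


def bootstrap_resample(
    index: ClusterIndex, plan: BootstrapPlan, rng: np.random.Generator
) -> np.ndarray:
    """One bootstrap replicate, as row indices into the sorted table.

    Within each cluster at each resampled level (outermost first), children
    are drawn with replacement to the original child count; levels above
    remain fixed.  Clusters of size one reproduce themselves.
    """
    levels = tuple(plan.resample_levels)
    if not levels:
        return np.arange(index.n_rows)
    # fast path: a single innermost level of singleton clusters reduces to
    # resampling rows within each parent cluster
    if levels == (index.n_levels,) and np.all(index.cluster_sizes[levels[0]] == 1):
        lev = levels[0]
        parent = (
            index.row_codes[lev - 1]
            if lev > 1
            else np.zeros(index.n_rows, dtype=np.int64)
        )
        starts = index.cluster_starts[lev - 1] if lev > 1 else np.array([0])
        sizes = index.cluster_sizes[lev - 1] if lev > 1 else np.array([index.n_rows])
        return starts[parent] + rng.integers(0, sizes[parent])
    return _resample_span(rng, index, 0, index.n_rows, list(levels))


def _count_span(index, lo, hi, levels) -> int:
    if not levels:
        return 1
    lev = levels[0]
    total = 1
    parents = _spans_within(index, lev - 1, lo, hi) if lev > 1 else [(lo, hi)]
    for plo, phi in parents:
        children = _spans_within(index, lev, plo, phi)
        slot = sum(_count_span(index, clo, chi, levels[1:]) for clo, chi in children)
        total *= slot ** len(children)
    return total


def count_bootstrap_resamples(spec: DesignSpec, index: ClusterIndex) -> int:
    """Exact count of distinct ordered hierarchical resamples.

    For a single resampled level with ``k`` children per cluster this is the
    product of ``k**k`` over clusters (e.g. six wells of three images each
    admit ``27**6`` ordered resamples).
    """
    return _count_span(index, 0, index.n_rows, list(spec.resample_levels))


def _enum_span(index, lo, hi, levels):
    if not levels:
        return [np.arange(lo, hi)]
    lev = levels[0]
    per_parent = []
    parents = _spans_within(index, lev - 1, lo, hi) if lev > 1 else [(lo, hi)]
    for plo, phi in parents:
        children = _spans_within(index, lev, plo, phi)
        child_opts = [_enum_span(index, clo, chi, levels[1:]) for clo, chi in children]
        slot_opts = [opt for opts in child_opts for opt in opts]
        k = len(children)
        opts = [
            np.concatenate(combo)
            for combo in itertools.product(slot_opts, repeat=k)
        ]
        per_parent.append(opts)
    return [np.concatenate(c) for c in itertools.product(*per_parent)]


def enumerate_bootstrap_resamples(
    spec: DesignSpec, index: ClusterIndex, cap: int = 20_000
):
    """All distinct ordered bootstrap outcomes (tiny designs only)."""
    total = count_bootstrap_resamples(spec, index)
    if total > cap:
        raise DesignError(
            f"{total} bootstrap outcomes exceed the enumeration cap ({cap})"
        )
    return _enum_span(index, 0, index.n_rows, list(spec.resample_levels))


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def aggregate_treated_means(index: ClusterIndex, rows=None) -> np.ndarray:
    """Mean response per treated entity (one y-value per entity).

    ``rows`` are (possibly resampled) row indices into the sorted table;
    ``None`` aggregates the original data.  The result aligns with
    ``index.entity_label`` / ``index.entity_block``.
    """
    E = index.n_entities
    if rows is None:
        ent = index.entity_of_row
        y = index.response
    else:
        rows = np.asarray(rows)
        ent = index.entity_of_row[rows]
        y = index.response[rows]
    counts = np.bincount(ent, minlength=E)
    if np.any(counts == 0):
        raise DesignError("empty treated entity after resampling")
    sums = np.bincount(ent, weights=y, minlength=E)
    return sums / counts
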