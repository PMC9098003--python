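import itertools
import math

import numpy as np
import pandas as pd
import pytest

from nestperm import DesignTable


@pytest.fixture
def imaging_table() -> DesignTable:
    """A four-level imaging layout: mice > treatments > wells > images.

    Fifteen observations, well labels unique within mouse; well 2 of mouse 1
    appears twice (six images), exercising unbalanced innermost clusters.
    """
    rows = [
        (1, 1, 1, 1, 1.35),
        (1, 1, 1, 2, 7.84),
        (1, 1, 1, 3, 55.2),
        (1, 1, 2, 1, 124.4),
        (1, 1, 2, 2, 12.2),
        (1, 1, 2, 3, 11.1),
        (1, 1, 2, 1, 4.444),
        (1, 1, 2, 2, 76.3),
        (1, 1, 2, 3, 395.3),
        (1, 2, 3, 1, 2.1),
        (1, 2, 3, 2, 1.199),
        (1, 2, 3, 3, 4.4),
        (1, 2, 3, 1, 3.3),
        (1, 2, 3, 2, 32.2),
        (1, 2, 3, 3, 8.8),
    ]
    df = pd.DataFrame(rows, columns=["Mouse", "Treatment", "Well", "Image", "value"])
    return DesignTable(df)


def make_four_level(
    n_blocks=3, n_wells=3, n_images=3, beta=0.0, seed=0
) -> pd.DataFrame:
    """Blocked design: blocks > 2 treatments > wells > images."""
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(n_blocks):
        base = rng.normal()
        for g, treat in enumerate(["ctrl", "drug"]):
            for w in range(n_wells):
                wb = rng.normal()
                for i in range(n_images):
                    rows.append(
                        (f"m{b}", treat, f"w{w}", f"i{i}",
                         base + wb + beta * g + rng.normal())
                    )
    return pd.DataFrame(rows, columns=["Mouse", "Treatment", "Well", "Image", "y"])


def make_three_level(n_clusters=4, n_obs=3, beta=0.0, seed=0) -> pd.DataFrame:
    """Unblocked design: 2 treatments > clusters > observations."""
    rng = np.random.default_rng(seed)
    rows = []
    for g, treat in enumerate(["ctrl", "drug"]):
        for c in range(n_clusters):
            cb = rng.normal()
            for o in range(n_obs):
                rows.append((treat, f"c{c}", f"o{o}", cb + beta * g + rng.normal()))
    return pd.DataFrame(rows, columns=["Treatment", "Cluster", "Obs", "y"])


# ---------------------------------------------------------------------------
# Independent brute-force oracle (pure python + math, no package internals)
# ---------------------------------------------------------------------------

def _oracle_welch_t(a, b):
    ma = sum(a) / len(a)
    mb = sum(b) / len(b)
    va = sum((v - ma) ** 2 for v in a) / (len(a) - 1)
    vb = sum((v - mb) ** 2 for v in b) / (len(b) - 1)
    return (mb - ma) / math.sqrt(vb / len(b) + va / len(a))


def brute_force_p(df: pd.DataFrame, treatment_level: int) -> float:
    """Exhaustive two-group p-value over every (bootstrap, permutation) pair.

    Enumerates all ordered with-replacement resamples of each treated
    entity's observations and, for each, all distinct within-block label
    arrangements, computing the Welch t on entity means from first
    principles.
    """
    t = treatment_level
    lev = list(df.columns[:-1])
    resp = df.columns[-1]
    block_cols = lev[: t - 1]
    ent_cols = lev[: t + 1]

    entities = []  # (block key, label, [observations])
    for key, grp in df.groupby(ent_cols, sort=False):
        key = (key,) if not isinstance(key, tuple) else key
        block = key[: t - 1]
        label = key[t - 1]
        entities.append((block, label, list(grp[resp])))

    labels_sorted = sorted({lab for _, lab, _ in entities})
    assert len(labels_sorted) == 2

    # all distinct label arrangements, restricted within blocks
    blocks = {}
    for pos, (block, label, _obs) in enumerate(entities):
        blocks.setdefault(block, []).append(pos)
    per_block = []
    for block, positions in blocks.items():
        labs = [entities[p][1] for p in positions]
        arrangements = sorted(set(itertools.permutations(labs)))
        per_block.append((positions, arrangements))

    def stat_for(means, assignment):
        a = [m for m, lab in zip(means, assignment) if lab == labels_sorted[0]]
        b = [m for m, lab in zip(means, assignment) if lab == labels_sorted[1]]
        return _oracle_welch_t(a, b)

    observed_means = [sum(obs) / len(obs) for _, _, obs in entities]
    observed_assignment = [lab for _, lab, _ in entities]
    t_obs = stat_for(observed_means, observed_assignment)

    per_entity_resamples = []
    for _, _, obs in entities:
        k = len(obs)
        draws = [
            [obs[i] for i in combo]
            for combo in itertools.product(range(k), repeat=k)
        ]
        per_entity_resamples.append(draws)

    null = []
    for resample in itertools.product(*per_entity_resamples):
        means = [sum(d) / len(d) for d in resample]
        for combo in itertools.product(*[arrs for _, arrs in per_block]):
            assignment = [None] * len(entities)
            for (positions, _), arr in zip(per_block, combo):
                for p, lab in zip(positions, arr):
                    assignment[p] = lab
            null.append(stat_for(means, assignment))
    extreme = sum(1 for v in null if abs(v) >= abs(t_obs))
    return extreme / len(null)
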