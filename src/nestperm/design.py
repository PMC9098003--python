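"""Long-format hierarchical design tables.

A nested experimental design is expressed purely by column order: label
columns run left-to-right from the outermost level of the hierarchy to the
innermost, and the final column holds the numeric response.  For example, an
imaging experiment in which wells of cultured cells from several mice are
treated and then imaged is laid out as

    Mouse   Treatment   Well    Image   value

Reading the columns left to right determines the resampling plan for the
randomization test:

* columns left of the treatment column are **blocks** — permutation of
  treatment labels is restricted within their joint labels;
* the column immediately after the treatment column identifies the **treated
  entities** (the clusters the labels attach to);
* columns below the treated-entity level are eligible for hierarchical
  **bootstrap** resampling.

An interaction (random treatment effect) is declared by duplicating the
treatment column, or by inserting any column whose unique-row partition adds
nothing to the columns left of it; in that case label permutation collapses
to exchanging whole treatment groups within each block.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DesignError",
    "DesignTable",
    "DesignSpec",
    "ClusterIndex",
    "load_table",
    "encode_design",
    "rearrange_crossed",
]


class DesignError(ValueError):
    """Raised when a table or design specification is invalid."""


# ---------------------------------------------------------------------------
# DesignTable
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignTable:
    """A validated long-format dataset.

    Parameters
    ----------
    data:
        DataFrame whose first ``len(level_names)`` columns are categorical
        level labels (outermost level first) and whose final column is the
        numeric response.  One row per lowest-level observation.
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        if df.shape[1] < 2:
            raise DesignError(
                "a design table needs at least one level column and a response "
                f"column; got {df.shape[1]} column(s)"
            )
        if df.shape[0] < 2:
            raise DesignError("a design table needs at least 2 rows")
        resp = df.iloc[:, -1]
        numeric = pd.to_numeric(resp, errors="coerce")
        bad = numeric.isna() | ~np.isfinite(numeric.astype(float))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DesignError(
                f"non-numeric or non-finite response value {resp.iloc[row]!r} "
                f"in column {df.columns[-1]!r}, row {row}"
            )
        levels = df.iloc[:, :-1]
        for name in levels.columns:
            col = levels[name]
            missing = col.isna() | (col.astype(str).str.strip() == "")
            if missing.any():
                row = int(np.flatnonzero(missing.to_numpy())[0])
                raise DesignError(
                    f"missing label in level column {name!r}, row {row}"
                )
        # normalize: labels as whitespace-trimmed strings, response as float
        clean = levels.astype(str).apply(lambda c: c.str.strip())
        clean[df.columns[-1]] = numeric.astype(float)
        object.__setattr__(self, "data", clean.reset_index(drop=True))

    # -- accessors ---------------------------------------------------------
    @property
    def level_names(self) -> list[str]:
        return list(self.data.columns[:-1])

    @property
    def response_name(self) -> str:
        return str(self.data.columns[-1])

    @property
    def n_levels(self) -> int:
        return self.data.shape[1] - 1

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def response(self) -> np.ndarray:
        return self.data.iloc[:, -1].to_numpy(dtype=float)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"DesignTable(levels={self.level_names}, "
            f"response={self.response_name!r}, n_rows={self.n_rows})"
        )


def load_table(path, sep: str = ",") -> DesignTable:
    """Read a delimited text file into a validated :class:`DesignTable`.

    The file must have a header row; every column except the last holds
    level labels and the last column holds the numeric response.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)
    return DesignTable(df)


# ---------------------------------------------------------------------------
# Encoding: DesignSpec + ClusterIndex
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignSpec:
    """The resampling plan inferred from column order.

    ``treatment_level`` is the 1-based index of the column whose labels are
    permuted.  Columns to its left are blocks; the column immediately to its
    right (skipping a detected interaction column) identifies the treated
    entities; any deeper columns are bootstrap levels.  ``skip_levels``
    removes bootstrap levels whose within-cluster observations are not a
    random sample and therefore must not be resampled.
    """

    treatment_level: int
    block_levels: tuple[int, ...]
    treated_entity_level: int | None
    bootstrap_levels: tuple[int, ...]
    skip_levels: tuple[int, ...] = ()
    has_interaction: bool = False
    interaction_level: int | None = None
    level_names: tuple[str, ...] = ()

    @property
    def resample_levels(self) -> tuple[int, ...]:
        return tuple(l for l in self.bootstrap_levels if l not in self.skip_levels)

    def to_dict(self) -> dict:
        return {
            "treatment_level": self.treatment_level,
            "block_levels": list(self.block_levels),
            "treated_entity_level": self.treated_entity_level,
            "bootstrap_levels": list(self.bootstrap_levels),
            "skip_levels": list(self.skip_levels),
            "has_interaction": self.has_interaction,
            "level_names": list(self.level_names),
        }


@dataclass
class ClusterIndex:
    """Row-span bookkeeping for every level of an encoded design.

    Rows are stably sorted so that each cluster's children are contiguous.
    ``row_codes[k]`` gives, for level ``k`` (1-based), the dense cluster id of
    every (sorted) row; ``cluster_starts[k]``/``cluster_sizes[k]`` give the
    contiguous span of each cluster.  The treated-entity arrays summarize the
    clusters the treatment labels attach to.
    """

    n_rows: int
    n_levels: int
    order: np.ndarray                      # sorted position -> original row
    response: np.ndarray                   # response in sorted order
    labels: list[np.ndarray]               # per level: label string per sorted row
    row_codes: dict[int, np.ndarray]       # level -> cluster id per sorted row
    cluster_starts: dict[int, np.ndarray]
    cluster_sizes: dict[int, np.ndarray]
    # treated entities
    entity_of_row: np.ndarray              # sorted row -> entity id
    entity_block: np.ndarray               # entity -> block id
    entity_label: np.ndarray               # entity -> treatment label code
    entity_group: np.ndarray               # entity -> block x treatment group id
    treatment_label_names: np.ndarray      # code -> original label string
    column_names: list[str] = field(default_factory=list)

    @property
    def n_entities(self) -> int:
        return int(self.entity_block.shape[0])

    @property
    def n_blocks(self) -> int:
        return int(self.entity_block.max()) + 1 if self.n_entities else 0

    def decode(self) -> pd.DataFrame:
        """Rebuild the original table (original row order) from the encoding."""
        inv = np.argsort(self.order, kind="stable")
        cols = {name: lab[inv] for name, lab in zip(self.column_names[:-1], self.labels)}
        cols[self.column_names[-1]] = self.response[inv]
        return pd.DataFrame(cols)

    def summary(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "clusters_per_level": {
                k: int(len(self.cluster_sizes[k])) for k in sorted(self.cluster_sizes)
            },
            "n_treated_entities": self.n_entities,
            "n_blocks": self.n_blocks,
        }

    def summary_json(self) -> str:
        return json.dumps(self.summary(), indent=2)


def _dense_codes(arrays: list[np.ndarray]) -> np.ndarray:
    """Dense group ids for the row-wise tuples of ``arrays`` (contiguity assumed)."""
    n = arrays[0].shape[0]
    if n == 0:
        return np.empty(0, dtype=np.int64)
    changed = np.zeros(n, dtype=bool)
    for a in arrays:
        changed[1:] |= a[1:] != a[:-1]
    return np.cumsum(changed).astype(np.int64)


def encode_design(
    table: DesignTable,
    treatment_level: int = 1,
    skip_levels=(),
    interaction: bool | None = None,
) -> tuple[DesignSpec, ClusterIndex]:
    """Infer the resampling plan and build the cluster index.

    Parameters
    ----------
    table:
        Validated long-format table.
    treatment_level:
        1-based index of the treatment-label column.
    skip_levels:
        1-based indices of bootstrap-eligible levels that must not be
        resampled (observations at that level are not a random sample).
    interaction:
        Force interaction handling on/off.  ``None`` auto-detects: the column
        right of the treatment column is an interaction/duplicate column when
        its unique-row partition is identical to that of the columns to its
        left.
    """
    L = table.n_levels
    t = int(treatment_level)
    if not 1 <= t <= L:
        raise DesignError(f"treatment_level {t} not in 1..{L}")

    df = table.data
    # first-appearance integer codes per column, then stable lexsort so that
    # labels like "10" do not sort before "2" and input order is respected
    col_codes = [pd.factorize(df.iloc[:, k])[0] for k in range(L)]
    order = np.lexsort(tuple(reversed([c for c in col_codes])))
    order = order.astype(np.int64)
    labels = [df.iloc[:, k].to_numpy(dtype=object)[order] for k in range(L)]
    sorted_codes = [c[order] for c in col_codes]
    response = table.response[order]

    row_codes: dict[int, np.ndarray] = {}
    cluster_starts: dict[int, np.ndarray] = {}
    cluster_sizes: dict[int, np.ndarray] = {}
    for k in range(1, L + 1):
        codes = _dense_codes(sorted_codes[:k])
        row_codes[k] = codes
        starts = np.flatnonzero(np.r_[True, codes[1:] != codes[:-1]])
        cluster_starts[k] = starts
        cluster_sizes[k] = np.diff(np.r_[starts, len(codes)])

    # interaction auto-detection: the column after the treatment column adds
    # no new distinctions to the unique-row partition
    interaction_level: int | None = None
    has_interaction = bool(interaction) if interaction is not None else False
    if interaction is None and t < L:
        if len(cluster_sizes[t + 1]) == len(cluster_sizes[t]):
            has_interaction = True
    if has_interaction:
        if t >= L:
            raise DesignError("interaction requires a column after the treatment column")
        interaction_level = t + 1

    te = t + 1 + (1 if has_interaction else 0)
    treated_entity_level: int | None = te if te <= L else None
    boot_start = (treated_entity_level or L) + 1
    bootstrap_levels = tuple(range(boot_start, L + 1))
    skip = tuple(sorted(int(s) for s in skip_levels))
    for s in skip:
        if s not in bootstrap_levels:
            raise DesignError(
                f"skip level {s} is not a bootstrap-eligible level {bootstrap_levels}"
            )

    spec = DesignSpec(
        treatment_level=t,
        block_levels=tuple(range(1, t)),
        treated_entity_level=treated_entity_level,
        bootstrap_levels=bootstrap_levels,
        skip_levels=skip,
        has_interaction=has_interaction,
        interaction_level=interaction_level,
        level_names=tuple(table.level_names),
    )

    # treated entities: clusters at the treated-entity level, or single rows
    if treated_entity_level is not None:
        ent_rows = row_codes[treated_entity_level]
    else:
        ent_rows = np.arange(table.n_rows, dtype=np.int64)
    ent_starts = np.flatnonzero(np.r_[True, ent_rows[1:] != ent_rows[:-1]])
    block_rows = row_codes[t - 1] if t > 1 else np.zeros(table.n_rows, dtype=np.int64)
    group_rows = row_codes[t]
    entity_block = block_rows[ent_starts]
    entity_group = group_rows[ent_starts]

    # treatment codes in first-appearance order (0, 1, 2, ...) so that a
    # hypothesized linear dose ordering follows the input's label order
    treat_labels = labels[t - 1]
    first_seen, label_names = pd.factorize(treat_labels)
    label_names = np.asarray(label_names, dtype=object)
    entity_label = first_seen[ent_starts].astype(np.int64)

    # nesting consistency: a child cluster id must never straddle two parents;
    # guaranteed by construction (each id extends the parent prefix tuple), but
    # verify cheaply so corrupted inputs fail loudly rather than silently
    for k in range(2, L + 1):
        parent = row_codes[k - 1][cluster_starts[k]]
        if np.any(np.diff(parent) < 0):
            raise DesignError(f"nesting violation between levels {k - 1} and {k}")

    index = ClusterIndex(
        n_rows=table.n_rows,
        n_levels=L,
        order=order,
        response=response,
        labels=labels,
        row_codes=row_codes,
        cluster_starts=cluster_starts,
        cluster_sizes=cluster_sizes,
        entity_of_row=ent_rows,
        entity_block=entity_block.astype(np.int64),
        entity_label=entity_label,
        entity_group=entity_group.astype(np.int64),
        treatment_label_names=label_names,
        column_names=list(df.columns),
    )
    return spec, index


# ---------------------------------------------------------------------------
# Crossed factors
# ---------------------------------------------------------------------------

def rearrange_crossed(
    table: DesignTable,
    factor_of_interest: int,
    other_factors,
    joiner: str = "-",
) -> DesignTable:
    """Recode crossed factors as a nested design.

    All ``other_factors`` (1-based column indices on the same hierarchy level
    as ``factor_of_interest``) are concatenated into a single composite label
    column placed immediately before the factor of interest, which is then
    treated as nested within the composite.  Row count is unchanged.
    """
    foi = int(factor_of_interest)
    others = [int(o) for o in other_factors]
    if foi in others:
        raise DesignError("factor_of_interest cannot be listed among other_factors")
    L = table.n_levels
    for c in [foi, *others]:
        if not 1 <= c <= L:
            raise DesignError(f"factor index {c} not in 1..{L}")
    if not others:
        return table

    df = table.data
    names = list(df.columns)
    other_names = [names[o - 1] for o in others]
    composite = df[other_names].agg(joiner.join, axis=1)
    comp_name = "|".join(other_names)

    new_cols = {}
    for pos, name in enumerate(names, start=1):
        if pos in others:
            continue
        if pos == foi:
            new_cols[comp_name] = composite
        new_cols[name] = df[name]
    return DesignTable(pd.DataFrame(new_cols))
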