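"""Directional RNA state-change calling from replicate expression matrices.

A "state change" is a gene called significantly up- or downregulated between a
treatment group and its vehicle control after three filters: an adjusted
p-value (Benjamini–Hochberg FDR) at or below ``alpha``, an average expression
intensity above ``min_intensity`` in at least one of the two groups, and an
absolute linear-scale fold change above ``min_fold``.  Genes represented by
multiple probes are considered changed if at least one probe changes; probes
that pass in opposite directions leave the gene out of the call set and in an
"ambiguous" side table.

The per-probe test is an ordinary two-sample pooled-variance t statistic on
log2 intensities — a deliberate, documented simplification of a moderated
linear-model fit, adequate at ~5 replicates per group.
"""

from __future__ import annotations

import math
from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .knowledge_graph import Direction

#: Columns of the probe-statistics frame returned by :func:`probe_statistics`.
PROBE_STAT_COLUMNS = (
    "probe",
    "gene",
    "fold_change",
    "t",
    "p_raw",
    "p_adj",
    "max_group_mean",
)


@dataclass
class ExpressionExperiment:
    """A probe-by-sample intensity matrix with group labels and a probe→gene map.

    Intensities are on the linear scale (nonnegative).  ``groups`` maps every
    sample (column) to a group label; ``probe_map`` maps every probe (row) to a
    gene, many-to-one allowed.
    """

    intensities: pd.DataFrame
    groups: Mapping[str, str]
    probe_map: Mapping[str, str]

    def __post_init__(self) -> None:
        missing_groups = [s for s in self.intensities.columns if s not in self.groups]
        if missing_groups:
            raise ValueError(f"samples without a group label: {missing_groups[:5]}")
        missing_genes = [p for p in self.intensities.index if p not in self.probe_map]
        if missing_genes:
            raise ValueError(f"probes without a gene mapping: {missing_genes[:5]}")
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("intensities must be nonnegative (linear scale)")

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.intensities.columns if self.groups[s] == group]

    @property
    def measured_genes(self) -> frozenset[str]:
        return frozenset(self.probe_map[p] for p in self.intensities.index)


@dataclass(frozen=True)
class StateChange:
    """A gene-level directional call."""

    gene: str
    direction: Direction
    log2_fold_change: float
    p_adj: float

    def __post_init__(self) -> None:
        up = self.log2_fold_change > 0
        if (self.direction == "up") != up:
            raise ValueError(
                f"{self.gene}: direction {self.direction!r} inconsistent with "
                f"log2 fold change {self.log2_fold_change}"
            )


@dataclass
class StateChangeSet:
    """At most one directional call per gene, plus an ambiguous-gene side table."""

    changes: dict[str, StateChange]
    contrast: str = ""
    ambiguous: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for gene, change in self.changes.items():
            if change.gene != gene:
                raise ValueError(f"key {gene!r} does not match change.gene {change.gene!r}")

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.changes)

    def direction_of(self, gene: str) -> Direction:
        return self.changes[gene].direction

    def __len__(self) -> int:
        return len(self.changes)


def quantile_normalize(matrix: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Force every column onto the common per-rank cross-column mean distribution.

    The reference vector is the mean, across columns, of each column's sorted
    values; entry i of a column is replaced by the reference value at its rank.
    Ties within a column receive the mean of the reference values over their
    tied rank span (so with ties, a column's multiset can deviate from the
    reference; tie-free columns match it exactly and the transform is then
    idempotent).
    """
    is_frame = isinstance(matrix, pd.DataFrame)
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0 or X.shape[1] == 0:
        raise ValueError("matrix must be 2-D and nonempty")
    if np.isnan(X).any():
        raise ValueError("matrix must not contain NaN")
    if (X < 0).any():
        raise ValueError("matrix must not contain negative intensities")
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        sorted_col = col[order]
        # run boundaries of tied values in sorted order
        starts = np.flatnonzero(np.r_[True, np.diff(sorted_col) != 0])
        ends = np.r_[starts[1:], len(col)]
        normalized_sorted = np.empty_like(sorted_col)
        csum = np.r_[0.0, np.cumsum(reference)]
        for a, b in zip(starts, ends):
            normalized_sorted[a:b] = (csum[b] - csum[a]) / (b - a)
        out[order, j] = normalized_sorted
    if is_frame:
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order, capped at 1."""
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if arr.size == 0:
        return arr.copy()
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def probe_statistics(
    exp: ExpressionExperiment,
    treatment: str,
    control: str,
) -> pd.DataFrame:
    """Per-probe fold change and pooled-variance t test of treatment vs control.

    The t statistic and two-sided p-value are computed on log2 intensities;
    the fold change is the ratio of linear-scale group means (treatment over
    control) and ``max_group_mean`` is the larger of the two linear means.
    BH-adjusted p-values across all probes of the contrast are included.

    Probes with zero variance in both groups get p=1 when the group means are
    equal and p=0 otherwise.
    """
    t_samples = exp.samples_in_group(treatment)
    c_samples = exp.samples_in_group(control)
    for label, samples in ((treatment, t_samples), (control, c_samples)):
        if len(samples) < 2:
            raise ValueError(f"group {label!r} needs >=2 replicates, has {len(samples)}")
    T = exp.intensities[t_samples].to_numpy(dtype=float)
    C = exp.intensities[c_samples].to_numpy(dtype=float)
    if (T <= 0).any() or (C <= 0).any():
        raise ValueError("intensities must be strictly positive to take log2")
    logT, logC = np.log2(T), np.log2(C)
    import warnings

    with warnings.catch_warnings():
        # near-constant probes trigger a precision warning; the zero-variance
        # convention below handles them explicitly
        warnings.filterwarnings("ignore", message="Precision loss occurred")
        res = sps.ttest_ind(logT, logC, axis=1, equal_var=True)
    tstat = np.asarray(res.statistic, dtype=float)
    p_raw = np.asarray(res.pvalue, dtype=float)
    # zero pooled variance: scipy yields nan; apply the stated convention
    degenerate = ~np.isfinite(tstat)
    if degenerate.any():
        diff = logT.mean(axis=1) - logC.mean(axis=1)
        equal = np.isclose(diff, 0.0)
        tstat[degenerate & equal] = 0.0
        p_raw[degenerate & equal] = 1.0
        unequal = degenerate & ~equal
        tstat[unequal] = np.sign(diff[unequal]) * np.inf
        p_raw[unequal] = 0.0
    mean_t = T.mean(axis=1)
    mean_c = C.mean(axis=1)
    frame = pd.DataFrame(
        {
            "probe": exp.intensities.index.astype(str),
            "gene": [exp.probe_map[p] for p in exp.intensities.index],
            "fold_change": mean_t / mean_c,
            "t": tstat,
            "p_raw": p_raw,
            "p_adj": bh_adjust(p_raw),
            "max_group_mean": np.maximum(mean_t, mean_c),
        }
    )
    return frame.reset_index(drop=True)


def call_state_changes(
    stats: pd.DataFrame,
    *,
    alpha: float = 0.05,
    min_intensity: float = 150.0,
    min_fold: float = 1.3,
    contrast: str = "",
) -> StateChangeSet:
    """Apply the significance filters and collapse probes to gene-level calls.

    A probe passes iff ``p_adj <= alpha`` and ``max_group_mean > min_intensity``
    and its fold change exceeds ``min_fold`` in either direction (ratio
    > min_fold or < 1/min_fold, strictly).  A gene is called if at least one of
    its probes passes; its direction and reported statistics come from the
    passing probe with the smallest adjusted p (ties broken by larger absolute
    log2 fold change, then probe id).  Genes whose passing probes disagree in
    direction are excluded and listed in ``ambiguous``.
    """
    if min_fold <= 1:
        raise ValueError("min_fold must exceed 1")
    if stats.empty:
        return StateChangeSet({}, contrast=contrast)
    fc = stats["fold_change"]
    passing = stats[
        (stats["p_adj"] <= alpha)
        & (stats["max_group_mean"] > min_intensity)
        & ((fc > min_fold) | (fc < 1.0 / min_fold))
    ].copy()
    changes: dict[str, StateChange] = {}
    ambiguous: list[str] = []
    if not passing.empty:
        passing["log2_fold_change"] = np.log2(passing["fold_change"])
        passing["_abs_l2fc"] = passing["log2_fold_change"].abs()
        passing = passing.sort_values(
            ["p_adj", "_abs_l2fc", "probe"], ascending=[True, False, True]
        )
        for gene, rows in passing.groupby("gene", sort=True):
            directions = {"up" if v > 0 else "down" for v in rows["log2_fold_change"]}
            if len(directions) > 1:
                ambiguous.append(gene)
                continue
            best = rows.iloc[0]
            changes[gene] = StateChange(
                gene=gene,
                direction="up" if best["log2_fold_change"] > 0 else "down",
                log2_fold_change=float(best["log2_fold_change"]),
                p_adj=float(best["p_adj"]),
            )
    return StateChangeSet(changes, contrast=contrast, ambiguous=tuple(sorted(ambiguous)))


def sample_pca(exp: ExpressionExperiment, n_components: int = 2) -> pd.DataFrame:
    """Sample coordinates on the leading principal components of log2 intensities.

    Offered as an outlier-screening report; no samples are excluded
    automatically (exclusion lists are a user decision).
    """
    X = np.log2(exp.intensities.to_numpy(dtype=float) + 1.0)
    centered = X - X.mean(axis=1, keepdims=True)
    # samples are observations: SVD of the samples-by-probes matrix
    _, _, vt = np.linalg.svd(centered.T - centered.T.mean(axis=0), full_matrices=False)
    coords = (centered.T - centered.T.mean(axis=0)) @ vt[:n_components].T
    return pd.DataFrame(
        coords,
        index=exp.intensities.columns,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )


def write_state_changes(sc: StateChangeSet, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("gene\tdirection\tlog2_fold_change\tp_adj\n")
        for gene in sorted(sc.changes):
            c = sc.changes[gene]
            fh.write(f"{c.gene}\t{c.direction}\t{c.log2_fold_change:.6g}\t{c.p_adj:.6g}\n")
    return path


def write_ambiguous_genes(sc: StateChangeSet, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("gene\n")
        for gene in sc.ambiguous:
            fh.write(f"{gene}\n")
    return path


def read_state_changes(path: str | Path, contrast: str = "") -> StateChangeSet:
    """Read a state-change TSV (gene, direction[, log2_fold_change, p_adj])."""
    frame = pd.read_csv(path, sep="\t", comment="#", dtype={"gene": str})
    required = {"gene", "direction"}
    if not required.issubset(frame.columns):
        raise ValueError(f"state-change table must have columns {sorted(required)}")
    changes: dict[str, StateChange] = {}
    for row in frame.itertuples(index=False):
        direction = str(row.direction)
        if direction not in ("up", "down"):
            raise ValueError(f"{row.gene}: direction must be 'up' or 'down', got {direction!r}")
        l2fc = float(getattr(row, "log2_fold_change", math.nan))
        if math.isnan(l2fc):
            l2fc = 1.0 if direction == "up" else -1.0
        p_adj = float(getattr(row, "p_adj", 0.0))
        changes[str(row.gene)] = StateChange(str(row.gene), direction, l2fc, p_adj)
    return StateChangeSet(changes, contrast=contrast)
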