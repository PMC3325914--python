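"""Multi-treatment comparison of state-change sets and scored hypotheses.

Answers the cross-treatment questions: how many state changes are shared
between treatments (exclusive Venn-region counts and percentages of the
union), and which upstream hypotheses are significant in which treatment
panel, with consistency of the inferred direction across panels.
"""

from __future__ import annotations

import json
import warnings
from collections.abc import Mapping, Set
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from .scoring import ScoredHypothesis, scored_to_frame
from .state_change import StateChangeSet


@dataclass(frozen=True)
class TreatmentPanel:
    """One treatment condition: its state changes and its scored hypotheses."""

    label: str
    state_changes: StateChangeSet
    scored: tuple[ScoredHypothesis, ...]

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("panel label must be non-empty")


@dataclass(frozen=True)
class VennSummary:
    """Exclusive region counts over labeled gene sets.

    ``region_counts`` maps every nonempty subset of labels to the number of
    genes lying in exactly those sets and no other; regions partition the
    union, so the counts sum to ``total``.
    """

    region_counts: dict[frozenset[str], int]
    total: int


@dataclass(frozen=True)
class ComparisonResult:
    """Hypothesis table across panels plus its summary quantities."""

    table: pd.DataFrame
    n_unique_significant: int
    inconsistent_mechanisms: frozenset[str]


def venn_region_counts(sets: Mapping[str, Set[str]]) -> VennSummary:
    """Exclusive-region counts for 2 or more labeled gene sets."""
    if len(sets) < 2:
        raise ValueError(f"need at least 2 labeled sets, got {len(sets)}")
    labels = sorted(sets)
    union: set[str] = set().union(*(sets[l] for l in labels))
    counts: dict[frozenset[str], int] = {}
    # every nonempty label subset appears, zero counts included
    from itertools import combinations

    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            counts[frozenset(combo)] = 0
    for gene in union:
        member = frozenset(l for l in labels if gene in sets[l])
        counts[member] += 1
    return VennSummary(region_counts=counts, total=len(union))


def overlap_percentage(count: int, total: int) -> float:
    """100·count/total, rounded half-up to one decimal (printed-style percent)."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError(f"need 0 <= count <= total, got {count}/{total}")
    exact = Decimal(count * 100) / Decimal(total)
    return float(exact.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def hypothesis_comparison_table(
    panels: list[TreatmentPanel],
    *,
    include_all: bool = False,
) -> ComparisonResult:
    """One row per (mechanism, direction) significant in at least one panel.

    Per-panel columns report the signed supporting count and both p-values.
    Rows whose mechanism is significant with *opposite* directions in
    different panels are flagged ``direction_inconsistent``.
    ``include_all=True`` keeps every scored hypothesis instead of only the
    significant ones.
    """
    if not panels:
        raise ValueError("need at least one panel")
    labels = [p.label for p in panels]
    if len(set(labels)) != len(labels):
        raise ValueError("panel labels must be unique")
    by_panel: dict[str, dict[tuple[str, str], ScoredHypothesis]] = {
        p.label: {(s.mechanism, s.direction): s for s in p.scored} for p in panels
    }
    keys: set[tuple[str, str]] = set()
    for p in panels:
        for s in p.scored:
            if include_all or s.significant:
                keys.add((s.mechanism, s.direction))
    sig_directions: dict[str, set[str]] = {}
    for p in panels:
        for s in p.scored:
            if s.significant:
                sig_directions.setdefault(s.mechanism, set()).add(s.direction)
    inconsistent = frozenset(m for m, dirs in sig_directions.items() if len(dirs) > 1)
    rows = []
    n_significant = 0
    for mech, direction in sorted(keys):
        row: dict[str, object] = {"mechanism": mech, "direction": direction}
        n_panels_sig = 0
        for label in labels:
            s = by_panel[label].get((mech, direction))
            row[f"{label}:supporting_count"] = s.supporting_count if s else pd.NA
            row[f"{label}:richness_p"] = s.richness_p if s else pd.NA
            row[f"{label}:concordance_p"] = s.concordance_p if s else pd.NA
            row[f"{label}:significant"] = bool(s.significant) if s else False
            if s and s.significant:
                n_panels_sig += 1
        row["n_panels_significant"] = n_panels_sig
        row["direction_inconsistent"] = mech in inconsistent
        if n_panels_sig > 0:
            n_significant += 1
        rows.append(row)
    table = pd.DataFrame(rows)
    return ComparisonResult(
        table=table,
        n_unique_significant=n_significant,
        inconsistent_mechanisms=inconsistent,
    )


def _venn_frame(venn: VennSummary) -> pd.DataFrame:
    rows = [
        {"region": "&".join(sorted(labels)), "count": count}
        for labels, count in sorted(
            venn.region_counts.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
        )
    ]
    return pd.DataFrame(rows)


def write_reports(
    panels: list[TreatmentPanel],
    venn: VennSummary | None,
    comparison: ComparisonResult | None,
    outdir: str | Path,
    *,
    config: Mapping[str, object] | None = None,
) -> list[Path]:
    """Write venn.tsv, hypotheses_by_treatment.tsv/.json, per-panel scored
    tables and a run manifest; returns the written paths.

    Output is deterministic for identical inputs (no timestamps); the manifest
    records the thresholds/config mapping verbatim.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    import numpy
    import scipy

    from . import __version__

    manifest: dict[str, object] = {
        "package": "rcrkit",
        "versions": {
            "rcrkit": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "panels": [p.label for p in panels],
        "config": dict(config) if config else {},
    }
    if not panels:
        warnings.warn("no panels supplied; writing manifest only", stacklevel=2)
    if venn is not None:
        path = outdir / "venn.tsv"
        _venn_frame(venn).to_csv(path, sep="\t", index=False)
        written.append(path)
        manifest["venn_total"] = venn.total
    if comparison is not None:
        path = outdir / "hypotheses_by_treatment.tsv"
        comparison.table.to_csv(path, sep="\t", index=False, float_format="%.6g")
        written.append(path)
        jpath = outdir / "hypotheses_by_treatment.json"
        comparison.table.to_json(jpath, orient="records", indent=2)
        written.append(jpath)
        manifest["n_unique_significant"] = comparison.n_unique_significant
        manifest["direction_inconsistent_mechanisms"] = sorted(
            comparison.inconsistent_mechanisms
        )
    for panel in panels:
        path = outdir / f"scored_{panel.label}.tsv"
        scored_to_frame(list(panel.scored)).to_csv(
            path, sep="\t", index=False, float_format="%.6g"
        )
        written.append(path)
    mpath = outdir / "manifest.json"
    with mpath.open("w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    written.append(mpath)
    return written
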