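"""Signed causal knowledge graphs.

A knowledge graph is the substrate for reverse causal reasoning: a set of
curated, signed causal edges from upstream *mechanisms* (e.g. the
transcriptional activity of a transcription factor, or the activity of a
kinase) to the RNA expression of downstream *genes*.  An edge sign of +1
means "increased mechanism activity increases expression of this gene",
-1 the opposite, and 0 records a causal connection whose direction is
ambiguous or contested in the literature.

Mechanisms and genes live in disjoint identifier namespaces (mechanisms are
conventionally prefixed, e.g. ``H:PPARG``); the loader enforces this so a
gene can never silently double as a mechanism.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Set
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

Direction = Literal["up", "down"]

DIRECTIONS: tuple[Direction, Direction] = ("up", "down")

_SIGN_TOKENS = {
    "+1": 1,
    "1": 1,
    "-1": -1,
    "−1": -1,  # unicode minus
    "0": 0,
    "increases": 1,
    "decreases": -1,
    "ambiguous": 0,
}
_SIGN_LABELS = {1: "+1", -1: "-1", 0: "0"}
_HEADER = ("mechanism", "sign", "gene")


class KnowledgeGraphFormatError(ValueError):
    """A knowledge-graph TSV is structurally malformed (wrong column count)."""


class EmptyUniverseError(ValueError):
    """No measured gene is the target of any causal edge; scoring is impossible."""


@dataclass(frozen=True, order=True)
class CausalEdge:
    """One signed causal relationship mechanism --(sign)--> gene."""

    mechanism: str
    gene: str
    sign: int

    def __post_init__(self) -> None:
        if self.sign not in (-1, 0, 1):
            raise ValueError(f"edge sign must be -1, 0 or +1, got {self.sign!r}")
        if not self.mechanism or not self.gene:
            raise ValueError("mechanism and gene identifiers must be non-empty")


@dataclass(frozen=True, order=True)
class Hypothesis:
    """A candidate upstream explanation: the mechanism's activity went up or down."""

    mechanism: str
    direction: Direction

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")


class KnowledgeGraph:
    """An immutable set of signed mechanism→gene edges.

    Duplicate rows are merged at construction: exact duplicates collapse to a
    single edge, and a (mechanism, gene) pair supported by conflicting signs
    collapses to sign 0 (ambiguous), mirroring how curated knowledgebases flag
    contested literature evidence.

    Parameters
    ----------
    edges:
        Iterable of :class:`CausalEdge`.
    extra_mechanisms:
        Mechanism identifiers to register even if they have no edges
        (isolated mechanisms still yield hypotheses, scored with m=0).
    """

    def __init__(self, edges: Iterable[CausalEdge], extra_mechanisms: Iterable[str] = ()) -> None:
        merged: dict[tuple[str, str], set[int]] = {}
        for edge in edges:
            merged.setdefault((edge.mechanism, edge.gene), set()).add(edge.sign)
        targets: dict[str, dict[str, int]] = {}
        for (mech, gene), signs in merged.items():
            sign = signs.pop() if len(signs) == 1 else 0
            targets.setdefault(mech, {})[gene] = sign
        for mech in extra_mechanisms:
            targets.setdefault(mech, {})
        self._targets = targets
        self._mechanisms = frozenset(targets)
        self._genes = frozenset(g for tgts in targets.values() for g in tgts)
        clash = self._mechanisms & self._genes
        if clash:
            raise ValueError(
                "mechanism and gene namespaces must be disjoint; "
                f"shared identifiers: {sorted(clash)[:5]}"
            )

    @property
    def mechanisms(self) -> frozenset[str]:
        return self._mechanisms

    @property
    def genes(self) -> frozenset[str]:
        """All genes appearing as an edge target."""
        return self._genes

    @property
    def edges(self) -> frozenset[CausalEdge]:
        return frozenset(
            CausalEdge(mech, gene, sign)
            for mech, tgts in self._targets.items()
            for gene, sign in tgts.items()
        )

    @property
    def n_edges(self) -> int:
        return sum(len(t) for t in self._targets.values())

    def downstream_targets(self, mechanism: str) -> dict[str, int]:
        """Map gene → edge sign for every target of ``mechanism``.

        The size of this map (restricted to the scoring universe) is the
        hypergeometric "successes in population" count m.  Raises ``KeyError``
        for an unknown mechanism; a mechanism with no edges returns ``{}``.
        """
        return dict(self._targets[mechanism])

    def hypotheses(self) -> list[Hypothesis]:
        """Both directional hypotheses for every mechanism, sorted."""
        return [Hypothesis(m, d) for m in sorted(self._mechanisms) for d in DIRECTIONS]

    def __len__(self) -> int:
        return self.n_edges

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"KnowledgeGraph({len(self._mechanisms)} mechanisms, "
            f"{len(self._genes)} genes, {self.n_edges} edges)"
        )


@dataclass(frozen=True)
class UniverseSpec:
    """The gene universe shared by all hypotheses in one scoring run.

    N = |universe_genes| is the hypergeometric population size.
    """

    universe_genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.universe_genes:
            raise EmptyUniverseError("scoring universe must contain at least one gene")

    @property
    def N(self) -> int:
        return len(self.universe_genes)


def build_universe(
    kg: KnowledgeGraph,
    measured_genes: Set[str] | Iterable[str],
    *,
    restrict_to_graph: bool = True,
) -> UniverseSpec:
    """Construct the scoring universe from a graph and the measured genes.

    By default the universe is the intersection of the measured genes with the
    graph's edge targets, so that richness compares hypotheses over the genes
    that could possibly have supported any of them.  ``restrict_to_graph=False``
    uses all measured genes instead (a larger, more conservative population).
    """
    measured = set(measured_genes)
    if not measured:
        raise ValueError("measured_genes must be nonempty")
    universe = measured & kg.genes if restrict_to_graph else measured
    if not universe:
        raise EmptyUniverseError(
            "no measured gene is a target of any causal edge; cannot score"
        )
    return UniverseSpec(frozenset(universe))


def load_knowledge_graph(
    path: str | Path,
    *,
    header: bool | Literal["auto"] = "auto",
) -> KnowledgeGraph:
    """Load a knowledge graph from a 3-column TSV (mechanism, sign, gene).

    Sign tokens may be ``+1|-1|0`` or ``increases|decreases|ambiguous``.
    Lines starting with ``#`` and blank lines are ignored.  ``header`` controls
    whether the first data row is a column-name row; ``"auto"`` detects it.
    """
    path = Path(path)
    edges: list[CausalEdge] = []
    first_data_row = True
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise KnowledgeGraphFormatError(
                    f"{path}:{lineno}: expected 3 tab-separated columns "
                    f"(mechanism, sign, gene), found {len(fields)}"
                )
            if first_data_row:
                first_data_row = False
                lowered = tuple(f.strip().lower() for f in fields)
                if header is True or (header == "auto" and lowered == _HEADER):
                    continue
            mech, sign_token, gene = (f.strip() for f in fields)
            token = sign_token.lower()
            if token not in _SIGN_TOKENS:
                raise ValueError(
                    f"{path}:{lineno}: unknown sign token {sign_token!r} "
                    f"(expected one of {sorted(set(_SIGN_TOKENS))})"
                )
            edges.append(CausalEdge(mech, gene, _SIGN_TOKENS[token]))
    return KnowledgeGraph(edges)


def write_knowledge_graph(kg: KnowledgeGraph, path: str | Path) -> Path:
    """Write the canonicalized edge set as a headered TSV, sorted."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("mechanism\tsign\tgene\n")
        for edge in sorted(kg.edges):
            fh.write(f"{edge.mechanism}\t{_SIGN_LABELS[edge.sign]}\t{edge.gene}\n")
    return path
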