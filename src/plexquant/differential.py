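"""Differential-expression calls and set-level summaries (Venn regions, COG tallies).

A protein is called up-regulated when it is accurately quantified with a median
ratio >= 1.2 and down-regulated at <= 0.83 (both boundaries inclusive); the
asymmetric thresholds are the published convention, roughly symmetric on the
log scale (log2 1.2 = 0.263, log2 0.83 = -0.269).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .errors import ConfigurationError
from .io import UNANNOTATED, AnnotationMap
from .quant import STATUS_QUANTIFIED, ProteinQuant

DIRECTION_UP = "up"
DIRECTION_DOWN = "down"
DIRECTION_NONE = "none"


@dataclass(frozen=True)
class DECall:
    protein_acc: str
    comparison: str
    median_ratio: float
    direction: str
    status: str  # quantitation status, preserved for non-called proteins


def call_de(
    quants: Iterable[ProteinQuant],
    up_threshold: float = 1.2,
    down_threshold: float = 0.83,
) -> list[DECall]:
    """Assign up/down/none to every quantitation record.

    Only accurately quantified proteins (n_psm and p-value gate passed) can be
    called; everything else keeps direction 'none' with its status preserved so
    absence is explicit in downstream set algebra.
    """
    if not down_threshold < 1 < up_threshold:
        raise ConfigurationError(
            f"need down_threshold < 1 < up_threshold, got {down_threshold}, {up_threshold}"
        )
    calls = []
    for q in quants:
        if q.status == STATUS_QUANTIFIED and q.median_ratio >= up_threshold:
            direction = DIRECTION_UP
        elif q.status == STATUS_QUANTIFIED and q.median_ratio <= down_threshold:
            direction = DIRECTION_DOWN
        else:
            direction = DIRECTION_NONE
        calls.append(
            DECall(
                protein_acc=q.protein_acc,
                comparison=q.comparison,
                median_ratio=q.median_ratio,
                direction=direction,
                status=q.status,
            )
        )
    return calls


def de_sets(calls: Iterable[DECall]) -> dict[str, set[str]]:
    """Accessions called DE (either direction), grouped by comparison."""
    out: dict[str, set[str]] = {}
    for c in calls:
        out.setdefault(c.comparison, set())
        if c.direction != DIRECTION_NONE:
            out[c.comparison].add(c.protein_acc)
    return out


@dataclass(frozen=True)
class VennSummary:
    """Region cardinalities of a 3-set Venn diagram.

    ``regions`` is keyed by the frozenset of set names whose intersection the
    region belongs to, exclusively: e.g. {'A'} counts members of A only,
    {'A','B'} members of A and B but not C.
    """

    names: tuple[str, str, str]
    regions: Mapping[frozenset, int]

    def region(self, *names: str) -> int:
        return self.regions[frozenset(names)]

    @property
    def totals(self) -> dict[str, int]:
        return {
            n: sum(c for key, c in self.regions.items() if n in key) for n in self.names
        }


def venn_counts(sets: Mapping[str, set]) -> VennSummary:
    """Exact region counts for three named sets."""
    if len(sets) != 3:
        raise ConfigurationError(f"need exactly 3 named sets, got {len(sets)}")
    names = tuple(sets)
    universe = set().union(*sets.values())
    regions = {
        frozenset(key): 0
        for key in (
            (names[0],),
            (names[1],),
            (names[2],),
            (names[0], names[1]),
            (names[0], names[2]),
            (names[1], names[2]),
            names,
        )
    }
    for item in universe:
        membership = frozenset(n for n in names if item in sets[n])
        regions[membership] += 1
    return VennSummary(names=names, regions=regions)  # type: ignore[arg-type]


def cog_tally(calls: Iterable[DECall], ann: AnnotationMap) -> dict[str, int]:
    """Count distinct DE accessions (union over comparisons) per COG category.

    Proteins without a COG annotation fall under the no-hit category.
    """
    accs = {c.protein_acc for c in calls if c.direction != DIRECTION_NONE}
    tally: dict[str, int] = {}
    for acc in accs:
        cat = ann.cog.get(acc, UNANNOTATED)
        tally[cat] = tally.get(cat, 0) + 1
    return tally
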