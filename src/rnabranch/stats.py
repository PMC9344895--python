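"""Branching-property statistics of sampled trees and dispersion placement.

Each plane tree yields a record of the branching quantities a structural
biologist reads off a secondary structure: hairpins (leaves), interior
loops (degree-1 non-root nodes), multiloops (non-root nodes where >= 3
helices meet, i.e. down degree >= 2), the maximum branching in a multiloop,
the exterior-loop degree, and two length-type quantities, height and
diameter in edges (each edge is one helix; diameter operationalizes the
longest helix-to-helix run through the tree).

A sample of records is condensed to per-statistic dispersion summaries
(mean, unbiased variance, nearest-rank quantiles), and an observed value —
for example a hairpin count predicted for a real sequence — is placed
within the sampled dispersion as a percentile rank and a z-score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

from .trees import PlaneTree, degree_summary

__all__ = [
    "TreeStatRecord",
    "DispersionSummary",
    "tree_statistics",
    "summarize",
    "placement",
    "STATISTIC_NAMES",
]

STATISTIC_NAMES = (
    "n",
    "hairpins",
    "internal_nodes",
    "root_degree",
    "max_down_degree",
    "multiloop_count",
    "height",
    "diameter",
)

QUANTILE_LEVELS = (0.025, 0.25, 0.5, 0.75, 0.975)


@dataclass(frozen=True)
class TreeStatRecord:
    n: int
    hairpins: int
    internal_nodes: int
    root_degree: int
    max_down_degree: int
    multiloop_count: int
    height: int
    diameter: int

    def as_dict(self) -> dict[str, int]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _height_diameter(node: tuple) -> tuple[int, int]:
    # returns (height, best diameter within the subtree), both in edges
    best = 0
    top1 = top2 = 0  # two largest child heights + 1
    for child in node:
        h, d = _height_diameter(child)
        best = max(best, d)
        reach = h + 1
        if reach > top1:
            top1, top2 = reach, top1
        elif reach > top2:
            top2 = reach
    return top1, max(best, top1 + top2)


def tree_statistics(tree: PlaneTree) -> TreeStatRecord:
    """All branching statistics of one tree.

    The root is excluded from ``multiloop_count`` and ``max_down_degree``:
    it models the exterior loop, not a multiloop.
    """
    ds = degree_summary(tree)
    multiloops = sum(ds.down_degree_counts[2:])
    height, diameter = _height_diameter(tree.root)
    return TreeStatRecord(
        n=ds.n,
        hairpins=ds.d0,
        internal_nodes=ds.d1,
        root_degree=ds.root_degree,
        max_down_degree=ds.max_down_degree,
        multiloop_count=multiloops,
        height=height,
        diameter=diameter,
    )


@dataclass(frozen=True)
class DispersionSummary:
    count: int
    mean: dict
    variance: dict  # unbiased (n-1 denominator)
    sd: dict
    quantiles: dict  # statistic -> {level: value}, nearest-rank

    def as_dict(self) -> dict:
        return {
            "count": self.count,
            "mean": self.mean,
            "variance": self.variance,
            "sd": self.sd,
            "quantiles": {
                stat: {str(level): value for level, value in qs.items()}
                for stat, qs in self.quantiles.items()
            },
        }


def _nearest_rank(sorted_values: list, level: float):
    # smallest value whose rank/count >= level; integer statistics stay integers
    count = len(sorted_values)
    rank = max(1, math.ceil(level * count))
    return sorted_values[rank - 1]


def summarize(records) -> DispersionSummary:
    """Dispersion summary of a sample of tree statistics (>= 2 records)."""
    records = list(records)
    if len(records) < 2:
        raise ValueError("need at least 2 records to summarize dispersion")
    count = len(records)
    mean: dict = {}
    variance: dict = {}
    sd: dict = {}
    quantiles: dict = {}
    for name in STATISTIC_NAMES:
        values = [getattr(rec, name) for rec in records]
        mu = sum(values) / count
        var = sum((v - mu) ** 2 for v in values) / (count - 1)
        mean[name] = mu
        variance[name] = var
        sd[name] = math.sqrt(var)
        ordered = sorted(values)
        quantiles[name] = {lvl: _nearest_rank(ordered, lvl) for lvl in QUANTILE_LEVELS}
    return DispersionSummary(count=count, mean=mean, variance=variance, sd=sd,
                             quantiles=quantiles)


def placement(observed: float, samples) -> tuple[float, float | None]:
    """Place an observed value within a sample of one statistic.

    Returns ``(percentile, z)``: the percentile rank is the fraction of
    samples below the observation plus half the ties (midpoint convention);
    z is (observed - mean) / sd, or None when the sample has zero variance.
    """
    values = list(samples)
    if len(values) < 2:
        raise ValueError("need at least 2 sample values for placement")
    count = len(values)
    below = sum(1 for v in values if v < observed)
    ties = sum(1 for v in values if v == observed)
    percentile = (below + 0.5 * ties) / count
    mu = sum(values) / count
    var = sum((v - mu) ** 2 for v in values) / (count - 1)
    z = (observed - mu) / math.sqrt(var) if var > 0 else None
    return percentile, z
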