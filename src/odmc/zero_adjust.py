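"""Pseudo-observation adjustment for group x category cells that are all zero.

A category observed in no cluster of a group makes the log odds estimate
infinite and inflates standard errors to the point where the affected
hypotheses can never be rejected.  The heuristic adds a single count of 1 to
one cluster of each such cell — either a seeded random cluster or the
cluster with the largest total.  Cluster-level zeros are legitimate data and
are never touched; only group-level all-zero cells qualify.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_fit import CountTable, DataError

__all__ = ["ZeroReport", "detect_zero_cells", "add_pseudo"]

STRATEGIES = ("random_cluster", "largest_cluster", "none")


@dataclass
class ZeroReport:
    """Which cells were all-zero and which single counts were incremented."""

    zero_cells: list[tuple[str, str]]  # (group label, category label)
    strategy: str = "none"
    modified: list[tuple[str, str, str]] = field(default_factory=list)  # (group, cluster, category)
    seed: int | None = None


def detect_zero_cells(ct: CountTable) -> ZeroReport:
    """List all (group, category) cells with zero total across clusters."""
    pooled = ct.group_counts()
    degenerate = np.flatnonzero(pooled.sum(axis=1) == 0)
    if len(degenerate):
        bad = [ct.group_levels[g] for g in degenerate]
        raise DataError(f"groups with all counts zero: {bad}")
    cells = [
        (ct.group_levels[g], ct.categories[c]) for g, c in np.argwhere(pooled == 0)
    ]
    return ZeroReport(zero_cells=cells)


def add_pseudo(
    ct: CountTable, strategy: str = "random_cluster", seed: int | None = None
) -> tuple[CountTable, ZeroReport]:
    """Add one count to a single cluster of each all-zero group x category cell.

    ``random_cluster`` picks the cluster uniformly at random (seeded);
    ``largest_cluster`` picks the cluster with maximal total, ties broken by
    the lowest cluster position.  A table without zero cells is returned
    unchanged.
    """
    if strategy not in ("random_cluster", "largest_cluster"):
        raise ValueError(
            f"strategy must be 'random_cluster' or 'largest_cluster', got {strategy!r}"
        )
    report = detect_zero_cells(ct)
    report.strategy = strategy
    report.seed = seed
    if not report.zero_cells:
        return ct, report
    rng = np.random.default_rng(seed)
    counts = ct.counts.copy()
    gi = ct.group_index
    glookup = {g: i for i, g in enumerate(ct.group_levels)}
    clookup = {c: i for i, c in enumerate(ct.categories)}
    totals = ct.cluster_totals
    for g_label, c_label in report.zero_cells:
        g, c = glookup[g_label], clookup[c_label]
        rows = np.flatnonzero(gi == g)
        if len(rows) == 0:
            raise DataError(f"group {g_label!r} has no clusters")
        if strategy == "random_cluster":
            row = rng.choice(rows)
        else:
            row = rows[int(np.argmax(totals[rows]))]
        counts[row, c] += 1
        report.modified.append((g_label, str(ct.clusters[row]), c_label))
    return ct.with_counts(counts), report
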