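"""Re-partitioning assays into the fewest mass-resolvable multiplex pools.

Two assays conflict when any pair of their analytes (optionally including
salt-adduct satellites) is closer than the minimum resolvable gap.  Pooling
is then graph coloring with a pool-capacity bound: the greedy first-fit-
decreasing heuristic handles panel-sized instances, and an exhaustive
branch-and-bound solver provides provably minimal pool counts on small
instances as an oracle for the greedy.

The default minimum gap of 16 Da exceeds the sodium (21.98) and potassium
(37.95) adduct shifts only when adducts are checked explicitly; with
``include_adducts`` off it still guarantees that no two expected analyte
peaks overlap at typical linear-TOF peak widths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .panel import Assay, MassTable, Panel, pool_conflicts

DEFAULT_MIN_GAP = 16.0


@dataclass(frozen=True)
class ConflictGraph:
    """Simple undirected graph over assay ids; an edge marks a mass conflict."""

    nodes: tuple[str, ...]
    edges: frozenset[frozenset[str]]

    def degree(self, assay_id: str) -> int:
        return sum(1 for e in self.edges if assay_id in e)

    def conflicts(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.edges


def build_conflict_graph(
    assays: Sequence[Assay],
    mass_table: MassTable,
    min_gap: float = DEFAULT_MIN_GAP,
    include_adducts: bool = False,
) -> ConflictGraph:
    """Edge iff the assay pair has any cross-assay analyte gap < ``min_gap``."""
    if not min_gap > 0:
        raise ValueError("min_gap must be > 0")
    ids = tuple(a.assay_id for a in assays)
    edges = set()
    for i in range(len(assays)):
        for j in range(i + 1, len(assays)):
            if pool_conflicts(
                [assays[i], assays[j]], mass_table, min_gap, include_adducts
            ):
                edges.add(frozenset((ids[i], ids[j])))
    return ConflictGraph(ids, frozenset(edges))


def replex(
    assays: Sequence[Assay],
    mass_table: MassTable,
    max_plex: int = 9,
    min_gap: float = DEFAULT_MIN_GAP,
    include_adducts: bool = False,
    name: str = "replexed",
) -> Panel:
    """Greedy first-fit-decreasing pooling of assays under mass constraints.

    Assays are placed in order of descending conflict degree (ties broken by
    ascending assay id) into the first existing pool with no conflicting
    member and spare capacity, opening a new pool otherwise.  Deterministic;
    the emitted panel always passes conflict validation (a singleton pool is
    always valid, so the construction cannot fail).
    """
    if max_plex < 1:
        raise ValueError("max_plex must be >= 1")
    graph = build_conflict_graph(assays, mass_table, min_gap, include_adducts)
    by_id = {a.assay_id: a for a in assays}
    order = sorted(by_id, key=lambda aid: (-graph.degree(aid), aid))
    pools: list[list[str]] = []
    for aid in order:
        placed = False
        for pool in pools:
            if len(pool) < max_plex and not any(
                graph.conflicts(aid, member) for member in pool
            ):
                pool.append(aid)
                placed = True
                break
        if not placed:
            pools.append([aid])
    return Panel(
        name=name,
        assays=by_id,
        pools={f"P{i + 1}": pool for i, pool in enumerate(pools)},
        mass_table=mass_table,
        max_plex=max_plex,
    )


MAX_EXHAUSTIVE = 12


def replex_optimal(
    assays: Sequence[Assay],
    mass_table: MassTable,
    max_plex: int = 9,
    min_gap: float = DEFAULT_MIN_GAP,
    include_adducts: bool = False,
    name: str = "replexed-optimal",
) -> Panel:
    """Provably minimal pool count by exhaustive search (small instances).

    Branch-and-bound over assignments in ascending assay-id order with pool
    symmetry breaking (an assay may open at most the next new pool), trying
    increasing pool counts; the first feasible assignment found is the
    lexicographically smallest minimal partition.  Instances above
    ``MAX_EXHAUSTIVE`` assays are refused.
    """
    n = len(assays)
    if n > MAX_EXHAUSTIVE:
        raise ValueError(
            f"exhaustive replexing is limited to {MAX_EXHAUSTIVE} assays, got {n}"
        )
    if max_plex < 1:
        raise ValueError("max_plex must be >= 1")
    graph = build_conflict_graph(assays, mass_table, min_gap, include_adducts)
    by_id = {a.assay_id: a for a in assays}
    order = sorted(by_id)

    def search(k: int) -> list[list[str]] | None:
        pools: list[list[str]] = [[] for _ in range(k)]

        def place(i: int) -> bool:
            if i == len(order):
                return True
            aid = order[i]
            opened = sum(1 for p in pools if p)
            for j, pool in enumerate(pools):
                if j > opened:  # symmetry break: only the next empty pool
                    break
                if len(pool) >= max_plex:
                    continue
                if any(graph.conflicts(aid, m) for m in pool):
                    continue
                pool.append(aid)
                if place(i + 1):
                    return True
                pool.pop()
            return False

        return [p for p in pools if p] if place(0) else None

    lower = max(1, -(-n // max_plex))
    for k in range(lower, n + 1):
        solution = search(k)
        if solution is not None:
            return Panel(
                name=name,
                assays=by_id,
                pools={f"P{i + 1}": pool for i, pool in enumerate(solution)},
                mass_table=mass_table,
                max_plex=max_plex,
            )
    raise AssertionError("unreachable: singleton pools are always feasible")
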