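"""Metabolic-route inference: minimal route selection and harmonic-mean abundance.

Per sample, the smallest set of catalog routes that jointly contains every
observed (positive-abundance) EC number is selected; each selected route is
then scored with the harmonic mean of its member EC abundances, with the
convention that a zero-abundance member zeroes the route (the harmonic-mean
limit — a missing required step means the route is not usable).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from itertools import combinations
from typing import AbstractSet, Iterable, Mapping

import numpy as np
import pandas as pd

from metgems.prediction import FunctionSampleTable
from metgems.reference_db import EC_PATTERN, normalize_function_id

log = logging.getLogger(__name__)

DEFAULT_EXACT_LIMIT = 20


@dataclass
class RouteCatalog:
    """Route id -> set of member EC numbers, with optional display names."""

    routes: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for route_id, ecs in self.routes.items():
            if not ecs:
                raise ValueError(f"route {route_id!r} has an empty EC set")
            for ec in ecs:
                if not EC_PATTERN.match(ec):
                    raise ValueError(f"route {route_id!r}: malformed EC {ec!r}")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "RouteCatalog":
        """Read a 2-column ``route_id<TAB>ec_number`` mapping (MinPath dialect)."""
        from metgems.io import read_two_column

        routes: dict[str, set[str]] = {}
        for route_id, token in read_two_column(path):
            routes.setdefault(route_id, set()).add(normalize_function_id(token))
        return cls({rid: frozenset(ecs) for rid, ecs in routes.items()})


@dataclass
class RouteSelection:
    """Outcome of minimal-route selection for one observed EC set."""

    selected: frozenset[str]
    covered: frozenset[str]
    uncoverable: frozenset[str]
    exact: bool  # True when the selection is provably minimal


def _exhaustive_minimum(
    candidates: dict[str, frozenset[str]], target: frozenset[str]
) -> tuple[str, ...]:
    """Smallest cover; ties broken by lexicographically smallest id tuple.

    ``itertools.combinations`` over sorted ids emits size-k subsets in
    lexicographic order, so the first cover found at the smallest feasible k
    is the canonical one.
    """
    ids = sorted(candidates)
    for k in range(1, len(ids) + 1):
        for combo in combinations(ids, k):
            union: set[str] = set()
            for rid in combo:
                union |= candidates[rid]
            if target <= union:
                return combo
    raise AssertionError("candidate union covers target by construction")


def _greedy_cover(
    candidates: dict[str, frozenset[str]], target: frozenset[str]
) -> tuple[str, ...]:
    remaining = set(target)
    chosen: list[str] = []
    while remaining:
        best = min(
            candidates, key=lambda rid: (-len(candidates[rid] & remaining), rid)
        )
        gain = candidates[best] & remaining
        if not gain:
            raise AssertionError("greedy stalled despite coverable target")
        chosen.append(best)
        remaining -= gain
    return tuple(chosen)


def select_minimal_routes(
    observed_ecs: AbstractSet[str],
    catalog: RouteCatalog,
    exact_limit: int = DEFAULT_EXACT_LIMIT,
) -> RouteSelection:
    """Select a minimum-cardinality route set covering the observed ECs.

    ECs found in no catalog route are reported as uncoverable.  Dominated
    candidates (whose observed coverage is a subset of another's) are pruned
    first; if the surviving candidate count is <= ``exact_limit``, the
    solution is provably minimal (exhaustive search), otherwise greedy
    largest-marginal-cover with a logged caveat.
    """
    if not catalog.routes:
        raise ValueError("route catalog is empty")
    observed = frozenset(observed_ecs)
    universe = frozenset().union(*catalog.routes.values())
    uncoverable = observed - universe
    target = observed & universe
    if uncoverable:
        log.warning("%d observed ECs appear in no route", len(uncoverable))
    if not target:
        return RouteSelection(frozenset(), frozenset(), uncoverable, exact=True)

    coverage = {
        rid: ecs & target for rid, ecs in catalog.routes.items() if ecs & target
    }
    # Dominance pruning: drop a route whose coverage is contained in another's.
    # On equal coverage keep the lexicographically smaller id, for determinism.
    ids = sorted(coverage)
    pruned: dict[str, frozenset[str]] = {}
    for rid in ids:
        dominated = False
        for other in ids:
            if other == rid:
                continue
            if coverage[rid] < coverage[other] or (
                coverage[rid] == coverage[other] and other < rid
            ):
                dominated = True
                break
        if not dominated:
            pruned[rid] = frozenset(coverage[rid])

    if len(pruned) <= exact_limit:
        chosen = _exhaustive_minimum(pruned, target)
        exact = True
    else:
        chosen = _greedy_cover(pruned, target)
        exact = False
        log.warning(
            "%d candidate routes exceed exact_limit=%d; greedy cover of size %d "
            "is not guaranteed minimal",
            len(pruned),
            exact_limit,
            len(chosen),
        )
    return RouteSelection(
        selected=frozenset(chosen),
        covered=target,
        uncoverable=uncoverable,
        exact=exact,
    )


def select_routes_per_sample(
    ec_table: FunctionSampleTable,
    catalog: RouteCatalog,
    exact_limit: int = DEFAULT_EXACT_LIMIT,
) -> dict[str, RouteSelection]:
    """Run minimal-route selection independently on each sample's positive ECs."""
    if ec_table.namespace != "EC":
        raise ValueError("route selection requires an EC-namespace table")
    selections = {}
    for sample in ec_table.abundance.columns:
        column = ec_table.abundance[sample]
        observed = set(column.index[column > 0])
        selections[sample] = select_minimal_routes(observed, catalog, exact_limit)
    return selections


@dataclass
class RouteSampleTable:
    """Route x sample harmonic-mean abundances (0 for unselected routes)."""

    abundance: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.abundance.to_numpy(dtype=float)
        if values.size and (not np.isfinite(values).all() or (values < 0).any()):
            raise ValueError("route abundances must be finite and non-negative")


def harmonic_mean(values: Iterable[float]) -> float:
    """Harmonic mean with the zero-forcing limit: any zero member gives 0."""
    vals = list(values)
    if not vals:
        return 0.0
    if any(v == 0 for v in vals):
        return 0.0
    return len(vals) / sum(1.0 / v for v in vals)


def route_abundance(
    ec_table: FunctionSampleTable,
    selections: Mapping[str, RouteSelection],
    catalog: RouteCatalog,
) -> RouteSampleTable:
    """Score each selected route with the harmonic mean of member EC abundances.

    Member ECs absent from the table are ignored; a route with no member in
    the table at all scores 0 with a warning.
    """
    if ec_table.namespace != "EC":
        raise ValueError("route abundance requires an EC-namespace table")
    all_routes = sorted({rid for sel in selections.values() for rid in sel.selected})
    samples = [s for s in ec_table.abundance.columns if s in selections]
    table = pd.DataFrame(0.0, index=pd.Index(all_routes, name="route"), columns=samples)
    for sample in samples:
        column = ec_table.abundance[sample]
        for rid in selections[sample].selected:
            members = [ec for ec in catalog.routes[rid] if ec in column.index]
            if not members:
                log.warning(
                    "route %s has no member EC in the table (sample %s)", rid, sample
                )
                continue
            table.at[rid, sample] = harmonic_mean(column[ec] for ec in members)
    return RouteSampleTable(abundance=table)


def compare_routes(routes: RouteSampleTable, design) -> pd.DataFrame:
    """Per-route two-group Wilcoxon rank-sum comparison, sorted by p-value.

    Delegates to :func:`metgems.differential.wilcoxon_test`; see there for
    the exact-vs-approximate switch and tie handling.
    """
    from metgems.differential import wilcoxon_test

    table = FunctionSampleTable(abundance=routes.abundance, namespace="EC")
    result = wilcoxon_test(table, design)
    return result.table.sort_values("p_value")
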