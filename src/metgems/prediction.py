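"""ASV table -> taxon table -> function table prediction pipeline.

Three stages: (1) sum ASV counts sharing a taxonomic assignment, (2) divide
each taxon's abundance by the median 16S copy number of its genomes, and
(3) multiply through a taxon x function reference network to obtain function
abundances per sample.
"""

from __future__ import annotations

import logging
import math
import os
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from metgems.reference_db import GenomeFunctionProfile, TaxonFunctionMatrix

log = logging.getLogger(__name__)

UNASSIGNED = "unassigned"

_LINEAGE_PREFIX = {"class": "c__", "genus": "g__", "species": "s__"}


def _check_matrix(df: pd.DataFrame, what: str) -> None:
    values = df.to_numpy(dtype=float)
    if values.size and (not np.isfinite(values).all() or (values < 0).any()):
        raise ValueError(f"{what} must be finite and non-negative")
    if df.index.has_duplicates:
        raise ValueError(f"duplicate row ids in {what}")
    if df.columns.has_duplicates:
        raise ValueError(f"duplicate sample ids in {what}")


@dataclass
class AsvSampleTable:
    """ASV x sample count matrix."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        _check_matrix(self.counts, "ASV table")

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class TaxonomyMap:
    """ASV -> taxon label assignment at a stated rank."""

    rank: str
    assignments: dict[str, str]

    def label(self, asv_id: str) -> str:
        return self.assignments.get(asv_id, UNASSIGNED)

    @classmethod
    def from_lineage_pairs(
        cls, pairs: Iterable[tuple[str, str]], rank: str
    ) -> "TaxonomyMap":
        """Extract one rank from QIIME/Greengenes-style lineage strings.

        A lineage like ``k__Bacteria;...;g__Bacteroides;s__`` yields
        ``Bacteroides`` at genus and ``unassigned`` at species.  A bare
        label without ``__`` prefixes is taken as the label itself.
        """
        prefix = _LINEAGE_PREFIX[rank]
        assignments: dict[str, str] = {}
        for asv_id, lineage in pairs:
            if asv_id in assignments:
                raise ValueError(f"ASV {asv_id!r} appears more than once")
            label = UNASSIGNED
            if "__" in lineage:
                for part in lineage.split(";"):
                    part = part.strip()
                    if part.startswith(prefix) and part[len(prefix):].strip():
                        label = part[len(prefix):].strip()
                        break
            elif lineage.strip():
                label = lineage.strip()
            assignments[asv_id] = label
        return cls(rank=rank, assignments=assignments)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike, rank: str) -> "TaxonomyMap":
        from metgems.io import read_two_column

        return cls.from_lineage_pairs(read_two_column(path), rank)


@dataclass
class CopyNumberTable:
    """Per-taxon 16S copy numbers pooled over genomes; the median is used."""

    values: dict[str, list[float]]

    def __post_init__(self) -> None:
        for taxon, numbers in self.values.items():
            if not numbers:
                raise ValueError(f"taxon {taxon!r} has no copy-number data")
            if any(not cn > 0 for cn in numbers):
                raise ValueError(f"taxon {taxon!r} has a non-positive copy number")

    def median(self, taxon: str) -> float | None:
        if taxon not in self.values:
            return None
        return float(statistics.median(self.values[taxon]))

    @classmethod
    def from_profiles(
        cls, profiles: Iterable[GenomeFunctionProfile], rank: str
    ) -> "CopyNumberTable":
        values: dict[str, list[float]] = {}
        for profile in profiles:
            label = profile.taxonomy.get(rank)
            if label and profile.copy_number_16s is not None:
                values.setdefault(label, []).append(profile.copy_number_16s)
        return cls(values)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "CopyNumberTable":
        from metgems.io import read_two_column

        values: dict[str, list[float]] = {}
        for taxon, cn in read_two_column(path):
            values.setdefault(taxon, []).append(float(cn))
        return cls(values)


@dataclass
class TaxonSampleTable:
    """Taxon x sample abundance matrix."""

    abundance: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        _check_matrix(self.abundance, "taxon table")


@dataclass
class FunctionSampleTable:
    """Function x sample abundance matrix with a namespace and scale tag."""

    abundance: pd.DataFrame
    namespace: str
    scale: str = "raw"

    def __post_init__(self) -> None:
        _check_matrix(self.abundance, "function table")
        if self.scale not in ("raw", "relative"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "relative" and not self.abundance.empty:
            sums = self.abundance.sum(axis=0).to_numpy()
            bad = ~(np.isclose(sums, 1.0, atol=1e-9) | (sums == 0.0))
            if bad.any():
                raise ValueError("relative-scale columns must sum to 1 or be all-zero")


@dataclass
class MappingReport:
    """Bookkeeping from ASV aggregation: what mapped, what was dropped."""

    n_asvs: int
    n_assigned: int
    retained_fraction: dict[str, float]
    taxa: list[str]
    unassigned_asvs: list[str] = field(default_factory=list)


def aggregate_asvs(
    table: AsvSampleTable, taxonomy: TaxonomyMap
) -> tuple[TaxonSampleTable, MappingReport]:
    """Sum ASV counts sharing a taxonomy label into taxon rows.

    Unassigned ASVs are excluded from the output but tallied in the report,
    which also carries the fraction of reads retained per sample.
    """
    labels = pd.Series(
        [taxonomy.label(asv) for asv in table.counts.index], index=table.counts.index
    )
    assigned = labels != UNASSIGNED
    unassigned_asvs = list(table.counts.index[~assigned])
    grouped = table.counts.loc[assigned].groupby(labels[assigned]).sum()
    grouped = grouped.sort_index()
    grouped.index.name = "taxon"
    if grouped.empty:
        grouped = pd.DataFrame(
            0.0, index=pd.Index([], name="taxon"), columns=table.counts.columns
        )
        log.warning("no ASV carries a taxonomy assignment; taxon table is empty")
    totals = table.counts.sum(axis=0)
    kept = grouped.sum(axis=0) if not grouped.empty else totals * 0.0
    retained = {
        s: (float(kept.get(s, 0.0) / totals[s]) if totals[s] > 0 else 0.0)
        for s in table.counts.columns
    }
    for sample, frac in retained.items():
        if frac == 0.0:
            log.warning("sample %s retained no assigned reads", sample)
    report = MappingReport(
        n_asvs=len(table.counts.index),
        n_assigned=int(assigned.sum()),
        retained_fraction=retained,
        taxa=list(grouped.index),
        unassigned_asvs=unassigned_asvs,
    )
    return TaxonSampleTable(abundance=grouped.astype(float)), report


def normalize_copy_number(
    table: TaxonSampleTable, cn: CopyNumberTable, default: float = 1.0
) -> TaxonSampleTable:
    """Divide each taxon row by its median 16S copy number.

    Taxa without copy-number data are divided by ``default`` (1.0) with a
    logged note, rather than dropped.
    """
    if table.normalized:
        raise ValueError("taxon table is already copy-number normalized")
    if not default > 0:
        raise ValueError("default copy number must be > 0")
    divisors = []
    n_defaulted = 0
    for taxon in table.abundance.index:
        median = cn.median(taxon)
        if median is None:
            divisors.append(default)
            n_defaulted += 1
        else:
            if not median > 0:
                raise ValueError(f"non-positive median copy number for {taxon!r}")
            divisors.append(median)
    if n_defaulted:
        log.info("%d taxa lack copy-number data; default %.3g used", n_defaulted, default)
    out = table.abundance.div(pd.Series(divisors, index=table.abundance.index), axis=0)
    return TaxonSampleTable(abundance=out, normalized=True)


@dataclass
class PredictionReport:
    taxa_used: list[str]
    taxa_missing_from_network: list[str]


def predict_functions(
    table: TaxonSampleTable, network: TaxonFunctionMatrix
) -> tuple[FunctionSampleTable, PredictionReport]:
    """Function abundance = sum over taxa of taxon abundance x network entry.

    Only taxa present in both the sample table and the network contribute;
    the rest are listed in the report.  An empty intersection is an error.
    """
    shared = sorted(set(table.abundance.index) & set(network.table.index))
    if not shared:
        raise ValueError(
            "no taxon shared between sample table and network "
            f"(table has {list(table.abundance.index)[:5]}..., "
            f"network has {list(network.table.index)[:5]}...)"
        )
    missing = sorted(set(table.abundance.index) - set(network.table.index))
    if missing:
        log.info("%d taxa absent from the network: %s", len(missing), missing[:10])
    functions = network.table.loc[shared].T @ table.abundance.loc[shared]
    functions = functions.sort_index()
    functions.index.name = "function"
    report = PredictionReport(taxa_used=shared, taxa_missing_from_network=missing)
    return (
        FunctionSampleTable(abundance=functions, namespace=network.namespace),
        report,
    )


def relative_abundance(table: FunctionSampleTable) -> FunctionSampleTable:
    """Scale each sample column to sum to 1; all-zero columns stay zero."""
    if table.scale != "raw":
        raise ValueError("table is already on a relative scale")
    sums = table.abundance.sum(axis=0)
    zero_samples = [str(s) for s in sums.index[sums == 0]]
    if zero_samples:
        log.warning("all-zero sample columns left unscaled: %s", zero_samples)
    safe = sums.replace(0.0, 1.0)
    return FunctionSampleTable(
        abundance=table.abundance.div(safe, axis=1),
        namespace=table.namespace,
        scale="relative",
    )


def summarize_by_category(
    table: FunctionSampleTable, category_map: Mapping[str, str]
) -> tuple[pd.DataFrame, pd.Series]:
    """Pool KO abundances into functional categories.

    Functions missing from ``category_map`` land in ``Unclassified``.
    Returns the category x sample table and the per-category KO counts.
    """
    if table.namespace != "KO":
        raise ValueError("category summarization is defined for the KO namespace")
    categories = pd.Series(
        [category_map.get(f, "Unclassified") for f in table.abundance.index],
        index=table.abundance.index,
    )
    summed = table.abundance.groupby(categories).sum().sort_index()
    summed.index.name = "category"
    counts = categories.value_counts().sort_index()
    counts.name = "n_functions"
    return summed, counts


def predict_two_rank(
    asv_table: AsvSampleTable,
    species_map: TaxonomyMap,
    genus_map: TaxonomyMap,
    species_network: TaxonFunctionMatrix,
    genus_network: TaxonFunctionMatrix,
    species_cn: CopyNumberTable | None = None,
    genus_cn: CopyNumberTable | None = None,
) -> tuple[FunctionSampleTable, dict[str, int]]:
    """Predict with species-level resolution where available, genus otherwise.

    An ASV is routed to the species network when its species label exists
    there; other ASVs fall back to the genus network.  The two predictions
    are summed (the pipeline is linear in ASVs).
    """
    if species_network.namespace != genus_network.namespace:
        raise ValueError("species and genus networks must share a namespace")
    species_taxa = set(species_network.table.index)
    to_species = [
        asv
        for asv in asv_table.counts.index
        if species_map.label(asv) in species_taxa
    ]
    to_genus = [asv for asv in asv_table.counts.index if asv not in set(to_species)]
    pieces: list[pd.DataFrame] = []
    for asvs, tax, net, cn in (
        (to_species, species_map, species_network, species_cn),
        (to_genus, genus_map, genus_network, genus_cn),
    ):
        if not asvs:
            continue
        sub = AsvSampleTable(counts=asv_table.counts.loc[asvs])
        taxon_table, _ = aggregate_asvs(sub, tax)
        if taxon_table.abundance.empty:
            continue
        if cn is not None:
            taxon_table = normalize_copy_number(taxon_table, cn)
        if set(taxon_table.abundance.index) & set(net.table.index):
            predicted, _ = predict_functions(taxon_table, net)
            pieces.append(predicted.abundance)
    if not pieces:
        raise ValueError("no ASV could be routed to either network")
    total = pieces[0]
    for piece in pieces[1:]:
        total = total.add(piece, fill_value=0.0)
    total = total.sort_index()
    routing = {"species": len(to_species), "genus": len(to_genus)}
    return (
        FunctionSampleTable(abundance=total, namespace=genus_network.namespace),
        routing,
    )
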