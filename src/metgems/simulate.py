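"""Synthetic genome collections, communities and catalogs with known truth.

Everything the other modules consume can be generated here, seeded and
deterministic: per-genome function profiles (core + accessory structure),
Dirichlet-multinomial ASV count tables with exact taxonomy, a noisy
reference function profile standing in for a shotgun-derived table, and
route catalogs with a planted, brute-force-verified unique minimum cover.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from metgems.prediction import AsvSampleTable, FunctionSampleTable, TaxonomyMap
from metgems.reference_db import GenomeFunctionProfile, TaxonWeightTable
from metgems.routes import RouteCatalog


@dataclass
class SyntheticSpec:
    """Knobs for the synthetic generators; every distribution is surfaced here."""

    n_taxa: int = 10
    genomes_per_taxon: int = 3
    n_functions: int = 200
    core_fraction: float = 0.3
    accessory_presence_prob: float = 0.3
    copy_number_range: tuple[int, int] = (1, 7)
    n_asvs_per_taxon: int = 3
    n_samples: int = 10
    sequencing_depth: int = 50_000
    abundance_dirichlet_alpha: float = 1.0
    reference_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_taxa",
            "genomes_per_taxon",
            "n_functions",
            "n_asvs_per_taxon",
            "n_samples",
            "sequencing_depth",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("core_fraction", "accessory_presence_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.reference_noise_sd < 0:
            raise ValueError("reference_noise_sd must be >= 0")
        lo, hi = self.copy_number_range
        if lo < 1 or hi < lo:
            raise ValueError("copy_number_range must satisfy 1 <= low <= high")


@dataclass
class GroundTruth:
    """What the generator knows: true compositions and the exact function mixture.

    ``function_profiles`` maps namespace -> function x sample table built as
    the copy-number-free mixture of per-taxon mean genome profiles weighted
    by the *realized* (post-sampling) taxon composition — exactly what the
    ideal prediction pipeline reconstructs.
    """

    taxon_proportions: pd.DataFrame  # taxon x sample, columns sum to 1 (Dirichlet draw)
    realized_proportions: pd.DataFrame  # taxon x sample, from the sampled counts
    function_profiles: dict[str, pd.DataFrame]
    spec: SyntheticSpec = field(repr=False, default=None)


def _taxon_labels(n: int) -> list[str]:
    return [f"genus{i:03d}" for i in range(1, n + 1)]


def _ko_pool(n: int) -> list[str]:
    return [f"K{i:05d}" for i in range(1, n + 1)]


def _ec_pool(n: int) -> list[str]:
    pool = []
    for i in range(n):
        a, rem = divmod(i, 6 * 6 * 40)
        b, rem = divmod(rem, 6 * 40)
        c, d = divmod(rem, 40)
        pool.append(f"{a + 1}.{b + 1}.{c + 1}.{d + 1}")
    return pool


def make_genomes(
    spec: SyntheticSpec,
) -> tuple[list[GenomeFunctionProfile], TaxonWeightTable]:
    """Generate per-taxon core + accessory genome function profiles.

    Each taxon draws a core set of ``core_fraction * n_functions`` function
    ids shared by all its genomes; every other pool function enters each
    genome independently with ``accessory_presence_prob``.  Counts are small
    positive integers, copy numbers uniform integers in range.  Weights are
    log-uniform in [0.5, 2).
    """
    rng = np.random.default_rng(spec.seed)
    taxa = _taxon_labels(spec.n_taxa)
    ko_pool = np.array(_ko_pool(spec.n_functions))
    ec_pool = np.array(_ec_pool(max(2, spec.n_functions // 2)))
    profiles: list[GenomeFunctionProfile] = []
    weights: dict[str, float] = {}
    n_core = round(spec.core_fraction * spec.n_functions)
    n_core_ec = round(spec.core_fraction * len(ec_pool))
    for t_idx, taxon in enumerate(taxa):
        core_ko = set(rng.choice(ko_pool, size=n_core, replace=False))
        core_ec = set(rng.choice(ec_pool, size=n_core_ec, replace=False))
        for g_idx in range(spec.genomes_per_taxon):
            gid = f"G_{taxon}_{g_idx:02d}"
            ko = {}
            for fid in ko_pool:
                if fid in core_ko or rng.random() < spec.accessory_presence_prob:
                    ko[fid] = float(rng.integers(1, 4))
            ec = {}
            for fid in ec_pool:
                if fid in core_ec or rng.random() < spec.accessory_presence_prob:
                    ec[fid] = float(rng.integers(1, 4))
            cn = float(
                rng.integers(spec.copy_number_range[0], spec.copy_number_range[1] + 1)
            )
            profiles.append(
                GenomeFunctionProfile(
                    genome_id=gid,
                    taxonomy={
                        "class": f"class{t_idx % 3:02d}",
                        "genus": taxon,
                        "species": f"{taxon}_sp{g_idx:02d}",
                    },
                    ko_counts=ko,
                    ec_counts=ec,
                    copy_number_16s=cn,
                )
            )
            weights[gid] = float(np.exp(rng.uniform(np.log(0.5), np.log(2.0))))
    return profiles, TaxonWeightTable(weights=weights)


def _mean_profiles_by_taxon(
    profiles: Sequence[GenomeFunctionProfile], namespace: str, rank: str = "genus"
) -> pd.DataFrame:
    """Taxon x function matrix of per-taxon mean genome counts."""
    groups: dict[str, list[GenomeFunctionProfile]] = {}
    for p in profiles:
        groups.setdefault(p.taxonomy[rank], []).append(p)
    functions = sorted({f for p in profiles for f in p.counts(namespace)})
    frame = pd.DataFrame(0.0, index=sorted(groups), columns=functions)
    for taxon, members in groups.items():
        for p in members:
            for fid, v in p.counts(namespace).items():
                frame.at[taxon, fid] += v / len(members)
    return frame


def make_community(
    spec: SyntheticSpec, genomes: Sequence[GenomeFunctionProfile]
) -> tuple[AsvSampleTable, TaxonomyMap, GroundTruth]:
    """Sample a Dirichlet-multinomial community over the generated taxa.

    Taxon proportions per sample are Dirichlet(alpha); each taxon's reads
    split over its ASVs by a fixed per-community Dirichlet draw; counts are
    multinomial at ``sequencing_depth``.  The taxonomy map is noise-free.
    """
    rng = np.random.default_rng(spec.seed + 1)
    taxa = sorted({p.taxonomy["genus"] for p in genomes})
    samples = [f"S{j:03d}" for j in range(1, spec.n_samples + 1)]
    asv_ids = []
    asv_taxon = []
    for taxon in taxa:
        for a in range(spec.n_asvs_per_taxon):
            asv_ids.append(f"asv_{taxon}_{a:02d}")
            asv_taxon.append(taxon)
    within = rng.dirichlet(
        np.ones(spec.n_asvs_per_taxon), size=len(taxa)
    )  # fixed per community
    alpha = np.full(len(taxa), spec.abundance_dirichlet_alpha)
    true_props = rng.dirichlet(alpha, size=spec.n_samples).T  # taxa x samples
    counts = np.zeros((len(asv_ids), spec.n_samples))
    p_asv = np.concatenate(
        [true_props[t][None, :] * within[t][:, None] for t in range(len(taxa))], axis=0
    )
    for j in range(spec.n_samples):
        counts[:, j] = rng.multinomial(spec.sequencing_depth, p_asv[:, j])
    table = AsvSampleTable(
        counts=pd.DataFrame(
            counts, index=pd.Index(asv_ids, name="ASV_ID"), columns=samples
        )
    )
    taxonomy = TaxonomyMap(
        rank="genus", assignments=dict(zip(asv_ids, asv_taxon))
    )
    taxon_counts = table.counts.groupby(pd.Series(asv_taxon, index=asv_ids)).sum()
    taxon_counts = taxon_counts.reindex(taxa, fill_value=0.0)
    realized = taxon_counts / taxon_counts.sum(axis=0)
    function_profiles = {}
    for namespace in ("KO", "EC"):
        mix = _mean_profiles_by_taxon(genomes, namespace)
        function_profiles[namespace] = mix.T @ realized
        function_profiles[namespace].index.name = "function"
    truth = GroundTruth(
        taxon_proportions=pd.DataFrame(true_props, index=taxa, columns=samples),
        realized_proportions=realized,
        function_profiles=function_profiles,
        spec=spec,
    )
    return table, taxonomy, truth


def make_reference_profile(
    truth: GroundTruth,
    noise_sd: float | None = None,
    namespace: str = "KO",
    seed: int | None = None,
) -> FunctionSampleTable:
    """Perturb the true function profile with multiplicative log-normal noise.

    ``noise_sd=0`` returns the exact truth (renormalized per sample); larger
    values degrade rank agreement monotonically in expectation.
    """
    spec = truth.spec
    if noise_sd is None:
        noise_sd = spec.reference_noise_sd if spec is not None else 0.0
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    base_seed = seed if seed is not None else (spec.seed + 2 if spec else 2)
    rng = np.random.default_rng(base_seed)
    profile = truth.function_profiles[namespace].copy()
    if noise_sd > 0:
        noise = rng.lognormal(mean=0.0, sigma=noise_sd, size=profile.shape)
        profile = profile * noise
    sums = profile.sum(axis=0).replace(0.0, 1.0)
    profile = profile / sums
    return FunctionSampleTable(
        abundance=profile, namespace=namespace, scale="relative"
    )


@dataclass
class PlantedCatalog:
    """A route catalog whose designated observed set has a known unique cover."""

    catalog: RouteCatalog
    planted: frozenset[str]
    observed_ecs: frozenset[str]


def _minimum_covers(
    routes: dict[str, frozenset[str]], target: frozenset[str]
) -> list[tuple[str, ...]]:
    ids = sorted(routes)
    for k in range(1, len(ids) + 1):
        found = [
            combo
            for combo in itertools.combinations(ids, k)
            if target <= frozenset().union(*(routes[r] for r in combo))
        ]
        if found:
            return found
    return []


def make_route_catalog(
    n_routes: int,
    ec_pool: Sequence[str],
    size_range: tuple[int, int] = (2, 5),
    seed: int = 0,
    planted_cover_size: int = 2,
    max_tries: int = 200,
) -> PlantedCatalog:
    """Generate a catalog with a brute-force-verified unique minimum cover.

    The planted routes get disjoint EC sets whose union is the designated
    observed set; decoy routes are random subsets of the pool.  Generation
    retries until exhaustive enumeration confirms the planted subset is the
    one and only minimum cover of the observed set.
    """
    if n_routes < planted_cover_size:
        raise ValueError("n_routes must be >= planted_cover_size")
    lo, hi = size_range
    if lo < 1 or hi < lo:
        raise ValueError("size_range must satisfy 1 <= low <= high")
    pool = np.array(sorted(set(ec_pool)))
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        sizes = rng.integers(lo, hi + 1, size=planted_cover_size)
        if sizes.sum() > len(pool):
            raise ValueError("ec_pool too small for the requested planted cover")
        picks = rng.choice(pool, size=int(sizes.sum()), replace=False)
        routes: dict[str, frozenset[str]] = {}
        offset = 0
        planted = []
        for i, size in enumerate(sizes):
            rid = f"RPLANT-{i:02d}"
            routes[rid] = frozenset(picks[offset : offset + size])
            planted.append(rid)
            offset += size
        observed = frozenset(picks)
        for i in range(n_routes - planted_cover_size):
            size = int(rng.integers(lo, hi + 1))
            routes[f"RDECOY-{i:02d}"] = frozenset(
                rng.choice(pool, size=min(size, len(pool)), replace=False)
            )
        covers = _minimum_covers(routes, observed)
        if len(covers) == 1 and set(covers[0]) == set(planted):
            return PlantedCatalog(
                catalog=RouteCatalog(routes=routes),
                planted=frozenset(planted),
                observed_ecs=observed,
            )
    raise RuntimeError(
        "could not plant a unique minimum cover; try a larger ec_pool"
    )
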