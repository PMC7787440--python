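import numpy as np
import pandas as pd
import pytest

from metgems.prediction import AsvSampleTable, FunctionSampleTable, TaxonomyMap
from metgems.reference_db import GenomeFunctionProfile
from metgems.simulate import SyntheticSpec, make_community, make_genomes


def make_profile(gid, genus, ko=None, ec=None, species=None, cn=None, cls="classA"):
    taxonomy = {"class": cls, "genus": genus}
    if species:
        taxonomy["species"] = species
    return GenomeFunctionProfile(
        genome_id=gid,
        taxonomy=taxonomy,
        ko_counts=ko or {},
        ec_counts=ec or {},
        copy_number_16s=cn,
    )


def random_profiles(rng, n_genomes=10, n_genera=3, n_functions=25):
    """Random genome profiles over a KO pool, for oracle comparisons."""
    pool = [f"K{i:05d}" for i in range(1, n_functions + 1)]
    profiles = []
    for g in range(n_genomes):
        genus = f"genus{g % n_genera}"
        ko = {
            fid: float(rng.integers(0, 4))
            for fid in pool
            if rng.random() < 0.6
        }
        ko = {fid: v for fid, v in ko.items() if v > 0}
        profiles.append(
            make_profile(f"G{g:02d}", genus, ko=ko, cn=float(rng.integers(1, 8)))
        )
    return profiles


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_spec():
    return SyntheticSpec(
        n_taxa=5,
        genomes_per_taxon=2,
        n_functions=60,
        n_asvs_per_taxon=2,
        n_samples=4,
        sequencing_depth=5_000,
        seed=11,
    )


@pytest.fixture
def exact_recovery_spec():
    """Single-genome taxa, copy number 1: pipeline should recover truth exactly."""
    return SyntheticSpec(
        n_taxa=10,
        genomes_per_taxon=1,
        n_functions=200,
        copy_number_range=(1, 1),
        n_asvs_per_taxon=3,
        n_samples=5,
        sequencing_depth=30_000,
        reference_noise_sd=0.0,
        seed=5,
    )


@pytest.fixture
def small_community(small_spec):
    profiles, weights = make_genomes(small_spec)
    table, taxonomy, truth = make_community(small_spec, profiles)
    return profiles, weights, table, taxonomy, truth


def function_table(values, samples=None, namespace="KO", scale="raw"):
    df = pd.DataFrame(values)
    if samples is not None:
        df.columns = samples
    return FunctionSampleTable(abundance=df.astype(float), namespace=namespace, scale=scale)


def asv_table(values, samples=None):
    df = pd.DataFrame(values)
    if samples is not None:
        df.columns = samples
    return AsvSampleTable(counts=df.astype(float))


def taxonomy_map(assignments, rank="genus"):
    return TaxonomyMap(rank=rank, assignments=dict(assignments))
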