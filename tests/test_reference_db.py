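import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_profile, random_profiles
from metgems.reference_db import (
    GenomeFunctionProfile,
    TaxonWeightTable,
    apply_weights,
    build_core,
    build_network,
    build_pan,
    coverage,
    function_count_correlation,
    load_gem_metadata,
    normalize_function_id,
    read_network,
    write_network,
)


# ---------------------------------------------------------------- oracles


def pan_oracle(profiles, rank, namespace, aggregation):
    """Independent loop-and-sum aggregation, dict-based."""
    groups = {}
    for p in profiles:
        label = p.taxonomy.get(rank)
        if label:
            groups.setdefault(label, []).append(p)
    out = {}
    for label, members in groups.items():
        acc = {}
        for p in members:
            for fid, v in p.counts(namespace).items():
                acc[fid] = acc.get(fid, 0.0) + v
        if aggregation == "mean":
            acc = {f: v / len(members) for f, v in acc.items()}
        out[label] = acc
    return out


def core_oracle(profiles, rank, namespace):
    """Set intersection of presence sets per taxon."""
    groups = {}
    for p in profiles:
        label = p.taxonomy.get(rank)
        if label:
            groups.setdefault(label, []).append(p)
    out = {}
    for label, members in groups.items():
        sets = [
            {f for f, v in p.counts(namespace).items() if v >= 1} for p in members
        ]
        out[label] = set.intersection(*sets)
    return out


# ---------------------------------------------------------------- loading


def test_load_wide_fixture(tmp_path):
    path = tmp_path / "gem.tsv"
    path.write_text(
        "genome_id\tclass\tgenus\tspecies\tcopy_number_16s\tK00001\tK00002\n"
        "G1\tBacilli\tLacto\tLacto_a\t5\t2\t0\n"
        "G2\tBacilli\tLacto\tLacto_b\t4\t1\t3\n"
    )
    profiles = load_gem_metadata(path)
    assert len(profiles) == 2
    by_id = {p.genome_id: p for p in profiles}
    assert by_id["G1"].ko_counts == {"K00001": 2.0}
    assert by_id["G2"].ko_counts == {"K00001": 1.0, "K00002": 3.0}
    assert by_id["G1"].copy_number_16s == 5.0


def test_load_long_fixture(tmp_path):
    path = tmp_path / "gem.tsv"
    path.write_text(
        "genome_id\tclass\tgenus\tspecies\tfunction_id\tcount\n"
        "G1\tc\tg\ts1\tK00001\t2\n"
        "G1\tc\tg\ts1\tEC:1.2.3.4\t1\n"
        "G2\tc\tg\ts2\tK00002\t1\n"
    )
    profiles = load_gem_metadata(path)
    by_id = {p.genome_id: p for p in profiles}
    assert by_id["G1"].ko_counts == {"K00001": 2.0}
    assert by_id["G1"].ec_counts == {"1.2.3.4": 1.0}


def test_load_empty_function_cell_warns(tmp_path, caplog):
    path = tmp_path / "gem.tsv"
    path.write_text(
        "genome_id\tclass\tgenus\tspecies\tfunction_id\tcount\n"
        "G1\tc\tg\ts1\t\t0\n"
    )
    with caplog.at_level("WARNING"):
        profiles = load_gem_metadata(path)
    assert profiles[0].ko_counts == {} and profiles[0].ec_counts == {}
    assert any("empty function cell" in r.message for r in caplog.records)


def test_load_duplicate_genome_id_errors(tmp_path):
    path = tmp_path / "gem.tsv"
    path.write_text(
        "genome_id\tclass\tgenus\tspecies\tK00001\n"
        "G1\tc\tg\ts1\t1\nG1\tc\tg\ts1\t2\n"
    )
    with pytest.raises(ValueError, match="duplicate genome_id"):
        load_gem_metadata(path)


def test_load_missing_column_errors(tmp_path):
    path = tmp_path / "gem.tsv"
    path.write_text("genome_id\tclass\tspecies\tK00001\nG1\tc\ts\t1\n")
    with pytest.raises(ValueError, match="genus"):
        load_gem_metadata(path)


def test_load_malformed_token_warns_with_line(tmp_path, caplog):
    path = tmp_path / "gem.tsv"
    path.write_text(
        "genome_id\tclass\tgenus\tspecies\tfunction_id\tcount\n"
        "G1\tc\tg\ts\tKXYZ\t1\n"
        "G1\tc\tg\ts\tK00001\t1\n"
    )
    with caplog.at_level("WARNING"):
        profiles = load_gem_metadata(path)
    assert profiles[0].ko_counts == {"K00001": 1.0}
    assert any("line 2" in r.message for r in caplog.records)


def test_normalize_function_id():
    assert normalize_function_id(" EC:1.2.3.4 ") == "1.2.3.4"
    assert normalize_function_id("1.2.3.-") == "1.2.3.-"
    assert normalize_function_id(" K00001 ") == "K00001"


# ---------------------------------------------------------------- build_pan


def test_pan_two_genome_average():
    profiles = [
        make_profile("G1", "g", ko={"K00001": 2}),
        make_profile("G2", "g", ko={}),
    ]
    mean = build_pan(profiles, "genus", "KO", "mean")
    assert mean.table.at["g", "K00001"] == 1.0
    total = build_pan(profiles, "genus", "KO", "sum")
    assert total.table.at["g", "K00001"] == 2.0


def test_pan_single_genome_identity():
    profiles = [make_profile("G1", "g", ko={"K00001": 3, "K00002": 1})]
    for agg in ("mean", "sum"):
        m = build_pan(profiles, "genus", "KO", agg)
        assert m.table.at["g", "K00001"] == 3.0
        assert m.table.at["g", "K00002"] == 1.0


def test_pan_matches_bruteforce_oracle(rng):
    profiles = random_profiles(rng, n_genomes=10, n_genera=3, n_functions=25)
    for agg in ("mean", "sum"):
        matrix = build_pan(profiles, "genus", "KO", agg)
        expected = pan_oracle(profiles, "genus", "KO", agg)
        for taxon, row in expected.items():
            for fid, v in row.items():
                assert matrix.table.at[taxon, fid] == pytest.approx(v, abs=1e-12)
        assert float(matrix.table.to_numpy().sum()) == pytest.approx(
            sum(v for row in expected.values() for v in row.values())
        )


def test_pan_excludes_missing_rank(caplog):
    profiles = [
        make_profile("G1", "g", ko={"K00001": 1}),
        GenomeFunctionProfile("G2", {"class": "c"}, ko_counts={"K00002": 1}),
    ]
    with caplog.at_level("WARNING"):
        matrix = build_pan(profiles, "genus", "KO")
    assert "K00002" not in matrix.table.columns
    only_unlabeled = [GenomeFunctionProfile("G3", {"class": "c"})]
    with pytest.raises(ValueError):
        build_pan(only_unlabeled, "genus", "KO")


# ---------------------------------------------------------------- build_core


def test_core_directly():
    profiles = [
        make_profile("G1", "g", ko={"K00001": 2, "K00002": 1}),
        make_profile("G2", "g", ko={"K00001": 1}),
    ]
    matrix = build_core(profiles, "genus", "KO")
    assert matrix.table.at["g", "K00001"] == 1.0
    assert "K00002" not in matrix.table.columns or matrix.table.at["g", "K00002"] == 0.0


def test_core_single_genome_is_presence():
    profiles = [make_profile("G1", "g", ko={"K00001": 7, "K00003": 1})]
    matrix = build_core(profiles, "genus", "KO")
    assert set(matrix.table.columns[(matrix.table.loc["g"] > 0)]) == {"K00001", "K00003"}


def test_core_matches_set_intersection_oracle(rng):
    profiles = random_profiles(rng, n_genomes=5, n_genera=1, n_functions=20)
    matrix = build_core(profiles, "genus", "KO")
    expected = core_oracle(profiles, "genus", "KO")
    got = {
        taxon: set(matrix.table.columns[matrix.table.loc[taxon] > 0])
        for taxon in matrix.table.index
    }
    assert got == expected


def test_core_invariant_to_rescaling(rng):
    profiles = random_profiles(rng, n_genomes=6, n_genera=2)
    scaled = [
        make_profile(
            p.genome_id, p.taxonomy["genus"],
            ko={f: 13.0 * v for f, v in p.ko_counts.items()},
        )
        for p in profiles
    ]
    a = build_core(profiles, "genus", "KO")
    b = build_core(scaled, "genus", "KO")
    assert a.table.equals(b.table)


# ---------------------------------------------------------------- weights


def test_weights_all_ones_equivalent(rng):
    profiles = random_profiles(rng)
    weights = TaxonWeightTable({p.genome_id: 1.0 for p in profiles})
    weighted = apply_weights(profiles, weights)
    for before, after in zip(profiles, weighted):
        assert before.ko_counts == after.ko_counts


def test_weight_scalar_multiply():
    profiles = [make_profile("G1", "g", ko={"K00001": 4})]
    out = apply_weights(profiles, TaxonWeightTable({"G1": 0.5}))
    assert out[0].ko_counts == {"K00001": 2.0}


def test_weighted_pan_matches_oracle(rng):
    profiles = random_profiles(rng)
    weights = TaxonWeightTable(
        {p.genome_id: float(rng.uniform(0.1, 3.0)) for p in profiles}
    )
    matrix = build_network(profiles, "pan_weight", "genus", "KO", weights=weights)
    scaled = [
        make_profile(
            p.genome_id, p.taxonomy["genus"],
            ko={f: weights.weights[p.genome_id] * v for f, v in p.ko_counts.items()},
        )
        for p in profiles
    ]
    expected = pan_oracle(scaled, "genus", "KO", "mean")
    for taxon, row in expected.items():
        for fid, v in row.items():
            assert matrix.table.at[taxon, fid] == pytest.approx(v, abs=1e-12)
    assert matrix.mode == "pan_weight"


def test_negative_weight_rejected():
    with pytest.raises(ValueError):
        TaxonWeightTable({"G1": -0.1})


def test_missing_weight_defaults_to_one(rng, caplog):
    profiles = random_profiles(rng, n_genomes=3)
    with caplog.at_level("WARNING"):
        out = apply_weights(profiles, TaxonWeightTable({profiles[0].genome_id: 2.0}))
    assert out[1].ko_counts == profiles[1].ko_counts


def test_core_weight_equals_core(rng):
    profiles = random_profiles(rng)
    weights = TaxonWeightTable(
        {p.genome_id: float(rng.uniform(0.1, 3.0)) for p in profiles}
    )
    core = build_network(profiles, "core", "genus", "KO")
    core_w = build_network(profiles, "core_weight", "genus", "KO", weights=weights)
    assert core.table.equals(core_w.table)
    assert core_w.mode == "core_weight"


# ---------------------------------------------------------------- coverage


def test_coverage_oracle(rng):
    profiles = random_profiles(rng)
    matrix = build_pan(profiles, "genus", "KO")
    expected = sum(
        1 for col in matrix.table.columns if (matrix.table[col] > 0).any()
    )
    assert coverage(matrix) == expected


def test_coverage_empty():
    profiles = [make_profile("G1", "g")]
    assert coverage(build_pan(profiles, "genus", "KO")) == 0


def test_core_coverage_le_pan_coverage(rng):
    for seed in range(10):
        profiles = random_profiles(np.random.default_rng(seed), n_genomes=8)
        assert coverage(build_core(profiles, "genus", "KO")) <= coverage(
            build_pan(profiles, "genus", "KO")
        )


def test_core_implies_pan_mean_ge_one(rng):
    profiles = random_profiles(rng, n_genomes=9, n_genera=3)
    core = build_core(profiles, "genus", "KO")
    pan = build_pan(profiles, "genus", "KO", "mean")
    for taxon in core.table.index:
        for fid in core.table.columns:
            if core.table.at[taxon, fid] == 1.0:
                assert pan.table.at[taxon, fid] >= 1.0


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=15, deadline=None)
def test_genome_order_invariance(seed):
    rng = np.random.default_rng(seed)
    profiles = random_profiles(rng, n_genomes=6, n_genera=2, n_functions=10)
    perm = list(rng.permutation(len(profiles)))
    shuffled = [profiles[i] for i in perm]
    for builder in (build_pan, build_core):
        a, b = builder(profiles, "genus", "KO"), builder(shuffled, "genus", "KO")
        assert a.table.equals(b.table)


# ------------------------------------------------- function count correlation


def test_pcc_perfect_linearity():
    profiles = [
        make_profile(
            f"G{i}", "g",
            ko={f"K{j:05d}": 1.0 for j in range(1, 2 * i + 2)},
            ec={f"1.1.1.{j}": 1.0 for j in range(1, i + 2)},
        )
        for i in range(5)
    ]
    # EC count = (KO count + 1) / 2 exactly: affine, so PCC = 1
    summary = function_count_correlation(profiles, "class")
    assert summary.pcc == pytest.approx(1.0)


def test_pcc_two_genomes_degenerate():
    profiles = [
        make_profile("G1", "g", ko={"K00001": 1}, ec={"1.1.1.1": 1}),
        make_profile("G2", "g", ko={"K00001": 1, "K00002": 1},
                     ec={"1.1.1.1": 1, "1.1.1.2": 1}),
    ]
    summary = function_count_correlation(profiles, "class")
    assert abs(summary.pcc) == pytest.approx(1.0)


def test_pcc_zero_variance_undefined():
    profiles = [
        make_profile("G1", "g", ko={"K00001": 1}, ec={"1.1.1.1": 1}),
        make_profile("G2", "g", ko={"K00001": 1}, ec={"1.1.1.1": 1, "1.1.1.2": 1}),
    ]
    summary = function_count_correlation(profiles, "class")
    assert summary.pcc is None
    assert not summary.pcc_defined


def test_pcc_matches_textbook_formula(rng):
    profiles = []
    for i in range(50):
        n_ko = int(rng.integers(5, 40))
        n_ec = max(1, n_ko // 2 + int(rng.integers(-3, 4)))
        profiles.append(
            make_profile(
                f"G{i}", f"g{i % 4}",
                ko={f"K{j:05d}": 1.0 for j in range(1, n_ko + 1)},
                ec={f"1.1.{1 + j // 40}.{1 + j % 40}": 1.0 for j in range(n_ec)},
            )
        )
    summary = function_count_correlation(profiles, "class")
    x = np.array([len(p.ko_counts) for p in profiles], dtype=float)
    y = np.array([len(p.ec_counts) for p in profiles], dtype=float)
    xc, yc = x - x.mean(), y - y.mean()
    expected = float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))
    assert summary.pcc == pytest.approx(expected, abs=1e-12)


def test_group_summaries(rng):
    profiles = random_profiles(rng, n_genomes=8, n_genera=2)
    summary = function_count_correlation(profiles, "genus")
    assert set(summary.groups.index) <= {"genus0", "genus1", "genus2"}
    assert (summary.groups["n"] >= 1).all()


# ---------------------------------------------------------------- network IO


def test_network_round_trip(tmp_path, rng):
    profiles = random_profiles(rng)
    matrix = build_pan(profiles, "genus", "KO")
    path = tmp_path / "net.tsv"
    write_network(matrix, path)
    back = read_network(path)
    assert back.mode == "pan" and back.rank == "genus" and back.namespace == "KO"
    assert back.genomes_per_taxon == matrix.genomes_per_taxon
    assert np.allclose(back.table.to_numpy(), matrix.table.to_numpy(), rtol=5e-6)
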