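"""Taxon-level function reference networks built from per-genome annotations.

A network is a taxon-group x function matrix produced under one of four
modes:

* ``pan`` — aggregate (mean or sum) of each member genome's function counts;
* ``core`` — 0/1 indicator of functions present in *every* member genome;
* ``pan_weight`` — pan computed on per-genome weighted counts;
* ``core_weight`` — identical values to core (presence is evaluated on
  unweighted counts), relabeled to record that weights were supplied.

Function identifiers live in one of two namespaces: KEGG Orthology ids
(``K00001`` style) and Enzyme Commission numbers (``1.2.3.4``, partial
numbers with a trailing ``-`` allowed).
"""

from __future__ import annotations

import logging
import math
import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from metgems.io import read_table, write_table

log = logging.getLogger(__name__)

KO_PATTERN = re.compile(r"K\d{5}\Z")
EC_PATTERN = re.compile(r"\d+\.\d+\.\d+\.(\d+|-)\Z")

RANKS = ("class", "genus", "species")
MODES = ("pan", "core", "pan_weight", "core_weight")
NAMESPACES = ("KO", "EC")


def normalize_function_id(token: str) -> str:
    """Trim a function token and strip a leading ``EC:`` prefix.

    Partial EC numbers with a trailing ``-`` are kept verbatim.
    """
    tok = token.strip()
    if tok[:3].upper() == "EC:":
        tok = tok[3:].strip()
    return tok


def classify_function_id(token: str) -> str | None:
    """Return ``"KO"``, ``"EC"`` or None for a normalized function id."""
    if KO_PATTERN.match(token):
        return "KO"
    if EC_PATTERN.match(token):
        return "EC"
    return None


def _check_counts(counts: Mapping[str, float], pattern: re.Pattern, kind: str) -> None:
    for fid, value in counts.items():
        if not pattern.match(fid):
            raise ValueError(f"malformed {kind} id {fid!r}")
        if not math.isfinite(value) or value < 0:
            raise ValueError(f"{kind} count for {fid!r} must be finite and >= 0")


@dataclass
class GenomeFunctionProfile:
    """One genome's function annotation: taxonomy, KO/EC counts, 16S copies."""

    genome_id: str
    taxonomy: dict[str, str]
    ko_counts: dict[str, float] = field(default_factory=dict)
    ec_counts: dict[str, float] = field(default_factory=dict)
    copy_number_16s: float | None = None

    def __post_init__(self) -> None:
        _check_counts(self.ko_counts, KO_PATTERN, "KO")
        _check_counts(self.ec_counts, EC_PATTERN, "EC")
        if self.copy_number_16s is not None and not self.copy_number_16s > 0:
            raise ValueError(
                f"genome {self.genome_id}: 16S copy number must be > 0"
            )

    def counts(self, namespace: str) -> dict[str, float]:
        if namespace == "KO":
            return self.ko_counts
        if namespace == "EC":
            return self.ec_counts
        raise ValueError(f"unknown namespace {namespace!r}")


@dataclass
class TaxonWeightTable:
    """Per-genome non-negative scalar weights (e.g. average gut abundance)."""

    weights: dict[str, float]

    def __post_init__(self) -> None:
        for gid, w in self.weights.items():
            if not math.isfinite(w) or w < 0:
                raise ValueError(f"weight for genome {gid!r} must be finite and >= 0")
        if self.weights and not any(w > 0 for w in self.weights.values()):
            raise ValueError("all weights are zero")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "TaxonWeightTable":
        from metgems.io import read_two_column

        return cls({gid: float(w) for gid, w in read_two_column(path)})


@dataclass
class TaxonFunctionMatrix:
    """Taxon-group x function reference network under one mode.

    ``table`` is a dense taxon x function DataFrame (absent entries are 0);
    rows and columns are kept sorted so construction order never matters.
    """

    mode: str
    rank: str
    namespace: str
    table: pd.DataFrame
    genomes_per_taxon: dict[str, int]

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.rank not in RANKS:
            raise ValueError(f"unknown rank {self.rank!r}")
        if self.namespace not in NAMESPACES:
            raise ValueError(f"unknown namespace {self.namespace!r}")
        values = self.table.to_numpy(dtype=float)
        if values.size and (not np.isfinite(values).all() or (values < 0).any()):
            raise ValueError("network entries must be finite and non-negative")
        if self.mode in ("core", "core_weight") and values.size:
            if not np.isin(values, (0.0, 1.0)).all():
                raise ValueError(f"{self.mode} entries must be 0 or 1")
        for taxon in self.table.index:
            if self.genomes_per_taxon.get(taxon, 0) < 1:
                raise ValueError(f"taxon {taxon!r} has no genomes")

    def functions_per_taxon(self) -> pd.Series:
        """Number of functions with a nonzero entry, per taxon row."""
        return (self.table > 0).sum(axis=1)


def load_gem_metadata(path: str | os.PathLike) -> list[GenomeFunctionProfile]:
    """Load per-genome function annotations from TSV.

    Two dialects are auto-detected from the header:

    * long — columns ``genome_id, class, genus, species[, copy_number_16s],
      function_id, count``, one (genome, function) pair per row;
    * wide — columns ``genome_id, class, genus, species[, copy_number_16s]``
      plus one column per function id.

    Malformed function tokens are skipped with a logged warning carrying the
    line number (long) or column name (wide).
    """
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\n")
    header = header_line.lstrip("#").split("\t")
    for col in ("genome_id", "class", "genus", "species"):
        if col not in header:
            raise ValueError(f"{path}: missing mandatory column {col!r}")
    if "function_id" in header:
        if "count" not in header:
            raise ValueError(f"{path}: long format requires a 'count' column")
        return _load_long(path, header)
    return _load_wide(path, header)


def _taxonomy_from_row(row: Mapping[str, str]) -> dict[str, str]:
    return {rank: row[rank].strip() for rank in RANKS if row.get(rank, "").strip()}


def _load_long(path: str | os.PathLike, header: list[str]) -> list[GenomeFunctionProfile]:
    idx = {name: i for i, name in enumerate(header)}
    has_cn = "copy_number_16s" in idx
    profiles: dict[str, GenomeFunctionProfile] = {}
    seen_pairs: set[tuple[str, str]] = set()
    n_malformed = 0
    with open(path, encoding="utf-8") as fh:
        next(fh)
        for lineno, raw in enumerate(fh, 2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            row = {name: fields[i] if i < len(fields) else "" for name, i in idx.items()}
            gid = row["genome_id"].strip()
            if gid not in profiles:
                cn = None
                if has_cn and row["copy_number_16s"].strip():
                    cn = float(row["copy_number_16s"])
                profiles[gid] = GenomeFunctionProfile(
                    genome_id=gid, taxonomy=_taxonomy_from_row(row), copy_number_16s=cn
                )
            token = row["function_id"].strip()
            if not token:
                log.warning("%s: line %d: empty function cell for %s", path, lineno, gid)
                continue
            fid = normalize_function_id(token)
            namespace = classify_function_id(fid)
            if namespace is None:
                n_malformed += 1
                log.warning(
                    "%s: line %d: malformed function id %r skipped", path, lineno, token
                )
                continue
            if (gid, fid) in seen_pairs:
                raise ValueError(
                    f"{path}: line {lineno}: duplicate entry for genome "
                    f"{gid!r}, function {fid!r}"
                )
            seen_pairs.add((gid, fid))
            profiles[gid].counts(namespace)[fid] = float(row["count"])
    if n_malformed:
        log.warning("%s: %d malformed function tokens skipped", path, n_malformed)
    return list(profiles.values())


def _load_wide(path: str | os.PathLike, header: list[str]) -> list[GenomeFunctionProfile]:
    meta_cols = {"genome_id", "class", "genus", "species", "copy_number_16s"}
    fn_columns: dict[str, tuple[str, str]] = {}  # column -> (normalized id, namespace)
    for col in header:
        if col in meta_cols:
            continue
        fid = normalize_function_id(col)
        namespace = classify_function_id(fid)
        if namespace is None:
            log.warning("%s: malformed function column %r skipped", path, col)
            continue
        fn_columns[col] = (fid, namespace)
    idx = {name: i for i, name in enumerate(header)}
    profiles: list[GenomeFunctionProfile] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        next(fh)
        for lineno, raw in enumerate(fh, 2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            row = {name: fields[i] if i < len(fields) else "" for name, i in idx.items()}
            gid = row["genome_id"].strip()
            if gid in seen:
                raise ValueError(f"{path}: line {lineno}: duplicate genome_id {gid!r}")
            seen.add(gid)
            cn = None
            if row.get("copy_number_16s", "").strip():
                cn = float(row["copy_number_16s"])
            ko: dict[str, float] = {}
            ec: dict[str, float] = {}
            for col, (fid, namespace) in fn_columns.items():
                cell = row.get(col, "").strip()
                value = float(cell) if cell else 0.0
                if value:
                    (ko if namespace == "KO" else ec)[fid] = value
            profiles.append(
                GenomeFunctionProfile(
                    genome_id=gid,
                    taxonomy=_taxonomy_from_row(row),
                    ko_counts=ko,
                    ec_counts=ec,
                    copy_number_16s=cn,
                )
            )
    return profiles


def _group_by_rank(
    profiles: Iterable[GenomeFunctionProfile], rank: str
) -> dict[str, list[GenomeFunctionProfile]]:
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    groups: dict[str, list[GenomeFunctionProfile]] = {}
    n_skipped = 0
    for profile in profiles:
        label = profile.taxonomy.get(rank)
        if not label:
            n_skipped += 1
            continue
        groups.setdefault(label, []).append(profile)
    if n_skipped:
        log.warning("%d genomes lack a %s label and were excluded", n_skipped, rank)
    if not groups:
        raise ValueError(f"no genome carries a {rank!r} label")
    return groups


def _matrix_frame(
    entries: dict[str, dict[str, float]], taxa: Sequence[str]
) -> pd.DataFrame:
    functions = sorted({fid for row in entries.values() for fid in row})
    frame = pd.DataFrame(0.0, index=sorted(taxa), columns=functions)
    for taxon, row in entries.items():
        for fid, value in row.items():
            frame.at[taxon, fid] = value
    frame.index.name = "taxon"
    return frame


def build_pan(
    profiles: Iterable[GenomeFunctionProfile],
    rank: str,
    namespace: str,
    aggregation: str = "mean",
    *,
    _mode: str = "pan",
) -> TaxonFunctionMatrix:
    """Aggregate member-genome function counts per taxon group.

    ``aggregation="mean"`` (default) divides the group sum by the number of
    member genomes, so heavily sequenced taxa do not dominate; ``"sum"``
    keeps the plain group total.
    """
    if aggregation not in ("mean", "sum"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    groups = _group_by_rank(profiles, rank)
    entries: dict[str, dict[str, float]] = {}
    for taxon, members in groups.items():
        acc: dict[str, float] = {}
        for profile in members:
            for fid, value in profile.counts(namespace).items():
                acc[fid] = acc.get(fid, 0.0) + value
        if aggregation == "mean":
            n = len(members)
            acc = {fid: value / n for fid, value in acc.items()}
        entries[taxon] = acc
    return TaxonFunctionMatrix(
        mode=_mode,
        rank=rank,
        namespace=namespace,
        table=_matrix_frame(entries, list(groups)),
        genomes_per_taxon={taxon: len(members) for taxon, members in groups.items()},
    )


def build_core(
    profiles: Iterable[GenomeFunctionProfile],
    rank: str,
    namespace: str,
    *,
    _mode: str = "core",
) -> TaxonFunctionMatrix:
    """Indicator of functions present (count >= 1) in every genome of a taxon."""
    groups = _group_by_rank(profiles, rank)
    entries: dict[str, dict[str, float]] = {}
    for taxon, members in groups.items():
        common: set[str] | None = None
        for profile in members:
            present = {fid for fid, v in profile.counts(namespace).items() if v >= 1}
            common = present if common is None else common & present
        entries[taxon] = {fid: 1.0 for fid in (common or set())}
    return TaxonFunctionMatrix(
        mode=_mode,
        rank=rank,
        namespace=namespace,
        table=_matrix_frame(entries, list(groups)),
        genomes_per_taxon={taxon: len(members) for taxon, members in groups.items()},
    )


def apply_weights(
    profiles: Iterable[GenomeFunctionProfile], weights: TaxonWeightTable
) -> list[GenomeFunctionProfile]:
    """Scale each genome's function counts by its weight.

    Genomes missing from the weight table get weight 1 with a warning; a
    negative weight is a hard error (enforced by :class:`TaxonWeightTable`).
    With all-ones weights the output counts equal the input counts.
    """
    out: list[GenomeFunctionProfile] = []
    n_missing = 0
    for profile in profiles:
        if profile.genome_id in weights.weights:
            w = weights.weights[profile.genome_id]
        else:
            w = 1.0
            n_missing += 1
        out.append(
            GenomeFunctionProfile(
                genome_id=profile.genome_id,
                taxonomy=dict(profile.taxonomy),
                ko_counts={fid: w * v for fid, v in profile.ko_counts.items()},
                ec_counts={fid: w * v for fid, v in profile.ec_counts.items()},
                copy_number_16s=profile.copy_number_16s,
            )
        )
    if n_missing:
        log.warning("%d genomes had no weight; default 1.0 applied", n_missing)
    return out


def build_network(
    profiles: Iterable[GenomeFunctionProfile],
    mode: str,
    rank: str,
    namespace: str,
    weights: TaxonWeightTable | None = None,
    aggregation: str = "mean",
) -> TaxonFunctionMatrix:
    """Build a reference network under any of the four modes.

    ``core_weight`` evaluates presence on *unweighted* counts, so its values
    always equal ``core``; the weighting is recorded in the mode label only.
    """
    profiles = list(profiles)
    if mode == "pan":
        return build_pan(profiles, rank, namespace, aggregation)
    if mode == "core":
        return build_core(profiles, rank, namespace)
    if mode == "pan_weight":
        if weights is None:
            raise ValueError("pan_weight requires a weight table")
        return build_pan(
            apply_weights(profiles, weights), rank, namespace, aggregation,
            _mode="pan_weight",
        )
    if mode == "core_weight":
        return build_core(profiles, rank, namespace, _mode="core_weight")
    raise ValueError(f"unknown mode {mode!r}")


def coverage(matrix: TaxonFunctionMatrix) -> int:
    """Number of distinct functions with a nonzero entry in >= 1 taxon."""
    if matrix.table.empty:
        return 0
    return int((matrix.table.to_numpy() > 0).any(axis=0).sum())


@dataclass
class FunctionCountSummary:
    """Per-group mean/SD of distinct KO and EC counts, plus their Pearson r."""

    groups: pd.DataFrame  # index: group label; columns: n, ko_mean, ko_sd, ec_mean, ec_sd
    pcc: float | None  # None when undefined (zero variance)

    @property
    def pcc_defined(self) -> bool:
        return self.pcc is not None


def function_count_correlation(
    profiles: Iterable[GenomeFunctionProfile], group_rank: str = "class"
) -> FunctionCountSummary:
    """Summarize per-genome distinct-function counts by taxon group.

    Counts the distinct KO ids and EC numbers with count >= 1 in each
    genome, reports mean +/- SD per group at ``group_rank``, and the Pearson
    correlation between the KO and EC count vectors across all genomes.  A
    zero-variance vector makes the correlation undefined (``pcc=None``),
    never a silent NaN.
    """
    profiles = list(profiles)
    if len(profiles) < 2:
        raise ValueError("need >= 2 genomes")
    n_ko = np.array(
        [sum(1 for v in p.ko_counts.values() if v >= 1) for p in profiles], dtype=float
    )
    n_ec = np.array(
        [sum(1 for v in p.ec_counts.values() if v >= 1) for p in profiles], dtype=float
    )
    if n_ko.std() == 0 or n_ec.std() == 0:
        pcc: float | None = None
    else:
        from scipy import stats

        pcc = float(stats.pearsonr(n_ko, n_ec).statistic)
    records = {}
    for i, profile in enumerate(profiles):
        label = profile.taxonomy.get(group_rank, "unassigned")
        records.setdefault(label, []).append(i)
    rows = {}
    for label, members in sorted(records.items()):
        ko = n_ko[members]
        ec = n_ec[members]
        rows[label] = {
            "n": len(members),
            "ko_mean": ko.mean(),
            "ko_sd": ko.std(ddof=1) if len(members) > 1 else 0.0,
            "ec_mean": ec.mean(),
            "ec_sd": ec.std(ddof=1) if len(members) > 1 else 0.0,
        }
    groups = pd.DataFrame.from_dict(rows, orient="index")
    groups.index.name = group_rank
    return FunctionCountSummary(groups=groups, pcc=pcc)


def write_network(matrix: TaxonFunctionMatrix, path: str | os.PathLike) -> None:
    meta = {
        "mode": matrix.mode,
        "rank": matrix.rank,
        "namespace": matrix.namespace,
        "n_genomes": sum(matrix.genomes_per_taxon.values()),
        "genomes_per_taxon": ",".join(
            f"{t}:{n}" for t, n in sorted(matrix.genomes_per_taxon.items())
        ),
    }
    write_table(matrix.table, path, index_name="taxon", meta=meta)


def read_network(path: str | os.PathLike) -> TaxonFunctionMatrix:
    df = read_table(path)
    meta = df.attrs.get("meta", {})
    for key in ("mode", "rank", "namespace"):
        if key not in meta:
            raise ValueError(f"{path}: network file lacks '# {key}=...' metadata")
    gpt: dict[str, int] = {}
    if meta.get("genomes_per_taxon"):
        for token in meta["genomes_per_taxon"].split(","):
            taxon, _, n = token.rpartition(":")
            gpt[taxon] = int(n)
    else:
        gpt = {taxon: 1 for taxon in df.index}
    df = df.astype(float)
    return TaxonFunctionMatrix(
        mode=meta["mode"],
        rank=meta["rank"],
        namespace=meta["namespace"],
        table=df,
        genomes_per_taxon=gpt,
    )
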