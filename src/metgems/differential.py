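"""Two-group cohort statistics: rank transform, geometric means of ranks,
Wilcoxon rank-sum tests, log2 fold changes, optional BH adjustment."""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from metgems.prediction import FunctionSampleTable

log = logging.getLogger(__name__)

EXACT_GROUP_LIMIT = 12  # exact Wilcoxon enumeration when both groups <= this, no ties


@dataclass
class GroupDesign:
    """Sample -> condition assignment with exactly two conditions for testing.

    ``case`` names the condition treated as group 1 (positive log2FC =
    higher in case); when omitted, the lexicographically first label is
    used.
    """

    assignments: dict[str, str]
    case: str | None = None

    def __post_init__(self) -> None:
        labels = sorted(set(self.assignments.values()))
        if len(labels) != 2:
            raise ValueError(f"design must have exactly two conditions, got {labels}")
        if self.case is None:
            self.case = labels[0]
        elif self.case not in labels:
            raise ValueError(f"case label {self.case!r} not among conditions {labels}")
        self.control = next(l for l in labels if l != self.case)

    def split(self, sample_ids: Sequence[str]) -> tuple[list[str], list[str]]:
        """Partition the given samples into (case, control) lists."""
        case = [s for s in sample_ids if self.assignments.get(s) == self.case]
        control = [s for s in sample_ids if self.assignments.get(s) == self.control]
        if not case or not control:
            raise ValueError(
                f"both groups need >= 1 sample among the tested ids "
                f"(case={len(case)}, control={len(control)})"
            )
        return case, control

    @classmethod
    def from_tsv(
        cls, path: str | os.PathLike, case: str | None = None, stratum: str | None = None
    ) -> "GroupDesign":
        """Read ``sample_id<TAB>condition[<TAB>stratum]``; optionally keep one stratum."""
        assignments: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            for raw in fh:
                line = raw.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if fields[0] == "sample_id":
                    continue
                if stratum is not None and (len(fields) < 3 or fields[2] != stratum):
                    continue
                assignments[fields[0]] = fields[1]
        return cls(assignments=assignments, case=case)


@dataclass
class DiffResult:
    """Per-feature test results.

    ``table`` columns: ``W`` (rank-sum of the case group), ``p_value``,
    ``gmean_rank_<case>``, ``gmean_rank_<control>``, ``log2fc``, ``constant``
    and optionally ``q_value``.
    """

    table: pd.DataFrame
    case: str
    control: str
    scale: str


def rank_transform(table: FunctionSampleTable) -> pd.DataFrame:
    """Replace each sample column by within-sample ranks (1 = smallest).

    Ties receive average ranks, so values stay in [1, n_features].
    """
    if len(table.abundance.index) < 2:
        raise ValueError("rank transform needs >= 2 features")
    return table.abundance.rank(axis=0, method="average")


def group_geometric_mean(ranked: pd.DataFrame, design: GroupDesign) -> pd.DataFrame:
    """Per-feature geometric mean of ranks within each condition."""
    if (ranked.to_numpy() <= 0).any():
        raise ValueError("geometric mean requires strictly positive values")
    case, control = design.split(list(ranked.columns))
    out = pd.DataFrame(index=ranked.index)
    for label, cols in ((design.case, case), (design.control, control)):
        out[label] = np.exp(np.log(ranked[cols]).mean(axis=1))
    return out


def _feature_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    """Two-sided rank-sum test for one feature.

    Returns (W of group x, p, constant-flag).  Exact null enumeration when
    both groups are small and the pooled values carry no ties; otherwise the
    normal approximation with tie and continuity corrections.
    """
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(len(x) * (len(pooled) + 1) / 2.0), 1.0, True
    no_ties = len(np.unique(pooled)) == len(pooled)
    use_exact = (
        len(x) <= EXACT_GROUP_LIMIT and len(y) <= EXACT_GROUP_LIMIT and no_ties
    )
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if use_exact else "asymptotic"
    )
    w = float(res.statistic + len(x) * (len(x) + 1) / 2.0)
    return w, float(res.pvalue), False


def wilcoxon_test(table: FunctionSampleTable, design: GroupDesign) -> DiffResult:
    """Per-feature two-sided Wilcoxon rank-sum test between the two conditions.

    Each feature is tested independently.  Constant features get p = 1 and a
    ``constant`` flag.  Geometric means of within-sample ranks and log2 fold
    changes of group means (with pseudocount) ride along.
    """
    case_ids, control_ids = design.split(list(table.abundance.columns))
    x_block = table.abundance[case_ids].to_numpy(dtype=float)
    y_block = table.abundance[control_ids].to_numpy(dtype=float)
    rows = []
    for i in range(x_block.shape[0]):
        w, p, constant = _feature_test(x_block[i], y_block[i])
        rows.append((w, p, constant))
    result = pd.DataFrame(
        rows, index=table.abundance.index, columns=["W", "p_value", "constant"]
    )
    if len(table.abundance.index) >= 2:
        gmeans = group_geometric_mean(rank_transform(table), design)
        result[f"gmean_rank_{design.case}"] = gmeans[design.case]
        result[f"gmean_rank_{design.control}"] = gmeans[design.control]
    result["log2fc"] = log2_foldchange(table, design)
    return DiffResult(
        table=result, case=design.case, control=design.control, scale=table.scale
    )


def log2_foldchange(
    table: FunctionSampleTable,
    design: GroupDesign,
    pseudocount: float | None = None,
) -> pd.Series:
    """log2 of case-over-control group means with a pseudocount.

    The default pseudocount is half the smallest nonzero value in the table,
    added to both means; positive values mean higher abundance in the case
    group.  Features undefined even after the pseudocount (all-zero table)
    come back as NaN with a warning.
    """
    case_ids, control_ids = design.split(list(table.abundance.columns))
    mean_case = table.abundance[case_ids].mean(axis=1)
    mean_control = table.abundance[control_ids].mean(axis=1)
    if pseudocount is None:
        positive = table.abundance.to_numpy()
        positive = positive[positive > 0]
        pseudocount = float(positive.min()) / 2.0 if positive.size else 0.0
    num = mean_case + pseudocount
    den = mean_control + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.log2(num / den)
    fc = pd.Series(fc, index=table.abundance.index, name="log2fc")
    undefined = ~np.isfinite(fc)
    if undefined.any():
        log.warning("%d features have undefined log2FC", int(undefined.sum()))
        fc[undefined] = np.nan
    return fc


def adjust_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    ps = np.asarray(p_values, dtype=float)
    if ps.size == 0:
        return ps
    if ((ps <= 0) | (ps > 1)).any() or not np.isfinite(ps).all():
        raise ValueError("p-values must lie in (0, 1]")
    return stats.false_discovery_control(ps, method="bh")
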