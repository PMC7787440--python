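"""Agreement between predicted and reference function profiles.

Per-sample Spearman correlation over the zero-filled union of function ids,
a permutation + bootstrap null distribution of those coefficients (shuffle
ASV labels, resample samples with replacement, re-run the prediction
pipeline), and a Welch t-test comparing real coefficients against the null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from metgems.prediction import (
    AsvSampleTable,
    CopyNumberTable,
    FunctionSampleTable,
    TaxonomyMap,
    aggregate_asvs,
    normalize_copy_number,
    predict_functions,
)
from metgems.reference_db import TaxonFunctionMatrix

log = logging.getLogger(__name__)


@dataclass
class SccResult:
    """Per-sample Spearman coefficients plus the correlation universe used."""

    coefficients: dict[str, float]  # defined coefficients only
    undefined: list[str] = field(default_factory=list)
    n_functions: int = 0
    fill_policy: str = "union-zero-fill"

    def values(self) -> np.ndarray:
        return np.array(list(self.coefficients.values()), dtype=float)


@dataclass
class NullSCC:
    """Pooled null Spearman coefficients from permutation + bootstrap."""

    values: np.ndarray
    n_permutations: int
    n_bootstrap: int
    seed: int
    n_undefined: int = 0


def _column_scc(pred: np.ndarray, ref: np.ndarray) -> float | None:
    if len(pred) < 2:
        return None
    # Relative scaling per column is numeric hygiene only; Spearman ignores it.
    import warnings

    with warnings.catch_warnings():
        # constant inputs are handled explicitly below (undefined, not NaN-silent)
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho = stats.spearmanr(pred, ref).statistic
    if not np.isfinite(rho):
        return None
    return float(rho)


def spearman_per_sample(
    pred: FunctionSampleTable, ref: FunctionSampleTable
) -> SccResult:
    """Spearman correlation per shared sample over the union of function ids.

    Functions absent from one table are zero-filled, so false presences and
    false absences both count against the correlation.  Ties get average
    ranks.  Samples with an undefined coefficient (fewer than 2 functions,
    or a constant profile) are reported, not silently dropped.
    """
    if pred.namespace != ref.namespace:
        raise ValueError(
            f"namespace mismatch: {pred.namespace} vs {ref.namespace}"
        )
    shared = [s for s in pred.abundance.columns if s in set(ref.abundance.columns)]
    if not shared:
        raise ValueError("no shared sample id between prediction and reference")
    union = sorted(set(pred.abundance.index) | set(ref.abundance.index))
    p = pred.abundance.reindex(index=union, fill_value=0.0)
    r = ref.abundance.reindex(index=union, fill_value=0.0)
    coefficients: dict[str, float] = {}
    undefined: list[str] = []
    for sample in shared:
        rho = _column_scc(p[sample].to_numpy(), r[sample].to_numpy())
        if rho is None:
            undefined.append(sample)
        else:
            coefficients[sample] = rho
    if undefined:
        log.warning("Spearman undefined for %d samples: %s", len(undefined), undefined)
    return SccResult(
        coefficients=coefficients, undefined=undefined, n_functions=len(union)
    )


def permute_asv_labels(table: AsvSampleTable, seed: int) -> AsvSampleTable:
    """Uniformly shuffle which ASV id owns which abundance row.

    The multiset of row vectors is unchanged; only the id -> row assignment
    (and therefore the downstream taxonomy) moves.
    """
    rng = np.random.default_rng(seed)
    ids = np.array(table.counts.index)
    shuffled = rng.permutation(ids)
    out = table.counts.copy()
    out.index = pd.Index(shuffled, name=table.counts.index.name)
    return AsvSampleTable(counts=out)


def _run_pipeline(
    asv_table: AsvSampleTable,
    taxonomy: TaxonomyMap,
    copy_numbers: CopyNumberTable | None,
    network: TaxonFunctionMatrix,
) -> FunctionSampleTable:
    taxon_table, _ = aggregate_asvs(asv_table, taxonomy)
    if copy_numbers is not None:
        taxon_table = normalize_copy_number(taxon_table, copy_numbers)
    predicted, _ = predict_functions(taxon_table, network)
    return predicted


def build_null(
    table: AsvSampleTable,
    taxonomy: TaxonomyMap,
    copy_numbers: CopyNumberTable | None,
    network: TaxonFunctionMatrix,
    ref: FunctionSampleTable,
    n_permutations: int = 100,
    n_bootstrap: int = 200,
    seed: int = 0,
) -> NullSCC:
    """Null distribution of per-sample Spearman coefficients.

    For each permutation the ASV labels are shuffled (child seed =
    ``seed + permutation index``, so any permutation is independently
    reproducible), ``n_bootstrap`` samples are drawn with replacement from
    the sample list, the aggregate -> normalize -> predict pipeline is
    re-run, and the coefficient of every drawn sample against the reference
    enters the pool.  Repeated draws of a sample contribute identical
    coefficients, so the pipeline runs once per unique sample.
    """
    if n_permutations < 1 or n_bootstrap < 1:
        raise ValueError("n_permutations and n_bootstrap must be >= 1")
    sample_ids = np.array(table.sample_ids)
    pooled: list[float] = []
    n_undefined = 0
    for p_idx in range(n_permutations):
        child_seed = seed + p_idx
        rng = np.random.default_rng(child_seed)
        try:
            shuffled = permute_asv_labels(table, child_seed)
            draws = rng.choice(sample_ids, size=n_bootstrap, replace=True)
            predicted = _run_pipeline(shuffled, taxonomy, copy_numbers, network)
            scc = spearman_per_sample(predicted, ref)
        except Exception as exc:
            raise RuntimeError(f"permutation {p_idx} failed: {exc}") from exc
        for sample in draws:
            if sample in scc.coefficients:
                pooled.append(scc.coefficients[sample])
            else:
                n_undefined += 1
    if n_undefined:
        log.warning("%d null draws had undefined coefficients", n_undefined)
    return NullSCC(
        values=np.array(pooled, dtype=float),
        n_permutations=n_permutations,
        n_bootstrap=n_bootstrap,
        seed=seed,
        n_undefined=n_undefined,
    )


@dataclass
class NullComparison:
    statistic: float
    p_value: float
    mean_real: float
    mean_null: float
    n_real: int
    n_null: int


def compare_to_null(real: SccResult, null: NullSCC) -> NullComparison:
    """Welch (unequal-variance) t-test of real per-sample SCCs vs the null pool."""
    real_values = real.values()
    if len(real_values) < 2 or len(null.values) < 2:
        raise ValueError("both groups need >= 2 defined coefficients")
    res = stats.ttest_ind(real_values, null.values, equal_var=False)
    return NullComparison(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        mean_real=float(real_values.mean()),
        mean_null=float(null.values.mean()),
        n_real=len(real_values),
        n_null=len(null.values),
    )
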