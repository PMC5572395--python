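"""Hub-gene co-expression neighborhoods and target prioritization.

For a focal hub gene (FASN in the motivating application) this module ranks
its co-expression partners per condition after an expression floor, takes the
intersection of the raw- and log-scale top lists as the robust set, keeps
only partners that are co-expressed with the hub in fewer than a handful of
conditions (tissue specificity) and carry a tissue-enriched annotation, and
finally contrasts samples in the upper vs lower quartile of hub expression
with a negative-binomial Wald test on raw counts.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .coexnet import CorrelationTable, ExpressionMatrix

__all__ = [
    "hub_neighborhood",
    "robust_hub_set",
    "tissue_specificity_filter",
    "quartile_groups",
    "nb_differential_expression",
]


def hub_neighborhood(
    table: CorrelationTable,
    matrix: ExpressionMatrix,
    hub: str,
    min_tpm: float = 1.0,
    top_n: int = 100,
) -> pd.DataFrame:
    """Top ``top_n`` genes most correlated with the hub, after a TPM floor.

    Candidates are genes whose mean expression exceeds ``min_tpm``; ties in r
    are broken by gene id.  Rejects a hub that is absent or itself below the
    floor.
    """
    means = matrix.values.mean(axis=1)
    if hub not in matrix.values.index:
        raise ValueError(f"hub gene {hub!r} absent from the expression matrix")
    if hub not in table:
        raise ValueError(f"hub gene {hub!r} absent from the correlation table")
    if means[hub] <= min_tpm:
        raise ValueError(
            f"hub gene {hub!r} mean expression {means[hub]:.3g} <= {min_tpm} TPM"
        )
    candidates = [
        g
        for g in table.genes
        if g != hub and g in means.index and means[g] > min_tpm
    ]
    if not candidates:
        return pd.DataFrame(columns=["gene", "r"])
    r_vals = table.lookup([(hub, g) for g in candidates])
    out = pd.DataFrame({"gene": candidates, "r": r_vals})
    out = out.sort_values(
        ["r", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return out.head(top_n).reset_index(drop=True)


def robust_hub_set(list_raw: pd.DataFrame, list_log: pd.DataFrame) -> set[str]:
    """Genes present in both the raw-scale and log-scale top lists."""
    return set(list_raw["gene"]) & set(list_log["gene"])


def tissue_specificity_filter(
    neighborhoods: dict[str, pd.DataFrame],
    focal_condition: str,
    enriched_genes=None,
    max_conditions: int = 3,
    robust_set=None,
) -> pd.DataFrame:
    """Keep focal hub partners seen in fewer than ``max_conditions`` conditions.

    ``neighborhoods`` maps condition label -> top-list table (per-condition
    hub neighborhood).  Candidates default to the focal condition's top list
    but are normally the robust (raw ∩ log) set.  A gene is kept iff it
    appears in the top lists of strictly fewer than ``max_conditions``
    conditions (the focal one included, so a strictly focal-only gene counts
    1) and, when an annotation set is supplied, is annotated tissue-enriched.
    Without an annotation set the membership criterion alone applies and a
    warning is emitted.
    """
    if len(neighborhoods) < 2:
        raise ValueError("need neighborhoods for at least 2 conditions")
    if focal_condition not in neighborhoods:
        raise ValueError(f"no neighborhood for focal condition {focal_condition!r}")
    if robust_set is None:
        robust_set = set(neighborhoods[focal_condition]["gene"])
    if enriched_genes is None:
        import warnings

        warnings.warn(
            "no tissue-enriched annotation supplied; specificity uses the "
            "condition-count criterion only",
            stacklevel=2,
        )
    membership = {
        cond: set(tbl["gene"]) for cond, tbl in neighborhoods.items()
    }
    rows = []
    for gene in sorted(robust_set):
        count = sum(1 for genes in membership.values() if gene in genes)
        annotated = True if enriched_genes is None else gene in set(enriched_genes)
        kept = count < max_conditions and annotated
        rows.append((gene, count, annotated, kept))
    return pd.DataFrame(
        rows, columns=["gene", "n_conditions", "annotated", "kept"]
    )


def quartile_groups(values: pd.Series) -> tuple[list[str], list[str]]:
    """Split samples at the hub-expression quartiles.

    Samples are ranked by the hub's expression; the high group is the
    ``round(n/4)`` samples with the highest values (0.5 rounds up) and the low
    group the same number with the lowest.  371 samples therefore give groups
    of 93 and 93.  Ties are resolved by sample id for determinism.
    """
    n = len(values)
    if n < 8:
        raise ValueError("need at least 8 samples for a quartile split")
    size = math.floor(n / 4 + 0.5)
    order = sorted(values.index, key=lambda s: (values[s], s))
    low = sorted(order[:size])
    high = sorted(order[-size:])
    return high, low


def _size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (genes x samples input)."""
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in every sample")
    log_geo = np.log(counts[positive]).mean(axis=1, keepdims=True)
    ratios = np.log(counts[positive]) - log_geo
    return np.exp(np.median(ratios, axis=0))


def nb_differential_expression(
    counts: pd.DataFrame,
    group_high,
    group_low,
    alpha: float = 0.05,
    dispersion_floor: float = 1e-8,
) -> pd.DataFrame:
    """Two-group negative-binomial Wald test on raw counts.

    Library depth is normalized by median-of-ratios size factors; a pooled
    per-gene NB dispersion is estimated by the method of moments from the
    within-group mean/variance of normalized counts (floored); the Wald
    statistic tests the log fold change high/low with a delta-method standard
    error, and p-values are Benjamini-Hochberg adjusted.  All-zero genes get
    p = 1 and are flagged.
    """
    group_high = list(group_high)
    group_low = list(group_low)
    if len(group_high) < 2 or len(group_low) < 2:
        raise ValueError("both groups need at least 2 samples")
    if set(group_high) & set(group_low):
        raise ValueError("groups overlap")
    sub = counts[group_high + group_low]
    arr = sub.to_numpy(dtype=float)
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("counts must be integers")
    sf = _size_factors(arr)
    q = arr / sf  # normalized counts
    n1, n2 = len(group_high), len(group_low)
    q1, q2 = q[:, :n1], q[:, n1:]
    mu1 = q1.mean(axis=1)
    mu2 = q2.mean(axis=1)
    v1 = q1.var(axis=1, ddof=1)
    v2 = q2.var(axis=1, ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        a1 = (v1 - mu1) / np.square(mu1)
        a2 = (v2 - mu2) / np.square(mu2)
    import warnings as _warnings

    with _warnings.catch_warnings():
        # all-zero genes yield NaN in both groups; they get p = 1 below
        _warnings.simplefilter("ignore", RuntimeWarning)
        alpha_g = np.nanmean(np.stack([a1, a2]), axis=0)
    alpha_g = np.where(np.isfinite(alpha_g), alpha_g, dispersion_floor)
    alpha_g = np.maximum(alpha_g, dispersion_floor)

    all_zero = arr.sum(axis=1) == 0
    m1 = np.maximum(mu1, 0.5)
    m2 = np.maximum(mu2, 0.5)
    log2fc = np.log2(m1 / m2)
    var_log = (1.0 / m1 + alpha_g) / n1 + (1.0 / m2 + alpha_g) / n2
    se_log2 = np.sqrt(var_log) / np.log(2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = log2fc / se_log2
    p = 2.0 * norm.sf(np.abs(z))
    p = np.where(all_zero, 1.0, np.clip(p, 0.0, 1.0))
    log2fc = np.where(all_zero, 0.0, log2fc)
    padj = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "gene": sub.index,
            "base_mean": q.mean(axis=1),
            "log2_fold_change": log2fc,
            "dispersion": alpha_g,
            "p": p,
            "padj": padj,
            "all_zero": all_zero,
        }
    )
    out["significant"] = out["padj"] < alpha
    return out.reset_index(drop=True)
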