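"""Random-forest importance of TF co-binding for pair co-expression.

The most highly co-expressed gene pairs (the network edges) become rows of a
binary feature matrix whose columns are TFs — 1 iff the TF binds both genes
of the pair — with the pair's r as the regression response.  A random forest
fit to this matrix yields a variable-importance score per TF; the top 1% are
flagged as the most influential regulators of co-expression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .coexnet import CoexpressionNetwork
from .coreg import PhysicalNetwork

__all__ = [
    "CobindingFeatureMatrix",
    "build_feature_matrix",
    "fit_importance",
    "select_top_influential",
]


@dataclass
class CobindingFeatureMatrix:
    """Binary (pairs x TFs) co-binding matrix with the pair r as response."""

    X: np.ndarray  # shape (n_pairs, n_tfs), {0,1}
    tfs: list[str]
    pairs: list[tuple[str, str]]
    response: np.ndarray
    dropped_tfs: list[str] = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape


def build_feature_matrix(
    network: CoexpressionNetwork, phys: PhysicalNetwork
) -> CobindingFeatureMatrix:
    """One row per co-expression edge; entry = 1 iff the TF binds both genes.

    TFs that co-bind no pair contribute an uninformative all-zero column and
    are dropped (recorded in ``dropped_tfs``); pairs with no co-binding TF
    keep their all-zero row.  Rejects a matrix in which no TF binds any pair.
    """
    if phys.kind != "regulatory":
        raise ValueError("co-binding features require a regulatory network")
    targets = phys.target_map()
    tfs = sorted(targets)
    pairs = network.edge_pairs()
    X = np.zeros((len(pairs), len(tfs)), dtype=np.uint8)
    for j, tf in enumerate(tfs):
        tset = targets[tf]
        for i, (a, b) in enumerate(pairs):
            if a in tset and b in tset:
                X[i, j] = 1
    col_any = X.any(axis=0)
    if not col_any.any():
        raise ValueError("no TF co-binds any co-expressed pair")
    dropped = [tf for tf, keep in zip(tfs, col_any) if not keep]
    kept = [tf for tf, keep in zip(tfs, col_any) if keep]
    return CobindingFeatureMatrix(
        X=X[:, col_any],
        tfs=kept,
        pairs=pairs,
        response=network.edges["r"].to_numpy(dtype=float),
        dropped_tfs=dropped,
    )


def fit_importance(
    matrix: CobindingFeatureMatrix,
    n_trees: int = 500,
    seed: int = 0,
    method: str = "impurity",
    normalize: bool = False,
    include_dropped: bool = True,
) -> pd.DataFrame:
    """Regression-forest variable importance of each TF.

    ``method='impurity'`` uses the mean variance-reduction importance;
    ``method='permutation'`` the out-of-fit permutation importance (less
    biased for correlated binary features).  Deterministic given ``seed``.
    With ``include_dropped`` (default) TFs whose all-zero co-binding column
    was dropped from the matrix are reported with score 0, so the table
    scores every TF of the regulatory network.  Returns a table
    (tf, score, rank) sorted by score descending; ranks are a 1-based
    permutation with ties broken by TF id.
    """
    n_rows, n_feat = matrix.shape
    if n_rows < 10:
        raise ValueError("need at least 10 pairs to fit")
    if n_feat < 2:
        raise ValueError("need at least 2 TF features")
    y = matrix.response
    if np.ptp(y) == 0:
        raise ValueError("constant response")
    forest = RandomForestRegressor(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    )
    forest.fit(matrix.X, y)
    if method == "impurity":
        scores = forest.feature_importances_
    elif method == "permutation":
        from sklearn.inspection import permutation_importance

        res = permutation_importance(
            forest, matrix.X, y, n_repeats=5, random_state=seed, n_jobs=1
        )
        scores = res.importances_mean
    else:
        raise ValueError("method must be 'impurity' or 'permutation'")
    if normalize and scores.sum() > 0:
        scores = scores / scores.sum()
    tfs = list(matrix.tfs)
    scores = list(scores)
    if include_dropped:
        tfs += list(matrix.dropped_tfs)
        scores += [0.0] * len(matrix.dropped_tfs)
    table = pd.DataFrame({"tf": tfs, "score": scores})
    table = table.sort_values(
        ["score", "tf"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def select_top_influential(table: pd.DataFrame, q: float = 0.01) -> list[str]:
    """Top ``ceil(q * T)`` TFs by importance score (ties: score desc, TF id)."""
    if len(table) == 0:
        raise ValueError("empty importance table")
    n_top = math.ceil(q * len(table))
    order = table.sort_values(
        ["score", "tf"], ascending=[False, True], kind="mergesort"
    )
    return list(order["tf"].iloc[:n_top])
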