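"""Correlation-matrix PCA and permutation-tested axis correlations.

Columns are z-scored before the eigendecomposition, so the analysis is the
classical correlation PCA and any affine range shift of the raw variables
(the study added +5 to keep values positive) provably cannot change it.
Loading signs follow a deterministic convention: the largest-magnitude
loading of each component is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from tmontanum.regression import CorrelationResult, correlation


class ConstantColumnError(ValueError):
    pass


@dataclass
class PcaResult:
    scores: pd.DataFrame            # rows x components
    loadings: pd.DataFrame          # variables x components (unit norm)
    variance_fraction: np.ndarray   # per component, sums to 1

    @property
    def populations(self) -> list:
        return list(self.scores.index)

    @property
    def variables(self) -> list:
        return list(self.loadings.index)

    def reconstruct(self) -> pd.DataFrame:
        """Back-project the scores onto the variables (z-score scale)."""
        return pd.DataFrame(
            self.scores.values @ self.loadings.values.T,
            index=self.scores.index, columns=self.loadings.index)


def pca(matrix: pd.DataFrame, standardize: bool = True) -> PcaResult:
    """PCA of a populations-x-variables table.

    Missing cells must be resolved by the caller (drop rows or columns
    explicitly); a constant column cannot be z-scored and raises.
    """
    X = matrix.astype(float)
    if X.isna().any().any():
        bad = list(X.columns[X.isna().any()])
        raise ValueError(f"missing cells in columns {bad}; drop rows/columns first")
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 rows and 2 columns")
    if standardize:
        sd = X.std(ddof=1)
        if (sd == 0).any():
            raise ConstantColumnError(
                f"constant column(s): {list(sd.index[sd == 0])}")
        X = (X - X.mean()) / sd
    else:
        X = X - X.mean()
    U, s, Vt = np.linalg.svd(X.values, full_matrices=False)
    # deterministic sign: largest |loading| per component positive
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    eig = s**2
    comps = [f"PC{i + 1}" for i in range(len(s))]
    return PcaResult(
        scores=pd.DataFrame(U * s, index=matrix.index, columns=comps),
        loadings=pd.DataFrame(Vt.T, index=matrix.columns, columns=comps),
        variance_fraction=eig / eig.sum(),
    )


def axis_correlations(
    result: PcaResult,
    external: pd.DataFrame,
    method: str = "spearman",
    n_perm: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
    n_components: int | None = None,
) -> pd.DataFrame:
    """Correlate each PCA axis with each external variable.

    ``external`` must share the score index.  Returns the full table
    (axis, variable, coefficient, parametric and permutation p, and a
    ``significant`` flag at ``alpha`` on the permutation p) so that
    reporting can filter without losing information.
    """
    if not result.scores.index.equals(external.index):
        missing = set(result.scores.index) ^ set(external.index)
        raise ValueError(f"row identifiers misaligned: {sorted(missing)}")
    comps = result.scores.columns[: (n_components or len(result.scores.columns))]
    rows = []
    for k, axis in enumerate(comps):
        for var in external.columns:
            res: CorrelationResult = correlation(
                result.scores[axis], external[var].astype(float),
                method=method, n_perm=n_perm,
                seed=None if seed is None else seed + 1000 * k + hash(var) % 997,
            )
            rows.append({
                "axis": axis,
                "variable": var,
                "coefficient": res.coefficient,
                "p_parametric": res.p_parametric,
                "p_permutation": res.p_permutation,
                "significant": (res.p_permutation or res.p_parametric) < alpha,
            })
    return pd.DataFrame(rows)
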