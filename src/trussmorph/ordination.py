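"""Principal component analysis of the correlation matrix with Kaiser retention."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .truss import TrussTable

#: |loading| above which a variable-component correlation is flagged significant
LOADING_THRESHOLD = 0.13


@dataclass
class OrdinationResult:
    """Eigenstructure, loadings and specimen scores of an ordination.

    ``loadings`` are variable-component correlations (eigenvector columns
    scaled by sqrt(eigenvalue)) for correlation-matrix PCA, raw
    eigenvector-projected loadings for covariance PCA. ``n_retained``
    counts eigenvalues > 1 (Kaiser criterion; only meaningful for
    correlation-matrix PCA).
    """

    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    cumulative_percent: np.ndarray
    loadings: pd.DataFrame
    eigenvectors: pd.DataFrame
    scores: pd.DataFrame
    n_retained: int

    def summary(self) -> pd.DataFrame:
        """Eigenvalue / % variance / cumulative % table, one row per component."""
        return pd.DataFrame(
            {
                "eigenvalue": self.eigenvalues,
                "percent_variance": self.percent_variance,
                "cumulative_percent": self.cumulative_percent,
            },
            index=[f"PC{k + 1}" for k in range(len(self.eigenvalues))],
        )

    def significant_loadings(self, threshold: float = LOADING_THRESHOLD) -> pd.DataFrame:
        """Boolean flags: |loading| exceeds the significance threshold."""
        return self.loadings.abs() > threshold


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude entry positive (reproducible tables)."""
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def pca(table: TrussTable) -> OrdinationResult:
    """Correlation-matrix PCA of a truss table.

    Variables are standardized, so eigenvalues sum to the number of
    variables and a component's percent variance is eigenvalue / p.
    Components are ordered by decreasing eigenvalue; each component's
    largest-magnitude loading is made positive. A zero-variance variable
    is an error (it has no correlation structure).
    """
    X = table.data.to_numpy(dtype=float)
    n, p = X.shape
    if p < 2 or n < 2:
        raise ValueError(f"PCA needs >= 2 variables and >= 2 specimens, got {X.shape}")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        dead = [v for v, s in zip(table.variables, sd) if s == 0]
        raise ValueError(f"constant variable(s) with zero variance: {dead}")
    Z = (X - X.mean(axis=0)) / sd
    corr = (Z.T @ Z) / (n - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = _fix_signs(eigvec[:, order])
    percent = 100.0 * eigval / eigval.sum()
    comp_names = [f"PC{k + 1}" for k in range(p)]
    loadings = pd.DataFrame(
        eigvec * np.sqrt(eigval), index=table.data.columns, columns=comp_names
    )
    scores = pd.DataFrame(Z @ eigvec, index=table.data.index, columns=comp_names)
    return OrdinationResult(
        eigenvalues=eigval,
        percent_variance=percent,
        cumulative_percent=np.cumsum(percent),
        loadings=loadings,
        eigenvectors=pd.DataFrame(
            eigvec, index=table.data.columns, columns=comp_names
        ),
        scores=scores,
        n_retained=int((eigval > 1.0).sum()),
    )
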