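"""Canonical discriminant analysis, DAPC, ROC grading and score densities.

CDFA solves the generalized eigenproblem of the between-group SSCP matrix B
against the pooled within-group SSCP matrix W. With eigenvalues l_k:

* percent of discriminant variance of function k = l_k / sum(l),
* canonical correlation_k = sqrt(l_k / (1 + l_k)),
* Wilks' Lambda for functions k..K = prod_{j>=k} 1/(1 + l_j), tested by
  Bartlett's chi-square -(n - 1 - (p + g)/2) * ln(Lambda) with
  (p - k + 1)(g - k) degrees of freedom.

Coefficients are unstandardized: eigenvectors scaled so canonical scores
have unit pooled within-group variance. Membership probabilities are
Gaussian class posteriors in the canonical space (shared identity
within-group covariance), with priors proportional to group sizes by
default.

DAPC first reduces the variables to a small number of correlation-matrix
principal components (default 6) and runs the same canonical analysis on
the component scores; its function coefficients are back-projected onto
the original (standardized) variables through the PCA eigenvectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .ordination import OrdinationResult, pca
from .truss import TrussTable


@dataclass
class DiscriminantResult:
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    canonical_correlations: np.ndarray
    wilks_lambda: np.ndarray
    chi_square: np.ndarray
    chi_df: np.ndarray
    chi_p: np.ndarray
    coefficients: pd.DataFrame
    group_centroids: pd.DataFrame
    scores: pd.DataFrame
    membership_probabilities: pd.DataFrame
    assignment: pd.Series
    loo_assignment: pd.Series
    groups: list[str]
    priors: pd.Series
    variable_coefficients: pd.DataFrame | None = None
    ordination: OrdinationResult | None = field(default=None, repr=False)

    @property
    def n_functions(self) -> int:
        return len(self.eigenvalues)

    def summary(self) -> pd.DataFrame:
        """Per-function eigenvalue, % variance, canonical r, Wilks tests."""
        return pd.DataFrame(
            {
                "eigenvalue": self.eigenvalues,
                "percent_variance": self.percent_variance,
                "cumulative_percent": np.cumsum(self.percent_variance),
                "canonical_correlation": self.canonical_correlations,
                "wilks_lambda": self.wilks_lambda,
                "chi_square": self.chi_square,
                "df": self.chi_df,
                "p": self.chi_p,
            },
            index=[f"F{k + 1}" for k in range(self.n_functions)],
        )

    def accuracy(self, loo: bool = False) -> float:
        """Fraction of specimens assigned to their own group."""
        assigned = self.loo_assignment if loo else self.assignment
        truth = self.membership_probabilities.attrs["true_groups"]
        return float(np.mean(assigned.to_numpy() == np.asarray(truth)))


def _solve_canonical(X: np.ndarray, labels: np.ndarray):
    """Generalized eigenproblem of between vs pooled within SSCP.

    Returns (eigenvalues, coefficient matrix) with coefficients scaled to
    unit pooled within-group variance of the canonical scores.
    """
    n, p = X.shape
    uniq = np.unique(labels)
    g = len(uniq)
    grand = X.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for grp in uniq:
        sub = X[labels == grp]
        d = sub - sub.mean(axis=0)
        W += d.T @ d
        m = sub.mean(axis=0) - grand
        B += len(sub) * np.outer(m, m)
    try:
        eigval, eigvec = linalg.eigh(B, W)
    except linalg.LinAlgError as exc:
        raise ValueError(
            "pooled within-group covariance is singular; reduce the variables "
            "first (e.g. run DAPC on retained principal components) or remove "
            "collinear variables"
        ) from exc
    order = np.argsort(eigval)[::-1]
    k = min(p, g - 1)
    eigval = np.clip(eigval[order][:k], 0.0, None)
    V = eigvec[:, order][:, :k]
    # unit pooled within-group variance of the scores
    wvar = np.einsum("ij,jk,ki->i", V.T, W / (n - g), V)
    V = V / np.sqrt(np.where(wvar > 0, wvar, 1.0))
    # reproducible sign: largest-magnitude coefficient positive
    idx = np.argmax(np.abs(V), axis=0)
    sgn = np.sign(V[idx, np.arange(V.shape[1])])
    sgn[sgn == 0] = 1.0
    return eigval, V * sgn


def _wilks_tests(eigval: np.ndarray, n: int, p: int, g: int):
    K = len(eigval)
    lam = np.array([np.prod(1.0 / (1.0 + eigval[k:])) for k in range(K)])
    factor = n - 1 - (p + g) / 2.0
    chi2 = -factor * np.log(np.clip(lam, 1e-300, None))
    df = np.array([(p - k) * (g - 1 - k) for k in range(K)], dtype=float)
    pval = stats.chi2.sf(chi2, np.where(df > 0, df, 1))
    return lam, chi2, df, pval


def _classify(scores: np.ndarray, centroids: np.ndarray, log_priors: np.ndarray):
    """Posterior membership in canonical space (identity within covariance)."""
    d2 = ((scores[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    logp = log_priors[None, :] - 0.5 * d2
    logp -= logp.max(axis=1, keepdims=True)
    post = np.exp(logp)
    post /= post.sum(axis=1, keepdims=True)
    return post


def _canonical_analysis(
    X: np.ndarray,
    labels: np.ndarray,
    index: pd.Index,
    var_names: list[str],
    priors: str = "proportional",
) -> DiscriminantResult:
    n, p = X.shape
    uniq = list(dict.fromkeys(labels))
    counts = np.array([np.sum(labels == grp) for grp in uniq], dtype=float)
    if len(uniq) < 2:
        raise ValueError("discriminant analysis needs >= 2 groups")
    g = len(uniq)
    if priors == "proportional":
        pr = counts / counts.sum()
    elif priors == "uniform":
        pr = np.full(g, 1.0 / g)
    else:
        raise ValueError(f"unknown priors {priors!r}")

    eigval, V = _solve_canonical(X, labels)
    total = eigval.sum()
    percent = 100.0 * eigval / total if total > 0 else np.zeros_like(eigval)
    canon = np.sqrt(eigval / (1.0 + eigval))
    lam, chi2, df, pval = _wilks_tests(eigval, n, p, g)

    grand = X.mean(axis=0)
    S = (X - grand) @ V
    cent = np.stack([S[labels == grp].mean(axis=0) for grp in uniq])
    post = _classify(S, cent, np.log(pr))
    assign = [uniq[j] for j in post.argmax(axis=1)]

    # leave-one-out: refit the canonical space without each specimen
    loo = []
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        Xi, li = X[keep], labels[keep]
        ev_i, V_i = _solve_canonical(Xi, li)
        S_i = (Xi - Xi.mean(axis=0)) @ V_i
        uniq_i = list(dict.fromkeys(li))
        cent_i = np.stack([S_i[li == grp].mean(axis=0) for grp in uniq_i])
        cnt_i = np.array([np.sum(li == grp) for grp in uniq_i], dtype=float)
        pr_i = cnt_i / cnt_i.sum() if priors == "proportional" else np.full(
            len(uniq_i), 1.0 / len(uniq_i)
        )
        s0 = (X[i] - Xi.mean(axis=0)) @ V_i
        p0 = _classify(s0[None, :], cent_i, np.log(pr_i))[0]
        loo.append(uniq_i[int(p0.argmax())])

    fn = [f"F{k + 1}" for k in range(len(eigval))]
    memb = pd.DataFrame(post, index=index, columns=uniq)
    memb.attrs["true_groups"] = list(labels)
    return DiscriminantResult(
        eigenvalues=eigval,
        percent_variance=percent,
        canonical_correlations=canon,
        wilks_lambda=lam,
        chi_square=chi2,
        chi_df=df,
        chi_p=pval,
        coefficients=pd.DataFrame(V, index=var_names, columns=fn),
        group_centroids=pd.DataFrame(cent, index=uniq, columns=fn),
        scores=pd.DataFrame(S, index=index, columns=fn),
        membership_probabilities=memb,
        assignment=pd.Series(assign, index=index, name="assigned"),
        loo_assignment=pd.Series(loo, index=index, name="loo_assigned"),
        groups=uniq,
        priors=pd.Series(pr, index=uniq, name="prior"),
    )


def cdfa(table: TrussTable, priors: str = "proportional") -> DiscriminantResult:
    """Canonical discriminant function analysis of a truss table."""
    labels = np.asarray(table.group_labels)
    return _canonical_analysis(
        table.data.to_numpy(dtype=float),
        labels,
        table.data.index,
        table.variables,
        priors=priors,
    )


def dapc(
    table: TrussTable,
    n_pcs: int = 6,
    priors: str = "proportional",
) -> DiscriminantResult:
    """Discriminant analysis of principal components.

    Correlation-matrix PCA scores on the first ``n_pcs`` components feed
    the canonical analysis. ``variable_coefficients`` holds the function
    coefficients back-projected onto the original standardized variables
    (eigenvector rows composed with the component coefficients).
    """
    ordination = pca(table)
    rank = int(np.sum(ordination.eigenvalues > 1e-10))
    if not 1 <= n_pcs <= rank:
        raise ValueError(f"n_pcs must be in [1, {rank}], got {n_pcs}")
    scores = ordination.scores.iloc[:, :n_pcs]
    labels = np.asarray(table.group_labels)
    result = _canonical_analysis(
        scores.to_numpy(),
        labels,
        table.data.index,
        list(scores.columns),
        priors=priors,
    )
    back = ordination.eigenvectors.to_numpy()[:, :n_pcs] @ result.coefficients.to_numpy()
    result.variable_coefficients = pd.DataFrame(
        back, index=table.data.columns, columns=result.coefficients.columns
    )
    result.ordination = ordination
    return result


_PERFORMANCE_BANDS = [(0.9, "outstanding"), (0.8, "excellent")]


def performance_band(auc: float) -> str:
    """Grade a discrimination AUC: >=0.9 outstanding, >=0.8 excellent."""
    for lo, label in _PERFORMANCE_BANDS:
        if auc >= lo:
            return label
    return "lower"


@dataclass
class RocResult:
    auc: float
    curve: pd.DataFrame  # columns: one_minus_specificity, sensitivity
    band: str


def roc_auc(scores, labels) -> RocResult:
    """One-vs-rest ROC of a score against a boolean in-group label.

    The AUC uses the Mann-Whitney pair-counting identity (ties count
    one half), computed through midranks; the curve is sensitivity vs
    (1 - specificity).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes nonempty")
    ranks = stats.rankdata(scores)
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, _ = _sk_roc_curve(labels.astype(int), scores)
    curve = pd.DataFrame({"one_minus_specificity": fpr, "sensitivity": tpr})
    return RocResult(auc=float(auc), curve=curve, band=performance_band(float(auc)))


def roc_by_group(result: DiscriminantResult) -> dict[str, RocResult]:
    """One-vs-rest ROC per group, scored by its membership probability."""
    truth = np.asarray(result.membership_probabilities.attrs["true_groups"])
    return {
        grp: roc_auc(result.membership_probabilities[grp].to_numpy(), truth == grp)
        for grp in result.groups
    }


def score_density(
    result: DiscriminantResult | OrdinationResult,
    function_index: int = 0,
    groups=None,
    grid_points: int = 512,
) -> pd.DataFrame:
    """Per-group kernel density of scores along one axis, on a shared grid.

    Returns a frame indexed by the grid with one column per group;
    ``attrs['group_means']`` holds each group's mean position on the axis.
    A group whose scores are all identical is represented by a narrow
    Gaussian at that value (bandwidth 1% of the grid span).
    """
    score_frame = result.scores
    axis = score_frame.iloc[:, function_index].to_numpy()
    if groups is None:
        if isinstance(result, DiscriminantResult):
            groups = result.membership_probabilities.attrs["true_groups"]
        else:
            raise ValueError("groups must be given for an ordination result")
    groups = np.asarray(groups)
    uniq = list(dict.fromkeys(groups))
    span = axis.max() - axis.min()
    pad = 0.25 * span if span > 0 else 1.0
    grid = np.linspace(axis.min() - pad, axis.max() + pad, grid_points)
    out = {}
    means = {}
    for grp in uniq:
        vals = axis[groups == grp]
        if len(vals) == 0:
            raise ValueError(f"empty group {grp!r}")
        means[grp] = float(vals.mean())
        if np.ptp(vals) == 0:
            bw = 0.01 * (grid[-1] - grid[0])
            out[grp] = stats.norm.pdf(grid, loc=vals[0], scale=bw)
        else:
            out[grp] = stats.gaussian_kde(vals)(grid)
    frame = pd.DataFrame(out, index=pd.Index(grid, name="score"))
    frame.attrs["group_means"] = means
    return frame
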