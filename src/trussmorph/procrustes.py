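"""Generalized Procrustes analysis, Procrustes ANOVA and group shape tests.

GPA iteratively translates each configuration to a zero centroid, scales it
to unit centroid size and rotates it (reflections disallowed — specimens
share a consistent left-facing orientation) into least-squares fit with the
running consensus, until the consensus stabilizes. Shape comparisons use
the full Procrustes distance between unit-size preshapes by default.

Group structure is tested two ways: a Goodall-style ANOVA that decomposes
the summed squared Procrustes residuals into between- and within-group
parts (the F statistic's null distribution obtained by permuting group
labels), and pairwise mean-shape tests combining the Procrustes distance,
a Mahalanobis distance in a two-group discriminant space built on shape-PCA
scores, a label-permutation p-value and leave-one-out cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import LandmarkDataset
from .ordination import OrdinationResult


# ---------------------------------------------------------------------------
# elementary shape operations


def centroid_size(shape: np.ndarray) -> float:
    """Square root of summed squared landmark distances from the centroid."""
    c = shape - shape.mean(axis=0)
    return float(np.sqrt((c**2).sum()))


def _preshape(shape: np.ndarray) -> np.ndarray:
    """Center and scale to unit centroid size."""
    c = shape - shape.mean(axis=0)
    size = np.sqrt((c**2).sum())
    if size == 0:
        raise ValueError("degenerate configuration: zero centroid size")
    return c / size


def optimal_rotation(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Rotation R (no reflection) minimizing ||X @ R - Y||."""
    H = X.T @ Y
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    S = np.diag([1.0, d])
    return U @ S @ Vt


def procrustes_distance(a: np.ndarray, b: np.ndarray, kind: str = "full") -> float:
    """Procrustes distance between two configurations.

    Both are reduced to unit-size preshapes and rotated into optimal fit
    (reflections disallowed). ``kind='full'`` additionally optimizes the
    relative scale (d = sqrt(1 - cos^2 rho)); ``'partial'`` keeps both at
    unit size (d = ||A - B R||). Both vanish iff the shapes coincide up
    to a similarity transform.
    """
    A = _preshape(np.asarray(a, dtype=float))
    B = _preshape(np.asarray(b, dtype=float))
    H = A.T @ B
    U, s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    cosr = s[0] + d * s[1]
    cosr = min(cosr, 1.0)
    if kind == "full":
        return float(np.sqrt(max(0.0, 1.0 - cosr**2)))
    if kind == "partial":
        return float(np.sqrt(max(0.0, 2.0 - 2.0 * cosr)))
    raise ValueError(f"unknown kind {kind!r}")


# ---------------------------------------------------------------------------
# generalized Procrustes analysis


@dataclass
class ProcrustesResult:
    """Aligned configurations (zero centroid, unit size) and their consensus."""

    aligned: np.ndarray  # (n, k, 2)
    consensus: np.ndarray  # (k, 2)
    centroid_sizes: np.ndarray  # (n,), mm
    specimen_ids: list[str]
    group_labels: list[str]
    iterations: int
    convergence_delta: float

    @property
    def n_specimens(self) -> int:
        return self.aligned.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.aligned.shape[1]

    @property
    def shape_dim(self) -> int:
        """Dimension of shape space: 2k - 4 similarity-free coordinates."""
        return 2 * self.n_landmarks - 4

    def residuals(self) -> np.ndarray:
        """Flattened deviations of aligned shapes from the consensus, (n, 2k)."""
        return (self.aligned - self.consensus).reshape(self.n_specimens, -1)

    def tangent_residuals(self) -> np.ndarray:
        """Residuals projected onto the shape tangent space at the consensus.

        Removes the four similarity directions (two translations, scaling
        along the consensus, infinitesimal rotation of the consensus), so
        exactly 2k - 4 dimensions can carry variance.
        """
        k = self.n_landmarks
        t1 = np.tile([1.0, 0.0], k)
        t2 = np.tile([0.0, 1.0], k)
        s = self.consensus.reshape(-1)
        rot = np.column_stack(
            [-self.consensus[:, 1], self.consensus[:, 0]]
        ).reshape(-1)
        basis = np.stack([t1, t2, s, rot])
        q, _ = np.linalg.qr(basis.T)
        R = self.residuals()
        return R - (R @ q) @ q.T

    def distance_matrix(self, kind: str = "full") -> pd.DataFrame:
        """Pairwise Procrustes distances between all aligned specimens."""
        n = self.n_specimens
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = procrustes_distance(
                    self.aligned[i], self.aligned[j], kind
                )
        return pd.DataFrame(D, index=self.specimen_ids, columns=self.specimen_ids)

    def group_mean_shapes(self) -> dict[str, np.ndarray]:
        labels = np.asarray(self.group_labels)
        return {
            g: self.aligned[labels == g].mean(axis=0)
            for g in dict.fromkeys(self.group_labels)
        }


def gpa(
    data: LandmarkDataset,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> ProcrustesResult:
    """Generalized Procrustes superimposition of a landmark dataset."""
    if data.n_specimens < 2:
        raise ValueError("GPA needs >= 2 specimens")
    sizes = np.empty(data.n_specimens)
    pre = np.empty_like(data.coords)
    for i in range(data.n_specimens):
        c = data.coords[i] - data.coords[i].mean(axis=0)
        s = np.sqrt((c**2).sum())
        if s == 0:
            raise ValueError(
                f"degenerate configuration (zero centroid size): "
                f"specimen {data.specimen_ids[i]}"
            )
        sizes[i] = s
        pre[i] = c / s

    consensus = pre[0].copy()
    aligned = pre.copy()
    delta = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(len(aligned)):
            aligned[i] = pre[i] @ optimal_rotation(pre[i], consensus)
        new = aligned.mean(axis=0)
        new = new - new.mean(axis=0)
        new /= np.sqrt((new**2).sum())
        delta = float(np.sqrt(((new - consensus) ** 2).sum()))
        consensus = new
        if delta < tol:
            break
    return ProcrustesResult(
        aligned=aligned,
        # reported consensus is the plain coordinate-wise mean of the
        # aligned shapes (its size is marginally below 1)
        consensus=aligned.mean(axis=0),
        centroid_sizes=sizes,
        specimen_ids=list(data.specimen_ids),
        group_labels=list(data.group_labels),
        iterations=it,
        convergence_delta=delta,
    )


# ---------------------------------------------------------------------------
# Procrustes ANOVA (Goodall-style, permutation p)


def _between_ss(R: np.ndarray, labels: np.ndarray, uniq: np.ndarray) -> float:
    grand = R.mean(axis=0)
    ssb = 0.0
    for g in uniq:
        sub = R[labels == g]
        m = sub.mean(axis=0) - grand
        ssb += len(sub) * float(m @ m)
    return ssb


def procrustes_anova(
    result: ProcrustesResult,
    n_perm: int = 999,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Centroid-size ANOVA and Goodall shape ANOVA across groups.

    Size: classical one-way ANOVA on log centroid size. Shape: Goodall
    decomposition of squared Procrustes residuals with the 2k-4 shape
    dimensions pooled into the degrees of freedom; the p-value comes from
    ``n_perm`` seeded label permutations of the F statistic (the
    parametric Goodall p is also reported).
    """
    labels = np.asarray(result.group_labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("Procrustes ANOVA needs >= 2 groups")
    if (counts < 2).any():
        small = dict(zip(uniq[counts < 2], counts[counts < 2]))
        raise ValueError(f"groups with < 2 specimens: {small}")

    logs = np.log(result.centroid_sizes)
    fs, ps = stats.f_oneway(*[logs[labels == g] for g in uniq])
    size_table = pd.DataFrame(
        {"F": [fs], "p": [ps], "df_between": [len(uniq) - 1],
         "df_within": [len(labels) - len(uniq)]},
        index=["log_centroid_size"],
    )

    R = result.residuals()
    n, g = len(labels), len(uniq)
    ssb = _between_ss(R, labels, uniq)
    sst = float(((R - R.mean(axis=0)) ** 2).sum())
    ssw = sst - ssb
    m = result.shape_dim
    dfb = (g - 1) * m
    dfw = (n - g) * m
    degenerate = sst <= 1e-300
    if degenerate:
        f_obs, p_param, p_perm = np.nan, np.nan, np.nan
    else:
        f_obs = (ssb / dfb) / (ssw / dfw)
        p_param = float(stats.f.sf(f_obs, dfb, dfw))
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(labels)
            ssb_p = _between_ss(R, perm, uniq)
            f_p = (ssb_p / dfb) / ((sst - ssb_p) / dfw)
            if f_p >= f_obs:
                hits += 1
        p_perm = (1 + hits) / (n_perm + 1)
    shape_table = pd.DataFrame(
        {
            "SS": [ssb, ssw],
            "df": [dfb, dfw],
            "MS": [ssb / dfb, ssw / dfw],
            "F": [f_obs, np.nan],
            "p_param": [p_param, np.nan],
            "p_perm": [p_perm, np.nan],
        },
        index=["between_groups", "within_groups"],
    )
    shape_table.attrs["degenerate"] = bool(degenerate)
    shape_table.attrs["n_perm"] = n_perm
    shape_table.attrs["seed"] = seed
    return {"size": size_table, "shape": shape_table}


# ---------------------------------------------------------------------------
# shape PCA


def shape_pca(result: ProcrustesResult) -> OrdinationResult:
    """Covariance-matrix PCA of the aligned coordinates (Procrustes residuals).

    At most 2k - 4 eigenvalues are nonzero (the residuals are projected
    onto the tangent space, removing the four similarity degrees of
    freedom). Loadings are the eigenvectors in coordinate space (columns
    x1, y1, ..., xk, yk).
    """
    R = result.tangent_residuals()
    n = R.shape[0]
    C = (R - R.mean(axis=0)).T @ (R - R.mean(axis=0)) / (n - 1)
    eigval, eigvec = np.linalg.eigh(C)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    idx = np.argmax(np.abs(eigvec), axis=0)
    sgn = np.sign(eigvec[idx, np.arange(eigvec.shape[1])])
    sgn[sgn == 0] = 1.0
    eigvec = eigvec * sgn
    total = eigval.sum()
    percent = (
        100.0 * eigval / total if total > 0 else np.zeros_like(eigval)
    )
    k = result.n_landmarks
    coord_names = [f"{ax}{j + 1}" for j in range(k) for ax in ("x", "y")]
    comp_names = [f"PC{j + 1}" for j in range(len(eigval))]
    scores = (R - R.mean(axis=0)) @ eigvec
    return OrdinationResult(
        eigenvalues=eigval,
        percent_variance=percent,
        cumulative_percent=np.cumsum(percent),
        loadings=pd.DataFrame(eigvec, index=coord_names, columns=comp_names),
        eigenvectors=pd.DataFrame(eigvec, index=coord_names, columns=comp_names),
        scores=pd.DataFrame(scores, index=result.specimen_ids, columns=comp_names),
        n_retained=int((eigval > 1.0).sum()),
    )


def confidence_ellipse(
    scores: pd.DataFrame,
    groups,
    components: tuple[int, int] = (0, 1),
    level: float = 0.95,
) -> pd.DataFrame:
    """Per-group confidence-ellipse parameters on a component pair.

    Returns center, semi-axes and orientation derived from each group's
    score covariance and the chi-square quantile of ``level``.
    """
    groups = np.asarray(groups)
    q = stats.chi2.ppf(level, df=2)
    rows = []
    for g in dict.fromkeys(groups):
        sub = scores.iloc[:, list(components)].to_numpy()[groups == g]
        if len(sub) < 3:
            continue
        center = sub.mean(axis=0)
        cov = np.cov(sub, rowvar=False)
        val, vec = np.linalg.eigh(cov)
        order = np.argsort(val)[::-1]
        val, vec = val[order], vec[:, order]
        rows.append(
            {
                "group": g,
                "center_x": center[0],
                "center_y": center[1],
                "semi_major": float(np.sqrt(q * max(val[0], 0.0))),
                "semi_minor": float(np.sqrt(q * max(val[1], 0.0))),
                "angle_deg": float(np.degrees(np.arctan2(vec[1, 0], vec[0, 0]))),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pairwise group mean-shape tests


@dataclass
class GroupShapeTest:
    group1: str
    group2: str
    procrustes_distance: float
    mahalanobis_distance: float
    p_perm: float
    loo_cv_accuracy: float
    shape_difference_vectors: np.ndarray  # (k, 2): mean2 - mean1 per landmark
    n_perm: int
    seed: int


def _pair_mahalanobis(scores: np.ndarray, labels01: np.ndarray) -> float:
    """Mahalanobis distance between two group means, pooled covariance."""
    a = scores[labels01 == 0]
    b = scores[labels01 == 1]
    da = a - a.mean(axis=0)
    db = b - b.mean(axis=0)
    pooled = (da.T @ da + db.T @ db) / (len(a) + len(b) - 2)
    diff = b.mean(axis=0) - a.mean(axis=0)
    sol = np.linalg.solve(pooled, diff)
    return float(np.sqrt(diff @ sol))


def _pair_loo_cv(scores: np.ndarray, labels01: np.ndarray) -> float:
    """Leave-one-out accuracy of two-group linear discriminant assignment."""
    n = len(scores)
    correct = 0
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        X, y = scores[keep], labels01[keep]
        m0 = X[y == 0].mean(axis=0)
        m1 = X[y == 1].mean(axis=0)
        d0 = X[y == 0] - m0
        d1 = X[y == 1] - m1
        pooled = (d0.T @ d0 + d1.T @ d1) / (len(X) - 2)
        w = np.linalg.solve(pooled, m1 - m0)
        thresh = w @ (m0 + m1) / 2.0
        pred = 1 if scores[i] @ w > thresh else 0
        correct += pred == labels01[i]
    return correct / n


def group_mean_tests(
    result: ProcrustesResult,
    n_perm: int = 999,
    seed: int = 0,
    variance_cutoff: float = 0.95,
) -> list[GroupShapeTest]:
    """Pairwise mean-shape comparisons between all groups.

    For each pair: full Procrustes distance between the group mean
    shapes; Mahalanobis distance between means in a discriminant space
    built on shape-PCA scores of the pair (components covering
    ``variance_cutoff`` of variance, capped so the pooled covariance
    stays invertible); a label-permutation p-value of the Procrustes
    distance; leave-one-out CV accuracy of two-group assignment; and the
    per-landmark mean-difference ("lollipop") vectors. Pairs in which a
    group has fewer than 3 specimens are skipped with a warning.
    """
    import logging

    logger = logging.getLogger(__name__)
    labels = np.asarray(result.group_labels)
    uniq = list(dict.fromkeys(result.group_labels))
    spca = shape_pca(result)
    all_scores = spca.scores.to_numpy()
    cum = spca.cumulative_percent
    k95 = int(np.searchsorted(cum, 100.0 * variance_cutoff) + 1)
    out: list[GroupShapeTest] = []
    rng = np.random.default_rng(seed)
    for ia, a in enumerate(uniq):
        for b in uniq[ia + 1 :]:
            na = int((labels == a).sum())
            nb = int((labels == b).sum())
            if na < 3 or nb < 3:
                logger.warning("skipping pair (%s, %s): group too small", a, b)
                continue
            mask = (labels == a) | (labels == b)
            sub = result.aligned[mask]
            sub_labels = (labels[mask] == b).astype(int)
            mean_a = sub[sub_labels == 0].mean(axis=0)
            mean_b = sub[sub_labels == 1].mean(axis=0)
            d_obs = procrustes_distance(mean_a, mean_b)
            # permutation: shuffle the pair's labels, recompute the distance
            hits = 0
            for _ in range(n_perm):
                perm = rng.permutation(sub_labels)
                pa = sub[perm == 0].mean(axis=0)
                pb = sub[perm == 1].mean(axis=0)
                if procrustes_distance(pa, pb) >= d_obs:
                    hits += 1
            p_perm = (1 + hits) / (n_perm + 1)
            ncomp = min(k95, na + nb - 3, int(np.sum(spca.eigenvalues > 1e-12)))
            scores = all_scores[mask][:, :ncomp]
            maha = _pair_mahalanobis(scores, sub_labels)
            cv = _pair_loo_cv(scores, sub_labels)
            out.append(
                GroupShapeTest(
                    group1=a,
                    group2=b,
                    procrustes_distance=d_obs,
                    mahalanobis_distance=maha,
                    p_perm=p_perm,
                    loo_cv_accuracy=cv,
                    shape_difference_vectors=mean_b - mean_a,
                    n_perm=n_perm,
                    seed=seed,
                )
            )
    return out


def group_tests_frame(tests: list[GroupShapeTest]) -> pd.DataFrame:
    """Tabular form of pairwise tests (one row per group pair)."""
    return pd.DataFrame(
        [
            {
                "group1": t.group1,
                "group2": t.group2,
                "proc_dist": t.procrustes_distance,
                "mahalanobis": t.mahalanobis_distance,
                "p_perm": t.p_perm,
                "loo_cv": t.loo_cv_accuracy,
                "n_perm": t.n_perm,
                "seed": t.seed,
            }
            for t in tests
        ]
    )
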