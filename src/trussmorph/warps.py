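"""Thin-plate-spline warps, relative warps, PSR/WDS scores, RV modularity.

The 2D thin-plate spline with kernel U(r) = r^2 log r^2 is the smoothest
interpolating map carrying one landmark configuration exactly onto
another; its bending energy (a quadratic form of the reference
configuration, zero exactly on affine targets) quantifies non-affine shape
change. Relative warps are principal components of Procrustes-aligned
shape residuals, optionally re-weighted by the bending-energy
eigenstructure of the consensus with exponent alpha (alpha = 0 reproduces
plain shape PCA).

Two group-level summaries of the warp scores are provided: the principal
score ratio PSR = (maximum extreme deformation magnitude) / (minimum
extreme deformation magnitude) per group and PC, and a warp density score
(a weighted sum of specimen scores; the weighting is pluggable and is
recorded in output metadata). Landmark-subset modularity is measured by
Escoufier's RV coefficient between two coordinate blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ordination import OrdinationResult
from .procrustes import ProcrustesResult

logger = logging.getLogger(__name__)

#: landmark subsets (1-based) used for the modularity presets:
#: the hump region and the fin region of the 9-landmark body plan
HUMP_SUBSET = (1, 8, 9)
FIN_SUBSET = (4, 5, 6)


# ---------------------------------------------------------------------------
# thin-plate spline


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    """U(r) = r^2 log r^2, with U(0) = 0."""
    out = np.zeros_like(r2)
    nz = r2 > 0
    out[nz] = r2[nz] * np.log(r2[nz])
    return out


@dataclass
class TpsWarp:
    """Fitted thin-plate spline carrying ``reference`` onto ``target``."""

    reference: np.ndarray  # (k, 2)
    target: np.ndarray  # (k, 2)
    kernel_weights: np.ndarray  # (k, 2)
    affine: np.ndarray  # (3, 2): [constant; x; y] rows
    bending_energy_matrix: np.ndarray  # (k, k), PSD, annihilates affine
    total_bending_energy: float

    def __call__(self, points: np.ndarray) -> np.ndarray:
        """Evaluate the warp at arbitrary 2D points, shape (m, 2)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        d = points[:, None, :] - self.reference[None, :, :]
        K = _tps_kernel((d**2).sum(axis=-1))
        P = np.column_stack([np.ones(len(points)), points])
        return K @ self.kernel_weights + P @ self.affine

    def grid(self, n: int = 25, padding: float = 0.10) -> np.ndarray:
        """Warped n x n lattice over the reference bounding box (padded)."""
        lo = self.reference.min(axis=0)
        hi = self.reference.max(axis=0)
        pad = padding * (hi - lo)
        xs = np.linspace(lo[0] - pad[0], hi[0] + pad[0], n)
        ys = np.linspace(lo[1] - pad[1], hi[1] + pad[1], n)
        pts = np.array([(x, y) for y in ys for x in xs])
        return self(pts).reshape(n, n, 2)


def bending_energy_matrix(reference: np.ndarray) -> np.ndarray:
    """Bending-energy quadratic form of a reference configuration.

    The k x k matrix L_k^-1 (upper-left block of the inverted bordered
    TPS system). It is positive semidefinite and annihilates constant and
    linear (affine) target coordinates.
    """
    ref = np.asarray(reference, dtype=float)
    k = len(ref)
    if k < 4:
        raise ValueError(f"TPS needs >= 4 landmarks, got {k}")
    d = ref[:, None, :] - ref[None, :, :]
    K = _tps_kernel((d**2).sum(axis=-1))
    P = np.column_stack([np.ones(k), ref])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = P
    L[k:, :k] = P.T
    try:
        Linv = np.linalg.inv(L)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular TPS system: reference landmarks are collinear"
        ) from exc
    B = Linv[:k, :k]
    return (B + B.T) / 2.0


def tps_fit(reference: np.ndarray, target: np.ndarray) -> TpsWarp:
    """Fit the thin-plate spline interpolating reference -> target."""
    ref = np.asarray(reference, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if ref.shape != tgt.shape:
        raise ValueError(
            f"shape mismatch: reference {ref.shape} vs target {tgt.shape}"
        )
    k = len(ref)
    if k < 4:
        raise ValueError(f"TPS needs >= 4 landmarks, got {k}")
    d = ref[:, None, :] - ref[None, :, :]
    K = _tps_kernel((d**2).sum(axis=-1))
    P = np.column_stack([np.ones(k), ref])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = P
    L[k:, :k] = P.T
    rhs = np.zeros((k + 3, 2))
    rhs[:k] = tgt
    try:
        sol = np.linalg.solve(L, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular TPS system: reference landmarks are collinear"
        ) from exc
    B = bending_energy_matrix(ref)
    energy = float(np.trace(tgt.T @ B @ tgt))
    return TpsWarp(
        reference=ref,
        target=tgt,
        kernel_weights=sol[:k],
        affine=sol[k:],
        bending_energy_matrix=B,
        total_bending_energy=max(energy, 0.0),
    )


# ---------------------------------------------------------------------------
# relative warps


def relative_warps(
    result: ProcrustesResult,
    alpha: float = 0.0,
) -> OrdinationResult:
    """Relative-warp analysis of Procrustes-aligned shapes.

    Principal components of the aligned residuals after re-weighting by
    the consensus bending-energy eigenstructure with exponent
    ``alpha/2`` (non-affine subspace only; the affine subspace keeps unit
    weight). alpha = 0 leaves the residuals untouched and is exactly
    shape PCA; alpha > 0 emphasizes large-scale (low bending energy)
    deformation, alpha < 0 small-scale. |alpha| must be <= 1.
    """
    if abs(alpha) > 1:
        raise ValueError(f"|alpha| must be <= 1, got {alpha}")
    R = result.tangent_residuals()
    n = R.shape[0]
    k = result.n_landmarks
    if alpha == 0.0:
        weighted = R
        gamma = np.eye(2 * k)
    else:
        B = bending_energy_matrix(result.consensus)
        val, vec = np.linalg.eigh(B)
        nonzero = val > 1e-10
        Q = vec[:, nonzero]
        lam = val[nonzero]
        N = Q @ Q.T  # projector onto the non-affine subspace
        g9 = Q @ np.diag(lam ** (-alpha / 2.0)) @ Q.T + (np.eye(k) - N)
        gamma = np.kron(g9, np.eye(2))
        weighted = R @ gamma
    C = (weighted - weighted.mean(axis=0)).T @ (
        weighted - weighted.mean(axis=0)
    ) / (n - 1)
    eigval, eigvec = np.linalg.eigh(C)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    idx = np.argmax(np.abs(eigvec), axis=0)
    sgn = np.sign(eigvec[idx, np.arange(eigvec.shape[1])])
    sgn[sgn == 0] = 1.0
    eigvec = eigvec * sgn
    total = eigval.sum()
    percent = 100.0 * eigval / total if total > 0 else np.zeros_like(eigval)
    scores = (weighted - weighted.mean(axis=0)) @ eigvec
    coord_names = [f"{ax}{j + 1}" for j in range(k) for ax in ("x", "y")]
    comp_names = [f"RW{j + 1}" for j in range(len(eigval))]
    out = OrdinationResult(
        eigenvalues=eigval,
        percent_variance=percent,
        cumulative_percent=np.cumsum(percent),
        loadings=pd.DataFrame(eigvec, index=coord_names, columns=comp_names),
        eigenvectors=pd.DataFrame(eigvec, index=coord_names, columns=comp_names),
        scores=pd.DataFrame(
            scores, index=result.specimen_ids, columns=comp_names
        ),
        n_retained=int((eigval > 1.0).sum()),
    )
    out.scores.attrs["alpha"] = alpha
    return out


# ---------------------------------------------------------------------------
# PSR and WDS


def psr(max_magnitude: float, min_magnitude: float) -> float:
    """Principal score ratio: max extreme deformation / min extreme deformation.

    Returns inf (with a warning) when the minimum magnitude is zero.
    """
    if min_magnitude == 0:
        logger.warning("zero minimum extreme magnitude: PSR is infinite")
        return float("inf")
    return float(max_magnitude) / float(min_magnitude)


def warp_summary(
    scores: pd.DataFrame,
    groups,
    components: tuple[int, ...] = (0, 1),
) -> pd.DataFrame:
    """Per-group score summary and PSR on the chosen components.

    For each group and component: mean, SD, min, max of the raw scores;
    the extreme-deformation pair (larger magnitude, smaller magnitude)
    taken from the group's two sign-extreme scores; and their ratio PSR.
    """
    groups = np.asarray(groups)
    rows = []
    for g in dict.fromkeys(groups):
        row: dict[str, object] = {"group": g}
        for c in components:
            vals = scores.iloc[:, c].to_numpy()[groups == g]
            if len(vals) == 0:
                raise ValueError(f"empty group {g!r}")
            hi, lo = abs(vals.max()), abs(vals.min())
            mx, mn = max(hi, lo), min(hi, lo)
            pc = scores.columns[c]
            row[f"{pc}_mean"] = vals.mean()
            row[f"{pc}_sd"] = vals.std(ddof=1) if len(vals) > 1 else 0.0
            row[f"{pc}_min"] = vals.min()
            row[f"{pc}_max"] = vals.max()
            row[f"{pc}_extreme_max"] = mx
            row[f"{pc}_extreme_min"] = mn
            row[f"{pc}_psr"] = psr(mx, mn)
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


def warp_density_score(
    scores,
    groups,
    weights=None,
) -> pd.Series:
    """Group-level aggregate of warp scores on one component.

    Default: the plain per-group sum of scores (unit weights); pass
    per-specimen ``weights`` (e.g. normalized bending energies) to weight
    the sum. The formula choice is recorded in the result's attrs since
    several aggregates are plausible.
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    if weights is None:
        weights = np.ones_like(scores)
        formula = "sum of scores (unit weights)"
    else:
        weights = np.asarray(weights, dtype=float)
        formula = "weighted sum of scores"
    vals = {
        g: float((scores[groups == g] * weights[groups == g]).sum())
        for g in dict.fromkeys(groups)
    }
    out = pd.Series(vals, name="wds")
    out.attrs["formula"] = formula
    return out


def specimen_bending_energies(result: ProcrustesResult) -> np.ndarray:
    """Bending energy of each aligned specimen against the consensus."""
    B = bending_energy_matrix(result.consensus)
    return np.array(
        [float(np.trace(s.T @ B @ s)) for s in result.aligned]
    )


# ---------------------------------------------------------------------------
# RV modularity


def rv_coefficient(X: np.ndarray, Y: np.ndarray) -> float:
    """Escoufier's RV between two column blocks of the same specimens.

    RV = tr(S12 S21) / sqrt(tr(S11^2) tr(S22^2)) with S the joint
    covariance; lies in [0, 1], equals 1 for identical (or linearly
    equivalent) blocks.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    n = len(X)
    S11 = Xc.T @ Xc / (n - 1)
    S22 = Yc.T @ Yc / (n - 1)
    S12 = Xc.T @ Yc / (n - 1)
    num = float(np.trace(S12 @ S12.T))
    den = float(np.sqrt(np.trace(S11 @ S11) * np.trace(S22 @ S22)))
    if den == 0:
        raise ValueError("zero-variance block: RV undefined")
    return num / den


def _block(result: ProcrustesResult, subset: tuple[int, ...]) -> np.ndarray:
    cols = []
    for lm in subset:
        cols.extend([2 * (lm - 1), 2 * (lm - 1) + 1])
    return result.aligned.reshape(result.n_specimens, -1)[:, cols]


def rv_modularity(
    result: ProcrustesResult,
    subset: tuple[int, ...],
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """RV coefficient between a landmark subset and its complement.

    ``subset`` holds 1-based landmark indices (e.g. the hump preset
    (1, 8, 9) or the fin preset (4, 5, 6)). The observed RV is compared
    against ``n_perm`` random partitions of the same sizes plus all
    contiguous (cyclically shifted) partitions; the proportion of
    alternatives with RV <= observed is reported (low values mean the
    hypothesized split covaries *less* than typical splits, i.e. is more
    modular).
    """
    k = result.n_landmarks
    subset = tuple(sorted(subset))
    if len(set(subset)) != len(subset):
        raise ValueError(f"subset has repeated landmarks: {subset}")
    if not all(1 <= lm <= k for lm in subset):
        raise ValueError(f"subset indices must be in 1..{k}: {subset}")
    complement = tuple(lm for lm in range(1, k + 1) if lm not in subset)
    if len(subset) < 2 or len(complement) < 2:
        raise ValueError("each block needs >= 2 landmarks")

    observed = rv_coefficient(_block(result, subset), _block(result, complement))

    alternatives = []
    m = len(subset)
    for shift in range(1, k):  # contiguous partitions of the same size
        alt = tuple(sorted(((lm - 1 + shift) % k) + 1 for lm in range(1, m + 1)))
        if alt != subset:
            comp = tuple(lm for lm in range(1, k + 1) if lm not in alt)
            alternatives.append(
                rv_coefficient(_block(result, alt), _block(result, comp))
            )
    rng = np.random.default_rng(seed)
    for _ in range(n_perm):
        alt = tuple(sorted(rng.choice(np.arange(1, k + 1), size=m, replace=False)))
        if alt == subset:
            continue
        comp = tuple(lm for lm in range(1, k + 1) if lm not in alt)
        alternatives.append(
            rv_coefficient(_block(result, alt), _block(result, comp))
        )
    alternatives = np.asarray(alternatives)
    return {
        "subset": subset,
        "complement": complement,
        "rv": observed,
        "alternatives": alternatives,
        "proportion_lower_or_equal": float(np.mean(alternatives <= observed)),
        "n_perm": n_perm,
        "seed": seed,
    }
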