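"""Truss distance network, allometric size correction, pre-analysis screens.

The truss network is the complete set of inter-landmark Euclidean distances
("i_j" with 1-based i < j): 36 variables for 9 landmarks. Variable 1_4
(snout to posterior end of the vertebral column) is the standard length SL,
the size covariate of the Elliott adjustment

    M_adj = M * (L_S / L_0) ** b

where L_0 is the specimen's SL, L_S the overall mean SL, and b the slope of
the pooled log-log regression of the measurement on SL. SL itself is
removed after adjustment, leaving 35 analysis variables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import LandmarkDataset

logger = logging.getLogger(__name__)

#: name of the standard-length variable in the 9-landmark schema
SL_VARIABLE = "1_4"


def pair_names(n_landmarks: int) -> list[str]:
    """All C(n,2) unordered pair names 'i_j' (1-based, i < j)."""
    return [
        f"{i}_{j}"
        for i in range(1, n_landmarks + 1)
        for j in range(i + 1, n_landmarks + 1)
    ]


@dataclass
class TrussTable:
    """Specimens x named inter-landmark distances.

    ``data`` is indexed by specimen id with 'i_j' columns; values are mm
    in the raw state, dimensionless after log transformation.
    ``transform_state`` is one of ``raw``, ``log``, ``size_adjusted``.
    """

    data: pd.DataFrame
    group_labels: list[str]
    transform_state: str = "raw"

    def __post_init__(self) -> None:
        if len(self.group_labels) != len(self.data):
            raise ValueError("group_labels and data disagree on specimen count")
        if self.transform_state not in {"raw", "log", "size_adjusted"}:
            raise ValueError(f"unknown transform_state {self.transform_state!r}")

    @property
    def specimen_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    @property
    def variables(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def groups(self) -> pd.Series:
        return pd.Series(self.group_labels, index=self.data.index, name="group")

    @property
    def n_specimens(self) -> int:
        return len(self.data)


@dataclass
class AllometricModel:
    """Fitted Elliott size-correction model.

    ``b`` holds one growth exponent per variable, ``L_S`` the overall mean
    standard length (mm) and ``L_0`` the per-specimen standard length (mm).
    """

    b: pd.Series
    L_S: float
    L_0: pd.Series

    def __post_init__(self) -> None:
        if (self.L_0 <= 0).any():
            bad = list(self.L_0.index[self.L_0 <= 0])
            raise ValueError(f"nonpositive standard length for specimens: {bad}")
        if self.L_S <= 0:
            raise ValueError(f"L_S must be > 0, got {self.L_S}")


def truss_distances(data: LandmarkDataset) -> TrussTable:
    """Full pairwise distance network of a landmark dataset.

    Produces n(n-1)/2 variables named 'i_j'. Coincident landmarks give a
    zero distance and a logged warning (not an error).
    """
    if data.n_landmarks < 3:
        raise ValueError(f"need >= 3 landmarks, got {data.n_landmarks}")
    c = data.coords
    diff = c[:, :, None, :] - c[:, None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    iu = np.triu_indices(data.n_landmarks, k=1)
    values = dist[:, iu[0], iu[1]]
    if np.any(values == 0):
        spec, pair = np.nonzero(values == 0)
        for s, p in zip(spec[:5], pair[:5]):
            logger.warning(
                "coincident landmarks (%d, %d) in specimen %s",
                iu[0][p] + 1,
                iu[1][p] + 1,
                data.specimen_ids[s],
            )
    frame = pd.DataFrame(
        values, index=data.specimen_ids, columns=pair_names(data.n_landmarks)
    )
    return TrussTable(frame, list(data.group_labels), "raw")


def fit_allometry(
    table: TrussTable,
    sl_variable: str = SL_VARIABLE,
    method: str = "pooled",
) -> AllometricModel:
    """Estimate the growth exponent b of every truss variable.

    b is the OLS slope of log10(M) on log10(SL). ``method='pooled'``
    regresses over all specimens pooled (the default reading of the
    Elliott adjustment); ``'pooled_within'`` centres each group first,
    giving a common within-group slope for sensitivity analysis.
    """
    if table.transform_state != "raw":
        raise ValueError("allometry must be fitted on the raw table")
    if sl_variable not in table.data.columns:
        raise ValueError(f"standard-length variable {sl_variable!r} not present")
    values = table.data.to_numpy()
    if (values <= 0).any():
        s, v = np.argwhere(values <= 0)[0]
        raise ValueError(
            f"nonpositive measurement: specimen {table.specimen_ids[s]}, "
            f"variable {table.variables[v]}"
        )
    L0 = table.data[sl_variable]
    x = np.log10(L0.to_numpy())
    Y = np.log10(values)
    if method == "pooled_within":
        labels = np.asarray(table.group_labels)
        for g in np.unique(labels):
            m = labels == g
            x[m] = x[m] - x[m].mean()
            Y[m] = Y[m] - Y[m].mean(axis=0)
    elif method != "pooled":
        raise ValueError(f"unknown method {method!r}")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        raise ValueError("zero variance in standard length; cannot fit allometry")
    slopes = xc @ (Y - Y.mean(axis=0)) / sxx
    return AllometricModel(
        b=pd.Series(slopes, index=table.data.columns, name="b"),
        L_S=float(L0.mean()),
        L_0=L0.copy(),
    )


def size_adjust(
    table: TrussTable,
    model: AllometricModel,
    sl_variable: str = SL_VARIABLE,
) -> TrussTable:
    """Apply the Elliott adjustment M * (L_S/L_0)**b and drop SL.

    Returns a table in state ``size_adjusted`` with one variable fewer
    (35 for the 9-landmark schema).
    """
    if table.transform_state != "raw":
        raise ValueError("size adjustment applies to the raw table")
    if not table.data.index.equals(model.L_0.index):
        raise ValueError("model and table were fitted on different specimens")
    ratio = model.L_S / model.L_0.to_numpy()[:, None]
    adjusted = table.data.to_numpy() * ratio ** model.b.to_numpy()[None, :]
    frame = pd.DataFrame(adjusted, index=table.data.index, columns=table.data.columns)
    frame = frame.drop(columns=[sl_variable])
    return TrussTable(frame, list(table.group_labels), "size_adjusted")


def log_transform(table: TrussTable) -> TrussTable:
    """Base-10 logarithm of every value (state ``log``)."""
    values = table.data.to_numpy()
    if (values <= 0).any():
        s, v = np.argwhere(values <= 0)[0]
        raise ValueError(
            f"nonpositive value: specimen {table.specimen_ids[s]}, "
            f"variable {table.variables[v]}"
        )
    return TrussTable(
        np.log10(table.data), list(table.group_labels), "log"
    )


#: recommended band for the specimens-to-variables ratio
NP_RATIO_BAND = (3.5, 8.0)


def anova_screen(table: TrussTable, alpha: float = 0.01) -> pd.DataFrame:
    """One-way fixed-effects ANOVA of every variable across groups.

    Returns a frame with columns F, p and keep (p < alpha), and attrs
    ``n_p_ratio`` (specimens divided by analysis variables) with the
    recommended 3.5-8 stability band flagged. The screen reports; it does
    not drop variables — the full variable set is retained for ordination
    unless the caller filters explicitly.
    """
    labels = np.asarray(table.group_labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("ANOVA screen needs >= 2 groups")
    if (counts < 2).any():
        small = dict(zip(uniq[counts < 2], counts[counts < 2]))
        raise ValueError(f"groups with < 2 specimens: {small}")
    F = np.empty(len(table.variables))
    p = np.empty(len(table.variables))
    for k, var in enumerate(table.variables):
        samples = [table.data[var].to_numpy()[labels == g] for g in uniq]
        F[k], p[k] = stats.f_oneway(*samples)
    out = pd.DataFrame(
        {"F": F, "p": p, "keep": p < alpha}, index=table.data.columns
    )
    ratio = table.n_specimens / len(table.variables)
    out.attrs["n_p_ratio"] = ratio
    out.attrs["n_p_band"] = NP_RATIO_BAND
    out.attrs["n_p_in_band"] = NP_RATIO_BAND[0] <= ratio <= NP_RATIO_BAND[1]
    return out
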