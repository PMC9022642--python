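"""Landmark dataset container shared by every analysis stage."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class LandmarkDataset:
    """Specimens x landmarks x 2 coordinates with group labels.

    Coordinates are Cartesian (y up) in millimetres after scale calibration.

    Parameters
    ----------
    specimen_ids
        Unique specimen identifiers, one per row of ``coords``.
    group_labels
        Group (population / sampling location) label per specimen.
    coords
        Array of shape ``(n_specimens, n_landmarks, 2)``.
    scale
        mm-per-unit calibration factor that was applied per specimen
        (kept for provenance; ``coords`` are already in mm).
    """

    specimen_ids: list[str]
    group_labels: list[str]
    coords: np.ndarray
    scale: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise ValueError(
                f"coords must have shape (n, k, 2), got {self.coords.shape}"
            )
        n = self.coords.shape[0]
        if len(self.specimen_ids) != n or len(self.group_labels) != n:
            raise ValueError("specimen_ids, group_labels and coords disagree on n")
        if len(set(self.specimen_ids)) != n:
            dupes = sorted(
                {s for s in self.specimen_ids if self.specimen_ids.count(s) > 1}
            )
            raise ValueError(f"duplicated specimen ids: {dupes}")
        if self.scale is None:
            self.scale = np.ones(n)
        self.scale = np.asarray(self.scale, dtype=float)
        self.specimen_ids = list(self.specimen_ids)
        self.group_labels = list(self.group_labels)

    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[1]

    @property
    def groups(self) -> list[str]:
        """Distinct group labels in order of first appearance."""
        seen: dict[str, None] = {}
        for g in self.group_labels:
            seen.setdefault(g, None)
        return list(seen)

    def group_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for g in self.group_labels:
            sizes[g] = sizes.get(g, 0) + 1
        return sizes

    def require_min_group_size(self, k: int) -> None:
        small = {g: n for g, n in self.group_sizes().items() if n < k}
        if small:
            raise ValueError(f"groups with fewer than {k} specimens: {small}")

    def subset(self, mask: np.ndarray) -> "LandmarkDataset":
        mask = np.asarray(mask, dtype=bool)
        return LandmarkDataset(
            [s for s, m in zip(self.specimen_ids, mask) if m],
            [g for g, m in zip(self.group_labels, mask) if m],
            self.coords[mask],
            self.scale[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide table: id, group, x1, y1, ..., xk, yk, scale."""
        k = self.n_landmarks
        cols: dict[str, object] = {
            "id": self.specimen_ids,
            "group": self.group_labels,
        }
        for j in range(k):
            cols[f"x{j + 1}"] = self.coords[:, j, 0]
            cols[f"y{j + 1}"] = self.coords[:, j, 1]
        cols["scale"] = self.scale
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "LandmarkDataset":
        k = 1
        while f"x{k + 1}" in frame.columns:
            k += 1
        coords = np.stack(
            [
                np.column_stack([frame[f"x{j + 1}"], frame[f"y{j + 1}"]])
                for j in range(k)
            ],
            axis=1,
        )
        scale = frame["scale"].to_numpy() if "scale" in frame.columns else None
        return cls(
            [str(s) for s in frame["id"]],
            [str(g) for g in frame["group"]],
            coords,
            scale,
        )
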