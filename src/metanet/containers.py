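"""Core in-memory containers shared across the pipeline.

The pipeline operates on region-by-time matrices sampled at a fixed
repetition time (TR), a region-to-network assignment, instantaneous
phase arrays, and small symmetric network-by-network "interaction"
matrices of metastability or synchrony.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RegionTimeSeries",
    "PhaseArray",
    "NetworkAssignment",
    "InteractionMatrix",
]


@dataclass
class RegionTimeSeries:
    """A frames x regions real-valued matrix with its sampling interval.

    Parameters
    ----------
    data
        Array of shape ``(n_frames, n_regions)``.
    tr_s
        Seconds per frame (repetition time).
    region_ids
        One identifier per column.
    """

    data: np.ndarray
    tr_s: float
    region_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (frames x regions)")
        if not self.region_ids:
            self.region_ids = [f"r{i:03d}" for i in range(self.data.shape[1])]
        if len(self.region_ids) != self.data.shape[1]:
            raise ValueError("region_ids length must match number of columns")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "RegionTimeSeries":
        """Copy of this series with new values (same TR and region ids)."""
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass
class PhaseArray:
    """Frames x regions instantaneous phases, wrapped to [-pi, pi)."""

    data: np.ndarray
    tr_s: float
    region_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (frames x regions)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("phases must be finite")
        if not self.region_ids:
            self.region_ids = [f"r{i:03d}" for i in range(self.data.shape[1])]

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


def wrap_phase(theta: np.ndarray) -> np.ndarray:
    """Wrap angles to the interval [-pi, pi)."""
    return np.mod(np.asarray(theta) + np.pi, 2.0 * np.pi) - np.pi


class NetworkAssignment:
    """Region -> network label lookup with a fixed label order.

    Every region belongs to exactly one of the (typically 14) labelled
    networks; one label may be a single region (e.g. the thalamus).
    """

    def __init__(
        self,
        mapping: Mapping[str, str] | pd.Series,
        label_order: Sequence[str] | None = None,
    ) -> None:
        if isinstance(mapping, pd.Series):
            mapping = mapping.to_dict()
        self.mapping: dict[str, str] = dict(mapping)
        if not self.mapping:
            raise ValueError("assignment must cover at least one region")
        if label_order is None:
            seen: list[str] = []
            for lab in self.mapping.values():
                if lab not in seen:
                    seen.append(lab)
            label_order = seen
        self.labels: list[str] = list(label_order)
        present = set(self.mapping.values())
        missing = [l for l in self.labels if l not in present]
        if missing:
            raise ValueError(f"empty network label(s): {missing}")
        extra = present - set(self.labels)
        if extra:
            raise ValueError(f"labels missing from label_order: {sorted(extra)}")

    @property
    def n_networks(self) -> int:
        return len(self.labels)

    def members(self, label: str) -> list[str]:
        """Region ids assigned to ``label``."""
        return [r for r, l in self.mapping.items() if l == label]

    def column_indices(self, region_ids: Sequence[str]) -> dict[str, np.ndarray]:
        """Map each network label to column indices within ``region_ids``."""
        unknown = [r for r in region_ids if r not in self.mapping]
        if unknown:
            raise KeyError(f"regions without network assignment: {unknown[:5]}")
        out: dict[str, list[int]] = {l: [] for l in self.labels}
        for i, r in enumerate(region_ids):
            out[self.mapping[r]].append(i)
        return {l: np.asarray(ix, dtype=int) for l, ix in out.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"region": list(self.mapping), "network": list(self.mapping.values())}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label_order=None) -> "NetworkAssignment":
        return cls(dict(zip(df["region"], df["network"])), label_order=label_order)


@dataclass
class InteractionMatrix:
    """Symmetric network x network matrix of metastability or synchrony.

    The diagonal holds the within-network value; entry (i, j) holds the
    value computed over the union of the regions of networks i and j.
    """

    values: np.ndarray
    kind: str  # "metastability" | "synchrony"
    labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        d = self.values.shape[0]
        if self.values.shape != (d, d):
            raise ValueError("interaction matrix must be square")
        if len(self.labels) != d:
            raise ValueError("label count must match matrix dimension")
        if self.kind not in ("metastability", "synchrony"):
            raise ValueError(f"unknown kind: {self.kind!r}")
        if not np.allclose(self.values, self.values.T, atol=1e-9, equal_nan=True):
            raise ValueError("interaction matrix must be symmetric")

    @property
    def n_networks(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)
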