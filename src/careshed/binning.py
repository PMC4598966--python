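"""Fixed-width binning of nearest-provider distances.

The distance-to-nearest-provider sample is summarised as counts per
half-open bin [k*w, (k+1)*w), with w = 50 m by default, matching the
convention of grouping participants into 50-m distance bands.  The binned
counts are the (x, y) data to which the trend curve is fitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .points import ValidationError

DEFAULT_BIN_WIDTH_M = 50.0


@dataclass(frozen=True)
class BinnedDistances:
    """Counts of participants per fixed-width nearest-distance bin.

    Bins are contiguous half-open intervals [k*w, (k+1)*w) starting at 0 and
    covering every observed distance.  ``counts[k]`` is the number of
    participants whose nearest-provider distance falls in bin k.
    """

    bin_width: float
    counts: np.ndarray

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValidationError(f"bin_width must be positive, got {self.bin_width}")
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 1:
            raise ValidationError("counts must be one-dimensional")
        if np.any(counts < 0):
            raise ValidationError("bin counts must be nonnegative")
        object.__setattr__(self, "counts", counts)

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def n_total(self) -> float:
        return float(self.counts.sum())

    @property
    def edges(self) -> np.ndarray:
        """Bin edges 0, w, 2w, ..., n_bins*w."""
        return np.arange(self.n_bins + 1) * self.bin_width

    @property
    def midpoints(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_width

    def to_frame(self) -> pd.DataFrame:
        e = self.edges
        return pd.DataFrame(
            {"bin_lo": e[:-1], "bin_hi": e[1:], "count": self.counts}
        )

    def to_csv(self, path: "str | Path") -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: "str | Path") -> "BinnedDistances":
        df = pd.read_csv(path)
        missing = {"bin_lo", "bin_hi", "count"} - set(df.columns)
        if missing:
            raise ValidationError(f"{path}: missing columns {sorted(missing)}")
        widths = (df["bin_hi"] - df["bin_lo"]).to_numpy(dtype=float)
        w = widths[0]
        if not (np.allclose(widths, w) and np.allclose(
                df["bin_lo"].to_numpy(dtype=float), np.arange(len(df)) * w)):
            raise ValidationError(f"{path}: bins must be contiguous, equal width, from 0")
        return cls(bin_width=float(w), counts=df["count"].to_numpy(dtype=float))


def bin_distances(distances, bin_width: float = DEFAULT_BIN_WIDTH_M) -> BinnedDistances:
    """Bin nonnegative distances (meters) into half-open [k*w, (k+1)*w) groups.

    ``distances`` may be an array, a mapping id -> distance, or the
    ``distance_m`` column of :func:`careshed.points.nearest_provider_distance`
    output.  Counts conserve the number of finite inputs.
    """
    if isinstance(distances, pd.DataFrame):
        d = distances["distance_m"].to_numpy(dtype=float)
    elif isinstance(distances, dict):
        d = np.fromiter(distances.values(), dtype=float)
    else:
        d = np.asarray(distances, dtype=float).ravel()
    if bin_width <= 0:
        raise ValidationError(f"bin_width must be positive, got {bin_width}")
    if np.any(d < 0):
        raise ValidationError("distances must be nonnegative")
    if len(d) == 0:
        return BinnedDistances(bin_width=bin_width, counts=np.zeros(1))
    k = np.floor(d / bin_width).astype(int)  # half-open: d = k*w lands in bin k
    return BinnedDistances(bin_width=bin_width, counts=np.bincount(k).astype(float))
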