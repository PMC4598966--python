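"""Buffer-ring provider choice and rural-urban disparity summaries.

Drawing a disk ("buffer ring") of radius R around every provider, the number
of disks covering a participant is the number of providers that participant
could choose within R.  R is taken from a region's own access indices (the
PWD or TLD buffer radius).  The resulting multiplicity table uses a two-level
percentage convention: the "no provider" and ">= 1 provider" rows are shares
of all participants, while the individual m = 1, 2, ... rows are shares of
the >= 1 subgroup.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .points import PointSet, ValidationError, distance_matrix

DEFAULT_MULTIPLICITY_CAP = 7


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of printed percentage tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def provider_multiplicity(
    participants: PointSet, providers: PointSet, radius_m: float
) -> pd.Series:
    """Number of providers within a closed ball of ``radius_m`` of each participant.

    Equals the number of provider buffer disks of that radius covering the
    participant.  Boundary inclusive: a provider at exactly ``radius_m``
    counts.
    """
    if radius_m <= 0:
        raise ValidationError(f"radius must be positive, got {radius_m}")
    d = distance_matrix(participants, providers)
    counts = (d <= radius_m).sum(axis=1)
    return pd.Series(counts, index=pd.Index(participants.ids, name="id"),
                     name="multiplicity")


@dataclass(frozen=True)
class ChoiceTable:
    """Participant counts by provider multiplicity within one buffer radius.

    ``counts`` maps multiplicity m (0, 1, ..., cap) to a participant count;
    multiplicities >= cap are pooled into the top bucket.  Percentages follow
    the two-level convention described in the module docstring and are
    reported rounded half-away-from-zero to two decimals.
    """

    radius_m: float
    cap: int
    counts: dict = field(default_factory=dict)  # multiplicity -> count

    @property
    def n_total(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def n_without(self) -> int:
        return int(self.counts.get(0, 0))

    @property
    def n_with_any(self) -> int:
        return self.n_total - self.n_without

    @property
    def pct_without(self) -> Optional[float]:
        if self.n_total == 0:
            return None
        return round_half_up(100.0 * self.n_without / self.n_total)

    @property
    def pct_with_any(self) -> Optional[float]:
        if self.n_total == 0:
            return None
        return round_half_up(100.0 * self.n_with_any / self.n_total)

    def pct_within_any(self) -> dict:
        """Shares of each m >= 1 row within the >= 1 subgroup (percent, 2 dp)."""
        sub = self.n_with_any
        if sub == 0:
            return {m: None for m in self.counts if m >= 1}
        return {m: round_half_up(100.0 * c / sub)
                for m, c in self.counts.items() if m >= 1}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        within = self.pct_within_any()
        for m in sorted(self.counts):
            label = f">={m}" if m == self.cap else str(m)
            rows.append({
                "multiplicity": label,
                "count": self.counts[m],
                "pct_total": (self.pct_without if m == 0
                              else (None if self.n_total == 0 else
                                    round_half_up(100.0 * self.counts[m] / self.n_total))),
                "pct_within_any": None if m == 0 else within.get(m),
            })
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "radius_m": self.radius_m,
            "cap": self.cap,
            "n_total": self.n_total,
            "counts": {str(m): int(c) for m, c in sorted(self.counts.items())},
            "pct_without": self.pct_without,
            "pct_with_any": self.pct_with_any,
            "pct_within_any": {str(m): v for m, v in sorted(self.pct_within_any().items())},
        }


def build_choice_table(
    multiplicities, radius_m: float = float("nan"),
    cap: int = DEFAULT_MULTIPLICITY_CAP,
) -> ChoiceTable:
    """Tally multiplicities into a ChoiceTable, pooling values >= cap.

    ``multiplicities`` may be a Series/array of per-participant provider
    counts or a precomputed mapping multiplicity -> participant count.
    An empty input yields a table with n_total 0 and undefined (None)
    percentages.
    """
    if cap < 1:
        raise ValidationError(f"cap must be >= 1, got {cap}")
    tally: dict[int, int] = {m: 0 for m in range(cap + 1)}
    if isinstance(multiplicities, Mapping):
        items = multiplicities.items()
    else:
        arr = np.asarray(multiplicities, dtype=int)
        vals, cnts = np.unique(arr, return_counts=True) if arr.size else ((), ())
        items = zip(vals, cnts)
    for m, c in items:
        m, c = int(m), int(c)
        if m < 0 or c < 0:
            raise ValidationError("multiplicities and counts must be nonnegative")
        tally[min(m, cap)] += c
    return ChoiceTable(radius_m=radius_m, cap=cap, counts=tally)


@dataclass(frozen=True)
class DensityRatio:
    """People-per-provider (and optionally people-per-km2) service density."""

    n_people: int
    n_providers: int
    people_per_provider: float
    population: Optional[int] = None
    area_km2: Optional[float] = None
    people_per_km2: Optional[float] = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def density_ratios(
    n_people: int,
    n_providers: int,
    population: Optional[int] = None,
    area_km2: Optional[float] = None,
) -> DensityRatio:
    """Service-density ratios: people/provider (1 dp) and people/km2 (2 dp)."""
    if n_providers <= 0:
        raise ValidationError("n_providers must be positive to form a ratio")
    ppp = round_half_up(n_people / n_providers, 1)
    ppk = None
    if population is not None and area_km2 is not None:
        if area_km2 <= 0:
            raise ValidationError("area_km2 must be positive to form a density")
        ppk = round_half_up(population / area_km2, 2)
    return DensityRatio(n_people=n_people, n_providers=n_providers,
                        people_per_provider=ppp, population=population,
                        area_km2=area_km2, people_per_km2=ppk)


def disparity_report(regions: dict) -> dict:
    """Side-by-side access comparison across regions (descriptive only).

    ``regions`` maps a region name to a dict with optional entries:
    ``indices`` (an InflectionIndices), ``tables`` (mapping label ->
    ChoiceTable), and ``density`` (a DensityRatio).  Emits detection flags,
    index bins, and the without/with-any percentages per region; no
    inferential claims are made.
    """
    out: dict = {"schema_version": 1, "regions": {}}
    for name, parts in regions.items():
        entry: dict = {}
        idx = parts.get("indices")
        if idx is not None:
            entry["pwd_detected"] = idx.pwd is not None
            entry["tld_detected"] = idx.tld is not None
            entry["indices"] = idx.to_dict()
        tables = parts.get("tables") or {}
        entry["tables"] = {}
        for label, tab in tables.items():
            if tab is None:
                entry["tables"][label] = {"skipped": True,
                                          "reason": "index undetected for this region"}
            else:
                entry["tables"][label] = tab.to_dict()
        dens = parts.get("density")
        if dens is not None:
            entry["density"] = dens.to_dict()
        out["regions"][name] = entry
    return out
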