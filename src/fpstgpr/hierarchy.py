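"""Location hierarchy: location -> region -> super-region, plus populations."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import AGE_GROUPS


@dataclass
class LocationHierarchy:
    """Three-level nesting of locations into regions and super-regions.

    ``table`` has one row per location with columns ``location_id``,
    ``region_id``, ``super_region_id``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"location_id", "region_id", "super_region_id"}
        missing = required.difference(self.table.columns)
        if missing:
            raise ValueError(f"hierarchy table missing columns: {sorted(missing)}")
        if self.table["location_id"].duplicated().any():
            raise ValueError("each location must appear exactly once in the hierarchy")
        self.table = self.table.reset_index(drop=True)

    @classmethod
    def balanced(
        cls, n_super_regions: int = 2, n_regions_per_super: int = 2, n_locations_per_region: int = 5
    ) -> "LocationHierarchy":
        rows = []
        loc = 0
        for sr in range(n_super_regions):
            for r in range(n_regions_per_super):
                region = sr * n_regions_per_super + r
                for _ in range(n_locations_per_region):
                    rows.append(
                        {
                            "location_id": f"L{loc:03d}",
                            "region_id": f"R{region:02d}",
                            "super_region_id": f"SR{sr:01d}",
                        }
                    )
                    loc += 1
        return cls(pd.DataFrame(rows))

    @property
    def locations(self) -> list[str]:
        return self.table["location_id"].tolist()

    @property
    def regions(self) -> list[str]:
        return sorted(self.table["region_id"].unique())

    @property
    def super_regions(self) -> list[str]:
        return sorted(self.table["super_region_id"].unique())

    def region_of(self, location_id: str) -> str:
        return self._lookup(location_id, "region_id")

    def super_region_of(self, location_id: str) -> str:
        return self._lookup(location_id, "super_region_id")

    def _lookup(self, location_id: str, col: str) -> str:
        m = self.table.loc[self.table["location_id"] == location_id, col]
        if m.empty:
            raise KeyError(f"unknown location: {location_id}")
        return m.iloc[0]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LocationHierarchy":
        return cls(pd.read_csv(path))


def global_age_weights(population: pd.DataFrame, year: int = 2019) -> pd.Series:
    """Relative global population size of each age group in a reference year.

    These are the fixed weights used for age standardization.
    """
    sub = population[population["year"] == year]
    if sub.empty:
        raise ValueError(f"population table has no rows for year {year}")
    totals = sub.groupby("age_group")["population"].sum()
    totals = totals.reindex(list(AGE_GROUPS))
    if totals.isna().any():
        raise ValueError("population table missing age groups for the reference year")
    return totals / totals.sum()


def generate_population(
    hierarchy: LocationHierarchy,
    years,
    seed: int,
    equal: bool = False,
) -> pd.DataFrame:
    """Synthetic women-of-reproductive-age counts by location-year-age.

    Each location gets a lognormal base size, a mildly declining age
    pyramid (perturbed per location), and ~1% annual growth. With
    ``equal=True`` every cell holds the same count, forcing uniform age
    weights (1/7) — useful for symmetry checks.
    """
    rng = np.random.default_rng(seed)
    years = list(years)
    locs = hierarchy.locations
    n_loc, n_age = len(locs), len(AGE_GROUPS)
    if equal:
        counts = np.full((n_loc, len(years), n_age), 100_000.0)
    else:
        base = rng.lognormal(mean=12.0, sigma=0.8, size=n_loc)
        pyramid = np.linspace(1.3, 0.7, n_age)
        pyramid = pyramid * rng.lognormal(0.0, 0.05, size=(n_loc, n_age))
        growth = 1.01 ** (np.array(years) - years[0])
        counts = base[:, None, None] * growth[None, :, None] * pyramid[:, None, :]
    idx = pd.MultiIndex.from_product(
        [locs, years, list(AGE_GROUPS)], names=["location_id", "year", "age_group"]
    )
    out = pd.DataFrame({"population": counts.reshape(-1)}, index=idx).reset_index()
    return out
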