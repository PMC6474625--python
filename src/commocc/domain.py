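"""Core data structures for multi-region camera-trap detection data.

A camera-trap survey of a mammal metacommunity is organised on three
nested scales: *sites* (individual camera stations, each operated for a
known number of trap-days), *regions* (arrays of sites whose detected
species form one community), and the *landscape* holding all regions.
The detection data are stored per region as an integer matrix
``y[k, i]`` counting, for species ``k`` at site ``i``, the number of
daily occasions on which the species was photographed.

The hierarchical model consumes an *augmented* version of these data in
which each region's species list is padded to a common pool size ``M``
with all-zero detection histories, so that the number of community
members that escaped detection can be estimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Site",
    "SpeciesRecord",
    "DetectionData",
    "AugmentedCommunity",
    "CovariateSpec",
    "build_detection_data",
    "augment",
    "standardize_covariates",
    "read_sites_csv",
    "read_detections_csv",
    "read_traits_csv",
    "write_sites_csv",
    "write_detections_csv",
    "write_traits_csv",
    "detections_to_records",
]

#: covariates retained for the occupancy/detection regressions
DEFAULT_COVARIATES = ("dSettl", "dRiv", "forCover")


@dataclass(frozen=True)
class Site:
    """A single camera-trap station.

    Parameters
    ----------
    site_id : str
        Unique identifier within the landscape.
    region_id : str
        Region (survey area) the site belongs to.
    effort : int
        Number of trap-days (daily sampling occasions), ``>= 1``.
    covariates : dict
        Mapping covariate name -> raw value (e.g. distances in metres,
        cover as a fraction).
    """

    site_id: str
    region_id: str
    effort: int
    covariates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if int(self.effort) < 1:
            raise ValueError(
                f"site {self.site_id!r}: effort must be >= 1, got {self.effort}"
            )
        for name, value in self.covariates.items():
            if not np.isfinite(value):
                raise ValueError(
                    f"site {self.site_id!r}: covariate {name!r} is not finite"
                )


@dataclass(frozen=True)
class SpeciesRecord:
    """A species trait record (body mass in kilograms)."""

    species_id: str
    mass_kg: float

    def __post_init__(self) -> None:
        if not (self.mass_kg > 0):
            raise ValueError(
                f"species {self.species_id!r}: mass_kg must be > 0, got {self.mass_kg}"
            )


@dataclass
class DetectionData:
    """Detection counts for every region, species and site.

    Attributes
    ----------
    regions : list of str
        Ordered region identifiers.
    sites_by_region : dict
        region -> ordered list of :class:`Site`.
    species_by_region : dict
        region -> ordered list of species ids detected in that region
        (length ``n_r``; every listed species has at least one
        detection in the region).
    y : dict
        region -> integer array of shape ``(n_r, S_r)`` with detection
        counts per species and site.
    """

    regions: list[str]
    sites_by_region: dict[str, list[Site]]
    species_by_region: dict[str, list[str]]
    y: dict[str, np.ndarray]

    def n_species(self, region: str) -> int:
        return len(self.species_by_region[region])

    @property
    def n_obs(self) -> dict[str, int]:
        return {r: len(s) for r, s in self.species_by_region.items()}

    @property
    def all_species(self) -> list[str]:
        """Distinct species across the landscape, in first-seen order."""
        seen: dict[str, None] = {}
        for r in self.regions:
            for sp in self.species_by_region[r]:
                seen.setdefault(sp)
        return list(seen)

    def effort(self, region: str) -> np.ndarray:
        return np.array([s.effort for s in self.sites_by_region[region]], dtype=int)

    def validate(self) -> None:
        for r in self.regions:
            y = self.y[r]
            eff = self.effort(r)
            if y.shape != (len(self.species_by_region[r]), len(eff)):
                raise ValueError(f"region {r!r}: y shape {y.shape} inconsistent")
            if (y < 0).any():
                raise ValueError(f"region {r!r}: negative detection counts")
            if (y > eff[None, :]).any():
                raise ValueError(f"region {r!r}: detection count exceeds effort")
            if (y.sum(axis=1) == 0).any():
                raise ValueError(
                    f"region {r!r}: species with all-zero history in detected list"
                )


@dataclass
class AugmentedCommunity:
    """Detection data padded to ``M`` species slots per region.

    Slots ``1..n_r`` hold the detected species (``observed_mask``
    true); slots ``n_r+1..M`` carry all-zero detection histories and
    stand for community members that may have escaped detection.
    """

    detection: DetectionData
    M: int
    observed_mask: np.ndarray  # bool (R, M)

    @property
    def regions(self) -> list[str]:
        return self.detection.regions

    def y_padded(self, region: str) -> np.ndarray:
        """(M, S_r) count array with all-zero rows for augmented slots."""
        y = self.detection.y[region]
        n_r, s_r = y.shape
        out = np.zeros((self.M, s_r), dtype=int)
        out[:n_r] = y
        return out


@dataclass
class CovariateSpec:
    """Centering/scaling transform applied to the site covariates.

    Stores, for each covariate, the landscape-pooled mean and SD so the
    standardization is reproducible and invertible.
    """

    names: list[str]
    means: dict[str, float]
    sds: dict[str, float]

    def transform(self, name: str, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.means[name]) / self.sds[name]

    def inverse(self, name: str, standardized: np.ndarray) -> np.ndarray:
        return np.asarray(standardized, dtype=float) * self.sds[name] + self.means[name]


def build_detection_data(
    records: pd.DataFrame, sites: Sequence[Site]
) -> DetectionData:
    """Assemble the per-region detection arrays from a long-format table.

    Parameters
    ----------
    records : DataFrame
        Columns ``region``, ``site``, ``species``, ``count`` — one row
        per (region, site, species) with the number of occasions on
        which the species was detected there. Zero-count rows are
        allowed and ignored for species-list membership.
    sites : sequence of Site
        All surveyed sites (defines regions, site order and effort).

    Species are ordered within each region by first appearance in the
    table (ties broken lexicographically when counts tie on the same
    row order); regions and sites keep the order of ``sites``.
    """
    required = {"region", "site", "species", "count"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records table missing columns: {sorted(missing)}")
    if len(records) == 0:
        raise ValueError("no detections in record table")

    site_index: dict[tuple[str, str], Site] = {}
    regions: list[str] = []
    sites_by_region: dict[str, list[Site]] = {}
    for s in sites:
        if s.region_id not in sites_by_region:
            regions.append(s.region_id)
            sites_by_region[s.region_id] = []
        sites_by_region[s.region_id].append(s)
        site_index[(s.region_id, s.site_id)] = s

    pos_in_region = {
        (r, s.site_id): j for r in regions for j, s in enumerate(sites_by_region[r])
    }

    dup = records.duplicated(subset=["region", "site", "species"])
    if dup.any():
        row = records[dup].iloc[0]
        raise ValueError(
            "duplicate record for "
            f"(region={row['region']!r}, site={row['site']!r}, species={row['species']!r})"
        )

    species_by_region: dict[str, list[str]] = {r: [] for r in regions}
    cells: list[tuple[str, int, str, int]] = []
    for row in records.itertuples(index=False):
        region, site_id, species = str(row.region), str(row.site), str(row.species)
        count = int(row.count)
        key = (region, site_id)
        if key not in site_index:
            raise ValueError(
                f"record references unknown site (region={region!r}, site={site_id!r})"
            )
        if count < 0:
            raise ValueError(
                f"negative count for (region={region!r}, site={site_id!r}, "
                f"species={species!r})"
            )
        if count > site_index[key].effort:
            raise ValueError(
                f"count {count} exceeds effort {site_index[key].effort} at "
                f"(region={region!r}, site={site_id!r}, species={species!r})"
            )
        if count > 0 and species not in species_by_region[region]:
            species_by_region[region].append(species)
        cells.append((region, pos_in_region[key], species, count))

    if not any(species_by_region.values()):
        raise ValueError("no detections in record table")

    y: dict[str, np.ndarray] = {}
    for r in regions:
        sp_pos = {sp: k for k, sp in enumerate(species_by_region[r])}
        arr = np.zeros((len(sp_pos), len(sites_by_region[r])), dtype=int)
        for region, j, species, count in cells:
            if region == r and species in sp_pos:
                arr[sp_pos[species], j] = count
        y[r] = arr

    data = DetectionData(
        regions=regions,
        sites_by_region=sites_by_region,
        species_by_region=species_by_region,
        y=y,
    )
    data.validate()
    return data


def augment(data: DetectionData, M: int) -> AugmentedCommunity:
    """Pad each region's species list to ``M`` slots with all-zero histories."""
    n_max = max(data.n_species(r) for r in data.regions)
    if M <= n_max:
        raise ValueError(
            f"augmentation pool M={M} must exceed the largest detected richness {n_max}"
        )
    mask = np.zeros((len(data.regions), M), dtype=bool)
    for ri, r in enumerate(data.regions):
        mask[ri, : data.n_species(r)] = True
    return AugmentedCommunity(detection=data, M=int(M), observed_mask=mask)


def standardize_covariates(
    sites: Sequence[Site], names: Sequence[str] = DEFAULT_COVARIATES
) -> tuple[dict[str, np.ndarray], CovariateSpec]:
    """Center and scale covariates pooled across the whole landscape.

    Uses the population-SD convention (ddof=0). Returns per-region
    design arrays of shape ``(S_r, len(names))`` keyed by region, plus
    the :class:`CovariateSpec` recording the transform.
    """
    for s in sites:
        for name in names:
            if name not in s.covariates:
                raise ValueError(f"site {s.site_id!r} missing covariate {name!r}")
    raw = {
        name: np.array([s.covariates[name] for s in sites], dtype=float)
        for name in names
    }
    means, sds = {}, {}
    for name, v in raw.items():
        sd = float(v.std(ddof=0))
        if sd == 0.0:
            raise ValueError(f"covariate {name!r} has zero variance")
        means[name] = float(v.mean())
        sds[name] = sd
    spec = CovariateSpec(names=list(names), means=means, sds=sds)

    regions: list[str] = []
    for s in sites:
        if s.region_id not in regions:
            regions.append(s.region_id)
    design: dict[str, np.ndarray] = {}
    for r in regions:
        rs = [s for s in sites if s.region_id == r]
        design[r] = np.column_stack(
            [
                spec.transform(name, np.array([s.covariates[name] for s in rs]))
                for name in names
            ]
        )
    return design, spec


# ---------------------------------------------------------------------------
# delimited-text interchange

def read_sites_csv(path: str | Path) -> list[Site]:
    df = pd.read_csv(path)
    required = {"site", "region", "effort"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sites file missing columns: {sorted(missing)}")
    cov_cols = [c for c in df.columns if c not in required]
    return [
        Site(
            site_id=str(row["site"]),
            region_id=str(row["region"]),
            effort=int(row["effort"]),
            covariates={c: float(row[c]) for c in cov_cols},
        )
        for _, row in df.iterrows()
    ]


def read_detections_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"region", "site", "species", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"detections file missing columns: {sorted(missing)}")
    return df


def read_traits_csv(path: str | Path) -> list[SpeciesRecord]:
    df = pd.read_csv(path)
    missing = {"species", "mass_kg"} - set(df.columns)
    if missing:
        raise ValueError(f"traits file missing columns: {sorted(missing)}")
    return [
        SpeciesRecord(species_id=str(row["species"]), mass_kg=float(row["mass_kg"]))
        for _, row in df.iterrows()
    ]


def write_sites_csv(sites: Sequence[Site], path: str | Path) -> None:
    cov_names: list[str] = []
    for s in sites:
        for name in s.covariates:
            if name not in cov_names:
                cov_names.append(name)
    rows = [
        {
            "site": s.site_id,
            "region": s.region_id,
            "effort": s.effort,
            **{c: s.covariates.get(c, np.nan) for c in cov_names},
        }
        for s in sites
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def detections_to_records(data: DetectionData) -> pd.DataFrame:
    """Flatten DetectionData back to the long-format record table."""
    rows = []
    for r in data.regions:
        sites = data.sites_by_region[r]
        for k, sp in enumerate(data.species_by_region[r]):
            for j, s in enumerate(sites):
                c = int(data.y[r][k, j])
                if c > 0:
                    rows.append(
                        {"region": r, "site": s.site_id, "species": sp, "count": c}
                    )
    return pd.DataFrame(rows, columns=["region", "site", "species", "count"])


def write_detections_csv(data: DetectionData, path: str | Path) -> None:
    detections_to_records(data).to_csv(path, index=False)


def write_traits_csv(traits: Sequence[SpeciesRecord], path: str | Path) -> None:
    pd.DataFrame(
        [{"species": t.species_id, "mass_kg": t.mass_kg} for t in traits]
    ).to_csv(path, index=False)
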