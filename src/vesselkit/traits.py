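"""Early-wood vessel traits computed per tree ring.

Eight traits are derived from the vessels measured inside a ring's area of
interest (aoi):

====== =========================================================== ==============
Symbol Definition                                                  Unit
====== =========================================================== ==============
LA     mean vessel lumen area                                      µm²
VFrac  total vessel lumen area / aoi                               µm² µm⁻²
VFreq  number of vessels / aoi                                     n mm⁻²
HWD    hydraulically weighted diameter, ΣD⁵/ΣD⁴                    µm
THC    theoretical hydraulic conductivity, πρΣD⁴/(128·η·aoi)       kg m⁻¹ MPa⁻¹ s⁻¹
VI     vulnerability index, mean D / VFreq                         —
GI     grouping index, n vessels / n groups (solitary = group)     —
SVI    solitary vessel index, n solitary / n vessels               —
====== =========================================================== ==============

D is the single-vessel diameter obtained from the lumen area assuming a round
vessel.  Vessels smaller than a resolution-driven cutoff (default 5000 µm²)
are excluded before any trait is computed, and group memberships are
recomputed on the retained vessels: a two-vessel cluster that loses one
member leaves a solitary vessel.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_MIN_AREA",
    "WaterProperties",
    "VesselRecord",
    "RingAnatomy",
    "TraitRecord",
    "TRAIT_NAMES",
    "filter_vessels",
    "diameter_from_area",
    "hydraulically_weighted_diameter",
    "theoretical_conductivity",
    "vulnerability_index",
    "grouping_indices",
    "compute_ring_traits",
    "combine_cores",
    "compute_trait_table",
    "rings_from_frame",
    "EmptyRingError",
]

logger = logging.getLogger(__name__)

#: Exclusion threshold below which measured lumina cannot be told apart from
#: latewood vessels or other wood structures at typical imaging resolution.
DEFAULT_MIN_AREA = 5000.0

TRAIT_NAMES = ("LA", "VFrac", "VFreq", "HWD", "THC", "VI", "GI", "SVI")


class EmptyRingError(ValueError):
    """Raised when no vessel of a ring survives the exclusion filter."""


@dataclass(frozen=True)
class WaterProperties:
    """Physical properties of water at 20 °C used by the Hagen-Poiseuille term.

    eta is kept in MPa·s so that conductivity lands directly in
    kg m⁻¹ MPa⁻¹ s⁻¹, the unit conventionally printed for xylem.
    """

    eta: float = 1.002e-9  # dynamic viscosity, MPa s
    rho: float = 998.2  # density, kg m⁻³

    def __post_init__(self) -> None:
        if self.eta <= 0 or self.rho <= 0:
            raise ValueError("water properties must be strictly positive")


@dataclass(frozen=True)
class VesselRecord:
    """One measured early-wood vessel."""

    tree_id: str
    site_type: str
    core_id: str
    ring_year: int
    lumen_area: float  # µm²
    group_id: str

    def __post_init__(self) -> None:
        if self.lumen_area <= 0:
            raise ValueError(f"lumen_area must be positive, got {self.lumen_area}")


@dataclass
class RingAnatomy:
    """All vessels of one tree-core-ring plus the analysed early-wood area."""

    tree_id: str
    site_type: str
    core_id: str
    ring_year: int
    aoi: float  # mm²
    vessels: list[VesselRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.aoi <= 0:
            raise ValueError(f"aoi must be positive, got {self.aoi}")
        for v in self.vessels:
            if (v.tree_id, v.core_id, v.ring_year) != (
                self.tree_id,
                self.core_id,
                self.ring_year,
            ):
                raise ValueError(
                    "vessel identifiers do not match the ring: "
                    f"{(v.tree_id, v.core_id, v.ring_year)}"
                )


@dataclass(frozen=True)
class TraitRecord:
    """The eight derived vessel traits of one ring at core or combined level."""

    tree_id: str
    site_type: str
    ring_year: int
    level: str  # "core" | "combined"
    core_id: str | None
    la_mean: float
    vfrac: float
    vfreq: float
    hwd: float
    thc: float
    vi: float
    gi: float
    svi: float
    n_vessels: int

    def trait(self, name: str) -> float:
        """Return a trait value by its field symbol (e.g. ``"LA"``)."""
        return getattr(self, _TRAIT_FIELDS[name])


_TRAIT_FIELDS = {
    "LA": "la_mean",
    "VFrac": "vfrac",
    "VFreq": "vfreq",
    "HWD": "hwd",
    "THC": "thc",
    "VI": "vi",
    "GI": "gi",
    "SVI": "svi",
}


# ---------------------------------------------------------------------------
# elementary operations


def filter_vessels(
    vessels: Iterable[VesselRecord], min_area: float = DEFAULT_MIN_AREA
) -> list[VesselRecord]:
    """Drop vessels with lumen area below ``min_area`` (boundary retained).

    Group ids are preserved; membership counts implied by the retained set are
    what the grouping indices see, so a depleted pair automatically becomes a
    solitary vessel. Order is preserved. An empty result is allowed.
    """
    if min_area < 0:
        raise ValueError("min_area must be non-negative")
    return [v for v in vessels if v.lumen_area >= min_area]


def diameter_from_area(lumen_area: float | np.ndarray) -> float | np.ndarray:
    """Diameter (µm) of a round vessel with the given lumen area (µm²)."""
    arr = np.asarray(lumen_area, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("lumen_area must be positive")
    out = 2.0 * np.sqrt(arr / math.pi)
    return float(out) if np.isscalar(lumen_area) or arr.ndim == 0 else out


def hydraulically_weighted_diameter(diameters: Sequence[float]) -> float:
    """ΣD⁵ / ΣD⁴ — the diameter class dominating hydraulic conductance."""
    d = np.asarray(diameters, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one diameter")
    if np.any(d <= 0):
        raise ValueError("diameters must be positive")
    d4 = d**4
    return float((d4 * d).sum() / d4.sum())


def theoretical_conductivity(
    diameters: Sequence[float],
    aoi: float,
    water: WaterProperties | None = None,
) -> float:
    """Hagen-Poiseuille conductivity of the ring per analysed xylem area.

    Parameters
    ----------
    diameters : vessel diameters in µm (may be empty → 0).
    aoi : analysed area in mm².
    water : viscosity/density constants; defaults to water at 20 °C.

    Returns conductivity in kg m⁻¹ MPa⁻¹ s⁻¹.  Diameters and aoi are converted
    to SI (m, m²) internally; viscosity stays in MPa·s so no further scaling
    is needed.
    """
    if aoi <= 0:
        raise ValueError("aoi must be positive")
    water = water or WaterProperties()
    d = np.asarray(diameters, dtype=float)
    if d.size == 0:
        return 0.0
    d_m = d * 1e-6
    aoi_m2 = aoi * 1e-6
    return float(math.pi * water.rho * (d_m**4).sum() / (128.0 * water.eta * aoi_m2))


def vulnerability_index(mean_diameter: float, vfreq: float) -> float:
    """Carlquist vulnerability index: mean diameter (µm) over VFreq (mm⁻²).

    By convention the raw units are divided without normalisation; larger
    values indicate theoretically more cavitation-prone xylem.
    """
    if vfreq <= 0:
        raise ValueError("vfreq must be positive")
    return mean_diameter / vfreq


def grouping_indices(vessels: Sequence[VesselRecord]) -> tuple[float, float]:
    """Grouping index and solitary vessel index of a vessel population.

    GI = n vessels / n groups, where every solitary vessel counts as its own
    group; SVI = n solitary vessels / n vessels.  Group sizes are taken from
    the population passed in (i.e. after any filtering).
    """
    if len(vessels) == 0:
        raise ValueError("need at least one vessel")
    sizes: dict[str, int] = {}
    for v in vessels:
        sizes[v.group_id] = sizes.get(v.group_id, 0) + 1
    n = len(vessels)
    n_groups = len(sizes)
    n_solitary = sum(1 for c in sizes.values() if c == 1)
    return n / n_groups, n_solitary / n


# ---------------------------------------------------------------------------
# ring-level aggregation


def compute_ring_traits(
    ring: RingAnatomy,
    min_area: float = DEFAULT_MIN_AREA,
    water: WaterProperties | None = None,
    level: str = "core",
) -> TraitRecord:
    """Compute all eight traits of one ring after the exclusion filter.

    Raises
    ------
    EmptyRingError
        If no vessel survives the filter; callers typically skip the ring and
        log a warning.
    """
    kept = filter_vessels(ring.vessels, min_area)
    if not kept:
        raise EmptyRingError(
            f"ring {ring.tree_id}/{ring.core_id}/{ring.ring_year}: "
            f"no vessel ≥ {min_area} µm²"
        )
    areas = np.array([v.lumen_area for v in kept])
    d = diameter_from_area(areas)
    n = areas.size
    la = float(areas.mean())
    vfreq = n / ring.aoi  # n mm⁻²
    vfrac = float(areas.sum()) / (ring.aoi * 1e6)  # aoi mm² → µm²
    hwd = hydraulically_weighted_diameter(d)
    thc = theoretical_conductivity(d, ring.aoi, water)
    vi = vulnerability_index(float(np.mean(d)), vfreq)
    gi, svi = grouping_indices(kept)
    return TraitRecord(
        tree_id=ring.tree_id,
        site_type=ring.site_type,
        ring_year=ring.ring_year,
        level=level,
        core_id=ring.core_id if level == "core" else None,
        la_mean=la,
        vfrac=vfrac,
        vfreq=vfreq,
        hwd=hwd,
        thc=thc,
        vi=vi,
        gi=gi,
        svi=svi,
        n_vessels=int(n),
    )


def combine_cores(
    rings: Sequence[RingAnatomy],
    min_area: float = DEFAULT_MIN_AREA,
    water: WaterProperties | None = None,
    method: str = "pool",
) -> TraitRecord:
    """Combine the A and B cores of one tree-ring into one trait record.

    ``method="pool"`` (default) pools the vessels of both cores and sums their
    aoi before computing the traits — the only convention under which the
    VFrac ≡ VFreq·LA·10⁻⁶ identity stays exact.  ``method="mean"`` averages
    the core-level trait values instead.  With a single core the combined
    record equals that core's values.
    """
    if not rings:
        raise ValueError("need at least one ring")
    tree_ids = {r.tree_id for r in rings}
    years = {r.ring_year for r in rings}
    if len(tree_ids) != 1 or len(years) != 1 or len(rings) > 2:
        raise ValueError("cores to combine must share tree_id and ring_year (1-2 cores)")
    if method == "pool":
        pooled = RingAnatomy(
            tree_id=rings[0].tree_id,
            site_type=rings[0].site_type,
            core_id=rings[0].core_id,  # placeholder, dropped at combined level
            ring_year=rings[0].ring_year,
            aoi=sum(r.aoi for r in rings),
            vessels=[
                # namespace group ids by core so clusters never merge across cores
                replace(
                    v,
                    core_id=rings[0].core_id,
                    group_id=f"{r.core_id}:{v.group_id}",
                )
                for r in rings
                for v in r.vessels
            ],
        )
        return compute_ring_traits(pooled, min_area, water, level="combined")
    if method == "mean":
        recs = [compute_ring_traits(r, min_area, water) for r in rings]
        mean = lambda f: float(np.mean([getattr(r, f) for r in recs]))
        return TraitRecord(
            tree_id=rings[0].tree_id,
            site_type=rings[0].site_type,
            ring_year=rings[0].ring_year,
            level="combined",
            core_id=None,
            la_mean=mean("la_mean"),
            vfrac=mean("vfrac"),
            vfreq=mean("vfreq"),
            hwd=mean("hwd"),
            thc=mean("thc"),
            vi=mean("vi"),
            gi=mean("gi"),
            svi=mean("svi"),
            n_vessels=sum(r.n_vessels for r in recs),
        )
    raise ValueError(f"unknown combine method {method!r}")


# ---------------------------------------------------------------------------
# table-level API


VESSEL_COLUMNS = [
    "tree_id",
    "site_type",
    "core_id",
    "ring_year",
    "aoi_mm2",
    "vessel_id",
    "lumen_area_um2",
    "group_id",
]


def rings_from_frame(vessels: pd.DataFrame) -> list[RingAnatomy]:
    """Group a vessel table (one row per vessel) into RingAnatomy objects.

    Expects the columns of ``VESSEL_COLUMNS`` (``vessel_id`` optional); the
    aoi is repeated on every row of a ring and must be constant within it.
    """
    missing = {"tree_id", "site_type", "core_id", "ring_year", "aoi_mm2",
               "lumen_area_um2", "group_id"} - set(vessels.columns)
    if missing:
        raise ValueError(f"vessel table is missing columns: {sorted(missing)}")
    rings = []
    keys = ["tree_id", "site_type", "core_id", "ring_year"]
    for (tree, site, core, year), sub in vessels.groupby(keys, sort=True):
        aoi = sub["aoi_mm2"].unique()
        if len(aoi) != 1:
            raise ValueError(f"aoi not constant within ring {(tree, core, year)}")
        recs = [
            VesselRecord(
                tree_id=str(tree),
                site_type=str(site),
                core_id=str(core),
                ring_year=int(year),
                lumen_area=float(a),
                group_id=str(g),
            )
            for a, g in zip(sub["lumen_area_um2"], sub["group_id"])
        ]
        rings.append(
            RingAnatomy(str(tree), str(site), str(core), int(year), float(aoi[0]), recs)
        )
    return rings


def _traits_by_keys(
    kept: pd.DataFrame,
    keys: list[str],
    aoi: pd.Series,
    water: WaterProperties,
) -> pd.DataFrame:
    """Vectorised per-ring trait computation for pre-filtered vessel rows."""
    d = 2.0 * np.sqrt(kept["lumen_area_um2"].to_numpy() / math.pi)
    work = kept[keys].copy()
    work["area"] = kept["lumen_area_um2"].to_numpy()
    work["d"] = d
    work["d4"] = d**4
    work["d5"] = d**5
    agg = work.groupby(keys, sort=True).agg(
        n_vessels=("area", "size"),
        area_sum=("area", "sum"),
        la=("area", "mean"),
        d_mean=("d", "mean"),
        d4_sum=("d4", "sum"),
        d5_sum=("d5", "sum"),
    )
    # group ids are namespaced by core so that pooling cores at the combined
    # level never merges clusters from different cores
    work["group_key"] = (
        kept["core_id"].astype(str) + ":" + kept["group_id"].astype(str)
    ).to_numpy()
    gsizes = work.groupby(keys + ["group_key"], sort=False).size()
    grp = gsizes.groupby(level=list(range(len(keys)))).agg(["size", lambda s: int((s == 1).sum())])
    grp.columns = ["n_groups", "n_solitary"]
    agg = agg.join(grp)
    agg = agg.join(aoi.rename("aoi"))
    out = pd.DataFrame(index=agg.index)
    out["LA"] = agg["la"]
    out["VFrac"] = agg["area_sum"] / (agg["aoi"] * 1e6)
    out["VFreq"] = agg["n_vessels"] / agg["aoi"]
    out["HWD"] = agg["d5_sum"] / agg["d4_sum"]
    water = water or WaterProperties()
    out["THC"] = (
        math.pi * water.rho * (agg["d4_sum"] * 1e-24) / (128.0 * water.eta * agg["aoi"] * 1e-6)
    )
    out["VI"] = agg["d_mean"] / out["VFreq"]
    out["GI"] = agg["n_vessels"] / agg["n_groups"]
    out["SVI"] = agg["n_solitary"] / agg["n_vessels"]
    out["n_vessels"] = agg["n_vessels"]
    return out.reset_index()


def compute_trait_table(
    vessels: pd.DataFrame,
    min_area: float = DEFAULT_MIN_AREA,
    water: WaterProperties | None = None,
    combine: str = "pool",
) -> pd.DataFrame:
    """Compute core-level and combined-level trait records for a vessel table.

    Returns a long table with one row per (tree, [core,] ring_year) × level;
    rings whose vessels are all filtered out are skipped with a warning.  A
    core whose ring is skipped contributes neither vessels nor aoi to the
    combined level.  ``combine="mean"`` averages core-level trait values
    instead of pooling vessels.
    """
    water = water or WaterProperties()
    missing = {"tree_id", "site_type", "core_id", "ring_year", "aoi_mm2",
               "lumen_area_um2", "group_id"} - set(vessels.columns)
    if missing:
        raise ValueError(f"vessel table is missing columns: {sorted(missing)}")
    core_keys = ["tree_id", "site_type", "core_id", "ring_year"]
    ring_aoi = vessels.groupby(core_keys)["aoi_mm2"].agg(["min", "max"])
    if (ring_aoi["min"] != ring_aoi["max"]).any():
        raise ValueError("aoi not constant within a ring")
    kept = vessels[vessels["lumen_area_um2"] >= min_area]
    # distinguish filtered groups from truly distinct ones per ring
    skipped = len(ring_aoi) - kept.groupby(core_keys).ngroups
    if skipped:
        logger.warning(
            "skipped %d rings with no vessel >= %.0f um^2", skipped, min_area
        )
    if kept.empty:
        raise EmptyRingError("no vessel survives the filter in any ring")

    core = _traits_by_keys(kept, core_keys, ring_aoi["min"], water)
    core["level"] = "core"

    if combine == "pool":
        comb_keys = ["tree_id", "site_type", "ring_year"]
        surviving = kept[core_keys].drop_duplicates().merge(
            ring_aoi["min"].rename("aoi_mm2").reset_index(), on=core_keys
        )
        comb_aoi = surviving.groupby(comb_keys)["aoi_mm2"].sum()
        combined = _traits_by_keys(kept, comb_keys, comb_aoi, water)
    elif combine == "mean":
        num_cols = list(TRAIT_NAMES)
        combined = (
            core.groupby(["tree_id", "site_type", "ring_year"])[num_cols + ["n_vessels"]]
            .agg({**{c: "mean" for c in num_cols}, "n_vessels": "sum"})
            .reset_index()
        )
    else:
        raise ValueError(f"unknown combine method {combine!r}")
    combined["level"] = "combined"
    combined["core_id"] = None

    cols = ["tree_id", "site_type", "core_id", "ring_year", "level",
            *TRAIT_NAMES, "n_vessels"]
    out = pd.concat([core[cols], combined[cols]], ignore_index=True)
    return out


def trait_records_to_frame(records: Sequence[TraitRecord]) -> pd.DataFrame:
    """Tabulate TraitRecords (columns named by trait symbol)."""
    return pd.DataFrame(
        {
            "tree_id": [r.tree_id for r in records],
            "site_type": [r.site_type for r in records],
            "core_id": [r.core_id for r in records],
            "ring_year": [r.ring_year for r in records],
            "level": [r.level for r in records],
            "LA": [r.la_mean for r in records],
            "VFrac": [r.vfrac for r in records],
            "VFreq": [r.vfreq for r in records],
            "HWD": [r.hwd for r in records],
            "THC": [r.thc for r in records],
            "VI": [r.vi for r in records],
            "GI": [r.gi for r in records],
            "SVI": [r.svi for r in records],
            "n_vessels": [r.n_vessels for r in records],
        }
    )
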