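"""Trait chronologies and common-signal statistics.

A chronology is the per-tree, year-indexed series of one trait at one site,
plus its site mean.  Signal strength is summarised by the mean inter-series
correlation r̄ (between trees, and within trees between the A and B cores)
and the expressed population signal EPS = n·r̄ / (1 + (n−1)·r̄).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TraitChronology",
    "SignalStats",
    "build_chronology",
    "first_differences",
    "mean_interseries_correlation",
    "eps",
]


@dataclass
class TraitChronology:
    site_type: str
    trait_name: str
    series: pd.DataFrame  # index: year; columns: tree_id; NaN = missing

    def __post_init__(self) -> None:
        if not self.series.index.is_monotonic_increasing:
            self.series = self.series.sort_index()

    @property
    def years(self) -> np.ndarray:
        return self.series.index.to_numpy()

    @property
    def site_mean(self) -> pd.Series:
        return self.series.mean(axis=1)

    @property
    def n_trees(self) -> pd.Series:
        return self.series.notna().sum(axis=1)

    def to_long(self) -> pd.DataFrame:
        long = (
            self.series.rename_axis("year")
            .reset_index()
            .melt(id_vars="year", var_name="tree_id", value_name="value")
            .dropna(subset=["value"])
        )
        long.insert(0, "site_type", self.site_type)
        long.insert(1, "trait", self.trait_name)
        return long


@dataclass(frozen=True)
class SignalStats:
    rbar_between: float
    rbar_within: float | None
    eps: float
    n_trees: int


def build_chronology(
    trait_records: pd.DataFrame, trait_name: str, site_type: str
) -> TraitChronology:
    """Pivot combined-level trait records of one site into a chronology.

    Takes the trait table of :func:`vesselkit.traits.compute_trait_table`;
    only rows with ``level == "combined"`` and the requested site are used.
    """
    sel = trait_records[
        (trait_records["level"] == "combined")
        & (trait_records["site_type"] == site_type)
    ]
    if sel.empty:
        raise ValueError(f"no combined-level records for site {site_type!r}")
    wide = sel.pivot_table(
        index="ring_year", columns="tree_id", values=trait_name, aggfunc="mean"
    ).sort_index()
    wide.index.name = "year"
    return TraitChronology(site_type, trait_name, wide)


def first_differences(series: pd.Series) -> pd.Series:
    """Year-over-year differences value(t) − value(t−1).

    The input is indexed by calendar year.  Only consecutive years yield a
    difference; a gap (year t−1 absent) makes year t missing.  Length n−1.
    """
    if len(series) < 2:
        raise ValueError("need at least two values to difference")
    s = series.sort_index()
    years = s.index.to_numpy()
    out_years = years[1:]
    prev = pd.Series(s.to_numpy()[:-1], index=years[:-1] + 1)
    diffs = pd.Series(s.to_numpy()[1:], index=out_years) - prev.reindex(out_years)
    diffs.index.name = s.index.name
    return diffs


def _pairwise_rbar(wide: pd.DataFrame, min_overlap: int = 3) -> float:
    cols = wide.columns
    rs = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            pair = wide[[cols[i], cols[j]]].dropna()
            if len(pair) < min_overlap:
                continue
            a = pair.iloc[:, 0].to_numpy()
            b = pair.iloc[:, 1].to_numpy()
            if a.std() == 0 or b.std() == 0:
                continue
            rs.append(np.corrcoef(a, b)[0, 1])
    if not rs:
        raise ValueError("no tree pair with sufficient overlap")
    return float(np.mean(rs))


def mean_interseries_correlation(
    chronology: TraitChronology,
    core_level_records: pd.DataFrame | None = None,
    min_overlap: int = 3,
) -> SignalStats:
    """Mean inter-series correlations and EPS of a trait chronology.

    rbar_between is the mean pairwise Pearson correlation between the tree
    series (pairs with fewer than ``min_overlap`` common years are skipped).
    When core-level records are supplied, rbar_within is the mean over trees
    of the correlation between the A-core and B-core series of the same
    trait — the within-tree between-core signal.
    """
    wide = chronology.series
    if wide.shape[1] < 2:
        raise ValueError("need at least two trees")
    rbar_b = _pairwise_rbar(wide, min_overlap)
    rbar_w: float | None = None
    if core_level_records is not None:
        sel = core_level_records[
            (core_level_records["level"] == "core")
            & (core_level_records["site_type"] == chronology.site_type)
        ]
        rs = []
        for _, tree_sub in sel.groupby("tree_id"):
            cores = tree_sub.pivot_table(
                index="ring_year",
                columns="core_id",
                values=chronology.trait_name,
            ).dropna()
            if cores.shape[1] == 2 and len(cores) >= min_overlap:
                a, b = cores.iloc[:, 0], cores.iloc[:, 1]
                if a.std() > 0 and b.std() > 0:
                    rs.append(np.corrcoef(a, b)[0, 1])
        rbar_w = float(np.mean(rs)) if rs else None
    n = wide.shape[1]
    return SignalStats(
        rbar_between=rbar_b,
        rbar_within=rbar_w,
        eps=eps(rbar_b, n),
        n_trees=n,
    )


def eps(rbar_between: float, n_trees: int) -> float:
    """Expressed population signal, n·r̄ / (1 + (n−1)·r̄), clipped to [0, 1].

    A non-positive r̄ gives 0: a chronology with no common signal expresses
    none of the population signal regardless of replication.
    """
    if n_trees < 2:
        raise ValueError("EPS requires at least two trees")
    if not -1 <= rbar_between <= 1:
        raise ValueError("rbar must lie in [-1, 1]")
    if rbar_between <= 0:
        return 0.0
    value = n_trees * rbar_between / (1.0 + (n_trees - 1) * rbar_between)
    return float(min(max(value, 0.0), 1.0))
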