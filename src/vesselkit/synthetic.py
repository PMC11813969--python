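"""Seeded synthetic daily climate and hierarchical vessel populations.

The generator emulates the statistical structure a quantitative wood-anatomy
analysis assumes, calibrated to published summary values for an urban
hackberry cohort (three site types × 15 trees × 2 cores × 10 rings):

* site-type gradients in mean vessel lumen area (LA) and vessel frequency;
* a mechanistic negative LA–VFreq coupling: rings hold a roughly constant
  vessel fraction of their analysed area, so larger lumina leave room for
  fewer vessels (expected count = VFrac · aoi / LA);
* lognormal LA variation decomposed into between-tree, shared year,
  tree-year and core components;
* within-ring lognormal diameter spread (σ = 0.1858, derived from the
  consistency of the published hydraulically weighted diameter with the
  published mean lumen area);
* vessel clustering tuned so the grouping and solitary-vessel indices hit
  their targets;
* per-site climate sensitivities that act on the shared year effects through
  standardized 30-day-window climate summaries, mirroring the qualitative
  published pattern (street trees: lumen area down with warm springs, up
  with arid summers; park trees: vessel frequency and grouping respond
  instead);
* a small contaminant fraction of sub-threshold vessels (default 4%) so the
  exclusion filter always has work to do.

Regeneration with the same seed is bit-identical.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from . import climate as climate_mod

__all__ = [
    "SiteCalibration",
    "Sensitivity",
    "SimulationConfig",
    "SyntheticCohort",
    "default_config",
    "simulate_climate",
    "simulate_cohort",
    "InvalidConfigError",
]


class InvalidConfigError(ValueError):
    """The simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class SiteCalibration:
    """Per-site calibration targets (post-filter summary-statistic scale)."""

    la_mean: float  # µm²
    la_sd: float  # µm², SD of core-ring LA observations
    vfreq_mean: float  # n mm⁻²
    vfrac_sd: float  # SD of core-ring VFrac observations
    gi: float
    svi: float


@dataclass(frozen=True)
class Sensitivity:
    """Effect of one standardized window-climate series on one channel.

    ``channel`` is one of ``log_la`` (ring lumen-area level), ``log_vfrac``
    (vessel-packing level, hence vessel frequency) or ``grouping`` (logit of
    the pairing propensity).  ``beta`` is expressed in units of the shared
    year-effect SD of that channel per 1 SD of the climate series.
    """

    channel: str
    window_label: str
    variable: str
    beta: float


@dataclass
class SimulationConfig:
    sites: dict[str, SiteCalibration]
    sensitivities: dict[str, list[Sensitivity]] = field(default_factory=dict)
    # variance fractions of ring-level log-LA
    la_frac_tree: float = 0.50
    la_frac_year: float = 0.15  # shared across trees of a site
    la_frac_tree_year: float = 0.20
    la_frac_core: float = 0.15
    # variance fractions of ring-level log-VFrac
    vfrac_frac_tree: float = 0.75
    vfrac_frac_year: float = 0.05
    vfrac_frac_ring: float = 0.20
    # within-ring lognormal sigma of vessel diameter; solves
    # HWD / (2*sqrt(LA/pi)) = exp(3.5 sigma^2) = 201/178.1 for the park targets
    sigma_within: float = 0.1858
    # grouping-propensity (logit) dispersion and its decomposition
    grouping_logit_sd: float = 0.5
    grouping_frac_tree: float = 0.4
    grouping_frac_year: float = 0.2
    grouping_frac_ring: float = 0.4
    #: tree-wise correlation between log-LA and log-VFrac the coupling targets
    la_vfrac_corr: float = 0.45
    aoi_mm2: float = 10.0
    n_trees: int = 15
    n_cores: int = 2
    year_start: int = 2009
    year_end: int = 2018
    small_vessel_frac: float = 0.04
    min_area: float = 5000.0
    station_offset_c: float | None = None  # optional second, warmer station
    seed: int = 0

    @property
    def ring_years(self) -> list[int]:
        return list(range(self.year_start, self.year_end + 1))

    def validate(self) -> None:
        for name, fracs in [
            ("la", (self.la_frac_tree, self.la_frac_year, self.la_frac_tree_year,
                    self.la_frac_core)),
            ("vfrac", (self.vfrac_frac_tree, self.vfrac_frac_year,
                       self.vfrac_frac_ring)),
            ("grouping", (self.grouping_frac_tree, self.grouping_frac_year,
                          self.grouping_frac_ring)),
        ]:
            if any(f < 0 for f in fracs) or abs(sum(fracs) - 1.0) > 1e-9:
                raise InvalidConfigError(
                    f"{name} variance fractions must be non-negative and sum to 1"
                )
        if min(self.n_trees, self.n_cores) < 1 or self.year_end < self.year_start:
            raise InvalidConfigError("counts must be positive")
        if self.aoi_mm2 <= 0 or self.sigma_within <= 0:
            raise InvalidConfigError("aoi and sigma_within must be positive")
        if not 0 <= self.small_vessel_frac < 0.5:
            raise InvalidConfigError("small_vessel_frac must be in [0, 0.5)")
        for site, cal in self.sites.items():
            if min(cal.la_mean, cal.la_sd, cal.vfreq_mean) <= 0:
                raise InvalidConfigError(f"site {site}: targets must be positive")
            if not 1 <= cal.gi:
                raise InvalidConfigError(f"site {site}: GI must be >= 1")
            if not 0 <= cal.svi <= 1:
                raise InvalidConfigError(f"site {site}: SVI must lie in [0, 1]")
            # the space constraint must leave room for at least one vessel
            n_expected = cal.vfreq_mean * self.aoi_mm2
            if n_expected < 1:
                raise InvalidConfigError(
                    f"site {site}: VFreq target and aoi imply <1 vessel per ring"
                )
        for sens_list in self.sensitivities.values():
            for s in sens_list:
                if not math.isfinite(s.beta):
                    raise InvalidConfigError("sensitivities must be finite")
                if s.channel not in ("log_la", "log_vfrac", "grouping"):
                    raise InvalidConfigError(f"unknown channel {s.channel!r}")


@dataclass
class SyntheticCohort:
    vessels: pd.DataFrame  # schema of vesselkit.traits.VESSEL_COLUMNS
    daily_climate: pd.DataFrame  # schema of the daily climate CSV
    tree_metadata: pd.DataFrame
    ground_truth: dict


def default_config(seed: int = 0) -> SimulationConfig:
    """The packaged calibration, matching published site-level summaries.

    LA site targets 24 920 / 21 980 / 18 530 µm² with their printed SDs,
    VFreq targets 11.3 / 12.7 / 14.3 mm⁻², grouping targets
    (GI, SVI) = (1.25, 0.595) / (1.25, 0.598) / (1.21, 0.594), and a
    within-ring diameter sigma of 0.1858 (solution of
    HWD / (2√(LA/π)) = exp(3.5σ²) with the published park HWD 201 µm and the
    178.1 µm implied by the park LA; for a lognormal D the mean-area diameter
    2√(LA/π) is exp(µ+σ²) while HWD is exp(µ+4.5σ²)).  Street-type
    sensitivities load negatively on current-spring
    temperature and positively on current-summer aridity for lumen area;
    park sensitivities act on vessel frequency and grouping instead.
    """
    sites = {
        "park": SiteCalibration(24920.0, 7008.0, 11.3, 0.061, 1.25, 0.595),
        "residential": SiteCalibration(21980.0, 4991.0, 12.7, 0.043, 1.25, 0.598),
        "central": SiteCalibration(18530.0, 5416.0, 14.3, 0.049, 1.21, 0.594),
    }
    street_la = [
        Sensitivity("log_la", "curr-Mar-16", "tmean_mean", -0.35),
        Sensitivity("log_la", "curr-Apr-1", "tmean_mean", -0.35),
        Sensitivity("log_la", "curr-Jun-16", "hmi", +0.35),
        Sensitivity("log_la", "curr-Jul-1", "hmi", +0.35),
    ]
    park = [
        Sensitivity("log_vfrac", "curr-Apr-16", "hmi", +0.35),
        Sensitivity("log_vfrac", "curr-Apr-1", "precip_sum", -0.35),
        Sensitivity("grouping", "curr-Jun-1", "tmean_mean", +0.35),
        Sensitivity("grouping", "curr-Jun-16", "tmean_mean", +0.35),
    ]
    return SimulationConfig(
        sites=sites,
        sensitivities={
            "park": park,
            "residential": list(street_la),
            "central": list(street_la),
        },
        seed=seed,
    )


# ---------------------------------------------------------------------------
# daily climate


def _seasonal_coefficients() -> tuple[float, float, float]:
    """Two-harmonic seasonal temperature curve hitting the climate normals.

    Solves mean + A·cos θ + B·cos 2θ (θ peaking mid-July) for an annual mean
    of 6.8 °C, a July mean of 21.2 °C and a January mean of −9.7 °C.
    """
    doy = np.arange(1, 366)
    theta = 2 * math.pi * (doy - 196) / 365.25
    basis = np.column_stack([np.ones_like(theta), np.cos(theta), np.cos(2 * theta)])
    months = pd.DatetimeIndex(
        [dt.date(2001, 1, 1) + dt.timedelta(days=int(d) - 1) for d in doy]
    ).month
    rows = np.vstack(
        [
            basis.mean(axis=0),
            basis[months == 7].mean(axis=0),
            basis[months == 1].mean(axis=0),
        ]
    )
    mean, a, b = np.linalg.solve(rows, np.array([6.8, 21.2, -9.7]))
    return float(mean), float(a), float(b)


_SEASONAL = _seasonal_coefficients()


def simulate_climate(
    year_start: int,
    year_end: int,
    seed: int = 0,
    station: str = "synthetic-main",
    offset_c: float = 0.0,
) -> pd.DataFrame:
    """Daily temperature and precipitation for a cool-temperate station.

    Temperature is a two-harmonic seasonal curve (annual mean 6.8 °C, July
    ≈ 21.2 °C, January ≈ −9.7 °C) plus AR(1) weather noise (φ = 0.7,
    innovation SD 2.5 °C).  Precipitation is a Bernoulli–gamma mixture (wet
    probability 0.45, gamma shape 0.65) targeting ≈1000 mm yr⁻¹.  Columns
    follow the daily-climate CSV schema.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 424243]))
    dates = pd.date_range(dt.date(year_start, 1, 1), dt.date(year_end, 12, 31), freq="D")
    doy = dates.day_of_year.to_numpy()
    mean, a, b = _SEASONAL
    theta = 2 * math.pi * (doy - 196) / 365.25
    seasonal = mean + a * np.cos(theta) + b * np.cos(2 * theta) + offset_c
    n = len(dates)
    innov = rng.normal(0.0, 2.5, n)
    noise = np.empty(n)
    phi = 0.7
    noise[0] = innov[0] / math.sqrt(1 - phi**2)
    for i in range(1, n):
        noise[i] = phi * noise[i - 1] + innov[i]
    tmean = seasonal + noise
    wet = rng.random(n) < 0.45
    target_daily = 1000.0 / 365.25
    amounts = rng.gamma(0.65, target_daily / 0.45 / 0.65, n)
    precip = np.where(wet, amounts, 0.0)
    spread = np.abs(rng.normal(4.5, 1.5, n))
    return pd.DataFrame(
        {
            "station": station,
            "date": dates,
            "tmean_c": np.round(tmean, 2),
            "tmax_c": np.round(tmean + spread, 2),
            "tmin_c": np.round(tmean - spread, 2),
            "precip_mm": np.round(precip, 2),
        }
    )


# ---------------------------------------------------------------------------
# grouping calibration


def _calibrate_grouping(gi: float, svi: float) -> tuple[float, float]:
    """Solve the cluster-growth probabilities hitting the GI/SVI targets.

    Vessels are laid down sequentially; a new vessel joins the open cluster
    with probability g1 while the cluster is a singleton and g2 once it
    already holds two or more vessels.  Group sizes then follow
    P(1) = 1−g1, P(k≥2) = g1(1−g2)g2^{k−2}, giving
    E[S] = (1−g1) + g1(2 + g2/(1−g2)) and SVI = (1−g1)/E[S].
    The published target pairs are typically infeasible by a fraction of a
    percent (they would need non-solitary clusters smaller than pairs), so
    the probabilities are found by least squares on the relative errors.
    """

    def err(params):
        g1, g2 = params
        es = (1 - g1) + g1 * (2 + g2 / (1 - g2))
        return [(es - gi) / gi, ((1 - g1) / es - svi) / svi]

    best, cost = None, np.inf
    for start in ((min(max(gi - 1.0, 1e-3), 0.95), 0.05), (0.3, 0.2)):
        res = optimize.least_squares(
            err, start, bounds=([1e-6, 0.0], [0.999, 0.9])
        )
        if res.cost < cost:
            best, cost = res.x, res.cost
    g1, g2 = best
    if cost > 0.01:  # worse than ~10% joint relative error
        raise InvalidConfigError(
            f"grouping targets GI={gi}, SVI={svi} cannot be approximated"
        )
    return float(g1), float(g2)


def _group_sizes(n: int, g1: float, g2: float, rng: np.random.Generator) -> np.ndarray:
    """Sequential cluster sizes summing exactly to n vessels."""
    sizes = []
    left = n
    while left > 0:
        size = 1
        if left > size and rng.random() < g1:
            size += 1
            while left > size and rng.random() < g2:
                size += 1
        sizes.append(size)
        left -= size
    return np.asarray(sizes)


# ---------------------------------------------------------------------------
# cohort generation


def _centered_normal(rng, sd: float, n: int) -> np.ndarray:
    """Zero-sum normal draws: balanced sampling of a random-effect vector."""
    x = rng.normal(0.0, sd, n)
    return x - x.mean() if n > 1 else x


def _logit(p: float) -> float:
    return math.log(p / (1 - p))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_cohort(
    config: SimulationConfig, daily_climate: pd.DataFrame | None = None
) -> SyntheticCohort:
    """Generate a full synthetic cohort (vessels + climate + ground truth).

    When ``daily_climate`` is omitted it is simulated from the config seed,
    covering one year before the first ring year (previous-year windows need
    it).  See the module docstring for the generative model.
    """
    config.validate()
    root = np.random.SeedSequence([config.seed, 77002])
    ss_climate, ss_sites = root.spawn(2)
    if daily_climate is None:
        daily_climate = simulate_climate(
            config.year_start - 1, config.year_end, seed=config.seed
        )
    daily_idx = climate_mod.daily_frame_to_series(
        daily_climate.drop(columns=["station"], errors="ignore")
    )
    matrix = climate_mod.assemble_climate_matrix(daily_idx, config.ring_years)

    # standardized yearly climate series per (window, variable)
    zcache: dict[tuple[str, str], np.ndarray] = {}
    for (label,), sub in matrix.groupby(["window_label"]):
        sub = sub.sort_values("ring_year")
        for var in ("tmean_mean", "precip_sum", "hmi"):
            v = sub[var].to_numpy(dtype=float)
            sd = np.nanstd(v)
            zcache[(label, var)] = (
                (v - np.nanmean(v)) / sd if sd > 0 else np.zeros_like(v)
            )

    years = np.array(config.ring_years)
    n_years = len(years)
    rows_tree, rows_site, rows_dbh, rows_height = [], [], [], []
    vessel_parts: list[pd.DataFrame] = []
    truth: dict = {"config": config, "sites": {}}

    site_seeds = {site: s for site, s in zip(sorted(config.sites), ss_sites.spawn(len(config.sites)))}
    for site in sorted(config.sites):
        cal = config.sites[site]
        rng = np.random.default_rng(site_seeds[site])
        sigma_la = math.sqrt(math.log(1.0 + (cal.la_sd / cal.la_mean) ** 2))
        cv_vfrac_proxy = cal.vfrac_sd / max(
            cal.vfreq_mean * cal.la_mean * 1e-6, 1e-12
        )
        sigma_vfrac = math.sqrt(math.log(1.0 + cv_vfrac_proxy**2))
        # LA-VFrac coupling: rings with larger lumina also pack a somewhat
        # larger vessel fraction (published tree-wise r ~ 0.45); lambda is the
        # regression of log-VFrac on log-LA that reproduces that correlation
        lam = config.la_vfrac_corr * sigma_vfrac / sigma_la
        sigma_f0_sq = sigma_vfrac**2 - lam**2 * sigma_la**2
        if sigma_f0_sq <= 0:
            raise InvalidConfigError(
                f"site {site}: VFrac dispersion too small for the configured "
                "LA-VFrac correlation"
            )
        sigma_f0 = math.sqrt(sigma_f0_sq)
        # VFrac location chosen so the space constraint reproduces the VFreq
        # target despite the Jensen term E[exp((1-lam)*l)] on 1/LA
        vfrac_mean = (
            cal.vfreq_mean * cal.la_mean / 1e6 / math.exp((1 - lam) * sigma_la**2)
        )
        g1, g2 = _calibrate_grouping(cal.gi, cal.svi)

        # Year effects: the across-tree *shared* part of the year-to-year
        # signal is exactly the climate-driven component; the remainder of
        # the year-variance budget is drawn per tree.  Trees of a site are
        # therefore conditionally independent given climate, which is what a
        # tree-as-subject correlation analysis assumes under its null.
        sens = config.sensitivities.get(site, [])
        year_effects = {}
        year_noise_sd = {}
        for channel, sd in [
            ("log_la", sigma_la * math.sqrt(config.la_frac_year)),
            ("log_vfrac", sigma_f0 * math.sqrt(config.vfrac_frac_year)),
            ("grouping", config.grouping_logit_sd * math.sqrt(config.grouping_frac_year)),
        ]:
            betas = [s for s in sens if s.channel == channel]
            signal = np.zeros(n_years)
            ssq = 0.0
            for s in betas:
                signal += s.beta * zcache[(s.window_label, s.variable)]
                ssq += s.beta**2
            year_effects[channel] = sd * signal
            year_noise_sd[channel] = sd * math.sqrt(max(0.0, 1.0 - ssq))

        tree_la = _centered_normal(rng, sigma_la * math.sqrt(config.la_frac_tree), config.n_trees)
        tree_vf = _centered_normal(
            rng, sigma_f0 * math.sqrt(config.vfrac_frac_tree), config.n_trees
        )
        tree_gr = _centered_normal(
            rng,
            config.grouping_logit_sd * math.sqrt(config.grouping_frac_tree),
            config.n_trees,
        )
        sd_la_ty = sigma_la * math.sqrt(config.la_frac_tree_year)
        sd_la_core = sigma_la * math.sqrt(config.la_frac_core)
        sd_vf_ring = sigma_f0 * math.sqrt(config.vfrac_frac_ring)
        sd_gr_ring = config.grouping_logit_sd * math.sqrt(config.grouping_frac_ring)
        sigma_area = 2.0 * config.sigma_within

        truth["sites"][site] = {
            "sigma_la": sigma_la,
            "sigma_vfrac": sigma_vfrac,
            "sigma_f0": sigma_f0,
            "lambda_la_vfrac": lam,
            "vfrac_mean": vfrac_mean,
            "g1": g1,
            "g2": g2,
            "tree_effect_log_la": tree_la.copy(),
            "year_effects": {k: v.copy() for k, v in year_effects.items()},
        }

        for t in range(config.n_trees):
            tree_id = f"{site[:4]}{t + 1:02d}"
            rows_tree.append(tree_id)
            rows_site.append(site)
            rows_dbh.append(float(np.round(rng.normal(43.0, 7.0), 1)))
            rows_height.append(float(np.round(rng.normal(15.0, 2.5), 1)))
            la_ty = rng.normal(0.0, sd_la_ty, n_years) + rng.normal(
                0.0, year_noise_sd["log_la"], n_years
            )
            vf_ring_year = rng.normal(0.0, sd_vf_ring, n_years) + rng.normal(
                0.0, year_noise_sd["log_vfrac"], n_years
            )
            gr_ring_year = rng.normal(0.0, sd_gr_ring, n_years) + rng.normal(
                0.0, year_noise_sd["grouping"], n_years
            )
            for yi, year in enumerate(years):
                for core in "AB"[: config.n_cores]:
                    l_dev = (
                        tree_la[t]
                        + year_effects["log_la"][yi]
                        + la_ty[yi]
                        + rng.normal(0.0, sd_la_core)
                    )
                    la_ring = cal.la_mean * math.exp(l_dev - 0.5 * sigma_la**2)
                    f_dev = (
                        tree_vf[t]
                        + year_effects["log_vfrac"][yi]
                        + vf_ring_year[yi]
                    )
                    vfrac_ring = vfrac_mean * math.exp(
                        lam * l_dev
                        + f_dev
                        - 0.5 * (lam**2 * sigma_la**2 + sigma_f0_sq)
                    )
                    n_exp = vfrac_ring * config.aoi_mm2 * 1e6 / la_ring
                    n_main = max(1, int(rng.poisson(n_exp)))
                    areas = np.exp(
                        rng.normal(
                            math.log(la_ring) - 0.5 * sigma_area**2,
                            sigma_area,
                            n_main,
                        )
                    )
                    g1_ring = float(
                        _sigmoid(
                            np.array(
                                _logit(min(max(g1, 1e-4), 1 - 1e-4))
                                + tree_gr[t]
                                + year_effects["grouping"][yi]
                                + gr_ring_year[yi]
                            )
                        )
                    )
                    sizes = _group_sizes(n_main, g1_ring, g2, rng)
                    group_idx = np.repeat(np.arange(len(sizes)), sizes)
                    # contaminant sub-threshold vessels, solitary by construction
                    n_small = rng.poisson(
                        n_exp * config.small_vessel_frac / (1 - config.small_vessel_frac)
                    )
                    small = rng.uniform(1500.0, 4900.0, n_small)
                    all_areas = np.concatenate([areas, small])
                    all_groups = np.concatenate(
                        [group_idx, len(sizes) + np.arange(n_small)]
                    )
                    n_all = n_main + n_small
                    vessel_parts.append(
                        pd.DataFrame(
                            {
                                "tree_id": tree_id,
                                "site_type": site,
                                "core_id": core,
                                "ring_year": int(year),
                                "aoi_mm2": config.aoi_mm2,
                                "vessel_id": np.arange(1, n_all + 1),
                                "lumen_area_um2": np.round(all_areas, 1),
                                "group_id": [f"g{g:04d}" for g in all_groups],
                            }
                        )
                    )

    vessels = pd.concat(vessel_parts, ignore_index=True)
    metadata = pd.DataFrame(
        {
            "tree_id": rows_tree,
            "site_type": rows_site,
            "dbh_cm": rows_dbh,
            "height_m": rows_height,
        }
    )
    return SyntheticCohort(
        vessels=vessels,
        daily_climate=daily_climate,
        tree_metadata=metadata,
        ground_truth=truth,
    )
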