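"""Synthetic seasonal community generator.

The generator emulates the statistical structure of a brackish-ditch
diatom calibration study: 32 locations sampled in spring, summer and
autumn (96 training samples, 400 valves counted per sample) plus 90
independent validation samples (250 valves, spring conditions), along a
chloride gradient of 200-9000 mg/l.

Species respond unimodally to log10 chloride: the raw response of taxon k
at salinity x in season s is

    r_k(x, s) = a_k * m_{k,s} * exp(-(x - u_k)^2 / (2 tau_k^2))

with true optimum u_k, tolerance tau_k, peak abundance a_k and a seasonal
abundance multiplier m_{k,s}.  Relative composition is the normalized
response vector and observed counts are one multinomial draw per sample.

Seasonality is modelled as multiplicative abundance modulation (species
abundances change between seasons; identities and niches do not): a
season-dependent multiplier is applied per taxon, with summer and autumn
modulating opposite halves of the gradient in opposite directions and
spring left neutral.  Because communities are compositional, boosting a
taxon inflates its relative abundance most where it was rare, which drags
its apparent (weighted-average) optimum toward the part of the gradient
dominated by other taxa — this closure effect is what makes single-season
calibrations disagree about optima even though the underlying niches are
season-invariant.

Nuisance covariates are generated linear in log10 chloride plus Gaussian
noise, scaled so the expected Pearson correlation with log10 chloride hits
a configurable target (defaults follow the all-season correlation pattern
of the study this emulates: strong for conductivity and sulphate, weak for
nutrients).

All randomness flows from one master seed through named
``numpy.random.SeedSequence`` substreams, so an identical seed reproduces
an identical study.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import CommunityTable, EnvironmentTable

__all__ = [
    "SpeciesPool",
    "SimulationConfig",
    "SyntheticStudy",
    "make_species_pool",
    "expected_composition",
    "sample_community",
    "simulate_study",
]

#: default target Pearson correlations of nuisance covariates with log10
#: chloride (pooled-seasons pattern: ions/conductivity strong, the rest weak)
DEFAULT_NUISANCE = {
    "temperature": -0.16,
    "oxygen": -0.19,
    "total_nitrogen": 0.07,
    "total_phosphorus": 0.15,
    "pH": -0.09,
    "secchi_depth": -0.26,
    "conductivity": 0.60,
    "sulphate": 0.70,
    "chlorophyll_a": 0.10,
}

SEASONS = ("spring", "summer", "autumn")


@dataclass
class SpeciesPool:
    """Ground-truth species parameters (one row per taxon)."""

    table: pd.DataFrame  # columns: optimum, tolerance, peak, mult_spring/summer/autumn

    @property
    def n_taxa(self) -> int:
        return len(self.table)

    @property
    def taxon_ids(self) -> list:
        return self.table.index.tolist()

    def multipliers(self, season: str | None) -> np.ndarray:
        """Seasonal abundance multipliers; ``None`` = the season-free
        (temporally integrated) reference with all multipliers 1."""
        if season is None:
            return np.ones(self.n_taxa)
        return self.table[f"mult_{season}"].to_numpy()


@dataclass
class SimulationConfig:
    n_locations: int = 32
    seasons: tuple = SEASONS
    n_validation_sites: int = 90
    gradient_mgl: tuple = (200.0, 9000.0)
    n_valves_training: int = 400
    n_valves_validation: int = 250
    n_taxa: int = 60
    #: magnitude of the log-scale seasonal abundance modulation
    modulation_strength: float = 1.0
    #: log-sd of per-sample, per-taxon lognormal response noise emulating
    #: secondary gradients and biotic variability beyond counting error
    response_noise_sigma: float = 1.0
    #: spring modulation magnitude relative to modulation_strength; spring
    #: multipliers take random directions (mixed optima shifts) while summer
    #: and autumn modulate the two gradient halves coherently
    spring_modulation_scale: float = 1.0
    #: gradient range of the validation sites; None = same as training
    validation_gradient_mgl: tuple | None = None
    #: median species tolerance in log10 mg/l units
    tolerance_median: float = 0.25
    #: log-sd of the tolerance distribution
    tolerance_sigma: float = 0.2
    #: log-sd of the peak-abundance distribution
    peak_sigma: float = 0.5
    #: optima margin beyond the gradient ends, log10 units
    optima_margin: float = 0.25
    nuisance: dict = field(default_factory=lambda: dict(DEFAULT_NUISANCE))

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("need at least 2 taxa")
        lo, hi = self.gradient_mgl
        if not 0 < lo < hi:
            raise ValueError("gradient must satisfy 0 < min < max")
        for name in ("n_locations", "n_validation_sites",
                     "n_valves_training", "n_valves_validation"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name, r in self.nuisance.items():
            if not abs(r) < 1:
                raise ValueError(f"nuisance target |r| must be < 1 ({name}: {r})")
        if self.modulation_strength < 0:
            raise ValueError("modulation_strength must be >= 0")
        if self.validation_gradient_mgl is not None:
            vlo, vhi = self.validation_gradient_mgl
            if not 0 < vlo < vhi:
                raise ValueError("validation gradient must satisfy 0 < min < max")

    @property
    def gradient_log10(self) -> tuple:
        return (float(np.log10(self.gradient_mgl[0])),
                float(np.log10(self.gradient_mgl[1])))

    @property
    def validation_gradient_log10(self) -> tuple:
        rng = self.validation_gradient_mgl or self.gradient_mgl
        return (float(np.log10(rng[0])), float(np.log10(rng[1])))


def _streams(seed: int, names):
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def make_species_pool(config: SimulationConfig, seed: int) -> SpeciesPool:
    """Draw a ground-truth species pool.

    Optima are evenly spaced (with uniform jitter of half a spacing) across
    the log10 gradient extended by a margin; tolerances and peak abundances
    are log-normal.  Seasonal multipliers are exp(+/- strength * e_k) with
    per-taxon magnitudes e_k: taxa with below-median optima are up-weighted
    in summer and down-weighted in autumn, and taxa with above-median
    optima the reverse.  Under compositional closure this pushes
    single-season optimum estimates apart in the direction observed in
    seasonal calibration studies (summer highest, autumn lowest).  Spring
    modulates with mixed, optimum-independent directions at a reduced
    magnitude, so spring optimum estimates scatter on both sides of the
    all-season average.
    """
    rngs = _streams(seed, ["optima", "tolerance", "peak", "modulation",
                           "spring_modulation"])
    lo, hi = config.gradient_log10
    lo, hi = lo - config.optima_margin, hi + config.optima_margin
    n = config.n_taxa
    spacing = (hi - lo) / n
    optima = np.linspace(lo + spacing / 2, hi - spacing / 2, n)
    optima = optima + rngs["optima"].uniform(-spacing / 2, spacing / 2, size=n)
    tolerance = np.exp(np.log(config.tolerance_median)
                       + config.tolerance_sigma * rngs["tolerance"].standard_normal(n))
    peak = np.exp(config.peak_sigma * rngs["peak"].standard_normal(n))

    median_opt = np.median(optima)
    sign = np.where(optima <= median_opt, 1.0, -1.0)  # low-optimum taxa: +1
    magnitude = rngs["modulation"].uniform(0.5, 1.5, size=n)
    log_m = config.modulation_strength * sign * magnitude
    spring_sign = rngs["spring_modulation"].choice([-1.0, 1.0], size=n)
    spring_mag = rngs["spring_modulation"].uniform(0.5, 1.5, size=n)
    log_m_spring = (config.modulation_strength * config.spring_modulation_scale
                    * spring_sign * spring_mag)
    table = pd.DataFrame({
        "optimum": optima, "tolerance": tolerance, "peak": peak,
        "mult_spring": np.exp(log_m_spring),
        "mult_summer": np.exp(log_m),
        "mult_autumn": np.exp(-log_m),
    }, index=pd.Index([f"taxon_{k:03d}" for k in range(n)], name="taxon"))
    return SpeciesPool(table)


def _raw_response(pool: SpeciesPool, x: float, season: str) -> np.ndarray:
    t = pool.table
    return (t["peak"].to_numpy() * pool.multipliers(season)
            * np.exp(-(x - t["optimum"].to_numpy()) ** 2
                     / (2 * t["tolerance"].to_numpy() ** 2)))


def expected_composition(pool: SpeciesPool, x: float, season: str = "spring") -> np.ndarray:
    """Expected relative abundances at log10 salinity *x* in *season*."""
    if not np.isfinite(x):
        raise ValueError("x must be finite")
    response = _raw_response(pool, x, season)
    total = response.sum()
    if total < 1e-300:
        raise ValueError(f"site at x={x} lies outside every taxon's niche")
    return response / total


def _noisy_composition(pool: SpeciesPool, x: float, season: str,
                       sigma: float, rng) -> np.ndarray:
    """Realized relative abundances: lognormal site-level response noise
    applied to the raw Gaussian responses before compositional closure."""
    response = _raw_response(pool, x, season)
    if sigma > 0:
        response = response * np.exp(sigma * rng.standard_normal(len(response)))
    total = response.sum()
    if total < 1e-300:
        raise ValueError(f"site at x={x} lies outside every taxon's niche")
    return response / total


def sample_community(expected: np.ndarray, n_valves: int, seed_or_rng) -> np.ndarray:
    """One multinomial valve-count draw from expected relative abundances."""
    expected = np.asarray(expected, dtype=float)
    if abs(expected.sum() - 1.0) > 1e-9:
        raise ValueError("expected abundances must sum to 1")
    if n_valves < 1:
        raise ValueError("n_valves must be >= 1")
    rng = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) \
        else np.random.default_rng(seed_or_rng)
    return rng.multinomial(n_valves, expected / expected.sum())


@dataclass
class SyntheticStudy:
    training_community: CommunityTable
    training_environment: EnvironmentTable
    validation_community: CommunityTable
    validation_environment: EnvironmentTable
    pool: SpeciesPool
    config: SimulationConfig
    seed: int


def _nuisance_columns(x_log: np.ndarray, targets: dict, rng) -> pd.DataFrame:
    """Covariates with prescribed expected Pearson correlation to x_log.

    Each covariate is r * z + sqrt(1 - r^2) * eps with z the standardized
    log10 chloride and eps standard normal, so corr(covariate, x) = r in
    expectation.
    """
    sd = x_log.std()
    if sd == 0:
        raise ValueError("degenerate chloride gradient (zero variance)")
    z = (x_log - x_log.mean()) / sd
    cols = {}
    for name, r in targets.items():
        eps = rng.standard_normal(len(x_log))
        cols[name] = r * z + np.sqrt(1 - r ** 2) * eps
    return pd.DataFrame(cols)


def simulate_study(config: SimulationConfig, seed: int) -> SyntheticStudy:
    """Generate the full paired training/validation study.

    Each location gets one salinity drawn uniformly on the log10 gradient,
    shared across its three seasonal samples (salinity itself is
    season-invariant; only species abundances are modulated).  Validation
    sites are drawn independently on the (possibly truncated) validation
    gradient under season-free conditions — multipliers 1, emulating an
    independently collected, temporally integrated monitoring dataset —
    with the validation valve count.
    """
    rngs = _streams(seed, ["pool", "locations", "train_counts",
                           "valid_x", "valid_counts", "nuisance_train",
                           "nuisance_valid", "train_noise", "valid_noise"])
    pool_seed = int(np.random.SeedSequence([seed, 17]).generate_state(1)[0] % (2 ** 31))
    pool = make_species_pool(config, seed=pool_seed)

    lo, hi = config.gradient_log10
    loc_x = rngs["locations"].uniform(lo, hi, size=config.n_locations)

    rows, site_ids, seasons, locations, train_x = [], [], [], [], []
    for i, x in enumerate(loc_x):
        loc = f"L{i + 1:02d}"
        for season in config.seasons:
            probs = _noisy_composition(pool, x, season,
                                       config.response_noise_sigma,
                                       rngs["train_noise"])
            rows.append(sample_community(probs, config.n_valves_training,
                                         rngs["train_counts"]))
            site_ids.append(f"{loc}_{season}")
            seasons.append(season)
            locations.append(loc)
            train_x.append(x)
    train_data = pd.DataFrame(rows, index=pd.Index(site_ids, name="site_id"),
                              columns=pool.taxon_ids)
    train_ct = CommunityTable(train_data, unit="counts",
                              season=pd.Series(seasons, index=train_data.index),
                              location=pd.Series(locations, index=train_data.index))
    train_x = np.asarray(train_x)
    train_env = pd.DataFrame({"Cl": 10.0 ** train_x}, index=train_data.index)
    train_env = pd.concat([train_env,
                           _nuisance_columns(train_x, config.nuisance,
                                             rngs["nuisance_train"])
                           .set_index(train_data.index)], axis=1)
    train_et = EnvironmentTable(train_env, units={"Cl": "mg/l"})

    vlo, vhi = config.validation_gradient_log10
    val_x = rngs["valid_x"].uniform(vlo, vhi, size=config.n_validation_sites)
    val_rows = [sample_community(_noisy_composition(pool, x, None,
                                                    config.response_noise_sigma,
                                                    rngs["valid_noise"]),
                                 config.n_valves_validation, rngs["valid_counts"])
                for x in val_x]
    val_ids = pd.Index([f"V{i + 1:02d}" for i in range(config.n_validation_sites)],
                       name="site_id")
    val_data = pd.DataFrame(val_rows, index=val_ids, columns=pool.taxon_ids)
    val_ct = CommunityTable(val_data, unit="counts")
    val_env = pd.DataFrame({"Cl": 10.0 ** val_x}, index=val_ids)
    val_env = pd.concat([val_env,
                         _nuisance_columns(val_x, config.nuisance,
                                           rngs["nuisance_valid"]).set_index(val_ids)],
                        axis=1)
    val_et = EnvironmentTable(val_env, units={"Cl": "mg/l"})

    return SyntheticStudy(training_community=train_ct, training_environment=train_et,
                          validation_community=val_ct, validation_environment=val_et,
                          pool=pool, config=config, seed=seed)
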