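"""Synthetic no-policy baseline panels.

Generates balanced state-year panels whose statistical structure mimics an
epidemic-era cause-specific mortality panel: right-skewed crude rates, strong
year-over-year autocorrelation within state, a rising national trend,
heterogeneous state levels and slopes, overdispersed death counts, and state
populations spanning roughly two orders of magnitude.  A stationary AR(1)
unemployment covariate is included.

The latent process is log-linear:

    log r_it = a_i + (log g + b_i) * (t - 1) + e_it,   e_it ~ AR(1)(rho, sd)

with state intercepts ``a_i`` and slope deviations ``b_i`` drawn once per
state and ``g`` the national multiplicative growth per year.  Death counts
are drawn from a gamma-Poisson (negative binomial) mixture with mean
``r_it * population_i / 1e5`` and shape ``nb_dispersion`` (variance
mu + mu^2/dispersion), and the realized crude rate is recomputed from the
realized count.  State populations are constant over time, drawn
log-uniformly.

A ``deterministic`` mode zeroes the AR noise and the count draw: the crude
rate equals the latent trend curve exactly and deaths are the rounded
expected counts.  This mode exists for exact-recovery tests; because the
exact rate is kept, the rate/count consistency check of
:func:`didsim.panel_core.validate_panel` does not apply to it (counts are
rounded, rates are not).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .panel_core import PER_100K, Panel


@dataclass
class BaselineConfig:
    """Parameters of the synthetic baseline process (defaults are the
    package's documented design targets, all overridable)."""

    n_states: int = 50
    n_years: int = 18
    seed: int = 1
    first_year: int = 1999
    pop_log10_range: tuple[float, float] = (5.7, 7.6)  # ~0.5M-40M persons
    rate_start_mean: float = 3.0        # per-100k crude rate, year 1 mean
    state_level_sd: float = 0.4         # sd of state log-level intercepts
    national_growth: float = 1.12       # multiplicative per-year trend
    state_slope_sd: float = 0.03        # sd of state log-slope deviations
    ar_rho: float = 0.8                 # lag-1 autocorrelation of log-rate noise
    noise_sd: float = 0.12              # sd of log-rate AR innovations
    nb_dispersion: float = 50.0         # NB shape; Var = mu + mu^2/dispersion
    unemp_mean: float = 5.5             # unemployment %, stationary mean
    unemp_sd: float = 1.0
    unemp_rho: float = 0.7
    deterministic: bool = False

    def validate(self) -> None:
        if self.n_states < 2 or self.n_years < 2:
            raise ValueError("need at least 2 states and 2 years")
        if not (0 <= self.ar_rho < 1):
            raise ValueError("ar_rho must be in [0, 1)")
        if not (0 <= self.unemp_rho < 1):
            raise ValueError("unemp_rho must be in [0, 1)")
        for name in ("state_level_sd", "state_slope_sd", "noise_sd", "unemp_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.rate_start_mean <= 0 or self.national_growth <= 0:
            raise ValueError("rates and growth must be strictly positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        lo, hi = self.pop_log10_range
        if not lo <= hi:
            raise ValueError("pop_log10_range must be ordered (lo, hi)")

    def replace(self, **kw) -> "BaselineConfig":
        return replace(self, **kw)


def _ar1_noise(rng: np.random.Generator, n: int, t: int, rho: float, sd: float) -> np.ndarray:
    """Stationary AR(1) noise matrix, shape (n, t)."""
    e = np.zeros((n, t))
    if sd == 0:
        return e
    stat_sd = sd / np.sqrt(1.0 - rho**2) if rho > 0 else sd
    e[:, 0] = rng.normal(0.0, stat_sd, size=n)
    for j in range(1, t):
        e[:, j] = rho * e[:, j - 1] + rng.normal(0.0, sd, size=n)
    return e


def draw_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Overdispersed counts via gamma-Poisson mixture: Var = mu + mu^2/dispersion."""
    mu = np.asarray(mu, dtype=float)
    lam = rng.gamma(shape=dispersion, scale=mu / dispersion)
    return rng.poisson(lam)


def generate_baseline(config: BaselineConfig) -> Panel:
    """Generate a balanced no-policy baseline panel (pure function of config).

    The returned panel carries an extra ``latent_rate`` column with the
    noise-free (deterministic mode) or pre-count-sampling (stochastic mode)
    latent crude rate; estimators ignore it.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, T = config.n_states, config.n_years
    width = max(2, len(str(n)))
    states = [f"S{i + 1:0{width}d}" for i in range(n)]
    years = np.arange(config.first_year, config.first_year + T)

    log10pop = rng.uniform(*config.pop_log10_range, size=n)
    population = np.round(10.0**log10pop).astype(np.int64)

    z_level = rng.normal(0.0, 1.0, size=n)
    z_slope = rng.normal(0.0, 1.0, size=n)
    intercept = np.log(config.rate_start_mean) + config.state_level_sd * z_level
    slope = np.log(config.national_growth) + config.state_slope_sd * z_slope

    tgrid = np.arange(T)  # 0..T-1 so the year-1 mean level is rate_start_mean
    log_latent = intercept[:, None] + slope[:, None] * tgrid[None, :]
    if not config.deterministic:
        log_latent = log_latent + _ar1_noise(rng, n, T, config.ar_rho, config.noise_sd)
    latent_rate = np.exp(log_latent)

    mu = latent_rate * population[:, None] / PER_100K
    if config.deterministic:
        deaths = np.rint(mu).astype(np.int64)
        crude = latent_rate.copy()
    else:
        deaths = draw_counts(rng, mu, config.nb_dispersion).astype(np.int64)
        crude = deaths / population[:, None] * PER_100K

    unemp = config.unemp_mean + _ar1_noise(rng, n, T, config.unemp_rho, config.unemp_sd)
    if config.deterministic:
        # keep a non-constant covariate without stochastic noise: smooth,
        # state-staggered cycle around the mean
        phase = 2.0 * np.pi * np.arange(n)[:, None] / max(n, 1)
        unemp = config.unemp_mean + 0.5 * np.sin(2.0 * np.pi * tgrid[None, :] / 6.0 + phase)

    df = pd.DataFrame(
        {
            "state": np.repeat(states, T),
            "year": np.tile(years, n),
            "population": np.repeat(population, T),
            "deaths": deaths.ravel(),
            "crude_rate": crude.ravel(),
            "unemployment_rate": unemp.ravel(),
            "latent_rate": latent_rate.ravel(),
        }
    )
    return Panel.from_dataframe(df, validate=not config.deterministic)


# ---------------------------------------------------------------------------
# summary instrument


@dataclass
class BaselineSummary:
    rate_skewness: float
    lag1_autocorr: float            # pooled within-state, detrended log rates
    lag1_autocorr_latent: float     # same but on the latent (pre-sampling) rates
    national_deaths_by_year: pd.Series = field(repr=False)
    min_population: int = 0
    max_population: int = 0
    degenerate: bool = False        # True when residuals are (near) constant


def _pooled_lag1_autocorr(wide_log: pd.DataFrame) -> tuple[float, bool]:
    """Lag-1 Pearson correlation of within-state detrended log series, pooling
    consecutive pairs across states. Returns (corr, degenerate_flag)."""
    resid = []
    T = wide_log.shape[1]
    t = np.arange(T, dtype=float)
    tc = t - t.mean()
    for _, row in wide_log.iterrows():
        y = row.to_numpy(dtype=float)
        denom = float(tc @ tc)
        beta = float(tc @ (y - y.mean())) / denom if denom > 0 else 0.0
        resid.append(y - y.mean() - beta * tc)
    r = np.asarray(resid)
    x, y = r[:, :-1].ravel(), r[:, 1:].ravel()
    if np.std(x) < 1e-12 or np.std(y) < 1e-12:
        return float("nan"), True
    return float(np.corrcoef(x, y)[0, 1]), False


def summarize_baseline(panel: Panel) -> BaselineSummary:
    """Summary statistics the generator is designed to hit: right-skewed
    rates, lag-1 autocorrelation near ``ar_rho`` (on the latent scale; count
    sampling attenuates the realized-rate version), rising national deaths,
    and a wide population span."""
    df = panel.data
    skew = float(stats.skew(df["crude_rate"].to_numpy()))
    with np.errstate(divide="ignore"):
        log_real = np.log(panel.wide("crude_rate").replace(0.0, np.nan))
    log_real = log_real.fillna(log_real.min().min())
    ac_real, degen = _pooled_lag1_autocorr(log_real)
    if "latent_rate" in df.columns:
        ac_lat, degen_lat = _pooled_lag1_autocorr(np.log(panel.wide("latent_rate")))
        degen = degen or degen_lat
    else:
        ac_lat = float("nan")
    national = df.groupby("year")["deaths"].sum()
    return BaselineSummary(
        rate_skewness=skew,
        lag1_autocorr=ac_real,
        lag1_autocorr_latent=ac_lat,
        national_deaths_by_year=national,
        min_population=int(df["population"].min()),
        max_population=int(df["population"].max()),
        degenerate=degen,
    )
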