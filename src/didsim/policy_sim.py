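"""Hypothetical policy assignment, exposure coding, and effect injection.

A simulated "study" starts from a no-policy baseline panel (Y0).  A random
subset of k states adopts the policy at a random month/year; the enactment
year is restricted so every treated state has at least three full years of
data before and after adoption.  Exposure A_it in [0, 1] is the fraction of
year t the policy was effective in state i:

* instantaneous: a step function; the enactment-year value is the fraction
  of the calendar year the policy was in effect (enactment on the first day
  of the drawn month, so July gives 6/12 = 0.5);
* linear 3-year phase-in: effectiveness ramps linearly by month, reaching
  full strength 36 months after enactment; the annual value is the mean of
  the 12 monthly values.

Known effects of size s on the multiplicative scale (or alpha per 100k on
the additive rate scale) are injected into treated post-period cells,

    additive:        r_obs = r0 + A * alpha_linear
    multiplicative:  r_obs = r0 * (1 + A * s)

which is the potential-outcomes mixture Y_obs = A*Y1 + (1-A)*Y0 with the
enactment-year dose scaled linearly in exposure.  Death counts are re-derived
from the injected rate (rounded to the nearest integer, floored at zero);
the injected crude rate itself is kept exact so linear-model recovery tests
are not polluted by count rounding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel_core import PER_100K, Panel

#: multiplicative effect size by class (sign applied separately)
SIZE_TO_S = {"null": 0.0, "small": 0.05, "medium": 0.15, "large": 0.25}

#: years of data required on both sides of every enactment
MIN_YEARS_AROUND = 3

PHASE_IN_CHOICES = ("instantaneous", "linear_3yr")
RAMP_MONTHS = 36


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# assignment


@dataclass(frozen=True)
class PolicyAssignment:
    """Treated states with their (year, month) of enactment."""

    enactment: dict[str, tuple[int, int]]  # state -> (year, month 1..12)

    @property
    def treated_states(self) -> list[str]:
        return sorted(self.enactment)

    @property
    def k(self) -> int:
        return len(self.enactment)


def admissible_years(panel: Panel) -> tuple[int, int]:
    """Inclusive enactment window leaving >= 3 full years each side."""
    years = panel.years
    return years[0] + MIN_YEARS_AROUND, years[-1] - MIN_YEARS_AROUND


def assign_policy(panel: Panel, k: int, seed) -> PolicyAssignment:
    """Choose k treated states uniformly at random with independent uniform
    enactment year (admissible window) and month (1..12)."""
    if not 1 <= k < panel.n_states:
        raise ValueError(f"k must satisfy 1 <= k < n_states={panel.n_states}, got {k}")
    lo, hi = admissible_years(panel)
    if lo > hi:
        raise ValueError("panel too short for any admissible enactment year")
    rng = _as_rng(seed)
    chosen = rng.choice(panel.states, size=k, replace=False)
    years = rng.integers(lo, hi + 1, size=k)
    months = rng.integers(1, 13, size=k)
    return PolicyAssignment(
        enactment={s: (int(y), int(m)) for s, y, m in zip(chosen, years, months)}
    )


# ---------------------------------------------------------------------------
# exposure


@dataclass
class ExposureSeries:
    """Annualized policy exposure A and its first difference (change coding).

    ``A`` and ``A_change`` are states x years frames aligned with the panel;
    ``A_change`` is NaN in the first panel year (no prior year to difference).
    """

    A: pd.DataFrame = field(repr=False)
    A_change: pd.DataFrame = field(repr=False)
    phase_in: str = "instantaneous"

    def long(self, panel: Panel, which: str = "A") -> pd.Series:
        """Exposure aligned to the panel's (state, year) row order."""
        frame = self.A if which == "A" else self.A_change
        stacked = frame.stack()
        idx = pd.MultiIndex.from_frame(panel.data[["state", "year"]])
        return stacked.reindex(idx).reset_index(drop=True)


def _monthly_exposure(delta_months: np.ndarray, phase_in: str) -> np.ndarray:
    """Per-month effectiveness given months since enactment (negative = before)."""
    if phase_in == "instantaneous":
        return (delta_months >= 0).astype(float)
    if phase_in == "linear_3yr":
        return np.clip(delta_months, 0, RAMP_MONTHS) / RAMP_MONTHS * (delta_months >= 0)
    raise ValueError(f"unknown phase_in {phase_in!r}; choose from {PHASE_IN_CHOICES}")


def code_exposure(
    assignment: PolicyAssignment, panel: Panel, phase_in: str = "instantaneous"
) -> ExposureSeries:
    """Annualize the monthly exposure profile for each state.

    The annual A is the mean of the 12 monthly values; under the
    instantaneous coding this reduces to (13 - month)/12 in the enactment
    year and 1 afterwards.
    """
    if phase_in not in PHASE_IN_CHOICES:
        raise ValueError(f"unknown phase_in {phase_in!r}; choose from {PHASE_IN_CHOICES}")
    years = np.asarray(panel.years)
    states = panel.states
    A = pd.DataFrame(0.0, index=pd.Index(states, name="state"), columns=pd.Index(years, name="year"))
    months = np.arange(1, 13)
    for state, (ey, em) in assignment.enactment.items():
        if not years[0] <= ey <= years[-1]:
            raise ValueError(f"enactment year {ey} outside panel years for state {state}")
        # months since enactment for each (year, calendar month); the
        # enactment month itself is delta 0 (policy starts on its first day)
        delta = (years[:, None] - ey) * 12 + (months[None, :] - em)
        A.loc[state] = _monthly_exposure(delta, phase_in).mean(axis=1)
    A_change = A.diff(axis=1)  # first panel year left as NaN
    return ExposureSeries(A=A, A_change=A_change, phase_in=phase_in)


# ---------------------------------------------------------------------------
# effects


@dataclass
class EffectSpec:
    """A signed effect on both scales.

    ``s`` is the signed multiplicative effect (m = 1 + s); ``alpha_linear``
    is the signed additive per-100k rate effect calibrated so that the
    national excess-death magnitude matches the multiplicative condition on
    the panel in use (see :func:`calibrate_alpha_linear`).
    """

    size_class: str
    sign: int = 1
    s: float = 0.0
    alpha_linear: float = 0.0

    def __post_init__(self):
        if self.size_class not in SIZE_TO_S:
            raise ValueError(f"unknown size_class {self.size_class!r}")
        if self.size_class == "null":
            if self.s != 0.0 or self.alpha_linear != 0.0:
                raise ValueError("null effect must have s = alpha_linear = 0")
        elif self.s != 0 and self.alpha_linear != 0:
            if np.sign(self.alpha_linear) != np.sign(self.s):
                raise ValueError("alpha_linear and s must share a sign")

    @property
    def multiplier(self) -> float:
        return 1.0 + self.s

    @classmethod
    def null(cls) -> "EffectSpec":
        return cls(size_class="null")

    @classmethod
    def from_size(cls, size_class: str, sign: int, alpha_linear: float | None = None) -> "EffectSpec":
        if size_class == "null":
            return cls.null()
        s = sign * SIZE_TO_S[size_class]
        return cls(
            size_class=size_class,
            sign=sign,
            s=s,
            alpha_linear=0.0 if alpha_linear is None else sign * abs(alpha_linear),
        )


def national_excess_deaths(panel: Panel, exposure: ExposureSeries, *, s: float = 0.0,
                           alpha_linear: float = 0.0) -> float:
    """Total excess deaths over the panel implied by an effect and exposure.

    Exactly one of ``s`` (multiplicative) / ``alpha_linear`` (additive) should
    be nonzero; additive excess is alpha * sum(A * pop)/1e5, multiplicative is
    s * sum(A * r0 * pop)/1e5.
    """
    A = exposure.long(panel)
    pop = panel.data["population"].to_numpy(dtype=float)
    if alpha_linear:
        return float(alpha_linear * np.sum(A * pop) / PER_100K)
    r0 = panel.data["crude_rate"].to_numpy(dtype=float)
    return float(s * np.sum(A * r0 * pop) / PER_100K)


def calibrate_alpha_linear(
    panel: Panel,
    s: float,
    *,
    k_values: tuple[int, ...] = (1, 5, 15, 30),
    phase_in: str = "instantaneous",
    n_draws: int = 200,
    seed: int = 12345,
) -> float:
    """Additive per-100k effect matching the multiplicative condition m = 1+s.

    Averages national excess deaths over ``n_draws`` random policy
    assignments (cycling through ``k_values``) and solves for the additive
    alpha producing the same average excess:

        alpha = s * E[sum A * r0 * pop] / E[sum A * pop]

    On a panel where every state-year has the same rate r this reduces to
    s * r exactly.
    """
    if s == 0:
        raise ValueError("null effect needs no calibration")
    rng = np.random.default_rng(seed)
    num = 0.0
    den = 0.0
    for j in range(n_draws):
        k = k_values[j % len(k_values)]
        assignment = assign_policy(panel, k, rng)
        exposure = code_exposure(assignment, panel, phase_in)
        num += national_excess_deaths(panel, exposure, s=s)
        den += national_excess_deaths(panel, exposure, alpha_linear=1.0)
    return float(num / den)


# ---------------------------------------------------------------------------
# injection


@dataclass
class SimulatedPanel:
    """Baseline and observed panels plus everything that produced them."""

    baseline: Panel
    observed: Panel
    assignment: PolicyAssignment
    exposure: ExposureSeries
    effect: EffectSpec
    scale: str                       # "additive_rate" | "multiplicative"
    expected_excess_deaths: float    # national total over the panel
    n_clamped: int = 0               # treated cells clamped at rate 0


def inject_effect(
    baseline: Panel,
    exposure: ExposureSeries,
    effect: EffectSpec,
    scale: str = "additive_rate",
) -> SimulatedPanel:
    """Inject a known effect into treated post-period cells.

    Untreated cells and null effects leave the panel untouched (the observed
    panel is then identical to the baseline).  Additive injections that would
    drive a rate negative are clamped at zero; the count of clamped cells is
    recorded and a warning emitted.
    """
    if scale not in ("additive_rate", "multiplicative"):
        raise ValueError(f"unknown scale {scale!r}")
    obs = baseline.data.copy()
    A = exposure.long(baseline).to_numpy(dtype=float)
    r0 = obs["crude_rate"].to_numpy(dtype=float)

    n_clamped = 0
    if effect.size_class == "null":
        r_obs = r0
        excess = 0.0
    elif scale == "additive_rate":
        r_obs = r0 + A * effect.alpha_linear
        n_clamped = int(np.sum(r_obs < 0))
        if n_clamped:
            # count kept on the SimulatedPanel; message static so the filter
            # can deduplicate it across simulation loops
            warnings.warn("additive injection clamped negative rates to 0")
            r_obs = np.maximum(r_obs, 0.0)
        excess = national_excess_deaths(baseline, exposure, alpha_linear=effect.alpha_linear)
    else:
        r_obs = r0 * (1.0 + A * effect.s)
        excess = national_excess_deaths(baseline, exposure, s=effect.s)

    changed = r_obs != r0
    obs["crude_rate"] = r_obs
    deaths = obs["deaths"].to_numpy(dtype=float).copy()
    pop = obs["population"].to_numpy(dtype=float)
    deaths[changed] = np.maximum(np.rint(r_obs[changed] * pop[changed] / PER_100K), 0.0)
    obs["deaths"] = deaths.astype(np.int64)

    return SimulatedPanel(
        baseline=baseline,
        observed=Panel.from_dataframe(obs, validate=False),
        assignment=exposure_assignment(exposure),
        exposure=exposure,
        effect=effect,
        scale=scale,
        expected_excess_deaths=excess,
        n_clamped=n_clamped,
    )


def exposure_assignment(exposure: ExposureSeries) -> PolicyAssignment:
    """Recover the treated-state set implied by an exposure matrix (states with
    any positive exposure); enactment dates are not recoverable exactly from
    annualized values, so the first exposed year with month 1 is recorded."""
    enact = {}
    for state, row in exposure.A.iterrows():
        pos = row[row > 0]
        if len(pos):
            enact[state] = (int(pos.index[0]), 1)
    return PolicyAssignment(enactment=enact)


def simulate_observed(
    baseline: Panel,
    k: int,
    effect: EffectSpec,
    *,
    phase_in: str = "instantaneous",
    scale: str = "additive_rate",
    seed=0,
) -> SimulatedPanel:
    """Convenience wrapper: assign, code exposure, inject."""
    rng = _as_rng(seed)
    assignment = assign_policy(baseline, k, rng)
    exposure = code_exposure(assignment, baseline, phase_in)
    sim = inject_effect(baseline, exposure, effect, scale)
    return SimulatedPanel(
        baseline=sim.baseline,
        observed=sim.observed,
        assignment=assignment,
        exposure=exposure,
        effect=effect,
        scale=scale,
        expected_excess_deaths=sim.expected_excess_deaths,
        n_clamped=sim.n_clamped,
    )
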