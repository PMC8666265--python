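"""Monte-Carlo performance metrics for the estimator benchmark.

Five metrics summarize a model's behaviour over paired positive/negative
effect conditions of the same magnitude (estimates alpha_hat_k over k
simulated datasets, truths alpha_pos = -alpha_neg):

* directional bias  (mean(pos - a_pos) + mean(neg - a_neg)) / 2 — the average
  signed error regardless of the direction of the true effect;
* magnitude bias    (mean(pos - a_pos) - mean(neg - a_neg)) / 2 — the
  tendency to exaggerate (+) or understate (-) the effect size;
* RMSE              sqrt(mean((alpha_hat - alpha)^2)) on the native scale;
* Type I error      fraction of null-condition p-values below the level;
* correct rejection rate — fraction of effect-condition estimates that are
  significant *and* correctly signed, after dividing test statistics by an
  SE correction factor calibrated so the null rejection rate is exactly the
  nominal level.

Bias is also standardized to national annual excess deaths so linear and
log-link models are comparable, and expressed as a percentage of the excess
implied by the true effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .panel_core import PER_100K, Panel


# ---------------------------------------------------------------------------
# bias and error


def _check_nonempty(*arrays):
    for a in arrays:
        if len(np.atleast_1d(a)) == 0:
            raise ValueError("metric requires non-empty estimate arrays")


def directional_bias(pos, neg, truth: tuple[float, float]) -> float:
    """Average of the mean bias over the positive- and negative-effect runs."""
    _check_nonempty(pos, neg)
    a_pos, a_neg = truth
    return float((np.mean(np.asarray(pos) - a_pos) + np.mean(np.asarray(neg) - a_neg)) / 2)


def magnitude_bias(pos, neg, truth: tuple[float, float]) -> float:
    """Sign-folded bias: negative-condition bias is negated before averaging,
    so a positive value means the effect size is exaggerated in both
    directions (e.g. estimates +0.4 / -0.4 for truth +-0.3 give +0.1)."""
    _check_nonempty(pos, neg)
    a_pos, a_neg = truth
    return float((np.mean(np.asarray(pos) - a_pos) - np.mean(np.asarray(neg) - a_neg)) / 2)


def rmse(estimates, truth: float) -> float:
    _check_nonempty(estimates)
    e = np.asarray(estimates, dtype=float) - truth
    return float(np.sqrt(np.mean(e * e)))


# ---------------------------------------------------------------------------
# death-count standardization


@dataclass(frozen=True)
class PanelContext:
    """National aggregates used to put effects on the excess-deaths scale."""

    national_population: float
    annual_baseline_deaths: float  # mean national deaths per year

    @classmethod
    def from_panel(cls, panel: Panel) -> "PanelContext":
        df = panel.data
        by_year = df.groupby("year")
        return cls(
            national_population=float(by_year["population"].sum().mean()),
            annual_baseline_deaths=float(by_year["deaths"].sum().mean()),
        )


def standardize_to_deaths(effect: float, link: str, ctx: PanelContext) -> float:
    """Convert a native-scale effect to national annual excess deaths.

    Linear links: a per-100k rate difference scaled by national population.
    Log links (log_linear, poisson, negbin): a log rate ratio applied to the
    national annual baseline death count, (exp(effect) - 1) * deaths.
    """
    if link == "linear":
        return float(effect * ctx.national_population / PER_100K)
    if link in ("log_linear", "poisson", "negbin"):
        return float(np.expm1(effect) * ctx.annual_baseline_deaths)
    raise ValueError(f"unknown link {link!r}")


# ---------------------------------------------------------------------------
# hypothesis-testing metrics


def type1_rate(null_p_values, level: float = 0.05, size_class: str = "null") -> float:
    """Fraction of null-condition tests rejecting at the given level."""
    if size_class != "null":
        raise ValueError("Type I error is defined on null-effect conditions only")
    p = np.asarray(null_p_values, dtype=float)
    p = p[np.isfinite(p)]
    _check_nonempty(p)
    return float(np.mean(p < level))


def se_correction_factor(null_t_stats, crit: float = 1.959963984540054,
                         level: float = 0.05) -> float:
    """Calibration factor making the null rejection rate exactly the level.

    The factor is the empirical upper-``level`` order statistic of |t| under
    the null divided by the nominal critical value: dividing test statistics
    by it (equivalently inflating SEs) and rejecting when |t|/factor
    strictly exceeds ``crit`` rejects exactly ``level`` of the calibration
    sample (up to ties)."""
    t = np.asarray(null_t_stats, dtype=float)
    t = np.abs(t[np.isfinite(t)])
    _check_nonempty(t)
    if len(t) < 100:
        warnings.warn(f"only {len(t)} null statistics; correction factor is noisy")
    n = len(t)
    k = int(np.ceil((1.0 - level) * n)) - 1  # 0-based order statistic
    q = np.sort(t)[max(k, 0)]
    return float(q / crit)


def correct_rejection_rate(t_stats, factor: float, truth_sign: int,
                           crit: float = 1.959963984540054) -> float:
    """Fraction of estimates significant after SE correction *and* signed like
    the true effect.  ``t_stats`` are signed statistics from a non-null
    condition; ``factor`` comes from the matching null condition."""
    if not (np.isfinite(factor) and factor > 0):
        raise ValueError(f"correction factor must be positive, got {factor}")
    if truth_sign not in (-1, 1):
        raise ValueError("truth_sign must be +1 or -1")
    t = np.asarray(t_stats, dtype=float)
    t = t[np.isfinite(t)]
    _check_nonempty(t)
    rej = (np.abs(t) / factor > crit) & (np.sign(t) == truth_sign)
    return float(np.mean(rej))


# ---------------------------------------------------------------------------
# row assembly


@dataclass
class MetricsRow:
    """One (model, SE method, condition) row of the benchmark output."""

    model_id: str
    se_method: str
    k: int
    size_class: str
    phase_in: str
    link: str
    n_sims: int
    n_converged: int
    directional_bias: float = float("nan")       # native scale
    magnitude_bias: float = float("nan")         # native scale
    directional_bias_deaths: float = float("nan")
    magnitude_bias_deaths: float = float("nan")
    pct_directional_bias: float = float("nan")
    pct_magnitude_bias: float = float("nan")
    rmse: float = float("nan")                   # native scale
    type1_rate: float = float("nan")
    correct_rejection_rate: float = float("nan")
    se_correction_factor: float = float("nan")
    meets_80pct_power: bool | None = None


def effect_condition_row(
    *, model_id: str, se_method: str, k: int, size_class: str, phase_in: str,
    link: str, pos: np.ndarray, neg: np.ndarray, truth: tuple[float, float],
    t_pos: np.ndarray, t_neg: np.ndarray, factor: float, ctx: PanelContext,
    expected_excess: float, n_sims: int, crit: float = 1.959963984540054,
) -> MetricsRow:
    """Assemble the full metrics row for one signed-pair effect condition.

    ``expected_excess`` is the national annual excess-death magnitude implied
    by the true (positive) effect: the denominator of the percent metrics.
    """
    db = directional_bias(pos, neg, truth)
    mb = magnitude_bias(pos, neg, truth)
    db_deaths = standardize_to_deaths(db, link, ctx)
    mb_deaths = standardize_to_deaths(mb, link, ctx)
    rm = (rmse(pos, truth[0]) + rmse(neg, truth[1])) / 2.0
    crr_pos = correct_rejection_rate(t_pos, factor, 1, crit)
    crr_neg = correct_rejection_rate(t_neg, factor, -1, crit)
    crr = (crr_pos + crr_neg) / 2.0
    return MetricsRow(
        model_id=model_id, se_method=se_method, k=k, size_class=size_class,
        phase_in=phase_in, link=link, n_sims=n_sims,
        n_converged=len(pos) + len(neg),
        directional_bias=db, magnitude_bias=mb,
        directional_bias_deaths=db_deaths, magnitude_bias_deaths=mb_deaths,
        pct_directional_bias=100.0 * db_deaths / expected_excess,
        pct_magnitude_bias=100.0 * mb_deaths / expected_excess,
        rmse=rm,
        correct_rejection_rate=crr,
        se_correction_factor=factor,
        meets_80pct_power=bool(crr >= 0.8),
    )
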