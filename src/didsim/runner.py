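"""Experiment orchestration: the full factorial Monte-Carlo benchmark.

A run crosses treated-group sizes k, effect-size classes (null, small,
medium, large; the non-null classes paired as +/- signed conditions), and
policy phase-in codings, fitting every requested model to every simulated
dataset.  Null conditions are always run first: they provide Type I error
rates, null RMSE, and the SE correction factors used to calibrate correct
rejection rates of the matching effect conditions.

Reproducibility contract: every simulated dataset's seed is derived by
hashing (master seed, condition key, simulation index), so results are
byte-identical across reruns, adding a model to the grid changes no other
model's estimates, and disjoint model subsets reproduce the combined run.
Completed conditions are persisted as CSV archives and skipped when a run
is resumed with an identical configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import metrics as mx
from .estimators import ModelSpec, fit_model, full_grid
from .panel_core import Panel, read_panel
from .policy_sim import (
    SIZE_TO_S,
    EffectSpec,
    assign_policy,
    calibrate_alpha_linear,
    code_exposure,
    inject_effect,
)
from .synthetic_baseline import BaselineConfig, generate_baseline

CANONICAL_K = (1, 5, 15, 30)
SIZE_CLASSES = ("null", "small", "medium", "large")
PHASE_INS = ("instantaneous", "linear_3yr")

_Z_CRIT = float(sps.norm.ppf(0.975))


def child_seed(master_seed: int, key: str, index: int = 0) -> int:
    """Deterministic sub-seed from (master seed, string key, index); the
    digest is truncated below 2^31 so any consumer can accept it."""
    h = hashlib.blake2b(f"{master_seed}|{key}|{index}".encode(), digest_size=8)
    return int.from_bytes(h.digest(), "big") & 0x7FFFFFFF


@dataclass(frozen=True)
class Condition:
    k: int
    size_class: str
    phase_in: str

    @property
    def key(self) -> str:
        return f"k{self.k}_{self.size_class}_{self.phase_in}"


@dataclass
class ExperimentConfig:
    """Everything a benchmark run needs; YAML-loadable, hashable for resume."""

    baseline: BaselineConfig = field(default_factory=BaselineConfig)
    panel_path: str | None = None        # user panel overrides the generator
    model_ids: list[str] = field(default_factory=lambda: [s.model_id for s in full_grid()])
    k_values: tuple[int, ...] = CANONICAL_K
    size_classes: tuple[str, ...] = SIZE_CLASSES
    phase_ins: tuple[str, ...] = PHASE_INS
    n_sims: int = 500                    # canonical scale is 5000
    master_seed: int = 0
    level: float = 0.05
    calibration_draws: int = 200
    out_dir: str = "results"

    def validate(self) -> None:
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")
        non_null = [s for s in self.size_classes if s != "null"]
        if non_null and "null" not in self.size_classes:
            raise ValueError(
                "effect conditions need matching null conditions for SE calibration; "
                "add 'null' to size_classes"
            )
        for s in self.size_classes:
            if s not in SIZE_TO_S:
                raise ValueError(f"unknown size_class {s!r}")
        for p in self.phase_ins:
            if p not in PHASE_INS:
                raise ValueError(f"unknown phase_in {p!r}")
        for mid in self.model_ids:
            ModelSpec.from_id(mid)  # raises on malformed ids

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["baseline"] = asdict(self.baseline)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "baseline" in d and isinstance(d["baseline"], dict):
            base = BaselineConfig(**{
                k: tuple(v) if k == "pop_log10_range" else v
                for k, v in d["baseline"].items()
            })
            d["baseline"] = base
        for key in ("k_values", "size_classes", "phase_ins"):
            if key in d:
                d[key] = tuple(d[key])
        if "size_classes" in d:
            # an unquoted YAML `null` arrives as None; it means the null class
            d["size_classes"] = tuple(
                "null" if s is None else s for s in d["size_classes"]
            )
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def conditions(self) -> list[Condition]:
        """Null conditions first (they feed the calibration of the rest)."""
        out = []
        for phase in self.phase_ins:
            for k in self.k_values:
                for size in self.size_classes:
                    out.append(Condition(k=k, size_class=size, phase_in=phase))
        return sorted(out, key=lambda c: (c.size_class != "null",))


def load_baseline(config: ExperimentConfig) -> Panel:
    if config.panel_path:
        return read_panel(config.panel_path)
    return generate_baseline(config.baseline)


def calibrate_effects(config: ExperimentConfig, baseline: Panel) -> dict[str, float]:
    """Positive-sign additive alpha per size class, matched in national
    excess deaths to the multiplicative condition on this baseline."""
    out = {}
    for size in config.size_classes:
        if size == "null":
            continue
        out[size] = calibrate_alpha_linear(
            baseline, SIZE_TO_S[size],
            k_values=tuple(config.k_values),
            n_draws=config.calibration_draws,
            seed=child_seed(config.master_seed, "calibration"),
        )
    return out


# ---------------------------------------------------------------------------
# per-condition simulation loop


def run_condition(
    config: ExperimentConfig,
    condition: Condition,
    specs: list[ModelSpec],
    baseline: Panel | None = None,
    alpha_by_size: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Simulate ``n_sims`` datasets for one condition and fit every model.

    Returns a tidy frame with one row per (sim, sign, model, SE method).
    Each simulated dataset is shared by all models; seeds depend only on the
    condition and simulation index, never on the model list.
    """
    config.validate()
    if baseline is None:
        baseline = load_baseline(config)
    if alpha_by_size is None and condition.size_class != "null":
        alpha_by_size = calibrate_effects(config, baseline)

    rows: list[dict] = []
    signs = (0,) if condition.size_class == "null" else (1, -1)
    for j in range(config.n_sims):
        seed_j = child_seed(config.master_seed, condition.key, j)
        rng = np.random.default_rng(seed_j)
        assignment = assign_policy(baseline, condition.k, rng)
        exposure = code_exposure(assignment, baseline, condition.phase_in)
        for sign in signs:
            if sign == 0:
                effect = EffectSpec.null()
                sim_add = inject_effect(baseline, exposure, effect, "additive_rate")
                sim_mult = sim_add  # null: observed == baseline either way
            else:
                effect = EffectSpec.from_size(
                    condition.size_class, sign,
                    alpha_linear=alpha_by_size[condition.size_class],
                )
                sim_add = inject_effect(baseline, exposure, effect, "additive_rate")
                sim_mult = inject_effect(baseline, exposure, effect, "multiplicative")
            for spec in specs:
                # each model analyses the data generated on its own scale
                sim = sim_add if spec.link == "linear" else sim_mult
                fit = fit_model(sim, spec)
                for method in spec.se_methods:
                    rows.append({
                        "condition": condition.key,
                        "k": condition.k,
                        "size_class": condition.size_class,
                        "phase_in": condition.phase_in,
                        "sim": j,
                        "sign": sign,
                        "model_id": spec.model_id,
                        "link": spec.link,
                        "se_method": method,
                        "alpha_hat": fit.alpha_hat,
                        "gamma_hat": fit.gamma_hat,
                        "se": fit.se.get(method, float("nan")),
                        "t": fit.t.get(method, float("nan")),
                        "p": fit.p.get(method, float("nan")),
                        "converged": fit.converged,
                        "n_obs": fit.n_obs_used,
                        "n_clusters": fit.n_clusters,
                        "n_zero_rates": fit.n_zero_rates,
                    })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# grid orchestration


def _crit_for(se_method: str, n_groups: int) -> float:
    if se_method == "cluster":
        return float(sps.t.ppf(0.975, df=max(n_groups - 1, 1)))
    return _Z_CRIT


def _truth_for(link: str, size_class: str, sign: int, alpha_by_size) -> float:
    if size_class == "null":
        return 0.0
    if link == "linear":
        return sign * alpha_by_size[size_class]
    return float(np.log1p(sign * SIZE_TO_S[size_class]))


def _null_rows(est: pd.DataFrame, cond: Condition, ctx, level: float) -> list[mx.MetricsRow]:
    out = []
    for (mid, method), g in est.groupby(["model_id", "se_method"], sort=True):
        ok = g[g["converged"]]
        n_groups = int(ok["n_clusters"].max()) if len(ok) else 0
        crit = _crit_for(method, n_groups)
        row = mx.MetricsRow(
            model_id=mid, se_method=method, k=cond.k, size_class="null",
            phase_in=cond.phase_in, link=g["link"].iloc[0],
            n_sims=int(g["sim"].nunique()), n_converged=len(ok),
        )
        if len(ok):
            row.type1_rate = mx.type1_rate(ok["p"].to_numpy(), level)
            row.rmse = mx.rmse(ok["alpha_hat"].to_numpy(), 0.0)
            row.se_correction_factor = mx.se_correction_factor(
                ok["t"].to_numpy(), crit=crit, level=level
            )
        out.append(row)
    return out


def _effect_rows(est: pd.DataFrame, cond: Condition, ctx, factors: dict,
                 alpha_by_size: dict, level: float) -> list[mx.MetricsRow]:
    out = []
    for (mid, method), g in est.groupby(["model_id", "se_method"], sort=True):
        ok = g[g["converged"]]
        pos = ok[ok["sign"] == 1]
        neg = ok[ok["sign"] == -1]
        link = g["link"].iloc[0]
        if not len(pos) or not len(neg):
            out.append(mx.MetricsRow(
                model_id=mid, se_method=method, k=cond.k,
                size_class=cond.size_class, phase_in=cond.phase_in, link=link,
                n_sims=int(g["sim"].nunique()), n_converged=len(ok),
            ))
            continue
        truth = (
            _truth_for(link, cond.size_class, 1, alpha_by_size),
            _truth_for(link, cond.size_class, -1, alpha_by_size),
        )
        n_groups = int(ok["n_clusters"].max())
        factor = factors.get((mid, method), float("nan"))
        expected_excess = mx.standardize_to_deaths(abs(truth[0]), link, ctx)
        out.append(mx.effect_condition_row(
            model_id=mid, se_method=method, k=cond.k,
            size_class=cond.size_class, phase_in=cond.phase_in, link=link,
            pos=pos["alpha_hat"].to_numpy(), neg=neg["alpha_hat"].to_numpy(),
            truth=truth,
            t_pos=pos["t"].to_numpy(), t_neg=neg["t"].to_numpy(),
            factor=factor, ctx=ctx, expected_excess=expected_excess,
            n_sims=int(g["sim"].nunique()),
            crit=_crit_for(method, n_groups),
        ))
    return out


def run_grid(config: ExperimentConfig) -> pd.DataFrame:
    """Run all conditions, compute metrics, persist everything.

    Writes per-condition estimate archives (``estimates_<condition>.csv``),
    the tidy metrics table (``metrics.csv``), a phase-in-averaged summary
    (``metrics_avg_phase.csv``), and a run manifest.  Conditions whose
    archive already exists under an identical configuration hash are loaded
    rather than recomputed.  Returns the metrics table.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest_path = out_dir / "manifest.json"
    prior_hash = None
    if manifest_path.exists():
        prior_hash = json.loads(manifest_path.read_text()).get("config_hash")

    baseline = load_baseline(config)
    alpha_by_size = calibrate_effects(config, baseline)
    ctx = mx.PanelContext.from_panel(baseline)
    specs = [ModelSpec.from_id(mid) for mid in config.model_ids]

    warnings_log: list[str] = []
    estimates: dict[str, pd.DataFrame] = {}
    for cond in config.conditions():
        path = out_dir / f"estimates_{cond.key}.csv"
        if path.exists() and prior_hash == chash:
            # keep_default_na: the size class "null" must stay a string
            est = pd.read_csv(path, keep_default_na=False, na_values=[""])
        else:
            est = run_condition(config, cond, specs, baseline, alpha_by_size)
            est.to_csv(path, index=False)
        estimates[cond.key] = est
        fail = est.groupby("model_id")["converged"].mean()
        for mid, frac in fail.items():
            if frac < 0.8:
                warnings_log.append(
                    f"{cond.key}: model {mid} failed on {100 * (1 - frac):.0f}% of sims"
                )

    # null calibrations per (k, phase_in)
    factors: dict[tuple[int, str], dict] = {}
    rows: list[mx.MetricsRow] = []
    for cond in config.conditions():
        if cond.size_class != "null":
            continue
        null_rows = _null_rows(estimates[cond.key], cond, ctx, config.level)
        rows.extend(null_rows)
        factors[(cond.k, cond.phase_in)] = {
            (r.model_id, r.se_method): r.se_correction_factor for r in null_rows
        }
    for cond in config.conditions():
        if cond.size_class == "null":
            continue
        rows.extend(_effect_rows(
            estimates[cond.key], cond, ctx,
            factors.get((cond.k, cond.phase_in), {}),
            alpha_by_size, config.level,
        ))

    table = pd.DataFrame([asdict(r) for r in rows])
    table.to_csv(out_dir / "metrics.csv", index=False)

    group_cols = ["model_id", "se_method", "k", "size_class", "link"]
    metric_cols = [c for c in table.columns
                   if table[c].dtype.kind == "f" and c != "se_correction_factor"]
    avg = table.groupby(group_cols, as_index=False)[metric_cols].mean()
    avg.to_csv(out_dir / "metrics_avg_phase.csv", index=False)

    manifest = {
        "config_hash": chash,
        "config": config.to_dict(),
        "alpha_linear_by_size": alpha_by_size,
        "conditions": [c.key for c in config.conditions()],
        "warnings": warnings_log,
        "n_metric_rows": len(table),
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return table


# ---------------------------------------------------------------------------
# reporting


def summarize(results_dir) -> str:
    """Human-readable report from a completed run directory."""
    results_dir = Path(results_dir)
    metrics_path = results_dir / "metrics.csv"
    if not metrics_path.exists():
        raise FileNotFoundError(
            f"no metrics.csv in {results_dir}; run the grid first"
        )
    table = pd.read_csv(metrics_path, keep_default_na=False, na_values=[""])
    lines = [f"didsim benchmark report ({len(table)} metric rows)", "=" * 46, ""]

    nulls = table[table["size_class"] == "null"]
    if len(nulls):
        lines.append("Type I error by model, SE method and k (null conditions)")
        piv = nulls.pivot_table(index=["model_id", "se_method"], columns="k",
                                values="type1_rate", aggfunc="mean")
        lines.append(piv.round(3).to_string())
        lines.append("")
        lines.append("RMSE under the null (native scale, averaged over k)")
        lines.append(
            nulls.groupby("model_id")["rmse"].mean().round(3).to_string()
        )
        lines.append("")

    effects = table[table["size_class"] != "null"]
    if len(effects):
        lines.append("Percent directional bias by model, k and effect size")
        piv = effects.pivot_table(index=["model_id"], columns=["size_class", "k"],
                                  values="pct_directional_bias", aggfunc="mean")
        lines.append(piv.round(1).to_string())
        lines.append("")
        lines.append("Correct rejection rate (SE-calibrated) by model, k, effect size")
        piv = effects.pivot_table(index=["model_id", "se_method"],
                                  columns=["size_class", "k"],
                                  values="correct_rejection_rate", aggfunc="mean")
        lines.append(piv.round(3).to_string())
        lines.append("")

    report = "\n".join(lines)
    (results_dir / "report.txt").write_text(report)
    return report
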