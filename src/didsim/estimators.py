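"""Panel policy-effect estimators and standard errors.

Implements the model grid benchmarked by the toolkit.  Four regression
families for an annual state panel with staggered policy exposure A_it:

* ``twfe``       two-way fixed effects (state + year indicators), the classic
                 difference-in-differences regression;
* ``detrended``  two-way fixed effects plus state-specific linear time slopes;
* ``ar``         lagged-outcome model: the prior year's outcome (on the link's
                 native scale) replaces state fixed effects, and the policy
                 term is change-coded (dA_it = A_it - A_{i,t-1});
* ``gee``        generalized estimating equations with year indicators,
                 clustered by state under an AR(1) working correlation.

Each family is crossed with a link (linear on crude rates, log-linear on log
crude rates, Poisson / negative-binomial on death counts with log-population
offset), a weighting scheme (population analytic weights, unweighted, or the
offset itself), and standard-error estimators (model-based, Huber/HC1
sandwich, state-clustered CR1 sandwich; GEE reports its own robust SE).

Sandwich covariances are computed explicitly from per-observation scores so
the same code path serves least-squares and maximum-likelihood fits:
V = H^{-1} (sum_i c s_i s_i' x_i x_i') H^{-1} with HC1 scaling n/(n-p) or
CR1 scaling G/(G-1) * (n-1)/(n-p) with within-state score sums.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg, stats
from statsmodels.discrete.discrete_model import NegativeBinomial as _DiscreteNB

from .panel_core import PER_100K, Panel
from .policy_sim import ExposureSeries, SimulatedPanel

FAMILIES = ("twfe", "detrended", "ar", "gee")
LINKS = ("linear", "log_linear", "poisson", "negbin")
WEIGHTINGS = ("population", "unweighted", "offset")
SE_METHODS = ("none", "huber", "cluster")

#: columns of the panel never used as covariates (truth leakage / bookkeeping)
NON_COVARIATES = ("latent_rate",)


# ---------------------------------------------------------------------------
# model grid


@dataclass(frozen=True)
class ModelSpec:
    """One cell of the benchmark grid (family x link x weighting)."""

    family: str
    link: str
    weighting: str
    se_methods: tuple[str, ...] = SE_METHODS
    ar_coding: str = "change"  # "change" (default) or "level", ar family only

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.link not in LINKS:
            raise ValueError(f"unknown link {self.link!r}")
        if self.weighting not in WEIGHTINGS:
            raise ValueError(f"unknown weighting {self.weighting!r}")
        if self.family == "gee" and self.link != "linear":
            raise ValueError("gee models are linear only")
        if self.link in ("poisson", "negbin") and self.weighting != "offset":
            raise ValueError("count links use the log-population offset, not weights")
        if self.link in ("linear", "log_linear") and self.weighting == "offset":
            raise ValueError("offset weighting is for count links only")
        if self.family == "detrended" and self.link not in ("linear", "negbin"):
            raise ValueError("detrended models are linear or negbin only")
        if self.ar_coding not in ("change", "level"):
            raise ValueError("ar_coding must be 'change' or 'level'")

    @property
    def model_id(self) -> str:
        return f"{self.family}_{self.link}_{self.weighting}"

    @classmethod
    def from_id(cls, model_id: str, **kw) -> "ModelSpec":
        family, link, weighting = model_id.split("_", 1)[0], None, None
        rest = model_id[len(family) + 1:]
        for lk in LINKS:
            if rest.startswith(lk + "_"):
                link, weighting = lk, rest[len(lk) + 1:]
                break
        if link is None or weighting not in WEIGHTINGS:
            raise ValueError(f"cannot parse model id {model_id!r}")
        if family == "gee":
            kw.setdefault("se_methods", ("robust",))
        return cls(family=family, link=link, weighting=weighting, **kw)


def full_grid() -> list[ModelSpec]:
    """The complete benchmarked grid: 17 family x link x weighting cells."""
    specs: list[ModelSpec] = []
    for family in ("twfe", "ar"):
        for link in ("linear", "log_linear"):
            for w in ("population", "unweighted"):
                specs.append(ModelSpec(family, link, w))
        for link in ("poisson", "negbin"):
            specs.append(ModelSpec(family, link, "offset"))
    for w in ("population", "unweighted"):
        specs.append(ModelSpec("detrended", "linear", w))
    specs.append(ModelSpec("detrended", "negbin", "offset"))
    for w in ("population", "unweighted"):
        specs.append(ModelSpec("gee", "linear", w, se_methods=("robust",)))
    return specs


# ---------------------------------------------------------------------------
# design construction


@dataclass
class Design:
    """Materialized regression inputs for one model on one simulated panel."""

    y: np.ndarray
    X: pd.DataFrame = field(repr=False)
    weights: np.ndarray | None
    offset: np.ndarray | None
    groups: np.ndarray
    time: np.ndarray
    alpha_col: str
    lag_col: str | None
    n_zero_rates: int
    spec: ModelSpec


def _log_rate_with_zero_fix(df: pd.DataFrame) -> tuple[np.ndarray, int]:
    """log crude rate; zero rates get a half-count continuity correction
    (0.5/population * 1e5) before logging.  Returns (values, n_replaced)."""
    rate = df["crude_rate"].to_numpy(dtype=float).copy()
    zero = rate <= 0
    n = int(zero.sum())
    if n:
        rate[zero] = 0.5 / df["population"].to_numpy(dtype=float)[zero] * PER_100K
    return np.log(rate), n


def build_design(sim: SimulatedPanel | Panel, spec: ModelSpec,
                 exposure: ExposureSeries | None = None) -> Design:
    """Assemble outcome, regressors, weights/offset and cluster ids.

    Accepts a :class:`SimulatedPanel` (preferred) or a bare panel plus an
    exposure series.  The analytic policy regressor uses the same annualized
    exposure (step or ramped) as the data-generating condition.
    """
    if isinstance(sim, SimulatedPanel):
        panel, exposure = sim.observed, sim.exposure
    else:
        panel = sim
        if exposure is None:
            raise ValueError("bare panel requires an exposure series")
    df = panel.data
    n_zero = 0

    if spec.link == "linear":
        y = df["crude_rate"].to_numpy(dtype=float)
    elif spec.link == "log_linear":
        y, n_zero = _log_rate_with_zero_fix(df)
    else:  # count links
        y = df["deaths"].to_numpy(dtype=float)

    A = exposure.long(panel, "A").to_numpy(dtype=float)
    t = panel.t_index().to_numpy()
    covs = [c for c in panel.covariates if c not in NON_COVARIATES]

    cols: dict[str, np.ndarray] = {"const": np.ones(len(df))}
    state = df["state"].to_numpy()
    states = panel.states
    years = panel.years

    if spec.family == "ar":
        dA = exposure.long(panel, "A_change").to_numpy(dtype=float)
        cols["A"] = dA if spec.ar_coding == "change" else A
        for c in covs:
            cols[c] = df[c].to_numpy(dtype=float)
        # lagged outcome on the link-native scale
        if spec.link == "linear":
            lagged_src = df["crude_rate"].to_numpy(dtype=float)
        else:
            lagged_src, nz = _log_rate_with_zero_fix(df)
            n_zero = max(n_zero, nz)
        wide = pd.Series(lagged_src, index=pd.MultiIndex.from_frame(df[["state", "year"]]))
        cols["lag_y"] = wide.groupby(level=0).shift(1).to_numpy()
        # year indicators on the post-lag sample (first remaining year is reference)
        for yr in years[2:]:
            cols[f"year_{yr}"] = (df["year"] == yr).to_numpy(dtype=float)
        keep = t > 1
    else:
        cols["A"] = A
        for c in covs:
            cols[c] = df[c].to_numpy(dtype=float)
        if spec.family in ("twfe", "detrended"):
            for s in states[1:]:
                cols[f"state_{s}"] = (state == s).astype(float)
        for yr in years[1:]:
            cols[f"year_{yr}"] = (df["year"] == yr).to_numpy(dtype=float)
        if spec.family == "detrended":
            tc = (t - t.mean()).astype(float)
            # one state's slope is absorbed by the year indicators (which carry
            # the shared national trend); the rest enter as state x time terms
            for s in states[1:]:
                cols[f"slope_{s}"] = (state == s) * tc
        keep = np.ones(len(df), dtype=bool)
    X = pd.DataFrame(cols)

    weights = None
    offset = None
    if spec.weighting == "population":
        weights = df["population"].to_numpy(dtype=float)
    elif spec.weighting == "offset":
        offset = np.log(df["population"].to_numpy(dtype=float) / PER_100K)

    return Design(
        y=y[keep],
        X=X.loc[keep].reset_index(drop=True),
        weights=None if weights is None else weights[keep],
        offset=None if offset is None else offset[keep],
        groups=state[keep],
        time=t[keep].astype(float),
        alpha_col="A",
        lag_col="lag_y" if spec.family == "ar" else None,
        n_zero_rates=n_zero,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# sandwich standard errors


@dataclass
class FitContext:
    """Everything the sandwich needs: design matrix, per-observation score
    factor s_i (score_i = s_i * x_i) and Hessian factor h_i
    (H = X' diag(h) X), plus cluster ids and the policy column index."""

    X: np.ndarray = field(repr=False)
    score_factor: np.ndarray = field(repr=False)
    hess_factor: np.ndarray = field(repr=False)
    groups: np.ndarray = field(repr=False)
    alpha_ix: int = 0


def _bread(ctx: FitContext) -> np.ndarray:
    H = ctx.X.T @ (ctx.X * ctx.hess_factor[:, None])
    return linalg.pinvh(H)


def huber_se(ctx: FitContext) -> float:
    """Heteroskedasticity-consistent sandwich SE with HC1 scaling n/(n-p)."""
    n, p = ctx.X.shape
    Hinv = _bread(ctx)
    U = ctx.X * ctx.score_factor[:, None]
    meat = U.T @ U * (n / (n - p))
    V = Hinv @ meat @ Hinv
    return float(np.sqrt(max(V[ctx.alpha_ix, ctx.alpha_ix], 0.0)))


def cluster_se(ctx: FitContext) -> float:
    """Cluster-robust (Liang-Zeger) sandwich SE with CR1 scaling
    G/(G-1) * (n-1)/(n-p); NaN (degenerate) with fewer than 2 clusters."""
    n, p = ctx.X.shape
    groups = np.asarray(ctx.groups)
    labels = pd.unique(groups)
    G = len(labels)
    if G < 2:
        return float("nan")
    Hinv = _bread(ctx)
    U = ctx.X * ctx.score_factor[:, None]
    sums = np.zeros((G, p))
    for g, lab in enumerate(labels):
        sums[g] = U[groups == lab].sum(axis=0)
    c = (G / (G - 1)) * ((n - 1) / (n - p))
    meat = sums.T @ sums * c
    V = Hinv @ meat @ Hinv
    # cluster-level fixed effects can drive the policy-term variance to a
    # structural zero; clip numerical negatives rather than emit NaN
    return float(np.sqrt(max(V[ctx.alpha_ix, ctx.alpha_ix], 0.0)))


def n_clusters(ctx: FitContext) -> int:
    return len(pd.unique(np.asarray(ctx.groups)))


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    """Policy-effect estimate for one model on one simulated panel.

    ``alpha_hat`` is on the model's native scale: a rate difference per 100k
    for linear links, a log-rate / log incidence-rate-ratio otherwise.
    """

    model_id: str
    alpha_hat: float = float("nan")
    se: dict[str, float] = field(default_factory=dict)
    t: dict[str, float] = field(default_factory=dict)
    p: dict[str, float] = field(default_factory=dict)
    gamma_hat: float | None = None
    converged: bool = False
    n_obs_used: int = 0
    n_zero_rates: int = 0
    n_clusters: int = 0
    message: str = ""


def _pvalues(alpha: float, se: dict[str, float], G: int) -> tuple[dict, dict]:
    """Test statistics and two-sided p-values: normal reference for
    model-based / Huber / GEE-robust SEs, t with G-1 df for clustered SEs."""
    tstat, pval = {}, {}
    for method, s in se.items():
        tv = alpha / s if (s and np.isfinite(s) and s > 0) else float("nan")
        tstat[method] = tv
        if not np.isfinite(tv):
            pval[method] = float("nan")
        elif method == "cluster":
            pval[method] = float(2 * stats.t.sf(abs(tv), df=max(G - 1, 1)))
        else:
            pval[method] = float(2 * stats.norm.sf(abs(tv)))
    return tstat, pval


def _finite(*vals) -> bool:
    return all(np.isfinite(v) for v in vals)


def fit_model(sim: SimulatedPanel | Panel, spec: ModelSpec,
              exposure: ExposureSeries | None = None) -> FitResult:
    """Fit one grid cell and return the policy coefficient with all requested
    SE variants.  Non-convergence or a singular design yields
    ``converged=False`` (downstream metrics exclude and count these)."""
    design = build_design(sim, spec, exposure)
    out = FitResult(model_id=spec.model_id, n_obs_used=len(design.y),
                    n_zero_rates=design.n_zero_rates)
    try:
        if spec.family == "gee":
            return _fit_gee(design, out)
        if spec.link in ("linear", "log_linear"):
            return _fit_wls(design, out)
        return _fit_count(design, out)
    except Exception as exc:  # singularity, separation, optimizer failure
        out.converged = False
        out.message = f"{type(exc).__name__}: {exc}"
        return out


def _fit_wls(design: Design, out: FitResult) -> FitResult:
    Xm = design.X.to_numpy(dtype=float)
    w = design.weights if design.weights is not None else np.ones(len(design.y))
    res = sm.WLS(design.y, Xm, weights=w).fit()
    aix = design.X.columns.get_loc(design.alpha_col)
    out.alpha_hat = float(res.params[aix])
    if design.lag_col is not None:
        out.gamma_hat = float(res.params[design.X.columns.get_loc(design.lag_col)])
    e = design.y - Xm @ res.params
    ctx = FitContext(X=Xm, score_factor=w * e, hess_factor=w,
                     groups=design.groups, alpha_ix=aix)
    out.n_clusters = n_clusters(ctx)
    se = {}
    if "none" in design.spec.se_methods:
        se["none"] = float(res.bse[aix])
    if "huber" in design.spec.se_methods:
        se["huber"] = huber_se(ctx)
    if "cluster" in design.spec.se_methods:
        se["cluster"] = cluster_se(ctx)
    out.se = se
    out.t, out.p = _pvalues(out.alpha_hat, se, out.n_clusters)
    out.converged = _finite(out.alpha_hat) and all(
        _finite(v) for k, v in se.items() if k != "cluster"
    )
    return out


def _fit_count(design: Design, out: FitResult) -> FitResult:
    Xm = design.X.to_numpy(dtype=float)
    aix = design.X.columns.get_loc(design.alpha_col)
    if design.spec.link == "poisson":
        res = sm.GLM(design.y, Xm, family=sm.families.Poisson(),
                     offset=design.offset).fit()
        mu = np.asarray(res.fittedvalues)
        score = design.y - mu
        hess = mu
        bse_none = float(res.bse[aix])
        params = res.params
    else:  # negbin: dispersion by ML, then GLM at the fitted dispersion
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pois = sm.GLM(design.y, Xm, family=sm.families.Poisson(),
                          offset=design.offset).fit()
            start = np.append(pois.params, 0.1)
            nb = _DiscreteNB(design.y, Xm, offset=design.offset)
            nbres = nb.fit(start_params=start, method="bfgs", maxiter=500, disp=0)
            if not nbres.mle_retvals.get("converged", False):
                nbres = nb.fit(start_params=start, method="nm",
                               maxiter=5000, disp=0)
        a = float(max(nbres.params[-1], 1e-8))
        res = sm.GLM(design.y, Xm, family=sm.families.NegativeBinomial(alpha=a),
                     offset=design.offset).fit()
        mu = np.asarray(res.fittedvalues)
        score = (design.y - mu) / (1.0 + a * mu)
        hess = mu / (1.0 + a * mu)
        bse_none = float(res.bse[aix])
        params = res.params
    out.alpha_hat = float(params[aix])
    if design.lag_col is not None:
        out.gamma_hat = float(params[design.X.columns.get_loc(design.lag_col)])
    ctx = FitContext(X=Xm, score_factor=score, hess_factor=hess,
                     groups=design.groups, alpha_ix=aix)
    out.n_clusters = n_clusters(ctx)
    se = {}
    if "none" in design.spec.se_methods:
        se["none"] = bse_none
    if "huber" in design.spec.se_methods:
        se["huber"] = huber_se(ctx)
    if "cluster" in design.spec.se_methods:
        se["cluster"] = cluster_se(ctx)
    out.se = se
    out.t, out.p = _pvalues(out.alpha_hat, se, out.n_clusters)
    out.converged = _finite(out.alpha_hat) and all(
        _finite(v) for k, v in se.items() if k != "cluster"
    )
    return out


def _fit_gee(design: Design, out: FitResult) -> FitResult:
    Xm = design.X.to_numpy(dtype=float)
    aix = design.X.columns.get_loc(design.alpha_col)
    kw = {}
    if design.weights is not None:
        # point estimates are invariant to weight scale; normalizing keeps the
        # iteration's convergence criterion well-conditioned
        kw["weights"] = design.weights / design.weights.mean()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GEE(design.y, Xm, groups=design.groups, time=design.time,
                       family=sm.families.Gaussian(),
                       cov_struct=sm.cov_struct.Autoregressive(grid=True), **kw)
        res = model.fit(maxiter=100)
    out.alpha_hat = float(res.params[aix])
    out.n_clusters = len(pd.unique(design.groups))
    se = {"robust": float(res.bse[aix])}
    out.se = se
    out.t, out.p = _pvalues(out.alpha_hat, se, out.n_clusters)
    out.converged = bool(getattr(res, "converged", True)) and _finite(
        out.alpha_hat, se["robust"]
    )
    return out


# ---------------------------------------------------------------------------
# lag-order diagnostics


@dataclass
class LagDiagnostics:
    pacf: np.ndarray            # partial autocorrelations, lags 1..max_lags
    threshold: float
    suggested_order: int | None
    degenerate: bool = False


def ar_lag_diagnostics(panel: Panel, max_lags: int = 10,
                       column: str = "crude_rate",
                       threshold: float | None = None) -> LagDiagnostics:
    """Pooled within-state partial autocorrelation profile of the outcome.

    Autocovariances are computed per state on demeaned series and pooled;
    partial autocorrelations come from the Yule-Walker equations
    (Durbin-Levinson).  The suggested lag order is the largest lag whose
    partial autocorrelation exceeds the guidance threshold (default
    1.96/sqrt(total observations)); a constant series is flagged degenerate.
    """
    wide = panel.wide(column)
    T = wide.shape[1]
    if max_lags >= T:
        raise ValueError(f"max_lags must be < T={T}")
    Y = wide.to_numpy(dtype=float)
    R = Y - Y.mean(axis=1, keepdims=True)
    gamma0 = float(np.mean(R * R))
    if gamma0 < 1e-24:
        return LagDiagnostics(pacf=np.full(max_lags, np.nan), threshold=float("nan"),
                              suggested_order=None, degenerate=True)
    acf = np.empty(max_lags + 1)
    acf[0] = 1.0
    for j in range(1, max_lags + 1):
        acf[j] = float(np.mean(R[:, :-j] * R[:, j:])) / gamma0
    pacf = np.empty(max_lags)
    for k in range(1, max_lags + 1):
        # last Yule-Walker coefficient at order k
        phi = linalg.solve_toeplitz(acf[:k], acf[1:k + 1])
        pacf[k - 1] = phi[-1]
    thr = threshold if threshold is not None else 1.96 / np.sqrt(Y.size)
    sig = np.nonzero(np.abs(pacf) > thr)[0]
    order = int(sig[-1] + 1) if len(sig) else 0
    return LagDiagnostics(pacf=pacf, threshold=float(thr), suggested_order=order)


def spec_grid_ids(specs: list[ModelSpec] | None = None) -> list[str]:
    return [s.model_id for s in (specs or full_grid())]


def expand_se_grid(specs: list[ModelSpec]) -> list[tuple[str, str]]:
    """(model_id, se_method) pairs across a spec list."""
    return list(
        itertools.chain.from_iterable(
            ((s.model_id, m) for m in s.se_methods) for s in specs
        )
    )
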