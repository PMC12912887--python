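"""Repeated-measures inference for colour-change experiments.

Fits the study's linear mixed model per colour metric,

    metric ~ time * population + length + sex + (1 | fish)

with time and population categorical and a random intercept per fish, then

* tests the time × population interaction with a Wald F statistic,
* computes estimated marginal means per population × time cell,
* forms all within-population time-pair contrasts on the response scale
  (back-transforming first when the metric was modelled on a log or sqrt
  scale), Tukey-adjusted within each population's family of pairs, and
* compares candidate fixed-effect structures by AIC (maximum likelihood).

Denominator degrees of freedom use the between–within partition (observations
minus subjects minus the rank of the within-subject design columns), the
classical split-plot value; the fitting backend does not expose a
Satterthwaite approximation, and on balanced designs the two coincide. The
df method used is recorded in every result.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import patsy
from scipy import stats
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "LmmFit",
    "InteractionTest",
    "ContrastResult",
    "TRANSFORMS",
    "fit_lmm",
    "test_interaction",
    "coefficient_table",
    "estimated_marginal_means",
    "time_contrasts_within_population",
    "choose_transform",
    "compare_models_aic",
]

TRANSFORMS = ("identity", "log", "sqrt")

_FORWARD = {"identity": lambda v: v, "log": np.log, "sqrt": np.sqrt}
_INVERSE = {"identity": lambda v: v, "log": np.exp, "sqrt": np.square}
_DERIV = {"identity": lambda v: np.ones_like(v), "log": np.exp,
          "sqrt": lambda v: 2.0 * v}


@dataclass(frozen=True)
class ModelSpec:
    """One candidate mixed-model structure for a colour metric."""

    response: str
    transform: str = "identity"
    interaction: bool = True
    include_length: bool = True
    include_sex: bool = True

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")

    def formula(self) -> str:
        op = "*" if self.interaction else "+"
        terms = [f"C(time_min) {op} C(population)"]
        if self.include_length:
            terms.append("length_cm")
        if self.include_sex:
            terms.append("C(sex)")
        return "_y ~ " + " + ".join(terms)

    def label(self) -> str:
        return (f"{self.transform}({self.response}) ~ time"
                f"{'*' if self.interaction else '+'}population"
                f"{'+length' if self.include_length else ''}"
                f"{'+sex' if self.include_sex else ''}")


@dataclass
class LmmFit:
    """A fitted mixed model plus the pieces downstream inference needs."""

    spec: ModelSpec
    result: object  # statsmodels MixedLMResults
    data: pd.DataFrame
    design_info: object
    fe_names: list[str]
    beta: np.ndarray
    cov_beta: np.ndarray
    ddf_within: float
    ddf_between: float
    reml: bool
    df_method: str = "between-within"

    @property
    def n_obs(self) -> int:
        return len(self.data)

    @property
    def n_fish(self) -> int:
        return self.data["fish_id"].nunique()

    @property
    def random_intercept_var(self) -> float:
        return float(np.asarray(self.result.cov_re)[0, 0] * self.result.scale)

    @property
    def residual_var(self) -> float:
        return float(self.result.scale)

    def aic(self) -> float:
        """AIC = -2 logLik + 2k; requires a maximum-likelihood fit."""
        if self.reml:
            raise ValueError("AIC comparison requires ML fits (reml=False); "
                             "REML log-likelihoods are not comparable across "
                             "fixed-effect structures")
        k = len(self.beta) + 2  # + random-intercept variance + residual variance
        return float(-2.0 * self.result.llf + 2.0 * k)


def _validate_table(table: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    required = {"fish_id", "population", "sex", "length_cm", "time_min",
                spec.response}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table missing columns: {sorted(missing)}")
    df = table.copy()
    if "role" in df.columns:
        df = df[df["role"] == "fish"]
    if df["population"].nunique() < 2:
        raise ValueError(
            "need >= 2 populations to fit the interaction model; got "
            f"{df['population'].unique().tolist()} (singular design)"
        )
    if df["time_min"].nunique() < 2:
        raise ValueError("need >= 2 time points")
    counts = df.groupby("fish_id")["time_min"].nunique()
    if (counts < 2).any():
        bad = counts.index[counts < 2].tolist()[:5]
        raise ValueError(f"every fish needs >= 2 time points; offenders: {bad}")
    y = df[spec.response].to_numpy(float)
    if not np.isfinite(y).all():
        raise ValueError(f"non-finite values in response {spec.response!r}")
    if np.ptp(y) == 0:
        raise ValueError(f"response {spec.response!r} is constant; nothing to model")
    if spec.transform == "log" and (y <= 0).any():
        raise ValueError("log transform requires strictly positive values")
    if spec.transform == "sqrt" and (y < 0).any():
        raise ValueError("sqrt transform requires non-negative values")
    df["_y"] = _FORWARD[spec.transform](y)
    return df


def _between_within_ddf(X: np.ndarray, groups: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Between–within denominator df partition.

    Returns (within ddf, between ddf, boolean mask of within-varying design
    columns). A column is "within" if it varies inside at least one subject;
    the within ddf is N − #subjects − rank(within-centred within columns),
    the between ddf is #subjects − rank(subject-level design).
    """
    n, _ = X.shape
    codes, _ = pd.factorize(groups)
    g = codes.max() + 1
    sums = np.zeros((g, X.shape[1]))
    np.add.at(sums, codes, X)
    counts = np.bincount(codes).astype(float)[:, None]
    means = sums / counts
    Xc = X - means[codes]
    within_mask = np.abs(Xc).max(axis=0) > 1e-8
    q_w = np.linalg.matrix_rank(Xc[:, within_mask]) if within_mask.any() else 0
    ddf_within = n - g - q_w
    r_b = np.linalg.matrix_rank(means)
    ddf_between = g - r_b
    return float(ddf_within), float(ddf_between), within_mask


def fit_lmm(table: pd.DataFrame, spec: ModelSpec, reml: bool = True) -> LmmFit:
    """Fit the mixed model for one colour metric by (RE)ML.

    Background rows (``role == "background"``) are excluded automatically.
    The transform in ``spec`` is applied to the response before fitting.
    """
    df = _validate_table(table, spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(spec.formula(), df, groups=df["fish_id"])
        result = None
        for method in (["bfgs"], ["lbfgs"], ["powell"], ["cg"]):
            try:
                candidate = model.fit(reml=reml, method=method)
            except np.linalg.LinAlgError:
                continue
            result = candidate
            if candidate.converged:
                break
        if result is None:
            raise RuntimeError(
                f"mixed-model fit failed for {spec.label()}: all optimisers "
                "hit singular working matrices")
    beta = np.asarray(result.fe_params)
    if not np.isfinite(beta).all():
        raise RuntimeError(f"non-finite fixed-effect estimates for {spec.label()}")
    p = len(beta)
    cov = np.asarray(result.cov_params())[:p, :p]
    ddf_w, ddf_b, _ = _between_within_ddf(
        np.asarray(model.exog), df["fish_id"].to_numpy())
    return LmmFit(
        spec=spec,
        result=result,
        data=df,
        design_info=model.data.design_info,
        fe_names=list(result.fe_params.index),
        beta=beta,
        cov_beta=cov,
        ddf_within=ddf_w,
        ddf_between=ddf_b,
        reml=reml,
    )


@dataclass(frozen=True)
class InteractionTest:
    """Joint Wald F test of all time × population interaction coefficients."""

    f_statistic: float
    df_num: int
    df_den: float
    p_value: float
    df_method: str


def test_interaction(fit: LmmFit) -> InteractionTest:
    """Joint F test that every time × population interaction coefficient is zero.

    Numerator df is the number of interaction coefficients,
    (n_times − 1) × (n_populations − 1); denominator df is the within-subject
    between–within value (the interaction is a within-subject effect).
    """
    idx = [i for i, name in enumerate(fit.fe_names)
           if "C(time_min)" in name and "C(population)" in name and ":" in name]
    if not idx:
        raise ValueError("model has no time × population interaction terms")
    L = np.zeros((len(idx), len(fit.beta)))
    for r, i in enumerate(idx):
        L[r, i] = 1.0
    lb = L @ fit.beta
    lvl = L @ fit.cov_beta @ L.T
    f_stat = float(lb @ np.linalg.solve(lvl, lb) / len(idx))
    ddf = fit.ddf_within
    p = float(stats.f.sf(f_stat, len(idx), ddf))
    return InteractionTest(f_statistic=f_stat, df_num=len(idx), df_den=ddf,
                           p_value=p, df_method=fit.df_method)


def coefficient_table(fit: LmmFit, level: float = 0.95) -> pd.DataFrame:
    """Fixed-effect estimates with t-based CIs at between–within df.

    Each coefficient uses the within-subject df if its design column varies
    within fish (time and interaction terms) and the between-subject df
    otherwise (population, sex, length, intercept).
    """
    X = patsy.build_design_matrices([fit.design_info], fit.data)[0]
    _, _, within_mask = _between_within_ddf(np.asarray(X),
                                            fit.data["fish_id"].to_numpy())
    se = np.sqrt(np.diag(fit.cov_beta))
    ddf = np.where(within_mask, fit.ddf_within, fit.ddf_between)
    tval = fit.beta / se
    alpha = 1.0 - level
    crit = stats.t.ppf(1.0 - alpha / 2.0, ddf)
    return pd.DataFrame({
        "term": fit.fe_names,
        "estimate": fit.beta,
        "se": se,
        "df": ddf,
        "t": tval,
        "p": 2.0 * stats.t.sf(np.abs(tval), ddf),
        "ci_low": fit.beta - crit * se,
        "ci_high": fit.beta + crit * se,
    })


def estimated_marginal_means(fit: LmmFit) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Model-based cell means for every population × time cell (link scale).

    The reference grid holds length at its sample mean and averages over the
    sex levels with equal weight. Returns the cell table plus the grid
    matrix R (cells × coefficients) and the cell covariance R Σ Rᵀ.
    """
    df = fit.data
    pops = sorted(df["population"].unique())
    times = sorted(df["time_min"].unique())
    observed = set(zip(df["population"], df["time_min"]))
    for pop in pops:
        for t in times:
            if (pop, t) not in observed:
                raise ValueError(f"empty design cell: population={pop!r}, "
                                 f"time_min={t!r}")
    sexes = sorted(df["sex"].unique())
    mean_len = float(df["length_cm"].mean())

    grid_rows = []
    for pop in pops:
        for t in times:
            for sex in sexes:
                grid_rows.append({"population": pop, "time_min": t,
                                  "sex": sex, "length_cm": mean_len})
    grid = pd.DataFrame(grid_rows)
    M = np.asarray(patsy.build_design_matrices([fit.design_info], grid)[0])
    n_cells = len(pops) * len(times)
    R = M.reshape(n_cells, len(sexes), -1).mean(axis=1)
    mean_link = R @ fit.beta
    cov_cells = R @ fit.cov_beta @ R.T
    cells = pd.DataFrame({
        "population": np.repeat(pops, len(times)),
        "time_min": np.tile(times, len(pops)),
        "emmean_link": mean_link,
        "se_link": np.sqrt(np.diag(cov_cells)),
    })
    return cells, R, cov_cells


@dataclass(frozen=True)
class ContrastResult:
    """One back-transformed time-pair contrast within a population."""

    population: str
    time_a: float
    time_b: float
    estimate: float  # response-scale mean(time_a) - mean(time_b)
    se: float
    t_ratio: float
    df: float
    p_unadjusted: float
    p_adjusted: float
    family_size: int


def time_contrasts_within_population(
    fit: LmmFit,
    adjust: str = "tukey",
    family: str = "within",
) -> pd.DataFrame:
    """All time-pair contrasts of estimated marginal means, per population.

    Means are back-transformed to the response scale before differencing
    when the model used a log or sqrt transform (delta-method standard
    errors), so estimates read directly in the metric's units. With
    ``family="within"`` (default) the Tukey studentised-range adjustment
    treats each population's C(n_times, 2) pairs as one family; with
    ``family="all"`` every population × time cell enters a single family.
    """
    if adjust not in ("tukey", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    if family not in ("within", "all"):
        raise ValueError(f"unknown family {family!r}")
    cells, _, cov_cells = estimated_marginal_means(fit)
    mean_link = cells["emmean_link"].to_numpy()
    inv, deriv = _INVERSE[fit.spec.transform], _DERIV[fit.spec.transform]
    mean_resp = inv(mean_link)
    d = deriv(mean_link)
    cov_resp = cov_cells * np.outer(d, d)

    times = sorted(cells["time_min"].unique())
    pops = sorted(cells["population"].unique())
    n_times = len(times)
    k_family = n_times if family == "within" else len(cells)
    ddf = fit.ddf_within
    cell_index = {(p, t): i for i, (p, t) in
                  enumerate(zip(cells["population"], cells["time_min"]))}

    rows = []
    for pop in pops:
        pairs = list(combinations(times, 2))
        for t_a, t_b in pairs:
            i, j = cell_index[(pop, t_a)], cell_index[(pop, t_b)]
            est = float(mean_resp[i] - mean_resp[j])
            var = cov_resp[i, i] + cov_resp[j, j] - 2.0 * cov_resp[i, j]
            se = float(np.sqrt(max(var, 0.0)))
            if se == 0.0:
                t_ratio = np.inf if est != 0 else 0.0
            else:
                t_ratio = est / se
            p_un = float(2.0 * stats.t.sf(abs(t_ratio), ddf))
            if adjust == "tukey":
                p_adj = float(stats.studentized_range.sf(
                    abs(t_ratio) * np.sqrt(2.0), k_family, ddf))
                p_adj = min(max(p_adj, p_un), 1.0)
            else:
                p_adj = p_un
            rows.append(ContrastResult(
                population=pop, time_a=float(t_a), time_b=float(t_b),
                estimate=est, se=se, t_ratio=float(t_ratio), df=ddf,
                p_unadjusted=p_un, p_adjusted=p_adj,
                family_size=len(pairs) if family == "within"
                else len(cells) * (len(cells) - 1) // 2,
            ))
    return pd.DataFrame([r.__dict__ for r in rows])


def choose_transform(
    table: pd.DataFrame,
    response: str,
    candidates: Sequence[str] = TRANSFORMS,
) -> str:
    """Pick the response transform giving the most normal model residuals.

    Fits the full model under each admissible candidate and selects the one
    maximising the Shapiro–Wilk W of its residuals. ``log`` is skipped (with
    a log message) when the response has non-positive values — JND responses
    may legitimately be zero — and ``sqrt`` when negatives are present.
    Deterministic given the data.
    """
    y = table.loc[table.get("role", "fish") == "fish", response] \
        if "role" in table.columns else table[response]
    y = y.to_numpy(float)
    if np.ptp(y) == 0:
        raise ValueError(f"response {response!r} is constant; no transform "
                         "selection possible")
    best_w, best = -np.inf, None
    for cand in candidates:
        if cand == "log" and (y <= 0).any():
            logger.info("transform selection: skipping log for %s "
                        "(non-positive values present)", response)
            continue
        if cand == "sqrt" and (y < 0).any():
            logger.info("transform selection: skipping sqrt for %s "
                        "(negative values present)", response)
            continue
        fit = fit_lmm(table, ModelSpec(response=response, transform=cand))
        resid = np.asarray(fit.result.resid)
        if len(resid) > 5000:  # Shapiro–Wilk validity limit
            resid = resid[:: len(resid) // 5000 + 1]
        w = float(stats.shapiro(resid).statistic)
        if w > best_w:
            best_w, best = w, cand
    if best is None:
        raise ValueError(f"no admissible transform for response {response!r}")
    return best


def compare_models_aic(
    table: pd.DataFrame,
    specs: Sequence[ModelSpec],
) -> pd.DataFrame:
    """Rank candidate fixed-effect structures by AIC.

    Every candidate is (re)fitted by maximum likelihood — REML fits with
    different fixed effects are not comparable — and ranked ascending by
    AIC = −2 logLik + 2k, with ΔAIC relative to the best model.
    """
    if not specs:
        raise ValueError("need at least one candidate spec")
    rows = []
    for spec in specs:
        fit = fit_lmm(table, spec, reml=False)
        rows.append({"model": spec.label(), "spec": spec, "aic": fit.aic(),
                     "loglik": float(fit.result.llf),
                     "k": len(fit.beta) + 2})
    out = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    out["delta_aic"] = out["aic"] - out["aic"].iloc[0]
    return out
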