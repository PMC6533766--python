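"""Longitudinal statistics for per-CpG methylation time courses.

Per site, methylation (percent) is modelled with a random-intercept linear
mixed model,

    level_ij = beta_0 + sum_t beta_t * 1[time_ij = t] + u_i + eps_ij,
    u_i ~ N(0, sigma_u^2),   eps_ij ~ N(0, sigma_e^2),

with time categorical and baseline (0 h) the reference.  The omnibus test
of a treatment effect is the Wald chi-square over all time coefficients,
b' Cov(b)^-1 b ~ chi2(#timepoints - 1) under the null; q-values are
Benjamini-Hochberg across all sites in a batch.  Post-hoc per-time-point
contrasts refit the model on the {baseline, t} subset; a differentially
methylated CpG (DMC) requires q <= fdr AND |delta| >= delta_threshold at a
time point whose contrast p <= 0.05.

Variance components are estimated by REML except where AIC comparisons
require maximum likelihood (stepwise covariate selection).  The same
machinery provides genotype additive/interaction models, simulation-based
power (set the tested coefficients to the minimum effect of interest,
simulate from the fitted variance components, refit), a parametric
bootstrap for fixed effects, an exact binomial test of cross-study
direction concordance, and efficiency-calibrated qPCR expression ratios.

The response need not be methylation: hormone or transcript time courses
fit with the same omnibus model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "TimeFit",
    "DMCResult",
    "GenotypeResult",
    "PowerResult",
    "BootstrapResult",
    "fit_time_model",
    "posthoc_contrasts",
    "bh_fdr",
    "call_dmcs",
    "dmc_analysis",
    "fit_covariate_model",
    "stepwise_aic",
    "fit_genotype_model",
    "power_sim",
    "parametric_bootstrap",
    "concordance_test",
    "relative_expression",
    "series_from_matrix",
]


def _prepare(df: pd.DataFrame) -> pd.DataFrame:
    d = df.copy()
    d["time_h"] = d["time_h"].astype(float)
    if d["time_h"].nunique() < 2:
        raise ValueError("need at least two time levels")
    if d["subject"].nunique() < 2:
        raise ValueError("need at least two subjects")
    return d.sort_values(["subject", "time_h"], kind="stable").reset_index(drop=True)


def _time_formula(extra: str = "") -> str:
    return "level ~ C(time_h, Treatment(0.0))" + extra


def _fit_mixedlm(formula: str, data: pd.DataFrame, reml: bool = True):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = smf.mixedlm(formula, data, groups=data["subject"])
        try:
            return model.fit(reml=reml)
        except np.linalg.LinAlgError:
            # boundary cases (sigma_u ~ 0) can defeat the default optimizer
            return model.fit(reml=reml, method="powell")


def _time_param_names(res) -> list[str]:
    return [
        n for n in res.fe_params.index if n.startswith("C(time_h") and ":" not in n
    ]


def _term_time(name: str) -> float | None:
    """Parse the time level out of a treatment-coded term name."""
    if "[T." not in name:
        return None
    frag = name.split("[T.", 1)[1].split("]", 1)[0]
    try:
        return float(frag)
    except ValueError:
        return None


def _time_term_name(index, t: float) -> str | None:
    for n in index:
        if ":" in n:
            continue
        tt = _term_time(n)
        if tt is not None and tt == float(t):
            return n
    return None


@dataclass
class TimeFit:
    """Omnibus random-intercept fit of one response time course."""

    params: pd.Series
    cov_params: pd.DataFrame
    chi2: float
    df: int
    p: float
    sigma_u2: float  # subject (random intercept) variance
    sigma_e2: float  # residual variance
    llf: float
    converged: bool
    n_obs: int
    times: tuple[float, ...]
    data: pd.DataFrame = field(repr=False, default=None)
    result: object = field(repr=False, default=None)

    @property
    def time_coefficients(self) -> pd.Series:
        return self.params[[n for n in self.params.index if n.startswith("C(time_h")]]


def _wald_chi2(res, names: list[str]) -> tuple[float, int, float]:
    b = res.fe_params[names].to_numpy()
    V = res.cov_params().loc[names, names].to_numpy()
    chi2 = float(b @ np.linalg.solve(V, b))
    df = len(names)
    return chi2, df, float(stats.chi2.sf(chi2, df))


def fit_time_model(series: pd.DataFrame, reml: bool = True) -> TimeFit:
    """Fit the omnibus time-effect model to one site's series.

    ``series`` needs columns ``subject``, ``time_h`` and ``level``
    (percent).  Unbalanced data (missing subject x time cells) are
    allowed.  Non-convergence yields a TimeFit flagged ``converged=False``
    with NaN statistics rather than an exception; a single-timepoint
    design raises ``ValueError``.
    """
    d = _prepare(series)
    try:
        res = _fit_mixedlm(_time_formula(), d, reml=reml)
    except (np.linalg.LinAlgError, ValueError):
        # degenerate data (e.g. zero-variance response): flagged, NA stats
        n_t = d["time_h"].nunique()
        return TimeFit(
            params=pd.Series(dtype=float),
            cov_params=pd.DataFrame(),
            chi2=float("nan"),
            df=n_t - 1,
            p=float("nan"),
            sigma_u2=float("nan"),
            sigma_e2=float("nan"),
            llf=float("nan"),
            converged=False,
            n_obs=len(d),
            times=tuple(sorted(d["time_h"].unique())),
            data=d,
            result=None,
        )
    names = _time_param_names(res)
    sigma_u2 = float(np.asarray(res.cov_re).ravel()[0])
    if sigma_u2 < 0:
        sigma_u2 = 0.0
    if res.converged:
        chi2, dof, p = _wald_chi2(res, names)
    else:
        chi2, dof, p = float("nan"), len(names), float("nan")
    return TimeFit(
        params=res.fe_params,
        cov_params=res.cov_params().loc[res.fe_params.index, res.fe_params.index],
        chi2=chi2,
        df=dof,
        p=p,
        sigma_u2=sigma_u2,
        sigma_e2=float(res.scale),
        llf=float(res.llf),
        converged=bool(res.converged),
        n_obs=len(d),
        times=tuple(sorted(d["time_h"].unique())),
        data=d,
        result=res,
    )


def posthoc_contrasts(series: pd.DataFrame) -> pd.DataFrame:
    """Per-time-point contrast against baseline via pairwise refits.

    For each t > 0 the random-intercept model is refit on the
    {baseline, t} subset; ``delta_pct`` is the model estimate of the mean
    shift (percentage points) and ``contrast_p`` its Wald p-value.
    """
    d = _prepare(series)
    base = min(d["time_h"].unique())
    rows = []
    for t in sorted(d["time_h"].unique()):
        if t == base:
            continue
        sub = d[d["time_h"].isin([base, t])]
        try:
            res = _fit_mixedlm(_time_formula(), sub, reml=True)
            name = _time_param_names(res)[0]
            delta = float(res.fe_params[name])
            se = float(np.sqrt(res.cov_params().loc[name, name]))
            p = float(stats.chi2.sf((delta / se) ** 2, 1)) if se > 0 else 0.0
        except Exception:
            delta, p = float("nan"), float("nan")
        rows.append((t, delta, p))
    return pd.DataFrame(rows, columns=["time_h", "delta_pct", "contrast_p"])


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_dmcs(
    results: pd.DataFrame,
    fdr_threshold: float = 0.05,
    delta_threshold: float = 1.0,
) -> pd.DataFrame:
    """Flag DMCs on a per-site results table.

    Expects columns ``q_value`` and per-time-point ``delta_<t>`` /
    ``p_<t>`` pairs.  ``max_abs_delta`` is taken over time points whose
    contrast p <= 0.05 only; ``is_dmc`` requires q <= fdr AND
    max_abs_delta >= delta_threshold.
    """
    out = results.copy()
    delta_cols = [c for c in out.columns if c.startswith("delta_")]
    maxes = []
    for _, row in out.iterrows():
        best = float("nan")
        for dc in delta_cols:
            pc = "p_" + dc[len("delta_") :]
            if pc in out.columns and row[pc] <= 0.05:
                v = abs(row[dc])
                if np.isnan(best) or v > best:
                    best = v
        maxes.append(best)
    out["max_abs_delta"] = maxes
    out["is_dmc"] = (
        (out["q_value"] <= fdr_threshold)
        & (~out["max_abs_delta"].isna())
        & (out["max_abs_delta"] >= delta_threshold)
    )
    return out


def series_from_matrix(
    matrix, sample_sheet: pd.DataFrame, context: str = "CpG"
):
    """Yield (cpg_id, series DataFrame) joining calls with the design."""
    sheet = sample_sheet.copy()
    calls = matrix.data[matrix.data["context"] == context]
    merged = calls.merge(sheet, on="sample_id", how="inner")
    merged = merged.rename(columns={"subject_id": "subject"})
    for cpg_id, g in merged.groupby("cpg_id", sort=True):
        yield cpg_id, g


def dmc_analysis(
    matrix,
    sample_sheet: pd.DataFrame,
    fdr_threshold: float = 0.05,
    delta_threshold: float = 1.0,
    posthoc_all: bool = False,
) -> pd.DataFrame:
    """Run the full DMC pipeline over a filtered call matrix.

    Omnibus fit per CpG, BH-FDR across all tested CpGs, post-hoc
    per-time-point contrasts for sites passing the FDR cut (or all sites
    with ``posthoc_all``), then the DMC rule.  Returns one row per site.
    """
    fits: dict[str, TimeFit] = {}
    rows = []
    for cpg_id, series in series_from_matrix(matrix, sample_sheet):
        if series["time_h"].nunique() < 2 or series["subject"].nunique() < 2:
            continue
        fit = fit_time_model(series)
        fits[cpg_id] = fit
        rows.append((cpg_id, fit.chi2, fit.df, fit.p, fit.converged))
    res = pd.DataFrame(
        rows, columns=["cpg_id", "omnibus_chi2", "omnibus_df", "omnibus_p", "converged"]
    )
    if res.empty:
        return res
    ok = res["omnibus_p"].notna()
    res["q_value"] = np.nan
    res.loc[ok, "q_value"] = bh_fdr(res.loc[ok, "omnibus_p"].to_numpy())

    times = sorted({t for f in fits.values() for t in f.times})[1:]
    for t in times:
        res[f"delta_{t:g}"] = np.nan
        res[f"p_{t:g}"] = np.nan
    for i, row in res.iterrows():
        if not posthoc_all and not (row["q_value"] <= fdr_threshold):
            continue
        fit = fits[row["cpg_id"]]
        ph = posthoc_contrasts(fit.data)
        for _, r in ph.iterrows():
            res.loc[i, f"delta_{r['time_h']:g}"] = r["delta_pct"]
            res.loc[i, f"p_{r['time_h']:g}"] = r["contrast_p"]
    return call_dmcs(res, fdr_threshold, delta_threshold)


@dataclass
class CovariateFit:
    params: pd.Series
    pvalues: pd.Series
    covariate_p: dict[str, float]
    coefficient_ratio: dict[str, float]
    dropped: list[str]
    omnibus_time: tuple[float, int, float]


def fit_covariate_model(
    series: pd.DataFrame,
    covariates: list[str],
    standardize: bool = False,
    ratio_time: float = 3.0,
) -> CovariateFit:
    """Random-intercept model with time plus covariates.

    With ``standardize`` continuous predictors are z-scored before the fit
    (the outcome is left on its own scale); Wald p-values are invariant to
    this rescaling.  ``coefficient_ratio`` reports
    ``|coef(time = ratio_time)| / |coef(covariate)|`` — how much larger
    the treatment shift is than the covariate effect on comparable
    scales.  Constant covariates are dropped with a warning.
    """
    d = _prepare(series)
    kept, dropped = [], []
    for cov in covariates:
        x = d[cov]
        if not np.issubdtype(x.dtype, np.number):
            codes, _ = pd.factorize(x, sort=True)
            d[cov] = codes.astype(float)
            x = d[cov]
        if x.nunique() <= 1:
            dropped.append(cov)
            warnings.warn(f"covariate {cov!r} is constant; dropped", stacklevel=2)
            continue
        if standardize:
            d[cov] = (x - x.mean()) / x.std(ddof=0)
        kept.append(cov)
    formula = _time_formula("".join(f" + {c}" for c in kept))
    res = _fit_mixedlm(formula, d, reml=True)
    names = _time_param_names(res)
    cov_p = {}
    for c in kept:
        se = float(np.sqrt(res.cov_params().loc[c, c]))
        cov_p[c] = float(stats.chi2.sf((res.fe_params[c] / se) ** 2, 1))
    tname = _time_term_name(names, ratio_time)
    ratios = {}
    if tname is not None:
        tcoef = abs(float(res.fe_params[tname]))
        for c in kept:
            denom = abs(float(res.fe_params[c]))
            ratios[c] = tcoef / denom if denom > 0 else float("inf")
    return CovariateFit(
        params=res.fe_params,
        pvalues=res.pvalues[res.fe_params.index],
        covariate_p=cov_p,
        coefficient_ratio=ratios,
        dropped=dropped,
        omnibus_time=_wald_chi2(res, names),
    )


def _ml_aic(formula: str, data: pd.DataFrame) -> tuple[float, object]:
    res = _fit_mixedlm(formula, data, reml=False)
    # fixed effects + random-intercept variance + residual variance
    k = len(res.fe_params) + 2
    return -2.0 * float(res.llf) + 2.0 * k, res


def stepwise_aic(
    series: pd.DataFrame,
    candidates: list[str],
    estimate_time: float = 3.0,
) -> pd.DataFrame:
    """Forward covariate selection by AIC on maximum-likelihood fits.

    Starts from the time-only model and greedily adds the candidate that
    most lowers AIC (-2 max log L + 2k), stopping when no addition helps.
    Returns the evaluation table (model, aic, selected flag, and the
    ``estimate_time`` contrast under each evaluated model).
    """
    d = _prepare(series)
    for cov in list(candidates):
        if not np.issubdtype(d[cov].dtype, np.number):
            d[cov], _ = pd.factorize(d[cov], sort=True)
            d[cov] = d[cov].astype(float)

    def _estimate(res) -> float:
        n = _time_term_name(_time_param_names(res), estimate_time)
        return float(res.fe_params[n]) if n is not None else float("nan")

    selected: list[str] = []
    remaining = list(candidates)
    aic0, res0 = _ml_aic(_time_formula(), d)
    table = [("time_only", aic0, _estimate(res0), True)]
    current = aic0
    while remaining:
        scores = []
        for cov in remaining:
            terms = "".join(f" + {c}" for c in selected + [cov])
            aic, res = _ml_aic(_time_formula(terms), d)
            scores.append((aic, cov, res))
            table.append(
                ("time + " + " + ".join(selected + [cov]), aic, _estimate(res), False)
            )
        scores.sort(key=lambda s: (s[0], s[1]))
        best_aic, best_cov, _ = scores[0]
        if best_aic < current:
            selected.append(best_cov)
            remaining.remove(best_cov)
            current = best_aic
        else:
            break
    df = pd.DataFrame(table, columns=["model", "aic", f"estimate_{estimate_time:g}h", "evaluated_in_path"])
    df["selected_model"] = df["model"] == (
        "time + " + " + ".join(selected) if selected else "time_only"
    )
    df.attrs["selected_covariates"] = selected
    return df


@dataclass
class GenotypeResult:
    """Per-time-point genotype statistics for one site."""

    additive_p: dict[float, float]
    interaction_p: dict[float, float]
    effect_signs: pd.DataFrame  # columns: time_h, group, sign
    interaction_coef: dict[float, float]

    def interaction_sign(self, time_h: float) -> int:
        v = self.interaction_coef.get(time_h, float("nan"))
        return 0 if (np.isnan(v) or v == 0) else int(np.sign(v))


def fit_genotype_model(series: pd.DataFrame) -> GenotypeResult:
    """Additive and interactive risk-allele models per time point.

    ``series`` must carry ``genotype_group`` in {CC, T-carrier} (risk-allele
    carriers CT/TT pooled).  For each post-baseline time point the models
    level ~ time + group and level ~ time * group are fit with random
    intercepts on the {baseline, t} subset; Wald p-values are reported for
    the additive group term and the interaction term, together with the
    sign of each group's within-group delta.
    """
    d = _prepare(series)
    d["group"] = (d["genotype_group"] != "CC").astype(float)  # 1 = T-carrier
    if d["group"].nunique() < 2:
        raise ValueError("genotype not estimable: only one genotype group present")
    base = min(d["time_h"].unique())
    additive_p, interaction_p, inter_coef = {}, {}, {}
    sign_rows = []
    for t in sorted(d["time_h"].unique()):
        if t == base:
            continue
        sub = d[d["time_h"].isin([base, t])]
        res_add = _fit_mixedlm(_time_formula(" + group"), sub, reml=True)
        se = float(np.sqrt(res_add.cov_params().loc["group", "group"]))
        additive_p[t] = float(
            stats.chi2.sf((res_add.fe_params["group"] / se) ** 2, 1)
        )
        res_int = _fit_mixedlm(
            _time_formula(" + group + C(time_h, Treatment(0.0)):group"),
            sub,
            reml=True,
        )
        iname = next(
            n for n in res_int.fe_params.index if ":group" in n and "C(time_h" in n
        )
        coef = float(res_int.fe_params[iname])
        se_i = float(np.sqrt(res_int.cov_params().loc[iname, iname]))
        interaction_p[t] = (
            float(stats.chi2.sf((coef / se_i) ** 2, 1)) if se_i > 0 else float("nan")
        )
        inter_coef[t] = coef
        for gname, gmask in (("CC", d["group"] == 0), ("T-carrier", d["group"] == 1)):
            gsub = d[gmask]
            delta = (
                gsub.loc[gsub["time_h"] == t, "level"].mean()
                - gsub.loc[gsub["time_h"] == base, "level"].mean()
            )
            sign_rows.append((t, gname, 0 if delta == 0 else int(np.sign(delta))))
    return GenotypeResult(
        additive_p,
        interaction_p,
        pd.DataFrame(sign_rows, columns=["time_h", "group", "sign"]),
        inter_coef,
    )


@dataclass
class PowerResult:
    power: float
    ci_low: float
    ci_high: float
    n_sim: int
    alpha: float
    min_effect_pct: float


def _simulate_response(fit: TimeFit, beta: pd.Series, rng) -> np.ndarray:
    """Draw a response vector from the random-intercept model."""
    d = fit.data
    X = pd.get_dummies(
        pd.Categorical(d["time_h"], categories=list(fit.times)), drop_first=True
    ).to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(d)), X])
    mu = X @ beta.to_numpy()
    subjects, idx = np.unique(d["subject"], return_inverse=True)
    u = rng.normal(0.0, np.sqrt(fit.sigma_u2), len(subjects))
    eps = rng.normal(0.0, np.sqrt(fit.sigma_e2), len(d))
    return mu + u[idx] + eps


def power_sim(
    fit: TimeFit,
    test_times: list[float] | None = None,
    min_effect_pct: float = 1.0,
    n_sim: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    n_boot: int = 1000,
) -> PowerResult:
    """Simulation-based power for the time effect at a minimum effect size.

    The coefficients of ``test_times`` (default: the 3 h and 6 h contrasts
    when present, else the peak non-baseline time) are set to
    ``min_effect_pct``; responses are simulated from the fitted variance
    components, the model refit, and power is the fraction of simulations
    whose Wald test over the tested coefficients has p <= alpha.  The 95%
    CI is a binomial bootstrap over the simulation outcomes.
    """
    if not fit.converged:
        raise ValueError("power_sim requires a converged fit")
    times = list(fit.times)
    if test_times is None:
        test_times = [t for t in (3.0, 6.0) if t in times] or [times[-1]]
    beta = fit.params.copy()
    names = []
    for t in test_times:
        name = _time_term_name(beta.index, t)
        if name is None:
            raise ValueError(f"no time coefficient for t={t}")
        beta[name] = min_effect_pct
        names.append(name)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9B0E]))
    d = fit.data.copy()
    hits = np.zeros(n_sim, dtype=bool)
    for s in range(n_sim):
        d["level"] = _simulate_response(fit, beta, rng)
        try:
            res = _fit_mixedlm(_time_formula(), d, reml=True)
            _, _, p = _wald_chi2(res, names)
            hits[s] = p <= alpha
        except Exception:
            hits[s] = False
    power = float(hits.mean())
    boot = rng.choice(hits.astype(float), size=(n_boot, n_sim), replace=True).mean(axis=1)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return PowerResult(power, float(lo), float(hi), n_sim, alpha, min_effect_pct)


@dataclass
class BootstrapResult:
    estimate: pd.Series
    bias: pd.Series
    se: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    n_sim: int
    n_failed: int
    reliable: bool


def parametric_bootstrap(
    fit: TimeFit, n_sim: int = 100, seed: int = 0
) -> BootstrapResult:
    """Simulate-from-model bootstrap of the fixed effects.

    Reports bias (mean of bootstrap estimates minus the original
    estimate), the bootstrap SE and 2.5/97.5 percentile intervals per
    fixed effect.  Flagged unreliable if more than 20% of refits fail.
    """
    if not fit.converged:
        raise ValueError("parametric_bootstrap requires a converged fit")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB007]))
    d = fit.data.copy()
    draws = []
    n_failed = 0
    for _ in range(n_sim):
        d["level"] = _simulate_response(fit, fit.params, rng)
        try:
            res = _fit_mixedlm(_time_formula(), d, reml=True)
            if not res.converged:
                raise RuntimeError("refit did not converge")
            draws.append(res.fe_params)
        except Exception:
            n_failed += 1
    boot = pd.DataFrame(draws)
    est = fit.params
    bias = boot.mean() - est
    se = boot.std(ddof=1)
    ci_low = boot.quantile(0.025)
    ci_high = boot.quantile(0.975)
    return BootstrapResult(
        estimate=est,
        bias=bias[est.index],
        se=se[est.index],
        ci_low=ci_low[est.index],
        ci_high=ci_high[est.index],
        n_sim=n_sim,
        n_failed=n_failed,
        reliable=n_failed <= 0.2 * n_sim,
    )


def concordance_test(signs_a, signs_b) -> tuple[int, int, float]:
    """Exact binomial test of cross-study direction concordance.

    Sites where either sign is 0 are excluded.  Returns (n, k, p) where k
    is the number of agreements among n compared sites and p the exact
    upper-tail probability P(X >= k), X ~ Binomial(n, 1/2) — the chance of
    observing this many or more concordant directions if direction were a
    coin flip per site.
    """
    a = np.asarray(signs_a, dtype=float)
    b = np.asarray(signs_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("sign vectors must have equal length")
    keep = (a != 0) & (b != 0) & ~np.isnan(a) & ~np.isnan(b)
    n = int(keep.sum())
    if n == 0:
        raise ValueError("no comparable sites (all signs zero or missing)")
    k = int((np.sign(a[keep]) == np.sign(b[keep])).sum())
    p = float(stats.binom.sf(k - 1, n, 0.5))
    return n, k, p


def relative_expression(
    ct_target: tuple[float, float],
    ct_ref: tuple[float, float],
    eff_target: float = 2.0,
    eff_ref: float = 2.0,
) -> float:
    """Efficiency-calibrated relative expression from qPCR Ct values.

    ratio = E_t^(Ct_t,control - Ct_t,treated) / E_r^(Ct_r,control - Ct_r,treated)

    with per-assay amplification efficiencies E (2 = perfect doubling;
    physically meaningful values lie in [1, 2]).  The reference gene
    (e.g. YWHAZ) normalises input amounts.
    """
    for nm, e in (("eff_target", eff_target), ("eff_ref", eff_ref)):
        if e <= 0:
            raise ValueError(f"{nm} must be > 0")
    dct_t = ct_target[0] - ct_target[1]
    dct_r = ct_ref[0] - ct_ref[1]
    return float(eff_target**dct_t / eff_ref**dct_r)
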