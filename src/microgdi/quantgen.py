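"""Quantitative-genetic core: INT, REML variance components, heritability,
genotype-by-diet interaction, and genetic/phenotypic correlations.

Model
-----
Observations from an inbred-line panel measured on two diets follow

    y = mu + L + D + L×D + e

with diet D a fixed effect, line L ~ N(0, sigma2_line) and the interaction
L×D ~ N(0, sigma2_lxd) random, and residual e ~ N(0, sigma2_resid). Because
lines are fully inbred, the among-line variance is the total genetic
variance, so per-diet broad-sense heritability is
H2 = sigma2_G / (sigma2_G + sigma2_e) from a one-way random-effects fit
within each diet.

REML is computed directly: the marginal covariance matrix is block-diagonal
by line (line and line-by-diet effects never link observations from
different lines), so the restricted log-likelihood is a sum of small
per-line contributions. Fixed effects are profiled out; the criterion is
optimised over log-variances; the asymptotic covariance of the variance
components — needed for delta-method standard errors on H2 — is the inverse
observed information on the variance scale, obtained by central finite
differences at the optimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import ndtri

logger = logging.getLogger("microgdi")

_VAR_FLOOR = 1e-12
_Z95 = 1.96


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    """REML variance components and their asymptotic covariance.

    ``vcov_components`` is ordered (line, [lxd,] resid); ``sigma_lxd`` is
    None for single-diet fits.
    """

    sigma_line: float
    sigma_resid: float
    sigma_lxd: float | None = None
    fixed_effects: dict = field(default_factory=dict)
    vcov_components: np.ndarray | None = None
    loglik_reml: float = np.nan
    n_lines: int = 0
    n_obs: int = 0
    converged: bool = True

    @property
    def component_vector(self) -> np.ndarray:
        if self.sigma_lxd is None:
            return np.array([self.sigma_line, self.sigma_resid])
        return np.array([self.sigma_line, self.sigma_lxd, self.sigma_resid])


@dataclass
class HeritabilityEstimate:
    h2: float
    se: float
    ci_low: float
    ci_high: float


@dataclass
class CorrelationEstimate:
    rho: float
    se: float
    ci_low: float
    ci_high: float
    kind: str
    n_units: int
    flag: str | None = None


@dataclass
class GdiTestResult:
    statistic: float
    p_value: float
    method: str
    df_description: str


# ---------------------------------------------------------------------------
# rank-based inverse normal transformation
# ---------------------------------------------------------------------------

def int_transform(values) -> np.ndarray:
    """Rank-based inverse normal transformation Phi^-1((rank - 0.5) / n).

    Ties receive average ranks; the output is monotone in the input and has
    sample mean 0 for tie-free data.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("int_transform needs a 1-D vector with n >= 2")
    if not np.isfinite(v).all():
        raise ValueError("non-finite values")
    ranks = stats.rankdata(v, method="average")
    return ndtri((ranks - 0.5) / len(v))


# ---------------------------------------------------------------------------
# REML engine (block-diagonal by line)
# ---------------------------------------------------------------------------

class _LineBlocks:
    """Per-line data grouped by within-line design pattern.

    Lines whose within-line diet pattern is identical share the same
    marginal covariance block, so each likelihood evaluation computes one
    small inverse per pattern and applies it to all matching lines.
    """

    def __init__(self, obs: pd.DataFrame, two_diet: bool, interaction: bool):
        self.two_diet = two_diet
        self.interaction = interaction
        self.p = 2 if two_diet else 1
        diets = sorted(obs["diet"].unique())
        if two_diet and len(diets) != 2:
            raise ValueError("two-diet model requires exactly two diets")
        diet_code = {d: i for i, d in enumerate(diets)}
        self.diet_levels = diets

        patterns: dict[tuple, dict] = {}
        self.n_obs = 0
        self.n_lines = obs["line_id"].nunique()
        for _, sub in obs.groupby("line_id", observed=True):
            codes = tuple(sorted(diet_code[d] for d in sub["diet"]))
            y = sub.sort_values("diet", kind="stable")["value"].to_numpy(float)
            pat = patterns.setdefault(codes, {"ys": []})
            pat["ys"].append(y)
            self.n_obs += len(y)

        self.patterns = []
        for codes, pat in patterns.items():
            m = len(codes)
            d = np.array(codes)
            x = np.ones((m, self.p))
            if two_diet:
                x[:, 1] = d  # contrast: second diet level vs first
            same_diet = (d[:, None] == d[None, :]).astype(float)
            self.patterns.append(
                {
                    "Y": np.array(pat["ys"]),  # (lines_in_pattern, m)
                    "X": x,
                    "J": np.ones((m, m)),
                    "B": same_diet,
                    "I": np.eye(m),
                }
            )

    def _cov_block(self, theta, pat):
        if self.two_diet and self.interaction:
            s_l, s_lxd, s_e = theta
            return s_l * pat["J"] + s_lxd * pat["B"] + s_e * pat["I"]
        s_l, s_e = theta[0], theta[-1]
        return s_l * pat["J"] + s_e * pat["I"]

    def neg2_loglik(self, theta, reml: bool = True):
        """-2 log-likelihood (REML or profile ML), full constants included."""
        p = self.p
        a_mat = np.zeros((p, p))
        b_vec = np.zeros(p)
        logdet = 0.0
        quad = 0.0
        for pat in self.patterns:
            v = self._cov_block(theta, pat)
            try:
                l_chol = np.linalg.cholesky(v)
            except np.linalg.LinAlgError:
                return np.inf
            n_rep = pat["Y"].shape[0]
            logdet += 2.0 * n_rep * np.log(np.diag(l_chol)).sum()
            vinv_x = np.linalg.solve(v, pat["X"])
            a_mat += n_rep * pat["X"].T @ vinv_x
            wy = np.linalg.solve(l_chol, pat["Y"].T)  # (m, n_rep)
            quad += float((wy**2).sum())
            b_vec += vinv_x.T @ pat["Y"].sum(axis=0)
        sign, logdet_a = np.linalg.slogdet(a_mat)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(a_mat, b_vec)
        rss = quad - b_vec @ beta
        n = self.n_obs
        if reml:
            return logdet + logdet_a + rss + (n - p) * np.log(2 * np.pi)
        return logdet + rss + n * np.log(2 * np.pi)

    def beta_hat(self, theta):
        p = self.p
        a_mat = np.zeros((p, p))
        b_vec = np.zeros(p)
        for pat in self.patterns:
            vinv_x = np.linalg.solve(self._cov_block(theta, pat), pat["X"])
            a_mat += pat["Y"].shape[0] * pat["X"].T @ vinv_x
            b_vec += vinv_x.T @ pat["Y"].sum(axis=0)
        return np.linalg.solve(a_mat, b_vec)


def _anova_moments(obs: pd.DataFrame, two_diet: bool):
    """Method-of-moments starting values from (approximately) balanced ANOVA."""
    total_var = float(np.var(obs["value"], ddof=1)) if len(obs) > 1 else 1.0
    total_var = max(total_var, 1e-8)
    cell = obs.groupby(["line_id", "diet"], observed=True)["value"]
    within = float(cell.var(ddof=1).mean())
    if not np.isfinite(within) or within <= 0:
        within = 0.5 * total_var
    r_bar = max(float(cell.size().mean()), 1.0)
    line_means = obs.groupby("line_id", observed=True)["value"].mean()
    between = float(line_means.var(ddof=1))
    if two_diet:
        cm = obs.groupby(["line_id", "diet"], observed=True)["value"].mean().unstack()
        cm = cm.dropna()
        if cm.shape[0] >= 3 and cm.shape[1] == 2:
            cov_ld = float(np.cov(cm.iloc[:, 0], cm.iloc[:, 1])[0, 1])
            var_ld = float(cm.var(ddof=1).mean())
        else:
            cov_ld, var_ld = 0.5 * between, between
        s_line = max(cov_ld, 1e-4 * total_var)
        s_lxd = max(var_ld - cov_ld - within / r_bar, 1e-4 * total_var)
        return np.array([s_line, s_lxd, within])
    s_line = max(between - within / r_bar, 1e-4 * total_var)
    return np.array([s_line, within])


def _optimize_reml(blocks: _LineBlocks, start: np.ndarray):
    scale = max(float(start.sum()), 1e-6)
    starts = [start, np.full_like(start, scale / len(start)),
              np.full_like(start, scale)]
    best = None
    prev_fun = None
    log_floor = np.log(_VAR_FLOOR)
    for s0 in starts:
        x0 = np.log(np.clip(s0, _VAR_FLOOR, None))
        res = optimize.minimize(
            lambda x: blocks.neg2_loglik(np.exp(x)),
            x0,
            method="Nelder-Mead",
            bounds=[(log_floor, None)] * len(x0),
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
        # two independent starts landing on the same optimum is enough
        if prev_fun is not None and abs(res.fun - prev_fun) < 1e-9:
            break
        prev_fun = res.fun
    theta = np.exp(best.x)
    theta[theta <= 2 * _VAR_FLOOR] = 0.0
    return theta, -0.5 * best.fun, bool(best.success)


def _observed_information_vcov(blocks: _LineBlocks, theta: np.ndarray):
    """Inverse observed information on the variance scale (central FD)."""
    k = len(theta)
    floor = 1e-10
    th = np.clip(theta, floor, None)
    h = np.maximum(1e-5 * np.maximum(th, th.sum() / k), 1e-8)

    def f(t):
        return 0.5 * blocks.neg2_loglik(np.clip(t, floor, None))

    hess = np.zeros((k, k))
    f0 = f(th)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            if i == j:
                hess[i, i] = (f(th + ei) - 2 * f0 + f(th - ei)) / h[i] ** 2
            else:
                hess[i, j] = hess[j, i] = (
                    f(th + ei + ej) - f(th + ei - ej)
                    - f(th - ei + ej) + f(th - ei - ej)
                ) / (4 * h[i] * h[j])
    try:
        vcov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(hess)
    if not np.all(np.isfinite(vcov)):
        vcov = np.linalg.pinv(hess)
    return vcov


def _validate_obs(obs: pd.DataFrame):
    required = {"line_id", "diet", "value"}
    if not required.issubset(obs.columns):
        raise ValueError(f"trait observations need columns {sorted(required)}")
    if not np.isfinite(obs["value"].to_numpy(float)).all():
        raise ValueError("non-finite trait values")
    if obs["line_id"].nunique() < 2:
        raise ValueError("at least 2 lines required")


def fit_mixed_two_diet(obs: pd.DataFrame, interaction: bool = True) -> VarianceComponents:
    """REML fit of the two-diet mixed model.

    Diet is fixed; line and (optionally) line-by-diet are random. Returns
    variance components in the order (line, lxd, resid) with their
    asymptotic covariance from the inverse observed information.
    """
    _validate_obs(obs)
    blocks = _LineBlocks(obs, two_diet=True, interaction=interaction)
    per_line_diets = obs.groupby("line_id", observed=True)["diet"].nunique()
    if (per_line_diets == 2).sum() < 2:
        raise ValueError("need >= 2 lines observed on both diets")
    start = _anova_moments(obs, two_diet=True)
    if not interaction:
        start = start[[0, 2]]
    theta, loglik, ok = _optimize_reml(blocks, start)
    vcov = _observed_information_vcov(blocks, theta)
    beta = blocks.beta_hat(np.clip(theta, 1e-10, None))
    fixed = {"intercept": float(beta[0]),
             f"diet[{blocks.diet_levels[1]}-{blocks.diet_levels[0]}]": float(beta[1])}
    if interaction:
        return VarianceComponents(
            sigma_line=float(theta[0]), sigma_lxd=float(theta[1]),
            sigma_resid=float(theta[2]), fixed_effects=fixed,
            vcov_components=vcov, loglik_reml=loglik,
            n_lines=blocks.n_lines, n_obs=blocks.n_obs, converged=ok,
        )
    return VarianceComponents(
        sigma_line=float(theta[0]), sigma_resid=float(theta[1]),
        fixed_effects=fixed, vcov_components=vcov, loglik_reml=loglik,
        n_lines=blocks.n_lines, n_obs=blocks.n_obs, converged=ok,
    )


def fit_mixed_single_diet(obs: pd.DataFrame) -> VarianceComponents:
    """One-way random-effects REML within a single diet.

    ``sigma_line`` is the genetic variance sigma2_G; ``sigma_resid`` the
    environmental variance sigma2_e. The 2x2 ``vcov_components`` feeds the
    delta-method standard error of H2.
    """
    _validate_obs(obs)
    if obs["diet"].nunique() != 1:
        raise ValueError("single-diet fit requires exactly one diet")
    if len(obs) - obs["line_id"].nunique() < 1:
        raise ValueError("residual variance unidentifiable: one observation per line")
    blocks = _LineBlocks(obs, two_diet=False, interaction=False)
    start = _anova_moments(obs, two_diet=False)
    theta, loglik, ok = _optimize_reml(blocks, start)
    vcov = _observed_information_vcov(blocks, theta)
    beta = blocks.beta_hat(np.clip(theta, 1e-10, None))
    return VarianceComponents(
        sigma_line=float(theta[0]), sigma_resid=float(theta[1]),
        fixed_effects={"intercept": float(beta[0])},
        vcov_components=vcov, loglik_reml=loglik,
        n_lines=blocks.n_lines, n_obs=blocks.n_obs, converged=ok,
    )


# ---------------------------------------------------------------------------
# heritability
# ---------------------------------------------------------------------------

def heritability_from_components(
    sigma_g2: float, sigma_e2: float, vcov: np.ndarray | None = None
) -> HeritabilityEstimate:
    """H2 = sigma2_G / (sigma2_G + sigma2_e) with delta-method SE.

    ``vcov`` is the 2x2 asymptotic covariance of (sigma2_G, sigma2_e); when
    absent the SE and CI are NaN. The CI is H2 +- 1.96 SE and may exceed
    [0, 1], as asymptotic intervals on a ratio do.
    """
    tot = sigma_g2 + sigma_e2
    if tot <= 0:
        raise ValueError("zero total variance")
    h2 = sigma_g2 / tot
    if vcov is None:
        return HeritabilityEstimate(h2, np.nan, np.nan, np.nan)
    dg = sigma_e2 / tot**2
    de = -sigma_g2 / tot**2
    var = (
        dg**2 * vcov[0, 0] + de**2 * vcov[1, 1] + 2 * dg * de * vcov[0, 1]
    )
    se = float(np.sqrt(max(var, 0.0)))
    return HeritabilityEstimate(h2, se, h2 - _Z95 * se, h2 + _Z95 * se)


def heritability(vc: VarianceComponents) -> HeritabilityEstimate:
    """Broad-sense heritability from a fitted variance-component object.

    Uses the line and residual components; for a three-component (two-diet)
    fit the corresponding rows of the asymptotic covariance are selected.
    """
    if vc.sigma_lxd is None:
        idx = [0, 1]
    else:
        idx = [0, 2]
    vcov = None
    if vc.vcov_components is not None:
        vcov = vc.vcov_components[np.ix_(idx, idx)]
    return heritability_from_components(vc.sigma_line, vc.sigma_resid, vcov)


# ---------------------------------------------------------------------------
# genotype-by-diet interaction and diet tests
# ---------------------------------------------------------------------------

def gdi_test(obs: pd.DataFrame, method: str = "mixture") -> GdiTestResult:
    """Likelihood-ratio test of the line-by-diet variance component.

    Compares REML fits with and without the interaction (same fixed
    effects, so REML likelihoods are comparable). Because the null puts
    sigma2_lxd on the boundary, the default reference distribution is the
    half-chi2(0) + half-chi2(1) mixture; ``method='chi2'`` uses plain
    chi2(1).
    """
    full = fit_mixed_two_diet(obs, interaction=True)
    reduced = fit_mixed_two_diet(obs, interaction=False)
    lr = 2.0 * (full.loglik_reml - reduced.loglik_reml)
    if lr < -1e-6:
        logger.warning("gdi_test: reduced model out-fit the full model (lr=%g)", lr)
    lr = max(lr, 0.0)
    if method == "mixture":
        p = 1.0 if lr == 0 else 0.5 * stats.chi2.sf(lr, df=1)
        df_desc = "0.5*chi2(0) + 0.5*chi2(1) boundary mixture"
    elif method == "chi2":
        p = stats.chi2.sf(lr, df=1)
        df_desc = "chi2(1)"
    else:
        raise ValueError("method must be 'mixture' or 'chi2'")
    return GdiTestResult(float(lr), float(p), method, df_desc)


def diet_effect_test(obs: pd.DataFrame, method: str = "lrt"):
    """Test of the fixed diet effect in the two-diet mixed model.

    Default is a likelihood-ratio test on ML fits with and without the diet
    term (random structure kept); ``method='f'`` is the paired comparison of
    per-line diet means (t squared, the balanced-ANOVA F of diet against
    the line-by-diet stratum). Returns (diet contrast, p-value).
    """
    _validate_obs(obs)
    if obs["diet"].nunique() != 2:
        raise ValueError("diet test requires two diets")
    blocks_full = _LineBlocks(obs, two_diet=True, interaction=True)
    start = _anova_moments(obs, two_diet=True)
    contrast = None
    if method == "lrt":
        theta_full, _, _ = _optimize_reml_ml(blocks_full, start)
        ll_full = -0.5 * blocks_full.neg2_loglik(np.clip(theta_full, 1e-12, None), reml=False)
        contrast = float(blocks_full.beta_hat(np.clip(theta_full, 1e-10, None))[1])
        blocks_null = _NullDietBlocks(obs)
        theta_null, _, _ = _optimize_reml_ml(blocks_null, start)
        ll_null = -0.5 * blocks_null.neg2_loglik(np.clip(theta_null, 1e-12, None), reml=False)
        lr = max(0.0, 2.0 * (ll_full - ll_null))
        p = float(stats.chi2.sf(lr, df=1))
        return contrast, p
    if method == "f":
        cm = obs.groupby(["line_id", "diet"], observed=True)["value"].mean().unstack()
        cm = cm.dropna()
        if cm.shape[0] < 3:
            raise ValueError("paired diet test needs >= 3 lines on both diets")
        diff = cm.iloc[:, 1] - cm.iloc[:, 0]
        t_stat, p = stats.ttest_1samp(diff, 0.0)
        return float(diff.mean()), float(p)
    raise ValueError("method must be 'lrt' or 'f'")


class _NullDietBlocks(_LineBlocks):
    """Two-diet random structure with the diet fixed effect removed."""

    def __init__(self, obs):
        super().__init__(obs, two_diet=True, interaction=True)
        self.p = 1
        for pat in self.patterns:
            pat["X"] = pat["X"][:, :1]


def _optimize_reml_ml(blocks, start):
    log_floor = np.log(_VAR_FLOOR)
    best = None
    for s0 in [start, np.full_like(start, max(start.sum(), 1e-6) / len(start))]:
        x0 = np.log(np.clip(s0, _VAR_FLOOR, None))
        res = optimize.minimize(
            lambda x: blocks.neg2_loglik(np.exp(x), reml=False),
            x0,
            method="Nelder-Mead",
            bounds=[(log_floor, None)] * len(x0),
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    theta = np.exp(best.x)
    theta[theta <= 2 * _VAR_FLOOR] = 0.0
    return theta, -0.5 * best.fun, bool(best.success)


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def genetic_correlation_yamada(vc: VarianceComponents) -> CorrelationEstimate:
    """Cross-environment genetic correlation from variance components:
    rho_G = sigma2_line / (sigma2_line + sigma2_lxd).

    Downward-biased when genetic variances differ between environments,
    which motivates the cross-environment covariance form.
    """
    if vc.sigma_lxd is None:
        raise ValueError("Yamada correlation needs a two-diet fit with interaction")
    denom = vc.sigma_line + vc.sigma_lxd
    if denom <= 0:
        raise ValueError("zero genetic + interaction variance")
    rho = vc.sigma_line / denom
    n = vc.n_lines
    se = _corr_se(rho, n)
    return CorrelationEstimate(
        rho, se, rho - _Z95 * se, rho + _Z95 * se, "genetic_yamada", n
    )


def _corr_se(rho: float, n: int) -> float:
    if n <= 3:
        return np.nan
    return float(max(1.0 - rho**2, 0.0) / np.sqrt(n - 3))


def genetic_correlation_cross_env(
    obs: pd.DataFrame,
    diets: tuple | None = None,
    fits: tuple[VarianceComponents, VarianceComponents] | None = None,
) -> CorrelationEstimate:
    """Cross-diet genetic correlation rho_G = cov_G(i,j)/sqrt(V_Gi * V_Gj).

    The per-diet genetic variances come from single-diet REML fits; the
    cross-diet genetic covariance is the sample covariance of per-line
    means across diets (unbiased here: the two diets use different
    individuals, so residual sampling errors are independent between
    diets). The estimate is deliberately not clamped to [-1, 1]; the SE is
    (1 - rho^2)/sqrt(n_lines - 3) and the CI is rho +- 1.96 SE.

    ``fits`` may supply the two per-diet fits (in diet order) when already
    computed; otherwise they are fitted here.
    """
    _validate_obs(obs)
    diets = diets or tuple(sorted(obs["diet"].unique()))
    if len(diets) != 2:
        raise ValueError("cross-environment correlation needs two diets")
    means = (
        obs.groupby(["line_id", "diet"], observed=True)["value"].mean().unstack()
    )[list(diets)].dropna()
    if means.shape[0] < 3:
        raise ValueError("need >= 3 lines observed on both diets")
    if fits is None:
        vc_i = fit_mixed_single_diet(obs[obs["diet"] == diets[0]])
        vc_j = fit_mixed_single_diet(obs[obs["diet"] == diets[1]])
    else:
        vc_i, vc_j = fits
    n = means.shape[0]
    cov_g = float(np.cov(means.iloc[:, 0], means.iloc[:, 1], ddof=1)[0, 1])
    flag = None
    if vc_i.sigma_line <= 0 or vc_j.sigma_line <= 0:
        rho, se = np.nan, np.nan
        flag = "undefined: non-positive genetic variance in a diet"
        return CorrelationEstimate(rho, se, np.nan, np.nan, "genetic_cross_env", n, flag)
    rho = cov_g / np.sqrt(vc_i.sigma_line * vc_j.sigma_line)
    if abs(rho) > 1:
        flag = "estimate outside [-1, 1] (unclamped)"
    se = _corr_se(rho, n)
    return CorrelationEstimate(
        float(rho), se, rho - _Z95 * se, rho + _Z95 * se,
        "genetic_cross_env", n, flag,
    )


def phenotypic_correlation(x, y, n_override: int | None = None) -> CorrelationEstimate:
    """Spearman correlation with Fisher-z confidence interval.

    rho is Spearman's rank correlation (average ranks for ties);
    SE = (1 - rho^2)/sqrt(n - 3); the 95% CI transforms
    z = arctanh(rho) +- 1.96 SE back through tanh. A perfectly monotone
    pair has infinite z; the CI collapses to [rho, rho] and is flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 4:
        raise ValueError("need n >= 4 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.ptp(stats.rankdata(x)) == 0 or np.ptp(stats.rankdata(y)) == 0:
        raise ValueError("zero variance in a ranked vector")
    rho = float(stats.spearmanr(x, y).statistic)
    n = n_override if n_override is not None else len(x)
    se = _corr_se(rho, n)
    if abs(rho) >= 1.0:
        return CorrelationEstimate(
            rho, 0.0, rho, rho, "phenotypic_spearman", n, "degenerate: |rho| = 1"
        )
    z = np.arctanh(rho)
    lo, hi = np.tanh(z - _Z95 * se), np.tanh(z + _Z95 * se)
    return CorrelationEstimate(rho, se, float(lo), float(hi), "phenotypic_spearman", n)
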