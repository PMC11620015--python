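"""Repeatability statistics for repeated CCFD% measurements.

Implements nested random-intercept (variance-components) models for
same-day repeat scans, the repeatability summaries derived from them —

* ICC = (total variance − residual variance) / total variance, where the
  residual is the variance attributable to repeated scans of the same eye;
* MDC95 = sqrt(2) x 1.96 x residual SD, the smallest between-visit change
  distinguishable from measurement noise at 95% confidence;

— parametric-bootstrap confidence intervals for the ICC, linear-mixed-model
group contrasts with Tukey (studentized-range) adjustment, and MDC95-based
significance calls for longitudinal box-level changes.

Balanced designs are fitted in closed form by expected mean squares
(method-of-moments nested ANOVA); unbalanced designs fall back to REML via
derivative-free maximization of the profiled restricted likelihood over
variance ratios.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import studentized_range

logger = logging.getLogger("ccfdgrid")

__all__ = [
    "VarianceComponents",
    "ICCResult",
    "MDCResult",
    "GroupComparison",
    "ChangeAssessment",
    "BalancedDesign",
    "fit_variance_components",
    "compute_icc",
    "bootstrap_icc_ci",
    "compute_mdc95",
    "compare_groups",
    "assess_change",
    "MDC95_FACTOR",
]

#: MDC95 multiplier: sqrt(2) for a difference of two measurements, 1.96 for
#: the 95% two-sided normal quantile.
MDC95_FACTOR = math.sqrt(2.0) * 1.96


@dataclass
class VarianceComponents:
    """Estimated variance components of a nested random-intercept model.

    ``components`` maps each random level (outermost first, e.g. patient,
    eye, box) to its variance; the residual is the repeat-to-repeat scan
    variance.
    """

    components: dict[str, float]
    sigma2_residual: float
    method: str  # "anova_mom" | "reml"
    loglik: float = float("nan")
    n_obs: int = 0

    def __post_init__(self):
        for name, v in self.components.items():
            if v < -1e-12:
                raise ValueError(f"negative variance component {name}: {v}")
        if self.sigma2_residual < 0:
            raise ValueError("negative residual variance")

    @property
    def levels_used(self) -> tuple[str, ...]:
        return tuple(self.components)

    @property
    def total(self) -> float:
        return sum(self.components.values()) + self.sigma2_residual

    @property
    def residual_sd(self) -> float:
        return math.sqrt(self.sigma2_residual)


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    n_failed: int = 0
    unstable: bool = False

    def __post_init__(self):
        if not (self.ci_low <= self.icc <= self.ci_high):
            logger.warning(
                "ICC %.4f outside bootstrap CI (%.4f, %.4f) — boundary case",
                self.icc,
                self.ci_low,
                self.ci_high,
            )


@dataclass(frozen=True)
class MDCResult:
    residual_sd: float
    mdc95: float


@dataclass(frozen=True)
class GroupComparison:
    pair: tuple[str, str]
    estimate: float
    ci_low: float
    ci_high: float
    p_adj: float
    p_unadj: float
    df: float


@dataclass(frozen=True)
class ChangeAssessment:
    box_id: str
    delta_ccfd: float
    mdc95_ref: float
    significant: bool
    role: str  # "target" | "control"


# --------------------------------------------------------------------------
# design handling


@dataclass(frozen=True)
class BalancedDesign:
    """A fully nested balanced design: ``children[i]`` units of level i per
    unit of level i−1 (``children[0]`` = number of top-level units), plus
    ``n_rep`` repeats within the innermost level."""

    level_names: tuple[str, ...]
    children: tuple[int, ...]
    n_rep: int

    @property
    def n_obs(self) -> int:
        return int(np.prod(self.children)) * self.n_rep

    def obs_per_unit(self, i: int) -> int:
        """Observations per level-i unit (0-based, outermost first)."""
        return int(np.prod(self.children[i + 1 :])) * self.n_rep


def _check_balanced(table: pd.DataFrame, levels: list[str], value_col: str):
    """Return a BalancedDesign if the table is fully nested and balanced,
    else None."""
    children = []
    parent_cols: list[str] = []
    for lv in levels:
        group = table.groupby(parent_cols, sort=False)[lv].nunique() if parent_cols else None
        if group is None:
            n = table[lv].nunique()
        else:
            counts = group.unique()
            if len(counts) != 1:
                return None
            n = int(counts[0])
        children.append(n)
        parent_cols = parent_cols + [lv]
    reps = table.groupby(levels, sort=False)[value_col].count()
    if reps.nunique() != 1:
        return None
    return BalancedDesign(tuple(levels), tuple(children), int(reps.iloc[0]))


# --------------------------------------------------------------------------
# method of moments (nested ANOVA, balanced)


def _mom_fit(table: pd.DataFrame, levels: list[str], value_col: str, design: BalancedDesign):
    y = table[value_col].to_numpy(dtype=np.float64)
    grand = y.mean()
    k = len(levels)
    # mean squares from nested group means, outermost to innermost
    ms = []
    dfs = []
    prev_means = None
    for i in range(k):
        cols = levels[: i + 1]
        means = table.groupby(cols, sort=False)[value_col].mean()
        n_per = design.obs_per_unit(i)
        if i == 0:
            ss = n_per * ((means.to_numpy() - grand) ** 2).sum()
            df = len(means) - 1
        else:
            parent = means.groupby(level=list(range(i)), sort=False).transform("mean")
            ss = n_per * ((means - parent).to_numpy() ** 2).sum()
            df = len(means) - means.groupby(level=list(range(i)), sort=False).ngroups
        if df < 1:
            raise ValueError(f"need >=2 units at level '{levels[i]}' to fit its variance")
        ms.append(ss / df)
        dfs.append(df)
    # residual: within innermost units
    inner_means = table.groupby(levels, sort=False)[value_col].transform("mean")
    ss_res = ((y - inner_means.to_numpy()) ** 2).sum()
    df_res = len(y) - int(np.prod(design.children))
    if df_res < 1:
        raise ValueError("need at least 2 repeats somewhere to estimate residual variance")
    ms_res = ss_res / df_res

    comps: dict[str, float] = {}
    ms_next = ms_res
    for i in range(k - 1, -1, -1):
        est = (ms[i] - ms_next) / design.obs_per_unit(i)
        if est < 0:
            logger.warning("negative MoM estimate for %s clamped to 0", levels[i])
            est = 0.0
        comps[levels[i]] = est
        ms_next = ms[i]
    comps = {lv: comps[lv] for lv in levels}  # outermost-first order
    return VarianceComponents(
        components=comps, sigma2_residual=ms_res, method="anova_mom", n_obs=len(y)
    )


# --------------------------------------------------------------------------
# REML (general nested design)


def _reml_neg2loglik(gammas, y, X, z_indices_list, n_levels):
    n, p = X.shape
    V = np.eye(n)
    for g, idx in zip(gammas, z_indices_list):
        # Z Z^T for a grouping factor is block-wise ones over shared units
        V += g * (idx[:, None] == idx[None, :])
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return np.inf, None, None
    logdet_v = 2.0 * np.log(np.diag(L)).sum()
    Vi_y = np.linalg.solve(V, y)
    Vi_X = np.linalg.solve(V, X)
    XtViX = X.T @ Vi_X
    sign, logdet_x = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return np.inf, None, None
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    resid = y - X @ beta
    quad = resid @ np.linalg.solve(V, resid)
    if quad <= 0:
        return np.inf, None, None
    sigma2 = quad / (n - p)
    crit = (n - p) * np.log(sigma2) + logdet_v + logdet_x
    return crit, sigma2, beta


def _reml_fit(
    table: pd.DataFrame,
    levels: list[str],
    value_col: str,
    X: np.ndarray | None = None,
    tol: float = 1e-8,
):
    y = table[value_col].to_numpy(dtype=np.float64)
    n = len(y)
    if X is None:
        X = np.ones((n, 1))
    z_indices = []
    for i, lv in enumerate(levels):
        # nested: unit identity includes all outer levels
        key = table[levels[: i + 1]].astype(str).agg("|".join, axis=1)
        z_indices.append(pd.factorize(key)[0])

    def objective(s):
        gammas = np.asarray(s, dtype=float) ** 2
        crit, _, _ = _reml_neg2loglik(gammas, y, X, z_indices, len(levels))
        return crit

    x0 = np.ones(len(levels))
    res = optimize.minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={"xatol": tol, "fatol": tol, "maxiter": 4000},
    )
    gammas = np.asarray(res.x, dtype=float) ** 2
    crit, sigma2, beta = _reml_neg2loglik(gammas, y, X, z_indices, len(levels))
    comps = {lv: max(0.0, g * sigma2) for lv, g in zip(levels, gammas)}
    vc = VarianceComponents(
        components=comps,
        sigma2_residual=sigma2,
        method="reml",
        loglik=-0.5 * crit,
        n_obs=n,
    )
    return vc, beta, gammas, (y, X, z_indices)


def fit_variance_components(
    table: pd.DataFrame,
    levels: list[str],
    value_col: str = "ccfd_percent",
    method: str = "auto",
) -> VarianceComponents:
    """Fit a nested random-intercept model with the given nesting levels
    (outermost first; e.g. ``["eye_id"]`` or ``["patient_id", "eye_id",
    "roi_id"]``); the residual is the repeat-to-repeat variance.

    Balanced tables use closed-form expected-mean-squares (method of
    moments, ``anova_mom``); unbalanced tables use REML over variance
    ratios.  Null measurements are dropped with a logged count.
    """
    if not levels:
        raise ValueError("at least one nesting level is required")
    work = table.dropna(subset=[value_col])
    dropped = len(table) - len(work)
    if dropped:
        logger.info("dropped %d null %s rows before fitting", dropped, value_col)
    reps = work.groupby(levels, sort=False)[value_col].count()
    if (reps < 2).all():
        raise ValueError("need >=2 repeats for at least one innermost unit")
    design = _check_balanced(work, levels, value_col)
    if method == "auto":
        method = "anova_mom" if design is not None else "reml"
    if method == "anova_mom":
        if design is None:
            raise ValueError("anova_mom requires a balanced nested table")
        return _mom_fit(work, levels, value_col, design)
    vc, _, _, _ = _reml_fit(work, levels, value_col)
    return vc


def compute_icc(vc: VarianceComponents) -> float:
    """ICC = (total variance − residual variance) / total variance."""
    total = vc.total
    if total <= 0:
        raise ValueError("no variance: total variance is zero")
    return float(np.clip((total - vc.sigma2_residual) / total, 0.0, 1.0))


def compute_mdc95(vc: VarianceComponents) -> MDCResult:
    """95% minimal detectable change: sqrt(2) x 1.96 x residual SD."""
    sd = vc.residual_sd
    return MDCResult(residual_sd=sd, mdc95=MDC95_FACTOR * sd)


# --------------------------------------------------------------------------
# parametric bootstrap for the ICC


def _simulate_balanced(vc: VarianceComponents, design: BalancedDesign, rng, size: int):
    """Simulate ``size`` tables from fitted normal components; returns an
    array of shape (size, *units..., n_rep)."""
    shape_units = design.children
    out = np.zeros((size, *shape_units, design.n_rep))
    for i, lv in enumerate(design.level_names):
        sd = math.sqrt(max(vc.components[lv], 0.0))
        eff_shape = (size, *shape_units[: i + 1]) + (1,) * (len(shape_units) - i - 1) + (1,)
        out += sd * rng.standard_normal(eff_shape)
    out += vc.residual_sd * rng.standard_normal(out.shape)
    return out


def _icc_from_arrays(data: np.ndarray, design: BalancedDesign) -> np.ndarray:
    """Vectorized MoM ICC for simulated balanced tables (axis 0 = replicate)."""
    k = len(design.children)
    n_rep = design.n_rep
    inner_means = data.mean(axis=-1)
    ss_res = ((data - inner_means[..., None]) ** 2).sum(axis=tuple(range(1, data.ndim)))
    df_res = int(np.prod(design.children)) * (n_rep - 1)
    ms_res = ss_res / df_res

    ms = []
    means = inner_means  # level-k unit means
    for i in range(k - 1, -1, -1):
        n_per = design.obs_per_unit(i)
        if i == 0:
            parent = means.mean(axis=tuple(range(1, means.ndim)), keepdims=True)
            df = design.children[0] - 1
        else:
            parent = means.mean(axis=-1, keepdims=True)
            df = int(np.prod(design.children[: i + 1])) - int(np.prod(design.children[:i]))
        ss = n_per * ((means - parent) ** 2).sum(axis=tuple(range(1, means.ndim)))
        ms.append((i, ss / df))
        means = means.mean(axis=-1) if i > 0 else means
    ms_by_level = dict(ms)

    comps_sum = np.zeros(data.shape[0])
    ms_next = ms_res
    for i in range(k - 1, -1, -1):
        est = np.maximum((ms_by_level[i] - ms_next) / design.obs_per_unit(i), 0.0)
        comps_sum += est
        ms_next = ms_by_level[i]
    total = comps_sum + ms_res
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = np.where(total > 0, comps_sum / total, np.nan)
    return icc


def bootstrap_icc_ci(
    vc: VarianceComponents,
    design: BalancedDesign,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> ICCResult:
    """Parametric-bootstrap percentile CI for the ICC.

    Tables are simulated from the fitted normal variance components under
    the same balanced design, refitted by nested ANOVA, and the ICC
    percentile interval taken.  Deterministic given ``seed``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if any(c < 2 for c in design.children) or design.n_rep < 2:
        raise ValueError("bootstrap requires >=2 units at every level and >=2 repeats")
    rng = np.random.default_rng(seed)
    icc_hat = compute_icc(vc)
    data = _simulate_balanced(vc, design, rng, n_boot)
    iccs = _icc_from_arrays(data, design)
    ok = np.isfinite(iccs)
    n_failed = int(n_boot - ok.sum())
    unstable = n_failed > 0.05 * n_boot
    if unstable:
        logger.warning("%d/%d bootstrap refits failed", n_failed, n_boot)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(iccs[ok], [alpha, 1.0 - alpha])
    return ICCResult(
        icc=icc_hat,
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        seed=seed,
        n_failed=n_failed,
        unstable=unstable,
    )


# --------------------------------------------------------------------------
# group contrasts (LMM + Tukey)


def compare_groups(
    table: pd.DataFrame,
    levels: tuple[str, ...] = ("eye_id",),
    group_col: str = "group_label",
    value_col: str = "ccfd_percent",
    level: float = 0.95,
    df_method: str = "containment",
) -> list[GroupComparison]:
    """All pairwise group contrasts from a mixed model with a fixed group
    effect and nested random intercepts, Tukey-adjusted via the
    studentized-range distribution.

    The default degrees of freedom are the containment df (number of eyes −
    number of groups), exact for balanced designs where the group-mean
    variance is carried entirely by the between-eye stratum;
    ``df_method="satterthwaite"`` combines the stratum mean squares by
    Satterthwaite's approximation instead.
    """
    levels = list(levels)
    work = table.dropna(subset=[value_col]).copy()
    groups = sorted(work[group_col].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    gidx = work[group_col].map({g: i for i, g in enumerate(groups)}).to_numpy()
    X = np.zeros((len(work), len(groups)))
    X[np.arange(len(work)), gidx] = 1.0  # cell-means coding

    vc, beta, gammas, (y, Xm, z_indices) = _reml_fit(work, levels, value_col, X=X)
    n, p = Xm.shape
    V = np.eye(n)
    for g, idx in zip(gammas, z_indices):
        V += g * (idx[:, None] == idx[None, :])
    XtViX = Xm.T @ np.linalg.solve(V, Xm)
    cov_beta = vc.sigma2_residual * np.linalg.inv(XtViX)

    eye_level = levels[-1] if levels else None
    n_eyes = work.groupby(levels, sort=False).ngroups if levels else len(work)
    k = len(groups)
    if df_method == "containment":
        df = max(n_eyes - k, 1)
    elif df_method == "satterthwaite":
        # combine between-eye and residual strata for the contrast variance
        r = len(work) / max(n_eyes, 1)
        s_eye = sum(vc.components.values())
        num = (s_eye + vc.sigma2_residual / r) ** 2
        den = (s_eye**2) / max(n_eyes - k, 1) + (vc.sigma2_residual / r) ** 2 / max(
            len(work) - n_eyes, 1
        )
        df = max(num / den, 1.0) if den > 0 else max(n_eyes - k, 1)
    else:
        raise ValueError("df_method must be 'containment' or 'satterthwaite'")

    q_crit = studentized_range.ppf(level, k, df)
    out = []
    from scipy.stats import t as t_dist

    for a in range(k):
        for b in range(a + 1, k):
            c = np.zeros(k)
            c[a], c[b] = 1.0, -1.0
            est = float(c @ beta)
            se = float(np.sqrt(c @ cov_beta @ c))
            if se == 0:
                raise ValueError("singular fit: zero contrast standard error")
            q_stat = abs(est) / se * math.sqrt(2.0)
            p_adj = float(studentized_range.sf(q_stat, k, df))
            p_un = float(2.0 * t_dist.sf(abs(est) / se, df))
            half = q_crit / math.sqrt(2.0) * se
            out.append(
                GroupComparison(
                    pair=(groups[a], groups[b]),
                    estimate=est,
                    ci_low=est - half,
                    ci_high=est + half,
                    p_adj=min(1.0, p_adj),
                    p_unadj=p_un,
                    df=float(df),
                )
            )
    return out


# --------------------------------------------------------------------------
# MDC95-based longitudinal change calls


def assess_change(
    baseline: pd.DataFrame,
    followup: pd.DataFrame,
    mdc95_ref: float,
    target_box_id: str,
    roi_col: str = "roi_id",
    value_col: str = "ccfd_percent",
) -> list[ChangeAssessment]:
    """Per-box change between visits, called significant iff the change
    strictly exceeds the MDC95 reference in magnitude.

    The box containing the lesion of interest is tagged ``target``; all
    other boxes serve as internal controls.  Boxes present in only one
    visit are excluded with a warning.
    """
    b = baseline.groupby(roi_col)[value_col].mean()
    f = followup.groupby(roi_col)[value_col].mean()
    only = set(b.index).symmetric_difference(f.index)
    if only:
        logger.warning("boxes present in one visit only, excluded: %s", sorted(only))
    shared = sorted(set(b.index) & set(f.index))
    out = []
    for box in shared:
        delta = float(f[box] - b[box])
        if math.isnan(delta):
            logger.warning("box %s has null measurement, excluded", box)
            continue
        out.append(
            ChangeAssessment(
                box_id=box,
                delta_ccfd=delta,
                mdc95_ref=mdc95_ref,
                significant=abs(delta) > mdc95_ref,
                role="target" if box == target_box_id else "control",
            )
        )
    return out
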