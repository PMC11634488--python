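"""Group-level statistics: limb selection, 1D SPM and adjusted regression.

One limb per participant enters analysis. Symptomatic participants
contribute their self-reported most-symptomatic limb; control participants
are assigned kicking or non-kicking limbs by a seeded random shuffle so that,
within each sex stratum, the proportion of kicking limbs matches the
symptomatic group's proportion as closely as integer counts allow.

Fat-infiltration profiles are compared node-wise with two-sample t statistics
along the 101-node muscle length, with a family-wise critical threshold t*
from either the permutation distribution of the maximum |t| (default) or a
1D random-field-theory approximation with residual smoothness (FWHM)
estimated from normalised residual gradients. Muscle volume is compared with
ordinary least squares adjusted for age, BMI, sport and sex, after screening
a group-by-sex interaction (retained only when its p-value is at most 0.05).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from scipy.optimize import brentq

from .morphometry import N_PROFILE_NODES, MuscleProfile

__all__ = [
    "SPMResult",
    "RegressionResult",
    "select_limbs",
    "spm_ttest",
    "volume_regression",
]

log = logging.getLogger(__name__)


def select_limbs(cohort: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Assign each participant's analysis limb.

    Symptomatic rows keep their reported most-symptomatic limb (never
    altered). For controls, within each sex stratum the number assigned their
    kicking limb is round(p * n) where p is the symptomatic stratum's
    proportion of most-symptomatic limbs that coincide with the kicking limb;
    which controls get the kicking limb is a seeded random permutation. A sex
    stratum with no symptomatic members falls back to the overall proportion
    (logged).
    """
    required = {"group", "sex", "kicking_limb", "symptomatic_limb"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    df = cohort.copy()
    df["selected_limb"] = pd.Series([None] * len(df), dtype=object)

    symp = df["group"] == "symptomatic"
    df.loc[symp, "selected_limb"] = df.loc[symp, "symptomatic_limb"]

    symp_rows = df[symp]
    overall_p = float(
        (symp_rows["symptomatic_limb"] == symp_rows["kicking_limb"]).mean()
    ) if len(symp_rows) else 0.5

    rng = np.random.default_rng(seed)
    for sex, ctrl_idx in df[~symp].groupby("sex").groups.items():
        stratum = symp_rows[symp_rows["sex"] == sex]
        if len(stratum):
            p = float(
                (stratum["symptomatic_limb"] == stratum["kicking_limb"]).mean()
            )
        else:
            p = overall_p
            log.warning(
                "sex stratum %r absent in symptomatic group; "
                "using overall kicking-limb proportion %.3f", sex, p,
            )
        idx = np.asarray(list(ctrl_idx))
        n_kick = int(round(p * len(idx)))
        shuffled = idx[rng.permutation(len(idx))]
        kick_rows, nonkick_rows = shuffled[:n_kick], shuffled[n_kick:]
        df.loc[kick_rows, "selected_limb"] = df.loc[kick_rows, "kicking_limb"]
        df.loc[nonkick_rows, "selected_limb"] = df.loc[nonkick_rows, "kicking_limb"].map(
            {"L": "R", "R": "L"}
        )
    return df


@dataclass
class SPMResult:
    t: np.ndarray                      # node-wise t statistic, NaN where flagged
    t_crit: float                      # family-wise critical threshold t*
    clusters: list[tuple[int, int]]    # maximal runs (start, end node) with |t| > t*
    alpha: float
    method: str
    df: int
    fwhm: float | None = None          # residual smoothness, RFT method only

    @property
    def significant(self) -> bool:
        return len(self.clusters) > 0


def _profiles_matrix(profiles) -> np.ndarray:
    if isinstance(profiles, np.ndarray):
        mat = np.asarray(profiles, dtype=float)
    else:
        mat = np.vstack([
            p.nodes if isinstance(p, MuscleProfile) else np.asarray(p, dtype=float)
            for p in profiles
        ])
    if mat.ndim != 2 or mat.shape[1] != N_PROFILE_NODES:
        raise ValueError(f"profiles must be n x {N_PROFILE_NODES}")
    return mat


def _tstat_pooled(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Node-wise equal-variance two-sample t; NaN where pooled variance is 0."""
    na, nb = xa.shape[0], xb.shape[0]
    ma, mb = xa.mean(axis=0), xb.mean(axis=0)
    ssa = ((xa - ma) ** 2).sum(axis=0)
    ssb = ((xb - mb) ** 2).sum(axis=0)
    sp2 = (ssa + ssb) / (na + nb - 2)
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / se
    t[se == 0] = np.nan
    return t


def _perm_max_abs_t(x: np.ndarray, na: int, n_perm: int, seed: int | None) -> np.ndarray:
    """Max |t| over nodes for seeded random relabelings (identity included)."""
    n, q = x.shape
    nb = n - na
    rng = np.random.default_rng(seed)
    member = np.zeros((n_perm, n), dtype=float)
    member[0, :na] = 1.0  # observed labeling
    for i in range(1, n_perm):
        member[i, rng.permutation(n)[:na]] = 1.0

    x2 = x**2
    tot, tot2 = x.sum(axis=0), x2.sum(axis=0)
    sa = member @ x
    sa2 = member @ x2
    ma, mb = sa / na, (tot - sa) / nb
    ssa = sa2 - sa**2 / na
    ssb = (tot2 - sa2) - (tot - sa) ** 2 / nb
    sp2 = (ssa + ssb) / (n - 2)
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs((ma - mb) / se)
    t[se == 0] = np.nan
    return np.nanmax(t, axis=1)


def _estimate_fwhm(residuals: np.ndarray) -> float:
    """Residual smoothness in node units from normalised residual gradients."""
    sd = residuals.std(axis=0, ddof=1)
    sd[sd == 0] = np.inf
    v = residuals / sd
    grad = np.gradient(v, axis=1)
    lam = np.mean(grad**2)
    if lam <= 0:
        return float("inf")
    return float(np.sqrt(4.0 * np.log(2.0) / lam))


def _rft_threshold(alpha: float, df: int, fwhm: float, length: float) -> float:
    """Two-sided 1D random-field critical value for a t field: solves the
    expected-Euler-characteristic approximation for the max of |t|."""

    def exceedance(u: float) -> float:
        ec0 = stats.t.sf(u, df)
        ec1 = (length / fwhm) * np.sqrt(4 * np.log(2)) / (2 * np.pi) * (
            1 + u**2 / df
        ) ** (-(df - 1) / 2.0)
        return 2.0 * (ec0 + ec1) - alpha

    lo = stats.t.ppf(1 - alpha / 2, df)  # uncorrected value: exceedance >= 0 there
    hi = 50.0
    if exceedance(lo) <= 0:
        return float(lo)
    return float(brentq(exceedance, lo, hi))


def _supra_clusters(t: np.ndarray, t_crit: float) -> list[tuple[int, int]]:
    above = np.abs(t) > t_crit
    above = np.where(np.isnan(t), False, above)
    clusters: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            clusters.append((start, i - 1))
            start = None
    if start is not None:
        clusters.append((start, len(above) - 1))
    return clusters


def spm_ttest(
    profiles_a,
    profiles_b,
    alpha: float = 0.05,
    method: str = "permutation",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> SPMResult:
    """Two-sample t test along the 101-node muscle length with family-wise
    control of the any-node false-positive rate.

    method 'permutation': t* is the (1-alpha) quantile of the maximum |t|
    over seeded group-label permutations (observed labeling included).
    method 'rft': closed-form 1D random-field threshold with smoothness
    estimated from the residuals. Nodes with zero pooled variance carry NaN
    and are excluded from the maximum.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    xa = _profiles_matrix(profiles_a)
    xb = _profiles_matrix(profiles_b)
    if xa.shape[0] < 2 or xb.shape[0] < 2:
        raise ValueError("need at least 2 profiles per group")
    na, nb = xa.shape[0], xb.shape[0]
    dof = na + nb - 2
    t = _tstat_pooled(xa, xb)
    if np.isnan(t).any():
        log.warning("%d node(s) with zero pooled variance flagged", int(np.isnan(t).sum()))

    fwhm = None
    if method == "permutation":
        max_t = _perm_max_abs_t(np.vstack([xa, xb]), na, n_perm, seed)
        t_crit = float(np.nanquantile(max_t, 1.0 - alpha))
    elif method == "rft":
        residuals = np.vstack([xa - xa.mean(axis=0), xb - xb.mean(axis=0)])
        fwhm = _estimate_fwhm(residuals)
        t_crit = _rft_threshold(alpha, dof, fwhm, float(N_PROFILE_NODES - 1))
    else:
        raise ValueError(f"unknown method {method!r}")

    return SPMResult(
        t=t, t_crit=t_crit, clusters=_supra_clusters(t, t_crit),
        alpha=alpha, method=method, df=dof, fwhm=fwhm,
    )


@dataclass
class RegressionResult:
    muscle: str
    adjusted_difference_mm3: float   # symptomatic minus control
    ci_low: float
    ci_high: float
    p_value: float
    interaction_p: float | None      # group x sex screening p-value
    interaction_retained: bool
    covariates: tuple[str, ...]
    n_symptomatic: int
    n_control: int
    adjusted_control_mean_mm3: float
    percent_difference: float        # difference / adjusted control mean x 100
    model_summary: str = field(repr=False, default="")


_GROUP_TERM = "C(group, Treatment('control'))[T.symptomatic]"


def _check_collinearity(df: pd.DataFrame, columns: list[str]) -> None:
    numeric = pd.get_dummies(df[columns], drop_first=True).astype(float)
    corr = numeric.corr().to_numpy()
    names = list(numeric.columns)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if np.isclose(abs(corr[i, j]), 1.0):
                raise ValueError(
                    f"collinear covariates: {names[i]!r} and {names[j]!r}"
                )


def volume_regression(
    cohort: pd.DataFrame,
    muscle: str,
    interaction_alpha: float = 0.05,
) -> RegressionResult:
    """Adjusted between-group difference in muscle volume.

    OLS of volume on group + age + BMI + sex + sport, with a first-pass
    group-by-sex interaction that is removed when its p-value exceeds 0.05.
    Reference levels: control, female, soccer. The percent difference uses
    the adjusted control mean (mean model prediction with every participant
    set to the control group) as denominator.
    """
    vol_col = f"vol_{muscle}" if f"vol_{muscle}" in cohort.columns else muscle
    if vol_col not in cohort.columns:
        raise ValueError(f"no volume column for muscle {muscle!r}")
    df = cohort.dropna(subset=[vol_col, "group", "age", "bmi", "sex", "sport"]).copy()
    if len(df) < 10:
        raise ValueError("need at least 10 complete rows")
    groups = set(df["group"])
    if not {"symptomatic", "control"} <= groups:
        raise ValueError("both groups must be represented")
    _check_collinearity(df, ["group", "age", "bmi", "sex", "sport"])
    df = df.rename(columns={vol_col: "volume"})

    terms = ["C(group, Treatment('control'))", "age", "bmi"]
    if df["sex"].nunique() > 1:
        terms.append("C(sex, Treatment('F'))")
    if df["sport"].nunique() > 1:
        terms.append("C(sport, Treatment('soccer'))")
    base = "volume ~ " + " + ".join(terms)
    interaction_term = "C(group, Treatment('control')):C(sex, Treatment('F'))"

    interaction_p: float | None = None
    retained = False
    if df["sex"].nunique() > 1:
        full = smf.ols(f"{base} + {interaction_term}", data=df).fit()
        inter_cols = [c for c in full.pvalues.index if ":" in c]
        interaction_p = float(full.pvalues[inter_cols].min())
        retained = interaction_p <= interaction_alpha
    else:
        log.warning("single-sex cohort: group x sex interaction skipped")

    model = smf.ols(f"{base} + {interaction_term}" if retained else base, data=df).fit()
    if retained:
        log.info("group x sex interaction retained (p = %.4f)", interaction_p)
        # with an interaction in the model, the single adjusted difference is
        # the marginal group contrast averaged over the sample sex mix
        contrast = np.zeros(len(model.params))
        names = list(model.params.index)
        contrast[names.index(_GROUP_TERM)] = 1.0
        w_nonref = float((df["sex"] != "F").mean())
        for i, name in enumerate(names):
            if ":" in name:
                contrast[i] = w_nonref
        tt = model.t_test(contrast)
        coef = float(np.squeeze(tt.effect))
        ci = np.squeeze(tt.conf_int())
        p = float(np.squeeze(tt.pvalue))
    else:
        coef = float(model.params[_GROUP_TERM])
        ci = model.conf_int().loc[_GROUP_TERM]
        p = float(model.pvalues[_GROUP_TERM])

    as_control = df.copy()
    as_control["group"] = "control"
    adj_control_mean = float(model.predict(as_control).mean())

    return RegressionResult(
        muscle=muscle,
        adjusted_difference_mm3=coef,
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p_value=p,
        interaction_p=interaction_p,
        interaction_retained=retained,
        covariates=("age", "bmi", "sex", "sport"),
        n_symptomatic=int((df["group"] == "symptomatic").sum()),
        n_control=int((df["group"] == "control").sum()),
        adjusted_control_mean_mm3=adj_control_mean,
        percent_difference=100.0 * coef / adj_control_mean,
        model_summary=str(model.summary()),
    )
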