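"""Differential protein turnover statistics with empirical-Bayes moderation.

Each protein's log2 abundances (light, heavy or total channel) are fitted
with a one-factor linear model over the experimental groups. Residual
variances are shrunk toward a scaled inverse-chi-square prior fitted across
proteins by the method of moments on log-variances (with optional
mean-intensity trend and outlier-robust winsorization), yielding moderated
t statistics per contrast and an omnibus moderated F per protein with
augmented degrees of freedom d0 + df. p-values are Benjamini-Hochberg
adjusted within each contrast family, and proteins are classified by the
sign-and-significance turnover rules:

    degraded    — light channel,  log2FC < 0 and adj. p < 0.05
    synthesized — heavy channel,  log2FC > 0 and adj. p < 0.05
    accumulated — light channel under inhibitor/atrophy contrasts,
                  log2FC > 0 and adj. p < 0.05
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats as sps
from statsmodels.stats.multitest import multipletests

from .design import SampleKey

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_PER_GROUP = 3

CALLS = ("degraded", "synthesized", "accumulated", "not_significant", "not_tested")


@dataclass(frozen=True)
class ContrastSpec:
    """One two-group comparison on one channel.

    ``numerator`` / ``denominator`` are experimental-group labels
    (e.g. "H72_none" vs "H24_none"); log2FC = mean(numerator) −
    mean(denominator). ``mode`` selects the classification rule family:
    "turnover" (degraded / synthesized) or "accumulation" (inhibitor- or
    atrophy-driven light-channel build-up).
    """

    name: str
    channel: str  # heavy | light | total
    numerator: str
    denominator: str
    mode: str = "turnover"

    def __post_init__(self) -> None:
        if self.channel not in ("heavy", "light", "total"):
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.mode not in ("turnover", "accumulation"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.numerator == self.denominator:
            raise ValueError("numerator and denominator groups must differ")


# -- transforms and filtering ----------------------------------------------

def log2_and_center(matrix: pd.DataFrame, center: bool = True) -> pd.DataFrame:
    """Elementwise log2; optionally subtract each run's median (column median 0)."""
    values = matrix.to_numpy(dtype=float)
    bad = (values <= 0) & ~np.isnan(values)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-positive intensity at protein {matrix.index[i]!r}, run {matrix.columns[j]!r}"
        )
    out = np.log2(values)
    if center:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            med = np.nanmedian(out, axis=0)
        out = out - np.where(np.isnan(med), 0.0, med)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def filter_min_obs(
    matrix: pd.DataFrame,
    run_groups: Mapping[str, str],
    min_per_group: int = DEFAULT_MIN_PER_GROUP,
    groups: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Keep proteins with >= min_per_group non-missing values in every group.

    ``run_groups`` maps run_id -> experimental-group label; ``groups``
    restricts which groups the requirement applies to (default: all groups
    present among the matrix columns).
    """
    col_groups = pd.Series({run: run_groups[run] for run in matrix.columns if run in run_groups})
    wanted = list(dict.fromkeys(col_groups)) if groups is None else list(groups)
    keep = pd.Series(True, index=matrix.index)
    for g in wanted:
        runs = col_groups.index[col_groups == g]
        if len(runs) < min_per_group:
            raise ValueError(
                f"group {g!r} has only {len(runs)} runs, fewer than min_per_group={min_per_group}"
            )
        keep &= matrix[runs].notna().sum(axis=1) >= min_per_group
    dropped = list(matrix.index[~keep])
    return matrix.loc[keep], dropped


# -- per-protein linear model ----------------------------------------------

@dataclass
class GroupFit:
    """Vectorized one-factor OLS across proteins (NaN-aware)."""

    groups: list[str]
    means: pd.DataFrame        # protein x group cell means
    n_obs: pd.DataFrame        # protein x group observation counts
    s2: pd.Series              # residual variance, RSS / df
    df: pd.Series              # residual df = n_obs_total - n_groups_with_data
    amean: pd.Series           # mean log2 intensity over all observations


def fit_group_model(matrix: pd.DataFrame, run_groups: Mapping[str, str]) -> GroupFit:
    """One-way layout per protein: cell means, pooled residual variance, df."""
    col_groups = np.array([run_groups[run] for run in matrix.columns])
    groups = list(dict.fromkeys(col_groups))
    values = matrix.to_numpy(dtype=float)
    obs = ~np.isnan(values)

    means = np.full((values.shape[0], len(groups)), np.nan)
    counts = np.zeros((values.shape[0], len(groups)), dtype=int)
    rss = np.zeros(values.shape[0])
    for gi, g in enumerate(groups):
        cols = col_groups == g
        sub = values[:, cols]
        n = (~np.isnan(sub)).sum(axis=1)
        counts[:, gi] = n
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m = np.nanmean(sub, axis=1)
        means[:, gi] = m
        resid = sub - m[:, None]
        rss += np.nansum(resid**2, axis=1)
    n_total = counts.sum(axis=1)
    g_used = (counts > 0).sum(axis=1)
    df = n_total - g_used
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = np.where(df > 0, rss / np.maximum(df, 1), np.nan)
        amean = np.nansum(np.where(obs, values, 0.0), axis=1) / np.maximum(n_total, 1)
    return GroupFit(
        groups=groups,
        means=pd.DataFrame(means, index=matrix.index, columns=groups),
        n_obs=pd.DataFrame(counts, index=matrix.index, columns=groups),
        s2=pd.Series(s2, index=matrix.index),
        df=pd.Series(df.astype(float), index=matrix.index),
        amean=pd.Series(amean, index=matrix.index),
    )


# -- empirical-Bayes variance moderation -----------------------------------

def _trigamma_inverse(y: np.ndarray) -> np.ndarray:
    """Solve trigamma(x) = y for x > 0 (Newton on the inverse scale)."""
    y = np.asarray(y, dtype=float)
    x = np.where(y > 1e7, 1.0 / np.sqrt(y), 0.5 + 1.0 / y)
    x = np.where(y < 1e-6, 1.0 / y, x)
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif) / np.maximum(x, 1e-12) < 1e-10):
            break
    return x


def _running_median(x: np.ndarray, window: int) -> np.ndarray:
    """Centered running median with edge padding (window forced odd)."""
    window = max(3, window | 1)
    half = window // 2
    padded = np.concatenate([np.repeat(x[0], half), x, np.repeat(x[-1], half)])
    return np.array([np.median(padded[i : i + window]) for i in range(len(x))])


@dataclass
class SqueezeResult:
    df_prior: float                # d0 (may be inf)
    s2_prior: pd.Series            # s0^2 per protein (constant unless trend)
    s2_post: pd.Series
    trend_used: bool = False
    robust_used: bool = False
    moderation_skipped: bool = False


def squeeze_variances(
    s2: pd.Series,
    df: pd.Series,
    amean: pd.Series | None = None,
    trend: bool = True,
    robust: bool = True,
) -> SqueezeResult:
    """Shrink per-protein residual variances toward an inverse-chi-square prior.

    Method of moments on z = log s^2: under s^2 | sigma^2 ~ sigma^2 X^2_df/df
    and sigma^2 ~ d0 s0^2 / X^2_d0,

        E[e] = log s0^2 + log(d0/2) - digamma(d0/2),
        Var(e) = trigamma(df/2) + trigamma(d0/2),

    with e = log s^2 - digamma(df/2) + log(df/2). ``trend`` replaces the
    constant log s0^2 with a running-median smooth over mean log-intensity;
    ``robust`` winsorizes e at +-3 scaled MADs before the moment fit. When
    the moments imply no excess variability, d0 = +inf and s2_post = s0^2.
    """
    usable = (df > 0) & s2.notna()
    if usable.sum() < 2:
        raise ValueError("need >= 2 proteins with positive residual df")
    s2_u = s2[usable].to_numpy(dtype=float)
    df_u = df[usable].to_numpy(dtype=float)

    if np.all(s2_u == 0):
        warnings.warn("all residual variances are zero; moderation skipped")
        return SqueezeResult(
            df_prior=0.0,
            s2_prior=pd.Series(np.nan, index=s2.index),
            s2_post=s2.copy(),
            moderation_skipped=True,
        )
    # guard exact zeros (log undefined); floor at a tiny fraction of the positive min
    floor = s2_u[s2_u > 0].min() * 1e-12
    s2_u = np.maximum(s2_u, floor)

    z = np.log(s2_u)
    e = z - special.digamma(df_u / 2.0) + np.log(df_u / 2.0)

    robust_used = False
    if robust:
        med = np.median(e)
        mad = np.median(np.abs(e - med)) * 1.4826
        if mad > 0:
            e_fit = np.clip(e, med - 3 * mad, med + 3 * mad)
            robust_used = True
        else:
            e_fit = e
    else:
        e_fit = e

    trend_used = False
    if trend and amean is not None and np.isfinite(amean[usable]).all() and len(e_fit) >= 10:
        order = np.argsort(amean[usable].to_numpy())
        window = max(11, int(0.1 * len(e_fit)))
        smooth_sorted = _running_median(e_fit[order], window)
        e_loc = np.empty_like(e_fit)
        e_loc[order] = smooth_sorted
        # re-center: the median of log-chi-square is offset from its mean,
        # so anchor the smoother's level at the (winsorized) mean to keep
        # the prior unbiased while the shape stays robust
        e_loc += np.mean(e_fit) - np.mean(e_loc)
        trend_used = True
    else:
        e_loc = np.full_like(e_fit, np.mean(e_fit))

    resid = e_fit - e_loc
    evar = float(np.var(resid, ddof=1))
    evar -= float(np.mean(special.polygamma(1, df_u / 2.0)))

    if evar > 0:
        d0 = float(2.0 * _trigamma_inverse(np.array([evar]))[0])
        s0_u = np.exp(e_loc - np.log(d0 / 2.0) + special.digamma(d0 / 2.0))
    else:
        # no excess spread beyond sampling noise: degenerate (point-mass) prior
        d0 = np.inf
        if trend_used and np.ptp(e_loc) > 0:
            s0_u = np.exp(e_loc)
        else:
            s0_u = np.full_like(e_loc, float(np.mean(s2_u)))

    s2_prior = pd.Series(np.nan, index=s2.index)
    s2_prior[usable] = s0_u
    s2_post = pd.Series(np.nan, index=s2.index)
    if np.isinf(d0):
        s2_post[usable] = s0_u
    else:
        s2_post[usable] = (d0 * s0_u + df_u * s2[usable].to_numpy()) / (d0 + df_u)
    return SqueezeResult(
        df_prior=d0,
        s2_prior=s2_prior,
        s2_post=s2_post,
        trend_used=trend_used,
        robust_used=robust_used,
    )


# -- moderated statistics ---------------------------------------------------

def moderated_t(fit: GroupFit, squeeze: SqueezeResult, numerator: str, denominator: str) -> pd.DataFrame:
    """Moderated two-group t per protein: log2fc, t, df_total, p."""
    for g in (numerator, denominator):
        if g not in fit.groups:
            raise ValueError(f"group {g!r} not in the fitted design; have {fit.groups}")
    m1, m2 = fit.means[numerator], fit.means[denominator]
    n1, n2 = fit.n_obs[numerator], fit.n_obs[denominator]
    log2fc = m1 - m2
    d0 = squeeze.df_prior
    df_total = fit.df + (0.0 if np.isinf(d0) else d0)
    se = np.sqrt(squeeze.s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = log2fc / se
    tested = (n1 > 0) & (n2 > 0) & squeeze.s2_post.notna() & np.isfinite(t)
    p = pd.Series(np.nan, index=fit.s2.index)
    if np.isinf(d0):
        p[tested] = 2.0 * sps.norm.sf(np.abs(t[tested]))
        df_total = pd.Series(np.inf, index=fit.s2.index)
    else:
        p[tested] = 2.0 * sps.t.sf(np.abs(t[tested]), df_total[tested])
    return pd.DataFrame(
        {"log2fc": log2fc, "t_mod": t, "df_total": df_total, "p": p}
    )


def moderated_F(fit: GroupFit, squeeze: SqueezeResult) -> pd.DataFrame:
    """Omnibus moderated F over all group differences: F, df1, df2, p."""
    means = fit.means.to_numpy()
    counts = fit.n_obs.to_numpy().astype(float)
    n_total = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        grand = np.nansum(np.where(counts > 0, means, 0.0) * counts, axis=1) / n_total
        between = np.nansum(counts * (np.where(counts > 0, means, 0.0) - grand[:, None]) ** 2, axis=1)
    g_used = (counts > 0).sum(axis=1)
    df1 = (g_used - 1).astype(float)
    d0 = squeeze.df_prior
    df2 = fit.df + (0.0 if np.isinf(d0) else d0)
    with np.errstate(invalid="ignore", divide="ignore"):
        F = (between / np.maximum(df1, 1)) / squeeze.s2_post.to_numpy()
    p = np.full(len(F), np.nan)
    tested = (df1 >= 1) & np.isfinite(F)
    if np.isinf(d0):
        # F*df1 -> chi-square_df1 in the infinite-prior limit
        p[tested] = sps.chi2.sf(F[tested] * df1[tested], df1[tested])
        df2 = pd.Series(np.inf, index=fit.s2.index)
    else:
        p[tested] = sps.f.sf(F[tested], df1[tested], df2.to_numpy()[tested])
    return pd.DataFrame(
        {"F": F, "df1": df1, "df2": df2, "p_F": p}, index=fit.s2.index
    )


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if len(p) == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# -- classification ---------------------------------------------------------

def classify_turnover(
    results: pd.DataFrame,
    channel: str,
    mode: str = "turnover",
    alpha: float = DEFAULT_ALPHA,
) -> pd.Series:
    """Sign-and-significance turnover call per protein.

    turnover mode: light log2FC<0 & adj p<alpha -> degraded;
    heavy log2FC>0 & adj p<alpha -> synthesized. accumulation mode
    (inhibitor-vs-vehicle or atrophy contrasts): light log2FC>0 &
    adj p<alpha -> accumulated. Strict inequalities throughout; proteins
    without a p-value are not_tested.
    """
    if mode == "turnover":
        if channel not in ("light", "heavy"):
            raise ValueError("turnover classification is defined on light or heavy channels")
    elif mode == "accumulation":
        if channel != "light":
            raise ValueError("accumulation classification is defined on the light channel only")
    else:
        raise ValueError(f"unknown mode {mode!r}")

    fc = results["log2fc"]
    adj = results["adj_p"]
    tested = adj.notna() & fc.notna()
    call = pd.Series("not_tested", index=results.index)
    call[tested] = "not_significant"
    sig = tested & (adj < alpha)
    if mode == "turnover" and channel == "light":
        call[sig & (fc < 0)] = "degraded"
    elif mode == "turnover" and channel == "heavy":
        call[sig & (fc > 0)] = "synthesized"
    else:
        call[sig & (fc > 0)] = "accumulated"
    return call


# -- high-level driver -------------------------------------------------------

def run_contrasts(
    matrices: Mapping[str, pd.DataFrame],
    design: Sequence[SampleKey],
    contrasts: Sequence[ContrastSpec],
    min_per_group: int = DEFAULT_MIN_PER_GROUP,
    alpha: float = DEFAULT_ALPHA,
    trend: bool = True,
    robust: bool = True,
    center_heavy: bool = True,
) -> dict[str, pd.DataFrame]:
    """Fit each channel once over the groups its contrasts reference.

    ``matrices`` maps channel name -> protein x run intensity matrix
    (linear scale). Per channel: log2 (median-centered for heavy), the
    min-observation filter over the referenced groups, one-factor fit,
    variance squeeze, then per contrast the moderated t, the omnibus
    moderated F, per-contrast BH adjustment and the turnover call.
    Returns contrast name -> results table.
    """
    run_groups = {k.run_id: k.group for k in design}
    by_channel: dict[str, list[ContrastSpec]] = {}
    for c in contrasts:
        by_channel.setdefault(c.channel, []).append(c)

    out: dict[str, pd.DataFrame] = {}
    for channel, specs in by_channel.items():
        if channel not in matrices:
            raise ValueError(f"no matrix provided for channel {channel!r}")
        wanted_groups = sorted({g for c in specs for g in (c.numerator, c.denominator)})
        known = {run_groups[r] for r in matrices[channel].columns if r in run_groups}
        unknown = [g for g in wanted_groups if g not in known]
        if unknown:
            raise ValueError(f"unknown groups {unknown}; valid groups: {sorted(known)}")
        cols = [r for r in matrices[channel].columns if run_groups.get(r) in wanted_groups]
        mat = matrices[channel][cols]
        logmat = log2_and_center(mat, center=(channel == "heavy" and center_heavy))
        filtered, _dropped = filter_min_obs(logmat, run_groups, min_per_group, wanted_groups)
        fit = fit_group_model(filtered, run_groups)
        squeeze = squeeze_variances(fit.s2, fit.df, fit.amean, trend=trend, robust=robust)
        fstats = moderated_F(fit, squeeze)
        for spec in specs:
            res = moderated_t(fit, squeeze, spec.numerator, spec.denominator)
            res = res.join(fstats)
            res["adj_p"] = np.nan
            tested = res["p"].notna()
            if tested.any():
                res.loc[tested, "adj_p"] = bh_adjust(res.loc[tested, "p"])
            res["call"] = classify_turnover(res, spec.channel, spec.mode, alpha)
            res.insert(0, "contrast", spec.name)
            out[spec.name] = res
    return out


def standard_contrasts(include_inhibitors: bool = True) -> list[ContrastSpec]:
    """The stepwise comparisons of the study design.

    Heavy and light channels for H72 vs H24, A72 vs A24, A24 vs H24,
    A72 vs H72 (vehicle arms), plus light-channel accumulation contrasts
    of each inhibitor arm against vehicle at matched condition and time.
    """
    pairs = [
        ("H72_vs_H24", "H72_none", "H24_none"),
        ("A72_vs_A24", "A72_none", "A24_none"),
        ("A24_vs_H24", "A24_none", "H24_none"),
        ("A72_vs_H72", "A72_none", "H72_none"),
    ]
    out = []
    for name, num, den in pairs:
        for channel in ("light", "heavy"):
            out.append(ContrastSpec(f"{name}_{channel}", channel, num, den, "turnover"))
    if include_inhibitors:
        for cond in ("H", "A"):
            for t in (24, 72):
                for inh in ("BafA1", "Lac"):
                    out.append(
                        ContrastSpec(
                            f"{cond}{t}_{inh}_vs_none_light",
                            "light",
                            f"{cond}{t}_{inh}",
                            f"{cond}{t}_none",
                            "accumulation",
                        )
                    )
    return out
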