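"""Hierarchical exposure-vs-control inference on litter-level loads.

Small-sample nonparametric tests are computed EXACTLY by full
enumeration whenever feasible (all C(n+m, n) group allocations for the
Mann-Whitney U, all 2^n sign patterns for the Wilcoxon signed-rank, all
n! rank permutations for the Spearman correlation), with mid-rank tie
handling throughout; approximations are used, and flagged, only beyond
the enumeration limits.  Mixed-effects biometry models regress organ
weights and weight ratios on log10 particle load with a random
intercept (and, for the placenta, random slope) per dam.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synthetic import ORGANS

MAX_ENUM = 1_000_000  # allocation limit for exact Mann-Whitney enumeration


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    exact: bool
    n: tuple

    def __post_init__(self) -> None:
        assert 0.0 <= self.p_value <= 1.0 + 1e-12


@dataclass
class FoldChange:
    organ: str
    control_mean: float
    exposed_mean: float
    ratio: float
    test: TestResult


@dataclass
class MixedModelFit:
    response: str
    organ: str
    fixed_effects: pd.DataFrame  # estimate, ci_low, ci_high, p per term
    dam_intercept_sd: float
    dam_slope_sd: float | None
    residual_sd: float
    converged: bool
    random_slope: bool
    fallback_intercept_only: bool
    n_zeros_replaced: int


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def summarize(values) -> dict:
    """Median (Q1; Q3) with linear-interpolation (type-7) quartiles."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    return {
        "median": float(np.median(v)),
        "q1": float(np.quantile(v, 0.25)),
        "q3": float(np.quantile(v, 0.75)),
        "n": int(v.size),
    }


def format_summary(values) -> str:
    s = summarize(values)
    return f"{s['median']:.3g} ({s['q1']:.3g}; {s['q3']:.3g})"


def mann_whitney_exact(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test, exact by full enumeration.

    The exact null distribution of U is built by enumerating every
    C(n+m, n) assignment of the pooled mid-ranks to the first group
    (3432 allocations at 7 vs 7); ties are therefore handled without
    approximation.  Beyond the enumeration limit a tie-corrected normal
    approximation is used and the result flagged non-exact.  Two-sided
    p = P(|U - nm/2| >= |u_obs - nm/2|), using the symmetry of U about
    nm/2 under exchangeability.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2.0

    from math import comb

    if comb(n + m, n) <= MAX_ENUM:
        combos = np.fromiter(
            (r for c in combinations(range(n + m), n) for r in c), dtype=np.intp
        ).reshape(-1, n)
        u_all = ranks[combos].sum(axis=1) - n * (n + 1) / 2.0
        center = n * m / 2.0
        p = float(np.mean(np.abs(u_all - center) >= np.abs(u_obs - center) - 1e-9))
        return TestResult(float(u_obs), p, "mann-whitney", True, (n, m))

    # tie-corrected normal approximation with continuity correction
    t = np.unique(ranks, return_counts=True)[1]
    tie_term = ((t**3 - t).sum()) / ((n + m) * (n + m - 1))
    sd = np.sqrt(n * m / 12.0 * ((n + m + 1) - tie_term))
    z = (abs(u_obs - n * m / 2.0) - 0.5) / sd if sd > 0 else 0.0
    p = float(min(1.0, 2.0 * sps.norm.sf(max(z, 0.0))))
    return TestResult(float(u_obs), p, "mann-whitney", False, (n, m))


def wilcoxon_signed_rank_exact(x, y=None, max_exact_n: int = 20) -> TestResult:
    """Two-sided Wilcoxon matched-pairs signed-rank test, exact sign enumeration.

    Zero differences are dropped before ranking (the classic
    convention).  For n <= ``max_exact_n`` non-zero pairs the exact
    two-sided p enumerates all 2^n sign patterns of the mid-ranks of
    |d|; otherwise a normal approximation is used.
    """
    x = np.asarray(x, float)
    if y is not None:
        y = np.asarray(y, float)
        if len(x) != len(y):
            raise ValueError("paired samples must have equal length")
        d = x - y
    else:
        d = x
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences zero")
    ranks = _midranks(np.abs(d))
    w_obs = ranks[d > 0].sum()
    total = ranks.sum()

    if n <= max_exact_n:
        # DP over the distribution of W+ on the doubled-rank integer lattice
        r2 = np.rint(2 * ranks).astype(int)
        dist = np.zeros(r2.sum() + 1)
        dist[0] = 1.0
        for r in r2:
            dist[r:] += dist[: len(dist) - r].copy()
        dist /= dist.sum()
        w2 = int(round(2 * w_obs))
        center = r2.sum() / 2.0
        support = np.arange(len(dist))
        p = float(dist[np.abs(support - center) >= abs(w2 - center) - 1e-9].sum())
        return TestResult(float(w_obs), min(p, 1.0), "wilcoxon-signed-rank", True, (n,))

    mean = total / 2.0
    sd = np.sqrt((ranks**2).sum() / 4.0)
    z = (abs(w_obs - mean) - 0.5) / sd if sd > 0 else 0.0
    p = float(min(1.0, 2.0 * sps.norm.sf(max(z, 0.0))))
    return TestResult(float(w_obs), p, "wilcoxon-signed-rank", False, (n,))


def spearman_exact(x, y, max_exact_n: int = 8) -> tuple[float, TestResult]:
    """Spearman rank correlation with exact permutation p for small n.

    rho is the Pearson correlation of mid-ranks.  For n <= 8 the
    two-sided p enumerates all n! permutations of one rank vector
    (5040 at n=7); beyond that, the t-distribution approximation.
    Constant input has undefined rho and raises.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n != len(y):
        raise ValueError("length mismatch")
    if n < 3:
        raise ValueError("need n >= 3")
    rx, ry = _midranks(x), _midranks(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("constant input: rho undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if n <= max_exact_n:
        from itertools import permutations

        perms = np.array(list(permutations(range(n))))
        ry_c = ry - ry.mean()
        rx_c = rx - rx.mean()
        denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
        rhos = (rx_c[perms] @ ry_c) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        return rho, TestResult(rho, p, "spearman", True, (n,))

    t = rho * np.sqrt((n - 2) / max(1e-12, 1 - rho**2))
    p = float(min(1.0, 2.0 * sps.t.sf(abs(t), n - 2)))
    return rho, TestResult(rho, p, "spearman", False, (n,))


def spearman_matrix(litter_table: pd.DataFrame, group: str = "DE", value_col: str = "cp_load") -> pd.DataFrame:
    """Organ x organ Spearman correlation matrix of litter-mean loads."""
    wide = (
        litter_table[litter_table["group"] == group]
        .pivot(index="dam_id", columns="organ", values=value_col)
        .reindex(columns=[o for o in ORGANS if o in litter_table["organ"].unique()])
    )
    organs = list(wide.columns)
    mat = pd.DataFrame(np.eye(len(organs)), index=organs, columns=organs)
    for a, b in combinations(organs, 2):
        rho, _ = spearman_exact(wide[a].to_numpy(), wide[b].to_numpy())
        mat.loc[a, b] = mat.loc[b, a] = rho
    return mat


def _dunn_posthoc(groups: list[np.ndarray]) -> np.ndarray:
    """Dunn's pairwise z-tests on mean ranks, Bonferroni-adjusted p-values."""
    pooled = np.concatenate(groups)
    ranks = _midranks(pooled)
    n_total = len(pooled)
    sizes = [len(g) for g in groups]
    idx = np.cumsum([0] + sizes)
    mean_ranks = [ranks[idx[i] : idx[i + 1]].mean() for i in range(len(groups))]
    t = np.unique(ranks, return_counts=True)[1]
    tie_corr = (t**3 - t).sum() / (12.0 * (n_total - 1))
    k = len(groups)
    n_pairs = k * (k - 1) // 2
    ps = []
    for i, j in combinations(range(k), 2):
        se = np.sqrt((n_total * (n_total + 1) / 12.0 - tie_corr) * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        ps.append(min(1.0, 2.0 * sps.norm.sf(abs(z)) * n_pairs))
    return np.array(ps)


def within_litter_check(fetus_table: pd.DataFrame, value_col: str = "cp_load", alpha: float = 0.05) -> pd.DataFrame:
    """Between-litter exchangeability check preceding litter pooling.

    Per group x organ: Kruskal-Wallis across the dams' fetuses, with
    Dunn's Bonferroni-adjusted pairwise post-hoc.  Pooling is permitted
    for a family when the Kruskal-Wallis p >= alpha or no adjusted
    pairwise p falls below alpha.  Returns one row per group x organ
    with the verdict.
    """
    results = []
    for (group, organ), sub in fetus_table.groupby(["group", "organ"], observed=True):
        litters = [g[value_col].to_numpy() for _, g in sub.groupby("dam_id", observed=True)]
        litters = [l for l in litters if len(l) > 0]
        if len(litters) < 2 or sum(len(l) > 1 for l in litters) < 2:
            raise ValueError("need >=2 fetuses in >=2 litters")
        if np.ptp(np.concatenate(litters)) == 0:
            kw_p = 1.0  # all values identical: nothing to distinguish
        else:
            _, kw_p = sps.kruskal(*litters)
        min_dunn = 1.0
        if kw_p < alpha:
            min_dunn = float(_dunn_posthoc(litters).min())
        results.append(
            dict(
                group=group, organ=organ, kw_p=float(kw_p), min_dunn_p=min_dunn,
                pooling_permitted=bool(kw_p >= alpha or min_dunn >= alpha),
            )
        )
    return pd.DataFrame(results)


def fold_changes(litter_table: pd.DataFrame, value_col: str = "cp_load", stat: str = "mean") -> pd.DataFrame:
    """Exposed/control ratio of group summaries of litter-mean loads, per organ.

    "On average X-fold higher" is read as the ratio of group means of
    litter means (``stat='median'`` switches to medians).  Each ratio
    carries the exact Mann-Whitney p comparing the litter means.
    """
    if stat not in ("mean", "median"):
        raise ValueError(f"unknown fold statistic {stat!r}")
    agg = np.mean if stat == "mean" else np.median
    rows = []
    for organ, sub in litter_table.groupby("organ", sort=False, observed=True):
        ctrl = sub.loc[sub["group"] == "C", value_col].to_numpy()
        expo = sub.loc[sub["group"] == "DE", value_col].to_numpy()
        if len(ctrl) == 0 or len(expo) == 0:
            raise ValueError(f"{organ}: both groups required")
        c, e = float(agg(ctrl)), float(agg(expo))
        if c <= 0:
            raise ValueError(f"{organ}: zero control mean")
        test = mann_whitney_exact(expo, ctrl)
        rows.append(
            dict(organ=organ, control_mean=c, exposed_mean=e, ratio=e / c,
                 u_statistic=test.statistic, p_value=test.p_value, exact=test.exact)
        )
    return pd.DataFrame(rows)


def organ_deficits(litter_table: pd.DataFrame, value_col: str = "cp_load") -> pd.DataFrame:
    """Exposed-group fractional deficit of each fetal organ vs the placenta.

    deficit = 1 - organ mean / placenta mean over exposed litter means,
    with the exact Wilcoxon matched-pairs p (paired within dam).
    """
    expo = litter_table[litter_table["group"] == "DE"]
    wide = expo.pivot(index="dam_id", columns="organ", values=value_col)
    if "placenta" not in wide:
        raise ValueError("missing placenta rows")
    rows = []
    for organ in [o for o in wide.columns if o != "placenta"]:
        paired = wide[[organ, "placenta"]].dropna()
        deficit = 1.0 - paired[organ].mean() / paired["placenta"].mean()
        try:
            test = wilcoxon_signed_rank_exact(paired["placenta"].to_numpy(), paired[organ].to_numpy())
            p, w, exact = test.p_value, test.statistic, test.exact
        except ValueError:
            p, w, exact = np.nan, np.nan, False
        rows.append(dict(organ=organ, deficit=float(deficit), w_statistic=w, p_value=p, exact=exact))
    return pd.DataFrame(rows)


def _log10_with_zero_policy(loads: np.ndarray) -> tuple[np.ndarray, int]:
    """log10 after replacing zeros with half the smallest positive load."""
    loads = np.asarray(loads, float)
    zeros = loads <= 0
    n_zero = int(zeros.sum())
    if n_zero:
        pos = loads[loads > 0]
        if pos.size == 0:
            raise ValueError("all loads zero: log10 transform impossible")
        loads = loads.copy()
        loads[zeros] = pos.min() / 2.0
    return np.log10(loads), n_zero


def fit_lmm(
    fetus_table: pd.DataFrame,
    response: str,
    organ: str,
    load_col: str = "cp_load",
    random_slope: bool | None = None,
    reml: bool = False,
) -> MixedModelFit:
    """Mixed model: response ~ log10(load) + treatment + sex, random dam effects.

    The load slope is the change in the response per 10-fold increase
    in particle load.  A random slope on log10 load is added for the
    placenta (the compartment with the strongest load gradient) unless
    overridden.  Fits use maximum likelihood by default so fixed
    effects are comparable across models; singular random-slope fits
    fall back to a random intercept only, flagged.
    """
    import statsmodels.api as sm

    sub = fetus_table[fetus_table["organ"] == organ].dropna(subset=[response, load_col]).copy()
    if sub["dam_id"].nunique() < 2:
        raise ValueError("need >=2 dams")
    llog, n_zeros = _log10_with_zero_policy(sub[load_col].to_numpy())
    sub["log10_load"] = llog
    sub["treated"] = (sub["group"] == "DE").astype(float)
    sub["male"] = (sub["sex"] == "M").astype(float)
    if random_slope is None:
        random_slope = organ == "placenta"

    exog = sm.add_constant(sub[["log10_load", "treated", "male"]])

    def _fit(with_slope: bool):
        exog_re = sub[["log10_load"]].assign(const=1.0)[["const", "log10_load"]] if with_slope else None
        model = sm.MixedLM(sub[response], exog, groups=sub["dam_id"], exog_re=exog_re)
        last_exc = None
        for method in ("lbfgs", "powell", "nm"):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    return model.fit(reml=reml, method=method)
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_exc = exc
        raise last_exc

    fallback = False
    fit = ci = None
    if random_slope:
        try:
            fit = _fit(True)
            if fit.converged and not np.any(np.diag(fit.cov_re) < 1e-10):
                ci = fit.conf_int()  # can itself be singular for degenerate fits
            else:
                fit = None
        except (np.linalg.LinAlgError, ValueError):
            fit = None
        if fit is None:
            random_slope = False
            fallback = True
    if fit is None or ci is None:
        try:
            fit = _fit(False)
            ci = fit.conf_int()
        except (np.linalg.LinAlgError, ValueError) as exc:
            raise RuntimeError(f"mixed model fit failed: {exc}") from exc
        random_slope = False
    if not fit.converged:
        raise RuntimeError("mixed model failed to converge")
    terms = ["const", "log10_load", "treated", "male"]
    fe = pd.DataFrame(
        dict(
            term=terms,
            estimate=[fit.params[t] for t in terms],
            ci_low=[ci.loc[t, 0] for t in terms],
            ci_high=[ci.loc[t, 1] for t in terms],
            p=[fit.pvalues[t] for t in terms],
        )
    )
    cov_re = np.atleast_2d(fit.cov_re)
    return MixedModelFit(
        response=response,
        organ=organ,
        fixed_effects=fe,
        dam_intercept_sd=float(np.sqrt(max(cov_re[0, 0], 0.0))),
        dam_slope_sd=float(np.sqrt(max(cov_re[1, 1], 0.0))) if random_slope else None,
        residual_sd=float(np.sqrt(fit.scale)),
        converged=bool(fit.converged),
        random_slope=random_slope,
        fallback_intercept_only=fallback,
        n_zeros_replaced=n_zeros,
    )
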