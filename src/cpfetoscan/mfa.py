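"""Multiple factor analysis: group-weighted principal component analysis.

Variables are organised into groups (here: particle loads, organ
weights, weight ratios).  Each column is centred and scaled to unit
population variance, then every column of a group is weighted by
1/sqrt(lambda1) where lambda1 is the first eigenvalue of that group's
own PCA — so no single group can dominate the first global dimension.
A global PCA (SVD with uniform individual weights 1/n) of the weighted
matrix yields eigenvalues, individual coordinates and
variable-dimension correlations.  Qualitative factors (exposure, sex)
are supplementary: projected as category barycentres with v.test and
cos^2 statistics, dimension-description R^2, and 95% confidence
ellipses — they never influence the fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class MFAInput:
    """Individuals x quantitative variables with a group structure."""

    data: pd.DataFrame  # numeric, no missing values after row-drop
    groups: dict  # group name -> list of column names
    factors: pd.DataFrame | None = None  # supplementary qualitative factors

    def __post_init__(self) -> None:
        assigned = [c for cols in self.groups.values() for c in cols]
        if sorted(assigned) != sorted(set(assigned)):
            raise ValueError("each variable must belong to exactly one group")
        missing = set(assigned) - set(self.data.columns)
        if missing:
            raise ValueError(f"variables not in data: {sorted(missing)}")
        if self.data[assigned].isna().any().any():
            raise ValueError("missing values: drop rows listwise before the fit")


@dataclass
class MFAResult:
    eigenvalues: np.ndarray
    inertia_pct: np.ndarray
    individual_coords: pd.DataFrame  # (n, n_dims), columns dim1..dimK
    variable_correlations: pd.DataFrame  # variable x dimension correlation
    group_weights: dict  # group -> 1/lambda1
    column_weights: pd.Series  # per-column weight applied (1/sqrt(lambda1))
    standardized: pd.DataFrame  # centred/scaled (unweighted) columns
    n_individuals: int


def _standardize(data: pd.DataFrame, cols: list) -> pd.DataFrame:
    x = data[cols].to_numpy(float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)  # population (1/n) sd
    if np.any(sd <= 0):
        bad = [c for c, s in zip(cols, sd) if s <= 0]
        raise ValueError(f"constant column(s): {bad}")
    return pd.DataFrame((x - mu) / sd, index=data.index, columns=cols)


def _first_eigenvalue(z: np.ndarray) -> float:
    # first eigenvalue of the population covariance z'z/n
    s = np.linalg.svd(z, compute_uv=False)
    return float(s[0] ** 2 / z.shape[0])


def fit_mfa(inp: MFAInput, n_dims: int = 5) -> MFAResult:
    """Fit the group-weighted PCA.

    Dimension signs are fixed by forcing the variable with the largest
    absolute correlation on each dimension to be positive, so repeated
    runs are reproducible.
    """
    cols = [c for g in inp.groups.values() for c in g]
    n = len(inp.data)
    if n < 3:
        raise ValueError("need >=3 individuals")
    z_std = _standardize(inp.data, cols)

    col_w = {}
    group_w = {}
    for gname, gcols in inp.groups.items():
        lam1 = _first_eigenvalue(z_std[gcols].to_numpy())
        group_w[gname] = 1.0 / lam1
        for c in gcols:
            col_w[c] = 1.0 / np.sqrt(lam1)
    w = pd.Series(col_w)[cols]
    z_w = z_std.to_numpy() * w.to_numpy()

    rank = np.linalg.matrix_rank(z_w)
    if n_dims > rank:
        raise ValueError(f"n_dims={n_dims} exceeds rank {rank}")

    # global PCA with uniform row weights 1/n
    u, s, vt = np.linalg.svd(z_w / np.sqrt(n), full_matrices=False)
    eig = s**2
    coords = z_w @ vt.T[:, :n_dims]  # individual coordinates, pop. var = eig

    # correlations of the unweighted standardized variables with dimensions
    corr = np.empty((len(cols), n_dims))
    zs = z_std.to_numpy()
    for d in range(n_dims):
        f = coords[:, d]
        fsd = f.std()
        corr[:, d] = (zs * (f - f.mean())[:, None]).mean(axis=0) / np.where(fsd > 0, fsd, 1.0)

    # deterministic sign convention
    for d in range(n_dims):
        j = int(np.argmax(np.abs(corr[:, d])))
        if corr[j, d] < 0:
            corr[:, d] *= -1
            coords[:, d] *= -1

    dims = [f"dim{i + 1}" for i in range(n_dims)]
    return MFAResult(
        eigenvalues=eig,
        inertia_pct=100.0 * eig / eig.sum(),
        individual_coords=pd.DataFrame(coords, index=inp.data.index, columns=dims),
        variable_correlations=pd.DataFrame(corr, index=cols, columns=dims),
        group_weights=group_w,
        column_weights=w,
        standardized=z_std,
        n_individuals=n,
    )


def supplementary_categories(result: MFAResult, factor: pd.Series) -> pd.DataFrame:
    """Barycentre, v.test and cos^2 of each level of a qualitative factor.

    v.test on dimension d is the barycentre coordinate standardized by
    the sd of a random barycentre of n_k individuals drawn without
    replacement: barycentre_d * sqrt(n_k (n-1) / (n - n_k)) /
    sqrt(lambda_d).  |v.test| > 1.96 conventionally flags significant
    separation.  cos^2 is the squared share of each dimension in the
    barycentre's squared norm over the retained dimensions.
    """
    factor = factor.reindex(result.individual_coords.index)
    n = result.n_individuals
    coords = result.individual_coords
    dims = list(coords.columns)
    rows = []
    for level, idx in factor.groupby(factor).groups.items():
        n_k = len(idx)
        if n_k == 0 or n_k == n:
            raise ValueError(f"level {level!r}: v.test undefined for n_k in {{0, n}}")
        bary = coords.loc[idx].mean(axis=0).to_numpy()
        lam = result.eigenvalues[: len(dims)]
        vtest = bary * np.sqrt(n_k * (n - 1) / (n - n_k)) / np.sqrt(lam)
        norm2 = (bary**2).sum()
        cos2 = bary**2 / norm2 if norm2 > 0 else np.zeros_like(bary)
        row = dict(level=level, n=n_k)
        for d, name in enumerate(dims):
            row[f"coord_{name}"] = bary[d]
            row[f"vtest_{name}"] = vtest[d]
            row[f"cos2_{name}"] = cos2[d]
            row[f"significant_{name}"] = bool(abs(vtest[d]) > 1.96)
        rows.append(row)
    return pd.DataFrame(rows)


def dimension_description(result: MFAResult, factor: pd.Series) -> pd.DataFrame:
    """One-way ANOVA R^2 (with F-test p) of each dimension on a factor."""
    factor = factor.reindex(result.individual_coords.index)
    levels = factor.unique()
    if len(levels) < 2:
        raise ValueError("single-level factor")
    n = result.n_individuals
    k = len(levels)
    rows = []
    for name in result.individual_coords.columns:
        y = result.individual_coords[name].to_numpy()
        grand = y.mean()
        ss_tot = ((y - grand) ** 2).sum()
        ss_between = sum(
            len(idx) * (y[factor.index.get_indexer(idx)].mean() - grand) ** 2
            for _, idx in factor.groupby(factor).groups.items()
        )
        r2 = ss_between / ss_tot if ss_tot > 0 else 0.0
        df1, df2 = k - 1, n - k
        if r2 >= 1.0:
            p = 0.0
        else:
            f = (r2 / df1) / ((1 - r2) / df2)
            p = float(sps.f.sf(f, df1, df2))
        rows.append(dict(dimension=name, r2=float(r2), p=p))
    return pd.DataFrame(rows)


def confidence_ellipse(result: MFAResult, factor: pd.Series, level, coverage: float = 0.95) -> dict:
    """95% confidence ellipse of a category barycentre on (dim1, dim2).

    The ellipse is centred on the barycentre with shape equal to the
    sample covariance of the level's coordinates divided by n_k, and
    radius scaled by the chi-squared(2) quantile at ``coverage``.
    Returns centre, semi-axes, rotation angle and the generating
    covariance.
    """
    factor = factor.reindex(result.individual_coords.index)
    idx = factor.index[factor == level]
    n_k = len(idx)
    if n_k < 3:
        raise ValueError("need n_k >= 3 for an ellipse")
    pts = result.individual_coords.loc[idx, ["dim1", "dim2"]].to_numpy()
    centre = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False) / n_k
    eigval, eigvec = np.linalg.eigh(cov)
    if eigval[0] <= 1e-14 * max(eigval[1], 1.0):
        raise ValueError("degenerate covariance: collinear coordinates")
    q = sps.chi2.ppf(coverage, df=2) if coverage > 0 else 0.0
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    return dict(
        centre=centre,
        semi_axes=np.sqrt(eigval * q),
        angle_rad=float(np.arctan2(eigvec[1, 0], eigvec[0, 0])),
        covariance=cov,
        coverage=coverage,
        n=n_k,
    )


def ellipses_disjoint(e1: dict, e2: dict, n_points: int = 256) -> bool:
    """Conservative disjointness check: no boundary point of either ellipse
    lies inside the other, and centres are mutually outside."""

    def boundary(e):
        t = np.linspace(0, 2 * np.pi, n_points)
        circ = np.stack([e["semi_axes"][0] * np.cos(t), e["semi_axes"][1] * np.sin(t)])
        a = e["angle_rad"]
        rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        return (rot @ circ).T + e["centre"]

    def inside(e, pts):
        q = sps.chi2.ppf(e["coverage"], df=2)
        d = pts - e["centre"]
        inv = np.linalg.inv(e["covariance"])
        return np.einsum("ij,jk,ik->i", d, inv, d) <= q

    return not inside(e1, boundary(e2)).any() and not inside(e2, boundary(e1)).any()


def variable_factor_map(result: MFAResult, dims: tuple = ("dim1", "dim2")) -> pd.DataFrame:
    """Variable-dimension correlations and representation quality.

    Quality is the squared norm of a variable's correlation vector over
    the plotted dimensions; all points lie within the unit circle.
    """
    corr = result.variable_correlations[list(dims)]
    out = corr.copy()
    out["quality"] = (corr**2).sum(axis=1)
    return out


def build_mfa_input(
    study_table: pd.DataFrame,
    factors: tuple = ("group",),
    log10_loads: bool = True,
) -> MFAInput:
    """Assemble the default MFA input from a fetus-level study table.

    Variables: per-organ particle loads (log10-transformed by default),
    fetal + organ weights (no gonad weight — gonads are too small to
    weigh), and the derived weight ratios.  Rows with any missing
    active variable are dropped listwise (count retained in the index
    difference).  Factors are taken per fetus.
    """
    from .stats import _log10_with_zero_policy

    wide = study_table.pivot_table(index="fetus_id", columns="organ", values="cp_load", aggfunc="first")
    wide.columns = [f"load_{c}" for c in wide.columns]
    per_fetus = study_table.drop_duplicates("fetus_id").set_index("fetus_id")
    wide["fetal_weight"] = per_fetus["fetal_weight_g"]
    weights = study_table.pivot_table(index="fetus_id", columns="organ", values="organ_weight_g", aggfunc="first")
    for organ in ("placenta", "heart", "kidney", "liver", "lung"):
        if organ in weights:
            wide[f"weight_{organ}"] = weights[organ]
    ratios = study_table.pivot_table(index="fetus_id", columns="organ", values="weight_ratio_scaled", aggfunc="first")
    for organ in ratios.columns:
        wide[f"ratio_{organ}"] = ratios[organ]
    if "placental_efficiency" in study_table:
        wide["efficiency"] = per_fetus["placental_efficiency"]

    load_cols = [c for c in wide.columns if c.startswith("load_")]
    if log10_loads:
        for c in load_cols:
            wide[c], _ = _log10_with_zero_policy(wide[c].to_numpy())
    groups = {
        "cp_load": load_cols,
        "organ_weight": [c for c in wide.columns if c.startswith("weight_") or c == "fetal_weight"],
        "weight_ratio": [c for c in wide.columns if c.startswith("ratio_") or c == "efficiency"],
    }
    active = [c for g in groups.values() for c in g]
    keep = wide[active].dropna().index
    fac = per_fetus.loc[keep, list(factors)]
    if "group" in fac and "sex" in fac:
        fac = fac.assign(group_sex=fac["group"] + "/" + fac["sex"])
    return MFAInput(data=wide.loc[keep], groups=groups, factors=fac)
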