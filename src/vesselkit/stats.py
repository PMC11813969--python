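"""Inferential layer: within-tree correlations, site-type contrasts, and the
climate–trait correlation surface.

* :func:`rmcorr` — repeated-measures correlation: the common within-subject
  association between two variables, computed from subject-mean-centred data
  (the ANCOVA formulation) with df = N − k − 1.
* :func:`pearson_matrix` — between-tree trait intercorrelations on tree-wise
  means.
* :class:`SiteEffectModel` / :func:`site_effect_model` — linear mixed model
  of a (transformed) trait on site type with random intercepts for tree and
  for core nested in tree, ANOVA-style F-test, Bonferroni post-hoc contrasts
  with a compact letter display, and a robust Levene variance check.
* :func:`climate_trait_correlations` — rmcorr of first-differenced trait
  series against first-differenced 30-day window climate series, per
  trait × window × variable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .chronology import build_chronology, first_differences

__all__ = [
    "RmcorrResult",
    "rmcorr",
    "CorrelationMatrix",
    "pearson_matrix",
    "SiteComparison",
    "SiteEffectModel",
    "site_effect_model",
    "levene_test",
    "climate_trait_correlations",
    "significance_stars",
    "DEFAULT_TRANSFORMS",
    "UndefinedStatisticError",
    "InsufficientDataError",
]


class UndefinedStatisticError(ValueError):
    """The requested statistic is undefined on these data (e.g. constant x)."""


class InsufficientDataError(ValueError):
    """Too few observations, subjects or groups for the statistic."""


# ---------------------------------------------------------------------------
# repeated-measures correlation


@dataclass(frozen=True)
class RmcorrResult:
    r_rm: float
    df: int
    p_value: float
    n_subjects: int
    n_obs: int


def rmcorr(x, y, subject) -> RmcorrResult:
    """Repeated-measures correlation with the given subject labels.

    Pairs with a missing x or y are dropped; subjects left with fewer than
    two complete pairs are removed entirely (N and k adjusted).  Both
    variables are centred on their subject means; r_rm is the Pearson
    correlation of the centred values, which carries the sign of the common
    within-subject slope.  df = N − k − 1 (N − 2 in the degenerate single-
    subject case, where r_rm reduces to an ordinary Pearson correlation),
    and p comes from t = r·√(df / (1 − r²)) on that df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    subject = np.asarray(subject)
    if not (len(x) == len(y) == len(subject)):
        raise ValueError("x, y and subject must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y, subject = x[keep], y[keep], subject[keep]
    labels, counts = np.unique(subject, return_counts=True)
    valid = set(labels[counts >= 2])
    keep = np.array([s in valid for s in subject])
    x, y, subject = x[keep], y[keep], subject[keep]
    k = len(valid)
    n = len(x)
    if k == 0:
        raise InsufficientDataError("no subject has two complete pairs")
    df = n - 2 if k == 1 else n - k - 1
    if df < 1:
        raise InsufficientDataError(f"df = {df} < 1 (N={n}, k={k})")
    xc = np.empty_like(x)
    yc = np.empty_like(y)
    for s in valid:
        m = subject == s
        xc[m] = x[m] - x[m].mean()
        yc[m] = y[m] - y[m].mean()
    sx = float(xc @ xc)
    sy = float(yc @ yc)
    if sx == 0:
        raise UndefinedStatisticError("x is constant within every subject")
    if sy == 0:
        raise UndefinedStatisticError("y is constant within every subject")
    r = float(xc @ yc / np.sqrt(sx * sy))
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return RmcorrResult(r_rm=r, df=df, p_value=p, n_subjects=k, n_obs=n)


# ---------------------------------------------------------------------------
# tree-wise Pearson intercorrelations


@dataclass
class CorrelationMatrix:
    """Lower-triangle Pearson correlations with p<0.05 significance flags."""

    variables: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    n: int

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, v1 in enumerate(self.variables):
            for v2 in self.variables[:i]:
                rows.append(
                    {
                        "var_row": v1,
                        "var_col": v2,
                        "r": self.r.loc[v1, v2],
                        "p": self.p.loc[v1, v2],
                        "significant": self.p.loc[v1, v2] < 0.05,
                    }
                )
        return pd.DataFrame(rows)

    def render(self) -> pd.DataFrame:
        """Table-style rendering: non-significant r in parentheses."""
        out = pd.DataFrame("", index=self.variables[1:], columns=self.variables[:-1])
        for i, v1 in enumerate(self.variables):
            for v2 in self.variables[:i]:
                r = self.r.loc[v1, v2]
                cell = f"{r:.2f}" if self.p.loc[v1, v2] < 0.05 else f"({r:.2f})"
                out.loc[v1, v2] = cell
        return out


def treewise_means(
    trait_records: pd.DataFrame, variables=("LA", "VFrac", "VFreq", "GI", "SVI")
) -> pd.DataFrame:
    """Per-tree mean of each trait over combined-level ring records."""
    sel = trait_records[trait_records["level"] == "combined"]
    return (
        sel.groupby(["site_type", "tree_id"])[list(variables)].mean().reset_index()
    )


def pearson_matrix(
    means: pd.DataFrame,
    variables=("LA", "VFrac", "VFreq", "GI", "SVI"),
    grouping: str = "all",
) -> CorrelationMatrix | dict[str, CorrelationMatrix]:
    """Pearson intercorrelation matrix of tree-wise trait means.

    ``grouping="all"`` pools all trees; ``grouping="by_site"`` returns a dict
    of one matrix per site type plus a pooled ``"all"`` entry.
    """
    variables = list(variables)
    if grouping == "by_site":
        out = {"all": pearson_matrix(means, variables, "all")}
        for site, sub in means.groupby("site_type"):
            out[str(site)] = pearson_matrix(sub, variables, "all")
        return out
    n = len(means)
    if n < 3:
        raise InsufficientDataError("need at least three trees")
    r = pd.DataFrame(np.eye(len(variables)), index=variables, columns=variables)
    p = pd.DataFrame(np.zeros((len(variables), len(variables))), index=variables, columns=variables)
    for i, v1 in enumerate(variables):
        for j in range(i):
            v2 = variables[j]
            res = sps.pearsonr(means[v1], means[v2])
            r.loc[v1, v2] = r.loc[v2, v1] = res.statistic
            p.loc[v1, v2] = p.loc[v2, v1] = res.pvalue
    return CorrelationMatrix(variables, r, p, n)


# ---------------------------------------------------------------------------
# site-type mixed model


#: trait → variance-stabilising transform used before the mixed model
DEFAULT_TRANSFORMS = {
    "LA": "log",
    "THC": "log",
    "VI": "log",
    "VFreq": "sqrt",
    "VFrac": "none",
    "HWD": "none",
    "GI": "none",
    "SVI": "none",
}

_TRANSFORMS = {
    "none": (lambda v: v, lambda v: v),
    "log": (np.log, np.exp),
    "sqrt": (np.sqrt, np.square),
}


@dataclass
class SiteComparison:
    """Site-type effect on one trait from the nested mixed model."""

    trait_name: str
    transform: str
    F: float
    df_num: int
    df_den: int
    p_value: float
    means: dict[str, float]  # back-transformed marginal means per site
    pairwise: pd.DataFrame  # site_a, site_b, estimate, se, t, p_raw, p_adj
    letters: dict[str, str]  # compact letter display
    levene_stat: float
    levene_p: float
    variance_components: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    warnings: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            f"Site-type effect on {self.trait_name} ({self.transform} scale)",
            f"  F({self.df_num}, {self.df_den}) = {self.F:.2f}, p = {self.p_value:.4g}",
            f"  Levene (median-centred) p = {self.levene_p:.3g}",
            "  Marginal means (back-transformed):",
        ]
        for site, m in self.means.items():
            lines.append(f"    {site:<12} {m:10.4g}  {self.letters[site]}")
        return "\n".join(lines)


def levene_test(values, groups) -> tuple[float, float]:
    """Brown–Forsythe variance homogeneity test (median-centred Levene)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in np.unique(groups)]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise InsufficientDataError("Levene test needs >=2 groups with >=2 values")
    stat, p = sps.levene(*samples, center="median")
    return float(stat), float(p)


def _compact_letters(sites: list[str], means: dict[str, float], distinct) -> dict[str, str]:
    """Insert-and-absorb compact letter display for pairwise decisions.

    ``distinct(a, b)`` is True when sites a and b differ significantly.
    Sites sharing a letter are not significantly different.
    """
    order = sorted(sites, key=lambda s: means[s], reverse=True)
    groups: list[set[str]] = [set(order)]
    for a in order:
        for b in order:
            if means[a] <= means[b] or not distinct(a, b):
                continue
            new_groups = []
            for g in groups:
                if a in g and b in g:
                    ga, gb = g - {b}, g - {a}
                    for cand in (ga, gb):
                        if not any(cand <= other for other in new_groups):
                            new_groups.append(cand)
                else:
                    new_groups.append(g)
            groups = [
                g for g in new_groups if not any(g < other for other in new_groups)
            ]
    groups.sort(key=lambda g: -max(means[s] for s in g))
    letters = {s: "" for s in sites}
    for letter, g in zip("abcdefg", groups):
        for s in g:
            letters[s] += letter
    return letters


class SiteEffectModel:
    """Linear mixed model of one trait on site type.

    value ~ site_type (+ optional covariate), random intercepts for tree and
    for core nested within tree, fitted by REML through statsmodels'
    ``MixedLM`` (tree as the grouping factor, the nested core intercept as a
    variance component).  The REML fit supplies the variance decomposition
    and convergence diagnostics.

    The site-type F-test and the pairwise contrasts use the containment
    (expected-mean-squares) construction: site type and any tree-level
    covariate vary between trees only, so they are tested at the
    between-tree stratum — an ANOVA/ANCOVA on the per-tree means with
    denominator df = n_trees − (number of between-tree parameters).  For
    balanced data this is the classical exact mixed-design F; as the random
    variances vanish it coincides with the fixed-effects ANOVA on tree
    means, and it does not rely on boundary-sensitive variance estimates.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        trait_name: str,
        transform: str | None = None,
        covariate: str | None = None,
    ):
        if transform is None:
            transform = DEFAULT_TRANSFORMS.get(trait_name, "none")
        if transform not in _TRANSFORMS:
            raise ValueError(f"unknown transform {transform!r}")
        sel = data
        if "level" in data.columns:
            sel = data[data["level"] == "core"]
        sel = sel.dropna(subset=[trait_name]).copy()
        sites = sorted(sel["site_type"].unique())
        if len(sites) < 2 or any(
            sel[sel["site_type"] == s]["tree_id"].nunique() < 2 for s in sites
        ):
            raise InsufficientDataError("need >=2 sites with >=2 trees each")
        fwd, _ = _TRANSFORMS[transform]
        if transform in ("log", "sqrt") and (sel[trait_name] <= 0).any():
            if transform == "log" or (sel[trait_name] < 0).any():
                raise ValueError(
                    f"{transform} transform needs positive {trait_name} values"
                )
        sel["y_"] = fwd(sel[trait_name].to_numpy(dtype=float))
        self.data = sel
        self.trait_name = trait_name
        self.transform = transform
        self.covariate = covariate
        self.sites = sites

    def fit(self, reml: bool = True) -> SiteComparison:
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        from statsmodels.tools.sm_exceptions import ConvergenceWarning

        data = self.data
        notes: list[str] = []
        converged = True
        variance_components: dict[str, float] = {}
        if reml:
            formula = "y_ ~ C(site_type)"
            if self.covariate:
                formula += f" + {self.covariate}"
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                try:
                    mixed = smf.mixedlm(
                        formula,
                        data,
                        groups="tree_id",
                        re_formula="1",
                        vc_formula={"core": "0 + C(core_id)"},
                    ).fit(reml=True)
                    variance_components = {
                        "tree": float(mixed.cov_re.iloc[0, 0]),
                        "core_in_tree": float(mixed.vcomp[0]),
                        "residual": float(mixed.scale),
                    }
                except np.linalg.LinAlgError as err:  # singular fit
                    converged = False
                    notes.append(str(err))
            for w in caught:
                if issubclass(w.category, (ConvergenceWarning, RuntimeWarning, UserWarning)):
                    converged = False
                    notes.append(str(w.message))

        # between-tree stratum: ANOVA/ANCOVA on per-tree means
        agg = {"y_": "mean", "site_type": "first"}
        if self.covariate:
            agg[self.covariate] = "mean"
        tree = data.groupby("tree_id").agg(agg).reset_index()
        k = len(tree)
        exog = pd.get_dummies(
            tree["site_type"], prefix="site", drop_first=True, dtype=float
        )
        site_cols = list(exog.columns)
        exog.insert(0, "const", 1.0)
        if self.covariate:
            exog[self.covariate] = tree[self.covariate].to_numpy()
        ols = sm.OLS(tree["y_"].to_numpy(), exog).fit()
        q = len(site_cols)
        df_den = k - exog.shape[1]
        if df_den < 1:
            raise InsufficientDataError("fewer trees than between-tree parameters")
        L = np.zeros((q, exog.shape[1]))
        for row, name in enumerate(site_cols):
            L[row, list(exog.columns).index(name)] = 1.0
        F = float(ols.f_test(L).fvalue)
        p = float(sps.f.sf(F, q, df_den))

        # marginal means on the transformed scale (covariate at its mean)
        _, back = _TRANSFORMS[self.transform]
        params = ols.params
        cov_b = ols.cov_params()
        base = params["const"]
        if self.covariate:
            base = base + params[self.covariate] * tree[self.covariate].mean()
        site_coef = {s: 0.0 for s in self.sites}
        for name in site_cols:
            site_coef[name.removeprefix("site_")] = params[name]
        tmeans = {s: float(base + site_coef[s]) for s in self.sites}
        means = {s: float(back(m)) for s, m in tmeans.items()}

        # pairwise contrasts at the tree stratum, Bonferroni over the 3 pairs
        pairs = [
            (a, b) for i, a in enumerate(self.sites) for b in self.sites[i + 1 :]
        ]
        rows = []
        colnames = list(exog.columns)
        for a, b in pairs:
            lvec = np.zeros(exog.shape[1])
            for s, sign in ((a, 1.0), (b, -1.0)):
                name = f"site_{s}"
                if name in colnames:
                    lvec[colnames.index(name)] = sign
            est = float(lvec @ params.to_numpy())
            se = float(np.sqrt(lvec @ cov_b.to_numpy() @ lvec))
            t = est / se if se > 0 else np.nan
            p_raw = float(2 * sps.t.sf(abs(t), df_den)) if np.isfinite(t) else np.nan
            rows.append(
                {
                    "site_a": a,
                    "site_b": b,
                    "estimate": est,
                    "se": se,
                    "t": t,
                    "p_raw": p_raw,
                    "p_adj": min(1.0, len(pairs) * p_raw) if np.isfinite(p_raw) else np.nan,
                }
            )
        pairwise = pd.DataFrame(rows)

        sig = {
            frozenset((r.site_a, r.site_b)): (r.p_adj < 0.05)
            for r in pairwise.itertuples()
        }
        # a non-significant global test reports no pairwise separation
        if p >= 0.05:
            sig = {k: False for k in sig}
        letters = _compact_letters(
            self.sites, tmeans, lambda a, b: sig[frozenset((a, b))]
        )

        lev_stat, lev_p = levene_test(data["y_"].to_numpy(), data["site_type"].to_numpy())
        return SiteComparison(
            trait_name=self.trait_name,
            transform=self.transform,
            F=F,
            df_num=q,
            df_den=df_den,
            p_value=p,
            means=means,
            pairwise=pairwise,
            letters=letters,
            levene_stat=lev_stat,
            levene_p=lev_p,
            variance_components=variance_components,
            converged=converged,
            warnings=notes,
        )


def site_effect_model(
    data: pd.DataFrame,
    trait_name: str,
    transform: str | None = None,
    covariate: str | None = None,
) -> SiteComparison:
    """Fit the nested mixed model for one trait; see :class:`SiteEffectModel`."""
    return SiteEffectModel(data, trait_name, transform, covariate).fit()


# ---------------------------------------------------------------------------
# climate–trait correlation surface


def significance_stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def climate_trait_correlations(
    trait_records: pd.DataFrame,
    climate_matrix: pd.DataFrame,
    site_type: str,
    traits=("LA", "VFreq", "GI"),
    variables=("tmean_mean", "precip_sum", "hmi"),
    detrend: bool = True,
) -> pd.DataFrame:
    """rmcorr surface of (detrended) traits vs (detrended) window climate.

    Both the per-tree trait series and each window's yearly climate series
    are first-differenced (``detrend=True``), then correlated with tree as
    the subject, separately per trait × window × climate variable.  Cells
    where the climate series is constant or the overlap insufficient carry
    NaN.  Returns a long table with r, p, df, n and star codes — the machine
    form of a climate-correlation heat map.
    """
    windows = climate_matrix["window_label"].unique()
    rows = []
    for trait in traits:
        chron = build_chronology(trait_records, trait, site_type)
        tree_diffs: dict[str, pd.Series] = {}
        for tree in chron.series.columns:
            s = chron.series[tree].dropna()
            if len(s) >= 2:
                d = first_differences(s) if detrend else s
                tree_diffs[tree] = d.dropna()
        for label in windows:
            wsub = climate_matrix[climate_matrix["window_label"] == label].set_index(
                "ring_year"
            )
            for var in variables:
                series = wsub[var].dropna().sort_index()
                if len(series) >= 2:
                    cdiff = (first_differences(series) if detrend else series).dropna()
                else:
                    cdiff = pd.Series(dtype=float)
                x_all, y_all, subj = [], [], []
                for tree, tdiff in tree_diffs.items():
                    common = tdiff.index.intersection(cdiff.index)
                    x_all.extend(cdiff.loc[common].to_numpy())
                    y_all.extend(tdiff.loc[common].to_numpy())
                    subj.extend([tree] * len(common))
                r = p = np.nan
                df = n = 0
                if subj:
                    try:
                        res = rmcorr(x_all, y_all, subj)
                        r, p, df, n = res.r_rm, res.p_value, res.df, res.n_obs
                    except (UndefinedStatisticError, InsufficientDataError):
                        pass
                rows.append(
                    {
                        "site_type": site_type,
                        "trait": trait,
                        "window_label": label,
                        "variable": var,
                        "r": r,
                        "p": p,
                        "df": df,
                        "n_obs": n,
                        "stars": significance_stars(p) if not np.isnan(p) else "",
                    }
                )
    return pd.DataFrame(rows)
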