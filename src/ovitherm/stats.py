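"""Group-comparison and correlation statistics.

The inferential layer mirrors the analysis style of a classic two-group
repeated-stressor animal study:

* name-driven variable transformations to normalise skewed assay
  distributions (log for oxidative stress, reciprocal for prolactin,
  ``1/sqrt`` for DHEA);
* Shapiro–Wilk and Bartlett checks of normality and variance homogeneity;
* factorial ordinary-least-squares models (group × session × time) with
  Type-III term tests, iterative pruning of non-significant interactions,
  and Bonferroni-adjusted pairwise contrasts of estimated marginal means;
* linear mixed-effects models (random animal intercept) for the
  circadian-period comparisons, with Benjamini–Hochberg (FDR) adjusted
  pairwise period contrasts;
* a Pearson correlation matrix over per-animal measures with listwise
  exclusion of animals carrying any missing variable.

Model matrices use sum-to-zero factor coding so the Type-III style term
tests are well defined for unbalanced data; fits go through statsmodels.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ModelSpec",
    "StatsResult",
    "CorrelationMatrix",
    "TransformResult",
    "transform_variable",
    "inverse_transform",
    "check_assumptions",
    "fit_factorial",
    "fit_mixed_periods",
    "correlation_matrix",
]

ALPHA = 0.05


# ---------------------------------------------------------------------------
# transformations


@dataclass
class TransformResult:
    name: str
    transform: str
    values: np.ndarray
    excluded: list[int] = field(default_factory=list)


def _transform_kind(name: str) -> str:
    low = name.lower()
    if "oxy" in low or "oxidative" in low:
        return "log"
    if "prolactin" in low:
        return "reciprocal"
    if "dhea" in low:
        return "inverse_sqrt"
    return "identity"


def transform_variable(name: str, values) -> TransformResult:
    """Normalising transformation selected by variable name.

    Oxidative-stress ratios are log-transformed, prolactin is
    reciprocal-transformed, DHEA gets ``1/sqrt``; everything else passes
    through unchanged.  Records violating the transform's domain (e.g. a
    non-positive value under log) are flagged, set to NaN and listed in
    ``excluded`` rather than silently dropped.
    """
    x = np.asarray(values, dtype=float)
    kind = _transform_kind(name)
    out = x.copy()
    excluded: list[int] = []
    with np.errstate(divide="ignore", invalid="ignore"):
        if kind == "log":
            bad = ~(x > 0)
            out = np.where(bad, np.nan, np.log(x))
        elif kind == "reciprocal":
            bad = x == 0
            out = np.where(bad, np.nan, 1.0 / x)
        elif kind == "inverse_sqrt":
            bad = ~(x > 0)
            out = np.where(bad, np.nan, 1.0 / np.sqrt(x))
        else:
            bad = np.zeros_like(x, dtype=bool)
    bad |= np.isnan(x)
    excluded = list(np.nonzero(bad)[0])
    return TransformResult(name=name, transform=kind, values=out, excluded=excluded)


def inverse_transform(name: str, values) -> np.ndarray:
    """Back-transform to the original measurement scale (exact inverse)."""
    x = np.asarray(values, dtype=float)
    kind = _transform_kind(name)
    if kind == "log":
        return np.exp(x)
    if kind == "reciprocal":
        return 1.0 / x
    if kind == "inverse_sqrt":
        return 1.0 / x**2
    return x.copy()


# ---------------------------------------------------------------------------
# assumption checks


@dataclass
class Diagnostics:
    shapiro_w: float = math.nan
    shapiro_p: float = math.nan
    bartlett_stat: float = math.nan
    bartlett_p: float = math.nan
    flagged: bool = False
    flag_reason: str = ""


def check_assumptions(values, groups) -> Diagnostics:
    """Shapiro–Wilk normality of within-group residuals + Bartlett homogeneity.

    Residuals are values minus their group mean, so the normality check
    applies to the error term of a one-way group model, not the raw
    (possibly group-shifted) values.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise ValueError("values and groups must align")
    levels = pd.unique(groups)
    samples = [values[groups == g] for g in levels]
    if any(len(s) < 3 for s in samples):
        return Diagnostics(flagged=True, flag_reason="fewer than 3 obs in a group")
    if np.ptp(values) == 0:
        return Diagnostics(flagged=True, flag_reason="constant data")
    resid = np.concatenate([s - s.mean() for s in samples])
    if np.ptp(resid) == 0:
        return Diagnostics(flagged=True, flag_reason="zero-range residuals")
    w, p_w = scipy.stats.shapiro(resid)
    if len(samples) < 2 or any(np.ptp(s) == 0 for s in samples):
        return Diagnostics(
            shapiro_w=float(w), shapiro_p=float(p_w),
            flagged=True, flag_reason="Bartlett undefined (single or constant group)",
        )
    b, p_b = scipy.stats.bartlett(*samples)
    return Diagnostics(
        shapiro_w=float(w), shapiro_p=float(p_w),
        bartlett_stat=float(b), bartlett_p=float(p_b),
    )


# ---------------------------------------------------------------------------
# factorial models


@dataclass
class ModelSpec:
    """Declarative description of one factorial analysis."""

    outcome: str
    fixed_factors: list[str]
    interactions: list[tuple[str, ...]] = field(default_factory=list)
    pruning: bool = True
    pairwise_adjustment: str = "bonferroni"  # bonferroni | fdr | none
    random_intercept: str | None = None
    transform: str = "auto"  # auto (by outcome name) | none
    alpha: float = ALPHA

    def __post_init__(self) -> None:
        self.interactions = [tuple(t) for t in self.interactions]
        for term in self.interactions:
            unknown = set(term) - set(self.fixed_factors)
            if unknown:
                raise ValueError(
                    f"interaction {term} references undeclared factors {unknown}"
                )
        if self.pairwise_adjustment not in ("bonferroni", "fdr", "none"):
            raise ValueError(f"unknown adjustment {self.pairwise_adjustment!r}")

    def all_interactions(self) -> list[tuple[str, ...]]:
        """Declared interactions, or every 2..k-way product if none given."""
        if self.interactions:
            return list(self.interactions)
        out = []
        for r in range(2, len(self.fixed_factors) + 1):
            out.extend(itertools.combinations(self.fixed_factors, r))
        return out


@dataclass
class StatsResult:
    """Term tests, pruning trail, pairwise contrasts and diagnostics."""

    terms: pd.DataFrame
    pairwise: pd.DataFrame
    pruned_terms: list[tuple[str, ...]] = field(default_factory=list)
    transformation: str = "identity"
    diagnostics: Diagnostics = field(default_factory=Diagnostics)
    excluded_rows: list[int] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def _sum_coding(levels: list) -> dict:
    """Sum-to-zero contrast rows per level (last level = -1 everywhere)."""
    k = len(levels)
    rows = {}
    for i, lev in enumerate(levels):
        if i < k - 1:
            row = np.zeros(k - 1)
            row[i] = 1.0
        else:
            row = -np.ones(k - 1)
        rows[lev] = row
    return rows


def _term_columns(term: tuple[str, ...], codings: dict, frame: pd.DataFrame) -> np.ndarray:
    """Design columns for one term: Kronecker products of factor codings."""
    blocks = []
    for _, row in frame.iterrows():
        vecs = [codings[f][row[f]] for f in term]
        prod = vecs[0]
        for v in vecs[1:]:
            prod = np.outer(prod, v).ravel()
        blocks.append(prod)
    return np.asarray(blocks)


def _build_design(
    frame: pd.DataFrame, terms: list[tuple[str, ...]], codings: dict
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    cols = [np.ones((len(frame), 1))]
    spans = []
    start = 1
    for term in terms:
        block = _term_columns(term, codings, frame)
        cols.append(block)
        spans.append((start, start + block.shape[1]))
        start += block.shape[1]
    return np.hstack(cols), spans


def _type3_table(
    y: np.ndarray, X: np.ndarray, spans: list[tuple[int, int]],
    terms: list[tuple[str, ...]],
) -> tuple[pd.DataFrame, sm.regression.linear_model.RegressionResultsWrapper]:
    fit = sm.OLS(y, X).fit()
    rss_full = float(fit.ssr)
    df_resid = float(fit.df_resid)
    if df_resid <= 0:
        raise ValueError("saturated model: zero residual degrees of freedom")
    rows = []
    mse = rss_full / df_resid
    for term, (a, b) in zip(terms, spans):
        keep = [i for i in range(X.shape[1]) if not (a <= i < b)]
        fit_r = sm.OLS(y, X[:, keep]).fit()
        q = b - a
        ss_term = max(float(fit_r.ssr) - rss_full, 0.0)
        if mse > 0:
            F = (ss_term / q) / mse
        else:
            # perfect fit: the term either explains something (F unbounded)
            # or nothing at all
            F = math.inf if ss_term > 0 else math.nan
        p = float(scipy.stats.f.sf(F, q, df_resid)) if math.isfinite(F) else (
            0.0 if F == math.inf else math.nan)
        rows.append(
            {"term": ":".join(term), "df_num": q, "df_den": df_resid,
             "F": float(F), "p": p}
        )
    return pd.DataFrame(rows), fit


def _emm_contrasts(
    frame: pd.DataFrame, factors: list[str],
    terms: list[tuple[str, ...]], codings: dict,
    fit, adjustment: str,
) -> pd.DataFrame:
    """Pairwise estimated-marginal-mean contrasts per factor.

    EMMs average the model prediction over the full factorial grid of the
    other factors (equal cell weights), so on balanced data they reduce to
    cell-mean contrasts.  Adjustment is applied within each factor's
    family of pairwise comparisons.
    """
    levels = {f: sorted(frame[f].unique()) for f in factors}
    grid = pd.DataFrame(
        list(itertools.product(*[levels[f] for f in factors])), columns=factors
    )
    Xg, _ = _build_design(grid, terms, codings)
    beta = fit.params
    cov = fit.cov_params()
    df_resid = float(fit.df_resid)
    rows = []
    for f in factors:
        fam = []
        for a, b in itertools.combinations(levels[f], 2):
            ca = Xg[(grid[f] == a).to_numpy()].mean(axis=0)
            cb = Xg[(grid[f] == b).to_numpy()].mean(axis=0)
            c = ca - cb
            est = float(c @ beta)
            se = float(np.sqrt(c @ cov @ c))
            t = est / se if se > 0 else math.nan
            p = float(2.0 * scipy.stats.t.sf(abs(t), df_resid)) if se > 0 else math.nan
            fam.append({"factor": f, "level_a": a, "level_b": b,
                        "estimate": est, "se": se, "statistic": t,
                        "df": df_resid, "p_raw": p})
        if fam:
            praw = [r["p_raw"] for r in fam]
            if adjustment == "bonferroni":
                padj = multipletests(praw, method="bonferroni")[1]
            elif adjustment == "fdr":
                padj = multipletests(praw, method="fdr_bh")[1]
            else:
                padj = praw
            for r, pa in zip(fam, padj):
                r["p_adj"] = float(pa)
            rows.extend(fam)
    return pd.DataFrame(rows)


def fit_factorial(spec: ModelSpec, data: pd.DataFrame) -> StatsResult:
    """Factorial OLS with interaction pruning and pairwise contrasts.

    Fits ``outcome ~ factors + interactions`` with sum-to-zero coding and
    Type-III style term F tests (each term dropped from the otherwise full
    model).  When ``spec.pruning`` is on, non-significant interactions
    (p ≥ alpha) are removed iteratively — highest order first, largest p
    first — and the model refitted, so a retained interaction is always
    significant in the model it was tested in.  Pairwise contrasts of
    estimated marginal means are computed for each main factor and
    adjusted per ``spec.pairwise_adjustment``.
    """
    frame = data[[spec.outcome, *spec.fixed_factors]].copy()
    tr = (
        transform_variable(spec.outcome, frame[spec.outcome].to_numpy())
        if spec.transform == "auto"
        else TransformResult(spec.outcome, "identity",
                             frame[spec.outcome].to_numpy(dtype=float))
    )
    frame[spec.outcome] = tr.values
    excluded = list(frame.index[frame[spec.outcome].isna()])
    frame = frame.dropna(subset=[spec.outcome]).reset_index(drop=True)
    codings = {
        f: _sum_coding(sorted(frame[f].unique())) for f in spec.fixed_factors
    }
    main_terms = [(f,) for f in spec.fixed_factors]
    interactions = sorted(spec.all_interactions(), key=len)
    pruned: list[tuple[str, ...]] = []
    y = frame[spec.outcome].to_numpy(dtype=float)
    while True:
        terms = main_terms + interactions
        X, spans = _build_design(frame, terms, codings)
        table, fit = _type3_table(y, X, spans, terms)
        if not spec.pruning or not interactions:
            break
        inter_rows = table.iloc[len(main_terms):]
        candidates = [
            (len(interactions[i]), inter_rows.iloc[i]["p"], i)
            for i in range(len(interactions))
            if inter_rows.iloc[i]["p"] >= spec.alpha
        ]
        if not candidates:
            break
        # drop the highest-order, then largest-p, non-significant interaction
        _, _, idx = max(candidates, key=lambda c: (c[0], c[1]))
        pruned.append(interactions.pop(idx))
    pairwise = _emm_contrasts(
        frame, spec.fixed_factors, terms, codings, fit,
        spec.pairwise_adjustment,
    )
    cells = frame[spec.fixed_factors].astype(str).agg("/".join, axis=1)
    diag = check_assumptions(y, cells.to_numpy())
    return StatsResult(
        terms=table,
        pairwise=pairwise,
        pruned_terms=pruned,
        transformation=tr.transform,
        diagnostics=diag,
        excluded_rows=excluded,
    )


# ---------------------------------------------------------------------------
# mixed-effects period comparisons


def fit_mixed_periods(
    data: pd.DataFrame,
    outcome: str = "value",
    period: str = "period",
    animal: str = "animal_id",
    baseline: str | None = "P1",
    alpha: float = ALPHA,
) -> StatsResult:
    """Mixed model for repeated per-animal period measures.

    Fits ``outcome ~ period`` with a random intercept per animal by REML,
    reports the overall period effect (Wald test) and every pairwise
    period contrast with Benjamini–Hochberg (FDR) adjusted p-values;
    contrasts against the ``baseline`` period are first in the table.
    With a single animal the random intercept is dropped (plain OLS on
    the period means) and a warning recorded.
    """
    frame = data[[animal, period, outcome]].dropna().reset_index(drop=True)
    periods = sorted(frame[period].unique())
    if len(periods) < 2:
        raise ValueError("need at least two periods")
    if baseline is not None and baseline in periods:
        periods = [baseline] + [p for p in periods if p != baseline]
    ref, others = periods[0], periods[1:]
    # treatment coding against the reference period
    X = np.column_stack(
        [np.ones(len(frame))]
        + [(frame[period] == p).to_numpy(dtype=float) for p in others]
    )
    y = frame[outcome].to_numpy(dtype=float)
    warns: list[str] = []
    n_animals = frame[animal].nunique()
    if n_animals < 2:
        warns.append("single animal: degenerated to ordinary least squares")
        if len(frame) <= X.shape[1]:
            raise ValueError(
                "single animal with one observation per period: "
                "no residual degrees of freedom")
        fit = sm.OLS(y, X).fit()
        cov = np.asarray(fit.cov_params())
        use_t, df_resid = True, float(fit.df_resid)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.MixedLM(y, X, groups=frame[animal]).fit(reml=True)
        cov = np.asarray(fit.cov_params())[: X.shape[1], : X.shape[1]]
        use_t, df_resid = False, math.inf
    beta = np.asarray(fit.params)[: X.shape[1]]
    # overall period effect: joint Wald test on the period coefficients
    R = np.zeros((len(others), X.shape[1]))
    for i in range(len(others)):
        R[i, 1 + i] = 1.0
    diff = R @ beta
    stat = float(diff @ np.linalg.solve(R @ cov @ R.T, diff))
    q = len(others)
    if use_t:
        Fstat = stat / q
        p_overall = float(scipy.stats.f.sf(Fstat, q, df_resid))
        term_row = {"term": period, "df_num": q, "df_den": df_resid,
                    "F": Fstat, "p": p_overall}
    else:
        p_overall = float(scipy.stats.chi2.sf(stat, q))
        term_row = {"term": period, "df_num": q, "df_den": math.inf,
                    "F": stat / q, "p": p_overall}
    # pairwise contrasts: coefficient differences under treatment coding
    coef = {ref: 0.0}
    coef.update({p: beta[1 + i] for i, p in enumerate(others)})
    cvec = {ref: np.zeros(X.shape[1])}
    for i, p in enumerate(others):
        v = np.zeros(X.shape[1])
        v[1 + i] = 1.0
        cvec[p] = v
    rows = []
    pair_list = [(ref, p) for p in others] + list(itertools.combinations(others, 2))
    for a, b in pair_list:
        c = cvec[b] - cvec[a]
        est = float(c @ beta)
        se = float(np.sqrt(c @ cov @ c))
        z = est / se if se > 0 else 0.0
        if use_t:
            p_raw = float(2.0 * scipy.stats.t.sf(abs(z), df_resid))
        else:
            p_raw = float(2.0 * scipy.stats.norm.sf(abs(z)))
        rows.append({"factor": period, "level_a": b, "level_b": a,
                     "estimate": est, "se": se, "statistic": z,
                     "df": df_resid, "p_raw": p_raw})
    padj = multipletests([r["p_raw"] for r in rows], method="fdr_bh")[1]
    for r, pa in zip(rows, padj):
        r["p_adj"] = float(pa)
    return StatsResult(
        terms=pd.DataFrame([term_row]),
        pairwise=pd.DataFrame(rows),
        transformation="identity",
        warnings=warns,
    )


# ---------------------------------------------------------------------------
# correlations


@dataclass
class CorrelationMatrix:
    """Pearson r and p over per-animal measures, listwise complete cases."""

    variables: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    n: int
    excluded_animals: list[str] = field(default_factory=list)
    undefined: list[str] = field(default_factory=list)


def correlation_matrix(
    table: pd.DataFrame, animal: str = "animal_id"
) -> CorrelationMatrix:
    """Pairwise Pearson correlations with listwise animal exclusion.

    Any animal with a missing value in any variable is excluded from every
    pair (so all pairs share the same n).  Zero-variance variables have
    undefined correlations; they are reported in ``undefined`` and their
    rows/columns set to NaN (diagonal kept at 1).
    """
    if animal in table.columns:
        table = table.set_index(animal)
    variables = list(table.columns)
    complete = table.dropna()
    excluded = [str(a) for a in table.index.difference(complete.index)]
    n = len(complete)
    if n < 3:
        raise ValueError("need at least 3 complete animals")
    undefined = [v for v in variables if np.ptp(complete[v].to_numpy()) == 0]
    r = pd.DataFrame(np.eye(len(variables)), index=variables, columns=variables)
    p = pd.DataFrame(np.full((len(variables),) * 2, np.nan),
                     index=variables, columns=variables)
    for a, b in itertools.combinations(variables, 2):
        if a in undefined or b in undefined:
            r.loc[a, b] = r.loc[b, a] = np.nan
            continue
        res = scipy.stats.pearsonr(complete[a], complete[b])
        r.loc[a, b] = r.loc[b, a] = float(res.statistic)
        p.loc[a, b] = p.loc[b, a] = float(res.pvalue)
    for v in undefined:
        r.loc[v, v] = np.nan
    return CorrelationMatrix(
        variables=variables, r=r, p=p, n=n,
        excluded_animals=excluded, undefined=undefined,
    )
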