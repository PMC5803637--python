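"""Odds of citation: fixed-effects and random-intercept logistic models.

The outcome is whether a potential citation path was realized; determinants
are characteristics of the cited article (or of the pair, for self-citation,
time to citation, authority and concordance).  Because one citing article
contributes many paths, the main estimator is a logistic regression with a
normally distributed random intercept per citing article; the marginal
likelihood is integrated by adaptive Gauss-Hermite quadrature (default 15
nodes, centred per cluster at the conditional mode).  Fixed-effects models
go through statsmodels; the 2x2 cross-product odds ratio with its Wald
interval is provided as a closed-form oracle for the univariate binary case.

Non-convergence (degenerate determinant, separation, failed optimisation) is
reported via ``ModelResult.converged`` — estimates are never silently
defaulted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from numpy.polynomial.hermite import hermgauss
from scipy import optimize
from scipy.special import expit, log_expit, logsumexp
from scipy.stats import chi2_contingency
from statsmodels.tools import numdiff

from .derived_metrics import CONCORDANCE_ATTRIBUTES
from .path_builder import PathDataset
from .records_io import ArticleRecord, effective_publication_date

# --------------------------------------------------------------------------
# Categorization (characteristics-table bands)
# --------------------------------------------------------------------------

#: corresponding-author country -> reported region
COUNTRY_REGION = {
    "belgium": "belgium",
    "netherlands": "other-nw-europe",
    "germany": "other-nw-europe",
    "uk": "other-nw-europe",
    "united kingdom": "other-nw-europe",
    "norway": "other-nw-europe",
    "sweden": "other-nw-europe",
    "denmark": "other-nw-europe",
    "finland": "other-nw-europe",
    "ireland": "other-nw-europe",
    "italy": "south-europe",
    "spain": "south-europe",
    "france": "south-europe",
    "portugal": "south-europe",
    "greece": "south-europe",
    "croatia": "south-europe",
    "usa": "north-america",
    "canada": "north-america",
}


def country_region(country: str) -> str:
    return COUNTRY_REGION.get(country.strip().lower(), "other")


def categorize(attribute: str, value) -> str | None:
    """Band a raw value the way the characteristics table reports it.

    All bands are half-open, lower-inclusive; a boundary value belongs to
    the upper band (40 references falls in ">=40").  None passes through
    (missing stays missing); negative values are errors.
    """
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    v = float(value)
    if v < 0:
        raise ValueError(f"negative value {value!r} for {attribute!r}")
    if attribute == "sample_size":
        return "low" if v < 200 else ("medium" if v < 2000 else "high")
    if attribute == "n_authors":
        return "1-2" if v <= 2 else ("3-4" if v <= 4 else ("5-6" if v <= 6 else ">=7"))
    if attribute == "n_affiliations":
        return "1" if v <= 1 else ("2" if v <= 2 else ">=3")
    if attribute == "n_references":
        return "<25" if v < 25 else ("25-40" if v < 40 else ">=40")
    if attribute == "journal_impact_factor":
        return "0-2" if v < 2 else ("2-4" if v < 4 else ">=4")
    if attribute == "authority":
        return "low" if v <= 5 else ("medium" if v <= 50 else "high")
    if attribute == "time_to_citation":
        k = int(v)  # years band [k, k+1)
        return f"{k}-<{k + 1}" if k < 8 else ">=8"
    raise ValueError(f"no banding defined for attribute {attribute!r}")


def round_or(value: float) -> float:
    """One-decimal, half-up rounding used for odds-ratio display."""
    return float(Decimal(repr(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# --------------------------------------------------------------------------
# Contingency oracle and chi-square discordance test
# --------------------------------------------------------------------------

Z975 = 1.959963984540054


def contingency_or(a: int, b: int, c: int, d: int) -> tuple[float, float, float]:
    """Cross-product odds ratio with Wald 95% CI for a 2x2 table.

    Cells are (exposed-outcome a, exposed-no-outcome b, unexposed-outcome c,
    unexposed-no-outcome d).  Zero cells are errors — no silent continuity
    correction is applied.
    """
    cells = (a, b, c, d)
    if any(x <= 0 for x in cells):
        raise ValueError(f"all four cells must be positive, got {cells}")
    oddsratio = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(oddsratio)
    return (
        oddsratio,
        math.exp(log_or - Z975 * se),
        math.exp(log_or + Z975 * se),
    )


def discordance_test(
    records: Sequence[ArticleRecord],
) -> tuple[float, int, float, pd.DataFrame]:
    """Pearson chi-square of data-based vs authors' conclusion (empirical only).

    Cross-tabulates the data-based conclusion (positive/negative) against
    the authors' conclusion dichotomised as positive vs not-positive, with
    no continuity correction.  A non-zero statistic with the asymmetric
    pattern (negative data interpreted as positive, never the reverse)
    signals spin in the authors' interpretation.
    """
    counts = np.zeros((2, 2), dtype=float)
    for rec in records:
        attrs = rec.attributes
        if attrs is None or attrs.article_type != "empirical":
            continue
        if attrs.data_based_conclusion not in ("positive", "negative"):
            continue
        i = 0 if attrs.data_based_conclusion == "positive" else 1
        j = 0 if attrs.authors_conclusion == "positive" else 1
        counts[i, j] += 1
    if counts.sum() < 2 or (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        raise ValueError("discordance test needs both conclusions on >= 2 articles "
                         "with non-empty margins")
    chi2, p_value, dof, _ = chi2_contingency(counts, correction=False)
    table = pd.DataFrame(
        counts.astype(int),
        index=pd.Index(["data-positive", "data-negative"], name="data_based"),
        columns=pd.Index(["authors-positive", "authors-not-positive"], name="authors"),
    )
    return float(chi2), int(dof), float(p_value), table


# --------------------------------------------------------------------------
# Path-level covariate table
# --------------------------------------------------------------------------


def covariate_frame(
    dataset: PathDataset, records: Sequence[ArticleRecord]
) -> pd.DataFrame:
    """Materialize one analysis row per path with all determinants.

    Determinant columns describe the *cited* article (the question is which
    characteristics attract citations); ``citing_``-prefixed
    columns exist for clustering, adjustment and subsetting.
    Paths must have been annotated (self-citation/authority/concordance).
    """
    by_id = {r.article_id: r for r in records}
    rows = []
    for p in dataset.paths:
        if p.self_citation is None or p.authority_band is None:
            raise ValueError("paths must be annotated before building covariates")
        cited = by_id[p.cited_id]
        citing = by_id[p.citing_id]
        ca = cited.attributes
        if ca is None or citing.attributes is None:
            raise ValueError("records must carry merged coded attributes")
        row = {
            "citing_id": p.citing_id,
            "cited_id": p.cited_id,
            "realized": int(p.realized),
            "time_to_citation": p.time_to_citation,
            "time_band": categorize("time_to_citation", p.time_to_citation),
            "self_citation": bool(p.self_citation),
            "authority_value": p.authority_value,
            "authority_band": p.authority_band,
            "authors_conclusion": ca.authors_conclusion,
            "data_based_conclusion": (
                None
                if ca.data_based_conclusion == "not-applicable"
                else ca.data_based_conclusion
            ),
            "article_type": ca.article_type,
            "study_design": ca.study_design,
            "sample_size_cat": categorize("sample_size", ca.sample_size),
            "study_quality": (
                None if ca.study_quality == "not-rated" else ca.study_quality
            ),
            "specificity": float(ca.specificity),
            "language_english": bool(ca.language_english),
            "conclusive_title": bool(ca.conclusive_title),
            "funding": ca.funding,
            "n_authors_cat": categorize("n_authors", ca.n_authors),
            "n_affiliations_cat": categorize("n_affiliations", ca.n_affiliations),
            "n_references_cat": categorize("n_references", ca.n_references),
            "impact_factor_cat": categorize(
                "journal_impact_factor", ca.journal_impact_factor
            ),
            "corr_gender": ca.corr_gender,
            "corr_region": country_region(ca.corr_country),
            "corr_affiliation": ca.corr_affiliation,
            "citing_article_type": citing.attributes.article_type,
            "citing_study_design": citing.attributes.study_design,
            "cited_pub_year": effective_publication_date(cited).year,
        }
        for attr, flag in p.concordance.items():
            row[f"conc_{attr}"] = flag
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Model specification and results
# --------------------------------------------------------------------------

#: reference categories mirroring the published odds-ratio table
DEFAULT_REFERENCE = {
    "authors_conclusion": "negative",
    "data_based_conclusion": "negative",
    "article_type": "narrative",
    "study_design": "cross-sectional",
    "sample_size_cat": "low",
    "study_quality": "poor",
    "funding": "non-profit",
    "n_authors_cat": "1-2",
    "n_affiliations_cat": "1",
    "n_references_cat": "<25",
    "impact_factor_cat": "0-2",
    "corr_gender": "male",
    "corr_region": "belgium",
    "corr_affiliation": "university",
    "authority_band": "low",
}

#: named path subsets for the sensitivity analyses
SUBSETS = ("all", "empirical", "empirical-no-eco-case")


@dataclass(frozen=True)
class ModelSpec:
    """One citation model: a determinant plus estimator/adjustment choices."""

    determinant: str
    reference: str | None = None
    levels: tuple[str, ...] | None = None
    continuous: bool = False
    covariates: tuple[str, ...] = ()
    estimator: str = "random-intercept"  # "fixed" | "random-intercept"
    subset: str = "all"

    def __post_init__(self) -> None:
        if self.determinant in self.covariates:
            raise ValueError("determinant may not appear among the covariates")
        if self.estimator not in ("fixed", "random-intercept"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if self.subset not in SUBSETS:
            raise ValueError(f"unknown subset {self.subset!r}; choose from {SUBSETS}")


@dataclass(frozen=True)
class EffectEstimate:
    level: str
    coef: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float


@dataclass
class ModelResult:
    determinant: str
    estimator: str
    subset: str
    covariates: tuple[str, ...]
    converged: bool
    effects: list[EffectEstimate] = field(default_factory=list)
    n_paths: int = 0
    n_citing_clusters: int = 0
    n_dropped: int = 0
    random_intercept_sd: float | None = None
    message: str = ""

    def effect(self, level: str | None = None) -> EffectEstimate:
        if not self.converged:
            raise ValueError(f"model for {self.determinant!r} did not converge: "
                             f"{self.message}")
        if level is None:
            if len(self.effects) != 1:
                raise ValueError("level must be named for multi-level determinants")
            return self.effects[0]
        for e in self.effects:
            if e.level == level:
                return e
        raise KeyError(level)


# --------------------------------------------------------------------------
# Design-matrix assembly
# --------------------------------------------------------------------------

_NA_SENTINELS = {"not-applicable", "not-rated"}


def _apply_subset(frame: pd.DataFrame, subset: str) -> pd.DataFrame:
    if subset == "all":
        return frame
    mask = (frame["article_type"] == "empirical") & (
        frame["citing_article_type"] == "empirical"
    )
    if subset == "empirical-no-eco-case":
        bad = {"ecological", "case-study"}
        mask &= ~frame["study_design"].isin(bad)
        mask &= ~frame["citing_study_design"].isin(bad)
    return frame.loc[mask]


def _column_terms(
    frame: pd.DataFrame, name: str, reference: str | None
) -> tuple[np.ndarray, list[str]]:
    """Encode one column: continuous passthrough, bool, or dummies vs reference."""
    col = frame[name]
    if col.dtype == bool or set(col.dropna().unique()) <= {True, False}:
        return col.astype(float).to_numpy()[:, None], [f"{name}[yes]"]
    if pd.api.types.is_numeric_dtype(col):
        return col.astype(float).to_numpy()[:, None], [name]
    levels = sorted(col.dropna().unique())
    if reference is not None:
        if reference not in levels:
            raise ValueError(f"reference level {reference!r} absent from {name!r}")
        ref = reference
    else:
        ref = DEFAULT_REFERENCE.get(name, levels[0])
        if ref not in levels:
            ref = levels[0]
    others = [lv for lv in levels if lv != ref]
    if not others:  # single observed level: nothing to contrast
        return np.empty((len(col), 0)), []
    cols = [(col == lv).astype(float).to_numpy() for lv in others]
    return np.column_stack(cols), [f"{name}[{lv}]" for lv in others]


def _build_design(
    frame: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str], int, int]:
    """Return (y, X, cluster codes, effect names, n kept, n dropped)."""
    data = _apply_subset(frame, spec.subset).copy()
    n_before = len(data)
    needed = [spec.determinant, *spec.covariates]
    for name in needed:
        col = data[name]
        if not pd.api.types.is_numeric_dtype(col) and col.dtype != bool:
            data[name] = col.where(~col.isin(_NA_SENTINELS))
        if spec.levels is not None and name == spec.determinant:
            data[name] = data[name].where(data[name].isin(spec.levels))
    data = data.dropna(subset=needed)
    if data.empty:
        raise ValueError(
            f"empty path subset for determinant {spec.determinant!r} "
            f"(subset={spec.subset!r})"
        )
    y = data["realized"].to_numpy(dtype=float)
    blocks, names = [], []
    det_block, det_names = _column_terms(data, spec.determinant, spec.reference)
    blocks.append(det_block)
    names.extend(det_names)
    for cov in spec.covariates:
        b, nm = _column_terms(data, cov, None)
        blocks.append(b)
        names.extend(nm)
    X = np.column_stack([np.ones(len(data))] + blocks)
    # a covariate level that is constant in the subset carries no information
    # and would make the design singular; determinant columns are kept so
    # degeneracy of the determinant itself is reported, not silently dropped
    keep = [0] + [
        j
        for j, nm in enumerate(names, start=1)
        if nm.split("[")[0] == spec.determinant or np.ptp(X[:, j]) > 0
    ]
    names = [names[j - 1] for j in keep[1:]]
    X = X[:, keep]
    clusters = pd.Categorical(data["citing_id"]).codes.astype(np.int64)
    return y, X, clusters, names, len(data), n_before - len(data)


# --------------------------------------------------------------------------
# Random-intercept logistic likelihood (adaptive Gauss-Hermite)
# --------------------------------------------------------------------------

_SQRT2 = math.sqrt(2.0)
_MIN_LOG_SIGMA = math.log(1e-6)


def _cluster_modes(
    eta: np.ndarray, y: np.ndarray, groups: np.ndarray, n_groups: int, s2: float
) -> tuple[np.ndarray, np.ndarray]:
    """Newton iteration for the conditional mode of each cluster intercept."""
    u = np.zeros(n_groups)
    curv = np.full(n_groups, 1.0 / s2)
    for _ in range(60):
        p = expit(eta + u[groups])
        grad = np.bincount(groups, weights=y - p, minlength=n_groups) - u / s2
        curv = np.bincount(groups, weights=p * (1 - p), minlength=n_groups) + 1.0 / s2
        step = grad / curv
        np.clip(step, -4.0, 4.0, out=step)
        u += step
        if np.max(np.abs(step)) < 1e-10:
            break
    return u, 1.0 / np.sqrt(curv)


def _ri_loglik(
    theta: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    n_groups: int,
    nodes: np.ndarray,
    log_weights: np.ndarray,
    adaptive: bool,
) -> float:
    beta, log_sigma = theta[:-1], theta[-1]
    sigma = math.exp(max(log_sigma, _MIN_LOG_SIGMA))
    s2 = sigma * sigma
    eta = X @ beta
    if adaptive:
        u_hat, tau = _cluster_modes(eta, y, groups, n_groups, s2)
    else:
        u_hat, tau = np.zeros(n_groups), np.full(n_groups, sigma)
    sign = 2.0 * y - 1.0
    kernel = np.empty((len(nodes), n_groups))
    for k, (zk, lwk) in enumerate(zip(nodes, log_weights)):
        uk = u_hat + _SQRT2 * tau * zk
        cond = np.bincount(
            groups, weights=log_expit(sign * (eta + uk[groups])), minlength=n_groups
        )
        kernel[k] = cond - uk * uk / (2.0 * s2) + zk * zk + lwk
    per_cluster = (
        logsumexp(kernel, axis=0)
        + np.log(_SQRT2 * tau)
        - 0.5 * math.log(2.0 * math.pi * s2)
    )
    return float(per_cluster.sum())


@dataclass
class RandomInterceptFit:
    params: np.ndarray
    bse: np.ndarray
    sigma: float
    loglik: float
    converged: bool
    message: str


def fit_logit_random_intercept(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    n_quad: int = 15,
    adaptive: bool = True,
) -> RandomInterceptFit:
    """Maximum-likelihood logistic regression with a normal random intercept.

    The per-cluster marginal likelihood is integrated with *n_quad*-node
    Gauss-Hermite quadrature, centred and scaled at each cluster's
    conditional mode when *adaptive* (the default).  Standard errors are
    Wald, from the numerically differentiated observed information.
    """
    if n_quad < 2:
        raise ValueError("need at least 2 quadrature nodes")
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups, dtype=np.int64)
    n_groups = int(groups.max()) + 1
    nodes, weights = hermgauss(n_quad)
    log_weights = np.log(weights)

    def nll(theta: np.ndarray) -> float:
        value = _ri_loglik(theta, y, X, groups, n_groups, nodes, log_weights, adaptive)
        return -value if np.isfinite(value) else 1e12

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            start_beta = sm.Logit(y, X).fit(disp=0, maxiter=100).params
        start_beta = np.clip(np.nan_to_num(start_beta), -4, 4)
    except Exception:
        start_beta = np.zeros(X.shape[1])
    x0 = np.append(start_beta, math.log(0.5))
    bounds = [(None, None)] * X.shape[1] + [(_MIN_LOG_SIGMA, math.log(50.0))]
    res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 500, "ftol": 1e-11})
    theta = res.x
    sigma = math.exp(theta[-1])
    at_floor = theta[-1] <= _MIN_LOG_SIGMA + 1e-6 or sigma < 1e-3
    if at_floor:
        # variance component at the boundary: the model collapses to the
        # fixed-effects logistic; condition on sigma for the information
        hess = numdiff.approx_hess1(theta[:-1], lambda b: nll(np.append(b, theta[-1])))
        sigma = 0.0
    else:
        hess = numdiff.approx_hess1(theta, nll)
    try:
        cov = np.linalg.pinv(hess)
        bse = np.sqrt(np.clip(np.diag(cov), 0, None))[: X.shape[1]]
    except np.linalg.LinAlgError:
        bse = np.full(X.shape[1], np.nan)
    ok = bool(res.success) and np.all(np.isfinite(bse)) and np.all(bse < 100)
    return RandomInterceptFit(
        params=theta[: X.shape[1]],
        bse=bse,
        sigma=sigma,
        loglik=-res.fun,
        converged=ok,
        message="" if ok else f"optimizer: {res.message}",
    )


# --------------------------------------------------------------------------
# Model fitting
# --------------------------------------------------------------------------


def _fit_fixed(y, X):
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence reported explicitly
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # separation, singular design
        return None, None, f"fixed-effects fit failed: {exc}"
    params, bse = np.asarray(fit.params), np.asarray(fit.bse)
    retvals = getattr(fit, "mle_retvals", {}) or {}
    if not retvals.get("converged", True):
        return None, None, "fixed-effects optimizer did not converge"
    if not np.all(np.isfinite(bse)) or np.any(np.abs(params) > 15) or np.any(bse > 100):
        return None, None, "separation: estimates diverged"
    return params, bse, ""


def fit_citation_model(frame: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """Fit the citation model described by *spec* on the path covariate table.

    Paths with a missing/not-applicable determinant (or covariate) value are
    dropped and counted in ``n_dropped``.  Returns odds ratios per
    non-reference level with Wald 95% confidence intervals.
    """
    y, X, clusters, names, n_kept, n_dropped = _build_design(frame, spec)
    result = ModelResult(
        determinant=spec.determinant,
        estimator=spec.estimator,
        subset=spec.subset,
        covariates=spec.covariates,
        converged=False,
        n_paths=n_kept,
        n_citing_clusters=int(len(np.unique(clusters))),
        n_dropped=n_dropped,
    )
    # no contrast -> the model cannot be identified; report, don't fit
    det_cols = [j for j, nm in enumerate(names, start=1)
                if nm.split("[")[0] == spec.determinant]
    degenerate = all(np.ptp(X[:, j]) == 0 for j in det_cols) if det_cols else True
    if degenerate:
        result.message = (
            f"determinant {spec.determinant!r} has a single level in the data"
        )
        return result
    if y.min() == y.max():
        result.message = "outcome has no variation in the subset"
        return result
    if spec.estimator == "fixed":
        params, bse, msg = _fit_fixed(y, X)
        sigma = None
    else:
        fit = fit_logit_random_intercept(y, X, clusters)
        params, bse, msg = (
            (fit.params, fit.bse, "") if fit.converged else (None, None, fit.message)
        )
        if params is not None and (
            np.any(np.abs(params) > 15) or np.any(bse > 100)
        ):
            params, bse, msg = None, None, "separation: estimates diverged"
        sigma = fit.sigma if fit.converged else None
    if params is None:
        result.message = msg or "model did not converge"
        return result
    effects = []
    for j, name in enumerate(names, start=1):
        coef, se = float(params[j]), float(bse[j])
        effects.append(
            EffectEstimate(
                level=name,
                coef=coef,
                se=se,
                odds_ratio=math.exp(coef),
                ci_low=math.exp(coef - Z975 * se),
                ci_high=math.exp(coef + Z975 * se),
            )
        )
    result.effects = effects
    result.converged = True
    result.random_intercept_sd = sigma
    return result


def fit_concordance_model(
    frame: pd.DataFrame, attribute: str, adjusted: bool = False
) -> ModelResult:
    """Fixed-effects logistic regression of citation on attribute concordance.

    The determinant is the flag "cited and citing article share the same
    value of *attribute*"; the adjusted variant adds the cited article's
    type.  Paths where concordance is undefined are dropped.
    """
    if attribute not in CONCORDANCE_ATTRIBUTES:
        raise ValueError(f"no concordance defined for {attribute!r}")
    column = f"conc_{attribute}"
    if column not in frame.columns:
        raise ValueError(f"column {column!r} missing; annotate paths first")
    spec = ModelSpec(
        determinant=column,
        covariates=("article_type",) if adjusted else (),
        estimator="fixed",
    )
    return fit_citation_model(frame, spec)


def models_to_frame(results: Sequence[ModelResult]) -> pd.DataFrame:
    """Tidy one-row-per-effect table of fitted models (full precision)."""
    rows = []
    for r in results:
        base = {
            "determinant": r.determinant,
            "estimator": r.estimator,
            "subset": r.subset,
            "adjusted_for": "+".join(r.covariates),
            "converged": r.converged,
            "n_paths": r.n_paths,
            "n_citing_clusters": r.n_citing_clusters,
            "n_dropped": r.n_dropped,
            "random_intercept_sd": r.random_intercept_sd,
            "message": r.message,
        }
        if not r.effects:
            rows.append({**base, "level": "", "odds_ratio": None,
                         "ci_low": None, "ci_high": None})
        for e in r.effects:
            rows.append(
                {
                    **base,
                    "level": e.level,
                    "odds_ratio": e.odds_ratio,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                }
            )
    return pd.DataFrame(rows)
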