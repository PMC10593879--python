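"""Vertexwise general linear models for score-morphometry association.

At each vertex i, morphometry T_i is modeled by ordinary least squares as

    T_i = b0 + b1*score + b2*age_c + b3*age_c^2 + b4*(score*age_c)
        + b5*(score*age_c^2) + b6*sex + b7*PCs + b8*scanner + b9*brain_volume

where age_c is age minus a centering value (default: sample mean), so that
the score main effect b1 is interpretable as the effect at the centering
age when score-by-age interactions are present. Categorical covariates are
treatment-coded; continuous non-age covariates are standardized by default.

The module returns per-vertex beta / SE / t maps for any coefficient, keeps
the residual maps for downstream smoothness estimation, and provides
age-group subset fits and the 1-year age-centering sweep.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

logger = logging.getLogger("polycortex")

DEFAULT_AGE_GROUPS = ((3.0, 9.0), (10.0, 15.0), (16.0, 21.0))


class DesignError(ValueError):
    """Raised for invalid or rank-deficient design specifications."""


@dataclass
class DesignSpec:
    """Configuration of the design matrix.

    age_center : value subtracted from age before polynomial/interaction
        expansion; None means the sample mean of the fitted subjects.
    include_interactions : include score-by-age and score-by-age^2 terms.
    contrast : name of the coefficient whose maps are reported (default the
        score main effect).
    standardize : z-score the score, the genetic PCs and brain volume
        (age is centered, never rescaled, so centering stays in years).
    """

    age_center: float | None = None
    include_interactions: bool = True
    contrast: str = "score"
    standardize: bool = True


@dataclass
class GLMResult:
    """Per-vertex OLS output for one fitted design.

    beta/se/tstat are the maps of the requested contrast coefficient;
    ``coef`` holds all coefficients (p, V); ``resid`` the per-subject
    residual maps retained for smoothness estimation.
    """

    beta: np.ndarray
    se: np.ndarray
    tstat: np.ndarray
    df: int
    contrast: str
    names: list
    coef: np.ndarray
    coef_se: np.ndarray
    resid: np.ndarray
    n: int
    age_center: float

    def coefficient(self, name: str) -> np.ndarray:
        return self.coef[self.names.index(name)]

    def coefficient_t(self, name: str) -> np.ndarray:
        j = self.names.index(name)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = self.coef[j] / self.coef_se[j]
        t[~np.isfinite(t)] = np.nan
        return t


def _dummies(series: pd.Series, prefix: str):
    """Treatment coding with the first (sorted) level as reference."""
    levels = sorted(pd.unique(series.astype(str)))
    cols, names = [], []
    for lev in levels[1:]:
        cols.append((series.astype(str) == lev).to_numpy(float))
        names.append(f"{prefix}_{lev}")
    return cols, names


def _zscore(x: np.ndarray) -> np.ndarray:
    s = x.std(ddof=0)
    if s == 0:
        raise DesignError("cannot standardize a constant covariate")
    return (x - x.mean()) / s


def build_design(subjects: pd.DataFrame, spec: DesignSpec | None = None):
    """Build the design matrix.

    Returns (X, names, age_center). Deterministic column order: intercept,
    score, age, age2, score_x_age, score_x_age2 (if enabled), sex dummies,
    pc1..pcN, scanner dummies, brain_volume. Single-level factors contribute
    zero columns; an actually rank-deficient design raises DesignError.
    """
    spec = spec or DesignSpec()
    required = ["score", "age", "sex", "scanner", "brain_volume"]
    for col in required:
        if col not in subjects.columns:
            raise DesignError(f"subject table lacks column '{col}'")
        if subjects[col].isna().any():
            raise DesignError(f"missing values in modeled column '{col}'")

    n = len(subjects)
    age = subjects["age"].to_numpy(float)
    center = float(np.mean(age)) if spec.age_center is None else float(spec.age_center)
    age_c = age - center
    score = subjects["score"].to_numpy(float)
    if spec.standardize:
        score = _zscore(score)

    cols = [np.ones(n), score, age_c, age_c ** 2]
    names = ["intercept", "score", "age", "age2"]
    if spec.include_interactions:
        cols += [score * age_c, score * age_c ** 2]
        names += ["score_x_age", "score_x_age2"]

    c, nm = _dummies(subjects["sex"], "sex")
    cols += c
    names += nm

    pc_cols = sorted((col for col in subjects.columns
                      if col.startswith("pc") and col[2:].isdigit()),
                     key=lambda s: int(s[2:]))
    for col in pc_cols:
        x = subjects[col].to_numpy(float)
        cols.append(_zscore(x) if spec.standardize else x)
        names.append(col)

    c, nm = _dummies(subjects["scanner"], "scanner")
    cols += c
    names += nm

    bv = subjects["brain_volume"].to_numpy(float)
    cols.append(_zscore(bv) if spec.standardize else bv)
    names.append("brain_volume")

    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("rank-deficient design matrix")
    return X, names, center


def fit_vertexwise(thickness: np.ndarray, X: np.ndarray, names: list,
                   contrast: str = "score",
                   age_center: float = np.nan) -> GLMResult:
    """OLS at every vertex with complete data (QR-based, vectorized).

    ``thickness`` is (n_subjects, V); vertices that are NaN for all subjects
    (medial wall) yield NaN outputs. Perfect-fit vertices (zero residual
    variance) return NaN t with a logged warning, keeping downstream random
    field theory on finite fields.
    """
    Y = np.asarray(thickness, float)
    n, p = X.shape
    if Y.ndim != 2 or Y.shape[0] != n:
        raise DesignError("thickness stack is not aligned to the design")
    if n <= p:
        raise DesignError(f"n={n} subjects <= {p} design columns")
    if contrast not in names:
        raise DesignError(f"unknown contrast '{contrast}'")

    finite = np.isfinite(Y)
    all_f = finite.all(axis=0)
    none_f = ~finite.any(axis=0)
    if not (all_f | none_f).all():
        raise DesignError("vertices with partially missing data are not "
                          "supported; maps must be NaN for all subjects or none")

    V = Y.shape[1]
    Q, R = np.linalg.qr(X)
    rank = int(np.sum(np.abs(np.diag(R)) > 1e-10 * np.abs(R[0, 0])))
    if rank < p:
        raise DesignError("rank-deficient design matrix")
    df = n - rank

    coef = np.full((p, V), np.nan)
    coef_se = np.full((p, V), np.nan)
    resid = np.full((n, V), np.nan)

    Yv = Y[:, all_f]
    B = scipy.linalg.solve_triangular(R, Q.T @ Yv)
    E = Yv - X @ B
    rss = np.einsum("ij,ij->j", E, E)
    # numerically perfect fits: zero out residual noise below float precision
    yss = np.einsum("ij,ij->j", Yv, Yv)
    rss[rss <= 1e-24 * np.maximum(yss, 1e-300)] = 0.0
    sigma2 = rss / df
    Rinv = scipy.linalg.solve_triangular(R, np.eye(p))
    covjj = np.einsum("ij,ij->i", Rinv, Rinv)  # diag of (X'X)^-1
    se = np.sqrt(np.outer(covjj, sigma2))

    coef[:, all_f] = B
    coef_se[:, all_f] = se
    resid[:, all_f] = E

    j = names.index(contrast)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_all = coef / coef_se
    n_perfect = int(np.sum((coef_se[j] == 0) & all_f))
    if n_perfect:
        logger.warning("%d perfect-fit vertices: t set to NaN", n_perfect)
    t_all[~np.isfinite(t_all)] = np.nan

    return GLMResult(beta=coef[j].copy(), se=coef_se[j].copy(),
                     tstat=t_all[j].copy(), df=df, contrast=contrast,
                     names=list(names), coef=coef, coef_se=coef_se,
                     resid=resid, n=n, age_center=float(age_center))


def fit_model(thickness, subjects: pd.DataFrame,
              spec: DesignSpec | None = None) -> GLMResult:
    """Convenience wrapper: build the design and fit in one call."""
    spec = spec or DesignSpec()
    X, names, center = build_design(subjects, spec)
    return fit_vertexwise(thickness, X, names, contrast=spec.contrast,
                          age_center=center)


def fit_age_groups(thickness, subjects: pd.DataFrame,
                   spec: DesignSpec | None = None,
                   bounds=DEFAULT_AGE_GROUPS) -> dict:
    """Fit the model within age-group subsets, age centered to group mean.

    Bounds are in completed years: a subject belongs to (lo, hi) when
    floor(age) is within [lo, hi], so the default 3-9 / 10-15 / 16-21
    bounds partition a 3-21-year cohort. Returns {(lo, hi): GLMResult};
    groups must be non-empty and larger than the design width.
    """
    spec = spec or DesignSpec()
    Y = np.asarray(thickness, float)
    age = np.floor(subjects["age"].to_numpy(float))
    out = {}
    for lo, hi in bounds:
        sel = (age >= lo) & (age <= hi)
        if sel.sum() == 0:
            raise DesignError(f"age group {lo}-{hi} is empty")
        sub = subjects.loc[sel].reset_index(drop=True)
        gspec = DesignSpec(age_center=None,
                           include_interactions=spec.include_interactions,
                           contrast=spec.contrast,
                           standardize=spec.standardize)
        out[(lo, hi)] = fit_model(Y[sel], sub, gspec)
    return out


def age_center_sweep(thickness, subjects: pd.DataFrame,
                     spec: DesignSpec | None = None,
                     centers=None) -> dict:
    """One full-cohort fit per age-centering value (default 3..21, 1-year).

    With interactions present the score main-effect map varies with the
    center c as beta1 + beta4*(c - c0) + beta5*(c - c0)^2 of any single fit
    centered at c0 (an exact reparameterization); without interactions all
    sweep maps are identical.
    """
    spec = spec or DesignSpec()
    if centers is None:
        centers = np.arange(3.0, 22.0, 1.0)
    out = {}
    for c in centers:
        cspec = DesignSpec(age_center=float(c),
                           include_interactions=spec.include_interactions,
                           contrast=spec.contrast,
                           standardize=spec.standardize)
        out[float(c)] = fit_model(thickness, subjects, cspec)
    return out


def age_polynomial_aic(thickness, subjects: pd.DataFrame,
                       spec: DesignSpec | None = None) -> pd.DataFrame:
    """Mean AIC across vertices for age polynomial degree 0, 1, 2.

    Reported for model comparison only, never enforced. Degree d keeps age
    terms (and score-by-age interactions) up to power d.
    """
    spec = spec or DesignSpec()
    Y = np.asarray(thickness, float)
    rows = []
    for degree in (0, 1, 2):
        X, names, center = build_design(subjects, DesignSpec(
            age_center=spec.age_center,
            include_interactions=spec.include_interactions,
            contrast=spec.contrast, standardize=spec.standardize))
        keep = [k for k, nm in enumerate(names)
                if not ((nm in ("age", "score_x_age") and degree < 1)
                        or (nm in ("age2", "score_x_age2") and degree < 2))]
        Xd = X[:, keep]
        n, p = Xd.shape
        valid = np.isfinite(Y).all(axis=0)
        B, *_ = np.linalg.lstsq(Xd, Y[:, valid], rcond=None)
        E = Y[:, valid] - Xd @ B
        rss = np.einsum("ij,ij->j", E, E)
        aic = n * np.log(rss / n) + 2.0 * (p + 1)
        rows.append({"degree": degree, "n_columns": p,
                     "mean_aic": float(aic.mean())})
    return pd.DataFrame(rows)
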