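"""Cross-map similarity statistics and comparisons of correlations.

Covers three analyses that share machinery: (1) correlating a parcellated
effect map with case-control disorder maps, with spin-permutation p-values
and Benjamini-Hochberg FDR across disorders; (2) comparing two dependent
overlapping correlations (Zou's confidence interval on r12 - r13 and
Steiger's z); (3) comparing two independent correlations via Fisher's
r-to-z, used for age-group versus whole-cohort map similarities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .nulls import spin_test_correlation
from .surfaces import map_values

logger = logging.getLogger("polycortex")

#: the six disorders of the meta-analytic comparison
DISORDERS = ["schizophrenia", "bipolar", "mdd", "adhd", "ocd", "asd"]


class SimilarityError(ValueError):
    pass


@dataclass
class CorrComparison:
    """Result of comparing two correlation coefficients."""

    r1: float
    r2: float
    n: int
    method: str
    estimate: float | tuple   # z statistic, or (lo, hi) CI bounds
    p: float | None = None
    p_one_tailed: float | None = None
    includes_zero: bool | None = None


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def fdr_bh(pvalues, q: float = 0.05):
    """Benjamini-Hochberg step-up adjusted p-values and flags at level q."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        raise SimilarityError("empty p-value input")
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise SimilarityError("p-values must lie in (0, 1]")
    reject, adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return adj, reject


# ---------------------------------------------------------------------------
# Comparing correlations
# ---------------------------------------------------------------------------

def _fisher_z(r):
    return np.arctanh(r)


def compare_correlations_independent(r1: float, n1: int, r2: float,
                                     n2: int) -> CorrComparison:
    """Fisher r-to-z test for correlations from independent samples.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)); antisymmetric in
    the two samples, exactly zero at r1 = r2.
    """
    for r, n in ((r1, n1), (r2, n2)):
        if not abs(r) < 1:
            raise SimilarityError("correlations must satisfy |r| < 1")
        if n < 4:
            raise SimilarityError("need n >= 4 per sample")
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = float((_fisher_z(r1) - _fisher_z(r2)) / se)
    return CorrComparison(r1=float(r1), r2=float(r2), n=int(n1),
                          method="fisher_z_independent", estimate=z,
                          p=float(2.0 * norm.sf(abs(z))),
                          p_one_tailed=float(norm.sf(z)))


def _check_triple(r12, r13, r23):
    C = np.array([[1.0, r12, r13], [r12, 1.0, r23], [r13, r23, 1.0]])
    if np.linalg.eigvalsh(C).min() < -1e-10:
        raise SimilarityError("inconsistent correlation triple "
                              "(not positive semidefinite)")


def zou_ci_dependent(r12: float, r13: float, r23: float, n: int,
                     conf: float = 0.95) -> tuple:
    """Zou's confidence interval for r12 - r13 (overlapping, dependent).

    Individual Fisher-z confidence limits for each correlation are combined
    with the sampling correlation c between the two correlation estimates
    (they share variable 1, observed on the same n units).
    """
    _check_triple(r12, r13, r23)
    if n < 4:
        raise SimilarityError("need n >= 4")
    zc = norm.ppf(0.5 + conf / 2.0)
    se = 1.0 / np.sqrt(n - 3)
    l1, u1 = np.tanh(_fisher_z(r12) + np.array([-1, 1]) * zc * se)
    l2, u2 = np.tanh(_fisher_z(r13) + np.array([-1, 1]) * zc * se)
    num = (r23 * (1 - r12 ** 2 - r13 ** 2)
           - 0.5 * r12 * r13 * (1 - r12 ** 2 - r13 ** 2 - r23 ** 2))
    c = num / ((1 - r12 ** 2) * (1 - r13 ** 2))
    d = r12 - r13
    lo = d - np.sqrt((r12 - l1) ** 2 + (u2 - r13) ** 2
                     - 2 * c * (r12 - l1) * (u2 - r13))
    hi = d + np.sqrt((u1 - r12) ** 2 + (r13 - l2) ** 2
                     - 2 * c * (u1 - r12) * (r13 - l2))
    return float(lo), float(hi)


def steiger_z_dependent(r12: float, r13: float, r23: float, n: int) -> tuple:
    """Steiger's z for two dependent overlapping correlations.

    Uses the pooled correlation (r12 + r13)/2 in the covariance term.
    Returns (z, two-tailed p).
    """
    _check_triple(r12, r13, r23)
    rbar = 0.5 * (r12 + r13)
    psi = (r23 * (1 - 2 * rbar ** 2)
           - 0.5 * rbar ** 2 * (1 - 2 * rbar ** 2 - r23 ** 2))
    cbar = psi / (1 - rbar ** 2) ** 2
    z = ((_fisher_z(r12) - _fisher_z(r13))
         * np.sqrt((n - 3) / (2.0 - 2.0 * cbar)))
    return float(z), float(2.0 * norm.sf(abs(z)))


def compare_correlations_dependent(r12: float, r13: float, r23: float,
                                   n: int) -> CorrComparison:
    """Zou 95% CI for r12 - r13 plus Steiger z (overlapping correlations)."""
    lo, hi = zou_ci_dependent(r12, r13, r23, n)
    z, p = steiger_z_dependent(r12, r13, r23, n)
    return CorrComparison(r1=float(r12), r2=float(r13), n=int(n),
                          method="zou_ci", estimate=(lo, hi), p=p,
                          includes_zero=bool(lo <= 0.0 <= hi))


# ---------------------------------------------------------------------------
# Disorder-map similarity
# ---------------------------------------------------------------------------

def disorder_similarity(effect, disorder_maps: dict, centroids,
                        n_perm: int = 10_000, seed: int | None = None,
                        spin_alpha: float = 0.025,
                        fdr_q: float = 0.05) -> pd.DataFrame:
    """Correlate a parcellated effect map with each disorder's d map.

    Pearson r on pairwise-complete parcels, two-tailed spin p per disorder,
    Benjamini-Hochberg FDR across disorders; significance flags at
    p_spin < ``spin_alpha`` (two-tailed convention, default .025) and
    p_FDR < ``fdr_q``.
    """
    eff = map_values(effect)
    rng = np.random.default_rng(seed)
    rows = []
    for name, dmap in disorder_maps.items():
        res = spin_test_correlation(eff, map_values(dmap),
                                    centroids=centroids, n_perm=n_perm,
                                    seed=int(rng.integers(2 ** 31)))
        n_complete = int(np.sum(np.isfinite(eff)
                                & np.isfinite(map_values(dmap))))
        rows.append({"disorder": name, "r": res.observed,
                     "p_spin": res.p, "n_parcels": n_complete})
    table = pd.DataFrame(rows)
    adj, _ = fdr_bh(table["p_spin"].to_numpy(), q=fdr_q)
    table["p_fdr"] = adj
    table["sig_spin"] = table["p_spin"] < spin_alpha
    table["sig_fdr"] = table["p_fdr"] < fdr_q
    return table


# ---------------------------------------------------------------------------
# Age-group trajectory
# ---------------------------------------------------------------------------

def age_group_similarity(group_maps: dict, whole_map, disorder_map,
                         method: str = "fisher_z_independent"):
    """Similarity trajectory of age-group maps (parcel level).

    For each age group, the Pearson correlation of its parcellated score
    t map with (a) the whole-cohort map and (b) a disorder reference map is
    computed on pairwise-complete parcels; all group pairs are then compared
    with Fisher's independent z by default (the dependent Steiger z, using
    the group-group map correlation, is available via
    method="steiger_dependent").

    Returns (per_group table, pairwise comparison table).
    """
    whole = map_values(whole_map)
    dis = map_values(disorder_map)
    names = list(group_maps)
    corr, nunits = {}, {}
    rows = []
    for g in names:
        gm = map_values(group_maps[g])
        m = np.isfinite(gm) & np.isfinite(whole)
        r_whole = _pearson(gm[m], whole[m])
        md = np.isfinite(gm) & np.isfinite(dis)
        r_dis = _pearson(gm[md], dis[md])
        corr[g], nunits[g] = (r_whole, r_dis), int(m.sum())
        rows.append({"group": str(g), "r_vs_whole": r_whole,
                     "r_vs_disorder": r_dis, "n_parcels": int(m.sum())})
    per_group = pd.DataFrame(rows)

    comp_rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            for which in ("r_vs_whole", "r_vs_disorder"):
                r1 = per_group.loc[i, which]
                r2 = per_group.loc[j, which]
                if method == "fisher_z_independent":
                    cc = compare_correlations_independent(
                        r1, nunits[a], r2, nunits[b])
                    est, p = cc.estimate, cc.p
                elif method == "steiger_dependent":
                    ga, gb = map_values(group_maps[a]), map_values(group_maps[b])
                    m = np.isfinite(ga) & np.isfinite(gb)
                    r12 = _pearson(ga[m], gb[m])
                    est, p = steiger_z_dependent(r1, r2, r12,
                                                 int(m.sum()))
                else:
                    raise SimilarityError(f"unknown method '{method}'")
                comp_rows.append({"group_a": str(a), "group_b": str(b),
                                  "statistic": which, "r_a": r1, "r_b": r2,
                                  "z": float(est), "p": float(p),
                                  "method": method})
    return per_group, pd.DataFrame(comp_rows)


def _pearson(a, b):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 3 or a.std() == 0 or b.std() == 0:
        raise SimilarityError("degenerate map pair for correlation")
    return float(np.corrcoef(a, b)[0, 1])
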