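"""Phenotype correction and circRNA-abundance association screens.

Motility traits (motile %, VCL, VSL, VAP) are corrected for the fixed
effects farm, age class and season-year by ordinary least squares on
dummy-coded factors; residuals are then screened against circRNA CPM by
Pearson correlation (two-sided t-transform p, n-2 df, no multiple-testing
correction by default).  Age-group differences in circRNA number and
abundance are tested with the two-sided Wilcoxon rank-sum test (exact when
both groups are small and tie-free, tie-corrected normal approximation
otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

TRAITS = ("motile_pct", "vcl", "vsl", "vap")
FACTORS = ("farm", "age_class", "season_year")


def _design_matrix(pheno: pd.DataFrame, factors: tuple[str, ...]) -> pd.DataFrame:
    X = pd.DataFrame({"intercept": np.ones(len(pheno))}, index=pheno.index)
    for f in factors:
        dummies = pd.get_dummies(pheno[f].astype("category"), prefix=f, drop_first=True)
        X = pd.concat([X, dummies.astype(float)], axis=1)
    return X


def correct_phenotypes(
    pheno: pd.DataFrame,
    traits: tuple[str, ...] = TRAITS,
    factors: tuple[str, ...] = FACTORS,
) -> pd.DataFrame:
    """OLS residuals of each trait on dummy-coded fixed effects.

    First level of each factor is the reference.  Raises on a rank-deficient
    design (aliased factor levels).
    """
    for col in traits + factors:
        if col not in pheno.columns:
            raise ValueError(f"phenotype table lacks column {col!r}")
    X = _design_matrix(pheno, factors)
    Xv = X.values
    rank = np.linalg.matrix_rank(Xv)
    if rank < Xv.shape[1]:
        # name columns that add no rank
        aliased = []
        r = 0
        for j in range(Xv.shape[1]):
            rj = np.linalg.matrix_rank(Xv[:, : j + 1])
            if rj == r:
                aliased.append(X.columns[j])
            r = rj
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    if Xv.shape[0] <= Xv.shape[1]:
        raise ValueError("need more observations than design columns")
    resid = {}
    for tr in traits:
        y = pheno[tr].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(Xv, y, rcond=None)
        resid[tr] = y - Xv @ beta
    out = pd.DataFrame(resid, index=pheno.index)
    if "sample_id" in pheno.columns:
        out.index = pheno["sample_id"]
    return out


@dataclass
class AssociationResult:
    circ_id: str
    trait: str
    pearson_r: float
    p_value: float
    significant: bool


def correlate_abundance(
    cpm: pd.DataFrame,
    corrected_traits: pd.DataFrame,
    alpha: float = 0.05,
    log2: bool = False,
) -> pd.DataFrame:
    """Pearson screen of every circRNA against every corrected trait.

    ``cpm`` is samples x circRNAs, ``corrected_traits`` samples x traits on
    the same index.  Constant circRNA vectors get r = NaN and are never
    flagged significant.  Returns a tidy frame (circ_id, trait, pearson_r,
    p_value, significant).
    """
    common = cpm.index.intersection(corrected_traits.index)
    if len(common) < 4:
        raise ValueError("need >=4 shared samples")
    X = cpm.loc[common].to_numpy(dtype=float)
    if log2:
        X = np.log2(X + 1.0)
    Y = corrected_traits.loc[common].to_numpy(dtype=float)
    n = len(common)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    xs = np.sqrt((Xc**2).sum(axis=0))
    ys = np.sqrt((Yc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        R = (Xc.T @ Yc) / np.outer(xs, ys)  # circ x trait
    R = np.clip(R, -1.0, 1.0)
    df = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = R * np.sqrt(df / (1.0 - R**2))
    P = 2.0 * stats.t.sf(np.abs(t), df)
    P = np.where(np.abs(R) >= 1.0, 0.0, P)
    rows = []
    for i, cid in enumerate(cpm.columns):
        defined = xs[i] > 0
        for j, tr in enumerate(corrected_traits.columns):
            r = float(R[i, j]) if defined else float("nan")
            p = float(P[i, j]) if defined else float("nan")
            rows.append(
                {
                    "circ_id": cid,
                    "trait": tr,
                    "pearson_r": r,
                    "p_value": p,
                    "significant": bool(defined and p < alpha),
                }
            )
    return pd.DataFrame(rows)


def bh_fdr(p_values: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional, off by default upstream)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    adj[order] = np.minimum.accumulate((p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
    return np.clip(adj, 0, 1)


def rank_sum_test(x, y, exact_max_n: int = 20) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null distribution when the pooled size is <= ``exact_max_n`` and
    there are no ties; tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (no_ties and pooled.size <= exact_max_n) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def age_group_test(
    per_sample_circ_counts: pd.Series,
    per_sample_mean_abundance: pd.Series,
    ages: pd.Series,
    cut_months: float = 24.0,
    extreme_k: int | None = None,
) -> dict:
    """Wilcoxon comparison of circRNA number and abundance between age groups.

    Samples split at ``cut_months`` (young < cut <= mature); with
    ``extreme_k`` only the k youngest vs k oldest samples are compared.
    Returns group sizes and the two p-values.
    """
    idx = per_sample_circ_counts.index
    ages = ages.loc[idx]
    if extreme_k is not None:
        order = ages.sort_values().index
        young_idx, old_idx = order[:extreme_k], order[-extreme_k:]
    else:
        young_idx = ages.index[ages < cut_months]
        old_idx = ages.index[ages >= cut_months]
    if len(young_idx) == 0 or len(old_idx) == 0:
        raise ValueError(f"empty age group at cut {cut_months} months")
    res = {
        "n_young": int(len(young_idx)),
        "n_mature": int(len(old_idx)),
        "p_circ_count": rank_sum_test(
            per_sample_circ_counts.loc[young_idx], per_sample_circ_counts.loc[old_idx]
        ),
        "p_abundance": rank_sum_test(
            per_sample_mean_abundance.loc[young_idx], per_sample_mean_abundance.loc[old_idx]
        ),
    }
    return res


def per_sample_summaries(catalog_cpm: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Per-sample number of detected circRNAs (CPM > 0) and mean CPM.

    ``catalog_cpm`` is circRNAs x samples.
    """
    counts = (catalog_cpm > 0).sum(axis=0)
    mean_ab = catalog_cpm.mean(axis=0)
    return counts, mean_ab
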