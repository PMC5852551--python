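"""Equivalent-normal model of the lPAI distribution and super-abundance calls.

The bulk of detected protein abundances is approximately log-normal; its
normal equivalent is fitted robustly so the heavy upper tail cannot distort
the fit: mu_e is the median lPAI and sigma_e is 0.74 times the interquartile
distance (the IQR of a normal distribution spans 1.35 standard deviations,
and 0.74 = 1/1.35).  Each protein then gets z = (x - mu_e)/sigma_e and a
Bonferroni-corrected e-value: the upper-tail standard-normal p-value of z
multiplied by the number of distinct proteins P.  Proteins with z > 0 and
e-value < 1 are super-abundant — more abundant than a log-normal bulk of P
proteins would produce by chance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .normalize import NormalizedMatrix

__all__ = [
    "IQR_TO_SD",
    "NORMAL_IQR_SD_UNITS",
    "EquivalentNormalFit",
    "fit_equivalent_normal",
    "e_value",
    "abundance_report",
    "category_abundance_comparison",
]

# interquartile distance of the standard normal, in SD units (~1.35)
NORMAL_IQR_SD_UNITS = 2.0 * stats.norm.ppf(0.75)
# the reciprocal, rounded to the two decimals conventionally used (0.74)
IQR_TO_SD = 0.74


@dataclass(frozen=True)
class EquivalentNormalFit:
    mu_e: float
    sigma_e: float
    n_proteins: int  # Bonferroni multiplier P

    def __post_init__(self) -> None:
        if self.sigma_e <= 0:
            raise ValueError("sigma_e must be positive")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be positive")


def fit_equivalent_normal(lpai_values, iqr_to_sd: float = IQR_TO_SD) -> tuple:
    """(mu_e, sigma_e): median and iqr_to_sd * (Q3 - Q1) of detected lPAI.

    Quartiles use linear interpolation between order statistics.  Fewer than
    4 values (quartiles undefined) or a zero IQR (degenerate sample) are
    rejected.
    """
    x = np.asarray(lpai_values, dtype=float)
    if x.size < 4:
        raise ValueError(f"need >= 4 values to fit quartiles, got {x.size}")
    q1, mu, q3 = np.percentile(x, [25, 50, 75], method="linear")
    iqr = q3 - q1
    if iqr <= 0:
        raise ValueError("zero interquartile distance: degenerate sample")
    return float(mu), float(iqr_to_sd * iqr)


def e_value(x: float, fit: EquivalentNormalFit) -> tuple:
    """(z, e_value, super_abundant) for one lPAI value.

    e_value = upper-tail standard-normal p(z) * P; super-abundant requires
    z > 0 and e_value < 1.
    """
    z = (x - fit.mu_e) / fit.sigma_e
    e = float(stats.norm.sf(z) * fit.n_proteins)
    return float(z), e, bool(z > 0 and e < 1)


def abundance_report(
    m: NormalizedMatrix, condition: str, top_k: int | None = None
) -> pd.DataFrame:
    """Detected proteins of one condition ranked by descending nemPAI, with
    z-score, Bonferroni e-value and the super-abundant flag."""
    if condition not in m.nempai.columns:
        raise KeyError(f"unknown condition {condition!r}")
    det = m.detected[condition]
    lpai = m.lpai.loc[det, condition]
    mu, sigma = fit_equivalent_normal(lpai.values)
    fit = EquivalentNormalFit(mu, sigma, m.scale_count)
    z = (lpai - mu) / sigma
    e = stats.norm.sf(z) * fit.n_proteins
    out = pd.DataFrame(
        {
            "nempai": m.nempai.loc[det, condition],
            "lpai": lpai,
            "z": z,
            "e_value": e,
            "super_abundant": (z > 0) & (e < 1),
        }
    ).sort_values("nempai", ascending=False)
    out.index.name = "locus_tag"
    if top_k is not None:
        out = out.head(top_k)
    return out


def category_abundance_comparison(
    m: NormalizedMatrix, records, condition: str, min_members: int = 3
) -> pd.DataFrame:
    """Per-category abundance summary in one condition.

    Each functional category with >= min_members detected members is
    compared against all other detected proteins by a two-sided
    Wilcoxon rank-sum test on lPAI; p-values are Bonferroni-corrected
    across the categories tested.  Identical values everywhere give p = 1
    by convention.
    """
    if condition not in m.lpai.columns:
        raise KeyError(f"unknown condition {condition!r}")
    det = m.detected[condition]
    lpai = m.lpai.loc[det, condition]
    cats = pd.Series(
        {r.locus_tag: r.category for r in records if r.category}, dtype=object
    )
    cats = cats[cats.index.isin(lpai.index)]
    counts = cats.value_counts()
    tested = [c for c in counts.index if counts[c] >= min_members]
    if len(tested) < 2:
        raise ValueError("need >= 2 categories with enough members")
    rows = []
    for cat in sorted(tested):
        members = cats.index[cats == cat]
        inside = lpai.loc[members]
        outside = lpai.drop(members)
        if inside.nunique() == 1 and outside.nunique() == 1 and inside.iloc[0] == outside.iloc[0]:
            p = 1.0
        else:
            p = float(stats.ranksums(inside, outside).pvalue)
        rows.append((cat, len(inside), float(inside.median()), p))
    out = pd.DataFrame(rows, columns=["category", "n", "median_lpai", "p_value"])
    out["p_corrected"] = np.minimum(out["p_value"] * len(tested), 1.0)
    return out.set_index("category")
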