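"""Correlation structure of paralogous-family abundance profiles.

Proteins whose abundance varies significantly across conditions are grouped
into paralogous families by shared orthologous-group ID; within each family
every unordered pair of coarse-grained profiles gets a Pearson correlation.
The observed tail fractions (|r| beyond a cutoff, default 0.8) are compared
with a null distribution built from randomly sampled pairs of singletons —
variable proteins without a family.  An excess of strongly correlated pairs
indicates co-regulated paralogs; an excess of anti-correlated pairs,
counter-regulated ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .io_tables import PipelineConfig
from .normalize import NormalizedMatrix

__all__ = [
    "ParalogFamily",
    "PairCorrelation",
    "CorrelationNull",
    "TailFractions",
    "select_variable_proteins",
    "group_families",
    "pair_correlation",
    "family_correlations",
    "null_fractions",
    "excess_report",
]


@dataclass(frozen=True)
class ParalogFamily:
    arcog_id: str
    member_loci: tuple

    def __post_init__(self) -> None:
        if len(self.member_loci) < 2:
            raise ValueError(f"family {self.arcog_id}: needs >= 2 members")


@dataclass(frozen=True)
class PairCorrelation:
    locus_a: str
    locus_b: str
    r: float  # NaN when invalid
    valid: bool  # False when either profile has zero variance


@dataclass(frozen=True)
class TailFractions:
    """Fractions of valid pairs with r > cutoff / r < -cutoff."""

    frac_pos: float
    frac_neg: float
    n_valid: int
    n_invalid: int
    cutoff: float


@dataclass(frozen=True)
class CorrelationNull:
    n_pairs: int
    seed: int
    fractions: TailFractions


def select_variable_proteins(m: NormalizedMatrix, tau: float) -> pd.Index:
    """Proteins whose lPAI range (max - min over conditions, pseudo-values
    included) reaches tau; boundary inclusive."""
    span = m.lpai.max(axis=1) - m.lpai.min(axis=1)
    return m.lpai.index[span >= tau]


def group_families(subset, records) -> tuple:
    """(families, singletons) within a protein subset.

    Families are orthologous groups with >= 2 subset members; every other
    subset protein — including those without a group assignment — is a
    singleton.
    """
    subset = list(subset)
    arcog = {r.locus_tag: r.arcog_id for r in records}
    groups = {}
    singletons = []
    for locus in subset:
        gid = arcog.get(locus)
        if gid:
            groups.setdefault(gid, []).append(locus)
        else:
            singletons.append(locus)
    families = []
    for gid in sorted(g for g, members in groups.items() if len(groups[g]) >= 2):
        families.append(ParalogFamily(gid, tuple(groups[gid])))
    for gid, members in groups.items():
        if len(members) < 2:
            singletons.extend(members)
    # keep the subset's original ordering for reproducible downstream sampling
    order = {locus: i for i, locus in enumerate(subset)}
    singletons.sort(key=order.__getitem__)
    return families, singletons


def pair_correlation(locus_a: str, locus_b: str, coarse: pd.DataFrame) -> PairCorrelation:
    """Pearson r of two coarse-grained level vectors.

    A constant profile leaves Pearson undefined; the pair is flagged invalid
    (never silently assigned r = 0)."""
    a = coarse.loc[locus_a].values.astype(float)
    b = coarse.loc[locus_b].values.astype(float)
    if a.std() == 0 or b.std() == 0:
        return PairCorrelation(locus_a, locus_b, float("nan"), False)
    r = float(np.corrcoef(a, b)[0, 1])
    return PairCorrelation(locus_a, locus_b, r, True)


def _tail_fractions(pairs, cutoff: float) -> TailFractions:
    valid = [p for p in pairs if p.valid]
    if not valid:
        raise ValueError("no valid (non-constant) profile pairs")
    rs = np.array([p.r for p in valid])
    return TailFractions(
        frac_pos=float(np.mean(rs > cutoff)),
        frac_neg=float(np.mean(rs < -cutoff)),
        n_valid=len(valid),
        n_invalid=len(pairs) - len(valid),
        cutoff=cutoff,
    )


def family_correlations(families, coarse: pd.DataFrame, cutoff: float = 0.8) -> tuple:
    """All within-family unordered pairs and their tail fractions."""
    pairs = []
    for fam in families:
        members = fam.member_loci
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                pairs.append(pair_correlation(members[i], members[j], coarse))
    return pairs, _tail_fractions(pairs, cutoff)


def null_fractions(singletons, coarse: pd.DataFrame, cfg: PipelineConfig) -> CorrelationNull:
    """Tail fractions over ``cfg.null_pairs`` random pairs of distinct
    singletons (sampled with replacement across draws; seeded)."""
    singletons = list(singletons)
    usable = [s for s in singletons if coarse.loc[s].values.std() > 0]
    if len(usable) < 2:
        raise ValueError("need >= 2 singletons with non-constant profiles")
    rng = np.random.default_rng(cfg.rng_seed)
    levels = coarse.loc[usable].values.astype(float)
    n = len(usable)
    idx_a = rng.integers(0, n, size=cfg.null_pairs)
    idx_b = rng.integers(0, n - 1, size=cfg.null_pairs)
    idx_b = np.where(idx_b >= idx_a, idx_b + 1, idx_b)  # distinct partner
    a = levels[idx_a]
    b = levels[idx_b]
    a_c = a - a.mean(axis=1, keepdims=True)
    b_c = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt((a_c**2).sum(axis=1) * (b_c**2).sum(axis=1))
    rs = (a_c * b_c).sum(axis=1) / denom
    fr = TailFractions(
        frac_pos=float(np.mean(rs > cfg.correlation_cutoff)),
        frac_neg=float(np.mean(rs < -cfg.correlation_cutoff)),
        n_valid=int(len(rs)),
        n_invalid=0,
        cutoff=cfg.correlation_cutoff,
    )
    return CorrelationNull(n_pairs=cfg.null_pairs, seed=cfg.rng_seed, fractions=fr)


def excess_report(observed: TailFractions, null: CorrelationNull) -> pd.DataFrame:
    """Observed/null tail ratios with 95% binomial (Wilson) intervals.

    The ratio interval is the conservative quotient of the two fraction
    intervals (observed_low/null_high, observed_high/null_low); a null
    fraction of 0 gives an infinite ratio with the zero-count interval rule.
    """
    if observed.cutoff != null.fractions.cutoff:
        raise ValueError("observed and null computed at different cutoffs")
    rows = []
    for tail in ("pos", "neg"):
        f_obs = getattr(observed, f"frac_{tail}")
        f_null = getattr(null.fractions, f"frac_{tail}")
        lo_o, hi_o = proportion_confint(
            round(f_obs * observed.n_valid), observed.n_valid, alpha=0.05, method="wilson"
        )
        null_count = round(f_null * null.fractions.n_valid)
        lo_n, hi_n = proportion_confint(
            null_count, null.fractions.n_valid, alpha=0.05, method="wilson"
        )
        ratio = f_obs / f_null if f_null > 0 else float("inf")
        ratio_lo = lo_o / hi_n if hi_n > 0 else float("inf")
        # zero null counts: upper ratio is unbounded (zero-count rule)
        ratio_hi = hi_o / lo_n if null_count > 0 and lo_n > 0 else float("inf")
        rows.append(
            (tail, f_obs, lo_o, hi_o, f_null, lo_n, hi_n, ratio, ratio_lo, ratio_hi)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "tail",
            "observed",
            "observed_lo",
            "observed_hi",
            "null",
            "null_lo",
            "null_hi",
            "ratio",
            "ratio_lo",
            "ratio_hi",
        ],
    ).set_index("tail")
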