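"""nemPAI / lPAI normalization and coarse-grained integer profiles.

nemPAI rescales each experiment so its emPAI values sum to the number of
distinct proteins P, making the scale commensurate with an average abundance
of 1.  lPAI is the decimal logarithm of nemPAI with zeros (undetected
proteins) replaced by a small pseudo-abundance (default 0.001) at the log
step only — the pseudo-value never enters the normalization sum.
Coarse-grained profiles rescale each protein's lPAI vector into integer
steps of the significance threshold tau: subtract the minimum, divide by
tau, floor.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_tables import AbundanceMatrix, PipelineConfig

__all__ = [
    "NormalizedMatrix",
    "normalize_empai",
    "to_lpai",
    "coarse_grain",
    "coarse_profiles",
    "detected_census",
    "write_normalized_table",
]


class NormalizedMatrix:
    """nemPAI and lPAI layers sharing one protein x condition index."""

    def __init__(
        self,
        nempai: pd.DataFrame,
        lpai: pd.DataFrame,
        detected: pd.DataFrame,
        baseline: str,
        scale_count: int,
        pseudo_abundance: float,
    ):
        self.nempai = nempai
        self.lpai = lpai
        self.detected = detected
        self.baseline = baseline
        self.scale_count = scale_count
        self.pseudo_abundance = pseudo_abundance

    @property
    def conditions(self) -> list:
        return list(self.nempai.columns)

    @property
    def loci(self) -> list:
        return list(self.nempai.index)

    @property
    def n_proteins(self) -> int:
        return self.nempai.shape[0]

    def __repr__(self) -> str:
        return (
            f"NormalizedMatrix({self.n_proteins} proteins x "
            f"{len(self.conditions)} conditions, P={self.scale_count}, "
            f"baseline={self.baseline!r})"
        )


def normalize_empai(m: AbundanceMatrix, cfg: PipelineConfig) -> NormalizedMatrix:
    """nemPAI_ic = emPAI_ic / sum_j emPAI_jc * P, plus the lPAI layer.

    P defaults to the matrix row count when ``cfg.scale_count`` is None.
    A condition in which nothing was detected has an undefined normalization
    and is rejected.
    """
    sums = m.data.sum(axis=0)
    dead = sums.index[sums <= 0]
    if len(dead):
        raise ValueError(f"condition {dead[0]!r} has no detected protein (all emPAI zero)")
    P = cfg.scale_count if cfg.scale_count is not None else m.n_proteins
    if P < 1:
        raise ValueError("scale_count must be positive")
    nempai = m.data * float(P) / sums
    detected = m.data > 0
    lpai = pd.DataFrame(
        np.where(detected, np.log10(nempai.where(detected, 1.0)), np.log10(cfg.pseudo_abundance)),
        index=nempai.index,
        columns=nempai.columns,
    )
    return NormalizedMatrix(
        nempai=nempai,
        lpai=lpai,
        detected=detected,
        baseline=m.baseline,
        scale_count=int(P),
        pseudo_abundance=cfg.pseudo_abundance,
    )


def to_lpai(nempai_value: float, cfg: PipelineConfig) -> float:
    """Decimal log of one nemPAI value; zeros map to log10(pseudo_abundance)."""
    if nempai_value < 0:
        raise ValueError("nemPAI must be non-negative")
    if nempai_value > 0:
        return float(np.log10(nempai_value))
    return float(np.log10(cfg.pseudo_abundance))


def coarse_grain(lpai_profile, tau: float) -> np.ndarray:
    """Integer levels: floor((lpai - min(lpai)) / tau); the minimum is 0."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    profile = np.asarray(lpai_profile, dtype=float)
    return np.floor((profile - profile.min()) / tau).astype(int)


def coarse_profiles(m: NormalizedMatrix, tau: float) -> pd.DataFrame:
    """Coarse-grained levels for every protein (rows) and condition."""
    values = m.lpai.values
    levels = np.floor((values - values.min(axis=1, keepdims=True)) / tau).astype(int)
    return pd.DataFrame(levels, index=m.lpai.index, columns=m.lpai.columns)


def detected_census(m: NormalizedMatrix, condition: str):
    """(count, fraction of scale_count P) of proteins detected in a condition."""
    if condition not in m.detected.columns:
        raise KeyError(f"unknown condition {condition!r}")
    count = int(m.detected[condition].sum())
    return count, count / m.scale_count


def write_normalized_table(m: NormalizedMatrix, path, tau: float | None = None) -> None:
    """One combined TSV: per-condition nemPAI, lPAI, detected flag and
    (optionally) coarse level columns."""
    parts = {
        "nempai": m.nempai,
        "lpai": m.lpai,
        "detected": m.detected.astype(int),
    }
    if tau is not None:
        parts["level"] = coarse_profiles(m, tau)
    out = pd.concat(
        {name: df for name, df in parts.items()}, axis=1
    )
    out.columns = [f"{layer}_{cond}" for layer, cond in out.columns]
    out.index.name = "locus_tag"
    out.to_csv(path, sep="\t")
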