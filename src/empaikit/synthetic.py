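"""Seeded synthetic proteome datasets with ground truth.

The generator emulates the statistical structure the analysis assumes:

* baseline protein abundance log-normal on the lPAI scale (Normal(mu, sigma)
  in decimal log units) with a small super-abundant heavy tail;
* a hard detection limit — true lPAI below a floor is emitted as emPAI 0;
* a stoichiometric reference set sharing one common abundance level, whose
  cells carry independent per-measurement noise (the only stochastic
  measurement error: all other proteins carry deterministic condition
  effects, so classifier truth is unambiguous);
* per-condition effects (additive on the lPAI scale, i.e. multiplicative on
  abundance) hitting a random subset of proteins, with the two
  temperature-like conditions drawing part of their affected sets from a
  shared pool with equal-direction effects;
* paralogous families whose members are co-regulated (identical effect
  vectors), counter-regulated (sign-alternating) or independent.

Emitted emPAI columns are rescaled by heterogeneous per-condition factors so
the normalization stage is actually exercised.  All randomness flows from a
single seed through one generator stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .io_tables import AbundanceMatrix, PipelineConfig, ProteinRecord

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "generate_dataset",
    "default_pipeline_config",
    "generate_worked_example",
]

_CANONICAL_CONDITIONS = ("base", "T34", "T55", "TMA", "FeS", "H2")
_CATEGORY_LETTERS = "EFGHIMPQJKLT"


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale defaults: 1529 proteins, 6 conditions, log-normal bulk of
    sigma 0.6 log10 units, detection floor -1.5, a 25-protein reference set
    with 0.25 log-unit per-cell noise, 10% of proteins affected per condition
    at 1.0 log unit, half of the temperature effects shared, 8 super-abundant
    proteins boosted 1.5 log units, 75 paralogous families."""

    n_proteins: int = 1529
    n_conditions: int = 6
    lpai_mu: float = 0.0
    lpai_sigma: float = 0.6
    detection_lpai_floor: float = -1.5
    n_reference: int = 25
    reference_noise_sd: float = 0.25
    reference_level: float = 1.0  # common baseline lPAI of the reference set
    frac_affected: float = 0.1
    effect_size: float = 1.0
    temp_shared_frac: float = 0.5
    n_families: int = 75
    family_size_probs: tuple = ((2, 0.45), (3, 0.25), (4, 0.15), (5, 0.10), (6, 0.05))
    frac_coregulated: float = 0.15
    frac_counterregulated: float = 0.15
    n_superabundant: int = 8
    superabundant_boost: float = 1.5
    frac_categorized: float = 0.7
    n_contigs: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "frac_affected",
            "temp_shared_frac",
            "frac_coregulated",
            "frac_counterregulated",
            "frac_categorized",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.frac_coregulated + self.frac_counterregulated > 1:
            raise ValueError("co- and counter-regulated fractions exceed 1")
        if self.lpai_sigma <= 0 or self.reference_noise_sd <= 0:
            raise ValueError("scale parameters must be positive")
        if self.n_reference + self.n_superabundant > self.n_proteins:
            raise ValueError("reference + super-abundant exceed n_proteins")
        if self.n_conditions < 2:
            raise ValueError("need at least a baseline and one other condition")
        need = self.n_families * max(s for s, _ in self.family_size_probs)
        if self.n_reference + need > self.n_proteins:
            raise ValueError("family demand exceeds available proteins")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth aligned row-for-row with the emitted matrix.

    ``table`` carries per-protein baseline lPAI and flags; ``effects`` the
    injected per-condition lPAI shifts (0 for the baseline column)."""

    table: pd.DataFrame
    effects: pd.DataFrame

    @property
    def affected(self) -> pd.DataFrame:
        """Boolean protein x condition truth of a nonzero injected effect."""
        return self.effects != 0.0


def _condition_labels(n: int) -> list:
    if n <= len(_CANONICAL_CONDITIONS):
        return list(_CANONICAL_CONDITIONS[:n])
    return list(_CANONICAL_CONDITIONS) + [f"alt{i}" for i in range(1, n - len(_CANONICAL_CONDITIONS) + 1)]


def generate_dataset(cfg: SimulationConfig):
    """Return (AbundanceMatrix, annotation records, SyntheticTruth)."""
    rng = np.random.default_rng(cfg.seed)
    n, k = cfg.n_proteins, cfg.n_conditions
    conditions = _condition_labels(k)
    loci = [f"SYN_{i + 1:04d}" for i in range(n)]

    baseline = rng.normal(cfg.lpai_mu, cfg.lpai_sigma, size=n)

    order = rng.permutation(n)
    ref_idx = order[: cfg.n_reference]
    super_idx = order[cfg.n_reference : cfg.n_reference + cfg.n_superabundant]
    baseline[ref_idx] = cfg.reference_level
    baseline[super_idx] += cfg.superabundant_boost

    # paralogous families drawn from the remaining proteins
    family_pool = list(order[cfg.n_reference + cfg.n_superabundant :])
    sizes, probs = zip(*cfg.family_size_probs)
    family_id = np.full(n, "", dtype=object)
    family_mode = np.full(n, "", dtype=object)
    families = []
    cursor = 0
    for f in range(cfg.n_families):
        size = int(rng.choice(sizes, p=np.asarray(probs) / np.sum(probs)))
        members = family_pool[cursor : cursor + size]
        cursor += size
        u = rng.random()
        if u < cfg.frac_coregulated:
            mode = "co"
        elif u < cfg.frac_coregulated + cfg.frac_counterregulated:
            mode = "counter"
        else:
            mode = "independent"
        fid = f"fam{f + 1:04d}"
        for m in members:
            family_id[m] = fid
            family_mode[m] = mode
        families.append((fid, mode, members))

    # per-condition affected sets and effects (baseline column stays 0)
    effects = np.zeros((n, k))
    temp_shared = np.zeros(n, dtype=bool)
    n_affected = int(round(cfg.frac_affected * n))
    temp_like = [i for i, c in enumerate(conditions) if c in ("T34", "T55")]
    if len(temp_like) == 2:
        n_shared = int(round(n_affected * cfg.temp_shared_frac))
        shared = rng.choice(n, size=n_shared, replace=False)
        temp_shared[shared] = True
        shared_sign = rng.choice([-1.0, 1.0], size=n_shared)
        others = np.setdiff1d(np.arange(n), shared)
        for ci in temp_like:
            effects[shared, ci] = shared_sign * cfg.effect_size
            own = rng.choice(others, size=n_affected - n_shared, replace=False)
            effects[own, ci] = rng.choice([-1.0, 1.0], size=own.size) * cfg.effect_size
    plain = [ci for ci in range(1, k) if ci not in temp_like]
    for ci in plain:
        hit = rng.choice(n, size=n_affected, replace=False)
        effects[hit, ci] = rng.choice([-1.0, 1.0], size=hit.size) * cfg.effect_size

    # regulated families overwrite their members with a family-level pattern
    for fid, mode, members in families:
        if mode == "independent":
            continue
        pattern = np.zeros(k)
        while not pattern[1:].any():
            hit = rng.random(k - 1) < cfg.frac_affected
            pattern[1:] = np.where(
                hit, rng.choice([-1.0, 1.0], size=k - 1) * cfg.effect_size, 0.0
            )
        for j, m in enumerate(members):
            sign = 1.0 if (mode == "co" or j % 2 == 0) else -1.0
            effects[m] = pattern * sign
    # the reference set is stoichiometric: no biological effects
    effects[ref_idx] = 0.0

    true_lpai = baseline[:, None] + effects
    noise = rng.normal(0.0, cfg.reference_noise_sd, size=(cfg.n_reference, k))
    true_lpai[ref_idx] += noise

    detected = true_lpai >= cfg.detection_lpai_floor
    col_scale = rng.uniform(0.5, 2.0, size=k)
    empai = np.where(detected, 10.0**true_lpai * col_scale, 0.0)

    matrix = AbundanceMatrix(
        pd.DataFrame(empai, index=loci, columns=conditions), baseline=conditions[0]
    )

    # annotation: contigs of near-equal size, categories for a random subset
    contig_of = np.sort(rng.integers(0, cfg.n_contigs, size=n))
    records = []
    order_within = {}
    categorized = rng.random(n) < cfg.frac_categorized
    categories = rng.choice(list(_CATEGORY_LETTERS), size=n)
    for i in range(n):
        contig = f"c{contig_of[i] + 1}"
        order_within[contig] = order_within.get(contig, 0) + 1
        arcog = family_id[i] or (f"sng{i:04d}" if rng.random() < 0.5 else None)
        records.append(
            ProteinRecord(
                locus_tag=loci[i],
                contig=contig,
                genome_order=order_within[contig],
                arcog_id=arcog,
                category=str(categories[i]) if categorized[i] else None,
                annotation="synthetic protein",
            )
        )

    truth = SyntheticTruth(
        table=pd.DataFrame(
            {
                "baseline_lpai": baseline,
                "is_reference": np.isin(np.arange(n), ref_idx),
                "temp_shared": temp_shared,
                "is_superabundant": np.isin(np.arange(n), super_idx),
                "family_id": family_id,
                "family_mode": family_mode,
            },
            index=loci,
        ),
        effects=pd.DataFrame(effects, index=loci, columns=conditions),
    )
    return matrix, records, truth


def default_pipeline_config(cfg: SimulationConfig, truth: SyntheticTruth) -> PipelineConfig:
    """PipelineConfig matched to a generated dataset (reference set filled in)."""
    refs = tuple(truth.table.index[truth.table["is_reference"]])
    return PipelineConfig(
        scale_count=cfg.n_proteins, rng_seed=cfg.seed, reference_set=refs
    )


# ---------------------------------------------------------------------------
# worked example: 10 proteins x 3 conditions, every expected value derived by
# hand from the dyadic emPAI literals below (column sums 10, 20 and 5; P=10)

_WE_CONDITIONS = ("base", "heat", "tma")
_WE_EMPAI = {
    #            base  heat  tma
    "WEX_0001": (2.0, 4.0, 0.25),
    "WEX_0002": (1.0, 8.0, 0.50),
    "WEX_0003": (0.5, 0.0, 0.25),
    "WEX_0004": (0.5, 1.0, 1.00),
    "WEX_0005": (1.0, 0.25, 0.50),
    "WEX_0006": (0.0, 1.0, 0.00),
    "WEX_0007": (2.0, 1.0, 0.00),
    "WEX_0008": (1.0, 1.25, 0.25),
    "WEX_0009": (1.0, 1.5, 0.50),
    "WEX_0010": (1.0, 2.0, 1.75),
}
_WE_NEMPAI = {  # empai * 10 / column sum (sums: 10, 20, 5) — hand arithmetic
    "WEX_0001": (2.0, 2.0, 0.5),
    "WEX_0002": (1.0, 4.0, 1.0),
    "WEX_0003": (0.5, 0.0, 0.5),
    "WEX_0004": (0.5, 0.5, 2.0),
    "WEX_0005": (1.0, 0.125, 1.0),
    "WEX_0006": (0.0, 0.5, 0.0),
    "WEX_0007": (2.0, 0.5, 0.0),
    "WEX_0008": (1.0, 0.625, 0.5),
    "WEX_0009": (1.0, 0.75, 1.0),
    "WEX_0010": (1.0, 1.0, 3.5),
}
_WE_LEVELS = {  # floor((lpai - min)/0.5), tau = 0.5 — hand arithmetic
    "WEX_0001": (1, 1, 0),
    "WEX_0002": (0, 1, 0),
    "WEX_0003": (5, 0, 5),
    "WEX_0004": (0, 0, 1),
    "WEX_0005": (1, 0, 1),
    "WEX_0006": (0, 5, 0),
    "WEX_0007": (6, 5, 0),
    "WEX_0008": (0, 0, 0),
    "WEX_0009": (0, 0, 0),
    "WEX_0010": (0, 0, 1),
}
_WE_CALLS = {  # (heat call, heat fold), (tma call, tma fold); None = no fold
    "WEX_0001": (("UNCHANGED", 1.0), ("DOWN", 4.0)),
    "WEX_0002": (("UP", 4.0), ("UNCHANGED", 1.0)),
    "WEX_0003": (("OFF", None), ("UNCHANGED", 1.0)),
    "WEX_0004": (("UNCHANGED", 1.0), ("UP", 4.0)),
    "WEX_0005": (("DOWN", 8.0), ("UNCHANGED", 1.0)),
    "WEX_0006": (("ON", None), ("UNCHANGED", None)),
    "WEX_0007": (("DOWN", 4.0), ("OFF", None)),
    "WEX_0008": (("UNCHANGED", 1.6), ("UNCHANGED", 2.0)),
    "WEX_0009": (("UNCHANGED", 4.0 / 3.0), ("UNCHANGED", 1.0)),
    "WEX_0010": (("UNCHANGED", 1.0), ("UP", 3.5)),
}
_WE_ANNOTATION = [
    # locus, contig, order, arcog, category
    ("WEX_0001", "c1", 1, "g1", "J"),
    ("WEX_0002", "c1", 2, "g1", "J"),
    ("WEX_0003", "c1", 3, None, "E"),
    ("WEX_0004", "c1", 4, "g2", "E"),
    ("WEX_0005", "c1", 5, None, None),
    ("WEX_0006", "c2", 1, None, "K"),
    ("WEX_0007", "c2", 2, None, None),
    ("WEX_0008", "c2", 3, None, "E"),
    ("WEX_0009", "c2", 4, None, "J"),
    ("WEX_0010", "c2", 5, None, None),
]


def generate_worked_example():
    """Fixed 10-protein, 3-condition dataset with hand-computed expectations.

    Returns a dict with keys ``matrix``, ``records``, ``config`` and the
    expected tables ``nempai`` (DataFrame), ``levels`` (DataFrame, tau 0.5),
    ``calls`` (dict locus -> ((heat call, fold), (tma call, fold))) and
    ``census_base`` (detected count, fraction).  emPAI literals are dyadic so
    the expected nemPAI values are exact in floating point.
    """
    matrix = AbundanceMatrix(
        pd.DataFrame.from_dict(_WE_EMPAI, orient="index", columns=list(_WE_CONDITIONS)),
        baseline="base",
    )
    records = [
        ProteinRecord(locus_tag=t, contig=c, genome_order=o, arcog_id=a, category=cat)
        for t, c, o, a, cat in _WE_ANNOTATION
    ]
    config = PipelineConfig(scale_count=10, threshold_tau=0.5, pseudo_abundance=1e-3)
    return {
        "matrix": matrix,
        "records": records,
        "config": config,
        "nempai": pd.DataFrame.from_dict(
            _WE_NEMPAI, orient="index", columns=list(_WE_CONDITIONS)
        ),
        "levels": pd.DataFrame.from_dict(
            _WE_LEVELS, orient="index", columns=list(_WE_CONDITIONS)
        ),
        "calls": dict(_WE_CALLS),
        "census_base": (9, 0.9),
    }
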