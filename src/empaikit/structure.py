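"""Condition-profile PCA, external-profile projection and silent islands.

PCA treats conditions as the variables (columns) and proteins as the
observations: columns are centred and rescaled to unit variance, then
decomposed by SVD.  The loadings say how each condition contributes to each
component; the "condition points" view embeds each condition (column) by its
correlation with the leading components, which is how profiles from
different organisms can be compared in one plane.

Silent islands are maximal runs of consecutive genes (by genome order,
within one contig) whose products are all undetected in a reference
condition; long runs typically mark integrated mobile elements, proviruses
or plasmids rather than scattered detection failures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .normalize import NormalizedMatrix

__all__ = [
    "PCAResult",
    "SilentIsland",
    "quality_filter",
    "pca_profiles",
    "project_profiles",
    "silent_islands",
    "islands_frame",
    "plot_condition_points",
    "plot_island_track",
]


@dataclass(frozen=True)
class PCAResult:
    """Decomposition of a proteins x conditions lPAI matrix.

    loadings: conditions x components (orthonormal columns).
    variance_fraction: per-component share of total variance (sums to 1).
    scores: proteins x components observation coordinates.
    condition_points: conditions x components; each condition embedded by
        loading * singular value / sqrt(n-1), i.e. its correlation with the
        component (columns are standardized).
    """

    loadings: pd.DataFrame
    variance_fraction: pd.Series
    scores: pd.DataFrame
    condition_points: pd.DataFrame


@dataclass(frozen=True)
class SilentIsland:
    contig: str
    start_order: int
    end_order: int
    member_loci: tuple

    @property
    def size(self) -> int:
        return self.end_order - self.start_order + 1


def quality_filter(m: NormalizedMatrix) -> pd.Index:
    """Proteins detected in at least one condition."""
    return m.detected.index[m.detected.any(axis=1)]


def _standardize(X: np.ndarray, columns) -> np.ndarray:
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    # constant columns can carry O(eps) spread from summation rounding
    dead = np.flatnonzero(sd <= 1e-12 * np.maximum(1.0, np.abs(mean)))
    if dead.size:
        raise ValueError(f"zero-variance column: {columns[dead[0]]!r}")
    return (X - mean) / sd


def _decompose(lpai: pd.DataFrame) -> PCAResult:
    X = _standardize(lpai.values.astype(float), list(lpai.columns))
    n, k = X.shape
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    var = s**2
    names = [f"PC{i + 1}" for i in range(len(s))]
    loadings = pd.DataFrame(Vt.T, index=lpai.columns, columns=names)
    scores = pd.DataFrame(U * s, index=lpai.index, columns=names)
    points = pd.DataFrame(
        Vt.T * s / np.sqrt(n - 1), index=lpai.columns, columns=names
    )
    return PCAResult(
        loadings=loadings,
        variance_fraction=pd.Series(var / var.sum(), index=names),
        scores=scores,
        condition_points=points,
    )


def pca_profiles(m: NormalizedMatrix, subset=None) -> PCAResult:
    """PCA of the lPAI matrix restricted to a protein subset (default: the
    quality-filtered set).  Needs >= 2 conditions and >= 3 proteins."""
    if subset is None:
        subset = quality_filter(m)
    lpai = m.lpai.loc[subset]
    if lpai.shape[1] < 2 or lpai.shape[0] < 3:
        raise ValueError("PCA needs >= 2 conditions and >= 3 proteins")
    return _decompose(lpai)


def project_profiles(
    m: NormalizedMatrix,
    external_profile: pd.Series,
    ortholog_map: dict | None = None,
    label: str = "external",
    min_coverage: float = 0.5,
) -> PCAResult:
    """Joint PCA of the internal condition profiles plus one external profile.

    ``external_profile`` holds lPAI values indexed by external locus tags (or
    directly by internal tags when ``ortholog_map`` is None).
    ``ortholog_map`` maps external locus -> internal locus.  Internal proteins
    not covered by the map are treated as undetected in the external profile
    (pseudo-abundance lPAI).  Coverage below ``min_coverage`` of the filtered
    proteins is rejected.
    """
    subset = quality_filter(m)
    if ortholog_map is not None:
        mapped = {
            ortholog_map[ext]: v
            for ext, v in external_profile.items()
            if ext in ortholog_map
        }
        external = pd.Series(mapped)
    else:
        external = external_profile
    covered = subset.intersection(external.index)
    coverage = len(covered) / len(subset)
    if coverage < min_coverage:
        raise ValueError(
            f"external profile covers {coverage:.1%} of filtered proteins "
            f"(floor {min_coverage:.0%})"
        )
    pseudo_lpai = float(np.log10(m.pseudo_abundance))
    col = pd.Series(pseudo_lpai, index=subset, name=label)
    col[covered] = external[covered]
    joint = m.lpai.loc[subset].copy()
    if label in joint.columns:
        raise ValueError(f"label {label!r} collides with a condition name")
    joint[label] = col
    return _decompose(joint)


def silent_islands(
    m: NormalizedMatrix, records, condition: str, min_run: int = 5
) -> list:
    """Maximal runs of >= min_run consecutive undetected genes.

    Runs are scanned within each contig in genome order and never cross a
    contig boundary; consecutiveness is strict in the gene rank (annotated
    genes without abundance rows break a run).
    """
    if condition not in m.detected.columns:
        raise KeyError(f"unknown condition {condition!r}")
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    detected = m.detected[condition]
    islands = []
    by_contig = {}
    for r in records:
        by_contig.setdefault(r.contig, []).append(r)
    for contig in sorted(by_contig):
        run = []
        prev_order = None
        for r in sorted(by_contig[contig], key=lambda r: r.genome_order):
            silent = r.locus_tag in detected.index and not bool(detected[r.locus_tag])
            contiguous = prev_order is not None and r.genome_order == prev_order + 1
            if silent and (contiguous and run):
                run.append(r)
            elif silent:
                if len(run) >= min_run:
                    islands.append(_island(contig, run))
                run = [r]
            else:
                if len(run) >= min_run:
                    islands.append(_island(contig, run))
                run = []
            prev_order = r.genome_order
        if len(run) >= min_run:
            islands.append(_island(contig, run))
    return islands


def _island(contig: str, run) -> SilentIsland:
    return SilentIsland(
        contig=contig,
        start_order=run[0].genome_order,
        end_order=run[-1].genome_order,
        member_loci=tuple(r.locus_tag for r in run),
    )


def islands_frame(islands) -> pd.DataFrame:
    """BED-like tabular view of a list of islands."""
    return pd.DataFrame(
        [
            (i.contig, i.start_order, i.end_order, i.size, ",".join(i.member_loci))
            for i in islands
        ],
        columns=["contig", "start_order", "end_order", "size", "member_loci"],
    )


def plot_condition_points(pca: PCAResult, ax=None):
    """Scatter of condition points against PC1/PC2."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    pts = pca.condition_points
    ax.scatter(pts["PC1"], pts["PC2"])
    for name, row in pts.iterrows():
        ax.annotate(str(name), (row["PC1"], row["PC2"]))
    v = pca.variance_fraction
    ax.set_xlabel(f"PC1 ({100 * v['PC1']:.0f}%)")
    ax.set_ylabel(f"PC2 ({100 * v['PC2']:.0f}%)")
    return ax


def plot_island_track(m: NormalizedMatrix, records, condition: str, islands, ax=None):
    """Linear detection track along the genome with islands shaded."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 2))
    order = {r.locus_tag: i for i, r in enumerate(records)}
    xs = [order[t] for t in m.detected.index if t in order]
    ys = [int(m.detected.loc[t, condition]) for t in m.detected.index if t in order]
    ax.vlines(xs, 0, ys, lw=0.5)
    pos = {r.locus_tag: i for i, r in enumerate(records)}
    for isl in islands:
        span = [pos[t] for t in isl.member_loci if t in pos]
        if span:
            ax.axvspan(min(span) - 0.5, max(span) + 0.5, color="red", alpha=0.2)
    ax.set_yticks([0, 1])
    ax.set_yticklabels(["silent", "detected"])
    ax.set_xlabel("gene rank along genome")
    return ax
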