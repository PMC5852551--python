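"""Model/Results facade over the full analysis.

``ProteomeAbundanceModel`` bundles an emPAI matrix, annotation records and a
``PipelineConfig``; ``fit()`` runs normalization, noise calibration, the
equivalent-normal abundance model, differential classification, condition
PCA, silent-island detection and the paralog correlation analysis, and
returns a ``ProteomeResults`` carrying every stage's output with a
``summary()`` table, in the spirit of a statsmodels results object.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import pandas as pd

from . import calibrate as _calibrate
from . import differential as _differential
from . import dist_stats as _dist_stats
from . import normalize as _normalize
from . import paralogs as _paralogs
from . import structure as _structure
from .io_tables import (
    AbundanceMatrix,
    PipelineConfig,
    ProteinRecord,
    read_abundance_table,
    read_annotation_table,
)

__all__ = ["ProteomeAbundanceModel", "ProteomeResults"]

logger = logging.getLogger(__name__)


class ProteomeAbundanceModel:
    """emPAI abundance analysis of one proteome across growth conditions."""

    def __init__(
        self,
        matrix: AbundanceMatrix,
        records: Optional[Sequence[ProteinRecord]] = None,
        config: Optional[PipelineConfig] = None,
    ):
        self.matrix = matrix
        self.records = list(records) if records is not None else None
        self.config = config or PipelineConfig()

    @classmethod
    def from_dataframe(
        cls,
        empai: pd.DataFrame,
        baseline: str,
        records: Optional[Sequence[ProteinRecord]] = None,
        config: Optional[PipelineConfig] = None,
    ) -> "ProteomeAbundanceModel":
        return cls(AbundanceMatrix(empai, baseline=baseline), records, config)

    @classmethod
    def from_tables(
        cls,
        abundance_path,
        baseline: str,
        annotation_path=None,
        config: Optional[PipelineConfig] = None,
    ) -> "ProteomeAbundanceModel":
        records = read_annotation_table(annotation_path) if annotation_path else None
        return cls(read_abundance_table(abundance_path, baseline), records, config)

    def fit(self) -> "ProteomeResults":
        cfg = self.config
        normalized = _normalize.normalize_empai(self.matrix, cfg)

        calibration = None
        if cfg.reference_set:
            calibration = _calibrate.calibrate_noise(
                normalized, cfg.reference_set, cfg.threshold_tau
            )

        calls = _differential.classify_all(normalized, cfg)

        reports = {}
        for cond in normalized.conditions:
            try:
                reports[cond] = _dist_stats.abundance_report(normalized, cond)
            except ValueError as exc:  # too few / degenerate detected values
                logger.warning("abundance report skipped for %s: %s", cond, exc)

        pca = None
        try:
            pca = _structure.pca_profiles(normalized)
        except ValueError as exc:  # e.g. too few proteins/conditions
            logger.warning("PCA skipped: %s", exc)

        islands = (
            _structure.silent_islands(
                normalized, self.records, normalized.baseline, cfg.min_silent_run
            )
            if self.records
            else []
        )

        paralog = None
        if self.records is not None:
            paralog = self._fit_paralogs(normalized, cfg)

        return ProteomeResults(
            model=self,
            normalized=normalized,
            calibration=calibration,
            calls=calls,
            abundance_reports=reports,
            pca=pca,
            islands=islands,
            paralog=paralog,
        )

    def _fit_paralogs(self, normalized, cfg):
        variable = _paralogs.select_variable_proteins(normalized, cfg.threshold_tau)
        families, singletons = _paralogs.group_families(variable, self.records)
        coarse = _normalize.coarse_profiles(normalized, cfg.threshold_tau)
        try:
            pairs, observed = _paralogs.family_correlations(
                families, coarse, cfg.correlation_cutoff
            )
            null = _paralogs.null_fractions(singletons, coarse, cfg)
            excess = _paralogs.excess_report(observed, null)
        except ValueError as exc:
            logger.warning("paralog analysis skipped: %s", exc)
            return None
        return {
            "variable": variable,
            "families": families,
            "singletons": singletons,
            "pairs": pairs,
            "observed": observed,
            "null": null,
            "excess": excess,
        }


class ProteomeResults:
    """Fitted pipeline outputs (see each module for the individual types)."""

    def __init__(
        self, model, normalized, calibration, calls, abundance_reports, pca, islands, paralog
    ):
        self.model = model
        self.normalized = normalized
        self.calibration = calibration
        self.calls = calls
        self.abundance_reports = abundance_reports
        self.pca = pca
        self.islands = islands
        self.paralog = paralog

    # convenience views -----------------------------------------------------
    @property
    def calls_frame(self) -> pd.DataFrame:
        return _differential.calls_frame(self.calls)

    def detected_census(self, condition: Optional[str] = None):
        cond = condition or self.normalized.baseline
        return _normalize.detected_census(self.normalized, cond)

    def shared_response(self, cond_a: str, cond_b: str, include_on_off: bool = True) -> set:
        return _differential.shared_response(self.calls, cond_a, cond_b, include_on_off)

    def super_abundant(self, condition: Optional[str] = None) -> pd.DataFrame:
        cond = condition or self.normalized.baseline
        if cond not in self.abundance_reports:
            return pd.DataFrame(
                columns=["nempai", "lpai", "z", "e_value", "super_abundant"]
            )
        report = self.abundance_reports[cond]
        return report[report["super_abundant"]]

    def plot_pca(self, ax=None):
        if self.pca is None:
            raise ValueError("PCA was not fitted")
        return _structure.plot_condition_points(self.pca, ax=ax)

    def summary(self) -> str:
        nm = self.normalized
        lines = [
            "Proteome abundance analysis",
            "=" * 60,
            f"proteins: {nm.n_proteins}  conditions: {len(nm.conditions)}  "
            f"baseline: {nm.baseline!r}  P: {nm.scale_count}",
        ]
        count, frac = self.detected_census()
        lines.append(f"detected at baseline: {count} ({100 * frac:.0f}% of P)")
        if self.calibration is not None:
            c = self.calibration
            lines.append(
                f"reference noise RMS: {c.rms_log:.3f} log10 units "
                f"(factor {c.rms_factor:.2f}); tau={c.tau:.2f} leaves "
                f"{100 * c.fraction_insignificant:.0f}% of deviations insignificant"
            )
        n_super = len(self.super_abundant())
        lines.append(f"super-abundant at baseline: {n_super}")
        frame = self.calls_frame
        sig = frame[frame["call"] != "UNCHANGED"]
        lines.append(
            "significant calls per condition: "
            + ", ".join(
                f"{cond}={int((sig['condition'] == cond).sum())}"
                for cond in nm.conditions
                if cond != nm.baseline
            )
        )
        if self.pca is not None:
            v = self.pca.variance_fraction
            lines.append(
                f"PCA: PC1 {100 * v.iloc[0]:.1f}% of variance"
                + (f", PC2 {100 * v.iloc[1]:.1f}%" if len(v) > 1 else "")
            )
        if self.islands:
            largest = max(self.islands, key=lambda i: i.size)
            lines.append(
                f"silent islands: {len(self.islands)} "
                f"(largest {largest.size} genes on {largest.contig})"
            )
        if self.paralog is not None:
            obs = self.paralog["observed"]
            nul = self.paralog["null"].fractions
            lines.append(
                f"paralog tails at |r|>{obs.cutoff:g}: observed "
                f"{100 * obs.frac_pos:.1f}%/{100 * obs.frac_neg:.1f}% "
                f"(pos/neg) vs null {100 * nul.frac_pos:.1f}%/{100 * nul.frac_neg:.1f}%"
            )
        return "\n".join(lines)
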