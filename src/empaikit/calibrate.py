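"""Noise calibration from a stoichiometric reference protein set.

Proteins bound in fixed stoichiometry within one complex (here: the 25
ribosomal proteins of the main ribosomal superoperon) should keep constant
relative abundance across growth conditions; their residual cross-condition
variation after normalization estimates the non-biological measurement
noise.  The root-mean-square of the pooled deviations (in decimal log
units) calibrates the significance threshold tau: a useful tau renders the
bulk of reference deviations insignificant (97% at tau = 0.5 for RMS 0.25).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .normalize import NormalizedMatrix

__all__ = [
    "NoiseCalibration",
    "reference_deviations",
    "noise_rms",
    "fraction_insignificant",
    "threshold_factor",
    "calibrate_noise",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NoiseCalibration:
    """Pooled reference deviations and the derived noise figures.

    rms_log is in decimal log10 units; rms_factor = 10**rms_log is the same
    noise as a linear fold factor.  fraction_insignificant is the share of
    deviations with |d| <= tau.
    """

    reference_loci: tuple
    deviations: np.ndarray
    rms_log: float
    rms_factor: float
    tau: float
    fraction_insignificant: float

    def summary(self) -> str:
        return (
            f"Noise calibration on {len(self.reference_loci)} reference proteins\n"
            f"  pooled deviations : {self.deviations.size}\n"
            f"  RMS               : {self.rms_log:.3f} log10 units "
            f"(factor {self.rms_factor:.2f})\n"
            f"  threshold tau     : {self.tau:.3f} log10 units "
            f"(factor {threshold_factor(self.tau):.2f})\n"
            f"  insignificant     : {100 * self.fraction_insignificant:.1f}% of deviations"
        )


def reference_deviations(
    m: NormalizedMatrix, reference_loci, expectation: str = "mean"
) -> np.ndarray:
    """Pooled per-cell deviations of reference proteins from their expectation.

    With ``expectation="mean"`` (default) each protein's expectation is its
    mean lPAI over the conditions in which it is detected; deviations are
    lPAI - mean, pooled over proteins and conditions.  With
    ``expectation="baseline"`` the baseline-condition lPAI is the expectation
    and the baseline cell itself contributes no deviation.

    Undetected cells are excluded (a pseudo-value would inject an artifact of
    the 0.001 constant into the RMS).  A reference locus absent from the
    matrix is an error; one detected in fewer than 2 conditions is skipped
    with a warning.
    """
    if expectation not in ("mean", "baseline"):
        raise ValueError(f"unknown expectation mode {expectation!r}")
    pooled = []
    for locus in reference_loci:
        if locus not in m.lpai.index:
            raise KeyError(f"reference locus {locus!r} not in matrix")
        det = m.detected.loc[locus]
        if int(det.sum()) < 2:
            logger.warning(
                "reference protein %s detected in %d condition(s); excluded",
                locus,
                int(det.sum()),
            )
            continue
        row = m.lpai.loc[locus][det]
        if expectation == "mean":
            pooled.extend(row - row.mean())
        else:
            if not bool(m.detected.loc[locus, m.baseline]):
                logger.warning(
                    "reference protein %s undetected at baseline; excluded", locus
                )
                continue
            base = m.lpai.loc[locus, m.baseline]
            pooled.extend(row.drop(m.baseline) - base)
    return np.asarray(pooled, dtype=float)


def noise_rms(deviations) -> tuple:
    """(rms_log, rms_factor): sqrt(mean(d^2)) and its linear fold factor."""
    d = np.asarray(deviations, dtype=float)
    if d.size == 0:
        raise ValueError("no deviations to summarize")
    rms = float(np.sqrt(np.mean(d**2)))
    return rms, float(10.0**rms)


def fraction_insignificant(deviations, tau: float) -> float:
    """Share of deviations with |d| <= tau (boundary counts as insignificant)."""
    d = np.asarray(deviations, dtype=float)
    if d.size == 0:
        raise ValueError("no deviations to summarize")
    if tau <= 0:
        raise ValueError("tau must be positive")
    return float(np.mean(np.abs(d) <= tau))


def threshold_factor(tau: float) -> float:
    """Linear fold factor of a log10 threshold: 10**tau (0.5 -> 3.16)."""
    if tau < 0:
        raise ValueError("tau must be non-negative")
    return float(10.0**tau)


def calibrate_noise(
    m: NormalizedMatrix, reference_loci, tau: float, expectation: str = "mean"
) -> NoiseCalibration:
    """Run the full calibration and bundle the results."""
    d = reference_deviations(m, reference_loci, expectation=expectation)
    rms_log, rms_factor = noise_rms(d)
    return NoiseCalibration(
        reference_loci=tuple(reference_loci),
        deviations=d,
        rms_log=rms_log,
        rms_factor=rms_factor,
        tau=tau,
        fraction_insignificant=fraction_insignificant(d, tau),
    )
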