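"""ON/OFF/UP/DOWN/UNCHANGED classification against a baseline condition.

A change is significant when the linear fold ratio reaches 10**tau
(inclusive; tau = 0.5 gives the factor 3.16).  Appearance (ON) and
disappearance (OFF) relative to the baseline detection state take precedence
over the ratio logic and never carry a fold change — the pseudo-abundance
would otherwise make every ON/OFF trivially "significant" by ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd

from .io_tables import PipelineConfig, ProteinRecord
from .normalize import NormalizedMatrix

__all__ = [
    "Call",
    "DifferentialCall",
    "classify_protein",
    "classify_all",
    "calls_frame",
    "shared_response",
    "category_counts",
    "write_calls",
]


class Call(str, Enum):
    ON = "ON"
    OFF = "OFF"
    UP = "UP"
    DOWN = "DOWN"
    UNCHANGED = "UNCHANGED"

    @property
    def significant(self) -> bool:
        return self is not Call.UNCHANGED

    @property
    def direction(self) -> int:
        """+1 for ON/UP, -1 for OFF/DOWN, 0 otherwise."""
        if self in (Call.ON, Call.UP):
            return 1
        if self in (Call.OFF, Call.DOWN):
            return -1
        return 0


@dataclass(frozen=True)
class DifferentialCall:
    locus_tag: str
    condition: str
    call: Call
    fold_change: Optional[float]  # linear ratio >= 1 (larger/smaller); None for ON/OFF
    direction_lpai: float  # lPAI_alt - lPAI_base


def classify_protein(
    base_nempai: float, alt_nempai: float, tau: float, locus_tag: str = "", condition: str = ""
) -> DifferentialCall:
    """Classify one protein in one condition against the baseline.

    ON: undetected at baseline, detected in the condition; OFF the reverse;
    UP/DOWN: detected in both with ratio >= 10**tau; otherwise UNCHANGED
    (including undetected in both).
    """
    if base_nempai < 0 or alt_nempai < 0:
        raise ValueError("abundances must be non-negative")
    if tau <= 0:
        raise ValueError("tau must be positive")
    factor = 10.0**tau
    if base_nempai == 0 and alt_nempai > 0:
        call, fold = Call.ON, None
    elif base_nempai > 0 and alt_nempai == 0:
        call, fold = Call.OFF, None
    elif base_nempai == 0 and alt_nempai == 0:
        call, fold = Call.UNCHANGED, None
    else:
        ratio_up = alt_nempai / base_nempai
        ratio_down = base_nempai / alt_nempai
        fold = max(ratio_up, ratio_down)
        if ratio_up >= factor:
            call = Call.UP
        elif ratio_down >= factor:
            call = Call.DOWN
        else:
            call = Call.UNCHANGED
    if base_nempai > 0 and alt_nempai > 0:
        delta = float(np.log10(alt_nempai) - np.log10(base_nempai))
    elif alt_nempai > base_nempai:
        delta = float("inf")
    elif base_nempai > alt_nempai:
        delta = float("-inf")
    else:
        delta = 0.0
    return DifferentialCall(locus_tag, condition, call, fold, delta)


def classify_all(m: NormalizedMatrix, cfg: PipelineConfig) -> list:
    """One DifferentialCall per protein per non-baseline condition."""
    calls = []
    base = m.nempai[m.baseline]
    for cond in m.conditions:
        if cond == m.baseline:
            continue
        alt = m.nempai[cond]
        for locus in m.loci:
            calls.append(
                classify_protein(
                    float(base[locus]), float(alt[locus]), cfg.threshold_tau, locus, cond
                )
            )
    return calls


def calls_frame(calls) -> pd.DataFrame:
    """Tabular view of a list of calls."""
    return pd.DataFrame(
        [
            (c.locus_tag, c.condition, c.call.value, c.fold_change, c.direction_lpai)
            for c in calls
        ],
        columns=["locus_tag", "condition", "call", "fold_change", "delta_lpai"],
    )


def shared_response(calls, cond_a: str, cond_b: str, include_on_off: bool = True) -> set:
    """Loci significantly and concordantly affected in both conditions.

    {ON, UP} count as one direction, {OFF, DOWN} as the other.  With
    ``include_on_off=False`` only fold-change UP/DOWN calls enter the
    concordance check.
    """
    by_cond = {cond_a: {}, cond_b: {}}
    for c in calls:
        if c.condition in by_cond:
            by_cond[c.condition][c.locus_tag] = c.call
    if not by_cond[cond_a] or not by_cond[cond_b]:
        raise ValueError(f"conditions {cond_a!r}/{cond_b!r} not both present in calls")
    allowed = {Call.ON, Call.OFF, Call.UP, Call.DOWN}
    if not include_on_off:
        allowed = {Call.UP, Call.DOWN}
    shared = set()
    for locus, call_a in by_cond[cond_a].items():
        call_b = by_cond[cond_b].get(locus)
        if call_b is None:
            continue
        if call_a in allowed and call_b in allowed and call_a.direction == call_b.direction:
            shared.add(locus)
    return shared


def category_counts(calls, records) -> pd.DataFrame:
    """UP-like (ON+UP) and DOWN-like (OFF+DOWN) counts per functional
    category and condition; proteins without a category land in
    'uncategorized'."""
    cat = {r.locus_tag: (r.category or "uncategorized") for r in records}
    rows = []
    for c in calls:
        if not c.call.significant:
            continue
        rows.append(
            (
                cat.get(c.locus_tag, "uncategorized"),
                c.condition,
                "UP-like" if c.call.direction > 0 else "DOWN-like",
            )
        )
    conditions = sorted({c.condition for c in calls})
    categories = sorted({cat.get(c.locus_tag, "uncategorized") for c in calls})
    index = pd.MultiIndex.from_product(
        [categories, ["UP-like", "DOWN-like"]], names=["category", "direction"]
    )
    out = pd.DataFrame(0, index=index, columns=conditions)
    for category, condition, direction in rows:
        out.loc[(category, direction), condition] += 1
    return out


def write_calls(calls, path) -> None:
    calls_frame(calls).to_csv(path, sep="\t", index=False)
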