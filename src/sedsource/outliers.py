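"""Robust MAD-based outlier screening of contamination matrices.

For each chemical the distribution of (hazard- or risk-quotient) values over
all sampling positions is summarised by its median and median absolute
deviation (MAD).  The statistic

    On(x) = |x - median| / MAD

counts how many MADs a position sits from the bulk; positions exceeding a
chosen cutoff ``n`` on at least one chemical are flagged as possible point
sources, with the offending chemicals identifying the likely discharge.
No consistency constant is applied to the MAD: On is used raw, so cutoff
values are in MAD units, not approximate standard deviations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ContaminationMatrix, ValidationError

__all__ = ["mad", "on_score", "on_scores", "OutlierReport", "identify_point_sources"]


def mad(values) -> float:
    """Median absolute deviation about the median (no consistency constant)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValidationError("mad of empty input")
    med = np.median(v)
    return float(np.median(np.abs(v - med)))


def on_score(x: float, values) -> float:
    """How many MADs ``x`` lies from the median of ``values``.

    A zero MAD (constant reference distribution) yields 0 when ``x`` equals
    the median and +inf otherwise — a sentinel flag rather than an error, so
    degenerate columns surface loudly instead of crashing a screen.
    """
    v = np.asarray(values, dtype=float)
    med = float(np.median(v[np.isfinite(v)]))
    m = mad(v)
    dev = abs(x - med)
    if m == 0.0:
        return 0.0 if dev == 0.0 else math.inf
    return dev / m


def on_scores(values) -> np.ndarray:
    """Vectorised On of each element against its own column (NaN-aware).

    Each observed value is scored against the full distribution including
    itself, matching the definition's indexing over all positions.
    """
    v = np.asarray(values, dtype=float)
    finite = v[np.isfinite(v)]
    if finite.size == 0:
        raise ValidationError("on_scores of all-missing input")
    med = np.median(finite)
    m = float(np.median(np.abs(finite - med)))
    dev = np.abs(v - med)
    if m == 0.0:
        out = np.where(dev == 0.0, 0.0, np.inf)
    else:
        out = dev / m
    out = np.where(np.isfinite(v), out, np.nan)
    return out


@dataclass
class OutlierReport:
    """Per-(position, chemical) On scores against a cutoff.

    ``ordered_sources`` ranks flagged positions by their maximum On over
    chemicals (ties: more offending chemicals first, then position id);
    ``per_source_chemicals`` lists, for each flagged position, the chemicals
    at or above the cutoff in descending On order.
    """

    cutoff: float
    scores: pd.DataFrame
    ordered_sources: list[str]
    per_source_chemicals: dict[str, list[str]]
    degenerate_chemicals: list[str] = field(default_factory=list)

    @property
    def source_set(self) -> frozenset[str]:
        return frozenset(self.ordered_sources)


def identify_point_sources(
    matrix: ContaminationMatrix, cutoff: float = 4.0, direction: str = "above"
) -> OutlierReport:
    """Flag positions whose value on any chemical exceeds ``cutoff`` MADs.

    Every position is scored against every chemical's full across-position
    distribution (the On grid in ``scores`` is two-sided).  Flagging, by
    default, considers only values *above* the column median that do not rest
    on below-detection-limit readings: a point source adds contamination, so
    low-side exceedances — typically censoring artefacts from detection-limit
    substitution — are not source evidence (pass ``direction="both"`` for the
    symmetric screen).  Raising the cutoff can only shrink the flagged list,
    so screening at several cutoffs produces nested source lists.
    """
    if direction not in ("above", "both"):
        raise ValueError(f"direction must be 'above' or 'both', got {direction!r}")
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    if matrix.value_kind not in ("hq", "risk_quotient"):
        raise ValueError("identify_point_sources expects a normalised matrix")
    if len(matrix.points) < 5:
        raise ValueError("need at least 5 positions per chemical column")

    scores = pd.DataFrame(index=matrix.data.index, columns=matrix.data.columns, dtype=float)
    degenerate: list[str] = []
    for c in matrix.chemicals:
        col = matrix.data[c].to_numpy(dtype=float)
        if not np.isfinite(col).any():
            continue
        s = on_scores(col)
        finite = col[np.isfinite(col)]
        if float(np.median(np.abs(finite - np.median(finite)))) == 0.0:
            degenerate.append(c)
        scores[c] = s

    flagged = scores >= cutoff
    if direction == "above":
        medians = matrix.data.median(axis=0, skipna=True)
        flagged &= matrix.data.gt(medians, axis=1).fillna(False)
    flagged &= ~matrix.bdl_mask.astype(bool)
    per_source: dict[str, list[str]] = {}
    keys: list[tuple[float, int, str]] = []
    for p in matrix.points:
        row = scores.loc[p]
        offending = row[flagged.loc[p].fillna(False)]
        if len(offending):
            per_source[p] = list(offending.sort_values(ascending=False).index)
            keys.append((float(offending.max()), len(offending), p))
    ordered = [p for _, _, p in sorted(keys, key=lambda t: (-t[0], -t[1], t[2]))]

    return OutlierReport(
        cutoff=cutoff,
        scores=scores,
        ordered_sources=ordered,
        per_source_chemicals=per_source,
        degenerate_chemicals=degenerate,
    )
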