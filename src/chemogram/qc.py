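"""Triplicate summarization, control normalization, and exclusion QC.

Each assay condition (PDO × drug × concentration level) is read in triplicate.
Per-well signals are normalized to the mean of the solvent-control wells —
pooled per plate by default, since absolute luminescence drifts between plates
— giving percent relative viability.  A condition whose standard error (SEM of
the normalized wells, in percent points) exceeds the threshold is excluded
outright; excluded levels make the whole dose-response profile for that
PDO × drug unavailable rather than being imputed.

The exclusion threshold defaults to 12 percent points and the comparison is
strict ("over" the threshold): a condition at exactly 12.0 is retained.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigError, DataError, NormalizationError
from .model import (
    ConcLevel,
    ConditionSummary,
    DoseResponseProfile,
    DrugPanel,
    LEVELS,
    WellReading,
)

__all__ = [
    "QcConfig",
    "summarize_condition",
    "summarize_screen",
    "apply_qc",
    "build_profiles",
]


@dataclass(frozen=True)
class QcConfig:
    """Exclusion-rule settings.

    se_threshold
        SEM cut-off in percent-of-control points; conditions strictly above it
        are excluded.  Default 12.
    control_scope
        ``"per_plate"`` normalizes each well to its own plate's controls
        (default); ``"per_screen"`` pools controls across all plates.
    """

    se_threshold: float = 12.0
    control_scope: str = "per_plate"

    def __post_init__(self) -> None:
        if self.se_threshold <= 0:
            raise ConfigError("se_threshold must be > 0")
        if self.control_scope not in ("per_plate", "per_screen"):
            raise ConfigError(
                f"control_scope must be per_plate or per_screen, "
                f"got {self.control_scope!r}"
            )


def _normalize(
    wells: Sequence[WellReading], control_mean: dict[str, float] | float
) -> np.ndarray:
    """Per-well percent-of-control values; negatives clamped to 0."""
    if isinstance(control_mean, dict):
        denom = np.array([control_mean[w.plate_id] for w in wells])
    else:
        denom = float(control_mean)
    values = 100.0 * np.array([w.luminescence for w in wells]) / denom
    return np.maximum(values, 0.0)


def _control_mean(controls: Sequence[WellReading], what: str) -> float:
    if not controls:
        raise NormalizationError(f"no control wells for {what}")
    mean = float(np.mean([w.luminescence for w in controls]))
    if mean <= 0:
        raise NormalizationError(f"control mean for {what} is not positive ({mean})")
    return mean


def summarize_condition(
    wells: Sequence[WellReading],
    controls: Sequence[WellReading],
    config: QcConfig | None = None,
) -> ConditionSummary:
    """Collapse one condition's wells against a shared control set.

    Mean relative viability is 100 × mean(condition) / mean(control); the
    standard error is the sample SD of the per-well normalized values divided
    by sqrt(n), in percent points (0 when n = 1).
    """
    config = config or QcConfig()
    if not wells:
        raise DataError("summarize_condition needs at least one condition well")
    keys = {(w.pdo_id, w.drug, w.conc_level) for w in wells}
    if len(keys) != 1:
        raise DataError(f"condition wells span multiple conditions: {sorted(keys)}")
    (pdo_id, drug, level), = keys
    if level == ConcLevel.control:
        raise DataError("control wells cannot form a drug condition")
    if any(not w.is_control for w in controls):
        raise DataError("the control set contains non-control wells")
    mean_ctrl = _control_mean(controls, f"{pdo_id}/{drug}/{level.value}")
    norm = _normalize(wells, mean_ctrl)
    mean = float(np.mean(norm))
    se = float(np.std(norm, ddof=1) / np.sqrt(len(norm))) if len(norm) > 1 else 0.0
    return ConditionSummary(
        pdo_id=pdo_id,
        drug=drug,
        conc_level=level,
        n_wells=len(wells),
        mean_rel_viability=mean,
        se_rel_viability=se,
        qc_pass=se <= config.se_threshold,
    )


def summarize_screen(
    wells: Iterable[WellReading], config: QcConfig | None = None
) -> list[ConditionSummary]:
    """Summarize every condition in a raw well table.

    Groups condition wells by PDO × drug × level and normalizes each well to
    the control mean in scope (its plate's controls, or the pooled screen
    controls).  Summaries come out in first-appearance order.
    """
    config = config or QcConfig()
    wells = list(wells)
    controls = [w for w in wells if w.is_control]
    conditions: dict[tuple[str, str, ConcLevel], list[WellReading]] = defaultdict(list)
    for w in wells:
        if not w.is_control:
            conditions[(w.pdo_id, w.drug, w.conc_level)].append(w)
    if not conditions:
        raise DataError("no condition wells in input")

    if config.control_scope == "per_screen":
        ctrl_mean: dict[str, float] | float = _control_mean(controls, "the screen")
    else:
        by_plate: dict[str, list[WellReading]] = defaultdict(list)
        for c in controls:
            by_plate[c.plate_id].append(c)
        needed = {w.plate_id for ws in conditions.values() for w in ws}
        ctrl_mean = {
            plate: _control_mean(by_plate.get(plate, []), f"plate {plate}")
            for plate in needed
        }

    summaries = []
    for (pdo_id, drug, level), cond_wells in conditions.items():
        norm = _normalize(cond_wells, ctrl_mean)
        mean = float(np.mean(norm))
        se = (
            float(np.std(norm, ddof=1) / np.sqrt(len(norm)))
            if len(norm) > 1
            else 0.0
        )
        summaries.append(
            ConditionSummary(
                pdo_id=pdo_id,
                drug=drug,
                conc_level=level,
                n_wells=len(cond_wells),
                mean_rel_viability=mean,
                se_rel_viability=se,
                qc_pass=se <= config.se_threshold,
            )
        )
    return summaries


def apply_qc(
    summaries: Iterable[ConditionSummary], config: QcConfig | None = None
) -> tuple[list[ConditionSummary], list[ConditionSummary]]:
    """Partition summaries into (retained, excluded) by the strict SE rule.

    A summary is excluded iff its standard error strictly exceeds the
    threshold; the partition depends on nothing else.
    """
    config = config or QcConfig()
    retained, excluded = [], []
    for s in summaries:
        (excluded if s.se_rel_viability > config.se_threshold else retained).append(s)
    return retained, excluded


def build_profiles(
    summaries: Iterable[ConditionSummary],
    panel: DrugPanel | None = None,
) -> tuple[list[DoseResponseProfile], list[tuple[str, str]]]:
    """Assemble complete (low, medium, high) profiles from retained summaries.

    Returns ``(profiles, missing_pairs)``: a PDO × drug pair yields a profile
    only when all three levels survived QC, and is otherwise recorded missing.
    Duplicate summaries for one PDO × drug × level are an error.  When a panel
    is given, drug names are resolved to the panel's spelling and unknown
    drugs are rejected.
    """
    grouped: dict[tuple[str, str], dict[ConcLevel, ConditionSummary]] = defaultdict(
        dict
    )
    for s in summaries:
        drug = s.drug
        if panel is not None:
            if drug not in panel:
                raise DataError(f"drug {drug!r} is not in the panel")
            drug = panel.resolve(drug)
        key = (s.pdo_id, drug)
        if s.conc_level in grouped[key]:
            raise DataError(
                f"duplicate summary for {s.pdo_id}/{drug}/{s.conc_level.value}"
            )
        grouped[key][s.conc_level] = s

    profiles: list[DoseResponseProfile] = []
    missing: list[tuple[str, str]] = []
    for (pdo_id, drug), by_level in grouped.items():
        if all(level in by_level for level in LEVELS):
            profiles.append(
                DoseResponseProfile(
                    pdo_id=pdo_id,
                    drug=drug,
                    viability=tuple(
                        by_level[level].mean_rel_viability for level in LEVELS
                    ),
                )
            )
        else:
            missing.append((pdo_id, drug))
    return profiles, missing
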