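"""End-to-end stage chain: raw wells → QC → profiles → score matrix."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .model import ConditionSummary, DrugPanel, ScoreMatrix, WellReading
from .qc import QcConfig, apply_qc, build_profiles, summarize_screen
from .scoring import ScoringConfig, score_cohort

__all__ = ["ChemogramRun", "score_wells"]


@dataclass(frozen=True)
class ChemogramRun:
    """Everything a scoring run produced, including its QC fallout."""

    matrix: ScoreMatrix
    excluded: list[ConditionSummary]
    missing_pairs: list[tuple[str, str]]


def score_wells(
    wells: Iterable[WellReading],
    panel: DrugPanel,
    qc_config: QcConfig | None = None,
    scoring_config: ScoringConfig | None = None,
) -> ChemogramRun:
    """Run the full chemogram pipeline on a raw well table.

    Summarizes triplicates against solvent controls, applies the SEM exclusion
    rule, assembles complete dose-response profiles, and scores every
    available PDO × drug pair against the cohort average.
    """
    qc_config = qc_config or QcConfig()
    scoring_config = scoring_config or ScoringConfig()
    summaries = summarize_screen(wells, qc_config)
    retained, excluded = apply_qc(summaries, qc_config)
    profiles, missing = build_profiles(retained, panel)
    matrix = score_cohort(
        profiles, scoring_config, panel=panel, missing_pairs=missing
    )
    return ChemogramRun(matrix=matrix, excluded=excluded, missing_pairs=missing)
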