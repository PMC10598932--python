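"""PDO-vs-patient concordance: does the dish predict the clinic?

Each matched record pairs a patient's best clinical response to a drug with
their PDO's chemogram call for the same drug.  The PDO call is *sensitive*
when the final score strictly exceeds the hit threshold.  The clinical call
defaults to the clinical-benefit reading: *responder* = partial response or
stable disease, *non-responder* = progressive disease (a strict mode counts
only partial responses as response).  The 2×2 table then yields the four
standard diagnostic metrics — sensitivity, specificity, PPV, NPV — as
percentages, with zero-denominator metrics flagged undefined rather than
silently zeroed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import ConfigError, DataError
from .model import ClinicalRecord, Response, ScoreMatrix
from .scoring import ScoringConfig

__all__ = [
    "ConcordanceResult",
    "classify_pairs",
    "concordance",
]

_RESPONDER_SETS = {
    "benefit": {Response.PR, Response.SD},
    "strict": {Response.PR},
}


@dataclass(frozen=True)
class ConcordanceResult:
    """2×2 PDO-call vs clinical-response table with diagnostic metrics.

    Counts: tp = sensitive ∧ responder, fn = non-sensitive ∧ responder,
    fp = sensitive ∧ non-responder, tn = non-sensitive ∧ non-responder.
    Metrics are percentages, ``None`` when their denominator is zero; the
    ``undefined`` tuple names any such metric.
    """

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise DataError("contingency counts must be >= 0")

    @property
    def n_pairs(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def n_concordant(self) -> int:
        return self.tp + self.tn

    @staticmethod
    def _ratio(num: int, denom: int) -> float | None:
        return None if denom == 0 else 100.0 * num / denom

    @property
    def sensitivity(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float | None:
        return self._ratio(self.tn, self.tn + self.fn)

    @property
    def undefined(self) -> tuple[str, ...]:
        return tuple(
            name
            for name in ("sensitivity", "specificity", "ppv", "npv")
            if getattr(self, name) is None
        )

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fn": self.fn,
            "fp": self.fp,
            "tn": self.tn,
            "n_pairs": self.n_pairs,
            "n_concordant": self.n_concordant,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
        }


def classify_pairs(
    matrix: ScoreMatrix,
    records: Iterable[ClinicalRecord],
    config: ScoringConfig | None = None,
    responder_def: str = "benefit",
) -> list[tuple[bool, bool]]:
    """Map clinical records to (pdo_sensitive, clinical_responder) pairs.

    The PDO call uses the final score of the record's PDO × drug against the
    configured threshold (strict >).  Records whose score is missing from the
    matrix are skipped with a warning.
    """
    config = config or ScoringConfig()
    if responder_def not in _RESPONDER_SETS:
        raise ConfigError(
            f"responder_def must be one of {sorted(_RESPONDER_SETS)}, "
            f"got {responder_def!r}"
        )
    responder_set = _RESPONDER_SETS[responder_def]
    pairs: list[tuple[bool, bool]] = []
    for rec in records:
        if (
            rec.pdo_id not in matrix.final_score.index
            or rec.drug_received not in matrix.final_score.columns
            or pd.isna(matrix.final_score.at[rec.pdo_id, rec.drug_received])
        ):
            warnings.warn(
                f"patient {rec.patient_id}: no score for "
                f"{rec.pdo_id} × {rec.drug_received}; record skipped",
                stacklevel=2,
            )
            continue
        score = float(matrix.final_score.at[rec.pdo_id, rec.drug_received])
        pairs.append((score > config.hit_threshold, rec.best_response in responder_set))
    return pairs


def concordance(pairs: Sequence[tuple[bool, bool]]) -> ConcordanceResult:
    """Tally (pdo_sensitive, responder) pairs into a :class:`ConcordanceResult`."""
    pairs = list(pairs)
    if not pairs:
        raise DataError("no classified pairs to tally")
    tp = sum(1 for s, r in pairs if s and r)
    fn = sum(1 for s, r in pairs if not s and r)
    fp = sum(1 for s, r in pairs if s and not r)
    tn = sum(1 for s, r in pairs if not s and not r)
    return ConcordanceResult(tp=tp, fn=fn, fp=fp, tn=tn)
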