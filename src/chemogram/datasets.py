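"""Small worked datasets for documentation and validation."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import ClinicalRecord, Response, ScoreMatrix

__all__ = ["synthetic_concordance_example"]

# (pdo, drug, auc_score, sensitivity_score, best_response)
_EXAMPLE_ROWS = [
    ("CGX0001", "Oxaliplatin", 2.10, 0.50, Response.PR),
    ("CGX0002", "5FU", 1.75, 0.45, Response.SD),
    ("CGX0003", "SN-38", 2.50, 0.60, Response.PR),
    ("CGX0004", "Oxaliplatin", 1.20, 0.30, Response.SD),
    ("CGX0005", "5FU", 2.05, 0.35, Response.PD),
    ("CGX0006", "SN-38", 0.95, 0.25, Response.PD),
    ("CGX0007", "Oxaliplatin", 0.70, 0.20, Response.PD),
    ("CGX0008", "5FU", 1.45, 0.25, Response.PD),
]


def synthetic_concordance_example() -> tuple[ScoreMatrix, list[ClinicalRecord]]:
    """Synthetic stand-in for an 8-patient PDO/clinic comparison cohort.

    The study design it mirrors — eight patients who received a panel drug
    after their PDO was chemogrammed, sorted into sensitive/non-sensitive by
    the 1.9 hit threshold and responder/non-responder by clinical benefit
    (PR or SD vs PD) — yields the 2×2 pattern (3 S∧R, 1 NS∧R, 1 S∧NR,
    3 NS∧NR).  The individual scores here are invented placeholders (the real
    per-pair values are not published); only the calls they induce carry
    meaning.  Metrics must be *computed* from this input, never assumed.
    """
    pdos = [r[0] for r in _EXAMPLE_ROWS]
    drugs = list(dict.fromkeys(r[1] for r in _EXAMPLE_ROWS))
    auc = pd.DataFrame(np.nan, index=pdos, columns=drugs)
    sens = pd.DataFrame(np.nan, index=pdos, columns=drugs)
    records = []
    for pdo, drug, a, s, response in _EXAMPLE_ROWS:
        auc.at[pdo, drug] = a
        sens.at[pdo, drug] = s
        records.append(
            ClinicalRecord(
                patient_id=f"PT-{pdo}",
                pdo_id=pdo,
                drug_received=drug,
                best_response=response,
            )
        )
    final = auc + sens
    hit = (final > 1.9).astype("boolean").mask(final.isna())
    matrix = ScoreMatrix(
        auc_score=auc,
        sensitivity_score=sens,
        final_score=final,
        hit=hit,
        threshold=1.9,
    )
    return matrix, records
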