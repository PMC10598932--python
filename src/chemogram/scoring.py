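"""The chemogram two-part score: AUC score + sensitivity score.

For every PDO × drug pair with a complete QC-passing dose-response profile
(relative viability at three increasing concentrations):

* **normalized AUC** — trapezoidal area under the viability curve divided by
  the full-response rectangle (100% viability across the whole x-range), a
  fraction in [0, 1] for sub-100% curves; 1 means no drug effect, 0 complete
  kill.
* **AUC score** — the cohort-average normalized AUC for that drug divided by
  the PDO's own normalized AUC.  A PDO more sensitive than the cohort average
  scores above 1.  The PDO of interest is part of the cohort average (it was
  one of the lines the reference was built from); a leave-one-out option is
  available for scoring prospective lines against a frozen reference.
* **sensitivity score** — 1 − normalized AUC, the area *over* the curve as a
  fraction of the total area: the drug's absolute effect irrespective of the
  cohort.
* **final score** — AUC score + sensitivity score.  A drug is a *hit* for a
  PDO when the final score strictly exceeds the threshold (default 1.9, the
  third quartile of the pooled study scores; the same quartile can be
  re-derived from any score matrix with :func:`hit_threshold_from_cohort`).

The x-axis defaults to the concentration *index* (0, 1, 2).  Panel dose
triples are uniformly spaced in log10 molarity, so index spacing differs from
log-molar spacing only by a per-drug constant that cancels in both the AUC
ratio and the normalized sensitivity score; the ``log10M`` spacing mode is
provided and gives identical scores on any uniformly spaced panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, ScoringError
from .model import DoseResponseProfile, DrugPanel, ScoreMatrix

__all__ = [
    "ScoringConfig",
    "CohortReference",
    "ChemogramScore",
    "normalized_auc",
    "build_reference",
    "auc_score",
    "sensitivity_score",
    "final_score",
    "score_cohort",
    "hit_threshold_from_cohort",
]


@dataclass(frozen=True)
class ScoringConfig:
    """Scoring knobs.

    hit_threshold
        Final-score cut-off; a pair is a hit when its score is strictly above
        it.  Default 1.9.
    threshold_mode
        ``"fixed"`` uses ``hit_threshold`` as-is (default, so a single new PDO
        can be scored against a stored reference); ``"cohort_q3"`` re-derives
        the threshold as the third quartile of the pooled score matrix.
    auc_floor_fraction
        Lower cap on the PDO's normalized AUC before the ratio, keeping the
        AUC score finite for total-kill profiles.  Default 0.01.
    spacing
        ``"index"`` (0, 1, 2) or ``"log10M"`` (the panel's dose triple).
    leave_one_out
        Exclude the scored PDO from the cohort average.  Off by default.
    full_scale
        The viability value meaning "no drug effect".  100 for the pipeline's
        percent-of-control convention; set to 1 for data expressed as
        fractions — all scores are invariant to that choice of units.
    """

    hit_threshold: float = 1.9
    threshold_mode: str = "fixed"
    auc_floor_fraction: float = 0.01
    spacing: str = "index"
    leave_one_out: bool = False
    full_scale: float = 100.0

    def __post_init__(self) -> None:
        if self.hit_threshold <= 0:
            raise ConfigError("hit_threshold must be > 0")
        if not 0 < self.auc_floor_fraction <= 0.1:
            raise ConfigError("auc_floor_fraction must be in (0, 0.1]")
        if self.threshold_mode not in ("fixed", "cohort_q3"):
            raise ConfigError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.spacing not in ("index", "log10M"):
            raise ConfigError(f"unknown spacing {self.spacing!r}")
        if self.full_scale <= 0:
            raise ConfigError("full_scale must be > 0")


@dataclass(frozen=True)
class ChemogramScore:
    pdo_id: str
    drug: str
    auc_score: float
    sensitivity_score: float
    final_score: float
    hit: bool

    def __post_init__(self) -> None:
        if self.final_score != self.auc_score + self.sensitivity_score:
            raise DataError("final score must equal AUC score + sensitivity score")


@dataclass(frozen=True)
class CohortReference:
    """Per-drug cohort-average dose-response profiles.

    ``mean_profile`` maps drug → mean viability triple over the reference PDOs
    with an available profile for that drug; ``n_pdos`` carries the count
    behind each average (at least 2 by construction).  ``members`` lists the
    contributing PDO ids per drug so leave-one-out averages can be formed.
    """

    mean_profile: dict[str, np.ndarray]
    n_pdos: dict[str, int]
    members: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __contains__(self, drug: str) -> bool:
        return drug in self.mean_profile


def _x_axis(
    config: ScoringConfig, drug: str, panel: DrugPanel | None
) -> np.ndarray:
    if config.spacing == "index":
        return np.array([0.0, 1.0, 2.0])
    if panel is None:
        raise ScoringError("log10M spacing requires a drug panel")
    return np.array(panel[drug].conc_log10M)


def normalized_auc(
    viability: Sequence[float] | DoseResponseProfile,
    x: Sequence[float] | None = None,
    full_scale: float = 100.0,
) -> float:
    """Trapezoidal AUC of a viability curve over the full-response rectangle.

    ``viability`` is in percent of control; the result is the fraction of the
    ``full_scale`` × x-range rectangle under the curve (may exceed 1 if the
    drug stimulates growth).  ``x`` defaults to the concentration index
    (0, 1, 2); ``full_scale`` defaults to 100 (percent convention).
    """
    if isinstance(viability, DoseResponseProfile):
        viability = viability.viability
    v = np.asarray(viability, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise DataError("normalized_auc needs at least two curve points")
    if np.any(v < 0):
        raise DataError("viabilities must be >= 0")
    xs = np.arange(len(v), dtype=float) if x is None else np.asarray(x, dtype=float)
    if len(xs) != len(v):
        raise DataError("x and viability lengths differ")
    if np.any(np.diff(xs) <= 0):
        raise DataError("x must be strictly increasing")
    return float(np.trapezoid(v, xs) / (full_scale * (xs[-1] - xs[0])))


def build_reference(
    profiles: Iterable[DoseResponseProfile],
    min_pdos: int = 2,
) -> CohortReference:
    """Average the available profiles per drug into a cohort reference.

    Drugs with fewer than ``min_pdos`` available profiles are dropped with a
    warning (they cannot anchor a relative score).
    """
    by_drug: dict[str, list[DoseResponseProfile]] = {}
    for p in profiles:
        by_drug.setdefault(p.drug, []).append(p)
    mean_profile: dict[str, np.ndarray] = {}
    n_pdos: dict[str, int] = {}
    members: dict[str, tuple[str, ...]] = {}
    for drug, plist in by_drug.items():
        plist = sorted(plist, key=lambda p: p.pdo_id)  # input-order independent
        pdos = [p.pdo_id for p in plist]
        if len(set(pdos)) != len(pdos):
            raise DataError(f"duplicate profiles for drug {drug!r}")
        if len(plist) < min_pdos:
            warnings.warn(
                f"drug {drug!r}: only {len(plist)} available profile(s); "
                "cohort average not formed",
                stacklevel=2,
            )
            continue
        mean_profile[drug] = np.mean([p.viability for p in plist], axis=0)
        n_pdos[drug] = len(plist)
        members[drug] = tuple(pdos)
    return CohortReference(mean_profile=mean_profile, n_pdos=n_pdos, members=members)


def auc_score(
    profile: DoseResponseProfile,
    reference: CohortReference,
    config: ScoringConfig | None = None,
    panel: DrugPanel | None = None,
) -> float:
    """Cohort-average AUC over the PDO's AUC (floored), for the profile's drug."""
    config = config or ScoringConfig()
    if profile.drug not in reference:
        raise ScoringError(f"drug {profile.drug!r} absent from the cohort reference")
    xs = _x_axis(config, profile.drug, panel)
    ref_profile = reference.mean_profile[profile.drug]
    if config.leave_one_out and profile.pdo_id in reference.members.get(
        profile.drug, ()
    ):
        n = reference.n_pdos[profile.drug]
        if n < 2:
            raise ScoringError(
                f"drug {profile.drug!r}: cannot leave {profile.pdo_id} out of a "
                f"reference built from {n} PDO(s)"
            )
        ref_profile = (ref_profile * n - np.asarray(profile.viability)) / (n - 1)
        ref_profile = np.maximum(ref_profile, 0.0)
    ref_auc = normalized_auc(ref_profile, xs, config.full_scale)
    pdo_auc = normalized_auc(profile.viability, xs, config.full_scale)
    return ref_auc / max(pdo_auc, config.auc_floor_fraction)


def sensitivity_score(
    profile: DoseResponseProfile,
    config: ScoringConfig | None = None,
    panel: DrugPanel | None = None,
) -> float:
    """Area over the curve as a fraction of the total area: 1 − normalized AUC."""
    config = config or ScoringConfig()
    xs = _x_axis(config, profile.drug, panel)
    return 1.0 - normalized_auc(profile.viability, xs, config.full_scale)


def final_score(
    profile: DoseResponseProfile,
    reference: CohortReference,
    config: ScoringConfig | None = None,
    panel: DrugPanel | None = None,
) -> ChemogramScore:
    """AUC score + sensitivity score, with the strict-``>`` hit call."""
    config = config or ScoringConfig()
    a = auc_score(profile, reference, config, panel)
    s = sensitivity_score(profile, config, panel)
    total = a + s
    return ChemogramScore(
        pdo_id=profile.pdo_id,
        drug=profile.drug,
        auc_score=a,
        sensitivity_score=s,
        final_score=total,
        hit=total > config.hit_threshold,
    )


def hit_threshold_from_cohort(matrix: ScoreMatrix | Sequence[float]) -> float:
    """Third quartile of all present final scores (linear-interpolation rule).

    This is how the default 1.9 threshold is derived from a pilot cohort's
    pooled score distribution.  Requires at least 4 present scores.
    """
    if isinstance(matrix, ScoreMatrix):
        values = matrix.final_score.to_numpy(float).ravel()
    else:
        values = np.asarray(matrix, dtype=float).ravel()
    values = values[~np.isnan(values)]
    if len(values) < 4:
        raise DataError(
            f"need at least 4 present scores to derive a quartile threshold, "
            f"got {len(values)}"
        )
    return float(np.quantile(values, 0.75))  # numpy default = linear interpolation


def score_cohort(
    profiles: Iterable[DoseResponseProfile],
    config: ScoringConfig | None = None,
    panel: DrugPanel | None = None,
    missing_pairs: Iterable[tuple[str, str]] = (),
) -> ScoreMatrix:
    """Score every available PDO × drug pair against the cohort built from them.

    The cohort reference is built once from the given profiles; pairs without
    an available profile (including ``missing_pairs`` from QC) stay missing.
    Drugs with fewer than 2 available profiles are left all-missing with a
    warning.  Output rows/columns are sorted (panel order for drugs when a
    panel is given), so the matrix is invariant to input order.
    """
    config = config or ScoringConfig()
    profiles = list(profiles)
    missing_pairs = list(missing_pairs)

    pdo_ids = sorted(
        {p.pdo_id for p in profiles} | {pdo for pdo, _ in missing_pairs}
    )
    seen_drugs = {p.drug for p in profiles} | {drug for _, drug in missing_pairs}
    if panel is not None:
        unknown = [d for d in seen_drugs if d not in panel]
        if unknown:
            raise DataError(f"drugs not in panel: {sorted(unknown)}")
        drugs = [name for name in panel.names if name in seen_drugs]
    else:
        drugs = sorted(seen_drugs)

    reference = build_reference(profiles)
    auc = pd.DataFrame(np.nan, index=pdo_ids, columns=drugs)
    sens = pd.DataFrame(np.nan, index=pdo_ids, columns=drugs)
    for p in profiles:
        if p.drug not in reference:
            continue
        auc.at[p.pdo_id, p.drug] = auc_score(p, reference, config, panel)
        sens.at[p.pdo_id, p.drug] = sensitivity_score(p, config, panel)
    final = auc + sens

    if config.threshold_mode == "cohort_q3":
        threshold = hit_threshold_from_cohort(final.to_numpy(float).ravel())
    else:
        threshold = config.hit_threshold
    hit = (final > threshold).astype("boolean").mask(final.isna())
    return ScoreMatrix(
        auc_score=auc,
        sensitivity_score=sens,
        final_score=final,
        hit=hit,
        threshold=threshold,
    )
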