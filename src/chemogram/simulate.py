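"""Synthetic 96-well organoid screens with known ground truth.

The generator emulates the statistical structure of a real chemogram run:
each simulated PDO line carries a latent log10 IC50 per drug (drawn around the
drug's medium panel concentration, which the assay was calibrated to bracket),
viability follows a three-parameter log-logistic (Hill) curve, every
PDO × drug × concentration condition is plated in triplicate in the 60 center
wells of sequential 96-well plates with solvent-control wells on each plate,
and the plate reader adds multiplicative noise.  Optional degradations mirror
real screens: randomly missing PDO × drug pairs ("not tested"), deliberately
noisy triplicates that the SEM-based QC rule must catch, and "spiked"
hypersensitive pairs (a negative IC50 shift) for parameter-recovery tests.

Everything is a pure function of (config, seed): the same config yields
bit-identical well tables.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .model import (
    CONTROL,
    ClinicalRecord,
    ConcLevel,
    DrugPanel,
    LEVELS,
    Response,
    WellReading,
    load_default_panel,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "expected_viability",
    "generate_screen",
    "generate_clinical",
]

#: The 60 assay wells (rows B-G × columns 2-11), row-major.
CENTER_WELLS: tuple[str, ...] = tuple(
    f"{row}{col}" for row in "BCDEFG" for col in range(2, 12)
)


@dataclass(frozen=True)
class SimConfig:
    """Screen-generator settings; ``seed`` is mandatory for reproducibility.

    Defaults describe a clean, realistic run: triplicate wells, 6 solvent
    controls per plate at a 10,000 RLU control scale, 8% well-level CV,
    Hill slope 1, 10% residual viability at saturation, and per-drug latent
    IC50s centred on the panel's medium dose with 0.5 log10-unit inter-PDO
    spread.
    """

    n_pdos: int
    seed: int
    panel: DrugPanel = field(default_factory=load_default_panel)
    log_ic50_mean: Mapping[str, float] | None = None  # default: medium panel dose
    log_ic50_sd: float = 0.5
    hill_slope: float = 1.0
    e_inf: float = 0.1
    well_cv: float = 0.08
    n_replicates: int = 3
    n_controls_per_plate: int = 6
    bad_triplicate_rate: float = 0.0
    bad_sem_points: float = 30.0
    missing_pair_rate: float = 0.0
    spiked_pairs: tuple[tuple[str, str, float], ...] = ()
    noise: str = "gaussian"  # or "lognormal"
    control_scale: float = 10000.0
    pdo_prefix: str = "SIM"

    def __post_init__(self) -> None:
        if self.n_pdos < 1:
            raise ConfigError("n_pdos must be >= 1")
        if self.seed is None:
            raise ConfigError("a seed is mandatory")
        for name in ("bad_triplicate_rate", "missing_pair_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate < 1.0:
                raise ConfigError(f"{name} must be in [0, 1), got {rate}")
        if not 0.0 <= self.e_inf < 1.0:
            raise ConfigError("e_inf must be in [0, 1)")
        if self.hill_slope <= 0:
            raise ConfigError("hill_slope must be > 0")
        if self.well_cv < 0:
            raise ConfigError("well_cv must be >= 0")
        if self.noise not in ("gaussian", "lognormal"):
            raise ConfigError(f"unknown noise model {self.noise!r}")
        if self.n_replicates < 1 or self.n_controls_per_plate < 1:
            raise ConfigError("n_replicates and n_controls_per_plate must be >= 1")
        if self.n_controls_per_plate + self.n_replicates > len(CENTER_WELLS):
            raise ConfigError("controls + one triplicate must fit in 60 center wells")
        if self.bad_sem_points <= 0:
            raise ConfigError("bad_sem_points must be > 0")
        if self.control_scale <= 0:
            raise ConfigError("control_scale must be > 0")

    @property
    def pdo_ids(self) -> list[str]:
        """The PDO identifiers this config will generate, in order."""
        return [f"{self.pdo_prefix}{i:04d}" for i in range(1, self.n_pdos + 1)]

    def digest(self) -> str:
        """Stable hash of the configuration, for run manifests."""
        payload = {
            k: v
            for k, v in asdict(self).items()
            if k != "panel"
        }
        payload["panel"] = [
            (e.name, e.conc_log10M) for e in self.panel
        ]
        payload["log_ic50_mean"] = (
            None if self.log_ic50_mean is None else dict(self.log_ic50_mean)
        )
        return hashlib.sha256(repr(sorted(payload.items())).encode()).hexdigest()


@dataclass(frozen=True)
class SimTruth:
    """Ground truth behind a generated screen.

    ``pairs`` has one row per PDO × drug with the latent curve parameters,
    the noise-free expected viability triple, and the spiked/missing flags;
    ``degraded`` lists the deliberately noisy triplicates with the SEM (in
    percent points) injected into them.
    """

    pairs: pd.DataFrame
    degraded: pd.DataFrame


def expected_viability(
    conc_log10M: Sequence[float],
    log_ic50: float,
    hill: float = 1.0,
    e_inf: float = 0.0,
) -> np.ndarray:
    """Noise-free percent viability of a log-logistic dose-response curve.

    ``v(c) = 100 · (e_inf + (1 − e_inf) / (1 + 10^(hill·(c − log_ic50))))``
    — 100% far below the IC50, ``100·e_inf`` far above, 50% at the IC50 when
    ``e_inf`` is 0.
    """
    if hill <= 0:
        raise ConfigError("hill must be > 0")
    c = np.asarray(conc_log10M, dtype=float)
    return 100.0 * (e_inf + (1.0 - e_inf) / (1.0 + 10.0 ** (hill * (c - log_ic50))))


def _noise_factor(rng: np.random.Generator, cv: float, n: int, model: str) -> np.ndarray:
    """Multiplicative noise factors with mean 1 and coefficient of variation cv."""
    if cv == 0.0:
        return np.ones(n)
    if model == "gaussian":
        return 1.0 + np.clip(rng.normal(0.0, cv, size=n), -1.0, None)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)


def generate_screen(config: SimConfig) -> tuple[list[WellReading], SimTruth]:
    """Generate the raw well table and its ground truth for one screen.

    Per PDO, conditions are packed triplicate-by-triplicate into the 60
    center wells of sequential plates (``<pdo>-P<k>``), each plate carrying
    its own solvent controls.  Condition wells read
    ``plate_scale × expected_viability/100 × noise``; degraded triplicates
    additionally receive a fixed ±spread offset pattern calibrated to inject
    a known SEM (``bad_sem_points``), recorded in the truth table.  Spiked
    pairs are never made missing.
    """
    rng = np.random.default_rng(config.seed)
    panel = config.panel
    pdo_ids = config.pdo_ids
    drugs = panel.names

    spike_shift: dict[tuple[str, str], float] = {}
    for pdo, drug, shift in config.spiked_pairs:
        if pdo not in pdo_ids:
            raise ConfigError(f"spiked pair references unknown PDO {pdo!r}")
        if drug not in panel:
            raise ConfigError(f"spiked pair references unknown drug {drug!r}")
        spike_shift[(pdo, panel.resolve(drug))] = float(shift)

    ic50_mean = {
        drug: (
            config.log_ic50_mean[drug]
            if config.log_ic50_mean is not None
            else panel[drug].conc_log10M[1]
        )
        for drug in drugs
    }

    # Latent parameters, missingness, and degraded-triplicate flags are drawn
    # in a fixed (pdo, drug, level) order so the whole screen is seed-stable.
    pair_rows = []
    degraded_rows = []
    conditions: dict[str, list[tuple[str, ConcLevel, np.ndarray, bool]]] = {
        pdo: [] for pdo in pdo_ids
    }
    for pdo in pdo_ids:
        for drug in drugs:
            shift = spike_shift.get((pdo, drug), 0.0)
            log_ic50 = rng.normal(ic50_mean[drug], config.log_ic50_sd) + shift
            missing = (
                (pdo, drug) not in spike_shift
                and rng.random() < config.missing_pair_rate
            )
            ev = expected_viability(
                panel[drug].conc_log10M, log_ic50, config.hill_slope, config.e_inf
            )
            pair_rows.append(
                {
                    "pdo": pdo,
                    "drug": drug,
                    "log_ic50": log_ic50,
                    "hill": config.hill_slope,
                    "e_inf": config.e_inf,
                    "ev_low": ev[0],
                    "ev_medium": ev[1],
                    "ev_high": ev[2],
                    "spiked": (pdo, drug) in spike_shift,
                    "missing": missing,
                }
            )
            if missing:
                continue
            for level, v in zip(LEVELS, ev):
                bad = rng.random() < config.bad_triplicate_rate
                if bad:
                    degraded_rows.append(
                        {
                            "pdo": pdo,
                            "drug": drug,
                            "level": level.value,
                            "injected_sem": config.bad_sem_points,
                        }
                    )
                conditions[pdo].append((drug, level, float(v), bad))

    capacity = (len(CENTER_WELLS) - config.n_controls_per_plate) // config.n_replicates
    # Offset magnitude whose (-1, 0, +1)-pattern sample SD equals bad_sem_points·√3,
    # i.e. a deterministic injected SEM of bad_sem_points (for triplicates).
    spread_points = config.bad_sem_points * np.sqrt(3.0)

    wells: list[WellReading] = []
    for pdo in pdo_ids:
        conds = conditions[pdo]
        n_plates = max(1, -(-len(conds) // capacity))
        for k in range(n_plates):
            plate_id = f"{pdo}-P{k + 1}"
            chunk = conds[k * capacity : (k + 1) * capacity]
            positions = iter(CENTER_WELLS)
            scale = config.control_scale
            factors = _noise_factor(
                rng, config.well_cv, config.n_controls_per_plate, config.noise
            )
            for f in factors:
                wells.append(
                    WellReading(
                        plate_id=plate_id,
                        well=next(positions),
                        pdo_id=pdo,
                        drug=CONTROL,
                        conc_level=ConcLevel.control,
                        luminescence=max(scale * f, 0.0),
                    )
                )
            for drug, level, v, bad in chunk:
                factors = _noise_factor(
                    rng, config.well_cv, config.n_replicates, config.noise
                )
                lum = scale * (v / 100.0) * factors
                if bad:
                    pattern = rng.permutation(
                        np.linspace(-1.0, 1.0, config.n_replicates)
                    )
                    lum = lum + scale * (spread_points / 100.0) * pattern
                for f_lum in lum:
                    wells.append(
                        WellReading(
                            plate_id=plate_id,
                            well=next(positions),
                            pdo_id=pdo,
                            drug=drug,
                            conc_level=level,
                            luminescence=max(float(f_lum), 0.0),
                        )
                    )
    truth = SimTruth(
        pairs=pd.DataFrame(pair_rows),
        degraded=pd.DataFrame(
            degraded_rows, columns=["pdo", "drug", "level", "injected_sem"]
        ),
    )
    return wells, truth


def generate_clinical(
    truth: SimTruth,
    p_responder_spiked: float = 0.9,
    p_responder_unspiked: float = 0.2,
    seed: int = 0,
    pdo_ids: Sequence[str] | None = None,
) -> list[ClinicalRecord]:
    """Sample matched clinical outcomes consistent with the ground truth.

    One record per selected PDO: the drug is the PDO's first spiked pair when
    it has one (the simulated "treatment received"), otherwise a random
    non-missing drug.  The probability that the patient shows clinical
    benefit (PR or SD, split evenly) is ``p_responder_spiked`` for spiked
    pairs and ``p_responder_unspiked`` otherwise; the remainder progress (PD).
    Deterministic under ``seed``.
    """
    for p in (p_responder_spiked, p_responder_unspiked):
        if not 0.0 <= p <= 1.0:
            raise ConfigError("responder probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    pairs = truth.pairs
    selected = list(pdo_ids) if pdo_ids is not None else list(
        dict.fromkeys(pairs["pdo"])
    )
    records: list[ClinicalRecord] = []
    for pdo in selected:
        sub = pairs[(pairs["pdo"] == pdo) & (~pairs["missing"])]
        if sub.empty:
            raise DataError(f"PDO {pdo!r} has no testable drug pair")
        spiked = sub[sub["spiked"]]
        if not spiked.empty:
            row = spiked.iloc[0]
            p_resp = p_responder_spiked
        else:
            row = sub.iloc[rng.integers(len(sub))]
            p_resp = p_responder_unspiked
        if rng.random() < p_resp:
            response = Response.PR if rng.random() < 0.5 else Response.SD
        else:
            response = Response.PD
        records.append(
            ClinicalRecord(
                patient_id=f"PT-{pdo}",
                pdo_id=pdo,
                drug_received=str(row["drug"]),
                best_response=response,
            )
        )
    return records
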