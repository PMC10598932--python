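"""Domain model for 96-well organoid drug screens.

The screen tests each patient-derived organoid (PDO) line against a panel of
drugs at three concentrations, in triplicate wells, with solvent-only control
wells on every plate.  ATP luminescence at day 8 is the viability readout.
This module holds the value types for that design — drugs and panels, raw well
readings, triplicate summaries, dose-response profiles, the PDO × drug score
matrix, and matched clinical records — plus readers and writers for the plain
CSV formats the pipeline exchanges.

The canonical raw format is long (one row per well); a plate-map (8 × 12 grid)
converter is provided as a convenience on top, since a full screen
(25 drugs × 3 concentrations × 3 replicates = 225 condition wells) spans
several plates and a grid per plate is how bench scientists record layouts.
"""

from __future__ import annotations

import csv
import math
import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ParseError

__all__ = [
    "CONTROL",
    "DrugClass",
    "Solvent",
    "ConcLevel",
    "LEVELS",
    "Response",
    "DrugEntry",
    "DrugPanel",
    "WellReading",
    "ConditionSummary",
    "DoseResponseProfile",
    "ScoreMatrix",
    "ClinicalRecord",
    "load_default_panel",
    "read_panel",
    "write_panel",
    "read_well_table",
    "write_well_table",
    "wells_from_platemap",
    "read_score_matrix",
    "write_score_matrix",
    "read_clinical_table",
    "write_clinical_table",
    "is_center_well",
]

#: Sentinel drug name for solvent-only control wells.
CONTROL = "CONTROL"


class DrugClass(str, Enum):
    chemotherapy = "chemotherapy"
    kinase_inhibitor = "kinase_inhibitor"
    epigenetic = "epigenetic"
    other = "other"


class Solvent(str, Enum):
    DMSO = "DMSO"
    PBS_tween = "PBS_tween"


class ConcLevel(str, Enum):
    low = "low"
    medium = "medium"
    high = "high"
    control = "control"


#: The three dose levels, in ascending concentration order.
LEVELS: tuple[ConcLevel, ConcLevel, ConcLevel] = (
    ConcLevel.low,
    ConcLevel.medium,
    ConcLevel.high,
)


class Response(str, Enum):
    """Best clinical response: partial response, stable disease, progression."""

    PR = "PR"
    SD = "SD"
    PD = "PD"


_WELL_RE = re.compile(r"^([A-H])([1-9]|1[0-2])$")


def _check_well(well: str) -> str:
    if not _WELL_RE.match(well):
        raise DataError(f"invalid well position {well!r} (expected A1-H12)")
    return well


def is_center_well(well: str) -> bool:
    """True for the 60 center wells (rows B-G, columns 2-11) of a 96-well plate.

    Edge wells evaporate faster and are conventionally left out of the assay;
    the pipeline warns about, but does not reject, readings from them.
    """
    m = _WELL_RE.match(well)
    if not m:
        raise DataError(f"invalid well position {well!r} (expected A1-H12)")
    row, col = m.group(1), int(m.group(2))
    return row in "BCDEFG" and 2 <= col <= 11


def canonical_drug_name(name: str) -> str:
    """Key used for case-insensitive, whitespace-tolerant drug matching."""
    return name.strip().lower()


@dataclass(frozen=True)
class DrugEntry:
    """One panel drug: class, solvent, and its (low, medium, high) log10 molar doses."""

    name: str
    drug_class: DrugClass
    conc_log10M: tuple[float, float, float]
    solvent: Solvent = Solvent.DMSO

    def __post_init__(self) -> None:
        if len(self.conc_log10M) != 3:
            raise DataError(f"{self.name}: exactly three concentrations required")
        lo, mid, hi = self.conc_log10M
        if not (lo < mid < hi):
            raise DataError(
                f"{self.name}: concentrations must be strictly increasing, "
                f"got {self.conc_log10M}"
            )
        if hi >= 0:
            raise DataError(
                f"{self.name}: concentrations must be sub-molar (log10 M < 0)"
            )


class DrugPanel:
    """An ordered collection of :class:`DrugEntry`, unique by name.

    Lookup is case-insensitive and ignores surrounding whitespace; the panel is
    the single source of truth for each drug's concentration axis.
    """

    def __init__(self, entries: Iterable[DrugEntry]):
        self._entries: dict[str, DrugEntry] = {}
        for e in entries:
            key = canonical_drug_name(e.name)
            if key in self._entries:
                raise DataError(f"duplicate drug in panel: {e.name!r}")
            self._entries[key] = e

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[DrugEntry]:
        return iter(self._entries.values())

    def __contains__(self, name: str) -> bool:
        return canonical_drug_name(name) in self._entries

    def __getitem__(self, name: str) -> DrugEntry:
        key = canonical_drug_name(name)
        if key not in self._entries:
            raise KeyError(name)
        return self._entries[key]

    @property
    def names(self) -> list[str]:
        return [e.name for e in self._entries.values()]

    def resolve(self, name: str) -> str:
        """Return the panel's canonical spelling for ``name``."""
        return self[name].name

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"DrugPanel({len(self)} drugs)"


@dataclass(frozen=True)
class WellReading:
    """Raw luminescence of a single well (relative light units)."""

    plate_id: str
    well: str
    pdo_id: str
    drug: str
    conc_level: ConcLevel
    luminescence: float

    def __post_init__(self) -> None:
        _check_well(self.well)
        if not math.isfinite(self.luminescence) or self.luminescence < 0:
            raise DataError(
                f"well {self.plate_id}/{self.well}: luminescence must be a "
                f"non-negative number, got {self.luminescence!r}"
            )
        is_ctrl_drug = self.drug == CONTROL
        is_ctrl_level = self.conc_level == ConcLevel.control
        if is_ctrl_drug != is_ctrl_level:
            raise DataError(
                f"well {self.plate_id}/{self.well}: drug {self.drug!r} and level "
                f"{self.conc_level.value!r} disagree on control status"
            )

    @property
    def is_control(self) -> bool:
        return self.conc_level == ConcLevel.control


@dataclass(frozen=True)
class ConditionSummary:
    """Triplicate summary for one PDO × drug × level, in percent of control.

    ``se_rel_viability`` is the standard error of the per-well normalized
    values (sample SD / sqrt(n)), in percent-of-control points; ``qc_pass``
    records whether it is within the exclusion threshold.
    """

    pdo_id: str
    drug: str
    conc_level: ConcLevel
    n_wells: int
    mean_rel_viability: float
    se_rel_viability: float
    qc_pass: bool

    def __post_init__(self) -> None:
        if self.n_wells < 1:
            raise DataError("a condition summary needs at least one well")
        if self.mean_rel_viability < 0:
            raise DataError("mean relative viability must be >= 0")


@dataclass(frozen=True)
class DoseResponseProfile:
    """Relative viability (% of control) of one PDO × drug at (low, medium, high)."""

    pdo_id: str
    drug: str
    viability: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.viability) != 3:
            raise DataError("a profile holds exactly three viability values")
        if any(v < 0 or not math.isfinite(v) for v in self.viability):
            raise DataError(
                f"{self.pdo_id}/{self.drug}: viabilities must be finite and >= 0"
            )


class ScoreMatrix:
    """PDO × drug chemogram scores with missing-allowed entries.

    Carries three aligned float grids (AUC score, sensitivity score, final
    score), a nullable-boolean hit grid, and the hit threshold used.  Missing
    entries (NaN / NA) mean the pair was not tested or failed QC.
    """

    def __init__(
        self,
        auc_score: pd.DataFrame,
        sensitivity_score: pd.DataFrame,
        final_score: pd.DataFrame,
        hit: pd.DataFrame,
        threshold: float = float("nan"),
    ):
        for df in (sensitivity_score, final_score, hit):
            if not (
                df.index.equals(auc_score.index)
                and df.columns.equals(auc_score.columns)
            ):
                raise DataError("score grids must share PDO index and drug columns")
        present = final_score.notna()
        if not present.equals(auc_score.notna()) or not present.equals(
            sensitivity_score.notna()
        ):
            raise DataError("component and final grids must share missingness")
        recomputed = auc_score + sensitivity_score
        if not np.allclose(
            final_score.to_numpy(float)[present.to_numpy()],
            recomputed.to_numpy(float)[present.to_numpy()],
            rtol=0.0,
            atol=1e-9,
        ):
            raise DataError("final score must equal AUC score + sensitivity score")
        self.auc_score = auc_score.astype(float)
        self.sensitivity_score = sensitivity_score.astype(float)
        self.final_score = final_score.astype(float)
        self.hit = hit.astype("boolean")
        self.threshold = float(threshold)

    @property
    def pdo_ids(self) -> list[str]:
        return list(self.final_score.index)

    @property
    def drugs(self) -> list[str]:
        return list(self.final_score.columns)

    @property
    def present(self) -> pd.DataFrame:
        return self.final_score.notna()

    def n_present(self) -> int:
        return int(self.present.to_numpy().sum())

    def score(self, pdo_id: str, drug: str) -> float:
        """Final score for a pair; NaN when missing."""
        return float(self.final_score.at[pdo_id, drug])

    def to_long(self) -> pd.DataFrame:
        """Long-format view: one row per PDO × drug, missing entries included."""
        rows = []
        for pdo in self.pdo_ids:
            for drug in self.drugs:
                hit = self.hit.at[pdo, drug]
                rows.append(
                    {
                        "pdo": pdo,
                        "drug": drug,
                        "auc_score": self.auc_score.at[pdo, drug],
                        "sensitivity_score": self.sensitivity_score.at[pdo, drug],
                        "final_score": self.final_score.at[pdo, drug],
                        "hit": bool(hit) if pd.notna(hit) else pd.NA,
                    }
                )
        return pd.DataFrame(rows)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScoreMatrix):
            return NotImplemented
        return (
            self.pdo_ids == other.pdo_ids
            and self.drugs == other.drugs
            and self.final_score.equals(other.final_score)
            and self.auc_score.equals(other.auc_score)
            and self.sensitivity_score.equals(other.sensitivity_score)
            and self.hit.equals(other.hit)
        )


@dataclass(frozen=True)
class ClinicalRecord:
    """A patient matched to their PDO, the panel drug received, and best response."""

    patient_id: str
    pdo_id: str
    drug_received: str
    best_response: Response


# ---------------------------------------------------------------------------
# Drug panel I/O


def _panel_from_frame(df: pd.DataFrame, source: str) -> DrugPanel:
    required = {"drug", "class", "log10M_low", "log10M_medium", "log10M_high"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{source}: missing panel columns {sorted(missing)}")
    entries = []
    for i, row in df.iterrows():
        try:
            entries.append(
                DrugEntry(
                    name=str(row["drug"]).strip(),
                    drug_class=DrugClass(str(row["class"]).strip()),
                    conc_log10M=(
                        float(row["log10M_low"]),
                        float(row["log10M_medium"]),
                        float(row["log10M_high"]),
                    ),
                    solvent=Solvent(str(row.get("solvent", "DMSO")).strip()),
                )
            )
        except (ValueError, DataError) as exc:
            raise ParseError(f"{source}, row {i + 2}: {exc}") from exc
    return DrugPanel(entries)


def read_panel(path) -> DrugPanel:
    """Read a drug panel CSV (drug, class, log10M_low/medium/high, solvent)."""
    return _panel_from_frame(pd.read_csv(path), str(path))


def write_panel(panel: DrugPanel, path) -> None:
    pd.DataFrame(
        [
            {
                "drug": e.name,
                "class": e.drug_class.value,
                "log10M_low": e.conc_log10M[0],
                "log10M_medium": e.conc_log10M[1],
                "log10M_high": e.conc_log10M[2],
                "solvent": e.solvent.value,
            }
            for e in panel
        ]
    ).to_csv(path, index=False)


def load_default_panel() -> DrugPanel:
    """The packaged 25-drug screening panel with its calibrated dose triples.

    Concentrations were calibrated on pilot organoid lines to bracket each
    drug's average IC50 while staying within the physiological range reached
    in patients; they are uniformly spaced in log10 molarity per drug.
    """
    with resources.files("chemogram.data").joinpath("drug_panel.csv").open() as fh:
        return _panel_from_frame(pd.read_csv(fh), "packaged drug_panel.csv")


# ---------------------------------------------------------------------------
# Raw well table I/O

_WELL_COLUMNS = ("plate", "well", "pdo", "drug", "level", "signal")


def read_well_table(path) -> list[WellReading]:
    """Read the long-format raw wells CSV (plate, well, pdo, drug, level, signal).

    Control rows are recognized case-insensitively (drug ``control`` with level
    ``control``).  Malformed rows raise :class:`ParseError` naming the row.
    """
    readings: list[WellReading] = []
    n_edge = 0
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not set(_WELL_COLUMNS) <= set(
            reader.fieldnames
        ):
            raise ParseError(
                f"{path}: expected header columns {list(_WELL_COLUMNS)}, "
                f"got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                drug = row["drug"].strip()
                level_raw = row["level"].strip().lower()
                try:
                    level = ConcLevel(level_raw)
                except ValueError:
                    raise DataError(f"unknown concentration level {row['level']!r}")
                if drug.lower() == CONTROL.lower():
                    drug = CONTROL
                try:
                    signal = float(row["signal"])
                except ValueError:
                    raise DataError(f"non-numeric signal {row['signal']!r}")
                reading = WellReading(
                    plate_id=row["plate"].strip(),
                    well=row["well"].strip().upper(),
                    pdo_id=row["pdo"].strip(),
                    drug=drug,
                    conc_level=level,
                    luminescence=signal,
                )
            except DataError as exc:
                raise ParseError(f"{path}, row {lineno}: {exc}") from exc
            if not is_center_well(reading.well):
                n_edge += 1
            readings.append(reading)
    if n_edge:
        warnings.warn(
            f"{path}: {n_edge} reading(s) outside the 60 center wells (B2-G11); "
            "edge wells are prone to evaporation artifacts",
            stacklevel=2,
        )
    return readings


def write_well_table(wells: Sequence[WellReading], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_WELL_COLUMNS)
        for w in wells:
            writer.writerow(
                [
                    w.plate_id,
                    w.well,
                    w.pdo_id,
                    w.drug,
                    w.conc_level.value,
                    _fmt(w.luminescence),
                ]
            )


def wells_from_platemap(
    plate_id: str,
    pdo_id: str,
    layout: pd.DataFrame,
    signal: pd.DataFrame,
) -> list[WellReading]:
    """Convert an 8 × 12 plate-map pair (layout, signal) to well readings.

    ``layout`` cells are ``"<drug>:<level>"``, ``"control"`` or empty/NaN;
    ``signal`` holds the matching luminescence grid.  Both frames must be
    indexed by rows A-H and columns 1-12 (any labels; position is what counts).
    """
    if layout.shape != (8, 12) or signal.shape != (8, 12):
        raise DataError("plate maps must be 8 rows x 12 columns")
    wells: list[WellReading] = []
    for i, row_letter in enumerate("ABCDEFGH"):
        for j in range(12):
            cell = layout.iat[i, j]
            if pd.isna(cell) or str(cell).strip() == "":
                continue
            cell = str(cell).strip()
            pos = f"{row_letter}{j + 1}"
            if cell.lower() == "control":
                drug, level = CONTROL, ConcLevel.control
            else:
                try:
                    drug, level_raw = cell.split(":")
                    level = ConcLevel(level_raw.strip().lower())
                except ValueError as exc:
                    raise ParseError(
                        f"plate {plate_id}, well {pos}: bad layout cell {cell!r}"
                    ) from exc
                drug = drug.strip()
            wells.append(
                WellReading(
                    plate_id=plate_id,
                    well=pos,
                    pdo_id=pdo_id,
                    drug=drug,
                    conc_level=level,
                    luminescence=float(signal.iat[i, j]),
                )
            )
    return wells


# ---------------------------------------------------------------------------
# Score matrix I/O


def _fmt(x: float) -> str:
    """12-significant-digit decimal rendering (lossless for pipeline scores)."""
    return f"{x:.12g}"


def write_score_matrix(matrix: ScoreMatrix, path) -> None:
    """Write a score matrix as long CSV; missing pairs get empty score fields."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["pdo", "drug", "auc_score", "sensitivity_score", "final_score", "hit"]
        )
        for pdo in matrix.pdo_ids:
            for drug in matrix.drugs:
                final = matrix.final_score.at[pdo, drug]
                if pd.isna(final):
                    writer.writerow([pdo, drug, "", "", "", ""])
                else:
                    hit = matrix.hit.at[pdo, drug]
                    writer.writerow(
                        [
                            pdo,
                            drug,
                            _fmt(matrix.auc_score.at[pdo, drug]),
                            _fmt(matrix.sensitivity_score.at[pdo, drug]),
                            _fmt(final),
                            "" if pd.isna(hit) else str(bool(hit)),
                        ]
                    )


def read_score_matrix(path, threshold: float = float("nan")) -> ScoreMatrix:
    """Read a long-format scores CSV back into a :class:`ScoreMatrix`."""
    df = pd.read_csv(path, dtype={"pdo": str, "drug": str})
    required = {"pdo", "drug", "auc_score", "sensitivity_score", "final_score", "hit"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing score columns {sorted(missing)}")
    pdos = list(dict.fromkeys(df["pdo"]))
    drugs = list(dict.fromkeys(df["drug"]))

    def grid(col: str) -> pd.DataFrame:
        return (
            df.pivot(index="pdo", columns="drug", values=col)
            .reindex(index=pdos, columns=drugs)
            .rename_axis(index=None, columns=None)
        )

    hit_raw = grid("hit")
    hit = hit_raw.map(
        lambda v: pd.NA if pd.isna(v) else str(v).strip().lower() == "true"
    ).astype("boolean")
    return ScoreMatrix(
        auc_score=grid("auc_score").astype(float),
        sensitivity_score=grid("sensitivity_score").astype(float),
        final_score=grid("final_score").astype(float),
        hit=hit,
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# Clinical table I/O


def read_clinical_table(path, panel: DrugPanel | None = None) -> list[ClinicalRecord]:
    """Read patient/PDO/drug/best_response records; validates drug against panel."""
    records: list[ClinicalRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"patient", "pdo", "drug", "best_response"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ParseError(
                f"{path}: expected header columns {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                response = Response(row["best_response"].strip().upper())
            except ValueError:
                raise ParseError(
                    f"{path}, row {lineno}: unknown best_response "
                    f"{row['best_response']!r} (expected PR/SD/PD)"
                )
            drug = row["drug"].strip()
            if panel is not None:
                if drug not in panel:
                    raise ParseError(
                        f"{path}, row {lineno}: drug {drug!r} is not in the panel"
                    )
                drug = panel.resolve(drug)
            records.append(
                ClinicalRecord(
                    patient_id=row["patient"].strip(),
                    pdo_id=row["pdo"].strip(),
                    drug_received=drug,
                    best_response=response,
                )
            )
    return records


def write_clinical_table(records: Sequence[ClinicalRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient", "pdo", "drug", "best_response"])
        for r in records:
            writer.writerow(
                [r.patient_id, r.pdo_id, r.drug_received, r.best_response.value]
            )
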