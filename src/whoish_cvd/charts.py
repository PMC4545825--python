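"""WHO/ISH SEAR-D risk prediction charts: domain types, binning, lookup.

The WHO/ISH charts quantize 10-year fatal/non-fatal CVD risk into five
ordinal bands from a handful of risk factors.  Two variants exist: the
low-information (LI) chart uses gender, age, smoking, diabetes and
systolic blood pressure; the high-information (HI) chart additionally
stratifies on total cholesterol.  Chart content ships as a validated
tabular resource file (one row per cell) so further WHO subregions can
be added without code changes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import IntEnum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

#: mg/dl of total cholesterol per mmol/l
TC_MGDL_PER_MMOLL = 38.67

#: fasting plasma glucose cut-off (mg/dl) used to impute diabetes status
GLUCOSE_DIABETES_THRESHOLD = 126.0

AGE_BANDS = (40, 50, 60, 70)
SBP_BANDS = (120, 140, 160, 180)
TC_BANDS = (4, 5, 6, 7, 8)

GENDERS = ("male", "female")


class RiskBand(IntEnum):
    """Ordinal 10-year CVD risk band; five quantization levels."""

    LT_10 = 0
    FROM_10_TO_20 = 1
    FROM_20_TO_30 = 2
    FROM_30_TO_40 = 3
    GE_40 = 4

    @property
    def label(self) -> str:
        return RISK_BAND_LABELS[int(self)]

    @classmethod
    def from_label(cls, label: str) -> "RiskBand":
        try:
            return cls(RISK_BAND_LEVELS[label.strip()])
        except KeyError:
            raise ValueError(f"unknown risk band label: {label!r}") from None


RISK_BAND_LABELS = {0: "<10%", 1: "10-<20%", 2: "20-<30%", 3: "30-<40%", 4: ">=40%"}
RISK_BAND_LEVELS = {v: k for k, v in RISK_BAND_LABELS.items()}


@dataclass
class Subject:
    """One person's risk-factor record.

    Units: age in years, pressures in mmHg, glucose and total
    cholesterol (tc) in mg/dl.  ``diabetes`` is the reported history of
    diabetes; the chart input additionally imputes diabetes from a
    fasting glucose >= 126 mg/dl (see :func:`effective_diabetes`).
    """

    id: str
    gender: str
    age: float
    smoker: bool
    diabetes: bool
    sbp: float
    dbp: float
    glucose: Optional[float] = None
    tc: Optional[float] = None
    on_htn_treatment: bool = False
    bmi: Optional[float] = None
    hist_high_chol: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.gender not in GENDERS:
            raise ValueError(f"gender must be one of {GENDERS}, got {self.gender!r}")
        if not self.age > 0:
            raise ValueError(f"age must be positive, got {self.age}")
        if not (self.sbp > 0 and self.dbp > 0):
            raise ValueError("sbp and dbp must be positive")
        for name in ("glucose", "tc", "bmi"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")


Cohort = Sequence[Subject]


def convert_tc_units(tc_mgdl: float) -> float:
    """Convert total cholesterol from mg/dl to mmol/l (factor 38.67)."""
    if tc_mgdl < 0:
        raise ValueError(f"total cholesterol must be nonnegative, got {tc_mgdl}")
    return tc_mgdl / TC_MGDL_PER_MMOLL


def bin_age(age: float) -> tuple[int, bool]:
    """Assign the chart decade band; ages <40 are scored on the 40 band.

    Returns ``(band, under_range)`` where ``under_range`` flags subjects
    below the chart's nominal 40-year floor (scored rather than rejected;
    the cohort contains them).
    """
    if not age > 0:
        raise ValueError(f"age must be positive, got {age}")
    if age < 40:
        return 40, True
    if age >= 70:
        return 70, False
    return int(age // 10) * 10, False


def bin_sbp(sbp: float) -> int:
    """Systolic blood pressure band: <140, 140-159, 160-179, >=180 mmHg."""
    if not sbp > 0:
        raise ValueError(f"sbp must be positive, got {sbp}")
    if sbp < 140:
        return 120
    if sbp < 160:
        return 140
    if sbp < 180:
        return 160
    return 180


def bin_tc(tc_mmoll: float) -> int:
    """Total cholesterol band (mmol/l): <5, [5,6), [6,7), [7,8), >=8."""
    if tc_mmoll < 0:
        raise ValueError(f"tc must be nonnegative, got {tc_mmoll}")
    if tc_mmoll < 5:
        return 4
    if tc_mmoll >= 8:
        return 8
    return int(tc_mmoll)


def effective_diabetes(
    subject: Subject, glucose_threshold: float = GLUCOSE_DIABETES_THRESHOLD
) -> bool:
    """Chart diabetes input: reported history OR fasting glucose >= threshold."""
    if subject.diabetes:
        return True
    return subject.glucose is not None and subject.glucose >= glucose_threshold


ChartKey = tuple  # (gender, smoker, diabetes, age_band, sbp_band[, tc_band])


def _key_space(variant: str) -> list[ChartKey]:
    keys = []
    for g in GENDERS:
        for sm in (False, True):
            for db in (False, True):
                for ab in AGE_BANDS:
                    for sb in SBP_BANDS:
                        if variant == "hi":
                            for tb in TC_BANDS:
                                keys.append((g, sm, db, ab, sb, tb))
                        else:
                            keys.append((g, sm, db, ab, sb))
    return keys


class ChartValidationError(ValueError):
    """Raised when a chart resource file is incomplete or inconsistent."""


@dataclass
class ChartTable:
    """Complete mapping from chart cell keys to risk bands for one variant.

    LI tables have 2*2*2*4*4 = 128 cells; HI tables 128*5 = 640.
    """

    variant: str
    region: str
    cells: Mapping[ChartKey, RiskBand]
    monotonicity_violations: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.variant not in ("li", "hi"):
            raise ChartValidationError(f"variant must be 'li' or 'hi', got {self.variant!r}")
        expected = _key_space(self.variant)
        missing = [k for k in expected if k not in self.cells]
        if missing:
            raise ChartValidationError(f"chart table missing cell {missing[0]!r} "
                                       f"({len(missing)} cells absent)")
        extra = set(self.cells) - set(expected)
        if extra:
            raise ChartValidationError(f"chart table has unexpected cell {sorted(extra)[0]!r}")
        self.monotonicity_violations = self._audit_monotonicity()

    def __len__(self) -> int:
        return len(self.cells)

    def lookup(self, key: ChartKey) -> RiskBand:
        return self.cells[key]

    def _audit_monotonicity(self) -> list:
        """Flag cells where the band decreases along age, SBP or TC.

        Violations are reported, never silently altered: the table is the
        authority, the audit exists to catch transcription slips.
        """
        violations = []
        axes = [AGE_BANDS, SBP_BANDS] + ([TC_BANDS] if self.variant == "hi" else [])
        for key, band in self.cells.items():
            for ax_idx, ax in enumerate(axes):
                pos = 3 + ax_idx
                i = ax.index(key[pos])
                if i + 1 < len(ax):
                    nxt = list(key)
                    nxt[pos] = ax[i + 1]
                    if self.cells[tuple(nxt)] < band:
                        violations.append((key, tuple(nxt)))
        return violations


_CHART_COLUMNS = ["variant", "gender", "smoker", "diabetes",
                  "age_band", "sbp_band", "tc_band", "risk_band"]


def _parse_bool(s: str, row: dict) -> bool:
    s = s.strip().lower()
    if s in ("1", "true", "yes"):
        return True
    if s in ("0", "false", "no"):
        return False
    raise ChartValidationError(f"unparseable boolean {s!r} in row {row}")


def load_chart_table(path: Union[str, Path], variant: str, region: str = "SEAR-D") -> ChartTable:
    """Load and validate one chart variant from a chart resource file.

    The file is CSV with columns ``variant, gender, smoker, diabetes,
    age_band, sbp_band, tc_band, risk_band`` (``tc_band`` empty for LI
    rows); a single file may hold both variants.  Duplicate keys, gaps
    in the key space and invalid band labels abort the load, naming the
    offending key.
    """
    variant = variant.lower()
    cells: dict[ChartKey, RiskBand] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != _CHART_COLUMNS:
            raise ChartValidationError(
                f"chart file header must be {_CHART_COLUMNS}, got {reader.fieldnames}")
        for row in reader:
            if row["variant"].strip().lower() != variant:
                continue
            key: ChartKey = (
                row["gender"].strip().lower(),
                _parse_bool(row["smoker"], row),
                _parse_bool(row["diabetes"], row),
                int(row["age_band"]),
                int(row["sbp_band"]),
            )
            if variant == "hi":
                if not row["tc_band"].strip():
                    raise ChartValidationError(f"HI row missing tc_band at key {key!r}")
                key = key + (int(row["tc_band"]),)
            elif row["tc_band"].strip():
                raise ChartValidationError(f"LI row carries tc_band at key {key!r}")
            if key in cells:
                raise ChartValidationError(f"duplicate chart cell {key!r}")
            cells[key] = RiskBand.from_label(row["risk_band"])
    if not cells:
        raise ChartValidationError(f"no rows for variant {variant!r} in {path}")
    return ChartTable(variant=variant, region=region, cells=cells)


def save_chart_tables(tables: Iterable[ChartTable], path: Union[str, Path]) -> None:
    """Write one or more chart tables to a single resource file."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CHART_COLUMNS)
        for table in tables:
            for key in _key_space(table.variant):
                g, sm, db, ab, sb = key[:5]
                tb = key[5] if table.variant == "hi" else ""
                writer.writerow([table.variant, g, int(sm), int(db), ab, sb, tb,
                                 table.cells[key].label])


def default_chart_path() -> Path:
    """Path of the bundled synthetic SEAR-D chart resource file.

    The bundled tables are a synthetic stand-in generated from a monotone
    latent risk surface (see :mod:`whoish_cvd.chartgen`), not a
    transcription of the published WHO/ISH figures.
    """
    return Path(resources.files("whoish_cvd").joinpath("data/seard_charts_synthetic.csv"))


def load_default_charts() -> tuple[ChartTable, ChartTable]:
    """Load the bundled (LI, HI) SEAR-D tables."""
    p = default_chart_path()
    return load_chart_table(p, "li"), load_chart_table(p, "hi")


@dataclass
class RiskPrediction:
    band: RiskBand
    under_age_range: bool = False


def predict_risk(
    subject: Subject,
    chart: ChartTable,
    glucose_threshold: float = GLUCOSE_DIABETES_THRESHOLD,
) -> RiskPrediction:
    """Deterministic chart lookup for one subject.

    HI charts require total cholesterol; LI charts ignore it.  Subjects
    under 40 are scored on the 40-49 band and flagged.
    """
    age_band, under = bin_age(subject.age)
    key: ChartKey = (
        subject.gender,
        bool(subject.smoker),
        effective_diabetes(subject, glucose_threshold),
        age_band,
        bin_sbp(subject.sbp),
    )
    if chart.variant == "hi":
        if subject.tc is None:
            raise ValueError(
                f"subject {subject.id!r}: HI chart requires total cholesterol")
        key = key + (bin_tc(convert_tc_units(subject.tc)),)
    return RiskPrediction(band=chart.lookup(key), under_age_range=under)


class WHOISHChartClassifier(BaseEstimator):
    """Chart-lookup risk band predictor with a scikit-learn face.

    Parameters
    ----------
    variant : {"li", "hi"}
        Chart variant; "hi" additionally requires total cholesterol.
    chart_path : str or None
        Resource file to load from; the bundled synthetic SEAR-D tables
        when None.
    glucose_threshold : float
        Fasting glucose (mg/dl) above which diabetes is imputed.

    The estimator is stateless apart from the loaded table; ``fit``
    loads and validates the chart and accepts (and ignores) ``X, y``
    so the class composes with sklearn pipelines.
    """

    def __init__(self, variant: str = "hi", chart_path: Optional[str] = None,
                 glucose_threshold: float = GLUCOSE_DIABETES_THRESHOLD):
        self.variant = variant
        self.chart_path = chart_path
        self.glucose_threshold = glucose_threshold

    def fit(self, X=None, y=None) -> "WHOISHChartClassifier":
        path = self.chart_path if self.chart_path is not None else default_chart_path()
        self.chart_ = load_chart_table(path, self.variant)
        return self

    def _ensure_fitted(self) -> None:
        if not hasattr(self, "chart_"):
            self.fit()

    def predict(self, X: Union[Cohort, pd.DataFrame]) -> np.ndarray:
        """Risk band levels (0..4) for a cohort or a subject-column DataFrame."""
        self._ensure_fitted()
        subjects = as_subjects(X)
        return np.array(
            [int(predict_risk(s, self.chart_, self.glucose_threshold).band)
             for s in subjects], dtype=int)


# ---------------------------------------------------------------------------
# Cohort CSV dialect

_COHORT_COLUMNS = ["id", "gender", "age", "smoker", "diabetes", "sbp", "dbp",
                   "glucose", "tc", "on_htn_treatment", "bmi", "hist_high_chol"]


def as_subjects(X: Union[Cohort, pd.DataFrame]) -> list[Subject]:
    """Coerce a DataFrame in the cohort dialect to a list of Subjects."""
    if isinstance(X, pd.DataFrame):
        return [
            Subject(
                id=str(r.get("id", i)),
                gender=str(r["gender"]),
                age=float(r["age"]),
                smoker=bool(r["smoker"]),
                diabetes=bool(r["diabetes"]),
                sbp=float(r["sbp"]),
                dbp=float(r["dbp"]),
                glucose=None if pd.isna(r.get("glucose")) else float(r["glucose"]),
                tc=None if pd.isna(r.get("tc")) else float(r["tc"]),
                on_htn_treatment=bool(r.get("on_htn_treatment", False)),
                bmi=None if pd.isna(r.get("bmi")) else float(r["bmi"]),
                hist_high_chol=(None if pd.isna(r.get("hist_high_chol"))
                                else bool(r["hist_high_chol"])),
            )
            for i, r in enumerate(X.to_dict("records"))
        ]
    return list(X)


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    rows = []
    for s in cohort:
        rows.append({
            "id": s.id, "gender": s.gender, "age": s.age,
            "smoker": int(s.smoker), "diabetes": int(s.diabetes),
            "sbp": s.sbp, "dbp": s.dbp,
            "glucose": s.glucose, "tc": s.tc,
            "on_htn_treatment": int(s.on_htn_treatment),
            "bmi": s.bmi,
            "hist_high_chol": None if s.hist_high_chol is None else int(s.hist_high_chol),
        })
    return pd.DataFrame(rows, columns=_COHORT_COLUMNS)


def write_cohort_csv(cohort: Cohort, path: Union[str, Path]) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def read_cohort_csv(path: Union[str, Path]) -> list[Subject]:
    return as_subjects(pd.read_csv(path))
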