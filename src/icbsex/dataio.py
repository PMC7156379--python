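"""Readers, writers and validated in-memory models for the pipeline's tables.

All tabular I/O is UTF-8 delimited text. The delimiter is auto-detected from
the file extension (``.tsv`` → tab, ``.csv`` → comma) and can be overridden.
Missing values are the sentinels ``""``, ``"NA"``, ``"NaN"`` (case-insensitive)
and are stored as missing, never coerced to zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING_SENTINELS = ["", "NA", "NaN", "na", "nan", "Na", "NAN"]

THERAPY_CLASSES = ("anti-PD-1/PD-L1", "anti-CTLA-4", "combination", "other")

#: sex normalization map; numeric coding documented as 1=female, 0=male
#: (matching the screen's group indicator Z).
_SEX_MAP = {
    "f": "female",
    "female": "female",
    "1": "female",
    "m": "male",
    "male": "male",
    "0": "male",
}

TRIAL_COLUMNS = [
    "trial_id",
    "cancer_type",
    "therapy_class",
    "control_arm",
    "hr_female",
    "ci_female_lo",
    "ci_female_hi",
    "hr_male",
    "ci_male_lo",
    "ci_male_hi",
    "n_female",
    "n_male",
]


class DataValidationError(ValueError):
    """A table violated a documented invariant."""


def _detect_sep(path: str | Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    suffix = Path(path).suffix.lower()
    return "," if suffix == ".csv" else "\t"


def normalize_sex(value: object) -> str:
    """Map common sex encodings onto {'female', 'male'}.

    Accepts F/M, Female/Male (any case) and the documented 0/1 coding
    (1 = female, 0 = male). Anything else raises — the screen is strictly
    two-group and a silent third category would corrupt it.
    """
    key = str(value).strip().lower()
    if key in ("1.0", "0.0"):
        key = key[0]
    if key not in _SEX_MAP:
        raise DataValidationError(f"unrecognized sex code: {value!r}")
    return _SEX_MAP[key]


@dataclass(frozen=True)
class TrialRecord:
    """One ICB trial's sex-subgroup overall-survival hazard ratios.

    HRs compare ICB against the trial's control arm within each sex; HR < 1
    means the treatment reduced the death hazard for that sex.
    """

    trial_id: str
    cancer_type: str
    therapy_class: str
    control_arm: str
    hr_female: float
    ci_female_lo: float
    ci_female_hi: float
    hr_male: float
    ci_male_lo: float
    ci_male_hi: float
    n_female: int
    n_male: int

    def __post_init__(self) -> None:
        for sex in ("female", "male"):
            hr = getattr(self, f"hr_{sex}")
            lo = getattr(self, f"ci_{sex}_lo")
            hi = getattr(self, f"ci_{sex}_hi")
            for name, v in ((f"hr_{sex}", hr), (f"ci_{sex}_lo", lo), (f"ci_{sex}_hi", hi)):
                if not (math.isfinite(v) and v > 0):
                    raise DataValidationError(
                        f"trial {self.trial_id}: {name} must be a positive real, got {v}"
                    )
            if not (lo <= hr <= hi):
                raise DataValidationError(
                    f"trial {self.trial_id}: CI [{lo}, {hi}] does not bracket HR {hr} ({sex})"
                )
        if self.therapy_class not in THERAPY_CLASSES:
            raise DataValidationError(
                f"trial {self.trial_id}: therapy_class {self.therapy_class!r} "
                f"not in {THERAPY_CLASSES}"
            )
        if self.n_female < 0 or self.n_male < 0:
            raise DataValidationError(f"trial {self.trial_id}: negative sample size")


@dataclass(frozen=True)
class GeneSet:
    """A named gene signature; genes are unique within the set."""

    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise DataValidationError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise DataValidationError(f"gene set {self.name!r} has duplicate genes")


def read_trials(
    path: str | Path,
    sep: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> list[TrialRecord]:
    """Read a trial-level table of sex-specific hazard ratios.

    ``column_map`` maps the file's column names onto the canonical
    :data:`TRIAL_COLUMNS` names, for supplements whose headers differ.
    """
    df = pd.read_csv(
        path,
        sep=_detect_sep(path, sep),
        dtype=str,
        keep_default_na=False,
        na_values=MISSING_SENTINELS,
    )
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing_cols = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing_cols:
        raise DataValidationError(f"{path}: missing trial columns {missing_cols}")

    records = []
    for idx, row in df.iterrows():
        kwargs: dict[str, object] = {}
        for col in TRIAL_COLUMNS:
            raw = row[col]
            if pd.isna(raw):
                raise DataValidationError(f"{path} row {idx}: missing value in {col!r}")
            if col.startswith(("hr_", "ci_")):
                try:
                    kwargs[col] = float(raw)
                except ValueError as exc:
                    raise DataValidationError(
                        f"{path} row {idx}, column {col!r}: malformed numeric {raw!r}"
                    ) from exc
            elif col.startswith("n_"):
                try:
                    kwargs[col] = int(float(raw))
                except ValueError as exc:
                    raise DataValidationError(
                        f"{path} row {idx}, column {col!r}: malformed integer {raw!r}"
                    ) from exc
            else:
                kwargs[col] = str(raw)
        records.append(TrialRecord(**kwargs))  # type: ignore[arg-type]
    return records


def write_trials(records: Sequence[TrialRecord], path: str | Path, sep: str | None = None) -> None:
    df = pd.DataFrame([vars(r) for r in records], columns=TRIAL_COLUMNS)
    df.to_csv(path, sep=_detect_sep(path, sep), index=False, float_format="%.17g")


def read_cohort(
    path: str | Path,
    sep: str | None = None,
    sex_column: str = "sex",
) -> pd.DataFrame:
    """Read a per-patient clinical table into a validated DataFrame.

    Requires ``patient_id`` and a sex column; normalizes sex coding to
    {'female', 'male'}. ``os_event`` must be 0/1 and ``purity`` in [0, 1]
    where present.
    """
    df = pd.read_csv(
        path,
        sep=_detect_sep(path, sep),
        keep_default_na=False,
        na_values=MISSING_SENTINELS,
    )
    if "patient_id" not in df.columns:
        raise DataValidationError(f"{path}: no patient_id column")
    if sex_column not in df.columns:
        raise DataValidationError(f"{path}: no {sex_column!r} column")
    df = df.rename(columns={sex_column: "sex"})
    return validate_cohort(df)


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if df["sex"].isna().any():
        raise DataValidationError("cohort has missing sex values")
    df["sex"] = df["sex"].map(normalize_sex)
    if "os_event" in df.columns:
        events = df["os_event"].dropna()
        if not events.isin([0, 1]).all():
            raise DataValidationError("os_event values must be 0 or 1")
    if "os_time" in df.columns:
        times = pd.to_numeric(df["os_time"], errors="raise")
        if (times.dropna() < 0).any():
            raise DataValidationError("negative os_time")
    if "purity" in df.columns:
        purity = df["purity"].dropna()
        if ((purity < 0) | (purity > 1)).any():
            raise DataValidationError("tumor purity outside [0, 1]")
    if df["patient_id"].duplicated().any():
        raise DataValidationError("duplicate patient_id values")
    return df


@dataclass
class FeatureMatrix:
    """Patients × named immune features, with per-feature continuity tags.

    ``values`` is indexed by patient_id; ``discrete`` names the features that
    are binary indicators (e.g. single-gene mutation status) and therefore go
    through Fisher's exact test rather than the weighted linear test.
    """

    values: pd.DataFrame
    discrete: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.discrete = frozenset(self.discrete)
        unknown = self.discrete - set(self.values.columns)
        if unknown:
            raise DataValidationError(f"discrete tags for unknown features: {sorted(unknown)}")

    def is_discrete(self, feature: str) -> bool:
        return feature in self.discrete


def read_matrix(
    path: str | Path,
    sep: str | None = None,
    orientation: str = "genes-by-samples",
) -> pd.DataFrame:
    """Read a labelled rectangular matrix (expression or feature table).

    ``orientation`` declares how the file is laid out; the returned frame is
    always rows = the file's row labels unless ``orientation`` ends with
    ``-transposed``, in which case the frame is transposed on read so callers
    get the canonical layout.
    """
    valid = {
        "genes-by-samples",
        "patients-by-features",
        "genes-by-samples-transposed",
        "patients-by-features-transposed",
    }
    if orientation not in valid:
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(
        path,
        sep=_detect_sep(path, sep),
        index_col=0,
        keep_default_na=False,
        na_values=MISSING_SENTINELS,
    )
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise DataValidationError(f"{path}: duplicate row labels {dupes[:5]}")
    if orientation.endswith("-transposed"):
        df = df.T
    return df.astype(float)


def write_matrix(df: pd.DataFrame, path: str | Path, sep: str | None = None) -> None:
    df.to_csv(path, sep=_detect_sep(path, sep), float_format="%.17g", na_rep="NA")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: one set per line, ``name TAB description TAB gene...``.

    Duplicate genes within a line are dropped (first occurrence kept) with a
    logged warning.
    """
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataValidationError(
                    f"{path} line {lineno}: GMT lines need >=3 tab-separated fields"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g.strip()]
            deduped = list(dict.fromkeys(genes))
            if len(deduped) != len(genes):
                logger.warning(
                    "GMT set %s (line %d): %d duplicate gene(s) removed",
                    name,
                    lineno,
                    len(genes) - len(deduped),
                )
            sets.append(GeneSet(name=name, description=description, genes=tuple(deduped)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


def trials_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records], columns=TRIAL_COLUMNS)
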