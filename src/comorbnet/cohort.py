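"""Person-level cohort tables, the chronic-condition catalog, and the COPD
case definition.

The analyses in this package operate on a cross-sectional EMR-style cohort:
one row per person carrying demographics (age, sex), the study group label
(index-disease cases vs matched controls), outcome flags (3-year death,
prior-year hospitalization, confirmed smoker) and a binary vector over a
catalog of chronic conditions.  Ages are integer years and the study floor
is 40; five incremental age brackets (40-55, 56-65, 66-75, 76-85, >85)
partition the age range.

Files are plain CSV (UTF-8, header row, "1"/"0" binaries) so that cohorts
round-trip deterministically through ``write_cohort`` / ``read_cohort``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, SchemaError, ValidationError

MIN_AGE = 40

#: ICD-9 root codes that define the index COPD diagnosis.
COPD_ICD9_ROOTS = frozenset({"490", "491", "492", "494", "496"})

#: Minimum number of qualifying encounters for a positive case definition.
MIN_COPD_ENCOUNTERS = 2

#: The 13 conditions characteristically affecting the elderly (Rowe-Kahn
#: successful-aging framing) used for the prevalence-trajectory analysis.
ELDER_DISEASE_NAMES = (
    "cataract",
    "degenerative joint disease",
    "diabetes mellitus",
    "coronary artery disease",
    "benign prostatic hypertrophy",
    "osteoporosis",
    "dementia",
    "depression",
    "hearing loss",
    "skin cancer",
    "lung cancer",
    "chronic renal failure",
    "atherosclerosis",
)

_ICD9_RE = re.compile(r"^\d{3}(\.\d{1,2})?$")

_REQUIRED_COLUMNS = (
    "person_id",
    "age",
    "sex",
    "group",
    "smoker",
    "died_3y",
    "hospitalized_prior_year",
)


@dataclass(frozen=True)
class AgeBracket:
    """One of the five incremental age groups; bounds are inclusive.

    ``upper is None`` marks the open-ended top bracket.  ``midpoint`` is the
    bracket's midpoint in years, with the open bracket capped at 95.
    """

    label: str
    lower: int
    upper: int | None

    def contains(self, age: int) -> bool:
        if self.upper is None:
            return age >= self.lower
        return self.lower <= age <= self.upper

    @property
    def midpoint(self) -> float:
        if self.upper is None:
            return (self.lower + 95) / 2.0  # open bracket capped at 95
        return (self.lower + self.upper) / 2.0


BRACKETS: tuple[AgeBracket, ...] = (
    AgeBracket("40-55", 40, 55),
    AgeBracket("56-65", 56, 65),
    AgeBracket("66-75", 66, 75),
    AgeBracket("76-85", 76, 85),
    AgeBracket(">85", 86, None),
)

BRACKET_LABELS: tuple[str, ...] = tuple(b.label for b in BRACKETS)


def assign_bracket(age: int) -> AgeBracket:
    """Return the unique age bracket containing ``age`` (years, >= 40)."""
    if age < MIN_AGE:
        raise DomainError(f"age {age} is below the study floor of {MIN_AGE}")
    for bracket in BRACKETS:
        if bracket.contains(int(age)):
            return bracket
    raise AssertionError("brackets must partition [40, inf)")  # pragma: no cover


@dataclass(frozen=True)
class CatalogEntry:
    condition_id: str
    name: str
    is_elder_disease: bool
    is_index_copd: bool
    icd9_codes: tuple[str, ...] = ()


class DiseaseCatalog:
    """Ordered list of chronic conditions with elder-disease flags.

    Exactly one entry must carry the index-COPD flag; its position defines
    which column of every person's disease vector is the index diagnosis.
    """

    def __init__(self, entries: Sequence[CatalogEntry]):
        ids = [e.condition_id for e in entries]
        if len(set(ids)) != len(ids):
            raise ValidationError("condition_ids must be unique")
        index_flags = [i for i, e in enumerate(entries) if e.is_index_copd]
        if len(index_flags) != 1:
            raise ValidationError(
                f"catalog must flag exactly one index-COPD entry, found {len(index_flags)}"
            )
        self.entries: tuple[CatalogEntry, ...] = tuple(entries)
        self.copd_index: int = index_flags[0]
        self._id_to_index = {e.condition_id: i for i, e in enumerate(self.entries)}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def condition_ids(self) -> list[str]:
        return [e.condition_id for e in self.entries]

    @property
    def elder_indices(self) -> list[int]:
        return [i for i, e in enumerate(self.entries) if e.is_elder_disease]

    def index_of(self, condition_id: str) -> int:
        try:
            return self._id_to_index[condition_id]
        except KeyError:
            raise KeyError(f"unknown condition_id {condition_id!r}") from None

    @classmethod
    def from_csv(cls, path: str | Path) -> "DiseaseCatalog":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        required = {"condition_id", "name", "is_elder_disease", "is_index_copd", "icd9_codes"}
        missing = required - set(df.columns)
        if missing:
            raise SchemaError(f"catalog file missing columns: {sorted(missing)}")
        entries = [
            CatalogEntry(
                condition_id=row.condition_id,
                name=row.name_,
                is_elder_disease=row.is_elder_disease in ("1", "true", "True"),
                is_index_copd=row.is_index_copd in ("1", "true", "True"),
                icd9_codes=tuple(c for c in row.icd9_codes.split(";") if c),
            )
            for row in df.rename(columns={"name": "name_"}).itertuples(index=False)
        ]
        return cls(entries)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "condition_id": [e.condition_id for e in self.entries],
                "name": [e.name for e in self.entries],
                "is_elder_disease": [int(e.is_elder_disease) for e in self.entries],
                "is_index_copd": [int(e.is_index_copd) for e in self.entries],
                "icd9_codes": [";".join(e.icd9_codes) for e in self.entries],
            }
        ).to_csv(path, index=False)


def default_catalog() -> DiseaseCatalog:
    """The bundled 119-condition synthetic catalog.

    Condition names seen in the published hub and elder-disease tables are
    real; the remainder are synthetic placeholders standing in for the full
    Salisbury chronic-condition list, which is not redistributed here.
    """
    path = Path(__file__).parent / "data" / "catalog_synthetic_119.csv"
    return DiseaseCatalog.from_csv(path)


@dataclass
class PersonRecord:
    """One individual: demographics, outcomes, and binary disease vector."""

    person_id: str
    age: int
    sex: str  # "male" | "female"
    group: str  # "copd" | "control"
    smoker: bool
    died_3y: bool
    hospitalized_prior_year: bool
    diseases: np.ndarray = field(repr=False)  # uint8, aligned to catalog

    def validate(self, catalog: DiseaseCatalog) -> None:
        if self.age < MIN_AGE:
            raise ValidationError(f"person {self.person_id}: age {self.age} < {MIN_AGE}")
        if self.sex not in ("male", "female"):
            raise ValidationError(f"person {self.person_id}: bad sex {self.sex!r}")
        if self.group not in ("copd", "control"):
            raise ValidationError(f"person {self.person_id}: bad group {self.group!r}")
        if len(self.diseases) != len(catalog):
            raise ValidationError(
                f"person {self.person_id}: disease vector length {len(self.diseases)} "
                f"!= catalog size {len(catalog)}"
            )
        if not np.isin(self.diseases, (0, 1)).all():
            raise ValidationError(f"person {self.person_id}: non-binary disease entries")
        if self.group == "copd" and self.diseases[catalog.copd_index] != 1:
            raise ValidationError(
                f"person {self.person_id}: copd group but index diagnosis absent"
            )


@dataclass(frozen=True)
class EncounterRecord:
    person_id: str
    icd9_code: str


def parse_icd9_root(code: str) -> str:
    """Return the 3-digit root of an ICD-9 code string ("491.21" -> "491")."""
    code = code.strip()
    if not _ICD9_RE.match(code):
        raise ValidationError(f"malformed ICD-9 code {code!r}")
    return code.split(".", 1)[0]


def is_copd_case(encounters: Iterable[EncounterRecord], person_id: str) -> bool:
    """COPD case definition: at least two encounters carrying an ICD-9 code
    whose 3-digit root is one of 490-492, 494, 496.

    The two qualifying encounters need not share the same root code.
    """
    n_qualifying = sum(
        1
        for e in encounters
        if e.person_id == person_id and parse_icd9_root(e.icd9_code) in COPD_ICD9_ROOTS
    )
    return n_qualifying >= MIN_COPD_ENCOUNTERS


def comorbidity_count(person: PersonRecord, catalog: DiseaseCatalog) -> int:
    """Number of chronic conditions present, never counting the index COPD
    diagnosis itself."""
    total = int(person.diseases.sum())
    return total - int(person.diseases[catalog.copd_index])


# ---------------------------------------------------------------------------
# Tabular conversion and file I/O
# ---------------------------------------------------------------------------


def cohort_to_frame(records: Sequence[PersonRecord], catalog: DiseaseCatalog) -> pd.DataFrame:
    """Flatten records into one DataFrame (disease columns named by
    condition_id), the in-memory currency of the downstream stages."""
    base = pd.DataFrame(
        {
            "person_id": [r.person_id for r in records],
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
            "group": [r.group for r in records],
            "smoker": [int(r.smoker) for r in records],
            "died_3y": [int(r.died_3y) for r in records],
            "hospitalized_prior_year": [int(r.hospitalized_prior_year) for r in records],
        }
    )
    mat = (
        np.vstack([r.diseases for r in records])
        if records
        else np.empty((0, len(catalog)), dtype=np.uint8)
    )
    disease = pd.DataFrame(mat, columns=catalog.condition_ids)
    return pd.concat([base, disease], axis=1)


def frame_to_cohort(df: pd.DataFrame, catalog: DiseaseCatalog) -> list[PersonRecord]:
    mat = df[catalog.condition_ids].to_numpy(dtype=np.uint8)
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        rec = PersonRecord(
            person_id=str(row.person_id),
            age=int(row.age),
            sex=str(row.sex),
            group=str(row.group),
            smoker=bool(int(row.smoker)),
            died_3y=bool(int(row.died_3y)),
            hospitalized_prior_year=bool(int(row.hospitalized_prior_year)),
            diseases=mat[i],
        )
        records.append(rec)
    return records


def read_cohort(path: str | Path, catalog: DiseaseCatalog) -> list[PersonRecord]:
    """Read and validate a cohort CSV; row order is preserved.

    Raises ``SchemaError`` naming any missing column, and ``ValidationError``
    listing offending person_ids for age-floor or non-binary violations.
    """
    df = pd.read_csv(path, dtype={"person_id": str})
    missing = [c for c in (*_REQUIRED_COLUMNS, *catalog.condition_ids) if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file missing columns: {missing}")

    underage = df.loc[df["age"] < MIN_AGE, "person_id"].tolist()
    if underage:
        raise ValidationError(f"ages below {MIN_AGE} for person_ids: {underage}")

    disease_block = df[catalog.condition_ids]
    bad = ~disease_block.isin((0, 1)).all(axis=1)
    if bad.any():
        raise ValidationError(
            f"non-binary disease cells for person_ids: {df.loc[bad, 'person_id'].tolist()}"
        )

    records = frame_to_cohort(df, catalog)
    for rec in records:
        rec.validate(catalog)
    return records


def write_cohort(
    records: Sequence[PersonRecord], catalog: DiseaseCatalog, path: str | Path
) -> None:
    """Write a cohort CSV readable by ``read_cohort`` (lossless round-trip)."""
    cohort_to_frame(records, catalog).to_csv(path, index=False)
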