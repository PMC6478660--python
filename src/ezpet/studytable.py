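"""The clinical study table: per-patient reference EZ and method calls.

Each row records, for one operated patient with a good post-surgical
outcome, the post-surgically confirmed epileptogenic zone (the reference),
the presurgical calls made by visual assessment, two fixed SPM threshold
settings (SPM1 = corrected p<0.05/k=50, SPM2 = uncorrected p<0.001/k=100),
the dynamic parametric analysis, and MRI, plus histopathology and the Engel
outcome class.

A call is either Negative or a (side, sublobar) pair written ``SIDE/REGION``
(e.g. ``R/MT``).  MRI findings are lesion strings (``L/MTS``, ``R/P FCD``,
``Non-L``); a shipped mapping table translates lesion tokens to sublobar
classes (mesial temporal sclerosis MTS -> MT, named lesions keep their
printed side and lobe).

Two fixtures are packaged: the table as published, and an erratum variant
in which patient 9's parametric-analysis call is Negative — the published
row is inconsistent with the published summary counts, and the published
discussion lists patient 9 among the incorrectly localizing studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "EZCall",
    "StudyRow",
    "METHODS",
    "ENGEL_CLASSES",
    "load_study_table",
    "save_study_table",
    "packaged_study_table",
    "packaged_table_path",
    "load_lesion_map",
]

METHODS = ("visual", "spm1", "spm2", "petanalysis", "mri")
ENGEL_CLASSES = ("I", "II", "III", "IV")

SIDE_VALUES = ("L", "R", "Negative")
SUBLOBAR_VALUES = ("MT", "LT", "MLT", "F", "P", "O", "I", "Negative")

_COLUMNS = [
    "patient",
    "reference_ez",
    "visual",
    "spm1",
    "spm2",
    "petanalysis",
    "mri",
    "histopathology",
    "engel",
]


@dataclass(frozen=True)
class EZCall:
    """A hemispheric + sublobar localization call, or Negative.

    ``side`` is Negative iff ``sublobar`` is Negative.
    """

    side: str
    sublobar: str

    def __post_init__(self) -> None:
        if self.side not in SIDE_VALUES:
            raise ValueError(f"unknown side {self.side!r}")
        if self.sublobar not in SUBLOBAR_VALUES:
            raise ValueError(f"unknown sublobar class {self.sublobar!r}")
        if (self.side == "Negative") != (self.sublobar == "Negative"):
            raise ValueError("side is Negative iff sublobar is Negative")

    @property
    def is_negative(self) -> bool:
        return self.side == "Negative"

    @classmethod
    def negative(cls) -> "EZCall":
        return cls("Negative", "Negative")

    @classmethod
    def parse(cls, token: str) -> "EZCall":
        """Parse a ``SIDE/REGION`` call token or ``Neg``."""
        token = token.strip()
        if token in ("Neg", "Negative"):
            return cls.negative()
        if "/" not in token:
            raise ValueError(f"malformed call token {token!r}")
        side, _, sub = token.partition("/")
        return cls(side.strip(), sub.strip())

    def __str__(self) -> str:
        return "Neg" if self.is_negative else f"{self.side}/{self.sublobar}"


@dataclass
class StudyRow:
    """One patient of the study table."""

    patient: int
    reference: EZCall
    calls: dict[str, EZCall]
    histopathology: str
    engel: str
    raw: dict[str, str] = field(default_factory=dict)  # printed tokens, for lossless round-trip

    def __post_init__(self) -> None:
        if self.engel not in ENGEL_CLASSES:
            raise ValueError(f"patient {self.patient}: Engel class {self.engel!r} not in {ENGEL_CLASSES}")
        missing = set(METHODS) - set(self.calls)
        if missing:
            raise ValueError(f"patient {self.patient}: missing method calls {sorted(missing)}")


def _data_path(name: str) -> Path:
    return Path(resources.files("ezpet") / "data" / name)  # type: ignore[arg-type]


def load_lesion_map(path=None) -> dict[str, str]:
    """Lesion-token -> sublobar mapping (shipped as data, not code)."""
    if path is None:
        path = _data_path("mri_lesion_map.tsv")
    table = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(table["token"], table["sublobar"]))


def _parse_mri(token: str, lesion_map: dict[str, str], rowno: int) -> EZCall:
    token = token.strip()
    if token in ("Non-L", "Neg", "Negative"):
        return EZCall.negative()
    if "/" not in token:
        raise ValueError(f"row {rowno}: malformed MRI lesion string {token!r}")
    side, _, rest = token.partition("/")
    lesion_token = rest.strip().split()[0]
    if lesion_token not in lesion_map:
        raise ValueError(f"row {rowno}: unmapped MRI lesion token {lesion_token!r}")
    return EZCall(side.strip(), lesion_map[lesion_token])


def load_study_table(path, lesion_map: dict[str, str] | None = None) -> list[StudyRow]:
    """Parse a study table TSV into :class:`StudyRow` records.

    The parse is lossless: :func:`save_study_table` reproduces the input
    file byte for byte.
    """
    if lesion_map is None:
        lesion_map = load_lesion_map()
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"study table is missing columns {missing}")
    rows: list[StudyRow] = []
    for i, rec in enumerate(table.itertuples(index=False), start=1):
        try:
            calls = {
                "visual": EZCall.parse(rec.visual),
                "spm1": EZCall.parse(rec.spm1),
                "spm2": EZCall.parse(rec.spm2),
                "petanalysis": EZCall.parse(rec.petanalysis),
                "mri": _parse_mri(rec.mri, lesion_map, i),
            }
            reference = EZCall.parse(rec.reference_ez)
        except ValueError as err:
            raise ValueError(f"row {i}: {err}") from err
        rows.append(
            StudyRow(
                patient=int(rec.patient),
                reference=reference,
                calls=calls,
                histopathology=rec.histopathology,
                engel=rec.engel,
                raw={c: getattr(rec, c) for c in _COLUMNS},
            )
        )
    return rows


def save_study_table(rows: list[StudyRow], path) -> None:
    """Serialize rows back to TSV, reproducing the source file."""
    records = []
    for row in rows:
        if row.raw:
            records.append(row.raw)
        else:
            records.append(
                {
                    "patient": str(row.patient),
                    "reference_ez": str(row.reference),
                    "visual": str(row.calls["visual"]),
                    "spm1": str(row.calls["spm1"]),
                    "spm2": str(row.calls["spm2"]),
                    "petanalysis": str(row.calls["petanalysis"]),
                    "mri": str(row.calls["mri"]),
                    "histopathology": row.histopathology,
                    "engel": row.engel,
                }
            )
    pd.DataFrame.from_records(records, columns=_COLUMNS).to_csv(path, sep="\t", index=False)


def packaged_table_path(erratum: bool = False) -> Path:
    """Path of the packaged study-table fixture."""
    name = "study_table_erratum.tsv" if erratum else "study_table.tsv"
    return _data_path(name)


def packaged_study_table(erratum: bool = False) -> list[StudyRow]:
    """The packaged 30-patient study table (optionally the erratum variant)."""
    return load_study_table(packaged_table_path(erratum))
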