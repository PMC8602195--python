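"""Cohort tables: the packaged prospective cohort and tabular plumbing.

The packaged fixture transcribes the 48-patient prospective study table
(patients P01–P52 minus four excluded cases) exactly as printed, one row per
subject, with per-modality five-level decisions plus the tokens ``_``
(not performed) and ``F`` (metric failed).  Two derived columns are included
because they are not recoverable from the printed procedure token alone:
``procedure`` (resection / rns / resection+rns / none — the two
resection+RNS cases are grouped with the RNS implant group downstream) and
``operated_side``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pandas as pd

from . import decisions as dec

#: modality decision columns, in table order
MODALITIES = (
    "volumetry", "flair", "msa", "pet", "mmm",
    "dti_uncertainty", "dti_connectivity", "fmri_connectivity",
)

SIDES = ("left", "right", "bilateral", "none")
PROCEDURES = ("resection", "rns", "resection+rns", "none")


@dataclass
class SubjectRecord:
    """One subject: clinical attributes plus per-modality decisions."""

    subject_id: str
    operated_side: str = "none"
    procedure: str = "none"
    engel_12: str | None = None
    engel_24: str | None = None
    decisions: dict[str, str] = field(default_factory=dict)
    scores: dict[str, float] = field(default_factory=dict)
    extra: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.operated_side not in SIDES:
            raise ValueError(
                f"{self.subject_id}: bad operated_side {self.operated_side!r}")
        if self.procedure not in PROCEDURES:
            raise ValueError(
                f"{self.subject_id}: bad procedure {self.procedure!r}")
        for modality, token in self.decisions.items():
            if modality not in MODALITIES:
                raise ValueError(
                    f"{self.subject_id}: unknown modality {modality!r}")
            if token not in dec.TOKENS:
                raise ValueError(
                    f"{self.subject_id}: bad decision {token!r} "
                    f"for {modality}")
        if self.engel_24 is not None and self.procedure == "none":
            raise ValueError(
                f"{self.subject_id}: 24-month outcome recorded without "
                "a procedure")

    def decision(self, modality: str) -> str:
        """Decision token for *modality* (``_`` when absent)."""
        return self.decisions.get(modality, dec.MISSING)

    @property
    def engel_1(self) -> bool | None:
        """Seizure-free (Engel class 1) at the 24-month horizon."""
        if self.engel_24 is None:
            return None
        return self.engel_24.startswith("1")


@dataclass
class CohortTable:
    """Ordered collection of :class:`SubjectRecord` with provenance."""

    records: list[SubjectRecord]
    provenance: str = "synthetic"
    seed: int | None = None

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate subject ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SubjectRecord]:
        return iter(self.records)

    def __getitem__(self, subject_id: str) -> SubjectRecord:
        for r in self.records:
            if r.subject_id == subject_id:
                return r
        raise KeyError(subject_id)

    def subset(self, predicate) -> "CohortTable":
        return CohortTable([r for r in self.records if predicate(r)],
                           provenance=self.provenance, seed=self.seed)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view in the fixture schema (round-trips through
        :func:`read_cohort_csv`)."""
        score_cols = {"volumetry": "vol_ratio", "flair_mean": "flair_mean",
                      "flair_sd": "flair_sd", "mmm": "mmm_score"}
        rows = []
        for r in self.records:
            row: dict[str, object] = {"patient_id": r.subject_id}
            row.update(r.extra)
            row.update(
                operated_side=r.operated_side,
                procedure=r.procedure,
                engel_12=r.engel_12 or dec.MISSING,
                engel_24=r.engel_24 or dec.MISSING,
            )
            for m in MODALITIES:
                row[m] = r.decision(m)
            for name, col in score_cols.items():
                row[col] = r.scores.get(name, dec.MISSING)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _cell(row: pd.Series, col: str, row_label: str) -> str:
    value = row.get(col)
    if value is None or (isinstance(value, float) and pd.isna(value)):
        raise ValueError(f"cohort fixture row {row_label}: missing {col!r}")
    return str(value).strip()


def _parse_row(row: pd.Series) -> SubjectRecord:
    label = str(row.get("patient_id", "<no id>"))
    decisions: dict[str, str] = {}
    for m in MODALITIES:
        token = _cell(row, m, label)
        if token not in dec.TOKENS:
            raise ValueError(
                f"cohort fixture row {label}: bad {m} decision {token!r}")
        if token != dec.MISSING:
            decisions[m] = token
    scores: dict[str, float] = {}
    for col, name in (("vol_ratio", "volumetry"), ("mmm_score", "mmm"),
                      ("flair_mean", "flair_mean"), ("flair_sd", "flair_sd")):
        raw = str(row.get(col, dec.MISSING)).strip()
        if raw not in (dec.MISSING, "", "nan"):
            try:
                scores[name] = float(raw)
            except ValueError as exc:
                raise ValueError(
                    f"cohort fixture row {label}: bad {col} value "
                    f"{raw!r}") from exc
    engel_12 = _cell(row, "engel_12", label)
    engel_24 = _cell(row, "engel_24", label)
    extra_cols = ("sex", "age_surgery", "duration_years", "phase1",
                  "phase2_3", "mts", "proc_side")
    extra = {c: str(row[c]) for c in extra_cols if c in row.index}
    try:
        return SubjectRecord(
            subject_id=label,
            operated_side=_cell(row, "operated_side", label),
            procedure=_cell(row, "procedure", label),
            engel_12=None if engel_12 == dec.MISSING else engel_12,
            engel_24=None if engel_24 == dec.MISSING else engel_24,
            decisions=decisions,
            scores=scores,
            extra=extra,
        )
    except ValueError as exc:
        raise ValueError(f"cohort fixture row {label}: {exc}") from exc


def read_cohort_csv(path: str | Path, provenance: str = "fixture",
                    seed: int | None = None) -> CohortTable:
    """Read a cohort table in the fixture schema from *path*."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    records = [_parse_row(row) for _, row in frame.iterrows()]
    return CohortTable(records, provenance=provenance, seed=seed)


def fixture_path() -> Path:
    """Filesystem path of the packaged prospective cohort CSV."""
    return Path(importlib.resources.files("epilat.data")
                / "prospective_cohort.csv")


def load_reference_cohort() -> CohortTable:
    """Load the packaged 48-patient prospective cohort."""
    table = read_cohort_csv(fixture_path(), provenance="fixture")
    if len(table) != 48:
        raise ValueError(
            f"packaged cohort fixture has {len(table)} rows, expected 48")
    return table
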