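"""Binary metastasis labeling from TCGA-CDR-style clinical tables.

A case is labeled metastasis (1) by the first matching rule:

  r1. tumor_status itself names a metastatic state (configurable vocabulary;
      with the standard TCGA-CDR vocabulary -- WITH TUMOR / TUMOR FREE /
      NOT CLEAR -- this rule never fires);
  r2. tumor_status is uninformative (NOT CLEAR or missing) but
      new_tumor_event_type is Metastasis;
  r3. neither tumor_status nor new_tumor_event_type is informative but a
      new_tumor_event_site is recorded.

Of the remaining cases, those with uninformative tumor_status are excluded;
a case is labeled non-metastasis (0) only when tumor_status is TUMOR FREE
and no new tumor event is recorded; everything else is excluded as
ambiguous.  Because a short follow-up can hide a later metastasis, only the
longest-followed fraction (default 70%) of non-metastasis cases, ranked by
progression-free-interval time, is retained; metastasis cases are always
kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import InvalidInputError, SchemaError

#: Cell values normalized to "missing" (case-insensitive, after trimming).
NA_TOKENS = frozenset(
    {"", "na", "n/a", "nan", "#n/a", "[not available]", "[not applicable]",
     "[unknown]", "[discrepancy]"}
)

#: tumor_status values that directly indicate metastasis (rule r1).
DEFAULT_METASTASIS_STATUS = frozenset({"METASTASIS", "METASTATIC"})

REQUIRED_COLUMNS = (
    "case_id",
    "cancer_type",
    "tumor_status",
    "new_tumor_event_type",
    "new_tumor_event_site",
    "pfi_time",
)

DEFAULT_ALIASES: dict[str, tuple[str, ...]] = {
    "case_id": ("case_id", "bcr_patient_barcode", "patient_id"),
    "cancer_type": ("cancer_type", "type", "acronym"),
    "tumor_status": ("tumor_status",),
    "new_tumor_event_type": ("new_tumor_event_type",),
    "new_tumor_event_site": ("new_tumor_event_site",),
    "pfi_time": ("pfi.time", "pfi_time", "pfi time"),
}


@dataclass(frozen=True)
class ClinicalRecord:
    case_id: str
    cancer_type: str
    tumor_status: str | None  # upper-cased, None if missing
    new_tumor_event_type: str | None  # upper-cased, None if missing
    new_tumor_event_site: str | None
    pfi_time: float | None  # days


@dataclass(frozen=True)
class LabeledCase:
    case_id: str
    cancer_type: str
    label: int  # 1 = metastasis, 0 = non-metastasis
    pfi_time: float | None


@dataclass
class LabeledCohort:
    """Labeled cases plus every excluded case with its reason.

    ``entries`` and ``excluded`` always partition the input records.
    """

    entries: list[LabeledCase] = field(default_factory=list)
    excluded: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_cases(self) -> int:
        return len(self.entries) + len(self.excluded)

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.case_id, e.cancer_type, e.label, e.pfi_time, 1) for e in self.entries],
            columns=["case_id", "cancer_type", "label", "pfi_time", "retained"],
        )

    def exclusions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.excluded, columns=["case_id", "reason"])


def _normalize_cell(value: object) -> str | None:
    text = str(value).strip()
    if text.lower() in NA_TOKENS:
        return None
    return text


def parse_clinical_table(
    path: str | Path,
    aliases: Mapping[str, Sequence[str]] | None = None,
) -> list[ClinicalRecord]:
    """Parse a clinical TSV into normalized records.

    Column names are matched case-insensitively against ``aliases`` (the
    TCGA-CDR names such as ``PFI.time`` are accepted by default).  Literal
    "NA", "[Not Available]" and empty cells become missing values; status and
    event values are upper-cased for case-insensitive matching downstream.
    """
    alias_map = dict(DEFAULT_ALIASES)
    if aliases:
        for key, names in aliases.items():
            alias_map[key] = tuple(names)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    lower_cols = {c.lower(): c for c in df.columns}
    resolved: dict[str, str] = {}
    for field_name in REQUIRED_COLUMNS:
        for candidate in alias_map[field_name]:
            if candidate.lower() in lower_cols:
                resolved[field_name] = lower_cols[candidate.lower()]
                break
        else:
            raise SchemaError(
                f"{path}: missing required column {field_name!r} "
                f"(accepted names: {', '.join(alias_map[field_name])})"
            )

    records: list[ClinicalRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        case_id = _normalize_cell(row[resolved["case_id"]])
        if case_id is None:
            raise SchemaError(f"{path}: empty case_id")
        if case_id in seen:
            raise SchemaError(f"{path}: duplicate case_id {case_id!r}")
        seen.add(case_id)
        status = _normalize_cell(row[resolved["tumor_status"]])
        event = _normalize_cell(row[resolved["new_tumor_event_type"]])
        site = _normalize_cell(row[resolved["new_tumor_event_site"]])
        pfi_raw = _normalize_cell(row[resolved["pfi_time"]])
        pfi: float | None = None
        if pfi_raw is not None:
            try:
                pfi = float(pfi_raw)
            except ValueError as err:
                raise SchemaError(
                    f"{path}: non-numeric PFI.time {pfi_raw!r} for case {case_id!r}"
                ) from err
            if pfi < 0:
                raise SchemaError(
                    f"{path}: negative PFI.time {pfi} for case {case_id!r}"
                )
        records.append(
            ClinicalRecord(
                case_id=case_id,
                cancer_type=_normalize_cell(row[resolved["cancer_type"]]) or "NA",
                tumor_status=status.upper() if status else None,
                new_tumor_event_type=event.upper() if event else None,
                new_tumor_event_site=site,
                pfi_time=pfi,
            )
        )
    return records


def assign_metastasis_labels(
    records: Iterable[ClinicalRecord],
    metastasis_status_values: frozenset[str] | set[str] = DEFAULT_METASTASIS_STATUS,
) -> LabeledCohort:
    """Apply the r1/r2/r3 positive rules and the tumor-free negative rule.

    Every input record lands either in ``entries`` (label 0/1) or in
    ``excluded`` with a reason; nothing is dropped silently.
    """
    status_vocab = {s.upper() for s in metastasis_status_values}
    cohort = LabeledCohort()
    for r in records:
        status_unclear = r.tumor_status is None or r.tumor_status == "NOT CLEAR"
        if r.tumor_status is not None and r.tumor_status in status_vocab:
            cohort.entries.append(LabeledCase(r.case_id, r.cancer_type, 1, r.pfi_time))
        elif status_unclear and r.new_tumor_event_type == "METASTASIS":
            cohort.entries.append(LabeledCase(r.case_id, r.cancer_type, 1, r.pfi_time))
        elif (
            status_unclear
            and r.new_tumor_event_type is None
            and r.new_tumor_event_site is not None
        ):
            cohort.entries.append(LabeledCase(r.case_id, r.cancer_type, 1, r.pfi_time))
        elif status_unclear:
            cohort.excluded.append((r.case_id, "unclear_tumor_status"))
        elif r.new_tumor_event_type is None and r.tumor_status == "TUMOR FREE":
            cohort.entries.append(LabeledCase(r.case_id, r.cancer_type, 0, r.pfi_time))
        else:
            cohort.excluded.append((r.case_id, "ambiguous_non_metastasis"))
    return cohort


def retain_longest_nonmet(
    cohort: LabeledCohort,
    fraction: float = 0.70,
    *,
    per_cancer: bool = False,
) -> LabeledCohort:
    """Keep the longest-followed fraction of non-metastasis cases.

    Metastasis cases are kept unconditionally.  Non-metastasis cases missing
    a PFI time are excluded first (reason ``missing_pfi``); the rest are
    ranked by PFI time descending (ties broken by case_id ascending) and the
    top ``floor(fraction * n0)`` are kept, the remainder excluded with reason
    ``pfi_retention``.  The ranking is global by default; ``per_cancer``
    applies the filter within each cancer type instead.
    """
    if not (0.0 < fraction <= 1.0):
        raise InvalidInputError(f"retention fraction must be in (0, 1], got {fraction}")
    out = LabeledCohort(excluded=list(cohort.excluded))
    positives = [e for e in cohort.entries if e.label == 1]
    negatives = [e for e in cohort.entries if e.label == 0]
    out.entries.extend(positives)
    with_pfi = [e for e in negatives if e.pfi_time is not None]
    for e in negatives:
        if e.pfi_time is None:
            out.excluded.append((e.case_id, "missing_pfi"))

    def _filter(group: list[LabeledCase]) -> None:
        ranked = sorted(group, key=lambda e: (-e.pfi_time, e.case_id))
        n_keep = math.floor(fraction * len(ranked))
        out.entries.extend(ranked[:n_keep])
        out.excluded.extend((e.case_id, "pfi_retention") for e in ranked[n_keep:])

    if per_cancer:
        by_type: dict[str, list[LabeledCase]] = {}
        for e in with_pfi:
            by_type.setdefault(e.cancer_type, []).append(e)
        for cancer_type in sorted(by_type):
            _filter(by_type[cancer_type])
    else:
        _filter(with_pfi)
    return out


def label_cohort(
    records: Iterable[ClinicalRecord],
    fraction: float = 0.70,
    *,
    per_cancer: bool = False,
    metastasis_status_values: frozenset[str] | set[str] = DEFAULT_METASTASIS_STATUS,
) -> LabeledCohort:
    """Convenience wrapper: label assignment followed by PFI retention."""
    cohort = assign_metastasis_labels(records, metastasis_status_values)
    return retain_longest_nonmet(cohort, fraction, per_cancer=per_cancer)


def write_labeled_cohort(cohort: LabeledCohort, path: str | Path) -> None:
    cohort.labels_frame().to_csv(path, sep="\t", index=False)


def write_exclusion_report(cohort: LabeledCohort, path: str | Path) -> None:
    cohort.exclusions_frame().to_csv(path, sep="\t", index=False)
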