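"""Record and feature filtering plus multimodal merging.

The filters mirror the cohort-construction rules used for clinical +
volumetric-MRI dementia cohorts: per-subject baseline-visit selection,
exclusion of features with more than a given fraction missing, removal of
incomplete records, an age floor, and a scan-within-window merge between two
modalities. All filters are pure functions on :class:`~fusebench.cohort.ModalityTable`
and record what they dropped in an optional :class:`PreprocessReport`.

Reading of the rules (kept strict and literal):

* "more than 10 percent missing" excludes, i.e. features with missing
  fraction <= threshold are KEPT;
* "over the age of 65" keeps age > 65 (strict);
* the scan-merge window "18 months" is interpreted as 548 days
  (365.25 * 1.5, rounded), with |date_a - date_b| <= window kept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import DataError
from .cohort import LabeledCohort, ModalityTable, code_labels

#: Default merge window: 18 months as days (365.25 * 1.5, rounded).
DEFAULT_WINDOW_DAYS = 548


@dataclass
class PreprocessReport:
    """Per-stage bookkeeping of rows/columns dropped during preprocessing."""

    stages: list[dict] = field(default_factory=list)

    def record(self, stage: str, table: str, **counts) -> None:
        self.stages.append({"stage": stage, "table": table, **counts})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.stages, fh, indent=2)


def filter_missing_features(
    table: ModalityTable, max_missing_frac: float, report: PreprocessReport | None = None
) -> ModalityTable:
    """Keep exactly the features whose missing fraction is <= ``max_missing_frac``.

    Feature order is preserved; the dropped-feature list goes into ``report``.
    """
    if not 0.0 <= max_missing_frac <= 1.0:
        raise DataError(f"max_missing_frac must be in [0, 1], got {max_missing_frac}")
    if table.n_subjects == 0 or table.n_features == 0:
        raise DataError(f"modality {table.name!r}: empty table")
    frac = table.data.isna().mean(axis=0)
    keep = frac.index[frac.to_numpy() <= max_missing_frac]
    dropped = [c for c in table.data.columns if c not in set(keep)]
    if report is not None:
        report.record(
            "filter_missing_features",
            table.name,
            n_features_before=table.n_features,
            n_features_after=len(keep),
            dropped_features=dropped,
        )
    return ModalityTable(table.name, table.data.loc[:, keep], table.visit_dates)


def drop_incomplete_records(
    table: ModalityTable, report: PreprocessReport | None = None
) -> ModalityTable:
    """Remove every subject row containing any missing entry."""
    mask = ~table.data.isna().any(axis=1).to_numpy()
    if not mask.any():
        raise DataError(f"modality {table.name!r}: all records incomplete")
    dates = None if table.visit_dates is None else table.visit_dates[mask]
    out = ModalityTable(table.name, table.data.loc[mask], dates)
    if report is not None:
        report.record(
            "drop_incomplete_records",
            table.name,
            n_rows_before=table.n_subjects,
            n_rows_after=out.n_subjects,
        )
    return out


def select_baseline_visit(
    table: ModalityTable, report: PreprocessReport | None = None
) -> ModalityTable:
    """Keep each subject's earliest-dated visit (one row per subject)."""
    if table.visit_dates is None:
        raise DataError(f"modality {table.name!r}: visit dates required for baseline selection")
    dates = pd.to_datetime(pd.Series(np.asarray(table.visit_dates), index=table.data.index))
    counts = table.data.index.value_counts()
    multi = counts.index[counts > 1]
    if dates.loc[multi].isna().any() if len(multi) else False:
        bad = sorted(set(dates.loc[multi].index[dates.loc[multi].isna()]))
        raise DataError(
            f"modality {table.name!r}: missing visit dates for multi-visit subjects {bad}"
        )
    order = np.arange(len(table.data))
    frame = pd.DataFrame(
        {"_date": dates.to_numpy(), "_pos": order}, index=table.data.index
    )
    # earliest date per subject; ties broken by original row order
    pos = (
        frame.sort_values(["_date", "_pos"], kind="stable")
        .groupby(level=0, sort=False)
        .head(1)["_pos"]
        .sort_values()
        .to_numpy()
    )
    out = ModalityTable(
        table.name,
        table.data.iloc[pos],
        pd.Series(dates.to_numpy()[pos], index=table.data.index[pos]),
    )
    if report is not None:
        report.record(
            "select_baseline_visit",
            table.name,
            n_rows_before=table.n_subjects,
            n_rows_after=out.n_subjects,
        )
    return out


def filter_age(
    table: ModalityTable,
    min_age_years: float,
    age_column: str = "age",
    report: PreprocessReport | None = None,
) -> ModalityTable:
    """Keep subjects strictly older than ``min_age_years`` ("over the age of N")."""
    if age_column not in table.data.columns:
        raise DataError(f"modality {table.name!r}: no age column {age_column!r}")
    mask = (table.data[age_column] > min_age_years).to_numpy()
    dates = None if table.visit_dates is None else table.visit_dates[mask]
    out = ModalityTable(table.name, table.data.loc[mask], dates)
    if report is not None:
        report.record(
            "filter_age",
            table.name,
            n_rows_before=table.n_subjects,
            n_rows_after=out.n_subjects,
        )
    return out


def merge_within_window(
    a: ModalityTable,
    b: ModalityTable,
    window_days: int = DEFAULT_WINDOW_DAYS,
    report: PreprocessReport | None = None,
) -> tuple[ModalityTable, ModalityTable]:
    """Keep subjects present in both tables with |date_a - date_b| <= window.

    When a subject has several eligible visit/scan pairs the pair with the
    minimal date gap wins; remaining ties go to the earliest ``a`` date, then
    the earliest ``b`` date. Returned tables are row-aligned on subject id.
    """
    if a.visit_dates is None or b.visit_dates is None:
        raise DataError("merge_within_window requires visit dates on both tables")
    da = pd.to_datetime(pd.Series(np.asarray(a.visit_dates)))
    db = pd.to_datetime(pd.Series(np.asarray(b.visit_dates)))
    fa = pd.DataFrame({"sid": a.data.index, "date_a": da.to_numpy(), "pos_a": range(len(da))})
    fb = pd.DataFrame({"sid": b.data.index, "date_b": db.to_numpy(), "pos_b": range(len(db))})
    pairs = fa.merge(fb, on="sid")
    if len(pairs):
        gap = (pairs["date_a"] - pairs["date_b"]).abs().dt.days
        pairs = pairs.assign(gap=gap)
        pairs = pairs[pairs["gap"] <= window_days]
    if not len(pairs):
        raise DataError(
            f"no subject has paired {a.name!r}/{b.name!r} records within {window_days} days"
        )
    best = (
        pairs.sort_values(["gap", "date_a", "date_b"], kind="stable")
        .groupby("sid", sort=True)
        .head(1)
        .sort_values("sid")
    )
    ia = best["pos_a"].to_numpy()
    ib = best["pos_b"].to_numpy()
    out_a = ModalityTable(
        a.name, a.data.iloc[ia], pd.Series(da.to_numpy()[ia], index=a.data.index[ia])
    )
    out_b = ModalityTable(
        b.name, b.data.iloc[ib], pd.Series(db.to_numpy()[ib], index=b.data.index[ib])
    )
    if report is not None:
        report.record(
            "merge_within_window",
            f"{a.name}+{b.name}",
            window_days=window_days,
            n_rows_a_before=a.n_subjects,
            n_rows_b_before=b.n_subjects,
            n_rows_after=len(best),
        )
    return out_a, out_b


def collapse_binary(labels) -> np.ndarray:
    """Collapse 3-class diagnoses to 0 = HC, 1 = impaired (MCI or AD)."""
    return code_labels(labels, "binary")


def build_cohort(tables: list[ModalityTable], labels: pd.Series) -> LabeledCohort:
    """Assemble aligned tables + labels into a validated LabeledCohort."""
    ref_ids = tables[0].data.index
    labels = labels.reindex(ref_ids)
    if labels.isna().any():
        missing = sorted(ref_ids[labels.isna()])
        raise DataError(f"labels missing for subjects {missing[:5]}...")
    return LabeledCohort({t.name: t for t in tables}, labels)


def preprocess_pipeline(
    a: ModalityTable,
    b: ModalityTable,
    labels: pd.Series,
    max_missing_frac: float = 0.10,
    min_age_years: float = 65.0,
    age_column: str | None = "age",
    window_days: int = DEFAULT_WINDOW_DAYS,
    report: PreprocessReport | None = None,
) -> LabeledCohort:
    """Run the full preprocessing chain in its fixed order.

    Order: baseline-visit selection -> feature missingness filter -> incomplete
    record drop -> age filter (on ``a`` if it carries the age column) -> merge
    within window. Row and column counts never increase at any step.
    """
    out = []
    for t in (a, b):
        t = select_baseline_visit(t, report)
        t = filter_missing_features(t, max_missing_frac, report)
        t = drop_incomplete_records(t, report)
        if age_column is not None and age_column in t.data.columns:
            t = filter_age(t, min_age_years, age_column, report)
        out.append(t)
    a2, b2 = merge_within_window(out[0], out[1], window_days, report)
    return build_cohort([a2, b2], labels)
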