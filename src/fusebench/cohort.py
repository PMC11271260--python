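"""Core in-memory containers: per-modality feature tables and labeled cohorts.

A :class:`ModalityTable` holds one modality's subject-by-feature numeric matrix
(a pandas DataFrame indexed by subject id, possibly with repeated subjects
before baseline-visit selection) plus optional visit dates. A
:class:`LabeledCohort` is a set of row-aligned modality tables together with a
per-subject three-class diagnosis label (HC / MCI / AD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import DataError

#: Canonical diagnosis labels, in disease-severity order.
LABELS = ("HC", "MCI", "AD")

#: Integer codes for the multiclass task (severity-ordered).
LABEL_CODES = {lab: i for i, lab in enumerate(LABELS)}


@dataclass
class ModalityTable:
    """One modality's subject-by-feature numeric matrix.

    Parameters
    ----------
    name : str
        Modality name (e.g. ``"clinical"``, ``"imaging"``).
    data : pandas.DataFrame
        Numeric feature matrix, index = subject id. The index may contain
        repeated subjects until baseline-visit selection has run.
    visit_dates : pandas.Series, optional
        Visit date per row, positionally aligned with ``data``.
    """

    name: str
    data: pd.DataFrame
    visit_dates: pd.Series | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise DataError(f"modality {self.name!r}: data must be a DataFrame")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise DataError(f"modality {self.name!r}: duplicate feature names {dupes}")
        if self.visit_dates is not None and len(self.visit_dates) != len(self.data):
            raise DataError(
                f"modality {self.name!r}: visit_dates length {len(self.visit_dates)}"
                f" != row count {len(self.data)}"
            )

    # -- convenience accessors -------------------------------------------------
    @property
    def subject_ids(self) -> np.ndarray:
        return self.data.index.to_numpy()

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def copy(self) -> "ModalityTable":
        return ModalityTable(
            name=self.name,
            data=self.data.copy(),
            visit_dates=None if self.visit_dates is None else self.visit_dates.copy(),
        )


@dataclass
class LabeledCohort:
    """Aligned multimodal dataset with per-subject diagnosis labels.

    Every modality table must hold one row per subject, in the identical
    subject order, with no missing entries; ``labels`` is a Series indexed the
    same way with values in :data:`LABELS`.
    """

    modalities: dict[str, ModalityTable] = field(default_factory=dict)
    labels: pd.Series = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.modalities:
            raise DataError("cohort has no modalities")
        if self.labels is None:
            raise DataError("cohort has no labels")
        ref = next(iter(self.modalities.values()))
        ref_ids = ref.data.index
        if ref_ids.duplicated().any():
            raise DataError("cohort subject ids are not unique")
        for name, tab in self.modalities.items():
            if not tab.data.index.equals(ref_ids):
                raise DataError(f"modality {name!r} subject order differs from others")
            if tab.data.isna().any().any():
                raise DataError(f"modality {name!r} contains missing entries")
        if not self.labels.index.equals(ref_ids):
            raise DataError("label index does not match modality subject order")
        bad = set(self.labels.unique()) - set(LABELS)
        if bad:
            raise DataError(f"unknown diagnosis labels: {sorted(bad)}")

    @property
    def subject_ids(self) -> np.ndarray:
        return next(iter(self.modalities.values())).subject_ids

    @property
    def n_subjects(self) -> int:
        return len(self.labels)

    def modality_names(self) -> list[str]:
        return list(self.modalities)

    def X(self, modality: str) -> np.ndarray:
        return self.modalities[modality].values()


def code_labels(labels, task: str) -> np.ndarray:
    """Encode diagnosis labels for a prediction task.

    ``task="multiclass"`` maps HC/MCI/AD to 0/1/2 (severity order);
    ``task="binary"`` collapses to 0 = HC, 1 = impaired (MCI or AD).
    """
    arr = np.asarray(labels)
    out = np.empty(arr.shape[0], dtype=int)
    for i, lab in enumerate(arr):
        if lab not in LABEL_CODES:
            raise DataError(f"unknown diagnosis label {lab!r}")
        out[i] = LABEL_CODES[lab]
    if task == "binary":
        return (out > 0).astype(int)
    if task == "multiclass":
        return out
    raise DataError(f"unknown task {task!r}")
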