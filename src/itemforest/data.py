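"""Core data containers: ordinal item matrices, labels, and their on-disk forms.

The package operates on a subjects x items grid of ordinal instrument codes
(ADOS and/or ADI-R items), a binary diagnostic label per subject (ASD vs
non-ASD), and per-item metadata (instrument, code range, simulated effect
size). Matrices are written as TSV with a JSON metadata sidecar; labels as a
two-column TSV. Missing codes use the reserved sentinel ``MISSING`` (-1) in
memory and ``NA`` on disk.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Reserved in-memory sentinel for a missing code (outside every code range).
MISSING: int = -1

ASD = "ASD"
NON_ASD = "NON_ASD"


class Instrument(str, Enum):
    """Which diagnostic instrument an item belongs to."""

    ADOS = "ADOS"
    ADI_R = "ADI_R"


class ValidationError(ValueError):
    """An input object violates its declared invariants."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but statistically degenerate (e.g. one class)."""


@dataclass(frozen=True)
class ItemDefinition:
    """One ordinal instrument item.

    Parameters
    ----------
    item_id:
        Unique short token, e.g. ``"ados_03"``.
    instrument:
        ``Instrument.ADOS`` or ``Instrument.ADI_R``.
    n_levels:
        Number of ordinal codes; codes run ``0 .. n_levels - 1``.
    shift:
        Ordered-logit location shift applied to the ASD group when the item is
        simulated. 0 means the item carries no diagnostic signal.
    """

    item_id: str
    instrument: Instrument
    n_levels: int = 3
    shift: float = 0.0

    def validate(self) -> None:
        if not self.item_id:
            raise ValidationError("item_id must be a non-empty token")
        if self.n_levels < 2:
            raise ValidationError(
                f"item {self.item_id!r}: n_levels must be >= 2, got {self.n_levels}"
            )
        if not np.isfinite(self.shift):
            raise ValidationError(f"item {self.item_id!r}: shift must be finite")

    def to_dict(self) -> dict:
        return {
            "item_id": self.item_id,
            "instrument": self.instrument.value,
            "n_levels": self.n_levels,
            "shift": self.shift,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ItemDefinition":
        return cls(
            item_id=str(d["item_id"]),
            instrument=Instrument(d["instrument"]),
            n_levels=int(d["n_levels"]),
            shift=float(d.get("shift", 0.0)),
        )


@dataclass
class ItemMatrix:
    """Subjects x items grid of ordinal codes with item metadata.

    ``codes[i, j]`` is the code of subject ``subject_ids[i]`` on item
    ``item_ids[j]``, or :data:`MISSING`.
    """

    subject_ids: list[str]
    item_ids: list[str]
    codes: np.ndarray
    item_meta: dict[str, ItemDefinition] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.shape != (len(self.subject_ids), len(self.item_ids)):
            raise ValidationError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.item_ids)} items"
            )
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValidationError("subject_ids must be unique")
        if len(set(self.item_ids)) != len(self.item_ids):
            raise ValidationError("item_ids must be unique")
        for j, item_id in enumerate(self.item_ids):
            meta = self.item_meta.get(item_id)
            if meta is None:
                continue
            col = self.codes[:, j]
            obs = col[col != MISSING]
            if obs.size and (obs.min() < 0 or obs.max() >= meta.n_levels):
                raise ValidationError(
                    f"item {item_id!r}: codes outside 0..{meta.n_levels - 1}"
                )

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    def column(self, item_id: str) -> np.ndarray:
        try:
            j = self.item_ids.index(item_id)
        except ValueError:
            raise KeyError(f"item {item_id!r} not present") from None
        return self.codes[:, j]

    def subset(
        self,
        subject_ids: Sequence[str] | None = None,
        item_ids: Sequence[str] | None = None,
    ) -> "ItemMatrix":
        """Restrict to the given subjects and/or items, preserving order given."""
        sub = list(subject_ids) if subject_ids is not None else self.subject_ids
        items = list(item_ids) if item_ids is not None else self.item_ids
        sidx = {s: i for i, s in enumerate(self.subject_ids)}
        iidx = {t: j for j, t in enumerate(self.item_ids)}
        missing_s = [s for s in sub if s not in sidx]
        if missing_s:
            raise KeyError(f"unknown subject ids: {missing_s[:5]}")
        missing_i = [t for t in items if t not in iidx]
        if missing_i:
            raise KeyError(f"unknown item ids: {missing_i[:5]}")
        rows = [sidx[s] for s in sub]
        cols = [iidx[t] for t in items]
        return ItemMatrix(
            subject_ids=sub,
            item_ids=items,
            codes=self.codes[np.ix_(rows, cols)],
            item_meta={t: self.item_meta[t] for t in items if t in self.item_meta},
        )

    def complete_case_ids(self, item_ids: Sequence[str] | None = None) -> list[str]:
        """Subjects with no missing code among ``item_ids`` (default: all items)."""
        sub = self if item_ids is None else self.subset(item_ids=item_ids)
        keep = ~(sub.codes == MISSING).any(axis=1)
        return [s for s, k in zip(sub.subject_ids, keep) if k]

    def items_for(self, instrument: Instrument) -> list[str]:
        return [
            t
            for t in self.item_ids
            if t in self.item_meta and self.item_meta[t].instrument == instrument
        ]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.codes, columns=self.item_ids)
        df.insert(0, "subject_id", self.subject_ids)
        return df


@dataclass
class CohortLabels:
    """Binary diagnostic label (ASD / NON_ASD) per subject."""

    by_subject: dict[str, str]

    def __post_init__(self) -> None:
        bad = {v for v in self.by_subject.values()} - {ASD, NON_ASD}
        if bad:
            raise ValidationError(f"unknown label values: {sorted(bad)}")

    def validate_against(self, subject_ids: Iterable[str]) -> None:
        ids = list(subject_ids)
        missing = [s for s in ids if s not in self.by_subject]
        extra = sorted(set(self.by_subject) - set(ids))
        if missing or extra:
            raise ValidationError(
                f"labels do not cover matrix subjects exactly "
                f"(missing {missing[:5]}, extra {extra[:5]})"
            )
        values = {self.by_subject[s] for s in ids}
        if values != {ASD, NON_ASD}:
            raise DegenerateInputError("both classes must be present")

    def is_asd(self, subject_ids: Sequence[str]) -> np.ndarray:
        """Boolean array aligned with ``subject_ids`` (True = ASD)."""
        try:
            return np.array([self.by_subject[s] == ASD for s in subject_ids])
        except KeyError as e:
            raise ValidationError(f"no label for subject {e.args[0]!r}") from None

    def subset(self, subject_ids: Sequence[str]) -> "CohortLabels":
        return CohortLabels({s: self.by_subject[s] for s in subject_ids})


# ---------------------------------------------------------------------------
# On-disk round-trip: TSV matrix + JSON metadata sidecar + TSV labels.
# ---------------------------------------------------------------------------


def write_matrix(matrix: ItemMatrix, path: str | Path, meta_path: str | Path) -> None:
    df = matrix.to_frame().astype(object)
    for col in matrix.item_ids:
        df[col] = df[col].where(df[col] != MISSING, "NA")
    df.to_csv(path, sep="\t", index=False)
    meta = {t: d.to_dict() for t, d in matrix.item_meta.items()}
    Path(meta_path).write_text(json.dumps(meta, indent=1) + "\n")


def read_matrix(path: str | Path, meta_path: str | Path | None = None) -> ItemMatrix:
    sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else None
    df = pd.read_csv(path, sep=sep, engine="python", na_values=["NA"])
    if df.columns[0] != "subject_id":
        raise ValidationError(
            f"{path}: first column must be 'subject_id', got {df.columns[0]!r}"
        )
    item_ids = list(df.columns[1:])
    codes = df[item_ids].to_numpy(dtype=float)
    codes = np.where(np.isnan(codes), MISSING, codes).astype(np.int64)
    meta: dict[str, ItemDefinition] = {}
    if meta_path is not None:
        raw = json.loads(Path(meta_path).read_text())
        meta = {t: ItemDefinition.from_dict(d) for t, d in raw.items()}
    return ItemMatrix(
        subject_ids=[str(s) for s in df["subject_id"]],
        item_ids=item_ids,
        codes=codes,
        item_meta=meta,
    )


def write_labels(labels: CohortLabels, path: str | Path) -> None:
    rows = sorted(labels.by_subject.items())
    pd.DataFrame(rows, columns=["subject_id", "label"]).to_csv(
        path, sep="\t", index=False
    )


def read_labels(path: str | Path) -> CohortLabels:
    sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else None
    df = pd.read_csv(path, sep=sep, engine="python")
    if list(df.columns[:2]) != ["subject_id", "label"]:
        raise ValidationError(f"{path}: expected columns subject_id, label")
    return CohortLabels(dict(zip(df["subject_id"].astype(str), df["label"])))


def config_to_dict(obj) -> dict:
    """Recursively convert nested dataclass configs to plain dicts (for hashing)."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: config_to_dict(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, Enum):
        return obj.value
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (list, tuple)):
        return [config_to_dict(x) for x in obj]
    if isinstance(obj, dict):
        return {k: config_to_dict(v) for k, v in obj.items()}
    return obj
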