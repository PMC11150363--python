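"""Volume and cohort I/O plus subject-level splitting.

Volumes are NIfTI-1 images read through nibabel into :class:`VolumeImage`,
a plain (x, y, z)-indexed intensity grid with voxel spacing in mm and an
optional boolean brain mask.  Cohorts are CSV manifests with one row per
scan (subject_id, scan_path, age, sex, diagnosis); splitting into
train/val/test is always done at the *subject* level so that repeated
scans of one subject can never leak across partitions.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger("brainage")

MANIFEST_COLUMNS = ("subject_id", "scan_path", "age", "sex", "diagnosis")

#: accepted spellings for the binary sex code (female=0, male=1)
SEX_ALIASES = {
    "f": 0, "female": 0, "0": 0,
    "m": 1, "male": 1, "1": 1,
}

AGE_RANGE_DEFAULT = (0.0, 120.0)


class FormatError(ValueError):
    """A file exists but does not have the expected layout."""


class SchemaError(ValueError):
    """A manifest is missing required columns or holds unparsable values."""


@dataclass
class VolumeImage:
    """A 3D intensity grid with voxel spacing and an optional brain mask.

    ``grid`` is indexed (x, y, z), 0-based.  ``spacing`` is the voxel size
    per axis in mm.  ``affine`` carries orientation metadata through
    round-trips but is never used for resampling.
    """

    grid: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    mask: Optional[np.ndarray] = None
    affine: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise FormatError(
                f"volume grid must have exactly 3 axes, got shape {self.grid.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.grid.shape:
                raise ValueError(
                    f"mask shape {self.mask.shape} != grid shape {self.grid.shape}"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def copy(self) -> "VolumeImage":
        return VolumeImage(
            grid=self.grid.copy(),
            spacing=self.spacing,
            mask=None if self.mask is None else self.mask.copy(),
            affine=None if self.affine is None else self.affine.copy(),
        )


@dataclass
class SubjectRecord:
    """One scan of one subject: identity, age at scan, sex code, diagnosis."""

    subject_id: str
    scan_path: str
    age: float
    sex: int
    diagnosis: str

    def __post_init__(self) -> None:
        lo, hi = AGE_RANGE_DEFAULT
        if not (lo <= float(self.age) <= hi):
            raise SchemaError(
                f"age {self.age} for subject {self.subject_id} outside plausible "
                f"range [{lo}, {hi}]"
            )
        if int(self.sex) not in (0, 1):
            raise SchemaError(f"sex must be 0 or 1, got {self.sex!r}")
        self.age = float(self.age)
        self.sex = int(self.sex)
        if self.diagnosis not in ("CN", "AD"):
            raise SchemaError(f"diagnosis must be CN or AD, got {self.diagnosis!r}")


@dataclass
class Cohort:
    """An ordered list of scan records plus an optional subject-level split map."""

    records: list[SubjectRecord]
    split: Optional[dict[str, str]] = None

    def __len__(self) -> int:
        return len(self.records)

    def subject_ids(self) -> list[str]:
        """Distinct subject ids in first-appearance order."""
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.subject_id, None)
        return list(seen)

    def subset(self, partition: str) -> "Cohort":
        """Records whose subject is assigned to the given partition."""
        if self.split is None:
            raise ValueError("cohort has no split assignment")
        recs = [r for r in self.records if self.split.get(r.subject_id) == partition]
        return Cohort(records=recs, split={r.subject_id: partition for r in recs})

    def ages(self) -> np.ndarray:
        return np.array([r.age for r in self.records], dtype=float)

    def sexes(self) -> np.ndarray:
        return np.array([r.sex for r in self.records], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "subject_id": [r.subject_id for r in self.records],
                "scan_path": [r.scan_path for r in self.records],
                "age": [r.age for r in self.records],
                "sex": [r.sex for r in self.records],
                "diagnosis": [r.diagnosis for r in self.records],
            }
        )
        if self.split is not None:
            df["split"] = [self.split.get(r.subject_id, "") for r in self.records]
        return df


# ---------------------------------------------------------------------------
# volume I/O


def read_volume(path: str | os.PathLike) -> VolumeImage:
    """Read a NIfTI volume; a trailing singleton 4th axis is squeezed."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"{path} is not a readable NIfTI image: {exc}") from exc
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(
            f"{path}: expected a 3D payload after squeezing, got shape {data.shape}"
        )
    zooms = img.header.get_zooms()[:3]
    return VolumeImage(grid=np.asarray(data), spacing=tuple(float(z) for z in zooms),
                       affine=np.asarray(img.affine))


def write_volume(vol: VolumeImage, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI-1; spacing goes into the header zooms."""
    path = Path(path)
    affine = vol.affine if vol.affine is not None else np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(vol.grid, dtype=np.float32), affine)
    img.header.set_zooms(vol.spacing)
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise IOError(f"cannot write volume to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# manifests


def _parse_sex(value) -> int:
    key = str(value).strip().lower()
    if key not in SEX_ALIASES:
        raise SchemaError(f"unrecognised sex code {value!r} (accepted: F/M, female/male, 0/1)")
    return SEX_ALIASES[key]


def load_manifest(path: str | os.PathLike) -> Cohort:
    """Load a cohort manifest CSV, preserving row order.

    Required columns: subject_id, scan_path, age, sex, diagnosis.  Sex may be
    coded "F"/"M", "female"/"male" or 0/1 (female=0, male=1).  Duplicate
    (subject_id, scan_path) rows are kept with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"manifest {path} is missing columns: {missing}")
    records = []
    for i, row in df.iterrows():
        try:
            age = float(row["age"])
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"row {i}: unparsable age {row['age']!r}") from exc
        try:
            records.append(
                SubjectRecord(
                    subject_id=str(row["subject_id"]),
                    scan_path=str(row["scan_path"]),
                    age=age,
                    sex=_parse_sex(row["sex"]),
                    diagnosis=str(row["diagnosis"]).strip(),
                )
            )
        except SchemaError as exc:
            raise SchemaError(f"row {i}: {exc}") from exc
    pairs = [(r.subject_id, r.scan_path) for r in records]
    if len(set(pairs)) != len(pairs):
        logger.warning("manifest %s contains duplicate (subject_id, scan_path) rows; keeping all", path)
    cohort = Cohort(records=records)
    if "split" in df.columns:
        split: dict[str, str] = {}
        for r, lab in zip(records, df["split"]):
            lab = str(lab)
            if split.setdefault(r.subject_id, lab) != lab:
                raise SchemaError(
                    f"subject {r.subject_id} carries conflicting split labels"
                )
        cohort.split = split
    return cohort


def save_manifest(cohort: Cohort, path: str | os.PathLike) -> None:
    cohort.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# splitting


def split_subjects(
    cohort: Cohort,
    test_fraction: float = 0.25,
    val_fraction: float = 0.10,
    seed: int = 0,
) -> Cohort:
    """Assign every subject (hence every scan) to train/val/test.

    The assignment is by subject, never by scan: all scans of one subject get
    the same label.  ``|test|`` is ``round(test_fraction * n_subjects)`` and
    likewise for val; the remainder trains.  Deterministic for a fixed seed.
    """
    if not (0 < test_fraction < 1) or not (0 <= val_fraction < 1):
        raise ValueError("test_fraction must be in (0,1) and val_fraction in [0,1)")
    if test_fraction + val_fraction >= 1:
        raise ValueError(
            f"test_fraction + val_fraction = {test_fraction + val_fraction} >= 1"
        )
    subjects = cohort.subject_ids()
    if len(subjects) < 3:
        raise ValueError(f"need at least 3 distinct subjects, got {len(subjects)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    n_test = int(round(test_fraction * len(subjects)))
    n_val = int(round(val_fraction * len(subjects)))
    split: dict[str, str] = {}
    for rank, idx in enumerate(order):
        if rank < n_test:
            label = "test"
        elif rank < n_test + n_val:
            label = "val"
        else:
            label = "train"
        split[subjects[idx]] = label
    return replace(cohort, split=split)
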