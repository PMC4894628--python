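"""Core domain types and per-slice HDF5 I/O.

A dataset is a directory of per-slice HDF5 containers, each holding the
fields ``image`` (2-D grayscale raster), ``tumorMask`` (binary raster of the
same shape), ``label`` (small integer class id) and ``PID`` (patient
identifier string).  The same reader also accepts the layout of the public
brain CE-MRI benchmark, where these fields live under a ``cjdata`` group and
the PID is stored as a character-code array.

Intensities are preserved exactly as stored; the pipeline converts to
float64 internally but the reader never rescales.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np

__all__ = [
    "TumorCase",
    "Cohort",
    "DatasetFormatError",
    "ValidationError",
    "read_dataset_case",
    "write_case",
    "read_cohort",
    "write_cohort",
]


class DatasetFormatError(ValueError):
    """A container file does not have the expected fields/layout."""


class ValidationError(ValueError):
    """A case violates a domain invariant (shape mismatch, empty mask, ...)."""


@dataclass
class TumorCase:
    """One 2-D slice: image, binary tumor mask, class label, patient id.

    The mask must match the image shape and contain at least one foreground
    pixel.  ``label`` is a small integer (for the public benchmark:
    1 = meningioma, 2 = glioma, 3 = pituitary tumor).
    """

    image: np.ndarray
    tumor_mask: np.ndarray
    label: int
    patient_id: str

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        self.tumor_mask = np.asarray(self.tumor_mask).astype(bool)
        if self.image.ndim != 2:
            raise ValidationError(f"image must be 2-D, got ndim={self.image.ndim}")
        if self.tumor_mask.shape != self.image.shape:
            raise ValidationError(
                f"mask shape {self.tumor_mask.shape} != image shape {self.image.shape}"
            )
        if not self.tumor_mask.any():
            raise ValidationError("tumor mask has no foreground pixel")
        self.label = int(self.label)
        self.patient_id = str(self.patient_id)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TumorCase):
            return NotImplemented
        return (
            np.array_equal(self.image, other.image)
            and np.array_equal(self.tumor_mask, other.tumor_mask)
            and self.label == other.label
            and self.patient_id == other.patient_id
        )


@dataclass
class Cohort:
    """An ordered collection of cases with a consistent class set.

    Each patient carries exactly one class label; a patient whose slices
    disagree on the label is rejected.
    """

    cases: list[TumorCase]
    class_set: frozenset[int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.cases = list(self.cases)
        labels = {c.label for c in self.cases}
        if self.class_set is None:
            self.class_set = frozenset(labels)
        else:
            self.class_set = frozenset(self.class_set)
            extra = labels - self.class_set
            if extra:
                raise ValidationError(f"labels {sorted(extra)} outside class set")
        per_patient: dict[str, int] = {}
        for c in self.cases:
            prev = per_patient.setdefault(c.patient_id, c.label)
            if prev != c.label:
                raise ValidationError(
                    f"patient {c.patient_id!r} has conflicting labels {prev} and {c.label}"
                )

    def __len__(self) -> int:
        return len(self.cases)

    def __iter__(self):
        return iter(self.cases)

    @property
    def labels(self) -> np.ndarray:
        return np.array([c.label for c in self.cases], dtype=int)

    @property
    def patient_ids(self) -> list[str]:
        return [c.patient_id for c in self.cases]


_FIELDS = ("image", "tumorMask", "label", "PID")


def _decode_pid(raw) -> str:
    arr = np.asarray(raw)
    if arr.dtype.kind in "SU":
        flat = arr.ravel()
        return "".join(x.decode() if isinstance(x, bytes) else str(x) for x in flat)
    if arr.dtype.kind in "iuf":
        # benchmark layout: PID stored as a column of character codes
        return "".join(chr(int(v)) for v in arr.ravel())
    raise DatasetFormatError(f"cannot decode PID of dtype {arr.dtype}")


def read_dataset_case(path: str | os.PathLike) -> TumorCase:
    """Read one per-slice container, validating shape and mask invariants.

    Accepts either this package's native layout (fields at the file root)
    or the public benchmark layout (fields under a ``cjdata`` group).
    """
    with h5py.File(path, "r") as f:
        root = f["cjdata"] if "cjdata" in f else f
        for name in _FIELDS:
            if name not in root:
                raise DatasetFormatError(f"{path}: missing field {name!r}")
        image = np.asarray(root["image"])
        mask = np.asarray(root["tumorMask"])
        label = int(np.asarray(root["label"]).ravel()[0])
        pid = _decode_pid(root["PID"][()])
    return TumorCase(image=image, tumor_mask=mask, label=label, patient_id=pid)


def write_case(case: TumorCase, path: str | os.PathLike) -> None:
    """Write a case to the native per-slice HDF5 layout (round-trip safe)."""
    if not isinstance(case, TumorCase):
        raise TypeError("write_case expects a TumorCase")
    with h5py.File(path, "w") as f:
        f.create_dataset("image", data=case.image)
        f.create_dataset("tumorMask", data=case.tumor_mask.astype(np.uint8))
        f.create_dataset("label", data=np.array([case.label], dtype=np.int64))
        f.create_dataset("PID", data=np.bytes_(case.patient_id))


def write_cohort(cohort: Cohort, out_dir: str | os.PathLike) -> list[Path]:
    """Write one file per slice (``case_0000.h5``, ...) and return the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, case in enumerate(cohort):
        p = out / f"case_{i:04d}.h5"
        write_case(case, p)
        paths.append(p)
    return paths


def read_cohort(data_dir: str | os.PathLike, pattern: str = "*.h5") -> Cohort:
    """Read every per-slice file in a directory, in sorted filename order."""
    paths = sorted(Path(data_dir).glob(pattern))
    if not paths:
        raise DatasetFormatError(f"no {pattern} files found in {data_dir}")
    return Cohort(cases=[read_dataset_case(p) for p in paths])
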