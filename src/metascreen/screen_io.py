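"""Data containers and tabular I/O shared by every pipeline stage.

The universal input is a :class:`ScreenTable`: a samples x ions intensity
matrix from flow-injection TOF mass spectrometry joined to per-sample
metadata (plate, batch, injection order, OD600, treatment identity, inducer
dose, timepoint, genotype, replicate).  Intensity files are tab-separated
UTF-8 with a header row of ion identifiers and a leading ``sample_id``
column; empty cells are recorded as missing (NaN), which is distinct from
zero and is excluded pairwise from downstream regressions and correlations.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

TREATMENT_CLASSES = ("drug", "overexpression", "vehicle_control", "wt_control")

#: metadata columns, one per SampleMeta field (sample_id is the index)
META_COLUMNS = (
    "plate_id",
    "batch_id",
    "injection_index",
    "od600",
    "treatment_class",
    "treatment_id",
    "dose",
    "timepoint",
    "genotype",
    "replicate",
)


class ScreenError(ValueError):
    """Structural problem in screen data or metadata."""


@dataclasses.dataclass(frozen=True)
class SampleMeta:
    """Per-sample annotation.

    ``dose`` is the inducer concentration in nM (0 for uninduced or vehicle
    wells); ``timepoint`` is hours of treatment before extraction;
    ``od600`` is the culture optical density at sampling.
    """

    sample_id: str
    plate_id: str
    batch_id: str
    injection_index: int
    od600: float
    treatment_class: str
    treatment_id: str
    dose: float
    timepoint: float
    genotype: str
    replicate: int

    def __post_init__(self) -> None:
        if self.treatment_class not in TREATMENT_CLASSES:
            raise ScreenError(
                f"unknown treatment_class {self.treatment_class!r} "
                f"for sample {self.sample_id!r}"
            )
        if self.od600 <= 0:
            raise ScreenError(f"od600 must be positive for {self.sample_id!r}")
        if self.dose < 0:
            raise ScreenError(f"dose must be non-negative for {self.sample_id!r}")
        if self.treatment_class == "vehicle_control" and self.dose != 0:
            raise ScreenError(
                f"vehicle_control sample {self.sample_id!r} must have dose 0"
            )


@dataclasses.dataclass
class ScreenTable:
    """Samples x ions intensity matrix plus aligned metadata.

    ``intensities`` is indexed by sample_id with ion identifiers as columns;
    NaN marks a flagged-missing measurement.  ``meta`` is indexed by
    sample_id with :data:`META_COLUMNS` as columns.
    """

    intensities: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.intensities.index.equals(self.meta.index):
            raise ScreenError("intensity rows and metadata rows are not aligned")
        if self.intensities.index.has_duplicates:
            dups = sorted(self.intensities.index[self.intensities.index.duplicated()])
            raise ScreenError(f"duplicate sample_ids: {dups}")
        if self.intensities.columns.has_duplicates:
            dups = sorted(
                self.intensities.columns[self.intensities.columns.duplicated()]
            )
            raise ScreenError(f"duplicate ion_ids: {dups}")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ScreenError(f"metadata missing columns: {missing}")
        bad_class = set(self.meta["treatment_class"]) - set(TREATMENT_CLASSES)
        if bad_class:
            raise ScreenError(f"unknown treatment_class values: {sorted(bad_class)}")
        vehicle = self.meta["treatment_class"] == "vehicle_control"
        if (self.meta.loc[vehicle, "dose"] != 0).any():
            bad = self.meta.index[vehicle & (self.meta["dose"] != 0)].tolist()
            raise ScreenError(f"vehicle_control samples with nonzero dose: {bad}")
        # injection_index unique within each batch
        dup = self.meta.duplicated(subset=None, keep=False)
        counts = self.meta.groupby("batch_id")["injection_index"].nunique()
        sizes = self.meta.groupby("batch_id").size()
        clashing = sizes.index[counts < sizes].tolist()
        if clashing:
            raise ScreenError(
                f"injection_index not unique within batch(es): {clashing}"
            )
        del dup

    # -- convenience accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def ion_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_ions(self) -> int:
        return self.intensities.shape[1]

    def copy(self) -> "ScreenTable":
        return ScreenTable(self.intensities.copy(), self.meta.copy())

    def subset(self, mask) -> "ScreenTable":
        """Row subset by a boolean mask or list of sample ids."""
        if isinstance(mask, (list, tuple, pd.Index)):
            return ScreenTable(self.intensities.loc[list(mask)], self.meta.loc[list(mask)])
        return ScreenTable(self.intensities.loc[mask], self.meta.loc[mask])


def read_screen_table(path: str | Path, meta_path: str | Path) -> ScreenTable:
    """Read an intensity TSV plus a metadata TSV into a :class:`ScreenTable`.

    Rows are canonicalized by sorting on sample_id, so the result does not
    depend on row order in either file.  Sample sets must match exactly;
    mismatches raise a :class:`ScreenError` listing the offenders.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise ScreenError(f"duplicate ion_id columns in {path}: {dups}")
    intens = pd.read_csv(path, sep="\t", index_col=0)
    intens.index = intens.index.astype(str)
    intens.columns = intens.columns.astype(str)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    only_intens = sorted(set(intens.index) - set(meta.index))
    only_meta = sorted(set(meta.index) - set(intens.index))
    if only_intens or only_meta:
        raise ScreenError(
            "sample_id mismatch between intensity and metadata files: "
            f"only in intensities={only_intens}, only in metadata={only_meta}"
        )
    order = sorted(meta.index)
    intens = intens.loc[order].astype(float)
    meta = meta.loc[order]
    meta = meta.astype(
        {
            "injection_index": int,
            "od600": float,
            "dose": float,
            "timepoint": float,
            "replicate": int,
        }
    )
    return ScreenTable(intens, meta)


def write_screen_table(table: ScreenTable, path: str | Path, meta_path: str | Path) -> None:
    write_table(table.intensities, path)
    write_table(table.meta, meta_path)


def write_table(obj, path: str | Path) -> None:
    """Write a tabular result as TSV with full float round-trip precision.

    Accepts a DataFrame (or anything with ``to_frame``).  Values survive a
    read/write cycle bitwise: floats are serialized with Python's shortest
    round-trip repr.
    """
    if hasattr(obj, "to_frame") and not isinstance(obj, pd.DataFrame):
        obj = obj.to_frame()
    if not isinstance(obj, pd.DataFrame):
        raise ScreenError(f"cannot write object of type {type(obj).__name__}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    obj.to_csv(path, sep="\t", float_format=None)


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read an ion -> compound annotation table.

    Expects columns ``ion_id``, ``compound_id``, ``is_organism_compound``.
    Exactly one annotation per ion: duplicates are rejected at read time.
    """
    ann = pd.read_csv(path, sep="\t", dtype={"ion_id": str, "compound_id": str})
    required = {"ion_id", "compound_id", "is_organism_compound"}
    missing = required - set(ann.columns)
    if missing:
        raise ScreenError(f"annotation table missing columns: {sorted(missing)}")
    if ann["ion_id"].duplicated().any():
        dups = sorted(set(ann.loc[ann["ion_id"].duplicated(), "ion_id"]))
        raise ScreenError(f"duplicate ion_id annotations: {dups}")
    ann["is_organism_compound"] = ann["is_organism_compound"].astype(bool)
    return ann


def organism_ions(annotations: pd.DataFrame) -> list[str]:
    """Ion ids annotated to an organism compound (the restriction set)."""
    return list(annotations.loc[annotations["is_organism_compound"], "ion_id"])
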