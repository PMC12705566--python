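"""Core domain types for excitation-emission matrix (EEM) fluorescence data.

An EEM records fluorescence intensity on a rectangular excitation x emission
wavelength grid. One spectrometer run yields one ``EEMSample``; a labelled
study (here: rice-seedling root exudates under microplastics stress) is an
``EEMDataset`` whose samples share a single :class:`WavelengthGrid`.

Files are plain CSV with explicit wavelength axes (first column = excitation
in nm, header row = emission in nm) so they are self-describing and diff-able;
masked cells are serialized as the token ``NA``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GridError",
    "GridMismatchError",
    "EEMParseError",
    "WavelengthGrid",
    "DEFAULT_GRID",
    "Polymer",
    "EEMSample",
    "EEMDataset",
    "make_grid",
    "read_eem_csv",
    "write_eem_csv",
    "extract_emission_slice",
    "read_dataset",
    "write_dataset",
]

MISSING_TOKEN = "NA"

#: Concentration classes used throughout the study, in mg/L.
CONCENTRATIONS = (0, 10, 100)


class GridError(ValueError):
    """Raised for wavelength ranges that do not form a valid grid."""


class GridMismatchError(ValueError):
    """Raised when file axes disagree with the expected grid."""


class EEMParseError(ValueError):
    """Raised for malformed cells in an EEM CSV."""


class Polymer(str, Enum):
    CONTROL = "CONTROL"
    PET = "PET"
    PS = "PS"
    PVC = "PVC"


@dataclass(frozen=True)
class WavelengthGrid:
    """Inclusive excitation/emission axes, all in nm."""

    ex_start: float
    ex_stop: float
    ex_step: float
    em_start: float
    em_stop: float
    em_step: float

    def __post_init__(self) -> None:
        for name, start, stop, step in (
            ("excitation", self.ex_start, self.ex_stop, self.ex_step),
            ("emission", self.em_start, self.em_stop, self.em_step),
        ):
            if step <= 0:
                raise GridError(f"{name} step must be positive, got {step}")
            if stop <= start:
                raise GridError(f"{name} range must have stop > start ({start}..{stop})")
            span = stop - start
            n = span / step
            if abs(n - round(n)) > 1e-9:
                raise GridError(
                    f"{name} range {start}-{stop} nm does not divide evenly by step {step} nm"
                )

    @property
    def n_ex(self) -> int:
        return int(round((self.ex_stop - self.ex_start) / self.ex_step)) + 1

    @property
    def n_em(self) -> int:
        return int(round((self.em_stop - self.em_start) / self.em_step)) + 1

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_ex, self.n_em)

    @property
    def ex_axis(self) -> np.ndarray:
        return self.ex_start + self.ex_step * np.arange(self.n_ex)

    @property
    def em_axis(self) -> np.ndarray:
        return self.em_start + self.em_step * np.arange(self.n_em)

    def ex_index(self, ex_nm: float) -> int:
        """Row index of an on-axis excitation wavelength.

        Off-axis wavelengths raise with the two nearest grid lines named.
        """
        pos = (ex_nm - self.ex_start) / self.ex_step
        idx = int(round(pos))
        if abs(pos - idx) > 1e-9 or not (0 <= idx < self.n_ex):
            axis = self.ex_axis
            below = axis[axis <= ex_nm]
            above = axis[axis >= ex_nm]
            hints = []
            if below.size:
                hints.append(f"{below[-1]:g}")
            if above.size:
                hints.append(f"{above[0]:g}")
            raise GridError(
                f"excitation {ex_nm} nm is not on the grid; nearest grid wavelengths: "
                + ", ".join(hints)
            )
        return idx


def make_grid(
    ex_start: float,
    ex_stop: float,
    ex_step: float,
    em_start: float,
    em_stop: float,
    em_step: float,
) -> WavelengthGrid:
    """Build a validated wavelength grid (axes inclusive of both endpoints)."""
    return WavelengthGrid(ex_start, ex_stop, ex_step, em_start, em_stop, em_step)


#: The instrument grid used throughout: Ex 220-550 nm step 5, Em 240-750 nm step 1.
DEFAULT_GRID = make_grid(220, 550, 5, 240, 750, 1)


@dataclass
class EEMSample:
    """One EEM intensity matrix with treatment metadata.

    ``intensities`` is ``n_ex x n_em`` (rows = excitation); NaN marks masked
    cells mid-pipeline. ``polymer`` is CONTROL iff concentration is 0 mg/L.
    """

    sample_id: str
    intensities: np.ndarray
    grid: WavelengthGrid
    polymer: Polymer = Polymer.CONTROL
    concentration_mg_per_L: int = 0
    replicate_index: int = 0

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != self.grid.shape:
            raise GridMismatchError(
                f"sample {self.sample_id}: matrix shape {self.intensities.shape} does not "
                f"match grid shape {self.grid.shape}"
            )
        self.polymer = Polymer(self.polymer)
        if self.concentration_mg_per_L not in CONCENTRATIONS:
            raise ValueError(
                f"concentration must be one of {CONCENTRATIONS} mg/L, "
                f"got {self.concentration_mg_per_L}"
            )
        if (self.polymer is Polymer.CONTROL) != (self.concentration_mg_per_L == 0):
            raise ValueError(
                f"sample {self.sample_id}: polymer is CONTROL iff concentration is 0 "
                f"(got {self.polymer.value} at {self.concentration_mg_per_L} mg/L)"
            )
        if self.replicate_index < 0:
            raise ValueError("replicate_index must be >= 0")

    def with_intensities(self, intensities: np.ndarray) -> "EEMSample":
        return replace(self, intensities=np.asarray(intensities, dtype=float))


@dataclass
class EEMDataset:
    """Ordered collection of EEM samples sharing one grid, with unique ids."""

    samples: list[EEMSample] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.samples:
            grid = self.samples[0].grid
            for s in self.samples:
                if s.grid != grid:
                    raise GridMismatchError(
                        f"sample {s.sample_id} is on a different grid than the dataset"
                    )
            ids = [s.sample_id for s in self.samples]
            if len(set(ids)) != len(ids):
                dup = sorted({i for i in ids if ids.count(i) > 1})
                raise ValueError(f"duplicate sample ids: {dup}")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[EEMSample]:
        return iter(self.samples)

    def __getitem__(self, i) -> EEMSample:
        return self.samples[i]

    @property
    def grid(self) -> WavelengthGrid:
        if not self.samples:
            raise ValueError("empty dataset has no grid")
        return self.samples[0].grid

    @property
    def manifest(self) -> list[dict]:
        return [
            {
                "sample_id": s.sample_id,
                "polymer": s.polymer.value,
                "concentration_mg_per_L": s.concentration_mg_per_L,
                "replicate_index": s.replicate_index,
            }
            for s in self.samples
        ]

    def concentrations(self) -> np.ndarray:
        return np.array([s.concentration_mg_per_L for s in self.samples])

    def polymers(self) -> np.ndarray:
        return np.array([s.polymer.value for s in self.samples])

    def to_tensor(self) -> np.ndarray:
        """Stack samples into the (sample, excitation, emission) data cube."""
        return np.stack([s.intensities for s in self.samples])

    def subset(self, indices: Sequence[int]) -> "EEMDataset":
        return EEMDataset([self.samples[int(i)] for i in indices])

    def map_intensities(self, fn) -> "EEMDataset":
        return EEMDataset([fn(s) for s in self.samples])


def write_eem_csv(sample: EEMSample, path) -> None:
    """Write one EEM as CSV: header = emission nm, first column = excitation nm."""
    df = pd.DataFrame(
        sample.intensities,
        index=pd.Index(sample.grid.ex_axis, name="ex_nm"),
        columns=sample.grid.em_axis,
    )
    df.to_csv(path, na_rep=MISSING_TOKEN)


def _check_axis(found: np.ndarray, expected: np.ndarray, name: str, path) -> None:
    if found.shape != expected.shape or not np.allclose(found, expected, atol=1e-6):
        n = min(len(found), len(expected))
        diff = np.nonzero(~np.isclose(found[:n], expected[:n]))[0]
        if len(found) != len(expected) and diff.size == 0:
            first = n
            msg = f"axis length {len(found)} != {len(expected)}"
        else:
            first = int(diff[0])
            msg = f"first differing wavelength at position {first}: {found[first]:g} != {expected[first]:g}"
        raise GridMismatchError(f"{path}: {name} axis mismatch ({msg})")


def read_eem_csv(
    path,
    grid: WavelengthGrid,
    *,
    sample_id: str | None = None,
    polymer: Polymer = Polymer.CONTROL,
    concentration_mg_per_L: int = 0,
    replicate_index: int = 0,
) -> EEMSample:
    """Read one EEM CSV and validate its axes against ``grid``."""
    path = Path(path)
    df = pd.read_csv(
        path,
        index_col=0,
        na_values=[MISSING_TOKEN],
        keep_default_na=False,
        float_precision="round_trip",
    )
    try:
        em = df.columns.to_numpy(dtype=float)
        ex = df.index.to_numpy(dtype=float)
    except (TypeError, ValueError) as e:
        raise EEMParseError(f"{path}: non-numeric wavelength axis ({e})") from None
    _check_axis(ex, grid.ex_axis, "excitation", path)
    _check_axis(em, grid.em_axis, "emission", path)
    values = df.to_numpy()
    if values.dtype == object:
        bad = np.vectorize(lambda v: isinstance(v, str))(values)
        r, c = np.argwhere(bad)[0]
        raise EEMParseError(
            f"{path}: malformed cell at row {r + 1} (ex {ex[r]:g} nm), "
            f"column {c + 1} (em {em[c]:g} nm): {values[r, c]!r}"
        )
    return EEMSample(
        sample_id=sample_id or path.stem,
        intensities=values.astype(float),
        grid=grid,
        polymer=polymer,
        concentration_mg_per_L=concentration_mg_per_L,
        replicate_index=replicate_index,
    )


def extract_emission_slice(sample: EEMSample, ex_nm: float) -> np.ndarray:
    """Return the emission spectrum (length n_em) at one excitation wavelength."""
    return sample.intensities[sample.grid.ex_index(ex_nm)].copy()


def write_dataset(dataset: EEMDataset, directory) -> Path:
    """Write per-sample CSVs plus a JSON manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records = []
    for s in dataset:
        fname = f"{s.sample_id}.csv"
        write_eem_csv(s, directory / fname)
        rec = {
            "sample_id": s.sample_id,
            "file": fname,
            "polymer": s.polymer.value,
            "concentration_mg_per_L": s.concentration_mg_per_L,
            "replicate_index": s.replicate_index,
        }
        records.append(rec)
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(records, indent=1))
    return manifest_path


def read_dataset(manifest_path, grid: WavelengthGrid) -> EEMDataset:
    """Load a dataset from a manifest written by :func:`write_dataset`."""
    manifest_path = Path(manifest_path)
    records = json.loads(manifest_path.read_text())
    samples = []
    for rec in records:
        samples.append(
            read_eem_csv(
                manifest_path.parent / rec["file"],
                grid,
                sample_id=rec["sample_id"],
                polymer=Polymer(rec["polymer"]),
                concentration_mg_per_L=int(rec["concentration_mg_per_L"]),
                replicate_index=int(rec.get("replicate_index", 0)),
            )
        )
    return EEMDataset(samples)
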