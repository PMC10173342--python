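"""Wavelength grids, acquisition masks and EEM containers.

An excitation-emission matrix (EEM) is a fluorescence landscape: emission
spectra recorded at a series of excitation wavelengths.  The acquisition
protocol modelled here records, for each excitation wavelength, only the
physically meaningful part of the emission axis — from a fixed floor for
short excitation wavelengths, and from ``ex + gap`` (just above the
first-order Rayleigh line) otherwise.  The cells never recorded form a
triangular unmeasured region that downstream preprocessing must fill.

Wavelengths are integers in nm on an exact lattice; there is no
floating-point axis drift.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Protocol defaults: excitation 250-500 nm step 10, emission to 650 nm step 5,
#: Rayleigh gap 20 nm, emission floor 300 nm applied below 290 nm excitation.
DEFAULT_GRID_PARAMS = dict(
    ex_start=250, ex_end=500, ex_step=10,
    em_max=650, em_step=5,
    gap=20, em_floor=300, floor_threshold=290,
)


@dataclass(frozen=True)
class EEMGrid:
    """Emission/excitation wavelength axes plus the measured-cell mask.

    Attributes
    ----------
    em_wavelengths : (J,) int array, strictly increasing, constant step.
    ex_wavelengths : (K,) int array, strictly increasing, constant step.
    measured_mask : (J, K) bool array, True where the protocol records
        intensity.  Within each excitation column the mask is monotone:
        once True it stays True for all larger emission wavelengths.
    """

    em_wavelengths: np.ndarray
    ex_wavelengths: np.ndarray
    measured_mask: np.ndarray

    def __post_init__(self):
        em = np.asarray(self.em_wavelengths, dtype=int)
        ex = np.asarray(self.ex_wavelengths, dtype=int)
        mask = np.asarray(self.measured_mask, dtype=bool)
        for name, ax in (("emission", em), ("excitation", ex)):
            if ax.ndim != 1 or ax.size < 2:
                raise ValueError(f"{name} axis must be 1-D with >= 2 points")
            steps = np.diff(ax)
            if not (steps > 0).all() or len(set(steps.tolist())) != 1:
                raise ValueError(f"{name} axis must be strictly increasing with constant step")
        if mask.shape != (em.size, ex.size):
            raise ValueError("measured_mask shape must be (n_em, n_ex)")
        # monotone within each column: once measured, measured upward
        if (np.diff(mask.astype(int), axis=0) < 0).any():
            raise ValueError("measured_mask must be monotone within each excitation column")
        object.__setattr__(self, "em_wavelengths", em)
        object.__setattr__(self, "ex_wavelengths", ex)
        object.__setattr__(self, "measured_mask", mask)

    @property
    def n_em(self) -> int:
        return int(self.em_wavelengths.size)

    @property
    def n_ex(self) -> int:
        return int(self.ex_wavelengths.size)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_em, self.n_ex)

    def n_unmeasured(self) -> int:
        return int((~self.measured_mask).sum())

    def __eq__(self, other) -> bool:
        if not isinstance(other, EEMGrid):
            return NotImplemented
        return (
            np.array_equal(self.em_wavelengths, other.em_wavelengths)
            and np.array_equal(self.ex_wavelengths, other.ex_wavelengths)
            and np.array_equal(self.measured_mask, other.measured_mask)
        )


def build_acquisition_grid(
    ex_start: int = 250,
    ex_end: int = 500,
    ex_step: int = 10,
    em_max: int = 650,
    em_step: int = 5,
    gap: int = 20,
    em_floor: int = 300,
    floor_threshold: int = 290,
) -> EEMGrid:
    """Construct the wavelength grid and measured-cell mask of the protocol.

    For an excitation column at wavelength ``ex``, emission is measured from
    ``ex + gap`` up to ``em_max`` when ``ex >= floor_threshold``, and from
    ``em_floor`` otherwise.  The emission axis is the union of all per-column
    measured ranges on the ``em_step`` lattice, so short-wavelength columns
    are fully measured while long-wavelength columns carry the triangular
    unmeasured region.

    With the defaults this yields 71 emission x 26 excitation points.
    """
    if ex_start > ex_end:
        raise ValueError("ex_start must be <= ex_end")
    if ex_step <= 0 or em_step <= 0:
        raise ValueError("wavelength steps must be positive")
    if em_max <= em_floor:
        raise ValueError("em_max must exceed em_floor")
    if (ex_end - ex_start) % ex_step != 0:
        raise ValueError(
            f"excitation range {ex_start}-{ex_end} is not aligned to step {ex_step}"
        )
    ex = np.arange(ex_start, ex_end + 1, ex_step, dtype=int)

    def first_measured(x: int) -> int:
        return em_floor if x < floor_threshold else x + gap

    starts = [first_measured(int(x)) for x in ex]
    em_min = min(starts)
    if (em_max - em_min) % em_step != 0:
        raise ValueError(
            f"emission range {em_min}-{em_max} is not aligned to step {em_step}"
        )
    for x, s in zip(ex, starts):
        if (s - em_min) % em_step != 0:
            raise ValueError(
                f"first measured emission {s} nm for excitation {x} nm "
                f"is not on the {em_step} nm emission lattice"
            )
    em = np.arange(em_min, em_max + 1, em_step, dtype=int)
    mask = em[:, None] >= np.array(starts)[None, :]
    return EEMGrid(em, ex, mask)


@dataclass
class EEMSample:
    """One sample's EEM: intensity matrix (em x ex) plus metadata.

    Unmeasured cells are NaN before preprocessing; after preprocessing the
    matrix is complete.  Metadata carries the cell-line label, dose in uM
    (0 = untreated control) and replicate index.
    """

    grid: EEMGrid
    intensity: np.ndarray
    cell_line: str
    dose_uM: float
    replicate: int

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != self.grid.shape:
            raise ValueError(
                f"intensity shape {self.intensity.shape} does not match grid {self.grid.shape}"
            )

    def validate_measured(self) -> None:
        """Check intensities are present exactly where the mask says measured."""
        miss = np.isnan(self.intensity)
        if (miss & self.grid.measured_mask).any():
            raise ValueError("missing intensity inside the measured region")

    @property
    def is_complete(self) -> bool:
        return not np.isnan(self.intensity).any()


@dataclass
class EEMCube:
    """Sample x emission x excitation intensity array with sample metadata.

    ``data[i, j, k]`` is the intensity of sample *i* at emission *j*,
    excitation *k*.  ``samples`` is a DataFrame with columns
    ``sample_id, cell_line, dose_uM, replicate`` aligned to the first mode.
    """

    grid: EEMGrid
    data: np.ndarray
    samples: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be 3-way (samples x em x ex)")
        if self.data.shape[1:] != self.grid.shape:
            raise ValueError("cube spectral dimensions do not match the grid")
        if len(self.samples) != self.data.shape[0]:
            raise ValueError("metadata rows must equal the number of samples")
        required = {"cell_line", "dose_uM", "replicate"}
        if not required.issubset(self.samples.columns):
            raise ValueError(f"metadata must contain columns {sorted(required)}")
        if "sample_id" not in self.samples.columns:
            self.samples = self.samples.copy()
            self.samples.insert(0, "sample_id", np.arange(len(self.samples)))

    @property
    def n_samples(self) -> int:
        return int(self.data.shape[0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)

    @property
    def is_complete(self) -> bool:
        return not np.isnan(self.data).any()

    def sample(self, i: int) -> EEMSample:
        row = self.samples.iloc[i]
        return EEMSample(
            grid=self.grid,
            intensity=self.data[i].copy(),
            cell_line=str(row["cell_line"]),
            dose_uM=float(row["dose_uM"]),
            replicate=int(row["replicate"]),
        )


def assemble_cube(samples: list[EEMSample]) -> EEMCube:
    """Stack per-sample EEMs into a cube, preserving order.

    All samples must share one grid; duplicate (cell_line, dose, replicate)
    triples are tolerated with a logged warning.
    """
    if not samples:
        raise ValueError("cannot assemble a cube from an empty sample list")
    grid = samples[0].grid
    for s in samples[1:]:
        if s.grid != grid:
            raise ValueError("all samples must share the same acquisition grid")
    data = np.stack([s.intensity for s in samples])
    meta = pd.DataFrame(
        {
            "sample_id": np.arange(len(samples)),
            "cell_line": [s.cell_line for s in samples],
            "dose_uM": [s.dose_uM for s in samples],
            "replicate": [s.replicate for s in samples],
        }
    )
    dup = meta.duplicated(subset=["cell_line", "dose_uM", "replicate"])
    if dup.any():
        logger.warning(
            "duplicate (cell_line, dose, replicate) triples in cube metadata: %d rows",
            int(dup.sum()),
        )
    return EEMCube(grid=grid, data=data, samples=meta)
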