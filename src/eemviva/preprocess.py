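"""Fill the unmeasured scatter region of masked EEMs.

The acquisition protocol leaves a triangular unmeasured band in each
long-wavelength excitation column: the cells at and below the first-order
Rayleigh line (emission <= excitation) and the band between the Rayleigh
line and the first measured emission point.  Zeros are inserted at and
below the Rayleigh line; the band above it is imputed so that the cube is
complete before trilinear modelling.

Two imputation schemes are provided:

``ratio`` (default)
    Each unmeasured cell (em j, ex k) is estimated from the nearest
    excitation column k' that measures row j, scaled by the intensity
    ratio of the two columns at the first emission row the target column
    measures::

        x[j, k] ~ x[j, k'] * x[m_k, k] / x[m_k, k']

    For locally rank-one data this is exact, so it preserves trilinear
    structure instead of imposing a fixed ramp shape on band flanks.
    Unstable estimates (weak reference signal, negative or non-finite
    ratios) fall back to the linear ramp.

``linear``
    A linear ramp along the emission axis anchored at 0 on the Rayleigh
    line and at the first measured intensity.  Simplest scheme; its filled
    values are bounded by [0, anchor] within each column.

Measured cells are never altered by either scheme.
"""

from __future__ import annotations

import logging

import numpy as np

from .grid import EEMCube, EEMGrid, EEMSample

logger = logging.getLogger(__name__)


def _column_plan(grid: EEMGrid) -> list[tuple[int, int, list[tuple[int, int | None]]]]:
    """Per partially-measured column: (k, first-measured row, cell plan).

    The cell plan lists (row j, reference column k' or None-for-zero) for
    every unmeasured row of the column, where k' is the nearest column that
    measures row j (None marks cells at or below the Rayleigh line).
    """
    em = grid.em_wavelengths
    ex = grid.ex_wavelengths
    plan = []
    for k in range(grid.n_ex):
        colm = grid.measured_mask[:, k]
        if colm.all():
            continue
        if not colm.any():
            raise ValueError(f"excitation column {ex[k]} nm has no measured cells")
        first = int(np.argmax(colm))
        cells: list[tuple[int, int | None]] = []
        for j in range(first):
            if em[j] <= ex[k]:
                cells.append((j, None))
            else:
                cands = np.nonzero(grid.measured_mask[j, :])[0]
                kp = int(cands[np.argmin(np.abs(ex[cands] - ex[k]))]) if cands.size else -1
                cells.append((j, kp))
        plan.append((k, first, cells))
    return plan


def _fill_matrix(intensity: np.ndarray, grid: EEMGrid, method: str,
                 band_halfwidth: float | None, clip_negative: bool) -> np.ndarray:
    out = intensity.copy()
    em = grid.em_wavelengths.astype(float)
    ex = grid.ex_wavelengths.astype(float)
    for k, first, cells in _column_plan(grid):
        m_wl = em[first]
        anchor = out[first, k]
        if np.isnan(anchor):
            raise ValueError("anchor intensity missing at first measured emission")
        if anchor < 0:
            logger.warning("negative measured anchor %.4g at em=%d/ex=%d",
                           anchor, int(m_wl), int(ex[k]))
            if clip_negative:
                anchor = 0.0
        zero_wl = ex[k] if band_halfwidth is None else max(ex[k], m_wl - band_halfwidth)
        col_scale = np.nanmax(np.abs(out[:, k])) if np.isfinite(out[:, k]).any() else 0.0
        for j, kp in cells:
            if kp is None or em[j] <= zero_wl:
                out[j, k] = 0.0
                continue
            ramp = (em[j] - zero_wl) / (m_wl - zero_wl) * anchor
            if method == "linear" or kp < 0:
                out[j, k] = ramp
                continue
            ref = out[j, kp]
            den = out[first, kp]
            ref_scale = np.nanmax(np.abs(out[:, kp]))
            if (not np.isfinite(ref) or not np.isfinite(den)
                    or abs(den) < 1e-3 * max(ref_scale, col_scale, 1e-300)):
                out[j, k] = ramp
            else:
                est = ref * anchor / den
                out[j, k] = est if np.isfinite(est) and est >= 0 else ramp
    if clip_negative:
        neg = out < 0
        if neg.any():
            logger.warning("clipping %d negative intensities to 0", int(neg.sum()))
            out[neg] = 0.0
    return out


def fill_nonphysical_region(sample: EEMSample, method: str = "ratio",
                            band_halfwidth: float | None = None,
                            clip_negative: bool = False) -> EEMSample:
    """Return a complete copy of ``sample`` with the unmeasured band filled.

    ``band_halfwidth`` (linear scheme) moves the zero anchor of the ramp to
    ``first_measured - band_halfwidth`` nm (never below the Rayleigh line);
    by default the ramp is anchored at 0 on the Rayleigh line itself.
    Negative measured intensities pass through with a logged warning unless
    ``clip_negative`` is set.
    """
    if method not in ("ratio", "linear"):
        raise ValueError(f"unknown fill method {method!r}")
    sample.validate_measured()
    out = _fill_matrix(sample.intensity, sample.grid, method, band_halfwidth, clip_negative)
    return EEMSample(grid=sample.grid, intensity=out, cell_line=sample.cell_line,
                     dose_uM=sample.dose_uM, replicate=sample.replicate)


def preprocess_cube(cube: EEMCube, method: str = "ratio",
                    band_halfwidth: float | None = None,
                    clip_negative: bool = False) -> EEMCube:
    """Apply :func:`fill_nonphysical_region` to every sample of a cube.

    The returned cube is complete (no NaN) and records in its provenance
    which cells were imputed and by what scheme.
    """
    if method not in ("ratio", "linear"):
        raise ValueError(f"unknown fill method {method!r}")
    filled = np.empty_like(cube.data)
    for i in range(cube.n_samples):
        sample = cube.sample(i)
        sample.validate_measured()
        filled[i] = _fill_matrix(sample.intensity, cube.grid, method,
                                 band_halfwidth, clip_negative)
    unmeasured = ~cube.grid.measured_mask
    prov = dict(cube.provenance)
    prov["preprocess"] = {
        "method": method,
        "band_halfwidth": band_halfwidth,
        "clip_negative": bool(clip_negative),
        "n_imputed_cells_per_sample": int(unmeasured.sum()),
        "imputed_cells": [[int(j), int(k)] for j, k in zip(*np.nonzero(unmeasured))],
    }
    return EEMCube(grid=cube.grid, data=filled, samples=cube.samples.copy(), provenance=prov)
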