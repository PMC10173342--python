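"""Cube serialization: one CSV matrix per sample plus a JSON manifest.

Each sample file is a plain CSV: the first row holds excitation wavelengths,
the first column emission wavelengths, and the body the intensities.
Unmeasured cells are written as empty fields and restored as NaN.  The
manifest records the grid axes, the mask row-starts and the metadata table,
so a read can validate consistency before touching the CSVs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import EEMCube, EEMGrid

MANIFEST_NAME = "cube_manifest.json"


def write_cube(cube: EEMCube, path: str | Path) -> Path:
    """Write a cube to ``path`` (a directory); returns the manifest path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    grid = cube.grid
    sample_files = []
    for i in range(cube.n_samples):
        fname = f"sample_{i:04d}.csv"
        _write_matrix_csv(path / fname, grid, cube.data[i])
        sample_files.append(fname)
    manifest = {
        "format": "eemviva-cube",
        "version": 1,
        "em_wavelengths": grid.em_wavelengths.tolist(),
        "ex_wavelengths": grid.ex_wavelengths.tolist(),
        # mask is column-monotone, so the first measured emission per column
        # encodes it losslessly
        "first_measured_em": [
            int(grid.em_wavelengths[grid.measured_mask[:, k]][0])
            if grid.measured_mask[:, k].any()
            else None
            for k in range(grid.n_ex)
        ],
        "samples": cube.samples.to_dict(orient="records"),
        "sample_files": sample_files,
        "provenance": cube.provenance,
    }
    manifest_path = path / MANIFEST_NAME
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def read_cube(path: str | Path) -> EEMCube:
    """Read a cube written by :func:`write_cube`; validates manifest/CSV agreement."""
    path = Path(path)
    manifest_path = path if path.is_file() else path / MANIFEST_NAME
    manifest = json.loads(manifest_path.read_text())
    if manifest.get("format") != "eemviva-cube":
        raise ValueError(f"{manifest_path} is not an eemviva cube manifest")
    base = manifest_path.parent
    em = np.asarray(manifest["em_wavelengths"], dtype=int)
    ex = np.asarray(manifest["ex_wavelengths"], dtype=int)
    starts = manifest["first_measured_em"]
    mask = np.zeros((em.size, ex.size), dtype=bool)
    for k, s in enumerate(starts):
        if s is not None:
            mask[:, k] = em >= int(s)
    grid = EEMGrid(em, ex, mask)
    meta = pd.DataFrame(manifest["samples"])
    files = manifest["sample_files"]
    if len(files) != len(meta):
        raise ValueError("manifest sample_files and metadata lengths disagree")
    data = np.empty((len(files), em.size, ex.size))
    for i, fname in enumerate(files):
        data[i] = _read_matrix_csv(base / fname, grid)
    return EEMCube(grid=grid, data=data, samples=meta,
                   provenance=manifest.get("provenance", {}))


def write_metadata_csv(cube: EEMCube, path: str | Path) -> None:
    cube.samples.to_csv(path, index=False,
                        columns=["sample_id", "cell_line", "dose_uM", "replicate"])


def _fmt(v: float) -> str:
    return "" if np.isnan(v) else repr(float(v))


def _write_matrix_csv(path: Path, grid: EEMGrid, intensity: np.ndarray) -> None:
    lines = ["em_nm\\ex_nm," + ",".join(str(int(x)) for x in grid.ex_wavelengths)]
    for j, em in enumerate(grid.em_wavelengths):
        lines.append(f"{int(em)}," + ",".join(_fmt(v) for v in intensity[j]))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _read_matrix_csv(path: Path, grid: EEMGrid) -> np.ndarray:
    df = pd.read_csv(path, index_col=0)
    ex = df.columns.astype(int).to_numpy()
    em = df.index.astype(int).to_numpy()
    if not np.array_equal(ex, grid.ex_wavelengths) or not np.array_equal(em, grid.em_wavelengths):
        raise ValueError(f"{path}: wavelength axes do not match the manifest grid")
    return df.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Model serialization
# ---------------------------------------------------------------------------

def write_model(model, diagnostics, path: str | Path) -> None:
    """Serialize a fitted PARAFAC model (+ diagnostics) to JSON."""
    payload = {
        "format": "eemviva-parafac",
        "F": int(model.F),
        "scores": model.scores.tolist(),
        "em_loadings": model.em_loadings.tolist(),
        "ex_loadings": model.ex_loadings.tolist(),
        "em_wavelengths": None if model.em_wavelengths is None else np.asarray(model.em_wavelengths).tolist(),
        "ex_wavelengths": None if model.ex_wavelengths is None else np.asarray(model.ex_wavelengths).tolist(),
        "diagnostics": None if diagnostics is None else {
            "explained_variance_pct": float(diagnostics.explained_variance_pct),
            "sse": float(diagnostics.sse),
            "n_iterations": int(diagnostics.n_iterations),
            "converged": bool(diagnostics.converged),
            "core_consistency_pct": float(diagnostics.core_consistency_pct),
            "n_starts": int(diagnostics.n_starts),
        },
    }
    Path(path).write_text(json.dumps(payload))


def read_model(path: str | Path):
    from .parafac import ParafacModel

    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "eemviva-parafac":
        raise ValueError(f"{path} is not an eemviva model file")
    wl = payload["em_wavelengths"]
    xl = payload["ex_wavelengths"]
    return ParafacModel(
        F=payload["F"],
        scores=np.asarray(payload["scores"]),
        em_loadings=np.asarray(payload["em_loadings"]),
        ex_loadings=np.asarray(payload["ex_loadings"]),
        em_wavelengths=None if wl is None else np.asarray(wl),
        ex_wavelengths=None if xl is None else np.asarray(xl),
    )
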