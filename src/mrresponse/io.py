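"""Array containers on disk.

Voxel-level data use HDF5: diffusion stacks with axes (voxel, b, direction)
and DCE concentration series with axes (voxel, time).  Axis order is fixed;
b-values / time grids are stored alongside the signal array.  Cohort tables
travel as CSV with a JSON sidecar (see :mod:`mrresponse.cohort`).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .dwi import DWStack


def save_dw_stack(stack: DWStack, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=stack.signals)  # (voxel, b, direction)
        f.create_dataset("b_values", data=stack.b_values)
        if stack.directions is not None:
            f.create_dataset("directions", data=stack.directions)


def load_dw_stack(path: str | Path) -> DWStack:
    with h5py.File(path, "r") as f:
        return DWStack(
            signals=f["signals"][...],
            b_values=f["b_values"][...],
            directions=f["directions"][...] if "directions" in f else None,
        )


def save_dce_series(conc: np.ndarray, times: np.ndarray, path: str | Path) -> None:
    """``conc`` has axes (voxel, time)."""
    conc = np.atleast_2d(np.asarray(conc, dtype=float))
    with h5py.File(path, "w") as f:
        f.create_dataset("conc", data=conc)
        f.create_dataset("times", data=np.asarray(times, dtype=float))


def load_dce_series(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    with h5py.File(path, "r") as f:
        return f["conc"][...], f["times"][...]
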