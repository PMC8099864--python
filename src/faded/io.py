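"""Reading and writing the plain-text and TIFF formats used by the toolkit.

Decays, instrument responses, spectra and anisotropy traces travel as
two-column delimited text (an optional single header line is tolerated);
titrations as two- or three-column text; fit reports and calibrations as
JSON; image stacks as multi-frame TIFF.
"""

from __future__ import annotations

import json

import numpy as np
import tifffile

from .calibration import TitrationTable
from .tcspc import DecayHistogram, InstrumentResponse
from .unmixing import EmissionSpectrum

__all__ = [
    "read_columns",
    "read_decay",
    "read_irf",
    "read_spectrum",
    "read_titration",
    "write_columns",
    "write_decay",
    "write_trace",
    "write_json",
    "read_stack_tiff",
    "write_stack_tiff",
]


def read_columns(path, n_cols_min: int = 2) -> np.ndarray:
    """Load a delimited numeric table, skipping a single header line if present."""
    for skip in (0, 1):
        try:
            data = np.loadtxt(path, skiprows=skip, ndmin=2)
        except ValueError:
            continue
        if data.shape[1] >= n_cols_min:
            return data
    raise ValueError(f"{path}: could not parse a numeric table with >= {n_cols_min} columns")


def read_decay(path) -> DecayHistogram:
    data = read_columns(path)
    return DecayHistogram.from_columns(data[:, 0], data[:, 1])


def read_irf(path, fwhm_estimate: float | None = None) -> InstrumentResponse:
    data = read_columns(path)
    decay = DecayHistogram.from_columns(data[:, 0], data[:, 1])
    return InstrumentResponse(
        counts=decay.counts, dwell=decay.dwell, fwhm_estimate=fwhm_estimate
    )


def read_spectrum(path, label: str = "") -> EmissionSpectrum:
    data = read_columns(path)
    return EmissionSpectrum(wavelengths=data[:, 0], intensities=data[:, 1], label=label)


def read_titration(path) -> TitrationTable:
    data = read_columns(path)
    sigma = data[:, 2] if data.shape[1] >= 3 else None
    return TitrationTable(
        concentrations=data[:, 0], anisotropies=data[:, 1], sigma=sigma
    )


def write_columns(path, columns, header: str = "") -> None:
    arr = np.column_stack(columns)
    np.savetxt(path, arr, header=header, fmt="%.10g", delimiter="\t")


def write_decay(path, decay: DecayHistogram, header: str = "time_ns\tcounts") -> None:
    write_columns(path, (decay.time_axis, decay.counts), header=header)


def write_trace(path, times, values, extra=None, header: str = "time\tr") -> None:
    cols = [times, values] + ([extra] if extra is not None else [])
    write_columns(path, cols, header=header)


def write_json(path, obj: dict) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2)


def read_stack_tiff(path) -> np.ndarray:
    """Multi-frame TIFF as a (frames, height, width) float array."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return np.asarray(arr, dtype=float)


def write_stack_tiff(path, stack: np.ndarray) -> None:
    stack = np.asarray(stack)
    photometric = "rgb" if stack.ndim == 4 and stack.shape[-1] == 3 else "minisblack"
    tifffile.imwrite(path, stack, photometric=photometric)
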