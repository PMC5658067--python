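"""File formats: delimited traces, events/HRF JSON, NIfTI BOLD volumes."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from swbold.types import BoldSession, CalciumTrace, EventArray, HemodynamicResponse


def write_trace(path: str | Path, trace: CalciumTrace) -> None:
    """Two-column delimited text (time_s, value) with a metadata header."""
    path = Path(path)
    header = f"fs_hz={trace.fs_hz} t0_s={trace.t0_s} units={trace.units}\ntime_s\tvalue"
    data = np.column_stack([trace.times_s, trace.values])
    np.savetxt(path, data, fmt="%.9g", delimiter="\t", header=header)


def read_trace(path: str | Path) -> CalciumTrace:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("#"):
        raise ValueError(f"{path}: missing trace metadata header")
    meta = dict(tok.split("=") for tok in first[1:].split() if "=" in tok)
    try:
        fs = float(meta["fs_hz"])
        t0 = float(meta.get("t0_s", 0.0))
        units = meta.get("units", "dff")
    except (KeyError, ValueError) as exc:
        raise ValueError(f"{path}: malformed trace header: {exc}") from exc
    data = np.loadtxt(path, delimiter="\t")
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns (time_s, value)")
    return CalciumTrace(values=data[:, 1], fs_hz=fs, t0_s=t0, units=units)


def write_events(path: str | Path, events: EventArray) -> None:
    payload = {
        "onsets_s": events.onsets_s.tolist(),
        "durations_s": events.durations_s.tolist(),
        "session_duration_s": events.session_duration_s,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_events(path: str | Path) -> EventArray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"events file not found: {path}")
    try:
        payload = json.loads(path.read_text())
        return EventArray(
            np.asarray(payload["onsets_s"], dtype=float),
            np.asarray(payload["durations_s"], dtype=float),
            float(payload["session_duration_s"]),
        )
    except (json.JSONDecodeError, KeyError) as exc:
        raise ValueError(f"{path}: malformed events JSON: {exc}") from exc


def write_hrf(path: str | Path, times_s: np.ndarray, values: np.ndarray) -> None:
    payload = {"times_s": np.asarray(times_s).tolist(),
               "values": np.asarray(values).tolist()}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_hrf(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
        return (np.asarray(payload["times_s"], dtype=float),
                np.asarray(payload["values"], dtype=float))
    except (json.JSONDecodeError, KeyError) as exc:
        raise ValueError(f"{path}: malformed HRF JSON: {exc}") from exc


def write_hr(path: str | Path, hr: HemodynamicResponse) -> None:
    write_hrf(path, hr.times_s, hr.values)


def read_hr(path: str | Path) -> HemodynamicResponse:
    t, v = read_hrf(path)
    return HemodynamicResponse(times_s=t, values=v)


def write_bold(path: str | Path, session: BoldSession) -> None:
    """NIfTI-1 4-D image; voxel size in the affine, TR in the time zoom."""
    affine = np.diag(list(session.voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(session.data.astype(np.float32), affine)
    img.header.set_zooms(tuple(session.voxel_size_mm) + (session.tr_s,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_bold(path: str | Path, brain_mask: np.ndarray | None = None) -> BoldSession:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"BOLD file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D BOLD image, got {data.ndim}-D")
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return BoldSession(
        data=data,
        tr_s=tr,
        voxel_size_mm=tuple(float(z) for z in zooms[:3]),
        brain_mask=brain_mask,
    )


def write_mask(path: str | Path, mask: np.ndarray,
               voxel_size_mm: tuple[float, float, float]) -> None:
    affine = np.diag(list(voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(mask.astype(np.uint8), affine)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj) > 0


def write_slow_wave_vector(path: str | Path, bins: np.ndarray, tr_s: float) -> None:
    np.savetxt(path, np.asarray(bins, dtype=int), fmt="%d",
               header=f"tr_s={tr_s}")
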