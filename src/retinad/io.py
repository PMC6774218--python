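"""Reading and writing traces, B-scan stacks and cohort tables.

Formats
-------
* ERG traces: CSV with columns ``time_ms, microvolts`` and ``# key=value``
  header comments carrying ``sampling_rate_hz``, ``flash_time_ms`` and
  ``label``.
* B-scan stacks: multi-page TIFF plus a JSON sidecar (``<stem>.json``)
  with ``axial_px_um``, ``spacing_um`` and optional ground-truth
  boundaries, or an HDF5 group with the same content as attributes and
  datasets.
* Cohort tables: long-format CSV (animal_id, genotype, age_months,
  parameter, value).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .exceptions import InvalidParameterError, RetinadWarning
from .types import BoundarySet, BScan, ErgTrace

DEFAULT_AXIAL_PX_UM = 3.9


def write_trace_csv(trace: ErgTrace, path: str | Path) -> None:
    path = Path(path)
    header = (
        f"# sampling_rate_hz={trace.sampling_rate}\n"
        f"# flash_time_ms={trace.flash_time}\n"
        f"# label={trace.label}\n"
        "time_ms,microvolts\n"
    )
    body = "\n".join(
        f"{t:.6g},{v:.6g}" for t, v in zip(trace.time_ms, trace.samples)
    )
    path.write_text(header + body + "\n")


def read_trace_csv(path: str | Path) -> ErgTrace:
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    data_lines = []
    for line in lines:
        if line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
        else:
            data_lines.append(line)
    df = pd.read_csv(pd.io.common.StringIO("".join(data_lines)))
    if "microvolts" not in df.columns:
        raise InvalidParameterError(f"{path}: missing 'microvolts' column")
    if "sampling_rate_hz" in meta:
        fs = float(meta["sampling_rate_hz"])
    elif "time_ms" in df.columns and len(df) > 1:
        fs = 1000.0 / float(np.mean(np.diff(df.time_ms)))
    else:
        raise InvalidParameterError(f"{path}: cannot determine sampling rate")
    return ErgTrace(
        samples=df.microvolts.to_numpy(float),
        sampling_rate=fs,
        flash_time=float(meta.get("flash_time_ms", 0.0)),
        label=meta.get("label", "bright-flash"),
    )


def _boundaries_to_json(truths: list[BoundarySet] | None) -> list | None:
    if truths is None:
        return None
    return [
        {"ilm": t.ilm.tolist(), "inl_opl": t.inl_opl.tolist(),
         "rpe_base": t.rpe_base.tolist()}
        for t in truths
    ]


def write_bscan_tiff(
    bscans: list[BScan],
    path: str | Path,
    spacing_um: float = 125.0,
    truths: list[BoundarySet] | None = None,
) -> None:
    """Multi-page TIFF stack (float32) with a JSON metadata sidecar."""
    path = Path(path)
    stack = np.stack([b.image for b in bscans]).astype(np.float32)
    tifffile.imwrite(path, stack, photometric="minisblack")
    sidecar = {
        "axial_px_um": bscans[0].axial_px_um,
        "spacing_um": spacing_um,
        "onh_cols": [list(b.onh_cols) if b.onh_cols else None for b in bscans],
        "ground_truth": _boundaries_to_json(truths),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_bscan_stack(path: str | Path) -> list[BScan]:
    """Read a multi-page TIFF (with optional sidecar) or HDF5 stack."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        return _read_bscan_hdf5(path)
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    sidecar = path.with_suffix(".json")
    axial = DEFAULT_AXIAL_PX_UM
    onh = [None] * len(stack)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        axial = float(meta.get("axial_px_um", DEFAULT_AXIAL_PX_UM))
        onh = meta.get("onh_cols") or onh
    else:
        warnings.warn(
            f"{path}: no metadata sidecar; assuming axial pitch "
            f"{DEFAULT_AXIAL_PX_UM} μm/px (device axial resolution)",
            RetinadWarning,
            stacklevel=2,
        )
    return [
        BScan(
            image=np.asarray(img, float),
            axial_px_um=axial,
            onh_cols=tuple(o) if o else None,
            scan_id=f"{path.stem}-b{i}",
        )
        for i, (img, o) in enumerate(zip(stack, onh))
    ]


def write_bscan_hdf5(
    bscans: list[BScan],
    path: str | Path,
    spacing_um: float = 125.0,
    truths: list[BoundarySet] | None = None,
    group: str = "eye",
) -> None:
    with h5py.File(path, "a") as fh:
        grp = fh.require_group(group)
        for i, b in enumerate(bscans):
            ds = grp.create_dataset(f"bscan{i}", data=b.image.astype(np.float32))
            if b.onh_cols:
                ds.attrs["onh_cols"] = b.onh_cols
            if truths is not None:
                ds.attrs["ground_truth"] = json.dumps(
                    _boundaries_to_json([truths[i]])[0]
                )
        grp.attrs["axial_px_um"] = bscans[0].axial_px_um
        grp.attrs["spacing_um"] = spacing_um


def _read_bscan_hdf5(path: Path) -> list[BScan]:
    out: list[BScan] = []
    with h5py.File(path, "r") as fh:
        for gname, grp in fh.items():
            if "axial_px_um" in grp.attrs:
                axial = float(grp.attrs["axial_px_um"])
            else:
                warnings.warn(
                    f"{path}:{gname}: missing axial_px_um attribute; assuming "
                    f"{DEFAULT_AXIAL_PX_UM} μm/px",
                    RetinadWarning,
                    stacklevel=2,
                )
                axial = DEFAULT_AXIAL_PX_UM
            for dname in sorted(k for k in grp if k.startswith("bscan")):
                ds = grp[dname]
                onh = ds.attrs.get("onh_cols")
                out.append(
                    BScan(
                        image=np.asarray(ds, float),
                        axial_px_um=axial,
                        onh_cols=tuple(int(v) for v in onh) if onh is not None else None,
                        scan_id=f"{path.stem}/{gname}/{dname}",
                    )
                )
    return out


def write_cohort_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"animal_id", "genotype", "age_months", "parameter", "value"}
    if not required.issubset(df.columns):
        raise InvalidParameterError(
            f"{path}: cohort CSV needs columns {sorted(required)}"
        )
    return df
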