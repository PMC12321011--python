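"""Read/write 1D SAXS curves, series manifests and analysis result containers.

The on-disk formats are deliberately plain: 3-column ASCII ``.dat`` files
(q [nm^-1], intensity, optional uncertainty), a CSV manifest for
time-resolved series, a JSON assignment report, and an HDF5 container for
full analysis provenance (NXcanSAS-inspired group layout: the
background-corrected pattern, the uncorrected signal, the reduction
parameters, peak fits and phase assignments live in separate groups).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "SAXSPattern",
    "read_dat",
    "write_dat",
    "read_manifest",
    "write_manifest",
    "subtract_background",
    "write_result_container",
    "read_result_container",
]


@dataclass
class SAXSPattern:
    """One reduced 1D scattering curve with metadata.

    Attributes
    ----------
    q : ndarray
        Scattering vector magnitudes in nm^-1, strictly increasing.
    I : ndarray
        Intensities (counts / arbitrary units), same length as q.
    sigma : ndarray or None
        1-sigma intensity uncertainties, same length, non-negative.
    metadata : dict
        Free-form; recognised keys include ``sample_id``, ``composition``,
        ``illumination_state`` ('trans' | 'cis' | 'transitioning'),
        ``time_s``, ``temperature_C``, ``ground_truth``.
    """

    q: np.ndarray
    I: np.ndarray
    sigma: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.q.ndim != 1 or self.q.size < 2:
            raise ValueError("q must be a 1D vector with >= 2 points")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing (duplicates/reversals present)")
        if self.I.shape != self.q.shape:
            raise ValueError("I and q lengths differ")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma and q lengths differ")
            if np.any(self.sigma < 0):
                raise ValueError("sigma must be non-negative")

    @property
    def time_s(self) -> Optional[float]:
        t = self.metadata.get("time_s")
        return None if t is None else float(t)

    def copy(self) -> "SAXSPattern":
        return SAXSPattern(
            self.q.copy(),
            self.I.copy(),
            None if self.sigma is None else self.sigma.copy(),
            dict(self.metadata),
        )


_ANGSTROM_RE = re.compile(r"(a|ang|angstrom|Å)\s*\^?\s*(-1|⁻¹)|1\s*/\s*(a|ang|angstrom|Å)\b",
                          re.IGNORECASE)


def read_dat(path) -> SAXSPattern:
    """Read a whitespace/comma-delimited q, I[, sigma] ASCII file.

    Lines starting with '#' are comments; a comment header mentioning
    Å^-1 (e.g. ``# q(A^-1)``) triggers conversion of q to nm^-1 (x10).
    """
    path = Path(path)
    rows: list[list[float]] = []
    angstrom = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if _ANGSTROM_RE.search(line):
                    angstrom = True
                continue
            parts = re.split(r"[,\s]+", line)
            try:
                rows.append([float(p) for p in parts if p])
            except ValueError:
                # tolerate a single non-numeric header line without '#'
                if rows:
                    raise
                continue
    if not rows:
        raise ValueError(f"{path}: no numeric data")
    ncol = min(len(r) for r in rows)
    if ncol < 2:
        raise ValueError(f"{path}: need >= 2 numeric columns, got {ncol}")
    arr = np.array([r[:ncol] for r in rows], dtype=float)
    q = arr[:, 0] * (10.0 if angstrom else 1.0)
    I = arr[:, 1]
    sigma = arr[:, 2] if ncol >= 3 else None
    return SAXSPattern(q, I, sigma, metadata={"source": str(path)})


def write_dat(pattern: SAXSPattern, path, header: str | None = None) -> Path:
    """Write a pattern as 3-column (or 2-column) ASCII, q in nm^-1."""
    path = Path(path)
    cols = [pattern.q, pattern.I]
    names = ["q_nm^-1", "intensity"]
    if pattern.sigma is not None:
        cols.append(pattern.sigma)
        names.append("sigma")
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# " + "  ".join(names) + "\n")
        for row in zip(*cols):
            fh.write("  ".join(f"{v:.9e}" for v in row) + "\n")
    return path


def read_manifest(path) -> pd.DataFrame:
    """Read a series manifest CSV (filename, time_s, illumination_nm, state)."""
    df = pd.read_csv(path)
    if "filename" not in df.columns:
        raise ValueError(f"{path}: manifest needs a 'filename' column")
    return df


def write_manifest(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def subtract_background(sample: SAXSPattern, buffer: SAXSPattern,
                        scale: float = 1.0) -> SAXSPattern:
    """Subtract a scaled buffer/solvent measurement from a sample pattern.

    The two patterns must share an identical q grid — no implicit
    interpolation is performed, because regridding silently corrupts
    counting statistics. Uncertainties combine in quadrature when both
    patterns carry them.
    """
    if sample.q.shape != buffer.q.shape or not np.allclose(
            sample.q, buffer.q, rtol=0, atol=1e-12):
        raise ValueError(
            "q grids of sample and buffer differ; regrid explicitly "
            "(e.g. numpy.interp onto a common grid) before subtraction")
    I_corr = sample.I - scale * buffer.I
    sigma = None
    if sample.sigma is not None and buffer.sigma is not None:
        sigma = np.sqrt(sample.sigma**2 + scale**2 * buffer.sigma**2)
    elif sample.sigma is not None:
        sigma = sample.sigma.copy()
    meta = dict(sample.metadata)
    meta["background_subtraction"] = {
        "scale": float(scale),
        "buffer_id": buffer.metadata.get("sample_id", buffer.metadata.get("source", "")),
    }
    return SAXSPattern(sample.q.copy(), I_corr, sigma, meta)


# ---------------------------------------------------------------------------
# HDF5 result container
# ---------------------------------------------------------------------------

def _write_pattern_group(grp: h5py.Group, pattern: SAXSPattern) -> None:
    grp.create_dataset("q", data=pattern.q)
    grp["q"].attrs["units"] = "1/nm"
    grp.create_dataset("I", data=pattern.I)
    if pattern.sigma is not None:
        grp.create_dataset("Idev", data=pattern.sigma)
        grp.attrs["has_uncertainty"] = True
    else:
        grp.attrs["has_uncertainty"] = False
    meta = {k: v for k, v in pattern.metadata.items() if k != "ground_truth"}
    grp.attrs["metadata_json"] = json.dumps(meta, sort_keys=True, default=str)


def _read_pattern_group(grp: h5py.Group) -> SAXSPattern:
    sigma = grp["Idev"][...] if "Idev" in grp else None
    meta = json.loads(grp.attrs.get("metadata_json", "{}"))
    return SAXSPattern(grp["q"][...], grp["I"][...], sigma, meta)


def write_result_container(path, raw: SAXSPattern,
                           corrected: SAXSPattern | None = None,
                           peaks=None, assignment=None,
                           extra: dict | None = None) -> Path:
    """Write an analysis result container (HDF5, NXcanSAS-inspired layout).

    Groups: ``entry/raw`` (uncorrected signal), ``entry/data`` (corrected
    signal, canonical q/I/Idev names), ``entry/reduction`` (background
    subtraction provenance), ``entry/peaks`` (fit table), and
    ``entry/assignment`` (phase-indexing report as JSON). No timestamps are
    written, so rewriting the same objects is byte-stable.
    """
    path = Path(path)
    with h5py.File(path, "w", track_order=True) as f:
        entry = f.create_group("entry")
        entry.attrs["NX_class"] = "NXentry"
        entry.attrs["definition"] = "NXcanSAS-inspired"
        _write_pattern_group(entry.create_group("raw"), raw)
        data = entry.create_group("data")
        data.attrs["NX_class"] = "NXdata"
        _write_pattern_group(data, corrected if corrected is not None else raw)
        red = entry.create_group("reduction")
        info = (corrected.metadata.get("background_subtraction")
                if corrected is not None else None)
        red.attrs["background_subtracted"] = info is not None
        if info is not None:
            red.attrs["scale"] = info["scale"]
            red.attrs["buffer_id"] = str(info["buffer_id"])
        if peaks:
            pk = entry.create_group("peaks")
            from .peaks import peaks_to_frame  # local import: avoid cycle at module load
            df = peaks_to_frame(peaks)
            for col in df.columns:
                vals = df[col].to_numpy()
                if vals.dtype == object:
                    vals = vals.astype("S")
                pk.create_dataset(col, data=vals)
        if assignment is not None:
            rep = assignment if isinstance(assignment, dict) else assignment.to_report()
            entry.create_dataset(
                "assignment", data=json.dumps(rep, sort_keys=True, default=str))
        if extra:
            entry.attrs["extra_json"] = json.dumps(extra, sort_keys=True, default=str)
    return path


def read_result_container(path) -> dict:
    """Reopen a result container; arrays are returned bit-exactly."""
    out: dict = {}
    with h5py.File(path, "r") as f:
        entry = f["entry"]
        out["raw"] = _read_pattern_group(entry["raw"])
        out["corrected"] = _read_pattern_group(entry["data"])
        red = entry["reduction"]
        out["reduction"] = {k: red.attrs[k] for k in red.attrs}
        if "peaks" in entry:
            pk = entry["peaks"]
            cols = {}
            for name in pk:
                vals = pk[name][...]
                if vals.dtype.kind == "S":
                    vals = vals.astype(str)
                cols[name] = vals
            out["peaks"] = pd.DataFrame(cols)
        if "assignment" in entry:
            out["assignment"] = json.loads(entry["assignment"][()].decode()
                                           if isinstance(entry["assignment"][()], bytes)
                                           else entry["assignment"][()])
    return out
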