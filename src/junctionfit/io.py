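"""CSV dialects for intensity tables, plus fit-report serialization.

Tables are plain CSV with commented (``#``) metadata header lines —
human-editable and spreadsheet-safe, and the carrier for ground truth and
seed in synthetic files::

    # junctionfit: 0.1.0
    # kind: cruciform
    # time_unit: min
    # seed: 7
    # truth: {"k1": 0.019, "k2": 0.2}
    time,S,N,L
    0,1,0,0
    ...

Dialects (column names are fixed):

* ``cleavage``  — columns ``time,F``; requires ``time_unit`` metadata.
* ``cruciform`` — columns ``time,S,N,L`` (raw intensities allowed; rows
  are renormalized to fractions on read); requires ``time_unit``.
* ``titration`` — columns ``Pt,fb`` (nM); requires ``Dt_nM`` metadata,
  optional ``stoichiometry`` (dimer/monomer, default dimer).

Time units are never inferred — a table without its unit tag is rejected,
since published rates in this assay family mix s⁻¹ and min⁻¹.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import BindingTitration, CruciformTrajectory, ProgressCurve
from .errors import DomainError, TableFormatError, UnitError

__all__ = ["read_intensity_table", "write_intensity_table", "file_sha256"]

_COLUMNS = {
    "cleavage": ["time", "F"],
    "cruciform": ["time", "S", "N", "L"],
    "titration": ["Pt", "fb"],
}


def file_sha256(path) -> str:
    """Hex digest of a file's contents (recorded in fit reports)."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _read_metadata(path: Path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" not in body:
                continue
            key, value = body.split(":", 1)
            meta[key.strip()] = value.strip()
    return meta


def _parse_truth(meta: dict):
    if "truth" in meta:
        try:
            return json.loads(meta["truth"])
        except json.JSONDecodeError as exc:
            raise TableFormatError(f"unparseable truth metadata: {exc}") from exc
    return None


def read_intensity_table(path, kind: str | None = None):
    """Read a CSV intensity table into its validated domain container.

    ``kind`` may be omitted when the file's metadata declares it.
    Validation failures name the offending row or column.
    """
    path = Path(path)
    if not path.exists():
        raise TableFormatError(f"no such file: {path}")
    meta = _read_metadata(path)
    kind = kind or meta.get("kind")
    if kind not in _COLUMNS:
        raise TableFormatError(
            f"{path}: unknown or undeclared table kind {kind!r}; "
            "pass kind= or add a '# kind:' metadata line"
        )
    if meta.get("kind") and meta["kind"] != kind:
        raise TableFormatError(
            f"{path}: requested kind {kind!r} but file declares {meta['kind']!r}"
        )
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise TableFormatError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = [c for c in _COLUMNS[kind] if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {missing}")
    df = df[_COLUMNS[kind]].apply(pd.to_numeric, errors="coerce")
    finite = np.isfinite(df.to_numpy(dtype=float))
    if not finite.all():
        row = int(np.argwhere(~finite)[0][0]) + 1
        raise TableFormatError(f"{path}: non-numeric or missing cell at row {row}")

    truth = _parse_truth(meta)
    seed = int(meta["seed"]) if meta.get("seed", "").lstrip("-").isdigit() else None

    if kind in ("cleavage", "cruciform"):
        if "time_unit" not in meta:
            raise UnitError(
                f"{path}: missing '# time_unit:' metadata (s or min); "
                "time units are never inferred"
            )
        unit = meta["time_unit"]
        t = df["time"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            row = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 2
            raise TableFormatError(f"{path}: time not strictly increasing at row {row}")
        if kind == "cleavage":
            return ProgressCurve(times=t, F=df["F"].to_numpy(dtype=float),
                                 time_unit=unit, truth=truth, seed=seed)
        inten = df[["S", "N", "L"]].to_numpy(dtype=float)
        if np.any(inten < 0):
            row = int(np.argwhere(inten < 0)[0][0]) + 1
            raise TableFormatError(f"{path}: negative intensity at row {row}")
        traj = CruciformTrajectory(
            times=t, fS=inten[:, 0], fN=inten[:, 1], fL=inten[:, 2],
            time_unit=unit, truth=truth, seed=seed,
        )
        return traj.renormalized()

    if "Dt_nM" not in meta:
        raise TableFormatError(f"{path}: missing '# Dt_nM:' metadata")
    try:
        Dt = float(meta["Dt_nM"])
    except ValueError as exc:
        raise TableFormatError(f"{path}: unparseable Dt_nM {meta['Dt_nM']!r}") from exc
    return BindingTitration(
        Pt=df["Pt"].to_numpy(dtype=float), fb=df["fb"].to_numpy(dtype=float),
        Dt=Dt, stoichiometry=meta.get("stoichiometry", "dimer"),
        truth=truth, seed=seed,
    )


def write_intensity_table(obj, path) -> Path:
    """Write a domain container to its CSV dialect (full precision).

    Round-trips through :func:`read_intensity_table` to ≤1e−12.
    """
    path = Path(path)
    if isinstance(obj, ProgressCurve):
        kind, unit = "cleavage", obj.time_unit
        df = pd.DataFrame({"time": obj.times, "F": obj.F})
    elif isinstance(obj, CruciformTrajectory):
        kind, unit = "cruciform", obj.time_unit
        df = pd.DataFrame({"time": obj.times, "S": obj.fS, "N": obj.fN, "L": obj.fL})
    elif isinstance(obj, BindingTitration):
        kind, unit = "titration", None
        df = pd.DataFrame({"Pt": obj.Pt, "fb": obj.fb})
    else:
        raise DomainError(f"cannot serialize object of type {type(obj).__name__}")

    lines = [f"# junctionfit: {__version__}", f"# kind: {kind}"]
    if unit is not None:
        lines.append(f"# time_unit: {unit}")
    else:
        lines.append(f"# Dt_nM: {obj.Dt!r}")
        lines.append(f"# stoichiometry: {obj.stoichiometry}")
    if obj.seed is not None:
        lines.append(f"# seed: {obj.seed}")
    if obj.truth is not None:
        lines.append(f"# truth: {json.dumps(obj.truth)}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False, float_format="%.17g")
    return path


def write_report(report: dict, path) -> Path:
    """Write a fit report as indented JSON."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=False)
        fh.write("\n")
    return path
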