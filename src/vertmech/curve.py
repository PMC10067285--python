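"""Per-specimen force-displacement recordings: container, validation, file I/O.

A compression test of one vertebral body yields a sampled trace of crosshead
displacement (mm) against axial force (N).  Curves are stored on disk as a
small self-describing CSV dialect::

    # specimen_id: L5-01
    # group_label: SHAM
    # crosshead_speed: 2.0
    displacement_mm,force_N
    0.000000,0.000000
    0.001000,0.152000
    ...

Metadata lines are ``#``-prefixed ``key: value`` pairs; the two data columns
are fixed (mm, N) and written at six decimal places, which bounds the
write/read round-trip error at 5e-7 per sample.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import CurveFormatError, CurveValidationError, VertmechError

#: Local displacement decreases up to this size (mm) are treated as sensor
#: jitter rather than a non-monotone trace.
MONOTONE_TOL = 1e-6

#: Default lowest admissible force sample (N); small negative excursions are
#: load-cell noise around zero contact force.
FORCE_FLOOR = -1.0

_METADATA_KEYS = ("specimen_id", "group_label", "crosshead_speed",
                  "sample_interval", "provenance")
_COLUMNS = ("displacement_mm", "force_N")


@dataclass
class ForceDisplacementCurve:
    """One specimen's sampled displacement/force trace plus acquisition metadata.

    Parameters
    ----------
    displacement : array-like of float
        Crosshead travel in mm, non-decreasing, starting at >= 0.
    force : array-like of float
        Axial force in N, same length as ``displacement``.
    specimen_id : str
        Label of the tested vertebral body.
    group_label : str or None
        Cohort label (e.g. ``"SHAM"`` / ``"OVX"``); optional.
    crosshead_speed : float
        Constant descent rate of the force arm, mm/min.
    sample_interval : float or None
        Seconds between successive samples, if known.
    provenance : str
        Free-text note on where the trace came from.
    """

    displacement: np.ndarray
    force: np.ndarray
    specimen_id: str = "unknown"
    group_label: str | None = None
    crosshead_speed: float = 2.0
    sample_interval: float | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.displacement.ndim != 1 or self.force.ndim != 1:
            raise CurveValidationError("displacement and force must be 1-D")
        if self.displacement.shape != self.force.shape:
            raise CurveValidationError(
                f"displacement ({self.displacement.size}) and force "
                f"({self.force.size}) must have equal length")

    @property
    def n_samples(self) -> int:
        return int(self.displacement.size)

    def validate(self, *, min_length: int = 10,
                 monotone_tol: float = MONOTONE_TOL,
                 force_floor: float = FORCE_FLOOR) -> "ForceDisplacementCurve":
        """Check structural invariants; return self or raise CurveValidationError.

        ``force_floor`` is the configurable noise floor: force may be negative
        only down to this value.
        """
        if self.n_samples < min_length:
            raise CurveValidationError(
                f"curve '{self.specimen_id}' has {self.n_samples} samples; "
                f"need at least {min_length}")
        if self.displacement[0] < -monotone_tol:
            raise CurveValidationError(
                f"curve '{self.specimen_id}': first displacement "
                f"{self.displacement[0]:g} mm is negative")
        steps = np.diff(self.displacement)
        bad = np.nonzero(steps < -monotone_tol)[0]
        if bad.size:
            i = int(bad[0]) + 1
            raise CurveValidationError(
                f"curve '{self.specimen_id}': displacement decreases by "
                f"{-steps[i - 1]:g} mm at sample index {i} "
                f"(tolerance {monotone_tol:g})")
        if not np.all(np.isfinite(self.force)):
            i = int(np.nonzero(~np.isfinite(self.force))[0][0])
            raise CurveValidationError(
                f"curve '{self.specimen_id}': non-finite force at sample {i}")
        if np.any(self.force < force_floor):
            i = int(np.nonzero(self.force < force_floor)[0][0])
            raise CurveValidationError(
                f"curve '{self.specimen_id}': force {self.force[i]:g} N at "
                f"sample {i} is below the noise floor {force_floor:g} N")
        return self

    def slice(self, stop: int) -> "ForceDisplacementCurve":
        """Return a copy truncated to samples ``[0, stop]`` inclusive."""
        return replace(self, displacement=self.displacement[:stop + 1].copy(),
                       force=self.force[:stop + 1].copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"displacement_mm": self.displacement,
                             "force_N": self.force})


def read_curve(path: str | Path, *, monotone_tol: float = MONOTONE_TOL,
               force_floor: float = FORCE_FLOOR,
               validate: bool = True) -> ForceDisplacementCurve:
    """Read one curve CSV written in the dialect described in the module docstring.

    Raises
    ------
    CurveFormatError
        On unparseable metadata, a missing/incorrect column header, or a data
        row that is not two numeric fields (the error names the line).
    CurveValidationError
        If the parsed curve violates a structural invariant.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    rows_d: list[float] = []
    rows_f: list[float] = []
    header_seen = False
    with path.open("r", encoding="utf-8", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" not in body:
                    raise CurveFormatError(
                        f"{path.name}:{lineno}: metadata line lacks 'key: value'")
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
                continue
            fields = next(csv.reader(io.StringIO(line)))
            fields = [f.strip() for f in fields]
            if not header_seen:
                if tuple(fields) != _COLUMNS:
                    raise CurveFormatError(
                        f"{path.name}:{lineno}: expected column header "
                        f"'{','.join(_COLUMNS)}', found '{line}'")
                header_seen = True
                continue
            if len(fields) != 2:
                raise CurveFormatError(
                    f"{path.name}:{lineno}: expected 2 columns, found "
                    f"{len(fields)}")
            try:
                rows_d.append(float(fields[0]))
                rows_f.append(float(fields[1]))
            except ValueError:
                raise CurveFormatError(
                    f"{path.name}:{lineno}: non-numeric value in '{line}'") from None
    if not header_seen:
        raise CurveFormatError(f"{path.name}: no column header found")
    if not rows_d:
        raise CurveFormatError(f"{path.name}: no data rows found")

    kwargs: dict = {}
    if "specimen_id" in meta:
        kwargs["specimen_id"] = meta["specimen_id"]
    else:
        kwargs["specimen_id"] = path.stem
    if meta.get("group_label"):
        kwargs["group_label"] = meta["group_label"]
    for key, cast in (("crosshead_speed", float), ("sample_interval", float)):
        if key in meta:
            try:
                kwargs[key] = cast(meta[key])
            except ValueError:
                raise CurveFormatError(
                    f"{path.name}: metadata '{key}: {meta[key]}' is not numeric"
                ) from None
    if "provenance" in meta:
        kwargs["provenance"] = meta["provenance"]

    curve = ForceDisplacementCurve(np.array(rows_d), np.array(rows_f), **kwargs)
    if validate:
        curve.validate(monotone_tol=monotone_tol, force_floor=force_floor)
    return curve


def write_curve(curve: ForceDisplacementCurve, path: str | Path) -> None:
    """Write ``curve`` in the dialect read by :func:`read_curve`.

    Numeric values are written at six decimal places; metadata whose value is
    unset (``group_label=None``, empty provenance) is omitted.
    """
    path = Path(path)
    lines = [f"# specimen_id: {curve.specimen_id}"]
    if curve.group_label is not None:
        lines.append(f"# group_label: {curve.group_label}")
    lines.append(f"# crosshead_speed: {curve.crosshead_speed:g}")
    if curve.sample_interval is not None:
        lines.append(f"# sample_interval: {curve.sample_interval:g}")
    if curve.provenance:
        lines.append(f"# provenance: {curve.provenance}")
    lines.append(",".join(_COLUMNS))
    for d, f in zip(curve.displacement, curve.force):
        lines.append(f"{d:.6f},{f:.6f}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def smooth_curve(curve: ForceDisplacementCurve,
                 window: int) -> ForceDisplacementCurve:
    """Centred moving-average smoothing of the force channel.

    The window must be odd and at most half the curve length.  At the curve
    ends the window shrinks symmetrically (no padding), so edge samples are
    averaged over fewer points rather than over fabricated data.  ``window=1``
    is the identity.  Displacement is never altered.
    """
    n = curve.n_samples
    if window < 1 or window % 2 == 0:
        raise VertmechError(f"smoothing window must be odd and >= 1, got {window}")
    if window > n // 2:
        raise VertmechError(
            f"smoothing window {window} exceeds half the curve length ({n})")
    if window == 1:
        return replace(curve, force=curve.force.copy())
    half = window // 2
    idx = np.arange(n)
    hw = np.minimum(half, np.minimum(idx, n - 1 - idx))
    cs = np.concatenate([[0.0], np.cumsum(curve.force)])
    smoothed = (cs[idx + hw + 1] - cs[idx - hw]) / (2 * hw + 1)
    return replace(curve, force=smoothed)


# -- cohort-level layout: one file per specimen plus an optional manifest ----

def write_cohort(curves: Sequence[ForceDisplacementCurve],
                 directory: str | Path,
                 manifest_name: str = "manifest.csv") -> Path:
    """Write one CSV per curve plus a manifest (specimen_id, group_label, path)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records = []
    for curve in curves:
        fname = f"curve_{curve.specimen_id}.csv"
        write_curve(curve, directory / fname)
        records.append({"specimen_id": curve.specimen_id,
                        "group_label": curve.group_label or "",
                        "path": fname})
    manifest = directory / manifest_name
    pd.DataFrame(records).to_csv(manifest, index=False)
    return manifest


def read_cohort(source: str | Path) -> list[ForceDisplacementCurve]:
    """Read a cohort from a manifest CSV or from a directory of curve CSVs.

    A directory is scanned for ``curve_*.csv`` (falling back to all ``*.csv``
    except the manifest/truth tables) in sorted order.
    """
    source = Path(source)
    if source.is_dir():
        paths = sorted(source.glob("curve_*.csv"))
        if not paths:
            skip = {"manifest.csv", "truth.csv", "summary.csv"}
            paths = sorted(p for p in source.glob("*.csv") if p.name not in skip)
        return [read_curve(p) for p in paths]
    manifest = pd.read_csv(source)
    if "path" not in manifest.columns:
        raise CurveFormatError(f"{source}: manifest lacks a 'path' column")
    base = source.parent
    return [read_curve(base / p) for p in manifest["path"]]
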