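"""Shared data model, study archive I/O, and map export.

The central objects are :class:`DynamicSeries` (one spatiotemporal image
stack with per-frame metadata), :class:`PerfusionStudy` (the stress/rest
bundle of AIF, myocardial, and proton-density series) and :class:`MBFMap`
(a per-pixel flow map with a validity mask).

Studies can be read from two dialects:

``archive``
    A self-describing directory written by :func:`write_study`: one
    ``.npy`` container per series plus a JSON manifest carrying all
    frame metadata.  This is the canonical interchange format of the
    package and requires no scanner-specific metadata.
``dicom``
    A directory of DICOM files.  Series roles are resolved from a
    sequence/protocol-name regex table, overridable by a sidecar
    ``manifest.json``.  Requires the optional ``pydicom`` dependency.

Intensities are kept in arbitrary signal units; physical meaning enters
downstream only after baseline normalization.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ROLE_AIF",
    "ROLE_MYO",
    "ROLE_PD",
    "AIF_SLICE",
    "CONDITIONS",
    "SLICE_NAMES",
    "PerfquantError",
    "MissingRoleError",
    "GeometryError",
    "DegenerateInputError",
    "DetectionFailureError",
    "TimingFailureError",
    "ParameterError",
    "FrameMeta",
    "DynamicSeries",
    "ConditionData",
    "PerfusionStudy",
    "MBFMap",
    "read_study",
    "write_study",
    "write_map",
    "read_map",
]

ROLE_AIF = "AIF"
ROLE_MYO = "MYO"
ROLE_PD = "PD"
_ROLES = (ROLE_AIF, ROLE_MYO, ROLE_PD)

#: Sentinel ``slice_index`` used for frames of the AIF series.
AIF_SLICE = -1

CONDITIONS = ("stress", "rest")
SLICE_NAMES = ("basal", "mid", "apical")


class PerfquantError(Exception):
    """Base class for all structured errors raised by this package."""


class MissingRoleError(PerfquantError):
    """A required series role (AIF/MYO/PD) is absent from a study."""

    def __init__(self, role: str, detail: str = ""):
        self.role = role
        super().__init__(f"missing series role {role!r}" + (f": {detail}" if detail else ""))


class GeometryError(PerfquantError):
    """Frame/series geometries are inconsistent."""


class DegenerateInputError(PerfquantError):
    """Input is structurally valid but carries no usable signal."""


class DetectionFailureError(PerfquantError):
    """Automatic ROI detection could not find the expected structure."""


class TimingFailureError(PerfquantError):
    """No first-pass contrast enhancement could be located in a curve."""


class ParameterError(PerfquantError):
    """A model parameter violates its declared domain."""


@dataclass(frozen=True)
class FrameMeta:
    """Acquisition metadata for a single frame.

    Parameters
    ----------
    acquisition_time : float
        Seconds from series start.
    trigger_index : int
        Heartbeat number (>= 0).
    slice_index : int
        0..2 for myocardial slices, :data:`AIF_SLICE` for AIF frames.
    pixel_spacing : (float, float)
        mm per pixel, (row, col); both components must be positive.
    slice_thickness : float
        mm.
    """

    acquisition_time: float
    trigger_index: int
    slice_index: int
    pixel_spacing: tuple[float, float] = (1.0, 1.0)
    slice_thickness: float = 8.0

    def __post_init__(self) -> None:
        if self.trigger_index < 0:
            raise ParameterError(f"trigger_index must be >= 0, got {self.trigger_index}")
        if not all(s > 0 for s in self.pixel_spacing):
            raise GeometryError(f"pixel_spacing components must be > 0, got {self.pixel_spacing}")

    def to_json(self) -> dict:
        return {
            "acquisition_time": float(self.acquisition_time),
            "trigger_index": int(self.trigger_index),
            "slice_index": int(self.slice_index),
            "pixel_spacing": [float(self.pixel_spacing[0]), float(self.pixel_spacing[1])],
            "slice_thickness": float(self.slice_thickness),
        }

    @classmethod
    def from_json(cls, d: Mapping) -> "FrameMeta":
        return cls(
            acquisition_time=float(d["acquisition_time"]),
            trigger_index=int(d["trigger_index"]),
            slice_index=int(d["slice_index"]),
            pixel_spacing=(float(d["pixel_spacing"][0]), float(d["pixel_spacing"][1])),
            slice_thickness=float(d["slice_thickness"]),
        )


@dataclass
class DynamicSeries:
    """One spatiotemporal image stack (time x rows x cols) plus metadata."""

    frames: np.ndarray
    meta: list[FrameMeta]
    role: str

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if self.role not in _ROLES:
            raise ParameterError(f"role must be one of {_ROLES}, got {self.role!r}")
        if self.frames.ndim != 3:
            raise GeometryError(f"frames must be 3-D (t, rows, cols), got shape {self.frames.shape}")
        if len(self.meta) != self.frames.shape[0]:
            raise GeometryError(
                f"meta length {len(self.meta)} != number of frames {self.frames.shape[0]}"
            )
        if np.any(self.frames < 0):
            raise ParameterError("frame intensities must be nonnegative")
        trig = [m.trigger_index for m in self.meta]
        t = [m.acquisition_time for m in self.meta]
        order = np.argsort(trig, kind="stable")
        t_sorted = np.asarray(t)[order]
        if len(t_sorted) > 1 and np.any(np.diff(t_sorted) <= 0):
            raise GeometryError("acquisition_time must strictly increase with trigger_index")

    # -- convenience ------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def times(self) -> np.ndarray:
        return np.asarray([m.acquisition_time for m in self.meta], dtype=float)

    def sorted_by_trigger(self) -> "DynamicSeries":
        """Return a copy with frames in canonical trigger order."""
        order = np.argsort([m.trigger_index for m in self.meta], kind="stable")
        return DynamicSeries(
            frames=self.frames[order].copy(),
            meta=[self.meta[i] for i in order],
            role=self.role,
        )

    def with_frames(self, frames: np.ndarray) -> "DynamicSeries":
        """Return a copy carrying ``frames`` but the same metadata/role."""
        return DynamicSeries(frames=frames, meta=list(self.meta), role=self.role)


@dataclass
class ConditionData:
    """All series acquired under one pharmacological condition."""

    aif: DynamicSeries
    myo: tuple[DynamicSeries, DynamicSeries, DynamicSeries]
    pd: tuple[DynamicSeries, ...]  # one 2-frame PD series per slice

    def validate(self) -> None:
        if self.aif.role != ROLE_AIF:
            raise MissingRoleError(ROLE_AIF, f"series has role {self.aif.role!r}")
        if len(self.myo) != 3:
            raise MissingRoleError(ROLE_MYO, f"expected 3 myocardial slices, got {len(self.myo)}")
        for s in self.myo:
            if s.role != ROLE_MYO:
                raise MissingRoleError(ROLE_MYO, f"series has role {s.role!r}")
        if len(self.pd) != 3:
            raise MissingRoleError(ROLE_PD, f"expected PD frames for 3 slices, got {len(self.pd)}")
        for i, (pd_s, myo_s) in enumerate(zip(self.pd, self.myo)):
            if pd_s.role != ROLE_PD:
                raise MissingRoleError(ROLE_PD, f"slice {i} series has role {pd_s.role!r}")
            if pd_s.shape != myo_s.shape:
                raise GeometryError(
                    f"PD frames of slice {i} have shape {pd_s.shape}, MYO has {myo_s.shape}"
                )
        # the AIF readout is deliberately low-resolution
        myo_px = self.myo[0].shape[0] * self.myo[0].shape[1]
        aif_px = self.aif.shape[0] * self.aif.shape[1]
        if aif_px >= myo_px:
            raise GeometryError(
                f"AIF series ({self.aif.shape}) must be lower-resolution than MYO ({self.myo[0].shape})"
            )


@dataclass
class PerfusionStudy:
    """Stress + rest dynamic series bundles for one subject.

    A single condition is permitted for MBF-only runs; both conditions are
    required before perfusion-reserve computation.
    """

    condition_series: dict[str, ConditionData]
    subject_id: str = "unknown"
    rr_interval_s: float = 1.0

    def validate(self) -> None:
        if not self.condition_series:
            raise DegenerateInputError("study contains no conditions")
        for cond, data in self.condition_series.items():
            if cond not in CONDITIONS:
                raise ParameterError(f"unknown condition {cond!r}")
            data.validate()

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(c for c in CONDITIONS if c in self.condition_series)


@dataclass
class MBFMap:
    """Per-pixel flow values (ml/g/min) restricted to a myocardial mask.

    ``values`` holds NaN outside the mask and at flagged fit failures;
    inside the mask all finite values are nonnegative.
    """

    values: np.ndarray
    mask: np.ndarray
    slice_index: int
    condition: str
    failed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise GeometryError("values and mask shapes differ")
        inside = self.values[self.mask]
        finite = inside[np.isfinite(inside)]
        if finite.size and np.any(finite < 0):
            raise ParameterError("masked MBF values must be nonnegative")
        bad = ~np.isfinite(inside)
        if np.any(bad) and self.failed is None:
            # NaN inside the mask must be accounted for by the failure flag
            f = np.zeros_like(self.mask)
            f[self.mask] = bad
            self.failed = f


# ---------------------------------------------------------------------------
# archive dialect
# ---------------------------------------------------------------------------

_ARCHIVE_FORMAT = "perfquant-archive"
_ARCHIVE_VERSION = 1


def _series_to_manifest(series: DynamicSeries, filename: str) -> dict:
    return {
        "file": filename,
        "role": series.role,
        "shape": list(series.frames.shape),
        "meta": [m.to_json() for m in series.meta],
    }


def _series_from_manifest(entry: Mapping, root: Path) -> DynamicSeries:
    frames = np.load(root / entry["file"])
    meta = [FrameMeta.from_json(m) for m in entry["meta"]]
    return DynamicSeries(frames=frames, meta=meta, role=entry["role"]).sorted_by_trigger()


def write_study(study: PerfusionStudy, path) -> dict:
    """Write ``study`` as a self-describing archive directory.

    Returns the manifest dictionary that was written.  Raises before
    creating anything when the study is empty or invalid.
    """
    study.validate()
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "format": _ARCHIVE_FORMAT,
        "version": _ARCHIVE_VERSION,
        "subject_id": study.subject_id,
        "rr_interval_s": float(study.rr_interval_s),
        "conditions": {},
    }
    for cond, data in study.condition_series.items():
        entry: dict = {}
        fn = f"{cond}_aif.npy"
        np.save(root / fn, data.aif.frames)
        entry["aif"] = _series_to_manifest(data.aif, fn)
        entry["myo"] = []
        for i, s in enumerate(data.myo):
            fn = f"{cond}_myo{i}.npy"
            np.save(root / fn, s.frames)
            entry["myo"].append(_series_to_manifest(s, fn))
        entry["pd"] = []
        for i, s in enumerate(data.pd):
            fn = f"{cond}_pd{i}.npy"
            np.save(root / fn, s.frames)
            entry["pd"].append(_series_to_manifest(s, fn))
        manifest["conditions"][cond] = entry
    with open(root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def _read_study_archive(root: Path) -> PerfusionStudy:
    mf_path = root / "manifest.json"
    if not mf_path.exists():
        raise PerfquantError(f"no manifest.json under {root}")
    with open(mf_path) as fh:
        manifest = json.load(fh)
    if manifest.get("format") != _ARCHIVE_FORMAT:
        raise PerfquantError(f"unrecognized archive format {manifest.get('format')!r}")
    conditions: dict[str, ConditionData] = {}
    for cond, entry in manifest["conditions"].items():
        if "aif" not in entry:
            raise MissingRoleError(ROLE_AIF, f"condition {cond!r}")
        if "myo" not in entry or not entry["myo"]:
            raise MissingRoleError(ROLE_MYO, f"condition {cond!r}")
        if "pd" not in entry or not entry["pd"]:
            raise MissingRoleError(ROLE_PD, f"condition {cond!r}")
        aif = _series_from_manifest(entry["aif"], root)
        myo = tuple(_series_from_manifest(e, root) for e in entry["myo"])
        pd_ = tuple(_series_from_manifest(e, root) for e in entry["pd"])
        conditions[cond] = ConditionData(aif=aif, myo=myo, pd=pd_)
    study = PerfusionStudy(
        condition_series=conditions,
        subject_id=manifest.get("subject_id", "unknown"),
        rr_interval_s=float(manifest.get("rr_interval_s", 1.0)),
    )
    study.validate()
    return study


# ---------------------------------------------------------------------------
# DICOM dialect
# ---------------------------------------------------------------------------

#: Default series-role resolution by sequence/protocol description.
#: Overridable via a sidecar ``manifest.json`` mapping SeriesInstanceUID to
#: {"role": ..., "condition": ..., "slice_index": ...}.
DICOM_ROLE_PATTERNS: dict[str, str] = {
    ROLE_AIF: r"(?i)\baif\b",
    ROLE_PD: r"(?i)(proton|\bpd\b)",
    ROLE_MYO: r"(?i)(perf|myo)",
}


def _read_study_dicom(root: Path) -> PerfusionStudy:
    try:
        import pydicom  # noqa: F401
    except ImportError as exc:  # pragma: no cover - exercised only without pydicom
        raise PerfquantError(
            "reading the DICOM dialect requires the optional 'pydicom' dependency; "
            "install it or convert the study to the archive dialect"
        ) from exc

    sidecar: dict = {}
    sc_path = root / "manifest.json"
    if sc_path.exists():
        with open(sc_path) as fh:
            sidecar = json.load(fh)

    series: dict[str, list] = {}
    for fp in sorted(root.rglob("*")):
        if not fp.is_file() or fp.name == "manifest.json":
            continue
        try:
            ds = pydicom.dcmread(fp)
        except Exception:
            continue
        series.setdefault(str(ds.SeriesInstanceUID), []).append(ds)

    def resolve_role(uid: str, desc: str) -> tuple[str | None, str | None, int | None]:
        if uid in sidecar:
            e = sidecar[uid]
            return e.get("role"), e.get("condition"), e.get("slice_index")
        for role, pat in DICOM_ROLE_PATTERNS.items():
            if re.search(pat, desc):
                cond = "stress" if re.search(r"(?i)stress", desc) else "rest"
                return role, cond, None
        return None, None, None

    buckets: dict[str, dict] = {c: {"aif": None, "myo": {}, "pd": {}} for c in CONDITIONS}
    for uid, dsets in series.items():
        desc = str(getattr(dsets[0], "SeriesDescription", ""))
        role, cond, slice_idx = resolve_role(uid, desc)
        if role is None or cond is None:
            warnings.warn(f"unresolved DICOM series {uid} ({desc!r}); skipped")
            continue
        dsets.sort(key=lambda d: float(getattr(d, "TriggerTime", 0.0)))
        frames, meta = [], []
        for k, d in enumerate(dsets):
            arr = d.pixel_array.astype(np.float64)
            slope = float(getattr(d, "RescaleSlope", 1.0))
            inter = float(getattr(d, "RescaleIntercept", 0.0))
            frames.append(arr * slope + inter)
            spacing = getattr(d, "PixelSpacing", [1.0, 1.0])
            meta.append(
                FrameMeta(
                    acquisition_time=float(getattr(d, "TriggerTime", k * 1000.0)) / 1000.0,
                    trigger_index=k,
                    slice_index=AIF_SLICE if role == ROLE_AIF else int(slice_idx or 0),
                    pixel_spacing=(float(spacing[0]), float(spacing[1])),
                    slice_thickness=float(getattr(d, "SliceThickness", 8.0)),
                )
            )
        ds_obj = DynamicSeries(np.stack(frames), meta, role)
        if role == ROLE_AIF:
            buckets[cond]["aif"] = ds_obj
        elif role == ROLE_MYO:
            buckets[cond]["myo"][int(slice_idx or len(buckets[cond]["myo"]))] = ds_obj
        else:
            buckets[cond]["pd"][int(slice_idx or len(buckets[cond]["pd"]))] = ds_obj

    conditions = {}
    for cond, b in buckets.items():
        if b["aif"] is None and not b["myo"]:
            continue
        if b["aif"] is None:
            raise MissingRoleError(ROLE_AIF, f"condition {cond!r}")
        if len(b["myo"]) != 3:
            raise MissingRoleError(ROLE_MYO, f"condition {cond!r}: found {len(b['myo'])} slices")
        if len(b["pd"]) != 3:
            raise MissingRoleError(ROLE_PD, f"condition {cond!r}: found {len(b['pd'])} slices")
        conditions[cond] = ConditionData(
            aif=b["aif"],
            myo=tuple(b["myo"][i] for i in sorted(b["myo"])),
            pd=tuple(b["pd"][i] for i in sorted(b["pd"])),
        )
    study = PerfusionStudy(condition_series=conditions)
    study.validate()
    return study


def read_study(path, dialect: str = "archive") -> PerfusionStudy:
    """Read a perfusion study from ``path``.

    Parameters
    ----------
    path : path-like
        Study directory.
    dialect : {"archive", "dicom"}
        On-disk layout; see the module docstring.
    """
    root = Path(path)
    if not root.exists():
        raise FileNotFoundError(root)
    if dialect == "archive":
        return _read_study_archive(root)
    if dialect == "dicom":
        return _read_study_dicom(root)
    raise ParameterError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# map export
# ---------------------------------------------------------------------------

def write_map(mbf_map: MBFMap, path, format: str = "float_image") -> None:
    """Write an MBF map either as a 32-bit float NIfTI or a masked CSV table.

    ``float_image`` preserves values losslessly in a float32 container;
    ``table`` writes one ``row,col,value`` line per masked pixel.
    """
    path = Path(path)
    if format == "float_image":
        import nibabel as nib

        img = nib.Nifti1Image(mbf_map.values.astype(np.float32), affine=np.eye(4))
        nib.save(img, str(path))
    elif format == "table":
        rows, cols = np.nonzero(mbf_map.mask)
        with open(path, "w") as fh:
            fh.write("row,col,value\n")
            for r, c in zip(rows, cols):
                fh.write(f"{r},{c},{mbf_map.values[r, c]!r}\n")
    else:
        raise ParameterError(f"unknown map format {format!r}")


def read_map(path) -> np.ndarray:
    """Read back a ``float_image`` map written by :func:`write_map`."""
    import nibabel as nib

    return np.asanyarray(nib.load(str(path)).dataobj).astype(np.float32)
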