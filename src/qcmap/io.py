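"""NIfTI reading/writing and YAML run-configuration loading.

NIfTI-1 is the reference on-disk format for every volume the pipeline
touches (echoes, phase maps, conductivity maps, label masks).  Two scanner
export dialects are supported for complex echo data:

* ``complex``  — a single complex-valued 3D NIfTI;
* ``magphase`` — a 4D NIfTI whose two volumes are magnitude then phase;
* ``pair``     — separate magnitude and phase files.

Phase on disk may be radians (default) or degrees (``degrees=True``); it is
always mapped into (-pi, pi] on load.  Invalid conductivity voxels are
written as NaN.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .errors import FormatError, ParameterError, ShapeError
from .volumes import (
    ConductivityMap,
    EchoRole,
    EchoVolume,
    LabelMask,
    PhaseVolume,
    wrap_phase,
)

__all__ = [
    "read_echo_volume",
    "write_map",
    "read_phase_volume",
    "read_label_mask",
    "write_label_mask",
    "load_yaml_config",
]

_DIALECTS = ("complex", "magphase", "pair")


def _load_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        zooms = img.header.get_zooms()
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    spacing = tuple(float(z) for z in zooms[:3])
    return data, spacing


def read_echo_volume(
    path,
    echo_role: EchoRole | str,
    dialect: str = "complex",
    phase_path=None,
    degrees: bool = False,
) -> EchoVolume:
    """Read one echo volume in the configured on-disk dialect.

    Phase is converted to radians when ``degrees`` is set, then wrapped to
    (-pi, pi]; voxel spacing comes from the NIfTI header.
    """
    if dialect not in _DIALECTS:
        raise ParameterError(f"dialect must be one of {_DIALECTS}, got {dialect!r}")
    data, spacing = _load_nifti(path)
    if dialect == "complex":
        if data.ndim != 3:
            raise ShapeError(f"complex dialect expects a 3D volume, got ndim={data.ndim}")
        if not np.iscomplexobj(data):
            raise FormatError(f"{path} does not hold complex-valued data")
        magnitude = np.abs(data)
        phase = np.angle(data)
    elif dialect == "magphase":
        if data.ndim != 4 or data.shape[3] != 2:
            raise ShapeError(
                "magphase dialect expects a 4D volume with 2 sub-volumes, "
                f"got shape {data.shape}"
            )
        magnitude = np.asarray(data[..., 0], dtype=float)
        phase = np.asarray(data[..., 1], dtype=float)
    else:  # pair
        if phase_path is None:
            raise ParameterError("pair dialect needs phase_path")
        if data.ndim != 3:
            raise ShapeError(f"magnitude volume must be 3D, got ndim={data.ndim}")
        magnitude = np.asarray(data, dtype=float)
        phase, phase_spacing = _load_nifti(phase_path)
        if phase.ndim != 3:
            raise ShapeError(f"phase volume must be 3D, got ndim={phase.ndim}")
        if phase.shape != magnitude.shape:
            raise ShapeError(
                f"paired volumes disagree: magnitude {magnitude.shape}, phase {phase.shape}"
            )
        phase = np.asarray(phase, dtype=float)
    if degrees:
        phase = np.deg2rad(phase)
    return EchoVolume(
        magnitude=np.asarray(magnitude, dtype=float),
        phase=wrap_phase(phase),
        spacing_mm=spacing,
        echo_role=EchoRole(echo_role),
    )


def _affine(spacing_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    return aff


def write_map(path, volume: ConductivityMap | PhaseVolume) -> None:
    """Write a conductivity or phase map as NIfTI with spacing in the header;
    invalid conductivity voxels are NaN in the file."""
    if isinstance(volume, ConductivityMap):
        data = np.where(volume.valid, volume.sigma, np.nan)
    elif isinstance(volume, PhaseVolume):
        data = volume.values
    else:
        raise ParameterError(f"cannot write object of type {type(volume).__name__}")
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), _affine(volume.spacing_mm))
    img.header.set_zooms(volume.spacing_mm)
    nib.save(img, str(path))


def read_phase_volume(path, wrapped: bool = False, degrees: bool = False) -> PhaseVolume:
    """Read a real-valued phase map written by :func:`write_map`."""
    data, spacing = _load_nifti(path)
    if data.ndim != 3:
        raise ShapeError(f"phase volume must be 3D, got ndim={data.ndim}")
    values = np.asarray(data, dtype=float)
    if degrees:
        values = np.deg2rad(values)
    if wrapped:
        values = wrap_phase(values)
    return PhaseVolume(values=values, spacing_mm=spacing, wrapped=wrapped)


def read_conductivity_map(path) -> ConductivityMap:
    """Read a conductivity map; NaN voxels become invalid."""
    data, spacing = _load_nifti(path)
    if data.ndim != 3:
        raise ShapeError(f"conductivity map must be 3D, got ndim={data.ndim}")
    data = np.asarray(data, dtype=float)
    return ConductivityMap(sigma=data, valid=np.isfinite(data), spacing_mm=spacing)


def read_label_mask(path) -> LabelMask:
    data, spacing = _load_nifti(path)
    if data.ndim != 3:
        raise ShapeError(f"label mask must be 3D, got ndim={data.ndim}")
    labels = np.asarray(data)
    if not np.issubdtype(labels.dtype, np.integer):
        rounded = np.rint(labels)
        if not np.allclose(labels, rounded):
            raise FormatError(f"{path} holds non-integer label values")
        labels = rounded
    return LabelMask(labels=labels.astype(np.int32))


def write_label_mask(path, mask: LabelMask, spacing_mm=(1.0, 1.0, 1.0)) -> None:
    img = nib.Nifti1Image(mask.labels.astype(np.int32), _affine(spacing_mm))
    img.header.set_zooms(spacing_mm)
    nib.save(img, str(path))


def load_yaml_config(path) -> dict:
    """Load a YAML run configuration into a plain dict."""
    path = Path(path)
    try:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise FormatError(f"cannot parse YAML config {path}: {exc}") from exc
    if not isinstance(cfg, dict):
        raise FormatError(f"config {path} must be a YAML mapping")
    return cfg
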