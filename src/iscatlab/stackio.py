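"""Image stack container and TIFF round-trip with sidecar metadata.

Stacks are 2-4D arrays with axes drawn from ``t z y x`` (time, focus,
lateral).  Axis order and voxel sizes travel in a JSON sidecar next to
the TIFF so that a stack written by the simulator is read back with its
full acquisition context (sampling, frame interval, seed, model
parameters).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np
import tifffile

_VALID_AXES = {2: ("yx",), 3: ("tyx", "zyx"), 4: ("tzyx",)}


@dataclass
class ImageStack:
    """An intensity or contrast stack plus axis metadata.

    ``axes`` is a string like ``"zyx"`` naming each array dimension;
    ``pixel_size`` / ``z_step`` are in nm, ``frame_interval`` in s.
    ``z_positions`` (nm) records the focus position of every z plane.
    """

    data: np.ndarray
    axes: str
    pixel_size: float = 30.0
    z_step: float = 30.0
    frame_interval: float = 1.0
    z_positions: np.ndarray | None = None
    meta: dict = dfield(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        valid = _VALID_AXES.get(self.data.ndim)
        if valid is None or self.axes not in valid:
            raise ValueError(
                f"unsupported stack: ndim={self.data.ndim}, axes={self.axes!r}; "
                f"supported axis orders are yx, tyx, zyx, tzyx"
            )
        if self.z_positions is not None:
            self.z_positions = np.asarray(self.z_positions, dtype=float)

    @property
    def shape(self):
        return self.data.shape


def write_stack(stack: ImageStack, path) -> None:
    """Write a multi-page TIFF plus a ``.json`` metadata sidecar."""
    path = Path(path)
    data = stack.data
    if data.dtype not in (np.float32, np.uint16, np.uint8):
        data = data.astype(np.float32)
    tifffile.imwrite(path, data, photometric="minisblack")
    meta = {
        "axes": stack.axes,
        "pixel_size_nm": stack.pixel_size,
        "z_step_nm": stack.z_step,
        "frame_interval_s": stack.frame_interval,
        "z_positions_nm": None if stack.z_positions is None
        else list(map(float, stack.z_positions)),
        **stack.meta,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_stack(path) -> ImageStack:
    """Read a TIFF written by :func:`write_stack` (sidecar required for >2D)."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim not in _VALID_AXES:
        raise ValueError(f"{path}: {data.ndim}-D stacks are not supported (2-4D only)")
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    elif data.ndim == 2:
        meta = {"axes": "yx"}
    else:
        raise ValueError(
            f"{path}: missing sidecar {sidecar.name}; cannot determine axis order "
            f"(need 'axes' plus voxel sizes for a {data.ndim}-D stack)"
        )
    zpos = meta.pop("z_positions_nm", None)
    return ImageStack(
        data=data,
        axes=meta.pop("axes"),
        pixel_size=meta.pop("pixel_size_nm", 30.0),
        z_step=meta.pop("z_step_nm", 30.0),
        frame_interval=meta.pop("frame_interval_s", 1.0),
        z_positions=None if zpos is None else np.asarray(zpos, dtype=float),
        meta=meta,
    )
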