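"""TIFF reading/writing for :class:`~ermech_quant.core.CellImage`.

Images are written as plain multi-channel TIFF with a JSON description
block carrying channel names, pixel size and z-step; masks travel as extra
uint8 channels named ``mask:<name>``. A pixel size supplied by a run
manifest overrides the file metadata (the mismatch is logged).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import tifffile

from .core import CellImage
from .errors import PipelineIOError

logger = logging.getLogger(__name__)

_MASK_PREFIX = "mask:"


def write_image(path: str | Path, image: CellImage) -> None:
    data = np.asarray(image.data, dtype=np.float32)
    names = list(image.channel_names)
    for name, mask in image.masks.items():
        data = np.concatenate([data, mask.astype(np.float32)[None]], axis=0)
        names.append(_MASK_PREFIX + name)
    meta = {
        "channel_names": names,
        "pixel_size_nm": image.pixel_size_nm,
        "z_step_nm": image.z_step_nm,
    }
    tifffile.imwrite(
        str(path),
        data,
        photometric="minisblack",
        description=json.dumps(meta, sort_keys=True),
    )


def read_image(
    path: str | Path,
    expected_channels: int | None = None,
    pixel_size_nm: float | None = None,
) -> CellImage:
    """Read a TIFF written by :func:`write_image`.

    ``pixel_size_nm`` (e.g. from a run manifest) takes precedence over the
    file's metadata; a conflict is logged, not raised. A channel-count
    mismatch is an error naming the path.
    """
    p = Path(path)
    if not p.exists():
        raise PipelineIOError(f"image file not found: {p}")
    try:
        with tifffile.TiffFile(str(p)) as tf:
            data = tf.asarray()
            desc = tf.pages[0].description
    except Exception as exc:  # malformed file
        raise PipelineIOError(f"cannot read TIFF {p}: {exc}") from exc
    try:
        meta = json.loads(desc) if desc else {}
    except json.JSONDecodeError:
        meta = {}
    names = meta.get("channel_names")
    if names is None:
        names = [f"ch{i}" for i in range(data.shape[0])] if data.ndim >= 3 else ["ch0"]
    if data.ndim == 2:
        data = data[None]
    masks = {}
    keep = []
    for i, name in enumerate(names):
        if name.startswith(_MASK_PREFIX):
            masks[name[len(_MASK_PREFIX):]] = data[i] > 0.5
        else:
            keep.append(i)
    channel_names = [names[i] for i in keep]
    data = data[keep]
    if expected_channels is not None and len(channel_names) != expected_channels:
        raise PipelineIOError(
            f"{p}: expected {expected_channels} channels, found "
            f"{len(channel_names)} ({channel_names})"
        )
    file_px = meta.get("pixel_size_nm")
    if pixel_size_nm is not None:
        if file_px is not None and abs(file_px - pixel_size_nm) > 1e-9:
            logger.warning(
                "%s: manifest pixel size %.6g nm overrides metadata %.6g nm",
                p, pixel_size_nm, file_px,
            )
        px = pixel_size_nm
    elif file_px is not None:
        px = file_px
    else:
        raise PipelineIOError(f"{p}: no pixel size in metadata or manifest")
    return CellImage(data, channel_names, px, meta.get("z_step_nm"), masks)
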