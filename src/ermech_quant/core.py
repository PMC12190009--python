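"""Shared carrier types: multi-channel images and synthetic ground truth.

Conventions used throughout the package:

* pixel coordinates are 0-based, row-major, half-open ranges;
* physical distances are derived from ``pixel_size_nm`` (isotropic in-plane)
  plus ``z_step_nm`` for stacks;
* every synthetic fixture travels with a :class:`SyntheticTruth` recording
  the generator name, all parameters (units in the key names) and the seed,
  so that regeneration is bit-for-bit reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

from .errors import DomainError, FormatError


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth record attached to every synthetic fixture.

    ``parameters`` keys carry their units as suffixes (``tau1_ns``,
    ``span_nm``, ...); values are JSON-serialisable scalars or lists.
    """

    generator_name: str
    parameters: Mapping[str, Any]
    seed: int

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise DomainError("seed must be a non-negative integer")

    def to_json(self) -> str:
        return json.dumps(
            {
                "generator_name": self.generator_name,
                "parameters": _jsonable(self.parameters),
                "seed": int(self.seed),
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(d["generator_name"], d["parameters"], d["seed"])


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


@dataclass(frozen=True)
class StretchGeometry:
    """Uniaxial stretch of a membrane-tethered domain.

    ``displacement_um`` is always ``length_um * strain_pct / 100`` — the
    conversion used to impose a percent strain on a domain of known length.
    """

    length_um: float
    strain_pct: float
    displacement_um: float = field(init=False)

    def __post_init__(self) -> None:
        if self.length_um <= 0:
            raise DomainError("length must be positive")
        if self.strain_pct < 0:
            raise DomainError("strain must be non-negative")
        object.__setattr__(
            self, "displacement_um", self.length_um * self.strain_pct / 100.0
        )


@dataclass
class CellImage:
    """Multi-channel 2D image or 3D stack with physical pixel size.

    ``data`` has shape ``(C, Y, X)`` or ``(C, Z, Y, X)``; all channels share
    one shape. ``masks`` are named boolean images matching the in-plane (2D)
    or full (3D) shape. When both ``cytoplasm`` and ``nucleus`` masks are
    present the cytoplasm excludes the nucleus.
    """

    data: np.ndarray
    channel_names: list[str]
    pixel_size_nm: float
    z_step_nm: float | None = None
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise FormatError("data must be (C, Y, X) or (C, Z, Y, X)")
        if len(self.channel_names) != self.data.shape[0]:
            raise FormatError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} channels"
            )
        if self.pixel_size_nm <= 0:
            raise DomainError("pixel_size must be positive")
        if self.data.ndim == 4 and (self.z_step_nm is None or self.z_step_nm <= 0):
            raise DomainError("3D stacks require a positive z_step_nm")
        frame_shape = self.data.shape[1:]
        for name, m in self.masks.items():
            if m.shape != frame_shape:
                raise FormatError(f"mask {name!r} shape {m.shape} != {frame_shape}")
            self.masks[name] = m.astype(bool)
        cyto, nuc = self.masks.get("cytoplasm"), self.masks.get("nucleus")
        if cyto is not None and nuc is not None and np.any(cyto & nuc):
            raise FormatError("cytoplasm mask must exclude the nucleus mask")

    @property
    def is_stack(self) -> bool:
        return self.data.ndim == 4

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.data[self.channel_names.index(name)]
        except ValueError:
            raise KeyError(f"no channel named {name!r}") from None
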