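"""Axis conventions for up-to-5D microscopy images.

Canonical in-memory order is TCZYX (the OME convention); any subsequence of it
is a valid axis set as long as Y and X are present. On-disk CTZYX (as some
writers emit) is accepted as a readable dialect and canonicalized on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CANONICAL_ORDER = "TCZYX"
SPATIAL = "ZYX"

#: axis order guessed from bare array rank when metadata is absent
RANK_DIALECT = {2: "YX", 3: "ZYX", 4: "CZYX", 5: "TCZYX"}


@dataclass(frozen=True)
class AxisSpec:
    """An ordered set of axis labels drawn from {T, C, Z, Y, X}."""

    labels: str

    def __post_init__(self):
        labels = self.labels.upper()
        object.__setattr__(self, "labels", labels)
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate axis labels in {labels!r}")
        unknown = set(labels) - set(CANONICAL_ORDER)
        if unknown:
            raise ValueError(f"unknown axis labels {sorted(unknown)}")
        if "Y" not in labels or "X" not in labels:
            raise ValueError(f"axes {labels!r} must contain Y and X")

    @property
    def is_canonical(self) -> bool:
        return self.labels == "".join(a for a in CANONICAL_ORDER if a in self.labels)

    @property
    def canonical(self) -> "AxisSpec":
        return AxisSpec("".join(a for a in CANONICAL_ORDER if a in self.labels))

    @property
    def spatial(self) -> str:
        return "".join(a for a in self.labels if a in SPATIAL)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def __len__(self):
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)


@dataclass
class NDImage:
    """Axis-labeled voxel array with optional physical voxel sizes (microns).

    ``voxel_size`` has one entry per spatial axis, in the order of
    ``axes.spatial`` (e.g. (Z, Y, X) for a 3D stack).
    """

    data: np.ndarray
    axes: AxisSpec
    voxel_size: tuple[float, ...] | None = None
    _loader: object = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if isinstance(self.axes, str):
            self.axes = AxisSpec(self.axes)
        self._validate()

    def _validate(self):
        if self._loader is not None and self.__dict__.get("data") is None:
            return  # lazy; validated on materialization
        if self.data.ndim != len(self.axes):
            raise ValueError(
                f"array rank {self.data.ndim} != number of axes {len(self.axes)}"
            )
        for label in self.axes.spatial:
            if self.data.shape[self.axes.index(label)] < 1:
                raise ValueError(f"spatial axis {label} has zero extent")
        if self.voxel_size is not None:
            vs = tuple(float(v) for v in self.voxel_size)
            if len(vs) != len(self.axes.spatial):
                raise ValueError(
                    "voxel_size needs one entry per spatial axis "
                    f"({len(self.axes.spatial)}), got {len(vs)}"
                )
            if any(v <= 0 for v in vs):
                raise ValueError("voxel sizes must be > 0")
            self.voxel_size = vs

    @property
    def dtype_kind(self) -> str:
        return {"u": "uint", "i": "int", "f": "float"}[self.data.dtype.kind]

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return tuple(self.data.shape[self.axes.index(a)] for a in self.axes.spatial)

    def canonicalize(self) -> "NDImage":
        """Reorder axes into TCZYX subsequence order; idempotent."""
        if self.axes.is_canonical:
            return self
        target = self.axes.canonical
        perm = [self.axes.index(a) for a in target.labels]
        return NDImage(
            np.transpose(self.data, perm), target, voxel_size=self.voxel_size
        )

    def with_data(self, data: np.ndarray) -> "NDImage":
        return NDImage(data, self.axes, voxel_size=self.voxel_size)


class LazyNDImage(NDImage):
    """NDImage whose pixels are read from disk on first access."""

    def __init__(self, loader, axes, voxel_size=None):
        self._loader = loader
        self._data = None
        self.axes = AxisSpec(axes) if isinstance(axes, str) else axes
        self.voxel_size = (
            tuple(float(v) for v in voxel_size) if voxel_size is not None else None
        )

    @property
    def data(self) -> np.ndarray:
        if self._data is None:
            self._data = np.asarray(self._loader())
            self._validate_loaded()
        return self._data

    @data.setter
    def data(self, value):
        self._data = value

    def _validate_loaded(self):
        if self._data.ndim != len(self.axes):
            raise ValueError(
                f"array rank {self._data.ndim} != number of axes {len(self.axes)}"
            )

    @property
    def materialized(self) -> bool:
        return self._data is not None
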