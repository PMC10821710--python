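"""TIFF / OME-TIFF reading and writing.

Axes come from OME metadata when present, otherwise from array rank via the
dialect table (2→YX, 3→ZYX, 4→CZYX, 5→TCZYX). On-disk CTZYX is accepted and
canonicalized to TCZYX in memory. Reading is deferred: pixels are materialized
from disk on first access to ``.data``. Writing always emits OME-TIFF with the
axis string and physical voxel sizes (microns) recorded; float data is stored
as float32, integer dtypes losslessly.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import tifffile

from ..core.axes import CANONICAL_ORDER, RANK_DIALECT, AxisSpec, LazyNDImage, NDImage


class ImageIOError(IOError):
    pass


def _axes_from_tiff(path: Path) -> tuple[str, tuple[float, ...] | None]:
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        axes = series.axes.upper().replace("S", "C").replace("I", "Z").replace("Q", "")
        shape = series.shape
        voxel = None
        if tf.ome_metadata:
            try:
                import xml.etree.ElementTree as ET

                root = ET.fromstring(tf.ome_metadata)
                ns = {"ome": root.tag.split("}")[0].strip("{")}
                px = root.find(".//ome:Pixels", ns)
                if px is not None:
                    sizes = {}
                    for ax in "ZYX":
                        v = px.get(f"PhysicalSize{ax}")
                        if v is not None:
                            sizes[ax] = float(v)
                    if sizes:
                        spatial = [a for a in axes if a in "ZYX"]
                        if all(a in sizes for a in spatial):
                            voxel = tuple(sizes[a] for a in spatial)
            except Exception:
                voxel = None
    if not axes or len(axes) != len(shape):
        axes = RANK_DIALECT.get(len(shape), "")
    return axes, voxel


def read_image(ref: str | os.PathLike, as_axes: AxisSpec | str | None = None) -> NDImage:
    """Read a TIFF/OME-TIFF into an axis-labeled image, lazily.

    ``as_axes`` overrides axis inference (must match the file's rank).
    """
    path = Path(ref)
    if not path.exists():
        raise ImageIOError(f"image file not found: {path}")
    try:
        with tifffile.TiffFile(path) as tf:
            rank = len(tf.series[0].shape)
    except Exception as err:
        raise ImageIOError(f"unreadable image {path}: {err}") from None
    if rank > 5:
        raise ImageIOError(f"unsupported dimensionality: {path} has rank {rank} > 5")
    if rank < 2:
        raise ImageIOError(f"image {path} has rank {rank} < 2")

    if as_axes is not None:
        axes = as_axes if isinstance(as_axes, str) else as_axes.labels
        voxel = None
    else:
        axes, voxel = _axes_from_tiff(path)
        if len(axes) != rank:
            axes = RANK_DIALECT[rank]

    spec = AxisSpec(axes)
    if spec.is_canonical:
        img = LazyNDImage(lambda: tifffile.imread(path), spec, voxel_size=voxel)
        return img
    # non-canonical dialect (e.g. CTZYX): materialize and transpose
    data = tifffile.imread(path)
    return NDImage(data, spec, voxel_size=voxel).canonicalize()


def write_image(img: NDImage, ref: str | os.PathLike) -> None:
    """Write an image as OME-TIFF with axes and voxel size in the metadata."""
    path = Path(ref)
    if not path.parent.exists():
        raise ImageIOError(f"parent directory does not exist: {path.parent}")
    img = img.canonicalize()
    data = img.data
    if data.dtype.kind == "f" and data.dtype != np.float32:
        data = data.astype(np.float32)
    metadata = {"axes": img.axes.labels}
    if img.voxel_size is not None:
        for ax, v in zip(img.axes.spatial, img.voxel_size):
            metadata[f"PhysicalSize{ax}"] = float(v)
    try:
        tifffile.imwrite(path, data, ome=True, metadata=metadata)
    except OSError as err:
        raise ImageIOError(f"cannot write {path}: {err}") from None
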