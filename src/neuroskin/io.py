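"""File formats: multi-channel TIFF, mask TIFF stacks, YAML sidecars, CSV.

A section on disk is three files sharing a stem:

* ``<stem>_channels.tif`` — uint16 stack, one page per fluorescence channel;
* ``<stem>_masks.tif``    — uint8 stack (0/255), one page per structure mask;
* ``<stem>.yaml``         — sidecar with ``pixel_size_um``, the channel
  order (index -> marker) and the mask page order.

Single-class label images (0 = background, documented integer per class)
are supported through :func:`write_label_image` / :func:`read_label_image`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .fluorescence import ChannelImage
from .masks import RasterMask
from .synthetic import AnnotatedSection

__all__ = [
    "write_section",
    "read_section",
    "write_label_image",
    "read_label_image",
    "write_polyline_csv",
]


def write_section(stem, section: AnnotatedSection) -> None:
    stem = Path(stem)
    markers = list(section.channels)
    mask_names = list(section.masks)
    chan_stack = np.stack([np.asarray(section.channels[m].grid, dtype=np.uint16) for m in markers])
    mask_stack = np.stack(
        [section.masks[m].grid.astype(np.uint8) * 255 for m in mask_names]
    )
    tifffile.imwrite(f"{stem}_channels.tif", chan_stack, photometric="minisblack")
    tifffile.imwrite(f"{stem}_masks.tif", mask_stack, photometric="minisblack")
    sidecar = {
        "pixel_size_um": float(section.pixel_size_um),
        "channels": markers,
        "masks": mask_names,
        "bit_depth": int(next(iter(section.channels.values())).bit_depth)
        if section.channels
        else 16,
    }
    with open(f"{stem}.yaml", "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=False)


def read_section(stem) -> AnnotatedSection:
    stem = Path(stem)
    with open(f"{stem}.yaml") as fh:
        sidecar = yaml.safe_load(fh)
    ps = float(sidecar["pixel_size_um"])
    chan_stack = tifffile.imread(f"{stem}_channels.tif")
    mask_stack = tifffile.imread(f"{stem}_masks.tif")
    if chan_stack.ndim == 2:
        chan_stack = chan_stack[None]
    if mask_stack.ndim == 2:
        mask_stack = mask_stack[None]
    channels = {
        marker: ChannelImage(
            grid=chan_stack[i], marker=marker, pixel_size_um=ps,
            bit_depth=int(sidecar.get("bit_depth", 16)),
        )
        for i, marker in enumerate(sidecar["channels"])
    }
    masks = {
        name: RasterMask(mask_stack[i] > 0, ps)
        for i, name in enumerate(sidecar["masks"])
    }
    return AnnotatedSection(channels=channels, masks=masks, pixel_size_um=ps)


def write_label_image(path, masks: dict, labels: dict, pixel_size_um: float) -> None:
    """Write disjoint class masks as one label image plus a YAML sidecar.

    ``labels`` maps class name -> positive integer; later classes overwrite
    earlier ones where masks overlap (callers should pass disjoint classes).
    """
    path = Path(path)
    shape = next(iter(masks.values())).shape
    img = np.zeros(shape, dtype=np.uint8)
    for name, label in labels.items():
        img[masks[name].grid] = label
    tifffile.imwrite(path, img)
    with open(path.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump(
            {"pixel_size_um": float(pixel_size_um), "labels": dict(labels)}, fh,
            sort_keys=False,
        )


def read_label_image(path) -> dict:
    """Read a label image back into per-class :class:`RasterMask` objects."""
    path = Path(path)
    img = tifffile.imread(path)
    with open(path.with_suffix(".yaml")) as fh:
        sidecar = yaml.safe_load(fh)
    ps = float(sidecar["pixel_size_um"])
    return {name: RasterMask(img == label, ps) for name, label in sidecar["labels"].items()}


def write_polyline_csv(path, polylines) -> None:
    """Export ordered (row, col) pixel-center coordinates, one segment id per polyline."""
    rows = []
    for seg, poly in enumerate(polylines):
        for r, c in poly:
            rows.append({"segment": seg, "row": float(r), "col": float(c)})
    pd.DataFrame(rows).to_csv(path, index=False)
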