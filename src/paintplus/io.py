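"""File-format handling: TIFF image stacks, CSV/Parquet tables, YAML sidecars.

Images are written as multi-page TIFF, one file per field per cycle, with
the channel order documented in a sidecar YAML next to the file.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml


def write_image_stack(path, stack: dict[str, np.ndarray], pixel_size_um: float = 0.65) -> None:
    """Multi-page TIFF (one page per channel) + channel-order sidecar YAML."""
    path = Path(path)
    channels = list(stack.keys())
    pages = np.stack([np.asarray(stack[c]) for c in channels])
    tifffile.imwrite(path, pages.astype(np.float32))
    sidecar = path.with_suffix(path.suffix + ".yaml")
    with open(sidecar, "w") as fh:
        yaml.safe_dump({"channels": channels, "pixel_size_um": pixel_size_um,
                        "axis_order": "CYX",
                        "coordinate_convention": "row-col 0-based; shift = cycle2->cycle1"},
                       fh)


def read_image_stack(path) -> tuple[dict[str, np.ndarray], dict]:
    path = Path(path)
    try:
        pages = tifffile.imread(path)
    except Exception as exc:
        raise IOError(f"cannot read TIFF {path}: {exc}") from exc
    sidecar = path.with_suffix(path.suffix + ".yaml")
    if not sidecar.exists():
        raise IOError(f"missing channel sidecar {sidecar}")
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh)
    channels = meta["channels"]
    if pages.ndim == 2:
        pages = pages[None]
    if len(channels) != pages.shape[0]:
        raise IOError(f"{path}: {pages.shape[0]} pages but {len(channels)} channels in sidecar")
    return {c: pages[i] for i, c in enumerate(channels)}, meta


def write_table(df: pd.DataFrame, path) -> None:
    """CSV or Parquet by extension."""
    path = Path(path)
    if path.suffix == ".parquet":
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such table: {path}")
    try:
        if path.suffix == ".parquet":
            return pd.read_parquet(path)
        # empty fields are missing; the literal string "NA" is a valid
        # categorical value (e.g. the BMC^NA activity class)
        return pd.read_csv(path, keep_default_na=False, na_values=[""])
    except Exception as exc:
        raise IOError(f"cannot read table {path}: {exc}") from exc
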