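"""Reading and writing image stacks and result tables.

Stacks are multi-page TIFFs (one page per channel).  Channel roles and
pixel size travel in the TIFF image description as JSON, so stacks
written by this package round-trip without any side information.
Result tables are plain CSV with stable column order and deterministic
row ordering.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from nucleopunct.stack import ChannelStack


def write_stack(stack: ChannelStack, path: str | Path) -> None:
    """Write `stack` as a multi-page TIFF with a JSON description
    carrying the role map and pixel size."""
    meta = {
        "roles": stack.roles,
        "pixel_size_um": stack.pixel_size_um,
        "source_id": stack.source_id,
    }
    tifffile.imwrite(
        str(path),
        np.stack(stack.planes),
        description=json.dumps(meta),
        photometric="minisblack",
    )


def read_stack(
    path: str | Path,
    role_map: dict[str, int] | None = None,
    pixel_size_um: float | None = None,
) -> ChannelStack:
    """Read a multi-page TIFF into a :class:`ChannelStack`.

    Role map and pixel size come from the embedded JSON description when
    present (stacks written by :func:`write_stack`); explicit arguments
    fill in for foreign files, and an explicit `pixel_size_um` always
    wins over the embedded one.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with tifffile.TiffFile(str(path)) as tif:
        planes = [page.asarray() for page in tif.pages]
        desc = tif.pages[0].description
    shapes = {p.shape for p in planes}
    if len(shapes) > 1:
        raise ValueError(f"pages of {path} have mismatched shapes: {shapes}")
    meta: dict = {}
    if desc:
        try:
            parsed = json.loads(desc)
            if isinstance(parsed, dict):
                meta = parsed
        except (json.JSONDecodeError, TypeError):
            pass
    roles = role_map if role_map is not None else meta.get("roles")
    if roles is None:
        raise ValueError(
            f"{path} carries no role metadata; pass role_map explicitly"
        )
    px = pixel_size_um if pixel_size_um is not None \
        else meta.get("pixel_size_um")
    if px is None:
        raise ValueError(
            f"{path} carries no pixel size; pass pixel_size_um explicitly"
        )
    return ChannelStack(
        planes=planes,
        roles={k: int(v) for k, v in roles.items()},
        pixel_size_um=float(px),
        source_id=str(meta.get("source_id", path.stem)),
    )


def write_results(
    records: pd.DataFrame | list[dict],
    path: str | Path,
    sort_by: list[str] | None = None,
) -> None:
    """Write a result table as CSV with deterministic row order.

    `sort_by` names the ordering columns; those present in the table are
    used (default: any of source_id, nucleus_label, punctum_id, group).
    An empty record list yields a header-only file when `records` is a
    DataFrame, or an empty file for an empty list.
    """
    df = records if isinstance(records, pd.DataFrame) \
        else pd.DataFrame(records)
    if sort_by is None:
        sort_by = ["source_id", "nucleus_label", "punctum_id", "group"]
    keys = [c for c in sort_by if c in df.columns]
    if keys and len(df):
        df = df.sort_values(keys, kind="mergesort")
    df.to_csv(path, index=False, lineterminator="\n")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
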