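"""Cerebral parcellation metadata.

The analysis parcellates the cerebrum into 90 cortical and subcortical
regions (45 per hemisphere, AAL scheme, cerebellum excluded) and flags the
subset of regions activated during voluntary saliva swallowing.  Both tables
ship with the package as a plain CSV resource.

Row order is a fixed package convention: structures appear in the canonical
atlas order with the left-hemisphere region immediately before its right
homologue, so region ``2*s`` is structure ``s`` on the left and ``2*s + 1``
is the same structure on the right.  A fixed order makes connectivity
matrices comparable across runs and makes homologous pairs trivial to locate.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "load_region_table",
    "swallowing_nodes",
    "homologous_pairs",
    "region_labels",
    "AtlasError",
]

N_REGIONS = 90
N_PER_HEMISPHERE = 45
N_SWALLOWING = 42

_COLUMNS = ["index", "name", "abbreviation", "hemisphere", "swallowing_roi"]


class AtlasError(RuntimeError):
    """Raised when the packaged atlas resource is missing or malformed."""


def _read_resource() -> pd.DataFrame:
    ref = resources.files("swallownet.data").joinpath("aal90.csv")
    try:
        with resources.as_file(ref) as path:
            table = pd.read_csv(path)
    except (FileNotFoundError, pd.errors.ParserError) as exc:  # pragma: no cover
        raise AtlasError(f"packaged atlas resource unreadable: {exc}") from exc
    return table


def load_region_table() -> pd.DataFrame:
    """Load the validated 90-region table.

    Returns
    -------
    pandas.DataFrame
        Columns ``index`` (0..89), ``name``, ``abbreviation``, ``hemisphere``
        (``"L"``/``"R"``) and ``swallowing_roi`` (bool).  Deterministic: the
        same table on every call.
    """
    table = _read_resource()
    if list(table.columns) != _COLUMNS:
        raise AtlasError(f"atlas columns {list(table.columns)!r} != {_COLUMNS!r}")
    if len(table) != N_REGIONS:
        raise AtlasError(f"atlas has {len(table)} rows, expected {N_REGIONS}")
    if not np.array_equal(table["index"].to_numpy(), np.arange(N_REGIONS)):
        raise AtlasError("atlas region indices must be 0..89 in order")
    counts = table["hemisphere"].value_counts()
    if counts.get("L", 0) != N_PER_HEMISPHERE or counts.get("R", 0) != N_PER_HEMISPHERE:
        raise AtlasError(f"expected {N_PER_HEMISPHERE} regions per hemisphere, got {dict(counts)}")
    for hemi in ("L", "R"):
        abbrs = table.loc[table["hemisphere"] == hemi, "abbreviation"]
        if abbrs.duplicated().any():
            raise AtlasError(f"duplicate abbreviations in hemisphere {hemi}")
    table = table.copy()
    table["swallowing_roi"] = table["swallowing_roi"].astype(bool)
    if int(table["swallowing_roi"].sum()) != N_SWALLOWING:
        raise AtlasError(
            f"expected {N_SWALLOWING} swallowing-ROI flags, got {int(table['swallowing_roi'].sum())}"
        )
    return table


def swallowing_nodes(table: pd.DataFrame | None = None) -> list[int]:
    """Region indices of the swallowing-related ROIs, ascending.

    Bilateral structures contribute both hemispheres; the four unilateral
    entries (postcentral gyrus L, precentral gyrus R, fusiform gyrus L,
    putamen L) contribute one side only.
    """
    if table is None:
        table = load_region_table()
    return table.loc[table["swallowing_roi"], "index"].astype(int).tolist()


def homologous_pairs(table: pd.DataFrame | None = None) -> list[tuple[int, int]]:
    """(left, right) index pairs of the same structure in the two hemispheres."""
    if table is None:
        table = load_region_table()
    out: list[tuple[int, int]] = []
    for _, group in table.groupby("abbreviation", sort=False):
        left = group.loc[group["hemisphere"] == "L", "index"]
        right = group.loc[group["hemisphere"] == "R", "index"]
        out.append((int(left.iloc[0]), int(right.iloc[0])))
    return sorted(out)


def region_labels(table: pd.DataFrame | None = None) -> list[str]:
    """Per-region labels in matrix order, ``ABBR.L`` / ``ABBR.R`` style."""
    if table is None:
        table = load_region_table()
    return [f"{a}.{h}" for a, h in zip(table["abbreviation"], table["hemisphere"])]
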