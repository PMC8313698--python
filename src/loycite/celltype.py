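"""Marker-protein cell typing.

Each of the six targeted leukocyte types carries one defining surface
marker in the antibody panel (CD19 B cells, CD14 and CD16 monocytes, CD56
NK cells, CD8 and CD4 T cells).  A cell is assigned the type of its highest
CLR-normalized typing marker when that marker clearly dominates (top minus
runner-up at least ``margin`` CLR units and top positive); otherwise it is
labeled OTHER.  CD99 is pseudoautosomal and broadly expressed, and is never
a typing marker.

CD14/CD16 is the one biologically double-positive pair (intermediate
monocytes); when those two are the top pair the larger value decides
regardless of the margin.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .normalize import NormalizedMatrix

log = logging.getLogger(__name__)

OTHER = "OTHER"

#: typing marker -> cell type
DEFAULT_MARKER_PANEL = {
    "CD19": "B",
    "CD14": "CD14_MONO",
    "CD16": "CD16_MONO",
    "CD56": "NK",
    "CD8": "CD8_T",
    "CD4": "CD4_T",
}

#: cell type -> its defining autosomal marker
MARKER_FOR_TYPE = {v: k for k, v in DEFAULT_MARKER_PANEL.items()}

CELL_TYPES = tuple(DEFAULT_MARKER_PANEL.values())


def assign_types(
    adt_clr: NormalizedMatrix, panel: dict | None = None, margin: float = 0.5
) -> pd.DataFrame:
    """Assign one label per cell from CLR-normalized ADT values."""
    panel = dict(panel or DEFAULT_MARKER_PANEL)
    if len(set(panel.values())) != len(panel):
        raise ConfigurationError("each typing marker must map to a distinct cell type")
    missing = [m for m in panel if m not in adt_clr.feature_ids]
    if missing:
        raise ConfigurationError(f"typing markers missing from ADT panel: {missing}")
    markers = list(panel)
    M = np.vstack([adt_clr.row(m) for m in markers])  # markers x cells
    order = np.argsort(-M, axis=0)
    top_i, second_i = order[0], order[1]
    ncells = M.shape[1]
    cols = np.arange(ncells)
    top_val = M[top_i, cols]
    second_val = M[second_i, cols]
    third_val = M[order[2], cols] if len(markers) > 2 else np.full(ncells, -np.inf)
    top_marker = np.array(markers, dtype=object)[top_i]
    second_marker = np.array(markers, dtype=object)[second_i]

    confident = ((top_val - second_val) >= margin) & (top_val > 0)
    # CD14/CD16 double-high (intermediate monocytes): both monocyte markers
    # must stand out from the rest of the panel before the larger one decides
    mono_pair = (
        (np.minimum(top_i, second_i) == markers.index("CD14"))
        & (np.maximum(top_i, second_i) == markers.index("CD16"))
        if {"CD14", "CD16"} <= set(markers)
        else np.zeros(ncells, dtype=bool)
    )
    double_high = mono_pair & (top_val > 0) & ((second_val - third_val) >= margin)
    assign = confident | double_high
    labels = np.where(assign, np.array([panel[m] for m in top_marker], dtype=object), OTHER)

    out = pd.DataFrame(
        {
            "barcode": adt_clr.barcodes,
            "assigned_type": labels,
            "top_marker": top_marker,
            "top_marker_clr": top_val,
            "second_marker": second_marker,
            "second_marker_clr": second_val,
        }
    )
    log.info(
        "typed %d cells: %s",
        ncells,
        out["assigned_type"].value_counts().to_dict(),
    )
    return out
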