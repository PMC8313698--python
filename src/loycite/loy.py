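"""LOY calling from MSY transcript evidence.

A cell with expression of autosomal genes but no transcript from any gene in
the male-specific region of chromosome Y (MSY) is classified as a LOY cell.
The rule operates on raw counts — it is a statement about transcript
presence, not abundance — and pseudoautosomal genes (e.g. *CD99*), whose
X-linked copy is retained in LOY cells, are excluded from the MSY evidence.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .annotation import GeneSets
from .errors import ConfigurationError, InputError
from .io import CountMatrix

log = logging.getLogger(__name__)

STATUS_LOY = "LOY"
STATUS_NORMAL = "NORMAL"
STATUS_UNDETERMINED = "UNDETERMINED"


def call_loy(cm: CountMatrix, sets: GeneSets) -> pd.DataFrame:
    """Classify every cell as LOY / NORMAL / UNDETERMINED.

    * LOY: zero MSY counts and positive autosomal counts.
    * NORMAL: any MSY count.
    * UNDETERMINED: zero MSY and zero autosomal counts (no evidence).
    """
    if not np.issubdtype(cm.matrix.dtype, np.integer):
        raise InputError("call_loy requires raw integer counts, not normalized values")
    msy_rows = [i for i, f in enumerate(cm.feature_ids) if f in sets.msy]
    if not msy_rows:
        raise ConfigurationError("no MSY genes present in the feature space")
    auto_rows = [i for i, f in enumerate(cm.feature_ids) if f in sets.autosomal]
    X = cm.matrix.tocsc()
    msy_umi = np.asarray(X[msy_rows].sum(axis=0)).ravel().astype(np.int64)
    auto_umi = np.asarray(X[auto_rows].sum(axis=0)).ravel().astype(np.int64)
    status = np.where(
        msy_umi > 0,
        STATUS_NORMAL,
        np.where(auto_umi > 0, STATUS_LOY, STATUS_UNDETERMINED),
    )
    calls = pd.DataFrame(
        {
            "barcode": cm.barcodes,
            "msy_umi": msy_umi,
            "autosomal_umi": auto_umi,
            "status": status,
        }
    )
    counts = calls["status"].value_counts().to_dict()
    log.info(
        "LOY calls: %d LOY, %d NORMAL, %d UNDETERMINED",
        counts.get(STATUS_LOY, 0),
        counts.get(STATUS_NORMAL, 0),
        counts.get(STATUS_UNDETERMINED, 0),
    )
    return calls


def loy_frequencies(calls: pd.DataFrame, types) -> pd.DataFrame:
    """Per-cell-type LOY percentage with a Wilson 95% confidence interval.

    ``types`` is a per-barcode label series aligned with ``calls``; every
    call must be determined (LOY or NORMAL).
    """
    if (calls["status"] == STATUS_UNDETERMINED).any():
        raise InputError("loy_frequencies requires determined calls only")
    t = pd.Series(np.asarray(types, dtype=object), index=calls.index, name="cell_type")
    df = pd.concat([calls.reset_index(drop=True), t.reset_index(drop=True)], axis=1)
    rows = []
    for cell_type, grp in df.groupby("cell_type", sort=True):
        n = len(grp)
        if n == 0:  # pragma: no cover - groupby never yields empty groups
            log.warning("empty cell-type group %r omitted", cell_type)
            continue
        n_loy = int((grp["status"] == STATUS_LOY).sum())
        lo, hi = proportion_confint(n_loy, n, alpha=0.05, method="wilson")
        rows.append(
            {
                "cell_type": cell_type,
                "n_cells": n,
                "n_loy": n_loy,
                "pct_loy": 100.0 * n_loy / n,
                "ci_lo": 100.0 * lo,
                "ci_hi": 100.0 * hi,
            }
        )
    return pd.DataFrame(rows)
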