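"""Per-cell quality control.

Three criteria, applied to the RNA assay of every droplet:

* droplets expressing more than ``max_genes`` genes are excluded (doublet
  guard; default 2000),
* at least ``min_umi`` total UMI counts are required (dead/low-quality
  guard; default 2500),
* the mitochondrial read percentage must lie inside the closed interval
  [``mito_lo``, ``mito_hi``] (default 1.5-5.0, on the 0-100 scale).

Boundary semantics are literal: 2000 genes is kept, 2001 rejected; 2500 UMI
kept, 2499 rejected; 1.5% and 5.0% mitochondrial content both kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import CountMatrix

log = logging.getLogger(__name__)

#: Order in which failed criteria are reported (first failure wins).
REJECTION_ORDER = ("genes", "umi", "mito")


@dataclass(frozen=True)
class QCThresholds:
    max_genes: int = 2000
    min_umi: int = 2500
    mito_lo: float = 1.5
    mito_hi: float = 5.0

    def __post_init__(self) -> None:
        if self.mito_lo > self.mito_hi:
            raise ConfigurationError(
                f"mito_lo ({self.mito_lo}) exceeds mito_hi ({self.mito_hi})"
            )


def default_mito_symbols(feature_ids) -> set:
    """Mitochondrial genes by the 'MT-' symbol prefix convention."""
    return {f for f in feature_ids if f.startswith("MT-")}


def compute_qc(cm: CountMatrix, mito_symbols=None) -> pd.DataFrame:
    """Per-cell QC metrics: expressed genes, total UMI, mitochondrial %.

    ``pct_mito`` of an all-zero cell is defined as 0 (such a cell fails the
    UMI criterion regardless).
    """
    if mito_symbols is None:
        mito_symbols = default_mito_symbols(cm.feature_ids)
    X = cm.matrix.tocsc()
    n_umi = np.asarray(X.sum(axis=0)).ravel().astype(np.int64)
    n_genes = np.asarray((X > 0).sum(axis=0)).ravel().astype(np.int64)
    mito_rows = [i for i, f in enumerate(cm.feature_ids) if f in mito_symbols]
    if mito_rows:
        mito_umi = np.asarray(X[mito_rows].sum(axis=0)).ravel().astype(np.int64)
    else:
        log.warning("no mitochondrial symbols matched; pct_mito will be 0")
        mito_umi = np.zeros_like(n_umi)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_mito = np.where(n_umi > 0, 100.0 * mito_umi / np.maximum(n_umi, 1), 0.0)
    return pd.DataFrame(
        {
            "barcode": cm.barcodes,
            "n_genes": n_genes,
            "n_umi": n_umi,
            "pct_mito": pct_mito,
        }
    )


def apply_qc(metrics: pd.DataFrame, thresholds: QCThresholds | None = None) -> pd.DataFrame:
    """Evaluate the three criteria; annotate each cell with kept/reason.

    The rejection reason is the first failing criterion in the fixed order
    genes, umi, mito.
    """
    t = thresholds or QCThresholds()
    fail = {
        "genes": metrics["n_genes"].to_numpy() > t.max_genes,
        "umi": metrics["n_umi"].to_numpy() < t.min_umi,
        "mito": (metrics["pct_mito"].to_numpy() < t.mito_lo)
        | (metrics["pct_mito"].to_numpy() > t.mito_hi),
    }
    reason = np.full(len(metrics), "", dtype=object)
    for name in reversed(REJECTION_ORDER):
        reason[fail[name]] = name
    kept = ~(fail["genes"] | fail["umi"] | fail["mito"])
    out = metrics.copy()
    out["kept"] = kept
    out["rejection_reason"] = reason
    log.info("QC kept %d of %d cells", int(kept.sum()), len(kept))
    return out
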