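"""Normalization of the two CITE-seq assays.

RNA counts are log-normalized to a fixed scale factor (default 10,000):
``ln(1 + count * scale_factor / cell_total)``.  Antibody-derived-tag (ADT)
counts are centered log-ratio (CLR) transformed per cell across the protein
panel, the standard compositional treatment for CITE-seq protein data:
``ln(1 + count_i) - mean_j ln(1 + count_j)``.

A per-group 0-1 min-max scaling is provided for display only; it never
feeds the statistics.  Natural logarithms throughout, so a log fold change
x converts to a percent change of 100*(exp(x)-1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigurationError, InputError
from .io import CountMatrix

log = logging.getLogger(__name__)


@dataclass
class NormalizedMatrix:
    """Real-valued features x cells matrix with its normalization method."""

    values: object  # scipy sparse or dense ndarray
    feature_ids: list = field(default_factory=list)
    barcodes: list = field(default_factory=list)
    assay: str = "RNA"
    method: str = "LOG_SF"

    def row(self, feature: str) -> np.ndarray:
        try:
            i = self.feature_ids.index(feature)
        except ValueError as exc:
            raise InputError(f"feature {feature!r} not present") from exc
        r = self.values[i]
        if sp.issparse(self.values):
            return np.asarray(r.todense()).ravel()
        return np.asarray(r).ravel()

    def to_frame(self) -> pd.DataFrame:
        dense = self.values.toarray() if sp.issparse(self.values) else np.asarray(self.values)
        return pd.DataFrame(dense, index=self.feature_ids, columns=self.barcodes)


def log_normalize(cm: CountMatrix, scale_factor: float = 10_000.0) -> NormalizedMatrix:
    """Depth-normalize to ``scale_factor`` counts per cell and take ln(1+x).

    Zero counts map to exactly 0; values are invariant to scaling all of a
    cell's counts by a constant.
    """
    if scale_factor <= 0:
        raise ConfigurationError("scale_factor must be positive")
    X = cm.matrix.tocsc().astype(np.float64)
    totals = np.asarray(X.sum(axis=0)).ravel()
    if np.any(totals <= 0):
        raise InputError("log_normalize requires every cell to have positive total counts")
    per_entry = np.repeat(scale_factor / totals, np.diff(X.indptr))
    X.data = np.log1p(X.data * per_entry)
    return NormalizedMatrix(
        X.tocsr(), list(cm.feature_ids), list(cm.barcodes), cm.assay, "LOG_SF"
    )


def clr_normalize(cm: CountMatrix) -> NormalizedMatrix:
    """Per-cell centered log-ratio across the protein panel.

    Each cell's values sum to zero by construction; a panel of fewer than
    two proteins makes the transform degenerate and is rejected.
    """
    if cm.n_features < 2:
        raise ConfigurationError("CLR requires at least 2 proteins in the panel")
    L = np.log1p(cm.matrix.toarray().astype(np.float64))
    clr = L - L.mean(axis=0, keepdims=True)
    return NormalizedMatrix(clr, list(cm.feature_ids), list(cm.barcodes), cm.assay, "CLR")


def minmax_scale(values, groups) -> pd.Series:
    """Linearly rescale to [0, 1] within each group (display only).

    A constant group maps to all zeros with a warning.
    """
    x = pd.Series(np.asarray(values, dtype=float))
    g = pd.Series(np.asarray(groups, dtype=object), index=x.index)
    out = pd.Series(np.zeros(len(x)), index=x.index)
    for label, idx in x.groupby(g).groups.items():
        sub = x.loc[idx]
        lo, hi = sub.min(), sub.max()
        if hi == lo:
            log.warning("minmax_scale: constant group %r mapped to 0", label)
            out.loc[idx] = 0.0
        else:
            out.loc[idx] = (sub - lo) / (hi - lo)
    return out
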