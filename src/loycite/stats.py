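"""LOY differential-abundance statistics.

Per cell type, two analytes are tested in each assay: *CD99* (the
pseudoautosomal, dosage-sensitive gene/protein of interest) and the type's
own autosomally encoded marker (negative control).  The protein test is a
1-df likelihood-ratio test between logistic models of LOY membership with
and without the CLR analyte; the RNA test is a two-part hurdle combining a
logistic detection component and a Gaussian component on the positive
log-normalized values, as is standard for zero-inflated single-cell
expression.  Both adjust for donor, library-prep batch, sequencing batch,
UMI depth and mitochondrial percentage; all p-values from every cell type
and assay are Benjamini-Hochberg adjusted together as one family.

Effect sizes are average natural-log fold changes; the percent change shown
next to a log fold change x is 100*(exp(x)-1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    DomainWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .celltype import CELL_TYPES, MARKER_FOR_TYPE
from .errors import InputError
from .loy import STATUS_LOY, STATUS_NORMAL
from .normalize import NormalizedMatrix

log = logging.getLogger(__name__)

CATEGORICAL_COVARIATES = ("donor", "library_prep_batch", "sequencing_batch", "cell_type")


@dataclass(frozen=True)
class PooledTestResult:
    """Wald test of the analyte coefficient in the pooled logistic model."""

    analyte: str
    assay: str
    z: float
    p: float
    coefficient: float


def pct_from_logfc(logfc: float) -> float:
    """Convert a natural-log fold change to a percent change."""
    if not np.isfinite(logfc):
        raise InputError("logfc must be finite")
    return 100.0 * (np.exp(logfc) - 1.0)


def avg_logfc(values, is_loy, assay: str) -> float:
    """Average log fold change of an analyte, LOY vs normal cells.

    RNA (LOG_SF values): group means are taken on the de-logged scale and
    re-logged with pseudocount 1, i.e. ``ln(mean(exp(x)-1)+1)`` per group.
    ADT (CLR values): difference of group means on the CLR scale.
    """
    x = np.asarray(values, dtype=float)
    g = np.asarray(is_loy, dtype=bool)
    if not g.any() or g.all():
        raise InputError("avg_logfc requires both a LOY and a normal group")
    a, b = x[g], x[~g]
    if assay == "RNA":
        return float(np.log(np.mean(np.expm1(a)) + 1.0) - np.log(np.mean(np.expm1(b)) + 1.0))
    if assay == "ADT":
        return float(a.mean() - b.mean())
    raise InputError(f"unknown assay {assay!r}")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment over one joint family."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# design matrices and model fits


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def build_design(cov: pd.DataFrame) -> tuple[np.ndarray, list]:
    """Intercept + dummy-coded categoricals + standardized continuous columns.

    Aliased (rank-deficient) columns are dropped deterministically in column
    order with a logged warning, so nested donor/batch designs stay fittable.
    """
    cols = [np.ones(len(cov))]
    names = ["const"]
    for c in cov.columns:
        if c in CATEGORICAL_COVARIATES or cov[c].dtype == object:
            d = pd.get_dummies(cov[c].astype(str), prefix=c, drop_first=True)
            for dc in d.columns:
                cols.append(d[dc].to_numpy(dtype=float))
                names.append(dc)
        else:
            x = cov[c].to_numpy(dtype=float)
            if not np.all(np.isfinite(x)):
                raise InputError(f"non-finite values in covariate {c!r}")
            cols.append(_standardize(x))
            names.append(c)
    X = np.column_stack(cols)
    keep: list[int] = []
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand) == len(keep) + 1:
            keep.append(j)
        else:
            log.warning("dropping aliased design column %r", names[j])
    return X[:, keep], [names[j] for j in keep]


def _fit_logistic(y: np.ndarray, X: np.ndarray):
    """GLM-Binomial fit returning (log-likelihood, params, bse, separated?)."""
    model = sm.GLM(y, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", DomainWarning)
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = model.fit(maxiter=200)
            return float(res.llf), np.asarray(res.params), np.asarray(res.bse), False
        except (PerfectSeparationError, PerfectSeparationWarning, ValueError):
            pass
    # penalized fallback under (quasi-)separation: small ridge, llf at the
    # regularized solution
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit_regularized(alpha=1e-3, L1_wt=0.0)
        params = np.asarray(res.params)
        llf = float(model.loglike(params))
    log.warning("perfect separation detected; penalized logistic fallback used")
    return llf, params, np.full(X.shape[1], np.nan), True


def _logistic_lrt(y: np.ndarray, X_reduced: np.ndarray, extra: np.ndarray):
    """1-df LRT for one added column in a logistic model."""
    X_full = np.column_stack([X_reduced, extra])
    llf_red, _, _, sep_r = _fit_logistic(y, X_reduced)
    llf_full, params, _, sep_f = _fit_logistic(y, X_full)
    stat = max(0.0, 2.0 * (llf_full - llf_red))
    p = float(scipy.stats.chi2.sf(stat, df=1))
    return p, float(params[-1]), (sep_r or sep_f)


def protein_lr_test(values, is_loy, cov: pd.DataFrame):
    """Likelihood-ratio test of a CLR analyte against LOY membership.

    Compares logistic models LOY ~ covariates + analyte vs LOY ~ covariates;
    returns ``(p_raw, direction)`` where direction is the sign of the
    analyte coefficient.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(is_loy, dtype=float)
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise InputError("protein_lr_test requires at least 2 cells per group")
    if x.std() == 0:
        log.warning("constant analyte carries no information; p = 1")
        return 1.0, 0
    X_red, _ = build_design(cov)
    p, coef, separated = _logistic_lrt(y, X_red, _standardize(x))
    if separated:
        log.warning("protein_lr_test: separation fallback in use")
    return p, int(np.sign(coef))


def _gaussian_lrt(y: np.ndarray, X_reduced: np.ndarray, extra: np.ndarray) -> float:
    """LRT statistic n*ln(RSS_reduced/RSS_full) for one added OLS column."""
    X_full = np.column_stack([X_reduced, extra])
    rss_red = float(np.sum(np.square(y - X_reduced @ np.linalg.lstsq(X_reduced, y, rcond=None)[0])))
    rss_full = float(np.sum(np.square(y - X_full @ np.linalg.lstsq(X_full, y, rcond=None)[0])))
    if rss_full <= 0 or rss_red <= 0:
        return 0.0
    return max(0.0, len(y) * np.log(rss_red / rss_full))


def rna_hurdle_test(values, is_loy, cov: pd.DataFrame) -> float:
    """Two-part hurdle test of a log-normalized RNA analyte.

    Part one: logistic model of detection (value > 0) on group + covariates.
    Part two: Gaussian model of the positive values on group + covariates.
    The part LRT statistics add, chi-square with one df per estimable part;
    a part with no variation (or too few cells) contributes zero df.
    """
    x = np.asarray(values, dtype=float)
    g = np.asarray(is_loy, dtype=float)
    if min((g == 1).sum(), (g == 0).sum()) < 2:
        raise InputError("rna_hurdle_test requires at least 2 cells per group")
    stat, df = 0.0, 0

    detected = (x > 0).astype(float)
    if 0 < detected.sum() < len(detected):
        X_red, _ = build_design(cov)
        llf_red = _fit_logistic(detected, X_red)[0]
        llf_full = _fit_logistic(detected, np.column_stack([X_red, g]))[0]
        stat += max(0.0, 2.0 * (llf_full - llf_red))
        df += 1

    pos = x > 0
    if pos.any():
        g_pos = g[pos]
        min_k = len(cov.columns) + 3
        if 0 < g_pos.sum() < len(g_pos) and pos.sum() >= min_k:
            X_red_pos, _ = build_design(cov.loc[pos])
            stat += _gaussian_lrt(x[pos], X_red_pos, g_pos)
            df += 1

    if df == 0:
        log.warning("hurdle test has no estimable part (analyte all zero?); p = 1")
        return 1.0
    return float(scipy.stats.chi2.sf(stat, df=df))


def pooled_overall_test(values, is_loy, cov: pd.DataFrame, analyte: str, assay: str) -> PooledTestResult:
    """Pooled logistic model LOY ~ analyte + confounders (incl. cell type).

    Reports the Wald z and two-sided p of the analyte coefficient, with the
    coefficient on the analyte's natural units (per CLR or log-expression
    unit).
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(is_loy, dtype=float)
    X_red, names = build_design(cov)
    X_full = np.column_stack([X_red, x])
    llf, params, bse, separated = _fit_logistic(y, X_full)
    coef = float(params[-1])
    se = float(bse[-1])
    if separated or not np.isfinite(se) or se == 0:
        log.warning("pooled model unstable; z from penalized fit unavailable")
        z, p = np.nan, np.nan
    else:
        z = coef / se
        p = float(2.0 * scipy.stats.norm.sf(abs(z)))
    return PooledTestResult(analyte=analyte, assay=assay, z=float(z), p=p, coefficient=coef)


# ---------------------------------------------------------------------------
# the full per-type differential table


def run_differential(
    rna_norm: NormalizedMatrix,
    adt_norm: NormalizedMatrix,
    status: pd.Series,
    cell_types: pd.Series,
    covariates: pd.DataFrame,
    min_cells: int = 20,
    cd99: str = "CD99",
) -> pd.DataFrame:
    """Per cell type, test CD99 and the type's own marker in both assays.

    Produces the 12-rows-per-assay layout (6 types x {CD99, own marker}):
    average log fold change, percent change, raw p and BH-adjusted p, with
    the BH family spanning every test in the run.  Types with fewer than
    ``min_cells`` cells in either group get NA p-values.
    """
    barcodes = list(rna_norm.barcodes)
    if list(adt_norm.barcodes) != barcodes:
        raise InputError("RNA and ADT barcodes must be aligned")
    status = status.reindex(barcodes)
    cell_types = cell_types.reindex(barcodes)
    covariates = covariates.reindex(barcodes)
    determined = status.isin([STATUS_LOY, STATUS_NORMAL]).to_numpy()
    is_loy_all = (status == STATUS_LOY).to_numpy()

    cache: dict[tuple, np.ndarray] = {}

    def analyte_values(analyte: str, assay: str) -> np.ndarray:
        key = (analyte, assay)
        if key not in cache:
            mat = rna_norm if assay == "RNA" else adt_norm
            cache[key] = mat.row(analyte)
        return cache[key]

    rows = []
    plan = [(t, cd99) for t in CELL_TYPES] + [(t, MARKER_FOR_TYPE[t]) for t in CELL_TYPES]
    for cell_type, analyte in plan:
        mask = determined & (cell_types == cell_type).to_numpy()
        for assay in ("RNA", "ADT"):
            vals = analyte_values(analyte, assay)[mask]
            loy = is_loy_all[mask]
            n_loy, n_norm = int(loy.sum()), int((~loy).sum())
            lfc = avg_logfc(vals, loy, assay) if n_loy and n_norm else np.nan
            if min(n_loy, n_norm) < min_cells:
                log.warning(
                    "%s/%s/%s: %d LOY vs %d normal below min_cells=%d; p set to NA",
                    cell_type, analyte, assay, n_loy, n_norm, min_cells,
                )
                p_raw = np.nan
            elif assay == "RNA":
                p_raw = rna_hurdle_test(vals, loy, covariates.loc[mask])
            else:
                p_raw, _ = protein_lr_test(vals, loy, covariates.loc[mask])
            rows.append(
                {
                    "cell_type": cell_type,
                    "analyte": analyte,
                    "assay": assay,
                    "avg_logfc": lfc,
                    "pct_change": pct_from_logfc(lfc) if np.isfinite(lfc) else np.nan,
                    "p_raw": p_raw,
                    "p_adj": np.nan,
                    "n_loy": n_loy,
                    "n_normal": n_norm,
                }
            )

    out = pd.DataFrame(rows)
    tested = out["p_raw"].notna()
    if tested.any():
        out.loc[tested, "p_adj"] = bh_adjust(out.loc[tested, "p_raw"].to_numpy())
    return out
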