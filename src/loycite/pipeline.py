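"""End-to-end orchestration: QC -> normalize -> LOY call -> type -> test.

``run_pipeline`` reads 10x-dialect RNA and ADT directories plus a per-cell
sample sheet and writes a tidy results directory:

* ``qc_report.tsv`` — per-cell metrics, kept flag, rejection reason
* ``loy_calls.tsv`` — per-kept-cell MSY/autosomal UMI and LOY status
* ``cell_types.tsv`` — marker-based type assignment
* ``loy_frequencies.tsv`` — per-type LOY % with Wilson 95% CI
* ``differential_results.tsv`` — per type x analyte x assay tests
* ``pooled_overall.tsv`` — pooled logistic CD99 tests (RNA and ADT)
* ``analyte_values.tsv`` — per-cell normalized analyte values (for figures)
* ``manifest.json`` — version, config hash, per-stage cell counts, warnings
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotation import AnnotationTable, default_annotation
from .celltype import CELL_TYPES, MARKER_FOR_TYPE, assign_types
from .errors import InputError, LoyCiteError
from .io import (
    CountMatrix,
    read_10x,
    read_sample_sheet,
    validate_adt_panel,
)
from .loy import STATUS_UNDETERMINED, call_loy, loy_frequencies
from .normalize import clr_normalize, log_normalize, minmax_scale
from .qc import QCThresholds, apply_qc, compute_qc
from .stats import pooled_overall_test, run_differential

log = logging.getLogger(__name__)

RESULT_FILES = (
    "qc_report.tsv",
    "loy_calls.tsv",
    "cell_types.tsv",
    "loy_frequencies.tsv",
    "differential_results.tsv",
    "pooled_overall.tsv",
    "analyte_values.tsv",
    "manifest.json",
)


class _WarningCollector(logging.Handler):
    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.messages: list = []

    def emit(self, record):
        self.messages.append(self.format(record))


def analyze(
    rna: CountMatrix,
    adt: CountMatrix,
    sheet: pd.DataFrame,
    annotation: AnnotationTable | None = None,
    thresholds: QCThresholds | None = None,
    margin: float = 0.5,
    min_cells: int = 20,
    scale_factor: float = 10_000.0,
) -> dict:
    """Run every analysis stage in memory; return a dict of result tables."""
    annotation = annotation or default_annotation()
    thresholds = thresholds or QCThresholds()
    if set(adt.barcodes) != set(rna.barcodes):
        raise InputError("RNA and ADT assays must share barcodes")
    validate_adt_panel(adt)
    adt = adt.subset_cells(rna.barcodes)
    if set(sheet["barcode"]) != set(rna.barcodes):
        raise InputError("sample sheet barcodes do not match the matrices")

    collector = _WarningCollector()
    logging.getLogger("loycite").addHandler(collector)
    try:
        stage = "qc"
        metrics = compute_qc(rna)
        report = apply_qc(metrics, thresholds)
        kept = report.loc[report["kept"], "barcode"].tolist()
        if not kept:
            raise InputError("no cells pass QC")

        stage = "normalize"
        rna_kept = rna.subset_cells(kept)
        adt_kept = adt.subset_cells(kept)
        rna_norm = log_normalize(rna_kept, scale_factor)
        adt_clr = clr_normalize(adt_kept)

        stage = "loy_call"
        sets = annotation.gene_sets(rna.feature_ids)
        calls = call_loy(rna_kept, sets)

        stage = "cell_typing"
        types = assign_types(adt_clr, margin=margin)

        stage = "differential"
        determined = calls["status"] != STATUS_UNDETERMINED
        status = pd.Series(calls["status"].to_numpy(), index=kept)
        type_s = pd.Series(types["assigned_type"].to_numpy(), index=kept)
        cov = (
            sheet.set_index("barcode")
            .loc[kept, ["donor", "library_prep_batch", "sequencing_batch"]]
            .copy()
        )
        cov["n_umi"] = report.set_index("barcode").loc[kept, "n_umi"].to_numpy(dtype=float)
        cov["pct_mito"] = report.set_index("barcode").loc[kept, "pct_mito"].to_numpy()
        differential = run_differential(
            rna_norm, adt_clr, status, type_s, cov, min_cells=min_cells
        )

        stage = "pooled"
        det_mask = determined.to_numpy()
        cov_pooled = cov.loc[det_mask].copy()
        cov_pooled["cell_type"] = type_s[det_mask].to_numpy()
        loy_mask = (status[det_mask] == "LOY").to_numpy()
        pooled_rows = []
        for assay, mat in (("RNA", rna_norm), ("ADT", adt_clr)):
            res = pooled_overall_test(
                mat.row("CD99")[det_mask], loy_mask, cov_pooled, "CD99", assay
            )
            pooled_rows.append(res.__dict__)
        pooled = pd.DataFrame(pooled_rows)

        stage = "frequencies"
        freqs = loy_frequencies(
            calls.loc[det_mask].reset_index(drop=True),
            type_s[det_mask].to_numpy(),
        )

        stage = "analyte_values"
        values = pd.DataFrame({"barcode": kept})
        values["cell_type"] = type_s.to_numpy()
        values["status"] = status.to_numpy()
        values["cd99_rna_lognorm"] = rna_norm.row("CD99")
        for prot in adt_clr.feature_ids:
            values[f"adt_{prot}_clr"] = adt_clr.row(prot)
    except LoyCiteError as exc:
        raise type(exc)(f"stage {stage!r}: {exc}") from exc
    finally:
        logging.getLogger("loycite").removeHandler(collector)

    n_kept = len(kept)
    manifest = {
        "tool": "loycite",
        "version": __version__,
        "stages": {
            "input_cells": rna.n_cells,
            "qc_kept": n_kept,
            "loy_called": int(len(calls)),
            "typed": int(len(types)),
            "determined": int(det_mask.sum()),
        },
        "warnings": collector.messages,
    }
    return {
        "qc_report": report,
        "loy_calls": calls,
        "cell_types": types,
        "loy_frequencies": freqs,
        "differential_results": differential,
        "pooled_overall": pooled,
        "analyte_values": values,
        "manifest": manifest,
    }


def run_pipeline(
    rna_dir,
    adt_dir,
    samples_csv,
    out_dir,
    annotation_path=None,
    thresholds: QCThresholds | None = None,
    margin: float = 0.5,
    min_cells: int = 20,
    scale_factor: float = 10_000.0,
    force: bool = False,
) -> Path:
    """Disk-to-disk pipeline; writes the tidy results directory."""
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise InputError(f"output directory {out_dir} not empty (use force)")
    out_dir.mkdir(parents=True, exist_ok=True)

    from .annotation import load_annotation

    rna = read_10x(rna_dir, assay="RNA")
    adt = read_10x(adt_dir, assay="ADT")
    sheet = read_sample_sheet(samples_csv)
    annotation = load_annotation(annotation_path) if annotation_path else None

    results = analyze(
        rna, adt, sheet,
        annotation=annotation,
        thresholds=thresholds,
        margin=margin,
        min_cells=min_cells,
        scale_factor=scale_factor,
    )

    config = {
        "rna_dir": str(rna_dir),
        "adt_dir": str(adt_dir),
        "samples_csv": str(samples_csv),
        "annotation": str(annotation_path) if annotation_path else "packaged default",
        "thresholds": (thresholds or QCThresholds()).__dict__,
        "margin": margin,
        "min_cells": min_cells,
        "scale_factor": scale_factor,
    }
    manifest = results["manifest"]
    manifest["inputs"] = config
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()
    ).hexdigest()[:16]

    for name in (
        "qc_report", "loy_calls", "cell_types", "loy_frequencies",
        "differential_results", "pooled_overall", "analyte_values",
    ):
        results[name].to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    log.info("results written to %s", out_dir)
    return out_dir


def make_figures(results_dir) -> pd.DataFrame:
    """Summaries behind violin/box displays: scaled quartiles per group.

    Within each (cell type x analyte), values are min-max scaled to [0, 1]
    across both groups jointly (display convention), then summarized per LOY
    status.  Returns the table and writes ``figure_summaries.tsv``.
    """
    results_dir = Path(results_dir)
    path = results_dir / "analyte_values.tsv"
    if not path.exists():
        raise InputError(f"missing {path}; run the pipeline first")
    values = pd.read_csv(path, sep="\t")
    rows = []
    for cell_type in CELL_TYPES:
        sub = values[values["cell_type"] == cell_type]
        analytes = {
            "CD99_RNA": "cd99_rna_lognorm",
            "CD99_ADT": "adt_CD99_clr",
            f"{MARKER_FOR_TYPE[cell_type]}_ADT": f"adt_{MARKER_FOR_TYPE[cell_type]}_clr",
        }
        for label, col in analytes.items():
            if len(sub) >= 2 and sub[col].nunique() > 1:
                scaled = minmax_scale(sub[col].to_numpy(), np.zeros(len(sub)))
                scaled.index = sub.index
            else:
                scaled = pd.Series(np.zeros(len(sub)), index=sub.index)
            for group in ("LOY", "NORMAL"):
                g = scaled[sub["status"] == group]
                if len(g) == 0:
                    log.warning("no %s cells of type %s for %s", group, cell_type, label)
                    rows.append(
                        dict(cell_type=cell_type, analyte=label, group=group, n=0,
                             q1=np.nan, median=np.nan, q3=np.nan,
                             minimum=np.nan, maximum=np.nan)
                    )
                    continue
                rows.append(
                    dict(
                        cell_type=cell_type,
                        analyte=label,
                        group=group,
                        n=int(len(g)),
                        q1=float(g.quantile(0.25)),
                        median=float(g.median()),
                        q3=float(g.quantile(0.75)),
                        minimum=float(g.min()),
                        maximum=float(g.max()),
                    )
                )
    summaries = pd.DataFrame(rows)
    summaries.to_csv(results_dir / "figure_summaries.tsv", sep="\t", index=False)
    return summaries
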