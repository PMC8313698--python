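"""Synthetic CITE-seq generator with known ground truth.

Emulates a pooled four-donor PBMC CITE-seq experiment: six targeted
leukocyte types (plus a marker-negative OTHER population), per-type LOY
fractions, negative-binomial RNA and antibody-tag counts, LOY cells lacking
all MSY transcripts, a CD99 dosage reduction in LOY cells with per-type
effect sizes, donor/batch/depth/mitochondrial confounders, dropout and
doublets.  Every draw flows from one seed, so a config is a complete,
reproducible description of a dataset.

RNA effects are injected as ``exp(logfc)`` multipliers on the CD99 count
mean.  ADT effects are injected through a CD99 mean multiplier solved
numerically (exact negative-binomial pmf) so that the expected per-cell CLR
difference between LOY and normal cells equals the configured log fold
change — the quantity the analysis-side estimator measures.  The CLR is
compositional, so a naive ``exp(logfc)`` count multiplier would be
attenuated by the panel-mean centering (factor (p-1)/p for a p-protein
panel) and by the ln(1+x) pseudocount.
"""

from __future__ import annotations

import configparser
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from .annotation import default_annotation, RegionClass
from .celltype import CELL_TYPES, MARKER_FOR_TYPE, OTHER
from .errors import ConfigurationError
from .io import (
    CountMatrix,
    DEFAULT_ADT_PANEL,
    write_10x,
    write_sample_sheet,
)

log = logging.getLogger(__name__)

X_GENES = ("RPS4X", "DDX3X", "KDM6A", "EIF1AX")
MITO_GENES = (
    "MT-ND1", "MT-ND2", "MT-ND3", "MT-ND4", "MT-ND4L", "MT-ND5", "MT-ND6",
    "MT-CO1", "MT-CO2", "MT-CO3", "MT-ATP6", "MT-ATP8", "MT-CYB",
)

_DEFAULT_TYPE_PROPORTIONS = {
    "B": 0.12,
    "CD14_MONO": 0.20,
    "CD16_MONO": 0.05,
    "NK": 0.10,
    "CD8_T": 0.15,
    "CD4_T": 0.30,
    OTHER: 0.08,
}

# Per-type LOY fractions observed in the four-donor study population.
_DEFAULT_LOY_FRACTIONS = {
    "B": 0.056,
    "CD14_MONO": 0.152,
    "CD16_MONO": 0.150,
    "NK": 0.209,
    "CD8_T": 0.086,
    "CD4_T": 0.024,
    OTHER: 0.10,
}

# CD99 log fold changes in LOY cells, per type (RNA and surface protein).
_DEFAULT_RNA_EFFECTS = {
    "B": -0.32,
    "CD14_MONO": -0.23,
    "CD16_MONO": -0.12,
    "NK": -0.17,
    "CD8_T": -0.05,
    "CD4_T": -0.09,
    OTHER: -0.16,
}
_DEFAULT_ADT_EFFECTS = {
    "B": -0.31,
    "CD14_MONO": -0.07,
    "CD16_MONO": -0.09,
    "NK": -0.05,
    "CD8_T": -0.11,
    "CD4_T": -0.08,
    OTHER: -0.10,
}


@dataclass
class SimulationConfig:
    """Full parameterization of one synthetic CITE-seq experiment."""

    n_cells_per_donor: int = 1250
    donors: int = 4
    seed: int = 0
    type_proportions: dict = field(default_factory=lambda: dict(_DEFAULT_TYPE_PROPORTIONS))
    loy_fraction_per_type: dict = field(default_factory=lambda: dict(_DEFAULT_LOY_FRACTIONS))
    rna_effects: dict = field(default_factory=lambda: dict(_DEFAULT_RNA_EFFECTS))
    adt_effects: dict = field(default_factory=lambda: dict(_DEFAULT_ADT_EFFECTS))
    nb_dispersion: float = 10.0
    adt_dispersion: float = 10.0
    depth_lognormal_params: tuple = (float(np.log(5000.0)), 0.4)
    adt_size_sigma: float = 0.3
    mito_beta_params: tuple = (10.0, 300.0)
    n_background_genes: int = 200
    msy_gene_count: int = 12
    msy_fraction: float = 0.006
    cd99_fraction: float = 0.0003
    x_fraction: float = 0.002
    marker_own_fraction: float = 0.012
    marker_background_fraction: float = 0.0005
    msy_dropout: float = 0.0
    doublet_rate: float = 0.01
    adt_background_level: float = 8.0
    adt_marker_level: float = 150.0
    adt_cd99_level: float = 60.0
    batch_scale_factors: dict = field(default_factory=lambda: {"S1": 0.9, "S2": 1.1})

    def __post_init__(self) -> None:
        total = sum(self.type_proportions.values())
        if abs(total - 1.0) > 1e-8:
            raise ConfigurationError(f"type proportions sum to {total}, expected 1")
        for name, d in (
            ("loy_fraction_per_type", self.loy_fraction_per_type),
            (None, {"msy_dropout": self.msy_dropout, "doublet_rate": self.doublet_rate}),
        ):
            for k, v in d.items():
                if not 0.0 <= v <= 1.0:
                    raise ConfigurationError(f"{name or k}[{k}] = {v} outside [0, 1]")
        if self.nb_dispersion <= 0 or self.adt_dispersion <= 0:
            raise ConfigurationError("dispersions must be positive")
        if self.msy_gene_count < 1 or self.n_cells_per_donor < 1 or self.donors < 1:
            raise ConfigurationError("counts must be positive")

    @property
    def n_cells(self) -> int:
        return self.n_cells_per_donor * self.donors

    # -- flat key-value (INI) round trip, for provenance capture --

    def to_flat(self) -> dict:
        def ser(v):
            return repr(v.item() if isinstance(v, np.generic) else v)

        flat = {}
        for key, val in asdict(self).items():
            if isinstance(val, dict):
                for k, v in val.items():
                    flat[f"{key}.{k}"] = ser(v)
            elif isinstance(val, tuple):
                for i, v in enumerate(val):
                    flat[f"{key}.{i}"] = ser(v)
            else:
                flat[key] = ser(val)
        return flat

    def write_ini(self, path) -> None:
        cp = configparser.ConfigParser()
        cp.optionxform = str  # keys are case-sensitive (type names)
        cp["simulation"] = self.to_flat()
        with open(path, "w") as fh:
            cp.write(fh)

    @classmethod
    def from_ini(cls, path) -> "SimulationConfig":
        cp = configparser.ConfigParser()
        cp.optionxform = str
        if not cp.read(path):
            raise ConfigurationError(f"cannot read config {path}")
        flat = dict(cp["simulation"])
        kwargs: dict = {}
        defaults = cls()
        for key, val in flat.items():
            parsed = eval(val, {"__builtins__": {}})  # values written by to_flat only
            if "." in key:
                base, sub = key.split(".", 1)
                ref = getattr(defaults, base)
                if isinstance(ref, tuple):
                    kwargs.setdefault(base, list(ref))[int(sub)] = parsed
                else:
                    kwargs.setdefault(base, dict(ref))[sub] = parsed
            else:
                kwargs[key] = parsed
        for k, v in list(kwargs.items()):
            if isinstance(getattr(defaults, k), tuple):
                kwargs[k] = tuple(v)
        return cls(**kwargs)


@dataclass
class SimulationResult:
    rna: CountMatrix
    adt: CountMatrix
    sheet: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig


def _gene_panel(config: SimulationConfig) -> dict:
    ann = default_annotation()
    msy = [s for s in ann.symbols if ann.region_of(s) == RegionClass.MSY]
    msy = msy[: config.msy_gene_count]
    if len(msy) < config.msy_gene_count:
        msy += [f"MSY{i:02d}" for i in range(len(msy), config.msy_gene_count)]
    filler = [f"GENE{i + 1:04d}" for i in range(config.n_background_genes)]
    markers = [MARKER_FOR_TYPE[t] for t in CELL_TYPES]
    genes = ["CD99"] + markers + list(msy) + list(X_GENES) + list(MITO_GENES) + filler
    return {"genes": genes, "msy": msy, "markers": markers, "filler": filler}


def _nb_mean_ln1p(mu: float, theta: float) -> float:
    """E[ln(1+X)] for X ~ NB(mean mu, dispersion theta), by pmf summation."""
    if mu <= 0:
        return 0.0
    n, p = theta, theta / (theta + mu)
    hi = int(mu + 12.0 * np.sqrt(mu + mu * mu / theta)) + 1
    k = np.arange(hi + 1)
    pmf = scipy.stats.nbinom.pmf(k, n, p)
    return float(np.sum(pmf * np.log1p(k)))


def _adt_multiplier(
    logfc: float, mu: float, theta: float, panel_size: int, size_sigma: float = 0.0
) -> float:
    """CD99 mean multiplier m so the expected CLR shift equals ``logfc``.

    The CLR difference induced by changing only CD99 is
    (p-1)/p * (E ln(1+X_{m mu s}) - E ln(1+X_{mu s})); solve for m, averaging
    over the lognormal per-cell ADT size factor s by Gauss-Hermite quadrature.
    """
    if logfc == 0.0:
        return 1.0
    target = logfc * panel_size / (panel_size - 1)
    if size_sigma > 0:
        z, w = np.polynomial.hermite_e.hermegauss(9)
        w = w / w.sum()
        sizes = np.exp(size_sigma * z)
    else:
        sizes, w = np.array([1.0]), np.array([1.0])

    def mean_ln1p(m: float) -> float:
        return float(sum(wi * _nb_mean_ln1p(m * mu * s, theta) for s, wi in zip(sizes, w)))

    base = mean_ln1p(1.0)

    def f(m: float) -> float:
        return mean_ln1p(m) - base - target

    return float(scipy.optimize.brentq(f, 1e-3, 20.0, xtol=1e-6))


def _compositions(config: SimulationConfig, panel: dict, rng: np.random.Generator):
    """Per (type, loy) relative expression over the non-mito gene block."""
    genes = panel["genes"]
    nonmito = [g for g in genes if g not in MITO_GENES]
    idx = {g: i for i, g in enumerate(nonmito)}
    filler_w = rng.lognormal(0.0, 1.5, size=len(panel["filler"]))
    filler_w /= filler_w.sum()

    comps = {}
    for cell_type in list(CELL_TYPES) + [OTHER]:
        for loy in (False, True):
            w = np.zeros(len(nonmito))
            w[idx["CD99"]] = config.cd99_fraction
            if loy:
                w[idx["CD99"]] *= np.exp(config.rna_effects[cell_type])
            else:
                for g in panel["msy"]:
                    w[idx[g]] = config.msy_fraction / len(panel["msy"])
            for g in X_GENES:
                w[idx[g]] = config.x_fraction / len(X_GENES)
            for m in panel["markers"]:
                own = cell_type in MARKER_FOR_TYPE and MARKER_FOR_TYPE[cell_type] == m
                w[idx[m]] = config.marker_own_fraction if own else config.marker_background_fraction
            remaining = 1.0 - w.sum()
            for g, fw in zip(panel["filler"], filler_w):
                w[idx[g]] = remaining * fw
            comps[(cell_type, loy)] = w / w.sum()
    return nonmito, comps


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    """Gamma-Poisson (negative binomial) counts; zero mean gives zero counts."""
    lam = rng.gamma(shape=theta, scale=np.maximum(mean, 0.0) / theta)
    return rng.poisson(lam)


def simulate(config: SimulationConfig | None = None) -> SimulationResult:
    """Generate one synthetic CITE-seq dataset from ``config``."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    panel = _gene_panel(config)
    genes = panel["genes"]
    nonmito, comps = _compositions(config, panel, rng)
    nonmito_idx = [genes.index(g) for g in nonmito]
    mito_idx = [genes.index(g) for g in MITO_GENES]
    mito_w = rng.lognormal(0.0, 0.5, size=len(MITO_GENES))
    mito_w /= mito_w.sum()

    n = config.n_cells
    n_doublet = int(round(config.doublet_rate * n))
    n_profiles = n + n_doublet
    types_list = list(config.type_proportions)
    type_p = np.array([config.type_proportions[t] for t in types_list])

    donor_names = [f"D{i + 1}" for i in range(config.donors)]
    donor = np.repeat(np.arange(config.donors), config.n_cells_per_donor)
    hosts = rng.choice(n, size=n_doublet, replace=False)
    donor = np.concatenate([donor, donor[hosts]])

    cell_type = rng.choice(len(types_list), size=n_profiles, p=type_p)
    loy_p = np.array([config.loy_fraction_per_type[t] for t in types_list])
    loy = rng.random(n_profiles) < loy_p[cell_type]

    half = (config.donors + 1) // 2
    lib_batch = np.where(donor < half, "L1", "L2")
    seq_batch = np.where(donor < half, "S1", "S2")
    batch_scale = np.array([config.batch_scale_factors[s] for s in seq_batch])

    meanlog, sdlog = config.depth_lognormal_params
    depth = rng.lognormal(meanlog, sdlog, size=n_profiles) * batch_scale
    a, b = config.mito_beta_params
    mito_frac = rng.beta(a, b, size=n_profiles)

    # RNA expected counts, then gamma-Poisson
    mean = np.zeros((n_profiles, len(genes)))
    comp_mat = np.zeros((n_profiles, len(nonmito)))
    for k, t in enumerate(types_list):
        for is_loy in (False, True):
            sel = (cell_type == k) & (loy == is_loy)
            if sel.any():
                comp_mat[sel] = comps[(t, is_loy)]
    if config.msy_dropout > 0:
        msy_cols = np.array([nonmito.index(g) for g in panel["msy"]])
        drop = rng.random((n_profiles, len(msy_cols))) < config.msy_dropout
        comp_mat[:, msy_cols] = np.where(drop, 0.0, comp_mat[:, msy_cols])
    mean[:, nonmito_idx] = comp_mat * (depth * (1.0 - mito_frac))[:, None]
    mean[:, mito_idx] = mito_w[None, :] * (depth * mito_frac)[:, None]
    rna_counts = _nb_draw(rng, mean, config.nb_dispersion)

    # ADT expected counts
    adt_panel = list(DEFAULT_ADT_PANEL)
    adt_mean = np.full((n_profiles, len(adt_panel)), config.adt_background_level)
    adt_mean[:, adt_panel.index("CD99")] = config.adt_cd99_level
    for k, t in enumerate(types_list):
        if t in MARKER_FOR_TYPE:
            col = adt_panel.index(MARKER_FOR_TYPE[t])
            adt_mean[cell_type == k, col] = config.adt_marker_level
    multipliers = {
        t: _adt_multiplier(
            config.adt_effects[t],
            config.adt_cd99_level,
            config.adt_dispersion,
            len(adt_panel),
            config.adt_size_sigma,
        )
        for t in types_list
    }
    cd99_col = adt_panel.index("CD99")
    for k, t in enumerate(types_list):
        sel = (cell_type == k) & loy
        adt_mean[sel, cd99_col] *= multipliers[t]
    adt_size = rng.lognormal(0.0, config.adt_size_sigma, size=n_profiles)
    adt_counts = _nb_draw(rng, adt_mean * adt_size[:, None], config.adt_dispersion)

    # fold doublet partners (the last n_doublet profiles) into their hosts
    if n_doublet:
        partners = np.arange(n, n_profiles)
        rna_counts[hosts] += rna_counts[partners]
        adt_counts[hosts] += adt_counts[partners]
    is_doublet = np.zeros(n, dtype=bool)
    true_loy = loy[:n].copy()
    if n_doublet:
        is_doublet[hosts] = True
        true_loy[hosts] = loy[hosts] & loy[n:]
    rna_counts = rna_counts[:n]
    adt_counts = adt_counts[:n]

    barcodes = [f"BC{i + 1:06d}" for i in range(n)]
    rna = CountMatrix(rna_counts.T, genes, barcodes, assay="RNA")
    adt = CountMatrix(adt_counts.T, adt_panel, barcodes, assay="ADT")
    sheet = pd.DataFrame(
        {
            "barcode": barcodes,
            "donor": [donor_names[d] for d in donor[:n]],
            "library_prep_batch": lib_batch[:n],
            "sequencing_batch": seq_batch[:n],
        }
    )
    truth = pd.DataFrame(
        {
            "barcode": barcodes,
            "true_type": [types_list[k] for k in cell_type[:n]],
            "true_loy": true_loy,
            "is_doublet": is_doublet,
        }
    )
    log.info(
        "simulated %d cells (%d doublets, %.1f%% LOY)",
        n, n_doublet, 100.0 * true_loy.mean(),
    )
    return SimulationResult(rna=rna, adt=adt, sheet=sheet, truth=truth, config=config)


def write_fixture(result: SimulationResult, dir_path) -> Path:
    """Write a simulated dataset as a 10x-dialect fixture directory."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    write_10x(result.rna, dir_path / "rna")
    write_10x(result.adt, dir_path / "adt")
    write_sample_sheet(result.sheet, dir_path / "samples.csv")
    result.truth.to_csv(dir_path / "truth.tsv", sep="\t", index=False)
    result.config.write_ini(dir_path / "config.ini")
    return dir_path
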