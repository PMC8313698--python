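"""Gene-region model: MSY, PAR, X non-PAR and autosomal gene sets.

Mosaic loss of chromosome Y (LOY) is called from the absence of transcripts
of genes in the male-specific region of chromosome Y (MSY).  Pseudoautosomal
(PAR) genes such as *CD99* are present on both X and Y, so their expression
is retained (dosage-halved, not absent) in LOY cells and they must never
contribute to the MSY evidence.  This module owns that partition.

The annotation ships as a static TSV derived from a fixed Ensembl release
concept; unknown symbols default to AUTOSOME so arbitrary 10x feature files
still resolve.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import FormatError, InputError

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("symbol", "chromosome", "region_class")


class RegionClass(str, enum.Enum):
    """Genomic region classes relevant to LOY calling."""

    MSY = "MSY"
    PAR = "PAR"
    X_NONPAR = "X_nonPAR"
    AUTOSOME = "AUTOSOME"


@dataclass(frozen=True)
class GeneSets:
    """Disjoint symbol sets partitioning an annotated feature space."""

    msy: frozenset
    par: frozenset
    x_nonpar: frozenset
    autosomal: frozenset

    def __post_init__(self) -> None:
        sets = [self.msy, self.par, self.x_nonpar, self.autosomal]
        total = sum(len(s) for s in sets)
        union = frozenset().union(*sets)
        if total != len(union):
            raise InputError("gene sets are not pairwise disjoint")

    @property
    def all_symbols(self) -> frozenset:
        return self.msy | self.par | self.x_nonpar | self.autosomal


class AnnotationTable:
    """Lookup from gene symbol to :class:`RegionClass`.

    Enforces the structural invariants of the region model: symbols are
    unique, MSY genes sit on chromosome Y only, and PAR genes are flagged
    on both X and Y.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"annotation table missing columns: {missing}")
        if len(df) == 0:
            raise InputError("annotation table is empty")
        df = df.loc[:, list(REQUIRED_COLUMNS)].astype(str)
        dup = df["symbol"][df["symbol"].duplicated()]
        if len(dup):
            raise InputError(f"duplicate symbols in annotation: {sorted(set(dup))}")
        valid = {rc.value for rc in RegionClass}
        bad = sorted(set(df["region_class"]) - valid)
        if bad:
            raise FormatError(f"unknown region_class values: {bad}")
        for _, row in df.iterrows():
            chroms = set(row["chromosome"].replace(",", ";").split(";"))
            rc = row["region_class"]
            if rc == RegionClass.MSY.value and chroms != {"Y"}:
                raise InputError(
                    f"MSY gene {row['symbol']} must be on chromosome Y, got {row['chromosome']}"
                )
            if rc == RegionClass.PAR.value and not {"X", "Y"} <= chroms:
                raise InputError(
                    f"PAR gene {row['symbol']} must be flagged on both X and Y, got {row['chromosome']}"
                )
        self._df = df.reset_index(drop=True)
        self._lookup = dict(zip(df["symbol"], df["region_class"]))

    def __len__(self) -> int:
        return len(self._df)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._lookup

    @property
    def symbols(self) -> list:
        return list(self._df["symbol"])

    def to_frame(self) -> pd.DataFrame:
        return self._df.copy()

    def region_of(self, symbol: str) -> RegionClass:
        """Region class of ``symbol``; unknown symbols default to AUTOSOME."""
        rc = self._lookup.get(symbol)
        if rc is None:
            log.warning("symbol %s not in annotation; defaulting to AUTOSOME", symbol)
            return RegionClass.AUTOSOME
        return RegionClass(rc)

    def gene_sets(self, symbols=None) -> GeneSets:
        """Partition ``symbols`` (default: all annotated) into region sets.

        Symbols absent from the annotation are counted as autosomal; a single
        summary warning reports how many defaulted.
        """
        if symbols is None:
            symbols = self.symbols
        symbols = list(symbols)
        if not symbols:
            raise InputError("no symbols to partition")
        buckets = {rc: set() for rc in RegionClass}
        n_unknown = 0
        for s in symbols:
            rc = self._lookup.get(s)
            if rc is None:
                n_unknown += 1
                buckets[RegionClass.AUTOSOME].add(s)
            else:
                buckets[RegionClass(rc)].add(s)
        if n_unknown:
            log.warning(
                "%d of %d symbols not in annotation; classified as AUTOSOME",
                n_unknown,
                len(symbols),
            )
        return GeneSets(
            msy=frozenset(buckets[RegionClass.MSY]),
            par=frozenset(buckets[RegionClass.PAR]),
            x_nonpar=frozenset(buckets[RegionClass.X_NONPAR]),
            autosomal=frozenset(buckets[RegionClass.AUTOSOME]),
        )


def load_annotation(path) -> AnnotationTable:
    """Read a tab-delimited annotation table (symbol, chromosome, region_class)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"annotation table {path} is empty") from exc
    return AnnotationTable(df)


def default_annotation() -> AnnotationTable:
    """The packaged MSY/PAR/X annotation fixture."""
    ref = resources.files("loycite") / "data" / "gene_annotation.tsv"
    with resources.as_file(ref) as path:
        return load_annotation(path)


def gene_sets(ann: AnnotationTable, symbols=None) -> GeneSets:
    """Functional alias for :meth:`AnnotationTable.gene_sets`."""
    return ann.gene_sets(symbols)
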