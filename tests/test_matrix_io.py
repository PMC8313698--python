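"""10x MatrixMarket dialect round trips and sample pooling."""

import gzip

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from loycite import (
    CountMatrix,
    FormatError,
    InputError,
    merge_samples,
    read_10x,
    write_10x,
)

from conftest import random_count_matrix


@pytest.mark.parametrize("compress", [False, True], ids=["plain", "gzip"])
def test_roundtrip_is_lossless(tmp_path, rng, compress):
    cm = random_count_matrix(rng, n_features=40, n_cells=25)
    write_10x(cm, tmp_path / "s", compress=compress)
    back = read_10x(tmp_path / "s")
    assert back.equals(cm)
    assert back.total() == cm.total()


def test_single_entry_matrix(tmp_path):
    cm = CountMatrix(
        sp.csr_matrix(np.array([[5, 0], [0, 0], [0, 0]])),
        ["g1", "g2", "g3"],
        ["c1", "c2"],
    )
    write_10x(cm, tmp_path)
    assert read_10x(tmp_path).total() == 5


def test_dimension_mismatch_rejected(tmp_path, rng):
    cm = random_count_matrix(rng, n_features=4, n_cells=3)
    write_10x(cm, tmp_path)
    lines = (tmp_path / "features.tsv").read_text().splitlines()
    (tmp_path / "features.tsv").write_text("\n".join(lines[:-1]) + "\n")
    with pytest.raises(FormatError, match="shape"):
        read_10x(tmp_path)


def test_non_integer_entries_rejected(tmp_path):
    (tmp_path / "matrix.mtx").write_text(
        "%%MatrixMarket matrix coordinate real general\n2 2 1\n1 1 2.5\n"
    )
    (tmp_path / "features.tsv").write_text("g1\ng2\n")
    (tmp_path / "barcodes.tsv").write_text("c1\nc2\n")
    with pytest.raises(FormatError, match="non-integer"):
        read_10x(tmp_path)


def test_negative_counts_rejected():
    with pytest.raises(FormatError, match="negative"):
        CountMatrix(sp.csr_matrix(np.array([[-1]])), ["g"], ["c"])


def test_features_file_symbol_column(tmp_path):
    (tmp_path / "matrix.mtx").write_text(
        "%%MatrixMarket matrix coordinate integer general\n2 1 1\n1 1 3\n"
    )
    (tmp_path / "features.tsv").write_text(
        "ENSG01\tCD99\tGene Expression\nENSG02\tCD19\tGene Expression\n"
    )
    (tmp_path / "barcodes.tsv").write_text("c1\n")
    cm = read_10x(tmp_path)
    assert cm.feature_ids == ["CD99", "CD19"]


def _sheet(barcodes, donor, lib, seq):
    return pd.DataFrame(
        {
            "barcode": barcodes,
            "donor": donor,
            "library_prep_batch": lib,
            "sequencing_batch": seq,
        }
    )


def test_merge_pools_and_uniquifies(rng):
    rng2 = np.random.default_rng(5)
    a = random_count_matrix(rng, n_features=10, n_cells=2)
    b = random_count_matrix(rng2, n_features=10, n_cells=2)
    b = CountMatrix(b.matrix, a.feature_ids, a.barcodes, a.assay)  # same barcodes on purpose
    sheets = [
        _sheet(a.barcodes, "D1", "L1", "S1"),
        _sheet(b.barcodes, "D2", "L2", "S2"),
    ]
    pooled, sheet = merge_samples([a, b], sheets)
    assert pooled.n_cells == 4
    assert len(set(pooled.barcodes)) == 4
    # pooling conserves total counts
    assert pooled.total() == a.total() + b.total()
    assert set(sheet["sequencing_batch"]) == {"S1", "S2"}
    assert set(sheet["library_prep_batch"]) == {"L1", "L2"}


def test_merge_rejects_panel_mismatch(rng):
    a = random_count_matrix(rng, n_features=5, n_cells=2)
    b = random_count_matrix(rng, n_features=6, n_cells=2)
    with pytest.raises(InputError, match="panel"):
        merge_samples([a, b], [_sheet(a.barcodes, "D1", "L1", "S1"),
                               _sheet(b.barcodes, "D2", "L1", "S1")])


def test_subset_cells_order_and_errors(rng):
    cm = random_count_matrix(rng, n_features=6, n_cells=5)
    sub = cm.subset_cells([cm.barcodes[3], cm.barcodes[0]])
    assert sub.barcodes == [cm.barcodes[3], cm.barcodes[0]]
    assert np.array_equal(
        sub.matrix[:, 0].toarray(), cm.matrix[:, 3].toarray()
    )
    with pytest.raises(InputError):
        cm.subset_cells(["NOPE"])
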