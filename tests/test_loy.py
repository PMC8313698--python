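"""LOY calling from MSY transcript absence and frequency tabulation."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from loycite import (
    ConfigurationError,
    CountMatrix,
    GeneSets,
    InputError,
    SimulationConfig,
    call_loy,
    loy_frequencies,
    simulate,
)


SETS = GeneSets(
    msy=frozenset({"RPS4Y1", "DDX3Y"}),
    par=frozenset({"CD99"}),
    x_nonpar=frozenset(),
    autosomal=frozenset({"ACTB", "B2M"}),
)


def _cm(rows, features, barcodes):
    return CountMatrix(sp.csr_matrix(np.asarray(rows)), features, barcodes)


def test_rule_on_constructed_cells():
    features = ["RPS4Y1", "DDX3Y", "CD99", "ACTB", "B2M"]
    cm = _cm(
        # cells: LOY, NORMAL (one MSY transcript), UNDETERMINED
        [[0, 1, 0], [0, 0, 0], [8, 5, 0], [2000, 900, 0], [1000, 100, 0]],
        features,
        ["loy", "norm", "und"],
    )
    calls = call_loy(cm, SETS).set_index("barcode")
    assert calls.loc["loy", "status"] == "LOY"
    assert calls.loc["norm", "status"] == "NORMAL"
    assert calls.loc["und", "status"] == "UNDETERMINED"
    # PAR counts (CD99) contribute to neither MSY nor autosomal evidence
    assert calls.loc["loy", "msy_umi"] == 0
    assert calls.loc["loy", "autosomal_umi"] == 3000


def test_empty_msy_set_is_configuration_error():
    cm = _cm([[1]], ["ACTB"], ["c"])
    with pytest.raises(ConfigurationError):
        call_loy(cm, GeneSets(frozenset(), frozenset(), frozenset(), frozenset({"ACTB"})))


def test_calls_match_dense_oracle(rng):
    features = ["RPS4Y1", "DDX3Y", "CD99", "ACTB", "B2M"]
    counts = rng.integers(0, 3, size=(5, 1000))
    cm = _cm(counts, features, [f"c{i}" for i in range(1000)])
    calls = call_loy(cm, SETS)
    msy = counts[:2].sum(axis=0)
    auto = counts[3:].sum(axis=0)
    expected = np.where(msy > 0, "NORMAL", np.where(auto > 0, "LOY", "UNDETERMINED"))
    assert np.array_equal(calls["status"].to_numpy(), expected)
    assert np.array_equal(calls["msy_umi"].to_numpy(), msy)
    assert np.array_equal(calls["autosomal_umi"].to_numpy(), auto)


def _calls(statuses):
    return pd.DataFrame(
        {
            "barcode": [f"c{i}" for i in range(len(statuses))],
            "msy_umi": [0 if s == "LOY" else 1 for s in statuses],
            "autosomal_umi": 10,
            "status": statuses,
        }
    )


def test_frequencies_reconstruct_reported_percentage():
    statuses = ["LOY"] * 56 + ["NORMAL"] * 944
    freqs = loy_frequencies(_calls(statuses), ["B"] * 1000)
    row = freqs.set_index("cell_type").loc["B"]
    assert row["pct_loy"] == pytest.approx(5.6)
    assert row["ci_lo"] < 5.6 < row["ci_hi"]


def test_frequencies_zero_loy_group():
    freqs = loy_frequencies(_calls(["NORMAL"] * 20), ["NK"] * 20)
    row = freqs.iloc[0]
    assert row["pct_loy"] == 0.0
    assert row["ci_lo"] == 0.0


def test_frequencies_counting_oracle_is_shuffle_invariant(rng):
    statuses = ["LOY"] * 30 + ["NORMAL"] * 170
    types = (["B"] * 100) + (["NK"] * 100)
    calls = _calls(statuses)
    base = loy_frequencies(calls, types)
    perm = rng.permutation(200)
    shuffled = loy_frequencies(
        calls.iloc[perm].reset_index(drop=True), list(np.array(types)[perm])
    )
    pd.testing.assert_frame_equal(base, shuffled)


def test_frequencies_reject_undetermined():
    with pytest.raises(InputError):
        loy_frequencies(_calls(["UNDETERMINED"]), ["B"])


def test_false_loy_rate_monotone_in_dropout_and_depth():
    """False-LOY calls rise with MSY dropout and fall with sequencing depth."""
    from loycite import default_annotation

    rates = np.zeros((3, 3))
    dropouts = [0.0, 0.5, 0.8]
    depths = [2500.0, 5000.0, 10000.0]
    for i, dropout in enumerate(dropouts):
        for j, depth in enumerate(depths):
            cfg = SimulationConfig(
                seed=42,
                n_cells_per_donor=400,
                msy_dropout=dropout,
                depth_lognormal_params=(float(np.log(depth)), 0.3),
                doublet_rate=0.0,
            )
            sim = simulate(cfg)
            sets = default_annotation().gene_sets(sim.rna.feature_ids)
            calls = call_loy(sim.rna, sets)
            normal = ~sim.truth["true_loy"].to_numpy()
            rates[i, j] = (calls["status"].to_numpy()[normal] == "LOY").mean()
    eps = 0.01
    for j in range(3):  # increasing in dropout at every depth
        assert rates[0, j] <= rates[1, j] + eps <= rates[2, j] + 2 * eps
    for i in range(3):  # decreasing in depth at every dropout level
        assert rates[i, 0] + eps >= rates[i, 1] >= rates[i, 2] - eps
    assert rates[2, 0] > rates[0, 0]  # strong dropout must actually hurt
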