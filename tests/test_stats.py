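"""Effect estimators, hurdle/logistic tests, and BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from loycite import (
    InputError,
    avg_logfc,
    bh_adjust,
    pct_from_logfc,
    pooled_overall_test,
    protein_lr_test,
    rna_hurdle_test,
)


def _cov(n, rng=None, donors=2):
    rng = rng or np.random.default_rng(0)
    return pd.DataFrame(
        {
            "donor": rng.choice([f"D{i}" for i in range(donors)], n),
            "library_prep_batch": rng.choice(["L1", "L2"], n),
            "sequencing_batch": rng.choice(["S1", "S2"], n),
            "n_umi": rng.normal(5000, 800, n),
            "pct_mito": rng.uniform(1.5, 5.0, n),
        }
    )


# --- avg_logfc and the percent transform -----------------------------------


def test_avg_logfc_symmetry_and_antisymmetry(rng):
    x = rng.normal(size=40)
    g = np.arange(40) < 20
    same = np.concatenate([x[:20], x[:20]])
    assert avg_logfc(same, g, "ADT") == pytest.approx(0.0)
    assert avg_logfc(x, g, "ADT") == pytest.approx(-avg_logfc(x, ~g, "ADT"))
    assert avg_logfc(x**2, g, "RNA") == pytest.approx(-avg_logfc(x**2, ~g, "RNA"))


def test_avg_logfc_rna_delogged_group_means():
    # de-logged LOY values (exp(x)-1): 1 and 3 -> mean 2 -> re-log ln(3);
    # normal: 7 -> ln(8); logfc = ln(3) - ln(8)
    x = np.log1p(np.array([1.0, 3.0, 7.0]))
    g = np.array([True, True, False])
    assert avg_logfc(x, g, "RNA") == pytest.approx(np.log(3) - np.log(8), abs=1e-12)


def test_avg_logfc_requires_both_groups():
    with pytest.raises(InputError):
        avg_logfc([1.0, 2.0], [True, True], "ADT")


def test_pct_from_logfc_reference_points():
    assert pct_from_logfc(0.0) == 0.0
    assert pct_from_logfc(np.log(2)) == pytest.approx(100.0)
    assert pct_from_logfc(-0.31) == pytest.approx(-26.66, abs=0.01)


# --- Benjamini-Hochberg ------------------------------------------------------


def brute_force_bh(p):
    """Textbook step-up: sort, scale by m/i, right-to-left cummin, cap at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def test_bh_hand_computed_example():
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])
    assert np.allclose(bh_adjust([0.3]), [0.3])


def test_bh_rejects_out_of_range():
    with pytest.raises(InputError):
        bh_adjust([0.1, 1.2])


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=50))
def test_bh_matches_brute_force(p):
    adjusted = bh_adjust(p)
    assert np.allclose(adjusted, brute_force_bh(p), atol=1e-12)
    assert np.all(adjusted >= np.asarray(p) - 1e-12)  # p_adj >= p_raw


# --- protein LR test ---------------------------------------------------------


def test_protein_lr_detects_shift_and_direction(rng):
    n = 600
    g = rng.random(n) < 0.25
    x = rng.normal(0, 0.4, n) - 0.4 * g
    p, direction = protein_lr_test(x, g, _cov(n, rng))
    assert p < 1e-4
    assert direction == -1


def test_protein_lr_null_is_not_significant(rng):
    n = 600
    g = rng.random(n) < 0.25
    x = rng.normal(0, 0.4, n)
    p, _ = protein_lr_test(x, g, _cov(n, rng))
    assert p > 0.01


def test_protein_lr_constant_analyte(caplog):
    g = np.arange(40) < 10
    with caplog.at_level("WARNING"):
        p, direction = protein_lr_test(np.ones(40), g, _cov(40))
    assert p == 1.0 and direction == 0


def test_protein_lr_requires_two_per_group():
    with pytest.raises(InputError):
        protein_lr_test(np.arange(5.0), np.array([True, False, False, False, False]), _cov(5))


# --- RNA hurdle test ---------------------------------------------------------


def test_hurdle_all_zero_analyte_gives_p_one(caplog):
    n = 100
    g = np.arange(n) < 30
    with caplog.at_level("WARNING"):
        assert rna_hurdle_test(np.zeros(n), g, _cov(n)) == 1.0


def test_hurdle_without_zeros_reduces_to_continuous_part(rng):
    n = 400
    g = rng.random(n) < 0.3
    x = np.abs(rng.normal(2.0, 0.5, n)) + 0.1 - 0.4 * g
    cov = _cov(n, rng)
    p = rna_hurdle_test(x, g, cov)
    assert p < 1e-6  # detection part contributes 0 df; continuous part drives it


def test_hurdle_detects_detection_only_effect(rng):
    """An effect on detection rate alone is caught by the combined test."""
    n = 1500
    g = rng.random(n) < 0.5
    detected = rng.random(n) < np.where(g, 0.35, 0.55)
    x = np.where(detected, np.abs(rng.normal(2.0, 0.5, n)) + 0.1, 0.0)
    cov = _cov(n, rng)
    p_combined = rna_hurdle_test(x, g, cov)
    assert p_combined < 1e-4
    # the positive values alone carry no group signal
    pos = x > 0
    p_cont_only = rna_hurdle_test(x[pos], g[pos], cov.loc[pos])
    assert p_cont_only > 0.01


def test_hurdle_null_is_calibrated_spotcheck(rng):
    n = 800
    g = rng.random(n) < 0.3
    detected = rng.random(n) < 0.7
    x = np.where(detected, np.abs(rng.normal(2.0, 0.5, n)) + 0.1, 0.0)
    assert rna_hurdle_test(x, g, _cov(n, rng)) > 0.01


# --- pooled overall model ----------------------------------------------------


def _pooled_cov(n, rng):
    cov = _cov(n, rng, donors=4)
    cov["cell_type"] = rng.choice(["B", "NK", "CD4_T"], n)
    return cov


def test_pooled_sign_recovery(rng):
    n = 2000
    g = rng.random(n) < 0.1
    x = rng.normal(0, 0.4, n) - 0.3 * g
    res = pooled_overall_test(x, g, _pooled_cov(n, rng), "CD99", "ADT")
    assert res.z < -3
    assert np.sign(res.z) == np.sign(res.coefficient)
    assert res.p < 1e-3


def test_pooled_perfect_confounding_not_attributed_to_analyte(rng):
    n = 1000
    cov = _pooled_cov(n, rng)
    donor_ind = (cov["donor"] == "D1").to_numpy(dtype=float)
    g = rng.random(n) < (0.05 + 0.15 * donor_ind)  # LOY enriched in donor 1
    analyte = donor_ind + 0.01 * rng.normal(size=n)  # measures donor, not LOY
    res = pooled_overall_test(analyte, g, cov, "fake", "ADT")
    assert abs(res.z) < 2.5  # the donor dummy absorbs the association
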