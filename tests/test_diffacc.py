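"""Normalization, dispersion estimation, the NB Wald test, FDR, direction calls."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from chromdyn import (
    CountMatrix,
    EffectSpec,
    bh_adjust,
    call_directions,
    estimate_dispersion,
    generate_gene_models,
    generate_peaks_and_counts,
    make_design,
    nb_wald_test,
    run_all_contrasts,
    size_factors,
)
from chromdyn.simulate import default_chrom_lengths


def _two_group_cm(y_sed, y_cond):
    y_sed, y_cond = np.atleast_2d(y_sed), np.atleast_2d(y_cond)
    n0, n1 = y_sed.shape[1], y_cond.shape[1]
    cols = [f"s{i}" for i in range(n0)] + [f"c{i}" for i in range(n1)]
    counts = pd.DataFrame(
        np.hstack([y_sed, y_cond]),
        index=[f"p{i}" for i in range(y_sed.shape[0])],
        columns=cols,
    )
    design = pd.DataFrame(
        {
            "state": ["sedentary"] * n0 + ["untrained"] * n1,
            "time": ["NA"] * n0 + ["0h"] * n1,
        },
        index=cols,
    )
    return CountMatrix(counts, design)


# --- size factors ----------------------------------------------------------

def test_size_factors_identity_and_doubling():
    counts = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5]})
    assert np.allclose(size_factors(counts), 1.0)
    doubled = pd.DataFrame({"a": [10, 20, 5], "b": [20, 40, 10]})
    sf = size_factors(doubled)
    assert sf["a"] == pytest.approx(2 ** -0.5)
    assert sf["b"] == pytest.approx(2 ** 0.5)


def test_size_factor_homogeneity():
    """Scaling one sample's counts by c scales its factor by c relative to
    the others (the geometric-mean reference rescales by c**(1/n))."""
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(rng.poisson(50, (200, 4)) + 1, columns=list("abcd"))
    sf = size_factors(counts)
    scaled = counts.copy()
    scaled["c"] = scaled["c"] * 3
    sf2 = size_factors(scaled)
    assert (sf2["c"] / sf2["a"]) / (sf["c"] / sf["a"]) == pytest.approx(3.0, rel=1e-9)
    assert sf2["c"] / sf["c"] == pytest.approx(3.0 ** 0.75, rel=1e-9)


def test_size_factors_require_zero_free_peak():
    counts = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
    with pytest.raises(ValueError, match="pseudo-reference"):
        size_factors(counts)


# --- dispersion ------------------------------------------------------------

def test_constant_counts_have_zero_dispersion():
    design = make_design(3)
    counts = pd.DataFrame(
        np.full((20, len(design)), 50), columns=design.index,
        index=[f"p{i}" for i in range(20)],
    )
    cm = CountMatrix(counts, design)
    disp = estimate_dispersion(cm, size_factors(counts))
    assert np.allclose(disp, 0.0)


def test_poisson_counts_give_near_zero_dispersion():
    design = make_design(8)
    rng = np.random.default_rng(1)
    counts = pd.DataFrame(
        rng.poisson(100, (300, len(design))), columns=design.index,
        index=[f"p{i}" for i in range(300)],
    )
    cm = CountMatrix(counts, design)
    disp = estimate_dispersion(cm, size_factors(counts))
    assert disp.median() < 0.01


def test_planted_dispersion_recovered_within_20_percent(design):
    spec = EffectSpec(
        frac_loss_0h_untrained=0.0, frac_gain_6h_untrained=0.0,
        amplification_trained=1.0, reversal_frac=0.0, dispersion=0.1,
    )
    genes = generate_gene_models(100, default_chrom_lengths(100), seed=17)
    _, cm, _ = generate_peaks_and_counts(genes, 2000, design, spec, seed=17)
    disp = estimate_dispersion(cm, size_factors(cm))
    assert disp.median() == pytest.approx(0.1, rel=0.2)


def test_dispersion_needs_replication():
    design = make_design(1)
    counts = pd.DataFrame(
        np.full((5, len(design)), 10), columns=design.index,
        index=[f"p{i}" for i in range(5)],
    )
    cm = CountMatrix(counts, design)
    with pytest.raises(ValueError):
        estimate_dispersion(cm, size_factors(counts))


# --- NB Wald test ----------------------------------------------------------

def test_identical_groups_give_null_result():
    y = np.array([[5, 9, 7, 5, 9, 7], [40, 52, 61, 40, 52, 61]])
    cm = _two_group_cm(y[:, :3], y[:, 3:])
    sf = pd.Series(1.0, index=cm.counts.columns)
    disp = pd.Series(0.1, index=cm.counts.index)
    res = nb_wald_test(cm, sf, disp, ("untrained", "0h"))
    assert np.allclose(res["log2fc"], 0.0, atol=1e-10)
    assert np.allclose(res["p_value"], 1.0, atol=1e-10)


def test_all_zero_peak_flagged():
    cm = _two_group_cm(np.zeros((1, 3), dtype=int), np.zeros((1, 3), dtype=int))
    sf = pd.Series(1.0, index=cm.counts.columns)
    res = nb_wald_test(cm, sf, pd.Series(0.1, index=cm.counts.index), ("untrained", "0h"))
    assert bool(res["all_zero"].iloc[0])
    assert res["log2fc"].iloc[0] == 0.0
    assert res["p_value"].iloc[0] == 1.0


def test_poisson_limit_matches_glm_oracle():
    """With alpha = 0 the fit must agree with a generic Poisson GLM optimizer."""
    rng = np.random.default_rng(3)
    n = 40
    s = np.tile([0.8, 1.1, 1.3, 0.9, 1.0, 1.2], (n, 1))
    mu = rng.lognormal(3, 0.5, n)
    shift = rng.choice([0.5, 1.0, 2.0], n)
    y = rng.poisson(s * mu[:, None] * np.concatenate(
        [np.ones((n, 3)), np.tile(shift, (3, 1)).T], axis=1))
    cm = _two_group_cm(y[:, :3], y[:, 3:])
    sf = pd.Series([0.8, 1.1, 1.3, 0.9, 1.0, 1.2], index=cm.counts.columns)
    res = nb_wald_test(cm, sf, pd.Series(0.0, index=cm.counts.index), ("untrained", "0h"))
    X = sm.add_constant(np.r_[np.zeros(3), np.ones(3)])
    for i in range(n):
        if y[i].sum() == 0 or y[i, :3].sum() == 0 or y[i, 3:].sum() == 0:
            continue
        fit = sm.GLM(y[i], X, family=sm.families.Poisson(), offset=np.log(sf)).fit(tol=1e-12)
        assert res["log2fc"].iloc[i] == pytest.approx(fit.params[1] / np.log(2), abs=1e-6)
        assert res["se"].iloc[i] == pytest.approx(fit.bse[1] / np.log(2), abs=1e-6)


def test_swapping_groups_negates_log2fc():
    rng = np.random.default_rng(4)
    y0, y1 = rng.poisson(30, (10, 3)), rng.poisson(60, (10, 3))
    cm = _two_group_cm(y0, y1)
    cm_swapped = _two_group_cm(y1, y0)
    sf = pd.Series(1.0, index=cm.counts.columns)
    disp = pd.Series(0.05, index=cm.counts.index)
    a = nb_wald_test(cm, sf, disp, ("untrained", "0h"))
    b = nb_wald_test(cm_swapped, sf, disp, ("untrained", "0h"))
    assert np.allclose(a["log2fc"], -b["log2fc"], atol=1e-8)
    assert np.allclose(a["p_value"], b["p_value"], atol=1e-8)


def test_normalization_invariance_of_log2fc():
    """Depth differences absorbed by the size factors leave log2fc unchanged.

    Exact in the Poisson limit when a whole group's counts and factors scale
    together; with NB dispersion the residual effect is negligible.
    """
    rng = np.random.default_rng(5)
    y = rng.poisson(50, (100, 6)) + 1
    cm = _two_group_cm(y[:, :3], y[:, 3:])
    sf = pd.Series(1.0, index=cm.counts.columns)
    zero = pd.Series(0.0, index=cm.counts.index)
    a = nb_wald_test(cm, sf, zero, ("untrained", "0h"))
    scaled = cm.counts.copy()
    scaled.iloc[:, 3:] = scaled.iloc[:, 3:] * 4  # whole condition group deeper
    cm2 = CountMatrix(scaled, cm.design)
    sf2 = sf.copy()
    sf2.iloc[3:] = 4.0
    b = nb_wald_test(cm2, sf2, zero, ("untrained", "0h"))
    assert np.allclose(a["log2fc"], b["log2fc"], atol=1e-9)
    disp = pd.Series(0.05, index=cm.counts.index)
    a_nb = nb_wald_test(cm, sf, disp, ("untrained", "0h"))
    b_nb = nb_wald_test(cm2, sf2, disp, ("untrained", "0h"))
    assert np.allclose(a_nb["log2fc"], b_nb["log2fc"], atol=0.05)


# --- BH and direction calls ------------------------------------------------

def _bh_oracle(p):
    """Step-up procedure written out longhand."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def test_bh_hand_examples():
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=40))
def test_bh_matches_brute_force_stepup(pvals):
    assert np.allclose(bh_adjust(pvals), _bh_oracle(pvals), atol=1e-12)


def test_direction_calls_and_strict_boundary():
    df = pd.DataFrame(
        {"log2fc": [-1.0, 2.0, 1.0, -1.0], "fdr": [0.04, 0.01, 0.05, 0.8],
         "p_value": [0.001, 0.0001, 0.01, 0.5]},
        index=list("abcd"),
    )
    out = call_directions(df, fdr_cutoff=0.05)
    assert list(out["direction"]) == ["loss", "gain", "none", "none"]


def test_loss_only_planting_yields_few_gain_calls(design):
    spec = EffectSpec(frac_loss_0h_untrained=0.15, frac_gain_6h_untrained=0.0,
                      amplification_trained=1.0, reversal_frac=0.0)
    genes = generate_gene_models(100, default_chrom_lengths(100), seed=23)
    _, cm, truth = generate_peaks_and_counts(genes, 1500, design, spec, seed=23)
    res = run_all_contrasts(cm)["untrained_0h"]
    n_gain = int((res["direction"] == "gain").sum())
    planted_losses = truth.planted_set("untrained", "0h", "loss")
    called_losses = set(res.index[res["direction"] == "loss"])
    assert n_gain <= 0.025 * len(res)  # false positives only
    assert len(called_losses & planted_losses) / len(planted_losses) > 0.8
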