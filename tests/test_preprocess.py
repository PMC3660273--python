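"""Background correction, quantile normalization, and median polish."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from ffpetconcord.annotate import RevisedDesign
from ffpetconcord.config import SimulationConfig
from ffpetconcord.containers import IntensityMatrix
from ffpetconcord.preprocess import (
    affinity_plot_data,
    background_correct,
    estimate_background_params,
    expression_index,
    mask_spatial_outliers,
    median_polish,
    quantile_normalize,
    rma_posterior_mean,
    summarize_probe_sets,
)
from ffpetconcord.synthetic import (
    generate_array_design,
    generate_reference,
    simulate_cohort,
)

from .oracles import median_polish_oracle


def _matrix(values, with_geometry=False, mask=None):
    df = pd.DataFrame(
        np.asarray(values, float),
        index=[f"p{i}" for i in range(len(values))],
        columns=[f"s{j}" for j in range(len(values[0]))],
    )
    geometry = None
    if with_geometry:
        n = len(values)
        side = int(np.ceil(np.sqrt(n)))
        geometry = pd.DataFrame(
            {"x": [i % side for i in range(n)], "y": [i // side for i in range(n)]},
            index=df.index,
        )
    return IntensityMatrix(df, geometry, mask)


# ------------------------- spatial masking -------------------------
def test_flat_chip_masks_nothing():
    m = _matrix(np.full((64, 3), 100.0), with_geometry=True)
    out, qc = mask_spatial_outliers(m, zone_grid=2, k_mad=5)
    assert not out.mask.to_numpy().any()
    assert (qc.masked_counts == 0).all()


def test_single_extreme_probe_is_masked():
    vals = np.full((64, 2), 100.0)
    vals[10, 0] = 10_000.0
    m = _matrix(vals, with_geometry=True)
    out, _ = mask_spatial_outliers(m, zone_grid=2, k_mad=5)
    assert out.mask.iloc[10, 0]
    assert out.mask.to_numpy().sum() == 1


def test_zone_medians_recover_planted_gradient():
    rng = np.random.default_rng(0)
    n = 256
    side = 16
    x = np.array([i % side for i in range(n)])
    base = 100.0 * 2.0 ** (0.2 * x)  # intensity rises along x
    vals = (base * np.exp(rng.normal(0, 0.01, n)))[:, None]
    m = _matrix(vals, with_geometry=True)
    _, qc = mask_spatial_outliers(m, zone_grid=4, k_mad=5)
    med = qc.zone_medians.iloc[:, 0]
    by_x = [med[[z for z in med.index if z // 4 == bx]].mean() for bx in range(4)]
    assert all(a < b for a, b in zip(by_x, by_x[1:]))


# ------------------------- background correction -------------------------
@pytest.fixture(scope="module")
def convolved_sample():
    rng = np.random.default_rng(12)
    n = 4000
    signal = rng.exponential(scale=200.0, size=n)
    bg = rng.normal(60.0, 8.0, size=n)
    return signal + bg


def test_posterior_mean_matches_numerical_integration(convolved_sample):
    mu, sigma, alpha = estimate_background_params(convolved_sample)

    def oracle(x):
        def integrand_num(s):
            return s * alpha * np.exp(-alpha * s) * stats.norm.pdf(x - s, mu, sigma)

        def integrand_den(s):
            return alpha * np.exp(-alpha * s) * stats.norm.pdf(x - s, mu, sigma)

        # the posterior mass sits near x - mu; keep the peak inside the
        # integration window so quadrature does not miss it
        hi = x + 10 * sigma
        peak = [p for p in (max(x - mu, 0.0),) if 0 < p < hi]
        num, _ = integrate.quad(integrand_num, 0, hi, limit=400, points=peak)
        den, _ = integrate.quad(integrand_den, 0, hi, limit=400, points=peak)
        return num / den

    for x in [40.0, 80.0, 150.0, 400.0, 1500.0]:
        closed = float(rma_posterior_mean(np.array([x]), mu, sigma, alpha)[0])
        assert closed == pytest.approx(oracle(x), rel=1e-6)


def test_large_values_shift_by_background_mean(convolved_sample):
    mu, sigma, alpha = estimate_background_params(convolved_sample)
    x = np.array([50_000.0])
    corrected = float(rma_posterior_mean(x, mu, sigma, alpha)[0])
    assert corrected == pytest.approx(float(x[0]) - mu, rel=0.01)


def test_background_correct_is_positive_and_columnwise(convolved_sample):
    vals = np.column_stack([convolved_sample, convolved_sample])
    m = _matrix(np.maximum(vals, 1e-6))
    out = background_correct(m)
    assert (out.values.to_numpy() > 0).all()
    # identical input columns give identical corrected columns
    assert np.array_equal(out.values.iloc[:, 0], out.values.iloc[:, 1])


def test_degenerate_sample_falls_back_to_min_shift():
    m = _matrix(np.full((50, 1), 7.0))
    out = background_correct(m)
    assert np.allclose(out.values.to_numpy(), 1.0)


# ------------------------- quantile normalization -------------------------
def test_two_columns_become_mean_of_order_statistics():
    m = _matrix([[1, 4], [2, 5], [3, 6]])
    out = quantile_normalize(m)
    expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
    assert np.allclose(out.values.to_numpy(), expected)


def test_identical_columns_are_unchanged():
    m = _matrix([[5, 5], [1, 1], [9, 9]])
    out = quantile_normalize(m)
    assert np.allclose(out.values.to_numpy(), m.values.to_numpy())


def test_ties_receive_mean_of_their_quantile_slots():
    m = _matrix([[1, 2], [1, 4], [3, 6]])
    out = quantile_normalize(m)
    # reference order statistics: (1.5, 2.5, 4.5); the tied pair shares
    # the mean of the first two slots = 2.0
    assert np.allclose(out.values.iloc[:, 0], [2.0, 2.0, 4.5])
    assert np.allclose(out.values.iloc[:, 1], [1.5, 2.5, 4.5])


def test_columns_share_one_multiset_and_equal_means():
    rng = np.random.default_rng(3)
    m = _matrix(rng.lognormal(5, 1, size=(200, 6)))
    out = quantile_normalize(m)
    v = out.values.to_numpy()
    ref = np.sort(v[:, 0])
    for j in range(1, v.shape[1]):
        assert np.array_equal(np.sort(v[:, j]), ref)
    assert np.ptp(v.mean(axis=0)) < 1e-9


def test_masked_entries_are_excluded_and_rank_filled():
    rng = np.random.default_rng(4)
    vals = rng.lognormal(5, 1, size=(100, 3))
    mask = pd.DataFrame(False, index=[f"p{i}" for i in range(100)],
                        columns=[f"s{j}" for j in range(3)])
    mask.iloc[0, 0] = True
    vals[0, 0] = 1e9  # the masked outlier must not distort the reference
    m = _matrix(vals, mask=mask)
    out = quantile_normalize(m)
    assert out.values.iloc[0, 0] < 1e6
    assert out.mask.iloc[0, 0]  # mask is preserved


# ------------------------- median polish -------------------------
def test_exactly_additive_matrix_is_recovered():
    row = np.array([0.0, 1.0, -1.0, 2.0])
    col = np.array([5.0, 6.0, 7.0])
    x = 10.0 + row[:, None] + col[None, :]
    overall, r, c, resid = median_polish(x)
    assert np.allclose(resid, 0, atol=1e-12)
    fitted = overall + r[:, None] + c[None, :]
    assert np.allclose(fitted, x, atol=1e-12)


def test_single_probe_set_passes_through(cohort):
    m = _matrix([[8.0, 16.0, 32.0]])
    design = RevisedDesign.identity(
        [type("P", (), {"probe_id": "p0", "probe_set_id": "S"})()]
    )
    expr, affin = summarize_probe_sets(m, design)
    assert np.allclose(expr.values.loc["S"], [3.0, 4.0, 5.0])
    assert np.allclose(affin["S"].to_numpy(), 0.0)


def test_median_polish_matches_independent_oracle():
    rng = np.random.default_rng(8)
    for _ in range(20):
        x = rng.normal(8, 1, size=(11, 16)) + rng.normal(0, 0.5, size=(11, 1))
        overall, r, c, resid = median_polish(x)
        o2, r2, c2, resid2 = median_polish_oracle(x)
        assert overall + 0 == pytest.approx(o2, abs=1e-6)
        assert np.allclose(r, r2, atol=1e-6)
        assert np.allclose(c, c2, atol=1e-6)


def test_residual_row_and_column_medians_are_near_zero():
    rng = np.random.default_rng(9)
    x = rng.normal(0, 1, size=(11, 16))
    *_, resid = median_polish(x)
    assert np.abs(np.median(resid, axis=1)).max() < 1e-4
    assert np.abs(np.median(resid, axis=0)).max() < 1e-4


def test_affinities_sum_to_zero(cohort):
    m = cohort["ff"]
    revised = cohort["revised"]
    _, affin = summarize_probe_sets(m, revised)
    assert affin.check_zero_sum(1e-6)


# ------------------------- affinity plot data -------------------------
def test_affinity_plot_table_shapes(cohort):
    revised = cohort["revised"]
    expr, affin, _ = expression_index(cohort["ff"], revised)
    set_id = revised.set_ids("unique")[0]
    n_probes = len(revised.retained[set_id])
    table = affinity_plot_data(affin, expr, set_id)
    assert len(table) == n_probes * expr.values.shape[1]
    assert "group" not in table.columns
    groups = {s: "ER+" for s in expr.values.columns}
    assert "group" in affinity_plot_data(affin, expr, set_id, groups).columns


def test_flawed_probes_sit_at_background_in_affinity_view():
    """Probes with no sequence signal get strongly negative affinities."""
    cfg = SimulationConfig(
        seed=21, n_genes=1, probe_sets_per_gene={1: 1.0},
        frac_nonmatching_probes=4 / 11, frac_crosshyb_probes=0.0,
        n_complete_mismatch_sets=0, include_degradation_control=False,
        kit_profiles={}, baseline_log2_range=(10.0, 10.0),
    )
    ref = generate_reference(cfg)
    design, truth, ref = generate_array_design(ref, cfg)
    ff, _, _ = simulate_cohort(ref, design, truth, cfg)
    full = RevisedDesign.identity(design)
    _, affin = summarize_probe_sets(ff, full)
    set_id = design[0].probe_set_id
    eff = affin[set_id]
    bad = [p for p in eff.index if truth.probe_classes[p] == "nonmatching"]
    good = [p for p in eff.index if truth.probe_classes[p] == "matching-unique"]
    assert eff[bad].max() < eff[good].min()


# ------------------------- end-to-end properties -------------------------
def test_duplicate_input_columns_yield_identical_expression(cohort):
    m = cohort["ff"]
    dup = m.values.copy()
    dup["dup_of_first"] = dup.iloc[:, 0]
    m2 = IntensityMatrix(dup, m.geometry.copy())
    expr, _, _ = expression_index(m2, cohort["revised"])
    assert np.array_equal(
        expr.values.iloc[:, 0].to_numpy(), expr.values["dup_of_first"].to_numpy()
    )


def test_raising_latent_expression_raises_summarized_expression():
    grid = np.linspace(6.0, 12.0, 20)
    out = []
    for b in grid:
        cfg = SimulationConfig(
            seed=31, n_genes=10, probe_sets_per_gene={1: 1.0},
            frac_nonmatching_probes=0.0, frac_crosshyb_probes=0.0,
            n_complete_mismatch_sets=0, include_degradation_control=False,
            kit_profiles={}, n_pairs_per_group=2,
            baseline_overrides={"G0010": float(b)},
        )
        ref = generate_reference(cfg)
        design, truth, ref = generate_array_design(ref, cfg)
        ff, _, _ = simulate_cohort(ref, design, truth, cfg)
        expr, _ = summarize_probe_sets(ff, RevisedDesign.identity(design))
        out.append(expr.values.loc["G0010_ps1"].mean())
    rho = stats.spearmanr(grid, out).statistic
    assert rho > 0.99
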