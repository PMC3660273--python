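"""Limit of blank, present calls, consistency, pair correlation, 3'/5' ratio."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ffpetconcord.annotate import ProbeRecord, TranscriptRecord
from ffpetconcord.config import DegradationProfile, SimulationConfig
from ffpetconcord.containers import ExpressionMatrix, IntensityMatrix
from ffpetconcord.errors import AnalysisError, InputError
from ffpetconcord.qc import (
    estimate_lob,
    pair_correlation,
    present_calls,
    probe_set_consistency,
    three_prime_ratio,
)
from ffpetconcord.synthetic import (
    GroundTruth,
    expected_three_prime_ratio,
    generate_array_design,
    generate_reference,
    simulate_cohort,
)


def _expr(values, index=None):
    arr = np.asarray(values, float)
    return ExpressionMatrix(
        pd.DataFrame(
            arr,
            index=index or [f"ps{i}" for i in range(arr.shape[0])],
            columns=[f"s{j}" for j in range(arr.shape[1])],
        )
    )


# ------------------------- LOB -------------------------
def test_lob_interpolation_convention():
    expr = _expr(np.arange(1, 21).reshape(-1, 1))
    lob = estimate_lob(expr, list(expr.values.index))
    assert float(lob.iloc[0]) == pytest.approx(19.05)


def test_lob_of_constant_blanks_is_that_constant():
    expr = _expr(np.full((30, 2), 4.25))
    lob = estimate_lob(expr, list(expr.values.index))
    assert np.allclose(lob, 4.25)


def test_lob_matches_gaussian_quantile():
    rng = np.random.default_rng(0)
    mu, sigma = 5.0, 0.8
    expr = _expr(rng.normal(mu, sigma, size=(10_000, 1)))
    lob = float(estimate_lob(expr, list(expr.values.index)).iloc[0])
    assert abs(lob - (mu + 1.645 * sigma)) < 0.05 * sigma


def test_lob_requires_blank_sets():
    with pytest.raises(AnalysisError):
        estimate_lob(_expr(np.ones((5, 1))), [])


# ------------------------- present calls -------------------------
def test_all_expression_below_lob_gives_zero_percent():
    blanks = _expr(np.full((30, 2), 10.0), index=[f"b{i}" for i in range(30)])
    signal = pd.DataFrame(np.full((10, 2), 5.0), columns=blanks.values.columns,
                          index=[f"g{i}" for i in range(10)])
    expr = ExpressionMatrix(pd.concat([signal, blanks.values]))
    lob = estimate_lob(expr, list(blanks.values.index))
    percent, pooled = present_calls(expr, lob, list(blanks.values.index))
    assert (percent == 0).all() and pooled == 0.0


def test_zero_degradation_present_calls_equal_ff(cohort):
    from ffpetconcord.qc import estimate_lob, present_calls

    revised = cohort["revised"]
    blanks = revised.complete_mismatch_set_ids
    p = {}
    for label in ("ff", "perfect"):
        e = cohort["expr"][label]
        lob = estimate_lob(e, blanks)
        percent, _ = present_calls(e, lob, blanks)
        p[label] = percent.to_numpy()
    assert np.array_equal(p["ff"], p["perfect"])


def test_half_silenced_genes_give_about_half_present():
    cfg = SimulationConfig(
        seed=41, n_genes=80, probe_sets_per_gene={1: 1.0},
        frac_silenced_genes=0.5, frac_nonmatching_probes=0.0,
        frac_crosshyb_probes=0.0, n_complete_mismatch_sets=40,
        include_degradation_control=False, kit_profiles={},
        baseline_log2_range=(8.0, 11.0),
    )
    ref = generate_reference(cfg)
    design, truth, ref = generate_array_design(ref, cfg)
    ff, _, _ = simulate_cohort(ref, design, truth, cfg)
    from ffpetconcord.annotate import revise_design
    from ffpetconcord.preprocess import expression_index

    revised = revise_design(design, ref)
    expr, _, _ = expression_index(ff, revised)
    lob = estimate_lob(expr, revised.complete_mismatch_set_ids)
    percent, _ = present_calls(expr, lob, revised.complete_mismatch_set_ids)
    # designed: 50% expressed + ~5% of silenced sets above the 95% LOB
    assert 40.0 < percent.mean() < 65.0


def test_percent_present_invariant_to_affine_rescaling():
    rng = np.random.default_rng(2)
    vals = rng.normal(6, 2, size=(120, 4))
    blanks = [f"ps{i}" for i in range(100, 120)]
    expr = _expr(vals)
    lob = estimate_lob(expr, blanks)
    p1, _ = present_calls(expr, lob, blanks)
    expr2 = ExpressionMatrix(expr.values * 3.0 + 2.0)
    p2, _ = present_calls(expr2, estimate_lob(expr2, blanks), blanks)
    assert np.array_equal(p1.to_numpy(), p2.to_numpy())


# ------------------------- consistency -------------------------
def test_identical_probe_sets_are_consistent():
    rng = np.random.default_rng(3)
    v = rng.normal(0, 1, size=16)
    expr = _expr(np.vstack([v, v]), index=["g1_a", "g1_b"])
    pct, detail = probe_set_consistency(expr, {"g1_a": "G1", "g1_b": "G1"})
    assert pct == 0.0
    assert detail.loc[0, "median_pairwise_r"] == pytest.approx(1.0)


def test_single_set_genes_are_excluded():
    rng = np.random.default_rng(4)
    expr = _expr(rng.normal(0, 1, size=(2, 8)), index=["a", "b"])
    pct, detail = probe_set_consistency(expr, {"a": "G1", "b": "G2"})
    assert np.isnan(pct) and detail.empty


def test_null_second_probe_set_is_usually_inconsistent():
    """Independent-noise partner sets flag inconsistency at the null rate."""
    rng = np.random.default_rng(5)
    n_genes, n_samples = 200, 16
    rows, gene_map = [], {}
    for g in range(n_genes):
        rows.append(rng.normal(0, 1, n_samples))
        rows.append(rng.normal(0, 1, n_samples))
        gene_map[f"ps{2 * g}"] = f"G{g}"
        gene_map[f"ps{2 * g + 1}"] = f"G{g}"
    pct, _ = probe_set_consistency(_expr(np.vstack(rows)), gene_map)
    # null P(r <= 0.5) from the exact t transform of Pearson r
    t_crit = 0.5 * np.sqrt(n_samples - 2) / np.sqrt(1 - 0.25)
    p_expected = 100.0 * stats.t.cdf(t_crit, df=n_samples - 2)
    assert abs(pct - p_expected) < 5.0  # ~3 binomial SDs at n=200


def test_zero_variance_pair_is_excluded_with_remaining_pairs_used():
    rng = np.random.default_rng(6)
    v = rng.normal(0, 1, 16)
    expr = _expr(np.vstack([v, v, np.zeros(16)]), index=["a", "b", "c"])
    pct, detail = probe_set_consistency(expr, {k: "G1" for k in "abc"})
    assert pct == 0.0  # median of the defined pair correlations is 1


def test_consistency_invariant_to_probe_set_location_shifts():
    """Pearson correlation ignores per-probe-set location/scale changes."""
    rng = np.random.default_rng(7)
    vals = rng.normal(0, 1, size=(6, 12))
    gene_map = {f"ps{i}": f"G{i // 2}" for i in range(6)}
    p1, d1 = probe_set_consistency(_expr(vals), gene_map)
    shifted = vals * 2.5 + rng.normal(0, 3, size=(6, 1))  # per-set affine map
    p2, d2 = probe_set_consistency(_expr(shifted), gene_map)
    assert p1 == p2
    assert np.allclose(d1["median_pairwise_r"], d2["median_pairwise_r"])


# ------------------------- pair correlation -------------------------
def _sheet_for(expr_ff, expr_fp):
    rows = []
    for c in expr_ff.values.columns:
        rows.append(dict(sample_id=c, preparation="FF", kit="ff",
                         er_status="ER+", pair_id=c.split("_")[0]))
    for c in expr_fp.values.columns:
        rows.append(dict(sample_id=c, preparation="FFPET", kit="k",
                         er_status="ER+", pair_id=c.split("_")[0]))
    return pd.DataFrame(rows)


def test_identical_ffpet_gives_unit_correlation():
    rng = np.random.default_rng(8)
    vals = rng.normal(8, 2, size=(50, 4))
    ff = ExpressionMatrix(pd.DataFrame(vals, columns=[f"P{i}_FF" for i in range(4)]))
    fp = ExpressionMatrix(pd.DataFrame(vals, columns=[f"P{i}_FFPET" for i in range(4)]))
    rs, summary = pair_correlation(ff, fp, _sheet_for(ff, fp))
    assert np.allclose(rs, 1.0) and summary["median"] == pytest.approx(1.0)


def test_pair_correlation_decreases_with_extra_noise():
    medians = []
    for noise in (0.0, 0.5, 1.0, 2.0):
        cfg = SimulationConfig(
            seed=51, n_genes=30, n_complete_mismatch_sets=0,
            include_degradation_control=False,
            kit_profiles={"k": DegradationProfile("k", extra_noise_sd=noise)},
        )
        ref = generate_reference(cfg)
        design, truth, ref = generate_array_design(ref, cfg)
        ff, ffpet, sheet = simulate_cohort(ref, design, truth, cfg)
        from ffpetconcord.annotate import RevisedDesign
        from ffpetconcord.preprocess import summarize_probe_sets

        full = RevisedDesign.identity(design)
        e_ff, _ = summarize_probe_sets(ff, full)
        e_fp, _ = summarize_probe_sets(ffpet["k"], full)
        _, summary = pair_correlation(e_ff, e_fp, sheet)
        medians.append(summary["median"])
    assert all(a > b for a, b in zip(medians, medians[1:]))


def test_constant_expression_column_raises():
    ff = ExpressionMatrix(pd.DataFrame(np.ones((10, 2)), columns=["P0_FF", "P1_FF"]))
    fp = ExpressionMatrix(
        pd.DataFrame(np.random.default_rng(0).normal(size=(10, 2)),
                     columns=["P0_FFPET", "P1_FFPET"])
    )
    with pytest.raises(AnalysisError):
        pair_correlation(ff, fp, _sheet_for(ff, fp))


# ------------------------- 3'/5' ratio -------------------------
def _two_group_setup(decay: float, affinity_sd: float = 0.0):
    """Probes pinned at two 3'-distances, background switched off."""
    cfg = SimulationConfig(
        seed=61, n_genes=1, probe_sets_per_gene={1: 1.0}, probes_per_set=2,
        frac_nonmatching_probes=0.0, frac_crosshyb_probes=0.0,
        n_complete_mismatch_sets=0, include_degradation_control=False,
        background_mean=0.0, background_sd=0.0, probe_affinity_sd=affinity_sd,
        transcript_length_range=(600, 600),
        baseline_log2_range=(10.0, 10.0),
        kit_profiles={"k": DegradationProfile("k", three_prime_decay=decay)},
    )
    ref = generate_reference(cfg)
    transcript = ref[0]
    L = len(transcript.sequence)
    probes, classes, d3s = [], {}, {}
    set_id = "CT_ps1"
    for j, off in enumerate([25, 50, 75, 100, 475, 500, 525, 550]):
        pid = f"{set_id}_p{j:02d}"
        probes.append(
            ProbeRecord(pid, set_id, transcript.sequence[off : off + 25],
                        x=j, y=0, d3prime=L - off - 25, target_gene=transcript.gene_id)
        )
        classes[pid] = "matching-unique"
        d3s[pid] = L - off - 25
    truth = GroundTruth(
        gene_effects={transcript.gene_id: 0.0}, probe_classes=classes, probe_d3=d3s,
        set_gene={set_id: transcript.gene_id},
    )
    ff, ffpet, sheet = simulate_cohort(ref, probes, truth, cfg)
    return cfg, transcript, probes, ff, ffpet["k"]


def test_intact_rna_ratio_is_one():
    _, transcript, probes, ff, _ = _two_group_setup(decay=0.0, affinity_sd=0.3)
    ratio = three_prime_ratio(ff, probes, transcript)
    assert abs(float(ratio.mean()) - 1.0) < 0.1


def test_decay_ratio_matches_closed_form():
    decay = 0.005
    _, transcript, probes, _, fp = _two_group_setup(decay)
    ratio = three_prime_ratio(fp, probes, transcript)
    d3 = np.array([p.d3prime for p in probes])
    delta_d = d3[d3 > 400].mean() - d3[d3 < 200].mean()
    expected = expected_three_prime_ratio(decay, delta_d)
    assert float(ratio.mean()) == pytest.approx(expected, rel=0.05)


def test_ratio_is_monotone_in_decay():
    means = []
    for decay in (0.0, 0.002, 0.004, 0.006, 0.008):
        _, transcript, probes, _, fp = _two_group_setup(decay)
        means.append(float(three_prime_ratio(fp, probes, transcript).mean()))
    assert all(a < b for a, b in zip(means, means[1:]))


def test_ratio_requires_probes_in_both_thirds():
    _, transcript, probes, ff, _ = _two_group_setup(0.0)
    only_three_prime = [p for p in probes if p.d3prime < 200]
    with pytest.raises(InputError):
        three_prime_ratio(ff, only_three_prime, transcript)
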