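import math

import numpy as np
import pandas as pd
import pytest

from methloess import (
    ArraySet,
    HousekeepingSet,
    LoessParams,
    ProbeClass,
    apply_intensity_curve,
    apply_mvalue_curve,
    normalize,
    replicate_correlation,
)
from methloess.normalize import GREEN, RED, MVALUE_II
from methloess.reference import ReferenceScale, ReferenceVector
from methloess.smoothing import BiasCurve, Extrapolation
from methloess.simulate import SimulationConfig, simulate_array_set


def _flat_curve(value, lo=0.0, hi=10.0):
    grid = np.linspace(lo, hi, 16)
    return BiasCurve(grid, np.full(16, value), (lo, hi), 16)


def test_zero_curve_leaves_intensities_untouched():
    S = np.array([1.0, 10.0, 1000.0])
    out, n = apply_intensity_curve(S, _flat_curve(0.0))
    np.testing.assert_allclose(out, S)
    assert n == 0


def test_constant_ln2_curve_halves_intensities():
    S = np.array([2.0, 8.0, 500.0])
    out, _ = apply_intensity_curve(S, _flat_curve(math.log(2)))
    np.testing.assert_allclose(out, S / 2)


def test_out_of_range_discarded_and_counted():
    S = np.array([0.5, 2.0, 1e6])  # ln(0.5) < 0 and ln(1e6) > 10
    out, n = apply_intensity_curve(S, _flat_curve(0.0), Extrapolation.DISCARD)
    assert n == 2
    assert np.isnan(out[0]) and np.isnan(out[2]) and out[1] == 2.0
    out2, n2 = apply_intensity_curve(S, _flat_curve(0.0), Extrapolation.CLAMP_TO_BOUNDARY)
    assert n2 == 0 and np.isfinite(out2).all()


def test_mvalue_curve_subtractive_correction():
    m = np.array([1.0, 5.0])
    out, _ = apply_mvalue_curve(m, _flat_curve(0.25))
    np.testing.assert_allclose(out, m - 0.25)
    out0, _ = apply_mvalue_curve(m, _flat_curve(0.0))
    np.testing.assert_allclose(out0, m)
    out_d, n = apply_mvalue_curve(np.array([-5.0, 1.0]), _flat_curve(0.0))
    assert n == 1 and np.isnan(out_d[0])


def _identical_cohort(n_samples=6, seed=2):
    cfg = SimulationConfig(
        n_probes_p1g=500, n_probes_p1r=500, n_probes_p2=2000,
        n_samples=n_samples, n_replicate_pairs=n_samples // 2,
        housekeeping_fraction=0.15,
        bias_family="none", noise_log_sd=0.0, typeII_bias_amplitude=0.0,
        background_sd=0.0, sample_scale_log_sd=0.0, seed=seed,
    )
    return simulate_array_set(cfg)


def test_identical_cohort_curves_and_values_are_null():
    aset, truth = _identical_cohort()
    hk = HousekeepingSet.from_iterable(truth.housekeeping_ids)
    res = normalize(aset, hk)
    for sample_curves in res.curves.values():
        for curve in sample_curves.values():
            assert curve.max_abs() < 1e-3
    raw = aset.mvalues().values
    both = np.isfinite(res.normalized.values) & np.isfinite(raw)
    assert np.max(np.abs(res.normalized.values[both] - raw[both])) < 1e-3


def test_normalization_is_deterministic():
    aset, truth = _identical_cohort(seed=5)
    hk = HousekeepingSet.from_iterable(truth.housekeeping_ids)
    a = normalize(aset, hk).normalized.values
    b = normalize(aset, hk).normalized.values
    np.testing.assert_array_equal(a, b)


def test_replicate_pair_correlation_improves_after_normalization():
    cfg = SimulationConfig(
        n_probes_p1g=800, n_probes_p1r=800, n_probes_p2=3400,
        n_samples=6, n_replicate_pairs=3, seed=17,
    )
    aset, truth = simulate_array_set(cfg)
    hk = HousekeepingSet.from_iterable(truth.housekeeping_ids)
    res = normalize(aset, hk)
    mask = aset.manifest.filter_mask(True, True)
    raw = replicate_correlation(aset.mvalues(), truth.replicate_pairs, probe_mask=mask)
    post = replicate_correlation(res.normalized, truth.replicate_pairs, probe_mask=mask)
    assert (post.values > raw.values).all()


def test_discard_counts_match_brute_force_range_check():
    cfg = SimulationConfig(
        n_probes_p1g=400, n_probes_p1r=400, n_probes_p2=1600,
        n_samples=4, n_replicate_pairs=2, housekeeping_fraction=0.1, seed=23,
    )
    aset, truth = simulate_array_set(cfg)
    hk_ids = set(truth.housekeeping_ids)
    hk = HousekeepingSet.from_iterable(hk_ids)
    res = normalize(aset, hk)

    manifest = aset.manifest
    is_hk = aset.probe_ids.isin(hk_ids)
    masks = {c: manifest.class_mask(c) for c in ProbeClass}
    expected = np.zeros(aset.n_samples, dtype=int)
    m_prime = np.full_like(aset.M, np.nan)
    u_prime = np.full_like(aset.U, np.nan)
    for z in range(aset.n_samples):
        for probe_class, channel_rows in (
            (ProbeClass.I_GREEN, (masks[ProbeClass.I_GREEN], "both", masks[ProbeClass.II], "M")),
            (ProbeClass.I_RED, (masks[ProbeClass.I_RED], "both", masks[ProbeClass.II], "U")),
        ):
            class_mask, _, t2_mask, t2_channel = channel_rows
            fit_rows = class_mask & is_hk
            pts = np.log(np.concatenate([aset.M[fit_rows, z], aset.U[fit_rows, z]]))
            lo, hi = pts.min(), pts.max()
            for source, rows in (("M", class_mask), ("U", class_mask)):
                ln_s = np.log((aset.M if source == "M" else aset.U)[rows, z])
                out = (ln_s < lo) | (ln_s > hi)
                expected[z] += out.sum()
                target = m_prime if source == "M" else u_prime
                target[rows, z] = np.where(out, np.nan, ln_s)
            ln_t2 = np.log((aset.M if t2_channel == "M" else aset.U)[t2_mask, z])
            out = (ln_t2 < lo) | (ln_t2 > hi)
            expected[z] += out.sum()
            target = m_prime if t2_channel == "M" else u_prime
            target[t2_mask, z] = np.where(out, np.nan, ln_t2)
    # stage-two range check on the pipeline's own corrected m-values
    t2 = masks[ProbeClass.II]
    with np.errstate(invalid="ignore", divide="ignore"):
        m2 = np.log(res.normalized_M[t2]) - np.log(res.normalized_U[t2])
    # mirror the reference rule: housekeeping probes missing in more than half
    # the samples are excluded from the stage-two reference and fit points
    fit2 = is_hk[t2] & (np.isfinite(m2).sum(axis=1) > 0.5 * aset.n_samples)
    for z in range(aset.n_samples):
        pts = m2[fit2, z]
        pts = pts[np.isfinite(pts)]
        lo, hi = pts.min(), pts.max()
        vals = m2[:, z]
        expected[z] += int((((vals < lo) | (vals > hi)) & np.isfinite(vals)).sum())
    np.testing.assert_array_equal(res.n_discarded.values, expected)


def test_clamp_policy_differs_only_at_out_of_range_entries():
    cfg = SimulationConfig(
        n_probes_p1g=400, n_probes_p1r=400, n_probes_p2=1600,
        n_samples=4, n_replicate_pairs=2, housekeeping_fraction=0.1, seed=29,
    )
    aset, truth = simulate_array_set(cfg)
    hk = HousekeepingSet.from_iterable(truth.housekeeping_ids)
    # compare the intensity stage, where the policies act: stage two refits
    # its curve on whichever housekeeping m-values survived, so downstream
    # Type II values legitimately differ between the policies
    discard = normalize(aset, hk, LoessParams(extrapolation=Extrapolation.DISCARD),
                        stage2=False)
    clamp = normalize(aset, hk,
                      LoessParams(extrapolation=Extrapolation.CLAMP_TO_BOUNDARY),
                      stage2=False)
    for d_mat, c_mat in ((discard.normalized_M, clamp.normalized_M),
                         (discard.normalized_U, clamp.normalized_U)):
        dropped = ~np.isfinite(d_mat) & np.isfinite(c_mat)
        same = np.isfinite(d_mat) & np.isfinite(c_mat)
        assert dropped.sum() > 0
        np.testing.assert_allclose(d_mat[same], c_mat[same], rtol=1e-12)
    total_dropped = (~np.isfinite(discard.normalized_M) & np.isfinite(clamp.normalized_M)).sum() \
        + (~np.isfinite(discard.normalized_U) & np.isfinite(clamp.normalized_U)).sum()
    assert total_dropped == discard.n_discarded.sum()
    assert clamp.n_discarded.sum() == 0


def test_disabling_stage_two_keeps_type_one_bit_identical():
    cfg = SimulationConfig(
        n_probes_p1g=400, n_probes_p1r=400, n_probes_p2=1600,
        n_samples=4, n_replicate_pairs=2, housekeeping_fraction=0.1, seed=31,
    )
    aset, truth = simulate_array_set(cfg)
    hk = HousekeepingSet.from_iterable(truth.housekeeping_ids)
    full = normalize(aset, hk)
    stage1 = normalize(aset, hk, stage2=False)
    type_i = ~aset.manifest.class_mask(ProbeClass.II)
    np.testing.assert_array_equal(
        full.normalized.values[type_i], stage1.normalized.values[type_i]
    )
    assert MVALUE_II not in next(iter(stage1.curves.values()))


def test_per_signal_fitting_produces_separate_curves():
    aset, truth = _identical_cohort(seed=37)
    hk = HousekeepingSet.from_iterable(truth.housekeeping_ids)
    res = normalize(aset, hk, pool_signals=False)
    curves = next(iter(res.curves.values()))
    assert {f"{GREEN}_M", f"{GREEN}_U", f"{RED}_M", f"{RED}_U", MVALUE_II} <= set(curves)


def test_frozen_reference_reproduces_cohort_reference():
    from methloess import build_intensity_reference, build_mvalue_reference
    from methloess.core import Measure, MethylationMatrix
    from methloess.core import Signal

    cfg = SimulationConfig(
        n_probes_p1g=400, n_probes_p1r=400, n_probes_p2=1600,
        n_samples=4, n_replicate_pairs=2, housekeeping_fraction=0.1, seed=41,
    )
    aset, truth = simulate_array_set(cfg)
    hk = HousekeepingSet.from_iterable(truth.housekeeping_ids)
    base = normalize(aset, hk)
    refs = {
        GREEN: build_intensity_reference(aset, hk, ProbeClass.I_GREEN),
        RED: build_intensity_reference(aset, hk, ProbeClass.I_RED),
    }
    frozen = normalize(aset, hk, intensity_references=refs)
    np.testing.assert_allclose(
        base.normalized.values, frozen.normalized.values, equal_nan=True
    )


def test_fit_failure_reports_sample_ids():
    cfg = SimulationConfig(
        n_probes_p1g=400, n_probes_p1r=400, n_probes_p2=1600,
        n_samples=4, n_replicate_pairs=2, housekeeping_fraction=0.03, seed=43,
    )
    aset, truth = simulate_array_set(cfg)
    hk = HousekeepingSet.from_iterable(truth.housekeeping_ids)
    with pytest.raises(ValueError, match="S001"):
        normalize(aset, hk)
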