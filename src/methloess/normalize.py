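"""Two-stage local-regression between-array normalization.

Stage one removes each sample's intensity-dependent bias, separately per
colour channel: on the housekeeping probes of a channel, log intensities are
regressed against their deviation from the virtual reference array, and the
fitted curve f is used to correct every intensity of that channel via
``S' = S * exp(-f(ln S))``.  The green-channel curve, learned on the Type I
green probes, also corrects the Type II methylated (Cy3) signals; the red
curve likewise corrects Type II unmethylated (Cy5) signals.  Fitting a
separate curve on Type II intensities is deliberately avoided because their
intensity- and methylation-dependent biases are entangled.

Stage two removes the residual methylation-dependent bias of Type II probes:
m-values computed from the corrected intensities are regressed against their
deviation from an m-value reference, and corrected subtractively,
``m'' = m' - f2(m')``.  Type I probes keep their stage-one m-values.

Measurements whose explanatory value falls outside the span of the sample's
housekeeping points would require extrapolating the curve; by default they
are discarded (set missing) and counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .core import (
    ArraySet,
    Measure,
    MethylationMatrix,
    ProbeClass,
    Signal,
    clamp_intensities,
    m_from_intensities,
)
from .reference import (
    HousekeepingSet,
    ReferenceScale,
    ReferenceVector,
    build_intensity_reference,
    build_mvalue_reference,
)
from .smoothing import BiasCurve, Extrapolation, LoessParams, loess_fit

logger = logging.getLogger(__name__)

GREEN = "green"
RED = "red"
MVALUE_II = "mvalue_II"


def fit_bias_curve(
    x: np.ndarray,
    delta: np.ndarray,
    params: LoessParams = LoessParams(),
    label: str = "",
) -> BiasCurve:
    """Loess fit of deviation-from-reference ``delta`` against explanatory ``x``."""
    return loess_fit(x, delta, params, label=label)


# Backwards-compatible alias: the m-value stage uses the same machinery on a
# different scale.
fit_mvalue_curve = fit_bias_curve


def apply_intensity_curve(
    S: np.ndarray,
    curve: BiasCurve,
    extrapolation: Extrapolation = Extrapolation.DISCARD,
    clamp_floor: Optional[float] = 1.0,
) -> tuple[np.ndarray, int]:
    """Correct intensities: ``S' = S * exp(-f(ln S))``.

    Returns the corrected array and the number of previously-present
    measurements set missing by the DISCARD out-of-range policy.
    """
    S = clamp_intensities(S, clamp_floor)
    with np.errstate(invalid="ignore"):
        ln_s = np.log(S)
    corrected = S * np.exp(-curve.evaluate(ln_s))
    n_discarded = 0
    if extrapolation == Extrapolation.DISCARD:
        out_of_range = ~curve.in_range(ln_s) & np.isfinite(S)
        n_discarded = int(out_of_range.sum())
        corrected = np.where(out_of_range, np.nan, corrected)
    return corrected, n_discarded


def apply_mvalue_curve(
    m: np.ndarray,
    curve: BiasCurve,
    extrapolation: Extrapolation = Extrapolation.DISCARD,
) -> tuple[np.ndarray, int]:
    """Correct m-values subtractively: ``m'' = m' - f2(m')``."""
    m = np.asarray(m, dtype=float)
    corrected = m - curve.evaluate(m)
    n_discarded = 0
    if extrapolation == Extrapolation.DISCARD:
        out_of_range = ~curve.in_range(m) & np.isfinite(m)
        n_discarded = int(out_of_range.sum())
        corrected = np.where(out_of_range, np.nan, corrected)
    return corrected, n_discarded


@dataclass
class NormalizationResult:
    """Output of :func:`normalize`.

    normalized: m-values for all probes after both stages.
    curves: per-sample fitted curves, keyed by stage ("green", "red",
        "mvalue_II"; per-signal keys like "green_M" when signals are not pooled).
    n_discarded: per-sample count of measurements set missing by the
        out-of-range policy (both stages combined).
    normalized_M / normalized_U: stage-one corrected intensity matrices.
    """

    normalized: MethylationMatrix
    curves: Dict[str, Dict[str, BiasCurve]]
    n_discarded: pd.Series
    normalized_M: np.ndarray
    normalized_U: np.ndarray

    def betas(self) -> MethylationMatrix:
        return self.normalized.to_beta()

    def curve_summary(self) -> pd.DataFrame:
        rows = []
        for sample, stage_curves in self.curves.items():
            for stage, curve in stage_curves.items():
                rows.append(
                    {
                        "sample_id": sample,
                        "stage": stage,
                        "n_points": curve.n_points,
                        "x_min": curve.x_range[0],
                        "x_max": curve.x_range[1],
                        "max_abs_f": curve.max_abs(),
                    }
                )
        return pd.DataFrame(rows)


def _reference_frame(ref: ReferenceVector) -> pd.Series:
    return pd.Series(ref.values, index=ref.keys)


def _stage_one_channel(
    aset: ArraySet,
    out_M: np.ndarray,
    out_U: np.ndarray,
    housekeeping: HousekeepingSet,
    channel: str,
    params: LoessParams,
    clamp_floor: Optional[float],
    pool_signals: bool,
    curves: Dict[str, Dict[str, BiasCurve]],
    discarded: np.ndarray,
    reference: Optional[ReferenceVector],
) -> list[str]:
    """Fit per-sample channel curves and correct the channel's intensities in place."""
    probe_class = ProbeClass.I_GREEN if channel == GREEN else ProbeClass.I_RED
    # Type II channel mapping: methylated signal is green (Cy3), unmethylated red (Cy5)
    typeII_matrix = out_M if channel == GREEN else out_U
    if reference is None:
        reference = build_intensity_reference(
            aset, housekeeping, probe_class, Signal.BOTH, clamp_floor
        )
    ref = _reference_frame(reference)

    class_rows = np.flatnonzero(aset.manifest.class_mask(probe_class))
    typeII_rows = np.flatnonzero(aset.manifest.class_mask(ProbeClass.II))
    probe_ids = aset.probe_ids[class_rows]

    ln_m = np.log(clamp_intensities(aset.M[class_rows], clamp_floor))
    ln_u = np.log(clamp_intensities(aset.U[class_rows], clamp_floor))
    frames = {
        Signal.M_SIGNAL.value: pd.DataFrame(ln_m, index=probe_ids),
        Signal.U_SIGNAL.value: pd.DataFrame(ln_u, index=probe_ids),
    }
    # align housekeeping fit points with the (probe, signal) reference keys
    stacked = pd.concat(frames, names=["signal", "probe_id"])
    stacked.index = stacked.index.reorder_levels(["probe_id", "signal"])
    fit_points = stacked.reindex(ref.index)

    errors: list[str] = []
    for z, sample in enumerate(aset.sample_ids):
        x_all = fit_points.iloc[:, z].to_numpy()
        delta_all = x_all - ref.to_numpy()
        sample_curves: Dict[str, BiasCurve] = {}
        try:
            if pool_signals:
                curve = fit_bias_curve(x_all, delta_all, params, label=channel)
                sample_curves[channel] = curve
                per_signal = {Signal.M_SIGNAL.value: curve, Signal.U_SIGNAL.value: curve}
            else:
                per_signal = {}
                for sig in (Signal.M_SIGNAL.value, Signal.U_SIGNAL.value):
                    sel = ref.index.get_level_values("signal") == sig
                    c = fit_bias_curve(x_all[sel], delta_all[sel], params, label=f"{channel}_{sig}")
                    per_signal[sig] = c
                    sample_curves[f"{channel}_{sig}"] = c
        except ValueError as exc:
            errors.append(f"{sample}: {channel} channel fit failed: {exc}")
            continue
        curves.setdefault(sample, {}).update(sample_curves)

        m_curve = per_signal[Signal.M_SIGNAL.value]
        u_curve = per_signal[Signal.U_SIGNAL.value]
        corrected, n1 = apply_intensity_curve(
            aset.M[class_rows, z], m_curve, params.extrapolation, clamp_floor
        )
        out_M[class_rows, z] = corrected
        corrected, n2 = apply_intensity_curve(
            aset.U[class_rows, z], u_curve, params.extrapolation, clamp_floor
        )
        out_U[class_rows, z] = corrected
        # reuse of the Type I channel curve for the matching Type II channel
        typeII_curve = m_curve if channel == GREEN else u_curve
        source = aset.M if channel == GREEN else aset.U
        corrected, n3 = apply_intensity_curve(
            source[typeII_rows, z], typeII_curve, params.extrapolation, clamp_floor
        )
        typeII_matrix[typeII_rows, z] = corrected
        discarded[z] += n1 + n2 + n3
    return errors


def normalize(
    aset: ArraySet,
    housekeeping: HousekeepingSet,
    params: LoessParams = LoessParams(),
    clamp_floor: Optional[float] = 1.0,
    pool_signals: bool = True,
    stage2: bool = True,
    intensity_references: Optional[Dict[str, ReferenceVector]] = None,
    mvalue_reference: Optional[ReferenceVector] = None,
) -> NormalizationResult:
    """Run the full two-stage normalization on a cohort.

    Parameters
    ----------
    aset : cohort of arrays to normalize (all samples share the reference).
    housekeeping : set E of equally-methylated CpG sites.
    params : loess settings, shared by all fits.
    clamp_floor : floor for non-positive intensities before logs.
    pool_signals : fit one curve per channel on pooled M and U housekeeping
        points (default), or one curve per (channel, signal).
    stage2 : apply the Type II m-value correction; disabling it leaves Type I
        outputs untouched bit for bit.
    intensity_references / mvalue_reference : optional frozen references from a
        previous cohort; by default references are built from ``aset`` itself.

    Entirely deterministic: no randomness is involved anywhere.
    """
    intensity_references = intensity_references or {}
    out_M = aset.M.astype(float).copy()
    out_U = aset.U.astype(float).copy()
    curves: Dict[str, Dict[str, BiasCurve]] = {}
    discarded = np.zeros(aset.n_samples, dtype=int)
    errors: list[str] = []

    for channel in (GREEN, RED):
        errors.extend(
            _stage_one_channel(
                aset, out_M, out_U, housekeeping, channel, params, clamp_floor,
                pool_signals, curves, discarded, intensity_references.get(channel),
            )
        )
    if errors:
        raise ValueError("normalization failed for some samples:\n" + "\n".join(errors))

    m_prime = m_from_intensities(out_M, out_U, clamp_floor)

    if stage2:
        typeII_rows = np.flatnonzero(aset.manifest.class_mask(ProbeClass.II))
        mm_typeII = MethylationMatrix(
            m_prime[typeII_rows], Measure.M_VALUE,
            aset.probe_ids[typeII_rows], aset.sample_ids,
        )
        ref2 = mvalue_reference
        if ref2 is None:
            ref2 = build_mvalue_reference(mm_typeII, housekeeping)
        ref2_series = _reference_frame(ref2)
        fit_points = mm_typeII.as_dataframe().reindex(ref2_series.index)
        for z, sample in enumerate(aset.sample_ids):
            x = fit_points.iloc[:, z].to_numpy()
            delta = x - ref2_series.to_numpy()
            try:
                curve = fit_mvalue_curve(x, delta, params, label=MVALUE_II)
            except ValueError as exc:
                errors.append(f"{sample}: m-value stage fit failed: {exc}")
                continue
            curves.setdefault(sample, {})[MVALUE_II] = curve
            corrected, n_disc = apply_mvalue_curve(
                m_prime[typeII_rows, z], curve, params.extrapolation
            )
            m_prime[typeII_rows, z] = corrected
            discarded[z] += n_disc
        if errors:
            raise ValueError(
                "normalization failed for some samples:\n" + "\n".join(errors)
            )

    normalized = MethylationMatrix(
        m_prime, Measure.M_VALUE, aset.probe_ids, aset.sample_ids
    )
    return NormalizationResult(
        normalized=normalized,
        curves=curves,
        n_discarded=pd.Series(discarded, index=list(aset.sample_ids), name="n_discarded"),
        normalized_M=out_M,
        normalized_U=out_U,
    )
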