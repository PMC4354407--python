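"""Quantile-normalization baselines QN1 and QN2.

Quantile normalization forces every sample (column) to share one empirical
distribution: each column's sorted values are replaced by the mean sorted
profile across columns.  Two variants serve as baselines for the loess
method:

* QN1 — QN applied to intensities, separately for each combination of probe
  type and colour channel: the Type I green block (M and U signals pooled),
  the Type I red block (pooled likewise), the Type II methylated signals and
  the Type II unmethylated signals.  m-values are then computed from the
  normalized intensities.
* QN2 — QN applied to raw m-values, separately for Type I green, Type I red
  and Type II probes.

Because QN forces identical distributions, cohorts mixing sexes would distort
sex-chromosome probes; by default only autosomal probes are normalized and
the rest pass through unchanged.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
from scipy.stats import rankdata

from .core import (
    SEX_CHROMOSOMES,
    ArraySet,
    Measure,
    MethylationMatrix,
    ProbeClass,
    m_from_intensities,
)

logger = logging.getLogger(__name__)


def quantile_normalize(matrix: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns of a 2-D array; NaN entries stay missing.

    With complete columns this is the classic construction: sorted values of
    every column are replaced by the mean of the sorted columns, ties
    receiving the mean of their would-be quantile values.  Columns with
    missing entries are mapped through rank interpolation onto the mean
    quantile profile, so within-column rank order is always preserved.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    n_rows, n_cols = matrix.shape
    if n_cols < 2:
        raise ValueError("quantile normalization needs at least 2 columns")
    counts = np.isfinite(matrix).sum(axis=0)
    if (counts == 0).any():
        bad = np.flatnonzero(counts == 0)
        raise ValueError(f"all-missing column(s) at positions {bad.tolist()}")

    probs = np.linspace(0.0, 1.0, n_rows) if n_rows > 1 else np.array([0.5])
    profiles = np.empty((n_rows, n_cols))
    for j in range(n_cols):
        obs = np.sort(matrix[np.isfinite(matrix[:, j]), j])
        if obs.size == 1:
            profiles[:, j] = obs[0]
        else:
            knots = np.linspace(0.0, 1.0, obs.size)
            profiles[:, j] = np.interp(probs, knots, obs)
    reference = profiles.mean(axis=1)

    out = np.full_like(matrix, np.nan)
    for j in range(n_cols):
        mask = np.isfinite(matrix[:, j])
        obs = matrix[mask, j]
        if obs.size == 1:
            out[mask, j] = reference.mean()
            continue
        ranks = rankdata(obs, method="average")
        rank_prop = (ranks - 1.0) / (obs.size - 1.0)
        out[mask, j] = np.interp(rank_prop, probs, reference)
    return out


def _autosomal_mask(aset: ArraySet, autosomes_only: bool) -> np.ndarray:
    if not autosomes_only:
        return np.ones(aset.n_probes, dtype=bool)
    return ~aset.manifest.table["chromosome"].isin(SEX_CHROMOSOMES).to_numpy()


def qn1(
    aset: ArraySet,
    autosomes_only: bool = True,
    clamp_floor: Optional[float] = 1.0,
) -> MethylationMatrix:
    """QN on intensities in four independent blocks, then m-values.

    Blocks: P1g intensities (M and U pooled), P1r intensities (pooled),
    Type II methylated signals, Type II unmethylated signals.
    """
    norm_M = aset.M.astype(float).copy()
    norm_U = aset.U.astype(float).copy()
    in_scope = _autosomal_mask(aset, autosomes_only)
    for probe_class in (ProbeClass.I_GREEN, ProbeClass.I_RED):
        rows = np.flatnonzero(aset.manifest.class_mask(probe_class) & in_scope)
        if rows.size == 0:
            continue
        stacked = np.vstack([aset.M[rows], aset.U[rows]])
        qn = quantile_normalize(stacked)
        norm_M[rows] = qn[: rows.size]
        norm_U[rows] = qn[rows.size :]
    rows2 = np.flatnonzero(aset.manifest.class_mask(ProbeClass.II) & in_scope)
    if rows2.size:
        norm_M[rows2] = quantile_normalize(aset.M[rows2])
        norm_U[rows2] = quantile_normalize(aset.U[rows2])
    return MethylationMatrix(
        m_from_intensities(norm_M, norm_U, clamp_floor),
        Measure.M_VALUE,
        aset.probe_ids,
        aset.sample_ids,
    )


def qn2(
    aset: ArraySet,
    autosomes_only: bool = True,
    clamp_floor: Optional[float] = 1.0,
) -> MethylationMatrix:
    """QN on raw m-values in three independent blocks (P1g, P1r, P2)."""
    m_raw = m_from_intensities(aset.M, aset.U, clamp_floor)
    out = m_raw.copy()
    in_scope = _autosomal_mask(aset, autosomes_only)
    for probe_class in (ProbeClass.I_GREEN, ProbeClass.I_RED, ProbeClass.II):
        rows = np.flatnonzero(aset.manifest.class_mask(probe_class) & in_scope)
        if rows.size == 0:
            continue
        out[rows] = quantile_normalize(m_raw[rows])
    return MethylationMatrix(out, Measure.M_VALUE, aset.probe_ids, aset.sample_ids)
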