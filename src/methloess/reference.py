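"""Virtual reference array: per-probe medians across samples on a housekeeping set.

The normalization learns each sample's bias relative to a baseline.  The
baseline is a virtual array built from a set E of housekeeping CpG sites that
are assumed equally methylated in all samples: for each probe (and each of its
M/U signals, on the log-intensity scale) the median across samples serves as
the reference value.  The same construction on Type II m-values provides the
baseline for the second normalization stage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .core import ArraySet, Measure, MethylationMatrix, ProbeClass, Signal, clamp_intensities
from .io import NA_TOKEN, SEP, read_probe_list

logger = logging.getLogger(__name__)


class ReferenceScale:
    LOG_INTENSITY = "LOG_INTENSITY"
    M_VALUE = "M_VALUE"


@dataclass(frozen=True)
class HousekeepingSet:
    """Set E of probes assumed equally methylated across all samples."""

    probe_ids: frozenset[str]

    @classmethod
    def from_iterable(cls, ids: Iterable[str]) -> "HousekeepingSet":
        return cls(frozenset(str(i) for i in ids))

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "HousekeepingSet":
        return cls.from_iterable(read_probe_list(path))

    def __len__(self) -> int:
        return len(self.probe_ids)

    def intersect_index(self, probe_ids: pd.Index, context: str = "") -> np.ndarray:
        """Boolean mask of ``probe_ids`` membership; warns about unknown ids."""
        mask = probe_ids.isin(self.probe_ids)
        n_unknown = len(self.probe_ids) - int(mask.sum())
        if n_unknown > 0 and context == "manifest":
            warnings.warn(
                f"{n_unknown} housekeeping probe_ids not present in the manifest",
                stacklevel=2,
            )
        return np.asarray(mask)


@dataclass
class ReferenceVector:
    """Per-probe (or per probe/signal) reference values on a fixed scale.

    ``keys`` is a pandas Index; for pooled-signal intensity references it is a
    MultiIndex of (probe_id, signal) so each probe contributes one M and one U
    reference point.
    """

    keys: pd.Index
    values: np.ndarray
    scale: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.keys) != len(self.values):
            raise ValueError("keys and values length mismatch")
        if not np.isfinite(self.values).all():
            raise ValueError("reference values must be finite")

    def __len__(self) -> int:
        return len(self.values)

    def to_file(self, path: Union[str, Path]) -> None:
        df = pd.DataFrame({"value": self.values})
        if isinstance(self.keys, pd.MultiIndex):
            df.insert(0, "probe_id", self.keys.get_level_values(0))
            df.insert(1, "signal", self.keys.get_level_values(1))
        else:
            df.insert(0, "probe_id", self.keys)
            df.insert(1, "signal", "")
        with open(path, "w") as fh:
            fh.write(f"# scale={self.scale}\n")
            df.to_csv(fh, sep=SEP, index=False, na_rep=NA_TOKEN, float_format="%.10g")

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "ReferenceVector":
        with open(path) as fh:
            first = fh.readline().strip()
            scale = first.split("scale=", 1)[1] if "scale=" in first else ReferenceScale.LOG_INTENSITY
            df = pd.read_csv(fh, sep=SEP, dtype={"probe_id": str})
        signals = df["signal"].fillna("")
        if (signals != "").any():
            keys = pd.MultiIndex.from_arrays([df["probe_id"], signals])
        else:
            keys = pd.Index(df["probe_id"])
        return cls(keys, df["value"].to_numpy(), scale)


def _median_ignoring_missing(
    values: np.ndarray,
    keys: pd.Index,
    max_missing_fraction: float = 0.5,
) -> tuple[pd.Index, np.ndarray]:
    """Row medians over samples, dropping rows missing in too many samples."""
    n_samples = values.shape[1]
    n_present = np.isfinite(values).sum(axis=1)
    usable = n_present > max_missing_fraction * n_samples
    n_dropped = int((~usable).sum())
    if n_dropped:
        warnings.warn(
            f"{n_dropped} housekeeping probes missing in more than "
            f"{max_missing_fraction:.0%} of samples were excluded from the reference",
            stacklevel=3,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows already excluded
        medians = np.nanmedian(values[usable], axis=1)
    return keys[usable], medians


def build_intensity_reference(
    aset: ArraySet,
    housekeeping: HousekeepingSet,
    probe_class: ProbeClass,
    signal: Signal = Signal.BOTH,
    clamp_floor: Optional[float] = 1.0,
) -> ReferenceVector:
    """Median log-intensity per housekeeping probe/signal of one probe class.

    With ``signal=BOTH`` (the default) each probe of the class contributes two
    reference points, one for its M signal and one for its U signal, both on
    the natural-log intensity scale.
    """
    if aset.n_samples < 2:
        raise ValueError("need at least 2 samples to build a reference")
    class_mask = aset.manifest.class_mask(probe_class)
    hk_mask = housekeeping.intersect_index(aset.probe_ids, context="manifest")
    rows = np.flatnonzero(class_mask & hk_mask)
    if rows.size == 0:
        raise ValueError(
            f"housekeeping set has no probes of class {probe_class.value}"
        )
    probe_ids = aset.probe_ids[rows]
    blocks = []
    key_arrays: list[tuple[np.ndarray, str]] = []
    if signal in (Signal.M_SIGNAL, Signal.BOTH):
        blocks.append(np.log(clamp_intensities(aset.M[rows], clamp_floor)))
        key_arrays.append((probe_ids.to_numpy(), Signal.M_SIGNAL.value))
    if signal in (Signal.U_SIGNAL, Signal.BOTH):
        blocks.append(np.log(clamp_intensities(aset.U[rows], clamp_floor)))
        key_arrays.append((probe_ids.to_numpy(), Signal.U_SIGNAL.value))
    values = np.vstack(blocks)
    keys = pd.MultiIndex.from_arrays(
        [
            np.concatenate([ids for ids, _ in key_arrays]),
            np.concatenate([[sig] * len(ids) for ids, sig in key_arrays]),
        ],
        names=["probe_id", "signal"],
    )
    kept_keys, medians = _median_ignoring_missing(values, keys)
    return ReferenceVector(kept_keys, medians, ReferenceScale.LOG_INTENSITY)


def build_mvalue_reference(
    mvalues: MethylationMatrix,
    housekeeping: HousekeepingSet,
) -> ReferenceVector:
    """Median m-value per housekeeping probe (stage-two reference for Type II)."""
    if mvalues.measure != Measure.M_VALUE:
        raise ValueError("m-value reference requires an m-value matrix")
    if len(mvalues.sample_ids) < 2:
        raise ValueError("need at least 2 samples to build a reference")
    mask = housekeeping.intersect_index(mvalues.probe_ids)
    rows = np.flatnonzero(mask)
    if rows.size == 0:
        raise ValueError("housekeeping set does not intersect the m-value matrix")
    kept_keys, medians = _median_ignoring_missing(
        mvalues.values[rows], mvalues.probe_ids[rows]
    )
    return ReferenceVector(kept_keys, medians, ReferenceScale.M_VALUE)
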