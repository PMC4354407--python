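"""Data model for two-channel methylation array data and the m/beta transforms.

The Infinium 450K chip reports, for every CpG locus ``i`` and sample ``z``, a
methylated intensity ``M_iz`` and an unmethylated intensity ``U_iz``.  Type I
probes measure both signals in a single colour channel (green subset P1g, red
subset P1r); Type II probes measure the methylated signal in green (Cy3) and
the unmethylated signal in red (Cy5).  Methylation is summarised either as the
m-value ``ln(M/U)`` or as the beta-value ``M/(M+U)``.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEX_CHROMOSOMES = frozenset({"X", "Y", "chrX", "chrY"})


class ProbeClass(str, enum.Enum):
    """Probe chemistry / colour-channel class."""

    I_GREEN = "I_GREEN"
    I_RED = "I_RED"
    II = "II"


class Measure(str, enum.Enum):
    M_VALUE = "M_VALUE"
    BETA = "BETA"


class Signal(str, enum.Enum):
    """Which of the two per-locus signals a number refers to."""

    M_SIGNAL = "M"
    U_SIGNAL = "U"
    BOTH = "BOTH"


# ---------------------------------------------------------------------------
# scalar / array transforms
# ---------------------------------------------------------------------------

def clamp_intensities(values: np.ndarray, floor: Optional[float] = 1.0) -> np.ndarray:
    """Clamp non-positive intensities to ``floor`` (NaN if ``floor`` is None).

    Upstream background subtraction in foreign data can produce zero or
    negative intensities; the log-ratio is undefined there.  Clamped entries
    are counted and logged at DEBUG level.
    """
    values = np.asarray(values, dtype=float)
    bad = values <= 0
    n_bad = int(np.count_nonzero(bad & np.isfinite(values)))
    if n_bad:
        logger.debug("clamped %d non-positive intensities", n_bad)
    if floor is None:
        return np.where(bad, np.nan, values)
    return np.where(bad, floor, values)


def m_from_intensities(
    M, U, clamp_floor: Optional[float] = 1.0, base: float = math.e
) -> np.ndarray:
    """m-value ``log(M/U)`` (natural log by default).

    Non-positive intensities are clamped to ``clamp_floor`` first; with
    ``clamp_floor=None`` they become missing (NaN).  Missing inputs propagate.
    """
    M = clamp_intensities(M, clamp_floor)
    U = clamp_intensities(U, clamp_floor)
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.log(M) - np.log(U)
    if base != math.e:
        m = m / math.log(base)
    return m


def beta_from_intensities(M, U) -> np.ndarray:
    """beta-value ``M/(M+U)`` in [0, 1]; ``M+U == 0`` yields missing."""
    M = np.asarray(M, dtype=float)
    U = np.asarray(U, dtype=float)
    total = M + U
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(total > 0, M / total, np.nan)
    return beta


def m_to_beta(m, base: float = math.e) -> np.ndarray:
    """beta = b^m / (b^m + 1); the logistic transform of the m-value."""
    m = np.asarray(m, dtype=float)
    if base != math.e:
        m = m * math.log(base)
    # logistic via exp(-|m|) to avoid overflow at large |m|
    with np.errstate(over="ignore"):
        out = np.where(m >= 0, 1.0 / (1.0 + np.exp(-m)), np.exp(m) / (1.0 + np.exp(m)))
    return out


def beta_to_m(beta, base: float = math.e) -> np.ndarray:
    """m = log(beta / (1 - beta)); beta in {0, 1} yields missing (logged)."""
    beta = np.asarray(beta, dtype=float)
    boundary = (beta <= 0) | (beta >= 1)
    n_boundary = int(np.count_nonzero(boundary & np.isfinite(beta)))
    if n_boundary:
        logger.debug("beta_to_m: %d boundary values set missing", n_boundary)
    safe = np.where(boundary, np.nan, beta)
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.log(safe) - np.log1p(-safe)
    if base != math.e:
        m = m / math.log(base)
    return m


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ProbeManifest:
    """Probe annotation table driving all per-class processing.

    One row per probe: class (I_GREEN / I_RED / II), chromosome and a CpG
    flag (False for the chip's non-CpG "ch" probes).  Probe ids are unique
    and every probe belongs to exactly one class, so the three classes
    partition the probe set.
    """

    table: pd.DataFrame  # index: probe_id; columns: probe_class, chromosome, is_cpg

    def __post_init__(self) -> None:
        required = {"probe_class", "chromosome", "is_cpg"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        if not self.table.index.is_unique:
            dupes = self.table.index[self.table.index.duplicated()].unique()
            raise ValueError(f"duplicate probe_ids in manifest: {list(dupes[:5])}")
        cls = self.table["probe_class"]
        valid = {c.value for c in ProbeClass}
        bad = set(cls.unique()) - valid
        if bad:
            raise ValueError(f"unknown probe classes: {sorted(bad)}")
        self.table = self.table.assign(is_cpg=self.table["is_cpg"].astype(bool))

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    def __len__(self) -> int:
        return len(self.table)

    def class_mask(self, probe_class: ProbeClass) -> np.ndarray:
        return (self.table["probe_class"] == probe_class.value).to_numpy()

    def subset(self, mask: np.ndarray) -> "ProbeManifest":
        return ProbeManifest(self.table.loc[np.asarray(mask)])

    def filter_mask(
        self,
        exclude_non_cpg: bool = False,
        exclude_sex_chromosomes: bool = False,
    ) -> np.ndarray:
        """Boolean mask of probes KEPT under the benchmark filtering rules."""
        keep = np.ones(len(self.table), dtype=bool)
        if exclude_non_cpg:
            keep &= self.table["is_cpg"].to_numpy()
        if exclude_sex_chromosomes:
            keep &= ~self.table["chromosome"].isin(SEX_CHROMOSOMES).to_numpy()
        return keep


@dataclass
class MethylationMatrix:
    """Probes x samples matrix of m-values or beta-values; NaN marks missing."""

    values: np.ndarray
    measure: Measure
    probe_ids: pd.Index
    sample_ids: Sequence[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.probe_ids = pd.Index(self.probe_ids)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if self.measure == Measure.BETA:
            finite = self.values[np.isfinite(self.values)]
            if finite.size and ((finite < 0).any() or (finite > 1).any()):
                raise ValueError("beta values outside [0, 1]")

    @property
    def missing_mask(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    def to_beta(self) -> "MethylationMatrix":
        if self.measure == Measure.BETA:
            return self
        return MethylationMatrix(
            m_to_beta(self.values), Measure.BETA, self.probe_ids, self.sample_ids
        )

    def to_m(self) -> "MethylationMatrix":
        if self.measure == Measure.M_VALUE:
            return self
        return MethylationMatrix(
            beta_to_m(self.values), Measure.M_VALUE, self.probe_ids, self.sample_ids
        )

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=list(self.sample_ids))

    def subset_probes(self, mask: np.ndarray) -> "MethylationMatrix":
        mask = np.asarray(mask)
        return MethylationMatrix(
            self.values[mask], self.measure, self.probe_ids[mask], self.sample_ids
        )


@dataclass
class ArraySet:
    """Paired M/U intensity matrices with their manifest: the unit of normalization."""

    M: np.ndarray
    U: np.ndarray
    manifest: ProbeManifest
    sample_ids: Sequence[str]
    sample_meta: Optional[pd.DataFrame] = None  # indexed by sample_id

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        self.U = np.asarray(self.U, dtype=float)
        shape = (len(self.manifest), len(self.sample_ids))
        if self.M.shape != shape or self.U.shape != shape:
            raise ValueError(
                f"intensity shapes {self.M.shape}/{self.U.shape} do not match "
                f"{shape[0]} probes x {shape[1]} samples"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_ids")
        for name, arr in (("M", self.M), ("U", self.U)):
            if np.isinf(arr).any():
                raise ValueError(f"non-finite (infinite) intensities in {name}")
        if self.sample_meta is not None:
            missing = set(self.sample_ids) - set(self.sample_meta.index)
            if missing:
                raise ValueError(f"sample_meta missing samples: {sorted(missing)[:5]}")

    @property
    def n_probes(self) -> int:
        return len(self.manifest)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def probe_ids(self) -> pd.Index:
        return self.manifest.probe_ids

    def copy(self) -> "ArraySet":
        meta = None if self.sample_meta is None else self.sample_meta.copy()
        return ArraySet(self.M.copy(), self.U.copy(), self.manifest, list(self.sample_ids), meta)

    def mvalues(self, clamp_floor: Optional[float] = 1.0) -> MethylationMatrix:
        return MethylationMatrix(
            m_from_intensities(self.M, self.U, clamp_floor),
            Measure.M_VALUE,
            self.probe_ids,
            self.sample_ids,
        )

    def betas(self) -> MethylationMatrix:
        return MethylationMatrix(
            beta_from_intensities(self.M, self.U),
            Measure.BETA,
            self.probe_ids,
            self.sample_ids,
        )

    def subset_by_class(self, probe_class: ProbeClass) -> "ArraySetView":
        mask = self.manifest.class_mask(probe_class)
        if not mask.any():
            raise ValueError(f"no probes of class {probe_class.value} in manifest")
        return ArraySetView(self, np.flatnonzero(mask))


@dataclass
class ArraySetView:
    """Row-subset view of an ArraySet; intensity writes pass through to the parent.

    The normalization pipeline corrects intensities class by class in place,
    so assignment to ``view.M`` / ``view.U`` must update the parent arrays.
    """

    parent: ArraySet
    rows: np.ndarray

    @property
    def M(self) -> np.ndarray:
        return self.parent.M[self.rows]

    @M.setter
    def M(self, values: np.ndarray) -> None:
        self.parent.M[self.rows] = values

    @property
    def U(self) -> np.ndarray:
        return self.parent.U[self.rows]

    @U.setter
    def U(self, values: np.ndarray) -> None:
        self.parent.U[self.rows] = values

    @property
    def probe_ids(self) -> pd.Index:
        return self.parent.probe_ids[self.rows]

    @property
    def manifest(self) -> ProbeManifest:
        return ProbeManifest(self.parent.manifest.table.iloc[self.rows])

    @property
    def sample_ids(self) -> Sequence[str]:
        return self.parent.sample_ids

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class FilterReport:
    n_input: int
    n_removed_non_cpg: int
    n_removed_sex_chromosome: int
    n_kept: int


def filter_probes(
    aset: ArraySet,
    exclude_non_cpg: bool = True,
    exclude_sex_chromosomes: bool = True,
) -> tuple[ArraySet, FilterReport]:
    """Drop non-CpG probes and/or sex-chromosome probes (the benchmark filter).

    Returns a new ArraySet (copy, not a view) plus counts of what was removed.
    A probe failing both filters is counted under the non-CpG rule.
    """
    table = aset.manifest.table
    non_cpg = ~table["is_cpg"].to_numpy() if exclude_non_cpg else np.zeros(len(table), bool)
    on_sex = (
        table["chromosome"].isin(SEX_CHROMOSOMES).to_numpy()
        if exclude_sex_chromosomes
        else np.zeros(len(table), bool)
    )
    keep = ~(non_cpg | on_sex)
    report = FilterReport(
        n_input=len(table),
        n_removed_non_cpg=int(non_cpg.sum()),
        n_removed_sex_chromosome=int((on_sex & ~non_cpg).sum()),
        n_kept=int(keep.sum()),
    )
    filtered = ArraySet(
        aset.M[keep].copy(),
        aset.U[keep].copy(),
        aset.manifest.subset(keep),
        list(aset.sample_ids),
        aset.sample_meta,
    )
    return filtered, report
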