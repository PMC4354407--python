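"""The three evaluation protocols for between-array normalization methods.

1. Technical-replicate correlation: Pearson correlation between the two
   members of each replicate pair, computed on both m-values and beta-values,
   separately for Type I and Type II probes.  Non-CpG probes and probes on
   the X and Y chromosomes are excluded.  For each method the number of pairs
   where it achieved the (strictly or jointly) highest correlation and the
   number of pairs where it fell below the raw values are counted.
2. Split-half concordance of differential-methylation rankings: replicate
   pairs are split into two halves; in each half probes are ranked by the
   p-value of a two-sample t-test on m-values between two groups (e.g. sex),
   and the overlap percentage of the top-k hits between the halves is traced
   over k.
3. Trait correlation: Spearman correlation of a probe's methylation level
   with a continuous or ordinal trait; normalization should increase its
   absolute value for genuinely trait-associated probes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .core import Measure, MethylationMatrix, ProbeClass, ArraySet
from .comparators import qn1, qn2
from .normalize import LoessParams, normalize
from .reference import HousekeepingSet
from .simulate import SimulationTruth, read_fixture

logger = logging.getLogger(__name__)

PairList = Sequence[tuple[str, str]]


# ---------------------------------------------------------------------------
# benchmark 1: replicate correlation
# ---------------------------------------------------------------------------

def replicate_correlation(
    mm: MethylationMatrix,
    pairs: PairList,
    measure: Measure = Measure.M_VALUE,
    probe_mask: Optional[np.ndarray] = None,
    min_shared: int = 100,
) -> pd.Series:
    """Pearson correlation per replicate pair over shared non-missing probes.

    ``probe_mask`` restricts to a probe subset (class and/or benchmark
    filters).  Beta-values are derived from m-values on demand.
    """
    data = mm.to_beta() if measure == Measure.BETA else mm.to_m()
    values = data.values
    if probe_mask is not None:
        values = values[np.asarray(probe_mask)]
    col = {s: j for j, s in enumerate(mm.sample_ids)}
    out = {}
    for a, b in pairs:
        if a not in col or b not in col:
            raise KeyError(f"replicate pair ({a}, {b}) not found among samples")
        x, y = values[:, col[a]], values[:, col[b]]
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < min_shared:
            raise ValueError(
                f"pair ({a}, {b}) shares only {int(ok.sum())} probes (< {min_shared})"
            )
        out[f"{a}|{b}"] = float(np.corrcoef(x[ok], y[ok])[0, 1])
    return pd.Series(out, name="correlation")


def win_decline_counts(
    raw: pd.Series,
    method_correlations: Mapping[str, pd.Series],
    tol: float = 0.0,
) -> pd.DataFrame:
    """Per-method: how often it achieved the highest correlation, and how often
    it declined relative to raw.

    Raw values compete for "best" under the label ``none``.  Ties for best
    count for every tied method.
    """
    table = pd.DataFrame({"none": raw, **dict(method_correlations)})
    best = table.max(axis=1)
    rows = []
    for name in table.columns:
        is_best = table[name] >= best - tol
        declined = table[name] < raw - tol
        rows.append(
            {
                "method": name,
                "n_best": int(is_best.sum()),
                "n_declined": int(declined.sum()),
                "n_pairs": len(table),
                "mean_correlation": float(table[name].mean()),
            }
        )
    return pd.DataFrame(rows).set_index("method")


# ---------------------------------------------------------------------------
# benchmark 2: split-half concordance
# ---------------------------------------------------------------------------

def _rank_probes(
    values: np.ndarray,
    groups: np.ndarray,
    probe_ids: pd.Index,
    welch: bool = True,
) -> np.ndarray:
    """Order of probe indices by ascending two-sample t-test p-value.

    Ties are broken by descending |t|, then probe_id; probes without a valid
    test (too few observations) sort last.
    """
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(labels)}")
    a = values[:, groups == labels[0]]
    b = values[:, groups == labels[1]]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples in each half")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.ttest_ind(a, b, axis=1, equal_var=not welch, nan_policy="omit")
    p = np.asarray(res.pvalue, dtype=float)
    t = np.abs(np.asarray(res.statistic, dtype=float))
    p = np.where(np.isfinite(p), p, np.inf)
    t = np.where(np.isfinite(t), t, -np.inf)
    # lexsort: last key is primary
    return np.lexsort((np.asarray(probe_ids), -t, p))


def split_half_concordance(
    mm: MethylationMatrix,
    pairs: PairList,
    groups: Mapping[str, str],
    k_max: int = 400,
    probe_mask: Optional[np.ndarray] = None,
    welch: bool = True,
) -> pd.Series:
    """Top-k overlap percentage between differential-methylation rankings of
    the two replicate halves.

    The first member of each pair forms half 1, the second half 2.  Within
    each half probes are ranked by two-sample t-test p-value on m-values
    between the two groups; the curve is 100 * |top_k(1) & top_k(2)| / k.
    """
    data = mm.to_m()
    values = data.values
    probe_ids = data.probe_ids
    if probe_mask is not None:
        probe_mask = np.asarray(probe_mask)
        values = values[probe_mask]
        probe_ids = probe_ids[probe_mask]
    col = {s: j for j, s in enumerate(mm.sample_ids)}
    halves = []
    for members in zip(*pairs):  # (firsts, seconds)
        idx = [col[s] for s in members]
        labels = np.array([groups[s] for s in members])
        halves.append(_rank_probes(values[:, idx], labels, probe_ids, welch))
    k_max = min(k_max, len(probe_ids))
    order1, order2 = halves
    overlap = np.empty(k_max)
    seen1: set = set()
    seen2: set = set()
    common = 0
    for k in range(k_max):
        p1, p2 = order1[k], order2[k]
        if p1 == p2:
            common += 1
        else:
            common += (p1 in seen2) + (p2 in seen1)
        seen1.add(p1)
        seen2.add(p2)
        overlap[k] = 100.0 * common / (k + 1)
    return pd.Series(overlap, index=pd.RangeIndex(1, k_max + 1, name="k"), name="overlap_pct")


def permutation_overlap_baseline(
    mm: MethylationMatrix,
    pairs: PairList,
    groups: Mapping[str, str],
    k: int,
    n_permutations: int = 20,
    seed: int = 0,
    probe_mask: Optional[np.ndarray] = None,
) -> float:
    """Mean top-k overlap percentage with group labels permuted (no-signal null)."""
    rng = np.random.default_rng(seed)
    sample_ids = list(groups.keys())
    labels = np.array([groups[s] for s in sample_ids])
    out = []
    for _ in range(n_permutations):
        perm = dict(zip(sample_ids, labels[rng.permutation(len(labels))]))
        # permutations may starve a group in one half; skip those draws
        try:
            curve = split_half_concordance(mm, pairs, perm, k_max=k, probe_mask=probe_mask)
        except ValueError:
            continue
        out.append(curve.iloc[-1])
    if not out:
        raise ValueError("no valid permutations (groups too small)")
    return float(np.mean(out))


# ---------------------------------------------------------------------------
# benchmark 3: trait correlation
# ---------------------------------------------------------------------------

def trait_correlation(
    mm: MethylationMatrix,
    probe_id: str,
    trait: Mapping[str, float],
) -> float:
    """Spearman correlation of one probe's methylation with a trait.

    Returns NaN (with a warning) for a constant trait; needs at least three
    complete (methylation, trait) pairs.
    """
    if probe_id not in mm.probe_ids:
        raise KeyError(f"probe {probe_id!r} not in matrix")
    row = mm.values[mm.probe_ids.get_loc(probe_id)]
    t = np.array([trait.get(s, np.nan) for s in mm.sample_ids], dtype=float)
    ok = np.isfinite(row) & np.isfinite(t)
    if ok.sum() < 3:
        raise ValueError(f"probe {probe_id!r}: fewer than 3 complete pairs")
    if np.ptp(t[ok]) == 0:
        warnings.warn(f"trait constant across samples for probe {probe_id!r}")
        return float("nan")
    rho, _ = stats.spearmanr(row[ok], t[ok])
    return float(rho)


# ---------------------------------------------------------------------------
# the full suite
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkResult:
    """All three benchmarks for a set of methods, reported per probe class."""

    replicate: pd.DataFrame    # method, probe_class, measure, pair, correlation
    win_decline: pd.DataFrame  # method, probe_class, measure, n_best, n_declined
    overlap: pd.DataFrame      # method, probe_class, k, overlap_pct
    trait: pd.DataFrame        # method, probe_id, spearman

    def table(self) -> pd.DataFrame:
        """One tidy results table: (method, benchmark, probe_class, measure, statistic, value)."""
        rows = []
        for _, r in self.replicate.iterrows():
            rows.append((r["method"], "replicate_correlation", r["probe_class"],
                         r["measure"], f"pair:{r['pair']}", r["correlation"]))
        for _, r in self.win_decline.iterrows():
            rows.append((r["method"], "replicate_correlation", r["probe_class"],
                         r["measure"], "n_best", r["n_best"]))
            rows.append((r["method"], "replicate_correlation", r["probe_class"],
                         r["measure"], "n_declined", r["n_declined"]))
        for _, r in self.overlap.iterrows():
            rows.append((r["method"], "split_half_overlap", r["probe_class"],
                         "m", f"k:{int(r['k'])}", r["overlap_pct"]))
        for _, r in self.trait.iterrows():
            rows.append((r["method"], "trait_spearman", "all", "m",
                         f"probe:{r['probe_id']}", r["spearman"]))
        return pd.DataFrame(
            rows,
            columns=["method", "benchmark", "probe_class", "measure", "statistic", "value"],
        )

    def write(self, directory: Union[str, Path]) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        path = directory / "benchmark_results.tsv"
        self.table().to_csv(path, sep="\t", index=False, float_format="%.10g")
        return path

    def plot(self, directory: Union[str, Path]) -> list[Path]:
        """Replicate-correlation boxplots and overlap curves, one figure each."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        fig, axes = plt.subplots(2, 2, figsize=(10, 7), sharex=True)
        for ax, (cls, measure) in zip(
            axes.ravel(), [("P1", "m"), ("P1", "beta"), ("P2", "m"), ("P2", "beta")]
        ):
            sub = self.replicate.query("probe_class == @cls and measure == @measure")
            methods = list(dict.fromkeys(sub["method"]))
            ax.boxplot(
                [sub.loc[sub["method"] == m, "correlation"] for m in methods],
                tick_labels=methods,
            )
            ax.set_title(f"{cls}, {measure}-values")
            ax.tick_params(axis="x", rotation=45)
        fig.suptitle("Replicate correlation by normalization method")
        fig.tight_layout()
        p = directory / "replicate_correlation.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)

        fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
        for ax, cls in zip(axes, ["P1", "P2"]):
            sub = self.overlap.query("probe_class == @cls")
            for m in dict.fromkeys(sub["method"]):
                s = sub[sub["method"] == m]
                ax.plot(s["k"], s["overlap_pct"], label=m)
            ax.set_title(cls)
            ax.set_xlabel("top k")
        axes[0].set_ylabel("overlap %")
        axes[0].legend()
        fig.suptitle("Split-half concordance of differential-methylation rankings")
        fig.tight_layout()
        p = directory / "split_half_overlap.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
        return written


CLASS_GROUPS = {
    "P1": (ProbeClass.I_GREEN, ProbeClass.I_RED),
    "P2": (ProbeClass.II,),
}


def _class_masks(aset: ArraySet) -> dict[str, np.ndarray]:
    bench_mask = aset.manifest.filter_mask(
        exclude_non_cpg=True, exclude_sex_chromosomes=True
    )
    out = {}
    for name, classes in CLASS_GROUPS.items():
        mask = np.zeros(aset.n_probes, dtype=bool)
        for c in classes:
            mask |= aset.manifest.class_mask(c)
        out[name] = mask & bench_mask
    return out


def compute_method_matrices(
    aset: ArraySet,
    housekeeping: HousekeepingSet,
    methods: Iterable[str] = ("none", "loess", "qn1", "qn2"),
    external: Optional[Mapping[str, MethylationMatrix]] = None,
    loess_params: Optional[LoessParams] = None,
) -> Dict[str, MethylationMatrix]:
    """Normalized m-value matrices for each requested method.

    ``external`` supplies pre-computed matrices for methods implemented
    elsewhere (e.g. SWAN or BMIQ outputs), keyed by method name.
    """
    external = dict(external or {})
    params = loess_params or LoessParams()
    out: Dict[str, MethylationMatrix] = {}
    for name in methods:
        if name in external:
            out[name] = external[name].to_m()
        elif name == "none":
            out[name] = aset.mvalues()
        elif name == "loess":
            out[name] = normalize(aset, housekeeping, params).normalized
        elif name == "qn1":
            out[name] = qn1(aset)
        elif name == "qn2":
            out[name] = qn2(aset)
        else:
            raise ValueError(f"unknown method {name!r} (and no external matrix given)")
    return out


def run_benchmark_suite(
    fixture: Union[str, Path, tuple[ArraySet, SimulationTruth]],
    methods: Iterable[str] = ("none", "loess", "qn1", "qn2"),
    external: Optional[Mapping[str, MethylationMatrix]] = None,
    k_max: int = 400,
    loess_params: Optional[LoessParams] = None,
    group_column: str = "sex",
    trait_column: str = "age",
) -> BenchmarkResult:
    """Run all three benchmarks for each method on a fixture.

    ``fixture`` is either a directory written by ``write_fixture`` or an
    in-memory ``(ArraySet, SimulationTruth)`` pair.
    """
    if isinstance(fixture, (str, Path)):
        aset, truth = read_fixture(fixture)
    else:
        aset, truth = fixture
    if aset.sample_meta is None:
        raise ValueError("fixture has no sample metadata (needed for groups/traits)")
    housekeeping = HousekeepingSet.from_iterable(truth.housekeeping_ids)
    matrices = compute_method_matrices(aset, housekeeping, methods, external, loess_params)
    masks = _class_masks(aset)
    pairs = truth.replicate_pairs
    groups = aset.sample_meta[group_column].to_dict()
    trait = aset.sample_meta[trait_column].to_dict()

    rep_rows, wd_rows, ov_rows, tr_rows = [], [], [], []
    for cls, mask in masks.items():
        for measure, mlabel in ((Measure.M_VALUE, "m"), (Measure.BETA, "beta")):
            per_method = {}
            for name, mm in matrices.items():
                corr = replicate_correlation(mm, pairs, measure, probe_mask=mask)
                per_method[name] = corr
                for pair_label, value in corr.items():
                    rep_rows.append((name, cls, mlabel, pair_label, value))
            raw = per_method.get("none")
            if raw is not None:
                wd = win_decline_counts(raw, {k: v for k, v in per_method.items() if k != "none"})
                for method, r in wd.iterrows():
                    wd_rows.append((method, cls, mlabel, r["n_best"], r["n_declined"], r["n_pairs"]))
        if pairs:
            for name, mm in matrices.items():
                try:
                    curve = split_half_concordance(mm, pairs, groups, k_max, probe_mask=mask)
                except ValueError as exc:
                    logger.warning("split-half skipped for %s/%s: %s", name, cls, exc)
                    continue
                for k, v in curve.items():
                    ov_rows.append((name, cls, int(k), v))
    for name, mm in matrices.items():
        for probe_id in truth.trait_probe_ids:
            try:
                rho = trait_correlation(mm, probe_id, trait)
            except (KeyError, ValueError):
                continue
            tr_rows.append((name, probe_id, rho))

    return BenchmarkResult(
        replicate=pd.DataFrame(
            rep_rows, columns=["method", "probe_class", "measure", "pair", "correlation"]
        ),
        win_decline=pd.DataFrame(
            wd_rows,
            columns=["method", "probe_class", "measure", "n_best", "n_declined", "n_pairs"],
        ),
        overlap=pd.DataFrame(ov_rows, columns=["method", "probe_class", "k", "overlap_pct"]),
        trait=pd.DataFrame(tr_rows, columns=["method", "probe_id", "spearman"]),
    )
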