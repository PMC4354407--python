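"""Synthetic two-channel methylation cohorts with realistic technical bias.

The generator emulates the documented failure modes of 450K-style data so the
normalization and its benchmarks can be exercised without access to real
cohorts:

* smooth per-sample intensity-dependent bias (each array distorts the
  log-intensity axis with its own linear / quadratic / sigmoid curve);
* an extra methylation-state-dependent dye bias on Type II probes, applied
  with opposite sign to the methylated (green) and unmethylated (red)
  channel, so unmethylated probes drift up and methylated probes drift down
  relative to a replicate;
* heteroscedastic m-values: an additive fluorescence background floor makes
  the weaker channel noisy, inflating the m-value spread at extreme
  methylation levels (the U-shape of sd against mean m).

Generative model, per probe i and sample z:

    M_true = a_i * c_z * beta_i * D        U_true = a_i * c_z * (1 - beta_i) * D
    ln S_obs = ln S_true + g_z(ln S_true) [+ dye term for Type II] + eps
    S = exp(ln S_obs) + background

with probe affinity ``a_i`` lognormal, sample scale ``c_z`` lognormal, and
``eps ~ N(0, noise_log_sd)``.  Technical replicate pairs share the underlying
individual (same true beta and affinities) but draw independent scale, bias
and noise.  A configurable set of probes is differentially methylated between
two groups (``sex``), and another set tracks a continuous trait (``age``).
Housekeeping probes have constant true methylation across individuals except
for a small contamination fraction of variable sites.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import ArraySet, ProbeClass, ProbeManifest, beta_to_m, m_to_beta
from .io import (
    SEP,
    read_array_set,
    read_key_value_config,
    read_probe_list,
    write_array_set,
    write_matrix,
    write_probe_list,
)

BiasFamily = str  # "none" | "linear" | "quadratic" | "sigmoid"

_BETA_COMPONENTS = ((0.6, 6.0), (3.0, 3.0), (6.0, 0.6))  # low, intermediate, high


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe the reference scenario used throughout the test suite:
    a 20,000-probe chip (30/70 Type I / Type II split), ten pairs of
    technical replicates, per-sample linear intensity bias and a Type II dye
    bias strong enough to push raw replicate m-value correlations into the
    0.95-0.99 range.
    """

    n_probes_p1g: int = 3000
    n_probes_p1r: int = 3000
    n_probes_p2: int = 14000
    n_samples: int = 20
    n_replicate_pairs: int = 10
    housekeeping_fraction: float = 0.05
    housekeeping_contamination: float = 0.05
    typeI_beta_weights: tuple[float, float, float] = (0.65, 0.15, 0.20)
    typeII_beta_weights: tuple[float, float, float] = (0.20, 0.15, 0.65)
    affinity_log_sd: float = 0.8
    sample_scale_log_sd: float = 0.15
    noise_log_sd: float = 0.10
    bias_family: BiasFamily = "linear"
    bias_coef_range: tuple[float, float] = (0.10, 0.30)
    bias_width: float = 2.0
    typeII_bias_amplitude: float = 0.4
    background_level: float = 100.0
    background_sd: float = 50.0
    intensity_scale: float = 5000.0
    biological_sd_m: float = 0.3
    n_differential: int = 50
    differential_effect_m: float = 1.0
    n_trait_probes: int = 20
    trait_effect_m_per_sd: float = 0.5
    fraction_non_cpg: float = 0.02
    fraction_chr_x: float = 0.03
    fraction_chr_y: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_probes_p1g, self.n_probes_p1r, self.n_probes_p2) <= 0:
            raise ValueError("probe counts must be positive")
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if 2 * self.n_replicate_pairs > self.n_samples:
            raise ValueError(
                f"{self.n_replicate_pairs} replicate pairs need "
                f"{2 * self.n_replicate_pairs} samples but n_samples={self.n_samples}"
            )
        if not (0 < self.housekeeping_fraction < 1):
            raise ValueError("housekeeping_fraction must be in (0, 1)")
        if self.bias_family not in ("none", "linear", "quadratic", "sigmoid"):
            raise ValueError(f"unknown bias family {self.bias_family!r}")

    @property
    def n_probes(self) -> int:
        return self.n_probes_p1g + self.n_probes_p1r + self.n_probes_p2

    # -- plain key = value serialization (the CLI's config format) ---------
    def to_key_value(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if isinstance(value, tuple):
                value = ",".join(str(v) for v in value)
            lines.append(f"{f.name} = {value}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_key_value(cls, text_or_path: Union[str, Path, dict]) -> "SimulationConfig":
        if isinstance(text_or_path, dict):
            raw = dict(text_or_path)
        else:
            raw = read_key_value_config(text_or_path)
        kwargs = {}
        field_types = {f.name: f for f in dataclasses.fields(cls)}
        for key, value in raw.items():
            if key not in field_types:
                raise ValueError(f"unknown config key {key!r}")
            default = getattr(cls, key, field_types[key].default)
            if isinstance(default, tuple):
                kwargs[key] = tuple(float(v) for v in str(value).split(","))
            elif isinstance(default, bool):
                kwargs[key] = str(value).lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                kwargs[key] = int(value)
            elif isinstance(default, float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = str(value)
        return cls(**kwargs)


@dataclass
class SimulationTruth:
    """Ground truth accompanying a simulated ArraySet."""

    true_beta: np.ndarray  # probes x samples
    replicate_pairs: list[tuple[str, str]]
    differential_probe_ids: list[str]
    trait_probe_ids: list[str]
    housekeeping_ids: list[str]
    bias_params: pd.DataFrame  # per sample: family, coef, center, dye_shift
    seed: int
    config: SimulationConfig


def _sample_bias_function(family: str, coef: float, center: float, width: float):
    if family == "none":
        return lambda t: np.zeros_like(np.asarray(t, dtype=float))
    if family == "linear":
        return lambda t: coef * (np.asarray(t, dtype=float) - center)
    if family == "quadratic":
        return lambda t: coef * ((np.asarray(t, dtype=float) - center) / width) ** 2
    if family == "sigmoid":
        return lambda t: coef * np.tanh((np.asarray(t, dtype=float) - center) / width)
    raise ValueError(f"unknown bias family {family!r}")


def _draw_betas(rng: np.random.Generator, n: int, weights: Sequence[float]) -> np.ndarray:
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    component = rng.choice(len(_BETA_COMPONENTS), size=n, p=weights)
    out = np.empty(n)
    for c, (a, b) in enumerate(_BETA_COMPONENTS):
        mask = component == c
        out[mask] = rng.beta(a, b, size=int(mask.sum()))
    return np.clip(out, 1e-4, 1 - 1e-4)


def _build_manifest(cfg: SimulationConfig, rng: np.random.Generator) -> ProbeManifest:
    n = cfg.n_probes
    classes = np.concatenate(
        [
            np.repeat(ProbeClass.I_GREEN.value, cfg.n_probes_p1g),
            np.repeat(ProbeClass.I_RED.value, cfg.n_probes_p1r),
            np.repeat(ProbeClass.II.value, cfg.n_probes_p2),
        ]
    )
    u = rng.random(n)
    chromosome = np.array([str(c) for c in rng.integers(1, 23, size=n)], dtype=object)
    chromosome[u < cfg.fraction_chr_x + cfg.fraction_chr_y] = "X"
    chromosome[u < cfg.fraction_chr_y] = "Y"
    is_cpg = rng.random(n) >= cfg.fraction_non_cpg
    prefix = np.where(is_cpg, "cg", "ch")
    probe_ids = [f"{p}{i:07d}" for i, p in enumerate(prefix)]
    table = pd.DataFrame(
        {"probe_class": classes, "chromosome": chromosome, "is_cpg": is_cpg},
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return ProbeManifest(table)


def simulate_array_set(
    config: SimulationConfig, seed: Optional[int] = None
) -> tuple[ArraySet, SimulationTruth]:
    """Draw one synthetic cohort; fixed seed gives a bit-identical result."""
    cfg = config
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    manifest = _build_manifest(cfg, rng)
    n = cfg.n_probes
    n_samples = cfg.n_samples
    n_pairs = cfg.n_replicate_pairs
    n_indiv = n_samples - n_pairs

    sample_ids = [f"S{j + 1:03d}" for j in range(n_samples)]
    # pairs occupy the leading samples: (S001, S002) -> individual 0, ...
    indiv_of_sample = np.empty(n_samples, dtype=int)
    pairs: list[tuple[str, str]] = []
    for p in range(n_pairs):
        indiv_of_sample[2 * p] = p
        indiv_of_sample[2 * p + 1] = p
        pairs.append((sample_ids[2 * p], sample_ids[2 * p + 1]))
    for j in range(2 * n_pairs, n_samples):
        indiv_of_sample[j] = n_pairs + (j - 2 * n_pairs)

    # individuals: balanced sexes, ages in the 50-74 screening range
    sexes = np.array(["F", "M"])[rng.permutation(np.arange(n_indiv) % 2)]
    ages = rng.uniform(50.0, 75.0, size=n_indiv)
    age_z = (ages - ages.mean()) / (ages.std() if n_indiv > 1 and ages.std() > 0 else 1.0)

    # baseline methylation per probe, class-specific mixtures
    beta_base = np.empty(n)
    is_typeII = manifest.class_mask(ProbeClass.II)
    beta_base[~is_typeII] = _draw_betas(rng, int((~is_typeII).sum()), cfg.typeI_beta_weights)
    beta_base[is_typeII] = _draw_betas(rng, int(is_typeII.sum()), cfg.typeII_beta_weights)

    # special probe sets: differential (sex), trait (age), housekeeping
    eligible = manifest.filter_mask(exclude_non_cpg=True, exclude_sex_chromosomes=True)
    eligible_idx = np.flatnonzero(eligible)
    if cfg.n_differential + cfg.n_trait_probes > eligible_idx.size:
        raise ValueError("not enough eligible probes for differential/trait sets")
    special = rng.choice(
        eligible_idx, size=cfg.n_differential + cfg.n_trait_probes, replace=False
    )
    diff_idx = special[: cfg.n_differential]
    trait_idx = special[cfg.n_differential :]

    hk_idx_parts = []
    special_set = set(special.tolist())
    for probe_class in ProbeClass:
        class_idx = np.flatnonzero(manifest.class_mask(probe_class) & eligible)
        class_idx = np.array([i for i in class_idx if i not in special_set])
        n_hk = max(1, int(round(cfg.housekeeping_fraction * class_idx.size)))
        hk_idx_parts.append(rng.choice(class_idx, size=n_hk, replace=False))
    hk_idx = np.concatenate(hk_idx_parts)
    is_hk = np.zeros(n, dtype=bool)
    is_hk[hk_idx] = True
    contaminated = is_hk & (rng.random(n) < cfg.housekeeping_contamination)
    variable = ~is_hk | contaminated

    # per-individual true methylation (m-scale jitter for variable probes)
    m_base = beta_to_m(beta_base)
    true_m = np.tile(m_base[:, None], (1, n_indiv))
    if cfg.biological_sd_m > 0:
        jitter = rng.normal(0.0, cfg.biological_sd_m, size=(int(variable.sum()), n_indiv))
        true_m[variable] += jitter
    true_m[diff_idx] += cfg.differential_effect_m * (sexes == "M")[None, :]
    true_m[trait_idx] += cfg.trait_effect_m_per_sd * age_z[None, :]
    true_beta_indiv = m_to_beta(true_m)

    affinity = rng.lognormal(0.0, cfg.affinity_log_sd, size=n)

    deterministic = (
        cfg.bias_family == "none"
        and cfg.noise_log_sd == 0
        and cfg.typeII_bias_amplitude == 0
        and cfg.background_sd == 0
    )
    scale = rng.lognormal(0.0, cfg.sample_scale_log_sd, size=n_samples)
    if deterministic:
        # replicates of a fully noiseless cohort must coincide exactly
        for a, b in zip(range(0, 2 * n_pairs, 2), range(1, 2 * n_pairs, 2)):
            scale[b] = scale[a]

    lo, hi = cfg.bias_coef_range
    coefs = rng.uniform(lo, hi, size=n_samples) * rng.choice([-1.0, 1.0], size=n_samples)
    dye_mag = rng.uniform(0.5, 1.5, size=n_samples) * rng.choice([-1.0, 1.0], size=n_samples)
    dye_shift = cfg.typeII_bias_amplitude * dye_mag

    M = np.empty((n, n_samples))
    U = np.empty((n, n_samples))
    true_beta = np.empty((n, n_samples))
    bias_rows = []
    for z in range(n_samples):
        beta_z = true_beta_indiv[:, indiv_of_sample[z]]
        true_beta[:, z] = beta_z
        m_true = affinity * scale[z] * beta_z * cfg.intensity_scale
        u_true = affinity * scale[z] * (1.0 - beta_z) * cfg.intensity_scale
        lt_m = np.log(np.maximum(m_true, 1e-12))
        lt_u = np.log(np.maximum(u_true, 1e-12))
        center = float(np.median(np.concatenate([lt_m, lt_u])))
        g = _sample_bias_function(cfg.bias_family, coefs[z], center, cfg.bias_width)
        lt_m = lt_m + g(lt_m)
        lt_u = lt_u + g(lt_u)
        # Type II dye bias: opposite sign in the two channels, scaled by the
        # probe's methylation state so the bias is a smooth function of m
        state = 1.0 - 2.0 * beta_z[is_typeII]
        lt_m[is_typeII] += 0.5 * dye_shift[z] * state
        lt_u[is_typeII] -= 0.5 * dye_shift[z] * state
        if cfg.noise_log_sd > 0:
            lt_m = lt_m + rng.normal(0.0, cfg.noise_log_sd, size=n)
            lt_u = lt_u + rng.normal(0.0, cfg.noise_log_sd, size=n)
        if cfg.background_sd > 0:
            bg_m = np.maximum(rng.normal(cfg.background_level, cfg.background_sd, size=n), 0.0)
            bg_u = np.maximum(rng.normal(cfg.background_level, cfg.background_sd, size=n), 0.0)
        else:
            bg_m = bg_u = np.full(n, cfg.background_level)
        M[:, z] = np.exp(lt_m) + bg_m
        U[:, z] = np.exp(lt_u) + bg_u
        bias_rows.append(
            {
                "sample_id": sample_ids[z],
                "family": cfg.bias_family,
                "coef": coefs[z] if cfg.bias_family != "none" else 0.0,
                "center": center,
                "dye_shift": dye_shift[z],
                "scale": scale[z],
            }
        )

    probe_ids = manifest.probe_ids
    sample_meta = pd.DataFrame(
        {
            "individual": [f"I{indiv_of_sample[z] + 1:03d}" for z in range(n_samples)],
            "replicate_pair": [
                f"P{indiv_of_sample[z] + 1:03d}" if indiv_of_sample[z] < n_pairs else ""
                for z in range(n_samples)
            ],
            "sex": [sexes[indiv_of_sample[z]] for z in range(n_samples)],
            "age": [ages[indiv_of_sample[z]] for z in range(n_samples)],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    aset = ArraySet(M, U, manifest, sample_ids, sample_meta)
    truth = SimulationTruth(
        true_beta=true_beta,
        replicate_pairs=pairs,
        differential_probe_ids=[probe_ids[i] for i in diff_idx],
        trait_probe_ids=[probe_ids[i] for i in trait_idx],
        housekeeping_ids=[probe_ids[i] for i in sorted(hk_idx)],
        bias_params=pd.DataFrame(bias_rows).set_index("sample_id"),
        seed=seed,
        config=cfg,
    )
    return aset, truth


# ---------------------------------------------------------------------------
# fixture round trip
# ---------------------------------------------------------------------------

def write_fixture(aset: ArraySet, truth: SimulationTruth, directory: Union[str, Path]) -> dict:
    """Serialize an ArraySet plus its ground truth as delimited text files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = write_array_set(aset, directory)
    paths["housekeeping"] = directory / "housekeeping.txt"
    write_probe_list(truth.housekeeping_ids, paths["housekeeping"], header="housekeeping probes")
    paths["differential"] = directory / "differential_probes.txt"
    write_probe_list(truth.differential_probe_ids, paths["differential"], header="planted differential probes")
    paths["trait_probes"] = directory / "trait_probes.txt"
    write_probe_list(truth.trait_probe_ids, paths["trait_probes"], header="planted trait-associated probes")
    paths["true_beta"] = directory / "true_beta.tsv"
    write_matrix(
        pd.DataFrame(truth.true_beta, index=aset.probe_ids, columns=list(aset.sample_ids)),
        paths["true_beta"],
    )
    paths["bias_params"] = directory / "bias_params.tsv"
    truth.bias_params.to_csv(paths["bias_params"], sep=SEP, float_format="%.10g")
    paths["config"] = directory / "config.txt"
    paths["config"].write_text(truth.config.to_key_value())
    return paths


def read_fixture(directory: Union[str, Path]) -> tuple[ArraySet, SimulationTruth]:
    """Read back a fixture written by :func:`write_fixture`."""
    directory = Path(directory)
    aset = read_array_set(
        directory / "M.tsv",
        directory / "U.tsv",
        directory / "manifest.tsv",
        directory / "samples.tsv",
    )
    cfg = SimulationConfig.from_key_value(directory / "config.txt")
    true_beta = pd.read_csv(directory / "true_beta.tsv", sep=SEP).set_index("probe_id")
    bias = pd.read_csv(directory / "bias_params.tsv", sep=SEP).set_index("sample_id")
    meta = aset.sample_meta
    pairs = []
    if meta is not None and "replicate_pair" in meta.columns:
        labelled = meta[meta["replicate_pair"].fillna("") != ""]
        for _, group in labelled.groupby("replicate_pair", sort=True):
            ids = list(group.index)
            if len(ids) == 2:
                pairs.append((ids[0], ids[1]))
    truth = SimulationTruth(
        true_beta=true_beta.to_numpy(),
        replicate_pairs=pairs,
        differential_probe_ids=read_probe_list(directory / "differential_probes.txt"),
        trait_probe_ids=read_probe_list(directory / "trait_probes.txt"),
        housekeeping_ids=read_probe_list(directory / "housekeeping.txt"),
        bias_params=bias,
        seed=cfg.seed,
        config=cfg,
    )
    return aset, truth
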