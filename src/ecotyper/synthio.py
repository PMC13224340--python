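"""Seeded generator of synthetic seasonal community datasets.

The generator emulates, at desk scale, a near-daily surface-ocean 16S
amplicon time series from a drifting polar platform: ~200 samples over
~11 months with two excised sampling gaps, a heavy-tailed ASV abundance
distribution including planted singletons, a handful of co-varying ASV
modules that track smooth seasonal latent signals (plus one short-lived
"pulse" module), contiguous sample-level ecotype windows, environmental
covariates that co-vary with season, genetic traits (16S copy number,
genome size, GC%, doubling time) tied to module identity, and a sparse
date x COG-category tpm table with planted per-ecotype enrichment.

Every quantity that a downstream stage is later asked to recover is
recorded in :class:`GroundTruth`, so the whole pipeline is testable
without any deposited data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CommunityTable

START_DATE = "2019-10-29"

#: Trait archetypes used to seed per-module means.  Rows cycle if the
#: configured module count exceeds the archetype count.  Columns:
#: doubling_time (h), genome_size (bp), gc_content (%), copy_number.
_TRAIT_ARCHETYPES = np.array(
    [
        [50.0, 1.6e6, 55.0, 1.2],   # winter/dark oligotroph
        [35.0, 2.0e6, 50.0, 1.5],   # spring/light mixed
        [6.0, 4.5e6, 38.0, 8.0],    # bloom-associated copiotroph
        [12.0, 3.5e6, 40.0, 5.0],   # post-bloom degrader
    ]
)
_BACKGROUND_TRAITS = np.array([30.0, 2.5e6, 45.0, 2.0])
_PULSE_TRAITS = np.array([8.0, 4.0e6, 36.0, 7.0])

TRAIT_NAMES = ("doubling_time", "genome_size", "gc_content", "copy_number")

#: COG single-letter category codes used for synthetic functional tables.
COG_LETTERS = "JKLMNOPQTUVWXYZABCDEFGHIRS"


@dataclass
class SynthConfig:
    """Configuration of the synthetic community generator.

    Defaults describe the emulated study conditions: ~200 near-daily
    samples, 800 heavy-tailed ASVs of which 30% are unstructured
    background, four seasonal modules plus a ~2-day pulse module,
    four contiguous ecotype windows, 50,000 reads per sample and 20
    planted singleton ASVs.
    """

    n_samples: int = 200
    n_asvs: int = 800
    n_modules: int = 4
    pulse_module: bool = True
    n_ecotypes: int = 4
    depth: int = 50_000
    noise_sd: float = 0.3
    background_fraction: float = 0.3
    singleton_count: int = 20
    loading_sigma: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_samples", "n_asvs", "n_modules", "n_ecotypes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 <= self.background_fraction < 1.0):
            raise ValueError("background_fraction must lie in [0, 1)")
        if self.depth < 1_000:
            raise ValueError("depth must be >= 1,000 reads per sample")
        if self.noise_sd < 0 or self.loading_sigma < 0:
            raise ValueError("noise scales must be non-negative")
        if self.singleton_count < 0:
            raise ValueError("singleton_count must be >= 0")
        n_structured = self.n_asvs - self.singleton_count
        n_module_asvs = n_structured - int(round(self.background_fraction * n_structured))
        total_modules = self.n_modules + int(self.pulse_module)
        if total_modules > n_module_asvs:
            raise ValueError(
                f"config inconsistency: {total_modules} modules but only "
                f"{n_module_asvs} non-background, non-singleton ASVs"
            )


@dataclass
class GroundTruth:
    """Planted structure of a synthetic dataset.

    ``module_of_asv`` uses 0 for background ASVs (singletons included);
    main modules are 1..n_modules and the pulse module, when present, is
    ``n_modules + 1``.  ``ecotype_of_sample`` uses 1..n_ecotypes with 0
    marking pulse-dominated outlier samples.
    """

    module_of_asv: pd.Series
    is_singleton: pd.Series
    ecotype_of_sample: pd.Series
    latent_signals: pd.DataFrame
    trait_means: pd.DataFrame
    asv_copy_number: pd.Series
    pulse_module_id: int | None = None

    @property
    def n_modules(self) -> int:
        labels = set(self.module_of_asv.unique()) - {0}
        return len(labels)

    def planted_cog_category(self, ecotype: int, n_categories: int) -> str:
        """Category planted as enriched for an ecotype (deterministic)."""
        if ecotype < 1:
            raise ValueError("ecotypes are labelled from 1")
        return COG_LETTERS[(ecotype - 1) % n_categories]


@dataclass
class SynthDataset:
    """Bundle returned by :func:`generate_dataset`."""

    counts: CommunityTable
    metadata: pd.DataFrame
    traits: pd.DataFrame
    truth: GroundTruth
    cog: pd.DataFrame | None = None


def _sample_dates(n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """Consecutive daily offsets with two excised gaps (70 d and 22 d).

    The gap lengths mirror a winter staffing gap and a late-summer ship
    relocation, so ~200 near-daily samples stretch over ~10-11 months.
    Gaps fall in the interiors of the planted ecotype windows (37% and
    87% of the series), not on a window boundary.
    """
    offsets = np.arange(n_samples, dtype=int)
    g1 = int(0.37 * n_samples)
    g2 = int(0.87 * n_samples)
    if g2 > g1 > 0:
        offsets[g1:] += 70
        offsets[g2:] += 22
    return offsets


def _latent_signals(
    offsets: np.ndarray, config: SynthConfig
) -> tuple[np.ndarray, np.ndarray, int | None, np.ndarray]:
    """Module activations over time plus planted ecotype labels.

    Main modules are flat-topped unimodal bumps centred on the
    midpoints of ``n_modules`` equal spans of the observed-sample axis;
    the optional pulse module is a narrow, high-amplitude bump centred
    between two consecutive samples so that exactly two samples are
    pulse-dominated.
    """
    t = offsets - offsets[0]
    # Bumps are parameterized on the observed-sample axis, not calendar
    # days: planted succession stages are contiguous spans of samples,
    # and the excised gaps do not swallow a stage (the generator does
    # not model unobserved dynamics inside a gap).
    n = len(offsets)
    u = np.arange(n, dtype=float)
    centers = (np.arange(config.n_modules) + 0.5) / config.n_modules * n
    width = n / (2.8 * config.n_modules)
    # flat-topped (generalized Gaussian, exponent 4) unimodal bumps:
    # within its window a module is near its plateau, so planted
    # ecotypes are quasi-stationary states separated by fast
    # transitions rather than a continuous drift
    z = (u[:, None] - centers[None, :]) / width
    main = np.exp(-0.5 * z**4)

    # Ecotype truth: when modules and ecotypes correspond one-to-one the
    # planted window of ecotype e is where module e dominates (argmax of
    # the latent signals, contiguous for ordered equal-width bumps);
    # otherwise fall back to equal contiguous day blocks.
    if config.n_ecotypes == config.n_modules:
        ecotype = main.argmax(axis=1) + 1
    else:
        edges = np.linspace(0, n, config.n_ecotypes + 1)
        ecotype = np.clip(np.digitize(u, edges[1:-1]), 0, config.n_ecotypes - 1) + 1

    pulse_id = None
    signals = main
    if config.pulse_module:
        pulse_id = config.n_modules + 1
        center = int(0.62 * n) + 0.5  # midway between two samples
        pulse = 6.0 * np.exp(-0.5 * ((u - center) / 0.6) ** 2)
        signals = np.column_stack([main, pulse])
        outlier = pulse > main.sum(axis=1)
        ecotype[outlier] = 0
    return signals, ecotype, pulse_id, t


def _assign_modules(config: SynthConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Random module assignment: background 0, singletons flagged separately."""
    n = config.n_asvs
    total_modules = config.n_modules + int(config.pulse_module)
    order = rng.permutation(n)
    is_singleton = np.zeros(n, dtype=bool)
    module = np.zeros(n, dtype=int)
    singles = order[: config.singleton_count]
    is_singleton[singles] = True
    structured = order[config.singleton_count :]
    n_background = int(round(config.background_fraction * len(structured)))
    members = structured[n_background:]
    module[members] = (np.arange(len(members)) % total_modules) + 1
    return module, is_singleton


def _trait_means(config: SynthConfig, pulse_id: int | None) -> pd.DataFrame:
    rows = [_BACKGROUND_TRAITS]
    for j in range(config.n_modules):
        rows.append(_TRAIT_ARCHETYPES[j % len(_TRAIT_ARCHETYPES)])
    if pulse_id is not None:
        rows.append(_PULSE_TRAITS)
    index = list(range(len(rows)))
    return pd.DataFrame(np.array(rows), index=index, columns=list(TRAIT_NAMES))


def generate_dataset(config: SynthConfig | None = None) -> SynthDataset:
    """Generate a seeded synthetic community dataset with ground truth.

    Counts are multinomial draws at ``config.depth`` from per-sample
    expected compositions (module latent signal x lognormal ASV loading
    x per-cell lognormal noise, plus a constant background level);
    singleton ASVs are planted explicitly as a single read in one
    rng-chosen sample, with the multinomial depth reduced accordingly so
    every row still sums exactly to ``depth``.  Deterministic for a
    fixed seed.
    """
    config = config or SynthConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    offsets = _sample_dates(config.n_samples, rng)
    dates = pd.to_datetime(START_DATE) + pd.to_timedelta(offsets, unit="D")
    sample_ids = [f"S{i:04d}" for i in range(config.n_samples)]
    asv_ids = [f"ASV{i:05d}" for i in range(config.n_asvs)]

    signals, ecotype, pulse_id, t = _latent_signals(offsets, config)
    module, is_singleton = _assign_modules(config, rng)

    loadings = rng.lognormal(mean=0.0, sigma=config.loading_sigma, size=config.n_asvs)
    # Equalize each module's total loading so every planted window holds
    # a comparable share of sequencing depth; within-module loadings
    # keep their heavy tail.
    target = float(np.exp(config.loading_sigma**2 / 2.0))
    for m in range(1, config.n_modules + int(config.pulse_module) + 1):
        mask = module == m
        if mask.any():
            loadings[mask] *= target * mask.sum() / loadings[mask].sum()
    # Background sits well below the module bump peak (1.0) so that each
    # planted window's most abundant ASVs are dominated by its module.
    background_level = 0.2

    # Expected intensity per (sample, asv) before noise.  Background
    # ASVs get independent slow seasonal wiggles (random-phase annual
    # sinusoids) so they share no planted co-variation beyond the
    # compositional closure every real community table carries.
    n_bg = int((module == 0).sum())
    phase_bg = rng.uniform(0, 2 * np.pi, size=n_bg)
    year = 2 * np.pi * t / 365.0
    wiggle = 1.0 + 0.3 * np.sin(year[:, None] + phase_bg[None, :])
    activity = np.empty((config.n_samples, config.n_asvs))
    activity[:, module == 0] = background_level * wiggle
    for m in range(1, signals.shape[1] + 1):
        mask = module == m
        if mask.any():
            activity[:, mask] = signals[:, m - 1][:, None]
    intensity = activity * loadings[None, :]
    if config.noise_sd > 0:
        intensity = intensity * np.exp(
            config.noise_sd * rng.standard_normal(intensity.shape)
        )
    intensity[:, is_singleton] = 0.0

    # Singletons: one read in one host sample each.
    host = rng.integers(0, config.n_samples, size=int(is_singleton.sum()))
    singleton_idx = np.flatnonzero(is_singleton)
    per_sample_singletons = np.bincount(host, minlength=config.n_samples)

    counts = np.zeros((config.n_samples, config.n_asvs), dtype=np.int64)
    for s in range(config.n_samples):
        p = intensity[s]
        p = p / p.sum()
        counts[s] = rng.multinomial(config.depth - per_sample_singletons[s], p)
    counts[host, singleton_idx] += 1

    counts_df = pd.DataFrame(counts, index=sample_ids, columns=asv_ids)

    # Environmental covariates: smooth seasonal functions of date + noise.
    span = max(t[-1], 1)
    phase = 2 * np.pi * t / 365.0
    metadata = pd.DataFrame(
        {
            "date": dates.strftime("%Y-%m-%d"),
            "numeric_month": dates.month + (dates.day - 1) / 31.0,
            "latitude": np.clip(
                89.0 - 10.0 * t / span + 0.4 * np.sin(3 * phase) + 0.1 * rng.standard_normal(len(t)),
                -90,
                90,
            ),
            "longitude": 120.0 - 90.0 * t / span + 3.0 * np.sin(2 * phase) + 0.5 * rng.standard_normal(len(t)),
            "temperature": -1.6 + 1.4 * np.clip(np.sin(phase - 1.8), -1, 1) ** 3 + 0.08 * rng.standard_normal(len(t)),
            "salinity": 33.0 - 1.5 * np.exp(-0.5 * ((t - 0.65 * span) / (0.08 * span)) ** 2) + 0.1 * rng.standard_normal(len(t)),
        },
        index=sample_ids,
    )

    trait_means = _trait_means(config, pulse_id)

    # Per-sample traits: abundance-weighted module trait means + noise.
    rel = counts / counts.sum(axis=1, keepdims=True)
    n_groups = trait_means.shape[0]
    weights = np.zeros((config.n_samples, n_groups))
    for g in range(n_groups):
        mask = module == g
        if mask.any():
            weights[:, g] = rel[:, mask].sum(axis=1)
    weights = weights / weights.sum(axis=1, keepdims=True)
    sample_traits = weights @ trait_means.to_numpy()
    sample_traits = sample_traits * np.exp(0.03 * rng.standard_normal(sample_traits.shape))
    traits = pd.DataFrame(sample_traits, index=sample_ids, columns=list(TRAIT_NAMES))
    traits["gc_content"] = traits["gc_content"].clip(1.0, 99.0)

    # Chlorophyll-a tracks the fastest-growing (bloom) main module.
    bloom = int(trait_means.iloc[1 : config.n_modules + 1]["doubling_time"].idxmin())
    chl = 0.05 + 2.0 * signals[:, bloom - 1] + 0.05 * np.abs(rng.standard_normal(len(t)))
    metadata["chlorophyll_a"] = chl
    metadata = metadata[
        ["date", "numeric_month", "latitude", "longitude", "temperature", "salinity", "chlorophyll_a"]
    ]

    asv_copy = trait_means["copy_number"].to_numpy()[module] * np.exp(
        0.1 * rng.standard_normal(config.n_asvs)
    )

    module_cols = [f"module_{m}" for m in range(1, config.n_modules + 1)]
    if pulse_id is not None:
        module_cols.append(f"pulse_{pulse_id}")
    truth = GroundTruth(
        module_of_asv=pd.Series(module, index=asv_ids, name="module"),
        is_singleton=pd.Series(is_singleton, index=asv_ids, name="is_singleton"),
        ecotype_of_sample=pd.Series(ecotype, index=sample_ids, name="ecotype"),
        latent_signals=pd.DataFrame(signals, index=sample_ids, columns=module_cols),
        trait_means=trait_means,
        asv_copy_number=pd.Series(asv_copy, index=asv_ids, name="copy_number"),
        pulse_module_id=pulse_id,
    )
    return SynthDataset(
        counts=CommunityTable(counts_df, state="raw"),
        metadata=metadata,
        traits=traits,
        truth=truth,
    )


def generate_cog_table(
    truth: GroundTruth,
    metadata: pd.DataFrame,
    n_categories: int = 10,
    effect: float = 5.0,
    seed: int = 0,
    every: int = 12,
) -> pd.DataFrame:
    """Sparse date x COG-category tpm table with planted enrichment.

    One row per ``every``-th sample (emulating a small number of
    metagenome-matched dates).  Each ecotype ``e`` has one planted
    enriched category, ``COG_LETTERS[(e-1) % n_categories]``, whose base
    intensity is multiplied by ``effect`` on that ecotype's dates.  Rows
    are normalized to 1e6 tpm.  Outlier samples (ecotype 0) receive no
    enrichment.
    """
    if n_categories < 4:
        raise ValueError("n_categories must be >= 4")
    rng = np.random.default_rng(seed)
    categories = list(COG_LETTERS[:n_categories])
    rows = np.arange(0, len(metadata), every)
    sample_ids = metadata.index[rows]
    ecotypes = truth.ecotype_of_sample.loc[sample_ids].to_numpy()
    base = rng.lognormal(mean=0.0, sigma=0.3, size=n_categories)

    values = np.empty((len(rows), n_categories))
    for i, e in enumerate(ecotypes):
        row = base * np.exp(0.2 * rng.standard_normal(n_categories))
        if e >= 1:
            row[(e - 1) % n_categories] *= effect
        values[i] = row / row.sum() * 1e6
    dates = metadata.loc[sample_ids, "date"]
    return pd.DataFrame(values, index=pd.Index(dates, name="date"), columns=categories)


# ---------------------------------------------------------------------------
# Fixture round-trip
# ---------------------------------------------------------------------------

_FILES = {
    "counts": "counts.tsv",
    "metadata": "metadata.tsv",
    "traits": "traits.tsv",
    "cog": "cog.tsv",
    "asv_truth": "truth_asvs.tsv",
    "sample_truth": "truth_samples.tsv",
    "latent": "truth_latent.tsv",
    "trait_means": "truth_trait_means.tsv",
}


def write_fixtures(dataset: SynthDataset, directory: str | Path) -> dict[str, Path]:
    """Write a dataset to plain TSV files; returns the path map.

    The files round-trip bit-identically through :func:`read_fixtures`.
    """
    from . import io as tio

    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"output directory does not exist: {directory}")
    paths = {k: directory / v for k, v in _FILES.items()}
    tio.write_community_table(dataset.counts, paths["counts"])
    tio.write_frame(dataset.metadata, paths["metadata"])
    tio.write_frame(dataset.traits, paths["traits"])
    if dataset.cog is not None:
        tio.write_frame(dataset.cog, paths["cog"], index_name="date")
    truth = dataset.truth
    asv_truth = pd.DataFrame(
        {
            "module": truth.module_of_asv,
            "is_singleton": truth.is_singleton.astype(int),
            "copy_number": truth.asv_copy_number,
        }
    )
    tio.write_frame(asv_truth, paths["asv_truth"], index_name="asv_id")
    sample_truth = pd.DataFrame({"ecotype": truth.ecotype_of_sample})
    tio.write_frame(sample_truth, paths["sample_truth"])
    tio.write_frame(truth.latent_signals, paths["latent"])
    tio.write_frame(truth.trait_means, paths["trait_means"], index_name="module")
    return paths


def read_fixtures(directory: str | Path) -> SynthDataset:
    """Reload a dataset written by :func:`write_fixtures`."""
    from . import io as tio

    directory = Path(directory)
    counts = tio.read_community_table(directory / _FILES["counts"], state="raw")
    metadata = tio.read_frame(directory / _FILES["metadata"])
    traits = tio.read_frame(directory / _FILES["traits"])
    cog_path = directory / _FILES["cog"]
    cog = tio.read_frame(cog_path) if cog_path.is_file() else None
    if cog is not None:
        cog.index.name = "date"
    asv_truth = tio.read_frame(directory / _FILES["asv_truth"])
    sample_truth = tio.read_frame(directory / _FILES["sample_truth"])
    latent = tio.read_frame(directory / _FILES["latent"])
    trait_means = tio.read_frame(directory / _FILES["trait_means"])
    last = latent.columns[-1]
    pulse_id = int(last.split("_")[1]) if last.startswith("pulse_") else None
    truth = GroundTruth(
        module_of_asv=asv_truth["module"].rename("module"),
        is_singleton=asv_truth["is_singleton"].astype(bool).rename("is_singleton"),
        ecotype_of_sample=sample_truth["ecotype"].rename("ecotype"),
        latent_signals=latent,
        trait_means=trait_means,
        asv_copy_number=asv_truth["copy_number"].rename("copy_number"),
        pulse_module_id=pulse_id,
    )
    return SynthDataset(counts=counts, metadata=metadata, traits=traits, truth=truth, cog=cog)
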