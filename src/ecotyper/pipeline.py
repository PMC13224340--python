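"""End-to-end orchestration: simulate -> preprocess -> segment -> qualify.

:func:`run_all` wires the full chain together with a single seed:
synthetic data generation, the normalization chain, the three
segmentation routes (PCoA + k-means, toroidal hex SOM + k-means,
signed TOM network + hybrid k-means with eigengene merging), PERMANOVA
validation of the sample clusterings, and the ecotype qualification
rule.  Per-stage wall times and the chosen parameters are logged via
the standard :mod:`logging` machinery.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cluster_select, ecotypes, group_stats, network, ordination, preprocess, som
from .containers import CommunityTable
from .synthio import SynthConfig, SynthDataset, generate_cog_table, generate_dataset

logger = logging.getLogger("ecotyper")


@dataclass
class PipelineConfig:
    """Knobs of the full pipeline (generator config passed separately)."""

    cog_effect: float = 5.0
    cog_categories: int = 10
    n_axes: int = 3
    k_range: tuple[int, int] = (2, 8)
    module_k_range: tuple[int, int] = (2, 10)
    som_rows: int = 4
    som_cols: int = 4
    som_toroidal: bool = True
    som_rlen: int = 100
    network_keep: int | None = None  # default: top 90% of surviving ASVs
    beta: float = 8.0
    merge_threshold: float = 0.7
    n_permutations: int = 999
    ecotype: ecotypes.EcotypeConfig = field(default_factory=ecotypes.EcotypeConfig)


@dataclass
class PipelineResult:
    dataset: SynthDataset
    hellinger_table: CommunityTable
    rel_table: CommunityTable
    pcoa_ordination: ordination.Ordination
    labels: dict[str, pd.Series]
    k_reports: dict[str, cluster_select.KSelectionReport]
    som_model: som.SOMModel
    som_mapping: som.SOMMapping
    network_model: network.NetworkModel
    module_labels: pd.Series
    eigengenes: pd.DataFrame
    module_trait_r: pd.DataFrame
    module_trait_p: pd.DataFrame
    kme: pd.DataFrame
    permanova: dict[str, group_stats.PermanovaResult]
    report: ecotypes.EcotypeReport
    summary: pd.DataFrame
    timings: dict[str, float] = field(default_factory=dict)


def _tick(timings: dict, name: str, t0: float) -> float:
    t1 = time.perf_counter()
    timings[name] = t1 - t0
    logger.info("stage %-12s %6.2f s", name, timings[name])
    return t1


def preprocess_chain(dataset: SynthDataset) -> tuple[CommunityTable, CommunityTable]:
    """raw -> drop singletons -> copy-number -> relative -> hellinger."""
    no_singletons = preprocess.drop_singletons(dataset.counts)
    corrected = preprocess.normalize_copy_number(
        no_singletons, dataset.truth.asv_copy_number
    )
    rel = preprocess.relative_abundance(corrected)
    hel = preprocess.hellinger(rel)
    return rel, hel


def run_all(
    seed: int = 0,
    synth_config: SynthConfig | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full pipeline on a synthetic dataset; see module docs."""
    config = config or PipelineConfig()
    synth_config = synth_config or SynthConfig(seed=seed)
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    dataset = generate_dataset(synth_config)
    dataset.cog = generate_cog_table(
        dataset.truth, dataset.metadata, n_categories=config.cog_categories,
        effect=config.cog_effect, seed=seed + 1,
    )
    t0 = _tick(timings, "simulate", t0)

    rel, hel = preprocess_chain(dataset)
    t0 = _tick(timings, "preprocess", t0)

    labels: dict[str, pd.Series] = {}
    k_reports: dict[str, cluster_select.KSelectionReport] = {}

    # --- PCoA + k-means -------------------------------------------------
    dist = ordination.pairwise_distance(hel, metric="euclidean")
    ord_pcoa = ordination.pcoa(dist, n_axes=config.n_axes)
    coords = ord_pcoa.coordinates.to_numpy()
    k_lo, k_hi = config.k_range
    rep = cluster_select.k_diagnostics(coords, range(k_lo, k_hi + 1), seed=seed + 2)
    k_pcoa = cluster_select.choose_k(rep)
    sol = cluster_select.kmeans_fit(coords, k_pcoa, seed=seed + 2)
    labels["pcoa"] = pd.Series(sol.labels, index=hel.sample_ids, name="pcoa")
    k_reports["pcoa"] = rep
    t0 = _tick(timings, "pcoa", t0)

    # --- SOM + k-means ---------------------------------------------------
    grid = som.build_grid(config.som_rows, config.som_cols, toroidal=config.som_toroidal)
    som_model = som.train_som(hel.values, grid, rlen=config.som_rlen, seed=seed + 3)
    mapping = som.map_samples(som_model, hel.values)
    # cluster the occupied map units' codebook vectors and carry each
    # sample's label over from its BMU; the k diagnostics are evaluated
    # on the samples themselves (per-sample BMU rows are duplicated
    # points, which would inflate a unit-free silhouette)
    occupied = np.flatnonzero(mapping.occupancy > 0)
    unit_vectors = som_model.codebook[occupied]
    k_hi_som = min(k_hi, len(occupied) - 1)
    x = hel.values
    ks, wss_list, sil_list, unit_solutions = [], [], [], {}
    for k in range(k_lo, k_hi_som + 1):
        sol = cluster_select.kmeans_fit(unit_vectors, k, seed=seed + 3)
        unit_label = dict(zip(occupied, sol.labels))
        sample_labels = np.array([unit_label[b] for b in mapping.bmu])
        wss = 0.0
        for c in np.unique(sample_labels):
            sub = x[sample_labels == c]
            wss += float(((sub - sub.mean(axis=0)) ** 2).sum())
        s, _ = cluster_select.mean_silhouette(x, sample_labels)
        ks.append(k)
        wss_list.append(wss)
        sil_list.append(s)
        unit_solutions[k] = sample_labels
    rep = cluster_select.KSelectionReport(k_values=ks, wss=wss_list, mean_silhouette=sil_list)
    k_som = cluster_select.choose_k(rep)
    labels["som"] = pd.Series(unit_solutions[k_som], index=hel.sample_ids, name="som")
    k_reports["som"] = rep
    t0 = _tick(timings, "som", t0)

    # --- signed network + hybrid k-means ---------------------------------
    if config.network_keep is None:
        n_keep = int(np.ceil(0.9 * hel.n_asvs))
    else:
        n_keep = min(config.network_keep, hel.n_asvs)
    qc_table, qc_report = preprocess.network_qc(hel, n_keep=n_keep)
    net = network.signed_adjacency(qc_table, beta=config.beta)
    network.tom(net)
    mk_lo, mk_hi = config.module_k_range
    mod_rep = cluster_select.k_diagnostics(
        net.diss_tom, range(mk_lo, mk_hi + 1), seed=seed + 4
    )
    k_mod = cluster_select.choose_k(mod_rep)
    raw_modules = network.detect_modules(net, k_mod, seed=seed + 4)
    module_labels, eigengenes = network.merge_modules(
        qc_table, raw_modules, merge_threshold=config.merge_threshold
    )
    k_reports["module"] = mod_rep

    trait_frame = dataset.traits.copy()
    trait_frame["chlorophyll_a"] = dataset.metadata["chlorophyll_a"]
    trait_frame = trait_frame.loc[qc_table.sample_ids]
    kme, mt_r, mt_p, _gs = network.kme_and_trait_stats(qc_table, eigengenes, trait_frame)
    net.module_labels = module_labels
    net.eigengenes = eigengenes
    net.kme = kme
    net.trait_correlations = mt_r
    net.trait_pvalues = mt_p
    t0 = _tick(timings, "network", t0)

    # --- cluster validation ----------------------------------------------
    perm: dict[str, group_stats.PermanovaResult] = {}
    for method, lab in labels.items():
        sizes = lab.value_counts()
        if (sizes >= 2).sum() >= 2:
            usable = lab[lab.isin(sizes.index[sizes >= 2])]
            sub = dist.matrix[np.ix_(
                [hel.sample_ids.index(s) for s in usable.index],
                [hel.sample_ids.index(s) for s in usable.index],
            )]
            from .containers import DistanceMatrix
            perm[method] = group_stats.permanova(
                DistanceMatrix(sub, ids=list(usable.index), metric=dist.metric),
                usable.to_numpy(), n_permutations=config.n_permutations, seed=seed + 5,
            )
    t0 = _tick(timings, "permanova", t0)

    # --- ecotype qualification -------------------------------------------
    dates = pd.to_datetime(dataset.metadata["date"])
    report = ecotypes.qualify_ecotypes(
        sample_methods=labels,
        dates=dates,
        traits=dataset.traits,
        rel_table=rel,
        module_labels=module_labels,
        module_trait_p=mt_p,
        cog=dataset.cog,
        config=config.ecotype,
    )
    summary = ecotypes.render_report(report, dataset.traits, rel_table=rel)
    _tick(timings, "ecotypes", t0)

    return PipelineResult(
        dataset=dataset, hellinger_table=hel, rel_table=rel,
        pcoa_ordination=ord_pcoa, labels=labels, k_reports=k_reports,
        som_model=som_model, som_mapping=mapping, network_model=net,
        module_labels=module_labels, eigengenes=eigengenes,
        module_trait_r=mt_r, module_trait_p=mt_p, kme=kme,
        permanova=perm, report=report, summary=summary, timings=timings,
    )
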