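"""Cross-method integration and the ecotype qualification rule.

Each cluster produced by a sample-based method (PCoA + k-means,
SOM + k-means) and each co-abundance module is a *candidate* ecotype.
A candidate qualifies as a functional ecotype when:

1. ``trait_distinct`` (sample methods): for at least one inferred
   genetic trait (default: doubling time, genome size) the candidate
   differs from *every* other cluster of the same method in a pairwise
   rank-sum test (adjusted p < alpha); or
   ``module_trait_correlated`` (modules): the module eigengene is
   significantly correlated (p < alpha) with at least 2 physiological
   variables;
2. ``composition_distinct``: the candidate's top-25 most abundant ASVs
   overlap the temporally adjacent dominant clusters' top-25 with a
   Jaccard index below 0.5; and
3. ``cog_validated``: at least one COG category whose scaled functional
   profile is >= 0.75 for the candidate while <= 0.5 for all temporally
   adjacent clusters (skipped with a warning when the candidate has no
   metagenome-matched dates).

Candidates supported by fewer than ``min_samples`` samples are rejected
outright with reason ``"insufficient support"`` — a two-sample cluster
cannot support trait statistics, however distinct it looks.

Qualified candidates from different methods whose time windows overlap
are grouped into a single ecotype described by the span its
representatives occupy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CommunityTable
from .group_stats import pairwise_wilcoxon


@dataclass
class EcotypeConfig:
    min_samples: int = 3
    alpha: float = 0.05
    top_n: int = 25
    jaccard_threshold: float = 0.5
    profile_hi: float = 0.75
    profile_lo: float = 0.5
    trait_candidates: tuple = ("doubling_time", "genome_size")
    module_trait_vars: tuple = (
        "copy_number", "doubling_time", "genome_size", "gc_content", "chlorophyll_a",
    )
    min_module_trait: int = 2
    overlap_fraction: float = 0.5
    gap_factor: float = 3.0


# ---------------------------------------------------------------------------
# Timelines
# ---------------------------------------------------------------------------

@dataclass
class TimelineRun:
    label: int
    start: pd.Timestamp
    end: pd.Timestamp
    sample_ids: list[str]


def cluster_timeline(
    labels: pd.Series, dates: pd.Series, gap_factor: float = 3.0
) -> list[TimelineRun]:
    """Runs of consecutive dates sharing a label; large date gaps break runs.

    A gap counts as "large" when it exceeds ``gap_factor`` times the
    median sampling interval.
    """
    dates = pd.to_datetime(dates.loc[labels.index])
    order = dates.sort_values().index
    dates = dates.loc[order]
    labels = labels.loc[order]
    diffs = dates.diff().dt.days.dropna()
    median_step = float(diffs.median()) if len(diffs) else 1.0
    gap_days = gap_factor * max(median_step, 1.0)

    runs: list[TimelineRun] = []
    current: list[str] = []
    for i, sid in enumerate(order):
        if current:
            prev = current[-1]
            same = labels[sid] == labels[prev]
            close = (dates[sid] - dates[prev]).days <= gap_days
            if same and close:
                current.append(sid)
                continue
            runs.append(TimelineRun(int(labels[prev]), dates[current[0]],
                                    dates[prev], list(current)))
        current = [sid]
    if current:
        runs.append(TimelineRun(int(labels[current[-1]]), dates[current[0]],
                                dates[current[-1]], list(current)))
    return runs


def dominant_module_per_date(
    rel_table: CommunityTable, module_labels: pd.Series
) -> pd.Series:
    """Per sample, the module with the largest summed relative abundance.

    Mirrors the construction of module abundance timelines: the
    relative abundances of all ASVs assigned to each module are summed
    per sampling date; background (label 0) ASVs are ignored.
    """
    if rel_table.state not in ("relative", "hellinger"):
        raise ValueError("dominant_module_per_date expects relative abundances")
    sums = {}
    for m in sorted(set(module_labels) - {0}):
        members = [a for a in rel_table.asv_ids if module_labels.get(a, 0) == m]
        sums[m] = rel_table.data[members].sum(axis=1)
    frame = pd.DataFrame(sums)
    return frame.idxmax(axis=1).astype(int)


# ---------------------------------------------------------------------------
# COG profiles
# ---------------------------------------------------------------------------

def cog_profile(
    cog: pd.DataFrame, cluster_per_date: pd.Series
) -> tuple[pd.DataFrame, list[str]]:
    """Per-cluster scaled functional profiles from a date x category table.

    Each category is z-scored across dates and then min-max rescaled to
    [0, 1]; the cluster profile is the mean scaled value over its
    dates.  Categories that are constant across dates are uninformative
    (set to 0.5) and returned in the flagged list.
    """
    missing = [d for d in cog.index if d not in cluster_per_date.index]
    if missing:
        raise ValueError(f"COG dates without a cluster assignment: {missing[:5]}")
    values = cog.to_numpy(dtype=float)
    flagged = []
    scaled = np.empty_like(values)
    for j, cat in enumerate(cog.columns):
        col = values[:, j]
        if np.ptp(col) == 0:
            scaled[:, j] = 0.5
            flagged.append(cat)
            continue
        z = (col - col.mean()) / col.std()
        scaled[:, j] = (z - z.min()) / (z.max() - z.min())
    scaled_df = pd.DataFrame(scaled, index=cog.index, columns=cog.columns)
    clusters = cluster_per_date.loc[cog.index]
    profiles = scaled_df.groupby(clusters.to_numpy()).mean()
    profiles.index.name = "cluster"
    return profiles, flagged


# ---------------------------------------------------------------------------
# Qualification
# ---------------------------------------------------------------------------

@dataclass
class Criterion:
    passed: bool
    evidence: str
    applicable: bool = True


@dataclass
class EcotypeRecord:
    method: str
    cluster_id: int
    sample_ids: list[str]
    windows: list[tuple[pd.Timestamp, pd.Timestamp]]
    criteria: dict = field(default_factory=dict)
    qualified: bool = False
    reject_reason: str | None = None


@dataclass
class EcotypeGroup:
    name: str
    members: list[EcotypeRecord]
    start: pd.Timestamp
    end: pd.Timestamp
    sample_ids: list[str]

    @property
    def representatives(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for rec in self.members:
            out.setdefault(rec.method, []).append(rec.cluster_id)
        return out


@dataclass
class EcotypeReport:
    ecotypes: list[EcotypeGroup]
    candidates: list[EcotypeRecord]

    @property
    def rejected(self) -> list[EcotypeRecord]:
        return [c for c in self.candidates if not c.qualified]


def _top_asvs(rel: CommunityTable, sample_ids: list[str], top_n: int) -> set[str]:
    means = rel.data.loc[sample_ids].mean(axis=0)
    return set(means.sort_values(ascending=False).index[:top_n])


def _adjacent_labels(runs: list[TimelineRun], cluster_id: int) -> set[int]:
    """Labels of the runs immediately before/after each of the cluster's runs."""
    adjacent: set[int] = set()
    for i, run in enumerate(runs):
        if run.label != cluster_id:
            continue
        if i > 0:
            adjacent.add(runs[i - 1].label)
        if i + 1 < len(runs):
            adjacent.add(runs[i + 1].label)
    adjacent.discard(cluster_id)
    return adjacent


def _trait_distinct(
    labels: pd.Series, traits: pd.DataFrame, cluster_id: int, config: EcotypeConfig
) -> Criterion:
    """Pairwise rank-sum vs every other (testable) cluster, any one trait."""
    sizes = labels.value_counts()
    testable = [c for c in sizes.index if sizes[c] >= 2]
    others = [c for c in testable if c != cluster_id]
    if cluster_id not in testable or not others:
        return Criterion(False, "no testable comparison clusters")
    mask = labels.isin(testable)
    details = []
    for trait in config.trait_candidates:
        res = pairwise_wilcoxon(
            traits.loc[mask.index[mask], trait].to_numpy(),
            labels[mask].to_numpy(),
            adjust="holm",
        )
        tab = res.pairwise
        ours = tab[(tab["group1"] == cluster_id) | (tab["group2"] == cluster_id)]
        if len(ours) == len(others) and (ours["p_adjusted"] < config.alpha).all():
            details.append(trait)
    if details:
        return Criterion(True, f"distinct from all clusters in: {', '.join(details)}")
    return Criterion(False, "no trait separates this cluster from all others")


def _composition_distinct(
    rel: CommunityTable,
    runs: list[TimelineRun],
    cluster_id: int,
    sample_ids: list[str],
    config: EcotypeConfig,
) -> Criterion:
    top = _top_asvs(rel, sample_ids, config.top_n)
    adjacent = _adjacent_labels(runs, cluster_id)
    if not adjacent:
        return Criterion(True, "no temporally adjacent cluster")
    overlaps = {}
    for other in adjacent:
        other_samples = [s for r in runs if r.label == other for s in r.sample_ids]
        other_top = _top_asvs(rel, other_samples, config.top_n)
        union = top | other_top
        overlaps[other] = len(top & other_top) / len(union) if union else 0.0
    worst = max(overlaps.values())
    passed = worst < config.jaccard_threshold
    ev = "; ".join(f"vs {o}: J={v:.2f}" for o, v in sorted(overlaps.items()))
    return Criterion(passed, ev)


def _cog_validated(
    profiles: pd.DataFrame | None,
    runs: list[TimelineRun],
    cluster_id: int,
    config: EcotypeConfig,
) -> Criterion:
    if profiles is None or cluster_id not in profiles.index:
        warnings.warn(
            f"cluster {cluster_id}: no metagenome-matched dates; COG criterion skipped",
            stacklevel=2,
        )
        return Criterion(True, "skipped: no metagenome-matched dates", applicable=False)
    adjacent = [a for a in _adjacent_labels(runs, cluster_id) if a in profiles.index]
    ours = profiles.loc[cluster_id]
    hits = []
    for cat in profiles.columns:
        if ours[cat] < config.profile_hi:
            continue
        if all(profiles.loc[a, cat] <= config.profile_lo for a in adjacent):
            hits.append(cat)
    if hits:
        return Criterion(True, f"enriched categories: {', '.join(hits)}")
    return Criterion(False, "no category enriched relative to adjacent clusters")


def _evaluate_candidate(
    method: str,
    cluster_id: int,
    labels: pd.Series,
    dates: pd.Series,
    traits: pd.DataFrame,
    rel: CommunityTable,
    profiles: pd.DataFrame | None,
    config: EcotypeConfig,
    module_trait_p: pd.DataFrame | None = None,
) -> EcotypeRecord:
    runs = cluster_timeline(labels, dates, gap_factor=config.gap_factor)
    own_runs = [r for r in runs if r.label == cluster_id]
    sample_ids = [s for r in own_runs for s in r.sample_ids]
    windows = [(r.start, r.end) for r in own_runs]
    rec = EcotypeRecord(method=method, cluster_id=cluster_id,
                        sample_ids=sample_ids, windows=windows)
    if len(sample_ids) < config.min_samples:
        rec.reject_reason = "insufficient support"
        rec.criteria["support"] = Criterion(
            False, f"only {len(sample_ids)} samples (< {config.min_samples})"
        )
        return rec

    if module_trait_p is not None:
        key = f"ME{cluster_id}"
        if key in module_trait_p.index:
            pvals = module_trait_p.loc[key, [v for v in config.module_trait_vars
                                             if v in module_trait_p.columns]]
            sig = pvals[pvals < config.alpha]
            rec.criteria["module_trait_correlated"] = Criterion(
                len(sig) >= config.min_module_trait,
                f"significant with {len(sig)} variables: {', '.join(sig.index)}",
            )
        else:
            rec.criteria["module_trait_correlated"] = Criterion(False, "module has no eigengene")
        rec.criteria["trait_distinct"] = Criterion(False, "not applicable to modules",
                                                   applicable=False)
    else:
        rec.criteria["trait_distinct"] = _trait_distinct(labels, traits, cluster_id, config)
        rec.criteria["module_trait_correlated"] = Criterion(
            False, "not applicable to sample clusters", applicable=False
        )

    rec.criteria["composition_distinct"] = _composition_distinct(
        rel, runs, cluster_id, sample_ids, config
    )
    rec.criteria["cog_validated"] = _cog_validated(profiles, runs, cluster_id, config)

    trait_ok = (rec.criteria["trait_distinct"].passed
                or rec.criteria["module_trait_correlated"].passed)
    rec.qualified = (trait_ok
                     and rec.criteria["composition_distinct"].passed
                     and rec.criteria["cog_validated"].passed)
    if not rec.qualified and rec.reject_reason is None:
        failing = [k for k, c in rec.criteria.items() if c.applicable and not c.passed]
        rec.reject_reason = "failed: " + ", ".join(failing)
    return rec


def _group_candidates(
    qualified: list[EcotypeRecord], dates: pd.Series, overlap_fraction: float
) -> list[EcotypeGroup]:
    """Union-find grouping of qualified candidates by sample-set overlap."""
    n = len(qualified)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    sets = [set(r.sample_ids) for r in qualified]
    for i in range(n):
        for j in range(i + 1, n):
            if not sets[i] or not sets[j]:
                continue
            frac = len(sets[i] & sets[j]) / min(len(sets[i]), len(sets[j]))
            if frac >= overlap_fraction:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    dates = pd.to_datetime(dates)
    out = []
    for members_idx in groups.values():
        members = [qualified[i] for i in members_idx]
        # a sample belongs to the ecotype if at least half the member
        # candidates include it
        votes: dict[str, int] = {}
        for rec in members:
            for s in rec.sample_ids:
                votes[s] = votes.get(s, 0) + 1
        need = max(1, int(np.ceil(len(members) / 2)))
        core = [s for s, v in votes.items() if v >= need]
        core_dates = dates.loc[core]
        out.append(EcotypeGroup(
            name="",
            members=members,
            start=core_dates.min(),
            end=core_dates.max(),
            sample_ids=sorted(core, key=lambda s: dates.loc[s]),
        ))
    out.sort(key=lambda g: g.start)
    for i, g in enumerate(out):
        g.name = f"Ecotype{i + 1}"
    return out


def qualify_ecotypes(
    sample_methods: dict[str, pd.Series],
    dates: pd.Series,
    traits: pd.DataFrame,
    rel_table: CommunityTable,
    module_labels: pd.Series | None = None,
    module_trait_p: pd.DataFrame | None = None,
    cog: pd.DataFrame | None = None,
    config: EcotypeConfig | None = None,
) -> EcotypeReport:
    """Evaluate every cluster/module candidate and group the qualified ones.

    ``sample_methods`` maps a method name (e.g. ``"pcoa"``, ``"som"``)
    to 1-based per-sample cluster labels.  ``dates`` is an ISO-8601 (or
    datetime) series per sample.  ``cog`` is an optional date x COG
    category table whose dates must be a subset of the sample dates.
    """
    config = config or EcotypeConfig()
    dates = pd.to_datetime(dates)
    for name, labels in sample_methods.items():
        if not labels.index.equals(traits.index):
            raise ValueError(f"labels for {name!r} are not aligned with traits")
    date_of_sample = dates.copy()
    date_str = date_of_sample.dt.strftime("%Y-%m-%d")

    candidates: list[EcotypeRecord] = []

    def _profiles_for(labels: pd.Series) -> pd.DataFrame | None:
        if cog is None:
            return None
        lookup = pd.Series(labels.to_numpy(), index=date_str.to_numpy())
        lookup = lookup[~lookup.index.duplicated()]
        per_date = lookup.reindex(cog.index)
        if per_date.isna().any():
            raise ValueError("COG dates do not all match sample dates")
        profiles, _ = cog_profile(cog, per_date)
        return profiles

    for method, labels in sample_methods.items():
        profiles = _profiles_for(labels)
        for cluster_id in sorted(labels.unique()):
            candidates.append(_evaluate_candidate(
                method, int(cluster_id), labels, dates, traits, rel_table,
                profiles, config,
            ))

    if module_labels is not None:
        dominant = dominant_module_per_date(rel_table, module_labels)
        profiles = _profiles_for(dominant)
        for module_id in sorted(dominant.unique()):
            candidates.append(_evaluate_candidate(
                "module", int(module_id), dominant, dates, traits, rel_table,
                profiles, config, module_trait_p=module_trait_p,
            ))

    qualified = [c for c in candidates if c.qualified]
    groups = _group_candidates(qualified, dates, config.overlap_fraction)
    return EcotypeReport(ecotypes=groups, candidates=candidates)


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

def render_report(
    report: EcotypeReport,
    traits: pd.DataFrame,
    rel_table: CommunityTable | None = None,
    top_taxa: int = 5,
) -> pd.DataFrame:
    """Summary table: one row per qualified ecotype.

    Growth-rate ranks are 1..n by ascending median doubling time
    (1 = fastest); genome-size classes compare the ecotype median to
    the overall median (Large vs Streamlined).  An empty report yields
    an empty frame.
    """
    if not report.ecotypes:
        return pd.DataFrame(columns=[
            "ecotype", "window", "growth_rank", "genome_class",
            "top_asvs", "enriched_cog", "representatives",
        ]).set_index("ecotype")
    overall_genome = float(traits["genome_size"].median())
    rows = []
    medians = {}
    for g in report.ecotypes:
        medians[g.name] = float(traits.loc[g.sample_ids, "doubling_time"].median())
    rank_order = sorted(medians, key=medians.get)
    rank = {name: i + 1 for i, name in enumerate(rank_order)}
    for g in report.ecotypes:
        genome = float(traits.loc[g.sample_ids, "genome_size"].median())
        top = []
        if rel_table is not None:
            top = sorted(_top_asvs(rel_table, g.sample_ids, top_taxa))
        enriched: list[str] = []
        for rec in g.members:
            crit = rec.criteria.get("cog_validated")
            if crit and crit.passed and crit.evidence.startswith("enriched categories: "):
                enriched.extend(crit.evidence.split(": ", 1)[1].split(", "))
        reps = "; ".join(f"{m}: {sorted(ids)}" for m, ids in sorted(g.representatives.items()))
        rows.append({
            "ecotype": g.name,
            "window": f"{g.start.date()} to {g.end.date()}",
            "growth_rank": rank[g.name],
            "genome_class": "Large" if genome >= overall_genome else "Streamlined",
            "top_asvs": ", ".join(top),
            "enriched_cog": ", ".join(sorted(set(enriched))),
            "representatives": reps,
        })
    return pd.DataFrame(rows).set_index("ecotype")


def report_to_markdown(table: pd.DataFrame) -> str:
    """Render the summary table as a GitHub-style markdown table."""
    cols = ["ecotype"] + list(table.columns)
    lines = ["| " + " | ".join(cols) + " |",
             "| " + " | ".join("---" for _ in cols) + " |"]
    for name, row in table.iterrows():
        cells = [str(name)] + [str(row[c]) for c in table.columns]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"
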