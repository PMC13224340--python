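"""Normalization and filtering from raw counts to analysis-ready matrices.

The canonical chain is::

    raw counts -> drop_singletons -> normalize_copy_number
               -> relative_abundance -> hellinger

Singleton removal operates on raw integer counts (singleton status is a
read-count concept); 16S copy-number correction divides each ASV column
by its estimated per-genome copy number so abundances approximate cell
proportions; the Hellinger transform (square root of relative
abundance) makes Euclidean distances ecologically meaningful for
downstream ordination and clustering.

:func:`network_qc` additionally emulates the sample/sequence selection
a weighted co-abundance network needs: it drops (near-)zero-variance
ASVs, drops samples that are mostly zeros across the retained ASVs, and
keeps only the most abundant ``n_keep`` ASVs by mean relative abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CommunityTable


def normalize_copy_number(counts: CommunityTable, copy_numbers: pd.Series) -> CommunityTable:
    """Divide each ASV column by its 16S copy number.

    Raises if any ASV lacks a copy number or a copy number is not
    strictly positive; the error lists the offending IDs.
    """
    if counts.state != "raw":
        raise ValueError(f"expected a raw table, got state={counts.state!r}")
    missing = [a for a in counts.asv_ids if a not in copy_numbers.index]
    if missing:
        raise ValueError(f"missing copy numbers for ASVs: {missing[:10]}" +
                         (f" (+{len(missing) - 10} more)" if len(missing) > 10 else ""))
    cn = copy_numbers.loc[counts.asv_ids].to_numpy(dtype=float)
    bad = [a for a, v in zip(counts.asv_ids, cn) if not v > 0]
    if bad:
        raise ValueError(f"non-positive copy numbers for ASVs: {bad[:10]}")
    data = counts.data.astype(float) / cn[None, :]
    return CommunityTable(data=data, state="copy_corrected")


def drop_singletons(counts: CommunityTable) -> CommunityTable:
    """Remove ASVs whose total count across all samples is exactly 1.

    An ASV observed once in each of two samples (total 2) is retained:
    singleton status is defined study-wide, not per sample.
    """
    if counts.state != "raw":
        raise ValueError(f"singleton removal applies to raw counts, got {counts.state!r}")
    totals = counts.data.sum(axis=0)
    keep = totals != 1
    return CommunityTable(data=counts.data.loc[:, keep], state="raw")


def relative_abundance(table: CommunityTable) -> CommunityTable:
    """Divide each row by its total so rows sum to 1."""
    sums = table.data.sum(axis=1)
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"zero-total samples: {list(zero.index)[:10]}")
    data = table.data.div(sums, axis=0)
    return CommunityTable(data=data, state="relative")


def hellinger(table: CommunityTable) -> CommunityTable:
    """Hellinger transform: sqrt of relative abundance, row-wise."""
    sums = table.data.sum(axis=1)
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"zero-total samples: {list(zero.index)[:10]}")
    data = np.sqrt(table.data.div(sums, axis=0))
    return CommunityTable(data=data, state="hellinger")


@dataclass
class QCReport:
    """What :func:`network_qc` removed and why."""

    dropped_zero_variance: list[str] = field(default_factory=list)
    dropped_sparse_samples: list[str] = field(default_factory=list)
    dropped_low_abundance: list[str] = field(default_factory=list)

    @property
    def n_asvs_dropped(self) -> int:
        return len(self.dropped_zero_variance) + len(self.dropped_low_abundance)

    @property
    def n_samples_dropped(self) -> int:
        return len(self.dropped_sparse_samples)


def network_qc(
    table: CommunityTable,
    n_keep: int,
    max_zero_fraction: float = 0.5,
    variance_tol: float = 1e-12,
) -> tuple[CommunityTable, QCReport]:
    """Sample/sequence QC ahead of co-abundance network construction.

    Drops ASVs with variance <= ``variance_tol``, keeps the top
    ``n_keep`` surviving ASVs by mean relative abundance, then drops
    samples with more than ``max_zero_fraction`` zero entries among the
    retained ASVs (sparsity is judged against the abundant ASVs a
    correlation network will actually use, so a full ASV table's many
    rare-taxon zeros do not disqualify whole samples).
    """
    report = QCReport()
    data = table.data

    variances = data.var(axis=0, ddof=0)
    keep_var = variances > variance_tol
    report.dropped_zero_variance = list(data.columns[~keep_var])
    data = data.loc[:, keep_var]

    if n_keep > data.shape[1]:
        raise ValueError(f"n_keep={n_keep} exceeds {data.shape[1]} surviving ASVs")
    rel = data.div(data.sum(axis=1), axis=0)
    order = rel.mean(axis=0).sort_values(ascending=False)
    kept = set(order.index[:n_keep])
    report.dropped_low_abundance = [a for a in data.columns if a not in kept]
    # preserve original column order among the kept ASVs
    data = data.loc[:, [a for a in data.columns if a in kept]]

    zero_frac = (data == 0).mean(axis=1)
    keep_samples = zero_frac <= max_zero_fraction
    report.dropped_sparse_samples = list(data.index[~keep_samples])
    data = data.loc[keep_samples]
    return table.with_data(data), report
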