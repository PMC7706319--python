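"""Feature transforms applied to each view before integration.

The default genomics pipeline is: per-gene event counting (with a symmetric
500 bp flank), top-variance gene filtering on the raw counts, then
log/pseudocount or z-score normalization — variance filtering runs on
pre-normalization values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from intervaltree import IntervalTree

from .io import GeneInterval, GenomicEvent, OmicsMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "TransformRecord",
    "log_pseudo",
    "zscore_features",
    "top_variance_features",
    "count_events_per_gene",
]


@dataclass
class TransformRecord:
    """What a transform did, with enough per-feature state to reproduce it."""

    name: str
    params: dict = field(default_factory=dict)
    feature_ids: list[str] = field(default_factory=list)
    means: np.ndarray | None = None
    sds: np.ndarray | None = None

    def __post_init__(self) -> None:
        for stats in (self.means, self.sds):
            if stats is not None and len(stats) != len(self.feature_ids):
                raise ValueError("per-feature statistics length mismatch")


def log_pseudo(
    m: OmicsMatrix, pseudocount: float = 1.0, base: float = 10.0
) -> OmicsMatrix:
    """Elementwise log_base(value + pseudocount); values must be nonnegative."""
    if np.any(m.values < 0):
        i, j = np.argwhere(m.values < 0)[0]
        raise ValueError(
            f"negative value {m.values[i, j]} at sample {m.sample_ids[i]!r}, "
            f"feature {m.feature_ids[j]!r}"
        )
    out = np.log(m.values + pseudocount) / np.log(base)
    return replace(m, values=out)


def zscore_features(
    m: OmicsMatrix, return_record: bool = False
) -> OmicsMatrix | tuple[OmicsMatrix, TransformRecord]:
    """Standardize each feature to mean 0 and sample sd 1 (ddof=1).

    Constant features are mapped to all-zero columns and logged; they carry
    no correlation signal but keep the feature IDs stable.
    """
    if m.n_samples < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    means = m.values.mean(axis=0)
    sds = m.values.std(axis=0, ddof=1)
    constant = sds == 0
    if constant.any():
        logger.warning(
            "%d constant feature(s) zeroed during z-scoring (e.g. %r)",
            int(constant.sum()),
            m.feature_ids[int(np.argmax(constant))],
        )
    safe = np.where(constant, 1.0, sds)
    out = (m.values - means) / safe
    out[:, constant] = 0.0
    result = replace(m, values=out)
    if return_record:
        record = TransformRecord(
            "zscore", {}, list(m.feature_ids), means=means, sds=sds
        )
        return result, record
    return result


def top_variance_features(m: OmicsMatrix, k: int) -> OmicsMatrix:
    """Keep the k features with largest sample variance (ddof=1).

    Original column order is preserved among survivors; exact ties at the
    cutoff are broken in favor of the earlier column index.  If k >= d the
    matrix is returned unchanged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= m.n_features:
        return m
    var = m.values.var(axis=0, ddof=1) if m.n_samples > 1 else np.zeros(m.n_features)
    # stable sort on -variance: equal variances keep ascending column index
    order = np.argsort(-var, kind="stable")[:k]
    keep = np.sort(order)
    return replace(
        m,
        feature_ids=[m.feature_ids[i] for i in keep],
        values=m.values[:, keep],
    )


def count_events_per_gene(
    events: list[GenomicEvent],
    genes: list[GeneInterval],
    flank: int = 500,
    sample_ids: list[str] | None = None,
) -> OmicsMatrix:
    """Count per-sample events falling in each gene's flanked window.

    The window is half-open ``[max(0, start-flank), end+flank)``; an event
    overlapping several flanked genes counts toward each of them, and a gene
    listed with several intervals accumulates counts over all of them.
    Columns follow first-appearance order of gene IDs; rows follow
    ``sample_ids`` if given, else first-appearance order of event samples.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    gene_order: list[str] = []
    for g in genes:
        if g.gene_id not in gene_order:
            gene_order.append(g.gene_id)
    gene_pos = {g: j for j, g in enumerate(gene_order)}
    if sample_ids is None:
        sample_ids = []
        seen: set[str] = set()
        for e in events:
            if e.sample_id not in seen:
                seen.add(e.sample_id)
                sample_ids.append(e.sample_id)
    sample_pos = {s: i for i, s in enumerate(sample_ids)}

    trees: dict[str, IntervalTree] = {}
    for g in genes:
        lo = max(0, g.start - flank)
        hi = g.end + flank
        trees.setdefault(g.chrom, IntervalTree()).addi(lo, hi, gene_pos[g.gene_id])

    counts = np.zeros((len(sample_ids), len(gene_order)))
    for e in events:
        i = sample_pos.get(e.sample_id)
        tree = trees.get(e.chrom)
        if i is None or tree is None:
            continue
        for hit in tree.at(e.pos):
            counts[i, hit.data] += e.count
    return OmicsMatrix(sample_ids=list(sample_ids), feature_ids=gene_order, values=counts)
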