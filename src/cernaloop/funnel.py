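"""The candidate funnel: miRNA selection, circRNA selection, miRNA
binding-site (MBS) totals, and the median-threshold filter.

Stages, in order:

1. ``select_candidate_mirnas`` — keep miRNAs validated against at least
   ``min_targets`` distinct signature genes (default 4).
2. ``select_candidate_circs`` — keep circRNAs whose host gene belongs to
   the signature and which sponge at least one candidate miRNA.
3. ``compute_mbs`` — per retained circRNA, total binding sites across all
   sponge edges to candidate miRNAs (multiple sites for the same miRNA
   all count); the cohort median is computed once over all retained
   circRNAs and frozen.
4. ``filter_by_mbs`` — keep circRNAs whose MBS is greater than or equal
   to that frozen median (ties at the median are retained).
5. ``correlate_size_mbs`` — Spearman correlation between circRNA size
   and MBS (larger circRNAs are expected to carry more sites).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import stats
from .datatypes import CircRecord, GeneSignature, MirTargetRecord, SpongeRecord, check_sponge_integrity
from .errors import UndefinedResultError
from .stats import CorrelationResult

logger = logging.getLogger("cernaloop")


@dataclass(frozen=True)
class CandidateMir:
    """One retained miRNA with its distinct signature targets."""

    mirna_id: str
    signature_targets: frozenset[str]

    @property
    def n_targets(self) -> int:
        return len(self.signature_targets)


@dataclass(frozen=True)
class CandidateMirSet:
    """The candidate miRNA set plus the signature genes it covers."""

    mirnas: tuple[CandidateMir, ...]
    covered_genes: frozenset[str]
    min_targets: int

    @property
    def ids(self) -> frozenset[str]:
        return frozenset(m.mirna_id for m in self.mirnas)

    def __len__(self) -> int:
        return len(self.mirnas)

    def __contains__(self, mirna_id: str) -> bool:
        return mirna_id in self.ids


@dataclass(frozen=True)
class MbsSummary:
    """Per-circRNA MBS totals with the frozen cohort median.

    ``records`` holds (circ_id, host_gene, mbs) tuples; ``cohort_median``
    is the median of the mbs values (mean of the middle two for even
    cohort sizes), computed once before filtering.
    """

    records: tuple[tuple[str, str, int], ...]
    cohort_median: float

    def mbs_of(self, circ_id: str) -> int:
        for cid, _, mbs in self.records:
            if cid == circ_id:
                return mbs
        raise KeyError(circ_id)


@dataclass(frozen=True)
class MbsFilterResult:
    """Outcome of the >=-median filter."""

    retained_ids: tuple[str, ...]
    host_genes: frozenset[str]
    threshold: float

    @property
    def n_retained(self) -> int:
        return len(self.retained_ids)


def select_candidate_mirnas(
    targets: list[MirTargetRecord],
    signature: GeneSignature,
    min_targets: int = 4,
) -> CandidateMirSet:
    """Retain miRNAs with >= ``min_targets`` distinct signature targets."""
    if min_targets < 1:
        raise ValueError("min_targets must be >= 1")
    if len(signature) == 0:
        raise ValueError("signature must be non-empty")
    sig = signature.as_set()
    per_mir: dict[str, set[str]] = {}
    for rec in targets:
        if rec.target_gene in sig:
            per_mir.setdefault(rec.mirna_id, set()).add(rec.target_gene)
    kept = tuple(
        CandidateMir(mirna_id=mid, signature_targets=frozenset(genes))
        for mid, genes in sorted(per_mir.items())
        if len(genes) >= min_targets
    )
    covered = frozenset().union(*(m.signature_targets for m in kept)) if kept else frozenset()
    logger.info(
        "candidate miRNA selection: %d of %d miRNAs retained (>= %d signature "
        "targets), covering %d signature gene(s)",
        len(kept), len(per_mir), min_targets, len(covered),
    )
    return CandidateMirSet(mirnas=kept, covered_genes=covered, min_targets=min_targets)


def select_candidate_circs(
    sponges: list[SpongeRecord],
    circs: list[CircRecord],
    candidates: CandidateMirSet,
    signature: GeneSignature,
) -> list[CircRecord]:
    """Retain circRNAs hosted by signature genes that sponge >= 1 candidate
    miRNA."""
    check_sponge_integrity(sponges, circs)
    sig = signature.as_set()
    cand = candidates.ids
    sponging = {s.circ_id for s in sponges if s.mirna_id in cand}
    kept = sorted(
        (c for c in circs if c.host_gene in sig and c.circ_id in sponging),
        key=lambda c: c.circ_id,
    )
    logger.info(
        "candidate circRNA selection: %d of %d retained (%d host gene(s))",
        len(kept), len(circs), len({c.host_gene for c in kept}),
    )
    return kept


def compute_mbs(
    sponges: list[SpongeRecord],
    retained_circs: list[CircRecord],
    candidates: CandidateMirSet,
) -> MbsSummary:
    """Total binding sites per circRNA for the candidate miRNA set.

    Sites for the same and for different candidate miRNAs all count; the
    cohort median is taken over all retained circRNAs and frozen in the
    summary for the downstream filter.
    """
    if not retained_circs:
        raise ValueError("compute_mbs requires a non-empty circRNA cohort")
    cand = candidates.ids
    totals = {c.circ_id: 0 for c in retained_circs}
    for s in sponges:
        if s.circ_id in totals and s.mirna_id in cand:
            totals[s.circ_id] += s.n_sites
    records = tuple(
        (c.circ_id, c.host_gene, totals[c.circ_id])
        for c in sorted(retained_circs, key=lambda c: c.circ_id)
    )
    median = float(np.median([m for _, _, m in records]))
    logger.info("MBS computed for %d circRNA(s); cohort median = %g", len(records), median)
    return MbsSummary(records=records, cohort_median=median)


def filter_by_mbs(summary: MbsSummary) -> MbsFilterResult:
    """Keep circRNAs with MBS >= the frozen cohort median (ties kept)."""
    if not summary.records:
        raise ValueError("cannot filter an empty MBS summary")
    retained = tuple(
        cid for cid, _, mbs in summary.records if mbs >= summary.cohort_median
    )
    hosts = frozenset(
        host for cid, host, mbs in summary.records if mbs >= summary.cohort_median
    )
    logger.info(
        "MBS filter (threshold %g): %d of %d circRNA(s) retained from %d host gene(s)",
        summary.cohort_median, len(retained), len(summary.records), len(hosts),
    )
    return MbsFilterResult(retained_ids=retained, host_genes=hosts,
                           threshold=summary.cohort_median)


def correlate_size_mbs(
    summary: MbsSummary, circs: list[CircRecord], size_mode: str = "auto"
) -> CorrelationResult:
    """Spearman correlation between circRNA size and MBS.

    ``size_mode`` picks spliced length vs genomic span (see
    :meth:`CircRecord.size`); which one external sponge databases report
    is source-dependent, so the choice is explicit and logged.
    """
    by_id = {c.circ_id: c for c in circs}
    sizes, mbs = [], []
    for cid, _, m in summary.records:
        if cid in by_id:
            sizes.append(by_id[cid].size(mode=size_mode))
            mbs.append(m)
    if len(sizes) < 3:
        raise UndefinedResultError(
            f"size-MBS correlation needs >= 3 circRNAs with a defined size, got {len(sizes)}"
        )
    logger.info("size-MBS correlation on %d circRNA(s), size_mode=%s", len(sizes), size_mode)
    return stats.spearman(sizes, mbs)
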