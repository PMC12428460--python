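"""Tripartite ceRNA graph assembly, feed-forward-loop enumeration, and
the RBP binding-site enrichment screen.

A ceRNA feed-forward loop (FFL) is a (circRNA, miRNA, gene) triple in
which the circRNA sponges a miRNA that is validated to repress the
circRNA's own host gene: the circRNA de-represses its host.  The graph
holds three node classes (circRNA, miRNA, gene) with sponge edges
(circRNA–miRNA) and target edges (miRNA–gene); same-class nodes are
never connected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from . import stats
from .datatypes import CircRecord, GeneSignature, MirTargetRecord, RbpSiteTable, SpongeRecord
from .funnel import CandidateMirSet

logger = logging.getLogger("cernaloop")


@dataclass(frozen=True)
class FflMotif:
    """One circRNA–miRNA–gene feed-forward loop.

    Invariants: the target gene is the circRNA's host gene, belongs to
    the signature, and is a validated target of the miRNA; ``n_sites``
    and ``agoclip_p_bound`` describe the supporting sponge edge.
    """

    circ_id: str
    mirna_id: str
    target_gene: str
    n_sites: int
    agoclip_p_bound: float


def build_tripartite(
    candidates: CandidateMirSet,
    sponges: list[SpongeRecord],
    circs: list[CircRecord],
    targets: list[MirTargetRecord],
    signature: GeneSignature,
) -> nx.Graph:
    """Assemble the tripartite ceRNA graph.

    Nodes: every signature gene (kind='gene'); every candidate miRNA
    (kind='mirna'); every circRNA with at least one sponge edge to a
    candidate miRNA (kind='circ', host gene stored as attribute).
    Sponge edges to non-candidate miRNAs are excluded; parallel sponge
    records for the same pair aggregate (site counts summed, tightest
    p bound kept).
    """
    g = nx.Graph()
    for gene in signature.genes:
        g.add_node(gene, kind="gene")
    for mir in candidates.ids:
        g.add_node(mir, kind="mirna")

    by_id = {c.circ_id: c for c in circs}
    for s in sponges:
        if s.mirna_id not in candidates.ids or s.circ_id not in by_id:
            continue
        circ = by_id[s.circ_id]
        if s.circ_id not in g:
            g.add_node(s.circ_id, kind="circ", host_gene=circ.host_gene)
        if g.has_edge(s.circ_id, s.mirna_id):
            data = g.edges[s.circ_id, s.mirna_id]
            data["n_sites"] += s.n_sites
            data["agoclip_p_bound"] = min(data["agoclip_p_bound"], s.agoclip_p_bound)
        else:
            g.add_edge(
                s.circ_id, s.mirna_id, kind="sponge",
                n_sites=s.n_sites, agoclip_p_bound=s.agoclip_p_bound,
            )

    sig = signature.as_set()
    for rec in targets:
        if rec.mirna_id in candidates.ids and rec.target_gene in sig:
            g.add_edge(rec.mirna_id, rec.target_gene, kind="target",
                       evidence=rec.evidence)

    kinds = [d["kind"] for _, d in g.nodes(data=True)]
    logger.info(
        "tripartite graph: %d circRNA, %d miRNA, %d gene node(s); %d edge(s)",
        kinds.count("circ"), kinds.count("mirna"), kinds.count("gene"),
        g.number_of_edges(),
    )
    return g


def enumerate_ffl(graph: nx.Graph) -> list[FflMotif]:
    """Enumerate all feed-forward loops in a tripartite ceRNA graph.

    A motif requires a sponge edge (circ, miR) and a target edge
    (miR, host gene of that circ).  Results are ordered by
    (circ_id, mirna_id).
    """
    motifs = []
    for node, data in graph.nodes(data=True):
        if data.get("kind") != "circ":
            continue
        host = data["host_gene"]
        if host not in graph or graph.nodes[host].get("kind") != "gene":
            continue
        for mir in graph.neighbors(node):
            edge = graph.edges[node, mir]
            if edge.get("kind") != "sponge":
                continue
            if graph.has_edge(mir, host) and graph.edges[mir, host].get("kind") == "target":
                motifs.append(
                    FflMotif(
                        circ_id=node,
                        mirna_id=mir,
                        target_gene=host,
                        n_sites=edge["n_sites"],
                        agoclip_p_bound=edge["agoclip_p_bound"],
                    )
                )
    motifs.sort(key=lambda m: (m.circ_id, m.mirna_id))
    logger.info(
        "feed-forward loops: %d motif(s) over %d target gene(s)",
        len(motifs), len({m.target_gene for m in motifs}),
    )
    return motifs


# ---------------------------------------------------------------------------
# RBP enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RbpResult:
    """Per-RBP enrichment outcome (candidate vs background site counts)."""

    rbp: str
    candidate_counts: tuple[int, ...]
    background_counts: tuple[int, ...]
    u_statistic: float
    p_raw: float
    p_adjusted: float
    enriched: bool


@dataclass(frozen=True)
class RbpEnrichmentResult:
    """The full screen: one row per tested RBP plus the FDR level used."""

    results: tuple[RbpResult, ...]
    fdr_level: float
    excluded_rbps: tuple[str, ...]

    @property
    def enriched_rbps(self) -> tuple[str, ...]:
        return tuple(r.rbp for r in self.results if r.enriched)


def rbp_enrichment(table: RbpSiteTable, fdr_level: float = 0.10) -> RbpEnrichmentResult:
    """Screen RBPs for binding-site enrichment in candidate circRNAs.

    Per RBP, a one-sided Mann–Whitney test of candidate > background site
    counts (the claim screened for is directional), followed by
    Benjamini–Hochberg adjustment across RBPs; an RBP is flagged enriched
    when its adjusted p falls below ``fdr_level``.  RBPs with all-zero
    counts in both groups are excluded with a warning.
    """
    if not (0.0 < fdr_level < 1.0):
        raise ValueError("fdr_level must lie in (0, 1)")
    cand = table.candidates
    back = table.background
    if len(back) < 2:
        raise ValueError("rbp_enrichment needs >= 2 background circRNAs")

    tested, excluded = [], []
    for rbp in table.counts.columns:
        c = cand[rbp].to_numpy()
        b = back[rbp].to_numpy()
        if (c == 0).all() and (b == 0).all():
            excluded.append(rbp)
            continue
        res = stats.mann_whitney(c, b, alternative="greater")
        tested.append((rbp, tuple(int(v) for v in c), tuple(int(v) for v in b), res))
    if excluded:
        logger.warning("RBP screen: %d RBP(s) excluded (all-zero counts): %s",
                       len(excluded), excluded[:5])
    adjusted = stats.bh_adjust([r.p_value for *_, r in tested]) if tested else np.array([])
    rows = tuple(
        RbpResult(
            rbp=rbp,
            candidate_counts=c,
            background_counts=b,
            u_statistic=res.statistic,
            p_raw=res.p_value,
            p_adjusted=float(p_adj),
            enriched=bool(p_adj < fdr_level),
        )
        for (rbp, c, b, res), p_adj in zip(tested, adjusted)
    )
    return RbpEnrichmentResult(results=rows, fdr_level=fdr_level,
                               excluded_rbps=tuple(excluded))


def sample_background_by_size(
    circs: list[CircRecord],
    candidate_ids: set[str],
    n: int,
    tolerance: float = 0.2,
    seed: int = 0,
    size_mode: str = "auto",
) -> list[str]:
    """Sample ``n`` background circRNAs of similar size to the candidates.

    "Similar" means within ±``tolerance`` (default 20%) of the candidate
    mean size; sampling is without replacement and seed-controlled.
    """
    cand_sizes = [c.size(size_mode) for c in circs if c.circ_id in candidate_ids]
    if not cand_sizes:
        raise ValueError("no candidate circRNAs found in the annotation")
    mean = float(np.mean(cand_sizes))
    lo, hi = mean * (1 - tolerance), mean * (1 + tolerance)
    pool = sorted(
        c.circ_id
        for c in circs
        if c.circ_id not in candidate_ids and lo <= c.size(size_mode) <= hi
    )
    if len(pool) < n:
        raise ValueError(
            f"only {len(pool)} background circRNA(s) within ±{tolerance:.0%} of the "
            f"candidate mean size {mean:.0f} nt (need {n})"
        )
    rng = np.random.default_rng(seed)
    return sorted(rng.choice(pool, size=n, replace=False).tolist())
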