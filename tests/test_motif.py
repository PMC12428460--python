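"""Motif-stage tests: tripartite assembly, FFL enumeration against a
brute-force oracle, and the RBP enrichment screen."""

import numpy as np
import pandas as pd
import pytest

from cernaloop import funnel as fn, motif as mt
from cernaloop.datatypes import (
    CircRecord,
    GeneSignature,
    MirTargetRecord,
    RbpSiteTable,
    SpongeRecord,
)


def _circ(cid, host, size=500):
    return CircRecord(cid, host, "chr1", 1000, 1000 + size, spliced_length=size)


def brute_force_ffl(candidates, sponges, circs, targets, signature):
    """Independent oracle: triple loop over all (circ, miR, gene)."""
    sig = signature.as_set()
    target_pairs = {
        (t.mirna_id, t.target_gene) for t in targets if t.target_gene in sig
    }
    sponge_pairs = {}
    for s in sponges:
        if s.mirna_id in candidates.ids:
            sponge_pairs.setdefault((s.circ_id, s.mirna_id), 0)
            sponge_pairs[(s.circ_id, s.mirna_id)] += s.n_sites
    out = set()
    for c in circs:
        for m in candidates.ids:
            for g in sig:
                if (
                    c.host_gene == g
                    and (c.circ_id, m) in sponge_pairs
                    and (m, g) in target_pairs
                ):
                    out.add((c.circ_id, m, g))
    return out


class TestTripartiteAndFfl:
    def test_demo_network_structure(self, demo_network):
        targets, sponges, circs, signature = demo_network
        cand = fn.select_candidate_mirnas(targets, signature, min_targets=1)
        g = mt.build_tripartite(cand, sponges, circs, targets, signature)
        kinds = [d["kind"] for _, d in g.nodes(data=True)]
        assert kinds.count("circ") == 7
        assert kinds.count("mirna") == 4
        assert kinds.count("gene") == len(signature)
        # no edge connects two nodes of the same class
        for u, v in g.edges:
            assert g.nodes[u]["kind"] != g.nodes[v]["kind"]

    def test_demo_network_motifs(self, demo_network):
        targets, sponges, circs, signature = demo_network
        cand = fn.select_candidate_mirnas(targets, signature, min_targets=1)
        g = mt.build_tripartite(cand, sponges, circs, targets, signature)
        motifs = mt.enumerate_ffl(g)
        assert sorted({m.target_gene for m in motifs}) == ["CHEK1", "PIM1"]
        mir16_pim1 = sorted(
            m.circ_id
            for m in motifs
            if m.mirna_id == "hsa-miR-16-5p" and m.target_gene == "PIM1"
        )
        assert mir16_pim1 == [
            "hsa_circ_0076213",
            "hsa_circ_0076214",
            "hsa_circ_0076215",
            "hsa_circ_0076216",
        ]

    def test_empty_candidate_set_leaves_gene_nodes_only(self, demo_network):
        targets, sponges, circs, signature = demo_network
        cand = fn.select_candidate_mirnas(targets, signature, min_targets=10)
        g = mt.build_tripartite(cand, sponges, circs, targets, signature)
        assert all(d["kind"] == "gene" for _, d in g.nodes(data=True))
        assert mt.enumerate_ffl(g) == []

    def test_sponge_edge_to_noncandidate_excluded(self):
        sig = GeneSignature("s", ("G1", "G2", "G3", "G4"))
        targets = [MirTargetRecord("mirA", g) for g in sig.genes]
        cand = fn.select_candidate_mirnas(targets, sig, min_targets=4)
        sponges = [
            SpongeRecord("c1", "mirA", 2),
            SpongeRecord("c1", "mirNOT", 9),
        ]
        g = mt.build_tripartite(cand, sponges, [_circ("c1", "G1")], targets, sig)
        assert "mirNOT" not in g
        assert g.edges["c1", "mirA"]["kind"] == "sponge"

    def test_host_never_targeted_yields_no_motifs(self):
        sig = GeneSignature("s", ("G1", "G2", "G3", "G4", "G5"))
        targets = [MirTargetRecord("mirA", g) for g in ("G2", "G3", "G4", "G5")]
        cand = fn.select_candidate_mirnas(targets, sig, min_targets=4)
        sponges = [SpongeRecord("c1", "mirA", 5)]
        g = mt.build_tripartite(cand, sponges, [_circ("c1", "G1")], targets, sig)
        assert mt.enumerate_ffl(g) == []

    def test_parallel_sponge_records_aggregate(self):
        sig = GeneSignature("s", ("G1", "G2", "G3", "G4"))
        targets = [MirTargetRecord("mirA", g) for g in sig.genes]
        cand = fn.select_candidate_mirnas(targets, sig, min_targets=4)
        sponges = [
            SpongeRecord("c1", "mirA", 2, 1e-6),
            SpongeRecord("c1", "mirA", 3, 1e-12),
        ]
        g = mt.build_tripartite(cand, sponges, [_circ("c1", "G1")], targets, sig)
        motifs = mt.enumerate_ffl(g)
        assert motifs[0].n_sites == 5
        assert motifs[0].agoclip_p_bound == 1e-12

    def test_matches_bruteforce_on_random_graphs(self):
        rng = np.random.default_rng(2024)
        for _ in range(40):
            n_genes = int(rng.integers(3, 9))
            n_mirs = int(rng.integers(2, 9))
            n_circs = int(rng.integers(2, 13))
            genes = [f"G{i}" for i in range(n_genes)]
            sig = GeneSignature("s", tuple(genes))
            mirs = [f"mir{i}" for i in range(n_mirs)]
            targets = [
                MirTargetRecord(m, g)
                for m in mirs
                for g in genes
                if rng.random() < 0.4
            ]
            circs = [
                _circ(f"c{i}", genes[int(rng.integers(0, n_genes))])
                for i in range(n_circs)
            ]
            sponges = [
                SpongeRecord(c.circ_id, m, int(rng.integers(1, 6)))
                for c in circs
                for m in mirs
                if rng.random() < 0.3
            ]
            cand = fn.select_candidate_mirnas(targets, sig, min_targets=1)
            g = mt.build_tripartite(cand, sponges, circs, targets, sig)
            found = {(m.circ_id, m.mirna_id, m.target_gene)
                     for m in mt.enumerate_ffl(g)}
            assert found == brute_force_ffl(cand, sponges, circs, targets, sig)

    def test_adding_a_sponge_edge_only_adds_motifs(self):
        sig = GeneSignature("s", ("G1", "G2", "G3", "G4"))
        targets = [MirTargetRecord("mirA", g) for g in sig.genes] + [
            MirTargetRecord("mirB", g) for g in sig.genes
        ]
        cand = fn.select_candidate_mirnas(targets, sig, min_targets=4)
        circs = [_circ("c1", "G1"), _circ("c2", "G2")]
        sponges = [SpongeRecord("c1", "mirA", 2)]
        g1 = mt.build_tripartite(cand, sponges, circs, targets, sig)
        before = {(m.circ_id, m.mirna_id) for m in mt.enumerate_ffl(g1)}
        g2 = mt.build_tripartite(
            cand, sponges + [SpongeRecord("c2", "mirB", 1)], circs, targets, sig
        )
        after = {(m.circ_id, m.mirna_id) for m in mt.enumerate_ffl(g2)}
        assert before <= after


class TestRbpEnrichment:
    def _table(self, cand_rows, back_rows, rbps):
        counts = pd.DataFrame(cand_rows + back_rows, columns=rbps)
        counts.index = [f"c{i}" for i in range(len(counts))]
        roles = pd.Series(
            ["candidate"] * len(cand_rows) + ["background"] * len(back_rows),
            index=counts.index,
        )
        return RbpSiteTable(counts=counts, roles=roles)

    def test_planted_rbp_is_the_only_flag(self):
        # 20 RBPs; one has clearly elevated candidate counts (11 vs all-1
        # background); all others identical between groups
        rbps = [f"RBP{i:02d}" for i in range(20)]
        cand = [[11 if r == "RBP07" else 1 for r in rbps]] * 2
        back = [[1] * 20] * 10
        res = mt.rbp_enrichment(self._table(cand, back, rbps), fdr_level=0.10)
        assert res.enriched_rbps == ("RBP07",)
        by_name = {r.rbp: r for r in res.results}
        assert by_name["RBP07"].p_adjusted < 0.10
        assert all(r.p_adjusted >= r.p_raw for r in res.results)

    def test_null_screen_rarely_flags(self):
        # identical sampling distributions: BH at 10% controls family error
        rbps = [f"R{i}" for i in range(12)]
        seeds_with_hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            cand = rng.poisson(2.0, size=(3, 12)).tolist()
            back = rng.poisson(2.0, size=(15, 12)).tolist()
            res = mt.rbp_enrichment(self._table(cand, back, rbps))
            seeds_with_hits += bool(res.enriched_rbps)
        assert seeds_with_hits <= 4

    def test_all_zero_rbp_excluded_with_warning(self):
        rbps = ["A", "B"]
        cand = [[3, 0]]
        back = [[1, 0], [2, 0]]
        res = mt.rbp_enrichment(self._table(cand, back, rbps))
        assert res.excluded_rbps == ("B",)
        assert [r.rbp for r in res.results] == ["A"]

    def test_enriched_set_nested_in_fdr_level(self):
        rng = np.random.default_rng(5)
        rbps = [f"R{i}" for i in range(10)]
        cand = (rng.poisson(6.0, size=(3, 10))).tolist()
        back = (rng.poisson(2.0, size=(12, 10))).tolist()
        table = self._table(cand, back, rbps)
        tight = set(mt.rbp_enrichment(table, fdr_level=0.02).enriched_rbps)
        loose = set(mt.rbp_enrichment(table, fdr_level=0.20).enriched_rbps)
        assert tight <= loose

    def test_background_sampler_respects_size_window(self):
        rng = np.random.default_rng(1)
        circs = [_circ("cand1", "G1", size=500)] + [
            _circ(f"b{i}", "G2", size=int(s))
            for i, s in enumerate(rng.integers(100, 1200, size=60))
        ]
        picked = mt.sample_background_by_size(circs, {"cand1"}, n=10, seed=3)
        sizes = {c.circ_id: c.size() for c in circs}
        assert len(picked) == 10
        assert all(400 <= sizes[cid] <= 600 for cid in picked)
        assert picked == mt.sample_background_by_size(circs, {"cand1"}, n=10, seed=3)
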