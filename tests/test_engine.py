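"""The RSGM/SGM search, scoring and database filtration."""

import math

import numpy as np
import pytest

from sgmfilter import (
    FixtureSpec,
    MassInterval,
    ProteinIndex,
    ResidueAlphabet,
    SGMParams,
    build_composition_table,
    build_spectrum_graph,
    extended_similarity_score,
    filter_database,
    filtration_efficiency,
    generate_proteins,
    generate_spectrum,
    naive_sgm,
    rsgm,
    sgm,
    similarity_score,
)
from sgmfilter.engine import CandidateRanking, CandidateScore, GraphMatch

from .conftest import make_random_instance
from .test_graph import chain_graph


def match_set(matches):
    return {(m.key, m.path_score, m.path_nodes) for m in matches}


class TestRSGM:
    def test_blocked_pattern_matches_whole_text_at_scale_one(self):
        # pattern 114,255,87 against the text of NRVS (114,156,99,87)
        alph1 = ResidueAlphabet(scale=1)
        table1 = build_composition_table(alph1, 400, tol=0)
        index = ProteinIndex.build([("p", "NRVS")], alph1)
        g = chain_graph([0.0, 114.0, 369.0, 456.0], [114, 255, 87], scale=1)
        out = rsgm(g, 0, index.tree, table1, ends={3}, text=index.text)
        assert len(out) == 1
        (m,) = out
        assert m.matched_residues == "NRVS"
        assert m.start_offset == 0
        assert m.path_nodes == 4

    def test_lnrvsg_match_and_noise_path(self, noisy_lnrvsg_graph, lnrvsg_index, table):
        out = rsgm(noisy_lnrvsg_graph, 0, lnrvsg_index.tree, table, ends={2, 3, 4},
                   text=lnrvsg_index.text)
        by_key = {m.key: m for m in out}
        m = by_key[("prot1", 1, "NRVS")]
        assert m.path_nodes == 4
        # the noise route spells NVR... which is not in LNRVSG
        assert not any(m.matched_residues.startswith("NV") for m in out)

    def test_unidentifiable_first_edge_gives_nothing(self, table, alphabet):
        index = ProteinIndex.build([("p", "AAAA")], alphabet)
        g = chain_graph([100.0, 286.08], [18608])  # W (or VS): absent from AAAA
        assert rsgm(g, 0, index.tree, table, ends={1}, text=index.text) == []

    def test_invalid_start_rejected(self, noisy_lnrvsg_graph, lnrvsg_index, table):
        with pytest.raises(ValueError):
            rsgm(noisy_lnrvsg_graph, 99, lnrvsg_index.tree, table, ends={1},
                 text=lnrvsg_index.text)


class TestSGM:
    def test_beta_zero_equals_rsgm_from_extremes(self, noisy_lnrvsg_graph,
                                                 lnrvsg_index, table):
        full = sgm(noisy_lnrvsg_graph, lnrvsg_index.tree, table, 0.0, lnrvsg_index.text)
        restricted = rsgm(noisy_lnrvsg_graph, 0, lnrvsg_index.tree, table,
                          ends={noisy_lnrvsg_graph.n_nodes - 1}, text=lnrvsg_index.text)
        assert match_set(full) == match_set(restricted)

    def test_empty_graph_gives_empty_result(self, table, lnrvsg_index):
        itv = MassInterval(lo=0, hi=10, masses=np.array([100.0]),
                           intensities=np.ones(1))
        g = build_spectrum_graph(itv, table, 350.0, 0.02, 3)
        assert sgm(g, lnrvsg_index.tree, table, 250.0, lnrvsg_index.text) == []

    def test_disconnected_components_both_searched(self, alphabet, table):
        # two AG gaps separated by an unexplainable 1000.5 Da jump
        index = ProteinIndex.build([("p", "AGWAG")], alphabet)
        masses = np.array([200.0, 271.037, 328.059, 1328.559, 1399.596, 1456.617])
        itv = MassInterval(lo=0, hi=2000, masses=masses,
                           intensities=np.ones(masses.size))
        g = build_spectrum_graph(itv, table, 350.0, 0.02, 3)
        assert not any(v == 3 for _, adj in enumerate(g.edges[:3]) for v, _ in adj)
        out = sgm(g, index.tree, table, 2000.0, index.text)
        offsets = {m.start_offset for m in out if m.matched_residues == "AG"}
        assert offsets == {0, 3}

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_agree_with_naive_search(self, seed, table, alphabet):
        graph, beta, index = make_random_instance(seed, table, alphabet)
        fast = sgm(graph, index.tree, table, beta, index.text)
        slow = naive_sgm(graph, index.text, beta, table)
        assert match_set(fast) == match_set(slow)

    @pytest.mark.parametrize("seed", range(15))
    def test_match_masses_telescope(self, seed, table, alphabet):
        graph, beta, index = make_random_instance(seed, table, alphabet)
        node_ints = {int(m) for m in graph.int_masses}
        spans = {int(b - a) for a in graph.int_masses for b in graph.int_masses}
        for m in sgm(graph, index.tree, table, beta, index.text):
            total = index.text.alphabet.mass_of_string(
                m.matched_residues.replace("I", "L"))
            # within the accumulated per-edge tolerance of some node-mass span
            assert any(abs(total - s) <= table.tol * (m.path_nodes - 1)
                       for s in spans)

    def test_monotone_in_beta(self, table, alphabet):
        for seed in range(10):
            graph, _, index = make_random_instance(seed, table, alphabet)
            prev = set()
            for beta in (0.0, 100.0, 250.0, 400.0, 1e6):
                cur = {m.key for m in sgm(graph, index.tree, table, beta,
                                          index.text)}
                assert prev <= cur
                prev = cur


class TestScores:
    def test_similarity_is_max_path_score(self):
        ms = [GraphMatch("p", 0, "AG", 3, 3.0), GraphMatch("p", 4, "GGR", 5, 5.0),
              GraphMatch("q", 1, "N", 2, 2.0)]
        assert similarity_score(ms) == {"p": 5.0, "q": 2.0}
        assert similarity_score([]) == {}

    def test_extended_score_full_ladder(self, alphabet):
        seq = "AGNRVSTKLM"
        sp = generate_spectrum(seq, FixtureSpec(seed=1))
        match = GraphMatch("p", 2, "NRV", 4, 4.0,
                           first_node_mass=71.03711 + 57.02146)
        score = extended_similarity_score(sp, seq, match, 0.02, alphabet)
        assert score == len(sp)

    def test_extended_score_with_downstream_modification(self, alphabet):
        seq = "AGNRVSTKLM"
        # +80 Da on residue 8 (fraction 0.75): cleavages 8..9 shift
        sp = generate_spectrum(seq, FixtureSpec(seed=1,
                                                ptm_shifts=[(0.75, 79.96633)]))
        match = GraphMatch("p", 2, "NRV", 4, 4.0,
                           first_node_mass=71.03711 + 57.02146)
        score = extended_similarity_score(sp, seq, match, 0.02, alphabet)
        # the 7 unmodified cleavages align, the 2 shifted ones do not
        assert score == 7

    def test_extended_score_empty_spectrum(self, alphabet):
        sp = generate_spectrum("AG", FixtureSpec(seed=1, miss_prob=1.0))
        match = GraphMatch("p", 0, "A", 1, 1.0, first_node_mass=0.0)
        assert extended_similarity_score(sp, "AG", match, 0.02, alphabet) == 0.0

    def test_extended_score_rejects_inconsistent_match(self, alphabet):
        sp = generate_spectrum("AGNR", FixtureSpec(seed=1))
        match = GraphMatch("p", 0, "WW", 3, 3.0, first_node_mass=0.0)
        with pytest.raises(ValueError):
            extended_similarity_score(sp, "AGNR", match, 0.02, alphabet)


@pytest.fixture(scope="module")
def small_db(alphabet):
    spec = FixtureSpec(n_proteins=50, length_range=(40, 80), seed=42)
    records = generate_proteins(spec)
    return records, ProteinIndex.build(records, alphabet)


class TestFilterDatabase:
    def test_unmodified_spectrum_ranks_true_protein_first(self, small_db, table):
        records, index = small_db
        pid, seq = records[7]
        sp = generate_spectrum(seq, FixtureSpec(seed=3), spectrum_id="q7")
        ranking = filter_database(sp, index, table, SGMParams())
        assert ranking.protein_ids()[0] == pid

    def test_modified_spectrum_stays_in_top_20(self, small_db, table):
        records, index = small_db
        pid, seq = records[7]
        sp = generate_spectrum(
            seq,
            FixtureSpec(seed=3, miss_prob=0.3, n_noise=5,
                        ptm_shifts=[(0.3, 79.96633), (0.7, 42.01057)]),
            spectrum_id="q7m",
        )
        ranking = filter_database(sp, index, table, SGMParams())
        assert pid in ranking.protein_ids()[:20]

    def test_reversed_intervals_recover_suffix_ladders(self, small_db, table):
        records, index = small_db
        pid, seq = records[3]
        # spectrum of suffix fragments only
        from sgmfilter import RESIDUE_MASSES, DeconvolutedSpectrum
        from sgmfilter.fixtures import WATER_MASS

        res = np.array([RESIDUE_MASSES[aa] for aa in seq])
        precursor = res.sum() + WATER_MASS
        suffix_masses = precursor - np.cumsum(res)[:-1]
        sp = DeconvolutedSpectrum(
            spectrum_id="suffixes", precursor_mass=precursor,
            masses=suffix_masses, intensities=np.ones(suffix_masses.size),
        )
        ranking = filter_database(sp, index, table, SGMParams())
        assert ranking.protein_ids()[0] == pid
        assert ranking.entries[0].best_match.orientation == "reversed"

    def test_tiny_spectrum_gives_empty_ranking(self, small_db, table):
        _, index = small_db
        sp = generate_spectrum("AGNRVS", FixtureSpec(seed=1), spectrum_id="tiny")
        assert len(sp) == 5
        ranking = filter_database(sp, index, table, SGMParams())
        assert ranking.entries == []

    def test_rankings_have_unique_proteins_and_respect_top_k(self, small_db, table):
        records, index = small_db
        _, seq = records[0]
        sp = generate_spectrum(seq, FixtureSpec(seed=9, miss_prob=0.2, n_noise=5))
        ranking = filter_database(sp, index, table, SGMParams(top_k=5))
        pids = ranking.protein_ids()
        assert len(pids) == len(set(pids)) <= 5


class TestFiltrationEfficiency:
    @staticmethod
    def ranking(sid, pids):
        return CandidateRanking(
            spectrum_id=sid,
            entries=[CandidateScore(protein_id=p, similarity=1.0) for p in pids],
            top_k=20,
        )

    def test_three_of_four(self):
        rankings = [self.ranking(f"s{i}", ["A", "B"]) for i in range(3)]
        rankings.append(self.ranking("s3", ["C"]))
        truth = {f"s{i}": "A" for i in range(4)}
        assert filtration_efficiency(rankings, truth, 20) == 0.75

    def test_empty_rankings_give_zero(self):
        rankings = [self.ranking("s0", []), self.ranking("s1", [])]
        assert filtration_efficiency(rankings, {"s0": "A", "s1": "B"}, 20) == 0.0

    def test_always_rank_one_gives_one(self):
        rankings = [self.ranking(f"s{i}", ["T", "X"]) for i in range(5)]
        assert filtration_efficiency(rankings, {f"s{i}": "T" for i in range(5)},
                                     1) == 1.0

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            filtration_efficiency([], {}, 20)
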