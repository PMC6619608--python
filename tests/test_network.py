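"""Statistical-parsimony networks: collapse, connection limit, construction,
export."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from orgvar.io import SnpMatrix, ValidationError
from orgvar.mito import complete_case_sites
from orgvar.network import (
    Haplotype,
    build_network,
    collapse_haplotypes,
    connection_limit,
    export_network,
    hamming,
    network_from_matrix,
    parsimony_probability,
)
from conftest import random_snp_matrix


def _haps(profiles: list[str]) -> list[Haplotype]:
    return [Haplotype(hap_id=f"H{i + 1:02d}", profile=p, members=[f"i{i}"])
            for i, p in enumerate(profiles)]


# ---------------------------------------------------------------------------
# Brute-force oracle: minimum-intermediate network with unit-step edges
# ---------------------------------------------------------------------------


def _valid(observed: list[str], intermediates: set[str], limit: int) -> bool:
    """All observed pairs at profile distance d <= limit must be joined by a
    path of length <= d in the unit-step graph over observed+intermediates."""
    nodes = list(dict.fromkeys(observed)) + sorted(intermediates)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for a, b in itertools.combinations(nodes, 2):
        if hamming(a, b) == 1:
            g.add_edge(a, b)
    for a, b in itertools.combinations(observed, 2):
        d = hamming(a, b)
        if d <= limit:
            try:
                if nx.shortest_path_length(g, a, b) > d:
                    return False
            except nx.NetworkXNoPath:
                return False
    return g


def steiner_oracle(observed: list[str], limit: int):
    """Smallest intermediate set (by exhaustive subset search over profiles
    on shortest paths) whose unit-step graph satisfies the parsimony
    connection conditions.  Returns the set of unique optimal edge sets."""
    candidates: set[str] = set()
    for a, b in itertools.combinations(observed, 2):
        d = hamming(a, b)
        if d > limit:
            continue
        diff = [i for i in range(len(a)) if a[i] != b[i]]
        for r in range(1, d):
            for sites in itertools.combinations(diff, r):
                p = list(a)
                for s in sites:
                    p[s] = b[s]
                candidates.add("".join(p))
    candidates -= set(observed)
    solutions = []
    for k in range(0, len(candidates) + 1):
        for subset in itertools.combinations(sorted(candidates), k):
            g = _valid(observed, set(subset), limit)
            if g:
                edges = frozenset(frozenset(e) for e in g.edges())
                solutions.append(edges)
        if solutions:
            break
    return set(solutions)


def _edge_profiles(net) -> set:
    return {
        frozenset((net.haplotypes[a].profile, net.haplotypes[b].profile))
        for a, b in net.graph.edges()
    }


class TestCollapse:
    def test_identical_individuals_merge(self):
        alleles = np.array([["A", "A", "G"], ["C", "C", "T"]], dtype="U1")
        m = SnpMatrix(site_ids=["s1", "s2"], sample_ids=["x", "y", "z"],
                      alleles=alleles)
        haps = collapse_haplotypes(m)
        assert len(haps) == 2
        assert haps[0].members == ["x", "y"] and haps[0].multiplicity == 2

    def test_missing_data_rejected(self):
        m = SnpMatrix(site_ids=["s1"], sample_ids=["x", "y", "z"],
                      alleles=np.array([["A", "?", "G"]], dtype="U1"))
        with pytest.raises(ValidationError, match="complete_case"):
            collapse_haplotypes(m)

    def test_matches_grouping_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            m = random_snp_matrix(rng, 8, 12, missing_rate=0.0)
            haps = collapse_haplotypes(m)
            profiles = {}
            for sid in m.sample_ids:
                profiles.setdefault(m.profile(sid), []).append(sid)
            assert {h.profile: h.members for h in haps} == profiles
            assert sum(h.multiplicity for h in haps) == m.n_samples


class TestConnectionLimit:
    def test_probability_matches_closed_form(self):
        # independent closed form: prod_{i=1}^{j-1}(m-i)/m = (m-1)!/((m-j)! m^{j-1})
        for m, j in [(100, 5), (500, 12), (1000, 30), (16, 4)]:
            closed = math.exp(
                math.lgamma(m) - math.lgamma(m - j + 1) - (j - 1) * math.log(m))
            assert parsimony_probability(j, m) == pytest.approx(closed, rel=1e-10)

    def test_limit_consistent_with_probability(self):
        for m in (100, 500, 1000, 20000):
            j = connection_limit(m, 0.95)
            assert parsimony_probability(j, m) >= 0.95
            assert parsimony_probability(j + 1, m) < 0.95

    def test_monotone_in_length(self):
        limits = [connection_limit(L, 0.95) for L in (50, 100, 500, 1000, 5000)]
        assert limits == sorted(limits)

    def test_non_increasing_in_confidence(self):
        for L in (100, 1000):
            limits = [connection_limit(L, c) for c in (0.5, 0.9, 0.95, 0.99)]
            assert limits == sorted(limits, reverse=True)

    def test_extreme_confidence_trusts_single_steps_only(self):
        assert connection_limit(50, 0.999999) == 1


class TestBuildNetwork:
    def test_two_haplotypes_distance_one(self):
        net = build_network(_haps(["A", "G"]), limit=5)
        assert net.graph.number_of_nodes() == 2
        assert net.graph.number_of_edges() == 1

    def test_three_haplotypes_share_inferred_median(self):
        # pairwise distance 2; the only single intermediate adjacent to all
        # three is the median profile AAA (verified by enumeration below)
        net = build_network(_haps(["GAA", "AGA", "AAG"]), limit=5)
        inferred = [h for h in net.haplotypes.values() if not h.observed]
        assert len(inferred) == 1 and inferred[0].profile == "AAA"
        assert net.graph.degree[inferred[0].hap_id] == 3
        # exhaustive enumeration over all 3-site A/G profiles
        adjacent_to_all = [
            "".join(p) for p in itertools.product("AG", repeat=3)
            if all(hamming("".join(p), o) == 1 for o in ("GAA", "AGA", "AAG"))
        ]
        assert adjacent_to_all == ["AAA"]

    def test_square_loop_retained(self):
        net = build_network(_haps(["AA", "AG", "GA", "GG"]), limit=3)
        assert net.graph.number_of_edges() == 4
        assert len(nx.cycle_basis(net.graph)) == 1  # one loop

    def test_pairs_beyond_limit_stay_separate(self):
        net = build_network(_haps(["AAAA", "GGGG"]), limit=3)
        assert len(net.components) == 2

    def test_connected_when_limit_reaches_max_distance(self):
        rng = np.random.default_rng(22)
        m = random_snp_matrix(rng, 9, 10, missing_rate=0.0)
        net = network_from_matrix(m)  # limit defaults to max pairwise distance
        assert len(net.components) == 1

    def test_determinism(self):
        profiles = ["ACGT", "ACGA", "GCGA", "GTTA", "ACTT"]
        n1 = build_network(_haps(profiles), limit=6)
        n2 = build_network(_haps(profiles), limit=6)
        assert n1.edges() == n2.edges()
        assert set(n1.haplotypes) == set(n2.haplotypes)

    def test_edges_are_unit_steps_and_intermediates_on_shortest_paths(self):
        rng = np.random.default_rng(23)
        m = random_snp_matrix(rng, 8, 12, missing_rate=0.0)
        net = network_from_matrix(m)
        for a, b in net.graph.edges():
            assert hamming(net.haplotypes[a].profile,
                           net.haplotypes[b].profile) == 1
        observed = [h.profile for h in net.haplotypes.values() if h.observed]
        for h in net.haplotypes.values():
            if h.observed:
                continue
            on_path = any(
                hamming(a, h.profile) + hamming(h.profile, b) == hamming(a, b)
                for a, b in itertools.combinations(observed, 2))
            assert on_path

    @pytest.mark.parametrize("profiles", [
        ["A", "G"],
        ["AA", "AG", "GG"],
        ["AA", "AG", "GA", "GG"],
        ["GAA", "AGA", "AAG"],
        ["AAAAA", "GAAAA", "AGAAA", "GGAAA", "AAAGA", "AAAGG"],
    ])
    def test_matches_brute_force_minimum_network(self, profiles):
        limit = max(hamming(a, b) for a, b in itertools.combinations(profiles, 2))
        net = build_network(_haps(profiles), limit=limit)
        solutions = steiner_oracle(profiles, limit)
        assert len(solutions) == 1, "fixture must have a unique optimum"
        (expected_edges,) = solutions
        got = {frozenset(p) for p in _edge_profiles(net)}
        assert got == expected_edges


class TestExport:
    def test_single_node_network(self, tmp_path):
        m = SnpMatrix(site_ids=["s1"], sample_ids=["x", "y"],
                      alleles=np.array([["A", "G"]], dtype="U1"))
        net = build_network(collapse_haplotypes(m), limit=1)
        export_network(net, {"x": "R1", "y": "R2"},
                       tmp_path / "n.graphml", tmp_path / "n.nex")
        back = nx.read_graphml(tmp_path / "n.graphml")
        assert back.number_of_nodes() == 2 and back.number_of_edges() == 1
        assert (tmp_path / "n.nex").read_text().startswith("#NEXUS")

    def test_graphml_roundtrip_preserves_topology(self, tmp_path, small_mito):
        matrix, _, truth = small_mito
        main = SnpMatrix(
            site_ids=list(matrix.site_ids),
            sample_ids=matrix.sample_ids[:-1],
            alleles=matrix.alleles[:, :-1],
        )
        complete = complete_case_sites(main)
        net = network_from_matrix(complete)
        region_of = {s: ("A" if i < 12 else "B")
                     for i, s in enumerate(main.sample_ids)}
        export_network(net, region_of, tmp_path / "n.graphml")
        back = nx.read_graphml(tmp_path / "n.graphml")
        assert set(back.nodes()) == set(net.graph.nodes())
        assert ({frozenset(e) for e in back.edges()}
                == {frozenset(e) for e in net.graph.edges()})
        # conservation: per-region member counts sum to the individuals
        total = sum(back.nodes[n]["n_A"] + back.nodes[n]["n_B"]
                    for n in back.nodes())
        assert total == len(main.sample_ids)

    def test_unknown_member_rejected(self):
        m = SnpMatrix(site_ids=["s1"], sample_ids=["x", "y"],
                      alleles=np.array([["A", "G"]], dtype="U1"))
        net = build_network(collapse_haplotypes(m), limit=1)
        with pytest.raises(ValidationError, match="metadata"):
            export_network(net, {"x": "R1"}, "/dev/null")
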