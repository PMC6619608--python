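"""Statistical-parsimony (TCS-style) haplotype networks.

Individuals are collapsed into haplotypes over complete-case SNP sites.
Haplotypes are then joined by unit-mutation edges, inserting inferred
intermediate nodes where observed haplotypes differ by more than one step,
up to a *connection limit* — the largest number of mutational steps for
which the estimated probability of parsimony (no site hit twice along the
path) still meets the confidence level.  Reusing an existing node whenever
its profile matches a required intermediate is what creates loops, the
alternative genealogical pathways characteristic of intraspecific networks.

The probability of parsimony is estimated with a multiple-hit model: for a
path of ``j`` mutational steps over a molecule of ``m`` sites, mutations
falling uniformly on sites hit ``j`` distinct sites with probability
``prod_{i=1}^{j-1} (1 - i/m)``.  The limit is the largest ``j`` whose
probability is at or above the confidence level (default 0.95).  This
estimator is non-decreasing in sequence length, non-increasing in
confidence, and tends to 1 as the confidence approaches 1 — a single step
is always parsimonious.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx

from .io import MISSING, SnpMatrix, ValidationError


@dataclass
class Haplotype:
    """A distinct allele combination; inferred intermediates have no members."""

    hap_id: str
    profile: str
    members: list[str] = field(default_factory=list)
    observed: bool = True

    @property
    def multiplicity(self) -> int:
        return len(self.members) if self.observed else 0


def collapse_haplotypes(matrix: SnpMatrix) -> list[Haplotype]:
    """Merge individuals with identical complete-case profiles.

    Haplotype ids H01, H02, ... follow first occurrence in the matrix
    sample order; the input must have no missing entries (reduce with
    :func:`orgvar.mito.complete_case_sites` first).
    """
    if (matrix.alleles == MISSING).any():
        raise ValidationError(
            "matrix contains missing entries; apply complete_case_sites first"
        )
    by_profile: dict[str, list[str]] = {}
    order: list[str] = []
    for sid in matrix.sample_ids:
        profile = matrix.profile(sid)
        if profile not in by_profile:
            by_profile[profile] = []
            order.append(profile)
        by_profile[profile].append(sid)
    return [
        Haplotype(hap_id=f"H{i + 1:02d}", profile=p, members=by_profile[p])
        for i, p in enumerate(order)
    ]


def parsimony_probability(steps: int, sequence_length: int) -> float:
    """Probability that ``steps`` mutations on ``sequence_length`` sites all
    hit distinct sites (so the observed differences equal the true number of
    mutational steps)."""
    if sequence_length < 1:
        raise ValidationError("sequence_length must be >= 1")
    if steps < 0:
        raise ValidationError("steps must be >= 0")
    p = 1.0
    for i in range(1, steps):
        p *= 1.0 - i / sequence_length
    return max(p, 0.0)


def connection_limit(sequence_length: int, confidence: float = 0.95) -> int:
    """Largest number of steps whose parsimony probability meets
    ``confidence``; at least 1 (a single step is always parsimonious)."""
    if not 0.0 < confidence < 1.0:
        raise ValidationError("confidence must be in (0, 1)")
    j = 1
    while j < sequence_length:
        if parsimony_probability(j + 1, sequence_length) < confidence:
            break
        j += 1
    return j


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValidationError("profiles of unequal length")
    return sum(1 for x, y in zip(a, b) if x != y)


@dataclass
class HaploNetwork:
    """Observed + inferred haplotype nodes joined by unit-mutation edges."""

    haplotypes: dict[str, Haplotype]
    graph: nx.Graph
    connection_limit: int

    @property
    def components(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self.graph)]

    def edges(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges())


def build_network(haplotypes: Sequence[Haplotype], limit: int) -> HaploNetwork:
    """Connect haplotypes by statistical parsimony up to ``limit`` steps.

    Distances d = 1..limit are processed in order; at each d, every observed
    pair at profile distance d not already joined by a network path of
    length <= d is connected by a path of d-1 inferred intermediates.
    Required intermediate profiles reuse any existing node with a matching
    profile (observed or inferred) — this reuse creates loops.  Determinism:
    pairs are processed in lexicographic (hap_id_a, hap_id_b) order and
    intermediate profiles mutate differing sites in ascending site order.
    """
    if limit < 1:
        raise ValidationError("limit must be >= 1")
    haps = {h.hap_id: h for h in haplotypes}
    profiles = [h.profile for h in haplotypes]
    if len(set(profiles)) != len(profiles):
        raise ValidationError("observed haplotypes must have distinct profiles")
    graph = nx.Graph()
    by_profile: dict[str, str] = {}
    for h in haplotypes:
        graph.add_node(h.hap_id)
        by_profile[h.profile] = h.hap_id
    n_inferred = 0

    def node_for(profile: str) -> str:
        nonlocal n_inferred
        if profile in by_profile:
            return by_profile[profile]
        n_inferred += 1
        hid = f"I{n_inferred:02d}"
        haps[hid] = Haplotype(hap_id=hid, profile=profile, members=[], observed=False)
        by_profile[profile] = hid
        graph.add_node(hid)
        return hid

    observed_ids = sorted(h.hap_id for h in haplotypes)
    for d in range(1, limit + 1):
        for ia, hap_a in enumerate(observed_ids):
            for hap_b in observed_ids[ia + 1:]:
                if hamming(haps[hap_a].profile, haps[hap_b].profile) != d:
                    continue
                try:
                    if nx.shortest_path_length(graph, hap_a, hap_b) <= d:
                        continue
                except nx.NetworkXNoPath:
                    pass
                profile = haps[hap_a].profile
                target = haps[hap_b].profile
                prev = hap_a
                diff_sites = [i for i in range(len(profile)) if profile[i] != target[i]]
                for site in diff_sites[:-1]:
                    profile = profile[:site] + target[site] + profile[site + 1:]
                    nid = node_for(profile)
                    graph.add_edge(prev, nid)
                    prev = nid
                graph.add_edge(prev, hap_b)
    return HaploNetwork(haplotypes=haps, graph=graph, connection_limit=limit)


def network_from_matrix(matrix: SnpMatrix, sequence_length: int | None = None,
                        confidence: float = 0.95,
                        limit: int | None = None) -> HaploNetwork:
    """Collapse a complete-case matrix and build its network.

    ``sequence_length`` is the length of the underlying molecule's
    alignment (not the SNP count) and feeds the connection limit; if
    omitted the limit defaults to the maximum pairwise distance, producing
    a fully connected network.
    """
    haps = collapse_haplotypes(matrix)
    if limit is None:
        if sequence_length is not None:
            limit = connection_limit(sequence_length, confidence)
        else:
            limit = max(
                (hamming(a.profile, b.profile)
                 for i, a in enumerate(haps) for b in haps[i + 1:]),
                default=1,
            )
            limit = max(limit, 1)
    return build_network(haps, limit)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def export_network(network: HaploNetwork,
                   node_metadata: Mapping[str, str],
                   graphml_path: str | Path,
                   nexus_path: str | Path | None = None) -> None:
    """Write the network as GraphML (and optionally a Nexus network block).

    ``node_metadata`` maps every member sample id to a region label; each
    node carries its multiplicity, observed flag and per-region member
    counts.  Unknown samples raise an error.
    """
    regions = sorted(set(node_metadata.values()))
    out = nx.Graph()
    for hid, hap in network.haplotypes.items():
        for m in hap.members:
            if m not in node_metadata:
                raise ValidationError(f"sample {m!r} missing from node metadata")
        attrs = {
            "multiplicity": hap.multiplicity,
            "observed": hap.observed,
            "members": ",".join(hap.members),
        }
        for r in regions:
            attrs[f"n_{r}"] = sum(1 for m in hap.members if node_metadata[m] == r)
        out.add_node(hid, **attrs)
    for a, b in network.graph.edges():
        out.add_edge(a, b, steps=1)
    nx.write_graphml(out, str(graphml_path))
    if nexus_path is not None:
        _write_nexus(network, nexus_path)


def _write_nexus(network: HaploNetwork, path: str | Path) -> None:
    """Minimal Nexus file with a Network block of vertices and edges."""
    lines = ["#NEXUS", "BEGIN NETWORK;", f"DIMENSIONS NVERTICES={network.graph.number_of_nodes()} "
             f"NEDGES={network.graph.number_of_edges()};", "VERTICES"]
    for hid in sorted(network.graph.nodes()):
        hap = network.haplotypes[hid]
        lines.append(f"  {hid} [label={hid},frequency={hap.multiplicity}]")
    lines.append(";")
    lines.append("EDGES")
    for i, (a, b) in enumerate(sorted(tuple(sorted(e)) for e in network.graph.edges())):
        lines.append(f"  e{i} {a} {b}")
    lines.append(";")
    lines.append("END;")
    Path(path).write_text("\n".join(lines) + "\n")
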