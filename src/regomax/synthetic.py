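"""Seeded generators of MetaCore-like signed directed networks.

The commercial MetaCore database cannot be shipped, so every downstream stage
is exercised on synthetic networks that emulate its published statistics:
mean out-degree ~7.3 links per node and activation/inhibition/neutral link
fractions 65157 : 49321 : 177713 (~0.223 / 0.169 / 0.608).  Out-degrees are
Poisson around the mean (truncated to [1, N-1]); link targets are drawn with
preferential attachment on the current in-degree, which produces the
heavy-tailed in-degree distribution that makes PageRank behavior
MetaCore-like.  The generator is a declared stand-in: no claim is made about
MetaCore's actual topology beyond size, density and sign mix.

The module also plants "ground-truth" external influencers into a background
network (for recovery tests of the selection procedure) and packages the
published 54-protein fibrosis group table, the 40 strongest sensitivity pairs
and the 14 (Pr, Ds(u/d)) summed-sensitivity pairs as fixtures.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .network import ProteinGroupTable, SignedDirectedNetwork

__all__ = [
    "SyntheticSpec",
    "PlantedTruth",
    "generate_metacore_like",
    "plant_external_influencers",
    "fibrosis_fixture",
    "DEFAULT_SIGN_FRACTIONS",
]

# exact ratios of the published MetaCore link counts 65157/49321/177713
DEFAULT_SIGN_FRACTIONS = (65157 / 292191, 49321 / 292191, 177713 / 292191)


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic network draw."""

    N: int
    mean_out_degree: float = 7.3
    sign_fractions: tuple = DEFAULT_SIGN_FRACTIONS
    attachment_exponent: float = 1.0
    # default 0: the emulated database's printed link counts satisfy the
    # doubled-network sparsity identity exactly, which requires unique
    # (source, target) interaction pairs; duplicates also make the split
    # PageRank identity P = P+ + P- only approximate
    multi_edge_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if abs(sum(self.sign_fractions) - 1.0) > 1e-12:
            raise ValueError("sign fractions must sum to 1")
        if self.attachment_exponent < 0:
            raise ValueError("attachment exponent must be >= 0")
        if not 0.0 <= self.multi_edge_prob < 1.0:
            raise ValueError("multi_edge_prob must be in [0, 1)")
        if self.mean_out_degree >= self.N - 1:
            raise ValueError("mean_out_degree must be < N - 1")


def generate_metacore_like(spec: SyntheticSpec) -> SignedDirectedNetwork:
    """Draw a seeded signed directed network per the spec.

    One private RNG stream per call; equal spec and seed give byte-identical
    edge lists.  Duplicate (source, target) draws are kept as multiplicity
    with probability ``multi_edge_prob``, otherwise redrawn.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.N
    out_deg = np.clip(rng.poisson(spec.mean_out_degree, size=n), 1, n - 1)
    in_deg = np.zeros(n)
    records: list[tuple[int, int]] = []
    for src in range(n):
        w = (in_deg + 1.0) ** spec.attachment_exponent
        w[src] = 0.0  # no self-loops
        p = w / w.sum()
        draws = rng.choice(n, size=int(out_deg[src]), replace=True, p=p)
        seen: set[int] = set()
        for t in draws:
            t = int(t)
            if t in seen and rng.random() >= spec.multi_edge_prob:
                for _ in range(64):  # redraw toward a fresh target
                    t = int(rng.choice(n, p=p))
                    if t not in seen:
                        break
            seen.add(t)
            records.append((src, t))
            in_deg[t] += 1
    signs = rng.choice(
        np.array([1, -1, 0]), size=len(records), p=np.asarray(spec.sign_fractions)
    )
    width = len(str(n - 1))
    ids = [f"n{j:0{width}d}" for j in range(n)]
    triples = [(ids[s], ids[t], int(g)) for (s, t), g in zip(records, signs)]
    return SignedDirectedNetwork.from_edge_records(triples, drop_self_loops=True)


@dataclass
class PlantedTruth:
    """Ground truth of a planted-influencer instance.

    ``planted_influencer_ids`` are externals wired to dominate influence on
    ``target_ids`` (the nodes playing the top-response role inside
    ``internal_ids``); ``boost`` is the number of extra convergent links added
    per planted influencer.
    """

    internal_ids: list = field(default_factory=list)
    target_ids: list = field(default_factory=list)
    planted_influencer_ids: list = field(default_factory=list)
    boost: int = 10

    def __post_init__(self):
        overlap = set(self.planted_influencer_ids) & set(self.internal_ids)
        if overlap:
            raise ValueError(
                f"planted influencers overlap the internal group: {sorted(overlap)}"
            )


def plant_external_influencers(
    network: SignedDirectedNetwork, truth: PlantedTruth, seed: int = 0
) -> SignedDirectedNetwork:
    """Augmented copy of the network with planted external influencers.

    Each planted influencer gains ``boost`` activation links into distinct
    members of ``target_ids`` (targets without a pre-existing link from the
    influencer are used first) plus ``boost`` incoming activation links from
    random other nodes, raising its PageRank.  The original is unmodified.
    """
    if truth.boost > len(truth.target_ids):
        raise ValueError("boost exceeds the number of distinct targets")
    rng = np.random.default_rng(seed)
    base = network.to_frame()
    records = [
        (s, t, {"activation": 1, "inhibition": -1, "neutral": 0}[g])
        for s, t, g in zip(base["source"], base["target"], base["sign"])
    ]
    existing = {(s, t) for s, t, _ in records}
    for pid in truth.planted_influencer_ids:
        fresh = [t for t in truth.target_ids if (pid, t) not in existing]
        stale = [t for t in truth.target_ids if (pid, t) in existing]
        chosen = (fresh + stale)[: truth.boost]
        for t in chosen:
            records.append((pid, t, 1))
        others = [nid for nid in network.node_ids if nid != pid]
        sources = rng.choice(len(others), size=truth.boost, replace=False)
        for s in sources:
            records.append((others[int(s)], pid, 1))
    return SignedDirectedNetwork.from_edge_records(
        records, drop_self_loops=True, nodes=network.node_ids
    )


DsPagerankRow = namedtuple(
    "DsPagerankRow", "rank Kg subgroup subgroup_index K protein Ds Pr"
)
TopPairRow = namedtuple(
    "TopPairRow", "Ks Kg_a label_a protein_a Kg_b label_b protein_b Dab"
)


def _data_path(name: str):
    return resources.files("regomax.data").joinpath(name)


def fibrosis_fixture():
    """Packaged fibrosis reference tables.

    Returns ``(groups, table3_pairs, table2_rows)``: the 54-row protein group
    table (unbound — the underlying commercial network is not shipped), the 14
    printed (Pr, Ds(u/d)) summed-sensitivity pairs, and the 40 printed
    strongest (a, b, Dab) sensitivity pairs.
    """
    gdf = pd.read_csv(_data_path("fibrosis_groups.tsv"), sep="\t",
                      dtype={"node_id": str, "protein_name": str})
    groups = ProteinGroupTable(gdf)
    t3 = pd.read_csv(_data_path("fibrosis_ds_pagerank.tsv"), sep="\t")
    table3 = [
        DsPagerankRow(int(r.rank), int(r.Kg), r.subgroup, int(r.subgroup_index),
                      int(r.K), r.protein, float(r.Ds_ud), float(r.Pr))
        for r in t3.itertuples()
    ]
    t2 = pd.read_csv(_data_path("fibrosis_top_pairs.tsv"), sep="\t")
    table2 = [
        TopPairRow(int(r.Ks), int(r.Kg_a), r.label_a, r.protein_a,
                   int(r.Kg_b), r.label_b, r.protein_b, float(r.Dab))
        for r in t2.itertuples()
    ]
    return groups, table3, table2
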