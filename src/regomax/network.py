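"""Signed directed interaction networks and protein-group annotation tables.

A network is a set of nodes (proteins) and directed links ``source -> target``
each carrying a sign: activation (+1), inhibition (-1) or neutral/unknown (0).
The simple (unsigned) network used for PageRank analysis treats the adjacency
as binary; signs and link multiplicities are preserved because the bifunctional
"Ising" doubling (see :mod:`regomax.ising`) needs them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "SignedDirectedNetwork",
    "ProteinGroupTable",
    "load_network",
    "load_group_table",
    "network_summary",
    "SIGN_TOKENS",
]

#: accepted sign tokens (case-insensitive) and their integer codes
SIGN_TOKENS = {"activation": 1, "inhibition": -1, "neutral": 0}
_SIGN_NAMES = {v: k for k, v in SIGN_TOKENS.items()}


@dataclass
class SignedDirectedNetwork:
    """Node/edge store for a signed directed network.

    Edges are kept aggregated: each distinct ``(source, target, sign)`` triple
    appears once, with ``multiplicity`` recording how many times it occurred in
    the input.  Self-loops are removed at construction when requested (the
    default, matching the convention of counting links without
    self-connections).
    """

    node_ids: list[str]
    src: np.ndarray          # int array, source node index per stored edge
    tgt: np.ndarray          # int array, target node index per stored edge
    sign: np.ndarray         # int8 array in {+1, -1, 0}
    multiplicity: np.ndarray  # int array, >= 1
    node_names: list[str] = field(default=None)  # display names, may repeat

    def __post_init__(self):
        if self.node_names is None:
            self.node_names = list(self.node_ids)
        self._index = {nid: i for i, nid in enumerate(self.node_ids)}
        if len(self._index) != len(self.node_ids):
            raise ValueError("node ids must be unique")

    # -- construction -----------------------------------------------------

    @classmethod
    def from_edge_records(
        cls,
        records,
        drop_self_loops: bool = True,
        node_names: dict[str, str] | None = None,
        nodes: list[str] | None = None,
    ) -> "SignedDirectedNetwork":
        """Build a network from an iterable of ``(source_id, target_id, sign)``.

        Node order is first-appearance order over sources then targets, read in
        input order; ``nodes`` may pre-register ids (e.g. isolated nodes).
        Duplicate identical triples are aggregated into multiplicity.
        """
        ids: list[str] = []
        index: dict[str, int] = {}
        if nodes:
            for nid in nodes:
                nid = str(nid)
                if nid not in index:
                    index[nid] = len(ids)
                    ids.append(nid)

        def _idx(nid: str) -> int:
            if nid not in index:
                index[nid] = len(ids)
                ids.append(nid)
            return index[nid]

        agg: dict[tuple[int, int, int], int] = {}
        for s_id, t_id, sgn in records:
            i, j = _idx(str(s_id)), _idx(str(t_id))
            if drop_self_loops and i == j:
                continue
            key = (i, j, int(sgn))
            agg[key] = agg.get(key, 0) + 1
        if agg:
            keys = np.array(sorted(agg), dtype=np.int64)
            mult = np.array([agg[tuple(k)] for k in keys], dtype=np.int64)
            src, tgt, sgn = keys[:, 0], keys[:, 1], keys[:, 2].astype(np.int8)
        else:
            src = tgt = np.zeros(0, dtype=np.int64)
            sgn = np.zeros(0, dtype=np.int8)
            mult = np.zeros(0, dtype=np.int64)
        names = [node_names.get(n, n) for n in ids] if node_names else None
        return cls(ids, src, tgt, sgn, mult, node_names=names)

    # -- basic properties -------------------------------------------------

    @property
    def N(self) -> int:
        return len(self.node_ids)

    @property
    def n_links(self) -> int:
        """Number of stored distinct signed edges (multiplicity not counted)."""
        return len(self.src)

    @property
    def N_plus(self) -> int:
        return int(np.sum(self.sign == 1))

    @property
    def N_minus(self) -> int:
        return int(np.sum(self.sign == -1))

    @property
    def N_neutral(self) -> int:
        return int(np.sum(self.sign == 0))

    def node_index(self, node_id: str) -> int:
        return self._index[node_id]

    # -- adjacency --------------------------------------------------------

    def adjacency(self, inverted: bool = False) -> sp.csc_matrix:
        """Binary adjacency ``A[i, j] = 1`` if node j points to node i.

        The simple network is directed and non-weighted: multiplicity and
        mixed-sign duplicate pairs collapse to a single entry.  ``inverted``
        flips every edge direction (the CheiRank construction).
        """
        s, t = (self.tgt, self.src) if inverted else (self.src, self.tgt)
        data = np.ones(len(s))
        a = sp.csc_matrix((data, (t, s)), shape=(self.N, self.N))
        a.sum_duplicates()
        a.data[:] = 1.0  # binary regardless of sign/multiplicity duplicates
        return a

    # -- I/O --------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = np.repeat(np.arange(self.n_links), self.multiplicity)
        return pd.DataFrame(
            {
                "source": [self.node_ids[i] for i in self.src[rows]],
                "target": [self.node_ids[i] for i in self.tgt[rows]],
                "sign": [_SIGN_NAMES[int(s)] for s in self.sign[rows]],
            }
        )

    def write(self, path) -> None:
        """Write the edge list as TSV, repeating edges per multiplicity."""
        self.to_frame().to_csv(path, sep="\t", index=False)


def load_network(edge_list_path, drop_self_loops: bool = True) -> SignedDirectedNetwork:
    """Load a signed edge list from TSV with columns source, target, sign.

    Sign tokens are ``activation`` / ``inhibition`` / ``neutral``
    (case-insensitive); anything else is a parse error naming the offending
    line.  Node order is first-appearance order.
    """
    df = pd.read_csv(edge_list_path, sep="\t", dtype=str)
    if df.empty:
        raise ValueError(f"empty edge list: {edge_list_path}")
    for col in ("source", "target", "sign"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in {edge_list_path}")
    tokens = df["sign"].str.strip().str.lower()
    bad = ~tokens.isin(SIGN_TOKENS)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        raise ValueError(
            f"unknown sign token {df['sign'].iloc[int(np.flatnonzero(bad.to_numpy())[0])]!r} "
            f"at line {line} of {edge_list_path}"
        )
    records = zip(df["source"], df["target"], tokens.map(SIGN_TOKENS))
    return SignedDirectedNetwork.from_edge_records(records, drop_self_loops=drop_self_loops)


def network_summary(network: SignedDirectedNetwork) -> dict:
    """Summary record: node count, link counts by sign, mean links per node."""
    n_links = network.n_links
    return {
        "N": network.N,
        "n_links": n_links,
        "N_plus": network.N_plus,
        "N_minus": network.N_minus,
        "N_neutral": network.N_neutral,
        "multiplicity_total": int(network.multiplicity.sum()),
        "mean_links_per_node": n_links / network.N if network.N else 0.0,
    }


class ProteinGroupTable:
    """Annotation table of a selected protein group.

    Rows carry a 1-based global group index ``Kg``, a subgroup label in
    ``{t, u, d, x}`` (TGF-beta, up-, down-, external X-proteins) with a
    per-subgroup 1-based index, a network node id and a display name.  Extra
    columns (e.g. global/local rank annotations) pass through untouched.
    """

    REQUIRED = ("Kg", "subgroup", "subgroup_index", "node_id", "protein_name")
    SUBGROUPS = ("t", "u", "d", "x")

    def __init__(self, frame: pd.DataFrame, network: SignedDirectedNetwork | None = None):
        for col in self.REQUIRED:
            if col not in frame.columns:
                raise ValueError(f"group table missing column {col!r}")
        df = frame.copy().reset_index(drop=True)
        df["Kg"] = df["Kg"].astype(int)
        df["subgroup_index"] = df["subgroup_index"].astype(int)
        df["subgroup"] = df["subgroup"].astype(str)
        kg = df["Kg"].to_numpy()
        if not np.array_equal(kg, np.arange(1, len(df) + 1)):
            raise ValueError("Kg values must be contiguous 1..Nr in row order")
        bad_sub = set(df["subgroup"]) - set(self.SUBGROUPS)
        if bad_sub:
            raise ValueError(f"unknown subgroup labels: {sorted(bad_sub)}")
        for sub, block in df.groupby("subgroup"):
            idx = np.sort(block["subgroup_index"].to_numpy())
            if not np.array_equal(idx, np.arange(1, len(block) + 1)):
                raise ValueError(f"subgroup_index not contiguous within {sub!r}")
        if df["node_id"].duplicated().any():
            dups = df.loc[df["node_id"].duplicated(), "node_id"].tolist()
            raise ValueError(f"duplicate node ids in group table: {dups}")
        self.frame = df
        self.network = None
        if network is not None:
            self.bind(network)

    def bind(self, network: SignedDirectedNetwork) -> "ProteinGroupTable":
        """Resolve node ids against a network; error lists any missing ids."""
        missing = [n for n in self.frame["node_id"] if n not in network._index]
        if missing:
            raise ValueError(f"group table node ids absent from network: {missing}")
        self.network = network
        self.frame["node_index"] = [network.node_index(n) for n in self.frame["node_id"]]
        return self

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def node_indices(self) -> np.ndarray:
        """Network node indices in Kg order (requires a bound network)."""
        if self.network is None:
            raise ValueError("group table not bound to a network")
        return self.frame["node_index"].to_numpy()

    def rows(self, subgroup: str) -> pd.DataFrame:
        """Rows of one subgroup, ordered by subgroup_index."""
        block = self.frame[self.frame["subgroup"] == subgroup]
        return block.sort_values("subgroup_index")

    def positions(self, subgroup: str, max_index: int | None = None) -> np.ndarray:
        """0-based positions (Kg - 1) of a subgroup within the group ordering."""
        block = self.rows(subgroup)
        if max_index is not None:
            block = block[block["subgroup_index"] <= max_index]
        return block["Kg"].to_numpy() - 1

    def label(self, position: int) -> str:
        """Short label like U1/D2/X9/T3 for the 0-based group position."""
        row = self.frame.iloc[position]
        return f"{row['subgroup'].upper()}{row['subgroup_index']}"

    def position_of_label(self, label: str) -> int:
        sub, idx = label[0].lower(), int(label[1:])
        block = self.frame[
            (self.frame["subgroup"] == sub) & (self.frame["subgroup_index"] == idx)
        ]
        if block.empty:
            raise ValueError(f"unknown group label {label!r}")
        return int(block["Kg"].iloc[0]) - 1

    def write(self, path) -> None:
        cols = [c for c in self.frame.columns if c != "node_index"]
        self.frame[cols].to_csv(path, sep="\t", index=False)


def load_group_table(path, network: SignedDirectedNetwork) -> ProteinGroupTable:
    """Load and validate a protein-group TSV against a network."""
    df = pd.read_csv(path, sep="\t", dtype={"node_id": str, "protein_name": str})
    return ProteinGroupTable(df, network=network)
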