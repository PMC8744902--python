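"""Exact PageRank-sensitivity derivatives and external-influencer selection.

The sensitivity of the reduced PageRank to an infinitesimal boost of a single
transition b -> a of the reduced Google matrix GR is the logarithmic
derivative

    D(b->a)(j) = (1 / Pr(j)) dPr_eps(j)/d_eps |_{eps=0}

where GR_eps multiplies element (a, b) by (1 + eps) and renormalizes column b
by 1 / (1 + eps GR(a, b)).  The derivative is evaluated exactly (no finite
differences): differentiating the perturbation gives the column-b matrix

    E(a, b) = GR(a, b) (1 - GR(a, b)),   E(c, b) = -GR(c, b) GR(a, b)  (c != a)

and the PageRank derivative P' solves (1 - GR) P' = E Pr on the zero-sum
subspace (the unit eigenvalue is deflated by adding the rank-1 term
ones ones^T / Nr, which leaves the zero-sum solution untouched).  The
sensitivity matrix is D[a, b] = D(b->a)(a).

The external-influencer ("X-protein") selection takes an internal protein
group, finds every outside node with a direct link into the top up/down
responders, computes the reduced matrix over internals + candidates, and ranks
candidates by the summed sensitivity of the top responders to them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .google import StochasticModel, compute_pagerank
from .network import ProteinGroupTable, SignedDirectedNetwork
from .reduced import ReducedSet, compute_reduced_google, reduced_pagerank

__all__ = [
    "SensitivityMatrix",
    "AggregateSensitivities",
    "XSelectionResult",
    "perturb_reduced_matrix",
    "pagerank_sensitivity",
    "sensitivity_matrix",
    "aggregate_sensitivity",
    "select_x_proteins",
]


@dataclass
class SensitivityMatrix:
    """D[a, b] = D(b->a)(a) over a ReducedSet's subset ordering."""

    D: np.ndarray
    Pr: np.ndarray
    epsilon_convention: str = "GR(a,b)(1+eps)/(1+eps GR(a,b)), column b renormalized"


def perturb_reduced_matrix(GR: np.ndarray, a: int, b: int, epsilon: float) -> np.ndarray:
    """Finite perturbation of the b -> a transition element of GR.

    Element (a, b) is multiplied by (1 + epsilon) and column b renormalized by
    1 / (1 + epsilon * GR(a, b)); every other column is untouched, so the
    result stays column-stochastic.
    """
    out = GR.copy()
    g = GR[a, b]
    out[:, b] = GR[:, b] / (1.0 + epsilon * g)
    out[a, b] = g * (1.0 + epsilon) / (1.0 + epsilon * g)
    return out


def _deflated_solve_matrix(GR: np.ndarray) -> np.ndarray:
    """LU-ready deflated system matrix A = 1 - GR + ones/Nr.

    For right-hand sides with zero column sum, the solution of A x = r has
    zero sum and satisfies (1 - GR) x = r exactly.
    """
    nr = GR.shape[0]
    return np.eye(nr) - GR + np.ones((nr, nr)) / nr


def pagerank_sensitivity(rs: ReducedSet, a: int, b: int) -> np.ndarray:
    """Exact derivative vector D(b->a)(.) for one perturbed element."""
    GR, Pr = rs.GR, rs.Pr
    g = GR[a, b]
    if g == 0.0:
        return np.zeros(rs.Nr)
    r = -g * Pr[b] * GR[:, b]
    r[a] += g * Pr[b]           # r = g Pr(b) (e_a - GR[:, b]) = E Pr
    A = _deflated_solve_matrix(GR)
    p_prime = scipy.linalg.solve(A, r)
    return p_prime / Pr


def sensitivity_matrix(rs: ReducedSet) -> SensitivityMatrix:
    """All-pairs sensitivity matrix D[a, b] (diagonal included).

    Vectorized over pairs: with A the deflated system matrix and
    B = A^{-1} GR,  D[a, b] = GR(a, b) Pr(b) (A^{-1}[a, a] - B[a, b]) / Pr(a).
    """
    GR, Pr = rs.GR, rs.Pr
    A = _deflated_solve_matrix(GR)
    Ainv = scipy.linalg.inv(A)
    B = Ainv @ GR
    diag = np.diag(Ainv)
    D = GR * (diag[:, None] - B) * Pr[None, :] / Pr[:, None]
    return SensitivityMatrix(D=D, Pr=Pr)


@dataclass
class AggregateSensitivities:
    """Group-aggregated sensitivities over a 54-style protein group.

    * ``Ds_TGFbeta`` — per up/down protein a, the sum over the TGF-beta
      columns, with the descending rank index ``Ks_TGFbeta``;
    * ``Ds_ud`` — per TGF-beta or X column b, the sum over all up/down rows;
    * ``pair_ranking`` — every (a in up/down, b in TGF-beta or X) pair ordered
      by decreasing D[a, b] with rank index Ks.
    """

    Ds_TGFbeta: pd.DataFrame
    Ds_ud: pd.DataFrame
    pair_ranking: pd.DataFrame


def aggregate_sensitivity(
    sm: SensitivityMatrix, groups: ProteinGroupTable
) -> AggregateSensitivities:
    D = sm.D
    if D.shape[0] != len(groups):
        raise ValueError(
            f"sensitivity matrix size {D.shape[0]} does not match group table "
            f"size {len(groups)}"
        )
    rows_ud = np.concatenate([groups.positions("u"), groups.positions("d")])
    rows_ud.sort()
    cols_tx = np.concatenate([groups.positions("t"), groups.positions("x")])
    cols_tx.sort()
    gf = groups.frame

    # TGF-beta influence on each up/down protein: sum over t columns
    cols_t = groups.positions("t")
    ds_t = D[np.ix_(rows_ud, cols_t)].sum(axis=1)
    order = np.lexsort((rows_ud, -ds_t))
    ks_t = np.empty(len(rows_ud), dtype=np.int64)
    ks_t[order] = np.arange(1, len(rows_ud) + 1)
    ds_tgf = pd.DataFrame(
        {
            "Kg": rows_ud + 1,
            "protein": gf["protein_name"].to_numpy()[rows_ud],
            "Ds_TGFbeta": ds_t,
            "Ks_TGFbeta": ks_t,
        }
    )

    # global up/down influence of each TGF-beta or X protein: sum over u,d rows
    ds_ud_vals = D[np.ix_(rows_ud, cols_tx)].sum(axis=0)
    order = np.lexsort((cols_tx, -ds_ud_vals))
    ds_ud = pd.DataFrame(
        {
            "Kg": cols_tx[order] + 1,
            "protein": gf["protein_name"].to_numpy()[cols_tx[order]],
            "Ds_ud": ds_ud_vals[order],
            "Pr": sm.Pr[cols_tx[order]],
        }
    )
    ds_ud.insert(0, "rank", np.arange(1, len(ds_ud) + 1))

    # full pair ranking (e.g. 40 x 14 = 560 pairs for the 54-protein group)
    aa, bb = np.meshgrid(rows_ud, cols_tx, indexing="ij")
    aa, bb = aa.ravel(), bb.ravel()
    vals = D[aa, bb]
    order = np.lexsort((bb, aa, -vals))
    pairs = pd.DataFrame(
        {
            "Ks": np.arange(1, len(vals) + 1),
            "Kg_a": aa[order] + 1,
            "protein_a": gf["protein_name"].to_numpy()[aa[order]],
            "Kg_b": bb[order] + 1,
            "protein_b": gf["protein_name"].to_numpy()[bb[order]],
            "Dab": vals[order],
        }
    )
    return AggregateSensitivities(Ds_TGFbeta=ds_tgf, Ds_ud=ds_ud, pair_ranking=pairs)


@dataclass
class XSelectionResult:
    """Outcome of the external-influencer selection procedure."""

    candidate_ids: list            # all candidate externals, PageRank-ordered
    n_candidate_links: int         # distinct (candidate, target) link pairs
    target_ids: list               # the top up/down response proteins
    reduced: ReducedSet            # GR over internals + candidates
    D: SensitivityMatrix
    ds_5plus5: pd.DataFrame        # per-candidate summed sensitivity, ranked
    selected_ids: list             # n_select winners, local-PageRank-ordered
    groups_extended: ProteinGroupTable  # internals + selected as Kx rows


def select_x_proteins(
    network: SignedDirectedNetwork,
    model: StochasticModel,
    groups44: ProteinGroupTable,
    n_top_up: int = 5,
    n_top_down: int = 5,
    n_select: int = 10,
    pagerank: np.ndarray | None = None,
) -> XSelectionResult:
    """Select the external proteins most influential on the internal group.

    Candidates are all nodes outside the internal group with at least one
    direct link (any sign) into the top ``n_top_up`` up- or top ``n_top_down``
    down-proteins.  The reduced Google matrix is computed over the internals
    (group-table order) followed by the candidates (global PageRank order),
    its sensitivity matrix evaluated, and each candidate b scored by
    Ds(5+5)(b): the sum of D[a, b] over the top-responder rows a.  The
    ``n_select`` highest scorers are returned as new Kx rows ordered by local
    PageRank.
    """
    if groups44.network is not network:
        groups44.bind(network)
    internal_idx = groups44.node_indices
    internal_set = set(internal_idx.tolist())

    top_positions = np.concatenate(
        [groups44.positions("u", n_top_up), groups44.positions("d", n_top_down)]
    )
    target_idx = internal_idx[top_positions]
    target_set = set(target_idx.tolist())

    # candidates: outside nodes with >= 1 direct edge into a target
    into_target = np.isin(network.tgt, list(target_set))
    cand_pairs = {
        (int(s), int(t))
        for s, t in zip(network.src[into_target], network.tgt[into_target])
        if int(s) not in internal_set
    }
    cand_set = sorted({s for s, _ in cand_pairs})
    if not cand_set:
        raise ValueError(
            "no external candidates: no node outside the internal group links "
            "into the top response proteins"
        )
    if pagerank is None:
        pagerank = compute_pagerank(model).P
    # ordered by global PageRank index (descending probability), ties by id
    cand_order = sorted(
        cand_set, key=lambda j: (-pagerank[j], network.node_ids[j])
    )
    subset = np.concatenate([internal_idx, np.array(cand_order, dtype=np.int64)])

    rs = compute_reduced_google(model, subset, pagerank=pagerank)
    sm = sensitivity_matrix(rs)

    n_int = len(internal_idx)
    cand_cols = np.arange(n_int, len(subset))
    ds = sm.D[np.ix_(top_positions, cand_cols)].sum(axis=0)
    order = np.argsort(-ds, kind="stable")
    ds_table = pd.DataFrame(
        {
            "node_id": [network.node_ids[cand_order[i]] for i in order],
            "Ds_5plus5": ds[order],
            "global_P": [pagerank[cand_order[i]] for i in order],
        }
    )
    ds_table.insert(0, "rank", np.arange(1, len(ds_table) + 1))

    winners = [cand_order[i] for i in order[:n_select]]
    # order the selected by local PageRank of the reduced matrix
    pr_local = reduced_pagerank(rs.GR)
    winner_cols = [n_int + cand_order.index(w) for w in winners]
    winners_sorted = [w for _, w in sorted(
        zip(-pr_local[winner_cols], winners),
        key=lambda p: p[0],
    )]

    ext = groups44.frame.drop(columns=["node_index"], errors="ignore").copy()
    new_rows = pd.DataFrame(
        {
            "Kg": np.arange(len(ext) + 1, len(ext) + 1 + len(winners_sorted)),
            "subgroup": "x",
            "subgroup_index": np.arange(1, len(winners_sorted) + 1),
            "node_id": [network.node_ids[w] for w in winners_sorted],
            "protein_name": [network.node_names[w] for w in winners_sorted],
        }
    )
    extended = ProteinGroupTable(
        pd.concat([ext, new_rows], ignore_index=True), network=network
    )
    return XSelectionResult(
        candidate_ids=[network.node_ids[j] for j in cand_order],
        n_candidate_links=len(cand_pairs),
        target_ids=[network.node_ids[j] for j in target_idx],
        reduced=rs,
        D=sm,
        ds_5plus5=ds_table,
        selected_ids=[network.node_ids[w] for w in winners_sorted],
        groups_extended=extended,
    )
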