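"""End-to-end orchestration: ranks -> selection -> reduction -> sensitivity ->
fits -> diagrams -> Ising magnetization, driven by a YAML config.

Config schema (all paths relative to the config file's directory)::

    seed: 1
    alpha: 0.85
    network:
      edges: edges.tsv            # either a TSV edge list ...
      # synthetic: {n: 600, mean_out_degree: 7.3, seed: 1}   # ... or a draw
    groups: groups.tsv            # optional; enables reduction stages
    selection:
      enabled: true               # X-protein selection (needs groups)
      n_top_up: 5
      n_top_down: 5
      n_select: 10
    diagrams:
      top_nodes: [U1, U2, D1, D2, X1]
      mode: friend
    ising: true
    fits: true
    output_dir: out

Every stage error is re-raised with the stage name.  Numeric table output is
printed at 6 decimals; a ``run_log.yaml`` records parameters and tolerances.
"""

from __future__ import annotations

import pathlib

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diagrams import assign_subgroup_colors, build_friend_follower_diagram, export_diagram
from .fits import fit_linear_through_origin, fit_powerlaw_loglog, make_report_tables
from .google import build_google_matrix, compute_pagerank
from .ising import build_ising_network, ising_pagerank_magnetization
from .network import load_group_table, load_network, network_summary
from .reduced import compute_reduced_google, local_rank_indices
from .sensitivity import aggregate_sensitivity, select_x_proteins, sensitivity_matrix
from .synthetic import SyntheticSpec, generate_metacore_like

__all__ = ["run_pipeline"]

_FLOAT_FMT = "%.6f"


class StageError(RuntimeError):
    """Pipeline failure annotated with the stage that raised it."""


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def _write(df: pd.DataFrame, path: pathlib.Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_pipeline(config, base_dir=None) -> pathlib.Path:
    """Run the full analysis described by ``config`` (path or dict).

    Returns the output directory.  Stages needing a group table are skipped
    when none is configured (partial-pipeline contract: ranks and Ising
    magnetization always run).
    """
    if isinstance(config, (str, pathlib.Path)):
        cfg_path = pathlib.Path(config)
        base_dir = base_dir or cfg_path.parent
        with open(cfg_path) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(config)
        base_dir = pathlib.Path(base_dir or ".")
    out_dir = base_dir / cfg.get("output_dir", "out")
    out_dir.mkdir(parents=True, exist_ok=True)
    alpha = float(cfg.get("alpha", 0.85))
    seed = int(cfg.get("seed", 0))

    network = _load_network_stage(cfg, base_dir, seed)
    network.write(out_dir / "edges_used.tsv")

    model, model_inv, ranks = _rank_stage(network, alpha, out_dir)

    groups = None
    if cfg.get("groups"):
        groups = load_group_table(base_dir / cfg["groups"], network)

    sel_cfg = cfg.get("selection") or {}
    if sel_cfg.get("enabled") and groups is not None:
        groups = _selection_stage(network, model, groups, sel_cfg, ranks, out_dir)

    if groups is not None:
        _reduction_stages(network, model, model_inv, groups, ranks, cfg, out_dir)

    if cfg.get("ising", True):
        _ising_stage(network, alpha, out_dir)

    log = {
        "version": __version__,
        "seed": seed,
        "alpha": alpha,
        "pagerank_tol": 1e-14,
        "network_summary": {k: (float(v) if isinstance(v, float) else int(v))
                            for k, v in network_summary(network).items()},
    }
    with open(out_dir / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh)
    return out_dir


@_stage("network")
def _load_network_stage(cfg, base_dir, seed):
    net_cfg = cfg.get("network") or {}
    if "edges" in net_cfg:
        return load_network(base_dir / net_cfg["edges"])
    if "synthetic" in net_cfg:
        syn = dict(net_cfg["synthetic"])
        syn.setdefault("seed", seed)
        n = syn.pop("n")
        return generate_metacore_like(SyntheticSpec(N=int(n), **syn))
    raise ValueError("config needs network.edges or network.synthetic")


@_stage("ranks")
def _rank_stage(network, alpha, out_dir):
    model = build_google_matrix(network, alpha=alpha)
    model_inv = build_google_matrix(network, alpha=alpha, inverted=True)
    pr = compute_pagerank(model)
    cr = compute_pagerank(model_inv)
    _write(pd.DataFrame({"node_id": network.node_ids, "P": pr.P, "K": pr.K,
                         "P_star": cr.P, "K_star": cr.K}),
           out_dir / "ranks.tsv")
    return model, model_inv, {"P": pr, "P_star": cr}


@_stage("selection")
def _selection_stage(network, model, groups, sel_cfg, ranks, out_dir):
    res = select_x_proteins(
        network, model, groups,
        n_top_up=int(sel_cfg.get("n_top_up", 5)),
        n_top_down=int(sel_cfg.get("n_top_down", 5)),
        n_select=int(sel_cfg.get("n_select", 10)),
        pagerank=ranks["P"].P,
    )
    _write(res.ds_5plus5, out_dir / "selection_ds.tsv")
    res.groups_extended.write(out_dir / "groups_extended.tsv")
    return res.groups_extended


@_stage("reduction")
def _reduction_stages(network, model, model_inv, groups, ranks, cfg, out_dir):
    subset = groups.node_indices
    rs = compute_reduced_google(model, subset, pagerank=ranks["P"].P)
    labels = [groups.label(i) for i in range(len(groups))]
    for name, mat in (("GR", rs.GR), ("Grr", rs.Grr), ("Gpr", rs.Gpr),
                      ("Gqr", rs.Gqr), ("Gqrnd", rs.Gqr_nd)):
        df = pd.DataFrame(mat, index=labels, columns=labels)
        df.to_csv(out_dir / f"gr_{name}.tsv", sep="\t", float_format=_FLOAT_FMT)
    _write(pd.DataFrame([rs.weights]), out_dir / "gr_weights.tsv")

    k_local, k_star_local = local_rank_indices(
        model, model_inv, subset,
        pagerank=ranks["P"].P, cheirank=ranks["P_star"].P)
    _write(pd.DataFrame({"label": labels, "K_local": k_local,
                         "K_star_local": k_star_local}),
           out_dir / "local_ranks.tsv")

    sm_ = sensitivity_matrix(rs)
    pd.DataFrame(sm_.D, index=labels, columns=labels).to_csv(
        out_dir / "sensitivity_D.tsv", sep="\t", float_format=_FLOAT_FMT)
    agg = aggregate_sensitivity(sm_, groups)
    for name, df in make_report_tables(agg).items():
        _write(df, out_dir / f"table_{name}.tsv")

    if cfg.get("fits", True):
        pairs = list(zip(agg.Ds_ud["Pr"], agg.Ds_ud["Ds_ud"]))
        rows = []
        lin = fit_linear_through_origin(pairs)
        rows.append({"model": lin.model, **lin.params,
                     **{f"se_{k}": v for k, v in lin.stderr.items()}})
        try:
            pw = fit_powerlaw_loglog(pairs)
            rows.append({"model": pw.model, **pw.params,
                         **{f"se_{k}": v for k, v in pw.stderr.items()}})
        except ValueError:
            pass  # non-positive sensitivities: power law undefined
        _write(pd.DataFrame(rows), out_dir / "fits.tsv")

    dia_cfg = cfg.get("diagrams") or {}
    if dia_cfg:
        g_nd = rs.Grr + rs.Gqr_nd
        mode = dia_cfg.get("mode", "friend")
        graph = build_friend_follower_diagram(
            rs.GR, groups, dia_cfg["top_nodes"], mode=mode, source_matrix="GR")
        assign_subgroup_colors(graph, g_nd, groups)
        export_diagram(graph, out_dir / f"diagram_{mode}_GR.dot", format="dot")


@_stage("ising")
def _ising_stage(network, alpha, out_dir):
    inet = build_ising_network(network)
    mag = ising_pagerank_magnetization(inet, alpha=alpha)
    _write(pd.DataFrame({"node_id": network.node_ids,
                         "P_plus": mag.P_plus, "P_minus": mag.P_minus,
                         "P_sum": mag.P_sum, "M": mag.M}),
           out_dir / "magnetization.tsv")
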