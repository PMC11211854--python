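"""End-to-end analysis: graph -> filter -> fit -> screen -> test -> score.

``run_analysis`` is the in-memory engine; ``run_pipeline`` wraps it with
file IO and writes the tidy results table (one row per pair per method),
edge-score tables for significant pairs, and a JSON run log carrying the
seed and a config hash so every output row is traceable.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .baselines import log_normalize_vector, naive_correlations
from .copula import fit_copula
from .graph import SpatialGraph, build_grid_graph, build_radius_graph, celltype_subgraph
from .io import RunConfig, align_coords, config_hash, read_coords, read_expression
from .lrdb import CountMatrix, LRPair, collapse_complex, filter_pairs, parse_lr_database
from .scoring import edge_scores
from .significance import PairResult, bh_adjust, permutation_pvalue
from .simulate import measure_sparsity

logger = logging.getLogger(__name__)

__all__ = ["run_analysis", "run_pipeline", "results_to_frame"]


def _build_graph(coords, layout, spacing, self_loops, labels):
    if layout in ("hex", "rect"):
        return build_grid_graph(coords, layout=layout, spacing=spacing,
                                self_loops=self_loops, labels=labels)
    if layout == "radius":
        return build_radius_graph(coords, threshold=spacing,
                                  self_loops=self_loops, labels=labels)
    raise ValueError(f"unknown graph layout {layout!r}")


def run_analysis(
    m: CountMatrix,
    coords: np.ndarray,
    pairs: list[LRPair],
    labels=None,
    graph_layout: str = "rect",
    graph_spacing: float = 1.0,
    self_loops: bool = True,
    celltype_pair: tuple | None = None,
    n_perm: int = 500,
    seed: int = 0,
    min_spots: int | None = None,
    screen_mode: str = "default",
    with_baselines: bool = True,
):
    """Fit every usable ligand-receptor pair and test its correlation.

    Returns (results, per_pair_scores, info): a list of
    :class:`PairResult`, a dict pair_id -> (graph, fit, edge scores) for
    non-screened copula fits, and a bookkeeping dict with the filtered /
    screened pair counts.
    """
    g = _build_graph(coords, graph_layout, graph_spacing, self_loops, labels)
    vertex_subset = None
    if celltype_pair is not None:
        g = celltype_subgraph(g, *celltype_pair)
        vertex_subset = g.parent_vertices
        if g.n_edges == 0:
            warnings.warn("cell-type restriction left no edges", stacklevel=2)
            return [], {}, {"n_filtered": 0, "n_screened": 0, "n_tested": 0}

    usable = filter_pairs(m, pairs, min_spots=min_spots)
    info = {"n_input": len(pairs), "n_filtered": len(usable)}

    def _subset(vec):
        return vec[vertex_subset] if vertex_subset is not None else vec

    depths = _subset(m.depths)
    ss = np.random.SeedSequence(seed)
    pair_seeds = ss.spawn(max(len(usable), 1))

    results: list[PairResult] = []
    per_pair_scores: dict[str, tuple] = {}
    n_screened = 0
    for pair, pseed in zip(usable, pair_seeds):
        lig = _subset(collapse_complex(m, pair.ligand_genes))
        rec = _subset(collapse_complex(m, pair.receptor_genes))
        sp_l = measure_sparsity(lig)
        sp_r = measure_sparsity(rec)
        fit = fit_copula(g, lig, rec, depths, screen_mode=screen_mode)
        if fit.screened_out:
            n_screened += 1
            results.append(PairResult(
                pair_id=pair.pair_id, method="copulacci", rho_hat=fit.rho,
                p_value=float("nan"), q_value=float("nan"),
                n_edges=g.n_edges, n_permutations=0,
                sparsity_ligand=sp_l, sparsity_receptor=sp_r,
                screened=True, screen_reason=fit.screen_reason,
            ))
        else:
            rng = np.random.default_rng(pseed)
            p, _null = permutation_pvalue(
                g, lig, rec, depths, fit.rho, n_perm=n_perm, seed=rng,
                mu_l=fit.params.mu_l, mu_r=fit.params.mu_r,
            )
            results.append(PairResult(
                pair_id=pair.pair_id, method="copulacci", rho_hat=fit.rho,
                p_value=p, q_value=float("nan"),
                n_edges=g.n_edges, n_permutations=n_perm,
                sparsity_ligand=sp_l, sparsity_receptor=sp_r,
            ))
            per_pair_scores[pair.pair_id] = (g, fit, edge_scores(g, lig, rec, depths, fit))

        if with_baselines:
            x = log_normalize_vector(lig, depths)
            y = log_normalize_vector(rec, depths)
            try:
                pear, spear = naive_correlations(x, y)
            except ValueError:
                pear = spear = float("nan")
            for method, rho_hat in (("pearson", pear), ("spearman", spear)):
                results.append(PairResult(
                    pair_id=pair.pair_id, method=method, rho_hat=rho_hat,
                    p_value=float("nan"), q_value=float("nan"),
                    n_edges=g.n_edges, n_permutations=0,
                    sparsity_ligand=sp_l, sparsity_receptor=sp_r,
                ))

    # BH across all tested (non-screened) copula pairs
    tested = [res for res in results if res.method == "copulacci" and not res.screened
              and np.isfinite(res.p_value)]
    if tested:
        qvals = bh_adjust([res.p_value for res in tested])
        for res, q in zip(tested, qvals):
            res.q_value = float(q)

    info["n_screened"] = n_screened
    info["n_tested"] = len(tested)
    return results, per_pair_scores, info


def results_to_frame(results: list[PairResult]) -> pd.DataFrame:
    """Tidy results table, copula rows ranked by (q, p, -|rho_hat|)."""
    df = pd.DataFrame([vars(res) for res in results])
    if df.empty:
        return df
    df["_absrho"] = df["rho_hat"].abs()
    df = df.sort_values(
        by=["method", "q_value", "p_value", "_absrho"],
        ascending=[True, True, True, False],
        na_position="last",
        kind="mergesort",
    ).drop(columns="_absrho")
    cop = df[df.method == "copulacci"]
    rest = df[df.method != "copulacci"]
    return pd.concat([cop, rest], ignore_index=True)


def run_pipeline(cfg: RunConfig):
    """File-based pipeline entry point; returns the results DataFrame."""
    m = read_expression(cfg.matrix_path, format=cfg.matrix_format)
    coords_df = align_coords(m, read_coords(cfg.coords_path))
    coords = coords_df[["x", "y"]].to_numpy(dtype=float)
    labels = coords_df["cell_type"].to_numpy() if "cell_type" in coords_df else None
    pairs = parse_lr_database(cfg.lrdb_path)

    results, per_pair_scores, info = run_analysis(
        m, coords, pairs, labels=labels,
        graph_layout=cfg.graph_layout, graph_spacing=cfg.graph_spacing,
        self_loops=cfg.self_loops, celltype_pair=cfg.celltype_pair,
        n_perm=cfg.n_perm, seed=cfg.seed, min_spots=cfg.min_spots,
        screen_mode=cfg.screen_mode,
    )
    if info.get("n_filtered", 0) == 0:
        logger.warning("no ligand-receptor pairs survived filtering")

    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    header = f"# seed={cfg.seed} config={chash} version={__version__}\n"

    df = results_to_frame(results)
    with open(out / "pair_results.tsv", "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")

    for pair_id, (g, fit, scores) in per_pair_scores.items():
        row = df[(df.pair_id == pair_id) & (df.method == "copulacci")]
        if row.empty or not (row.q_value.iloc[0] <= cfg.fdr_threshold):
            continue
        safe = pair_id.replace("::", "__")
        with open(out / f"edge_scores_{safe}.tsv", "w") as fh:
            fh.write(header)
            fh.write("i\tj\tx_i\ty_i\tx_j\ty_j\tz_l\tz_r\tscore\n")
            for es in scores:
                i, j = es.edge
                xi, yi = g.coords[i] if g.coords is not None else (np.nan, np.nan)
                xj, yj = g.coords[j] if g.coords is not None else (np.nan, np.nan)
                fh.write(
                    f"{i}\t{j}\t{xi:.6g}\t{yi:.6g}\t{xj:.6g}\t{yj:.6g}\t"
                    f"{es.z_l:.10g}\t{es.z_r:.10g}\t{es.score:.10g}\n"
                )

    log = {
        "seed": cfg.seed,
        "config_hash": chash,
        "version": __version__,
        **info,
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return df
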