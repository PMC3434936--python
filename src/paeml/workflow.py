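"""End-to-end analysis pipeline: one call chains validation, both rooting
conventions, parsimony and likelihood searches with bootstraps, UPGMA,
extinct-taxa scenarios and per-species stochastic maps, writing every
output plus a manifest sufficient to re-run the command bit-identically.

The pipeline is a pure composition of the library operations; nothing is
computed here that the modules do not expose.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import __version__
from .cluster import distance_matrix, upgma
from .matrix import TaxonAreaMatrix, add_allzero_outgroup
from .mk import MkModel
from .parsimony import fitch_length
from .scenarios import run_scenarios
from .search import SearchConfig, bootstrap, search
from .stochmap import map_character
from .trees import AreaTree, lundberg_root, rf_distance
from .io import read_matrix, write_matrix, write_tree


@dataclass
class WorkflowConfig:
    seed: int = 0
    outgroup_name: str = "ROOT"
    gamma: bool = True
    invariant: bool = False
    mp_starts: int = 10
    ml_starts: int = 2
    swap: str = "spr"
    mp_replicates: int = 100
    ml_replicates: int = 0          # likelihood bootstrap off at desk scale
    fractions: tuple = (0.5, 1.0, 1.5, 2.0)
    scenario_starts: int = 1
    map_species: str = "endemics"   # "all" | "endemics" | "none" | comma list
    map_samples: int = 200
    metric: str = "hamming"


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_workflow(
    matrix: TaxonAreaMatrix | str | os.PathLike,
    out_dir: str | os.PathLike,
    config: WorkflowConfig | None = None,
) -> dict:
    """Run the full taxon-area analysis and write results under ``out_dir``.

    Returns the manifest dictionary (also written as ``manifest.json``).
    """
    cfg = config or WorkflowConfig()
    out = os.fspath(out_dir)
    os.makedirs(out, exist_ok=True)
    stages: dict[str, float] = {}
    manifest: dict = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": [],
    }

    def emit(name: str) -> str:
        path = os.path.join(out, name)
        manifest["outputs"].append(name)
        return path

    if isinstance(matrix, (str, os.PathLike)):
        manifest["input"] = {
            "path": os.fspath(matrix), "sha256": _sha256(os.fspath(matrix))
        }
        matrix = read_matrix(matrix)
    else:
        manifest["input"] = {"provenance": matrix.provenance}
    manifest["n_areas"] = matrix.n_areas
    manifest["n_species"] = matrix.n_species

    rooted = add_allzero_outgroup(matrix, cfg.outgroup_name)
    write_matrix(rooted, emit("matrix_with_outgroup.nex"), "nexus")

    # --- parsimony ----------------------------------------------------
    t0 = time.time()
    mp_cfg = SearchConfig(
        objective="parsimony", n_starts=cfg.mp_starts, swap=cfg.swap,
        seed=cfg.seed,
    )
    mp_res = search(rooted, mp_cfg)
    mp_tree = mp_res.trees[0]
    mp_score = fitch_length(mp_tree, rooted)
    write_tree(mp_tree, emit("mp_tree.nwk"))
    mp_pruned = mp_tree.prune_tips([cfg.outgroup_name])
    write_tree(lundberg_root(mp_pruned, matrix), emit("mp_tree_lundberg.nwk"))
    manifest["mp"] = {
        "tree_length": mp_score.length,
        "ci": mp_score.ci,
        "ri": mp_score.ri,
        "ci_informative_only": mp_score.ci_informative_only,
        "ri_informative_only": mp_score.ri_informative_only,
        "n_optimal_trees": mp_res.n_optimal,
    }
    stages["mp_search"] = time.time() - t0

    if cfg.mp_replicates > 0:
        t0 = time.time()
        bs_cfg = replace(mp_cfg, bootstrap_replicates=cfg.mp_replicates,
                         seed=cfg.seed + 1)
        mp_bs_tree, mp_supports = bootstrap(rooted, bs_cfg, best_tree=mp_tree)
        write_tree(mp_bs_tree, emit("mp_tree_bootstrap.nwk"))
        stages["mp_bootstrap"] = time.time() - t0

    # --- likelihood ---------------------------------------------------
    t0 = time.time()
    ml_cfg = SearchConfig(
        objective="likelihood", n_starts=cfg.ml_starts, swap=cfg.swap,
        gamma=cfg.gamma, invariant=cfg.invariant, seed=cfg.seed,
    )
    ml_res = search(rooted, ml_cfg)
    ml_tree = ml_res.trees[0]
    write_tree(ml_tree, emit("ml_tree.nwk"))
    ml_pruned = ml_tree.prune_tips([cfg.outgroup_name])
    write_tree(lundberg_root(ml_pruned, matrix), emit("ml_tree_lundberg.nwk"))
    manifest["ml"] = {
        "log_likelihood": ml_res.fit.log_likelihood,
        "neg_log_likelihood": -ml_res.fit.log_likelihood,
        "gamma_shape": ml_res.fit.gamma_shape,
        "p_invariant": ml_res.fit.p_invariant,
        "rf_mp_vs_ml_unrooted": rf_distance(mp_pruned, ml_pruned),
    }
    stages["ml_search"] = time.time() - t0

    if cfg.ml_replicates > 0:
        t0 = time.time()
        bs_cfg = replace(ml_cfg, bootstrap_replicates=cfg.ml_replicates,
                         bootstrap_starts=1, seed=cfg.seed + 2)
        ml_bs_tree, _ = bootstrap(rooted, bs_cfg, best_tree=ml_tree)
        write_tree(ml_bs_tree, emit("ml_tree_bootstrap.nwk"))
        stages["ml_bootstrap"] = time.time() - t0

    # --- overall similarity --------------------------------------------
    t0 = time.time()
    dm = distance_matrix(matrix, cfg.metric)
    pd.DataFrame(dm.values, index=dm.area_names, columns=dm.area_names).to_csv(
        emit("distances.tsv"), sep="\t"
    )
    write_tree(upgma(dm), emit("upgma.nwk"))
    stages["upgma"] = time.time() - t0

    # --- extinct-taxa scenarios ----------------------------------------
    t0 = time.time()
    scen_cfg = replace(ml_cfg, n_starts=cfg.scenario_starts, seed=cfg.seed + 3)
    scen = run_scenarios(matrix, scen_cfg, fractions=list(cfg.fractions),
                         outgroup_name=cfg.outgroup_name)
    rows = []
    for s in scen:
        write_tree(s.tree, emit(f"scenario_{s.n_extinct}_extinct.nwk"))
        rows.append({
            "n_extinct": s.n_extinct,
            "log_likelihood": s.log_likelihood,
            "neg_log_likelihood": -s.log_likelihood,
            "rf_to_baseline": s.rf_to_baseline,
        })
    pd.DataFrame(rows).to_csv(emit("scenarios.tsv"), sep="\t", index=False)
    manifest["scenarios"] = rows
    stages["scenarios"] = time.time() - t0

    # --- stochastic species maps ---------------------------------------
    chosen = _select_species(matrix, cfg.map_species)
    if chosen:
        t0 = time.time()
        model = MkModel(
            gamma_shape=ml_res.fit.gamma_shape,
            p_invariant=ml_res.fit.p_invariant,
        )
        rows = []
        for i, sp in enumerate(chosen):
            _, summary = map_character(
                ml_pruned_with_lengths(ml_tree, cfg.outgroup_name), matrix, sp,
                model=model, n_samples=cfg.map_samples,
                seed=cfg.seed + 10 + i, keep_histories=False,
            )
            rows.append({
                "species": sp,
                "expected_gains": summary.branch_gains.sum(),
                "expected_losses": summary.branch_losses.sum(),
                "root_posterior_presence":
                    summary.node_posterior_presence[summary.flat.root],
            })
        pd.DataFrame(rows).to_csv(emit("species_maps.tsv"), sep="\t", index=False)
        stages["stochastic_maps"] = time.time() - t0

    manifest["stage_seconds"] = {k: round(v, 2) for k, v in stages.items()}
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    manifest["outputs"].append("manifest.json")
    return manifest


def ml_pruned_with_lengths(ml_tree: AreaTree, outgroup: str) -> AreaTree:
    """Drop the artificial outgroup but keep the fitted branch lengths."""
    return ml_tree.prune_tips([outgroup])


def _select_species(matrix: TaxonAreaMatrix, selector: str) -> list[str]:
    if selector == "none":
        return []
    if selector == "all":
        return list(matrix.species_names)
    if selector == "endemics":
        counts = matrix.cells.sum(axis=0)
        return [s for s, c in zip(matrix.species_names, counts) if 1 <= c <= 2]
    return [s.strip() for s in selector.split(",") if s.strip()]
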