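"""File formats: numeric matrices, edge lists, clique trees, configs."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .copent import EstimatorConfig
from .graph import CliqueTree, UndirectedGraph

PathLike = Union[str, Path]


def read_data_matrix(path: PathLike) -> pd.DataFrame:
    """Numeric sample-by-variable matrix from CSV/TSV with a header row."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    if not all(np.issubdtype(t, np.number) for t in df.dtypes):
        raise ValueError(f"{path} contains non-numeric columns")
    return df


def write_edge_list(G: UndirectedGraph, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("i\tj\n")
        for (i, j) in sorted(G.edges):
            fh.write(f"{i}\t{j}\n")


def read_edge_list(path: PathLike, d: Optional[int] = None) -> UndirectedGraph:
    """Edge-list TSV (0-based vertex pairs, header ``i<TAB>j``)."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["i", "j"]:
        raise ValueError(f"{path}: expected header 'i\\tj'")
    edges = {(int(a), int(b)) for a, b in df.itertuples(index=False)}
    if d is None:
        d = 1 + max((max(e) for e in edges), default=0)
    return UndirectedGraph(d, edges)


def clique_tree_to_json(T: CliqueTree) -> Dict:
    ids = sorted(T.cliques, key=lambda nid: sorted(T.cliques[nid]))
    pos = {nid: k for k, nid in enumerate(ids)}
    return {
        "d": T.d,
        "cliques": [sorted(T.cliques[nid]) for nid in ids],
        "tree_edges": sorted(
            [pos[a], pos[b], sorted(T.separator(a, b))]
            if pos[a] < pos[b] else [pos[b], pos[a], sorted(T.separator(a, b))]
            for (a, b) in T.tree_edges()
        ),
    }


def write_clique_tree(T: CliqueTree, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(clique_tree_to_json(T), fh, indent=1)


def load_config(path: Optional[PathLike]) -> Dict:
    """YAML/JSON config; flat dict with optional nested optimizer/split keys."""
    if path is None:
        return {}
    text = Path(path).read_text()
    cfg = yaml.safe_load(text) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def estimator_config_from(cfg: Dict, seed: int = 0) -> EstimatorConfig:
    opt = cfg.get("optimizer", {})
    return EstimatorConfig(
        k_folds=int(cfg.get("k_folds", 5)),
        epsilon=float(cfg.get("epsilon", 1e-5)),
        density_floor=float(cfg.get("density_floor", 1e-100)),
        beta_min=float(cfg.get("beta_min", 1.0)),
        beta_max=cfg.get("beta_max"),
        max_iter=int(opt.get("max_iter", 200)),
        rel_tol=float(opt.get("rel_tol", 1e-8)),
        seed=seed,
    )
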