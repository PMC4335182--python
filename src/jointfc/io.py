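"""Readers, writers, and run configuration.

Input formats
-------------
* functional profiles: one TSV/CSV per subject, rows = scans, columns =
  regions, header row of region labels;
* structural counts: either one square region-by-region TSV/CSV per
  subject (optionally several, one per scan) with the trial count given
  in the configuration, or a long-format table with columns
  (region_a, region_b, subject, scan, count);
* precomputed sufficient statistics: long-format joint-activation and
  structural-count tables, as written by the simulator (round-trips
  through ``read_pair_dataset``).

All writers produce plain text (TSV / JSON / GraphML) and every writer
has a matching reader used in the round-trip tests.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .data_prep import (
    ActivationIndicator,
    RegionalProfile,
    combine_scans_and_rescale,
    dichotomize,
    joint_activation_counts,
    rescale_joint_counts,
    symmetrize_pair_counts,
)
from .edges import InferenceThresholds
from .model import LinkFunction, ModelHyperparameters
from .network import BrainNetwork
from .sampler import ChainSettings

__all__ = [
    "load_config",
    "hyper_from_config",
    "settings_from_config",
    "thresholds_from_config",
    "read_functional_profiles",
    "read_structural_matrix",
    "build_pair_dataset",
    "write_pair_dataset",
    "read_pair_dataset",
    "write_edge_table",
    "read_edge_table",
    "write_metrics_json",
    "write_graph",
    "read_graph_edgelist",
]

_CONFIG_KEYS = {
    "functional", "structural", "counts", "structural_counts", "m_star",
    "t_star", "hyperparameters", "link", "chain", "thresholds", "network",
    "output_dir", "seed", "verbosity", "on_missing_structural",
}


def load_config(path) -> dict:
    """Load and validate a JSON or YAML run configuration."""
    path = Path(path)
    text = path.read_text()
    config = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(config, dict):
        raise ValueError("configuration must be a mapping")
    unknown = set(config) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    if "seed" in config and not isinstance(config["seed"], int):
        raise ValueError("seed must be an integer")
    return config


def link_from_config(config: dict) -> LinkFunction:
    spec = config.get("link", {})
    return LinkFunction(
        family=spec.get("family", "exp10"),
        parameter=float(spec.get("parameter", 10.0)),
        target_mean=float(spec.get("target_mean", 10.0)),
    )


def hyper_from_config(config: dict) -> ModelHyperparameters:
    h = config.get("hyperparameters", {})
    return ModelHyperparameters(
        alpha0=float(h.get("alpha0", 1.0)),
        beta0=float(h.get("beta0", 1.0)),
        alpha1=float(h.get("alpha1", 5.0)),
        alpha2=float(h.get("alpha2", 10.0)),
        alpha3=float(h.get("alpha3", 10.0)),
        alpha4=float(h.get("alpha4", 10.0)),
        link=link_from_config(config),
        T=int(h.get("T", 100)),
        M=int(h.get("M", 1000)),
        c=float(h.get("c", 0.01)),
    )


def settings_from_config(config: dict) -> ChainSettings:
    ch = config.get("chain", {})
    return ChainSettings(
        n_iterations=int(ch.get("n_iterations", 10000)),
        n_burnin=int(ch.get("n_burnin", 2000)),
        thin=int(ch.get("thin", 10)),
        jump_sd=float(ch.get("jump_sd", 0.05)),
        target_acceptance=float(ch.get("target_acceptance", 0.25)),
        seed=int(ch.get("seed", config.get("seed", 0))),
    )


def thresholds_from_config(config: dict) -> InferenceThresholds:
    th = config.get("thresholds", {})
    e_tau = th.get("e_tau", "auto-median")
    return InferenceThresholds(
        e_kappa=float(th.get("e_kappa", 0.4)),
        p_kappa=float(th.get("p_kappa", 0.5)),
        e_tau=e_tau if isinstance(e_tau, str) else float(e_tau),
        p_tau=float(th.get("p_tau", 0.5)),
    )


def _read_table(path) -> pd.DataFrame:
    sep = "," if Path(path).suffix == ".csv" else "\t"
    return pd.read_csv(path, sep=sep)


def read_functional_profiles(path) -> pd.DataFrame:
    """One subject's profile table: rows = scans, columns = regions."""
    frame = _read_table(path)
    if frame.shape[0] < 2 or frame.shape[1] < 2:
        raise ValueError(f"{path}: need >= 2 scans and >= 2 regions")
    if not np.all(np.isfinite(frame.to_numpy(dtype=float))):
        raise ValueError(f"{path}: non-finite values in profile table")
    return frame


def read_structural_matrix(path) -> pd.DataFrame:
    """One subject/scan's square region-by-region count matrix."""
    sep = "," if Path(path).suffix == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep, index_col=0)
    if frame.shape[0] != frame.shape[1]:
        raise ValueError(f"{path}: structural matrix must be square")
    if list(frame.index) != list(frame.columns):
        raise ValueError(f"{path}: row and column labels must match")
    return frame


def build_pair_dataset(
    functional: dict[str, pd.DataFrame],
    structural: dict[str, list[pd.DataFrame]] | None,
    hyper: ModelHyperparameters,
    m_star: int | None = None,
) -> dict:
    """Assemble per-pair sufficient statistics from per-subject tables.

    ``functional`` maps subject id to a scans-by-regions profile table;
    ``structural`` maps subject id to one or more (per-scan) square count
    matrices with ``m_star`` tractography trials each, or is None when no
    structural data exist.  Returns ``{(a, b): (Z_all [N,4], S_all [N] or
    None)}`` over all region pairs, with counts rescaled to (T, M).
    """
    subjects = sorted(functional)
    regions = list(functional[subjects[0]].columns)
    for sid in subjects:
        if list(functional[sid].columns) != regions:
            raise ValueError(f"subject {sid}: region columns differ across subjects")
    if structural is not None:
        if m_star is None:
            raise ValueError("m_star is required with structural matrices")
        for sid in subjects:
            if sid not in structural:
                raise ValueError(f"subject {sid}: missing structural data")
            for mat in structural[sid]:
                missing = set(regions) - set(mat.columns)
                if missing:
                    raise ValueError(
                        f"subject {sid}: structural matrix lacks regions {sorted(missing)}"
                    )

    indicators: dict[str, dict[str, ActivationIndicator]] = {}
    for sid in subjects:
        table = functional[sid]
        indicators[sid] = {
            region: dichotomize(
                RegionalProfile(region, sid, table[region].to_numpy(float)),
                hyper.c,
            )
            for region in regions
        }

    dataset: dict = {}
    for i, a in enumerate(regions):
        for b in regions[i + 1 :]:
            Z_rows = []
            S_rows: list[float] | None = [] if structural is not None else None
            for sid in subjects:
                raw = joint_activation_counts(indicators[sid][a], indicators[sid][b])
                Z_rows.append(rescale_joint_counts(raw, int(raw.sum()), hyper.T))
                if structural is not None:
                    per_scan = [
                        symmetrize_pair_counts(
                            float(mat.loc[a, b]), float(mat.loc[b, a])
                        )
                        for mat in structural[sid]
                    ]
                    sc = combine_scans_and_rescale(
                        per_scan, m_star, hyper.M, pair=(a, b), subject_id=sid
                    )
                    S_rows.append(sc.scaled_count)
            dataset[(a, b)] = (
                np.array(Z_rows),
                np.array(S_rows) if S_rows is not None else None,
            )
    return dataset


def write_pair_dataset(dataset: dict, counts_path, structural_path, hyper) -> None:
    """Write per-pair counts as two long-format TSVs (Z and S)."""
    z_rows, s_rows = [], []
    for (a, b), (Z_all, S_all) in sorted(dataset.items()):
        for n, z in enumerate(np.atleast_2d(Z_all)):
            z_rows.append(
                {
                    "region_a": a, "region_b": b, "subject": n,
                    "Z1": int(z[0]), "Z2": int(z[1]),
                    "Z3": int(z[2]), "Z4": int(z[3]), "T": hyper.T,
                }
            )
        if S_all is not None:
            for n, s in enumerate(np.atleast_1d(S_all)):
                s_rows.append(
                    {
                        "region_a": a, "region_b": b, "subject": n,
                        "S": int(s), "M": hyper.M,
                    }
                )
    pd.DataFrame(z_rows).to_csv(counts_path, sep="\t", index=False)
    pd.DataFrame(s_rows).to_csv(structural_path, sep="\t", index=False)


def read_pair_dataset(counts_path, structural_path=None) -> dict:
    """Read long-format counts back into ``{pair: (Z_all, S_all)}``."""
    z = pd.read_csv(counts_path, sep="\t")
    s = (
        pd.read_csv(structural_path, sep="\t")
        if structural_path is not None
        else None
    )
    dataset: dict = {}
    for (a, b), group in z.groupby(["region_a", "region_b"]):
        group = group.sort_values("subject")
        Z_all = group[["Z1", "Z2", "Z3", "Z4"]].to_numpy(np.int64)
        S_all = None
        if s is not None:
            sg = s[(s.region_a == a) & (s.region_b == b)].sort_values("subject")
            if len(sg):
                if len(sg) != len(group):
                    raise ValueError(f"pair {(a, b)}: Z/S subject mismatch")
                S_all = sg["S"].to_numpy(np.int64)
        dataset[(a, b)] = (Z_all, S_all)
    return dataset


def write_edge_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_edge_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_metrics_json(metrics, path, extra: dict | None = None) -> None:
    """Write a NetworkMetrics report (plus provenance fields) as JSON."""
    payload = metrics.to_dict() if hasattr(metrics, "to_dict") else dict(metrics)
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")


def write_graph(network: BrainNetwork, base_path) -> tuple[Path, Path]:
    """Write a network as an edge-list TSV and a GraphML file."""
    base = Path(base_path)
    edgelist = base.with_suffix(".edges.tsv")
    graphml = base.with_suffix(".graphml")
    pd.DataFrame(network.edges, columns=["region_a", "region_b"]).to_csv(
        edgelist, sep="\t", index=False
    )
    nx.write_graphml(network.to_networkx(), graphml)
    return edgelist, graphml


def read_graph_edgelist(path, directed: bool = False) -> BrainNetwork:
    frame = pd.read_csv(path, sep="\t")
    edges = [tuple(r) for r in frame.to_numpy()]
    nodes = sorted({n for e in edges for n in e})
    return BrainNetwork(nodes=nodes, edges=edges, directed=directed)
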