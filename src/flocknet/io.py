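"""Reading and writing the pipeline's file formats.

Event logs are plain CSV with header ``day,time_s,hen_id,antenna_id``;
gate maps and configs are YAML; matrices and tables are TSV; the DTW
hypermatrix is persisted as compressed ``.npz`` with a JSON sidecar
carrying dimensions and identifiers; networks export to GraphML and a
weighted edge list.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

EVENT_COLUMNS = ["day", "time_s", "hen_id", "antenna_id"]


def write_events(events: pd.DataFrame, path) -> None:
    events[EVENT_COLUMNS].to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"day": int, "time_s": int, "hen_id": str, "antenna_id": str})
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"event CSV is missing columns: {sorted(missing)}")
    return df[EVENT_COLUMNS]


def write_gate_map(gate_map: dict, path) -> None:
    serializable = {
        ant: {"gate": v["gate"], "side_area": v["side_area"], "areas": list(v["areas"])}
        for ant, v in gate_map.items()
    }
    Path(path).write_text(yaml.safe_dump(serializable, sort_keys=True))


def read_gate_map(path) -> dict:
    raw = yaml.safe_load(Path(path).read_text())
    return {
        ant: {"gate": v["gate"], "side_area": v["side_area"], "areas": tuple(v["areas"])}
        for ant, v in raw.items()
    }


def write_matrix(mat: np.ndarray, hens: list[str], path) -> None:
    pd.DataFrame(mat, index=hens, columns=hens).to_csv(path, sep="\t")


def read_matrix(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(), list(df.index)


def write_hypermatrix(M4: np.ndarray, hens: list[str], days: list[int], path) -> None:
    path = Path(path)
    np.savez_compressed(path, dd=M4)
    sidecar = {"a": len(hens), "b": len(days), "hens": hens, "days": list(map(int, days))}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_hypermatrix(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    dd = np.load(path)["dd"]
    meta = json.loads(path.with_suffix(".json").read_text())
    return dd, meta


def write_network(ai: np.ndarray, hens: list[str], graphml_path, edgelist_path) -> None:
    G = nx.Graph()
    G.add_nodes_from(hens)
    a = len(hens)
    rows = []
    for i in range(a):
        for j in range(i + 1, a):
            if ai[i, j] > 0:
                G.add_edge(hens[i], hens[j], weight=float(ai[i, j]))
                rows.append((hens[i], hens[j], ai[i, j]))
    nx.write_graphml(G, graphml_path)
    pd.DataFrame(rows, columns=["hen_a", "hen_b", "ai"]).to_csv(edgelist_path, index=False)


def dump_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify))


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
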