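"""Readers and writers for the pipeline's on-disk formats.

* Morphology: SWC, one file per neuron per session, with a sidecar JSON
  manifest (neuron id, session id, home barrel, tree ids and kinds).
  Structure-type codes follow the common convention 1 = soma, 2 = axon,
  3 = (basal) dendrite, 4 = apical dendrite; coordinates are µm.
* Barrel maps: GeoJSON FeatureCollection of µm-coordinate polygons with
  ``id`` and ``center`` properties.
* Calcium movies: multi-page TIFF plus JSON metadata (um_per_px, hz,
  excluded_frames).
* Tables: CSV via pandas.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .calcium import CalciumMovie
from .morphometry import (
    Barrel,
    BarrelMap,
    DendriticTree,
    StructuralError,
    TracedNeuron,
)

__all__ = [
    "SWC_TYPE_CODES",
    "ParseError",
    "write_swc",
    "read_swc",
    "write_barrel_map",
    "read_barrel_map",
    "write_movie",
    "read_movie",
    "write_dataset",
    "read_dataset",
]

SWC_TYPE_CODES = {"soma": 1, "axon": 2, "BD": 3, "AD": 4}
_KIND_OF_CODE = {2: "axon", 3: "BD", 4: "AD"}


class ParseError(ValueError):
    pass


def write_swc(neuron: TracedNeuron, path, soma_radius: float = 7.0) -> None:
    """Write a traced neuron as SWC plus a ``.json`` manifest."""
    path = Path(path)
    lines = ["# id type x y z radius parent"]
    sx, sy, sz = neuron.soma_center
    lines.append(f"1 1 {sx:.4f} {sy:.4f} {sz:.4f} {soma_radius:.2f} -1")
    next_id = 2
    tree_ids = []
    for tree in neuron.trees:
        code = SWC_TYPE_CODES[tree.kind]
        offset = next_id
        for i, (pt, par) in enumerate(zip(tree.nodes, tree.parents)):
            swc_parent = 1 if par < 0 else offset + par
            lines.append(
                f"{offset + i} {code} {pt[0]:.4f} {pt[1]:.4f} {pt[2]:.4f} "
                f"0.50 {swc_parent}"
            )
        next_id = offset + len(tree.nodes)
        tree_ids.append(tree.tree_id)
    path.write_text("\n".join(lines) + "\n")
    manifest = {
        "neuron_id": neuron.neuron_id,
        "session_id": neuron.session_id,
        "home_barrel_id": neuron.home_barrel_id,
        "units": "um",
        "tree_ids": tree_ids,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(manifest, indent=1)
    )


def read_swc(path) -> TracedNeuron:
    """Read one neuron's SWC + manifest back into a :class:`TracedNeuron`."""
    path = Path(path)
    mpath = path.with_suffix(path.suffix + ".json")
    if not mpath.exists():
        raise ParseError(f"{path}: missing sidecar manifest {mpath.name}")
    manifest = json.loads(mpath.read_text())

    nodes: dict[int, tuple[int, np.ndarray, int]] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise ParseError(f"{path}:{lineno}: expected 7 columns")
        try:
            nid, code = int(parts[0]), int(parts[1])
            xyz = np.array([float(parts[2]), float(parts[3]), float(parts[4])])
            parent = int(parts[6])
        except ValueError as e:
            raise ParseError(f"{path}:{lineno}: {e}") from None
        nodes[nid] = (code, xyz, parent)
    for nid, (_, _, parent) in nodes.items():
        if parent != -1 and parent not in nodes:
            raise ParseError(f"{path}: node {nid} has dangling parent {parent}")

    soma_ids = [nid for nid, (c, _, _) in nodes.items() if c == 1]
    if len(soma_ids) != 1:
        raise ParseError(f"{path}: expected exactly one soma node")
    soma_id = soma_ids[0]
    soma_center = nodes[soma_id][1]

    # split into arbors: one per child-of-soma subtree, grouped by walking
    children: dict[int, list[int]] = {}
    for nid, (_, _, parent) in nodes.items():
        children.setdefault(parent, []).append(nid)
    trees = []
    tree_ids = manifest.get("tree_ids") or []
    for k, root in enumerate(sorted(children.get(soma_id, []))):
        order = []
        stack = [root]
        while stack:
            cur = stack.pop()
            order.append(cur)
            stack.extend(sorted(children.get(cur, []), reverse=True))
        index_of = {nid: i for i, nid in enumerate(order)}
        code = nodes[root][0]
        kind = _KIND_OF_CODE.get(code)
        if kind is None:
            raise ParseError(f"{path}: unknown structure code {code}")
        pts = np.array([nodes[nid][1] for nid in order])
        parents = np.array(
            [
                -1 if nodes[nid][2] == soma_id else index_of[nodes[nid][2]]
                for nid in order
            ]
        )
        tid = tree_ids[k] if k < len(tree_ids) else f"tree{k}"
        trees.append(DendriticTree(tree_id=tid, nodes=pts, parents=parents, kind=kind))
    return TracedNeuron(
        neuron_id=manifest["neuron_id"],
        session_id=manifest["session_id"],
        soma_center=soma_center,
        trees=trees,
        home_barrel_id=manifest.get("home_barrel_id"),
    )


# ---------------------------------------------------------------------------
# barrel map GeoJSON
# ---------------------------------------------------------------------------


def write_barrel_map(barrel_map: BarrelMap, path) -> None:
    features = []
    for b in barrel_map.barrels:
        ring = [[float(x), float(y)] for x, y in b.boundary]
        if ring[0] != ring[-1]:
            ring.append(ring[0])
        features.append(
            {
                "type": "Feature",
                "properties": {
                    "id": b.barrel_id,
                    "center": [float(b.center[0]), float(b.center[1])],
                },
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
    doc = {"type": "FeatureCollection", "units": "um", "features": features}
    Path(path).write_text(json.dumps(doc))


def read_barrel_map(path) -> BarrelMap:
    doc = json.loads(Path(path).read_text())
    barrels = []
    for feat in doc.get("features", []):
        props = feat.get("properties", {})
        geom = feat.get("geometry", {})
        if geom.get("type") != "Polygon":
            raise ParseError(f"{path}: feature {props.get('id')} is not a Polygon")
        ring = np.array(geom["coordinates"][0], float)
        if np.allclose(ring[0], ring[-1]):
            ring = ring[:-1]
        barrels.append(
            Barrel(
                barrel_id=str(props["id"]),
                center=np.array(props["center"], float),
                boundary=ring,
            )
        )
    return BarrelMap(barrels=barrels)  # validates polygons/centers/ids


# ---------------------------------------------------------------------------
# movies
# ---------------------------------------------------------------------------


def write_movie(movie: CalciumMovie, path) -> None:
    path = Path(path)
    tifffile.imwrite(path, movie.frames.astype(np.float32))
    meta = {
        "um_per_px": movie.um_per_px,
        "hz": movie.hz,
        "excluded_frames": list(map(int, movie.excluded_frames)),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def read_movie(path) -> CalciumMovie:
    path = Path(path)
    mpath = path.with_suffix(path.suffix + ".json")
    if not mpath.exists():
        raise ParseError(f"{path}: missing metadata {mpath.name}")
    meta = json.loads(mpath.read_text())
    frames = tifffile.imread(path)
    return CalciumMovie(
        frames=np.asarray(frames, float),
        um_per_px=float(meta["um_per_px"]),
        hz=float(meta.get("hz", 1.0)),
        excluded_frames=list(meta.get("excluded_frames", [])),
    )


# ---------------------------------------------------------------------------
# longitudinal datasets on disk
# ---------------------------------------------------------------------------


def write_dataset(dataset: dict, out_dir) -> None:
    """Write session -> neurons as ``<session>/<neuron>.swc`` files."""
    out = Path(out_dir)
    for session, neurons in dataset.items():
        sdir = out / session
        sdir.mkdir(parents=True, exist_ok=True)
        for neu in neurons:
            write_swc(neu, sdir / f"{neu.neuron_id}.swc")
    (out / "sessions.json").write_text(json.dumps(list(dataset.keys())))


def read_dataset(in_dir) -> dict:
    root = Path(in_dir)
    sessions = json.loads((root / "sessions.json").read_text())
    dataset = {}
    for session in sessions:
        sdir = root / session
        neurons = [read_swc(p) for p in sorted(sdir.glob("*.swc"))]
        dataset[session] = neurons
    return dataset
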