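"""Readers and writers for the pipeline's on-disk formats.

Expression matrices travel as TSV (rows = genes, header = sample names)
with a sidecar JSON of sample -> group labels; gene sets as GMT; graphs
as (source,target,relation) CSV edge lists or GraphML; images as 16-bit
grayscale TIFF with the pixel size in a sidecar JSON; metrics and
tables as TSV; truth records and manifests as JSON.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd


# -- expression matrices ----------------------------------------------------

def write_matrix(matrix, groups, path):
    path = Path(path)
    matrix.to_csv(path, sep="\t", index_label="gene_id",
                  float_format="%.6f")
    path.with_suffix(".groups.json").write_text(
        json.dumps(groups, indent=1, sort_keys=True))


def read_matrix(path):
    path = Path(path)
    matrix = pd.read_csv(path, sep="\t", index_col="gene_id")
    groups = json.loads(path.with_suffix(".groups.json").read_text())
    return matrix, groups


# -- gene sets (GMT) --------------------------------------------------------

def write_gmt(collection, path, descriptions=None):
    """Write {set_id: members} in GMT (id, description, members...)."""
    with open(path, "w") as fh:
        for sid, members in collection.items():
            desc = (descriptions or {}).get(sid, "na")
            fh.write("\t".join([sid, desc, *sorted(members)]) + "\n")


def read_gmt(path):
    collection = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            collection[parts[0]] = set(parts[2:])
    return collection


# -- regulation graphs ------------------------------------------------------

def write_edges_csv(edges, path):
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["source", "target", "relation"])
        w.writerows(edges)


def read_edges_csv(path):
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if [h.strip().lower() for h in header[:3]] != \
                ["source", "target", "relation"]:
            raise ValueError(f"{path}: expected header source,target,relation")
        return [tuple(row[:3]) for row in reader if row]


def write_network_graphml(network, path):
    """Hierarchical network as GraphML: level on nodes, relation on edges."""
    import networkx as nx

    g = nx.DiGraph()
    for node, lv in network.level_of.items():
        g.add_node(node, level=int(lv),
                   upstream=bool(node in network.upstream))
    for s, t, rel in network.edges:
        g.add_edge(s, t, relation=rel)
    nx.write_graphml(g, path)


def write_levels_tsv(network, path):
    pd.DataFrame(
        [(n, lv, n in network.upstream)
         for n, lv in sorted(network.level_of.items())],
        columns=["node", "level", "is_upstream"],
    ).to_csv(path, sep="\t", index=False)


# -- images -----------------------------------------------------------------

def write_image(image, path, pixel_size=None):
    """Write a [0,1] float image as 16-bit grayscale TIFF (+ sidecar)."""
    import tifffile

    path = Path(path)
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    tifffile.imwrite(path, (arr * 65535).round().astype(np.uint16))
    if pixel_size is not None:
        path.with_suffix(".meta.json").write_text(
            json.dumps({"pixel_size_mm": pixel_size}))


def read_image(path, pixel_size=None):
    """Read an 8/16-bit grayscale TIFF/PNG, normalised to [0,1].

    The pixel size (mm/px) comes from the argument or the sidecar JSON;
    it defaults to 1.0 when neither is present.
    """
    import imageio.v3 as iio

    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise ValueError(f"unreadable image {path}: {exc}") from exc
    if arr.ndim == 3:                     # RGB(A): luminance
        arr = arr[..., :3].mean(axis=-1)
    arr = arr.astype(float)
    if arr.max() > 1.0:
        arr /= 65535.0 if arr.max() > 255 else 255.0
    if pixel_size is None:
        sidecar = path.with_suffix(".meta.json")
        if sidecar.exists():
            pixel_size = json.loads(sidecar.read_text())["pixel_size_mm"]
        else:
            pixel_size = 1.0
    return arr, float(pixel_size)


def write_overlay(skeleton, path, branch_mask=None, endpoint_mask=None,
                  background=None):
    """Skeleton overlay PNG: white skeleton, green branch clusters, red
    endpoints, mirroring the usual whole-mount annotation colours."""
    import imageio.v3 as iio

    skel = np.asarray(skeleton, dtype=bool)
    if background is not None:
        base = (np.clip(background, 0, 1) * 180).astype(np.uint8)
    else:
        base = np.zeros(skel.shape, dtype=np.uint8)
    rgb = np.stack([base] * 3, axis=-1)
    rgb[skel] = (255, 255, 255)
    if branch_mask is not None:
        rgb[np.asarray(branch_mask, bool)] = (0, 200, 0)
    if endpoint_mask is not None:
        rgb[np.asarray(endpoint_mask, bool)] = (255, 0, 0)
    iio.imwrite(path, rgb)


# -- generic tables / JSON --------------------------------------------------

def write_tsv(df, path):
    pd.DataFrame(df).to_csv(path, sep="\t", index=False,
                            float_format="%.10g")


def write_json(obj, path):
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True,
                                     default=str) + "\n")
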