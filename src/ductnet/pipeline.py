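"""End-to-end orchestration of the two analysis arms.

``run_transcriptomics`` chains expression matrix -> DEG screen ->
gene-set over-representation -> per-function hierarchical regulator
networks -> multiplicity and common intermediates.
``run_wholemount`` chains image -> vesselness -> segmentation ->
skeleton -> morphometrics -> group comparison. Both write their tables
plus a JSON manifest of every parameter actually used and the SHA-256
of every input file, so a run is reproducible bit for bit from the
manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from . import degs as _degs
from . import enrichment as _enr
from . import hierarchy as _hier
from . import io as _io
from . import wholemount as _wm

__all__ = ["RunConfig", "run_transcriptomics", "run_wholemount", "run_all"]


@dataclass
class RunConfig:
    """Validated run configuration (one YAML/JSON file)."""

    arm: str = "both"
    seed: int = 0
    transcriptomics: dict = field(default_factory=dict)
    wholemount: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path):
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml
            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        return cls(**raw)

    def __post_init__(self):
        if self.arm not in ("transcriptomics", "wholemount", "both"):
            raise ValueError(f"unknown arm {self.arm!r}")
        fc = self.transcriptomics.get("fc_threshold", _degs.FC_THRESHOLD)
        alpha = self.transcriptomics.get("alpha", _degs.ALPHA)
        if fc < 1:
            raise ValueError("fc_threshold must be >= 1 (folded ratio)")
        if not 0 < alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    def validate_paths(self):
        """Check every referenced input path exists (--dry-run backend)."""
        missing = []
        tc, wm = self.transcriptomics, self.wholemount
        for p in [tc.get("matrix"), tc.get("graph"), tc.get("pathways"),
                  *(tc.get("genesets") or {}).values(),
                  *(tc.get("functions") or {}).values(),
                  *(img["path"] for img in wm.get("images", []))]:
            if p is not None and not Path(p).exists():
                missing.append(str(p))
        if missing:
            raise FileNotFoundError("missing input(s): " + ", ".join(missing))
        return self


def _sha256(path):
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _read_gene_list(path):
    """Gene ids from a one-per-line text file or a single-set GMT."""
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines()
             if ln.strip()]
    if lines and "\t" in lines[0]:            # GMT row(s)
        genes = set()
        for ln in lines:
            genes |= set(ln.split("\t")[2:])
        return genes
    return set(lines)


def run_transcriptomics(config, outdir):
    """DEGs -> enrichment -> hierarchical networks -> common intermediates.

    Expects in ``config.transcriptomics``: ``matrix`` (TSV + sidecar
    groups JSON), optional ``genesets`` ({label: GMT path}), optional
    ``graph`` (edge CSV), ``upstream`` (gene list or file),
    ``functions`` ({name: gene-list/GMT file}) and ``pathways``
    (gene-list file). Writes all tables under ``outdir`` and returns a
    dict of the in-memory results.
    """
    tc = config.transcriptomics
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"arm": "transcriptomics", "seed": config.seed,
                "version": __version__, "inputs": {}, "parameters": {}}
    results = {}

    try:
        matrix, groups = _io.read_matrix(tc["matrix"])
    except KeyError:
        raise ValueError("transcriptomics.matrix is required")
    manifest["inputs"]["matrix"] = _sha256(tc["matrix"])

    fc = tc.get("fc_threshold", _degs.FC_THRESHOLD)
    alpha = tc.get("alpha", _degs.ALPHA)
    scale = tc.get("input_scale", "linear")
    manifest["parameters"].update(fc_threshold=fc, alpha=alpha,
                                  input_scale=scale)
    table = _degs.deg_screen(matrix, groups, fc_threshold=fc, alpha=alpha,
                             input_scale=scale)
    table.index.name = "gene_id"
    table.reset_index().to_csv(outdir / "deg_table.tsv", sep="\t",
                               index=False, float_format="%.10g")
    deg_list = _degs.deg_list(table)
    universe = list(table.index)
    results["deg_table"] = table
    results["deg_list"] = deg_list
    if not deg_list:
        import warnings
        warnings.warn("no gene passed the DEG criterion; downstream "
                      "networks will be empty", stacklevel=2)

    top = tc.get("top", 4)
    manifest["parameters"]["top"] = top
    results["enrichment"] = {}
    for label, gmt in (tc.get("genesets") or {}).items():
        collection = _io.read_gmt(gmt)
        manifest["inputs"][f"genesets.{label}"] = _sha256(gmt)
        ranked = _enr.rank_sets(collection, deg_list, universe, top=None)
        _io.write_tsv(ranked, outdir / f"enrichment_{label}.tsv")
        _io.write_tsv(ranked.head(top),
                      outdir / f"enrichment_{label}_top{top}.tsv")
        results["enrichment"][label] = ranked

    if tc.get("graph"):
        edges = _io.read_edges_csv(tc["graph"])
        manifest["inputs"]["graph"] = _sha256(tc["graph"])
        upstream = tc.get("upstream", [])
        if isinstance(upstream, str):
            upstream = sorted(_read_gene_list(upstream))
        graph = _hier.ingest_graph(edges, deg_list=deg_list,
                                   upstream=upstream)
        networks = []
        for name, fpath in sorted((tc.get("functions") or {}).items()):
            fgenes = _read_gene_list(fpath) & set(deg_list)
            manifest["inputs"][f"functions.{name}"] = _sha256(fpath)
            net = _hier.build_hierarchy(graph, fgenes, function_label=name)
            _io.write_network_graphml(net, outdir / f"network_{name}.graphml")
            _io.write_levels_tsv(net, outdir / f"levels_{name}.tsv")
            networks.append(net)
        results["networks"] = networks

        if len(networks) >= 2:
            mult = _hier.network_multiplicity(networks)
            _io.write_tsv(
                [{"node": n, "multiplicity": c} for n, c in mult.items()],
                outdir / "multiplicity.tsv")
            pathway_members = None
            if tc.get("pathways"):
                pathway_members = _read_gene_list(tc["pathways"])
                manifest["inputs"]["pathways"] = _sha256(tc["pathways"])
            common = _hier.common_intermediates(
                mult, n_networks=len(networks),
                pathway_members=pathway_members,
                min_count=tc.get("min_count"))
            (outdir / "common_intermediates.txt").write_text(
                "\n".join(sorted(common)) + "\n")
            results["multiplicity"] = mult
            results["common_intermediates"] = common

    _io.write_json(manifest, outdir / "manifest_transcriptomics.json")
    return results


def run_wholemount(config, outdir):
    """Vesselness -> mask -> skeleton -> metrics -> group comparison.

    ``config.wholemount`` lists ``images`` as ``{path, group}`` records
    (group optional) plus the vesselness/segmentation parameters.
    Writes per-image metrics, overlays, and a group-comparison table
    when two groups with >= 2 animals each are present.
    """
    wm = config.wholemount
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    images = wm.get("images", [])
    if not images:
        raise ValueError("wholemount.images is empty")

    params = _wm.VesselnessParams(
        sigmas=tuple(wm.get("sigmas", _wm.VesselnessParams().sigmas)),
        beta=wm.get("beta", 0.5),
        c=wm.get("c", "half_max_hessian_norm"))
    policy = wm.get("policy", "otsu")
    min_obj = wm.get("min_object_px", 50)
    polarity = wm.get("polarity", "ducts_dark")
    manifest = {"arm": "wholemount", "seed": config.seed,
                "version": __version__, "inputs": {},
                "parameters": {"sigmas": list(params.sigmas),
                               "beta": params.beta, "c": str(params.c),
                               "policy": str(policy),
                               "min_object_px": min_obj,
                               "polarity": polarity}}

    rows, metrics, labels = [], [], []
    for rec in images:
        path = rec["path"]
        image, px = _io.read_image(path, wm.get("pixel_size"))
        manifest["inputs"][Path(path).name] = _sha256(path)
        m, response, mask = _wm.quantify_image(
            image, params=params, polarity=polarity, policy=policy,
            min_object_px=min_obj, pixel_size=px)
        stem = Path(path).stem
        if wm.get("save_intermediates"):
            _io.write_image(response, outdir / f"{stem}_response.tif")
            _io.write_image(mask.astype(float), outdir / f"{stem}_mask.tif")
        nbrs = _wm._neighbor_counts(m.skeleton)
        _io.write_overlay(m.skeleton, outdir / f"{stem}_overlay.png",
                          branch_mask=m.skeleton & (nbrs >= 3),
                          endpoint_mask=m.skeleton & (nbrs == 1),
                          background=image)
        row = {"image": Path(path).name, "group": rec.get("group", "")}
        row.update(m.as_row())
        rows.append(row)
        metrics.append(m)
        labels.append(rec.get("group"))

    _io.write_tsv(rows, outdir / "metrics.tsv")
    results = {"metrics": metrics, "rows": rows}

    groups = [g for g in labels if g]
    if len(set(groups)) == 2 and len(groups) == len(labels) and \
            min(groups.count(g) for g in set(groups)) >= 2:
        stats = _wm.compare_groups(metrics, labels)
        _io.write_tsv(stats, outdir / "group_stats.tsv")
        results["group_stats"] = stats

    _io.write_json(manifest, outdir / "manifest_wholemount.json")
    return results


def run_all(config, outdir):
    """Run whichever arms the config declares."""
    config.validate_paths()
    out = {}
    if config.arm in ("transcriptomics", "both"):
        out["transcriptomics"] = run_transcriptomics(config, outdir)
    if config.arm in ("wholemount", "both"):
        out["wholemount"] = run_wholemount(config, outdir)
    return out
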