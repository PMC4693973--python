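"""End-to-end orchestration: fuse coevolution networks with dynamic weights.

The fusion step overlays two independent evidence channels on the shared
reference residue numbering: per-residue dynamic weights (square
displacements along the top-2 most anharmonic collective modes) and
per-residue cumulative coevolution scores. Residues above a weight quantile
are flagged "important"; the ranking demands joint support — the combined
score is the product of the two channels, with linker status breaking ahead.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from . import io as cio
from .alignment import (
    cluster_and_weight,
    filter_gappy,
    filter_redundancy,
    map_to_reference,
    read_alignment,
    trivial_weighting,
)
from .coevolution import CoevolutionScorer
from .generate import ModeSpec, MsaGenSpec, TrajGenSpec, gen_msa, gen_trajectory
from .modes import fca, residue_weights
from .network import ResidueNetwork, build_network, communities, layout, linkers
from .trajectory import (
    Trajectory,
    fit_and_center,
    load_trajectory,
    spectrum_peaks,
    vacf,
    vacf_spectrum,
)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; partial artifacts are preserved on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class AllostericMap:
    """Per-residue fusion table plus the induced important-node subgraph."""

    table: pd.DataFrame  # indexed by residue number
    important_subgraph: nx.Graph
    quantile_cut: float


def overlay(
    net: ResidueNetwork,
    weights: dict[int, float],
    quantile_cut: float = 0.90,
    conservation: dict[int, float] | None = None,
) -> AllostericMap:
    """Fuse dynamic weights with the coevolution network.

    Residues at or above the ``quantile_cut`` quantile of the dynamic weight
    are flagged important and the subgraph they induce is extracted
    (``quantile_cut=0`` flags all residues, ``1`` none). Requires identical
    residue numbering in both channels.
    """
    if not 0 <= quantile_cut <= 1:
        raise ValueError("quantile_cut must be in [0, 1]")
    net_res = set(net.graph.nodes)
    w_res = set(weights)
    if net_res != w_res:
        orphans = sorted(net_res ^ w_res)
        raise ValueError(f"residue numbering mismatch; orphan residues: {orphans}")
    if net.partition is None:
        communities(net)
    part = net.partition
    link = {r for r, _, _ in linkers(net)}
    residues = sorted(w_res)
    wvals = np.array([weights[r] for r in residues])
    if quantile_cut >= 1.0:
        important = set()
    else:
        thr = float(np.quantile(wvals, quantile_cut))
        important = {r for r in residues if weights[r] >= thr}
    rows = {
        "dynamic_weight": [weights[r] for r in residues],
        "mi_node_score": [net.node_scores.get(r, 0.0) for r in residues],
        "conservation": [
            (conservation or {}).get(r, np.nan) for r in residues
        ],
        "community": [part[r] for r in residues],
        "linker": [r in link for r in residues],
        "important": [r in important for r in residues],
    }
    table = pd.DataFrame(rows, index=pd.Index(residues, name="residue"))
    sub = net.graph.subgraph(important).copy()
    return AllostericMap(table, sub, quantile_cut)


def rank_residues(amap: AllostericMap) -> pd.DataFrame:
    """Rank residues by (linker flag, dynamic_weight * mi_node_score) desc.

    Ties break by ascending residue number; adds ``combined_score`` and a
    1-based ``combined_rank`` column and returns the sorted table.
    """
    t = amap.table.copy()
    t["combined_score"] = t["dynamic_weight"] * t["mi_node_score"]
    order = sorted(
        t.index,
        key=lambda r: (-int(t.at[r, "linker"]), -t.at[r, "combined_score"], r),
    )
    t = t.loc[order]
    t["combined_rank"] = np.arange(1, len(t) + 1)
    amap.table = t
    return t


# ---------------------------------------------------------------------------
# configuration


DEFAULT_CONFIG: dict = {
    "seed": 17,
    "synthetic": {
        "msa": {
            "n_seq": 400,
            "n_col": 30,
            "coupled_pairs": [[11, 24, 0.9]],
            "conserved_cols": [[5, "G", 0.95]],
            "gap_rate": 0.0,
        },
        "trajectory": {
            "n_res": 30,
            "n_frames": 2500,
            "dt": 0.01,
            "noise_sd": 0.02,
            "modes": [
                {"support": [11, 24], "amplitude": 0.25, "kind": "double_well",
                 "barrier": 3.0},
                {"support": [4, 5, 6], "amplitude": 0.45, "kind": "gaussian",
                 "tau": 0.2},
                {"support": [15, 16], "amplitude": 0.15, "kind": "harmonic",
                 "wavenumber": 100.0},
            ],
        },
        "allosteric_residues": [12, 25],
    },
    "prep": {
        "min_ref_id": 0.0,  # synthetic families are diverse; real runs use 0.95
        "max_red": 0.99,
        "max_gap": 0.20,
        "cluster_id": 0.62,
    },
    "mi": {
        "pseudocount": 0.05,
        "gap_mode": "exclude_pairs",
        "n_rand": 100,
        "statistic": "mi_corrected",
        "cutoff": 6.5,
    },
    "dyn": {"fit_frame": 0, "n_pca": 8, "window": "hann"},
    "net": {"resolution": 1.0},
    "overlay": {"quantile": 0.90},
}


def default_config(seed: int = 17) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    cfg["seed"] = int(seed)
    return cfg


def validate_config(cfg: dict) -> None:
    """Validate thresholds, ranges and input paths before any compute."""
    import os

    if "seed" not in cfg:
        raise ValueError("config must set a seed")
    mi = cfg.get("mi", {})
    if mi.get("cutoff", 6.5) < 0:
        raise ValueError("mi.cutoff must be non-negative")
    if mi.get("n_rand", 100) < 2:
        raise ValueError("mi.n_rand must be >= 2")
    if mi.get("pseudocount", 0.05) < 0:
        raise ValueError("mi.pseudocount must be non-negative")
    prep = cfg.get("prep", {})
    for key in ("min_ref_id", "max_red", "max_gap", "cluster_id"):
        v = prep.get(key)
        if v is not None and not 0 <= v <= 1:
            raise ValueError(f"prep.{key} must be in [0, 1]")
    ov = cfg.get("overlay", {})
    if not 0 <= ov.get("quantile", 0.90) <= 1:
        raise ValueError("overlay.quantile must be in [0, 1]")
    if "synthetic" not in cfg:
        inputs = cfg.get("inputs", {})
        for key in ("msa", "traj"):
            if key not in inputs:
                raise ValueError(f"inputs.{key} required without a synthetic block")
            if not os.path.exists(inputs[key]):
                raise ValueError(f"input path does not exist: {inputs[key]}")


def _digest(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def run_pipeline(cfg: dict, out_dir) -> dict:
    """Execute prep -> mi -> dyn -> net -> overlay and write all artifacts.

    Returns a bundle dict with the fitted objects and artifact paths. The run
    is fully deterministic for a fixed config: re-running from the written
    manifest reproduces byte-identical TSV outputs.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    validate_config(cfg)
    seed = int(cfg["seed"])
    manifest: dict = {"parameters": cfg, "inputs": {}, "artifacts": []}
    t0 = time.time()

    def log(stage: str) -> None:
        print(f"[coevo] {stage} done ({time.time() - t0:.1f}s)", file=sys.stderr)

    def emit(name: str) -> str:
        manifest["artifacts"].append(name)
        return str(out / name)

    # ---- inputs -----------------------------------------------------------
    stage = "inputs"
    try:
        if "synthetic" in cfg:
            syn = cfg["synthetic"]
            mspec = MsaGenSpec(
                seed=seed,
                **{k: (
                    [tuple(x) for x in v]
                    if k in ("coupled_pairs", "conserved_cols")
                    else v
                ) for k, v in syn.get("msa", {}).items()},
            )
            msa, msa_truth = gen_msa(mspec)
            tdict = dict(syn.get("trajectory", {}))
            modes = [ModeSpec(**m) for m in tdict.pop("modes", [])]
            tspec = TrajGenSpec(seed=seed + 1, modes=modes, **tdict)
            traj, traj_truth = gen_trajectory(tspec)
            ref_seq = msa.rows[0].replace("-", "")
            ref_id = msa.ids[0]
            manifest["inputs"]["synthetic_truth"] = {
                "msa": msa_truth,
                "trajectory": {k: v for k, v in traj_truth.items() if k != "modes"},
                "allosteric_residues": syn.get("allosteric_residues"),
            }
        else:
            inputs = cfg["inputs"]
            msa = read_alignment(inputs["msa"], inputs.get("msa_format", "fasta"))
            traj = load_trajectory(inputs["traj"])
            ref_path = inputs.get("ref")
            if ref_path and str(ref_path).endswith(".pdb"):
                ref_seq, _, _ = cio.read_pdb_calpha(ref_path)
                ref_id = str(ref_path)
            elif ref_path:
                ref = read_alignment(ref_path, "fasta")
                ref_seq, ref_id = ref.rows[0].replace("-", ""), ref.ids[0]
            else:
                ref_seq, ref_id = msa.rows[0].replace("-", ""), msa.ids[0]
            for key, p in inputs.items():
                if isinstance(p, str) and Path(p).exists():
                    manifest["inputs"][key] = _digest(Path(p).read_bytes())
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc
    log(stage)

    # ---- prep -------------------------------------------------------------
    stage = "prep"
    try:
        prep = cfg.get("prep", {})
        kept, mapping = map_to_reference(
            msa, ref_seq, ref_id=ref_id,
            min_identity=prep.get("min_ref_id", 0.95),
        )
        kept = filter_redundancy(kept, prep.get("max_red", 0.99), ref_id=ref_id)
        kept = filter_gappy(kept, prep.get("max_gap", 0.20))
        wa = cluster_and_weight(kept, mapping, prep.get("cluster_id", 0.62))
        cio.write_fasta(kept, emit("curated.fasta"))
        cio.write_mapping_tsv(mapping, emit("mapping.tsv"))
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc
    log(stage)

    # ---- mi ---------------------------------------------------------------
    stage = "mi"
    try:
        mi_cfg = cfg.get("mi", {})
        scorer = CoevolutionScorer(
            pseudocount=mi_cfg.get("pseudocount", 0.05),
            gap_mode=mi_cfg.get("gap_mode", "exclude_pairs"),
            n_randomizations=mi_cfg.get("n_rand", 100),
            statistic=mi_cfg.get("statistic", "mi_corrected"),
            cutoff=mi_cfg.get("cutoff", 6.5),
            random_state=seed + 2,
        ).fit(wa)
        res = wa.residue_numbers
        cio.write_matrix_tsv(scorer.mi_, res, emit("mi.tsv"))
        cio.write_matrix_tsv(scorer.mi_corrected_, res, emit("mi_corrected.tsv"))
        cio.write_matrix_tsv(scorer.z_, res, emit("z.tsv"))
        cio.write_conservation_tsv(scorer.conservation_, res, emit("conservation.tsv"))
        cio.write_edges_tsv(scorer.edges_, emit("edges.tsv"))
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc
    log(stage)

    # ---- dyn --------------------------------------------------------------
    stage = "dyn"
    try:
        dyn = cfg.get("dyn", {})
        fitted = fit_and_center(traj, dyn.get("fit_frame", 0))
        mode_set = fca(fitted, n_modes=dyn.get("n_pca", 10))
        dyn_weights: dict[int, float] = {int(r): 0.0 for r in traj.residue_ids}
        for k in range(min(2, mode_set.vectors.shape[1])):
            for r, w in residue_weights(
                mode_set.vectors[:, k], traj.residue_ids
            ).items():
                dyn_weights[r] += w
        lags, acf = vacf(traj)
        wn, inten = vacf_spectrum(acf, traj.dt, dyn.get("window", "hann"))
        cio.write_series_tsv(
            {"residue": np.array(sorted(dyn_weights)),
             "dynamic_weight": np.array([dyn_weights[r] for r in sorted(dyn_weights)])},
            emit("dynamic_weights.tsv"),
        )
        cio.write_series_tsv(
            {"anharmonicity": mode_set.anharmonicity,
             "cosine_content": mode_set.cosine_content,
             "variance": mode_set.extras["mode_variances"]},
            emit("fca_modes.tsv"),
        )
        cio.write_series_tsv({"lag_ps": lags, "vacf": acf}, emit("vacf.tsv"))
        cio.write_series_tsv(
            {"wavenumber_cm1": wn, "intensity": inten}, emit("spectrum.tsv")
        )
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc
    log(stage)

    # ---- net --------------------------------------------------------------
    stage = "net"
    try:
        net = build_network(scorer.edges_, scorer.node_scores_)
        part, q = communities(net, cfg.get("net", {}).get("resolution", 1.0))
        pos = layout(net)
        cio.write_edges_tsv(net.edges, emit("network_edges.tsv"))
        cio.write_series_tsv(
            {"residue": np.array(net.nodes),
             "community": np.array([part[n] for n in net.nodes]),
             "x": np.array([pos[n][0] for n in net.nodes]),
             "y": np.array([pos[n][1] for n in net.nodes])},
            emit("network_nodes.tsv"),
        )
        cio.write_graphml(net, emit("network.graphml"))
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc
    log(stage)

    # ---- overlay ----------------------------------------------------------
    stage = "overlay"
    try:
        cons = dict(zip(wa.residue_numbers, scorer.conservation_))
        amap = overlay(
            net,
            dyn_weights,
            cfg.get("overlay", {}).get("quantile", 0.90),
            conservation=cons,
        )
        table = rank_residues(amap)
        with open(emit("allosteric_map.tsv"), "w") as fh:
            table.to_csv(fh, sep="\t", float_format="%.10g")
        summary = {
            "n_seq_curated": wa.n_seq,
            "n_clusters": wa.n_clusters,
            "min_identity": round(wa.min_identity, 6),
            "n_edges": len(scorer.edges_),
            "n_communities": len(set(part.values())),
            "modularity": round(q, 6),
            "top2_fluctuation_fraction": round(
                mode_set.extras["top2_fluctuation_fraction"], 6
            ),
            "vacf_peak_cm1": round(spectrum_peaks(wn, inten, 1)[0], 3),
            "top5_residues": [int(r) for r in table.index[:5]],
        }
        with open(emit("summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc
    log(stage)

    manifest["versions"] = {"python": sys.version.split()[0]}
    from . import __version__

    manifest["versions"]["coevodyn"] = __version__
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "wa": wa,
        "scorer": scorer,
        "mode_set": mode_set,
        "dynamic_weights": dyn_weights,
        "network": net,
        "map": amap,
        "table": table,
        "summary": summary,
        "out_dir": str(out),
    }


def rerun_from_manifest(manifest_path, out_dir) -> dict:
    """Re-execute a recorded run; deterministic stages are byte-identical."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    return run_pipeline(manifest["parameters"], out_dir)
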