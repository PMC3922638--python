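"""TSV input, result serialization, and trace round-tripping.

Input is a UTF-8 TSV with one row per (SNV, sample):

    id  gene  sample  variant_reads  total_reads  copy_number  zygosity

`gene` is optional; counts may use thousands separators ("12,085").
Outputs are plain text: a best-tree JSON, the partial-order DOT, the
co-clustering matrix TSV, the likelihood trace TSV, a YAML echo of the run
configuration, and a compact JSON trace for later consensus summaries.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .consensus import coclustering_matrix, edge_frequencies, write_dot
from .mcmc import McmcConfig, McmcTrace, TreeSnapshot, best_tree
from .model import SampleSet, SnvObservation, default_genotype_config

__all__ = ["read_snv_table", "write_results", "write_trace", "read_trace"]


class FormatError(ValueError):
    """Malformed input table."""


_REQUIRED = ["id", "sample", "variant_reads", "total_reads"]


def read_snv_table(path: str | Path) -> SampleSet:
    """Parse a counts TSV into a SampleSet.

    Genotype configurations are built from the copy_number and zygosity
    columns (defaulting to heterozygous diploid when absent).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", thousands=",", dtype={"id": str, "sample": str})
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    for col in _REQUIRED:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if "copy_number" not in df.columns:
        df["copy_number"] = 2
    if "zygosity" not in df.columns:
        df["zygosity"] = "heterozygous"

    samples = list(dict.fromkeys(df["sample"]))
    snv_ids = list(dict.fromkeys(df["id"]))
    by_key = {(r["id"], r["sample"]): r for _, r in df.iterrows()}
    snvs = []
    for sid in snv_ids:
        b_list, d_list = [], []
        first = None
        for sample in samples:
            row = by_key.get((sid, sample))
            if row is None:
                raise FormatError(f"{path}: missing cell for SNV {sid!r}, sample {sample!r}")
            b_list.append(int(row["variant_reads"]))
            d_list.append(int(row["total_reads"]))
            if first is None:
                first = row
        genotype = default_genotype_config(
            int(first["copy_number"]), str(first["zygosity"])
        )
        snvs.append(SnvObservation(sid, tuple(b_list), tuple(d_list), genotype))
    return SampleSet(snvs, samples)


def _snapshot_to_dict(snap: TreeSnapshot, snv_ids: list[str]) -> dict:
    return {
        "parents": snap.parents.tolist(),
        "z": snap.z.tolist(),
        "phi": np.round(snap.phi, 6).tolist(),
        "eta": np.round(snap.eta, 6).tolist(),
        "log_weights": np.round(snap.log_weights, 6).tolist(),
        "hypers": list(snap.hypers),
        "loglik_data": snap.loglik_data,
        "loglik_complete": snap.loglik_complete,
        "node_genotypes": [sorted(g) for g in snap.node_genotypes(snv_ids)],
    }


def _snapshot_from_dict(d: dict) -> TreeSnapshot:
    return TreeSnapshot(
        parents=np.array(d["parents"], dtype=int),
        z=np.array(d["z"], dtype=int),
        phi=np.array(d["phi"], dtype=float),
        eta=np.array(d["eta"], dtype=float),
        log_weights=np.array(d["log_weights"], dtype=float),
        hypers=tuple(d["hypers"]),
        loglik_data=float(d["loglik_data"]),
        loglik_complete=float(d["loglik_complete"]),
    )


def write_trace(trace: McmcTrace, path: str | Path) -> None:
    """Serialize a trace as JSON (snapshots without the genotype cache)."""
    payload = {
        "snv_ids": trace.snv_ids,
        "sample_labels": trace.sample_labels,
        "config": dataclasses.asdict(trace.config),
        "snapshots": [
            {
                k: v
                for k, v in _snapshot_to_dict(s, trace.snv_ids).items()
                if k != "node_genotypes"
            }
            for s in trace.snapshots
        ],
    }
    Path(path).write_text(json.dumps(payload))


def read_trace(path: str | Path) -> McmcTrace:
    payload = json.loads(Path(path).read_text())
    cfg_dict = payload["config"]
    if cfg_dict.get("fixed_hypers") is not None:
        cfg_dict["fixed_hypers"] = tuple(cfg_dict["fixed_hypers"])
    config = McmcConfig(**cfg_dict)
    return McmcTrace(
        [_snapshot_from_dict(d) for d in payload["snapshots"]],
        payload["snv_ids"],
        payload["sample_labels"],
        config,
    )


def write_results(
    trace: McmcTrace, outdir: str | Path, edge_threshold: float = 0.1
) -> dict[str, Path]:
    """Write all run artifacts to `outdir`; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    best = best_tree(trace)
    paths["best_tree"] = outdir / "best_tree.json"
    paths["best_tree"].write_text(
        json.dumps(_snapshot_to_dict(best, trace.snv_ids), indent=2)
    )

    po = edge_frequencies(trace)
    paths["partial_order"] = outdir / "partial_order.dot"
    paths["partial_order"].write_text(write_dot(po, edge_threshold))

    cc = coclustering_matrix(trace)
    paths["cocluster"] = outdir / "cocluster.tsv"
    pd.DataFrame(cc.C, index=trace.snv_ids, columns=trace.snv_ids).to_csv(
        paths["cocluster"], sep="\t"
    )

    paths["loglik_trace"] = outdir / "loglik_trace.tsv"
    pd.DataFrame(
        {
            "iteration": np.arange(len(trace.snapshots)) + trace.config.burn_in,
            "loglik_complete": [s.loglik_complete for s in trace.snapshots],
            "loglik_data": [s.loglik_data for s in trace.snapshots],
        }
    ).to_csv(paths["loglik_trace"], sep="\t", index=False)

    paths["config"] = outdir / "run_config.yaml"
    paths["config"].write_text(yaml.safe_dump(dataclasses.asdict(trace.config)))

    paths["trace"] = outdir / "trace.json"
    write_trace(trace, paths["trace"])
    return paths
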