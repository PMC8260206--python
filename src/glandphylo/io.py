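"""Readers and writers for the pipeline's interchange formats.

Canonical formats are tab-separated tables (UTF-8, header row, no index
column) for flat data, JSON for structured objects, Newick for clone
trees, and a minimal per-sample VCF for interoperability with variant
callers.  Every writer here produces files its reader accepts.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ductal import DuctalGraph
from .matrix import VafMatrix, VafMatrixError
from .phylogeny import CloneTree


class SchemaError(ValueError):
    """A file violates its declared schema (exit code 2 in the CLI)."""


SAMPLE_COLUMNS = [
    "sample_id",
    "donor_id",
    "age_years",
    "x_um",
    "y_um",
    "z_um",
    "duct_node",
    "telomere_bp",
]


def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# -- mutation table ---------------------------------------------------


def write_mutation_table(vaf_matrix: VafMatrix, path) -> None:
    _write_tsv(vaf_matrix.to_long(), path)


def read_mutation_table(path) -> VafMatrix:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"mutation_id": str, "sample_id": str})
    except Exception as exc:  # noqa: BLE001 - rewrap as schema error
        raise SchemaError(f"cannot parse {path}: {exc}") from exc
    try:
        return VafMatrix.from_long(df)
    except VafMatrixError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


# -- samples ----------------------------------------------------------


def write_samples(samples: pd.DataFrame, path) -> None:
    _write_tsv(samples, path)


def read_samples(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "duct_node": str})
    missing = set(SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise SchemaError(f"{path}: duplicate sample ids")
    return df


# -- ductal graph -----------------------------------------------------


def write_duct(graph: DuctalGraph, path) -> None:
    graph.to_json(path)


def read_duct(path) -> DuctalGraph:
    try:
        return DuctalGraph.from_json(path)
    except (KeyError, ValueError) as exc:
        raise SchemaError(f"{path}: {exc}") from exc


# -- simulation truth -------------------------------------------------


def write_truth(truth, path) -> None:
    from dataclasses import asdict

    payload = {
        "config": asdict(truth.config),
        "clone_table": truth.clone_table.to_dict(orient="records"),
        "cc": {c: truth.cc.loc[c].to_dict() for c in truth.cc.index},
        "true_burden": truth.true_burden.to_dict(),
        "stem_counts": {k: int(v) for k, v in truth.stem_counts.items()},
        "mutation_assignments": dict(
            zip(truth.mutations["mutation_id"], truth.mutations["clone_id"])
        ),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True)


def read_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# -- burden / clock ---------------------------------------------------


def write_burden(burden_table: pd.DataFrame, path) -> None:
    _write_tsv(burden_table, path)


def read_burden(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str})


def write_clock_fit(fit, path) -> None:
    with open(path, "w") as fh:
        json.dump(None if fit is None else fit.to_dict(), fh, sort_keys=True, indent=1)


# -- clusters ---------------------------------------------------------


def write_clusters(result, path_assignments, path_cc, path_diagnostics=None) -> None:
    assign = result.assignments.rename_axis("mutation_id").reset_index()
    assign = assign.sort_values(["cluster_id", "mutation_id"], kind="stable")
    _write_tsv(assign[["cluster_id", "mutation_id"]], path_assignments)
    long = (
        result.median_vaf.rename_axis("cluster_id")
        .reset_index()
        .melt(id_vars="cluster_id", var_name="sample_id", value_name="m")
    )
    cc_long = (
        result.cc.rename_axis("cluster_id")
        .reset_index()
        .melt(id_vars="cluster_id", var_name="sample_id", value_name="cc")
    )
    merged = long.merge(cc_long, on=["cluster_id", "sample_id"]).sort_values(
        ["cluster_id", "sample_id"], kind="stable"
    )
    _write_tsv(merged, path_cc)
    if path_diagnostics is not None:
        diag = {
            "converged": bool(result.converged),
            "trace_n_clusters": list(map(int, result.trace_n_clusters)),
            "map_score": float(result.map_score),
            "n_clusters": int(len(result.clusters)),
        }
        if result.cocluster is not None:
            vals = result.cocluster.to_numpy()
            diag["cocluster_checksum"] = float(np.round(vals.sum(), 6))
        with open(path_diagnostics, "w") as fh:
            json.dump(diag, fh, sort_keys=True, indent=1)


def read_cluster_cc(path) -> pd.DataFrame:
    """cluster x sample cc matrix from cluster_cc.tsv."""
    df = pd.read_csv(path, sep="\t", dtype={"cluster_id": str, "sample_id": str})
    return df.pivot(index="cluster_id", columns="sample_id", values="cc")


def read_cluster_assignments(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return pd.Series(
        df["cluster_id"].to_numpy(), index=df["mutation_id"], name="cluster_id"
    )


# -- trees ------------------------------------------------------------


def write_tree(tree: CloneTree, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


def read_tree(path) -> CloneTree:
    return CloneTree.from_newick(Path(path).read_text())


def write_evidence(evidence, conflicts, path_evidence, path_conflicts) -> None:
    ev = pd.DataFrame(
        [
            {
                "ancestor": e.ancestor,
                "descendant": e.descendant,
                "rule": e.rule,
                "witness_samples": ",".join(e.witness_samples),
            }
            for e in evidence
        ],
        columns=["ancestor", "descendant", "rule", "witness_samples"],
    )
    _write_tsv(ev, path_evidence)
    cf = pd.DataFrame(
        [
            {
                "cluster_a": c.cluster_a,
                "cluster_b": c.cluster_b,
                "rule": c.rule,
                "detail": c.detail,
            }
            for c in conflicts
        ],
        columns=["cluster_a", "cluster_b", "rule", "detail"],
    )
    _write_tsv(cf, path_conflicts)


# -- spatial ----------------------------------------------------------


def write_spatial(spatial: pd.DataFrame, path) -> None:
    _write_tsv(spatial, path)


def write_gradients(gradients: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(gradients, fh, sort_keys=True, indent=1)


def write_territories(territories, path) -> None:
    rows = []
    for t in territories:
        rows.append(
            {
                "cluster_id": t.cluster_id,
                "n_samples": t.n_samples,
                "n_components": t.n_components,
                "span_um": t.span_um,
                "positive_samples": ",".join(t.positive_samples),
                "components": ";".join(
                    ",".join(sorted(c)) for c in t.components
                ),
            }
        )
    _write_tsv(
        pd.DataFrame(
            rows,
            columns=[
                "cluster_id",
                "n_samples",
                "n_components",
                "span_um",
                "positive_samples",
                "components",
            ],
        ),
        path,
    )


# -- VCF import/export ------------------------------------------------

_VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chrSim>
##INFO=<ID=ALTC,Number=1,Type=Integer,Description="Alt read count">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def export_vcf(vaf_matrix: VafMatrix, out_dir, samples=None) -> list[Path]:
    """Write one minimal VCF per sample (synthetic coordinates).

    Positions are the 1-based rank of the mutation id on a synthetic
    contig ``chrSim``; the mutation id is kept in the ID column and the
    counts travel in both INFO (ALTC/DP) and the sample's AD/DP fields.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vm = vaf_matrix.sort()
    samples = samples or vm.samples
    paths = []
    pos = {m: i + 1 for i, m in enumerate(vm.mutations)}
    for s in samples:
        lines = [_VCF_HEADER.format(sample=s)]
        for m in vm.mutations:
            depth = int(vm.depth.loc[m, s])
            if depth == 0:
                continue
            alt = int(vm.alt.loc[m, s])
            lines.append(
                f"chrSim\t{pos[m]}\t{m}\tA\tT\t.\tPASS\t"
                f"ALTC={alt};DP={depth}\tAD:DP\t{depth - alt},{alt}:{depth}\n"
            )
        path = out_dir / f"{s}.vcf"
        path.write_text("".join(lines))
        paths.append(path)
    return paths


def import_vcf(paths, sample_ids=None) -> VafMatrix:
    """Assemble a VafMatrix from one VCF per sample.

    Counts come from INFO ALTC/DP when present, otherwise from the
    first sample's AD (ref,alt) / DP fields.  Loci are unioned across
    files; a sample missing a locus gets depth 0.
    """
    from cyvcf2 import VCF

    paths = [Path(p) for p in paths]
    if sample_ids is None:
        sample_ids = [p.stem for p in paths]
    records: list[pd.DataFrame] = []
    for path, s_id in zip(paths, sample_ids):
        rows = []
        try:
            vcf = VCF(str(path))
            for var in vcf:
                m_id = var.ID or f"{var.CHROM}_{var.POS}"
                alt = var.INFO.get("ALTC")
                depth = var.INFO.get("DP")
                if alt is None or depth is None:
                    ad = var.format("AD")
                    dp = var.format("DP")
                    if ad is None or dp is None:
                        raise SchemaError(
                            f"{path}: record {m_id} has neither ALTC/DP INFO "
                            "nor AD/DP FORMAT fields"
                        )
                    alt = int(ad[0][-1])
                    depth = int(dp[0][0])
                rows.append((str(m_id), s_id, int(alt), int(depth)))
        except SchemaError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise SchemaError(f"malformed VCF {path}: {exc}") from exc
        records.append(
            pd.DataFrame(rows, columns=["mutation_id", "sample_id", "alt_count", "depth"])
        )
    long = pd.concat(records, ignore_index=True)
    if long.empty:
        raise SchemaError("no records in any VCF")
    try:
        return VafMatrix.from_long(long)
    except VafMatrixError as exc:
        raise SchemaError(str(exc)) from exc
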