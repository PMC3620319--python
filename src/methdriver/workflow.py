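"""End-to-end orchestration: preprocess -> discretize -> drivers -> evidence.

``run_pipeline`` works on in-memory objects; ``run_from_paths`` reads the
input files, runs the pipeline and writes every stage artifact plus a
run manifest (config, seed, input checksums, cascade counts), from which
a run is reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import discretize, drivers, preprocess, subtype, validation
from .config import AnalysisConfig
from .data_model import (
    ValidationError,
    normal_samples,
    read_annotation,
    read_edge_list,
    read_gene_list,
    read_gmt,
    read_matrix,
    read_sample_sheet,
    tumor_samples,
    validate_beta_matrix,
    write_gene_list,
    write_gmt,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    ternary: pd.DataFrame
    driver_result: drivers.DriverResult
    validation_report: pd.DataFrame | None
    cluster: subtype.ClusterResult | None
    subtype_calls: list[subtype.SubtypeCall] | None
    manifest: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    methylation: pd.DataFrame,
    expression: pd.DataFrame,
    annotation: pd.DataFrame,
    samples: pd.DataFrame,
    pathways: dict[str, frozenset[str]],
    config: AnalysisConfig,
    cancer_genes: frozenset[str] | None = None,
    network=None,
    detection_p: pd.DataFrame | None = None,
) -> PipelineResult:
    """Run every stage on in-memory inputs; subtype stage only when labeled."""
    validate_beta_matrix(methylation)
    loci = methylation.index
    if detection_p is not None:
        if not detection_p.index.equals(loci) or not detection_p.columns.equals(
            methylation.columns
        ):
            raise ValidationError("detection p-value matrix index mismatch with beta matrix")
        loci = preprocess.filter_unreliable_loci(
            detection_p, config.detection_p_cut, config.detection_max_fraction
        )
    loci = preprocess.exclude_sex_chromosomes(loci, annotation)
    meth = methylation.loc[loci]

    normals = [s for s in normal_samples(samples) if s in meth.columns]
    tumors = [s for s in tumor_samples(samples) if s in meth.columns]
    if not set(tumors) & set(expression.columns):
        raise ValidationError("no tumor sample overlap between methylation and expression")

    ref = discretize.normal_reference(meth, normals)
    ternary = discretize.discretize_matrix(
        meth.loc[ref.loci, tumors], ref, config.discretize_q, config.discretize_scope
    )

    result = drivers.call_drivers(ternary, expression, annotation, pathways, config)

    report = None
    if cancer_genes is not None and result.driver_genes:
        background = frozenset(annotation.loc[ternary.index, "gene_id"]) | frozenset(
            result.driver_genes
        )
        rows = []
        enr = validation.cancer_gene_enrichment(
            frozenset(result.driver_genes), cancer_genes, background
        )
        rows.append(
            {
                "test": "known_cancer_gene_enrichment",
                "n_test": enr.n_test,
                "overlap": enr.overlap,
                "percentage": enr.percentage,
                "p": enr.p,
            }
        )
        if network is not None:
            ppi = validation.ppi_neighbor_enrichment(
                frozenset(result.driver_genes), cancer_genes, network
            )
            if ppi is None:
                rows.append(
                    {"test": "ppi_neighbor_enrichment", "n_test": 0, "overlap": 0,
                     "percentage": float("nan"), "p": float("nan")}
                )
            else:
                rows.append(
                    {
                        "test": "ppi_neighbor_enrichment",
                        "n_test": ppi.n_test,
                        "overlap": ppi.overlap,
                        "percentage": ppi.percentage,
                        "p": ppi.p,
                    }
                )
        report = pd.DataFrame(rows)

    cluster = None
    subtype_calls = None
    labeled = samples.set_index("sample_id")["subtype"]
    has_labels = labeled.loc[[t for t in tumors if t in labeled.index]].notna().any()
    driver_loci = [loc for loc in result.driver_loci if loc in ternary.index]
    if has_labels and driver_loci:
        sub_ternary = ternary.loc[driver_loci]
        k = min(config.n_clusters, sub_ternary.shape[1])
        cluster = subtype.hierarchical_cluster(sub_ternary, k, config.jaccard_binarize)
        locus_dir = {
            c.locus_id: c.direction
            for c in result.calls
            if c.is_driver and c.locus_id in sub_ternary.index
        }
        subtype_calls = subtype.subtype_specific_test(
            sub_ternary, locus_dir, labeled, annotation, config.subtype_q
        )

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "n_loci_analyzed": int(ternary.shape[0]),
        "n_tumors": len(tumors),
        "n_normals": len(normals),
        "cascade": result.cascade,
        "inputs": {},
    }
    return PipelineResult(
        ternary=ternary,
        driver_result=result,
        validation_report=report,
        cluster=cluster,
        subtype_calls=subtype_calls,
        manifest=manifest,
    )


def run_from_paths(
    methylation_path,
    expression_path,
    annotation_path,
    samples_path,
    pathways_path,
    outdir,
    config: AnalysisConfig,
    cancer_genes_path=None,
    network_path=None,
    detection_p_path=None,
) -> PipelineResult:
    """File-based entry point: read inputs, run, write artifacts + manifest."""
    paths = {
        "methylation": methylation_path,
        "expression": expression_path,
        "annotation": annotation_path,
        "samples": samples_path,
        "pathways": pathways_path,
    }
    if cancer_genes_path:
        paths["cancer_genes"] = cancer_genes_path
    if network_path:
        paths["network"] = network_path
    if detection_p_path:
        paths["detection_p"] = detection_p_path
    for name, p in paths.items():
        if not Path(p).exists():
            raise FileNotFoundError(f"missing {name} input: {p}")

    meth = read_matrix(methylation_path)
    expr = read_matrix(expression_path)
    annotation = read_annotation(annotation_path)
    samples = read_sample_sheet(samples_path)
    pathways = read_gmt(pathways_path)
    cancer_genes = read_gene_list(cancer_genes_path) if cancer_genes_path else None
    network = read_edge_list(network_path) if network_path else None
    detection_p = read_matrix(detection_p_path) if detection_p_path else None

    result = run_pipeline(
        meth,
        expr,
        annotation,
        samples,
        pathways,
        config,
        cancer_genes=cancer_genes,
        network=network,
        detection_p=detection_p,
    )
    result.manifest["inputs"] = {name: _sha256(Path(p)) for name, p in paths.items()}

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    discretize.write_ternary(result.ternary, out / "ternary.tsv")
    result.driver_result.to_frame().to_csv(out / "driver_calls.tsv", sep="\t", index=False)
    write_gene_list(result.driver_result.driver_genes, out / "driver_genes.txt")
    downstream = {
        f"{c.locus_id}|{c.gene_id}": c.downstream_gene_ids
        for c in result.driver_result.calls
        if c.is_driver
    }
    if downstream:
        write_gmt(downstream, out / "downstream.gmt")
    enr_rows = [
        {"locus_id": c.locus_id, "gene_id": c.gene_id, "pathway": name,
         "overlap": k, "p": p, "q": q}
        for c in result.driver_result.calls
        for name, (k, p, q) in sorted(c.enriched_pathways.items())
    ]
    pd.DataFrame(enr_rows).to_csv(out / "enriched_pathways.tsv", sep="\t", index=False)
    if result.validation_report is not None:
        result.validation_report.to_csv(out / "validation.tsv", sep="\t", index=False)
    if result.cluster is not None:
        result.cluster.labels.rename_axis("sample_id").to_csv(
            out / "cluster_labels.tsv", sep="\t"
        )
        (out / "dendrogram.nwk").write_text(result.cluster.newick + "\n")
    if result.subtype_calls is not None:
        subtype.subtype_calls_frame(result.subtype_calls).to_csv(
            out / "subtype_calls.tsv", sep="\t", index=False
        )
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(result.manifest, fh, indent=1, default=str)
    return result
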