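"""Thin orchestration tying the modules into the end-to-end pipeline.

``build_species_profile`` runs annotations → profile for one species;
``compare_species`` runs the cross-species stage on two built profiles.
The CLI wraps these; library users can call them directly.
"""

from __future__ import annotations

import logging
import os
import time

import pandas as pd

from . import __version__
from .annotations import (
    build_binary_matrix,
    filter_evidence,
    read_emapper,
    read_gaf,
    read_table,
)
from .config import RunConfig, SpeciesInputs, file_checksum, output_header
from .crossspecies import (
    celltype_means,
    correlate,
    rescale_shared,
    shared_signature,
    shared_terms,
)
from .differential import rank_terms, write_table
from .errors import IntegrityError, UsageError
from .ontology import OntologyDAG, parse_obo
from .profile import (
    ExpressionMatrix,
    FunctionalProfile,
    build_profile,
    embed_and_cluster,
    normalize,
    read_cell_meta,
    read_counts_dense,
    read_counts_mtx,
    scale,
    write_profile,
)

logger = logging.getLogger(__name__)


def _timed(stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s started", stage)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                logger.info("stage %s finished in %.2fs", stage, dt)
            else:
                logger.error("stage %s failed after %.2fs: %s", stage, dt, exc)
            return False

    return _Timer()


def load_expression(inputs: SpeciesInputs) -> ExpressionMatrix:
    if inputs.counts_dense:
        expr = read_counts_dense(inputs.counts_dense)
    elif inputs.counts_mtx:
        expr = read_counts_mtx(
            inputs.counts_mtx, inputs.counts_cells, inputs.counts_genes
        )
    else:
        raise UsageError("no counts input configured")
    if inputs.cell_meta:
        expr.cell_meta = read_cell_meta(inputs.cell_meta)
    return expr


def load_annotations(inputs: SpeciesInputs):
    fmt = inputs.annotation_format
    if fmt == "gaf":
        return read_gaf(inputs.annotations)
    if fmt == "table":
        return read_table(
            inputs.annotations,
            gene_col=inputs.gene_col,
            term_col=inputs.term_col,
            evidence_col=inputs.evidence_col or None,
        )
    if fmt == "emapper":
        return read_emapper(inputs.annotations)
    raise UsageError(f"unknown annotation format {fmt!r}")


def build_species_profile(
    config: RunConfig,
    inputs: SpeciesInputs,
    dag: OntologyDAG | None = None,
    cluster: bool = True,
) -> FunctionalProfile:
    """annotations → binary matrix → profile → normalize/scale (→ cluster)."""
    if dag is None:
        with _timed("ontology"):
            dag = parse_obo(config.obo, relations=config.relations)
    with _timed("annotations"):
        records = filter_evidence(load_annotations(inputs), config.evidence_set)
        expr = load_expression(inputs)
        bam = build_binary_matrix(
            records,
            dag,
            namespace=config.namespace,
            gene_universe=expr.genes,
            propagate_ancestors=config.propagate_ancestors,
        )
    with _timed("profile"):
        prof = build_profile(expr, bam)
        prof = normalize(prof, total=config.normalize_total)
        prof = scale(prof, clip=config.clip)
        if "term_name" not in prof.adata.var:
            prof.adata.var["term_name"] = [
                dag.names.get(t, t) for t in prof.terms
            ]
    if cluster:
        with _timed("embed_and_cluster"):
            n_pcs = min(config.n_pcs, prof.adata.shape[0] - 1, prof.adata.shape[1] - 1)
            prof = embed_and_cluster(
                prof,
                n_pcs=n_pcs,
                k_neighbors=config.k_neighbors,
                resolution=config.resolution,
                seed=config.seed,
                n_variable=config.n_variable_terms,
            )
    prof.adata.uns["ontology_sha256"] = (
        file_checksum(config.obo) if config.obo and os.path.exists(config.obo) else ""
    )
    return prof


def compare_species(
    config: RunConfig,
    profile_a: FunctionalProfile,
    profile_b: FunctionalProfile,
    dag: OntologyDAG,
):
    """Shared-term restriction, rescale, means, correlation, differential tables.

    Returns ``(correlation matrix, diff table A, diff table B, rescaled A,
    rescaled B)``.
    """
    sum_a = profile_a.adata.uns.get("ontology_sha256", "")
    sum_b = profile_b.adata.uns.get("ontology_sha256", "")
    if sum_a and sum_b and sum_a != sum_b:
        raise IntegrityError(
            "profiles were built against different ontology releases"
        )
    with _timed("crossspecies"):
        shared = shared_terms(profile_a, profile_b)
        res_a = rescale_shared(profile_a, shared, clip=config.clip)
        res_b = rescale_shared(profile_b, shared, clip=config.clip)
        corr = correlate(
            celltype_means(res_a, config.group_key),
            celltype_means(res_b, config.group_key),
        )
    with _timed("differential"):
        diff_a = rank_terms(
            res_a,
            group_key=config.group_key,
            alpha=config.alpha,
            min_log2fc=config.min_log2fc,
            min_pct=config.min_pct,
        )
        diff_b = rank_terms(
            res_b,
            group_key=config.group_key,
            alpha=config.alpha,
            min_log2fc=config.min_log2fc,
            min_pct=config.min_pct,
        )
    return corr, diff_a, diff_b, res_a, res_b


def write_compare_outputs(
    config: RunConfig,
    corr: pd.DataFrame,
    diff_a: pd.DataFrame,
    diff_b: pd.DataFrame,
    dag: OntologyDAG,
    pairs: list[tuple[str, str]] | None = None,
    heatmap: bool = True,
) -> None:
    """Write correlation matrix, per-species marker tables, pair signatures."""
    os.makedirs(config.outdir, exist_ok=True)
    checksum = file_checksum(config.obo) if config.obo else ""
    header = output_header(__version__, checksum, config.seed)

    corr_path = os.path.join(config.outdir, "correlation.tsv")
    with open(corr_path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        corr.to_csv(fh, sep="\t")
    write_table(diff_a, os.path.join(config.outdir, "markers_species_a.tsv"), header)
    write_table(diff_b, os.path.join(config.outdir, "markers_species_b.tsv"), header)

    if pairs is None:
        # best partner per species-A cell type
        pairs = [(a, corr.loc[a].idxmax()) for a in corr.index]
    for ct_a, ct_b in pairs:
        for direction in ("up", "down"):
            sig = shared_signature(
                diff_a,
                diff_b,
                ct_a,
                ct_b,
                dag,
                direction=direction,
                alpha=config.alpha,
                top_n=config.top_n,
            )
            safe = f"{ct_a}__{ct_b}__{direction}".replace("/", "_").replace(" ", "_")
            path = os.path.join(config.outdir, f"signature_{safe}.tsv")
            with open(path, "w") as fh:
                for line in header:
                    fh.write(f"# {line}\n")
                sig.to_csv(fh, sep="\t", index=False)

    if heatmap:
        try:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt
            import seaborn as sns

            g = sns.clustermap(corr.fillna(0), cmap="vlag", center=0)
            g.savefig(os.path.join(config.outdir, "correlation_heatmap.png"), dpi=120)
            plt.close("all")
        except Exception as exc:  # plotting must never sink a run
            logger.warning("heatmap skipped: %s", exc)

    with open(os.path.join(config.outdir, "config_echo.yaml"), "w") as fh:
        fh.write(config.to_yaml())
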