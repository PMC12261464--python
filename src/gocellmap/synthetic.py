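"""Synthetic ontologies and paired-species data with planted correspondences.

The generator builds everything the pipeline consumes — a toy GO BP
ontology, per-species gene→term annotation tables, and per-species count
matrices with cell-type labels — around a known ground truth: pairs of
cell types across the two "species" share a planted set of active GO
terms, while the species share NO gene identifiers. Any cross-species
signal the pipeline recovers must therefore flow through the ontology,
exactly the situation the method is designed for.

Counts follow a negative-binomial model (gamma–Poisson mixture) with a
log-normal baseline mean per gene; genes annotated to a cell's active
terms have their mean multiplied by ``signal_fold``. A fraction of each
species' term universe is private, emulating unequal annotation coverage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .annotations import AnnotationRecord
from .errors import UsageError
from .ontology import OntologyDAG
from .profile import ExpressionMatrix


def make_ontology(
    n_terms: int = 60, max_depth: int = 5, branching: int = 3, seed: int = 0
) -> OntologyDAG:
    """Random rooted DAG in the biological_process namespace.

    Terms are generated in a fixed order; every non-root term draws 1–2
    parents among earlier terms whose depth is below ``max_depth``, so the
    graph is acyclic by construction. ``branching`` controls how quickly
    the shallow layers fill up (expected children per term).
    """
    if n_terms < 3:
        raise UsageError("need at least 3 terms")
    if max_depth < 1 or branching < 1:
        raise UsageError("max_depth and branching must be >= 1")
    rng = np.random.default_rng(seed)
    ids = [f"GO:{i:07d}" for i in range(1, n_terms + 1)]
    parents: dict[str, set[str]] = {ids[0]: set()}
    depth = {ids[0]: 0}
    for i in range(1, n_terms):
        # candidates: earlier terms not yet at max depth, preferring shallow
        # ones early on to emulate a broad upper ontology
        candidates = [t for t in ids[:i] if depth[t] < max_depth]
        if not candidates:
            raise UsageError("max_depth too small for n_terms")
        weights = np.array([1.0 / (1 + depth[t]) ** (1.0 / branching) for t in candidates])
        weights /= weights.sum()
        n_parents = 1 + int(rng.random() < 0.3) if len(candidates) > 1 else 1
        chosen = rng.choice(len(candidates), size=min(n_parents, len(candidates)), replace=False, p=weights)
        ps = {candidates[j] for j in chosen}
        parents[ids[i]] = ps
        depth[ids[i]] = 1 + max(depth[p] for p in ps)
    return OntologyDAG(
        terms=set(ids),
        parents=parents,
        namespace={t: "biological_process" for t in ids},
        names={t: f"synthetic process {t[3:]}" for t in ids},
        relations=frozenset({"is_a"}),
    )


@dataclass
class SyntheticTruth:
    """Everything the generator planted, for downstream verification."""

    ontology: OntologyDAG
    annotations: dict[str, list[AnnotationRecord]]  # species -> records
    counts: dict[str, ExpressionMatrix]  # species -> expression
    correspondence: dict[str, str]  # species-A cell type -> species-B cell type
    planted_terms: dict[str, set[str]]  # cell type -> active terms
    species: tuple[str, str] = ("species_a", "species_b")


def make_species_pair(
    dag: OntologyDAG,
    n_cell_types: int = 5,
    cells_per_type: int = 50,
    genes_per_species: int = 300,
    terms_per_type: int = 5,
    noise: float = 2.0,
    signal_fold: float = 8.0,
    shared_term_fraction: float = 0.7,
    base_mean: float = 2.0,
    seed: int = 0,
) -> SyntheticTruth:
    """Paired-species count matrices with planted cell-type correspondences.

    Parameters
    ----------
    noise
        Negative-binomial dispersion theta (smaller = noisier); counts are
        Poisson(Gamma(theta, mu/theta)).
    signal_fold
        Mean multiplier for genes annotated to a cell's active terms;
        ``signal_fold=1`` plants no signal (a null construction).
    shared_term_fraction
        Fraction of each species' usable terms drawn from a common pool;
        the rest are species-private, emulating unequal annotation
        coverage. Planted active terms always come from the common pool.
    """
    rng = np.random.default_rng(seed)
    # leaf-ish terms: no children → most specific, used for planting
    children = dag.children_map()
    leaves = sorted(t for t in dag.terms if not children[t])
    need = terms_per_type * n_cell_types
    if need > len(leaves):
        raise UsageError(
            f"terms_per_type*n_cell_types={need} exceeds {len(leaves)} leaf terms"
        )
    if not 0 < shared_term_fraction <= 1:
        raise UsageError("shared_term_fraction must be in (0, 1]")

    planted_pool = rng.permutation(leaves)[:need]
    cell_types = [f"type_{i:02d}" for i in range(n_cell_types)]
    planted_terms = {
        ct: set(planted_pool[i * terms_per_type : (i + 1) * terms_per_type])
        for i, ct in enumerate(cell_types)
    }

    # shared term pool: all planted terms plus a slice of the rest
    rest = [t for t in sorted(dag.terms) if t not in set(planted_pool)]
    n_shared_extra = int(round(shared_term_fraction * len(rest)))
    shared_extra = list(rng.permutation(rest)[:n_shared_extra])
    private_pool = [t for t in rest if t not in set(shared_extra)]
    half = len(private_pool) // 2
    private = {
        "species_a": private_pool[:half],
        "species_b": private_pool[half:],
    }

    # species-B cell types carry A's functional programs under shuffled names
    perm = rng.permutation(n_cell_types)
    b_names = [f"b_type_{i:02d}" for i in range(n_cell_types)]
    correspondence = {cell_types[i]: b_names[perm[i]] for i in range(n_cell_types)}
    planted_b = {correspondence[ct]: planted_terms[ct] for ct in cell_types}

    annotations: dict[str, list[AnnotationRecord]] = {}
    counts: dict[str, ExpressionMatrix] = {}
    for species, label_names, planted in (
        ("species_a", cell_types, planted_terms),
        ("species_b", b_names, planted_b),
    ):
        usable = sorted(set(planted_pool) | set(shared_extra) | set(private[species]))
        genes = [f"{species}_g{j:05d}" for j in range(genes_per_species)]
        gene_terms: dict[str, list[str]] = {}
        records = []
        # ensure every usable term gets at least one gene before random fill
        order = list(rng.permutation(usable))
        for j, g in enumerate(genes):
            k = int(rng.integers(1, 4))
            if j < len(order):
                terms = [order[j]] + list(rng.choice(usable, size=k - 1, replace=False))
            else:
                terms = list(rng.choice(usable, size=k, replace=False))
            terms = sorted(set(terms))
            gene_terms[g] = terms
            records.extend(AnnotationRecord(gene=g, term=t, evidence="IDA") for t in terms)
        annotations[species] = records

        base = rng.lognormal(mean=np.log(base_mean), sigma=0.6, size=genes_per_species)
        n_cells = cells_per_type * len(label_names)
        mat = np.zeros((n_cells, genes_per_species), dtype=np.int64)
        labels = []
        row = 0
        for ct in label_names:
            active = planted[ct]
            boost = np.array(
                [signal_fold if set(gene_terms[g]) & active else 1.0 for g in genes]
            )
            mu = base * boost
            lam = rng.gamma(shape=noise, scale=np.tile(mu / noise, (cells_per_type, 1)))
            mat[row : row + cells_per_type] = rng.poisson(lam)
            labels.extend([ct] * cells_per_type)
            row += cells_per_type
        cell_ids = [f"{species}_c{j:05d}" for j in range(n_cells)]
        meta = pd.DataFrame({"cell_type": labels}, index=pd.Index(cell_ids, name="cell"))
        counts[species] = ExpressionMatrix(
            cells=cell_ids, genes=genes, counts=sp.csr_matrix(mat), cell_meta=meta
        )

    return SyntheticTruth(
        ontology=dag,
        annotations=annotations,
        counts=counts,
        correspondence=correspondence,
        planted_terms={**planted_terms, **planted_b},
    )


# ---------------------------------------------------------------------------
# fixture writing


def write_obo(dag: OntologyDAG, path) -> None:
    """Serialize a DAG as a minimal OBO 1.4 document."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.4\nontology: synthetic\n")
        for t in sorted(dag.terms):
            fh.write(f"\n[Term]\nid: {t}\nname: {dag.names.get(t, t)}\n")
            fh.write(f"namespace: {dag.namespace[t]}\n")
            for p in sorted(dag.parents.get(t, ())):
                fh.write(f"is_a: {p} ! {dag.names.get(p, p)}\n")
        for t in sorted(dag.obsolete):
            fh.write(f"\n[Term]\nid: {t}\nname: obsolete\nis_obsolete: true\n")


def write_fixture_set(truth: SyntheticTruth, outdir) -> dict[str, str]:
    """Write the full fixture set: OBO, annotation TSVs, MTX counts, metadata, truth JSON."""
    import os
    from scipy.io import mmwrite

    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}
    obo = os.path.join(outdir, "ontology.obo")
    write_obo(truth.ontology, obo)
    paths["obo"] = obo
    for species in truth.species:
        ann = os.path.join(outdir, f"{species}.annotations.tsv")
        pd.DataFrame(
            [(r.gene, r.term, r.evidence) for r in truth.annotations[species]],
            columns=["gene", "go_id", "evidence"],
        ).to_csv(ann, sep="\t", index=False)
        paths[f"{species}_annotations"] = ann

        expr = truth.counts[species]
        prefix = os.path.join(outdir, f"{species}.counts")
        mmwrite(prefix + ".mtx", sp.coo_matrix(expr.counts))
        with open(prefix + ".cells.txt", "w") as fh:
            fh.write("\n".join(expr.cells) + "\n")
        with open(prefix + ".genes.txt", "w") as fh:
            fh.write("\n".join(expr.genes) + "\n")
        meta = os.path.join(outdir, f"{species}.cell_meta.tsv")
        expr.cell_meta.to_csv(meta, sep="\t")
        paths[f"{species}_counts"] = prefix + ".mtx"
        paths[f"{species}_cell_meta"] = meta

    truth_path = os.path.join(outdir, "truth.json")
    with open(truth_path, "w") as fh:
        json.dump(
            {
                "correspondence": truth.correspondence,
                "planted_terms": {k: sorted(v) for k, v in truth.planted_terms.items()},
            },
            fh,
            indent=1,
        )
    paths["truth"] = truth_path
    return paths
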