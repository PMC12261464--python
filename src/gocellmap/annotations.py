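"""Gene→GO annotation loading, evidence filtering, and the binary matrix.

Three carriers of annotations are supported: GAF 2.2, a delimited
gene/term(/evidence) table (the biomart export shape), and eggNOG-mapper
annotation TSVs (which carry no evidence codes). After optional filtering
by evidence-code set, annotations are materialized as a binary gene×term
indicator matrix restricted to a gene universe — the right-hand factor of
the functional-profile product.

Evidence-code sets
------------------
``all``        every record, including electronic (IEA) and records without
               a code (eggNOG-mapper output).
``standard``   every curated code; drops IEA, which is not manually reviewed.
``stringent``  experimental, reviewed-computational and traceable
               author/curator codes only:
               EXP, IDA, IPI, IMP, IGI, HDA, HMP, HGI, RCA, TAS, IC.
               Drops phylogenetic (IBA) and computational (ISS/ISO/ISA/ISM)
               codes, non-traceable author statements (NAS) and
               expression-pattern inferences (IEP/HEP).

A (gene, term) pair survives filtering if ANY of its records survives —
the same pair can be supported by several evidence codes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import DataError, FormatError, UsageError
from .ontology import OntologyDAG

logger = logging.getLogger(__name__)

#: The 20 GAF evidence codes, grouped as on annotation-statistics overviews.
EXPERIMENTAL_CODES = ("EXP", "IDA", "IPI", "IMP", "IGI", "HDA", "HMP", "HGI")
PHYLOGENETIC_CODES = ("IBA",)
COMPUTATIONAL_CODES = ("ISS", "ISO", "ISA", "ISM", "RCA")
AUTHOR_CURATOR_CODES = ("TAS", "NAS", "IC")
EXPRESSION_CODES = ("IEP", "HEP")
ELECTRONIC_CODES = ("IEA",)

KNOWN_CODES = frozenset(
    EXPERIMENTAL_CODES
    + PHYLOGENETIC_CODES
    + COMPUTATIONAL_CODES
    + AUTHOR_CURATOR_CODES
    + EXPRESSION_CODES
    + ELECTRONIC_CODES
)

STRINGENT_CODES = frozenset(
    {"EXP", "IDA", "IPI", "IMP", "IGI", "HDA", "HMP", "HGI", "RCA", "TAS", "IC"}
)
STANDARD_CODES = KNOWN_CODES - frozenset(ELECTRONIC_CODES)

EVIDENCE_SETS = ("all", "standard", "stringent")

#: Sentinel for sources that carry no evidence codes (eggNOG-mapper).
NO_EVIDENCE = "IEA-like"

_ASPECT_TO_NAMESPACE = {
    "P": "biological_process",
    "F": "molecular_function",
    "C": "cellular_component",
}


@dataclass(frozen=True)
class AnnotationRecord:
    gene: str
    term: str
    evidence: str = ""
    namespace: str = ""


def read_gaf(path, gene_column: str = "symbol") -> list[AnnotationRecord]:
    """Read a GAF 2.2 file.

    Uses DB Object Symbol as the gene id by default (expression matrices
    typically carry symbols); pass ``gene_column="id"`` for DB Object ID.
    Rows whose Qualifier contains ``NOT`` are dropped.
    """
    if gene_column not in ("symbol", "id"):
        raise UsageError(f"gene_column must be 'symbol' or 'id', got {gene_column!r}")
    gene_idx = 2 if gene_column == "symbol" else 1
    records = []
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("!"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 17:
                raise FormatError(
                    f"{path}: line {lineno}: expected 17 tab-separated columns, "
                    f"got {len(fields)}"
                )
            qualifier = fields[3]
            if "NOT" in qualifier.split("|"):
                continue
            records.append(
                AnnotationRecord(
                    gene=fields[gene_idx],
                    term=fields[4],
                    evidence=fields[6],
                    namespace=_ASPECT_TO_NAMESPACE.get(fields[8], ""),
                )
            )
    return records


def read_table(
    path,
    gene_col: str,
    term_col: str,
    evidence_col: str | None = None,
    delimiter: str | None = None,
) -> list[AnnotationRecord]:
    """Read a delimited annotation table with a header row.

    ``delimiter=None`` sniffs between tab and comma. Rows with an empty
    term field are skipped (count logged). Duplicated (gene, term) rows are
    kept; deduplication happens at matrix build.
    """
    if delimiter is None:
        delimiter = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    for col in filter(None, (gene_col, term_col, evidence_col)):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    n_empty = int((df[term_col].isna() | (df[term_col].str.strip() == "")).sum())
    if n_empty:
        logger.info("%s: skipped %d rows with empty term field", path, n_empty)
        df = df[~(df[term_col].isna() | (df[term_col].str.strip() == ""))]
    evidence = df[evidence_col].fillna("") if evidence_col else [""] * len(df)
    return [
        AnnotationRecord(gene=g, term=t, evidence=e)
        for g, t, e in zip(df[gene_col], df[term_col], evidence)
    ]


def read_emapper(path) -> list[AnnotationRecord]:
    """Read an eggNOG-mapper annotations TSV.

    ``##`` lines are comments; the header line starts with ``#query``; the
    ``GOs`` column holds comma-separated GO ids or ``-`` for none. Records
    carry the :data:`NO_EVIDENCE` sentinel, admitted only by the ``all``
    evidence set.
    """
    records: list[AnnotationRecord] = []
    header: list[str] | None = None
    gos_idx = query_idx = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("##") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#"):
                header = [fields[0].lstrip("#")] + fields[1:]
                if "GOs" not in header:
                    raise FormatError(f"{path}: header has no GOs column")
                gos_idx = header.index("GOs")
                query_idx = header.index("query")
                continue
            if header is None:
                raise FormatError(f"{path}: data before the #query header line")
            gene = fields[query_idx]
            gos = fields[gos_idx]
            if gos == "-" or not gos:
                continue
            for term in dict.fromkeys(g.strip() for g in gos.split(",")):
                if term:
                    records.append(
                        AnnotationRecord(gene=gene, term=term, evidence=NO_EVIDENCE)
                    )
    if header is None:
        raise FormatError(f"{path}: no #query header line found")
    return records


def filter_evidence(
    records: Iterable[AnnotationRecord], set_name: str
) -> list[AnnotationRecord]:
    """Keep records whose evidence code belongs to the named set.

    Unknown codes (outside the 20-code enumeration) are admitted by ``all``
    with a warning and treated as non-curated under standard/stringent.
    """
    if set_name not in EVIDENCE_SETS:
        raise UsageError(
            f"unknown evidence set {set_name!r}; expected one of {EVIDENCE_SETS}"
        )
    records = list(records)
    if set_name == "all":
        odd = {
            r.evidence
            for r in records
            if r.evidence and r.evidence != NO_EVIDENCE and r.evidence not in KNOWN_CODES
        }
        if odd:
            logger.warning("unrecognized evidence codes kept under 'all': %s", sorted(odd))
        return records
    keep = STANDARD_CODES if set_name == "standard" else STRINGENT_CODES
    return [r for r in records if r.evidence in keep]


def surviving_pairs(records: Iterable[AnnotationRecord]) -> set[tuple[str, str]]:
    """The distinct (gene, term) pairs carried by ``records``."""
    return {(r.gene, r.term) for r in records}


@dataclass
class BinaryAnnotationMatrix:
    """Binary gene×term indicator with ordered axis labels.

    No all-zero row or column is present after construction; ``matrix`` is
    a CSR sparse boolean-as-int8 indicator.
    """

    genes: list[str]
    terms: list[str]
    matrix: sp.csr_matrix

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix.toarray(), index=self.genes, columns=self.terms
        )


def build_binary_matrix(
    records: Iterable[AnnotationRecord],
    dag: OntologyDAG,
    namespace: str = "biological_process",
    gene_universe: Sequence[str] | None = None,
    propagate_ancestors: bool = False,
) -> BinaryAnnotationMatrix:
    """Materialize annotation records as a binary gene×term matrix.

    Terms are resolved through alt_ids and restricted to ``namespace``;
    genes are restricted to ``gene_universe`` (typically the expression
    matrix's genes). Terms absent from the ontology are dropped with a
    logged count rather than raising: real annotation files routinely lag
    or lead the ontology release. ``propagate_ancestors=True`` additionally
    sets the indicator for every ancestor of an annotated term (true-path
    propagation); the default keeps direct annotations as provided.
    """
    pairs: set[tuple[str, str]] = set()
    n_unknown = 0
    for r in records:
        try:
            term = dag.resolve(r.term)
        except Exception:
            n_unknown += 1
            continue
        if dag.namespace.get(term) != namespace:
            continue
        pairs.add((r.gene, term))
    if n_unknown:
        logger.info("dropped %d records with terms not in the ontology", n_unknown)

    if propagate_ancestors:
        from .ontology import ancestors as _anc

        extra = set()
        for gene, term in pairs:
            for a in _anc(dag, term):
                if dag.namespace.get(a) == namespace:
                    extra.add((gene, a))
        pairs |= extra

    if gene_universe is not None:
        universe = set(gene_universe)
        pairs = {(g, t) for g, t in pairs if g in universe}
    if not pairs:
        raise DataError(
            "no annotations remain after namespace/universe restriction"
        )

    genes = sorted({g for g, _ in pairs})
    terms = sorted({t for _, t in pairs})
    if gene_universe is not None:
        order = {g: i for i, g in enumerate(gene_universe)}
        genes.sort(key=order.__getitem__)
    g_idx = {g: i for i, g in enumerate(genes)}
    t_idx = {t: i for i, t in enumerate(terms)}
    rows = np.fromiter((g_idx[g] for g, _ in pairs), dtype=np.int64, count=len(pairs))
    cols = np.fromiter((t_idx[t] for _, t in pairs), dtype=np.int64, count=len(pairs))
    mat = sp.csr_matrix(
        (np.ones(len(pairs), dtype=np.int8), (rows, cols)),
        shape=(len(genes), len(terms)),
    )
    return BinaryAnnotationMatrix(genes=genes, terms=terms, matrix=mat)


def write_binary_matrix(bam: BinaryAnnotationMatrix, prefix: str) -> None:
    """Write the indicator as MTX plus gene/term sidecar files."""
    from scipy.io import mmwrite

    mmwrite(f"{prefix}.mtx", bam.matrix)
    with open(f"{prefix}.genes.txt", "w") as fh:
        fh.write("\n".join(bam.genes) + "\n")
    with open(f"{prefix}.terms.txt", "w") as fh:
        fh.write("\n".join(bam.terms) + "\n")
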