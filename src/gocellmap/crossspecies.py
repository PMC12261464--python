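"""Cross-species comparison of functional profiles.

Two species' profiles are made comparable by restricting to the GO BP
terms annotated in both, re-scaling on that shared term set, and
averaging the scaled activity per cell type. Pearson correlation of the
cell-type mean vectors then quantifies functional similarity — cell-type
pairs with similar activation *and* repression patterns score high. For a
pair of interest, the terms driving the similarity are extracted as a
harmonized, minimal, fold-change-ranked shared signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, LookupError_
from .differential import significant_terms
from .ontology import OntologyDAG, harmonize_lists, minimal_set
from .profile import FunctionalProfile, zscore_columns

SIGNATURE_COLUMNS = [
    "term",
    "term_a",
    "term_b",
    "log2fc_a",
    "log2fc_b",
    "avg_log2fc",
    "pval_adj_a",
    "pval_adj_b",
    "direction",
]


def shared_terms(profile_a: FunctionalProfile, profile_b: FunctionalProfile) -> list[str]:
    """Lexically ordered intersection of the two profiles' term sets."""
    common = set(profile_a.terms) & set(profile_b.terms)
    if not common:
        raise DataError("the two profiles share no GO terms")
    return sorted(common)


def rescale_shared(profile: FunctionalProfile, shared: list[str], clip: float = 10.0) -> FunctionalProfile:
    """Subset the normalized layer to ``shared`` and recompute the z-scale.

    Because the z-score is per-column, re-scaling after subsetting equals
    subsetting the full-scale result column by column — but doing it here
    keeps the contract explicit and robust to upstream layer state.
    """
    missing = set(shared) - set(profile.terms)
    if missing:
        raise LookupError_(f"terms not in profile: {sorted(missing)[:5]}")
    adata = profile.adata[:, shared].copy()
    out = FunctionalProfile(adata)
    adata.layers["scaled"] = zscore_columns(out.layer("normalized"), clip=clip)
    return out


@dataclass
class CellTypeMeans:
    """Cell-type×term matrix of mean scaled activity on shared terms."""

    values: pd.DataFrame  # index = cell types, columns = terms

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.index)

    @property
    def terms(self) -> list[str]:
        return list(self.values.columns)


def celltype_means(profile: FunctionalProfile, group_key: str = "cell_type") -> CellTypeMeans:
    """Arithmetic mean of the scaled layer per cell type."""
    obs = profile.adata.obs
    if group_key not in obs:
        raise DataError(f"metadata column {group_key!r} not found")
    labels = obs[group_key]
    n_unlabeled = int(labels.isna().sum())
    if n_unlabeled:
        raise DataError(f"{n_unlabeled} cells have no {group_key!r} label")
    x = pd.DataFrame(profile.layer("scaled"), index=profile.cells, columns=profile.terms)
    means = x.groupby(labels.astype(str).to_numpy()).mean()
    means = means.sort_index()
    return CellTypeMeans(values=means)


def correlate(means_a: CellTypeMeans, means_b: CellTypeMeans) -> pd.DataFrame:
    """Pearson correlation matrix between all cell-type pairs.

    Rows are species-A cell types, columns species-B cell types.
    Zero-variance mean vectors yield NaN (explicitly undefined, not 0) for
    their pairs.
    """
    if means_a.terms != means_b.terms:
        raise DataError("term lists differ between the two species' means")
    a = means_a.values.to_numpy(dtype=np.float64)
    b = means_b.values.to_numpy(dtype=np.float64)
    a_c = a - a.mean(axis=1, keepdims=True)
    b_c = b - b.mean(axis=1, keepdims=True)
    a_sd = np.sqrt((a_c**2).sum(axis=1))
    b_sd = np.sqrt((b_c**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (a_c @ b_c.T) / np.outer(a_sd, b_sd)
    r[np.outer(a_sd == 0, np.ones(len(b_sd), dtype=bool))] = np.nan
    r[np.outer(np.ones(len(a_sd), dtype=bool), b_sd == 0)] = np.nan
    r = np.clip(r, -1.0, 1.0, out=r)  # guard rounding just past ±1; NaN passes through
    return pd.DataFrame(r, index=means_a.cell_types, columns=means_b.cell_types)


def correlation_long(matrix: pd.DataFrame) -> pd.DataFrame:
    """Long form of the correlation matrix: (cell_type_a, cell_type_b, r)."""
    long = matrix.stack(future_stack=True).reset_index()
    long.columns = ["cell_type_a", "cell_type_b", "pearson_r"]
    return long


def shared_signature(
    diff_a: pd.DataFrame,
    diff_b: pd.DataFrame,
    cell_type_a: str,
    cell_type_b: str,
    dag: OntologyDAG,
    direction: str = "up",
    alpha: float = 0.05,
    top_n: int = 10,
) -> pd.DataFrame:
    """Harmonized, minimal, ranked co-regulated terms for one cell-type pair.

    Each species' significant terms in ``direction`` are harmonized (shared
    terms plus cross-species ancestor/descendant pairs represented by the
    ancestor), reduced to the minimal antichain, annotated with each
    species' log2FC from its contributing source term, and ranked by
    \\|average log2FC\\| descending; the ``top_n`` rows are returned. When a
    representative has several source terms in one species, the source with
    the largest \\|log2FC\\| is attached.
    """
    rows_a = significant_terms(diff_a, cell_type_a, direction, alpha)
    rows_b = significant_terms(diff_b, cell_type_b, direction, alpha)

    stats_a = _best_stats(rows_a)
    stats_b = _best_stats(rows_b)

    harmonized = harmonize_lists(dag, stats_a.keys(), stats_b.keys())
    if not harmonized:
        return pd.DataFrame(columns=SIGNATURE_COLUMNS)

    representatives = minimal_set(dag, [h.term for h in harmonized])
    records = []
    for h in harmonized:
        if h.term not in representatives:
            continue
        src_a = max(h.from_a, key=lambda t: (abs(stats_a[t][0]), t))
        src_b = max(h.from_b, key=lambda t: (abs(stats_b[t][0]), t))
        fc_a, p_a = stats_a[src_a]
        fc_b, p_b = stats_b[src_b]
        records.append(
            {
                "term": h.term,
                "term_a": src_a,
                "term_b": src_b,
                "log2fc_a": fc_a,
                "log2fc_b": fc_b,
                "avg_log2fc": (fc_a + fc_b) / 2.0,
                "pval_adj_a": p_a,
                "pval_adj_b": p_b,
                "direction": direction,
            }
        )
    table = pd.DataFrame(records, columns=SIGNATURE_COLUMNS)
    # duplicates by representative id: keep the max |avg_log2fc|
    table = (
        table.assign(_rank=table["avg_log2fc"].abs())
        .sort_values(["_rank", "term"], ascending=[False, True])
        .drop_duplicates(subset="term", keep="first")
        .drop(columns="_rank")
        .reset_index(drop=True)
    )
    return table.head(top_n)


def _best_stats(rows: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """term → (log2fc, pval_adj), keeping the largest |log2fc| per term."""
    out: dict[str, tuple[float, float]] = {}
    for _, r in rows.iterrows():
        prev = out.get(r["term"])
        if prev is None or abs(r["log2fc"]) > abs(prev[0]):
            out[r["term"]] = (float(r["log2fc"]), float(r["pval_adj"]))
    return out
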