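"""One-vs-rest differential GO-BP testing per cell group.

For every group (typically a cell-type label) and every term, the
in-group cells' normalized values are compared against all remaining
cells with a two-sided Wilcoxon rank-sum (Mann–Whitney) test. The
historical framework label for this test is "Wilcoxon"; the signed-rank
variant is for paired samples and does not apply to one-vs-rest groups.

P-values are Bonferroni-corrected over all (group, term) tests performed
in one call — the most conservative family. The fold change is

    log2FC = log2((mean(expm1(normalized)) in group + eps) /
                  (mean(expm1(normalized)) in rest  + eps)),  eps = 1e-9,

i.e. a fold change of de-logged normalized values with a pseudocount.
Rows are flagged ``up`` when log2FC > min_log2fc and adjusted p ≤ alpha,
``down`` symmetrically.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .profile import FunctionalProfile

logger = logging.getLogger(__name__)

LOG2FC_EPS = 1e-9

#: Largest smaller-group size for which the exact null distribution is used
#: (tie-free data only); above this the normal approximation with tie and
#: continuity corrections applies.
EXACT_SIZE_LIMIT = 8

COLUMNS = [
    "group",
    "term",
    "term_name",
    "log2fc",
    "pval",
    "pval_adj",
    "pct_in",
    "pct_out",
    "direction",
]


def wilcoxon_rank_sum(
    in_values: np.ndarray, out_values: np.ndarray
) -> float:
    """Two-sided Wilcoxon rank-sum p-value for one term.

    Exact enumeration when the smaller group has ≤ :data:`EXACT_SIZE_LIMIT`
    observations and the pooled data are tie-free; otherwise the normal
    approximation with tie correction and continuity correction.
    """
    in_values = np.asarray(in_values, dtype=np.float64)
    out_values = np.asarray(out_values, dtype=np.float64)
    pooled = np.concatenate([in_values, out_values])
    tie_free = len(np.unique(pooled)) == len(pooled)
    if min(len(in_values), len(out_values)) <= EXACT_SIZE_LIMIT and tie_free:
        method = "exact"
    else:
        method = "asymptotic"
    return float(
        stats.mannwhitneyu(
            in_values, out_values, alternative="two-sided", method=method
        ).pvalue
    )


def _group_pvalues(x: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Vectorized two-sided Mann–Whitney p-values for one group, all terms."""
    n_in = int(mask.sum())
    n_out = int((~mask).sum())
    if min(n_in, n_out) <= EXACT_SIZE_LIMIT:
        # exact path possible per term; loop (small groups only)
        return np.array(
            [wilcoxon_rank_sum(x[mask, j], x[~mask, j]) for j in range(x.shape[1])]
        )
    res = stats.mannwhitneyu(
        x[mask, :], x[~mask, :], alternative="two-sided", method="asymptotic", axis=0
    )
    return np.asarray(res.pvalue, dtype=np.float64)


def rank_terms(
    profile: FunctionalProfile,
    group_key: str = "cell_type",
    alpha: float = 0.05,
    min_log2fc: float = 0.0,
    min_pct: float = 0.0,
    min_group_size: int = 3,
    groups: Sequence[str] | None = None,
) -> pd.DataFrame:
    """One-vs-rest differential table over all groups of ``group_key``.

    Returns a DataFrame with columns ``group, term, term_name, log2fc,
    pval, pval_adj, pct_in, pct_out, direction``; ``direction`` is ``up``,
    ``down`` or ``ns``. Groups with fewer than ``min_group_size`` cells are
    skipped with a warning. ``min_pct`` optionally requires a minimum
    expressed fraction in either group before testing (default 0: test
    everything).
    """
    adata = profile.adata
    if group_key not in adata.obs:
        raise DataError(f"metadata column {group_key!r} not found")
    labels = adata.obs[group_key].astype(str).to_numpy()
    x = profile.layer("normalized")
    terms = np.asarray(profile.terms)
    term_names = (
        adata.var["term_name"].to_numpy()
        if "term_name" in adata.var
        else np.asarray(profile.terms)
    )

    unique_groups = sorted(set(labels)) if groups is None else list(groups)
    if len(set(labels)) < 2:
        raise DataError("differential testing needs at least 2 groups")

    frames = []
    n_tests = 0
    expm = np.expm1(x)
    for g in unique_groups:
        mask = labels == g
        if mask.sum() < min_group_size or (~mask).sum() < min_group_size:
            logger.warning(
                "group %r skipped: %d cells (< %d)", g, int(mask.sum()), min_group_size
            )
            continue
        # normalized layers are non-negative; clamp guards synthetic inputs
        mean_in = np.maximum(expm[mask].mean(axis=0), 0.0)
        mean_out = np.maximum(expm[~mask].mean(axis=0), 0.0)
        log2fc = np.log2((mean_in + LOG2FC_EPS) / (mean_out + LOG2FC_EPS))
        pct_in = (x[mask] > 0).mean(axis=0)
        pct_out = (x[~mask] > 0).mean(axis=0)

        testable = np.maximum(pct_in, pct_out) >= min_pct
        pvals = np.ones(len(terms))
        if testable.any():
            pvals[testable] = _group_pvalues(x[:, testable], mask)
        n_tests += int(testable.sum())
        frames.append(
            pd.DataFrame(
                {
                    "group": g,
                    "term": terms,
                    "term_name": term_names,
                    "log2fc": log2fc,
                    "pval": pvals,
                    "pct_in": pct_in,
                    "pct_out": pct_out,
                    "_tested": testable,
                }
            )
        )
    if not frames:
        raise DataError("all groups were below the minimum size; nothing tested")

    table = pd.concat(frames, ignore_index=True)
    table["pval_adj"] = np.where(
        table["_tested"], np.minimum(1.0, table["pval"] * n_tests), 1.0
    )
    up = (table["log2fc"] > min_log2fc) & (table["pval_adj"] <= alpha)
    down = (table["log2fc"] < -min_log2fc) & (table["pval_adj"] <= alpha)
    table["direction"] = np.select([up, down], ["up", "down"], default="ns")
    table = table.drop(columns="_tested")
    return table[COLUMNS]


def significant_terms(
    table: pd.DataFrame, group: str, direction: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Rows of ``table`` for one group, significant in one direction."""
    if group not in set(table["group"]):
        from .errors import LookupError_

        raise LookupError_(f"cell type {group!r} not present in the table")
    sel = (
        (table["group"] == group)
        & (table["direction"] == direction)
        & (table["pval_adj"] <= alpha)
    )
    return table[sel]


def write_table(table: pd.DataFrame, path, header_lines: Sequence[str] = ()) -> None:
    """Write the differential table with the stable column order."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        table[COLUMNS].to_csv(fh, sep="\t", index=False)
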