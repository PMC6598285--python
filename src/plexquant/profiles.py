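"""Expression profiles: log-ratio matrix, row z-scores, hierarchical clustering,
and hypergeometric pathway enrichment.

The profile matrix has one row per differentially expressed protein and one
column per culture condition; entries are log2 median ratios against the
control condition (so the control column is identically 0).  Rows are
standardized to mean 0 / sample SD 1 before clustering, which makes the
clustering group proteins by the *shape* of their response across conditions
rather than its magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io import AnnotationMap
from .quant import ProteinQuant

#: Default channel-comparison → condition (mM exogenous ethanol) mapping.
DEFAULT_CONDITION_OF = {"115/114": 50, "116/114": 100, "117/114": 200}
DEFAULT_CONTROL_CONDITION = 0


@dataclass
class ProfileMatrix:
    """Protein × condition log2-ratio matrix with optional z-scores and clusters."""

    values: pd.DataFrame  # rows: accessions, columns: condition (mM), log2 ratio
    imputed: pd.DataFrame  # True where a missing comparison was imputed as 0
    zmatrix: pd.DataFrame | None = None
    cluster_of: pd.Series | None = None
    leaf_order: list | None = None


def build_profile(
    quants: Iterable[ProteinQuant],
    de_union: Iterable[str],
    condition_of: Mapping[str, int] | None = None,
    control_condition: int = DEFAULT_CONTROL_CONDITION,
) -> ProfileMatrix:
    """Assemble the log2 ratio matrix for the union of DE proteins.

    Every requested accession must be quantified in at least one comparison;
    comparisons a protein was not quantified in are imputed as log2 ratio 0
    (no change) and flagged in ``imputed``.
    """
    cond_of = dict(condition_of or DEFAULT_CONDITION_OF)
    ratio_of: dict[tuple[str, str], float] = {}
    for q in quants:
        if q.comparison in cond_of:
            ratio_of[(q.protein_acc, q.comparison)] = q.median_ratio
    quantified_accs = {acc for acc, _ in ratio_of}

    rows = sorted(set(de_union))
    missing = [acc for acc in rows if acc not in quantified_accs]
    if missing:
        raise ValidationError(
            f"accessions not quantified in any comparison: {missing[:5]}"
        )

    conditions = [control_condition] + sorted(cond_of.values())
    values = pd.DataFrame(0.0, index=rows, columns=conditions)
    imputed = pd.DataFrame(False, index=rows, columns=conditions)
    for acc in rows:
        for comp, cond in cond_of.items():
            key = (acc, comp)
            if key in ratio_of:
                values.loc[acc, cond] = float(np.log2(ratio_of[key]))
            else:
                imputed.loc[acc, cond] = True
    return ProfileMatrix(values=values, imputed=imputed)


def zscore_rows(values: pd.DataFrame) -> pd.DataFrame:
    """Row standardization with sample SD (n-1); constant rows map to all-zero."""
    if values.shape[1] < 2:
        raise ValidationError("need at least 2 columns to z-score rows")
    arr = values.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    z = np.zeros_like(arr)
    ok = (sd > 0).ravel()
    z[ok] = (arr[ok] - mean[ok]) / sd[ok]
    return pd.DataFrame(z, index=values.index, columns=values.columns)


def cluster_rows(
    zmatrix: pd.DataFrame,
    k: int = 6,
    metric: str = "euclidean",
    method: str = "average",
) -> tuple[pd.Series, list]:
    """Agglomerative clustering of profile rows, cut to exactly k clusters.

    Returns (labels in 1..k, dendrogram leaf order).  Cluster ids are
    relabeled by first appearance in row order so the assignment is
    deterministic and invariant to scipy's internal numbering.
    """
    n = zmatrix.shape[0]
    if k > n:
        raise ValidationError(f"k={k} exceeds number of rows ({n})")
    if k < 1:
        raise ValidationError("k must be >= 1")
    if n == 1:
        return pd.Series([1], index=zmatrix.index), [zmatrix.index[0]]
    Z = hierarchy.linkage(zmatrix.to_numpy(dtype=float), method=method, metric=metric)
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(raw):
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        labels[i] = relabel[r]
    leaf_order = [zmatrix.index[i] for i in hierarchy.leaves_list(Z)]
    return pd.Series(labels, index=zmatrix.index), leaf_order


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k):
        raise ValidationError(f"inconsistent hypergeometric parameters k={k} K={K} n={n} N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    k: int  # overlap: query proteins in the pathway
    K: int  # pathway size within the background
    n: int  # query size
    N: int  # background size
    p: float  # hypergeometric upper-tail probability
    p_adj: float  # Benjamini–Hochberg adjusted
    significant: bool  # raw p <= threshold, matching the published convention


def enrich(
    query: Iterable[str],
    background: Iterable[str],
    ann: AnnotationMap,
    p_threshold: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of each pathway in the query set.

    The background is the population the query was drawn from (by default all
    accurately quantified proteins).  Pathways with no background member are
    skipped.  Raw p <= ``p_threshold`` defines significance; BH-adjusted values
    are reported alongside.  Results are sorted by (p, pathway id).
    """
    query = set(query)
    background = set(background)
    if not query <= background:
        raise ValidationError("query set must be a subset of the background")
    N = len(background)
    n = len(query)

    members: dict[str, set[str]] = {}
    for acc in background:
        for pw in ann.pathways.get(acc, ()):
            members.setdefault(pw, set()).add(acc)
    if not members:
        return []

    rows = []
    for pw in sorted(members):
        K = len(members[pw])
        k = len(members[pw] & query)
        rows.append((pw, k, K, hypergeom_tail(k, K, n, N)))
    pvals = [r[3] for r in rows]
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    results = [
        EnrichmentResult(
            pathway_id=pw,
            k=k,
            K=K,
            n=n,
            N=N,
            p=p,
            p_adj=float(pa),
            significant=bool(p <= p_threshold),
        )
        for (pw, k, K, p), pa in zip(rows, p_adj)
    ]
    results.sort(key=lambda r: (r.p, r.pathway_id))
    return results
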