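"""Consensus target prediction, tissue filtering, and over-representation.

Target prediction is consumed as exported tables from independent predictors
(TargetScan, miRanda, miRDB, miRWalk in the motivating study); a miRNA-gene
pair is kept when at least ``min_support`` of them agree. Predicted targets
can then be restricted to genes annotated as expressed/specific in a chosen
tissue. Over-representation of annotation terms in a gene selection is
tested with a one-sided Fisher exact test (hypergeometric upper tail),
Pearson's chi-squared reported alongside, and Benjamini-Hochberg FDR applied
within each annotation category; a term is significant when both p and FDR
fall below alpha.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, InputError

logger = logging.getLogger("mirarray")

ALPHA_DEFAULT = 0.05
MIN_SUPPORT_DEFAULT = 3
TOP_K_DEFAULT = 10


def normalize_symbol(gene: str) -> str:
    """Case-normalize a gene symbol to the mouse convention (Abcd1)."""
    return gene.strip().capitalize()


def consensus_targets(
    tables: Mapping[str, Iterable[tuple[str, str]]],
    min_support: int = MIN_SUPPORT_DEFAULT,
) -> dict[str, set[str]]:
    """miRNA -> genes predicted by at least ``min_support`` of the tables."""
    if min_support < 1:
        raise ConfigurationError("min_support must be >= 1")
    if len(tables) < 2:
        raise InputError("need at least two predictor tables")
    if min_support > len(tables):
        raise ConfigurationError(
            f"min_support={min_support} exceeds the {len(tables)} predictor tables"
        )
    support: dict[tuple[str, str], int] = {}
    for pairs in tables.values():
        for mirna, gene in set((m, normalize_symbol(g)) for m, g in pairs):
            support[(mirna, gene)] = support.get((mirna, gene), 0) + 1
    out: dict[str, set[str]] = {}
    for (mirna, gene), count in support.items():
        if count >= min_support:
            out.setdefault(mirna, set()).add(gene)
    return out


def tissue_filter(
    targets: Mapping[str, Iterable[str]],
    specificity: Mapping[str, Iterable[str]],
    tissue: str = "liver",
) -> tuple[dict[str, set[str]], dict]:
    """Keep target genes annotated to ``tissue``; report what was dropped.

    Genes absent from the specificity table are dropped and counted
    separately from genes annotated only to other tissues.
    """
    spec = {normalize_symbol(g): set(t) for g, t in specificity.items()}
    known_tissues = set().union(*spec.values()) if spec else set()
    if tissue not in known_tissues:
        logger.warning("tissue %r absent from the specificity table; empty result", tissue)
        return {}, {"n_kept": 0, "n_dropped_unannotated": 0, "n_dropped_other_tissue": 0}
    kept: dict[str, set[str]] = {}
    n_unannotated = 0
    n_other = 0
    for mirna, genes in targets.items():
        keep = set()
        for gene in genes:
            g = normalize_symbol(gene)
            if g not in spec:
                n_unannotated += 1
            elif tissue in spec[g]:
                keep.add(g)
            else:
                n_other += 1
        if keep:
            kept[mirna] = keep
    n_kept = len(set().union(*kept.values())) if kept else 0
    report = {
        "n_kept": n_kept,
        "n_dropped_unannotated": n_unannotated,
        "n_dropped_other_tissue": n_other,
    }
    return kept, report


def target_gene_union(targets: Mapping[str, Iterable[str]]) -> set[str]:
    return set().union(*targets.values()) if targets else set()


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n); the one-sided Fisher p.

    Summed from the far tail toward k so small terms accumulate first.
    """
    if not (0 <= k <= min(K, n) + 1):
        raise InputError("k outside the hypergeometric support")
    kmax = min(K, n)
    if k <= max(0, n + K - N):
        return 1.0
    ks = np.arange(kmax, k - 1, -1)
    terms = stats.hypergeom.pmf(ks, N, K, n)
    return float(min(1.0, terms.sum()))


def _pearson_chi2(k: int, K: int, n: int, N: int, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-squared on the 2x2 table (k, n-k; K-k, N-K-n+k)."""
    table = np.array([[k, n - k], [K - k, N - K - n + k]], dtype=float)
    if table.min() < 0:
        raise InputError("invalid 2x2 table")
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    total = table.sum()
    expected = row @ col / total
    if (expected == 0).any():
        return np.nan, np.nan
    diff = np.abs(table - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    chi2 = float((diff**2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def _terms_from_frame(term_map: pd.DataFrame) -> pd.DataFrame:
    required = {"term_id", "term_name", "category", "gene"}
    missing = required - set(term_map.columns)
    if missing:
        raise InputError(f"term map lacks column(s): {', '.join(sorted(missing))}")
    return term_map


def enrich(
    selected: Iterable[str],
    universe: Iterable[str],
    term_map: pd.DataFrame,
    method: str = "fisher",
    alpha: float = ALPHA_DEFAULT,
    ease: bool = False,
    yates: bool = False,
) -> pd.DataFrame:
    """Per-term over-representation of ``selected`` within ``universe``.

    Returns one row per term with counts (k of n selected, K of N universe),
    fisher and chi-squared p-values, BH FDR within each category on the
    chosen method's p, and the significance call (p < alpha and FDR < alpha).
    ``ease`` applies the EASE-score deflation (k-1 in the tested table).
    """
    if method not in ("fisher", "chi2"):
        raise ConfigurationError(f"unknown method {method!r}")
    if not 0 < alpha < 1:
        raise ConfigurationError("alpha must be in (0, 1)")
    universe_set = set(universe)
    selected_set = set(selected)
    stray = sorted(selected_set - universe_set)
    if stray:
        raise InputError(f"selected genes outside the universe: {', '.join(stray[:10])}")
    N = len(universe_set)
    n = len(selected_set)

    term_map = _terms_from_frame(term_map)
    rows = []
    for (term_id, term_name, category), grp in term_map.groupby(
        ["term_id", "term_name", "category"], sort=True
    ):
        members = set(grp["gene"]) & universe_set
        K = len(members)
        if K == 0:
            logger.warning("term %s has no universe genes; skipped", term_id)
            continue
        k = len(members & selected_set)
        k_test = max(k - 1, 0) if ease else k
        p_fisher = hypergeom_upper_tail(k_test, K, n, N)
        chi2_stat, p_chi2 = _pearson_chi2(k, K, n, N, yates=yates)
        rows.append(
            {
                "term_id": term_id,
                "term_name": term_name,
                "category": category,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "fold_enrichment": (k / n) / (K / N) if n else np.nan,
                "p_fisher": p_fisher,
                "chi2": chi2_stat,
                "p_chi2": p_chi2,
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "term_id", "term_name", "category", "k", "K", "n", "N",
            "fold_enrichment", "p_fisher", "chi2", "p_chi2",
        ],
    )
    pcol = "p_fisher" if method == "fisher" else "p_chi2"
    result["p_value"] = result[pcol]
    result["fdr"] = np.nan
    for cat, idx in result.groupby("category").groups.items():
        ps = result.loc[idx, "p_value"].to_numpy()
        if np.isnan(ps).any():
            raise InputError(f"undefined p-values in category {cat}")
        result.loc[idx, "fdr"] = multipletests(ps, method="fdr_bh")[1]
    result["significant"] = (result["p_value"] < alpha) & (result["fdr"] < alpha)
    return result.sort_values(["category", "p_value", "term_id"], ignore_index=True)


def top_terms(rows: pd.DataFrame, k: int = TOP_K_DEFAULT) -> pd.DataFrame:
    """Per category: significant terms by ascending p, ties broken by larger
    overlap then term id, truncated to ``k``."""
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    sig = rows[rows["significant"]].copy()
    sig = sig.sort_values(
        ["category", "p_value", "k", "term_id"],
        ascending=[True, True, False, True],
    )
    return sig.groupby("category", group_keys=False).head(k).reset_index(drop=True)
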