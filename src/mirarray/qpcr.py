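"""Relative quantification by 2^-ddCt and group comparisons.

Per sample, dCt = Ct(target) - Ct(reference gene); ddCt = dCt minus the
arithmetic mean dCt of the control group; relative quantity RQ = 2^-ddCt, so
the control group averages to RQ 1 (geometric mean exactly 1). Technical
replicates are averaged before dCt. Group comparisons follow the classical
recipe: Student's t-test for two groups, one-way ANOVA with Tukey's HSD
post-hoc for more, values reported as mean +/- SE.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import ConfigurationError, InputError

logger = logging.getLogger("mirarray")


def delta_delta_ct(
    ct: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    control_group: str,
    replicate_agg: str = "mean",
) -> pd.DataFrame:
    """Per-sample dCt, ddCt and RQ for one target gene.

    ``ct`` is a long table (sample, group, gene, replicate, ct). Technical
    replicates are collapsed by ``replicate_agg`` (mean or median) first.
    """
    if replicate_agg not in ("mean", "median"):
        raise ConfigurationError("replicate_agg must be 'mean' or 'median'")
    required = {"sample", "group", "gene", "ct"}
    missing = required - set(ct.columns)
    if missing:
        raise InputError(f"Ct table lacks column(s): {', '.join(sorted(missing))}")
    sub = ct[ct["gene"].isin([target_gene, reference_gene])]
    if target_gene not in set(sub["gene"]):
        raise InputError(f"no Ct rows for target gene {target_gene!r}")
    if reference_gene not in set(sub["gene"]):
        raise InputError(f"no Ct rows for reference gene {reference_gene!r}")
    collapsed = (
        sub.groupby(["sample", "group", "gene"], sort=True)["ct"]
        .agg(replicate_agg)
        .unstack("gene")
        .reset_index()
    )
    for _, row in collapsed.iterrows():
        if pd.isna(row.get(reference_gene)):
            raise InputError(f"sample {row['sample']!r} lacks a reference-gene Ct")
        if pd.isna(row.get(target_gene)):
            raise InputError(f"sample {row['sample']!r} lacks a target-gene Ct")
    collapsed["delta_ct"] = collapsed[target_gene] - collapsed[reference_gene]
    control = collapsed.loc[collapsed["group"] == control_group, "delta_ct"]
    if len(control) == 0:
        raise InputError(f"control group {control_group!r} has no samples")
    anchor = float(control.mean())
    collapsed["delta_delta_ct"] = collapsed["delta_ct"] - anchor
    collapsed["rq"] = 2.0 ** (-collapsed["delta_delta_ct"])
    out = collapsed[["sample", "group", "delta_ct", "delta_delta_ct", "rq"]].copy()
    out.insert(2, "gene", target_gene)
    return out


def group_summary(rq: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SE of RQ per group."""
    g = rq.groupby("group", sort=True)["rq"]
    out = g.agg(n="count", mean="mean", sd="std").reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n"])
    return out


def _check_groups(values_by_group: dict[str, np.ndarray]) -> None:
    for name, vals in values_by_group.items():
        if len(vals) < 2:
            raise InputError(f"group {name!r} has fewer than 2 values")


def group_stats(
    values_by_group: dict[str, "np.ndarray | list[float]"],
    design: str = "two_group",
    welch: bool = False,
    alpha: float = 0.05,
) -> dict:
    """Two-group t-test or one-way ANOVA + Tukey HSD over RQ values.

    Zero-variance degenerate inputs are flagged: equal means give t = 0,
    p = 1; unequal means are reported with p at machine epsilon and a
    warning rather than a division by zero.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    _check_groups(groups)
    if design == "two_group":
        if len(groups) != 2:
            raise InputError("two_group design requires exactly 2 groups")
        (na, a), (nb, b) = groups.items()
        report = {
            "design": "two_group",
            "groups": [na, nb],
            "means": {na: float(a.mean()), nb: float(b.mean())},
            "se": {na: float(a.std(ddof=1) / math.sqrt(len(a))),
                   nb: float(b.std(ddof=1) / math.sqrt(len(b)))},
            "degenerate": False,
        }
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            report["degenerate"] = True
            if a.mean() == b.mean():
                report.update(t=0.0, df=len(a) + len(b) - 2, p_value=1.0)
            else:
                logger.warning("zero within-group variance with unequal means; p set to eps")
                report.update(
                    t=math.inf, df=len(a) + len(b) - 2, p_value=float(np.finfo(float).eps)
                )
        else:
            t, p = stats.ttest_ind(a, b, equal_var=not welch)
            df = (len(a) + len(b) - 2) if not welch else None
            report.update(t=float(t), df=df, p_value=float(p))
        report["significant"] = report["p_value"] < alpha
        return report
    if design == "multi_group":
        if len(groups) < 3:
            raise InputError("multi_group design requires >= 3 groups")
        names = list(groups)
        arrays = [groups[g] for g in names]
        if all(x.var(ddof=1) == 0 for x in arrays):
            same = len({float(x.mean()) for x in arrays}) == 1
            logger.warning("zero within-group variance in all groups")
            return {
                "design": "multi_group",
                "groups": names,
                "degenerate": True,
                "f": 0.0 if same else math.inf,
                "p_value": 1.0 if same else float(np.finfo(float).eps),
                "tukey": [],
                "means": {g: float(groups[g].mean()) for g in names},
            }
        f, p = stats.f_oneway(*arrays)
        values = np.concatenate(arrays)
        labels = np.concatenate([[g] * len(groups[g]) for g in names])
        tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
        pairs = [
            {
                "group1": str(r[0]),
                "group2": str(r[1]),
                "diff": float(r[2]),
                "p_adj": float(r[3]),
                "reject": bool(r[6]),
            }
            for r in tukey.summary().data[1:]
        ]
        return {
            "design": "multi_group",
            "groups": names,
            "degenerate": False,
            "f": float(f),
            "df_between": len(names) - 1,
            "df_within": sum(len(x) for x in arrays) - len(names),
            "p_value": float(p),
            "tukey": pairs,
            "means": {g: float(groups[g].mean()) for g in names},
            "se": {g: float(groups[g].std(ddof=1) / math.sqrt(len(groups[g]))) for g in names},
        }
    raise ConfigurationError(f"unknown design {design!r}")


@dataclass
class QpcrReport:
    rq: pd.DataFrame
    summary: pd.DataFrame
    stats: dict


def analyze_target(
    ct: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    control_group: str,
    design: str = "multi_group",
) -> QpcrReport:
    """Full per-target workflow: ddCt -> RQ -> group summary and tests."""
    rq = delta_delta_ct(ct, target_gene, reference_gene, control_group)
    summary = group_summary(rq)
    by_group = {g: sub["rq"].to_numpy() for g, sub in rq.groupby("group", sort=True)}
    report = group_stats(by_group, design=design)
    return QpcrReport(rq=rq, summary=summary, stats=report)
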