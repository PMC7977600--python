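"""Abundance stratification of probes within each group's array.

Probes below the 50-unit net-intensity floor in a group are "very low"
abundance there regardless of their normalized value. The remaining
(accepted) probes are ranked by normalized intensity: top quartile high,
bottom quartile low, middle half medium. Quartile sizes use half-up rounding
of 0.25*n at both tails, so |high| and |low| are equal and the partition is
exact; value ties are broken by probe id for determinism.
"""

from __future__ import annotations

import logging

import pandas as pd

from .de_screen import ComparisonResult
from .errors import InputError
from .normalization import INTENSITY_FLOOR, NormalizedMatrix

logger = logging.getLogger("mirarray")

CLASSES = ("very_low", "low", "medium", "high")


def quartile_counts(n: int) -> tuple[int, int, int]:
    """(n_high, n_medium, n_low) for n accepted probes; tails get
    round-half-up of n/4 each, the middle the remainder."""
    if n < 0:
        raise InputError("n must be >= 0")
    tail = int(n / 4 + 0.5)
    return tail, n - 2 * tail, tail


def classify_abundance(
    norm: NormalizedMatrix | pd.DataFrame,
    matrix: pd.DataFrame,
    sample: str,
    floor: float = INTENSITY_FLOOR,
) -> pd.Series:
    """Abundance class per probe for one group's array."""
    data = norm.normalized if isinstance(norm, NormalizedMatrix) else norm
    for frame in (data, matrix):
        if sample not in frame.columns:
            raise InputError(f"unknown sample/group label {sample!r}")
    classes = pd.Series("very_low", index=data.index, name=sample)
    accepted = matrix.index[matrix[sample] >= floor]
    if len(accepted) == 0:
        logger.warning("no accepted probes in sample %s; all classed very_low", sample)
        return classes
    ranked = (
        data.loc[accepted, sample]
        .rename("value")
        .reset_index()
        .rename(columns={"index": "probe_id", data.index.name or "index": "probe_id"})
        .sort_values(["value", "probe_id"], ascending=[False, True])
    )
    n_high, n_medium, n_low = quartile_counts(len(accepted))
    order = ranked["probe_id"].to_list()
    classes.loc[order[:n_high]] = "high"
    classes.loc[order[n_high : n_high + n_medium]] = "medium"
    classes.loc[order[n_high + n_medium :]] = "low"
    return classes


def crosstab_de_abundance(
    result: ComparisonResult,
    classes_treatment: pd.Series,
    classes_control: pd.Series,
) -> dict:
    """Cross-tabulate DE calls by (treatment class, control class).

    Returns per-probe pairs, aggregated counts by direction and class pair,
    and the share of DE probes that are high-abundance in each group.
    """
    if not result.table.index.equals(classes_treatment.index) or not result.table.index.equals(
        classes_control.index
    ):
        missing = result.table.index.difference(classes_treatment.index).union(
            result.table.index.difference(classes_control.index)
        )
        if len(missing):
            raise InputError("class tables do not cover the comparison's probe universe")
    de = result.de
    pairs = pd.DataFrame(
        {
            "probe_id": de,
            "direction": result.table.loc[de, "status"].to_numpy(),
            "class_treatment": classes_treatment.loc[de].to_numpy(),
            "class_control": classes_control.loc[de].to_numpy(),
        }
    ).sort_values("probe_id", ignore_index=True)
    counts = (
        pairs.groupby(["direction", "class_treatment", "class_control"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    n_de = len(pairs)
    share_high = {
        "treatment": (
            float((pairs["class_treatment"] == "high").sum() / n_de * 100) if n_de else 0.0
        ),
        "control": (
            float((pairs["class_control"] == "high").sum() / n_de * 100) if n_de else 0.0
        ),
    }
    return {"pairs": pairs, "counts": counts, "n_de": n_de, "share_high_pct": share_high}
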