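"""Low-intensity acceptance filter and fold-change DE classification.

With one pooled array per group there are no replicate-based statistics:
differential expression is a fold-change screen. A probe enters a
treatment-vs-control comparison only if its raw net intensity reaches 50 in
at least one of the two compared samples (probes below 50 in both are
"filtered"). Accepted probes are called up when normalized treatment /
control >= 1.5 and down when the ratio <= 2/3 (reciprocal symmetry of the
1.5x screen), otherwise unchanged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .normalization import INTENSITY_FLOOR, NormalizedMatrix

logger = logging.getLogger("mirarray")

FC_UP_DEFAULT = 1.5
FC_DOWN_DEFAULT = 1.0 / 1.5

STATUSES = ("up", "down", "unchanged", "filtered")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding, the convention used for printed percentages."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """100 * numerator / denominator, half-up rounded."""
    if denominator == 0:
        raise InputError("percentage with zero denominator")
    return round_half_up(100.0 * numerator / denominator, ndigits)


@dataclass
class AcceptanceResult:
    treatment: str
    control: str
    accepted: pd.Index
    #: per-sample detection (net >= floor in that sample alone)
    detected: dict[str, pd.Index]
    filtered: pd.Index


@dataclass
class ComparisonResult:
    """Fold-change calls for one treatment-vs-control comparison."""

    treatment: str
    control: str
    table: pd.DataFrame  # index probe; columns fold_change, status, accepted

    @property
    def probes(self) -> pd.Index:
        return self.table.index

    def probes_with_status(self, status: str) -> pd.Index:
        return self.table.index[self.table["status"] == status]

    @property
    def up(self) -> pd.Index:
        return self.probes_with_status("up")

    @property
    def down(self) -> pd.Index:
        return self.probes_with_status("down")

    @property
    def de(self) -> pd.Index:
        return self.table.index[self.table["status"].isin(["up", "down"])]

    @property
    def accepted(self) -> pd.Index:
        return self.table.index[self.table["accepted"]]


def _require_sample(matrix: pd.DataFrame, sample: str) -> None:
    if sample not in matrix.columns:
        raise InputError(f"unknown sample/group label {sample!r}")


def accept_probes(
    matrix: pd.DataFrame,
    treatment: str,
    control: str,
    floor: float = INTENSITY_FLOOR,
) -> AcceptanceResult:
    """Acceptance filter on raw net intensities for one comparison.

    A probe is filtered only when its net is below ``floor`` in *both*
    compared samples; net exactly at the floor counts as detected.
    """
    _require_sample(matrix, treatment)
    _require_sample(matrix, control)
    detected = {s: matrix.index[matrix[s] >= floor] for s in (treatment, control)}
    keep = (matrix[treatment] >= floor) | (matrix[control] >= floor)
    return AcceptanceResult(
        treatment=treatment,
        control=control,
        accepted=matrix.index[keep],
        detected=detected,
        filtered=matrix.index[~keep],
    )


def classify_de(
    norm: NormalizedMatrix | pd.DataFrame,
    accepted: pd.Index,
    treatment: str,
    control: str,
    fc_up: float = FC_UP_DEFAULT,
    fc_down: float = FC_DOWN_DEFAULT,
) -> ComparisonResult:
    """Call up/down/unchanged on accepted probes from normalized ratios."""
    if fc_up <= 1.0:
        raise ConfigurationError("fc_up must exceed 1")
    if fc_down >= 1.0:
        raise ConfigurationError("fc_down must be below 1")
    data = norm.normalized if isinstance(norm, NormalizedMatrix) else norm
    _require_sample(data, treatment)
    _require_sample(data, control)

    table = pd.DataFrame(index=data.index)
    table["fold_change"] = np.nan
    table["status"] = "filtered"
    table["accepted"] = False

    accepted = data.index.intersection(accepted)
    ctrl = data.loc[accepted, control]
    usable = accepted[ctrl > 0]
    dropped = accepted[~(ctrl > 0)]
    if len(dropped):
        logger.warning(
            "%d accepted probe(s) with non-positive control signal excluded from %s vs %s",
            len(dropped), treatment, control,
        )
    fc = data.loc[usable, treatment] / data.loc[usable, control]
    status = np.where(fc >= fc_up, "up", np.where(fc <= fc_down, "down", "unchanged"))
    table.loc[usable, "fold_change"] = fc
    table.loc[usable, "status"] = status
    table.loc[usable, "accepted"] = True
    return ComparisonResult(treatment=treatment, control=control, table=table)


def summarize_comparison(result: ComparisonResult) -> dict:
    """Counts, fold-change ranges and DE percentage for one comparison."""
    t = result.table
    if len(t) == 0:
        raise InputError("comparison result is empty")
    counts = {s: int((t["status"] == s).sum()) for s in STATUSES}
    up_fc = t.loc[t["status"] == "up", "fold_change"]
    down_fc = t.loc[t["status"] == "down", "fold_change"]
    n_accepted = int(t["accepted"].sum())
    n_de = counts["up"] + counts["down"]
    summary = {
        "treatment": result.treatment,
        "control": result.control,
        "n_probes": len(t),
        "n_accepted": n_accepted,
        "n_up": counts["up"],
        "n_down": counts["down"],
        "n_unchanged": counts["unchanged"],
        "n_filtered": counts["filtered"],
        "n_de": n_de,
        "n_up_fc_gt2": int((up_fc > 2).sum()),
        "n_up_fc_gt5": int((up_fc > 5).sum()),
        "n_up_fc_gt10": int((up_fc > 10).sum()),
        "n_down_fc_lt_half": int((down_fc < 0.5).sum()),
        "max_up_fc": float(up_fc.max()) if len(up_fc) else math.nan,
        "min_down_fc": float(down_fc.min()) if len(down_fc) else math.nan,
        "pct_de_of_accepted": percent(n_de, n_accepted) if n_accepted else 0.0,
        "pct_up_of_de": percent(counts["up"], n_de) if n_de else 0.0,
        "pct_down_of_de": percent(counts["down"], n_de) if n_de else 0.0,
    }
    return summary


def comparison_frame(result: ComparisonResult, mirna_by_probe: pd.Series | None = None) -> pd.DataFrame:
    """Flat TSV-ready view of a comparison (probe, mirna, fc, status)."""
    out = result.table.reset_index().rename(columns={"index": "probe_id"})
    if "probe_id" not in out.columns:  # index had a name already
        out = out.rename(columns={out.columns[0]: "probe_id"})
    if mirna_by_probe is not None:
        out.insert(1, "mirna", out["probe_id"].map(mirna_by_probe))
    out["treatment"] = result.treatment
    out["control"] = result.control
    return out
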