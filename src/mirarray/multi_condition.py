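"""Set algebra over DE calls across treatment-vs-control comparisons.

Each probe gets a call per treatment drawn from {up, down, absent}; a probe
filtered or unchanged in a comparison is "absent" there. The union of DE
probes across treatments, pairwise concordant/discordant overlaps, and
direction-pattern labels such as ``CR^EX^HFv`` (rendered with real arrows)
summarise how the conditions share or oppose each other's responses.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .de_screen import ComparisonResult, percent
from .errors import InputError

UP_ARROW = "↑"
DOWN_ARROW = "↓"


def _check_shared_control(results: dict[str, ComparisonResult]) -> None:
    if not results:
        raise InputError("no comparison results supplied")
    controls = {r.control for r in results.values()}
    if len(controls) != 1:
        raise InputError(f"comparisons use different controls: {sorted(controls)}")


def calls_table(results: dict[str, ComparisonResult]) -> pd.DataFrame:
    """Probe x treatment table of calls in {up, down, absent}."""
    _check_shared_control(results)
    treatments = list(results)
    universe = None
    for r in results.values():
        universe = r.table.index if universe is None else universe.union(r.table.index)
    out = pd.DataFrame("absent", index=universe.sort_values(), columns=treatments)
    for trt, r in results.items():
        out.loc[r.up, trt] = "up"
        out.loc[r.down, trt] = "down"
    return out


def pattern_label(calls: dict[str, str], order: list[str]) -> str:
    """Direction-pattern label, e.g. CR↑EX↑HF↓; absent treatments omitted."""
    arrow = {"up": UP_ARROW, "down": DOWN_ARROW}
    return "".join(f"{t}{arrow[calls[t]]}" for t in order if calls.get(t, "absent") != "absent")


def de_union(
    results: dict[str, ComparisonResult],
    universe_size: int | None = None,
) -> dict:
    """Probes DE in at least one comparison, with per-treatment membership."""
    calls = calls_table(results)
    member = calls != "absent"
    in_union = member.any(axis=1)
    membership = member.loc[in_union]
    out = {
        "union_probes": list(membership.index),
        "union_size": int(in_union.sum()),
        "membership": membership,
        "per_treatment_size": {t: int(member[t].sum()) for t in calls.columns},
    }
    if universe_size is not None:
        if universe_size <= 0:
            raise InputError("universe_size must be positive")
        out["pct_of_universe"] = percent(out["union_size"], universe_size)
    return out


def overlap_patterns(results: dict[str, ComparisonResult]) -> dict:
    """Direction-pattern counts plus pairwise concordant/discordant overlaps."""
    calls = calls_table(results)
    order = list(calls.columns)
    patterns: dict[str, list[str]] = {}
    for probe, row in calls.iterrows():
        if (row == "absent").all():
            continue
        label = pattern_label(row.to_dict(), order)
        patterns.setdefault(label, []).append(probe)

    pairwise_rows = []
    for i, a in enumerate(order):
        for b in order[i + 1 :]:
            both = calls.index[(calls[a] != "absent") & (calls[b] != "absent")]
            conc = int((calls.loc[both, a] == calls.loc[both, b]).sum())
            pairwise_rows.append(
                {
                    "pair": f"{a}-{b}",
                    "overlap": len(both),
                    "concordant": conc,
                    "discordant": len(both) - conc,
                }
            )
    return {
        "pattern_counts": {k: len(v) for k, v in sorted(patterns.items())},
        "pattern_probes": {k: sorted(v) for k, v in sorted(patterns.items())},
        "pairwise": pd.DataFrame(pairwise_rows, columns=["pair", "overlap", "concordant", "discordant"]),
    }


def share_of_union(results: dict[str, ComparisonResult]) -> dict[str, float] | None:
    """Per-treatment DE set size as a percentage of the union; None if the
    union is empty."""
    union = de_union(results)
    if union["union_size"] == 0:
        return None
    return {
        t: percent(n, union["union_size"])
        for t, n in union["per_treatment_size"].items()
    }


def patterns_frame(patterns: dict) -> pd.DataFrame:
    rows = [
        {"pattern": label, "count": count, "probes": ";".join(patterns["pattern_probes"][label])}
        for label, count in patterns["pattern_counts"].items()
    ]
    return pd.DataFrame(rows, columns=["pattern", "count", "probes"])
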