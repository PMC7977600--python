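"""Background subtraction, replicate-spot collapsing, and median scaling.

The scheme: net intensity = foreground - background per spot; replicated
spots for a probe on one array are collapsed to their median; each array is
then divided by its median net intensity over a shared reference probe set -
the probes whose net exceeds 50 raw units in *every* sample. One divisor per
sample, so between-array scale differences cancel while within-array ratios
are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError, NormalizationError

#: raw-intensity detection floor, in scanner units
INTENSITY_FLOOR = 50.0


@dataclass
class NormalizedMatrix:
    """Probe x sample matrix after per-sample median scaling."""

    normalized: pd.DataFrame
    scale_factors: pd.Series
    reference_probes: pd.Index

    @property
    def probes(self) -> pd.Index:
        return self.normalized.index

    @property
    def samples(self) -> pd.Index:
        return self.normalized.columns


def collapse_replicates(spots: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicate spots to a probe x sample net-intensity matrix.

    Net per spot is foreground - background; replicates of one probe on one
    array are summarised by their median (midpoint of the central pair for
    even counts). Negative nets are retained.
    """
    required = {"probe_id", "sample", "foreground", "background"}
    missing = required - set(spots.columns)
    if missing:
        raise InputError(f"spot table lacks column(s): {', '.join(sorted(missing))}")
    if len(spots) == 0:
        raise InputError("spot table is empty")
    work = spots.assign(net=spots["foreground"] - spots["background"])
    matrix = (
        work.groupby(["probe_id", "sample"], sort=True)["net"]
        .median()
        .unstack("sample")
    )
    if matrix.isna().any().any():
        bad = matrix.stack(dropna=False)
        probe, sample = bad.index[bad.isna()][0]
        raise InputError(f"probe {probe!r} has no spots in sample {sample!r}")
    return matrix


def reference_probe_set(matrix: pd.DataFrame, floor: float = INTENSITY_FLOOR) -> pd.Index:
    """Probes with net intensity strictly above ``floor`` in every sample."""
    if matrix.shape[1] < 1:
        raise InputError("matrix has no samples")
    mask = (matrix > floor).all(axis=1)
    ref = matrix.index[mask]
    if len(ref) == 0:
        raise NormalizationError(
            f"no reference probes: no probe exceeds {floor} in all samples; "
            "lower the floor or check the input intensities"
        )
    return ref


def median_normalize(matrix: pd.DataFrame, floor: float = INTENSITY_FLOOR) -> NormalizedMatrix:
    """Divide each sample column by its median over the reference probe set."""
    ref = reference_probe_set(matrix, floor)
    scale = matrix.loc[ref].median(axis=0)
    if (scale <= 0).any():
        bad = scale.index[scale <= 0][0]
        raise NormalizationError(f"non-positive scale factor for sample {bad!r}")
    normalized = matrix.div(scale, axis=1)
    return NormalizedMatrix(normalized=normalized, scale_factors=scale, reference_probes=ref)
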