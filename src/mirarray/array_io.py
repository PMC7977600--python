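"""Tabular I/O for the pipeline.

Every table travels as UTF-8, tab-delimited text with a header row. The spot
table carries one row per physical spot: the probe it interrogates, the miRNA
it reports, the array (sample) it sits on, its replicate index on the slide,
and the scanner's foreground and local-background estimates in raw intensity
units. Readers validate eagerly and reject malformed numerics with line
numbers instead of silently coercing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigurationError, FormatError

logger = logging.getLogger("mirarray")

SPOT_COLUMNS = ["probe_id", "mirna", "sample", "replicate", "foreground", "background"]
CT_COLUMNS = ["sample", "group", "gene", "replicate", "ct"]

#: GenePix-subset column mapping: only the four columns that enter the math.
GPR_COLUMN_MAP = {
    "ID": "probe_id",
    "Name": "mirna",
    "F532 Median": "foreground",
    "B532 Median": "background",
}


@dataclass
class SampleSheet:
    """Maps array samples to experimental groups (AL/CR/EX/HF by default)."""

    sample_to_group: dict[str, str]
    control_group: str = "AL"

    def __post_init__(self) -> None:
        if self.control_group not in self.sample_to_group.values():
            raise ConfigurationError(
                f"control group {self.control_group!r} has no sample in the sheet"
            )
        counts: dict[str, int] = {}
        for g in self.sample_to_group.values():
            counts[g] = counts.get(g, 0) + 1
        for g, c in counts.items():
            if c > 1:
                logger.warning(
                    "group %s has %d samples; pooled design expects one", g, c
                )

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for g in self.sample_to_group.values():
            if g not in seen:
                seen.append(g)
        return seen

    @property
    def samples(self) -> list[str]:
        return list(self.sample_to_group)

    def samples_for_group(self, group: str) -> list[str]:
        return [s for s, g in self.sample_to_group.items() if g == group]

    def sample_for_group(self, group: str) -> str:
        hits = self.samples_for_group(group)
        if not hits:
            raise ConfigurationError(f"no sample for group {group!r}")
        return hits[0]

    @property
    def treatments(self) -> list[str]:
        return [g for g in self.groups if g != self.control_group]


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty file: {path}") from None
    return df


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")


def _numeric(df: pd.DataFrame, column: str, path) -> pd.Series:
    # header is line 1, so data row i (0-based) lives on line i + 2
    values = pd.to_numeric(df[column], errors="coerce")
    bad = values.isna()
    if bad.any():
        lines = [str(i + 2) for i in df.index[bad][:10]]
        raise FormatError(
            f"{path}: non-numeric value(s) in column {column!r} at line(s) {', '.join(lines)}"
        )
    return values


def read_spot_table(
    path: str | Path,
    dialect: str = "simple_tsv",
    sample: str | None = None,
) -> pd.DataFrame:
    """Read a spot-level intensity table.

    ``simple_tsv`` expects the full six-column dialect. ``gpr_subset`` reads
    the four GenePix columns actually used (ID, Name, F532 Median, B532
    Median); the sample name must then be supplied and replicate indices are
    assigned by order of appearance per probe.
    """
    if dialect not in ("simple_tsv", "gpr_subset"):
        raise ConfigurationError(f"unknown dialect {dialect!r}")
    df = _read_tsv(path)
    if dialect == "gpr_subset":
        _require_columns(df, list(GPR_COLUMN_MAP), path)
        df = df.rename(columns=GPR_COLUMN_MAP)[list(GPR_COLUMN_MAP.values())]
        if sample is None:
            raise ConfigurationError("gpr_subset dialect requires an explicit sample name")
        df["sample"] = sample
        df["replicate"] = (df.groupby("probe_id").cumcount() + 1).astype(str)
    _require_columns(df, SPOT_COLUMNS, path)
    df = df[SPOT_COLUMNS].copy()
    for col in ("foreground", "background"):
        df[col] = _numeric(df, col, path)
        if (df[col] < 0).any():
            raise FormatError(f"{path}: negative intensity in column {col!r}")
    rep = pd.to_numeric(df["replicate"], errors="coerce")
    if rep.isna().any() or (rep < 1).any() or (rep != rep.astype(int)).any():
        raise FormatError(f"{path}: replicate must be an integer >= 1")
    df["replicate"] = rep.astype(int)
    dupes = df.duplicated(subset=["probe_id", "sample", "replicate"])
    if dupes.any():
        line = df.index[dupes][0] + 2
        raise FormatError(
            f"{path}: duplicate (probe_id, sample, replicate) at line {line}"
        )
    return df.reset_index(drop=True)


def write_spot_table(table: pd.DataFrame, path: str | Path) -> None:
    table[SPOT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path, control_group: str = "AL") -> SampleSheet:
    df = _read_tsv(path)
    _require_columns(df, ["sample", "group"], path)
    if len(df) == 0:
        raise FormatError(f"{path}: sample sheet has no rows")
    if df["sample"].duplicated().any():
        dup = df["sample"][df["sample"].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate sample id {dup!r}")
    return SampleSheet(dict(zip(df["sample"], df["group"])), control_group=control_group)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    pd.DataFrame(
        {"sample": sheet.samples, "group": [sheet.sample_to_group[s] for s in sheet.samples]}
    ).to_csv(path, sep="\t", index=False)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    _require_columns(df, CT_COLUMNS, path)
    df = df[CT_COLUMNS].copy()
    df["ct"] = _numeric(df, "ct", path)
    if (df["ct"] <= 0).any():
        raise FormatError(f"{path}: Ct values must be positive")
    df["replicate"] = _numeric(df, "replicate", path).astype(int)
    if df.duplicated(subset=["sample", "gene", "replicate"]).any():
        raise FormatError(f"{path}: duplicate (sample, gene, replicate)")
    return df


def read_pairs_table(path: str | Path) -> set[tuple[str, str]]:
    """Read a two-column predictor export (mirna, gene)."""
    df = _read_tsv(path)
    _require_columns(df, ["mirna", "gene"], path)
    return set(zip(df["mirna"], df["gene"]))


def read_tissue_table(path: str | Path) -> dict[str, set[str]]:
    """Read a gene -> tissue annotation table (one row per gene-tissue pair)."""
    df = _read_tsv(path)
    _require_columns(df, ["gene", "tissue"], path)
    out: dict[str, set[str]] = {}
    for g, t in zip(df["gene"], df["tissue"]):
        out.setdefault(g, set()).add(t)
    return out


def read_term_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format term annotation table (term_id, term_name, category, gene)."""
    df = _read_tsv(path)
    _require_columns(df, ["term_id", "term_name", "category", "gene"], path)
    return df[["term_id", "term_name", "category", "gene"]].copy()


def load_run_config(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: run config must be a mapping")
    return cfg


def write_results(tables: dict[str, pd.DataFrame], outdir: str | Path) -> pd.DataFrame:
    """Write each table as ``<name>.tsv`` under ``outdir``; return a manifest.

    The manifest lists one row per file with its data row count. Writing is
    deterministic: same tables, same bytes.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        rows = []
        for name in sorted(tables):
            table = tables[name]
            path = outdir / f"{name}.tsv"
            table.to_csv(path, sep="\t", index=False)
            rows.append({"file": path.name, "rows": len(table)})
        manifest = pd.DataFrame(rows, columns=["file", "rows"])
        manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    except OSError as exc:
        raise MirArrayIOError(f"cannot write results under {outdir}: {exc}") from exc
    return manifest


class MirArrayIOError(FormatError):
    """Filesystem-level failure while writing results."""
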