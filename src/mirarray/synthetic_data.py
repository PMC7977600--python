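"""Synthetic inputs with known ground truth for every pipeline stage.

The array generator emulates the pooled one-sample-per-group design of the
study it models: 601 probes spotted in quadruplicate on one array per group
(ad libitum control AL, caloric restriction CR, exercise EX, high-fat diet
HF). Expressed probes carry a log-normal baseline signal well above the
50-unit detection floor; non-expressed probes read foreground ~ background.
Differential expression is planted per treatment with condition-specific
direction balance (CR mostly up, EX almost all up, HF balanced) and is
biased toward low/medium-abundance probes, the qualitative feature the real
chips showed.

Default rates are calibrated to the study's printed counts: ~55% of probes
detected, DE fractions 8.7/12.0/13.5% of expressed probes in CR/EX/HF, with
80.8/97.4/51.3% of DE probes up-regulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .array_io import SPOT_COLUMNS, SampleSheet
from .errors import ConfigurationError, InputError

PREDICTORS = ("targetscan", "miranda", "mirdb", "mirwalk")
GO_CATEGORIES = ("BP", "CC", "MF", "pathway")


@dataclass(frozen=True)
class DESpec:
    """Per-treatment differential-expression plan.

    frac_de: fraction of expressed probes planted DE in this treatment.
    frac_up: fraction of those DE probes that are up-regulated.
    log2fc_excess_sd: sd of the half-normal log2 excess above the 1.5x
        screening threshold; planted up FCs are 1.5 * 2^|N(0, sd)| (>= 1.5 by
        construction) and down FCs their reciprocals (<= 2/3).
    """

    frac_de: float
    frac_up: float
    log2fc_excess_sd: float = 0.5
    #: fixed log2 offset added to every excess draw; e.g. 1.0 with sd 0 plants
    #: fold changes of exactly 3 (up) and 1/3 (down)
    log2fc_excess_min: float = 0.0


#: Condition-specific DE structure: CR mostly up, EX almost all up, HF balanced.
DEFAULT_DE_SPEC: dict[str, DESpec] = {
    "CR": DESpec(frac_de=0.087, frac_up=0.808),
    "EX": DESpec(frac_de=0.120, frac_up=0.974),
    "HF": DESpec(frac_de=0.135, frac_up=0.513),
}


@dataclass
class ArraySimConfig:
    n_probes: int = 601
    n_replicate_spots: int = 4
    groups: tuple[str, ...] = ("AL", "CR", "EX", "HF")
    control_group: str = "AL"
    frac_expressed: float = 0.55
    de_spec: Mapping[str, DESpec] = field(default_factory=lambda: dict(DEFAULT_DE_SPEC))
    #: weight exponent concentrating DE among low/medium-abundance probes;
    #: 0 = uniform, larger = stronger low-abundance bias
    abundance_bias: float = 2.0
    background_mean: float = 30.0
    background_sd: float = 5.0
    #: baseline expressed signal: log2 ~ N(mean, sd), truncated at signal_min
    intensity_log2_mean: float = 8.0
    intensity_log2_sd: float = 2.0
    signal_min: float = 60.0
    #: multiplicative spot noise, sd on the log2 scale
    spot_noise_log2_sd: float = 0.1
    #: additive scanner noise on the foreground read
    foreground_noise_sd: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_probes < 8:
            raise ConfigurationError("n_probes must be >= 8")
        if self.n_replicate_spots < 1:
            raise ConfigurationError("n_replicate_spots must be >= 1")
        if not 0.0 <= self.frac_expressed <= 1.0:
            raise ConfigurationError("frac_expressed must be in [0, 1]")
        if self.control_group not in self.groups:
            raise ConfigurationError("control_group must be one of groups")
        if len(set(self.groups)) != len(self.groups):
            raise ConfigurationError("groups must be unique")
        for trt, spec in self.de_spec.items():
            if trt not in self.groups:
                raise ConfigurationError(f"de_spec group {trt!r} not in groups")
            if not 0.0 <= spec.frac_de <= 1.0:
                raise ConfigurationError(f"de_spec[{trt}].frac_de must be in [0, 1]")
            if not 0.0 <= spec.frac_up <= 1.0:
                raise ConfigurationError(f"de_spec[{trt}].frac_up must be in [0, 1]")
            if spec.log2fc_excess_sd < 0:
                raise ConfigurationError(f"de_spec[{trt}].log2fc_excess_sd must be >= 0")
            if spec.log2fc_excess_min < 0:
                raise ConfigurationError(f"de_spec[{trt}].log2fc_excess_min must be >= 0")
        for name in ("background_sd", "spot_noise_log2_sd", "foreground_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.signal_min <= 50:
            raise ConfigurationError("signal_min must exceed the 50-unit detection floor")

    @property
    def treatments(self) -> tuple[str, ...]:
        return tuple(g for g in self.groups if g != self.control_group)

    def sample_sheet(self) -> SampleSheet:
        # pooled design: sample id == group label, one array per group
        return SampleSheet({g: g for g in self.groups}, control_group=self.control_group)


@dataclass
class GroundTruth:
    """Planted truth behind one simulated experiment."""

    expressed_probes: frozenset[str]
    #: treatment -> probe -> "up" | "down"; probes absent are null
    de_status: dict[str, dict[str, str]]
    #: treatment -> probe -> planted fold change (1.0 wherever null)
    true_fold_change: dict[str, dict[str, float]]
    base_signal: dict[str, float] = field(default_factory=dict)

    def status(self, treatment: str, probe: str) -> str:
        return self.de_status.get(treatment, {}).get(probe, "null")

    def fold_change(self, treatment: str, probe: str) -> float:
        return self.true_fold_change.get(treatment, {}).get(probe, 1.0)

    def de_probes(self, treatment: str, direction: str | None = None) -> set[str]:
        calls = self.de_status.get(treatment, {})
        if direction is None:
            return set(calls)
        return {p for p, d in calls.items() if d == direction}

    def to_frame(self, treatments: Sequence[str]) -> pd.DataFrame:
        probes = sorted(self.base_signal) if self.base_signal else sorted(
            {p for m in self.de_status.values() for p in m} | set(self.expressed_probes)
        )
        out = pd.DataFrame({"probe_id": probes})
        out["expressed"] = [int(p in self.expressed_probes) for p in probes]
        for trt in treatments:
            out[f"{trt}_status"] = [self.status(trt, p) for p in probes]
            out[f"{trt}_fc"] = [self.fold_change(trt, p) for p in probes]
        return out


def probe_ids(n: int) -> list[str]:
    return [f"P{i:04d}" for i in range(1, n + 1)]


def mirna_names(n: int) -> list[str]:
    return [f"mmu-miR-sim-{i}" for i in range(1, n + 1)]


def generate_array_experiment(
    config: ArraySimConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one pooled-sample array per group plus its ground truth.

    Each spot reads foreground = background draw + signal x fold change x
    multiplicative spot noise + scanner noise; the recorded background is the
    same draw, so net intensity estimates the signal term.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_probes
    probes = np.array(probe_ids(n))
    mirnas = np.array(mirna_names(n))

    n_expressed = int(round(config.frac_expressed * n))
    expressed_idx = np.sort(rng.choice(n, size=n_expressed, replace=False))
    expressed_mask = np.zeros(n, dtype=bool)
    expressed_mask[expressed_idx] = True

    # baseline log2 signal, truncated below at the expressed-signal floor
    log2_min = np.log2(config.signal_min)
    base_log2 = np.zeros(n)
    if n_expressed:
        draws = rng.normal(config.intensity_log2_mean, config.intensity_log2_sd, n_expressed)
        while True:
            low = draws < log2_min
            if not low.any():
                break
            draws[low] = rng.normal(
                config.intensity_log2_mean, config.intensity_log2_sd, int(low.sum())
            )
        base_log2[expressed_idx] = draws
    base_signal = np.where(expressed_mask, 2.0 ** base_log2, 0.0)

    # plant DE per treatment, biased toward low-abundance expressed probes
    de_status: dict[str, dict[str, str]] = {}
    true_fc: dict[str, dict[str, float]] = {}
    fc_matrix = np.ones((n, len(config.groups)))
    if n_expressed:
        order = np.argsort(np.argsort(base_log2[expressed_idx]))  # 0 = least abundant
        pct = (order + 0.5) / n_expressed
        weights = np.exp(-config.abundance_bias * pct)
        weights /= weights.sum()
    for gi, group in enumerate(config.groups):
        if group == config.control_group or group not in config.de_spec:
            continue
        spec = config.de_spec[group]
        status: dict[str, str] = {}
        fcs: dict[str, float] = {}
        n_de = int(round(spec.frac_de * n_expressed))
        if n_de:
            chosen = rng.choice(expressed_idx, size=n_de, replace=False, p=weights)
            n_up = int(round(spec.frac_up * n_de))
            chosen = rng.permutation(chosen)
            excess = spec.log2fc_excess_min + np.abs(rng.normal(0.0, spec.log2fc_excess_sd, n_de))
            fold = 1.5 * 2.0 ** excess
            for j, idx in enumerate(chosen):
                fc = fold[j] if j < n_up else 1.0 / fold[j]
                status[probes[idx]] = "up" if j < n_up else "down"
                fcs[probes[idx]] = fc
                fc_matrix[idx, gi] = fc
        de_status[group] = status
        true_fc[group] = fcs

    n_rep = config.n_replicate_spots
    frames = []
    for gi, group in enumerate(config.groups):
        shape = (n, n_rep)
        bg = np.clip(rng.normal(config.background_mean, config.background_sd, shape), 0, None)
        spot_noise = 2.0 ** rng.normal(0.0, config.spot_noise_log2_sd, shape)
        scanner = rng.normal(0.0, config.foreground_noise_sd, shape)
        signal = (base_signal * fc_matrix[:, gi])[:, None] * spot_noise
        fg = np.clip(bg + signal + scanner, 0, None)
        frames.append(
            pd.DataFrame(
                {
                    "probe_id": np.repeat(probes, n_rep),
                    "mirna": np.repeat(mirnas, n_rep),
                    "sample": group,
                    "replicate": np.tile(np.arange(1, n_rep + 1), n),
                    "foreground": np.round(fg.ravel(), 4),
                    "background": np.round(bg.ravel(), 4),
                }
            )
        )
    spots = pd.concat(frames, ignore_index=True)[SPOT_COLUMNS]

    truth = GroundTruth(
        expressed_probes=frozenset(probes[expressed_mask]),
        de_status={t: de_status.get(t, {}) for t in config.treatments},
        true_fold_change={t: true_fc.get(t, {}) for t in config.treatments},
        base_signal=dict(zip(probes, base_signal)),
    )
    return spots, truth


def generate_prediction_tables(
    mirnas: Sequence[str],
    genes: Sequence[str],
    hit_rates: Mapping[int, float] | None = None,
    seed: int = 0,
    targets_per_mirna: int = 10,
    decoys_per_mirna: int = 12,
    predictors: Sequence[str] = PREDICTORS,
) -> tuple[dict[str, set[tuple[str, str]]], dict[str, set[str]]]:
    """Simulate predictor exports around a planted target map.

    ``hit_rates`` is a distribution over the number of predictors supporting
    a true miRNA-gene pair (keys 0..len(predictors)); decoy pairs are always
    supported by at most two predictors, so a 3-of-4 consensus can in
    principle recover the truth exactly.
    """
    if len(mirnas) == 0:
        raise InputError("at least one miRNA is required")
    if len(genes) == 0:
        raise InputError("at least one gene is required")
    n_pred = len(predictors)
    if hit_rates is None:
        hit_rates = {4: 0.6, 3: 0.3, 2: 0.1}
    supports = np.array(sorted(hit_rates))
    probs = np.array([hit_rates[s] for s in supports], dtype=float)
    if (supports < 0).any() or (supports > n_pred).any():
        raise ConfigurationError(f"hit_rates keys must lie in 0..{n_pred}")
    if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-9:
        raise ConfigurationError("hit_rates probabilities must be >= 0 and sum to 1")
    if targets_per_mirna + decoys_per_mirna > len(genes):
        raise InputError("not enough genes for the requested targets and decoys")

    rng = np.random.default_rng(seed)
    tables: dict[str, set[tuple[str, str]]] = {p: set() for p in predictors}
    true_map: dict[str, set[str]] = {}
    genes_arr = np.array(genes)
    for mirna in mirnas:
        picked = rng.choice(len(genes_arr), targets_per_mirna + decoys_per_mirna, replace=False)
        true_genes = genes_arr[picked[:targets_per_mirna]]
        decoy_genes = genes_arr[picked[targets_per_mirna:]]
        true_map[mirna] = set(true_genes)
        for gene in true_genes:
            k = int(rng.choice(supports, p=probs))
            for pi in rng.choice(n_pred, size=k, replace=False):
                tables[predictors[pi]].add((mirna, gene))
        for gene in decoy_genes:
            k = int(rng.integers(1, min(2, n_pred) + 1))
            for pi in rng.choice(n_pred, size=k, replace=False):
                tables[predictors[pi]].add((mirna, gene))
    return tables, true_map


def generate_tissue_table(
    genes: Sequence[str],
    liver_genes: Iterable[str],
    seed: int = 0,
    tissues: Sequence[str] = ("liver", "kidney", "brain", "muscle"),
) -> dict[str, set[str]]:
    """Tissue-specificity table: designated genes carry the liver flag, the
    rest are assigned 1-2 non-liver tissues."""
    rng = np.random.default_rng(seed)
    liver = set(liver_genes)
    others = [t for t in tissues if t != "liver"]
    table: dict[str, set[str]] = {}
    for gene in genes:
        assigned = set(rng.choice(others, size=int(rng.integers(1, 3)), replace=False))
        if gene in liver:
            assigned.add("liver")
        table[gene] = assigned
    return table


@dataclass(frozen=True)
class EnrichedTermSpec:
    """One planted over-represented term: its size and the odds multiplier
    favouring selection genes when its members are drawn."""

    size: int
    odds_ratio: float = 8.0
    category: str = "BP"


def generate_annotation_tables(
    genes: Sequence[str],
    n_terms: int,
    enriched_terms_spec: Sequence[EnrichedTermSpec] = (),
    seed: int = 0,
    term_size_range: tuple[int, int] = (10, 50),
    selection: Sequence[str] | None = None,
    selection_size: int = 50,
    categories: Sequence[str] = GO_CATEGORIES,
) -> tuple[pd.DataFrame, dict]:
    """Simulate term -> gene annotation with optional planted enrichment.

    Null terms draw members uniformly from ``genes``; enriched terms draw
    with weight ``odds_ratio`` on the designated selection, so that selection
    is over-represented among their members. Returns the long-format table
    and a truth dict with the selection and enriched term ids.
    """
    if n_terms < 1:
        raise InputError("n_terms must be >= 1")
    lo, hi = term_size_range
    if hi > len(genes) or any(s.size > len(genes) for s in enriched_terms_spec):
        raise InputError("term size exceeds the number of genes")
    rng = np.random.default_rng(seed)
    genes_arr = np.array(genes)
    if selection is None:
        selection = list(genes_arr[rng.choice(len(genes_arr), selection_size, replace=False)])
    sel_mask = np.isin(genes_arr, list(selection))

    rows = []
    enriched_ids = []
    for i in range(n_terms):
        term_id = f"T{i + 1:04d}"
        category = categories[i % len(categories)]
        if i < len(enriched_terms_spec):
            spec = enriched_terms_spec[i]
            category = spec.category
            weights = np.where(sel_mask, spec.odds_ratio, 1.0)
            weights = weights / weights.sum()
            members = genes_arr[rng.choice(len(genes_arr), spec.size, replace=False, p=weights)]
            enriched_ids.append(term_id)
        else:
            size = int(rng.integers(lo, hi + 1))
            members = genes_arr[rng.choice(len(genes_arr), size, replace=False)]
        for g in sorted(members):
            rows.append((term_id, f"term {i + 1}", category, g))
    table = pd.DataFrame(rows, columns=["term_id", "term_name", "category", "gene"])
    truth = {"selection": sorted(selection), "enriched_terms": enriched_ids}
    return table, truth


@dataclass
class QpcrDesign:
    """Layout of a simulated qPCR validation plate."""

    genes: tuple[str, ...] = ("mmu-miR-34a-5p",)
    reference_gene: str = "U6"
    groups: tuple[str, ...] = ("AL", "CR", "EX", "HF")
    control_group: str = "AL"
    n_per_group: int = 5
    n_technical_replicates: int = 3
    #: gene -> group -> planted expression fold change vs the control group
    true_fold_change: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    ct_noise_sd: float = 0.2
    #: per-animal loading/RT efficiency shift, cancels in dCt
    sample_effect_sd: float = 0.3
    base_ct: float = 25.0
    reference_base_ct: float = 18.0

    def validate(self) -> None:
        if self.reference_gene in self.genes:
            raise InputError("reference gene cannot also be a target")
        if not self.genes:
            raise InputError("design lists no target genes")
        if self.reference_gene is None or self.reference_gene == "":
            raise InputError("reference gene absent from design")
        if self.control_group not in self.groups:
            raise InputError("control group absent from design")
        if self.n_per_group < 2:
            raise InputError("n_per_group must be >= 2")
        if self.ct_noise_sd < 0 or self.sample_effect_sd < 0:
            raise ConfigurationError("noise sds must be >= 0")
        for gene, per_group in self.true_fold_change.items():
            if gene not in self.genes:
                raise InputError(f"true_fold_change gene {gene!r} not in design")
            for g, fc in per_group.items():
                if g not in self.groups:
                    raise InputError(f"true_fold_change group {g!r} not in design")
                if fc <= 0:
                    raise ConfigurationError("fold changes must be positive")


def generate_qpcr_plate(design: QpcrDesign, seed: int = 0) -> pd.DataFrame:
    """Simulate a Ct table where target dCt vs the reference encodes
    -log2(planted fold change) relative to the control group."""
    design.validate()
    rng = np.random.default_rng(seed)
    rows = []
    for group in design.groups:
        for animal in range(1, design.n_per_group + 1):
            sample = f"{group}_{animal}"
            eff = rng.normal(0.0, design.sample_effect_sd)
            for gene in (*design.genes, design.reference_gene):
                if gene == design.reference_gene:
                    mean_ct = design.reference_base_ct + eff
                else:
                    fc = design.true_fold_change.get(gene, {}).get(group, 1.0)
                    mean_ct = design.base_ct - np.log2(fc) + eff
                for rep in range(1, design.n_technical_replicates + 1):
                    ct = mean_ct + rng.normal(0.0, design.ct_noise_sd)
                    rows.append((sample, group, gene, rep, float(ct)))
    return pd.DataFrame(rows, columns=["sample", "group", "gene", "replicate", "ct"])


def write_ground_truth(truth: GroundTruth, treatments: Sequence[str], path: str | Path) -> None:
    truth.to_frame(treatments).to_csv(path, sep="\t", index=False)
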