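"""End-to-end orchestration: simulate -> normalize -> screen -> stratify ->
overlap -> targets -> enrich, under one config, one seed, one manifest.

Each stage's output is written as a TSV under the run directory so any stage
can be audited or re-run from intermediates; the run summary quotes the
stage outputs directly rather than recomputing them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import abundance_strata, array_io, de_screen, function_annotation, multi_condition
from . import normalization as norm_mod
from . import synthetic_data
from .errors import ConfigurationError, MirArrayError
from .synthetic_data import ArraySimConfig, EnrichedTermSpec

logger = logging.getLogger("mirarray")


@dataclass
class RunConfig:
    sim: ArraySimConfig = field(default_factory=ArraySimConfig)
    floor: float = 50.0
    fc_up: float = 1.5
    fc_down: float = 1.0 / 1.5
    min_support: int = 3
    alpha: float = 0.05
    top_k: int = 10
    tissue: str = "liver"
    #: gene pool behind the simulated predictor/annotation tables
    n_genes: int = 2000
    n_terms: int = 40
    n_enriched_terms: int = 4
    liver_fraction: float = 0.6
    seed: int = 0
    outdir: str | Path = "results/run"

    def validate(self) -> None:
        if self.fc_up <= 1 or self.fc_down >= 1:
            raise ConfigurationError("fc_up must exceed 1 and fc_down be below 1")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.min_support < 1:
            raise ConfigurationError("min_support must be >= 1")
        if self.top_k < 1:
            raise ConfigurationError("top_k must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = array_io.load_run_config(path)
        sim_block = raw.pop("sim", {})
        de_spec = sim_block.pop("de_spec", None)
        sim = ArraySimConfig(**sim_block)
        if de_spec is not None:
            sim.de_spec = {
                trt: synthetic_data.DESpec(**spec) for trt, spec in de_spec.items()
            }
        cfg = cls(sim=sim, **raw)
        cfg.validate()
        return cfg


@dataclass
class RunResult:
    manifest: pd.DataFrame
    summary: dict
    summary_text: str
    tables: dict[str, pd.DataFrame]
    truth: synthetic_data.GroundTruth


def _stage(name: str):
    """Wrap stage bodies so failures carry the stage name."""

    def deco(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except MirArrayError as exc:
                raise type(exc)(f"stage {name!r} failed: {exc}") from exc

        return inner

    return deco


def run_all(config: RunConfig) -> RunResult:
    """Execute every stage in order and write all outputs plus a summary.

    A stage failure aborts the run with the stage name and cause; tables
    produced by earlier stages are still written, and the manifest carries a
    FAILED marker row.
    """
    config.validate()
    partial: dict[str, pd.DataFrame] = {}
    try:
        return _run_all(config, partial)
    except MirArrayError:
        if partial:
            manifest = array_io.write_results(partial, config.outdir)
            failed = pd.DataFrame([{"file": "FAILED", "rows": 0}])
            pd.concat([manifest, failed], ignore_index=True).to_csv(
                Path(config.outdir) / "manifest.tsv", sep="\t", index=False
            )
        raise


def _run_all(config: RunConfig, tables: dict[str, pd.DataFrame]) -> RunResult:
    sim = replace(config.sim, seed=config.seed)
    sheet = sim.sample_sheet()
    treatments = list(sim.treatments)
    rng_seeds = np.random.SeedSequence(config.seed).spawn(3)
    summary: dict = {"seed": config.seed, "thresholds": {
        "floor": config.floor, "fc_up": config.fc_up, "fc_down": round(config.fc_down, 6),
        "min_support": config.min_support, "alpha": config.alpha, "top_k": config.top_k,
    }}
    logger.info("run-all thresholds: %s", summary["thresholds"])

    # --- simulate ---
    spots, truth = _stage("simulate")(synthetic_data.generate_array_experiment)(sim)
    tables["spots"] = spots
    tables["ground_truth"] = truth.to_frame(treatments)

    # --- normalize ---
    matrix = _stage("normalize")(norm_mod.collapse_replicates)(spots)
    normalized = _stage("normalize")(norm_mod.median_normalize)(matrix, config.floor)
    tables["normalized_matrix"] = normalized.normalized.reset_index()
    tables["scale_factors"] = normalized.scale_factors.rename("scale_factor").reset_index()

    # --- de screen ---
    mirna_by_probe = spots.drop_duplicates("probe_id").set_index("probe_id")["mirna"]
    control_sample = sheet.sample_for_group(sim.control_group)
    results: dict[str, de_screen.ComparisonResult] = {}
    comp_summaries = {}
    detected_counts = {}
    accepted_union = None
    for trt in treatments:
        trt_sample = sheet.sample_for_group(trt)
        acc = _stage("de")(de_screen.accept_probes)(matrix, trt_sample, control_sample, config.floor)
        res = _stage("de")(de_screen.classify_de)(
            normalized, acc.accepted, trt_sample, control_sample, config.fc_up, config.fc_down
        )
        results[trt] = res
        comp_summaries[trt] = de_screen.summarize_comparison(res)
        detected_counts[trt] = len(acc.detected[trt_sample])
        detected_counts[sim.control_group] = len(acc.detected[control_sample])
        acc_idx = pd.Index(acc.accepted)
        accepted_union = acc_idx if accepted_union is None else accepted_union.union(acc_idx)
        tables[f"comparison_{trt}"] = de_screen.comparison_frame(res, mirna_by_probe)
    summary["detected_per_group"] = detected_counts
    summary["accepted_union_size"] = int(len(accepted_union))
    summary["comparisons"] = comp_summaries

    # --- abundance strata ---
    classes = {}
    for group in sim.groups:
        s = sheet.sample_for_group(group)
        classes[group] = _stage("abundance")(abundance_strata.classify_abundance)(
            normalized, matrix, s, config.floor
        )
    tables["abundance_classes"] = pd.DataFrame(classes).rename_axis("probe_id").reset_index()
    crosstabs = {}
    for trt in treatments:
        ct = abundance_strata.crosstab_de_abundance(
            results[trt], classes[trt], classes[sim.control_group]
        )
        crosstabs[trt] = ct
        tables[f"abundance_crosstab_{trt}"] = ct["counts"]
    summary["abundance_share_high_pct"] = {
        t: round(c["share_high_pct"]["treatment"], 1) for t, c in crosstabs.items()
    }

    # --- overlap ---
    union = _stage("overlap")(multi_condition.de_union)(
        results, universe_size=summary["accepted_union_size"]
    )
    patterns = _stage("overlap")(multi_condition.overlap_patterns)(results)
    shares = multi_condition.share_of_union(results)
    tables["de_patterns"] = multi_condition.patterns_frame(patterns)
    tables["pairwise_overlap"] = patterns["pairwise"]
    summary["union"] = {
        "size": union["union_size"],
        "pct_of_accepted": union["pct_of_universe"],
        "per_treatment_size": union["per_treatment_size"],
        "share_of_union_pct": shares,
        "pattern_counts": patterns["pattern_counts"],
    }

    # --- targets ---
    de_mirnas = sorted(mirna_by_probe.loc[p] for p in union["union_probes"])
    genes = [f"Gene{i:04d}" for i in range(1, config.n_genes + 1)]
    pred_seed = int(rng_seeds[0].generate_state(1)[0] % (2**31))
    if de_mirnas:
        pred_tables, true_targets = _stage("targets")(synthetic_data.generate_prediction_tables)(
            de_mirnas, genes, seed=pred_seed
        )
        consensus = _stage("targets")(function_annotation.consensus_targets)(
            pred_tables, config.min_support
        )
    else:
        pred_tables, true_targets, consensus = {}, {}, {}
    liver_rng = np.random.default_rng(int(rng_seeds[1].generate_state(1)[0] % (2**31)))
    consensus_genes = sorted(function_annotation.target_gene_union(consensus))
    n_liver = int(round(config.liver_fraction * len(consensus_genes)))
    liver_flagged = set(
        liver_rng.choice(consensus_genes, size=n_liver, replace=False)
    ) if consensus_genes else set()
    tissue_table = synthetic_data.generate_tissue_table(
        genes, liver_flagged, seed=int(rng_seeds[1].generate_state(2)[1] % (2**31))
    )
    filtered, tissue_report = function_annotation.tissue_filter(
        consensus, tissue_table, config.tissue
    )
    target_genes = sorted(function_annotation.target_gene_union(filtered))
    tables["consensus_targets"] = pd.DataFrame(
        [(m, g) for m in sorted(filtered) for g in sorted(filtered[m])],
        columns=["mirna", "gene"],
    )
    summary["targets"] = {
        "n_de_mirnas": len(de_mirnas),
        "n_consensus_pairs": sum(len(v) for v in consensus.values()),
        "n_target_genes_consensus": len(consensus_genes),
        "n_target_genes_tissue_filtered": len(target_genes),
        "tissue_report": tissue_report,
    }

    # --- enrich ---
    ann_seed = int(rng_seeds[2].generate_state(1)[0] % (2**31))
    enriched_spec = [
        EnrichedTermSpec(size=60, odds_ratio=8.0, category=c)
        for c in ("BP", "CC", "MF", "pathway")[: config.n_enriched_terms]
    ]
    norm_targets = [function_annotation.normalize_symbol(g) for g in target_genes]
    term_table, ann_truth = _stage("enrich")(synthetic_data.generate_annotation_tables)(
        genes,
        config.n_terms,
        enriched_terms_spec=enriched_spec if norm_targets else (),
        seed=ann_seed,
        selection=norm_targets or None,
    )
    enrichment = _stage("enrich")(function_annotation.enrich)(
        norm_targets or ann_truth["selection"], genes, term_table, alpha=config.alpha
    )
    top = function_annotation.top_terms(enrichment, config.top_k)
    tables["enrichment"] = enrichment
    tables["top_terms"] = top
    summary["enrichment"] = {
        "n_terms_tested": len(enrichment),
        "n_significant": int(enrichment["significant"].sum()),
        "planted_terms": ann_truth["enriched_terms"],
        "top_term_per_category": {
            c: grp.iloc[0]["term_id"] for c, grp in top.groupby("category")
        },
    }

    manifest = array_io.write_results(tables, config.outdir)
    text = summary_text(summary)
    Path(config.outdir, "summary.txt").write_text(text, encoding="utf-8")
    return RunResult(manifest=manifest, summary=summary, summary_text=text,
                     tables=tables, truth=truth)


def summary_text(summary: dict) -> str:
    lines = [
        "miRNA array screening run summary",
        f"seed: {summary['seed']}",
        f"thresholds: {summary['thresholds']}",
        "",
        "Accepted / detected probes",
        f"  accepted in >=1 comparison: {summary['accepted_union_size']}",
    ]
    for g, n in summary["detected_per_group"].items():
        lines.append(f"  detected in {g}: {n}")
    lines.append("")
    lines.append("Differential expression (vs control)")
    for trt, s in summary["comparisons"].items():
        lines.append(
            f"  {trt}: accepted {s['n_accepted']}, up {s['n_up']}, down {s['n_down']}"
            f" ({s['pct_de_of_accepted']}% DE; {s['pct_up_of_de']}% of DE up)"
        )
    u = summary["union"]
    lines += [
        "",
        "Cross-condition overlap",
        f"  union of DE probes: {u['size']} ({u['pct_of_accepted']}% of accepted)",
        f"  share of union: {u['share_of_union_pct']}",
        f"  direction patterns: {u['pattern_counts']}",
        "",
        "Targets and enrichment",
        f"  consensus target genes: {summary['targets']['n_target_genes_consensus']}"
        f" -> {summary['targets']['n_target_genes_tissue_filtered']} after tissue filter",
        f"  significant terms: {summary['enrichment']['n_significant']}"
        f" of {summary['enrichment']['n_terms_tested']}",
    ]
    return "\n".join(lines) + "\n"
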