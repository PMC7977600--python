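"""Consensus target prediction, liver filter, and over-representation.

Runs the whole upstream pipeline (simulate -> normalize -> screen ->
overlap) and then: simulates four predictor exports for the DE miRNAs,
keeps miRNA-gene pairs supported by >= 3 of 4 predictors, restricts targets
to liver-annotated genes, and tests annotation terms for over-representation
(one-sided Fisher, BH FDR per category, significant when p and FDR < 0.05).
"""

import argparse
from pathlib import Path

from mirarray.pipeline import RunConfig, run_all


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results/targets"))
    args = ap.parse_args()

    res = run_all(RunConfig(seed=args.seed, outdir=args.outdir))
    t = res.summary["targets"]
    e = res.summary["enrichment"]
    print(f"DE miRNAs: {t['n_de_mirnas']}; consensus pairs (>=3 of 4 predictors): "
          f"{t['n_consensus_pairs']} over {t['n_target_genes_consensus']} genes")
    print(f"after liver filter: {t['n_target_genes_tissue_filtered']} target genes "
          f"(dropped {t['tissue_report']['n_dropped_other_tissue']} other-tissue, "
          f"{t['tissue_report']['n_dropped_unannotated']} unannotated)")
    print(f"enrichment: {e['n_significant']} of {e['n_terms_tested']} terms significant; "
          f"planted terms {e['planted_terms']}, top per category {e['top_term_per_category']}")
    print(f"full run manifest -> {args.outdir}/manifest.tsv")


if __name__ == "__main__":
    main()
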