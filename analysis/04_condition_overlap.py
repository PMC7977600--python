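"""Cross-condition set algebra over the DE calls.

Builds the union of probes DE in any treatment, each treatment's share of
that union, pairwise concordant/discordant overlaps, and direction-pattern
labels (e.g. a probe up in CR and EX but down in HF).
"""

import argparse
from pathlib import Path

import pandas as pd

from mirarray import array_io, de_screen, multi_condition, normalization, synthetic_data


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results/overlap"))
    args = ap.parse_args()

    cfg = synthetic_data.ArraySimConfig(seed=args.seed)
    spots, _ = synthetic_data.generate_array_experiment(cfg)
    matrix = normalization.collapse_replicates(spots)
    norm = normalization.median_normalize(matrix)

    results, accepted_union = {}, None
    for trt in cfg.treatments:
        acc = de_screen.accept_probes(matrix, trt, "AL")
        results[trt] = de_screen.classify_de(norm, acc.accepted, trt, "AL")
        idx = pd.Index(acc.accepted)
        accepted_union = idx if accepted_union is None else accepted_union.union(idx)

    union = multi_condition.de_union(results, universe_size=len(accepted_union))
    shares = multi_condition.share_of_union(results)
    patterns = multi_condition.overlap_patterns(results)

    print(f"accepted in >=1 comparison: {len(accepted_union)}")
    print(f"DE union: {union['union_size']} probes = {union['pct_of_universe']}% of accepted")
    print(f"per-treatment DE sizes: {union['per_treatment_size']}; share of union: {shares}")
    print("pairwise overlaps (concordant/discordant):")
    print(patterns["pairwise"].to_string(index=False))

    array_io.write_results(
        {
            "de_patterns": multi_condition.patterns_frame(patterns),
            "pairwise_overlap": patterns["pairwise"],
            "union_membership": union["membership"].rename_axis("probe_id").reset_index(),
        },
        args.outdir,
    )
    print(f"wrote tables -> {args.outdir}")


if __name__ == "__main__":
    main()
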