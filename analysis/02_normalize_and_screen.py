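"""Median-normalize the arrays and screen for fold-change DE vs control.

Reads the spot table written by 01 (or regenerates it from the seed),
collapses replicate spots, scales each array by its reference-set median,
applies the 50-unit acceptance filter per comparison and the 1.5x / (2/3)
fold-change screen, and writes per-comparison call tables plus a summary.
"""

import argparse
from pathlib import Path

import pandas as pd

from mirarray import array_io, de_screen, normalization, synthetic_data


def load_or_simulate(indir: Path, seed: int):
    spot_path = indir / "spots.tsv"
    if spot_path.exists():
        return array_io.read_spot_table(spot_path)
    return synthetic_data.generate_array_experiment(synthetic_data.ArraySimConfig(seed=seed))[0]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--indir", type=Path, default=Path("results/arrays"))
    ap.add_argument("--outdir", type=Path, default=Path("results/de"))
    ap.add_argument("--floor", type=float, default=50.0)
    args = ap.parse_args()

    spots = load_or_simulate(args.indir, args.seed)
    matrix = normalization.collapse_replicates(spots)
    norm = normalization.median_normalize(matrix, args.floor)
    print("per-array scale factors (reference-set medians):")
    print(norm.scale_factors.round(2).to_string())

    mirna = spots.drop_duplicates("probe_id").set_index("probe_id")["mirna"]
    tables, rows = {}, []
    for trt in [s for s in matrix.columns if s != "AL"]:
        acc = de_screen.accept_probes(matrix, trt, "AL", args.floor)
        res = de_screen.classify_de(norm, acc.accepted, trt, "AL")
        s = de_screen.summarize_comparison(res)
        rows.append(s)
        tables[f"comparison_{trt}"] = de_screen.comparison_frame(res, mirna)
        print(f"{trt} vs AL: accepted {s['n_accepted']}, up {s['n_up']}, down {s['n_down']} "
              f"-> {s['pct_de_of_accepted']}% DE ({s['pct_up_of_de']}% of DE up); "
              f"max up FC {s['max_up_fc']:.2f}")
    tables["de_summary"] = pd.DataFrame(rows)
    array_io.write_results(tables, args.outdir)
    print(f"wrote {len(tables)} tables -> {args.outdir}")


if __name__ == "__main__":
    main()
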