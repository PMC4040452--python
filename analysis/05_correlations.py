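#!/usr/bin/env python
"""Standardized pairwise correlations and the Ward-ordered heat map.

River: restricts to the 4 consecutive dry weekdays, z-scores TCC, %LNA and
the four sensor channels, computes Pearson and Spearman matrices with
t-based p-values, reorders by Ward clustering on 1 - r, and writes the
matrices, the leaf order and a diverging (green/red) heat map.

Tap: the 2-parameter TCC vs %LNA correlation on the weekday baseline.
"""

import argparse
import json
from pathlib import Path

from flowmon import assembly, baseline, correlate
from flowmon import synthetic_data as syn

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    # river: full 6-parameter analysis on the dry-weather window
    series = assembly.MultiSeries.from_csv(args.results / "river_multiseries.csv")
    cfg = syn.river_published()
    s, e = syn.dry_subset_window(cfg)
    frame = series.frame.loc[(series.frame.index >= s) & (series.frame.index < e)]
    res = correlate.correlation_analysis(
        frame[["tcc", "pct_lna", "T", "DO", "EC", "pH"]]
    )
    res.pcc.round(3).to_csv(args.results / "river_pcc.csv")
    res.scc.round(3).to_csv(args.results / "river_scc.csv")
    res.p_pcc.to_csv(args.results / "river_p_pcc.csv")
    paths = correlate.export_heatmap(res, args.results / "river_heatmap")
    (args.results / "river_leaf_order.json").write_text(
        json.dumps({"leaf_order": res.leaf_order}, indent=1)
    )
    n = int(res.n_used.at["EC", "tcc"])
    print(
        f"river dry-weather subset (n={n}): "
        f"EC-TCC r={res.pcc.at['EC', 'tcc']:.2f}, "
        f"pH-%LNA r={res.pcc.at['pH', 'pct_lna']:.2f}; "
        f"Ward leaf order {res.leaf_order} -> {paths['figure']}"
    )

    # tap: TCC vs %LNA on the weekday non-event baseline
    tap = assembly.MultiSeries.from_csv(args.results / "tap_multiseries.csv")
    tap_cfg = syn.tap_published()
    subset = baseline.apply_exclusions(tap, syn.preset_exclusions(tap_cfg))
    z = correlate.standardize(subset.frame[["tcc", "pct_lna"]])
    r, p, n_used = correlate.pearson_pairwise(z)
    print(
        f"tap weekday baseline (n={int(n_used.at['tcc', 'pct_lna'])}): "
        f"TCC-%LNA r={r.at['tcc', 'pct_lna']:.2f} "
        f"(p={p.at['tcc', 'pct_lna']:.2g})"
    )
    (args.results / "tap_tcc_lna_correlation.json").write_text(
        json.dumps(
            {
                "r": round(float(r.at["tcc", "pct_lna"]), 3),
                "p": float(p.at["tcc", "pct_lna"]),
                "n": int(n_used.at["tcc", "pct_lna"]),
            },
            indent=1,
        )
    )


if __name__ == "__main__":
    main()
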