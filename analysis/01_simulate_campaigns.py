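#!/usr/bin/env python
"""Generate the two synthetic monitoring campaigns as on-disk file trees.

Emits, for each of the tap_published (14-day drinking water) and river_published
(12-day river with two rainfall events) presets: one FCS 3.1 file per
15-min sample, a 10-s sensor CSV (river only), a rainfall CSV, the
ground-truth ledger and the generator configuration.

Output goes to scratch/campaigns/{tap,river} (several hundred MB for the
river campaign; everything downstream reads from there). Run with
``--seed`` to change the realization; the default matches the downstream
scripts.
"""

import argparse
from pathlib import Path

from flowmon import synthetic_data as syn

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=ROOT / "scratch" / "campaigns")
    args = ap.parse_args()

    for preset, site in (("tap_published", "tap"), ("river_published", "river")):
        cfg = syn.PRESETS[preset](seed=args.seed)
        truth, gt = syn.simulate_campaign(cfg)
        outdir = args.outdir / site
        paths = syn.emit_campaign_files(truth, gt, cfg, outdir)
        n_files = len(list(paths["fcs_dir"].glob("*.fcs")))
        print(
            f"{site}: {cfg.duration_days} d, {len(truth.frame)} slots, "
            f"{n_files} FCS files emitted, {gt.programmed['n_missing']} slots missing "
            f"-> {outdir}"
        )


if __name__ == "__main__":
    main()
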