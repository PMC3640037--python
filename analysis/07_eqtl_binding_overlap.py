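"""Overlap interaction-eQTL classes with binding regions.

Counts GC-only and control-only eQTL SNPs within 100 bp of a receptor
binding region (1 kb for NF-kB), reports the fold enrichment between the
two classes, and attaches a label-permutation resampling p-value.
"""

import numpy as np
import pandas as pd

from common import load_cohort, parse_args
from gcresponse.eqtl import cis_scan
from gcresponse.io import write_table
from gcresponse.overlap import class_overlap_counts, fold_enrichment, resampling_pvalue


def main() -> None:
    args = parse_args(__doc__)
    cfg, data, h = load_cohort(args)
    outdir = args.results / "overlap"
    outdir.mkdir(parents=True, exist_ok=True)

    scan = cis_scan(
        data["expression"], data["genotypes"], data["tracks"].genes,
        window=cfg.cis_window, priors=cfg.priors,
    )
    frames = []
    for factor, pk, window in (
        ("GR", data["gr_dex"], cfg.gr_window),
        ("NFKB", data["nfkb_dex"], cfg.nfkb_window),
    ):
        counts = class_overlap_counts(scan, pk, window)
        counts.insert(0, "factor", factor)
        a = scan[scan["class"] == "gc_only"]
        b = scan[scan["class"] == "control_only"]
        fold = p = np.nan
        na = nb = 0
        if len(a) and len(b):
            p, na, nb = resampling_pvalue(
                a, b, pk, window, n_resamples=cfg.n_resamples, seed=cfg.sim.seed
            )
            fold = fold_enrichment(na, nb) if nb else np.nan
        counts["gc_vs_ctrl_fold"] = fold
        counts["gc_vs_ctrl_p"] = p
        frames.append(counts)
        desc = f"{na} GC-only vs {nb} control-only within {window} bp"
        if np.isfinite(fold):
            print(f"{factor}: {desc} ({fold:.1f}-fold, p = {p:.3f})")
        else:
            print(f"{factor}: {desc} (fold undefined, p = {p:.3f})")
    write_table(pd.concat(frames, ignore_index=True), outdir / "class_overlap.tsv", h)


if __name__ == "__main__":
    main()
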