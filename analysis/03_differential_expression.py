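"""Call treatment-responsive genes from the time-course panel.

Per-individual log2 fold changes (treated minus control) are tested per
timepoint with the paired moderated t-test; q-values control the FDR and
a gene is responsive if significant at one or more timepoints.
"""

import pandas as pd

from common import load_cohort, parse_args
from gcresponse.de import de_from_panel
from gcresponse.io import write_table


def main() -> None:
    args = parse_args(__doc__)
    cfg, data, h = load_cohort(args)
    outdir = args.results / "de"
    outdir.mkdir(parents=True, exist_ok=True)

    result = de_from_panel(data["panel"], fdr=cfg.fdr)
    frames = []
    for tp, tab in result.tables.items():
        t = tab.reset_index()
        t.insert(0, "timepoint", tp)
        frames.append(t)
        n_sig = int((tab["q"] <= cfg.fdr).sum())
        print(f"  {tp:>2} h: {n_sig} genes at FDR {cfg.fdr:.0%} "
              f"(pi0 = {result.pi0[tp]:.2f})")
    write_table(pd.concat(frames, ignore_index=True), outdir / "de_tests.tsv", h)
    write_table(pd.DataFrame({"gene": result.de_genes}), outdir / "de_genes.tsv", h)
    print(f"{len(result.de_genes)} of {len(data['panel'])} genes responsive at "
          f"one or more timepoints")


if __name__ == "__main__":
    main()
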