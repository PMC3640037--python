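"""Compare binding landscapes across treatment conditions.

Asks whether receptor occupancy is ligand-dependent (what fraction of
treated-condition GR regions is also bound in the control, and whether
the control regions are a subset of the treated ones) and whether NF-kB
tag counts at its sites rise under treatment.
"""

import pandas as pd

from common import load_cohort, parse_args
from gcresponse.enrichment import mann_whitney_u, percent_increase
from gcresponse.io import write_table
from gcresponse.peaks import overlap_fraction, subset_report, tags_at_sites


def main() -> None:
    args = parse_args(__doc__)
    _, data, h = load_cohort(args)
    outdir = args.results / "peaks"
    outdir.mkdir(parents=True, exist_ok=True)

    gr_dex, gr_ctrl = data["gr_dex"], data["gr_ctrl"]
    n_shared, frac = overlap_fraction(gr_dex, gr_ctrl)
    x, y = subset_report(gr_ctrl, gr_dex)
    print(f"{100 * frac:.1f}% of treated GR regions ({n_shared}/{len(gr_dex)}) "
          f"are also bound in the control")
    print(f"control GR regions inside the treated set: {x} out of {y}")

    tags = tags_at_sites(data["nfkb_ctrl"], {"dex": data["nfkb_dex"],
                                             "ctrl": data["nfkb_ctrl"]})
    u, p = mann_whitney_u(tags["dex"], tags["ctrl"])
    inc = percent_increase(float(tags["dex"].mean()), float(tags["ctrl"].mean()))
    print(f"NF-kB tags at its {len(tags)} sites: {inc:+.1f}% under treatment "
          f"(MWU p = {p:.2g})")

    write_table(
        pd.DataFrame(
            [
                {"comparison": "GR dex overlapping ctrl", "n": n_shared,
                 "total": len(gr_dex), "fraction": frac},
                {"comparison": "GR ctrl inside dex", "n": x, "total": y,
                 "fraction": x / y if y else float("nan")},
                {"comparison": "NFKB tag increase (%)", "n": len(tags),
                 "total": len(tags), "fraction": inc},
            ]
        ),
        outdir / "peak_landscape.tsv",
        h,
    )


if __name__ == "__main__":
    main()
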