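"""Classify cis eQTLs by their interaction with treatment.

Every SNP within 100 kb of a gene's TSS is scored with Bayes factors for
the no-interaction, GC-only, control-only and general-interaction models;
posteriors combine them with the conservative prior (0.999 null,
0.001/4 per alternative).  The confusion against the planted truth is
reported.
"""

import pandas as pd

from common import load_cohort, parse_args
from gcresponse.eqtl import cis_scan
from gcresponse.io import write_table


def main() -> None:
    args = parse_args(__doc__)
    cfg, data, h = load_cohort(args)
    outdir = args.results / "eqtl"
    outdir.mkdir(parents=True, exist_ok=True)

    scan = cis_scan(
        data["expression"], data["genotypes"], data["tracks"].genes,
        window=cfg.cis_window, priors=cfg.priors,
    )
    write_table(scan, outdir / "eqtl_scan.tsv", h)
    print(f"tested {len(scan)} gene-SNP pairs within {cfg.cis_window // 1000} kb")
    print("assigned classes:", scan["class"].value_counts().to_dict())

    truth = data["truth"]
    merged = scan.merge(truth.reset_index(), on=["gene", "snp"],
                        suffixes=("_called", "_planted"))
    confusion = pd.crosstab(merged["class_planted"], merged["class_called"])
    write_table(confusion.reset_index(), outdir / "confusion.tsv", h)
    correct = (merged["class_planted"] == merged["class_called"]).mean()
    print(f"causal-pair agreement with planted truth: {100 * correct:.1f}%")
    print(confusion.to_string())


if __name__ == "__main__":
    main()
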