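"""Cluster temporal response profiles and test primary-target enrichment.

Responsive genes are clustered (k-means on the per-interval change in
log2 fold change); each cluster is summarized by direction and peak time,
its share of primary receptor targets (genes with a binding region within
100 kb of the TSS) is tested against the overall rate with one-tailed
hypergeometric probabilities, and a multinomial Monte-Carlo test asks
whether primary targets distribute randomly across clusters.
"""

import numpy as np
import pandas as pd

from common import load_cohort, parse_args
from gcresponse.annotation import primary_targets
from gcresponse.de import de_from_panel
from gcresponse.enrichment import cluster_enrichment, multinomial_cluster_test
from gcresponse.io import write_table
from gcresponse.timecourse import cluster_panel

def main() -> None:
    args = parse_args(__doc__)
    cfg, data, h = load_cohort(args)
    outdir = args.results / "clusters"
    outdir.mkdir(parents=True, exist_ok=True)

    de_genes = de_from_panel(data["panel"], fdr=cfg.fdr).de_genes
    panel = data["panel"].loc[de_genes]
    k = min(cfg.k, np.unique(panel.to_numpy(), axis=0).shape[0])
    result, _ = cluster_panel(panel, k=k, seed=cfg.sim.seed)

    primary = primary_targets(data["tracks"].genes, data["gr_dex"],
                              window=cfg.primary_target_window)
    primary = primary.reindex(result.assignments.index).fillna(False)
    enrich = cluster_enrichment(result.assignments, primary)
    p_multi = multinomial_cluster_test(
        enrich["successes"].to_numpy(), enrich["size"].to_numpy(),
        n_sim=cfg.n_multinomial_sim, seed=cfg.sim.seed,
    )
    table = result.summary.drop(columns="size").merge(enrich, on="cluster")
    table["multinomial_p"] = p_multi

    write_table(result.assignments.reset_index(), outdir / "assignments.tsv", h)
    write_table(result.centers, outdir / "centers.tsv", h)
    write_table(table, outdir / "cluster_table.tsv", h)
    print(f"clustered {len(panel)} responsive genes into k={k} clusters")
    cols = ["cluster", "direction", "peak_time", "size", "percent", "p"]
    print(table[cols].to_string(index=False,
                                formatters={"percent": "{:.0f}".format,
                                            "p": "{:.3f}".format}))
    print(f"multinomial test of random distribution across clusters: p = {p_multi:.3f}")


if __name__ == "__main__":
    main()
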