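"""Model the direction of response from binding-region features.

For every gene with a receptor binding region within 100 kb of its TSS,
seven covariates are derived (distance, upstream flag, closer-to-other-
gene flag, tag count, intervening CTCF, DNase overlap, canonical motif)
and a logistic model regresses the probability of up-regulation on them.
"""

from common import load_cohort, parse_args
from gcresponse.annotation import (
    default_gr_pwm,
    fit_logistic,
    nearest_peak_features,
    scan_peaks,
)
from gcresponse.io import write_table
from gcresponse.timecourse import median_profile


def main() -> None:
    args = parse_args(__doc__)
    cfg, data, h = load_cohort(args)
    outdir = args.results / "features"
    outdir.mkdir(parents=True, exist_ok=True)

    tracks = data["tracks"]
    motif = scan_peaks(tracks.peak_sequences, default_gr_pwm(),
                       tracks.background_sequence)
    lfc8 = median_profile(data["panel"])[8]  # response at 8 h
    rows = nearest_peak_features(
        tracks.genes, data["gr_dex"], tracks.ctcf, tracks.dnase, motif, lfc8,
        window=cfg.primary_target_window,
    )
    fit = fit_logistic(rows)

    write_table(rows, outdir / "feature_rows.tsv", h)
    write_table(fit.summary.reset_index(), outdir / "logistic_fit.tsv", h)
    print(f"{len(rows)} genes with a binding region within "
          f"{cfg.primary_target_window // 1000} kb of the TSS "
          f"({int(rows['label'].sum())} up-regulated)")
    print(fit.summary.to_string(float_format=lambda v: f"{v:.3g}"))
    if not fit.converged:
        print("warning: IRLS did not converge")


if __name__ == "__main__":
    main()
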