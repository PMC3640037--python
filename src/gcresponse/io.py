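"""Readers and writers for the pipeline's plain-text formats.

All genomic coordinates are normalized internally to 0-based half-open
(BED convention); VCF positions (1-based) are converted at the boundary.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import GenotypeMatrix, PairedExpression

logger = logging.getLogger(__name__)

_BED_CORE = ["chrom", "start", "end"]


class BedFormatError(ValueError):
    pass


def read_bed(path, extra_names=("name", "tags", "factor", "condition")) -> pd.DataFrame:
    """Read a BED-like tab-separated file (>= 3 columns, extras preserved).

    Malformed lines (non-integer coordinates, start >= end) raise an error
    citing the line number.
    """
    rows = []
    n_extra = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedFormatError(f"{path}: line {lineno}: fewer than 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise BedFormatError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start >= end:
                raise BedFormatError(
                    f"{path}: line {lineno}: start >= end ({start} >= {end})"
                )
            rows.append([parts[0], start, end, *parts[3:]])
            n_extra = max(n_extra, len(parts) - 3)
    names = _BED_CORE + [
        extra_names[i] if i < len(extra_names) else f"col{i + 4}"
        for i in range(n_extra)
    ]
    df = pd.DataFrame(rows, columns=names[: 3 + n_extra] if rows else names)
    if "tags" in df.columns:
        df["tags"] = pd.to_numeric(df["tags"], errors="coerce")
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = _BED_CORE + [c for c in df.columns if c not in _BED_CORE]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

_GT_CODE = {"0/0": 0.0, "0/1": 1.0, "1/0": 1.0, "1/1": 2.0, "./.": np.nan,
            "0|0": 0.0, "0|1": 1.0, "1|0": 1.0, "1|1": 2.0, ".|.": np.nan}


def read_genotypes(path, expression_samples=None) -> GenotypeMatrix:
    """Read a VCF-lite (CHROM POS ID REF ALT + per-sample GT) or dosage TSV.

    Multi-allelic VCF records are skipped with a warning; VCF POS is
    1-based and converted to 0-based.  If ``expression_samples`` is given,
    the sample header must match it.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##") or first.startswith("#CHROM"):
        gm = _read_vcf_lite(path)
    else:
        gm = _read_dosage_tsv(path)
    if expression_samples is not None and list(gm.sample_ids) != list(expression_samples):
        raise ValueError("genotype sample header does not match the expression table")
    return gm


def _read_vcf_lite(path) -> GenotypeMatrix:
    header = None
    snp_ids, positions, chroms, rows = [], [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                header = line.lstrip("#").split("\t")
                continue
            parts = line.split("\t")
            chrom, pos, vid, ref, alt = parts[:5]
            if "," in alt:
                logger.warning("skipping multi-allelic record %s", vid)
                continue
            gts = parts[5:]
            rows.append([_GT_CODE.get(gt.split(":")[0], np.nan) for gt in gts])
            snp_ids.append(vid)
            positions.append(int(pos) - 1)  # to 0-based
            chroms.append(chrom)
    if header is None:
        raise ValueError(f"{path}: missing #CHROM header line")
    samples = header[5:]
    dosages = pd.DataFrame(
        np.array(rows, dtype=float).T,
        index=pd.Index(samples, name="sample"),
        columns=pd.Index(snp_ids, name="snp"),
    )
    pos = pd.Series(positions, index=dosages.columns, name="pos")
    chrom = chroms[0] if chroms else "chrS"
    return GenotypeMatrix(dosages=dosages, positions=pos, chrom=chrom)


def _read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    pos = df["pos"]
    chrom = str(df["chrom"].iloc[0]) if "chrom" in df else "chrS"
    dos = df.drop(columns=[c for c in ("pos", "chrom") if c in df]).T
    dos.index.name = "sample"
    dos.columns.name = "snp"
    bad = dos.to_numpy(dtype=float)
    if np.nanmin(bad) < 0 or np.nanmax(bad) > 2:
        raise ValueError(f"{path}: dosages must lie in [0, 2]")
    return GenotypeMatrix(dosages=dos.astype(float), positions=pos.astype(np.int64),
                          chrom=chrom)


def write_vcf_lite(gm: GenotypeMatrix, path) -> None:
    """Write genotypes as a minimal VCF (GT only; dosages rounded)."""
    inv = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=gcresponse\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\t" + "\t".join(gm.sample_ids) + "\n")
        for snp in gm.snp_ids:
            pos1 = int(gm.positions[snp]) + 1
            gts = []
            for v in gm.dosages[snp]:
                gts.append("./." if np.isnan(v) else inv[int(round(v))])
            fh.write(
                f"{gm.chrom}\t{pos1}\t{snp}\tA\tG\t" + "\t".join(gts) + "\n"
            )


def write_dosage_tsv(gm: GenotypeMatrix, path) -> None:
    out = gm.dosages.T.copy()
    out.insert(0, "chrom", gm.chrom)
    out.insert(1, "pos", gm.positions)
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# expression and generic tables
# ---------------------------------------------------------------------------

def write_expression(expr: PairedExpression, treat_path, ctrl_path) -> None:
    expr.treated.to_csv(treat_path, sep="\t")
    expr.control.to_csv(ctrl_path, sep="\t")


def read_expression(treat_path, ctrl_path) -> PairedExpression:
    t = pd.read_csv(treat_path, sep="\t", index_col=0)
    c = pd.read_csv(ctrl_path, sep="\t", index_col=0)
    return PairedExpression(treated=t, control=c)


def config_hash(obj) -> str:
    """Stable short hash of a configuration mapping."""
    text = yaml.safe_dump(obj, sort_keys=True, default_flow_style=True)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, cfg_hash: str | None = None,
                index: bool = False) -> None:
    """TSV writer that stamps the config hash as a leading comment line."""
    with open(path, "w") as fh:
        if cfg_hash is not None:
            fh.write(f"# config={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def read_table(path, **kw) -> pd.DataFrame:
    # keep_default_na=False so the eQTL class label "null" survives a round trip
    kw.setdefault("keep_default_na", False)
    kw.setdefault("na_values", ["", "NA", "NaN", "nan"])
    return pd.read_csv(path, sep="\t", comment="#", **kw)


def read_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
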