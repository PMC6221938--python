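"""Readers and writers for the package's plain-text interchange formats.

BED is 0-based half-open with no header; all TSVs carry a header row.
Missing numeric annotations are empty fields (pandas NA) in TSVs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cnv import BinnedCounts, GenomeBinning
from .ddpcr import DropletWell
from .variants import Consequence, Sift, VariantRecord

# ---------------------------------------------------------------------------
# BED / counts


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64},
    )
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def write_counts(counts: BinnedCounts, path) -> None:
    counts.to_frame().to_csv(path, sep="\t", index=False)


def read_counts(path, binning: GenomeBinning, sample_id: str = "") -> BinnedCounts:
    """Read a per-bin count TSV (chrom, start, end, count) against a binning.

    The rows must match the binning bin-for-bin, in order.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if len(df) != len(binning):
        raise ValueError(
            f"count table has {len(df)} rows but binning has {len(binning)} bins"
        )
    expected = binning.to_frame()
    if not (
        df["chrom"].to_numpy() == expected["chrom"].to_numpy()
    ).all() or not (df["start"].to_numpy() == expected["start"].to_numpy()).all():
        raise ValueError("count table bins do not match the binning")
    return BinnedCounts(binning, df["count"].to_numpy(np.int64), sample_id=sample_id)


# ---------------------------------------------------------------------------
# droplet data


def write_droplet_counts(wells: Sequence[DropletWell], path, well_ids=None) -> None:
    ids = well_ids or [f"W{i+1}" for i in range(len(wells))]
    rows = [
        {
            "well": wid,
            "n_mut_only": w.n_mut_only,
            "n_wt_only": w.n_wt_only,
            "n_double": w.n_double,
            "n_negative": w.n_negative,
        }
        for wid, w in zip(ids, wells)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_droplet_counts(path) -> list[DropletWell]:
    df = pd.read_csv(path, sep="\t")
    return [
        DropletWell(
            n_mut_only=int(r.n_mut_only),
            n_wt_only=int(r.n_wt_only),
            n_double=int(r.n_double),
            n_negative=int(r.n_negative),
        )
        for r in df.itertuples()
    ]


def write_amplitudes(df: pd.DataFrame, path) -> None:
    cols = [c for c in ("well", "ch1", "ch2") if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False)


def read_amplitudes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("ch1", "ch2"):
        if col not in df.columns:
            raise ValueError(f"amplitude table missing column {col!r}")
    return df


# ---------------------------------------------------------------------------
# variant tables

_VARIANT_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "consequence",
    "vaf_tumor",
    "af_dbsnp",
    "af_exac",
    "af_1000g",
    "cadd_phred",
    "sift",
    "in_net_genes",
    "in_cosmic_census",
]


def variants_to_frame(variants: Sequence[VariantRecord]) -> pd.DataFrame:
    rows = []
    for v in variants:
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "gene": v.gene,
                "consequence": v.consequence.value,
                "vaf_tumor": v.vaf_tumor,
                "af_dbsnp": v.af_dbsnp,
                "af_exac": v.af_exac,
                "af_1000g": v.af_1000g,
                "cadd_phred": v.cadd_phred,
                "sift": v.sift.value,
                "in_net_genes": v.in_net_genes,
                "in_cosmic_census": v.in_cosmic_census,
            }
        )
    return pd.DataFrame(rows, columns=_VARIANT_COLUMNS)


def write_variant_table(variants: Sequence[VariantRecord], path) -> None:
    variants_to_frame(variants).to_csv(path, sep="\t", index=False)


def _opt_float(value) -> Optional[float]:
    return None if pd.isna(value) else float(value)


def read_variant_table(path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(("chrom", "pos", "ref", "alt")) - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    records = []
    for r in df.itertuples():
        records.append(
            VariantRecord(
                chrom=str(r.chrom),
                pos=int(r.pos),
                ref=str(r.ref),
                alt=str(r.alt),
                gene=str(getattr(r, "gene", "")) if pd.notna(getattr(r, "gene", "")) else "",
                consequence=Consequence(getattr(r, "consequence", "other")),
                vaf_tumor=_opt_float(getattr(r, "vaf_tumor", None)),
                af_dbsnp=_opt_float(getattr(r, "af_dbsnp", None)),
                af_exac=_opt_float(getattr(r, "af_exac", None)),
                af_1000g=_opt_float(getattr(r, "af_1000g", None)),
                cadd_phred=_opt_float(getattr(r, "cadd_phred", None)),
                sift=Sift(getattr(r, "sift", "missing")),
                in_net_genes=bool(getattr(r, "in_net_genes", False)),
                in_cosmic_census=bool(getattr(r, "in_cosmic_census", False)),
            )
        )
    return records


def read_vcf_variants(vcf_path, sidecar_path) -> list[VariantRecord]:
    """Read SNVs from a VCF plus a TSV annotation sidecar.

    The sidecar is keyed by ``chrom:pos:ref:alt`` (column ``key``) and
    carries the annotation columns of the plain TSV format; VCF records
    without a sidecar row are dropped.
    """
    import cyvcf2  # local import: heavy optional dependency

    side = pd.read_csv(sidecar_path, sep="\t", dtype={"key": str}).set_index("key")
    records = []
    for var in cyvcf2.VCF(str(vcf_path)):
        for alt in var.ALT:
            key = f"{var.CHROM}:{var.POS}:{var.REF}:{alt}"
            if key not in side.index:
                continue
            r = side.loc[key]
            records.append(
                VariantRecord(
                    chrom=var.CHROM,
                    pos=var.POS,
                    ref=var.REF,
                    alt=alt,
                    gene=str(r.get("gene", "")),
                    consequence=Consequence(r.get("consequence", "other")),
                    vaf_tumor=_opt_float(r.get("vaf_tumor")),
                    af_dbsnp=_opt_float(r.get("af_dbsnp")),
                    af_exac=_opt_float(r.get("af_exac")),
                    af_1000g=_opt_float(r.get("af_1000g")),
                    cadd_phred=_opt_float(r.get("cadd_phred")),
                    sift=Sift(r.get("sift", "missing")),
                    in_net_genes=bool(r.get("in_net_genes", False)),
                    in_cosmic_census=bool(r.get("in_cosmic_census", False)),
                )
            )
    return records


# ---------------------------------------------------------------------------
# JSON


def write_json(obj, path) -> None:
    """Canonical JSON: sorted keys, fixed separators, trailing newline."""
    Path(path).write_text(dumps_canonical(obj) + "\n")


def dumps_canonical(obj) -> str:
    return json.dumps(obj, indent=2, sort_keys=True, allow_nan=False)
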