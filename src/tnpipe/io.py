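"""Readers and writers for the pipeline's plain-text interchange formats.

TSV is the native format everywhere (pandas-backed, LF line endings, fixed
6-significant-digit floats so reruns diff cleanly); paired allele depths can
additionally round-trip through minimal VCF 4.2 with per-sample AD fields
(pysam-backed).
"""

from __future__ import annotations

import json
from dataclasses import asdict

import pandas as pd

from .somatic import AlleleDepth, PairedSiteCounts, VariantAnnotation

FLOAT_FORMAT = "%.6g"

PAIRED_COLUMNS = ["chrom", "pos", "ref", "alt", "t_ref", "t_alt", "n_ref", "n_alt"]


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT, lineterminator="\n")


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def paired_counts_to_frame(sites: list[PairedSiteCounts]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "pos": [s.pos for s in sites],
            "ref": [s.ref for s in sites],
            "alt": [s.alt for s in sites],
            "t_ref": [s.tumor.ref_count for s in sites],
            "t_alt": [s.tumor.alt_count for s in sites],
            "n_ref": [s.normal.ref_count for s in sites],
            "n_alt": [s.normal.alt_count for s in sites],
        }
    )


def write_paired_counts(sites: list[PairedSiteCounts], path) -> None:
    write_tsv(paired_counts_to_frame(sites), path)


def read_paired_counts(path) -> list[PairedSiteCounts]:
    df = read_tsv(path)
    missing = set(PAIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"paired-counts TSV missing columns: {sorted(missing)}")
    return [
        PairedSiteCounts(
            chrom=str(r.chrom),
            pos=int(r.pos),
            ref=str(r.ref),
            alt=str(r.alt),
            tumor=AlleleDepth(int(r.t_ref), int(r.t_alt)),
            normal=AlleleDepth(int(r.n_ref), int(r.n_alt)),
        )
        for r in df.itertuples(index=False)
    ]


def write_paired_vcf(
    sites: list[PairedSiteCounts],
    path,
    tumor_sample: str = "TUMOR",
    normal_sample: str = "NORMAL",
) -> None:
    """Minimal VCF 4.2 with per-sample AD (ref,alt read depths)."""
    import pysam

    header = pysam.VariantHeader()
    chroms = sorted({s.chrom for s in sites})
    for c in chroms:
        header.contigs.add(c)
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref,alt)")
    header.add_sample(tumor_sample)
    header.add_sample(normal_sample)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for s in sorted(sites, key=lambda x: (x.chrom, x.pos)):
            rec = vcf.new_record(
                contig=s.chrom, start=s.pos - 1, alleles=(s.ref, s.alt)
            )
            rec.samples[tumor_sample]["AD"] = (s.tumor.ref_count, s.tumor.alt_count)
            rec.samples[normal_sample]["AD"] = (s.normal.ref_count, s.normal.alt_count)
            vcf.write(rec)


def read_paired_vcf(
    path,
    tumor_sample: str = "TUMOR",
    normal_sample: str = "NORMAL",
) -> list[PairedSiteCounts]:
    """Read paired allele depths from a VCF with per-sample AD fields.

    Multi-allelic records must be split upstream; only the first ALT is
    read.
    """
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for name in (tumor_sample, normal_sample):
            if name not in samples:
                raise ValueError(f"sample {name!r} not in VCF (has {samples})")
        for rec in vcf:
            if not rec.alts:
                continue
            t_ad = rec.samples[tumor_sample]["AD"]
            n_ad = rec.samples[normal_sample]["AD"]
            out.append(
                PairedSiteCounts(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    tumor=AlleleDepth(int(t_ad[0]), int(t_ad[1])),
                    normal=AlleleDepth(int(n_ad[0]), int(n_ad[1])),
                )
            )
    return out


def write_annotations(ann: dict, path) -> None:
    rows = [asdict(a) for a in (ann.values() if isinstance(ann, dict) else ann)]
    df = pd.DataFrame(rows).sort_values("site_id").reset_index(drop=True)
    write_tsv(df, path)


def read_annotations(path) -> dict:
    df = read_tsv(path)
    return {
        str(r.site_id): VariantAnnotation(str(r.site_id), str(r.consequence), float(r.pop_af))
        for r in df.itertuples(index=False)
    }


def write_count_matrix(cm, dirpath) -> None:
    """counts.tsv (genes x samples), lengths.tsv, samples.tsv in a directory."""
    from pathlib import Path

    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    write_tsv(cm.counts.rename_axis("gene"), d / "counts.tsv", index=True)
    write_tsv(
        cm.gene_lengths.rename("length_bp").rename_axis("gene").reset_index(),
        d / "lengths.tsv",
    )
    samples = pd.DataFrame({"sample": cm.counts.columns, "group": cm.groups.to_numpy()})
    if cm.total_mapped is not None:
        samples["total_mapped"] = cm.total_mapped.to_numpy()
    write_tsv(samples, d / "samples.tsv")


def read_count_matrix(counts_path, lengths_path, samples_path):
    from .expression import CountMatrix

    counts = read_tsv(counts_path, index_col=0)
    lengths = read_tsv(lengths_path).set_index("gene")["length_bp"]
    samples = read_tsv(samples_path).set_index("sample")
    total = samples["total_mapped"] if "total_mapped" in samples.columns else None
    return CountMatrix(
        counts=counts,
        gene_lengths=lengths,
        groups=samples["group"],
        total_mapped=total,
    )


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_gene_list(path) -> list:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
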