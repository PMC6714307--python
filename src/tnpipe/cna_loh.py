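"""Copy-number and loss-of-heterozygosity calling.

Four pieces:

* exon-level depth log2 ratios summarized to gene-level calls (median over a
  gene's exons, then thresholded into HOM_DEL / HET_DEL / NEUTRAL / GAIN),
* per-site LOH from paired VAFs (a site heterozygous in the normal sample
  that appears homozygous in the tumor),
* a windowed Z statistic over array probe log ratios (1 Mb tiles, |Z| >= 4
  flagged, matching the aCGH screening convention), and
* a mechanism classifier for biallelic gene inactivation combining copy
  state, LOH, and somatic mutations (homozygous deletion; heterozygous
  deletion plus mutation; copy-neutral LOH plus mutation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExonDepthRecord",
    "GeneCNAResult",
    "LOHCall",
    "WindowZResult",
    "CNACutoffs",
    "LOHParams",
    "gene_level_log2",
    "call_loh",
    "aggregate_loh",
    "windowed_z",
    "classify_inactivation",
    "HOM_DEL",
    "HET_DEL",
    "NEUTRAL",
    "GAIN",
    "LOH",
    "NO_LOH",
    "UNINFORMATIVE",
    "MECHANISMS",
]

HOM_DEL = "HOM_DEL"
HET_DEL = "HET_DEL"
NEUTRAL = "NEUTRAL"
GAIN = "GAIN"

LOH = "LOH"
NO_LOH = "NO_LOH"
UNINFORMATIVE = "UNINFORMATIVE"

HOMOZYGOUS_DELETION = "HOMOZYGOUS_DELETION"
HET_DELETION_PLUS_MUTATION = "HET_DELETION_PLUS_MUTATION"
COPY_NEUTRAL_LOH_PLUS_MUTATION = "COPY_NEUTRAL_LOH_PLUS_MUTATION"
HET_DELETION_ONLY = "HET_DELETION_ONLY"
NO_BIALLELIC_EVIDENCE = "NO_BIALLELIC_EVIDENCE"

MECHANISMS = (
    HOMOZYGOUS_DELETION,
    HET_DELETION_PLUS_MUTATION,
    COPY_NEUTRAL_LOH_PLUS_MUTATION,
    HET_DELETION_ONLY,
    NO_BIALLELIC_EVIDENCE,
)

#: mechanisms that assert biallelic inactivation
BIALLELIC = frozenset(
    {HOMOZYGOUS_DELETION, HET_DELETION_PLUS_MUTATION, COPY_NEUTRAL_LOH_PLUS_MUTATION}
)


@dataclass(frozen=True)
class ExonDepthRecord:
    gene: str
    exon_index: int
    log2_ratio: float


@dataclass(frozen=True)
class GeneCNAResult:
    gene: str
    gene_log2: float
    n_exons: int
    category: str


@dataclass(frozen=True)
class LOHCall:
    site_id: str
    normal_vaf: float
    tumor_vaf: float
    status: str


@dataclass(frozen=True)
class WindowZResult:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # inclusive
    n_probes: int
    mean_ratio: float
    z: float
    flagged: bool


@dataclass(frozen=True)
class CNACutoffs:
    """Gene-level log2 category thresholds (<= for losses, >= for gain)."""

    hom_del: float = -2.0
    het_del: float = -0.5
    gain: float = 0.5


@dataclass(frozen=True)
class LOHParams:
    """Normal-het window and the tumor homozygosity margin."""

    het_lo: float = 0.4
    het_hi: float = 0.6
    hom_margin: float = 0.1


def _categorize(log2: float, cuts: CNACutoffs) -> str:
    if log2 <= cuts.hom_del:
        return HOM_DEL
    if log2 <= cuts.het_del:
        return HET_DEL
    if log2 >= cuts.gain:
        return GAIN
    return NEUTRAL


def gene_level_log2(
    exons,
    cutoffs: CNACutoffs = CNACutoffs(),
) -> list[GeneCNAResult]:
    """Summarize exon depth log2 ratios to per-gene calls.

    ``exons`` is a list of ExonDepthRecord or a DataFrame with columns
    (gene, exon_index, log2_ratio).  The gene summary is the median exon
    ratio — robust to a single aberrant exon — and categories follow
    ``cutoffs``.  Output is sorted by gene id; genes with no records are
    simply absent.
    """
    if isinstance(exons, pd.DataFrame):
        df = exons[["gene", "exon_index", "log2_ratio"]]
    else:
        df = pd.DataFrame(
            {
                "gene": [e.gene for e in exons],
                "exon_index": [e.exon_index for e in exons],
                "log2_ratio": [e.log2_ratio for e in exons],
            }
        )
    if not np.isfinite(df["log2_ratio"].to_numpy(dtype=float)).all():
        raise ValueError("non-finite exon log2 ratio")
    out = []
    grouped = df.groupby("gene", sort=True)["log2_ratio"]
    for gene, vals in grouped:
        med = float(np.median(vals.to_numpy(dtype=float)))
        out.append(GeneCNAResult(gene, med, int(vals.size), _categorize(med, cutoffs)))
    return out


def call_loh(sites, params: LOHParams = LOHParams()) -> list[LOHCall]:
    """Per-site LOH from paired VAFs.

    ``sites`` is an iterable of (site_id, normal_vaf, tumor_vaf) or a
    DataFrame with those columns.  A site is UNINFORMATIVE unless the normal
    VAF lies in the het window; an informative site is LOH when the tumor
    VAF is within ``hom_margin`` of 0 or 1, else NO_LOH.  Pure function of
    the two VAFs and the thresholds.
    """
    if isinstance(sites, pd.DataFrame):
        rows = sites[["site_id", "normal_vaf", "tumor_vaf"]].itertuples(index=False)
    else:
        rows = sites
    out = []
    for site_id, nv, tv in rows:
        if not (0.0 <= nv <= 1.0 and 0.0 <= tv <= 1.0):
            raise ValueError(f"VAF out of [0,1] at {site_id}")
        if not params.het_lo <= nv <= params.het_hi:
            status = UNINFORMATIVE
        elif tv <= params.hom_margin or tv >= 1.0 - params.hom_margin:
            status = LOH
        else:
            status = NO_LOH
        out.append(LOHCall(str(site_id), float(nv), float(tv), status))
    return out


def aggregate_loh(calls: list[LOHCall], min_fraction: float = 0.8, min_sites: int = 3) -> str:
    """Region-level LOH status from per-site calls.

    LOH if at least ``min_fraction`` of informative sites are LOH and there
    are at least ``min_sites`` informative sites; UNINFORMATIVE with too few
    informative sites; NO_LOH otherwise.
    """
    informative = [c for c in calls if c.status != UNINFORMATIVE]
    if len(informative) < min_sites:
        return UNINFORMATIVE
    n_loh = sum(c.status == LOH for c in informative)
    return LOH if n_loh / len(informative) >= min_fraction else NO_LOH


def windowed_z(
    probes,
    window_bp: int = 1_000_000,
    z_threshold: float = 4.0,
    min_probes: int = 10,
    chrom: str = "chr1",
) -> list[WindowZResult]:
    """Z statistic per non-overlapping genomic tile of probe log ratios.

    ``probes`` is an iterable of (position, log2_ratio) or a DataFrame with
    columns (pos, log2_ratio), sorted by position (unsorted input is a hard
    error).  Tiles are anchored at the chromosome start (window i covers
    [i*W+1, (i+1)*W]).  z = window mean / (global robust sd / sqrt(n)) with
    global robust sd = 1.4826 * MAD over all probes; a window is flagged iff
    |z| >= ``z_threshold`` and it holds at least ``min_probes`` probes.  A
    zero robust sd (noiseless input) yields z = +/-inf for windows with a
    non-zero mean and z = 0 otherwise.
    """
    if isinstance(probes, pd.DataFrame):
        pos = probes["pos"].to_numpy(dtype=np.int64)
        ratio = probes["log2_ratio"].to_numpy(dtype=float)
    else:
        arr = list(probes)
        pos = np.array([p for p, _ in arr], dtype=np.int64)
        ratio = np.array([r for _, r in arr], dtype=float)
    if pos.size == 0:
        return []
    if np.any(np.diff(pos) < 0):
        raise ValueError("probes must be sorted by position")

    sd = 1.4826 * float(np.median(np.abs(ratio - np.median(ratio))))
    idx = (pos - 1) // window_bp
    out = []
    for w in np.unique(idx):
        sel = ratio[idx == w]
        n = sel.size
        mean = float(sel.mean())
        if sd > 0:
            z = mean / (sd / np.sqrt(n))
        else:
            z = 0.0 if mean == 0.0 else float(np.inf) * np.sign(mean)
        flagged = bool(abs(z) >= z_threshold and n >= min_probes)
        out.append(
            WindowZResult(
                chrom=chrom,
                start=int(w) * window_bp + 1,
                end=(int(w) + 1) * window_bp,
                n_probes=int(n),
                mean_ratio=mean,
                z=float(z),
                flagged=flagged,
            )
        )
    return out


def classify_inactivation(
    gene: str,
    cna: GeneCNAResult | None,
    loh_status: str,
    mutations,
) -> str:
    """Mechanism of biallelic inactivation for one gene in one tumor.

    ``mutations`` is the list of somatic calls (any object) hitting the
    gene; only its emptiness matters here — consequence-level screening
    belongs to the variant filter upstream.  Returns one of ``MECHANISMS``;
    the first three assert biallelic inactivation.
    """
    category = cna.category if cna is not None else NEUTRAL
    has_mut = len(mutations) > 0
    if category == HOM_DEL:
        return HOMOZYGOUS_DELETION
    if category == HET_DEL and has_mut:
        return HET_DELETION_PLUS_MUTATION
    if category == NEUTRAL and loh_status == LOH and has_mut:
        return COPY_NEUTRAL_LOH_PLUS_MUTATION
    if category == HET_DEL:
        return HET_DELETION_ONLY
    return NO_BIALLELIC_EVIDENCE
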