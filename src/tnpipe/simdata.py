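"""Seeded synthetic paired tumor/normal data with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, at study-like scale:

* ~150x exome depth pairs (per-site depths Poisson around ``depth_mean``)
  with tumor purity scaling the observed somatic VAF,
* germline heterozygous sites at VAF ~0.5 in both samples, planted somatic
  sites (tumor alt reads binomial at purity x somatic VAF, normal alt reads
  at the sequencing error rate), and LOH regions where the tumor VAF is
  pushed toward 0 or 1 while the normal stays heterozygous,
* exon-level depth log2 ratios and an array probe track carrying planted
  heterozygous/homozygous deletions, including a designated driver gene
  that is biallelically inactivated in every tumor through a different
  mechanism (the SMARCB1-like lesion spectrum),
* negative-binomial RNA count matrices for a small tumor cohort against
  controls, with planted up/down DE genes at a configurable up:down ratio,
  a strongly knocked-down driver gene, and a designated top cancer gene
  (NPM1-like) planted as the most significant upregulated gene,
* gene-set collections with planted enriched sets, a cancer-gene list
  containing the top gene, and subgroup signature genes scored against a
  reference gene (EZH2-like).

Every quantity is drawn from named, seed-derived RNG streams, so each
generator is reproducible in isolation and consistent inside a cohort.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import cna_loh
from .enrichment import GeneSetCollection, SubgroupSignature
from .expression import CountMatrix
from .somatic import AlleleDepth, PairedSiteCounts, VariantAnnotation

__all__ = [
    "SimConfig",
    "GenomicInterval",
    "TruthSet",
    "Cohort",
    "DriverLesion",
    "MECHANISM_PRESETS",
    "gene_model",
    "gen_paired_counts",
    "gen_count_matrix",
    "gen_gene_sets",
    "gen_exon_depth_and_probes",
    "gen_annotations",
    "subgroup_signatures",
    "simulate_cohort",
]

SUBGROUPS = ("TYR", "SHH", "MYC")

_STREAMS = {
    "model": 1,
    "sites": 2,
    "reads": 3,
    "expr": 4,
    "counts": 5,
    "de": 6,
    "sets": 7,
    "exons": 8,
    "probes": 9,
    "ann": 10,
    "signatures": 11,
}


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class GenomicInterval(BaseModel):
    chrom: str = "chr22"
    start: int  # 1-based inclusive
    end: int  # inclusive

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


class SimConfig(BaseModel):
    """All knobs of the synthetic study, with study-like defaults."""

    n_sites: int = 5500
    n_genes: int = 2000
    n_tumors: int = 4
    n_controls: int = 5
    depth_mean: float = 150.0
    purity: float = Field(default=0.9, gt=0.0, le=1.0)
    somatic_vaf: float = Field(default=0.4, ge=0.0, le=1.0)
    germline_het_rate: float = Field(default=1.0, ge=0.0, le=1.0)
    n_somatic: int = 500
    error_rate: float = Field(default=1e-3, ge=0.0, le=0.5)
    loh_regions: list[GenomicInterval] | None = None  # default: driver 1 Mb tile
    driver_gene: str = "SMARCB1"
    top_gene: str = "NPM1"
    reference_gene: str = "EZH2"
    de_up_frac: float = Field(default=0.05, ge=0.0)
    de_down_frac: float = Field(default=0.025, ge=0.0)
    lfc_magnitude: float = 2.0
    driver_lfc: float = -3.5
    top_gene_lfc: float = 4.0  # strongest planted effect, above |driver_lfc|
    reference_lfc: float = 2.2
    nb_dispersion: float = Field(default=0.1, ge=0.0)
    libsize_sd: float = Field(default=0.2, ge=0.0)
    n_gene_sets: int = 20
    n_enriched_sets: int = 3
    enriched_de_frac: float = Field(default=0.6, ge=0.0, le=1.0)
    set_size_min: int = 30
    set_size_max: int = 80
    disjoint_sets: bool = False
    exon_noise_sd: float = Field(default=0.1, ge=0.0)
    probe_noise_sd: float = Field(default=0.15, ge=0.0)
    probe_spacing: int = 10_000
    window_bp: int = 1_000_000
    seed: int = 20190828

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        if self.depth_mean <= 0:
            raise ConfigError("depth_mean must be positive")
        if self.n_sites <= 0:
            raise ConfigError("n_sites must be positive")
        if self.n_somatic < 0 or self.n_somatic > self.n_sites:
            raise ConfigError("n_somatic must be in [0, n_sites]")
        if self.n_genes < 10:
            raise ConfigError("n_genes must be at least 10")
        if self.n_gene_sets < 0:
            raise ConfigError("n_gene_sets must be >= 0")
        if self.n_enriched_sets > self.n_gene_sets:
            raise ConfigError("n_enriched_sets cannot exceed n_gene_sets")
        if self.de_up_frac > 0 and self.de_down_frac > 0:
            ratio = self.de_up_frac / self.de_down_frac
            if not 1.5 <= ratio <= 3.0:
                raise ConfigError(
                    f"up:down DE ratio {ratio:.3g} outside the modelled [1.5, 3] range"
                )
        return self


@dataclass
class TruthSet:
    """Ground truth planted by the generator, for truth-recovery tests."""

    somatic_sites: dict = field(default_factory=dict)  # site_id -> true tumor VAF
    germline_sites: list = field(default_factory=list)
    loh_sites: list = field(default_factory=list)
    deleted_genes: dict = field(default_factory=dict)  # gene -> true copy log2
    de_genes: dict = field(default_factory=dict)  # gene -> (direction, true lfc)
    enriched_sets: list = field(default_factory=list)
    top_gene: str = ""
    driver_gene: str = ""
    subgroup_labels: dict = field(default_factory=dict)  # sample -> subgroup
    mechanisms: dict = field(default_factory=dict)  # sample -> mechanism label

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        with open(path) as fh:
            raw = json.load(fh)
        raw["de_genes"] = {g: tuple(v) for g, v in raw.get("de_genes", {}).items()}
        return cls(**raw)


@dataclass(frozen=True)
class DriverLesion:
    """Per-tumor driver lesion: copy state, mutation consequence, LOH."""

    cna: str  # HOM_DEL | HET_DEL | NEUTRAL
    mutation: str | None  # stop_gain | splice | None
    loh: bool

    @property
    def expected_mechanism(self) -> str:
        if self.cna == cna_loh.HOM_DEL:
            return cna_loh.HOMOZYGOUS_DELETION
        if self.cna == cna_loh.HET_DEL and self.mutation:
            return cna_loh.HET_DELETION_PLUS_MUTATION
        if self.cna == cna_loh.NEUTRAL and self.loh and self.mutation:
            return cna_loh.COPY_NEUTRAL_LOH_PLUS_MUTATION
        if self.cna == cna_loh.HET_DEL:
            return cna_loh.HET_DELETION_ONLY
        return cna_loh.NO_BIALLELIC_EVIDENCE

    @property
    def exon_log2(self) -> float:
        return {cna_loh.HOM_DEL: -3.0, cna_loh.HET_DEL: -1.0, cna_loh.NEUTRAL: 0.0}[self.cna]


#: the four-patient lesion spectrum cycled over tumors in a cohort
MECHANISM_PRESETS = (
    DriverLesion(cna_loh.HET_DEL, "stop_gain", True),
    DriverLesion(cna_loh.HOM_DEL, None, False),
    DriverLesion(cna_loh.NEUTRAL, "stop_gain", True),
    DriverLesion(cna_loh.HET_DEL, "splice", True),
)

NO_LESION = DriverLesion(cna_loh.NEUTRAL, None, False)


def _rng(config: SimConfig, stream: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, _STREAMS[stream], extra])
    )


# ---------------------------------------------------------------- gene model


def gene_model(config: SimConfig) -> pd.DataFrame:
    """Deterministic synthetic gene model on one chromosome.

    Genes sit every 30 kb on chr22 with a 10 kb genomic footprint; transcript
    lengths are drawn once from the model stream.  The driver, top, and
    reference genes replace ordinary ids at fixed relative positions.
    """
    rng = _rng(config, "model")
    n = config.n_genes
    names = [f"G{i:04d}" for i in range(n)]
    names[int(0.33 * n)] = config.driver_gene
    names[int(0.10 * n)] = config.top_gene
    names[int(0.20 * n)] = config.reference_gene
    start = 100_001 + 30_000 * np.arange(n)
    lengths = rng.integers(500, 5001, size=n)
    exons = rng.integers(5, 13, size=n)
    return pd.DataFrame(
        {
            "gene": names,
            "chrom": "chr22",
            "start": start,
            "end": start + 9_999,
            "length_bp": lengths,
            "n_exons": exons,
        }
    ).set_index("gene", drop=False)


def genome_length(config: SimConfig) -> int:
    return 200_000 + 30_000 * config.n_genes


def _driver_tile(config: SimConfig, model: pd.DataFrame) -> GenomicInterval:
    start = int(model.at[config.driver_gene, "start"])
    tile = (start - 1) // config.window_bp
    return GenomicInterval(
        chrom="chr22",
        start=tile * config.window_bp + 1,
        end=(tile + 1) * config.window_bp,
    )


def _loh_regions(config: SimConfig, model: pd.DataFrame) -> list[GenomicInterval]:
    if config.loh_regions is not None:
        return config.loh_regions
    return [_driver_tile(config, model)]


def _extra_deleted(config: SimConfig, model: pd.DataFrame) -> dict:
    """Two constitutive non-driver deletions: one het loss, one hom loss."""
    genes = list(model["gene"])
    return {genes[int(0.60 * config.n_genes)]: -1.0, genes[int(0.80 * config.n_genes)]: -3.0}


# ------------------------------------------------------------- paired counts


@dataclass
class _SiteClasses:
    positions: np.ndarray
    is_somatic: np.ndarray
    is_het: np.ndarray
    loh_mask: np.ndarray
    loh_allele: np.ndarray  # 0/1 retained allele for pushed sites


def _classify_sites(config: SimConfig, model: pd.DataFrame) -> _SiteClasses:
    rng = _rng(config, "sites")
    glen = genome_length(config)
    pos: set[int] = set()
    while len(pos) < config.n_sites:
        draw = rng.integers(1, glen + 1, size=config.n_sites - len(pos))
        pos.update(int(p) for p in draw)
    positions = np.array(sorted(pos), dtype=np.int64)

    n = config.n_sites
    is_somatic = np.zeros(n, dtype=bool)
    if config.n_somatic:
        is_somatic[rng.choice(n, size=config.n_somatic, replace=False)] = True
    is_het = ~is_somatic & (rng.random(n) < config.germline_het_rate)

    regions = _loh_regions(config, model)
    in_region = np.zeros(n, dtype=bool)
    for r in regions:
        in_region |= (positions >= r.start) & (positions <= r.end)
    loh_mask = is_het & in_region
    loh_allele = rng.integers(0, 2, size=n)
    return _SiteClasses(positions, is_somatic, is_het, loh_mask, loh_allele)


def _sample_pair(
    config: SimConfig,
    classes: _SiteClasses,
    rng: np.random.Generator,
    lesion: DriverLesion | None,
) -> list[PairedSiteCounts]:
    n = config.n_sites
    d_t = rng.poisson(config.depth_mean, size=n)
    d_n = rng.poisson(config.depth_mean, size=n)

    p_t = np.full(n, config.error_rate)
    p_n = np.full(n, config.error_rate)
    p_t[classes.is_het] = 0.5
    p_n[classes.is_het] = 0.5
    p_t[classes.is_somatic] = config.purity * config.somatic_vaf

    push = classes.loh_mask.copy()
    if lesion is not None and not lesion.loh and lesion.cna != cna_loh.HOM_DEL:
        push[:] = False
    pushed_vaf = (
        config.purity * classes.loh_allele + (1.0 - config.purity) * 0.5
    )
    if lesion is not None and lesion.cna == cna_loh.HOM_DEL:
        # homozygous deletion: tumor reads at the locus come from the
        # contaminating normal fraction -- depth drops, VAF stays ~0.5
        d_t = np.where(
            classes.loh_mask,
            rng.poisson(max(config.depth_mean * (1.0 - config.purity), 1.0), size=n),
            d_t,
        )
        push[:] = False
    p_t = np.where(push, pushed_vaf, p_t)

    a_t = rng.binomial(d_t, np.clip(p_t, 0.0, 1.0))
    a_n = rng.binomial(d_n, np.clip(p_n, 0.0, 1.0))

    sites = []
    for i in range(n):
        sites.append(
            PairedSiteCounts(
                chrom="chr22",
                pos=int(classes.positions[i]),
                ref="A",
                alt="G",
                tumor=AlleleDepth(int(d_t[i] - a_t[i]), int(a_t[i])),
                normal=AlleleDepth(int(d_n[i] - a_n[i]), int(a_n[i])),
            )
        )
    return sites


def _base_truth(config: SimConfig, classes: _SiteClasses) -> TruthSet:
    ids = [f"chr22:{p}:A>G" for p in classes.positions]
    truth = TruthSet(driver_gene=config.driver_gene, top_gene=config.top_gene)
    truth.somatic_sites = {
        ids[i]: config.purity * config.somatic_vaf
        for i in np.flatnonzero(classes.is_somatic)
    }
    truth.germline_sites = [ids[i] for i in np.flatnonzero(classes.is_het)]
    truth.loh_sites = [ids[i] for i in np.flatnonzero(classes.loh_mask)]
    return truth


def gen_paired_counts(config: SimConfig) -> tuple[list[PairedSiteCounts], TruthSet]:
    """One tumor/normal pair of per-site allele depths plus ground truth.

    Germline het sites are binomial at VAF 0.5 in both samples at per-sample
    Poisson depths; somatic sites carry tumor alt reads at purity x
    somatic_vaf and normal alt reads at the error rate; het sites inside
    ``loh_regions`` have the tumor VAF pushed toward 0 or 1.
    """
    model = gene_model(config)
    classes = _classify_sites(config, model)
    sites = _sample_pair(config, classes, _rng(config, "reads", 0), lesion=None)
    return sites, _base_truth(config, classes)


# -------------------------------------------------------------- count matrix


def _plant_de(config: SimConfig) -> dict:
    """Choose planted DE genes: gene -> (direction, true log2FC).

    Quotas n_up/n_down are deterministic rounds of the configured fractions,
    so the planted up:down ratio is exact by construction.  The top gene and
    the reference gene occupy up slots (with their own effect sizes) and the
    driver occupies a down slot.  A zero ``lfc_magnitude`` plants nothing.
    """
    if config.lfc_magnitude == 0:
        return {}
    rng = _rng(config, "de")
    model_genes = list(gene_model(config)["gene"])
    specials_up = [config.top_gene, config.reference_gene]
    specials_down = [config.driver_gene]
    ordinary = [g for g in model_genes if g not in specials_up + specials_down]

    n_up = int(round(config.n_genes * config.de_up_frac))
    n_down = int(round(config.n_genes * config.de_down_frac))
    de: dict = {}
    up_specials = specials_up[:n_up]
    down_specials = specials_down[:n_down]
    n_up_rand = n_up - len(up_specials)
    n_down_rand = n_down - len(down_specials)
    picked = rng.choice(len(ordinary), size=n_up_rand + n_down_rand, replace=False)
    up_rand = [ordinary[i] for i in picked[:n_up_rand]]
    down_rand = [ordinary[i] for i in picked[n_up_rand:]]

    for g in up_rand:
        de[g] = ("UP", config.lfc_magnitude)
    for g in down_rand:
        de[g] = ("DOWN", -config.lfc_magnitude)
    if config.top_gene in up_specials:
        de[config.top_gene] = ("UP", config.top_gene_lfc)
    if config.reference_gene in up_specials:
        de[config.reference_gene] = ("UP", config.reference_lfc)
    if config.driver_gene in down_specials:
        de[config.driver_gene] = ("DOWN", config.driver_lfc)
    return de


def subgroup_signatures(config: SimConfig, genes_per_subgroup: int = 5) -> SubgroupSignature:
    """Deterministic subgroup signature genes drawn from the non-DE pool."""
    rng = _rng(config, "signatures")
    de = _plant_de(config)
    model_genes = list(gene_model(config)["gene"])
    pool = [
        g
        for g in model_genes
        if g not in de
        and g not in (config.driver_gene, config.top_gene, config.reference_gene)
    ]
    picked = rng.choice(len(pool), size=genes_per_subgroup * len(SUBGROUPS), replace=False)
    sigs = {
        sg: [pool[i] for i in picked[j * genes_per_subgroup : (j + 1) * genes_per_subgroup]]
        for j, sg in enumerate(SUBGROUPS)
    }
    return SubgroupSignature(signatures=sigs, reference_gene=config.reference_gene)


def _sample_names(config: SimConfig) -> tuple[list[str], list[str]]:
    tumors = [f"T{i+1}" for i in range(config.n_tumors)]
    controls = [f"C{i+1}" for i in range(config.n_controls)]
    return tumors, controls


def _subgroup_labels(config: SimConfig) -> dict:
    tumors, _ = _sample_names(config)
    return {t: SUBGROUPS[i % len(SUBGROUPS)] for i, t in enumerate(tumors)}


def baseline_means(config: SimConfig) -> pd.Series:
    """Per-gene baseline expression means (control-group scale).

    Ordinary genes are log-normal around ~30; planted DE genes are placed in
    the well-expressed 50-500 range so recovery is threshold-limited rather
    than power-limited; the signature/reference genes share a fixed
    baseline of 100 so subgroup scores compare like with like; the top gene
    sits at 500 so its test statistic dominates the candidate ranking.
    """
    rng = _rng(config, "expr")
    model = gene_model(config)
    base = np.exp(rng.normal(np.log(30.0), 1.2, size=config.n_genes))
    s = pd.Series(base, index=model.index)
    de = _plant_de(config)
    if de:
        de_genes = [g for g in de if g in s.index]
        s.loc[de_genes] = rng.uniform(50.0, 500.0, size=len(de_genes))
    sig = subgroup_signatures(config)
    for genes in sig.signatures.values():
        s.loc[genes] = 100.0
    s.loc[config.reference_gene] = 100.0
    s.loc[config.driver_gene] = 100.0
    s.loc[config.top_gene] = 500.0
    return s


def gen_count_matrix(config: SimConfig) -> tuple[CountMatrix, TruthSet]:
    """NB count matrix for tumors vs controls with planted DE structure.

    Counts are negative binomial with gene baselines, per-sample log-normal
    library-size factors, tumor-group means shifted by the planted log2FC,
    and a per-tumor boost of that tumor's subgroup signature genes.
    """
    if config.n_tumors < 2 or config.n_controls < 2:
        raise ConfigError("need at least 2 tumors and 2 controls")
    model = gene_model(config)
    base = baseline_means(config)
    de = _plant_de(config)
    sig = subgroup_signatures(config)
    labels = _subgroup_labels(config)
    tumors, controls = _sample_names(config)
    samples = tumors + controls

    rng = _rng(config, "counts")
    libsize = np.exp(rng.normal(0.0, config.libsize_sd, size=len(samples)))

    mean = pd.DataFrame(
        np.tile(base.to_numpy()[:, None], (1, len(samples))),
        index=model.index,
        columns=samples,
    )
    for g, (_, lfc) in de.items():
        mean.loc[g, tumors] = base[g] * 2.0**lfc
    for t in tumors:
        mean.loc[sig.signatures[labels[t]], t] *= 4.0
    mean *= libsize[None, :]

    mu = mean.to_numpy()
    alpha = config.nb_dispersion
    if alpha > 0:
        r = 1.0 / alpha
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=model.index, columns=samples),
        gene_lengths=model["length_bp"].astype(float),
        groups=pd.Series(
            ["tumor"] * len(tumors) + ["control"] * len(controls), index=samples
        ),
    )
    truth = TruthSet(
        driver_gene=config.driver_gene,
        top_gene=config.top_gene,
        de_genes=de,
        subgroup_labels=labels,
    )
    return cm, truth


# ----------------------------------------------------------------- gene sets


def gen_gene_sets(config: SimConfig) -> tuple[GeneSetCollection, list, TruthSet]:
    """Gene-set collection, cancer-gene list, and enrichment ground truth.

    The first ``n_enriched_sets`` sets are stuffed with planted DE genes at
    ``enriched_de_frac`` (the first of them slightly more, and it always
    contains the top gene); the rest are uniform draws from the universe.
    With ``disjoint_sets`` every gene appears in at most one set.
    """
    if config.n_gene_sets < 0:
        raise ConfigError("n_gene_sets must be >= 0")
    rng = _rng(config, "sets")
    model_genes = list(gene_model(config)["gene"])
    de = _plant_de(config)
    de_genes = sorted(de)
    non_de = [g for g in model_genes if g not in de]

    available_de = list(de_genes)
    available_non = list(non_de)

    def _draw(pool: list, k: int, consume: bool) -> list:
        k = max(0, min(k, len(pool)))
        idx = rng.choice(len(pool), size=k, replace=False)
        picked = [pool[i] for i in sorted(idx)]
        if consume:
            for g in picked:
                pool.remove(g)
        return picked

    sets: dict = {}
    truth_sets: list = []
    for i in range(config.n_gene_sets):
        name = f"SET{i+1:03d}"
        size = int(rng.integers(config.set_size_min, config.set_size_max + 1))
        if i < config.n_enriched_sets and de_genes:
            frac = min(config.enriched_de_frac + (0.15 if i == 0 else 0.0), 1.0)
            n_de = max(int(round(size * frac)), 1)
            members = set(_draw(available_de if config.disjoint_sets else de_genes, n_de, config.disjoint_sets))
            if i == 0:
                members.add(config.top_gene)
            fill = size - len(members)
            members |= set(_draw(available_non if config.disjoint_sets else non_de, fill, config.disjoint_sets))
            truth_sets.append(name)
        else:
            pool = available_non if config.disjoint_sets else model_genes
            members = set(_draw(pool, size, config.disjoint_sets))
        sets[name] = frozenset(members)

    collection = GeneSetCollection(sets=sets, universe=frozenset(model_genes))

    cancer = {config.top_gene, config.driver_gene}
    cancer |= set(_draw(de_genes, 20, False)) if de_genes else set()
    cancer |= set(_draw(non_de, 20, False))
    truth = TruthSet(
        driver_gene=config.driver_gene,
        top_gene=config.top_gene,
        de_genes=de,
        enriched_sets=truth_sets,
    )
    return collection, sorted(cancer), truth


# ------------------------------------------------------------ exons / probes


def _exon_table(
    config: SimConfig,
    model: pd.DataFrame,
    deleted: dict,
    rng: np.random.Generator,
) -> pd.DataFrame:
    rows = {"gene": [], "exon_index": [], "log2_ratio": []}
    for gene, rec in model.iterrows():
        true = deleted.get(gene, 0.0)
        k = int(rec["n_exons"])
        noise = rng.normal(0.0, config.exon_noise_sd, size=k) if config.exon_noise_sd else np.zeros(k)
        rows["gene"].extend([gene] * k)
        rows["exon_index"].extend(range(k))
        rows["log2_ratio"].extend(true + noise)
    return pd.DataFrame(rows)


def _probe_table(
    config: SimConfig,
    model: pd.DataFrame,
    deleted: dict,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, list]:
    glen = genome_length(config)
    pos = np.arange(config.probe_spacing, glen + 1, config.probe_spacing, dtype=np.int64)
    ratio = (
        rng.normal(0.0, config.probe_noise_sd, size=pos.size)
        if config.probe_noise_sd
        else np.zeros(pos.size)
    )
    tiles = []
    for gene, true in deleted.items():
        start = int(model.at[gene, "start"])
        t = (start - 1) // config.window_bp
        lo = t * config.window_bp + 1
        hi = (t + 1) * config.window_bp
        ratio = np.where((pos >= lo) & (pos <= hi), ratio + true, ratio)
        tiles.append((lo, hi, true))
    return pd.DataFrame({"pos": pos, "log2_ratio": ratio}), tiles


def gen_exon_depth_and_probes(
    config: SimConfig,
    lesion: DriverLesion | None = None,
    tumor_index: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthSet]:
    """Exon depth log2 ratios and an aCGH-like probe track with planted CNAs.

    Planted deletions: the driver gene (heterozygous loss by default, or the
    per-tumor ``lesion``'s copy state) plus one constitutive het-loss gene
    and one hom-loss gene; exon ratios sit at the true copy log2 plus
    Gaussian noise, and the probe track carries the 1 Mb tile of each
    deleted gene at the same ratio.
    """
    model = gene_model(config)
    deleted = dict(_extra_deleted(config, model))
    driver_log2 = lesion.exon_log2 if lesion is not None else -1.0
    if driver_log2 != 0.0:
        deleted[config.driver_gene] = driver_log2

    exons = _exon_table(config, model, deleted, _rng(config, "exons", tumor_index))
    probes, _tiles = _probe_table(config, model, deleted, _rng(config, "probes", tumor_index))
    truth = TruthSet(
        driver_gene=config.driver_gene,
        top_gene=config.top_gene,
        deleted_genes=deleted,
    )
    return exons, probes, truth


# --------------------------------------------------------------- annotations


def gen_annotations(config: SimConfig, truth: TruthSet, all_site_ids=None) -> dict:
    """Per-site consequence + population AF emulating a variant annotator.

    Planted somatic sites are mostly rare non-synonymous changes (a small
    share synonymous or common, to exercise the rarity/consequence filter);
    germline het sites carry common population frequencies; remaining sites
    (reference-homozygous background) are rare non-synonymous so the filter
    never masks a caller false positive.
    """
    rng = _rng(config, "ann")
    ann: dict = {}
    for sid in sorted(truth.somatic_sites):
        u = rng.random()
        if u < 0.8:
            ann[sid] = VariantAnnotation(sid, "nonsynonymous", 0.0)
        elif u < 0.9:
            ann[sid] = VariantAnnotation(sid, "synonymous", 0.0)
        else:
            ann[sid] = VariantAnnotation(sid, "nonsynonymous", float(rng.uniform(0.02, 0.2)))
    for sid in truth.germline_sites:
        cons = "nonsynonymous" if rng.random() < 0.5 else "synonymous"
        ann[sid] = VariantAnnotation(sid, cons, float(rng.uniform(0.02, 0.5)))
    if all_site_ids is not None:
        for sid in all_site_ids:
            if sid not in ann:
                ann[sid] = VariantAnnotation(sid, "nonsynonymous", 0.0)
    return ann


# -------------------------------------------------------------------- cohort


@dataclass
class Cohort:
    """Everything one synthetic study produces, plus its ground truth."""

    config: SimConfig
    model: pd.DataFrame
    truth: TruthSet
    tumor_samples: list
    control_samples: list
    lesions: dict  # sample -> DriverLesion
    paired_counts: dict  # sample -> list[PairedSiteCounts]
    driver_mutation_sites: dict  # sample -> site_id or None
    annotations: dict  # site_id -> VariantAnnotation
    exon_tables: dict  # sample -> DataFrame
    probe_tables: dict  # sample -> DataFrame
    count_matrix: CountMatrix
    gene_sets: GeneSetCollection
    cancer_genes: list
    signatures: SubgroupSignature


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate the full multi-tumor study with per-tumor driver mechanisms.

    Tumor i receives the i-th driver lesion from ``MECHANISM_PRESETS``
    (cycled), so a default 4-tumor cohort reproduces the full mechanism
    spectrum: het deletion + stop, homozygous deletion, copy-neutral LOH +
    stop, and het deletion + splice.
    """
    model = gene_model(config)
    classes = _classify_sites(config, model)
    truth = _base_truth(config, classes)
    tumors, controls = _sample_names(config)

    lesions = {t: MECHANISM_PRESETS[i % len(MECHANISM_PRESETS)] for i, t in enumerate(tumors)}
    truth.mechanisms = {t: lesions[t].expected_mechanism for t in tumors}

    driver_start = int(model.at[config.driver_gene, "start"])
    paired: dict = {}
    mut_sites: dict = {}
    extra_ann: dict = {}
    for i, t in enumerate(tumors):
        rng = _rng(config, "reads", i)
        sites = _sample_pair(config, classes, rng, lesions[t])
        lesion = lesions[t]
        if lesion.mutation is not None:
            taken = set(int(p) for p in classes.positions)
            pos = driver_start + 4_000 + 17 * i
            while pos in taken:
                pos += 1
            d_t = int(rng.poisson(config.depth_mean))
            d_n = int(rng.poisson(config.depth_mean))
            # remaining-allele mutation: effectively homozygous in the tumor
            a_t = int(rng.binomial(d_t, 0.8 * config.purity + 0.1))
            a_n = int(rng.binomial(d_n, config.error_rate))
            ms = PairedSiteCounts(
                "chr22", pos, "C", "T", AlleleDepth(d_t - a_t, a_t), AlleleDepth(d_n - a_n, a_n)
            )
            sites.append(ms)
            sites.sort(key=lambda s: s.pos)
            mut_sites[t] = ms.site_id
            truth.somatic_sites[ms.site_id] = 0.8 * config.purity + 0.1
            extra_ann[ms.site_id] = VariantAnnotation(ms.site_id, lesion.mutation, 0.0)
        else:
            mut_sites[t] = None
        paired[t] = sites

    all_ids = [f"chr22:{p}:A>G" for p in classes.positions]
    annotations = gen_annotations(config, truth, all_site_ids=all_ids)
    annotations.update(extra_ann)

    exon_tables = {}
    probe_tables = {}
    for i, t in enumerate(tumors):
        ex, pr, del_truth = gen_exon_depth_and_probes(config, lesions[t], tumor_index=i)
        exon_tables[t] = ex
        probe_tables[t] = pr
        for g, v in del_truth.deleted_genes.items():
            truth.deleted_genes.setdefault(g, v)

    cm, expr_truth = gen_count_matrix(config)
    truth.de_genes = expr_truth.de_genes
    truth.subgroup_labels = expr_truth.subgroup_labels

    collection, cancer, set_truth = gen_gene_sets(config)
    truth.enriched_sets = set_truth.enriched_sets

    return Cohort(
        config=config,
        model=model,
        truth=truth,
        tumor_samples=tumors,
        control_samples=controls,
        lesions=lesions,
        paired_counts=paired,
        driver_mutation_sites=mut_sites,
        annotations=annotations,
        exon_tables=exon_tables,
        probe_tables=probe_tables,
        count_matrix=cm,
        gene_sets=collection,
        cancer_genes=cancer,
        signatures=subgroup_signatures(config),
    )
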