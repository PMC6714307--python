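"""Somatic SNV selection from paired tumor/normal allele depths.

The caller runs the three-step contrastive protocol used for exome pairs:

1. per-site high-quality read counts for the reference and variant allele in
   both samples (inputs here; upstream read filtering is out of scope),
2. a one-sided permutation test for the hypothesis that the tumor variant
   allele fraction (VAF) exceeds the normal VAF, and
3. joint "volcano" selection on VAF_frac = VAF_T / (VAF_T + VAF_N) and the
   permutation p-value, with a depth-based quality exclusion.

Downstream, calls are restricted to non-synonymous-class variants that are
rare (<1% by default) in a population allele-frequency resource.

The permutation null pools all reads at a site and reassigns them to the two
samples keeping each sample's depth fixed.  Because the VAF difference is
monotone in the number of alt reads landing in the tumor slot, the exact
permutation distribution is the hypergeometric law of that count; sites whose
total depth is at or below ``exact_cap`` are scored by the closed-form tail
and deeper sites by seeded Monte Carlo with add-one smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "AlleleDepth",
    "PairedSiteCounts",
    "SomaticCall",
    "VariantAnnotation",
    "CallerParams",
    "UndefinedVAFError",
    "ConfigurationError",
    "MissingAnnotationError",
    "compute_vaf",
    "vaf_frac",
    "permutation_test",
    "call_somatic",
    "filter_variants",
    "calls_to_frame",
    "volcano_table",
    "NONSYNONYMOUS_CLASSES",
]

# filter flags
LOW_DEPTH = "LOW_DEPTH"
GERMLINE_LIKE = "GERMLINE_LIKE"
FAIL_P = "FAIL_P"
FAIL_FRAC = "FAIL_FRAC"

SOMATIC = "SOMATIC"
REJECTED = "REJECTED"

#: consequence classes retained by the rarity/consequence filter
NONSYNONYMOUS_CLASSES = frozenset({"nonsynonymous", "stop_gain", "splice"})


class UndefinedVAFError(ValueError):
    """VAF requested at zero depth (or VAF_frac at VAF_T = VAF_N = 0)."""


class ConfigurationError(ValueError):
    """Invalid caller parameters."""


class MissingAnnotationError(KeyError):
    """A SOMATIC call has no annotation record for the rarity filter."""


@dataclass(frozen=True)
class AlleleDepth:
    """High-quality read support for the reference and variant allele."""

    ref_count: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count


@dataclass(frozen=True)
class PairedSiteCounts:
    """One candidate variant site with tumor and normal allele depths."""

    chrom: str
    pos: int
    ref: str
    alt: str
    tumor: AlleleDepth
    normal: AlleleDepth

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if self.ref == self.alt:
            raise ValueError("ref and alt allele must differ")

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class VariantAnnotation:
    """Consequence class and population allele frequency for one site."""

    site_id: str
    consequence: str
    pop_af: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pop_af <= 1.0:
            raise ValueError("pop_af must be in [0, 1]")


@dataclass
class SomaticCall:
    """Per-site caller output: VAFs, permutation p, VAF_frac, flags, verdict.

    ``vaf_tumor``/``vaf_normal``/``p_perm``/``vaf_frac`` are NaN where
    undefined (zero depth, or both VAFs zero for ``vaf_frac``); such sites
    always carry an explanatory filter flag.
    """

    site: PairedSiteCounts
    vaf_tumor: float
    vaf_normal: float
    p_perm: float
    vaf_frac: float
    filters: frozenset = field(default_factory=frozenset)
    verdict: str = REJECTED


@dataclass(frozen=True)
class CallerParams:
    """Thresholds for the volcano selection; all configurable, none hidden.

    The p/VAF_frac cut-offs are explicit defaults of this implementation:
    joint selection is described only via a volcano plot in the protocol the
    caller follows, so the numeric values are surfaced here and echoed into
    run manifests rather than hard-coded.
    """

    min_depth: int = 8
    p_max: float = 0.05
    frac_min: float = 0.9
    n_perm: int = 10_000
    seed: int = 0
    exact_cap: int = 1000
    germline_vaf: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 < self.p_max < 1.0:
            raise ConfigurationError("p_max must be in (0, 1)")
        if not 0.5 <= self.frac_min <= 1.0:
            raise ConfigurationError("frac_min must be in [0.5, 1]")
        if self.n_perm < 1:
            raise ConfigurationError("n_perm must be >= 1")
        if self.min_depth < 0:
            raise ConfigurationError("min_depth must be >= 0")


def compute_vaf(d: AlleleDepth) -> float:
    """Variant allele fraction alt/(ref+alt); error at zero depth."""
    if d.depth == 0:
        raise UndefinedVAFError("VAF undefined at zero depth")
    return d.alt_count / d.depth


def vaf_frac(vaf_t: float, vaf_c: float) -> float:
    """VAF_frac = VAF_T / (VAF_T + VAF_C); near 1 for tumor-specific sites."""
    if vaf_t < 0 or vaf_c < 0:
        raise ValueError("VAFs must be non-negative")
    total = vaf_t + vaf_c
    if total <= 0:
        raise UndefinedVAFError("VAF_frac undefined when both VAFs are zero")
    return vaf_t / total


def _exact_tail(t_depth: int, t_alt: int, n_depth: int, n_alt: int) -> float:
    # Pooled-read reassignment: X = alt reads landing in the tumor slot is
    # Hypergeometric(N=total depth, K=total alt, n=tumor depth), and the
    # permuted VAF difference is monotone increasing in X, so
    # P(diff >= observed) = P(X >= t_alt).
    total = t_depth + n_depth
    k_alt = t_alt + n_alt
    return float(hypergeom.sf(t_alt - 1, total, k_alt, t_depth))


def _mc_tail(
    t_depth: int,
    t_alt: int,
    n_depth: int,
    n_alt: int,
    n_perm: int,
    rng: np.random.Generator,
) -> float:
    total_alt = t_alt + n_alt
    x = rng.hypergeometric(total_alt, t_depth + n_depth - total_alt, t_depth, size=n_perm)
    diffs = x / t_depth - (total_alt - x) / n_depth
    obs = t_alt / t_depth - n_alt / n_depth
    # ties count as >= observed (conservative); identical X gives bitwise
    # identical floats so no epsilon is needed
    k = int(np.count_nonzero(diffs >= obs))
    return (1 + k) / (1 + n_perm)


def _site_rng(seed: int, t_depth: int, t_alt: int, n_depth: int, n_alt: int) -> np.random.Generator:
    # seed derived from site content, not input position, so that the caller
    # is equivariant under reordering of its input
    ss = np.random.SeedSequence([seed, t_depth, t_alt, n_depth, n_alt])
    return np.random.default_rng(ss)


def permutation_test(
    site: PairedSiteCounts,
    n_perm: int = 10_000,
    seed: int = 0,
    method: str = "auto",
    exact_cap: int = 1000,
) -> float:
    """One-sided permutation p-value for VAF_tumor > VAF_normal.

    ``method`` is ``"auto"`` (exact closed form when total depth <=
    ``exact_cap``, Monte Carlo otherwise), ``"exact"``, or ``"mc"``.  Monte
    Carlo uses add-one smoothing, p = (1 + #{permuted diff >= observed}) /
    (1 + n_perm), so p is never zero.
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    td, ta = site.tumor.depth, site.tumor.alt_count
    nd, na = site.normal.depth, site.normal.alt_count
    if td == 0 or nd == 0:
        raise UndefinedVAFError(f"zero depth at {site.site_id}")
    if method not in ("auto", "exact", "mc"):
        raise ConfigurationError(f"unknown method {method!r}")
    if method == "exact" or (method == "auto" and td + nd <= exact_cap):
        return _exact_tail(td, ta, nd, na)
    return _mc_tail(td, ta, nd, na, n_perm, _site_rng(seed, td, ta, nd, na))


def call_somatic(
    sites: list[PairedSiteCounts],
    params: CallerParams = CallerParams(),
) -> list[SomaticCall]:
    """Score and filter every site; verdict SOMATIC iff no filter fires.

    Filters: LOW_DEPTH (either sample below ``min_depth``), GERMLINE_LIKE
    (normal VAF at or above ``germline_vaf``), FAIL_P (permutation p >=
    ``p_max`` or undefined), FAIL_FRAC (VAF_frac < ``frac_min`` or
    undefined).  Output order preserves input order.
    """
    if not sites:
        return []

    td = np.array([s.tumor.depth for s in sites], dtype=np.int64)
    ta = np.array([s.tumor.alt_count for s in sites], dtype=np.int64)
    nd = np.array([s.normal.depth for s in sites], dtype=np.int64)
    na = np.array([s.normal.alt_count for s in sites], dtype=np.int64)

    n = len(sites)
    vaf_t = np.full(n, np.nan)
    vaf_n = np.full(n, np.nan)
    pvals = np.full(n, np.nan)
    fracs = np.full(n, np.nan)

    ok = (td > 0) & (nd > 0)
    vaf_t[td > 0] = ta[td > 0] / td[td > 0]
    vaf_n[nd > 0] = na[nd > 0] / nd[nd > 0]

    exact = ok & (td + nd <= params.exact_cap)
    if np.any(exact):
        pvals[exact] = hypergeom.sf(
            ta[exact] - 1, td[exact] + nd[exact], ta[exact] + na[exact], td[exact]
        )
    for i in np.flatnonzero(ok & ~exact):
        rng = _site_rng(params.seed, int(td[i]), int(ta[i]), int(nd[i]), int(na[i]))
        pvals[i] = _mc_tail(int(td[i]), int(ta[i]), int(nd[i]), int(na[i]), params.n_perm, rng)

    total_vaf = vaf_t + vaf_n
    defined = ok & (total_vaf > 0)
    fracs[defined] = vaf_t[defined] / total_vaf[defined]

    calls: list[SomaticCall] = []
    for i, s in enumerate(sites):
        flags: set[str] = set()
        if td[i] < params.min_depth or nd[i] < params.min_depth:
            flags.add(LOW_DEPTH)
        if not np.isnan(vaf_n[i]) and vaf_n[i] >= params.germline_vaf:
            flags.add(GERMLINE_LIKE)
        if np.isnan(pvals[i]) or pvals[i] >= params.p_max:
            flags.add(FAIL_P)
        if np.isnan(fracs[i]) or fracs[i] < params.frac_min:
            flags.add(FAIL_FRAC)
        calls.append(
            SomaticCall(
                site=s,
                vaf_tumor=float(vaf_t[i]),
                vaf_normal=float(vaf_n[i]),
                p_perm=float(pvals[i]),
                vaf_frac=float(fracs[i]),
                filters=frozenset(flags),
                verdict=SOMATIC if not flags else REJECTED,
            )
        )
    return calls


def filter_variants(
    calls: list[SomaticCall],
    annotations,
    af_max: float = 0.01,
) -> list[SomaticCall]:
    """Keep SOMATIC calls that are non-synonymous-class and population-rare.

    ``annotations`` is a mapping site_id -> VariantAnnotation or an iterable
    of VariantAnnotation.  A SOMATIC call without an annotation record is a
    hard error naming the offending sites.
    """
    if not isinstance(annotations, dict):
        annotations = {a.site_id: a for a in annotations}
    somatic = [c for c in calls if c.verdict == SOMATIC]
    missing = [c.site.site_id for c in somatic if c.site.site_id not in annotations]
    if missing:
        raise MissingAnnotationError(
            f"no annotation for SOMATIC site(s): {', '.join(missing)}"
        )
    kept = []
    for c in somatic:
        ann = annotations[c.site.site_id]
        if ann.consequence in NONSYNONYMOUS_CLASSES and ann.pop_af < af_max:
            kept.append(c)
    return kept


def calls_to_frame(calls: list[SomaticCall]) -> pd.DataFrame:
    """Tabular view of calls (one row per site, input order)."""
    return pd.DataFrame(
        {
            "chrom": [c.site.chrom for c in calls],
            "pos": [c.site.pos for c in calls],
            "ref": [c.site.ref for c in calls],
            "alt": [c.site.alt for c in calls],
            "t_ref": [c.site.tumor.ref_count for c in calls],
            "t_alt": [c.site.tumor.alt_count for c in calls],
            "n_ref": [c.site.normal.ref_count for c in calls],
            "n_alt": [c.site.normal.alt_count for c in calls],
            "vaf_t": [c.vaf_tumor for c in calls],
            "vaf_n": [c.vaf_normal for c in calls],
            "p_perm": [c.p_perm for c in calls],
            "vaf_frac": [c.vaf_frac for c in calls],
            "filters": [";".join(sorted(c.filters)) or "PASS" for c in calls],
            "verdict": [c.verdict for c in calls],
        }
    )


def volcano_table(calls: list[SomaticCall]) -> pd.DataFrame:
    """(VAF_frac, -log10 p) pairs for the volcano selection plot."""
    frac = np.array([c.vaf_frac for c in calls])
    p = np.array([c.p_perm for c in calls])
    neg = -np.log10(np.clip(p, 1e-300, None))
    return pd.DataFrame({"vaf_frac": frac, "neg_log10_p": neg})
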