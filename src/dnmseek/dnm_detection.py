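"""De novo mutation detection from trio genotype evidence.

A candidate DNM is an alt allele carried by the proband and absent from both
parental genotypes.  Candidates are then screened by four read-level
criteria (depth, genotype quality, proband alt fraction, parental alt
fraction), ranked 1-5 for confidence from genotype quality and strand bias,
flagged for likely post-zygotic (mosaic) origin from a depressed alt read
fraction, classified by protein consequence, and filtered to rare variants
against population frequency databases.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy import stats

from .variant_io import TrioSite, VariantRecord

log = logging.getLogger(__name__)

# consequence classes
LOF = "LOF"
MISSENSE = "missense"
INFRAME = "inframe_indel"
SYNONYMOUS = "synonymous"
OTHER = "other"
CONSEQUENCE_CLASSES = (LOF, MISSENSE, INFRAME, SYNONYMOUS, OTHER)

# filter criterion labels
F_DEPTH = "min_depth"
F_GQ = "min_gq"
F_PROBAND_FRAC = "proband_alt_fraction"
F_PARENT_FRAC = "parent_alt_fraction"


@dataclass(frozen=True)
class DnmFilterConfig:
    """Thresholds of the four candidate-DNM criteria plus the rare filter.

    All boundaries are inclusive: a site exactly at a printed threshold
    (depth 5, GQ 10, 10% alt fraction) passes.
    """

    min_depth: int = 5
    min_gq: float = 10.0
    min_proband_alt_fraction: float = 0.10
    max_parent_alt_fraction: float = 0.10
    maf_threshold: float = 0.01

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        for name in ("min_proband_alt_fraction", "max_parent_alt_fraction",
                     "maf_threshold"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0,1], got {v}")


@dataclass(frozen=True)
class DnmCall:
    """A candidate DNM with its screening verdicts."""

    site: TrioSite
    consequence_class: str | None = None
    confidence_rank: int | None = None  # 1 best .. 5 worst; passing calls only
    mosaic_flag: bool = False
    passed_filters: bool = False
    filter_failures: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.passed_filters != (len(self.filter_failures) == 0):
            raise ValueError("passed_filters must mirror an empty failure set")


def candidate_dnms(sites: Iterable[TrioSite]) -> Iterator[TrioSite]:
    """Yield sites whose genotype configuration is de novo.

    Retained iff the proband genotype contains the alt allele and both
    parents are called homozygous reference.  A missing parental genotype
    cannot certify absence, so such sites are excluded.
    """
    for site in sites:
        if is_denovo_configuration(site.proband.genotype,
                                   site.father.genotype,
                                   site.mother.genotype):
            yield site


def is_denovo_configuration(proband: tuple[int, int] | None,
                            father: tuple[int, int] | None,
                            mother: tuple[int, int] | None) -> bool:
    """The de novo genotype rule on one (proband, father, mother) triple."""
    return (proband is not None and 1 in proband
            and father == (0, 0) and mother == (0, 0))


def apply_dnm_filters(candidate: TrioSite,
                      cfg: DnmFilterConfig = DnmFilterConfig()) -> DnmCall:
    """Evaluate the four read-level criteria on one candidate.

    Every criterion is evaluated independently so the report can show all
    failures at once:

    1. depth >= min_depth in the proband and both parents;
    2. genotype quality >= min_gq in all three (missing GQ fails: absence
       of a quality score cannot certify a minimum);
    3. proband alt read fraction >= min_proband_alt_fraction;
    4. each parent's alt read fraction <= max_parent_alt_fraction (a parent
       with zero depth passes this criterion only vacuously, with zero alt
       reads, and in any case fails criterion 1).
    """
    failures: set[str] = set()
    members = (candidate.proband, candidate.father, candidate.mother)

    if any(m.depth < cfg.min_depth for m in members):
        failures.add(F_DEPTH)
    if any(m.gq is None or m.gq < cfg.min_gq for m in members):
        failures.add(F_GQ)

    pf = candidate.proband.alt_fraction
    if pf is None or pf < cfg.min_proband_alt_fraction:
        failures.add(F_PROBAND_FRAC)

    for parent in (candidate.father, candidate.mother):
        frac = parent.alt_fraction
        if frac is None:
            if parent.alt_depth > 0:  # unreachable under the depth invariant
                failures.add(F_PARENT_FRAC)
        elif frac > cfg.max_parent_alt_fraction:
            failures.add(F_PARENT_FRAC)

    return DnmCall(site=candidate, passed_filters=not failures,
                   filter_failures=frozenset(failures))


def strand_bias_phred(strand_counts: tuple[int, int, int, int] | None) -> float | None:
    """Phred-scaled two-tailed exact test on the 2x2 strand table.

    Rows are (ref, alt), columns (forward, reverse).  Returns None when
    strand counts are unavailable.  Larger values mean stronger bias.
    """
    if strand_counts is None:
        return None
    rf, rr, af, ar = strand_counts
    p = stats.fisher_exact([[rf, rr], [af, ar]], alternative="two-sided")[1]
    p = max(p, 1e-300)
    return -10.0 * math.log10(p)


@dataclass
class RankCutoffs:
    """Cutoffs of the deterministic two-axis confidence grid.

    The quality axis grades the proband call (GQ and alt fraction); the
    strand axis grades the phred-scaled strand-bias exact test.  Each axis is
    good / intermediate / poor; the grid maps the pair to ranks 1-5 with a
    worst strand axis forcing rank >= 4.
    """

    gq_good: float = 50.0
    gq_mid: float = 20.0
    frac_good_low: float = 0.30
    frac_good_high: float = 0.70
    sb_good: float = 10.0  # phred; weaker bias than this is unremarkable
    sb_mid: float = 30.0


_RANK_GRID = {  # (quality_axis, strand_axis) -> rank
    (0, 0): 1, (0, 1): 2, (0, 2): 4,
    (1, 0): 2, (1, 1): 3, (1, 2): 5,
    (2, 0): 3, (2, 1): 4, (2, 2): 5,
}


class RankModel:
    """Logistic re-evaluation model for low-confidence candidates.

    Trained from candidates with orthogonal validation outcomes (the
    confirmation labels play the role of Sanger results).  Features per call:
    strand-bias phred score, proband GQ, and proband alt fraction; the GQ
    doubles as the base-calling-quality proxy.  Produces a probability that
    the candidate is a true DNM.
    """

    FEATURES = ("strand_bias_phred", "proband_gq", "proband_alt_fraction")

    def __init__(self, coef: Sequence[float], intercept: float):
        self.coef = np.asarray(coef, dtype=float)
        if self.coef.shape != (len(self.FEATURES),):
            raise ValueError(f"expected {len(self.FEATURES)} coefficients")
        self.intercept = float(intercept)

    @staticmethod
    def featurize(call: DnmCall) -> np.ndarray:
        sb = strand_bias_phred(call.site.proband.strand_counts)
        gq = call.site.proband.gq
        frac = call.site.proband.alt_fraction
        return np.array([0.0 if sb is None else sb,
                         0.0 if gq is None else gq,
                         0.0 if frac is None else frac])

    def predict_proba(self, call: DnmCall) -> float:
        eta = float(self.coef @ self.featurize(call)) + self.intercept
        return 1.0 / (1.0 + math.exp(-eta))

    @classmethod
    def train(cls, calls: Sequence[DnmCall], labels: Sequence[bool]) -> "RankModel":
        """Fit by logistic regression on validation outcomes."""
        from sklearn.linear_model import LogisticRegression

        X = np.vstack([cls.featurize(c) for c in calls])
        y = np.asarray(labels, dtype=int)
        fit = LogisticRegression(max_iter=1000).fit(X, y)
        return cls(coef=fit.coef_[0], intercept=float(fit.intercept_[0]))


def assign_confidence_rank(call: DnmCall,
                           model: RankModel | None = None,
                           cutoffs: RankCutoffs = RankCutoffs()) -> DnmCall:
    """Rank a passing call 1 (best) to 5 (worst) on the two-axis grid.

    Missing strand counts leave the strand axis neutral (intermediate).  An
    implausible homozygous-alt proband genotype (both alleles de novo)
    demotes the quality axis to poor.  When a trained model is supplied,
    ranks 3-5 are re-evaluated: predicted probability >= 0.5 promotes the
    call to rank 2 (the validation-worthy tier).
    """
    if not call.passed_filters:
        raise ValueError("confidence ranks are defined only for passing calls")

    gq = call.site.proband.gq or 0.0
    frac = call.site.proband.alt_fraction or 0.0
    if call.site.proband.is_hom_alt:
        quality = 2  # two simultaneous de novo alleles: implausible
    elif gq >= cutoffs.gq_good and cutoffs.frac_good_low <= frac <= cutoffs.frac_good_high:
        quality = 0
    elif gq >= cutoffs.gq_mid:
        quality = 1
    else:
        quality = 2

    sb = strand_bias_phred(call.site.proband.strand_counts)
    if sb is None:
        strand = 1
    elif sb <= cutoffs.sb_good:
        strand = 0
    elif sb <= cutoffs.sb_mid:
        strand = 1
    else:
        strand = 2

    rank = _RANK_GRID[(quality, strand)]
    if model is not None and rank >= 3 and model.predict_proba(call) >= 0.5:
        rank = 2
    return replace(call, confidence_rank=rank)


DEFAULT_MOSAIC_BAND = (0.10, 0.30)


def flag_mosaic(call: DnmCall,
                band: tuple[float, float] = DEFAULT_MOSAIC_BAND) -> DnmCall:
    """Flag likely post-zygotic origin from a depressed alt fraction.

    A germline heterozygous DNM is expected near 50% alt reads; a mutation
    arising after fertilization is carried by a subset of cells and shows a
    lower fraction.  The flag is set iff the proband alt fraction lies in the
    half-open band [low, high).
    """
    frac = call.site.proband.alt_fraction
    flagged = frac is not None and band[0] <= frac < band[1]
    return replace(call, mosaic_flag=flagged)


def classify_consequence(variant: VariantRecord) -> str:
    """Map a raw annotation string to a consequence class.

    Nonsense/stop-gain SNVs, frameshift indels and canonical splice-site
    changes (exon +/- 2 bp) are loss-of-function; nonsynonymous SNVs are
    missense; length-preserving coding indels are in-frame; synonymous SNVs
    are synonymous; anything unrecognized falls to "other" with a warning.
    """
    raw = (variant.consequence_raw or "").strip().lower()
    if not raw:
        return OTHER
    compact = raw.replace("-", "").replace("_", "").replace(" ", "")

    if "nonframeshift" in compact or "inframe" in compact:
        return INFRAME
    if ("stopgain" in compact or "nonsense" in compact
            or "frameshift" in compact or "splic" in compact):
        return LOF
    if "nonsynonymous" in compact or "missense" in compact:
        return MISSENSE
    if "synonymous" in compact:
        return SYNONYMOUS
    log.warning("unrecognized consequence annotation %r at %s:%d; classified other",
                variant.consequence_raw, variant.chrom, variant.pos)
    return OTHER


def lof_subtype(variant: VariantRecord) -> str | None:
    """Subdivide a LOF annotation into nonsense / frameshift / splicing."""
    raw = (variant.consequence_raw or "").lower().replace("-", "").replace("_", "")
    if "nonframeshift" in raw:
        return None
    if "stopgain" in raw or "nonsense" in raw:
        return "nonsense"
    if "frameshift" in raw:
        return "frameshift"
    if "splic" in raw:
        return "splicing"
    return None


def filter_rare(variant: VariantRecord, maf_threshold: float = 0.01) -> bool:
    """True iff the variant is rare in every population database.

    Excluded (False) iff any database reports an allele frequency above the
    threshold; databases with no entry count as rare — absence of frequency
    data is the expected signature of a genuinely novel variant.
    """
    return not any(af > maf_threshold for af in variant.pop_afs.values())


def detect_dnms(sites: Iterable[TrioSite],
                cfg: DnmFilterConfig = DnmFilterConfig(),
                model: RankModel | None = None,
                mosaic_band: tuple[float, float] = DEFAULT_MOSAIC_BAND,
                keep_failed: bool = False) -> list[DnmCall]:
    """Full detection pass: candidates, filters, rank, mosaic, class, rarity.

    Returns passing, rare calls with all verdicts populated; with
    ``keep_failed`` the filter-failing candidates are also returned (ranked
    None) for reporting.
    """
    out: list[DnmCall] = []
    for site in candidate_dnms(sites):
        if not filter_rare(site.variant, cfg.maf_threshold):
            continue
        call = apply_dnm_filters(site, cfg)
        if call.passed_filters:
            call = assign_confidence_rank(call, model=model)
            call = flag_mosaic(call, band=mosaic_band)
            call = replace(call, consequence_class=classify_consequence(site.variant))
            out.append(call)
        elif keep_failed:
            call = replace(call, consequence_class=classify_consequence(site.variant))
            out.append(call)
    return out
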