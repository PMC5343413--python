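"""Seeded generators for every input the pipeline consumes.

Three generators, each deterministic given (config, seed):

* ``simulate_trio_cohort`` — exome trio cohorts with Mendelian-consistent
  inherited variation at population allele frequencies, de novo mutations
  planted at a Poisson per-proband rate (a configurable share post-zygotic
  with depressed alt fraction), negative-binomial sequencing depth,
  binomial allele-sampling noise, and genotype qualities from a simple
  genotype-likelihood model.
* ``simulate_case_control`` — per-study rare-variant dosage matrices with
  configurable per-gene case enrichment for burden testing.
* ``simulate_probe_track`` — SNP-array probe tracks with Gaussian LRR noise
  and planted loss/gain/ROH segments.

The exome is abstracted as (gene, site) slots with synthetic gene symbols;
no genomic sequence is involved.  Each generator returns in-memory objects
plus a truth table, and has a writer producing the standard on-disk formats
(VCF + PED, dosage TSV, probe TSV).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cnv_rules import ProbeTrack
from .burden_meta import GenotypeMatrix
from .variant_io import (GenotypeObservation, Pedigree, TrioSite,
                         VariantRecord)

BASE_ERROR = 0.005  # per-read miscall probability of the likelihood model
_GQ_CAP = 99.0

# de novo consequence spectrum: most coding DNMs are missense, a quarter
# synonymous, a minority truncating; in-frame indels are rare
DNM_CLASS_SPECTRUM = {
    "nonsynonymous SNV": 0.55,
    "synonymous SNV": 0.25,
    "stopgain": 0.06,
    "frameshift deletion": 0.07,
    "splicing": 0.02,
    "nonframeshift deletion": 0.05,
}


@dataclass
class TrioSimConfig:
    """Study conditions of the simulated exome trio cohort.

    Defaults mirror the cohort the pipeline targets: 24 trios, ~1.2 DNMs per
    proband per generation, mean on-target depth 46x with a per-sample
    spread reaching roughly 18-74x (negative-binomial dispersion 8), and
    6.5% of DNMs post-zygotic with alt fraction in [0.08, 0.30].
    """

    n_trios: int = 24
    dnm_rate: float = 1.2
    n_inherited_sites: int = 2000
    maf_beta_a: float = 0.2
    maf_beta_b: float = 2.0
    maf_min: float = 1e-4
    maf_max: float = 0.5
    mean_depth: int = 46
    depth_dispersion: float = 8.0  # NB size parameter; larger = tighter
    mosaic_probability: float = 0.065
    mosaic_fraction_range: tuple[float, float] = (0.08, 0.30)
    genotyping_error: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dnm_rate", "mosaic_probability", "genotyping_error"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.mosaic_probability > 1 or self.genotyping_error > 1:
            raise ValueError("probabilities must lie in [0,1]")
        if self.mean_depth < 1:
            raise ValueError("mean_depth must be >= 1")


def _nb_depth(rng: np.random.Generator, mean: float, dispersion: float,
              size) -> np.ndarray:
    """Negative-binomial depths parameterized by mean and size (dispersion)."""
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def _genotype_loglik(alt_reads: int, depth: int) -> tuple[float, float, float]:
    """Log-likelihoods of (hom-ref, het, hom-alt) under a binomial read model."""
    if depth == 0:
        return (0.0, 0.0, 0.0)
    k, n = alt_reads, depth
    def ll(f: float) -> float:
        return k * math.log(f) + (n - k) * math.log1p(-f)
    return (ll(BASE_ERROR), ll(0.5), ll(1.0 - BASE_ERROR))


def _gq_for(genotype: tuple[int, int], alt_reads: int, depth: int) -> float:
    """Phred-scaled support for the emitted genotype.

    Ratio of the emitted genotype's likelihood to the best competing one,
    clamped to [0, 99].  Genotypes whose read support favors a competitor
    (e.g. a low-fraction mosaic het) receive GQ 0 and fail the quality
    filter downstream, which is the intended behaviour.
    """
    lls = _genotype_loglik(alt_reads, depth)
    i = sum(genotype)  # 0 hom-ref, 1 het, 2 hom-alt
    best_other = max(ll for j, ll in enumerate(lls) if j != i)
    gq = 10.0 / math.log(10.0) * (lls[i] - best_other)
    return float(min(max(gq, 0.0), _GQ_CAP))


_TRUE_FRACTION = {0: BASE_ERROR, 1: 0.5, 2: 1.0 - BASE_ERROR}


@dataclass
class TrioCohortSim:
    """In-memory result of ``simulate_trio_cohort``."""

    config: TrioSimConfig
    pedigrees: list[Pedigree]
    sites: dict[str, list[TrioSite]]  # trio id -> sites
    truth: pd.DataFrame  # one row per planted DNM
    annotation: pd.DataFrame  # per variant: gene, consequence, pop AF

    def all_sites(self) -> list[TrioSite]:
        return [s for trio in self.pedigrees for s in self.sites[trio.family_id]]


def _draw_mafs(rng: np.random.Generator, cfg: TrioSimConfig, n: int) -> np.ndarray:
    maf = rng.beta(cfg.maf_beta_a, cfg.maf_beta_b, size=n)
    return np.clip(maf, cfg.maf_min, cfg.maf_max)


def _observe(rng: np.random.Generator, genotype: tuple[int, int] | None,
             true_fraction: float, cfg: TrioSimConfig) -> GenotypeObservation:
    """Sequence one sample at one site: depth, reads, GQ, strand counts."""
    depth = int(_nb_depth(rng, cfg.mean_depth, cfg.depth_dispersion, None))
    alt = int(rng.binomial(depth, true_fraction)) if depth > 0 else 0
    gq = _gq_for(genotype, alt, depth) if genotype is not None else None
    alt_fwd = int(rng.binomial(alt, 0.5)) if alt else 0
    ref = depth - alt
    ref_fwd = int(rng.binomial(ref, 0.5)) if ref else 0
    return GenotypeObservation(
        genotype=genotype, depth=depth, alt_depth=alt, gq=gq,
        strand_counts=(ref_fwd, ref - ref_fwd, alt_fwd, alt - alt_fwd),
    )


def _maybe_err(rng: np.random.Generator, genotype: tuple[int, int],
               rate: float) -> tuple[int, int]:
    """Inject a genotyping error: replace with a random different genotype."""
    if rate <= 0 or rng.random() >= rate:
        return genotype
    pool = [(0, 0), (0, 1), (1, 1)]
    pool.remove(tuple(sorted(genotype)))
    return pool[rng.integers(len(pool))]

def _transmit(rng: np.random.Generator, parent: tuple[int, int]) -> int:
    return int(parent[rng.integers(2)])


def simulate_trio_cohort(cfg: TrioSimConfig = TrioSimConfig()) -> TrioCohortSim:
    """Generate a trio cohort under the configured study conditions.

    Inherited sites: population MAF drawn per site, parental genotypes at
    Hardy-Weinberg, child by Mendelian transmission; sites where nobody in
    a trio carries the alt allele are not emitted for that trio.  DNMs:
    count per proband ~ Poisson(dnm_rate), planted child-het /
    parents-hom-ref at fresh positions, post-zygotic with probability
    ``mosaic_probability`` (alt fraction uniform in the mosaic range,
    0.5 otherwise).  Optional genotyping errors replace emitted genotypes
    at the configured per-genotype rate (depths are re-sampled under the
    erroneous genotype so the record remains internally consistent).
    """
    rng = np.random.default_rng(cfg.seed)
    n_sites = cfg.n_inherited_sites
    mafs = _draw_mafs(rng, cfg, n_sites)
    genes = [f"GENE{i // 10 + 1:04d}" for i in range(n_sites)]  # 10 sites/gene
    csq_names = list(DNM_CLASS_SPECTRUM)
    csq_p = np.array(list(DNM_CLASS_SPECTRUM.values()))
    site_csq = [csq_names[i] for i in rng.choice(len(csq_names), size=n_sites, p=csq_p)]
    positions = np.arange(1, n_sites + 1) * 1000  # inherited site slots
    variants = [
        VariantRecord(chrom="1", pos=int(positions[i]), ref="A", alt="G",
                      gene=genes[i], consequence_raw=site_csq[i],
                      pop_afs={"popdb": float(mafs[i])})
        for i in range(n_sites)
    ]

    pedigrees = [
        Pedigree(family_id=f"TRIO{t + 1:02d}", proband_id=f"TRIO{t + 1:02d}_C",
                 father_id=f"TRIO{t + 1:02d}_F", mother_id=f"TRIO{t + 1:02d}_M",
                 proband_sex="female" if t % 2 == 0 else "male",
                 phenotype="2")
        for t in range(cfg.n_trios)
    ]

    sites: dict[str, list[TrioSite]] = {p.family_id: [] for p in pedigrees}
    truth_rows = []
    dnm_pos = n_sites * 1000 + 10_000  # DNM slots beyond inherited slots

    for ped in pedigrees:
        # inherited variation
        father_gt = rng.binomial(1, mafs, size=(2, n_sites))
        mother_gt = rng.binomial(1, mafs, size=(2, n_sites))
        carried = (father_gt.sum(axis=0) + mother_gt.sum(axis=0)) > 0
        for i in np.flatnonzero(carried):
            f = (int(father_gt[0, i]), int(father_gt[1, i]))
            m = (int(mother_gt[0, i]), int(mother_gt[1, i]))
            c = (_transmit(rng, f), _transmit(rng, m))
            if f == (0, 0) and m == (0, 0) and 1 not in c:
                continue
            trio_gts = []
            for gt in (c, f, m):
                gt = tuple(sorted(gt))
                gt = _maybe_err(rng, gt, cfg.genotyping_error)
                trio_gts.append(gt)
            if all(gt == (0, 0) for gt in trio_gts):
                continue
            obs = [_observe(rng, gt, _TRUE_FRACTION[sum(gt)], cfg)
                   for gt in trio_gts]
            sites[ped.family_id].append(TrioSite(
                variant=variants[i], proband=obs[0], father=obs[1],
                mother=obs[2], trio_id=ped.family_id))

        # de novo mutations
        n_dnm = rng.poisson(cfg.dnm_rate)
        for _ in range(n_dnm):
            dnm_pos += 1000
            mosaic = bool(rng.random() < cfg.mosaic_probability)
            frac = (float(rng.uniform(*cfg.mosaic_fraction_range))
                    if mosaic else 0.5)
            csq = csq_names[rng.choice(len(csq_names), p=csq_p)]
            gene = f"DNMG{dnm_pos // 1000:05d}"
            variant = VariantRecord(chrom="1", pos=dnm_pos, ref="C", alt="T",
                                    gene=gene, consequence_raw=csq, pop_afs={})
            child = _observe(rng, (0, 1), frac, cfg)
            fa = _observe(rng, (0, 0), BASE_ERROR, cfg)
            mo = _observe(rng, (0, 0), BASE_ERROR, cfg)
            sites[ped.family_id].append(TrioSite(
                variant=variant, proband=child, father=fa, mother=mo,
                trio_id=ped.family_id))
            truth_rows.append({
                "trio": ped.family_id, "chrom": "1", "pos": dnm_pos,
                "ref": "C", "alt": "T", "gene": gene, "consequence_raw": csq,
                "mosaic": mosaic, "true_alt_fraction": frac,
            })

    truth = pd.DataFrame(
        truth_rows, columns=["trio", "chrom", "pos", "ref", "alt", "gene",
                             "consequence_raw", "mosaic", "true_alt_fraction"])
    annotation = pd.DataFrame({
        "chrom": [v.chrom for v in variants], "pos": [v.pos for v in variants],
        "ref": [v.ref for v in variants], "alt": [v.alt for v in variants],
        "gene": genes, "consequence": site_csq, "af_popdb": mafs,
    })
    return TrioCohortSim(config=cfg, pedigrees=pedigrees, sites=sites,
                         truth=truth, annotation=annotation)


def write_trio_cohort(sim: TrioCohortSim, outdir: str | Path) -> dict[str, Path]:
    """Write per-trio VCFs, the cohort PED, and the DNM truth table.

    VCFs are uncompressed v4.2 text with GT:DP:AD:GQ genotype columns and
    GENE/CSQ/POPAF INFO annotation.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    ped_path = outdir / "cohort.ped"
    with open(ped_path, "w") as fh:
        for p in sim.pedigrees:
            sex = {"male": "1", "female": "2"}.get(p.proband_sex, "0")
            fh.write(f"{p.family_id} {p.father_id} 0 0 1 1\n")
            fh.write(f"{p.family_id} {p.mother_id} 0 0 2 1\n")
            fh.write(f"{p.family_id} {p.proband_id} {p.father_id} "
                     f"{p.mother_id} {sex} {p.phenotype or '2'}\n")
    paths["ped"] = ped_path

    for ped in sim.pedigrees:
        vcf_path = outdir / f"{ped.family_id}.vcf"
        with open(vcf_path, "w") as fh:
            fh.write(_vcf_header(ped))
            for site in sorted(sim.sites[ped.family_id],
                               key=lambda s: s.variant.pos):
                fh.write(_vcf_line(site, ped))
        paths[ped.family_id] = vcf_path

    truth_path = outdir / "dnm_truth.tsv"
    sim.truth.to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    ann_path = outdir / "annotation.tsv"
    sim.annotation.to_csv(ann_path, sep="\t", index=False)
    paths["annotation"] = ann_path
    return paths


def _vcf_header(ped: Pedigree) -> str:
    cols = "\t".join(ped.sample_ids)
    return (
        "##fileformat=VCFv4.2\n"
        "##source=dnmseek-simulator\n"
        "##contig=<ID=1>\n"
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n'
        '##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence annotation">\n'
        '##INFO=<ID=POPAF,Number=.,Type=String,Description="db:af population frequencies">\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n'
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n"
    )


def _vcf_line(site: TrioSite, ped: Pedigree) -> str:
    v = site.variant
    info = []
    if v.gene:
        info.append(f"GENE={v.gene}")
    if v.consequence_raw:
        info.append(f"CSQ={v.consequence_raw.replace(' ', '_')}")
    if v.pop_afs:
        info.append("POPAF=" + ",".join(f"{db}:{af:.6g}"
                                        for db, af in v.pop_afs.items()))
    cells = []
    for obs in (site.proband, site.father, site.mother):
        gt = "./." if obs.genotype is None else f"{obs.genotype[0]}/{obs.genotype[1]}"
        gq = "." if obs.gq is None else str(int(round(obs.gq)))
        cells.append(f"{gt}:{obs.depth}:{obs.depth - obs.alt_depth},"
                     f"{obs.alt_depth}:{gq}")
    return (f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t"
            f"{';'.join(info) or '.'}\tGT:DP:AD:GQ\t" + "\t".join(cells) + "\n")


@dataclass
class BurdenSimConfig:
    """Case/control rare-variant study conditions for burden testing."""

    n_cases: int = 48
    n_controls: int = 212
    n_genes: int = 20
    variants_per_gene: int = 3
    baseline_carrier_p: float = 0.05  # per-gene carrier probability
    enriched_genes: dict[str, float] = field(default_factory=dict)  # odds mult
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("both cohorts must have at least one sample")
        if not (0.0 <= self.baseline_carrier_p <= 1.0):
            raise ValueError("baseline_carrier_p must lie in [0,1]")
        bad = [g for g in self.enriched_genes
               if not g.startswith("BGENE") or not g[5:].isdigit()
               or not (1 <= int(g[5:]) <= self.n_genes)]
        if bad:
            raise ValueError(f"enriched genes outside the gene set: {bad}")


def burden_gene_names(cfg: BurdenSimConfig) -> list[str]:
    return [f"BGENE{i + 1:03d}" for i in range(cfg.n_genes)]


def simulate_case_control(cfg: BurdenSimConfig = BurdenSimConfig()
                          ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Generate one study's dosage matrix plus the enrichment truth table.

    Per gene, the per-variant carrier probability is set so the gene-level
    carrier probability equals ``baseline_carrier_p`` in controls; in cases
    the per-variant odds are multiplied by the gene's enrichment multiplier
    (1 = null).  Dosages are 0/1 carrier indicators per variant.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = burden_gene_names(cfg)
    n = cfg.n_cases + cfg.n_controls
    is_case = np.zeros(n, dtype=bool)
    is_case[:cfg.n_cases] = True
    sample_ids = [f"{'CASE' if c else 'CTRL'}{i + 1:04d}"
                  for i, c in enumerate(is_case)]

    p_var = 1.0 - (1.0 - cfg.baseline_carrier_p) ** (1.0 / cfg.variants_per_gene)
    base_odds = p_var / (1.0 - p_var)

    cols = []
    variant_genes = []
    variants = []
    pos = 0
    for gene in genes:
        mult = cfg.enriched_genes.get(gene, 1.0)
        case_odds = base_odds * mult
        p_case = case_odds / (1.0 + case_odds)
        p = np.where(is_case, p_case, p_var)
        for v in range(cfg.variants_per_gene):
            pos += 1000
            cols.append(rng.binomial(1, p))
            variant_genes.append(gene)
            variants.append(VariantRecord(chrom="2", pos=pos, ref="G", alt="A",
                                          gene=gene))
    dosage = np.column_stack(cols).astype(np.int8)
    matrix = GenotypeMatrix(sample_ids=sample_ids, is_case=is_case,
                            variant_genes=variant_genes, dosage=dosage,
                            variants=variants)
    truth = pd.DataFrame({
        "gene": genes,
        "odds_multiplier": [cfg.enriched_genes.get(g, 1.0) for g in genes],
    })
    return matrix, truth


@dataclass
class ArraySimConfig:
    """Probe-track conditions: one focused 4-Mb region by default.

    The default track length keeps the expected rule-based false-call
    probability per null track well below 1% at the default thresholds
    (Gaussian LRR noise sd 0.15); see the methods note for the design
    computation.
    """

    n_probes: int = 200
    probe_spacing_bp: int = 20_000
    lrr_noise_sd: float = 0.15
    baseline_het_p: float = 0.35  # genotype AB probability outside ROH
    planted_segments: list[tuple[str, int, int, float]] = field(default_factory=list)
    chrom: str = "1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.probe_spacing_bp <= 0 or self.n_probes < 1:
            raise ValueError("probe grid must be positive")
        span = self.n_probes * self.probe_spacing_bp
        prev_end = 0
        for kind, start, end, _ in sorted(self.planted_segments,
                                          key=lambda s: s[1]):
            if kind not in ("loss", "gain", "roh"):
                raise ValueError(f"unknown planted segment kind {kind!r}")
            if start < 1 or end > span or start > end:
                raise ValueError(f"planted segment {kind} [{start},{end}] "
                                 f"outside the {span}-bp track")
            if start <= prev_end:
                raise ValueError("planted segments must not overlap")
            prev_end = end


def simulate_probe_track(cfg: ArraySimConfig = ArraySimConfig()
                         ) -> tuple[ProbeTrack, pd.DataFrame]:
    """Generate a probe track with planted CNV/ROH segments.

    Baseline LRR ~ Normal(0, sd); planted loss/gain segments shift the mean
    to the configured level.  BAF and genotypes follow the segment kind: a
    loss removes heterozygosity (hemizygous probes read homozygous), an ROH
    is homozygous by descent, and a gain shifts het BAF toward 1/3 : 2/3.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_probes
    positions = (np.arange(n) * cfg.probe_spacing_bp + 1).astype(np.int64)
    lrr = rng.normal(0.0, cfg.lrr_noise_sd, size=n)
    het = rng.random(n) < cfg.baseline_het_p
    b_allele = rng.random(n) < 0.5  # which homozygote at non-het probes

    baf = np.where(het, rng.normal(0.5, 0.03, n),
                   np.where(b_allele, rng.normal(1.0, 0.01, n),
                            rng.normal(0.0, 0.01, n)))
    gt = np.where(het, "AB", np.where(b_allele, "BB", "AA")).astype(object)

    truth_rows = []
    for kind, start, end, mean_lrr in cfg.planted_segments:
        mask = (positions >= start) & (positions <= end)
        if kind in ("loss", "gain"):
            lrr[mask] = rng.normal(mean_lrr, cfg.lrr_noise_sd, size=mask.sum())
        if kind in ("loss", "roh"):  # loss of heterozygosity in both
            hom_b = rng.random(mask.sum()) < 0.5
            gt[mask] = np.where(hom_b, "BB", "AA")
            baf[mask] = np.where(hom_b, rng.normal(1.0, 0.01, mask.sum()),
                                 rng.normal(0.0, 0.01, mask.sum()))
        elif kind == "gain":
            seg_het = het[mask]
            shifted = np.where(rng.random(mask.sum()) < 0.5, 1 / 3, 2 / 3)
            baf[mask] = np.where(seg_het,
                                 rng.normal(shifted, 0.03),
                                 baf[mask])
        truth_rows.append({"kind": kind, "start": start, "end": end,
                           "mean_lrr": mean_lrr,
                           "n_probes": int(mask.sum())})

    baf = np.clip(baf, 0.0, 1.0)
    track = ProbeTrack(chrom=cfg.chrom, positions=positions, lrr=lrr,
                       baf=baf, genotype=gt)
    truth = pd.DataFrame(truth_rows,
                         columns=["kind", "start", "end", "mean_lrr", "n_probes"])
    return track, truth


def write_probe_track(track: ProbeTrack, path: str | Path) -> None:
    df = pd.DataFrame({"chrom": track.chrom, "pos": track.positions,
                       "lrr": track.lrr})
    if track.baf is not None:
        df["baf"] = track.baf
    if track.genotype is not None:
        df["gt"] = track.genotype
    df.to_csv(path, sep="\t", index=False)
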