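"""Input/output for the trio variant pipeline.

Reads multi-sample VCFs (via cyvcf2), 6-column PED pedigrees, per-gene
mutation-rate tables and variant annotation tables into the internal data
model, and round-trips the per-trio DNM report as TSV.

Coordinates are 1-based fully closed throughout, as in VCF.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = None  # sentinel semantics: absent genotype / GQ / strand counts


class VariantIOError(ValueError):
    """Malformed or inconsistent input file."""


@dataclass(frozen=True)
class Pedigree:
    """One sequenced trio: proband plus both biological parents."""

    family_id: str
    proband_id: str
    father_id: str
    mother_id: str
    proband_sex: str = "unknown"  # {male, female, unknown}
    phenotype: str = ""

    def __post_init__(self) -> None:
        ids = {self.proband_id, self.father_id, self.mother_id}
        if len(ids) != 3:
            raise VariantIOError(
                f"trio {self.family_id}: proband/father/mother identifiers "
                f"must be three distinct samples, got {ids}"
            )

    @property
    def sample_ids(self) -> tuple[str, str, str]:
        return (self.proband_id, self.father_id, self.mother_id)


@dataclass(frozen=True)
class GenotypeObservation:
    """Per-sample evidence at one site.

    genotype is an unordered allele pair over {0 (ref), 1 (alt)}, or None when
    the genotype call is missing.  strand_counts, when present, is
    (ref_fwd, ref_rev, alt_fwd, alt_rev) and must be consistent with depth
    and alt_depth.
    """

    genotype: tuple[int, int] | None
    depth: int
    alt_depth: int
    gq: float | None = None
    strand_counts: tuple[int, int, int, int] | None = None

    def __post_init__(self) -> None:
        if self.depth < 0 or self.alt_depth < 0 or self.alt_depth > self.depth:
            raise VariantIOError(
                f"inconsistent depths: depth={self.depth} alt_depth={self.alt_depth}"
            )
        if self.strand_counts is not None:
            rf, rr, af, ar = self.strand_counts
            if af + ar != self.alt_depth or rf + rr + af + ar != self.depth:
                raise VariantIOError(
                    f"strand counts {self.strand_counts} inconsistent with "
                    f"depth={self.depth}, alt_depth={self.alt_depth}"
                )

    @property
    def alt_fraction(self) -> float | None:
        """Alt-supporting read fraction; undefined (None) at zero depth."""
        if self.depth == 0:
            return None
        return self.alt_depth / self.depth

    @property
    def is_missing(self) -> bool:
        return self.genotype is None

    @property
    def is_hom_ref(self) -> bool:
        return self.genotype == (0, 0)

    @property
    def is_hom_alt(self) -> bool:
        return self.genotype == (1, 1)

    @property
    def is_het(self) -> bool:
        return self.genotype is not None and sorted(self.genotype) == [0, 1]

    @property
    def has_alt(self) -> bool:
        return self.genotype is not None and 1 in self.genotype


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic variant with its annotation payload."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str | None = None
    consequence_raw: str | None = None
    pop_afs: Mapping[str, float] = field(default_factory=dict)
    deleteriousness: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VariantIOError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise VariantIOError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        for db, af in self.pop_afs.items():
            if not (0.0 <= af <= 1.0):
                raise VariantIOError(
                    f"{self.chrom}:{self.pos} {db} allele frequency {af} outside [0,1]"
                )

    @property
    def is_autosomal(self) -> bool:
        c = self.chrom.removeprefix("chr")
        return c not in {"X", "Y", "M", "MT"}

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class TrioSite:
    """One variant locus with the three genotype observations of a trio."""

    variant: VariantRecord
    proband: GenotypeObservation
    father: GenotypeObservation
    mother: GenotypeObservation
    trio_id: str = ""


def read_pedigree(ped_path: str | Path) -> list[Pedigree]:
    """Parse a 6-column PED file into one Pedigree per complete trio.

    Offspring rows with a missing parent ("0") are excluded with a warning:
    the trio design requires both parents.  Sex codes 1/2 map to male/female;
    column 6 is carried through as the phenotype label.
    """
    rows: list[tuple[str, ...]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 6:
                raise VariantIOError(
                    f"{ped_path}: line {lineno}: expected 6 PED columns, got {len(cols)}"
                )
            rows.append(tuple(cols[:6]))

    sample_ids = {r[1] for r in rows}
    sex_map = {"1": "male", "2": "female"}
    trios: list[Pedigree] = []
    for fam, iid, fid, mid, sex, pheno in rows:
        if fid == "0" and mid == "0":
            continue  # founder
        if fid == "0" or mid == "0":
            log.warning("family %s: offspring %s has only one parent listed; "
                        "excluded (trio design requires both)", fam, iid)
            continue
        if fid not in sample_ids or mid not in sample_ids:
            log.warning("family %s: parent of %s not present as a sample row; excluded",
                        fam, iid)
            continue
        trios.append(Pedigree(
            family_id=fam, proband_id=iid, father_id=fid, mother_id=mid,
            proband_sex=sex_map.get(sex, "unknown"), phenotype=pheno,
        ))
    return trios


def _parse_info_afs(info_af: str | None) -> dict[str, float]:
    """Parse 'db1:0.001,db2:0.02' population-AF INFO payload."""
    if not info_af:
        return {}
    out = {}
    for item in str(info_af).split(","):
        db, _, val = item.partition(":")
        if val:
            out[db] = float(val)
    return out


def read_trio_vcf(vcf_path: str | Path, pedigree: Pedigree) -> Iterator[TrioSite]:
    """Stream TrioSites for one pedigree from a multi-sample VCF.

    Yields one TrioSite per biallelic alt allele; multiallelic records are
    decomposed into one site per alt allele, with alt_depth taken from that
    allele's AD entry (other alt reads count toward depth but not alt_depth).
    Records where all three genotypes are missing are dropped and counted in
    the log.  GENE / CSQ / POPAF / DELSCORE INFO fields, when present,
    populate the annotation payload.
    """
    import cyvcf2

    vcf = cyvcf2.VCF(str(vcf_path))
    header_samples = list(vcf.samples)
    for sid in pedigree.sample_ids:
        if sid not in header_samples:
            raise VariantIOError(
                f"{vcf_path}: pedigree sample {sid!r} absent from VCF header "
                f"(header samples: {header_samples})"
            )
    idx = {sid: header_samples.index(sid) for sid in pedigree.sample_ids}
    n_all_missing = 0

    for rec in vcf:
        gts = rec.genotypes  # [[a0, a1, phased], ...]
        try:
            depths = rec.format("DP")
        except KeyError:
            depths = None
        if depths is not None:
            depths = np.asarray(depths).reshape(len(header_samples), -1)[:, 0]
        try:
            ads = rec.format("AD")
        except KeyError:
            ads = None
        try:
            gqs = rec.gt_quals
        except Exception:
            gqs = None
        gene = rec.INFO.get("GENE")
        csq = rec.INFO.get("CSQ")
        popaf = _parse_info_afs(rec.INFO.get("POPAF"))
        delscore = rec.INFO.get("DELSCORE")

        for alt_index, alt in enumerate(rec.ALT, start=1):
            variant = VariantRecord(
                chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=alt,
                gene=gene, consequence_raw=csq, pop_afs=popaf,
                deleteriousness=float(delscore) if delscore is not None else None,
            )
            obs: dict[str, GenotypeObservation] = {}
            for role, sid in zip(("proband", "father", "mother"),
                                 pedigree.sample_ids):
                i = idx[sid]
                a0, a1 = gts[i][0], gts[i][1]
                if a0 < 0 or a1 < 0:
                    genotype = None
                else:
                    # project onto the current alt allele
                    genotype = (int(a0 == alt_index), int(a1 == alt_index))
                ad_row = None if ads is None else ads[i]
                if ad_row is not None and len(ad_row) > alt_index and ad_row[alt_index] >= 0:
                    alt_depth = int(ad_row[alt_index])
                    depth = int(sum(x for x in ad_row if x >= 0))
                elif depths is not None and depths[i] >= 0:
                    alt_depth, depth = 0, int(depths[i])
                else:
                    alt_depth, depth = 0, 0
                if depths is not None and depths[i] >= 0:
                    depth = max(depth, int(depths[i]))
                gq = None
                if gqs is not None and gqs[i] >= 0:
                    gq = float(gqs[i])
                obs[role] = GenotypeObservation(
                    genotype=genotype, depth=depth, alt_depth=alt_depth, gq=gq,
                )
            if all(o.is_missing for o in obs.values()):
                n_all_missing += 1
                continue
            yield TrioSite(variant=variant, trio_id=pedigree.family_id, **obs)

    if n_all_missing:
        log.info("%s: dropped %d records with all three genotypes missing",
                 vcf_path, n_all_missing)


class GeneRateTable:
    """Per-gene expected de novo mutation rate per trio per generation.

    A sequence-context mutability prior: lookups for genes absent from the
    table return the configured genome-wide default, or None when no default
    is set (an explicit absent marker, never silently zero).
    """

    def __init__(self, rates: Mapping[str, float], default: float | None = None):
        for gene, mu in rates.items():
            if mu < 0:
                raise VariantIOError(f"negative mutation rate for {gene}: {mu}")
        if default is not None and default < 0:
            raise VariantIOError(f"negative default mutation rate: {default}")
        self._rates = dict(rates)
        self.default = default

    def get(self, gene: str) -> float | None:
        return self._rates.get(gene, self.default)

    def __contains__(self, gene: str) -> bool:
        return gene in self._rates

    def __len__(self) -> int:
        return len(self._rates)


def read_gene_rates(table_path: str | Path,
                    default: float | None = None) -> GeneRateTable:
    """Read a two-column TSV (gene, per-trio rate) into a GeneRateTable.

    Duplicate gene rows and negative rates are fatal.
    """
    df = pd.read_csv(table_path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise VariantIOError(f"{table_path}: expected two columns (gene, rate)")
    gene_col, rate_col = df.columns[:2]
    dups = df[gene_col][df[gene_col].duplicated()].unique()
    if len(dups):
        raise VariantIOError(
            f"{table_path}: duplicate gene rows: {', '.join(map(str, dups))}"
        )
    if (df[rate_col] < 0).any():
        bad = df.loc[df[rate_col] < 0, gene_col].iloc[0]
        raise VariantIOError(f"{table_path}: negative rate for gene {bad}")
    return GeneRateTable(dict(zip(df[gene_col], df[rate_col].astype(float))),
                         default=default)


def read_annotation_table(table_path: str | Path) -> pd.DataFrame:
    """Read a variant annotation TSV keyed by (chrom, pos, ref, alt).

    Recognized optional columns: gene, consequence, deleteriousness, and any
    number of ``af_<database>`` population-frequency columns.
    """
    df = pd.read_csv(table_path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise VariantIOError(f"{table_path}: missing columns {sorted(missing)}")
    return df.set_index(["chrom", "pos", "ref", "alt"])


def annotate_sites(sites: Iterator[TrioSite],
                   annotation: pd.DataFrame) -> Iterator[TrioSite]:
    """Merge annotation-table rows onto streamed TrioSites by variant key."""
    af_cols = [c for c in annotation.columns if c.startswith("af_")]
    for site in sites:
        key = site.variant.key
        if key not in annotation.index:
            yield site
            continue
        row = annotation.loc[key]
        pop_afs = dict(site.variant.pop_afs)
        for c in af_cols:
            if pd.notna(row[c]):
                pop_afs[c.removeprefix("af_")] = float(row[c])
        variant = VariantRecord(
            chrom=site.variant.chrom, pos=site.variant.pos,
            ref=site.variant.ref, alt=site.variant.alt,
            gene=row.get("gene", site.variant.gene),
            consequence_raw=row.get("consequence", site.variant.consequence_raw),
            pop_afs=pop_afs,
            deleteriousness=(float(row["deleteriousness"])
                             if "deleteriousness" in row and pd.notna(row["deleteriousness"])
                             else site.variant.deleteriousness),
        )
        yield TrioSite(variant=variant, proband=site.proband,
                       father=site.father, mother=site.mother,
                       trio_id=site.trio_id)


DNM_REPORT_COLUMNS = [
    "trio", "chrom", "pos", "ref", "alt", "gene", "consequence_raw",
    "consequence_class", "confidence_rank", "mosaic", "passed_filters",
    "filter_failures", "proband_alt_fraction",
]


def write_dnm_report(calls, path: str | Path) -> pd.DataFrame:
    """Write the per-trio DNM report TSV; returns the frame written."""
    rows = []
    for c in calls:
        v = c.site.variant
        rows.append({
            "trio": c.site.trio_id, "chrom": v.chrom, "pos": v.pos,
            "ref": v.ref, "alt": v.alt, "gene": v.gene,
            "consequence_raw": v.consequence_raw,
            "consequence_class": c.consequence_class,
            "confidence_rank": c.confidence_rank,
            "mosaic": c.mosaic_flag, "passed_filters": c.passed_filters,
            "filter_failures": ";".join(sorted(c.filter_failures)),
            "proband_alt_fraction": c.site.proband.alt_fraction,
        })
    df = pd.DataFrame(rows, columns=DNM_REPORT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    return df


def read_dnm_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "trio": str})
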