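"""Gene-wise rare-variant collapsing burden test with cross-center
meta-analysis.

Rare damaging variants in a gene are collapsed to a per-sample carrier
indicator (the collapsing step of the CMC family of tests); the carrier
2x2 table is compared between cases and controls by an asymptotic 1-df
chi-square.  Per-study signed results are combined across centers by the
sample-size-weighted Z-score method (Stouffer weights sqrt(n)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .variant_io import VariantRecord


@dataclass
class GenotypeMatrix:
    """Rare damaging variant dosages for one study.

    dosage is samples x variants with entries {0, 1, 2}; missing dosages are
    encoded as -1 and treated as 0 (non-carrier) when collapsing.
    """

    sample_ids: list[str]
    is_case: np.ndarray  # bool per sample
    variant_genes: list[str]  # gene per variant column
    dosage: np.ndarray  # int8/int matrix, -1 = missing
    variants: list[VariantRecord] | None = None

    def __post_init__(self) -> None:
        self.is_case = np.asarray(self.is_case, dtype=bool)
        self.dosage = np.asarray(self.dosage)
        n_s, n_v = self.dosage.shape
        if n_s != len(self.sample_ids) or n_s != len(self.is_case):
            raise ValueError("sample dimension mismatch")
        if n_v != len(self.variant_genes):
            raise ValueError("variant dimension mismatch")

    @property
    def n_cases(self) -> int:
        return int(self.is_case.sum())

    @property
    def n_controls(self) -> int:
        return int((~self.is_case).sum())

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.variant_genes:
            seen.setdefault(g)
        return list(seen)


@dataclass(frozen=True)
class CarrierCounts:
    """2x2 carrier table margins for one gene in one study."""

    case_carriers: int
    n_cases: int
    control_carriers: int
    n_controls: int

    def table(self) -> np.ndarray:
        return np.array([
            [self.case_carriers, self.n_cases - self.case_carriers],
            [self.control_carriers, self.n_controls - self.control_carriers],
        ])


@dataclass(frozen=True)
class StudyBurdenResult:
    gene: str
    p: float
    direction: int  # +1 case-enriched, -1 control-enriched, 0 tied/degenerate
    n_samples: int
    carrier_counts: CarrierCounts
    chi2: float = 0.0


@dataclass(frozen=True)
class MetaResult:
    gene: str
    z: float
    p: float
    studies_used: int


def collapse_carriers(matrix: GenotypeMatrix, gene: str) -> CarrierCounts | None:
    """Collapse a gene's variants to carrier counts.

    A sample is a carrier iff it has dosage >= 1 at any of the gene's
    variants; missing dosages count as non-carrying.  Returns None when the
    gene has no variants in the matrix (explicit absent result).
    """
    cols = [i for i, g in enumerate(matrix.variant_genes) if g == gene]
    if not cols:
        return None
    sub = matrix.dosage[:, cols]
    carrier = (sub >= 1).any(axis=1)
    return CarrierCounts(
        case_carriers=int(carrier[matrix.is_case].sum()),
        n_cases=matrix.n_cases,
        control_carriers=int(carrier[~matrix.is_case].sum()),
        n_controls=matrix.n_controls,
    )


def cmc_test(counts: CarrierCounts, gene: str = "",
             continuity_correction: bool = False) -> StudyBurdenResult:
    """1-df chi-square on the collapsed 2x2 carrier table.

    The statistic is the textbook (ad-bc)^2 N / (row x column products) form
    without continuity correction by default (Yates' correction available by
    flag).  Tables with a zero margin carry no burden information and return
    p = 1, direction 0.
    """
    a = counts.case_carriers
    b = counts.n_cases - counts.case_carriers
    c = counts.control_carriers
    d = counts.n_controls - counts.control_carriers
    if min(counts.n_cases, counts.n_controls) < 1:
        raise ValueError("both cohorts must be non-empty")
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n_samples = counts.n_cases + counts.n_controls

    if c1 == 0 or c2 == 0:  # all carriers or none: degenerate margin
        return StudyBurdenResult(gene=gene, p=1.0, direction=0,
                                 n_samples=n_samples, carrier_counts=counts,
                                 chi2=0.0)
    diff = a * d - b * c
    if continuity_correction:
        diff = max(abs(diff) - n / 2, 0.0)
    chi2 = (diff * diff * n) / (r1 * r2 * c1 * c2)
    p = float(stats.chi2.sf(chi2, 1))
    rate_diff = a / counts.n_cases - c / counts.n_controls
    direction = 0 if rate_diff == 0 else (1 if rate_diff > 0 else -1)
    if direction == 0:
        p = 1.0
    return StudyBurdenResult(gene=gene, p=p, direction=direction,
                             n_samples=n_samples, carrier_counts=counts,
                             chi2=float(chi2))


def burden_scan(matrix: GenotypeMatrix,
                continuity_correction: bool = False) -> list[StudyBurdenResult]:
    """CMC test for every gene present in the study matrix."""
    out = []
    for gene in matrix.genes:
        counts = collapse_carriers(matrix, gene)
        if counts is not None:
            out.append(cmc_test(counts, gene=gene,
                                continuity_correction=continuity_correction))
    return out


_MIN_P = 1e-300  # keeps the probit finite for underflowing study p-values


def weighted_z_meta(results: Sequence[StudyBurdenResult],
                    gene: str | None = None) -> MetaResult:
    """Sample-size-weighted Z-score combination of per-study burden results.

    Each study's two-sided p is converted to a signed normal quantile
    z_i = Φ⁻¹(1 - p_i/2) · direction_i (direction 0 contributes z = 0),
    weighted by w_i = sqrt(n_i), and combined as
    Z = Σ w_i z_i / sqrt(Σ w_i²) with two-sided p = 2(1 - Φ(|Z|)).
    With equal weights this is Stouffer's method.
    """
    results = [r for r in results if np.isfinite(r.p)]
    if not results:
        raise ValueError("meta-analysis requires at least one study with finite p")
    if gene is None:
        gene = results[0].gene
    w = np.sqrt([r.n_samples for r in results])
    z = np.array([
        0.0 if r.direction == 0
        else float(stats.norm.isf(max(r.p, _MIN_P) / 2)) * r.direction
        for r in results
    ])
    Z = float((w @ z) / np.sqrt((w ** 2).sum()))
    p = float(2 * stats.norm.sf(abs(Z)))
    return MetaResult(gene=gene, z=Z, p=min(p, 1.0), studies_used=len(results))


def meta_scan(studies: Sequence[Sequence[StudyBurdenResult]],
              bonferroni: bool = True) -> pd.DataFrame:
    """Combine per-study scans gene-by-gene into a meta table.

    Genes are combined across whichever studies report them.  Returns a frame
    with per-gene Z, combined p, studies used, pooled carrier counts, and an
    optional Bonferroni-adjusted column (uncorrected p is the primary
    output).
    """
    by_gene: dict[str, list[StudyBurdenResult]] = {}
    for study in studies:
        for r in study:
            by_gene.setdefault(r.gene, []).append(r)
    rows = []
    for gene, rs in by_gene.items():
        meta = weighted_z_meta(rs, gene=gene)
        rows.append({
            "gene": gene, "z": meta.z, "p": meta.p,
            "studies_used": meta.studies_used,
            "case_carriers": sum(r.carrier_counts.case_carriers for r in rs),
            "n_cases": sum(r.carrier_counts.n_cases for r in rs),
            "control_carriers": sum(r.carrier_counts.control_carriers for r in rs),
            "n_controls": sum(r.carrier_counts.n_controls for r in rs),
        })
    df = pd.DataFrame(rows).sort_values("p", ignore_index=True)
    if bonferroni and len(df):
        df["p_bonferroni"] = np.minimum(df["p"] * len(df), 1.0)
    return df


def read_genotype_matrix(dosage_path, samples_path) -> GenotypeMatrix:
    """Read a study matrix from TSV.

    ``dosage_path``: columns chrom, pos, ref, alt, gene, then one column per
    sample with dosages {0,1,2} (missing: -1 or NA).  ``samples_path``:
    columns sample, status (case/control).
    """
    samples = pd.read_csv(samples_path, sep="\t")
    if not {"sample", "status"} <= set(samples.columns):
        raise ValueError(f"{samples_path}: expected columns sample, status")
    dos = pd.read_csv(dosage_path, sep="\t", dtype={"chrom": str})
    meta_cols = ["chrom", "pos", "ref", "alt", "gene"]
    if not set(meta_cols) <= set(dos.columns):
        raise ValueError(f"{dosage_path}: expected columns {meta_cols} + samples")
    sample_ids = [s for s in samples["sample"].astype(str)]
    missing = [s for s in sample_ids if s not in dos.columns]
    if missing:
        raise ValueError(f"{dosage_path}: samples missing from matrix: {missing}")
    dosage = (dos[sample_ids].fillna(-1).astype(int).to_numpy().T)
    is_case = samples["status"].str.lower().eq("case").to_numpy()
    variants = [
        VariantRecord(chrom=str(r.chrom), pos=int(r.pos), ref=r.ref, alt=r.alt,
                      gene=r.gene)
        for r in dos[meta_cols].itertuples()
    ]
    return GenotypeMatrix(sample_ids=sample_ids, is_case=is_case,
                          variant_genes=list(dos["gene"]), dosage=dosage,
                          variants=variants)


def write_genotype_matrix(matrix: GenotypeMatrix, dosage_path, samples_path) -> None:
    """Inverse of read_genotype_matrix."""
    if matrix.variants is None:
        raise ValueError("matrix has no variant records to write")
    meta = pd.DataFrame({
        "chrom": [v.chrom for v in matrix.variants],
        "pos": [v.pos for v in matrix.variants],
        "ref": [v.ref for v in matrix.variants],
        "alt": [v.alt for v in matrix.variants],
        "gene": matrix.variant_genes,
    })
    for i, sid in enumerate(matrix.sample_ids):
        meta[sid] = matrix.dosage[i]
    meta.to_csv(dosage_path, sep="\t", index=False)
    pd.DataFrame({
        "sample": matrix.sample_ids,
        "status": np.where(matrix.is_case, "case", "control"),
    }).to_csv(samples_path, sep="\t", index=False)
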