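"""Cohort-level de novo mutation rate statistics.

Per-trio DNM counts are modelled as Poisson with rate λ estimated by the
cohort mean.  The module provides a goodness-of-fit test of that model, an
exact conditional binomial comparison of event rates between two trio
cohorts, and an exact Poisson-tail test of per-gene over-representation
against a sequence-context expected mutation rate.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import special, stats

from .dnm_detection import CONSEQUENCE_CLASSES, DnmCall, lof_subtype
from .variant_io import GeneRateTable, Pedigree


@dataclass
class CohortDnmSummary:
    """Per-trio DNM counts with class breakdown and the fitted rate."""

    n_trios: int
    per_trio_counts: dict[str, int]
    class_counts: dict[str, int]
    lambda_hat: float

    @property
    def total(self) -> int:
        return sum(self.per_trio_counts.values())

    @property
    def lambda_reported(self) -> float:
        """The rate rounded to one decimal, as conventionally reported."""
        return round(self.lambda_hat, 1)


@dataclass(frozen=True)
class ReferenceCohort:
    """A published comparison cohort: events (e.g. trios with >=1 LOF DNM)
    out of trios."""

    label: str
    n_trios: int
    n_events: int

    def __post_init__(self) -> None:
        if self.n_trios < 1 or self.n_events < 0:
            raise ValueError(f"invalid reference cohort {self.label}: "
                             f"{self.n_events}/{self.n_trios}")


def summarize_cohort(calls: Sequence[DnmCall],
                     trios: Sequence[Pedigree] | Sequence[str]) -> CohortDnmSummary:
    """Count validated calls per trio and per consequence class.

    Every trio appears in the per-trio map, zero-count trios included, so the
    fitted rate is total calls over all trios.  ``trios`` may be Pedigree
    objects or bare trio identifiers.
    """
    trio_ids = [t.family_id if isinstance(t, Pedigree) else str(t) for t in trios]
    per_trio = {tid: 0 for tid in trio_ids}
    class_counts = {c: 0 for c in CONSEQUENCE_CLASSES}
    for call in calls:
        tid = call.site.trio_id
        if tid not in per_trio:
            raise ValueError(f"call references unknown trio {tid!r}")
        per_trio[tid] += 1
        cls = call.consequence_class or "other"
        class_counts[cls] = class_counts.get(cls, 0) + 1
    n = len(trio_ids)
    total = sum(per_trio.values())
    return CohortDnmSummary(
        n_trios=n, per_trio_counts=per_trio, class_counts=class_counts,
        lambda_hat=total / n if n else 0.0,
    )


def classwise_summary(calls: Sequence[DnmCall]) -> dict[str, int]:
    """Exact partition of calls into consequence classes.

    LOF calls are additionally subdivided into nonsense / frameshift /
    splicing under keys ``LOF_<subtype>``.
    """
    counts = {c: 0 for c in CONSEQUENCE_CLASSES}
    for call in calls:
        cls = call.consequence_class or "other"
        counts[cls] = counts.get(cls, 0) + 1
        if cls == "LOF":
            sub = lof_subtype(call.site.variant)
            if sub:
                key = f"LOF_{sub}"
                counts[key] = counts.get(key, 0) + 1
    return counts


@dataclass(frozen=True)
class GofResult:
    """Poisson goodness-of-fit of per-trio counts."""

    lambda_hat: float
    ks_statistic: float
    p_value: float
    chi2_statistic: float
    chi2_p_value: float
    method: str  # "exact" | "asymptotic"


def _discrete_ks(counts: np.ndarray, lam: float) -> float:
    """sup |ECDF - F| for a Poisson null, evaluated on the integer support.

    Both the empirical and the null CDF are right-continuous step functions
    with jumps only at integers, so the supremum over the real line is
    attained at an integer; evaluating anywhere else (as a continuous-null KS
    would, via F(x-)) overstates the discrepancy.
    """
    hi = int(counts.max()) if len(counts) else 0
    ks = np.arange(0, hi + 1)
    ecdf = np.searchsorted(np.sort(counts), ks, side="right") / len(counts)
    return float(np.abs(ecdf - stats.poisson.cdf(ks, lam)).max())


def poisson_gof(summary: CohortDnmSummary | Sequence[int],
                lam: float | None = None,
                exact_max_n: int = 30) -> GofResult:
    """Two-sided one-sample KS test of per-trio counts against Poisson(λ).

    λ defaults to the full-precision cohort mean.  The KS p-value is the
    exact small-sample distribution (scipy ``kstwo``) for n <= ``exact_max_n``
    and the asymptotic Kolmogorov distribution otherwise; against a discrete
    null either is conservative.  A chi-square goodness-of-fit on binned
    counts (bins pooled to expected >= 1, one estimated parameter) is
    reported as a cross-check.
    """
    if isinstance(summary, CohortDnmSummary):
        counts = np.array(sorted(summary.per_trio_counts.values()))
    else:
        counts = np.array(sorted(summary))
    n = len(counts)
    if n < 2:
        raise ValueError("goodness of fit requires at least 2 trios")
    if lam is None:
        lam = float(counts.mean())

    d = _discrete_ks(counts, lam)
    if n <= exact_max_n:
        p = float(stats.kstwo.sf(d, n))
        method = "exact"
    else:
        p = float(special.kolmogorov(np.sqrt(n) * d))
        method = "asymptotic"

    chi2_stat, chi2_p = _chi2_gof(counts, lam)
    return GofResult(lambda_hat=lam, ks_statistic=d, p_value=min(p, 1.0),
                     chi2_statistic=chi2_stat, chi2_p_value=chi2_p,
                     method=method)


def _chi2_gof(counts: np.ndarray, lam: float) -> tuple[float, float]:
    """Chi-square GOF with right-tail pooling to expected counts >= 1."""
    n = len(counts)
    if lam == 0:
        return (0.0, 1.0) if counts.max() == 0 else (np.inf, 0.0)
    hi = int(max(counts.max(), stats.poisson.isf(1 / (2 * n), lam))) + 1
    probs = stats.poisson.pmf(np.arange(hi), lam)
    probs = np.append(probs, 1.0 - probs.sum())
    obs = np.bincount(counts, minlength=hi + 1).astype(float)

    # pool cells from the right until every expected count is >= 1
    exp = n * probs
    while len(exp) > 2 and exp[-1] < 1.0:
        exp[-2] += exp[-1]; exp = exp[:-1]
        obs[-2] += obs[-1]; obs = obs[:-1]
    dof = max(len(exp) - 1 - 1, 1)  # one parameter (λ) estimated
    stat = float(((obs - exp) ** 2 / exp).sum())
    return stat, float(stats.chi2.sf(stat, dof))


def cohort_rate_test(k_case: int, n_case: int, ref: ReferenceCohort) -> float:
    """Exact conditional binomial comparison of two cohort event rates.

    Conditioning on the total number of events m = k_case + ref.n_events,
    each event falls in the case cohort with probability
    π0 = n_case / (n_case + ref.n_trios) under the null of equal per-trio
    rates.  Returns the one-sided upper tail P(X >= k_case | m, π0),
    inclusive of the observed count.  No events at all gives p = 1.
    """
    if k_case < 0 or n_case < 1:
        raise ValueError(f"invalid case cohort: {k_case}/{n_case}")
    m = k_case + ref.n_events
    if m == 0:
        return 1.0
    pi0 = n_case / (n_case + ref.n_trios)
    return float(stats.binom.sf(k_case - 1, m, pi0))


@dataclass(frozen=True)
class GeneEnrichmentResult:
    """Per-gene DNM over-representation against the expected rate."""

    gene: str
    observed: int
    n_trios: int
    mu: float | None  # expected DNMs per trio; None when absent from table
    p_value: float | None
    method: str = "poisson"

    @property
    def rate_per_trio(self) -> float:
        return self.observed / self.n_trios

    @property
    def expected(self) -> float | None:
        return None if self.mu is None else self.n_trios * self.mu


def gene_enrichment_test(gene: str, observed: int, n_trios: int,
                         rates: GeneRateTable,
                         method: str = "poisson") -> GeneEnrichmentResult:
    """Exact upper-tail test of observed DNM count vs the gene's expectation.

    Primary mode: Poisson tail P(X >= observed) at rate n_trios * μ_g,
    floored at machine precision.  Secondary "fisher" mode: two-sided
    Fisher's exact test on the 2x2 table
    [[observed, n_trios - observed], [round(expected), n_trios - round(expected)]],
    an approximate construction provided for cross-checking.
    A gene absent from the rate table yields an explicit absent result
    (p None), never p = 0.
    """
    if observed < 0 or n_trios < 1:
        raise ValueError(f"invalid observation: {observed} in {n_trios} trios")
    mu = rates.get(gene)
    if mu is None:
        return GeneEnrichmentResult(gene=gene, observed=observed,
                                    n_trios=n_trios, mu=None, p_value=None,
                                    method=method)
    expected = n_trios * mu
    if method == "poisson":
        p = float(stats.poisson.sf(observed - 1, expected)) if observed > 0 else 1.0
        p = max(p, np.finfo(float).tiny)
    elif method == "fisher":
        exp_k = int(round(expected))
        table = [[observed, max(n_trios - observed, 0)],
                 [exp_k, max(n_trios - exp_k, 0)]]
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    else:
        raise ValueError(f"unknown method {method!r}")
    return GeneEnrichmentResult(gene=gene, observed=observed, n_trios=n_trios,
                                mu=mu, p_value=p, method=method)


def trios_with_class(calls: Iterable[DnmCall], consequence_class: str,
                     gene: str | None = None) -> set[str]:
    """Trios carrying >= 1 call of a class (optionally restricted to a gene)."""
    out = set()
    for c in calls:
        if c.consequence_class != consequence_class:
            continue
        if gene is not None and c.site.variant.gene != gene:
            continue
        out.add(c.site.trio_id)
    return out
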