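"""Rule-based CNV and run-of-homozygosity calling from SNP-array probes.

Calls are driven entirely by fixed thresholds on the probe-level log R
ratio (LRR) and B-allele frequency (BAF): a copy-number loss is a run of
probes with LRR at or below -0.2 containing at least five qualifying probes
within a 150-kb window; a gain is LRR at or above +0.15 with at least seven
probes within 200 kb; a run of homozygosity (ROH) is a stretch of
homozygous probes spanning at least 2 Mb.  Runs tolerate a configurable
number of interior probes that miss the threshold, provided the run mean
still satisfies it.  No segmentation model (HMM/CBS) is involved.

Coordinates are 1-based fully closed internally; the BED-like writer emits
0-based half-open intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

LOSS = "loss"
GAIN = "gain"
ROH = "roh"


@dataclass
class CnvRuleConfig:
    """Printed rule thresholds; all boundaries inclusive."""

    loss_min_probes: int = 5
    loss_span_bp: int = 150_000
    loss_lrr_max: float = -0.2
    gain_min_probes: int = 7
    gain_span_bp: int = 200_000
    gain_lrr_min: float = 0.15
    roh_min_bp: int = 2_000_000
    gap_probes: int = 1        # interior sub-threshold probes tolerated per run
    roh_het_per_mb: float = 1.0  # interior het probes tolerated per Mb of span
    baf_hom_low: float = 0.05  # BAF at or below -> homozygous A
    baf_hom_high: float = 0.95  # BAF at or above -> homozygous B

    def __post_init__(self) -> None:
        if self.loss_min_probes < 1 or self.gain_min_probes < 1:
            raise ValueError("probe minima must be >= 1")
        if min(self.loss_span_bp, self.gain_span_bp, self.roh_min_bp) <= 0:
            raise ValueError("spans must be positive")


@dataclass
class ProbeTrack:
    """Probe-level array signal for one chromosome."""

    chrom: str
    positions: np.ndarray  # ascending, 1-based
    lrr: np.ndarray
    baf: np.ndarray | None = None
    genotype: np.ndarray | None = None  # {"AA","AB","BB",""} per probe

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.lrr = np.asarray(self.lrr, dtype=float)
        n = len(self.positions)
        if len(self.lrr) != n:
            raise ValueError("positions and lrr must have equal length")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError(f"{self.chrom}: probe positions must be strictly increasing")
        if self.baf is not None:
            self.baf = np.asarray(self.baf, dtype=float)
            if len(self.baf) != n:
                raise ValueError("baf length mismatch")
        if self.genotype is not None:
            self.genotype = np.asarray(self.genotype, dtype=object)
            if len(self.genotype) != n:
                raise ValueError("genotype length mismatch")


@dataclass(frozen=True)
class CnvSegment:
    """A called interval, anchored at its first and last probe."""

    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    kind: str   # loss | gain | roh
    n_probes: int
    mean_lrr: float

    @property
    def span_bp(self) -> int:
        return self.end - self.start + 1


def _find_runs(qualify: np.ndarray, gap_budget: int) -> list[tuple[int, int]]:
    """Maximal index runs of qualifying probes.

    A run starts and ends on a qualifying probe and may contain up to
    ``gap_budget`` interior non-qualifying probes in total, each immediately
    followed by a qualifying probe (gaps never stack).
    """
    runs: list[tuple[int, int]] = []
    n = len(qualify)
    i = 0
    while i < n:
        if not qualify[i]:
            i += 1
            continue
        j = i
        gaps = 0
        while j + 1 < n:
            if qualify[j + 1]:
                j += 1
            elif gaps < gap_budget and j + 2 < n and qualify[j + 2]:
                gaps += 1
                j += 2
            else:
                break
        runs.append((i, j))
        i = j + 1
    return runs


def _window_ok(positions: np.ndarray, min_probes: int, span_bp: int) -> bool:
    """True iff some ``min_probes`` consecutive probes fit within span_bp."""
    if len(positions) < min_probes:
        return False
    spans = positions[min_probes - 1:] - positions[:len(positions) - min_probes + 1] + 1
    return bool((spans <= span_bp).any())


def call_cnv_segments(track: ProbeTrack,
                      cfg: CnvRuleConfig = CnvRuleConfig()) -> list[CnvSegment]:
    """Call copy-number losses and gains on one probe track.

    Probes with non-finite LRR are dropped (counted) before calling.  For
    each direction, maximal runs of threshold-qualifying probes (with gap
    tolerance) are kept when the run mean satisfies the threshold and the
    required probe count occurs within the rule's window.  Loss and gain
    calls cannot overlap; if a pathological configuration produces both, the
    run with the larger |mean LRR| wins.
    """
    finite = np.isfinite(track.lrr)
    pos = track.positions[finite]
    lrr = track.lrr[finite]

    segments: list[CnvSegment] = []
    rules = (
        (LOSS, lrr <= cfg.loss_lrr_max, cfg.loss_min_probes, cfg.loss_span_bp),
        (GAIN, lrr >= cfg.gain_lrr_min, cfg.gain_min_probes, cfg.gain_span_bp),
    )
    for kind, qualify, min_probes, span_bp in rules:
        for a, b in _find_runs(qualify, cfg.gap_probes):
            run_pos = pos[a:b + 1]
            run_lrr = lrr[a:b + 1]
            qual_pos = run_pos[qualify[a:b + 1]]
            n_q = len(qual_pos)
            if n_q < min_probes:
                continue
            mean_lrr = float(run_lrr.mean())
            # numerical tolerance keeps exact-boundary runs inclusive
            if kind == LOSS and mean_lrr > cfg.loss_lrr_max + 1e-9:
                continue
            if kind == GAIN and mean_lrr < cfg.gain_lrr_min - 1e-9:
                continue
            if not _window_ok(qual_pos, min_probes, span_bp):
                continue
            segments.append(CnvSegment(
                chrom=track.chrom, start=int(run_pos[0]), end=int(run_pos[-1]),
                kind=kind, n_probes=n_q, mean_lrr=mean_lrr,
            ))

    segments.sort(key=lambda s: (s.start, s.end))
    return _drop_cross_kind_overlaps(segments)


def _drop_cross_kind_overlaps(segments: list[CnvSegment]) -> list[CnvSegment]:
    keep: list[CnvSegment] = []
    for seg in segments:
        clash = next((k for k in keep
                      if k.kind != seg.kind and k.kind in (LOSS, GAIN)
                      and seg.kind in (LOSS, GAIN)
                      and not (seg.end < k.start or seg.start > k.end)), None)
        if clash is None:
            keep.append(seg)
        elif abs(seg.mean_lrr) > abs(clash.mean_lrr):
            keep.remove(clash)
            keep.append(seg)
    keep.sort(key=lambda s: (s.start, s.end))
    return keep


def _homozygosity_masks(track: ProbeTrack,
                        cfg: CnvRuleConfig) -> tuple[np.ndarray, np.ndarray]:
    """(hom, het) masks; probes informative by genotype or BAF.

    Genotype takes precedence where present; probes informative by neither
    channel are neutral (neither hom nor het: they extend runs without
    counting against the het tolerance).
    """
    n = len(track.positions)
    hom = np.zeros(n, dtype=bool)
    het = np.zeros(n, dtype=bool)
    if track.genotype is not None:
        gt = track.genotype.astype(str)
        hom |= (gt == "AA") | (gt == "BB")
        het |= gt == "AB"
    if track.baf is not None:
        with np.errstate(invalid="ignore"):
            informative = np.isfinite(track.baf) & ~hom & ~het
            b = track.baf
            hom |= informative & ((b <= cfg.baf_hom_low) | (b >= cfg.baf_hom_high))
            het |= informative & (b > cfg.baf_hom_low) & (b < cfg.baf_hom_high)
    return hom, het


def call_roh(track: ProbeTrack,
             cfg: CnvRuleConfig = CnvRuleConfig()) -> list[CnvSegment]:
    """Call runs of homozygosity spanning at least ``roh_min_bp``.

    Maximal homozygous stretches are merged across interior heterozygous
    probes while the merged run's het count stays within
    ``roh_het_per_mb`` per Mb of span (at least one het always tolerated).
    Requires genotype calls or BAF.
    """
    if track.genotype is None and track.baf is None:
        raise ValueError(f"{track.chrom}: ROH calling requires genotype or BAF")
    hom, het = _homozygosity_masks(track, cfg)
    pos = track.positions

    # maximal hom stretches (het-free, anchored on hom probes)
    stretches: list[tuple[int, int, int]] = []  # (first_idx, last_idx, n_het=0)
    i = 0
    n = len(pos)
    while i < n:
        if not hom[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and not het[j + 1]:
            j += 1
        # trim trailing neutral probes back to the last hom probe
        last = j
        while last > i and not hom[last]:
            last -= 1
        stretches.append((i, last, 0))
        i = j + 1

    # greedy left-to-right merge across single het probes under the tolerance
    merged: list[tuple[int, int, int]] = []
    for s in stretches:
        if merged:
            a0, a1, ah = merged[-1]
            b0, b1, bh = s
            n_het_between = int(het[a1 + 1:b0].sum())
            span_mb = (pos[b1] - pos[a0] + 1) / 1e6
            allowed = max(1, int(np.floor(span_mb * cfg.roh_het_per_mb)))
            if ah + bh + n_het_between <= allowed:
                merged[-1] = (a0, b1, ah + bh + n_het_between)
                continue
        merged.append(s)

    out = []
    for a, b, _ in merged:
        span = int(pos[b] - pos[a] + 1)
        if span >= cfg.roh_min_bp:
            run_lrr = track.lrr[a:b + 1]
            out.append(CnvSegment(
                chrom=track.chrom, start=int(pos[a]), end=int(pos[b]), kind=ROH,
                n_probes=int(hom[a:b + 1].sum()),
                mean_lrr=float(np.nanmean(run_lrr)) if len(run_lrr) else 0.0,
            ))
    return out


def read_probe_track(path) -> list[ProbeTrack]:
    """Read a probe TSV (chrom, pos, lrr[, baf][, gt]) into per-chromosome tracks."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if not {"chrom", "pos", "lrr"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns chrom, pos, lrr")
    tracks = []
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        tracks.append(ProbeTrack(
            chrom=str(chrom),
            positions=sub["pos"].to_numpy(),
            lrr=sub["lrr"].to_numpy(),
            baf=sub["baf"].to_numpy() if "baf" in sub else None,
            genotype=sub["gt"].fillna("").to_numpy() if "gt" in sub else None,
        ))
    return tracks


def write_segments_bed(segments: Sequence[CnvSegment], path) -> pd.DataFrame:
    """Write calls as BED-like TSV (0-based half-open start, inclusive end)."""
    df = pd.DataFrame([{
        "chrom": s.chrom, "start": s.start - 1, "end": s.end, "kind": s.kind,
        "n_probes": s.n_probes, "mean_lrr": s.mean_lrr, "span_bp": s.span_bp,
    } for s in segments])
    df.to_csv(path, sep="\t", index=False)
    return df
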