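"""Runs-of-homozygosity detection and per-individual/per-breed summaries.

A run of homozygosity (ROH) is reported when a stretch of genotypes
satisfies all of:

(i)   total length >= ``min_length_kb`` (default 1 Mb),
(ii)  at least ``min_snps`` SNPs (default 100),
(iii) average density of at least 1 SNP per ``min_density_kb_per_snp`` kb,
(iv)  no inter-SNP gap above ``max_gap_kb`` (runs are split at larger gaps),
(v)   at most ``window_max_het`` heterozygous and ``window_max_missing``
      missing calls inside any ``window_snps``-SNP window of the run —
      the genotype-counting allowance that lets a multi-megabase
      autozygous run absorb occasional genotyping errors without being
      rejected outright.

Two detectors are provided.  :func:`detect_roh_windowed` is the
genotype-counting sliding-window scan popularised by PLINK's ``--homozyg``:
a SNP becomes run-eligible when enough of the windows overlapping it are
nearly homozygous, and eligible stretches are then resolved into runs.
:func:`detect_roh_direct` skips the window stage and scans genotype arrays
exhaustively; it is the simpler of the two and serves as an independent
cross-check (the two agree when genotyping errors inside true segments are
within the window allowances).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset

LENGTH_CLASSES = ("1-4", "4-8", ">8")


@dataclass(frozen=True)
class ROHParams:
    """Detection thresholds; defaults follow the usual genotype-counting
    settings for 50K-600K SNP arrays."""

    min_length_kb: float = 1000.0
    min_snps: int = 100
    min_density_kb_per_snp: float = 50.0
    max_gap_kb: float = 1000.0
    window_snps: int = 50
    window_max_het: int = 1
    window_max_missing: int = 5
    window_hit_threshold: float = 0.05

    def __post_init__(self):
        numeric = (self.min_length_kb, self.min_snps,
                   self.min_density_kb_per_snp, self.max_gap_kb,
                   self.window_snps)
        if any(v <= 0 for v in numeric):
            raise ValueError("ROH thresholds must be positive")
        if self.window_max_het < 0 or self.window_max_missing < 0:
            raise ValueError("window allowances must be nonnegative")
        if not 0 < self.window_hit_threshold <= 1:
            raise ValueError("window_hit_threshold must lie in (0, 1]")


@dataclass(frozen=True)
class ROHSegment:
    """One homozygous run; bp bounds are 1-based inclusive SNP positions."""

    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    n_het_inside: int = 0
    n_missing_inside: int = 0

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def length_mb(self) -> float:
        return self.length_bp / 1e6


def segments_to_frame(segments) -> pd.DataFrame:
    """Tabulate segments in PLINK ``.hom``-style columns."""
    rows = [(s.sample_id, s.chrom, s.start_bp, s.end_bp,
             s.length_bp / 1000.0, s.n_snps, s.n_het_inside,
             s.n_missing_inside) for s in segments]
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "start_bp",
                                       "end_bp", "length_kb", "n_snps",
                                       "n_het", "n_miss"])


def frame_to_segments(frame: pd.DataFrame) -> list[ROHSegment]:
    return [ROHSegment(str(r.sample_id), str(r.chrom), int(r.start_bp),
                       int(r.end_bp), int(r.n_snps), int(r.n_het),
                       int(r.n_miss))
            for r in frame.itertuples(index=False)]


def _finalize_candidate(sample_id, chrom, bp, geno, lo, hi, params, out):
    """Resolve a candidate run [lo, hi] (SNP indices, inclusive) into
    reported segments: split at large gaps, trim ends to the outermost
    homozygous calls, then apply the length/count/density criteria and the
    total heterozygote/missing allowances.

    Trimming before counting matters: a candidate may legitimately end on
    the heterozygous call that terminated it, and that call must not spend
    the run's heterozygote budget."""
    if hi < lo:
        return
    max_gap_bp = params.max_gap_kb * 1000.0
    gaps = np.diff(bp[lo:hi + 1])
    breaks = np.flatnonzero(gaps > max_gap_bp)
    starts = [lo] + [lo + b + 1 for b in breaks]
    ends = [lo + b for b in breaks] + [hi]
    for s, e in zip(starts, ends):
        if e - s + 1 < params.min_snps:
            continue
        hom = (geno[s:e + 1] == 0) | (geno[s:e + 1] == 2)
        idx = np.flatnonzero(hom)
        if idx.size == 0:
            continue
        s2, e2 = s + idx[0], s + idx[-1]
        n_snps = e2 - s2 + 1
        length_bp = int(bp[e2] - bp[s2] + 1)
        if n_snps < params.min_snps:
            continue
        if length_bp < params.min_length_kb * 1000.0:
            continue
        if length_bp / n_snps > params.min_density_kb_per_snp * 1000.0:
            continue
        seg = geno[s2:e2 + 1]
        out.append(ROHSegment(sample_id, chrom, int(bp[s2]), int(bp[e2]),
                              n_snps, int((seg == 1).sum()),
                              int((seg == MISSING).sum())))


def _drop_contained(segments):
    """Remove segments nested inside another segment of the same sample
    and chromosome (maximal-window enumeration can emit both a run and a
    sub-run that trim to nested intervals)."""
    by_key = {}
    for s in segments:
        by_key.setdefault((s.sample_id, s.chrom), []).append(s)
    kept = []
    for group in by_key.values():
        group.sort(key=lambda s: (s.start_bp, -s.end_bp))
        max_end = -1
        for s in group:
            if s.end_bp > max_end:
                kept.append(s)
                max_end = s.end_bp
    kept.sort(key=lambda s: (s.sample_id, s.chrom, s.start_bp))
    return kept


def _iter_chromosomes(dataset: GenotypeDataset):
    chroms = dataset.markers["chrom"].to_numpy()
    bp = dataset.markers["bp"].to_numpy(dtype=np.int64)
    # markers are sorted, so chromosomes form contiguous blocks
    change = np.flatnonzero(chroms[1:] != chroms[:-1]) + 1
    bounds = np.concatenate(([0], change, [len(chroms)]))
    for b, e in zip(bounds[:-1], bounds[1:]):
        yield str(chroms[b]), slice(b, e), bp[b:e]


def _eligible_mask(geno_chrom: np.ndarray, params: ROHParams) -> np.ndarray:
    """Fraction-of-hit-windows eligibility for every SNP on one chromosome."""
    n = geno_chrom.shape[0]
    w = params.window_snps
    if n < w:
        w = n  # single shortened window; caller warns once
    het = (geno_chrom == 1).astype(np.int32)
    mis = (geno_chrom == MISSING).astype(np.int32)
    kernel = np.ones(w, dtype=np.int32)
    h_ct = np.convolve(het, kernel, mode="valid")
    m_ct = np.convolve(mis, kernel, mode="valid")
    hit = ((h_ct <= params.window_max_het)
           & (m_ct <= params.window_max_missing)).astype(np.int32)
    # windows overlapping SNP i start at s in [i-w+1, i] ∩ [0, n-w]
    cum = np.concatenate(([0], np.cumsum(hit)))
    i = np.arange(n)
    s_lo = np.clip(i - w + 1, 0, n - w)
    s_hi = np.minimum(i, n - w)
    n_hits = cum[s_hi + 1] - cum[s_lo]
    n_windows = s_hi - s_lo + 1
    return n_hits / n_windows >= params.window_hit_threshold


def detect_roh_windowed(dataset: GenotypeDataset,
                        params: ROHParams = ROHParams()) -> list[ROHSegment]:
    """Sliding-window genotype-counting ROH scan."""
    out: list[ROHSegment] = []
    sample_ids = dataset.samples["sample_id"].astype(str).to_numpy()
    short_chroms = set()
    for chrom, sl, bp in _iter_chromosomes(dataset):
        if sl.stop - sl.start < params.window_snps:
            short_chroms.add(chrom)
        for si, sample_id in enumerate(sample_ids):
            geno = dataset.genotypes[si, sl]
            elig = _eligible_mask(geno, params)
            if not elig.any():
                continue
            padded = np.concatenate(([False], elig, [False]))
            edges = np.flatnonzero(padded[1:] != padded[:-1])
            for lo, hi in zip(edges[::2], edges[1::2] - 1):
                _finalize_candidate(sample_id, chrom, bp, geno, int(lo),
                                    int(hi), params, out)
    if short_chroms:
        warnings.warn(
            f"chromosome(s) {sorted(short_chroms)} have fewer SNPs than the "
            f"{params.window_snps}-SNP window; scanned with one shortened "
            "window", stacklevel=2)
    return _drop_contained(out)


def detect_roh_direct(dataset: GenotypeDataset,
                      params: ROHParams = ROHParams()) -> list[ROHSegment]:
    """Exhaustive maximal-run scan without the window stage (cross-check).

    Enumerates, by a single left-to-right sweep, every maximal stretch in
    which no ``window_snps``-SNP window holds more than ``window_max_het``
    heterozygous or ``window_max_missing`` missing calls (the same
    allowance the window stage certifies), finalizes each stretch (gap
    split, trim, length/count/density filters) and drops nested
    duplicates."""
    out: list[ROHSegment] = []
    sample_ids = dataset.samples["sample_id"].astype(str).to_numpy()
    for chrom, sl, bp in _iter_chromosomes(dataset):
        n = sl.stop - sl.start
        w = min(params.window_snps, n)
        for si, sample_id in enumerate(sample_ids):
            geno = dataset.genotypes[si, sl]
            hets = np.flatnonzero(geno == 1)
            miss = np.flatnonzero(geno == MISSING)
            # a window with window_max_het+1 hets exists iff some het and
            # the window_max_het-th het before it sit < w SNPs apart; the
            # stretch must then exclude one of them (same for missing)
            left = 0
            prev_r = -1
            barriers = []  # (position_to_pass, conflicting_earlier_index)
            kh, km = params.window_max_het, params.window_max_missing
            for arr, k in ((hets, kh), (miss, km)):
                if k < arr.size:
                    close = arr[k:] - arr[:-k] < w
                    for j in np.flatnonzero(close):
                        barriers.append((int(arr[j + k]), int(arr[j])))
            barriers.sort()
            for pos, conflict in barriers:
                # maximal stretch ends just before `pos`
                if pos - 1 > prev_r:
                    _finalize_candidate(sample_id, chrom, bp, geno, left,
                                        pos - 1, params, out)
                    prev_r = pos - 1
                left = max(left, conflict + 1)
            if n - 1 > prev_r:
                _finalize_candidate(sample_id, chrom, bp, geno, left, n - 1,
                                    params, out)
    return _drop_contained(out)


def classify_roh(segment: ROHSegment) -> str:
    """Length class of a segment: half-open bins [1,4), [4,8), [8,inf) Mb."""
    mb = segment.length_mb
    if mb < 1.0:
        raise ValueError(
            f"segment of {mb:.3f} Mb violates the 1 Mb detection minimum")
    if mb < 4.0:
        return "1-4"
    if mb < 8.0:
        return "4-8"
    return ">8"


def roh_summary(segments, samples: pd.DataFrame
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-individual and per-breed ROH descriptive statistics.

    ``samples`` must carry ``sample_id`` and, for the breed table, a
    ``breed`` column; individuals with no ROH contribute zeros (their
    average length is reported as NaN).
    """
    frame = segments_to_frame(segments)
    per = frame.groupby("sample_id").agg(
        n_roh=("length_kb", "size"),
        total_length_mb=("length_kb", lambda x: x.sum() / 1000.0))
    base = samples[["sample_id"]].astype(str).set_index("sample_id")
    per = base.join(per).fillna({"n_roh": 0, "total_length_mb": 0.0})
    per["n_roh"] = per["n_roh"].astype(int)
    with np.errstate(invalid="ignore"):
        per["avg_length_mb"] = np.where(
            per["n_roh"] > 0, per["total_length_mb"] / per["n_roh"], np.nan)
    per = per.reset_index()

    if "breed" in samples.columns:
        merged = per.merge(samples[["sample_id", "breed"]].astype(str),
                           on="sample_id")
    else:
        merged = per.assign(breed="all")
    breed = merged.groupby("breed")[
        ["n_roh", "total_length_mb", "avg_length_mb"]].agg(
        ["mean", "std", "max"])
    breed.columns = ["_".join(c) for c in breed.columns]
    return per, breed.reset_index()
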