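"""Consensus ROH hotspots and case/control association.

A hotspot is a maximal run of consecutive SNPs each covered by the ROH of
at least ``min_share`` individuals, kept when it spans at least
``min_snps_hotspot`` SNPs.  Each animal's carrier status per hotspot feeds
a two-sided Fisher exact test of carrier counts against the high/low-yield
labels, with a Bonferroni threshold of alpha over the number of hotspots
tested in the cohort.  Per-SNP allelic Fisher tests follow up candidate
regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact as _scipy_fisher

from .genotype_io import MISSING, GenotypeDataset


@dataclass(frozen=True)
class Hotspot:
    hotspot_id: str
    chrom: str
    start_bp: int
    end_bp: int
    snp_start: int  # index into the marker map, inclusive
    snp_end: int
    n_snps: int

    @property
    def length_kb(self) -> float:
        return (self.end_bp - self.start_bp + 1) / 1000.0

    @property
    def midpoint_bp(self) -> int:
        return (self.start_bp + self.end_bp) // 2


@dataclass(frozen=True)
class AssociationResult:
    hotspot_id: str
    a: int  # case carriers
    b: int  # case non-carriers
    c: int  # control carriers
    d: int  # control non-carriers
    p_two_sided: float
    bonferroni_threshold: float

    @property
    def significant(self) -> bool:
        return self.p_two_sided < self.bonferroni_threshold


def _chrom_blocks(marker_map: pd.DataFrame):
    chroms = marker_map["chrom"].astype(str).to_numpy()
    change = np.flatnonzero(chroms[1:] != chroms[:-1]) + 1
    bounds = np.concatenate(([0], change, [len(chroms)]))
    return {chroms[b]: (b, e) for b, e in zip(bounds[:-1], bounds[1:])}


def _segment_snp_span(seg, blocks, bp):
    """Marker-index range [lo, hi) of SNPs covered by a segment."""
    if seg.chrom not in blocks:
        raise ValueError(f"segment references unknown chromosome {seg.chrom}")
    b, e = blocks[seg.chrom]
    lo = b + np.searchsorted(bp[b:e], seg.start_bp, side="left")
    hi = b + np.searchsorted(bp[b:e], seg.end_bp, side="right")
    return int(lo), int(hi)


def snp_incidence(segments, marker_map: pd.DataFrame) -> np.ndarray:
    """Number of individuals whose ROH covers each SNP in the map.

    Overlapping segments of the same individual count that individual once.
    """
    blocks = _chrom_blocks(marker_map)
    bp = marker_map["bp"].to_numpy(dtype=np.int64)
    n = len(marker_map)
    per_sample: dict[str, np.ndarray] = {}
    for seg in segments:
        lo, hi = _segment_snp_span(seg, blocks, bp)
        if hi <= lo:
            continue
        diff = per_sample.setdefault(seg.sample_id,
                                     np.zeros(n + 1, dtype=np.int32))
        diff[lo] += 1
        diff[hi] -= 1
    incidence = np.zeros(n, dtype=np.int32)
    for diff in per_sample.values():
        incidence += np.cumsum(diff[:-1]) > 0
    return incidence


def build_hotspots(incidence: np.ndarray, marker_map: pd.DataFrame,
                   min_share: int = 2,
                   min_snps_hotspot: int = 10) -> list[Hotspot]:
    """Maximal shared runs of SNP incidence >= ``min_share``.

    IDs are assigned in genome order with an "S" prefix; runs never cross
    chromosome boundaries.
    """
    bp = marker_map["bp"].to_numpy(dtype=np.int64)
    chroms = marker_map["chrom"].astype(str).to_numpy()
    hot = incidence >= min_share
    # break runs at chromosome boundaries
    padded = np.concatenate(([False], hot, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    hotspots = []
    for lo, hi in zip(edges[::2], edges[1::2] - 1):
        sub_lo = lo
        for i in range(lo, hi):
            if chroms[i + 1] != chroms[i]:
                hotspots.append((sub_lo, i))
                sub_lo = i + 1
        hotspots.append((sub_lo, hi))
    out = []
    for k, (lo, hi) in enumerate(h for h in hotspots
                                 if h[1] - h[0] + 1 >= min_snps_hotspot):
        out.append(Hotspot(hotspot_id=f"S{k + 1}", chrom=chroms[lo],
                           start_bp=int(bp[lo]), end_bp=int(bp[hi]),
                           snp_start=int(lo), snp_end=int(hi),
                           n_snps=int(hi - lo + 1)))
    return out


def carrier_matrix(hotspots, segments, sample_ids, marker_map: pd.DataFrame,
                   overlap_fraction: float = 0.5) -> pd.DataFrame:
    """Presence/absence of each hotspot per individual.

    An individual carries a hotspot iff one of its ROH covers at least
    ``overlap_fraction`` of the hotspot's SNPs.  The default of 0.5
    (majority coverage) is robust to the few-SNP endpoint jitter of
    detected runs: a maximal incidence run is strictly wider than any one
    member segment whenever endpoints vary, so requiring full coverage
    would leave genuine sharers uncounted.
    """
    if not 0 < overlap_fraction <= 1:
        raise ValueError("overlap_fraction must lie in (0, 1]")
    blocks = _chrom_blocks(marker_map)
    bp = marker_map["bp"].to_numpy(dtype=np.int64)
    sample_ids = [str(s) for s in sample_ids]
    idx = {s: i for i, s in enumerate(sample_ids)}
    mat = np.zeros((len(sample_ids), len(hotspots)), dtype=bool)
    spans = []
    for seg in segments:
        if seg.sample_id not in idx:
            continue
        lo, hi = _segment_snp_span(seg, blocks, bp)
        spans.append((idx[seg.sample_id], seg.chrom, lo, hi))
    for j, h in enumerate(hotspots):
        need = int(np.ceil(overlap_fraction * h.n_snps))
        for si, chrom, lo, hi in spans:
            if chrom != h.chrom or mat[si, j]:
                continue
            covered = min(hi - 1, h.snp_end) - max(lo, h.snp_start) + 1
            if covered >= need:
                mat[si, j] = True
    return pd.DataFrame(mat, index=pd.Index(sample_ids, name="sample_id"),
                        columns=[h.hotspot_id for h in hotspots])


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for a 2x2 table (probability-mass rule)."""
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be nonnegative")
    if a + b + c + d == 0:
        raise ValueError("all-zero table")
    return float(_scipy_fisher([[a, b], [c, d]], alternative="two-sided")[1])


def associate_hotspots(carriers: pd.DataFrame, groups: pd.Series,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Fisher exact case/control scan over all hotspots.

    ``groups`` maps sample_id -> "case" | "control" and must label every
    individual in ``carriers``; the Bonferroni threshold is alpha over the
    number of hotspots tested.  Returns a table sorted by p.
    """
    groups = groups.astype(str).reindex(carriers.index)
    if groups.isna().any():
        raise ValueError("every individual needs a case/control label")
    is_case = (groups == "case").to_numpy()
    is_ctrl = (groups == "control").to_numpy()
    if not is_case.any() or not is_ctrl.any():
        raise ValueError("both case and control groups must be non-empty")
    m = carriers.shape[1]
    threshold = alpha / m if m else alpha
    rows = []
    for hid in carriers.columns:
        carrier = carriers[hid].to_numpy()
        a = int((carrier & is_case).sum())
        b = int((~carrier & is_case).sum())
        c = int((carrier & is_ctrl).sum())
        d = int((~carrier & is_ctrl).sum())
        p = fisher_exact_2x2(a, b, c, d)
        rows.append({"hotspot_id": hid, "a": a, "b": b, "c": c, "d": d,
                     "p_value": p, "bonferroni_threshold": threshold,
                     "significant": p < threshold})
    return (pd.DataFrame(rows)
            .sort_values("p_value", kind="mergesort")
            .reset_index(drop=True))


def association_results(assoc: pd.DataFrame) -> list[AssociationResult]:
    return [AssociationResult(r.hotspot_id, r.a, r.b, r.c, r.d,
                              r.p_value, r.bonferroni_threshold)
            for r in assoc.itertuples(index=False)]


def manhattan_export(assoc: pd.DataFrame, hotspots) -> pd.DataFrame:
    """Hotspot, chromosome, midpoint bp and -log10 p for plotting."""
    info = {h.hotspot_id: h for h in hotspots}
    rows = []
    for r in assoc.itertuples(index=False):
        h = info[r.hotspot_id]
        rows.append({"hotspot_id": h.hotspot_id, "chrom": h.chrom,
                     "midpoint_bp": h.midpoint_bp,
                     "neg_log10_p": -np.log10(r.p_value)})
    return (pd.DataFrame(rows)
            .sort_values(["chrom", "midpoint_bp"], kind="mergesort")
            .reset_index(drop=True))


def hotspot_table(hotspots, assoc: pd.DataFrame | None = None,
                  gene_counts: dict | None = None) -> pd.DataFrame:
    """Region-style report: hotspot, chrom:start-end, length kb, N_SNP[, ...]."""
    rows = []
    pmap = ({r.hotspot_id: r.p_value for r in assoc.itertuples(index=False)}
            if assoc is not None else {})
    for h in hotspots:
        row = {"hotspot_id": h.hotspot_id,
               "region": f"{h.chrom}:{h.start_bp}-{h.end_bp}",
               "length_kb": round(h.length_kb, 3), "n_snp": h.n_snps}
        if gene_counts is not None:
            row["n_gene"] = gene_counts.get(h.hotspot_id, 0)
        if pmap:
            row["p_value"] = pmap.get(h.hotspot_id, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def snp_assoc_fisher(dataset: GenotypeDataset, groups: pd.Series,
                     region: tuple[str, int, int],
                     alpha: float = 0.05) -> pd.DataFrame:
    """Per-SNP allelic Fisher tests within a candidate region.

    ``region`` is (chrom, start_bp, end_bp), 1-based inclusive.  Each SNP's
    case/control allele counts (missing calls excluded) form the 2x2 table;
    monomorphic SNPs get p = 1 by convention.  The within-region Bonferroni
    threshold is alpha over the number of SNPs tested.
    """
    chrom, start_bp, end_bp = region
    m = dataset.markers
    mask = ((m["chrom"].astype(str) == str(chrom))
            & (m["bp"] >= start_bp) & (m["bp"] <= end_bp)).to_numpy()
    if not mask.any():
        raise ValueError(f"no SNPs in region {chrom}:{start_bp}-{end_bp}")
    groups = groups.astype(str).reindex(
        dataset.samples["sample_id"].astype(str))
    is_case = (groups == "case").to_numpy()
    is_ctrl = (groups == "control").to_numpy()
    idx = np.flatnonzero(mask)
    threshold = alpha / idx.size
    rows = []
    for j in idx:
        g = dataset.genotypes[:, j]
        called = g != MISSING
        case_alt = int(g[called & is_case].sum())
        case_ref = int(2 * (called & is_case).sum() - case_alt)
        ctrl_alt = int(g[called & is_ctrl].sum())
        ctrl_ref = int(2 * (called & is_ctrl).sum() - ctrl_alt)
        if (case_alt + ctrl_alt == 0) or (case_ref + ctrl_ref == 0):
            p = 1.0  # monomorphic
        else:
            p = fisher_exact_2x2(case_alt, case_ref, ctrl_alt, ctrl_ref)
        rows.append({"snp_id": m["snp_id"].iloc[j], "chrom": str(chrom),
                     "bp": int(m["bp"].iloc[j]), "case_alt": case_alt,
                     "case_ref": case_ref, "ctrl_alt": ctrl_alt,
                     "ctrl_ref": ctrl_ref, "p_value": p,
                     "bonferroni_threshold": threshold,
                     "significant": p < threshold})
    return pd.DataFrame(rows)
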