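"""Synthetic genotype/phenotype cohorts with known planted structure.

The generator emulates the statistical features the analysis pipeline
assumes, at reduced marker density:

* dense, evenly spaced autosomal SNP maps with Hardy-Weinberg background
  genotypes (no linkage disequilibrium — planted segments supply all the
  spatial structure the ROH scan needs);
* per-individual autozygous segments in the three length classes
  (1-4, 4-8, >8 Mb), with genotyping error and missingness inside them;
* segment placement concentrated at recurrent "island" loci so that
  consensus regions stay distinct (uniform placement at realistic ROH
  loads makes per-SNP carrier incidence exceed 2 almost everywhere and
  consensus runs merge);
* litter-size phenotypes linear in F_ROH, floored at one lamb;
* one causal homozygous region whose carriers have multiplied odds of
  landing in the low-yield (control) tail — the direction an autozygous
  segment depressing litter size produces.

Every stochastic operation takes an explicit seed or generator; outputs
are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset, write_plink, write_phenotypes

LENGTH_CLASS_RANGES_MB = {"1-4": (1.2, 3.8), "4-8": (4.2, 7.8),
                          ">8": (8.5, 16.0)}


@dataclass(frozen=True)
class CausalHotspotSpec:
    """A homozygous region shifting case/control odds.

    ``low_yield_odds_ratio`` multiplies a carrier's odds of being labelled
    low-yield (control); magnitudes >= 8 give the planted region a
    separation a two-sided Fisher test can detect even with very few
    low-yield animals.
    """

    chrom: str = "1"
    start_bp: int | None = None   # None: centred on the chromosome
    length_mb: float = 1.2
    carrier_frequency: float = 0.4
    low_yield_odds_ratio: float = 16.0


@dataclass(frozen=True)
class SimulationConfig:
    n_individuals: int = 71
    n_chromosomes: int = 26
    snps_per_chromosome: int = 2000
    mean_spacing_bp: int = 10_000
    allele_freq_range: tuple[float, float] = (0.05, 0.5)
    #: mean planted-segment count per individual, per length class
    class_rates: dict = field(default_factory=lambda: {
        "1-4": 3.5, "4-8": 0.5, ">8": 0.12})
    #: fraction of background segments anchored at island loci
    island_fraction: float = 0.9
    n_islands: int = 130
    island_jitter_mb: float = 0.4
    het_error_rate: float = 0.002
    missing_rate: float = 0.01
    beta0: float = 2.1            # lambs at F_ROH = 0
    beta1: float = -0.02          # lambs per 1% inbreeding
    noise_sd: float = 0.3
    n_cases: int = 58
    n_controls: int = 13
    breed: str = "synthetic"
    causal: CausalHotspotSpec | None = None

    def __post_init__(self):
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        for rate in (self.het_error_rate, self.missing_rate,
                     self.island_fraction):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.n_cases + self.n_controls > self.n_individuals:
            raise ValueError("case and control tails overlap")

    @property
    def chrom_length_bp(self) -> int:
        return self.snps_per_chromosome * self.mean_spacing_bp

    @property
    def genome_length_mb(self) -> float:
        return self.n_chromosomes * self.chrom_length_bp / 1e6


@dataclass(frozen=True)
class PlantedSegment:
    sample_id: str
    chrom: str
    start_bp: int   # snapped to the first SNP at/after the drawn start
    end_bp: int     # snapped to the last SNP at/before the drawn end
    length_class: str

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class TruthTable:
    """Ground truth for recovery tests."""

    segments: dict            # sample_id -> [PlantedSegment]
    froh: pd.DataFrame        # realized F by class, from planted lengths
    carrier: pd.Series | None  # causal-hotspot carrier status
    causal_region: tuple | None  # (chrom, start_bp, end_bp)
    config: SimulationConfig

    def realized_f(self, sample_id: str) -> float:
        row = self.froh.loc[self.froh["sample_id"] == sample_id]
        return float(row["f_total"].iloc[0])


def _rng(seed) -> np.random.Generator:
    if seed is None:
        raise ValueError("a seed is required for every stochastic operation")
    return seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)


def simulate_genotypes(config: SimulationConfig, seed) -> GenotypeDataset:
    """Hardy-Weinberg background genotypes on an evenly spaced map.

    Inter-SNP spacing is jittered uniformly within +/-50% of the mean so
    gaps stay well under the ROH density and gap thresholds.
    """
    rng = _rng(seed)
    n, m = config.n_individuals, config.snps_per_chromosome
    chroms, bps = [], []
    for c in range(1, config.n_chromosomes + 1):
        spacing = rng.uniform(0.5, 1.5, size=m) * config.mean_spacing_bp
        pos = np.cumsum(spacing).astype(np.int64)
        chroms.extend([str(c)] * m)
        bps.append(pos)
    bp = np.concatenate(bps)
    n_snps = bp.size
    freq = rng.uniform(*config.allele_freq_range, size=n_snps)
    markers = pd.DataFrame({
        "chrom": chroms,
        "snp_id": [f"snp_{c}_{i}" for c in range(1, config.n_chromosomes + 1)
                   for i in range(m)],
        "cm": 0.0, "bp": bp, "allele1": "A", "allele2": "B", "freq": freq})
    genotypes = rng.binomial(2, freq, size=(n, n_snps)).astype(np.int8)
    samples = pd.DataFrame({
        "sample_id": [f"ind{i:03d}" for i in range(1, n + 1)],
        "breed": config.breed, "als": np.nan, "group": "unassigned"})
    return GenotypeDataset(markers, samples, genotypes)


def _snap_to_snps(bp_chrom: np.ndarray, start: float, end: float):
    lo = int(np.searchsorted(bp_chrom, start, side="left"))
    hi = int(np.searchsorted(bp_chrom, end, side="right")) - 1
    if hi < lo:
        return None
    return int(bp_chrom[lo]), int(bp_chrom[hi]), lo, hi


def _overlaps(existing, chrom, start, end) -> bool:
    return any(s.chrom == chrom and s.start_bp <= end and s.end_bp >= start
               for s in existing)


def _island_centers(config: SimulationConfig, rng) -> list[tuple[str, float]]:
    """Deterministic island loci, evenly spread over the genome."""
    centers = []
    per_chrom = int(np.ceil(config.n_islands / config.n_chromosomes))
    L = config.chrom_length_bp
    for c in range(1, config.n_chromosomes + 1):
        for k in range(per_chrom):
            if len(centers) >= config.n_islands:
                break
            centers.append((str(c), L * (k + 0.5) / per_chrom))
    return centers


def _set_homozygous(dataset, freq, si, lo, hi, rng, het_rate, miss_rate):
    m = hi - lo + 1
    hom = 2 * rng.binomial(1, freq[lo:hi + 1]).astype(np.int8)
    err = rng.random(m) < het_rate
    hom[err] = 1
    mis = rng.random(m) < miss_rate
    hom[mis] = MISSING
    dataset.genotypes[si, lo:hi + 1] = hom


def plant_autozygous_segments(dataset: GenotypeDataset,
                              config: SimulationConfig, seed,
                              exclusion: tuple | None = None
                              ) -> tuple[GenotypeDataset, TruthTable]:
    """Plant per-class autozygous segments and record the truth.

    Segment counts per individual and class are Poisson with the configured
    means; placement is island-anchored with probability
    ``island_fraction``, else uniform.  Segments overlapping an existing
    one of the same individual (or the optional ``exclusion`` interval,
    e.g. a reserved causal region) are redrawn.  Within each planted
    interval genotypes become homozygous (allele chosen by frequency),
    then heterozygote errors and missing calls are injected.
    """
    rng = _rng(seed)
    dataset = GenotypeDataset(dataset.markers, dataset.samples,
                              dataset.genotypes.copy())
    freq = dataset.markers["freq"].to_numpy() if "freq" in dataset.markers \
        else np.full(dataset.n_snps, 0.25)
    chrom_arr = dataset.markers["chrom"].astype(str).to_numpy()
    bp = dataset.markers["bp"].to_numpy(dtype=np.int64)
    blocks = {}
    for c in pd.unique(chrom_arr):
        idx = np.flatnonzero(chrom_arr == c)
        blocks[c] = (idx[0], idx[-1] + 1)
    islands = _island_centers(config, rng)
    if exclusion is not None:
        ex_chrom, ex_start, ex_end = exclusion
        pad = 4e6  # keep islands clear of the reserved region
        islands = [(c, pos) for c, pos in islands
                   if not (c == str(ex_chrom)
                           and ex_start - pad <= pos <= ex_end + pad)]
    L = config.chrom_length_bp
    truth_segments: dict[str, list] = {}
    sample_ids = dataset.samples["sample_id"].astype(str).to_numpy()
    for si, sid in enumerate(sample_ids):
        mine: list[PlantedSegment] = []
        for cls, rate in config.class_rates.items():
            lo_mb, hi_mb = LENGTH_CLASS_RANGES_MB[cls]
            for _ in range(rng.poisson(rate)):
                for _attempt in range(50):
                    length = rng.uniform(lo_mb, hi_mb) * 1e6
                    if length >= L:
                        continue
                    if rng.random() < config.island_fraction and islands:
                        chrom, center = islands[rng.integers(len(islands))]
                        center += rng.uniform(-1, 1) * \
                            config.island_jitter_mb * 1e6
                        start = np.clip(center - length / 2, 1, L - length)
                    else:
                        chrom = str(rng.integers(1, config.n_chromosomes + 1))
                        start = rng.uniform(1, L - length)
                    end = start + length - 1
                    if _overlaps(mine, chrom, start, end):
                        continue
                    if exclusion is not None and str(ex_chrom) == chrom \
                            and start <= ex_end + 2e6 \
                            and end >= ex_start - 2e6:
                        continue
                    b, e = blocks[chrom]
                    snapped = _snap_to_snps(bp[b:e], start, end)
                    if snapped is None:
                        continue
                    s_bp, e_bp, s_i, e_i = snapped
                    seg = PlantedSegment(sid, chrom, s_bp, e_bp, cls)
                    # snapping can nudge the length across a class boundary
                    if not (lo_mb * 1e6 * 0.8 <= seg.length_bp):
                        continue
                    mine.append(seg)
                    _set_homozygous(dataset, freq, si, b + s_i, b + e_i, rng,
                                    config.het_error_rate,
                                    config.missing_rate)
                    break
        truth_segments[sid] = mine
    froh = _truth_froh(truth_segments, sample_ids, config)
    return dataset, TruthTable(segments=truth_segments, froh=froh,
                               carrier=None, causal_region=None,
                               config=config)


def _truth_froh(truth_segments, sample_ids, config) -> pd.DataFrame:
    genome_bp = config.n_chromosomes * config.chrom_length_bp
    rows = []
    for sid in sample_ids:
        by_class = {"1-4": 0, "4-8": 0, ">8": 0}
        for seg in truth_segments.get(sid, []):
            by_class[seg.length_class] += seg.length_bp
        total = sum(by_class.values())
        rows.append({"sample_id": sid,
                     "f_1_4": by_class["1-4"] / genome_bp,
                     "f_4_8": by_class["4-8"] / genome_bp,
                     "f_gt8": by_class[">8"] / genome_bp,
                     "f_total": total / genome_bp})
    return pd.DataFrame(rows)


def plant_causal_hotspot(dataset: GenotypeDataset, truth: TruthTable,
                         config: SimulationConfig, seed
                         ) -> tuple[GenotypeDataset, TruthTable]:
    """Give a random carrier subset a homozygous segment over the causal
    region; carrier status later weights the case/control draw."""
    spec = config.causal
    if spec is None:
        raise ValueError("config.causal is not set")
    rng = _rng(seed)
    dataset = GenotypeDataset(dataset.markers, dataset.samples,
                              dataset.genotypes.copy())
    chrom_arr = dataset.markers["chrom"].astype(str).to_numpy()
    bp = dataset.markers["bp"].to_numpy(dtype=np.int64)
    idx = np.flatnonzero(chrom_arr == str(spec.chrom))
    if idx.size == 0:
        raise ValueError(f"causal chromosome {spec.chrom} not in map")
    region = causal_region_bounds(config, dataset)
    _, start_bp, end_bp = region
    b = idx[0]
    snapped = _snap_to_snps(bp[idx], start_bp, end_bp)
    if snapped is None or snapped[3] - snapped[2] + 1 < 10:
        raise ValueError("causal region must cover at least 10 SNPs")
    s_bp, e_bp, s_i, e_i = snapped
    freq = dataset.markers["freq"].to_numpy() if "freq" in dataset.markers \
        else np.full(dataset.n_snps, 0.25)
    sample_ids = dataset.samples["sample_id"].astype(str).to_numpy()
    carrier = rng.random(len(sample_ids)) < spec.carrier_frequency
    segments = {sid: list(segs) for sid, segs in truth.segments.items()}
    for si, sid in enumerate(sample_ids):
        if not carrier[si]:
            continue
        if _overlaps(segments.get(sid, []), str(spec.chrom), s_bp, e_bp):
            raise ValueError(
                f"{sid}: causal region overlaps an existing planted segment")
        cls = "1-4" if (e_bp - s_bp + 1) < 4e6 else \
            ("4-8" if (e_bp - s_bp + 1) < 8e6 else ">8")
        segments.setdefault(sid, []).append(
            PlantedSegment(sid, str(spec.chrom), s_bp, e_bp, cls))
        _set_homozygous(dataset, freq, si, b + s_i, b + e_i, rng,
                        config.het_error_rate, config.missing_rate)
    froh = _truth_froh(segments, sample_ids, config)
    return dataset, TruthTable(segments=segments, froh=froh,
                               carrier=pd.Series(carrier, index=sample_ids),
                               causal_region=(str(spec.chrom), s_bp, e_bp),
                               config=config)


def causal_region_bounds(config: SimulationConfig,
                         dataset: GenotypeDataset | None = None):
    """(chrom, start_bp, end_bp) of the configured causal region."""
    spec = config.causal
    length = spec.length_mb * 1e6
    start = spec.start_bp if spec.start_bp is not None else \
        int(config.chrom_length_bp / 2 - length / 2)
    return (str(spec.chrom), int(start), int(start + length - 1))


def simulate_phenotypes(truth: TruthTable, config: SimulationConfig, seed
                        ) -> pd.DataFrame:
    """ALS linear in realized F_ROH plus Gaussian noise, floored at one
    lamb; case/control labels from the ALS tails, or — when a causal
    hotspot was planted — from an odds-weighted draw of the low-yield tail
    (carriers' control odds multiplied by the configured odds ratio)."""
    rng = _rng(seed)
    froh = truth.froh
    n = len(froh)
    if config.n_cases + config.n_controls > n:
        raise ValueError("case and control tails overlap")
    als = (config.beta0 + config.beta1 * 100.0 * froh["f_total"].to_numpy()
           + rng.normal(0.0, config.noise_sd, size=n))
    als = np.maximum(als, 1.0)
    group = np.full(n, "unassigned", dtype=object)
    if truth.carrier is not None and config.causal is not None \
            and config.causal.low_yield_odds_ratio != 1.0:
        weights = np.where(truth.carrier.to_numpy(),
                           config.causal.low_yield_odds_ratio, 1.0)
        # weighted sampling without replacement (Gumbel-max trick)
        keys = np.log(weights) + rng.gumbel(size=n)
        controls = np.argsort(-keys)[:config.n_controls]
        group[controls] = "control"
        remaining = np.setdiff1d(np.arange(n), controls)
        # highest-ALS remaining animals form the high-yield tail
        order = remaining[np.argsort(-als[remaining], kind="stable")]
        group[order[:config.n_cases]] = "case"
    else:
        order = np.argsort(als, kind="stable")
        group[order[:config.n_controls]] = "control"
        group[order[::-1][:config.n_cases]] = "case"
    return pd.DataFrame({"sample_id": froh["sample_id"], "breed": config.breed,
                         "als": als, "group": group})


def simulate_froh_cohort(n: int, seed, mean_f: float = 0.093,
                         sd_f: float = 0.146, f_cap: float = 0.62,
                         class_split=(0.35, 0.30, 0.35)) -> pd.DataFrame:
    """Truth-level F_ROH draws with the heavy-tailed moments of a highly
    variable breed (Gamma-distributed total, split across length classes).

    Used for regression studies where genotype-level simulation is not
    needed; the default moments give a right-skewed distribution with a
    small number of strongly inbred animals.
    """
    rng = _rng(seed)
    shape = (mean_f / sd_f) ** 2
    scale = sd_f ** 2 / mean_f
    f = np.minimum(rng.gamma(shape, scale, size=n), f_cap)
    w = np.asarray(class_split, dtype=float)
    w = w / w.sum()
    parts = rng.dirichlet(10 * w, size=n) * f[:, None]
    return pd.DataFrame({
        "sample_id": [f"ind{i:03d}" for i in range(1, n + 1)],
        "f_1_4": parts[:, 0], "f_4_8": parts[:, 1], "f_gt8": parts[:, 2],
        "f_total": f})


def simulate_boundary_fixture(seed, n_individuals: int = 3,
                              n_chromosomes: int = 1,
                              snps_per_chromosome: int = 3000,
                              mean_spacing_bp: int = 10_000,
                              segments_per_chromosome: int = 2,
                              min_run_snps: int = 150,
                              max_run_snps: int = 300,
                              het_errors: bool = True):
    """Fixture for detector-validation studies: planted homozygous runs
    with exactly known SNP boundaries.

    Each planted run (>= ``min_run_snps`` SNPs, so >= ~1.5 Mb at the
    default spacing) carries at most one interior heterozygote error and a
    couple of interior missing calls, and is flanked on both sides by two
    heterozygous calls.  The double-het flanks pin the run's true edges:
    a scan with a one-heterozygote budget must terminate there regardless
    of its internal state, which makes recovery of the exact planted
    bounds the correct answer rather than a lucky one.

    Returns ``(dataset, truth)`` where ``truth`` is a list of
    ``(sample_id, chrom, start_bp, end_bp)`` tuples.
    """
    rng = _rng(seed)
    config = SimulationConfig(
        n_individuals=n_individuals, n_chromosomes=n_chromosomes,
        snps_per_chromosome=snps_per_chromosome,
        mean_spacing_bp=mean_spacing_bp, n_cases=1, n_controls=0)
    dataset = simulate_genotypes(config, rng)
    freq = dataset.markers["freq"].to_numpy()
    bp = dataset.markers["bp"].to_numpy(dtype=np.int64)
    m = snps_per_chromosome
    truth = []
    sample_ids = dataset.samples["sample_id"].astype(str).to_numpy()
    for si, sid in enumerate(sample_ids):
        for c in range(n_chromosomes):
            base = c * m
            used: list[tuple[int, int]] = []
            for _ in range(segments_per_chromosome):
                for _attempt in range(100):
                    k = int(rng.integers(min_run_snps, max_run_snps + 1))
                    lo = int(rng.integers(10, m - k - 10))
                    hi = lo + k - 1
                    # 100-SNP clearance keeps runs cleanly separated
                    if any(lo - 100 <= u_hi and hi + 100 >= u_lo
                           for u_lo, u_hi in used):
                        continue
                    if bp[base + hi] - bp[base + lo] + 1 < 1_500_000:
                        continue
                    used.append((lo, hi))
                    hom = 2 * rng.binomial(
                        1, freq[base + lo:base + hi + 1]).astype(np.int8)
                    if het_errors and rng.random() < 0.5:
                        hom[int(rng.integers(2, k - 2))] = 1
                    for _j in range(int(rng.integers(0, 3))):
                        hom[int(rng.integers(2, k - 2))] = MISSING
                    dataset.genotypes[si, base + lo:base + hi + 1] = hom
                    # double-het flanks pin the true boundaries
                    dataset.genotypes[si, base + lo - 2:base + lo] = 1
                    dataset.genotypes[si, base + hi + 1:base + hi + 3] = 1
                    truth.append((sid, str(c + 1), int(bp[base + lo]),
                                  int(bp[base + hi])))
                    break
    return dataset, truth


def simulate_cohort(config: SimulationConfig, seed
                    ) -> tuple[GenotypeDataset, TruthTable, pd.DataFrame]:
    """Full generative chain: genotypes, planted segments, optional causal
    hotspot, phenotypes.  Sub-seeds are derived from one parent seed."""
    rng = _rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=4)
    dataset = simulate_genotypes(config, int(seeds[0]))
    exclusion = None
    if config.causal is not None:
        exclusion = causal_region_bounds(config, dataset)
    dataset, truth = plant_autozygous_segments(dataset, config,
                                               int(seeds[1]),
                                               exclusion=exclusion)
    if config.causal is not None:
        dataset, truth = plant_causal_hotspot(dataset, truth, config,
                                              int(seeds[2]))
    phenotypes = simulate_phenotypes(truth, config, int(seeds[3]))
    samples = dataset.samples.copy()
    samples["als"] = phenotypes["als"].to_numpy()
    samples["group"] = phenotypes["group"].to_numpy()
    dataset = GenotypeDataset(dataset.markers, samples, dataset.genotypes)
    return dataset, truth, phenotypes


PROFILES = {
    "tiny": SimulationConfig(
        n_individuals=12, n_chromosomes=2, snps_per_chromosome=800,
        mean_spacing_bp=10_000, class_rates={"1-4": 1.0, "4-8": 0.3,
                                             ">8": 0.0},
        island_fraction=0.5, n_islands=4, n_cases=8, n_controls=4,
        breed="tiny"),
    "hu_like": SimulationConfig(causal=CausalHotspotSpec(), breed="hu_like"),
    "null": SimulationConfig(
        causal=CausalHotspotSpec(low_yield_odds_ratio=1.0),
        beta1=0.0, breed="null"),
}


def make_fixture(profile: str, out_dir, seed=0):
    """Write a reproducible PLINK fileset + phenotype table + truth tables.

    Profiles: ``tiny`` (fast smoke fixture), ``hu_like`` (71 ewes, 58
    high-yield vs 13 low-yield, planted depression and causal hotspot),
    ``null`` (no depression, no causal effect).
    """
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; "
                         f"choose from {sorted(PROFILES)}")
    config = PROFILES[profile]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dataset, truth, phenotypes = simulate_cohort(config, seed)
    paths = write_plink(dataset, out_dir / profile)
    write_phenotypes(dataset.samples, out_dir / f"{profile}.phen.tsv")
    truth.froh.to_csv(out_dir / f"{profile}.truth_froh.tsv", sep="\t",
                      index=False)
    seg_rows = [(s.sample_id, s.chrom, s.start_bp, s.end_bp, s.length_class)
                for segs in truth.segments.values() for s in segs]
    pd.DataFrame(seg_rows, columns=["sample_id", "chrom", "start_bp",
                                    "end_bp", "length_class"]).to_csv(
        out_dir / f"{profile}.truth_segments.tsv", sep="\t", index=False)
    paths["phenotypes"] = out_dir / f"{profile}.phen.tsv"
    return dataset, truth, paths
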