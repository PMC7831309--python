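"""Genotype fileset I/O, quality control, and phenotype summaries.

Genotypes are held as a sample-major ``numpy`` matrix of allele2 dosages
(0, 1, 2) with ``-1`` marking missing calls, alongside a marker map and a
sample table (both :class:`pandas.DataFrame`).  The on-disk dialects are the
PLINK 1 binary trio (.bed/.bim/.fam) and diploid-GT VCF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

MISSING = -1  # shared sentinel for .bed and VCF missing calls

_BED_MAGIC = bytes([0x6C, 0x1B])
_MODE_SNP_MAJOR = 0x01

#: .bed 2-bit code (LSB-first pair) -> allele2 dosage
_BED_DECODE = np.array([0, MISSING, 1, 2], dtype=np.int8)
#: allele2 dosage (missing mapped to index 3) -> 2-bit code
_BED_ENCODE = np.array([0b00, 0b10, 0b11, 0b01], dtype=np.uint8)

BIM_COLUMNS = ["chrom", "snp_id", "cm", "bp", "allele1", "allele2"]
FAM_COLUMNS = ["fid", "sample_id", "father", "mother", "sex", "phenotype"]


class FormatError(ValueError):
    """Raised when an on-disk fileset violates its format contract."""


@dataclass
class QCReport:
    """Per-filter removal counts; removed + retained reconcile to input."""

    n_snps_in: int = 0
    n_samples_in: int = 0
    snps_non_autosomal: int = 0
    samples_call_rate: int = 0
    snps_call_rate: int = 0
    snps_maf: int = 0
    snps_hwe: int = 0
    snps_duplicate_position: int = 0
    thresholds: dict = field(default_factory=dict)

    @property
    def n_snps_removed(self) -> int:
        return (self.snps_non_autosomal + self.snps_call_rate
                + self.snps_maf + self.snps_hwe + self.snps_duplicate_position)

    @property
    def n_snps_out(self) -> int:
        return self.n_snps_in - self.n_snps_removed

    @property
    def n_samples_out(self) -> int:
        return self.n_samples_in - self.samples_call_rate

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("snps_input", self.n_snps_in),
            ("snps_non_autosomal", self.snps_non_autosomal),
            ("snps_duplicate_position", self.snps_duplicate_position),
            ("snps_call_rate", self.snps_call_rate),
            ("snps_maf", self.snps_maf),
            ("snps_hwe", self.snps_hwe),
            ("snps_retained", self.n_snps_out),
            ("samples_input", self.n_samples_in),
            ("samples_call_rate", self.samples_call_rate),
            ("samples_retained", self.n_samples_out),
        ]
        return pd.DataFrame(rows, columns=["filter", "count"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class GenotypeDataset:
    """Marker map + sample table + sample-major dosage matrix.

    ``genotypes`` has shape ``(n_samples, n_snps)`` with entries in
    {0, 1, 2, MISSING}; column order matches ``markers`` rows, which are
    sorted by (chromosome, bp).
    """

    markers: pd.DataFrame
    samples: pd.DataFrame
    genotypes: np.ndarray

    def __post_init__(self):
        n_samples, n_snps = self.genotypes.shape
        if len(self.markers) != n_snps or len(self.samples) != n_samples:
            raise ValueError(
                f"genotype matrix {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be 0, 1, 2 or missing")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def sort_markers(self) -> "GenotypeDataset":
        order = self.markers.sort_values(
            ["chrom", "bp"], kind="mergesort").index.to_numpy()
        markers = self.markers.loc[order].reset_index(drop=True)
        return GenotypeDataset(markers, self.samples.reset_index(drop=True),
                               self.genotypes[:, order])


def read_plink(bed_path, bim_path=None, fam_path=None) -> GenotypeDataset:
    """Read a PLINK 1 SNP-major binary fileset.

    ``bim_path``/``fam_path`` default to the .bed path with swapped suffix.
    """
    bed_path = Path(bed_path)
    bim_path = Path(bim_path) if bim_path else bed_path.with_suffix(".bim")
    fam_path = Path(fam_path) if fam_path else bed_path.with_suffix(".fam")

    markers = pd.read_csv(bim_path, sep=r"\s+", names=BIM_COLUMNS,
                          dtype={"chrom": str, "snp_id": str,
                                 "allele1": str, "allele2": str})
    samples = pd.read_csv(fam_path, sep=r"\s+", names=FAM_COLUMNS,
                          dtype={"fid": str, "sample_id": str})
    n_snps, n_samples = len(markers), len(samples)

    raw = bed_path.read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise FormatError(f"{bed_path}: not a PLINK .bed file (bad magic)")
    if raw[2] != _MODE_SNP_MAJOR:
        raise FormatError(
            f"{bed_path}: sample-major (mode 0x{raw[2]:02X}) .bed is not "
            "supported; only SNP-major (mode 0x01)")
    bytes_per_snp = (n_samples + 3) // 4
    expected = 3 + bytes_per_snp * n_snps
    if len(raw) != expected:
        raise FormatError(
            f"{bed_path}: expected {expected} bytes for {n_samples} samples "
            f"x {n_snps} SNPs, found {len(raw)}")

    data = np.frombuffer(raw, dtype=np.uint8, offset=3)
    data = data.reshape(n_snps, bytes_per_snp)
    # unpack 2-bit fields, LSB-first within each byte
    shifts = np.arange(4, dtype=np.uint8) * 2
    codes = (data[:, :, None] >> shifts) & 0b11          # (snp, byte, 4)
    codes = codes.reshape(n_snps, bytes_per_snp * 4)[:, :n_samples]
    genotypes = _BED_DECODE[codes].T.copy()              # sample-major

    ds = GenotypeDataset(markers, samples, genotypes)
    return ds.sort_markers()


def write_plink(dataset: GenotypeDataset, out_prefix) -> dict:
    """Write a SNP-major .bed/.bim/.fam trio; returns the three paths."""
    if dataset.n_samples == 0:
        raise ValueError("refusing to write a zero-sample fileset")
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {ext: out_prefix.with_suffix("." + ext)
             for ext in ("bed", "bim", "fam")}

    markers = dataset.markers
    bim = pd.DataFrame({
        "chrom": markers["chrom"],
        "snp_id": markers["snp_id"],
        "cm": markers["cm"] if "cm" in markers else 0,
        "bp": markers["bp"],
        "allele1": markers.get("allele1", "A"),
        "allele2": markers.get("allele2", "B"),
    })
    bim.to_csv(paths["bim"], sep="\t", header=False, index=False)

    samples = dataset.samples
    fam = pd.DataFrame({
        "fid": samples["fid"] if "fid" in samples else samples["sample_id"],
        "sample_id": samples["sample_id"],
        "father": samples.get("father", 0),
        "mother": samples.get("mother", 0),
        "sex": samples.get("sex", 0),
        "phenotype": samples.get("phenotype", -9),
    })
    fam.to_csv(paths["fam"], sep="\t", header=False, index=False)

    n_samples, n_snps = dataset.genotypes.shape
    g = dataset.genotypes.T  # snp-major
    codes = _BED_ENCODE[np.where(g == MISSING, 3, g)]
    bytes_per_snp = (n_samples + 3) // 4
    padded = np.zeros((n_snps, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n_samples] = codes
    shifts = np.arange(4, dtype=np.uint8) * 2
    packed = (padded.reshape(n_snps, bytes_per_snp, 4)
              << shifts).sum(axis=2).astype(np.uint8)
    with open(paths["bed"], "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_MODE_SNP_MAJOR]))
        fh.write(packed.tobytes())
    return paths


def read_vcf(path) -> GenotypeDataset:
    """Read diploid GT calls from a VCF into a dataset.

    Multi-allelic records are rejected; phase separators are ignored.
    """
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        sample_ids = list(vcf.header.samples)
        rows, geno_cols = [], []
        for rec in vcf:
            if rec.alts is not None and len(rec.alts) > 1:
                raise FormatError(
                    f"{path}: multi-allelic site at {rec.chrom}:{rec.pos}; "
                    "split with bcftools norm first")
            alt = rec.alts[0] if rec.alts else "."
            rows.append((str(rec.chrom), rec.id or f"{rec.chrom}:{rec.pos}",
                         0.0, rec.pos, str(rec.ref), str(alt)))
            col = np.empty(len(sample_ids), dtype=np.int8)
            for j, sample in enumerate(rec.samples.values()):
                gt = sample.get("GT")
                if gt is None or all(a is None for a in gt):
                    col[j] = MISSING
                    continue
                if len(gt) != 2 or any(a is None for a in gt):
                    raise FormatError(
                        f"{path}: non-diploid GT {gt} at {rec.chrom}:{rec.pos}")
                col[j] = gt[0] + gt[1]
            geno_cols.append(col)

    markers = pd.DataFrame(rows, columns=BIM_COLUMNS)
    samples = pd.DataFrame({"sample_id": sample_ids})
    genotypes = (np.stack(geno_cols, axis=1) if geno_cols
                 else np.empty((len(sample_ids), 0), dtype=np.int8))
    return GenotypeDataset(markers, samples, genotypes).sort_markers()


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided exact test of Hardy-Weinberg genotype proportions.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed
    that of the observed count.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("empty genotype table")
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    # attainable het counts share the parity of the rare-allele count
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    rare_hom = (n_rare - hets) // 2
    common_hom = n - hets - rare_hom
    # P(het | allele counts) up to a shared constant:
    #   n! / (hom1! het! hom2!) * 2^het
    logp = (hets * np.log(2) - gammaln(hets + 1)
            - gammaln(rare_hom + 1) - gammaln(common_hom + 1))
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, n_het)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


_AUTOSOME_EXCLUDE = {"X", "Y", "XY", "MT", "M", "0"}


def _is_autosome(chrom: pd.Series) -> np.ndarray:
    labels = chrom.astype(str).str.upper().str.removeprefix("CHR")
    numeric = pd.to_numeric(labels, errors="coerce")
    return ((~labels.isin(_AUTOSOME_EXCLUDE))
            & (numeric.isna() | (numeric >= 1))).to_numpy()


def qc_filter(dataset: GenotypeDataset,
              snp_call_rate: float = 0.9,
              sample_call_rate: float = 0.9,
              maf_min: float = 0.01,
              hwe_p_min: float = 1e-6,
              autosomes_only: bool = True) -> tuple[GenotypeDataset, QCReport]:
    """Apply marker/sample QC in a fixed order.

    Order: non-autosomal markers -> duplicate positions -> sample call rate
    -> SNP call rate -> MAF -> HWE.  The default HWE cutoff of 1e-6 is the
    relaxed threshold appropriate for livestock breeds with unusual
    demographic histories.
    """
    for name, value in (("snp_call_rate", snp_call_rate),
                        ("sample_call_rate", sample_call_rate),
                        ("maf_min", maf_min), ("hwe_p_min", hwe_p_min)):
        if not 0 <= value <= 1:
            raise ValueError(f"{name} must lie in [0, 1], got {value}")

    report = QCReport(n_snps_in=dataset.n_snps, n_samples_in=dataset.n_samples,
                      thresholds={"snp_call_rate": snp_call_rate,
                                  "sample_call_rate": sample_call_rate,
                                  "maf_min": maf_min, "hwe_p_min": hwe_p_min,
                                  "autosomes_only": autosomes_only})
    markers, samples, g = dataset.markers, dataset.samples, dataset.genotypes

    if autosomes_only:
        keep = _is_autosome(markers["chrom"])
        report.snps_non_autosomal = int((~keep).sum())
        markers, g = markers.loc[keep].reset_index(drop=True), g[:, keep]

    dup = markers.duplicated(["chrom", "bp"]).to_numpy()
    if dup.any():
        warnings.warn(f"dropping {dup.sum()} duplicate-position markers "
                      "(keeping first)", stacklevel=2)
        report.snps_duplicate_position = int(dup.sum())
        markers, g = markers.loc[~dup].reset_index(drop=True), g[:, ~dup]

    if g.shape[1]:
        called = g != MISSING
        keep_s = called.mean(axis=1) >= sample_call_rate
        report.samples_call_rate = int((~keep_s).sum())
        samples, g = samples.loc[keep_s].reset_index(drop=True), g[keep_s]
        if len(samples) == 0:
            raise ValueError("sample call-rate filter removed every sample")

        called = g != MISSING
        keep = (called.mean(axis=0) >= snp_call_rate) & called.any(axis=0)
        report.snps_call_rate = int((~keep).sum())
        markers, g = markers.loc[keep].reset_index(drop=True), g[:, keep]

    if g.shape[1]:
        called = g != MISSING
        alt = np.where(called, g, 0).sum(axis=0)
        freq = alt / (2 * called.sum(axis=0))
        maf = np.minimum(freq, 1 - freq)
        keep = maf >= maf_min
        report.snps_maf = int((~keep).sum())
        markers, g = markers.loc[keep].reset_index(drop=True), g[:, keep]

    if g.shape[1] and hwe_p_min > 0:
        keep = np.ones(g.shape[1], dtype=bool)
        for j in range(g.shape[1]):
            col = g[:, j]
            counts = ((col == 0).sum(), (col == 1).sum(), (col == 2).sum())
            keep[j] = hwe_exact_test(*counts) >= hwe_p_min
        report.snps_hwe = int((~keep).sum())
        markers, g = markers.loc[keep].reset_index(drop=True), g[:, keep]

    if g.shape[1] == 0:
        raise ValueError("QC removed every SNP")
    return GenotypeDataset(markers, samples, g.copy()), report


def phenotype_summary(values) -> tuple[float, float, float]:
    """Mean, sample SD and coefficient of variation (percent) of a trait."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two observations")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if mean <= 0:
        raise ValueError("CV undefined for nonpositive mean")
    return mean, sd, 100.0 * sd / mean


def read_phenotypes(path) -> pd.DataFrame:
    """Read the tab-separated phenotype table (sample_id, breed, als, group)."""
    tbl = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "breed": str,
                                             "group": str})
    required = {"sample_id", "breed", "als", "group"}
    missing = required - set(tbl.columns)
    if missing:
        raise FormatError(f"{path}: phenotype table lacks columns {missing}")
    if tbl["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample_ids in phenotype table")
    return tbl


def write_phenotypes(samples: pd.DataFrame, path) -> None:
    cols = ["sample_id", "breed", "als", "group"]
    samples[cols].to_csv(path, sep="\t", index=False)
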