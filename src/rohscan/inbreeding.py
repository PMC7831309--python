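"""Genomic inbreeding coefficients (F_ROH) and inbreeding-depression
regression.

F_ROH is the fraction of the autosomal genome lying inside runs of
homozygosity; splitting segments into the 1-4 Mb, 4-8 Mb and >8 Mb length
classes separates ancient from recent inbreeding.  Depression on litter
size is estimated by ordinary least squares of average litter size (ALS,
lambs per lambing) on F_ROH expressed in percent, so the slope reads as
the change in ALS per 1 percentage-point increase in inbreeding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .roh import LENGTH_CLASSES, classify_roh

#: autosomal genome length (Mb) covered by the ovine HD array map
DEFAULT_GENOME_LENGTH_MB = 2655.71

_CLASS_FIELD = {"1-4": "f_1_4", "4-8": "f_4_8", ">8": "f_gt8"}


@dataclass(frozen=True)
class FrohRecord:
    """Per-individual inbreeding coefficients (dimensionless proportions)."""

    sample_id: str
    f_1_4: float
    f_4_8: float
    f_gt8: float
    f_total: float
    genome_length_mb: float


@dataclass(frozen=True)
class RegressionFit:
    """Univariate OLS fit of ALS on percent inbreeding."""

    measure: str
    beta0: float
    beta1: float
    se_beta1: float
    t_stat: float
    p_value: float
    n: int
    r_squared: float

    @property
    def stars(self) -> str:
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return ""


def compute_froh(segments_for_sample,
                 genome_length_mb: float = DEFAULT_GENOME_LENGTH_MB,
                 sample_id: str | None = None) -> FrohRecord:
    """Total and per-length-class F_ROH for one individual's segments.

    The three classes partition the segments, so the class coefficients
    sum exactly to the total.
    """
    if genome_length_mb <= 0:
        raise ValueError("genome length must be positive")
    segments = list(segments_for_sample)
    if sample_id is None:
        sample_id = segments[0].sample_id if segments else ""
    by_class = dict.fromkeys(LENGTH_CLASSES, 0.0)
    for seg in segments:
        by_class[classify_roh(seg)] += seg.length_mb
    f = {cls: mb / genome_length_mb for cls, mb in by_class.items()}
    return FrohRecord(sample_id=sample_id,
                      f_1_4=f["1-4"], f_4_8=f["4-8"], f_gt8=f[">8"],
                      f_total=f["1-4"] + f["4-8"] + f[">8"],
                      genome_length_mb=genome_length_mb)


def froh_table(segments, samples: pd.DataFrame,
               genome_length_mb: float = DEFAULT_GENOME_LENGTH_MB
               ) -> pd.DataFrame:
    """Per-sample F_ROH table; samples without ROH get zeros."""
    by_sample: dict[str, list] = {
        str(s): [] for s in samples["sample_id"].astype(str)}
    for seg in segments:
        by_sample.setdefault(seg.sample_id, []).append(seg)
    rows = [compute_froh(segs, genome_length_mb, sample_id=sid)
            for sid, segs in by_sample.items()]
    return pd.DataFrame([{
        "sample_id": r.sample_id, "f_1_4": r.f_1_4, "f_4_8": r.f_4_8,
        "f_gt8": r.f_gt8, "f_total": r.f_total} for r in rows])


def regress_depression(froh_values, als_values,
                       measure: str = "all") -> RegressionFit:
    """OLS of ALS on 100*F_ROH with a two-sided t test on the slope.

    ``froh_values`` are proportions for one inbreeding measure (one of the
    length classes or the total); each measure gets its own univariate fit.
    """
    f = np.asarray(froh_values, dtype=float)
    y = np.asarray(als_values, dtype=float)
    if f.shape != y.shape or f.ndim != 1:
        raise ValueError("froh_values and als_values must be equal-length 1-D")
    n = f.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    x = 100.0 * f  # percent scale: slope per 1% inbreeding
    if np.ptp(x) == 0:
        raise ValueError("inbreeding measure has zero variance; "
                         "slope undefined")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionFit(measure=measure,
                         beta0=float(fit.params[0]),
                         beta1=float(fit.params[1]),
                         se_beta1=float(fit.bse[1]),
                         t_stat=float(fit.tvalues[1]),
                         p_value=float(fit.pvalues[1]),
                         n=n, r_squared=float(fit.rsquared))


def depression_report(froh: pd.DataFrame, phenotypes: pd.DataFrame
                      ) -> pd.DataFrame:
    """Fit all four inbreeding measures against ALS and tabulate.

    ``froh`` comes from :func:`froh_table`; ``phenotypes`` carries
    ``sample_id`` and ``als``.  Output mirrors the usual depression table:
    measure, estimate, SE, p, significance stars.
    """
    merged = froh.merge(phenotypes[["sample_id", "als"]].astype(
        {"sample_id": str}), on="sample_id")
    rows = []
    for measure, col in (("1-4", "f_1_4"), ("4-8", "f_4_8"),
                         (">8", "f_gt8"), ("all", "f_total")):
        try:
            fit = regress_depression(merged[col], merged["als"], measure)
        except ValueError:
            rows.append({"measure": measure, "estimate": np.nan,
                         "se": np.nan, "p_value": np.nan, "n": len(merged),
                         "significance": "NA"})
            continue
        rows.append({"measure": measure, "estimate": fit.beta1,
                     "se": fit.se_beta1, "p_value": fit.p_value,
                     "n": fit.n, "significance": fit.stars})
    return pd.DataFrame(rows)
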