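"""Gene-level copy number, signature-exposure distances, and feature summaries.

Gene-level total CN is the overlap-length-weighted mean of the covering
segments' total copy numbers.  Gain/loss calls follow the COSMIC convention
relative to sample ploidy: for average genome ploidy <= 2.7, gain means total
CN >= 5 and loss means total CN = 0; for ploidy > 2.7, gain means total CN
>= 9 and loss means total CN < ploidy - 2.7.

Copy-number-signature heterogeneity per patient is the mean over all
unordered sample pairs of the sum of squared differences between the two
samples' seven-signature exposure vectors (a Euclidean mode takes the square
root per pair).

Phenotypic variation across a patient's deposits is summarized with the
(unscaled) median absolute deviation, and Ki67 proliferative-index scores are
binned into low (0-20%), moderate (21-60%, i.e. >20 to <=60), and high
(>60%) categories.
"""

from __future__ import annotations

import itertools
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .distance import DistanceMatrix
from .errors import ValidationError
from .io import AllelicCNProfile, GeneAnnotation, SampleRecord, metadata_by_sample

logger = logging.getLogger(__name__)

GAIN, LOSS, NEUTRAL = "gain", "loss", "neutral"

#: COSMIC ploidy boundary between the near-diploid and polyploid rules.
COSMIC_PLOIDY_CUT = 2.7


def gene_total_cn(
    p: AllelicCNProfile,
    genes: Sequence[GeneAnnotation],
) -> pd.DataFrame:
    """Overlap-weighted mean total CN per gene for one sample.

    Genes with no overlapping segment get NaN with a logged warning.
    Invariant to splitting segments into equal-state pieces.
    """
    rows = []
    for g in genes:
        total = 0.0
        covered = 0
        for s in p.by_chrom(g.chrom):
            lo, hi = max(s.start, g.start), min(s.end, g.end)
            if lo <= hi:
                total += s.total_cn * (hi - lo + 1)
                covered += hi - lo + 1
        if covered == 0:
            logger.warning("gene %s: no overlapping segment in sample %s",
                           g.gene_symbol, p.sample_id)
            mean_cn = np.nan
        else:
            mean_cn = total / covered
        rows.append({"sample": p.sample_id, "gene": g.gene_symbol, "mean_cn": mean_cn})
    return pd.DataFrame(rows, columns=["sample", "gene", "mean_cn"])


def cosmic_call(mean_total_cn: float, ploidy: float) -> str:
    """COSMIC gain/loss/neutral call relative to sample ploidy."""
    if ploidy <= 0:
        raise ValidationError("ploidy must be > 0")
    if mean_total_cn < 0:
        raise ValidationError("copy number must be >= 0")
    cn = float(mean_total_cn)
    if ploidy <= COSMIC_PLOIDY_CUT:
        if cn >= 5:
            return GAIN
        if cn == 0:
            return LOSS
    else:
        if cn >= 9:
            return GAIN
        if cn < ploidy - COSMIC_PLOIDY_CUT:
            return LOSS
    return NEUTRAL


def gene_cn_table(
    profiles: Sequence[AllelicCNProfile],
    genes: Sequence[GeneAnnotation],
    meta: Sequence[SampleRecord] | Mapping[str, SampleRecord],
) -> pd.DataFrame:
    """Cohort gene-CN table ``sample gene mean_cn call`` (call needs ploidy)."""
    by_sample = meta if isinstance(meta, Mapping) else metadata_by_sample(meta)
    frames = []
    for p in profiles:
        df = gene_total_cn(p, genes)
        rec = by_sample.get(p.sample_id)
        ploidy = rec.ploidy if rec is not None else None
        if ploidy is None:
            logger.warning("sample %s: no ploidy; COSMIC calls omitted", p.sample_id)
            df["call"] = pd.NA
        else:
            df["call"] = [
                cosmic_call(cn, ploidy) if np.isfinite(cn) else pd.NA
                for cn in df["mean_cn"]
            ]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# CN-signature exposures
# ---------------------------------------------------------------------------


def validate_exposures(exposures: pd.DataFrame) -> None:
    """Exposures must be non-negative; warn if rows are not normalized."""
    if (exposures.to_numpy(float) < 0).any():
        raise ValidationError("signature exposures must be non-negative")
    sums = exposures.sum(axis=1)
    off = sums[(sums < 0.99) | (sums > 1.01)]
    if len(off):
        logger.warning("exposure rows not normalized to 1: %s", list(off.index))


def exposure_distance(e1, e2, mode: str = "sum_squared") -> float:
    """Sum of squared differences between two exposure vectors (or its root)."""
    a, b = np.asarray(e1, dtype=float), np.asarray(e2, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"exposure length mismatch: {a.shape} vs {b.shape}")
    ss = float(np.sum((a - b) ** 2))
    if mode == "sum_squared":
        return ss
    if mode == "euclidean":
        return float(np.sqrt(ss))
    raise ValidationError(f"unknown exposure distance mode {mode!r}")


def patient_exposure_heterogeneity(
    exposures: pd.DataFrame,
    meta: Sequence[SampleRecord] | Mapping[str, SampleRecord],
    mode: str = "sum_squared",
) -> pd.DataFrame:
    """Mean pairwise exposure distance per patient.

    Zero iff all of a patient's samples share one exposure vector.  Patients
    with fewer than two profiled samples get NaN.
    """
    by_sample = meta if isinstance(meta, Mapping) else metadata_by_sample(meta)
    validate_exposures(exposures)
    per_patient: dict[str, list[str]] = {}
    for s in exposures.index:
        rec = by_sample.get(str(s))
        if rec is not None:
            per_patient.setdefault(rec.patient_id, []).append(str(s))
    rows = []
    for pid, samples in sorted(per_patient.items()):
        if len(samples) < 2:
            rows.append({"patient": pid, "statistic": f"mean_{mode}_exposure_distance",
                         "value": np.nan, "n_samples": len(samples)})
            continue
        dists = [
            exposure_distance(exposures.loc[s1], exposures.loc[s2], mode=mode)
            for s1, s2 in itertools.combinations(samples, 2)
        ]
        rows.append({"patient": pid, "statistic": f"mean_{mode}_exposure_distance",
                     "value": float(np.mean(dists)), "n_samples": len(samples)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Feature-vs-genomic correlation
# ---------------------------------------------------------------------------


def feature_genomic_correlation(
    fd: DistanceMatrix,
    gd: DistanceMatrix,
    *,
    mode: str = "plain",
    n_perm: int = 999,
    seed: int | None = None,
):
    """Correlate a feature-derived distance matrix with the genomic one.

    ``mode='plain'``: Pearson r over the upper-triangle entries with the
    parametric p-value (appropriate for cohort-level summaries).
    ``mode='mantel'``: same r with a permutation p over sample relabellings
    (appropriate within a patient, where pairs are not independent).
    """
    if mode == "mantel":
        from .spatial import mantel_test

        res = mantel_test(fd, gd, n_perm=n_perm, seed=seed)
        return res.r, res.p
    if mode != "plain":
        raise ValidationError(f"unknown correlation mode {mode!r}")
    if list(fd.sample_ids) != list(gd.sample_ids):
        raise ValidationError("distance matrices must share sample set and order")
    x, y = fd.condensed(), gd.condensed()
    if x.size < 3:
        raise ValidationError("need at least 3 pairs to correlate")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance in distance entries")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Phenotypic summaries
# ---------------------------------------------------------------------------


def mad_summary(values: Iterable[float], *, scaled: bool = False) -> float:
    """Median absolute deviation: median(|x - median(x)|).

    Unscaled by default (no 1.4826 normal-consistency factor);
    ``scaled=True`` applies it.  Fewer than two values -> NaN with a warning.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        logger.warning("MAD needs >= 2 values; returning NaN")
        return float("nan")
    mad = float(np.median(np.abs(x - np.median(x))))
    return mad * 1.4826 if scaled else mad


KI67_LOW, KI67_MODERATE, KI67_HIGH = "low", "moderate", "high"


def ki67_category(pi: float) -> str:
    """Bin a Ki67 proliferative index (%) into low / moderate / high.

    low: 0-20; moderate: >20 to 60; high: >60.  Fractional scores between 20
    and 21 fall in moderate (the bins are intervals, not integer labels).
    """
    if not (0 <= pi <= 100):
        raise ValidationError(f"Ki67 index {pi} outside [0, 100]")
    if pi <= 20:
        return KI67_LOW
    if pi <= 60:
        return KI67_MODERATE
    return KI67_HIGH
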