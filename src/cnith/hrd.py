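"""Homologous-recombination-deficiency genomic scar scores.

Three allele-specific scar components are counted per sample and summed:

* **HRD-LOH** — loss-of-heterozygosity regions (minor allele 0, at least one
  copy retained) longer than 15 Mb that do not span the whole chromosome.
* **LST** — large-scale state transitions: after dropping segments < 3 Mb and
  re-joining, breakpoints between adjacent segments on the same chromosome
  arm whose allele-specific states differ, with both flanks >= 10 Mb and a
  gap of at most 3 Mb.
* **ntAI** — allelic-imbalance regions (major != minor) that reach a
  chromosome end, do not cross the centromere, and do not span the whole
  chromosome.

A sample is called HR-deficient (HRD) when the sum reaches 42, otherwise
HR-proficient (HRP).  Samples with purity (aberrant cell fraction) below 0.3
are not scorable, nor are samples with purity exactly 1 whose three components
are all zero (likely non-aberrant genomes mistaken for pure tumors).

"Chromosome end" means the first or last base covered by the sample's
segmentation on that chromosome — array segmentations rarely reach literal
telomere coordinates.  All size cut-offs are keyword parameters with the
defaults above.  Ploidy plays no role in scar scoring.

The per-patient mixed-status analysis and the ambiguity model quantify how
reliable a single-deposit HR call is: the outcome for each sample is whether
some other deposit from the same patient falls on the opposite side of the
42 cut, modelled by logistic regression on |HRD sum - 42| (the probability of
a contradictory call peaks at the cut, which a monotone-in-score logistic
cannot represent).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._logit import LogitFit, fit_ridge_logit
from .errors import DegenerateOutcomeError, ValidationError
from .io import (
    AllelicCNProfile,
    GenomeCoordinates,
    GenomicSegment,
    SampleRecord,
    coalesce_profile,
    metadata_by_sample,
)

logger = logging.getLogger(__name__)

HRD_SUM_THRESHOLD = 42
HRD, HRP = "HRD", "HRP"

DEFAULT_EXCLUDE_CHROMS = ("X", "chrX", "Y", "chrY")


@dataclass(frozen=True)
class HRDComponents:
    """Scar components, their sum, and the HRD/HRP call."""

    ntai: int
    lst: int
    hrd_loh: int
    hrd_sum: int
    call: str

    def __post_init__(self) -> None:
        if min(self.ntai, self.lst, self.hrd_loh) < 0:
            raise ValidationError("scar components must be >= 0")
        if self.hrd_sum != self.ntai + self.lst + self.hrd_loh:
            raise ValidationError("hrd_sum must equal ntai + lst + hrd_loh")


def hrd_sum_classify(ntai: int, lst: int, hrd_loh: int,
                     threshold: int = HRD_SUM_THRESHOLD) -> HRDComponents:
    total = ntai + lst + hrd_loh
    return HRDComponents(ntai, lst, hrd_loh, total, HRD if total >= threshold else HRP)


# ---------------------------------------------------------------------------
# Run extraction helpers
# ---------------------------------------------------------------------------


def _require_alleles(p: AllelicCNProfile, op: str) -> None:
    if not p.has_alleles:
        raise ValidationError(f"{op}: allele-specific input required "
                              f"(sample {p.sample_id} is total-CN only)")


def _runs(segs: Sequence[GenomicSegment], predicate) -> list[tuple[int, int]]:
    """Maximal runs of physically adjacent (gap 0) segments satisfying predicate."""
    runs: list[tuple[int, int]] = []
    cur: tuple[int, int] | None = None
    prev_end: int | None = None
    for s in segs:
        if predicate(s):
            if cur is not None and prev_end is not None and s.start == prev_end + 1:
                cur = (cur[0], s.end)
            else:
                if cur is not None:
                    runs.append(cur)
                cur = (s.start, s.end)
        else:
            if cur is not None:
                runs.append(cur)
                cur = None
        prev_end = s.end
    if cur is not None:
        runs.append(cur)
    return runs


def _prepare(p: AllelicCNProfile, g: GenomeCoordinates,
             exclude_chroms: Sequence[str]) -> AllelicCNProfile:
    p = coalesce_profile(p.drop_chromosomes(exclude_chroms))
    p.validate_against(g)
    return p


# ---------------------------------------------------------------------------
# Components
# ---------------------------------------------------------------------------


def score_hrd_loh(
    p: AllelicCNProfile,
    g: GenomeCoordinates,
    *,
    min_length: float = 15e6,
    exclude_chroms: Sequence[str] = DEFAULT_EXCLUDE_CHROMS,
) -> int:
    """Count LOH regions longer than ``min_length`` not spanning a whole chromosome."""
    _require_alleles(p, "score_hrd_loh")
    p = _prepare(p, g, exclude_chroms)
    count = 0
    for chrom in p.chromosomes:
        segs = p.by_chrom(chrom)
        first, last = segs[0].start, segs[-1].end
        for start, end in _runs(segs, lambda s: s.n_minor == 0 and s.total_cn >= 1):
            if end - start + 1 > min_length and not (start == first and end == last):
                count += 1
    return count


def score_ntai(
    p: AllelicCNProfile,
    g: GenomeCoordinates,
    *,
    min_length: float = 0.0,
    exclude_chroms: Sequence[str] = DEFAULT_EXCLUDE_CHROMS,
) -> int:
    """Count telomeric allelic-imbalance regions.

    A region qualifies when it reaches the first or last covered base of its
    chromosome, does not cross the centromere interval, and does not span the
    whole chromosome.  ``min_length`` (default 0: no minimum) optionally
    filters short regions.
    """
    _require_alleles(p, "score_ntai")
    p = _prepare(p, g, exclude_chroms)
    count = 0
    for chrom in p.chromosomes:
        if chrom not in g.centromeres:
            raise ValidationError(f"missing centromere for chromosome {chrom!r}")
        cen_start, cen_end = g.centromeres[chrom]
        segs = p.by_chrom(chrom)
        first, last = segs[0].start, segs[-1].end
        for start, end in _runs(segs, lambda s: s.n_major != s.n_minor):
            telomeric = start == first or end == last
            whole = start == first and end == last
            crosses_cen = start < cen_start and end > cen_end
            if telomeric and not whole and not crosses_cen and (end - start + 1) >= min_length:
                count += 1
    return count


def _clip_to_arm(segs: Sequence[GenomicSegment], lo: int, hi: int) -> list[GenomicSegment]:
    out = []
    for s in segs:
        if s.end < lo or s.start > hi:
            continue
        out.append(
            GenomicSegment(s.chrom, max(s.start, lo), min(s.end, hi), s.n_major, s.n_minor)
        )
    return out


def score_lst(
    p: AllelicCNProfile,
    g: GenomeCoordinates,
    *,
    min_segment: float = 3e6,
    min_flank: float = 10e6,
    max_gap: float = 3e6,
    exclude_chroms: Sequence[str] = DEFAULT_EXCLUDE_CHROMS,
) -> int:
    """Count large-scale state transitions per chromosome arm.

    Per arm: clip segments to the arm, merge equal-state neighbours, drop
    segments shorter than ``min_segment``, re-join equal-state neighbours now
    separated by at most ``max_gap``, then count breakpoints between adjacent
    unequal-state segments that are both at least ``min_flank`` long and at
    most ``max_gap`` apart.
    """
    _require_alleles(p, "score_lst")
    p = _prepare(p, g, exclude_chroms)
    count = 0
    for chrom in p.chromosomes:
        if chrom not in g.centromeres:
            raise ValidationError(f"missing centromere for chromosome {chrom!r}")
        for lo, hi in g.arms(chrom):
            if lo > hi:
                continue
            segs = _clip_to_arm(p.by_chrom(chrom), lo, hi)
            # smoothing: drop sub-3Mb segments, then merge equal-state
            # neighbours separated by the gaps the removal created
            segs = [s for s in segs if s.length >= min_segment]
            merged: list[GenomicSegment] = []
            for s in segs:
                if (merged
                        and merged[-1].allele_state == s.allele_state
                        and s.start - merged[-1].end - 1 <= max_gap):
                    merged[-1] = GenomicSegment(
                        s.chrom, merged[-1].start, s.end, s.n_major, s.n_minor
                    )
                else:
                    merged.append(s)
            for left, right in zip(merged[:-1], merged[1:]):
                gap = right.start - left.end - 1
                if (left.allele_state != right.allele_state
                        and left.length >= min_flank
                        and right.length >= min_flank
                        and gap <= max_gap):
                    count += 1
    return count


def score_components(
    p: AllelicCNProfile,
    g: GenomeCoordinates,
    *,
    hrd_threshold: int = HRD_SUM_THRESHOLD,
    exclude_chroms: Sequence[str] = DEFAULT_EXCLUDE_CHROMS,
) -> HRDComponents:
    """All three scar components and the HRD/HRP call for one sample."""
    return hrd_sum_classify(
        score_ntai(p, g, exclude_chroms=exclude_chroms),
        score_lst(p, g, exclude_chroms=exclude_chroms),
        score_hrd_loh(p, g, exclude_chroms=exclude_chroms),
        threshold=hrd_threshold,
    )


# ---------------------------------------------------------------------------
# Scorability filter
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Exclusion:
    sample_id: str
    reason: str


def filter_scorable(
    profiles: Sequence[AllelicCNProfile],
    meta: Sequence[SampleRecord] | Mapping[str, SampleRecord],
    genome: GenomeCoordinates,
    *,
    min_purity: float = 0.3,
) -> tuple[list[AllelicCNProfile], list[Exclusion]]:
    """Apply the scar-scoring sample filters.

    Excluded: samples with purity below ``min_purity``; samples with purity
    exactly 1 whose provisional components are all zero (non-aberrant genome);
    samples with missing purity (treated as failing the filter).  Every
    exclusion is logged with its reason.
    """
    by_sample = meta if isinstance(meta, Mapping) else metadata_by_sample(meta)
    kept, excluded = [], []
    for p in profiles:
        rec = by_sample.get(p.sample_id)
        purity = rec.purity if rec is not None else None
        if purity is None:
            excluded.append(Exclusion(p.sample_id, "purity missing"))
        elif purity < min_purity:
            excluded.append(Exclusion(p.sample_id, f"purity<{min_purity}"))
        elif purity == 1.0:
            comp = score_components(p, genome)
            if comp.hrd_sum == 0:
                excluded.append(
                    Exclusion(p.sample_id, "purity=1 with zero ntAI/LST/HRD-LOH")
                )
            else:
                kept.append(p)
        else:
            kept.append(p)
    for e in excluded:
        logger.info("sample %s excluded from HR scoring: %s", e.sample_id, e.reason)
    if not kept:
        logger.warning("no scorable samples remain after purity filtering")
    return kept, excluded


def score_cohort(
    profiles: Sequence[AllelicCNProfile],
    genome: GenomeCoordinates,
    **kwargs,
) -> pd.DataFrame:
    """HRD component table: one row per sample (``sample ntai lst hrd_loh hrd_sum call``)."""
    rows = []
    for p in profiles:
        c = score_components(p, genome, **kwargs)
        rows.append(
            {"sample": p.sample_id, "ntai": c.ntai, "lst": c.lst,
             "hrd_loh": c.hrd_loh, "hrd_sum": c.hrd_sum, "call": c.call}
        )
    return pd.DataFrame(rows, columns=["sample", "ntai", "lst", "hrd_loh", "hrd_sum", "call"])


# ---------------------------------------------------------------------------
# Patient-level status
# ---------------------------------------------------------------------------

ALL_HRD, ALL_HRP, MIXED = "all_HRD", "all_HRP", "mixed"


@dataclass(frozen=True)
class PatientHRStatus:
    patient_id: str
    status: str
    sample_calls: Mapping[str, str]


def patient_hr_status(
    calls: Mapping[str, str],
    meta: Sequence[SampleRecord] | Mapping[str, SampleRecord],
) -> dict[str, PatientHRStatus]:
    """Group per-sample HRD/HRP calls into per-patient status.

    A patient is ``mixed`` iff both calls occur among their scored samples;
    single-sample patients can never be mixed.
    """
    by_sample = meta if isinstance(meta, Mapping) else metadata_by_sample(meta)
    per_patient: dict[str, dict[str, str]] = {}
    for s, call in calls.items():
        rec = by_sample.get(s)
        if rec is None:
            raise ValidationError(f"scored sample {s!r} has no metadata")
        per_patient.setdefault(rec.patient_id, {})[s] = call
    out = {}
    for pid, sample_calls in per_patient.items():
        values = set(sample_calls.values())
        status = MIXED if len(values) == 2 else (ALL_HRD if HRD in values else ALL_HRP)
        out[pid] = PatientHRStatus(pid, status, sample_calls)
    return out


# ---------------------------------------------------------------------------
# Ambiguity model (Model -> fit() -> Results)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AmbiguityResults:
    """Logistic model of contradictory HR calls vs distance from the 42 cut.

    The outcome for each sample is 1 iff some other sample from the same
    patient lies strictly on the opposite side of the threshold.  The
    covariate is |HRD sum - threshold|, so the predicted probability is
    maximal at the threshold by construction.
    """

    intercept: float
    slope: float
    threshold: int
    fit: LogitFit
    raw_score_fit: LogitFit
    n_samples: int
    n_discordant: int

    def predict(self, hrd_sum) -> np.ndarray:
        return self.fit.predict(np.abs(np.asarray(hrd_sum, dtype=float) - self.threshold))

    def curve(self, scores: Iterable[int] | None = None) -> pd.DataFrame:
        if scores is None:
            scores = np.arange(0, 2 * self.threshold + 1)
        scores = np.asarray(list(scores))
        return pd.DataFrame({"hrd_sum": scores, "p_contradictory": self.predict(scores)})

    def summary(self) -> str:
        lines = [
            "HR-status ambiguity model (logistic on |HRD sum - 42|)",
            "=" * 58,
            f"{'n scored samples':<34}{self.n_samples:>12}",
            f"{'n with contradictory partner':<34}{self.n_discordant:>12}",
            f"{'intercept':<34}{self.intercept:>12.4f}",
            f"{'slope (per score unit)':<34}{self.slope:>12.4f}",
            f"{'P(contradiction) at the cut':<34}{float(self.predict(self.threshold)):>12.3f}",
            f"{'LR test p (slope)':<34}{self.fit.lr_pvalue:>12.3g}",
            "=" * 58,
        ]
        return "\n".join(lines)


class AmbiguityModel:
    """Quantifies how ambiguous a single-deposit HR call is for a patient.

    ``scores`` maps sample_id -> HRD sum; patient grouping comes from the
    metadata.  Patients contribute an outcome per sample: whether any other
    same-patient sample falls on the opposite side of the threshold.
    """

    def __init__(
        self,
        scores: Mapping[str, int],
        meta: Sequence[SampleRecord] | Mapping[str, SampleRecord],
        *,
        threshold: int = HRD_SUM_THRESHOLD,
        ridge: float = 1e-4,
    ) -> None:
        by_sample = meta if isinstance(meta, Mapping) else metadata_by_sample(meta)
        per_patient: dict[str, list[str]] = {}
        for s in scores:
            rec = by_sample.get(s)
            if rec is None:
                raise ValidationError(f"scored sample {s!r} has no metadata")
            per_patient.setdefault(rec.patient_id, []).append(s)
        if not any(len(v) >= 2 for v in per_patient.values()):
            raise ValidationError(
                "ambiguity model needs at least one patient with >= 2 scored samples"
            )
        rows = []
        for pid, samples in per_patient.items():
            sides = {s: scores[s] >= threshold for s in samples}
            for s in samples:
                contradictory = any(sides[o] != sides[s] for o in samples if o != s)
                rows.append({"sample": s, "patient": pid, "hrd_sum": scores[s],
                             "outcome": int(contradictory)})
        self.data = pd.DataFrame(rows)
        self.threshold = threshold
        self.ridge = ridge

    def fit(self) -> AmbiguityResults:
        y = self.data["outcome"].to_numpy(float)
        if y.min() == y.max():
            raise DegenerateOutcomeError(
                "all ambiguity outcomes identical; cannot fit a logistic model"
            )
        score = self.data["hrd_sum"].to_numpy(float)
        x = np.abs(score - self.threshold)
        fit = fit_ridge_logit(x, y, ridge=self.ridge)
        raw_fit = fit_ridge_logit(score, y, ridge=self.ridge)
        if np.sign(raw_fit.slope) != np.sign(fit.slope):
            logger.info(
                "raw-score and distance-from-cut ambiguity fits disagree in sign; "
                "both are reported in the results object"
            )
        return AmbiguityResults(
            intercept=fit.intercept,
            slope=fit.slope,
            threshold=self.threshold,
            fit=fit,
            raw_score_fit=raw_fit,
            n_samples=len(y),
            n_discordant=int(y.sum()),
        )


def fit_ambiguity_model(scores, meta, **kwargs) -> AmbiguityResults:
    """Convenience wrapper: ``AmbiguityModel(scores, meta, **kwargs).fit()``."""
    return AmbiguityModel(scores, meta, **kwargs).fit()
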