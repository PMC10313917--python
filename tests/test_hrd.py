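import numpy as np
import pytest

from cnith.errors import DegenerateOutcomeError, ValidationError
from cnith.hrd import (
    AmbiguityModel,
    filter_scorable,
    fit_ambiguity_model,
    hrd_sum_classify,
    patient_hr_status,
    score_components,
    score_hrd_loh,
    score_lst,
    score_ntai,
)
from cnith.io import SampleRecord

from conftest import profile

MB = 1_000_000

# mb_genome fixture: chrom 1 = 100 Mb, centromere 45-50 Mb;
# chrom 2 = 150 Mb, centromere 70-75 Mb.


def _fill(chrom, segments, length):
    """Pad explicit segments with heterozygous diploid (1,1) to full coverage."""
    out, pos = [], 1
    for start, end, nmaj, nmin in segments:
        if start > pos:
            out.append((chrom, pos, start - 1, 1, 1))
        out.append((chrom, start, end, nmaj, nmin))
        pos = end + 1
    if pos <= length:
        out.append((chrom, pos, length, 1, 1))
    return out


def _single_chrom_profile(segments, length=100 * MB, chrom="1"):
    return profile("S", _fill(chrom, segments, length))


# ---------------------------------------------------------------------------
# HRD-LOH
# ---------------------------------------------------------------------------


def test_hrd_loh_counts_long_subchromosomal_regions(mb_genome):
    p = _single_chrom_profile([(10 * MB, 30 * MB - 1, 2, 0)])  # 20 Mb LOH
    assert score_hrd_loh(p, mb_genome) == 1


def test_hrd_loh_ignores_whole_chromosome_and_short(mb_genome):
    whole = profile("S", [("1", 1, 100 * MB, 1, 0)])
    assert score_hrd_loh(whole, mb_genome) == 0
    short = _single_chrom_profile([(10 * MB, 20 * MB - 1, 2, 0)])  # 10 Mb
    assert score_hrd_loh(short, mb_genome) == 0


def test_hrd_loh_merges_adjacent_loh_states(mb_genome):
    # 10 Mb at (1,0) + adjacent 10 Mb at (2,0): one 20 Mb LOH run
    p = _single_chrom_profile([(10 * MB, 20 * MB - 1, 1, 0),
                               (20 * MB, 30 * MB - 1, 2, 0)])
    assert score_hrd_loh(p, mb_genome) == 1


def test_hrd_loh_requires_retained_copy(mb_genome):
    # homozygous deletion (0,0) is not LOH with retention
    p = _single_chrom_profile([(10 * MB, 30 * MB - 1, 0, 0)])
    assert score_hrd_loh(p, mb_genome) == 0


def test_allele_operations_refuse_total_only(mb_genome):
    p = profile("S", [("1", 1, 100 * MB, 2)])
    for fn in (score_hrd_loh, score_lst, score_ntai):
        with pytest.raises(ValidationError, match="allele-specific"):
            fn(p, mb_genome)


# ---------------------------------------------------------------------------
# LST
# ---------------------------------------------------------------------------


def test_lst_transition_on_one_arm(mb_genome):
    # q arm of chrom 1 runs 50-100 Mb: two adjacent 20 Mb segments, distinct states
    p = profile("S", _fill("1", [(55 * MB, 75 * MB - 1, 2, 1),
                                 (75 * MB, 95 * MB - 1, 3, 1)], 100 * MB))
    assert score_lst(p, mb_genome) == 1


def test_lst_not_counted_across_centromere(mb_genome):
    # state change exactly at the centromere: flanks on different arms
    p = profile("S", [("1", 1, 45 * MB - 1, 2, 1),
                      ("1", 45 * MB, 100 * MB, 3, 1)])
    assert score_lst(p, mb_genome) == 0


def test_lst_smoothing_removes_small_blip(mb_genome):
    # 2 Mb blip between two identical 20 Mb segments: smoothed away
    p = profile("S", _fill("1", [
        (55 * MB, 75 * MB - 1, 2, 1),
        (75 * MB, 77 * MB - 1, 5, 2),
        (77 * MB, 97 * MB - 1, 2, 1),
    ], 100 * MB))
    assert score_lst(p, mb_genome) == 0


def test_lst_short_flank_not_counted(mb_genome):
    # second segment only 8 Mb: below the 10 Mb flank requirement
    p = profile("S", _fill("1", [(55 * MB, 85 * MB - 1, 2, 1),
                                 (85 * MB, 93 * MB - 1, 3, 1)], 100 * MB))
    assert score_lst(p, mb_genome) == 0


def test_lst_missing_centromere_errors():
    from cnith.io import GenomeCoordinates

    g = GenomeCoordinates({"1": 100 * MB}, {})
    p = profile("S", [("1", 1, 100 * MB, 2, 1)])
    with pytest.raises(ValidationError, match="centromere"):
        score_lst(p, g)


# ---------------------------------------------------------------------------
# ntAI
# ---------------------------------------------------------------------------


def test_ntai_telomeric_imbalance(mb_genome):
    # AI from the p-telomere ending before the centromere
    p = _single_chrom_profile([(1, 20 * MB, 2, 1)])
    # (1,1) elsewhere is balanced; (2,1) run touches the first covered base
    assert score_ntai(p, mb_genome) == 1


def test_ntai_interstitial_not_counted(mb_genome):
    p = _single_chrom_profile([(30 * MB, 40 * MB, 2, 1)])
    assert score_ntai(p, mb_genome) == 0


def test_ntai_whole_chromosome_excluded(mb_genome):
    p = profile("S", [("1", 1, 100 * MB, 2, 1)])
    assert score_ntai(p, mb_genome) == 0


def test_ntai_centromere_crossing_excluded(mb_genome):
    # AI from p-telomere through the centromere into the q arm
    p = _single_chrom_profile([(1, 60 * MB, 2, 1)])
    assert score_ntai(p, mb_genome) == 0
    # both telomeres of chrom 1 imbalanced but interrupted: 2 regions
    p2 = _single_chrom_profile([(1, 20 * MB, 2, 1), (80 * MB, 100 * MB, 3, 1)])
    assert score_ntai(p2, mb_genome) == 2


def test_ntai_end_means_covered_extent(mb_genome):
    # segmentation stops at 95 Mb; AI run ending there is telomeric
    p = profile("S", [("1", 1, 80 * MB - 1, 1, 1), ("1", 80 * MB, 95 * MB, 2, 1)])
    assert score_ntai(p, mb_genome) == 1


# ---------------------------------------------------------------------------
# classification, filters, patient status
# ---------------------------------------------------------------------------


def test_hrd_sum_classification_boundary():
    assert hrd_sum_classify(10, 20, 12).call == "HRD"
    assert hrd_sum_classify(10, 20, 11).call == "HRP"
    assert hrd_sum_classify(0, 0, 0).call == "HRP"
    with pytest.raises(ValidationError):
        hrd_sum_classify(-1, 0, 0)


def test_diploid_heterozygous_genome_scores_zero(mb_genome):
    p = profile("S", [("1", 1, 100 * MB, 1, 1), ("2", 1, 150 * MB, 1, 1)])
    comp = score_components(p, mb_genome)
    assert (comp.ntai, comp.lst, comp.hrd_loh, comp.call) == (0, 0, 0, "HRP")


def test_scar_scores_invariant_to_splitting(mb_genome):
    rng = np.random.default_rng(21)
    base = profile("S", _fill("1", [
        (1, 20 * MB, 3, 1),
        (55 * MB, 75 * MB - 1, 2, 0),
        (75 * MB, 95 * MB - 1, 3, 1),
    ], 100 * MB))
    ref = (score_ntai(base, mb_genome), score_lst(base, mb_genome),
           score_hrd_loh(base, mb_genome))
    for _ in range(25):
        segs = []
        for s in base.segments:
            if s.length > 2 and rng.random() < 0.7:
                cut = int(rng.integers(s.start + 1, s.end))
                segs += [(s.chrom, s.start, cut, s.n_major, s.n_minor),
                         (s.chrom, cut + 1, s.end, s.n_major, s.n_minor)]
            else:
                segs.append((s.chrom, s.start, s.end, s.n_major, s.n_minor))
        split = profile("S", segs)
        assert (score_ntai(split, mb_genome), score_lst(split, mb_genome),
                score_hrd_loh(split, mb_genome)) == ref


def test_additional_loh_region_increments_by_one(mb_genome):
    p1 = profile("S", _fill("1", [(10 * MB, 30 * MB - 1, 2, 0)], 100 * MB)
                 + _fill("2", [], 150 * MB))
    p2 = profile("S", _fill("1", [(10 * MB, 30 * MB - 1, 2, 0)], 100 * MB)
                 + _fill("2", [(80 * MB, 110 * MB, 2, 0)], 150 * MB))
    assert score_hrd_loh(p2, mb_genome) == score_hrd_loh(p1, mb_genome) + 1
    # untouched chromosome 1 contributes identically; the new interstitial
    # region may add LST on its own chromosome but never removes any
    assert score_ntai(p2, mb_genome) == score_ntai(p1, mb_genome)
    assert score_lst(p2, mb_genome) >= score_lst(p1, mb_genome)


def test_filter_scorable_rules(mb_genome):
    diploid = lambda s: profile(s, [("1", 1, 100 * MB, 1, 1)])
    scarred = profile("pure_scarred", _fill("1", [(10 * MB, 30 * MB, 2, 0)], 100 * MB))
    profiles = [diploid("low"), diploid("edge"), diploid("pure_flat"),
                scarred, diploid("nopurity")]
    meta = [
        SampleRecord("low", "P1", "primary", purity=0.25),
        SampleRecord("edge", "P1", "primary", purity=0.31),
        SampleRecord("pure_flat", "P2", "primary", purity=1.0),
        SampleRecord("pure_scarred", "P2", "primary", purity=1.0),
        SampleRecord("nopurity", "P3", "primary"),
    ]
    kept, excluded = filter_scorable(profiles, meta, mb_genome)
    assert {p.sample_id for p in kept} == {"edge", "pure_scarred"}
    reasons = {e.sample_id: e.reason for e in excluded}
    assert reasons["low"] == "purity<0.3"
    assert "zero" in reasons["pure_flat"]
    assert "missing" in reasons["nopurity"]


def test_patient_hr_status_grouping():
    meta = [SampleRecord(s, p, "primary") for s, p in
            [("a", "P1"), ("b", "P1"), ("c", "P2"), ("d", "P3"), ("e", "P3")]]
    status = patient_hr_status(
        {"a": "HRD", "b": "HRD", "c": "HRP", "d": "HRD", "e": "HRP"}, meta)
    assert status["P1"].status == "all_HRD"
    assert status["P2"].status == "all_HRP"
    assert status["P3"].status == "mixed"


# ---------------------------------------------------------------------------
# ambiguity model
# ---------------------------------------------------------------------------


def _ambiguity_cohort():
    """Near-42 patients discordant, far patients concordant."""
    scores, meta = {}, []
    rng = np.random.default_rng(5)
    for i in range(30):
        pid = f"N{i}"   # near the cut, straddling it
        vals = (41 - rng.integers(0, 4), 43 + rng.integers(0, 4))
        for j, v in enumerate(vals):
            s = f"{pid}_{j}"
            scores[s] = int(v)
            meta.append(SampleRecord(s, pid, "primary"))
    for i in range(30):
        pid = f"F{i}"   # far from the cut, concordant
        base = int(rng.choice([5, 80]))
        for j in range(2):
            s = f"{pid}_{j}"
            scores[s] = base + int(rng.integers(0, 5))
            meta.append(SampleRecord(s, pid, "primary"))
    return scores, meta


def test_ambiguity_probability_peaks_at_cut():
    scores, meta = _ambiguity_cohort()
    res = fit_ambiguity_model(scores, meta)
    assert res.slope < 0  # contradiction less likely far from the cut
    p42 = float(res.predict(42))
    for other in (0, 20, 41, 43, 60, 100):
        assert p42 >= float(res.predict(other))
    curve = res.curve()
    assert curve["p_contradictory"].between(0, 1).all()
    assert "42" in res.summary()


def test_ambiguity_degenerate_and_single_sample_errors():
    meta = [SampleRecord("a", "P1", "primary"), SampleRecord("b", "P2", "primary")]
    with pytest.raises(ValidationError, match=">= 2 scored"):
        AmbiguityModel({"a": 50, "b": 30}, meta)
    meta2 = [SampleRecord(s, "P1", "primary") for s in ("a", "b")]
    with pytest.raises(DegenerateOutcomeError):
        AmbiguityModel({"a": 50, "b": 55}, meta2).fit()
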