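"""Forward simulator for multi-site copy-number cohorts with known truth.

Each patient starts from a diploid heterozygous genome.  A binary clone tree
is generated (caterpillar for a sympodial target, maximally balanced for a
dichotomous one, or uniform over labelled topologies); truncal events are
applied at the root, clone-private events along each edge, and every emitted
sample inherits its clone's profile plus sample-private noise events.  Events
are interval copy-number changes on one parental allele (a configurable
fraction produce LOH, half of those copy-neutral), composing additively and
clipped at zero copies — no back-mutation, so the generative event count is
the analogue of the CN-event distance the pipeline estimates.

Relapse samples are drawn under three scenarios: type 1 — a monoclonal
patient whose relapse deposits come from the single clone; type 2 — relapse
deposits drawn from the patient's existing primary clones; type 3 — relapse
deposits from a fresh clone branched off the tree with its own private
events.

Each clone has a home cell on the 3x3 IMO grid; a sample is placed in its
clone's home cell with probability ``spatial_concordance`` and uniformly at
random otherwise.  Signature-exposure vectors are drawn from clone-specific
Dirichlet means.  Purity is drawn per sample and recorded in the metadata but
does not dilute the integer clonal copy-number states (the pipeline consumes
ASCAT-style clonal integers); ``dilute_and_round=True`` adds a
rounding-after-dilution mode for robustness testing.

The default genome is a reduced three-chromosome model (100/150/200 Mb) for
desk-scale speed; :func:`grch37_genome` provides the full autosome table.
All randomness flows from the single config seed: identical config and seed
give byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import (
    AllelicCNProfile,
    GenomeCoordinates,
    GenomicSegment,
    SampleRecord,
    coalesce_profile,
    write_genome,
    write_metadata,
    write_segment_table,
)

logger = logging.getLogger(__name__)

N_SIGNATURES = 7
IMO_CELLS = tuple(f"{c}{r}" for c in "ABC" for r in "123")


def reduced_genome() -> GenomeCoordinates:
    """Three-chromosome desk-scale genome (100/150/200 Mb)."""
    return GenomeCoordinates(
        chrom_lengths={"1": 100_000_000, "2": 150_000_000, "3": 200_000_000},
        centromeres={
            "1": (45_000_000, 50_000_000),
            "2": (70_000_000, 75_000_000),
            "3": (95_000_000, 100_000_000),
        },
    )


#: GRCh37 autosome lengths and centromere intervals (Mb resolution).
_GRCH37 = {
    "1": (249_250_621, 121_500_000, 128_900_000),
    "2": (243_199_373, 90_500_000, 96_800_000),
    "3": (198_022_430, 87_900_000, 93_900_000),
    "4": (191_154_276, 48_200_000, 52_700_000),
    "5": (180_915_260, 46_100_000, 50_700_000),
    "6": (171_115_067, 58_700_000, 63_300_000),
    "7": (159_138_663, 58_000_000, 61_700_000),
    "8": (146_364_022, 43_100_000, 48_100_000),
    "9": (141_213_431, 47_300_000, 50_700_000),
    "10": (135_534_747, 38_000_000, 42_300_000),
    "11": (135_006_516, 51_600_000, 55_700_000),
    "12": (133_851_895, 33_300_000, 38_200_000),
    "13": (115_169_878, 16_300_000, 19_500_000),
    "14": (107_349_540, 16_100_000, 19_100_000),
    "15": (102_531_392, 15_800_000, 20_700_000),
    "16": (90_354_753, 34_600_000, 38_600_000),
    "17": (81_195_210, 22_200_000, 25_800_000),
    "18": (78_077_248, 15_400_000, 19_000_000),
    "19": (59_128_983, 24_400_000, 28_600_000),
    "20": (63_025_520, 25_600_000, 29_400_000),
    "21": (48_129_895, 10_900_000, 14_300_000),
    "22": (51_304_566, 12_200_000, 17_900_000),
}


def grch37_genome() -> GenomeCoordinates:
    """GRCh37 autosomes with approximate centromere intervals."""
    return GenomeCoordinates(
        chrom_lengths={c: v[0] for c, v in _GRCH37.items()},
        centromeres={c: (v[1], v[2]) for c, v in _GRCH37.items()},
    )


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

TREE_SHAPES = ("sympodial", "dichotomous", "random")
SCENARIOS = ("none", "type1", "type2", "type3")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate a 49-patient multi-site cohort with 4-15 deposits per
    patient and 2-3 clones.  Clone-edge event counts dominate the truncal
    load so that distinct clones within a patient are nearly as divergent as
    deposits from different patients — the regime in which a cohort-derived
    inter-patient threshold can separate clones at all.
    """

    n_patients: int = 49
    samples_per_patient: tuple[int, int] = (4, 15)
    clones_per_patient: tuple[int, int] = (2, 3)
    tree_shape: str = "random"
    n_truncal_events: int = 10
    n_clone_events: int = 40
    n_sample_noise_events: int = 3
    event_length_range: tuple[float, float] = (1e6, 5e7)
    loh_fraction: float = 0.3
    terminal_fraction: float = 0.4
    relapse_scenario: str = "none"
    n_relapse_samples: int = 2
    spatial_concordance: float = 0.5
    purity_range: tuple[float, float] = (0.35, 0.95)
    exposure_concentration: float = 100.0
    dilute_and_round: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        for name in ("samples_per_patient", "clones_per_patient"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ValidationError(f"{name} range ({lo}, {hi}) is empty or invalid")
        if self.tree_shape not in TREE_SHAPES:
            raise ValidationError(f"tree_shape must be one of {TREE_SHAPES}")
        if self.relapse_scenario not in SCENARIOS:
            raise ValidationError(f"relapse_scenario must be one of {SCENARIOS}")
        if not (0.0 <= self.spatial_concordance <= 1.0):
            raise ValidationError("spatial_concordance must be in [0, 1]")
        if not (0.0 <= self.loh_fraction <= 1.0):
            raise ValidationError("loh_fraction must be in [0, 1]")
        if not (0.0 <= self.terminal_fraction <= 1.0):
            raise ValidationError("terminal_fraction must be in [0, 1]")
        if min(self.n_truncal_events, self.n_clone_events,
               self.n_sample_noise_events, self.n_relapse_samples) < 0:
            raise ValidationError("event and sample counts must be >= 0")
        if self.relapse_scenario == "type2" and self.clones_per_patient[1] < 2:
            raise ValidationError(
                "infeasible scenario: type2 relapse requires >= 2 clones per patient"
            )


# ---------------------------------------------------------------------------
# Clone trees
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CloneTree:
    """Rooted binary tree over clone labels 1..k (nested-tuple topology)."""

    topology: object  # int leaf label, or (left, right) tuple

    def leaves(self) -> list[int]:
        out: list[int] = []

        def walk(node):
            if isinstance(node, tuple):
                walk(node[0])
                walk(node[1])
            else:
                out.append(node)

        walk(self.topology)
        return out

    def to_newick(self) -> str:
        def render(node):
            if isinstance(node, tuple):
                return f"({render(node[0])},{render(node[1])})"
            return f"clone{node}"

        return render(self.topology) + ";"

    def edges(self) -> list[tuple[object, object]]:
        """(parent, child) pairs; nodes are nested tuples or leaf labels."""
        out = []

        def walk(node):
            if isinstance(node, tuple):
                for child in node:
                    out.append((node, child))
                    walk(child)

        walk(self.topology)
        return out


def simulate_clone_tree(k: int, shape: str, rng: np.random.Generator) -> CloneTree:
    """Binary tree over ``k`` clone labels with the requested shape.

    ``sympodial``: caterpillar/ladder.  ``dichotomous``: maximally balanced
    (exact for powers of two); requires k >= 4, else coerced to random with a
    warning.  ``random``: uniform over rooted labelled topologies (random
    leaf insertion).
    """
    if k < 1:
        raise ValidationError("need at least one clone")
    if shape not in TREE_SHAPES:
        raise ValidationError(f"unknown tree shape {shape!r}")
    if k == 1:
        return CloneTree(1)
    if shape == "dichotomous" and k < 4:
        logger.warning("dichotomous shape needs >= 4 clones; using random topology")
        shape = "random"
    labels = list(range(1, k + 1))
    if shape == "sympodial":
        node: object = (labels[0], labels[1])
        for lab in labels[2:]:
            node = (node, lab)
        return CloneTree(node)
    if shape == "dichotomous":

        def balanced(ls: list[int]):
            if len(ls) == 1:
                return ls[0]
            mid = (len(ls) + 1) // 2
            return (balanced(ls[:mid]), balanced(ls[mid:]))

        return CloneTree(balanced(labels))
    # random: sequential uniform insertion (every node an attachment point)
    tree: object = labels[0]
    for lab in labels[1:]:
        nodes: list[tuple] = []  # (parent, index) of every node; None parent = root

        def collect(node, parent, idx):
            nodes.append((parent, idx, node))
            if isinstance(node, tuple):
                collect(node[0], node, 0)
                collect(node[1], node, 1)

        collect(tree, None, 0)
        parent, idx, target = nodes[rng.integers(len(nodes))]
        new = (target, lab)
        if parent is None:
            tree = new
        else:
            tree = _replace_child(tree, target, new)
    return CloneTree(tree)


def _replace_child(tree, old, new):
    if tree is old:
        return new
    if not isinstance(tree, tuple):
        return tree
    left = _replace_child(tree[0], old, new)
    if left is not tree[0]:
        return (left, tree[1])
    return (tree[0], _replace_child(tree[1], old, new))


# ---------------------------------------------------------------------------
# Genome state and events
# ---------------------------------------------------------------------------

# per-chromosome state: list of [start, end, copies_allele_A, copies_allele_B]
State = dict


def _diploid_state(genome: GenomeCoordinates) -> State:
    return {c: [[1, length, 1, 1]] for c, length in genome.chrom_lengths.items()}


def _copy_state(state: State) -> State:
    return {c: [seg.copy() for seg in segs] for c, segs in state.items()}


def _split_at(segs: list, pos: int) -> None:
    """Ensure ``pos`` is a segment start (split the covering segment)."""
    for i, (s, e, a, b) in enumerate(segs):
        if s < pos <= e:
            segs[i] = [s, pos - 1, a, b]
            segs.insert(i + 1, [pos, e, a, b])
            return


@dataclass(frozen=True)
class CNEvent:
    chrom: str
    start: int
    end: int
    kind: str          # "gain", "loss", or "loh"
    allele: int        # 0 or 1
    delta: int         # signed copy change for gain/loss; 0 for loh
    copy_neutral: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def _apply_event(state: State, ev: CNEvent) -> None:
    segs = state[ev.chrom]
    _split_at(segs, ev.start)
    _split_at(segs, ev.end + 1)
    for seg in segs:
        if seg[0] >= ev.start and seg[1] <= ev.end:
            a, b = seg[2], seg[3]
            if ev.kind == "loh":
                lost = (a, b)[ev.allele]
                if ev.copy_neutral:
                    seg[2 + (1 - ev.allele)] += lost
                seg[2 + ev.allele] = 0
            else:
                # overlapping events compose additively, clipped at zero
                seg[2 + ev.allele] = max(0, seg[2 + ev.allele] + ev.delta)


def _draw_event(genome: GenomeCoordinates, cfg: SimulationConfig,
                rng: np.random.Generator) -> CNEvent:
    chroms = list(genome.chrom_lengths)
    lengths = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
    chrom = chroms[rng.choice(len(chroms), p=lengths / lengths.sum())]
    lmin, lmax = cfg.event_length_range
    length = int(np.exp(rng.uniform(np.log(lmin), np.log(lmax))))
    length = min(length, genome.chrom_lengths[chrom])
    if rng.random() < cfg.terminal_fraction:
        # terminal event anchored at the p- or q-end of the chromosome
        if rng.random() < 0.5:
            start = 1
        else:
            start = genome.chrom_lengths[chrom] - length + 1
    else:
        start = int(rng.integers(1, genome.chrom_lengths[chrom] - length + 2))
    allele = int(rng.integers(2))
    if rng.random() < cfg.loh_fraction:
        return CNEvent(chrom, start, start + length - 1, "loh", allele, 0,
                       copy_neutral=bool(rng.random() < 0.5))
    delta = int(rng.choice([1, 2], p=[0.8, 0.2])) * int(rng.choice([-1, 1]))
    return CNEvent(chrom, start, start + length - 1,
                   "gain" if delta > 0 else "loss", allele, delta)


def _state_to_profile(sample_id: str, state: State) -> AllelicCNProfile:
    segs = []
    for chrom, rows in state.items():
        for s, e, a, b in rows:
            segs.append(GenomicSegment(chrom, s, e, max(a, b), min(a, b)))
    return coalesce_profile(AllelicCNProfile(sample_id, tuple(segs)))


def _length_weighted_ploidy(p: AllelicCNProfile) -> float:
    total = sum(s.total_cn * s.length for s in p.segments)
    span = sum(s.length for s in p.segments)
    return total / span


def _dilute(p: AllelicCNProfile, purity: float) -> AllelicCNProfile:
    """Mix with a diploid (1,1) normal component and round back to integers."""
    segs = []
    for s in p.segments:
        nmaj = round(purity * s.n_major + (1 - purity) * 1)
        nmin = round(purity * s.n_minor + (1 - purity) * 1)
        segs.append(GenomicSegment(s.chrom, s.start, s.end, max(nmaj, nmin), min(nmaj, nmin)))
    return coalesce_profile(AllelicCNProfile(p.sample_id, tuple(segs)))


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatientTruth:
    patient_id: str
    tree_newick: str
    clone_of: Mapping[str, int]
    scenario: str
    n_clones: int
    home_cells: Mapping[int, str]
    n_events: Mapping[str, int]


@dataclass(frozen=True)
class SyntheticCohort:
    profiles: tuple[AllelicCNProfile, ...]
    metadata: tuple[SampleRecord, ...]
    exposures: pd.DataFrame
    truth: Mapping[str, PatientTruth]
    genome: GenomeCoordinates
    config: SimulationConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit the io-module TSV dialects plus the truth tables."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "segments": outdir / "segments.tsv",
            "metadata": outdir / "metadata.tsv",
            "exposures": outdir / "exposures.tsv",
            "genome": outdir / "genome.tsv",
            "truth_clones": outdir / "truth_clones.tsv",
            "truth_tree": outdir / "truth_tree.nwk",
            "truth_scenario": outdir / "truth_scenario.json",
        }
        write_segment_table(self.profiles, paths["segments"])
        write_metadata(self.metadata, paths["metadata"])
        self.exposures.to_csv(paths["exposures"], sep="\t", index_label="sample")
        write_genome(self.genome, paths["genome"])
        clone_rows = [
            {"sample": s, "patient": pid, "clone": clone}
            for pid, t in self.truth.items()
            for s, clone in t.clone_of.items()
        ]
        pd.DataFrame(clone_rows).to_csv(paths["truth_clones"], sep="\t", index=False)
        with open(paths["truth_tree"], "w") as fh:
            for pid in self.truth:
                fh.write(self.truth[pid].tree_newick + "\n")
        scenario = {
            pid: {
                "scenario": t.scenario,
                "n_clones": t.n_clones,
                "home_cells": {str(k): v for k, v in t.home_cells.items()},
                "tree_order": list(self.truth),
            }
            for pid, t in self.truth.items()
        }
        with open(paths["truth_scenario"], "w") as fh:
            json.dump(scenario, fh, indent=1, sort_keys=True)
        return paths


def _simulate_patient(
    patient_id: str,
    cfg: SimulationConfig,
    genome: GenomeCoordinates,
    rng: np.random.Generator,
):
    scenario = cfg.relapse_scenario
    lo, hi = cfg.clones_per_patient
    if scenario == "type1":
        k = 1  # monoclonal patient by construction
    elif scenario == "type2":
        if hi < 2:
            raise ValidationError("infeasible scenario: type2 with 1 clone")
        k = int(rng.integers(max(lo, 2), hi + 1))
    else:
        k = int(rng.integers(lo, hi + 1))
    tree = simulate_clone_tree(k, cfg.tree_shape, rng)

    root_state = _diploid_state(genome)
    truncal = [_draw_event(genome, cfg, rng) for _ in range(cfg.n_truncal_events)]
    for ev in truncal:
        _apply_event(root_state, ev)

    clone_states: dict[int, State] = {}

    # Edge event counts scale with the drop in divergence level so the clone
    # tree metric is ultrametric-like (distance between clones ~ 2 * level of
    # their common ancestor * n_clone_events): complete linkage can then
    # recover the generating topology, matching how real dendrogram shapes
    # reflect when each clone stopped diverging.
    def level(node) -> int:
        if not isinstance(node, tuple):
            return 0
        return max(level(node[0]), level(node[1])) + 1

    def descend(node, state):
        if isinstance(node, tuple):
            for child in node:
                child_state = _copy_state(state)
                n_events = cfg.n_clone_events * (level(node) - level(child))
                for _ in range(n_events):
                    _apply_event(child_state, _draw_event(genome, cfg, rng))
                descend(child, child_state)
        else:
            clone_states[node] = state

    descend(tree.topology, root_state)

    # primary sample -> clone assignment: every clone observed at least once
    n_samples = max(int(rng.integers(*cfg.samples_per_patient, endpoint=True)), k)
    clone_ids = sorted(clone_states)
    assignment = clone_ids + list(rng.choice(clone_ids, size=n_samples - k))
    assignment = [int(c) for c in assignment]
    rng.shuffle(assignment)

    # relapse clones
    relapse_clones: list[int] = []
    newick = tree.to_newick()
    if scenario != "none":
        if scenario == "type1":
            relapse_clones = [1] * cfg.n_relapse_samples
        elif scenario == "type2":
            relapse_clones = [int(rng.choice(clone_ids))
                              for _ in range(cfg.n_relapse_samples)]
        else:  # type3: fresh clone branched off a random existing clone,
            # with the divergence of sibling clones (two tree edges' worth)
            parent = int(rng.choice(clone_ids))
            new_clone = k + 1
            state = _copy_state(clone_states[parent])
            for _ in range(2 * cfg.n_clone_events):
                _apply_event(state, _draw_event(genome, cfg, rng))
            clone_states[new_clone] = state
            relapse_clones = [new_clone] * cfg.n_relapse_samples
            newick = re.sub(
                rf"clone{parent}(?=[,);])",
                f"(clone{parent},clone{new_clone})",
                newick,
            )

    home = {c: IMO_CELLS[i] for c, i in zip(
        sorted(clone_states),
        rng.choice(len(IMO_CELLS), size=len(clone_states), replace=False),
    )}
    clone_mean = {c: rng.dirichlet(np.ones(N_SIGNATURES)) for c in sorted(clone_states)}

    profiles, records, exp_rows, clone_of = [], [], [], {}

    def emit(sample_id: str, clone: int, timepoint: str):
        state = _copy_state(clone_states[clone])
        for _ in range(cfg.n_sample_noise_events):
            _apply_event(state, _draw_event(genome, cfg, rng))
        prof = _state_to_profile(sample_id, state)
        purity = float(rng.uniform(*cfg.purity_range))
        if cfg.dilute_and_round:
            prof = _dilute(prof, purity)
        cell = home[clone] if rng.random() < cfg.spatial_concordance \
            else IMO_CELLS[rng.integers(len(IMO_CELLS))]
        records.append(SampleRecord(
            sample_id=sample_id,
            patient_id=patient_id,
            timepoint=timepoint,
            site_label=f"IMO_{cell}",
            imo_cell=cell,
            purity=round(purity, 4),
            ploidy=round(_length_weighted_ploidy(prof), 4),
        ))
        profiles.append(prof)
        expo = rng.dirichlet(clone_mean[clone] * cfg.exposure_concentration)
        exp_rows.append({"sample": sample_id,
                         **{f"s{i + 1}": expo[i] for i in range(N_SIGNATURES)}})
        clone_of[sample_id] = clone

    for j, clone in enumerate(assignment, start=1):
        emit(f"{patient_id}_S{j:02d}", clone, "primary")
    for j, clone in enumerate(relapse_clones, start=1):
        emit(f"{patient_id}_R{j:02d}", clone, "relapse")

    truth = PatientTruth(
        patient_id=patient_id,
        tree_newick=newick,
        clone_of=clone_of,
        scenario=scenario,
        n_clones=len(clone_states),
        home_cells=home,
        n_events={"truncal": cfg.n_truncal_events,
                  "per_clone_edge": cfg.n_clone_events,
                  "per_sample": cfg.n_sample_noise_events},
    )
    return profiles, records, exp_rows, truth


def simulate_cohort(
    cfg: SimulationConfig,
    genome: GenomeCoordinates | None = None,
) -> SyntheticCohort:
    """Generate a full synthetic cohort with ground truth.

    Every generated profile passes the io-module invariants; identical config
    and seed give identical output.
    """
    genome = genome or reduced_genome()
    rng = np.random.default_rng(cfg.seed)
    profiles, records, exp_rows, truths = [], [], [], {}
    for i in range(cfg.n_patients):
        pid = f"P{i + 1:03d}"
        p, r, e, t = _simulate_patient(pid, cfg, genome, rng)
        profiles += p
        records += r
        exp_rows += e
        truths[pid] = t
    exposures = pd.DataFrame(exp_rows).set_index("sample")
    for p in profiles:
        p.validate_against(genome)
    return SyntheticCohort(
        profiles=tuple(profiles),
        metadata=tuple(records),
        exposures=exposures,
        truth=truths,
        genome=genome,
        config=cfg,
    )


def make_germline_profile(genome: GenomeCoordinates, sample_id: str = "germline") -> AllelicCNProfile:
    """All-(1,1) diploid profile covering the genome (a matched normal)."""
    return AllelicCNProfile(
        sample_id,
        tuple(GenomicSegment(c, 1, length, 1, 1)
              for c, length in genome.chrom_lengths.items()),
    )
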