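"""Clone calling, dendrogram topology, and primary-to-relapse patterns.

The clone-calling threshold is derived cohort-wide: pool the CN-event
distances of all same-patient (intra) and different-patient (inter) sample
pairs, fit a logistic regression of P(inter-patient | distance), and take the
smallest distance at which a pair is more likely to come from different
patients than from the same one — the 0.5 crossing, -intercept/slope.  Sets
of deposits within a patient are called distinct clones when they are as
divergent as deposits from different patients, i.e. the patient's dendrogram
is cut at that threshold.

Dendrogram topology is classified structurally: *sympodial* (ladder-like;
one branch stops diverging at each split — every internal node has a leaf
child) versus *dichotomous* (some split produces two further-diverging
branches — an internal node with two internal children).  Trees with fewer
than four leaves are *indeterminate* since the two shapes coincide.

Relapse patterns: type 1 — monoclonal primary and all relapse deposits from
that clone; type 2 — polyclonal primary and relapse deposits from existing
primary clones; type 3 — at least one relapse deposit from a clone not seen
in the primary deposits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._logit import LogitFit, fit_ridge_logit
from .distance import Dendrogram, DistanceMatrix
from .errors import NoSignalError, ValidationError
from .io import SampleRecord, metadata_by_sample

logger = logging.getLogger(__name__)

INTRA, INTER = "intra_patient", "inter_patient"


@dataclass(frozen=True)
class PairDistancePool:
    """Pooled unordered sample-pair distances labelled intra-/inter-patient."""

    records: pd.DataFrame  # columns: sample_a, sample_b, distance, label

    def __post_init__(self) -> None:
        if (self.records["distance"] < 0).any():
            raise ValidationError("pair distances must be >= 0")

    def distances(self, label: str) -> np.ndarray:
        return self.records.loc[self.records["label"] == label, "distance"].to_numpy(float)

    @property
    def n_intra(self) -> int:
        return int((self.records["label"] == INTRA).sum())

    @property
    def n_inter(self) -> int:
        return int((self.records["label"] == INTER).sum())


def pool_pair_distances(
    d: DistanceMatrix,
    meta: Sequence[SampleRecord] | Mapping[str, SampleRecord],
    *,
    include_relapse: bool = False,
    exclude: Iterable[str] = (),
) -> PairDistancePool:
    """Label every unordered sample pair intra- or inter-patient.

    Samples absent from ``meta`` (e.g. germline/normal profiles) and samples
    named in ``exclude`` are dropped.  Relapse samples are excluded from the
    pool by default so the threshold reflects the primary disease;
    ``include_relapse=True`` keeps them.
    """
    by_sample = meta if isinstance(meta, Mapping) else metadata_by_sample(meta)
    drop = set(exclude)
    ids = []
    for s in d.sample_ids:
        rec = by_sample.get(s)
        if rec is None:
            logger.warning("sample %s has no metadata; excluded from the pool", s)
            continue
        if s in drop:
            continue
        if not include_relapse and rec.timepoint == "relapse":
            continue
        ids.append(s)
    patients = {s: by_sample[s].patient_id for s in ids}
    if len(set(patients.values())) < 2:
        raise ValidationError("single-patient cohort: no inter-patient pairs to pool")
    rows = []
    for i, s1 in enumerate(ids):
        for s2 in ids[i + 1:]:
            rows.append(
                {
                    "sample_a": s1,
                    "sample_b": s2,
                    "distance": d.get(s1, s2),
                    "label": INTRA if patients[s1] == patients[s2] else INTER,
                }
            )
    pool = PairDistancePool(pd.DataFrame(rows))
    if pool.n_intra == 0:
        logger.warning("no intra-patient pairs in the pool; threshold fit will fail")
    return pool


# ---------------------------------------------------------------------------
# Clone-threshold model (Model -> fit() -> Results)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CloneThresholdResults:
    """Fitted clone-calling threshold and its logistic model.

    ``threshold`` is the smallest distance at which the predicted probability
    that a pair comes from different patients exceeds 0.5, computed in closed
    form as -intercept/slope.
    """

    intercept: float
    slope: float
    threshold: float
    fit: LogitFit
    n_intra: int
    n_inter: int
    ridge: float

    def predict_inter_probability(self, distance) -> np.ndarray:
        return self.fit.predict(distance)

    @property
    def fit_diagnostics(self) -> dict[str, float]:
        return {
            "loglike": self.fit.loglike,
            "loglike_null": self.fit.loglike_null,
            "lr_pvalue": self.fit.lr_pvalue,
            "slope_std": self.fit.slope_std,
            "n_intra": float(self.n_intra),
            "n_inter": float(self.n_inter),
        }

    def summary(self) -> str:
        lines = [
            "Clone-calling threshold (logistic P(inter-patient | distance))",
            "=" * 62,
            f"{'n intra-patient pairs':<34}{self.n_intra:>12}",
            f"{'n inter-patient pairs':<34}{self.n_inter:>12}",
            f"{'intercept':<34}{self.intercept:>12.4f}",
            f"{'slope (per distance unit)':<34}{self.slope:>12.6f}",
            f"{'threshold (-intercept/slope)':<34}{self.threshold:>12.1f}",
            f"{'LR test p (slope)':<34}{self.fit.lr_pvalue:>12.3g}",
            f"{'ridge penalty (std. covariate)':<34}{self.ridge:>12.2g}",
            "=" * 62,
        ]
        return "\n".join(lines)


class CloneThresholdModel:
    """Logistic model of P(inter-patient) as a function of genomic distance.

    Parameters
    ----------
    pool:
        Pooled labelled pair distances (see :func:`pool_pair_distances`).
    ridge:
        L2 penalty strength on the standardized slope; keeps coefficients
        finite under complete separation of the two pools.
    signal_alpha:
        Significance level of the likelihood-ratio test that guards against a
        non-discriminating distance; ``None`` disables the test.
    """

    MIN_RECOMMENDED = 10

    def __init__(self, pool: PairDistancePool, *, ridge: float = 1e-4,
                 signal_alpha: float | None = 0.05) -> None:
        if pool.n_intra == 0 or pool.n_inter == 0:
            raise ValidationError("both intra- and inter-patient pairs are required")
        if min(pool.n_intra, pool.n_inter) < self.MIN_RECOMMENDED:
            logger.warning(
                "fewer than %d pairs per label (intra=%d, inter=%d); "
                "threshold estimate may be unstable",
                self.MIN_RECOMMENDED, pool.n_intra, pool.n_inter,
            )
        self.pool = pool
        self.ridge = ridge
        self.signal_alpha = signal_alpha

    @classmethod
    def from_distance_matrix(cls, d: DistanceMatrix, meta, **kwargs) -> "CloneThresholdModel":
        pool_kwargs = {k: kwargs.pop(k) for k in ("include_relapse", "exclude") if k in kwargs}
        return cls(pool_pair_distances(d, meta, **pool_kwargs), **kwargs)

    def fit(self) -> CloneThresholdResults:
        rec = self.pool.records
        x = rec["distance"].to_numpy(float)
        y = (rec["label"] == INTER).to_numpy(float)
        fit = fit_ridge_logit(x, y, ridge=self.ridge)
        if fit.slope_std <= 1e-8:
            raise NoSignalError(
                "distance does not discriminate patients (slope <= 0)"
            )
        if self.signal_alpha is not None and fit.lr_pvalue > self.signal_alpha:
            raise NoSignalError(
                "distance does not discriminate patients "
                f"(likelihood-ratio p = {fit.lr_pvalue:.3g} > {self.signal_alpha})"
            )
        threshold = -fit.intercept / fit.slope
        if not np.isfinite(threshold):
            raise NoSignalError("threshold is not finite")  # pragma: no cover
        return CloneThresholdResults(
            intercept=fit.intercept,
            slope=fit.slope,
            threshold=float(threshold),
            fit=fit,
            n_intra=self.pool.n_intra,
            n_inter=self.pool.n_inter,
            ridge=self.ridge,
        )


def fit_clone_threshold(pool: PairDistancePool, **kwargs) -> CloneThresholdResults:
    """Convenience wrapper: ``CloneThresholdModel(pool, **kwargs).fit()``."""
    return CloneThresholdModel(pool, **kwargs).fit()


# ---------------------------------------------------------------------------
# Clone assignment
# ---------------------------------------------------------------------------


def assign_clones(
    dend: Dendrogram,
    threshold: float | CloneThresholdResults,
) -> dict[str, int]:
    """Cut a patient's dendrogram at the clone-calling threshold.

    Complete linkage makes the merge height the maximal within-group pairwise
    distance, so any two samples placed in different clones were merged only
    at a height above the threshold.  Returns sample_id -> clone index (1..k).
    """
    if isinstance(threshold, CloneThresholdResults):
        threshold = threshold.threshold
    if threshold <= 0:
        logger.warning("threshold <= 0: every sample becomes its own clone")
        return {s: i + 1 for i, s in enumerate(dend.leaf_ids)}
    return dend.cut(threshold)


def assign_clones_pairwise(d: DistanceMatrix, threshold: float) -> dict[str, int]:
    """Single-linkage-style alternative: connect pairs with distance <= threshold.

    Exposed for sensitivity analysis against the dendrogram-cut assignment.
    """
    n = len(d)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if d.values[i, j] <= threshold:
                parent[find(i)] = find(j)
    labels: dict[str, int] = {}
    root_label: dict[int, int] = {}
    for i, s in enumerate(d.sample_ids):
        r = find(i)
        if r not in root_label:
            root_label[r] = len(root_label) + 1
        labels[s] = root_label[r]
    return labels


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

SYMPODIAL, DICHOTOMOUS, INDETERMINATE = "sympodial", "dichotomous", "indeterminate"


def classify_topology(dend: Dendrogram) -> str:
    """Classify a dendrogram as sympodial, dichotomous, or indeterminate.

    Sympodial: every internal node has at least one leaf child (caterpillar).
    Dichotomous: some internal node has two internal children.  These are
    complementary for binary trees, so the classification is total.  Trees
    with fewer than 4 leaves (shapes coincide) or with all merge heights tied
    (shape not identified by the data) are indeterminate.
    """
    if dend.n_leaves < 4:
        return INDETERMINATE
    heights = dend.merges[:, 2]
    if np.allclose(heights, heights[0]):
        return INDETERMINATE
    n = dend.n_leaves
    for k in range(len(dend.merges)):
        i, j = int(dend.merges[k, 0]), int(dend.merges[k, 1])
        if i >= n and j >= n:
            return DICHOTOMOUS
    return SYMPODIAL


# ---------------------------------------------------------------------------
# Relapse patterns
# ---------------------------------------------------------------------------

TYPE1, TYPE2, TYPE3 = "type1", "type2", "type3"


def classify_relapse_pattern(
    assignment: Mapping[str, int],
    meta: Sequence[SampleRecord] | Mapping[str, SampleRecord],
) -> str:
    """Type the primary-to-relapse evolutionary pattern of one patient.

    Requires the clone assignment to pool the patient's primary and relapse
    samples in a single clustering.  Invariant to clone relabelling.
    """
    by_sample = meta if isinstance(meta, Mapping) else metadata_by_sample(meta)
    primary_clones, relapse_clones = set(), set()
    for s, clone in assignment.items():
        rec = by_sample.get(s)
        if rec is None:
            raise ValidationError(f"sample {s!r} in assignment has no metadata")
        if rec.timepoint == "primary":
            primary_clones.add(clone)
        else:
            relapse_clones.add(clone)
    if not relapse_clones:
        raise ValidationError("relapse pattern undefined: no relapse samples")
    if not primary_clones:
        raise ValidationError("relapse pattern undefined: no primary samples")
    if relapse_clones - primary_clones:
        return TYPE3
    return TYPE1 if len(primary_clones) == 1 else TYPE2


# ---------------------------------------------------------------------------
# Per-patient report
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatientEvolutionReport:
    patient_id: str
    clone_assignment: dict[str, int]
    n_clones: int
    threshold: float
    topology: str
    relapse_pattern: str | None
    newick: str

    def to_dict(self) -> dict:
        return {
            "patient": self.patient_id,
            "threshold": self.threshold,
            "clones": self.clone_assignment,
            "n_clones": self.n_clones,
            "topology": self.topology,
            "relapse_pattern": self.relapse_pattern,
            "newick": self.newick,
        }


def patient_evolution_report(
    patient_id: str,
    d: DistanceMatrix,
    meta,
    threshold: float | CloneThresholdResults,
) -> PatientEvolutionReport:
    """Cluster one patient's deposits, call clones, topology, and relapse pattern."""
    from .distance import cluster_complete_linkage

    by_sample = meta if isinstance(meta, Mapping) else metadata_by_sample(meta)
    dend = cluster_complete_linkage(d)
    assignment = assign_clones(dend, threshold)
    thr = threshold.threshold if isinstance(threshold, CloneThresholdResults) else threshold
    timepoints = {by_sample[s].timepoint for s in d.sample_ids if s in by_sample}
    pattern = None
    if {"primary", "relapse"} <= timepoints:
        pattern = classify_relapse_pattern(assignment, by_sample)
    # annotate clone index into leaf labels of the exported tree
    annotated = Dendrogram(
        tuple(f"{s}|clone{assignment[s]}" for s in dend.leaf_ids), dend.merges
    )
    return PatientEvolutionReport(
        patient_id=patient_id,
        clone_assignment=assignment,
        n_clones=len(set(assignment.values())),
        threshold=float(thr),
        topology=classify_topology(dend),
        relapse_pattern=pattern,
        newick=annotated.to_newick(),
    )
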