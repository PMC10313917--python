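"""Shared fixtures and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from cnith.io import AllelicCNProfile, GenomeCoordinates, GenomicSegment


# ---------------------------------------------------------------------------
# Profile builders
# ---------------------------------------------------------------------------


def profile(sample_id: str, segments) -> AllelicCNProfile:
    """Build a profile from (chrom, start, end, n_major, n_minor) or
    (chrom, start, end, total) tuples."""
    segs = []
    for t in segments:
        if len(t) == 5:
            segs.append(GenomicSegment(t[0], t[1], t[2], t[3], t[4]))
        else:
            segs.append(GenomicSegment(t[0], t[1], t[2], total_cn=t[3]))
    return AllelicCNProfile(sample_id, tuple(segs))


def random_total_profile_pair(rng: np.random.Generator, *, n_cells: int = 60,
                              cell: int = 1_000, max_cn: int = 5):
    """Random pair of total-CN profiles with breakpoints on a 1 kb lattice.

    Both profiles tile chr1:1..n_cells*cell completely, so the pair is valid
    for breakpoint merging and exactly representable on the oracle grid.
    """
    def draw(sample_id):
        n_bp = int(rng.integers(0, 9))
        cuts = np.sort(rng.choice(np.arange(1, n_cells), size=n_bp, replace=False))
        bounds = [0, *cuts.tolist(), n_cells]
        segs = []
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            segs.append(("1", lo * cell + 1, hi * cell, int(rng.integers(0, max_cn + 1))))
        return profile(sample_id, segs)

    return draw("A"), draw("B")


def grid_cn_event_oracle(a: AllelicCNProfile, b: AllelicCNProfile,
                         grid: int = 1_000) -> int:
    """Brute-force CN-event distance.

    Evaluates the total CN of both profiles at every ``grid``-bp position and
    counts maximal runs where the (cn_a, cn_b) value pair is constant and
    unequal.  Independent of the breakpoint-merge implementation.
    """
    end = max(s.end for s in list(a.segments) + list(b.segments))
    positions = np.arange(1, end + 1, grid)

    def evaluate(p):
        out = np.full(positions.shape, -1)
        for s in p.segments:
            mask = (positions >= s.start) & (positions <= s.end)
            out[mask] = s.total_cn
        return out

    ca, cb = evaluate(a), evaluate(b)
    count = 0
    prev_pair = None
    for va, vb in zip(ca, cb):
        pair = (int(va), int(vb))
        if va != vb and pair != prev_pair:
            count += 1
        prev_pair = pair
    return count


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


@pytest.fixture
def fig_style_pair():
    """Two single-chromosome total-CN profiles whose event distance is 2."""
    a = profile("A", [("1", 1, 100, 2), ("1", 101, 200, 3)])
    b = profile("B", [("1", 1, 150, 2), ("1", 151, 200, 4)])
    return a, b


@pytest.fixture
def mb_genome():
    """One 100 Mb + one 150 Mb chromosome with mid centromeres (scar tests)."""
    return GenomeCoordinates(
        chrom_lengths={"1": 100_000_000, "2": 150_000_000},
        centromeres={"1": (45_000_000, 50_000_000), "2": (70_000_000, 75_000_000)},
    )
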