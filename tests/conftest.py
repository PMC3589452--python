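"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library code paths they check:
UPGMA is re-implemented as a naive O(n^3) loop over explicit cluster
member lists, and reciprocal best hits as plain dictionary scans.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import corequant as cq


# ---------------------------------------------------------------------------
# oracles


def naive_upgma(points: np.ndarray) -> list[tuple[frozenset, frozenset, float]]:
    """Brute-force average-linkage agglomeration.

    Inter-cluster distance is recomputed each round as the mean of all
    pairwise point distances; equal-distance merges take the pair with the
    smallest (i, j) cluster indices.  Returns the merge history as
    (members_a, members_b, height) triples over original point indices.
    """
    n = len(points)
    pair = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    clusters: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    next_id = n
    merges = []
    while len(clusters) > 1:
        ids = sorted(clusters)
        best = None
        for ai, a in enumerate(ids):
            for b in ids[ai + 1:]:
                d = np.mean([pair[x, y] for x in clusters[a] for y in clusters[b]])
                if best is None or d < best[0] - 1e-12:
                    best = (d, a, b)
        d, a, b = best
        merges.append((clusters[a], clusters[b], d))
        clusters[next_id] = clusters[a] | clusters[b]
        del clusters[a], clusters[b]
        next_id += 1
    return merges


def scipy_merge_history(Z: np.ndarray, n: int) -> list[tuple[frozenset, frozenset, float]]:
    """Decode a scipy linkage matrix into the same merge-history form."""
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for step, (a, b, d, _) in enumerate(Z):
        a, b = int(a), int(b)
        out.append((members[a], members[b], float(d)))
        members[n + step] = members[a] | members[b]
    return out


def brute_force_rbh(rows: pd.DataFrame, genome_a: str, genome_b: str) -> set[tuple[str, str]]:
    """Enumerate mutual best hits with plain loops (bitscore, then pident,
    then lexicographic subject id)."""

    def best_map(qg: str, sg: str) -> dict[str, str]:
        best: dict[str, tuple] = {}
        for r in rows.itertuples(index=False):
            if r.qgenome != qg or r.sgenome != sg:
                continue
            key = (-r.bitscore, -r.pident, r.sseqid)
            if r.qseqid not in best or key < best[r.qseqid][0]:
                best[r.qseqid] = (key, r.sseqid)
        return {q: s for q, (_, s) in best.items()}

    fwd = best_map(genome_a, genome_b)
    rev = best_map(genome_b, genome_a)
    return {(a, b) for a, b in fwd.items() if rev.get(b) == a}


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def small_noiseless():
    """One deterministic small dataset plus its pipeline result."""
    dataset = cq.simulate_dataset(cq.SimConfig.small(seed=11, noiseless=True))
    result = cq.run_pipeline(dataset)
    return dataset, result


@pytest.fixture()
def toy_catalog():
    table = pd.DataFrame(
        {
            "protein_id": ["p1", "p2", "p3"],
            "length": [100, 200, 50],
            "cog": ["J", "C", "-"],
        }
    )
    return cq.ProteinCatalog(genome="gX", table=table)


def random_psm_table(rng: np.random.Generator, n: int = 60) -> pd.DataFrame:
    """Randomised PSM table spanning both sides of every filter boundary."""
    peptides = [f"PEP{rng.integers(0, n // 3)}" for _ in range(n)]
    return pd.DataFrame(
        {
            "peptide": peptides,
            "protein_id": [f"p{rng.integers(0, 10)}" for _ in range(n)],
            "charge": rng.integers(1, 4, size=n),
            "xcorr": rng.uniform(0.0, 5.0, size=n),
            "msgf": 10.0 ** rng.uniform(-14.0, -6.0, size=n),
            "sample_id": [f"s{rng.integers(0, 3)}" for _ in range(n)],
            "count": rng.integers(1, 5, size=n),
        }
    )
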