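"""Cross-genome ortholog groups, core proteome, and detection statistics.

Orthologs are approximated by reciprocal best hits (RBH): proteins a (in
genome A) and b (in genome B) are paired iff b is a's highest-bitscore
subject in B and a is b's highest-bitscore subject in A.  Groups are
connected components of the RBH pair graph across all genome pairs; the
"core" proteome is the set of groups spanning every genome in the panel.
This is a deliberate simplification of full in-paralog-aware ortholog
clustering (the INPARANOID family of methods): within-genome duplicate
resolution here is a deterministic weakest-edge split, and no in-paralog
clusters or bootstrap confidences are computed.

Detection statistics summarise which focal-genome proteins were observed
per sample; the per-genome expressed fraction extrapolates the focal
genome's detected set across the panel, exactly as the strain-panel
summary table convention does.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .catalog import ProteinCatalog
from .matrix import AbundanceMatrix

#: BLAST tabular (outfmt 6) column order.
OUTFMT6_COLUMNS = (
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
)

SIMILARITY_COLUMNS = ("qseqid", "sseqid", "qgenome", "sgenome", "pident", "bitscore")


def _validate_similarity(rows: pd.DataFrame) -> None:
    missing = set(SIMILARITY_COLUMNS) - set(rows.columns)
    if missing:
        raise ValueError(f"similarity table missing columns: {sorted(missing)}")
    if len(rows):
        if ((rows["pident"] < 0) | (rows["pident"] > 100)).any():
            raise ValueError("pident must lie in [0, 100]")
        if (rows["bitscore"] < 0).any():
            raise ValueError("bitscores must be non-negative")
        if (rows["qgenome"] == rows["sgenome"]).any():
            raise ValueError("similarity rows must compare different genomes")


def _best_hits(direction: pd.DataFrame) -> pd.DataFrame:
    """One best subject per query: max bitscore, ties by higher pident,
    then lexicographically smallest subject id."""
    ranked = direction.sort_values(
        ["qseqid", "bitscore", "pident", "sseqid"],
        ascending=[True, False, False, True],
        kind="mergesort",
    )
    return ranked.drop_duplicates("qseqid", keep="first")


def reciprocal_best_hits(
    rows: pd.DataFrame, genome_pair: tuple[str, str]
) -> pd.DataFrame:
    """RBH pairs for one genome pair.

    Returns a DataFrame with columns ``genome_a, protein_a, genome_b,
    protein_b, bitscore, pident`` (scores averaged over the two
    directions), ordered deterministically.  Both search directions must
    be present in ``rows``.
    """
    _validate_similarity(rows)
    a, b = genome_pair
    fwd = rows[(rows["qgenome"] == a) & (rows["sgenome"] == b)]
    rev = rows[(rows["qgenome"] == b) & (rows["sgenome"] == a)]
    if len(fwd) == 0 or len(rev) == 0:
        raise ValueError(
            f"similarity table must cover both directions of ({a}, {b}); "
            f"found {len(fwd)} {a}->{b} rows and {len(rev)} {b}->{a} rows"
        )
    best_fwd = _best_hits(fwd)[["qseqid", "sseqid", "bitscore", "pident"]]
    best_rev = _best_hits(rev)[["qseqid", "sseqid", "bitscore", "pident"]]
    merged = best_fwd.merge(
        best_rev,
        left_on=["qseqid", "sseqid"],
        right_on=["sseqid", "qseqid"],
        suffixes=("_f", "_r"),
    )
    out = pd.DataFrame(
        {
            "genome_a": a,
            "protein_a": merged["qseqid_f"],
            "genome_b": b,
            "protein_b": merged["sseqid_f"],
            "bitscore": (merged["bitscore_f"] + merged["bitscore_r"]) / 2.0,
            "pident": (merged["pident_f"] + merged["pident_r"]) / 2.0,
        }
    )
    return out.sort_values(["protein_a", "protein_b"]).reset_index(drop=True)


@dataclass
class OrthologGroupSet:
    """Ortholog groups as sets of (genome, protein) members."""

    groups: dict[str, frozenset[tuple[str, str]]]

    def span(self, group_id: str) -> frozenset[str]:
        return frozenset(g for g, _ in self.groups[group_id])

    def spans(self) -> dict[str, frozenset[str]]:
        return {gid: self.span(gid) for gid in self.groups}

    def membership(self) -> dict[tuple[str, str], str]:
        out: dict[tuple[str, str], str] = {}
        for gid, members in self.groups.items():
            for member in members:
                if member in out:
                    raise ValueError(f"protein {member} belongs to multiple groups")
                out[member] = gid
        return out

    def groups_of_genome(self, genome: str) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for gid, members in self.groups.items():
            prots = {p for g, p in members if g == genome}
            if prots:
                out[gid] = prots
        return out

    def span_histogram(self) -> pd.Series:
        sizes = pd.Series([len(self.span(g)) for g in self.groups], dtype=int)
        return sizes.value_counts().sort_index()

    def as_set(self) -> set[frozenset[tuple[str, str]]]:
        return set(self.groups.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"group_id": gid, "genome": g, "protein_id": p}
            for gid, members in sorted(self.groups.items())
            for g, p in sorted(members)
        ]
        return pd.DataFrame(rows, columns=["group_id", "genome", "protein_id"])


def build_groups(
    pairs: pd.DataFrame,
    proteins: list[tuple[str, str]] | None = None,
) -> OrthologGroupSet:
    """Connected components of the RBH pair graph, one genome per component.

    Components containing two proteins of the same genome are resolved by
    repeatedly removing the lowest-bitscore edge of the offending
    component (ties broken by lexicographic edge endpoints) until every
    component is genome-unique.  Group ids are assigned in sorted order of
    each group's smallest member.  ``proteins`` optionally lists all
    (genome, protein) entries of the panel so that proteins with no pair
    appear as singleton groups.
    """
    graph = nx.Graph()
    if proteins is not None:
        graph.add_nodes_from(proteins)
    for row in pairs.itertuples(index=False):
        u = (row.genome_a, row.protein_a)
        v = (row.genome_b, row.protein_b)
        w = float(row.bitscore)
        if graph.has_edge(u, v):
            w = max(w, graph.edges[u, v]["bitscore"])
        graph.add_edge(u, v, bitscore=w)

    def genome_conflict(component: set) -> bool:
        genomes = [g for g, _ in component]
        return len(genomes) != len(set(genomes))

    changed = True
    while changed:
        changed = False
        for comp in list(nx.connected_components(graph)):
            if not genome_conflict(comp):
                continue
            edges = sorted(
                graph.subgraph(comp).edges(data="bitscore"),
                key=lambda e: (e[2], min(e[0], e[1]), max(e[0], e[1])),
            )
            u, v, _ = edges[0]
            graph.remove_edge(u, v)
            changed = True

    components = sorted(nx.connected_components(graph), key=lambda c: min(c))
    width = max(4, len(str(len(components))))
    groups = {
        f"OG{idx:0{width}d}": frozenset(comp) for idx, comp in enumerate(components, start=1)
    }
    return OrthologGroupSet(groups=groups)


def core_set(groups: OrthologGroupSet, genomes: list[str]) -> list[str]:
    """Group ids whose span covers every genome in the panel."""
    if not genomes:
        raise ValueError("genome panel must be non-empty")
    full = frozenset(genomes)
    return sorted(gid for gid in groups.groups if full <= groups.span(gid))


def core_proteins_of_genome(
    groups: OrthologGroupSet, genomes: list[str], genome: str
) -> set[str]:
    """Proteins of ``genome`` belonging to all-panel (core) groups."""
    core = core_set(groups, genomes)
    return {p for gid in core for g, p in groups.groups[gid] if g == genome}


# ---------------------------------------------------------------------------
# detection


@dataclass
class DetectionSet:
    """Per-sample sets of detected focal-genome proteins."""

    per_sample: dict[str, set[str]] = field(default_factory=dict)

    @property
    def all_samples_intersection(self) -> set[str]:
        sets = list(self.per_sample.values())
        return set.intersection(*sets) if sets else set()

    @property
    def detected_anywhere(self) -> set[str]:
        sets = list(self.per_sample.values())
        return set.union(*sets) if sets else set()

    @classmethod
    def from_matrix(cls, counts: AbundanceMatrix) -> "DetectionSet":
        present = ~counts.missing_mask
        return cls(
            per_sample={
                sample: set(counts.protein_ids[present[sample]])
                for sample in counts.sample_ids
            }
        )


def detected_core_percent(core_proteins: set[str], detection: DetectionSet) -> float:
    """Percent of core proteins detected in every sample."""
    if not core_proteins:
        raise ValueError("core set is empty")
    hit = core_proteins & detection.all_samples_intersection
    return 100.0 * len(hit) / len(core_proteins)


def shared_detected(
    groups: OrthologGroupSet,
    detection: DetectionSet,
    focal_genome: str,
    other_genome: str,
    known_genomes: list[str] | None = None,
) -> int:
    """Detected focal-genome proteins whose group spans both named genomes."""
    if known_genomes is not None:
        for g in (focal_genome, other_genome):
            if g not in known_genomes:
                raise ValueError(f"unknown genome {g!r}")
    detected = detection.detected_anywhere
    n = 0
    for gid, members in groups.groups.items():
        span = groups.span(gid)
        if focal_genome in span and other_genome in span:
            n += sum(1 for g, p in members if g == focal_genome and p in detected)
    return n


# ---------------------------------------------------------------------------
# strain-panel summary table


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def table_fractions(
    genome_sizes: dict[str, int], core_size: int, expressed_core_size: int
) -> pd.DataFrame:
    """Per-genome core and expressed fractions at integer-percent rounding.

    ``core_size`` is the number of all-panel ortholog groups and
    ``expressed_core_size`` the number of focal-genome core proteins
    detected in every sample; both are divided by each genome's
    protein-coding count (the expressed set is extrapolated across the
    panel).  Rounding is to the nearest integer percent, ties away from
    zero.
    """
    if not genome_sizes:
        raise ValueError("genome panel must be non-empty")
    for g, n in genome_sizes.items():
        if n <= 0:
            raise ValueError(f"genome {g!r} has non-positive protein count")
    rows = {
        "protein_coding_genes": {g: n for g, n in genome_sizes.items()},
        "core_fraction_pct": {
            g: _round_half_away(100.0 * core_size / n) for g, n in genome_sizes.items()
        },
        "expressed_fraction_pct": {
            g: _round_half_away(100.0 * expressed_core_size / n)
            for g, n in genome_sizes.items()
        },
    }
    return pd.DataFrame(rows).T[list(genome_sizes)]


def fraction_table(
    groups: OrthologGroupSet,
    catalogs: list[ProteinCatalog],
    detection: DetectionSet,
    focal_genome: str,
) -> pd.DataFrame:
    """Strain-panel summary computed from groups, catalogs and detection."""
    if not catalogs:
        raise ValueError("catalog list must be non-empty")
    for cat in catalogs:
        if len(cat) == 0:
            raise ValueError(f"catalog {cat.genome!r} is empty")
    genomes = [c.genome for c in catalogs]
    core_ids = core_set(groups, genomes)
    focal_core = core_proteins_of_genome(groups, genomes, focal_genome)
    expressed = focal_core & detection.all_samples_intersection
    sizes = {c.genome: len(c) for c in catalogs}
    return table_fractions(sizes, len(core_ids), len(expressed))


class OrthologGroupBuilder:
    """Estimator-style wrapper: fit on a similarity table, expose groups.

    Fitted attributes: ``pairs_`` (RBH pairs across all genome pairs),
    ``groups_`` (:class:`OrthologGroupSet`), ``genomes_``.
    """

    def __init__(self) -> None:
        pass

    def fit(self, similarity: pd.DataFrame, y=None) -> "OrthologGroupBuilder":
        _validate_similarity(similarity)
        genomes = sorted(set(similarity["qgenome"]) | set(similarity["sgenome"]))
        frames = []
        for i, a in enumerate(genomes):
            for b in genomes[i + 1 :]:
                sub = similarity[
                    ((similarity["qgenome"] == a) & (similarity["sgenome"] == b))
                    | ((similarity["qgenome"] == b) & (similarity["sgenome"] == a))
                ]
                if len(sub):
                    frames.append(reciprocal_best_hits(sub, (a, b)))
        self.genomes_ = genomes
        self.pairs_ = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(
                columns=["genome_a", "protein_a", "genome_b", "protein_b", "bitscore", "pident"]
            )
        )
        self.groups_ = build_groups(self.pairs_)
        return self

    def core_ids(self) -> list[str]:
        return core_set(self.groups_, self.genomes_)


def mean_ortholog_identity(pairs: pd.DataFrame) -> float:
    """Unweighted per-pair mean percent identity over RBH pairs."""
    if not len(pairs):
        raise ValueError("no ortholog pairs")
    return float(pairs["pident"].mean())
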