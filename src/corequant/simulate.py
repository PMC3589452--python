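"""Synthetic study generator: catalogs, similarity tables, PSMs, geochemistry.

Generates every input the pipeline consumes, with the statistical
structure the analysis assumes, so the full workflow is testable without
any external download:

* eight protein catalogs with planted ortholog groups, including an
  all-genome core and accessory groups over proper genome subsets;
* pairwise similarity tables in which true ortholog pairs are mutual top
  scorers and decoy hits score strictly lower (score noise optional);
* a peptide-spectrum match table for the focal genome with
  negative-binomial spectral counts (over-dispersed, as spectral counts
  are), per-sample Bernoulli dropout, planted stage-specific shifts in
  chosen COG categories, and a configurable fraction of rows that
  deliberately fail the peptide filters;
* a nine-sample, three-phase geochemical trajectory (acetate arrival and
  Fe(II) rise, Fe(II) plateau, late decline with sulfide onset).

Every generated dataset is accompanied by a :class:`GroundTruth` ledger;
the generator guarantees that ledger and emitted tables are mutually
consistent, and all randomness flows from the single ``seed`` through
named sub-streams (same seed, same bytes).

Planted differential proteins are expressed near the configured baseline
in their "high" stages and ``effect_log_fold`` decades lower in their
"low" stages.  With the default baseline (mean count ~10) and an effect of
two decades the low-side mean is far below the detection floor, so planted
shifts manifest as stage-wise presence/absence — exactly the signal the
extreme-value imputation is designed to amplify into |ΔZ| >= 2 calls.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import UNANNOTATED, ProteinCatalog

COG_LETTERS = "JAKLBDYVTMNZWUOCGEFHIPQRS"[:20]
AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: Protein-coding gene counts of an eight-strain Geobacter panel, used as
#: the default genome sizes for full-scale simulations.
DEFAULT_GENOME_SIZES = (4034, 4152, 4523, 4430, 3839, 3465, 3576, 3725)

DEFAULT_STAGE_PLAN = (
    ("early", (5, 8, 10)),
    ("middle", (13, 15, 17)),
    ("late", (29, 36, 43)),
)

#: Additive measurement noise (1 SD, native units) per geochemical analyte.
GEOCHEM_NOISE_SD = {"fe2": 5.0, "sulfide": 0.3, "u6": 0.03, "acetate": 0.2, "sulfate": 0.2}


@dataclass(frozen=True)
class DifferentialSpec:
    """One planted differential contrast: ``n`` proteins of COG category
    ``cog`` shift ``direction`` between ``stage_from`` and ``stage_to``."""

    cog: str
    stage_from: str
    stage_to: str
    direction: str  # "increased" | "decreased"
    n: int


DEFAULT_DIFFERENTIAL_PLAN = (
    DifferentialSpec("J", "early", "middle", "decreased", 8),
    DifferentialSpec("C", "early", "middle", "increased", 8),
    DifferentialSpec("E", "early", "middle", "increased", 4),
    DifferentialSpec("O", "middle", "late", "decreased", 6),
)


@dataclass
class SimConfig:
    """Study design of a simulated biostimulation experiment.

    Defaults mirror the full design: eight genomes at realistic
    protein-coding sizes, nine samples over three stages, a core fraction
    of 0.28 of the smallest genome, a two-decade planted effect, and
    moderate per-sample dropout.  ``noiseless=True`` switches every
    stochastic element to its deterministic centre (rounded means, no
    dropout, no filter failures, no score or geochemistry noise) for exact
    ledger-recovery checks.
    """

    n_genomes: int = 8
    genome_sizes: tuple[int, ...] = DEFAULT_GENOME_SIZES
    genome_names: tuple[str, ...] | None = None
    core_fraction: float = 0.28
    accessory_fill: float = 0.5
    n_samples: int = 9
    stage_plan: tuple[tuple[str, tuple[int, ...]], ...] = DEFAULT_STAGE_PLAN
    effect_log_fold: float = 2.0
    dropout_rate: float | dict[str, float] = 0.05
    dispersion: float = 5.0
    base_log10_count: float = 1.0
    baseline_sigma: float = 0.3
    sample_depth_cycle: tuple[float, ...] = (0.9, 1.0, 1.1)
    filter_fail_rate: float = 0.1
    unannotated_fraction: float = 0.1
    detected_fraction: float = 0.25
    differential_plan: tuple[DifferentialSpec, ...] = DEFAULT_DIFFERENTIAL_PLAN
    similarity_noise: float = 0.0
    geochem_noise: float = 1.0
    fe_background: float = 50.0
    with_sequences: bool = True
    noiseless: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 1:
            raise ValueError("need at least one genome")
        if len(self.genome_sizes) != self.n_genomes:
            raise ValueError("genome_sizes length must equal n_genomes")
        if any(s <= 0 for s in self.genome_sizes):
            raise ValueError("genome sizes must be positive")
        if not (0.0 <= self.core_fraction <= 1.0):
            raise ValueError("core_fraction must lie in [0, 1]")
        for rate in self._dropout_map().values():
            if not (0.0 <= rate < 1.0):
                raise ValueError("dropout_rate must lie in [0, 1)")
        days = [d for _, stage_days in self.stage_plan for d in stage_days]
        if len(days) != self.n_samples:
            raise ValueError("n_samples must equal the total days in stage_plan")
        if len(set(days)) != len(days):
            raise ValueError("stage_plan days must be distinct")
        if not (0.0 <= self.filter_fail_rate < 1.0):
            raise ValueError("filter_fail_rate must lie in [0, 1)")
        if not (0.0 < self.detected_fraction <= 1.0):
            raise ValueError("detected_fraction must lie in (0, 1]")
        n_diff = sum(s.n for s in self.differential_plan)
        n_expressed = int(round(self.detected_fraction * self.genome_sizes[0]))
        if n_diff > n_expressed:
            raise ValueError(
                f"differential plan ({n_diff} proteins) exceeds the expressed "
                f"set of the focal genome ({n_expressed})"
            )
        stages = [s for s, _ in self.stage_plan]
        for spec in self.differential_plan:
            if spec.stage_from not in stages or spec.stage_to not in stages:
                raise ValueError(f"unknown stage in differential spec {spec}")
            if stages.index(spec.stage_from) >= stages.index(spec.stage_to):
                raise ValueError("differential specs must name an ordered stage pair")
            if spec.direction not in ("increased", "decreased"):
                raise ValueError("direction must be 'increased' or 'decreased'")

    # -- derived views -------------------------------------------------------

    @property
    def names(self) -> tuple[str, ...]:
        if self.genome_names is not None:
            return self.genome_names
        return tuple(f"g{i + 1}" for i in range(self.n_genomes))

    @property
    def focal_genome(self) -> str:
        return self.names[0]

    @property
    def stage_order(self) -> list[str]:
        return [s for s, _ in self.stage_plan]

    @property
    def days(self) -> list[int]:
        return [d for _, stage_days in self.stage_plan for d in stage_days]

    @property
    def sample_ids(self) -> list[str]:
        return [f"day{d}" for d in self.days]

    def stage_of_day(self) -> dict[int, str]:
        return {d: s for s, stage_days in self.stage_plan for d in stage_days}

    def _dropout_map(self) -> dict[str, float]:
        if isinstance(self.dropout_rate, dict):
            return dict(self.dropout_rate)
        return {s: float(self.dropout_rate) for s, _ in self.stage_plan}

    @classmethod
    def small(cls, seed: int = 0, **overrides) -> "SimConfig":
        """Scaled-down eight-genome design for fast tests and demos."""
        defaults = dict(
            genome_sizes=(140, 150, 160, 155, 135, 120, 125, 130),
            core_fraction=0.3,
            detected_fraction=0.5,
            differential_plan=(
                DifferentialSpec("J", "early", "middle", "decreased", 8),
                DifferentialSpec("C", "early", "middle", "increased", 8),
                DifferentialSpec("E", "early", "middle", "increased", 4),
                DifferentialSpec("O", "middle", "late", "decreased", 6),
            ),
            with_sequences=False,
            seed=seed,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class GroundTruth:
    """Generator ledger for one simulated dataset.

    ``ortholog_membership`` records every multi-protein group (singletons
    are implicit); ``differential_proteins`` records the planted contrasts
    for focal-genome proteins; ``stage_labels`` maps sampling day to stage;
    ``expressed_proteins`` is the focal-genome expressed set.
    """

    ortholog_membership: dict[str, tuple[tuple[str, str], ...]]
    differential_proteins: dict[str, dict]
    stage_labels: dict[int, str]
    expressed_proteins: set[str] = field(default_factory=set)

    def multi_groups(self) -> set[frozenset[tuple[str, str]]]:
        return {frozenset(m) for m in self.ortholog_membership.values()}

    def core_group_ids(self, genomes: list[str]) -> list[str]:
        full = set(genomes)
        return sorted(
            gid
            for gid, members in self.ortholog_membership.items()
            if {g for g, _ in members} == full
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "ortholog_membership": {
                gid: [list(m) for m in members]
                for gid, members in sorted(self.ortholog_membership.items())
            },
            "differential_proteins": self.differential_proteins,
            "stage_labels": {str(d): s for d, s in sorted(self.stage_labels.items())},
            "expressed_proteins": sorted(self.expressed_proteins),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            ortholog_membership={
                gid: tuple((g, p) for g, p in members)
                for gid, members in payload["ortholog_membership"].items()
            },
            differential_proteins=payload["differential_proteins"],
            stage_labels={int(d): s for d, s in payload["stage_labels"].items()},
            expressed_proteins=set(payload["expressed_proteins"]),
        )


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(stream,)))


_STREAM_CATALOGS, _STREAM_SIMILARITY, _STREAM_PSM, _STREAM_GEOCHEM = range(4)


# ---------------------------------------------------------------------------
# catalogs and ortholog structure


def gen_catalogs(config: SimConfig) -> tuple[list[ProteinCatalog], GroundTruth]:
    """Generate one catalog per genome plus the ground-truth ledger.

    A ``core_fraction`` share (of the smallest genome) of ortholog groups
    spans all genomes; accessory groups span random proper subsets of at
    least two genomes until ``accessory_fill`` of the remaining capacity
    is consumed; everything left is a singleton.  COG letters and lengths
    (log-normal, median ~300 aa) are drawn per group so orthologs agree in
    annotation and size.
    """
    rng = _rng(config, _STREAM_CATALOGS)
    names = config.names
    sizes = config.genome_sizes
    n_core = int(round(config.core_fraction * min(sizes)))

    slot_perm = {g: list(rng.permutation(size)) for g, size in zip(names, sizes)}
    pid = {
        g: [f"{g}_{i + 1:04d}" for i in range(size)] for g, size in zip(names, sizes)
    }

    groups: list[list[tuple[str, str]]] = []
    cursor = {g: 0 for g in names}

    def take(genome: str) -> tuple[str, str]:
        slot = slot_perm[genome][cursor[genome]]
        cursor[genome] += 1
        return (genome, pid[genome][slot])

    for _ in range(n_core):
        groups.append([take(g) for g in names])

    remaining = {g: size - n_core for g, size in zip(names, sizes)}
    target = int(config.accessory_fill * sum(remaining.values()))
    consumed = 0
    while consumed < target:
        candidates = sorted(g for g in names if remaining[g] > 0)
        max_size = min(len(candidates), config.n_genomes - 1)
        if max_size < 2:
            break
        m = int(rng.integers(2, max_size + 1))
        chosen = sorted(rng.choice(candidates, size=m, replace=False))
        groups.append([take(g) for g in chosen])
        for g in chosen:
            remaining[g] -= 1
        consumed += m

    # per-protein annotation, drawn per group then per leftover singleton
    length_of: dict[tuple[str, str], int] = {}
    cog_of: dict[tuple[str, str], str] = {}

    def draw_cog() -> str:
        if rng.random() < config.unannotated_fraction:
            return UNANNOTATED
        return str(rng.choice(list(COG_LETTERS)))

    for members in groups:
        base_len = rng.lognormal(mean=np.log(300.0), sigma=0.35)
        cog = draw_cog()
        for member in members:
            length = max(50, int(round(base_len * (1.0 + rng.normal(0.0, 0.03)))))
            length_of[member] = length
            cog_of[member] = cog
    for g, size in zip(names, sizes):
        for slot in slot_perm[g][cursor[g]:]:
            member = (g, pid[g][slot])
            length_of[member] = max(50, int(round(rng.lognormal(np.log(300.0), 0.35))))
            cog_of[member] = draw_cog()

    # focal expressed set and planted differential assignments
    focal = config.focal_genome
    n_expressed = int(round(config.detected_fraction * sizes[0]))
    expressed = [pid[focal][i] for i in rng.permutation(sizes[0])[:n_expressed]]
    differential: dict[str, dict] = {}
    idx = 0
    membership_of = {
        member: gi for gi, members in enumerate(groups) for member in members
    }
    for spec in config.differential_plan:
        for _ in range(spec.n):
            p = expressed[idx]
            idx += 1
            differential[p] = {
                "stage_from": spec.stage_from,
                "stage_to": spec.stage_to,
                "direction": spec.direction,
                "log_fold": config.effect_log_fold,
            }
            # force the planted category onto the protein (and its group,
            # so cross-genome annotations stay consistent)
            member = (focal, p)
            if member in membership_of:
                for other in groups[membership_of[member]]:
                    cog_of[other] = spec.cog
            else:
                cog_of[member] = spec.cog

    catalogs = []
    for g, size in zip(names, sizes):
        table = pd.DataFrame(
            {
                "protein_id": pid[g],
                "length": [length_of[(g, p)] for p in pid[g]],
                "cog": [cog_of[(g, p)] for p in pid[g]],
            }
        )
        sequences: dict[str, str] = {}
        if config.with_sequences:
            lengths = table["length"].to_numpy()
            pool = rng.integers(0, len(AMINO_ACIDS), size=int(lengths.sum()))
            letters = AMINO_ACIDS[pool]
            offsets = np.concatenate([[0], np.cumsum(lengths)])
            sequences = {
                p: "".join(letters[offsets[i]: offsets[i + 1]])
                for i, p in enumerate(pid[g])
            }
        catalogs.append(ProteinCatalog(genome=g, table=table, sequences=sequences))

    width = max(4, len(str(len(groups))))
    membership = {
        f"OG{i + 1:0{width}d}": tuple(sorted(members))
        for i, members in enumerate(groups)
        if len(members) >= 2
    }
    truth = GroundTruth(
        ortholog_membership=membership,
        differential_proteins=differential,
        stage_labels=config.stage_of_day(),
        expressed_proteins=set(expressed),
    )
    return catalogs, truth


# ---------------------------------------------------------------------------
# similarity tables


def gen_similarity_tables(
    catalogs: list[ProteinCatalog],
    truth: GroundTruth,
    noise_level: float = 0.0,
    config: SimConfig | None = None,
) -> pd.DataFrame:
    """Pairwise similarity rows for every ordered genome pair.

    True ortholog pairs score around bitscore 500 in both directions;
    decoy off-group rows score in [50, 300], strictly lower.  Gaussian
    score noise of SD ``40 * noise_level`` is added to every bitscore;
    the mutual-top property of true pairs is guaranteed up to a break
    point near ``noise_level ~ 2.5``, where noise tails start to bridge
    the 200-point score gap.
    """
    rng = (
        _rng(config, _STREAM_SIMILARITY)
        if config is not None
        else np.random.default_rng(12345)
    )
    genomes = [c.genome for c in catalogs]
    ids = {c.genome: list(c.table["protein_id"]) for c in catalogs}
    partner: dict[tuple[str, str], dict[str, str]] = {}
    for members in truth.ortholog_membership.values():
        for g, p in members:
            partner.setdefault((g, p), {})
            for g2, p2 in members:
                if g2 != g:
                    partner[(g, p)][g2] = p2

    frames = []
    for qg in genomes:
        for sg in genomes:
            if qg == sg:
                continue
            q_ids, s_ids, pident, bits = [], [], [], []
            # true ortholog rows
            for p in ids[qg]:
                mate = partner.get((qg, p), {}).get(sg)
                if mate is not None:
                    q_ids.append(p)
                    s_ids.append(mate)
                    pident.append(94.0 + rng.normal(0.0, 2.0) * noise_level)
                    bits.append(500.0 + rng.normal(0.0, 40.0) * noise_level)
            # decoy rows; subjects are restricted to proteins that have a
            # true partner in the query genome, so a decoy hit can never be
            # reciprocated (the subject's own best hit is its ortholog)
            decoy_pool = [
                s for s in ids[sg] if partner.get((sg, s), {}).get(qg) is not None
            ]
            if decoy_pool:
                for p in ids[qg]:
                    mate = partner.get((qg, p), {}).get(sg)
                    for _ in range(int(rng.integers(0, 3))):
                        s = decoy_pool[int(rng.integers(0, len(decoy_pool)))]
                        if s == mate:
                            continue
                        q_ids.append(p)
                        s_ids.append(s)
                        pident.append(float(rng.uniform(25.0, 60.0)))
                        bits.append(
                            float(rng.uniform(50.0, 300.0))
                            + rng.normal(0.0, 40.0) * noise_level
                        )
            if q_ids:
                frames.append(
                    pd.DataFrame(
                        {
                            "qseqid": q_ids,
                            "sseqid": s_ids,
                            "qgenome": qg,
                            "sgenome": sg,
                            "pident": np.clip(pident, 0.0, 100.0),
                            "bitscore": np.clip(bits, 0.0, None),
                        }
                    )
                )
    if not frames:
        return pd.DataFrame(
            columns=["qseqid", "sseqid", "qgenome", "sgenome", "pident", "bitscore"]
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(
        ["qgenome", "sgenome", "qseqid", "sseqid"], kind="mergesort"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# peptide-spectrum matches


_XCORR_MIN = {1: 1.9, 2: 2.2, 3: 3.5}


def _low_stages(spec: dict, stage_order: list[str]) -> set[str]:
    """Stages in which a planted protein sits ``effect_log_fold`` decades low."""
    boundary = stage_order.index(spec["stage_to"])
    if spec["direction"] == "increased":
        return set(stage_order[:boundary])
    return set(stage_order[boundary:])


def gen_psm_table(
    catalog: ProteinCatalog, truth: GroundTruth, config: SimConfig
) -> pd.DataFrame:
    """Peptide-spectrum match table for the focal genome.

    Per sample and expressed protein, a spectral count is drawn from a
    negative binomial whose log10 mean is the protein baseline plus the
    planted stage effect and a per-sample depth factor; the count is split
    over the protein's 1-5 tryptic-like peptides, which carry charge
    states 1-3 and passing scores.  A ``filter_fail_rate`` fraction of
    rows is emitted with deliberately failing scores, and per-sample
    Bernoulli dropout (stage-specific rate) zeroes truly present proteins.
    Zero-count (protein, sample) combinations emit no rows.
    """
    rng = _rng(config, _STREAM_PSM)
    stage_order = config.stage_order
    stage_of_day = truth.stage_labels
    days = config.days
    sample_stage = [stage_of_day[d] for d in days]
    depth = np.array(
        [config.sample_depth_cycle[i % len(config.sample_depth_cycle)] for i in range(len(days))]
    )
    dropout = config._dropout_map()

    expressed = sorted(truth.expressed_proteins)
    n_prot, n_samp = len(expressed), len(days)

    baseline = np.full(n_prot, config.base_log10_count)
    if not config.noiseless:
        baseline = baseline + rng.normal(0.0, config.baseline_sigma, size=n_prot)
        # planted proteins are seeded at the common reference level so each
        # planted contrast is exactly effect_log_fold decades; a baseline
        # drawn above it would lift the low state over the detection floor
        # (and one below it would censor the high state), making the realised
        # effect differ from the ledgered one
        for i, p in enumerate(expressed):
            if p in truth.differential_proteins:
                baseline[i] = config.base_log10_count

    log_mean = np.tile(baseline[:, None], (1, n_samp))
    for i, p in enumerate(expressed):
        spec = truth.differential_proteins.get(p)
        if spec is None:
            continue
        low = _low_stages(spec, stage_order)
        for j, stage in enumerate(sample_stage):
            if stage in low:
                log_mean[i, j] -= spec["log_fold"]
    mu = (10.0 ** log_mean) * depth[None, :]

    if config.noiseless:
        counts = np.round(mu).astype(int)
    else:
        r = config.dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
        drop_p = np.array([dropout[s] for s in sample_stage])
        counts[rng.random((n_prot, n_samp)) < drop_p[None, :]] = 0

    # peptide inventory per protein
    def peptide_seq() -> str:
        n = int(rng.integers(8, 21))
        core = "".join(AMINO_ACIDS[rng.integers(0, len(AMINO_ACIDS), size=n)])
        return core + ("K" if rng.random() < 0.5 else "R")

    n_pep = (
        np.arange(n_prot) % 5 + 1
        if config.noiseless
        else rng.integers(1, 6, size=n_prot)
    )
    peptides = [[peptide_seq() for _ in range(n_pep[i])] for i in range(n_prot)]

    rows: list[tuple] = []
    for i, p in enumerate(expressed):
        for j in range(n_samp):
            total = int(counts[i, j])
            if total <= 0:
                continue
            k = len(peptides[i])
            if config.noiseless:
                split = np.full(k, total // k)
                split[0] += total - split.sum()
            else:
                split = rng.multinomial(total, np.full(k, 1.0 / k))
            for q, pep in enumerate(peptides[i]):
                c = int(split[q])
                if c == 0:
                    continue
                if config.noiseless:
                    charge = (i + q) % 3 + 1
                    xcorr = _XCORR_MIN[charge] + 0.5
                    msgf = 1e-12
                else:
                    charge = int(rng.choice([1, 2, 3], p=[0.25, 0.5, 0.25]))
                    xcorr = _XCORR_MIN[charge] + float(rng.uniform(0.0, 2.0))
                    msgf = float(10.0 ** rng.uniform(-15.0, -10.0))
                rows.append((pep, p, charge, xcorr, msgf, f"day{days[j]}", c))

    # deliberately failing rows, in addition to the passing ones
    f = config.filter_fail_rate
    if not config.noiseless and f > 0 and rows:
        n_fail = int(rng.binomial(len(rows), f / (1.0 - f)))
        for _ in range(n_fail):
            p = expressed[int(rng.integers(0, n_prot))]
            j = int(rng.integers(0, n_samp))
            charge = int(rng.choice([1, 2, 3], p=[0.25, 0.5, 0.25]))
            mode = int(rng.integers(0, 3))
            xcorr = (
                float(rng.uniform(0.2, _XCORR_MIN[charge] - 0.05))
                if mode in (0, 2)
                else _XCORR_MIN[charge] + float(rng.uniform(0.0, 2.0))
            )
            msgf = (
                float(10.0 ** rng.uniform(-9.5, -4.0))
                if mode in (1, 2)
                else float(10.0 ** rng.uniform(-15.0, -10.0))
            )
            rows.append(
                (peptide_seq(), p, charge, xcorr, msgf, f"day{days[j]}", int(rng.integers(1, 4)))
            )

    out = pd.DataFrame(
        rows,
        columns=["peptide", "protein_id", "charge", "xcorr", "msgf", "sample_id", "count"],
    )
    return out.sort_values(
        ["sample_id", "protein_id", "peptide"], kind="mergesort"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# geochemistry


def _geochem_anchors(config: SimConfig) -> dict[str, tuple[list[float], list[float]]]:
    if len(config.stage_plan) != 3:
        raise ValueError("the geochemical template defines exactly three phases")
    (e_days, m_days, l_days) = [sorted(d) for _, d in config.stage_plan]
    bg = config.fe_background
    levels = {
        "fe2": [bg, 100.0, 130.0, 170.0, 185.0, 105.0, 85.0],
        "sulfide": [0.0, 0.0, 0.0, 0.0, 0.0, 4.0, 12.0],
        "u6": [1.3, 1.2, 1.05, 0.5, 0.2, 0.1, 0.05],
        "acetate": [0.0, 3.5, 4.5, 5.0, 5.1, 2.0, 0.8],
        "sulfate": [8.6, 8.5, 8.2, 8.0, 7.8, 7.0, 6.0],
    }
    anchor_days = [0, e_days[0], e_days[-1], m_days[0], m_days[-1], l_days[0], l_days[-1]]
    out = {}
    for analyte, values in levels.items():
        xs, ys = [], []
        for d, v in zip(anchor_days, values):
            if not xs or d > xs[-1]:
                xs.append(float(d))
                ys.append(v)
        out[analyte] = (xs, ys)
    return out


def gen_geochem(config: SimConfig) -> pd.DataFrame:
    """Per-day geochemistry following the three-phase template.

    Fe(II) rises from the configured background (~50 µM) to 100-130 µM in
    the early phase, plateaus at 170-185 µM in the middle phase, and
    declines with sulfide onset in the late phase; acetate, U(VI) and
    sulfate follow matching trajectories.  Additive Gaussian noise per
    analyte (SDs in :data:`GEOCHEM_NOISE_SD`, scaled by
    ``geochem_noise``) is clipped at zero; phases align with
    ``stage_plan`` by construction.
    """
    rng = _rng(config, _STREAM_GEOCHEM)
    anchors = _geochem_anchors(config)
    days = config.days
    data = {"day": days}
    scale = 0.0 if config.noiseless else config.geochem_noise
    for analyte, (xs, ys) in anchors.items():
        base = np.interp(days, xs, ys)
        noise = rng.normal(0.0, GEOCHEM_NOISE_SD[analyte] * scale, size=len(days))
        data[analyte] = np.clip(base + noise, 0.0, None)
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# one-call dataset


@dataclass
class Dataset:
    """Everything the pipeline consumes, plus the ledger when simulated."""

    catalogs: list[ProteinCatalog]
    psms: pd.DataFrame
    similarity: pd.DataFrame
    geochem: pd.DataFrame
    focal_genome: str
    sample_ids: list[str]
    stage_order: list[str] = field(default_factory=lambda: ["early", "middle", "late"])
    truth: GroundTruth | None = None

    @property
    def focal_catalog(self) -> ProteinCatalog:
        for cat in self.catalogs:
            if cat.genome == self.focal_genome:
                return cat
        raise ValueError(f"focal genome {self.focal_genome!r} not among catalogs")


def simulate_dataset(config: SimConfig) -> Dataset:
    """Generate catalogs, similarity, PSMs and geochemistry in one call."""
    catalogs, truth = gen_catalogs(config)
    similarity = gen_similarity_tables(
        catalogs, truth, noise_level=0.0 if config.noiseless else config.similarity_noise,
        config=config,
    )
    psms = gen_psm_table(catalogs[0], truth, config)
    geochem = gen_geochem(config)
    return Dataset(
        catalogs=catalogs,
        psms=psms,
        similarity=similarity,
        geochem=geochem,
        focal_genome=config.focal_genome,
        sample_ids=config.sample_ids,
        stage_order=config.stage_order,
        truth=truth,
    )
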