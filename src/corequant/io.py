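"""Readers and writers for the plain-text interchange formats.

Matrices travel as TSV with the processing level in a ``# level:`` header
comment and missing cells left empty; similarity tables are written one
file per ordered genome pair in BLAST outfmt-6 column order together with
a two-column protein -> genome map (the positional alignment columns are
score-free placeholders, since these tables carry only identities and
bitscores).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .catalog import ProteinCatalog
from .matrix import AbundanceMatrix
from .orthology import OUTFMT6_COLUMNS
from .simulate import Dataset, GroundTruth, SimConfig, DifferentialSpec
from .staging import StageAssignment

# ---------------------------------------------------------------------------
# matrices


def write_matrix(m: AbundanceMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# level: {m.level}\n")
        out = m.values.mask(m.missing_mask)
        out.to_csv(fh, sep="\t", index_label="protein_id", na_rep="")


def read_matrix(path: str | Path) -> AbundanceMatrix:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
        if not header.startswith("# level:"):
            raise ValueError(f"{path} lacks a '# level:' header")
        level = header.split(":", 1)[1].strip()
        values = pd.read_csv(fh, sep="\t", index_col="protein_id")
    return AbundanceMatrix(values, level=level)


# ---------------------------------------------------------------------------
# PSMs, geochemistry, stages, calls


def write_psms(psms: pd.DataFrame, path: str | Path) -> None:
    psms.to_csv(path, sep="\t", index=False)


def read_psms(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype={"peptide": str, "protein_id": str, "sample_id": str}
    )


def write_geochem(geochem: pd.DataFrame, path: str | Path) -> None:
    geochem.to_csv(path, index=False)


def read_geochem(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_stages(assignment: StageAssignment, path: str | Path) -> None:
    frame = assignment.to_frame()
    frame["sample_id"] = [f"day{d}" for d in frame["day"]]
    frame[["day", "sample_id", "stage"]].to_csv(path, sep="\t", index=False)


def read_stages(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_calls(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# similarity tables


def write_similarity(similarity: pd.DataFrame, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome_map = (
        pd.concat(
            [
                similarity[["qseqid", "qgenome"]].rename(
                    columns={"qseqid": "protein_id", "qgenome": "genome"}
                ),
                similarity[["sseqid", "sgenome"]].rename(
                    columns={"sseqid": "protein_id", "sgenome": "genome"}
                ),
            ]
        )
        .drop_duplicates()
        .sort_values(["genome", "protein_id"])
    )
    genome_map.to_csv(outdir / "genome_map.tsv", sep="\t", index=False, header=False)
    for (qg, sg), sub in similarity.groupby(["qgenome", "sgenome"], sort=True):
        out = pd.DataFrame(
            {
                "qseqid": sub["qseqid"],
                "sseqid": sub["sseqid"],
                "pident": sub["pident"].round(2),
                "length": 0,
                "mismatch": 0,
                "gapopen": 0,
                "qstart": 0,
                "qend": 0,
                "sstart": 0,
                "send": 0,
                "evalue": np.clip(10.0 ** (-sub["bitscore"] / 10.0), 1e-180, None),
                "bitscore": sub["bitscore"].round(1),
            },
            columns=list(OUTFMT6_COLUMNS),
        )
        out.to_csv(outdir / f"sim_{qg}__{sg}.tsv", sep="\t", index=False, header=False)


def read_similarity(simdir: str | Path) -> pd.DataFrame:
    """Read all per-pair outfmt-6 files plus genome_map.tsv from a directory."""
    simdir = Path(simdir)
    genome_map = pd.read_csv(
        simdir / "genome_map.tsv", sep="\t", names=["protein_id", "genome"], dtype=str
    )
    lookup = dict(zip(genome_map["protein_id"], genome_map["genome"]))
    frames = []
    for path in sorted(simdir.glob("sim_*.tsv")):
        table = pd.read_csv(
            path, sep="\t", names=list(OUTFMT6_COLUMNS), dtype={"qseqid": str, "sseqid": str}
        )
        table["qgenome"] = table["qseqid"].map(lookup)
        table["sgenome"] = table["sseqid"].map(lookup)
        frames.append(
            table[["qseqid", "sseqid", "qgenome", "sgenome", "pident", "bitscore"]]
        )
    if not frames:
        raise ValueError(f"no sim_*.tsv files under {simdir}")
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# whole datasets


def write_dataset(dataset: Dataset, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    catdir = outdir / "catalogs"
    catdir.mkdir(exist_ok=True)
    for cat in dataset.catalogs:
        cat.to_tsv(catdir / f"{cat.genome}.tsv")
        if cat.sequences:
            cat.to_fasta(catdir / f"{cat.genome}.faa")
    write_psms(dataset.psms, outdir / "psms.tsv")
    write_similarity(dataset.similarity, outdir / "similarity")
    write_geochem(dataset.geochem, outdir / "geochem.csv")
    meta = {
        "focal_genome": dataset.focal_genome,
        "sample_ids": dataset.sample_ids,
        "stage_order": dataset.stage_order,
        "genomes": [c.genome for c in dataset.catalogs],
    }
    (outdir / "dataset.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    if dataset.truth is not None:
        dataset.truth.to_json(outdir / "ground_truth.json")


def load_dataset(indir: str | Path) -> Dataset:
    indir = Path(indir)
    meta = yaml.safe_load((indir / "dataset.yaml").read_text())
    catalogs = [
        ProteinCatalog.from_tsv(indir / "catalogs" / f"{g}.tsv", genome=g)
        for g in meta["genomes"]
    ]
    truth_path = indir / "ground_truth.json"
    return Dataset(
        catalogs=catalogs,
        psms=read_psms(indir / "psms.tsv"),
        similarity=read_similarity(indir / "similarity"),
        geochem=read_geochem(indir / "geochem.csv"),
        focal_genome=meta["focal_genome"],
        sample_ids=list(meta["sample_ids"]),
        stage_order=list(meta["stage_order"]),
        truth=GroundTruth.from_json(truth_path) if truth_path.exists() else None,
    )


# ---------------------------------------------------------------------------
# configs


def load_sim_config(path: str | Path) -> SimConfig:
    """Build a :class:`SimConfig` from a YAML mapping of its fields."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "differential_plan" in raw:
        raw["differential_plan"] = tuple(
            DifferentialSpec(**spec) for spec in raw["differential_plan"]
        )
    for key in ("genome_sizes", "genome_names", "sample_depth_cycle"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    if "stage_plan" in raw:
        raw["stage_plan"] = tuple((s, tuple(d)) for s, d in raw["stage_plan"])
    return SimConfig(**raw)
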