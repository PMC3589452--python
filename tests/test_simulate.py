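"""The synthetic study generator: structure, determinism, ledger consistency."""

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import corequant as cq
from corequant import io
from corequant.identifications import FilterPolicy, filter_psms
from corequant.simulate import DifferentialSpec, SimConfig


def tiny_config(**overrides):
    defaults = dict(
        n_genomes=3,
        genome_sizes=(30, 32, 28),
        core_fraction=0.5,
        detected_fraction=0.8,
        differential_plan=(DifferentialSpec("C", "early", "middle", "increased", 3),),
        with_sequences=False,
        seed=0,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


class TestConfigValidation:
    def test_rejects_inconsistent_designs(self):
        with pytest.raises(ValueError):
            tiny_config(genome_sizes=(30, 32))  # wrong length
        with pytest.raises(ValueError):
            tiny_config(genome_sizes=(30, -1, 28))
        with pytest.raises(ValueError):
            tiny_config(core_fraction=1.2)
        with pytest.raises(ValueError):
            tiny_config(dropout_rate=1.0)
        with pytest.raises(ValueError):
            tiny_config(n_samples=5)  # stage plan still lists 9 days
        with pytest.raises(ValueError):
            tiny_config(
                differential_plan=(DifferentialSpec("C", "middle", "early", "increased", 2),)
            )


class TestCatalogs:
    def test_full_core_two_genomes(self):
        cfg = SimConfig(
            n_genomes=2, genome_sizes=(10, 10), core_fraction=1.0,
            detected_fraction=1.0, differential_plan=(), with_sequences=False, seed=1,
        )
        catalogs, truth = cq.gen_catalogs(cfg)
        assert len(truth.ortholog_membership) == 10
        for members in truth.ortholog_membership.values():
            assert {g for g, _ in members} == {"g1", "g2"}

    def test_zero_core_fraction_spans_no_full_panel_group(self):
        cfg = tiny_config(core_fraction=0.0)
        _, truth = cq.gen_catalogs(cfg)
        spans = [{g for g, _ in m} for m in truth.ortholog_membership.values()]
        assert all(len(s) < cfg.n_genomes for s in spans)

    def test_core_count_matches_design(self):
        cfg = cq.SimConfig.small(seed=1)
        catalogs, truth = cq.gen_catalogs(cfg)
        expected = round(cfg.core_fraction * min(cfg.genome_sizes))
        assert len(truth.core_group_ids([c.genome for c in catalogs])) == expected

    def test_catalog_sizes_lengths_and_cogs(self):
        cfg = tiny_config()
        catalogs, truth = cq.gen_catalogs(cfg)
        assert [len(c) for c in catalogs] == list(cfg.genome_sizes)
        for cat in catalogs:
            assert (cat.table["length"] >= 50).all()
            assert set(cat.table["cog"]) <= set(cq.simulate.COG_LETTERS) | {"-"}
        # planted proteins carry their planted category
        focal = catalogs[0].cogs()
        for pid in truth.differential_proteins:
            assert focal[pid] == "C"

    def test_sequences_match_lengths_and_fasta_round_trip(self, tmp_path):
        cfg = tiny_config(with_sequences=True)
        catalogs, _ = cq.gen_catalogs(cfg)
        cat = catalogs[0]
        for pid, length in cat.lengths().items():
            assert len(cat.sequences[pid]) == length
        path = tmp_path / "cat.faa"
        cat.to_fasta(path)
        from Bio import SeqIO

        records = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
        assert records == cat.sequences


class TestSimilarity:
    def test_noiseless_true_pairs_are_mutual_best(self):
        cfg = tiny_config()
        catalogs, truth = cq.gen_catalogs(cfg)
        sim = cq.gen_similarity_tables(catalogs, truth, noise_level=0.0, config=cfg)
        builder = cq.OrthologGroupBuilder().fit(sim)
        assert {g for g in builder.groups_.as_set() if len(g) >= 2} == truth.multi_groups()

    def test_two_genome_hand_enumeration(self):
        cfg = SimConfig(
            n_genomes=2, genome_sizes=(3, 3), core_fraction=1.0,
            detected_fraction=1.0, differential_plan=(), with_sequences=False, seed=2,
        )
        catalogs, truth = cq.gen_catalogs(cfg)
        sim = cq.gen_similarity_tables(catalogs, truth, noise_level=0.0, config=cfg)
        true_rows = sim[sim["bitscore"] == 500.0]
        # every planted pair appears in both directions at the top score
        expected = set()
        for members in truth.ortholog_membership.values():
            (g1, p1), (g2, p2) = sorted(members)
            expected |= {(p1, p2), (p2, p1)}
        assert set(zip(true_rows["qseqid"], true_rows["sseqid"])) == expected
        # decoys never reach the true score
        assert (sim.loc[~sim.index.isin(true_rows.index), "bitscore"] < 500).all()

    def test_empty_catalog_pair_gives_empty_table(self):
        cfg = SimConfig(
            n_genomes=2, genome_sizes=(1, 1), core_fraction=0.0,
            detected_fraction=1.0, differential_plan=(), with_sequences=False, seed=0,
        )
        catalogs, truth = cq.gen_catalogs(cfg)
        sim = cq.gen_similarity_tables(catalogs, truth, config=cfg)
        assert len(sim) == 0


class TestPSMs:
    def test_full_dropout_stage_emits_no_rows(self):
        cfg = tiny_config(
            dropout_rate={"early": 0.0, "middle": 0.999999, "late": 0.0},
            filter_fail_rate=0.0,
        )
        ds = cq.simulate_dataset(cfg)
        middle_days = dict(cfg.stage_plan)["middle"]
        middle = ds.psms[ds.psms["sample_id"].isin([f"day{d}" for d in middle_days])]
        assert len(middle) == 0

    def test_filter_fail_fraction_close_to_configured(self):
        cfg = cq.SimConfig.small(seed=5, filter_fail_rate=0.3)
        ds = cq.simulate_dataset(cfg)
        kept = filter_psms(ds.psms, FilterPolicy())
        frac = 1.0 - len(kept) / len(ds.psms)
        # binomial error on ~1000 rows is well under 0.05
        assert abs(frac - 0.3) < 0.05

    def test_zero_count_proteins_emit_no_rows(self):
        cfg = tiny_config(noiseless=True)
        ds = cq.simulate_dataset(cfg)
        # planted proteins are two decades down in their low stage: absent
        for pid, spec in ds.truth.differential_proteins.items():
            low_days = dict(cfg.stage_plan)["early"]  # increased e->m: low early
            rows = ds.psms[
                (ds.psms["protein_id"] == pid)
                & ds.psms["sample_id"].isin([f"day{d}" for d in low_days])
            ]
            assert len(rows) == 0

    def test_planted_up_shift_gives_positive_delta_z_sign(self):
        positive = evaluated = 0
        n = 30
        for seed in range(n):
            cfg = tiny_config(seed=seed)
            ds = cq.simulate_dataset(cfg)
            res = cq.run_pipeline(ds, with_orthology=False)
            calls = res.calls.set_index(["protein_id", "stage_from", "stage_to"])
            for pid, spec in ds.truth.differential_proteins.items():
                key = (pid, spec["stage_from"], spec["stage_to"])
                if key in calls.index:
                    evaluated += 1
                    positive += calls.loc[key, "delta_z"] > 0
        assert evaluated >= 0.8 * n * 3  # planted proteins are nearly always detected
        assert positive / evaluated > 0.95


class TestGeochem:
    def test_day_zero_equals_background(self):
        cfg = tiny_config(
            noiseless=True,
            stage_plan=(("early", (0, 8, 10)), ("middle", (13, 15, 17)), ("late", (29, 36, 43))),
        )
        geo = cq.gen_geochem(cfg)
        assert geo.loc[geo["day"] == 0, "fe2"].iloc[0] == pytest.approx(cfg.fe_background)

    def test_phases_align_with_stage_plan(self):
        geo = cq.gen_geochem(tiny_config(noiseless=True))
        by_day = geo.set_index("day")
        early_fe = by_day.loc[[5, 8, 10], "fe2"].mean()
        middle_fe = by_day.loc[[13, 15, 17], "fe2"].mean()
        late_s = by_day.loc[[29, 36, 43], "sulfide"]
        assert middle_fe > early_fe > cq.SimConfig().fe_background
        assert (by_day.loc[[5, 8, 10, 13, 15, 17], "sulfide"] == 0).all()
        assert (late_s > 0).all()

    def test_concentrations_never_negative(self):
        for seed in range(5):
            geo = cq.gen_geochem(tiny_config(seed=seed, geochem_noise=3.0))
            assert (geo[list(cq.staging.ANALYTES)].to_numpy() >= 0).all()


class TestDeterminismAndLedger:
    def _digest(self, tmp_path: Path, seed: int, tag: str) -> str:
        out = tmp_path / f"run_{tag}"
        io.write_dataset(cq.simulate_dataset(cq.SimConfig.small(seed=seed)), out)
        h = hashlib.sha256()
        for p in sorted(out.rglob("*")):
            if p.is_file():
                h.update(p.relative_to(out).as_posix().encode())
                h.update(p.read_bytes())
        return h.hexdigest()

    def test_same_seed_byte_identical_outputs(self, tmp_path):
        assert self._digest(tmp_path, 7, "a") == self._digest(tmp_path, 7, "b")
        assert self._digest(tmp_path, 7, "c") != self._digest(tmp_path, 8, "d")

    def test_files_reproduce_ledger_membership(self, tmp_path):
        # re-deriving groups from the written similarity files gives back
        # exactly the ledgered membership
        cfg = cq.SimConfig.small(seed=9, noiseless=True)
        out = tmp_path / "ds"
        io.write_dataset(cq.simulate_dataset(cfg), out)
        reloaded = io.load_dataset(out)
        builder = cq.OrthologGroupBuilder().fit(reloaded.similarity)
        found = {g for g in builder.groups_.as_set() if len(g) >= 2}
        assert found == reloaded.truth.multi_groups()

    def test_ground_truth_json_round_trip(self, tmp_path):
        _, truth = cq.gen_catalogs(tiny_config())
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = cq.GroundTruth.from_json(path)
        assert back.ortholog_membership == truth.ortholog_membership
        assert back.differential_proteins == truth.differential_proteins
        assert back.stage_labels == truth.stage_labels
        assert back.expressed_proteins == truth.expressed_proteins
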