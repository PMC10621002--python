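"""Generator contracts: determinism, planted structure, round trips."""

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import magcoex as m
from magcoex.errors import ConfigError


def _dir_hashes(d):
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(Path(d).iterdir())
    }


class TestDeterminism:
    def test_same_seed_same_tables(self):
        cfg = m.SyntheticConfig(seed=3, n_mags=12, genes_per_mag=(3, 5),
                                target_block=frozenset({0, 1}),
                                anti_block=frozenset({2, 3}),
                                role_plantings={})
        a, b = m.simulate(cfg), m.simulate(cfg)
        pd.testing.assert_frame_equal(a.quant, b.quant)
        pd.testing.assert_frame_equal(a.gene_meta, b.gene_meta)
        pd.testing.assert_frame_equal(a.truth.trajectories,
                                      b.truth.trajectories)

    def test_written_files_byte_identical(self, tmp_path, toy_community):
        m.write_community(toy_community, tmp_path / "a")
        m.write_community(toy_community, tmp_path / "b")
        assert _dir_hashes(tmp_path / "a") == _dir_hashes(tmp_path / "b")


class TestConfig:
    def test_overlapping_blocks_rejected(self):
        with pytest.raises(ConfigError, match="overlap"):
            m.SyntheticConfig(
                target_block=frozenset({1, 2}), anti_block=frozenset({2, 3})
            ).resolved()

    def test_out_of_range_planting_rejected(self):
        with pytest.raises(ConfigError):
            m.SyntheticConfig(
                n_mags=5, target_block=frozenset({0}), n_targets=1,
                anti_block=frozenset(),
                role_plantings={"rp_producer": frozenset({9})},
            ).resolved()

    def test_no_rrna_when_fraction_zero(self):
        c = m.simulate(m.SyntheticConfig(seed=1, n_mags=6, frac_rrna=0.0,
                                         target_block=frozenset({0, 1}),
                                         anti_block=frozenset(),
                                         role_plantings={}))
        assert set(c.gene_meta["biotype"]) == {"CDS"}


class TestPlantedStructure:
    def test_rank_preservation_in_noise_free_limit(self):
        """Summed CDS counts per MAG follow the latent trajectory's sample
        rank order exactly when dispersion is zero."""
        c = m.simulate(m.SyntheticConfig(seed=5, n_mags=10, nb_dispersion=0.0,
                                         target_block=frozenset({0, 1}),
                                         anti_block=frozenset({2, 3}),
                                         role_plantings={}))
        cds = c.gene_meta.loc[c.gene_meta.biotype == "CDS", "gene_id"]
        counts = (
            c.quant[c.quant.gene_id.isin(cds)]
            .merge(c.gene_meta[["gene_id", "mag_id"]], on="gene_id")
            .pivot_table(index="mag_id", columns="sample_id",
                         values="est_count", aggfunc="sum")
        )
        traj = c.truth.trajectories
        for mag in counts.index:
            assert (
                counts.loc[mag].rank().sort_index().tolist()
                == traj.loc[mag].rank().sort_index().tolist()
            )

    def test_block_tpm_profiles_perfectly_co_monotone(self):
        """In the noise-free limit the whole target block reaches Spearman
        rho = 1 pairwise after the TPM aggregation stage (the pipeline
        itself serves as the oracle)."""
        block = frozenset(range(5))
        c = m.simulate(m.SyntheticConfig(seed=9, n_mags=12, nb_dispersion=0.0,
                                         target_block=block,
                                         anti_block=frozenset({5, 6}),
                                         role_plantings={}))
        tpm = m.mag_tpm(c.quant, c.gene_meta).tpm
        ids = sorted(f"MAG{i:03d}" for i in block)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                rho, _ = m.spearman(tpm.loc[a], tpm.loc[b])
                assert rho == pytest.approx(1.0, abs=1e-12)

    def test_anti_block_never_tracks_the_target(self, toy_community):
        traj = toy_community.truth.trajectories
        cfg = toy_community.config
        target = traj.loc[f"MAG{min(cfg.target_block):03d}"]
        for i in cfg.anti_block:
            rho, _ = m.spearman(traj.loc[f"MAG{i:03d}"], target)
            assert rho <= 0

    def test_marker_planting_expressed_in_two_samples(self, toy_community):
        """Every planted role MAG carries expressed marker genes that
        satisfy the rule at the default threshold."""
        rules = {r.role: r for r in m.default_rules()}
        for mag, roles in toy_community.truth.planted_roles.items():
            genes = toy_community.gene_meta[
                toy_community.gene_meta.mag_id == mag
            ]
            for role in roles:
                fams = {f for fs in genes.marker_families for f in fs}
                from magcoex.roles import evaluate_rule

                assert evaluate_rule(rules[role].requirement, fams)
                for gid in genes.loc[genes.marker_families.map(bool),
                                     "gene_id"]:
                    assert m.gene_expressed(toy_community.quant, gid,
                                            min_samples=2)


class TestWriteCommunity:
    def test_toy_layout(self, tmp_path):
        c = m.simulate(m.SyntheticConfig(seed=2, n_mags=2, genes_per_mag=(2, 3),
                                         n_samples_per_condition=1,
                                         target_block=frozenset({0, 1}),
                                         anti_block=frozenset(),
                                         role_plantings={}, n_targets=1))
        m.write_community(c, tmp_path)
        names = {p.name for p in tmp_path.iterdir()}
        assert names == {"quant_T1.tsv", "quant_C1.tsv", "gene_meta.tsv",
                         "samples.tsv", "targets.txt", "ground_truth.json"}

    def test_round_trip_through_io(self, tmp_path, toy_community):
        m.write_community(toy_community, tmp_path)
        samples = m.read_samples(tmp_path / "samples.tsv")
        pd.testing.assert_frame_equal(samples, toy_community.samples)
        meta = m.read_gene_meta(tmp_path / "gene_meta.tsv")
        pd.testing.assert_frame_equal(meta, toy_community.gene_meta)
        assert m.read_targets(tmp_path / "targets.txt") == toy_community.targets
        frames = [
            m.read_quant(tmp_path / f"quant_{s}.tsv", s)
            for s in samples["sample_id"]
        ]
        quant = (
            pd.concat(frames, ignore_index=True)
            .sort_values(["gene_id", "sample_id"])
            .reset_index(drop=True)
        )
        orig = (
            toy_community.quant.sort_values(["gene_id", "sample_id"])
            .reset_index(drop=True)
        )
        assert np.allclose(quant["est_count"], orig["est_count"], rtol=1e-12)
        assert np.allclose(quant["eff_length"], orig["eff_length"], rtol=1e-12)

    def test_ground_truth_json_lists_planted_edges(self, tmp_path,
                                                   toy_community):
        m.write_community(toy_community, tmp_path)
        payload = json.loads((tmp_path / "ground_truth.json").read_text())
        assert {tuple(e) for e in payload["planted_edges"]} == \
            toy_community.truth.planted_edges
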