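import filecmp

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import vmerv
from vmerv.methylation import ReplicateMeta

from conftest import single_element_config


class TestGenerateAnnotation:
    def test_zero_counts_give_empty_fragments_but_genes(self):
        cfg = vmerv.SimulationConfig(seed=0, element_counts={})
        fragments, genes, truth = vmerv.generate_annotation(cfg)
        assert len(fragments) == 0
        assert len(genes) > 0
        assert len(truth.elements) == 0

    def test_full_length_elements_emit_fragment_triplets(self):
        cfg = vmerv.SimulationConfig(
            seed=3,
            element_counts={("IAP", "full_length", "hypermethylated"): 5},
        )
        fragments, _genes, truth = vmerv.generate_annotation(cfg)
        assert len(fragments) == 15  # LTR + internal + LTR per element
        assert (fragments["repFamily"] == "ERVK").all()
        assert len(truth.elements) == 5

    def test_same_seed_gives_byte_identical_outputs(self, tmp_path):
        outs = []
        for sub in ("a", "b"):
            cfg = single_element_config("variable", seed=11)
            fragments, genes, truth = vmerv.generate_annotation(cfg)
            trackset = vmerv.generate_methylation_tracks(truth, cfg)
            d = tmp_path / sub
            vmerv.simulate.write_annotation(fragments, genes, d)
            truth.write(d)
            trackset.write(d / "tracks")
            outs.append(d)
        for rel in ("rmsk.tsv", "genes.bed", "truth.json", "tracks/B_F_WGBS_1.bedGraph"):
            assert filecmp.cmp(outs[0] / rel, outs[1] / rel, shallow=False), rel

    def test_zero_chromosome_length_rejected(self):
        cfg = vmerv.SimulationConfig(seed=0, chrom_length_bp=0)
        with pytest.raises(ValueError):
            vmerv.generate_annotation(cfg)

    def test_intervals_within_chromosome_bounds(self, sim_bundle):
        cfg = sim_bundle["config"]
        el = sim_bundle["truth"].elements
        assert (el["start"] >= 0).all()
        assert (el["end"] <= cfg.chrom_length_bp).all()
        frags = sim_bundle["fragments"]
        assert (frags["start"] < frags["end"]).all()

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = vmerv.SimulationConfig(seed=9, coverage=12.5)
        cfg.to_yaml(tmp_path / "cfg.yaml")
        back = vmerv.SimulationConfig.from_yaml(tmp_path / "cfg.yaml")
        assert back == cfg


class TestGenerateMethylationTracks:
    def test_high_coverage_hypermethylated_converges_to_mean(self):
        cfg = single_element_config("hypermethylated", coverage=1e6)
        cfg.hyper_mean, cfg.hyper_sd = 0.9, 0.0
        _f, _g, truth = vmerv.generate_annotation(cfg)
        trackset = vmerv.generate_methylation_tracks(truth, cfg)
        for rep in cfg.replicates:
            vals = trackset.tracks[rep.id]["fraction"].to_numpy()
            expected = 0.9 * (1 - cfg.hmc_fraction) if rep.assay == "oxBS" else 0.9
            assert np.allclose(vals, expected, atol=0.005)

    def test_celltype_dmr_separates_cell_types(self):
        cfg = single_element_config("celltype_DMR", seed=5)
        _f, _g, truth = vmerv.generate_annotation(cfg)
        trackset = vmerv.generate_methylation_tracks(truth, cfg)
        elements = vmerv.truth_to_elements(truth)
        summaries = vmerv.summarize_ltr_methylation(elements, trackset)
        s = summaries[0]
        b_means = [s.means[r.id] for r in cfg.replicates if r.cell_type == "B"]
        t_means = [s.means[r.id] for r in cfg.replicates if r.cell_type == "T"]
        assert min(b_means) > max(t_means)

    def test_all_fractions_within_unit_interval(self, sim_bundle):
        for df in sim_bundle["trackset"].tracks.values():
            vals = df["fraction"].to_numpy()
            assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_each_cpg_yields_two_strand_records(self, sim_bundle):
        truth = sim_bundle["truth"]
        df = sim_bundle["trackset"].tracks["B_F_WGBS_1"]
        with_5p = truth.elements[truth.elements["ltr5_start"] >= 0]
        row = with_5p.iloc[0]
        seq = truth.ltr_sequences[(row["id"], "5p")]
        n_cpg = sum(1 for i in range(len(seq) - 1) if seq[i : i + 2] == "CG")
        lo, hi = int(row["ltr5_start"]), int(row["ltr5_end"])
        sub = df[(df["chrom"] == row["chrom"]) & (df["pos"] >= lo) & (df["pos"] < hi + 1)]
        # Poisson depth at coverage 30 essentially never drops a strand record
        assert len(sub) == 2 * n_cpg

    def test_smaller_pools_give_larger_across_replicate_variance(self):
        # pooling averages individual levels, so 1-individual pools must scatter more
        def across_rep_variance(pool_size, seed):
            reps = [
                ReplicateMeta(id=f"r{i}", cell_type="B", sex="F", assay="WGBS", pool_size=pool_size)
                for i in range(8)
            ]
            cfg = single_element_config("variable", seed=seed, coverage=200.0)
            cfg.replicates = reps
            _f, _g, truth = vmerv.generate_annotation(cfg)
            trackset = vmerv.generate_methylation_tracks(truth, cfg)
            elements = vmerv.truth_to_elements(truth)
            s = vmerv.summarize_ltr_methylation(elements, trackset)[0]
            return np.var([s.means[r.id] for r in reps])

        v1 = np.mean([across_rep_variance(1, s) for s in range(100)])
        v5 = np.mean([across_rep_variance(5, s) for s in range(100)])
        assert v1 > v5

    def test_shared_pools_reuse_individuals_across_cell_types(self):
        cfg = vmerv.SimulationConfig(seed=0, share_individuals_between_cell_types=True)
        _f, _g, truth = vmerv.generate_annotation(cfg)
        assert np.array_equal(truth.pools["B_F_WGBS_1"], truth.pools["T_F_WGBS_1"])
        assert not np.array_equal(truth.pools["B_F_WGBS_1"], truth.pools["B_M_WGBS_1"])

    def test_latent_levels_within_unit_interval(self, sim_bundle):
        for arr in sim_bundle["truth"].latents.values():
            assert arr.min() >= 0.0 and arr.max() <= 1.0


class TestGenerateContext:
    def test_planted_distance_zero_yields_touching_peak(self):
        cfg = single_element_config("variable", seed=2)
        cfg.peak_distance_bp = (0, 0)
        _f, _g, truth = vmerv.generate_annotation(cfg)
        ctx = vmerv.generate_context(truth, cfg)
        el = vmerv.truth_to_elements(truth)[0]
        planted = ctx.peaks[ctx.peaks["name"] == f"peak_{el.id}"]
        assert len(planted) == 1
        assert vmerv.distance_to_nearest_peak(el, planted) == 0

    def test_planted_transcripts_hit_exactly_the_planted_group(self):
        cfg = single_element_config("variable", seed=4)
        cfg.n_transcript_elements = 1
        _f, _g, truth = vmerv.generate_annotation(cfg)
        truth.elements.loc[0, ["transcript_cell", "transcript_sex"]] = ("B", "F")
        truth.elements.loc[0, "transcript_nreps"] = 3
        ctx = vmerv.generate_context(truth, cfg)
        el = vmerv.truth_to_elements(truth)[0]
        planted = {
            rid
            for rid, df in ctx.transcripts.items()
            if (df["name"] == f"tx_{el.id}").any()
        }
        assert planted == {"RNA_B_F_1", "RNA_B_F_2", "RNA_B_F_3"}
        for rid in planted:
            df = ctx.transcripts[rid]
            tx = df[df["name"] == f"tx_{el.id}"].iloc[0]
            assert tx["start"] < el.end and tx["end"] > el.start

    def test_empty_truth_gives_empty_context(self):
        cfg = vmerv.SimulationConfig(seed=0, element_counts={}, n_genes=0)
        _f, _g, truth = vmerv.generate_annotation(cfg)
        ctx = vmerv.generate_context(truth, cfg)
        assert len(ctx.signal) == 0
        assert len(ctx.de_genes) == 0
        assert all(len(df) == 0 for df in ctx.transcripts.values())
        assert (ctx.peaks["name"].str.startswith("bg_")).all()

    def test_planted_peak_beyond_bounds_rejected(self):
        cfg = single_element_config("variable", seed=2)
        _f, _g, truth = vmerv.generate_annotation(cfg)
        truth.elements.loc[0, "peak_distance"] = 10**9
        with pytest.raises(ValueError):
            vmerv.generate_context(truth, cfg)

    def test_de_list_contains_nearest_genes_of_flagged_elements(self, sim_bundle):
        truth = sim_bundle["truth"]
        ctx = vmerv.generate_context(truth, sim_bundle["config"])
        flagged = truth.elements[truth.elements["de_overlap"]]
        assert len(ctx.de_genes) > 0
        by_id = {e.id: e for e in vmerv.truth_to_elements(truth)}
        for eid in flagged["id"]:
            gene, _d = vmerv.nearest_gene(by_id[eid], truth.genes)
            assert gene in ctx.de_genes


class TestGeneratePedigree:
    def test_degenerate_model_returns_intercept_everywhere(self):
        df = vmerv.generate_pedigree(
            seed=1, n_pairs=3, litters_per_pair=2, pups_per_litter=4,
            beta_maternal=0, beta_paternal=0, beta_sex=0, intercept=0.7,
            sd_pair=0, sd_litter=0, sd_residual=0,
        )
        assert np.allclose(df["methylation"], expit(0.7))

    def test_pure_maternal_identity(self):
        df = vmerv.generate_pedigree(
            seed=2, n_pairs=4, litters_per_pair=1, pups_per_litter=3,
            beta_maternal=1.0, beta_paternal=0, beta_sex=0, intercept=0,
            sd_pair=0, sd_litter=0, sd_residual=0,
        )
        assert np.allclose(df["methylation"], df["maternal_methylation"])

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError):
            vmerv.generate_pedigree(n_pairs=0)
        with pytest.raises(ValueError):
            vmerv.generate_pedigree(sd_pair=-1)

    def test_litters_nested_within_pairs(self):
        df = vmerv.generate_pedigree(seed=3, n_pairs=5, litters_per_pair=2, pups_per_litter=4)
        nesting = df.groupby("litter_id")["pair_id"].nunique()
        assert (nesting == 1).all()
        assert df["litter_id"].nunique() == 10
        assert set(df["sex"]) == {"F", "M"}
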