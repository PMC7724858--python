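from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from germnet import network_analysis as na
from germnet import synthetic_data as sd
from germnet.errors import ArgumentError, DataError, SizingError
from germnet.stats_core import ContingencyTable2x2, woolf_or


class TestConfig:
    def test_probability_bounds(self):
        with pytest.raises(ArgumentError):
            sd.SimulationConfig(error_rate=1.5)

    def test_negative_count(self):
        with pytest.raises(ArgumentError):
            sd.SimulationConfig(n_genes=-1)

    def test_variants_exceed_genome(self):
        with pytest.raises(ArgumentError):
            sd.SimulationConfig(genome_length=10, n_genes=0, n_germline=8, n_somatic=5)

    def test_true_or(self):
        cfg = sd.SimulationConfig(exposure_probs=(0.3, 0.15))
        assert cfg.true_or == pytest.approx(2.4286, abs=1e-4)


class TestSynthGenome:
    def test_no_genes(self):
        cfg = sd.SimulationConfig(seed=1, genome_length=500, n_genes=0)
        genome, models = sd.synth_genome(cfg)
        assert len(genome) == 500
        assert models == []
        assert set(genome) <= set("ACGT")

    def test_determinism(self, small_config):
        a = sd.synth_genome(small_config)
        b = sd.synth_genome(small_config)
        assert a[0] == b[0]
        assert a[1] == b[1]

    def test_model_invariants(self):
        cfg = sd.SimulationConfig(seed=7, genome_length=60000, n_genes=20)
        genome, models = sd.synth_genome(cfg)
        assert len(models) == 20
        prev_end = -1
        for m in models:
            cds = m.cds_positions()
            assert len(cds) % 3 == 0
            assert m.codable
            assert m.tx_start > prev_end  # non-overlapping
            prev_end = m.tx_end
            # start codon in transcript orientation
            if m.strand == "+":
                first = "".join(genome[p] for p in cds[:3])
                assert first == "ATG"
            else:
                comp = str.maketrans("ACGT", "TGCA")
                first = "".join(genome[p] for p in cds[-3:][::-1]).translate(comp)
                assert first == "ATG"

    def test_infeasible_sizing(self):
        with pytest.raises(SizingError):
            sd.synth_genome(sd.SimulationConfig(genome_length=1000, n_genes=10))


class TestSynthPileup:
    def noiseless_cfg(self, **kw):
        base = dict(
            seed=2, genome_length=400, n_genes=0, depth_mean=30.0, error_rate=0.0,
            n_germline=0, n_somatic=0,
        )
        base.update(kw)
        return sd.SimulationConfig(**base)

    def test_noiseless_no_variants(self):
        cfg = self.noiseless_cfg()
        genome, _ = sd.synth_genome(cfg)
        pile = sd.synth_pileup(genome, sd.GroundTruth(), cfg, "blood")
        for b in "ACGT":
            non_ref = pile.loc[pile["REF"] != b, b]
            ref_rows = pile.loc[pile["REF"] == b]
            assert (ref_rows[b] == ref_rows["DEPTH"]).all()
        assert (pile[["A", "C", "G", "T"]].sum(axis=1) == pile["DEPTH"]).all()

    def test_hom_site_forced_in_all_tissues(self):
        cfg = self.noiseless_cfg()
        genome, _ = sd.synth_genome(cfg)
        ref = genome[49]
        alt = "A" if ref != "A" else "C"
        truth = sd.GroundTruth(germline_sites=[(50, ref, alt, "hom")])
        for tissue in ("blood", "para", "cancer"):
            pile = sd.synth_pileup(genome, truth, cfg, tissue)
            row = pile.iloc[49]
            assert row[alt] == row["DEPTH"]

    def test_somatic_only_in_cancer(self):
        cfg = self.noiseless_cfg(cancer_fraction=1.0)
        genome, _ = sd.synth_genome(cfg)
        ref = genome[99]
        alt = "G" if ref != "G" else "T"
        truth = sd.GroundTruth(somatic_sites=[(100, ref, alt, 1.0)])
        cancer = sd.synth_pileup(genome, truth, cfg, "cancer")
        blood = sd.synth_pileup(genome, truth, cfg, "blood")
        assert cancer.iloc[99][alt] == cancer.iloc[99]["DEPTH"]
        assert blood.iloc[99][alt] == 0

    def test_het_alt_fraction_law_of_large_numbers(self):
        cfg = sd.SimulationConfig(
            seed=3, genome_length=2000, n_genes=0, depth_mean=50.0, error_rate=0.0,
            n_germline=0, n_somatic=0,
        )
        genome = "A" * 2000
        sites = [(p, "A", "G", "het") for p in range(1, 1001)]
        truth = sd.GroundTruth(germline_sites=sites)
        pile = sd.synth_pileup(genome, truth, cfg, "blood")
        sub = pile.iloc[:1000]
        frac = (sub["G"] / sub["DEPTH"]).mean()
        assert frac == pytest.approx(0.5, abs=0.02)

    def test_unknown_tissue(self):
        cfg = self.noiseless_cfg()
        genome, _ = sd.synth_genome(cfg)
        with pytest.raises(ArgumentError):
            sd.synth_pileup(genome, sd.GroundTruth(), cfg, "plasma")

    def test_out_of_genome_position(self):
        cfg = self.noiseless_cfg()
        genome, _ = sd.synth_genome(cfg)
        truth = sd.GroundTruth(germline_sites=[(5000, "A", "G", "hom")])
        with pytest.raises(DataError):
            sd.synth_pileup(genome, truth, cfg, "blood")

    def test_determinism(self, small_config):
        genome, models = sd.synth_genome(small_config)
        truth = sd.synth_truth(small_config, genome, models, coding_only=True)
        a = sd.synth_pileup(genome, truth, small_config, "para")
        b = sd.synth_pileup(genome, truth, small_config, "para")
        pd.testing.assert_frame_equal(a, b)


class TestSynthTruth:
    def test_disjoint_positions(self, small_config):
        genome, models = sd.synth_genome(small_config)
        truth = sd.synth_truth(small_config, genome, models)
        germ = {p for p, *_ in truth.germline_sites}
        som = {p for p, *_ in truth.somatic_sites}
        assert germ.isdisjoint(som)
        assert len(germ) == small_config.n_germline
        assert len(som) == small_config.n_somatic

    def test_ref_matches_genome(self, small_config):
        genome, models = sd.synth_genome(small_config)
        truth = sd.synth_truth(small_config, genome, models, coding_only=True)
        for pos, ref, alt, _ in truth.germline_sites:
            assert genome[pos - 1] == ref
            assert alt != ref

    def test_json_roundtrip(self, small_config):
        genome, models = sd.synth_genome(small_config)
        truth = sd.synth_truth(small_config, genome, models)
        back = sd.GroundTruth.from_json(truth.to_json())
        assert back == truth


class TestSynthPPI:
    def test_tree_when_attach_one(self):
        cfg = sd.SimulationConfig(
            seed=4, ppi_nodes=50, ppi_attach=1, planted_module_size=0
        )
        edges, planted = sd.synth_ppi(cfg, sd.default_gene_names(100))
        assert planted == set()
        assert len(edges) == 49

    def test_determinism(self, small_config):
        a_edges, a_planted = sd.synth_ppi(small_config, sd.default_gene_names(600))
        b_edges, b_planted = sd.synth_ppi(small_config, sd.default_gene_names(600))
        pd.testing.assert_frame_equal(a_edges, b_edges)
        assert a_planted == b_planted

    def test_no_self_loops_or_duplicates(self, small_config):
        edges, _ = sd.synth_ppi(small_config, sd.default_gene_names(600))
        assert (edges["protein1"] != edges["protein2"]).all()
        pairs = list(zip(edges["protein1"], edges["protein2"]))
        assert len(set(pairs)) == len(pairs)

    def test_scores_clear_threshold(self, small_config):
        edges, _ = sd.synth_ppi(small_config, sd.default_gene_names(600))
        assert (edges["combined_score"] >= 700).all()
        assert (edges["combined_score"] <= 950).all()

    def test_attach_too_large(self):
        cfg = sd.SimulationConfig(ppi_nodes=5, ppi_attach=5, planted_module_size=0)
        with pytest.raises(ArgumentError):
            sd.synth_ppi(cfg, sd.default_gene_names(100))

    def test_planted_module_more_interconnected(self, small_config):
        """Main-graph fraction of a module-drawn gene set beats an equal-size
        random set in >= 95% of seeds (module size >= 20)."""
        wins = 0
        n_seeds = 40
        names = sd.default_gene_names(small_config.n_gene_universe)
        for seed in range(n_seeds):
            cfg = replace(small_config, seed=seed)
            edges, planted = sd.synth_ppi(cfg, names)
            rng = np.random.default_rng(seed)
            module_set = set(
                np.array(sorted(planted))[
                    rng.choice(len(planted), size=20, replace=False)
                ]
            )
            random_set = set(
                np.array(names)[rng.choice(len(names), size=20, replace=False)]
            )
            _, f_mod = na.main_fraction_point(module_set, edges)
            _, f_rand = na.main_fraction_point(random_set, edges)
            wins += f_mod > f_rand
        assert wins / n_seeds >= 0.95


class TestSynthPathways:
    def test_requires_two(self):
        with pytest.raises(ArgumentError):
            sd.synth_pathways(sd.default_gene_names(100), [], n_pathways=1)

    def test_planted_genes_in_first_pathway(self):
        names = sd.default_gene_names(400)
        planted = set(names[:20])
        text = sd.synth_pathways(names, planted, n_pathways=5, seed=3)
        from germnet.pathway_analysis import load_gmt

        db = load_gmt(text)
        assert planted <= db.genes("PI3K_AKT_LIKE")
        # deliberate 60% core overlap (12 of 20); random fillers may add more
        assert len(db.genes("CANCER_LIKE") & planted) >= 12

    def test_empty_planted_is_random(self):
        names = sd.default_gene_names(400)
        text = sd.synth_pathways(names, [], n_pathways=3, seed=3)
        from germnet.pathway_analysis import load_gmt

        db = load_gmt(text)
        assert len(db.pathways) == 3

    def test_sizes_within_bounds(self):
        names = sd.default_gene_names(500)
        text = sd.synth_pathways(names, [], n_pathways=10, seed=5, size_range=(30, 50))
        from germnet.pathway_analysis import load_gmt

        db = load_gmt(text)
        assert len(db.pathways) == 10
        for pid in db.pathways:
            assert 30 <= len(db.genes(pid)) <= 50


class TestSynthCohort:
    def test_null_or_near_one(self):
        cfg = sd.SimulationConfig(
            seed=6, cohort_sizes=(4000, 4000), exposure_probs=(0.2, 0.2)
        )
        df = sd.synth_cohort(cfg)
        from germnet.epidemiology import tabulate

        t = tabulate(df, "exposure", "yes", "no")
        assert woolf_or(t).odds_ratio == pytest.approx(1.0, abs=0.15)

    def test_degenerate_single_certain_case(self):
        cfg = sd.SimulationConfig(
            seed=6, cohort_sizes=(1, 5), exposure_probs=(1.0, 0.5)
        )
        df = sd.synth_cohort(cfg)
        case = df[df["status"] == "case"]
        assert len(case) == 1
        assert case.iloc[0]["exposure"] == "yes"

    def test_ci_coverage_monte_carlo(self):
        """Woolf 95% CI covers the true OR in >= 93% of 100 seeds."""
        from germnet.epidemiology import tabulate

        covered = 0
        for seed in range(100):
            cfg = sd.SimulationConfig(
                seed=seed, cohort_sizes=(2000, 2000), exposure_probs=(0.3, 0.15)
            )
            t = tabulate(sd.synth_cohort(cfg), "exposure", "yes", "no")
            res = woolf_or(t)
            covered += res.ci_low <= cfg.true_or <= res.ci_high
        assert covered >= 93


class TestGeneSetsAndSimulateAll:
    def test_gene_set_shapes(self, small_config):
        names = sd.default_gene_names(small_config.n_gene_universe)
        _, planted = sd.synth_ppi(small_config, names)
        sets = sd.synth_individual_gene_sets(small_config, names, planted)
        assert len(sets) == 20
        for _, label, genes in sets:
            assert len(genes) == 40
            assert label in ("familial_patient", "control")

    def test_simulate_all_deterministic_bytes(self, tmp_path, small_config):
        cfg = replace(small_config, genome_length=6000, n_genes=6, n_germline=15,
                      n_somatic=5)
        sd.simulate_all(cfg, tmp_path / "a", n_seq_individuals=1)
        sd.simulate_all(cfg, tmp_path / "b", n_seq_individuals=1)
        for rel in ["genome.fa", "genes.refflat", "ppi_edges.tsv", "pathways.gmt",
                    "cohort.csv", "gene_sets.json", "truth.json",
                    "pileups/IND01_blood.tsv"]:
            a = (tmp_path / "a" / rel).read_bytes()
            b = (tmp_path / "b" / rel).read_bytes()
            assert a == b, rel

    def test_fasta_roundtrip(self, small_config):
        genome, _ = sd.synth_genome(small_config)
        assert sd.read_fasta(sd.write_fasta(genome))["chr1"] == genome
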