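import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sagmag.clustering import ClusterParams, greedy_cluster, \
    records_from_fasta
from sagmag.io_model import validate_table
from sagmag.quality import consensus_chimera_call, evidence_from_tables
from sagmag.synthetic import (CommunitySpec, simulate_community_counts,
                              simulate_gene_catalog,
                              simulate_genome_collections,
                              simulate_quality_reports)


class TestCommunityCounts:
    def test_tables_validate_and_are_deterministic(self):
        spec = CommunitySpec(n_lineages=10, n_samples=4,
                             depth_range=(1000, 2000), seed=5)
        a, truth_a = simulate_community_counts(spec)
        b, truth_b = simulate_community_counts(spec)
        validate_table(a, "counts")
        pd.testing.assert_frame_equal(a, b)
        assert truth_a.true_proportions == truth_b.true_proportions

    def test_sample_proportions_track_truth(self):
        spec = CommunitySpec(n_lineages=10, n_samples=20,
                             depth_range=(1_000_000, 1_000_000), seed=8)
        counts, truth = simulate_community_counts(spec)
        sag = counts[counts["method"] == "SAG"]
        pivot = sag.pivot(index="sample_id", columns="lineage",
                          values="count").astype(float)
        props = pivot.div(pivot.sum(axis=1), axis=0)
        for lineage, p_true in truth.true_proportions.items():
            est = props[lineage].mean()
            se = max(props[lineage].std(ddof=1) / np.sqrt(20), 1e-6)
            assert abs(est - p_true) < 4 * se + 1e-4

    def test_planted_effect_recorded_and_applied(self):
        spec = CommunitySpec(n_lineages=12, n_samples=6,
                             planted_method="MAG", planted_fold=8.0, seed=2)
        counts, truth = simulate_community_counts(spec)
        assert len(truth.planted_differentials) == 1
        planted = truth.planted_differentials[0]
        assert planted["shifted_proportion"] == pytest.approx(
            8.0 * planted["base_proportion"])


class TestGenomeCollections:
    def _truth(self, seed=4):
        spec = CommunitySpec(n_lineages=30, n_samples=3,
                             depth_range=(1000, 1100), seed=seed)
        return simulate_community_counts(spec)[1]

    def test_counts_and_validation(self):
        truth = self._truth()
        genomes, bundle = simulate_genome_collections(
            truth, n_sag=50, n_mag=40, n_isolate=5, seed=1)
        validate_table(genomes, "genomes")
        assert (genomes["collection"] == "SAG").sum() == 50
        assert (genomes["collection"] == "MAG").sum() == 40
        assert (genomes["collection"] == "ISOLATE").sum() == 5
        assert set(bundle.genome_lineages) == set(genomes["genome_id"])

    def test_tempering_enriches_rare_lineages(self):
        rare_share = {"SAG": [], "MAG": []}
        for seed in range(10):
            truth = self._truth(seed)
            probs = np.array(list(truth.true_proportions.values()))
            rare = {l for l, p in truth.true_proportions.items()
                    if p <= np.quantile(probs, 0.25)}
            genomes, bundle = simulate_genome_collections(
                truth, n_sag=150, n_mag=150, n_isolate=0, tau=0.3,
                seed=seed + 100)
            for coll in ("SAG", "MAG"):
                ids = genomes.loc[genomes["collection"] == coll,
                                  "genome_id"]
                share = np.mean([bundle.genome_lineages[g] in rare
                                 for g in ids])
                rare_share[coll].append(share)
        wins = sum(m > s for s, m in zip(rare_share["SAG"],
                                         rare_share["MAG"]))
        assert wins >= 9

    def test_tau_one_is_unbiased(self):
        ok = 0
        for seed in range(10):
            truth = self._truth(seed)
            genomes, bundle = simulate_genome_collections(
                truth, n_sag=200, n_mag=200, n_isolate=0, tau=1.0,
                seed=seed + 50)
            lineages = sorted(truth.true_proportions)
            table = np.zeros((2, len(lineages)))
            for row in genomes.itertuples(index=False):
                i = 0 if row.collection == "SAG" else 1
                table[i, lineages.index(
                    bundle.genome_lineages[row.genome_id])] += 1
            keep = table.sum(axis=0) > 0
            _, p, _, _ = sps.chi2_contingency(table[:, keep] + 0.5)
            ok += int(p > 0.01)
        assert ok >= 9

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            simulate_genome_collections(self._truth(), tau=0.0, seed=0)


class TestGeneCatalog:
    def _genomes(self, n_sag=6, n_mag=6, n_iso=3, seed=9):
        truth = simulate_community_counts(
            CommunitySpec(n_lineages=8, n_samples=2,
                          depth_range=(500, 600), seed=seed))[1]
        return simulate_genome_collections(truth, n_sag=n_sag, n_mag=n_mag,
                                           n_isolate=n_iso, seed=seed)[0]

    def test_no_noise_recovers_exact_families(self):
        genomes = self._genomes(3, 3, 1)
        fasta, annotations, modules, _ = simulate_gene_catalog(
            genomes, n_core=5, n_flexible=5, gene_length=60,
            sag_gene_dropout=0.0, mag_flexible_dropout=0.0,
            mutation_rate=0.0, planted_module_dropout=None,
            sequence_genomes=7, sequence_families=10, seed=3)
        records = records_from_fasta(fasta, "nucleotide")
        out = greedy_cluster(records, ClusterParams(0.95, 0.9))
        assert out["cluster_id"].nunique() == 10
        # every genome carries every family
        per_genome = annotations.groupby("genome_id")["ko_id"].nunique()
        assert (per_genome == 10).all()

    def test_isolates_carry_everything(self):
        genomes = self._genomes()
        _, annotations, _, _ = simulate_gene_catalog(
            genomes, n_core=20, n_flexible=30, gene_length=30,
            sequence_genomes=0, seed=2)
        iso = genomes.loc[genomes["collection"] == "ISOLATE", "genome_id"]
        per_iso = annotations[annotations["genome_id"].isin(iso)] \
            .groupby("genome_id")["gene_id"].count()
        assert (per_iso == 50).all()

    def test_mag_flexible_depletion(self):
        genomes = self._genomes(20, 20, 2)
        _, annotations, _, truth = simulate_gene_catalog(
            genomes, n_core=40, n_flexible=100, gene_length=30,
            sag_gene_dropout=0.1, mag_flexible_dropout=0.6,
            sequence_genomes=0, planted_module_dropout=None, seed=6)
        flexible_kos = {f"K{i:05d}" for i in range(40, 140)}
        colls = dict(zip(genomes["genome_id"], genomes["collection"]))
        flex_counts = {"SAG": [], "MAG": []}
        for genome_id, group in annotations.groupby("genome_id"):
            coll = colls[genome_id]
            if coll in flex_counts:
                flex_counts[coll].append(
                    len(set(group["ko_id"]) & flexible_kos))
        assert np.mean(flex_counts["MAG"]) < 0.6 * np.mean(
            flex_counts["SAG"])

    def test_mutation_keeps_families_mostly_intact(self):
        genomes = self._genomes(4, 4, 0)
        fasta, _, _, _ = simulate_gene_catalog(
            genomes, n_core=6, n_flexible=0, gene_length=300,
            sag_gene_dropout=0.0, mag_flexible_dropout=0.0,
            mutation_rate=0.02, planted_module_dropout=None,
            sequence_genomes=8, sequence_families=6, seed=4)
        from sagmag.clustering import pairwise_identity
        records = records_from_fasta(fasta, "nucleotide")
        by_family = {}
        for rec in records:
            by_family.setdefault(rec.seq_id.rsplit("_", 1)[-1],
                                 []).append(rec)
        high = total = 0
        for members in by_family.values():
            for i in range(len(members) - 1):
                ident, _, _ = pairwise_identity(members[i], members[i + 1])
                total += 1
                high += int(ident >= 0.95)
        assert high / total > 0.8

    def test_determinism(self):
        genomes = self._genomes()
        a = simulate_gene_catalog(genomes, n_core=10, n_flexible=10,
                                  gene_length=40, seed=11)
        b = simulate_gene_catalog(genomes, n_core=10, n_flexible=10,
                                  gene_length=40, seed=11)
        assert a[0] == b[0]
        pd.testing.assert_frame_equal(a[1], b[1])
        pd.testing.assert_frame_equal(a[2], b[2])


class TestQualityReports:
    def _genomes(self, n=100, seed=1):
        truth = simulate_community_counts(
            CommunitySpec(n_lineages=10, n_samples=2,
                          depth_range=(500, 600), seed=seed))[1]
        return simulate_genome_collections(truth, n_sag=n // 2,
                                           n_mag=n - n // 2, n_isolate=0,
                                           seed=seed)[0]

    def test_zero_fractions(self):
        genomes = self._genomes()
        gunc, mdm, rrna, truth = simulate_quality_reports(
            genomes, chimera_fraction=0.0, conflict_fraction=0.0, seed=3)
        validate_table(gunc, "gunc")
        validate_table(mdm, "mdm")
        validate_table(rrna, "rrna")
        assert truth.chimera_ids == []
        evs = evidence_from_tables(gunc, mdm)
        assert not any(consensus_chimera_call(e).consensus_call for e in evs)

    def test_planted_chimeras_recovered_exactly(self):
        genomes = self._genomes(200, seed=7)
        gunc, mdm, _, truth = simulate_quality_reports(
            genomes, chimera_fraction=0.05, seed=9)
        evs = evidence_from_tables(gunc, mdm)
        called = sorted(e.genome_id for e in evs
                        if consensus_chimera_call(e).consensus_call)
        assert called == sorted(truth.chimera_ids)

    def test_determinism(self):
        genomes = self._genomes()
        a = simulate_quality_reports(genomes, seed=5)
        b = simulate_quality_reports(genomes, seed=5)
        for x, y in zip(a[:3], b[:3]):
            pd.testing.assert_frame_equal(x, y)
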