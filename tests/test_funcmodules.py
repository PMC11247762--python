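import itertools

import numpy as np
import pandas as pd
import pytest

from sagmag.funcmodules import (MergedCategory, ModuleDefinition,
                                call_presence, compare_categories,
                                merge_overlapping, module_completeness,
                                modules_from_table, presence_matrix,
                                retain_modules, standardized_counts)

import oracles


def module(mid, kos):
    return ModuleDefinition(module_id=mid, ko_set=frozenset(kos))


def annotations_frame(genome_genes):
    rows = []
    for genome, genes in genome_genes.items():
        for gene, ko in genes:
            rows.append({"genome_id": genome, "gene_id": gene, "ko_id": ko})
    return pd.DataFrame(rows, columns=["genome_id", "gene_id", "ko_id"])


class TestCompletenessAndPresence:
    @pytest.mark.parametrize("held,expected", [
        (3, 0.75), (0, 0.0), (4, 1.0),
    ])
    def test_fraction(self, held, expected):
        mod = module("M1", ["k1", "k2", "k3", "k4"])
        kos = {f"k{i}" for i in range(1, held + 1)}
        assert module_completeness(kos, mod) == expected

    @pytest.mark.parametrize("completeness,expected", [
        (0.75, True), (0.749, False), (1.0, True), (0.0, False),
    ])
    def test_presence_boundary_inclusive(self, completeness, expected):
        assert call_presence(completeness) is expected

    def test_empty_module_rejected(self):
        with pytest.raises(ValueError):
            module("M1", [])


class TestRetainModules:
    def _presence(self, fractions, n=100):
        # fractions: module -> fraction of pooled genomes carrying it
        genomes = [f"g{i}" for i in range(n)]
        data = {m: [i < int(round(f * n)) for i in range(n)]
                for m, f in fractions.items()}
        return pd.DataFrame(data, index=genomes), {
            g: ("SAG" if i % 2 else "MAG") for i, g in enumerate(genomes)}

    def test_reference_genome_alone_retains(self):
        presence, colls = self._presence({"M1": 0.0})
        out = retain_modules(presence, {"M1": True}, colls)
        assert out == {"M1"}

    def test_below_prevalence_dropped(self):
        presence, colls = self._presence({"M1": 0.04})
        assert retain_modules(presence, {}, colls) == set()

    def test_exact_prevalence_retained(self):
        presence, colls = self._presence({"M1": 0.05})
        assert retain_modules(presence, {}, colls) == {"M1"}


class TestMergeOverlapping:
    def test_boundary_overlap_two_thirds(self):
        out = merge_overlapping([module("A", "k1 k2 k3".split()),
                                 module("B", "k1 k2 k4".split())])
        assert len(out) == 1
        assert out[0].member_modules == {"A", "B"}
        assert out[0].ko_union == {"k1", "k2", "k3", "k4"}

    def test_disjoint_modules_stay_separate(self):
        out = merge_overlapping([module("A", ["k1"]), module("B", ["k2"])])
        assert len(out) == 2

    def test_transitive_chain_single_category(self):
        # A-B and B-C overlap >= 0.65, A-C do not; components merge all three
        a = module("A", ["k1", "k2", "k3"])
        b = module("B", ["k2", "k3", "k4"])
        c = module("C", ["k3", "k4", "k5"])
        out = merge_overlapping([a, b, c])
        assert len(out) == 1
        assert out[0].member_modules == {"A", "B", "C"}

    def test_matches_component_oracle(self, rng):
        for _ in range(30):
            mods = [
                module(f"M{i}", rng.choice(20, size=rng.integers(2, 7),
                                           replace=False).astype(str))
                for i in range(8)
            ]
            out = merge_overlapping(mods)
            edges = []
            for x, y in itertools.combinations(mods, 2):
                ov = len(x.ko_set & y.ko_set) / min(len(x.ko_set),
                                                    len(y.ko_set))
                if ov >= 0.65:
                    edges.append((x.module_id, y.module_id))
            ref = set(oracles.connected_components(
                [m.module_id for m in mods], edges))
            assert {c.member_modules for c in out} == ref

    def test_remerging_never_splits_categories(self, rng):
        # KO unions can overlap afresh, so re-merging may coarsen the
        # partition further, but it can never split an existing category
        mods = [
            module(f"M{i}", rng.choice(15, size=rng.integers(2, 6),
                                       replace=False).astype(str))
            for i in range(10)
        ]
        once = merge_overlapping(mods)
        again = merge_overlapping([
            module(c.category_id, c.ko_union) for c in once])
        for cat in again:
            assert cat.category_id in {c.category_id for c in once}

    def test_idempotent_on_disjoint_unions(self):
        # with pairwise-disjoint unions the partition is a fixed point
        mods = [module("A", ["k1", "k2", "k3"]),
                module("B", ["k2", "k3", "k4"]),
                module("C", ["k9", "k10"])]
        once = merge_overlapping(mods)
        again = merge_overlapping(
            [module(c.category_id, c.ko_union) for c in once])
        assert {c.member_modules for c in again} == \
            {frozenset({c.category_id}) for c in once}

    def test_threshold_monotonicity(self, rng):
        mods = [
            module(f"M{i}", rng.choice(12, size=rng.integers(2, 6),
                                       replace=False).astype(str))
            for i in range(10)
        ]
        sizes = [len(merge_overlapping(mods, thr))
                 for thr in (0.3, 0.5, 0.65, 0.8, 1.0)]
        assert sizes == sorted(sizes)

    def test_representative_is_largest_then_lexicographic(self):
        out = merge_overlapping([module("B", ["k1", "k2"]),
                                 module("A", ["k1", "k2"]),
                                 module("C", ["k1", "k2", "k3"])])
        assert out[0].category_id == "C"


class TestStandardizedCounts:
    def _category(self):
        return MergedCategory(category_id="M1",
                              member_modules=frozenset({"M1", "M2"}),
                              ko_union=frozenset({"k1", "k2"}))

    def test_division_by_isolate_median(self):
        ann = annotations_frame({"g1": [("a", "k1"), ("b", "k1"),
                                        ("c", "k2")]})
        iso = annotations_frame({"i1": [("x", "k1"), ("y", "k2")],
                                 "i2": [("x", "k1"), ("y", "k1")],
                                 "i3": [("x", "k2"), ("y", "k1")]})
        out = standardized_counts(ann, [self._category()], iso)
        assert out["raw_gene_count"].item() == 3
        assert out["isolate_median"].item() == 2.0
        assert out["standardized_count"].item() == 1.5

    def test_isolates_self_normalise_to_median_one(self):
        iso = annotations_frame({
            f"i{k}": [(f"x{j}", "k1") for j in range(k + 1)]
            for k in range(5)
        })
        out = standardized_counts(iso, [self._category()], iso)
        assert np.median(out["standardized_count"]) == pytest.approx(1.0)

    def test_gene_counted_once_across_member_modules(self):
        ann = annotations_frame({"g1": [("a", "k1")]})
        iso = annotations_frame({"i1": [("x", "k1")]})
        out = standardized_counts(ann, [self._category()], iso)
        assert out["raw_gene_count"].item() == 1

    def test_zero_isolate_median_falls_back(self):
        ann = annotations_frame({"g1": [("a", "k1")], "g2": [("b", "k1")],
                                 "g3": [("c", "k9")]})
        iso = annotations_frame({"i1": [("x", "k9")]})
        out = standardized_counts(ann, [self._category()], iso)
        # isolates lack k1/k2 entirely -> fallback to compared-genome median
        assert (out["isolate_median"] == 1.0).all()

    def test_no_isolates_rejected(self):
        ann = annotations_frame({"g1": [("a", "k1")]})
        with pytest.raises(ValueError):
            standardized_counts(ann, [self._category()], ann.iloc[0:0])


class TestCompareCategories:
    def _counts(self, sag, mag):
        rows = []
        for i, v in enumerate(sag):
            rows.append({"genome_id": f"s{i}", "category_id": "M1",
                         "raw_gene_count": 0, "standardized_count": v,
                         "isolate_median": 1.0})
        for i, v in enumerate(mag):
            rows.append({"genome_id": f"m{i}", "category_id": "M1",
                         "raw_gene_count": 0, "standardized_count": v,
                         "isolate_median": 1.0})
        colls = {f"s{i}": "SAG" for i in range(len(sag))}
        colls.update({f"m{i}": "MAG" for i in range(len(mag))})
        return pd.DataFrame(rows), colls

    def test_null_not_flagged(self, rng):
        values = rng.normal(1, 0.2, 30)
        counts, colls = self._counts(values, values)
        out = compare_categories(counts, colls)
        assert not out["significant"].any()

    def test_planted_depletion_flagged_sag_positive(self, rng):
        counts, colls = self._counts(rng.normal(2.0, 0.5, 200),
                                     rng.normal(0.5, 0.5, 200))
        out = compare_categories(counts, colls)
        row = out.iloc[0]
        assert row["significant"]
        assert row["estimated_difference"] > 0

    def test_k2_p_equals_welch(self, rng):
        from scipy import stats as sps
        sag = rng.normal(1, 0.4, 25)
        mag = rng.normal(1.2, 0.6, 18)
        counts, colls = self._counts(sag, mag)
        out = compare_categories(counts, colls)
        _, p_ref = sps.ttest_ind(sag, mag, equal_var=False)
        assert out["p_value"].item() == pytest.approx(p_ref, abs=1e-9)

    def test_zero_variance_reported_not_flagged(self):
        counts, colls = self._counts([1.0, 1.0, 1.0], [0.5, 0.6, 0.7])
        out = compare_categories(counts, colls)
        assert not out["tested"].item()
        assert not out["significant"].item()


def test_modules_from_table_and_presence_matrix():
    table = pd.DataFrame({"module_id": ["M1", "M1", "M2"],
                          "ko_id": ["k1", "k2", "k3"]})
    mods = modules_from_table(table)
    assert [m.module_id for m in mods] == ["M1", "M2"]
    ann = annotations_frame({"g1": [("a", "k1"), ("b", "k2")],
                             "g2": [("a", "k3")]})
    pm = presence_matrix(ann, mods)
    assert bool(pm.loc["g1", "M1"]) is True
    assert bool(pm.loc["g1", "M2"]) is False
    assert bool(pm.loc["g2", "M2"]) is True
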