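"""Batch analytics tests against planted fixture ground truth."""

import io
from fractions import Fraction

import numpy as np
import pytest

from seqcol.analysis import (
    CollectionManifest,
    ManifestEntry,
    compare_one_vs_many,
    density_summary,
    find_duplicates,
    find_identical_attribute_sets,
    find_subsets,
    pairwise_matrices,
    provider_summary,
    sequence_presence,
    write_analysis,
)
from seqcol.fasta import digest_fasta_entries, parse_fasta
from seqcol.synthfix import generate_genome

from conftest import digest_text


def _manifest(named_fastas, providers=None, classes=None):
    entries = []
    for label, fasta in named_fastas.items():
        entries.append(
            ManifestEntry(
                label=label,
                provider=(providers or {}).get(label, "p"),
                genome_class=(classes or {}).get(label, "g"),
                collection=digest_text(fasta),
            )
        )
    return CollectionManifest(entries)


GENOME = generate_genome(4, (60, 90), seed=100)
OTHER = generate_genome(3, (60, 90), seed=101, name_prefix="ctg")


class TestManifest:
    def test_duplicate_labels_rejected(self):
        e = ManifestEntry(label="x", collection=digest_text(GENOME))
        with pytest.raises(ValueError):
            CollectionManifest([e, ManifestEntry(label="x", collection=e.collection)])

    def test_read_tsv_and_resolve(self, universe, tmp_path):
        manifest_path = universe.write(tmp_path / "fx")
        m = CollectionManifest.read(manifest_path)
        assert m.labels == universe.truth["labels"]
        resolved = m.resolve()
        for label, coll in resolved.items():
            assert coll.level0 == universe.truth["level0"][label]

    def test_unresolvable_entry_names_label(self):
        m = CollectionManifest([ManifestEntry(label="ghost", path="/no/such.fa")])
        with pytest.raises(ValueError, match="ghost"):
            m.resolve()


class TestPairwiseMatrices:
    def test_duplicated_collection_all_ones(self):
        m = _manifest({"a": GENOME, "b": GENOME})
        for mat in pairwise_matrices(m):
            assert mat.jaccard[0, 1] == 1.0

    def test_pair_count(self):
        m = _manifest({f"g{i}": GENOME for i in range(5)})
        mats = pairwise_matrices(m, attributes=("names",))
        assert mats[0].n_pairs == 5 * 4 // 2

    def test_matrix_invariants(self, manifest):
        for mat in pairwise_matrices(manifest):
            assert np.allclose(mat.jaccard, mat.jaccard.T, equal_nan=True)
            assert np.all(np.diag(mat.jaccard) == 1.0)
            assert np.allclose(mat.opa, mat.opb.T, equal_nan=True)

    def test_short_circuit_consistency(self, manifest):
        fast = pairwise_matrices(manifest, use_short_circuit=True)
        slow = pairwise_matrices(manifest, use_short_circuit=False)
        for f, s in zip(fast, slow):
            np.testing.assert_array_equal(f.jaccard, s.jaccard)
            np.testing.assert_array_equal(f.opa, s.opa)
            np.testing.assert_array_equal(f.opb, s.opb)

    def test_universe_matches_declared_relations(self, universe, manifest):
        mats = {m.attribute: m for m in pairwise_matrices(manifest)}
        idx = {l: i for i, l in enumerate(manifest.labels)}
        for attr, table in universe.truth["expected_relations"].items():
            mat = mats[attr]
            for pair, relation in table.items():
                la, lb = pair.split("|")
                j = mat.jaccard[idx[la], idx[lb]]
                if relation == "identical-as-sets":
                    assert j == 1.0, (attr, pair)
                elif relation == "disjoint":
                    assert j == 0.0, (attr, pair)
                else:
                    assert 0.0 < j < 1.0, (attr, pair, relation)


class TestFindDuplicates:
    def test_all_distinct(self):
        m = _manifest({"a": GENOME, "b": OTHER})
        census = find_duplicates(m)
        assert census.groups == [] and census.duplicate_fraction == 0

    def test_stated_formula(self):
        # 10 labels, 3 sharing one digest -> (10 - 8) / 10 = 0.2
        fastas = {f"u{i}": generate_genome(2, (40, 60), seed=200 + i) for i in range(7)}
        fastas.update({"d1": GENOME, "d2": GENOME, "d3": GENOME})
        census = find_duplicates(_manifest(fastas))
        assert census.n_total == 10 and census.n_distinct == 8
        assert census.duplicate_fraction == Fraction(2, 10)
        assert census.member_fraction == Fraction(3, 10)

    def test_universe_planted_duplicates(self, universe, manifest):
        census = find_duplicates(manifest)
        assert census.groups == universe.truth["duplicate_groups"]
        assert float(census.duplicate_fraction) == universe.truth["duplicate_fraction"]


class TestIdenticalAttributeSets:
    def test_renamed_pair(self, manifest):
        seq_groups = find_identical_attribute_sets(manifest, "sequences").groups
        grouped = next(g for g in seq_groups if "A-ensembl-renamed" in g)
        assert "A-ncbi" in grouped
        name_groups = find_identical_attribute_sets(manifest, "names").groups
        assert not any("A-ensembl-renamed" in g and "A-ncbi" in g for g in name_groups)

    def test_hard_masked_pair(self, manifest):
        seq_groups = find_identical_attribute_sets(manifest, "sequences").groups
        assert not any(
            "A-ucsc-hardmask" in g and "A-ncbi" in g for g in seq_groups
        )
        len_groups = find_identical_attribute_sets(manifest, "lengths").groups
        assert any("A-ucsc-hardmask" in g and "A-ncbi" in g for g in len_groups)

    def test_empty_manifest(self):
        census = find_identical_attribute_sets(CollectionManifest([]), "names")
        assert census.groups == [] and census.n_total == 0


class TestFindSubsets:
    def test_planted_subset_detected_all_attributes(self, manifest):
        for attr in ("names", "lengths", "sequences", "name_length_pairs"):
            assert ("A-noalt", "A-ncbi") in find_subsets(manifest, attr), attr

    def test_identical_pair_not_listed(self, manifest):
        for attr in ("names", "sequences"):
            pairs = find_subsets(manifest, attr)
            assert ("A-broad", "A-ncbi") not in pairs
            assert ("A-ncbi", "A-broad") not in pairs

    def test_disjoint_pair_not_listed(self, manifest):
        pairs = find_subsets(manifest, "sequences")
        assert ("A-ncbi", "B-ncbi") not in pairs and ("B-ncbi", "A-ncbi") not in pairs

    def test_exact_match_with_declared_relations(self, universe, manifest):
        # zero false positives/negatives against construction-side truth
        for attr, table in universe.truth["expected_relations"].items():
            found = set(find_subsets(manifest, attr))
            expected = set()
            for pair, relation in table.items():
                la, lb = pair.split("|")
                if relation == "a-subset-of-b":
                    expected.add((la, lb))
                elif relation == "b-subset-of-a":
                    expected.add((lb, la))
            assert found == expected, attr


class TestSequencePresence:
    def test_identical_pair_all_frequency_two(self):
        m = _manifest({"a": GENOME, "b": GENOME})
        pm = sequence_presence(m, "g")
        assert (pm.row_frequency == 2).all()

    def test_decoy_rows_frequency_one(self, universe, manifest):
        pm = sequence_presence(manifest, "gA")
        decoy_label = "A-ncbi-decoy"
        decoy_names = universe.truth["decoy_pairs"][0]["decoy_names"]
        coll = manifest.resolve()[decoy_label]
        decoy_ids = [
            coll.level2["sequences"][coll.level2["names"].index(n)] for n in decoy_names
        ]
        for d in decoy_ids:
            assert pm.row_frequency[d] == 1
            assert pm.matrix.loc[d, decoy_label]

    def test_row_count_is_union(self, manifest):
        pm = sequence_presence(manifest, "gB")
        brute = set()
        for e in manifest.entries:
            if e.genome_class == "gB":
                brute |= set(e.resolve().level2["sequences"])
        assert pm.n_sequences == len(brute)

    def test_unknown_class(self, manifest):
        with pytest.raises(ValueError):
            sequence_presence(manifest, "nope")


class TestProviderSummary:
    def test_single_provider_identical(self):
        m = _manifest({"a": GENOME, "b": GENOME})
        df = provider_summary(pairwise_matrices(m), m)
        assert (df["mean_jaccard"] == 1.0).all()
        assert (df["median_difference"] == 0.0).all()

    def test_outlier_provider_has_lowest_mean(self):
        m = _manifest(
            {"a1": GENOME, "a2": GENOME, "b1": GENOME, "out": OTHER},
            providers={"a1": "p1", "a2": "p1", "b1": "p2", "out": "weird"},
        )
        df = provider_summary(pairwise_matrices(m, attributes=("sequences",)), m)
        means = df.set_index("provider")["mean_jaccard"]
        assert means.idxmin() == "weird"

    def test_means_bounded(self, manifest):
        df = provider_summary(pairwise_matrices(manifest), manifest)
        vals = df["mean_jaccard"].dropna()
        assert ((vals >= 0) & (vals <= 1)).all()

    def test_within_only_flag(self):
        m = _manifest(
            {"a1": GENOME, "a2": GENOME, "out": OTHER},
            providers={"a1": "p1", "a2": "p1", "out": "w"},
        )
        df = provider_summary(
            pairwise_matrices(m, attributes=("sequences",)), m, within_only=True
        )
        by = df.set_index("provider")
        assert by.loc["p1", "n_pairs"] == 1 and by.loc["p1", "mean_jaccard"] == 1.0
        assert by.loc["w", "n_pairs"] == 0


class TestOneVsMany:
    def test_self_query_ranked_first(self, manifest, collections):
        results = compare_one_vs_many(collections["A-ncbi"], manifest)
        assert results[0].label in ("A-ncbi", "A-broad", "A-ucsc-softmask")
        top = results[0]
        for attr in ("names", "lengths", "sequences"):
            assert top.scores[attr].jaccard == 1

    def test_disjoint_query_all_zero(self, manifest):
        query = digest_text(">zzz\n" + "A" * 50 + "\n")
        sub = CollectionManifest(
            [e for e in manifest.entries if e.genome_class == "gB"]
        )
        for r in compare_one_vs_many(query, sub):
            assert r.scores["sequences"].jaccard == 0

    def test_planted_subset_verdict(self, manifest, collections):
        results = compare_one_vs_many(collections["A-noalt-min"], manifest)
        by_label = {r.label: r for r in results}
        assert by_label["A-ncbi"].verdicts["sequences"].relation == "a-subset-of-b"

    def test_ranking_is_deterministic(self, manifest, collections):
        r1 = [r.label for r in compare_one_vs_many(collections["A-noalt"], manifest)]
        r2 = [r.label for r in compare_one_vs_many(collections["A-noalt"], manifest)]
        assert r1 == r2


class TestDensitySummary:
    def test_all_identical_mass_in_top_bin(self):
        m = _manifest({f"c{i}": GENOME for i in range(4)})
        hist = density_summary(pairwise_matrices(m, attributes=("sequences",))[0])
        assert hist.counts[-1] == 6 and sum(hist.counts[:-1]) == 0

    def test_bimodal_two_clusters(self):
        m = _manifest({"a1": GENOME, "a2": GENOME, "b1": OTHER, "b2": OTHER})
        hist = density_summary(pairwise_matrices(m, attributes=("sequences",))[0])
        assert hist.counts[0] == 4  # cross-cluster pairs at 0
        assert hist.counts[-1] == 2  # within-cluster pairs at 1

    def test_total_equals_defined_pairs(self, manifest):
        mat = pairwise_matrices(manifest, attributes=("sequences",))[0]
        hist = density_summary(mat)
        n = len(manifest)
        defined = sum(
            1
            for i in range(n)
            for j in range(i + 1, n)
            if not np.isnan(mat.jaccard[i, j])
        )
        assert hist.total == defined

    def test_fixed_bin_edges(self, manifest):
        hist = density_summary(pairwise_matrices(manifest, attributes=("names",))[0])
        assert len(hist.counts) == 20
        assert hist.edges[0] == 0.0 and hist.edges[-1] == 1.0


class TestWriteAnalysis:
    def test_outputs_written_and_deterministic(self, manifest, tmp_path):
        s1 = write_analysis(manifest, tmp_path / "run1")
        s2 = write_analysis(manifest, tmp_path / "run2")
        assert s1 == s2
        for name in ("pairwise_long.tsv", "duplicates.csv", "subsets.csv",
                     "provider_summary.csv", "presence_gA.csv"):
            f1 = (tmp_path / "run1" / name).read_text()
            f2 = (tmp_path / "run2" / name).read_text()
            assert f1 == f2, name
        assert s1["n_pairs"] == len(manifest) * (len(manifest) - 1) // 2
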