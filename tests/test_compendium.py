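"""Compendium I/O, log-TPM arithmetic, QC filters, and centering."""

import numpy as np
import pandas as pd
import pytest

from imodkit.compendium import (
    Compendium,
    CompendiumError,
    build_regulon_table,
    center_to_reference,
    compute_log_tpm,
    gene_lengths_from_gff,
    qc_filter_genes,
    qc_filter_replicates,
)


def counts_frame(data, genes=None, samples=None):
    data = np.atleast_2d(data)
    genes = genes or [f"g{i}" for i in range(data.shape[0])]
    samples = samples or [f"s{j}" for j in range(data.shape[1])]
    return pd.DataFrame(data, index=genes, columns=samples)


class TestLogTpm:
    def test_single_gene_takes_all_mass(self):
        counts = counts_frame([[5]])
        lengths = pd.Series({"g0": 100.0})
        out = compute_log_tpm(counts, lengths)
        assert out.iloc[0, 0] == pytest.approx(np.log2(1e6 + 1))

    def test_equal_counts_equal_lengths_split_evenly(self):
        counts = counts_frame([[50], [50]])
        lengths = pd.Series({"g0": 200.0, "g1": 200.0})
        tpm = 2 ** compute_log_tpm(counts, lengths) - 1
        assert np.allclose(tpm.iloc[:, 0], [5e5, 5e5])

    def test_length_normalization(self):
        # counts (10, 90), lengths (100, 300): rates (0.1, 0.3) -> TPM (25e4, 75e4)
        counts = counts_frame([[10], [90]])
        lengths = pd.Series({"g0": 100.0, "g1": 300.0})
        tpm = 2 ** compute_log_tpm(counts, lengths) - 1
        assert np.allclose(tpm.iloc[:, 0], [250000.0, 750000.0])

    def test_tpm_recovered_by_inverse_transform(self, rng):
        counts = counts_frame(rng.integers(1, 1000, size=(30, 4)))
        lengths = pd.Series(
            rng.integers(100, 3000, size=30).astype(float),
            index=counts.index,
        )
        tpm = 2 ** compute_log_tpm(counts, lengths) - 1
        assert np.allclose(tpm.sum(axis=0), 1e6, rtol=1e-6)

    def test_zero_count_sample_is_named(self):
        counts = counts_frame([[5, 0]], samples=["ok", "bad"])
        lengths = pd.Series({"g0": 100.0})
        with pytest.raises(CompendiumError, match="bad"):
            compute_log_tpm(counts, lengths)

    def test_missing_length_is_named(self):
        counts = counts_frame([[5], [5]])
        lengths = pd.Series({"g0": 100.0})
        with pytest.raises(CompendiumError, match="g1"):
            compute_log_tpm(counts, lengths)


class TestGeneQc:
    def test_short_gene_removed_despite_high_counts(self):
        counts = counts_frame([[10000], [10000]])
        lengths = pd.Series({"g0": 99.0, "g1": 150.0})
        assert qc_filter_genes(counts, lengths) == ["g1"]

    def test_silent_gene_removed(self):
        counts = counts_frame([[0, 0], [100, 100]])
        lengths = pd.Series({"g0": 500.0, "g1": 500.0})
        assert qc_filter_genes(counts, lengths) == ["g1"]

    def test_single_sample_reaching_fpm_floor_retains_gene(self):
        # g0 has FPM 12 in sample 0 only; kept under the max-over-samples rule
        counts = counts_frame(
            [[12, 0], [999_000, 999_000], [988, 1000]],
        )
        lengths = pd.Series(
            {"g0": 500.0, "g1": 500.0, "g2": 500.0}
        )
        retained = qc_filter_genes(counts, lengths)
        assert "g0" in retained
        assert retained == sorted(retained, key=["g0", "g1", "g2"].index)

    def test_all_filtered_raises(self):
        counts = counts_frame([[5]])
        lengths = pd.Series({"g0": 50.0})
        with pytest.raises(CompendiumError, match="all genes filtered"):
            qc_filter_genes(counts, lengths)


class TestReplicateQc:
    def test_identical_replicates_kept(self, rng):
        col = rng.normal(size=50)
        logtpm = pd.DataFrame({"a": col, "b": col})
        groups = pd.Series({"a": "g", "b": "g"})
        assert qc_filter_replicates(logtpm, groups) == ["a", "b"]

    def test_uncorrelated_pair_both_removed(self, rng):
        logtpm = pd.DataFrame(
            {"a": rng.normal(size=200), "b": rng.normal(size=200)}
        )
        groups = pd.Series({"a": "g", "b": "g"})
        assert qc_filter_replicates(logtpm, groups) == []

    def test_discordant_third_replicate_removed(self, rng):
        base = rng.normal(size=200)
        logtpm = pd.DataFrame(
            {
                "a": base,
                "b": base + rng.normal(scale=0.05, size=200),
                "c": rng.normal(size=200),
            }
        )
        groups = pd.Series({"a": "g", "b": "g", "c": "g"})
        assert qc_filter_replicates(logtpm, groups) == ["a", "b"]

    def test_singleton_group_kept(self, rng):
        logtpm = pd.DataFrame({"a": rng.normal(size=20)})
        assert qc_filter_replicates(logtpm, pd.Series({"a": "g"})) == ["a"]


class TestCentering:
    def test_reference_only_compendium_becomes_zero(self, rng):
        vals = pd.DataFrame(rng.normal(size=(10, 2)), columns=["r1", "r2"])
        vals["r2"] = vals["r1"]
        out = center_to_reference(vals, ["r1", "r2"])
        assert np.allclose(out.values, 0.0)
        assert out.centered

    def test_mean_offset_subtracted_everywhere(self):
        vals = pd.DataFrame(
            {"r1": [1.0], "r2": [3.0], "x": [10.0]}, index=["g0"]
        )
        out = center_to_reference(vals, ["r1", "r2"])
        assert np.allclose(out.values.loc["g0"], [-1.0, 1.0, 8.0])

    def test_idempotent_and_difference_preserving(self, rng):
        vals = pd.DataFrame(rng.normal(size=(20, 5)))
        vals.columns = [f"s{j}" for j in range(5)]
        once = center_to_reference(vals, ["s0", "s1"])
        twice = center_to_reference(once.values, ["s0", "s1"])
        assert np.allclose(once.values, twice.values)
        diff_before = vals["s3"] - vals["s4"]
        diff_after = once.values["s3"] - once.values["s4"]
        assert np.allclose(diff_before, diff_after)

    def test_unknown_reference_rejected(self, rng):
        vals = pd.DataFrame(rng.normal(size=(5, 2)), columns=["a", "b"])
        with pytest.raises(CompendiumError, match="unknown reference"):
            center_to_reference(vals, ["nope"])


class TestRegulonTable:
    def test_interactions_outside_universe_dropped(self):
        raw = pd.DataFrame(
            {
                "regulator": ["r1", "r1"],
                "gene": ["g0", "absent"],
                "effect": ["activation", "activation"],
            }
        )
        table = build_regulon_table(raw, ["g0", "g1"])
        assert table.regulon("r1") == {"g0"}

    def test_conflicting_effects_collapse_to_unknown(self):
        raw = pd.DataFrame(
            {
                "regulator": ["r1", "r1"],
                "gene": ["g0", "g0"],
                "effect": ["activation", "repression"],
            }
        )
        table = build_regulon_table(raw, ["g0"])
        assert len(table) == 1
        assert table.interactions["effect"].iloc[0] == "unknown"

    def test_consistent_duplicate_keeps_effect(self):
        raw = pd.DataFrame(
            {
                "regulator": ["r1", "r1"],
                "gene": ["g0", "g0"],
                "effect": ["repression", "repression"],
            }
        )
        table = build_regulon_table(raw, ["g0"])
        assert table.interactions["effect"].iloc[0] == "repression"

    def test_empty_table_warns(self, caplog):
        raw = pd.DataFrame(columns=["regulator", "gene", "effect"])
        with caplog.at_level("WARNING"):
            table = build_regulon_table(raw, ["g0"])
        assert len(table) == 0

    def test_missing_columns_rejected(self):
        with pytest.raises(CompendiumError):
            build_regulon_table(pd.DataFrame({"regulator": ["r"]}), ["g0"])


class TestGffLengths:
    GFF = (
        "##gff-version 3\n"
        "chr1\t.\tgene\t101\t200\t.\t+\t.\tID=gene1;locus_tag=b0001\n"
        "chr1\t.\tgene\t301\t400\t.\t-\t.\tID=gene2;locus_tag=b0002\n"
        "chr1\t.\tgene\t350\t450\t.\t-\t.\tID=gene2b;locus_tag=b0002\n"
    )

    def test_span_and_interval_union(self, tmp_path):
        path = tmp_path / "genes.gff"
        path.write_text(self.GFF)
        lengths = gene_lengths_from_gff(path)
        assert lengths["b0001"] == 100.0  # 1-based inclusive span
        assert lengths["b0002"] == 150.0  # overlapping intervals merged


class TestCompendiumInvariants:
    def test_duplicate_genes_rejected(self, rng):
        vals = pd.DataFrame(rng.normal(size=(2, 1)), index=["g", "g"], columns=["s"])
        meta = pd.DataFrame(
            {
                "project": ["p"],
                "condition": ["c"],
                "replicate_group": ["c"],
                "is_reference": [True],
            },
            index=["s"],
        )
        with pytest.raises(CompendiumError, match="duplicate gene"):
            Compendium(vals, meta)

    def test_missing_values_rejected(self):
        vals = pd.DataFrame({"s": [np.nan]}, index=["g"])
        meta = pd.DataFrame(
            {
                "project": ["p"],
                "condition": ["c"],
                "replicate_group": ["c"],
                "is_reference": [True],
            },
            index=["s"],
        )
        with pytest.raises(CompendiumError, match="missing"):
            Compendium(vals, meta)

    def test_centered_flag_checks_reference_mean(self, rng):
        vals = pd.DataFrame(rng.normal(size=(5, 2)) + 1.0, columns=["a", "b"])
        meta = pd.DataFrame(
            {
                "project": "p",
                "condition": "c",
                "replicate_group": ["c", "c"],
                "is_reference": [True, True],
            },
            index=["a", "b"],
        )
        with pytest.raises(CompendiumError, match="nonzero reference"):
            Compendium(vals, meta, centered=True, reference_samples=["a", "b"])
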