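"""Condition embeddings against naive per-gene loop oracles, plus the
quantile-normalization convention."""

import numpy as np
import pandas as pd
import pytest

from histobridge.conditioning import (CategoricalCondition, ConditionBundle,
                                      EmbeddingTables, GenomicProfile,
                                      TranscriptomicProfile, combine_conditions,
                                      embed_categorical, embed_genomic,
                                      embed_transcriptomic, quantile_normalize,
                                      read_genomic_matrix, read_genomic_tsv,
                                      read_transcriptomic_tsv)
from histobridge.nn import Tensor, concat

LABELS = ["cryosection", "ffpe"]
GENES = ["TP53", "KRAS", "EGFR", "BRAF"]


@pytest.fixture
def tables():
    return EmbeddingTables(LABELS, GENES, dim=8, rng=np.random.default_rng(5))


def _loop_genomic(profile: dict, tables: EmbeddingTables) -> np.ndarray:
    """Independent oracle: explicit per-gene loop through the same MLP."""
    total = np.zeros(tables.dim)
    for i, g in enumerate(tables.genes):
        table = tables.mut_table if profile[g] else tables.wt_table
        row = Tensor(table.data[i:i + 1].copy())
        total = total + tables.mlp_genomic(row).data[0]
    return total


def _loop_transcriptomic(profile: dict, tables: EmbeddingTables) -> np.ndarray:
    total = np.zeros(tables.dim)
    for i, g in enumerate(tables.expression_genes):
        e_g = Tensor(tables.txn_gene_table.data[i:i + 1].copy())
        gene_part = tables.mlp_transcriptomic(e_g).data[0]
        ti = np.array([[profile[g]]], dtype=np.float32)
        exp_part = tables.mlp_exp(concat([e_g, Tensor(ti)], axis=1)).data[0]
        total = total + gene_part * exp_part
    return total


class TestCategorical:
    def test_lookup_is_deterministic_and_label_specific(self, tables):
        a1 = embed_categorical(CategoricalCondition("cryosection"), tables).data
        a2 = embed_categorical(CategoricalCondition("cryosection"), tables).data
        b = embed_categorical(CategoricalCondition("ffpe"), tables).data
        np.testing.assert_array_equal(a1, a2)
        assert not np.array_equal(a1, b)

    def test_unregistered_label_named_in_error(self, tables):
        with pytest.raises(KeyError, match="he_stain"):
            embed_categorical(CategoricalCondition("he_stain"), tables)


class TestGenomic:
    def test_empty_gene_set_gives_zero_vector(self):
        t = EmbeddingTables(LABELS, [], dim=8, rng=np.random.default_rng(0))
        out = embed_genomic(GenomicProfile({}), t)
        np.testing.assert_array_equal(out.data, np.zeros(8))

    def test_all_wt_matches_per_gene_loop(self, tables):
        profile = {g: False for g in GENES}
        out = embed_genomic(GenomicProfile(profile), tables).data
        np.testing.assert_allclose(out, _loop_genomic(profile, tables), rtol=1e-5)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_profiles_match_per_gene_loop(self, tables, seed):
        rng = np.random.default_rng(seed)
        profile = {g: bool(rng.random() < 0.5) for g in GENES}
        out = embed_genomic(GenomicProfile(profile), tables).data
        np.testing.assert_allclose(out, _loop_genomic(profile, tables), rtol=1e-5)

    def test_single_flip_changes_output_by_term_difference(self, tables):
        base = {g: False for g in GENES}
        flipped = dict(base, KRAS=True)
        diff = (embed_genomic(GenomicProfile(flipped), tables).data
                - embed_genomic(GenomicProfile(base), tables).data)
        expected = (_loop_genomic(flipped, tables) - _loop_genomic(base, tables))
        np.testing.assert_allclose(diff, expected, rtol=1e-4, atol=1e-7)

    def test_profile_mismatch_lists_offenders(self, tables):
        with pytest.raises(KeyError, match="BRAF"):
            embed_genomic(GenomicProfile({g: False for g in GENES[:3]}), tables)
        with pytest.raises(KeyError, match="MYC"):
            embed_genomic(
                GenomicProfile({**{g: False for g in GENES}, "MYC": True}), tables)


class TestTranscriptomic:
    def test_single_gene_matches_direct_product(self):
        t = EmbeddingTables(LABELS, ["TP53"], dim=8, rng=np.random.default_rng(2))
        profile = {"TP53": 0.7}
        out = embed_transcriptomic(TranscriptomicProfile(profile), t).data
        np.testing.assert_allclose(out, _loop_transcriptomic(profile, t), rtol=1e-5)

    def test_matches_per_gene_loop(self, tables):
        profile = {g: v for g, v in zip(GENES, [0.1, 0.5, 0.9, 0.3])}
        out = embed_transcriptomic(TranscriptomicProfile(profile), tables).data
        np.testing.assert_allclose(out, _loop_transcriptomic(profile, tables),
                                   rtol=1e-5)

    def test_changing_one_value_leaves_other_summands_fixed(self, tables):
        p1 = {g: 0.5 for g in GENES}
        p2 = dict(p1, EGFR=0.9)
        diff = (embed_transcriptomic(TranscriptomicProfile(p2), tables).data
                - embed_transcriptomic(TranscriptomicProfile(p1), tables).data)
        loop_diff = (_loop_transcriptomic(p2, tables)
                     - _loop_transcriptomic(p1, tables))
        np.testing.assert_allclose(diff, loop_diff, rtol=1e-4, atol=1e-7)

    def test_non_finite_expression_rejected(self, tables):
        profile = {g: 0.5 for g in GENES}
        profile["KRAS"] = float("nan")
        with pytest.raises(ValueError, match="KRAS"):
            embed_transcriptomic(TranscriptomicProfile(profile), tables)


class TestCombine:
    def test_categorical_only_equals_categorical_embedding(self, tables):
        bundle = ConditionBundle.make("ffpe")
        np.testing.assert_array_equal(
            combine_conditions(bundle, tables).data,
            embed_categorical(CategoricalCondition("ffpe"), tables).data)

    def test_full_bundle_is_sum_of_parts(self, tables):
        genomic = {g: g == "TP53" for g in GENES}
        txn = {g: 0.25 for g in GENES}
        bundle = ConditionBundle.make("cryosection", genomic, txn)
        expected = (embed_categorical(CategoricalCondition("cryosection"), tables).data
                    + embed_genomic(GenomicProfile(genomic), tables).data
                    + embed_transcriptomic(TranscriptomicProfile(txn), tables).data)
        np.testing.assert_allclose(combine_conditions(bundle, tables).data,
                                   expected, rtol=1e-6)

    def test_swapping_genomic_component_swaps_its_contribution(self, tables):
        g1 = {g: False for g in GENES}
        g2 = dict(g1, BRAF=True)
        b1 = ConditionBundle.make("ffpe", g1)
        b2 = ConditionBundle.make("ffpe", g2)
        diff = (combine_conditions(b2, tables).data
                - combine_conditions(b1, tables).data)
        expected = (embed_genomic(GenomicProfile(g2), tables).data
                    - embed_genomic(GenomicProfile(g1), tables).data)
        np.testing.assert_allclose(diff, expected, rtol=1e-4, atol=1e-7)

    def test_gene_order_permutation_is_irrelevant(self, tables):
        profile = {g: v for g, v in zip(GENES, [True, False, True, False])}
        reversed_profile = dict(reversed(list(profile.items())))
        out1 = embed_genomic(GenomicProfile(profile), tables).data
        out2 = embed_genomic(GenomicProfile(reversed_profile), tables).data
        np.testing.assert_allclose(out1, out2, rtol=1e-6)


class TestQuantileNormalize:
    def test_three_sample_column_ranks(self):
        df = pd.DataFrame({"g": [1.0, 2.0, 3.0]})
        out = quantile_normalize(df)
        np.testing.assert_allclose(out["g"], [0.25, 0.5, 0.75])

    def test_constant_column_maps_to_half(self):
        df = pd.DataFrame({"g": [5.0, 5.0, 5.0], "h": [1.0, 2.0, 3.0]})
        out = quantile_normalize(df)
        np.testing.assert_allclose(out["g"], [0.5, 0.5, 0.5])

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(20)
        a = quantile_normalize(pd.DataFrame({"g": x}))
        b = quantile_normalize(pd.DataFrame({"g": np.exp(3 * x)}))
        np.testing.assert_allclose(a["g"], b["g"])

    def test_ties_get_average_rank(self):
        out = quantile_normalize(pd.DataFrame({"g": [1.0, 2.0, 2.0, 4.0]}))
        np.testing.assert_allclose(out["g"], [1 / 5, 2.5 / 5, 2.5 / 5, 4 / 5])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize(pd.DataFrame({"g": []}))


class TestProfileIO:
    def test_two_column_tsv_roundtrip(self, tmp_path):
        (tmp_path / "g.tsv").write_text("gene\tstatus\nTP53\t1\nKRAS\t0\n")
        (tmp_path / "t.tsv").write_text("gene\tvalue\nTP53\t0.25\nKRAS\t0.9\n")
        g = read_genomic_tsv(tmp_path / "g.tsv")
        t = read_transcriptomic_tsv(tmp_path / "t.tsv")
        assert g.entries == {"TP53": True, "KRAS": False}
        assert t.entries == {"TP53": 0.25, "KRAS": 0.9}

    def test_wide_matrix_by_sample(self, tmp_path):
        (tmp_path / "m.tsv").write_text(
            "sample\tTP53\tKRAS\ns1\t1\t0\ns2\t0\t1\n")
        profiles = read_genomic_matrix(tmp_path / "m.tsv")
        assert profiles["s1"].entries == {"TP53": True, "KRAS": False}
        assert profiles["s2"].entries == {"TP53": False, "KRAS": True}

    def test_wide_matrix_without_sample_column_rejected(self, tmp_path):
        (tmp_path / "m.tsv").write_text("TP53\tKRAS\n1\t0\n")
        with pytest.raises(ValueError, match="sample"):
            read_genomic_matrix(tmp_path / "m.tsv")
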