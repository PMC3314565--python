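import numpy as np
import pandas as pd
import pytest

from exonflow import (
    QueryPoint,
    compute_meta,
    rank_by_distance,
    rank_within_set,
    scale_meta,
    search_genes,
)
from exonflow.meta_stats import META_COMPONENTS, unscale_meta


def _exon_table(rng, n_genes=10, per_gene=4):
    n = n_genes * per_gene
    return pd.DataFrame(
        {
            "gene_id": np.repeat([f"G{i:03d}" for i in range(n_genes)], per_gene),
            "t_p": rng.uniform(size=n),
            "midas_p": rng.uniform(size=n),
            "splicing_index": rng.normal(size=n),
            "log2_fold_change": rng.normal(size=n),
        },
        index=pd.Index([f"PS{i:04d}" for i in range(n)], name="probeset_id"),
    )


def _random_meta(rng, n_genes=100):
    table = pd.DataFrame(
        rng.normal(size=(n_genes, len(META_COMPONENTS))),
        index=pd.Index([f"G{i:03d}" for i in range(n_genes)], name="gene_id"),
        columns=list(META_COMPONENTS),
    )
    table.insert(0, "n_probesets", 4)
    return table


class TestComputeMeta:
    def test_hand_arithmetic(self):
        table = pd.DataFrame(
            {
                "gene_id": ["G1"] * 3,
                "t_p": [0.001, 0.9, 0.95],
                "midas_p": [0.5] * 3,
                "splicing_index": [0.0] * 3,
                "log2_fold_change": [0.0] * 3,
            },
            index=["PS1", "PS2", "PS3"],
        )
        meta = compute_meta(table)
        rec = meta.loc["G1"]
        assert rec["t_p_min"] == 0.001
        assert rec["t_p_max"] == 0.95
        assert rec["t_p_mean"] == pytest.approx(0.617)
        # sample variance (n-1): ((0.616)^2 + (0.283)^2 + (0.333)^2) / 2
        assert rec["t_p_var"] == pytest.approx(0.285217, abs=1e-6)

    def test_single_probeset_gene_degenerate(self):
        table = pd.DataFrame(
            {
                "gene_id": ["G1"],
                "t_p": [0.5],
                "midas_p": [0.5],
                "splicing_index": [0.4],
                "log2_fold_change": [0.1],
            },
            index=["PS1"],
        )
        rec = compute_meta(table).loc["G1"]
        assert rec["splicing_index_min"] == rec["splicing_index_max"] == 0.4
        assert rec["splicing_index_mean"] == 0.4
        assert rec["splicing_index_var"] == 0.0

    def test_filtered_probesets_excluded_by_default(self, rng):
        table = _exon_table(rng, n_genes=5)
        table["filtered"] = False
        table.iloc[:4, table.columns.get_loc("filtered")] = True  # all of G000
        meta = compute_meta(table)
        assert "G000" not in meta.index
        assert compute_meta(table, use_filtered=True).loc["G000", "n_probesets"] == 4

    def test_min_mean_max_ordering(self, exon_stats_small):
        meta = compute_meta(exon_stats_small)
        for stat in ("t_p", "midas_p", "splicing_index", "log2_fold_change"):
            assert (meta[f"{stat}_min"] <= meta[f"{stat}_mean"] + 1e-12).all()
            assert (meta[f"{stat}_mean"] <= meta[f"{stat}_max"] + 1e-12).all()
            assert (meta[f"{stat}_var"] >= 0).all()


class TestScaling:
    def test_zscore_columns(self, rng):
        meta = _random_meta(rng)
        scaled, params = scale_meta(meta)
        np.testing.assert_allclose(scaled.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(scaled.std(axis=0, ddof=0), 1.0, atol=1e-10)
        np.testing.assert_allclose(
            unscale_meta(scaled, params).to_numpy(),
            meta[list(META_COMPONENTS)].to_numpy(),
            atol=1e-10,
        )

    def test_constant_column_maps_to_zero(self, rng):
        meta = _random_meta(rng)
        meta["t_p_min"] = 0.25
        scaled, params = scale_meta(meta)
        assert (scaled["t_p_min"] == 0.0).all()
        assert params.transform({"t_p_min": 0.7})["t_p_min"] == 0.0


class TestRanking:
    def test_self_query_is_first_with_zero_distance(self, rng):
        meta = _random_meta(rng)
        scaled, _ = scale_meta(meta)
        query = QueryPoint(values=scaled.loc["G007"].to_dict())
        ranked = rank_by_distance(scaled, query)
        assert ranked[0] == ("G007", 0.0)

    def test_one_dimensional_ordering(self):
        scaled = pd.DataFrame(
            {"t_p_min": [1.0, 3.0]}, index=pd.Index(["GA", "GB"], name="gene_id")
        )
        ranked = rank_by_distance(scaled, QueryPoint(values={"t_p_min": 0.0}))
        assert ranked == [("GA", 1.0), ("GB", 3.0)]

    def test_empty_query_rejected(self, rng):
        meta = _random_meta(rng)
        scaled, _ = scale_meta(meta)
        with pytest.raises(ValueError, match="no active components"):
            rank_by_distance(scaled, QueryPoint(values={}))

    def test_matches_brute_force(self, rng):
        meta = _random_meta(rng)
        scaled, _ = scale_meta(meta)
        comps = list(rng.choice(META_COMPONENTS, size=5, replace=False))
        point = {c: float(rng.normal()) for c in comps}
        ranked = rank_by_distance(scaled, QueryPoint(values=point))
        brute = sorted(
            (
                (np.sqrt(sum((scaled.at[g, c] - point[c]) ** 2 for c in comps)), g)
                for g in scaled.index
            )
        )
        assert [g for g, _ in ranked] == [g for _, g in brute]

    def test_inactive_component_never_changes_order(self, rng):
        meta = _random_meta(rng)
        scaled, _ = scale_meta(meta)
        q1 = QueryPoint(values={"t_p_min": -1.0})
        ranked1 = rank_by_distance(scaled, q1)
        # still only one active component; the rest of the vector is ignored
        assert [g for g, _ in ranked1] == [
            g for g, _ in rank_by_distance(scaled[["t_p_min", "t_p_max"]], q1)
        ]

    def test_order_invariant_to_gene_order(self, rng):
        meta = _random_meta(rng)
        scaled, _ = scale_meta(meta)
        q = QueryPoint(values={"splicing_index_max": 2.0, "t_p_min": -1.0})
        shuffled = scaled.sample(frac=1.0, random_state=1)
        assert rank_by_distance(scaled, q) == rank_by_distance(shuffled, q)


class TestRankWithinSet:
    def _sets(self, members):
        return pd.DataFrame(
            {"set_id": ["PW1"] * len(members), "gene_id": members,
             "kind": ["pathway"] * len(members)}
        )

    def test_singleton_set_is_empty(self, rng):
        meta = _random_meta(rng)
        scaled, _ = scale_meta(meta)
        assert rank_within_set("G000", "PW1", scaled, self._sets(["G000"])) == []

    def test_identical_gene_ranks_first(self, rng):
        meta = _random_meta(rng)
        meta.loc["G001"] = meta.loc["G000"]
        scaled, _ = scale_meta(meta)
        ranked = rank_within_set(
            "G000", "PW1", scaled, self._sets(["G000", "G001", "G002"])
        )
        assert ranked[0] == ("G001", 0.0)

    def test_matches_brute_force(self, rng):
        meta = _random_meta(rng)
        scaled, _ = scale_meta(meta)
        members = [f"G{i:03d}" for i in range(20)]
        ranked = rank_within_set("G000", "PW1", scaled, self._sets(members))
        focal = scaled.loc["G000"]
        brute = sorted(
            (float(np.sqrt(((scaled.loc[g] - focal) ** 2).sum())), g)
            for g in members[1:]
        )
        assert [g for g, _ in ranked] == [g for _, g in brute]

    def test_non_member_focal_rejected(self, rng):
        meta = _random_meta(rng)
        scaled, _ = scale_meta(meta)
        with pytest.raises(KeyError):
            rank_within_set("G099", "PW1", scaled, self._sets(["G000", "G001"]))


class TestSearch:
    def _genes(self):
        return pd.DataFrame(
            {
                "symbol": ["ALPHA", "BETA", "GAMMA"],
                "aliases": [("ALF",), (), ("GMA", "G3")],
                "chrom": ["chr8", "chr8", "chr2"],
                "start": [100, 5000, 100],
                "stop": [400, 5400, 400],
                "strand": ["+", "-", "+"],
                "pathway_ids": [frozenset({"PW1"}), frozenset(), frozenset({"PW1"})],
                "go_ids": [frozenset(), frozenset({"GO:1"}), frozenset()],
            },
            index=pd.Index(["GA", "GB", "GC"], name="gene_id"),
        )

    def test_chromosome_filter(self, rng):
        meta = _random_meta(rng, 3).set_axis(["GA", "GB", "GC"])
        out = search_genes(self._genes(), meta, chrom="chr8")
        assert list(out.index) == ["GA", "GB"]

    def test_alias_substring(self, rng):
        meta = _random_meta(rng, 3).set_axis(["GA", "GB", "GC"])
        out = search_genes(self._genes(), meta, symbol="alf")
        assert list(out.index) == ["GA"]

    def test_interval_overlap_and_malformed(self, rng):
        meta = _random_meta(rng, 3).set_axis(["GA", "GB", "GC"])
        out = search_genes(self._genes(), meta, chrom="chr8", start=4500, stop=6000)
        assert list(out.index) == ["GB"]
        with pytest.raises(ValueError, match="start.*stop"):
            search_genes(self._genes(), meta, start=10, stop=5)

    def test_filter_then_rank_equals_brute_force(self, rng):
        meta = _random_meta(rng, 3).set_axis(["GA", "GB", "GC"])
        scaled, params = scale_meta(meta)
        q = QueryPoint(values={"t_p_min": 0.0})
        out = search_genes(
            self._genes(), meta, chrom="chr8", query=q, scaled=scaled, params=params
        )
        survivors = ["GA", "GB"]
        brute = rank_by_distance(scaled.loc[survivors], q, params)
        assert list(out.index) == [g for g, _ in brute]
        np.testing.assert_allclose(out["distance"], [d for _, d in brute])
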