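"""Determinism, geometry, and parse-cleanliness of the synthetic generators."""

import warnings

import pytest

from oxscreen import enrichment, ppi_network, screen_stats, synthetic_data, target_catalog
from oxscreen.exceptions import InvalidParameterError


def _hits_as_records(df):
    return [
        target_catalog.BlastHit(r.qseqid, r.sseqid, r.pident, r.evalue, r.bitscore)
        for r in df.itertuples(index=False)
    ]


class TestDeterminism:
    def test_same_seed_gives_byte_identical_files(self, tmp_path):
        for name, gen in {
            "plate.csv": lambda s: synthetic_data.simulate_screen(
                n_sirnas=5, replicates=3, timepoints=2, noise_sd=8.0, seed=s
            )[0].to_csv(index=False),
            "blast.tsv": lambda s: synthetic_data.simulate_hits_and_annotation(
                n_genes=30, n_queries=8, decoys_per_query=2, seed=s
            )[0].to_csv(sep="\t", index=False),
            "ppi.tsv": lambda s: synthetic_data.simulate_interactome(seed=s)[0].to_csv(
                sep="\t", index=False
            ),
        }.items():
            assert gen(123) == gen(123), name

    def test_different_seeds_differ(self):
        a, _ = synthetic_data.simulate_screen(n_sirnas=5, noise_sd=8.0, seed=1)
        b, _ = synthetic_data.simulate_screen(n_sirnas=5, noise_sd=8.0, seed=2)
        assert not a.equals(b)


class TestScreenGenerator:
    def test_screen_geometry_matches_assay_design(self):
        plate, truth = synthetic_data.simulate_screen(
            n_sirnas=181, replicates=4, timepoints=6, noise_sd=10.0, seed=0
        )
        assert plate["condition"].nunique() == 182  # 181 siRNAs + negative control
        assert sorted(plate["timepoint_h"].unique()) == [19, 24, 48, 72, 120, 144]
        per_condition = plate.groupby(["condition", "timepoint_h"]).size()
        assert (per_condition == 4).all()
        assert len(truth.planted_effects) == 181
        assert synthetic_data.NEGATIVE_CONTROL in set(plate["condition"])

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(InvalidParameterError):
            synthetic_data.simulate_screen(n_sirnas=0, seed=0)
        with pytest.raises(InvalidParameterError):
            synthetic_data.simulate_screen(n_sirnas=5, replicates=1, seed=0)

    def test_plate_parses_cleanly(self, tmp_path):
        plate, _ = synthetic_data.simulate_screen(n_sirnas=4, seed=3)
        path = tmp_path / "plate.csv"
        synthetic_data.write_plate_csv(plate, path)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            parsed = screen_stats.read_plate_csv(path)
        assert len(parsed) == len(plate)


class TestBlastGenerator:
    def test_catalog_closure_and_no_decoy_cases(self, tmp_path):
        hits, ann, truth = synthetic_data.simulate_hits_and_annotation(
            n_genes=40, n_queries=10, decoys_per_query=0, seed=5
        )
        catalog = target_catalog.reduce_hits(_hits_as_records(hits), ann)
        assert len(catalog.per_query) == 10  # every hit survives with no decoys
        recovered = {q: genes[0][0] for q, genes in catalog.per_query.items()}
        assert recovered == truth.planted_targets

    def test_biotype_mix_must_sum_to_one(self):
        with pytest.raises(InvalidParameterError):
            synthetic_data.simulate_hits_and_annotation(
                n_genes=10, biotype_mix=(0.5, 0.2, 0.2, 0.2), seed=0
            )

    def test_blast_file_round_trips_through_parser(self, tmp_path):
        hits, _, _ = synthetic_data.simulate_hits_and_annotation(
            n_genes=20, n_queries=5, decoys_per_query=2, seed=7
        )
        path = tmp_path / "hits.tsv"
        synthetic_data.write_blast_tsv(hits, path)
        parsed = target_catalog.parse_blast_tabular(path)
        assert len(parsed) == len(hits)


class TestInteractomeGenerator:
    def test_largest_module_is_lcc_at_high_threshold(self):
        table, truth = synthetic_data.simulate_interactome(
            module_sizes=(7, 4, 3), n_background=10, p_within=1.0, seed=1
        )
        import io

        edges = ppi_network.load_interactions(
            io.StringIO(table.to_csv(sep="\t", index=False)), min_score=900
        )
        import networkx as nx

        g = nx.Graph()
        g.add_edges_from(edges[["node_a", "node_b"]].itertuples(index=False))
        lcc = ppi_network.largest_connected_component(g)
        assert lcc == set(max(truth.planted_modules, key=len))

    def test_p_within_zero_gives_no_component_above_two(self):
        table, _ = synthetic_data.simulate_interactome(
            module_sizes=(6, 4), n_background=8, p_within=0.0, seed=2
        )
        import networkx as nx

        g = nx.Graph()
        g.add_edges_from(table[["protein1", "protein2"]].itertuples(index=False))
        assert all(len(c) <= 2 for c in nx.connected_components(g))

    def test_no_duplicate_unordered_pairs(self):
        table, _ = synthetic_data.simulate_interactome(seed=4)
        pairs = {frozenset((a, b)) for a, b in table[["protein1", "protein2"]].itertuples(index=False)}
        assert len(pairs) == len(table)

    def test_score_range_validated(self):
        with pytest.raises(InvalidParameterError):
            synthetic_data.simulate_interactome(score_range=(40, 998), seed=0)
        with pytest.raises(InvalidParameterError):
            synthetic_data.simulate_interactome(score_range=(41, 999), seed=0)


class TestGenesetGenerator:
    def test_gmt_round_trips(self, tmp_path):
        sets, _, _ = synthetic_data.simulate_genesets(seed=6)
        path = tmp_path / "sets.gmt"
        enrichment.write_gmt(sets, path)
        parsed = enrichment.read_gmt(path)
        assert [(s.set_id, s.genes) for s in parsed] == [(s.set_id, s.genes) for s in sets]

    def test_zero_overlap_planted_set_never_significant(self):
        sets, query, truth = synthetic_data.simulate_genesets(
            planted_set_overlap=0, query_size=20, seed=8
        )
        results = enrichment.run_ora(query, sets)
        planted_id = truth.planted_enriched_sets[0]["set_id"]
        row = results[results["set_id"] == planted_id].iloc[0]
        assert not row["significant"]


class TestDrugGenerator:
    def test_planted_overlap_counts_recovered(self, tmp_path):
        from oxscreen import drug_mining

        la = [f"A{i}" for i in range(6)]
        lb = [f"B{i}" for i in range(6)]
        db, ttd, truth = synthetic_data.simulate_drug_tables(
            la, lb, n_common_drugs=4, n_cross_db_common=2, approved_fraction=0.5, seed=3
        )
        pdb, pttd = tmp_path / "db.tsv", tmp_path / "ttd.tsv"
        synthetic_data.write_drug_tsv(db, pdb)
        synthetic_data.write_drug_tsv(ttd, pttd)
        rdb = drug_mining.load_drug_table(pdb, "DB")
        rttd = drug_mining.load_drug_table(pttd, "TTD")
        hits_a = drug_mining.query_drugs(la, rdb)
        hits_b = drug_mining.query_drugs(lb, rdb)
        assert len(drug_mining.intersect_hits(hits_a, hits_b)) == 4
        both_db = drug_mining.query_drugs(la + lb, rdb)
        both_ttd = drug_mining.query_drugs(la + lb, rttd)
        assert len(drug_mining.cross_database_common(both_db, both_ttd)) == 2
        assert truth.planted_drug_overlaps == {
            "common_within_db": 4,
            "cross_db_common": 2,
        }

    def test_zero_common_drugs_gives_empty_intersection(self):
        from oxscreen import drug_mining

        db, _, _ = synthetic_data.simulate_drug_tables(
            ["A1"], ["B1"], n_common_drugs=0, n_cross_db_common=0, seed=1
        )
        recs = [
            drug_mining.DrugTargetRecord(r.drug_id, r.name, drug_mining.map_status(r.group), r.gene, "DB")
            for r in db.itertuples(index=False)
        ]
        hits_a = drug_mining.query_drugs(["A1"], recs)
        hits_b = drug_mining.query_drugs(["B1"], recs)
        assert drug_mining.intersect_hits(hits_a, hits_b, "any") == set()

    def test_approved_fraction_one_means_all_approved(self):
        db, ttd, _ = synthetic_data.simulate_drug_tables(
            ["A1", "A2"], ["B1"], approved_fraction=1.0, seed=2
        )
        assert set(db["group"].str.lower()) == {"approved"}
        assert set(ttd["status"].str.lower()) == {"approved"}
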