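"""Eligibility, aggregation and the two population predictions."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ccfkit.errors import NoDataError, NoReferenceError, RecordValidationError, UndefinedSimilarityError
from ccfkit.populations import (
    CellTypePopulation,
    DatasetRecord,
    aggregate_as_populations,
    cosine_similarity,
    filter_eligible,
    population_similarity,
    predict_origin,
    predict_site_population,
    read_population_csv,
    write_population_csv,
)
from ccfkit.registration import CollisionRecord

from conftest import make_site


def site_with_fractions(fractions, site_id="00000000-0000-4000-8000-000000000042"):
    site = make_site((1, 1, 1), (0, 0, 0), site_id=site_id)
    site.annotations = [
        CollisionRecord(as_id=a, method="mesh", intersection_volume=f, fraction_of_block=f)
        for a, f in fractions.items()
    ]
    return site


def record(dataset_id="d1", site=None, pop=None, provenance="portal_qc"):
    return DatasetRecord(
        dataset_id=dataset_id,
        modality="sc_transcriptomics",
        extraction_site=site,
        population=pop,
        provenance=provenance,
    )


class TestCellTypePopulation:
    def test_proportions_sum_to_one(self):
        pop = CellTypePopulation(counts={"CL:1": 3.0, "CL:2": 7.0})
        assert sum(pop.proportions().values()) == pytest.approx(1.0, abs=1e-9)

    def test_negative_count_rejected(self):
        with pytest.raises(RecordValidationError):
            CellTypePopulation(counts={"CL:1": -1.0})

    def test_csv_roundtrip_with_expressions(self, tmp_path):
        pops = {
            "ds1": CellTypePopulation(
                counts={"CL:1": 10.0, "CL:2": 5.0},
                biomarkers=("NPHS1", "UMOD"),
                mean_expression={"CL:1": [1.5, 0.1], "CL:2": [0.0, 2.5]},
            )
        }
        path = tmp_path / "pops.csv"
        write_population_csv(pops, path)
        again = read_population_csv(path)
        assert again["ds1"].counts == pops["ds1"].counts
        assert np.allclose(again["ds1"].mean_expression["CL:2"], [0.0, 2.5])


class TestEligibility:
    def test_complete_record_eligible(self):
        rec = record(site=site_with_fractions({"A": 1.0}), pop=CellTypePopulation({"CL:1": 1}))
        eligible, reasons = filter_eligible([rec])
        assert eligible == [rec] and reasons == {}

    def test_missing_registration_cited_first(self):
        rec = record(site=None, pop=CellTypePopulation({"CL:1": 1}))
        _, reasons = filter_eligible([rec])
        assert "registered" in reasons["d1"]

    def test_five_record_fixture(self):
        site = site_with_fractions({"A": 1.0})
        pop = CellTypePopulation({"CL:1": 1})
        records = [
            record("c1", site, pop),
            record("c2", site, pop, "peer_reviewed"),
            record("c3", site, pop),
            record("nopop", site, None),
            record("noprov", site, pop, "none"),
        ]
        eligible, reasons = filter_eligible(records)
        assert [r.dataset_id for r in eligible] == ["c1", "c2", "c3"]
        assert "population" in reasons["nopop"] and "provenance" in reasons["noprov"]


class TestAggregation:
    def test_dataset_wholly_inside_one_structure(self):
        pop = CellTypePopulation(counts={"CL:1": 30.0, "CL:2": 70.0})
        rec = record(site=site_with_fractions({"A": 1.0}), pop=pop)
        agg = aggregate_as_populations([rec])
        assert agg["A"].counts == pop.counts

    def test_even_split_halves_every_count(self):
        pop = CellTypePopulation(counts={"CL:1": 30.0, "CL:2": 70.0})
        rec = record(site=site_with_fractions({"A": 0.5, "B": 0.5}), pop=pop)
        agg = aggregate_as_populations([rec])
        for s in ("A", "B"):
            assert agg[s].counts == {"CL:1": 15.0, "CL:2": 35.0}

    def test_total_count_conserved_on_random_fixtures(self):
        rng = np.random.default_rng(2)
        records = []
        for i in range(20):
            k = rng.integers(1, 4)
            fr = rng.dirichlet(np.ones(k)) * rng.uniform(0.3, 1.0)
            site = site_with_fractions(
                {f"AS:{j}": float(f) for j, f in enumerate(fr)},
                site_id=f"00000000-0000-4000-8000-0000000001{i:02d}",
            )
            counts = {f"CL:{t}": float(c) for t, c in enumerate(rng.integers(1, 500, 5))}
            records.append(record(f"d{i}", site, CellTypePopulation(counts)))
        agg = aggregate_as_populations(records)
        total_in = sum(r.population.total() for r in records)
        total_out = sum(p.total() for p in agg.values())
        assert total_out == pytest.approx(total_in, rel=1e-9)

    def test_weighted_mean_expression_matches_cell_level_oracle(self):
        # build per-cell data, roll up two ways: per-dataset means -> aggregation
        # vs a direct mean over all cells apportioned to the structure
        rng = np.random.default_rng(9)
        records = []
        cell_level = {"A": [], "B": []}
        for i in range(4):
            w_a = float(rng.uniform(0.2, 0.8))
            fractions = {"A": w_a, "B": 1 - w_a}
            n = int(rng.integers(50, 150))
            expr = rng.normal(size=n)  # one biomarker, one cell type
            pop = CellTypePopulation(
                counts={"CL:1": float(n)},
                biomarkers=("BM",),
                mean_expression={"CL:1": [float(expr.mean())]},
            )
            site = site_with_fractions(
                fractions, site_id=f"00000000-0000-4000-8000-0000000002{i:02d}"
            )
            records.append(record(f"d{i}", site, pop))
            # the same dataset mean applies to both structures; the oracle
            # weights dataset means by apportioned counts
            for s, w in fractions.items():
                cell_level[s].append((w * n, expr.mean()))
        agg = aggregate_as_populations(records)
        for s in ("A", "B"):
            weights = np.array([w for w, _ in cell_level[s]])
            means = np.array([m for _, m in cell_level[s]])
            oracle = float((weights * means).sum() / weights.sum())
            assert agg[s].mean_expression["CL:1"][0] == pytest.approx(oracle, rel=1e-9)

    def test_site_without_mesh_records_skipped_with_warning(self):
        rec = record(site=make_site((1, 1, 1), (0, 0, 0)), pop=CellTypePopulation({"CL:1": 1}))
        with pytest.warns(UserWarning, match="no mesh-method"):
            agg = aggregate_as_populations([rec])
        assert agg == {}


class TestPredictSitePopulation:
    AS_POPS = {
        "A": CellTypePopulation(counts={"X": 100.0}),
        "B": CellTypePopulation(counts={"Y": 50.0}),
    }

    def test_site_entirely_in_one_structure(self):
        site = site_with_fractions({"A": 1.0})
        pred = predict_site_population(site, self.AS_POPS)
        assert pred.counts == {"X": 1.0}

    def test_even_split_mixes_half_half(self):
        site = site_with_fractions({"A": 0.5, "B": 0.5})
        pred = predict_site_population(site, self.AS_POPS)
        assert pred.counts == {"X": pytest.approx(0.5), "Y": pytest.approx(0.5)}

    def test_total_cell_budget_scales_counts(self):
        site = site_with_fractions({"A": 0.5, "B": 0.5})
        pred = predict_site_population(site, self.AS_POPS, total_cells=2000)
        assert pred.total() == pytest.approx(2000)

    def test_unknown_structure_triggers_renormalization_warning(self):
        site = site_with_fractions({"A": 0.5, "Z": 0.5})
        with pytest.warns(UserWarning, match="renormalized"):
            pred = predict_site_population(site, self.AS_POPS)
        assert pred.counts == {"X": pytest.approx(1.0)}

    def test_no_known_structures_is_an_error(self):
        site = site_with_fractions({"Z": 1.0})
        with pytest.raises(NoDataError):
            predict_site_population(site, self.AS_POPS)

    def test_aggregate_then_predict_roundtrip(self):
        pop = CellTypePopulation(counts={"CL:1": 20.0, "CL:2": 80.0})
        site = site_with_fractions({"A": 1.0})
        agg = aggregate_as_populations([record(site=site, pop=pop)])
        pred = predict_site_population(site, agg)
        for ct, p in pop.proportions().items():
            assert pred.counts[ct] == pytest.approx(p, abs=1e-9)

    def test_prediction_matches_empirical_mean_of_sampled_datasets(self):
        from ccfkit.synth import simulate_dataset_from_site

        as_pops = {
            "A": CellTypePopulation(counts={"X": 70.0, "Y": 30.0}),
            "B": CellTypePopulation(counts={"Y": 40.0, "Z": 60.0}),
        }
        site = site_with_fractions({"A": 0.6, "B": 0.4})
        pred = predict_site_population(site, as_pops)
        n_cells, n_datasets = 200, 10_000
        totals = {}
        for i in range(n_datasets):
            ds = simulate_dataset_from_site(site, as_pops, n_cells=n_cells, seed=i)
            for ct, c in ds.population.counts.items():
                totals[ct] = totals.get(ct, 0.0) + c
        for ct, p in pred.counts.items():
            emp = totals[ct] / (n_cells * n_datasets)
            se = np.sqrt(p * (1 - p) / (n_cells * n_datasets))
            assert abs(emp - p) < 3 * se + 1e-12


class TestCosineSimilarity:
    def test_identical_vectors_score_one(self):
        v = np.array([3.0, 1.0, 2.0])
        assert cosine_similarity(v, v) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_supports_score_zero(self):
        assert cosine_similarity([1.0, 2.0, 0.0, 0.0], [0.0, 0.0, 3.0, 4.0]) == 0.0

    def test_closed_form_value(self):
        assert cosine_similarity([1.0, 0.0], [1.0, 1.0]) == pytest.approx(1 / np.sqrt(2), abs=1e-5)

    def test_zero_vector_rejected(self):
        with pytest.raises(UndefinedSimilarityError):
            cosine_similarity([0.0, 0.0], [1.0, 1.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        u=st.lists(st.floats(0, 100), min_size=3, max_size=3),
        v=st.lists(st.floats(0, 100), min_size=3, max_size=3),
        alpha=st.floats(0.01, 100),
        beta=st.floats(0.01, 100),
    )
    def test_symmetric_and_scale_invariant(self, u, v, alpha, beta):
        u, v = np.array(u), np.array(v)
        if u.sum() == 0 or v.sum() == 0:
            return
        s1 = cosine_similarity(u, v)
        assert s1 == pytest.approx(cosine_similarity(v, u), abs=1e-12)
        assert s1 == pytest.approx(cosine_similarity(alpha * u, beta * v), abs=1e-9)
        assert 0.0 <= s1 <= 1.0


class TestPredictOrigin:
    AS_POPS = {
        "UBERON:1": CellTypePopulation(counts={"X": 80.0, "Y": 20.0}),
        "UBERON:2": CellTypePopulation(counts={"Y": 10.0, "Z": 90.0}),
    }

    def test_query_equal_to_structure_vector_ranks_it_first(self):
        query = CellTypePopulation(counts={"X": 8.0, "Y": 2.0})
        pred = predict_origin(query, self.AS_POPS)
        assert pred.ranked[0] == ("UBERON:1", pytest.approx(1.0, abs=1e-12))

    def test_query_on_unique_types_picks_their_structure(self):
        query = CellTypePopulation(counts={"Z": 5.0})
        pred = predict_origin(query, self.AS_POPS)
        assert pred.ranked[0][0] == "UBERON:2"

    def test_ties_broken_lexicographically(self):
        pops = {
            "UBERON:b": CellTypePopulation(counts={"X": 1.0}),
            "UBERON:a": CellTypePopulation(counts={"X": 2.0}),
        }
        pred = predict_origin(CellTypePopulation(counts={"X": 1.0}), pops)
        assert [a for a, _ in pred.ranked] == ["UBERON:a", "UBERON:b"]

    def test_top_k_truncates(self):
        pred = predict_origin(CellTypePopulation(counts={"Y": 1.0}), self.AS_POPS, top_k=1)
        assert len(pred.ranked) == 1

    def test_empty_reference_rejected(self):
        with pytest.raises(NoReferenceError):
            predict_origin(CellTypePopulation(counts={"X": 1.0}), {})

    def test_similarities_sorted_non_increasing(self):
        pred = predict_origin(CellTypePopulation(counts={"Y": 1.0, "Z": 1.0}), self.AS_POPS)
        sims = [s for _, s in pred.ranked]
        assert sims == sorted(sims, reverse=True)
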