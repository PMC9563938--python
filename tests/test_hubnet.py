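import math

import numpy as np
import pytest

from semhub import hubnet, linkpred, synthgen
from semhub.hubnet import (AggregateEntry, HubNeighborhood, HubSimResult,
                           aggregate, apply_foci, assign_tiers,
                           build_neighborhood, export_curation_template,
                           import_curation, read_foci_map, run_hub_simulation,
                           select_hubs)

from conftest import make_graph


def entry_list(n):
    ranking = aggregate([HubSimResult("h", [(f"n{i:04d}", i / max(n - 1, 1))
                                            for i in range(n)])])
    return ranking


class TestSelectHubs:
    def test_shared_neighbors_degree_ordered(self):
        g = make_graph(
            [("A1", "DSYN"), ("A2", "AAPP"), ("S1", "DSYN"), ("S2", "DSYN"),
             ("S3", "DSYN"), ("X", "GNGM")],
            [("S1", "AFFECTS", "A1", 1.0), ("S1", "AFFECTS", "A2", 1.0),
             ("S2", "AFFECTS", "A1", 1.0), ("S2", "AFFECTS", "A2", 1.0),
             ("S2", "AFFECTS", "X", 9.0),
             ("S3", "AFFECTS", "A1", 1.0), ("S3", "AFFECTS", "A2", 1.0),
             ("S3", "AFFECTS", "X", 4.0)])
        assert select_hubs(g, ("A1", "A2"), n=6) == ["S2", "S3", "S1"]

    def test_disjoint_anchor_neighborhoods_empty(self):
        g = make_graph([("A1", "DSYN"), ("A2", "AAPP"), ("B", "GNGM"),
                        ("C", "GNGM")],
                       [("B", "AFFECTS", "A1", 1.0), ("C", "AFFECTS", "A2", 1.0)])
        assert select_hubs(g, ("A1", "A2")) == []

    def test_construction_ground_truth_recovered(self):
        for seed in range(3):
            g, truth = synthgen.gen_kg(synthgen.KGSpec(seed=seed))
            assert sorted(select_hubs(g, truth.anchors)) == sorted(truth.hubs)


class TestBuildNeighborhood:
    @pytest.fixture(scope="class")
    def trained(self):
        g, truth = synthgen.gen_kg(synthgen.KGSpec(seed=0))
        model = linkpred.train_transe(g, linkpred.TransEConfig(epochs=20),
                                      seed=0)
        return g, truth, model

    def test_cap_and_dedup(self, trained):
        g, truth, model = trained
        nb = build_neighborhood(model, g, truth.hubs[0], cap=5)
        assert len(nb.members) <= 5
        ids = nb.member_ids()
        assert len(ids) == len(set(ids))
        assert truth.hubs[0] not in ids
        weights = [w for _, w in nb.members]
        assert weights == sorted(weights, reverse=True)
        assert all(0 <= w <= 1 for w in weights)

    def test_dedup_keeps_max_weight(self, trained):
        g, truth, model = trained
        per_pred = {}
        for pred in ("CAUSES", "AFFECTS"):
            for link in linkpred.predict_entities(model, g, truth.hubs[0],
                                                  pred, ("AAPP",), top_k=25):
                per_pred.setdefault(link.tail, []).append(link.norm_weight)
        nb = build_neighborhood(model, g, truth.hubs[0],
                                predicates=("CAUSES", "AFFECTS"),
                                ntypes=("AAPP",), cap=25)
        got = dict(nb.members)
        for tail, ws in per_pred.items():
            if tail in got:
                assert got[tail] == pytest.approx(max(ws))


class TestRunHubSimulation:
    def test_minmax_span_and_order_preserved(self):
        g, truth = synthgen.gen_kg(synthgen.KGSpec(seed=1))
        model = linkpred.train_transe(g, linkpred.TransEConfig(epochs=20),
                                      seed=1)
        nb = build_neighborhood(model, g, truth.hubs[0], cap=10)
        sim = run_hub_simulation(g, nb, truth.anchors[1])
        scores = [s for _, s in sim.candidates]
        assert len(set(scores)) >= 2
        assert min(scores) == 0.0 and max(scores) == 1.0
        assert scores == sorted(scores)   # monotone transform keeps ordering

    def test_single_candidate_normalizes_to_zero(self):
        g = make_graph(
            [("F", "AAPP"), ("N", "AAPP"), ("M", "GNGM"), ("D", "DSYN")],
            [("F", "AFFECTS", "M", 1.0), ("N", "AFFECTS", "M", 1.0),
             ("D", "AFFECTS", "M", 2.0)])
        nb = HubNeighborhood(hub="H", members=[("N", 1.0)])
        sim = run_hub_simulation(g, nb, "F")
        assert sim.candidates == [("D", 0.0)]

    def test_empty_neighborhood_rejected(self):
        g = make_graph([("F", "AAPP")], [])
        with pytest.raises(ValueError):
            run_hub_simulation(g, HubNeighborhood(hub="H", members=[]), "F")


class TestAggregate:
    def test_full_presence_zero_score_tops(self):
        sims = [HubSimResult(f"h{i}", [("best", 0.0), ("meh", 0.8)])
                for i in range(6)]
        ranking = aggregate(sims)
        assert ranking[0].node == "best"
        assert ranking[0].composite == pytest.approx(1.0)
        assert ranking[0].rank == 1

    def test_partial_presence_arithmetic(self):
        sims = [HubSimResult(f"h{i}", [("c", 0.5)] if i < 3 else [("d", 0.0)])
                for i in range(6)]
        entry = {e.node: e for e in aggregate(sims)}["c"]
        assert entry.occurrence_rate == pytest.approx(0.5)
        assert entry.composite == pytest.approx(0.25)

    def test_absent_candidate_absent_from_output(self):
        ranking = aggregate([HubSimResult("h", [("a", 0.1)])])
        assert [e.node for e in ranking] == ["a"]

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        sims = [HubSimResult(f"h{i}",
                             [(f"n{j}", float(rng.random()))
                              for j in rng.choice(20, 8, replace=False)])
                for i in range(6)]
        fwd = aggregate(sims)
        rev = aggregate(sims[::-1])
        assert [(e.node, e.rank, e.composite) for e in fwd] == \
               [(e.node, e.rank, e.composite) for e in rev]

    def test_composite_bounds(self):
        rng = np.random.default_rng(1)
        sims = [HubSimResult(f"h{i}",
                             [(f"n{j}", float(rng.random())) for j in range(10)])
                for i in range(4)]
        for e in aggregate(sims):
            assert 0.0 <= e.composite <= 1.0


class TestAssignTiers:
    @pytest.mark.parametrize("n,sizes", [
        (1000, (10, 50, 100)),
        (100, (1, 5, 10)),
        (10, (1, 1, 1)),
        (3, (1, 1, 1)),
    ])
    def test_ceiling_arithmetic(self, n, sizes):
        ranking = assign_tiers(entry_list(n))
        cum1 = sum(e.tier == "1" for e in ranking)
        cum2 = cum1 + sum(e.tier == "2" for e in ranking)
        cum3 = cum2 + sum(e.tier == "3" for e in ranking)
        assert (cum1, cum2, cum3) == sizes

    def test_nesting(self):
        for n in (1, 3, 7, 42, 500):
            ranking = assign_tiers(entry_list(n))
            t1 = {e.node for e in ranking if e.tier == "1"}
            top5 = {e.node for e in ranking if e.rank <= math.ceil(0.05 * n)}
            top10 = {e.node for e in ranking if e.rank <= math.ceil(0.10 * n)}
            assert t1 <= top5 <= top10

    def test_bad_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            assign_tiers(entry_list(5), cutoffs=(0.05, 0.01, 0.10))


class TestFociAndCuration:
    def make_ranking(self):
        return assign_tiers(entry_list(30))

    def test_empty_map_all_other(self):
        groups = apply_foci(self.make_ranking(), {})
        assert set(groups) == {"other"}

    def test_focus_grouping_top3(self, tmp_path):
        ranking = self.make_ranking()
        tiered = [e.node for e in ranking if e.tier != "none"]
        p = tmp_path / "foci.tsv"
        p.write_text("".join(f"{n}\thematology\n" for n in tiered[:5]))
        groups = apply_foci(ranking, read_foci_map(p))
        assert len(groups["hematology"]) == min(3, len(tiered[:5]))
        ranks = [e.rank for e in groups["hematology"]]
        assert ranks == sorted(ranks)

    def test_malformed_map_line_number(self, tmp_path):
        p = tmp_path / "foci.tsv"
        p.write_text("a\tx\nbroken-line\n")
        with pytest.raises(ValueError, match=":2:"):
            read_foci_map(p)

    def test_template_roundtrip_and_validation(self, tmp_path):
        ranking = self.make_ranking()
        path = tmp_path / "curation.tsv"
        n_rows = export_curation_template(ranking, path)
        assert n_rows == sum(e.tier != "none" for e in ranking)
        # unfilled template fails validation
        with pytest.raises(ValueError, match="invalid verdict"):
            import_curation(path)
        filled = path.read_text().splitlines()
        filled = [filled[0]] + [l + "agrees" for l in filled[1:]]
        path.write_text("\n".join(filled) + "\n")
        assert import_curation(path) == {"agrees": n_rows, "disagrees": 0,
                                         "missing": 0}

    def test_invalid_verdict_rejected(self, tmp_path):
        path = tmp_path / "curation.tsv"
        export_curation_template(self.make_ranking(), path)
        lines = path.read_text().splitlines()
        filled = [lines[0], lines[1] + "maybe"] + [l + "agrees"
                                                   for l in lines[2:]]
        path.write_text("\n".join(filled) + "\n")
        with pytest.raises(ValueError, match="maybe"):
            import_curation(path)
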