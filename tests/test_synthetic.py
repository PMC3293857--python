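"""Planted synthetic studies: determinism, feasibility checks, ground truth."""

import filecmp

import numpy as np
import pytest

from nfkbkit.errors import SyntheticSpecError
from nfkbkit.interactome import InteractionNetwork
from nfkbkit.ppi_io import ProteinSet, read_edges_and_isolated, read_gmt, read_protein_set
from nfkbkit.set_algebra import REGIONS, venn3
from nfkbkit.synthetic import (
    SyntheticSpec,
    generate_ppi,
    plant_annotation,
    plant_downstream,
    plant_sets,
    simulate_study,
    write_study,
)

SMALL = dict(
    n_proteins=300,
    region_counts=(60, 30, 20, 10, 6, 6, 8),
    downstream_size=40,
    planted_feedback=12,
    n_pathways=6,
    pathway_size_range=(10, 60),
)


def small_spec(**over):
    return SyntheticSpec(**{**SMALL, **over})


class TestGeneratePpi:
    def test_deterministic_under_seed(self):
        rng1 = np.random.default_rng(42)
        rng2 = np.random.default_rng(42)
        spec = small_spec(rng_seed=42)
        assert generate_ppi(spec, rng1) == generate_ppi(spec, rng2)

    @pytest.mark.parametrize("rate,expected", [(0.0, 0), (1.0, 300)])
    def test_self_loop_rate_extremes(self, rate, expected):
        spec = small_spec(self_loop_rate=rate)
        records = generate_ppi(spec, np.random.default_rng(0))
        assert sum(1 for r in records if r.is_self) == expected

    def test_node_count_and_namespace(self):
        records = generate_ppi(small_spec(), np.random.default_rng(0))
        nodes = {n for r in records for n in r.pair}
        assert len(nodes) == 300
        assert all(n.startswith("SYN") for n in nodes)


class TestPlantSets:
    def test_venn_recovers_planted_regions_exactly(self):
        spec = small_spec()
        universe = [f"SYN{i:05d}" for i in range(300)]
        sets, knob, _ = plant_sets(spec, universe, np.random.default_rng(3))
        v = venn3(*(sets[n] for n in spec.set_names))
        assert tuple(v.region_counts[p] for p in REGIONS) == spec.region_counts

    def test_knob_inside_triple_intersection(self):
        spec = small_spec()
        universe = [f"SYN{i:05d}" for i in range(300)]
        sets, knob, regions = plant_sets(spec, universe, np.random.default_rng(3))
        assert knob.members <= set(regions["111"])
        for s in sets.values():
            assert knob.members <= s.members

    def test_all_mass_in_triple_region_gives_identical_sets(self):
        spec = small_spec(
            region_counts=(0, 0, 0, 0, 0, 0, 5), knob_size=5,
            downstream_size=10, planted_feedback=3,
        )
        universe = [f"SYN{i:05d}" for i in range(300)]
        sets, _, _ = plant_sets(spec, universe, np.random.default_rng(1))
        a, b, c = (sets[n] for n in spec.set_names)
        assert a.members == b.members == c.members

    def test_infeasible_region_counts_rejected(self):
        with pytest.raises(SyntheticSpecError):
            small_spec(region_counts=(500, 0, 0, 0, 0, 0, 8)).validate()


class TestPlantAnnotation:
    def test_planted_pathway_enriched_in_target(self):
        spec = small_spec(planted_odds={"PL": 8.0})
        universe = [f"SYN{i:05d}" for i in range(300)]
        target = ProteinSet("t", frozenset(universe[:60]))
        rng = np.random.default_rng(4)
        pathways, planted = plant_annotation(spec, universe, target, rng)
        assert planted == ["PL"]
        pl = next(p for p in pathways if p.pathway_id == "PL")
        in_rate = len(pl.members & target.members) / 60
        out_rate = len(pl.members - target.members) / 240
        assert in_rate > out_rate

    def test_odds_one_everywhere_is_null(self):
        spec = small_spec(planted_odds={})
        universe = [f"SYN{i:05d}" for i in range(300)]
        target = ProteinSet("t", frozenset(universe[:60]))
        pathways, planted = plant_annotation(
            spec, universe, target, np.random.default_rng(4)
        )
        assert planted == [] and len(pathways) == spec.n_pathways

    def test_pathway_spanning_universe_covers_target(self):
        spec = small_spec(planted_odds={}, n_pathways=1,
                          pathway_size_range=(300, 300))
        universe = [f"SYN{i:05d}" for i in range(300)]
        target = ProteinSet("t", frozenset(universe[:60]))
        (pw,), _ = plant_annotation(spec, universe, target, np.random.default_rng(0))
        assert len(pw.members & target.members) == 60


class TestPlantDownstream:
    def test_planted_overlap_exact(self):
        spec = small_spec()
        upstream = frozenset(f"SYN{i:05d}" for i in range(100))
        down, planted = plant_downstream(spec, upstream, np.random.default_rng(0))
        assert len(planted) == 12
        assert down.members & upstream == set(planted)
        assert len(down) == 40

    def test_zero_planted_disjoint(self):
        spec = small_spec(planted_feedback=0)
        upstream = frozenset(f"SYN{i:05d}" for i in range(100))
        down, planted = plant_downstream(spec, upstream, np.random.default_rng(0))
        assert planted == () and not (down.members & upstream)

    def test_fully_planted_subset(self):
        spec = small_spec(planted_feedback=40, downstream_size=40)
        upstream = frozenset(f"SYN{i:05d}" for i in range(100))
        down, planted = plant_downstream(spec, upstream, np.random.default_rng(0))
        assert down.members <= upstream and len(planted) == 40


class TestStudyRoundTrip:
    def test_byte_identical_outputs_under_fixed_seed(self, tmp_path):
        s1 = simulate_study(small_spec(rng_seed=9))
        s2 = simulate_study(small_spec(rng_seed=9))
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1 = write_study(s1, d1)
        p2 = write_study(s2, d2)
        for key in p1:
            assert filecmp.cmp(p1[key], p2[key], shallow=False), key

    def test_round_trips_through_io_layer(self, tmp_path):
        study = simulate_study(small_spec(rng_seed=2))
        paths = write_study(study, tmp_path)
        records, isolated = read_edges_and_isolated(paths["edges"], "tsv-pairs")
        net = InteractionNetwork.from_records("ppi", records, extra_nodes=isolated)
        assert net.nodes == {n for r in study.ppi for n in r.pair}
        assert net.edge_pairs() == sorted(r.pair for r in study.ppi)
        for name, pset in study.seed_sets.items():
            back = read_protein_set(paths[f"set_{name}"], name)
            assert back.members == pset.members
        gmt = read_gmt(paths["gmt"])
        assert {p.pathway_id: p.members for p in gmt} == {
            p.pathway_id: p.members for p in study.pathways
        }
        down = read_protein_set(paths["downstream"], "DG")
        assert down.members == study.downstream.members
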