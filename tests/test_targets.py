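"""Target integration rule, seed scanning, network export, enrichment."""

import math

import numpy as np
import pandas as pd
import pytest

from mirmeta._util import revcomp_rna
from mirmeta.simulate import SimulationConfig, gen_prediction_tables
from mirmeta.targets import (
    IntegrationParams,
    TargetEdge,
    enrich,
    export_network,
    integrate_targets,
    read_network,
    seed_sites,
)

MIR = "UGAGGUAGUAGGUUGUAUAGUU"
SITE = revcomp_rna(MIR[1:8])


def _table(pairs, energy=False):
    rows = [
        {"mirna": m, "gene": g, "score": 50.0, "energy": -12.5 if energy else None}
        for m, g in pairs
    ]
    return pd.DataFrame(rows, columns=["mirna", "gene", "score", "energy"])


PROFILES_M = {"mir1": np.array([1.0, 2.0, 4.0])}


class TestSeedSites:
    def test_constructed_site_found(self):
        utr = "AAAA" + SITE + "CCCC"
        sites = seed_sites(MIR, utr, gene="g")
        assert len(sites) == 1
        assert sites[0].start == 4
        assert sites[0].matched == SITE

    def test_two_sites_ascending(self):
        utr = SITE + "AAAA" + SITE
        sites = seed_sites(MIR, utr)
        assert [s.start for s in sites] == [0, len(SITE) + 4]

    def test_agrees_with_brute_force_scan(self):
        rng = np.random.default_rng(5)
        utr = "".join(rng.choice(list("ACGU"), size=2000))
        got = {s.start for s in seed_sites(MIR, utr)}
        target = revcomp_rna(MIR[1:8])
        expected = {
            i
            for i in range(len(utr) - 6)
            if utr[i : i + 7] == target
        }
        assert got == expected

    def test_utr_too_short(self):
        with pytest.raises(ValueError):
            seed_sites(MIR, "ACGU")

    def test_non_nucleotide_rejected(self):
        with pytest.raises(ValueError):
            seed_sites(MIR, "ACGTXACGT")

    def test_wobble_widens_matches(self):
        # replace an A (pairing seed U) with G: G:U wobble accepted only
        # when enabled
        pos = SITE.find("A")
        utr = "CC" + SITE[:pos] + "G" + SITE[pos + 1 :] + "CC"
        assert seed_sites(MIR, utr) == []
        assert len(seed_sites(MIR, utr, wobble=True)) == 1


class TestIntegrationRule:
    def test_overlap_kept_despite_positive_r(self):
        ta = _table([("mir1", "g1")])
        tb = _table([("mir1", "g1")])
        gp = {"g1": np.array([2.0, 4.0, 8.0])}  # r = +1 with mir1
        edges = integrate_targets(ta, tb, PROFILES_M, gp)
        assert len(edges) == 1 and edges[0].evidence == "overlap"

    def test_a_only_anticorrelated_kept(self):
        ta = _table([("mir1", "g1")])
        tb = _table([])
        gp = {"g1": np.array([4.0, 2.0, 1.0])}
        edges = integrate_targets(ta, tb, PROFILES_M, gp)
        assert len(edges) == 1
        assert edges[0].evidence == "anti_correlation"
        assert edges[0].correlation < 0

    def test_b_only_anticorrelated_dropped(self):
        ta = _table([])
        tb = _table([("mir1", "g1")])
        gp = {"g1": np.array([4.0, 2.0, 1.0])}
        assert integrate_targets(ta, tb, PROFILES_M, gp) == []

    def test_symmetric_flag_admits_b_only(self):
        ta = _table([])
        tb = _table([("mir1", "g1")])
        gp = {"g1": np.array([4.0, 2.0, 1.0])}
        edges = integrate_targets(
            ta, tb, PROFILES_M, gp, IntegrationParams(symmetric=True)
        )
        assert len(edges) == 1

    def test_a_only_positive_dropped(self):
        ta = _table([("mir1", "g1")])
        tb = _table([])
        gp = {"g1": np.array([2.0, 4.0, 8.0])}
        assert integrate_targets(ta, tb, PROFILES_M, gp) == []

    def test_energy_passthrough_from_a(self):
        ta = _table([("mir1", "g1")], energy=True)
        tb = _table([("mir1", "g1")])
        gp = {"g1": np.array([2.0, 4.0, 8.0])}
        edges = integrate_targets(ta, tb, PROFILES_M, gp)
        assert edges[0].energy == -12.5

    def test_short_profiles_disable_correlation(self):
        ta = _table([("mir1", "g1")])
        tb = _table([])
        with pytest.warns(UserWarning, match="disabled"):
            edges = integrate_targets(
                ta, tb, {"mir1": np.array([1.0, 2.0])}, {"g1": np.array([2.0, 1.0])}
            )
        assert edges == []

    def test_planted_four_class_truth(self):
        cfg = SimulationConfig(seed=11)
        ta, tb, mdf, gdf, truth = gen_prediction_tables(cfg)
        edges = integrate_targets(ta, tb, mdf, gdf)
        assert {(e.mirna, e.gene) for e in edges} == truth.kept_pairs
        by_class = {
            truth.target_pairs[(e.mirna, e.gene)] for e in edges
        }
        assert "b_only" not in by_class and "a_only_pos" not in by_class

    def test_intersection_always_kept_and_monotonicity(self):
        rng = np.random.default_rng(13)
        mirnas = [f"m{i}" for i in range(4)]
        genes = [f"g{i}" for i in range(12)]
        mp = {m: rng.uniform(1, 9, 3) for m in mirnas}
        gp = {g: rng.uniform(1, 9, 3) for g in genes}
        pa = [(m, g) for m in mirnas for g in genes if rng.random() < 0.4]
        pb = [(m, g) for m in mirnas for g in genes if rng.random() < 0.4]
        ta, tb = _table(pa), _table(pb)
        strict = integrate_targets(ta, tb, mp, gp, IntegrationParams(max_r=0.0))
        relaxed = integrate_targets(ta, tb, mp, gp, IntegrationParams(max_r=0.5))
        kept_strict = {(e.mirna, e.gene) for e in strict}
        kept_relaxed = {(e.mirna, e.gene) for e in relaxed}
        assert set(pa) & set(pb) <= kept_strict
        assert kept_strict <= kept_relaxed


class TestExportNetwork:
    def test_empty_header_only(self, tmp_path):
        path = tmp_path / "net.tsv"
        export_network([], path)
        assert path.read_text() == "mirna\tgene\tevidence\tcorrelation\tenergy\n"

    def test_sorted_rows(self, tmp_path):
        edges = [
            TargetEdge("m2", "g1", "overlap"),
            TargetEdge("m1", "g2", "overlap"),
            TargetEdge("m1", "g1", "both", correlation=-0.5, energy=-3.0),
        ]
        path = tmp_path / "net.tsv"
        export_network(edges, path)
        lines = path.read_text().splitlines()[1:]
        assert [ln.split("\t")[:2] for ln in lines] == [
            ["m1", "g1"],
            ["m1", "g2"],
            ["m2", "g1"],
        ]

    def test_round_trip(self, tmp_path):
        edges = sorted(
            [
                TargetEdge("m1", "g1", "both", correlation=-0.25, energy=-3.5),
                TargetEdge("m2", "g2", "overlap"),
            ],
            key=lambda e: (e.mirna, e.gene),
        )
        path = tmp_path / "net.tsv"
        export_network(edges, path)
        assert read_network(path) == edges


class TestEnrich:
    UNIVERSE = {f"g{i}" for i in range(100)}

    def test_whole_universe_set(self):
        genes = {f"g{i}" for i in range(5)}
        table = enrich(genes, {"all": set(self.UNIVERSE)}, self.UNIVERSE)
        assert table.loc[0, "p_value"] == pytest.approx(1.0)

    def test_closed_form_five_of_five(self):
        genes = {f"g{i}" for i in range(5)}
        sets = {"s": {f"g{i}" for i in range(10)}}
        table = enrich(genes, sets, self.UNIVERSE)
        expected = math.comb(10, 5) / math.comb(100, 5)
        assert table.loc[0, "p_value"] == pytest.approx(expected, rel=1e-9)

    def test_disjoint_set(self):
        genes = {f"g{i}" for i in range(5)}
        sets = {"s": {f"g{i}" for i in range(90, 95)}}
        table = enrich(genes, sets, self.UNIVERSE)
        assert table.loc[0, "overlap"] == 0
        assert table.loc[0, "p_value"] == 1.0

    def test_empty_universe(self):
        with pytest.raises(ValueError):
            enrich(set(), {"s": {"g"}}, set())

    def test_matches_monte_carlo(self):
        """Hypergeometric tail within 3 SE of resampling frequency."""
        rng = np.random.default_rng(17)
        universe = [f"g{i}" for i in range(40)]
        gene_set = set(universe[:12])
        genes = set(universe[5:13])  # 8 drawn, overlap with set = 7
        k_obs = len(genes & gene_set)
        n_draw = len(genes)
        n_sim = 100_000
        draws = np.array(
            [
                len(set(rng.choice(universe, size=n_draw, replace=False)) & gene_set)
                for _ in range(n_sim)
            ]
        )
        mc_p = np.mean(draws >= k_obs)
        table = enrich(genes, {"s": gene_set}, set(universe))
        se = math.sqrt(mc_p * (1 - mc_p) / n_sim)
        assert abs(table.loc[0, "p_value"] - mc_p) <= 3 * se
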