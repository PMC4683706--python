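import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from codonscan.alignment import CodonAlignment
from codonscan.codon_model import FitOptions, FittedModel, CodonFrequencies, ModelSpec
from codonscan.go_selection import (
    ScanHit,
    bh_fdr,
    branch_lrt_scan,
    collect_go_terms,
    fisher_enrichment,
    go_log_ratios,
    overlap,
    propagate_go,
    quadrant_percent,
)
from codonscan.io_formats import parse_newick
from codonscan.synthetic_data import DEFAULT_OMEGAS, DEFAULT_TREE_NEWICK, simulate_alignment


class TestPropagate:
    def test_single_edge(self):
        out = propagate_go({"g": {"GO:0000002"}}, {"GO:0000002": {"GO:0000001"}})
        assert out == {"g": {"GO:0000001", "GO:0000002"}}

    def test_empty_dag_unchanged(self):
        annot = {"g": {"GO:0000002"}, "h": set()}
        assert propagate_go(annot, {}) == annot

    def test_three_level_chain(self):
        dag = {"GO:0000003": {"GO:0000002"}, "GO:0000002": {"GO:0000001"}}
        out = propagate_go({"g": {"GO:0000003"}}, dag)
        assert out["g"] == {"GO:0000001", "GO:0000002", "GO:0000003"}

    def test_cycle_detected(self):
        dag = {"GO:0000001": {"GO:0000002"}, "GO:0000002": {"GO:0000001"}}
        with pytest.raises(ValueError, match="cycle"):
            propagate_go({}, dag)


def tiny_aln(n_codons, taxa=("a", "b")):
    return CodonAlignment({t: "ATG" * n_codons for t in taxa})


class TestCollectTerms:
    def test_threshold_and_concat_length(self):
        alns = {f"g{i}": tiny_aln(50) for i in range(12)}
        annot = {f"g{i}": {"GO:0000001"} for i in range(10)}
        annot.update({f"g{i}": {"GO:0000002"} for i in range(10, 12)})
        # term 2 has 9 genes only
        annot["g0"].add("GO:0000002")
        for i in range(1, 8):
            annot[f"g{i}"].add("GO:0000002")
        units = collect_go_terms(annot, alns, min_genes=10)
        assert [u.go_id for u in units] == ["GO:0000001", "GO:0000002"]
        by_id = {u.go_id: u for u in units}
        assert by_id["GO:0000001"].alignment.n_codons == 500
        assert by_id["GO:0000002"].alignment.n_codons == 500

    def test_nine_genes_excluded(self):
        alns = {f"g{i}": tiny_aln(50) for i in range(9)}
        annot = {f"g{i}": {"GO:0000001"} for i in range(9)}
        assert collect_go_terms(annot, alns, min_genes=10) == []

    def test_counting_oracle(self, rng):
        """Qualifying terms match a hand count over a random annotation."""
        genes = [f"g{i}" for i in range(30)]
        terms = [f"GO:{i + 1:07d}" for i in range(6)]
        annot = {
            g: {t for t in terms if rng.random() < 0.3} for g in genes
        }
        alns = {g: tiny_aln(10) for g in genes}
        expected = sorted(
            t for t in terms if sum(t in annot[g] for g in genes) >= 5
        )
        units = collect_go_terms(annot, alns, min_genes=5)
        assert [u.go_id for u in units] == expected
        for u in units:
            assert u.genes == sorted(u.genes)


def fit_stub(omegas):
    return FittedModel(
        spec=ModelSpec("free_ratio"), kappa=2.0,
        branch_lengths={b: 0.1 for b in omegas}, omegas=omegas,
        site_params=None, lnL=0.0, n_free_params=0, converged=True,
        n_restarts_used=1, freqs=CodonFrequencies.uniform(),
    )


class TestLogRatios:
    BRANCHES = ("BMR", "mouse", "NMR", "guinea_pig")

    def test_hand_assigned_quadrants(self):
        fits = {
            "GO:0000001": fit_stub({"BMR": 0.2, "mouse": 0.1, "NMR": 0.3, "guinea_pig": 0.1}),
            "GO:0000002": fit_stub({"BMR": 0.2, "mouse": 0.1, "NMR": 0.1, "guinea_pig": 0.3}),
            "GO:0000003": fit_stub({"BMR": 0.1, "mouse": 0.2, "NMR": 0.3, "guinea_pig": 0.1}),
            "GO:0000004": fit_stub({"BMR": 0.1, "mouse": 0.2, "NMR": 0.1, "guinea_pig": 0.3}),
            "GO:0000005": fit_stub({"BMR": 0.2, "mouse": 0.2, "NMR": 0.3, "guinea_pig": 0.1}),
            "GO:0000006": fit_stub({"BMR": 0.4, "mouse": 0.1, "NMR": 0.5, "guinea_pig": 0.1}),
        }
        records, counts, percent = go_log_ratios(fits)
        assert counts == {"++": 2, "+-": 1, "-+": 1, "--": 1, "zero": 1}
        byid = dict(zip(records["go_id"], records["quadrant"]))
        assert byid["GO:0000001"] == "++"
        assert byid["GO:0000005"] == "zero"
        assert percent == quadrant_percent(2, 6) == 33

    def test_quadrant_counts_partition(self, rng):
        fits = {
            f"GO:{i:07d}": fit_stub(
                {b: float(rng.uniform(0.05, 0.5)) for b in self.BRANCHES}
            )
            for i in range(1, 40)
        }
        records, counts, _ = go_log_ratios(fits)
        nonzero = (records["quadrant"] != "zero").sum()
        assert sum(counts[q] for q in ("++", "+-", "-+", "--")) == nonzero

    def test_quadrant_percentage_rounding(self):
        assert quadrant_percent(731, 1307) == 56

    def test_omega_floor_keeps_ratios_finite(self):
        fits = {"GO:0000001": fit_stub(
            {"BMR": 0.0, "mouse": 0.2, "NMR": 0.3, "guinea_pig": 0.1})}
        records, _, _ = go_log_ratios(fits)
        assert np.isfinite(records["log_ratio_1"]).all()


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.031]).tolist() == [0.031]

    def test_hand_stepup(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]).tolist() == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_against_brute_force_stepup(self, rng):
        """Independent step-up implementation on random vectors."""

        def oracle(p):
            p = np.asarray(p)
            n = len(p)
            order = np.argsort(p)
            adj = np.empty(n)
            prev = 1.0
            for rank_from_top, idx in enumerate(order[::-1]):
                k = n - rank_from_top  # 1-based rank of this p
                prev = min(prev, p[idx] * n / k)
                adj[idx] = prev
            return adj

        for _ in range(20):
            p = rng.uniform(size=int(rng.integers(1, 50)))
            assert bh_fdr(p) == pytest.approx(oracle(p))

    def test_sorted_input_monotone(self, rng):
        p = np.sort(rng.uniform(size=30))
        adj = bh_fdr(p)
        assert (np.diff(adj) >= -1e-15).all()

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestOverlap:
    @staticmethod
    def hit(uid):
        return ScanHit(uid, frozenset(), 0, 0, 0, 0, 0, 0, 0, "higher")

    def test_overlap_cases(self):
        a = [self.hit("g1"), self.hit("g2")]
        b = [self.hit("g2"), self.hit("g3")]
        assert overlap(a, b) == {"g2"}
        assert overlap(a, []) == set()
        assert overlap(a, a) == {"g1", "g2"}


class TestFisher:
    def test_study_equals_background(self):
        genes = {f"g{i}" for i in range(10)}
        annot = {g: {"GO:0000001"} for g in genes}
        table = fisher_enrichment(genes, genes, annot)
        assert (table["p"] == 1.0).all()

    def test_hypergeometric_oracle(self):
        """8 of 10 study genes vs 10 of 90 others carry the term; p equals
        the hypergeometric upper tail computed by explicit summation."""
        study = {f"s{i}" for i in range(10)}
        rest = {f"r{i}" for i in range(90)}
        annot = {f"s{i}": {"GO:0000001"} for i in range(8)}
        annot.update({f"r{i}": {"GO:0000001"} for i in range(10)})
        table = fisher_enrichment(study, study | rest, annot)
        # N=100, K=18 with term, n=10 drawn (study), observed 8
        expected = sum(hypergeom.pmf(k, 100, 18, 10) for k in range(8, 11))
        assert table.loc[0, "p"] == pytest.approx(expected, rel=1e-10)

    def test_term_absent_from_study(self):
        study = {"s1"}
        bg = {"s1", "r1", "r2"}
        annot = {"r1": {"GO:0000009"}, "s1": set(), "r2": set()}
        table = fisher_enrichment(study, bg, annot)
        assert table.loc[0, "p"] == 1.0

    def test_empty_study_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment(set(), {"g"}, {})


class TestBranchSiteScan:
    def test_positive_selection_detected(self):
        """A gene with 10% of sites at omega2 = 6 on the BMR branch (800
        codons) is flagged by the branch-site scan; alpha = 0 silences it."""
        tree = parse_newick(DEFAULT_TREE_NEWICK)
        aln, _ = simulate_alignment(
            tree, 2.5, DEFAULT_OMEGAS, CodonFrequencies.uniform(), 800,
            seed=100, foreground_omega2=6.0, foreground=("BMR",),
            site_fraction=0.1,
        )
        from codonscan.go_selection import branch_site_scan

        hits, table = branch_site_scan(
            [("g1", aln)], tree, frozenset({"BMR"}), alpha=0.05,
            options=FitOptions(n_restarts=1),
        )
        assert len(hits) == 1
        assert hits[0].omega_fore > 1.0  # fitted omega2
        assert table.loc[0, "p_selected"] == pytest.approx(0.1, abs=0.08)
        # at alpha = 0 the same scan table yields no hits
        assert not (table["p_adj"] < 0.0).any()


class TestBranchScan:
    def test_empty_unit_list(self):
        tree = parse_newick(DEFAULT_TREE_NEWICK)
        hits, table = branch_lrt_scan([], tree, frozenset({"BMR"}))
        assert hits == [] and len(table) == 0

    def test_strong_constraint_detected_with_direction(self):
        """A unit with foreground omega 0.05 vs background 0.3 over 2000
        codons is flagged by the 'lower' scan."""
        tree = parse_newick(DEFAULT_TREE_NEWICK)
        omegas = {b: 0.3 for b in DEFAULT_OMEGAS}
        omegas["BMR"] = 0.05
        omegas["NMR"] = 0.05
        aln, _ = simulate_alignment(
            tree, 2.5, omegas, CodonFrequencies.uniform(), 2000, seed=5
        )
        fg = frozenset({"BMR", "NMR"})
        hits, table = branch_lrt_scan(
            [("u1", aln)], tree, fg, direction="lower", alpha=0.01,
            options=FitOptions(n_restarts=1),
        )
        assert len(hits) == 1
        assert hits[0].omega_fore < hits[0].omega_back
        # and the opposite direction must not fire on the same data
        hits_hi, _ = branch_lrt_scan(
            [("u1", aln)], tree, fg, direction="higher", alpha=0.01,
            options=FitOptions(n_restarts=1),
        )
        assert hits_hi == []
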