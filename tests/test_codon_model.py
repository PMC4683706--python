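import itertools

import numpy as np
import pytest
from scipy import stats
from scipy.linalg import expm

from codonscan.alignment import AlignmentError, CodonAlignment
from codonscan.codon_model import (
    STANDARD_CODE,
    CodonFrequencies,
    FitOptions,
    LikelihoodEngine,
    ModelSpec,
    branch_measures,
    build_rate_matrix,
    fit_model,
    log_likelihood,
    lrt,
    rate_coefficients,
    transition_matrix,
)
from codonscan.io_formats import parse_newick
from codonscan.synthetic_data import simulate_alignment


def brute_force_loglik(aln, branch_ids_lengths, kappa, omega, freqs):
    """Independent oracle: marginalize the root state explicitly on a star
    tree (the unrooted form of any 3-taxon tree)."""
    code = STANDARD_CODE
    Ps = {
        taxon: transition_matrix(build_rate_matrix(kappa, omega, freqs), t)
        for taxon, t in branch_ids_lengths.items()
    }
    total = 0.0
    for site in range(aln.n_codons):
        site_l = 0.0
        for root in range(61):
            term = freqs.pi[root]
            for taxon in aln.taxa:
                s = code.codon_index[aln.codon(taxon, site)]
                term *= Ps[taxon][root, s]
            site_l += term
        total += np.log(site_l)
    return total


class TestRateMatrix:
    @pytest.mark.parametrize("kappa,omega", [(1.0, 1.0), (2.0, 0.5), (5.0, 3.0)])
    def test_structural_invariants(self, kappa, omega, uniform_freqs):
        Q = build_rate_matrix(kappa, omega, uniform_freqs)
        assert np.abs(Q.Q.sum(axis=1)).max() < 1e-10
        assert -(uniform_freqs.pi * np.diag(Q.Q)).sum() == pytest.approx(1.0, abs=1e-10)
        # detailed balance
        F = uniform_freqs.pi[:, None] * Q.Q
        assert np.abs(F - F.T).max() < 1e-10

    def test_multistep_rates_zero(self, uniform_freqs, code):
        Q = build_rate_matrix(2.0, 0.5, uniform_freqs)
        for i, ci in enumerate(code.sense_codons):
            for j, cj in enumerate(code.sense_codons):
                ndiff = sum(a != b for a, b in zip(ci, cj))
                if ndiff > 1:
                    assert Q.Q[i, j] == 0.0

    def test_transition_vs_transversion_ratio(self, uniform_freqs, code):
        """ATT->ATC (synonymous transition) is kappa times faster than
        ATT->ATA (synonymous transversion); classification built here by
        brute force over the code table."""
        assert code.codon_to_aa["ATT"] == code.codon_to_aa["ATC"] == "I"
        assert code.codon_to_aa["ATA"] == "I"
        Q = build_rate_matrix(2.0, 0.5, uniform_freqs)
        i = code.codon_index["ATT"]
        ratio = Q.Q[i, code.codon_index["ATC"]] / Q.Q[i, code.codon_index["ATA"]]
        assert ratio == pytest.approx(2.0)

    def test_parameter_collapse_kappa1_omega1(self, uniform_freqs, code):
        Q = build_rate_matrix(1.0, 1.0, uniform_freqs)
        off = Q.Q[code.single_step]
        assert np.allclose(off, off[0])

    def test_invalid_parameters(self, uniform_freqs):
        with pytest.raises(ValueError):
            build_rate_matrix(-1.0, 0.5, uniform_freqs)
        with pytest.raises(ValueError):
            build_rate_matrix(2.0, np.nan, uniform_freqs)


class TestTransitionMatrix:
    def test_t_zero_identity(self, uniform_freqs):
        Q = build_rate_matrix(2.0, 0.3, uniform_freqs)
        assert np.abs(transition_matrix(Q, 0.0) - np.eye(61)).max() < 1e-12

    def test_ergodic_limit(self):
        rng = np.random.default_rng(5)
        pi = rng.dirichlet(np.full(61, 5.0))
        freqs = CodonFrequencies(pi=pi, source="F61")
        Q = build_rate_matrix(2.0, 0.3, freqs)
        P = transition_matrix(Q, 1e6)
        assert np.abs(P - freqs.pi[None, :]).max() < 1e-8

    def test_rows_sum_to_one(self, uniform_freqs):
        Q = build_rate_matrix(3.0, 0.1, uniform_freqs)
        for t in (0.01, 0.5, 4.0):
            P = transition_matrix(Q, t)
            assert np.abs(P.sum(axis=1) - 1).max() < 1e-10
            assert P.min() >= 0.0

    def test_matches_scipy_expm(self, uniform_freqs):
        Q = build_rate_matrix(2.0, 0.5, uniform_freqs)
        for t in (0.01, 0.3):
            assert np.abs(
                transition_matrix(Q, t) - expm(Q.Q * t)
            ).max() < 1e-10


class TestLikelihood:
    def test_identical_onecodon_t0(self, uniform_freqs, code):
        tree = parse_newick("(A:0,B:0);")
        aln = CodonAlignment({"A": "ATG", "B": "ATG"})
        lnl = log_likelihood(aln, tree, kappa=2.0, omegas=0.5, freqs=uniform_freqs)
        assert lnl == pytest.approx(np.log(uniform_freqs.pi[code.codon_index["ATG"]]))

    @pytest.mark.parametrize(
        "newick,lengths",
        [
            ("(A:0.2,B:0.3,C:0.1);", {"A": 0.2, "B": 0.3, "C": 0.1}),
            # rooted: root branches merge (C absorbs 0.15) when unrooted
            ("((A:0.2,B:0.3):0.15,C:0.1);", {"A": 0.2, "B": 0.3, "C": 0.25}),
        ],
    )
    def test_pruning_equals_brute_force(self, newick, lengths, uniform_freqs):
        tree = parse_newick(newick)
        aln = CodonAlignment({"A": "ATGAAA", "B": "ATGAAG", "C": "ACGAAA"})
        lnl = log_likelihood(aln, tree, kappa=2.0, omegas=0.4, freqs=uniform_freqs)
        oracle = brute_force_loglik(aln, lengths, 2.0, 0.4, uniform_freqs)
        assert abs(lnl - oracle) / abs(oracle) < 1e-10

    def test_column_duplication_doubles_lnl(self, uniform_freqs):
        tree = parse_newick("(A:0.2,B:0.3,C:0.1);")
        aln = CodonAlignment({"A": "ATGAAA", "B": "ATGAAG", "C": "ACGAAA"})
        aln2 = CodonAlignment({k: v + v for k, v in aln.seqs.items()})
        l1 = log_likelihood(aln, tree, kappa=2.0, omegas=0.4, freqs=uniform_freqs)
        l2 = log_likelihood(aln2, tree, kappa=2.0, omegas=0.4, freqs=uniform_freqs)
        assert l2 == pytest.approx(2 * l1, rel=1e-12)

    def test_stop_codon_rejected(self):
        with pytest.raises(AlignmentError, match="stop"):
            CodonAlignment({"A": "ATGTAA", "B": "ATGAAA"})

    def test_gap_codon_is_ambiguous(self, uniform_freqs):
        """A fully gapped taxon contributes nothing: lnL equals the
        likelihood of the other taxa alone."""
        tree = parse_newick("(A:0.2,B:0.3,C:0.1);")
        aln = CodonAlignment({"A": "ATG", "B": "ACG", "C": "---"})
        two = CodonAlignment({"A": "ATG", "B": "ACG"})
        l3 = log_likelihood(aln, tree, kappa=2.0, omegas=0.4, freqs=uniform_freqs)
        # A-B path length is 0.5 regardless of where C attaches
        l2 = log_likelihood(
            two, parse_newick("(A:0.2,B:0.3);"), kappa=2.0, omegas=0.4,
            freqs=uniform_freqs,
        )
        assert l3 == pytest.approx(l2, rel=1e-10)


class TestFitting:
    def test_one_ratio_recovery(self, rodent_tree, uniform_freqs):
        """Data simulated under omega=0.2 recovers omega in [0.15, 0.26]."""
        aln, _ = simulate_alignment(rodent_tree, 2.0, 0.2, uniform_freqs, 500, seed=7)
        fit = fit_model(aln, rodent_tree, ModelSpec("one_ratio"),
                        FitOptions(n_restarts=1))
        omega = next(iter(fit.omegas.values()))
        assert 0.15 <= omega <= 0.26
        assert fit.converged

    def test_nesting_order(self, small_gene, rodent_tree):
        aln, _ = small_gene
        opts = FitOptions(n_restarts=1)
        engine = LikelihoodEngine(aln, rodent_tree)
        f1 = fit_model(aln, rodent_tree, ModelSpec("one_ratio"), opts, engine=engine)
        f2 = fit_model(aln, rodent_tree, ModelSpec("two_ratio", frozenset({"BMR"})),
                       opts, init=f1, engine=engine)
        ff = fit_model(aln, rodent_tree, ModelSpec("free_ratio"), opts, init=f1,
                       engine=engine)
        assert f2.lnL >= f1.lnL - 1e-6
        assert ff.lnL >= f2.lnL - 1e-6

    def test_profile_matches_grid_search(self, small_gene, rodent_tree):
        """Refitting one omega with everything else fixed lands within one
        grid step of an exhaustive 1-D search."""
        aln, _ = small_gene
        engine = LikelihoodEngine(aln, rodent_tree)
        fit = fit_model(aln, rodent_tree, ModelSpec("one_ratio"),
                        FitOptions(n_restarts=1), engine=engine)
        ts = np.array([fit.branch_lengths[b] for b in engine.branch_ids])
        grid = np.arange(0.02, 0.6, 1e-3)
        lnls = [
            engine.lnl_branch(fit.kappa, ts, np.full(len(ts), w)) for w in grid
        ]
        w_grid = grid[int(np.argmax(lnls))]
        w_fit = next(iter(fit.omegas.values()))
        assert abs(w_fit - w_grid) <= 1e-3

    def test_model_spec_validation(self):
        with pytest.raises(ValueError, match="foreground"):
            ModelSpec("two_ratio")
        with pytest.raises(ValueError, match="foreground"):
            ModelSpec("one_ratio", frozenset({"BMR"}))
        with pytest.raises(ValueError, match="unknown"):
            ModelSpec("site_model_M8")


class TestBranchMeasures:
    def test_dnds_equals_omega_random_draws(self, rodent_tree, uniform_freqs):
        """Algebraic identity dN/dS = omega, checked over 100 random
        parameter draws without any fitting."""
        rng = np.random.default_rng(11)
        from codonscan.codon_model import FittedModel

        branch_ids = ["BMR", "mouse"]
        worst = 0.0
        for _ in range(100):
            kappa = rng.uniform(0.5, 10)
            pi = rng.dirichlet(np.full(61, 2.0))
            freqs = CodonFrequencies(pi=pi, source="F61")
            omegas = {b: rng.uniform(0.05, 5.0) for b in branch_ids}
            ts = {b: rng.uniform(0.01, 1.0) for b in branch_ids}
            fit = FittedModel(
                spec=ModelSpec("free_ratio"), kappa=kappa, branch_lengths=ts,
                omegas=omegas, site_params=None, lnL=0.0, n_free_params=0,
                converged=True, n_restarts_used=1, freqs=freqs,
            )
            for m in branch_measures(fit, 100).values():
                worst = max(worst, abs(m.dN / m.dS - m.omega))
        assert worst < 1e-8

    def test_neutral_flux_partition(self, uniform_freqs):
        """At omega=1 the per-site rates coincide: dN = dS = t/3."""
        from codonscan.codon_model import FittedModel

        fit = FittedModel(
            spec=ModelSpec("free_ratio"), kappa=2.0,
            branch_lengths={"A": 0.3, "B": 0.0}, omegas={"A": 1.0, "B": 1.0},
            site_params=None, lnL=0.0, n_free_params=0, converged=True,
            n_restarts_used=1, freqs=uniform_freqs,
        )
        ms = branch_measures(fit, 50)
        assert ms["A"].dN == pytest.approx(0.1)
        assert ms["A"].dS == pytest.approx(0.1)
        assert ms["B"].dN == ms["B"].dS == 0.0
        assert ms["A"].N + ms["A"].S == pytest.approx(150)

    def test_requires_free_ratio(self, small_gene, rodent_tree):
        aln, _ = small_gene
        fit = fit_model(aln, rodent_tree, ModelSpec("one_ratio"),
                        FitOptions(n_restarts=1))
        with pytest.raises(ValueError, match="free-ratio"):
            branch_measures(fit, aln.n_codons)


class TestLRT:
    def test_chi2_oracle(self, uniform_freqs):
        """stat = 3.8415 at df 1 sits at the 5% point of the chi-square."""
        from codonscan.codon_model import FittedModel

        def stub(lnl, n_par):
            return FittedModel(
                spec=ModelSpec("one_ratio"), kappa=2.0, branch_lengths={},
                omegas={}, site_params=None, lnL=lnl, n_free_params=n_par,
                converged=True, n_restarts_used=1, freqs=uniform_freqs,
            )

        res = lrt(stub(-100.0, 3), stub(-100.0 + 3.8415 / 2, 4))
        assert res.df == 1
        assert res.stat == pytest.approx(3.8415)
        assert res.p == pytest.approx(0.05, abs=1e-4)

    def test_equal_likelihoods(self, small_gene, rodent_tree):
        aln, _ = small_gene
        fit = fit_model(aln, rodent_tree, ModelSpec("one_ratio"),
                        FitOptions(n_restarts=1))
        res = lrt(fit, fit, df=1)
        assert res.stat == 0.0
        assert res.p == 1.0

    def test_negative_noise_clamped(self, small_gene, rodent_tree):
        aln, _ = small_gene
        fit = fit_model(aln, rodent_tree, ModelSpec("one_ratio"),
                        FitOptions(n_restarts=1))
        import copy

        worse = copy.deepcopy(fit)
        worse.lnL += 1e-8  # "alternative" loses by numerical noise
        res = lrt(fit, worse, df=1)
        assert res.stat >= 0.0

    def test_df_inferred_from_param_counts(self, small_gene, rodent_tree):
        aln, _ = small_gene
        opts = FitOptions(n_restarts=1)
        f1 = fit_model(aln, rodent_tree, ModelSpec("one_ratio"), opts)
        ff = fit_model(aln, rodent_tree, ModelSpec("free_ratio"), opts, init=f1)
        res = lrt(f1, ff)
        assert res.df == len(f1.branch_lengths) - 1
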