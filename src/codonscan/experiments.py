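"""Calibration experiments: simulation-based checks of the estimator and
the scans, with known ground truth.

These are the package's own validation suite — parameter recovery for
the free-ratio model, type-I error of the LRTs under null simulations,
sensitivity/FDR of the gene scan, and the paired lineage comparisons on
a background-only synthetic study. Each function is deterministic given
its seed and returns plain numbers, so the same code backs both the test
suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .alignment import CodonAlignment
from .codon_model import (
    CodonFrequencies,
    FitOptions,
    LikelihoodEngine,
    ModelSpec,
    branch_measures,
    build_rate_matrix,
    fit_model,
    log_likelihood,
    lrt,
    transition_matrix,
)
from .evo_rates import filter_by_ds, paired_rank_test, rate_table
from .go_selection import bh_fdr
from .io_formats import parse_newick
from .synthetic_data import (
    DEFAULT_OMEGAS,
    DEFAULT_TREE_NEWICK,
    SimConfig,
    simulate_alignment,
    simulate_study,
)

_FAST = FitOptions(n_restarts=1)


def pruning_oracle_error(seed: int = 1, n_cases: int = 5) -> float:
    """Max relative |pruning - brute force| over random 3-taxon, 2-codon
    instances; the oracle marginalizes the root state explicitly."""
    rng = np.random.default_rng(seed)
    freqs = CodonFrequencies.uniform()
    from .codon_model import STANDARD_CODE as code

    worst = 0.0
    for _ in range(n_cases):
        lengths = {t: float(rng.uniform(0.05, 0.6)) for t in "ABC"}
        kappa = float(rng.uniform(1.0, 4.0))
        omega = float(rng.uniform(0.1, 2.0))
        tree = parse_newick(
            f"(A:{lengths['A']},B:{lengths['B']},C:{lengths['C']});"
        )
        codons = rng.choice(code.sense_codons, size=(3, 2))
        aln = CodonAlignment(
            {t: "".join(codons[i]) for i, t in enumerate("ABC")}
        )
        lnl = log_likelihood(aln, tree, kappa=kappa, omegas=omega, freqs=freqs)
        Ps = {
            t: transition_matrix(build_rate_matrix(kappa, omega, freqs), L)
            for t, L in lengths.items()
        }
        oracle = 0.0
        for site in range(2):
            site_l = 0.0
            for root in range(61):
                term = freqs.pi[root]
                for i, t in enumerate("ABC"):
                    term *= Ps[t][root, code.codon_index[codons[i][site]]]
                site_l += term
            oracle += np.log(site_l)
        worst = max(worst, abs(lnl - oracle) / abs(oracle))
    return worst


def dnds_identity_error(seed: int = 1, n_draws: int = 100) -> float:
    """Max |dN/dS - omega| over random (kappa, omega, pi) draws."""
    from .codon_model import FittedModel

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_draws):
        freqs = CodonFrequencies(pi=rng.dirichlet(np.full(61, 2.0)), source="F61")
        fit = FittedModel(
            spec=ModelSpec("free_ratio"), kappa=float(rng.uniform(0.5, 10)),
            branch_lengths={"x": float(rng.uniform(0.01, 1.0))},
            omegas={"x": float(rng.uniform(0.05, 5.0))}, site_params=None,
            lnL=0.0, n_free_params=0, converged=True, n_restarts_used=1,
            freqs=freqs,
        )
        m = next(iter(branch_measures(fit, 100).values()))
        worst = max(worst, abs(m.dN / m.dS - m.omega))
    return worst


def omega_recovery(
    seed: int = 1, n_genes: int = 24, n_codons: int = 500
) -> tuple[float, int]:
    """Median relative error of free-ratio omega estimates across genes
    simulated with per-branch omega drawn uniformly from [0.05, 0.5]."""
    tree = parse_newick(DEFAULT_TREE_NEWICK)
    freqs = CodonFrequencies.uniform()
    rng = np.random.default_rng(seed)
    rel_errs: list[float] = []
    for g in range(n_genes):
        omegas = {b: float(rng.uniform(0.05, 0.5)) for b in DEFAULT_OMEGAS}
        aln, truth = simulate_alignment(
            tree, 2.5, omegas, freqs, n_codons, seed=seed * 1000 + g
        )
        engine = LikelihoodEngine(aln, tree)
        f1 = fit_model(aln, tree, ModelSpec("one_ratio"), _FAST, engine=engine)
        ff = fit_model(
            aln, tree, ModelSpec("free_ratio"), _FAST, init=f1, engine=engine
        )
        true = dict(zip(truth["branch"], truth["omega_true"]))
        rel_errs.extend(
            abs(ff.omegas[b] - true[b]) / true[b] for b in ff.omegas
        )
    return float(np.median(rel_errs)), len(rel_errs)


def two_ratio_type1(
    seed: int = 1, n_reps: int = 100, n_codons: int = 200, alpha: float = 0.05
) -> float:
    """Empirical rejection rate of the two-ratio LRT on one-ratio data."""
    tree = parse_newick(DEFAULT_TREE_NEWICK)
    freqs = CodonFrequencies.uniform()
    fg = frozenset({"BMR"})
    rejections = 0
    for r in range(n_reps):
        aln, _ = simulate_alignment(
            tree, 2.5, 0.15, freqs, n_codons, seed=seed * 5000 + r
        )
        engine = LikelihoodEngine(aln, tree)
        f1 = fit_model(aln, tree, ModelSpec("one_ratio"), _FAST, engine=engine)
        f2 = fit_model(
            aln, tree, ModelSpec("two_ratio", fg), _FAST, init=f1, engine=engine
        )
        rejections += lrt(f1, f2, df=1).p < alpha
    return rejections / n_reps


def branch_site_type1(
    seed: int = 1, n_reps: int = 20, n_codons: int = 200, alpha: float = 0.05
) -> float:
    """Empirical rejection rate of the branch-site LRT on data without
    positive selection (expected conservative against chi-square 1)."""
    tree = parse_newick(DEFAULT_TREE_NEWICK)
    freqs = CodonFrequencies.uniform()
    fg = frozenset({"BMR"})
    rejections = 0
    for r in range(n_reps):
        aln, _ = simulate_alignment(
            tree, 2.5, DEFAULT_OMEGAS, freqs, n_codons, seed=seed * 7000 + r
        )
        engine = LikelihoodEngine(aln, tree)
        f0 = fit_model(
            aln, tree, ModelSpec("branch_site_null", fg), _FAST, engine=engine
        )
        fa = fit_model(
            aln, tree, ModelSpec("branch_site_A", fg), _FAST, init=f0,
            engine=engine,
        )
        rejections += lrt(f0, fa, df=1).p < alpha
    return rejections / n_reps


def gene_scan_benchmark(
    seed: int = 2025,
    n_genes: int = 120,
    length_range: tuple[int, int] = (150, 300),
    effect_fraction: float = 0.1,
    baseline_omega: float = 0.1,
    effect_omega: float = 0.8,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Sensitivity and observed FDR of the branch LRT scan on genes with a
    known subset carrying foreground-elevated omega."""
    cfg = SimConfig(
        seed=seed, n_genes=n_genes, length_range=length_range,
        effect_fraction=effect_fraction, effect_kind="branch",
        effect_omega=effect_omega,
        omegas={b: baseline_omega for b in DEFAULT_OMEGAS},
        n_go_terms=10, min_big_term_genes=5,
    )
    bundle = simulate_study(cfg)
    tree = cfg.tree()
    fg = frozenset(cfg.foreground)
    rows = []
    for gene, aln in bundle.alignments.items():
        engine = LikelihoodEngine(aln, tree)
        f1 = fit_model(aln, tree, ModelSpec("one_ratio"), _FAST, engine=engine)
        f2 = fit_model(
            aln, tree, ModelSpec("two_ratio", fg), _FAST, init=f1, engine=engine
        )
        fg_branch = next(iter(fg))
        bg_branch = next(b for b in f2.omegas if b not in fg)
        rows.append(
            {
                "gene": gene,
                "p": lrt(f1, f2, df=1).p,
                "higher": f2.omegas[fg_branch] > f2.omegas[bg_branch],
            }
        )
    scan = pd.DataFrame(rows)
    scan["p_adj"] = bh_fdr(scan["p"].to_numpy())
    scan["hit"] = (scan["p_adj"] < alpha) & scan["higher"]
    selected = bundle.truth.groupby("gene")["selected"].first()
    hits = scan.set_index("gene")["hit"]
    tp = int((hits & selected).sum())
    n_hits = int(hits.sum())
    n_true = int(selected.sum())
    return {
        "sensitivity": tp / n_true if n_true else float("nan"),
        "fdr": (n_hits - tp) / n_hits if n_hits else 0.0,
        "n_true": n_true,
        "n_hits": n_hits,
        "n_genes": n_genes,
    }


def lineage_comparison_benchmark(
    seed: int = 2024,
    n_genes: int = 100,
    length_range: tuple[int, int] = (350, 550),
) -> pd.DataFrame:
    """Paired Wilcoxon comparisons (rN, rS, omega) between each
    subterranean lineage and its surface counterpart on a background-only
    synthetic study (no per-gene selection effects)."""
    cfg = SimConfig(
        seed=seed, n_genes=n_genes, length_range=length_range,
        effect_fraction=0.0, n_go_terms=10, min_big_term_genes=5,
    )
    bundle = simulate_study(cfg)
    tree = cfg.tree()
    measures = {}
    for gene, aln in bundle.alignments.items():
        engine = LikelihoodEngine(aln, tree)
        f1 = fit_model(aln, tree, ModelSpec("one_ratio"), _FAST, engine=engine)
        ff = fit_model(
            aln, tree, ModelSpec("free_ratio"), _FAST, init=f1, engine=engine
        )
        measures[gene] = branch_measures(ff, aln.n_codons)
    kept, _ = filter_by_ds(measures)
    table = rate_table(
        {g: m for g, m in measures.items() if g in kept}, bundle.alignments
    )
    rows = []
    for sub, surf in (("BMR", "mouse"), ("NMR", "guinea_pig")):
        for col in ("rN", "rS", "omega"):
            wide = table.pivot_table(
                index="gene", columns="lineage", values=col
            )[[sub, surf]].dropna()
            diff = wide[sub] - wide[surf]
            rows.append(
                {
                    "comparison": f"{col}:{sub}_vs_{surf}",
                    "quantity": col,
                    "n": len(wide),
                    "median_diff": float(diff.median()),
                    "p": paired_rank_test(wide[sub], wide[surf]),
                    # subterranean rates are slower (negative diff), their
                    # dN/dS is higher (positive diff)
                    "expected_sign": 1.0 if col == "omega" else -1.0,
                }
            )
    return pd.DataFrame(rows)
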