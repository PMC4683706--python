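"""GO-level and gene-level selection analyses.

Covers the functional-category side of the pipeline: true-path
propagation of GO annotations, concatenation of member-gene alignments
into per-term units, the log(omega-ratio) quadrant comparison between
subterranean lineages and their surface counterparts, branch and
branch-site LRT scans with Benjamini-Hochberg FDR control, hit overlap,
and classic Fisher 2x2 enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .alignment import CodonAlignment
from .codon_model import (
    FitOptions,
    FittedModel,
    LikelihoodEngine,
    ModelSpec,
    fit_model,
    lrt,
)
from .io_formats import PhyloTree

__all__ = [
    "GoTermUnit",
    "ScanHit",
    "propagate_go",
    "collect_go_terms",
    "go_log_ratios",
    "quadrant_percent",
    "branch_lrt_scan",
    "branch_site_scan",
    "bh_fdr",
    "overlap",
    "fisher_enrichment",
]

OMEGA_FLOOR = 1e-4  # floor omega before taking logs: keeps ratios finite


@dataclass
class GoTermUnit:
    """A GO term with its member genes and their concatenated alignment."""

    go_id: str
    genes: list[str]
    alignment: CodonAlignment


@dataclass
class ScanHit:
    """One significant unit from an LRT scan."""

    unit_id: str
    foreground: frozenset
    lnl0: float
    lnl1: float
    stat: float
    p: float
    p_adj: float
    omega_fore: float
    omega_back: float
    direction: str


# ---------------------------------------------------------------------------
# GO bookkeeping
# ---------------------------------------------------------------------------


def propagate_go(
    annot: dict[str, set[str]], dag: dict[str, set[str]]
) -> dict[str, set[str]]:
    """True-path propagation: each gene inherits all ancestors of its terms."""
    g = nx.DiGraph()
    for child, parents in dag.items():
        for parent in parents:
            g.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("GO DAG contains a cycle")
    ancestors: dict[str, set[str]] = {}

    def anc(term: str) -> set[str]:
        if term not in ancestors:
            ancestors[term] = (
                nx.descendants(g, term) if term in g else set()
            )  # edges point child -> parent
        return ancestors[term]

    return {
        gene: set().union(terms, *(anc(t) for t in terms)) if terms else set()
        for gene, terms in annot.items()
    }


def collect_go_terms(
    annot: dict[str, set[str]],
    alignments: dict[str, CodonAlignment],
    min_genes: int = 10,
) -> list[GoTermUnit]:
    """One concatenated unit per GO term annotating >= ``min_genes`` of the
    supplied genes; members sorted by gene id for determinism."""
    by_term: dict[str, list[str]] = {}
    for gene, terms in annot.items():
        if gene not in alignments:
            continue
        for term in terms:
            by_term.setdefault(term, []).append(gene)
    units = []
    for term in sorted(by_term):
        genes = sorted(by_term[term])
        if len(genes) < min_genes:
            continue
        concat = CodonAlignment.concatenate([alignments[g] for g in genes])
        units.append(GoTermUnit(go_id=term, genes=genes, alignment=concat))
    return units


# ---------------------------------------------------------------------------
# log(omega ratio) comparison
# ---------------------------------------------------------------------------


def go_log_ratios(
    fits: dict[str, FittedModel],
    pair_1: tuple[str, str] = ("BMR", "mouse"),
    pair_2: tuple[str, str] = ("NMR", "guinea_pig"),
) -> tuple[pd.DataFrame, dict[str, int], int]:
    """Per-term log ratios of omega between each subterranean lineage and
    its surface counterpart, with quadrant counts.

    Quadrants (``++``, ``+-``, ``-+``, ``--``) partition the terms whose
    two log ratios are both nonzero; terms with a zero ratio are tallied
    separately under ``zero``. Returns (records, quadrant counts, percent
    of all terms in the ``++`` quadrant, rounded to the nearest integer).
    """
    rows = []
    counts = {"++": 0, "+-": 0, "-+": 0, "--": 0, "zero": 0}
    for go_id, fit in fits.items():
        if fit.omegas is None:
            raise ValueError(f"fit for {go_id} has no per-branch omega")
        w = {
            b: max(fit.omegas[b], OMEGA_FLOOR)
            for b in (pair_1[0], pair_1[1], pair_2[0], pair_2[1])
        }
        lr1 = float(np.log(w[pair_1[0]] / w[pair_1[1]]))
        lr2 = float(np.log(w[pair_2[0]] / w[pair_2[1]]))
        if lr1 == 0.0 or lr2 == 0.0:
            quadrant = "zero"
        else:
            quadrant = ("+" if lr1 > 0 else "-") + ("+" if lr2 > 0 else "-")
        counts[quadrant] += 1
        rows.append(
            {
                "go_id": go_id,
                f"omega_{pair_1[0]}": fit.omegas[pair_1[0]],
                f"omega_{pair_1[1]}": fit.omegas[pair_1[1]],
                f"omega_{pair_2[0]}": fit.omegas[pair_2[0]],
                f"omega_{pair_2[1]}": fit.omegas[pair_2[1]],
                "log_ratio_1": lr1,
                "log_ratio_2": lr2,
                "quadrant": quadrant,
            }
        )
    records = pd.DataFrame(rows)
    percent = quadrant_percent(counts["++"], len(fits)) if fits else 0
    return records, counts, percent


def quadrant_percent(n_both_positive: int, n_total: int) -> int:
    """Percent of terms with both log ratios positive, to the nearest
    integer (e.g. 731 of 1307 -> 56)."""
    if n_total <= 0:
        raise ValueError("no terms")
    return int(round(100.0 * n_both_positive / n_total))


# ---------------------------------------------------------------------------
# LRT scans
# ---------------------------------------------------------------------------


def branch_lrt_scan(
    units: list[tuple[str, CodonAlignment]],
    tree: PhyloTree,
    foreground: frozenset,
    direction: str = "higher",
    alpha: float = 0.05,
    alpha_is_on_adjusted: bool = True,
    options: FitOptions | None = None,
) -> tuple[list[ScanHit], pd.DataFrame]:
    """One-ratio vs two-ratio LRT over every unit, BH-corrected.

    A unit is a hit when its (adjusted) p is below ``alpha`` and the
    foreground omega lies on the requested side (``higher``/``lower``) of
    the background omega. Non-converged fits are dropped from the testing
    family and flagged in the returned table.
    """
    if direction not in ("higher", "lower"):
        raise ValueError("direction must be 'higher' or 'lower'")
    opts = options or FitOptions(n_restarts=1)
    rows = []
    for unit_id, aln in units:
        engine = LikelihoodEngine(aln, tree)
        fit0 = fit_model(aln, tree, ModelSpec("one_ratio"), opts, engine=engine)
        fit1 = fit_model(
            aln, tree, ModelSpec("two_ratio", foreground), opts, init=fit0,
            engine=engine,
        )
        res = lrt(fit0, fit1, df=1)
        fg_branch = next(iter(foreground & set(fit1.omegas)))
        bg_branch = next(b for b in fit1.omegas if b not in foreground)
        rows.append(
            {
                "unit_id": unit_id,
                "lnl0": fit0.lnL,
                "lnl1": fit1.lnL,
                "stat": res.stat,
                "p": res.p,
                "omega_fore": fit1.omegas[fg_branch],
                "omega_back": fit1.omegas[bg_branch],
                "converged": fit0.converged and fit1.converged,
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        table = pd.DataFrame(
            columns=["unit_id", "lnl0", "lnl1", "stat", "p", "omega_fore",
                     "omega_back", "converged", "p_adj", "hit"]
        )
        return [], table
    ok = table["converged"].to_numpy()
    table["p_adj"] = np.nan
    table.loc[ok, "p_adj"] = bh_fdr(table.loc[ok, "p"].to_numpy())
    crit = table["p_adj"] if alpha_is_on_adjusted else table["p"]
    side = (
        table["omega_fore"] > table["omega_back"]
        if direction == "higher"
        else table["omega_fore"] < table["omega_back"]
    )
    table["hit"] = ok & (crit < alpha) & side
    hits = [
        ScanHit(
            unit_id=r.unit_id, foreground=foreground, lnl0=r.lnl0, lnl1=r.lnl1,
            stat=r.stat, p=r.p, p_adj=r.p_adj, omega_fore=r.omega_fore,
            omega_back=r.omega_back, direction=direction,
        )
        for r in table[table["hit"]].itertuples()
    ]
    return hits, table


def branch_site_scan(
    genes: list[tuple[str, CodonAlignment]],
    tree: PhyloTree,
    foreground: frozenset,
    alpha: float = 0.05,
    options: FitOptions | None = None,
) -> tuple[list[ScanHit], pd.DataFrame]:
    """Branch-site model A vs its omega2=1 null over every gene (the
    positively-selected-gene scan), BH-corrected at ``alpha``."""
    opts = options or FitOptions(n_restarts=1)
    rows = []
    for gene, aln in genes:
        engine = LikelihoodEngine(aln, tree)
        fit0 = fit_model(
            aln, tree, ModelSpec("branch_site_null", foreground), opts,
            engine=engine,
        )
        fit1 = fit_model(
            aln, tree, ModelSpec("branch_site_A", foreground), opts, init=fit0,
            engine=engine,
        )
        res = lrt(fit0, fit1, df=1)
        rows.append(
            {
                "unit_id": gene,
                "lnl0": fit0.lnL,
                "lnl1": fit1.lnL,
                "stat": res.stat,
                "p": res.p,
                "omega2": fit1.site_params["omega2"],
                "omega0": fit1.site_params["omega0"],
                "p_selected": fit1.site_params["p2a"] + fit1.site_params["p2b"],
                "converged": fit0.converged and fit1.converged,
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        table = pd.DataFrame(
            columns=["unit_id", "lnl0", "lnl1", "stat", "p", "omega2", "omega0",
                     "p_selected", "converged", "p_adj", "hit"]
        )
        return [], table
    ok = table["converged"].to_numpy()
    table["p_adj"] = np.nan
    table.loc[ok, "p_adj"] = bh_fdr(table.loc[ok, "p"].to_numpy())
    table["hit"] = ok & (table["p_adj"] < alpha)
    hits = [
        ScanHit(
            unit_id=r.unit_id, foreground=foreground, lnl0=r.lnl0, lnl1=r.lnl1,
            stat=r.stat, p=r.p, p_adj=r.p_adj, omega_fore=r.omega2,
            omega_back=r.omega0, direction="positive",
        )
        for r in table[table["hit"]].itertuples()
    ]
    return hits, table


# ---------------------------------------------------------------------------
# multiple testing, overlap, enrichment
# ---------------------------------------------------------------------------


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def overlap(hits_a: list[ScanHit], hits_b: list[ScanHit]) -> set[str]:
    """Unit ids significant in both scans."""
    return {h.unit_id for h in hits_a} & {h.unit_id for h in hits_b}


def fisher_enrichment(
    study_genes: set[str],
    background_genes: set[str],
    annot: dict[str, set[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Classic one-sided Fisher 2x2 over-representation test per GO term.

    The contingency table splits the background into study/non-study and
    with-term/without-term; p-values are BH-adjusted and terms with
    p_adj < ``alpha`` are flagged ``enriched``.
    """
    if not study_genes:
        raise ValueError("empty study set")
    if not study_genes <= background_genes:
        raise ValueError("study genes must be a subset of the background")
    terms = sorted({t for g in background_genes for t in annot.get(g, set())})
    n_bg = len(background_genes)
    n_study = len(study_genes)
    rows = []
    for term in terms:
        with_term = {g for g in background_genes if term in annot.get(g, set())}
        a = len(study_genes & with_term)
        b = n_study - a
        c = len(with_term) - a
        d = n_bg - n_study - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append(
            {
                "go_id": term,
                "study_with_term": a,
                "study_total": n_study,
                "background_with_term": len(with_term),
                "background_total": n_bg,
                "p": float(p),
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        table = pd.DataFrame(
            columns=["go_id", "study_with_term", "study_total",
                     "background_with_term", "background_total", "p",
                     "p_adj", "enriched"]
        )
        return table
    table["p_adj"] = bh_fdr(table["p"].to_numpy())
    table["enriched"] = table["p_adj"] < alpha
    return table.sort_values("p").reset_index(drop=True)
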