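"""Rate-and-pattern statistics across lineages.

Given per-gene, per-branch substitution measures from free-ratio fits,
this module applies the dS-based quality filters, converts dN/dS into
per-year rates rN/rS using divergence dates, compares paired lineages
with rank tests, stratifies genes by dN/dS, and computes GC/GC3.

Units: divergence dates in Ma; rN and rS in substitutions/site/year
x 10^-9 (d / T_Ma * 1000); GC and GC3 in percent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import CodonAlignment
from .codon_model import BranchMeasures

__all__ = [
    "RateConfig",
    "StrataResult",
    "filter_by_ds",
    "per_year_rate",
    "paired_rank_test",
    "unpaired_rank_test",
    "stratify_dnds",
    "gc_stats",
    "rate_table",
    "summarize_lineages",
]

# The six-lineage filter set: four focal terminals plus the two ancestral
# branches of the subterranean/surface pairs.
DEFAULT_FILTER_LINEAGES = (
    "BMR",
    "mouse",
    "BMR+mouse",
    "NMR",
    "guinea_pig",
    "NMR+guinea_pig",
)


@dataclass
class RateConfig:
    """Divergence dates (Ma) and the lineage sets the statistics run over.

    A terminal lineage's time span is the split date of its pair: both
    sides of a split have evolved for the same absolute time.
    """

    dates_ma: dict[str, float] = field(
        default_factory=lambda: {
            "BMR": 47.4,
            "mouse": 47.4,
            "NMR": 39.5,
            "guinea_pig": 39.5,
        }
    )
    filter_lineages: tuple[str, ...] = DEFAULT_FILTER_LINEAGES
    ds_max: float = 1.0
    min_syn_events: float = 1.0

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.dates_ma.values()):
            raise ValueError("divergence dates must be positive")


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def filter_by_ds(
    measures: dict[str, dict[str, BranchMeasures]],
    config: RateConfig | None = None,
) -> tuple[set[str], pd.DataFrame]:
    """Keep a gene only if, on *every* listed lineage, dS <= ds_max and
    S*dS >= min_syn_events.

    ``measures`` maps gene -> branch id -> :class:`BranchMeasures`. A gene
    missing any listed lineage is excluded and logged. Returns the kept
    gene set and a log of exclusions (gene, lineage, reason).
    """
    cfg = config or RateConfig()
    kept: set[str] = set()
    log_rows = []
    for gene, by_branch in measures.items():
        ok = True
        for lineage in cfg.filter_lineages:
            m = by_branch.get(lineage)
            if m is None:
                log_rows.append(
                    {"gene": gene, "lineage": lineage, "reason": "missing_measure"}
                )
                ok = False
                continue
            if m.dS > cfg.ds_max:
                log_rows.append(
                    {"gene": gene, "lineage": lineage, "reason": "ds_too_high"}
                )
                ok = False
            if m.syn_events < cfg.min_syn_events:
                log_rows.append(
                    {"gene": gene, "lineage": lineage, "reason": "too_few_syn_events"}
                )
                ok = False
        if ok:
            kept.add(gene)
    log = pd.DataFrame(log_rows, columns=["gene", "lineage", "reason"])
    return kept, log


# ---------------------------------------------------------------------------
# rates and tests
# ---------------------------------------------------------------------------


def per_year_rate(d: float, t_ma: float) -> float:
    """d substitutions/site over t_ma million years, in 10^-9 subs/site/yr."""
    if t_ma <= 0:
        raise ValueError("time span must be positive")
    if d < 0:
        raise ValueError("negative substitution estimate")
    return d / t_ma * 1000.0


def paired_rank_test(x, y) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped; the null is exact for n <= 25 pairs and
    a continuity-corrected normal approximation above. All-zero
    differences give p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    diffs = x - y
    nz = diffs[diffs != 0]
    if nz.size == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return 1.0
    method = "exact" if nz.size <= 25 else "approx"
    res = stats.wilcoxon(
        nz, zero_method="wilcox", correction=True, alternative="two-sided",
        method=method,
    )
    return float(res.pvalue)


def unpaired_rank_test(x, y) -> float:
    """Two-sided Mann-Whitney U p-value (exact for small tie-free samples,
    tie-corrected normal approximation otherwise)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------


@dataclass
class StrataResult:
    """dN/dS strata for one lineage pair: group 1 (omega < 1 in both),
    group 2 (omega > 1 in either); boundary genes belong to neither."""

    lineage_a: str
    lineage_b: str
    group1: list[str]
    group2: list[str]
    neither: list[str]
    group1_means: tuple[float, float]  # mean omega (a, b) over group 1
    group2_means: tuple[float, float]
    group1_p: float
    group2_p: float | None  # None when group 2 is empty


def stratify_dnds(records: pd.DataFrame, lineage_a: str, lineage_b: str) -> StrataResult:
    """Split genes by dN/dS in two lineages and test each stratum.

    ``records`` is tidy: columns ``gene``, ``lineage``, ``omega`` (other
    columns ignored). Within each stratum a paired Wilcoxon signed-rank
    test compares omega between the two lineages.
    """
    wide = records.pivot_table(index="gene", columns="lineage", values="omega")
    wide = wide[[lineage_a, lineage_b]].dropna()
    wa, wb = wide[lineage_a], wide[lineage_b]
    g1 = wide.index[(wa < 1) & (wb < 1)].tolist()
    g2 = wide.index[(wa > 1) | (wb > 1)].tolist()
    neither = sorted(set(wide.index) - set(g1) - set(g2))

    def mean_pair(genes):
        if not genes:
            return (float("nan"), float("nan"))
        return (float(wa.loc[genes].mean()), float(wb.loc[genes].mean()))

    g1_p = paired_rank_test(wa.loc[g1], wb.loc[g1]) if g1 else 1.0
    g2_p = paired_rank_test(wa.loc[g2], wb.loc[g2]) if g2 else None
    return StrataResult(
        lineage_a=lineage_a,
        lineage_b=lineage_b,
        group1=g1,
        group2=g2,
        neither=neither,
        group1_means=mean_pair(g1),
        group2_means=mean_pair(g2),
        group1_p=g1_p,
        group2_p=g2_p,
    )


# ---------------------------------------------------------------------------
# GC content
# ---------------------------------------------------------------------------


def gc_stats(cds: str) -> tuple[float, float]:
    """(GC %, GC3 %) of one aligned codon sequence; gap and ambiguity
    positions count in neither numerator nor denominator."""
    seq = cds.upper()
    if len(seq) % 3 != 0:
        raise ValueError("sequence length must be divisible by 3")
    valid = [c for c in seq if c in "ACGT"]
    if not valid:
        raise ValueError("no unambiguous bases in sequence")
    gc = 100.0 * sum(c in "GC" for c in valid) / len(valid)
    third = [seq[i] for i in range(2, len(seq), 3) if seq[i] in "ACGT"]
    gc3 = 100.0 * sum(c in "GC" for c in third) / len(third) if third else 0.0
    return gc, gc3


# ---------------------------------------------------------------------------
# per-gene rate table and lineage summary
# ---------------------------------------------------------------------------


def rate_table(
    measures: dict[str, dict[str, BranchMeasures]],
    alignments: dict[str, CodonAlignment] | None = None,
    config: RateConfig | None = None,
) -> pd.DataFrame:
    """Tidy per-gene, per-lineage table: dN, dS, omega, rN, rS, GC, GC3.

    rN/rS are filled for lineages with a divergence date (terminals).
    omega is left NaN where dS = 0 (no synonymous signal; such genes stay
    usable for rN). GC/GC3 are computed on the gene's aligned row for the
    lineage's taxon when alignments are given.
    """
    cfg = config or RateConfig()
    rows = []
    for gene, by_branch in measures.items():
        for lineage, m in by_branch.items():
            t_ma = cfg.dates_ma.get(lineage)
            gc = gc3 = np.nan
            if alignments is not None and gene in alignments:
                aln = alignments[gene]
                if lineage in aln.seqs:
                    gc, gc3 = gc_stats(aln.seqs[lineage])
            rows.append(
                {
                    "gene": gene,
                    "lineage": lineage,
                    "dN": m.dN,
                    "dS": m.dS,
                    "omega": m.omega if m.dS > 0 else np.nan,
                    "rN": per_year_rate(m.dN, t_ma) if t_ma else np.nan,
                    "rS": per_year_rate(m.dS, t_ma) if t_ma else np.nan,
                    "GC": gc,
                    "GC3": gc3,
                }
            )
    return pd.DataFrame(rows)


def summarize_lineages(records: pd.DataFrame) -> pd.DataFrame:
    """Per-lineage means of the rate table's columns.

    ``mean_dnds`` is the mean of per-gene omega values (mean of ratios);
    ``dnds_of_means`` is mean dN / mean dS (ratio of means) — the two
    differ and both are reported.
    """
    out = []
    for lineage, grp in records.groupby("lineage"):
        out.append(
            {
                "lineage": lineage,
                "n_genes": len(grp),
                "mean_dN": grp["dN"].mean(),
                "mean_dS": grp["dS"].mean(),
                "mean_rN": grp["rN"].mean(),
                "mean_rS": grp["rS"].mean(),
                "mean_dnds": grp["omega"].mean(),
                "dnds_of_means": grp["dN"].mean() / grp["dS"].mean()
                if grp["dS"].mean() > 0
                else np.nan,
                "mean_GC": grp["GC"].mean(),
                "mean_GC3": grp["GC3"].mean(),
            }
        )
    return pd.DataFrame(out).sort_values("lineage").reset_index(drop=True)
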