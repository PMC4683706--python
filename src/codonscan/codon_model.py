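"""GY94-style codon substitution models: rate matrices, pruning
likelihoods, maximum-likelihood fitting and likelihood-ratio tests.

The model. A Markov process on the 61 sense codons of the standard
genetic code. The instantaneous rate from codon *i* to codon *j* is zero
when the codons differ at more than one nucleotide position and otherwise

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous]

with kappa the transition/transversion rate ratio and omega = dN/dS the
selection-intensity parameter. The matrix is normalized so branch lengths
are expected substitutions per codon. Four model classes are supported:

* ``one_ratio``   — a single omega shared by every branch;
* ``free_ratio``  — an independent omega per branch;
* ``two_ratio``   — one omega on designated foreground branches, another
  on the background (the "branch model");
* ``branch_site_A`` / ``branch_site_null`` — a four-class site mixture
  (0, 1, 2a, 2b) in which a fraction of sites may have omega2 > 1 on the
  foreground branch only; the null fixes omega2 = 1.

Trees are treated as unrooted for likelihood (the two branches meeting
at a root of degree two are merged), but branch identities are preserved
by leaf-set labelling so that per-branch estimates are addressable.
"""

from __future__ import annotations

import math
from collections import OrderedDict
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable
from scipy import optimize, stats
from scipy.special import logsumexp

from .alignment import CodonAlignment
from .io_formats import PhyloTree, TreeNode

__all__ = [
    "GeneticCode",
    "STANDARD_CODE",
    "CodonFrequencies",
    "CodonRateMatrix",
    "build_rate_matrix",
    "transition_matrix",
    "ModelSpec",
    "FitOptions",
    "FittedModel",
    "BranchMeasures",
    "LRTResult",
    "log_likelihood",
    "fit_model",
    "branch_measures",
    "lrt",
]

_NUCS = "TCAG"
_TRANSITION_PAIRS = {frozenset("AG"), frozenset("CT")}


class GeneticCode:
    """The standard genetic code restricted to its 61 sense codons.

    Precomputes, for every ordered codon pair differing at exactly one
    nucleotide, whether the change is a transition and whether it is
    nonsynonymous — the classification the rate matrix is built from.
    """

    def __init__(self, table_id: int = 1):
        table = CodonTable.unambiguous_dna_by_id[table_id]
        self.stop_codons = frozenset(table.stop_codons)
        self.sense_codons = tuple(sorted(table.forward_table))
        if len(self.sense_codons) != 61:
            raise ValueError(f"expected 61 sense codons, got {len(self.sense_codons)}")
        self.codon_to_aa = dict(table.forward_table)
        self.codon_index = {c: i for i, c in enumerate(self.sense_codons)}
        n = len(self.sense_codons)
        single = np.zeros((n, n), dtype=bool)
        transition = np.zeros((n, n), dtype=bool)
        nonsyn = np.zeros((n, n), dtype=bool)
        for i, ci in enumerate(self.sense_codons):
            for j, cj in enumerate(self.sense_codons):
                diffs = [p for p in range(3) if ci[p] != cj[p]]
                if len(diffs) != 1:
                    continue
                (p,) = diffs
                single[i, j] = True
                transition[i, j] = frozenset((ci[p], cj[p])) in _TRANSITION_PAIRS
                nonsyn[i, j] = self.codon_to_aa[ci] != self.codon_to_aa[cj]
        self.single_step = single
        self.is_transition = transition
        self.is_nonsyn = nonsyn

    def translate(self, cds: str) -> str:
        aas = []
        for i in range(0, len(cds) - len(cds) % 3, 3):
            codon = cds[i : i + 3].upper()
            if codon in self.stop_codons:
                aas.append("*")
            else:
                aas.append(self.codon_to_aa.get(codon, "X"))
        return "".join(aas)


STANDARD_CODE = GeneticCode()


# ---------------------------------------------------------------------------
# equilibrium frequencies
# ---------------------------------------------------------------------------


@dataclass
class CodonFrequencies:
    """Equilibrium codon frequencies over the 61 sense codons.

    ``source`` records how they were obtained (uniform, F1x4, F3x4, F61).
    Stop-codon mass is implicitly zero; the vector is renormalized to 1.
    """

    pi: np.ndarray
    source: str

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (61,):
            raise ValueError("pi must have 61 entries")
        if np.any(self.pi < 0) or not np.all(np.isfinite(self.pi)):
            raise ValueError("pi entries must be finite and non-negative")
        total = self.pi.sum()
        if abs(total - 1.0) > 1e-8:
            self.pi = self.pi / total

    @classmethod
    def uniform(cls, code: GeneticCode = STANDARD_CODE) -> "CodonFrequencies":
        return cls(pi=np.full(61, 1.0 / 61), source="uniform")

    @classmethod
    def from_alignment(
        cls,
        aln: CodonAlignment,
        source: str = "F3x4",
        code: GeneticCode = STANDARD_CODE,
        floor: float = 1e-3,
    ) -> "CodonFrequencies":
        """Estimate frequencies from observed codons.

        Nucleotide frequencies are floored at ``floor`` (then renormalized)
        so that unobserved states never get exactly zero equilibrium mass,
        which would break reversibility arithmetic.
        """
        if source == "uniform":
            return cls.uniform(code)
        codon_counts = np.zeros(61)
        nuc_pos = np.zeros((3, 4))  # position x TCAG
        nuc_idx = {n: k for k, n in enumerate(_NUCS)}
        for seq in aln.seqs.values():
            for i in range(0, len(seq), 3):
                codon = seq[i : i + 3]
                if any(ch not in "ACGT" for ch in codon):
                    continue
                if codon in code.codon_index:
                    codon_counts[code.codon_index[codon]] += 1
                for p, ch in enumerate(codon):
                    nuc_pos[p, nuc_idx[ch]] += 1
        if source == "F61":
            pi = codon_counts + floor
        elif source in ("F1x4", "F3x4"):
            if source == "F1x4":
                nuc_pos = np.tile(nuc_pos.sum(axis=0), (3, 1))
            nuc_freq = nuc_pos / np.maximum(nuc_pos.sum(axis=1, keepdims=True), 1.0)
            nuc_freq = np.maximum(nuc_freq, floor)
            nuc_freq /= nuc_freq.sum(axis=1, keepdims=True)
            pi = np.array(
                [
                    nuc_freq[0, nuc_idx[c[0]]]
                    * nuc_freq[1, nuc_idx[c[1]]]
                    * nuc_freq[2, nuc_idx[c[2]]]
                    for c in code.sense_codons
                ]
            )
        else:
            raise ValueError(f"unknown frequency source {source!r}")
        return cls(pi=pi / pi.sum(), source=source)


# ---------------------------------------------------------------------------
# rate matrix and transition probabilities
# ---------------------------------------------------------------------------


@dataclass
class CodonRateMatrix:
    """A normalized GY94 rate matrix (61 x 61) plus its parameters."""

    Q: np.ndarray
    kappa: float
    omega: float
    pi: np.ndarray


def build_rate_matrix(
    kappa: float,
    omega: float,
    freqs: CodonFrequencies,
    code: GeneticCode = STANDARD_CODE,
) -> CodonRateMatrix:
    """Build the normalized codon rate matrix Q(kappa, omega, pi).

    Off-diagonal rates follow the single-step GY94 parameterization; the
    diagonal makes rows sum to zero and the whole matrix is scaled so the
    mean rate -sum_i pi_i q_ii equals 1 (branch length = expected
    substitutions per codon).
    """
    if not (np.isfinite(kappa) and np.isfinite(omega)):
        raise ValueError("non-finite kappa or omega")
    if kappa <= 0 or omega < 0:
        raise ValueError("require kappa > 0 and omega >= 0")
    pi = freqs.pi
    if np.any(pi >= 1.0):
        raise ValueError("degenerate pi: an entry equals 1")
    Q = np.where(code.single_step, pi[None, :], 0.0)
    Q = Q * np.where(code.is_transition, kappa, 1.0)
    Q = Q * np.where(code.is_nonsyn, omega, 1.0)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -(pi * np.diag(Q)).sum()
    if mean_rate <= 0:
        raise ValueError("degenerate rate matrix (zero mean rate)")
    return CodonRateMatrix(Q=Q / mean_rate, kappa=kappa, omega=omega, pi=pi)


def _spectral(Q: CodonRateMatrix):
    """Eigendecomposition via the reversibility transform.

    For a reversible Q, S = D Q D^-1 with D = diag(sqrt(pi)) is symmetric;
    P(t) = A exp(L t) B with A = D^-1 U, B = U^T D.
    """
    d = np.sqrt(Q.pi)
    S = Q.Q * (d[:, None] / d[None, :])
    asym = np.max(np.abs(S - S.T))
    if asym > 1e-8:
        raise ValueError(f"rate matrix violates detailed balance (|S-S^T|={asym:.2e})")
    lam, U = np.linalg.eigh(0.5 * (S + S.T))
    A = U / d[:, None]
    B = (U * d[:, None]).T
    return lam, A, B


def rate_coefficients(
    kappa: float, freqs: CodonFrequencies, code: GeneticCode = STANDARD_CODE
) -> tuple[float, float]:
    """(synonymous, nonsynonymous) flux coefficients of the unnormalized
    GY94 matrix: its mean substitution rate is ``syn + omega * nonsyn``."""
    pi = freqs.pi
    R = np.where(
        code.single_step,
        pi[None, :] * np.where(code.is_transition, kappa, 1.0),
        0.0,
    )
    flux = pi[:, None] * R
    syn = float(flux[code.single_step & ~code.is_nonsyn].sum())
    nonsyn = float(flux[code.single_step & code.is_nonsyn].sum())
    return syn, nonsyn


def transition_matrix(Q: CodonRateMatrix, t: float) -> np.ndarray:
    """P(t) = exp(Qt); rows sum to 1, tiny negative entries clamped to 0."""
    if t < 0 or not np.isfinite(t):
        raise ValueError(f"invalid branch length {t}")
    lam, A, B = _spectral(Q)
    P = (A * np.exp(lam * t)) @ B
    np.clip(P, 0.0, None, out=P)
    return P


# ---------------------------------------------------------------------------
# model specification and fit containers
# ---------------------------------------------------------------------------

_KINDS = ("one_ratio", "free_ratio", "two_ratio", "branch_site_A", "branch_site_null")
_NEEDS_FOREGROUND = ("two_ratio", "branch_site_A", "branch_site_null")


@dataclass(frozen=True)
class ModelSpec:
    """Which model class to fit, and on which foreground branches."""

    kind: str
    foreground: frozenset = frozenset()
    freq_source: str = "F3x4"

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.kind in _NEEDS_FOREGROUND and not self.foreground:
            raise ValueError(f"{self.kind} requires a non-empty foreground set")
        if self.kind not in _NEEDS_FOREGROUND and self.foreground:
            raise ValueError(f"{self.kind} takes no foreground set")
        object.__setattr__(self, "foreground", frozenset(self.foreground))


@dataclass
class FitOptions:
    """Optimizer controls. ``n_restarts`` deterministic starts are tried
    (the first seeded from the nested model's fit, the rest perturbed)."""

    n_restarts: int = 3
    seed: int = 0
    maxiter: int = 500
    ftol: float = 1e-11
    gtol: float = 1e-6
    omega_bounds: tuple[float, float] = (1e-4, 50.0)
    t_bounds: tuple[float, float] = (1e-6, 20.0)
    kappa_bounds: tuple[float, float] = (0.05, 50.0)


@dataclass
class FittedModel:
    """A maximum-likelihood codon-model fit for one alignment."""

    spec: ModelSpec
    kappa: float
    branch_lengths: dict[str, float]
    omegas: dict[str, float] | None
    site_params: dict[str, float] | None
    lnL: float
    n_free_params: int
    converged: bool
    n_restarts_used: int
    freqs: CodonFrequencies
    at_bounds: list[str] = field(default_factory=list)

    def omega_for(self, branch_id: str) -> float:
        if self.omegas is None:
            raise ValueError("site-class model has no per-branch omega")
        return self.omegas[branch_id]


@dataclass
class BranchMeasures:
    """Per-branch substitution summaries from a free-ratio fit."""

    branch_id: str
    t: float
    omega: float
    dN: float
    dS: float
    N: float
    S: float
    syn_events: float  # S * dS


@dataclass
class LRTResult:
    stat: float
    df: int
    p: float


# ---------------------------------------------------------------------------
# the likelihood engine
# ---------------------------------------------------------------------------


def _unroot(tree: PhyloTree) -> PhyloTree:
    """Merge the two root branches of a degree-two root into one.

    The merged branch keeps the identity of the root child that is NOT
    promoted, so a basal terminal branch (e.g. an outgroup) remains
    addressable; the promoted child's own branch parameter disappears,
    as it must on an unrooted tree.
    """
    t = tree.copy()
    root = t.root
    if len(root.children) != 2:
        return t
    a, b = root.children
    internal = [c for c in (a, b) if not c.is_leaf]
    if not internal:  # two-taxon tree: single branch, keep one parameter
        a.length += b.length
        a.mark = a.mark or b.mark
        b.length = 0.0
        return t
    keep = internal[0] if len(internal) == 1 else max(
        (a, b), key=lambda c: (len(t.clade_leaves(c)), t.branch_id(c))
    )
    other = b if keep is a else a
    other.length += keep.length
    other.mark = other.mark or keep.mark
    new_root = TreeNode(name=root.name, children=list(keep.children) + [other])
    return PhyloTree(new_root)


class LikelihoodEngine:
    """Pruning likelihood for one alignment on one (unrooted) tree.

    Caches spectral decompositions by (kappa, omega) so that the
    finite-difference sweeps of the optimizer recompute only what a
    perturbed parameter actually changes.
    """

    _CACHE_MAX = 256

    def __init__(
        self,
        aln: CodonAlignment,
        tree: PhyloTree,
        freqs: CodonFrequencies | None = None,
        code: GeneticCode = STANDARD_CODE,
    ):
        if set(aln.taxa) != set(tree.leaf_names()):
            raise ValueError(
                f"alignment taxa {sorted(aln.taxa)} do not match tree leaves "
                f"{sorted(tree.leaf_names())}"
            )
        self.code = code
        self.tree = _unroot(tree)
        self.freqs = freqs or CodonFrequencies.from_alignment(aln, "F3x4", code)
        self.taxa = self.tree.leaf_names()
        states = aln.state_matrix(code.codon_index, self.taxa)
        informative = ~np.all(states < 0, axis=0)
        states = states[:, informative]
        if states.shape[1] == 0:
            raise ValueError("alignment has no informative codon columns")
        self.patterns, self.counts = np.unique(states, axis=1, return_counts=True)
        self.n_codons = int(informative.sum())
        # flat node bookkeeping, postorder
        self.nodes = list(self.tree.postorder())
        self._node_index = {id(n): i for i, n in enumerate(self.nodes)}
        self.branch_nodes = [n for n in self.nodes if n is not self.tree.root]
        self.branch_ids = [self.tree.branch_id(n) for n in self.branch_nodes]
        self._branch_pos = {bid: k for k, bid in enumerate(self.branch_ids)}
        self._leaf_row = {name: r for r, name in enumerate(self.taxa)}
        self._eig_cache: OrderedDict = OrderedDict()
        self._rate_coeff_cache: dict[float, tuple[float, float]] = {}

    # -- spectral cache ----------------------------------------------------

    def _eig(self, kappa: float, omega: float):
        key = (kappa, omega)
        hit = self._eig_cache.get(key)
        if hit is not None:
            self._eig_cache.move_to_end(key)
            return hit
        Q = build_rate_matrix(kappa, omega, self.freqs, self.code)
        val = _spectral(Q)
        self._eig_cache[key] = val
        if len(self._eig_cache) > self._CACHE_MAX:
            self._eig_cache.popitem(last=False)
        return val

    def _pmat(self, kappa: float, omega: float, t: float) -> np.ndarray:
        lam, A, B = self._eig(kappa, omega)
        P = (A * np.exp(lam * t)) @ B
        np.clip(P, 0.0, None, out=P)
        return P

    def rate_coeffs(self, kappa: float) -> tuple[float, float]:
        """(synonymous, nonsynonymous) flux coefficients of the
        *unnormalized* GY94 matrix: its mean rate is syn + omega * nonsyn.

        Used to put the site classes of a mixture model on one clock, so a
        branch length is the expected substitutions per codon averaged
        over classes (sites under omega2 > 1 genuinely evolve faster)."""
        cached = self._rate_coeff_cache.get(kappa)
        if cached is None:
            cached = rate_coefficients(kappa, self.freqs, self.code)
            self._rate_coeff_cache[kappa] = cached
        return cached

    # -- pruning -----------------------------------------------------------

    def _site_loglik(self, pmats: list[np.ndarray]) -> np.ndarray:
        """Per-pattern log-likelihood given one P matrix per branch node."""
        n_pat = self.patterns.shape[1]
        partials: list[np.ndarray | None] = [None] * len(self.nodes)
        logscale = np.zeros(n_pat)
        for i, node in enumerate(self.nodes):
            if node.is_leaf:
                continue
            M = np.ones((61, n_pat))
            for child in node.children:
                ci = self._node_index[id(child)]
                P = pmats[self._branch_pos[self.branch_ids_by_node[ci]]]
                if child.is_leaf:
                    s = self.patterns[self._leaf_row[child.name]]
                    C = P[:, np.clip(s, 0, None)].copy()
                    C[:, s < 0] = 1.0
                else:
                    C = P @ partials[ci]
                M *= C
            if node is self.tree.root:
                site_l = self.freqs.pi @ M
                with np.errstate(divide="ignore"):
                    return np.log(site_l) + logscale
            m = M.max(axis=0)
            m[m == 0.0] = 1.0
            partials[i] = M / m
            logscale += np.log(m)
        raise AssertionError("postorder traversal did not reach the root")

    @property
    def branch_ids_by_node(self) -> dict[int, str]:
        cached = getattr(self, "_bibn", None)
        if cached is None:
            cached = {
                self._node_index[id(n)]: bid
                for n, bid in zip(self.branch_nodes, self.branch_ids)
            }
            self._bibn = cached
        return cached

    def lnl_branch(
        self, kappa: float, ts: np.ndarray, omegas: np.ndarray
    ) -> float:
        """lnL of a branch model: per-branch length and omega arrays ordered
        like ``branch_ids``."""
        pmats = [
            self._pmat(kappa, float(w), float(t)) for t, w in zip(ts, omegas)
        ]
        return float(self.counts @ self._site_loglik(pmats))

    def lnl_branch_site(
        self,
        kappa: float,
        ts: np.ndarray,
        p0: float,
        p1: float,
        omega0: float,
        omega2: float,
        foreground: frozenset,
    ) -> float:
        """lnL of branch-site model A (or its null when omega2 = 1).

        Site classes: 0 (omega0 everywhere), 1 (neutral everywhere),
        2a (background omega0, foreground omega2), 2b (background 1,
        foreground omega2); proportions p0, p1 and the remainder split
        p0:(p1) between 2a and 2b. A branch length is the expected number
        of substitutions per codon averaged over site classes, so the
        classes share one clock and omega2 > 1 sites substitute faster.
        """
        fg = np.array([bid in foreground for bid in self.branch_ids])
        if not fg.any():
            raise ValueError("foreground branches not found in tree")
        rest = max(0.0, 1.0 - p0 - p1)
        denom = p0 + p1
        if denom <= 0:
            raise ValueError("p0 + p1 must be positive")
        weights = np.array([p0, p1, rest * p0 / denom, rest * p1 / denom])
        class_back = [omega0, 1.0, omega0, 1.0]
        class_fore = [omega0, 1.0, omega2, omega2]
        syn, nonsyn = self.rate_coeffs(kappa)

        def rate(w: float) -> float:
            return syn + w * nonsyn

        site_logl = np.empty((4, self.patterns.shape[1]))
        for k in range(4):
            pmats = []
            for t, f in zip(ts, fg):
                ws = class_fore if f else class_back
                mean_rate = float(weights @ [rate(w) for w in ws])
                w = ws[k]
                # own-normalized matrix run for rescaled time = common clock
                pmats.append(self._pmat(kappa, w, float(t) * rate(w) / mean_rate))
            site_logl[k] = self._site_loglik(pmats)
        with np.errstate(divide="ignore"):
            logw = np.where(weights > 0, np.log(np.maximum(weights, 1e-300)), -np.inf)
        per_site = logsumexp(site_logl + logw[:, None], axis=0)
        return float(self.counts @ per_site)


def log_likelihood(
    aln: CodonAlignment,
    tree: PhyloTree,
    kappa: float,
    omegas: float | dict[str, float] = 1.0,
    freqs: CodonFrequencies | None = None,
    branch_lengths: dict[str, float] | None = None,
    site_params: dict[str, float] | None = None,
    foreground: frozenset | None = None,
) -> float:
    """Pruning log-likelihood at fixed parameters.

    Branch lengths default to the lengths on ``tree`` (in expected
    substitutions per codon, on the unrooted topology). ``omegas`` may be
    one shared value or a dict keyed by branch id. For the branch-site
    models pass ``site_params`` = {p0, p1, omega0, omega2} plus a
    foreground set (defaulting to the tree's ``#k``-marked branches).
    """
    engine = LikelihoodEngine(aln, tree, freqs=freqs)
    if branch_lengths is None:
        ts = np.array([n.length for n in engine.branch_nodes])
    else:
        ts = np.array([branch_lengths[b] for b in engine.branch_ids])
    if site_params is not None:
        fg = foreground if foreground is not None else frozenset(engine.tree.marked_branches())
        return engine.lnl_branch_site(
            kappa, ts, site_params["p0"], site_params["p1"],
            site_params["omega0"], site_params["omega2"], frozenset(fg),
        )
    if isinstance(omegas, dict):
        w = np.array([omegas[b] for b in engine.branch_ids])
    else:
        w = np.full(len(engine.branch_ids), float(omegas))
    return engine.lnl_branch(kappa, ts, w)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _nested_kind(kind: str) -> str | None:
    return {
        "one_ratio": None,
        "two_ratio": "one_ratio",
        "free_ratio": "one_ratio",
        "branch_site_null": "one_ratio",
        "branch_site_A": "branch_site_null",
    }[kind]


def _softmax3(a: float, b: float) -> tuple[float, float]:
    m = max(a, b, 0.0)
    ea, eb, ec = math.exp(a - m), math.exp(b - m), math.exp(-m)
    z = ea + eb + ec
    return ea / z, eb / z


def _pack(spec: ModelSpec, engine: LikelihoodEngine, init: FittedModel | None,
          opts: FitOptions):
    """Build (x0, bounds, unpack) for the requested model class.

    All rate-like parameters are optimized on the log scale inside box
    bounds; the branch-site class proportions use two softmax logits.
    """
    B = len(engine.branch_ids)
    lo_t, hi_t = opts.t_bounds
    lo_k, hi_k = opts.kappa_bounds
    lo_w, hi_w = opts.omega_bounds

    kappa0 = init.kappa if init else 2.0
    if init:
        t0 = np.array([
            np.clip(init.branch_lengths.get(b, 0.1), lo_t * 2, hi_t / 2)
            for b in engine.branch_ids
        ])
    else:
        t0 = np.full(B, 0.1)

    def w_init(branch: str) -> float:
        if init and init.omegas is not None:
            return float(np.clip(init.omegas.get(branch, 0.2), lo_w * 2, hi_w / 2))
        return 0.2

    x_t = list(np.log(t0))
    bounds = [(math.log(lo_k), math.log(hi_k))] + [
        (math.log(lo_t), math.log(hi_t))
    ] * B
    x0 = [math.log(kappa0)] + x_t
    t_slice = slice(1, 1 + B)

    if spec.kind == "one_ratio":
        x0 += [math.log(w_init(engine.branch_ids[0]))]
        bounds += [(math.log(lo_w), math.log(hi_w))]

        def unpack(x):
            ts = np.exp(x[t_slice])
            w = np.full(B, math.exp(x[-1]))
            return math.exp(x[0]), ts, {"omegas": w}

    elif spec.kind == "free_ratio":
        x0 += [math.log(w_init(b)) for b in engine.branch_ids]
        bounds += [(math.log(lo_w), math.log(hi_w))] * B

        def unpack(x):
            ts = np.exp(x[t_slice])
            w = np.exp(x[1 + B : 1 + 2 * B])
            return math.exp(x[0]), ts, {"omegas": w}

    elif spec.kind == "two_ratio":
        fg_mask = np.array([b in spec.foreground for b in engine.branch_ids])
        if not fg_mask.any():
            raise ValueError("foreground branches not present in tree")
        x0 += [math.log(w_init(engine.branch_ids[0]))] * 2
        bounds += [(math.log(lo_w), math.log(hi_w))] * 2

        def unpack(x):
            ts = np.exp(x[t_slice])
            w_back, w_fore = math.exp(x[-2]), math.exp(x[-1])
            w = np.where(fg_mask, w_fore, w_back)
            return math.exp(x[0]), ts, {"omegas": w}

    else:  # branch-site A / null
        free_w2 = spec.kind == "branch_site_A"
        if init and init.site_params:
            p0i = init.site_params["p0"]
            p1i = init.site_params["p1"]
            w0i = init.site_params["omega0"]
            w2i = init.site_params.get("omega2", 2.0)
            if w2i <= 1.01:  # null fixes omega2=1; start the free fit off the bound
                w2i = 2.0
        else:
            p0i, p1i = 0.75, 0.2
            w0i = min(w_init(engine.branch_ids[0]), 0.9)
            w2i = 2.0
        rest = max(1e-3, 1.0 - p0i - p1i)
        a0 = math.log(max(p0i, 1e-3) / rest)
        b0 = math.log(max(p1i, 1e-3) / rest)
        x0 += [a0, b0, math.log(np.clip(w0i, lo_w * 2, 0.999))]
        bounds += [(-12.0, 12.0), (-12.0, 12.0), (math.log(lo_w), 0.0)]
        if free_w2:
            x0 += [math.log(np.clip(w2i, 1.001, hi_w / 2))]
            bounds += [(0.0, math.log(hi_w))]

        def unpack(x):
            ts = np.exp(x[t_slice])
            k = 1 + B
            p0, p1 = _softmax3(x[k], x[k + 1])
            w0 = math.exp(x[k + 2])
            w2 = math.exp(x[k + 3]) if free_w2 else 1.0
            return math.exp(x[0]), ts, {
                "site": (p0, p1, w0, w2)
            }

    return np.array(x0), bounds, unpack


def fit_model(
    aln: CodonAlignment,
    tree: PhyloTree,
    spec: ModelSpec,
    options: FitOptions | None = None,
    init: FittedModel | None = None,
    engine: LikelihoodEngine | None = None,
) -> FittedModel:
    """Maximize the codon-model likelihood with bounded quasi-Newton search.

    When no explicit ``init`` is given the nested simpler model is fitted
    first (one restart) and seeds the search; ``options.n_restarts - 1``
    additional deterministically perturbed starts guard against local
    optima. Non-convergence is reported through the ``converged`` flag,
    not an exception.
    """
    opts = options or FitOptions()
    if aln.n_codons < 1:
        raise ValueError("alignment shorter than one codon")
    if engine is None:
        freqs = (
            CodonFrequencies.uniform()
            if spec.freq_source == "uniform"
            else CodonFrequencies.from_alignment(aln, spec.freq_source)
        )
        engine = LikelihoodEngine(aln, tree, freqs=freqs)

    if init is None:
        nested = _nested_kind(spec.kind)
        if nested is not None:
            nested_fg = spec.foreground if nested in _NEEDS_FOREGROUND else frozenset()
            nested_spec = ModelSpec(nested, nested_fg, spec.freq_source)
            nested_opts = FitOptions(
                n_restarts=1, seed=opts.seed, maxiter=opts.maxiter,
                ftol=opts.ftol, gtol=opts.gtol,
                omega_bounds=opts.omega_bounds, t_bounds=opts.t_bounds,
                kappa_bounds=opts.kappa_bounds,
            )
            init = fit_model(aln, tree, nested_spec, nested_opts, engine=engine)

    x0, bounds, unpack = _pack(spec, engine, init, opts)
    fg = frozenset(spec.foreground)

    def negloglik(x):
        kappa, ts, rest = unpack(x)
        try:
            if "omegas" in rest:
                val = engine.lnl_branch(kappa, ts, rest["omegas"])
            else:
                p0, p1, w0, w2 = rest["site"]
                val = engine.lnl_branch_site(kappa, ts, p0, p1, w0, w2, fg)
        except (ValueError, np.linalg.LinAlgError):
            return 1e12
        if not np.isfinite(val):
            return 1e12
        return -val

    best = None
    converged = False
    rng = np.random.default_rng(opts.seed)
    n_used = 0
    for r in range(max(1, opts.n_restarts)):
        start = x0 if r == 0 else np.clip(
            x0 + rng.normal(0.0, 0.4, size=x0.shape),
            [b[0] for b in bounds],
            [b[1] for b in bounds],
        )
        res = optimize.minimize(
            negloglik,
            start,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": opts.maxiter, "ftol": opts.ftol, "gtol": opts.gtol},
        )
        n_used = r + 1
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        converged = converged or bool(res.success)

    kappa, ts, rest = unpack(best.x)
    branch_lengths = dict(zip(engine.branch_ids, map(float, ts)))
    omegas = site_params = None
    if "omegas" in rest:
        omegas = dict(zip(engine.branch_ids, map(float, rest["omegas"])))
    else:
        p0, p1, w0, w2 = rest["site"]
        rest_p = max(0.0, 1.0 - p0 - p1)
        site_params = {
            "p0": p0, "p1": p1, "omega0": w0, "omega2": w2,
            "p2a": rest_p * p0 / (p0 + p1), "p2b": rest_p * p1 / (p0 + p1),
        }

    at_bounds = []
    names = _param_names(spec, engine)
    for name, xi, (lo, hi) in zip(names, best.x, bounds):
        if min(xi - lo, hi - xi) < 1e-6:
            at_bounds.append(name)

    return FittedModel(
        spec=spec,
        kappa=float(kappa),
        branch_lengths=branch_lengths,
        omegas=omegas,
        site_params=site_params,
        lnL=float(-best.fun),
        n_free_params=len(best.x),
        converged=converged,
        n_restarts_used=n_used,
        freqs=engine.freqs,
        at_bounds=at_bounds,
    )


def _param_names(spec: ModelSpec, engine: LikelihoodEngine) -> list[str]:
    names = ["kappa"] + [f"t:{b}" for b in engine.branch_ids]
    if spec.kind == "one_ratio":
        names += ["omega"]
    elif spec.kind == "free_ratio":
        names += [f"omega:{b}" for b in engine.branch_ids]
    elif spec.kind == "two_ratio":
        names += ["omega_back", "omega_fore"]
    else:
        names += ["p_logit0", "p_logit1", "omega0"]
        if spec.kind == "branch_site_A":
            names += ["omega2"]
    return names


# ---------------------------------------------------------------------------
# branch measures and LRT
# ---------------------------------------------------------------------------


def _syn_flux_fraction(
    kappa: float, omega: float, freqs: CodonFrequencies,
    code: GeneticCode = STANDARD_CODE,
) -> float:
    """Fraction of the (normalized) substitution flux that is synonymous."""
    Q = build_rate_matrix(kappa, omega, freqs, code)
    flux = freqs.pi[:, None] * Q.Q
    syn = flux[code.single_step & ~code.is_nonsyn].sum()
    nonsyn = flux[code.single_step & code.is_nonsyn].sum()
    return syn / (syn + nonsyn)


def branch_measures(
    fit: FittedModel, L_codons: int, code: GeneticCode = STANDARD_CODE
) -> dict[str, BranchMeasures]:
    """Per-branch t, omega, dN, dS, site counts and synonymous-event counts
    from a free-ratio fit.

    Synonymous/nonsynonymous site counts partition the 3*L nucleotide
    sites by the neutral (omega = 1) flux fractions, so dN/dS equals the
    fitted omega exactly.
    """
    if fit.spec.kind != "free_ratio":
        raise ValueError("branch_measures requires a free-ratio fit")
    pS1 = _syn_flux_fraction(fit.kappa, 1.0, fit.freqs, code)
    if pS1 <= 0 or pS1 >= 1:
        raise ValueError("degenerate alignment: no synonymous or no nonsynonymous flux")
    S = 3.0 * L_codons * pS1
    N = 3.0 * L_codons * (1.0 - pS1)
    out: dict[str, BranchMeasures] = {}
    for bid, t in fit.branch_lengths.items():
        omega = fit.omegas[bid]
        rhoS = _syn_flux_fraction(fit.kappa, omega, fit.freqs, code)
        dS = t * rhoS / (3.0 * pS1)
        dN = t * (1.0 - rhoS) / (3.0 * (1.0 - pS1))
        out[bid] = BranchMeasures(
            branch_id=bid, t=float(t), omega=float(omega),
            dN=float(dN), dS=float(dS), N=N, S=S, syn_events=float(S * dS),
        )
    return out


def lrt(fit_null: FittedModel, fit_alt: FittedModel, df: int | None = None) -> LRTResult:
    """Likelihood-ratio test of nested fits: 2*dlnL against chi-square.

    A tiny negative 2*dlnL from numerical noise is clamped to zero. ``df``
    defaults to the difference in free-parameter counts.
    """
    if df is None:
        df = fit_alt.n_free_params - fit_null.n_free_params
    if df < 1:
        raise ValueError("degrees of freedom must be >= 1")
    stat = max(0.0, 2.0 * (fit_alt.lnL - fit_null.lnL))
    p = float(stats.chi2.sf(stat, df))
    return LRTResult(stat=stat, df=int(df), p=p)
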