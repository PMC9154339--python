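"""Codon site-model likelihoods: M1a vs M2a and empirical-Bayes site counts.

A Goldman-Yang-style codon substitution process is defined on the 61 sense
codons: only single-nucleotide changes have nonzero rate, transitions are
weighted ``kappa``, nonsynonymous changes ``omega``, and the target codon's
stationary frequency ``pi_j`` multiplies every rate.  Site-to-site variation
in selective pressure is modeled as a mixture over site classes:

* M1a (nearly neutral): a conserved class (proportion ``p0``, ``omega0 < 1``)
  and a neutral class (``p1``, ``omega1 = 1``).
* M2a (positive selection): adds a selected class (``p2``, ``omega2 >= 1``).

Both models are fit by maximizing the Felsenstein pruning likelihood over
kappa, branch lengths and class parameters; twice the log-likelihood gain of
M2a is referred to a chi-square with 2 degrees of freedom (the standard,
slightly conservative, null for this boundary case).  A2 = p2 * L is the
implied number of adaptive codons; A2' counts codons whose empirical-Bayes
posterior probability of the selected class (NEB, evaluated at the MLEs)
exceeds a threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import dendropy
import numpy as np
from scipy import optimize, stats

from .counting import CodonAlignment
from .genetics import NUCS, is_transition, sense_codons, translate_codon

__all__ = [
    "CodonModel",
    "PhyloTree",
    "SiteModelFit",
    "build_rate_matrix",
    "transition_probability",
    "pruning_loglik",
    "fit_site_models",
    "lrt_pvalue",
    "site_posteriors",
    "f1x4_frequencies",
    "f3x4_frequencies",
]

OMEGA_MAX = 50.0


# ---------------------------------------------------------------------------
# model structure


@lru_cache(maxsize=None)
def _structure(table_id: int = 1):
    """Static 61x61 masks: single-nt difference, transition, synonymous."""
    codons = sense_codons(table_id)
    n = len(codons)
    diff = np.zeros((n, n), dtype=bool)
    ts = np.zeros((n, n), dtype=bool)
    syn = np.zeros((n, n), dtype=bool)
    for i, ci in enumerate(codons):
        for j, cj in enumerate(codons):
            if i == j:
                continue
            mismatches = [k for k in range(3) if ci[k] != cj[k]]
            if len(mismatches) != 1:
                continue
            k = mismatches[0]
            diff[i, j] = True
            ts[i, j] = is_transition(ci[k], cj[k])
            syn[i, j] = translate_codon(ci, table_id) == translate_codon(cj, table_id)
    index = {c: i for i, c in enumerate(codons)}
    return codons, index, diff, ts, syn


@dataclass(frozen=True)
class CodonModel:
    """One site class: kappa, omega and stationary codon frequencies."""

    kappa: float
    omega: float
    pi: np.ndarray
    table_id: int = 1

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        if pi.ndim != 1 or len(pi) != len(sense_codons(self.table_id)):
            raise ValueError("pi must have one entry per sense codon")
        if np.any(pi <= 0):
            raise ValueError("stationary frequencies must be positive")
        object.__setattr__(self, "pi", pi / pi.sum())
        if self.kappa <= 0 or self.omega < 0:
            raise ValueError("kappa must be > 0 and omega >= 0")


def build_rate_matrix(model: CodonModel, scale: bool = True) -> np.ndarray:
    """61x61 rate matrix; rows sum to 0; mean rate 1 at stationarity if scaled."""
    _, _, diff, ts, syn = _structure(model.table_id)
    mult = np.where(ts, model.kappa, 1.0) * np.where(syn, 1.0, model.omega)
    q = np.where(diff, mult, 0.0) * model.pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    if scale:
        mu = -(model.pi * np.diag(q)).sum()
        if mu > 0:
            q = q / mu
    return q


class _EigQ:
    """Eigendecomposition of the (unscaled) reversible rate matrix."""

    __slots__ = ("w", "u", "sqrt_pi", "inv_sqrt_pi", "mu")

    def __init__(self, model: CodonModel):
        q = build_rate_matrix(model, scale=False)
        self.mu = -(model.pi * np.diag(q)).sum()
        sqrt_pi = np.sqrt(model.pi)
        b = (sqrt_pi[:, None] * q) / sqrt_pi[None, :]
        b = (b + b.T) / 2.0
        self.w, self.u = np.linalg.eigh(b)
        self.sqrt_pi = sqrt_pi
        self.inv_sqrt_pi = 1.0 / sqrt_pi

    def transition(self, t: float) -> np.ndarray:
        """P(t) = exp(Q t) for the unscaled Q."""
        m = (self.u * np.exp(self.w * t)) @ self.u.T
        p = (self.inv_sqrt_pi[:, None] * m) * self.sqrt_pi[None, :]
        np.clip(p, 0.0, None, out=p)
        return p


class _EigCache:
    """Memoize eigendecompositions by (kappa, omega); pi is fixed per cache."""

    def __init__(self, pi: np.ndarray, table_id: int = 1):
        self.pi = pi
        self.table_id = table_id
        self._store: dict[tuple[float, float], _EigQ] = {}

    def get(self, kappa: float, omega: float) -> _EigQ:
        key = (float(kappa), float(omega))
        eig = self._store.get(key)
        if eig is None:
            eig = _EigQ(CodonModel(kappa, omega, self.pi, self.table_id))
            if len(self._store) > 4096:
                self._store.clear()
            self._store[key] = eig
        return eig


def transition_probability(model: CodonModel, t: float, scale: bool = True) -> np.ndarray:
    """exp(Q t) for one site class (Q mean-rate-scaled by default)."""
    eig = _EigQ(model)
    if scale and eig.mu > 0:
        t = t / eig.mu
    return eig.transition(t)


# ---------------------------------------------------------------------------
# trees


class PhyloTree:
    """A phylogeny prepared for pruning: postorder arrays over a dendropy tree.

    Branch lengths are expected substitutions per codon.  Trees whose root has
    exactly two children are derooted (the basal bifurcation is collapsed) so
    that branch lengths are identifiable under the reversible model.
    """

    def __init__(self, tree: dendropy.Tree, deroot: bool = True):
        tree = tree.clone(depth=1)
        leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if deroot and len(leaves) >= 3 and len(tree.seed_node.child_nodes()) == 2:
            tree.deroot()
        self._dtree = tree
        nodes = list(tree.postorder_node_iter())
        self.n_nodes = len(nodes)
        self._node_id = {id(nd): i for i, nd in enumerate(nodes)}
        self.children: list[list[int]] = [[] for _ in nodes]
        self.leaf_row = np.full(self.n_nodes, -1, dtype=int)
        self.leaf_names: list[str] = []
        blen = np.full(self.n_nodes, np.nan)
        for i, nd in enumerate(nodes):
            for ch in nd.child_nodes():
                self.children[i].append(self._node_id[id(ch)])
            if nd.is_leaf():
                self.leaf_row[i] = len(self.leaf_names)
                self.leaf_names.append(nd.taxon.label)
            if nd.parent_node is not None:
                blen[i] = nd.edge.length if nd.edge.length is not None else 0.1
        self.root = self.n_nodes - 1
        self.branch_nodes = np.array(
            [i for i in range(self.n_nodes) if i != self.root], dtype=int
        )
        self.branch_lengths = blen[self.branch_nodes].copy()

    @classmethod
    def from_newick(cls, source: str | Path, deroot: bool = True) -> "PhyloTree":
        if isinstance(source, Path) or (isinstance(source, str) and Path(source).is_file()):
            tree = dendropy.Tree.get(path=str(source), schema="newick")
        else:
            tree = dendropy.Tree.get(data=source, schema="newick")
        return cls(tree, deroot=deroot)

    @property
    def n_branches(self) -> int:
        return len(self.branch_nodes)

    def with_branch_lengths(self, blens: np.ndarray) -> "PhyloTree":
        out = PhyloTree(self._dtree, deroot=False)
        out.branch_lengths = np.asarray(blens, dtype=float).copy()
        return out


def _pattern_compress(tree: PhyloTree, aln: CodonAlignment):
    """Map the alignment onto the tree's leaf order and compress codon columns."""
    codons, index, *_ = _structure(aln.table_id)
    if set(tree.leaf_names) != set(aln.names):
        raise ValueError(
            f"tree leaves {sorted(tree.leaf_names)} do not match alignment names {sorted(aln.names)}"
        )
    rows = []
    for name in tree.leaf_names:
        seq = aln[name]
        rows.append(
            [index.get(seq[3 * i : 3 * i + 3], -1) for i in range(aln.n_codons)]
        )
    mat = np.asarray(rows, dtype=np.int16)  # (n_leaves, n_sites); -1 = missing
    patterns, site_to_pattern, counts = np.unique(
        mat.T, axis=0, return_inverse=True, return_counts=True
    )
    return patterns.T.copy(), counts.astype(float), site_to_pattern


def _class_site_likelihood(tree, patterns, eig, blens, rate_scale, pi):
    """Per-pattern likelihood under one site class (vector over patterns)."""
    n_states = len(pi)
    n_pat = patterns.shape[1]
    partial = [None] * tree.n_nodes
    blen_of = np.full(tree.n_nodes, np.nan)
    blen_of[tree.branch_nodes] = blens
    for node in range(tree.n_nodes):
        if tree.leaf_row[node] >= 0:
            idx = patterns[tree.leaf_row[node]]
            lk = np.zeros((n_states, n_pat))
            present = idx >= 0
            lk[idx[present], np.nonzero(present)[0]] = 1.0
            lk[:, ~present] = 1.0
            partial[node] = lk
        else:
            lk = np.ones((n_states, n_pat))
            for ch in tree.children[node]:
                p = eig.transition(blen_of[ch] * rate_scale)
                lk *= p @ partial[ch]
                partial[ch] = None
            partial[node] = lk
    return pi @ partial[tree.root]


def _mixture_loglik(tree, patterns, counts, cache, pi, classes, blens):
    """lnL of a site-class mixture; branch lengths in subs/codon (mixture mean)."""
    weights = np.array([w for w, _, _ in classes])
    mus = np.array([cache.get(k, o).mu for _, k, o in classes])
    mean_rate = float(weights @ mus)
    if mean_rate <= 0:
        return -np.inf, None
    site_lik = np.zeros(patterns.shape[1])
    per_class = []
    for (w, kappa, omega), mu in zip(classes, mus):
        eig = cache.get(kappa, omega)
        lk = _class_site_likelihood(tree, patterns, eig, blens, 1.0 / mean_rate, pi)
        per_class.append(lk)
        site_lik += w * lk
    if np.any(site_lik <= 0):
        return -np.inf, per_class
    return float(counts @ np.log(site_lik)), per_class


def pruning_loglik(
    tree: PhyloTree,
    aln: CodonAlignment,
    classes: list[tuple[float, CodonModel]],
) -> float:
    """Log-likelihood of a codon alignment under a site-class mixture.

    ``classes`` is a list of ``(weight, CodonModel)``; weights must sum to 1
    and all classes share the same pi.  Branch lengths are taken from the
    tree, in expected substitutions per codon averaged over the mixture.
    """
    weights = [w for w, _ in classes]
    if abs(sum(weights) - 1.0) > 1e-8:
        raise ValueError("class weights must sum to 1")
    pi = classes[0][1].pi
    cache = _EigCache(pi, classes[0][1].table_id)
    patterns, counts, _ = _pattern_compress(tree, aln)
    spec = [(w, m.kappa, m.omega) for w, m in classes]
    lnl, _ = _mixture_loglik(tree, patterns, counts, cache, pi, spec, tree.branch_lengths)
    return lnl


# ---------------------------------------------------------------------------
# frequencies


def f1x4_frequencies(aln: CodonAlignment) -> np.ndarray:
    """Codon frequencies from overall nucleotide frequencies (F1x4)."""
    codons, *_ = _structure(aln.table_id)
    counts = {b: 1.0 for b in NUCS}  # +1 pseudocount
    for seq in aln.sequences:
        for b in seq:
            if b in counts:
                counts[b] += 1.0
    total = sum(counts.values())
    nuc = {b: c / total for b, c in counts.items()}
    pi = np.array([nuc[c[0]] * nuc[c[1]] * nuc[c[2]] for c in codons])
    return pi / pi.sum()


def f3x4_frequencies(aln: CodonAlignment) -> np.ndarray:
    """Codon frequencies from position-specific nucleotide frequencies (F3x4)."""
    codons, *_ = _structure(aln.table_id)
    counts = [{b: 1.0 for b in NUCS} for _ in range(3)]
    for seq in aln.sequences:
        for i, b in enumerate(seq):
            if b in NUCS:
                counts[i % 3][b] += 1.0
    freqs = []
    for pos in counts:
        tot = sum(pos.values())
        freqs.append({b: c / tot for b, c in pos.items()})
    pi = np.array([freqs[0][c[0]] * freqs[1][c[1]] * freqs[2][c[2]] for c in codons])
    return pi / pi.sum()


def uniform_frequencies(table_id: int = 1) -> np.ndarray:
    n = len(sense_codons(table_id))
    return np.full(n, 1.0 / n)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class SiteModelFit:
    """M1a and M2a fits plus the LRT and adaptive-site summaries."""

    lnl_m1a: float
    lnl_m2a: float
    m1a: dict
    m2a: dict
    lrt_stat: float
    p_value: float
    a2: float
    a2prime: int
    n_codons: int
    pi_mode: str
    converged: bool
    seed: int
    notes: list[str] = field(default_factory=list)


def lrt_pvalue(lnl0: float, lnl1: float, df: int = 2, tol: float = 1e-6) -> float:
    """Upper chi-square tail at 2*(lnl1 - lnl0); small negatives clamp to 0."""
    stat = 2.0 * (lnl1 - lnl0)
    if stat < -2.0 * tol:
        raise ValueError(
            f"alternative log-likelihood below null by {-stat / 2:.3g}: optimizer failure"
        )
    return float(stats.chi2.sf(max(stat, 0.0), df))


def _initial_branch_lengths(tree: PhyloTree, aln: CodonAlignment) -> np.ndarray:
    seqs = [aln[n] for n in tree.leaf_names]
    diffs = []
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            a, b = seqs[i], seqs[j]
            comp = [(x, y) for x, y in zip(a, b) if x in NUCS and y in NUCS]
            if comp:
                diffs.append(sum(x != y for x, y in comp) / len(comp))
    mean_diff = float(np.mean(diffs)) if diffs else 0.1
    t0 = max(3.0 * mean_diff / max(tree.n_branches, 1) * 2.0, 0.02)
    return np.full(tree.n_branches, t0)


_KAPPA_BOUNDS = (math.log(0.05), math.log(50.0))
_T_BOUNDS = (math.log(1e-6), math.log(30.0))
_EPS = 1e-7


def _fit_one(neg, x0, bounds, maxiter):
    return optimize.minimize(
        neg, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": maxiter, "maxfun": 20 * maxiter},
    )


def fit_site_models(
    tree: PhyloTree,
    aln: CodonAlignment,
    pi_mode: str = "f1x4",
    n_restarts: int = 2,
    seed: int = 0,
    maxiter: int = 300,
    posterior_threshold: float = 0.5,
) -> SiteModelFit:
    """Maximum-likelihood M1a and M2a fits with the M1a-vs-M2a LRT.

    Kappa, all branch lengths and the class parameters are optimized jointly
    (L-BFGS-B on log/bounded coordinates).  M2a is seeded at the M1a solution
    with a vanishing selected class, plus ``n_restarts`` random restarts, so
    ``lnl_m2a >= lnl_m1a - 1e-6`` by construction.  Non-convergence is
    flagged on the result, not raised.
    """
    if len(aln.names) < 3:
        raise ValueError("site models need at least 3 sequences")
    if pi_mode == "f1x4":
        pi = f1x4_frequencies(aln)
    elif pi_mode == "f3x4":
        pi = f3x4_frequencies(aln)
    elif pi_mode == "uniform":
        pi = uniform_frequencies(aln.table_id)
    else:
        raise ValueError(f"unknown pi_mode {pi_mode!r}")
    cache = _EigCache(pi, aln.table_id)
    patterns, counts, site_to_pattern = _pattern_compress(tree, aln)
    rng = np.random.default_rng(seed)
    nb = tree.n_branches
    t0 = np.log(_initial_branch_lengths(tree, aln))
    notes: list[str] = []

    def m1a_classes(x):
        kappa = math.exp(x[0])
        p0, w0 = x[nb + 1], x[nb + 2]
        return [(p0, kappa, w0), (1.0 - p0, kappa, 1.0)]

    def m2a_classes(x):
        kappa = math.exp(x[0])
        p0, w0, p2, w2 = x[nb + 1], x[nb + 2], x[nb + 3], x[nb + 4]
        p0_eff = p0 * (1.0 - p2)
        p1 = 1.0 - p0_eff - p2
        return [(p0_eff, kappa, w0), (p1, kappa, 1.0), (p2, kappa, w2)]

    def make_neg(classes_of):
        def neg(x):
            blens = np.exp(x[1 : nb + 1])
            lnl, _ = _mixture_loglik(
                tree, patterns, counts, cache, pi, classes_of(x), blens
            )
            return -lnl if np.isfinite(lnl) else 1e12

        return neg

    neg1 = make_neg(m1a_classes)
    b1 = [_KAPPA_BOUNDS] + [_T_BOUNDS] * nb + [(_EPS, 1 - _EPS), (_EPS, 1 - _EPS)]
    x0 = np.concatenate([[math.log(2.0)], t0, [0.7, 0.2]])
    starts = [x0]
    for _ in range(n_restarts):
        xr = x0.copy()
        xr[: nb + 1] += rng.normal(0, 0.5, nb + 1)
        xr[nb + 1] = rng.uniform(0.2, 0.95)
        xr[nb + 2] = rng.uniform(0.02, 0.8)
        starts.append(xr)
    best1 = None
    converged = True
    for s in starts:
        res = _fit_one(neg1, s, b1, maxiter)
        if best1 is None or res.fun < best1.fun:
            best1 = res
    converged &= bool(best1.success)
    lnl1 = -best1.fun
    x1 = best1.x
    m1a = {
        "kappa": math.exp(x1[0]),
        "branch_lengths": np.exp(x1[1 : nb + 1]),
        "p0": float(x1[nb + 1]),
        "omega0": float(x1[nb + 2]),
        "p1": float(1 - x1[nb + 1]),
        "omega1": 1.0,
    }

    neg2 = make_neg(m2a_classes)
    b2 = b1 + [(_EPS, 1 - _EPS), (1.0 + 1e-6, OMEGA_MAX)]
    x0_2 = np.concatenate([x1, [0.02, 3.0]])
    starts2 = [x0_2]
    for _ in range(n_restarts):
        xr = x0_2.copy()
        xr[: nb + 1] += rng.normal(0, 0.3, nb + 1)
        xr[nb + 3] = rng.uniform(0.01, 0.3)
        xr[nb + 4] = rng.uniform(1.5, 10.0)
        starts2.append(xr)
    best2 = None
    for s in starts2:
        res = _fit_one(neg2, s, b2, maxiter)
        if best2 is None or res.fun < best2.fun:
            best2 = res
    converged &= bool(best2.success)
    lnl2 = -best2.fun
    x2 = best2.x
    if lnl2 < lnl1:
        # The boundary p2 -> 0 reproduces M1a exactly; take that solution.
        lnl2 = lnl1
        x2 = np.concatenate([x1, [_EPS, 1.0 + 1e-6]])
        notes.append("M2a no better than M1a; selected class collapsed to the boundary")
    p2 = float(x2[nb + 3])
    p0_eff = float(x2[nb + 1]) * (1.0 - p2)
    m2a = {
        "kappa": math.exp(x2[0]),
        "branch_lengths": np.exp(x2[1 : nb + 1]),
        "p0": p0_eff,
        "omega0": float(x2[nb + 2]),
        "p1": float(1.0 - p0_eff - p2),
        "omega1": 1.0,
        "p2": p2,
        "omega2": float(x2[nb + 4]),
    }

    stat = max(2.0 * (lnl2 - lnl1), 0.0)
    p_value = lrt_pvalue(lnl1, lnl2)
    a2 = m2a["p2"] * aln.n_codons
    post = _selected_class_posteriors(
        tree, patterns, counts, site_to_pattern, cache, pi, m2a
    )
    a2prime = int(np.sum(post > posterior_threshold))
    return SiteModelFit(
        lnl_m1a=lnl1,
        lnl_m2a=lnl2,
        m1a=m1a,
        m2a=m2a,
        lrt_stat=stat,
        p_value=p_value,
        a2=a2,
        a2prime=a2prime,
        n_codons=aln.n_codons,
        pi_mode=pi_mode,
        converged=converged,
        seed=seed,
        notes=notes,
    )


def _m2a_class_spec(m2a: dict):
    k = m2a["kappa"]
    return [
        (m2a["p0"], k, m2a["omega0"]),
        (m2a["p1"], k, 1.0),
        (m2a["p2"], k, m2a["omega2"]),
    ]


def _selected_class_posteriors(tree, patterns, counts, site_to_pattern, cache, pi, m2a):
    classes = _m2a_class_spec(m2a)
    blens = np.asarray(m2a["branch_lengths"], dtype=float)
    _, per_class = _mixture_loglik(tree, patterns, counts, cache, pi, classes, blens)
    lik = np.stack(per_class)  # (3, n_patterns)
    weights = np.array([w for w, _, _ in classes])
    joint = weights[:, None] * lik
    total = joint.sum(axis=0)
    total[total <= 0] = np.nan
    post_sel = joint[2] / total
    return post_sel[site_to_pattern]


def site_posteriors(fit: SiteModelFit, tree: PhyloTree, aln: CodonAlignment) -> np.ndarray:
    """Per-codon NEB posterior of the selected (omega2) class at the M2a MLEs."""
    if fit.pi_mode == "f1x4":
        pi = f1x4_frequencies(aln)
    elif fit.pi_mode == "f3x4":
        pi = f3x4_frequencies(aln)
    else:
        pi = uniform_frequencies(aln.table_id)
    cache = _EigCache(pi, aln.table_id)
    patterns, counts, site_to_pattern = _pattern_compress(tree, aln)
    if fit.m2a["p2"] <= _EPS * 2:
        return np.zeros(aln.n_codons)
    return _selected_class_posteriors(
        tree, patterns, counts, site_to_pattern, cache, pi, fit.m2a
    )
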