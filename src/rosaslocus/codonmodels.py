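"""Codon site models of positive selection (GY94 mixture models).

The substitution process follows the Goldman–Yang codon model on the 61
sense codons: single-nucleotide changes occur at rate proportional to the
target codon frequency, multiplied by kappa for transitions and by omega
for non-synonymous changes; multi-nucleotide changes and changes through
stop codons are forbidden.  Site models mix omega across sites:

* M0    — one omega for all sites
* M1a   — nearly neutral: omega0 < 1 and omega1 = 1
* M2a   — M1a plus a positive-selection class omega2 > 1
* M7    — omega ~ Beta(p, q) on (0, 1), discretised into K classes
* M8    — M7 plus a positive-selection class omega_s > 1

Positive selection is inferred from the M2a–M1a and M8–M7 likelihood
ratio tests (2*dlnL ~ chi2, df=2) and sites are called from the
empirical-Bayes posterior of the positive class: NEB plugs in the MLEs;
BEB integrates the class posterior over a parameter grid.

Likelihoods are computed by Felsenstein pruning with per-site scaling;
the rate matrix is diagonalised in its reversible (symmetrised) form.
Branch lengths are measured in expected substitutions per codon under
the fitted mixture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
from scipy import optimize, special, stats

from .config import CODON_INDEX, CODON_TABLE, SENSE_CODONS, STOP_CODONS, is_transition
from .phylo import Alignment

logger = logging.getLogger(__name__)

N_CODONS = len(SENSE_CODONS)        # 61
DEFAULT_BETA_CLASSES = 10

# ---------------------------------------------------------------------------
# Static neighbour structure of the sense-codon graph
# ---------------------------------------------------------------------------

def _build_neighbors():
    rows, cols, ts_flags, syn_flags = [], [], [], []
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diff = [k for k in range(3) if ci[k] != cj[k]]
            if len(diff) != 1:
                continue
            k = diff[0]
            rows.append(i)
            cols.append(j)
            ts_flags.append(is_transition(ci[k], cj[k]))
            syn_flags.append(CODON_TABLE[ci] == CODON_TABLE[cj])
    return (np.array(rows), np.array(cols),
            np.array(ts_flags, dtype=bool), np.array(syn_flags, dtype=bool))


_NB_ROW, _NB_COL, _NB_TS, _NB_SYN = _build_neighbors()


# ---------------------------------------------------------------------------
# Model parameters
# ---------------------------------------------------------------------------

MODELS = ("M0", "M1a", "M2a", "M7", "M8")


@dataclass(frozen=True)
class SiteModelParams:
    """Parameters of one codon site model (only the fields the model uses
    are meaningful)."""

    model: str
    kappa: float = 2.0
    codon_freq: str = "equal"        # equal | F3x4
    omega: float = 0.5               # M0
    p0: float = 0.5                  # M1a/M2a: weight of omega0; M8: beta weight
    p1: float = 0.5                  # M2a: weight of the neutral class
    omega0: float = 0.1              # M1a/M2a purifying class
    omega2: float = 2.0              # M2a positive class
    beta_p: float = 0.5              # M7/M8
    beta_q: float = 0.5
    omega_s: float = 2.0             # M8 positive class
    n_beta_classes: int = DEFAULT_BETA_CLASSES

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.model in ("M7", "M8") and (self.beta_p <= 0 or self.beta_q <= 0):
            raise ValueError("beta shape parameters must be positive")
        if self.n_beta_classes < 3:
            raise ValueError("need at least 3 beta classes")
        for w in (self.omega, self.omega0, self.omega2, self.omega_s):
            if w < 0:
                raise ValueError("omega values must be >= 0")
        if self.model == "M1a" and not 0 <= self.p0 <= 1:
            raise ValueError("p0 must lie in [0, 1]")
        if self.model == "M2a":
            if min(self.p0, self.p1) < 0 or self.p0 + self.p1 > 1 + 1e-9:
                raise ValueError("class proportions must be >= 0 and sum to <= 1")
        if self.model == "M8" and not 0 <= self.p0 <= 1:
            raise ValueError("p0 must lie in [0, 1]")

    def class_distribution(self) -> tuple[np.ndarray, np.ndarray]:
        """(omega values, proportions) of the site mixture."""
        if self.model == "M0":
            return np.array([self.omega]), np.array([1.0])
        if self.model == "M1a":
            return np.array([self.omega0, 1.0]), np.array([self.p0, 1.0 - self.p0])
        if self.model == "M2a":
            p2 = max(1.0 - self.p0 - self.p1, 0.0)
            return (np.array([self.omega0, 1.0, self.omega2]),
                    np.array([self.p0, self.p1, p2]))
        cats = discretize_beta(self.beta_p, self.beta_q, self.n_beta_classes)
        if self.model == "M7":
            props = np.full(self.n_beta_classes, 1.0 / self.n_beta_classes)
            return cats, props
        # M8
        props = np.concatenate([
            np.full(self.n_beta_classes, self.p0 / self.n_beta_classes),
            [1.0 - self.p0],
        ])
        return np.concatenate([cats, [self.omega_s]]), props


def discretize_beta(p: float, q: float, k: int) -> np.ndarray:
    """Mean omega of k equal-probability categories of Beta(p, q)."""
    edges = special.betaincinv(p, q, np.linspace(0.0, 1.0, k + 1))
    mean_mass = special.betainc(p + 1.0, q, edges)     # scaled CDF of Beta(p+1, q)
    cat_means = (mean_mass[1:] - mean_mass[:-1]) * (p / (p + q)) * k
    return np.clip(cat_means, 1e-8, 1.0)


# ---------------------------------------------------------------------------
# Rate matrices and transition probabilities
# ---------------------------------------------------------------------------

def equal_codon_frequencies() -> np.ndarray:
    return np.full(N_CODONS, 1.0 / N_CODONS)


def f3x4_frequencies(aln: Alignment) -> np.ndarray:
    """Codon frequencies from position-specific nucleotide frequencies."""
    counts = np.full((3, 4), 1e-6)
    base_index = {b: k for k, b in enumerate("ACGT")}
    for row in aln.rows:
        for i in range(0, len(row), 3):
            codon = row[i:i + 3]
            for pos, base in enumerate(codon):
                if base in base_index:
                    counts[pos, base_index[base]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array([
        freqs[0, base_index[c[0]]] * freqs[1, base_index[c[1]]] * freqs[2, base_index[c[2]]]
        for c in SENSE_CODONS
    ])
    return pi / pi.sum()


def build_rate_matrix(omega: float, kappa: float, pi: np.ndarray) -> np.ndarray:
    """Unscaled GY94 rate matrix for one omega class."""
    q = np.zeros((N_CODONS, N_CODONS))
    rates = pi[_NB_COL] * np.where(_NB_TS, kappa, 1.0) * np.where(_NB_SYN, 1.0, omega)
    q[_NB_ROW, _NB_COL] = rates
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


class ClassMatrices:
    """Per-class eigendecompositions, scaled so the mixture-average rate is 1."""

    def __init__(self, omegas: np.ndarray, props: np.ndarray, kappa: float,
                 pi: np.ndarray):
        self.pi = pi
        qs = [build_rate_matrix(w, kappa, pi) for w in omegas]
        mean_rate = sum(p * (-np.dot(pi, np.diag(q))) for p, q in zip(props, qs))
        if mean_rate <= 0:
            mean_rate = 1.0
        sqrt_pi = np.sqrt(pi)
        self._decomp = []
        for q in qs:
            q = q / mean_rate
            sym = sqrt_pi[:, None] * q / sqrt_pi[None, :]
            w, u = np.linalg.eigh(0.5 * (sym + sym.T))
            self._decomp.append((w, u))
        self._sqrt_pi = sqrt_pi

    def transition(self, class_index: int, t: float) -> np.ndarray:
        w, u = self._decomp[class_index]
        inner = (u * np.exp(w * t)) @ u.T
        p = inner / self._sqrt_pi[:, None] * self._sqrt_pi[None, :]
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p


# ---------------------------------------------------------------------------
# Alignment and tree preparation
# ---------------------------------------------------------------------------

def encode_alignment(aln: Alignment, drop_gapped: bool = True) -> tuple[np.ndarray, list[int]]:
    """Codon alignment -> integer state matrix (n_seqs, n_sites); -1 = missing.

    Columns with any gap/ambiguous codon are dropped (logged) when
    ``drop_gapped``; stop codons are an error.
    """
    if aln.alphabet != "codon":
        raise ValueError("expected a codon alignment")
    n_sites = aln.length // 3
    states = np.full((len(aln), n_sites), -1, dtype=int)
    for r, row in enumerate(aln.rows):
        for s in range(n_sites):
            codon = row[3 * s: 3 * s + 3]
            if codon in STOP_CODONS:
                raise ValueError(f"stop codon {codon} in {aln.ids[r]!r} at codon column {s}")
            states[r, s] = CODON_INDEX.get(codon, -1)
    kept = list(range(n_sites))
    if drop_gapped:
        full = np.all(states >= 0, axis=0)
        dropped = int((~full).sum())
        if dropped:
            logger.info("dropping %d gapped/ambiguous codon columns", dropped)
        kept = [s for s in range(n_sites) if full[s]]
        states = states[:, full]
    if states.shape[1] == 0:
        raise ValueError("no usable codon columns")
    return states, kept


class TreeIndex:
    """Post-order traversal structure of a tree with editable branch lengths."""

    def __init__(self, tree: dendropy.Tree, tip_order: list[str]):
        tip_pos = {label: i for i, label in enumerate(tip_order)}
        self.nodes = []            # post-order: (children [(idx, edge_slot)], tip_index)
        self.edge_lengths = []     # initial lengths, one slot per non-root node
        index_of = {}
        tree_tips = {lf.taxon.label for lf in tree.leaf_node_iter()}
        if tree_tips != set(tip_order):
            raise ValueError("tree tips do not match alignment ids")
        for node in tree.postorder_node_iter():
            children = []
            for child in node.child_nodes():
                cidx = index_of[id(child)]
                children.append((cidx, self.nodes[cidx][2]))
            if node.is_leaf():
                tip_index = tip_pos[node.taxon.label]
            else:
                tip_index = -1
            if node.parent_node is not None:
                slot = len(self.edge_lengths)
                length = node.edge.length if node.edge.length is not None else 0.1
                self.edge_lengths.append(max(float(length), 1e-6))
            else:
                slot = -1
            index_of[id(node)] = len(self.nodes)
            self.nodes.append((children, tip_index, slot))
        self.n_edges = len(self.edge_lengths)
        self.root_index = len(self.nodes) - 1


def _site_class_likelihoods(states: np.ndarray, tree: TreeIndex,
                            branch_lengths: np.ndarray, mats: ClassMatrices,
                            n_classes: int) -> np.ndarray:
    """log L(site | class): array (n_classes, n_sites), pruning with scaling."""
    n_sites = states.shape[1]
    out = np.zeros((n_classes, n_sites))
    identity = np.ones((N_CODONS, n_sites))
    for k in range(n_classes):
        partial: list[np.ndarray] = [None] * len(tree.nodes)
        log_scale = np.zeros(n_sites)
        p_cache = {}
        for idx, (children, tip_index, _slot) in enumerate(tree.nodes):
            if tip_index >= 0:
                arr = np.zeros((N_CODONS, n_sites))
                site_states = states[tip_index]
                observed = site_states >= 0
                arr[site_states[observed], np.nonzero(observed)[0]] = 1.0
                arr[:, ~observed] = 1.0
                partial[idx] = arr
                continue
            acc = identity.copy() if not children else None
            for cidx, slot in children:
                t = branch_lengths[slot]
                key = (slot, k)
                if key not in p_cache:
                    p_cache[key] = mats.transition(k, t)
                term = p_cache[key] @ partial[cidx]
                acc = term if acc is None else acc * term
            mx = acc.max(axis=0)
            mx[mx <= 0] = 1.0
            acc /= mx
            log_scale += np.log(mx)
            partial[idx] = acc
        root = partial[tree.root_index]
        site_l = mats.pi @ root
        out[k] = np.log(np.clip(site_l, 1e-300, None)) + log_scale
    return out


def _mixture_loglik(log_class: np.ndarray, props: np.ndarray) -> tuple[float, np.ndarray]:
    """Total lnL and per-site class posteriors from per-class site log-liks."""
    logw = np.log(np.clip(props, 1e-300, None))[:, None] + log_class
    mx = logw.max(axis=0)
    site_log = mx + np.log(np.exp(logw - mx).sum(axis=0))
    post = np.exp(logw - site_log)
    return float(site_log.sum()), post.T        # (n_sites, n_classes)


# ---------------------------------------------------------------------------
# Fit result container
# ---------------------------------------------------------------------------

@dataclass
class SiteModelFit:
    params: SiteModelParams
    lnL: float
    converged: bool
    site_posteriors: np.ndarray                # (n_sites, n_classes), NEB
    omegas: np.ndarray
    proportions: np.ndarray
    branch_lengths: np.ndarray
    kept_columns: list[int]                    # codon columns used (pre-drop indices)
    n_sites: int
    beb_posteriors: np.ndarray | None = None   # positive-class BEB, (n_sites,)

    @property
    def positive_class_posterior(self) -> np.ndarray:
        """NEB posterior of the positive-selection class (zeros if none)."""
        pos = self.omegas > 1.0 + 1e-9
        if not pos.any():
            return np.zeros(self.n_sites)
        return self.site_posteriors[:, pos].sum(axis=1)


# ---------------------------------------------------------------------------
# Parameter transforms per model
# ---------------------------------------------------------------------------

def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p: float) -> float:
    p = min(max(p, 1e-6), 1 - 1e-6)
    return float(np.log(p / (1.0 - p)))


class _ModelSpec:
    """Mapping between the optimiser vector and SiteModelParams."""

    def __init__(self, model: str, base: SiteModelParams, fit_kappa: bool = True,
                 fit_scale: bool = True):
        self.model = model
        self.base = base
        self.fit_kappa = fit_kappa
        self.fit_scale = fit_scale

    def names(self) -> list[str]:
        names = []
        if self.fit_kappa:
            names.append("log_kappa")
        if self.fit_scale:
            names.append("log_scale")
        names += {
            "M0": ["log_omega"],
            "M1a": ["logit_p0", "logit_omega0"],
            "M2a": ["logit_p0", "logit_p1c", "logit_omega0", "log_omega2m1"],
            "M7": ["log_p", "log_q"],
            "M8": ["log_p", "log_q", "logit_p0", "log_omegasm1"],
        }[self.model]
        return names

    def initial(self, rng: np.random.Generator | None = None) -> np.ndarray:
        b = self.base
        vec = []
        if self.fit_kappa:
            vec.append(np.log(b.kappa))
        if self.fit_scale:
            vec.append(0.0)
        if self.model == "M0":
            vec.append(np.log(max(b.omega, 1e-4)))
        elif self.model == "M1a":
            vec += [_logit(b.p0), _logit(b.omega0)]
        elif self.model == "M2a":
            p2 = max(1 - b.p0 - b.p1, 1e-4)
            p1c = b.p1 / max(b.p1 + p2, 1e-9)
            vec += [_logit(b.p0), _logit(p1c), _logit(b.omega0),
                    np.log(max(b.omega2 - 1.0, 1e-3))]
        elif self.model == "M7":
            vec += [np.log(b.beta_p), np.log(b.beta_q)]
        else:
            vec += [np.log(b.beta_p), np.log(b.beta_q), _logit(b.p0),
                    np.log(max(b.omega_s - 1.0, 1e-3))]
        return np.array(vec, dtype=float)

    def random_start(self, rng: np.random.Generator) -> np.ndarray:
        """A dispersed start, independent of the base parameters (escapes
        the nested-model boundary where positive classes vanish)."""
        draw = {
            "log_kappa": lambda: rng.normal(np.log(2.0), 0.3),
            "log_scale": lambda: rng.normal(0.0, 0.4),
            "log_omega": lambda: rng.normal(-1.0, 1.0),
            "logit_p0": lambda: rng.normal(0.0, 1.0),
            "logit_p1c": lambda: rng.normal(0.0, 1.0),
            "logit_omega0": lambda: rng.normal(-2.0, 1.0),
            "log_omega2m1": lambda: rng.normal(0.7, 0.8),
            "log_p": lambda: rng.normal(0.0, 0.8),
            "log_q": lambda: rng.normal(0.0, 0.8),
            "log_omegasm1": lambda: rng.normal(0.7, 0.8),
        }
        return np.array([draw[name]() for name in self.names()])

    def to_params(self, vec: np.ndarray) -> tuple[SiteModelParams, float]:
        i = 0
        kappa = self.base.kappa
        scale = 1.0
        if self.fit_kappa:
            kappa = float(np.exp(np.clip(vec[i], -3, 4)))
            i += 1
        if self.fit_scale:
            scale = float(np.exp(np.clip(vec[i], -4, 4)))
            i += 1
        b = self.base
        if self.model == "M0":
            params = replace(b, model="M0", kappa=kappa,
                             omega=float(np.exp(np.clip(vec[i], -12, 4))))
        elif self.model == "M1a":
            params = replace(b, model="M1a", kappa=kappa,
                             p0=_sigmoid(vec[i]), omega0=_sigmoid(vec[i + 1]))
        elif self.model == "M2a":
            p0 = _sigmoid(vec[i])
            p1 = (1.0 - p0) * _sigmoid(vec[i + 1])
            params = replace(b, model="M2a", kappa=kappa, p0=p0, p1=p1,
                             omega0=_sigmoid(vec[i + 2]),
                             omega2=1.0 + float(np.exp(np.clip(vec[i + 3], -8, 5))))
        elif self.model == "M7":
            params = replace(b, model="M7", kappa=kappa,
                             beta_p=float(np.exp(np.clip(vec[i], -3, 4.6))),
                             beta_q=float(np.exp(np.clip(vec[i + 1], -3, 4.6))))
        else:
            params = replace(b, model="M8", kappa=kappa,
                             beta_p=float(np.exp(np.clip(vec[i], -3, 4.6))),
                             beta_q=float(np.exp(np.clip(vec[i + 1], -3, 4.6))),
                             p0=_sigmoid(vec[i + 2]),
                             omega_s=1.0 + float(np.exp(np.clip(vec[i + 3], -8, 5))))
        return params, scale


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _loglik_for(params: SiteModelParams, scale: float, states: np.ndarray,
                tindex: TreeIndex, base_lengths: np.ndarray,
                pi: np.ndarray) -> tuple[float, np.ndarray]:
    omegas, props = params.class_distribution()
    mats = ClassMatrices(omegas, props, params.kappa, pi)
    log_class = _site_class_likelihoods(states, tindex, base_lengths * scale,
                                        mats, len(omegas))
    return _mixture_loglik(log_class, props)


def fit_site_model(
    aln: Alignment,
    tree: dendropy.Tree,
    model: str,
    seed: int = 0,
    n_starts: int = 3,
    base_params: SiteModelParams | None = None,
    init_from: "SiteModelFit | None" = None,
    optimize_branches: bool = False,
    fit_kappa: bool = True,
    codon_freq: str = "equal",
) -> SiteModelFit:
    """Maximum-likelihood fit of one site model.

    Branch lengths are taken from the tree (fit them under M0 first with
    ``optimize_branches=True``, then reuse the fitted tree); a global
    tree-scale factor is always re-optimised per model.  Multi-start
    optimisation (seeded) guards against local optima; ``init_from``
    additionally seeds one start from a nested model's fit, which keeps
    the nested-model likelihood ordering (e.g. lnL(M2a) >= lnL(M1a)).
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    if len(aln) < 3:
        raise ValueError("need at least 3 sequences")
    states, kept = encode_alignment(aln)
    tindex = TreeIndex(tree, aln.ids)
    base_lengths = np.asarray(tree_branch_lengths(tree, aln.ids), dtype=float)
    pi = equal_codon_frequencies() if codon_freq == "equal" else f3x4_frequencies(aln)

    base = base_params or SiteModelParams(model=model, codon_freq=codon_freq)
    base = replace(base, model=model, codon_freq=codon_freq)
    if init_from is not None:
        base = _seed_from_nested(model, base, init_from)
    # with free branch lengths a global scale would be redundant
    spec = _ModelSpec(model, base, fit_kappa=fit_kappa, fit_scale=not optimize_branches)
    rng = np.random.default_rng(seed)

    n_extra = tindex.n_edges if optimize_branches else 0

    def objective(vec: np.ndarray) -> float:
        params, scale = spec.to_params(vec[:len(vec) - n_extra] if n_extra else vec)
        lengths = base_lengths
        if n_extra:
            lengths = np.exp(np.clip(vec[-n_extra:], -9, 3))
        try:
            lnl, _ = _loglik_for(params, scale, states, tindex, lengths, pi)
        except np.linalg.LinAlgError:
            return 1e10
        if not np.isfinite(lnl):
            return 1e10
        return -lnl

    best = None
    for start in range(n_starts):
        x0 = spec.initial() if start == 0 else spec.random_start(rng)
        if n_extra:
            x0 = np.concatenate([x0, np.log(np.clip(base_lengths, 1e-4, None))])
        res = optimize.minimize(objective, x0, method="L-BFGS-B",
                                options={"maxiter": 300, "ftol": 1e-9})
        if best is None or res.fun < best.fun:
            best = res

    vec = best.x
    params, scale = spec.to_params(vec[:len(vec) - n_extra] if n_extra else vec)
    if n_extra:
        lengths = np.exp(np.clip(vec[-n_extra:], -9, 3))
    else:
        lengths = base_lengths * scale
    omegas, props = params.class_distribution()
    mats = ClassMatrices(omegas, props, params.kappa, pi)
    log_class = _site_class_likelihoods(states, tindex, lengths, mats, len(omegas))
    lnl, post = _mixture_loglik(log_class, props)
    if post.shape[1] > 1 and np.allclose(log_class.std(axis=1), 0.0):
        logger.warning("alignment carries no variation; site-model fit is not identifiable")
    return SiteModelFit(
        params=params, lnL=lnl, converged=bool(best.success),
        site_posteriors=post, omegas=omegas, proportions=props,
        branch_lengths=lengths, kept_columns=kept, n_sites=states.shape[1],
    )


def _seed_from_nested(model: str, base: SiteModelParams,
                      nested: SiteModelFit) -> SiteModelParams:
    np_ = nested.params
    if model == "M2a" and np_.model == "M1a":
        return replace(base, kappa=np_.kappa, p0=np_.p0 * 0.999,
                       p1=(1 - np_.p0) * 0.999, omega0=np_.omega0, omega2=1.001)
    if model == "M8" and np_.model == "M7":
        return replace(base, kappa=np_.kappa, beta_p=np_.beta_p, beta_q=np_.beta_q,
                       p0=0.999, omega_s=1.001)
    if np_.model == "M0":
        return replace(base, kappa=np_.kappa)
    return base


def tree_branch_lengths(tree: dendropy.Tree, tip_order: list[str]) -> list[float]:
    """Branch lengths in the slot order used by TreeIndex."""
    tindex = TreeIndex(tree, tip_order)
    return list(tindex.edge_lengths)


def fit_branch_lengths_m0(aln: Alignment, tree: dendropy.Tree, seed: int = 0,
                          codon_freq: str = "equal") -> tuple[dendropy.Tree, SiteModelFit]:
    """Fit M0 with free branch lengths; returns (tree copy with fitted
    lengths in substitutions/codon, the M0 fit)."""
    fit = fit_site_model(aln, tree, "M0", seed=seed, n_starts=2,
                         optimize_branches=True, codon_freq=codon_freq)
    fitted = tree.clone(depth=1)
    # the clone's postorder matches the slot order used during fitting
    k = 0
    for node in fitted.postorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = float(fit.branch_lengths[k])
            k += 1
    return fitted, fit


# ---------------------------------------------------------------------------
# Likelihood-ratio test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LrtResult:
    null_model: str
    alt_model: str
    statistic: float
    df: int
    p_value: float


def lrt(null_fit: SiteModelFit, alt_fit: SiteModelFit, df: int = 2) -> LrtResult:
    """2*dlnL against chi-square; clamped at zero if optimiser noise makes
    the alternative apparently worse."""
    if null_fit.n_sites != alt_fit.n_sites:
        raise ValueError("fits are not on the same data")
    stat = 2.0 * (alt_fit.lnL - null_fit.lnL)
    if stat < 0:
        if stat < -1e-3:
            logger.warning("negative LRT statistic %.4g clamped to 0", stat)
        stat = 0.0
    return LrtResult(null_fit.params.model, alt_fit.params.model, stat, df,
                     float(stats.chi2.sf(stat, df)))


# ---------------------------------------------------------------------------
# BEB (grid integration over the positive-model parameters)
# ---------------------------------------------------------------------------

def beb_positive_posterior(aln: Alignment, tree: dendropy.Tree, fit: SiteModelFit,
                           grid: int = 8) -> np.ndarray:
    """Bayes-empirical-Bayes posterior of the positive class per site.

    Integrates the class posterior over a uniform grid on the mixture
    parameters (proportions and omegas for M2a; beta shapes, p0 and
    omega_s for M8), weighting each grid point by its data likelihood.
    kappa and branch lengths stay at their MLEs.
    """
    model = fit.params.model
    if model not in ("M2a", "M8"):
        raise ValueError("BEB applies to the positive-selection models M2a/M8")
    states, _ = encode_alignment(aln)
    tindex = TreeIndex(tree, aln.ids)
    pi = (equal_codon_frequencies() if fit.params.codon_freq == "equal"
          else f3x4_frequencies(aln))
    lengths = fit.branch_lengths
    kappa = fit.params.kappa

    cache: dict[float, np.ndarray] = {}

    def class_loglik(omega: float) -> np.ndarray:
        key = round(float(omega), 10)
        if key not in cache:
            mats = ClassMatrices(np.array([omega]), np.array([1.0]), kappa, pi)
            cache[key] = _site_class_likelihoods(states, tindex, lengths, mats, 1)[0]
        return cache[key]

    mixtures = []       # (log prior-weighted site matrix rows, positive flags)
    if model == "M2a":
        w0_grid = np.linspace(0.05, 0.95, grid)
        w2_grid = 1.0 + np.linspace(0.5, 8.0, grid)
        p_grid = np.linspace(0.05, 0.95, grid)
        for w0 in w0_grid:
            l0 = class_loglik(w0)
            l1 = class_loglik(1.0)
            for w2 in w2_grid:
                l2 = class_loglik(w2)
                for p0 in p_grid:
                    for p1c in p_grid:
                        p1 = (1 - p0) * p1c
                        p2 = 1 - p0 - p1
                        if p2 < 1e-6:
                            continue
                        mixtures.append(((np.array([p0, p1, p2]),
                                          np.vstack([l0, l1, l2])),
                                         np.array([False, False, True])))
    else:
        shp = np.exp(np.linspace(np.log(0.1), np.log(5.0), max(grid // 2, 3)))
        ws_grid = 1.0 + np.linspace(0.5, 8.0, grid)
        p0_grid = np.linspace(0.05, 0.95, grid)
        k = fit.params.n_beta_classes
        for p in shp:
            for q in shp:
                cats = discretize_beta(p, q, k)
                lcats = np.vstack([class_loglik(w) for w in cats])
                for ws in ws_grid:
                    ls = class_loglik(ws)
                    for p0 in p0_grid:
                        props = np.concatenate([np.full(k, p0 / k), [1 - p0]])
                        mixtures.append(((props, np.vstack([lcats, ls])),
                                         np.concatenate([np.zeros(k, bool), [True]])))

    n_sites = states.shape[1]
    log_marginals = np.empty(len(mixtures))
    pos_posts = np.empty((len(mixtures), n_sites))
    for idx, ((props, lclass), pos_mask) in enumerate(mixtures):
        lnl, post = _mixture_loglik(lclass, props)
        log_marginals[idx] = lnl
        pos_posts[idx] = post[:, pos_mask].sum(axis=1)
    log_marginals -= log_marginals.max()
    weights = np.exp(log_marginals)
    weights /= weights.sum()
    return weights @ pos_posts


# ---------------------------------------------------------------------------
# Site calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PositiveSiteCall:
    column: int                     # codon column in the (un-dropped) alignment
    reference_position: int | None  # 1-based residue number in the reference row
    neb_m2a: float
    neb_m8: float
    beb_m2a: float | None
    beb_m8: float | None
    called: bool


def call_positive_sites(
    fit_m1a: SiteModelFit,
    fit_m2a: SiteModelFit,
    fit_m7: SiteModelFit,
    fit_m8: SiteModelFit,
    aln: Alignment | None = None,
    reference_id: str | None = None,
    threshold: float = 0.90,
    rule: str = "NEB_only",          # NEB_only | NEB_and_BEB
    tree: dendropy.Tree | None = None,
) -> list[PositiveSiteCall]:
    """Sites in the positive class of both model comparisons.

    A site is called when its positive-class posterior exceeds the
    threshold under both M2a and M8 (and, with rule ``NEB_and_BEB``, under
    the BEB posteriors as well, which are computed on demand).  Columns
    are mapped to residue numbering of ``reference_id`` skipping gaps in
    that row.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    if rule not in ("NEB_only", "NEB_and_BEB"):
        raise ValueError(f"unknown rule {rule!r}")
    del fit_m1a, fit_m7     # part of the comparison workflow; calls use the alternatives
    neb2 = fit_m2a.positive_class_posterior
    neb8 = fit_m8.positive_class_posterior
    beb2 = beb8 = None
    if rule == "NEB_and_BEB":
        if aln is None or tree is None:
            raise ValueError("NEB_and_BEB needs the alignment and tree for BEB")
        if fit_m2a.beb_posteriors is None:
            fit_m2a.beb_posteriors = beb_positive_posterior(aln, tree, fit_m2a)
        if fit_m8.beb_posteriors is None:
            fit_m8.beb_posteriors = beb_positive_posterior(aln, tree, fit_m8)
        beb2, beb8 = fit_m2a.beb_posteriors, fit_m8.beb_posteriors

    ref_map: dict[int, int] = {}
    if aln is not None and reference_id is not None:
        row = aln.rows[aln.ids.index(reference_id)]
        residue = 0
        for col in range(aln.length // 3):
            codon = row[3 * col: 3 * col + 3]
            if codon != "---":
                residue += 1
                ref_map[col] = residue

    calls = []
    for local_idx, column in enumerate(fit_m2a.kept_columns):
        ok = neb2[local_idx] > threshold and neb8[local_idx] > threshold
        b2 = float(beb2[local_idx]) if beb2 is not None else None
        b8 = float(beb8[local_idx]) if beb8 is not None else None
        if rule == "NEB_and_BEB" and ok:
            ok = b2 > threshold and b8 > threshold
        if not ok:
            continue
        calls.append(PositiveSiteCall(
            column=column,
            reference_position=ref_map.get(column),
            neb_m2a=float(neb2[local_idx]), neb_m8=float(neb8[local_idx]),
            beb_m2a=b2, beb_m8=b8, called=True,
        ))
    return calls


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate_codon_alignment(
    tree: dendropy.Tree,
    params: SiteModelParams,
    n_codons: int,
    seed: int,
) -> tuple[Alignment, np.ndarray]:
    """Evolve a gap-free codon alignment along a tree under a site model.

    Sites evolve independently; each site draws its omega class from the
    model's mixture (recorded in the returned true-class array) and its
    root codon from the stationary distribution.
    """
    tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(tips) < 3:
        raise ValueError("tree must have at least 3 tips")
    if n_codons <= 0:
        raise ValueError("n_codons must be positive")
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None and (edge.length is None or edge.length <= 0):
            raise ValueError("all branch lengths must be positive")
    rng = np.random.default_rng(seed)
    omegas, props = params.class_distribution()
    pi = equal_codon_frequencies()
    mats = ClassMatrices(omegas, props, params.kappa, pi)

    classes = rng.choice(len(omegas), size=n_codons, p=props / props.sum())
    root_states = rng.choice(N_CODONS, size=n_codons, p=pi)

    states_at = {id(tree.seed_node): root_states}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent_states = states_at[id(node.parent_node)]
        child_states = np.empty(n_codons, dtype=int)
        for k in range(len(omegas)):
            mask = classes == k
            if not mask.any():
                continue
            p = mats.transition(k, float(node.edge.length))
            cum = np.cumsum(p, axis=1)
            u = rng.random(int(mask.sum()))
            rows = cum[parent_states[mask]]
            child_states[mask] = (rows < u[:, None]).sum(axis=1)
        states_at[id(node)] = child_states

    rows = []
    for lf in tree.leaf_node_iter():
        st = states_at[id(lf)]
        rows.append("".join(SENSE_CODONS[s] for s in st))
    aln = Alignment([lf.taxon.label for lf in tree.leaf_node_iter()], rows, "codon")
    return aln, classes
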