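"""Tree-based numerics.

* Brownian shared-path covariance (:func:`build_vcv`);
* Mk-model fitting by Felsenstein pruning and marginal tip imputation;
* phylogenetic logistic regression by Firth-penalised GEE scoring with a
  tree-derived working correlation ("logistic MPLE");
* phylogenetic Poisson GEE with log link;
* likelihood-based pseudo-R².

Correlation model
-----------------
Both regressions use the Ornstein–Uhlenbeck-with-fixed-root correlation

    R_ij(alpha) = exp(-alpha * d_ij) * (1 - exp(-2*alpha*s_ij))
                  / sqrt((1 - exp(-2*alpha*t_i)) * (1 - exp(-2*alpha*t_j)))

where s_ij is the shared root-to-MRCA path, t_i the root-to-tip depth and
d_ij = t_i + t_j - 2 s_ij the patristic distance, all on the
depth-normalised tree (branch lengths divided by the maximum depth).
alpha is the phylogenetic-signal parameter: alpha -> 0 recovers the
Brownian correlation s_ij / sqrt(t_i t_j); alpha -> infinity gives
independent tips.  A star phylogeny has s_ij = 0 and is therefore exactly
independent at every alpha.  alpha is profiled on a Gaussian
quasi-likelihood of the Pearson residuals, bounded in
[ALPHA_MIN, ALPHA_MAX] on the log scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np
from scipy.linalg import cho_factor, cho_solve, expm
from scipy.optimize import minimize, minimize_scalar
from scipy.special import expit, gammaln
from scipy.stats import norm

from .types import DielNiche, NICHE_ORDER, NICHE_TERMS, normalize_label

ALPHA_MIN = 1e-4
ALPHA_MAX = 1e6  # large enough that exp(-alpha*d) vanishes for the shortest cherries
#: selection margin (quasi-likelihood units) required to keep an interior
#: alpha over working independence
ALPHA_PENALTY = 2.0
#: convergence tolerance on the (penalised) objective
TOL = 1e-8
_JITTER = 1e-8


# ---------------------------------------------------------------------------
# Covariance construction


def _node_depths(tree: dendropy.Tree) -> dict:
    depths = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            bl = node.edge.length if node.edge.length is not None else 0.0
            if bl < 0:
                raise ValueError("negative branch length")
            depths[node] = depths[node.parent_node] + bl
    return depths


def build_vcv(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Shared-path (Brownian) covariance: C[i, j] = root-to-MRCA path length.

    Returns tip labels (normalised, in leaf-iteration order) and the
    symmetric PSD matrix with root-to-tip depths on the diagonal.
    """
    if tree.seed_node is None:
        raise ValueError("tree has no root")
    depths = _node_depths(tree)
    leaves = list(tree.leaf_node_iter())
    labels = [normalize_label(lf.taxon.label) for lf in leaves]
    index = {lf: i for i, lf in enumerate(leaves)}
    n = len(leaves)
    C = np.zeros((n, n))
    # For each internal node, its depth is the covariance of every leaf pair
    # whose MRCA it is: pairs spanning two different child subtrees.
    leafsets: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leafsets[node] = [index[node]]
            C[index[node], index[node]] = depths[node]
        else:
            children = [leafsets[ch] for ch in node.child_nodes()]
            d = depths[node]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    for i in children[a]:
                        C[i, children[b]] = d
                        C[np.asarray(children[b]), i] = d
            merged = [i for ch in children for i in ch]
            leafsets[node] = merged
    return labels, C


def vcv_in_order(tree: dendropy.Tree, order: Sequence[str]) -> np.ndarray:
    """Shared-path covariance with rows/columns in a caller-specified order."""
    labels, C = build_vcv(tree)
    pos = {lab: i for i, lab in enumerate(labels)}
    wanted = [normalize_label(s) for s in order]
    missing = [s for s in wanted if s not in pos]
    if missing:
        raise ValueError(f"species not on tree: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    idx = np.array([pos[s] for s in wanted])
    return C[np.ix_(idx, idx)]


#: minimum between-tip distance (unit-depth scale) used in the working
#: correlation; zero-length cherries would otherwise make R exactly singular
#: and leave independence unreachable at any alpha
DIST_FLOOR = 1e-4


def ou_correlation(C: np.ndarray, alpha: float) -> np.ndarray:
    """OU-with-fixed-root correlation from a (depth-normalised) shared-path
    covariance matrix. See module docstring.

    Between-tip distances are floored at DIST_FLOOR so that tips joined by
    zero-length branches stay distinguishable."""
    t = np.diag(C).copy()
    if np.any(t <= 0):
        raise ValueError("zero root-to-tip depth; tree degenerate")
    d = np.maximum(t[:, None] + t[None, :] - 2.0 * C, DIST_FLOOR)
    var = 1.0 - np.exp(-2.0 * alpha * t)
    R = np.exp(-alpha * d) * (1.0 - np.exp(-2.0 * alpha * C))
    R /= np.sqrt(np.outer(var, var))
    np.fill_diagonal(R, 1.0)
    return R


def _normalize_depth(C: np.ndarray) -> np.ndarray:
    return C / np.diag(C).max()


# ---------------------------------------------------------------------------
# Mk model


@dataclass
class MkFit:
    states: tuple[str, ...]
    Q: np.ndarray
    log_likelihood: float
    tip_posteriors: dict[str, np.ndarray]
    converged: bool = True
    message: str = ""


def _tree_arrays(tree: dendropy.Tree):
    """Postorder edge arrays: (nodes, parent index, branch length, leaf idx)."""
    nodes = list(tree.postorder_node_iter())
    node_ix = {nd: i for i, nd in enumerate(nodes)}
    parent = np.full(len(nodes), -1, dtype=int)
    blen = np.zeros(len(nodes))
    for nd in nodes:
        if nd.parent_node is not None:
            parent[node_ix[nd]] = node_ix[nd.parent_node]
            blen[node_ix[nd]] = nd.edge.length if nd.edge.length is not None else 0.0
    return nodes, node_ix, parent, blen


def _er_transition(k: int, rate: float, t: float) -> np.ndarray:
    """Closed-form equal-rates transition matrix."""
    decay = np.exp(-k * rate * t)
    P = np.full((k, k), (1.0 - decay) / k)
    np.fill_diagonal(P, (1.0 + (k - 1) * decay) / k)
    return P


def _mk_q(k: int, rates: np.ndarray, model: str) -> np.ndarray:
    Q = np.zeros((k, k))
    if model == "equal_rates":
        Q[:] = rates[0]
    else:  # all_rates_different: rates in row-major off-diagonal order
        it = iter(rates)
        for i in range(k):
            for j in range(k):
                if i != j:
                    Q[i, j] = next(it)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


class _MkEngine:
    """Pruning machinery bound to one tree + observed tip states."""

    def __init__(self, tree, observed: dict[str, Optional[str]], states: Sequence[str], model: str):
        self.states = tuple(states)
        self.k = len(states)
        self.model = model
        self.nodes, self.node_ix, self.parent, self.blen = _tree_arrays(tree)
        self.n_nodes = len(self.nodes)
        self.is_leaf = np.array([nd.is_leaf() for nd in self.nodes])
        self.leaf_labels = {
            i: normalize_label(nd.taxon.label) for i, nd in enumerate(self.nodes) if nd.is_leaf()
        }
        sx = {s: i for i, s in enumerate(self.states)}
        # tip conditional likelihoods: indicator for observed, ones for missing
        self.tipL = np.ones((self.n_nodes, self.k))
        for i, lab in self.leaf_labels.items():
            st = observed.get(lab)
            if st is not None:
                self.tipL[i] = 0.0
                self.tipL[i, sx[st]] = 1.0
        self.root_freq = np.full(self.k, 1.0 / self.k)

    def _transitions(self, Q_or_rate) -> np.ndarray:
        P = np.empty((self.n_nodes, self.k, self.k))
        if self.model == "equal_rates":
            for i in range(self.n_nodes):
                if self.parent[i] >= 0:
                    P[i] = _er_transition(self.k, Q_or_rate, self.blen[i])
        else:
            for i in range(self.n_nodes):
                if self.parent[i] >= 0:
                    P[i] = expm(Q_or_rate * self.blen[i])
        return P

    def loglik(self, P: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
        """Up-pass: returns (loglik, partials L, log-scalers)."""
        scale = np.zeros(self.n_nodes)
        L = np.ones((self.n_nodes, self.k))
        L[self.is_leaf] = self.tipL[self.is_leaf]
        for i in range(self.n_nodes):
            p = self.parent[i]
            if p >= 0:
                msg = P[i] @ L[i]
                L[p] *= msg
                m = L[p].max()
                if m < 1e-200:
                    raise FloatingPointError("underflow in pruning")
                if m < 1e-6:
                    L[p] /= m
                    scale[p] += np.log(m)
        root = self.n_nodes - 1  # postorder: root last
        # propagate child scalers up
        total_scale = scale.sum()
        ll = np.log(self.root_freq @ L[root]) + total_scale
        return ll, L, scale

    def tip_posteriors(self, P: np.ndarray, L: np.ndarray) -> dict[str, np.ndarray]:
        """Down-pass marginal posteriors for missing tips.

        G[v](s) = P(data outside subtree v | state s at node v), up to a
        constant; posterior at a missing tip is proportional to G (its own
        partial is flat).
        """
        G = np.ones((self.n_nodes, self.k))
        root = self.n_nodes - 1
        G[root] = self.root_freq
        for i in range(self.n_nodes - 1, -1, -1):  # preorder = reversed postorder
            nd = self.nodes[i]
            if self.is_leaf[i]:
                continue
            children = [self.node_ix[ch] for ch in nd.child_nodes()]
            msgs = {c: P[c] @ L[c] for c in children}
            for c in children:
                sib = np.ones(self.k)
                for c2 in children:
                    if c2 != c:
                        sib = sib * msgs[c2]
                G[c] = (G[i] * sib) @ P[c]
        out = {}
        for i, lab in self.leaf_labels.items():
            if np.all(self.tipL[i] == 1.0):  # missing tip
                post = G[i] * 1.0
                total = post.sum()
                out[lab] = post / total if total > 0 else np.full(self.k, 1.0 / self.k)
        return out


def fit_mk(
    tree: dendropy.Tree,
    observed_tip_states: dict[str, Optional[str]],
    model: str = "equal_rates",
    states: Optional[Sequence[str]] = None,
) -> MkFit:
    """Maximum-likelihood Mk fit with missing tips integrated as uninformative.

    ``observed_tip_states`` maps normalised tip label to a state name or
    ``None`` for missing.  Root state frequencies are uniform.  With every
    observed tip in one state the process is degenerate: rate 0 is returned
    with a warning and missing tips get a point posterior on that state.
    """
    if states is None:
        seen = [v for v in observed_tip_states.values() if v is not None]
        order = [n.value for n in NICHE_ORDER]
        pool = set(seen)
        states = [s for s in order if s in pool] if pool <= set(order) else sorted(pool)
    k = len(states)
    distinct = {v for v in observed_tip_states.values() if v is not None}
    tip_set = {normalize_label(lf.taxon.label) for lf in tree.leaf_node_iter()}
    unknown = set(observed_tip_states) - tip_set
    if unknown:
        raise ValueError(f"states given for labels not on tree: {sorted(unknown)[:5]}")

    eng = _MkEngine(tree, observed_tip_states, states, model)
    depth = max(_node_depths(tree).values())

    if len(distinct) < 2:
        warnings.warn("all observed tips share one state; Mk rate degenerate at 0")
        Q = np.zeros((k, k))
        only = states.index(next(iter(distinct))) if distinct else 0
        post = np.zeros(k)
        post[only] = 1.0
        missing = [lab for lab, v in observed_tip_states.items() if v is None]
        return MkFit(tuple(states), Q, 0.0, {m: post.copy() for m in missing},
                     converged=True, message="degenerate: single observed state")

    if model == "equal_rates":
        def nll(log_rate: float) -> float:
            P = eng._transitions(np.exp(log_rate))
            return -eng.loglik(P)[0]

        res = minimize_scalar(
            nll, bounds=(np.log(1e-6 / depth), np.log(1e3 / depth)),
            method="bounded", options={"xatol": 1e-8},
        )
        rate = float(np.exp(res.x))
        Q = _mk_q(k, np.array([rate]), model)
        P = eng._transitions(rate)
        ll, L, _ = eng.loglik(P)
        posts = eng.tip_posteriors(P, L)
        return MkFit(tuple(states), Q, float(ll), posts, converged=bool(res.success))
    elif model == "all_rates_different":
        n_rates = k * (k - 1)
        x0 = np.full(n_rates, np.log(1.0 / depth))

        def nll_v(logr: np.ndarray) -> float:
            Q = _mk_q(k, np.exp(logr), model)
            P = eng._transitions(Q)
            return -eng.loglik(P)[0]

        res = minimize(nll_v, x0, method="L-BFGS-B",
                       bounds=[(np.log(1e-6 / depth), np.log(1e3 / depth))] * n_rates)
        Q = _mk_q(k, np.exp(res.x), model)
        P = eng._transitions(Q)
        ll, L, _ = eng.loglik(P)
        posts = eng.tip_posteriors(P, L)
        return MkFit(tuple(states), Q, float(ll), posts, converged=bool(res.success))
    raise ValueError(f"unknown Mk model {model!r}")


def impute_tips(
    mkfit: MkFit, rule: str = "max_posterior"
) -> tuple[dict[str, str], list[str]]:
    """Assign each missing tip its maximum-posterior state.

    Exact ties go to the first state in the documented fixed order
    (the order of ``mkfit.states``); tied tips are returned for logging.
    """
    if rule != "max_posterior":
        raise ValueError(f"unknown imputation rule {rule!r}")
    assigned: dict[str, str] = {}
    ties: list[str] = []
    for tip, post in mkfit.tip_posteriors.items():
        best = int(np.argmax(post))  # argmax takes the first maximum
        if np.sum(np.isclose(post, post[best], rtol=0, atol=1e-12)) > 1:
            ties.append(tip)
        assigned[tip] = mkfit.states[best]
    return assigned, ties


# ---------------------------------------------------------------------------
# Regressions


@dataclass
class FitResult:
    model_id: str
    terms: tuple[str, ...]
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    p_values: dict[str, float]
    alpha: float
    pseudo_R2: float
    n_obs: int
    converged: bool
    log_likelihood: float = np.nan
    null_log_likelihood: float = np.nan
    degenerate: bool = False
    message: str = ""

    def coef_vector(self) -> np.ndarray:
        return np.array([self.coefficients[t] for t in self.terms])


def niche_design(
    niches: Sequence[DielNiche], drop_empty: bool = False
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Design matrix with intercept and dummies for the non-base niches.

    ``drop_empty=True`` omits dummy columns for niche levels with no
    observations (which would otherwise make the fit singular)."""
    coerced = [nn if isinstance(nn, DielNiche) else DielNiche(str(nn)) for nn in niches]
    levels = NICHE_TERMS if not drop_empty else tuple(
        n for n in NICHE_TERMS if any(nn is n for nn in coerced)
    )
    terms = ("intercept",) + tuple(n.value for n in levels)
    X = np.zeros((len(coerced), len(terms)))
    X[:, 0] = 1.0
    for j, n in enumerate(levels, start=1):
        X[:, j] = [nn is n for nn in coerced]
    return X, terms


def _chol(R: np.ndarray):
    return cho_factor(R + _JITTER * np.eye(R.shape[0]), lower=True)


def _profile_alpha(C: np.ndarray, e: np.ndarray) -> float:
    """Maximise the Gaussian quasi-likelihood of standardised residuals over
    alpha (bounded in log space).

    The interior optimum is kept only when it beats the independence end of
    the search range by an AIC-type margin (ALPHA_PENALTY, 2 units for the
    one free correlation parameter); this guards against a spurious working
    correlation distorting the fit when the residuals carry no signal."""

    n = len(e)

    def obj(log_alpha: float) -> float:
        R = ou_correlation(C, float(np.exp(log_alpha)))
        cf = _chol(R)
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        quad = float(e @ cho_solve(cf, e))
        # profile out the residual scale: n*log(e'R^-1 e / n) + log|R|
        return n * np.log(max(quad, 1e-300) / n) + logdet

    res = minimize_scalar(
        obj, bounds=(np.log(ALPHA_MIN), np.log(ALPHA_MAX)), method="bounded",
        options={"xatol": 1e-4},
    )
    if obj(np.log(ALPHA_MAX)) - res.fun < ALPHA_PENALTY:
        return ALPHA_MAX
    return float(np.exp(res.x))


def _bernoulli_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    return float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


def _adjusted_score(y, X, R_chol, beta):
    """Firth-adjusted GEE score, information and its Cholesky at beta."""
    p = X.shape[1]
    mu = expit(X @ beta)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    sw = np.sqrt(w)
    A = sw[:, None] * X
    B = cho_solve(R_chol, A)
    info = A.T @ B
    info_chol = cho_factor(info + 1e-12 * np.eye(p))
    h = np.einsum("ij,ij->i", A @ cho_solve(info_chol, np.eye(p)), B)
    resid = y - mu + h * (0.5 - mu)
    U = B.T @ (resid / sw)
    return U, info_chol


def _firth_gee_logistic(y, X, R_chol, beta0=None, max_iter=100):
    """Firth-adjusted logistic scoring with working correlation R.

    Returns (beta, cov, penalised objective, converged). With R = I this is
    exactly Firth's penalised logistic regression. Steps are halved until the
    adjusted-score norm does not increase.
    """
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    converged = False
    U, info_chol = _adjusted_score(y, X, R_chol, beta)
    for _ in range(max_iter):
        if np.max(np.abs(U)) < TOL:
            converged = True
            break
        step = cho_solve(info_chol, U)
        norm0 = np.linalg.norm(U)
        for _ in range(30):
            U_new, info_chol_new = _adjusted_score(y, X, R_chol, beta + step)
            if np.linalg.norm(U_new) <= norm0 * (1 + 1e-8) or np.max(np.abs(step)) < 1e-13:
                break
            step *= 0.5
        beta = beta + step
        U, info_chol = U_new, info_chol_new
    eta = X @ beta
    mu = expit(eta)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    A = np.sqrt(w)[:, None] * X
    info = A.T @ cho_solve(R_chol, A)
    cov = np.linalg.inv(info)
    sign, logdet = np.linalg.slogdet(info)
    pl_final = _bernoulli_loglik(y, mu) + 0.5 * logdet
    return beta, cov, pl_final, converged


def fit_phylo_logistic(
    y: np.ndarray,
    X: np.ndarray,
    tree: dendropy.Tree,
    tip_order: Sequence[str],
    terms: Optional[Sequence[str]] = None,
    model_id: str = "logistic_mple",
    max_outer: int = 6,
    vcv: Optional[np.ndarray] = None,
) -> FitResult:
    """Phylogenetic logistic regression (Firth-penalised GEE / MPLE).

    ``tip_order`` gives the species label for each row of ``y``/``X``; the
    tree may contain extra tips, which are ignored. alpha is profiled on the
    Pearson residuals of the current fit and the fit alternates between beta
    and alpha until the penalised objective changes by less than ``TOL``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if terms is None:
        terms = tuple(f"b{j}" for j in range(p))
    terms = tuple(terms)
    if len(y) != n or len(tip_order) != n:
        raise ValueError("y, X and tip_order must align")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary")

    def _degenerate(msg: str) -> FitResult:
        nanmap = {t: np.nan for t in terms}
        return FitResult(model_id, terms, dict(nanmap), dict(nanmap), dict(nanmap),
                         np.nan, np.nan, n, False, degenerate=True, message=msg)

    if np.all(y == y[0]):
        return _degenerate("constant response")

    C = _normalize_depth(vcv_in_order(tree, list(tip_order)) if vcv is None else np.asarray(vcv))
    try:
        alpha = ALPHA_MAX  # start at the independence end
        R_chol = _chol(ou_correlation(C, alpha))
        beta, cov, pl, conv_b = _firth_gee_logistic(y, X, R_chol)
        converged = conv_b
        for _ in range(max_outer):
            mu = expit(X @ beta)
            e = (y - mu) / np.sqrt(np.clip(mu * (1 - mu), 1e-10, None))
            alpha_new = _profile_alpha(C, e)
            R_chol = _chol(ou_correlation(C, alpha_new))
            beta, cov, pl_new, conv_b = _firth_gee_logistic(y, X, R_chol, beta0=beta)
            if abs(pl_new - pl) < 1e-6 or abs(np.log(alpha_new) - np.log(alpha)) < 1e-3:
                alpha, pl = alpha_new, pl_new
                converged = conv_b
                break
            alpha, pl = alpha_new, pl_new
            converged = conv_b
    except np.linalg.LinAlgError:
        return _degenerate("singular design (empty niche level?)")

    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.inf * np.sign(beta))
    pvals = np.where(np.isnan(z), 1.0, 2.0 * norm.sf(np.abs(z)))
    mu = expit(X @ beta)
    ll = _bernoulli_loglik(y, mu)
    # null model: intercept only, same alpha
    R_chol_null = _chol(ou_correlation(C, alpha))
    b0, _, _, _ = _firth_gee_logistic(y, np.ones((n, 1)), R_chol_null)
    ll0 = _bernoulli_loglik(y, expit(np.full(n, b0[0])))
    pr2 = pseudo_r2_from_loglik(ll, ll0, n, kind="mcfadden")
    return FitResult(
        model_id, terms,
        dict(zip(terms, beta)), dict(zip(terms, se)), dict(zip(terms, pvals)),
        float(alpha), pr2, n, bool(converged),
        log_likelihood=ll, null_log_likelihood=ll0,
    )


def _poisson_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-12, None)
    return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))


def _gee_poisson(y, X, R_chol, beta0=None, max_iter=200):
    n, p = X.shape
    if beta0 is None:
        beta = np.zeros(p)
        beta[0] = np.log(max(y.mean(), 1e-6)) if np.allclose(X[:, 0], 1) else 0.0
    else:
        beta = beta0.copy()
    converged = False
    for _ in range(max_iter):
        mu = np.exp(np.clip(X @ beta, -30, 30))
        sa = np.sqrt(mu)
        A = sa[:, None] * X
        B = cho_solve(R_chol, A)
        info = A.T @ B
        U = B.T @ ((y - mu) / sa)
        step = np.linalg.solve(info + 1e-12 * np.eye(p), U)
        beta = beta + step
        if np.max(np.abs(U)) < TOL and np.max(np.abs(step)) < TOL:
            converged = True
            break
    mu = np.exp(np.clip(X @ beta, -30, 30))
    e = (y - mu) / np.sqrt(mu)
    phi = float(e @ e) / max(n - p, 1)
    sa = np.sqrt(mu)
    A = sa[:, None] * X
    info = A.T @ cho_solve(R_chol, A)
    cov = phi * np.linalg.inv(info)
    return beta, cov, phi, converged


def fit_phylo_poisson_gee(
    y: np.ndarray,
    X: np.ndarray,
    tree: dendropy.Tree,
    tip_order: Sequence[str],
    terms: Optional[Sequence[str]] = None,
    model_id: str = "poisson_gee",
    working: str = "tree",
    max_outer: int = 6,
    vcv: Optional[np.ndarray] = None,
) -> FitResult:
    """Phylogenetic Poisson GEE with log link.

    ``working='tree'`` uses the OU working correlation with profiled alpha;
    ``working='independence'`` fixes R = I, which reproduces an ordinary
    Poisson GLM exactly (same estimating equations). The dispersion is the
    Pearson estimate; SEs are model-based (single-cluster data admit no
    between-cluster sandwich).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if terms is None:
        terms = tuple(f"b{j}" for j in range(p))
    terms = tuple(terms)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("y must be non-negative integer counts")

    def _degenerate(msg: str) -> FitResult:
        nanmap = {t: np.nan for t in terms}
        return FitResult(model_id, terms, dict(nanmap), dict(nanmap), dict(nanmap),
                         np.nan, np.nan, n, False, degenerate=True, message=msg)

    if np.all(y == 0):
        return _degenerate("all-zero counts")

    eye_chol = _chol(np.eye(n))
    try:
        return _fit_poisson_inner(y, X, tree, tip_order, terms, model_id, working,
                                  max_outer, eye_chol, n, _degenerate, vcv)
    except np.linalg.LinAlgError:
        return _degenerate("singular design (empty niche level?)")


def _fit_poisson_inner(y, X, tree, tip_order, terms, model_id, working,
                       max_outer, eye_chol, n, _degenerate, vcv=None):
    if working == "independence":
        beta, cov, phi, converged = _gee_poisson(y, X, eye_chol)
        alpha = np.inf
        R_chol = eye_chol
        C = None
    elif working == "tree":
        C = _normalize_depth(vcv_in_order(tree, list(tip_order)) if vcv is None else np.asarray(vcv))
        beta, cov, phi, conv = _gee_poisson(y, X, eye_chol)
        alpha = ALPHA_MAX
        converged = conv
        for _ in range(max_outer):
            mu = np.exp(np.clip(X @ beta, -30, 30))
            e = (y - mu) / np.sqrt(mu)
            alpha_new = _profile_alpha(C, e)
            R_chol = _chol(ou_correlation(C, alpha_new))
            beta_new, cov, phi, conv = _gee_poisson(y, X, R_chol, beta0=beta)
            if np.max(np.abs(beta_new - beta)) < 1e-7 or abs(np.log(alpha_new) - np.log(alpha)) < 1e-3:
                beta, alpha = beta_new, alpha_new
                converged = conv
                break
            beta, alpha = beta_new, alpha_new
            converged = conv
    else:
        raise ValueError(f"unknown working correlation {working!r}")

    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.inf * np.sign(beta))
    pvals = np.where(np.isnan(z), 1.0, 2.0 * norm.sf(np.abs(z)))
    mu = np.exp(np.clip(X @ beta, -30, 30))
    ll = _poisson_loglik(y, mu)
    b0 = np.log(y.mean())
    ll0 = _poisson_loglik(y, np.full(n, y.mean()))
    pr2 = pseudo_r2_from_loglik(ll, ll0, n, kind="mcfadden")
    return FitResult(
        model_id, terms,
        dict(zip(terms, beta)), dict(zip(terms, se)), dict(zip(terms, pvals)),
        float(alpha), pr2, n, bool(converged),
        log_likelihood=ll, null_log_likelihood=ll0,
    )


def pseudo_r2_from_loglik(ll: float, ll0: float, n: int, kind: str = "mcfadden") -> float:
    """Likelihood-based pseudo-R² in [0, 1).

    ``mcfadden``: 1 - ll/ll0. ``nagelkerke``: Cox–Snell rescaled to [0, 1).
    A model log-likelihood materially below the null is flagged.
    """
    if ll < ll0 - 1e-6:
        warnings.warn("model log-likelihood below null; pseudo-R2 clamped to 0")
        return 0.0
    ll = max(ll, ll0)
    if kind == "mcfadden":
        if ll0 == 0.0:
            return 0.0
        r2 = 1.0 - ll / ll0
    elif kind == "nagelkerke":
        cs = 1.0 - np.exp(2.0 * (ll0 - ll) / n)
        denom = 1.0 - np.exp(2.0 * ll0 / n)
        r2 = cs / denom if denom > 0 else 0.0
    else:
        raise ValueError(f"unknown pseudo-R2 kind {kind!r}")
    return float(min(max(r2, 0.0), 1.0 - 1e-12))


def pseudo_r2(fit: FitResult, null_fit: FitResult, kind: str = "mcfadden") -> float:
    """Pseudo-R² from a fitted model and its intercept-only null."""
    return pseudo_r2_from_loglik(fit.log_likelihood, null_fit.log_likelihood, fit.n_obs, kind)
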