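import dendropy
import numpy as np
import pytest

from dieldecline.synth import SynthConfig, simulate_bundle


def make_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


def star_tree(n: int, depth: float = 1.0) -> tuple[dendropy.Tree, list[str]]:
    labels = [f"s{i:03d}" for i in range(n)]
    nwk = "(" + ",".join(f"{l}:{depth}" for l in labels) + ");"
    return make_tree(nwk), labels


def random_tree(n: int, seed: int) -> dendropy.Tree:
    """Random birth-death tree with unit depth, tips sp0001..spNNNN."""
    cfg = SynthConfig(n_species=n, seed=seed)
    from dieldecline.synth import sim_tree

    return sim_tree(cfg)


@pytest.fixture(scope="session")
def small_bundle():
    """One synthetic study bundle at reduced scale, shared across tests."""
    cfg = SynthConfig(n_species=300, n_trees=6, seed=42)
    records, truth, tree, ensemble, stack, countries, overrides = simulate_bundle(cfg)
    return {
        "config": cfg,
        "records": records,
        "truth": truth,
        "tree": tree,
        "ensemble": ensemble,
        "stack": stack,
        "countries": countries,
        "overrides": overrides,
    }


# ---------------------------------------------------------------------------
# Independent oracles (deliberately simple, loop-based implementations)


def vcv_bruteforce(tree: dendropy.Tree):
    """Pairwise shared-path covariance by explicit root-path enumeration."""
    from dieldecline.types import normalize_label

    leaves = list(tree.leaf_node_iter())
    labels = [normalize_label(lf.taxon.label) for lf in leaves]

    def path_to_root(node):
        path = []
        while node.parent_node is not None:
            path.append(node)
            node = node.parent_node
        return path

    n = len(leaves)
    C = np.zeros((n, n))
    for i in range(n):
        pi = path_to_root(leaves[i])
        for j in range(n):
            pj = set(path_to_root(leaves[j]))
            shared = [nd for nd in pi if nd in pj]
            C[i, j] = sum(nd.edge.length or 0.0 for nd in shared)
    return labels, C


def mk_loglik_enumeration(tree, observed, states, rate):
    """Exact Mk likelihood by summation over all ancestral-state assignments
    (equal-rates model, uniform root)."""
    import itertools

    k = len(states)

    def ptrans(t):
        decay = np.exp(-k * rate * t)
        P = np.full((k, k), (1 - decay) / k)
        np.fill_diagonal(P, (1 + (k - 1) * decay) / k)
        return P

    from dieldecline.types import normalize_label

    internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    leaves = list(tree.leaf_node_iter())
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internals)):
        amap = dict(zip(internals, assign))
        prob = 1.0 / k  # uniform root
        for nd in internals:
            if nd.parent_node is not None:
                prob *= ptrans(nd.edge.length or 0.0)[amap[nd.parent_node], amap[nd]]
        for lf in leaves:
            P = ptrans(lf.edge.length or 0.0)[amap[lf.parent_node]]
            st = observed.get(normalize_label(lf.taxon.label))
            prob *= 1.0 if st is None else P[states.index(st)]
        total += prob
    return np.log(total)


def firth_logistic_oracle(y, X, tol=1e-10, maxit=500):
    """Textbook Firth-penalised logistic regression (independent data)."""
    from scipy.special import expit

    beta = np.zeros(X.shape[1])
    for _ in range(maxit):
        mu = expit(X @ beta)
        W = mu * (1 - mu)
        info = X.T @ (X * W[:, None])
        info_inv = np.linalg.inv(info)
        Xs = X * np.sqrt(W)[:, None]
        h = np.einsum("ij,ij->i", Xs @ info_inv, Xs)
        U = X.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ U
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            return beta
    raise RuntimeError("oracle did not converge")


def poisson_irls_oracle(y, X, tol=1e-12, maxit=500):
    """Textbook Poisson IRLS (log link), independent data."""
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(max(np.mean(y), 1e-9))
    for _ in range(maxit):
        mu = np.exp(X @ beta)
        z = X @ beta + (y - mu) / mu
        WX = X * mu[:, None]
        beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        if np.max(np.abs(beta_new - beta)) < tol:
            return beta_new
        beta = beta_new
    raise RuntimeError("oracle did not converge")
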