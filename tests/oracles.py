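"""Independent brute-force oracles shared by the unit and acceptance tests.

These reimplement definitions directly (numerical differentiation, exhaustive
loops) and never call the code paths they check.
"""

import numpy as np
from scipy.special import logsumexp


def gmm_loglik(X, weights, means, sigmas):
    """log u_lambda(X) for a diagonal GMM parameterized by std deviations."""
    X = np.atleast_2d(X)
    K, d = means.shape
    log_comp = np.empty((X.shape[0], K))
    for k in range(K):
        log_comp[:, k] = (
            np.log(weights[k])
            - 0.5 * d * np.log(2 * np.pi)
            - np.log(sigmas[k]).sum()
            - 0.5 * (((X - means[k]) / sigmas[k]) ** 2).sum(axis=1)
        )
    return logsumexp(log_comp, axis=1).sum()


def fisher_vector_numerical(X, weights, means, variances, step=1e-5):
    """(1/T) F^(-1/2) grad log u_lambda(X) by central differences.

    Gradients are taken w.r.t. the component means and standard deviations;
    the diagonal Fisher-information approximation is F_mu = w_k / sigma^2 and
    F_sigma = 2 w_k / sigma^2 per dimension.  Blocks are concatenated as
    (g_mu_1, g_sigma_1, ..., g_mu_K, g_sigma_K) to match the encoder layout.
    """
    X = np.atleast_2d(X)
    T = X.shape[0]
    K, d = means.shape
    sigmas = np.sqrt(variances)
    blocks = []
    for k in range(K):
        g_mu = np.empty(d)
        g_sigma = np.empty(d)
        for j in range(d):
            for target, grad in ((means, g_mu), (sigmas, g_sigma)):
                orig = target[k, j]
                target[k, j] = orig + step
                hi = gmm_loglik(X, weights, means, sigmas)
                target[k, j] = orig - step
                lo = gmm_loglik(X, weights, means, sigmas)
                target[k, j] = orig
                grad[j] = (hi - lo) / (2 * step)
        fisher_mu = weights[k] / sigmas[k] ** 2
        fisher_sigma = 2 * weights[k] / sigmas[k] ** 2
        blocks.append(g_mu / (T * np.sqrt(fisher_mu)))
        blocks.append(g_sigma / (T * np.sqrt(fisher_sigma)))
    return np.concatenate(blocks)


def random_gmm_instance(rng, K, d, T):
    """A random small GMM plus descriptor set for oracle comparisons."""
    weights = rng.dirichlet(np.full(K, 5.0))
    means = rng.normal(0, 2, size=(K, d))
    variances = rng.uniform(0.5, 2.0, size=(K, d))
    X = rng.normal(0, 2, size=(T, d))
    return weights, means, variances, X


def average_precision_brute(relevance):
    """AP exactly as defined: mean precision at each relevant rank."""
    rel = np.asarray(relevance, dtype=bool)
    precisions = []
    hits = 0
    for p, r in enumerate(rel, start=1):
        if r:
            hits += 1
            precisions.append(hits / p)
    return sum(precisions) / len(precisions)


def pair_scatter_brute(X, y):
    """O(n^2) double loop over unordered pairs."""
    n, F = X.shape
    M_S = np.zeros((F, F))
    M_D = np.zeros((F, F))
    n_s = n_d = 0
    for i in range(n):
        for j in range(i + 1, n):
            diff = X[i] - X[j]
            outer = np.outer(diff, diff)
            if y[i] == y[j]:
                M_S += outer
                n_s += 1
            else:
                M_D += outer
                n_d += 1
    return M_S / n_s, M_D / n_d
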