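"""Independent reference implementations used only by the tests.

These deliberately avoid the package's vectorized/stabilized code paths:
the WHAM oracle is a plain-Python fixed-point iteration of the two
self-consistency equations, and the Boltzmann oracle integrates exp(-U)
numerically bin by bin.
"""

import math

import numpy as np


def wham_fixed_point(counts, n_samples, bias, tol=1e-14, max_iter=500_000):
    """Naive WHAM fixed point, pure Python loops, energies in kT.

    counts: (n_win, n_bins) histogram; n_samples: retained N_i per window;
    bias: (n_win, n_bins) bias energy c_ij at bin centers.  Returns
    (W per bin with math.inf sentinels, window constants f with f[0]=0),
    iterated from f = 0 to machine precision.
    """
    n_win = len(counts)
    n_bins = len(counts[0])
    f = [0.0] * n_win
    for _ in range(max_iter):
        p = []
        for j in range(n_bins):
            num = sum(counts[i][j] for i in range(n_win))
            den = sum(n_samples[i] * math.exp(f[i] - bias[i][j]) for i in range(n_win))
            p.append(num / den if num > 0 else 0.0)
        f_new = []
        for i in range(n_win):
            s = sum(p[j] * math.exp(-bias[i][j]) for j in range(n_bins))
            f_new.append(-math.log(s))
        f_new = [fi - f_new[0] for fi in f_new]
        resid = max(abs(a - b) for a, b in zip(f_new, f))
        f = f_new
        if resid <= tol:
            break
    w = [-math.log(pj) if pj > 0 else math.inf for pj in p]
    return w, f


def rezero_bulk(w):
    """Subtract W at the largest finite-z entry; keep inf sentinels."""
    finite = [x for x in w if math.isfinite(x)]
    anchor = finite[-1]
    return [x - anchor if math.isfinite(x) else math.inf for x in w]


def boltzmann_bin_probs(u_func, edges, n_sub=64):
    """Normalized Boltzmann probability of each bin by midpoint quadrature."""
    edges = np.asarray(edges, dtype=float)
    masses = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        zs = lo + (hi - lo) * (np.arange(n_sub) + 0.5) / n_sub
        masses.append(np.exp(-np.asarray(u_func(zs))).mean() * (hi - lo))
    masses = np.asarray(masses)
    return masses / masses.sum()


def merge_small_bins(observed, expected, min_expected=5.0):
    """Merge adjacent bins until every expected count reaches min_expected."""
    obs_out, exp_out = [], []
    acc_o = acc_e = 0.0
    for o, e in zip(observed, expected):
        acc_o += o
        acc_e += e
        if acc_e >= min_expected:
            obs_out.append(acc_o)
            exp_out.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0 and obs_out:  # fold the remainder into the last kept bin
        obs_out[-1] += acc_o
        exp_out[-1] += acc_e
    return np.asarray(obs_out), np.asarray(exp_out)
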