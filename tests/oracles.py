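"""Independent brute-force oracles used only by the test suite.

Each oracle is written naively (explicit loops, generic optimizers)
and stays independent of the library code paths it checks.
"""

import numpy as np
from scipy.optimize import minimize_scalar


def bruteforce_peto_peto(time, event, group):
    """Weighted log-rank statistic, computed by looping over distinct
    event times and rebuilding each risk set from scratch. The weight
    at each event time is the pooled Kaplan-Meier estimate just before
    that time."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group, bool)
    event_times = sorted(set(time[event == 1]))

    u = 0.0
    v = 0.0
    km = 1.0  # pooled KM, updated after each event time
    for t in event_times:
        at_risk = [i for i in range(len(time)) if time[i] >= t]
        deaths = [i for i in at_risk if time[i] == t and event[i] == 1]
        n = len(at_risk)
        d = len(deaths)
        n1 = sum(1 for i in at_risk if group[i])
        d1 = sum(1 for i in deaths if group[i])
        w = km  # left-continuous: value before this time's deaths
        u += w * (d1 - n1 * d / n)
        if n > 1:
            v += w * w * d * (n - d) * n1 * (n - n1) / (n * n * (n - 1))
        km *= 1.0 - d / n
    if v <= 0:
        return 0.0
    return u * u / v


def efron_partial_loglik(beta, time, event, group):
    """Efron-approximation Cox partial log-likelihood for one binary
    covariate, computed with explicit per-event-time loops."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    x = np.asarray(group, float)
    loglik = 0.0
    for t in sorted(set(time[event == 1])):
        tied = np.flatnonzero((time == t) & (event == 1))
        risk = np.flatnonzero(time >= t)
        d = len(tied)
        sum_risk = np.exp(beta * x[risk]).sum()
        sum_tied = np.exp(beta * x[tied]).sum()
        loglik += beta * x[tied].sum()
        for ell in range(d):
            loglik -= np.log(sum_risk - (ell / d) * sum_tied)
    return loglik


def optimizer_cox_coef(time, event, group):
    """Maximize the Efron partial likelihood with a generic scalar
    optimizer (no derivatives), then polish with one parabolic vertex
    step to handle nearly-flat likelihoods."""
    res = minimize_scalar(
        lambda b: -efron_partial_loglik(b, time, event, group),
        bounds=(-10, 10),
        method="bounded",
        options={"xatol": 1e-10},
    )
    x = float(res.x)
    h = 1e-4
    f = [efron_partial_loglik(b, time, event, group) for b in (x - h, x, x + h)]
    denom = f[0] - 2 * f[1] + f[2]
    if denom < 0:  # concave locally; quadratic vertex refinement
        x += 0.5 * h * (f[0] - f[2]) / denom
    return x


def bruteforce_edge_weights(counts, cell_types, genes, pairs, detection_threshold, scale=None):
    """Mean-expression-product edge weights recomputed per cell with
    plain Python loops over a dense matrix.

    ``scale``: per-cell multiplicative normalization factors (None =
    raw counts). Returns {(sender, receiver, (ligand, receptor)): weight}.
    """
    counts = np.asarray(counts, float)
    n_cells, n_genes = counts.shape
    if scale is None:
        scale = np.ones(n_cells)
    gene_idx = {g: j for j, g in enumerate(genes)}
    types = sorted(set(cell_types))
    edges = {}
    for sender in types:
        s_cells = [i for i in range(n_cells) if cell_types[i] == sender]
        for receiver in types:
            r_cells = [i for i in range(n_cells) if cell_types[i] == receiver]
            for lig, rec in pairs:
                if lig not in gene_idx or rec not in gene_idx:
                    continue
                lj, rj = gene_idx[lig], gene_idx[rec]
                det_l = sum(1 for i in s_cells if counts[i, lj] > 0) / len(s_cells)
                det_r = sum(1 for i in r_cells if counts[i, rj] > 0) / len(r_cells)
                if det_l < detection_threshold or det_r < detection_threshold:
                    continue
                mean_l = sum(counts[i, lj] * scale[i] for i in s_cells) / len(s_cells)
                mean_r = sum(counts[i, rj] * scale[i] for i in r_cells) / len(r_cells)
                edges[(sender, receiver, (lig, rec))] = mean_l * mean_r
    return edges


def benjamini_hochberg(p_values):
    """Step-up BH adjusted p-values, written directly from the
    definition."""
    p = np.asarray(p_values, float)
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, m * p[i] / rank_from_top)
        adjusted[i] = running_min
    return adjusted
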