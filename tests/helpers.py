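"""Independent plain-numpy oracles used across the test suite.

These deliberately re-derive the forward pass and finite-difference
gradients without touching the package's autodiff engine, so agreement is a
genuine cross-check rather than a tautology.
"""

import numpy as np


def np_normalize_adjacency(a):
    at = a + np.eye(a.shape[0])
    d = at.sum(axis=1)
    dinv = 1.0 / np.sqrt(d)
    return at * dinv[:, None] * dinv[None, :]


def np_forward(a, x, weights, head_w, head_b, activation="relu"):
    """Dense reference GCN forward; returns (activations list, pooled, logits)."""
    ahat = np_normalize_adjacency(a)
    f = x
    acts = [f]
    for w in weights:
        z = ahat @ f @ w
        f = np.maximum(z, 0.0) if activation == "relu" else z
        acts.append(f)
    pooled = f.mean(axis=0)
    return acts, pooled, pooled @ head_w + head_b


def np_forward_from_layer(a, f_l, weights_after, head_w, head_b, activation="relu"):
    """Forward from a given layer activation downstream to the logits."""
    ahat = np_normalize_adjacency(a)
    f = f_l
    for w in weights_after:
        z = ahat @ f @ w
        f = np.maximum(z, 0.0) if activation == "relu" else z
    pooled = f.mean(axis=0)
    return pooled @ head_w + head_b


def unpack(params):
    return ([w.data for w in params.layer_weights],
            params.head_weight.data, params.head_bias.data)


def fd_logit_grad_wrt_layer(a, params, layer, c, h=1e-4):
    """Central finite differences of y_c w.r.t. each entry of F(layer)."""
    ws, hw, hb = unpack(params)
    acts, _, _ = np_forward(a["adj"], a["x"], ws, hw, hb)
    f_l = acts[layer]
    g = np.zeros_like(f_l)
    for i in range(f_l.shape[0]):
        for k in range(f_l.shape[1]):
            fp, fm = f_l.copy(), f_l.copy()
            fp[i, k] += h
            fm[i, k] -= h
            yp = np_forward_from_layer(a["adj"], fp, ws[layer:], hw, hb)[c]
            ym = np_forward_from_layer(a["adj"], fm, ws[layer:], hw, hb)[c]
            g[i, k] = (yp - ym) / (2 * h)
    return g


def fd_logit_grad_wrt_adj(a, params, c, h=1e-4):
    """Central finite differences of y_c w.r.t. each *directed* entry of A."""
    ws, hw, hb = unpack(params)
    n = a["adj"].shape[0]
    g = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            ap, am = a["adj"].copy(), a["adj"].copy()
            ap[i, j] += h
            am[i, j] -= h
            yp = np_forward(ap, a["x"], ws, hw, hb)[2][c]
            ym = np_forward(am, a["x"], ws, hw, hb)[2][c]
            g[i, j] = (yp - ym) / (2 * h)
    return g


def random_graph(rng, n, d_in=2):
    a = rng.random((n, n))
    a = np.triu(a, 1)
    a = a + a.T
    x = rng.normal(size=(n, d_in))
    return {"adj": a, "x": x}


def stable_fd(fd_fn, *args, h=1e-4, rtol=1e-4):
    """FD value plus a mask of entries where halving the step leaves the
    estimate unchanged (i.e. no ReLU kink inside the stencil)."""
    g1 = fd_fn(*args, h=h)
    g2 = fd_fn(*args, h=h / 2)
    mask = np.abs(g1 - g2) <= rtol * (1.0 + np.abs(g1))
    return g2, mask
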