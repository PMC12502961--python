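"""Brute-force dense reference implementation of the attention network.

Materializes the full N×N score matrix per head with −inf masking of
non-edges, for cross-checking the sparse segment implementation.  Kept
deliberately naive and loop-based so it shares no code path with the
package.
"""

import numpy as np


def _elu(x):
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def dense_layer_forward(model, params, layer, x, edge_index, edge_attr, slope):
    """One message layer on a single graph, dense N×N attention per head."""
    w = model.get(params, f"layer{layer}.W")
    we = model.get(params, f"layer{layer}.We")
    a_src = model.get(params, f"layer{layer}.a_src")
    a_dst = model.get(params, f"layer{layer}.a_dst")
    a_edge = model.get(params, f"layer{layer}.a_edge")
    f_in, n_heads, d = w.shape
    n = x.shape[0]
    head_outputs = []
    for h in range(n_heads):
        z = x @ w[:, h, :]                       # (N, d)
        scores = np.full((n, n), -np.inf)
        # receiver i attends over incoming edges j->i plus itself
        for e in range(edge_index.shape[1]):
            j, i = edge_index[0, e], edge_index[1, e]
            ze = edge_attr[e] @ we[:, h, :]
            u = a_dst[h] @ z[i] + a_src[h] @ z[j] + a_edge[h] @ ze
            scores[i, j] = np.where(u > 0, u, slope * u)
        for i in range(n):
            u = a_dst[h] @ z[i] + a_src[h] @ z[i]  # self-loop, zero edge feature
            scores[i, i] = np.where(u > 0, u, slope * u)
        smax = scores.max(axis=1, keepdims=True)
        ex = np.exp(scores - smax)
        ex[~np.isfinite(scores)] = 0.0
        alpha = ex / ex.sum(axis=1, keepdims=True)
        head_outputs.append(alpha @ z)
    return head_outputs


def dense_model_forward(model, params, graph):
    """Full forward pass for one graph: returns (prediction (5,), embedding)."""
    cfg = model.config
    x = graph.node_features.astype(np.float64)
    for layer in range(cfg.n_message_layers):
        heads = dense_layer_forward(
            model, params, layer, x, graph.edge_index, graph.edge_features, cfg.attn_slope
        )
        if layer == cfg.n_message_layers - 1:
            x = _elu(np.mean(heads, axis=0))
        else:
            x = np.concatenate([_elu(m) for m in heads], axis=1)
    emb = x.mean(axis=0)
    h = emb
    for i in range(len(cfg.head_dims)):
        h = h @ model.get(params, f"fc{i}.W") + model.get(params, f"fc{i}.b")
        if i < len(cfg.head_dims) - 1:
            h = _elu(h)
    return h, emb
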