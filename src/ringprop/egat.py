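"""Edge-aware graph attention regressor (NumPy, explicit gradients).

Three message-passing layers in which the attention score of an incoming
edge j→i concatenates the transformed features of both endpoints and of the
bond itself,

    s_ij = LeakyReLU( a^T [ W h_i  ||  W h_j  ||  W_e e_ij ] ),

a softmax over the incoming edges of each node (plus a self-loop carrying a
zero edge-feature vector) yields attention weights, and the node update is
the attention-weighted sum of transformed neighbour features followed by an
ELU.  Heads are concatenated in the hidden message layers and averaged in
the final one; global mean pooling produces the molecular embedding, which
three fully connected layers map to the five property outputs.

The network is implemented directly on flat parameter vectors with
hand-derived backward passes (verified against central finite differences),
which keeps training, checkpointing and gradient checking free of any
autodiff dependency.  Compute precision follows the dtype of the parameter
vector: float32 for fast training, float64 for exact gradient checks and
oracle comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .featurize import MolecularGraph

__all__ = [
    "EGATConfig",
    "GraphBatch",
    "EGATModel",
    "count_parameters",
    "global_mean_pool",
]


@dataclass(frozen=True)
class EGATConfig:
    """Architecture hyperparameters.

    ``hidden_dim`` must be divisible by ``n_heads``; ``head_dims`` are the
    widths of the three fully connected layers and must end in the five
    property outputs.
    """

    n_message_layers: int = 3
    hidden_dim: int = 128
    n_heads: int = 4
    head_dims: tuple[int, ...] = (128, 64, 5)
    attn_slope: float = 0.2
    dropout_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_message_layers < 0:
            raise ValueError("n_message_layers must be >= 0")
        if self.n_message_layers and self.hidden_dim % self.n_heads:
            raise ValueError("hidden_dim must be divisible by n_heads")
        if not self.head_dims or self.head_dims[-1] != 5:
            raise ValueError("head_dims must end in the 5 property outputs")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


# ---------------------------------------------------------------------------
# batching
# ---------------------------------------------------------------------------

class GraphBatch:
    """A disjoint union of molecular graphs with precomputed segment index.

    Self-loops (one per node, zero edge features) are appended to the bond
    edges so that every node attends to itself even in edgeless graphs.
    Segment reductions over incoming/outgoing edges are precompiled into
    sparse incidence operators; the softmax max-subtraction uses a
    destination-sorted ``reduceat`` index.
    """

    def __init__(self, graphs: list[MolecularGraph]):
        if not graphs:
            raise ValueError("empty batch")
        xs, srcs, dsts, eattrs, membership = [], [], [], [], []
        offset = 0
        for g, graph in enumerate(graphs):
            n = graph.n_nodes
            if n == 0:
                raise ValueError(f"graph {graph.mol_id!r} has zero nodes")
            xs.append(graph.node_features)
            srcs.append(graph.edge_index[0] + offset)
            dsts.append(graph.edge_index[1] + offset)
            eattrs.append(graph.edge_features)
            membership.append(np.full(n, g))
            offset += n
        self.n_graphs = len(graphs)
        self.mol_ids = [g.mol_id for g in graphs]
        self.x = np.ascontiguousarray(np.concatenate(xs), dtype=np.float32)
        n_nodes = self.x.shape[0]
        loop = np.arange(n_nodes)
        self.src = np.concatenate(srcs + [loop]).astype(np.int64)
        self.dst = np.concatenate(dsts + [loop]).astype(np.int64)
        edge_dim = eattrs[0].shape[1] if eattrs[0].ndim == 2 else 0
        self.edge_attr = np.ascontiguousarray(
            np.concatenate(eattrs + [np.zeros((n_nodes, edge_dim))]), dtype=np.float32
        )
        self.node_graph = np.concatenate(membership).astype(np.int64)
        self.n_nodes = n_nodes
        # segment index over incoming edges, sorted by destination
        self.perm = np.argsort(self.dst, kind="stable")
        self.inv_perm = np.empty_like(self.perm)
        self.inv_perm[self.perm] = np.arange(self.perm.size)
        self.sdst = self.dst[self.perm]
        self.seg_start = np.searchsorted(self.sdst, np.arange(n_nodes))
        # sparse incidence operators: segment sums over destination / source
        # nodes become CSR matmuls (much faster than scatter-add loops)
        n_edges = self.src.size
        ones = np.ones(n_edges, dtype=np.float32)
        self.agg_dst = sparse.csr_matrix(
            (ones, (self.dst, np.arange(n_edges))), shape=(n_nodes, n_edges)
        )
        self.agg_src = sparse.csr_matrix(
            (ones, (self.src, np.arange(n_edges))), shape=(n_nodes, n_edges)
        )
        self.graph_sizes = np.bincount(self.node_graph, minlength=self.n_graphs).astype(np.float64)


def global_mean_pool(node_features: np.ndarray, graph_membership: np.ndarray,
                     n_graphs: int | None = None) -> np.ndarray:
    """Average node vectors per graph → (B, D) embedding matrix."""
    if node_features.shape[0] != graph_membership.shape[0]:
        raise ValueError("membership must cover all nodes")
    b = int(graph_membership.max()) + 1 if n_graphs is None else n_graphs
    counts = np.bincount(graph_membership, minlength=b).astype(np.float64)
    if np.any(counts == 0):
        raise ValueError("every graph in the batch needs at least one node")
    out = np.zeros((b, node_features.shape[1]))
    np.add.at(out, graph_membership, node_features)
    return out / counts[:, None]


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _ParamEntry:
    name: str
    shape: tuple[int, ...]
    offset: int

    @property
    def size(self) -> int:
        return int(np.prod(self.shape))


def _build_param_spec(cfg: EGATConfig, node_dim: int, edge_dim: int) -> list[_ParamEntry]:
    entries: list[_ParamEntry] = []
    offset = 0

    def add(name, shape):
        nonlocal offset
        entries.append(_ParamEntry(name, tuple(shape), offset))
        offset += int(np.prod(shape))

    f_in = node_dim
    h = cfg.n_heads
    for layer in range(cfg.n_message_layers):
        last = layer == cfg.n_message_layers - 1
        d_out = cfg.hidden_dim if last else cfg.hidden_dim // h
        add(f"layer{layer}.W", (f_in, h, d_out))
        add(f"layer{layer}.We", (edge_dim, h, d_out))
        add(f"layer{layer}.a_src", (h, d_out))
        add(f"layer{layer}.a_dst", (h, d_out))
        add(f"layer{layer}.a_edge", (h, d_out))
        f_in = cfg.hidden_dim
    d = f_in  # embedding width (node_dim when there are no message layers)
    for i, width in enumerate(cfg.head_dims):
        add(f"fc{i}.W", (d, width))
        add(f"fc{i}.b", (width,))
        d = width
    return entries


def count_parameters(config: EGATConfig, node_dim: int, edge_dim: int) -> int:
    """Closed-form total parameter count for a feature scheme of the given widths."""
    config.validate()
    return sum(e.size for e in _build_param_spec(config, node_dim, edge_dim))


def _elu(x):
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _elu_grad(x):
    return np.where(x > 0, 1.0, np.exp(np.minimum(x, 0.0)))


class EGATModel:
    """The regressor bound to a fixed feature-scheme width."""

    def __init__(self, config: EGATConfig, node_dim: int, edge_dim: int):
        config.validate()
        self.config = config
        self.node_dim = node_dim
        self.edge_dim = edge_dim
        self.param_spec = _build_param_spec(config, node_dim, edge_dim)
        self.n_params = sum(e.size for e in self.param_spec)
        self._index = {e.name: e for e in self.param_spec}

    # -- parameter plumbing -------------------------------------------------

    def get(self, params: np.ndarray, name: str) -> np.ndarray:
        e = self._index[name]
        return params[e.offset : e.offset + e.size].reshape(e.shape)

    def init_params(self, seed: int | None = None) -> np.ndarray:
        """Seeded uniform Glorot initialization (biases zero)."""
        rng = np.random.default_rng(self.config.seed if seed is None else seed)
        flat = np.zeros(self.n_params)
        for e in self.param_spec:
            view = flat[e.offset : e.offset + e.size]
            if e.name.endswith(".b"):
                continue
            if len(e.shape) == 3:           # (fan_in, heads, fan_out)
                fan_in, _, fan_out = e.shape
            elif len(e.shape) == 2 and e.name.startswith("fc"):
                fan_in, fan_out = e.shape
            else:                            # attention vectors (heads, d)
                fan_in, fan_out = e.shape[-1] * 3, 1
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            view[:] = rng.uniform(-limit, limit, size=e.size)
        return flat

    # -- forward ------------------------------------------------------------

    def _segment_softmax(self, batch: GraphBatch, scores: np.ndarray) -> np.ndarray:
        """Softmax over incoming edges per destination node (max-subtracted)."""
        ssort = scores[batch.perm]
        seg_max = np.maximum.reduceat(ssort, batch.seg_start, axis=0)
        ex = np.exp(scores - seg_max[batch.dst])
        seg_sum = batch.agg_dst @ ex
        return ex / seg_sum[batch.dst]

    def forward(
        self,
        batch: GraphBatch,
        params: np.ndarray,
        training: bool = False,
        dropout_rng: np.random.Generator | None = None,
        return_cache: bool = False,
    ):
        """Returns (predictions (B, 5), embeddings (B, hidden)[, cache]).

        Deterministic in evaluation mode; dropout is applied only when
        ``training`` is true and ``dropout_rate`` > 0.
        """
        cfg = self.config
        if batch.x.shape[1] != self.node_dim or batch.edge_attr.shape[1] != self.edge_dim:
            raise ValueError(
                f"feature widths ({batch.x.shape[1]}, {batch.edge_attr.shape[1]}) do not "
                f"match the model's scheme ({self.node_dim}, {self.edge_dim})"
            )
        drop = cfg.dropout_rate if training else 0.0
        if drop > 0 and dropout_rng is None:
            raise ValueError("training with dropout requires a dropout_rng")
        # precision follows the parameter vector: float32 params give a
        # single-precision training path, float64 an exactly checkable one
        x = batch.x.astype(params.dtype, copy=False)
        edge_attr = batch.edge_attr.astype(params.dtype, copy=False)
        layer_caches = []
        for layer in range(cfg.n_message_layers):
            last = layer == cfg.n_message_layers - 1
            w = self.get(params, f"layer{layer}.W")
            we = self.get(params, f"layer{layer}.We")
            a_src = self.get(params, f"layer{layer}.a_src")
            a_dst = self.get(params, f"layer{layer}.a_dst")
            a_edge = self.get(params, f"layer{layer}.a_edge")
            f_in, h_heads, d_out = w.shape
            z = (x @ w.reshape(f_in, -1)).reshape(-1, h_heads, d_out)   # (N, H, d)
            # score projections a·(W h) collapse to single matmuls
            c_src = x @ (w * a_src[None]).sum(axis=2)                   # (N, H)
            c_dst = x @ (w * a_dst[None]).sum(axis=2)
            c_edge = edge_attr @ (we * a_edge[None]).sum(axis=2)  # (E, H)
            u = c_src[batch.src] + c_dst[batch.dst] + c_edge   # (E, H)
            s = np.where(u > 0, u, cfg.attn_slope * u)
            alpha = self._segment_softmax(batch, s)
            weighted = (alpha[..., None] * z[batch.src]).reshape(len(batch.src), -1)
            m = (batch.agg_dst @ weighted).reshape(batch.n_nodes, h_heads, d_out)
            if last:
                mbar = m.mean(axis=1)
                out = _elu(mbar)
                pre = mbar
            else:
                pre = m
                out = _elu(m).reshape(batch.n_nodes, -1)
            mask = None
            if drop > 0:
                mask = (dropout_rng.random(out.shape) >= drop) / (1.0 - drop)
                out = out * mask
            layer_caches.append(
                dict(x=x, z=z, u=u, alpha=alpha, pre=pre, last=last, mask=mask)
            )
            x = out
        embeddings = global_mean_pool(x, batch.node_graph, batch.n_graphs)
        # fully connected head (ELU between layers, linear output)
        h = embeddings
        fc_caches = []
        n_fc = len(cfg.head_dims)
        for i in range(n_fc):
            w = self.get(params, f"fc{i}.W")
            b = self.get(params, f"fc{i}.b")
            lin = h @ w + b
            if i < n_fc - 1:
                out = _elu(lin)
                mask = None
                if drop > 0:
                    mask = (dropout_rng.random(out.shape) >= drop) / (1.0 - drop)
                    out = out * mask
            else:
                out, mask = lin, None
            fc_caches.append(dict(h=h, lin=lin, mask=mask))
            h = out
        preds = h
        if return_cache:
            cache = dict(batch=batch, edge_attr=edge_attr, layers=layer_caches,
                         fcs=fc_caches, embeddings=embeddings, pooled_input=x)
            return preds, embeddings, cache
        return preds, embeddings

    # -- backward -----------------------------------------------------------

    def backward(self, params: np.ndarray, cache: dict, dpreds: np.ndarray) -> np.ndarray:
        """Gradient of a scalar loss w.r.t. all parameters, given dL/dpredictions."""
        cfg = self.config
        batch: GraphBatch = cache["batch"]
        edge_attr = cache["edge_attr"]
        grad = np.zeros_like(params)

        def gview(name):
            e = self._index[name]
            return grad[e.offset : e.offset + e.size].reshape(e.shape)

        # head
        dh = dpreds
        n_fc = len(cfg.head_dims)
        for i in reversed(range(n_fc)):
            fc = cache["fcs"][i]
            if i < n_fc - 1:
                if fc["mask"] is not None:
                    dh = dh * fc["mask"]
                dh = dh * _elu_grad(fc["lin"])
            gview(f"fc{i}.W")[...] += fc["h"].T @ dh
            gview(f"fc{i}.b")[...] += dh.sum(axis=0)
            dh = dh @ self.get(params, f"fc{i}.W").T
        # pooling
        counts = batch.graph_sizes
        dx = dh[batch.node_graph] / counts[batch.node_graph][:, None]
        # message layers
        for layer in reversed(range(cfg.n_message_layers)):
            lc = cache["layers"][layer]
            z, u, alpha, pre = lc["z"], lc["u"], lc["alpha"], lc["pre"]
            n, h_heads, d = z.shape
            if lc["mask"] is not None:
                dx = dx * lc["mask"]
            if lc["last"]:
                dm = (dx * _elu_grad(pre))[:, None, :] / h_heads   # broadcast (N, 1, d)
                dm = np.broadcast_to(dm, (n, h_heads, d))
            else:
                dm = (dx.reshape(n, h_heads, d)) * _elu_grad(pre)
            # aggregation m_t = sum_e alpha_e z[src_e]
            dm_at_dst = dm[batch.dst]                  # (E, H, d)
            z_src = z[batch.src]
            dalpha = (dm_at_dst * z_src).sum(axis=2)
            n_e = len(batch.src)
            dz = (batch.agg_src @ (alpha[..., None] * dm_at_dst).reshape(n_e, -1)).reshape(
                n, h_heads, d
            )
            # softmax backward per destination segment
            seg = batch.agg_dst @ (alpha * dalpha)                 # (N, H)
            ds = alpha * (dalpha - seg[batch.dst])
            du = ds * np.where(u > 0, 1.0, cfg.attn_slope)
            # score terms: per-node gathered score gradients
            a_src = self.get(params, f"layer{layer}.a_src")
            a_dst = self.get(params, f"layer{layer}.a_dst")
            a_edge = self.get(params, f"layer{layer}.a_edge")
            we = self.get(params, f"layer{layer}.We")
            dc_src = batch.agg_src @ du
            dc_dst = batch.agg_dst @ du
            gview(f"layer{layer}.a_src")[...] += (z * dc_src[:, :, None]).sum(axis=0)
            gview(f"layer{layer}.a_dst")[...] += (z * dc_dst[:, :, None]).sum(axis=0)
            dz += dc_src[:, :, None] * a_src[None] + dc_dst[:, :, None] * a_dst[None]
            # edge path: c_edge = E @ (We ⊙ a_edge).sum(d); factor through F_e
            dv_edge = edge_attr.T @ du                       # (F_e, H)
            gview(f"layer{layer}.a_edge")[...] += (we * dv_edge[:, :, None]).sum(axis=0)
            gview(f"layer{layer}.We")[...] += dv_edge[:, :, None] * a_edge[None]
            # node linear transform collects all z-paths
            x_in = lc["x"]
            w = self.get(params, f"layer{layer}.W")
            dz_flat = dz.reshape(n, h_heads * d)
            gview(f"layer{layer}.W")[...] += (x_in.T @ dz_flat).reshape(w.shape)
            dx = dz_flat @ w.reshape(-1, h_heads * d).T
        return grad

    # -- loss ---------------------------------------------------------------

    def loss_and_grad(
        self,
        batch: GraphBatch,
        targets: np.ndarray,
        params: np.ndarray,
        training: bool = True,
        dropout_rng: np.random.Generator | None = None,
    ) -> tuple[float, np.ndarray]:
        """Mean squared error over all (graph, property) entries and its gradient."""
        preds, _, cache = self.forward(
            batch, params, training=training, dropout_rng=dropout_rng, return_cache=True
        )
        resid = preds - targets
        loss = float(np.mean(resid**2))
        dpreds = 2.0 * resid / resid.size
        return loss, self.backward(params, cache, dpreds)
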