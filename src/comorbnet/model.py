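"""Meta-path-aggregated attention embedding of disease nodes.

The embedding composes five stages:

1. **Node content projection** — each node type's features are mapped into a
   shared d'-dimensional latent space by a type-specific linear map.
2. **Relational rotation encoding** — each meta-path instance is folded into
   one vector by iteratively rotating the running sum with a per-edge-type
   unit phasor (RotatE-style composition on d'/2 complex components) and
   dividing by the instance length, so path structure, not just the node
   set, shapes the encoding.
3. **Intra-meta-path attention** — per target disease and schema, a
   multi-head additive attention over the target's instances produces one
   vector per schema (softmax-normalized coefficients per head).
4. **Inter-meta-path attention** — schema-level summaries (mean of
   tanh-transformed per-node vectors) are scored by a shared query vector;
   the resulting softmax weights fuse the per-schema vectors.
5. **Output projection** — a final linear map plus nonlinearity yields the
   embedding used for pair scoring.

Relation vectors are parameterised by phase angles, so their components sit
on the complex unit circle by construction; traversing an edge layer
against its canonical orientation conjugates the phasor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .graph import EdgeType, HeterogeneousGraph, NodeType
from .metapaths import DEFAULT_INSTANCE_CAP, SCHEMAS, MetaPathSchema, \
    enumerate_metapath_instances

logger = logging.getLogger(__name__)

_ACTIVATIONS = {
    "elu": ad.elu,
    "tanh": ad.tanh,
    "identity": lambda t: t,
}


@dataclass(frozen=True)
class EmbeddingConfig:
    """Dimensions and regularisation of the embedding model.

    hidden_dim: shared latent dimension d' (must be even for the complex
        rotation and divisible by `heads`).
    out_dim: final embedding dimension (64 by default).
    heads: attention heads in intra-meta-path aggregation (8 by default).
    summary_dim: dimension of the inter-meta-path attention space (128).
    dropout: rate applied to projected features and attention coefficients
        during training only.
    activation: nonlinearity used after intra-path aggregation and the
        output projection ('elu', 'tanh' or 'identity').
    feature_mode: 'learnable' free per-node features, or 'onehot'.
    metapaths: schema ids to aggregate over.
    instance_cap: per-(target, schema) instance subsample size (None = all).
    seed: parameter initialisation / instance subsampling seed.
    """

    hidden_dim: int = 64
    out_dim: int = 64
    heads: int = 8
    summary_dim: int = 128
    dropout: float = 0.5
    activation: str = "elu"
    feature_mode: str = "learnable"
    metapaths: tuple[str, ...] = ("M1", "M2", "M3", "M4")
    instance_cap: int | None = DEFAULT_INSTANCE_CAP
    seed: int = 0

    def __post_init__(self):
        if self.hidden_dim <= 0 or self.out_dim <= 0 or self.summary_dim <= 0:
            raise ValueError("all dimensions must be positive")
        if self.hidden_dim % 2:
            raise ValueError("hidden_dim must be even (complex pairs)")
        if self.hidden_dim % self.heads:
            raise ValueError("heads must divide hidden_dim")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        for m in self.metapaths:
            if m not in SCHEMAS:
                raise ValueError(f"unknown meta-path schema {m!r}")


class GraphIndex:
    """Integer-indexed view of a graph plus enumerated meta-path instances.

    Built once per (graph, config); training epochs reuse it.  For each
    schema the instances of every disease target are stacked into one
    (n_instances, path_length) array of type-local node indices.
    """

    def __init__(self, graph: HeterogeneousGraph, config: EmbeddingConfig):
        self.graph = graph
        self.config = config
        self.type_nodes: dict[NodeType, list[str]] = {
            t: graph.nodes_of_type(t) for t in NodeType}
        self.local_index: dict[NodeType, dict[str, int]] = {
            t: {n: i for i, n in enumerate(nodes)}
            for t, nodes in self.type_nodes.items()}
        self.disease_ids = self.type_nodes[NodeType.DISEASE]
        self.n_diseases = len(self.disease_ids)
        self.instances: dict[str, np.ndarray] = {}
        self.instance_targets: dict[str, np.ndarray] = {}
        starved: dict[str, int] = {}
        for si, schema_id in enumerate(config.metapaths):
            schema = SCHEMAS[schema_id]
            rows: list[list[int]] = []
            targets: list[int] = []
            for di, disease in enumerate(self.disease_ids):
                sub_seed = np.random.SeedSequence(
                    [config.seed, si, di]).generate_state(1)[0]
                walks = enumerate_metapath_instances(
                    graph, schema, disease, cap=config.instance_cap,
                    seed=int(sub_seed))
                if not walks:
                    starved[disease] = starved.get(disease, 0) + 1
                    continue
                for walk in walks:
                    rows.append([self.local_index[t][n]
                                 for t, n in zip(schema.node_types, walk)])
                    targets.append(di)
            self.instances[schema_id] = np.asarray(
                rows, dtype=np.intp).reshape(len(rows), schema.length)
            self.instance_targets[schema_id] = np.asarray(targets, dtype=np.intp)
        if starved:
            logger.info("%d disease nodes lack instances on at least one "
                        "meta-path: %s%s", len(starved),
                        sorted(starved)[:5], "..." if len(starved) > 5 else "")


def init_params(index: GraphIndex, config: EmbeddingConfig,
                features: dict[NodeType, np.ndarray] | None = None,
                ) -> dict[str, Tensor]:
    """Initialise every learnable tensor (Glorot-scaled normals; phases
    uniform on [-pi, pi))."""
    rng = np.random.default_rng(config.seed)
    params: dict[str, Tensor] = {}

    def glorot(shape):
        std = np.sqrt(2.0 / sum(shape))
        return Tensor(rng.normal(0.0, std, size=shape), requires_grad=True)

    d = config.hidden_dim
    for t in NodeType:
        n = len(index.type_nodes[t])
        if n == 0:
            continue
        if features is not None and t in features:
            x = np.asarray(features[t], dtype=np.float64)
            if x.shape[0] != n:
                raise ValueError(f"feature matrix for {t.value} has "
                                 f"{x.shape[0]} rows, expected {n}")
            params[f"X_{t.value}"] = Tensor(x)
        elif config.feature_mode == "onehot":
            params[f"X_{t.value}"] = Tensor(np.eye(n))
        else:
            params[f"X_{t.value}"] = glorot((n, d))
        d_a = params[f"X_{t.value}"].shape[1]
        params[f"W_{t.value}"] = glorot((d_a, d))
    for et in EdgeType:
        params[f"theta_{et.value}"] = Tensor(
            rng.uniform(-np.pi, np.pi, size=d // 2), requires_grad=True)
    head_dim = d // config.heads
    for schema_id in config.metapaths:
        params[f"a_{schema_id}"] = glorot((config.heads, 2 * head_dim))
    params["M_A"] = glorot((d, config.summary_dim))
    params["b_A"] = Tensor(np.zeros(config.summary_dim), requires_grad=True)
    params["q_A"] = glorot((config.summary_dim,))
    params["W_o"] = glorot((d, config.out_dim))
    return params


def trainable(params: dict[str, Tensor]) -> list[Tensor]:
    return [p for p in params.values() if p.requires_grad]


# ---------------------------------------------------------------------------
# forward stages


def project_node_features(x: Tensor | np.ndarray, w: Tensor | np.ndarray,
                          ) -> Tensor:
    """Project per-type features into the shared latent space: h' = x W."""
    x = x if isinstance(x, Tensor) else Tensor(x)
    w = w if isinstance(w, Tensor) else Tensor(w)
    if x.shape[-1] != w.shape[0]:
        raise ValueError(f"feature dim {x.shape[-1]} does not match "
                         f"projection input dim {w.shape[0]}")
    return ad.matmul(x, w)


def encode_instances(gathered: list[Tensor], schema: MetaPathSchema,
                     params: dict[str, Tensor]) -> Tensor:
    """Relational rotation encoding of stacked instances.

    `gathered[j]` holds the projected vectors of node position j for every
    instance, shape (n_instances, d').  The recursion o_i = h'_{t_i} +
    o_{i-1} (x) r_i runs from the target end; the result is divided by the
    node count.
    """
    o = gathered[0]
    for i, (et, sign) in enumerate(zip(schema.edge_types, schema.edge_signs),
                                   start=1):
        theta = params.get(f"theta_{et.value}")
        if theta is None:
            raise ValueError(f"no relation vector for edge type {et.value}")
        o = ad.add(gathered[i], ad.complex_rotate(o, theta, sign=float(sign)))
    return ad.scale(o, 1.0 / schema.length)


def encode_instance(node_vectors: np.ndarray, schema: MetaPathSchema | str,
                    params: dict[str, Tensor]) -> np.ndarray:
    """Encode a single instance given its (path_length, d') node vectors."""
    if isinstance(schema, str):
        schema = SCHEMAS[schema]
    node_vectors = np.asarray(node_vectors, dtype=np.float64)
    if node_vectors.ndim != 2 or node_vectors.shape[0] != schema.length:
        raise ValueError("node_vectors must be (path_length, d')")
    gathered = [Tensor(node_vectors[j][None, :]) for j in range(schema.length)]
    return encode_instances(gathered, schema, params).data[0]


def _dropout(t: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    mask = (rng.random(t.shape) >= rate) / (1.0 - rate)
    return ad.mul(t, Tensor(mask))


def intra_metapath_aggregate(h_inst: Tensor, h_targets: Tensor,
                             targets: np.ndarray, n_targets: int,
                             attn_vec: Tensor, config: EmbeddingConfig,
                             training: bool = False,
                             rng: np.random.Generator | None = None,
                             return_alpha: bool = False):
    """Multi-head attention over each target's instances -> (n_targets, d').

    Per head k the instance logit is LeakyReLU(a_k . [h'_d || h_inst]) on
    the head's feature slice; coefficients are softmax-normalized over the
    instances of each target; targets without instances receive the
    activation of the zero vector.
    """
    d, heads = config.hidden_dim, config.heads
    head_dim = d // heads
    act = _ACTIVATIONS[config.activation]
    n_inst = h_inst.shape[0]
    if n_inst == 0:
        zeros = Tensor(np.zeros((n_targets, d)))
        out = act(zeros)
        return (out, None) if return_alpha else out
    hh = ad.reshape(h_inst, (n_inst, heads, head_dim))
    ht = ad.reshape(h_targets, (n_inst, heads, head_dim))
    cat = ad.concat([ht, hh], axis=-1)
    logits = ad.tensor_sum(
        ad.mul(cat, ad.reshape(attn_vec, (1, heads, 2 * head_dim))), axis=-1)
    e = ad.leaky_relu(logits)
    alpha = ad.segment_softmax(e, targets, n_targets)
    if training and config.dropout > 0:
        alpha = _dropout(alpha, config.dropout, rng)
    weighted = ad.mul(ad.reshape(alpha, (n_inst, heads, 1)), hh)
    agg = ad.segment_sum(weighted, targets, n_targets)
    out = act(ad.reshape(agg, (n_targets, d)))
    return (out, alpha) if return_alpha else out


def summarize_metapath(h_p: Tensor, m_a: Tensor, b_a: Tensor) -> Tensor:
    """Schema summary s_P = mean_d tanh(M_A h^P_d + b_A)."""
    return ad.tensor_mean(ad.tanh(ad.add(ad.matmul(h_p, m_a), b_a)), axis=0)


def inter_metapath_aggregate(h_by_schema: list[Tensor],
                             summaries: list[Tensor], q_a: Tensor,
                             return_beta: bool = False):
    """Fuse per-schema vectors with softmax weights over schema summaries.

    One global weight per schema, shared by every disease node.
    """
    logits = ad.concat([ad.reshape(ad.tensor_sum(ad.mul(q_a, s)), (1,))
                        for s in summaries], axis=0)
    beta = ad.softmax(logits, axis=0)
    fused = None
    for i, h_p in enumerate(h_by_schema):
        term = ad.mul(h_p, ad.take_rows(beta, np.array([i])))
        fused = term if fused is None else ad.add(fused, term)
    return (fused, beta) if return_beta else fused


def project_output(fused: Tensor, w_o: Tensor, activation: str = "elu",
                   ) -> Tensor:
    """Final linear map plus nonlinearity: h_d = act(W_o h^{P_A}_d)."""
    if fused.shape[-1] != w_o.shape[0]:
        raise ValueError(f"fused dim {fused.shape[-1]} does not match output "
                         f"projection input dim {w_o.shape[0]}")
    return _ACTIVATIONS[activation](ad.matmul(fused, w_o))


def forward_embed(index: GraphIndex, params: dict[str, Tensor],
                  config: EmbeddingConfig | None = None,
                  training: bool = False,
                  rng: np.random.Generator | None = None,
                  return_attention: bool = False):
    """Full forward pass -> Tensor of disease embeddings (n_diseases, out_dim).

    Deterministic in eval mode; during training, dropout draws come from
    `rng` (required if config.dropout > 0).
    """
    config = config or index.config
    if training and config.dropout > 0 and rng is None:
        raise ValueError("training-mode forward with dropout needs an rng")
    act = config.activation
    h_proj: dict[NodeType, Tensor] = {}
    for t in NodeType:
        if not index.type_nodes[t]:
            continue
        h = project_node_features(params[f"X_{t.value}"], params[f"W_{t.value}"])
        if training and config.dropout > 0:
            h = _dropout(h, config.dropout, rng)
        h_proj[t] = h
    h_by_schema, summaries, alphas = [], [], {}
    for schema_id in config.metapaths:
        schema = SCHEMAS[schema_id]
        inst = index.instances[schema_id]
        targets = index.instance_targets[schema_id]
        if inst.shape[0]:
            gathered = [ad.take_rows(h_proj[t], inst[:, j])
                        for j, t in enumerate(schema.node_types)]
            h_inst = encode_instances(gathered, schema, params)
            h_tgt = ad.take_rows(h_proj[NodeType.DISEASE], inst[:, 0])
        else:
            h_inst = Tensor(np.zeros((0, config.hidden_dim)))
            h_tgt = Tensor(np.zeros((0, config.hidden_dim)))
        h_p, alpha = intra_metapath_aggregate(
            h_inst, h_tgt, targets, index.n_diseases,
            params[f"a_{schema_id}"], config, training=training, rng=rng,
            return_alpha=True)
        alphas[schema_id] = alpha
        h_by_schema.append(h_p)
        summaries.append(summarize_metapath(h_p, params["M_A"], params["b_A"]))
    fused, beta = inter_metapath_aggregate(h_by_schema, summaries,
                                           params["q_A"], return_beta=True)
    out = project_output(fused, params["W_o"], activation=act)
    if return_attention:
        return out, {"alpha": alphas, "beta": beta}
    return out


def embed_diseases(graph: HeterogeneousGraph, params: dict[str, Tensor],
                   config: EmbeddingConfig) -> tuple[list[str], np.ndarray]:
    """Convenience eval-mode embedding of every disease node."""
    index = GraphIndex(graph, config)
    emb = forward_embed(index, params, config, training=False)
    return index.disease_ids, emb.data
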