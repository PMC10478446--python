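"""Attention-based graph neural network for molecular property regression.

The backbone follows the Attentive FP design: atoms are embedded from their
76-dimensional feature vectors, passed through attention-gated
message-passing layers (each combining neighbor messages by a learned
softmax attention over incoming edges, then updating node states with a
GRU cell; the first layer's messages also carry bond features), and pooled
by an attentive super-node readout (a virtual graph node that repeatedly
attends over all atoms and updates through its own GRU). The pooled vector
passes through batch normalization, dropout and a two-layer MLP that emits
one output (retention-time pretraining) or two (logD and logP heads).

Everything runs on the package's own NumPy autodiff engine, so training and
inference are CPU-only and bit-reproducible under a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace

import numpy as np

from ._autodiff import Tensor, concat, segment_softmax
from .featurize import ATOM_FDIM, BOND_FDIM, FEATURIZATION_VERSION, MolecularGraph

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


@dataclass(frozen=True)
class ModelConfig:
    hidden_dim: int = 200
    n_message_layers: int = 3
    n_readout_timesteps: int = 2
    dropout_p: float = 0.2
    n_heads_out: int = 1
    mlp_layers: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must lie in [0, 1)")
        if self.hidden_dim <= 0 or self.n_message_layers < 1:
            raise ValueError("hidden_dim > 0 and n_message_layers >= 1 required")
        if self.n_heads_out not in (1, 2):
            raise ValueError("n_heads_out must be 1 or 2")
        if self.mlp_layers != 2:
            raise ValueError("the output MLP has two fully connected layers")


@dataclass
class GraphBatch:
    """Disjoint union of molecular graphs with directed edge arrays."""

    x: np.ndarray         # (N, 76) atom features
    edge_feats: np.ndarray  # (E, 12), each undirected bond twice
    src: np.ndarray       # (E,) source atom of each directed edge
    dst: np.ndarray       # (E,)
    graph_id: np.ndarray  # (N,) molecule index per atom
    n_graphs: int


def batch_graphs(graphs: list[MolecularGraph]) -> GraphBatch:
    xs, efs, srcs, dsts, gids = [], [], [], [], []
    offset = 0
    for gi, g in enumerate(graphs):
        if g.atom_features.shape[1] != ATOM_FDIM:
            raise ValueError(
                f"atom feature width {g.atom_features.shape[1]} != expected {ATOM_FDIM}"
            )
        xs.append(g.atom_features)
        gids.append(np.full(g.n_atoms, gi, dtype=np.int64))
        if len(g.bonds):
            b = g.bonds + offset
            srcs.append(np.concatenate([b[:, 0], b[:, 1]]))
            dsts.append(np.concatenate([b[:, 1], b[:, 0]]))
            efs.append(np.vstack([g.bond_features, g.bond_features]))
        offset += g.n_atoms
    cat = lambda parts, width: (
        np.concatenate(parts) if parts else np.zeros(0, dtype=np.int64)
    )
    return GraphBatch(
        x=np.vstack(xs),
        edge_feats=np.vstack(efs) if efs else np.zeros((0, BOND_FDIM)),
        src=cat(srcs, 0).astype(np.int64),
        dst=cat(dsts, 0).astype(np.int64),
        graph_id=np.concatenate(gids),
        n_graphs=len(graphs),
    )


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=(fan_in, fan_out))


def _gru_params(rng, h: int, prefix: str) -> dict[str, np.ndarray]:
    return {
        f"{prefix}.wx": _glorot(rng, h, 3 * h),
        f"{prefix}.wh": _glorot(rng, h, 3 * h),
        f"{prefix}.b": np.zeros(3 * h),
    }


class Model:
    """The graph attention regressor. Build with :func:`build_model`."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.featurization_version = FEATURIZATION_VERSION
        self.training_meta: dict = {}
        h = config.hidden_dim
        rng = np.random.default_rng(seed)
        w: dict[str, np.ndarray] = {
            "embed.w": _glorot(rng, ATOM_FDIM, h),
            "embed.b": np.zeros(h),
            "bond.w": _glorot(rng, h + BOND_FDIM, h),
            "bond.b": np.zeros(h),
        }
        for l in range(config.n_message_layers):
            w[f"mp{l}.align_w"] = _glorot(rng, 2 * h, 1)
            w[f"mp{l}.align_b"] = np.zeros(1)
            w[f"mp{l}.msg_w"] = _glorot(rng, h, h)
            w.update(_gru_params(rng, h, f"mp{l}.gru"))
        w["read.align_w"] = _glorot(rng, 2 * h, 1)
        w["read.align_b"] = np.zeros(1)
        w["read.msg_w"] = _glorot(rng, h, h)
        w.update(_gru_params(rng, h, "read.gru"))
        w["bn.gamma"] = np.ones(h)
        w["bn.beta"] = np.zeros(h)
        h2 = max(h // 2, 1)
        w["mlp.w"] = _glorot(rng, h, h2)
        w["mlp.b"] = np.zeros(h2)
        w["head.w"] = _glorot(rng, h2, config.n_heads_out)
        w["head.b"] = np.zeros(config.n_heads_out)
        self.params = {k: Tensor(v, requires_grad=True) for k, v in w.items()}
        self.bn_running_mean = np.zeros(h)
        self.bn_running_var = np.ones(h)
        self._last_attention: np.ndarray | None = None

    # -- pieces --------------------------------------------------------------
    def _gru(self, prefix: str, x: Tensor, hstate: Tensor) -> Tensor:
        h = self.config.hidden_dim
        p = self.params
        gx = x @ p[f"{prefix}.wx"] + p[f"{prefix}.b"]
        gh = hstate @ p[f"{prefix}.wh"]
        r = (gx[slice(0, h)] + gh[slice(0, h)]).sigmoid()
        z = (gx[slice(h, 2 * h)] + gh[slice(h, 2 * h)]).sigmoid()
        n = (gx[slice(2 * h, 3 * h)] + r * gh[slice(2 * h, 3 * h)]).tanh()
        return (1.0 - z) * n + z * hstate

    def forward(
        self,
        batch: GraphBatch | list[MolecularGraph],
        training: bool = False,
        dropout_rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Predictions, shape (n_graphs, n_heads_out).

        In training mode batch statistics drive the normalization layer and
        dropout masks are drawn from ``dropout_rng``; in inference mode the
        layer uses its running statistics and dropout is disabled, so
        repeated calls are identical.
        """
        if isinstance(batch, list):
            batch = batch_graphs(batch)
        if batch.x.shape[1] != ATOM_FDIM:
            raise ValueError(f"atom feature width {batch.x.shape[1]} != expected {ATOM_FDIM}")
        p = self.params
        n_atoms = batch.x.shape[0]

        x = Tensor(batch.x)
        hidden = (x @ p["embed.w"] + p["embed.b"]).leaky_relu()

        has_edges = batch.src.size > 0
        if has_edges:
            e = Tensor(batch.edge_feats)
            edge_h = (
                concat([hidden.gather(batch.src), e]) @ p["bond.w"] + p["bond.b"]
            ).leaky_relu()

        for l in range(self.config.n_message_layers):
            if not has_edges:
                ctx = Tensor(np.zeros_like(hidden.data))
            else:
                nbr = edge_h if l == 0 else hidden.gather(batch.src)
                align = (
                    concat([hidden.gather(batch.dst), nbr]) @ p[f"mp{l}.align_w"]
                    + p[f"mp{l}.align_b"]
                ).leaky_relu()
                att = segment_softmax(align, batch.dst, n_atoms)
                ctx = (att * (nbr @ p[f"mp{l}.msg_w"])).segment_sum(batch.dst, n_atoms).elu()
            hidden = self._gru(f"mp{l}.gru", ctx, hidden)

        g = hidden.segment_sum(batch.graph_id, batch.n_graphs)
        att_data = None
        for _ in range(self.config.n_readout_timesteps):
            align = (
                concat([g.gather(batch.graph_id), hidden]) @ p["read.align_w"]
                + p["read.align_b"]
            ).leaky_relu()
            att = segment_softmax(align, batch.graph_id, batch.n_graphs)
            ctx = (att * (hidden @ p["read.msg_w"])).segment_sum(
                batch.graph_id, batch.n_graphs
            ).elu()
            g = self._gru("read.gru", ctx, g)
            att_data = att.data
        self._last_attention = None if att_data is None else att_data.ravel()

        # batch normalization on the pooled vector
        if training and batch.n_graphs > 1:
            mu = g.mean(axis=0, keepdims=True)
            var = ((g - mu) ** 2).mean(axis=0, keepdims=True)
            self.bn_running_mean = (
                (1 - _BN_MOMENTUM) * self.bn_running_mean + _BN_MOMENTUM * mu.data.ravel()
            )
            self.bn_running_var = (
                (1 - _BN_MOMENTUM) * self.bn_running_var + _BN_MOMENTUM * var.data.ravel()
            )
            g = (g - mu) / ((var + _BN_EPS) ** 0.5)
        else:
            g = (g - Tensor(self.bn_running_mean)) / (
                Tensor(self.bn_running_var + _BN_EPS) ** 0.5
            )
        g = g * p["bn.gamma"] + p["bn.beta"]

        if training and self.config.dropout_p > 0:
            rng = dropout_rng or np.random.default_rng(0)
            keep = 1.0 - self.config.dropout_p
            mask = (rng.random(g.shape) < keep) / keep
            g = g * Tensor(mask)

        z = (g @ p["mlp.w"] + p["mlp.b"]).relu()
        return z @ p["head.w"] + p["head.b"]

    def predict(self, graphs: list[MolecularGraph]) -> np.ndarray:
        return self.forward(graphs, training=False).data

    def atom_attention(self, graph: MolecularGraph) -> np.ndarray:
        """Per-atom readout attention, min-max normalized within the molecule.

        Raw readout attention weights (last readout timestep) are rescaled
        to [0, 1]; if every atom received the same raw weight — including
        the single-atom case — the whole molecule maps to 0.5.
        """
        self.forward([graph], training=False)
        raw = self._last_attention
        if raw is None or raw.size != graph.n_atoms:
            raise RuntimeError("attention cache missing")
        lo, hi = raw.min(), raw.max()
        if hi - lo < 1e-12:
            return np.full(graph.n_atoms, 0.5)
        return (raw - lo) / (hi - lo)

    def zero_grad(self) -> None:
        for t in self.params.values():
            t.grad = None

    def n_parameters(self) -> int:
        return sum(t.data.size for t in self.params.values())

    def copy_backbone_from(self, other: "Model") -> None:
        """Transfer all weights except the output head (fresh heads remain)."""
        for k, t in other.params.items():
            if k.startswith("head."):
                continue
            if k not in self.params or self.params[k].data.shape != t.data.shape:
                raise ValueError(f"incompatible backbone parameter {k}")
            self.params[k].data = t.data.copy()
        self.bn_running_mean = other.bn_running_mean.copy()
        self.bn_running_var = other.bn_running_var.copy()

    # -- persistence ---------------------------------------------------------
    def save(self, path) -> None:
        meta = {
            "config": asdict(self.config),
            "featurization_version": self.featurization_version,
            "training_meta": self.training_meta,
        }
        arrays = {f"w::{k}": t.data for k, t in self.params.items()}
        arrays["bn_running_mean"] = self.bn_running_mean
        arrays["bn_running_var"] = self.bn_running_var
        arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "Model":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            if meta["featurization_version"] != FEATURIZATION_VERSION:
                raise ValueError(
                    "featurization version mismatch: checkpoint "
                    f"{meta['featurization_version']!r} vs current {FEATURIZATION_VERSION!r}"
                )
            model = cls(ModelConfig(**meta["config"]))
            for k in model.params:
                arr = data[f"w::{k}"]
                if arr.shape != model.params[k].data.shape:
                    raise ValueError(f"shape mismatch for parameter {k}")
                model.params[k].data = arr.copy()
            model.bn_running_mean = data["bn_running_mean"].copy()
            model.bn_running_var = data["bn_running_var"].copy()
            model.training_meta = meta["training_meta"]
        return model


def build_model(config: ModelConfig, seed: int = 0) -> Model:
    """Seeded model construction; identical (config, seed) gives identical weights."""
    return Model(config, seed=seed)


def widen_to_multitask(pretrained: Model) -> Model:
    """A 2-head model whose backbone is copied from a pretrained 1-head model."""
    cfg = replace(pretrained.config, n_heads_out=2)
    model = Model(cfg, seed=int(pretrained.training_meta.get("seed", 0)) + 1)
    model.copy_backbone_from(pretrained)
    return model
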