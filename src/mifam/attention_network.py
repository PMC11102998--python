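"""The attention model core.

Per entity type (drugs, targets) the encoder runs ``n_blocks`` blocks on a
fixed similarity graph.  Each block is:

1. a stack of graph-attention (GAT) layers — attention logits
   e_ij = a . [W h_i || W h_j] over each node's neighbourhood, LeakyReLU,
   neighbourhood softmax, ReLU-activated weighted sum; the per-layer outputs
   are concatenated column-wise into V_GAT (width n_layers x heads x hidden);
2. multi-head self-attention (MHSA) over the entity rows of V_GAT — per head
   scaled dot-product attention softmax(Q K^T / sqrt(d_K)) V; the head
   outputs are averaged, and that average is averaged with V_GAT itself to
   give the block output (same width as V_GAT).

Pair scoring concatenates the two entity embeddings and applies a 3-layer
MLP (ReLU hidden, sigmoid output); training minimizes mean squared error.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import numpy as np

from . import _autodiff as ad
from .containers import AdjacencyMatrix, FeatureMatrix, FeatureSource
from .errors import MifamError

DEFAULT_MLP_HIDDEN = (256, 64)


@dataclass
class BlockConfig:
    """Architecture hyperparameters for one GAT+MHSA block (and the stack)."""

    n_gat_layers: int = 4
    hidden_units: int = 16
    gat_heads: int = 1
    mhsa_heads: int = 4
    leaky_slope: float = 0.2
    n_blocks: int = 2

    def __post_init__(self) -> None:
        if min(self.n_gat_layers, self.hidden_units, self.gat_heads,
               self.mhsa_heads, self.n_blocks) < 1:
            raise MifamError("all block-config integers must be >= 1")
        if self.leaky_slope <= 0:
            raise MifamError("leaky_slope must be positive")

    @property
    def block_width(self) -> int:
        """Width of V_GAT = concatenation of all layer outputs."""
        return self.n_gat_layers * self.gat_heads * self.hidden_units


@dataclass
class GATLayerParams:
    """Per-head transform W (d_in x d_hidden) and attention vector a (2 d_hidden)."""

    W: list[np.ndarray]
    a: list[np.ndarray]
    leaky_slope: float = 0.2

    @property
    def n_heads(self) -> int:
        return len(self.W)


@dataclass
class MHSAParams:
    """Per-head query/key/value projections, each (d_model x d_k)."""

    WQ: list[np.ndarray]
    WK: list[np.ndarray]
    WV: list[np.ndarray]

    @property
    def n_heads(self) -> int:
        return len(self.WQ)

    @property
    def d_k(self) -> int:
        return self.WQ[0].shape[1]


@dataclass
class BlockParams:
    gat_layers: list[GATLayerParams]
    mhsa: MHSAParams


@dataclass
class MLPParams:
    """Three fully connected layers; ReLU on hidden, sigmoid on the output."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]


@dataclass
class ModelParams:
    """All learned weights of the model plus its architecture config."""

    drug_blocks: list[BlockParams]
    target_blocks: list[BlockParams]
    mlp: MLPParams
    config: BlockConfig = field(default_factory=BlockConfig)

    def copy(self) -> "ModelParams":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# initialization

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _init_block(rng: np.random.Generator, d_in: int, cfg: BlockConfig) -> BlockParams:
    layers = []
    cur = d_in
    layer_out = cfg.gat_heads * cfg.hidden_units
    for _ in range(cfg.n_gat_layers):
        W = [_glorot(rng, cur, cfg.hidden_units, (cur, cfg.hidden_units))
             for _ in range(cfg.gat_heads)]
        a = [_glorot(rng, 2 * cfg.hidden_units, 1, (2 * cfg.hidden_units,))
             for _ in range(cfg.gat_heads)]
        layers.append(GATLayerParams(W, a, cfg.leaky_slope))
        cur = layer_out
    d_model = cfg.block_width
    mhsa = MHSAParams(
        WQ=[_glorot(rng, d_model, d_model, (d_model, d_model))
            for _ in range(cfg.mhsa_heads)],
        WK=[_glorot(rng, d_model, d_model, (d_model, d_model))
            for _ in range(cfg.mhsa_heads)],
        WV=[_glorot(rng, d_model, d_model, (d_model, d_model))
            for _ in range(cfg.mhsa_heads)],
    )
    return BlockParams(layers, mhsa)


def init_model_params(
    d_drug_in: int,
    d_target_in: int,
    cfg: BlockConfig | None = None,
    seed: int = 0,
    mlp_hidden: tuple[int, int] = DEFAULT_MLP_HIDDEN,
) -> ModelParams:
    """Glorot-uniform initialization of every learned weight, seeded."""
    cfg = cfg or BlockConfig()
    rng = np.random.default_rng(seed)

    def blocks(d_in: int) -> list[BlockParams]:
        out = []
        cur = d_in
        for _ in range(cfg.n_blocks):
            out.append(_init_block(rng, cur, cfg))
            cur = cfg.block_width
        return out

    drug_blocks = blocks(d_drug_in)
    target_blocks = blocks(d_target_in)
    dims = [2 * cfg.block_width, *mlp_hidden, 1]
    mlp = MLPParams(
        weights=[_glorot(rng, dims[i], dims[i + 1], (dims[i], dims[i + 1]))
                 for i in range(3)],
        biases=[np.zeros(dims[i + 1]) for i in range(3)],
    )
    return ModelParams(drug_blocks, target_blocks, mlp, cfg)


# ---------------------------------------------------------------------------
# tensorized parameters (used for both inference and training passes)

def _tensorize(model: ModelParams, trainable: bool) -> tuple[ModelParams, list[ad.Tensor]]:
    """Mirror the parameter structure with autodiff tensors."""
    make = ad.parameter if trainable else ad.constant
    tensors: list[ad.Tensor] = []

    def wrap(arr: np.ndarray) -> ad.Tensor:
        t = make(arr)
        tensors.append(t)
        return t

    def wrap_block(bp: BlockParams) -> BlockParams:
        return BlockParams(
            gat_layers=[
                GATLayerParams([wrap(w) for w in lp.W], [wrap(a) for a in lp.a],
                               lp.leaky_slope)
                for lp in bp.gat_layers
            ],
            mhsa=MHSAParams(
                WQ=[wrap(w) for w in bp.mhsa.WQ],
                WK=[wrap(w) for w in bp.mhsa.WK],
                WV=[wrap(w) for w in bp.mhsa.WV],
            ),
        )

    mirror = ModelParams(
        drug_blocks=[wrap_block(b) for b in model.drug_blocks],
        target_blocks=[wrap_block(b) for b in model.target_blocks],
        mlp=MLPParams([wrap(w) for w in model.mlp.weights],
                      [wrap(b) for b in model.mlp.biases]),
        config=model.config,
    )
    return mirror, tensors


def _write_back(model: ModelParams, mirror: ModelParams) -> None:
    """Copy tensor values from a mirror back into the numpy parameter bundle."""
    for bdst, bsrc in zip(model.drug_blocks + model.target_blocks,
                          mirror.drug_blocks + mirror.target_blocks):
        for ldst, lsrc in zip(bdst.gat_layers, bsrc.gat_layers):
            ldst.W = [t.value.copy() for t in lsrc.W]
            ldst.a = [t.value.copy() for t in lsrc.a]
        bdst.mhsa.WQ = [t.value.copy() for t in bsrc.mhsa.WQ]
        bdst.mhsa.WK = [t.value.copy() for t in bsrc.mhsa.WK]
        bdst.mhsa.WV = [t.value.copy() for t in bsrc.mhsa.WV]
    model.mlp.weights = [t.value.copy() for t in mirror.mlp.weights]
    model.mlp.biases = [t.value.copy() for t in mirror.mlp.biases]


# ---------------------------------------------------------------------------
# tensor-level forward passes

def _gat_attention_T(H: ad.Tensor, mask: np.ndarray, W: ad.Tensor, a: ad.Tensor,
                     slope: float) -> tuple[ad.Tensor, ad.Tensor]:
    """One head's attention matrix and transformed features HW."""
    if W.value.shape[0] != H.value.shape[1]:
        raise MifamError(
            f"GAT weight expects {W.value.shape[0]} input features, "
            f"got {H.value.shape[1]}"
        )
    HW = ad.matmul(H, W)
    d = W.value.shape[1]
    # a . [Wh_i || Wh_j] splits into a source part and a destination part
    f = ad.matvec(HW, ad.slice_vec(a, 0, d))
    g = ad.matvec(HW, ad.slice_vec(a, d, 2 * d))
    E = ad.pairwise_sum(f, g)
    alpha = ad.masked_softmax(ad.leaky_relu(E, slope), mask)
    return alpha, HW


def _gat_layer_T(H: ad.Tensor, mask: np.ndarray, lp: GATLayerParams) -> ad.Tensor:
    heads = []
    for W, a in zip(lp.W, lp.a):
        alpha, HW = _gat_attention_T(H, mask, W, a, lp.leaky_slope)
        heads.append(ad.relu(ad.matmul(alpha, HW)))
    return heads[0] if len(heads) == 1 else ad.concat_cols(heads)


def _gat_stack_T(H0: ad.Tensor, mask: np.ndarray,
                 layers: list[GATLayerParams]) -> ad.Tensor:
    outs = []
    cur = H0
    for lp in layers:
        cur = _gat_layer_T(cur, mask, lp)
        outs.append(cur)
    return outs[0] if len(outs) == 1 else ad.concat_cols(outs)


def _mhsa_heads_T(X: ad.Tensor, p: MHSAParams) -> list[ad.Tensor]:
    if p.WQ[0].value.shape[0] != X.value.shape[1]:
        raise MifamError(
            f"MHSA expects d_model={p.WQ[0].value.shape[0]}, got width "
            f"{X.value.shape[1]}"
        )
    n = X.value.shape[0]
    full = np.ones((n, n), dtype=bool)
    outs = []
    for WQ, WK, WV in zip(p.WQ, p.WK, p.WV):
        Q = ad.matmul(X, WQ)
        K = ad.matmul(X, WK)
        V = ad.matmul(X, WV)
        scores = ad.scale(ad.matmul(Q, ad.transpose(K)),
                          1.0 / np.sqrt(WK.value.shape[1]))
        W = ad.masked_softmax(scores, full)
        outs.append(ad.matmul(W, V))
    return outs


def _block_T(H: ad.Tensor, mask: np.ndarray, bp: BlockParams) -> ad.Tensor:
    V = _gat_stack_T(H, mask, bp.gat_layers)
    M = ad.mean_tensors(_mhsa_heads_T(V, bp.mhsa))
    return ad.scale(ad.add(V, M), 0.5)


def _encode_T(H0: ad.Tensor, mask: np.ndarray, blocks: list[BlockParams]) -> ad.Tensor:
    cur = H0
    for bp in blocks:
        cur = _block_T(cur, mask, bp)
    return cur


def _mlp_T(X: ad.Tensor, mlp: MLPParams) -> ad.Tensor:
    h = ad.relu(ad.add(ad.matmul(X, mlp.weights[0]), mlp.biases[0]))
    h = ad.relu(ad.add(ad.matmul(h, mlp.weights[1]), mlp.biases[1]))
    return ad.sigmoid(ad.add(ad.matmul(h, mlp.weights[2]), mlp.biases[2]))


def _const_layer(lp: GATLayerParams) -> GATLayerParams:
    return GATLayerParams([ad.constant(w) for w in lp.W],
                          [ad.constant(a) for a in lp.a], lp.leaky_slope)


def _const_mhsa(p: MHSAParams) -> MHSAParams:
    return MHSAParams([ad.constant(w) for w in p.WQ],
                      [ad.constant(w) for w in p.WK],
                      [ad.constant(w) for w in p.WV])


def _const_block(bp: BlockParams) -> BlockParams:
    return BlockParams([_const_layer(lp) for lp in bp.gat_layers],
                       _const_mhsa(bp.mhsa))


# ---------------------------------------------------------------------------
# public (numpy / container) API

def _check_aligned(H: FeatureMatrix, A: AdjacencyMatrix) -> None:
    if H.ids != A.ids:
        raise MifamError("feature and adjacency ids do not match")


def gat_attention_coefficients(
    H: FeatureMatrix, A: AdjacencyMatrix, params: GATLayerParams, head: int = 0
) -> np.ndarray:
    """The n x n attention matrix of one head: softmax over each neighbourhood.

    Entries are zero off the neighbourhood and each row sums to 1 over
    N_i united with {i}.
    """
    _check_aligned(H, A)
    alpha, _ = _gat_attention_T(
        ad.constant(H.matrix), A.neighbor_mask(),
        ad.constant(params.W[head]), ad.constant(params.a[head]),
        params.leaky_slope,
    )
    return np.where(A.neighbor_mask(), alpha.value, 0.0)


def gat_layer_forward(
    H: FeatureMatrix, A: AdjacencyMatrix, params: GATLayerParams
) -> FeatureMatrix:
    """One GAT layer: per-head attention-weighted sums, ReLU, head concat."""
    _check_aligned(H, A)
    out = _gat_layer_T(ad.constant(H.matrix), A.neighbor_mask(), _const_layer(params))
    return FeatureMatrix(list(H.ids), out.value, FeatureSource.FUSED)


def gat_stack(
    H0: FeatureMatrix, A: AdjacencyMatrix, layers: list[GATLayerParams]
) -> FeatureMatrix:
    """Sequential GAT layers; returns the column concatenation of all outputs."""
    _check_aligned(H0, A)
    out = _gat_stack_T(ad.constant(H0.matrix), A.neighbor_mask(),
                       [_const_layer(lp) for lp in layers])
    return FeatureMatrix(list(H0.ids), out.value, FeatureSource.FUSED)


def mhsa_forward(
    X: FeatureMatrix, p: MHSAParams, combine: str = "average"
) -> FeatureMatrix:
    """Multi-head self-attention over the entity rows of X.

    ``combine="average"`` (the block's mode) averages the head outputs
    (width d_k); ``combine="concat"`` concatenates them (width
    n_heads x d_k).
    """
    heads = _mhsa_heads_T(ad.constant(X.matrix), _const_mhsa(p))
    if combine == "average":
        out = ad.mean_tensors(heads)
    elif combine == "concat":
        out = ad.concat_cols(heads)
    else:
        raise MifamError(f"unknown head combination {combine!r}")
    return FeatureMatrix(list(X.ids), out.value, FeatureSource.FUSED)


def gat_mhsa_block(
    H: FeatureMatrix, A: AdjacencyMatrix, block: BlockParams
) -> FeatureMatrix:
    """One block: V_GAT from the stack, then (V_GAT + mean of MHSA heads) / 2."""
    _check_aligned(H, A)
    out = _block_T(ad.constant(H.matrix), A.neighbor_mask(), _const_block(block))
    return FeatureMatrix(list(H.ids), out.value, FeatureSource.FUSED)


def encode_entities(
    H0: FeatureMatrix, A: AdjacencyMatrix, blocks: list[BlockParams]
) -> FeatureMatrix:
    """Compose the blocks sequentially on the same adjacency."""
    _check_aligned(H0, A)
    out = _encode_T(ad.constant(H0.matrix), A.neighbor_mask(),
                    [_const_block(bp) for bp in blocks])
    return FeatureMatrix(list(H0.ids), out.value, FeatureSource.FUSED)


def predict_pair(drug_vec: np.ndarray, protein_vec: np.ndarray,
                 mlp: MLPParams) -> float:
    """Score one (drug, target) pair in (0, 1) via the 3-layer MLP."""
    x = np.concatenate([np.asarray(drug_vec, float), np.asarray(protein_vec, float)])
    if x.shape[0] != mlp.weights[0].shape[0]:
        raise MifamError(
            f"MLP expects input width {mlp.weights[0].shape[0]}, got {x.shape[0]}"
        )
    out = _mlp_T(ad.constant(x[None, :]), MLPParams(
        [ad.constant(w) for w in mlp.weights], [ad.constant(b) for b in mlp.biases]
    ))
    return float(out.value[0, 0])


def score_pairs(
    model: ModelParams,
    drug_features: FeatureMatrix,
    drug_adj: AdjacencyMatrix,
    target_features: FeatureMatrix,
    target_adj: AdjacencyMatrix,
    drug_idx: np.ndarray,
    target_idx: np.ndarray,
) -> np.ndarray:
    """Encode both entity sets and score the indexed pairs (inference path)."""
    mirror, _ = _tensorize(model, trainable=False)
    zd = _encode_T(ad.constant(drug_features.matrix), drug_adj.neighbor_mask(),
                   mirror.drug_blocks)
    zt = _encode_T(ad.constant(target_features.matrix), target_adj.neighbor_mask(),
                   mirror.target_blocks)
    x = ad.concat_cols([ad.gather_rows(zd, drug_idx), ad.gather_rows(zt, target_idx)])
    return _mlp_T(x, mirror.mlp).value[:, 0]


def mse_loss(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Mean squared error (1/N) sum (x_i - y_i)^2."""
    predicted = np.asarray(predicted, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if predicted.size == 0:
        raise MifamError("MSE of an empty vector is undefined")
    if predicted.shape != truth.shape:
        raise MifamError("predicted and truth lengths differ")
    return float(np.mean((predicted - truth) ** 2))


# ---------------------------------------------------------------------------
# checkpointing

CHECKPOINT_VERSION = 1


def save_checkpoint(path, model: ModelParams) -> None:
    """Serialize the parameter bundle with a JSON config header (npz file)."""
    arrays: dict[str, np.ndarray] = {}

    def put_block(prefix: str, bp: BlockParams) -> None:
        for li, lp in enumerate(bp.gat_layers):
            for hi, (W, a) in enumerate(zip(lp.W, lp.a)):
                arrays[f"{prefix}.gat{li}.W{hi}"] = W
                arrays[f"{prefix}.gat{li}.a{hi}"] = a
        for hi in range(bp.mhsa.n_heads):
            arrays[f"{prefix}.mhsa.WQ{hi}"] = bp.mhsa.WQ[hi]
            arrays[f"{prefix}.mhsa.WK{hi}"] = bp.mhsa.WK[hi]
            arrays[f"{prefix}.mhsa.WV{hi}"] = bp.mhsa.WV[hi]

    for bi, bp in enumerate(model.drug_blocks):
        put_block(f"drug{bi}", bp)
    for bi, bp in enumerate(model.target_blocks):
        put_block(f"target{bi}", bp)
    for i, (w, b) in enumerate(zip(model.mlp.weights, model.mlp.biases)):
        arrays[f"mlp.W{i}"] = w
        arrays[f"mlp.b{i}"] = b
    header = dict(version=CHECKPOINT_VERSION, **model.config.__dict__)
    arrays["__config__"] = np.frombuffer(
        json.dumps(header).encode("utf-8"), dtype=np.uint8
    ).copy()
    np.savez(path, **arrays)


def load_checkpoint(path) -> ModelParams:
    with np.load(path) as data:
        header = json.loads(bytes(data["__config__"]).decode("utf-8"))
        if header.pop("version") != CHECKPOINT_VERSION:
            raise MifamError("unsupported checkpoint version")
        cfg = BlockConfig(**header)

        def get_block(prefix: str) -> BlockParams:
            layers = []
            for li in range(cfg.n_gat_layers):
                W = [data[f"{prefix}.gat{li}.W{hi}"] for hi in range(cfg.gat_heads)]
                a = [data[f"{prefix}.gat{li}.a{hi}"] for hi in range(cfg.gat_heads)]
                layers.append(GATLayerParams(W, a, cfg.leaky_slope))
            mhsa = MHSAParams(
                WQ=[data[f"{prefix}.mhsa.WQ{h}"] for h in range(cfg.mhsa_heads)],
                WK=[data[f"{prefix}.mhsa.WK{h}"] for h in range(cfg.mhsa_heads)],
                WV=[data[f"{prefix}.mhsa.WV{h}"] for h in range(cfg.mhsa_heads)],
            )
            return BlockParams(layers, mhsa)

        return ModelParams(
            drug_blocks=[get_block(f"drug{b}") for b in range(cfg.n_blocks)],
            target_blocks=[get_block(f"target{b}") for b in range(cfg.n_blocks)],
            mlp=MLPParams(
                weights=[data[f"mlp.W{i}"] for i in range(3)],
                biases=[data[f"mlp.b{i}"] for i in range(3)],
            ),
            config=cfg,
        )
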