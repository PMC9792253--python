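"""A lightweight 1-D inverted-residual CNN for EEG window classification.

The network is a one-dimensional MobileNet-style stack: an initial strided
convolution, seven inverted-residual bottleneck stages, a 1x1 expansion
convolution to 1280 channels, global average pooling and a 2-class linear
head.  Each bottleneck expands channels by factor ``t`` with a pointwise
convolution, applies a depthwise convolution (kernel 3, stride ``s`` on
the first block of a stage), projects back down with a second pointwise
convolution, and adds a skip connection when the stride is 1 and input
and output channel counts match.  Batch normalisation follows every
convolution; the clipped linear activation (ReLU6) follows the expand and
depthwise convolutions but not the projection.

Per-layer parameter and multiply-add accounting is analytic (closed-form
per layer type) so model size can be audited without instantiating
weights; :func:`build_model` additionally instantiates trainable NumPy
layers for :func:`train` / :func:`predict`.

Accounting conventions: convolutions are bias-free (batch norm supplies
the shift); batch norm contributes its scale and shift; mult-adds count
convolutional and linear layers only
(``kernel * in_channels_per_group * out_channels * output_length``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .preprocessing import SegmentSet

__all__ = ["LayerSpec", "ModelSpec", "ModelGraph", "TrainConfig",
           "default_spec", "build_model", "count_parameters",
           "count_mult_adds", "train", "predict", "knn_classifier",
           "summary_table"]

_OPERATORS = ("conv1d", "bottleneck", "pointwise_conv", "avgpool", "linear")


@dataclass(frozen=True)
class LayerSpec:
    """One row of the architecture table.

    t : channel expansion factor (bottleneck rows only)
    c : output channels
    n : number of repetitions of the block
    s : stride (applied by the first repetition only)
    kernel : (depthwise) kernel size, odd
    """

    operator: str
    c: int = 0
    t: int = 1
    n: int = 1
    s: int = 1
    kernel: int = 3

    def __post_init__(self) -> None:
        if self.operator not in _OPERATORS:
            raise ValueError(f"unknown operator {self.operator!r}")
        if self.operator not in ("avgpool",) and self.c < 1 \
                and self.operator != "linear":
            raise ValueError("c must be >= 1")
        if self.t < 1 or self.n < 1 or self.s not in (1, 2):
            raise ValueError("require t >= 1, n >= 1, s in {1, 2}")
        if self.kernel % 2 == 0:
            raise ValueError("kernel must be odd")


@dataclass(frozen=True)
class ModelSpec:
    """Ordered layer list plus input/output contract."""

    layers: tuple[LayerSpec, ...]
    input_length: int = 1024
    input_channels: int = 1
    num_classes: int = 2

    def shape_flow(self) -> list[tuple[int, int]]:
        """(length, channels) entering each table row, plus final output.

        The last entry is (1, num_classes) after the linear head.
        """
        L, C = self.input_length, self.input_channels
        flow = []
        for spec in self.layers:
            flow.append((L, C))
            if spec.operator in ("conv1d", "pointwise_conv"):
                L = -(-L // spec.s)
                C = spec.c
            elif spec.operator == "bottleneck":
                L = -(-L // spec.s)       # only the first repetition strides
                C = spec.c
            elif spec.operator == "avgpool":
                L = 1
            elif spec.operator == "linear":
                C = spec.c
        flow.append((1, self.num_classes))
        return flow


def default_spec() -> ModelSpec:
    """The reference 11-row architecture for 1024-sample windows.

    The first convolution is strided (stride 2, kernel 3): the tabulated
    shape flow 1024x1 -> 512x32 requires it.  Depthwise kernels are 3.
    """
    rows = (
        LayerSpec("conv1d", c=32, s=2, kernel=3),
        LayerSpec("bottleneck", t=1, c=16, n=1, s=1),
        LayerSpec("bottleneck", t=6, c=24, n=2, s=2),
        LayerSpec("bottleneck", t=6, c=32, n=3, s=2),
        LayerSpec("bottleneck", t=6, c=64, n=4, s=2),
        LayerSpec("bottleneck", t=6, c=96, n=3, s=1),
        LayerSpec("bottleneck", t=6, c=160, n=3, s=2),
        LayerSpec("bottleneck", t=6, c=320, n=1, s=1),
        LayerSpec("pointwise_conv", c=1280, kernel=1),
        LayerSpec("avgpool"),
        LayerSpec("linear", c=2),
    )
    return ModelSpec(rows, input_length=1024, input_channels=1, num_classes=2)


# ---------------------------------------------------------------------------
# graph construction with analytic accounting
# ---------------------------------------------------------------------------

@dataclass
class LayerRecord:
    """Bookkeeping for one instantiated primitive layer."""

    name: str
    out_shape: tuple[int, int]      # (channels, length)
    n_params: int
    macs: int


class _BottleneckBlock:
    """expand (pointwise, skipped when t=1) -> depthwise -> project."""

    def __init__(self, in_ch: int, out_ch: int, t: int, stride: int,
                 kernel: int, rng: np.random.Generator):
        exp = in_ch * t
        self.use_residual = stride == 1 and in_ch == out_ch
        self.layers: list[nn.Layer] = []
        if t > 1:
            self.layers += [nn.Conv1d(in_ch, exp, 1, rng=rng),
                            nn.BatchNorm1d(exp), nn.ReLU6()]
        self.layers += [nn.Conv1d(exp, exp, kernel, stride=stride,
                                  groups=exp, rng=rng),
                        nn.BatchNorm1d(exp), nn.ReLU6()]
        self.layers += [nn.Conv1d(exp, out_ch, 1, rng=rng),
                        nn.BatchNorm1d(out_ch)]

    def params(self) -> list[nn.Param]:
        return [p for lay in self.layers for p in lay.params()]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        out = x
        for lay in self.layers:
            out = lay.forward(out, training)
        if self.use_residual:
            out = out + x
        self._residual = self.use_residual
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = grad
        for lay in reversed(self.layers):
            g = lay.backward(g)
        if self._residual:
            g = g + grad
        return g


class ModelGraph:
    """Instantiated network with per-layer parameter/MAC records.

    ``records`` lists every primitive layer (convolution, norm, linear,
    pool) with its output shape, parameter count and MAC count at the
    spec's input length.  Totals are sums of the per-layer values.
    """

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        self.records: list[LayerRecord] = []
        self.blocks: list = []       # forward order: blocks + head layers
        rng = np.random.default_rng(seed)
        L, C = spec.input_length, spec.input_channels
        for i, row in enumerate(spec.layers):
            if row.operator == "conv1d":
                conv = nn.Conv1d(C, row.c, row.kernel, stride=row.s, rng=rng)
                bn = nn.BatchNorm1d(row.c)
                Lo = conv.out_length(L)
                self._record(f"conv1d_{i}", (row.c, Lo), conv.n_params,
                             conv.macs(L))
                self._record(f"bn_{i}", (row.c, Lo), bn.n_params, 0)
                self.blocks += [conv, bn, nn.ReLU6()]
                L, C = Lo, row.c
            elif row.operator == "bottleneck":
                for rep in range(row.n):
                    stride = row.s if rep == 0 else 1
                    blk = _BottleneckBlock(C, row.c, row.t, stride,
                                           row.kernel, rng)
                    Lo = -(-L // stride)
                    self._record_block(f"bottleneck_{i}.{rep}", blk, C,
                                       row.c, row.t, stride, row.kernel,
                                       L, Lo)
                    self.blocks.append(blk)
                    L, C = Lo, row.c
            elif row.operator == "pointwise_conv":
                conv = nn.Conv1d(C, row.c, 1, rng=rng)
                bn = nn.BatchNorm1d(row.c)
                self._record(f"pointwise_{i}", (row.c, L), conv.n_params,
                             conv.macs(L))
                self._record(f"bn_{i}", (row.c, L), bn.n_params, 0)
                self.blocks += [conv, bn, nn.ReLU6()]
                C = row.c
            elif row.operator == "avgpool":
                self._record(f"avgpool_{i}", (C, 1), 0, 0)
                self.blocks.append(nn.GlobalAvgPool1d())
                L = 1
            elif row.operator == "linear":
                if L != 1:
                    raise ValueError(
                        f"linear head at layer {i} expects pooled input, "
                        f"got length {L}")
                lin = nn.Linear(C, spec.num_classes, rng=rng)
                self._record(f"linear_{i}", (spec.num_classes, 1),
                             lin.n_params, lin.macs())
                self.blocks.append(lin)
                C = spec.num_classes
        self._out_channels = C

    def _record(self, name, shape, n_params, macs):
        self.records.append(LayerRecord(name, shape, n_params, macs))

    def _record_block(self, name, blk, in_ch, out_ch, t, stride, kernel,
                      L_in, L_out):
        exp = in_ch * t
        if t > 1:
            self._record(f"{name}.expand", (exp, L_in), in_ch * exp,
                         in_ch * exp * L_in)
            self._record(f"{name}.expand_bn", (exp, L_in), 2 * exp, 0)
        self._record(f"{name}.depthwise", (exp, L_out), kernel * exp,
                     kernel * 1 * exp * L_out)
        self._record(f"{name}.depthwise_bn", (exp, L_out), 2 * exp, 0)
        self._record(f"{name}.project", (out_ch, L_out), exp * out_ch,
                     exp * out_ch * L_out)
        self._record(f"{name}.project_bn", (out_ch, L_out), 2 * out_ch, 0)

    # -- accounting ----------------------------------------------------
    @property
    def total_parameters(self) -> int:
        return sum(r.n_params for r in self.records)

    @property
    def total_macs(self) -> int:
        return sum(r.macs for r in self.records)

    def parameter_arrays(self) -> list[nn.Param]:
        out = []
        for blk in self.blocks:
            if isinstance(blk, _BottleneckBlock):
                out += blk.params()
            else:
                out += blk.params()
        return out

    # -- execution -----------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = x
        for blk in self.blocks:
            if isinstance(blk, nn.Linear) and out.ndim == 3:
                out = out.reshape(len(out), -1)    # drop the pooled axis
            out = blk.forward(out, training)
        return out

    def backward(self, grad: np.ndarray) -> None:
        g = grad
        for blk in reversed(self.blocks):
            if isinstance(blk, nn.Linear):
                g = blk.backward(g)
                g = g[:, :, None]        # restore (n, c, 1) for the pool
            else:
                g = blk.backward(g)


def build_model(spec: ModelSpec, seed: int = 0) -> ModelGraph:
    """Instantiate the layer graph, validating the shape flow."""
    flow = spec.shape_flow()
    for (L, C) in flow[:-1]:
        if L < 1:
            raise ValueError("shape flow collapses to zero length; "
                             "too many strided layers for the input length")
    return ModelGraph(spec, seed=seed)


def count_parameters(graph: ModelGraph) -> int:
    """Total learnable scalars (conv weights, norm scale/shift, linear
    weights + bias)."""
    return graph.total_parameters


def count_mult_adds(graph: ModelGraph, input_length: int | None = None
                    ) -> int:
    """Total multiply-adds for one forward pass at ``input_length``.

    Counts convolutional and linear layers only.  When ``input_length``
    differs from the spec's, the shape flow is re-simulated; parameters
    do not depend on length but MACs do.
    """
    if input_length is None or input_length == graph.spec.input_length:
        return graph.total_macs
    respec = ModelSpec(graph.spec.layers, input_length=input_length,
                       input_channels=graph.spec.input_channels,
                       num_classes=graph.spec.num_classes)
    return ModelGraph(respec).total_macs


def summary_table(graph: ModelGraph) -> str:
    """Plain-text per-layer table: shapes, parameters, MACs, totals."""
    lines = [f"{'layer':34s} {'out shape':>14s} {'params':>10s} {'MACs':>12s}"]
    for r in graph.records:
        shape = f"{r.out_shape[1]}x{r.out_shape[0]}"
        lines.append(f"{r.name:34s} {shape:>14s} {r.n_params:>10,d} "
                     f"{r.macs:>12,d}")
    lines.append("-" * 74)
    lines.append(f"{'total':34s} {'':>14s} {graph.total_parameters:>10,d} "
                 f"{graph.total_macs:>12,d}")
    lines.append(f"parameters: {graph.total_parameters / 1e6:.1f} M   "
                 f"mult-adds: {graph.total_macs / 1e6:.1f} M")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# training / prediction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Optimiser defaults: Adam, lr 1e-3, batch 64, 30 epochs."""

    lr: float = 1e-3
    batch_size: int = 64
    epochs: int = 30
    seed: int = 0


def train(graph: ModelGraph, train_segs: SegmentSet,
          hp: TrainConfig = TrainConfig()) -> dict:
    """Minimise two-class cross-entropy on the given windows.

    Deterministic given ``hp.seed`` (which drives only the shuffling; the
    weights were seeded at :func:`build_model` time).  Returns a history
    dict with per-epoch mean loss and training accuracy.
    """
    y = train_segs.labels
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    X = train_segs.segments
    if X.shape[1] != graph.spec.input_channels:
        raise ValueError(
            f"model expects {graph.spec.input_channels} channel(s), "
            f"got {X.shape[1]}; use SegmentSet.channel_view")
    rng = np.random.default_rng(hp.seed)
    params = graph.parameter_arrays()
    opt = nn.Adam(params, lr=hp.lr)
    history = {"loss": [], "accuracy": []}
    n = len(y)
    for _ in range(hp.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, hp.batch_size):
            idx = order[start:start + hp.batch_size]
            opt.zero_grad()
            logits = graph.forward(X[idx], training=True)
            loss, dlogits = nn.cross_entropy_grad(logits, y[idx])
            graph.backward(dlogits)
            opt.step()
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == y[idx]).sum())
        history["loss"].append(float(np.mean(losses)))
        history["accuracy"].append(correct / n)
    return history


def predict(graph: ModelGraph, segs: SegmentSet,
            batch_size: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Class labels and positive-class (seizure) scores in [0, 1]."""
    X = segs.segments
    scores = np.empty(len(X))
    for start in range(0, len(X), batch_size):
        logits = graph.forward(X[start:start + batch_size], training=False)
        scores[start:start + batch_size] = nn.softmax(logits)[:, 1]
    labels = (scores >= 0.5).astype(int)
    return labels, scores


def knn_classifier(train_data, test_X: np.ndarray) -> np.ndarray:
    """1-nearest-neighbour labels — a fast surrogate classifier so
    resampler behaviour can be evaluated without network training."""
    from .resampling import compute_neighbors

    # copy so a shared array never triggers kNN self-exclusion: a test row
    # identical to a training row should get that row's label
    nt = compute_neighbors(train_data.X, np.array(test_X, dtype=float), k=1)
    return train_data.y[nt.indices[:, 0]]
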