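"""The bag classifier: shared CNN slice encoder, squeeze-and-excitation
modality attention, and a dual-stream multiple-instance aggregator.

A patient's lesion is a *bag*: the s axial slices of the lesion, seen in
K co-registered MRI sequences (modalities), are its instances.  Each slice
of each modality is encoded by one weight-shared CNN into a 128-d embedding,
giving K matrices m_k of shape (s, 128).  Modality attention squeezes each
m_k to a scalar descriptor d_k by global average pooling, maps d through a
two-layer excitation network to weights a, and fuses the modalities as
h_i = sum_k a_k * m_k[i].  The aggregator scores the bag in two streams:

* instance stream — an instance classifier W0 scores every h_i and
  max-pools; the argmax slice is the *critical instance* h_m;
* bag stream — queries q_i = Wq h_i are compared to q_m by inner product,
  softmax-normalized into similarity weights U, and the information vectors
  v_i = Wv h_i are averaged under U into a bag embedding b scored by Wb.

The final bag logit is the mean of the two stream scores.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Parameter, Tensor

MODALITY_NAMES = ("t2", "arterial", "venous", "delay", "adc")


def default_channels(depth: int) -> tuple[int, ...]:
    """Channel widths per conv block: 16 doubling per block, capped at 256."""
    return tuple(min(16 * 2 ** i, 256) for i in range(depth))


@dataclass(frozen=True)
class ExtractorConfig:
    """Architecture of the per-slice CNN encoder.

    Each of `n_conv_layers` blocks is conv3x3(pad 1) -> ReLU -> batch norm
    -> 2x2 max pool; the flattened map feeds one fully connected layer of
    `embed_dim` units.  With the default depth 5 at 64x64 input the
    pre-flatten map is 256x2x2 (4096 flat).
    """

    n_conv_layers: int = 5
    channels: tuple[int, ...] | None = None
    embed_dim: int = 128
    input_size: int = 64

    def resolved_channels(self) -> tuple[int, ...]:
        ch = self.channels if self.channels is not None else default_channels(
            self.n_conv_layers)
        if len(ch) != self.n_conv_layers:
            raise ValueError(
                f"channels {ch} does not match depth {self.n_conv_layers}")
        return tuple(ch)

    def validate(self) -> None:
        if not 3 <= self.n_conv_layers <= 7:
            raise ValueError("n_conv_layers must be in [3, 7]")
        self.resolved_channels()
        if self.spatial_sides()[-1] < 1:
            raise ValueError(
                f"input {self.input_size} collapses below 1px at depth "
                f"{self.n_conv_layers}")

    def spatial_sides(self) -> list[int]:
        """Spatial side after each block (pooling halves, floor, min 1)."""
        sides, s = [], self.input_size
        for _ in range(self.n_conv_layers):
            if s >= 2:
                s //= 2
            sides.append(s)
        return sides

    def flat_dim(self) -> int:
        return self.resolved_channels()[-1] * self.spatial_sides()[-1] ** 2


# ---------------------------------------------------------------------------
# attention + aggregation primitives (operate on autodiff tensors)
# ---------------------------------------------------------------------------

def squeeze(m: Tensor) -> Tensor:
    """Global average pooling of modality features (K, s, E) -> descriptors (K,)."""
    if m.shape[1] == 0:
        raise ValueError("cannot squeeze a bag with zero slices")
    return m.mean(axis=(1, 2))


def excite(d: Tensor, w1: Tensor, b1: Tensor, w2: Tensor, b2: Tensor,
           gate: str = "sigmoid") -> Tensor:
    """Two-layer excitation a = gate(W2 relu(W1 d + b1) + b2)."""
    pre = nn.linear(nn.relu(nn.linear(d, w1, b1)), w2, b2)
    if gate == "sigmoid":
        return nn.sigmoid(pre)
    if gate == "softmax":
        return nn.softmax(pre)
    if gate == "none":
        return pre
    raise ValueError(f"unknown excitation gate {gate!r}")


def reweight(m: Tensor, a: Tensor) -> Tensor:
    """Fuse modality features (K, s, E) under weights a (K,) -> (s, E)."""
    k = m.shape[0]
    return (a.reshape(k, 1, 1) * m).sum(axis=0)


def instance_stream(h: Tensor, w0: Tensor) -> tuple[Tensor, Tensor, int]:
    """Instance scores W0 h_i, their max c_m, and the critical index."""
    if h.shape[0] < 1:
        raise ValueError("empty bag")
    scores = nn.matmul(h, w0)
    c_m, idx = nn.max_with_index(scores)
    return scores, c_m, idx


def bag_stream(h: Tensor, critical_index: int, wq: Tensor, wv: Tensor,
               wb: Tensor) -> tuple[Tensor, Tensor, Tensor]:
    """Similarity weights U, bag embedding b, and bag score c_b.

    The similarity of instance i to the critical instance is the cosine of
    their query vectors, softmax-normalized over the bag.  (A raw inner
    product of 128-d queries saturates the softmax to one-hot at any
    reasonable weight scale, freezing the stream; the cosine keeps it in
    the trainable range.)
    """
    s = h.shape[0]
    if not 0 <= critical_index < s:
        raise IndexError(f"critical index {critical_index} out of range")
    q = nn.normalize_rows(nn.linear(h, wq))
    v = nn.linear(h, wv)
    qm = nn.getrow(q, critical_index)
    u = nn.softmax(nn.matmul(q, qm))
    b = nn.matmul(u, v)
    c_b = nn.dot(wb, b)
    return u, b, c_b


def fuse_scores(c_m: Tensor, c_b: Tensor) -> Tensor:
    """Final bag logit: mean of the two stream scores."""
    return (c_m + c_b) * 0.5


# ---------------------------------------------------------------------------
# diagnostics containers
# ---------------------------------------------------------------------------

@dataclass
class AttentionState:
    """Modality descriptors and attention weights for one bag."""

    d: np.ndarray
    a: np.ndarray


@dataclass
class DualStreamOutput:
    """Per-bag aggregation diagnostics."""

    instance_scores: np.ndarray
    critical_index: int
    c_m: float
    U: np.ndarray
    b: np.ndarray | None
    c_b: float | None
    c_final: float


@dataclass
class BagForward:
    """Full forward pass: differentiable logit plus detached diagnostics."""

    logit: Tensor
    attention: AttentionState
    aggregation: DualStreamOutput

    @property
    def probability(self) -> float:
        return float(1.0 / (1.0 + np.exp(-self.aggregation.c_final)))


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

class FeatureExtractor:
    """Weight-shared CNN mapping (N, 1, size, size) slices to (N, embed_dim)."""

    def __init__(self, config: ExtractorConfig, rng: np.random.Generator):
        config.validate()
        self.config = config
        chans = config.resolved_channels()
        self.conv_w: list[Parameter] = []
        self.conv_b: list[Parameter] = []
        self.bn_gamma: list[Parameter] = []
        self.bn_beta: list[Parameter] = []
        self.bn_running: list[dict] = []
        cin = 1
        for cout in chans:
            fan_in = cin * 9
            self.conv_w.append(Parameter(
                rng.normal(0.0, np.sqrt(2.0 / fan_in), (cout, cin, 3, 3))))
            self.conv_b.append(Parameter(np.zeros(cout)))
            self.bn_gamma.append(Parameter(np.ones(cout)))
            self.bn_beta.append(Parameter(np.zeros(cout)))
            self.bn_running.append({"mean": np.zeros(cout), "var": np.ones(cout)})
            cin = cout
        flat = config.flat_dim()
        self.fc_w = Parameter(rng.normal(0.0, np.sqrt(2.0 / flat),
                                         (config.embed_dim, flat)))
        self.fc_b = Parameter(np.zeros(config.embed_dim))

    def parameters(self) -> list[Parameter]:
        return (self.conv_w + self.conv_b + self.bn_gamma + self.bn_beta
                + [self.fc_w, self.fc_b])

    def forward(self, x: Tensor, training: bool) -> Tensor:
        n = x.shape[0]
        for i in range(self.config.n_conv_layers):
            x = nn.conv2d(x, self.conv_w[i], self.conv_b[i], pad=1)
            x = nn.relu(x)
            x = nn.batchnorm2d(x, self.bn_gamma[i], self.bn_beta[i],
                               self.bn_running[i], training)
            if x.shape[2] >= 2 and x.shape[3] >= 2:
                x = nn.maxpool2x2(x)
        x = x.reshape(n, -1)
        return nn.linear(x, self.fc_w, self.fc_b)

    def forward_with_maps(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Eval-mode forward returning (pre-flatten map, embedding) arrays."""
        t = Tensor(x)
        n = t.shape[0]
        for i in range(self.config.n_conv_layers):
            t = nn.conv2d(t, self.conv_w[i], self.conv_b[i], pad=1)
            t = nn.relu(t)
            t = nn.batchnorm2d(t, self.bn_gamma[i], self.bn_beta[i],
                               self.bn_running[i], training=False)
            if t.shape[2] >= 2 and t.shape[3] >= 2:
                t = nn.maxpool2x2(t)
        pre = t.value
        emb = nn.linear(t.reshape(n, -1), self.fc_w, self.fc_b).value
        return pre, emb


class MILNet:
    """Modality-attention dual-stream MIL classifier.

    Parameters
    ----------
    extractor
        CNN encoder architecture.
    n_modalities
        Number of co-registered sequences per case (5: T2, arterial,
        venous, delay, ADC).
    use_attention
        If False the excitation network is removed and every modality gets
        the fixed weight 1/K (the ablation benchmark's fusion).
    use_aggregator
        If False the dual-stream module is removed and the bag logit is the
        mean of the instance scores (mean-pooling MIL baseline).
    attention_gate
        Output nonlinearity of the excitation network: sigmoid (default),
        softmax or none.
    attention_hidden
        Hidden width of the excitation network; defaults to n_modalities
        (no reduction — with only 5 modalities there is nothing to squeeze).
    """

    def __init__(self, extractor: ExtractorConfig | None = None,
                 n_modalities: int = 5, use_attention: bool = True,
                 use_aggregator: bool = True, attention_gate: str = "sigmoid",
                 attention_hidden: int | None = None, seed: int = 0):
        self.extractor_config = extractor or ExtractorConfig()
        self.n_modalities = n_modalities
        self.use_attention = use_attention
        self.use_aggregator = use_aggregator
        self.attention_gate = attention_gate
        self.attention_hidden = attention_hidden or n_modalities
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.extractor = FeatureExtractor(self.extractor_config, rng)
        e = self.extractor_config.embed_dim
        k, hdim = n_modalities, self.attention_hidden
        if use_attention:
            self.att_w1 = Parameter(rng.normal(0, np.sqrt(1.0 / k), (hdim, k)))
            self.att_b1 = Parameter(np.zeros(hdim))
            self.att_w2 = Parameter(rng.normal(0, np.sqrt(1.0 / hdim), (k, hdim)))
            self.att_b2 = Parameter(np.zeros(k))
        # W0, Wq, Wv, Wb carry no bias.  The scalar score heads W0 and Wb
        # start near zero so initial bag logits sit close to 0 (p ~ 0.5)
        # instead of deep in the sigmoid tails.
        self.w0 = Parameter(rng.normal(0, 0.01 / np.sqrt(e), e))
        if use_aggregator:
            self.wq = Parameter(rng.normal(0, np.sqrt(1.0 / e), (e, e)))
            self.wv = Parameter(rng.normal(0, np.sqrt(1.0 / e), (e, e)))
            self.wb = Parameter(rng.normal(0, 0.01 / np.sqrt(e), e))

    # -- parameters --------------------------------------------------------
    def parameters(self) -> list[Parameter]:
        ps = self.extractor.parameters() + [self.w0]
        if self.use_attention:
            ps += [self.att_w1, self.att_b1, self.att_w2, self.att_b2]
        if self.use_aggregator:
            ps += [self.wq, self.wv, self.wb]
        return ps

    # -- forward -----------------------------------------------------------
    def forward_bag(self, slices: np.ndarray, training: bool = False) -> BagForward:
        """Run one bag of shape (K, s, size, size) through the network."""
        k, s, hh, ww = slices.shape
        if k != self.n_modalities:
            raise ValueError(f"expected {self.n_modalities} modalities, got {k}")
        if s < 1:
            raise ValueError("empty bag")
        x = Tensor(slices.reshape(k * s, 1, hh, ww))
        emb = self.extractor.forward(x, training)          # (K*s, E)
        m = emb.reshape(k, s, self.extractor_config.embed_dim)
        if self.use_attention:
            d = squeeze(m)
            a = excite(d, self.att_w1, self.att_b1, self.att_w2, self.att_b2,
                       self.attention_gate)
            d_val = d.value.copy()
        else:
            a = Tensor(np.full(k, 1.0 / k))
            d_val = m.value.mean(axis=(1, 2))
        h = reweight(m, a)
        scores, c_m, idx = instance_stream(h, self.w0)
        if self.use_aggregator:
            u, b, c_b = bag_stream(h, idx, self.wq, self.wv, self.wb)
            logit = fuse_scores(c_m, c_b)
            agg = DualStreamOutput(
                instance_scores=scores.value.copy(), critical_index=idx,
                c_m=float(c_m.value), U=u.value.copy(), b=b.value.copy(),
                c_b=float(c_b.value), c_final=float(logit.value))
        else:
            logit = scores.mean()
            agg = DualStreamOutput(
                instance_scores=scores.value.copy(), critical_index=idx,
                c_m=float(c_m.value), U=np.full(s, 1.0 / s), b=None,
                c_b=None, c_final=float(logit.value))
        att = AttentionState(d=d_val, a=a.value.copy())
        return BagForward(logit=logit, attention=att, aggregation=agg)

    def forward_case(self, bag) -> tuple[float, AttentionState, DualStreamOutput]:
        """Eval-mode forward of a PreparedBag; returns (logit, attention, aggregation)."""
        out = self.forward_bag(np.asarray(bag.slices, dtype=np.float64),
                               training=False)
        return out.aggregation.c_final, out.attention, out.aggregation

    # -- persistence -------------------------------------------------------
    def _arch(self) -> dict:
        c = self.extractor_config
        return {
            "n_conv_layers": c.n_conv_layers,
            "channels": list(c.resolved_channels()),
            "embed_dim": c.embed_dim,
            "input_size": c.input_size,
            "n_modalities": self.n_modalities,
            "use_attention": self.use_attention,
            "use_aggregator": self.use_aggregator,
            "attention_gate": self.attention_gate,
            "attention_hidden": self.attention_hidden,
        }

    def state_arrays(self) -> dict[str, np.ndarray]:
        arrs = {f"param_{i}": p.value for i, p in enumerate(self.parameters())}
        for i, run in enumerate(self.extractor.bn_running):
            arrs[f"bn_mean_{i}"] = run["mean"]
            arrs[f"bn_var_{i}"] = run["var"]
        return arrs

    def get_state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.state_arrays().items()}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            val = np.asarray(state[f"param_{i}"])
            if val.shape != p.value.shape:
                raise ValueError(
                    f"checkpoint/architecture mismatch for param_{i}: "
                    f"{val.shape} vs {p.value.shape}")
            p.value = val.astype(np.float64).copy()
        for i, run in enumerate(self.extractor.bn_running):
            run["mean"] = np.asarray(state[f"bn_mean_{i}"], dtype=np.float64).copy()
            run["var"] = np.asarray(state[f"bn_var_{i}"], dtype=np.float64).copy()

    def save(self, path) -> None:
        """Single-archive checkpoint: architecture JSON + weight arrays."""
        buf = io.BytesIO()
        np.savez(buf, **self.state_arrays())
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("architecture.json", json.dumps(self._arch(), indent=1))
            zf.writestr("weights.npz", buf.getvalue())

    @classmethod
    def load(cls, path, seed: int = 0) -> "MILNet":
        with zipfile.ZipFile(path) as zf:
            arch = json.loads(zf.read("architecture.json"))
            with zf.open("weights.npz") as f:
                npz = np.load(io.BytesIO(f.read()))
                state = {k: npz[k] for k in npz.files}
        cfg = ExtractorConfig(
            n_conv_layers=arch["n_conv_layers"],
            channels=tuple(arch["channels"]),
            embed_dim=arch["embed_dim"], input_size=arch["input_size"])
        net = cls(cfg, n_modalities=arch["n_modalities"],
                  use_attention=arch["use_attention"],
                  use_aggregator=arch["use_aggregator"],
                  attention_gate=arch["attention_gate"],
                  attention_hidden=arch["attention_hidden"], seed=seed)
        net.set_state(state)
        return net
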