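"""Dense-connected Bi-GRU encoder, GRU decoder with Luong general attention.

The encoder reads the 5-s two-channel PPG window through three bidirectional
GRU layers (4, 20, 100 units per direction by default) with dense
connections: each layer sees the module input concatenated with every
previous layer's output.  The decoder mirrors it with three unidirectional
GRU layers (8, 40, 200 units), each initialized from the concatenated
forward/backward final states of the matching encoder layer (the decoder
widths are exactly twice the encoder widths, making the concatenation
dimension-exact).  At each output step the top decoder state queries the
encoder outputs through a general bilinear score ``h_t^T W h_s``; the
softmax-normalized weights produce a context vector, and two small heads
emit the pressure value (1 ELU unit on [context || h_t]) and the
cardiac-cycle class probabilities (4 ELU units + softmax on h_t).  The
first decoder input is a vector of ones; afterwards the previous output
(optionally concatenated with the demographic vector) is fed back.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import _autodiff as ad
from ._autodiff import Parameter, Tensor


@dataclass(frozen=True)
class ModelConfig:
    encoder_units: tuple = (4, 20, 100)
    decoder_units: tuple = (8, 40, 200)
    input_channels: int = 2
    n_classes: int = 4
    use_di: bool = True
    di_dim: int = 2
    gru_bias: bool = True

    def __post_init__(self):
        if len(self.encoder_units) != len(self.decoder_units):
            raise ValueError("encoder and decoder must have the same number of layers")
        for eu, du in zip(self.encoder_units, self.decoder_units):
            if du != 2 * eu:
                raise ValueError(
                    "decoder layer width must be twice the matching encoder width "
                    f"(got {du} vs {eu})"
                )

    @property
    def y_dim(self) -> int:
        return 1 + self.n_classes

    @property
    def dec_in_dim(self) -> int:
        return self.y_dim + (self.di_dim if self.use_di else 0)


class GRUCell:
    """One GRU direction: update/reset gates and candidate state.

        z_t = sigmoid(Whz h_{t-1} + Wtz x_t + bz)
        r_t = sigmoid(Whr h_{t-1} + Wtr x_t + br)
        hcand_t = tanh(Whh (r_t * h_{t-1}) + Wth x_t + bh)
        h_t = (1 - z_t) * h_{t-1} + z_t * hcand_t

    Biases are optional (initialized to zero) so that the bias-free textbook
    form is recovered exactly at initialization.
    """

    def __init__(self, in_dim: int, units: int, name: str, bias: bool = True):
        self.in_dim, self.units, self.name = in_dim, units, name
        z = lambda *s: np.zeros(s)
        self.Wtz = Parameter(z(in_dim, units), f"{name}.Wtz")
        self.Wtr = Parameter(z(in_dim, units), f"{name}.Wtr")
        self.Wth = Parameter(z(in_dim, units), f"{name}.Wth")
        self.Whz = Parameter(z(units, units), f"{name}.Whz")
        self.Whr = Parameter(z(units, units), f"{name}.Whr")
        self.Whh = Parameter(z(units, units), f"{name}.Whh")
        self.bias = bias
        if bias:
            self.bz = Parameter(z(units), f"{name}.bz")
            self.br = Parameter(z(units), f"{name}.br")
            self.bh = Parameter(z(units), f"{name}.bh")

    def parameters(self):
        ps = [self.Wtz, self.Wtr, self.Wth, self.Whz, self.Whr, self.Whh]
        if self.bias:
            ps += [self.bz, self.br, self.bh]
        return ps

    def step(self, h_prev: Tensor, x: Tensor) -> Tensor:
        zi = (h_prev @ self.Whz) + (x @ self.Wtz)
        ri = (h_prev @ self.Whr) + (x @ self.Wtr)
        if self.bias:
            zi, ri = zi + self.bz, ri + self.br
        z = ad.sigmoid(zi)
        r = ad.sigmoid(ri)
        hi = ((r * h_prev) @ self.Whh) + (x @ self.Wth)
        if self.bias:
            hi = hi + self.bh
        hcand = ad.tanh(hi)
        return (1.0 - z) * h_prev + z * hcand


def gru_step(cell: GRUCell, h_prev, x) -> Tensor:
    """Functional single GRU step (thin wrapper over :meth:`GRUCell.step`)."""
    return cell.step(ad.as_tensor(h_prev), ad.as_tensor(x))


def gru_sequence(cell: GRUCell, X, h0=None, reverse: bool = False) -> Tensor:
    """Run a GRU direction over a whole (N, L, in) sequence as one tape op.

    Recurrent nets dominate the training cost of this package; recording
    every gate of every step on the autodiff tape is prohibitively slow in
    pure Python.  This op runs the forward recurrence with pre-batched
    input projections and implements backpropagation-through-time by hand;
    its gradients are pinned against the per-step tape path in the tests.
    Returns per-step hidden states aligned to the input time axis (for
    ``reverse=True`` the recurrence runs from the last step backwards, so
    the direction's final state sits at aligned position 0).
    """
    X = ad.as_tensor(X)
    n, L, _ = X.data.shape
    h0 = ad.as_tensor(h0 if h0 is not None else np.zeros((n, cell.units)))
    Xd = X.data[:, ::-1, :] if reverse else X.data
    Wtz, Wtr, Wth = cell.Wtz.data, cell.Wtr.data, cell.Wth.data
    Whz, Whr, Whh = cell.Whz.data, cell.Whr.data, cell.Whh.data
    PZ = Xd @ Wtz
    PR = Xd @ Wtr
    PH = Xd @ Wth
    if cell.bias:
        PZ += cell.bz.data
        PR += cell.br.data
        PH += cell.bh.data
    H_prev = np.empty((L, n, cell.units))
    Z = np.empty_like(H_prev)
    R = np.empty_like(H_prev)
    HC = np.empty_like(H_prev)
    out = np.empty((n, L, cell.units))
    h = h0.data
    for t in range(L):
        H_prev[t] = h
        z = 1.0 / (1.0 + np.exp(-(h @ Whz + PZ[:, t])))
        r = 1.0 / (1.0 + np.exp(-(h @ Whr + PR[:, t])))
        hc = np.tanh((r * h) @ Whh + PH[:, t])
        h = (1.0 - z) * h + z * hc
        Z[t], R[t], HC[t] = z, r, hc
        out[:, t] = h
    out_data = out[:, ::-1, :].copy() if reverse else out

    parents = [X, h0] + cell.parameters()

    def backward(g):
        gseq = g[:, ::-1, :] if reverse else g
        dh = np.zeros((n, cell.units))
        dAZ = np.empty((L, n, cell.units))
        dAR = np.empty_like(dAZ)
        dAH = np.empty_like(dAZ)
        dWhz = np.zeros_like(Whz)
        dWhr = np.zeros_like(Whr)
        dWhh = np.zeros_like(Whh)
        for t in range(L - 1, -1, -1):
            dh = dh + gseq[:, t]
            hp, z, r, hc = H_prev[t], Z[t], R[t], HC[t]
            dz = dh * (hc - hp)
            dhc = dh * z
            dh_next = dh * (1.0 - z)
            da_h = dhc * (1.0 - hc * hc)
            d_rh = da_h @ Whh.T
            da_r = d_rh * hp * r * (1.0 - r)
            da_z = dz * z * (1.0 - z)
            dWhh += (r * hp).T @ da_h
            dWhz += hp.T @ da_z
            dWhr += hp.T @ da_r
            dAZ[t], dAR[t], dAH[t] = da_z, da_r, da_h
            dh = dh_next + d_rh * r + da_z @ Whz.T + da_r @ Whr.T
        dAZs = dAZ.transpose(1, 0, 2)
        dARs = dAR.transpose(1, 0, 2)
        dAHs = dAH.transpose(1, 0, 2)
        if X.requires_grad:
            dX = dAZs @ Wtz.T + dARs @ Wtr.T + dAHs @ Wth.T
            X._accumulate(dX[:, ::-1, :] if reverse else dX)
        if h0.requires_grad:
            h0._accumulate(dh)
        if cell.Wtz.requires_grad:
            cell.Wtz._accumulate(np.einsum("nti,nto->io", Xd, dAZs))
            cell.Wtr._accumulate(np.einsum("nti,nto->io", Xd, dARs))
            cell.Wth._accumulate(np.einsum("nti,nto->io", Xd, dAHs))
            cell.Whz._accumulate(dWhz)
            cell.Whr._accumulate(dWhr)
            cell.Whh._accumulate(dWhh)
            if cell.bias:
                cell.bz._accumulate(dAZs.sum(axis=(0, 1)))
                cell.br._accumulate(dARs.sum(axis=(0, 1)))
                cell.bh._accumulate(dAHs.sum(axis=(0, 1)))

    return ad._make(out_data, tuple(parents), backward)


class Dense:
    def __init__(self, in_dim: int, out_dim: int, name: str):
        self.W = Parameter(np.zeros((in_dim, out_dim)), f"{name}.W")
        self.b = Parameter(np.zeros(out_dim), f"{name}.b")

    def parameters(self):
        return [self.W, self.b]

    def __call__(self, x: Tensor) -> Tensor:
        return (x @ self.W) + self.b


class Encoder:
    """Three dense-connected bidirectional GRU layers."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.layers = []
        in_dim = config.input_channels
        acc = in_dim
        for li, units in enumerate(config.encoder_units):
            fwd = GRUCell(acc, units, f"enc{li}.fwd", config.gru_bias)
            bwd = GRUCell(acc, units, f"enc{li}.bwd", config.gru_bias)
            self.layers.append((fwd, bwd))
            acc += 2 * units  # dense connection: input + all previous outputs

    def parameters(self):
        return [p for fwd, bwd in self.layers for p in fwd.parameters() + bwd.parameters()]

    def __call__(self, X: np.ndarray):
        """X of shape (N, L, C) -> (encoder outputs (N, L, 2*u_last), final states).

        Final states: one Tensor (N, 2*u_l) per layer, forward and backward
        final states concatenated.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        _n, L, _ = X.shape
        inputs = Tensor(X)
        finals = []
        layer_out = None
        for fwd, bwd in self.layers:
            out_f = gru_sequence(fwd, inputs)
            out_b = gru_sequence(bwd, inputs, reverse=True)
            layer_out = ad.concat([out_f, out_b], axis=-1)
            finals.append(
                ad.concat([ad.time_index(out_f, L - 1), ad.time_index(out_b, 0)])
            )
            inputs = ad.concat([inputs, layer_out], axis=-1)
        return layer_out, finals


class Attention:
    """Luong general attention: score(h_t, h_s) = h_t^T W h_s."""

    def __init__(self, dec_dim: int, enc_dim: int):
        self.W = Parameter(np.zeros((dec_dim, enc_dim)), "attention.W")

    def parameters(self):
        return [self.W]

    def __call__(self, h_t: Tensor, enc: Tensor):
        q = h_t @ self.W                      # (N, enc_dim)
        scores = ad.attention_scores(q, enc)  # (N, L)
        a = ad.softmax(scores, axis=-1)
        c = ad.attention_context(a, enc)      # (N, enc_dim)
        return a, c


class Decoder:
    """Three dense-connected GRU layers plus the two output heads."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.layers = []
        acc = config.dec_in_dim
        for li, units in enumerate(config.decoder_units):
            self.layers.append(GRUCell(acc, units, f"dec{li}", config.gru_bias))
            acc += units
        enc_out = 2 * config.encoder_units[-1]
        dec_out = config.decoder_units[-1]
        self.attention = Attention(dec_out, enc_out)
        self.head_value = Dense(enc_out + dec_out, 1, "head_value")
        self.head_class = Dense(dec_out, config.n_classes, "head_class")

    def parameters(self):
        ps = [p for layer in self.layers for p in layer.parameters()]
        ps += self.attention.parameters()
        ps += self.head_value.parameters() + self.head_class.parameters()
        return ps

    def step(self, y_prev: Tensor, x_di, states: list, enc: Tensor):
        """One decoder step; returns (y, value, class_probs, attention, new states)."""
        if x_di is not None and not self.config.use_di:
            raise ValueError("demographic vector supplied to a no-DI model")
        if self.config.use_di:
            if x_di is None:
                raise ValueError("DI-enabled model requires a demographic vector")
            inp = ad.concat([y_prev, ad.as_tensor(x_di)])
        else:
            inp = y_prev
        new_states = []
        dense_in = inp
        h = None
        for layer, h_prev in zip(self.layers, states):
            h = layer.step(h_prev, dense_in)
            new_states.append(h)
            dense_in = ad.concat([dense_in, h])
        a, c = self.attention(h, enc)
        value = ad.elu(self.head_value(ad.concat([c, h])))
        probs = ad.softmax(ad.elu(self.head_class(h)), axis=-1)
        y = ad.concat([value, probs])
        return y, value, probs, a, new_states

    def forward_teacher(self, dec_inputs, states: list, enc: Tensor):
        """All decoder steps at once for known (teacher-forced) inputs.

        ``dec_inputs``: (N, T, dec_in_dim) with the start-of-sequence ones
        at step 0 and the ground-truth outputs shifted by one afterwards.
        Returns (values (N,T,1), probs (N,T,n_classes), attention (N,T,L)).
        """
        dense_in = ad.as_tensor(dec_inputs)
        H = None
        for layer, h0 in zip(self.layers, states):
            H = gru_sequence(layer, dense_in, h0=h0)
            dense_in = ad.concat([dense_in, H], axis=-1)
        q = ad.linear3(H, self.attention.W)
        scores = ad.attention_scores3(q, enc)
        a = ad.softmax(scores, axis=-1)
        c = ad.attention_context3(a, enc)
        value = ad.elu(
            ad.linear3(ad.concat([c, H], axis=-1), self.head_value.W, self.head_value.b)
        )
        probs = ad.softmax(ad.elu(ad.linear3(H, self.head_class.W, self.head_class.b)), axis=-1)
        return value, probs, a


class Seq2SeqModel:
    """The full encoder-decoder with attention.

    ``init_fn`` (see :func:`pulsemorph.training.init_weights`) must be
    applied before the model is useful; freshly constructed weights are
    zero.
    """

    def __init__(self, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        self.encoder = Encoder(self.config)
        self.decoder = Decoder(self.config)

    def parameters(self):
        return self.encoder.parameters() + self.decoder.parameters()

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def y0(self, n: int) -> Tensor:
        return Tensor(np.ones((n, self.config.y_dim)))

    def decode(self, enc, finals, x_di, T: int, teacher_inputs=None,
               feedback: str = "hard"):
        """Run T decoder steps.

        ``teacher_inputs``: optional array (N, T, y_dim) of ground-truth
        decoder inputs ([value, one-hot class]); element i is fed as the
        input of step i+1.  When absent the model feeds back its own
        predictions (autoregressive decoding); with ``feedback="hard"`` the
        fed-back class probabilities are hardened to the one-hot argmax so
        the decoder sees the same input distribution it was teacher-forced
        on, with ``"soft"`` the raw probability vector is fed back.
        Returns (values list, probs list, attention list, states).
        """
        n = enc.data.shape[0]
        states = list(finals)
        y_prev = self.y0(n)
        x_di_t = None if x_di is None else ad.as_tensor(np.asarray(x_di, dtype=float).reshape(n, -1))
        values, probs_seq, att_seq = [], [], []
        for t in range(T):
            y, value, probs, a, states = self.decoder.step(y_prev, x_di_t, states, enc)
            values.append(value)
            probs_seq.append(probs)
            att_seq.append(a)
            if teacher_inputs is not None:
                y_prev = Tensor(teacher_inputs[:, t, :])
            elif feedback == "hard":
                hard = np.eye(self.config.n_classes)[probs.data.argmax(axis=1)]
                y_prev = Tensor(np.concatenate([value.data, hard], axis=1))
            else:
                y_prev = y
        return values, probs_seq, att_seq, states

    def forward_teacher(self, X, x_di, teacher_inputs, T: int):
        """Teacher-forced pass; returns (values (N,T), probs (N,T,C), att).

        With ``teacher_inputs`` (N, T, y_dim) the decoder runs fully
        vectorized over time; with ``teacher_inputs=None`` it decodes
        autoregressively step by step (gradients flow in both cases).
        """
        enc, finals = self.encoder(X)
        n = enc.data.shape[0]
        if teacher_inputs is not None:
            dec_in = np.empty((n, T, self.config.y_dim))
            dec_in[:, 0, :] = 1.0
            dec_in[:, 1:, :] = np.asarray(teacher_inputs, dtype=float)[:, : T - 1, :]
            if self.config.use_di:
                if x_di is None:
                    raise ValueError("DI-enabled model requires a demographic vector")
                di = np.asarray(x_di, dtype=float).reshape(n, 1, -1)
                dec_in = np.concatenate([dec_in, np.broadcast_to(di, (n, T, di.shape[-1]))], axis=2)
            elif x_di is not None:
                raise ValueError("demographic vector supplied to a no-DI model")
            values, probs, att = self.decoder.forward_teacher(dec_in, finals, enc)
            pred_v = ad.reduce_sum(values, axis=2)  # squeeze the singleton head axis
            return pred_v, probs, att
        values, probs_seq, att_seq, _ = self.decode(enc, finals, x_di, T)
        pred_v = ad.concat(values, axis=1)
        pred_p = ad.stack(probs_seq, axis=1)
        att = ad.stack(att_seq, axis=1)
        return pred_v, pred_p, att

    def predict_sequence(self, X, x_di, T: int, feedback: str = "hard"):
        """Autoregressive prediction (no gradients).

        Returns ``(values (N, T), class_probs (N, T, n_classes),
        attention (N, T, L))``; singleton batch dimensions are preserved.
        """
        with ad.no_grad():
            enc, finals = self.encoder(X)
            values, probs_seq, att_seq, _ = self.decode(enc, finals, x_di, T,
                                                        feedback=feedback)
        v = np.stack([t.data[:, 0] for t in values], axis=1)
        p = np.stack([t.data for t in probs_seq], axis=1)
        a = np.stack([t.data for t in att_seq], axis=1)
        return v, p, a

    # -- persistence -------------------------------------------------------
    def state_dict(self) -> dict:
        return {p.name: p.data for p in self.parameters()}

    def load_state_dict(self, state: dict) -> None:
        for p in self.parameters():
            p.data = np.asarray(state[p.name], dtype=float)

    def save(self, path, extra: dict | None = None) -> None:
        """Checkpoint: weights (npz) + JSON sidecar with config and extras."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.state_dict())
        meta = {"config": asdict(self.config)}
        if extra:
            meta.update(extra)
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path):
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        cfg_d = dict(meta["config"])
        cfg_d["encoder_units"] = tuple(cfg_d["encoder_units"])
        cfg_d["decoder_units"] = tuple(cfg_d["decoder_units"])
        model = cls(ModelConfig(**cfg_d))
        with np.load(path.with_suffix(".npz")) as npz:
            model.load_state_dict({k: npz[k] for k in npz.files})
        return model, meta


def attention_op(W: np.ndarray, h_t: np.ndarray, enc_outputs: np.ndarray):
    """Functional Luong general attention on plain arrays.

    Returns (weights, context) for a single decoder state ``h_t`` (H_dec,)
    against encoder outputs (L, H_enc).
    """
    scores = h_t @ W @ np.asarray(enc_outputs).T
    z = scores - scores.max()
    a = np.exp(z) / np.exp(z).sum()
    c = a @ enc_outputs
    return a, c
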