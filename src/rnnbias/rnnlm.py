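"""Character-level recurrent language models over the nucleotide alphabet.

The models assign a probability to a DNA sequence S = s_1..s_m via the chain
rule p(S) = p(s_1) * prod_t p(s_t | s_1..s_{t-1}), with each conditional read
off a softmax over the recurrent hidden state:

    vanilla:  h_t = tanh(W s_t + U h_{t-1} + b)
    GRU:      z = sigm(W_z s + U_z h + b_z + d_z)
              r = sigm(W_r s + U_r h + b_r + d_r)
              hbar = tanh(W_h s + U_h (r * h) + b_h + d_h)
              h_t = (1 - z) * hbar + z * h_{t-1}
    LSTM:     i,f,o = sigm(.), g = tanh(.),
              c_t = f * c_{t-1} + i * g,  h_t = o * tanh(c_t)
    output:   y_t = softmax(V h_t + c)

The first conditional p(s_1) is produced from a zero initial state driven by
an all-zero input vector, which keeps the input dimension at 4.  Gated units
carry both an input-side bias (b) and a recurrent-side bias (d) per gate;
the vanilla unit has a single bias, as its recurrence shows.  Training is
mini-batch gradient descent with backpropagation through time over full
fixed-length sequences, with element-wise gradient clipping; the returned
parameters are those of the epoch with the lowest validation
prediction-error rate (earliest epoch on ties).

The module follows the statsmodels convention: :class:`NucleotideRNN` is the
model built from data, ``fit()`` returns an :class:`RNNResults` carrying the
selected parameters, the per-epoch history and evaluation methods.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, dataclass, field

import numpy as np

__all__ = [
    "ALPHABET",
    "RNNSpec",
    "RNNParams",
    "TrainConfig",
    "NucleotideRNN",
    "RNNResults",
    "TrainedModel",
    "count_parameters",
    "init_params",
    "cell_forward",
    "output_distribution",
    "sequence_log_prob",
    "sequence_log_probs",
    "train_model",
    "check_gradients",
    "prediction_error_rate",
    "perplexity",
    "save_model",
    "load_model",
    "encode_sequences",
]

ALPHABET = "ACGT"
_A2I = {c: i for i, c in enumerate(ALPHABET)}

_UNITS = ("rnn", "gru", "lstm")
# gate labels per unit; the last label is always the candidate activation
_GATES = {"rnn": ("h",), "gru": ("z", "r", "h"), "lstm": ("i", "f", "o", "g")}


@dataclass(frozen=True)
class RNNSpec:
    """Architecture of one language model: unit type and hidden width."""

    unit: str
    hidden: int
    alphabet_size: int = 4

    def __post_init__(self) -> None:
        if self.unit not in _UNITS:
            raise ValueError(f"unit must be one of {_UNITS}, got {self.unit!r}")
        if self.hidden < 1:
            raise ValueError("hidden must be >= 1")
        if self.alphabet_size != 4:
            raise ValueError("alphabet_size is fixed at 4")


def _param_shapes(spec: RNNSpec) -> dict[str, tuple[int, ...]]:
    H, A = spec.hidden, spec.alphabet_size
    shapes: dict[str, tuple[int, ...]] = {}
    for g in _GATES[spec.unit]:
        shapes[f"W_{g}"] = (H, A)
        shapes[f"U_{g}"] = (H, H)
        shapes[f"b_{g}"] = (H,)
        if spec.unit != "rnn":  # gated units carry a recurrent-side bias too
            shapes[f"d_{g}"] = (H,)
    shapes["V"] = (A, H)
    shapes["c"] = (A,)
    return shapes


def count_parameters(spec: RNNSpec) -> int:
    """Total number of scalar parameters of a model with this spec."""
    return sum(int(np.prod(s)) for s in _param_shapes(spec).values())


class RNNParams:
    """All weight/bias tensors of one model, keyed by name."""

    def __init__(self, spec: RNNSpec, arrays: dict[str, np.ndarray]):
        shapes = _param_shapes(spec)
        if set(arrays) != set(shapes):
            raise ValueError(
                f"parameter names {sorted(arrays)} do not match spec "
                f"{sorted(shapes)}"
            )
        for name, arr in arrays.items():
            if arr.shape != shapes[name]:
                raise ValueError(
                    f"parameter {name}: shape {arr.shape} != {shapes[name]}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"parameter {name} contains non-finite values")
        self.spec = spec
        self.arrays = {k: np.asarray(v, dtype=np.float64) for k, v in arrays.items()}

    def __getitem__(self, name: str) -> np.ndarray:
        return self.arrays[name]

    def copy(self) -> "RNNParams":
        return RNNParams(self.spec, {k: v.copy() for k, v in self.arrays.items()})

    def zeros_like(self) -> dict[str, np.ndarray]:
        return {k: np.zeros_like(v) for k, v in self.arrays.items()}

    @property
    def n_parameters(self) -> int:
        return sum(v.size for v in self.arrays.values())

    def flatten(self) -> np.ndarray:
        return np.concatenate([self.arrays[k].ravel() for k in sorted(self.arrays)])

    def set_flat(self, flat: np.ndarray) -> None:
        i = 0
        for k in sorted(self.arrays):
            n = self.arrays[k].size
            self.arrays[k][...] = flat[i : i + n].reshape(self.arrays[k].shape)
            i += n


@dataclass
class TrainConfig:
    """Training hyper-parameters for BPTT mini-batch gradient descent."""

    epochs: int = 30
    batch_size: int = 50
    learning_rate: float = 0.1
    optimizer: str = "sgd"  # "sgd" | "adam"
    clip: float = 5.0
    seed: int = 0
    init_scale: float = 0.08

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


def init_params(
    spec: RNNSpec, seed: int | np.random.Generator = 0, init_scale: float = 0.08
) -> RNNParams:
    """Weights i.i.d. uniform on (-init_scale, +init_scale); biases zero."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arrays = {}
    for name, shape in _param_shapes(spec).items():
        if name.startswith(("b_", "d_")) or name == "c":
            arrays[name] = np.zeros(shape)
        else:
            arrays[name] = rng.uniform(-init_scale, init_scale, size=shape)
    return RNNParams(spec, arrays)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _step(spec: RNNSpec, p: dict[str, np.ndarray], S_t, h_prev, c_prev):
    """One recurrence step on a batch.  Returns (h, c, cache)."""
    if spec.unit == "rnn":
        h = np.tanh(S_t @ p["W_h"].T + h_prev @ p["U_h"].T + p["b_h"])
        return h, None, (h_prev, h)
    if spec.unit == "gru":
        z = _sigmoid(S_t @ p["W_z"].T + h_prev @ p["U_z"].T + p["b_z"] + p["d_z"])
        r = _sigmoid(S_t @ p["W_r"].T + h_prev @ p["U_r"].T + p["b_r"] + p["d_r"])
        rh = r * h_prev
        hbar = np.tanh(S_t @ p["W_h"].T + rh @ p["U_h"].T + p["b_h"] + p["d_h"])
        h = (1.0 - z) * hbar + z * h_prev
        return h, None, (h_prev, z, r, rh, hbar)
    # lstm
    i = _sigmoid(S_t @ p["W_i"].T + h_prev @ p["U_i"].T + p["b_i"] + p["d_i"])
    f = _sigmoid(S_t @ p["W_f"].T + h_prev @ p["U_f"].T + p["b_f"] + p["d_f"])
    o = _sigmoid(S_t @ p["W_o"].T + h_prev @ p["U_o"].T + p["b_o"] + p["d_o"])
    g = np.tanh(S_t @ p["W_g"].T + h_prev @ p["U_g"].T + p["b_g"] + p["d_g"])
    c = f * c_prev + i * g
    tc = np.tanh(c)
    h = o * tc
    return h, c, (h_prev, c_prev, i, f, o, g, tc)


def cell_forward(params: RNNParams, s_t: np.ndarray, state=None):
    """Public single-step recurrence.

    ``s_t`` is a one-hot 4-vector (or the all-zero begin-of-sequence vector);
    ``state`` is the hidden vector h (vanilla/GRU) or an (h, c) pair (LSTM).
    Returns the new state in the same form.
    """
    spec = params.spec
    H = spec.hidden
    s = np.asarray(s_t, dtype=float).reshape(1, -1)
    if s.shape[1] != spec.alphabet_size:
        raise ValueError("input vector must have length 4")
    if spec.unit == "lstm":
        h_prev, c_prev = state if state is not None else (np.zeros(H), np.zeros(H))
        h, c, _ = _step(spec, params.arrays, s, h_prev.reshape(1, H), c_prev.reshape(1, H))
        return h.ravel(), c.ravel()
    h_prev = state if state is not None else np.zeros(H)
    if np.asarray(h_prev).shape != (H,):
        raise ValueError(f"hidden state must have shape ({H},)")
    h, _, _ = _step(spec, params.arrays, s, np.asarray(h_prev).reshape(1, H), None)
    return h.ravel()


def output_distribution(params: RNNParams, h_t: np.ndarray) -> np.ndarray:
    """softmax(V h_t + c) — the next-symbol conditional distribution."""
    logits = params["V"] @ np.asarray(h_t, dtype=float) + params["c"]
    logits = logits - logits.max()
    e = np.exp(logits)
    return e / e.sum()


def encode_sequences(seqs) -> np.ndarray:
    """Encode equal-length sequences over {A,C,G,T} to an int (B, T) array."""
    strings = [s.seq if hasattr(s, "seq") else s for s in seqs]
    if not strings:
        raise ValueError("empty sequence list")
    T = len(strings[0])
    if T < 1:
        raise ValueError("sequences must be non-empty")
    if any(len(s) != T for s in strings):
        raise ValueError("sequences must all have the same length")
    flat = "".join(strings)
    try:
        codes = np.fromiter((_A2I[ch] for ch in flat), dtype=np.int64, count=len(flat))
    except KeyError as exc:
        raise ValueError(f"illegal character {exc.args[0]!r} in sequence") from exc
    return codes.reshape(len(strings), T)


def _one_hot_inputs(X: np.ndarray) -> np.ndarray:
    """Input vectors S (T, B, 4): all-zero at t=0, one-hot of s_{t-1} after."""
    B, T = X.shape
    S = np.zeros((T, B, 4))
    rows = np.arange(B)
    for t in range(1, T):
        S[t, rows, X[:, t - 1]] = 1.0
    return S


def _eval_batch(params: RNNParams, X: np.ndarray):
    """Streaming forward pass.

    Returns (per-sequence log-probs (B,), n_correct, total_nll_nats) where
    n_correct counts positions whose argmax conditional matches the observed
    symbol (ties broken toward A<C<G<T by first-argmax).
    """
    spec, p = params.spec, params.arrays
    B, T = X.shape
    H = spec.hidden
    S = _one_hot_inputs(X)
    h = np.zeros((B, H))
    c = np.zeros((B, H)) if spec.unit == "lstm" else None
    rows = np.arange(B)
    seq_logp = np.zeros(B)
    n_correct = 0
    for t in range(T):
        h, c, _ = _step(spec, p, S[t], h, c)
        logits = h @ p["V"].T + p["c"]
        m = logits.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logits - m).sum(axis=1))
        logp_target = logits[rows, X[:, t]] - lse
        seq_logp += logp_target
        n_correct += int((logits.argmax(axis=1) == X[:, t]).sum())
    total_nll = -float(seq_logp.sum())
    return seq_logp, n_correct, total_nll


def _loss_and_grads(params: RNNParams, X: np.ndarray):
    """Mean per-symbol NLL over the batch and its analytic BPTT gradients."""
    spec, p = params.spec, params.arrays
    B, T = X.shape
    H = spec.hidden
    S = _one_hot_inputs(X)
    rows = np.arange(B)

    h = np.zeros((B, H))
    c = np.zeros((B, H)) if spec.unit == "lstm" else None
    caches = []
    hs = []
    dlogits_all = np.empty((T, B, 4))
    loss = 0.0
    scale = 1.0 / (B * T)
    for t in range(T):
        h, c, cache = _step(spec, p, S[t], h, c)
        caches.append(cache)
        hs.append(h)
        logits = h @ p["V"].T + p["c"]
        m = logits.max(axis=1, keepdims=True)
        z = logits - m
        ez = np.exp(z)
        sez = ez.sum(axis=1, keepdims=True)
        logp = z - np.log(sez)
        loss -= logp[rows, X[:, t]].sum()
        probs = ez / sez
        probs[rows, X[:, t]] -= 1.0
        dlogits_all[t] = probs * scale
    loss *= scale

    g = {k: np.zeros_like(v) for k, v in p.items()}
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H)) if spec.unit == "lstm" else None
    for t in range(T - 1, -1, -1):
        dlogits = dlogits_all[t]
        h_t = hs[t]
        g["V"] += dlogits.T @ h_t
        g["c"] += dlogits.sum(axis=0)
        dh = dlogits @ p["V"] + dh_next
        if spec.unit == "rnn":
            h_prev, h_cur = caches[t]
            da = dh * (1.0 - h_cur * h_cur)
            g["W_h"] += da.T @ S[t]
            g["U_h"] += da.T @ h_prev
            g["b_h"] += da.sum(axis=0)
            dh_next = da @ p["U_h"]
        elif spec.unit == "gru":
            h_prev, zg, r, rh, hbar = caches[t]
            dz = dh * (h_prev - hbar)
            dhbar = dh * (1.0 - zg)
            dh_prev = dh * zg
            dah = dhbar * (1.0 - hbar * hbar)
            g["W_h"] += dah.T @ S[t]
            g["U_h"] += dah.T @ rh
            sh = dah.sum(axis=0)
            g["b_h"] += sh
            g["d_h"] += sh
            drh = dah @ p["U_h"]
            dr = drh * h_prev
            dh_prev += drh * r
            daz = dz * zg * (1.0 - zg)
            g["W_z"] += daz.T @ S[t]
            g["U_z"] += daz.T @ h_prev
            sz = daz.sum(axis=0)
            g["b_z"] += sz
            g["d_z"] += sz
            dh_prev += daz @ p["U_z"]
            dar = dr * r * (1.0 - r)
            g["W_r"] += dar.T @ S[t]
            g["U_r"] += dar.T @ h_prev
            sr = dar.sum(axis=0)
            g["b_r"] += sr
            g["d_r"] += sr
            dh_prev += dar @ p["U_r"]
            dh_next = dh_prev
        else:  # lstm
            h_prev, c_prev, gi, gf, go, gg, tc = caches[t]
            do = dh * tc
            dc = dc_next + dh * go * (1.0 - tc * tc)
            df = dc * c_prev
            di = dc * gg
            dg = dc * gi
            dh_prev = np.zeros((B, H))
            for name, act, dact in (
                ("i", gi, di * gi * (1.0 - gi)),
                ("f", gf, df * gf * (1.0 - gf)),
                ("o", go, do * go * (1.0 - go)),
                ("g", gg, dg * (1.0 - gg * gg)),
            ):
                g[f"W_{name}"] += dact.T @ S[t]
                g[f"U_{name}"] += dact.T @ h_prev
                s = dact.sum(axis=0)
                g[f"b_{name}"] += s
                g[f"d_{name}"] += s
                dh_prev += dact @ p[f"U_{name}"]
            dh_next = dh_prev
            dc_next = dc * gf
    return loss, g


def sequence_log_probs(
    params_or_model, seqs, batch_size: int = 512
) -> np.ndarray:
    """Natural-log sequence probabilities for a list of sequences.

    Sequences may have different lengths; they are scored in per-length
    batches and returned in input order.
    """
    params = getattr(params_or_model, "params", params_or_model)
    strings = [s.seq if hasattr(s, "seq") else s for s in seqs]
    out = np.empty(len(strings))
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(strings):
        by_len.setdefault(len(s), []).append(i)
    for _, idx in sorted(by_len.items()):
        X = encode_sequences([strings[i] for i in idx])
        for lo in range(0, len(idx), batch_size):
            sel = idx[lo : lo + batch_size]
            lp, _, _ = _eval_batch(params, X[lo : lo + batch_size])
            out[sel] = lp
    return out


def sequence_log_prob(params_or_model, seq: str) -> float:
    """Natural-log probability of one sequence under the chain rule."""
    return float(sequence_log_probs(params_or_model, [seq])[0])


def _eval_stats(params: RNNParams, seqs, batch_size: int = 512):
    """(total_nll_nats, n_correct, n_positions) over a sequence set."""
    strings = [s.seq if hasattr(s, "seq") else s for s in seqs]
    if not strings:
        raise ValueError("empty sequence list")
    total_nll = 0.0
    n_correct = 0
    n_pos = 0
    by_len: dict[int, list[str]] = {}
    for s in strings:
        by_len.setdefault(len(s), []).append(s)
    for _, group in sorted(by_len.items()):
        X = encode_sequences(group)
        for lo in range(0, len(group), batch_size):
            chunk = X[lo : lo + batch_size]
            _, nc, nll = _eval_batch(params, chunk)
            total_nll += nll
            n_correct += nc
            n_pos += chunk.size
    return total_nll, n_correct, n_pos


def perplexity(params_or_model, seqs) -> float:
    """2 to the mean per-symbol negative log2 probability over the set.

    4.0 is chance level for the 4-letter alphabet; lower is better.
    """
    params = getattr(params_or_model, "params", params_or_model)
    total_nll, _, n_pos = _eval_stats(params, seqs)
    return float(2.0 ** (total_nll / math.log(2.0) / n_pos))


def prediction_error_rate(params_or_model, seqs) -> float:
    """Fraction of positions where the argmax conditional misses the symbol."""
    params = getattr(params_or_model, "params", params_or_model)
    _, n_correct, n_pos = _eval_stats(params, seqs)
    return 1.0 - n_correct / n_pos


def check_gradients(
    params: RNNParams,
    X: np.ndarray,
    eps: float = 1e-5,
    floor: float = 1e-6,
) -> float:
    """Max relative error between analytic BPTT gradients and central
    finite differences of the mean per-symbol NLL.

    The relative error of each component is |analytic - numeric| divided by
    max(|analytic|, |numeric|, floor); the floor makes near-zero components
    an absolute comparison, since a ratio of finite-difference roundoff to a
    ~1e-8 gradient is noise, not a derivative mismatch.
    """
    _, grads = _loss_and_grads(params, X)
    flat = params.flatten()
    analytic = np.concatenate([grads[k].ravel() for k in sorted(grads)])
    numeric = np.empty_like(flat)
    for i in range(flat.size):
        f = flat.copy()
        f[i] += eps
        params.set_flat(f)
        lp, _ = _loss_and_grads(params, X)
        f[i] -= 2 * eps
        params.set_flat(f)
        lm, _ = _loss_and_grads(params, X)
        numeric[i] = (lp - lm) / (2 * eps)
    params.set_flat(flat)
    denom = np.maximum(np.maximum(np.abs(analytic), np.abs(numeric)), floor)
    return float(np.max(np.abs(analytic - numeric) / denom))


class RNNResults:
    """Fit results: selected parameters, training history, evaluation API."""

    def __init__(
        self,
        spec: RNNSpec,
        params: RNNParams,
        history: list[dict],
        selected_epoch: int | None,
        config: TrainConfig,
    ):
        self.spec = spec
        self.params = params
        self.history = history
        self.selected_epoch = selected_epoch
        self.config = config

    # -- evaluation ---------------------------------------------------
    def log_prob(self, seq: str) -> float:
        return sequence_log_prob(self.params, seq)

    def log_probs(self, seqs) -> np.ndarray:
        return sequence_log_probs(self.params, seqs)

    def perplexity(self, seqs) -> float:
        return perplexity(self.params, seqs)

    def prediction_error_rate(self, seqs) -> float:
        return prediction_error_rate(self.params, seqs)

    @property
    def n_parameters(self) -> int:
        return self.params.n_parameters

    def history_frame(self):
        import pandas as pd

        return pd.DataFrame(self.history)

    def summary(self) -> str:
        lines = [
            "Nucleotide RNN language model",
            "=" * 44,
            f"unit:            {self.spec.unit}",
            f"hidden units:    {self.spec.hidden}",
            f"parameters:      {self.n_parameters}",
            f"epochs run:      {len(self.history)}",
            f"selected epoch:  {self.selected_epoch}",
        ]
        if self.history and self.selected_epoch is not None:
            row = self.history[self.selected_epoch - 1]
            lines += [
                f"train NLL/sym:   {row['train_nll']:.6f}",
                f"valid NLL/sym:   {row['val_nll']:.6f}",
                f"valid err rate:  {row['val_error_rate']:.6f}",
            ]
        return "\n".join(lines)

    def plot_history(self, ax=None):
        """Training/validation NLL per epoch (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        epochs = [h["epoch"] for h in self.history]
        ax.plot(epochs, [h["train_nll"] for h in self.history], label="train NLL")
        ax.plot(epochs, [h["val_nll"] for h in self.history], label="valid NLL")
        ax.set_xlabel("epoch")
        ax.set_ylabel("NLL per symbol (nats)")
        ax.legend()
        return ax

    # -- persistence --------------------------------------------------
    def save(self, path: str | os.PathLike) -> None:
        save_model(self, path)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "RNNResults":
        return load_model(path)


TrainedModel = RNNResults


class NucleotideRNN:
    """Character-level language model over {A,C,G,T} built from sequences.

    Parameters
    ----------
    train_sequences, validation_sequences
        Lists of equal-length strings (or objects with a ``.seq``).
    unit : {"rnn", "gru", "lstm"}
    hidden : int
        Hidden-state width; the method uses lightweight models (<= ~20).
    """

    def __init__(
        self,
        train_sequences,
        validation_sequences=None,
        unit: str = "gru",
        hidden: int = 10,
    ):
        self.spec = RNNSpec(unit, hidden)
        self.train_sequences = [
            s.seq if hasattr(s, "seq") else s for s in train_sequences
        ]
        self.validation_sequences = [
            s.seq if hasattr(s, "seq") else s for s in (validation_sequences or [])
        ]
        if not self.train_sequences:
            raise ValueError("training set is empty")

    @classmethod
    def from_dataset(cls, dataset, unit: str = "gru", hidden: int = 10):
        """Build from a :class:`~rnnbias.sampling.SequenceDataset`."""
        return cls(dataset.train, dataset.validation, unit=unit, hidden=hidden)

    def fit(self, config: TrainConfig | None = None, **kwargs) -> RNNResults:
        """Train by mini-batch BPTT; returns the results object.

        Keyword arguments override :class:`TrainConfig` fields.
        """
        if config is None:
            config = TrainConfig(**kwargs)
        elif kwargs:
            config = TrainConfig(**{**asdict(config), **kwargs})
        rng = np.random.default_rng(config.seed)
        params = init_params(self.spec, rng, config.init_scale)
        X = encode_sequences(self.train_sequences)
        n = X.shape[0]
        has_val = bool(self.validation_sequences)

        history: list[dict] = []
        best_err = np.inf
        best_epoch: int | None = None
        best_params = params.copy()
        if config.optimizer == "adam":
            m = params.zeros_like()
            v = params.zeros_like()
            beta1, beta2, eps = 0.9, 0.999, 1e-8
            step = 0
        for epoch in range(1, config.epochs + 1):
            order = rng.permutation(n)
            train_nll = 0.0
            n_sym = 0
            for lo in range(0, n, config.batch_size):
                batch = X[order[lo : lo + config.batch_size]]
                loss, grads = _loss_and_grads(params, batch)
                train_nll += loss * batch.size
                n_sym += batch.size
                if config.optimizer == "sgd":
                    for k, arr in params.arrays.items():
                        gk = np.clip(grads[k], -config.clip, config.clip)
                        arr -= config.learning_rate * gk
                else:
                    step += 1
                    corr1 = 1.0 - beta1**step
                    corr2 = 1.0 - beta2**step
                    for k, arr in params.arrays.items():
                        gk = np.clip(grads[k], -config.clip, config.clip)
                        m[k] = beta1 * m[k] + (1 - beta1) * gk
                        v[k] = beta2 * v[k] + (1 - beta2) * gk * gk
                        arr -= config.learning_rate * (m[k] / corr1) / (
                            np.sqrt(v[k] / corr2) + eps
                        )
            row = {"epoch": epoch, "train_nll": train_nll / n_sym}
            if has_val:
                nll, nc, npos = _eval_stats(params, self.validation_sequences)
                row["val_nll"] = nll / npos
                row["val_error_rate"] = 1.0 - nc / npos
                if row["val_error_rate"] < best_err:
                    best_err = row["val_error_rate"]
                    best_epoch = epoch
                    best_params = params.copy()
            else:
                row["val_nll"] = float("nan")
                row["val_error_rate"] = float("nan")
            history.append(row)
        if not has_val or best_epoch is None:
            best_params = params
            best_epoch = config.epochs if config.epochs > 0 else None
        return RNNResults(self.spec, best_params, history, best_epoch, config)


def train_model(spec: RNNSpec, dataset, config: TrainConfig | None = None) -> RNNResults:
    """Functional wrapper: train a model of ``spec`` on a dataset.

    ``dataset`` is a :class:`~rnnbias.sampling.SequenceDataset` or a
    ``(train, validation)`` pair of sequence lists.
    """
    if hasattr(dataset, "train"):
        train, val = dataset.train, dataset.validation
    else:
        train, val = dataset
    model = NucleotideRNN(train, val, unit=spec.unit, hidden=spec.hidden)
    return model.fit(config or TrainConfig())


_FORMAT = "rnnbias-model"
_VERSION = 1


def save_model(model: RNNResults, path: str | os.PathLike) -> None:
    """Lossless JSON serialization (full double precision via repr round-trip)."""
    doc = {
        "format": _FORMAT,
        "version": _VERSION,
        "spec": asdict(model.spec),
        "params": {k: v.tolist() for k, v in model.params.arrays.items()},
        "history": model.history,
        "selected_epoch": model.selected_epoch,
        "config": asdict(model.config),
    }
    with open(path, "w") as out:
        json.dump(doc, out)


def load_model(path: str | os.PathLike, spec: RNNSpec | None = None) -> RNNResults:
    """Load a saved model; raises on version, shape or spec mismatch."""
    with open(path) as handle:
        doc = json.load(handle)
    if doc.get("format") != _FORMAT or doc.get("version") != _VERSION:
        raise ValueError(f"{path}: not a version-{_VERSION} {_FORMAT} file")
    file_spec = RNNSpec(**doc["spec"])
    if spec is not None and spec != file_spec:
        raise ValueError(
            f"{path}: file contains a {file_spec.unit} (H={file_spec.hidden}) "
            f"model, expected {spec.unit} (H={spec.hidden})"
        )
    arrays = {k: np.asarray(v, dtype=np.float64) for k, v in doc["params"].items()}
    params = RNNParams(file_spec, arrays)  # validates shapes
    return RNNResults(
        file_spec,
        params,
        doc["history"],
        doc["selected_epoch"],
        TrainConfig(**doc["config"]),
    )
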