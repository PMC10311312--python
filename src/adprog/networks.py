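"""Recurrent architectures for conversion prediction, in plain NumPy.

Two models are provided:

* :class:`PPAD` — a recurrent encoder (GRU, LSTM, or their bidirectional
  variants) summarises the first ``t`` visits into a latent vector, which is
  concatenated with the encoded demographics and fed to a one-hidden-layer
  MLP with a sigmoid output: the probability of an AD diagnosis at the next
  visit.

* :class:`PPADAutoencoder` — the same encoder, followed by a recurrent
  decoder of the same cell type that is initialised with the encoder's final
  hidden state and rolled forward ``n`` steps to produce latent
  representations of future visits; the classification head consumes the
  last generated latent (with demographics) to predict the diagnosis ``n``
  visits ahead.

All parameters — encoder, decoder and head — are trained jointly against a
sensitivity-weighted binary cross-entropy (``weighted_bce``): the positive
(conversion) term is weighted by ``alpha`` (default 0.7) and the negative
term by ``1 - alpha``, trading false positives for fewer false negatives.

Forward and backward passes are written out explicitly (no autodiff
framework); gradients are exact and checked against scalar-loop oracles in
the test-suite.  Optimisation uses Adam.

The GRU recurrences, written for one time step with input ``x`` and
previous hidden state ``h``::

    r = sigmoid(Wr x + Ur h + br)          # reset gate
    z = sigmoid(Wz x + Uz h + bz)          # update gate
    h~ = tanh(Wh x + Uh (r . h) + bh)      # candidate state
    h' = (1 - z) . h + z . h~              # convex blend

Bidirectional encoding concatenates a left-to-right pass and a
right-to-left pass; the latent handed to the head is each direction's
terminal state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError

EPS = 1e-7  # probability clipping inside the loss

CELL_TYPES = ("GRU", "LSTM", "BiGRU", "BiLSTM")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    fan_out, fan_in = shape
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


# ---------------------------------------------------------------------------
# recurrent cells
# ---------------------------------------------------------------------------

class GRUCell:
    """Gated recurrent unit; hidden state is a single vector."""

    GATES = ("r", "z", "h")

    @staticmethod
    def init(rng: np.random.Generator, input_dim: int,
             hidden_dim: int) -> dict[str, np.ndarray]:
        p = {}
        for g in GRUCell.GATES:
            p[f"W{g}"] = _glorot(rng, (hidden_dim, input_dim))
            p[f"U{g}"] = _glorot(rng, (hidden_dim, hidden_dim))
            p[f"b{g}"] = np.zeros(hidden_dim)
        return p

    @staticmethod
    def init_state(batch: int, hidden_dim: int):
        return np.zeros((batch, hidden_dim))

    @staticmethod
    def hidden_of(state):
        return state

    @staticmethod
    def promote_grad(dh, state):
        return dh

    @staticmethod
    def step(p, x, h):
        r = _sigmoid(x @ p["Wr"].T + h @ p["Ur"].T + p["br"])
        z = _sigmoid(x @ p["Wz"].T + h @ p["Uz"].T + p["bz"])
        hc = np.tanh(x @ p["Wh"].T + (r * h) @ p["Uh"].T + p["bh"])
        h_new = (1.0 - z) * h + z * hc
        return h_new, (x, h, r, z, hc)

    @staticmethod
    def backward(p, cache, dh_new, g, need_dx=False):
        x, h, r, z, hc = cache
        dz = dh_new * (hc - h)
        dhc = dh_new * z
        dh = dh_new * (1.0 - z)

        dah = dhc * (1.0 - hc ** 2)
        g["Wh"] += dah.T @ x
        g["Uh"] += dah.T @ (r * h)
        g["bh"] += dah.sum(axis=0)
        drh = dah @ p["Uh"]
        dr = drh * h
        dh = dh + drh * r

        daz = dz * z * (1.0 - z)
        g["Wz"] += daz.T @ x
        g["Uz"] += daz.T @ h
        g["bz"] += daz.sum(axis=0)
        dh = dh + daz @ p["Uz"]

        dar = dr * r * (1.0 - r)
        g["Wr"] += dar.T @ x
        g["Ur"] += dar.T @ h
        g["br"] += dar.sum(axis=0)
        dh = dh + dar @ p["Ur"]

        dx = dar @ p["Wr"] + daz @ p["Wz"] + dah @ p["Wh"] if need_dx else None
        return dh, dx


class LSTMCell:
    """Long short-term memory cell; state is a (hidden, cell) pair.

    Standard formulation: input/forget/output gates and a tanh candidate;
    the cell memory is gated additively, the hidden state is the output
    gate applied to tanh of the memory.
    """

    GATES = ("i", "f", "o", "g")

    @staticmethod
    def init(rng, input_dim, hidden_dim):
        p = {}
        for g in LSTMCell.GATES:
            p[f"W{g}"] = _glorot(rng, (hidden_dim, input_dim))
            p[f"U{g}"] = _glorot(rng, (hidden_dim, hidden_dim))
            p[f"b{g}"] = np.zeros(hidden_dim)
        p["bf"] += 1.0  # forget-gate bias: retain memory early in training
        return p

    @staticmethod
    def init_state(batch, hidden_dim):
        return (np.zeros((batch, hidden_dim)), np.zeros((batch, hidden_dim)))

    @staticmethod
    def hidden_of(state):
        return state[0]

    @staticmethod
    def promote_grad(dh, state):
        return (dh, np.zeros_like(state[1]))

    @staticmethod
    def step(p, x, state):
        h, c = state
        i = _sigmoid(x @ p["Wi"].T + h @ p["Ui"].T + p["bi"])
        f = _sigmoid(x @ p["Wf"].T + h @ p["Uf"].T + p["bf"])
        o = _sigmoid(x @ p["Wo"].T + h @ p["Uo"].T + p["bo"])
        gt = np.tanh(x @ p["Wg"].T + h @ p["Ug"].T + p["bg"])
        c_new = f * c + i * gt
        h_new = o * np.tanh(c_new)
        return (h_new, c_new), (x, h, c, i, f, o, gt, c_new)

    @staticmethod
    def backward(p, cache, dstate, g, need_dx=False):
        x, h, c, i, f, o, gt, c_new = cache
        dh, dc = dstate
        tc = np.tanh(c_new)
        do = dh * tc
        dc = dc + dh * o * (1.0 - tc ** 2)
        di, df, dg_ = dc * gt, dc * c, dc * i
        dc_prev = dc * f

        dai = di * i * (1.0 - i)
        daf = df * f * (1.0 - f)
        dao = do * o * (1.0 - o)
        dag = dg_ * (1.0 - gt ** 2)

        dh_prev = np.zeros_like(dh)
        dx = np.zeros((x.shape[0], x.shape[1])) if need_dx else None
        for name, da in (("i", dai), ("f", daf), ("o", dao), ("g", dag)):
            g[f"W{name}"] += da.T @ x
            g[f"U{name}"] += da.T @ h
            g[f"b{name}"] += da.sum(axis=0)
            dh_prev = dh_prev + da @ p[f"U{name}"]
            if need_dx:
                dx += da @ p[f"W{name}"]
        return (dh_prev, dc_prev), dx


_CELLS = {"GRU": GRUCell, "LSTM": LSTMCell,
          "BiGRU": GRUCell, "BiLSTM": LSTMCell}


def zero_grads(params: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    return {k: np.zeros_like(v) for k, v in params.items()}


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

def run_rnn(cell, params, X, state=None):
    """Run a unidirectional pass over X (B, T, F); returns the final state,
    the per-step hidden outputs (B, T, H) and the step caches."""
    B, T, _ = X.shape
    H = params[f"b{cell.GATES[0]}"].shape[0]
    if state is None:
        state = cell.init_state(B, H)
    caches, hiddens = [], []
    for t in range(T):
        state, cache = cell.step(params, X[:, t], state)
        caches.append(cache)
        hiddens.append(cell.hidden_of(state))
    return state, np.stack(hiddens, axis=1), caches


def backprop_rnn_from_final(cell, params, caches, dh_final, g,
                            state_final=None):
    """Backpropagate a gradient arriving only at the final hidden state.

    Returns the gradient with respect to the initial hidden state (used to
    chain decoder gradients into the encoder).
    """
    dstate = cell.promote_grad(dh_final, state_final) \
        if state_final is not None and cell is LSTMCell else dh_final
    if cell is LSTMCell and state_final is None:
        raise ConfigError("LSTM backward needs the final state")
    for cache in reversed(caches):
        dstate, _ = cell.backward(params, cache, dstate, g)
    return cell.hidden_of(dstate) if cell is LSTMCell else dstate


# ---------------------------------------------------------------------------
# spec-level functional ops (single-sample, used directly by oracle tests)
# ---------------------------------------------------------------------------

def gru_step(params: dict[str, np.ndarray], x_t: np.ndarray,
             h_prev: np.ndarray) -> np.ndarray:
    """One GRU update for a single input vector (no batch axis)."""
    h_new, _ = GRUCell.step(params, x_t[None, :], h_prev[None, :])
    return h_new[0]


def bigru_encode(forward: dict, backward: dict, X: np.ndarray) -> np.ndarray:
    """Bidirectional GRU encoding of a (T, F) sequence.

    Row ``t`` is the forward pass state after input ``t`` concatenated with
    the backward pass state after input ``t`` (the backward GRU consumes the
    sequence right-to-left).  Output width is exactly 2H.
    """
    if X.ndim != 2 or X.shape[0] < 1:
        raise ConfigError("X must be a (T, F) matrix with T >= 1")
    Xb = X[None, :, :]
    _, hf, _ = run_rnn(GRUCell, forward, Xb)
    _, hb_rev, _ = run_rnn(GRUCell, backward, Xb[:, ::-1])
    hb = hb_rev[:, ::-1]
    return np.concatenate([hf[0], hb[0]], axis=1)


# ---------------------------------------------------------------------------
# classification head
# ---------------------------------------------------------------------------

class MLPHead:
    """ReLU hidden layer plus sigmoid output on (latent (+) demographics)."""

    @staticmethod
    def init(rng, in_dim, hidden_dim):
        return {
            "W2": _glorot(rng, (hidden_dim, in_dim)),
            "b2": np.zeros(hidden_dim),
            "W1": _glorot(rng, (1, hidden_dim)),
            "b1": np.zeros(1),
        }

    @staticmethod
    def forward(p, u):
        a = u @ p["W2"].T + p["b2"]
        hrelu = np.maximum(a, 0.0)
        logit = (hrelu @ p["W1"].T + p["b1"])[:, 0]
        prob = _sigmoid(logit)
        return prob, logit, (u, a, hrelu)

    @staticmethod
    def backward(p, cache, dlogit, g):
        u, a, hrelu = cache
        dl = dlogit[:, None]
        g["W1"] += dl.T @ hrelu
        g["b1"] += dl.sum(axis=0)
        dhrelu = dl @ p["W1"]
        da = dhrelu * (a > 0)
        g["W2"] += da.T @ u
        g["b2"] += da.sum(axis=0)
        return da @ p["W2"]


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def weighted_bce(y: np.ndarray, y_pred: np.ndarray,
                 alpha: float = 0.7) -> float:
    """Sensitivity-weighted binary cross-entropy (batch mean, natural log).

    ``Loss = -(1/N) * sum( alpha*y*log(y') + (1-alpha)*(1-y)*log(1-y') )``.
    ``alpha > 0.5`` penalises false negatives more than false positives.
    Predictions are clipped to (EPS, 1-EPS) before the logarithm.
    """
    if not 0.0 < alpha < 1.0:
        raise ConfigError("alpha must lie strictly in (0, 1)")
    y = np.asarray(y, dtype=float)
    p = np.clip(np.asarray(y_pred, dtype=float), EPS, 1.0 - EPS)
    terms = alpha * y * np.log(p) + (1.0 - alpha) * (1.0 - y) * np.log(1.0 - p)
    return float(-terms.mean())


def weighted_bce_logit_grad(y: np.ndarray, prob: np.ndarray,
                            alpha: float) -> np.ndarray:
    """Exact gradient of :func:`weighted_bce` with respect to the logit."""
    n = len(y)
    return (-(alpha * y * (1.0 - prob)) + (1.0 - alpha) * (1.0 - y) * prob) / n


# ---------------------------------------------------------------------------
# model configuration
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    ``cell`` selects the recurrent unit; ``alpha`` weights the positive
    class in the loss (0.7 by default); ``hidden_dim`` is the encoder state
    width (the latent fed to the head is 2x that for bidirectional cells);
    ``mlp_hidden`` defaults to the latent width.
    """

    cell: str = "GRU"
    hidden_dim: int = 32
    epochs: int = 30
    batch_size: int = 32
    dropout: float = 0.0
    l2: float = 0.0
    alpha: float = 0.7
    learning_rate: float = 0.001
    seed: int = 0
    horizon: int = 1  # decoder steps; used by PPADAutoencoder only
    mlp_hidden: int | None = None
    autoregressive_decoder: bool = False
    threshold: float = 0.5  # probability cut-off for confusion counts

    def validate(self) -> None:
        if self.cell not in CELL_TYPES:
            raise ConfigError(f"unknown cell {self.cell!r}; "
                              f"choose from {CELL_TYPES}")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError("dropout must lie in [0, 1)")
        if self.horizon < 1:
            raise ConfigError("horizon must be >= 1")

    @property
    def bidirectional(self) -> bool:
        return self.cell.startswith("Bi")


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

class _RecurrentClassifier:
    """Shared machinery: encoder (+ optional backward direction) and head."""

    def __init__(self, config: ModelConfig, input_dim: int, demo_dim: int):
        config.validate()
        self.config = config
        self.input_dim = input_dim
        self.demo_dim = demo_dim
        self.cell = _CELLS[config.cell]
        self.latent_dim = config.hidden_dim * (2 if config.bidirectional else 1)
        rng = np.random.default_rng(config.seed)
        self.params: dict[str, dict[str, np.ndarray]] = {
            "enc_f": self.cell.init(rng, input_dim, config.hidden_dim)
        }
        if config.bidirectional:
            self.params["enc_b"] = self.cell.init(rng, input_dim,
                                                  config.hidden_dim)
        self._init_extra(rng)
        mlp_hidden = config.mlp_hidden or self.latent_dim
        self.params["head"] = MLPHead.init(
            rng, self.head_input_dim(), mlp_hidden)

    def _init_extra(self, rng):  # decoder hook
        pass

    def head_input_dim(self) -> int:
        return self.latent_dim + self.demo_dim

    # -- encoder ---------------------------------------------------------

    def encode(self, X: np.ndarray):
        """Latent for each sample in X (B, T, F): forward final state,
        concatenated with the backward direction's final state when
        bidirectional."""
        state_f, _, caches_f = run_rnn(self.cell, self.params["enc_f"], X)
        latent = self.cell.hidden_of(state_f)
        enc_cache = {"f": (caches_f, state_f)}
        if self.config.bidirectional:
            state_b, _, caches_b = run_rnn(
                self.cell, self.params["enc_b"], X[:, ::-1])
            latent = np.concatenate([latent, self.cell.hidden_of(state_b)],
                                    axis=1)
            enc_cache["b"] = (caches_b, state_b)
        return latent, enc_cache

    def _encoder_backward(self, enc_cache, dlatent, grads):
        H = self.config.hidden_dim
        caches_f, state_f = enc_cache["f"]
        backprop_rnn_from_final(self.cell, self.params["enc_f"], caches_f,
                                dlatent[:, :H], grads["enc_f"],
                                state_final=state_f)
        if self.config.bidirectional:
            caches_b, state_b = enc_cache["b"]
            backprop_rnn_from_final(self.cell, self.params["enc_b"], caches_b,
                                    dlatent[:, H:], grads["enc_b"],
                                    state_final=state_b)

    # -- dropout on the latent, before the head --------------------------

    def _apply_dropout(self, latent, train, rng):
        p = self.config.dropout
        if not train or p <= 0.0:
            return latent, None
        if rng is None:
            rng = np.random.default_rng(self.config.seed)
        mask = (rng.random(latent.shape) >= p) / (1.0 - p)
        return latent * mask, mask

    # -- public API ------------------------------------------------------

    def predict_proba(self, X: np.ndarray, D: np.ndarray) -> np.ndarray:
        prob, _ = self.forward(X, D, train=False)
        return prob

    def predict(self, X, D, threshold: float | None = None) -> np.ndarray:
        thr = self.config.threshold if threshold is None else threshold
        return (self.predict_proba(X, D) >= thr).astype(int)

    def parameter_count(self) -> int:
        return sum(v.size for group in self.params.values()
                   for v in group.values())

    def grads_template(self):
        return {name: zero_grads(group) for name, group in self.params.items()}


class PPAD(_RecurrentClassifier):
    """Next-visit conversion predictor: recurrent encoder + MLP head."""

    architecture = "ppad"

    def forward(self, X, D, train=False, rng=None):
        if D.shape[1] != self.demo_dim:
            raise ConfigError(f"demographic width {D.shape[1]} != "
                              f"{self.demo_dim}")
        latent, enc_cache = self.encode(X)
        dropped, mask = self._apply_dropout(latent, train, rng)
        u = np.concatenate([dropped, D], axis=1)
        prob, logit, head_cache = MLPHead.forward(self.params["head"], u)
        return prob, {"enc": enc_cache, "head": head_cache, "mask": mask}

    def backward(self, cache, dlogit):
        grads = self.grads_template()
        du = MLPHead.backward(self.params["head"], cache["head"], dlogit,
                              grads["head"])
        dlatent = du[:, :self.latent_dim]
        if cache["mask"] is not None:
            dlatent = dlatent * cache["mask"]
        self._encoder_backward(cache["enc"], dlatent, grads)
        return grads


class PPADAutoencoder(_RecurrentClassifier):
    """Multi-horizon predictor: encoder, recurrent decoder, MLP head.

    The decoder is a unidirectional cell of the same type whose hidden
    width equals the encoder latent width; it starts from the encoder's
    final latent and is stepped ``horizon`` times.  By default each step's
    input is a zero vector (the latent state carries all information);
    with ``autoregressive_decoder`` the previous latent is fed back as
    input.  The head reads the last generated latent.
    """

    architecture = "ppad_ae"

    def _init_extra(self, rng):
        L = self.latent_dim
        self.params["dec"] = self.cell.init(rng, L, L)

    def forward(self, X, D, train=False, rng=None, horizon=None):
        if D.shape[1] != self.demo_dim:
            raise ConfigError(f"demographic width {D.shape[1]} != "
                              f"{self.demo_dim}")
        n = horizon or self.config.horizon
        latent, enc_cache = self.encode(X)
        B, L = latent.shape

        state = latent if self.cell is GRUCell else (latent, np.zeros_like(latent))
        dec_caches, latents = [], []
        x_in = np.zeros((B, L))
        for _ in range(n):
            state, c = self.cell.step(self.params["dec"], x_in, state)
            dec_caches.append(c)
            latents.append(self.cell.hidden_of(state))
            if self.config.autoregressive_decoder:
                x_in = self.cell.hidden_of(state)

        last = latents[-1]
        dropped, mask = self._apply_dropout(last, train, rng)
        u = np.concatenate([dropped, D], axis=1)
        prob, logit, head_cache = MLPHead.forward(self.params["head"], u)
        cache = {"enc": enc_cache, "dec": dec_caches, "head": head_cache,
                 "mask": mask, "latents": latents}
        return prob, cache

    def decoder_latents(self, X, D, horizon=None):
        _, cache = self.forward(X, D, train=False, horizon=horizon)
        return cache["latents"]

    def backward(self, cache, dlogit):
        grads = self.grads_template()
        du = MLPHead.backward(self.params["head"], cache["head"], dlogit,
                              grads["head"])
        dlast = du[:, :self.latent_dim]
        if cache["mask"] is not None:
            dlast = dlast * cache["mask"]

        # walk the decoder backwards; feed dx into the previous step's
        # hidden gradient when the decoder is autoregressive
        cellc = self.cell
        dstate = cellc.promote_grad(dlast, None) if cellc is GRUCell else \
            (dlast, np.zeros_like(dlast))
        need_dx = self.config.autoregressive_decoder
        for i in reversed(range(len(cache["dec"]))):
            dstate, dx = cellc.backward(self.params["dec"], cache["dec"][i],
                                        dstate, grads["dec"], need_dx=need_dx)
            if need_dx and i > 0 and dx is not None:
                if cellc is GRUCell:
                    dstate = dstate + dx
                else:
                    dstate = (dstate[0] + dx, dstate[1])

        dlatent0 = cellc.hidden_of(dstate) if cellc is LSTMCell else dstate
        self._encoder_backward(cache["enc"], dlatent0, grads)
        return grads


def init_model(config: ModelConfig, input_dim: int, demo_dim: int,
               architecture: str = "ppad"):
    """Build a reproducibly initialised model (``ppad`` or ``ppad_ae``)."""
    if architecture == "ppad":
        return PPAD(config, input_dim, demo_dim)
    if architecture in ("ppad_ae", "ppad-ae"):
        return PPADAutoencoder(config, input_dim, demo_dim)
    raise ConfigError(f"unknown architecture {architecture!r}")


def ppad_forward(model: PPAD, X: np.ndarray, D: np.ndarray) -> float:
    """Single-sample convenience wrapper: (T, F) window -> probability."""
    prob, _ = model.forward(X[None, :, :], np.asarray(D, float)[None, :])
    return float(prob[0])


def ppad_ae_forward(model: PPADAutoencoder, X: np.ndarray, D: np.ndarray,
                    n: int | None = None) -> tuple[float, list[np.ndarray]]:
    """Single-sample wrapper returning (probability, decoder latents)."""
    prob, cache = model.forward(X[None, :, :], np.asarray(D, float)[None, :],
                                horizon=n)
    return float(prob[0]), [lat[0] for lat in cache["latents"]]


# ---------------------------------------------------------------------------
# optimiser
# ---------------------------------------------------------------------------

class Adam:
    """Adaptive moment estimation over the model's nested parameter dict."""

    def __init__(self, params, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {g: {k: np.zeros_like(v) for k, v in grp.items()}
                  for g, grp in params.items()}
        self.v = {g: {k: np.zeros_like(v) for k, v in grp.items()}
                  for g, grp in params.items()}

    def step(self, params, grads):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for gname, grp in params.items():
            for k in grp:
                gr = grads[gname][k]
                m = self.m[gname][k] = self.b1 * self.m[gname][k] \
                    + (1 - self.b1) * gr
                v = self.v[gname][k] = self.b2 * self.v[gname][k] \
                    + (1 - self.b2) * gr ** 2
                grp[k] -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def add_l2_gradients(model, grads, l2: float) -> float:
    """Add the L2 penalty gradient (2*l2*W on every weight matrix, biases
    exempt) and return the penalty value."""
    if l2 <= 0:
        return 0.0
    penalty = 0.0
    for gname, grp in model.params.items():
        for k, w in grp.items():
            if k.startswith(("W", "U")):
                penalty += float(np.sum(w ** 2))
                grads[gname][k] += 2.0 * l2 * w
    return l2 * penalty
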