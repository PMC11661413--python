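"""The 1D bidirectional-GRU arrhythmia classifier.

Architecture, for an (L, d) input segment (L = 1,500 samples):

1. 1D convolution embedding d -> 4d channels (kernel 5, stride 1,
   padding 2; linear, no activation) keeping the sequence length;
2. bidirectional GRU, 128 units per direction, outputs concatenated to
   (L, 256);
3. batch normalization over the 256 features (statistics pooled over
   batch and time), then 20% dropout;
4. a per-time-step dense layer 256 -> 3, giving (L, 3) logits;
5. aggregation of per-step logits to one segment-level 3-class
   distribution (mean of logits by default) followed by softmax.

Classes are coded 0 = NSR, 1 = AF, 2 = PAC/PVC.

The implementation is self-contained NumPy/Numba: the forward pass,
full backpropagation through time, and parameter counting live here;
the optimization loop lives in :mod:`ppgarr.training`.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import _kernels
from .records import L as SEGMENT_L

__all__ = ["ModelSpec", "BiGRUClassifier", "build_model", "count_parameters",
           "predict", "save_checkpoint", "load_checkpoint"]

_AGGREGATIONS = ("mean_logits", "last_step", "max_logits")


@dataclass(frozen=True)
class ModelSpec:
    """Every architectural hyperparameter of the classifier."""

    d: int = 4
    L: int = SEGMENT_L
    conv_multiplier: int = 4        # conv output channels = conv_multiplier * d
    conv_kernel: int = 5
    conv_stride: int = 1
    conv_padding: int = 2
    gru_hidden: int = 128
    dropout_rate: float = 0.20
    n_classes: int = 3
    aggregation: str = "mean_logits"

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("d must be >= 1")
        if self.conv_stride != 1 or self.conv_padding * 2 + 1 != self.conv_kernel:
            raise ValueError("conv must preserve sequence length "
                             "(stride 1, kernel = 2*padding + 1)")
        if self.aggregation not in _AGGREGATIONS:
            raise ValueError(f"aggregation must be one of {_AGGREGATIONS}")

    @property
    def conv_out(self) -> int:
        return self.conv_multiplier * self.d

    @property
    def bn_features(self) -> int:
        return 2 * self.gru_hidden


class BiGRUClassifier:
    """NumPy/Numba implementation with forward, BPTT and inference."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        d, co, H, C = spec.d, spec.conv_out, spec.gru_hidden, spec.n_classes
        k = spec.conv_kernel

        def u(fan_in, *shape):
            bound = 1.0 / np.sqrt(fan_in)
            return rng.uniform(-bound, bound, size=shape).astype(np.float32)

        p: dict[str, np.ndarray] = {}
        p["conv_w"] = u(d * k, d * k, co)
        p["conv_b"] = u(d * k, co)
        for dir_ in ("fwd", "bwd"):
            p[f"wi_{dir_}"] = u(H, co, 3 * H)
            p[f"bi_{dir_}"] = u(H, 3 * H)
            p[f"wh_{dir_}"] = u(H, H, 3 * H)
            p[f"bh_{dir_}"] = u(H, 3 * H)
        p["bn_gamma"] = np.ones(2 * H, dtype=np.float32)
        p["bn_beta"] = np.zeros(2 * H, dtype=np.float32)
        p["fc_w"] = u(2 * H, 2 * H, C)
        p["fc_b"] = u(2 * H, C)
        self.params = p
        # batch-norm running statistics: tracked, not trainable
        self.bn_mean = np.zeros(2 * H, dtype=np.float32)
        self.bn_var = np.ones(2 * H, dtype=np.float32)
        self.bn_momentum = 0.1
        self.bn_eps = 1e-5
        # reusable scratch arrays for the large per-step tensors; avoids
        # re-faulting hundreds of MB of fresh pages on every optimizer step
        self._buffers: dict[str, np.ndarray] = {}

    def _buf(self, key: str, shape: tuple[int, ...]) -> np.ndarray:
        arr = self._buffers.get(key)
        if arr is None or arr.shape != shape:
            arr = np.empty(shape, dtype=np.float32)
            self._buffers[key] = arr
        return arr

    # -- forward pieces ----------------------------------------------------

    def _conv(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        spec = self.spec
        B, T, d = x.shape
        pad = spec.conv_padding
        xp = np.zeros((B, T + 2 * pad, d), dtype=np.float32)
        xp[:, pad:pad + T, :] = x
        cols = np.empty((B, T, spec.conv_kernel * d), dtype=np.float32)
        for k in range(spec.conv_kernel):
            cols[:, :, k * d:(k + 1) * d] = xp[:, k:k + T, :]
        flat = cols.reshape(B * T, -1)
        out = flat @ self.params["conv_w"] + self.params["conv_b"]
        return out.reshape(B, T, spec.conv_out), flat

    def _gru_direction(self, c_t: np.ndarray, dir_: str, training: bool):
        """Run one direction; c_t is (T, B, co) in that direction's time order."""
        p = self.params
        T, B, co = c_t.shape
        H = self.spec.gru_hidden
        P = self._buf(f"P_{dir_}", (T, B, 3 * H))
        np.matmul(c_t.reshape(T * B, co), p[f"wi_{dir_}"],
                  out=P.reshape(T * B, 3 * H))
        P += p[f"bi_{dir_}"]
        Hs = self._buf(f"Hs_{dir_}", (T, B, H))
        if training:
            R = self._buf(f"R_{dir_}", (T, B, H))
            Z = self._buf(f"Z_{dir_}", (T, B, H))
            N = self._buf(f"N_{dir_}", (T, B, H))
            HN = self._buf(f"HN_{dir_}", (T, B, H))
            _kernels.gru_forward(P, p[f"wh_{dir_}"], p[f"bh_{dir_}"], R, Z, N, HN, Hs)
            cache = {"R": R, "Z": Z, "N": N, "HN": HN, "Hs": Hs}
        else:
            _kernels.gru_forward_infer(P, p[f"wh_{dir_}"], p[f"bh_{dir_}"], Hs)
            cache = {"Hs": Hs}
        return Hs, cache

    def _embed(self, x: np.ndarray):
        """Conv embedding in time-major layout plus both GRU input streams."""
        c, conv_cols = self._conv(x)
        c_t = np.ascontiguousarray(c.transpose(1, 0, 2))      # (T, B, co)
        c_rev = np.ascontiguousarray(c_t[::-1])
        return c_t, c_rev, conv_cols

    def _forward(self, x: np.ndarray, training: bool,
                 rng: np.random.Generator | None = None,
                 use_batch_stats: bool | None = None):
        spec = self.spec
        x = np.ascontiguousarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        B, T, d = x.shape
        if d != spec.d:
            raise ValueError(f"expected {spec.d} input channels, got {d}")
        if T != spec.L:
            raise ValueError(f"expected sequence length {spec.L}, got {T}")
        H = spec.gru_hidden
        cache: dict = {"B": B, "T": T}

        c_t, c_rev, conv_cols = self._embed(x)
        cache["conv_cols"] = conv_cols
        hs_f, cache_f = self._gru_direction(c_t, "fwd", training)
        hs_b, cache_b = self._gru_direction(c_rev, "bwd", training)
        cache["c_t"], cache["c_rev"] = c_t, c_rev
        cache["gru_fwd"], cache["gru_bwd"] = cache_f, cache_b
        # time-major concat (T,B,2H); backward direction back in real time
        hcat = self._buf("hcat", (T, B, 2 * H))
        hcat[:, :, :H] = hs_f
        hcat[:, :, H:] = hs_b[::-1]

        flat = hcat.reshape(T * B, 2 * H)
        if use_batch_stats is None:
            use_batch_stats = training
        if use_batch_stats:
            mu = flat.mean(axis=0)
            var = flat.var(axis=0)
            if training:
                self.bn_mean = ((1 - self.bn_momentum) * self.bn_mean
                                + self.bn_momentum * mu)
                self.bn_var = ((1 - self.bn_momentum) * self.bn_var
                               + self.bn_momentum * var)
        else:
            mu, var = self.bn_mean, self.bn_var
        ivar = (1.0 / np.sqrt(var + self.bn_eps)).astype(np.float32)
        xhat = self._buf("xhat", flat.shape)
        np.subtract(flat, mu.astype(np.float32), out=xhat)
        xhat *= ivar
        bn_out = self._buf("bn_out", flat.shape)
        np.multiply(xhat, self.params["bn_gamma"], out=bn_out)
        bn_out += self.params["bn_beta"]
        cache["xhat"], cache["ivar"] = xhat, ivar

        if training and spec.dropout_rate > 0:
            if rng is None:
                raise ValueError("training forward pass needs an rng for dropout")
            keep = np.float32(1.0 - spec.dropout_rate)
            mask = self._buf("dropout_mask", bn_out.shape)
            rng.random(out=mask, dtype=np.float32)
            # floor(u + keep) is 1 with probability `keep`, else 0
            mask += keep
            np.floor(mask, out=mask)
            mask /= keep
            bn_out *= mask
            cache["dropout_mask"] = mask
        cache["bn_out"] = bn_out

        step_logits = (bn_out @ self.params["fc_w"]
                       + self.params["fc_b"]).reshape(T, B, spec.n_classes)
        if spec.aggregation == "mean_logits":
            logits = step_logits.mean(axis=0)
        elif spec.aggregation == "last_step":
            logits = step_logits[-1]
        else:  # max_logits
            cache["argmax_t"] = step_logits.argmax(axis=0)
            logits = step_logits.max(axis=0)
        cache["step_logits"] = step_logits
        return logits.astype(np.float32), cache

    def recalibrate_bn(self, x: np.ndarray, batch_size: int = 64) -> None:
        """Replace BN running statistics with exact statistics under the
        current weights, pooled over the given (training) segments.

        At full scale the exponentially averaged statistics converge on
        their own; with few optimizer steps they lag the weights, so the
        checkpointed model re-estimates them in one frozen-weight pass.
        """
        x = np.asarray(x, dtype=np.float32)
        H = self.spec.gru_hidden
        total = np.zeros(2 * H, dtype=np.float64)
        total_sq = np.zeros(2 * H, dtype=np.float64)
        count = 0
        for lo in range(0, x.shape[0], batch_size):
            xb = np.ascontiguousarray(x[lo:lo + batch_size])
            c_t, c_rev, _ = self._embed(xb)
            hs_f, _ = self._gru_direction(c_t, "fwd", training=False)
            hs_b, _ = self._gru_direction(c_rev, "bwd", training=False)
            for part, sl in ((hs_f, slice(0, H)), (hs_b, slice(H, 2 * H))):
                flat = part.reshape(-1, H).astype(np.float64)
                total[sl] += flat.sum(axis=0)
                total_sq[sl] += (flat * flat).sum(axis=0)
            count += xb.shape[0] * xb.shape[1]
        mean = total / count
        var = total_sq / count - mean ** 2
        self.bn_mean = mean.astype(np.float32)
        self.bn_var = np.maximum(var, 0.0).astype(np.float32)

    # -- public API --------------------------------------------------------

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Class probabilities, (n, 3); deterministic (dropout off)."""
        x = np.asarray(x, dtype=np.float32)
        single = x.ndim == 2
        if single:
            x = x[None]
        out = np.empty((x.shape[0], self.spec.n_classes), dtype=np.float64)
        for lo in range(0, x.shape[0], batch_size):
            logits, _ = self._forward(x[lo:lo + batch_size], training=False)
            out[lo:lo + batch_size] = _softmax(logits)
        return out[0] if single else out

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray,
                       rng: np.random.Generator):
        """Mean cross-entropy over the batch plus gradients for every parameter."""
        y = np.asarray(y, dtype=np.int64)
        logits, cache = self._forward(x, training=True, rng=rng)
        B = logits.shape[0]
        probs = _softmax(logits)
        loss = float(-np.mean(np.log(probs[np.arange(B), y] + 1e-12)))
        dlogits = probs.astype(np.float32)
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        grads = self._backward(dlogits, cache)
        return loss, grads

    def eval_loss(self, x: np.ndarray, y: np.ndarray, batch_size: int = 64,
                  use_batch_stats: bool = False) -> float:
        """Mean cross-entropy without dropout.

        With ``use_batch_stats`` the normalization uses the statistics of
        the evaluated batches instead of the running averages — the
        train-loop uses this for epoch-wise validation, where the running
        averages may still trail the current weights.
        """
        x = np.asarray(x, dtype=np.float32)
        y = np.asarray(y, dtype=np.int64)
        losses = []
        for lo in range(0, x.shape[0], batch_size):
            logits, _ = self._forward(x[lo:lo + batch_size], training=False,
                                      use_batch_stats=use_batch_stats)
            probs = _softmax(logits)
            yb = y[lo:lo + batch_size]
            losses.append(-np.log(probs[np.arange(yb.size), yb] + 1e-12))
        return float(np.mean(np.concatenate(losses)))

    # -- backward ----------------------------------------------------------

    def _backward(self, dlogits: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        spec = self.spec
        p = self.params
        B, T = cache["B"], cache["T"]
        H = spec.gru_hidden
        grads: dict[str, np.ndarray] = {}

        # aggregation -> per-step logits (time-major)
        dstep = np.zeros((T, B, spec.n_classes), dtype=np.float32)
        if spec.aggregation == "mean_logits":
            dstep += (dlogits / T)[None, :, :]
        elif spec.aggregation == "last_step":
            dstep[-1] = dlogits
        else:
            am = cache["argmax_t"]
            for c in range(spec.n_classes):
                dstep[am[:, c], np.arange(B), c] = dlogits[:, c]
        dflat = dstep.reshape(T * B, spec.n_classes)

        bn_out = cache["bn_out"]
        grads["fc_w"] = bn_out.T @ dflat
        grads["fc_b"] = dflat.sum(axis=0)
        dbn = self._buf("dbn", bn_out.shape)
        np.matmul(dflat, p["fc_w"].T, out=dbn)
        if "dropout_mask" in cache:
            dbn *= cache["dropout_mask"]

        # batch norm backward (batch statistics)
        xhat, ivar = cache["xhat"], cache["ivar"]
        n = xhat.shape[0]
        grads["bn_gamma"] = (dbn * xhat).sum(axis=0)
        grads["bn_beta"] = dbn.sum(axis=0)
        dxhat = dbn
        dxhat *= p["bn_gamma"]
        dhcat = dxhat
        dhcat -= dxhat.mean(axis=0)
        dhcat -= xhat * (dxhat * xhat).mean(axis=0)
        dhcat *= ivar
        dhcat = dhcat.reshape(T, B, 2 * H)

        # split directions; the backward direction runs on reversed time
        dH_f = self._buf("dH_f", (T, B, H))
        dH_f[:] = dhcat[:, :, :H]
        dH_b = self._buf("dH_b", (T, B, H))
        dH_b[:] = dhcat[::-1, :, H:]
        dc_t = None
        for dir_, dH, c_dir in (("fwd", dH_f, cache["c_t"]),
                                ("bwd", dH_b, cache["c_rev"])):
            g = cache[f"gru_{dir_}"]
            dQ = self._buf("dQ", (T, B, 3 * H))
            dN = self._buf("dN", (T, B, H))
            WhT = np.ascontiguousarray(p[f"wh_{dir_}"].T)
            _kernels.gru_backward(dH, WhT, g["R"], g["Z"], g["N"], g["HN"],
                                  g["Hs"], dQ, dN)
            # h_0 = 0, so the t=0 term contributes nothing to wh
            grads[f"wh_{dir_}"] = (g["Hs"][:-1].reshape((T - 1) * B, H).T
                                   @ dQ[1:].reshape((T - 1) * B, 3 * H))
            grads[f"bh_{dir_}"] = dQ.reshape(T * B, 3 * H).sum(axis=0)
            # input-projection gradient: n-block uses dn (not r*dn)
            dQ[:, :, 2 * H:] = dN
            dP = dQ.reshape(T * B, 3 * H)
            c_flat = c_dir.reshape(T * B, spec.conv_out)
            grads[f"wi_{dir_}"] = c_flat.T @ dP
            grads[f"bi_{dir_}"] = dP.sum(axis=0)
            dc_dir = (dP @ p[f"wi_{dir_}"].T).reshape(T, B, spec.conv_out)
            if dir_ == "bwd":
                dc_dir = dc_dir[::-1]
            dc_t = dc_dir if dc_t is None else dc_t + dc_dir

        # back to batch-major for the conv col gradient
        dc_flat = np.ascontiguousarray(
            dc_t.transpose(1, 0, 2)).reshape(B * T, spec.conv_out)
        grads["conv_w"] = cache["conv_cols"].T @ dc_flat
        grads["conv_b"] = dc_flat.sum(axis=0)
        return grads

    # -- bookkeeping -------------------------------------------------------

    def count_parameters(self) -> int:
        """Trainable parameters only; BN running statistics are excluded."""
        return int(sum(v.size for v in self.params.values()))

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {k: v.copy() for k, v in self.params.items()}
        out["_bn_mean"] = self.bn_mean.copy()
        out["_bn_var"] = self.bn_var.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=np.float32).copy()
        self.bn_mean = np.asarray(state["_bn_mean"], dtype=np.float32).copy()
        self.bn_var = np.asarray(state["_bn_var"], dtype=np.float32).copy()


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits.astype(np.float64)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def build_model(spec: ModelSpec, seed: int = 0) -> BiGRUClassifier:
    """Instantiate the classifier for the given architecture spec."""
    return BiGRUClassifier(spec, seed=seed)


def count_parameters(model: BiGRUClassifier) -> int:
    """Total trainable parameter count of a built model."""
    return model.count_parameters()


def predict(model: BiGRUClassifier, x: np.ndarray) -> np.ndarray:
    """Segment-level class probabilities for one (L, d) matrix or a batch."""
    return model.predict_proba(x)


def save_checkpoint(path, model: BiGRUClassifier, *, seed: int | None = None,
                    extra: dict | None = None) -> None:
    """Serialize spec + weights (+ training seed) into one ``.npz`` file."""
    meta = {"spec": asdict(model.spec), "seed": seed, "extra": extra or {}}
    np.savez(path, _meta=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **model.state_dict())


def load_checkpoint(path) -> tuple[BiGRUClassifier, dict]:
    """Rebuild a model from :func:`save_checkpoint` output."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["_meta"].tobytes()).decode())
        state = {k: data[k] for k in data.files if k != "_meta"}
    spec = ModelSpec(**meta["spec"])
    model = BiGRUClassifier(spec)
    model.load_state_dict(state)
    return model, meta
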