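"""Small feed-forward regression network trained by Levenberg–Marquardt.

Mirrors the classic shallow-network fitting recipe: tanh hidden layers,
linear outputs, min-max normalisation of inputs and targets to [-1, 1],
full-batch damped least-squares (LM) optimisation with an analytic
Jacobian, and early stopping on a validation set (patience 6).  The damping
factor follows the usual schedule (start 1e-3, ×10 on a rejected step,
×0.1 on an accepted one, give up above 1e10).

Deliberately dependency-light: everything is plain numpy so that training
is bit-reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MinMaxScaler", "LMNet"]


@dataclass
class MinMaxScaler:
    """Map each column linearly from [lo, hi] to [-1, 1] (and back)."""

    lo: np.ndarray
    hi: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray) -> "MinMaxScaler":
        lo = x.min(axis=0)
        hi = x.max(axis=0)
        span = hi - lo
        # constant columns map to 0
        hi = np.where(span == 0.0, lo + 1.0, hi)
        return cls(lo, hi)

    def transform(self, x: np.ndarray) -> np.ndarray:
        return 2.0 * (x - self.lo) / (self.hi - self.lo) - 1.0

    def inverse(self, xn: np.ndarray) -> np.ndarray:
        return (xn + 1.0) / 2.0 * (self.hi - self.lo) + self.lo


class LMNet:
    """Tanh multilayer perceptron fitted with Levenberg–Marquardt.

    Parameters
    ----------
    layer_sizes:
        Full layer widths including input and output, e.g. ``(3, 12, 12,
        12, 2)`` for the two-DoF orientation net.
    seed:
        Seed for the weight initialisation; training is deterministic
        given the seed and the data.
    """

    def __init__(self, layer_sizes=(3, 12, 12, 12, 2), seed: int = 0):
        self.layer_sizes = tuple(int(s) for s in layer_sizes)
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(self.layer_sizes[:-1], self.layer_sizes[1:]):
            self.weights.append(rng.normal(0.0, 1.0 / np.sqrt(fan_in),
                                           size=(fan_out, fan_in)))
            self.biases.append(np.zeros(fan_out))
        self.history: dict = {}

    # -- parameter packing ---------------------------------------------------

    def _pack(self) -> np.ndarray:
        return np.concatenate(
            [w.ravel() for w in self.weights] + [b for b in self.biases]
        )

    def _unpack(self, p: np.ndarray) -> None:
        i = 0
        for li, w in enumerate(self.weights):
            self.weights[li] = p[i:i + w.size].reshape(w.shape)
            i += w.size
        for li, b in enumerate(self.biases):
            self.biases[li] = p[i:i + b.size].copy()
            i += b.size

    @property
    def n_params(self) -> int:
        return sum(w.size for w in self.weights) + sum(b.size for b in self.biases)

    # -- forward / jacobian --------------------------------------------------

    def _forward(self, xn: np.ndarray) -> list[np.ndarray]:
        acts = [xn]
        a = xn
        last = len(self.weights) - 1
        for li, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ w.T + b
            a = z if li == last else np.tanh(z)
            acts.append(a)
        return acts

    def predict_norm(self, xn: np.ndarray) -> np.ndarray:
        return self._forward(xn)[-1]

    def _jacobian(self, acts: list[np.ndarray]) -> np.ndarray:
        """Analytic Jacobian of the outputs w.r.t. every parameter.

        Returns shape (n_samples, n_outputs, n_params), parameter order
        matching :meth:`_pack`.
        """
        n = acts[0].shape[0]
        n_out = self.layer_sizes[-1]
        n_layers = len(self.weights)
        jac_w = []
        jac_b = []
        # delta[k] per output unit k, computed for all outputs at once:
        # shape (n, n_out, width_l)
        delta = np.broadcast_to(
            np.eye(n_out), (n, n_out, n_out)
        ).copy()
        deltas = [None] * n_layers
        deltas[n_layers - 1] = delta
        for li in range(n_layers - 1, 0, -1):
            d_prev = np.einsum("nko,oi->nki", deltas[li], self.weights[li])
            d_prev *= (1.0 - acts[li] ** 2)[:, None, :]
            deltas[li - 1] = d_prev
        parts = []
        for li in range(n_layers):
            a_in = acts[li]  # (n, fan_in)
            d = deltas[li]  # (n, n_out, fan_out)
            jw = np.einsum("nko,ni->nkoi", d, a_in).reshape(n, n_out, -1)
            jac_w.append(jw)
            jac_b.append(d)
        parts = jac_w + jac_b
        return np.concatenate(parts, axis=2)

    # -- training ------------------------------------------------------------

    def fit(self, xn: np.ndarray, yn: np.ndarray,
            xval: np.ndarray | None = None, yval: np.ndarray | None = None,
            max_iter: int = 150, patience: int = 6,
            mu0: float = 1.0e-3, mu_max: float = 1.0e10,
            grad_tol: float = 1.0e-8) -> "LMNet":
        """Full-batch LM fit on normalised data; early stop on validation.

        On exit the network holds the weights with the best validation
        error seen (or the final weights when no validation set is given).
        """
        p = self._pack()
        eye = np.eye(p.size)

        def residuals(param: np.ndarray) -> np.ndarray:
            self._unpack(param)
            return (self.predict_norm(xn) - yn).ravel()

        r = residuals(p)
        cost = float(r @ r)
        mu = mu0
        best_val = np.inf
        best_p = p.copy()
        bad = 0
        hist = {"train_mse": [], "val_mse": []}
        converged = "max_iter"
        for _ in range(max_iter):
            self._unpack(p)
            acts = self._forward(xn)
            jac = self._jacobian(acts)
            j2 = jac.reshape(-1, p.size)
            jtj = j2.T @ j2
            jtr = j2.T @ r
            if np.max(np.abs(jtr)) < grad_tol:
                converged = "gradient"
                break
            accepted = False
            while mu <= mu_max:
                try:
                    dp = np.linalg.solve(jtj + mu * eye, -jtr)
                except np.linalg.LinAlgError:
                    mu *= 10.0
                    continue
                r_new = residuals(p + dp)
                cost_new = float(r_new @ r_new)
                if cost_new < cost:
                    p = p + dp
                    r, cost = r_new, cost_new
                    mu = max(mu * 0.1, 1.0e-20)
                    accepted = True
                    break
                mu *= 10.0
            if not accepted:
                converged = "mu_max"
                break
            hist["train_mse"].append(cost / r.size)
            if xval is not None:
                self._unpack(p)
                rv = self.predict_norm(xval) - yval
                val = float(np.mean(rv ** 2))
                hist["val_mse"].append(val)
                if val < best_val - 1.0e-12:
                    best_val = val
                    best_p = p.copy()
                    bad = 0
                else:
                    bad += 1
                    if bad >= patience:
                        converged = "early_stop"
                        break
        if xval is not None:
            self._unpack(best_p)
        else:
            self._unpack(p)
        hist["stop_reason"] = converged
        self.history = hist
        return self
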