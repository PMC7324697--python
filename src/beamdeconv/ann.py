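"""Sliding-window neural network for beam-profile deconvolution.

The network is a three-layer perceptron: ``lsw`` inputs (a window of
consecutive measured-profile samples at 1 mm spacing), ``nhn`` tanh hidden
units, and one linear output — the deconvolved dose value at the window's
center.  At the defaults (lsw=15, nhn=5) it has 86 free parameters
(80 weights + 6 biases).

Training minimizes the sum of squared output errors with a damped
Gauss–Newton (Levenberg–Marquardt) loop using the analytic Jacobian of the
forward pass with respect to all parameters.  Because random initialization
matters for so small a network, training restarts several times and the
restart with the lowest validation MSE is kept.

The model/results split follows the usual statistical-modelling pattern:
:class:`SlidingWindowANN` holds the (input window, target) samples and
:meth:`SlidingWindowANN.fit` returns an :class:`ANNResults` that carries the
selected parameters, per-restart training records, and the
:meth:`ANNResults.deconvolve` method.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .profiles import Profile

__all__ = [
    "NetworkParams",
    "TrainingRecord",
    "TrainingFailure",
    "forward",
    "extract_windows",
    "SlidingWindowANN",
    "ANNResults",
    "train",
    "deconvolve",
]

DEFAULT_LSW = 15
DEFAULT_NHN = 5


@dataclass(frozen=True, eq=False)
class NetworkParams:
    """All weights and biases of the three-layer network.

    ``w_hidden[j, k]`` links input j to hidden unit k; ``w_out[k]`` links
    hidden unit k to the output. Parameter count is
    ``lsw*nhn + nhn + nhn + 1`` (86 at the defaults).
    """

    w_hidden: np.ndarray  # (lsw, nhn)
    b_hidden: np.ndarray  # (nhn,)
    w_out: np.ndarray  # (nhn,)
    b_out: float

    def __post_init__(self):
        w = np.asarray(self.w_hidden, dtype=float)
        object.__setattr__(self, "w_hidden", w)
        object.__setattr__(self, "b_hidden", np.asarray(self.b_hidden, dtype=float))
        object.__setattr__(self, "w_out", np.asarray(self.w_out, dtype=float))
        object.__setattr__(self, "b_out", float(self.b_out))
        if self.b_hidden.shape != (self.nhn,) or self.w_out.shape != (self.nhn,):
            raise ValueError("inconsistent hidden/output shapes")
        if not all(
            np.all(np.isfinite(a)) for a in (w, self.b_hidden, self.w_out)
        ) or not np.isfinite(self.b_out):
            raise ValueError("parameters must be finite")

    @property
    def lsw(self) -> int:
        return self.w_hidden.shape[0]

    @property
    def nhn(self) -> int:
        return self.w_hidden.shape[1]

    @property
    def n_params(self) -> int:
        return self.lsw * self.nhn + 2 * self.nhn + 1

    # -- flat-vector view used by the optimizer ---------------------------

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [self.w_hidden.ravel(), self.b_hidden, self.w_out, [self.b_out]]
        )

    @classmethod
    def from_vector(cls, theta: np.ndarray, lsw: int, nhn: int) -> "NetworkParams":
        theta = np.asarray(theta, dtype=float)
        if theta.size != lsw * nhn + 2 * nhn + 1:
            raise ValueError("parameter vector has wrong length")
        w_end = lsw * nhn
        return cls(
            w_hidden=theta[:w_end].reshape(lsw, nhn),
            b_hidden=theta[w_end : w_end + nhn],
            w_out=theta[w_end + nhn : w_end + 2 * nhn],
            b_out=theta[-1],
        )

    @classmethod
    def random(cls, lsw: int, nhn: int, rng: np.random.Generator) -> "NetworkParams":
        """Uniform(-1, 1) initialization of every weight and bias."""
        n = lsw * nhn + 2 * nhn + 1
        return cls.from_vector(rng.uniform(-1.0, 1.0, size=n), lsw, nhn)

    def to_dict(self) -> dict:
        return {
            "lsw": self.lsw,
            "nhn": self.nhn,
            "w_hidden": self.w_hidden.tolist(),
            "b_hidden": self.b_hidden.tolist(),
            "w_out": self.w_out.tolist(),
            "b_out": self.b_out,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkParams":
        return cls(
            w_hidden=np.array(d["w_hidden"], dtype=float),
            b_hidden=np.array(d["b_hidden"], dtype=float),
            w_out=np.array(d["w_out"], dtype=float),
            b_out=d["b_out"],
        )


@dataclass(frozen=True)
class TrainingRecord:
    """Diagnostics of one random-restart training attempt."""

    restart_index: int
    seed: int
    epochs_run: int
    final_train_mse: float
    final_validation_mse: float
    train_loss_history: list = field(default_factory=list, repr=False)


class TrainingFailure(RuntimeError):
    """All restarts produced a non-finite loss; records attached."""

    def __init__(self, records):
        super().__init__("training diverged in every restart")
        self.records = records


# ---------------------------------------------------------------------------
# forward pass and Jacobian
# ---------------------------------------------------------------------------


def _forward_batch(theta, X, lsw, nhn):
    """Outputs for a batch of windows X (n, lsw), theta a flat vector."""
    w_end = lsw * nhn
    W = theta[:w_end].reshape(lsw, nhn)
    bh = theta[w_end : w_end + nhn]
    wo = theta[w_end + nhn : w_end + 2 * nhn]
    bo = theta[-1]
    H = np.tanh(X @ W + bh)
    return H @ wo + bo, H, wo


def forward(params: NetworkParams, window: np.ndarray) -> float:
    """Deconvolved value for a single input window of ``lsw`` samples."""
    window = np.asarray(window, dtype=float)
    if window.shape != (params.lsw,):
        raise ValueError(f"window must have length {params.lsw}")
    if not np.all(np.isfinite(window)):
        raise ValueError("window values must be finite")
    out, _, _ = _forward_batch(params.to_vector(), window[None, :], params.lsw, params.nhn)
    return float(out[0])


def _jacobian(theta, X, lsw, nhn):
    """Analytic Jacobian dO/dtheta, shape (n, n_params).

    Column order matches :meth:`NetworkParams.to_vector`:
    w_hidden (row-major), b_hidden, w_out, b_out.
    """
    out, H, wo = _forward_batch(theta, X, lsw, nhn)
    G = (1.0 - H * H) * wo  # (n, nhn): dO/d(pre-activation_k)
    n = X.shape[0]
    J = np.empty((n, lsw * nhn + 2 * nhn + 1))
    J[:, : lsw * nhn] = (X[:, :, None] * G[:, None, :]).reshape(n, lsw * nhn)
    J[:, lsw * nhn : lsw * nhn + nhn] = G
    J[:, lsw * nhn + nhn : lsw * nhn + 2 * nhn] = H
    J[:, -1] = 1.0
    return out, J


def _levenberg_marquardt(
    theta0,
    X,
    y,
    lsw,
    nhn,
    max_epochs=400,
    mu0=1e-3,
    mu_max=1e10,
    grad_tol=1e-10,
):
    """Damped Gauss–Newton minimization of the sum of squared errors.

    One epoch = one outer iteration: the damping factor mu grows tenfold
    until a step reduces the loss (then shrinks tenfold), so accepted steps
    never increase the training loss. Stops at ``max_epochs``, when the
    gradient infinity-norm falls below ``grad_tol``, or when mu exceeds
    ``mu_max``.
    """
    theta = np.asarray(theta0, dtype=float).copy()
    out, _, _ = _forward_batch(theta, X, lsw, nhn)
    loss = float(np.sum((out - y) ** 2))
    mu = mu0
    history = [loss]
    eye = np.eye(theta.size)
    epoch = 0
    while epoch < max_epochs:
        if not np.isfinite(loss):
            break
        out, J = _jacobian(theta, X, lsw, nhn)
        r = out - y
        g = J.T @ r
        if np.max(np.abs(g)) < grad_tol:
            break
        A = J.T @ J
        accepted = False
        while mu <= mu_max:
            try:
                delta = np.linalg.solve(A + mu * eye, -g)
            except np.linalg.LinAlgError:
                mu *= 10.0
                continue
            cand = theta + delta
            out_c, _, _ = _forward_batch(cand, X, lsw, nhn)
            cand_loss = float(np.sum((out_c - y) ** 2))
            if np.isfinite(cand_loss) and cand_loss < loss:
                theta, loss = cand, cand_loss
                mu = max(mu / 10.0, 1e-20)
                accepted = True
                break
            mu *= 10.0
        epoch += 1
        history.append(loss)
        if not accepted:  # mu exhausted: local minimum to machine precision
            break
    return theta, loss, epoch, history


# ---------------------------------------------------------------------------
# samples
# ---------------------------------------------------------------------------


def extract_windows(measured: Profile, reference: Profile, lsw: int = DEFAULT_LSW):
    """Paired (window, target) samples from one measured/reference scan pair.

    For every position where a full ``lsw``-sample window fits on the
    measured profile, the input is the window and the target is the
    reference value at the window's center; a profile of N samples yields
    ``N - lsw + 1`` pairs.
    """
    if lsw % 2 != 1:
        raise ValueError("lsw must be odd")
    n = measured.values.size
    if n < lsw:
        raise ValueError(f"profile of {n} samples shorter than window {lsw}")
    if reference.values.size != n or not np.allclose(
        measured.positions, reference.positions, atol=1e-9
    ):
        raise ValueError("measured and reference must share a common grid")
    X = np.lib.stride_tricks.sliding_window_view(measured.values, lsw).copy()
    y = reference.values[lsw // 2 : n - lsw // 2].copy()
    return X, y


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


class SlidingWindowANN:
    """Deconvolution network built from pooled (window, target) samples.

    Parameters
    ----------
    X : ndarray (n_samples, lsw)
        Input windows of measured relative dose.
    y : ndarray (n_samples,)
        Reference (true) dose at each window's center.
    nhn : int
        Hidden-layer size.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, nhn: int = DEFAULT_NHN):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
            raise ValueError("X must be (n, lsw) and y (n,)")
        self.X, self.y = X, y
        self.lsw = X.shape[1]
        self.nhn = nhn
        n_params = self.lsw * nhn + 2 * nhn + 1
        if X.shape[0] < n_params:
            raise ValueError(
                f"need at least {n_params} samples to determine {n_params} "
                f"parameters; got {X.shape[0]}"
            )

    @classmethod
    def from_profile_pairs(cls, pairs, lsw: int = DEFAULT_LSW, nhn: int = DEFAULT_NHN):
        """Pool sliding-window samples from (measured, reference) profile pairs."""
        Xs, ys = [], []
        for measured, reference in pairs:
            X, y = extract_windows(measured, reference, lsw)
            Xs.append(X)
            ys.append(y)
        return cls(np.vstack(Xs), np.concatenate(ys), nhn=nhn)

    def fit(
        self,
        restarts: int = 10,
        max_epochs: int = 400,
        seed: int = 0,
        validation_fraction: float = 0.2,
    ) -> "ANNResults":
        """Train with random restarts; keep the lowest-validation-MSE network.

        Each restart initializes all parameters uniform(-1, 1) with seed
        ``seed + restart`` and runs up to ``max_epochs`` Levenberg–Marquardt
        epochs. The sample-level train/validation split (seeded by ``seed``)
        is shared across restarts so their validation MSEs are comparable.
        """
        if restarts < 1:
            raise ValueError("restarts must be >= 1")
        n = self.X.shape[0]
        perm = np.random.default_rng(seed).permutation(n)
        n_val = max(1, int(round(validation_fraction * n)))
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        Xt, yt = self.X[train_idx], self.y[train_idx]
        Xv, yv = self.X[val_idx], self.y[val_idx]

        records, thetas = [], []
        for r in range(restarts):
            rng = np.random.default_rng(seed + r)
            theta0 = NetworkParams.random(self.lsw, self.nhn, rng).to_vector()
            theta, loss, epochs, history = _levenberg_marquardt(
                theta0, Xt, yt, self.lsw, self.nhn, max_epochs=max_epochs
            )
            out_v, _, _ = _forward_batch(theta, Xv, self.lsw, self.nhn)
            val_mse = float(np.mean((out_v - yv) ** 2))
            records.append(
                TrainingRecord(
                    restart_index=r,
                    seed=seed + r,
                    epochs_run=epochs,
                    final_train_mse=loss / Xt.shape[0],
                    final_validation_mse=val_mse,
                    train_loss_history=history,
                )
            )
            thetas.append(theta)

        val = np.array([rec.final_validation_mse for rec in records])
        finite = np.isfinite(val)
        if not finite.any():
            raise TrainingFailure(records)
        best = int(np.flatnonzero(finite)[np.argmin(val[finite])])
        params = NetworkParams.from_vector(thetas[best], self.lsw, self.nhn)
        return ANNResults(model=self, params=params, records=records, selected=best)


@dataclass(frozen=True, eq=False)
class ANNResults:
    """Selected network parameters plus per-restart training diagnostics."""

    model: SlidingWindowANN
    params: NetworkParams
    records: list
    selected: int

    @property
    def train_mse(self) -> float:
        return self.records[self.selected].final_train_mse

    @property
    def validation_mse(self) -> float:
        return self.records[self.selected].final_validation_mse

    def deconvolve(self, measured: Profile) -> Profile:
        """Point-by-point deconvolution of a measured profile."""
        return deconvolve(self.params, measured)

    def summary(self) -> str:
        p = self.params
        lines = [
            "Sliding-window deconvolution network",
            f"  architecture      {p.lsw}-{p.nhn}-1 ({p.n_params} parameters)",
            f"  training samples  {self.model.X.shape[0]}",
            f"  restarts          {len(self.records)} (selected #{self.selected})",
            f"  train MSE         {self.train_mse:.3e}",
            f"  validation MSE    {self.validation_mse:.3e}",
            "  restart  epochs   train MSE      val MSE",
        ]
        for rec in self.records:
            mark = "*" if rec.restart_index == self.selected else " "
            lines.append(
                f"  {mark}{rec.restart_index:5d}  {rec.epochs_run:6d}  "
                f"{rec.final_train_mse:11.3e}  {rec.final_validation_mse:11.3e}"
            )
        return "\n".join(lines)

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        d = self.params.to_dict()
        d["training"] = {
            "selected": self.selected,
            "records": [
                {
                    "restart_index": r.restart_index,
                    "seed": r.seed,
                    "epochs_run": r.epochs_run,
                    "final_train_mse": r.final_train_mse,
                    "final_validation_mse": r.final_validation_mse,
                }
                for r in self.records
            ],
        }
        Path(path).write_text(json.dumps(d, indent=1))


def load_params(path) -> NetworkParams:
    """Load serialized network parameters from JSON."""
    return NetworkParams.from_dict(json.loads(Path(path).read_text()))


def train(
    pairs,
    lsw: int = DEFAULT_LSW,
    nhn: int = DEFAULT_NHN,
    restarts: int = 10,
    max_epochs: int = 400,
    seed: int = 0,
) -> ANNResults:
    """Functional shorthand: pool windows from profile pairs and fit."""
    return SlidingWindowANN.from_profile_pairs(pairs, lsw=lsw, nhn=nhn).fit(
        restarts=restarts, max_epochs=max_epochs, seed=seed
    )


def deconvolve(params: NetworkParams, measured: Profile) -> Profile:
    """Slide the network across a measured profile to rebuild the true one.

    The measured profile is replicate-padded by half a window on each end
    so the output covers the full input grid; scans end on flat tails where
    replication is benign. Output values are not clipped or renormalized.
    """
    n = measured.values.size
    if n < params.lsw:
        raise ValueError(f"profile of {n} samples shorter than window {params.lsw}")
    half = params.lsw // 2
    padded = np.pad(measured.values, half, mode="edge")
    X = np.lib.stride_tricks.sliding_window_view(padded, params.lsw)
    out, _, _ = _forward_batch(params.to_vector(), X, params.lsw, params.nhn)
    return measured.with_values(out, role="deconvolved")
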