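"""Leaky echo state network with a ridge-regression readout.

The reservoir is a sparse random matrix rescaled to a prescribed spectral
radius; the dense input weights have magnitudes drawn from a fixed interval.
States follow an explicit Euler discretization (one step per sample) of

    dq = (1/tau) * (-gamma * q + tanh(C q + F x)) dt + d(noise)

and the only trained parameters are the linear output weights W, obtained by
(pseudo-inverse or ridge-regularized) least squares over the concatenated
usable state columns of all training series. State noise is applied during
training only and switched off for prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.linalg

logger = logging.getLogger(__name__)

_FORMAT_VERSION = 1


@dataclass
class EsnConfig:
    """Hyperparameters of the echo state network."""

    n_nodes: int = 1000
    spectral_radius: float = 0.5
    density: float = 0.05
    input_weight_low: float = 0.1
    input_weight_high: float = 0.5
    input_sign_symmetric: bool = True
    tau: float = 1.0
    gamma: float = 0.5
    noise_scale: float = 1e-4
    ridge_lambda: float = 0.0
    seed: int = 0
    n_inputs: int = 3

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if not self.spectral_radius > 0:
            raise ValueError("spectral_radius must be > 0")
        if not 0 < self.density <= 1:
            raise ValueError("density must be in (0, 1]")
        if not 0 < self.gamma <= 1:
            raise ValueError("gamma must be in (0, 1]")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if self.ridge_lambda < 0:
            raise ValueError("ridge_lambda must be >= 0")
        if self.input_weight_high < self.input_weight_low:
            raise ValueError("input weight interval is empty")


@dataclass
class EchoStateNetwork:
    """Reservoir connectivity, input weights and (once trained) readout."""

    C: scipy.sparse.csr_matrix
    F_in: np.ndarray
    config: EsnConfig
    W: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return self.config.n_nodes

    @property
    def trained(self) -> bool:
        return self.W is not None


@dataclass
class StateMatrix:
    """All reservoir states for one input sequence (columns q_1 ... q_T)."""

    Q: np.ndarray
    q0: np.ndarray

    @property
    def n_steps(self) -> int:
        return self.Q.shape[1]


def _leading_eigenvalue_magnitude(C: scipy.sparse.spmatrix) -> float:
    """Magnitude of the leading eigenvalue. Sparse Arnoldi with several
    Ritz values for large matrices (a single Ritz pair is unreliable when
    the top eigenvalues are closely spaced), dense otherwise."""
    n = C.shape[0]
    if n <= 400:
        return float(np.max(np.abs(np.linalg.eigvals(C.toarray()))))
    v0 = np.ones(n) / np.sqrt(n)
    try:
        vals = scipy.sparse.linalg.eigs(
            C, k=8, which="LM", v0=v0, return_eigenvectors=False, maxiter=5000, tol=0
        )
        return float(np.max(np.abs(vals)))
    except scipy.sparse.linalg.ArpackNoConvergence:  # pragma: no cover
        return float(np.max(np.abs(np.linalg.eigvals(C.toarray()))))


def init_network(config: EsnConfig) -> EchoStateNetwork:
    """Draw a reservoir and input weights, fully determined by the seed.

    Nonzero reservoir positions are Bernoulli(density) with uniform(-1, 1)
    values, then the whole matrix is rescaled so its leading eigenvalue has
    magnitude ``spectral_radius`` exactly. Input weight magnitudes are
    uniform on [low, high], with random signs unless disabled.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_nodes
    C = None
    for _ in range(2):
        mask = rng.random((n, n)) < config.density
        if not mask.any():
            continue
        values = rng.uniform(-1.0, 1.0, size=int(mask.sum()))
        rows, cols = np.nonzero(mask)
        cand = scipy.sparse.csr_matrix((values, (rows, cols)), shape=(n, n))
        lam = _leading_eigenvalue_magnitude(cand)
        if lam > 0:
            C = cand * (config.spectral_radius / lam)
            # the estimate can be slightly off for closely spaced leading
            # eigenvalues; verify and correct until exact
            for _ in range(5):
                check = _leading_eigenvalue_magnitude(C)
                if abs(check - config.spectral_radius) <= 1e-10:
                    break
                C = C * (config.spectral_radius / check)
            break
    if C is None:
        raise ValueError("degenerate reservoir (all-zero connectivity after redraw)")
    F_in = rng.uniform(config.input_weight_low, config.input_weight_high, size=(n, config.n_inputs))
    if config.input_sign_symmetric:
        F_in = F_in * rng.choice([-1.0, 1.0], size=F_in.shape)
    return EchoStateNetwork(C=C, F_in=F_in, config=config)


def run_states(
    esn: EchoStateNetwork,
    x: np.ndarray,
    q0: np.ndarray | None = None,
    noise_on: bool = False,
    rng: np.random.Generator | None = None,
) -> StateMatrix:
    """Propagate the reservoir over an input sequence.

    One explicit Euler step per sample:

        q_{t+1} = (1 - gamma/tau) q_t + (1/tau) tanh(C q_t + F x_{t+1}) + eps u_t

    with ``u_t`` i.i.d. uniform(-1, 1) per node when ``noise_on`` and eps the
    configured noise scale (zero otherwise).
    """
    from .preprocess import NetworkInput

    if isinstance(x, NetworkInput):
        x = x.x
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] != esn.F_in.shape[1]:
        raise ValueError(f"input must have {esn.F_in.shape[1]} rows")
    n = esn.n_nodes
    cfg = esn.config
    if q0 is None:
        q0 = np.zeros(n)
    q0 = np.asarray(q0, dtype=float)
    if q0.shape != (n,):
        raise ValueError("q0 has wrong length")
    T = x.shape[1]
    drive = esn.F_in @ x  # (n, T)
    if noise_on and cfg.noise_scale > 0:
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        noise = cfg.noise_scale * rng.uniform(-1.0, 1.0, size=(n, T))
    else:
        noise = None
    keep = 1.0 - cfg.gamma / cfg.tau
    gain = 1.0 / cfg.tau
    Q = np.empty((n, T))
    q = q0.copy()
    C = esn.C
    for t in range(T):
        pre = C.dot(q)
        pre += drive[:, t]
        np.tanh(pre, out=pre)
        q = keep * q + gain * pre
        if noise is not None:
            q += noise[:, t]
        Q[:, t] = q
    if not np.isfinite(Q).all():
        bad = int(np.argmax(~np.isfinite(Q).all(axis=0)))
        raise FloatingPointError(f"non-finite reservoir state at step {bad}")
    return StateMatrix(Q=Q, q0=q0)


def fit_readout(
    states: Sequence[StateMatrix | np.ndarray],
    targets: Sequence[np.ndarray],
    masks: Sequence[np.ndarray] | None = None,
    ridge_lambda: float = 0.0,
) -> tuple[np.ndarray, float]:
    """Fit the linear readout over concatenated state/target series.

    Columns whose mask entry is ``False`` are dropped before concatenation.
    With ``ridge_lambda == 0`` the minimum-norm least-squares (pseudo-inverse)
    solution is returned; otherwise the regularized normal equations
    ``W = (Q Q^T + lambda I)^{-1} Q z^T`` are solved.

    Returns ``(W, training_residual_rms)``.
    """
    if len(states) != len(targets):
        raise ValueError("states and targets must have equal length")
    if masks is not None and len(masks) != len(states):
        raise ValueError("masks must match states")
    qs, zs = [], []
    for i, (S, z) in enumerate(zip(states, targets)):
        Q = S.Q if isinstance(S, StateMatrix) else np.asarray(S, dtype=float)
        z = np.asarray(z, dtype=float).ravel()
        if Q.shape[1] != z.shape[0]:
            raise ValueError(f"series {i}: state and target lengths differ")
        if masks is not None:
            m = np.asarray(masks[i], dtype=bool)
            if m.shape[0] != z.shape[0]:
                raise ValueError(f"series {i}: mask length mismatch")
            Q, z = Q[:, m], z[m]
        qs.append(Q)
        zs.append(z)
    Qc = np.hstack(qs) if qs else np.empty((0, 0))
    zc = np.concatenate(zs) if zs else np.empty(0)
    n, k = Qc.shape
    if k == 0:
        raise ValueError("no usable training columns")
    if k < n:
        logger.warning("only %d usable columns for %d nodes; readout is underdetermined", k, n)
    if ridge_lambda > 0:
        G = Qc @ Qc.T + ridge_lambda * np.eye(n)
        w = scipy.linalg.solve(G, Qc @ zc, assume_a="pos")
    else:
        G = Qc @ Qc.T
        try:
            cho = scipy.linalg.cho_factor(G)
            w = scipy.linalg.cho_solve(cho, Qc @ zc)
        except scipy.linalg.LinAlgError:
            w, *_ = scipy.linalg.lstsq(Qc.T, zc)
    residual = float(np.sqrt(np.mean((zc - w @ Qc) ** 2)))
    return w, residual


def predict_grf(
    esn: EchoStateNetwork, x: np.ndarray, q0: np.ndarray | None = None
) -> np.ndarray:
    """Predict the z-scored force waveform ``y = W q`` (noise off)."""
    if esn.W is None:
        raise ValueError("readout not trained")
    Q = run_states(esn, x, q0=q0, noise_on=False).Q
    return esn.W @ Q


def save_network(esn: EchoStateNetwork, path: str | Path) -> None:
    """Serialize a (trained) network to a single archive file."""
    coo = esn.C.tocoo()
    cfg = esn.config
    np.savez(
        path,
        format_version=_FORMAT_VERSION,
        c_row=coo.row,
        c_col=coo.col,
        c_data=coo.data,
        n_nodes=cfg.n_nodes,
        F_in=esn.F_in,
        W=esn.W if esn.W is not None else np.empty(0),
        config_json=np.frombuffer(
            _config_to_json(cfg).encode("utf-8"), dtype=np.uint8
        ),
    )


def load_network(path: str | Path) -> EchoStateNetwork:
    with np.load(path) as data:
        if int(data["format_version"]) != _FORMAT_VERSION:
            raise ValueError("unsupported network archive version")
        cfg = _config_from_json(bytes(data["config_json"]).decode("utf-8"))
        n = int(data["n_nodes"])
        C = scipy.sparse.csr_matrix(
            (data["c_data"], (data["c_row"], data["c_col"])), shape=(n, n)
        )
        W = data["W"]
        return EchoStateNetwork(
            C=C, F_in=data["F_in"], config=cfg, W=None if W.size == 0 else W
        )


def _config_to_json(cfg: EsnConfig) -> str:
    import dataclasses
    import json

    return json.dumps(dataclasses.asdict(cfg))


def _config_from_json(text: str) -> EsnConfig:
    import json

    return EsnConfig(**json.loads(text))
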