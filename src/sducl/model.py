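"""GCN autoencoder with signal-diffusion contrastive learning.

The representation learner couples two objectives on the fused feature
matrix F and spot graph:

* a two-layer GCN encoder (d → hidden → embed, ReLU) with a mirrored GCN
  decoder whose reconstruction loss L_rec = (1/N) Σ_i ||f_i − x_i||² keeps
  embeddings faithful to the input;
* a Deep-Graph-Infomax-style contrastive loss: each node's embedding h_i is
  scored against its microenvironment summary S_i (sigmoid of the mean
  embedding over its diffusion-selected members) by a bilinear discriminator
  D(h, s) = σ(hᵀ W s).  Positives pair h_i with S_i; negatives pair the
  embedding h′_i of a row-shuffled ("corrupted") feature matrix — topology
  unchanged — with the same S_i.  A symmetric term swaps the roles of the
  clean and corrupted branches.

Total loss L = α_rec·L_rec + β_con·(L_con + L_con′), minimized full-batch
with Adam.  The whole network and its gradients are written directly in
NumPy; gradient correctness is pinned by finite-difference tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .diffusion import MicroenvironmentMap

__all__ = [
    "TrainConfig",
    "SDUCLModel",
    "EmbeddingResult",
    "gcn_layer",
    "corrupt",
    "readout",
    "discriminate",
    "contrastive_loss",
    "reconstruction_loss",
    "train",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softplus(x: np.ndarray) -> np.ndarray:
    # log(1 + e^x), overflow-safe
    return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))


# ---------------------------------------------------------------------------
# Elementary operations (each independently testable)
# ---------------------------------------------------------------------------


def gcn_layer(
    H_in: np.ndarray,
    A_hat_norm: np.ndarray,
    W: np.ndarray,
    b: np.ndarray,
    activation: str = "relu",
) -> np.ndarray:
    """One graph-convolution layer: act(Â_norm · H · W + b)."""
    pre = A_hat_norm @ H_in @ W + b
    if activation == "relu":
        return np.maximum(pre, 0.0)
    if activation in (None, "linear"):
        return pre
    raise ValueError(f"unknown activation {activation!r}")


def corrupt(F: np.ndarray, graph, rng: np.random.Generator):
    """Corruption for contrastive negatives: shuffle feature rows, keep
    topology.  Returns (F_permuted, graph) and the permutation used."""
    perm = rng.permutation(F.shape[0])
    return F[perm], graph, perm


def readout(H: np.ndarray, me: MicroenvironmentMap | np.ndarray) -> np.ndarray:
    """Microenvironment summaries S[i] = sigmoid(mean of H over members(i)).

    Accepts either a :class:`MicroenvironmentMap` or a precomputed
    row-stochastic membership matrix M, in which case S = sigmoid(M·H).
    """
    M = me.membership_matrix() if isinstance(me, MicroenvironmentMap) else me
    return _sigmoid(M @ H)


def discriminate(
    h: np.ndarray, s: np.ndarray, W_disc: np.ndarray, return_logit: bool = False
):
    """Bilinear discriminator D(h, s) = σ(hᵀ W s), row-wise for matrices."""
    h = np.atleast_2d(h)
    s = np.atleast_2d(s)
    logit = np.einsum("ij,jk,ik->i", h, W_disc, s)
    if h.shape[0] == 1:
        logit = logit[0]
    return logit if return_logit else _sigmoid(np.asarray(logit))


def contrastive_loss(
    H: np.ndarray,
    H_prime: np.ndarray,
    S: np.ndarray,
    S_prime: np.ndarray,
    W_disc: np.ndarray,
) -> Tuple[float, float]:
    """The pair of DGI-style binary cross-entropy losses.

    L_con scores (h_i, S_i) as positives against (h′_i, S_i) negatives;
    the symmetric term L_con′ scores (h′_i, S′_i) against (h_i, S′_i).
    Both use the logit-stable softplus form of the cross-entropy.
    """
    HW = H @ W_disc
    HpW = H_prime @ W_disc
    z_pos = np.sum(HW * S, axis=1)
    z_neg = np.sum(HpW * S, axis=1)
    z_pos_sym = np.sum(HpW * S_prime, axis=1)
    z_neg_sym = np.sum(HW * S_prime, axis=1)
    l_con = 0.5 * float(np.mean(_softplus(-z_pos) + _softplus(z_neg)))
    l_sym = 0.5 * float(np.mean(_softplus(-z_pos_sym) + _softplus(z_neg_sym)))
    return l_con, l_sym


def reconstruction_loss(F: np.ndarray, X_rec: np.ndarray) -> float:
    """Mean-per-spot squared reconstruction error (1/N) Σ_i ||f_i − x_i||²."""
    diff = F - X_rec
    return float(np.sum(diff * diff) / F.shape[0])


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    """Hyperparameters of the representation learner."""

    hidden_dim: int = 512
    embed_dim: int = 64
    epochs: int = 500
    lr: float = 1e-3
    weight_decay: float = 1e-4
    alpha_rec: float = 1.0   # weight of the reconstruction loss
    beta_con: float = 1.0    # weight of the contrastive pair
    rec_reduction: str = "mean"  # "mean" (per spot) or "sum"
    seed: int = 0
    dtype: str = "float64"


@dataclass
class EmbeddingResult:
    """Learned representations and the training trace."""

    H: np.ndarray            # (N, embed) local embeddings
    S: np.ndarray            # (N, embed) microenvironment summaries, in (0,1)
    losses: List[Dict[str, float]] = field(default_factory=list)

    def loss_frame(self):
        import pandas as pd

        return pd.DataFrame(self.losses)


class SDUCLModel:
    """Encoder/decoder/discriminator weights plus the Adam training loop."""

    _WEIGHTS = ("W1", "W2", "W3", "W4", "Wd")

    def __init__(self, in_dim: int, config: Optional[TrainConfig] = None):
        self.config = config or TrainConfig()
        self.in_dim = in_dim
        if self.config.alpha_rec == 0 and self.config.beta_con == 0:
            raise ValueError(
                "alpha_rec and beta_con are both zero: no training signal"
            )
        self.rng = np.random.default_rng(self.config.seed)
        self._init_params()

    # -- parameters -----------------------------------------------------
    def _glorot(self, fan_in: int, fan_out: int) -> np.ndarray:
        a = np.sqrt(6.0 / (fan_in + fan_out))
        return self.rng.uniform(-a, a, size=(fan_in, fan_out)).astype(
            self.config.dtype
        )

    def _init_params(self) -> None:
        d, h, e = self.in_dim, self.config.hidden_dim, self.config.embed_dim
        dt = self.config.dtype
        self.params: Dict[str, np.ndarray] = {
            "W1": self._glorot(d, h), "b1": np.zeros(h, dtype=dt),
            "W2": self._glorot(h, e), "b2": np.zeros(e, dtype=dt),
            "W3": self._glorot(e, h), "b3": np.zeros(h, dtype=dt),
            "W4": self._glorot(h, d), "b4": np.zeros(d, dtype=dt),
            "Wd": self._glorot(e, e),
        }

    # -- forward pieces -------------------------------------------------
    def encode(self, F: np.ndarray, A: np.ndarray) -> np.ndarray:
        p = self.params
        H1 = gcn_layer(F, A, p["W1"], p["b1"], "relu")
        return gcn_layer(H1, A, p["W2"], p["b2"], "relu")

    def decode(self, H: np.ndarray, A: np.ndarray) -> np.ndarray:
        p = self.params
        D1 = gcn_layer(H, A, p["W3"], p["b3"], "relu")
        return gcn_layer(D1, A, p["W4"], p["b4"], "linear")

    # -- loss + gradients ----------------------------------------------
    def loss_and_grads(
        self,
        F: np.ndarray,
        A: np.ndarray,
        M: np.ndarray,
        perm: np.ndarray,
        AF: Optional[np.ndarray] = None,
    ) -> Tuple[Dict[str, float], Dict[str, np.ndarray]]:
        """Full forward pass and analytic gradients for one epoch.

        ``A`` is the normalized adjacency, ``M`` the row-stochastic
        microenvironment membership operator, ``perm`` the corruption
        permutation; ``AF`` optionally caches A·F across epochs.
        """
        cfg = self.config
        p = self.params
        N = F.shape[0]
        a_rec, b_con = cfg.alpha_rec, cfg.beta_con
        rec_scale = 1.0 if cfg.rec_reduction == "sum" else 1.0 / N

        if AF is None:
            AF = A @ F

        # encoder, clean branch
        P1 = AF @ p["W1"] + p["b1"]
        H1 = np.maximum(P1, 0.0)
        AH1 = A @ H1
        P2 = AH1 @ p["W2"] + p["b2"]
        H = np.maximum(P2, 0.0)

        grads = {k: np.zeros_like(v) for k, v in p.items()}
        losses: Dict[str, float] = {}
        dH = np.zeros_like(H)

        # reconstruction branch
        if a_rec != 0:
            AH = A @ H
            P3 = AH @ p["W3"] + p["b3"]
            D1 = np.maximum(P3, 0.0)
            AD1 = A @ D1
            X = AD1 @ p["W4"] + p["b4"]
            diff = X - F
            losses["L_rec"] = float(np.sum(diff * diff) * rec_scale)
            dX = (2.0 * a_rec * rec_scale) * diff
            grads["W4"] += AD1.T @ dX
            grads["b4"] += dX.sum(axis=0)
            dD1 = A @ (dX @ p["W4"].T)
            dP3 = dD1 * (P3 > 0)
            grads["W3"] += AH.T @ dP3
            grads["b3"] += dP3.sum(axis=0)
            dH += A @ (dP3 @ p["W3"].T)
        else:
            losses["L_rec"] = float("nan")

        # contrastive branch
        if b_con != 0:
            Fp = F[perm]
            AFp = A @ Fp
            P1p = AFp @ p["W1"] + p["b1"]
            H1p = np.maximum(P1p, 0.0)
            AH1p = A @ H1p
            P2p = AH1p @ p["W2"] + p["b2"]
            Hp = np.maximum(P2p, 0.0)

            MH = M @ H
            S = _sigmoid(MH)
            MHp = M @ Hp
            Sp = _sigmoid(MHp)

            HW = H @ p["Wd"]
            HpW = Hp @ p["Wd"]
            z1 = np.sum(HW * S, axis=1)    # positives (h, S)
            z2 = np.sum(HpW * S, axis=1)   # negatives (h', S)
            z3 = np.sum(HpW * Sp, axis=1)  # sym positives (h', S')
            z4 = np.sum(HW * Sp, axis=1)   # sym negatives (h, S')
            l_con = 0.5 * float(np.mean(_softplus(-z1) + _softplus(z2)))
            l_sym = 0.5 * float(np.mean(_softplus(-z3) + _softplus(z4)))
            losses["L_con"] = l_con
            losses["L_con_sym"] = l_sym

            c = b_con / (2.0 * N)
            g1 = (_sigmoid(z1) - 1.0) * c
            g2 = _sigmoid(z2) * c
            g3 = (_sigmoid(z3) - 1.0) * c
            g4 = _sigmoid(z4) * c

            GS = g1[:, None] * S + g4[:, None] * Sp
            GSp = g2[:, None] * S + g3[:, None] * Sp
            grads["Wd"] += H.T @ GS + Hp.T @ GSp
            dH += GS @ p["Wd"].T
            dHp = GSp @ p["Wd"].T
            dS = g1[:, None] * HW + g2[:, None] * HpW
            dSp = g3[:, None] * HpW + g4[:, None] * HW
            dH += M.T @ (dS * S * (1.0 - S))
            dHp += M.T @ (dSp * Sp * (1.0 - Sp))

            # corrupted-encoder backprop
            dP2p = dHp * (P2p > 0)
            grads["W2"] += AH1p.T @ dP2p
            grads["b2"] += dP2p.sum(axis=0)
            dH1p = A @ (dP2p @ p["W2"].T)
            dP1p = dH1p * (P1p > 0)
            grads["W1"] += AFp.T @ dP1p
            grads["b1"] += dP1p.sum(axis=0)
        else:
            losses["L_con"] = float("nan")
            losses["L_con_sym"] = float("nan")

        # clean-encoder backprop
        dP2 = dH * (P2 > 0)
        grads["W2"] += AH1.T @ dP2
        grads["b2"] += dP2.sum(axis=0)
        dH1 = A @ (dP2 @ p["W2"].T)
        dP1 = dH1 * (P1 > 0)
        grads["W1"] += AF.T @ dP1
        grads["b1"] += dP1.sum(axis=0)

        total = a_rec * (losses["L_rec"] if a_rec != 0 else 0.0)
        if b_con != 0:
            total += b_con * (losses["L_con"] + losses["L_con_sym"])
        losses["L"] = float(total)
        return losses, grads

    # -- training -------------------------------------------------------
    def fit(
        self,
        F: np.ndarray,
        A_hat_norm: np.ndarray,
        me: MicroenvironmentMap,
        verbose: bool = False,
    ) -> EmbeddingResult:
        """Full-batch Adam training; returns the final embeddings.

        Each epoch draws a fresh corruption permutation from the run's
        seeded generator, so the whole trajectory is deterministic given
        the config seed.
        """
        cfg = self.config
        dt = cfg.dtype
        F = np.ascontiguousarray(F, dtype=dt)
        A = np.ascontiguousarray(A_hat_norm, dtype=dt)
        M = np.ascontiguousarray(me.membership_matrix(), dtype=dt)
        AF = A @ F

        m_state = {k: np.zeros_like(v) for k, v in self.params.items()}
        v_state = {k: np.zeros_like(v) for k, v in self.params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        trace: List[Dict[str, float]] = []

        for epoch in range(1, cfg.epochs + 1):
            perm = self.rng.permutation(F.shape[0])
            losses, grads = self.loss_and_grads(F, A, M, perm, AF=AF)
            if not np.isfinite(losses["L"]):
                bad = [k for k, v in losses.items() if not np.isfinite(v)]
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {bad} diverged"
                )
            for k in self._WEIGHTS:  # L2 regularization on weight matrices
                grads[k] += cfg.weight_decay * self.params[k]
            for k, g in grads.items():
                m_state[k] = beta1 * m_state[k] + (1 - beta1) * g
                v_state[k] = beta2 * v_state[k] + (1 - beta2) * g * g
                m_hat = m_state[k] / (1 - beta1 ** epoch)
                v_hat = v_state[k] / (1 - beta2 ** epoch)
                self.params[k] -= cfg.lr * m_hat / (np.sqrt(v_hat) + eps)
            trace.append({"epoch": epoch, **losses})
            if verbose and (epoch == 1 or epoch % 50 == 0):
                print(
                    f"epoch {epoch:4d}  L={losses['L']:.4f}  "
                    f"L_rec={losses['L_rec']:.4f}  L_con={losses['L_con']:.4f}"
                )

        H = self.encode(F, A)
        S = _sigmoid(M @ H)
        return EmbeddingResult(H=H, S=S, losses=trace)


def train(
    features, graph, me: MicroenvironmentMap, config: Optional[TrainConfig] = None,
    verbose: bool = False,
) -> Tuple[SDUCLModel, EmbeddingResult]:
    """Train a fresh model on prepared inputs.

    ``features`` is an :class:`~sducl.features.AugmentedFeatures` (or a bare
    matrix), ``graph`` the :class:`~sducl.graph.SpatialGraph`, ``me`` the
    microenvironment map computed from the uncorrupted topology.
    """
    F = features.F if hasattr(features, "F") else np.asarray(features)
    model = SDUCLModel(in_dim=F.shape[1], config=config)
    result = model.fit(F, graph.A_hat_norm, me, verbose=verbose)
    return model, result
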