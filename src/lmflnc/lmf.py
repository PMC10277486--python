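"""Logistic matrix factorization with dual local-spectral regularization.

Each metabolite ``i`` and disease ``j`` receives a latent vector (rows of
``U`` and ``V``); an interaction is Bernoulli with probability
``sigmoid(u_i . v_j)``. Observed interactions are up-weighted by an
importance factor ``c >= 1``. Two penalties are subtracted from the
log-likelihood: a Frobenius ridge ``alpha/2 (||U||_F^2 + ||V||_F^2)`` and a
local-neighbourhood term ``lambda/2 (tr(U^T vir_u U) + tr(V^T vir_v V))``
built from the Vicus matrices of the metabolite and disease similarity
networks, which pulls the latent vectors of locally similar nodes together.

Training minimizes the negative penalized log-likelihood by full-batch
AdaGrad from a seeded Gaussian initialization.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit as _sigmoid
from sklearn.base import BaseEstimator

from .containers import InteractionMatrix
from .vicus import VicusMatrix

__all__ = [
    "interaction_probability",
    "objective",
    "gradient_U",
    "gradient_V",
    "LMFLNC",
    "TrainingDivergedError",
]


class TrainingDivergedError(RuntimeError):
    pass


def _log1pexp(x: np.ndarray) -> np.ndarray:
    # log(1 + e^x) without overflow
    return np.logaddexp(0.0, x)


def interaction_probability(u: np.ndarray, v: np.ndarray) -> float:
    """Interaction probability ``sigmoid(u . v)`` of one latent pair."""
    return float(_sigmoid(float(np.dot(np.ravel(u), np.ravel(v)))))


def _as_array(A) -> np.ndarray:
    if isinstance(A, InteractionMatrix):
        return A.values
    return np.asarray(A, dtype=float)


def _reg_matrix(vir, n: int) -> np.ndarray | None:
    if vir is None:
        return None
    M = vir.vir if isinstance(vir, VicusMatrix) else np.asarray(vir, dtype=float)
    if M.shape != (n, n):
        raise ValueError(f"regularizer shape {M.shape} does not match {n} nodes")
    return M


def objective(U: np.ndarray, V: np.ndarray, A, vir_u=None, vir_v=None, *,
              c: float = 2.0, alpha_reg: float = 4.0,
              lambda_nbr: float = 8.0) -> float:
    """Penalized Bernoulli log-likelihood (both penalties subtracted).

    Larger is better; training minimizes its negation. With ``c = 1`` and
    both penalties zero this is exactly the plain logistic-MF
    log-likelihood ``sum A log p + (1 - A) log(1 - p)``.
    """
    A = _as_array(A)
    n, m = A.shape
    if U.shape[0] != n or V.shape[0] != m or U.shape[1] != V.shape[1]:
        raise ValueError(
            f"shape mismatch: A {A.shape}, U {U.shape}, V {V.shape}")
    X = U @ V.T
    ll = float(np.sum(c * A * X - (1.0 + c * A - A) * _log1pexp(X)))
    pen = 0.5 * alpha_reg * (np.sum(U * U) + np.sum(V * V))
    Ru = _reg_matrix(vir_u, n)
    Rv = _reg_matrix(vir_v, m)
    if Ru is not None:
        pen += 0.5 * lambda_nbr * float(np.sum(U * (Ru @ U)))
    if Rv is not None:
        pen += 0.5 * lambda_nbr * float(np.sum(V * (Rv @ V)))
    return ll - pen


def gradient_U(U, V, A, vir_u=None, *, c: float = 2.0, alpha_reg: float = 4.0,
               lambda_nbr: float = 8.0) -> np.ndarray:
    """Gradient of the negative penalized log-likelihood w.r.t. ``U``:
    ``P V + (c-1)(A o P) V - c A V + (alpha I + lambda vir_u) U``."""
    A = _as_array(A)
    P = _sigmoid(U @ V.T)
    G = P @ V + (c - 1.0) * (A * P) @ V - c * A @ V + alpha_reg * U
    Ru = _reg_matrix(vir_u, A.shape[0])
    if Ru is not None:
        G = G + lambda_nbr * (Ru @ U)
    return G


def gradient_V(U, V, A, vir_v=None, *, c: float = 2.0, alpha_reg: float = 4.0,
               lambda_nbr: float = 8.0) -> np.ndarray:
    """Gradient of the negative penalized log-likelihood w.r.t. ``V``."""
    A = _as_array(A)
    P = _sigmoid(U @ V.T)
    G = P.T @ U + (c - 1.0) * (A * P).T @ U - c * A.T @ U + alpha_reg * V
    Rv = _reg_matrix(vir_v, A.shape[1])
    if Rv is not None:
        G = G + lambda_nbr * (Rv @ V)
    return G


class LMFLNC(BaseEstimator):
    """Logistic matrix factorization with local-neighbourhood constraints.

    Parameters
    ----------
    r : int, default=50
        Latent dimension; must satisfy ``r <= min(n, m)``.
    c : float, default=2.0
        Importance level of observed interactions (each positive counts as
        ``c`` observations in the likelihood).
    alpha_reg : float, default=4.0
        Frobenius-norm (ridge) penalty weight on the latent matrices.
    lambda_nbr : float, default=8.0
        Weight of the local-spectral (Vicus) penalty.
    learning_rate : float, default=0.01
        AdaGrad base step size.
    max_iter : int, default=1000
        Maximum number of full-batch gradient iterations.
    tol : float, default=1e-6
        Stop when the relative loss change over ``tol_window`` iterations
        falls below this.
    tol_window : int, default=10
        Window length for the stopping rule.
    binarize_weights : bool, default=False
        Use the binarized matrix (``A > 0``) inside the likelihood weights
        instead of the smoothed real values.
    random_state : int, default=0
        Seed for the Gaussian ``N(0, 1/r)`` initialization of ``U`` and
        ``V``; identical seeds and inputs give bitwise-identical factors.

    Attributes
    ----------
    U_ : ndarray of shape (n_metabolites, r)
    V_ : ndarray of shape (n_diseases, r)
    loss_trace_ : ndarray
        Negative penalized log-likelihood per iteration.
    n_iter_ : int
    """

    def __init__(self, r: int = 50, c: float = 2.0, alpha_reg: float = 4.0,
                 lambda_nbr: float = 8.0, learning_rate: float = 0.01,
                 max_iter: int = 1000, tol: float = 1e-6,
                 tol_window: int = 10, eps: float = 1e-8,
                 binarize_weights: bool = False, random_state: int = 0):
        self.r = r
        self.c = c
        self.alpha_reg = alpha_reg
        self.lambda_nbr = lambda_nbr
        self.learning_rate = learning_rate
        self.max_iter = max_iter
        self.tol = tol
        self.tol_window = tol_window
        self.eps = eps
        self.binarize_weights = binarize_weights
        self.random_state = random_state

    def _validate(self, A: np.ndarray) -> None:
        if self.c < 1:
            raise ValueError("c must be >= 1")
        if self.alpha_reg < 0 or self.lambda_nbr < 0:
            raise ValueError("penalty weights must be nonnegative")
        n, m = A.shape
        if not 1 <= self.r <= min(n, m):
            raise ValueError(
                f"latent dimension r={self.r} must satisfy 1 <= r <= "
                f"min(n, m) = {min(n, m)}")

    def fit(self, A, vir_u=None, vir_v=None) -> "LMFLNC":
        """Fit latent factors to an interaction matrix.

        Parameters
        ----------
        A : InteractionMatrix or array of shape (n, m)
            (Smoothed) interaction matrix with values in [0, 1].
        vir_u, vir_v : VicusMatrix, array or None
            Local spectral regularizers for metabolites and diseases; pass
            ``None`` (or set ``lambda_nbr=0``) to disable.
        """
        Amat = _as_array(A)
        self._validate(Amat)
        if self.binarize_weights:
            Amat = (Amat > 0).astype(float)
        n, m = Amat.shape
        Ru = _reg_matrix(vir_u, n)
        Rv = _reg_matrix(vir_v, m)
        kwargs = dict(c=self.c, alpha_reg=self.alpha_reg,
                      lambda_nbr=self.lambda_nbr)
        rng = np.random.default_rng(self.random_state)
        scale = 1.0 / np.sqrt(self.r)
        U = rng.normal(0.0, scale, size=(n, self.r))
        V = rng.normal(0.0, scale, size=(m, self.r))
        Gu = np.zeros_like(U)
        Gv = np.zeros_like(V)
        losses = [-objective(U, V, Amat, Ru, Rv, **kwargs)]
        for it in range(self.max_iter):
            gu = gradient_U(U, V, Amat, Ru, **kwargs)
            gv = gradient_V(U, V, Amat, Rv, **kwargs)
            Gu += gu * gu
            Gv += gv * gv
            U = U - self.learning_rate * gu / (np.sqrt(Gu) + self.eps)
            V = V - self.learning_rate * gv / (np.sqrt(Gv) + self.eps)
            loss = -objective(U, V, Amat, Ru, Rv, **kwargs)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at iteration {it + 1} "
                    f"(learning_rate={self.learning_rate})")
            losses.append(loss)
            w = self.tol_window
            if it + 1 >= w:
                prev, cur = losses[-w - 1], losses[-1]
                denom = max(abs(prev), 1.0)
                if abs(prev - cur) / denom < self.tol:
                    break
        self.U_ = U
        self.V_ = V
        self.loss_trace_ = np.asarray(losses)
        self.n_iter_ = len(losses) - 1
        if isinstance(A, InteractionMatrix):
            self.metabolite_ids_ = list(A.metabolite_ids)
            self.disease_ids_ = list(A.disease_ids)
        return self

    def predict_proba_matrix(self, U: np.ndarray | None = None,
                             V: np.ndarray | None = None) -> np.ndarray:
        """Full matrix of interaction probabilities ``sigmoid(U V^T)``."""
        U = self.U_ if U is None else U
        V = self.V_ if V is None else V
        return np.asarray(_sigmoid(U @ V.T), dtype=float)

    # -- checkpoint persistence -------------------------------------------

    def save_checkpoint(self, path) -> None:
        """Write a flat text checkpoint: a header line with the shapes and
        hyperparameters, then the rows of ``U`` and ``V`` as TSV."""
        n, r = self.U_.shape
        m = self.V_.shape[0]
        with open(path, "w") as fh:
            fh.write(f"#lmflnc-checkpoint\tn={n}\tm={m}\tr={r}\t"
                     f"c={self.c}\talpha_reg={self.alpha_reg}\t"
                     f"lambda_nbr={self.lambda_nbr}\t"
                     f"random_state={self.random_state}\n")
            ids = getattr(self, "metabolite_ids_",
                          [str(i) for i in range(n)])
            for i in range(n):
                row = "\t".join(format(x, ".17g") for x in self.U_[i])
                fh.write(f"U\t{ids[i]}\t{row}\n")
            ids = getattr(self, "disease_ids_", [str(j) for j in range(m)])
            for j in range(m):
                row = "\t".join(format(x, ".17g") for x in self.V_[j])
                fh.write(f"V\t{ids[j]}\t{row}\n")

    @classmethod
    def load_checkpoint(cls, path) -> "LMFLNC":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if not header or header[0] != "#lmflnc-checkpoint":
                raise ValueError("not an lmflnc checkpoint file")
            meta = dict(tok.split("=", 1) for tok in header[1:])
            model = cls(r=int(meta["r"]), c=float(meta["c"]),
                        alpha_reg=float(meta["alpha_reg"]),
                        lambda_nbr=float(meta["lambda_nbr"]),
                        random_state=int(meta["random_state"]))
            u_rows, v_rows, u_ids, v_ids = [], [], [], []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                (u_rows if parts[0] == "U" else v_rows).append(
                    [float(x) for x in parts[2:]])
                (u_ids if parts[0] == "U" else v_ids).append(parts[1])
        model.U_ = np.asarray(u_rows)
        model.V_ = np.asarray(v_rows)
        model.metabolite_ids_ = u_ids
        model.disease_ids_ = v_ids
        return model
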