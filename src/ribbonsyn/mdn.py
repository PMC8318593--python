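"""Mixture-density network and Gaussian-mixture distributions.

A small fully connected network maps a scalar conditioning value (here the
relevant loss of a simulation) to the parameters of a Gaussian mixture over
the normalised model parameters: mixture logits, component means and
full covariances via a lower-triangular precision-Cholesky factor whose
diagonal is kept positive through an exponential map. The network is written
directly in numpy with analytic gradients (the architecture is tiny — two
hidden tanh layers of 120 units — so no autodiff framework is needed); the
gradients are verified against finite differences in the test suite.

Training minimises the weighted negative log-likelihood

    -(1/sum w) * sum_i w_i * log sum_c pi_c(x_i) N(theta_i; mu_c(x_i), Sigma_c(x_i))

with Adam and global gradient-norm clipping. Evaluating the network at a
fixed conditioning value yields a :class:`GaussianMixture` posterior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class GaussianMixture:
    """A finite mixture of full-covariance Gaussians."""

    weights: np.ndarray   # (C,)
    means: np.ndarray     # (C, d)
    covs: np.ndarray      # (C, d, d)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float)
        self.weights = self.weights / self.weights.sum()
        self.means = np.atleast_2d(np.asarray(self.means, float))
        self.covs = np.asarray(self.covs, float)

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    @property
    def n_components(self) -> int:
        return self.means.shape[0]

    @classmethod
    def single(cls, mean, cov) -> "GaussianMixture":
        mean = np.atleast_1d(np.asarray(mean, float))
        cov = np.atleast_2d(np.asarray(cov, float))
        return cls(np.array([1.0]), mean[None, :], cov[None, :, :])

    def sample(self, n: int, rng) -> np.ndarray:
        rng = np.random.default_rng(rng)
        comp = rng.choice(self.n_components, size=n, p=self.weights)
        out = np.empty((n, self.dim))
        for c in range(self.n_components):
            m = comp == c
            if m.any():
                out[m] = rng.multivariate_normal(
                    self.means[c], self.covs[c], size=int(m.sum()),
                    method="cholesky")
        return out

    def log_prob(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, float))
        parts = np.empty((x.shape[0], self.n_components))
        for c in range(self.n_components):
            u = x - self.means[c]
            L = np.linalg.cholesky(self.covs[c])
            y = np.linalg.solve(L, u.T).T
            logdet = 2.0 * np.sum(np.log(np.diag(L)))
            parts[:, c] = (np.log(self.weights[c])
                           - 0.5 * (self.dim * _LOG2PI + logdet
                                    + np.sum(y ** 2, axis=1)))
        return logsumexp(parts, axis=1)

    def marginal(self, i: int) -> "GaussianMixture":
        """The 1-D marginal mixture of dimension ``i``."""
        return GaussianMixture(self.weights.copy(),
                               self.means[:, [i]],
                               self.covs[:, [i], [i]][:, :, None])

    def marginal_std(self, i: int) -> float:
        mu = self.means[:, i]
        var = self.covs[:, i, i]
        m = np.sum(self.weights * mu)
        return float(np.sqrt(np.sum(self.weights * (var + mu ** 2)) - m ** 2))

    def mean(self) -> np.ndarray:
        return self.weights @ self.means


def _tril_info(d: int):
    rows, cols = np.tril_indices(d)
    diag = np.flatnonzero(rows == cols)
    return rows, cols, diag


class MixtureDensityNetwork:
    """MDN q_phi(theta | x) with a scalar conditioning input.

    Parameters
    ----------
    dim : int
        Dimension of theta.
    n_components : int
        Number of Gaussian components (default 3).
    hidden : tuple of int
        Hidden layer widths (default (120, 120)).
    seed : int
        Initialisation seed (training is deterministic given seed and data).
    """

    def __init__(self, dim: int, n_components: int = 3,
                 hidden: tuple[int, int] = (120, 120), seed: int = 0):
        self.dim = dim
        self.C = n_components
        self.ntri = dim * (dim + 1) // 2
        self.K = self.C * (1 + dim + self.ntri)
        self._rows, self._cols, self._diag = _tril_info(dim)
        rng = np.random.default_rng(seed)
        h1, h2 = hidden
        def init(n_in, n_out):
            return rng.normal(0, np.sqrt(1.0 / n_in), size=(n_in, n_out))
        self.W1, self.b1 = init(1, h1), np.zeros(h1)
        self.W2, self.b2 = init(h1, h2), np.zeros(h2)
        self.W3, self.b3 = init(h2, self.K) * 0.1, np.zeros(self.K)
        self.x_loc, self.x_scale = 0.0, 1.0
        self.training_curve: list[float] = []

    # -- forward -----------------------------------------------------------
    def _net(self, x: np.ndarray):
        xs = ((np.asarray(x, float).reshape(-1, 1) - self.x_loc)
              / self.x_scale)
        h1 = np.tanh(xs @ self.W1 + self.b1)
        h2 = np.tanh(h1 @ self.W2 + self.b2)
        out = h2 @ self.W3 + self.b3
        return xs, h1, h2, out

    def _split(self, out: np.ndarray):
        m = out.shape[0]
        C, d, ntri = self.C, self.dim, self.ntri
        logits = out[:, :C]
        mu = out[:, C:C + C * d].reshape(m, C, d)
        traw = out[:, C + C * d:].reshape(m, C, ntri)
        A = np.zeros((m, C, d, d))
        A[:, :, self._rows, self._cols] = traw
        dg = np.exp(np.clip(traw[:, :, self._diag], -20, 20))
        A[:, :, np.arange(d), np.arange(d)] = dg
        return logits, mu, traw, A

    def _log_components(self, theta, logits, mu, traw, A):
        u = theta[:, None, :] - mu                        # (m, C, d)
        z = np.einsum("mcij,mcj->mci", A, u)
        logdet = np.clip(traw[:, :, self._diag], -20, 20).sum(axis=2)
        log_n = logdet - 0.5 * self.dim * _LOG2PI - 0.5 * (z ** 2).sum(axis=2)
        log_pi = logits - logsumexp(logits, axis=1, keepdims=True)
        return log_pi, log_n, u, z

    def log_prob(self, theta: np.ndarray, x: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(np.asarray(theta, float))
        *_, out = self._net(x)
        logits, mu, traw, A = self._split(out)
        log_pi, log_n, _, _ = self._log_components(theta, logits, mu, traw, A)
        return logsumexp(log_pi + log_n, axis=1)

    # -- loss and analytic gradients --------------------------------------
    def _loss_and_grads(self, theta, x, w):
        m = theta.shape[0]
        xs, h1, h2, out = self._net(x)
        logits, mu, traw, A = self._split(out)
        log_pi, log_n, u, z = self._log_components(theta, logits, mu, traw, A)
        joint = log_pi + log_n
        logp = logsumexp(joint, axis=1)
        wn = w / w.sum()
        loss = -float(wn @ logp)

        r = np.exp(joint - logp[:, None])                 # responsibilities
        pi = np.exp(log_pi)
        g_logits = wn[:, None] * (pi - r)                 # (m, C)
        At_z = np.einsum("mcji,mcj->mci", A, z)           # A^T z
        g_mu = -wn[:, None, None] * r[:, :, None] * At_z  # (m, C, d)
        # dlogN/dA = diag(1/A_jj) - z u^T; chain exp() through the diagonal
        M = -z[:, :, :, None] * u[:, :, None, :]          # (m, C, d, d)
        Mtril = M[:, :, self._rows, self._cols]           # (m, C, ntri)
        Adiag = A[:, :, np.arange(self.dim), np.arange(self.dim)]
        Mtril[:, :, self._diag] = 1.0 + Mtril[:, :, self._diag] * Adiag
        g_traw = -wn[:, None, None] * r[:, :, None] * Mtril

        d_out = np.concatenate(
            [g_logits, g_mu.reshape(m, -1), g_traw.reshape(m, -1)], axis=1)
        gW3 = h2.T @ d_out
        gb3 = d_out.sum(axis=0)
        dh2 = (d_out @ self.W3.T) * (1.0 - h2 ** 2)
        gW2 = h1.T @ dh2
        gb2 = dh2.sum(axis=0)
        dh1 = (dh2 @ self.W2.T) * (1.0 - h1 ** 2)
        gW1 = xs.T @ dh1
        gb1 = dh1.sum(axis=0)
        return loss, (gW1, gb1, gW2, gb2, gW3, gb3)

    @property
    def _params(self):
        return [self.W1, self.b1, self.W2, self.b2, self.W3, self.b3]

    # -- training ----------------------------------------------------------
    def fit(self, theta: np.ndarray, x: np.ndarray,
            weights: np.ndarray | None = None, epochs: int = 800,
            minibatch: int = 1000, lr: float = 1e-3,
            clip_norm: float = 10.0, seed: int = 0) -> None:
        """Train on pairs (theta_i, x_i) with per-sample weights.

        Weighted NLL objective, Adam optimiser, minibatch shuffling with a
        dedicated generator so training is bit-reproducible under a fixed
        seed.
        """
        theta = np.atleast_2d(np.asarray(theta, float))
        x = np.asarray(x, float).ravel()
        n = theta.shape[0]
        if n < 10 * self.dim * self.C:
            raise ValueError("too few training pairs for the architecture")
        w = np.ones(n) if weights is None else np.asarray(weights, float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        self.x_loc = float(x.mean())
        self.x_scale = float(x.std()) or 1.0
        rng = np.random.default_rng(seed)
        ms = [np.zeros_like(p) for p in self._params]
        vs = [np.zeros_like(p) for p in self._params]
        t_step = 0
        self.training_curve = []
        for _ in range(epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, minibatch):
                idx = order[start:start + minibatch]
                loss, grads = self._loss_and_grads(theta[idx], x[idx], w[idx])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"NaN/inf training loss at step {t_step}")
                gn = np.sqrt(sum(float((g ** 2).sum()) for g in grads))
                scale = min(1.0, clip_norm / (gn + 1e-12))
                t_step += 1
                for p, g, m_, v_ in zip(self._params, grads, ms, vs):
                    g = g * scale
                    m_ += (1 - 0.9) * (g - m_)
                    v_ += (1 - 0.999) * (g * g - v_)
                    mhat = m_ / (1 - 0.9 ** t_step)
                    vhat = v_ / (1 - 0.999 ** t_step)
                    p -= lr * mhat / (np.sqrt(vhat) + 1e-8)
                epoch_loss += loss * idx.size
            self.training_curve.append(epoch_loss / n)

    # -- conditioning ------------------------------------------------------
    def posterior_at(self, x0: float) -> GaussianMixture:
        """Evaluate the conditional q(theta | x = x0) as a Gaussian mixture."""
        *_, out = self._net(np.array([x0]))
        logits, mu, _, A = self._split(out)
        pi = np.exp(logits[0] - logsumexp(logits[0]))
        covs = np.empty((self.C, self.dim, self.dim))
        for c in range(self.C):
            Ac = A[0, c]
            prec = Ac.T @ Ac
            covs[c] = np.linalg.inv(prec)
            covs[c] = 0.5 * (covs[c] + covs[c].T)
        return GaussianMixture(pi, mu[0], covs)
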