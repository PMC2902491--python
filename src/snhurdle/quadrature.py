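"""Marginal log-likelihood by Gauss-Hermite quadrature over the random effects.

Each subject contributes

    log L_i = log iint prod_j f(y_ij | tau0, tau1) phi2(tau0, tau1; 0, S) dtau,

a two-dimensional integral over the bivariate-normal random intercepts.
The integral is computed by transforming to independent standard normals
via the Cholesky factor of ``S`` and applying a tensor-product
Gauss-Hermite rule (default 21 points per dimension), or, in adaptive
mode, by recentering and rescaling a smaller rule (default 7 points) at
the per-subject posterior mode and curvature.  Node accumulation is done
in log space, so subjects with up to dozens of occasions do not underflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._likelihood import find_modes, gh_normal, loglik_parts
from .model import LongDataset, ParameterSet, _binary_logdensity
from .skewnormal import _logpdf as _sn_logpdf_raw

__all__ = ["QuadratureRule", "subject_logliks", "subject_loglik", "total_loglik"]

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class QuadratureRule:
    """Gauss-Hermite product rule for the 2-D random-effects integral.

    ``n_points`` is the number of nodes per dimension.  ``adaptive=True``
    recenters the rule at each subject's conditional posterior mode with
    curvature-based rescaling, which keeps few-point rules accurate when
    subjects carry many observations.
    """

    n_points: int = 21
    adaptive: bool = False

    def __post_init__(self):
        if self.n_points < 1:
            raise ValueError(f"n_points must be >= 1, got {self.n_points}")

    @property
    def nodes(self) -> np.ndarray:
        return gh_normal(self.n_points)[0]

    @property
    def weights(self) -> np.ndarray:
        """Weights normalized against the N(0,1) kernel (sum to 1)."""
        return gh_normal(self.n_points)[1]


def _conditional_logliks(data, s, tau0, tau1, params, link):
    """Conditional log-likelihood of subject ``s`` at paired (tau0[k], tau1[k])."""
    i0 = data.starts[s]
    i1 = data.starts[s + 1] if s + 1 < data.n_subjects else data.n_obs
    eta = data.X1[i0:i1] @ params.beta1
    sgn = data.sgn[i0:i1]
    tau0 = np.atleast_1d(np.asarray(tau0, float))
    tau1 = np.atleast_1d(np.asarray(tau1, float))
    ll = _binary_logdensity(eta[None, :] + tau0[:, None], sgn[None, :], link).sum(axis=-1)
    pos = data.y[i0:i1] > 0
    if pos.any():
        t = np.log(data.y[i0:i1][pos])
        mu = data.X2[i0:i1][pos] @ params.beta2
        B = _sn_logpdf_raw(t[None, :], mu[None, :] + tau1[:, None], params.sigma, params.delta)
        ll = ll + B.sum(axis=-1)
    return ll


def subject_logliks(
    data: LongDataset, params: ParameterSet, rule: QuadratureRule | None = None, link="probit"
) -> np.ndarray:
    """Marginal log-likelihood of every subject (array of length n_subjects)."""
    rule = rule or QuadratureRule()
    Lm = params.chol
    L = (Lm[0, 0], Lm[1, 0], Lm[1, 1])
    centers = None
    if rule.adaptive:
        centers = find_modes(
            data, params.beta1, params.beta2, params.sigma, params.delta, L, link=link
        )
    ll, _ = loglik_parts(
        data,
        params.beta1,
        params.beta2,
        params.sigma,
        params.delta,
        L,
        rule.nodes,
        rule.weights,
        link=link,
        centers=centers,
    )
    return ll


def subject_loglik(
    data: LongDataset,
    params: ParameterSet,
    rule: QuadratureRule | None = None,
    link: str = "probit",
    subject=None,
) -> float:
    """Marginal log-likelihood of a single subject.

    ``data`` may hold a single subject, or ``subject`` selects one by label.
    """
    if subject is not None:
        data = data.subset(subject)
    elif data.n_subjects != 1:
        raise ValueError("pass a single-subject dataset or a subject label")
    return float(subject_logliks(data, params, rule, link)[0])


def total_loglik(
    data: LongDataset, params: ParameterSet, rule: QuadratureRule | None = None, link="probit"
) -> float:
    """Total marginal log-likelihood: sum over independent subjects."""
    return float(subject_logliks(data, params, rule, link).sum())
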