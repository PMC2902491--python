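"""Two-part (hurdle) observation model for zero-inflated repeated measures.

An observation ``Y_ij >= 0`` on subject ``i`` at occasion ``j`` is either
exactly zero or strictly positive.  The model couples

* a binary part: ``P(Y_ij > 0 | tau0_i) = Phi(x1_ij' beta1 + tau0_i)``
  (probit link; a logit link is also supported), and
* a severity part: given ``Y_ij > 0``, ``log Y_ij`` follows an SDB
  skew-normal with location ``x2_ij' beta2 + tau1_i``, scale ``sigma`` and
  skewness ``delta``,

where ``(tau0_i, tau1_i)`` are correlated subject-level random intercepts,
bivariate normal with covariance ``[[s11, s12], [s12, s22]]``.  The linear
predictor of the binary part drives the probability of a *positive*
response; "probability symptom free" is its complement.

The severity likelihood is defined on the log-scale response (the density
of ``log Y``, no ``1/y`` Jacobian), so that deviance and information
criteria are directly comparable between the skew-normal and the nested
lognormal (``delta = 0``) severity models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import log_expit, log_ndtr, ndtr

from .skewnormal import _logpdf as _sn_logpdf_raw

__all__ = [
    "ParameterSet",
    "RandomEffects",
    "LongDataset",
    "prob_positive",
    "obs_logdensity",
    "add_derived_columns",
]

_LINKS = ("probit", "logit")


def _check_link(link: str) -> None:
    if link not in _LINKS:
        raise ValueError(f"link must be one of {_LINKS}, got {link!r}")


@dataclass(frozen=True)
class ParameterSet:
    """Full parameter vector of the two-part mixed model.

    ``beta1`` / ``beta2`` are the binary-part and severity-part regression
    coefficients; ``sigma``/``delta`` the skew-normal scale and skewness;
    ``s11``, ``s22``, ``s12`` the random-intercept covariance entries.  The
    covariance matrix must be symmetric positive definite.
    """

    beta1: np.ndarray
    beta2: np.ndarray
    sigma: float
    delta: float
    s11: float
    s22: float
    s12: float

    def __post_init__(self):
        object.__setattr__(self, "beta1", np.atleast_1d(np.asarray(self.beta1, float)))
        object.__setattr__(self, "beta2", np.atleast_1d(np.asarray(self.beta2, float)))
        vals = np.concatenate(
            [self.beta1, self.beta2, [self.sigma, self.delta, self.s11, self.s22, self.s12]]
        )
        if not np.all(np.isfinite(vals)):
            raise ValueError("all parameters must be finite")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma!r}")
        if self.s11 <= 0 or self.s22 <= 0 or self.s11 * self.s22 - self.s12**2 <= 0:
            raise ValueError(
                "random-effects covariance [[s11,s12],[s12,s22]] must be positive definite"
            )

    @property
    def cov(self) -> np.ndarray:
        """Random-effects covariance matrix ``S`` (2x2)."""
        return np.array([[self.s11, self.s12], [self.s12, self.s22]])

    @property
    def chol(self) -> np.ndarray:
        """Lower Cholesky factor of ``S``."""
        return np.linalg.cholesky(self.cov)


@dataclass(frozen=True)
class RandomEffects:
    """Subject-level random intercepts (binary part, severity part)."""

    tau0: float
    tau1: float


class LongDataset:
    """Subject-clustered long-format data with two design blocks.

    Rows are sorted by subject at construction; per-subject slice indices
    and the positive-response index structures used by the quadrature
    kernel are precomputed once here.

    Parameters
    ----------
    subject_ids : array_like
        Subject label per row (any hashable labels).
    y : array_like
        Non-negative response; exactly 0 or strictly positive, no missing.
    X1, X2 : ndarray (n_obs, p)
        Design matrices of the binary and severity parts (include an
        intercept column explicitly if wanted; `from_frame` does so).
    x1_names, x2_names : sequence of str, optional
        Column names for reporting.
    occasion : array_like, optional
        Occasion index within subject (kept for bookkeeping only).
    """

    def __init__(self, subject_ids, y, X1, X2, x1_names=None, x2_names=None, occasion=None):
        subject_ids = np.asarray(subject_ids)
        y = np.asarray(y, dtype=float)
        X1 = np.atleast_2d(np.asarray(X1, dtype=float))
        X2 = np.atleast_2d(np.asarray(X2, dtype=float))
        n = y.shape[0]
        if subject_ids.shape[0] != n or X1.shape[0] != n or X2.shape[0] != n:
            raise ValueError("subject_ids, y, X1, X2 must have equal row counts")
        if n == 0:
            raise ValueError("dataset must contain at least one observation")
        if not np.all(np.isfinite(y)) or np.any(y < 0):
            raise ValueError("y must be finite and >= 0 (drop missing rows upstream)")
        if not (np.all(np.isfinite(X1)) and np.all(np.isfinite(X2))):
            raise ValueError("design matrices must be finite (no missing covariates)")

        codes, uniques = pd.factorize(subject_ids, sort=True)
        order = np.argsort(codes, kind="stable")
        self.subject_labels = np.asarray(uniques)
        self.subj = codes[order]
        self.y = y[order]
        self.X1 = X1[order]
        self.X2 = X2[order]
        self.occasion = None if occasion is None else np.asarray(occasion)[order]
        self.x1_names = list(x1_names) if x1_names is not None else [f"x1_{k}" for k in range(X1.shape[1])]
        self.x2_names = list(x2_names) if x2_names is not None else [f"x2_{k}" for k in range(X2.shape[1])]
        if len(self.x1_names) != X1.shape[1] or len(self.x2_names) != X2.shape[1]:
            raise ValueError("covariate name lists must match design column counts")

        self.n_obs = n
        self.n_subjects = len(self.subject_labels)
        # first row of each subject block (rows are sorted by subject code)
        self.starts = np.searchsorted(self.subj, np.arange(self.n_subjects))
        # +1 where y > 0, -1 where y == 0: lets the binary-part log-likelihood
        # be written as log Phi(sign * eta) in a single vectorized call
        self.sgn = np.where(self.y > 0, 1.0, -1.0)
        self.pos_idx = np.flatnonzero(self.y > 0)
        self.t_pos = np.log(self.y[self.pos_idx])
        self.X2_pos = self.X2[self.pos_idx]
        pos_subj = self.subj[self.pos_idx]
        self.pos_subj = pos_subj
        if pos_subj.size:
            present, pstarts = np.unique(pos_subj, return_index=True)
        else:
            present, pstarts = np.array([], dtype=int), np.array([], dtype=int)
        self.pos_present = present
        self.pos_starts = pstarts

    # -- construction -----------------------------------------------------

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        response: str = "y",
        subject: str = "subject",
        x1_cols=(),
        x2_cols=(),
        occasion: str | None = None,
        intercept: bool = True,
    ) -> "LongDataset":
        """Build a dataset from a long-format data frame.

        ``x1_cols``/``x2_cols`` name the covariate columns of the binary
        and severity parts; an intercept column is prepended to each block
        unless ``intercept=False``.
        """
        for col in [response, subject, *x1_cols, *x2_cols] + ([occasion] if occasion else []):
            if col not in df.columns:
                raise KeyError(f"column {col!r} not found in data")
        n = len(df)
        blocks = []
        names = []
        for cols in (x1_cols, x2_cols):
            X = df[list(cols)].to_numpy(dtype=float) if cols else np.empty((n, 0))
            nm = list(cols)
            if intercept:
                X = np.column_stack([np.ones(n), X])
                nm = ["intercept"] + nm
            blocks.append(X)
            names.append(nm)
        return cls(
            df[subject].to_numpy(),
            df[response].to_numpy(dtype=float),
            blocks[0],
            blocks[1],
            x1_names=names[0],
            x2_names=names[1],
            occasion=df[occasion].to_numpy() if occasion else None,
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame (subject, y and both design blocks)."""
        out = pd.DataFrame({"subject": self.subject_labels[self.subj], "y": self.y})
        if self.occasion is not None:
            out.insert(1, "occasion", self.occasion)
        for name, col in zip(self.x1_names, self.X1.T):
            out[f"x1:{name}"] = col
        for name, col in zip(self.x2_names, self.X2.T):
            out[f"x2:{name}"] = col
        return out

    def subset(self, subject_label) -> "LongDataset":
        """Single-subject slice as a new dataset."""
        mask = self.subject_labels[self.subj] == subject_label
        if not mask.any():
            raise KeyError(f"unknown subject {subject_label!r}")
        return LongDataset(
            self.subject_labels[self.subj][mask],
            self.y[mask],
            self.X1[mask],
            self.X2[mask],
            x1_names=self.x1_names,
            x2_names=self.x2_names,
        )

    def fingerprint(self) -> tuple:
        """Cheap content fingerprint used to guard model comparisons."""
        return (
            self.n_subjects,
            self.n_obs,
            float(self.y.sum()),
            float((self.y**2).sum()),
            tuple(self.x1_names),
            tuple(self.x2_names),
        )


# -- observation-level model pieces ---------------------------------------


def prob_positive(x1, beta1, tau0: float = 0.0, link: str = "probit"):
    """``P(Y > 0 | tau0)`` for covariate vector(s) ``x1``.

    ``Phi(x1' beta1 + tau0)`` under the probit link, ``expit`` under the
    logit link; strictly increasing in the linear predictor.
    """
    _check_link(link)
    x1 = np.asarray(x1, dtype=float)
    beta1 = np.asarray(beta1, dtype=float)
    if x1.shape[-1] != beta1.shape[0]:
        raise ValueError(
            f"covariate/coefficient dimension mismatch: {x1.shape[-1]} vs {beta1.shape[0]}"
        )
    eta = x1 @ beta1 + tau0
    if link == "probit":
        p = ndtr(eta)
    else:
        p = 1.0 / (1.0 + np.exp(-eta))
    return float(p) if np.ndim(p) == 0 else p


def _binary_logdensity(eta, sgn, link):
    """log P of the observed zero/positive indicator; sgn=+1 for y>0."""
    if link == "probit":
        return log_ndtr(sgn * eta)
    return log_expit(sgn * eta)


def obs_logdensity(y, x1, x2, params: ParameterSet, effects: RandomEffects, link="probit"):
    """Log-density of one observation given the random effects.

    ``y = 0`` contributes ``log(1 - p)``; ``y > 0`` contributes
    ``log p + log f_SN(log y; x2' beta2 + tau1, sigma, delta)``.
    """
    _check_link(link)
    y = float(y)
    if not np.isfinite(y) or y < 0:
        raise ValueError(f"y must be finite and >= 0, got {y!r}")
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape[-1] != params.beta1.shape[0] or x2.shape[-1] != params.beta2.shape[0]:
        raise ValueError("covariate/coefficient dimension mismatch")
    eta = float(x1 @ params.beta1) + effects.tau0
    out = float(_binary_logdensity(np.asarray(eta), 1.0 if y > 0 else -1.0, link))
    if y > 0:
        mu = float(x2 @ params.beta2) + effects.tau1
        out += float(_sn_logpdf_raw(np.log(y), mu, params.sigma, params.delta))
    return out


def add_derived_columns(df: pd.DataFrame, terms: dict[str, str]) -> pd.DataFrame:
    """Return a copy of ``df`` with derived design columns.

    ``terms`` maps new column names to pandas ``eval`` expressions over
    existing columns, e.g. ``{"week2": "week**2", "age_week": "age*week"}``.
    Interaction and polynomial terms for the model designs are built this
    way rather than inside the fitter.
    """
    out = df.copy()
    for name, expr in terms.items():
        out[name] = out.eval(expr)
    return out
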