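"""Aitchison-geometry primitives for intensity-band time-use compositions.

A day's physical behaviour is summarised as a *composition*: nine non-negative
durations (minutes per day in each acceleration intensity band) carrying only
relative information, analysed after closure to a fixed total (960 min for the
07:00-23:00 standardised day).  This module provides the compositional
machinery the analysis rests on:

* closure and the centred log-ratio (clr) transform;
* pivot-coordinate isometric log-ratio (ILR) bases, in which the first
  coordinate contrasts one designated band against the geometric mean of all
  the remaining bands;
* the inverse ILR transform;
* sample geometric-mean compositions and variation matrices;
* the "one-for-remaining" reallocation operator used by isotemporal
  substitution (move t minutes into one band, taking t/(D-1) from each of the
  others).

Compositions are plain numpy arrays (1-D for a single participant, 2-D with
one row per participant); band labels live in :data:`bandcoda.bands.BAND_LABELS`
and CSV I/O helpers at the bottom of this module tie the two together.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "DAY_MINUTES",
    "close",
    "clr",
    "clr_inverse",
    "PivotBasis",
    "pivot_ilr",
    "ilr_inverse",
    "geometric_mean_composition",
    "reallocate_one_for_remaining",
    "variation_matrix",
    "aitchison_distance",
    "replace_zeros",
    "PivotCoordinates",
    "read_composition_csv",
    "write_composition_csv",
]

#: Closure constant of the standardised 07:00-23:00 waking-hours day (16 h).
DAY_MINUTES = 960.0

#: Pseudo-duration (minutes) added to empty bands before closure: 0.5 s.
#: Far below the 1-min reporting resolution of the band durations.
ZERO_PSEUDO_MINUTES = 1.0 / 120.0


def _as_array(parts) -> np.ndarray:
    x = np.asarray(parts, dtype=float)
    if x.ndim not in (1, 2):
        raise ValueError("compositions must be 1-D or 2-D (rows = participants)")
    return x


def close(parts, total: float = DAY_MINUTES) -> np.ndarray:
    """Rescale non-negative parts to sum to ``total`` (the closure operation).

    Parameters
    ----------
    parts : array-like, shape (D,) or (n, D)
        Non-negative durations; each row must have at least one positive part.
    total : float
        Closure constant in minutes (default: the 960-min day).

    Returns
    -------
    numpy.ndarray
        ``parts * total / sum(parts)`` row-wise, order preserved.
    """
    x = _as_array(parts)
    if total <= 0:
        raise ValueError("closure total must be positive")
    if np.any(x < 0):
        raise ValueError("composition parts must be non-negative")
    s = x.sum(axis=-1, keepdims=True)
    if np.any(s == 0):
        raise ValueError("cannot close an empty (all-zero) composition")
    return x * (total / s)


def replace_zeros(parts, pseudo: float = ZERO_PSEUDO_MINUTES) -> np.ndarray:
    """Add a small pseudo-duration to zero parts so log-ratio transforms apply.

    Day-averaged band durations can be exactly zero for participants who never
    reach a high-intensity band; log-ratio transforms require strict
    positivity.  The default pseudo-duration is 0.5 s — far below the 1-min
    resolution at which band times are reported — and rows without zeros are
    returned unchanged.
    """
    x = _as_array(parts)
    if pseudo <= 0:
        raise ValueError("pseudo-duration must be positive")
    return np.where(x <= 0, pseudo, x)


def _check_positive(x: np.ndarray, labels=None) -> None:
    if np.any(x <= 0):
        bad = np.argwhere(x <= 0)
        idx = int(bad[0][-1])
        name = labels[idx] if labels is not None else f"part {idx + 1}"
        raise ValueError(
            f"log-ratio transforms require strictly positive parts; {name} is "
            f"non-positive (use replace_zeros first)"
        )


def clr(comp, labels=None) -> np.ndarray:
    """Centred log-ratio transform: ``clr_j = ln x_j - mean_k ln x_k``.

    The result sums to zero along the last axis and is invariant to closure.
    """
    x = _as_array(comp)
    _check_positive(x, labels)
    logs = np.log(x)
    return logs - logs.mean(axis=-1, keepdims=True)


def clr_inverse(coords, total: float = DAY_MINUTES) -> np.ndarray:
    """Map clr coordinates back to a composition closed to ``total``."""
    return close(np.exp(_as_array(coords)), total)


@dataclass(frozen=True)
class PivotBasis:
    """Pivot-coordinate ILR basis isolating one part in its first coordinate.

    The basis orders the D parts with ``lead`` first, followed by the
    remaining parts in ``order`` (default: original order with the lead
    removed).  Coordinate k contrasts the part at position k against the
    geometric mean of all later parts:

        z_k = sqrt((D-k)/(D-k+1)) * ln( x_(k) / gm(x_(k+1), ..., x_(D)) )

    so the first pivot coordinate z_1 captures the lead band relative to the
    geometric mean of all the remaining bands, and satisfies
    ``z_1 = sqrt(D/(D-1)) * clr_lead``.  z_1 (and hence its regression
    coefficient) does not depend on the ordering of the remaining parts.

    Parameters use 0-based indices; band labels are the external interface.
    """

    D: int
    lead: int = 0
    order: tuple = field(default=None)

    def __post_init__(self):
        if self.D < 3:
            raise ValueError("pivot bases require at least 3 parts")
        if not 0 <= self.lead < self.D:
            raise ValueError(f"lead index {self.lead} outside 0..{self.D - 1}")
        order = self.order
        if order is None:
            order = tuple(j for j in range(self.D) if j != self.lead)
        else:
            order = tuple(int(j) for j in order)
            if sorted(order) != sorted(j for j in range(self.D) if j != self.lead):
                raise ValueError("order must be a permutation of the non-lead indices")
        object.__setattr__(self, "order", order)

    @property
    def permutation(self) -> np.ndarray:
        """Part indices in basis order (lead first)."""
        return np.asarray((self.lead,) + self.order)

    def matrix(self) -> np.ndarray:
        """The (D-1) x D contrast matrix V with orthonormal rows in clr space.

        ``pivot_ilr(x) = V @ clr(x)``; rows satisfy V V^T = I and V 1 = 0.
        """
        D = self.D
        V = np.zeros((D - 1, D))
        perm = self.permutation
        for k in range(D - 1):
            r = D - 1 - k  # number of parts after position k
            coef = np.sqrt(r / (r + 1.0))
            V[k, perm[k]] = coef
            V[k, perm[k + 1 :]] = -coef / r
        return V


def pivot_ilr(comp, basis: PivotBasis | None = None, lead: int = 0) -> np.ndarray:
    """Pivot-coordinate ILR transform of one or more compositions.

    Returns D-1 coordinates per row; the first coordinate contrasts the lead
    part against the geometric mean of the rest.
    """
    x = _as_array(comp)
    D = x.shape[-1]
    if basis is None:
        basis = PivotBasis(D, lead)
    if basis.D != D:
        raise ValueError(f"basis is for {basis.D} parts, composition has {D}")
    _check_positive(x)
    return clr(x) @ basis.matrix().T


def ilr_inverse(
    coords, basis: PivotBasis | None = None, total: float = DAY_MINUTES
) -> np.ndarray:
    """Inverse pivot ILR: the unique composition (closed to ``total``) with the
    given coordinates."""
    z = _as_array(coords)
    D = z.shape[-1] + 1
    if basis is None:
        basis = PivotBasis(D)
    if basis.D != D:
        raise ValueError(f"basis is for {basis.D} parts, coordinates imply {D}")
    return clr_inverse(z @ basis.matrix(), total)


def geometric_mean_composition(sample, total: float = DAY_MINUTES) -> np.ndarray:
    """Component-wise geometric mean across a sample, closed to ``total``.

    This is the compositional centre: the minimiser of summed squared
    Aitchison distances to the sample.
    """
    x = _as_array(sample)
    if x.ndim != 2 or x.shape[0] == 0:
        raise ValueError("need a non-empty 2-D sample of compositions")
    _check_positive(x)
    return close(np.exp(np.log(x).mean(axis=0)), total)


def reallocate_one_for_remaining(comp, band: int, t: float) -> np.ndarray:
    """Move ``t`` minutes into part ``band``, taking t/(D-1) from each other part.

    Negative ``t`` removes time from ``band`` and redistributes it equally
    among the remaining parts.  The total is conserved exactly.
    """
    x = _as_array(comp)
    if x.ndim != 1:
        raise ValueError("reallocation operates on a single composition")
    D = x.shape[0]
    if not 0 <= band < D:
        raise ValueError(f"band index {band} outside 0..{D - 1}")
    delta = np.full(D, -t / (D - 1))
    delta[band] = t
    out = x + delta
    if np.any(out <= 0):
        bad = int(np.argwhere(out <= 0)[0][0])
        raise ValueError(
            f"reallocating {t:+g} min drives part {bad + 1} to "
            f"{out[bad]:.4g} min (must stay positive)"
        )
    return out


def variation_matrix(sample) -> np.ndarray:
    """D x D matrix of variances of pairwise log-ratios over the sample.

    Entry (i, j) is ``var(ln(x_i / x_j))`` — the canonical description of
    compositional spread.  Symmetric with zero diagonal.
    """
    x = _as_array(sample)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("variation matrix needs at least 2 compositions")
    _check_positive(x)
    logs = np.log(x)
    # var(log xi - log xj) via the covariance of the logs
    cov = np.cov(logs, rowvar=False, ddof=1)
    d = np.diag(cov)
    return d[:, None] + d[None, :] - 2 * cov


def aitchison_distance(a, b) -> float:
    """Aitchison distance: Euclidean distance between clr images."""
    return float(np.linalg.norm(clr(a) - clr(b)))


class PivotCoordinates(TransformerMixin, BaseEstimator):
    """Transformer mapping closed compositions to pivot ILR coordinates.

    A stateless sklearn transformer: ``transform`` maps an (n, D) array of
    strictly positive compositions to (n, D-1) pivot coordinates whose first
    column contrasts the ``lead`` part against the geometric mean of the rest.

    Parameters
    ----------
    lead : int
        Index of the part isolated by the first coordinate.
    zero_pseudo : float or None
        Pseudo-duration substituted for zero parts before the transform
        (None disables zero replacement and zeros raise).
    """

    def __init__(self, lead: int = 0, zero_pseudo: float | None = ZERO_PSEUDO_MINUTES):
        self.lead = lead
        self.zero_pseudo = zero_pseudo

    def fit(self, X, y=None):
        X = _as_array(X)
        self.n_features_in_ = X.shape[-1]
        self.basis_ = PivotBasis(self.n_features_in_, self.lead)
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "basis_")
        X = _as_array(X)
        if self.zero_pseudo is not None:
            X = replace_zeros(X, self.zero_pseudo)
        return pivot_ilr(X, self.basis_)

    def inverse_transform(self, Z, total: float = DAY_MINUTES) -> np.ndarray:
        check_is_fitted(self, "basis_")
        return ilr_inverse(Z, self.basis_, total)


def read_composition_csv(path, labels) -> pd.DataFrame:
    """Read per-participant compositions (one row each, columns = band labels)."""
    df = pd.read_csv(path)
    missing = [c for c in labels if c not in df.columns]
    if missing:
        raise ValueError(f"composition CSV is missing band columns: {missing}")
    return df


def write_composition_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
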