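"""Base contact predictors: mutual information, APC correction, external maps.

These stand in for the coevolution-derived coupling maps (PSICOV- and
plmDCA-style) that a production pipeline would compute from deep
alignments. Any number k ≥ 1 of base maps can feed the stacked learner.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .msa import ALPHABET, Msa

__all__ = [
    "PredictionMap",
    "mutual_information",
    "apc_correct",
    "load_external_map",
]


@dataclass
class PredictionMap:
    """Symmetric real-valued residue-pair score matrix from one predictor."""

    scores: np.ndarray  # (L, L) float
    method_tag: str = ""

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[0] != self.scores.shape[1]:
            raise ValueError("score matrix must be square")
        if not np.isfinite(self.scores).all():
            raise ValueError("scores must be finite")
        if not np.allclose(self.scores, self.scores.T, atol=1e-8):
            raise ValueError("score matrix must be symmetric")

    @property
    def length(self) -> int:
        return self.scores.shape[0]


def mutual_information(
    msa: Msa,
    pseudocount: float | None = None,
    weights: np.ndarray | None = None,
) -> PredictionMap:
    """Column-pair mutual information over the 21-state alphabet, in nats.

    MI(i, j) = Σ_ab p(a, b) log(p(a, b) / (p(a) p(b))), with joint counts
    regularised by an additive pseudocount per cell (default 1/21²).
    ``weights`` optionally reweights rows (e.g. inverse cluster sizes);
    unweighted counting is the default. The alignment should already have
    gappy rows removed (see :func:`contactstack.msa.filter_gappy_rows`).
    """
    q = len(ALPHABET)
    if pseudocount is None:
        pseudocount = 1.0 / (q * q)
    arr = msa.to_array()
    n, ncol = arr.shape
    if n == 1:
        warnings.warn("single-row alignment: mutual information is all zero")
        return PredictionMap(np.zeros((ncol, ncol)), method_tag="MI")
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float)

    # one-hot encode once: (ncol, q) weighted single-column counts and
    # (ncol*q, n) indicator for fast joint counting
    onehot = np.zeros((n, ncol, q), dtype=float)
    rows = np.repeat(np.arange(n), ncol)
    cols = np.tile(np.arange(ncol), n)
    onehot[rows, cols, arr.ravel()] = 1.0
    w_onehot = onehot * weights[:, None, None]

    mi = np.zeros((ncol, ncol))
    flat = onehot.reshape(n, ncol * q)
    wflat = w_onehot.reshape(n, ncol * q)
    # joint counts for all column pairs at once: (ncol*q, ncol*q)
    joint = flat.T @ wflat
    joint = joint.reshape(ncol, q, ncol, q)
    for i in range(ncol):
        for j in range(i + 1, ncol):
            pab = joint[i, :, j, :] + pseudocount
            pab /= pab.sum()
            pa = pab.sum(axis=1)
            pb = pab.sum(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                term = pab * np.log(pab / (pa[:, None] * pb[None, :]))
            mi_ij = float(np.nansum(term))
            mi[i, j] = mi[j, i] = max(mi_ij, 0.0)
    # diagonal: MI(X, X) = H(X), useful for sanity checks only
    for i in range(ncol):
        pa = (joint[i, :, i, :].diagonal() + pseudocount)
        pa = pa / pa.sum()
        nz = pa > 0
        mi[i, i] = float(-(pa[nz] * np.log(pa[nz])).sum())
    return PredictionMap(mi, method_tag="MI")


def apc_correct(pmap: PredictionMap) -> PredictionMap:
    """Average product correction: subtract rowmean_i·rowmean_j/grandmean.

    Means exclude the diagonal. Removes the background row/column signal
    from an MI or coupling matrix; a pure product-form matrix
    raw(i,j)=u_i·u_j maps to (numerically) zero off the diagonal.
    """
    s = pmap.scores.copy()
    L = s.shape[0]
    if L < 2:
        return PredictionMap(np.zeros_like(s), method_tag=pmap.method_tag + "+APC")
    off = ~np.eye(L, dtype=bool)
    row_mean = np.array([s[i, off[i]].mean() for i in range(L)])
    grand_mean = s[off].mean()
    if grand_mean == 0.0:
        warnings.warn("grand mean is zero; APC returns the input unchanged")
        return PredictionMap(s, method_tag=pmap.method_tag + "+APC")
    corrected = s - np.outer(row_mean, row_mean) / grand_mean
    np.fill_diagonal(corrected, 0.0)
    return PredictionMap(corrected, method_tag=pmap.method_tag + "+APC")


def load_external_map(
    path, length: int, dialect: str = "triplet", atol: float = 1e-6
) -> PredictionMap:
    """Load an externally computed coupling map.

    ``dialect='triplet'`` reads "i j score" records (1-based, i≠j),
    mirrored into a full symmetric matrix with unlisted pairs at 0;
    PSICOV-style "i j d1 d2 score" records are accepted too.
    ``dialect='dense'`` reads a whitespace-delimited L×L matrix and
    requires symmetry within ``atol``.
    """
    if dialect == "triplet":
        scores = np.zeros((length, length))
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                parts = line.split()
                try:
                    i, j = int(parts[0]), int(parts[1])
                    s = float(parts[-1])
                except (ValueError, IndexError) as exc:
                    raise ValueError(
                        f"malformed triplet at line {lineno}: {line!r}"
                    ) from exc
                if not (1 <= i <= length and 1 <= j <= length):
                    raise ValueError(
                        f"index out of range 1..{length} at line {lineno}"
                    )
                scores[i - 1, j - 1] = s
                scores[j - 1, i - 1] = s
        return PredictionMap(scores, method_tag="external")
    elif dialect == "dense":
        scores = np.loadtxt(path)
        if scores.shape != (length, length):
            raise ValueError(
                f"dense map has shape {scores.shape}, expected ({length}, {length})"
            )
        if not np.allclose(scores, scores.T, atol=atol):
            raise ValueError("dense map is asymmetric beyond tolerance")
        scores = (scores + scores.T) / 2.0
        return PredictionMap(scores, method_tag="external")
    raise ValueError(f"unknown dialect {dialect!r}")
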