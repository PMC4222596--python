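"""Per-pair feature encoding and receptive-field extraction.

Each residue pair (i, j), i<j, is described by a fixed-order *ordinary*
feature vector — base-predictor scores at (i, j), sequence separation,
the PSSM rows of i and j, and windowed secondary-structure and solvent-
accessibility profiles — optionally concatenated with the *receptive
field*: the square window of previous-layer contact probabilities
centred at (i, j). The feature order is frozen (the order listed below)
so serialised models stay valid across sessions.

Windows that extend past either sequence end are zero-padded, and so is
the receptive field outside the map: absent positions carry "no predicted
contact" rather than mirrored or imputed structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FeatureConfig",
    "PairFeatureVector",
    "encode_pair",
    "encode_family",
    "receptive_field",
    "receptive_fields_batch",
]

N_SS_CLASSES = 3  # helix, strand, coil probabilities
N_RSA_VALUES = 5  # rsa, z-fit, 3 SS-class probabilities
N_PSSM_STATES = 21  # 20 amino acids + gap


@dataclass(frozen=True)
class FeatureConfig:
    """Which features are encoded, and the window geometry.

    ``field_halfwidth`` h gives a (2h+1)×(2h+1) receptive field; with the
    default h=5 that is the 11×11 window. With everything enabled the
    ordinary dimension is k + 1 + 2·21 + 2·ss_window·3 + 2·rsa_window·5.
    """

    n_base_maps: int = 1
    use_separation: bool = True
    use_pssm: bool = True
    use_ss: bool = True
    use_rsa: bool = True
    ss_window: int = 9
    rsa_window: int = 9
    field_halfwidth: int = 5

    def __post_init__(self):
        if self.n_base_maps < 1:
            raise ValueError("need at least one base map")
        if self.ss_window % 2 != 1 or self.rsa_window % 2 != 1:
            raise ValueError("windows must be odd")
        if self.field_halfwidth < 0:
            raise ValueError("field halfwidth must be >= 0")

    @property
    def ordinary_dim(self) -> int:
        d = self.n_base_maps
        if self.use_separation:
            d += 1
        if self.use_pssm:
            d += 2 * N_PSSM_STATES
        if self.use_ss:
            d += 2 * self.ss_window * N_SS_CLASSES
        if self.use_rsa:
            d += 2 * self.rsa_window * N_RSA_VALUES
        return d

    @property
    def field_dim(self) -> int:
        w = 2 * self.field_halfwidth + 1
        return w * w


@dataclass
class PairFeatureVector:
    pair: tuple[int, int]  # (i, j), 0-based, i < j
    ordinary: np.ndarray
    field: np.ndarray | None = None  # absent at layer 0

    @property
    def full(self) -> np.ndarray:
        if self.field is None:
            return self.ordinary
        return np.concatenate([self.ordinary, self.field])


def _window_rows(table: np.ndarray, center: int, window: int) -> np.ndarray:
    """Rows of a per-residue table in a window around ``center``, zero-padded."""
    L, width = table.shape
    half = window // 2
    out = np.zeros((window, width), dtype=table.dtype)
    lo = max(0, center - half)
    hi = min(L, center + half + 1)
    out[lo - (center - half) : hi - (center - half)] = table[lo:hi]
    return out


def encode_pair(
    i: int,
    j: int,
    base_maps: list[np.ndarray],
    config: FeatureConfig,
    pssm: np.ndarray | None = None,
    ss: np.ndarray | None = None,
    rsa: np.ndarray | None = None,
) -> PairFeatureVector:
    """Ordinary feature vector for a single pair (0-based indices, i<j).

    ``base_maps`` are L×L score matrices; ``pssm`` is (L, 21); ``ss`` is
    (L, 3) class probabilities; ``rsa`` is (L, 5). Missing tables for
    enabled features raise.
    """
    if not i < j:
        raise ValueError("pairs must satisfy i < j")
    if len(base_maps) != config.n_base_maps:
        raise ValueError(
            f"expected {config.n_base_maps} base maps, got {len(base_maps)}"
        )
    L = base_maps[0].shape[0]
    parts = [np.array([m[i, j] for m in base_maps], dtype=float)]
    if config.use_separation:
        parts.append(np.array([float(j - i)]))
    if config.use_pssm:
        if pssm is None:
            raise ValueError("config enables PSSM but no PSSM table given")
        if pssm.shape[0] != L:
            raise ValueError(f"PSSM missing rows: has {pssm.shape[0]}, need {L}")
        parts.extend([pssm[i], pssm[j]])
    if config.use_ss:
        if ss is None:
            raise ValueError("config enables SS but no SS table given")
        if ss.shape[0] != L:
            raise ValueError(f"SS table missing rows: has {ss.shape[0]}, need {L}")
        parts.append(_window_rows(ss, i, config.ss_window).ravel())
        parts.append(_window_rows(ss, j, config.ss_window).ravel())
    if config.use_rsa:
        if rsa is None:
            raise ValueError("config enables RSA but no RSA table given")
        if rsa.shape[0] != L:
            raise ValueError(f"RSA table missing rows: has {rsa.shape[0]}, need {L}")
        parts.append(_window_rows(rsa, i, config.rsa_window).ravel())
        parts.append(_window_rows(rsa, j, config.rsa_window).ravel())
    vec = np.concatenate(parts)
    assert vec.shape[0] == config.ordinary_dim
    if not np.isfinite(vec).all():
        raise ValueError("non-finite feature values")
    return PairFeatureVector(pair=(i, j), ordinary=vec)


def encode_family(
    pairs: np.ndarray,
    base_maps: list[np.ndarray],
    config: FeatureConfig,
    pssm: np.ndarray | None = None,
    ss: np.ndarray | None = None,
    rsa: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorised ordinary features for many pairs at once.

    ``pairs`` is an (n, 2) int array of 0-based (i, j) with i<j. Returns
    an (n, ordinary_dim) float32 matrix identical row-by-row to
    :func:`encode_pair`.
    """
    pairs = np.asarray(pairs)
    ii, jj = pairs[:, 0], pairs[:, 1]
    L = base_maps[0].shape[0]
    n = len(pairs)
    cols = []
    for m in base_maps:
        cols.append(m[ii, jj][:, None])
    if config.use_separation:
        cols.append((jj - ii).astype(float)[:, None])
    if config.use_pssm:
        cols.extend([pssm[ii], pssm[jj]])

    def windowed(table, centers, window):
        width = table.shape[1]
        half = window // 2
        padded = np.zeros((L + 2 * half, width), dtype=table.dtype)
        padded[half : half + L] = table
        offsets = np.arange(window)
        idx = centers[:, None] + offsets[None, :]  # already shifted by pad
        return padded[idx].reshape(n, window * width)

    if config.use_ss:
        cols.append(windowed(ss, ii, config.ss_window))
        cols.append(windowed(ss, jj, config.ss_window))
    if config.use_rsa:
        cols.append(windowed(rsa, ii, config.rsa_window))
        cols.append(windowed(rsa, jj, config.rsa_window))
    X = np.concatenate([np.asarray(c, dtype=np.float32) for c in cols], axis=1)
    assert X.shape == (n, config.ordinary_dim)
    return X


def receptive_field(map_scores: np.ndarray, i: int, j: int, halfwidth: int) -> np.ndarray:
    """The (2h+1)×(2h+1) window of a score map centred at (i, j).

    Entry (a, b) is map[i−h+a, j−h+b]; positions outside the map are 0.
    The centre entry equals map[i, j].
    """
    if halfwidth < 0:
        raise ValueError("halfwidth must be >= 0")
    m = np.asarray(map_scores)
    L = m.shape[0]
    w = 2 * halfwidth + 1
    out = np.zeros((w, w), dtype=m.dtype)
    r_lo, r_hi = max(0, i - halfwidth), min(L, i + halfwidth + 1)
    c_lo, c_hi = max(0, j - halfwidth), min(L, j + halfwidth + 1)
    if r_lo < r_hi and c_lo < c_hi:
        out[
            r_lo - (i - halfwidth) : r_hi - (i - halfwidth),
            c_lo - (j - halfwidth) : c_hi - (j - halfwidth),
        ] = m[r_lo:r_hi, c_lo:c_hi]
    return out


def receptive_fields_batch(
    map_scores: np.ndarray, pairs: np.ndarray, halfwidth: int
) -> np.ndarray:
    """Receptive fields for many pairs at once; rows match
    :func:`receptive_field` flattened."""
    if halfwidth < 0:
        raise ValueError("halfwidth must be >= 0")
    m = np.asarray(map_scores, dtype=np.float32)
    L = m.shape[0]
    h = halfwidth
    w = 2 * h + 1
    padded = np.zeros((L + 2 * h, L + 2 * h), dtype=np.float32)
    padded[h : h + L, h : h + L] = m
    pairs = np.asarray(pairs)
    ii, jj = pairs[:, 0], pairs[:, 1]
    offs = np.arange(w)
    rows = ii[:, None, None] + offs[None, :, None]
    colz = jj[:, None, None] + offs[None, None, :]
    return padded[rows, colz].reshape(len(pairs), w * w)
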