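"""Alignment handling: I/O, identity, effective sequences, gap filtering, PSSM.

The effective number of sequences (Meff) collapses near-identical rows of
an alignment before counting: rows are linked whenever their fractional
identity exceeds a threshold and each connected cluster counts once. Meff
is the usual predictor of how well covariation statistics will work for a
family. The identity threshold is an explicit parameter (default 0.62);
a hook accepting a MeanID-derived callable is provided for callers who
want a data-dependent threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "Msa",
    "Pssm",
    "AMINO_ACIDS",
    "ALPHABET",
    "GAP",
    "BACKGROUND_FREQS",
    "read_msa",
    "pairwise_identity",
    "mean_identity",
    "effective_sequences",
    "filter_gappy_rows",
    "compute_pssm",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
#: 21-state alphabet: the 20 amino acids plus the gap character.
ALPHABET = AMINO_ACIDS + GAP

# Swiss-Prot-style background amino-acid frequencies (order AMINO_ACIDS),
# renormalised after appending a small gap background.
_AA_BACKGROUND = np.array(
    [
        0.0825, 0.0138, 0.0546, 0.0672, 0.0386, 0.0707, 0.0227, 0.0591,
        0.0580, 0.0965, 0.0241, 0.0406, 0.0474, 0.0393, 0.0553, 0.0664,
        0.0535, 0.0686, 0.0110, 0.0292,
    ]
)
_GAP_BACKGROUND = 0.01
BACKGROUND_FREQS = np.concatenate(
    [_AA_BACKGROUND * (1.0 - _GAP_BACKGROUND) / _AA_BACKGROUND.sum(),
     [_GAP_BACKGROUND]]
)

DEFAULT_IDENTITY_THRESHOLD = 0.62


@dataclass
class Msa:
    """A multiple sequence alignment: equal-length rows over 20 aa + gap."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if not self.rows:
            raise ValueError("alignment has no rows")
        ncol = len(self.rows[0])
        for k, row in enumerate(self.rows):
            if len(row) != ncol:
                raise ValueError(
                    f"ragged alignment: row {k} has length {len(row)}, "
                    f"expected {ncol}"
                )

    @property
    def ncol(self) -> int:
        return len(self.rows[0])

    @property
    def nrow(self) -> int:
        return len(self.rows)

    def to_array(self) -> np.ndarray:
        """Integer-encoded alignment, unknown symbols mapped to the gap state."""
        lut = np.full(128, len(ALPHABET) - 1, dtype=np.int8)
        for idx, ch in enumerate(ALPHABET):
            lut[ord(ch)] = idx
        flat = np.frombuffer(
            "".join(r.upper() for r in self.rows).encode("ascii"), dtype=np.uint8
        )
        return lut[flat].reshape(self.nrow, self.ncol)


@dataclass
class Pssm:
    """Per-position log-ratios of observed to background frequencies.

    ``values[i, a]`` = log(freq(a at column i) / background(a)) over the
    21-state alphabet; zero everywhere when observed equals background.
    """

    values: np.ndarray  # (ncol, 21)
    background: np.ndarray  # (21,)

    def to_tsv(self, path) -> None:
        header = "pos\t" + "\t".join(ALPHABET)
        with open(path, "w") as fh:
            fh.write(header + "\n")
            for i, row in enumerate(self.values, start=1):
                fh.write(str(i) + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def read_msa(path, fmt: str | None = None) -> Msa:
    """Read an aligned FASTA or a3m file.

    In a3m, lowercase letters are insertions relative to the query and are
    removed so every row aligns to the (gapless) first row. ``fmt`` is
    inferred from the suffix when not given.
    """
    path = Path(path)
    if fmt is None:
        fmt = "a3m" if path.suffix.lower() == ".a3m" else "fasta"
    if fmt not in ("fasta", "a3m"):
        raise ValueError(f"unknown alignment format {fmt!r}")
    ids, rows = [], []
    current = None
    chunks: list[str] = []
    for line in path.read_text().splitlines():
        if line.startswith(">"):
            if current is not None:
                ids.append(current)
                rows.append("".join(chunks))
            current = line[1:].split()[0] if len(line) > 1 else ""
            chunks = []
        elif line.strip():
            chunks.append(line.strip())
    if current is not None:
        ids.append(current)
        rows.append("".join(chunks))
    if not rows:
        raise ValueError(f"no sequences found in {path}")
    if fmt == "a3m":
        rows = ["".join(c for c in r if not c.islower()) for r in rows]
    rows = [r.upper().replace(".", GAP) for r in rows]
    return Msa(ids=ids, rows=rows)


def pairwise_identity(a: str, b: str) -> float:
    """Fractional identity between two aligned rows.

    Columns gapped in both rows are skipped; a column gapped in exactly
    one row counts as a mismatch.
    """
    if len(a) != len(b):
        raise ValueError("aligned rows must have equal length")
    matches = compared = 0
    for x, y in zip(a.upper(), b.upper()):
        if x == GAP and y == GAP:
            continue
        compared += 1
        if x == y:
            matches += 1
    if compared == 0:
        raise ValueError("no comparable columns between the two rows")
    return matches / compared


def _identity_matrix(arr: np.ndarray) -> np.ndarray:
    """All-pairs fractional identity for an integer-encoded alignment."""
    gap_state = len(ALPHABET) - 1
    n = arr.shape[0]
    ident = np.ones((n, n))
    is_gap = arr == gap_state
    for i in range(n):
        eq = arr[i] == arr  # (n, ncol)
        both_gap = is_gap[i] & is_gap
        compared = (~both_gap).sum(axis=1)
        matches = (eq & ~both_gap).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ident[i] = np.where(compared > 0, matches / np.maximum(compared, 1), 1.0)
    return ident


def mean_identity(msa: Msa) -> float:
    """Mean pairwise identity over all distinct row pairs."""
    if msa.nrow < 2:
        return 1.0
    ident = _identity_matrix(msa.to_array())
    iu = np.triu_indices(msa.nrow, k=1)
    return float(ident[iu].mean())


def effective_sequences(
    msa: Msa,
    identity_threshold: float | None = DEFAULT_IDENTITY_THRESHOLD,
    mode: str = "clusters",
    threshold_fn=None,
) -> float:
    """Effective number of sequences after collapsing near-identical rows.

    Rows with pairwise identity above ``identity_threshold`` are linked;
    clusters are the connected components of that graph.

    ``mode='clusters'`` (default, the reported value) returns the number
    of clusters. ``mode='weights'`` returns the inverse-neighbourhood sum
    Σ_r 1 / |{r' : id(r, r') > threshold}| used by DCA-style reweighting.
    ``threshold_fn``, when given, receives this alignment's mean pairwise
    identity and must return the threshold (overrides the fixed value).
    """
    if threshold_fn is not None:
        identity_threshold = float(threshold_fn(mean_identity(msa)))
    if not (0.0 < identity_threshold < 1.0):
        raise ValueError(
            f"identity threshold must be in (0, 1), got {identity_threshold}"
        )
    if mode not in ("clusters", "weights"):
        raise ValueError(f"unknown mode {mode!r}")
    n = msa.nrow
    if n == 1:
        return 1.0
    ident = _identity_matrix(msa.to_array())
    linked = ident > identity_threshold
    if mode == "weights":
        return float((1.0 / linked.sum(axis=1)).sum())
    np.fill_diagonal(linked, False)
    ncomp, _ = connected_components(csr_matrix(linked), directed=False)
    return float(ncomp)


def filter_gappy_rows(msa: Msa, max_gap_fraction: float = 0.20) -> Msa:
    """Drop rows with more than ``max_gap_fraction`` gaps; keep the query."""
    ids, rows = [], []
    for k, (sid, row) in enumerate(zip(msa.ids, msa.rows)):
        gap_frac = row.count(GAP) / len(row)
        if k == 0 or gap_frac <= max_gap_fraction:
            ids.append(sid)
            rows.append(row)
    return Msa(ids=ids, rows=rows)


def compute_pssm(
    msa: Msa,
    background: np.ndarray | None = None,
    pseudocount: float = 1.0,
) -> Pssm:
    """Position-specific scoring matrix over the 21-state alphabet.

    value(i, a) = log(((f_ia + pseudocount·q_a) / (1 + pseudocount)) / q_a)
    where f_ia is the observed frequency of state a in column i and q the
    background distribution. The background-weighted (additive) pseudocount
    acts on frequencies, not counts, so the matrix is exactly zero when
    observed equals background and is invariant under row duplication.
    """
    if background is None:
        background = BACKGROUND_FREQS
    background = np.asarray(background, dtype=float)
    if background.shape != (len(ALPHABET),):
        raise ValueError(f"background must have {len(ALPHABET)} entries")
    if (background <= 0).any():
        raise ValueError("background frequencies must be strictly positive")
    if not np.isclose(background.sum(), 1.0, atol=1e-6):
        raise ValueError("background frequencies must sum to 1")
    arr = msa.to_array()
    n_rows, ncol = arr.shape
    counts = np.zeros((ncol, len(ALPHABET)))
    for a in range(len(ALPHABET)):
        counts[:, a] = (arr == a).sum(axis=0)
    freqs = (counts / n_rows + pseudocount * background) / (1.0 + pseudocount)
    values = np.log(freqs / background)
    return Pssm(values=values, background=background)
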