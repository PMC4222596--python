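"""Structure I/O: ground-truth contact maps and CASP RR interchange.

A residue pair is in contact when the Euclidean distance between the two
Cβ atoms (Cα for glycine) is at most 8 Å — the CASP contact definition.
Residues without a usable Cβ or Cα coordinate are carried along but
flagged absent; pairs touching an absent residue are masked out of every
downstream count rather than imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning
from Bio.SeqUtils import seq1

__all__ = [
    "ResidueCoordinates",
    "ContactMap",
    "read_structure",
    "contact_map_from_coords",
    "write_rr",
    "read_rr",
]

#: Contact distance cutoff in Å (CASP convention).
DEFAULT_CUTOFF = 8.0

#: Fixed precision used when serialising RR scores.
RR_SCORE_DECIMALS = 6


@dataclass
class ResidueCoordinates:
    """Coordinates of the contact-defining atom of one residue.

    ``position`` holds the Cβ coordinate, or Cα for glycine and for any
    residue whose Cβ is missing from the model; ``present`` is False when
    neither atom is resolved.
    """

    residue_index: int  # 1-based position in the chain
    amino_acid: str  # one-letter code, 'X' for unknowns
    position: np.ndarray  # shape (3,), Å
    present: bool = True


@dataclass
class ContactMap:
    """Symmetric boolean contact matrix with a validity mask.

    ``mask[i, j]`` is True when the pair is observable (both residues have
    coordinates); masked-out pairs never count as contact or non-contact.
    """

    matrix: np.ndarray  # (L, L) bool
    mask: np.ndarray = None  # (L, L) bool, True = usable

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=bool)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("contact matrix must be symmetric")
        if self.matrix.diagonal().any():
            raise ValueError("contact matrix diagonal must be empty")
        if self.mask is None:
            self.mask = np.ones_like(self.matrix, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.matrix.shape:
                raise ValueError("mask shape must match matrix")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]


def _residue_sort_key(res_id):
    """Order residues by number, insertion codes after their base number."""
    hetflag, resseq, icode = res_id
    return (resseq, icode if icode != " " else "")


def _pick_altloc(atom):
    """Highest-occupancy conformer wins; ties go to the first encountered."""
    if atom.is_disordered():
        best = max(
            atom.disordered_get_list(),
            key=lambda a: (a.get_occupancy() or 0.0),
        )
        return best
    return atom


def read_structure(path, chain: str) -> list[ResidueCoordinates]:
    """Read one chain of a PDB file into per-residue coordinates.

    Parameters
    ----------
    path : str or Path
        PDB file.
    chain : str
        Chain identifier within the first model.

    Returns
    -------
    list of ResidueCoordinates, ordered by residue number (insertion codes
    after their base number), 1-based ``residue_index`` assigned by rank.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = PDBParser(QUIET=True).get_structure("s", str(path))
    model = next(structure.get_models())
    chain_ids = [c.id for c in model]
    if chain not in chain_ids:
        raise KeyError(f"chain {chain!r} not found; available: {chain_ids}")
    residues = [r for r in model[chain] if r.id[0] == " "]
    residues.sort(key=lambda r: _residue_sort_key(r.id))

    out: list[ResidueCoordinates] = []
    for rank, res in enumerate(residues, start=1):
        aa = seq1(res.get_resname(), undef_code="X")
        is_gly = res.get_resname().upper() == "GLY"
        atom = None
        if not is_gly and "CB" in res:
            atom = _pick_altloc(res["CB"])
        elif "CA" in res:
            atom = _pick_altloc(res["CA"])
        if atom is None:
            out.append(
                ResidueCoordinates(rank, aa, np.full(3, np.nan), present=False)
            )
        else:
            out.append(
                ResidueCoordinates(rank, aa, np.asarray(atom.get_coord(), float))
            )
    if not any(r.present for r in out):
        raise ValueError(f"chain {chain!r} has no usable residue coordinates")
    return out


def contact_map_from_coords(
    coords: list[ResidueCoordinates], cutoff: float = DEFAULT_CUTOFF
) -> ContactMap:
    """Build the boolean contact map from residue coordinates.

    Pair (i, j) is a contact iff the distance is ≤ ``cutoff`` (default 8 Å).
    Pairs involving a residue without coordinates are masked; the diagonal
    is always False and masked.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    present = np.array([r.present for r in coords], dtype=bool)
    if present.sum() < 2:
        raise ValueError("need at least two residues with coordinates")
    pos = np.array([r.position for r in coords], dtype=float)
    L = len(coords)
    with np.errstate(invalid="ignore"):
        diff = pos[:, None, :] - pos[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=-1))
    matrix = np.zeros((L, L), dtype=bool)
    ok = present[:, None] & present[None, :]
    matrix[ok] = dist[ok] <= cutoff
    np.fill_diagonal(matrix, False)
    mask = ok.copy()
    np.fill_diagonal(mask, False)
    return ContactMap(matrix=matrix, mask=mask)


def write_rr(pred, sequence: str, path) -> None:
    """Write a prediction map in CASP RR format.

    Header is the sequence; records are ``i j 0 8 score`` with i<j,
    1-based, scores rounded to :data:`RR_SCORE_DECIMALS` decimals.
    Zero-score pairs are omitted.
    """
    scores = np.asarray(pred.scores if hasattr(pred, "scores") else pred, float)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    L = scores.shape[0]
    with open(path, "w") as fh:
        fh.write(sequence + "\n")
        for i in range(L):
            for j in range(i + 1, L):
                s = scores[i, j]
                if s != 0.0:
                    fh.write(f"{i + 1} {j + 1} 0 8 {s:.{RR_SCORE_DECIMALS}f}\n")


def read_rr(path, length: int | None = None):
    """Read a CASP RR file into a symmetric score matrix.

    Returns ``(scores, sequence)``. Records with j<i are normalised to
    i<j. ``length`` defaults to the header-sequence length.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError("empty RR file")
    sequence = lines[0].strip()
    L = length if length is not None else len(sequence)
    scores = np.zeros((L, L), dtype=float)
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip() or line.startswith(("PFRMAT", "TARGET", "MODEL", "END")):
            continue
        parts = line.split()
        try:
            i, j = int(parts[0]), int(parts[1])
            s = float(parts[4]) if len(parts) >= 5 else float(parts[2])
        except (ValueError, IndexError) as exc:
            raise ValueError(f"malformed RR record at line {lineno}: {line!r}") from exc
        if not (1 <= i <= L and 1 <= j <= L):
            raise ValueError(f"residue index out of range at line {lineno}")
        if j < i:
            i, j = j, i
        scores[i - 1, j - 1] = s
        scores[j - 1, i - 1] = s
    return scores, sequence
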