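"""Evaluation statistics for contact predictions.

The central metric is the top-αL positive predictive value: rank all
residue pairs at sequence separation ≥ 5 by predicted score, keep the
⌈α·L⌉ best, and report the fraction that are true contacts (α = 1 is one
prediction per residue). Breakdowns by separation range (short 6–12,
medium 12–24, long ≥ 24, with L/10 predictions per range), by the
secondary-structure category of the two residues, by family depth
(running PPV against Meff), and the w×w neighbour-count statistics of
contact maps are provided alongside.

Score ties are broken by (separation descending, then i, then j) so every
ranking is deterministic. Masked truth pairs are excluded from both the
ranking and the counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter

__all__ = [
    "EvalReport",
    "top_l_ppv",
    "ranked_pairs",
    "ppv_by_separation",
    "ppv_by_ss_category",
    "window_contact_statistics",
    "ppv_vs_meff",
    "isolated_prediction_count",
    "SS_CATEGORIES",
]

DEFAULT_MIN_SEPARATION = 5
#: (label, lowest separation, highest separation); boundary pairs go to
#: the lower-labelled range, long has no upper bound.
DEFAULT_SEPARATION_RANGES = (
    ("short", 6, 12),
    ("medium", 13, 24),
    ("long", 25, None),
)

_SS_NAME = {"H": "helix", "E": "strand", "C": "loop"}
SS_CATEGORIES = (
    "helix-helix",
    "helix-strand",
    "helix-loop",
    "strand-strand",
    "strand-loop",
    "loop-loop",
)


def _scores(pred):
    return pred.scores if hasattr(pred, "scores") else np.asarray(pred, float)


def _truth_parts(truth):
    if hasattr(truth, "matrix"):
        return truth.matrix, truth.mask
    m = np.asarray(truth, bool)
    return m, np.ones_like(m)


def ranked_pairs(pred, truth, min_sep: int = DEFAULT_MIN_SEPARATION):
    """Unmasked pairs i<j at separation ≥ min_sep, best score first.

    Ties broken by separation (descending), then i, then j.
    """
    s = _scores(pred)
    matrix, mask = _truth_parts(truth)
    L = s.shape[0]
    if matrix.shape[0] != L:
        raise ValueError("prediction and truth have different lengths")
    iu = np.triu_indices(L, k=max(min_sep, 1))
    keep = mask[iu]
    ii, jj = iu[0][keep], iu[1][keep]
    if len(ii) == 0:
        raise ValueError("no eligible pairs at this separation")
    sep = jj - ii
    order = np.lexsort((jj, ii, -sep, -s[ii, jj]))
    return ii[order], jj[order], matrix[ii, jj][order]


def top_l_ppv(
    pred,
    truth,
    alpha: float = 1.0,
    min_sep: int = DEFAULT_MIN_SEPARATION,
) -> float:
    """PPV over the top ⌈α·L⌉ ranked pairs."""
    matrix, _ = _truth_parts(truth)
    L = matrix.shape[0]
    ii, jj, hits = ranked_pairs(pred, truth, min_sep)
    n_take = min(int(np.ceil(alpha * L)), len(ii))
    if n_take == 0:
        raise ValueError("alpha too small: zero predictions taken")
    return float(hits[:n_take].sum() / n_take)


def ppv_by_separation(
    pred,
    truth,
    ranges=DEFAULT_SEPARATION_RANGES,
    per_class_count: float | None = None,
) -> dict:
    """PPV per separation range, top ⌈L/10⌉ predictions within each range.

    Ranges with no eligible pair report None (undefined), never 0.
    """
    s = _scores(pred)
    matrix, mask = _truth_parts(truth)
    L = s.shape[0]
    n_take_default = int(np.ceil(L / 10)) if per_class_count is None else int(
        np.ceil(per_class_count)
    )
    out = {}
    for label, lo, hi in ranges:
        iu = np.triu_indices(L, k=lo)
        sep = iu[1] - iu[0]
        keep = mask[iu]
        if hi is not None:
            keep &= sep <= hi
        ii, jj = iu[0][keep], iu[1][keep]
        if len(ii) == 0:
            out[label] = None
            continue
        sep = jj - ii
        order = np.lexsort((jj, ii, -sep, -s[ii, jj]))
        take = order[: min(n_take_default, len(order))]
        out[label] = float(matrix[ii[take], jj[take]].mean())
    return out


def ppv_by_ss_category(
    pred,
    truth,
    ss_classes,
    alpha: float = 1.0,
    min_sep: int = DEFAULT_MIN_SEPARATION,
) -> dict:
    """Global top-αL predictions, categorized by the residues' SS classes.

    ``ss_classes`` is a length-L string or sequence over {H, E, C}.
    Returns ``{category: {"ppv": float|None, "fraction": float}}``; the
    fractions sum to 1 over the taken predictions.
    """
    ss = list(ss_classes)
    matrix, _ = _truth_parts(truth)
    L = matrix.shape[0]
    if len(ss) != L:
        raise ValueError("SS classes must cover every residue")
    for c in ss:
        if c not in _SS_NAME:
            raise ValueError(f"unknown secondary-structure class {c!r}")
    ii, jj, hits = ranked_pairs(pred, truth, min_sep)
    n_take = min(int(np.ceil(alpha * L)), len(ii))
    counts = {c: 0 for c in SS_CATEGORIES}
    correct = {c: 0 for c in SS_CATEGORIES}
    for i, j, hit in zip(ii[:n_take], jj[:n_take], hits[:n_take]):
        a, b = sorted((_SS_NAME[ss[i]], _SS_NAME[ss[j]]), key="helix strand loop".split().index)
        cat = f"{a}-{b}"
        counts[cat] += 1
        correct[cat] += int(hit)
    return {
        cat: {
            "ppv": (correct[cat] / counts[cat]) if counts[cat] else None,
            "fraction": counts[cat] / n_take,
        }
        for cat in SS_CATEGORIES
    }


def window_contact_statistics(maps, w: int = 3):
    """Neighbour-contact histograms conditioned on the centre's state.

    For every interior cell (i, j), i ≠ j, of each map, count the contacts
    among the w×w neighbourhood excluding the centre. Returns two
    normalised histograms over 0..w²−1 neighbour counts: the first
    conditioned on the centre being a contact, the second on it not.
    """
    if w % 2 != 1:
        raise ValueError("window width must be odd")
    half = w // 2
    n_bins = w * w
    hist_c = np.zeros(n_bins)
    hist_n = np.zeros(n_bins)
    for cm in maps:
        matrix, _ = _truth_parts(cm)
        L = matrix.shape[0]
        if L < w:
            continue
        m = matrix.astype(int)
        sums = uniform_filter(m.astype(float), size=w, mode="constant") * (w * w)
        sums = np.rint(sums).astype(int)
        neigh = sums - m
        interior = np.zeros((L, L), dtype=bool)
        interior[half : L - half, half : L - half] = True
        np.fill_diagonal(interior, False)
        for centre_state, hist in ((1, hist_c), (0, hist_n)):
            sel = interior & (m == centre_state)
            counts = neigh[sel]
            hist += np.bincount(counts, minlength=n_bins)[:n_bins]
    for hist in (hist_c, hist_n):
        total = hist.sum()
        if total > 0:
            hist /= total
    return hist_c, hist_n


def ppv_vs_meff(results, frame: int = 20):
    """Running-average PPV against family depth.

    ``results`` is a sequence of (meff, ppv) pairs. Families are sorted by
    Meff and a sliding mean of width ``frame`` is taken; frame = 1 returns
    the sorted raw points, frame > n collapses to one global mean point.
    """
    results = sorted((float(m), float(p)) for m, p in results)
    if not results:
        raise ValueError("need at least one family")
    meffs = np.array([m for m, _ in results])
    ppvs = np.array([p for _, p in results])
    n = len(results)
    if frame > n:
        return np.array([meffs.mean()]), np.array([ppvs.mean()])
    kernel = np.ones(frame) / frame
    return (
        np.convolve(meffs, kernel, mode="valid"),
        np.convolve(ppvs, kernel, mode="valid"),
    )


def isolated_prediction_count(
    pred,
    truth,
    alpha: float = 1.0,
    min_sep: int = DEFAULT_MIN_SEPARATION,
) -> int:
    """Number of top-αL predictions with no other top prediction in their
    3×3 neighbourhood — the "sporadic isolated" predictions a
    receptive-field stack is expected to suppress."""
    matrix, _ = _truth_parts(truth)
    L = matrix.shape[0]
    ii, jj, _ = ranked_pairs(pred, truth, min_sep)
    n_take = min(int(np.ceil(alpha * L)), len(ii))
    chosen = np.zeros((L, L), dtype=bool)
    chosen[ii[:n_take], jj[:n_take]] = True
    chosen[jj[:n_take], ii[:n_take]] = True
    n_isolated = 0
    for i, j in zip(ii[:n_take], jj[:n_take]):
        neigh = chosen[
            max(0, i - 1) : min(L, i + 2), max(0, j - 1) : min(L, j + 2)
        ].sum()
        # the pair itself is marked at (i, j); its mirror is outside the
        # window except right at the diagonal
        if neigh - 1 == 0:
            n_isolated += 1
    return n_isolated


@dataclass
class EvalReport:
    """Per-family evaluation results plus set-level summaries.

    ``per_family`` rows hold the family identifier, its PPV at each
    requested α, optional breakdowns, and Meff when known. The reported
    set-level PPV is the mean of per-family PPVs.
    """

    alphas: tuple = (1.0,)
    per_family: list[dict] = field(default_factory=list)

    def add(self, name, pred, truth, ss_classes=None, meff=None,
            min_sep: int = DEFAULT_MIN_SEPARATION):
        row = {"family": str(name)}
        for a in self.alphas:
            row[f"ppv@{a:g}L"] = top_l_ppv(pred, truth, alpha=a, min_sep=min_sep)
        row["by_separation"] = ppv_by_separation(pred, truth)
        if ss_classes is not None:
            row["by_ss_category"] = ppv_by_ss_category(
                pred, truth, ss_classes, min_sep=min_sep
            )
        if meff is not None:
            row["meff"] = float(meff)
        self.per_family.append(row)
        return row

    def mean_ppv(self, alpha: float = 1.0) -> float:
        key = f"ppv@{alpha:g}L"
        vals = [r[key] for r in self.per_family if key in r]
        if not vals:
            raise ValueError("no families evaluated at this alpha")
        return float(np.mean(vals))

    def to_json(self, path) -> None:
        summary = {
            f"mean_ppv@{a:g}L": self.mean_ppv(a) for a in self.alphas
        }
        with open(path, "w") as fh:
            json.dump(
                {"summary": summary, "families": self.per_family}, fh, indent=2
            )

    def to_tsv(self, path) -> None:
        cols = ["family"] + [f"ppv@{a:g}L" for a in self.alphas] + ["meff"]
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for row in self.per_family:
                fh.write(
                    "\t".join(
                        str(row.get(c, "")) for c in cols
                    )
                    + "\n"
                )
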