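"""Protein-like synthetic families: topologies, noisy base maps, surrogates.

Real contact maps are not random scatter: helices lay down short |i−j| ∈
{3, 4} ladders near the diagonal, paired β-strands produce diagonal
(parallel) or anti-diagonal (antiparallel) ladders where a contact at
(i, j) implies contacts at (i±1, j∓1), and packed helices leave broad
anti-diagonal stripes. The generator reproduces exactly this neighbourhood
structure — the property the stacked learner exploits — without any claim
of physical realism in 3D.

Base prediction maps emulate coevolution-method outputs: the truth scaled
by a signal strength, plus rectified Gaussian noise, plus separately
controlled *clustered* and *isolated* false-positive peaks. Isolated
peaks are the "sporadic" errors a receptive-field learner should filter;
keeping their rate a separate dial makes that behaviour testable.

Surrogate per-residue tables (SS probabilities, PSSM, RSA) are derived
from the true secondary-structure string with class-conditional noise;
their job is to carry recoverable signal, not biological realism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .baseline import PredictionMap
from .msa import ALPHABET, AMINO_ACIDS, BACKGROUND_FREQS, Pssm
from .structio import ContactMap

__all__ = [
    "SyntheticFamily",
    "generate_topology",
    "simulate_base_maps",
    "generate_family",
    "generate_dataset",
]

# Segment-length ranges (residues): typical for globular domains.
HELIX_LEN = (6, 14)
STRAND_LEN = (5, 9)
COIL_LEN = (2, 6)

#: Default number of base prediction maps per family.
DEFAULT_N_BASE_MAPS = 4
#: Default signal-strength range: base-map top-L precision in the range
#: coevolution methods reach on mid-sized families.
DEFAULT_SIGNAL_RANGE = (0.9, 1.9)
DEFAULT_FP_RATE = 0.04
DEFAULT_ISOLATED_FP_RATE = 0.8

# PSSM class signatures: amino acids enriched in each SS class.
_CLASS_ENRICHED = {
    "H": "AELMQ",
    "E": "VIFYW",
    "C": "GPSND",
}
# Mean relative surface accessibility per class (strands most buried).
_RSA_MEAN = {"H": 0.40, "E": 0.28, "C": 0.58}


@dataclass
class SyntheticFamily:
    """One generated family: truth, noisy base maps, and feature surrogates."""

    length: int
    ss_string: str
    truth: ContactMap
    base_maps: list[PredictionMap]
    pssm: Pssm
    ss: np.ndarray  # (L, 3) class probabilities
    rsa: np.ndarray  # (L, 5): rsa, z-fit, 3 SS probabilities
    sequence: str
    meff_surrogate: float
    seed: int


def _sample_segments(rng, length, composition):
    """Lay down H/E/C segments left to right until ``length`` is filled."""
    p = np.asarray(composition, dtype=float)
    if not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError("composition fractions must sum to 1")
    shortest = min(HELIX_LEN[0], STRAND_LEN[0], COIL_LEN[0])
    if length < shortest:
        raise ValueError(f"length {length} shorter than the shortest segment")
    ranges = {"H": HELIX_LEN, "E": STRAND_LEN, "C": COIL_LEN}
    # weight segment-type draws by target fraction / expected length so the
    # realised residue composition tracks the requested fractions
    exp_len = np.array([np.mean(ranges[c]) for c in "HEC"])
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(p > 0, p / exp_len, 0.0)
    segments = []
    pos = 0
    prev = None
    while pos < length:
        wk = w.copy()
        if prev is not None and prev != "C" and w[2] > 0:
            # favour a coil linker between consecutive structured segments
            wk = np.array([0.0, 0.0, 1.0]) if rng.random() < 0.7 else wk
        wk = wk / wk.sum()
        kind = "HEC"[rng.choice(3, p=wk)]
        lo, hi = ranges[kind]
        seg_len = min(int(rng.integers(lo, hi + 1)), length - pos)
        segments.append((kind, pos, pos + seg_len))
        pos += seg_len
        prev = kind
    return segments


def generate_topology(seed, length: int, composition=(0.35, 0.30, 0.35)):
    """Generate an SS string and its implied contact map.

    ``composition`` gives target (helix, strand, coil) residue fractions.
    Helices contribute |i−j| ∈ {3, 4} local contacts and anti-diagonal
    packing stripes between paired helices; paired strands contribute
    parallel (diagonal) or antiparallel (anti-diagonal) ladders.
    """
    rng = np.random.default_rng(seed)
    segments = _sample_segments(rng, length, composition)
    ss = np.empty(length, dtype="U1")
    for kind, a, b in segments:
        ss[a:b] = kind
    contacts = np.zeros((length, length), dtype=bool)

    def add(i, j):
        if 0 <= i < length and 0 <= j < length and i != j:
            contacts[i, j] = contacts[j, i] = True

    helices = [(a, b) for kind, a, b in segments if kind == "H"]
    strands = [(a, b) for kind, a, b in segments if kind == "E"]

    # helix-local ladder
    for a, b in helices:
        for i in range(a, b):
            for d in (3, 4):
                if i + d < b:
                    add(i, i + d)

    # strand pairing: every consecutive strand pairs (sheet order follows
    # sequence order, hairpins dominating); with three or more strands the
    # sheet closes between the first and last strand
    pairs = list(zip(strands, strands[1:]))
    if len(strands) >= 3 and rng.random() < 0.6:
        pairs.append((strands[0], strands[-1]))
    for (a1, b1), (a2, b2) in pairs:
        n = min(b1 - a1, b2 - a2)
        antiparallel = rng.random() < 0.7
        for t in range(n):
            if antiparallel:
                i, j = a1 + t, b2 - 1 - t
            else:
                i, j = a1 + t, a2 + t
            add(i, j)
            # ladders are a few cells wide in real maps (H-bond + sidechain)
            add(i, j + 1)
            add(i, j - 1)

    # helix-helix packing stripes between sequence-adjacent helices:
    # partially occupied, less regular than strand ladders
    for (a1, b1), (a2, b2) in zip(helices, helices[1:]):
        if rng.random() < 0.8:
            n = min(b1 - a1, b2 - a2)
            for t in range(n):
                i, j = a1 + t, b2 - 1 - t
                if rng.random() < 0.7:
                    add(i, j)
                if rng.random() < 0.4:
                    add(i, j - 1)

    # occasional tertiary packing between sequence-distant segments
    structured = [(a, b) for kind, a, b in segments if kind != "C"]
    if len(structured) >= 3 and rng.random() < 0.7:
        (a1, b1), (a2, b2) = structured[0], structured[-1]
        n = min(b1 - a1, b2 - a2)
        for t in range(n):
            if rng.random() < 0.8:
                add(a1 + t, b2 - 1 - t)

    # a folded chain with two or more structured segments always packs
    # somewhere: force one interface if none of the draws above made one
    iu = np.triu_indices(length, k=5)
    if len(structured) >= 2 and not contacts[iu].any():
        (a1, b1), (a2, b2) = sorted(
            structured, key=lambda s: s[1] - s[0], reverse=True
        )[:2]
        n = min(b1 - a1, b2 - a2)
        for t in range(n):
            add(a1 + t, b2 - 1 - t)
            add(a1 + t, b2 - 2 - t)
    return "".join(ss), ContactMap(matrix=contacts)


def simulate_base_maps(
    truth: ContactMap,
    k: int = DEFAULT_N_BASE_MAPS,
    signal: float = 2.0,
    fp_rate: float = DEFAULT_FP_RATE,
    isolated_fp_rate: float = DEFAULT_ISOLATED_FP_RATE,
    detection_budget: float | None = None,
    seed=0,
) -> list[PredictionMap]:
    """k noisy score maps correlated with the truth.

    score(i, j) = max(0, signal·truth(i, j) + N(0, 1)) plus clustered 3×3
    false-positive blobs (about ``fp_rate``·L per map) and isolated
    single-pair peaks (about ``isolated_fp_rate``·L per map). Maps share
    the truth but carry independent noise.

    Coevolution methods resolve roughly a fixed number of strong couplings
    per family — set by alignment depth, not by how many contacts the fold
    has — and predictors run on the same alignment resolve largely the
    same ones. A single family-level random subset of about
    ``detection_budget``·L true contacts (the budget usually binds below L) therefore receives full signal in
    every map; the rest keep a weak residual (15 % of the signal).
    Contact-dense folds then saturate neither the base maps nor the flat
    classifier, and the undetected ladder rungs are recoverable only from
    map context. ``None`` disables the budget.
    """
    if signal < 0:
        raise ValueError("signal must be >= 0")
    if not (0 <= fp_rate <= 1 and 0 <= isolated_fp_rate <= 1):
        raise ValueError("false-positive rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    L = truth.length
    t = truth.matrix.astype(float)
    maps = []
    iu = np.triu_indices(L, k=1)
    contact_pairs = np.flatnonzero(truth.matrix[iu])
    amp = np.zeros((L, L))
    amp[iu] = signal * t[iu]
    if detection_budget is not None and len(contact_pairs) > 0:
        budget = int(round(detection_budget * L))
        if budget < len(contact_pairs):
            undetected = rng.choice(
                contact_pairs,
                size=len(contact_pairs) - budget,
                replace=False,
            )
            vals = amp[iu]
            vals[undetected] *= 0.15
            amp[iu] = vals
    amp = amp + amp.T
    for m in range(k):
        noise = np.zeros((L, L))
        noise[iu] = rng.standard_normal(len(iu[0]))
        noise = noise + noise.T
        scores = amp + noise

        def peaks(n_events, clustered):
            for _ in range(n_events):
                i = int(rng.integers(0, L))
                j = int(rng.integers(0, L))
                if abs(i - j) < 5:
                    continue
                amp = signal * rng.uniform(0.8, 1.3)
                if clustered:
                    for di in (-1, 0, 1):
                        for dj in (-1, 0, 1):
                            a, b = i + di, j + dj
                            if 0 <= a < L and 0 <= b < L and a != b:
                                scores[a, b] += amp * rng.uniform(0.5, 1.0)
                                scores[b, a] = scores[a, b]
                elif i != j:
                    scores[i, j] += amp
                    scores[j, i] = scores[i, j]

        peaks(int(round(fp_rate * L)), clustered=True)
        peaks(int(round(isolated_fp_rate * L)), clustered=False)
        scores = np.maximum(scores, 0.0)
        scores = (scores + scores.T) / 2.0
        np.fill_diagonal(scores, 0.0)
        maps.append(PredictionMap(scores, method_tag=f"synthetic-{m}"))
    return maps


def _surrogate_tables(rng, ss_string):
    """Noisy SS-probability, PSSM and RSA tables from the true SS string."""
    L = len(ss_string)
    cls_idx = np.array(["HEC".index(c) for c in ss_string])

    logits = rng.normal(0.0, 0.8, size=(L, 3))
    logits[np.arange(L), cls_idx] += 1.1
    ss_probs = np.exp(logits)
    ss_probs /= ss_probs.sum(axis=1, keepdims=True)

    # PSSM surrogate: class-enriched residues get positive log-ratios
    values = rng.normal(0.0, 0.25, size=(L, len(ALPHABET)))
    for i, c in enumerate(ss_string):
        for aa in _CLASS_ENRICHED[c]:
            values[i, AMINO_ACIDS.index(aa)] += 0.8
    values[:, -1] = rng.normal(-1.0, 0.1, size=L)  # gap state depleted
    pssm = Pssm(values=values, background=BACKGROUND_FREQS.copy())

    rsa_val = np.clip(
        np.array([_RSA_MEAN[c] for c in ss_string]) + rng.normal(0, 0.12, L),
        0.0,
        1.0,
    )
    zfit = rng.uniform(0.5, 1.0, L)
    logits2 = rng.normal(0.0, 0.9, size=(L, 3))
    logits2[np.arange(L), cls_idx] += 0.9
    rsa_ss = np.exp(logits2)
    rsa_ss /= rsa_ss.sum(axis=1, keepdims=True)
    rsa = np.column_stack([rsa_val, zfit, rsa_ss])

    # a plausible sequence consistent with the class enrichments
    seq = []
    for c in ss_string:
        if rng.random() < 0.5:
            seq.append(_CLASS_ENRICHED[c][rng.integers(len(_CLASS_ENRICHED[c]))])
        else:
            seq.append(AMINO_ACIDS[rng.choice(20, p=BACKGROUND_FREQS[:20] / BACKGROUND_FREQS[:20].sum())])
    return ss_probs, pssm, rsa, "".join(seq)


def generate_family(
    seed,
    length: int = 80,
    composition=(0.35, 0.30, 0.35),
    n_base_maps: int = DEFAULT_N_BASE_MAPS,
    signal: float = 2.0,
    fp_rate: float = DEFAULT_FP_RATE,
    isolated_fp_rate: float = DEFAULT_ISOLATED_FP_RATE,
) -> SyntheticFamily:
    """One fully featured synthetic family, deterministic per seed."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_topo, s_maps, s_feat = ss.spawn(3)
    ss_string, truth = generate_topology(s_topo, length, composition)
    base_maps = simulate_base_maps(
        truth,
        k=n_base_maps,
        signal=signal,
        fp_rate=fp_rate,
        isolated_fp_rate=isolated_fp_rate,
        seed=s_maps,
    )
    rng = np.random.default_rng(s_feat)
    ss_probs, pssm, rsa, seq = _surrogate_tables(rng, ss_string)
    # a crude Meff stand-in: more signal behaves like a deeper alignment
    meff_surrogate = float(np.exp(2.0 * signal))
    if isinstance(seed, np.random.SeedSequence):
        seed = seed.entropy if isinstance(seed.entropy, int) else 0
    return SyntheticFamily(
        length=length,
        ss_string=ss_string,
        truth=truth,
        base_maps=base_maps,
        pssm=pssm,
        ss=ss_probs,
        rsa=rsa,
        sequence=seq,
        meff_surrogate=meff_surrogate,
        seed=int(seed) if isinstance(seed, (int, np.integer)) else 0,
    )


def generate_dataset(
    n_families: int,
    seed: int = 0,
    length_range=(70, 90),
    signal_range=DEFAULT_SIGNAL_RANGE,
    composition=None,
    n_base_maps: int = DEFAULT_N_BASE_MAPS,
    fp_rate: float = DEFAULT_FP_RATE,
    isolated_fp_rate: float = DEFAULT_ISOLATED_FP_RATE,
) -> list[SyntheticFamily]:
    """A list of varied families, deterministic per seed.

    Lengths are uniform over ``length_range`` and signal strengths uniform
    over ``signal_range`` (emulating the family-depth spread of real
    benchmark sets). ``composition`` fixes the H/E/C fractions for every
    family when given; by default each family draws its own mix.
    """
    if n_families < 1:
        raise ValueError("need at least one family")
    root = np.random.SeedSequence(seed)
    fam_seeds = root.spawn(n_families)
    rng = np.random.default_rng(root.spawn(1)[0])
    out = []
    for fs in fam_seeds:
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        signal = float(rng.uniform(*signal_range))
        if composition is None:
            h = rng.uniform(0.2, 0.55)
            e = rng.uniform(0.15, 0.5)
            c = max(1.0 - h - e, 0.15)
            comp = np.array([h, e, c])
            comp = comp / comp.sum()
        else:
            comp = composition
        out.append(
            generate_family(
                fs,
                length=length,
                composition=tuple(comp),
                n_base_maps=n_base_maps,
                signal=signal,
                fp_rate=fp_rate,
                isolated_fp_rate=isolated_fp_rate,
            )
        )
    return out
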