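"""The multi-layer stacked learner with receptive-field feedback.

Layer 0 is an ordinary per-pair classifier: it sees only the fixed
feature vector of each residue pair. Every later layer additionally sees
the receptive field — the square window of the previous layer's predicted
contact probabilities around (i, j) — and so can learn the neighbourhood
patterns (β-ladders, helix stripes) that distinguish real contacts from
sporadic isolated false positives.

During training, the fields fed to layer t default to the layer t−1
forest's own predictions on the training families (``in_fold``): the
min-leaf constraint keeps those maps far from memorized labels, and they
match the distribution of the fields the stack produces at prediction
time. Two guarded alternatives exist. ``oob`` scores each pair in the
fit sample only by the trees whose bootstrap draw excluded it (honest
feedback at no extra fits, but averaged over ~37 % of the trees, hence
noisier than the full-forest fields seen at prediction time).
``out_of_fold`` is classical stacked generalization with family-level
folds; its fold models are trained on fewer families and produce fields
that mismatch the full model's, a shift that compounds across layers
and measurably degrades the deeper layers.

Each layer is a random forest (100 trees, at least 500 samples per leaf
by default) — shallow enough to generalise from heavily unbalanced pair
data — but any classifier exposing ``fit``/``predict_proba`` can be
plugged in. Pooled training vectors are capped per fit by a seeded
subsample that keeps every positive pair, which bounds the cost of a
layer fit independently of the number of training families.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .baseline import PredictionMap
from .features import FeatureConfig, encode_family, receptive_fields_batch
from .evaluate import top_l_ppv

__all__ = ["StackConfig", "Stack", "train_stack", "predict", "save_stack", "load_stack"]

logger = logging.getLogger(__name__)

ARCHIVE_FORMAT_VERSION = 1


@dataclass(frozen=True)
class StackConfig:
    """Architecture and training-protocol parameters."""

    n_layers: int = 5
    n_trees: int = 100
    min_samples_leaf: int = 500
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    min_separation: int = 5  # pairs closer in sequence are never scored
    seed: int = 0
    oof_folds: int = 5  # internal split, used in out_of_fold mode
    oof_mode: str = "in_fold"  # or "oob" / "out_of_fold"
    max_train_samples: int = 60000  # per-fit cap on pooled vectors

    def __post_init__(self):
        if self.n_layers < 1:
            raise ValueError("need at least one layer")
        if self.n_trees < 1 or self.min_samples_leaf < 1:
            raise ValueError("invalid learner parameters")
        if self.oof_mode not in ("oob", "in_fold", "out_of_fold"):
            raise ValueError(f"unknown oof_mode {self.oof_mode!r}")
        if self.oof_folds < 2:
            raise ValueError("need at least two internal folds")


@dataclass
class Stack:
    """Trained layer models plus everything needed to reproduce predictions."""

    layers: list
    config: StackConfig
    layer_train_ppv: list[float] = field(default_factory=list)
    fold_assignment: list[int] = field(default_factory=list)
    probe: dict | None = None


# ---------------------------------------------------------------------------
# family plumbing


def _as_scores(m):
    return m.scores if isinstance(m, PredictionMap) else np.asarray(m, float)


def _family_arrays(family, cfg: FeatureConfig):
    """Extract (base_maps, pssm, ss, rsa, truth) arrays from a family object."""
    base = [_as_scores(m) for m in family.base_maps[: cfg.n_base_maps]]
    if len(base) < cfg.n_base_maps:
        raise ValueError(
            f"family provides {len(base)} base maps, config needs {cfg.n_base_maps}"
        )
    pssm = getattr(family, "pssm", None)
    pssm = pssm.values if hasattr(pssm, "values") else pssm
    ss = getattr(family, "ss", None)
    rsa = getattr(family, "rsa", None)
    return base, pssm, ss, rsa


def _eligible_pairs(L: int, min_sep: int, mask: np.ndarray | None = None):
    iu = np.triu_indices(L, k=min_sep)
    pairs = np.column_stack(iu)
    if mask is not None:
        keep = mask[pairs[:, 0], pairs[:, 1]]
        pairs = pairs[keep]
    return pairs


def _ordinary_features(family, cfg: FeatureConfig, min_sep: int):
    base, pssm, ss, rsa = _family_arrays(family, cfg)
    L = base[0].shape[0]
    pairs = _eligible_pairs(L, min_sep, family.truth.mask if hasattr(family, "truth") and family.truth is not None else None)
    X = encode_family(pairs, base, cfg, pssm=pssm, ss=ss, rsa=rsa)
    return pairs, X, L


def _pairs_to_map(pairs: np.ndarray, probs: np.ndarray, L: int) -> np.ndarray:
    out = np.zeros((L, L), dtype=np.float32)
    out[pairs[:, 0], pairs[:, 1]] = probs
    out[pairs[:, 1], pairs[:, 0]] = probs
    return out


# ---------------------------------------------------------------------------
# learner


def _make_learner(config: StackConfig, seed: int):
    return RandomForestClassifier(
        n_estimators=config.n_trees,
        min_samples_leaf=config.min_samples_leaf,
        n_jobs=1,
        random_state=int(seed) % (2**31),
    )


def _subsample_indices(y, cap, rng):
    """Seeded cap on training vectors keeping the whole positive class."""
    n = len(y)
    if n <= cap:
        return np.arange(n)
    pos = np.flatnonzero(y)
    neg = np.flatnonzero(~y)
    if len(pos) >= cap:
        keep = rng.choice(pos, size=cap, replace=False)
    else:
        fill = rng.choice(neg, size=cap - len(pos), replace=False)
        keep = np.concatenate([pos, fill])
    keep.sort()
    return keep


def _subsample(X, y, cap, rng):
    keep = _subsample_indices(y, cap, rng)
    return X[keep], y[keep]


def _fit(X, y, config: StackConfig, seed: int, rng, oob: bool = False):
    """Fit one layer model on a seeded subsample; returns (model, indices)."""
    if not y.any():
        raise ValueError("empty positive class: no contacts in training data")
    keep = _subsample_indices(y, config.max_train_samples, rng)
    model = _make_learner(config, seed)
    if oob:
        model.set_params(oob_score=True, bootstrap=True)
    with warnings.catch_warnings():
        # OOB probabilities are undefined for the rare sample that every
        # bootstrap draw happened to include; handled via NaN fallback
        warnings.filterwarnings("ignore", message="Some inputs do not have OOB")
        model.fit(X[keep], y[keep])
    return model, keep


def _oob_proba(model, y_fit):
    """Out-of-bag contact probabilities for the fitted samples (NaN where
    a sample was in every bootstrap draw)."""
    dec = getattr(model, "oob_decision_function_", None)
    if dec is None:
        return None
    if dec.shape[1] == 1:
        return np.full(len(y_fit), float(model.classes_[0]))
    return dec[:, list(model.classes_).index(True)]


def _proba(model, X):
    p = model.predict_proba(X)
    if p.shape[1] == 1:  # degenerate single-class fit
        return np.full(len(X), float(model.classes_[0]))
    return p[:, list(model.classes_).index(True)]


# ---------------------------------------------------------------------------
# training


def train_stack(families, config: StackConfig | None = None) -> Stack:
    """Train the layered stack on a list of feature-complete families.

    Each family must expose ``truth`` (a ContactMap), ``base_maps``, and —
    when the feature config enables them — ``pssm``, ``ss`` and ``rsa``
    tables. Returns a :class:`Stack`; per-layer mean training (out-of-fold)
    top-L PPV is logged and stored, with a warning when a layer fails to
    improve on its predecessor.
    """
    if config is None:
        config = StackConfig()
    families = list(families)
    if not families:
        raise ValueError("need at least one training family")
    cfg = config.feature_config
    h = cfg.field_halfwidth
    field_size = 2 * h + 1

    rng = np.random.default_rng(config.seed)
    pairs_l, X_l, y_l, L_l = [], [], [], []
    for fam in families:
        pairs, X, L = _ordinary_features(fam, cfg, config.min_separation)
        if L < 2 * field_size:
            warnings.warn(
                f"family of length {L} is shorter than twice the receptive "
                f"field ({field_size}); zero-padding covers it"
            )
        pairs_l.append(pairs)
        X_l.append(X)
        y_l.append(fam.truth.matrix[pairs[:, 0], pairs[:, 1]])
        L_l.append(L)

    n_fam = len(families)
    folds = np.arange(n_fam) % config.oof_folds
    rng.shuffle(folds)
    y_all = np.concatenate(y_l)
    if not y_all.any():
        raise ValueError("empty positive class: no contacts in training data")

    def pooled(Xs, idx):
        return np.concatenate([Xs[f] for f in idx]), np.concatenate(
            [y_l[f] for f in idx]
        )

    # pooled-array offset of each family's block, for OOB bookkeeping
    block_sizes = np.array([len(y) for y in y_l])
    offsets = np.concatenate([[0], np.cumsum(block_sizes)])

    layers = []
    layer_ppv = []
    cur_X = X_l  # features fed to the layer being trained
    feedback_maps = [None] * n_fam  # receptive-field source for next layer
    all_idx = np.arange(n_fam)

    for t in range(config.n_layers):
        last = t == config.n_layers - 1
        X_pool, y_pool = pooled(cur_X, all_idx)
        want_oob = config.oof_mode == "oob" and not last
        model, kept = _fit(
            X_pool, y_pool, config, config.seed + 1000 * t, rng, oob=want_oob
        )
        layers.append(model)

        # feedback maps for the next layer (and PPV bookkeeping)
        if config.oof_mode == "out_of_fold" and not last:
            fold_maps = [None] * n_fam
            for k in range(config.oof_folds):
                train_idx = all_idx[folds != k]
                test_idx = all_idx[folds == k]
                if len(test_idx) == 0:
                    continue
                if len(train_idx) == 0:
                    fm = model
                else:
                    Xk, yk = pooled(cur_X, train_idx)
                    fm, _ = _fit(
                        Xk, yk, config, config.seed + 1000 * t + k + 1, rng
                    )
                for f in test_idx:
                    fold_maps[f] = _pairs_to_map(
                        pairs_l[f], _proba(fm, cur_X[f]), L_l[f]
                    )
            feedback_maps = fold_maps
        elif not last:
            probs = [
                _proba(model, cur_X[f]) for f in range(n_fam)
            ]
            if want_oob:
                # pairs in the fit sample get their out-of-bag estimate, so
                # every feedback value comes from trees that never saw it
                oob = _oob_proba(model, y_pool[kept])
                if oob is not None:
                    fam_of = np.searchsorted(offsets, kept, side="right") - 1
                    local = kept - offsets[fam_of]
                    ok = ~np.isnan(oob)
                    for f_idx, loc, val in zip(
                        fam_of[ok], local[ok], oob[ok]
                    ):
                        probs[f_idx][loc] = val
            feedback_maps = [
                _pairs_to_map(pairs_l[f], probs[f], L_l[f])
                for f in range(n_fam)
            ]

        # per-layer training PPV from the model's own maps (diagnostic)
        ppvs = []
        for f in range(n_fam):
            m = _pairs_to_map(pairs_l[f], _proba(model, cur_X[f]), L_l[f])
            try:
                ppvs.append(
                    top_l_ppv(
                        m,
                        families[f].truth,
                        alpha=1.0,
                        min_sep=config.min_separation,
                    )
                )
            except ValueError:
                pass
        mean_ppv = float(np.mean(ppvs)) if ppvs else float("nan")
        layer_ppv.append(mean_ppv)
        logger.info("layer %d mean training top-L PPV: %.4f", t, mean_ppv)
        if t > 0 and mean_ppv < layer_ppv[t - 1]:
            warnings.warn(
                f"layer {t} training PPV ({mean_ppv:.4f}) below layer "
                f"{t - 1} ({layer_ppv[t - 1]:.4f}): the stack may be over-deep"
            )

        if not last:
            cur_X = [
                np.concatenate(
                    [
                        X_l[f],
                        receptive_fields_batch(feedback_maps[f], pairs_l[f], h),
                    ],
                    axis=1,
                )
                for f in range(n_fam)
            ]

    stack = Stack(
        layers=layers,
        config=config,
        layer_train_ppv=layer_ppv,
        fold_assignment=folds.tolist(),
    )
    stack.probe = _make_probe(stack)
    return stack


# ---------------------------------------------------------------------------
# prediction


def predict(stack: Stack, family) -> list[PredictionMap]:
    """Apply a trained stack to one family; one map per layer.

    The last map is the method's output. Pairs with separation below
    ``config.min_separation`` (and masked pairs) stay at 0.
    """
    cfg = stack.config.feature_config
    h = cfg.field_halfwidth
    base, pssm, ss, rsa = _family_arrays(family, cfg)
    L = base[0].shape[0]
    mask = family.truth.mask if getattr(family, "truth", None) is not None else None
    pairs = _eligible_pairs(L, stack.config.min_separation, mask)
    X_ord = encode_family(pairs, base, cfg, pssm=pssm, ss=ss, rsa=rsa)

    maps = []
    X = X_ord
    for t, model in enumerate(stack.layers):
        expected = model.n_features_in_
        if X.shape[1] != expected:
            raise ValueError(
                f"layer {t} expects {expected} features, got {X.shape[1]}; "
                "inputs do not match the stack's stored configuration"
            )
        probs = _proba(model, X)
        m = _pairs_to_map(pairs, probs, L)
        maps.append(PredictionMap(m.astype(float), method_tag=f"layer-{t}"))
        if t + 1 < len(stack.layers):
            X = np.concatenate(
                [X_ord, receptive_fields_batch(m, pairs, h)], axis=1
            )
    return maps


# ---------------------------------------------------------------------------
# persistence


def _make_probe(stack: Stack, n: int = 16) -> dict:
    """A frozen random input and the layer-0 probabilities it produces."""
    rng = np.random.default_rng(12345)
    d0 = stack.layers[0].n_features_in_
    X = rng.random((n, d0)).astype(np.float32)
    return {"X": X, "proba": _proba(stack.layers[0], X)}


def save_stack(stack: Stack, path) -> None:
    """Serialise a trained stack (single-file joblib bundle)."""
    payload = {
        "format_version": ARCHIVE_FORMAT_VERSION,
        "config": stack.config,
        "layers": stack.layers,
        "layer_train_ppv": stack.layer_train_ppv,
        "fold_assignment": stack.fold_assignment,
        "probe": stack.probe if stack.probe is not None else _make_probe(stack),
    }
    joblib.dump(payload, path)


def load_stack(path) -> Stack:
    """Load a stack archive; verifies version and the stored probe output."""
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ValueError(f"cannot read stack archive {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ValueError(f"{path} is not a stack archive")
    if payload["format_version"] != ARCHIVE_FORMAT_VERSION:
        raise ValueError(
            f"archive format {payload['format_version']} unsupported "
            f"(expected {ARCHIVE_FORMAT_VERSION})"
        )
    stack = Stack(
        layers=payload["layers"],
        config=payload["config"],
        layer_train_ppv=payload.get("layer_train_ppv", []),
        fold_assignment=payload.get("fold_assignment", []),
        probe=payload.get("probe"),
    )
    probe = stack.probe
    got = _proba(stack.layers[0], probe["X"])
    if not np.allclose(got, probe["proba"], atol=1e-10):
        raise ValueError("stack archive failed its probe check after load")
    return stack
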