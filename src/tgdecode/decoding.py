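"""Time-resolved MVPA decoding, temporal generalization, cross-task transfer.

The decoding scheme follows the standard single-trial ERP classification
recipe: for each of ``n_reps`` repetitions the two conditions are balanced by
under-sampling the majority condition, trials are shuffled and averaged in
groups of ``k`` into pseudo-trials, and a linear SVM (C = 1) is trained and
tested per time point on the channel-vector features under stratified
``n_folds``-fold cross-validation; accuracies are averaged over folds and
repetitions.  Temporal generalization tests every classifier at every time
point; its diagonal reproduces the time-by-time decoding when the same seed
is used.  Cross-task transfer trains at each time point on all pseudo-trials
of one task and tests on all pseudo-trials of the other, in both directions;
the shared-representation matrix is (A + B^T) / 2.

Features are z-scored per channel with training-set statistics only; the
scaler fitted at the training time point is applied to the test features at
every test time point.  Condition order is canonicalized by label name, so
swapping the two condition arguments gives bit-identical results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import sklearn
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import LinearSVC

from .epochs import EpochsSet


@dataclass
class DecodingConfig:
    """Resampling and classifier parameters for all decoding operations."""

    k: int = 4                      # pseudo-trial size (trials averaged)
    n_folds: int = 4
    n_reps: int = 100
    decode_window: tuple[float, float] = (0.0, 1000.0)
    seed: int = 0
    standardize_features: bool = True
    svm_c: float = 1.0
    cross_task_cv: bool = False     # k-fold CV on the training task, too

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


@dataclass
class DecodingResult:
    """Per-subject decoding accuracy over time (or train x test time)."""

    kind: str                 # "timecourse" | "generalization"
    times: np.ndarray         # ms; train-time axis for matrices
    accuracy: np.ndarray      # (n_times,) or (n_train, n_test)
    chance: float = 0.5
    subject: str = ""
    test_times: np.ndarray | None = None
    config: DecodingConfig | None = None


@dataclass
class CrossTaskResult:
    """Both cross-task transfer directions and their shared average."""

    matrix_a: np.ndarray      # train task 1 x test task 2
    matrix_b: np.ndarray      # train task 2 x test task 1
    times_task1: np.ndarray
    times_task2: np.ndarray
    chance: float = 0.5
    subject: str = ""
    config: DecodingConfig | None = None

    @property
    def shared(self) -> np.ndarray:
        """(A + B^T) / 2 — the shared-representation matrix."""
        return (self.matrix_a + self.matrix_b.T) / 2.0


# ---------------------------------------------------------------------------
# resampling primitives
# ---------------------------------------------------------------------------

def undersample_balance(
    trials_a: np.ndarray, trials_b: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Equalize class sizes by subsampling the larger set w/o replacement."""
    if len(trials_a) == 0 or len(trials_b) == 0:
        raise ValueError("cannot balance an empty trial set")
    n = min(len(trials_a), len(trials_b))
    if len(trials_a) > n:
        trials_a = trials_a[rng.choice(len(trials_a), size=n, replace=False)]
    elif len(trials_b) > n:
        trials_b = trials_b[rng.choice(len(trials_b), size=n, replace=False)]
    return trials_a, trials_b


def make_pseudo_trials(
    trials: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Shuffle trials and average consecutive groups of ``k``.

    Remainder trials (fewer than ``k``) are dropped.
    """
    n = len(trials)
    if n < k:
        raise ValueError(f"need at least k = {k} trials, got {n}")
    order = rng.permutation(n)
    n_groups = n // k
    grouped = trials[order[: n_groups * k]]
    return grouped.reshape(n_groups, k, *trials.shape[1:]).mean(axis=1)


def _fold_split(n: int, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    if n < n_folds:
        raise ValueError(
            f"stratified {n_folds}-fold CV needs at least {n_folds} "
            f"pseudo-trials per condition, got {n}")
    return np.array_split(rng.permutation(n), n_folds)


def _make_clf(config: DecodingConfig) -> LinearSVC:
    # fixed random_state: liblinear's dual solver permutes coordinates
    # stochastically and must be pinned for bit-identical re-runs
    return LinearSVC(C=config.svm_c, max_iter=5000, random_state=0)


def _standardizer(train: np.ndarray, enabled: bool):
    """Per-(channel, time) z-scoring parameters from the training set."""
    if not enabled:
        return 0.0, 1.0
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mu, sd


def _prep_pair(
    epochs_a: EpochsSet, epochs_b: EpochsSet, window: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Crop both condition sets to the decode window; canonical order."""
    if epochs_a.channels != epochs_b.channels:
        raise ValueError("conditions must share the channel set")
    if (len(epochs_a.times) != len(epochs_b.times)
            or not np.allclose(epochs_a.times, epochs_b.times)):
        raise ValueError("conditions must share the time grid")
    mask = epochs_a.time_mask(window)
    if not mask.any():
        raise ValueError(f"decode window {window} contains no samples")
    return epochs_a.data[:, :, mask], epochs_b.data[:, :, mask], \
        epochs_a.times[mask]


def _canonical(epochs_a: EpochsSet, epochs_b: EpochsSet):
    """Order the two conditions by label name (accuracy is symmetric)."""
    name_a = str(epochs_a.labels[0]) if len(epochs_a.labels) else ""
    name_b = str(epochs_b.labels[0]) if len(epochs_b.labels) else ""
    if name_b < name_a:
        return epochs_b, epochs_a
    return epochs_a, epochs_b


# ---------------------------------------------------------------------------
# within-task decoding
# ---------------------------------------------------------------------------

def _within_task(
    epochs_a: EpochsSet, epochs_b: EpochsSet, config: DecodingConfig,
    generalize: bool,
) -> tuple[np.ndarray, np.ndarray]:
    epochs_a, epochs_b = _canonical(epochs_a, epochs_b)
    Xa, Xb, times = _prep_pair(epochs_a, epochs_b, config.decode_window)
    n_t = len(times)
    acc = np.zeros((n_t, n_t) if generalize else n_t)
    clf = _make_clf(config)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    with warnings.catch_warnings(), \
            sklearn.config_context(assume_finite=True):
        warnings.simplefilter("ignore", ConvergenceWarning)
        for _ in range(config.n_reps):
            a, b = undersample_balance(Xa, Xb, rng)
            pa = make_pseudo_trials(a, config.k, rng)
            pb = make_pseudo_trials(b, config.k, rng)
            folds_a = _fold_split(len(pa), config.n_folds, rng)
            folds_b = _fold_split(len(pb), config.n_folds, rng)
            rep_acc = np.zeros_like(acc)
            for f in range(config.n_folds):
                te_a, te_b = folds_a[f], folds_b[f]
                tr_a = np.concatenate([folds_a[g]
                                       for g in range(config.n_folds)
                                       if g != f])
                tr_b = np.concatenate([folds_b[g]
                                       for g in range(config.n_folds)
                                       if g != f])
                Xtr = np.concatenate([pa[tr_a], pb[tr_b]])
                Xte = np.concatenate([pa[te_a], pb[te_b]])
                y_tr = np.r_[np.zeros(len(tr_a)), np.ones(len(tr_b))]
                y_te = np.r_[np.zeros(len(te_a)), np.ones(len(te_b))]
                for t in range(n_t):
                    mu, sd = _standardizer(Xtr[:, :, t],
                                           config.standardize_features)
                    clf.fit((Xtr[:, :, t] - mu) / sd, y_tr)
                    w, b0 = clf.coef_[0], clf.intercept_[0]
                    if generalize:
                        z = ((Xte - mu[:, None]) / sd[:, None]
                             if config.standardize_features else Xte)
                        dec = np.einsum("sct,c->st", z, w) + b0
                        rep_acc[t] += ((dec > 0) == (y_te[:, None] == 1)) \
                            .mean(axis=0)
                    else:
                        dec = np.einsum("sc,c->s",
                                        (Xte[:, :, t] - mu) / sd
                                        if config.standardize_features
                                        else Xte[:, :, t], w) + b0
                        rep_acc[t] += ((dec > 0) == (y_te == 1)).mean()
            acc += rep_acc / config.n_folds
    return acc / config.n_reps, times


def decode_timecourse(
    epochs_a: EpochsSet, epochs_b: EpochsSet, config: DecodingConfig
) -> DecodingResult:
    """Time-by-time decoding accuracy between two conditions (one subject)."""
    acc, times = _within_task(epochs_a, epochs_b, config, generalize=False)
    return DecodingResult(kind="timecourse", times=times, accuracy=acc,
                          subject=epochs_a.subject, config=config)


def temporal_generalization(
    epochs_a: EpochsSet, epochs_b: EpochsSet, config: DecodingConfig
) -> DecodingResult:
    """Train x test time generalization matrix between two conditions.

    With the same config (seed included) its diagonal equals the
    :func:`decode_timecourse` output, because both consume identical
    resampling draws and fit identical classifiers.
    """
    acc, times = _within_task(epochs_a, epochs_b, config, generalize=True)
    return DecodingResult(kind="generalization", times=times, accuracy=acc,
                          subject=epochs_a.subject, test_times=times,
                          config=config)


# ---------------------------------------------------------------------------
# cross-task generalization
# ---------------------------------------------------------------------------

def _rep_pseudo_sets(Xa, Xb, config, rng):
    a, b = undersample_balance(Xa, Xb, rng)
    pa = make_pseudo_trials(a, config.k, rng)
    pb = make_pseudo_trials(b, config.k, rng)
    X = np.concatenate([pa, pb])
    y = np.r_[np.zeros(len(pa)), np.ones(len(pb))]
    return X, y


def _transfer(
    Xtr, y_tr, Xte, y_te, config: DecodingConfig, clf: LinearSVC
) -> np.ndarray:
    """Accuracy matrix (train time of Xtr) x (test time of Xte).

    Each task is z-scored with its own class-pooled per-channel statistics:
    train features with the training task's, test features with the test
    task's (per test time point).  Pooling over both conditions leaks no
    label information, and task-specific centering removes the between-task
    offset of the common ERP mode, which is what allows a classifier
    calibrated on one task to transfer to the other.
    """
    n_tr_t, n_te_t = Xtr.shape[2], Xte.shape[2]
    out = np.empty((n_tr_t, n_te_t))
    correct = (y_te[:, None] == 1)
    if config.standardize_features:
        mu_te = Xte.mean(axis=0)
        sd_te = Xte.std(axis=0)
        sd_te = np.where(sd_te > 0, sd_te, 1.0)
        z_te = (Xte - mu_te) / sd_te
    else:
        z_te = Xte
    for t in range(n_tr_t):
        mu, sd = _standardizer(Xtr[:, :, t], config.standardize_features)
        clf.fit((Xtr[:, :, t] - mu) / sd, y_tr)
        w, b0 = clf.coef_[0], clf.intercept_[0]
        dec = np.einsum("sct,c->st", z_te, w) + b0
        out[t] = ((dec > 0) == correct).mean(axis=0)
    return out


def cross_task_generalization(
    task1_pair: tuple[EpochsSet, EpochsSet],
    task2_pair: tuple[EpochsSet, EpochsSet],
    config: DecodingConfig,
) -> CrossTaskResult:
    """Cross-task transfer matrices A, B and their shared average.

    Per repetition, each task's condition pair is independently balanced and
    pseudo-trial-averaged; classifiers trained at every time point of the
    training task are tested at every time point of the other task.  By
    default all pseudo-trials of the training task are used (train and test
    sets are disjoint by construction); with ``config.cross_task_cv`` the
    training task is additionally split into ``n_folds`` folds and only the
    training folds are used per fit.

    The class correspondence across tasks is positional: the first element
    of each pair is mapped to the same class (put the target-like condition
    first in both), so transfer of a shared representation scores above
    chance rather than inverting.
    """
    ep1a, ep1b = task1_pair
    ep2a, ep2b = task2_pair
    X1a, X1b, times1 = _prep_pair(ep1a, ep1b, config.decode_window)
    X2a, X2b, times2 = _prep_pair(ep2a, ep2b, config.decode_window)
    if X1a.shape[1] != X2a.shape[1]:
        raise ValueError("tasks must share the channel set")
    if len(times1) != len(times2) or not np.allclose(times1, times2):
        raise ValueError("tasks must share the time grid in the decode window")

    A = np.zeros((len(times1), len(times2)))
    B = np.zeros((len(times2), len(times1)))
    clf = _make_clf(config)
    with warnings.catch_warnings(), \
            sklearn.config_context(assume_finite=True):
        warnings.simplefilter("ignore", ConvergenceWarning)
        for rep in range(config.n_reps):
            # identically-seeded per-task streams: identical tasks then get
            # identical resampling draws, making A = B (and the shared
            # matrix exactly symmetric) in that degenerate case
            rng = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(rep,)))
            rng2 = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(rep,)))
            X1, y1 = _rep_pseudo_sets(X1a, X1b, config, rng)
            X2, y2 = _rep_pseudo_sets(X2a, X2b, config, rng2)
            if config.cross_task_cv:
                a_sum = np.zeros_like(A)
                b_sum = np.zeros_like(B)
                for Xtr, y_tr, Xte, y_te, out, fold_rng in (
                        (X1, y1, X2, y2, a_sum, rng),
                        (X2, y2, X1, y1, b_sum, rng2)):
                    idx0 = np.flatnonzero(y_tr == 0)
                    idx1 = np.flatnonzero(y_tr == 1)
                    f0 = _fold_split(len(idx0), config.n_folds, fold_rng)
                    f1 = _fold_split(len(idx1), config.n_folds, fold_rng)
                    for f in range(config.n_folds):
                        keep = np.concatenate(
                            [idx0[np.concatenate(
                                [f0[g] for g in range(config.n_folds)
                                 if g != f])],
                             idx1[np.concatenate(
                                 [f1[g] for g in range(config.n_folds)
                                  if g != f])]])
                        out += _transfer(Xtr[keep], y_tr[keep], Xte, y_te,
                                         config, clf)
                A += a_sum / config.n_folds
                B += b_sum / config.n_folds
            else:
                A += _transfer(X1, y1, X2, y2, config, clf)
                B += _transfer(X2, y2, X1, y1, config, clf)
    return CrossTaskResult(
        matrix_a=A / config.n_reps, matrix_b=B / config.n_reps,
        times_task1=times1, times_task2=times2,
        subject=ep1a.subject, config=config)


# ---------------------------------------------------------------------------
# peak extraction
# ---------------------------------------------------------------------------

@dataclass
class PeakResult:
    """Peak accuracy and latency inside the largest significant cluster."""

    found: bool
    accuracy: float | None = None
    latency_ms: float | None = None        # train axis for matrices
    test_latency_ms: float | None = None   # matrices only
    cluster_mass: float | None = None


def _largest_cluster_indices(mask_or_result, shape) -> tuple[np.ndarray, float]:
    """Flat indices of the largest significant cluster and its mass."""
    clusters = getattr(mask_or_result, "significant_clusters", None)
    if clusters is not None:
        if not clusters:
            return np.array([], dtype=int), 0.0
        best = max(clusters, key=lambda c: abs(c.mass))
        return np.asarray(best.indices, dtype=int), float(best.mass)
    # plain boolean mask: largest connected component by extent
    import scipy.ndimage

    mask = np.asarray(mask_or_result, dtype=bool)
    if mask.shape != tuple(shape):
        raise ValueError(
            f"mask shape {mask.shape} does not match accuracy shape {shape}")
    lab, n = scipy.ndimage.label(
        mask, structure=scipy.ndimage.generate_binary_structure(mask.ndim, 1))
    if n == 0:
        return np.array([], dtype=int), 0.0
    sizes = scipy.ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    return np.flatnonzero(lab.ravel() == best), float(sizes.max())


def peak_accuracy_latency(
    result: DecodingResult | np.ndarray,
    mask,
    window: tuple[float, float],
    times: np.ndarray | None = None,
    test_times: np.ndarray | None = None,
) -> PeakResult:
    """Peak accuracy and latency within the largest significant cluster.

    ``mask`` may be a :class:`~tgdecode.cluster.ClusterResult` (the largest
    cluster is then the one with the largest |mass|) or a boolean mask of the
    same shape as the accuracy (largest cluster by extent).  The cluster is
    intersected with the closed ``window`` on every time axis; an empty
    intersection gives ``PeakResult(found=False)``.
    """
    if isinstance(result, DecodingResult):
        acc = result.accuracy
        times = result.times
        test_times = (result.test_times if result.test_times is not None
                      else None)
    else:
        acc = np.asarray(result)
        if times is None:
            raise ValueError("times required when passing a bare array")
    idx, mass = _largest_cluster_indices(mask, acc.shape)
    if idx.size == 0:
        return PeakResult(found=False)
    lo, hi = window
    in_win = np.zeros(acc.shape, dtype=bool).ravel()
    in_win[idx] = True
    in_win = in_win.reshape(acc.shape)
    t_ok = (times >= lo - 1e-9) & (times <= hi + 1e-9)
    if acc.ndim == 1:
        in_win &= t_ok
    else:
        tt = np.asarray(test_times if test_times is not None else times)
        tt_ok = (tt >= lo - 1e-9) & (tt <= hi + 1e-9)
        in_win &= t_ok[:, None] & tt_ok[None, :]
    if not in_win.any():
        return PeakResult(found=False)
    masked = np.where(in_win, acc, -np.inf)
    flat_peak = int(np.argmax(masked))
    if acc.ndim == 1:
        return PeakResult(found=True, accuracy=float(acc[flat_peak]),
                          latency_ms=float(times[flat_peak]),
                          cluster_mass=mass)
    i, j = np.unravel_index(flat_peak, acc.shape)
    tt = np.asarray(test_times if test_times is not None else times)
    return PeakResult(found=True, accuracy=float(acc[i, j]),
                      latency_ms=float(times[i]),
                      test_latency_ms=float(tt[j]),
                      cluster_mass=mass)
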