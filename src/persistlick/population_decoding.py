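"""Population decoding, PCA-trajectory separation, and Hammerstein-Wiener
prediction of facial activity from single-unit firing.

Decoding pipeline: per-unit max normalisation over the pooled water and
quinine windows, PCA keeping the leading dimensions that explain >= 85 % of
variance (fit on the training split only), and a linear-SVM classifier —
error-correcting output codes for three or more classes, a single binary
SVM for two.  Accuracy is averaged over repeated 50/50 splits; the chance
band comes from pseudo datasets in which the anchoring lick onsets are
drawn at random from the whole recording (or, equivalently for the
classifier, the labels are permuted).

The Hammerstein-Wiener predictor is a static polynomial input
nonlinearity feeding a rational linear transfer function with ``nb - 1``
zeros and ``nf`` poles, fitted by least squares in ARX form over the grid
nb-1 in {0,1,2}, nf in {1,2,3}, polynomial degree in {2..5}; prediction
accuracy on held-out trials is the normalised-RMSE fit percentage
``100 * (1 - ||y - yhat|| / ||y - ybar||)``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from sklearn.decomposition import PCA
from sklearn.multiclass import OutputCodeClassifier
from sklearn.svm import SVC


@dataclass
class DecoderConfig:
    variance_keep: float = 0.85
    pseudo_repeats: int = 50
    split: float = 0.5
    fit_repeats: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.variance_keep <= 1:
            raise ValueError("variance_keep must lie in (0, 1]")


@dataclass
class HWConfig:
    nb_values: tuple[int, ...] = (1, 2, 3)      # nb - 1 zeros in {0, 1, 2}
    nf_values: tuple[int, ...] = (1, 2, 3)      # poles
    degree_values: tuple[int, ...] = (2, 3, 4, 5)
    accuracy_threshold: float = 30.0            # % fit counted as predictive
    smooth_sigma: float = 2.0                   # samples, facial pre-smoothing
    parsimony_tol: float = 0.1                  # % fit margin for tie-breaks


@dataclass
class DecodeResult:
    accuracy_mean: float
    accuracy_sd: float
    chance_band: tuple[float, float]
    chance_accuracies: np.ndarray
    n_components: int


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------


def _normalize_per_unit(X: np.ndarray) -> np.ndarray:
    """Divide each unit's features by its max over all trials/bins."""
    # X: (n_trials, n_units, n_bins)
    mx = np.abs(X).max(axis=(0, 2), keepdims=True)
    mx[mx == 0] = 1.0
    return X / mx


def _fit_eval(
    X: np.ndarray, y: np.ndarray, cfg: DecoderConfig, rng: np.random.Generator
) -> float:
    n = len(y)
    classes = np.unique(y)
    # stratified 50/50 split
    train_idx, test_idx = [], []
    for c in classes:
        idx = np.flatnonzero(y == c)
        idx = rng.permutation(idx)
        k = max(1, int(round(len(idx) * cfg.split)))
        k = min(k, len(idx) - 1)
        train_idx.extend(idx[:k])
        test_idx.extend(idx[k:])
    train_idx, test_idx = np.array(train_idx), np.array(test_idx)
    pca = PCA()
    Z = pca.fit_transform(X[train_idx])
    n_comp = int(np.searchsorted(np.cumsum(pca.explained_variance_ratio_),
                                 cfg.variance_keep) + 1)
    n_comp = min(n_comp, Z.shape[1])
    if len(classes) > 2:
        clf = OutputCodeClassifier(
            SVC(kernel="linear"), code_size=2.0,
            random_state=int(rng.integers(2**31)),
        )
    else:
        clf = SVC(kernel="linear")
    clf.fit(Z[:, :n_comp], y[train_idx])
    Zt = pca.transform(X[test_idx])[:, :n_comp]
    return float(np.mean(clf.predict(Zt) == y[test_idx]))


def decode(
    rates: np.ndarray,
    labels: Sequence,
    cfg: DecoderConfig = DecoderConfig(),
    seed: int = 0,
    pseudo_rates: Optional[np.ndarray] = None,
) -> DecodeResult:
    """Decode trial labels from population rates.

    ``rates`` is (n_trials, n_units, n_bins).  The chance band is the
    2.5-97.5 percentile range of accuracies on ``pseudo_repeats`` pseudo
    datasets: ``pseudo_rates`` (pseudo_repeats, n_trials, n_units, n_bins)
    built from randomly drawn lick onsets when available, otherwise
    label permutations of the real data.
    """
    rng = np.random.default_rng(seed)
    X = _normalize_per_unit(np.asarray(rates, float))
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("need at least two classes")
    counts = [np.sum(y == c) for c in np.unique(y)]
    if min(counts) < 2:
        raise ValueError("need at least two trials per class")
    if np.any(X.std(axis=(0, 2)) == 0) and np.all(X.var() == 0):
        raise ValueError("degenerate (zero-variance) population")
    Xf = X.reshape(X.shape[0], -1)

    accs = [_fit_eval(Xf, y, cfg, rng) for _ in range(cfg.fit_repeats)]

    chance = np.empty(cfg.pseudo_repeats)
    for r in range(cfg.pseudo_repeats):
        if pseudo_rates is not None:
            Xp = _normalize_per_unit(np.asarray(pseudo_rates[r], float))
            Xp = Xp.reshape(Xp.shape[0], -1)
            yp = y
        else:
            Xp = Xf
            yp = rng.permutation(y)
        chance[r] = _fit_eval(Xp, yp, cfg, rng)

    pca_all = PCA().fit(Xf)
    n_comp = int(np.searchsorted(np.cumsum(pca_all.explained_variance_ratio_),
                                 cfg.variance_keep) + 1)
    return DecodeResult(
        accuracy_mean=float(np.mean(accs)),
        accuracy_sd=float(np.std(accs)),
        chance_band=(float(np.percentile(chance, 2.5)),
                     float(np.percentile(chance, 97.5))),
        chance_accuracies=chance,
        n_components=n_comp,
    )


def pseudo_anchor_rates(
    rate_fn,
    n_repeats: int,
    n_trials: int,
    t_range: tuple[float, float],
    seed: int = 0,
) -> np.ndarray:
    """Build pseudo rate tensors from randomly drawn anchor times.

    ``rate_fn(anchor) -> (n_units, n_bins)`` evaluates the population in a
    window around an anchor; anchors are drawn uniformly from ``t_range``.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_repeats):
        anchors = rng.uniform(t_range[0], t_range[1], n_trials)
        out.append(np.stack([rate_fn(a) for a in anchors]))
    return np.stack(out)


# ---------------------------------------------------------------------------
# PCA trajectory separation
# ---------------------------------------------------------------------------


def trajectory_separation(
    condition_rates: dict[str, np.ndarray],
    variance_keep: float = 0.85,
) -> tuple[float, np.ndarray]:
    """Mean Euclidean distance between condition PCA trajectories.

    ``condition_rates[c]`` is (n_trials, n_units, n_bins); each condition
    is reduced to its trial-mean trajectory (one population vector per time
    bin), all trajectories are embedded in a common PCA space keeping the
    dimensions that explain ``variance_keep`` of variance, and the mean
    pairwise point-by-point distance between condition trajectories is
    returned together with the per-PC explained variance ratios.
    """
    if len(condition_rates) < 2:
        raise ValueError("need at least two conditions")
    names = sorted(condition_rates)
    trajs = {c: np.asarray(condition_rates[c], float).mean(axis=0).T for c in names}
    # samples: (bins, units) stacked over conditions
    stacked = np.concatenate([trajs[c] for c in names], axis=0)
    if stacked.shape[0] < 2:
        raise ValueError("fewer samples than components")
    pca = PCA()
    pca.fit(stacked)
    evr = pca.explained_variance_ratio_
    n_comp = int(np.searchsorted(np.cumsum(evr), variance_keep) + 1)
    n_comp = min(n_comp, stacked.shape[1])
    emb = {c: pca.transform(trajs[c])[:, :n_comp] for c in names}
    dists = []
    for a, b in itertools.combinations(names, 2):
        dists.append(np.linalg.norm(emb[a] - emb[b], axis=1).mean())
    return float(np.mean(dists)), evr


# ---------------------------------------------------------------------------
# Hammerstein-Wiener prediction
# ---------------------------------------------------------------------------


def _poly_features(u: np.ndarray, degree: int) -> np.ndarray:
    return np.stack([u**k for k in range(1, degree + 1)], axis=-1)


def _fit_arx(
    u_trials: list[np.ndarray],
    y_trials: list[np.ndarray],
    nb: int,
    nf: int,
    degree: int,
) -> Optional[np.ndarray]:
    """Least-squares fit of y_t = sum_i -f_i y_{t-i} + sum_{j,k} b_jk u_{t-1-j}^k + c.

    Returns the coefficient vector, or None when the fitted autoregressive
    polynomial is unstable.
    """
    rows, targets = [], []
    lag = max(nf, nb)
    for u, y in zip(u_trials, y_trials):
        pf = _poly_features(u, degree)
        for t in range(lag, len(y)):
            past_y = [y[t - i] for i in range(1, nf + 1)]
            past_u = [pf[t - 1 - j] for j in range(nb)]
            rows.append(np.concatenate([past_y, np.concatenate(past_u), [1.0]]))
            targets.append(y[t])
    A = np.asarray(rows)
    b = np.asarray(targets)
    coef, *_ = np.linalg.lstsq(A, b, rcond=None)
    ar = coef[:nf]
    poles = np.roots(np.concatenate([[1.0], -ar])) if nf else np.empty(0)
    if poles.size and np.any(np.abs(poles) >= 1.0):
        return None
    return coef


def _simulate_arx(
    coef: np.ndarray, u: np.ndarray, y_init: np.ndarray, nb: int, nf: int, degree: int
) -> np.ndarray:
    pf = _poly_features(u, degree)
    lag = max(nf, nb)
    y = np.empty(len(u))
    y[:lag] = y_init[:lag]
    ar = coef[:nf]
    rest = coef[nf:]
    for t in range(lag, len(u)):
        feats = np.concatenate(
            [np.concatenate([pf[t - 1 - j] for j in range(nb)]), [1.0]]
        )
        y[t] = float(np.dot(ar, [y[t - i] for i in range(1, nf + 1)])) + float(
            np.dot(rest, feats)
        )
    return y


def fit_percent(y: np.ndarray, yhat: np.ndarray) -> float:
    """Normalised-RMSE fit percentage; raises for a constant reference."""
    denom = np.linalg.norm(y - y.mean())
    if denom == 0:
        raise ValueError("constant reference trace: fit undefined")
    return float(100.0 * (1.0 - np.linalg.norm(y - yhat) / denom))


@dataclass
class HWResult:
    accuracy: float
    predicted: list[np.ndarray]
    nb: int
    nf: int
    degree: int
    train_fit: float


def hw_fit_predict(
    rate_trials: Sequence[np.ndarray],
    facial_trials: Sequence[np.ndarray],
    cfg: HWConfig = HWConfig(),
    presmoothed: bool = False,
) -> HWResult:
    """Grid-searched Hammerstein-Wiener fit on trials 1-2, tested on 3-4.

    Among grid points whose training free-run fit ties within
    ``parsimony_tol`` of the best, the least complex (degree, nf, nb) is
    selected; candidates with unstable poles are rejected.
    """
    if len(rate_trials) != 4 or len(facial_trials) != 4:
        raise ValueError("expect exactly four trials (2 train + 2 test)")
    u = [np.asarray(r, float) for r in rate_trials]
    y = [np.asarray(f, float) for f in facial_trials]
    if not presmoothed and cfg.smooth_sigma > 0:
        y = [gaussian_filter1d(t, cfg.smooth_sigma) for t in y]
    u_tr, y_tr = u[:2], y[:2]
    u_te, y_te = u[2:], y[2:]
    if any(t.std() == 0 for t in y_te):
        raise ValueError("constant facial trace in test trials")

    candidates = []
    for degree, nf, nb in itertools.product(
        cfg.degree_values, cfg.nf_values, cfg.nb_values
    ):
        if nf < nb:  # realizability: at least as many poles as zeros + 1
            continue
        coef = _fit_arx(u_tr, y_tr, nb, nf, degree)
        if coef is None:
            continue
        sims = [
            _simulate_arx(coef, ut, yt, nb, nf, degree)
            for ut, yt in zip(u_tr, y_tr)
        ]
        lag = max(nf, nb)
        tr_fit = np.mean(
            [fit_percent(yt[lag:], s[lag:]) for yt, s in zip(y_tr, sims)]
        )
        candidates.append((tr_fit, degree, nf, nb, coef))
    if not candidates:
        raise ValueError("no stable candidate in the model grid")
    best_fit = max(c[0] for c in candidates)
    viable = [c for c in candidates if c[0] >= best_fit - cfg.parsimony_tol]
    viable.sort(key=lambda c: (c[1], c[2], c[3]))
    tr_fit, degree, nf, nb, coef = viable[0]

    lag = max(nf, nb)
    preds = [
        _simulate_arx(coef, ut, yt, nb, nf, degree) for ut, yt in zip(u_te, y_te)
    ]
    acc = float(
        np.mean([fit_percent(yt[lag:], p[lag:]) for yt, p in zip(y_te, preds)])
    )
    return HWResult(acc, preds, nb, nf, degree, float(tr_fit))
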