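"""One-class SVM rhythm classification and unsupervised baselines.

AF is the majority/inlier class; SR patients are treated as outliers.
The OCSVM hyperparameters (kernel family, c, d, gamma, nu) are tuned by
a grid search whose score is the mean absolute decision-function value
over the data the candidate was fit on; non-finite scores are penalized
and can never win. Validation uses a deterministic, order-based group
5-fold. Classification metrics follow the convention that SR (the
outlier class) is the positive/sensitivity class.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.cluster import DBSCAN, MeanShift
from sklearn.metrics import silhouette_score
from sklearn.mixture import GaussianMixture
from sklearn.svm import OneClassSVM

from . import nn

__all__ = [
    "AF", "SR",
    "RhythmDataset", "OCSVMConfig", "OCSVMModel", "ClassificationReport",
    "kernel_eval", "default_gamma", "fit_ocsvm", "decision_scores",
    "predict_labels", "train_autoencoder", "training_outlier_fraction",
    "grid_search", "default_grid", "group_kfold_deterministic",
    "classification_report", "evaluate_ocsvm", "feature_ablation",
    "baseline_classifiers",
]

AF = "AF"
SR = "SR"
FEATURE_NAMES = ("laei", "laef", "ap")


@dataclass
class RhythmDataset:
    features: np.ndarray          # (n, d)
    labels: np.ndarray            # (n,) in {"AF", "SR"}
    patient_ids: np.ndarray
    feature_names: tuple = FEATURE_NAMES

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        self.patient_ids = np.asarray(self.patient_ids)
        if len(self.features) < 2:
            raise ValueError("need at least 2 samples")
        if np.isnan(self.features).any():
            raise ValueError("missing values in features")
        bad = set(self.labels) - {AF, SR}
        if bad:
            raise ValueError(f"unknown labels {bad}")


@dataclass
class OCSVMConfig:
    kernel: str = "rbf"           # linear | poly | rbf | sigmoid
    c: float = 0.0                # polynomial constant
    degree: int = 3
    gamma: float | None = None    # None -> Eq.-15 default (1 / (n var))
    r: float = 0.0                # sigmoid shift
    nu: float = 0.1

    def __post_init__(self):
        if not (0.0 < self.nu <= 1.0):
            raise ValueError("nu must be in (0, 1]")
        if self.degree < 1:
            raise ValueError("degree must be >= 1")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be > 0 where used")
        if self.kernel not in ("linear", "poly", "rbf", "sigmoid"):
            raise ValueError(f"unknown kernel {self.kernel!r}")


@dataclass
class OCSVMModel:
    estimator: OneClassSVM
    config: OCSVMConfig
    gamma_used: float
    mean_: np.ndarray | None = None   # standardization applied before fit
    scale_: np.ndarray | None = None

    def _transform(self, X):
        X = np.asarray(X, dtype=float)
        if self.mean_ is None:
            return X
        return (X - self.mean_) / self.scale_


@dataclass
class ClassificationReport:
    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float   # percent; SR (outlier) is the positive class
    specificity: float   # percent; AF is the negative class
    acc: float
    b_acc: float
    meta: dict = field(default_factory=dict)


def kernel_eval(cfg: OCSVMConfig, x, y) -> float:
    """Direct evaluation of the four kernel formulas (independent of sklearn)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    dot = float(x @ y)
    if cfg.kernel == "linear":
        return dot
    if cfg.kernel == "poly":
        return (dot + cfg.c) ** cfg.degree
    gamma = cfg.gamma
    if gamma is None:
        raise ValueError("explicit gamma required for pointwise evaluation")
    if cfg.kernel == "rbf":
        return float(np.exp(-gamma * np.sum((x - y) ** 2)))
    return float(np.tanh(gamma * dot + cfg.r))


def default_gamma(X) -> float:
    """1 / (n * var(X)), var over the flattened feature table."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    if n < 2:
        raise ValueError("need at least 2 samples")
    var = float(X.var())
    if var == 0.0:
        raise ValueError("zero variance: gamma undefined")
    return 1.0 / (n * var)


def fit_ocsvm(X, cfg: OCSVMConfig, standardize: bool = True) -> OCSVMModel:
    """Solve the nu-parameterized one-class problem for one configuration."""
    X = np.asarray(X, dtype=float)
    if len(X) < 2:
        raise ValueError("need at least 2 samples")
    mean = scale = None
    Xs = X
    if standardize:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale == 0, 1.0, scale)
        Xs = (X - mean) / scale
    if cfg.kernel == "poly":
        gamma = 1.0  # printed polynomial kernel has no gamma
    elif cfg.gamma is not None:
        gamma = cfg.gamma
    else:
        gamma = default_gamma(Xs)
    est = OneClassSVM(kernel=cfg.kernel, degree=cfg.degree, gamma=gamma,
                      coef0=cfg.c if cfg.kernel == "poly" else cfg.r,
                      nu=cfg.nu)
    try:
        est.fit(Xs)
    except Exception as exc:  # pragma: no cover - solver failure surface
        raise RuntimeError(f"OCSVM solver failed for {cfg}: {exc}") from exc
    return OCSVMModel(estimator=est, config=cfg, gamma_used=gamma,
                      mean_=mean, scale_=scale)


def decision_scores(model: OCSVMModel, X) -> np.ndarray:
    """Signed distances f(x); negative marks predicted outliers (SR)."""
    Xs = model._transform(X)
    if Xs.shape[1] != model.estimator.shape_fit_[1]:
        raise ValueError("feature dimension mismatch")
    return model.estimator.decision_function(Xs)


def predict_labels(model: OCSVMModel, X) -> np.ndarray:
    return np.where(decision_scores(model, X) < 0, SR, AF)


def training_outlier_fraction(model: OCSVMModel) -> float:
    """Fraction of training points strictly outside the boundary (margin errors).

    Counted from the dual coefficients (alpha at the box bound), which is the
    quantity the nu-property bounds; counting sign(f) instead is unstable for
    degenerate fits where the solution collapses to f = 0 on every point and
    the sign is solver noise.
    """
    est = model.estimator
    alpha = np.abs(est.dual_coef_.ravel())  # libsvm-scaled to [0, 1]
    n = est.shape_fit_[0]
    return float(np.sum(alpha >= 1.0 - 1e-6)) / n


def default_grid() -> list[OCSVMConfig]:
    """c in {0..0.3}, d in {2..5}, nu in {0.05..0.2}; gamma per Eq.-15 default."""
    nus = (0.05, 0.10, 0.15, 0.20)
    grid: list[OCSVMConfig] = []
    for nu in nus:
        grid.append(OCSVMConfig(kernel="linear", nu=nu))
        grid.append(OCSVMConfig(kernel="rbf", nu=nu))
        grid.append(OCSVMConfig(kernel="sigmoid", nu=nu))
        for c, d in itertools.product((0.0, 0.1, 0.2, 0.3), (2, 3, 4, 5)):
            grid.append(OCSVMConfig(kernel="poly", c=c, degree=d, nu=nu))
    return grid


PENALTY = -np.inf


def grid_search(X, space=None, standardize: bool = True
                ) -> tuple[OCSVMConfig, list[tuple[OCSVMConfig, float]]]:
    """Pick the candidate maximizing mean |f(x)| over the fit data.

    Candidates whose decision scores contain non-finite values (or whose
    solver fails) receive a -inf penalty and cannot win.
    """
    space = list(space) if space is not None else default_grid()
    if not space:
        raise ValueError("empty grid")
    table = []
    for cfg in space:
        try:
            model = fit_ocsvm(X, cfg, standardize=standardize)
            f = decision_scores(model, X)
            score = float(np.mean(np.abs(f))) if np.all(np.isfinite(f)) else PENALTY
        except (RuntimeError, ValueError):
            score = PENALTY
        table.append((cfg, score))
    best_cfg, best_score = max(table, key=lambda t: t[1])
    if not np.isfinite(best_score):
        raise RuntimeError("all grid candidates produced invalid scores")
    return best_cfg, table


def group_kfold_deterministic(ids, k: int = 5) -> list[np.ndarray]:
    """Contiguous order-based folds; sizes differ by <= 1, larger folds first.

    Returns, per fold, the integer indices of its test samples.
    """
    ids = list(ids)
    n = len(ids)
    if n < k:
        raise ValueError(f"need at least {k} groups, got {n}")
    base, extra = divmod(n, k)
    folds, start = [], 0
    for i in range(k):
        size = base + (1 if i < extra else 0)
        folds.append(np.arange(start, start + size))
        start += size
    return folds


def classification_report(pred, truth, positive: str = SR,
                          meta: dict | None = None) -> ClassificationReport:
    """Counts plus sensitivity/specificity/accuracy/balanced accuracy (percent)."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("length mismatch")
    for arr in (pred, truth):
        bad = set(arr.tolist()) - {AF, SR}
        if bad:
            raise ValueError(f"labels outside {{AF, SR}}: {bad}")
    negative = AF if positive == SR else SR
    tp = int(np.sum((pred == positive) & (truth == positive)))
    tn = int(np.sum((pred == negative) & (truth == negative)))
    fp = int(np.sum((pred == positive) & (truth == negative)))
    fn = int(np.sum((pred == negative) & (truth == positive)))
    sens = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    spec = 100.0 * tn / (tn + fp) if tn + fp else 0.0
    acc = 100.0 * (tp + tn) / max(tp + tn + fp + fn, 1)
    return ClassificationReport(tp=tp, tn=tn, fp=fp, fn=fn,
                                sensitivity=sens, specificity=spec, acc=acc,
                                b_acc=(sens + spec) / 2.0, meta=meta or {})


def evaluate_ocsvm(ds: RhythmDataset, space=None, k: int = 5,
                   feature_idx=None,
                   fit_on_inliers: bool = False) -> ClassificationReport:
    """Tune once on the full table, then validate with the group 5-fold.

    Per fold the tuned configuration is re-fit on the training groups and
    applied to the held-out groups; pooled counts form the report. With
    ``fit_on_inliers`` the per-fold fit uses only the AF (inlier) training
    samples — the conventional one-class protocol — instead of the mixed
    training set the source procedure implies.
    """
    X = ds.features if feature_idx is None else ds.features[:, list(feature_idx)]
    best_cfg, _ = grid_search(X, space)
    folds = group_kfold_deterministic(ds.patient_ids, k)
    pred = np.empty(len(X), dtype=object)
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(len(X)), test_idx)
        if fit_on_inliers:
            train_idx = train_idx[ds.labels[train_idx] == AF]
        model = fit_ocsvm(X[train_idx], best_cfg)
        pred[test_idx] = predict_labels(model, X[test_idx])
    return classification_report(pred.astype(str), ds.labels,
                                 meta={"config": best_cfg})


def feature_ablation(ds: RhythmDataset, subsets=None, space=None
                     ) -> dict[tuple[str, ...], ClassificationReport]:
    """Tune + group-5-fold OCSVM evaluation for each feature subset."""
    if subsets is None:
        names = list(ds.feature_names)
        subsets = [(n,) for n in names] + \
            [tuple(c) for c in itertools.combinations(names, 2)] + \
            [tuple(names)]
    out = {}
    for subset in subsets:
        subset = tuple(subset)
        if not subset:
            raise ValueError("empty feature subset")
        idx = [ds.feature_names.index(name) for name in subset]
        out[subset] = evaluate_ocsvm(ds, space=space, feature_idx=idx)
    return out


# -- unsupervised baselines ----------------------------------------------


class _Autoencoder(nn.Module):
    """Tiny dense autoencoder (d -> latent -> d) trained on MSE."""

    def __init__(self, d: int, latent: int, seed: int = 0, linear: bool = False):
        rng = np.random.default_rng(seed)
        self.enc = nn.Linear(d, latent, rng=rng)
        self.dec = nn.Linear(latent, d, rng=rng)
        self.act = None if linear else nn.Tanh()

    def encode(self, x):
        z = self.enc(x)
        return z if self.act is None else self.act(z)

    def forward(self, x):
        return self.dec(self.encode(x))


def train_autoencoder(X, latent: int = 2, seed: int = 0, linear: bool = False,
                      epochs: int = 2000, lr: float = 1e-2):
    """Fit the autoencoder on standardized features; returns (model, latents)."""
    X = np.asarray(X, dtype=float)
    mean, scale = X.mean(axis=0), X.std(axis=0)
    scale = np.where(scale == 0, 1.0, scale)
    Xs = (X - mean) / scale
    ae = _Autoencoder(X.shape[1], latent, seed=seed, linear=linear)
    opt = nn.Adam(ae.parameters(), lr=lr)
    n = Xs.size
    for _ in range(epochs):
        xt = nn.Tensor(Xs)
        rec = ae(xt)
        loss = ((rec - Xs) * (rec - Xs)).sum() * (1.0 / n)
        opt.zero_grad()
        loss.backward()
        opt.step()
    latents = ae.encode(nn.Tensor(Xs)).data
    recon_mse = float(((ae(nn.Tensor(Xs)).data - Xs) ** 2).mean())
    return ae, latents, recon_mse


def _clusters_to_labels(cluster_ids: np.ndarray, mapping: str = "largest",
                        truth: np.ndarray | None = None) -> np.ndarray:
    """Largest cluster -> AF (majority class); noise (-1) and the rest -> SR."""
    ids = np.asarray(cluster_ids)
    valid = ids[ids >= 0]
    if valid.size == 0:
        return np.full(ids.shape, SR, dtype=object)
    if mapping == "largest":
        af_cluster = np.bincount(valid).argmax()
        return np.where(ids == af_cluster, AF, SR).astype(object)
    if mapping == "best":
        if truth is None:
            raise ValueError("mapping='best' needs truth labels")
        best, best_acc = None, -1.0
        for af_cluster in np.unique(valid):
            lab = np.where(ids == af_cluster, AF, SR)
            acc = float(np.mean(lab == truth))
            if acc > best_acc:
                best, best_acc = lab, acc
        return best.astype(object)
    raise ValueError(f"unknown mapping {mapping!r}")


def _tune_dbscan(X, min_samples: int = 3):
    """Pick eps from pairwise-distance quantiles by training silhouette."""
    from scipy.spatial.distance import pdist
    d = pdist(X)
    candidates = np.quantile(d[d > 0], [0.05, 0.1, 0.2, 0.3, 0.5]) if np.any(d > 0) \
        else np.array([1.0])
    best_eps, best_score = candidates[0], -np.inf
    for eps in candidates:
        labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(X)
        mask = labels >= 0
        uniq = np.unique(labels[mask])
        if len(uniq) >= 2 and mask.sum() > len(uniq):
            score = silhouette_score(X[mask], labels[mask])
        elif len(uniq) == 1 and mask.all():
            score = -1.0  # single cluster, no noise: degenerate
        else:
            score = -0.5
        if score > best_score:
            best_eps, best_score = eps, score
    return float(best_eps)


def _predict_clusters(method: str, Xtr, Xte, seed: int, eps: float | None):
    """Fit the clusterer on Xtr, assign clusters to Xte."""
    if method == "GMM":
        gm = GaussianMixture(n_components=2, random_state=seed,
                             covariance_type="full").fit(Xtr)
        return gm.predict(Xte)
    if method == "MEANSHIFT":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ms = MeanShift().fit(Xtr)
        return ms.predict(Xte)
    if method == "DBSCAN":
        db = DBSCAN(eps=eps, min_samples=3).fit(Xtr)
        core = db.components_
        if core.shape[0] == 0:
            return np.full(len(Xte), -1)
        core_labels = db.labels_[db.core_sample_indices_]
        d = np.linalg.norm(Xte[:, None, :] - core[None, :, :], axis=2)
        nearest = d.argmin(axis=1)
        assigned = core_labels[nearest]
        assigned[d.min(axis=1) > eps] = -1
        return assigned
    raise ValueError(f"unknown clustering method {method!r}")


def baseline_classifiers(ds: RhythmDataset, method: str, seed: int = 0,
                         k: int = 5, mapping: str = "largest",
                         ae_latent: int = 2, ae_linear: bool = False
                         ) -> ClassificationReport:
    """One of AE_DBSCAN, AE_GMM, DBSCAN, GMM, MEANSHIFT under the group 5-fold."""
    method = method.upper().replace("-", "_")
    if method not in ("AE_DBSCAN", "AE_GMM", "DBSCAN", "GMM", "MEANSHIFT"):
        raise ValueError(f"unknown method {method!r}")
    if len(ds.features) < 4:
        raise ValueError("need at least 4 samples")
    X = ds.features
    meta: dict = {"method": method}
    if method.startswith("AE_"):
        _, X, mse = train_autoencoder(ds.features, latent=ae_latent, seed=seed,
                                      linear=ae_linear)
        meta["ae_recon_mse"] = mse
        base = method[3:]
    else:
        mean, scale = X.mean(axis=0), X.std(axis=0)
        scale = np.where(scale == 0, 1.0, scale)
        X = (X - mean) / scale
        base = method
    eps = _tune_dbscan(X) if base == "DBSCAN" else None
    folds = group_kfold_deterministic(ds.patient_ids, k)
    pred = np.empty(len(X), dtype=object)
    degenerate = False
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(len(X)), test_idx)
        clusters_tr = _predict_clusters(base, X[train_idx], X[train_idx], seed, eps)
        clusters_te = _predict_clusters(base, X[train_idx], X[test_idx], seed, eps)
        uniq = np.unique(clusters_tr)
        if len(uniq) == 1 and uniq[0] >= 0:
            degenerate = True
        all_clusters = np.concatenate([clusters_tr, clusters_te])
        all_labels = _clusters_to_labels(
            all_clusters, mapping=mapping,
            truth=np.concatenate([ds.labels[train_idx], ds.labels[test_idx]])
            if mapping == "best" else None)
        pred[test_idx] = all_labels[len(clusters_tr):]
    if degenerate:
        warnings.warn("clustering produced a single cluster with no noise; "
                      "report maps everything to AF", RuntimeWarning)
        meta["degenerate"] = True
    return classification_report(pred.astype(str), ds.labels, meta=meta)
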