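"""Retention-time-free species identification by spectral fingerprinting.

A compound's UV–vis absorption spectrum is a fingerprint that survives
the matrix effects which shift retention times. Reference spectra from
heterogeneous sources are harmonised (common grid, Savitzky–Golay
smoothing, first derivative to cancel baseline offsets, unit-norm
scaling), projected onto a variance basis — raw per-pixel features far
outnumber the training spectra, which would make the within-class
scatter singular — and a linear discriminant model is trained on the
projections. Because reference libraries are small (often 1–3 spectra
per species), an r² tiebreak handles inconclusive posteriors: the top
candidates are re-compared to the query on smoothed, non-derivative
absorbance curves and the best mean r² wins.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .io import ReferenceSpectrum, SpectralLibrary, ValidationError
from .mcr import compare_spectra
from .preprocess import first_derivative, resample_to_grid, savgol_smooth

__all__ = [
    "FeatureConfig",
    "FingerprintModel",
    "ClassificationResult",
    "featurize",
    "train_fingerprint_model",
    "classify_spectrum",
    "save_model",
    "load_model",
]


@dataclass
class FeatureConfig:
    """Preprocessing settings shared by training and prediction."""

    grid_start: float = 200.0       # nm; common window where most spectra have support
    grid_stop: float = 450.0
    grid_step: float = 1.0
    savgol_order: int = 5
    savgol_half_window_nm: float = 4.5
    min_coverage: float = 0.5       # fraction of the window a spectrum must cover

    @property
    def grid(self) -> np.ndarray:
        n = int(round((self.grid_stop - self.grid_start) / self.grid_step)) + 1
        return self.grid_start + self.grid_step * np.arange(n)


@dataclass
class ClassificationResult:
    """Ranked candidate species for one query spectrum."""

    candidates: list[dict]          # [{"species", "posterior"}, ...] descending
    final_label: str
    tiebreak_used: bool
    r2_to_final: float
    frechet_to_final: float

    @property
    def posterior(self) -> float:
        for c in self.candidates:
            if c["species"] == self.final_label:
                return c["posterior"]
        return 0.0


@dataclass
class FingerprintModel:
    """Variance-projected linear discriminant over spectral derivatives."""

    feature_config: FeatureConfig
    projection: PCA
    discriminant: LinearDiscriminantAnalysis
    classes: list[str]
    training_meta: dict = field(default_factory=dict)
    # smoothed non-derivative reference curves per class, for the r2 tiebreak
    tiebreak_refs: dict[str, list[tuple[np.ndarray, np.ndarray]]] = field(default_factory=dict)


def _smooth_on_grid(spectrum: ReferenceSpectrum, cfg: FeatureConfig) -> tuple[np.ndarray, np.ndarray]:
    """Resample to the model grid and smooth within the valid support.

    Returns (values, valid); values are NaN outside the support.
    """
    grid = cfg.grid
    values, valid = resample_to_grid(spectrum, grid)
    idx = np.where(valid)[0]
    seg = values[idx]
    from .preprocess import savgol_window_length

    if seg.size >= savgol_window_length(cfg.grid_step, cfg.savgol_half_window_nm):
        seg = savgol_smooth(seg, cfg.grid_step, cfg.savgol_order, cfg.savgol_half_window_nm)
    out = np.full(grid.shape, np.nan)
    out[idx] = seg
    return out, valid


def featurize(spectrum: ReferenceSpectrum, cfg: FeatureConfig) -> np.ndarray:
    """Spectrum → fingerprint feature vector.

    Resample to the common grid, Savitzky–Golay smooth, differentiate
    once (cancelling constant offsets), zero-impute positions outside
    the spectrum's support *after* differentiation (so imputation adds
    no spurious derivative structure), and scale to unit Euclidean norm
    (cancelling positive scale). Spectra covering less than half the
    common window are rejected.
    """
    grid = cfg.grid
    values, valid = _smooth_on_grid(spectrum, cfg)
    coverage = valid.mean()
    if coverage < cfg.min_coverage:
        raise ValidationError(
            f"spectrum covers {coverage:.0%} of the {cfg.grid_start:g}–"
            f"{cfg.grid_stop:g} nm window (need >= {cfg.min_coverage:.0%})"
        )
    idx = np.where(valid)[0]
    deriv_seg = first_derivative(values[idx], grid[idx])
    feat = np.zeros(grid.size)
    feat[idx] = deriv_seg
    norm = np.linalg.norm(feat)
    if norm == 0:
        raise ValidationError("flat spectrum has no fingerprint")
    return feat / norm


def _assemble(
    X: np.ndarray,
    y: np.ndarray,
    tiebreak_refs: dict[str, list],
    cfg: FeatureConfig,
    meta: dict,
) -> FingerprintModel:
    n, n_classes = X.shape[0], len(set(y))
    n_comp = max(1, min(n - n_classes, n - 1, X.shape[1]))
    proj, lda = _fit(X, y, n_comp)
    meta = dict(meta, n_spectra=n, n_classes=n_classes, n_components=n_comp)
    return FingerprintModel(
        feature_config=cfg,
        projection=proj,
        discriminant=lda,
        classes=list(lda.classes_),
        training_meta=meta,
        tiebreak_refs=tiebreak_refs,
    )


def train_fingerprint_model(
    library: SpectralLibrary, cfg: FeatureConfig | None = None
) -> FingerprintModel:
    """Train the variance-projected discriminant on a reference library.

    Features are projected to at most (n_samples − n_classes) principal
    components before the discriminant fit. If the within-class scatter
    is still singular the discriminant falls back to a shrinkage
    estimator. When every class has ≥2 spectra a leave-one-out accuracy
    of the full classifier — discriminant plus r² tiebreak — is recorded
    in ``training_meta``.
    """
    cfg = cfg or FeatureConfig()
    if not library.training_fit:
        raise ValidationError("library has fewer than 2 distinct species")
    X, y, curves = [], [], []
    for entry in library.entries:
        X.append(featurize(entry, cfg))
        y.append(entry.species)
        smoothed, valid = _smooth_on_grid(entry, cfg)
        curves.append((cfg.grid[valid], smoothed[valid]))
    X = np.vstack(X)
    y = np.asarray(y)
    classes = sorted(set(y))
    tiebreak_refs: dict[str, list] = {c: [] for c in classes}
    for label, curve in zip(y, curves):
        tiebreak_refs[label].append(curve)
    meta = {"per_class": {c: int((y == c).sum()) for c in classes}}
    model = _assemble(X, y, tiebreak_refs, cfg, meta)

    counts = np.array([(y == c).sum() for c in classes])
    n = X.shape[0]
    if counts.min() >= 2:
        correct = 0
        for i in range(n):
            keep = np.arange(n) != i
            refs_i = {c: [] for c in classes}
            for label, curve in zip(y[keep], (curves[j] for j in np.where(keep)[0])):
                refs_i[label].append(curve)
            m_i = _assemble(X[keep], y[keep], refs_i, cfg, {})
            res = _classify_features(m_i, X[i], *curves[i])
            correct += int(res.final_label == y[i])
        model.training_meta["loo_accuracy"] = correct / n
    return model


class NearestCentroidDiscriminant:
    """Fallback discriminant when every class has a single spectrum.

    With one sample per class the within-class covariance is undefined,
    so the model reduces to nearest centroid with a Gaussian kernel whose
    width is tied to the centroid spacing. Posteriors are deliberately
    diffuse: single-reference classes cannot be called with confidence,
    which routes decisions through the r² tiebreak.
    """

    def __init__(self, means: np.ndarray, classes: np.ndarray, s2: float):
        self.means_ = means
        self.classes_ = classes
        self.s2 = float(s2)

    @classmethod
    def fit_centroids(cls, Z: np.ndarray, y: np.ndarray) -> "NearestCentroidDiscriminant":
        classes = np.unique(y)
        means = np.vstack([Z[y == c].mean(axis=0) for c in classes])
        d2 = ((means[:, None, :] - means[None, :, :]) ** 2).sum(axis=2)
        off = d2[~np.eye(len(classes), dtype=bool)]
        s = 0.5 * np.sqrt(np.median(off)) if off.size else 1.0
        return cls(means, classes, max(s**2, np.finfo(float).tiny))

    def predict_proba(self, Z: np.ndarray) -> np.ndarray:
        d2 = ((Z[:, None, :] - self.means_[None, :, :]) ** 2).sum(axis=2)
        logp = -0.5 * d2 / self.s2
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, Z: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(Z), axis=1)]


def _fit(X: np.ndarray, y: np.ndarray, n_comp: int):
    proj = PCA(n_components=n_comp, svd_solver="full")
    Z = proj.fit_transform(X)
    if X.shape[0] <= len(set(y)):
        return proj, NearestCentroidDiscriminant.fit_centroids(Z, y)
    # Ledoit-Wolf shrinkage of the shared covariance: with 1-3 spectra per
    # class the empirical scatter is singular/ill-conditioned and plain LDA
    # produces overconfident posteriors that bypass the tiebreak stage
    lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    lda.fit(Z, y)
    return proj, lda


def classify_spectrum(
    model: FingerprintModel,
    spectrum: ReferenceSpectrum,
    p_conf: float = 0.95,
    margin: float = 0.25,
    n_tiebreak: int = 3,
) -> ClassificationResult:
    """Classify a (deconvolved or apex) spectrum.

    The discriminant's posterior ranking decides directly when it is
    confident (top posterior ≥ ``p_conf`` and top-two margin ≥
    ``margin``); otherwise the top ``n_tiebreak`` candidates are
    compared to the query by r² on smoothed, non-derivative absorbance
    curves and the best mean r² wins.
    """
    cfg = model.feature_config
    feat = featurize(spectrum, cfg)
    q_smooth, q_valid = _smooth_on_grid(spectrum, cfg)
    return _classify_features(
        model, feat, cfg.grid[q_valid], q_smooth[q_valid],
        p_conf=p_conf, margin=margin, n_tiebreak=n_tiebreak,
    )


def _classify_features(
    model: FingerprintModel,
    feat: np.ndarray,
    q_wl: np.ndarray,
    q_ab: np.ndarray,
    p_conf: float = 0.95,
    margin: float = 0.25,
    n_tiebreak: int = 3,
) -> ClassificationResult:
    z = model.projection.transform(feat[None, :])
    post = model.discriminant.predict_proba(z)[0]
    order = np.argsort(post)[::-1]
    candidates = [
        {"species": model.discriminant.classes_[i], "posterior": float(post[i])}
        for i in order
    ]
    top = candidates[0]["posterior"]
    second = candidates[1]["posterior"] if len(candidates) > 1 else 0.0
    tiebreak = top < p_conf or (top - second) < margin

    def mean_r2(species: str) -> float:
        vals = []
        for wl, ab in model.tiebreak_refs.get(species, []):
            try:
                vals.append(compare_spectra(q_wl, q_ab, wl, ab)["r2"])
            except ValidationError:
                continue
        return float(np.mean(vals)) if vals else -1.0

    if tiebreak:
        pool = [c["species"] for c in candidates[:n_tiebreak]]
        final = max(pool, key=mean_r2)
    else:
        final = candidates[0]["species"]

    # similarity of the query to the winning class's best reference
    best = {"r2": float("nan"), "frechet": float("nan")}
    best_r2 = -np.inf
    for wl, ab in model.tiebreak_refs.get(final, []):
        try:
            cmp_ = compare_spectra(q_wl, q_ab, wl, ab)
        except ValidationError:
            continue
        if cmp_["r2"] > best_r2:
            best_r2 = cmp_["r2"]
            best = cmp_
    return ClassificationResult(
        candidates=candidates,
        final_label=final,
        tiebreak_used=bool(tiebreak),
        r2_to_final=float(best["r2"]),
        frechet_to_final=float(best["frechet"]),
    )


# ---------------------------------------------------------------------------
# serialisation: one portable JSON archive (text metadata + numeric arrays)


def save_model(model: FingerprintModel, path: str | os.PathLike) -> None:
    proj, lda = model.projection, model.discriminant
    payload = {
        "feature_config": vars(model.feature_config),
        "classes": [str(c) for c in model.classes],
        "training_meta": model.training_meta,
        "projection": {
            "mean": proj.mean_.tolist(),
            "components": proj.components_.tolist(),
            "explained_variance": proj.explained_variance_.tolist(),
        },
        "discriminant": (
            {
                "kind": "centroid",
                "means": lda.means_.tolist(),
                "classes": [str(c) for c in lda.classes_],
                "s2": lda.s2,
            }
            if isinstance(lda, NearestCentroidDiscriminant)
            else {
                "kind": "lda",
                "means": lda.means_.tolist(),
                "coef": lda.coef_.tolist(),
                "intercept": lda.intercept_.tolist(),
                "classes": [str(c) for c in lda.classes_],
            }
        ),
        "tiebreak_refs": {
            sp: [[wl.tolist(), ab.tolist()] for wl, ab in refs]
            for sp, refs in model.tiebreak_refs.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path: str | os.PathLike) -> FingerprintModel:
    with open(path) as fh:
        payload = json.load(fh)
    cfg = FeatureConfig(**payload["feature_config"])
    proj = PCA(n_components=len(payload["projection"]["components"]))
    proj.mean_ = np.array(payload["projection"]["mean"])
    proj.components_ = np.array(payload["projection"]["components"])
    proj.explained_variance_ = np.array(payload["projection"]["explained_variance"])
    proj.n_components_ = proj.components_.shape[0]
    d = payload["discriminant"]
    if d.get("kind") == "centroid":
        lda = NearestCentroidDiscriminant(
            np.array(d["means"]), np.array(d["classes"]), d["s2"]
        )
    else:
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        lda.means_ = np.array(d["means"])
        lda.coef_ = np.array(d["coef"])
        lda.intercept_ = np.array(d["intercept"])
        lda.classes_ = np.array(d["classes"])
    tiebreak_refs = {
        sp: [(np.array(wl), np.array(ab)) for wl, ab in refs]
        for sp, refs in payload["tiebreak_refs"].items()
    }
    return FingerprintModel(
        feature_config=cfg,
        projection=proj,
        discriminant=lda,
        classes=list(lda.classes_),
        training_meta=payload["training_meta"],
        tiebreak_refs=tiebreak_refs,
    )
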