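"""Discriminant analysis of site preferences, and confidence-ranked filtering.

The model asks: how well do nuisance statistics (site rate, clade GC,
clade missingness) predict which topology a site prefers?  Gaussian
class-conditional discriminants (LDA with a pooled covariance, or QDA with
class-specific covariances) are fitted with the preferred topology as the
class label and class priors equal to the observed class proportions.
Per-site posteriors are computed by leave-one-out cross-validation (LOOCV)
and normalized by the prior of the site's observed class; a
posterior/prior ratio well above 1 marks a site whose preference is
predictable from features that should carry no phylogenetic information —
a putatively biased site.  Filtering removes the top-ranked fraction of
informative sites (with a seeded random-removal control).

The public surface follows the model/results idiom:

>>> model = SiteDiscriminantAnalysis.from_site_table(table, feature_set="rate")
>>> res = model.fit()
>>> res.prediction_lift()["overall"]
>>> res.permutation_test(n_perm=199, seed=1).pvalue
>>> res.rank_and_filter(aln, fraction=0.2)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqio import Alignment

__all__ = [
    "DiscriminantModel",
    "SiteDiscriminantAnalysis",
    "SiteDiscriminantResults",
    "PermutationResult",
    "FilterResult",
    "fit_discriminant",
    "loocv_posteriors",
    "prediction_lift",
    "permutation_test",
    "rank_and_filter",
    "random_filter",
]


# ---------------------------------------------------------------- fitting
@dataclass
class DiscriminantModel:
    """Fitted Gaussian class-conditional parameters."""

    method: str
    classes: list[str]
    means: np.ndarray          # (K, d)
    covariances: np.ndarray    # (K, d, d); identical copies for LDA
    priors: np.ndarray         # (K,)
    ridge: float

    def _discriminants(self, X: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.covariances)
        sign, logdet = np.linalg.slogdet(self.covariances)
        if np.any(sign <= 0):
            raise np.linalg.LinAlgError("non-PD covariance")
        diff = X[:, None, :] - self.means[None, :, :]  # (n, K, d)
        maha = np.einsum("nkd,kde,nke->nk", diff, inv, diff)
        return np.log(self.priors)[None, :] - 0.5 * logdet[None, :] - 0.5 * maha

    def posteriors(self, X: np.ndarray) -> np.ndarray:
        """Class posterior probabilities, rows summing to 1."""
        d = self._discriminants(np.asarray(X, float))
        d -= d.max(axis=1, keepdims=True)
        e = np.exp(d)
        return e / e.sum(axis=1, keepdims=True)


def _class_stats(X, y, classes):
    means, scatters, counts = [], [], []
    for k in classes:
        Xk = X[y == k]
        mu = Xk.mean(axis=0)
        diff = Xk - mu
        means.append(mu)
        scatters.append(diff.T @ diff)
        counts.append(len(Xk))
    return np.array(means), np.array(scatters), np.array(counts)


def _ridge_value(X: np.ndarray, ridge_scale: float) -> float:
    v = X.var(axis=0, ddof=1)
    return float(ridge_scale * v.mean()) if len(X) > 1 else ridge_scale


def fit_discriminant(X, y, method: str = "qda",
                     ridge_scale: float = 1e-6,
                     min_class_size: int | None = None) -> DiscriminantModel:
    """Fit LDA/QDA with priors equal to class proportions.

    A small ridge (``ridge_scale`` x mean feature variance) stabilizes
    covariances of near-constant features.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, dtype=object)
    if X.ndim != 2 or not np.isfinite(X).all():
        raise ValueError("features must be a finite 2-D array")
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    d = X.shape[1]
    need = (d + 2) if min_class_size is None else min_class_size
    small = [k for k in classes if (y == k).sum() < need]
    if small:
        raise ValueError(
            f"classes too small for a {d}-feature discriminant: {small}"
        )
    means, scatters, counts = _class_stats(X, y, classes)
    ridge = _ridge_value(X, ridge_scale)
    eye = np.eye(d)
    if method == "qda":
        covs = scatters / (counts - 1)[:, None, None] + ridge * eye
    elif method == "lda":
        pooled = scatters.sum(axis=0) / (len(X) - len(classes)) + ridge * eye
        covs = np.repeat(pooled[None], len(classes), axis=0)
    else:
        raise ValueError(f"unknown method {method!r}")
    sign, _ = np.linalg.slogdet(covs)
    if np.any(sign <= 0):
        raise np.linalg.LinAlgError(
            "singular class covariance after ridge; prune collinear features"
        )
    priors = counts / counts.sum()
    return DiscriminantModel(method, classes, means, covs, priors, ridge)


def loocv_posteriors(X, y, method: str = "qda",
                     ridge_scale: float = 1e-6) -> tuple[np.ndarray, list[str]]:
    """Leave-one-out posteriors: site i is scored by the model fitted to all
    sites except i (class parameters and priors downdated exactly).

    Batched per class: the left-out site only changes its own class's mean
    and scatter (rank-one downdate) and all priors; covariance inverses and
    log-determinants are evaluated with stacked linear algebra.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, dtype=object)
    model = fit_discriminant(X, y, method, ridge_scale)
    classes = model.classes
    K, (n, d) = len(classes), X.shape
    means, scatters, counts = _class_stats(X, y, classes)
    ridge, eye = model.ridge, np.eye(d)
    pooled_scatter = scatters.sum(axis=0)

    logpost = np.empty((n, K))
    for ki, k in enumerate(classes):
        idx = np.where(y == k)[0]
        nk = counts[ki]
        Xk = X[idx]
        diff = Xk - means[ki]                         # (nk, d)
        mu_new = (nk * means[ki] - Xk) / (nk - 1)     # (nk, d)
        down = scatters[ki] - (nk / (nk - 1)) * np.einsum(
            "ni,nj->nij", diff, diff
        )                                             # (nk, d, d)
        if method == "qda":
            covs_k = down / (nk - 2) + ridge * eye
        else:
            pooled = (pooled_scatter - scatters[ki] + down) / (n - 1 - K)
            covs_k = pooled + ridge * eye
        inv_k = np.linalg.inv(covs_k)
        sign_k, logdet_k = np.linalg.slogdet(covs_k)
        if np.any(sign_k <= 0):
            raise np.linalg.LinAlgError("singular LOOCV covariance")
        new_counts = counts.copy().astype(float)
        new_counts[ki] -= 1
        priors = new_counts / (n - 1)
        # discriminants for the left-out sites
        delta = np.empty((nk, K))
        for kj in range(K):
            if kj == ki:
                dmu = Xk - mu_new
                maha = np.einsum("ni,nij,nj->n", dmu, inv_k, dmu)
                delta[:, kj] = (
                    np.log(priors[kj]) - 0.5 * logdet_k - 0.5 * maha
                )
            else:
                if method == "qda":
                    cov_j = scatters[kj] / (counts[kj] - 1) + ridge * eye
                    inv_j = np.linalg.inv(cov_j)
                    _, logdet_j = np.linalg.slogdet(cov_j)
                    inv_j_s = np.broadcast_to(inv_j, (nk, d, d))
                    logdet_j_s = logdet_j
                else:
                    inv_j_s, logdet_j_s = inv_k, logdet_k
                dmu = Xk - means[kj]
                maha = np.einsum("ni,nij,nj->n", dmu, inv_j_s, dmu)
                delta[:, kj] = (
                    np.log(priors[kj]) - 0.5 * logdet_j_s - 0.5 * maha
                )
        logpost[idx] = delta
    logpost -= logpost.max(axis=1, keepdims=True)
    post = np.exp(logpost)
    post /= post.sum(axis=1, keepdims=True)
    return post, classes


# ---------------------------------------------------------------- results
@dataclass
class PermutationResult:
    pvalue: float
    observed: float
    null: np.ndarray
    n_perm: int
    seed: int


@dataclass
class FilterResult:
    """Outcome of removing sites from an alignment."""

    fraction: float | None
    removed_sites: np.ndarray      # 1-based site indices, sorted
    retained: Alignment
    removed: Alignment
    seed: int | None = None

    @property
    def n_removed(self) -> int:
        return len(self.removed_sites)


class SiteDiscriminantAnalysis:
    """Discriminant model of preferred topology from nuisance features.

    Parameters
    ----------
    features : DataFrame (n_sites_eligible, d)
        Finite feature values for *informative* sites only.
    classes : array of str
        Preferred topology per eligible site.
    sites : array of int
        1-based alignment positions of the eligible sites.
    method : {'qda', 'lda'}
    ridge_scale : float
        Ridge added to covariances, as a fraction of mean feature variance.
    confidence : {'observed_ratio', 'predicted_posterior'}
        Ranking key for filtering: the LOOCV posterior/prior ratio of the
        observed class (default), or the posterior of the predicted class.
    """

    def __init__(self, features: pd.DataFrame, classes, sites=None,
                 method: str = "qda", ridge_scale: float = 1e-6,
                 confidence: str = "observed_ratio"):
        self.feature_names = list(features.columns)
        self.X = features.to_numpy(dtype=float)
        self.y = np.asarray(classes, dtype=object)
        if len(self.X) != len(self.y):
            raise ValueError("features/classes length mismatch")
        self.sites = (
            np.asarray(sites, int)
            if sites is not None
            else np.arange(1, len(self.y) + 1)
        )
        if method not in ("qda", "lda"):
            raise ValueError("method must be 'qda' or 'lda'")
        if confidence not in ("observed_ratio", "predicted_posterior"):
            raise ValueError("unknown confidence metric")
        self.method = method
        self.ridge_scale = ridge_scale
        self.confidence = confidence

    @classmethod
    def from_site_table(cls, table, feature_set: str = "rate+gc+missing",
                        method: str = "qda", **kwargs) -> "SiteDiscriminantAnalysis":
        mask = table.informative_mask
        feats = table.features(feature_set).loc[mask]
        return cls(
            feats,
            table.df.loc[mask, "preferred"].to_numpy(),
            table.df.loc[mask, "site"].to_numpy(),
            method=method,
            **kwargs,
        )

    def fit(self) -> "SiteDiscriminantResults":
        model = fit_discriminant(self.X, self.y, self.method, self.ridge_scale)
        post, classes = loocv_posteriors(
            self.X, self.y, self.method, self.ridge_scale
        )
        return SiteDiscriminantResults(self, model, post, classes)


class SiteDiscriminantResults:
    """LOOCV posteriors, lifts, permutation test and filtering."""

    def __init__(self, model_spec: SiteDiscriminantAnalysis,
                 model: DiscriminantModel, loocv: np.ndarray,
                 classes: list[str]):
        self.model_spec = model_spec
        self.model = model
        self.classes = classes
        self.loocv_posteriors = loocv
        y = model_spec.y
        self.observed = y
        self.predicted = np.array(
            [classes[i] for i in loocv.argmax(axis=1)], dtype=object
        )
        self.priors = model.priors
        cls_index = {k: i for i, k in enumerate(classes)}
        obs_idx = np.array([cls_index[c] for c in y])
        self.posterior_observed = loocv[np.arange(len(y)), obs_idx]
        self.posterior_prior_ratio = (
            self.posterior_observed / self.priors[obs_idx]
        )

    # ------------------------------------------------------------- stats
    @property
    def accuracy(self) -> float:
        return float((self.predicted == self.observed).mean())

    @property
    def mean_ratio(self) -> float:
        """Average LOOCV posterior/prior ratio of the observed class."""
        return float(self.posterior_prior_ratio.mean())

    def prediction_lift(self) -> dict:
        """Accuracy relative to a prior-proportional random assigner.

        Overall lift = accuracy / sum(prior_k^2); per-class lift =
        recall_k / prior_k (NA for empty classes).
        """
        out = {"overall": self.accuracy / float((self.priors ** 2).sum())}
        per = {}
        for i, k in enumerate(self.classes):
            mask = self.observed == k
            if mask.sum() == 0:
                per[k] = float("nan")
            else:
                recall = float((self.predicted[mask] == k).mean())
                per[k] = recall / float(self.priors[i])
        out["per_class"] = per
        return out

    def permutation_test(self, n_perm: int = 1000,
                         seed: int = 0) -> PermutationResult:
        """Permute preferred-topology labels among sites and recompute the
        mean LOOCV posterior/prior ratio; p = (1 + #{null >= obs})/(n+1)."""
        if n_perm < 99:
            raise ValueError("n_perm must be at least 99")
        spec = self.model_spec
        rng = np.random.default_rng(seed)
        null = np.empty(n_perm)
        for b in range(n_perm):
            yp = rng.permutation(spec.y)
            post, classes = loocv_posteriors(
                spec.X, yp, spec.method, spec.ridge_scale
            )
            cls_index = {k: i for i, k in enumerate(classes)}
            counts = np.array([(yp == k).sum() for k in classes])
            priors = counts / counts.sum()
            oi = np.array([cls_index[c] for c in yp])
            null[b] = (post[np.arange(len(yp)), oi] / priors[oi]).mean()
        obs = self.mean_ratio
        p = (1.0 + float((null >= obs).sum())) / (n_perm + 1.0)
        return PermutationResult(p, obs, null, n_perm, seed)

    # --------------------------------------------------------- filtering
    def _ranking_key(self) -> np.ndarray:
        if self.model_spec.confidence == "observed_ratio":
            return self.posterior_prior_ratio
        return self.loocv_posteriors.max(axis=1)

    def ranked_sites(self) -> np.ndarray:
        """Eligible sites ranked most-suspect first (ties by site index)."""
        key = self._ranking_key()
        order = np.lexsort((self.model_spec.sites, -key))
        return self.model_spec.sites[order]

    def rank_and_filter(self, aln: Alignment, fraction: float) -> FilterResult:
        """Remove the top `fraction` of eligible (informative) sites by
        prediction confidence; uninformative sites are always retained."""
        if not 0 < fraction < 1:
            raise ValueError("fraction must be in (0, 1)")
        eligible = self.model_spec.sites
        k = int(round(fraction * len(eligible)))
        if k >= len(eligible):
            raise ValueError("fraction would remove all informative sites")
        removed = np.sort(self.ranked_sites()[:k])
        return _split_alignment(aln, removed, fraction=fraction)

    def random_filter(self, aln: Alignment, count: int,
                      seed: int = 0) -> FilterResult:
        """Remove `count` eligible sites uniformly at random (control)."""
        eligible = self.model_spec.sites
        if count > len(eligible):
            raise ValueError("count exceeds eligible sites")
        rng = np.random.default_rng(seed)
        removed = np.sort(rng.choice(eligible, size=count, replace=False))
        return _split_alignment(aln, removed, fraction=None, seed=seed)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.loocv_posteriors,
            columns=[f"posterior_{c}" for c in self.classes],
        )
        df.insert(0, "site", self.model_spec.sites)
        df["predicted"] = self.predicted
        df["observed"] = self.observed
        df["ratio"] = self.posterior_prior_ratio
        order = np.empty(len(df), dtype=int)
        order[np.lexsort((self.model_spec.sites, -self._ranking_key()))] = (
            np.arange(1, len(df) + 1)
        )
        df["rank"] = order
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.8g")

    def summary(self) -> str:
        lift = self.prediction_lift()
        lines = [
            f"Site discriminant analysis ({self.model_spec.method.upper()}, "
            f"features: {', '.join(self.model_spec.feature_names)})",
            f"  sites (informative) : {len(self.observed)}",
            f"  classes             : "
            + ", ".join(
                f"{k} (prior {p:.3f})"
                for k, p in zip(self.classes, self.priors)
            ),
            f"  LOOCV accuracy      : {self.accuracy:.4f}",
            f"  overall lift        : {lift['overall']:.3f}",
            f"  mean post/prior     : {self.mean_ratio:.3f}",
        ]
        for k, v in lift["per_class"].items():
            lines.append(f"    lift[{k}] : {v:.3f}")
        return "\n".join(lines)


def _split_alignment(aln: Alignment, removed_sites: np.ndarray,
                     fraction, seed=None) -> FilterResult:
    removed_sites = np.asarray(removed_sites, int)
    mask = np.zeros(aln.n_sites, dtype=bool)
    mask[removed_sites - 1] = True
    retained = aln.take_sites(np.where(~mask)[0], "retained")
    removed = aln.take_sites(np.where(mask)[0], "removed")
    return FilterResult(fraction, removed_sites, retained, removed, seed)


# ------------------------------------------------- functional conveniences
def prediction_lift(results: SiteDiscriminantResults) -> dict:
    return results.prediction_lift()


def permutation_test(X, y, method: str = "qda", n_perm: int = 1000,
                     seed: int = 0) -> PermutationResult:
    feats = pd.DataFrame(np.asarray(X, float))
    feats.columns = [f"f{i}" for i in range(feats.shape[1])]
    res = SiteDiscriminantAnalysis(feats, y, method=method).fit()
    return res.permutation_test(n_perm=n_perm, seed=seed)


def rank_and_filter(aln: Alignment, results: SiteDiscriminantResults,
                    fraction: float) -> FilterResult:
    return results.rank_and_filter(aln, fraction)


def random_filter(aln: Alignment, results: SiteDiscriminantResults,
                  count: int, seed: int = 0) -> FilterResult:
    return results.random_filter(aln, count, seed)
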