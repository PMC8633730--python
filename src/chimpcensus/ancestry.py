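"""Reference-panel PCA projection and supervised admixture estimation.

Both estimators follow the scikit-learn protocol.  Inputs are dosage arrays
(samples x sites) as floats with ``numpy.nan`` for missing genotypes; the
``from_matrix`` helper converts a :class:`~chimpcensus.genio.GenotypeMatrix`.

``ReferencePCA`` standardizes panel genotypes site-wise — mean-centering and
scaling by sqrt(p(1-p)) with p the panel allele frequency, the usual
genotype-PCA normalization — and projects unlabeled samples onto the panel's
principal axes, with missing entries contributing zero after centering.

``SupervisedAdmixture`` holds per-subspecies allele frequencies fixed (the
supervised setting) and maximizes, per sample, the binomial log-likelihood
of its dosages under the mixture frequency f = sum_k q_k p_k over the
simplex of ancestry proportions q, via EM (guaranteed monotone).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .genio import GenotypeMatrix
from .popsim import MISSING, ReferencePanel

#: One unadmixed great-great-grandparent contributes 1/2**4 of a genome.
ASSIGNMENT_THRESHOLD = 0.0625


def from_matrix(g: GenotypeMatrix) -> np.ndarray:
    """Dosages as float with NaN for missing."""
    x = g.dosages.astype(float)
    x[g.dosages == MISSING] = np.nan
    return x


def _check_dosages(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D samples x sites dosage array")
    with np.errstate(invalid="ignore"):
        if np.nanmin(X, initial=0) < 0 or np.nanmax(X, initial=0) > 2:
            raise ValueError("dosages must lie in [0, 2] or be NaN")
    return X


def panel_frequencies(panel: ReferencePanel,
                      pseudocount: float = 0.5) -> pd.DataFrame:
    """Empirical per-subspecies alternate-allele frequencies.

    A pseudocount (default half an allele) keeps frequencies off the 0/1
    boundaries, where the admixture likelihood degenerates.
    """
    rows = {}
    g = panel.genotypes
    labels = np.array([panel.labels[s] for s in panel.samples])
    for pop in panel.populations:
        sub = g[labels == pop]
        valid = sub != MISSING
        alt = np.where(valid, sub, 0).sum(axis=0)
        tot = 2 * valid.sum(axis=0)
        rows[pop] = (alt + pseudocount) / (tot + 2 * pseudocount)
    return pd.DataFrame(rows).T


class ReferencePCA(TransformerMixin, BaseEstimator):
    """PCA fit on a labeled reference panel; unknowns are projected.

    Parameters
    ----------
    n_components : int, default 4
        Number of principal axes to retain.

    Attributes
    ----------
    mean_, scale_ : per-site centering and scaling from the panel.
    components_ : principal axes (n_components x n_sites).
    explained_variance_ratio_ : variance shares, ordered.
    """

    def __init__(self, n_components: int = 4):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = _check_dosages(X)
        freq = np.nanmean(X, axis=0) / 2.0
        poly = (freq > 0) & (freq < 1) & ~np.isnan(freq)
        if poly.sum() < self.n_components:
            raise ValueError("fewer polymorphic sites than components")
        self.site_mask_ = poly
        self.mean_ = 2 * freq[poly]
        self.scale_ = np.sqrt(freq[poly] * (1 - freq[poly]))
        Z = self._standardize(X)
        self._pca = PCA(n_components=self.n_components, svd_solver="full")
        self._pca.fit(Z)
        self.components_ = self._pca.components_
        self.explained_variance_ = self._pca.explained_variance_
        self.explained_variance_ratio_ = self._pca.explained_variance_ratio_
        self.panel_coords_ = self._pca.transform(Z)
        return self

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        Z = (X[:, self.site_mask_] - self.mean_) / self.scale_
        return np.nan_to_num(Z, nan=0.0)   # missing -> site mean

    def transform(self, X) -> np.ndarray:
        X = _check_dosages(X)
        if X.shape[1] != self.site_mask_.shape[0]:
            raise ValueError("site registry mismatch with fitted panel")
        overlap = 1 - np.isnan(X[:, self.site_mask_]).mean(axis=1)
        if (overlap < 0.5).any():
            import logging
            logging.getLogger(__name__).warning(
                "%d samples share <50%% of panel sites",
                int((overlap < 0.5).sum()))
        return self._standardize(X) @ self.components_.T


class SupervisedAdmixture(BaseEstimator):
    """Per-sample ancestry proportions with fixed source frequencies.

    ``fit(X, y)`` takes labeled panel dosages and stores per-population
    allele frequencies (with a pseudocount); ``predict_proba(X)`` runs the
    EM to convergence independently for each query sample and returns the
    n x K matrix of ancestry proportions (rows on the simplex).

    Parameters
    ----------
    tol : float
        Convergence threshold on the per-sample log-likelihood gain.
    max_iter : int
        EM iteration cap; non-converged samples keep their last iterate and
        are flagged in ``converged_``.
    pseudocount : float
        Alleles added when estimating panel frequencies.
    """

    _EPS = 1e-6

    def __init__(self, tol: float = 1e-6, max_iter: int = 2000,
                 pseudocount: float = 0.5):
        self.tol = tol
        self.max_iter = max_iter
        self.pseudocount = pseudocount

    def fit(self, X, y):
        X = _check_dosages(X)
        y = np.asarray(y)
        self.classes_ = np.array(sorted(set(y)))
        freqs = []
        for pop in self.classes_:
            sub = X[y == pop]
            alt = np.nansum(sub, axis=0)
            tot = 2 * np.sum(~np.isnan(sub), axis=0)
            freqs.append((alt + self.pseudocount) / (tot + 2 * self.pseudocount))
        self.pop_freqs_ = np.clip(np.vstack(freqs), self._EPS, 1 - self._EPS)
        return self

    @classmethod
    def from_frequencies(cls, freqs: pd.DataFrame, **kwargs) -> "SupervisedAdmixture":
        """Build a fitted estimator from a populations x sites table."""
        est = cls(**kwargs)
        est.classes_ = np.array(list(freqs.index))
        est.pop_freqs_ = np.clip(freqs.to_numpy(dtype=float),
                                 cls._EPS, 1 - cls._EPS)
        return est

    def _loglik(self, D, valid, Q):
        F = self.pop_freqs_
        f = np.clip(Q @ F, self._EPS, 1 - self._EPS)
        ll = np.where(valid, D * np.log(f) + (2 - D) * np.log(1 - f), 0.0)
        return ll.sum(axis=1)

    def predict_proba(self, X) -> np.ndarray:
        X = _check_dosages(X)
        F = self.pop_freqs_                       # (K, L)
        K = F.shape[0]
        if K == 1:
            self.n_iter_ = np.zeros(X.shape[0], dtype=int)
            self.converged_ = np.ones(X.shape[0], dtype=bool)
            self.loglik_ = self._loglik(np.nan_to_num(X), ~np.isnan(X),
                                        np.ones((X.shape[0], 1)))
            return np.ones((X.shape[0], 1))
        valid = ~np.isnan(X)
        D = np.nan_to_num(X, nan=0.0)
        n = X.shape[0]
        Q = np.full((n, K), 1.0 / K)
        n_valid = valid.sum(axis=1)
        ll_old = self._loglik(D, valid, Q)
        active = np.ones(n, dtype=bool)
        n_iter = np.zeros(n, dtype=int)
        for _ in range(self.max_iter):
            if not active.any():
                break
            Qa = Q[active]
            Da = D[active]
            va = valid[active]
            f = np.clip(Qa @ F, self._EPS, 1 - self._EPS)       # (n_a, L)
            # allele-level EM responsibilities, summed over sites
            alt_post = Qa[:, :, None] * F[None, :, :] / f[:, None, :]
            ref_post = Qa[:, :, None] * (1 - F)[None, :, :] / (1 - f)[:, None, :]
            num = (np.where(va, Da, 0.0)[:, None, :] * alt_post
                   + np.where(va, 2 - Da, 0.0)[:, None, :] * ref_post).sum(axis=2)
            Qa_new = num / (2 * n_valid[active])[:, None]
            Qa_new /= Qa_new.sum(axis=1, keepdims=True)
            Q[active] = Qa_new
            ll_new = self._loglik(D[active], valid[active], Qa_new)
            gain = ll_new - ll_old[active]
            n_iter[active] += 1
            done = gain < self.tol
            ll_old[active] = ll_new
            idx = np.flatnonzero(active)
            active[idx[done]] = False
        self.n_iter_ = n_iter
        self.converged_ = ~active
        self.loglik_ = ll_old
        return Q

    def predict(self, X) -> np.ndarray:
        """Majority-ancestry label per sample."""
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def supervised_admixture(panel: ReferencePanel, X, tol: float = 1e-6,
                         max_iter: int = 2000,
                         ) -> tuple[np.ndarray, list[str], "SupervisedAdmixture"]:
    """Ancestry proportions for query dosages against a reference panel.

    Uses the panel's per-subspecies frequency vectors as the fixed source
    frequencies (the supervised setting).  Returns (Q, populations,
    estimator); convergence flags live on ``estimator.converged_``.
    """
    freqs = pd.DataFrame({p: panel.pop_freqs[p] for p in panel.populations}).T
    est = SupervisedAdmixture.from_frequencies(freqs, tol=tol,
                                               max_iter=max_iter)
    Q = est.predict_proba(X)
    return Q, list(est.classes_), est


@dataclass(frozen=True)
class AncestryCall:
    """Threshold ancestry assignment for one sample."""

    assigned: tuple[str, ...]
    exclusive: bool


def assign_ancestry(q, populations, threshold: float = ASSIGNMENT_THRESHOLD,
                    ) -> AncestryCall:
    """Assign subspecies contributing >= threshold; exclusivity is strict.

    A subspecies is assigned when its proportion reaches the threshold
    (inclusive, default 6.25% — one unadmixed great-great-grandparent); a
    sample is exclusively of one ancestry only when that component strictly
    exceeds 1 - threshold (93.75%).
    """
    q = np.asarray(q, dtype=float)
    if (q < -1e-9).any() or abs(q.sum() - 1) > 1e-6:
        raise ValueError("q must lie on the simplex")
    assigned = tuple(p for p, v in zip(populations, q) if v >= threshold)
    exclusive = bool(q.max() > 1 - threshold)
    return AncestryCall(assigned=assigned, exclusive=exclusive)


def ancestry_profiles(samples: list[str], Q: np.ndarray, populations,
                      threshold: float = ASSIGNMENT_THRESHOLD,
                      converged: np.ndarray | None = None) -> pd.DataFrame:
    """Long-form ancestry table: q per subspecies, assigned set, flags."""
    rows = []
    for i, s in enumerate(samples):
        call = assign_ancestry(Q[i], populations, threshold)
        row = {"sample_id": s}
        row.update({f"q_{p}": Q[i, k] for k, p in enumerate(populations)})
        row["assigned"] = ",".join(call.assigned)
        row["exclusive"] = call.exclusive
        row["converged"] = bool(converged[i]) if converged is not None else True
        rows.append(row)
    return pd.DataFrame(rows)
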