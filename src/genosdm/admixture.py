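"""Ancestry-proportion estimation and cluster assignment.

The model is the standard binomial admixture likelihood: individual ``i``
carries dosage ``g_is ~ Binomial(2, f_is)`` at site ``s`` with
``f_is = sum_l q_il p_ls``, where ``q_i`` are the individual's ancestry
proportions over ``L`` ancestral populations (a point on the simplex) and
``p_l`` the ancestral allele frequencies. Both joint estimation (q and p
learned together, the usual unsupervised mode) and projection (q estimated
with p frozen from a reference fit, used to place individuals from newly
sampled ranges onto an existing ancestry space) are supported.

Optimization is expectation–maximization on the complete-data likelihood in
which each of an individual's 2 allele copies at a site is attributed to an
ancestral population. EM is monotone in the log-likelihood, which the
implementation asserts per iteration. Missing dosages are skipped per
individual per site.

Hard cluster labels are obtained by k-means on the rows of Q; labels are
renumbered canonically (descending cluster size, ties by centroid
lexicographic order) so results are reproducible across runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans, kmeans_plusplus

from .genotypes import GenotypeMatrix

__all__ = [
    "AncestryMatrix",
    "AdmixtureEM",
    "estimate_q_projection",
    "estimate_admixture_joint",
    "choose_L",
    "assign_clusters",
]

_EPS = 1e-6  # allele-frequency clip keeping likelihoods finite


@dataclass
class AncestryMatrix:
    """Per-individual ancestry proportions plus hard cluster labels.

    ``q`` has one row per individual on the L-simplex; ``cluster`` holds
    1-based k-means labels (0 meaning "not yet assigned").
    """

    q: np.ndarray
    cluster: np.ndarray | None = None
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.ndim != 2:
            raise ValueError("q must be 2-D (individuals x L)")
        if np.any(self.q < -1e-12):
            raise ValueError("ancestry proportions must be non-negative")
        if not np.allclose(self.q.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each row of q must sum to 1")
        if self.cluster is not None:
            self.cluster = np.asarray(self.cluster, dtype=int)
            if self.cluster.shape[0] != self.q.shape[0]:
                raise ValueError("cluster labels do not match q rows")

    @property
    def L(self) -> int:
        return self.q.shape[1]

    def dominant(self) -> np.ndarray:
        """0-based index of each individual's largest ancestry component."""
        return np.argmax(self.q, axis=1)


def _as_dosages(X) -> np.ndarray:
    if isinstance(X, GenotypeMatrix):
        return X.dosages
    return np.asarray(X, dtype=float)


def _loglik(G: np.ndarray, F: np.ndarray) -> float:
    """Binomial log-likelihood (without the constant) over non-missing calls."""
    with np.errstate(invalid="ignore"):
        ll = G * np.log(F) + (2.0 - G) * np.log1p(-F)
    return float(np.nansum(ll))


def _em_responsibility_sums(G, Q, P):
    """Shared E-step sums for the q and p updates.

    Returns (Nq, Na, Nb): Nq[i,l] is the expected number of allele copies
    individual i derives from population l; Na[l,s]/Nb[l,s] are expected
    alternate/reference allele counts attributed to population l at site s.
    """
    F = np.clip(Q @ P, _EPS, 1.0 - _EPS)
    with np.errstate(invalid="ignore"):
        R = G / F
        S = (2.0 - G) / (1.0 - F)
    R = np.nan_to_num(R)
    S = np.nan_to_num(S)
    Nq = Q * (R @ P.T + S @ (1.0 - P.T))
    Na = P * (Q.T @ R)
    Nb = (1.0 - P) * (Q.T @ S)
    return Nq, Na, Nb


class AdmixtureEM(BaseEstimator, TransformerMixin):
    """EM estimator of ancestry proportions under the admixture model.

    Parameters
    ----------
    n_components : int
        Number of ancestral populations L.
    max_iter : int
        Iteration cap for both joint fitting and projection.
    tol : float
        Joint mode stops when the log-likelihood improves by less than
        ``tol`` in an iteration.
    projection_tol : float
        Projection mode stops when ``max |dq| < projection_tol``.
    random_state : int or None
        Seeds the k-means++ initialization of the ancestral frequencies.

    Attributes
    ----------
    allele_freqs_ : ndarray (L, n_sites)
        Estimated ancestral allele frequencies, clipped to [1e-6, 1 - 1e-6].
    q_ : ndarray (n_individuals, L)
        Ancestry proportions of the training individuals.
    loglik_history_ : list of float
        Log-likelihood after every joint-EM iteration (non-decreasing).
    converged_ : bool
    n_iter_ : int

    Columns are ordered by descending mean ancestry proportion so label
    switching between runs is resolved deterministically.
    """

    def __init__(self, n_components: int = 3, max_iter: int = 5000,
                 tol: float = 1e-3, projection_tol: float = 1e-6,
                 random_state: int | None = None):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.projection_tol = projection_tol
        self.random_state = random_state

    # -- joint mode ---------------------------------------------------------
    def fit(self, X, y=None) -> "AdmixtureEM":
        G = _as_dosages(X)
        n, m = G.shape
        L = self.n_components
        if L < 1 or L >= max(n, 2):
            raise ValueError("n_components must satisfy 1 <= L < n_individuals")
        if L == 1:
            freq = np.nanmean(G, axis=0) / 2.0
            self.allele_freqs_ = np.clip(freq, _EPS, 1.0 - _EPS)[None, :]
            self.q_ = np.ones((n, 1))
            F = np.broadcast_to(self.allele_freqs_, (n, m))
            self.loglik_history_ = [_loglik(G, F)]
            self.converged_, self.n_iter_ = True, 0
            return self

        rng = np.random.default_rng(self.random_state)
        G_imp = np.where(np.isnan(G), np.nanmean(G, axis=0, keepdims=True), G)
        G_imp = np.nan_to_num(G_imp, nan=1.0)  # all-missing sites
        centers, _ = kmeans_plusplus(G_imp, L,
                                     random_state=int(rng.integers(2**31 - 1)))
        P = np.clip(centers / 2.0, _EPS, 1.0 - _EPS)
        Q = np.full((n, L), 1.0 / L)

        history: list[float] = [_loglik(G, np.clip(Q @ P, _EPS, 1 - _EPS))]
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            Nq, Na, Nb = _em_responsibility_sums(G, Q, P)
            Q = Nq / Nq.sum(axis=1, keepdims=True)
            denom = Na + Nb
            with np.errstate(invalid="ignore", divide="ignore"):
                P_new = np.where(denom > 0, Na / denom, P)
            P = np.clip(P_new, _EPS, 1.0 - _EPS)
            ll = _loglik(G, np.clip(Q @ P, _EPS, 1 - _EPS))
            if ll < history[-1] - 1e-8 * max(1.0, abs(history[-1])):
                raise RuntimeError("EM log-likelihood decreased; numerical failure")
            improvement = ll - history[-1]
            history.append(ll)
            if improvement < self.tol:
                converged = True
                break
        if not converged:
            warnings.warn("admixture EM did not converge within max_iter")

        order = np.argsort(-Q.mean(axis=0), kind="stable")
        self.q_ = Q[:, order]
        self.allele_freqs_ = P[order]
        self.loglik_history_ = history
        self.converged_ = converged
        self.n_iter_ = it
        return self

    # -- projection mode ----------------------------------------------------
    def transform(self, X) -> np.ndarray:
        """Project new individuals onto the fitted ancestral frequencies.

        Runs EM on q only (p frozen) from a uniform start; this is the
        standard way to place individuals from newly sampled ranges onto an
        ancestry space learned in a reference range.
        """
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "allele_freqs_")
        return project_q(_as_dosages(X), self.allele_freqs_,
                         tol=self.projection_tol, max_iter=self.max_iter)

    def score(self, X, y=None) -> float:
        """Mean per-individual log-likelihood under the fitted model."""
        G = _as_dosages(X)
        Q = self.transform(X)
        F = np.clip(Q @ self.allele_freqs_, _EPS, 1.0 - _EPS)
        return _loglik(G, F) / G.shape[0]


def project_q(G: np.ndarray, P: np.ndarray, tol: float = 1e-6,
              max_iter: int = 2000) -> np.ndarray:
    """EM for ancestry proportions with ancestral frequencies fixed.

    Maximizes the binomial admixture likelihood per individual; rows stay on
    the simplex after every step, and the per-individual log-likelihood is
    non-decreasing (EM). Returns Q of shape (n_individuals, L).
    """
    G = np.asarray(G, dtype=float)
    P = np.clip(np.asarray(P, dtype=float), _EPS, 1.0 - _EPS)
    n = G.shape[0]
    L = P.shape[0]
    Q = np.full((n, L), 1.0 / L)
    for _ in range(max_iter):
        F = np.clip(Q @ P, _EPS, 1.0 - _EPS)
        with np.errstate(invalid="ignore"):
            R = np.nan_to_num(G / F)
            S = np.nan_to_num((2.0 - G) / (1.0 - F))
        Nq = Q * (R @ P.T + S @ (1.0 - P.T))
        total = Nq.sum(axis=1, keepdims=True)
        Q_new = np.where(total > 0, Nq / np.where(total > 0, total, 1.0), Q)
        delta = np.abs(Q_new - Q).max()
        Q = Q_new
        if delta < tol:
            break
    else:
        warnings.warn("projection EM did not converge within max_iter")
    return Q


# -- module-level wrappers mirroring the pipeline vocabulary ----------------

def estimate_q_projection(g, p, tol: float = 1e-6,
                          max_iter: int = 2000) -> AncestryMatrix:
    """Ancestry proportions for new individuals given fixed ancestral freqs."""
    G = _as_dosages(g)
    p = np.asarray(p, dtype=float)
    if G.shape[1] != p.shape[1]:
        raise ValueError("genotypes and allele frequencies have different "
                         "numbers of sites")
    ids = g.sample_ids if isinstance(g, GenotypeMatrix) else None
    return AncestryMatrix(project_q(G, p, tol=tol, max_iter=max_iter),
                          sample_ids=ids)


def estimate_admixture_joint(g, L: int, seed: int | None = None,
                             tol: float = 1e-3, max_iter: int = 5000
                             ) -> tuple[AncestryMatrix, np.ndarray]:
    """Joint EM estimate of (Q, P); columns ordered by descending mean q."""
    est = AdmixtureEM(n_components=L, tol=tol, max_iter=max_iter,
                      random_state=seed).fit(g)
    ids = g.sample_ids if isinstance(g, GenotypeMatrix) else None
    return AncestryMatrix(est.q_, sample_ids=ids), est.allele_freqs_


def choose_L(g, L_values, n_folds: int = 5, seed: int | None = None,
             tol: float = 1e-2, max_iter: int = 1000) -> int:
    """Pick L by masked-entry cross-validation.

    A random 1/n_folds of the dosage entries is masked per fold; the joint
    model is fitted on the remainder and the masked entries are scored by
    binomial deviance under the fitted presence probabilities. Returns the
    candidate with the smallest mean CV error (ties go to the smaller L).
    """
    L_values = list(L_values)
    if not L_values:
        raise ValueError("L_values must be non-empty")
    if len(L_values) == 1:
        return L_values[0]
    G = _as_dosages(g)
    rng = np.random.default_rng(seed)
    observed = np.isfinite(G)
    fold_of = rng.integers(0, n_folds, size=G.shape)
    errors = {L: [] for L in L_values}
    for fold in range(n_folds):
        held = observed & (fold_of == fold)
        if not held.any():
            continue
        G_train = G.copy()
        G_train[held] = np.nan
        for L in L_values:
            est = AdmixtureEM(n_components=L, tol=tol, max_iter=max_iter,
                              random_state=int(rng.integers(2**31 - 1)))
            est.fit(G_train)
            F = np.clip(est.q_ @ est.allele_freqs_, _EPS, 1.0 - _EPS)
            gh, fh = G[held], F[held]
            dev = -2.0 * np.sum(gh * np.log(fh) + (2.0 - gh) * np.log1p(-fh))
            errors[L].append(dev / held.sum())
    mean_err = {L: float(np.mean(v)) for L, v in errors.items()}
    return min(sorted(L_values), key=lambda L: mean_err[L])


def assign_clusters(q: AncestryMatrix | np.ndarray, k: int,
                    seed: int | None = None, n_init: int = 10) -> AncestryMatrix:
    """K-means on ancestry proportions with canonical 1..k labels.

    Labels are renumbered by descending cluster size (ties by centroid
    lexicographic order) so runs are comparable without label alignment.
    """
    anc = q if isinstance(q, AncestryMatrix) else AncestryMatrix(np.asarray(q))
    n = anc.q.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError("k cannot exceed the number of individuals")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(anc.q)
    sizes = np.bincount(raw, minlength=k)
    if (sizes == 0).any():
        warnings.warn("k-means produced an empty cluster; input may be degenerate")
    order = sorted(range(k),
                   key=lambda c: (-sizes[c], tuple(km.cluster_centers_[c])))
    relabel = {old: new + 1 for new, old in enumerate(order)}
    labels = np.array([relabel[c] for c in raw], dtype=int)
    return AncestryMatrix(anc.q, cluster=labels, sample_ids=anc.sample_ids)
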