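"""Strand-specific signature extraction.

192-element strand-specific signatures are extracted from count catalogs by
non-negative matrix factorization (multiplicative updates, Frobenius loss)
with multinomial bootstrap resampling.  The factorization rank K is chosen
by jointly minimizing the normalized reconstruction error and maximizing
the bootstrap stability (average silhouette width of the clustered,
pooled per-resample signatures), requiring stability >= 0.8.  Extracted
signatures can be clustered together with a 96-element reference catalog
(cosine distance, complete linkage) and each cluster condensed into a
96-element *directional signature* carrying a leading/lagging flag per
mutation type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import nnls
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator
from sklearn.metrics import silhouette_score

from .exposures import DirectionalSignature
from .mutation_types import N_TYPES_96, N_TYPES_192

_EPS = 1e-12


@dataclass
class ModelSelection:
    """Error/stability summary for one factorization rank."""

    K: int
    error: float
    stability: float
    objective: float = float("nan")
    meets_stability: bool = True


@dataclass
class SignatureCluster:
    """One cluster of pooled strand-specific and reference signatures."""

    cluster_id: int
    strand_members: dict[str, np.ndarray] = field(default_factory=dict)  # name -> 192
    reference_members: dict[str, np.ndarray] = field(default_factory=dict)  # name -> 96
    representative_name: str = ""
    representative: np.ndarray | None = None  # 96 weights
    provenance: str = "novel"


def _frobenius(V, W, H) -> float:
    return float(np.linalg.norm(V - W @ H))


def multiplicative_nmf(
    V: np.ndarray,
    K: int,
    rng: np.random.Generator,
    max_iter: int = 10_000,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Rank-K NMF of V (features x samples) by multiplicative updates.

    Minimizes the Frobenius reconstruction error, which is checked to be
    non-increasing over iterations; stops at relative improvement < tol.
    """
    m, n = V.shape
    scale = np.sqrt(V.mean() / K) if V.mean() > 0 else 1.0
    W = rng.uniform(0.1, 1.0, size=(m, K)) * scale
    H = rng.uniform(0.1, 1.0, size=(K, n)) * scale
    err = _frobenius(V, W, H)
    for _ in range(max_iter):
        H *= (W.T @ V) / (W.T @ W @ H + _EPS)
        W *= (V @ H.T) / (W @ (H @ H.T) + _EPS)
        new_err = _frobenius(V, W, H)
        if new_err > err * (1 + 1e-8) + 1e-12:
            raise AssertionError(
                f"multiplicative update increased the Frobenius error "
                f"({err:.6g} -> {new_err:.6g})"
            )
        if err - new_err < tol * max(err, 1.0):
            err = new_err
            break
        err = new_err
    return W, H, err


def _best_of_restarts(V, K, rng, n_restarts, max_iter, tol):
    best = None
    for _ in range(n_restarts):
        W, H, err = multiplicative_nmf(V, K, rng, max_iter=max_iter, tol=tol)
        if best is None or err < best[2]:
            best = (W, H, err)
    return best


def _bootstrap_counts(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Multinomial bootstrap of each sample's (row's) counts."""
    out = np.zeros_like(X, dtype=float)
    for i in range(X.shape[0]):
        total = int(round(X[i].sum()))
        if total == 0:
            continue
        p = X[i] / X[i].sum()
        out[i] = rng.multinomial(total, p)
    return out


def _cluster_pool(pool: np.ndarray, K: int) -> np.ndarray:
    """Partition pooled signatures (rows) into K clusters, cosine/complete."""
    if K == 1:
        return np.ones(pool.shape[0], dtype=int)
    d = pdist(pool, metric="cosine")
    Z = linkage(d, method="complete")
    return fcluster(Z, t=K, criterion="maxclust")


def nmf_extract(
    catalog,
    K: int,
    n_resamples: int = 100,
    seed: int | None = None,
    n_restarts: int = 10,
    max_iter: int = 10_000,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, ModelSelection]:
    """Extract K strand-specific signatures with bootstrap stability.

    ``catalog`` is samples x 192 counts.  Per resample, each sample's counts
    are multinomially bootstrapped and factorized (best of ``n_restarts``
    multiplicative-update runs).  All per-resample signatures are pooled and
    partitioned into K clusters (cosine distance); stability is the mean
    silhouette width of that partition and the error the mean Frobenius
    reconstruction error.  Returns (signatures 192 x K, exposures n x K,
    ModelSelection) with signatures column-normalized to sum 1 and exposures
    refit by NNLS against the representatives.
    """
    X = catalog.to_numpy(float) if isinstance(catalog, pd.DataFrame) else np.asarray(catalog, float)
    if X.ndim != 2 or X.shape[1] != N_TYPES_192:
        raise ValueError("catalog must be samples x 192")
    nz = (X.sum(axis=1) > 0).sum()
    if K > nz:
        raise ValueError(f"K={K} exceeds the {nz} samples with nonzero totals")
    rng = np.random.default_rng(seed)
    pool = []
    errors = []
    for _ in range(n_resamples):
        Xb = _bootstrap_counts(X, rng)
        W, H, err = _best_of_restarts(Xb.T, K, rng, n_restarts, max_iter, tol)
        norms = W.sum(axis=0)
        norms[norms == 0] = 1.0
        pool.append((W / norms).T)  # K x 192, L1-normalized signatures
        errors.append(err)
    pool = np.vstack(pool)
    labels = _cluster_pool(pool, K)
    if K == 1 or len(set(labels)) < 2:
        stability = 1.0
    else:
        stability = float(silhouette_score(pool, labels, metric="cosine"))
    reps = np.zeros((N_TYPES_192, K))
    for j, lab in enumerate(sorted(set(labels))):
        centroid = pool[labels == lab].mean(axis=0)
        reps[:, j] = centroid / centroid.sum()
    # deterministic column order: lexicographic by weights
    order = sorted(range(reps.shape[1]), key=lambda j: tuple(-reps[:, j]))
    reps = reps[:, order]
    exposures = refit_exposures(X, reps)
    return reps, exposures, ModelSelection(K, float(np.mean(errors)), stability)


def refit_exposures(X: np.ndarray, signatures: np.ndarray) -> np.ndarray:
    """Per-sample NNLS exposures against fixed signatures (192 x K)."""
    n = X.shape[0]
    E = np.zeros((n, signatures.shape[1]))
    for i in range(n):
        E[i], _ = nnls(signatures, X[i])
    return E


def select_K(
    catalog,
    K_range=range(2, 8),
    stability_min: float = 0.8,
    seed: int | None = None,
    **nmf_kwargs,
) -> tuple[ModelSelection, dict[int, tuple[np.ndarray, np.ndarray, ModelSelection]]]:
    """Choose the signature count minimizing error/max(error) + (1 - stability).

    Only ranks with stability >= ``stability_min`` qualify; ties break to
    the smaller K.  If no rank qualifies the maximum-stability rank is
    returned with ``meets_stability=False``.
    """
    ks = list(K_range)
    if not ks:
        raise ValueError("K_range must be non-empty")
    results = {}
    for k in ks:
        results[k] = nmf_extract(catalog, k, seed=seed, **nmf_kwargs)
    max_err = max(ms.error for _, _, ms in results.values()) or 1.0
    for _, _, ms in results.values():
        ms.objective = ms.error / max_err + (1.0 - ms.stability)
        ms.meets_stability = ms.stability >= stability_min
    eligible = [ms for _, _, ms in results.values() if ms.meets_stability]
    if eligible:
        best = min(eligible, key=lambda ms: (ms.objective, ms.K))
    else:
        best = max((ms for _, _, ms in results.values()),
                   key=lambda ms: (ms.stability, -ms.K))
        warnings.warn(
            f"no K reached stability {stability_min}; returning K={best.K} "
            f"(stability {best.stability:.3f})"
        )
    return best, results


def filter_low_exposure(
    signatures: np.ndarray,
    exposures: np.ndarray,
    threshold: float = 0.2,
    catalog: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Drop signatures present only at very low exposures.

    A signature is removed when the 95th percentile of its per-sample
    exposures, divided by the mean total exposure per sample, is strictly
    below ``threshold``.  When the catalog is given, exposures are refit on
    the retained set.  Returns (signatures, exposures, kept_mask).
    """
    mean_total = exposures.sum(axis=1).mean()
    if mean_total == 0:
        raise ValueError("all exposures are zero")
    ratio = np.percentile(exposures, 95, axis=0) / mean_total
    kept = ratio >= threshold
    if not kept.any():
        raise ValueError("low-exposure filter removed every signature")
    sigs = signatures[:, kept]
    expo = refit_exposures(np.asarray(catalog, float), sigs) if catalog is not None \
        else exposures[:, kept]
    return sigs, expo, kept


def cluster_with_reference(
    strand_signatures: pd.DataFrame,
    reference_96: pd.DataFrame | None = None,
    n_clusters: int = 27,
    overrides: dict[str, int] | None = None,
) -> list[SignatureCluster]:
    """Cluster strand-specific signatures with a 96-element reference set.

    ``strand_signatures``: 192 x M frame (columns = signature names),
    already renormalized to genome trinucleotide scale so they are
    comparable with genome-based reference signatures.  Reference
    signatures are embedded with equal values in the leading and lagging
    halves, the pooled set is clustered (cosine, complete linkage) and the
    tree cut at ``n_clusters``.  A cluster containing reference members is
    represented by the (alphabetically first) reference signature in its
    original 96-element form; clusters of only novel signatures by the mean
    of their members' leading/lagging averages.  ``overrides`` maps member
    names to cluster ids, applied after the cut.
    """
    names = list(strand_signatures.columns)
    mat = strand_signatures.to_numpy(float).T  # M x 192
    ref_names: list[str] = []
    if reference_96 is not None:
        ref_names = list(reference_96.columns)
        ref = reference_96.to_numpy(float)
        ref = ref / ref.sum(axis=0, keepdims=True)
        embedded = np.vstack([np.hstack([ref.T / 2.0, ref.T / 2.0])])
        pool = np.vstack([mat, embedded])
    else:
        pool = mat
    all_names = names + ref_names
    if n_clusters > pool.shape[0]:
        raise ValueError("n_clusters exceeds the pooled signature count")
    labels = _cluster_pool(pool, n_clusters)
    if overrides:
        for nm, cid in overrides.items():
            labels[all_names.index(nm)] = cid
    clusters: list[SignatureCluster] = []
    for cid in sorted(set(labels)):
        members = np.where(labels == cid)[0]
        c = SignatureCluster(cluster_id=int(cid))
        for i in members:
            if i < len(names):
                c.strand_members[names[i]] = mat[i]
            else:
                rn = ref_names[i - len(names)]
                c.reference_members[rn] = reference_96[rn].to_numpy(float)
        if c.reference_members:
            rep_name = sorted(c.reference_members)[0]
            rep = c.reference_members[rep_name]
            c.provenance = f"reference:{rep_name}"
        elif c.strand_members:
            rep = np.mean(
                [(v[:N_TYPES_96] + v[N_TYPES_96:]) / 2.0 for v in c.strand_members.values()],
                axis=0,
            )
            rep_name = "novel_" + "+".join(sorted(c.strand_members))
            c.provenance = "novel"
        else:  # unreachable
            continue
        c.representative = rep / rep.sum() if rep.sum() > 0 else rep
        c.representative_name = rep_name
        clusters.append(c)
    return clusters


def annotate_direction(
    cluster: SignatureCluster,
    min_mass_frac: float = 0.005,
) -> DirectionalSignature:
    """Condense a cluster into a directional signature.

    Per mutation type, leading vs lagging weight is summed across the
    cluster's strand-specific members and the larger side wins.  Types with
    small evidence mass (< ``min_mass_frac`` of the total) or an exact tie
    fall back to the predominant direction among the clear types of the
    same substitution group (then to the overall majority).  A cluster with
    only reference members gets all-leading flags and a ``no-evidence``
    provenance marker.
    """
    rep = cluster.representative
    if rep is None:
        raise ValueError("cluster has no representative")
    if not cluster.strand_members:
        return DirectionalSignature(
            cluster.representative_name, rep, np.ones(N_TYPES_96, dtype=bool),
            provenance=cluster.provenance + "|no-evidence",
        )
    lead = np.zeros(N_TYPES_96)
    lag = np.zeros(N_TYPES_96)
    for v in cluster.strand_members.values():
        lead += v[:N_TYPES_96]
        lag += v[N_TYPES_96:]
    mass = lead + lag
    total = mass.sum()
    clear = (mass >= min_mass_frac * total) & (lead != lag)
    flags = lead > lag
    # group fallback for unclear types
    for g in range(6):
        sl = slice(g * 16, (g + 1) * 16)
        unclear = ~clear[sl]
        if not unclear.any():
            continue
        gl = lead[sl][clear[sl]].sum()
        gg = lag[sl][clear[sl]].sum()
        if gl == gg == 0:  # no clear type in this group: overall majority
            gl = lead[clear].sum()
            gg = lag[clear].sum()
        flags[sl] = np.where(unclear, gl >= gg, flags[sl])
    return DirectionalSignature(
        cluster.representative_name, rep, flags, provenance=cluster.provenance
    )


class StrandSignatureNMF(BaseEstimator):
    """Sklearn-style estimator for strand-specific signature extraction.

    ``fit`` on a samples x 192 count catalog extracts signatures at
    ``n_signatures`` (or selects the rank over ``k_range`` by the
    error/stability objective), applies the low-exposure filter, and stores:

    - ``signatures_`` : 192 x K array, columns sum to 1
    - ``exposures_`` : samples x K NNLS exposures
    - ``model_selection_`` : chosen :class:`ModelSelection`
    - ``selection_path_`` : per-rank :class:`ModelSelection` list
    - ``n_signatures_`` : retained signature count
    """

    def __init__(
        self,
        n_signatures: int | None = None,
        k_range: tuple[int, int] = (2, 7),
        n_resamples: int = 100,
        n_restarts: int = 10,
        max_iter: int = 10_000,
        tol: float = 1e-9,
        stability_min: float = 0.8,
        exposure_filter: float = 0.2,
        random_state: int | None = None,
    ):
        self.n_signatures = n_signatures
        self.k_range = k_range
        self.n_resamples = n_resamples
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.stability_min = stability_min
        self.exposure_filter = exposure_filter
        self.random_state = random_state

    def fit(self, X, y=None):
        kwargs = dict(
            n_resamples=self.n_resamples, n_restarts=self.n_restarts,
            max_iter=self.max_iter, tol=self.tol,
        )
        if self.n_signatures is not None:
            sigs, expo, ms = nmf_extract(
                X, self.n_signatures, seed=self.random_state, **kwargs
            )
            self.selection_path_ = [ms]
        else:
            lo, hi = self.k_range
            ms, results = select_K(
                X, range(lo, hi + 1), stability_min=self.stability_min,
                seed=self.random_state, **kwargs,
            )
            sigs, expo, _ = results[ms.K]
            self.selection_path_ = [r[2] for r in results.values()]
        self.model_selection_ = ms
        if self.exposure_filter > 0 and sigs.shape[1] > 1:
            Xv = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
            sigs, expo, kept = filter_low_exposure(
                sigs, expo, self.exposure_filter, catalog=Xv
            )
        self.signatures_ = sigs
        self.exposures_ = expo
        self.n_signatures_ = sigs.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        """NNLS exposures of new samples against the fitted signatures."""
        Xv = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        return refit_exposures(Xv, self.signatures_)
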