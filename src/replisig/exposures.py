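"""Matching/inverse exposure decomposition by block non-negative least squares.

A *directional signature* is a 96-element signature in which every mutation
type carries a leading/lagging template flag.  Splitting each signature s
into its leading part ``s_LD`` (zeros at lagging-flagged types) and lagging
part ``s_LG`` builds the block design matrix

    S = [[S_LD, S_LG],
         [S_LG, S_LD]]

against the stacked strand spectrum m = [m_LD; m_LG].  Solving
``min_{e>=0} ||m - S e||_2`` splits each signature's exposure into a
*matching* component (leading part explaining leading-strand mutations,
lagging part explaining lagging-strand mutations) and an *inverse*
component (the two crossed options).  The per-sample asymmetry statistic is
the difference (or log2 fold change) of the two.

Spurious exposures are suppressed two ways: greedy pruning of the least
exposed signature while the residual stays within a relative tolerance of
the full-model residual, and a perturbation-based stability filter that
drops signatures whose exposure quartiles move by >=30% under small input
noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, TransformerMixin

from .mutation_types import N_TYPES_96, N_TYPES_192, TYPE96_LABELS


@dataclass
class DirectionalSignature:
    """96 non-negative weights with a leading/lagging flag per type.

    ``leading_mask[t]`` is True where type ``t``'s dominant template is the
    leading strand.  Weights are normalized so their absolute values sum
    to 1.
    """

    name: str
    weights: np.ndarray
    leading_mask: np.ndarray
    provenance: str = "novel"

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.leading_mask = np.asarray(self.leading_mask, dtype=bool)
        if self.weights.shape != (N_TYPES_96,) or self.leading_mask.shape != (N_TYPES_96,):
            raise ValueError("weights and leading_mask must have length 96")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        total = self.weights.sum()
        if total > 0:
            self.weights = self.weights / total

    def to_series(self) -> pd.Series:
        return pd.Series(self.weights, index=list(TYPE96_LABELS), name=self.name)


@dataclass
class BlockSignatureMatrix:
    """Assembled 192 x 2N design matrix with stable column order.

    Columns 0..N-1 are the matching orientations of the N signatures,
    columns N..2N-1 the inverse orientations.
    """

    S: np.ndarray
    names: list[str]

    @property
    def n_signatures(self) -> int:
        return len(self.names)

    def restrict(self, keep: np.ndarray) -> "BlockSignatureMatrix":
        keep = np.asarray(keep)
        idx = np.concatenate([np.where(keep)[0], self.n_signatures + np.where(keep)[0]])
        return BlockSignatureMatrix(self.S[:, idx], [n for n, k in zip(self.names, keep) if k])


@dataclass
class ExposurePair:
    """Per-signature matching and inverse exposures for one spectrum."""

    names: list[str]
    e_matching: np.ndarray
    e_inverse: np.ndarray
    residual: float
    pruned: list[str] = field(default_factory=list)
    unstable: list[str] = field(default_factory=list)

    def difference(self) -> np.ndarray:
        return self.e_matching - self.e_inverse

    def fold_change(self, epsilon: float = 1.0) -> np.ndarray:
        return np.log2((self.e_matching + epsilon) / (self.e_inverse + epsilon))

    def total(self) -> np.ndarray:
        return self.e_matching + self.e_inverse


def build_block_matrix(signatures: list[DirectionalSignature]) -> BlockSignatureMatrix:
    """Assemble the block design matrix from directional signatures."""
    if not signatures:
        raise ValueError("need at least one signature")
    n = len(signatures)
    s_ld = np.zeros((N_TYPES_96, n))
    s_lg = np.zeros((N_TYPES_96, n))
    for j, sig in enumerate(signatures):
        s_ld[:, j] = np.where(sig.leading_mask, sig.weights, 0.0)
        s_lg[:, j] = np.where(sig.leading_mask, 0.0, sig.weights)
    S = np.block([[s_ld, s_lg], [s_lg, s_ld]])
    return BlockSignatureMatrix(S, [s.name for s in signatures])


def _stack(m_ld: np.ndarray, m_lg: np.ndarray) -> np.ndarray:
    m_ld = np.asarray(m_ld, dtype=float)
    m_lg = np.asarray(m_lg, dtype=float)
    if m_ld.shape != (N_TYPES_96,) or m_lg.shape != (N_TYPES_96,):
        raise ValueError("strand spectra must each have length 96")
    return np.concatenate([m_ld, m_lg])


def decompose(
    m_ld: np.ndarray, m_lg: np.ndarray, block: BlockSignatureMatrix
) -> ExposurePair:
    """Non-negative least squares fit of the stacked strand spectrum."""
    m = _stack(m_ld, m_lg)
    n = block.n_signatures
    if not np.any(m):
        return ExposurePair(list(block.names), np.zeros(n), np.zeros(n), 0.0)
    e, res = nnls(block.S, m)
    return ExposurePair(list(block.names), e[:n].copy(), e[n:].copy(), float(res))


def prune_signatures(
    m_ld: np.ndarray,
    m_lg: np.ndarray,
    block: BlockSignatureMatrix,
    tolerance: float = 0.005,
) -> ExposurePair:
    """Greedily drop the least exposed signature while the fit stays good.

    Starting from the full fit, the signature with the smallest total
    (matching + inverse) exposure is removed — in both orientations — and
    the model refitted; the removal stands while the new residual does not
    exceed the *original* full-model residual by more than ``tolerance``
    (relative).  One signature is removed per iteration, no backtracking.
    """
    full = decompose(m_ld, m_lg, block)
    limit = full.residual * (1.0 + tolerance)
    keep = np.ones(block.n_signatures, dtype=bool)
    current = full
    while keep.sum() > 0:
        active = np.where(keep)[0]
        totals = current.total()
        victim = active[int(np.argmin(totals))]
        trial_keep = keep.copy()
        trial_keep[victim] = False
        if trial_keep.sum() == 0:
            if np.any(_stack(m_ld, m_lg)):
                break
            keep = trial_keep
            current = ExposurePair([], np.zeros(0), np.zeros(0), 0.0)
            break
        trial = decompose(m_ld, m_lg, block.restrict(trial_keep))
        if trial.residual <= limit:
            keep = trial_keep
            current = trial
        else:
            break
    pruned = [n for n, k in zip(block.names, keep) if not k]
    e_m = np.zeros(block.n_signatures)
    e_i = np.zeros(block.n_signatures)
    if keep.any():
        e_m[keep] = current.e_matching
        e_i[keep] = current.e_inverse
    return ExposurePair(list(block.names), e_m, e_i,
                        current.residual if keep.any() else full.residual,
                        pruned=pruned)


def robustness_filter(
    m_ld: np.ndarray,
    m_lg: np.ndarray,
    block: BlockSignatureMatrix,
    n_perturb: int = 1000,
    noise_frac: float = 0.05,
    seed: int | None = None,
    instability: float = 0.3,
    zero_floor: float = 10.0,
) -> ExposurePair:
    """Drop signatures whose exposures are not robust to input noise.

    Each of ``n_perturb`` perturbations adds independent Gaussian noise with
    sd = ``noise_frac`` x the entry value to every element of the stacked
    spectrum (negatives clamped to 0) and refits the exposures.  With x the
    unperturbed total exposure of a signature and qtl25/qtl75 the quartiles
    over perturbations, the signature is unstable for this sample when
    (qtl75 - x)/x >= ``instability`` or (x - qtl25)/x >= ``instability``.
    A signature with x = 0 is unstable only when some perturbed exposure
    exceeds ``zero_floor``.  Exposures are then recomputed using only the
    stable signatures.
    """
    rng = np.random.default_rng(seed)
    base = decompose(m_ld, m_lg, block)
    x = base.total()
    m = _stack(m_ld, m_lg)
    n = block.n_signatures
    perturbed = np.empty((n_perturb, n))
    for p in range(n_perturb):
        noisy = m + rng.normal(0.0, noise_frac * np.abs(m))
        np.clip(noisy, 0.0, None, out=noisy)
        e, _ = nnls(block.S, noisy)
        perturbed[p] = e[:n] + e[n:]
    q25 = np.quantile(perturbed, 0.25, axis=0)
    q75 = np.quantile(perturbed, 0.75, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        unstable = np.where(
            x > 0,
            ((q75 - x) / x >= instability) | ((x - q25) / x >= instability),
            perturbed.max(axis=0) > zero_floor,
        )
    stable = ~unstable
    if not stable.any():
        result = ExposurePair(list(block.names), np.zeros(n), np.zeros(n), base.residual)
    else:
        refit = decompose(m_ld, m_lg, block.restrict(stable))
        e_m = np.zeros(n)
        e_i = np.zeros(n)
        e_m[stable] = refit.e_matching
        e_i[stable] = refit.e_inverse
        result = ExposurePair(list(block.names), e_m, e_i, refit.residual)
    result.unstable = [nm for nm, u in zip(block.names, unstable) if u]
    return result


class ExposureDecomposer(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer from strand spectra to exposure tables.

    Parameters
    ----------
    signatures : list of DirectionalSignature
        The signature library to decompose against.
    prune : bool, default True
        Apply greedy low-exposure pruning at ``prune_tol`` relative
        tolerance on the residual.
    robustness : bool, default False
        Apply the perturbation stability filter after pruning.
    epsilon : float, default 1.0
        Pseudo-exposure for the log2 fold-change statistic (exposures are
        in mutation-count-like units).
    """

    def __init__(
        self,
        signatures=None,
        prune: bool = True,
        prune_tol: float = 0.005,
        robustness: bool = False,
        n_perturb: int = 1000,
        noise_frac: float = 0.05,
        instability: float = 0.3,
        zero_floor: float = 10.0,
        epsilon: float = 1.0,
        random_state: int | None = None,
    ):
        self.signatures = signatures
        self.prune = prune
        self.prune_tol = prune_tol
        self.robustness = robustness
        self.n_perturb = n_perturb
        self.noise_frac = noise_frac
        self.instability = instability
        self.zero_floor = zero_floor
        self.epsilon = epsilon
        self.random_state = random_state

    def fit(self, X=None, y=None):
        if not self.signatures:
            raise ValueError("signatures must be provided")
        self.block_ = build_block_matrix(list(self.signatures))
        self.signature_names_ = list(self.block_.names)
        return self

    def decompose_one(self, m_ld, m_lg, seed: int | None = None) -> ExposurePair:
        if self.prune:
            pair = prune_signatures(m_ld, m_lg, self.block_, tolerance=self.prune_tol)
        else:
            pair = decompose(m_ld, m_lg, self.block_)
        if self.robustness:
            keep = ~np.isin(self.block_.names, pair.pruned)
            sub = self.block_.restrict(keep) if pair.pruned else self.block_
            filt = robustness_filter(
                m_ld, m_lg, sub,
                n_perturb=self.n_perturb, noise_frac=self.noise_frac,
                seed=self.random_state if seed is None else seed,
                instability=self.instability, zero_floor=self.zero_floor,
            )
            e_m = np.zeros(self.block_.n_signatures)
            e_i = np.zeros(self.block_.n_signatures)
            pos = {n: i for i, n in enumerate(self.block_.names)}
            for nm, em, ei in zip(filt.names, filt.e_matching, filt.e_inverse):
                e_m[pos[nm]] = em
                e_i[pos[nm]] = ei
            pair = ExposurePair(list(self.block_.names), e_m, e_i, filt.residual,
                                pruned=pair.pruned, unstable=filt.unstable)
        return pair

    def transform(self, X) -> pd.DataFrame:
        """Decompose each row of a samples x 192 matrix.

        Returns a long DataFrame with one row per (sample, signature):
        e_matching, e_inverse, difference, fold_change, residual, and
        pruned/unstable flags.
        """
        if isinstance(X, pd.DataFrame):
            index = list(X.index)
            values = X.to_numpy(float)
        else:
            values = np.asarray(X, dtype=float)
            index = list(range(values.shape[0]))
        if values.ndim != 2 or values.shape[1] != N_TYPES_192:
            raise ValueError("X must be samples x 192")
        rows = []
        base_seed = self.random_state
        for i, sample in enumerate(index):
            seed = None if base_seed is None else int(base_seed) + i
            pair = self.decompose_one(values[i, :96], values[i, 96:], seed=seed)
            fc = pair.fold_change(self.epsilon)
            for j, name in enumerate(pair.names):
                rows.append(
                    {
                        "sample": sample,
                        "signature": name,
                        "e_matching": pair.e_matching[j],
                        "e_inverse": pair.e_inverse[j],
                        "difference": pair.e_matching[j] - pair.e_inverse[j],
                        "fold_change": fc[j],
                        "residual": pair.residual,
                        "pruned": name in pair.pruned,
                        "unstable": name in pair.unstable,
                    }
                )
        return pd.DataFrame(rows)
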