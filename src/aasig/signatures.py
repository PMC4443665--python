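"""Opportunity-weighted Poisson factorization of mutation spectra.

De novo signature extraction models the 96 × G count matrix V as

    V_cg ~ Poisson( o_c · Σ_k S_ck E_kg )

where o_c is the trinucleotide opportunity of channel c, the columns of S
are signatures (per-opportunity mutation-type profiles, column sums 1) and
E_kg is the expected number of sample g's mutations attributed to
signature k. This is the model family shared by EMu-style inference and
KL-divergence NMF; it is fitted here by multiplicative updates that
monotonically non-decrease the Poisson log-likelihood, with multi-restart
initialization and BIC model selection over the number of signatures.

Identifiability caveats are the usual NMF ones: columns are recovered up
to permutation (resolved by sorting on total attributed mutations,
descending) and the S/E scale split is fixed by the column-stochastic
constraint on S.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .channels import CHANNEL_LABELS, N_CHANNELS, TA_SLICE
from .exposure import cosine_similarity
from .opportunity import expand_to_96

__all__ = [
    "FitResult",
    "fit_poisson_factorization",
    "select_k",
    "attribute_exposures",
    "compare_signatures",
]

_EPS = 1e-12


@dataclass
class FitResult:
    """Outcome of one factorization fit."""

    S: pd.DataFrame  # 96 x K, column-stochastic
    E: pd.DataFrame  # K x G, expected mutation counts
    log_likelihood: float
    bic: float
    K: int
    seed: int
    iterations: int
    converged: bool
    ll_trace: np.ndarray = field(repr=False, default=None)
    k_scores: dict | None = None  # per-K BIC when produced by select_k


def _as_matrix(V) -> tuple[np.ndarray, list[str]]:
    if isinstance(V, pd.DataFrame):
        return V.to_numpy(dtype=float), [str(c) for c in V.columns]
    V = np.asarray(V, dtype=float)
    return V, [f"s{j}" for j in range(V.shape[1])]


def _opp96(opportunities) -> np.ndarray:
    o = np.asarray(opportunities, dtype=float)
    if o.shape != (N_CHANNELS,):
        o = expand_to_96(opportunities)
    if (o < 0).any():
        raise ValueError("opportunities must be nonnegative")
    # scale to mean 1: pure reparametrization of E, better conditioned
    return o / o.mean()


def _poisson_ll(V: np.ndarray, M: np.ndarray, lgV: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(V > 0, V * np.log(np.maximum(M, _EPS)), 0.0)
    return float((t - M - lgV).sum())


def _run_updates(
    V: np.ndarray,
    o: np.ndarray,
    S: np.ndarray,
    E: np.ndarray,
    tol: float,
    max_iter: int,
    update_S: bool = True,
    trace_every: int = 1,
):
    """Multiplicative updates for V ~ Poisson(diag(o) S E); returns trace."""
    lgV = gammaln(V + 1.0)
    oc = o[:, None]
    trace = []
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        M = oc * (S @ E)
        R = V / np.maximum(M, _EPS)  # V_cg / M_cg
        if update_S:
            # the o_c factor cancels between numerator and denominator here
            S *= (R @ E.T) / np.maximum(E.sum(axis=1)[None, :], _EPS)
            # renormalize columns, compensate in E (scale invariance)
            col = S.sum(axis=0)
            col = np.maximum(col, _EPS)
            S /= col[None, :]
            E *= col[:, None]
            M = oc * (S @ E)
            R = V / np.maximum(M, _EPS)
        E *= (S.T @ (R * oc)) / np.maximum((S * oc).sum(axis=0)[:, None], _EPS)
        if it % trace_every == 0 or it == max_iter:
            M = oc * (S @ E)
            ll = _poisson_ll(V, M, lgV)
            trace.append(ll)
            if ll_prev > -np.inf and abs(ll - ll_prev) <= tol * max(abs(ll_prev), 1.0):
                converged = True
                break
            ll_prev = ll
    return S, E, np.array(trace), it, converged


def fit_poisson_factorization(
    V,
    opportunities,
    K: int,
    restarts: int = 10,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 5000,
) -> FitResult:
    """Fit K signatures to a 96 × G count matrix.

    Best Poisson log-likelihood over ``restarts`` seeded random
    initializations (entries uniform on (0.1, 1)); deterministic for a
    given seed. Columns of the returned S sum to 1 and are ordered by
    total attributed mutations, descending.

    Raises
    ------
    ValueError
        On an all-zero V, K < 1, or a channel with observed mutations but
        zero opportunity.
    """
    Vm, samples = _as_matrix(V)
    if Vm.ndim != 2 or Vm.shape[0] != N_CHANNELS:
        raise ValueError("V must be 96 x G")
    if (Vm < 0).any():
        raise ValueError("V must be nonnegative")
    if Vm.sum() == 0:
        raise ValueError("V is all zero")
    if K < 1:
        raise ValueError("K must be >= 1")
    o = _opp96(opportunities)
    if ((o <= 0) & (Vm.sum(axis=1) > 0)).any():
        raise ValueError("zero opportunity on a channel with observed mutations")
    G = Vm.shape[1]
    ss = np.random.SeedSequence(seed)
    best = None
    for child in ss.spawn(max(restarts, 1)):
        rng = np.random.default_rng(child)
        S0 = rng.uniform(0.1, 1.0, size=(N_CHANNELS, K))
        S0 /= S0.sum(axis=0)[None, :]
        E0 = rng.uniform(0.1, 1.0, size=(K, G)) * (Vm.sum() / (K * G))
        S, E, trace, iters, conv = _run_updates(Vm, o, S0, E0, tol, max_iter)
        if best is None or trace[-1] > best[2][-1]:
            best = (S, E, trace, iters, conv)
    S, E, trace, iters, conv = best
    # zero out numerically-floored entries, re-normalize
    S[S < 1e-10] = 0.0
    col = np.maximum(S.sum(axis=0), _EPS)
    S /= col[None, :]
    E *= col[:, None]
    order = np.argsort(-E.sum(axis=1), kind="stable")
    S, E = S[:, order], E[order, :]
    ll = float(trace[-1])
    n_params = N_CHANNELS * K + K * G - K  # column-stochastic S loses K dof
    bic = -2.0 * ll + n_params * np.log(Vm.sum())
    names = [f"sig{j + 1}" for j in range(K)]
    return FitResult(
        S=pd.DataFrame(S, index=pd.Index(CHANNEL_LABELS, name="channel"), columns=names),
        E=pd.DataFrame(E, index=names, columns=samples),
        log_likelihood=ll,
        bic=bic,
        K=K,
        seed=seed,
        iterations=iters,
        converged=conv,
        ll_trace=trace,
    )


def select_k(
    V,
    opportunities,
    k_min: int = 2,
    k_max: int = 8,
    restarts: int = 10,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 5000,
) -> FitResult:
    """Fit every K in [k_min, k_max] and return the BIC-minimizing fit.

    The per-K scores are attached as ``k_scores`` on the returned result.
    """
    if k_min > k_max or k_min < 1:
        raise ValueError(f"invalid K range [{k_min}, {k_max}]")
    fits = {}
    for K in range(k_min, k_max + 1):
        fits[K] = fit_poisson_factorization(
            V, opportunities, K, restarts=restarts, seed=seed + K, tol=tol, max_iter=max_iter
        )
    best = min(fits.values(), key=lambda f: f.bic)
    best.k_scores = {K: {"bic": f.bic, "log_likelihood": f.log_likelihood} for K, f in fits.items()}
    return best


def attribute_exposures(S: pd.DataFrame, spectrum, opportunities) -> pd.Series:
    """Per-signature mutation proportions for one sample, S held fixed.

    Fits the sample's exposure column by the same multiplicative updates
    with the signature matrix frozen; returns proportions summing to 1.
    """
    Sm = S.to_numpy(dtype=float) if isinstance(S, pd.DataFrame) else np.asarray(S, float)
    v = np.asarray(spectrum, dtype=float).reshape(-1, 1)
    if v.sum() == 0:
        raise ValueError("zero spectrum: exposures undefined")
    o = _opp96(opportunities)
    K = Sm.shape[1]
    E0 = np.full((K, 1), v.sum() / K)
    _, E, trace, _, _ = _run_updates(
        v, o, Sm.copy(), E0, tol=1e-10, max_iter=10000, update_S=False
    )
    props = E[:, 0] / E[:, 0].sum()
    names = list(S.columns) if isinstance(S, pd.DataFrame) else [f"sig{j+1}" for j in range(K)]
    return pd.Series(props, index=names, name="proportion")


def compare_signatures(A: pd.DataFrame, B: pd.DataFrame) -> pd.DataFrame:
    """Greedy best-match pairing of two signature sets by 96-channel cosine.

    Each pair is also scored on the A:T>T:A 16-channel subvector, the
    region that discriminates adenine-adduct signatures.
    """
    Am, a_names = _as_matrix(A)
    Bm, b_names = _as_matrix(B)
    if Am.shape[0] != Bm.shape[0]:
        raise ValueError("signature matrices have different channel dimension")
    sim = np.zeros((Am.shape[1], Bm.shape[1]))
    for i in range(Am.shape[1]):
        for j in range(Bm.shape[1]):
            sim[i, j] = cosine_similarity(Am[:, i], Bm[:, j])
    pairs = []
    free_a = set(range(Am.shape[1]))
    free_b = set(range(Bm.shape[1]))
    while free_a and free_b:
        i, j = max(
            ((i, j) for i in free_a for j in free_b), key=lambda ij: sim[ij[0], ij[1]]
        )
        ta_a, ta_b = Am[TA_SLICE, i], Bm[TA_SLICE, j]
        ta_cos = (
            cosine_similarity(ta_a, ta_b)
            if ta_a.sum() > 0 and ta_b.sum() > 0
            else float("nan")
        )
        pairs.append((a_names[i], b_names[j], sim[i, j], ta_cos))
        free_a.remove(i)
        free_b.remove(j)
    return pd.DataFrame(pairs, columns=["a", "b", "cosine", "cosine_atta"])
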