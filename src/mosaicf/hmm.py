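"""Multi-class homozygosity-by-descent (HBD) hidden Markov model.

The genome of a diploid individual is modelled as a mosaic of segments,
each belonging to one of K HBD classes or to a non-HBD class.  Segment
lengths in class k are exponential with rate R_k per Morgan, so each
class captures autozygosity tracing back to common ancestors roughly
R_k / 2 generations ago (R = 2G when no recombination interrupts either
path to the ancestor): small rates mean long segments and recent
inbreeding.  Class rates are fixed on a doubling ladder and the
per-individual mixing proportions pi (the probability that a new segment
belongs to each class) are estimated by EM.

Emissions are genotype probabilities given the population B-allele
frequency p and a genotyping error rate e.  Inside an HBD segment both
haplotypes are copies of one ancestral allele, so a heterozygous call can
only arise through error; outside, genotypes follow Hardy-Weinberg
proportions.

Between adjacent markers separated by d Morgans the chain either stays in
its current segment, with probability exp(-R_k d), or the segment ends
and a new class is drawn from pi:

    T[k, j] = exp(-R_k d) * 1[k = j] + (1 - exp(-R_k d)) * pi_j

This "any class may follow any class" structure lets the forward,
backward and EM recursions run in O(K) per marker instead of O(K^2).

The per-marker posterior probability of being in any HBD class, averaged
over the genome, is the global inbreeding coefficient F_G; averaging one
class at a time partitions F_G by age.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .markers import MarkerMap

logger = logging.getLogger(__name__)

__all__ = [
    "HBDModelConfig", "MixingProportions", "HBDPosterior", "ClassInbreeding",
    "emission_probability", "genotype_emissions", "transition_matrix",
    "forward_backward", "fit_mixing_proportions", "global_and_class_inbreeding",
    "fit_cohort", "CohortFit",
]

DEFAULT_RATES = tuple(float(2 ** g) for g in range(1, 12))  # 2, 4, ..., 2048


@dataclass
class HBDModelConfig:
    """Model parameters.

    hbd_rates
        Strictly increasing exponential rates R_k (per Morgan) for the K
        HBD classes; default the 11-value doubling ladder 2..2048.
    nonhbd_rate
        Rate of the single non-HBD class (default 2048, tied to the
        oldest HBD class).
    error
        Genotyping error rate e (default 0.001).
    maf_min
        Markers with minor allele frequency below this floor are treated
        as uninformative (emission 1 in every state) rather than dropped,
        so genomic coordinates are preserved (default 0.01).
    cm_per_mb
        Physical-to-genetic scaling used when the map carries no genetic
        positions (default 1 cM/Mb).
    em_tol, em_max_iter
        EM stops when the log-likelihood gain drops below ``em_tol``
        (default 1e-6) or after ``em_max_iter`` iterations (default 1000).
    """

    hbd_rates: tuple = DEFAULT_RATES
    nonhbd_rate: float = 2048.0
    error: float = 0.001
    maf_min: float = 0.01
    cm_per_mb: float = 1.0
    em_tol: float = 1e-6
    em_max_iter: int = 1000

    def __post_init__(self) -> None:
        rates = np.asarray(self.hbd_rates, dtype=float)
        if rates.size < 1 or np.any(rates <= 0) or np.any(np.diff(rates) <= 0):
            raise ValueError("hbd_rates must be strictly increasing positives")
        if self.nonhbd_rate <= 0:
            raise ValueError("nonhbd_rate must be positive")
        if not 0 <= self.error < 0.5:
            raise ValueError("error must lie in [0, 0.5)")

    @property
    def n_classes(self) -> int:
        """Number of states: K HBD classes plus the non-HBD class."""
        return len(self.hbd_rates) + 1

    @property
    def rates(self) -> np.ndarray:
        """All state rates, non-HBD last."""
        return np.append(np.asarray(self.hbd_rates, float), self.nonhbd_rate)


@dataclass
class MixingProportions:
    """Per-individual mixing proportions over the K+1 classes (non-HBD last)."""

    weights: np.ndarray
    converged: bool = True
    n_iter: int = 0
    loglik_path: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-10:
            raise ValueError("mixing proportions must be a simplex vector")
        self.weights = w


@dataclass
class HBDPosterior:
    """Forward-backward output for one individual: markers x (K+1) state
    probabilities (non-HBD last) and the total log-likelihood."""

    gamma: np.ndarray
    loglik: float


@dataclass
class ClassInbreeding:
    """Realized inbreeding partitioned by HBD class for one individual."""

    f_class: np.ndarray   # length K, one entry per HBD class
    f_g: float            # total = sum of f_class

    def __post_init__(self) -> None:
        if abs(float(np.sum(self.f_class)) - self.f_g) > 1e-10:
            raise ValueError("F_G must equal the sum of per-class terms")


# ----------------------------------------------------------------------
# Emissions
# ----------------------------------------------------------------------

def emission_probability(genotype: int, p: float, e: float, hbd: bool) -> float:
    """P(observed genotype | state), genotype coded as B-allele dosage.

    HBD: the single underlying allele is B with probability p; with
    probability e the call is replaced by a Hardy-Weinberg draw.
    Missing genotypes (negative code) have probability 1 in every state.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"allele frequency {p} outside [0, 1]")
    if genotype < 0:
        return 1.0
    q = 1.0 - p
    if hbd:
        return ((1 - e) * q + e * q * q,
                e * 2 * p * q,
                (1 - e) * p + e * p * p)[genotype]
    return (q * q, 2 * p * q, p * p)[genotype]


def genotype_emissions(genotypes: np.ndarray, freqs: np.ndarray, error: float,
                       uninformative: np.ndarray | None = None):
    """Vectorized emissions for one individual.

    Returns ``(b_hbd, b_non)`` — per-marker emission probabilities shared
    by all HBD classes and for the non-HBD class.  Missing calls and
    markers flagged ``uninformative`` emit 1 in every state.
    """
    g = np.asarray(genotypes)
    p = np.asarray(freqs, dtype=float)
    q = 1.0 - p
    e = error
    bh = np.ones(g.shape, dtype=float)
    bn = np.ones(g.shape, dtype=float)
    m0, m1, m2 = g == 0, g == 1, g == 2
    bh[m0] = (1 - e) * q[m0] + e * q[m0] ** 2
    bh[m1] = e * 2 * p[m1] * q[m1]
    bh[m2] = (1 - e) * p[m2] + e * p[m2] ** 2
    bn[m0] = q[m0] ** 2
    bn[m1] = 2 * p[m1] * q[m1]
    bn[m2] = p[m2] ** 2
    if uninformative is not None:
        bh[uninformative] = 1.0
        bn[uninformative] = 1.0
    bad = np.isnan(p) & (g >= 0)
    bh[bad] = 1.0
    bn[bad] = 1.0
    return bh, bn


def transition_matrix(d_morgans: float, config: HBDModelConfig,
                      pi: np.ndarray) -> np.ndarray:
    """Dense (K+1) x (K+1) transition matrix over d Morgans."""
    if d_morgans < 0:
        raise ValueError("distance must be non-negative")
    rates = config.rates
    stay = np.exp(-rates * d_morgans)
    return np.diag(stay) + (1.0 - stay)[:, None] * np.asarray(pi, float)[None, :]


# ----------------------------------------------------------------------
# Numba kernels (O(K) per marker, exploiting the mixture transition)
# ----------------------------------------------------------------------

@njit(cache=True)
def _forward_kernel(bh, bn, a, pi, K):
    T = bh.shape[0]
    S = K + 1
    alpha = np.empty((T, S))
    c = np.empty(T)
    tot = 0.0
    for j in range(S):
        b = bh[0] if j < K else bn[0]
        alpha[0, j] = pi[j] * b
        tot += alpha[0, j]
    c[0] = tot
    if tot > 0.0:
        for j in range(S):
            alpha[0, j] /= tot
    for t in range(T - 1):
        s = 0.0
        for i in range(S):
            s += alpha[t, i] * (1.0 - a[t, i])
        tot = 0.0
        for j in range(S):
            b = bh[t + 1] if j < K else bn[t + 1]
            v = b * (alpha[t, j] * a[t, j] + s * pi[j])
            alpha[t + 1, j] = v
            tot += v
        c[t + 1] = tot
        if tot > 0.0:
            inv = 1.0 / tot
            for j in range(S):
                alpha[t + 1, j] *= inv
    return alpha, c


@njit(cache=True)
def _backward_kernel(bh, bn, a, pi, K, alpha, c):
    """Scaled backward pass; returns posteriors gamma and the expected
    number of segment-class draws nk (change events landing in each class,
    plus the initial draw) used by the EM M-step."""
    T = bh.shape[0]
    S = K + 1
    gamma = np.empty((T, S))
    nk = np.zeros(S)
    beta = np.ones(S)
    for j in range(S):
        gamma[T - 1, j] = alpha[T - 1, j]
    for t in range(T - 2, -1, -1):
        s = 0.0
        for i in range(S):
            s += alpha[t, i] * (1.0 - a[t, i])
        invc = 1.0 / c[t + 1]
        wsum = 0.0
        for j in range(S):
            b = bh[t + 1] if j < K else bn[t + 1]
            w = b * beta[j]
            nk[j] += s * pi[j] * w * invc
            wsum += pi[j] * w
        newbeta = np.empty(S)
        for i in range(S):
            b = bh[t + 1] if i < K else bn[t + 1]
            newbeta[i] = (a[t, i] * b * beta[i] + (1.0 - a[t, i]) * wsum) * invc
        for i in range(S):
            beta[i] = newbeta[i]
            gamma[t, i] = alpha[t, i] * beta[i]
    for j in range(S):
        nk[j] += gamma[0, j]
    return gamma, nk


@njit(cache=True)
def _viterbi_kernel(bh, bn, a, pi, K):
    T = bh.shape[0]
    S = K + 1
    NEG = -1e300
    logpi = np.empty(S)
    for j in range(S):
        logpi[j] = np.log(pi[j]) if pi[j] > 0.0 else NEG
    delta = np.empty(S)
    back = np.zeros((T, S), np.int64)
    for j in range(S):
        b = bh[0] if j < K else bn[0]
        delta[j] = logpi[j] + (np.log(b) if b > 0.0 else NEG)
    for t in range(T - 1):
        newdelta = np.empty(S)
        for j in range(S):
            b = bh[t + 1] if j < K else bn[t + 1]
            lb = np.log(b) if b > 0.0 else NEG
            best = -np.inf
            arg = 0
            for i in range(S):
                tij = (1.0 - a[t, i]) * pi[j]
                if i == j:
                    tij += a[t, i]
                lt = np.log(tij) if tij > 0.0 else NEG
                v = delta[i] + lt
                if v > best:
                    best = v
                    arg = i
            newdelta[j] = best + lb
            back[t + 1, j] = arg
        for j in range(S):
            delta[j] = newdelta[j]
    best = -np.inf
    arg = 0
    for j in range(S):
        if delta[j] > best:
            best = delta[j]
            arg = j
    path = np.empty(T, np.int64)
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


# ----------------------------------------------------------------------
# Chain preparation
# ----------------------------------------------------------------------

MIN_D_MORGANS = 1e-8  # floor avoiding zero-distance degeneracy


def chain_stay_probabilities(marker_map: MarkerMap, config: HBDModelConfig):
    """Per chromosome, the (T-1, K+1) matrix of stay probabilities
    exp(-R_k * d_t) between adjacent markers."""
    morg = marker_map.morgans(config.cm_per_mb)
    rates = config.rates
    out = {}
    for chrom in marker_map.chromosomes:
        sl = marker_map.chrom_slice(chrom)
        d = np.maximum(np.diff(morg[sl]), MIN_D_MORGANS)
        out[chrom] = np.exp(-np.outer(d, rates))
    return out


def _chains(genotypes, marker_map, freqs, config, stay=None,
            uninformative=None):
    """Yield (chrom, b_hbd, b_non, a) per chromosome chain."""
    if stay is None:
        stay = chain_stay_probabilities(marker_map, config)
    if uninformative is None:
        with np.errstate(invalid="ignore"):
            maf = np.minimum(freqs, 1.0 - freqs)
        uninformative = ~(maf >= config.maf_min)   # catches NaN too
    bh, bn = genotype_emissions(genotypes, freqs, config.error, uninformative)
    for chrom in marker_map.chromosomes:
        sl = marker_map.chrom_slice(chrom)
        yield chrom, bh[sl], bn[sl], stay[chrom]


# ----------------------------------------------------------------------
# Inference
# ----------------------------------------------------------------------

def forward_backward(genotypes, marker_map: MarkerMap, freqs, config:
                     HBDModelConfig, pi) -> HBDPosterior:
    """Exact posterior state probabilities for one individual.

    Chromosomes are independent chains, each starting from the mixing
    distribution ``pi``; numerical stability comes from per-marker
    scaling constants.
    """
    K = config.n_classes - 1
    pi = np.asarray(pi, dtype=float)
    gammas = []
    loglik = 0.0
    for chrom, bh, bn, a in _chains(genotypes, marker_map, freqs, config):
        alpha, c = _forward_kernel(bh, bn, a, pi, K)
        if np.any(c <= 0.0) or np.any(np.isnan(c)):
            t = int(np.flatnonzero((c <= 0) | np.isnan(c))[0])
            sl = marker_map.chrom_slice(chrom)
            raise FloatingPointError(
                "observation impossible under the model at marker "
                f"{marker_map.marker_id[sl.start + t]} ({chrom})")
        gamma, _ = _backward_kernel(bh, bn, a, pi, K, alpha, c)
        gammas.append(gamma)
        loglik += float(np.sum(np.log(c)))
    return HBDPosterior(np.concatenate(gammas, axis=0), loglik)


def fit_mixing_proportions(genotypes, marker_map: MarkerMap, freqs,
                           config: HBDModelConfig, pi0=None):
    """EM estimation of the mixing proportions with rates held fixed.

    E-step: forward-backward over each chromosome chain.  M-step: pi_k
    proportional to the expected number of segments assigned to class k
    (expected change events landing in k across all chains, plus the
    initial draw of each chain).  The log-likelihood is non-decreasing;
    iteration stops at ``em_tol`` gain or ``em_max_iter``.

    Returns ``(MixingProportions, HBDPosterior)`` evaluated at the
    returned proportions.
    """
    K = config.n_classes - 1
    S = K + 1
    pi = (np.full(S, 1.0 / S) if pi0 is None
          else np.asarray(pi0, dtype=float).copy())
    stay = chain_stay_probabilities(marker_map, config)
    with np.errstate(invalid="ignore"):
        maf = np.minimum(freqs, 1.0 - freqs)
    uninf = ~(maf >= config.maf_min)
    prepared = list(_chains(genotypes, marker_map, freqs, config,
                            stay=stay, uninformative=uninf))
    logliks = []
    converged = False
    it = 0
    gamma_out = None
    for it in range(1, config.em_max_iter + 1):
        ll = 0.0
        nk = np.zeros(S)
        gammas = []
        for chrom, bh, bn, a in prepared:
            alpha, c = _forward_kernel(bh, bn, a, pi, K)
            if np.any(c <= 0.0):
                raise FloatingPointError(
                    f"zero likelihood on {chrom} during EM")
            gamma, nkc = _backward_kernel(bh, bn, a, pi, K, alpha, c)
            nk += nkc
            gammas.append(gamma)
            ll += float(np.sum(np.log(c)))
        logliks.append(ll)
        gamma_out = gammas
        if len(logliks) > 1 and ll - logliks[-2] < config.em_tol:
            converged = True
            break
        pi = nk / nk.sum()
    if not converged:
        logger.warning("EM did not converge in %d iterations (last gain %.3g)",
                       it, (logliks[-1] - logliks[-2]) if len(logliks) > 1
                       else float("nan"))
    mix = MixingProportions(pi, converged=converged, n_iter=it,
                            loglik_path=np.asarray(logliks))
    post = HBDPosterior(np.concatenate(gamma_out, axis=0), logliks[-1])
    return mix, post


def global_and_class_inbreeding(posterior: HBDPosterior) -> ClassInbreeding:
    """Average the HBD posteriors over markers: F_k per class and their sum
    F_G.  The non-HBD class (last column) is excluded."""
    f_class = posterior.gamma[:, :-1].mean(axis=0)
    return ClassInbreeding(f_class=f_class, f_g=float(f_class.sum()))


# ----------------------------------------------------------------------
# Cohort driver
# ----------------------------------------------------------------------

@dataclass
class CohortFit:
    """Per-individual EM fits for a genotype dataset."""

    individuals: list
    config: HBDModelConfig
    mixing: list          # MixingProportions per individual
    posteriors: list      # HBDPosterior per individual (None if not stored)
    inbreeding: list      # ClassInbreeding per individual

    def f_g(self) -> np.ndarray:
        return np.array([ci.f_g for ci in self.inbreeding])

    def summary(self):
        import pandas as pd
        K = self.config.n_classes - 1
        rows = {}
        rows["individual"] = self.individuals
        rows["F_G"] = self.f_g()
        for k in range(K):
            rows[f"F_R{self.config.hbd_rates[k]:g}"] = [
                ci.f_class[k] for ci in self.inbreeding]
        return pd.DataFrame(rows)


def fit_cohort(dataset, config: HBDModelConfig | None = None,
               freqs=None, store_posteriors: bool = True) -> CohortFit:
    """Fit the model to every individual of a :class:`GenotypeDataset`.

    Allele frequencies default to the dataset's pooled B-allele
    frequencies.  Each individual gets its own mixing proportions, so
    F_G is individual-specific.
    """
    from .qc import allele_frequencies

    config = config or HBDModelConfig()
    if freqs is None:
        freqs, _ = allele_frequencies(dataset, maf_min=config.maf_min)
    mixing, posteriors, inbreeding = [], [], []
    for i in range(len(dataset.individuals)):
        mix, post = fit_mixing_proportions(dataset.calls[i], dataset.markers,
                                           freqs, config)
        mixing.append(mix)
        inbreeding.append(global_and_class_inbreeding(post))
        posteriors.append(post if store_posteriors else None)
    return CohortFit(list(dataset.individuals), config, mixing, posteriors,
                     inbreeding)
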