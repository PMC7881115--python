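"""edgeR-style differential testing for count data (ATAC regions or genes).

The two-group test is a conditional exact negative-binomial test: after
scaling counts to a common effective library size (TMM factors x library
size), per-group sums are compared conditionally on their total. Under a
common dispersion phi, the sum of n i.i.d. NB(mu, 1/phi) variables is
NB(n*mu, n/phi), and conditionally on the total the group-A sum follows a
Dirichlet-multinomial law that does not depend on mu:

    P(S_A = a | S_A + S_B = t) = C(a + r_A - 1, a) C(t - a + r_B - 1, t - a)
                                  / C(t + r_A + r_B - 1, t)

with r_g = n_g / phi. The two-sided p-value sums the probabilities of all
splits at most as likely as the observed one. At phi = 0 this reduces to an
exact binomial split test with success probability n_A / (n_A + n_B).

Common dispersion is estimated by maximizing the conditional log-likelihood
on library-size-equalized pseudo-counts; optional tagwise dispersions shrink
per-feature estimates toward the common value. Exact parity with edgeR is not
claimed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from charflow.atac_quant import CountMatrix

TAGWISE_PRIOR_WEIGHT = 10.0  # pseudo-features of weight given to the common value


@dataclass
class DifferentialResult:
    feature_id: str
    log2fc: float
    p_value: float
    q_value: float = np.nan
    mean_logcpm: float = np.nan
    all_zero: bool = False


def tmm_factors(
    matrix: CountMatrix | np.ndarray,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    library_sizes: np.ndarray | None = None,
) -> np.ndarray:
    """Trimmed-mean-of-M-values scaling factors (one per sample).

    M and A values are computed against a reference sample (the one whose
    upper-quartile CPM is closest to the mean upper quartile); features in the
    most extreme ``trim_m`` fraction of M values and ``trim_a`` fraction of A
    values are trimmed; the factor is 2^(precision-weighted mean of the
    remaining M values). Factors are rescaled so their geometric mean is 1.
    """
    if isinstance(matrix, CountMatrix):
        counts = np.asarray(matrix.counts, dtype=float)
        libs = matrix.library_sizes.astype(float)
    else:
        counts = np.asarray(matrix, dtype=float)
        libs = (
            np.asarray(library_sizes, dtype=float)
            if library_sizes is not None
            else counts.sum(axis=0)
        )
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise ValueError("TMM requires a features x samples matrix with >= 2 samples")
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("all-zero sample column")
    if (libs <= 0).any():
        raise ValueError("non-positive library size")

    p = counts / libs[None, :]
    uq = np.array([np.quantile(p[:, j][counts[:, j] > 0], 0.75) for j in range(p.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    log_factors = np.zeros(p.shape[1])
    for j in range(p.shape[1]):
        if j == ref:
            continue
        keep = (counts[:, j] > 0) & (counts[:, ref] > 0)
        if keep.sum() == 0:
            continue
        pj, pr = p[keep, j], p[keep, ref]
        m = np.log2(pj / pr)
        a = 0.5 * np.log2(pj * pr)
        # asymptotic delta-method variance of M
        w = (
            (libs[j] - counts[keep, j]) / (libs[j] * counts[keep, j])
            + (libs[ref] - counts[keep, ref]) / (libs[ref] * counts[keep, ref])
        )
        n = len(m)
        lo_m, hi_m = int(np.floor(n * trim_m)) + 1, n - int(np.floor(n * trim_m))
        lo_a, hi_a = int(np.floor(n * trim_a)) + 1, n - int(np.floor(n * trim_a))
        rank_m = stats.rankdata(m, method="ordinal")
        rank_a = stats.rankdata(a, method="ordinal")
        keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if keep2.sum() == 0 or np.isclose(np.abs(m[keep2]).max(), 0, atol=1e-10):
            log_factors[j] = 0.0
            continue
        log_factors[j] = np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])

    factors = 2.0**log_factors
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def _equalize_libraries(counts: np.ndarray, eff_libs: np.ndarray) -> np.ndarray:
    """Scale each column to the geometric-mean effective library and round.

    This is a pragmatic stand-in for edgeR's quantile adjustment; the
    conditional test below requires integer pseudo-counts.
    """
    target = np.exp(np.mean(np.log(eff_libs)))
    pseudo = counts * (target / eff_libs)[None, :]
    return np.rint(pseudo).astype(np.int64)


def _cond_loglik_common(delta: float, pseudo: np.ndarray, groups: list[np.ndarray]) -> float:
    """Conditional log-likelihood of delta = phi/(1+phi), summed over features
    and groups, on equalized pseudo-counts (equal means within a group)."""
    phi = delta / (1.0 - delta)
    r = 1.0 / phi
    total = 0.0
    for idx in groups:
        y = pseudo[:, idx]
        n = y.shape[1]
        z = y.sum(axis=1)
        total += np.sum(
            gammaln(y + r).sum(axis=1)
            + gammaln(n * r)
            - gammaln(z + n * r)
            - n * gammaln(r)
            + gammaln(z + 1)
            - gammaln(y + 1).sum(axis=1)
        )
    return total


def estimate_common_dispersion(
    pseudo: np.ndarray, groups: list[np.ndarray]
) -> float:
    """Common NB dispersion maximizing the conditional likelihood (0 allowed)."""
    res = optimize.minimize_scalar(
        lambda d: -_cond_loglik_common(d, pseudo, groups),
        bounds=(1e-6, 0.95),
        method="bounded",
        options={"xatol": 1e-6},
    )
    delta = float(res.x)
    # likelihood flat toward 0 means Poisson-like data
    if _cond_loglik_common(1e-6, pseudo, groups) >= _cond_loglik_common(delta, pseudo, groups) - 1e-9:
        return 1e-6 / (1 - 1e-6)
    return delta / (1.0 - delta)


def estimate_tagwise_dispersions(
    pseudo: np.ndarray,
    groups: list[np.ndarray],
    common: float,
    prior_weight: float = TAGWISE_PRIOR_WEIGHT,
) -> np.ndarray:
    """Per-feature dispersions shrunk toward the common value.

    Each feature's conditional likelihood is augmented with ``prior_weight``
    copies of the average per-feature likelihood at the common dispersion
    (weighted-likelihood empirical Bayes in the edgeR spirit).
    """
    n_feat = pseudo.shape[0]
    out = np.empty(n_feat)
    deltas = np.linspace(1e-6, 0.9, 60)
    # per-feature conditional log-likelihood profile on a delta grid
    prof = np.zeros((n_feat, deltas.size))
    for k, d in enumerate(deltas):
        phi = d / (1 - d)
        r = 1.0 / phi
        acc = np.zeros(n_feat)
        for idx in groups:
            y = pseudo[:, idx]
            n = y.shape[1]
            z = y.sum(axis=1)
            acc += (
                gammaln(y + r).sum(axis=1)
                + gammaln(n * r)
                - gammaln(z + n * r)
                - n * gammaln(r)
            )
        prof[:, k] = acc
    common_delta = common / (1 + common)
    k_common = int(np.argmin(np.abs(deltas - common_delta)))
    mean_prof = prof.mean(axis=0)
    weighted = prof + prior_weight * mean_prof[None, :]
    # anchor the prior at the common dispersion by recentring the mean profile
    weighted += prior_weight * (mean_prof[k_common] - mean_prof)[None, :]
    best = np.argmax(weighted, axis=1)
    out = deltas[best] / (1 - deltas[best])
    return out


def _exact_conditional_p(a_obs: int, t: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided exact p for observing group-A sum ``a_obs`` of total ``t``."""
    if t == 0:
        return 1.0
    a = np.arange(t + 1)
    if phi <= 1e-8:
        logp = stats.binom.logpmf(a, t, n_a / (n_a + n_b))
    else:
        r_a, r_b = n_a / phi, n_b / phi
        logp = (
            gammaln(a + r_a)
            - gammaln(a + 1)
            - gammaln(r_a)
            + gammaln(t - a + r_b)
            - gammaln(t - a + 1)
            - gammaln(r_b)
        )
        logp -= gammaln(t + r_a + r_b) - gammaln(t + 1) - gammaln(r_a + r_b)
    p_obs = logp[a_obs]
    mask = logp <= p_obs + 1e-10
    p = float(np.exp(logp[mask]).sum() / np.exp(logp).sum())
    return min(p, 1.0)


def nb_exact_test(
    matrix: CountMatrix,
    group_labels: list[str] | np.ndarray,
    dispersion: str | float = "common",
    norm_factors: np.ndarray | None = None,
    lfc_prior_cpm: float = 0.5,
    groups: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Two-group exact NB differential test on a count matrix.

    Parameters
    ----------
    group_labels : per-sample labels; exactly two distinct values. log2FC is
        reported for the second group over the first; pass ``groups=(A, B)``
        to fix the direction explicitly (default: labels sorted).
    dispersion : ``"common"`` (default), ``"tagwise"``, or a fixed float
        (0 gives the exact binomial split test).
    norm_factors : TMM factors; computed from the matrix when omitted.

    Returns a DataFrame with feature_id, log2FC, p, q (BH), mean logCPM and
    an all_zero flag; all-zero features get p = 1 and log2FC = 0.
    """
    labels = np.asarray(group_labels)
    uniq = list(groups) if groups is not None else sorted(set(labels.tolist()))
    if len(set(labels.tolist()) | set(uniq)) != 2:
        raise ValueError(f"exactly two groups required, got {sorted(set(labels.tolist()))}")
    idx_a = np.where(labels == uniq[0])[0]
    idx_b = np.where(labels == uniq[1])[0]
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError("each group needs >= 1 replicate")

    counts = np.asarray(matrix.counts, dtype=float)
    libs = matrix.library_sizes.astype(float)
    if norm_factors is None:
        norm_factors = tmm_factors(matrix)
    eff_libs = libs * norm_factors

    pseudo = _equalize_libraries(counts, eff_libs)
    groups = [idx_a, idx_b]
    nonzero = pseudo.sum(axis=1) > 0

    if isinstance(dispersion, str):
        if dispersion == "common":
            phi_common = estimate_common_dispersion(pseudo[nonzero], groups)
            phis = np.full(pseudo.shape[0], phi_common)
        elif dispersion == "tagwise":
            phi_common = estimate_common_dispersion(pseudo[nonzero], groups)
            phis = np.full(pseudo.shape[0], phi_common)
            phis[nonzero] = estimate_tagwise_dispersions(
                pseudo[nonzero], groups, phi_common
            )
        else:
            raise ValueError(f"unknown dispersion mode {dispersion!r}")
    else:
        phis = np.full(pseudo.shape[0], float(dispersion))

    n_a, n_b = len(idx_a), len(idx_b)
    cpm = counts / eff_libs[None, :] * 1e6
    mean_a = cpm[:, idx_a].mean(axis=1)
    mean_b = cpm[:, idx_b].mean(axis=1)
    log2fc = np.log2((mean_b + lfc_prior_cpm) / (mean_a + lfc_prior_cpm))
    mean_logcpm = np.log2(cpm.mean(axis=1) + lfc_prior_cpm)

    pvals = np.ones(pseudo.shape[0])
    for i in range(pseudo.shape[0]):
        if not nonzero[i]:
            continue
        s_a = int(pseudo[i, idx_a].sum())
        s_b = int(pseudo[i, idx_b].sum())
        pvals[i] = _exact_conditional_p(s_a, s_a + s_b, n_a, n_b, phis[i])

    log2fc = np.where(nonzero, log2fc, 0.0)
    qvals = bh_adjust(pvals)
    return pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "log2FC": log2fc,
            "p_value": pvals,
            "q_value": qvals,
            "mean_logcpm": mean_logcpm,
            "all_zero": ~nonzero,
        }
    )


def fisher_test(
    matrix: CountMatrix,
    group_labels: list[str] | np.ndarray,
    norm_factors: np.ndarray | None = None,
    lfc_prior_cpm: float = 0.5,
) -> pd.DataFrame:
    """Fisher-exact alternative: per feature, 2x2 table of pooled group counts
    vs the rest of each group's library. Provided for comparison with the NB
    exact test; ignores within-group dispersion."""
    labels = np.asarray(group_labels)
    uniq = sorted(set(labels.tolist()))
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {uniq}")
    idx_a = np.where(labels == uniq[0])[0]
    idx_b = np.where(labels == uniq[1])[0]
    counts = np.asarray(matrix.counts, dtype=float)
    libs = matrix.library_sizes.astype(float)
    if norm_factors is None:
        norm_factors = tmm_factors(matrix)
    eff = libs * norm_factors
    tot_a, tot_b = eff[idx_a].sum(), eff[idx_b].sum()
    sum_a = counts[:, idx_a].sum(axis=1)
    sum_b = counts[:, idx_b].sum(axis=1)
    cpm = counts / eff[None, :] * 1e6
    log2fc = np.log2(
        (cpm[:, idx_b].mean(axis=1) + lfc_prior_cpm)
        / (cpm[:, idx_a].mean(axis=1) + lfc_prior_cpm)
    )
    pvals = np.ones(counts.shape[0])
    for i in range(counts.shape[0]):
        table = [
            [int(sum_a[i]), int(round(tot_a - sum_a[i]))],
            [int(sum_b[i]), int(round(tot_b - sum_b[i]))],
        ]
        pvals[i] = stats.fisher_exact(table)[1]
    qvals = bh_adjust(pvals)
    return pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "log2FC": log2fc,
            "p_value": pvals,
            "q_value": qvals,
            "mean_logcpm": np.log2(cpm.mean(axis=1) + lfc_prior_cpm),
            "all_zero": (sum_a + sum_b) == 0,
        }
    )


def bh_adjust(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_differential(
    results: pd.DataFrame, lfc_threshold: float = 1.0, q_threshold: float = 0.05
) -> pd.DataFrame:
    """Label features up/down/unchanged at |log2FC| >= t and q < alpha."""
    if lfc_threshold <= 0 or q_threshold <= 0:
        raise ValueError("thresholds must be positive")
    call = np.where(
        (results["log2FC"] >= lfc_threshold) & (results["q_value"] < q_threshold),
        "up",
        np.where(
            (results["log2FC"] <= -lfc_threshold) & (results["q_value"] < q_threshold),
            "down",
            "unchanged",
        ),
    )
    out = results.copy()
    out["call"] = call
    return out
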