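"""Bayesian FST-outlier scan.

Population- and locus-specific differentiation is decomposed on the logistic
scale, ``logit(FST_ij) = alpha_i + beta_j``: ``beta_j`` captures the shared
demography of population j, and a non-zero locus effect ``alpha_i`` marks a
locus whose differentiation departs from the genome-wide pattern
(diversifying selection when positive). The observed minor-allele count in
population j at locus i is beta-binomial: the island-model deme frequency
``p_ij ~ Beta(theta_ij p_i, theta_ij (1 - p_i))`` with
``theta_ij = 1/FST_ij - 1`` is marginalised analytically, which shrinks the
MCMC state to (p_i, alpha_i, beta_j) and the per-locus inclusion indicator
for alpha_i. Inclusion is toggled by a reversible-jump move whose proposal
is the alpha prior, so the acceptance ratio reduces to the likelihood ratio
times the prior odds. Posterior inclusion probabilities are converted to
q-values by the running-mean Bayesian false-discovery rate.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logit

from .popgen import PopAlleleFreq

ALPHA_PRIOR_SD = 1.0
BETA_PRIOR_MEAN = -1.0
BETA_PRIOR_SD = 1.0
ACCEPT_LOW, ACCEPT_HIGH = 0.25, 0.45


@dataclass
class OutlierScanResult:
    """Per-locus posterior summaries of the outlier scan."""

    table: pd.DataFrame            # locus, P, fst, q, alpha_mean, outlier
    settings: dict = field(default_factory=dict)
    acceptance: dict = field(default_factory=dict)
    excluded: list[str] = field(default_factory=list)

    def __getitem__(self, col):
        return self.table[col]


def bayes_qvalues(P: np.ndarray) -> np.ndarray:
    """Bayesian FDR q-values from posterior inclusion probabilities.

    Sorting loci by decreasing P, q(i) is the mean of (1 - P) over loci
    ranked at or above i: the expected false-discovery proportion of the
    rejection set that stops at rank i.
    """
    P = np.asarray(P, dtype=float)
    if np.any((P < 0) | (P > 1)):
        raise ValueError("posterior probabilities must lie in [0, 1]")
    order = np.argsort(-P, kind="stable")
    q_sorted = np.cumsum(1.0 - P[order]) / np.arange(1, len(P) + 1)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def _loglik(k, n, p, alpha_eff, beta):
    """Beta-binomial log likelihood matrix, binomial coefficient dropped.

    k, n: (L, P) counts; p: (L,); alpha_eff: (L,) (zero where excluded);
    beta: (P,).
    """
    F = expit(alpha_eff[:, None] + beta[None, :])
    theta = 1.0 / F - 1.0
    a = theta * p[:, None]
    b = theta * (1.0 - p[:, None])
    ll = (
        gammaln(k + a) + gammaln(n - k + b) - gammaln(n + theta)
        - gammaln(a) - gammaln(b) + gammaln(theta)
    )
    return np.where(n > 0, ll, 0.0)


def fit_rjmcmc(
    freqs: PopAlleleFreq,
    prior_odds: float = 10.0,
    n_out: int = 5000,
    thin: int = 10,
    pilot_runs: int = 20,
    pilot_len: int = 5000,
    burn_in: int = 50000,
    seed: int = 0,
    q_threshold: float = 0.05,
) -> OutlierScanResult:
    """Run the reversible-jump scan and return posterior summaries.

    ``n_out`` posterior samples are recorded every ``thin`` sweeps after
    ``burn_in`` sweeps; ``pilot_runs`` pilot chains of ``pilot_len`` sweeps
    adapt the random-walk proposal widths into the 0.25-0.45 acceptance
    band first. Monomorphic loci (no minor alleles anywhere) carry no
    information about differentiation and are excluded with a notice.
    """
    n_mat = np.asarray(freqs.n_alleles, dtype=float).T         # (L, P)
    with np.errstate(invalid="ignore"):
        k_mat = np.round(np.nan_to_num(freqs.freq.T) * n_mat)   # minor-allele counts
    L_all = n_mat.shape[0]

    informative = k_mat.sum(axis=1) > 0
    excluded = [freqs.locus_ids[i] for i in np.flatnonzero(~informative)]
    k = k_mat[informative]
    n = n_mat[informative]
    L, P = k.shape
    if L == 0:
        raise ValueError("no polymorphic loci to scan")

    rng = np.random.default_rng(seed)
    pi1 = 1.0 / (1.0 + prior_odds)          # prior inclusion probability

    # state
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.clip(k.sum(axis=1) / np.maximum(n.sum(axis=1), 1), 0.01, 0.99)
    alpha = np.zeros(L)
    incl = rng.random(L) < pi1
    beta = np.full(P, BETA_PRIOR_MEAN)

    w_p = np.full(L, 0.5)
    w_a = np.full(L, 0.5)
    w_b = np.full(P, 0.2)

    ll = _loglik(k, n, p, alpha * incl, beta)
    acc = {"p": 0, "alpha": 0, "alpha_n": 0, "beta": 0, "rj": 0}

    def sweep(adapting_counts=None):
        nonlocal p, alpha, incl, beta, ll
        # -- p_i : random walk on the logit scale, U(0,1) prior (Jacobian)
        prop = expit(logit(p) + w_p * rng.standard_normal(L))
        prop = np.clip(prop, 1e-9, 1 - 1e-9)
        ll_prop = _loglik(k, n, prop, alpha * incl, beta)
        log_acc = (ll_prop - ll).sum(axis=1) + (
            np.log(prop * (1 - prop)) - np.log(p * (1 - p))
        )
        take = np.log(rng.random(L)) < log_acc
        p = np.where(take, prop, p)
        ll[take] = ll_prop[take]
        if adapting_counts is not None:
            adapting_counts["p"] += take

        # -- alpha_i for included loci : random walk, N(0,1) prior
        if incl.any():
            prop_a = alpha + w_a * rng.standard_normal(L)
            ll_prop = _loglik(k, n, p, prop_a * incl, beta)
            log_acc = (ll_prop - ll).sum(axis=1) + (alpha**2 - prop_a**2) / (
                2 * ALPHA_PRIOR_SD**2
            )
            take = incl & (np.log(rng.random(L)) < log_acc)
            alpha = np.where(take, prop_a, alpha)
            ll[take] = ll_prop[take]
            if adapting_counts is not None:
                adapting_counts["alpha"] += take

        # -- reversible jump: toggle inclusion, proposal = alpha prior
        alpha_new = np.where(incl, 0.0, rng.standard_normal(L) * ALPHA_PRIOR_SD)
        incl_prop = ~incl
        ll_prop = _loglik(k, n, p, alpha_new * incl_prop, beta)
        log_odds = np.where(incl, np.log(prior_odds), -np.log(prior_odds))
        log_acc = (ll_prop - ll).sum(axis=1) + log_odds
        take = np.log(rng.random(L)) < log_acc
        incl = np.where(take, incl_prop, incl)
        alpha = np.where(take, alpha_new, alpha)
        ll[take] = ll_prop[take]
        acc["rj"] += int(take.sum())

        # -- beta_j : one-at-a-time random walk, N(-1,1) prior
        for j in range(P):
            bprop = beta.copy()
            bprop[j] = beta[j] + w_b[j] * rng.standard_normal()
            F = expit(alpha * incl + bprop[j])
            theta = 1.0 / F - 1.0
            a_col = theta * p
            b_col = theta * (1 - p)
            col = (
                gammaln(k[:, j] + a_col) + gammaln(n[:, j] - k[:, j] + b_col)
                - gammaln(n[:, j] + theta) - gammaln(a_col) - gammaln(b_col)
                + gammaln(theta)
            )
            col = np.where(n[:, j] > 0, col, 0.0)
            log_acc_b = (col - ll[:, j]).sum() + (
                (beta[j] - BETA_PRIOR_MEAN) ** 2 - (bprop[j] - BETA_PRIOR_MEAN) ** 2
            ) / (2 * BETA_PRIOR_SD**2)
            if np.log(rng.random()) < log_acc_b:
                beta[j] = bprop[j]
                ll[:, j] = col
                if adapting_counts is not None:
                    adapting_counts["beta"][j] += 1

    # ---- pilot adaptation
    for _pilot in range(pilot_runs):
        counts = {"p": np.zeros(L), "alpha": np.zeros(L), "beta": np.zeros(P)}
        incl_steps = np.zeros(L)
        for _ in range(pilot_len):
            incl_steps += incl
            sweep(adapting_counts=counts)
        for widths, key, steps in (
            (w_p, "p", pilot_len),
            (w_a, "alpha", None),
            (w_b, "beta", pilot_len),
        ):
            denom = incl_steps if steps is None else steps
            rate = counts[key] / np.maximum(denom, 1)
            widths[rate < ACCEPT_LOW] *= 0.7
            widths[rate > ACCEPT_HIGH] *= 1.4
    np.clip(w_p, 1e-3, 10, out=w_p)
    np.clip(w_a, 1e-3, 10, out=w_a)
    np.clip(w_b, 1e-3, 10, out=w_b)

    # ---- burn-in
    final_counts = {"p": np.zeros(L), "alpha": np.zeros(L), "beta": np.zeros(P)}
    for _ in range(burn_in):
        sweep(adapting_counts=final_counts)

    rate_p = float(np.mean(final_counts["p"]) / max(burn_in, 1))
    if burn_in > 0 and not (0.05 < rate_p < 0.8):
        import warnings

        warnings.warn(
            f"p-update acceptance {rate_p:.2f} outside a healthy range after pilots",
            stacklevel=2,
        )

    # ---- sampling
    incl_sum = np.zeros(L)
    fst_sum = np.zeros(L)
    alpha_sum = np.zeros(L)
    for _s in range(n_out):
        for _ in range(thin):
            sweep()
        incl_sum += incl
        alpha_sum += alpha * incl
        fst_sum += expit(alpha[:, None] * incl[:, None] + beta[None, :]).mean(axis=1)

    P_incl = incl_sum / n_out
    fst_mean = fst_sum / n_out
    alpha_mean = alpha_sum / n_out
    q = bayes_qvalues(P_incl)

    table = pd.DataFrame(
        {
            "locus": [freqs.locus_ids[i] for i in np.flatnonzero(informative)],
            "P": P_incl,
            "fst": fst_mean,
            "alpha_mean": alpha_mean,
            "q": q,
        }
    )
    table["outlier"] = classify_outliers(table, q_threshold=q_threshold)
    # re-insert excluded loci as NaN rows so callers can align with input
    if excluded:
        pad = pd.DataFrame({"locus": excluded})
        table = (
            pd.concat([table, pad], ignore_index=True)
            .set_index("locus")
            .loc[freqs.locus_ids if L_all == len(freqs.locus_ids) else None]
            .reset_index()
        )
        table["outlier"] = table["outlier"].fillna(False).astype(bool)
    settings = dict(
        prior_odds=prior_odds, n_out=n_out, thin=thin, pilot_runs=pilot_runs,
        pilot_len=pilot_len, burn_in=burn_in, seed=seed, q_threshold=q_threshold,
    )
    return OutlierScanResult(table, settings=settings, excluded=excluded,
                             acceptance={"rate_p": rate_p})


def classify_outliers(result, q_threshold: float = 0.05) -> pd.Series | np.ndarray:
    """Diversifying outliers: strictly q < threshold and positive locus effect."""
    table = result.table if isinstance(result, OutlierScanResult) else result
    if len(table) == 0:
        return np.zeros(0, dtype=bool)
    return (table["q"] < q_threshold) & (table["alpha_mean"] > 0)


def write_scan_tsv(result: OutlierScanResult, path) -> None:
    with open(path, "w") as fh:
        for key, val in result.settings.items():
            fh.write(f"# {key} = {val}\n")
        result.table.to_csv(fh, sep="\t", index=False, float_format="%.6g")
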