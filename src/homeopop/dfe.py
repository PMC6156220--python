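"""Gamma-DFE and adaptive-substitution-proportion estimation by MCMC.

The deleterious distribution of fitness effects (DFE) of new
nonsynonymous mutations is a gamma distribution of the scaled selection
strength gamma = Ne*s (shape ``beta``, mean ``mean_gamma``), fitted to a
pair of folded site-frequency spectra: synonymous classes are neutral,
nonsynonymous classes are weighted by the Poisson-random-field sampling
kernel integrated over the DFE.  Demography and ascertainment distortions
shared by the two site classes are absorbed by per-frequency-class
nuisance multipliers r_j (r_1 = 1) multiplying both expectations — the
device used by the DoFE family of methods.  Counts are modelled as
independent Poissons and sampled by Metropolis-Hastings on log-scale
parameters with Gaussian proposals (adaptive scaling during burn-in
only).

The proportion of adaptive nonsynonymous substitutions is

    alpha = (Dn - d0) / Dn,
    d0 = Ds * (Ln/Ls) * E_DFE[ 2 gamma / (e^{2 gamma} - 1) ],

the observed nonsynonymous divergence in excess of what the fitted
deleterious DFE predicts from the synonymous divergence; alpha is
computed per posterior sample and summarised with a central 95% interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from . import prf
from .popgen import SiteFrequencySpectrum

__all__ = [
    "DFEModel",
    "DFEPosterior",
    "PRIOR_BOUNDS",
    "expected_sfs",
    "loglik",
    "run_mcmc",
    "nes_categories",
    "estimate_alpha",
    "stratify_by_expression",
    "subsample_accessions",
    "gelman_rubin",
]

#: log-uniform prior bounds (weakly informative, scale-free)
PRIOR_BOUNDS = {
    "shape": (0.05, 5.0),
    "mean_gamma": (1e-3, 1e5),
    "theta": (1e-8, 1e8),
    "r": (1e-3, 1e3),
}


@dataclass
class DFEModel:
    shape: float
    mean_gamma: float
    theta_s: float              # per-locus synonymous mutation scale
    theta_n: float
    r: np.ndarray               # nuisance multipliers, r[0] == 1

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        if self.r[0] != 1.0:
            raise ValueError("r_1 must be fixed at 1")
        if np.any(self.r <= 0) or self.theta_s <= 0 or self.theta_n <= 0 \
                or self.shape <= 0 or self.mean_gamma < 0:
            raise ValueError("invalid DFE model parameters")


def _folded_neutral(n: int) -> np.ndarray:
    i = np.arange(1, n)
    return prf.fold_expected(1.0 / i, n)


def expected_sfs(model: DFEModel, n: int, quad: prf.DFEQuadrature | None = None,
                 folded: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """(synonymous, nonsynonymous) expected class counts for sample size n."""
    if n < 4:
        raise ValueError("need n >= 4")
    quad = quad or prf.DFEQuadrature(n)
    if folded:
        neutral = _folded_neutral(n)
        sel = quad.folded_class_means(model.shape, model.mean_gamma) \
            if model.mean_gamma > 0 else neutral
    else:
        neutral = 1.0 / np.arange(1, n)
        sel = quad.class_means(model.shape, model.mean_gamma) \
            if model.mean_gamma > 0 else neutral
    if len(model.r) != len(neutral):
        raise ValueError(f"need {len(neutral)} nuisance multipliers")
    return model.theta_s * model.r * neutral, model.theta_n * model.r * sel


def loglik(model: DFEModel, sfs_syn, sfs_nonsyn, n: int,
           quad: prf.DFEQuadrature | None = None) -> float:
    """Poisson log-likelihood of the two folded spectra under the model."""
    ks = np.asarray(sfs_syn, dtype=float)
    kn = np.asarray(sfs_nonsyn, dtype=float)
    lam_s, lam_n = expected_sfs(model, n, quad)
    ll = 0.0
    for k, lam in ((ks, lam_s), (kn, lam_n)):
        if np.any((lam == 0) & (k > 0)):
            return -np.inf
        good = lam > 0
        ll += float((k[good] * np.log(lam[good]) - lam[good]
                     - gammaln(k[good] + 1)).sum())
    return ll


@dataclass
class DFEPosterior:
    """Thinned post-burn-in MCMC samples plus chain diagnostics."""

    n: int
    samples: pd.DataFrame       # theta_s, theta_n, shape, mean_gamma, r_j...
    acceptance_rate: float
    quad: prf.DFEQuadrature = field(repr=False)

    def category_matrix(self) -> np.ndarray:
        """(n_samples, 4) Ne*s category proportions per posterior sample."""
        out = np.empty((len(self.samples), len(prf.NES_BREAKS) + 1))
        for i, row in enumerate(self.samples.itertuples()):
            out[i] = prf.gamma_category_proportions(row.shape, row.mean_gamma)
        return out


def _unpack(x: np.ndarray, J: int) -> DFEModel:
    r = np.concatenate([[1.0], np.exp(x[4:4 + J - 1])])
    return DFEModel(np.exp(x[2]), np.exp(x[3]), np.exp(x[0]), np.exp(x[1]), r)


def _log_prior_ok(x: np.ndarray, J: int) -> bool:
    th_lo, th_hi = np.log(PRIOR_BOUNDS["theta"])
    b_lo, b_hi = np.log(PRIOR_BOUNDS["shape"])
    m_lo, m_hi = np.log(PRIOR_BOUNDS["mean_gamma"])
    r_lo, r_hi = np.log(PRIOR_BOUNDS["r"])
    return bool(
        th_lo <= x[0] <= th_hi and th_lo <= x[1] <= th_hi
        and b_lo <= x[2] <= b_hi and m_lo <= x[3] <= m_hi
        and np.all(x[4:] >= r_lo) and np.all(x[4:] <= r_hi))


def run_mcmc(sfs_syn, sfs_nonsyn, n: int, reps: int = 100_000,
             thin: int = 100, burn: int | None = None, seed: int = 0,
             quad: prf.DFEQuadrature | None = None,
             site_ratio: float | None = None) -> DFEPosterior:
    """Metropolis-Hastings fit of the DFE model to a folded SFS pair.

    ``sfs_syn`` / ``sfs_nonsyn`` are folded spectra (arrays of length
    n//2, or SiteFrequencySpectrum).  The default desk-scale schedule is
    1e5 replicates thinned every 100 after a burn-in of reps//10;
    the full-scale schedule (reps=1e6, thin=1000, burn=1e5) is a flag
    away.  Proposals are Gaussian on log parameters with a scale adapted
    during burn-in toward an acceptance rate of 0.2-0.4.

    ``site_ratio`` = Ln/Ls, the nonsynonymous/synonymous site-count
    ratio.  When given, theta_n is tied to theta_s * site_ratio (equal
    per-site mutation rates), so the genome-wide deficit of nonsynonymous
    polymorphism informs the strongly deleterious tail of the DFE, which
    the SFS shape alone cannot see; without it theta_n is a free
    parameter and the tail is only weakly identified.
    """

    def as_array(s):
        if isinstance(s, SiteFrequencySpectrum):
            if not s.folded:
                s = s.fold()
            return s.counts.astype(float)
        return np.asarray(s, dtype=float)

    ks, kn = as_array(sfs_syn), as_array(sfs_nonsyn)
    J = n // 2
    if len(ks) != J or len(kn) != J:
        raise ValueError(f"folded spectra for n={n} need {J} classes")
    if burn is None:
        # at least 20k iterations of burn-in unless the chain is tiny:
        # weakly informative data need the time to find the posterior bulk
        burn = max(reps // 10, min(20_000, reps // 2))
    if reps - burn < thin:
        raise ValueError("chain too short: no samples after burn-in")
    quad = quad or prf.DFEQuadrature(n)
    rng = np.random.default_rng(seed)
    neutral = _folded_neutral(n)

    # data-driven but deterministic start
    tied = site_ratio is not None
    theta_s0 = max(ks.sum() / neutral.sum(), 1e-6)
    theta_n0 = theta_s0 * site_ratio if tied \
        else max(kn.sum() / neutral.sum(), 1e-6)
    x = np.concatenate([
        [np.log(theta_s0), np.log(theta_n0), np.log(0.5), np.log(10.0)],
        np.zeros(J - 1)])
    D = len(x)
    scales = np.full(D, 0.08)
    if tied:
        scales[1] = 0.0
        log_ratio = np.log(site_ratio)

    def ll_of(xv):
        model = _unpack(xv, J)
        return loglik(model, ks, kn, n, quad)

    cur_ll = ll_of(x)
    kept = []
    n_acc = 0
    n_prop = 0
    window_acc = 0
    for it in range(reps):
        prop = x + rng.normal(0, scales)
        if tied:
            prop[1] = prop[0] + log_ratio
        if _log_prior_ok(prop, J):
            ll = ll_of(prop)
            if np.log(rng.random()) < ll - cur_ll:
                x, cur_ll = prop, ll
                n_acc += 1
                window_acc += 1
        n_prop += 1
        if it < burn and (it + 1) % 200 == 0:
            rate = window_acc / 200.0
            scales *= np.exp(0.6 * (rate - 0.3))
            window_acc = 0
        if it >= burn and (it - burn) % thin == 0:
            kept.append(np.concatenate([x, [cur_ll]]))
    acc_rate = n_acc / n_prop
    if acc_rate < 0.05:
        raise RuntimeError(
            f"MCMC acceptance rate {acc_rate:.3f} < 0.05 after adaptation")
    cols = (["theta_s", "theta_n", "shape", "mean_gamma"]
            + [f"r_{j}" for j in range(2, J + 1)] + ["loglik"])
    arr = np.asarray(kept)
    df = pd.DataFrame(np.column_stack([np.exp(arr[:, :D]), arr[:, D]]),
                      columns=cols)
    return DFEPosterior(n, df, acc_rate, quad)


def nes_categories(posterior: DFEPosterior) -> pd.DataFrame:
    """Posterior mean and sd of the four Ne*s category proportions."""
    mat = posterior.category_matrix()
    labels = ["0<Nes<1", "1<Nes<10", "10<Nes<100", "Nes>100"]
    return pd.DataFrame({"category": labels,
                         "mean": mat.mean(axis=0),
                         "sd": mat.std(axis=0, ddof=1)})


def estimate_alpha(posterior: DFEPosterior, Dn: int, Ds: int,
                   Ln: float, Ls: float) -> dict | None:
    """alpha per posterior sample; point estimate and central 95% interval."""
    if Dn == 0:
        return None
    quad = posterior.quad
    alphas = []
    for row in posterior.samples.itertuples():
        fix = quad.mean_fixation_rate(row.shape, row.mean_gamma)
        d0 = Ds * (Ln / Ls) * fix
        alphas.append((Dn - d0) / Dn)
    a = np.asarray(alphas)
    return {"alpha": float(a.mean()),
            "ci_low": float(np.quantile(a, 0.025)),
            "ci_high": float(np.quantile(a, 0.975)),
            "samples": a}


def stratify_by_expression(gene_ids, rpkm, q: float = 0.10) -> dict:
    """Upper-q / lower-q expression strata (deterministic tie-break).

    ``gene_ids`` and ``rpkm`` are parallel sequences.  Ties at the cut are
    broken by gene_id order.  Returns {"high": [...], "low": [...]}.
    """
    if not 0 < q <= 0.5:
        raise ValueError("q must be in (0, 0.5]")
    df = pd.DataFrame({"gene_id": list(gene_ids), "rpkm": list(rpkm)})
    if len(df) < int(np.ceil(1.0 / q)):
        raise ValueError("too few genes for the requested quantile")
    k = max(1, int(round(q * len(df))))
    df_hi = df.sort_values(["rpkm", "gene_id"], ascending=[False, True])
    df_lo = df.sort_values(["rpkm", "gene_id"], ascending=[True, True])
    return {"high": df_hi["gene_id"].head(k).tolist(),
            "low": df_lo["gene_id"].head(k).tolist()}


def subsample_accessions(items, m: int, seed: int = 0) -> list:
    """Uniform subsample of accessions without replacement (reproducible)."""
    items = list(items)
    if m > len(items):
        raise ValueError("m must be <= number of accessions")
    if m == len(items):
        return items
    rng = np.random.default_rng(seed)
    idx = sorted(rng.choice(len(items), size=m, replace=False))
    return [items[i] for i in idx]


def gelman_rubin(chains: list[np.ndarray]) -> float:
    """Potential scale reduction factor over >= 2 chains of equal length."""
    arr = np.asarray(chains, dtype=float)
    m, n = arr.shape
    if m < 2 or n < 2:
        raise ValueError("need >= 2 chains of length >= 2")
    means = arr.mean(axis=1)
    W = arr.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(var_hat / W))
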