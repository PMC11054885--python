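"""Beta-binomial likelihood-ratio test for differential miRNA editing.

Editing proportions from count data are over-dispersed relative to a
binomial: replicate animals differ biologically on top of sampling
noise. The model here treats the edited count k_i of sample i as

    k_i | p_i ~ Binomial(n_i, p_i),    p_i ~ Beta(a_g, b_g)

with a mean/dispersion parameterization a = mu(1-rho)/rho,
b = (1-mu)(1-rho)/rho: mu is the group's mean editing level and
rho in [0,1) the intra-class dispersion (rho -> 0 recovers a plain
binomial). The null fits a common mean and the dispersion jointly; the
alternative then gives each group its own mean at that shared, fixed
dispersion — holding rho fixed across the two likelihoods keeps the
statistic calibrated with n = 3 replicates per group.
2*(llf_alt - llf_null) is referred to chi-square with 1 degree of
freedom.

`DifferentialEditingModel` / `DifferentialEditingResults` follow the
statsmodels model/results idiom; `pairwise_differential` applies the
test per site to every unordered stage pair (4 stages -> 6 pairs).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

_EPS_MU = 1e-6
_RHO_MIN = 1e-8
_RHO_MAX = 0.999


def betabinom_loglik(k, n, mu, rho):
    """Sum of beta-binomial log-pmfs at mean mu, dispersion rho.

    In the rho -> 0 limit the binomial log-likelihood is returned
    directly to avoid overflowing the Beta parameters.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    mu = min(max(mu, _EPS_MU), 1.0 - _EPS_MU)
    if rho < _RHO_MIN:
        return float(np.sum(stats.binom.logpmf(k, n, mu)))
    a = mu * (1.0 - rho) / rho
    b = (1.0 - mu) * (1.0 - rho) / rho
    ll = (
        special.gammaln(n + 1)
        - special.gammaln(k + 1)
        - special.gammaln(n - k + 1)
        + special.betaln(k + a, n - k + b)
        - special.betaln(a, b)
    )
    return float(np.sum(ll))


def _logit(p):
    return np.log(p / (1.0 - p))


def _expit(x):
    return special.expit(x)


@dataclass
class DifferentialEditingResults:
    """Fit results for one site and one group comparison."""

    group_means: dict[str, float]
    rho: float
    llf_alt: float
    llf_null: float
    null_mean: float
    converged: bool
    groups: tuple[str, str]
    nobs: int

    @property
    def lrt(self) -> float:
        return max(0.0, 2.0 * (self.llf_alt - self.llf_null))

    @property
    def pvalue(self) -> float:
        if not self.converged:
            return np.nan
        return float(stats.chi2.sf(self.lrt, df=1))

    def summary(self) -> str:
        g1, g2 = self.groups
        lines = [
            "Beta-binomial differential editing test",
            "=" * 46,
            f"groups:            {g1} vs {g2} (n = {self.nobs})",
            f"mean level {g1}:   {self.group_means[g1]:.4f}",
            f"mean level {g2}:   {self.group_means[g2]:.4f}",
            f"dispersion rho:    {self.rho:.4g}",
            f"log-lik (alt/null): {self.llf_alt:.4f} / {self.llf_null:.4f}",
            f"LRT (df=1):        {self.lrt:.4f}",
            f"p-value:           {self.pvalue:.4g}",
            f"converged:         {self.converged}",
        ]
        return "\n".join(lines)


class DifferentialEditingModel:
    """Two-group beta-binomial model for one editing site.

    Parameters
    ----------
    edited, total : array-like of int
        Per-sample edited and total read counts.
    groups : array-like
        Group label per sample; exactly two distinct labels.
    """

    def __init__(self, edited, total, groups):
        self.k = np.asarray(edited, dtype=float)
        self.n = np.asarray(total, dtype=float)
        self.groups = np.asarray(groups)
        if self.k.shape != self.n.shape or self.k.shape != self.groups.shape:
            raise ValueError("edited/total/groups must have equal length")
        if np.any(self.k < 0) or np.any(self.k > self.n):
            raise ValueError("need 0 <= edited <= total")
        if len(self.k) < 2:
            raise ValueError("need at least 2 samples")
        if not np.any(self.n > 0):
            raise ValueError("all totals are zero")
        self.labels = tuple(pd.unique(self.groups))
        if len(self.labels) != 2:
            raise ValueError(f"need exactly 2 groups, got {self.labels}")
        self._masks = [self.groups == lab for lab in self.labels]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, group_col="stage", edited_col="edited", total_col="total"):
        return cls(df[edited_col].to_numpy(), df[total_col].to_numpy(), df[group_col].to_numpy())

    def _degenerate_dispersion(self) -> bool:
        """True when every group's observed proportions are constant, so
        the dispersion has no information to be estimated from."""
        for mask in self._masks:
            n, k = self.n[mask], self.k[mask]
            ok = n > 0
            if ok.sum() < 2:
                continue
            props = k[ok] / n[ok]
            if np.ptp(props) > 1e-12:
                return False
        return True

    # -- likelihoods ----------------------------------------------------
    def _moment_start(self):
        means = []
        for mask in self._masks:
            tot = self.n[mask].sum()
            means.append(self.k[mask].sum() / tot if tot > 0 else 0.5)
        props = np.divide(self.k, self.n, out=np.full_like(self.k, np.nan), where=self.n > 0)
        var = np.nanvar(props)
        mu0 = float(np.clip(np.nanmean(props), 0.01, 0.99))
        nbar = max(np.mean(self.n[self.n > 0]), 1.0)
        denom = mu0 * (1 - mu0)
        rho0 = float(np.clip((var - denom / nbar) / max(denom, 1e-9), 1e-4, 0.5)) if denom > 0 else 1e-3
        return [float(np.clip(m, _EPS_MU, 1 - _EPS_MU)) for m in means], rho0

    def fit(self, fixed_rho: float | None = None) -> DifferentialEditingResults:
        """Maximum-likelihood fit of the null, then the alternative.

        The dispersion is estimated jointly with the common mean under
        the null and then held fixed for both likelihoods, so the LRT
        compares one free mean against two at the same rho (df = 1).
        Estimating rho under the alternative instead lets the group
        difference leak into a smaller dispersion and inflates the
        type-I error severely at n = 3 per group. When every group's
        proportions are constant the dispersion carries no information
        and the parsimonious binomial limit (rho = 0) is used.

        ``fixed_rho`` pins the dispersion instead of estimating it;
        ``fixed_rho=0`` gives the plain-binomial limit of the test.
        """
        (m1, m2), rho0 = self._moment_start()
        converged = True
        pooled = float(np.clip(self.k.sum() / max(self.n.sum(), 1.0), _EPS_MU, 1 - _EPS_MU))
        if fixed_rho is None and self._degenerate_dispersion():
            fixed_rho = 0.0

        if fixed_rho is None:

            def nll_null_joint(theta):
                return -betabinom_loglik(
                    self.k, self.n, _expit(theta[0]), _expit(theta[1]) * _RHO_MAX
                )

            best = None
            any_ok = False
            for r0 in (min(rho0 / _RHO_MAX, 0.9), 0.001, 0.1):
                res = optimize.minimize(
                    nll_null_joint,
                    np.array([_logit(pooled), _logit(r0)]),
                    method="L-BFGS-B",
                    options={"ftol": 1e-11, "gtol": 1e-9},
                )
                any_ok = any_ok or bool(res.success)
                if best is None or res.fun < best.fun - 1e-12:
                    best = res
            null_polish = optimize.minimize(
                nll_null_joint, best.x, method="Nelder-Mead",
                options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 600},
            )
            if null_polish.fun <= best.fun:
                best = null_polish
            converged = any_ok or bool(null_polish.success)
            rho = float(_expit(best.x[1]) * _RHO_MAX)
            llf_null = -float(best.fun)
            null_mean = float(_expit(best.x[0]))
        else:
            rho = float(fixed_rho)
            null_res = optimize.minimize_scalar(
                lambda t: -betabinom_loglik(self.k, self.n, _expit(t), rho),
                bracket=(_logit(pooled) - 2, _logit(pooled) + 2),
                method="brent",
                options={"xtol": 1e-12},
            )
            llf_null = -float(null_res.fun)
            null_mean = float(_expit(null_res.x))

        def nll_alt(theta):
            ll = 0.0
            for mask, t in zip(self._masks, theta):
                ll += betabinom_loglik(self.k[mask], self.n[mask], _expit(t), rho)
            return -ll

        lbfgs = optimize.minimize(
            nll_alt,
            np.array([_logit(m1), _logit(m2)]),
            method="L-BFGS-B",
            options={"ftol": 1e-11, "gtol": 1e-9},
        )
        polish = optimize.minimize(
            nll_alt, lbfgs.x, method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 600},
        )
        alt_res = polish if polish.fun <= lbfgs.fun else lbfgs
        converged = converged and (bool(lbfgs.success) or bool(polish.success))
        mu1, mu2 = _expit(alt_res.x[0]), _expit(alt_res.x[1])
        llf_alt = -float(alt_res.fun)
        return DifferentialEditingResults(
            group_means={self.labels[0]: float(mu1), self.labels[1]: float(mu2)},
            rho=rho,
            llf_alt=llf_alt,
            llf_null=min(llf_null, llf_alt),
            null_mean=null_mean,
            converged=converged,
            groups=self.labels,
            nobs=len(self.k),
        )


# ---------------------------------------------------------------------------
# pairwise orchestration


def stage_pairs(stages) -> list[tuple[str, str]]:
    """All unordered stage pairs in stage order (4 stages -> 6 pairs)."""
    return list(combinations(stages, 2))


def pairwise_differential(
    counts: pd.DataFrame,
    stages,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run the beta-binomial LRT per site for every stage pair.

    ``counts`` is long-format with columns site_id, sample, stage,
    edited, total. Stage pairs without usable samples on both sides are
    skipped. Benjamini-Hochberg q-values are reported per pair for
    transparency; the significance flag follows raw p < alpha.
    """
    rows = []
    for s1, s2 in stage_pairs(stages):
        sub_all = counts[counts["stage"].isin([s1, s2])]
        for site_id, sub in sub_all.groupby("site_id", sort=True):
            sub = sub[sub["total"] > 0]
            if (sub["stage"] == s1).sum() == 0 or (sub["stage"] == s2).sum() == 0:
                continue
            model = DifferentialEditingModel.from_dataframe(sub)
            res = model.fit()
            rows.append(
                {
                    "site_id": site_id,
                    "stage_pair": f"{s1}_vs_{s2}",
                    "mean_1": res.group_means.get(s1, np.nan),
                    "mean_2": res.group_means.get(s2, np.nan),
                    "rho": res.rho,
                    "lrt": res.lrt,
                    "pvalue": res.pvalue,
                    "converged": res.converged,
                }
            )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["qvalue"] = np.nan
    for pair, idx in out.groupby("stage_pair").groups.items():
        pvals = out.loc[idx, "pvalue"].to_numpy()
        ok = np.isfinite(pvals)
        if ok.any():
            out.loc[np.asarray(idx)[ok], "qvalue"] = multipletests(pvals[ok], method="fdr_bh")[1]
    out["significant"] = out["pvalue"] < alpha
    return out


def select_seed_differential(
    results: pd.DataFrame | None,
    sites: pd.DataFrame,
    alpha: float = 0.05,
    sex_chromosomes: tuple[str, ...] = ("X", "Y"),
) -> pd.DataFrame:
    """Seed-region differential site table with per-pair significance counts.

    Keeps sites significant (p < alpha) in at least one stage pair,
    drops sex-chromosome sites, keeps seed-region sites, and tabulates
    in how many pairs each site is significant. When ``results`` is
    None or lacks p-values (a pre-selected table), all rows count as
    significant somewhere.
    """
    sites = sites.copy()
    if "seed" not in sites.columns and "position_in_mirna" in sites.columns:
        pos = pd.to_numeric(sites["position_in_mirna"], errors="coerce")
        sites["seed"] = (pos >= 2) & (pos <= 8)

    if results is not None and not results.empty and "pvalue" in results.columns:
        sig = results[results["pvalue"] < alpha]
        n_sig = sig.groupby("site_id").size()
        sites = sites[sites["site_id"].isin(n_sig.index)]
        sites["n_pairs_significant"] = sites["site_id"].map(n_sig).astype(int)
    else:
        sites["n_pairs_significant"] = pd.NA

    if "chromosome" in sites.columns:
        chrom = sites["chromosome"].astype(str).str.upper()
        sites = sites[~chrom.isin([c.upper() for c in sex_chromosomes])]
    return sites[sites["seed"].astype(bool)].reset_index(drop=True)


def simulate_null_rejection_rate(
    n_sites: int = 2000,
    n_per_group: int = 3,
    mean_level: float = 0.2,
    dispersion: float = 0.05,
    total_range: tuple[int, int] = (10, 200),
    alpha: float = 0.05,
    rng_seed: int = 0,
) -> dict:
    """Empirical type-I error of the LRT on null beta-binomial data.

    Two groups share the same mean; totals are uniform over
    ``total_range``. Returns the rejection fraction at ``alpha`` plus
    its Monte-Carlo standard error.
    """
    rng = np.random.default_rng(rng_seed)
    groups = np.array(["g1"] * n_per_group + ["g2"] * n_per_group)
    a = mean_level * (1 - dispersion) / dispersion
    b = (1 - mean_level) * (1 - dispersion) / dispersion
    rejected = 0
    tested = 0
    for _ in range(n_sites):
        n = rng.integers(total_range[0], total_range[1] + 1, size=2 * n_per_group)
        p = rng.beta(a, b, size=2 * n_per_group)
        k = rng.binomial(n, p)
        pval = DifferentialEditingModel(k, n, groups).fit().pvalue
        if np.isfinite(pval):
            tested += 1
            rejected += pval < alpha
    rate = rejected / tested if tested else np.nan
    return {
        "rate": rate,
        "n_tested": tested,
        "mc_se": float(np.sqrt(alpha * (1 - alpha) / tested)) if tested else np.nan,
    }


def count_by_editing_type(seed_table: pd.DataFrame) -> pd.Series:
    """Sites per editing type, largest class first."""
    return seed_table["editing_type"].value_counts()
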