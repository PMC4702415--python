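"""Genotype-expression association for read-count endpoints.

Expression endpoints are uniquely-mapped read counts (a gene's total, one
exon's, or one junction's reads) modelled with a negative-binomial
regression: log link, offset log(library size), genotype as an unordered
three-level factor, and sample covariates. The model reads

    log E[count] = log(library_size) + covariates + genotype

with NB2 dispersion estimated by maximum likelihood per model. The genotype
p-value is a likelihood-ratio test of the genotype term (Wald available).
The covariate set is chosen per endpoint by exhaustive subset search
minimizing BIC. Multiplicity is controlled with Bonferroni over the number
of endpoints times the effective number of independent SNPs (the
eigenvalue-based Li-Ji count, which collapses SNPs in strong linkage
disequilibrium), at an experiment-wise alpha of 0.2.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ExpressionEndpoint",
    "NbFit",
    "AssociationResult",
    "fit_nb_model",
    "select_covariates_bic",
    "effective_n_snps",
    "adjust",
    "associate",
]


@dataclass
class ExpressionEndpoint:
    """One expression read-count endpoint across samples."""

    endpoint_id: str
    counts: pd.Series  # non-negative integers, indexed by sample
    library_size: pd.Series  # positive, same index

    def __post_init__(self) -> None:
        if (self.counts.dropna() < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.library_size.dropna() <= 0).any():
            raise ValueError("library sizes must be positive")


@dataclass
class NbFit:
    endpoint_id: str
    p_genotype: float
    df_genotype: int
    coef_genotype: dict  # level -> log-scale coefficient vs baseline
    se_genotype: dict  # level -> Wald standard error of that coefficient
    lsmeans: dict  # genotype level -> predicted count at covariate means
    alpha: float  # NB2 dispersion
    llf: float
    bic: float
    nobs: int
    converged: bool
    covariates: tuple


class SingularDesignError(ValueError):
    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"design matrix is singular; collinear columns: {self.columns}")


def _check_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        # name the columns whose removal restores full rank
        bad = []
        for col in X.columns:
            sub = X.drop(columns=[col]).to_numpy(dtype=float)
            if np.linalg.matrix_rank(sub) == np.linalg.matrix_rank(mat):
                bad.append(col)
        raise SingularDesignError(bad or list(X.columns))


def _fit_nb(endog, exog, offset):
    model = sm.NegativeBinomial(endog, exog, offset=offset, loglike_method="nb2")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=500, method="bfgs", gtol=1e-7)
        except Exception:
            res = None
        if res is None or not res.mle_retvals.get("converged", False):
            try:
                res2 = model.fit(disp=0, maxiter=500, method="nm", xtol=1e-8, ftol=1e-8)
                if res is None or res2.llf > res.llf:
                    res = res2
            except Exception:
                pass
    if res is None:
        raise RuntimeError("negative-binomial fit failed")
    return res


def _design(
    covariates: Optional[pd.DataFrame],
    genotype: pd.Series,
    coding: str,
) -> tuple[pd.DataFrame, list]:
    parts = [pd.Series(1.0, index=genotype.index, name="const")]
    if covariates is not None and covariates.shape[1] > 0:
        parts.append(covariates.astype(float))
    X = pd.concat(parts, axis=1)
    levels = sorted(genotype.dropna().unique())
    if len(levels) < 2:
        raise ValueError("genotype must have at least two levels present")
    geno_cols = []
    if coding == "factor":
        for lvl in levels[1:]:
            col = f"geno_{lvl}"
            X[col] = (genotype == lvl).astype(float)
            geno_cols.append(col)
    elif coding == "additive":
        X["geno_add"] = genotype.astype(float)
        geno_cols.append("geno_add")
    else:
        raise ValueError(f"unknown genotype coding {coding!r}")
    return X, geno_cols


def fit_nb_model(
    endpoint: ExpressionEndpoint,
    covariates: Optional[pd.DataFrame],
    genotype: pd.Series,
    coding: str = "factor",
    test: str = "lrt",
) -> NbFit:
    """NB regression of one endpoint on genotype, with covariates and offset.

    Missing data are removed per model (complete-case). The genotype
    p-value is a likelihood-ratio chi-square comparing the model with and
    without the genotype term (df = number of genotype design columns), or a
    Wald joint test with ``test='wald'``.
    """
    frame = pd.DataFrame(
        {"_y": endpoint.counts, "_lib": endpoint.library_size, "_g": genotype}
    )
    if covariates is not None:
        frame = frame.join(covariates)
    frame = frame.dropna()
    if len(frame) < 10:
        raise ValueError(f"only {len(frame)} complete cases; need >= 10")
    cov = frame[covariates.columns] if covariates is not None else None
    X, geno_cols = _design(cov, frame["_g"], coding)
    _check_rank(X)
    offset = np.log(frame["_lib"].to_numpy(dtype=float))
    y = frame["_y"].to_numpy(dtype=float)

    res_full = _fit_nb(y, X.to_numpy(dtype=float), offset)
    X_red = X.drop(columns=geno_cols)
    res_red = _fit_nb(y, X_red.to_numpy(dtype=float), offset)

    df_g = len(geno_cols)
    if test == "lrt":
        lr = max(0.0, 2.0 * (res_full.llf - res_red.llf))
        p = float(stats.chi2.sf(lr, df_g))
    elif test == "wald":
        names = list(X.columns) + ["alpha"]
        idx = [names.index(c) for c in geno_cols]
        beta = res_full.params[idx]
        cov_b = res_full.cov_params()[np.ix_(idx, idx)]
        w = float(beta @ np.linalg.solve(cov_b, beta))
        p = float(stats.chi2.sf(w, df_g))
    else:
        raise ValueError(f"unknown test {test!r}")

    params = pd.Series(res_full.params[: X.shape[1]], index=X.columns)
    levels = sorted(frame["_g"].dropna().unique())
    # least-square means: covariates at their means, offset at mean log-library
    base = X.mean(axis=0)
    mean_offset = float(np.mean(offset))
    lsmeans = {}
    for lvl in levels:
        row = base.copy()
        for col in geno_cols:
            row[col] = 0.0
        if coding == "factor" and lvl != levels[0]:
            row[f"geno_{lvl}"] = 1.0
        if coding == "additive":
            row["geno_add"] = float(lvl)
        lsmeans[lvl] = float(np.exp(row @ params + mean_offset))
    bse = pd.Series(np.asarray(res_full.bse)[: X.shape[1]], index=X.columns)
    coef = {}
    se = {}
    if coding == "factor":
        for lvl in levels[1:]:
            coef[lvl] = float(params[f"geno_{lvl}"])
            se[lvl] = float(bse[f"geno_{lvl}"])
    else:
        coef["additive"] = float(params["geno_add"])
        se["additive"] = float(bse["geno_add"])

    k = X.shape[1] + 1  # + dispersion
    bic = -2.0 * res_full.llf + k * math.log(len(frame))
    return NbFit(
        endpoint_id=endpoint.endpoint_id,
        p_genotype=p,
        df_genotype=df_g,
        coef_genotype=coef,
        se_genotype=se,
        lsmeans=lsmeans,
        alpha=float(res_full.params[-1]),
        llf=float(res_full.llf),
        bic=float(bic),
        nobs=len(frame),
        converged=bool(res_full.mle_retvals.get("converged", True)),
        covariates=tuple(covariates.columns) if covariates is not None else (),
    )


def select_covariates_bic(
    endpoint: ExpressionEndpoint,
    candidates: pd.DataFrame,
    genotype: pd.Series,
    coding: str = "factor",
) -> tuple:
    """Exhaustive BIC covariate-subset search (SNP term always included).

    Every subset of candidate covariate columns is fitted; the subset with
    minimal BIC wins. Ties break toward the smaller subset, then
    lexicographically. Subsets whose fit fails are skipped. Returns
    (chosen column names, NbFit of the winning model).
    """
    cols = list(candidates.columns)
    best = None
    for r in range(len(cols) + 1):
        for subset in itertools.combinations(cols, r):
            sub = candidates[list(subset)] if subset else None
            try:
                fit = fit_nb_model(endpoint, sub, genotype, coding=coding)
            except (SingularDesignError, RuntimeError, ValueError):
                continue
            key = (fit.bic, len(subset), subset)
            if best is None or key < best[0]:
                best = (key, subset, fit)
    if best is None:
        raise RuntimeError("no covariate subset produced a successful fit")
    return best[1], best[2]


def effective_n_snps(genotypes: pd.DataFrame) -> float:
    """Effective number of independent SNPs (Li-Ji eigenvalue method).

    Eigenvalues of the SNP-SNP correlation matrix are mapped through
    f(lambda) = I(lambda >= 1) + (lambda - floor(lambda)) and summed, so a
    pair in perfect LD counts once and independent SNPs count fully.
    """
    g = genotypes.dropna()
    if g.shape[1] < 1:
        raise ValueError("need at least one SNP")
    stds = g.std(ddof=0)
    if (stds == 0).any():
        const = list(stds[stds == 0].index)
        raise ValueError(f"constant SNP column(s): {const}")
    if g.shape[1] == 1:
        return 1.0
    corr = np.corrcoef(g.to_numpy(dtype=float), rowvar=False)
    lam = np.linalg.eigvalsh(corr)
    lam = np.clip(lam, 0.0, None)
    eff = sum((1.0 if x >= 1.0 else 0.0) + (x - math.floor(x)) for x in lam)
    return float(min(eff, g.shape[1]))


def adjust(p_raw: float, n_endpoints: int, n_eff: float) -> float:
    """Bonferroni over endpoints x effective independent SNPs, capped at 1."""
    if n_endpoints < 1 or n_eff < 1:
        raise ValueError("n_endpoints and n_eff must be >= 1")
    return min(1.0, p_raw * n_endpoints * n_eff)


@dataclass
class AssociationResult:
    endpoint_id: str
    snp_id: str
    p_raw: float
    p_adjusted: float
    lsmeans: dict
    coef_genotype: dict
    selected_covariates: tuple
    nobs: int
    significant: bool


def associate(
    endpoints: Sequence[ExpressionEndpoint],
    candidates: pd.DataFrame,
    genotypes: pd.DataFrame,
    coding: str = "factor",
    alpha: float = 0.2,
) -> list:
    """Full association scan: every endpoint x every SNP, BIC-selected
    covariates, adjusted for endpoints x effective independent SNPs."""
    n_eff = effective_n_snps(genotypes)
    n_end = len(endpoints)
    out = []
    for ep in endpoints:
        for snp in genotypes.columns:
            chosen, fit = select_covariates_bic(ep, candidates, genotypes[snp], coding)
            p_adj = adjust(fit.p_genotype, n_end, n_eff)
            out.append(
                AssociationResult(
                    endpoint_id=ep.endpoint_id,
                    snp_id=snp,
                    p_raw=fit.p_genotype,
                    p_adjusted=p_adj,
                    lsmeans=fit.lsmeans,
                    coef_genotype=fit.coef_genotype,
                    selected_covariates=chosen,
                    nobs=fit.nobs,
                    significant=p_adj <= alpha,
                )
            )
    return out
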