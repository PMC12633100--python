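"""Surrogate-variable estimation and per-gene differential expression.

The default model is a Gaussian log-linear GLM: ordinary least squares on
``ln(normalized + 1)`` per gene against a shared design matrix (intercept,
condition indicator, surrogate variables, optional batch). Effects are
therefore natural-log fold-changes, and significance comes from a Wald test
on the condition coefficient with Benjamini-Hochberg FDR across genes.
A negative-binomial family (log link, per-gene dispersion) is available for
robustness studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GlmFit",
    "SignatureGeneSet",
    "design_matrix",
    "estimate_svs",
    "fit_glm",
    "wald_test",
    "bh_fdr",
    "de_table",
    "call_signature_genes",
]


@dataclass
class GlmFit:
    """Per-gene GLM fit against a shared design.

    ``beta`` and ``se`` are genes x variables (natural-log scale);
    ``residuals`` is the genes x samples matrix of log-scale residuals used
    for adjusted-count reconstruction; ``df_resid`` is the residual degrees
    of freedom of the Gaussian fit (``None`` for negative binomial, which
    uses a normal reference); ``dispersion`` holds per-gene NB dispersions
    when the family is ``negative_binomial``.
    """

    beta: pd.DataFrame
    se: pd.DataFrame
    residuals: pd.DataFrame
    design: pd.DataFrame
    family: str
    df_resid: int | None = None
    dispersion: pd.Series | None = None


@dataclass
class SignatureGeneSet:
    """Genes differentially expressed between disease and control.

    ``table`` is indexed by gene with columns ``lfc`` (natural-log
    fold-change disease vs control), ``q`` and ``direction`` in
    {``up``, ``down``}.
    """

    table: pd.DataFrame
    fdr_threshold: float = 0.10

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def direction(self, gene: str) -> str:
        return str(self.table.loc[gene, "direction"])


def design_matrix(
    condition: pd.Series,
    svs: pd.DataFrame | None = None,
    batch: pd.Series | None = None,
) -> pd.DataFrame:
    """Assemble a model matrix: intercept, 0/1 condition, SVs, batch dummies.

    ``condition`` is a boolean/0-1 series indexed by sample (1 = disease or
    treated group). Batch, if given, is encoded as treatment-coded dummies
    dropping the first level.
    """
    cols = {"intercept": pd.Series(1.0, index=condition.index)}
    cols["condition"] = condition.astype(float)
    out = pd.DataFrame(cols)
    if svs is not None:
        out = pd.concat([out, svs.loc[condition.index]], axis=1)
    if batch is not None:
        dummies = pd.get_dummies(batch.loc[condition.index], prefix="batch", drop_first=True)
        out = pd.concat([out, dummies.astype(float)], axis=1)
    return out


def _check_full_rank(design: pd.DataFrame) -> None:
    m = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(m)
    if rank < m.shape[1]:
        # Identify offending columns via the pivoted QR diagonal.
        _, r, piv = _qr_pivot(m)
        small = np.abs(np.diag(r)) < 1e-10 * max(1.0, np.abs(r[0, 0]))
        bad = [design.columns[piv[i]] for i in np.flatnonzero(small)]
        raise ValueError(f"design matrix is rank-deficient; collinear column(s): {bad}")


def _qr_pivot(m: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(m, pivoting=True, mode="economic")
    return q, r, piv


def estimate_svs(
    x: pd.DataFrame,
    primary_design: pd.DataFrame,
    k: int | str = "auto",
    n_perm: int = 100,
    seed: int = 0,
    quantile: float = 0.95,
) -> pd.DataFrame:
    """Estimate surrogate variables from residual expression.

    Log-transformed expression (``ln(x+1)``) is residualized against the
    primary design (which must exclude the latent factors being sought); the
    top-k right-singular vectors of the residual matrix are returned as
    per-sample scores. With ``k="auto"``, k is chosen by permutation
    parallel analysis: each gene's residuals are permuted across samples
    ``n_perm`` times, and k is the number of leading observed singular
    values exceeding the permutation ``quantile`` of the corresponding
    permuted singular value.

    Returns a samples x k frame with columns ``SV1..SVk`` (mean-centered);
    k may be 0, giving an empty frame.
    """
    m = primary_design.to_numpy(dtype=float)
    n_samples = x.shape[1]
    design_rank = np.linalg.matrix_rank(m)
    max_k = n_samples - design_rank - 1
    if isinstance(k, (int, np.integer)) and k > max_k:
        raise ValueError(f"k={k} too large: at most {max_k} SVs are estimable "
                         f"with {n_samples} samples and design rank {design_rank}")

    y = np.log1p(x.to_numpy(dtype=float))  # genes x samples
    beta, *_ = np.linalg.lstsq(m, y.T, rcond=None)
    resid = y - (m @ beta).T  # genes x samples

    s_obs = np.linalg.svd(resid, compute_uv=False)
    if k == "auto":
        # Buja-Eyuboglu-style permutation: permute each gene's values across
        # samples, then re-residualize against the design so the null
        # singular values live in the same projected subspace as s_obs.
        rng = np.random.default_rng(seed)
        hat = m @ np.linalg.pinv(m)
        n_vals = min(resid.shape)
        s_perm = np.empty((n_perm, n_vals))
        for p in range(n_perm):
            permuted = rng.permuted(y, axis=1)
            presid = permuted - permuted @ hat.T
            s_perm[p] = np.linalg.svd(presid, compute_uv=False)
        thresh = np.quantile(s_perm, quantile, axis=0)
        exceeds = s_obs > thresh
        k_sel = 0
        for flag in exceeds:
            if flag:
                k_sel += 1
            else:
                break
        k_sel = min(k_sel, max_k)
    else:
        k_sel = int(k)

    if k_sel <= 0:
        return pd.DataFrame(index=x.columns)
    _, _, vt = np.linalg.svd(resid, full_matrices=False)
    scores = vt[:k_sel].T
    scores = scores - scores.mean(axis=0)
    return pd.DataFrame(scores, index=x.columns,
                        columns=[f"SV{i + 1}" for i in range(k_sel)])


def fit_glm(x: pd.DataFrame, design: pd.DataFrame, family: str = "gaussian_log") -> GlmFit:
    """Fit the per-gene GLM for every gene against a shared design.

    gaussian_log
        OLS of ``ln(x+1)`` on the design, vectorized over genes. Residuals
        are on the natural-log response scale.
    negative_binomial
        Per-gene IRLS with log link; dispersion initialized by method of
        moments from a Poisson fit and refined by one numeric Newton step on
        the profile likelihood. ``x`` should then hold (normalized) counts.
    """
    if list(design.index) != list(x.columns):
        design = design.loc[x.columns]
    _check_full_rank(design)
    m = design.to_numpy(dtype=float)
    n, p = m.shape

    if family == "gaussian_log":
        y = np.log1p(x.to_numpy(dtype=float))  # genes x samples
        beta, *_ = np.linalg.lstsq(m, y.T, rcond=None)  # p x genes
        fitted = (m @ beta).T
        resid = y - fitted
        df = n - p
        if df <= 0:
            raise ValueError(f"no residual degrees of freedom (n={n}, p={p})")
        sigma2 = (resid ** 2).sum(axis=1) / df
        cov_diag = np.diag(np.linalg.inv(m.T @ m))
        se = np.sqrt(np.outer(sigma2, cov_diag))
        return GlmFit(
            beta=pd.DataFrame(beta.T, index=x.index, columns=design.columns),
            se=pd.DataFrame(se, index=x.index, columns=design.columns),
            residuals=pd.DataFrame(resid, index=x.index, columns=x.columns),
            design=design,
            family=family,
            df_resid=df,
        )
    if family == "negative_binomial":
        return _fit_nb(x, design)
    raise ValueError(f"unknown family {family!r}")


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    alpha = max(alpha, 1e-10)
    size = 1.0 / alpha
    prob = size / (size + mu)
    return float(stats.nbinom.logpmf(np.round(y).astype(int), size, prob).sum())


def _refine_alpha(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """One numeric Newton step on the profile log-likelihood in log-alpha."""
    la = np.log(alpha)
    h = 1e-4
    f = lambda v: _nb_loglik(y, mu, np.exp(v))
    g = (f(la + h) - f(la - h)) / (2 * h)
    hess = (f(la + h) - 2 * f(la) + f(la - h)) / h**2
    if hess < 0 and np.isfinite(g):
        la = la - g / hess
    return float(np.clip(np.exp(la), 1e-8, 100.0))


def _fit_nb(x: pd.DataFrame, design: pd.DataFrame) -> GlmFit:
    import statsmodels.api as sm

    m = design.to_numpy(dtype=float)
    betas, ses, resids, alphas = [], [], [], []
    for _, row in x.iterrows():
        y = row.to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pois = sm.GLM(y, m, family=sm.families.Poisson()).fit()
            mu0 = np.asarray(pois.fittedvalues)
            mom = ((y - mu0) ** 2 - mu0).sum() / max((mu0**2).sum(), 1e-12)
            alpha = float(np.clip(mom, 1e-8, 100.0))
            alpha = _refine_alpha(y, mu0, alpha)
            nb = sm.GLM(y, m, family=sm.families.NegativeBinomial(alpha=alpha)).fit()
        mu = np.asarray(nb.fittedvalues)
        betas.append(np.asarray(nb.params))
        ses.append(np.asarray(nb.bse))
        resids.append(np.log1p(y) - np.log1p(mu))
        alphas.append(alpha)
    return GlmFit(
        beta=pd.DataFrame(betas, index=x.index, columns=design.columns),
        se=pd.DataFrame(ses, index=x.index, columns=design.columns),
        residuals=pd.DataFrame(resids, index=x.index, columns=x.columns),
        design=design,
        family="negative_binomial",
        df_resid=None,
        dispersion=pd.Series(alphas, index=x.index, name="dispersion"),
    )


def wald_test(fit: GlmFit, variable: str) -> pd.DataFrame:
    """Wald test on one design variable for every gene.

    Returns a frame with columns ``lfc``, ``se``, ``z``, ``p``. For the
    Gaussian log-linear family the reference distribution is Student's t
    with the fit's residual degrees of freedom; the negative-binomial family
    uses the standard normal. Genes with SE = 0 get a missing p-value (with
    a warning) rather than a spurious zero.
    """
    if variable not in fit.beta.columns:
        raise KeyError(f"variable {variable!r} not in fit (has {list(fit.beta.columns)})")
    lfc = fit.beta[variable].to_numpy()
    se = fit.se[variable].to_numpy()
    zero_se = se == 0
    if zero_se.any():
        warnings.warn(f"{int(zero_se.sum())} gene(s) with SE=0; p reported as missing")
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(zero_se, np.nan, lfc / np.where(zero_se, np.nan, se))
    if fit.family == "gaussian_log":
        p = 2 * stats.t.sf(np.abs(z), df=fit.df_resid)
    else:
        p = 2 * stats.norm.sf(np.abs(z))
    p = np.where(zero_se, np.nan, p)
    return pd.DataFrame({"lfc": lfc, "se": se, "z": z, "p": p}, index=fit.beta.index)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone); NaNs pass through."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    vals = p[mask]
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if vals.size:
        out[mask] = multipletests(vals, method="fdr_bh")[1]
    return out


def de_table(fit: GlmFit, variable: str) -> pd.DataFrame:
    """Wald test plus BH q-values: columns ``lfc, se, z, p, q``."""
    de = wald_test(fit, variable)
    de["q"] = bh_fdr(de["p"].to_numpy())
    return de


def call_signature_genes(de: pd.DataFrame, fdr_threshold: float = 0.10) -> SignatureGeneSet:
    """Select signature genes at ``q < fdr_threshold`` and annotate direction."""
    hits = de[de["q"] < fdr_threshold].copy()
    hits["direction"] = np.where(hits["lfc"] > 0, "up", "down")
    return SignatureGeneSet(table=hits[["lfc", "q", "direction"]], fdr_threshold=fdr_threshold)
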