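"""ASO-screen statistics.

Normalized splice-junction quantification with group fold-changes,
intron-retention ratios and their identity-link group model, qPCR
2^(-dCT) relative expression, and constrained variable-slope dose-response
fitting with EC50 rank ordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from . import dge

__all__ = [
    "JunctionQuant",
    "GroupFoldChange",
    "DoseResponseFit",
    "quantify_junction",
    "group_fold_change",
    "ir_ratio",
    "ir_group_model",
    "ddct",
    "fit_ec50",
    "rank_asos",
]

BED_COLUMNS = ["chrom", "start", "end", "strand", "junction_id"]


@dataclass
class JunctionQuant:
    """Size-factor-normalized counts for one junction, with group means."""

    junction: str
    normalized: pd.Series
    group_means: pd.Series | None = None

    def fold(self, group: str, baseline: str) -> float:
        """Ratio of group means; NaN when the baseline mean is zero."""
        if self.group_means is None:
            raise ValueError("no grouping was supplied")
        b = self.group_means[baseline]
        return float(self.group_means[group] / b) if b > 0 else float("nan")


@dataclass
class GroupFoldChange:
    fc: float
    ci_low: float
    ci_high: float
    n_group: int
    n_baseline: int
    pseudocount_used: bool = False


@dataclass
class DoseResponseFit:
    """Constrained logistic fit y = 1 / (1 + (x/ec50)^hill), top=1, bottom=0."""

    ec50: float
    hill: float
    rss: float
    converged: bool
    boundary: bool = False


def quantify_junction(
    jt: pd.DataFrame,
    size_factors: pd.Series,
    junction: str,
    groups: pd.Series | None = None,
) -> JunctionQuant:
    """Per-sample normalized counts (count / size factor) for one junction.

    ``jt`` is a BED-like table (chrom, start, end, strand, junction_id, then
    one column per sample). ``groups`` optionally maps sample -> group label
    for group means.
    """
    hits = jt[jt["junction_id"] == junction]
    if len(hits) != 1:
        raise KeyError(f"junction {junction!r} not found (or duplicated) in table")
    sample_cols = [c for c in jt.columns if c not in BED_COLUMNS]
    counts = hits.iloc[0][sample_cols].astype(float)
    missing = [s for s in sample_cols if s not in size_factors.index]
    if missing:
        raise ValueError(f"no size factor for sample(s) {missing}")
    normalized = counts / size_factors[sample_cols]
    group_means = None
    if groups is not None:
        group_means = normalized.groupby(groups[sample_cols]).mean()
    return JunctionQuant(junction=junction, normalized=normalized, group_means=group_means)


def group_fold_change(
    values: pd.Series,
    groups: pd.Series,
    group: str,
    baseline: str,
    pseudocount: float = 0.5,
) -> GroupFoldChange:
    """Geometric-mean fold-change of ``group`` over ``baseline`` with 95% CI.

    Computed on the natural-log scale (difference of log means, Welch t
    interval, back-transformed), so the point estimate is a ratio of
    geometric means. When zeros are present, ``pseudocount`` is added to
    every value before taking logs (flagged in the result); a baseline whose
    values are all zero is undefined.
    """
    g = values[groups[values.index] == group].astype(float)
    b = values[groups[values.index] == baseline].astype(float)
    if len(g) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if (b == 0).all():
        raise ValueError("baseline group is all zero; fold-change undefined")
    used_pc = bool((g == 0).any() or (b == 0).any())
    offset = pseudocount if used_pc else 0.0
    lg = np.log(g + offset)
    lb = np.log(b + offset)
    d = lg.mean() - lb.mean()
    if len(g) >= 2 and len(b) >= 2:
        v1, v2 = lg.var(ddof=1) / len(g), lb.var(ddof=1) / len(b)
        se = np.sqrt(v1 + v2)
        if se > 0:
            df = (v1 + v2) ** 2 / (v1**2 / (len(g) - 1) + v2**2 / (len(b) - 1))
            half = stats.t.ppf(0.975, df) * se
        else:
            half = 0.0
        lo, hi = np.exp(d - half), np.exp(d + half)
    else:
        lo = hi = float("nan")
    return GroupFoldChange(fc=float(np.exp(d)), ci_low=float(lo), ci_high=float(hi),
                           n_group=len(g), n_baseline=len(b), pseudocount_used=used_pc)


def ir_ratio(intronic, spliced, convention: str = "bounded"):
    """Intron-retention ratio.

    ``bounded`` (default): intronic / (intronic + spliced), in [0, 1].
    ``simple``: intronic / spliced. Undefined (NaN) when both measures are
    zero (or, for ``simple``, when spliced is zero).
    Accepts scalars or arrays.
    """
    i = np.asarray(intronic, dtype=float)
    s = np.asarray(spliced, dtype=float)
    if (i < 0).any() or (s < 0).any():
        raise ValueError("read measures must be non-negative")
    with np.errstate(invalid="ignore", divide="ignore"):
        if convention == "bounded":
            out = np.where(i + s > 0, i / np.where(i + s > 0, i + s, 1.0), np.nan)
        elif convention == "simple":
            out = np.where(s > 0, i / np.where(s > 0, s, 1.0), np.nan)
        else:
            raise ValueError(f"unknown convention {convention!r}")
    if out.ndim == 0:
        return float(out)
    return out


def ir_group_model(ir: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    """Identity-link linear model of IR ratio on genotype and treatment.

    ``ir`` is introns x samples of defined ratios. Fits, per intron, an OLS
    of ratio on intercept + disease indicator + one dummy per non-"none"
    treatment, and returns a tidy frame (intron, term, effect, se, t, p).
    Zero-variance introns yield undefined p-values with a warning.
    """
    meta = sheet.set_index("sample_id").loc[ir.columns]
    design = pd.DataFrame({"intercept": 1.0}, index=ir.columns)
    design["genotype_XDP"] = (meta["genotype"] == "XDP").astype(float)
    for t in sorted(set(meta["treatment"]) - {"none"}):
        design[f"treatment_{t}"] = (meta["treatment"] == t).astype(float)
    m = design.to_numpy()
    n, p = m.shape
    y = ir.to_numpy(dtype=float)  # introns x samples
    beta, *_ = np.linalg.lstsq(m, y.T, rcond=None)
    resid = y - (m @ beta).T
    df = n - p
    if df <= 0:
        raise ValueError("not enough samples for the IR model")
    sigma2 = (resid**2).sum(axis=1) / df
    dust = 1e-20 * max(1.0, float(np.abs(y).max()) ** 2)
    sigma2 = np.where(sigma2 <= dust, 0.0, sigma2)
    if (sigma2 == 0).any():
        warnings.warn("intron(s) with zero residual variance; p undefined")
    cov_diag = np.diag(np.linalg.inv(m.T @ m))
    se = np.sqrt(np.outer(sigma2, cov_diag))
    rows = []
    for gi, intron in enumerate(ir.index):
        for vi, term in enumerate(design.columns):
            b, s = beta[vi, gi], se[gi, vi]
            tval = b / s if s > 0 else np.nan
            pval = 2 * stats.t.sf(abs(tval), df) if s > 0 else np.nan
            rows.append((intron, term, b, s, tval, pval))
    return pd.DataFrame(rows, columns=["intron", "term", "effect", "se", "t", "p"])


def ddct(ct_target: float, ct_housekeeping: float,
         reference_delta: float | None = None) -> float:
    """qPCR relative expression by 2^(-dCT).

    dCT = CT(target) - CT(housekeeping). With ``reference_delta`` (the dCT
    of a reference condition, e.g. untreated), the result is normalized to
    that condition: 2^-(dCT - dCT_ref).
    """
    delta = ct_target - ct_housekeeping
    if reference_delta is not None:
        delta -= reference_delta
    return float(2.0 ** (-delta))


def _logistic(conc: np.ndarray, log_ec50: float, log_hill: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(np.exp(log_hill) * (np.log(conc) - log_ec50)))


def fit_ec50(d: pd.DataFrame) -> DoseResponseFit:
    """Fit the constrained variable-slope dose-response curve.

    Least-squares fit of response = 1 / (1 + (x/ec50)^hill) with the top
    fixed at 1 and the bottom at 0 (responses are knockdown fractions
    normalized to the untreated level). Optimization runs on log(EC50) and
    log(hill) from a grid of starts (concentration quantiles x slope
    guesses); the best solution by residual sum of squares is kept. Fits
    landing far outside the assayed concentration range are flagged as
    boundary (non-converged): that is the signature of flat or non-monotone
    data.
    """
    conc = d["concentration"].to_numpy(dtype=float)
    resp = d["response"].to_numpy(dtype=float)
    if len(np.unique(conc)) < 3:
        raise ValueError("need at least 3 distinct concentrations")
    lo, hi = np.log(conc.min()), np.log(conc.max())
    starts = [(q, np.log(h))
              for q in np.quantile(np.log(conc), [0.25, 0.5, 0.75])
              for h in (0.5, 1.0, 2.0)]
    best = None
    for x0 in starts:
        try:
            res = least_squares(
                lambda th: _logistic(conc, th[0], th[1]) - resp,
                x0=np.array(x0), method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:
            continue
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[0] - 1e-15:
            best = (rss, res)
    if best is None:
        return DoseResponseFit(ec50=np.nan, hill=np.nan, rss=np.inf,
                               converged=False, boundary=True)
    rss, res = best
    log_ec50, log_hill = res.x
    # an EC50 more than 100x outside the assayed range is not supported by
    # the data (flat or non-monotone response)
    margin = np.log(100.0)
    boundary = bool(log_ec50 < lo - margin or log_ec50 > hi + margin)
    return DoseResponseFit(
        ec50=float(np.exp(log_ec50)),
        hill=float(np.exp(log_hill)),
        rss=rss,
        converged=bool(res.success and not boundary),
        boundary=boundary,
    )


def rank_asos(fits: dict[str, DoseResponseFit]) -> pd.DataFrame:
    """Rank treatments by ascending EC50.

    Ties break by lower residual sum of squares, then identifier;
    non-converged fits go last and are flagged.
    """
    rows = [(name, f.ec50, f.hill, f.rss, f.converged) for name, f in fits.items()]
    out = pd.DataFrame(rows, columns=["treatment", "ec50", "hill", "rss", "converged"])
    out["_sort_ec50"] = np.where(out["converged"], out["ec50"], np.inf)
    out = (out.sort_values(["converged", "_sort_ec50", "rss", "treatment"],
                           ascending=[False, True, True, True])
           .drop(columns="_sort_ec50").reset_index(drop=True))
    out.index = pd.RangeIndex(1, len(out) + 1, name="rank")
    return out
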