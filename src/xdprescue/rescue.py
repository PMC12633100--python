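"""Paired treatment-effect estimation and rescue/reversal classification.

The core of the analysis: reconstruct covariate-adjusted log expression
("adjusted counts") from a GLM fit, difference treated minus untreated
within clone pairs to obtain per-gene treatment effects with confidence
intervals, classify signature genes as rescued when their treated-vs-control
contrast is no longer distinguishable from zero, and test overlap between
rescued sets (or arbitrary gene sets) with one-tailed Fisher exact tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dge import GlmFit, SignatureGeneSet, bh_fdr

__all__ = [
    "SamplePair",
    "AdjustedCounts",
    "PairedEffect",
    "EnrichmentResult",
    "pairs_from_sheet",
    "adjusted_counts",
    "paired_effects",
    "call_rescued",
    "reversal",
    "overlap_enrichment",
    "geneset_enrichment",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SamplePair:
    """A treated library and its matched untreated library from one clone."""

    treatment: str
    treated: str
    untreated: str
    clone: str


@dataclass
class AdjustedCounts:
    """Natural-log expression with nuisance (dropped) covariates removed.

    ``y`` is genes x samples. ``keep_vars`` lists the design variables whose
    fitted contributions were retained; everything else (surrogate
    variables, batch terms) was subtracted out.
    """

    y: pd.DataFrame
    treatment: str
    keep_vars: tuple[str, ...]


@dataclass
class PairedEffect:
    """Per-gene paired treatment effect for one treatment.

    ``d`` is genes x pairs of within-clone log fold-changes
    (treated - untreated on the adjusted natural-log scale); ``mean`` is the
    arithmetic mean over pairs; ``ci_low``/``ci_high`` bound a t-based 95%
    interval (NaN when fewer than 2 pairs).
    """

    treatment: str
    d: pd.DataFrame
    mean: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    n_pairs: int


@dataclass
class EnrichmentResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p: float
    overlap_fraction: float
    correction: str = "none"
    p_adjusted: float | None = None


def pairs_from_sheet(sheet: pd.DataFrame, treatment: str) -> list[SamplePair]:
    """Build clone-level treated/untreated pairs for one treatment.

    A "treated" sample is either ``treatment == <treatment>`` or — for the
    CRISPR-edited comparator — ``edit_status == "dSVA"`` when ``treatment``
    is ``"dSVA"``. Its partner is the sample named by ``pair_id``.
    """
    s = sheet.set_index("sample_id", drop=False)
    if treatment == "dSVA":
        treated = s[s["edit_status"] == "dSVA"]
    else:
        treated = s[s["treatment"] == treatment]
    pairs = []
    for sid, row in treated.iterrows():
        partner = row.get("pair_id", "")
        if not isinstance(partner, str) or partner == "":
            continue
        if partner not in s.index:
            raise ValueError(f"pair_id {partner!r} of sample {sid!r} not in sheet")
        pairs.append(SamplePair(treatment=treatment, treated=str(sid),
                                untreated=str(partner), clone=str(row["subject_id"])))
    return pairs


def adjusted_counts(fit: GlmFit, keep_vars: list[str] | tuple[str, ...],
                    treatment: str = "") -> AdjustedCounts:
    """Reconstruct log expression keeping only the named design variables.

    Y = beta[:, keep] @ M[:, keep].T + R: the observed log expression minus
    the fitted contributions of every dropped variable. Because both beta
    and R live on the natural-log scale, this is exactly the
    exp-then-clamp-then-log reconstruction of covariate-corrected counts —
    the exponential is positive, so the clamp never binds and the identity
    form is used directly.
    """
    keep_vars = tuple(keep_vars)
    missing = [v for v in keep_vars if v not in fit.design.columns]
    if missing:
        raise ValueError(f"keep_vars not in design: {missing}")
    b = fit.beta[list(keep_vars)].to_numpy()
    m = fit.design[list(keep_vars)].to_numpy(dtype=float)
    y = b @ m.T + fit.residuals.to_numpy()
    return AdjustedCounts(
        y=pd.DataFrame(y, index=fit.beta.index, columns=fit.residuals.columns),
        treatment=treatment,
        keep_vars=keep_vars,
    )


def paired_effects(y: AdjustedCounts, pairs: list[SamplePair]) -> PairedEffect:
    """Within-pair log fold-changes and their per-gene mean with 95% CI.

    D[g, i] = Y[g, treated_i] - Y[g, untreated_i]. The CI is
    mean +/- t(0.975, n-1) * sd / sqrt(n) over pairs; with a single pair the
    mean is returned and the interval is marked unavailable (NaN).
    """
    if not pairs:
        raise ValueError("no sample pairs supplied")
    missing = [p.treated for p in pairs if p.treated not in y.y.columns]
    missing += [p.untreated for p in pairs if p.untreated not in y.y.columns]
    if missing:
        raise ValueError(f"pair sample(s) absent from adjusted counts: {sorted(set(missing))}")
    cols = {f"{p.treated}|{p.untreated}": y.y[p.treated] - y.y[p.untreated] for p in pairs}
    d = pd.DataFrame(cols)
    n = len(pairs)
    mean = d.mean(axis=1)
    if n >= 2:
        sd = d.std(axis=1, ddof=1)
        half = stats.t.ppf(0.975, df=n - 1) * sd / np.sqrt(n)
        lo, hi = mean - half, mean + half
    else:
        lo = pd.Series(np.nan, index=mean.index)
        hi = pd.Series(np.nan, index=mean.index)
    return PairedEffect(treatment=y.treatment, d=d, mean=mean,
                        ci_low=lo, ci_high=hi, n_pairs=n)


def call_rescued(
    signature: SignatureGeneSet,
    treated_vs_control: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Nominal rescue rule applied to each signature gene.

    A gene is rescued iff (1) it is a signature gene and (2) its
    treated-vs-control Wald z-test p exceeds ``alpha`` — i.e. the treated
    disease samples are no longer distinguishable from controls for that
    gene. Signature genes absent from ``treated_vs_control`` (e.g. filtered
    out of that comparison) are flagged unevaluable.

    Returns a frame indexed by signature gene with columns
    ``rescued`` (nullable boolean), ``evaluable``, ``lfc``, ``se``, ``z``,
    ``p`` (treated vs control) and ``xdp_direction``.
    """
    rows = []
    for gene in signature.genes:
        if gene in treated_vs_control.index:
            r = treated_vs_control.loc[gene]
            p = float(r["p"])
            rescued = bool(p > alpha) if np.isfinite(p) else pd.NA
            rows.append((gene, rescued, np.isfinite(p), r["lfc"], r["se"], r["z"], p))
        else:
            rows.append((gene, pd.NA, False, np.nan, np.nan, np.nan, np.nan))
    out = pd.DataFrame(
        rows, columns=["gene", "rescued", "evaluable", "lfc", "se", "z", "p"]
    ).set_index("gene")
    out["rescued"] = out["rescued"].astype("boolean")
    out["xdp_direction"] = signature.table["direction"]
    return out


def reversal(
    signature: SignatureGeneSet,
    effects: PairedEffect,
    rescue: pd.DataFrame,
) -> tuple[pd.Series, dict]:
    """Directional reversal among rescued genes.

    A rescued gene is reversed iff the sign of its mean paired treatment
    effect is opposite to the sign of its disease-vs-control fold-change.
    Genes with an exactly-zero mean effect are indeterminate and excluded
    from both numerator and denominator of the summary fraction.

    Returns (per-gene flags over rescued genes with values
    True/False/NA-indeterminate, summary dict with ``rescued``,
    ``reversed``, ``indeterminate`` counts and ``fraction``).
    """
    rescued_genes = rescue.index[rescue["rescued"].fillna(False).astype(bool)]
    xdp_lfc = signature.table.loc[rescued_genes, "lfc"]
    d_mean = effects.mean.reindex(rescued_genes)
    flags = pd.Series(pd.NA, index=rescued_genes, dtype="boolean", name="reversed")
    determinate = d_mean != 0
    flags[determinate] = np.sign(d_mean[determinate]) == -np.sign(xdp_lfc[determinate])
    n_rev = int(flags.fillna(False).sum())
    n_det = int(determinate.sum())
    summary = {
        "rescued": int(len(rescued_genes)),
        "reversed": n_rev,
        "indeterminate": int(len(rescued_genes) - n_det),
        "fraction": (n_rev / n_det) if n_det else np.nan,
    }
    return flags, summary


def _fisher_greater(table) -> tuple[float, float]:
    odds, p = stats.fisher_exact(np.asarray(table), alternative="greater")
    return float(odds), float(p)


def overlap_enrichment(set_a, set_b, universe) -> EnrichmentResult:
    """One-tailed Fisher exact test for overlap of two gene sets.

    Both sets must lie within ``universe``. The 2x2 table is
    [[|a&b|, |a-b|], [|b-a|, |universe-(a|b)|]] and the alternative is
    "greater" (over-enrichment). Also reports |a&b|/|a| as the overlap
    fraction (NaN for empty ``set_a``).
    """
    a, b, u = set(set_a), set(set_b), set(universe)
    if not a <= u or not b <= u:
        raise ValueError("gene sets must be subsets of the universe")
    n_ab = len(a & b)
    table = ((n_ab, len(a - b)), (len(b - a), len(u - (a | b))))
    odds, p = _fisher_greater(table)
    frac = n_ab / len(a) if a else np.nan
    return EnrichmentResult(table=table, odds_ratio=odds, p=p, overlap_fraction=frac)


def geneset_enrichment(
    hits,
    collection: dict,
    universe,
    correction: str = "bh",
) -> pd.DataFrame:
    """Per-term one-tailed Fisher enrichment of ``hits`` against a GMT collection.

    Terms are intersected with the universe first; terms empty after
    intersection are skipped (logged). ``correction`` is ``bonferroni`` or
    ``bh`` across the tested terms.
    """
    u = set(universe)
    if not u:
        raise ValueError("empty universe")
    h = set(hits) & u
    rows = []
    for term, genes in collection.items():
        t = set(genes) & u
        if not t:
            logger.info("term %s empty after intersecting with universe; skipped", term)
            continue
        n_ht = len(h & t)
        table = ((n_ht, len(h - t)), (len(t - h), len(u - (h | t))))
        odds, p = _fisher_greater(table)
        rows.append((term, len(t), n_ht, odds, p))
    out = pd.DataFrame(rows, columns=["term", "term_size", "overlap", "odds_ratio", "p"])
    out = out.set_index("term")
    if len(out):
        if correction == "bonferroni":
            out["p_adjusted"] = np.minimum(out["p"] * len(out), 1.0)
        elif correction == "bh":
            out["p_adjusted"] = bh_fdr(out["p"].to_numpy())
        else:
            raise ValueError(f"unknown correction {correction!r}")
    else:
        out["p_adjusted"] = []
    return out
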