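"""End-to-end rescue pipeline.

Chains the stages: CPM filter -> size-factor normalization -> PCA outlier
exclusion -> surrogate variables -> disease-vs-control GLM -> signature
calling -> per-treatment rescue (treated-vs-control z-test), paired
treatment effects and reversal -> overlap/gene-set enrichment -> optional
bootstrap reproducibility. All randomness flows from one root seed through
per-stage derived streams.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import bootstrap as bootstrap_mod
from . import dge, io, preprocess, rescue

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run; ``seed`` is mandatory."""

    seed: int
    cpm_threshold: float = 0.1
    cpm_fraction: float = 0.5
    fdr_threshold: float = 0.10
    alpha: float = 0.05
    n_pcs: int = 2
    sd_mult: float = 2.0
    exclude_outliers: bool = True
    sv_k: int | str = "auto"
    sv_n_perm: int = 100
    family: str = "gaussian_log"
    keep_vars: tuple = ("intercept", "condition")
    counts_path: str | None = None
    sheet_path: str | None = None
    gmt_path: str | None = None
    outdir: str | None = None
    bootstrap: bootstrap_mod.BootstrapConfig | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0 < self.cpm_fraction <= 1:
            raise ValueError("cpm_fraction must lie in (0, 1]")
        if not 0 < self.fdr_threshold < 1 or not 0 < self.alpha < 1:
            raise ValueError("fdr_threshold and alpha must lie in (0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load configuration from JSON or YAML; refuses configs without a seed."""
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        if "seed" not in raw:
            raise ValueError(f"{path}: config must set a seed")
        boot = raw.pop("bootstrap", None)
        cfg = cls(**{k: v for k, v in raw.items()})
        if boot is not None:
            if "seed" not in boot:
                raise ValueError(f"{path}: bootstrap enabled but no bootstrap seed given")
            cfg.bootstrap = bootstrap_mod.BootstrapConfig(**boot)
        return cfg


@dataclass
class PipelineResult:
    signature: dge.SignatureGeneSet
    de_table: pd.DataFrame
    size_factors: pd.Series
    outliers: list
    svs: pd.DataFrame
    rescue_tables: dict
    paired: dict
    adjusted: dict
    reversal_flags: dict
    overlap: dict
    enrichment: dict
    bootstrap_summary: object | None
    summary: dict


def _treatments_in(sheet: pd.DataFrame) -> list[str]:
    out = sorted(set(sheet["treatment"]) - {"none"})
    if (sheet["edit_status"] == "dSVA").any() and (
        sheet.loc[sheet["edit_status"] == "dSVA", "pair_id"] != ""
    ).any():
        out.append("dSVA")
    return out


def run_pipeline(
    cfg: PipelineConfig,
    counts: pd.DataFrame | None = None,
    sheet: pd.DataFrame | None = None,
    gene_sets: dict | None = None,
) -> PipelineResult:
    """Run the full rescue analysis; see module docstring for the stages."""
    if counts is None:
        if cfg.counts_path is None:
            raise ValueError("no counts given (in memory or via counts_path)")
        counts = io.read_counts(cfg.counts_path)
    if sheet is None:
        if cfg.sheet_path is None:
            raise ValueError("no sample sheet given (in memory or via sheet_path)")
        sheet = io.read_sample_sheet(cfg.sheet_path)
    else:
        sheet = io.validate_sample_sheet(sheet)
    if gene_sets is None and cfg.gmt_path is not None:
        gene_sets = io.read_gmt(cfg.gmt_path)

    root = np.random.SeedSequence(cfg.seed)
    stage_seeds = {name: int(s.generate_state(1)[0] % (2**31 - 1))
                   for name, s in zip(
                       ("sv_main", "sv_treat", "sv_pair", "bootstrap"), root.spawn(4))}

    meta = sheet.set_index("sample_id")
    untreated = meta[meta["treatment"] == "none"]
    con_ids = untreated.index[untreated["genotype"] == "CON"].tolist()
    xdp_ids = untreated.index[(untreated["genotype"] == "XDP")
                              & untreated["edit_status"].isin(["naive", "unedited"])].tolist()
    if not con_ids or not xdp_ids:
        raise ValueError("pipeline stage 'design': need untreated CON and XDP samples")

    # -- stage: filter on the disease-vs-control contrast -------------------
    base_ids = con_ids + xdp_ids
    filt = preprocess.cpm_filter(counts[base_ids], sheet[sheet["sample_id"].isin(base_ids)],
                                 threshold=cfg.cpm_threshold, fraction=cfg.cpm_fraction)
    retained = filt.retained

    # -- stage: size factors on the full matrix (all libraries) -------------
    size_factors = preprocess.compute_size_factors(counts.loc[retained])
    norm = preprocess.normalize(counts.loc[retained], size_factors)

    # -- stage: PCA outlier exclusion among the untreated pool --------------
    outliers: list[str] = []
    if cfg.exclude_outliers:
        outliers = list(preprocess.pca_outliers(norm[base_ids], n_pcs=cfg.n_pcs,
                                                sd_mult=cfg.sd_mult))
        if outliers:
            logger.info("excluding PCA outlier sample(s): %s", outliers)
        base_ids = [s for s in base_ids if s not in outliers]
        con_ids = [s for s in con_ids if s not in outliers]
        xdp_ids = [s for s in xdp_ids if s not in outliers]

    # -- stage: surrogate variables + disease-vs-control DE -----------------
    x_base = norm[base_ids]
    condition = pd.Series(
        [1.0 if s in set(xdp_ids) else 0.0 for s in base_ids], index=base_ids)
    svs = dge.estimate_svs(x_base, dge.design_matrix(condition), k=cfg.sv_k,
                           n_perm=cfg.sv_n_perm, seed=stage_seeds["sv_main"])
    design = dge.design_matrix(condition, svs=svs if svs.shape[1] else None)
    fit = dge.fit_glm(x_base, design, family=cfg.family)
    de = dge.de_table(fit, "condition")
    signature = dge.call_signature_genes(de, fdr_threshold=cfg.fdr_threshold)

    # -- stage: per-treatment rescue, paired effects, reversal --------------
    rescue_tables: dict[str, pd.DataFrame] = {}
    paired: dict[str, rescue.PairedEffect] = {}
    reversal_flags: dict[str, pd.Series] = {}
    reversal_summaries: dict[str, dict] = {}
    adjusted: dict[str, rescue.AdjustedCounts] = {}
    for t_num, treatment in enumerate(_treatments_in(sheet)):
        if treatment == "dSVA":
            treated_ids = meta.index[meta["edit_status"] == "dSVA"].tolist()
        else:
            treated_ids = meta.index[meta["treatment"] == treatment].tolist()
        treated_ids = [s for s in treated_ids if s not in outliers]
        if not treated_ids:
            continue

        # treated-XDP vs untreated-control z-test for the rescue rule
        tc_ids = treated_ids + con_ids
        x_tc = norm[tc_ids]
        cond_tc = pd.Series([1.0 if s in set(treated_ids) else 0.0 for s in tc_ids],
                            index=tc_ids)
        svs_tc = dge.estimate_svs(x_tc, dge.design_matrix(cond_tc), k=cfg.sv_k,
                                  n_perm=cfg.sv_n_perm,
                                  seed=stage_seeds["sv_treat"] + t_num)
        fit_tc = dge.fit_glm(x_tc, dge.design_matrix(
            cond_tc, svs=svs_tc if svs_tc.shape[1] else None), family=cfg.family)
        de_tc = dge.wald_test(fit_tc, "condition")
        rescue_tables[treatment] = rescue.call_rescued(signature, de_tc, alpha=cfg.alpha)

        # paired treated/untreated fit for adjusted counts and D
        pairs = rescue.pairs_from_sheet(sheet, treatment)
        pairs = [p for p in pairs
                 if p.treated not in outliers and p.untreated not in outliers]
        if not pairs:
            continue
        pair_ids = sorted({p.treated for p in pairs} | {p.untreated for p in pairs})
        x_pair = norm[pair_ids]
        cond_pair = pd.Series(
            [1.0 if s in {p.treated for p in pairs} else 0.0 for s in pair_ids],
            index=pair_ids)
        svs_pair = dge.estimate_svs(x_pair, dge.design_matrix(cond_pair), k=cfg.sv_k,
                                    n_perm=cfg.sv_n_perm,
                                    seed=stage_seeds["sv_pair"] + t_num)
        fit_pair = dge.fit_glm(x_pair, dge.design_matrix(
            cond_pair, svs=svs_pair if svs_pair.shape[1] else None), family=cfg.family)
        adj = rescue.adjusted_counts(fit_pair, cfg.keep_vars, treatment=treatment)
        adjusted[treatment] = adj
        eff = rescue.paired_effects(adj, pairs)
        paired[treatment] = eff
        flags, summ = rescue.reversal(signature, eff, rescue_tables[treatment])
        reversal_flags[treatment] = flags
        reversal_summaries[treatment] = summ

    # -- stage: overlap and gene-set enrichment ----------------------------
    overlap: dict[tuple, rescue.EnrichmentResult] = {}
    rescued_sets = {
        t: set(tab.index[tab["rescued"].fillna(False).astype(bool)])
        for t, tab in rescue_tables.items()
    }
    universe = set(signature.genes)
    names = sorted(rescued_sets)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            overlap[(a, b)] = rescue.overlap_enrichment(
                rescued_sets[a], rescued_sets[b], universe)
    enrichment: dict[str, pd.DataFrame] = {}
    if gene_sets:
        annotated = set().union(*gene_sets.values()) if gene_sets else set()
        enr_universe = annotated & set(de.index)
        for t, hits in rescued_sets.items():
            if enr_universe:
                enrichment[t] = rescue.geneset_enrichment(
                    hits & enr_universe, gene_sets, enr_universe, correction="bh")

    # -- stage: optional bootstrap ------------------------------------------
    boot_summary = None
    if cfg.bootstrap is not None:
        boot_summary = bootstrap_mod.run_bootstraps(counts, sheet, cfg.bootstrap)

    summary = {
        "seed": cfg.seed,
        "stage_seeds": stage_seeds,
        "thresholds": {"cpm": cfg.cpm_threshold, "fdr": cfg.fdr_threshold,
                       "alpha": cfg.alpha, "sd_mult": cfg.sd_mult},
        "n_genes_input": int(counts.shape[0]),
        "n_genes_tested": int(len(retained)),
        "n_svs": int(svs.shape[1]),
        "outliers": list(outliers),
        "n_signature": int(len(signature.genes)),
        "n_signature_up": int((signature.table["direction"] == "up").sum()),
        "n_signature_down": int((signature.table["direction"] == "down").sum()),
        "rescued": {t: int(len(s)) for t, s in rescued_sets.items()},
        "reversal": reversal_summaries,
    }
    _check_consistency(summary)

    result = PipelineResult(
        signature=signature, de_table=de, size_factors=size_factors,
        outliers=list(outliers), svs=svs, rescue_tables=rescue_tables,
        paired=paired, adjusted=adjusted, reversal_flags=reversal_flags, overlap=overlap,
        enrichment=enrichment, bootstrap_summary=boot_summary, summary=summary,
    )
    if cfg.outdir is not None:
        _write_outputs(result, cfg)
    return result


def _check_consistency(summary: dict) -> None:
    n_sig, n_tested = summary["n_signature"], summary["n_genes_tested"]
    assert n_sig <= n_tested
    for t, n_resc in summary["rescued"].items():
        assert n_resc <= n_sig, (t, n_resc, n_sig)
        rev = summary["reversal"].get(t)
        if rev is not None:
            assert rev["reversed"] <= rev["rescued"] <= n_sig


def _write_outputs(result: PipelineResult, cfg: PipelineConfig) -> None:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.de_table.to_csv(out / "de_table.tsv", sep="\t")
    result.signature.table.to_csv(out / "signature_genes.tsv", sep="\t")
    result.size_factors.to_csv(out / "size_factors.tsv", sep="\t")
    for t, tab in result.rescue_tables.items():
        tab.to_csv(out / f"rescue_{t}.tsv", sep="\t")
    for t, eff in result.paired.items():
        frame = pd.DataFrame({"mean_d": eff.mean, "ci_low": eff.ci_low,
                              "ci_high": eff.ci_high})
        frame.to_csv(out / f"paired_effects_{t}.tsv", sep="\t")
    for t, tab in result.enrichment.items():
        tab.to_csv(out / f"enrichment_{t}.tsv", sep="\t")
    if result.bootstrap_summary is not None:
        result.bootstrap_summary.table.to_csv(out / "bootstrap_summary.tsv", sep="\t")
    (out / "summary.json").write_text(json.dumps(result.summary, indent=2, sort_keys=True))
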