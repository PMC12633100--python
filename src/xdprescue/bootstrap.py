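"""Balanced-subsample reproducibility of differential-expression calls.

Each bootstrap draws a balanced subset of untreated samples (default 6
controls and 6 disease, without replacement), reruns the full DE workflow
— CPM filter, size factors, surrogate-variable estimation, GLM, Wald test,
BH correction within the bootstrap — and accumulates per-gene frequencies:
how often the gene passes the filter, is called up/down, and is significant
at p and FDR thresholds in each direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import dge, preprocess

__all__ = ["BootstrapConfig", "BootstrapSummary", "run_bootstraps", "summarize_gene"]


@dataclass
class BootstrapConfig:
    n_boot: int = 200
    n_per_group: int = 6
    seed: int = 0
    fdr_threshold: float = 0.10
    p_threshold: float = 0.05
    cpm_threshold: float = 0.1
    cpm_fraction: float = 0.5
    sv_k: int | str = "auto"
    sv_n_perm: int = 50


@dataclass
class BootstrapSummary:
    """Per-gene bootstrap frequencies.

    ``table`` is indexed by gene with columns: ``f_filter`` (fraction of
    bootstraps passing the CPM filter, over all bootstraps) and — as
    fractions of the passing bootstraps — ``f_down``, ``f_up``,
    ``f_sig_p_down``, ``f_sig_p_up``, ``f_sig_fdr_down``, ``f_sig_fdr_up``.
    Direction fractions are NaN for genes never passing the filter.
    """

    table: pd.DataFrame
    n_boot_run: int
    config: BootstrapConfig


def _de_on_subset(counts: pd.DataFrame, sub_sheet: pd.DataFrame,
                  cfg: BootstrapConfig, sv_seed: int) -> pd.DataFrame:
    """One full DE pass (filter/normalize/SV/GLM/Wald/BH) on a sample subset."""
    keep = preprocess.cpm_filter(
        counts, sub_sheet, threshold=cfg.cpm_threshold, fraction=cfg.cpm_fraction
    ).retained
    sub = counts.loc[keep]
    factors = preprocess.compute_size_factors(sub)
    norm = preprocess.normalize(sub, factors)
    condition = (sub_sheet.set_index("sample_id")
                 .loc[norm.columns, "genotype"] == "XDP").astype(float)
    base = dge.design_matrix(condition)
    svs = dge.estimate_svs(norm, base, k=cfg.sv_k, n_perm=cfg.sv_n_perm, seed=sv_seed)
    design = dge.design_matrix(condition, svs=svs if svs.shape[1] else None)
    fit = dge.fit_glm(norm, design, family="gaussian_log")
    return dge.de_table(fit, "condition")


def run_bootstraps(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    cfg: BootstrapConfig,
    subsets: list[tuple[list, list]] | None = None,
) -> BootstrapSummary:
    """Run the balanced-subsample engine.

    ``subsets`` injects explicit (control_ids, disease_ids) lists — one per
    bootstrap — replacing the random draw; used to verify the engine adds no
    computation beyond repeated direct DE runs.
    """
    meta = sheet.set_index("sample_id")
    untreated = meta[meta["treatment"] == "none"]
    con = untreated.index[(untreated["genotype"] == "CON")].tolist()
    xdp = untreated.index[(untreated["genotype"] == "XDP")
                          & untreated["edit_status"].isin(["naive", "unedited"])].tolist()
    if subsets is None:
        if len(con) < cfg.n_per_group or len(xdp) < cfg.n_per_group:
            raise ValueError(
                f"need >= {cfg.n_per_group} untreated samples per genotype "
                f"(have {len(con)} CON, {len(xdp)} XDP)")
        ss = np.random.SeedSequence(cfg.seed)
        draw_rng = np.random.default_rng(ss.spawn(1)[0])
        subsets = []
        for _ in range(cfg.n_boot):
            c = list(draw_rng.choice(con, size=cfg.n_per_group, replace=False))
            x = list(draw_rng.choice(xdp, size=cfg.n_per_group, replace=False))
            subsets.append((c, x))
        sv_seeds = draw_rng.integers(0, 2**31 - 1, size=cfg.n_boot)
    else:
        sv_seeds = np.random.default_rng(cfg.seed).integers(0, 2**31 - 1, size=len(subsets))

    genes = counts.index
    zeros = lambda: pd.Series(0, index=genes, dtype=float)
    n_pass, n_down, n_up = zeros(), zeros(), zeros()
    n_sp_down, n_sp_up, n_sf_down, n_sf_up = zeros(), zeros(), zeros(), zeros()

    for b, (c_ids, x_ids) in enumerate(subsets):
        ids = list(c_ids) + list(x_ids)
        sub_sheet = sheet[sheet["sample_id"].isin(ids)]
        de = _de_on_subset(counts[ids], sub_sheet, cfg, int(sv_seeds[b]))
        tested = de.index
        n_pass[tested] += 1
        down = de["lfc"] < 0
        up = de["lfc"] > 0
        n_down[tested[down]] += 1
        n_up[tested[up]] += 1
        sig_p = de["p"] < cfg.p_threshold
        sig_f = de["q"] < cfg.fdr_threshold
        n_sp_down[tested[down & sig_p]] += 1
        n_sp_up[tested[up & sig_p]] += 1
        n_sf_down[tested[down & sig_f]] += 1
        n_sf_up[tested[up & sig_f]] += 1

    n_boot = len(subsets)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = n_pass.replace(0, np.nan)
        table = pd.DataFrame({
            "f_filter": n_pass / n_boot,
            "f_down": n_down / denom,
            "f_up": n_up / denom,
            "f_sig_p_down": n_sp_down / denom,
            "f_sig_p_up": n_sp_up / denom,
            "f_sig_fdr_down": n_sf_down / denom,
            "f_sig_fdr_up": n_sf_up / denom,
        })
    return BootstrapSummary(table=table, n_boot_run=n_boot, config=cfg)


def summarize_gene(summary: BootstrapSummary, gene: str) -> dict:
    """Frequency record for one gene.

    Besides the raw per-direction frequencies, reports ``f_sig_p`` and
    ``f_sig_fdr`` for the gene's dominant direction (the more frequent of
    up/down across passing bootstraps).
    """
    if gene not in summary.table.index:
        raise KeyError(f"gene {gene!r} not in bootstrap summary")
    row = summary.table.loc[gene]
    rec = row.to_dict()
    rec["n_boot_run"] = summary.n_boot_run
    if np.isnan(row["f_down"]):
        rec["f_sig_p"] = np.nan
        rec["f_sig_fdr"] = np.nan
    else:
        direction = "down" if row["f_down"] >= row["f_up"] else "up"
        rec["f_sig_p"] = row[f"f_sig_p_{direction}"]
        rec["f_sig_fdr"] = row[f"f_sig_fdr_{direction}"]
        rec["dominant_direction"] = direction
    return rec
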