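"""Synthetic data with known ground truth.

Emulates the neural-stem-cell experiment the analysis was designed for:
negative-binomial gene counts over controls, disease (XDP) clones carrying
the causal insertion, CRISPR-edited (dSVA) clones, and per-clone treated
libraries for a panel of antisense oligonucleotides — with genotype,
treatment, batch and latent-factor structure on the natural-log mean scale.
Also generates the disease-exclusive splice-junction count table and
dose-response curves for the EC50 screen.

Default group sizes follow the experiment: 8 controls, 9 naive + 21
unedited disease clones, 30 edited (dSVA) clones, and seven ASO treatments
applied to every disease clone. Counts use a gamma-Poisson draw so that
Var = mu + dispersion * mu^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_experiment",
    "simulate_junction_counts",
    "simulate_dose_response",
    "DEFAULT_GROUP_SIZES",
    "DEFAULT_TREATMENTS",
]

DEFAULT_GROUP_SIZES: dict[tuple[str, str], int] = {
    ("CON", "none"): 8,
    ("XDP", "naive"): 9,
    ("XDP", "unedited"): 21,
    ("XDP", "dSVA"): 30,
}

DEFAULT_TREATMENTS: tuple[str, ...] = tuple(f"ASO{i:02d}" for i in range(1, 8))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic experiment.

    Effects are on the natural-log scale. Genotype effect magnitudes are
    drawn as ``effect_size_loc + |N(0, effect_size_scale)|`` with random
    sign, so the default guarantees effects of at least one ln-unit.
    ``frac_rescued`` of signature genes have a treatment effect that exactly
    cancels the genotype effect; ``frac_partial`` cancel half of it; the
    rest are untouched by treatment. Latent confounders enter additively on
    the log-mean with Gaussian scores, matching the surrogate-variable model
    fitted downstream.
    """

    n_genes: int = 2000
    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    treatments: tuple = DEFAULT_TREATMENTS
    frac_signature: float = 0.20
    frac_rescued: float = 0.30
    frac_partial: float = 0.0
    effect_size_loc: float = 1.0
    effect_size_scale: float = 0.25
    dispersion: float = 0.05
    n_latent: int = 2
    latent_scale: float = 0.2
    baseline_meanlog: float = 4.0
    baseline_sdlog: float = 1.5
    n_batches: int = 2
    batch_sd: float = 0.1
    libsize_sdlog: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_signature", "frac_rescued", "frac_partial"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if self.frac_rescued + self.frac_partial > 1.0 + 1e-12:
            raise ValueError("frac_rescued + frac_partial must not exceed 1")
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 0")
        n_con = sum(n for (g, _), n in self.group_sizes.items() if g == "CON")
        n_xdp = sum(n for (g, e), n in self.group_sizes.items()
                    if g == "XDP" and e in ("naive", "unedited"))
        if n_con == 0 or n_xdp == 0:
            raise ValueError("need at least one control and one unedited/naive "
                             "disease sample")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated experiment.

    ``genotype_effect``: per-gene disease log-effect (0 off signature).
    ``treatment_effect``: genes x treatments log-effects (includes a
    ``dSVA`` column when edited clones are simulated: editing acts like a
    clone-level treatment through the same rescue labels).
    ``rescue_label``: rescued / partial / unrescued / non-signature.
    ``latent_loadings`` (genes x k) and ``latent_scores`` (samples x k).
    """

    genotype_effect: pd.Series
    treatment_effect: pd.DataFrame
    rescue_label: pd.Series
    latent_loadings: pd.DataFrame
    latent_scores: pd.DataFrame


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with Var = mu + dispersion * mu^2 (Poisson at 0)."""
    mu = np.asarray(mu, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam)


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate counts, sample sheet, and ground truth.

    Returns ``(counts, sheet, truth)``: genes x samples integer counts; a
    sheet with columns sample_id, subject_id, genotype, edit_status,
    treatment, pair_id, batch; and the :class:`SyntheticTruth`.

    Each untreated disease clone contributes one untreated library plus one
    library per treatment (paired within clone via ``pair_id``); edited
    (dSVA) clones are matched to unedited clones of the same subject when
    possible so the CRISPR comparison is paired too.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes = pd.Index([f"g{i + 1:05d}" for i in range(cfg.n_genes)], name="gene")

    # --- gene-level truth -------------------------------------------------
    baseline = rng.normal(cfg.baseline_meanlog, cfg.baseline_sdlog, cfg.n_genes)
    n_sig = int(round(cfg.frac_signature * cfg.n_genes))
    sig_idx = rng.choice(cfg.n_genes, size=n_sig, replace=False)
    magnitude = cfg.effect_size_loc + np.abs(rng.normal(0.0, cfg.effect_size_scale, n_sig))
    sign = rng.choice([-1.0, 1.0], size=n_sig)
    geno = np.zeros(cfg.n_genes)
    geno[sig_idx] = magnitude * sign

    label = np.full(cfg.n_genes, "non-signature", dtype=object)
    n_resc = int(round(cfg.frac_rescued * n_sig))
    n_part = int(round(cfg.frac_partial * n_sig))
    shuffled = rng.permutation(sig_idx)
    label[shuffled[:n_resc]] = "rescued"
    label[shuffled[n_resc:n_resc + n_part]] = "partial"
    label[shuffled[n_resc + n_part:]] = "unrescued"

    cancel = np.zeros(cfg.n_genes)
    cancel[label == "rescued"] = -1.0
    cancel[label == "partial"] = -0.5
    per_treatment_effect = cancel * geno

    # --- samples ----------------------------------------------------------
    records = []  # sample_id, subject_id, genotype, edit_status, treatment, pair_id

    def add(sample_id, subject, genotype, edit, treatment, pair_id):
        records.append((sample_id, subject, genotype, edit, treatment, pair_id))

    n_con = cfg.group_sizes.get(("CON", "none"), 0)
    for i in range(n_con):
        add(f"CON{i + 1:02d}", f"conS{i + 1:02d}", "CON", "none", "none", "")

    xdp_untreated: list[tuple[str, str, str]] = []  # (sample_id, subject, edit)
    for edit in ("naive", "unedited"):
        for i in range(cfg.group_sizes.get(("XDP", edit), 0)):
            sid = f"XDP_{edit[:2]}{i + 1:02d}"
            subj = f"xdpS_{edit[:2]}{i + 1:02d}"
            add(sid, subj, "XDP", edit, "none", "")
            xdp_untreated.append((sid, subj, edit))

    for j in cfg.treatments:
        for sid, subj, edit in xdp_untreated:
            add(f"{sid}_{j}", subj, "XDP", edit, j, sid)

    unedited_ids = [sid for sid, _, edit in xdp_untreated if edit == "unedited"]
    n_dsva = cfg.group_sizes.get(("XDP", "dSVA"), 0)
    for i in range(n_dsva):
        partner = unedited_ids[i % len(unedited_ids)] if unedited_ids else ""
        subj = (f"xdpS_un{(i % len(unedited_ids)) + 1:02d}"
                if unedited_ids else f"xdpS_ds{i + 1:02d}")
        add(f"XDP_ds{i + 1:02d}", subj, "XDP", "dSVA", "none", partner)

    sheet = pd.DataFrame(
        records,
        columns=["sample_id", "subject_id", "genotype", "edit_status", "treatment", "pair_id"],
    )
    sheet["batch"] = [f"b{i % cfg.n_batches + 1}" for i in range(len(sheet))]
    samples = pd.Index(sheet["sample_id"], name="sample")

    # --- log-mean assembly -------------------------------------------------
    n_samples = len(sheet)
    loadings = rng.normal(0.0, cfg.latent_scale, (cfg.n_genes, cfg.n_latent))
    # Latent confounders are clone-level (culture/line state): all libraries
    # of a subject share one score vector, so the paired design cancels them.
    subjects = sheet["subject_id"].unique()
    subject_scores = {s: rng.normal(0.0, 1.0, cfg.n_latent) for s in subjects}
    scores = np.vstack([subject_scores[s] for s in sheet["subject_id"]])
    batch_levels = sorted(sheet["batch"].unique())
    batch_effect = rng.normal(0.0, cfg.batch_sd, (cfg.n_genes, len(batch_levels)))
    batch_col = {b: k for k, b in enumerate(batch_levels)}
    lib_factor = np.exp(rng.normal(0.0, cfg.libsize_sdlog, n_samples))

    has_sva = ((sheet["genotype"] == "XDP")
               & sheet["edit_status"].isin(["naive", "unedited"])).to_numpy()
    is_dsva = (sheet["edit_status"] == "dSVA").to_numpy()
    treatment = sheet["treatment"].to_numpy()

    log_mu = np.repeat(baseline[:, None], n_samples, axis=1)
    for s in range(n_samples):
        if has_sva[s]:
            log_mu[:, s] += geno
            if treatment[s] != "none":
                log_mu[:, s] += per_treatment_effect
        elif is_dsva[s]:
            # Editing removes the insertion: acts through the rescue labels.
            log_mu[:, s] += geno + per_treatment_effect
        log_mu[:, s] += loadings @ scores[s]
        log_mu[:, s] += batch_effect[:, batch_col[sheet["batch"].iloc[s]]]
        log_mu[:, s] += np.log(lib_factor[s])

    counts = _nb_draw(rng, np.exp(log_mu), cfg.dispersion)
    counts = pd.DataFrame(counts, index=genes, columns=samples)

    treat_cols = list(cfg.treatments) + (["dSVA"] if n_dsva else [])
    treatment_effect = pd.DataFrame(
        {t: per_treatment_effect for t in treat_cols}, index=genes
    )
    truth = SyntheticTruth(
        genotype_effect=pd.Series(geno, index=genes, name="genotype_effect"),
        treatment_effect=treatment_effect,
        rescue_label=pd.Series(label, index=genes, name="rescue_label"),
        latent_loadings=pd.DataFrame(
            loadings, index=genes, columns=[f"L{k + 1}" for k in range(cfg.n_latent)]
        ),
        latent_scores=pd.DataFrame(
            scores, index=samples, columns=[f"L{k + 1}" for k in range(cfg.n_latent)]
        ),
    )
    return counts, sheet, truth


def simulate_junction_counts(
    sheet: pd.DataFrame,
    xdp_mean: float = 425.4,
    control_mean: float = 2.3,
    dsva_fc: float = 0.016,
    dispersion: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the disease-exclusive splice-junction count table.

    Untreated disease samples (insertion present) draw from a negative
    binomial with mean ``xdp_mean``; controls from ``control_mean``; edited
    (dSVA) samples from ``xdp_mean * dsva_fc``. The defaults reproduce the
    reported group means of the disease-specific junction (425.4 vs 2.3
    normalized counts, edited fold-change 0.016).

    Returns a BED-like table: chrom, start, end, strand, junction_id,
    then one count column per sample.
    """
    for name, v in (("xdp_mean", xdp_mean), ("control_mean", control_mean),
                    ("dsva_fc", dsva_fc)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = np.random.default_rng(seed)
    means = np.empty(len(sheet))
    for i, row in enumerate(sheet.itertuples(index=False)):
        if row.edit_status == "dSVA":
            means[i] = xdp_mean * dsva_fc
        elif row.genotype == "XDP":
            means[i] = xdp_mean
        else:
            means[i] = control_mean
    draws = np.where(means > 0, _nb_draw(rng, np.maximum(means, 1e-300), dispersion), 0)
    rec = {"chrom": "chrX", "start": 70659100, "end": 70660300,
           "strand": "+", "junction_id": "AS-i32"}
    out = pd.DataFrame([rec])
    for sid, c in zip(sheet["sample_id"], draws):
        out[sid] = int(c)
    return out


def simulate_dose_response(
    ec50: float,
    hill: float,
    concentrations,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 6,
) -> pd.DataFrame:
    """Simulate normalized knockdown responses on a decreasing logistic.

    response = 1 / (1 + (x / ec50)^hill) + N(0, noise_sd), truncated to
    [0, 1.5]; the untreated level is 1 and complete knockdown is 0.
    ``n_replicates`` independent measurements are drawn per concentration;
    the default of 6 reflects the screen's assay design of two patient cell
    lines each measured in qPCR technical triplicate.

    Returns a frame with columns ``concentration``, ``replicate``,
    ``response``.
    """
    if ec50 <= 0 or hill <= 0:
        raise ValueError("ec50 and hill must be positive")
    conc = np.asarray(list(concentrations), dtype=float)
    if conc.size == 0:
        raise ValueError("concentrations must be non-empty")
    if (conc <= 0).any():
        raise ValueError("concentrations must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for x in conc:
        y0 = 1.0 / (1.0 + (x / ec50) ** hill)
        for r in range(n_replicates):
            y = y0 + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append((x, r + 1, float(np.clip(y, 0.0, 1.5))))
    return pd.DataFrame(rows, columns=["concentration", "replicate", "response"])
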