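"""Synthetic cohorts with planted sex effects.

The generator emulates the four inputs the pipeline consumes — an
FPKM-scale expression matrix, MAF-like mutation records, a clinical table
and the cell-signature gene sets — with ground truth for every planted
effect:

* Each patient carries latent per-cell abundances (log-normal; the Gaussian
  log-abundance has unit variance, and female means can be shifted per
  cell).  Cell-signature genes respond linearly in log2-expression to the
  log-abundance of their cell; a separate stromal latent drives a stromal
  signature block.
* Non-silent mutations are per-gene Bernoulli draws whose per-patient rate
  factor is coupled to the latent immune abundance through a Gaussian
  copula, so the within-sex TMB-immune correlation can be set directly.
  Independent silent records exercise the non-silent filters.
* Survival times are exponential with hazard proportional to
  ``exp(sum_k gamma_k * L_k)``; uniform censoring is tuned to a target
  censoring fraction.  Immunotherapy response is Bernoulli in a logistic
  model on TMB with per-sex slopes.

Signatures are mutually disjoint by construction so that recovery can be
attributed unambiguously; real marker signatures overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .readwrite import GeneSetCollection

NON_SILENT_CHOICES = (
    "Missense_Mutation", "Nonsense_Mutation", "Splice_Site",
    "Frame_Shift_Del", "Frame_Shift_Ins", "In_Frame_Del", "In_Frame_Ins",
    "Nonstop_Mutation", "Translation_Start_Site",
)
NON_SILENT_PROBS = (0.65, 0.11, 0.06, 0.05, 0.05, 0.03, 0.02, 0.015, 0.015)


class ConfigError(ValueError):
    """Infeasible simulation configuration."""


@dataclass
class SimulationConfig:
    """Study conditions for one simulated cohort.

    Effects default to zero (a null cohort); planted effects are supplied
    through the mapping fields.  ``sex_cell_effects`` shifts the female
    mean of a cell's Gaussian log-abundance (units: latent SD);
    ``tmb_tme_corr`` sets the within-sex Gaussian-copula correlation
    between the latent immune abundance and the mutation-rate factor;
    ``hazard_gammas`` are log-hazard coefficients per latent-abundance SD;
    ``icb_tmb_effect`` is the log-odds of response per TMB unit, per sex.
    """

    seed: int = 0
    n_male: int = 100
    n_female: int = 100
    n_genes: int = 1000
    n_cells: int = 24
    genes_per_signature: int = 30
    n_stromal_genes: int = 50
    signature_effect: float = 1.0
    expression_noise_sd: float = 0.5
    baseline_mean: float = 3.0
    baseline_sd: float = 1.5
    zero_quantile: float = 0.05
    sex_cell_effects: dict = field(default_factory=dict)
    sex_stromal_effect: float = 0.0
    n_mutation_genes: int = 300
    background_mutation_rate: float = 0.08
    silent_mutation_rate: float = 0.01
    sex_mutation_rates: dict = field(default_factory=dict)
    mutation_dispersion: float = 0.8
    tmb_tme_corr: dict = field(default_factory=lambda: {"male": 0.0, "female": 0.0})
    hazard_gammas: dict = field(default_factory=dict)
    baseline_hazard: float = 1.0 / 1500.0
    censor_fraction: float = 0.3
    icb_intercept: float = -1.0
    icb_tmb_effect: dict = field(default_factory=lambda: {"male": 0.3, "female": 0.8})

    def validate(self) -> None:
        if min(self.n_male, self.n_female, self.n_genes, self.n_cells,
               self.genes_per_signature, self.n_mutation_genes) <= 0:
            raise ConfigError("counts must be positive")
        needed = self.n_cells * self.genes_per_signature + self.n_stromal_genes
        if needed >= self.n_genes:
            raise ConfigError(f"n_genes={self.n_genes} too small for "
                              f"{needed} signature genes plus background")
        for sex, rho in self.tmb_tme_corr.items():
            if abs(rho) >= 1:
                raise ConfigError(f"infeasible correlation target {rho} for {sex}")
        for rate in (self.background_mutation_rate, self.silent_mutation_rate):
            if not 0 <= rate <= 1:
                raise ConfigError("mutation rates must lie in [0, 1]")
        for gene, (rm, rf) in self.sex_mutation_rates.items():
            if not (0 <= rm <= 1 and 0 <= rf <= 1):
                raise ConfigError(f"rates for {gene} must lie in [0, 1]")
        if not 0 <= self.censor_fraction < 1:
            raise ConfigError("censor_fraction must lie in [0, 1)")

    @property
    def cell_names(self) -> list[str]:
        return [f"cell_{k+1:02d}" for k in range(self.n_cells)]


@dataclass
class TruthRecord:
    """Planted ground truth for one simulated cohort."""

    config: SimulationConfig
    latent: pd.DataFrame                 # samples x cells (Gaussian log-abundance)
    stromal_latent: pd.Series
    immune_latent: pd.Series             # standardized within sex
    mutation_factor: pd.Series
    gene_rates: pd.DataFrame             # mutation gene x (rate_male, rate_female)
    event_times: pd.Series
    achieved: dict = field(default_factory=dict)

    def planted_cells(self) -> dict[str, float]:
        return {c: s for c, s in self.config.sex_cell_effects.items() if s != 0}

    def planted_mutations(self) -> dict[str, float]:
        return {g: rf - rm for g, (rm, rf) in self.config.sex_mutation_rates.items()
                if rf != rm}

    def planted_hazards(self) -> dict[str, float]:
        return {c: g for c, g in self.config.hazard_gammas.items() if g != 0}


@dataclass
class SimulatedCohort:
    expression: pd.DataFrame             # genes x samples, FPKM scale
    mutations: pd.DataFrame
    clinical: pd.DataFrame
    signatures: GeneSetCollection
    estimate_sets: GeneSetCollection
    truth: TruthRecord


def _tune_censor_bound(times: np.ndarray, target: float) -> float:
    """Upper bound c of Uniform(0, c) censoring so that the expected
    censored fraction mean_i min(T_i, c)/c matches ``target`` (bisection)."""
    lo, hi = 1e-9, float(times.max()) * 2
    frac = lambda c: float(np.mean(np.minimum(times, c)) / c)
    while frac(hi) > target:
        hi *= 2
        if hi > 1e12:
            break
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _standardize_within(values: np.ndarray, female: np.ndarray) -> np.ndarray:
    out = np.empty_like(values)
    for mask in (female, ~female):
        v = values[mask]
        out[mask] = (v - v.mean()) / (v.std() if v.std() > 0 else 1.0)
    return out


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate one fully synthetic cohort; byte-reproducible from the seed."""
    config.validate()
    seeds = np.random.SeedSequence(config.seed).spawn(6)
    rng_latent, rng_expr, rng_mut, rng_surv, rng_icb, rng_clin = \
        (np.random.default_rng(s) for s in seeds)

    n = config.n_male + config.n_female
    samples = [f"S{i+1:04d}" for i in range(n)]
    sex = np.array(["male"] * config.n_male + ["female"] * config.n_female)
    female = sex == "female"
    cells = config.cell_names

    # --- latent abundances -------------------------------------------------
    latent = rng_latent.standard_normal((n, config.n_cells))
    for cell, shift in config.sex_cell_effects.items():
        if cell not in cells:
            raise ConfigError(f"unknown cell {cell!r} in sex_cell_effects")
        latent[female, cells.index(cell)] += shift
    stromal = rng_latent.standard_normal(n)
    stromal[female] += config.sex_stromal_effect
    immune_raw = latent.mean(axis=1)
    immune_z = _standardize_within(immune_raw, female)

    # --- expression --------------------------------------------------------
    gps = config.genes_per_signature
    sig_genes = [f"G{g+1:05d}" for g in range(config.n_cells * gps)]
    str_genes = [f"G{g+1:05d}" for g in range(len(sig_genes),
                                              len(sig_genes) + config.n_stromal_genes)]
    n_bg = config.n_genes - len(sig_genes) - len(str_genes)
    bg_genes = [f"G{g+1:05d}" for g in range(len(sig_genes) + len(str_genes),
                                             config.n_genes)]
    genes = sig_genes + str_genes + bg_genes

    baseline = rng_expr.normal(config.baseline_mean, config.baseline_sd,
                               size=config.n_genes)
    log_expr = np.tile(baseline[:, None], (1, n))
    for k in range(config.n_cells):
        rows = slice(k * gps, (k + 1) * gps)
        log_expr[rows, :] += config.signature_effect * latent[:, k][None, :]
    log_expr[len(sig_genes):len(sig_genes) + config.n_stromal_genes, :] += \
        config.signature_effect * stromal[None, :]
    log_expr += rng_expr.normal(0.0, config.expression_noise_sd,
                                size=log_expr.shape)
    fpkm = np.maximum(np.exp2(log_expr) - 1.0, 0.0)
    if config.zero_quantile > 0:
        threshold = np.quantile(fpkm, config.zero_quantile)
        fpkm[fpkm < threshold] = 0.0
    expression = pd.DataFrame(fpkm, index=genes, columns=samples)

    signatures = GeneSetCollection()
    for k, cell in enumerate(cells):
        signatures.add(cell, sig_genes[k * gps:(k + 1) * gps],
                       description="synthetic cell signature")
    estimate_sets = GeneSetCollection()
    estimate_sets.add("IMMUNE", sig_genes, description="synthetic immune compartment")
    estimate_sets.add("STROMAL", str_genes, description="synthetic stromal compartment")

    # --- mutations ---------------------------------------------------------
    mut_genes = [f"MUT{g+1:04d}" for g in range(config.n_mutation_genes)]
    rates = pd.DataFrame({
        "rate_male": config.background_mutation_rate,
        "rate_female": config.background_mutation_rate,
    }, index=pd.Index(mut_genes, name="gene"), dtype=float)
    for gene, (rm, rf) in config.sex_mutation_rates.items():
        if gene not in rates.index:
            raise ConfigError(f"unknown mutation gene {gene!r}")
        rates.loc[gene] = [rm, rf]

    sigma = config.mutation_dispersion
    eps = rng_mut.standard_normal(n)
    z_mut = np.empty(n)
    for label, mask in (("male", ~female), ("female", female)):
        rho = float(config.tmb_tme_corr.get(label, 0.0))
        z_mut[mask] = rho * immune_z[mask] + np.sqrt(1 - rho ** 2) * eps[mask]
    factor = np.exp(sigma * z_mut - sigma ** 2 / 2.0)

    rate_matrix = np.where(female[None, :],
                           rates["rate_female"].to_numpy()[:, None],
                           rates["rate_male"].to_numpy()[:, None])
    prob = np.clip(rate_matrix * factor[None, :], 0.0, 0.99)
    hits = rng_mut.random(prob.shape) < prob
    silent_hits = rng_mut.random(prob.shape) < config.silent_mutation_rate

    g_idx, s_idx = np.nonzero(hits)
    classes = rng_mut.choice(NON_SILENT_CHOICES, size=g_idx.size,
                             p=NON_SILENT_PROBS)
    records = pd.DataFrame({
        "sample": np.array(samples)[s_idx],
        "gene": np.array(mut_genes)[g_idx],
        "variant_classification": classes,
    })
    g_idx, s_idx = np.nonzero(silent_hits)
    silent = pd.DataFrame({
        "sample": np.array(samples)[s_idx],
        "gene": np.array(mut_genes)[g_idx],
        "variant_classification": "Silent",
    })
    mutations = pd.concat([records, silent], ignore_index=True)
    mutations = mutations.sort_values(["sample", "gene"]).reset_index(drop=True)
    tmb = hits.sum(axis=0) / 38.0

    # --- survival ----------------------------------------------------------
    log_hazard = np.zeros(n)
    for cell, gamma in config.hazard_gammas.items():
        if cell not in cells:
            raise ConfigError(f"unknown cell {cell!r} in hazard_gammas")
        log_hazard += gamma * latent[:, cells.index(cell)]
    hazard = config.baseline_hazard * np.exp(log_hazard)
    event_time = rng_surv.exponential(1.0 / hazard)
    if config.censor_fraction > 0:
        bound = _tune_censor_bound(event_time, config.censor_fraction)
        censor_time = rng_surv.uniform(0.0, bound, size=n)
        os_time = np.minimum(event_time, censor_time)
        os_event = (event_time <= censor_time).astype(int)
    else:
        os_time = event_time
        os_event = np.ones(n, dtype=int)

    # --- immunotherapy response --------------------------------------------
    slope = np.where(female, float(config.icb_tmb_effect.get("female", 0.0)),
                     float(config.icb_tmb_effect.get("male", 0.0)))
    p_resp = 1.0 / (1.0 + np.exp(-(config.icb_intercept + slope * tmb)))
    responder = rng_icb.random(n) < p_resp

    clinical = pd.DataFrame({
        "sex": sex,
        "age": rng_clin.integers(25, 80, size=n),
        "stage": rng_clin.choice(["I", "II", "III", "IV"], size=n,
                                 p=[0.3, 0.3, 0.25, 0.15]),
        "os_time": np.round(os_time, 2),
        "os_event": os_event,
        "response": np.where(responder, "responder", "nonresponder"),
        "immune_infiltrated": True,
    }, index=pd.Index(samples, name="sample"))

    truth = TruthRecord(
        config=config,
        latent=pd.DataFrame(latent, index=samples, columns=cells),
        stromal_latent=pd.Series(stromal, index=samples, name="stromal"),
        immune_latent=pd.Series(immune_z, index=samples, name="immune_z"),
        mutation_factor=pd.Series(factor, index=samples, name="factor"),
        gene_rates=rates,
        event_times=pd.Series(event_time, index=samples, name="event_time"),
        achieved={
            "censor_fraction": float(1 - os_event.mean()),
            "mean_tmb": float(tmb.mean()),
        },
    )
    return SimulatedCohort(expression=expression, mutations=mutations,
                           clinical=clinical, signatures=signatures,
                           estimate_sets=estimate_sets, truth=truth)


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------

def evaluate_recovery(results: dict, truth: TruthRecord) -> dict[str, pd.DataFrame]:
    """Score pipeline outputs against the planted ground truth.

    ``results`` may contain ``cells`` (sex-bias cell table with fdr and
    direction columns), ``mutation_bias`` (table with fdr/direction) and
    ``signature_<sex>`` entries (mappings cell -> fitted beta).  Returns
    per-effect rows plus an aggregated sensitivity/specificity summary.
    """
    rows = []

    cells_table = results.get("cells")
    if cells_table is not None:
        planted = truth.planted_cells()
        for cell in truth.config.cell_names:
            if cell not in cells_table.index:
                continue
            detected = bool(cells_table.loc[cell, "fdr"] < 0.25)
            direction = cells_table.loc[cell, "direction"]
            shift = planted.get(cell, 0.0)
            expected = "female_biased" if shift > 0 else "male_biased"
            rows.append({
                "family": "cells", "feature": cell, "planted": cell in planted,
                "truth_effect": shift, "detected": detected,
                "sign_ok": detected and (not planted.get(cell)
                                         or direction == expected),
            })

    bias_table = results.get("mutation_bias")
    if bias_table is not None:
        planted = truth.planted_mutations()
        for gene in bias_table.index:
            detected = bool(bias_table.loc[gene, "fdr"] < 0.25)
            direction = bias_table.loc[gene, "direction"]
            diff = planted.get(gene, 0.0)
            expected = "female_biased" if diff > 0 else "male_biased"
            rows.append({
                "family": "mutations", "feature": gene, "planted": gene in planted,
                "truth_effect": diff, "detected": detected,
                "sign_ok": detected and (gene not in planted
                                         or direction == expected),
            })

    for sex in ("male", "female"):
        betas = results.get(f"signature_{sex}")
        if betas is None:
            continue
        planted = truth.planted_hazards()
        for cell in truth.config.cell_names:
            gamma = planted.get(cell, 0.0)
            detected = cell in betas
            rows.append({
                "family": f"hazard_{sex}", "feature": cell,
                "planted": cell in planted, "truth_effect": gamma,
                "detected": detected,
                "sign_ok": detected and (cell not in planted
                                         or np.sign(betas[cell]) == np.sign(gamma)),
            })

    effects = pd.DataFrame(rows)
    if len(effects) == 0:
        raise ValueError("no matching result tables to score")
    summaries = []
    for family, sub in effects.groupby("family"):
        planted = sub[sub["planted"]]
        unplanted = sub[~sub["planted"]]
        summaries.append({
            "family": family,
            "n_planted": len(planted),
            "sensitivity": float(planted["sign_ok"].mean()) if len(planted) else np.nan,
            "false_positives": int(unplanted["detected"].sum()),
            "specificity": float((~unplanted["detected"]).mean()) if len(unplanted) else np.nan,
        })
    return {"effects": effects, "summary": pd.DataFrame(summaries)}


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
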