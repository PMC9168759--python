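"""End-to-end orchestration of the sex-difference TME analysis.

Stage order: preprocess -> scores -> sex-bias tests -> differential
correlation -> pathway GSEA -> mutation association -> survival models
(per sex) -> ICB AUC (when response labels exist) -> strong/weak
classification.  Every stage writes TSV outputs into the run directory and
a JSON manifest records the seed, thresholds and per-stage row counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import readwrite as rw
from . import preprocess, scores, sex_bias, diff_corr, pathway_gsea
from . import mutation_assoc, survival, icb

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs and thresholds for one pipeline run."""

    expression: str
    maf: str
    clinical: str
    signatures: str
    estimate_sets: str = None          # GMT with IMMUNE and STROMAL sets
    icg: str = None                    # one checkpoint gene per line
    pathways: str = None               # GMT of immune-function pathways
    out_dir: str = "sextme_run"
    cancer_label: str = "cohort"
    p_cut: float = 0.05
    fdr_cut: float = 0.25
    min_mut_freq: float = 0.05
    zero_frac: float = 0.9
    n_perm: int = 1000
    seed: int = 0
    two_sided_diffcorr: bool = False
    extra: dict = field(default_factory=dict)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _read_gene_list(path) -> list[str]:
    with open(path) as handle:
        return [line.strip() for line in handle if line.strip()]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the in-memory stage outputs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {"p_cut": config.p_cut, "fdr_cut": config.fdr_cut,
                       "min_mut_freq": config.min_mut_freq,
                       "zero_frac": config.zero_frac},
        "n_perm": config.n_perm,
        "stages": {},
    }
    results: dict = {}

    def stage(name):
        def wrap(fn):
            try:
                value = fn()
            except Exception as err:
                _write_manifest(out, manifest)
                raise StageError(name, err) from err
            manifest["stages"][name] = _describe(value)
            return value
        return wrap

    expression_raw = stage("read_expression")(lambda: rw.read_expression(config.expression))
    mutations = stage("read_maf")(lambda: rw.read_maf(config.maf))
    clinical = stage("read_clinical")(lambda: rw.read_clinical(config.clinical))
    signatures = stage("read_signatures")(lambda: rw.read_gmt(config.signatures))

    cohort = stage("filter_samples")(lambda: preprocess.filter_samples(
        clinical, expression_raw, mutations, cancer_label=config.cancer_label))
    cohort.filter_report.to_csv(out / "filter_report.tsv", sep="\t", index=False)
    expr = stage("filter_genes")(lambda: preprocess.filter_genes(
        cohort.expression, zero_fraction_threshold=config.zero_frac))
    rw.write_expression(expr, out / "expression_filtered.tsv")
    rw.write_clinical(cohort.clinical, out / "clinical_filtered.tsv")
    results["cohort"] = cohort

    if config.estimate_sets:
        est = rw.read_gmt(config.estimate_sets)
        immune_set, stromal_set = est["IMMUNE"], est["STROMAL"]
    else:
        logger.warning("no compartment GMT supplied; using the union of all "
                       "cell signatures as the immune set and skipping the "
                       "stromal score")
        immune_set = sorted({g for _, m in signatures.items() for g in m})
        stromal_set = immune_set
    score_table = stage("scores")(lambda: scores.compute_sample_scores(
        expr, cohort.mutations, signatures, stromal_set, immune_set))
    score_table.to_csv(out / "scores.tsv", sep="\t", index_label="sample")
    results["scores"] = score_table

    icg_list = _read_gene_list(config.icg) if config.icg else []
    bias = stage("sex_bias")(lambda: sex_bias.sex_bias_scan(
        score_table, expr, cohort.clinical, icg_list,
        p_cut=config.p_cut, fdr_cut=config.fdr_cut))
    bias["summary"].to_csv(out / "summary_tests.tsv", sep="\t")
    bias["cells"].to_csv(out / "cell_tests.tsv", sep="\t")
    if "icgs" in bias:
        bias["icgs"].to_csv(out / "icg_tests.tsv", sep="\t")
    results["sex_bias"] = bias

    dc = stage("diff_corr")(lambda: diff_corr.diffcorr_scan(
        score_table, cohort.clinical, two_sided=config.two_sided_diffcorr,
        p_cut=config.p_cut))
    dc.to_csv(out / "diffcorr.tsv", sep="\t")
    results["diff_corr"] = dc

    gsea_table = None
    if config.pathways:
        pathways = rw.read_gmt(config.pathways)
        gsea_table = stage("pathway_gsea")(lambda: pathway_gsea.gsea_permutation(
            expr, cohort.clinical, pathways, n_perm=config.n_perm,
            seed=config.seed))
        gsea_table.to_csv(out / "gsea.tsv", sep="\t")
        results["pathway_gsea"] = gsea_table
    else:
        logger.info("no pathway GMT supplied; GSEA stage skipped")

    matrix = stage("mutation_matrix")(lambda: mutation_assoc.mutation_matrix(
        cohort.mutations, cohort.samples, min_freq=config.min_mut_freq))
    if len(matrix):
        bias_table = stage("sex_biased_mutations")(
            lambda: mutation_assoc.sex_biased_mutations(
                matrix, cohort.clinical, fdr_cut=config.fdr_cut))
        bias_table.to_csv(out / "mutation_bias.tsv", sep="\t")
        results["mutation_bias"] = bias_table
        biased = bias_table.index[bias_table["direction"] != "none"].tolist()
        if biased:
            assoc = stage("mutation_cell_association")(
                lambda: mutation_assoc.mutation_cell_association(
                    matrix, score_table[scores.cell_columns(score_table)],
                    biased, p_cut=config.p_cut))
            assoc.to_csv(out / "mutation_cell_assoc.tsv", sep="\t", index=False)
            results["mutation_cell_assoc"] = assoc

    for sex in ("male", "female"):
        try:
            signature = survival.build_signature(
                score_table, cohort.clinical, sex, p_cut=config.p_cut)
        except Exception as err:
            logger.warning("survival screen skipped for %s: %s", sex, err)
            continue
        signature.all_results.to_csv(out / f"cox_univariate_{sex}.tsv", sep="\t")
        results[f"signature_{sex}"] = signature
        if not signature.betas:
            continue
        stratum = cohort.clinical.index[cohort.clinical["sex"] == sex]
        stratum = stratum.intersection(score_table.index)
        clin = cohort.clinical.loc[stratum]
        usable = clin["os_time"].notna() & clin["os_event"].notna()
        clin = clin.loc[usable]
        strat = survival.risk_score(signature, score_table.loc[clin.index])
        strat.to_csv(out / f"risk_groups_{sex}.tsv", sep="\t", index_label="sample")
        curves, chi2, p = survival.km_logrank(
            clin["os_time"], clin["os_event"], strat["group"])
        curves.to_csv(out / f"km_curves_{sex}.tsv", sep="\t", index=False)
        (out / f"logrank_{sex}.txt").write_text(f"chi2\t{chi2}\np\t{p}\n")
        results[f"logrank_{sex}"] = (chi2, p)
        covs = pd.DataFrame({
            "risk_score": strat["risk_score"],
            "age": clin["age"],
            "stage": clin["stage"].map(survival.stage_to_ordinal),
        }).dropna()
        if len(covs) >= 10:
            try:
                multi = survival.cox_multivariable(
                    clin.loc[covs.index, "os_time"],
                    clin.loc[covs.index, "os_event"], covs)
                multi.to_csv(out / f"cox_multivariable_{sex}.tsv", sep="\t")
                results[f"cox_multivariable_{sex}"] = multi
            except Exception as err:
                logger.warning("multivariable Cox skipped for %s: %s", sex, err)

    if cohort.clinical["response"].notna().any():
        tmb = score_table["tmb"]
        auc_results = stage("icb_auc")(lambda: icb.tmb_auc(tmb, cohort.clinical))
        if auc_results:
            pd.DataFrame([{
                "sex": r.sex, "n_responders": r.n_responders,
                "n_nonresponders": r.n_nonresponders, "auc": r.auc,
            } for r in auc_results]).to_csv(out / "auc.tsv", sep="\t", index=False)
            results["icb_auc"] = auc_results
    else:
        logger.info("no response labels; ICB stage skipped")

    bias_summary = bias["summary"]
    classification = sex_bias.classify_cancer(
        tmb_p=bias_summary.loc["tmb", "p"],
        immune_p=bias_summary.loc["immune_score", "p"],
        stromal_p=bias_summary.loc["stromal_score", "p"],
        purity_p=bias_summary.loc["purity", "p"],
        cell_fdrs=bias["cells"]["fdr"],
        icg_fdrs=bias.get("icgs", pd.DataFrame(columns=["fdr"]))["fdr"],
        pathway_fdrs=(gsea_table["fdr"] if gsea_table is not None else []),
        p_cut=config.p_cut, fdr_cut=config.fdr_cut,
        cancer_label=config.cancer_label)
    pd.DataFrame([classification.__dict__]).to_csv(
        out / "classification.tsv", sep="\t", index=False)
    results["classification"] = classification

    _write_manifest(out, manifest)
    results["manifest"] = manifest
    return results


def _describe(value) -> dict:
    if isinstance(value, pd.DataFrame):
        return {"rows": int(value.shape[0]), "cols": int(value.shape[1])}
    if isinstance(value, dict):
        return {k: _describe(v) for k, v in value.items()
                if isinstance(v, pd.DataFrame)}
    if isinstance(value, preprocess.Cohort):
        return {"samples": len(value.samples), **value.n_by_sex()}
    return {"type": type(value).__name__}


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
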