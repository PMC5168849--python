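"""Run configuration and the end-to-end benchmark runner.

The runner ties the stages together: simulate -> normalize -> estimate and
remove surrogates -> call differential expression for every intra- and
cross-site comparison -> calibrate the average-expression filter -> evaluate.
Call counts are staged the way benchmark tables present them:

    raw        q < 5% on uncorrected expression
    sva        q < 5% after surrogate-variable removal
    sva_fc     additionally |log2FC| > 1
    sva_fc_ae  additionally the calibrated average-expression percentile

so specificity (eFDR) and reproducibility can be read off before and after
each improvement.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from debench import confounders as conf
from debench import data_model as dm
from debench import de_callers as dc
from debench import evaluation as ev
from debench import filters as fl
from debench import simulate as sim

log = logging.getLogger("debench")

__all__ = [
    "RunConfig",
    "ConfigError",
    "StageError",
    "validate_config",
    "run_benchmark",
    "BenchmarkResult",
    "STAGES",
]

STAGES = ("raw", "sva", "sva_fc", "sva_fc_ae")


class ConfigError(ValueError):
    """Invalid run configuration; ``errors`` lists path-qualified messages."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


class ProfileConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    log_mean: float = float(np.log(70.0))
    log_sd: float = Field(2.0, ge=0)
    a_only_fraction: float = Field(0.05, ge=0, le=1)
    b_only_fraction: float = Field(0.05, ge=0, le=1)
    phi0: float = Field(0.01, ge=0)
    phi1: float = Field(2.0, ge=0)


class SimulationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_genes: int = Field(20_000, ge=1)
    n_sites: int = Field(6, ge=2)
    replicates_per_sample: int = Field(4, ge=2)
    p_a: float = Field(0.75, ge=0, le=1)
    library_size_mean: float = Field(1e7, gt=0)
    library_size_cv: float = Field(0.2, ge=0)
    n_confounders_per_site: int = Field(2, ge=0)
    confounder_loading_sparsity: float = Field(0.3, ge=0, le=1)
    confounder_sd: float = Field(0.5, ge=0)
    profile: ProfileConfig = ProfileConfig()


class AnalysisConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    callers: list[Literal["moderated_t", "nb_wald"]] = ["moderated_t", "nb_wald"]
    prior_df: float = Field(4.0, ge=0)
    dispersion_shrink: float = Field(0.5, ge=0, le=1)
    surrogate_k: int | Literal["auto"] = "auto"
    n_perm: int = Field(20, ge=1)
    alpha: float = Field(0.05, gt=0, lt=1)
    q_max: float = Field(0.05, gt=0, le=1)
    min_abs_log2fc: float = Field(1.0, ge=0)
    calibration_target: int = Field(3000, ge=1)


class EvaluationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    topn_grid: list[int] = [50, 100, 200, 500, 1000]
    make_plots: bool = False
    write_matrices: bool = False


class RunConfig(BaseModel):
    """Fully-defaulted benchmark configuration (JSON-serializable)."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    simulation: SimulationConfig = SimulationConfig()
    analysis: AnalysisConfig = AnalysisConfig()
    evaluation: EvaluationConfig = EvaluationConfig()

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON run configuration (unknown keys rejected)."""
    try:
        payload = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ConfigError([f"<file>: {exc}"]) from None
    return validate_config_dict(payload)


def validate_config_dict(payload: dict) -> RunConfig:
    try:
        return RunConfig.model_validate(payload)
    except ValidationError as exc:
        msgs = [
            ".".join(str(p) for p in err["loc"]) + f": {err['msg']}" for err in exc.errors()
        ]
        raise ConfigError(msgs) from None


# ---------------------------------------------------------------------------
# Runner
# ---------------------------------------------------------------------------


@dataclass
class BenchmarkResult:
    """In-memory report bundle of one benchmark run."""

    config: RunConfig
    config_hash: str
    truth: pd.DataFrame
    counts: dm.ExpressionMatrix
    confounder_record: sim.ConfounderRecord
    size_factors: np.ndarray
    surrogate_model: conf.SurrogateModel
    calibration: dict[str, fl.CalibrationResult]
    de_tables: dict[tuple, pd.DataFrame]  # (caller, input, comparison_key)
    callsets: dict[tuple, fl.CallSet]  # (caller, stage, comparison_key)
    comparisons: pd.DataFrame  # per caller/stage/pair cross-site counts + eFDR
    intra_counts: pd.DataFrame  # per caller/stage/site
    agreements: pd.DataFrame  # per caller/stage/pair intra-list agreement
    topn: pd.DataFrame  # per caller/pair/N (final stage)
    truth_scores: pd.DataFrame  # per caller/stage/comparison realized FDR etc.
    anova: pd.DataFrame

    def median_efdr(self, caller: str, stage: str) -> float:
        sub = self.comparisons.query("caller == @caller and stage == @stage")
        return float(np.nanmedian(sub["efdr"].to_numpy()))

    def median_intra(self, caller: str, stage: str) -> float:
        sub = self.intra_counts.query("caller == @caller and stage == @stage")
        return float(np.median(sub["n_calls"].to_numpy()))


def _comparison_keys(sites: list[str]) -> list[tuple]:
    keys: list[tuple] = [("intra", s) for s in sites]
    for s1, s2 in itertools.combinations(sites, 2):
        keys += [(s1, "A", s2, "A"), (s1, "C", s2, "C"), (s1, "A", s2, "C"), (s2, "A", s1, "C")]
    return keys


def _groups_for(matrix: dm.ExpressionMatrix, key: tuple) -> tuple[list[str], list[str]]:
    if key[0] == "intra":
        return matrix.ids_for(site=key[1], sample_type="A"), matrix.ids_for(
            site=key[1], sample_type="C"
        )
    s1, t1, s2, t2 = key
    return matrix.ids_for(site=s1, sample_type=t1), matrix.ids_for(site=s2, sample_type=t2)


def _counts_from_log(
    corrected: dm.ExpressionMatrix, eff_lib: np.ndarray, prior: float = 0.5
) -> dm.ExpressionMatrix:
    """Reconstruct integer counts from (corrected) log2-CPM for the NB caller."""
    prior_scaled = prior * eff_lib / eff_lib.mean()
    vals = 2.0 ** corrected.values * (eff_lib + 2 * prior_scaled) / 1e6 - prior_scaled
    vals = np.rint(np.clip(vals, 0.0, None)).astype(np.int64)
    return dm.ExpressionMatrix(
        gene_ids=corrected.gene_ids, values=vals, samples=corrected.samples.copy(), scale="counts"
    )


def run_benchmark(config: RunConfig, outdir: str | Path | None = None) -> BenchmarkResult:
    """Execute the full benchmark for one configuration and seed."""
    scfg, acfg, ecfg = config.simulation, config.analysis, config.evaluation
    seeds = np.random.SeedSequence(config.seed).generate_state(4) % (2**31)

    stage = "simulate"
    try:
        params = sim.ProfileParams(**scfg.profile.model_dump())
        profiles = sim.sample_gene_profiles(scfg.n_genes, params, seed=int(seeds[0]))
        mix = sim.MixtureDesign(p_a=scfg.p_a)
        truth = sim.true_log2fc(profiles, mix)
        design = sim.StudyDesign(
            n_sites=scfg.n_sites,
            replicates_per_sample=scfg.replicates_per_sample,
            library_size_mean=scfg.library_size_mean,
            library_size_cv=scfg.library_size_cv,
            n_confounders_per_site=scfg.n_confounders_per_site,
            confounder_loading_sparsity=scfg.confounder_loading_sparsity,
            confounder_sd=scfg.confounder_sd,
            seed=int(seeds[1]),
        )
        counts, record = sim.simulate_counts(profiles, design, mix)
        sites = sorted(counts.samples["site"].unique(), key=lambda s: int(s))
        log.info("simulated %d genes x %d samples (%d sites)", counts.n_genes,
                 counts.n_samples, len(sites))

        stage = "normalize"
        size_factors = dm.tmm_size_factors(counts)
        raw_log = dm.log_cpm(counts, size_factors)
        eff_lib = dm.effective_library_sizes(counts, size_factors)

        stage = "correct"
        model = conf.estimate_surrogates(
            raw_log, k=acfg.surrogate_k, n_perm=acfg.n_perm, alpha=acfg.alpha,
            seed=int(seeds[2]),
        )
        corrected = conf.remove_confounders(raw_log, model)
        log.info("surrogate factors: %d", model.n_factors)

        stage = "call"
        inputs = {"raw": (raw_log, counts), "sva": (corrected, _counts_from_log(corrected, eff_lib))}
        keys = _comparison_keys(sites)
        de_tables: dict[tuple, pd.DataFrame] = {}
        for inp, (log_mat, count_mat) in inputs.items():
            for caller in acfg.callers:
                for key in keys:
                    g1, g2 = _groups_for(log_mat, key)
                    if caller == "moderated_t":
                        table = dc.moderated_t_caller(log_mat, g1, g2, prior_df=acfg.prior_df)
                    else:
                        table = dc.nb_wald_caller(
                            count_mat, size_factors, g1, g2,
                            dispersion_shrink=acfg.dispersion_shrink,
                        )
                    de_tables[(caller, inp, key)] = table

        stage = "calibrate"
        calibration: dict[str, fl.CalibrationResult] = {}
        for caller in acfg.callers:
            per_site = [de_tables[(caller, "sva", ("intra", s))] for s in sites]
            calibration[caller] = fl.calibrate_ae_threshold(
                per_site,
                target=acfg.calibration_target,
                q_max=acfg.q_max,
                min_abs_log2fc=acfg.min_abs_log2fc,
            )
            log.info("caller %s: AE percentile %.1f (median %.0f)", caller,
                     calibration[caller].ae_percentile, calibration[caller].achieved_median)

        stage = "evaluate"
        result = _evaluate(config, sites, keys, de_tables, calibration, truth)
    except Exception as exc:  # noqa: BLE001 - re-raised with the stage name
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc

    bundle = BenchmarkResult(
        config=config,
        config_hash=config.config_hash(),
        truth=truth,
        counts=counts,
        confounder_record=record,
        size_factors=size_factors,
        surrogate_model=model,
        calibration=calibration,
        de_tables=de_tables,
        **result,
    )
    if outdir is not None:
        write_report(bundle, outdir)
    return bundle


def _stage_spec(stage: str, acfg: AnalysisConfig, cal: fl.CalibrationResult) -> fl.FilterSpec:
    if stage == "raw" or stage == "sva":
        return fl.FilterSpec(q_max=acfg.q_max, min_abs_log2fc=0.0, ae_percentile=None)
    if stage == "sva_fc":
        return fl.FilterSpec(q_max=acfg.q_max, min_abs_log2fc=acfg.min_abs_log2fc,
                             ae_percentile=None)
    return fl.FilterSpec(q_max=acfg.q_max, min_abs_log2fc=acfg.min_abs_log2fc,
                         ae_percentile=cal.ae_percentile)


def _evaluate(config, sites, keys, de_tables, calibration, truth) -> dict:
    acfg, ecfg = config.analysis, config.evaluation
    callsets: dict[tuple, fl.CallSet] = {}
    comp_rows, intra_rows, agree_rows, topn_rows, truth_rows = [], [], [], [], []

    for caller in acfg.callers:
        for stage in STAGES:
            inp = "raw" if stage == "raw" else "sva"
            spec = _stage_spec(stage, acfg, calibration[caller])
            stage_sets = {}
            for key in keys:
                cs = fl.apply_filters(de_tables[(caller, inp, key)], spec, label=str(key))
                stage_sets[key] = cs
                callsets[(caller, stage, key)] = cs
            pair_df, intra_df = ev.run_comparisons(stage_sets, sites)
            pair_df.insert(0, "caller", caller)
            pair_df.insert(1, "stage", stage)
            intra_df.insert(0, "caller", caller)
            intra_df.insert(1, "stage", stage)
            comp_rows.append(pair_df)
            intra_rows.append(intra_df)

            for s1, s2 in itertools.combinations(sites, 2):
                res = ev.agreement(stage_sets[("intra", s1)], stage_sets[("intra", s2)])
                agree_rows.append(
                    {"caller": caller, "stage": stage, "site1": s1, "site2": s2,
                     "n_union": res.n_union,
                     "n_consistent": res.n_consistent_intersection,
                     "agreement": res.agreement}
                )
            for key in keys:
                if key[0] == "intra" or (key[1], key[3]) == ("A", "C"):
                    tm = ev.truth_metrics(stage_sets[key], truth)
                    truth_rows.append(
                        {"caller": caller, "stage": stage, "comparison": str(key), **tm}
                    )

        # top-N concordance at the fully filtered stage, per the ranked-list view
        final_spec = _stage_spec("sva_fc_ae", acfg, calibration[caller])
        for s1, s2 in itertools.combinations(sites, 2):
            t1 = de_tables[(caller, "sva", ("intra", s1))]
            t2 = de_tables[(caller, "sva", ("intra", s2))]
            for n in ecfg.topn_grid:
                res = ev.topn_agreement(t1, t2, final_spec, n)
                topn_rows.append(
                    {"caller": caller, "site1": s1, "site2": s2, "n_top": n,
                     "agreement": res.agreement}
                )

    intra_counts = pd.concat(intra_rows, ignore_index=True)
    if len(acfg.callers) >= 2:
        anova = ev.anova_sensitivity(
            intra_counts.rename(columns={"stage": "variant"})[
                ["variant", "caller", "site", "n_calls"]
            ]
        )
    else:  # two-way decomposition needs >= 2 levels per factor
        anova = pd.DataFrame()
    return {
        "callsets": callsets,
        "comparisons": pd.concat(comp_rows, ignore_index=True),
        "intra_counts": intra_counts,
        "agreements": pd.DataFrame(agree_rows),
        "topn": pd.DataFrame(topn_rows),
        "truth_scores": pd.DataFrame(truth_rows),
        "anova": anova,
    }


def write_report(bundle: BenchmarkResult, outdir: str | Path) -> None:
    """Write the TSV/JSON report bundle (and optional matrices/plots)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ff = "%.6g"
    bundle.comparisons.to_csv(out / "comparisons.tsv", sep="\t", index=False, float_format=ff)
    bundle.intra_counts.to_csv(out / "intra_counts.tsv", sep="\t", index=False)
    bundle.agreements.to_csv(out / "agreement.tsv", sep="\t", index=False, float_format=ff)
    bundle.topn.to_csv(out / "topn.tsv", sep="\t", index=False, float_format=ff)
    bundle.anova.to_csv(out / "anova.tsv", sep="\t", float_format=ff)
    bundle.truth_scores.to_csv(out / "truth_metrics.tsv", sep="\t", index=False, float_format=ff)
    cal = pd.DataFrame(
        [
            {"caller": c, "ae_percentile": r.ae_percentile,
             "achieved_median": r.achieved_median, "target": r.target,
             "unreachable": r.unreachable}
            for c, r in bundle.calibration.items()
        ]
    )
    cal.to_csv(out / "calibration.tsv", sep="\t", index=False, float_format=ff)
    summary = {
        "config_hash": bundle.config_hash,
        "seed": bundle.config.seed,
        "n_surrogates": bundle.surrogate_model.n_factors,
        "config": bundle.config.model_dump(mode="json"),
    }
    (out / "run_summary.json").write_text(json.dumps(summary, indent=2))
    if bundle.config.evaluation.write_matrices:
        dm.write_counts(bundle.counts, out / "counts.tsv", out / "samples.tsv")
        sim.write_truth(bundle.truth, out / "truth.tsv")
    if bundle.config.evaluation.make_plots:
        from debench import plotting

        plotting.efdr_violin(bundle.comparisons, out / "efdr_violin.png")
        plotting.intra_count_violin(bundle.intra_counts, out / "intra_counts_violin.png")
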