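"""End-to-end orchestration: simulate -> QC -> concordance -> CNV -> STR.

One :class:`RunConfig` drives every stage with the thresholds the
analysis is defined by (no-call score 0.25, call-rate pass at 95%,
duplicate-locus concordance split at 99%, 50-kb windows, CBS with at
least 20 probes per segment).  ``run_all`` writes each stage's tables
under a run directory and a consolidated JSON report whose metrics
equal what the stage functions return when invoked individually; any
stage error propagates wrapped with the stage name.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (cnv, concordance, genotype_io as gio, locus_qc, sample_qc,
               str_qc, wave_norm)
from .simulate import SimulationConfig, write_simulation

log = logging.getLogger("arrayqc")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Run-wide parameters; defaults match the study's analysis values."""
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    gc_score_threshold: float = 0.25
    call_rate_threshold: float = 0.95
    het_fence_k: float = 3.0
    duplicate_threshold: float = 0.99
    window_size: int = 50_000
    subtelomere_k: int = 3
    wave_degree: int = 2
    cbs_alpha: float = 0.01
    cbs_permutations: int = 200
    cbs_min_probes: int = 20
    cnv_overlap: float = 0.5
    cnv_sd_gate: float = 0.30
    cnv_max_pairs: int = 8

    def validate(self) -> "RunConfig":
        for name in ("gc_score_threshold", "call_rate_threshold",
                     "duplicate_threshold", "cnv_overlap"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        self.sim.validate()
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sim" in d:
            d["sim"] = SimulationConfig.from_dict(d["sim"])
        return cls(**d).validate()

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        return cls.from_dict(yaml.safe_load(path.read_text()))


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, float) and np.isnan(obj):
        return None
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _matrix(calls: pd.DataFrame, column: str, cohort, manifest) -> np.ndarray:
    """(samples x probes) float matrix aligned to cohort/manifest order."""
    s_index = pd.Index(cohort["sample_id"])
    p_index = pd.Index(manifest["probe_id"])
    mat = np.full((len(s_index), len(p_index)), np.nan)
    mat[s_index.get_indexer(calls["sample_id"]),
        p_index.get_indexer(calls["probe_id"])] = calls[column].to_numpy()
    return mat


def run_all(config: RunConfig, outdir, seed: int | None = None) -> dict:
    """Run every stage on a fresh simulation; return the report dict."""
    config.validate()
    if seed is not None:
        config = RunConfig.from_dict(config.to_dict())
        config.sim.seed = int(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.sim.seed}

    def stage(name):
        log.info("stage %s", name)
        return name

    try:
        name = stage("simulate")
        manifest, cohort, calls, truth, profiles = write_simulation(
            outdir / "sim", config.sim)

        name = stage("sample_qc")
        denom = sample_qc.compute_denominators(calls, cohort)
        call_rates = sample_qc.compute_call_rates(
            calls, denom.denominators, cohort, config.call_rate_threshold)
        chips, plates = sample_qc.detect_systematic_failures(call_rates, cohort)
        het = sample_qc.compute_heterozygosity(calls, manifest)
        het = sample_qc.flag_het_outliers(het, config.het_fence_k)
        failure = sample_qc.failure_rate_report(call_rates, cohort)
        repeats = sample_qc.select_repeats(call_rates, het)
        call_rates.to_csv(outdir / "call_rates.tsv", sep="\t", index=False)
        het.to_csv(outdir / "heterozygosity.tsv", sep="\t", index=False)
        failure.to_csv(outdir / "failure_rates.tsv", sep="\t", index=False)
        repeats.to_csv(outdir / "repeat_selection.tsv", sep="\t", index=False)
        report["sample_qc"] = {
            "denominators": denom.denominators,
            "n_failed_all_probes": denom.n_failed_all,
            "n_failed_wga_only_probes": denom.n_failed_wga_only,
            "failure_rates": failure.to_dict("records"),
            "median_heterozygosity": float(het["het_rate"].median()),
            "n_het_outliers": int(het["is_outlier"].sum()),
            "n_chips_excluded": int((chips["action"] == "exclude").sum()),
            "n_chips_flagged": int((chips["action"] == "flag").sum()),
            "n_plates_flagged": len(plates),
            "n_repeats_selected": len(repeats),
        }

        name = stage("concordance")
        matrix = concordance.genotype_matrix(calls)
        pairs = concordance.pair_replicates(cohort, call_rates)
        pairs = concordance.compute_pair_concordance(calls, pairs, matrix)
        summary, outliers = concordance.summarize_concordance(pairs)
        maf = concordance.compute_maf(calls, cohort, manifest, call_rates)
        dup, dup_summary = concordance.duplicate_locus_concordance(
            calls, manifest, maf, cohort, config.duplicate_threshold, matrix)
        pairs.to_csv(outdir / "replicate_pairs.tsv", sep="\t", index=False)
        dup.to_csv(outdir / "duplicate_loci.tsv", sep="\t", index=False)
        report["concordance"] = {
            "pair_summary": summary.to_dict("records"),
            "n_outlier_pairs": len(outliers),
            "duplicate_loci": {k: v for k, v in dup_summary.items()
                               if k != "skipped_loci"},
        }

        name = stage("locus_qc")
        classes = locus_qc.classify_probe_failures(calls, cohort)
        loci = locus_qc.collapse_to_loci(classes, manifest)
        windows = locus_qc.window_failure_counts(loci, manifest,
                                                 config.window_size)
        windows = locus_qc.flag_subtelomeric(windows, config.subtelomere_k)
        assoc = locus_qc.gc_association(windows, seed=config.sim.seed)
        windows.to_csv(outdir / "window_failures.tsv", sep="\t", index=False)
        gio.write_windows_bed(windows, outdir / "window_failures.bed",
                              window_size=config.window_size)
        n_fail_wga = int((loci["failure_class"] == "failed_wga_only").sum())
        subtel_share = (
            windows.loc[windows["is_subtelomeric"], "n_failed_wga_only"].sum()
            / n_fail_wga if n_fail_wga else None)
        report["locus_qc"] = {
            "n_failed_all_loci": int((loci["failure_class"] == "failed_all").sum()),
            "n_failed_wga_only_loci": n_fail_wga,
            "subtelomeric_share_of_wga_failures": subtel_share,
            "gc_association": assoc,
        }

        name = stage("wave_norm")
        lrr = _matrix(calls, "lrr", cohort, manifest)
        model = wave_norm.fit_wave_model(lrr, manifest, cohort,
                                         config.wave_degree)
        adjusted = wave_norm.correct_waves(lrr, model, manifest)
        gmat = _matrix(calls, "genotype", cohort, manifest)
        bmat = _matrix(calls, "baf", cohort, manifest)
        sd = wave_norm.sd_report(lrr, adjusted, bmat,
                                 gmat.astype(np.int8), cohort["sample_id"])
        sd.to_csv(outdir / "sd_report.tsv", sep="\t", index=False)
        report["wave_norm"] = {
            "median_lrr_sd_raw": float(sd["lrr_sd_raw"].median()),
            "median_lrr_sd_adjusted": float(sd["lrr_sd_adjusted"].median()),
            "frac_samples_sd_reduced": float(
                (sd["lrr_sd_adjusted"] < sd["lrr_sd_raw"]).mean()),
        }

        name = stage("cnv")
        passing = set(call_rates.loc[call_rates["passes"], "sample_id"])
        gate = cnv.noise_gate(sd.set_index("sample_id")["lrr_sd_adjusted"],
                              config.cnv_sd_gate)
        eligible = set(gate[gate].index)
        acc = cnv.CNVConcordance(0, 0, 0, 0)
        pairs_used = 0
        all_events = []
        for ind, grp in cohort.groupby("individual_id"):
            if pairs_used >= config.cnv_max_pairs:
                break
            g = [s for s in grp.loc[grp["input_type"] == "gDNA", "sample_id"]
                 if s in passing and s in eligible]
            w = [s for s in grp.loc[grp["input_type"] == "wgaDNA", "sample_id"]
                 if s in passing and s in eligible]
            if not g or not w:
                continue
            ev_g = cnv.call_cnvs(calls, manifest, g[0], config.cbs_alpha,
                                 config.cbs_permutations, config.cbs_min_probes,
                                 seed=config.sim.seed + pairs_used)
            ev_w = cnv.call_cnvs(calls, manifest, w[0], config.cbs_alpha,
                                 config.cbs_permutations, config.cbs_min_probes,
                                 seed=config.sim.seed + 500 + pairs_used)
            ev_g, ev_w = ev_g[~ev_g["flagged"]], ev_w[~ev_w["flagged"]]
            m = cnv.match_events(ev_g, ev_w, config.cnv_overlap)
            acc = cnv.CNVConcordance(
                acc.n_events_reference + m.n_events_reference,
                acc.n_tp + m.n_tp, acc.n_fn + m.n_fn, acc.n_fp + m.n_fp)
            all_events.extend([ev_g, ev_w])
            pairs_used += 1
        if all_events:
            pd.concat(all_events, ignore_index=True).to_csv(
                outdir / "cnv_events.tsv", sep="\t", index=False)
        report["cnv"] = {
            "n_pairs_analyzed": pairs_used,
            "n_events_reference": acc.n_events_reference,
            "n_tp": acc.n_tp, "n_fn": acc.n_fn, "n_fp": acc.n_fp,
            "concordance_rate": acc.concordance_rate
            if acc.n_events_reference else None,
        }

        name = stage("str_qc")
        comparisons = str_qc.compare_cohort(profiles, cohort)
        by_cat, counterfactual = str_qc.screen_report(
            comparisons, call_rates, cohort)
        comparisons.to_csv(outdir / "str_comparisons.tsv", sep="\t", index=False)
        report["str_qc"] = {
            "category_counts": comparisons["quality_category"]
            .value_counts().to_dict(),
            "by_category": by_cat.to_dict("records"),
            "counterfactual": counterfactual,
        }
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    report = _jsonify(report)
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True))
    return report
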