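"""Stage orchestration: call -> callability -> rate -> phase -> regress ->
spectrum, with a JSON config, per-stage artifacts and structured logs.

Two input routes feed the stages: a cohort VCF + PED (discovery,
callability, aggregate rate, phasing) and/or a trio summary table plus a
phased reference DNM table (rate, age regression, spectrum). Each enabled
stage writes its TSV/JSON artifact into the output directory and appends a
JSON-lines log record with its in/out counters; a failing stage halts
everything downstream.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Any, Optional

import pandas as pd

from . import age_models, callability, discovery, io, phasing, spectrum
from .model import FilterConfig, LongevityConfig

STAGES = ("call", "callability", "rate", "phase", "regress", "spectrum")


class PipelineError(RuntimeError):
    """A stage failed or stage outputs disagree with a consumer's schema."""


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    out_dir: str = "dnm_out"
    vcf: Optional[str] = None
    ped: Optional[str] = None
    trio_table: Optional[str] = None
    reference_dnm_table: Optional[str] = None
    read_phase_table: Optional[str] = None
    genome_span_bp: int = 1_800_000_000
    filters: FilterConfig = field(default_factory=FilterConfig)
    longevity: LongevityConfig = field(default_factory=LongevityConfig)
    spectrum_shift_years: float = 13.0
    spectrum_boot: int = 1000
    spectrum_mother_age: float = 2.92
    spectrum_father_age: float = 4.68
    scale_bp: float = 5e9
    predict_age: float = 0.5
    seed: int = 0
    stages: tuple[str, ...] = STAGES

    def require(self, attr: str, stage: str) -> Any:
        value = getattr(self, attr)
        if value is None:
            raise PipelineError(f"stage {stage!r} requires config key {attr!r}")
        return value


_FILTER_KEYS = {f.name for f in dataclasses.fields(FilterConfig)}
_TOP_KEYS = {f.name for f in dataclasses.fields(RunConfig)} - {"filters", "longevity"} | {
    "filters",
    "longevity",
}


def validate_config(path: str) -> RunConfig:
    """Load and validate a JSON config; unknown keys are rejected."""
    with open(path) as fh:
        raw = json.load(fh) if os.path.getsize(path) else {}
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise PipelineError(f"unknown config keys: {sorted(unknown)}")
    filters = raw.pop("filters", {})
    bad = set(filters) - _FILTER_KEYS
    if bad:
        raise PipelineError(f"unknown filter keys: {sorted(bad)}")
    longevity = raw.pop("longevity", {})
    bad = set(longevity) - {"puberty_age_target", "puberty_age_reference"}
    if bad:
        raise PipelineError(f"unknown longevity keys: {sorted(bad)}")
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
        bad = set(raw["stages"]) - set(STAGES)
        if bad:
            raise PipelineError(f"unknown stages: {sorted(bad)}")
    try:
        cfg = RunConfig(
            filters=FilterConfig(**filters),
            longevity=LongevityConfig(**longevity),
            **raw,
        )
    except (TypeError, ValueError) as exc:
        raise PipelineError(f"invalid config: {exc}") from exc
    for key in ("vcf", "ped", "trio_table", "reference_dnm_table", "read_phase_table"):
        p = getattr(cfg, key)
        if p is not None and not os.path.exists(p):
            raise PipelineError(f"config key {key!r}: file not found: {p}")
    return cfg


def _log(out_dir: str, record: dict) -> None:
    with open(os.path.join(out_dir, "pipeline_log.jsonl"), "a") as fh:
        fh.write(json.dumps(record, default=str) + "\n")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; return the report.

    The report (also written to ``report.json``) carries each stage's
    headline numbers: candidate/high-confidence counts, per-trio and
    aggregate rates, phase summary, regression coefficients and the
    spectrum comparison.
    """
    os.makedirs(cfg.out_dir, exist_ok=True)
    report: dict[str, Any] = {"seed": cfg.seed}
    enabled = [s for s in STAGES if s in cfg.stages]

    sites = None
    ped = None
    high_conf: dict[str, list] = {}
    trio_records = None

    def load_cohort():
        nonlocal sites, ped
        if sites is None:
            vcf = cfg.require("vcf", "call")
            pedp = cfg.require("ped", "call")
            ped = io.read_pedigree(pedp)
            sites = list(io.read_vcf_cohort(vcf))
        return sites, ped

    for stage in enabled:
        try:
            if stage == "call":
                sts, pd_ = load_cohort()
                all_cands = []
                for trio in pd_.trios():
                    cands = discovery.discover_dnms(sts, trio, pd_, cfg.filters)
                    all_cands.extend(cands)
                    high_conf[trio[0]] = [
                        c for c in cands if c.status == "high_confidence"
                    ]
                io.candidates_to_frame(all_cands).to_csv(
                    os.path.join(cfg.out_dir, "candidates.tsv"), sep="\t", index=False
                )
                io.write_dnm_table(all_cands, os.path.join(cfg.out_dir, "dnms.tsv"))
                report["call"] = {
                    "n_candidates": len(all_cands),
                    "n_high_confidence": sum(len(v) for v in high_conf.values()),
                }
                _log(cfg.out_dir, {"stage": "call", **report["call"]})

            elif stage == "callability":
                sts, pd_ = load_cohort()
                rows = []
                for trio in pd_.trios():
                    tc = callability.estimate_trio_callability(sts, trio, cfg.filters)
                    rows.append(
                        {
                            "proband": trio[0],
                            "c_child": tc.c_child,
                            "c_father": tc.c_father,
                            "c_mother": tc.c_mother,
                            "C": tc.C,
                        }
                    )
                df = pd.DataFrame(rows)
                df.to_csv(
                    os.path.join(cfg.out_dir, "callability.tsv"), sep="\t", index=False
                )
                report["callability"] = {"mean_C": float(df["C"].mean())}
                _log(cfg.out_dir, {"stage": "callability", **report["callability"]})

            elif stage == "rate":
                trio_records = _trio_records(cfg, report, high_conf)
                est = callability.aggregate_rate(trio_records)
                out = {
                    "rate_per_bp_per_gen": est.rate_per_bp_per_gen,
                    "ci": [est.ci_low, est.ci_high],
                    "pooled_rate": est.pooled_rate,
                    "pooled_ci": list(est.pooled_ci),
                    "n_mutations": est.n_mutations_total,
                    "callable_diploid_sites": est.callable_diploid_sites,
                }
                try:
                    age = callability.mean_parental_age(trio_records)
                    per_year = callability.per_year_rate(est, age)
                    out["mean_parental_age"] = age
                    out["rate_per_bp_per_year"] = per_year.rate_per_bp_per_gen
                    out["per_year_ci"] = [per_year.ci_low, per_year.ci_high]
                except ValueError:
                    pass
                report["rate"] = out
                with open(os.path.join(cfg.out_dir, "rate.json"), "w") as fh:
                    json.dump(out, fh, indent=2)
                _log(cfg.out_dir, {"stage": "rate", **out})

            elif stage == "phase":
                sts, pd_ = load_cohort()
                if not high_conf:
                    raise PipelineError("phase stage needs the call stage's output")
                transmission = []
                for trio_id, cands in high_conf.items():
                    if not pd_.children_of(trio_id):
                        continue
                    for c in cands:
                        transmission.append(phasing.transmission_phase(c, sts, pd_))
                read_based = (
                    io.read_phase_table(cfg.read_phase_table)
                    if cfg.read_phase_table
                    else []
                )
                combined = phasing.combine_phase(transmission, read_based)
                io.write_phase_table(
                    combined, os.path.join(cfg.out_dir, "phase.tsv")
                )
                out = {"n_phased": len(combined)}
                if combined:
                    np_, nm, frac, p = phasing.male_bias_summary(combined)
                    out.update(
                        n_paternal=np_, n_maternal=nm, fraction_paternal=frac, binomial_p=p
                    )
                report["phase"] = out
                _log(cfg.out_dir, {"stage": "phase", **out})

            elif stage == "regress":
                trio_records = trio_records or _trio_records(cfg, report, high_conf)
                design = age_models.build_design(trio_records)
                fit = age_models.fit_identity_poisson(design)
                eff, eff_ci = age_models.scale_effect(fit, cfg.scale_bp)
                rate_at, rate_ci = age_models.predict_rate_at_age(fit, cfg.predict_age)
                out = {
                    "beta_N": fit.beta_N,
                    "beta_p": fit.beta_p,
                    "se": list(fit.se),
                    "scaled_effect_per_year": eff,
                    "scaled_effect_ci": list(eff_ci),
                    "predict_age": cfg.predict_age,
                    "rate_at_age": rate_at,
                    "rate_at_age_ci": list(rate_ci),
                    "n_obs": fit.n_obs,
                }
                report["regress"] = out
                with open(os.path.join(cfg.out_dir, "regression.json"), "w") as fh:
                    json.dump(out, fh, indent=2)
                _log(cfg.out_dir, {"stage": "regress", **out})

            elif stage == "spectrum":
                table = io.read_dnm_table(cfg.require("reference_dnm_table", "spectrum"))
                needed = {"proband", "class", "parent", "father_age", "mother_age"}
                if not needed <= set(table.columns):
                    raise PipelineError(
                        f"reference DNM table lacks columns {sorted(needed - set(table.columns))}"
                    )
                fits = spectrum.fit_class_regressions(table)
                observed = _observed_counts(cfg, high_conf)
                out: dict[str, Any] = {}
                for model in ("total", "reproductive"):
                    pred = spectrum.longevity_spectrum(
                        fits,
                        cfg.spectrum_mother_age,
                        cfg.spectrum_father_age,
                        model,
                        cfg.spectrum_shift_years,
                    )
                    entry: dict[str, Any] = {"f": pred.as_dict()}
                    if observed:
                        if cfg.spectrum_boot > 0:
                            point, lo, hi = spectrum.bootstrap_rmse_ci(
                                table,
                                observed,
                                cfg.spectrum_mother_age,
                                cfg.spectrum_father_age,
                                model,
                                cfg.spectrum_shift_years,
                                n_boot=cfg.spectrum_boot,
                                seed=cfg.seed,
                            )
                            entry["rmse_pct"] = point
                            entry["rmse_ci"] = [lo, hi]
                        else:
                            entry["rmse_pct"] = spectrum.spectrum_rmse(pred, observed)
                    out[model] = entry
                report["spectrum"] = out
                with open(os.path.join(cfg.out_dir, "spectrum.json"), "w") as fh:
                    json.dump(out, fh, indent=2)
                _log(cfg.out_dir, {"stage": "spectrum", "models": list(out)})
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    with open(os.path.join(cfg.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def _trio_records(cfg: RunConfig, report: dict, high_conf: dict):
    """TrioRecords from the trio table, or from call+callability artifacts."""
    if cfg.trio_table is not None:
        return io.trio_records_from_table(io.read_trio_table(cfg.trio_table))
    call_path = os.path.join(cfg.out_dir, "callability.tsv")
    if not (high_conf and os.path.exists(call_path)):
        raise PipelineError(
            "rate/regress stages need either trio_table or the call and "
            "callability stages"
        )
    from .model import TrioCallability, TrioRecord

    cal = pd.read_csv(call_path, sep="\t", dtype={"proband": str}).set_index("proband")
    ped = io.read_pedigree(cfg.require("ped", "rate"))
    records = []
    for trio_id, cands in high_conf.items():
        row = cal.loc[trio_id]
        fa, ma = ped.ages.get(trio_id, (None, None))
        records.append(
            TrioRecord(
                proband=trio_id,
                paternal_age=fa,
                maternal_age=ma,
                n_mutations=len(cands),
                callability=TrioCallability(
                    c_child=row["c_child"],
                    c_father=row["c_father"],
                    c_mother=row["c_mother"],
                ),
                haploid_span_bp=cfg.genome_span_bp,
            )
        )
    return records


def _observed_counts(cfg: RunConfig, high_conf: dict) -> Optional[dict[str, int]]:
    if high_conf:
        all_muts = [c for v in high_conf.values() for c in v]
        counts, _ = discovery.spectrum_counts(all_muts)
        return counts
    return None
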