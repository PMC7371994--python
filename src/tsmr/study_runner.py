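"""Configuration layer and CLI chaining selection, estimation, and sensitivity.

``run_analysis`` executes one configured exposure-outcome analysis end to
end: instrument selection, optional directionality (Steiger) filtering,
IVW / weighted-median / MR-Egger estimation with Cochran's Q, leave-one-out
re-estimation, and a single-SNP scan, writing TSV/JSON outputs plus a run
log of every decision.  ``run_all_fixture_analyses`` runs the packaged
fixture suite (four phenotypes, primary + Steiger arm each) and compares the
deterministic results against expected values shipped as a data file.

Conventions differ between the two arms, mirroring the two software stacks
commonly used for such analyses: the primary arm uses simple inverse-variance
weighted-median weights, normal p-values, and the J-dependent default IVW
variance model; the Steiger arm uses delta-method weighted-median weights,
t-based Egger p-values, and the multiplicative random-effects IVW model at
every J.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import click
import pandas as pd
import yaml

from . import __version__
from .harmonize import NoInstrumentsError, SelectionRules, write_drop_log
from .mr_estimators import (
    HeterogeneityResult,
    MrEstimate,
    egger,
    estimates_to_frame,
    ivw,
    weighted_median,
)
from .sensitivity import leave_one_out, loo_to_frame, single_snp_scan
from .steiger import SteigerFilterResult, steiger_filter, write_steiger_log
from .summary_io import (
    FIXTURE_PHENOTYPES,
    SummaryDataset,
    load_fixture,
    read_summary_table,
    write_summary_table,
)
from .synthetic_data import ScenarioConfig, simulate_pair

__all__ = [
    "AnalysisConfig",
    "AnalysisReport",
    "run_analysis",
    "run_all_fixture_analyses",
    "load_expected_estimates",
    "write_reverse_mr_template",
    "cli",
]

#: Cohort sizes used for Steiger-mode runs on the packaged fixtures.
EXPOSURE_N = 521_612
OUTCOME_N = 54_162


@dataclass
class AnalysisConfig:
    """One exposure-outcome analysis: sources, rules, and estimator settings.

    Sources are fixture keys (``"AS:exposure"``) or file paths.  When
    ``steiger_mode`` is on, palindromic dropping is forced, the directionality
    filter runs with ``n_exp``/``n_out``, and the Steiger-arm estimator
    conventions apply unless overridden.
    """

    label: str
    exposure_source: str
    outcome_source: str
    rules: SelectionRules = field(default_factory=SelectionRules)
    variance_model: str = "default"
    steiger_mode: bool = False
    n_exp: float | None = None
    n_out: float | None = None
    n_boot: int = 1000
    seed: int = 0
    output_dir: str | None = None
    wm_weighting: str | None = None
    egger_use_t: bool | None = None

    def __post_init__(self) -> None:
        if self.steiger_mode and (self.n_exp is None or self.n_out is None):
            raise ValueError("steiger_mode requires n_exp and n_out")

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        data = dict(data)
        if isinstance(data.get("rules"), dict):
            data["rules"] = SelectionRules.from_dict(data["rules"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class AnalysisReport:
    label: str
    config: AnalysisConfig
    instruments: list
    dropped: list[tuple[str, str]]
    steiger: SteigerFilterResult | None
    estimates: dict[str, MrEstimate]
    heterogeneity: HeterogeneityResult
    loo: list | None
    single_snp: list[MrEstimate]
    log: list[str]

    @property
    def n_snps(self) -> int:
        return len(self.instruments)

    def results_frame(self) -> pd.DataFrame:
        return estimates_to_frame(
            self.estimates.values(), analysis=self.label, heterogeneity=self.heterogeneity
        )


def _resolve_source(source: str, role: str) -> SummaryDataset:
    if ":" in source:
        name, _, src_role = source.partition(":")
        if name.upper() in FIXTURE_PHENOTYPES:
            return load_fixture(name, src_role or role)
    return read_summary_table(source, trait_label=Path(source).stem)


def run_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Execute one analysis end to end; see the module docstring for stages."""
    log: list[str] = [f"tsmr {__version__}: analysis {config.label!r}"]
    exposure = _resolve_source(config.exposure_source, "exposure")
    outcome = _resolve_source(config.outcome_source, "outcome")
    log.append(f"exposure {exposure.trait_label!r}: {len(exposure)} SNPs")
    log.append(f"outcome {outcome.trait_label!r}: {len(outcome)} SNPs")

    rules = config.rules
    if config.steiger_mode and not rules.drop_palindromic:
        rules = dataclasses.replace(rules, drop_palindromic=True)
        log.append("steiger_mode: forcing drop_palindromic=True")
    kept, dropped = select_instruments_logged(exposure, outcome, rules, log)

    steiger_result = None
    if config.steiger_mode:
        steiger_result = steiger_filter(kept, config.n_exp, config.n_out)
        for res in steiger_result.log:
            log.append(
                f"steiger {res.snp_id}: r2_exp={res.r2_exp:.3g} r2_out={res.r2_out:.3g} "
                f"z={res.z:.3f} kept={res.correct_direction}"
            )
        kept = steiger_result.kept
        if not kept:
            raise NoInstrumentsError("no_instruments")

    wm_weighting = config.wm_weighting or ("delta" if config.steiger_mode else "simple")
    egger_use_t = (
        config.egger_use_t
        if config.egger_use_t is not None
        else bool(config.steiger_mode)
    )

    est_ivw, heterogeneity = ivw(kept, variance_model=config.variance_model)
    log.append(
        f"ivw: variance_model={est_ivw.variance_model} scale={est_ivw.scale_factor:.4f} "
        f"seed={config.seed} n_boot={config.n_boot} wm_weighting={wm_weighting} "
        f"egger_use_t={egger_use_t}"
    )
    estimates: dict[str, MrEstimate] = {"ivw": est_ivw}
    if len(kept) >= 3:
        estimates["weighted_median"] = weighted_median(
            kept, n_boot=config.n_boot, seed=config.seed, weighting=wm_weighting
        )
        slope, intercept, _ = egger(kept, use_t=egger_use_t)
        estimates["egger_slope"] = slope
        estimates["egger_intercept"] = intercept

    loo = None
    if len(kept) >= 4:
        loo = leave_one_out(
            kept,
            variance_model=config.variance_model,
            n_boot=config.n_boot,
            seed=config.seed,
            wm_weighting=wm_weighting,
            egger_use_t=egger_use_t,
        )
    single = single_snp_scan(kept)

    report = AnalysisReport(
        label=config.label,
        config=config,
        instruments=kept,
        dropped=dropped,
        steiger=steiger_result,
        estimates=estimates,
        heterogeneity=heterogeneity,
        loo=loo,
        single_snp=single,
        log=log,
    )
    if config.output_dir:
        _write_report(report, Path(config.output_dir))
    return report


def select_instruments_logged(exposure, outcome, rules, log):
    from .harmonize import select_instruments

    kept, dropped = select_instruments(exposure, outcome, rules)
    for snp, reason in dropped:
        log.append(f"drop {snp}: {reason}")
    for inst in kept:
        notes = []
        if inst.flipped:
            notes.append("flipped")
        if inst.proxy_of:
            notes.append(f"proxy_for={inst.proxy_of}")
        if inst.palindromic:
            notes.append("palindromic")
        log.append(f"keep {inst.snp_id}" + (f" ({', '.join(notes)})" if notes else ""))
    return kept, dropped


def _write_report(report: AnalysisReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    label = report.label
    frame = report.results_frame()
    frame.to_csv(outdir / f"{label}_results.tsv", sep="\t", index=False)
    frame.to_json(outdir / f"{label}_results.json", orient="records", indent=2)
    write_drop_log(report.dropped, outdir / f"{label}_drops.tsv")
    if report.steiger is not None:
        write_steiger_log(report.steiger.log, outdir / f"{label}_steiger.tsv")
    if report.loo is not None:
        loo_to_frame(report.loo).to_csv(outdir / f"{label}_loo.tsv", sep="\t", index=False)
    single = estimates_to_frame(report.single_snp, analysis=label)
    single.insert(1, "snp_id", [inst.snp_id for inst in report.instruments])
    single.to_csv(outdir / f"{label}_single_snp.tsv", sep="\t", index=False)
    (outdir / f"{label}_run.log").write_text("\n".join(report.log) + "\n")


def _fixture_configs(seed: int, n_boot: int, output_dir: str | None):
    proxy_maps = {"AIS": {"rs6825454": "rs56010410"}}
    configs = []
    for phenotype in FIXTURE_PHENOTYPES:
        rules = SelectionRules(proxy_map=proxy_maps.get(phenotype, {}))
        configs.append(
            AnalysisConfig(
                label=phenotype,
                exposure_source=f"{phenotype}:exposure",
                outcome_source=f"{phenotype}:outcome",
                rules=rules,
                seed=seed,
                n_boot=n_boot,
                output_dir=output_dir,
            )
        )
        configs.append(
            AnalysisConfig(
                label=f"{phenotype}_steiger",
                exposure_source=f"{phenotype}:exposure",
                outcome_source=f"{phenotype}:outcome",
                rules=SelectionRules(
                    proxy_map=proxy_maps.get(phenotype, {}), drop_palindromic=True
                ),
                variance_model="random",
                steiger_mode=True,
                n_exp=EXPOSURE_N,
                n_out=OUTCOME_N,
                seed=seed,
                n_boot=n_boot,
                output_dir=output_dir,
            )
        )
    return configs


def load_expected_estimates() -> pd.DataFrame:
    """Published point values for the fixture analyses (comparison data file)."""
    from .summary_io import _fixture_path

    return pd.read_csv(_fixture_path("expected_estimates.tsv"), sep="\t")


@dataclass
class CombinedReport:
    reports: dict[str, AnalysisReport]
    comparison: pd.DataFrame

    @property
    def all_passed(self) -> bool:
        return bool(self.comparison["passed"].all())


def run_all_fixture_analyses(
    seed: int = 0, n_boot: int = 1000, output_dir: str | None = None
) -> CombinedReport:
    """Run the eight fixture analyses and compare against the expected table.

    Exact rows (betas, Q, deterministic p-values) are checked at printed
    precision (half a unit in the last printed decimal); bootstrap-dependent
    weighted-median p-values are checked within the tabulated tolerance.
    """
    reports = {
        cfg.label: run_analysis(cfg) for cfg in _fixture_configs(seed, n_boot, output_dir)
    }
    expected = load_expected_estimates()
    rows = []
    for _, exp_row in expected.iterrows():
        report = reports[exp_row["analysis"]]
        if exp_row["method"] == "heterogeneity":
            computed = (
                report.heterogeneity.q
                if exp_row["field"] == "q"
                else report.heterogeneity.pvalue
            )
        else:
            computed = getattr(report.estimates[exp_row["method"]], exp_row["field"])
        if pd.notna(exp_row["tol"]):
            passed = abs(computed - exp_row["expected"]) <= exp_row["tol"]
        else:
            half_ulp = 0.5 * 10.0 ** (-int(exp_row["decimals"])) + 1e-12
            passed = abs(computed - exp_row["expected"]) <= half_ulp
        rows.append(
            {
                "analysis": exp_row["analysis"],
                "method": exp_row["method"],
                "field": exp_row["field"],
                "expected": exp_row["expected"],
                "computed": computed,
                "passed": passed,
            }
        )
    comparison = pd.DataFrame(rows)
    if output_dir:
        comparison.to_csv(Path(output_dir) / "comparison.tsv", sep="\t", index=False)
    return CombinedReport(reports, comparison)


_REVERSE_TEMPLATE = """\
# Reverse-direction MR template: AD (exposure) against any-stroke (outcome).
# Transcribe the 14 genome-wide-significant AD SNPs into two summary tables
# with columns: snp, chr, ea, nea, eaf, beta, se, pval (TSV). rs9271192 is
# absent from typical outcome panels; its published proxy is rs9271162
# (r2 = 0.96), declared below. rs983392 and rs10792832 are excluded for
# outcome association (p < 0.05), leaving 12 instruments.
label: AD_to_AS
exposure_source: path/to/ad_exposure.tsv
outcome_source: path/to/as_outcome.tsv
rules:
  exposure_p_max: 5.0e-8
  outcome_p_min: 0.05
  drop_palindromic: false
  palindromic_eaf_window: [0.42, 0.58]
  explicit_exclusions: {}
  palindromic_exclusions: []
  proxy_map:
    rs9271192: rs9271162
variance_model: default
steiger_mode: false
n_boot: 1000
seed: 0
"""


def write_reverse_mr_template(path) -> None:
    """Write a documented YAML config template for the reverse-direction MR."""
    Path(path).write_text(_REVERSE_TEMPLATE)


@click.group()
@click.version_option(__version__)
def cli() -> None:
    """Two-sample Mendelian randomization from GWAS summary statistics."""


@cli.command("run")
@click.option("--config", "-c", "config_path", required=True, type=click.Path(exists=True))
@click.option("--seed", type=int, default=None, help="Override the config seed.")
@click.option("--out", type=click.Path(), default=None, help="Override output directory.")
def cli_run(config_path, seed, out):
    """Run one analysis from a YAML config."""
    config = AnalysisConfig.from_yaml(config_path)
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    if out is not None:
        config = dataclasses.replace(config, output_dir=out)
    report = run_analysis(config)
    click.echo(report.results_frame().to_string(index=False))


@cli.command("reproduce")
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--n-boot", type=int, default=1000, show_default=True)
@click.option("--out", type=click.Path(), default=None)
def cli_reproduce(seed, n_boot, out):
    """Run the packaged fixture suite and the published-value comparison."""
    combined = run_all_fixture_analyses(seed=seed, n_boot=n_boot, output_dir=out)
    click.echo(combined.comparison.to_string(index=False))
    n_pass = int(combined.comparison["passed"].sum())
    click.echo(f"{n_pass}/{len(combined.comparison)} comparisons passed")


@cli.command("simulate")
@click.option("--n-snps", type=int, default=50, show_default=True)
@click.option("--theta", type=float, default=0.0, show_default=True)
@click.option(
    "--pleiotropy-mode",
    type=click.Choice(["none", "balanced", "directional", "invalid_majority"]),
    default="none",
    show_default=True,
)
@click.option("--alpha-mean", type=float, default=0.0, show_default=True)
@click.option("--alpha-sd", type=float, default=0.0, show_default=True)
@click.option("--prop-invalid", type=float, default=0.0, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", type=click.Path(), required=True, help="Output file prefix.")
def cli_simulate(n_snps, theta, pleiotropy_mode, alpha_mean, alpha_sd, prop_invalid, seed, out):
    """Simulate a paired exposure/outcome dataset with known truth."""
    config = ScenarioConfig(
        n_snps=n_snps,
        theta=theta,
        pleiotropy_mode=pleiotropy_mode,
        alpha_mean=alpha_mean,
        alpha_sd=alpha_sd,
        prop_invalid=prop_invalid,
        seed=seed,
    )
    pair = simulate_pair(config)
    write_summary_table(pair.exposure, f"{out}_exposure.tsv")
    write_summary_table(pair.outcome, f"{out}_outcome.tsv")
    meta = {
        "theta": config.theta,
        "seed": config.seed,
        "generator": pair.truth["generator"],
        "pleiotropy_mode": config.pleiotropy_mode,
    }
    Path(f"{out}_truth.json").write_text(json.dumps(meta, indent=2))
    click.echo(f"wrote {out}_exposure.tsv, {out}_outcome.tsv, {out}_truth.json")


@cli.command("reverse-template")
@click.option("--out", type=click.Path(), required=True)
def cli_reverse_template(out):
    """Write the reverse-direction MR config template."""
    write_reverse_mr_template(out)
    click.echo(f"wrote {out}")
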