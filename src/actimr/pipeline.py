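"""Full-study orchestration: estimate grid, FDR family, report artefacts.

``run_full_analysis`` executes harmonisation, the configured estimators, and
diagnostics for every (instrument, outcome) cell, rescales milligravity-unit
instruments to per-SD estimates, applies Benjamini-Hochberg FDR across the
configured family of IVW tests, and serialises machine- and human-readable
report files.
"""

from __future__ import annotations

import csv
import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError, DomainError, UnknownInstrumentError
from .mr_estimators import (
    MrResult,
    SD_MILLIGRAVITY,
    ivw,
    mr_egger,
    scale_to_sd,
    wald_ratios,
    weighted_median,
)
from .pleiotropy import leave_one_out, mr_presso
from .summary_stats import (
    Instrument,
    builtin_instrument,
    harmonise,
    read_summary_stats,
)

KNOWN_METHODS = ("ivw", "egger", "wmedian")


def bh_fdr(pvalues) -> list[float]:
    """Benjamini-Hochberg q-values, order-preserving with the input.

    q_i = min over j with p_j >= p_i of p_j * m / rank_j, the standard
    step-up monotonisation.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise DomainError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q.tolist()


@dataclass
class InstrumentSpec:
    """Either a built-in instrument name or a file + unit + dialect."""

    name: str
    path: str | None = None
    exposure_unit: str = "sd"
    r2_formula: str = "from_se"
    dialect: dict | None = None

    def load(self) -> Instrument:
        if self.path is None:
            return builtin_instrument(self.name)
        variants = read_summary_stats(self.path, dialect=self.dialect)
        return Instrument(
            name=self.name,
            variants=variants,
            exposure_unit=self.exposure_unit,
            r2_formula=self.r2_formula,
        )


@dataclass
class OutcomeSpec:
    label: str
    path: str
    dialect: dict | None = None


@dataclass
class AnalysisConfig:
    instruments: list[InstrumentSpec]
    outcomes: list[OutcomeSpec]
    methods: tuple[str, ...] = ("ivw", "egger", "wmedian")
    effects: str = "auto"
    sd_units: float = SD_MILLIGRAVITY
    n_boot: int = 10_000
    run_presso: bool = False
    presso_n_sim: int = 5_000
    seed: int = 0
    palindrome_policy: str = "infer_by_eaf"
    fdr_family: list[tuple[str, str, str]] | None = None  # default: all IVW cells
    out_dir: str | None = None

    def __post_init__(self) -> None:
        for m in self.methods:
            if m not in KNOWN_METHODS:
                raise ConfigurationError(f"unknown method {m!r}; known {KNOWN_METHODS}")
        labels = [o.label for o in self.outcomes]
        if len(set(labels)) != len(labels):
            raise ConfigurationError("outcome labels must be unique")
        names = [i.name for i in self.instruments]
        if len(set(names)) != len(names):
            raise ConfigurationError("instrument names must be unique")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        instruments = [InstrumentSpec(**spec) for spec in raw.get("instruments", [])]
        outcomes = [OutcomeSpec(**spec) for spec in raw.get("outcomes", [])]
        kwargs = {
            k: raw[k]
            for k in (
                "effects", "sd_units", "n_boot", "run_presso", "presso_n_sim",
                "seed", "palindrome_policy", "out_dir",
            )
            if k in raw
        }
        if "methods" in raw:
            kwargs["methods"] = tuple(raw["methods"])
        if "fdr_family" in raw:
            kwargs["fdr_family"] = [tuple(cell) for cell in raw["fdr_family"]]
        return cls(instruments=instruments, outcomes=outcomes, **kwargs)


@dataclass
class CellResult:
    instrument: str
    outcome: str
    results: dict[str, MrResult]  # method key -> result (SD scale)
    ratios: list  # per-SNP RatioEstimate, SD scale
    dropped: list[tuple[str, str]]
    snp_effects: list[tuple[str, float, float]] = field(default_factory=list)  # (rsid, beta_X, beta_Y)
    loo: list[tuple[str, MrResult]] | None = None
    presso: object | None = None
    qvalues: dict[str, float] = field(default_factory=dict)
    failed: str | None = None  # reason code


@dataclass
class AnalysisReport:
    cells: dict[tuple[str, str], CellResult]
    config_hash: str
    seed: int
    version: str = "0.1.0"

    def cell(self, instrument: str, outcome: str) -> CellResult:
        try:
            return self.cells[(instrument, outcome)]
        except KeyError:
            raise UnknownInstrumentError(
                f"no cell ({instrument}, {outcome}) in report"
            ) from None


def _cell_seed(master: int, instrument: str, outcome: str, purpose: str) -> int:
    """Stable per-cell seed derived from the master seed."""
    digest = hashlib.sha256(
        f"{master}:{instrument}:{outcome}:{purpose}".encode()
    ).digest()
    return int.from_bytes(digest[:4], "big")


def run_full_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Run the configured estimate grid and FDR family; write report files."""
    outcome_data = {o.label: read_summary_stats(o.path, o.dialect) for o in config.outcomes}
    cells: dict[tuple[str, str], CellResult] = {}
    for ispec in config.instruments:
        instrument = ispec.load()
        sd = config.sd_units if instrument.exposure_unit == "milligravity" else 1.0
        for label, records in outcome_data.items():
            cells[(instrument.name, label)] = _run_cell(
                config, instrument, label, records, sd
            )

    family = config.fdr_family
    if family is None:
        family = [
            (i.name, o.label, "ivw") for i in config.instruments for o in config.outcomes
        ]
    keys, ps = [], []
    for inst, out, method in family:
        cell = cells.get((inst, out))
        if cell is None or cell.failed or method not in cell.results:
            continue
        keys.append((inst, out, method))
        # p-values can underflow to exactly 0; clamp to the smallest positive
        ps.append(max(cell.results[method].pvalue, 5e-324))
    for (inst, out, method), q in zip(keys, bh_fdr(ps)):
        cells[(inst, out)].qvalues[method] = q

    report = AnalysisReport(
        cells=cells,
        config_hash=hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        seed=config.seed,
    )
    if config.out_dir is not None:
        write_report(report, config.out_dir)
    return report


def _run_cell(config, instrument, label, records, sd) -> CellResult:
    name = instrument.name
    try:
        harmonised = harmonise(
            instrument.variants, records, palindrome_policy=config.palindrome_policy,
            outcome_name=label,
        )
    except Exception as exc:  # failed cells never abort the run
        return CellResult(name, label, {}, [], [], failed=f"harmonise: {exc}")
    ratios = wald_ratios(harmonised, label)
    if len(ratios) < 2:
        return CellResult(
            name, label, {}, [], harmonised.dropped, failed="fewer_than_2_snps"
        )
    results: dict[str, MrResult] = {}
    if "ivw" in config.methods:
        results["ivw"] = scale_to_sd(ivw(ratios, effects=config.effects), sd)
    if "egger" in config.methods and len(ratios) >= 3:
        results["egger"] = scale_to_sd(mr_egger(harmonised, label), sd)
    if "wmedian" in config.methods and len(ratios) >= 3:
        results["wmedian"] = scale_to_sd(
            weighted_median(
                harmonised, label, n_boot=config.n_boot,
                seed=_cell_seed(config.seed, name, label, "wmedian"),
            ),
            sd,
        )
    loo = None
    if len(ratios) >= 3:
        loo = [
            (rsid, scale_to_sd(res, sd)) for rsid, res in leave_one_out(harmonised, label)
        ]
    presso = None
    if config.run_presso and len(ratios) >= 4:
        presso = mr_presso(
            harmonised, label, n_sim=config.presso_n_sim,
            seed=_cell_seed(config.seed, name, label, "presso"),
        )
    from dataclasses import replace as dc_replace

    scaled_ratios = [
        dc_replace(r, theta=r.theta * sd, se_theta=r.se_theta * sd) for r in ratios
    ]
    return CellResult(
        instrument=name, outcome=label, results=results, ratios=scaled_ratios,
        dropped=harmonised.dropped, loo=loo, presso=presso,
        snp_effects=[
            (v.rsid, v.exposure.beta, v.outcomes[label].beta)
            for v in harmonised.variants
        ],
    )


# ---------------------------------------------------------------------------
# Serialisation


def _result_to_dict(res: MrResult) -> dict:
    return {
        "method": res.method,
        "beta": res.beta,
        "se": res.se,
        "or": res.or_,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "pvalue": res.pvalue,
        "n_snps": res.n_snps,
        "effects_model": res.effects_model,
        "q_stat": res.q_stat,
        "q_df": res.q_df,
        "q_pvalue": res.q_pvalue,
        "i2": res.i2,
        "egger_intercept": res.egger_intercept,
        "egger_intercept_se": res.egger_intercept_se,
        "egger_intercept_p": res.egger_intercept_p,
        "degenerate": res.degenerate,
    }


def write_report(report: AnalysisReport, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {
        "provenance": {
            "config_hash": report.config_hash,
            "seed": report.seed,
            "version": report.version,
        },
        "cells": [],
    }
    for (inst, label), cell in sorted(report.cells.items()):
        entry = {
            "instrument": inst,
            "outcome": label,
            "failed": cell.failed,
            "dropped": cell.dropped,
            "qvalues": cell.qvalues,
            "results": {k: _result_to_dict(v) for k, v in cell.results.items()},
        }
        if cell.presso is not None:
            entry["presso"] = {
                "global_pvalue": cell.presso.global_pvalue,
                "outliers": cell.presso.outlier_rsids,
                "distortion_pvalue": cell.presso.distortion_pvalue,
            }
        payload["cells"].append(entry)
        if not cell.failed:
            _write_ratios(cell, out / f"ratios_{inst}_{label}.tsv")
    with open(out / "report.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    _write_table(report, out / "table1.csv")


def _write_ratios(cell: CellResult, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["SNP", "theta", "se", "ci_low", "ci_high"])
        for r in cell.ratios:
            writer.writerow(
                [r.rsid, format(r.theta, ".12g"), format(r.se_theta, ".12g"),
                 format(r.theta - 1.959964 * r.se_theta, ".12g"),
                 format(r.theta + 1.959964 * r.se_theta, ".12g")]
            )


def _round2sf(x: float) -> str:
    if x == 0 or not math.isfinite(x):
        return str(x)
    return format(x, f".{max(0, 1 - int(math.floor(math.log10(abs(x)))))}f") if abs(x) >= 1e-4 else format(x, ".2g")


def _write_table(report: AnalysisReport, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(
            ["instrument", "outcome", "method", "OR", "ci_low", "ci_high",
             "pvalue", "qvalue", "het_or_pleio_p"]
        )
        for (inst, label), cell in sorted(report.cells.items()):
            if cell.failed:
                writer.writerow([inst, label, "-", "-", "-", "-", "-", "-", cell.failed])
                continue
            for key, res in cell.results.items():
                diag = (
                    res.egger_intercept_p if key == "egger" else res.q_pvalue
                )
                writer.writerow(
                    [inst, label, res.method,
                     _round2sf(res.or_), _round2sf(res.ci_low), _round2sf(res.ci_high),
                     _round2sf(res.pvalue),
                     _round2sf(cell.qvalues[key]) if key in cell.qvalues else "",
                     _round2sf(diag) if diag is not None else ""]
                )


def export_plot_data(
    report: AnalysisReport, instrument: str, outcome: str, kind: str
):
    """Tabular data behind standard MR figures for one cell.

    Kinds: ``forest`` (per-SNP log OR + CI + pooled row), ``funnel``
    ((theta, 1/se) pairs + pooled vertical), ``scatter`` ((beta_X, beta_Y)
    with per-method slopes), ``loo`` (per-exclusion estimates).  Returns a
    list of header + rows.
    """
    cell = report.cell(instrument, outcome)
    if cell.failed:
        raise UnknownInstrumentError(f"cell ({instrument}, {outcome}) failed")
    if kind == "forest":
        rows = [["label", "theta", "ci_low", "ci_high"]]
        for r in sorted(cell.ratios, key=lambda r: r.rsid):
            rows.append(
                [r.rsid, r.theta, r.theta - 1.959964 * r.se_theta,
                 r.theta + 1.959964 * r.se_theta]
            )
        pooled = cell.results["ivw"]
        rows.append(["pooled_ivw", pooled.beta, pooled.beta - 1.959964 * pooled.se,
                     pooled.beta + 1.959964 * pooled.se])
        return rows
    if kind == "funnel":
        rows = [["theta", "precision"]]
        for r in sorted(cell.ratios, key=lambda r: r.rsid):
            rows.append([r.theta, 1.0 / r.se_theta])
        rows.append(["pooled_ivw", cell.results["ivw"].beta])
        return rows
    if kind == "scatter":
        rows = [["kind", "a", "b", "c"]]
        for rsid, bx, by in cell.snp_effects:
            rows.append(["point", rsid, bx, by])
        for key, res in cell.results.items():
            intercept = res.egger_intercept if key == "egger" else 0.0
            rows.append(["slope", key, res.beta, intercept])
        return rows
    if kind == "loo":
        if cell.loo is None:
            raise UnknownInstrumentError("no leave-one-out data in this cell")
        rows = [["excluded", "beta", "ci_low", "ci_high"]]
        for rsid, res in cell.loo:
            rows.append([rsid, res.beta, res.beta - 1.959964 * res.se,
                         res.beta + 1.959964 * res.se])
        return rows
    raise UnknownInstrumentError(f"unknown plot kind {kind!r}")
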