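"""Run the full bidirectional MR analysis from a single configuration.

Each configured direction goes select -> clump -> harmonise -> estimate
(all configured methods) -> diagnose, producing a consolidated forest
table (one row per direction x method) plus a per-direction diagnostics
directory, and a JSON-lines audit trail recording every SNP-level
decision (drops, SIMEX trigger, PRESSO outliers).
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diagnostics as diag
from . import estimators as est
from . import summary_data as sd

__all__ = ["DirectionConfig", "AnalysisConfig", "run_bidirectional", "report"]

KNOWN_METHODS = ("ivw", "egger", "weighted_median", "weighted_mode")
KNOWN_DIAGNOSTICS = ("q", "i2gx", "simex", "presso", "loo", "funnel")


@dataclass
class DirectionConfig:
    name: str
    exposure_file: str
    outcome_file: str
    exposure_column_map: dict | None = None
    outcome_column_map: dict | None = None
    p_instrument: float = 5e-8
    clump_r2: float = 0.001
    clump_kb: float = 10_000
    maf_limit: float = 0.3
    proxy_r2: float = 0.8
    use_proxies: bool = False
    ld_file: str | None = None
    binary_outcome: bool = False


@dataclass
class AnalysisConfig:
    directions: list = field(default_factory=list)
    methods: tuple = KNOWN_METHODS
    diagnostics: tuple = ("q", "i2gx", "simex", "presso", "loo", "funnel")
    n_boot: int = 1000
    n_sim: int = 1000
    seed: int | None = None
    out_dir: str = "results"

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory (stochastic steps must be reproducible)")
        unknown = [m for m in self.methods if m not in KNOWN_METHODS]
        if unknown:
            raise ValueError(f"unknown method(s): {', '.join(unknown)}; know {KNOWN_METHODS}")
        unknown = [d for d in self.diagnostics if d not in KNOWN_DIAGNOSTICS]
        if unknown:
            raise ValueError(
                f"unknown diagnostic(s): {', '.join(unknown)}; know {KNOWN_DIAGNOSTICS}"
            )
        if not self.directions:
            raise ValueError("no directions configured")
        for d in self.directions:
            for path in (d.exposure_file, d.outcome_file):
                if not Path(path).exists():
                    raise FileNotFoundError(f"direction {d.name!r}: {path} does not exist")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        directions = [DirectionConfig(**d) for d in raw.pop("directions", [])]
        cfg = cls(directions=directions, **{k: v for k, v in raw.items()})
        if isinstance(cfg.methods, list):
            cfg.methods = tuple(cfg.methods)
        if isinstance(cfg.diagnostics, list):
            cfg.diagnostics = tuple(cfg.diagnostics)
        return cfg


class _Audit:
    """Timestamped key-value log: stderr lines plus a JSON-lines file."""

    def __init__(self, path: Path):
        self._fh = open(path, "w")

    def log(self, event: str, **kv) -> None:
        record = {"t": time.strftime("%Y-%m-%dT%H:%M:%S"), "event": event, **kv}
        print(" ".join(f"{k}={v}" for k, v in record.items()), file=sys.stderr)
        self._fh.write(json.dumps(record, default=str) + "\n")

    def close(self) -> None:
        self._fh.close()


def _estimate_direction(instr, methods, n_boot, seed) -> list[est.MREstimate]:
    out = []
    for i, method in enumerate(methods):
        if method == "ivw":
            out.append(est.ivw(instr))
        elif method == "egger":
            out.append(est.egger(instr))
        elif method == "weighted_median":
            out.append(est.weighted_median(instr, n_boot=n_boot, seed=seed + 11 * i))
        elif method == "weighted_mode":
            out.append(est.weighted_mode(instr, n_boot=n_boot, seed=seed + 11 * i))
    return out


def run_bidirectional(config: AnalysisConfig):
    """Execute every configured direction; failures abort that direction only.

    Returns ``(forest_table, diagnostics_bundle)`` and writes
    ``forest.tsv``, per-direction harmonised tables and diagnostic TSVs,
    and an ``audit.jsonl`` under ``config.out_dir``.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    audit = _Audit(out_dir / "audit.jsonl")
    forest_rows = []
    bundle: dict[str, dict] = {}
    failures: dict[str, str] = {}

    for direction in config.directions:
        try:
            d_out = out_dir / direction.name
            d_out.mkdir(exist_ok=True)
            audit.log("direction_start", direction=direction.name)
            exposure = sd.read_summary_stats(
                direction.exposure_file, direction.exposure_column_map
            )
            outcome = sd.read_summary_stats(direction.outcome_file, direction.outcome_column_map)
            selected = sd.select_instruments(exposure, direction.p_instrument)
            audit.log(
                "instruments_selected",
                direction=direction.name,
                n_in=len(exposure),
                n_selected=len(selected),
                p_threshold=direction.p_instrument,
            )
            ld = sd.LDTable.from_table(direction.ld_file) if direction.ld_file else None
            clumped = sd.clump(selected, ld, direction.clump_r2, direction.clump_kb)
            audit.log("clumped", direction=direction.name, n_kept=len(clumped))
            harm = sd.harmonise(
                clumped,
                outcome,
                direction.maf_limit,
                use_proxies=direction.use_proxies,
                ld=ld,
                proxy_r2_min=direction.proxy_r2,
            )
            harm.to_csv(d_out / "harmonised.tsv", sep="\t", index=False)
            for action, count in harm["action"].value_counts().items():
                audit.log("harmonise_action", direction=direction.name, action=action, n=int(count))
            instr = sd.retained(harm)
            if instr.empty:
                raise ValueError("no instruments retained after harmonisation")

            estimates = _estimate_direction(instr, config.methods, config.n_boot, config.seed)
            diagnostics = _run_diagnostics(instr, config, audit, direction.name)
            if "simex_estimate" in diagnostics:
                estimates.append(diagnostics["simex_estimate"])

            for e in estimates:
                row = {"direction": direction.name, **e.to_dict()}
                if direction.binary_outcome:
                    row.update(e.exponentiate())
                forest_rows.append(row)
            _write_diagnostics(diagnostics, d_out)
            bundle[direction.name] = diagnostics
            audit.log("direction_done", direction=direction.name)
        except Exception as exc:  # direction-level isolation
            audit.log("direction_failed", direction=direction.name, error=str(exc))
            failures[direction.name] = str(exc)

    forest = pd.DataFrame(forest_rows)
    forest.to_csv(out_dir / "forest.tsv", sep="\t", index=False)
    audit.close()
    bundle["_failures"] = failures
    return forest, bundle


def _run_diagnostics(instr, config: AnalysisConfig, audit: _Audit, name: str) -> dict:
    results: dict = {}
    if "q" in config.diagnostics:
        results["heterogeneity"] = diag.cochran_q(instr)
    if "i2gx" in config.diagnostics or "simex" in config.diagnostics:
        nome = diag.i2_gx(instr)
        results["nome"] = nome
        audit.log("i2gx", direction=name, i2_gx=nome.i2_gx, simex_triggered=nome.simex_triggered)
        if "simex" in config.diagnostics and nome.simex_triggered and len(instr) >= 3:
            results["simex_estimate"] = diag.egger_simex(
                instr, B=max(100, config.n_boot), seed=config.seed + 101
            )
    if "presso" in config.diagnostics and len(instr) >= 4:
        presso = diag.mr_presso(instr, n_sim=config.n_sim, seed=config.seed + 202)
        results["presso"] = presso
        audit.log(
            "presso",
            direction=name,
            global_pval=presso.global_pval,
            outliers=",".join(presso.outliers) or "-",
        )
    if "loo" in config.diagnostics and len(instr) >= 3:
        results["leave_one_out"] = diag.leave_one_out(instr)
    if "funnel" in config.diagnostics:
        results["funnel"] = diag.funnel_data(instr)
    return results


def _write_diagnostics(results: dict, d_out: Path) -> None:
    if "heterogeneity" in results:
        pd.DataFrame([asdict(results["heterogeneity"])]).to_csv(
            d_out / "heterogeneity.tsv", sep="\t", index=False
        )
    if "nome" in results:
        pd.DataFrame([asdict(results["nome"])]).to_csv(d_out / "nome.tsv", sep="\t", index=False)
    if "presso" in results:
        p = results["presso"]
        pd.DataFrame(
            [
                {
                    "global_rss": p.global_rss,
                    "global_pval": p.global_pval,
                    "outliers": ",".join(p.outliers),
                    "distortion_pval": p.distortion_pval,
                    "corrected_beta": p.corrected.beta if p.corrected else np.nan,
                    "report_corrected": p.report_corrected,
                }
            ]
        ).to_csv(d_out / "presso.tsv", sep="\t", index=False)
    if "leave_one_out" in results:
        results["leave_one_out"].to_csv(d_out / "leave_one_out.tsv", sep="\t", index=False)
    if "funnel" in results:
        results["funnel"].table.to_csv(d_out / "funnel.tsv", sep="\t", index=False)


def report(forest: pd.DataFrame, bundle: dict) -> str:
    """Human-readable Markdown summary of a completed run."""
    lines = ["# Bidirectional MR analysis summary", ""]
    if forest.empty:
        lines.append("No direction completed.")
    for direction in forest.get("direction", pd.Series(dtype=str)).unique():
        sub = forest.loc[forest["direction"] == direction]
        lines.append(f"## {direction}")
        lines.append("")
        lines.append("| method | n SNP | beta | 95% CI | p |")
        lines.append("|---|---|---|---|---|")
        for _, row in sub.iterrows():
            lines.append(
                f"| {row['method']} | {int(row['n_snp'])} | {row['beta']:.4f} | "
                f"({row['ci_low']:.4f}, {row['ci_high']:.4f}) | {row['pval']:.3g} |"
            )
        lines.append("")
        d = bundle.get(direction, {})
        if not d:
            lines.append("No diagnostics requested.")
        if "heterogeneity" in d:
            h = d["heterogeneity"]
            lines.append(
                f"- Cochran's Q = {h.Q:.2f} (df {h.df}, p = {h.pval:.3g}), I2 = {h.i2:.2f}"
            )
        if "nome" in d:
            nome = d["nome"]
            note = "SIMEX correction was applied" if nome.simex_triggered else "SIMEX not required"
            lines.append(f"- I2_GX = {nome.i2_gx:.3f}; {note}")
        if "presso" in d:
            p = d["presso"]
            if p.outliers:
                lines.append(
                    f"- MR-PRESSO outliers: {', '.join(p.outliers)} "
                    f"(global p = {p.global_pval:.3g}, distortion p = {p.distortion_pval:.3g})"
                )
            else:
                lines.append(f"- MR-PRESSO: no outliers (global p = {p.global_pval:.3g})")
        lines.append("")
    failures = bundle.get("_failures", {})
    for name, err in failures.items():
        lines.append(f"**Direction {name} failed:** {err}")
    return "\n".join(lines)
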