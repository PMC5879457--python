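"""End-to-end pipeline: simulate a study, analyse it, benchmark recovery.

``run_simulate`` writes a complete synthetic dataset (design JSON, roster,
ground-truth parameters, one waveform CSV per animal x PEEP, pooled qPCR CT
table, BAL differential counts) plus a manifest with SHA-256 checksums.
``run_analyze`` re-reads the dataset through the manifest and produces
impedance tables, R/E spectra, per-animal fits, treatment x PEEP ANOVA and
Holm-Sidak pairwise tables per parameter and day, ddCT fold-expression and
differential-fraction tables, and a plain-text report of significant
treatment effects.  ``run_recovery_benchmark`` runs the
synthesize -> estimate -> fit round trip over a parameter grid and tabulates
true-vs-estimated relative errors.

All randomness flows from one root seed through named substreams, so every
output is byte-identical given (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import bal_analytics, group_stats, impedance, mechfit, synthetic_data
from .synthetic_data import (
    DEFAULT_BASE_PARAMS,
    DEFAULT_FREQUENCIES,
    EffectTemplate,
    MechParams,
    StudyDesign,
    WaveformRecord,
    build_design,
    default_effect_template,
)

__all__ = [
    "PipelineConfig",
    "ConfigError",
    "run_simulate",
    "run_analyze",
    "run_recovery_benchmark",
    "substream",
]

log = logging.getLogger("fotmech")


class ConfigError(ValueError):
    """Invalid pipeline configuration; message lists field-level problems."""


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent random substream derived from the root seed."""
    digest = hashlib.sha256(name.encode()).digest()
    key = int.from_bytes(digest[:4], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, key]))


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved configuration of one pipeline run; JSON-serialisable."""

    treatments: tuple[str, ...] = ("HBSS", "CB", "AgNP")
    doses: tuple[tuple[str, float], ...] = (("high", 0.5),)
    days: tuple[int, ...] = (1, 3, 7)
    peeps: tuple[float, ...] = (0.0, 1.0, 3.0, 6.0)
    n_per_group: int = 5
    base_params: Mapping[str, float] = field(
        default_factory=lambda: DEFAULT_BASE_PARAMS.as_dict()
    )
    cv: float = 0.15
    freqs: tuple[float, ...] = DEFAULT_FREQUENCIES
    duration: float = 8.0
    sample_rate: float = 256.0
    noise_sd: float = 0.05
    ct_noise_sd: float = 0.1
    total_cells: int = 200
    coherence_threshold: float = 0.9
    alpha: float = 0.05
    compare_peep: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        problems: list[str] = []
        if not self.treatments:
            problems.append("treatments: must be non-empty")
        if not (1 <= self.n_per_group <= 1000):
            problems.append(f"n_per_group: {self.n_per_group} outside [1, 1000]")
        if not (0.0 <= self.cv <= 0.5):
            problems.append(f"cv: {self.cv} outside [0, 0.5]")
        if self.duration <= 0:
            problems.append(f"duration: {self.duration} must be positive")
        if self.sample_rate <= 0:
            problems.append(f"sample_rate: {self.sample_rate} must be positive")
        if any(f <= 0 or f >= self.sample_rate / 2 for f in self.freqs):
            problems.append("freqs: every frequency must lie in (0, sample_rate/2)")
        if not (0.0 <= self.coherence_threshold <= 1.0):
            problems.append(f"coherence_threshold: {self.coherence_threshold} outside [0, 1]")
        if not (0.0 < self.alpha < 1.0):
            problems.append(f"alpha: {self.alpha} outside (0, 1)")
        if self.noise_sd < 0 or self.ct_noise_sd < 0:
            problems.append("noise_sd / ct_noise_sd: must be non-negative")
        if self.compare_peep not in self.peeps:
            problems.append(f"compare_peep: {self.compare_peep} not among peeps {self.peeps}")
        try:
            MechParams(**dict(self.base_params))
        except (TypeError, ValueError) as exc:
            problems.append(f"base_params: {exc}")
        if problems:
            raise ConfigError("invalid configuration:\n  " + "\n  ".join(problems))

    def base(self) -> MechParams:
        return MechParams(**dict(self.base_params))

    def design(self) -> StudyDesign:
        return build_design(
            treatments=self.treatments,
            doses=self.doses,
            days=self.days,
            peeps=self.peeps,
            n_per_group=self.n_per_group,
            seed=self.seed,
        )

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["base_params"] = dict(d["base_params"])
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        raw = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        for key in ("treatments", "days", "peeps", "freqs"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "doses" in raw:
            raw["doses"] = tuple((str(l), float(v)) for l, v in raw["doses"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, lineterminator="\n", float_format="%.10g")


def _write_manifest(out: Path, files: list[Path]) -> None:
    manifest = {
        "files": {str(p.relative_to(out)): _sha256(p) for p in sorted(files)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def run_simulate(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Generate and write the full synthetic dataset; returns the dataset dir."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "waveforms").mkdir(exist_ok=True)
    files: list[Path] = []

    design = config.design()
    template = default_effect_template()
    truth = synthetic_data.sample_animal_params(
        design, template, config.base(), config.cv, rng=substream(config.seed, "animal-params")
    )

    cfg_path = out / "config_resolved.json"
    cfg_path.write_text(config.to_json() + "\n")
    files.append(cfg_path)

    design_path = out / "design.json"
    design_path.write_text(
        json.dumps(
            {
                "treatments": list(design.treatments),
                "doses": [[l, v] for l, v in design.doses],
                "days": list(design.days),
                "peeps": list(design.peeps),
                "n_per_group": design.n_per_group,
                "seed": design.seed,
            },
            indent=2,
        )
        + "\n"
    )
    files.append(design_path)

    roster_path = out / "roster.csv"
    _write_csv(design.roster, roster_path)
    files.append(roster_path)

    truth_rows = [{"animal_id": aid, **p.as_dict(), "a_over_c": p.a_over_c} for aid, p in truth.items()]
    truth_path = out / "truth_params.csv"
    _write_csv(pd.DataFrame(truth_rows), truth_path)
    files.append(truth_path)

    wf_rng = substream(config.seed, "waveforms")
    for row in design.roster.itertuples(index=False):
        for peep in design.peeps:
            rec = synthetic_data.synthesize_waveform(
                truth[row.animal_id],
                peep=peep,
                freqs=config.freqs,
                duration=config.duration,
                sample_rate=config.sample_rate,
                noise_sd=config.noise_sd,
                rng=wf_rng,
                animal_id=row.animal_id,
            )
            path = out / "waveforms" / f"{row.animal_id}_peep{peep:g}.csv"
            _write_csv(rec.to_frame(), path)
            files.append(path)

    ct = synthetic_data.simulate_ct_table(
        design, template, ct_noise_sd=config.ct_noise_sd, rng=substream(config.seed, "qpcr")
    )
    ct_path = out / "ct_table.csv"
    _write_csv(ct, ct_path)
    files.append(ct_path)

    diff = synthetic_data.simulate_differentials(
        design, template, total_cells=config.total_cells, rng=substream(config.seed, "differentials")
    )
    diff_path = out / "differentials.csv"
    _write_csv(diff, diff_path)
    files.append(diff_path)

    _write_manifest(out, files)
    log.info("simulated dataset: %d animals, %d waveform files -> %s",
             len(design.roster), len(design.roster) * len(design.peeps), out)
    return out


def _load_dataset(dataset_dir: Path) -> tuple[PipelineConfig, pd.DataFrame, dict]:
    manifest_path = dataset_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {dataset_dir}")
    manifest = json.loads(manifest_path.read_text())
    for rel in manifest["files"]:
        if not (dataset_dir / rel).exists():
            raise FileNotFoundError(f"dataset file listed in manifest is missing: {rel}")
    config = PipelineConfig.from_json((dataset_dir / "config_resolved.json").read_text())
    roster = pd.read_csv(dataset_dir / "roster.csv")
    return config, roster, manifest


def run_analyze(dataset_dir: str | Path, out_dir: str | Path) -> Path:
    """Analyse a simulated dataset end to end; returns the results dir."""
    dataset_dir = Path(dataset_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config, roster, _ = _load_dataset(dataset_dir)

    imp_rows, spec_rows, fit_rows = [], [], []
    failures: list[str] = []
    for row in roster.itertuples(index=False):
        for peep in config.peeps:
            name = f"{row.animal_id}_peep{peep:g}.csv"
            path = dataset_dir / "waveforms" / name
            if not path.exists():
                raise FileNotFoundError(f"missing waveform file: {name}")
            try:
                rec = WaveformRecord.from_frame(pd.read_csv(path), row.animal_id, peep)
                spec = impedance.estimate_impedance(rec, config.freqs)
                spec = impedance.filter_by_coherence(spec, config.coherence_threshold)
                re_spec = impedance.spectra_from_impedance(spec)
                fit = mechfit.fit_animal(spec)
            except Exception as exc:  # isolate per-animal failures
                failures.append(f"{row.animal_id} @ PEEP {peep:g}: {exc}")
                continue
            imp_rows.append(spec.to_frame())
            spec_rows.append(re_spec.to_frame())
            rec_row = fit.to_row()
            rec_row.update(treatment=row.treatment, dose_label=row.dose_label, day=row.day)
            fit_rows.append(rec_row)

    if not fit_rows:
        raise RuntimeError("no animal could be analysed; first failure: " + failures[0])
    imp_table = pd.concat(imp_rows, ignore_index=True)
    spec_table = pd.concat(spec_rows, ignore_index=True)
    fit_table = pd.DataFrame(fit_rows)
    _write_csv(imp_table, out / "impedance.csv")
    _write_csv(spec_table, out / "spectra.csv")
    _write_csv(fit_table, out / "fits.csv")

    # per-day treatment x PEEP comparison of the five reported parameters
    anova_rows, pair_rows = [], []
    report_lines = ["Forced-oscillation study report", "=" * 33, ""]
    if failures:
        report_lines.append(f"Skipped {len(failures)} animal-records (see failures below).")
    converged = fit_table[fit_table["converged"]]
    for day in sorted(fit_table["day"].unique()):
        day_table = converged[converged["day"] == day]
        report_lines.append(f"Day {day}:")
        try:
            report = group_stats.compare_parameters(
                day_table, alpha=config.alpha, peep=config.compare_peep
            )
        except ValueError as exc:
            report_lines.append(f"  comparison unavailable: {exc}")
            continue
        any_flag = False
        for param, entry in report.items():
            aov: group_stats.AnovaResult = entry["anova"]
            for effect in aov.table.index[:-1]:
                anova_rows.append(
                    {
                        "day": day, "parameter": param, "effect": effect,
                        **aov.table.loc[effect].to_dict(),
                    }
                )
            for pw in entry["pairwise"]:
                pair_rows.append(
                    {
                        "day": day, "parameter": param, "comparison": pw.label,
                        "p_raw": pw.p_raw, "p_adjusted": pw.p_adjusted,
                        "significant": pw.significant,
                    }
                )
                if pw.significant:
                    any_flag = True
                    report_lines.append(
                        f"  * {param}: {pw.label} significant "
                        f"(adj p = {pw.p_adjusted:.4g}) at PEEP {config.compare_peep:g}"
                    )
        if not any_flag:
            report_lines.append("  no significant treatment differences")
        report_lines.append("")
    _write_csv(pd.DataFrame(anova_rows), out / "anova.csv")
    _write_csv(pd.DataFrame(pair_rows), out / "pairwise.csv")

    # BAL analytics
    ct = pd.read_csv(dataset_dir / "ct_table.csv")
    fold_frames = []
    for day in sorted(ct["day"].unique()):
        ct_day = ct[ct["day"] == day]
        control_groups = ct_day.loc[ct_day["treatment"] == "HBSS", "group"].unique()
        if len(control_groups) == 0:
            continue
        for dose_label in ct_day["dose_label"].unique():
            sub = ct_day[ct_day["dose_label"] == dose_label]
            control = f"HBSS-{dose_label}-d{day}"
            if control not in set(sub["group"]):
                continue
            folds = bal_analytics.ddct_fold_expression(sub, control_label=control)
            folds.insert(1, "day", day)
            fold_frames.append(folds)
    if fold_frames:
        _write_csv(pd.concat(fold_frames, ignore_index=True), out / "ddct_folds.csv")

    diff = pd.read_csv(dataset_dir / "differentials.csv")
    fractions, _summary = bal_analytics.differential_fractions(diff)
    _write_csv(fractions, out / "differential_fractions.csv")

    n_records = len(fit_table)
    report_lines.append(
        f"Fits: {n_records} records analysed, {int(fit_table['converged'].sum())} converged."
    )
    if failures:
        report_lines.append("Failures:")
        report_lines.extend(f"  {f}" for f in failures)
    (out / "report.txt").write_text("\n".join(report_lines) + "\n")
    log.info("analysis complete: %d fitted records -> %s", n_records, out)
    return out


def run_recovery_benchmark(
    grid: Sequence[MechParams],
    config: PipelineConfig = PipelineConfig(),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthesize -> estimate -> fit round trip over a parameter grid.

    Returns one row per grid point with true and estimated values and the
    relative error of each parameter (plus a/c).  An empty grid yields an
    empty table.
    """
    rows = []
    rng = substream(seed, "recovery")
    for i, truth in enumerate(grid):
        rec = synthetic_data.synthesize_waveform(
            truth, peep=3.0, freqs=config.freqs, duration=config.duration,
            sample_rate=config.sample_rate, noise_sd=noise_sd, rng=rng,
            animal_id=f"grid-{i:03d}",
        )
        spec = impedance.estimate_impedance(rec, config.freqs)
        fit = mechfit.fit_animal(spec)
        row: dict[str, Any] = {"point": i}
        est = fit.params.as_dict()
        est["a_over_c"] = fit.params.a_over_c
        tru = truth.as_dict()
        tru["a_over_c"] = truth.a_over_c
        for name, tv in tru.items():
            row[f"true_{name}"] = tv
            row[f"est_{name}"] = est[name]
            row[f"relerr_{name}"] = (est[name] - tv) / tv
        row["converged"] = fit.converged
        rows.append(row)
    columns = (
        ["point"]
        + [f"{kind}_{n}" for n in list(synthetic_data.PARAM_FIELDS) + ["a_over_c"] for kind in ("true", "est", "relerr")]
        + ["converged"]
    )
    return pd.DataFrame(rows, columns=columns if rows else None)
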