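"""End-to-end orchestration: synthesize → extract → summarize.

``run`` drives the full study on a synthetic cohort: per-animal ERG
feature extraction (a-/b-wave, pSTR, total OP), OCT segmentation and
thickness averaging over the five B-scans of each eye, the NOR D²
index, and the complete statistical battery, writing CSV/JSON outputs
that mirror the study's result surface (functional and structural
summary tables, slope analyses, per-age comparisons).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import behaviour, erg, oct, stats, synth
from .exceptions import RetinadError

log = logging.getLogger("retinad.pipeline")

ERG_PARAMETERS = ("a_amp", "b_amp", "pstr_amp", "op_total")
OCT_PARAMETERS = ("inner_um", "outer_um")


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    ``design`` carries the cohort structure and generator conditions;
    the remaining fields override analysis-module defaults.
    """

    design: synth.CohortDesign = field(default_factory=synth.CohortDesign)
    modalities: tuple[str, ...] = ("erg", "oct", "nor")
    band_hz: tuple[float, float] = erg.DEFAULT_BAND_HZ
    a_window_ms: float = erg.DEFAULT_A_WINDOW_MS
    op_window_ms: float = erg.DEFAULT_OP_WINDOW_MS
    n_ops: int = 3
    onh_frac: float = oct.DEFAULT_ONH_FRAC
    subpixel: bool = False
    equal_var_ttest: bool = True
    out_dir: str | Path | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.design.seed = self.seed

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        design_kw = raw.pop("design", {})
        for key in ("genotypes", "ages", "nor_ages"):
            if key in design_kw:
                design_kw[key] = tuple(design_kw[key])
        design = synth.CohortDesign(**design_kw)
        for key in ("modalities", "band_hz"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(design=design, **raw)


def extract_cohort_table(
    cohort: synth.CohortData, config: RunConfig | None = None
) -> pd.DataFrame:
    """Apply the measurement modules to every animal of a raw cohort.

    Returns the long-format table (animal_id, genotype, age_months,
    parameter, value) consumed by the statistics module.  The a-wave is
    reported signed (negative), matching the convention of the summary
    tables.
    """
    config = config or RunConfig()
    rows: list[tuple] = []

    def add(rec, name, value):
        rows.append((rec.animal_id, rec.genotype, rec.age_months, name, value))

    opts = oct.EyeOptions(onh_frac=config.onh_frac, subpixel=config.subpixel)
    for rec in cohort.animals:
        if rec.erg_bright is not None:
            feats = erg.extract_features(
                rec.erg_bright,
                rec.str_traces,
                a_window_ms=config.a_window_ms,
                band_hz=config.band_hz,
                n_ops=config.n_ops,
                op_window_ms=config.op_window_ms,
            )
            add(rec, "a_amp", feats.a_amp)
            add(rec, "b_amp", feats.b_amp)
            add(rec, "pstr_amp", feats.pstr_amp)
            add(rec, "op_total", feats.op_total)
        if rec.bscans:
            res = oct.summarize_eye(rec.bscans, options=opts)
            add(rec, "inner_um", res.inner_um)
            add(rec, "outer_um", res.outer_um)
            add(rec, "inner_norm_intensity", res.inner_norm_intensity)
            add(rec, "outer_norm_intensity", res.outer_norm_intensity)
        if rec.nor is not None:
            add(rec, "nor_novel_s", rec.nor.novel)
            add(rec, "nor_familiar_s", rec.nor.familiar)
            add(rec, "d2", behaviour.d2_index(rec.nor))
    return pd.DataFrame(
        rows, columns=["animal_id", "genotype", "age_months", "parameter", "value"]
    )


def _format_summary_table(report: stats.StatsReport, parameters) -> pd.DataFrame:
    """Wide mean ± SD grid (rows: genotype × age, columns: parameters)."""
    cs = report.cell_summary
    rows = []
    for (g, a), sub in cs[cs.parameter.isin(parameters)].groupby(
        ["genotype", "age_months"]
    ):
        row = {"genotype": g, "age_months": a}
        for _, r in sub.iterrows():
            letters = f" {r.letters}" if r.letters else ""
            row[r.parameter] = f"{r['mean']:.1f} ± {r.sd:.1f}{letters}"
        rows.append(row)
    return pd.DataFrame(rows).sort_values(["genotype", "age_months"])


def run(config: RunConfig) -> dict:
    """Execute the pipeline; returns a result bundle (also written to disk).

    Deterministic given ``config.seed``.  Stage failures surface as
    exceptions after the manifest of completed stages is written.
    """
    t_start = time.time()
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, object] = {"seed": config.seed, "stages": []}
    bundle: dict[str, object] = {"manifest": manifest}

    def stage(name):
        log.info("stage %s (t=%.1fs)", name, time.time() - t_start)
        manifest["stages"].append(name)

    try:
        stage("synth")
        cohort = synth.simulate_cohort(config.design, modalities=config.modalities)
        stage("extract")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = extract_cohort_table(cohort, config)
        bundle["cohort_table"] = table
        stage("stats")
        analysed = table[
            table.parameter.isin(ERG_PARAMETERS + OCT_PARAMETERS + ("d2",))
        ]
        report = stats.build_summary(analysed)
        bundle["report"] = report
        bundle["functional_table"] = _format_summary_table(report, ERG_PARAMETERS)
        bundle["structural_table"] = _format_summary_table(report, OCT_PARAMETERS)
        stage("write")
        if out_dir:
            table.to_csv(out_dir / "cohort_table.csv", index=False)
            bundle["functional_table"].to_csv(
                out_dir / "functional_summary.csv", index=False
            )
            bundle["structural_table"].to_csv(
                out_dir / "structural_summary.csv", index=False
            )
            report.anova.to_csv(out_dir / "anova.csv", index=False)
            report.tukey.to_csv(out_dir / "tukey.csv", index=False)
            report.ancova.to_csv(out_dir / "ancova.csv", index=False)
            report.ttests.to_csv(out_dir / "ttests.csv", index=False)
            summary_json = {
                "seed": config.seed,
                "n_animals": len(cohort.animals),
                "ancova": report.ancova.to_dict(orient="records"),
                "notes": report.notes,
                "runtime_s": round(time.time() - t_start, 2),
            }
            (out_dir / "report.json").write_text(json.dumps(summary_json, indent=2))
    except RetinadError:
        if out_dir:
            (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    manifest["runtime_s"] = round(time.time() - t_start, 2)
    if out_dir:
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("run complete in %.1fs", time.time() - t_start)
    return bundle


def config_to_yaml(config: RunConfig, path: str | Path) -> None:
    raw = dataclasses.asdict(config)
    raw["design"].pop("erg_means", None)
    raw["design"].pop("thickness_means", None)
    raw["design"].pop("nor_means", None)
    raw["out_dir"] = str(raw["out_dir"]) if raw["out_dir"] else None
    Path(path).write_text(yaml.safe_dump(raw))
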