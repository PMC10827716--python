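"""End-to-end pipeline: generate -> quantify -> score -> compare.

Runs the full chain on a synthetic cohort: serial-section generation,
lesion volumetry, mirrored-tile reactivity scoring, behavioral scoring,
and the gated group statistics, writing per-stage CSV tables and a
markdown report into a run directory. Every output row is traceable to an
animal id and the master seed; the run is bit-reproducible for a given
config + seed because each animal draws from its own stable sub-stream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import tiling, volumetry
from .behavior import mnss_total, mnss_relative_change, select_trials, pasta_summary
from .imaging import write_stack
from .stats import DEFAULT_ALPHA, RM_ANOVA_SS_NOTE, outcome_report, repeated_measures
from .synthesis import AnimalRecord, CohortConfig, CohortDataset, generate_cohort

log = logging.getLogger("strokequant")


@dataclass
class PipelineConfig:
    """Cohort generation plus analysis parameters for one run.

    Analysis defaults follow the study conventions the package models:
    200 µm tiles, high-reactivity threshold at contralesional mean +
    1.5 SD, the three printed region windows, treatment arms {0.0, 0.8,
    31.8, 47.8} A/m² and alpha = 0.05.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    tile_um: float = tiling.DEFAULT_TILE_UM
    sd_multiplier: float = tiling.DEFAULT_SD_MULTIPLIER
    excluded_pixel_fraction: float = tiling.DEFAULT_EXCLUDED_PIXEL_FRACTION
    segmentation: str = "otsu"
    alpha: float = DEFAULT_ALPHA
    save_images: bool = False

    def config_hash(self) -> str:
        blob = json.dumps(_asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _asdict(cfg) -> dict:
    return dataclasses.asdict(cfg)


# --------------------------------------------------------------------------
# per-stage table builders


def volumetry_table(cohort: CohortDataset, config: PipelineConfig,
                    sections_by_animal: dict | None = None) -> pd.DataFrame:
    rows = []
    for animal in cohort.animals:
        sections = (sections_by_animal or {}).get(animal.animal_id) \
            or animal.sections()
        est = volumetry.measure_stack(
            [s for s in sections if s.channel == "fjc"],
            method=config.segmentation)
        for ap, area in est.per_section:
            rows.append({"animal_id": animal.animal_id, "arm": animal.arm,
                         "ap_mm": ap, "area_mm2": area,
                         "volume_mm3": est.volume_mm3,
                         "caudal_border_mm": est.caudal_border_mm})
    return pd.DataFrame(rows)


def reactivity_tables(cohort: CohortDataset, config: PipelineConfig,
                      sections_by_animal: dict | None = None,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-section tile results and the per-animal region summary."""
    sec_rows, sum_rows = [], []
    for animal in cohort.animals:
        sections = (sections_by_animal or {}).get(animal.animal_id) \
            or animal.sections()
        results = []
        for s in sections:
            if s.channel != "iba1" or tiling.assign_region(s.ap_mm) is None:
                continue
            res = tiling.score_section(
                s, exclusion=animal.exclusion_mask(s.ap_mm),
                tile_um=config.tile_um, sd_multiplier=config.sd_multiplier,
                excluded_pixel_fraction=config.excluded_pixel_fraction)
            results.append(res)
            sec_rows.append({"animal_id": animal.animal_id, "arm": animal.arm,
                             "ap_mm": res.ap_mm, "region": res.region,
                             "threshold": res.threshold,
                             "ratio_ipsi": res.ratio_ipsi,
                             "ratio_contra": res.ratio_contra,
                             "ratio_diff": res.ratio_diff})
        summary = tiling.animal_reactivity_summary(results)
        row = {"animal_id": animal.animal_id, "arm": animal.arm,
               "pooled_mean": summary.pooled_mean}
        for region in ("D", "E", "F"):
            row[f"region_{region}"] = summary.region_values.get(region)
        sum_rows.append(row)
    return pd.DataFrame(sec_rows), pd.DataFrame(sum_rows)


def behavior_tables(cohort: CohortDataset,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-animal mNSS table (one row per timepoint) and pasta metrics
    (one row per timepoint; animals without a valid trial are dropped
    from that timepoint)."""
    mnss_rows, pasta_rows = [], []
    for animal in cohort.animals:
        totals = {tp: mnss_total(items) for tp, items in animal.mnss.items()}
        rel = mnss_relative_change(totals["post_stroke"], totals["post_tdcs"])
        for tp, tot in totals.items():
            mnss_rows.append({"animal_id": animal.animal_id,
                              "arm": animal.arm, "timepoint": tp,
                              "mnss_total": tot,
                              "relative_change": rel})
        for tp, session in animal.pasta.items():
            valid = select_trials(session)
            if not valid:
                log.info("animal %s excluded from pasta at %s (no valid "
                         "trial)", animal.animal_id, tp)
                continue
            m = pasta_summary(valid)
            pasta_rows.append({"animal_id": animal.animal_id,
                               "arm": animal.arm, "timepoint": tp,
                               "n_valid": m.n_valid,
                               "time_per_pasta_s": m.time_per_pasta_s,
                               "grasps_ipsi": m.grasps_ipsi_per_pasta,
                               "grasps_contra": m.grasps_contra_per_pasta,
                               "atypicals": m.atypicals_per_pasta})
    return pd.DataFrame(mnss_rows), pd.DataFrame(pasta_rows)


def build_outcomes(vol: pd.DataFrame, react_summary: pd.DataFrame,
                   mnss: pd.DataFrame, pasta: pd.DataFrame,
                   ) -> dict[str, pd.DataFrame]:
    """Assemble the per-animal group-comparison tables for the report.

    Each outcome is a single value per animal; repeated-measures analyses
    (time effects) are reported separately in the markdown summary.
    """
    outcomes: dict[str, pd.DataFrame] = {}

    per_animal = vol.drop_duplicates("animal_id")
    outcomes["volume_mm3"] = per_animal.rename(
        columns={"volume_mm3": "value"})[["animal_id", "arm", "value"]]
    outcomes["caudal_border_mm"] = per_animal.rename(
        columns={"caudal_border_mm": "value"})[["animal_id", "arm", "value"]]

    outcomes["mnss"] = mnss.rename(columns={"mnss_total": "value"})[
        ["animal_id", "arm", "timepoint", "value"]]
    rel = mnss.drop_duplicates("animal_id")
    outcomes["mnss_relative_change"] = rel.rename(
        columns={"relative_change": "value"})[["animal_id", "arm", "value"]]

    # pasta outcomes: repeated measures over baseline/day2 (group x time),
    # plus the baseline-to-day2 change in atypical counts as its own row
    for col, name in (("time_per_pasta_s", "time_per_pasta"),
                      ("grasps_ipsi", "grasps_ipsi"),
                      ("grasps_contra", "grasps_contra"),
                      ("atypicals", "atypicals")):
        outcomes[name] = pasta.rename(columns={col: "value"})[
            ["animal_id", "arm", "timepoint", "value"]]
    wide = pasta.pivot_table(index=["animal_id", "arm"], columns="timepoint",
                             values="atypicals").reset_index()
    if {"baseline", "day2"} <= set(wide.columns):
        wide["value"] = wide["day2"] - wide["baseline"]
        outcomes["atypicals_change"] = wide.dropna(subset=["value"])[
            ["animal_id", "arm", "value"]]

    outcomes["reactivity_overall"] = react_summary.rename(
        columns={"pooled_mean": "value"})[["animal_id", "arm", "value"]]
    for region in ("D", "E", "F"):
        outcomes[f"reactivity_region_{region}"] = react_summary.rename(
            columns={f"region_{region}": "value"})[
                ["animal_id", "arm", "value"]].dropna(subset=["value"])
    return outcomes


# --------------------------------------------------------------------------
# orchestration


@dataclass
class PipelineResult:
    cohort: CohortDataset
    volumetry: pd.DataFrame
    reactivity_sections: pd.DataFrame
    reactivity_summary: pd.DataFrame
    mnss: pd.DataFrame
    pasta: pd.DataFrame
    report: pd.DataFrame
    outdir: Path | None = None


def run_pipeline(config: PipelineConfig | None = None,
                 seed: int | None = None,
                 outdir: str | Path | None = None) -> PipelineResult:
    """Execute every stage in order and (optionally) write the run
    directory: cohort manifest, per-stage CSV tables, a markdown report
    and — when ``save_images`` is on — per-animal TIFF stacks with JSON
    sidecars. Any stage failure aborts with a stage-identified error.
    """
    config = config or PipelineConfig()
    if seed is not None:
        config = dataclasses.replace(
            config, cohort=dataclasses.replace(config.cohort, seed=seed))
    stage = "generate"
    try:
        cohort = generate_cohort(config.cohort)
        sections_by_animal: dict[str, list] = {}
        if config.save_images and outdir is not None:
            imgdir = Path(outdir) / "images"
            imgdir.mkdir(parents=True, exist_ok=True)
            for a in cohort.animals:
                secs = a.sections()
                write_stack(imgdir / f"{a.animal_id}.tiff", secs,
                            extra={"ground_truth": _truth_json(a)})
        # quantify animal by animal so only one image stack is resident
        stage = "volumetry/reactivity"
        vol_parts, sec_parts, sum_parts = [], [], []
        for animal in cohort.animals:
            secs = {animal.animal_id: animal.sections()}
            sub = CohortDataset([animal], cohort.seed, cohort.config)
            vol_parts.append(volumetry_table(sub, config, secs))
            rs, rsum = reactivity_tables(sub, config, secs)
            sec_parts.append(rs)
            sum_parts.append(rsum)
        vol = pd.concat(vol_parts, ignore_index=True)
        react_sec = pd.concat(sec_parts, ignore_index=True)
        react_sum = pd.concat(sum_parts, ignore_index=True)
        stage = "behavior"
        mnss, pasta = behavior_tables(cohort)
        stage = "stats"
        outcomes = build_outcomes(vol, react_sum, mnss, pasta)
        report = outcome_report(outcomes, alpha=config.alpha)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    result = PipelineResult(cohort, vol, react_sec, react_sum, mnss, pasta,
                            report)
    if outdir is not None:
        result.outdir = Path(outdir)
        _write_run(result, config)
    return result


def _truth_json(animal: AnimalRecord) -> dict:
    t = animal.ground_truth
    return {"true_volume_mm3": t.true_volume_mm3,
            "true_caudal_border_mm": t.true_caudal_border_mm,
            "true_activated_fraction": t.true_activated_fraction,
            "group_effects": t.group_effects,
            "lesion_clipped": t.lesion_clipped}


def _write_run(result: PipelineResult, config: PipelineConfig) -> None:
    outdir = result.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    header = f"# strokequant run, seed={config.cohort.seed}, config={h}\n"

    def _csv(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)

    manifest = pd.DataFrame(result.cohort.manifest())
    _csv(manifest, "manifest.csv")
    _csv(result.volumetry, "volumetry.csv")
    _csv(result.reactivity_sections, "reactivity_sections.csv")
    _csv(result.reactivity_summary, "reactivity_summary.csv")
    _csv(result.mnss, "mnss.csv")
    _csv(result.pasta, "pasta.csv")
    _csv(result.report, "report.csv")
    (outdir / "config.json").write_text(
        json.dumps(_asdict(config), indent=1, default=str))
    (outdir / "report.md").write_text(render_report(result, config))


def render_report(result: PipelineResult, config: PipelineConfig) -> str:
    """Human-readable markdown summary of the run."""
    lines = [
        "# Group comparison report",
        "",
        f"seed: {config.cohort.seed}; config hash: {config.config_hash()}",
        f"alpha: {config.alpha}; {RM_ANOVA_SS_NOTE}",
        "",
        "| outcome | gate | test | statistic | p | significant | post-hoc |",
        "|---|---|---|---|---|---|---|",
    ]
    for _, r in result.report.iterrows():
        lines.append(
            f"| {r['outcome']} | {r['gate']} | {r['test']} | "
            f"{r['symbol']}={r['statistic']:.3g} | {r['p']:.4g} | "
            f"{'yes' if r['significant'] else 'no'} | "
            f"{r['posthoc_significant'] or '-'} |")
    # repeated-measures time effects, reported alongside the group table
    lines += ["", "## Time effects (repeated measures)", ""]
    for name, tab, val in (("mNSS", result.mnss, "mnss_total"),
                           ("time per pasta", result.pasta, "time_per_pasta_s"),
                           ("atypicals per pasta", result.pasta, "atypicals")):
        try:
            res = repeated_measures(
                tab.rename(columns={val: "value"}), alpha=config.alpha)
            time = res.effects.get("time", res)
            lines.append(f"- {name}: {time.test_name}, "
                         f"{time.symbol}={time.statistic:.3g}, "
                         f"p={time.p:.4g}")
        except ValueError as err:
            lines.append(f"- {name}: not testable ({err})")
    return "\n".join(lines) + "\n"
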