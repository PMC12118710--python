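"""End-to-end orchestration: simulate -> preprocess -> detect -> compare ->
enrichment -> differential expression -> report.

Every stage writes plain TSV into the run directory, and a machine-readable
``manifest.json`` records the package version, the configuration (and its
hash), the seed, and per-stage row counts.  Reruns with the same
configuration and seed reproduce byte-identical tables; nothing
time-dependent is written to the outputs.  Progress and timings go to
stderr only.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datamodel import TimedSampleMatrix, read_matrix
from .preprocess import filter_low_counts, normalize_and_log
from .rhythm import DEFAULT_METHODS, RhythmCallTable, detect_all
from .differential import compare_all, class_totals, mean_phase_shift, summarize_drg
from .enrichment import (
    merge_categories,
    category_phase_difference,
    ora_fisher,
    psea_analysis,
    read_category_map,
    read_gmt,
)
from .deg import nb_global_test, nb_time_adjusted_test
from .lipids import LipidParseError, class_distribution, parse_lipid_name
from .simulate import GroundTruth, SimulationConfig, generate_counts, generate_lipidome

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Thresholds, inputs and methods of a full pipeline run.

    Either ``matrix``/``sample_sheet`` point at input files, or
    ``simulation`` configures the synthetic generator.  Thresholds default
    to the analysis constants used throughout the package: rhythm detection
    at p < 0.01 ("any" consensus), rhythm comparison at p < 0.05, ORA at
    >= 3 genes and p < 0.05, PSEA at >= 10 genes and p < 0.01, and a
    low-count filter at a summed count of 100.
    """

    matrix: str | None = None
    sample_sheet: str | None = None
    simulation: SimulationConfig | None = None
    value_kind: str = "counts"
    gmt: str | None = None
    category_map: str | None = None
    detection_alpha: float = 0.01
    detection_rule: str = "any"
    methods: tuple[str, ...] = DEFAULT_METHODS
    comparison_alpha: float = 0.05
    ora_min_genes: int = 3
    ora_alpha: float = 0.05
    psea_min_genes: int = 10
    psea_alpha: float = 0.01
    min_total_count: int = 100
    run_deg: bool = True
    seed: int = 0
    output_dir: str = "diurnalomics_run"

    def __post_init__(self) -> None:
        for name in ("detection_alpha", "comparison_alpha", "ora_alpha", "psea_alpha"):
            value = getattr(self, name)
            if not (0.0 < value < 1.0):
                raise ValueError(f"{name}: must lie in (0, 1)")
        if self.matrix is None and self.simulation is None:
            raise ValueError("either matrix/sample_sheet or simulation required")
        if (self.matrix is None) != (self.sample_sheet is None):
            raise ValueError("matrix and sample_sheet must be given together")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as handle:
            data = yaml.safe_load(handle) or {}
        if "simulation" in data and data["simulation"] is not None:
            data["simulation"] = SimulationConfig(**data["simulation"])
        if "methods" in data:
            data["methods"] = tuple(data["methods"])
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        data = asdict(self)
        data["methods"] = list(self.methods)
        # the output location is not an analysis parameter; leaving it out
        # keeps reruns into different directories byte-identical
        data.pop("output_dir", None)
        return data

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def _write(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return len(df)


def _log(msg: str) -> None:
    print(f"[diurnalomics] {msg}", file=sys.stderr)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all configured stages; returns the run directory.

    Stage outputs already written are retained if a later stage fails; the
    raised :class:`PipelineError` names the failing stage.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    t0 = time.time()

    # -- input stage ---------------------------------------------------------
    stage = "input"
    try:
        if config.simulation is not None:
            sim = config.simulation
            if sim.noise_kind == "negative-binomial":
                m, gt = generate_counts(sim)
            else:
                m, gt = generate_lipidome(sim)
            m.write(out / "matrix.tsv", out / "samples.tsv")
            gt.write(out / "ground_truth.tsv")
            counts["ground_truth"] = len(gt.table)
        else:
            m = read_matrix(config.matrix, config.sample_sheet, config.value_kind)
            gt = None
        counts["features_in"] = m.n_features
        counts["samples"] = m.n_samples
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    _log(f"input: {m.n_features} features x {m.n_samples} samples")

    # -- preprocessing -------------------------------------------------------
    stage = "preprocess"
    try:
        if m.value_kind == "counts":
            m_filtered = filter_low_counts(m, config.min_total_count)
            transformed = normalize_and_log(m_filtered)
        else:
            m_filtered = m
            transformed = m
        transformed.write(out / "transformed.tsv", out / "samples_used.tsv")
        counts["features_after_filter"] = m_filtered.n_features
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # -- rhythm detection ----------------------------------------------------
    stage = "detect"
    try:
        calls = detect_all(
            transformed,
            methods=config.methods,
            alpha=config.detection_alpha,
            rule=config.detection_rule,
        )
        counts["rhythm_calls"] = _write(calls.table, out / "rhythm_calls.tsv")
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    _log(f"detect: {int(calls.table['consensus'].sum())} rhythmic calls")

    # -- differential rhythmicity -------------------------------------------
    stage = "compare"
    try:
        comparison = compare_all(transformed, calls, alpha=config.comparison_alpha)
        counts["rhythm_comparisons"] = _write(comparison, out / "rhythm_comparison.tsv")
        counts["drg_combinations"] = _write(
            summarize_drg(comparison), out / "drg_upset.tsv"
        )
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # -- enrichment ----------------------------------------------------------
    if config.gmt is not None:
        stage = "enrichment"
        try:
            if not Path(config.gmt).exists():
                raise FileNotFoundError(f"missing GMT file {config.gmt}")
            sets = read_gmt(config.gmt)
            groups = transformed.groups
            cat_phases: dict[str, dict[str, float]] = {}
            for group in groups:
                sub = calls.table[
                    (calls.table["group"] == group) & calls.table["consensus"]
                ]
                phases = dict(zip(sub["feature"], sub["acrophase"]))
                psea = psea_analysis(
                    phases, sets,
                    min_genes=config.psea_min_genes, alpha=config.psea_alpha,
                )
                counts[f"psea_{group}"] = _write(psea, out / f"psea_{group}.tsv")
                if config.category_map is not None:
                    mapping = read_category_map(config.category_map)
                    cat_phases[group] = merge_categories(
                        psea[psea["significant"]], mapping
                    )
                rhythmic = set(sub["feature"])
                background = set(transformed.feature_ids)
                ora = ora_fisher(
                    rhythmic, background, sets,
                    min_genes=config.ora_min_genes, alpha=config.ora_alpha,
                )
                counts[f"ora_{group}"] = _write(ora, out / f"ora_{group}.tsv")
            if len(cat_phases) == 2:
                g1, g2 = groups
                diffs = category_phase_difference(cat_phases[g1], cat_phases[g2])
                diff_df = pd.DataFrame(
                    sorted(diffs.items()), columns=["category", "delta_phase_h"]
                )
                counts["category_phase_diff"] = _write(
                    diff_df, out / "category_phase_difference.tsv"
                )
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    # -- differential expression ---------------------------------------------
    if config.run_deg and m.value_kind == "counts":
        stage = "deg"
        try:
            deg_global = nb_global_test(m_filtered)
            counts["deg_global"] = _write(deg_global, out / "deg_global.tsv")
            deg_lrt = nb_time_adjusted_test(m_filtered)
            counts["deg_time_adjusted"] = _write(deg_lrt, out / "deg_time_adjusted.tsv")
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    # -- manifest -------------------------------------------------------------
    manifest = {
        "package": "diurnalomics",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "row_counts": counts,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n",
        encoding="utf-8",
    )
    _log(f"pipeline finished in {time.time() - t0:.1f} s -> {out}")
    return out


def make_report(run_dir: str | Path) -> Path:
    """Summarise a completed run into figure-analog tables.

    Writes, where the corresponding stage outputs exist: rhythmic counts per
    group with the group overlap (Venn-style), totals per rhythm-change
    class, the mean phase shift of robustly rhythmic features, a lipid
    class distribution (when feature names parse as lipid shorthand), and a
    pass-through of the enrichment tables.  An incomplete run produces a
    partial report listing the gaps.
    """
    run_dir = Path(run_dir)
    report_dir = run_dir / "report"
    report_dir.mkdir(exist_ok=True)
    gaps: list[str] = []

    calls_path = run_dir / "rhythm_calls.tsv"
    if calls_path.exists():
        calls = pd.read_csv(calls_path, sep="\t")
        groups = list(pd.unique(calls["group"]))
        rows = []
        sets = {
            g: set(calls.loc[(calls["group"] == g) & calls["consensus"], "feature"])
            for g in groups
        }
        for g in groups:
            rows.append({"group": g, "n_rhythmic": len(sets[g])})
        summary = pd.DataFrame(rows)
        _write(summary, report_dir / "rhythmic_counts.tsv")
        if len(groups) == 2:
            g1, g2 = groups
            venn = pd.DataFrame(
                [
                    {"region": f"{g1}_only", "count": len(sets[g1] - sets[g2])},
                    {"region": f"{g2}_only", "count": len(sets[g2] - sets[g1])},
                    {"region": "both", "count": len(sets[g1] & sets[g2])},
                    {"region": "union", "count": len(sets[g1] | sets[g2])},
                ]
            )
            _write(venn, report_dir / "rhythmic_venn.tsv")
        # lipid class distribution, if names follow the shorthand grammar
        features = list(dict.fromkeys(calls["feature"]))
        try:
            for name in features:
                parse_lipid_name(name)
            lipid_ok = True
        except LipidParseError:
            lipid_ok = False
        if lipid_ok and features:
            for g in groups:
                flags = [f in sets[g] for f in features]
                dist = class_distribution(features, flags).reset_index()
                _write(dist, report_dir / f"lipid_classes_{g}.tsv")
    else:
        gaps.append("rhythm_calls.tsv missing: no rhythmicity summary")

    comp_path = run_dir / "rhythm_comparison.tsv"
    if comp_path.exists():
        comp = pd.read_csv(comp_path, sep="\t")
        if "classes" in comp.columns:
            comp["classes"] = comp["classes"].fillna("")
        totals = class_totals(comp).rename_axis("class").reset_index()
        _write(totals, report_dir / "drg_class_totals.tsv")
        if comp["p_phase"].notna().any():
            mean_shift, p_shift = mean_phase_shift(comp)
            shift = pd.DataFrame(
                [
                    {
                        "n_robustly_rhythmic": int(comp["p_phase"].notna().sum()),
                        "mean_phase_shift_h": mean_shift,
                        "p_value": p_shift,
                    }
                ]
            )
            _write(shift, report_dir / "phase_shift_summary.tsv")
        else:
            gaps.append("no robustly rhythmic features: no phase-shift summary")
    else:
        gaps.append("rhythm_comparison.tsv missing: no DRG summary")

    (report_dir / "gaps.txt").write_text(
        "\n".join(gaps) + ("\n" if gaps else ""), encoding="utf-8"
    )
    return report_dir
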