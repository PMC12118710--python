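"""Synthetic two-group diurnal omics data with known ground truth.

The generator reproduces the study design this package targets: two groups
(e.g. wild-type vs receptor knockout), samples every 4 h across one 24-h
cycle, three replicates per timepoint and group.  Each feature carries a
log-scale cosinor signal

    log-mean(t) = mesor + amplitude * cos(2*pi*(t - acrophase)/24)

so that downstream log-transformed harmonic fits are well specified.
Transcriptome-like data adds negative-binomial count noise (variance
mu + dispersion*mu^2); lipidome-like data is log-normal around the same
curve and its features are named with valid shorthand lipid species drawn
from a class palette.  Group 2 can differ by configurable deltas on mesor,
amplitude and acrophase (positive delta_phase = later peak, a delay).

Non-rhythmic features have amplitude exactly zero — a clean null for
calibration studies.  One master seed spawns one substream per feature, so
results do not depend on feature order and are bit-reproducible.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .datamodel import SampleMeta, TimedSampleMatrix, matrix_from_arrays
from .lipids import parse_lipid_name
from .phase import wrap_phase

PERIOD = 24.0

#: 4-h sampling grids; the anchor (ZT0 vs ZT2) is a study-design choice,
#: both are offered as presets.
TIMEPOINT_PRESETS = {
    "ZT2": (2.0, 6.0, 10.0, 14.0, 18.0, 22.0),
    "ZT0": (0.0, 4.0, 8.0, 12.0, 16.0, 20.0),
}

DEFAULT_LIPID_PALETTE = (
    "TG", "DG", "PC", "PE", "PI", "PG", "Cer", "SM", "CE", "ST", "LPC", "FFA",
)

# ParamSpec: a fixed number, or ("uniform", lo, hi), or ("normal", mu, sd)
ParamSpec = float | tuple


def _draw(spec: ParamSpec, rng: np.random.Generator) -> float:
    if isinstance(spec, numbers.Real):
        return float(spec)
    kind = spec[0]
    if kind == "uniform":
        return float(rng.uniform(spec[1], spec[2]))
    if kind == "normal":
        return float(rng.normal(spec[1], spec[2]))
    if kind == "fixed":
        return float(spec[1])
    raise ValueError(f"unknown parameter spec {spec!r}")


@dataclass
class SimulationConfig:
    """Study-design and effect-model parameters of the generator.

    Defaults encode the emulated design: 2 groups x 6 timepoints (every 4 h)
    x 3 replicates, just over half of the features rhythmic, log-scale
    mesors/amplitudes in a realistic bulk-RNA-seq range, and no group
    effect (all deltas zero) unless configured.
    """

    n_features: int = 1000
    fraction_rhythmic: float = 0.54
    timepoints: Sequence[float] = TIMEPOINT_PRESETS["ZT2"]
    n_replicates: int = 3
    group_labels: tuple[str, str] = ("WT", "KO")
    mesor: ParamSpec = ("uniform", 3.0, 8.0)  # log scale (natural log)
    amplitude: ParamSpec = ("uniform", 0.3, 1.0)  # log scale, rhythmic only
    acrophase: ParamSpec = ("uniform", 0.0, 24.0)  # hours
    delta_mesor: ParamSpec = 0.0
    delta_amplitude: ParamSpec = 0.0
    delta_phase: ParamSpec = 0.0  # hours; positive = group 2 delayed
    noise_kind: str = "negative-binomial"  # or "lognormal"
    dispersion: float = 0.05  # NB: Var = mu + dispersion * mu^2
    sigma: float = 0.25  # log-normal sd on the log scale
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.timepoints, str):
            try:
                self.timepoints = TIMEPOINT_PRESETS[self.timepoints]
            except KeyError:
                raise ValueError(
                    f"timepoints: unknown preset {self.timepoints!r}"
                ) from None
        self.timepoints = tuple(float(t) for t in self.timepoints)
        if self.n_features < 0:
            raise ValueError("n_features: must be non-negative")
        if not (0.0 <= self.fraction_rhythmic <= 1.0):
            raise ValueError("fraction_rhythmic: must lie in [0, 1]")
        if len(self.timepoints) == 0:
            raise ValueError("timepoints: must be non-empty")
        if any(not (0 <= t < 24) for t in self.timepoints):
            raise ValueError("timepoints: all values must lie in [0, 24)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates: must be >= 1")
        if len(self.group_labels) != 2 or self.group_labels[0] == self.group_labels[1]:
            raise ValueError("group_labels: need two distinct labels")
        if self.noise_kind not in ("negative-binomial", "lognormal"):
            raise ValueError("noise_kind: must be 'negative-binomial' or 'lognormal'")
        if self.noise_kind == "negative-binomial" and self.dispersion <= 0:
            raise ValueError("dispersion: must be > 0")
        if self.noise_kind == "lognormal" and self.sigma < 0:
            raise ValueError("sigma: must be >= 0")
        if isinstance(self.amplitude, numbers.Real) and self.amplitude < 0:
            raise ValueError("amplitude: must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as handle:
            data = yaml.safe_load(handle) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        for key in ("mesor", "amplitude", "acrophase",
                    "delta_mesor", "delta_amplitude", "delta_phase"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        if "group_labels" in data:
            data["group_labels"] = tuple(data["group_labels"])
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


GT_COLUMNS = (
    "feature", "group", "is_rhythmic", "mesor", "amplitude", "acrophase",
    "noise_kind", "noise_param",
)


@dataclass
class GroundTruth:
    """True per-feature, per-group rhythm parameters used by the generator."""

    table: pd.DataFrame  # one row per feature per group, columns GT_COLUMNS

    def __post_init__(self) -> None:
        missing = set(GT_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"ground truth missing columns {sorted(missing)}")
        amp = self.table["amplitude"].to_numpy(dtype=float)
        phi = self.table["acrophase"].to_numpy(dtype=float)
        if (amp < 0).any():
            raise ValueError("negative amplitude in ground truth")
        if ((phi < 0) | (phi >= 24)).any():
            raise ValueError("acrophase outside [0, 24) in ground truth")
        if bool((self.table.loc[amp == 0, "is_rhythmic"]).any()):
            raise ValueError("amplitude 0 must imply is_rhythmic False")

    def params(self, feature: str, group: str) -> pd.Series:
        sub = self.table[
            (self.table["feature"] == feature) & (self.table["group"] == group)
        ]
        if len(sub) != 1:
            raise KeyError(f"no unique ground truth for {feature!r}/{group!r}")
        return sub.iloc[0]

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def read(cls, path: str | Path) -> "GroundTruth":
        table = pd.read_csv(
            path, sep="\t",
            dtype={"feature": str, "group": str, "noise_kind": str},
        )
        if len(table):
            table["is_rhythmic"] = table["is_rhythmic"].astype(bool)
        else:
            table = table.reindex(columns=list(GT_COLUMNS))
        return cls(table)


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    gt.write(path)


def read_ground_truth(path: str | Path) -> GroundTruth:
    return GroundTruth.read(path)


def _sample_meta(config: SimulationConfig) -> list[SampleMeta]:
    meta = []
    for group in config.group_labels:
        for t in config.timepoints:
            for rep in range(1, config.n_replicates + 1):
                meta.append(
                    SampleMeta(f"{group}_ZT{t:g}_r{rep}", group, float(t), rep)
                )
    return meta


def _feature_params(config: SimulationConfig, rng: np.random.Generator, rhythmic: bool):
    """Draw one feature's (group1, group2) parameter rows in a fixed order."""
    mesor = _draw(config.mesor, rng)
    if rhythmic:
        amp = abs(_draw(config.amplitude, rng))
        phi = float(wrap_phase(_draw(config.acrophase, rng)))
    else:
        amp, phi = 0.0, 0.0
    d_mesor = _draw(config.delta_mesor, rng)
    d_amp = _draw(config.delta_amplitude, rng) if rhythmic else 0.0
    d_phi = _draw(config.delta_phase, rng) if rhythmic else 0.0
    amp2 = max(amp + d_amp, 0.0)
    phi2 = float(wrap_phase(phi + d_phi)) if amp2 > 0 else 0.0
    g1 = (rhythmic and amp > 0, mesor, amp, phi)
    g2 = (rhythmic and amp2 > 0, mesor + d_mesor, amp2, phi2)
    return g1, g2


def _log_means(params, times: np.ndarray) -> np.ndarray:
    _, mesor, amp, phi = params
    return mesor + amp * np.cos(2 * np.pi * (times - phi) / PERIOD)


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, dispersion: float):
    if dispersion < 1e-8:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def _gt_rows(config, feature, g1, g2, noise_param):
    rows = []
    for group, params in zip(config.group_labels, (g1, g2)):
        rhythmic, mesor, amp, phi = params
        rows.append(
            {
                "feature": feature,
                "group": group,
                "is_rhythmic": bool(rhythmic),
                "mesor": mesor,
                "amplitude": amp,
                "acrophase": phi,
                "noise_kind": config.noise_kind,
                "noise_param": noise_param,
            }
        )
    return rows


def generate_counts(config: SimulationConfig) -> tuple[TimedSampleMatrix, GroundTruth]:
    """Simulate a two-group diurnal count matrix with known ground truth.

    Per-sample means follow exp(mesor + amplitude*cos(2*pi*(t-phi)/24)) with
    negative-binomial noise of the configured dispersion.  The first
    round(fraction_rhythmic * n_features) features are rhythmic.
    """
    if config.noise_kind != "negative-binomial":
        raise ValueError("noise_kind: generate_counts requires 'negative-binomial'")
    meta = _sample_meta(config)
    times = np.array([m.time for m in meta])
    group2 = np.array([m.group == config.group_labels[1] for m in meta])
    n_rhythmic = int(round(config.fraction_rhythmic * config.n_features))

    streams = np.random.SeedSequence(config.seed).spawn(config.n_features)
    values = np.zeros((config.n_features, len(meta)), dtype=np.int64)
    gt_rows = []
    features = [f"gene{i + 1:05d}" for i in range(config.n_features)]
    for i, feature in enumerate(features):
        rng = np.random.default_rng(streams[i])
        g1, g2 = _feature_params(config, rng, rhythmic=i < n_rhythmic)
        log_mu = np.where(group2, _log_means(g2, times), _log_means(g1, times))
        values[i] = _nb_sample(rng, np.exp(log_mu), config.dispersion)
        gt_rows.extend(_gt_rows(config, feature, g1, g2, config.dispersion))
    matrix = matrix_from_arrays(values, features, meta, value_kind="counts")
    gt = GroundTruth(pd.DataFrame(gt_rows, columns=GT_COLUMNS))
    return matrix, gt


def _lipid_name(cls: str, rng: np.random.Generator) -> str:
    """Generate one plausible shorthand name for a class."""
    even = lambda lo, hi: int(2 * rng.integers(lo // 2, hi // 2 + 1))
    if cls == "TG":
        return f"TG {even(48, 62)}:{rng.integers(0, 11)}"
    if cls == "DG":
        c1, c2 = even(14, 20), even(16, 22)
        return f"DG {c1}:{rng.integers(0, 3)}_{c2}:{rng.integers(0, 7)}"
    if cls in ("PC", "PE", "PI", "PG", "PS"):
        c1, c2 = even(14, 20), even(16, 22)
        body = f"{c1}:{rng.integers(0, 2)}_{c2}:{rng.integers(0, 7)}"
        if cls == "PC" and rng.random() < 0.15:
            return f"PC O-{body}"
        return f"{cls} {body}"
    if cls == "Cer":
        if rng.random() < 0.5:
            return f"Cer {even(34, 44)}:{rng.integers(1, 4)};2O"
        return f"Cer 18:1;2O/{even(16, 26)}:{rng.integers(0, 2)}"
    if cls == "SM":
        return f"SM {even(32, 42)}:{rng.integers(1, 3)};2O"
    if cls == "CE":
        return f"CE {even(16, 22)}:{rng.integers(0, 5)}"
    if cls == "ST":
        return f"ST {even(28, 30)}:{rng.integers(1, 3)};O;S"
    if cls == "LPC":
        return f"LPC {even(14, 20)}:{rng.integers(0, 3)}"
    if cls == "FFA":
        return f"FFA {even(14, 22)}:{rng.integers(0, 7)}"
    # generic fallback: sum composition
    return f"{cls} {even(30, 44)}:{rng.integers(0, 7)}"


def generate_lipidome(
    config: SimulationConfig,
    class_palette: Sequence[str] = DEFAULT_LIPID_PALETTE,
) -> tuple[TimedSampleMatrix, GroundTruth]:
    """Simulate a lipidome-like positive continuous matrix.

    Features carry valid shorthand lipid names drawn from ``class_palette``
    (round-trippable through the parser); values are log-normal around the
    log-scale cosinor curve, so sigma = 0 returns the noiseless curve
    exactly.
    """
    if config.noise_kind != "lognormal":
        raise ValueError("noise_kind: generate_lipidome requires 'lognormal'")
    if not class_palette:
        raise ValueError("class_palette: must be non-empty")
    for cls in class_palette:
        probe = f"{cls} 18:1"
        try:
            parsed = parse_lipid_name(probe)
        except Exception as exc:
            raise ValueError(f"class template {cls!r} fails the grammar: {exc}")
        if parsed.lipid_class != cls:
            raise ValueError(f"class template {cls!r} fails the grammar")

    meta = _sample_meta(config)
    times = np.array([m.time for m in meta])
    group2 = np.array([m.group == config.group_labels[1] for m in meta])
    n_rhythmic = int(round(config.fraction_rhythmic * config.n_features))

    master = np.random.SeedSequence(config.seed)
    streams = master.spawn(config.n_features)
    name_rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(10**6,)))
    names: list[str] = []
    seen: set[str] = set()
    while len(names) < config.n_features:
        cls = class_palette[int(name_rng.integers(0, len(class_palette)))]
        candidate = _lipid_name(cls, name_rng)
        if candidate not in seen:
            parse_lipid_name(candidate)  # grammar closure guard
            seen.add(candidate)
            names.append(candidate)

    values = np.zeros((config.n_features, len(meta)), dtype=float)
    gt_rows = []
    for i, name in enumerate(names):
        rng = np.random.default_rng(streams[i])
        g1, g2 = _feature_params(config, rng, rhythmic=i < n_rhythmic)
        log_mu = np.where(group2, _log_means(g2, times), _log_means(g1, times))
        noise = rng.standard_normal(len(meta)) * config.sigma if config.sigma > 0 else 0.0
        values[i] = np.exp(log_mu + noise)
        gt_rows.extend(_gt_rows(config, name, g1, g2, config.sigma))
    matrix = matrix_from_arrays(values, names, meta, value_kind="continuous")
    gt = GroundTruth(pd.DataFrame(gt_rows, columns=GT_COLUMNS))
    return matrix, gt
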