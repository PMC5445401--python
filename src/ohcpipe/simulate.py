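"""Synthetic data with the statistical structure the pipeline assumes.

The expression generator emulates the study design of eight MCF-7-derived
cell lines (parent, blank vector, MT3, MT3-delta-CT, MT3-delta-NT, MT1E,
MT1E-CT, MT1E-NT) profiled in triplicate on a chip-scale probe panel.
Intensities are log-normal: log-intensity = per-probe baseline + log(true
fold factor for the line) + per-array noise, so planted effects are exact
fold changes in the zero-noise limit.

Three co-regulated probe blocks encode the C-/N-terminal regulatory
structure:

* a GAGE-like block, up-regulated by ``ct_effect`` in lines carrying the
  C-terminal domain without the N-terminal domain, and suppressed by
  ``nt_effect`` (< 1) whenever the N-terminal domain is present — the
  N-terminal effect is dominant;
* a shared transfection-response block, up-regulated in every transformed
  (non-reference) line — stable transfection and selection perturb every
  clone relative to the parent;
* an NT-suppressed response block, up-regulated in transformed lines that
  lack the N-terminal domain — the dominance of the N-terminal domain
  applied to the transfection response.

The last two blocks are what lets overlap clustering of up-regulated gene
sets reproduce the dendrogram split between N-terminal-bearing and other
lines; set their sizes to 0 for a single-planted-block design.

Growth curves follow lag -> exponential (doubling every ``true_td`` hours)
-> plateau plus Gaussian absorbance noise. Dome counts are Poisson per
field; TER filter values are Gaussian per day. Every generator records its
ground truth and is reproducible from a single seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .growth import GrowthCurve
from .io import ExpressionMatrix, SampleRecord, SampleSheet
from .phenotype import DomeRecord, TerRecord, N_FIELDS

__all__ = [
    "LineSpec",
    "SimulationConfig",
    "SimulationTruth",
    "default_study_lines",
    "simulate_expression",
    "simulate_growth",
    "simulate_phenotype",
    "STUDY_DOUBLING_TIMES_H",
    "STUDY_DOME_RATES",
    "STUDY_TER_DAILY_MEANS",
]


@dataclass(frozen=True)
class LineSpec:
    name: str
    has_ct: bool
    has_nt: bool
    is_reference: bool = False
    n_replicates: int = 3


def default_study_lines() -> list[LineSpec]:
    """The study's eight lines: parent reference plus seven constructs."""
    return [
        LineSpec("MCF-7", False, False, is_reference=True),
        LineSpec("pcDNA-blank", False, False),
        LineSpec("MT3", True, True),       # wild type: both domains
        LineSpec("MT3dCT", False, True),   # C-terminal removed
        LineSpec("MT3dNT", True, False),   # N-terminal removed
        LineSpec("MT1E", False, False),
        LineSpec("MT1E-CT", True, False),
        LineSpec("MT1E-NT", False, True),
    ]


# Fig-7-scale doubling times (hours) used as simulation ground truth for the
# study replica: parent-like lines grow fast, domain-bearing lines slowly.
STUDY_DOUBLING_TIMES_H = {
    "MCF-7": 32.5,
    "MT1E": 35.8,
    "pcDNA-blank": 39.5,
    "MT3": 53.1,
    "MT3dCT": 57.3,
    "MT3dNT": 64.7,
    "MT1E-NT": 60.9,
    "MT1E-CT": 55.2,
}

# Dome rates (domes per 100x field): the C-terminal domain without the
# N-terminal domain confers dome formation; wild-type MT3 forms rare domes.
STUDY_DOME_RATES = {
    "MCF-7": 0.0,
    "pcDNA-blank": 0.0,
    "MT3": 0.1,
    "MT3dCT": 0.0,
    "MT3dNT": 2.72,
    "MT1E": 0.0,
    "MT1E-CT": 2.69,
    "MT1E-NT": 0.0,
}

# Per-line daily TER means (Ohm*cm^2) for days 5/6/7 used as Gaussian means
# in the study replica (all lines similar: TER is domain-independent).
STUDY_TER_DAILY_MEANS = {
    "MT3": (35.32, 53.57, 52.27),
    "MT3dCT": (41.99, 53.08, 47.67),
    "MT3dNT": (26.39, 44.06, 28.16),
    "MT1E": (32.68, 35.92, 30.91),
    "MT1E-CT": (22.96, 29.34, 37.98),
    "MT1E-NT": (37.58, 34.30, 32.28),
    "MCF-7": (38.80, 22.21, 32.40),
    "pcDNA-blank": (41.99, 27.38, 36.80),
}


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Parameters of the expression generator; defaults are the study replica."""

    n_probes: int = 2000
    lines: list[LineSpec] = field(default_factory=default_study_lines)
    planted_block_size: int = 16
    ct_effect: float = 4.0
    nt_effect: float = 0.25
    shared_block_size: int = 16
    shared_effect: float = 4.0
    nt_suppressed_block_size: int = 16
    nt_suppressed_effect: float = 4.0
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 1.0
    noise_log_sd: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.ct_effect <= 1:
            raise ConfigError(f"ct_effect must exceed 1, got {self.ct_effect}")
        if not 0 < self.nt_effect < 1:
            raise ConfigError(f"nt_effect must be in (0, 1), got {self.nt_effect}")
        if self.shared_block_size and self.shared_effect <= 1:
            raise ConfigError("shared_effect must exceed 1")
        if self.nt_suppressed_block_size and self.nt_suppressed_effect <= 1:
            raise ConfigError("nt_suppressed_effect must exceed 1")
        total_block = (
            self.planted_block_size + self.shared_block_size + self.nt_suppressed_block_size
        )
        if total_block > self.n_probes:
            raise ConfigError("planted blocks exceed n_probes")
        if min(self.planted_block_size, self.shared_block_size,
               self.nt_suppressed_block_size) < 0:
            raise ConfigError("block sizes must be non-negative")
        if self.baseline_log_sd <= 0 or self.noise_log_sd < 0:
            raise ConfigError("sd parameters must be positive (noise may be 0)")
        if not any(l.is_reference for l in self.lines):
            raise ConfigError("configuration declares no reference line")
        if any(l.n_replicates < 1 for l in self.lines):
            raise ConfigError("n_replicates must be >= 1")
        names = [l.name for l in self.lines]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate line names")


@dataclass
class SimulationTruth:
    """Ground truth of a simulation run (the acceptance oracle)."""

    # per line: probe_id -> true fold factor (only probes with factor != 1)
    line_fold_factors: dict[str, dict[str, float]] = field(default_factory=dict)
    # named planted blocks: block name -> probe ids
    blocks: dict[str, list[str]] = field(default_factory=dict)
    # growth: curve id -> true doubling time (hours)
    doubling_times_h: dict[str, float] = field(default_factory=dict)
    # phenotype: flask id -> true dome rate (domes per field)
    dome_rates: dict[str, float] = field(default_factory=dict)

    def regulated_probes(self, line: str, min_fold: float = 1.0) -> frozenset[str]:
        """Probes with true fold factor strictly above ``min_fold`` in a line."""
        factors = self.line_fold_factors.get(line, {})
        return frozenset(p for p, f in factors.items() if f > min_fold)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _line_fold_factor(line: LineSpec, block: str, config: SimulationConfig) -> float:
    """True fold factor of one planted block in one line (1 = unchanged)."""
    if line.is_reference:
        return 1.0
    if block == "gage_like":
        if line.has_nt:
            return config.nt_effect  # dominant suppression
        if line.has_ct:
            return config.ct_effect
        return 1.0
    if block == "transfection_shared":
        return config.shared_effect
    if block == "nt_suppressed_response":
        return 1.0 if line.has_nt else config.nt_suppressed_effect
    raise KeyError(block)


def simulate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SampleSheet, SimulationTruth]:
    """Simulate a probes x arrays intensity matrix with planted structure."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_probes
    probe_ids = [f"P{i + 1:05d}" for i in range(n)]

    sizes = {
        "gage_like": config.planted_block_size,
        "transfection_shared": config.shared_block_size,
        "nt_suppressed_response": config.nt_suppressed_block_size,
    }
    blocks: dict[str, list[str]] = {}
    offset = 0
    block_index: dict[str, np.ndarray] = {}
    for name, size in sizes.items():
        idx = np.arange(offset, offset + size)
        block_index[name] = idx
        blocks[name] = [probe_ids[i] for i in idx]
        offset += size

    baseline = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=n)

    truth = SimulationTruth(blocks=blocks)
    columns: dict[str, np.ndarray] = {}
    records: list[SampleRecord] = []
    replicate_labels = "abcdefghijklmnopqrstuvwxyz"
    for line in config.lines:
        log_fold = np.zeros(n)
        factors: dict[str, float] = {}
        for bname, idx in block_index.items():
            f = _line_fold_factor(line, bname, config)
            if f != 1.0 and idx.size:
                log_fold[idx] = np.log(f)
                for i in idx:
                    factors[probe_ids[i]] = f
        truth.line_fold_factors[line.name] = factors
        for r in range(line.n_replicates):
            rep = replicate_labels[r % len(replicate_labels)]
            array_id = f"{line.name}_{rep}"
            noise = rng.normal(0.0, config.noise_log_sd, size=n) if config.noise_log_sd else 0.0
            columns[array_id] = np.exp(baseline + log_fold + noise)
            records.append(
                SampleRecord(
                    array_id=array_id,
                    cell_line=line.name,
                    replicate=rep,
                    is_reference=line.is_reference,
                    has_ct=line.has_ct,
                    has_nt=line.has_nt,
                )
            )
    matrix = ExpressionMatrix(pd.DataFrame(columns, index=probe_ids))
    return matrix, SampleSheet(records), truth


def simulate_growth(
    true_td: float,
    t_points: Sequence[float],
    lag: float = 0.0,
    plateau_level: float = np.inf,
    noise_sd: float = 0.0,
    seed: int | None = None,
    a0: float = 0.05,
    n_wells: int = 3,
) -> tuple[GrowthCurve, float]:
    """Simulate an MTT growth curve: lag -> exponential -> plateau + noise.

    Absorbance doubles every ``true_td`` hours once the lag has elapsed,
    capped at ``plateau_level``; Gaussian noise of ``noise_sd`` absorbance
    units is added per well. Returns the curve and the true doubling time.
    """
    if true_td <= 0:
        raise ValueError(f"true_td must be positive, got {true_td}")
    t = np.asarray(t_points, dtype=float)
    if t.ndim != 1 or t.size < 3 or np.any(np.diff(t) <= 0):
        raise ValueError("t_points must be >= 3 strictly increasing values")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    effective = np.maximum(t - lag, 0.0)
    signal = np.minimum(a0 * 2.0 ** (effective / true_td), plateau_level)
    wells = np.tile(signal[:, None], (1, n_wells))
    if noise_sd > 0:
        if seed is None:
            raise ValueError("seed is required when noise_sd > 0")
        rng = np.random.default_rng(seed)
        wells = wells + rng.normal(0.0, noise_sd, size=wells.shape)
        wells = np.maximum(wells, 1e-6)
    return GrowthCurve(t, wells if n_wells > 1 else wells[:, 0]), float(true_td)


def simulate_phenotype(
    dome_rate: float,
    n_fields: int = N_FIELDS,
    n_flasks: int = 3,
    ter_mean: float | Sequence[float] = 35.0,
    ter_sd: float = 8.0,
    n_days: int = 3,
    seed: int | None = None,
    line: str = "line",
    area_cm2: float = 1.0,
    blank_ohm: float = 100.0,
) -> tuple[list[DomeRecord], list[TerRecord], dict]:
    """Simulate dome-count and TER tables for one cell line.

    Per-field dome counts are Poisson(``dome_rate``); each filter-day TER
    value is Gaussian around ``ter_mean`` (scalar, or one mean per day,
    days numbered 5, 6, ...). Raw readings are generated so that
    (mean reading - blank) * area reproduces the drawn filter value.
    Returns dome records, TER records and a truth dict.
    """
    if dome_rate < 0:
        raise ValueError(f"dome_rate must be non-negative, got {dome_rate}")
    if n_fields < 1 or n_flasks < 1 or n_days < 1:
        raise ValueError("counts must be positive")
    if seed is None:
        raise ValueError("seed is required")
    rng = np.random.default_rng(seed)
    domes = [
        DomeRecord(
            flask_id=f"{line}_flask{f + 1}",
            counts=tuple(int(c) for c in rng.poisson(dome_rate, size=n_fields)),
        )
        for f in range(n_flasks)
    ]
    means = np.broadcast_to(np.asarray(ter_mean, dtype=float), (n_days,)) \
        if np.ndim(ter_mean) == 0 else np.asarray(ter_mean, dtype=float)
    if means.size != n_days:
        raise ValueError("ter_mean must be scalar or one value per day")
    ters: list[TerRecord] = []
    for d in range(n_days):
        day = 5 + d
        for f in range(n_flasks):
            target = rng.normal(means[d], ter_sd)
            # spread 8 raw readings around the target resistance
            jitter = rng.normal(0.0, 0.5, size=8)
            readings = blank_ohm + target / area_cm2 + (jitter - jitter.mean())
            readings = np.maximum(readings, 1e-3)
            ters.append(
                TerRecord(
                    filter_id=f"{line}_filter{f + 1}",
                    day=day,
                    readings_ohm=tuple(readings),
                    blank_ohm=blank_ohm,
                    area_cm2=area_cm2,
                )
            )
    truth = {
        "dome_rate": float(dome_rate),
        "ter_means": [float(m) for m in means],
        "ter_sd": float(ter_sd),
    }
    return domes, ters, truth
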