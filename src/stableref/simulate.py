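"""Synthetic expression and RT-qPCR panels with known ground truth.

The generators emulate the study design the package targets: 12 samples in
4 condition groups (2 tissues × infected/control, 3 replicates each) for
RNA-seq FPKM matrices, and a 2-group × 6-sample layout for Cq panels.

* :func:`simulate_fpkm` draws log-normal expression around class-dependent
  means for five transcript classes — ``stable_high`` / ``stable_low``
  (low multiplicative noise, fold range capped below 2), ``variable``
  (inflated noise), ``condition_specific`` (silenced in at least one
  group) and ``silent`` (all-zero).
* :func:`simulate_cq` draws Cq values as a per-gene baseline plus additive
  Gaussian cycle noise; unstable genes get inflated noise and, with
  probability one half, a systematic between-group shift.

Both are deterministic under a fixed seed; the true stability labels are
returned alongside the data so recovery can be measured.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from stableref.io import CqMatrix, ExpressionMatrix, SampleDesign

__all__ = [
    "FpkmSimConfig",
    "CqSimConfig",
    "FpkmSim",
    "CqSim",
    "simulate_fpkm",
    "simulate_cq",
]

CLASSES = ("stable_high", "stable_low", "variable", "condition_specific", "silent")


def _default_class_counts() -> dict[str, int]:
    return {
        "stable_high": 30,
        "stable_low": 20,
        "variable": 100,
        "condition_specific": 30,
        "silent": 20,
    }


def _default_expr_ranges() -> dict[str, tuple[float, float]]:
    return {
        "stable_high": (50.0, 1000.0),
        "stable_low": (0.1, 1.0),
        "variable": (1.0, 500.0),
        "condition_specific": (10.0, 500.0),
        "silent": (0.0, 0.0),
    }


def _default_noise_cv() -> dict[str, float]:
    return {
        "stable_high": 0.05,
        "stable_low": 0.05,
        "variable": 0.8,
        "condition_specific": 0.5,
        "silent": 0.0,
    }


@dataclass
class FpkmSimConfig:
    """Configuration of the FPKM matrix generator.

    ``noise_cv`` is the target coefficient of variation of the multiplicative
    log-normal noise per class; stable classes stay well below the 20 %
    screening threshold, variable classes well above it.  ``mfc_cap`` clips
    stable-class values so their max/min fold range stays below 2.
    """

    seed: int
    groups: dict[str, int] = field(
        default_factory=lambda: {"PI": 3, "XI": 3, "PN": 3, "XN": 3}
    )
    class_counts: dict[str, int] = field(default_factory=_default_class_counts)
    base_expr_range: dict[str, tuple[float, float]] = field(
        default_factory=_default_expr_ranges
    )
    noise_cv: dict[str, float] = field(default_factory=_default_noise_cv)
    mfc_cap: float = 1.5

    def __post_init__(self) -> None:
        unknown = set(self.class_counts) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown transcript classes: {sorted(unknown)}")
        if sum(self.class_counts.values()) <= 0:
            raise ValueError("class counts must sum to a positive number")
        for cls, cv in self.noise_cv.items():
            if cls.startswith("stable") and cv >= 0.1:
                raise ValueError(f"stable class {cls} needs noise_cv < 0.1")
        if not 1.0 < self.mfc_cap < 2.0:
            raise ValueError("mfc_cap must lie in (1, 2)")

    @property
    def n_samples(self) -> int:
        return sum(self.groups.values())

    def design(self) -> SampleDesign:
        group_of: dict[str, str] = {}
        for g, n in self.groups.items():
            for r in range(1, n + 1):
                group_of[f"{g}{r}"] = g
        return SampleDesign(group_of)


class FpkmSim(NamedTuple):
    matrix: ExpressionMatrix
    design: SampleDesign
    truth: pd.Series  # transcript id -> class label


def _lognormal_sigma(cv: float) -> float:
    # CV of a log-normal: sqrt(exp(sigma^2) - 1)
    return math.sqrt(math.log(1.0 + cv * cv))


def simulate_fpkm(config: FpkmSimConfig) -> FpkmSim:
    """Draw an FPKM matrix with designated stable / variable transcripts."""
    rng = np.random.default_rng(config.seed)
    design = config.design()
    samples = design.sample_ids
    n = len(samples)
    rows: dict[str, np.ndarray] = {}
    truth: dict[str, str] = {}
    groups = list(config.groups)
    for cls in CLASSES:
        count = config.class_counts.get(cls, 0)
        lo, hi = config.base_expr_range[cls]
        sigma = _lognormal_sigma(config.noise_cv[cls])
        for i in range(count):
            tid = f"{cls}_{i:03d}"
            truth[tid] = cls
            if cls == "silent":
                rows[tid] = np.zeros(n)
                continue
            base = math.exp(rng.uniform(math.log(lo), math.log(hi)))
            vals = base * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)
            if cls.startswith("stable"):
                cap = math.sqrt(config.mfc_cap)
                vals = np.clip(vals, base / cap, base * cap)
            if cls == "condition_specific":
                n_off = int(rng.integers(1, len(groups)))
                off = rng.choice(groups, size=n_off, replace=False)
                mask = np.array([design.group_of[s] in set(off) for s in samples])
                vals = np.where(mask, 0.0, vals)
            rows[tid] = vals
    matrix = ExpressionMatrix(
        pd.DataFrame.from_dict(rows, orient="index", columns=samples),
        unit_label="FPKM",
    )
    return FpkmSim(matrix, design, pd.Series(truth, name="class"))


@dataclass
class CqSimConfig:
    """Configuration of the Cq panel generator.

    Stable genes receive only small cycle noise (default SD 0.1 cycles) and
    no between-group shift; unstable genes receive inflated noise (default
    SD 1.0) and, with probability one half, a ±``group_shift_unstable``
    offset in every non-baseline group.
    """

    seed: int
    k_genes: int = 15
    n_groups: int = 2
    n_per_group: int = 6
    stable_gene_count: int = 3
    noise_sd_stable: float = 0.1
    noise_sd_unstable: float = 1.0
    group_shift_unstable: float = 1.5
    base_cq_range: tuple[float, float] = (18.0, 32.0)

    def __post_init__(self) -> None:
        if not self.k_genes >= self.stable_gene_count >= 2:
            raise ValueError("need k_genes >= stable_gene_count >= 2")
        if self.n_groups < 1 or self.n_per_group < 2:
            raise ValueError("need >= 1 group with >= 2 samples each")
        lo, hi = self.base_cq_range
        if not 0 < lo < hi < 40:
            raise ValueError("base_cq_range must lie inside (0, 40)")

    def design(self) -> SampleDesign:
        group_of: dict[str, str] = {}
        for g in range(self.n_groups):
            for r in range(1, self.n_per_group + 1):
                group_of[f"G{g + 1}_s{r}"] = f"G{g + 1}"
        return SampleDesign(group_of)


class CqSim(NamedTuple):
    cq: CqMatrix
    design: SampleDesign
    truth_order: list[str]  # genes ascending by total perturbation


def simulate_cq(config: CqSimConfig) -> CqSim:
    """Draw a Cq panel with designated truth-stable genes.

    ``Cq[g, s] = base_g + shift_g(group of s) + N(0, noise_sd_g)``.  The
    returned truth order sorts genes by total perturbation (noise SD plus
    RMS group shift), most stable first.
    """
    rng = np.random.default_rng(config.seed)
    design = config.design()
    samples = design.sample_ids
    groups = [f"G{g + 1}" for g in range(config.n_groups)]
    gene_ids = [
        f"stable_{i:02d}" if i < config.stable_gene_count else f"unstable_{i:02d}"
        for i in range(config.k_genes)
    ]
    rows: dict[str, np.ndarray] = {}
    perturbation: dict[str, float] = {}
    for i, gid in enumerate(gene_ids):
        base = rng.uniform(*config.base_cq_range)
        stable = i < config.stable_gene_count
        noise_sd = config.noise_sd_stable if stable else config.noise_sd_unstable
        shifts = {g: 0.0 for g in groups}
        if not stable and config.n_groups > 1 and rng.random() < 0.5:
            for g in groups[1:]:
                shifts[g] = float(rng.choice([-1.0, 1.0])) * config.group_shift_unstable
        shift_vec = np.array([shifts[design.group_of[s]] for s in samples])
        cq = base + shift_vec + rng.normal(0.0, noise_sd, size=len(samples))
        cq = np.clip(cq, 1.0, 39.9)  # keep every value under the Cq<40 QC rule
        rows[gid] = cq
        perturbation[gid] = noise_sd + float(
            np.sqrt(np.mean([v**2 for v in shifts.values()]))
        )
    cq_matrix = CqMatrix(pd.DataFrame.from_dict(rows, orient="index", columns=samples))
    truth_order = sorted(gene_ids, key=lambda g: (perturbation[g], g))
    return CqSim(cq_matrix, design, truth_order)
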