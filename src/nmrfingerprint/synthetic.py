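"""Synthetic data emulating the amyloid-challenge fingerprinting study design.

The generator produces, from a single seed, everything the pipeline consumes:
a 10-condition design (control plus {Aβ40, Aβ42, α-synuclein} × {monomer,
oligomer, fibril}) with 3 biological × 2 technical replicates, a bucket table
whose ~232 buckets map onto ~78 metabolites (several correlated buckets per
metabolite, a fraction unassigned), per-sample dilution factors, and planted
condition-specific fold changes on a designated set of key metabolites.  The
planted structure is returned as a :class:`SyntheticTruth` so recovery tests
can score every pipeline stage against ground truth.

Noise is multiplicative log-normal throughout — intensities are nonnegative
and NMR error after normalization is predominantly multiplicative.  Dilution
is applied last, mirroring the physical dilution PQN is designed to remove.
A small built-in Lorentzian peak library renders full spectra for the QC and
bucketing stages; it is illustrative, not a claim about real compounds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    Bucket,
    BucketTable,
    PathwayLibrary,
    SampleMetadata,
    Spectrum,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "DEFAULT_CONDITIONS",
    "generate_design",
    "generate_bucket_table",
    "generate_latent_class_table",
    "generate_pathway_library",
    "default_peak_library",
    "buckets_for_peak_library",
    "render_spectrum",
]

DEFAULT_CONDITIONS = (
    "control",
    "abeta40_monomer", "abeta40_oligomer", "abeta40_fibril",
    "abeta42_monomer", "abeta42_oligomer", "abeta42_fibril",
    "asyn_monomer", "asyn_oligomer", "asyn_fibril",
)


def _lognormal_sigma(cv: float) -> float:
    """Log-sd of a unit-mean log-normal with coefficient of variation cv."""
    return math.sqrt(math.log(1.0 + cv * cv))


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv <= 0:
        return np.ones(size)
    sigma = _lognormal_sigma(cv)
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


@dataclass
class SyntheticConfig:
    """Study-design parameters of the generator.

    Defaults mirror the emulated study: 10 conditions × 3 biological × 2
    technical replicates (60 samples), 232 buckets of which 80% map to 78
    metabolites, 8 key metabolites carrying condition-specific fold changes
    of 1.5–3×, 15% biological and 2% technical CV, 3% independent per-bucket
    noise and per-sample dilution uniform on (0.5, 2).
    """

    n_bio: int = 3
    n_tech: int = 2
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    n_metabolites: int = 78
    n_buckets: int = 232
    n_key_metabolites: int = 8
    fold_change_range: tuple[float, float] = (1.5, 3.0)
    bio_cv: float = 0.15
    tech_cv: float = 0.02
    bucket_noise_cv: float = 0.03
    dilution_range: tuple[float, float] = (0.5, 2.0)
    unassigned_fraction: float = 0.20
    max_buckets_per_metabolite: int = 4
    base_log_sd: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_buckets < self.n_metabolites:
            raise ValueError("n_buckets must be >= n_metabolites")
        for cv in (self.bio_cv, self.tech_cv, self.bucket_noise_cv):
            if cv < 0:
                raise ValueError("CVs must be >= 0")
        lo, hi = self.fold_change_range
        if not 0 < lo <= hi:
            raise ValueError("fold changes must be positive")
        if self.n_key_metabolites > self.n_metabolites:
            raise ValueError("n_key_metabolites exceeds n_metabolites")


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery tests."""

    bucket_to_metabolite: dict[str, str]
    metabolite_ids: dict[str, str]                 # name -> compound ID
    base_concentrations: dict[str, float]
    fold_changes: pd.DataFrame                     # conditions × metabolites
    dilution_factors: dict[str, float]
    key_metabolites: list[str]

    def save(self, path: str | Path) -> None:
        payload = {
            "bucket_to_metabolite": self.bucket_to_metabolite,
            "metabolite_ids": self.metabolite_ids,
            "base_concentrations": self.base_concentrations,
            "fold_changes": {
                c: self.fold_changes.loc[c].to_dict() for c in self.fold_changes.index
            },
            "dilution_factors": self.dilution_factors,
            "key_metabolites": self.key_metabolites,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True),
                              encoding="utf-8")


def _condition_parts(condition: str) -> tuple[str, str]:
    if condition == "control":
        return "none", "control"
    protein, conformation = condition.rsplit("_", 1)
    return protein, conformation


def generate_design(config: SyntheticConfig = SyntheticConfig()) -> list[SampleMetadata]:
    """Full-factorial sample metadata: conditions × bio reps × tech reps."""
    records = []
    for cond in config.conditions:
        protein, conformation = _condition_parts(cond)
        for b in range(1, config.n_bio + 1):
            for t in range(1, config.n_tech + 1):
                records.append(
                    SampleMetadata(
                        sample_id=f"{cond}_b{b}t{t}",
                        protein=protein,
                        conformation=conformation,
                        bio_rep=b,
                        tech_rep=t,
                    )
                )
    return records


def _allocate_buckets(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[list[int], int]:
    """Counts of buckets per metabolite (1..max) plus the unassigned count."""
    n_assigned = int(round((1.0 - config.unassigned_fraction) * config.n_buckets))
    n_assigned = max(config.n_metabolites, n_assigned)
    if n_assigned > config.n_metabolites * config.max_buckets_per_metabolite:
        raise ValueError(
            "infeasible bucket allocation: too many assigned buckets for "
            f"{config.n_metabolites} metabolites at <= "
            f"{config.max_buckets_per_metabolite} buckets each"
        )
    if n_assigned > config.n_buckets:
        raise ValueError("infeasible bucket allocation: more assigned than total buckets")
    counts = [1] * config.n_metabolites
    spare = n_assigned - config.n_metabolites
    while spare > 0:
        open_idx = [i for i, c in enumerate(counts) if c < config.max_buckets_per_metabolite]
        i = int(rng.integers(len(open_idx)))
        counts[open_idx[i]] += 1
        spare -= 1
    return counts, config.n_buckets - n_assigned


def _make_bucket_grid(n_buckets: int) -> list[tuple[str, float, float]]:
    """Contiguous descending ppm intervals covering a typical 1H window."""
    left0, right0 = 9.5, 0.5
    width = (left0 - right0) / n_buckets
    out = []
    for i in range(n_buckets):
        left = left0 - i * width
        right = left - width
        out.append((f"{left:.4f}..{right:.4f}", round(left, 4), round(right, 4)))
    return out


def generate_bucket_table(
    config: SyntheticConfig = SyntheticConfig(),
) -> tuple[BucketTable, list[SampleMetadata], SyntheticTruth]:
    """Generate a bucket table with planted effects, plus metadata and truth.

    Generative model: metabolite base concentrations are log-normal (median
    1, log-sd ``base_log_sd``); key metabolites are multiplied per condition
    by a fold change drawn uniformly from ``fold_change_range`` with random
    direction (up or down); each biological replicate carries a shared
    log-normal effect (CV ``bio_cv``) and each sample an independent
    technical effect (CV ``tech_cv``); every bucket is a fixed
    proportionality constant times its metabolite's level times independent
    per-bucket noise (CV ``bucket_noise_cv``); unassigned buckets are
    independent log-normal; finally each sample row is multiplied by a
    dilution factor uniform on ``dilution_range``.
    """
    rng = np.random.default_rng(config.seed)
    metadata = generate_design(config)
    samples = [m.sample_id for m in metadata]
    n_samples = len(samples)

    met_names = [f"met{i + 1:03d}" for i in range(config.n_metabolites)]
    met_ids = {m: f"C{i + 1:05d}" for i, m in enumerate(met_names)}
    counts, n_unassigned = _allocate_buckets(config, rng)

    base = np.exp(rng.normal(0.0, config.base_log_sd, size=config.n_metabolites))

    key_idx = rng.choice(config.n_metabolites, size=config.n_key_metabolites, replace=False)
    key_set = sorted(met_names[i] for i in key_idx)

    fold = np.ones((len(config.conditions), config.n_metabolites))
    lo, hi = config.fold_change_range
    for ci, cond in enumerate(config.conditions):
        if cond == "control":
            continue
        for mi in key_idx:
            magnitude = rng.uniform(lo, hi)
            up = rng.random() < 0.5
            fold[ci, mi] = magnitude if up else 1.0 / magnitude
    fold_df = pd.DataFrame(fold, index=list(config.conditions), columns=met_names)

    cond_of = {m.sample_id: m.condition for m in metadata}
    cond_index = {c: i for i, c in enumerate(config.conditions)}

    # per (condition, bio replicate) biological effect, shared by tech reps
    bio_eff: dict[tuple[str, int], np.ndarray] = {}
    for cond in config.conditions:
        for b in range(1, config.n_bio + 1):
            bio_eff[(cond, b)] = _lognormal_noise(rng, config.bio_cv, config.n_metabolites)

    levels = np.empty((n_samples, config.n_metabolites))
    for si, m in enumerate(metadata):
        tech = _lognormal_noise(rng, config.tech_cv, config.n_metabolites)
        levels[si] = (
            base
            * fold[cond_index[m.condition]]
            * bio_eff[(m.condition, m.bio_rep)]
            * tech
        )

    grid = _make_bucket_grid(config.n_buckets)
    # interleave assigned and unassigned buckets deterministically across the grid
    assignment: list[str | None] = []
    for mi, c in enumerate(counts):
        assignment += [met_names[mi]] * c
    assignment += [None] * n_unassigned
    rng.shuffle(assignment)  # type: ignore[arg-type]

    buckets: list[Bucket] = []
    values = np.empty((n_samples, config.n_buckets))
    met_index = {m: i for i, m in enumerate(met_names)}
    for j, ((bid, left, right), met) in enumerate(zip(grid, assignment)):
        if met is None:
            b_base = float(np.exp(rng.normal(0.0, config.base_log_sd)))
            noise_cv = math.sqrt(config.bio_cv ** 2 + config.tech_cv ** 2)
            col = b_base * _lognormal_noise(rng, noise_cv, n_samples)
            buckets.append(Bucket(bid, left, right))
        else:
            prop = float(rng.uniform(0.5, 1.5))
            noise = _lognormal_noise(rng, config.bucket_noise_cv, n_samples)
            col = prop * levels[:, met_index[met]] * noise
            buckets.append(Bucket(bid, left, right, annotation=met,
                                  metabolite_id=met_ids[met]))
        values[:, j] = col

    dilution = rng.uniform(config.dilution_range[0], config.dilution_range[1],
                           size=n_samples)
    values *= dilution[:, None]

    truth = SyntheticTruth(
        bucket_to_metabolite={
            b.bucket_id: b.annotation for b in buckets if b.annotation
        },
        metabolite_ids=met_ids,
        base_concentrations={m: float(v) for m, v in zip(met_names, base)},
        fold_changes=fold_df,
        dilution_factors={s: float(d) for s, d in zip(samples, dilution)},
        key_metabolites=key_set,
    )
    return BucketTable(samples, buckets, values), metadata, truth


def generate_latent_class_table(
    rng: np.random.Generator,
    n_per: int = 10,
    n_buckets: int = 40,
    d: float = 6.0,
    h: float = 2.0,
    noise_sd: float = 1.0,
) -> tuple[BucketTable, dict[str, str]]:
    """Four groups whose means span exactly three latent components.

    Group means sit at (±d, 0, 0), (0, d, ±h) in a 3-dimensional latent space
    embedded in bucket space by a random orthonormal map; two of the groups
    differ only along the third, lowest-variance component, so any analysis
    truncated to two components cannot tell them apart.  Used to validate
    cross-validated dimensionality selection.
    """
    B = np.linalg.qr(rng.normal(size=(n_buckets, 3)))[0].T
    centers = {"a": (d, 0.0, 0.0), "b": (-d, 0.0, 0.0),
               "c": (0.0, d, h), "d": (0.0, d, -h)}
    rows, labels = [], {}
    i = 0
    for g in sorted(centers):
        for _ in range(n_per):
            rows.append(np.array(centers[g]) @ B * 3 + rng.normal(size=n_buckets) * noise_sd)
            labels[f"s{i}"] = g
            i += 1
    X = np.array(rows)
    buckets = [Bucket(f"{9.0 - 0.05 * j:.3f}..{8.96 - 0.05 * j:.3f}",
                      round(9.0 - 0.05 * j, 3), round(8.96 - 0.05 * j, 3))
               for j in range(n_buckets)]
    table = BucketTable([f"s{i}" for i in range(X.shape[0])], buckets, X)
    return table, labels


def generate_pathway_library(
    n_pathways: int = 250,
    n_compounds: int = 5432,
    size_range: tuple[int, int] = (5, 60),
    n_types: int = 0,
    seed: int = 0,
) -> PathwayLibrary:
    """A random pathway library over a fixed compound universe.

    Pathway sizes are uniform on ``size_range`` and members are drawn without
    replacement from the universe; with ``n_types > 0`` each pathway gets a
    type label (for type-grouped ranking).  The explicit universe is the full
    compound set, mirroring a fixed-size reference database.
    """
    rng = np.random.default_rng(seed)
    compounds = [f"C{i + 1:05d}" for i in range(n_compounds)]
    pathways = {}
    types = {}
    for p in range(n_pathways):
        pid = f"path{p + 1:04d}"
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        members = rng.choice(n_compounds, size=size, replace=False)
        pathways[pid] = (f"synthetic pathway {p + 1}",
                         frozenset(compounds[i] for i in members))
        if n_types > 0:
            types[pid] = f"type{int(rng.integers(n_types)) + 1}"
    return PathwayLibrary(pathways, universe=set(compounds), types=types)


# ---------------------------------------------------------------------------
# spectrum rendering
# ---------------------------------------------------------------------------

# metabolite -> multiplet lines (center ppm, relative area, linewidth Hz);
# shifts and multiplicities are plausible for a polar cell extract but the
# library is illustrative only.
_PEAK_LIBRARY: dict[str, list[tuple[float, float, float]]] = {
    "alanine": [(1.47, 0.5, 1.2), (1.49, 0.5, 1.2), (3.78, 0.25, 1.2)],
    "lactate": [(1.32, 0.5, 1.2), (1.34, 0.5, 1.2), (4.11, 0.25, 1.3)],
    "acetate": [(1.91, 1.0, 1.1)],
    "glutamine": [(2.13, 0.5, 1.4), (2.45, 0.5, 1.4)],
    "glutamate": [(2.05, 0.5, 1.4), (2.34, 0.5, 1.4)],
    "creatine": [(3.03, 0.6, 1.1), (3.92, 0.4, 1.1)],
    "creatinine": [(3.04, 0.6, 1.1), (4.05, 0.4, 1.1)],
    "choline": [(3.19, 1.0, 1.1)],
    "phosphocholine": [(3.21, 1.0, 1.1)],
    "taurine": [(3.25, 0.5, 1.3), (3.42, 0.5, 1.3)],
    "glycine": [(3.55, 1.0, 1.1)],
    "myoinositol": [(3.27, 0.3, 1.3), (3.52, 0.4, 1.3), (4.06, 0.3, 1.3)],
    "dimethylamine": [(2.72, 1.0, 1.1)],
    "formate": [(8.44, 1.0, 1.2)],
    "atp": [(6.15, 0.3, 1.5), (8.26, 0.35, 1.5), (8.54, 0.35, 1.5)],
}


def default_peak_library() -> dict[str, list[tuple[float, float, float]]]:
    """The built-in illustrative multiplet library (~15 metabolites)."""
    return {k: list(v) for k, v in _PEAK_LIBRARY.items()}


def buckets_for_peak_library(
    peak_library: Mapping[str, Sequence[tuple[float, float, float]]],
    half_width_ppm: float = 0.02,
) -> list[Bucket]:
    """One bucket per spectral line, annotated with its metabolite."""
    buckets = []
    for met in sorted(peak_library):
        for center, _, _ in peak_library[met]:
            left, right = center + half_width_ppm, center - half_width_ppm
            buckets.append(
                Bucket(f"{left:.4f}..{right:.4f}", round(left, 4), round(right, 4),
                       annotation=met)
            )
    return buckets


def lorentzian(ppm: np.ndarray, center: float, area: float, width_ppm: float) -> np.ndarray:
    """Area-normalized Lorentzian line: integrates to ``area``; apex
    ``2 area / (π width)``."""
    hw = width_ppm / 2.0
    return area * (width_ppm / (2.0 * math.pi)) / ((ppm - center) ** 2 + hw ** 2)


def render_spectrum(
    levels: Mapping[str, float],
    peak_library: Mapping[str, Sequence[tuple[float, float, float]]] | None = None,
    sample_id: str = "synthetic",
    spectrometer_freq: float = 600.13,
    ppm_range: tuple[float, float] = (-0.5, 10.0),
    n_points: int = 32768,
    tsp_area: float = 1.0,
    tsp_linewidth_hz: float = 1.0,
    baseline_coeffs: Sequence[float] | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Spectrum:
    """Render a 1D spectrum as a sum of Lorentzian multiplets plus TSP.

    Each metabolite's lines are scaled by its level; a TSP reference singlet
    at 0 ppm, an optional polynomial baseline (coefficients in ascending
    powers of ppm) and optional Gaussian noise complete the trace.
    """
    if peak_library is None:
        peak_library = _PEAK_LIBRARY
    lo, hi = ppm_range
    ppm = np.linspace(hi, lo, n_points)  # descending display convention
    intensity = np.zeros_like(ppm)
    margin = 0.05
    for met, level in levels.items():
        if met not in peak_library:
            raise KeyError(f"metabolite {met!r} not in peak library")
        for center, rel_area, lw_hz in peak_library[met]:
            if not (lo + margin) <= center <= (hi - margin):
                raise ValueError(
                    f"line of {met!r} at {center} ppm overlaps the spectral edge "
                    f"[{lo}, {hi}]"
                )
            width_ppm = lw_hz / spectrometer_freq
            intensity += lorentzian(ppm, center, level * rel_area, width_ppm)
    # TSP reference singlet
    intensity += lorentzian(ppm, 0.0, tsp_area, tsp_linewidth_hz / spectrometer_freq)
    if baseline_coeffs is not None:
        intensity += np.polynomial.polynomial.polyval(ppm, np.asarray(baseline_coeffs))
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        intensity += rng.normal(0.0, noise_sd, size=n_points)
    return Spectrum(sample_id=sample_id, ppm=ppm, intensity=intensity,
                    spectrometer_freq=spectrometer_freq)
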