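"""Synthetic STR profiles, drifted variants, and peak tables.

Real mouse STR reference data are scarce: no public allele-frequency tables
exist for the CellCheck panel loci, and typed profiles live in curated
databases. This module generates panel-conformant stand-ins so that parsing,
scoring, search and calling can all be exercised end to end:

* :func:`generate_profile` draws diploid genotypes uniformly inside each
  marker's known allele range (uniform sampling is a modelling convenience,
  not population genetics — documented in the methods note);
* :func:`mutate_profile` emulates the genetic drift of continuous cell
  lines: per-allele dropout and ±1-repeat shifts;
* :func:`generate_peak_table` turns a profile into an electropherogram
  summary, with optional contaminant mixture, for the calling stage.

All randomness flows through a single integer seed; equal configurations
produce bitwise-equal outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .allele_calling import Peak
from .profile_model import (
    Allele,
    Genotype,
    MarkerDefinition,
    STRProfile,
)

__all__ = [
    "SimConfig",
    "generate_profile",
    "mutate_profile",
    "generate_peak_table",
    "drop_alleles",
]


@dataclass(frozen=True)
class SimConfig:
    """Knobs for the generators; all probabilities in [0, 1].

    ``het_prob``
        chance a marker is heterozygous (two draws instead of one);
    ``microvariant_prob``
        chance a drawn allele carries a partial-repeat microvariant;
    ``dropout_rate`` / ``shift_rate``
        per-allele drift probabilities for :func:`mutate_profile`;
    ``contaminant_fraction``
        mixture proportion for contaminant peaks in peak tables;
    ``rfu_threshold``
        calling threshold that peak heights are scaled to clear.
    """

    seed: int = 0
    het_prob: float = 0.5
    microvariant_prob: float = 0.15
    dropout_rate: float = 0.0
    shift_rate: float = 0.0
    contaminant_fraction: float = 0.0
    rfu_threshold: float = 100.0

    def __post_init__(self) -> None:
        for name in (
            "het_prob",
            "microvariant_prob",
            "dropout_rate",
            "shift_rate",
            "contaminant_fraction",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]: {value}")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))


def _draw_allele(marker: MarkerDefinition, cfg: SimConfig, rng: np.random.Generator) -> Allele:
    lo, hi = marker.integer_repeat_range()
    repeats = int(rng.integers(lo, hi + 1))
    allele = Allele(repeats)
    if rng.random() < cfg.microvariant_prob:
        candidate = Allele(repeats, int(rng.integers(1, 4)))
        # keep the microvariant only if it stays inside the known range
        if marker.contains(candidate):
            allele = candidate
    return allele


def generate_profile(
    panel: Sequence[MarkerDefinition],
    config: SimConfig = SimConfig(),
    name: str = "synthetic",
) -> STRProfile:
    """Draw a diploid profile with every marker typed (1–2 alleles in range).

    Heterozygous markers draw two alleles independently; a collision (both
    draws equal) collapses to a homozygous single allele, as in real typing.
    """
    if not panel:
        raise ValueError("panel must be non-empty")
    rng = config.rng(salt=1)
    profile = STRProfile(name=name)
    for marker in panel:
        alleles = {_draw_allele(marker, config, rng)}
        if rng.random() < config.het_prob:
            alleles.add(_draw_allele(marker, config, rng))
        profile.set_genotype(marker.marker_id, Genotype(frozenset(alleles)))
    return profile


def mutate_profile(
    profile: STRProfile,
    config: SimConfig,
    panel: Sequence[MarkerDefinition] | None = None,
) -> STRProfile:
    """Apply drift: each allele is dropped with ``dropout_rate``, and each
    survivor shifts ±1 repeat with ``shift_rate`` (clipped to the marker's
    known range when a panel is supplied). Markers may become empty.
    """
    rng = config.rng(salt=2)
    by_id = (
        {m.marker_id: m for m in panel} if panel is not None else {}
    )
    mutated = STRProfile(name=f"{profile.name}-drifted", species=profile.species)
    for marker_id in profile.genotypes:
        marker = by_id.get(marker_id)
        survivors: set[Allele] = set()
        for allele in profile.genotypes[marker_id]:
            if rng.random() < config.dropout_rate:
                continue
            if rng.random() < config.shift_rate:
                step = 1 if rng.random() < 0.5 else -1
                shifted = Allele(max(allele.repeats + step, 0), allele.microvariant)
                if marker is not None and not marker.contains(shifted):
                    shifted = Allele(allele.repeats - step, allele.microvariant)
                    if marker is not None and not marker.contains(shifted):
                        shifted = allele
                allele = shifted
            survivors.add(allele)
        mutated.set_genotype(marker_id, Genotype(frozenset(survivors)))
    return mutated


def drop_alleles(profile: STRProfile, k: int) -> STRProfile:
    """Deterministically remove the first ``k`` alleles in canonical marker
    order — a drift mask with a closed-form match score against the original.
    """
    out = STRProfile(name=f"{profile.name}-minus{k}", species=profile.species)
    remaining = k
    for marker_id in profile.genotypes:
        kept = []
        for allele in profile.genotypes[marker_id]:
            if remaining > 0:
                remaining -= 1
            else:
                kept.append(allele)
        out.set_genotype(marker_id, Genotype(frozenset(kept)))
    if remaining > 0:
        raise ValueError(f"profile has fewer than k={k} alleles")
    return out


def generate_peak_table(
    profile: STRProfile,
    config: SimConfig = SimConfig(),
    contaminant_profile: STRProfile | None = None,
) -> list[Peak]:
    """Emit one peak per allele, heights log-uniform in ``[2t, 100t]`` for
    threshold ``t`` so that noise-free calling is unambiguous.

    With a contaminant profile, its alleles are added with heights scaled by
    ``contaminant_fraction`` — a two-line mixture as seen in cross-
    contaminated cultures. A contaminant allele shared with the host merges
    into the host peak (heights add).
    """
    rng = config.rng(salt=3)
    t = config.rfu_threshold

    def _height() -> float:
        return float(np.exp(rng.uniform(np.log(2 * t), np.log(100 * t))))

    heights: dict[tuple[str, Allele], float] = {}
    for marker_id in profile.genotypes:
        for allele in profile.genotypes[marker_id]:
            heights[(marker_id, allele)] = _height()
    if contaminant_profile is not None and config.contaminant_fraction > 0:
        for marker_id in contaminant_profile.genotypes:
            for allele in contaminant_profile.genotypes[marker_id]:
                h = _height() * config.contaminant_fraction
                key = (marker_id, allele)
                heights[key] = heights.get(key, 0.0) + h
    return [
        Peak(marker_id, allele, round(h, 1))
        for (marker_id, allele), h in heights.items()
    ]
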