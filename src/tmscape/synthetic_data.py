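"""Synthetic membrane proteomes with known ground truth.

The generator emulates the statistical structure that the analysis
pipeline consumes: a distribution of proteins over helix count n,
per-helix lengths near 21-26 residues, taxon-specific transmembrane
compositions (optionally placed exactly on linear or exponential
f_X-f_Phe relations), flanking/loop segments with a distinct
(charged/aromatic-enriched) composition, and optional depth-dependent
enrichment such as Trp/Tyr at the helix periphery. It makes no attempt
at biologically realistic sequence grammar beyond this compositional
and depth structure.

Every record produced passes the default filter criteria, and a fixed
seed yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .amino_acids import AMINO_ACIDS
from .record_store import (
    MULTI_PASS_TAG,
    SINGLE_PASS_TAG,
    HelixKind,
    HelixSpan,
    MPRecord,
)
from .universal_ratios import TaxonPoint


class ConfigError(ValueError):
    pass


#: Realistic default transmembrane composition in residues per helix
#: (sums to ~21.3, i.e. one bilayer-spanning helix), Leu-dominated with
#: sparse charged residues.
DEFAULT_TM_COMPOSITION: Mapping[str, float] = {
    "L": 4.0, "A": 2.0, "V": 2.0, "I": 1.8, "F": 1.7, "G": 1.6,
    "S": 1.3, "T": 1.2, "M": 0.8, "P": 0.7, "Y": 0.7, "C": 0.6,
    "W": 0.5, "N": 0.5, "Q": 0.4, "R": 0.4, "H": 0.3, "K": 0.3,
    "E": 0.3, "D": 0.2,
}

#: Flank/loop composition enriched in charged and aromatic residues, the
#: hallmark of lipid-headgroup and juxtamembrane segments; this contrast
#: with the helix interior is what border perturbation and extension
#: are sensitive to.
DEFAULT_FLANK_COMPOSITION: Mapping[str, float] = {
    "K": 0.12, "R": 0.11, "D": 0.08, "E": 0.08, "W": 0.04, "Y": 0.06,
    "F": 0.04, "G": 0.08, "S": 0.08, "P": 0.06, "L": 0.05, "A": 0.05,
    "T": 0.04, "N": 0.04, "Q": 0.03, "H": 0.03, "I": 0.03, "V": 0.03,
    "M": 0.02, "C": 0.01,
}

#: Default per-helix length weights, centered on the 21-26 residue range
#: typical of bilayer-spanning helices.
DEFAULT_HELIX_LENGTHS: Mapping[int, float] = {21: 1, 22: 2, 23: 3, 24: 3, 25: 2, 26: 1}


@dataclass(frozen=True)
class DepthWeight:
    """Multiplies a residue's base weight at peripheral depths |m| >= cutoff."""

    multiplier: float
    cutoff: int

    def __post_init__(self) -> None:
        if self.multiplier < 0 or self.cutoff < 0:
            raise ConfigError("depth weights must be non-negative")


#: A taxon spec is either an explicit composition or an f_Phe coordinate
#: (the latter requires a ratio_model to derive the other residues).
TaxonSpec = Union[Mapping[str, float], float]

#: Ratio relations per residue: ("linear", a, b) or ("exp", a, b, c).
RatioRelation = Tuple


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic proteome (or taxon panel)."""

    taxa: Tuple[Tuple[str, Optional[TaxonSpec]], ...] = (("Synthetica", None),)
    n_distribution: Mapping[int, int] = field(
        default_factory=lambda: {1: 40, 2: 60, 3: 50, 4: 40, 5: 30, 6: 20, 7: 10}
    )
    helix_length_distribution: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_HELIX_LENGTHS)
    )
    flank_length: int = 10
    flank_composition: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FLANK_COMPOSITION)
    )
    depth_model: Optional[Mapping[str, DepthWeight]] = None
    ratio_model: Optional[Mapping[str, RatioRelation]] = None
    reference: str = "F"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_distribution:
            raise ConfigError("n_distribution must not be empty")
        for n, count in self.n_distribution.items():
            if n < 1 or count < 0:
                raise ConfigError(f"invalid n_distribution entry ({n}: {count})")
        if self.flank_length < 1:
            raise ConfigError("flank_length must be >= 1")
        if any(l < 1 or w < 0 for l, w in self.helix_length_distribution.items()):
            raise ConfigError("invalid helix_length_distribution")


def _normalize(comp: Mapping[str, float]) -> np.ndarray:
    p = np.array([float(comp.get(aa, 0.0)) for aa in AMINO_ACIDS])
    if (p < 0).any():
        raise ConfigError("composition has negative entries")
    total = p.sum()
    if total <= 0:
        raise ConfigError("composition does not normalize")
    return p / total


def evaluate_ratio_model(
    ratio_model: Mapping[str, RatioRelation], f_phe: float, reference: str = "F"
) -> pd.Series:
    """Target f per residue implied by the ratio relations at one f_Phe.

    Raises :class:`ConfigError` if any implied frequency is negative.
    """
    values = {reference: float(f_phe)}
    for aa in AMINO_ACIDS:
        if aa == reference:
            continue
        rel = ratio_model.get(aa)
        if rel is None:
            values[aa] = 0.0
            continue
        kind = rel[0]
        if kind == "linear":
            _, a, b = rel
            values[aa] = a * f_phe + b
        elif kind == "exp":
            _, a, b, c = rel
            values[aa] = a * float(np.exp(b * f_phe)) + c
        else:
            raise ConfigError(f"unknown relation kind {kind!r} for {aa}")
    series = pd.Series(values).loc[list(AMINO_ACIDS)]
    if (series < 0).any():
        bad = series[series < 0].index.tolist()
        raise ConfigError(f"ratio model implies negative frequencies for {bad}")
    return series


def _taxon_targets(config: SyntheticConfig, spec: Optional[TaxonSpec]) -> pd.Series:
    """Resolve a taxon spec to target f values (residues per helix)."""
    if spec is None:
        spec = DEFAULT_TM_COMPOSITION
    if isinstance(spec, (int, float)):
        if config.ratio_model is None:
            raise ConfigError("f_Phe taxon specs require a ratio_model")
        return evaluate_ratio_model(config.ratio_model, float(spec), config.reference)
    series = pd.Series({aa: float(spec.get(aa, 0.0)) for aa in AMINO_ACIDS})
    if (series < 0).any():
        raise ConfigError("composition has negative entries")
    if series.sum() <= 0:
        raise ConfigError("composition does not normalize")
    if series.sum() < 1.5:  # probabilities: scale to the mean helix length
        lengths = pd.Series(config.helix_length_distribution, dtype=float)
        mean_len = float((lengths.index * lengths).sum() / lengths.sum())
        series = series / series.sum() * mean_len
    return series


def _draw_helix(
    rng: np.random.Generator,
    length: int,
    p: np.ndarray,
    depth_model: Optional[Mapping[str, DepthWeight]],
) -> str:
    aa = np.array(AMINO_ACIDS)
    if not depth_model:
        return "".join(rng.choice(aa, size=length, p=p))
    chars = []
    center_offset = (length - 1) // 2  # floor-midpoint convention
    for j in range(length):
        m = j - center_offset
        w = p.copy()
        for residue, dw in depth_model.items():
            idx = AMINO_ACIDS.index(residue)
            if abs(m) >= dw.cutoff:
                w[idx] *= dw.multiplier
        w_sum = w.sum()
        if w_sum <= 0:
            raise ConfigError("depth model zeroes out the composition")
        chars.append(rng.choice(aa, p=w / w_sum))
    return "".join(chars)


def _helix_lengths(
    rng: np.random.Generator, config: SyntheticConfig, sigma_f: float, n: int,
    exact_length: bool,
) -> List[int]:
    if exact_length:
        # lengths average the target helix length sigma_f in expectation
        base = int(np.floor(sigma_f))
        frac = sigma_f - base
        return [base + int(rng.random() < frac) for _ in range(n)]
    lengths = sorted(config.helix_length_distribution)
    weights = np.array([config.helix_length_distribution[l] for l in lengths], float)
    weights /= weights.sum()
    return [int(rng.choice(lengths, p=weights)) for _ in range(n)]


def _generate_records(
    rng: np.random.Generator,
    config: SyntheticConfig,
    taxon: str,
    targets: pd.Series,
    exact_length: bool,
) -> List[MPRecord]:
    p = _normalize(dict(targets))
    flank_p = _normalize(config.flank_composition)
    aa = np.array(AMINO_ACIDS)
    sigma = float(targets.sum())
    flank = config.flank_length
    linker = 2 * flank  # inter-helix gap wide enough for extension and MC draws
    records: List[MPRecord] = []
    idx = 0
    for n in sorted(config.n_distribution):
        for _ in range(config.n_distribution[n]):
            idx += 1
            lengths = _helix_lengths(rng, config, sigma, n, exact_length)
            parts = ["".join(rng.choice(aa, size=flank, p=flank_p))]
            spans: List[HelixSpan] = []
            pos = flank
            for i, L in enumerate(lengths):
                helix = _draw_helix(rng, L, p, config.depth_model)
                parts.append(helix)
                spans.append(HelixSpan(start=pos + 1, end=pos + L, kind=HelixKind.HELICAL))
                pos += L
                gap = linker if i + 1 < n else flank
                parts.append("".join(rng.choice(aa, size=gap, p=flank_p)))
                pos += gap
            records.append(
                MPRecord(
                    id=f"SYN_{taxon.upper()[:8]}_{idx:06d}",
                    sequence="".join(parts),
                    lineage=("Synthetica", taxon),
                    location_tag=MULTI_PASS_TAG if n >= 2 else SINGLE_PASS_TAG,
                    existence_code=1,
                    helices=tuple(spans),
                )
            )
    return records


def generate_proteome(config: SyntheticConfig) -> List[MPRecord]:
    """Generate one proteome for the first configured taxon.

    Helix residues are drawn i.i.d. from the taxon composition (depth-
    modulated if a depth model is set); flanks and inter-helix linkers
    come from the flank composition, with linkers at least twice the
    flank length so border transforms never merge adjacent helices.
    """
    taxon, spec = config.taxa[0]
    targets = _taxon_targets(config, spec)
    rng = np.random.default_rng(config.seed)
    return _generate_records(rng, config, taxon, targets, exact_length=False)


def expected_f(config: SyntheticConfig, taxon_index: int = 0) -> pd.Series:
    """Ground-truth expected f (residues per helix) for a configured taxon.

    Exact for depth-uniform compositions: E[f_X] = p_X * E[helix length].
    """
    _, spec = config.taxa[taxon_index]
    targets = _taxon_targets(config, spec)
    if isinstance(spec, (int, float)):
        return targets  # lengths are matched to sigma_f, targets are exact
    lengths = pd.Series(config.helix_length_distribution, dtype=float)
    mean_len = float((lengths.index * lengths).sum() / lengths.sum())
    return targets / targets.sum() * mean_len


@dataclass
class TaxonPanel:
    """Per-taxon proteomes plus the exact (noise-free) placement points."""

    proteomes: Dict[str, List[MPRecord]]
    exact_points: List[TaxonPoint]
    config: SyntheticConfig


def generate_taxon_panel(config: SyntheticConfig) -> TaxonPanel:
    """Generate proteomes for >= 3 taxa whose target compositions lie
    exactly on the configured f_X-f_Phe relations.

    ``exact_points`` carries the deterministic placement (taxon means
    exactly on the curves, before sampling noise); the proteomes realise
    those targets with multinomial sampling noise. Helix lengths are
    drawn to match each taxon's target helix length in expectation.
    """
    if config.ratio_model is None:
        raise ConfigError("generate_taxon_panel requires a ratio_model")
    if len(config.taxa) < 3:
        raise ConfigError("a taxon panel requires at least 3 taxa")
    rng = np.random.default_rng(config.seed)
    proteomes: Dict[str, List[MPRecord]] = {}
    exact_points: List[TaxonPoint] = []
    for taxon, spec in config.taxa:
        if not isinstance(spec, (int, float)):
            raise ConfigError(
                f"taxon {taxon!r}: panel taxa must be specified by their f_Phe coordinate"
            )
        targets = _taxon_targets(config, spec)
        exact_points.append(TaxonPoint(taxon=taxon, f_mean=targets))
        proteomes[taxon] = _generate_records(rng, config, taxon, targets, exact_length=True)
    return TaxonPanel(proteomes=proteomes, exact_points=exact_points, config=config)


def ground_truth_sidecar(config: SyntheticConfig) -> dict:
    """JSON-serialisable ground truth: per-taxon target f and depth weights."""
    out: dict = {"seed": config.seed, "taxa": {}}
    for taxon, spec in config.taxa:
        targets = _taxon_targets(config, spec)
        out["taxa"][taxon] = {aa: float(targets[aa]) for aa in AMINO_ACIDS}
    if config.depth_model:
        out["depth_model"] = {
            aa: {"multiplier": dw.multiplier, "cutoff": dw.cutoff}
            for aa, dw in config.depth_model.items()
        }
    return out
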