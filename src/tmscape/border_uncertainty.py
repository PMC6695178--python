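"""Propagation of transmembrane-border prediction uncertainty into f.

Sequence-based helix-border predictions carry an uncertainty of a few
residues. Its impact on the frequency table is assessed three ways:

* Monte-Carlo: every helix border is offset by a rounded Gaussian draw
  (default SD 3.8 residues) under the constraint that no helix shrinks
  by more than 5 residues; f is averaged over replicate perturbed
  datasets.
* Deterministic shrink/extend transforms (default 4 residues per side)
  that bracket the headgroup-inclusion question.
* An empirical border-prediction SD estimated from pairs of predicted
  vs reference (structure-derived) spans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .amino_acids import AMINO_ACIDS
from .composition_stats import FrequencyTable, compute_f
from .record_store import HelixSpan, MPRecord, ValidationError


class BorderSamplingError(RuntimeError):
    """Raised when rejection sampling for a helix exceeds the retry cap."""


class BorderTransformError(ValueError):
    pass


@dataclass(frozen=True)
class PerturbationConfig:
    """Monte-Carlo border-perturbation settings.

    ``sd`` is the Gaussian standard deviation of each border offset in
    residues; ``max_shrink`` the largest allowed loss of helix length
    relative to the annotation; draws violating it (or the sequence
    bounds, or helix ordering) are redrawn per helix up to ``retry_cap``
    times.
    """

    sd: float = 3.8
    max_shrink: int = 5
    replicates: int = 100
    seed: Optional[int] = None
    retry_cap: int = 1000

    def __post_init__(self) -> None:
        if self.sd < 0 or self.max_shrink < 0 or self.replicates < 1:
            raise ValueError("sd >= 0, max_shrink >= 0 and replicates >= 1 required")


@dataclass(frozen=True)
class BorderComparison:
    """Aligned pairs of (predicted, reference) spans for the same helices."""

    pairs: Tuple[Tuple[HelixSpan, HelixSpan], ...]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("at least one span pair required")


def perturb_record(
    record: MPRecord, config: PerturbationConfig, rng: np.random.Generator
) -> MPRecord:
    """Offset every helix border by an independent rounded Gaussian draw.

    Each helix is resampled until its perturbed span keeps at least
    length >= max(1, original length - max_shrink), stays inside the
    sequence, and does not run into the previously perturbed helix.
    Annotation kinds are preserved. With sd = 0 the record is returned
    unchanged.
    """
    if config.sd == 0:
        return record
    new_spans: List[HelixSpan] = []
    seq_len = len(record.sequence)
    prev_end = 0
    for h in record.helices:
        min_len = max(1, h.length - config.max_shrink)
        for _ in range(config.retry_cap):
            ds, de = np.rint(rng.normal(0.0, config.sd, size=2)).astype(int)
            start, end = h.start + int(ds), h.end + int(de)
            if start < 1 or end > seq_len:
                continue
            if end - start + 1 < min_len:
                continue
            if start <= prev_end:
                continue
            new_spans.append(HelixSpan(start=start, end=end, kind=h.kind))
            prev_end = end
            break
        else:
            raise BorderSamplingError(
                f"{record.id}: no admissible perturbation for helix "
                f"({h.start}, {h.end}) after {config.retry_cap} draws"
            )
    return record.with_helices(new_spans)


@dataclass
class MonteCarloTable:
    """Replicate-averaged frequency table plus across-replicate spread.

    ``table`` holds mean counts (fractional) so every downstream
    operation (sigma_f, groups, diversity, cost) applies unchanged;
    ``f_sd`` is the across-replicate standard deviation of f per (n, X).
    """

    table: FrequencyTable
    f_sd: pd.DataFrame
    replicates: int
    seed: Optional[int] = None

    @property
    def f(self) -> pd.DataFrame:
        return self.table.f


def monte_carlo_f(
    records: Sequence[MPRecord],
    config: PerturbationConfig,
    n_max: int = 19,
) -> MonteCarloTable:
    """Average compute_f over replicate border-perturbed datasets.

    Fully reproducible from ``config.seed``. Helix counts per record are
    invariant under perturbation, so the n binning and denominators are
    identical across replicates and averaging counts equals averaging f.
    """
    rng = np.random.default_rng(config.seed)
    records = list(records)
    tables: List[FrequencyTable] = []
    for _ in range(config.replicates):
        perturbed = [perturb_record(rec, config, rng) for rec in records]
        tables.append(compute_f(perturbed, n_max=n_max))
    mean_counts = tables[0].counts.copy()
    for t in tables[1:]:
        mean_counts = mean_counts.add(t.counts, fill_value=0.0)
    mean_counts /= config.replicates
    helices = tables[0].helices
    for t in tables[1:]:
        helices = helices.combine_first(t.helices)
    mean_table = FrequencyTable(
        counts=mean_counts,
        helices=helices,
        skipped_ambiguous=int(round(np.mean([t.skipped_ambiguous for t in tables]))),
    )
    if config.sd == 0:  # replicates are identical by construction
        sd_values = np.zeros((len(mean_table.counts.index), len(AMINO_ACIDS)))
    else:
        f_stack = [t.f.reindex(index=mean_table.counts.index).fillna(0.0) for t in tables]
        sd_values = np.stack([fr.to_numpy(dtype=float) for fr in f_stack]).std(axis=0, ddof=0)
    f_sd = pd.DataFrame(
        sd_values,
        index=mean_table.counts.index,
        columns=mean_table.counts.columns,
    )
    return MonteCarloTable(
        table=mean_table, f_sd=f_sd, replicates=config.replicates, seed=config.seed
    )


def shrink_borders(record: MPRecord, k: int = 4) -> MPRecord:
    """Symmetrically shrink every helix span by k residues on each side."""
    if k < 0:
        raise ValueError("k must be >= 0")
    spans = []
    for h in record.helices:
        start, end = h.start + k, h.end - k
        if end < start:
            raise BorderTransformError(
                f"{record.id}: shrinking helix ({h.start}, {h.end}) by {k} "
                "collapses it below one residue"
            )
        spans.append(HelixSpan(start=start, end=end, kind=h.kind))
    return record.with_helices(spans)


def extend_borders(record: MPRecord, k: int = 4) -> MPRecord:
    """Symmetrically extend every helix span by k residues on each side.

    Extension is clipped at the sequence ends and, for interior helices,
    at the midpoint of the gap to the neighbouring span so that spans
    never merge or overlap.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    seq_len = len(record.sequence)
    old = record.helices
    spans = []
    for i, h in enumerate(old):
        start = max(1, h.start - k)
        end = min(seq_len, h.end + k)
        if i > 0:
            gap_mid = (old[i - 1].end + h.start) // 2 + 1
            start = max(start, gap_mid)
        if i + 1 < len(old):
            gap_mid = (h.end + old[i + 1].start) // 2
            end = min(end, gap_mid)
        spans.append(HelixSpan(start=start, end=end, kind=h.kind))
    return record.with_helices(spans)


def border_prediction_sd(comparison: BorderComparison, centered: bool = False) -> float:
    """Spread of predicted-minus-reference border positions, in residues.

    Start and end differences are pooled as signed offsets. The default
    is the root-mean-square deviation (mean not removed); ``centered``
    subtracts the mean first (sample SD, ddof=1).
    """
    diffs = []
    for predicted, reference in comparison.pairs:
        diffs.append(predicted.start - reference.start)
        diffs.append(predicted.end - reference.end)
    arr = np.asarray(diffs, dtype=float)
    if centered:
        if arr.size < 2:
            raise ValueError("centered mode needs at least two border differences")
        return float(arr.std(ddof=1))
    return float(np.sqrt(np.mean(arr**2)))


def rounded_truncated_sd(
    sd: float, max_shrink: int = 5, offset_range: int = 60
) -> float:
    """SD of one accepted border offset under the joint shrink constraint.

    Independent start/end offsets are rounded Gaussian draws; a pair is
    accepted when the length change (end offset - start offset) is at
    least -max_shrink. The marginal SD of one accepted offset is
    computed by direct summation over the integer offset grid. Serves as
    the closed-form reference for the Monte-Carlo sampler.
    """
    from scipy.stats import norm

    ks = np.arange(-offset_range, offset_range + 1)
    p = norm.cdf(ks + 0.5, scale=sd) - norm.cdf(ks - 0.5, scale=sd)
    joint = np.outer(p, p)  # [start, end]
    accept = (ks[None, :] - ks[:, None]) >= -max_shrink
    joint = np.where(accept, joint, 0.0)
    total = joint.sum()
    marg_start = joint.sum(axis=1) / total
    mean = float((ks * marg_start).sum())
    var = float(((ks - mean) ** 2 * marg_start).sum())
    return float(np.sqrt(var))
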