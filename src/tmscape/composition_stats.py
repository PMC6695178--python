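"""Transmembrane amino-acid frequency statistics.

The central quantity is the frequency f(n, X): for proteins with n
annotated transmembrane helices, the total count of residue X inside the
helices divided by the number of examined helices. f is therefore
expressed in residues per helix, and its sum over the 20 amino acids
equals the mean examined-helix length for that n bin.

Depth profiles f(n, X, m) resolve the same counts by residue position m
relative to the helix center (m = 0 at the center, negative toward the
N-terminus); an optional symmetric extension widens the counted window
beyond the annotated borders into the lipid headgroup region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .amino_acids import AMINO_ACIDS, AMBIGUITY_LETTERS, GroupScheme, SchemeError
from .record_store import MPRecord, ValidationError

#: An f-vs-n curve: a float Series indexed by strictly increasing n.
FrequencySeries = pd.Series


@dataclass
class FrequencyTable:
    """Per-n amino-acid counts and the derived frequencies f(n, X).

    ``counts`` holds residue counts (rows: n, columns: the 20 amino
    acids); ``helices`` the number of examined helices per n bin. Bins
    with zero helices are absent rather than zero. Counts may be
    fractional when the table is an average over Monte-Carlo replicates.
    """

    counts: pd.DataFrame
    helices: pd.Series
    skipped_ambiguous: int = 0

    def __post_init__(self) -> None:
        self.counts = self.counts.reindex(columns=list(AMINO_ACIDS)).fillna(0.0)
        self.counts.index = self.counts.index.astype(int)
        self.helices = self.helices.astype(float)
        self.helices.index = self.helices.index.astype(int)
        populated = self.helices[self.helices > 0].index
        self.counts = self.counts.loc[populated].sort_index()
        self.helices = self.helices.loc[populated].sort_index()
        self.counts.index.name = "n"
        self.helices.index.name = "n"

    @property
    def f(self) -> pd.DataFrame:
        """f(n, X) in residues per helix."""
        return self.counts.div(self.helices, axis=0)

    @property
    def bins(self) -> List[int]:
        return list(self.helices.index)

    def bin_f(self, n: int) -> pd.Series:
        if n not in self.helices.index:
            raise KeyError(f"no helices examined for n={n}")
        return self.f.loc[n]

    def merge(self, other: "FrequencyTable") -> "FrequencyTable":
        """Combine count tables from two batches of records."""
        counts = self.counts.add(other.counts, fill_value=0.0)
        helices = self.helices.add(other.helices, fill_value=0.0)
        return FrequencyTable(
            counts=counts,
            helices=helices,
            skipped_ambiguous=self.skipped_ambiguous + other.skipped_ambiguous,
        )

    def to_frame(self, taxon: str = "") -> pd.DataFrame:
        """Long-format table: taxon, n, AA, count, helices, f."""
        rows = []
        f = self.f
        for n in self.bins:
            for aa in AMINO_ACIDS:
                rows.append(
                    (taxon, n, aa, self.counts.at[n, aa], self.helices.at[n], f.at[n, aa])
                )
        return pd.DataFrame(rows, columns=["taxon", "n", "AA", "count", "helices", "f"])


@dataclass
class PositionalProfile:
    """Depth-resolved frequencies f(n, X, m).

    The helix center is the floor of the span midpoint, so even-length
    helices sit one residue toward the N-terminus. The per-(n, m)
    denominator is the number of helices that contribute a residue at
    that depth, keeping f at residues-per-contributing-helix semantics
    at every m.
    """

    counts: pd.DataFrame          # rows MultiIndex (n, m), columns AA
    helices_at: pd.Series         # (n, m) -> contributing helices
    extension: int = 0
    parity: Optional[str] = None  # None, "even" or "odd" helix lengths

    @property
    def f(self) -> pd.DataFrame:
        return self.counts.div(self.helices_at, axis=0)

    def profile(self, n: int, aa: str) -> pd.Series:
        """f(m) for one (n, X), indexed by m."""
        return self.f.xs(n, level="n")[aa]

    def to_frame(self, taxon: str = "") -> pd.DataFrame:
        f = self.f.stack()
        f.index.names = ["n", "m", "AA"]
        out = f.rename("f").reset_index()
        out.insert(0, "taxon", taxon)
        return out[["taxon", "n", "AA", "m", "f"]]


def _count_span(sequence: str, start: int, end: int) -> Tuple[np.ndarray, int]:
    """Counts of the 20 canonical AA in sequence[start-1:end]; second value
    is the number of ambiguity letters skipped."""
    counts = np.zeros(len(AMINO_ACIDS))
    skipped = 0
    segment = sequence[start - 1 : end].upper()
    for ch in segment:
        idx = _AA_INDEX.get(ch)
        if idx is None:
            if ch in AMBIGUITY_LETTERS:
                skipped += 1
            else:  # defensive; record validation should have caught it
                raise ValidationError(f"unexpected letter {ch!r} in span")
        else:
            counts[idx] += 1
    return counts, skipped


_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def compute_f(records: Iterable[MPRecord], n_max: int = 19) -> FrequencyTable:
    """Amino-acid counts per helix-count bin n = 1..n_max.

    Residues are counted only inside annotated helix spans (apply any
    border transform upstream). Records with n > n_max are excluded.
    Ambiguity letters add to helix length implicitly but are excluded
    from counts; their number is reported on the table.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    count_rows: dict[int, np.ndarray] = {}
    helix_counts: dict[int, float] = {}
    skipped_total = 0
    for rec in records:
        n = rec.n
        if n > n_max:
            continue
        if rec.helices[-1].end > len(rec.sequence):
            raise ValidationError(f"{rec.id}: helix span outside sequence")
        row = count_rows.setdefault(n, np.zeros(len(AMINO_ACIDS)))
        for h in rec.helices:
            c, skipped = _count_span(rec.sequence, h.start, h.end)
            row += c
            skipped_total += skipped
        helix_counts[n] = helix_counts.get(n, 0.0) + n
    counts = pd.DataFrame(count_rows, index=list(AMINO_ACIDS)).T.sort_index()
    if counts.empty:
        counts = pd.DataFrame(columns=list(AMINO_ACIDS), dtype=float)
    return FrequencyTable(
        counts=counts,
        helices=pd.Series(helix_counts, dtype=float),
        skipped_ambiguous=skipped_total,
    )


def compute_f_nm(
    records: Iterable[MPRecord],
    extension: int = 0,
    n_max: int = 19,
    parity: Optional[str] = None,
) -> PositionalProfile:
    """Depth profiles f(n, X, m) with an optional border extension.

    Each residue at sequence position i of a helix contributes at depth
    m = i - center(helix). ``extension`` widens the window by that many
    residues on both helix sides, clipped at the sequence ends.
    ``parity`` restricts the examined helices to even- or odd-length
    ones, which keeps the center convention comparable across helices.
    """
    if extension < 0:
        raise ValueError("extension must be >= 0")
    if parity not in (None, "even", "odd"):
        raise ValueError("parity must be None, 'even' or 'odd'")
    counts: dict[tuple[int, int], np.ndarray] = {}
    helices_at: dict[tuple[int, int], float] = {}
    for rec in records:
        n = rec.n
        if n > n_max:
            continue
        for h in rec.helices:
            if parity == "even" and h.length % 2 != 0:
                continue
            if parity == "odd" and h.length % 2 != 1:
                continue
            center = h.center
            lo = max(1, h.start - extension)
            hi = min(len(rec.sequence), h.end + extension)
            for i in range(lo, hi + 1):
                m = i - center
                key = (n, m)
                ch = rec.sequence[i - 1].upper()
                row = counts.setdefault(key, np.zeros(len(AMINO_ACIDS)))
                helices_at[key] = helices_at.get(key, 0.0) + 1
                idx = _AA_INDEX.get(ch)
                if idx is not None:
                    row[idx] += 1
    if counts:
        index = pd.MultiIndex.from_tuples(sorted(counts), names=["n", "m"])
        mat = pd.DataFrame(
            [counts[k] for k in sorted(counts)], index=index, columns=list(AMINO_ACIDS)
        )
        denom = pd.Series([helices_at[k] for k in sorted(counts)], index=index)
    else:
        index = pd.MultiIndex.from_tuples([], names=["n", "m"])
        mat = pd.DataFrame(index=index, columns=list(AMINO_ACIDS), dtype=float)
        denom = pd.Series(index=index, dtype=float)
    return PositionalProfile(counts=mat, helices_at=denom, extension=extension, parity=parity)


def group_frequencies(table: FrequencyTable, scheme: GroupScheme) -> pd.DataFrame:
    """Per-group frequency sums: value(n, g) = sum of f(n, X) over X in g."""
    f = table.f
    out = {}
    for name, members in scheme.groups.items():
        cols = sorted(members)
        unknown = set(cols) - set(AMINO_ACIDS)
        if unknown:
            raise SchemeError(f"unknown amino acids in group {name!r}: {unknown}")
        out[name] = f[cols].sum(axis=1)
    return pd.DataFrame(out)


def sigma_f(table: FrequencyTable) -> FrequencySeries:
    """Mean examined-helix length per n bin: the sum of f over all AA."""
    return table.f.sum(axis=1).rename("sigma_f")


def running_average(series: FrequencySeries, window: int = 2) -> FrequencySeries:
    """Forward running average over n bins.

    The value reported at n is the mean of the raw values at bins
    {n, ..., n+window-1} that are present in the series; trailing partial
    windows shrink to the available points, so the output has the same
    index as the input.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if series.empty:
        return series.copy()
    idx = series.index
    values = [
        series.loc[[j for j in range(n, n + window) if j in idx]].mean() for n in idx
    ]
    return pd.Series(values, index=idx, name=series.name)


def sampling_uncertainty(table: FrequencyTable, mode: str = "literal") -> pd.DataFrame:
    """Finite-database sampling uncertainty per (n, X).

    ``literal`` evaluates 2*sqrt(count/4) on the per-bin residue count
    (algebraically equal to sqrt(count); a count-scale, not an f-scale,
    quantity). ``binomial`` instead propagates the Poisson error of the
    count onto the f scale, sqrt(count)/helices. Neither mode is asserted
    to be the "right" one; they bracket the sensible interpretations.
    """
    counts = table.counts
    if mode == "literal":
        return 2.0 * np.sqrt(counts / 4.0)
    if mode == "binomial":
        return np.sqrt(counts).div(table.helices, axis=0)
    raise ValueError(f"unknown mode {mode!r}")


def frequency_table_from_f(
    f_values: Mapping[str, float], n: int = 1, helices: float = 1.0
) -> FrequencyTable:
    """Build a single-bin table directly from f values (residues/helix).

    Useful for pushing published composition tables through the same
    operations as count-derived tables: counts are f * helices.
    """
    row = {aa: float(f_values.get(aa, 0.0)) * helices for aa in AMINO_ACIDS}
    counts = pd.DataFrame([row], index=[n])
    return FrequencyTable(counts=counts, helices=pd.Series({n: helices}))
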