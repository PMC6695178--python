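"""Shannon diversity and biosynthetic cost of transmembrane compositions.

Diversity of a TM composition is quantified by the Shannon index
H = -sum_X p_X ln p_X with p_X = f_X / sum(f), reported as the
equitability E_H = H / ln 20, which is 1 for a uniform usage of all 20
amino acids and 0 when a single residue dominates completely.

Biosynthetic cost per helix is sum_X f_X * ATP(X), in high-energy
phosphate bonds, with ATP(X) the cost of de-novo synthesis of X in
E. coli. The cost table ships as an editable two-column TSV and is
treated as configuration, not ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import IO, Mapping, Optional, Union

import numpy as np
import pandas as pd

from .amino_acids import AMINO_ACIDS
from .composition_stats import FrequencySeries, FrequencyTable

LN20 = float(np.log(20.0))

#: A probability vector over the 20 amino acids.
CompositionVector = pd.Series


class CostTableError(ValueError):
    pass


class EmptyBinError(KeyError):
    pass


@dataclass(frozen=True)
class DiversityResult:
    """Shannon index H (nats) and equitability E_H = H / ln 20."""

    H: float
    E_H: float


@dataclass(frozen=True)
class CostTable:
    """Per-amino-acid de-novo synthesis cost in high-energy phosphate bonds."""

    cost: pd.Series

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.cost.index)
        if missing:
            raise CostTableError(f"cost table missing amino acids: {sorted(missing)}")
        if (self.cost.loc[list(AMINO_ACIDS)] <= 0).any():
            raise CostTableError("all costs must be positive")
        object.__setattr__(self, "cost", self.cost.loc[list(AMINO_ACIDS)].astype(float))


def load_cost_table(source: Union[str, Path, IO[str], None] = None) -> CostTable:
    """Load a two-column (AA, cost) TSV; default is the bundled E. coli table."""
    if source is None:
        ref = resources.files("tmscape").joinpath("data/aa_costs.tsv")
        with ref.open("r") as handle:
            return load_cost_table(handle)
    frame = pd.read_csv(source, sep="\t", comment="#", header=None, names=["AA", "cost"])
    if frame["AA"].duplicated().any():
        raise CostTableError("duplicate amino-acid rows in cost table")
    series = frame.set_index("AA")["cost"]
    try:
        series = series.astype(float)
    except ValueError as exc:
        raise CostTableError(f"non-numeric cost value: {exc}") from exc
    return CostTable(cost=series)


def to_composition(table: FrequencyTable, n: int) -> CompositionVector:
    """Normalize the f values of bin n into probabilities p_X = f_X / sum(f)."""
    if n not in table.helices.index:
        raise EmptyBinError(f"no helices examined for n={n}")
    f = table.bin_f(n)
    total = f.sum()
    if total <= 0:
        raise EmptyBinError(f"bin n={n} has zero total frequency")
    return f / total


def shannon_equitability(p: CompositionVector) -> DiversityResult:
    """H = -sum p ln p (zero-probability terms contribute 0); E_H = H / ln 20."""
    values = np.asarray(p, dtype=float)
    if (values < -1e-12).any():
        raise ValueError("composition has negative entries")
    total = values.sum()
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError(f"composition sums to {total}, not 1")
    nz = values[values > 0]
    H = float(-(nz * np.log(nz)).sum())
    return DiversityResult(H=H, E_H=H / LN20)


def helix_cost(table: FrequencyTable, n: int, costs: Optional[CostTable] = None) -> float:
    """Biosynthetic cost per helix for bin n: sum_X f(n, X) * ATP(X).

    Reported positive: f and ATP(X) are non-negative, matching the
    positive cost-per-helix axis this quantity is plotted on.
    """
    if costs is None:
        costs = load_cost_table()
    if n not in table.helices.index:
        raise EmptyBinError(f"no helices examined for n={n}")
    f = table.bin_f(n)
    return float((f * costs.cost).sum())


def diversity_series(table: FrequencyTable) -> FrequencySeries:
    """E_H as a function of n over the populated bins."""
    values = {n: shannon_equitability(to_composition(table, n)).E_H for n in table.bins}
    return pd.Series(values, name="E_H").sort_index()


def cost_series(table: FrequencyTable, costs: Optional[CostTable] = None) -> FrequencySeries:
    """ATP cost per helix as a function of n over the populated bins."""
    if costs is None:
        costs = load_cost_table()
    values = {n: helix_cost(table, n, costs) for n in table.bins}
    return pd.Series(values, name="cost").sort_index()
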