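"""Taxa-level frequency ratios against a reference residue and ancestral
composition extrapolation.

Across biological taxa, the mean transmembrane frequencies of most amino
acids co-vary tightly with the mean frequency of a reference residue
(Phe by default, chosen as the residue maximising the summed squared
correlation over all candidate references). Two model families are
fitted per residue X:

* linear:      f_X = a * f_Phe + b
* exponential: f_X = a * exp(b * f_Phe) + c   (c fixed at 0 for residues
  whose f_X rises with f_Phe)

Because the reference coordinate tracks evolutionary history, the fitted
relations can be evaluated at early (even negative) f_Phe values to
extrapolate the composition of primordial membrane proteins, with
residues that had not yet entered the genetic code masked to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .amino_acids import AMINO_ACIDS, CODE_ENTRY_ORDER, GroupScheme, default_scheme
from .composition_stats import FrequencyTable


class FitError(RuntimeError):
    pass


class DegenerateReferenceError(ValueError):
    pass


@dataclass(frozen=True)
class TaxonPoint:
    """Mean f per amino acid for one taxon over an n range."""

    taxon: str
    f_mean: pd.Series

    def __post_init__(self) -> None:
        if (self.f_mean < 0).any():
            raise ValueError(f"{self.taxon}: negative mean frequencies")


@dataclass(frozen=True)
class LinearFit:
    """f_X = a * f_ref + b with Pearson correlation R of the point set."""

    a: float
    b: float
    R: float
    degenerate: bool = False

    def predict(self, f_ref: float) -> float:
        return self.a * f_ref + self.b


@dataclass(frozen=True)
class ExpFit:
    """f_X = a * exp(b * f_ref) + c; R correlates fitted with observed f_X."""

    a: float
    b: float
    c: float
    R: float
    c_constrained: bool = False
    converged: bool = True
    degenerate: bool = False

    def predict(self, f_ref: float) -> float:
        return self.a * np.exp(self.b * f_ref) + self.c


Fit = Union[LinearFit, ExpFit]


def taxon_points(
    tables: Mapping[str, FrequencyTable],
    n_range: Tuple[int, int] = (2, 7),
    weight_by_helices: bool = False,
) -> List[TaxonPoint]:
    """Average f(n, X) over the populated bins of an inclusive n range.

    The default is the unweighted mean over bins; ``weight_by_helices``
    weights each bin by its examined-helix count instead.
    """
    lo, hi = n_range
    points = []
    for taxon, table in tables.items():
        bins = [n for n in table.bins if lo <= n <= hi]
        if not bins:
            raise ValueError(f"taxon {taxon!r} has no populated bin in {lo}..{hi}")
        f = table.f.loc[bins]
        if weight_by_helices:
            w = table.helices.loc[bins]
            mean = f.mul(w, axis=0).sum(axis=0) / w.sum()
        else:
            mean = f.mean(axis=0)
        points.append(TaxonPoint(taxon=taxon, f_mean=mean))
    return points


def _xy(points: Sequence[TaxonPoint], X: str, reference: str) -> Tuple[np.ndarray, np.ndarray]:
    x = np.array([p.f_mean[reference] for p in points], dtype=float)
    y = np.array([p.f_mean[X] for p in points], dtype=float)
    return x, y


def fit_linear(points: Sequence[TaxonPoint], X: str, reference: str = "F") -> LinearFit:
    """Ordinary least squares of f_X on f_reference across taxa."""
    if len(points) < 3:
        raise FitError("linear fit requires at least 3 taxon points")
    x, y = _xy(points, X, reference)
    if np.ptp(x) == 0:
        raise DegenerateReferenceError(f"reference {reference} has zero variance")
    if np.ptp(y) == 0:
        return LinearFit(a=0.0, b=float(y[0]), R=0.0, degenerate=True)
    res = stats.linregress(x, y)
    return LinearFit(a=float(res.slope), b=float(res.intercept), R=float(res.rvalue))


def _exp_model(x: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    return a * np.exp(b * x) + c


def fit_exponential(
    points: Sequence[TaxonPoint],
    X: str,
    reference: str = "F",
    rising: Optional[bool] = None,
    n_restarts: int = 5,
    tol: float = 1e-10,
) -> ExpFit:
    """Nonlinear least squares of f_X = a*exp(b*f_ref) + c across taxa.

    ``c`` is constrained to 0 when f_X rises with the reference; by
    default "rising" is the sign (>= 0) of the linear-fit slope for the
    same residue. Initialisation is seeded from the linear fit with
    multiplicative multi-start perturbations; the best of all converged
    starts is returned. R is the Pearson correlation between fitted and
    observed f_X.
    """
    x, y = _xy(points, X, reference)
    if rising is None:
        rising = fit_linear(points, X, reference).a >= 0
    min_pts = 3 if rising else 4
    if len(points) < min_pts:
        raise FitError(f"exponential fit requires at least {min_pts} points")
    if np.ptp(y) == 0:
        return ExpFit(
            a=0.0, b=0.0, c=float(y[0]), R=0.0,
            c_constrained=rising, degenerate=True,
        )

    lin = fit_linear(points, X, reference)
    span = np.ptp(x) if np.ptp(x) > 0 else 1.0
    b0 = np.clip(lin.a / max(abs(y).max(), 1e-6), -4.0 / span, 4.0 / span)
    c0 = 0.0 if rising else float(min(y.min(), 0.0) if lin.a < 0 else y.min()) * 0.5
    a0 = float(np.mean(y) - c0) or 1e-3
    rng = np.random.default_rng(0)  # fixed: restarts are part of the algorithm

    best: Optional[Tuple[float, Tuple[float, float, float]]] = None
    for trial in range(n_restarts):
        scale = 1.0 if trial == 0 else rng.uniform(0.25, 4.0)
        shift = 0.0 if trial == 0 else rng.normal(0.0, 0.5 / span)
        p0 = [a0 * scale, float(b0) + shift] + ([] if rising else [c0])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if rising:
                    popt, _ = optimize.curve_fit(
                        lambda xx, a, b: _exp_model(xx, a, b, 0.0),
                        x, y, p0=p0, maxfev=20000, xtol=tol, ftol=tol,
                    )
                    params = (float(popt[0]), float(popt[1]), 0.0)
                else:
                    popt, _ = optimize.curve_fit(
                        _exp_model, x, y, p0=p0, maxfev=20000, xtol=tol, ftol=tol,
                    )
                    params = (float(popt[0]), float(popt[1]), float(popt[2]))
        except (RuntimeError, optimize.OptimizeWarning):
            continue
        resid = y - _exp_model(x, *params)
        sse = float(resid @ resid)
        if best is None or sse < best[0]:
            best = (sse, params)
    if best is None:
        raise FitError(f"exponential fit for {X} failed to converge in {n_restarts} starts")
    a, b, c = best[1]
    fitted = _exp_model(x, a, b, c)
    if np.ptp(fitted) == 0:
        R = 0.0
    else:
        R = float(np.corrcoef(fitted, y)[0, 1])
    return ExpFit(a=a, b=b, c=c, R=R, c_constrained=rising, degenerate=False)


def fit_all(
    points: Sequence[TaxonPoint],
    reference: str = "F",
    model: str = "linear",
) -> Dict[str, Fit]:
    """Fit every residue except the reference against the reference."""
    fits: Dict[str, Fit] = {}
    for aa in AMINO_ACIDS:
        if aa == reference:
            continue
        if model == "linear":
            fits[aa] = fit_linear(points, aa, reference)
        elif model == "exp":
            fits[aa] = fit_exponential(points, aa, reference)
        else:
            raise ValueError(f"unknown model {model!r}")
    return fits


def rank_by_R(fits: Mapping[str, Fit]) -> List[Tuple[str, float]]:
    """Residues ordered by decreasing |R|; the sign of R is retained."""
    if len(fits) < 2:
        raise ValueError("ranking requires fits for at least 2 residues")
    return sorted(
        ((aa, fit.R) for aa, fit in fits.items()),
        key=lambda item: (-abs(item[1]), item[0]),
    )


def reference_scores(points: Sequence[TaxonPoint]) -> pd.Series:
    """Sum of squared linear-fit correlations for every candidate reference.

    Degenerate residues (zero variance across taxa) contribute R = 0; a
    residue that cannot serve as reference (zero variance itself) gets a
    score of NaN.
    """
    scores = {}
    for ref in AMINO_ACIDS:
        try:
            fits = {aa: fit_linear(points, aa, ref) for aa in AMINO_ACIDS if aa != ref}
        except DegenerateReferenceError:
            scores[ref] = np.nan
            continue
        scores[ref] = float(sum(fit.R**2 for fit in fits.values()))
    return pd.Series(scores, name="sum_R2")


def select_reference(points: Sequence[TaxonPoint]) -> str:
    """The residue with the largest summed R^2 over all pairwise linear fits."""
    scores = reference_scores(points)
    return str(scores.idxmax())


@dataclass(frozen=True)
class AncestralModel:
    """Extrapolation settings: per-residue fits, code-entry mask and coordinate.

    ``k`` is the number of amino acids assumed present (the first k of
    ``code_order``); ``f_phe`` the evolutionary coordinate at which the
    fits are evaluated.
    """

    fits: Mapping[str, Fit]
    k: int = 20
    f_phe: float = 0.0
    reference: str = "F"
    code_order: Tuple[str, ...] = CODE_ENTRY_ORDER

    def __post_init__(self) -> None:
        if sorted(self.code_order) != sorted(AMINO_ACIDS):
            raise ValueError("code_order must be a permutation of the 20 amino acids")
        if not 0 <= self.k <= 20:
            raise ValueError("k must be between 0 and 20")


def extrapolate_composition(model: AncestralModel) -> Tuple[pd.Series, float]:
    """Predicted f per amino acid at the model's coordinate, plus the sum.

    Residues beyond the first k of the code order are set to 0 (not yet
    in the genetic code). The reference residue takes max(f_phe, 0); all
    others evaluate their fit at f_phe, floored at 0. Returns the
    composition in code order and its sum (the predicted helix length).
    """
    allowed = set(model.code_order[: model.k])
    values = {}
    for aa in model.code_order:
        if aa not in allowed:
            values[aa] = 0.0
        elif aa == model.reference:
            values[aa] = max(model.f_phe, 0.0)
        else:
            if aa not in model.fits:
                raise FitError(f"no fit available for allowed residue {aa}")
            values[aa] = max(float(model.fits[aa].predict(model.f_phe)), 0.0)
    comp = pd.Series(values).loc[list(model.code_order)]
    return comp, float(comp.sum())


@dataclass(frozen=True)
class CorrelationResult:
    x: str
    y: str
    r: float
    slope: float
    intercept: float
    n_taxa: int
    degenerate: bool = False


def taxa_correlations(
    points: Sequence[TaxonPoint],
    extras: Optional[Mapping[str, Mapping[str, float]]] = None,
    pairs: Optional[Sequence[Tuple[str, str]]] = None,
    scheme: Optional[GroupScheme] = None,
) -> List[CorrelationResult]:
    """Pearson correlations between taxa-level variables.

    Available variables per taxon are the group-frequency sums of the
    scheme (default five-way functional partition, named f_<group>) plus
    any named scalars supplied in ``extras`` (e.g. node_number, E_H,
    cost, sigma_f). Taxa with missing values for a pair are dropped with
    a warning; pairs left with fewer than 3 taxa or with a constant
    variable are flagged degenerate.
    """
    scheme = scheme or default_scheme()
    if pairs is None:
        pairs = [("f_polar", "f_packing")]
    rows = {}
    for p in points:
        row = {
            f"f_{name}": float(p.f_mean[sorted(members)].sum())
            for name, members in scheme.groups.items()
        }
        if extras and p.taxon in extras:
            row.update({k: float(v) for k, v in extras[p.taxon].items()})
        rows[p.taxon] = row
    frame = pd.DataFrame(rows).T
    results = []
    for xvar, yvar in pairs:
        if xvar not in frame.columns or yvar not in frame.columns:
            warnings.warn(f"pair ({xvar}, {yvar}) dropped: variable missing for all taxa")
            continue
        sub = frame[[xvar, yvar]].dropna()
        if len(sub) < len(frame):
            warnings.warn(
                f"pair ({xvar}, {yvar}): dropped {len(frame) - len(sub)} taxa with missing values"
            )
        x, y = sub[xvar].to_numpy(float), sub[yvar].to_numpy(float)
        if len(sub) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            results.append(
                CorrelationResult(xvar, yvar, np.nan, np.nan, np.nan, len(sub), degenerate=True)
            )
            continue
        res = stats.linregress(x, y)
        results.append(
            CorrelationResult(
                xvar, yvar, float(res.rvalue), float(res.slope),
                float(res.intercept), len(sub),
            )
        )
    return results


def fits_to_frame(fits: Mapping[str, Fit]) -> pd.DataFrame:
    """Fit-parameter table: (AA, model, a, b, c, R, constrained_c)."""
    rows = []
    for aa in sorted(fits):
        fit = fits[aa]
        if isinstance(fit, LinearFit):
            rows.append((aa, "linear", fit.a, fit.b, np.nan, fit.R, False))
        else:
            rows.append((aa, "exp", fit.a, fit.b, fit.c, fit.R, fit.c_constrained))
    return pd.DataFrame(
        rows, columns=["AA", "model", "a", "b", "c", "R", "constrained_c"]
    )
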