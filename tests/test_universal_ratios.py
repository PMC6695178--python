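"""Taxa-level fits against the Phe reference and ancestral extrapolation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tmscape import (
    AMINO_ACIDS,
    CODE_ENTRY_ORDER,
    AncestralModel,
    ExpFit,
    LinearFit,
    TaxonPoint,
    extrapolate_composition,
    fit_exponential,
    fit_linear,
    frequency_table_from_f,
    rank_by_R,
    reference_scores,
    select_reference,
    taxa_correlations,
    taxon_points,
)
from tmscape.composition_stats import FrequencyTable
from tmscape.universal_ratios import (
    DegenerateReferenceError,
    FitError,
    fit_all,
    fits_to_frame,
)


def points_on(relation, f_phes, other_aa="A", fill=1.0):
    """Taxon points with f_A = relation(f_Phe) and constant everything else."""
    pts = []
    for i, x in enumerate(f_phes):
        f = pd.Series(fill, index=list(AMINO_ACIDS))
        f["F"] = x
        f[other_aa] = relation(x)
        pts.append(TaxonPoint(taxon=f"t{i}", f_mean=f))
    return pts


class TestTaxonPoints:
    def _table(self, per_bin):
        counts = pd.DataFrame(
            {aa: [v.get(aa, 0.0) for v in per_bin.values()] for aa in AMINO_ACIDS},
            index=list(per_bin),
        )
        helices = pd.Series({n: 1.0 for n in per_bin})
        return FrequencyTable(counts=counts, helices=helices)

    def test_single_bin_point_equals_bin(self):
        table = self._table({3: {"L": 4.0, "F": 1.5}})
        (pt,) = taxon_points({"tax": table}, n_range=(2, 7))
        assert pt.f_mean["L"] == 4.0 and pt.f_mean["F"] == 1.5

    def test_unweighted_mean_over_bins(self):
        table = self._table({2: {"L": 1.0}, 3: {"L": 3.0}})
        (pt,) = taxon_points({"tax": table}, n_range=(2, 7))
        assert pt.f_mean["L"] == 2.0

    def test_helix_weighted_mode(self):
        counts = pd.DataFrame(
            {aa: [1.0 if aa == "L" else 0.0, 9.0 if aa == "L" else 0.0] for aa in AMINO_ACIDS},
            index=[2, 3],
        )
        table = FrequencyTable(counts=counts, helices=pd.Series({2: 1.0, 3: 3.0}))
        (pt,) = taxon_points({"tax": table}, n_range=(2, 7), weight_by_helices=True)
        # f = 1.0 and 3.0; weights 1 and 3 -> (1*1 + 3*3)/4
        assert pt.f_mean["L"] == pytest.approx(2.5)

    def test_empty_range_names_taxon(self):
        table = self._table({9: {"L": 1.0}})
        with pytest.raises(ValueError, match="tax"):
            taxon_points({"tax": table}, n_range=(2, 7))


class TestLinearFit:
    def test_exact_collinear_points(self):
        pts = points_on(lambda x: 2 * x + 1, [0.5, 1.0, 1.5, 2.0, 2.5])
        fit = fit_linear(pts, "A")
        assert fit.a == pytest.approx(2.0)
        assert fit.b == pytest.approx(1.0)
        assert fit.R == pytest.approx(1.0)

    def test_constant_response_degenerate(self):
        pts = points_on(lambda x: 3.0, [0.5, 1.0, 1.5])
        fit = fit_linear(pts, "A")
        assert fit.a == 0.0 and fit.R == 0.0 and fit.degenerate

    def test_zero_variance_reference_raises(self):
        pts = points_on(lambda x: x, [1.0, 1.0, 1.0])
        with pytest.raises(DegenerateReferenceError):
            fit_linear(pts, "A")

    def test_noisy_points_match_normal_equations(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(0.5, 3.0, 9)
        y = -1.2 * x + 7 + rng.normal(0, 0.3, 9)
        pts = []
        for i, (xi, yi) in enumerate(zip(x, y)):
            f = pd.Series(1.0, index=list(AMINO_ACIDS))
            f["F"], f["A"] = xi, yi
            pts.append(TaxonPoint(f"t{i}", f))
        fit = fit_linear(pts, "A")
        X = np.column_stack([x, np.ones_like(x)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)  # normal-equations oracle
        assert fit.a == pytest.approx(beta[0], abs=1e-10)
        assert fit.b == pytest.approx(beta[1], abs=1e-10)
        assert fit.R == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)


class TestExponentialFit:
    def test_noiseless_recovery_with_offset(self):
        # falling response (linear slope < 0) -> c is free
        pts = points_on(lambda x: 2 * np.exp(-0.5 * x) + 1, np.linspace(0.2, 4.2, 9))
        fit = fit_exponential(pts, "A")
        assert not fit.c_constrained
        assert fit.a == pytest.approx(2.0, abs=1e-6)
        assert fit.b == pytest.approx(-0.5, abs=1e-6)
        assert fit.c == pytest.approx(1.0, abs=1e-6)
        assert fit.R == pytest.approx(1.0, abs=1e-9)

    def test_rising_response_constrains_c_to_zero(self):
        pts = points_on(lambda x: 0.3 * np.exp(0.8 * x), np.linspace(0.2, 2.6, 7))
        fit = fit_exponential(pts, "A")
        assert fit.c_constrained and fit.c == 0.0
        assert fit.a == pytest.approx(0.3, abs=1e-6)
        assert fit.b == pytest.approx(0.8, abs=1e-6)

    def test_flat_data_degenerate(self):
        pts = points_on(lambda x: 2.0, [0.5, 1.0, 1.5, 2.0])
        fit = fit_exponential(pts, "A")
        assert fit.degenerate and fit.c == pytest.approx(2.0)

    def test_small_curvature_limit_agrees_with_linear_fit(self):
        b_tiny = 1e-4
        x = np.linspace(0.5, 3.5, 9)
        pts = points_on(lambda v: 5 * np.exp(b_tiny * v), x)
        exp_fit = fit_exponential(pts, "A")
        lin_fit = fit_linear(pts, "A")
        for xi in x:
            assert exp_fit.predict(xi) == pytest.approx(lin_fit.predict(xi), abs=1e-5)

    def test_too_few_points_raises(self):
        pts = points_on(lambda x: 2 * np.exp(-0.5 * x) + 1, [0.5, 1.0, 2.0])
        with pytest.raises(FitError):
            fit_exponential(pts, "A", rising=False)


class TestRanking:
    def test_magnitude_order_keeps_sign(self):
        fits = {"A": LinearFit(1, 0, 0.9), "G": LinearFit(-1, 0, -0.95)}
        assert rank_by_R(fits) == [("G", -0.95), ("A", 0.9)]

    def test_generator_truth_ordering(self):
        rng = np.random.default_rng(21)
        x = np.linspace(0.5, 3.0, 9)
        noise = {"A": 0.01, "G": 0.2, "P": 0.9}
        pts = []
        for i, xi in enumerate(x):
            f = pd.Series(1.0, index=list(AMINO_ACIDS))
            f["F"] = xi
            for aa, s in noise.items():
                f[aa] = abs(2 * xi + 1 + rng.normal(0, s))
            pts.append(TaxonPoint(f"t{i}", f))
        fits = {aa: fit_linear(pts, aa) for aa in noise}
        order = [aa for aa, _ in rank_by_R(fits)]
        assert order == ["A", "G", "P"]  # least noise -> highest |R|

    def test_reference_selection_brute_force(self):
        """The designated hub residue wins the summed-R^2 criterion."""
        rng = np.random.default_rng(33)
        x = np.linspace(0.5, 3.0, 9)
        pts = []
        for i, xi in enumerate(x):
            f = pd.Series(index=list(AMINO_ACIDS), dtype=float)
            f["F"] = xi
            for j, aa in enumerate(aa for aa in AMINO_ACIDS if aa != "F"):
                # every residue tracks F linearly, plus independent noise
                f[aa] = abs((0.5 + 0.1 * j) * xi + 0.3 + rng.normal(0, 0.05))
            pts.append(TaxonPoint(f"t{i}", f))
        scores = reference_scores(pts)
        assert select_reference(pts) == "F"
        # brute-force re-computation of one candidate's score
        manual = sum(fit_linear(pts, aa, "G").R ** 2 for aa in AMINO_ACIDS if aa != "G")
        assert scores["G"] == pytest.approx(manual)


class TestExtrapolation:
    def _toy_fits(self):
        return {
            aa: ExpFit(a=0.5 + 0.01 * i, b=0.3, c=0.2, R=1.0)
            for i, aa in enumerate(AMINO_ACIDS)
            if aa != "F"
        }

    def test_masking_beyond_first_k(self):
        comp, _ = extrapolate_composition(
            AncestralModel(fits=self._toy_fits(), k=10, f_phe=-2.24)
        )
        assert comp["N"] == 0.0  # Asn is 11th in the entry order
        for aa in CODE_ENTRY_ORDER[10:]:
            assert comp[aa] == 0.0

    def test_reference_floored_at_zero(self):
        comp, _ = extrapolate_composition(
            AncestralModel(fits=self._toy_fits(), k=20, f_phe=-2.24)
        )
        assert comp["F"] == 0.0

    def test_toy_fits_at_zero_coordinate(self):
        fits = self._toy_fits()
        comp, total = extrapolate_composition(
            AncestralModel(fits=fits, k=20, f_phe=0.0)
        )
        for aa, fit in fits.items():
            assert comp[aa] == pytest.approx(fit.a + fit.c)  # a*exp(0)+c
        assert total == pytest.approx(comp.sum())

    def test_self_consistency_at_observed_coordinate(self):
        pts = points_on(lambda x: 2 * np.exp(-0.5 * x) + 1, np.linspace(0.2, 4.2, 9))
        fits = fit_all(pts, model="exp")
        x0 = float(pts[3].f_mean["F"])
        comp, _ = extrapolate_composition(AncestralModel(fits=fits, k=20, f_phe=x0))
        for aa in AMINO_ACIDS:
            if aa == "F":
                continue
            assert comp[aa] == pytest.approx(max(fits[aa].predict(x0), 0.0), abs=1e-9)

    def test_output_nonnegative_and_in_code_order(self):
        comp, total = extrapolate_composition(
            AncestralModel(fits=self._toy_fits(), k=16, f_phe=-5.0)
        )
        assert (comp >= 0).all()
        assert list(comp.index) == list(CODE_ENTRY_ORDER)
        assert total == pytest.approx(comp.sum())

    def test_missing_fit_for_allowed_residue(self):
        fits = self._toy_fits()
        del fits["G"]
        with pytest.raises(FitError, match="G"):
            extrapolate_composition(AncestralModel(fits=fits, k=10, f_phe=0.0))


class TestTaxaCorrelations:
    def _anti_points(self, n=6):
        pts = []
        for i in range(n):
            f = pd.Series(0.5, index=list(AMINO_ACIDS))
            polar = 1.0 + 0.4 * i
            packing = 5.0 - 0.4 * i
            for aa in "CHNQST":
                f[aa] = polar / 6
            for aa in "AGP":
                f[aa] = packing / 3
            pts.append(TaxonPoint(f"t{i}", f))
        return pts

    def test_perfect_anticorrelation(self):
        (res,) = taxa_correlations(self._anti_points(), pairs=[("f_polar", "f_packing")])
        assert res.r == pytest.approx(-1.0)

    def test_degenerate_extra_flagged(self):
        pts = self._anti_points()
        extras = {p.taxon: {"node_number": 5.0} for p in pts}
        (res,) = taxa_correlations(pts, extras, pairs=[("f_polar", "node_number")])
        assert res.degenerate

    def test_matches_brute_force_pearson(self):
        rng = np.random.default_rng(8)
        pts = self._anti_points()
        extras = {p.taxon: {"node_number": float(v)} for p, v in zip(pts, rng.uniform(1, 40, 6))}
        (res,) = taxa_correlations(pts, extras, pairs=[("f_polar", "node_number")])
        x = np.array([p.f_mean[list("CHNQST")].sum() for p in pts])
        y = np.array([extras[p.taxon]["node_number"] for p in pts])
        assert res.r == pytest.approx(np.corrcoef(x, y)[0, 1])

    def test_incomplete_taxa_dropped_with_warning(self):
        pts = self._anti_points()
        extras = {p.taxon: {"node_number": float(i)} for i, p in enumerate(pts[:-1])}
        with pytest.warns(UserWarning, match="dropped"):
            (res,) = taxa_correlations(pts, extras, pairs=[("f_polar", "node_number")])
        assert res.n_taxa == len(pts) - 1


def test_fit_table_layout():
    fits = {
        "A": LinearFit(a=1.0, b=2.0, R=0.5),
        "G": ExpFit(a=1.0, b=-0.2, c=0.1, R=0.9, c_constrained=False),
    }
    frame = fits_to_frame(fits)
    assert list(frame.columns) == ["AA", "model", "a", "b", "c", "R", "constrained_c"]
    assert set(frame["model"]) == {"linear", "exp"}
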