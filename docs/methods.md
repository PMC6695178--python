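# Methods notes

This note records the statistical model behind each stage, the
conventions the implementation fixes where several were defensible, and
what the synthetic-data tests do and do not demonstrate.

## Records and filtering

A record is one membrane protein: sequence, taxonomic lineage,
protein-existence code (1–5), a subcellular-location tag, and a sorted,
non-overlapping list of TM helix spans. Coordinates are 1-based and
inclusive on both ends, following UniProt feature-table conventions;
the conversion from Biopython's 0-based feature starts happens once, in
the flat-file parser, and nowhere else.

Default retention criteria: location tag exactly equal to
"Multi-pass membrane protein [SL-9909]" or "Single-pass membrane
protein [SL-9904]" (a substring mode exists for flat-file dialects that
omit the SL code), existence codes 1–3 (4 and 5 denote predicted and
uncertain proteins), an optional taxon that may match anywhere in the
lineage, and helical or discontinuously-helical span kinds. Taxon
filtering is by lineage match only; no cross-check cleanup of
foreign-taxon cluster representatives is attempted, so a small
percentage of out-of-group entries is retained by design. A record
failing several criteria is attributed to the first failing one
(location → existence → taxon → helix kind) in the removal tally.
Overlapping TRANSMEM spans are a validation error, not silently merged;
entries with fuzzy span coordinates ("<1", "?") are skipped and logged.

## Frequencies

f(n, X) = (count of X inside helix spans of n-helix proteins) /
(number of examined helices). It is a per-helix expectation, not a
probability: Σ_X f(n, X) is the mean examined-helix length of the bin.
Ambiguity letters (B, J, O, U, X, Z) count toward helix length but are
excluded from per-residue counts; the number skipped is carried on the
table so the residue balance can be audited. Bins with zero helices are
absent rather than zero, and downstream consumers skip them instead of
imputing. Counting is order- and batch-invariant (tables merge by
adding counts), which the tests assert.

Depth profiles use center index floor((start+end)/2), so even-length
helices sit one residue toward the N-terminus; a parity option computes
even- and odd-length helices separately for analyses sensitive to that
convention. The per-(n, m) denominator is the number of helices that
contribute a residue at that m, not the total helix count — far-
periphery bins are then not diluted by short helices and f(n, ·, m)
retains residues-per-contributing-helix semantics at every depth. A
window extension of 4 residues per side (clipped at sequence ends) is
the default way to include the lipid-headgroup region.

Running averages over n use a forward window {n, …, n+window−1}
restricted to populated bins and are reported at n; a window of two has
no center, so the placement is a convention and is fixed here once.

The literal finite-sampling uncertainty 2·√(count/4) is provided as
printed; note it is algebraically √count, a count-scale quantity that
grows with database size. A binomial alternative, √count / helices, on
the f scale, is provided alongside; the package asserts neither as the
uniquely correct reading and reports whichever is requested.

## Diversity and cost

p_X = f_X / Σf; H = −Σ p_X ln p_X in nats (zero terms contribute 0);
E_H = H / ln 20 ∈ [0, 1]. Costs are Σ f_X·ATP(X) per helix, with ATP(X)
the de-novo *E. coli* synthesis cost in high-energy phosphate bonds
(Akashi & Gojobori 2002 values, shipped as `data/aa_costs.tsv` and
user-replaceable — the table is configuration, not ground truth). Cost
is reported positive: a leading minus on a sum of non-negative terms
would make every proteome's cost negative, contradicting the quantity's
use as an expenditure.

## Border uncertainty

Monte-Carlo model: each helix border (start and end independently) is
offset by a Gaussian draw of SD 3.8 residues rounded to the nearest
integer. Draws are rejected and redrawn, per helix with a retry cap of
1000, when the helix would shrink by more than 5 residues relative to
its annotation, collapse below one residue, leave the sequence, or run
into the previously placed helix. Rejection (rather than clipping) is
used because clipping would pile probability mass on the constraint
boundary and bias lengths. The default of 100 replicates puts the
across-replicate SD well below sampling error at desk scale; averaging
replicate count tables equals averaging f because helix counts per
record are invariant under perturbation. With SD = 0 the sampler is the
identity and the replicate spread is exactly zero.

The one-sided shrink constraint makes accepted offsets asymmetric
(starts drift left, ends right, helices grow on average); the sampler
is validated against the marginal SD of the accepted-offset
distribution computed by direct summation over the integer offset grid
(`rounded_truncated_sd`), agreeing within 5% at 10⁵ draws.

Deterministic transforms shrink or extend every span symmetrically
(default 4 residues per side). Extension clips at sequence ends and at
the midpoint of the gap to a neighbouring helix so spans never merge.
Shrink-then-count residues are a subset of fixed-border residues, so
per-residue counts are monotone under both transforms — a set-theoretic
invariant the tests exercise.

The border-prediction SD estimator pools signed start and end
differences of (predicted, reference) span pairs and reports their RMS
by default (mean not removed); a centered mode (ddof = 1) exists
because the published estimate does not state whether the mean offset
was removed.

## Universal ratios and extrapolation

Taxon points are unweighted means of f(n, X) over populated bins in an
inclusive n range (default 2–7); helix-count weighting is available
behind a flag but is not the default because the source analyses do not
state a weighting. Linear fits are ordinary least squares with R the
Pearson correlation; a constant response returns slope 0 with R = 0 and
a degeneracy flag, and a zero-variance reference is an error.

Exponential fits f_X = a·exp(b·f_Phe) + c use Levenberg–Marquardt with
xtol = ftol = 1e−10 and five restarts: the first start is seeded from
the linear fit (b from the slope scaled by the response magnitude and
clamped to ±4/range, a from the mean response, c from the observed
minimum), subsequent starts perturb it multiplicatively with a fixed
internal RNG so results are reproducible. c is constrained to 0 when
f_X rises with the reference, operationalised as a non-negative linear
slope (ties count as rising). R for the nonlinear model is the Pearson
correlation between fitted and observed values, since the linear
definition does not carry over. Reference selection recomputes all
20×19 linear fits and ranks candidates by Σ R²; degenerate responses
contribute 0.

Extrapolation evaluates each residue's fit at a chosen f_Phe
coordinate, floors negative predictions at 0, assigns the reference
residue max(f_Phe, 0), and zeroes every residue beyond the first k of
the genetic-code entry order (Gly, Ala, Asp, Val, Pro, Ser, Glu, Thr,
Leu, Arg, Asn, Ile, Gln, His, Lys, Cys, Phe, Tyr, Met, Trp). The
bundled `data/primordial_composition.tsv` is a reference outcome of
this procedure at f_Phe = −2.24 (k = 10) and f_Phe = 0 (k = 16); the
acceptance checks recompute its helix length (21.1 and 21.0 residues)
and functional-group sums through `sigma_f` and `group_frequencies`.
Under the five-group scheme those sums are packing 9.2/8.4, polar
0.9/1.7 and hydrophobic 9.6/9.7 — when comparing against prose
summaries elsewhere, note that group labels on the polar/hydrophobic
pair are easily swapped, and that multi-residue sums of values printed
at 1–2 decimals carry up to ~0.1 of rounding slack.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical features the pipeline is
sensitive to: an exact protein count per n; helix lengths drawn from a
distribution centered on 21–26 residues (the default mean is 23.5);
helix residues i.i.d. from a taxon composition, optionally modulated by
per-residue depth weights (a multiplier applied at |m| ≥ cutoff, e.g.
Trp enriched at the periphery); flanks and linkers from a distinct
charged/aromatic-enriched composition, which is what makes Monte-Carlo
vs fixed-border contrasts visible; linkers at least twice the flank
length so border transforms never merge helices. The default TM
composition is a Leu-dominated, sparsely charged vector summing to
~21.3 residues per helix — values a membrane proteomicist would accept
as typical — and all defaults are fixed once, not tuned per test.

Taxon panels place target compositions exactly on configured
f_X–f_Phe relations; the exact placement is exposed as `exact_points`
(used for the R = ±1 and parameter-recovery checks) while the sampled
proteomes realise those targets with multinomial noise, with helix
lengths drawn to match each taxon's target Σf in expectation.

Passing tests on this generator demonstrate correctness of counting,
normalisation, perturbation and fitting — not biological realism: real
TM sequences have positional autocorrelation (motifs such as GxxxG),
composition–length coupling, annotation errors, and n misclassification,
none of which are modelled. Quantities that depend only on counting
identities (conservation, partition sums, monotonicity under border
transforms) transfer to real data unconditionally; quantities that
depend on distributional assumptions (uncertainty magnitudes, fit R
values) do not.

## Problem sizes

The bundled test and acceptance runs use proteomes of 10²–10³ proteins
with n ≤ 9, 10⁵ draws for the sampler calibration, and 9-taxon panels —
sizes at which every check completes in seconds while keeping ≥100
helices in the bins that assert parameter recovery (3× binomial SE).
The same code paths scale to database-sized inputs; only the statistics
in this repository are computed at these sizes.

## Known limitations

* The flat-file parser targets the modern (2019+) FT coordinate syntax
  via Biopython; legacy three-column FT lines are not supported.
* Monte-Carlo perturbation treats helices independently except for the
  no-overlap constraint against the previously placed helix; a joint
  model of correlated border errors is out of scope.
* The exponential fit can be ill-conditioned when the response is
  nearly linear over the observed range (a and c trade off against b);
  the multi-start procedure returns the best converged optimum and the
  degeneracy flag marks flat responses, but parameter values (as
  opposed to predictions) should not be over-interpreted in that
  regime.
* Node numbers and any other external covariates are consumed as
  given; the package never derives them.
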