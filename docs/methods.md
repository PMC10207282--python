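# Methods

## Model and conventions

All schemes reduce to one relation: for the dissociation
HA → A⁻ + H⁺ (or HA⁺ → A + H⁺; charge bookkeeping is uniform, no
special-casing of cationic acids),

    pKa = ΔG_aq / (ln(10)·R·T),

with ΔG_aq the solution-phase deprotonation free energy, products minus
reactants. Internal units are kcal/mol throughout, with
R = 1.98720425×10⁻³ kcal·mol⁻¹·K⁻¹ and T = 298.15 K by default
(ln(10)·R·T ≈ 1.3642 kcal/mol per pKa unit). Temperature is a
`ThermoContext` parameter; nothing else in the package is
temperature-aware (no pKa extrapolation, no activity or ionic-strength
corrections — out of scope by design).

Free energies enter as two numbers per species: the gas-phase standard
free energy `g_gas` and the gas→solution transfer free energy
`dg_solv`. Both are treated as opaque outputs of an electronic-structure
workflow; whether `g_gas` carries scaled thermal/entropic terms is the
producer's concern. Species carry `method_tag`/`solvent_tag` labels and
every cycle operation enforces strict tag equality, because the level of
theory is the central experimental variable in this kind of study and
silently mixing levels is the classic failure mode.

## The four schemes

* **direct**: ΔG_soln = G_soln(A) + G_soln(H⁺) − G_soln(HA) with
  G_soln = g_gas + dg_solv and the proton's solution free energy as a
  single user-supplied number. Provided mainly as a baseline; its
  accuracy is bounded by that one number.
* **TC1**: ΔG_aq = ΔG_gas + ΔΔG_solv with a bare proton.
  ΔG_solv(H⁺) is an empirical convention; the presets −265.9 and
  −270.3 kcal/mol are exposed, and the analytic consequence of
  switching them — every pKa moves by −4.4/(ln(10)RT) ≈ −3.225 units —
  is a tested invariant. G_gas(H⁺) defaults to −6.287 kcal/mol
  (Sackur–Tetrode at 298.15 K, 1 atm); TC1 cannot be evaluated without
  some convention, and this is the standard one.
* **TC2**: the H₂O/H₃O⁺ pair replaces the bare proton. When the pair's
  free-energy differences equal the TC1 proton parameters, TC2 reduces
  to TC1 exactly; this algebraic identity is verified on randomized
  inputs rather than assumed. An optional −log₁₀(55.34) correction
  moves water from its pure-liquid to a 1 M standard state. It defaults
  to off, and is never applied in non-aqueous solvents, where the pair
  is treated as ordinary solutes.
* **isodesmic**: pKa(HA) = pKa(HB) + ΔG_soln/(ln(10)RT) for the
  exchange HA + B → A + HB. Only solution free energies enter, so any
  error term shared between query and reference — gas-phase systematics,
  charged-species solvation offsets — cancels in the difference. Two
  quantified forms of this cancellation are tested: a constant added to
  every charged species' dg_solv shifts TC1 by c/(ln(10)RT) but leaves
  the isodesmic result between two cationic-acid pairs unchanged; and a
  synthetic per-method bias propagates 1:1 into TC1 estimates while the
  isodesmic route recovers true values exactly at zero noise.

Standard-state handling: a 1 atm → 1 M correction of 1.894 kcal/mol per
net mole of gas-phase species created is available on `ThermoContext`
but off by default (TC1 creates one mole, TC2 and the isodesmic exchange
none). The published protocol this package follows never states such a
correction, so the default reproduces its arithmetic while the toggle
lets users study the effect.

Conformers: a `ConformerSet` is reduced either by keeping the lowest
total free energy member (default, matching the usual
most-stable-conformer practice) or by the ensemble effective free energy
−RT·ln Σ exp(−Gᵢ/RT), computed with a shifted log-sum-exp. The
effective energy always lies in [G_min − RT·ln n, G_min], a tested
bound.

## Protonation-site rule

The dominant protonation site is the nitrogen with the most negative
partial charge. NPA is the primary analysis; CM5 and Hirshfeld act as a
consensus check, and on disagreement the NPA pick wins with
`consensus=False` recorded. Exact ties break to the lowest atom index —
an arbitrary but deterministic rule; selection is invariant to record
order and to uniform charge shifts. The element filter defaults to
nitrogen because the target chemistry (amidine-conjugated heterocycles)
only ever protonates N. Charges are consumed as data; computing them is
out of scope. The qualitative relation "more negative q_N ⇒ higher
pKa" holds in the fixtures but no quantitative charge→pKa model is
implemented, since none is defined.

## Benchmark statistics

Δ = calculated − experimental, a fixed documented convention (report
JSON also carries −MD for readers using the opposite sign). RMSE, MAD,
MD and max |Δ| are computed from raw deltas; the regression is OLS of
calculated on experimental with R² the squared Pearson correlation
(scipy's linregress). Rows lacking experimental values are retained in
output but excluded from every statistic. Degenerate inputs: all-missing
experimental → error; zero experimental variance → regression reported
as missing. Presentation rounds to two decimals; all internal math is
full precision.

`flag_inconsistent_deltas` recomputes Δ from the primary columns and
flags rows where an externally supplied deviation differs by more than
0.01 — needed because the transcribed benchmark tables contain summary
and deviation cells that contradict their own columns (e.g. the
acetonitrile test set's printed RMSE of 0.39 vs the column-derived 0.40,
its water MAD 0.21 vs ≈0.35, and per-row delta cells for molecules 9,
11 and 16; likewise the TC1 scan's stated worst deviation 10.43 vs the
column-derived 9.57). The package always recomputes from primary
columns; the contradictory cells are flagged, never reproduced.

## Synthetic data generator

`synthetic_qm.generate` emulates the statistical structure of a QM
backend, not its physics. Per molecule i: a true pKa tᵢ drawn uniformly
from `true_pka_range` (default (10, 25), the span of the acetonitrile
test compounds) and noise εᵢ ~ N(0, `noise_sd`). The acid is pinned at
zero energy and the base receives the total ΔG that makes TC1 return
tᵢ + bias + εᵢ identically, split 50/50 between g_gas and dg_solv — an
arbitrary split the schemes are provably invariant to (tested at splits
0, 0.3, 1). A single reference pair shares the bias with its own noise
draw, and the generated H₂O/H₃O⁺ species satisfy the TC2-reduction
condition. Noise is injected on the pKa scale rather than per energy
term so `noise_sd` has direct meaning in the units all errors are
discussed in. Generation is bit-reproducible under a fixed seed.

What the generator does *not* emulate: correlated errors across related
molecules, conformational ensembles, solvent-dependent error structure,
or charge tables. Passing recovery tests therefore demonstrates the
correctness of the cycle algebra and the bias-cancellation mechanism,
not the accuracy of any quantum-chemical method on real molecules.

One statistical consequence of the single-reference design is worth
stating: the isodesmic error of molecule i is εᵢ − ε_ref, so errors
share the reference draw and the *mean* recovery error over n molecules
has standard deviation sd·√(1/n + 1) ≈ sd — it does not shrink with n.
Tests of mean recovery use this correct bound. In practice this mirrors
the real protocol, where one reference molecule's error enters every
prediction made from it.

## Problem sizes and numerics

The packaged fixtures are small (36-row level scans, 17-molecule test
set, 8×2×3 charge table) and all fixture-derived statistics are exact
recomputations. Property suites use 100–1000 randomized pairs and
synthetic datasets of 100–200 molecules — sizes at which the sampling
assertions have comfortable margins and the whole suite runs in
seconds. Algebraic identities (TC2→TC1 reduction, self-exchange,
antisymmetry round trips) are asserted to 1e−9 absolute in pKa units;
pure conversions to 1e−12. The Boltzmann reduction uses log-sum-exp
shifting; no other numerical care is needed, as every computation is a
short linear combination of kcal/mol-scale numbers.

## Known limitations

Single-site, single-macrostate pKa only: no microstate averaging over
multiple protonation sites, no proton-affinity ladders, no
explicit-solvent clusters beyond the single H₂O/H₃O⁺ pair. No chemistry
structure formats (SMILES/SDF) are consumed and no QM program output is
parsed — the documented CSVs are the ingestion contract, with
`read_energies` as the extension point for future format readers.
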