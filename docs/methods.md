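# Methods

## The model

A bivalent adaptor `G` carries two peptide-binding domains (N and C); a
scaffold `S` carries `m` short binding motifs on an intrinsically
disordered region. Single-site binding is characterised by
dissociation constants `Kd_N(i)` and `Kd_C(j)` per motif and domain.
When one domain is bound to motif `i`, the free domain experiences
motif `j` at an effective local concentration `C_eff(i,j)`, and the
doubly bound state has

    Kd_eff(i,j) = Kd_N(i) · Kd_C(j) / C_eff(i,j).

This relation is symmetric in binding order (detailed balance): it is a
single product, so which domain binds first cannot matter.

All associations are handled internally in µM⁻¹; `C_eff` enters in mM
and is converted on use. ΔG ↔ Kd conversion uses `Kd = exp(ΔG/RT)`
with `R = 1.987×10⁻³ kcal/(mol·K)` and `T = 298 K` by default — these
reproduce the packaged tables' paired free-energy/Kd columns to their
printed two significant figures.

### Effective concentration

`C_eff` is the overlap integral of two spatial probability densities,

    C_eff(i,j) = ∫ p(r) q(r) d³r,

where `p` is the density of the linker end-to-end vector and `q` the
density of the vector between the two binding sites of the bound
adaptor. The linker (the `n` residues strictly between the two motif
spans; a flag includes the motif residues) is a worm-like chain in the
long-chain limit:

    p(r) = (3 / 4π l_p L_c)^{3/2} · exp(−3r² / 4 l_p L_c),
    L_c = n·b,   ⟨r²⟩ = 2 l_p L_c.

Defaults: `l_p = 3.0 Å` (typical for unfolded polypeptides; note the
persistence length of natively disordered proteins rises weakly with
length, so it is a per-call parameter, not a constant) and
`b = 3.8 Å`/residue (the Cα–Cα virtual bond). The Gaussian form is only
valid for `L_c ≫ l_p` and separations well below `L_c`; near full
extension it underestimates nothing useful and the model should not be
trusted there.

Two density conventions matter and are named explicitly throughout:
the *vector* (per-Å³) density above enters the overlap directly; the
*radial* (per-Å) density is `4πr²` times it and is what a histogram of
scalar distances estimates. Conflating them is the classic error in
effective-concentration calculations.

`q` is treated as isotropic because only scalar inter-site distances
are available (frame-by-frame Cα–Cα separations); the overlap then
reduces to averaging the vector density over sampled radii,
`C_eff = ⟨p(r_k)⟩`. Back-ends: **hybrid** (raw samples), **histogram**
(bin-midpoint quadrature of a normalised radial histogram, 100 bins by
default), **delta** (a single separation, `C_eff = p(d0)`). A
degenerate (constant) trace is evaluated once so hybrid and delta are
bit-identical. Unit conversion: `1 Å⁻³ = 10²⁷/N_A mol/L` (one molecule
per µm³ ≈ 1.66 nM). Which motif termini anchor the measured distance
depends on the motif classes and their sequence order; the caller
selects the appropriate trace — this is data, not module logic.

### Mode enumeration and effective constants

For motifs `M`, the 1:1 modes are `2m` singly bound (either domain on
any motif) plus `m(m−1)` doubly bound (ordered pairs of distinct
motifs); `m = 5` gives 30. The overall 1:1 association constant is the
sum of mode associations,

    K_GS = Σ_i (1/Kd_N(i) + 1/Kd_C(i)) + Σ_{i≠j} 1/Kd_eff(i,j),

and the singly bound fraction of the 1:1 complex is the first sum's
share.

For the 2:1 complex, all unordered pairs of modes with disjoint motif
sets are enumerated. Two weighting conventions are implemented because
they disagree measurably and the choice is genuinely ambiguous:

* **strict** — every unordered pair of distinct modes carries
  `K₁·K₂` (the global ½ for indistinguishable adaptors exactly cancels
  the ordered double count). This is the physically standard counting.
* **paper** (default) — mixed doubly–singly pairs additionally carry a
  factor ½, as if the doubly–singly cross terms entered the double sum
  once before the global ½. On the packaged inputs this yields the 2:1
  composition 67/28/5 (both-doubly/mixed/both-singly), the published
  split; strict yields ≈52/44/4.

The discrepancy is documented rather than silently resolved; all
downstream defaults use `paper`. `K_GSG = (total pair weight)/K_GS` is
the conditional association constant for a second adaptor binding an
existing 1:1 complex.

The packaged model substitutes the unmeasured RP motif's single-site
affinities with P3's (the weakest measured binder); substitutions are
logged and configurable. Flanking-sequence effects on single-site
affinity and allosteric coupling between the two domains are neglected.

Two routes to `Kd_eff` are packaged: from the tabulated `C_eff`
(`use_measured_kd_eff=False`) or back-computed from the tabulated
effective Kds (`use_measured_kd_eff=True`, the default for composition
results, since the printed `C_eff` are rounded to one decimal in mM and
that rounding propagates up to ~8% into derived Kds). Two cells of the
reference table (the P4/RP cross pairs) are internally inconsistent
beyond printing precision — no `C_eff` within the printed value's
rounding interval reproduces the printed effective Kd; the acceptance
test records the ~6–9% deviation explicitly.

### Speciation

With only 1:1 and 2:1 complexes ([GS] = K_GS[G][S],
[GSG] = K_GSG[G][GS]; scaffold cross-linking by one adaptor neglected,
valid at low scaffold concentration), scaffold conservation is solved
exactly for trial free [G], leaving one monotone scalar equation for
adaptor conservation. It is solved by bracketed Brent root-finding on
[0, G_tot] at machine-precision tolerance plus one analytic Newton
polish; conservation holds to better than 1e-9 relative on random
instances spanning nM–100 µM totals and 10³–10⁹ M⁻¹ constants.
Reported derived measures: `f_GSG = [GSG]/([GS]+[GSG])`, effective
stoichiometry (bound G per bound S, in (0, 2]), bound fractions.
Absolute cellular concentrations are user input; the 10:1
adaptor:scaffold scenario is a documented example, not a fixed
constant.

## Synthetic data

The generators define the test conditions; they are not tuning knobs.

* **Separation traces** — frame `k` carries `|µ + ε_k|` with isotropic
  Gaussian `ε`; the scalar distances follow a scaled non-central chi
  distribution (3 dof) with closed-form moments, and the
  hybrid-overlap result has a closed Gaussian–Gaussian convolution
  form, so parameter recovery is testable to Monte-Carlo error. What
  this does *not* emulate: autocorrelated frames, anisotropic or
  multimodal separation densities, and finite-sampling drift of a real
  trajectory — agreement here shows the estimator is correct, not that
  a given trajectory is converged.
* **Sequences** — motif templates (minimal class I/II consensus
  windows) placed at requested linker spacings over a background
  alphabet that excludes P/R/K (and C), making accidental motif
  creation impossible and round-trip recovery exact. Real disordered
  sequence has proline-rich background; scanning specificity on such
  background is exercised by the reference peptides, not the
  generator.
* **Alignments** — per column, a consensus residue with probability
  `p`, else a uniform other residue; recovered majority-identity
  conservation equals `p` up to binomial error for `p` above chance.

All generators are deterministic under a fixed seed.

## Numerical choices

* Motif scanning reports the minimal consensus window; overlapping
  same-class candidates are merged leftmost-maximal (greedy, order-
  independent). Coordinates are 1-based inclusive.
* Conservation: majority identity over non-gap rows only; all-gap
  columns score 0; ties break deterministically (fraction unaffected).
* WLC quadrature oracles use adaptive quadrature to 1e-6 relative;
  histogram densities normalise by construction and are validated to
  1e-9.
* Monte-Carlo problem sizes: 10⁶ frames for overlap-vs-closed-form
  checks (≲1% relative error), 10⁵ for distribution-recovery checks —
  chosen so sampling error sits an order of magnitude below the
  asserted tolerances.
* The speciation solver's bracket is guaranteed: the residual is
  −G_tot at 0 and non-negative at G_tot.

## Limitations

* The Gaussian WLC ignores excluded volume, linker–domain
  interactions, and finite-stiffness corrections; composite rod+chain
  models are out of scope.
* `C_eff` accuracy is bounded by the supplied separation distribution;
  the packaged tabulated values derive from long explicit-solvent
  simulations and are consumed as data, not recomputed.
* The speciation model stops at 2:1 complexes: no scaffold
  cross-linking, no membrane/scaffold-aggregation effects, no higher
  stoichiometries.
* Motif consensus patterns use pure wildcards at the x positions;
  hydrophobic-restricted variants would prune matches on other
  proteomes but are indistinguishable on the packaged reference
  peptides.
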