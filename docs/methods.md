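# Methods

## NQR parameter algebra

A spin-1 nucleus (here ¹⁴N) in zero field has three quadrupole transition
frequencies fixed by two EFG parameters: ν± = (e²qQ/4h)(3 ± η) and
ν₀ = ν₊ − ν₋ = (e²qQ/2h)η. The toolkit treats ν₊ and ν₋ as primary and ν₀
as a consistency check: a measured triplet is accepted when
|ν₀ − (ν₊ − ν₋)| falls within a tolerance, default 0.01 MHz (the order of
experimental resolution implied by three-decimal frequency tables),
configurable everywhere it is used. Valid spin-1 triplets necessarily obey
ν₊ ≤ 2ν₋; the conversion raises a validation error otherwise, since η
would exceed 1.

Coupling constants are stored and reported as magnitudes |e²qQ/h|, as
experiments determine. Where a signed value exists — the EFG reduction —
the signed q_zz and signed coupling constant are retained in the
operation's metadata.

**EFG reduction.** Principal values are ordered by magnitude
|q_xx| ≤ |q_yy| ≤ |q_zz| (the ordering that guarantees η ∈ [0, 1]), and
η = |q_xx − q_yy|/|q_zz|. The coupling constant is
e²qQ/h = K·Q[barn]·|q_zz|[a.u.] with K = e·(1 a.u. of EFG)·(1 barn)/h ≈
234.96 MHz derived at import time from CODATA constants (scipy.constants).
The ¹⁴N quadrupole moment defaults to 2.044 fm². Degenerate tensors
(q_zz = 0) are rejected: η is undefined there.

**Spectral grouping.** A spectrum of 3n lines is partitioned into n
triplets by exhaustive search with early pruning; every candidate triplet
must pass the ν₀ consistency check and yield η ∈ [0, 1]. Partitions are
ranked by total consistency residual. For spectra with spurious peaks
(molecular motions produce supplementary lines), a leftover mode instead
searches for the largest families of disjoint consistent triplets and
reports unabsorbed lines. Exhaustive partition counts grow as
(3n−1)!!·…, which is trivial for the 12–18-line spectra the method
targets (15 400 partitions at n = 4).

**Site assignment.** Experimental and calculated parameter sets are matched
by evaluating all n! bijections, comparing the 3n regenerated frequencies
by Pearson correlation; this follows the practice of correlating
frequencies, not parameters, when validating assignments against
DFT-computed spectra. fit_sd is the root mean square residual about the
identity line (not about a fitted slope), in MHz. Ties break on smaller
fit_sd, then lexicographic order — deterministic. Exhaustive evaluation is
exact; n ≤ 8 keeps it instantaneous, and larger panels are outside the
method's intended use.

## Quadrupolar indices

Δs = |e²qQ/h|_solid − |e²qQ/h|_single, δs = η_solid − η_single, and
analogously Δc/δc (complex vs single molecule) and ΔCS/δCS (complex vs
solid). All are computed from magnitudes. When all three contexts share a
single-molecule reference, ΔCS = Δc − Δs holds identically and is exposed
as a tabulation invariant. Missing contexts yield absent (NaN) fields,
never zeros — a zero index is a meaningful "no change". Site matching
across contexts is by exact label; comparing chemically different sites
(e.g. a ring nitrogen against its ribose-substituted counterpart) requires
an explicit join and is never silent.

## Structure-binding strength indices

All seven indices share the form (term_ref − term_lig)/(1 − s). The
binding-affinity term comes from a separate affinity estimate, not from
the decomposition total, and the schema keeps all terms distinct. At
s = 1 the index diverges; the toolkit returns a signed infinity carrying
the numerator's sign (+inf for the reference against itself) — an explicit
sentinel, not a large float. Classification splits on the sign of SBAI,
with an exact zero classified strongly binding under a boundary warning.
Values are rounded to one decimal only at report time.

## Similarity kernels

The fingerprint kernel uses hashed path fingerprints (RDKit), 2048 bits,
paths up to 7 bonds — classical defaults, configurable. Published
similarity tables rarely state their fingerprint scheme, so specific
literature Tanimoto values are treated as inputs, not as numbers this
kernel must reproduce. The atom-pair kernel uses descriptors
(element, heavy-neighbor count, aromatic flag) at graph topological
distance ≥ 1, compared as multisets (Σ min / Σ max). Both kernels define
self-similarity of an empty set as 1.

The MCS kernel finds the **connected** maximal common edge subgraph, atoms
matched on element + aromatic flag, bonds on order. Connectedness is
chosen because the disconnected variant inflates similarity on
multi-fragment matches. Similarity is m/(e_a + e_b − m) over edge counts.
The search is an exact branch-and-bound over growing node mappings
(each added pair must contribute at least one matched edge; tried pairs
are forbidden in sibling subtrees so no mapping is revisited); on
ribavirin-scale ligands (≈20 heavy atoms) it completes in milliseconds.
A wall-clock timeout (default 10 s) switches to a seeded multi-start
greedy search whose result is a lower bound and is flagged approximate.
RDKit's own MCS search is not used because its atom comparators cannot
express the element + aromaticity matching rule; it would, e.g., match an
aromatic carbon to an aliphatic one across a single bond. Hydrogens are
implicit in all three kernels.

## Contact-surface statistics

Surface fractions from a contact matrix: S_X = C_XX + ½ Σ_{Y≠X} C_XY,
renormalized to 100. The random-mixing model is R_XX = s_x²·100,
R_XY = 2 s_x s_y·100, which sums to 100 exactly; enrichment is
E_XY = C_XY/R_XY. Pairs with R_XY < 0.5 % are flagged sparse — the ratio
is numerically unstable on small surfaces — and excluded from summary
distances. Percentage tables are accepted when they close to 100 within
1.5 % absolute (published tables round each entry to 0.05–0.1).

Contribution-vector distances zero-fill channels absent from one vector
and use n = size of the channel union: RMSD = √(Σ(a_i − b_i)²/n),
ED = RMSD·√n. A channel naming an element absent from the molecule is a
genuine zero, so zero-filling is the physically correct convention; the
bundled nitrogen-surface reference table carries explicit zeros for such
channels so that n = 5 for every comparison.

## Binding-mode and B-factor comparison

Binding modes are compared over the union of residue identifiers with
zero fill ("all bindings included"): a residue contacted by only one
ligand contributes its full energy. RMSD_BM divides by the union size;
Manhattan and Euclidean distances are the plain norms, and
Manhattan ≥ Euclidean holds for every input — any reported pair violating
it cannot come from a single difference vector.

B-factors are z-scored per structure with the **population** standard
deviation (the choice is documented because either convention appears in
practice; at typical chain lengths the difference is < 1 %). ΔB′ pairs
residues by identical identifiers by default — appropriate for
near-identical chains — with an explicit alignment override, and is
summarized by windowed mean absolute deviation. PDB extraction takes the
Cα B-factor per residue, falling back to the atom mean, skipping
heteroatoms and waters.

## Synthetic spectrum generator

The fixture generator emulates a multi-site ¹⁴N spectrum: n_sites
(e²qQ/h, η) pairs drawn uniformly from configurable ranges, expanded to
triplets, independent Gaussian noise per line, uniform spurious lines
appended, deterministic shuffle under a seed. Defaults (4 sites,
e²qQ/h ∈ [2.4, 4.6] MHz, η ∈ [0.1, 0.75]) bracket the values observed for
azole-type nitrogens at room temperature, so a default spectrum resembles
the 12-line experimental case. It emulates line positions only — no
intensities, linewidths, or temperature dependence — so passing recovery
tests demonstrate the combinatorial assignment logic, not robustness to
lineshape effects in real spectra.

## Numerical and testing choices

- Frequency/parameter round-trips are exact to 1e−9 relative; tests assert
  at that tolerance.
- Printed reference values are asserted to half a unit in their last
  printed decimal.
- The one published index block whose sign convention is internally
  inconsistent (the favipiravir solid-vs-complex rows, which list
  solid − complex with the polymorph columns interchanged) is checked
  through the corresponding negate-and-swap identity; the defining
  convention (complex − solid) is never altered.
- Two published nitrogen-surface RMSD entries omit a zero-filled channel
  from their sum; the toolkit keeps the symmetric zero-fill convention and
  its tests freeze the recomputed values for those rows.
- Problem sizes in tests (≤5 sites for exhaustive assignment checks,
  ≤8-edge graphs for brute-force MCS cross-checks, 100-seed recovery
  batches) were chosen to keep exhaustive oracles exact and the suite
  fast.

## Known limitations

- The exact MCES search is exponential in the worst case; highly symmetric
  graphs beyond ~40 heavy atoms may hit the timeout and return flagged
  lower bounds.
- Spectral grouping assumes every true triplet is complete; a spectrum
  with a missing line can only be handled in leftover mode.
- The toolkit consumes EFG tensors, docking decompositions, contact
  percentage tables, and B-factors as data; it performs no electronic-
  structure computation, docking, Hirshfeld-surface generation, or MD.
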