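# Methods

`circuitchain` models a folded linear chain — a protein, a genomic DNA
segment, or any system that maps onto a chain of sorted objects — by the
arrangement of its intrachain contacts rather than by coordinates.  This
note records the model, the conventions the implementation had to fix where
the theory leaves freedom, and the checks behind each component.

## The chain model

A chain is an ordered sequence of *events*:

* **Hard contacts** (h-contacts) glue two chain sites together through a
  bond; breaking the bond is the only way to remove one.  Each name occurs
  exactly twice in the string.
* **Soft contacts** (s-contacts) encode entanglement: two chain loops hooked
  through each other.  A soft contact carries a chirality (`+`/`-`, by the
  right-hand rule along the chain orientation) and a parity (`even`/`odd`,
  the direction in which the loops hook).  Chirality and parity are
  orientation-independent, so they survive reading the chain from the other
  end.
* **Threads** (`_{+A}`) record a chain segment passing through contact A's
  loop with a signed direction.  A thread is "half a contact": it is how
  slip-knots arise and the only way a soft contact can disappear.
* **Concerted groups** `(A B …)` are sites of different contacts merged at
  one chain location.  The written order inside and around a group is
  meaningful, and merged contacts are never written in a cross arrangement;
  the parser enforces this (`ConcertedOrderError`).

The ASCII dialect marks soft attributes as `^{+e}`, `^{-o}` … on the first
occurrence only; a contact is soft if and only if it carries such an
attribute somewhere.  Whitespace-separated and compact (`AABB`,
`NtABDBADCt`) spellings parse identically.  Site indices are 1-based and
count contact sites only, so a chain of n contacts has sites 1..2n and a
2n×2n connectivity matrix S with S_kl = 1 iff k and l belong to one
contact.  The matrix is lossy for soft attributes, threads, and groups; a
JSON sidecar keeps them.

Threads that sit outside every contact span are accepted (they are real at
chain ends, where a dangling segment can lock a structure) and logged as a
warning elsewhere, since the notation prefers threads written inside the
contact they interact with.

## Pairwise relations

Restricting the site order to two contacts leaves `aabb` (series),
`abba` (parallel; the ordered query distinguishes P from P⁻¹), or `abab`
(cross).  Threads are invisible to this classification.  Contacts sharing a
merged location are classified from the residual site order and reported as
CS or CP; cross never occurs there by construction.  Classification is
exactly invariant under chain reversal — reversal maps `abba` to `abba` —
so no P↔P⁻¹ swap occurs; the stronger statement is property-tested.

Enumeration of all n-contact strings generates perfect matchings of 2n
ordered sites with letters canonicalized by first occurrence, giving
(2n−1)!! = (2n)!/(n!2ⁿ) distinct strings (3 for n = 2, 15 for n = 3, 105
for n = 4).

**Reversal classes (a documented discrepancy).**  Grouping the 15
three-contact strings by reversal-plus-renaming equivalence yields **11**
classes, not the tabulated 12.  Three symmetric pairs are well known
(AABCBC/ABABCC, AABCCB/ABBACC, ABACCB/ABBCAC) but there is a fourth:
reverse(ABCACB) = BCACBA, which canonicalizes to ABCBAC.  Both members
appear as separate rows with identical size [100] in the usual table, i.e.
one configuration is double-counted there.  `reduce_by_reversal` implements
the mathematically correct grouping; the test suite carries one
deliberately failing check against the tabulated 12 so the discrepancy
stays visible, and an independent brute-force orbit count (all six letter
bijections, both orientations) confirms 11.

## Circuits, size, metric, roughness

A **circuit** is a contiguous span of the site sequence that is
self-contained: every contact with a site inside has both sites inside,
every thread inside targets a contact inside, and no thread outside targets
a contact inside.  The last clause is a deliberate choice — a loop threaded
from outside is not a separable blob — and makes circuit spans unique per
contact set.  Spans range over individual site positions, so a circuit may
begin or end inside a concerted group: that is what the worked protein
example requires (below).  The **order** of a circuit is its number of
contact pairs; the **size vector** x counts circuits per order and is
displayed highest order first (AABB → [12]).  For any valid chain the whole
string is a circuit, so the leading digit is 1.  Adding threads can only
remove circuits, never change the total order (property-tested).

The metric is d(X,Y) = √(Σₖ k²(xₖ−yₖ)²), weighting higher-order circuits
by their order; roughness is r(X) = d(X,0).  The radical is part of the
definition (d between [600] and [400] is 3·(6−4) = 6), but the tabulated
worked numbers (8 for AABB, 34 for AABBCC, 122 for the protein example) are
the under-radical values, so both `distance`/`roughness` and their
`squared_*` variants are exposed and the printed numerals are matched by
the squared forms.  API note: plain Python lists passed to the metric are
read in display order; `SizeVector` objects carry the internal ascending
order.  Metric axioms including the triangle inequality (Cauchy–Schwarz on
aₖ = k(xₖ−yₖ)) are property-tested on 10⁴ random triples, and the closed
forms for homogeneous chains — all-cross r = n, all-parallel
r² = n(n+1)(2n+1)/6, all-series r² = n(n+1)(n³+4n²+6n+4)/30 — are verified
against direct circuit enumeration for n = 1..8.

**The [122] row (a documented discrepancy).**  No three-contact string has
size [122].  An order-2 circuit of a 3-contact chain occupies one of the
windows 1–4, 2–5, 3–6; two closed windows force partners at their overlap,
which forces AABBCC — whose size is [123].  The string ABBCCA, tabulated as
[122] with squared roughness 29, actually has circuits BB, CC, BBCC and the
whole string: size [112], squared roughness 17.  The arithmetic 29 = 9+16+4
is correct *for* a hypothetical [122], so the size→roughness map is fine;
the attribution to ABBCCA is not.  The implementation reports 17, and one
deliberately failing acceptance check records the tabulated association.

Realizability of arbitrary size vectors (e.g. rejecting [120]) is out of
scope; the metric accepts any nonnegative vector.

**Worked protein example.**  The YibK methyltransferase string
`(AB) C (BDE) (EF) (FDG) S^{+e} (HI) (IGA) H S C` (nine hard contacts, many
concerted, plus one `+e` soft contact — the trefoil entanglement the
protein is known for) has circuits EE, FF, II (order 1), EEFF (order 2),
DEEFFD (order 3) and the whole string: size [1000000113], squared roughness
122.  Note EE, FF, EEFF and DEEFFD all cut through concerted groups, which
is why circuit spans must be allowed to split groups.

## Knot matrices and Alexander polynomials

Soft contacts close into mathematical knots when the chain ends are joined:
even types give the trefoil, odd types the figure-eight.  Hard contacts are
invisible to knot theory and threads are removable by Reidemeister moves,
so `knots` rejects both (`soft_restriction` drops hard contacts first).

Each contact type carries an explicit closed diagram: a cyclic sequence of
over/under passages through 4 crossings, traversed from the closure arc
(arc 1).  Arcs begin and end under crossings; the knot matrix has one row
per crossing with −1 on the ending arc, t on the beginning arc and 1−t on
the over arc for right-handed crossings (t/−1 swapped for left-handed).
Deleting any row and column and taking a fraction-free determinant gives
Δ(t), defined up to ±tᵏ; `LaurentPolynomial` normalizes (lowest exponent 0,
positive constant term) so equality is canonical.

The concrete codes were fixed by exhaustive search over the 4-crossing
closed Gauss codes satisfying, simultaneously: Gauss's evenness condition
and the Rosenstiehl interlacement criterion (planar realizability), three
nonzero entries {−1, t, 1−t} in every matrix row, agreement of all 16
minors, and the correct Δ — t²−t+1 with knot determinant |Δ(−1)| = 3 for
the even contact, t²−3t+1 with determinant 5 for the odd one.  The even
diagram (`O1 O2 U3 U1 O4 O3 U2 U4`) is all right-handed for `+e` and its
full flip (all left-handed) for `-e`.  The odd contact uses the standard
alternating figure-eight code (`O1 U2 O3 U4 O2 U1 O4 U3`) with two
right- and two left-handed crossings: an all-same-handed 4-crossing diagram
has writhe ±4 and cannot be the figure-eight (its diagrams have writhe 0),
so a description of the odd contacts as uniformly handed cannot hold in the
crossing-sign sense; the printed polynomials are the pinned ground truth.
`-o` is the full flip of `+o`.

**Series/parallel.**  Joining contacts that are not in cross creates no new
crossing: the closed diagram is a connected sum, built by walking the chain
and emitting each contact's traversal halves at its two sites.  Δ of the
joined 8×8 matrix equals the product of the contact polynomials; this
multiplicativity is tested against the full matrix construction for every
type assignment in both arrangements, so `combine_series_parallel` simply
multiplies.

**Cross.**  Two contacts in cross cannot be closed without one extra
crossing — crossing 9, where the closure arc crosses a strand once — giving
a 9×9 matrix whose polynomial is *not* the product.  Which strand is
crossed, and the over/under and handedness of crossing 9, are not fully
determined by the flat figures, so they were fixed by the same exhaustive
search, with two additional physical requirements: the polynomial must be a
genuine knot polynomial (palindromic, |Δ(1)| = 1), and it must be identical
for the two reading directions of the chain and for the mirror chain (those
all describe the same closed curve).  A consistent assignment exists and is
unique per type pair up to these constraints; the resulting closure
crossing shifts the knot determinant by +4 when the two chiralities agree
and −4 when they differ (e.g. +e with +o closes into the 7₆ knot,
Δ = 1−5t+7t²−5t³+t⁴, determinant 19 against the product's 15; +e with −o
gives 6₂, determinant 11).  For two even contacts in cross no diagram in
this family satisfies the constraints; that combination raises
`KnotModelError` rather than returning an unvalidated matrix.  Chains
whose segments each contain at most one cross pair are handled by
multiplying segment polynomials; larger mutually-crossing clusters are
unsupported.

## Positional measures

`PositionedChain` attaches a coordinate in [0, L] to each site (monomer
units; merged concerted sites share one coordinate).  Contact order is
CO = (1/mL) Σ|p₂−p₁| over the m selected contacts, filterable by kind;
soft-contact sites slide freely, so the difference in soft CO between two
positionings of the same chain (`delta_contact_order`) measures
deformation.  CO over both kinds is the contact-count-weighted mean of the
per-kind values.  Averaging is contact-wise, not site-wise, also when
concerted contacts share coordinates.

Homogeneity is the product of the gaps between consecutive occupied
locations (chain ends included) divided by its equal-spacing maximum
(L/m)^m, where m is the number of gaps; by AM–GM it lies in [0, 1] with
equality only at equal spacing (property-tested on 10⁴ random layouts).
Sites merged at one concerted location contribute a single gap boundary —
otherwise every concerted chain would score 0 — while coincident sites of
*different* locations are genuine zero gaps.  Coordinates must lie strictly
inside (0, L) for homogeneity; contact order tolerates sites at the ends.

## Random chains

`GeneratorSpec` draws uniformly random perfect matchings of the 2n sites
(pairing a random permutation two by two), marks a random subset of
contacts soft with types from a configurable distribution (uniform over
the four types by default), and inserts threads only strictly inside the
span of an existing contact with coin-flip signs — so every generated chain
is valid by construction.  The same spec and seed reproduce the same chain.
Uniformity is verified by chi-square against exact matching counts (three
2-contact configurations; the 105-matching class weights at n = 4,
α = 0.01).  Generated chains exercise the round-trip properties
(parse/serialize, string/matrix) on 10³ chains per run.

The generator produces topology only; it does not emulate geometric
features of real molecules (loop sizes, excluded volume, persistence
length), so passing tests certify the combinatorial machinery, not any
claim about real-chain statistics.

## Problem sizes and runtime

All tabulated quantities are desk-scale: enumeration is used up to n = 6
(10 395 strings; the bound is configurable), property tests use 10³–10⁴
random instances, and symbolic determinants stay at 9×9.  The full test
suite runs in well under a minute on one CPU; the acceptance script in a
few seconds.

## Known limitations

* Contacts must be extracted from structures upstream; nothing here reads
  3D coordinates.
* Knot polynomials cover single contacts, cross-free chains, and validated
  two-contact cross pairs; even–even cross pairs and clusters of three or
  more mutually crossing soft contacts are reported as unsupported.
* Realizability of size vectors is not checked.
* Dynamics (reptation, folding kinetics, entropy estimates) are outside the
  model.
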