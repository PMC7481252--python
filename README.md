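# circuitchain

Circuit topology of folded linear chains: a notation and algebra for the
arrangement of intrachain contacts, extended to chain entanglement.

Proteins, genomic DNA, and many other systems are linear chains folded by
intrachain interactions.  Two complementary theories describe such folds:
circuit topology classifies the pairwise arrangement of *contacts* —
series (S), parallel (P), cross (X) — while knot theory describes chain
*entanglement* but ignores contacts.  `circuitchain` implements the
generalized framework that joins the two: **hard contacts** (bonds gluing
two chain sites), **soft contacts** (loops hooked through each other, with
a chirality ± and a parity even/odd), and **threads** (segments passing
through a loop, the anatomy of slip-knots) are all events on one string,
e.g.

```
AABB              two bonds in series
A^{+o} A _{+A}    a slip-knot
(AB) C (BDE) (EF) (FDG) S^{+e} (HI) (IGA) H S C    the YibK fold
```

On top of the notation the package provides:

* **notation** — parse/serialize chain strings (compact or spaced ASCII),
  convert to/from 2n×2n connectivity matrices, break contacts, merge
  chains, JSON/TSV/`.ctstr` I/O;
* **relations** — classify contact pairs (S/P/P⁻¹/X and the concerted
  CS/CP), enumerate all (2n−1)!! configurations, reduce by chain-reversal
  symmetry, split chains into independent segments;
* **circuits** — find all self-contained circuits, the size vector
  (circuit counts per order), the weighted metric
  d(X,Y) = √(Σₖ k²(xₖ−yₖ)²) and the roughness r(X) = d(X,0);
* **knots** — 4×4 knot matrices of the four soft-contact types and their
  Alexander polynomials (trefoil t²−t+1 for ±e, figure-eight t²−3t+1 for
  ±o), multiplicative joining for series/parallel, and the 9-crossing
  matrix for two contacts in cross;
* **measures** — contact order (hard, soft, or both) and homogeneity of
  contact positions for chains with site coordinates;
* **toolkit / CLI** — seeded random-chain generation, batch comparison,
  and a `circuitchain` command exposing all of the above.

## Worked example

The knotted methyltransferase YibK has nine hard contacts (several
concerted, written in parentheses) and one `+e` soft contact — the
trefoil entanglement the protein is famous for:

```python
>>> from circuitchain import *
>>> yibk = parse_chain("(AB) C (BDE) (EF) (FDG) S^{+e} (HI) (IGA) H S C")
>>> [(s.order, "".join(sorted(s.contacts))) for s in find_circuits(yibk)]
[(1, 'E'), (1, 'F'), (1, 'I'), (2, 'EF'), (3, 'DEF'), (10, 'ABCDEFGHIS')]
>>> str(size_vector(yibk))
'[1000000113]'
>>> squared_roughness(yibk)
122
>>> poly = alexander_of_chain(soft_restriction(yibk))
>>> str(poly), poly.determinant()
('1 - t + t^2', 3)
```

Reading: the fold contains three one-contact circuits (EE, FF, II), one
two-contact circuit (EEFF), the three-contact blob DEEFFD, and the whole
string — size vector [1000000113], squared roughness 122, so this fold
sits far from a disentangled chain (r ≈ 11.0).  Its soft part alone is the
trefoil: Alexander polynomial t²−t+1, knot determinant 3.

The same from the shell:

```sh
circuitchain size "(AB) C (BDE) (EF) (FDG) S^{+e} (HI) (IGA) H S C"
circuitchain distance AABBCC ABCCAB --squared   # -> 20
circuitchain alexander "A^{+o} A"               # -> 1 - 3t + t^2
circuitchain enumerate 3 --reduce
```

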