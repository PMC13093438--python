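# The quartet-invariant hybridization statistic

This note records the exact algebra implemented in
`phyloconflict.hyde.hils_test` so that any transcription error is
detectable against the calibration and recovery simulations in the test
suite.

## Setup

For an ordered quartet (outgroup O, parent candidate P1, putative hybrid
H, parent candidate P2), every site with unambiguous A/C/G/T in all four
rows is mapped to one of the 15 set partitions of 4 items, written as a
letter pattern anchored on the outgroup (first base = `A`, next distinct
base = `B`, ...). Three classes matter:

| class  | meaning                         |
|--------|---------------------------------|
| `ABBA` | P1 and H share a non-outgroup state |
| `ABAB` | P1 and P2 share a non-outgroup state |
| `AABB` | H and P2 share a non-outgroup state |

Let `n` be the number of classified sites and `p9`, `p7`, `p4` the
relative frequencies of `ABBA`, `ABAB`, `AABB` (a continuity offset of
0.05 counts is added to each to avoid degeneracies at small `n`).

## Null hypothesis and invariants

H0 is hybrid speciation with inheritance probability `gamma = 0`, i.e. a
plain species tree in which H is sister to P2 relative to P1 and O, with
free incomplete lineage sorting. Under H0 the coalescent process is
exchangeable in H and P2, which maps the pattern class `ABBA` onto
`ABAB`; hence

    X = n (p9 - p7)   has expectation 0 under H0,
    Y = n (p4 - p7)   is the (positive) concordance excess.

Under the hybrid speciation model with symmetric parental attachment,
E[X] = gamma * D and E[Y] = (1 - gamma) * D for a common positive D, so

    R = X / Y   estimates gamma / (1 - gamma),
    gamma_hat = R / (1 + R).

## Test statistic

Treating the classified sites as multinomial,

    Var(X)   = n [ p9 (1 - p9) + p7 (1 - p7) + 2 p9 p7 ]
    Var(Y)   = n [ p4 (1 - p4) + p7 (1 - p7) + 2 p4 p7 ]
    Cov(X,Y) = n [ -p9 p4 + p9 p7 + p4 p7 + p7 (1 - p7) ]

and the delta-method variance of the ratio is

    Var(R) = Var(X)/Y^2 - 2 Cov(X,Y) X / Y^3 + Var(Y) X^2 / Y^4 .

The statistic `z = R / sqrt(Var(R))` is asymptotically standard normal
under H0; the p-value is one-sided (`gamma > 0`). Two regimes make the
ratio form preferable to the plain score `X / sd(X)`:

* correctly arranged triple (H sister to P2): Y is large and nearly
  constant, so z ~ X / sd(X);
* H actually sister to P1 (no hybridization): E[Y] = 0 and the
  `Var(Y) X^2 / Y^4` term dominates, so z ~ Y / sd(Y) — still standard
  normal rather than exploding.

When the triple is misarranged with H the outgroup of the quartet's
ingroup, both X and Y are strongly negative and R is a ratio of two
majority-pattern deficits; the test is undefined there. The
implementation therefore reports `defined = False` (p = 1) whenever
`Y <= 0`.

## Caveats

The multinomial variance assumes sites are independent draws (the
coalescent-independent-sites model). Long multi-site loci share one gene
tree per locus, which inflates the variance of X and Y relative to the
multinomial expression and makes the test slightly anticonservative;
the calibration suite therefore uses many short loci. Real-data analyses
should treat borderline z values with caution or thin sites.
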