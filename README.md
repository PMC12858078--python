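# pkscan

Section-based analysis and prediction of RNA pseudoknots on known secondary
structures.

## The problem

Pseudoknots — base pairs that cross the nested secondary structure — are
central to the function of many non-coding RNAs (tmRNA, RNase P RNA, viral
elements), but predicting them globally is NP-complete under realistic
energy models, and even restricted global algorithms cost O(N⁵)–O(N⁶).
pkscan takes the hierarchical view: the nested secondary structure is given
(from a database or an upstream predictor), and pseudoknots are sought only
between *sections* — maximal runs of bases the secondary structure leaves
unpaired.  Each section pair is scored independently with a nearest-neighbor
thermodynamic model, which makes the whole scan O(n²ℓ⁴) for n sections of
typical length ℓ — roughly O(N²) in total sequence length.

## The model and algorithm

For two sections of lengths ℓ₁, ℓ₂ a dynamic-programming matrix C is filled,
where C(i, j) is the minimum free-energy contribution over duplex structures
in which base i of section 1 pairs base j of section 2 and (i, j) is the
outermost pair.  Pairs are canonical only (AU, UA, CG, GC, GU, UG), strands
run antiparallel, and pairs within a section pair may not cross, so

    C(i,j) = min( C(i+1, j−1) + E_stack,
                  C(i+d, j−1) + E_bulge(d−1)      for d ≥ 2,
                  C(i+1, j−d) + E_bulge(d−1)      for d ≥ 2,
                  C(i+d₁,j−d₂) + E_interior(d₁−1, d₂−1)  for d₁, d₂ ≥ 2,
                  0                                if (i, j) is innermost )

with energies (kcal/mol, 37 °C) from bundled mfold-style nearest-neighbor
tables.  Only loops made of pseudoknot pairs are scored — loops containing
secondary-structure pairs are excluded by the hierarchical assumption.  The
section-pair MFE is min(0, min C); a negative MFE predicts that the sections
*connect*.  Sections of the same loop are never paired (such pairs would be
nested, not pseudoknotted).

Connected sections form clusters: 2-clusters (pseudoknot order 1; H-/K-type)
are predicted directly by the MFE duplex; type-1 3-clusters (order 2;
kissing-hairpin-like chains s1–s2–s3) are predicted by minimizing
E(former) + w·E(latter) with w = 0.8 by default, never reusing a base of the
shared section — reflecting co-transcriptional folding, where the 5′
("former") duplex forms first.  Survey statistics (exponential MFE-gain
decay and the implied per-pair pairing probability, connecting probability
per gain bin, top-K coverage, TPR/PPV) complete the evaluation pipeline.

## Worked example

Generate a small synthetic molecule with one implanted H-type pseudoknot and
analyze it:

```bash
$ pkscan simulate --seed 1 --n 1 --out demo
$ cat demo/mol0000.dbn
>mol0000 seed=1
CGAUGCUCCACACUCCUUGGCAUGAGUGUAGCAGGGCCGCGAGCCUGCCUCGCGUUGCCAGGGCAGUGCCCUGGCU
..............................(((((..[[[[[[)))))]]]]]]..((((((((...)))))))).

$ pkscan pairscan demo/mol0000.dbn
rank  molecule   sec_i  sec_j  mfe    gain  predicted_connected  true_connected
1     mol0000:0  1      2      -12.7  12.7  True                 True
2     mol0000:0  0      1      -9.3   9.3   True                 False
3     mol0000:0  0      3      -4.6   4.6   True                 False
...
```

The implanted pseudoknot (hairpin-loop section 1 against the downstream
linker, section 2) tops the gain ranking at 12.7 kcal/mol; the remaining
rows are spurious complementarity in the random background.  Predicting and
checking the base pairs:

```bash
$ pkscan predict demo/mol0000.dbn | tail -7
molecule   cluster   pos5  pos3  energy
mol0000:0  2cluster  37    53    -12.7
mol0000:0  2cluster  38    52    -12.7
mol0000:0  2cluster  39    51    -12.7
mol0000:0  2cluster  40    50    -12.7
mol0000:0  2cluster  41    49    -12.7
mol0000:0  2cluster  42    48    -12.7
```

exactly the six implanted pairs recorded in `demo/mol0000.truth.tsv`
(TPR = PPV = 1).  The gain-distribution machinery can be exercised directly
from the independent-pairing model:

```bash
$ pkscan fitdecay --simulate-n 100000 --seed 1
a         pairing_probability  bin_width  r_squared  n_bins
0.495347  0.609359             1.0        0.999834   18
```

The recovered pairing probability ≈ 0.609 equals the analytic value
1 − (5/8)² = 39/64 for extending a helix when 6 of the 16 ordered base
combinations can pair.  Real structures in CT, BPSEQ, or layered dot-bracket
can be fed to `sections`, `pairscan`, `predict`, and `evaluate` the same way.

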