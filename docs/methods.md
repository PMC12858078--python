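# Methods

## Model and assumptions

pkscan analyzes pseudoknots *given* a nested secondary structure.  The
structure's unpaired bases are grouped into sections (maximal unpaired runs),
each tagged with the loop it sits in (hairpin, interior/bulge, multi, or the
single exterior loop).  The core quantity is the minimum free energy (MFE)
of a pseudoknot duplex between two sections, computed by dynamic programming
under a nearest-neighbor model with three assumptions:

1. **Locality.** Only loops consisting entirely of pseudoknot base pairs are
   scored; loops containing secondary-structure pairs are excluded.  This is
   what keeps section pairs independent and the scan O(n²ℓ⁴).  The duplex
   recursion therefore uses only stacking, bulge, and interior-loop terms;
   hairpin and multiloop parameters are carried in the parameter set for
   completeness of the loop-based model but never enter the recursion.
2. **Additivity.** Free energies of consecutive loop motifs add; conformational
   entropy of the global fold is ignored.  This is why some long section
   pairs show large MFE gain without actually connecting: many weak pairs
   accumulate energy on paper while the (unmodelled) entropy loss of forming
   them dominates in reality.
3. **Canonical pairs at 37 °C.** Only AU/UA/CG/GC/GU/UG pair; no
   enthalpy/entropy decomposition, no salt correction, no dangling ends, no
   coaxial stacking, no special 1×1/1×2/2×2 interior tables.

A section pair's MFE is min(0, min C), so it is never positive; "predicted
connected" means MFE < 0.  Sections of the same loop are inadmissible (their
pairs would be nested).  Within a section pair, pseudoknot pairs may not
cross and strands are antiparallel.

## Parameter tables

Energies are kcal/mol at 37 °C, bundled as plain TSV under `pkscan/data`
and validated on load against the model's published value ranges: stacking
in [−3.4, +1.5] (GC-on-CG the most stable motif), interior-loop initiation
in [4.1, 7.4] and bulge initiation in [3.9, 6.7] for lengths 1–30, terminal
mismatches in [−2.7, +0.2].  The stacking table satisfies the strand-swap
identity E(5′XW3′/3′YZ5′) = E(5′ZY3′/3′WX5′); loop initiations are anchored
at their published endpoints and interpolated logarithmically in length.
Remaining knobs:

| parameter | default | meaning |
|---|---|---|
| asymmetry_coeff | 0.5 kcal/mol per unit | interior-loop asymmetry penalty |
| extrapolation_coeff | 1.75·RT ≈ 1.079 kcal/mol | Jacobson–Stockmayer log extension beyond length 30 |
| length-1 bulge | initiation + flanking stack | helix continuity retained |
| bulge mismatches | ignored | terminal mismatches apply to interior loops only (conventional nearest-neighbor rule) |

A user-supplied directory with the same three files can replace the bundled
tables; the range validation still applies.

## Numerical choices

- Co-optimality tolerance 1e-6 kcal/mol; tracebacks return all distinct MFE
  structures up to a cap (default 64) in lexicographic order, so output is
  deterministic.  MFE = 0 returns no structures (no pairs predicted).
- Masked positions (bases claimed by another duplex) become unpairable but
  still count toward bulge/interior loop lengths — they are physically
  present, just unavailable.
- Energies are floats; parameter precision is 0.1 kcal/mol, so exact
  comparisons in tests use 1e-9 and user-facing tables round to 6 digits.
- Non-ACGU residues are kept, never pair, and contribute no terminal-mismatch
  bonus when they sit next to a closing pair.
- CT/BPSEQ carry no layer annotation; the pair set is split by a
  maximum-cardinality non-crossing subset (dynamic program over endpoint
  intervals), with ties broken toward minimum total span and then the
  lexicographically smallest pair list.  On dot-bracket input, layer 0 is
  the secondary structure and all other bracket alphabets are pseudoknots.
- The 5′ and 3′ exterior tails share the single exterior loop, so tail–tail
  pairing is inadmissible.  This is a modelling choice where the convention
  is genuinely open; it errs toward fewer candidate pairs.

## 3-cluster prediction

In a type-1 3-cluster (sections s1 < s2 < s3 with edges s1–s2 and s2–s3) the
weighted objective E(former) + w·E(latter) is minimized subject to no base
of s2 serving both duplexes.  The search enumerates contiguous splits of s2:
for every boundary k and both side-assignments, the masked DP scores
s1 × s2-block and s2-complement × s3, and the best weighted sum wins
(deterministic tie-break on assignment then boundary).  Interleaved
allocations of s2 are not enumerated: skipping a base inside a helix costs a
loop penalty of at least the bulge initiation (≥ 3.9) against a best stack
of −3.4, so contiguous blocks dominate; the test suite confirms exact
agreement with brute-force joint enumeration over all compatible duplex
pairs on small instances.  w = 1 is the equal-weighting strategy; the
sequential strategy instead fixes the former duplex at its unconstrained
MFE (first co-optimal in deterministic order) and fills the latter from the
remaining bases.  The default w = 0.8 weights the 5′ duplex preferentially,
consistent with co-transcriptional formation of former pairs.  Type-2
3-clusters and clusters of ≥ 4 sections are detected and labelled but not
structurally predicted.

## Synthetic data

The generator builds what the algorithms consume: a nested scaffold of 2–3
hairpins (stems 4–8 bp) separated by exterior linkers, section lengths drawn
geometrically with mean 6 nt truncated at 30 nt — the scale of curated tmRNA
/ RNase P RNA structures (~30 sections per molecule, mean section lengths
5–8 nt) — and pseudoknot helices implanted as reverse-complementary,
GC-biased stretches between sections of different loops.  An H-type implant
connects a hairpin loop to the following linker; a type-1 3-cluster implant
places two disjoint blocks in one linker, pairing the preceding and
following hairpin loops.  "Perfect" implants are re-verified at build time:
the section-pair DP must have a unique MFE structure equal to the implant
(candidates are redrawn otherwise), so exact recovery downstream is a
meaningful test.  "Noisy" implants carry one injected mismatch; "decoy"
implants add complementarity without marking the pair connected, emulating
entropic false positives.

What the generator does **not** emulate: real tmRNA/RNase P sequence
composition, helix lengths and loop geometry correlations, non-canonical
pairs, base triples, or 3D constraints.  Passing tests therefore show the
machinery is correct under the stated energy model, not that accuracy on
real corpora matches any particular figure.

The gain sampler draws from the independent-pairing model: the number of
pairs in a duplex is geometric with continuation probability p0 and each
pair contributes 1.0 kcal/mol, so frequency(gain) ∝ p0^gain.  The analytic
p0 for helix extension is 1 − (5/8)² = 39/64 ≈ 0.609: of the 16 ordered
base combinations 6 pair (probability 3/8), and either of the two adjacent
candidate positions can continue the helix.

## Statistics

- TPR = TP/(TP+FN), PPV = TP/(TP+FP); with several co-optimal structures the
  metrics are computed per structure and averaged, undefined values (empty
  truth or empty prediction) flagged and excluded from averages.
- The decay fit histograms gains at 1.0 kcal/mol (the approximate per-pair
  energy), drops bins with fewer than 5 counts, and fits log counts by
  weighted least squares (weights √count, the Poisson choice); the pairing
  probability is exp(−a · 1.0 kcal/mol).
- Connecting probability is connected/total per gain bin, empty bins
  omitted.  Cumulative coverage ranks pairs by gain descending (stable
  tie-break by molecule then indices) and is monotone to exactly 1.0.
- Accuracy-vs-length uses Pearson correlation with two-sided p-values;
  constant vectors are flagged rather than reported as 0.

## Problem sizes and verification

The DP is verified against an exhaustive oracle that enumerates every
antiparallel non-crossing canonical pairing (guarded to sections ≤ 10 nt;
joint 3-cluster oracle ≤ 6 nt): 500+ random section pairs of length ≤ 8
agree to 1e-9, and every traceback re-scores to the MFE.  Perfect-fixture
recovery runs 100 seeds; the decay fit uses 10⁵ samples; DP operation
counts are measured at section lengths 4–32 and stay below c·ℓ⁴.  These
sizes make the full suite run in seconds while exercising every code path;
the oracle refuses larger instances because its enumeration grows
exponentially.

## Known limitations

- Salt-free parameters approximate in-vivo conditions; no salt-corrected
  tables exist at this coverage.
- Latter pairs of 3-clusters are poorly described by local energy
  minimization in real molecules (their formation depends on global/3D
  context); the machinery predicts them, but the model's own assumptions are
  weakest there.
- The bundled tables are constructed to the model's published ranges and
  thermodynamic symmetries rather than copied from a specific parameter
  release; absolute energies of individual motifs may differ from any given
  mfold/Turner file even though all validated ranges and the qualitative
  ordering of motifs match.
- `decompose_layers` maximizes cardinality; for structures whose pseudoknot
  helix is longer than the crossing stem, the layers of an unannotated
  (CT/BPSEQ) file will differ from a curator's labelling.
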