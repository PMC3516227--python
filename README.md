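# tehgt — detecting horizontal transfer of DNA transposons

`tehgt` is a Python toolkit for asking whether a transposable-element
(TE) family moved between host lineages horizontally rather than by
descent.  The motivating case is a Tc1/mariner DNA transposon shared at
95–99% nucleotide identity between lampreys and several only distantly
related teleost fishes — far too similar for lineages that split over
500 Ma ago, and distributed in a mosaic pattern across the vertebrate
tree.  The package reconstructs that style of analysis end to end, and
ships a simulator of TE families with known transfer histories so every
stage can be validated against ground truth.

## What it computes

Given nucleotide copies of a TE family (real or simulated), the
pipeline:

1. **Harvests copies** by a BLASTN-like seed-and-extend search, merges
   overlapping EST/GSS-style fragments (≥99% identity over ≥40 bp), and
   builds a **simple-majority consensus** from the top 300 hits stacked
   on query coordinates — the stand-in for the ancestral active element.
2. **Handles decayed ORFs**: locates the transposase ORF, classifies
   copies as intact or disrupted, and deduces peptides by excising
   consensus-frame codons that carry frameshift or nonsense mutations.
3. **Filters and aligns** (MAFFT; sites with gaps in ≥15% of rows and
   rows shorter than 75% of the alignment are removed; near-duplicates
   within species collapsed at ≥95% nt / ≥80% aa identity).
4. **Builds trees and tests topologies**: neighbor joining on p- or
   Poisson-corrected distances (d = −ln(1−p)), bootstrap supports,
   GTR+Γ log-likelihoods by Felsenstein pruning, and Kishino–Hasegawa
   topology tests with RELL resampling of per-site log-likelihoods
   against constrained topologies (e.g. "the lamprey copies are
   monophyletic", the vertical-transmission hypothesis).
5. **Synthesizes transfer evidence**: identity-to-consensus
   distributions that split a recent family (≥92.5%) from old
   background copies (<90%); Nei–Gojobori Ka/Ks (neutral decay gives
   ω = dN/dS ≈ 1); **Dollo parsimony** loss counting (how many
   independent losses would vertical transmission require?); and
   **nesting-based transfer calls** that name recipient and donor
   lineages from a copy gene tree.

## Worked example

Simulate a recent family on a five-species host tree with one
horizontal transfer from a northern lamprey lineage into a teleost
(`lampN → tel1`, late on the recipient branch, 10-copy bursts), then
run the whole pipeline:

```bash
tehgt simulate --tree host.nwk \
  --transfers '[{"donor":"lampN","recipient":"tel1","time":0.9}]' \
  --burst 10 --sub-rate 0.3 --seed 42 --out copies.fasta
tehgt all --config config.json --seed 7 --out demo_out
```

A run on the tree
`((lampN:0.06,lampS:0.06):0.04,((tel1:0.05,tel2:0.05):0.03,outg:0.08):0.02);`
prints a run log whose stages read:

```
harvest    {'n_hits': 60, 'consensus_length': 1604, 'orf': [294, 1314]}
identity   {'n_scored': 60, 'n_group1': 60}
toptest    {'delta_lnL': -62.99, 'p_value': 0.0}
kaks       {'n_pairs': 15, 'median_omega': 0.797}
transfers  {'n_calls': 2, 'mosaic': True}
```

and `transfer_calls.tsv` contains:

```
recipient  donor_clade  nesting_depth  support
lampN      tel1         7              NA
tel1       lampN        3              NA
```

Reading the numbers: all 60 copies score ≥92.5% identity to the
majority consensus (a single recent family, peaking at 97.5–98% in the
identity histogram, like a family that proliferated recently in every
carrier genome); forcing the lamprey copies to be monophyletic costs
63 log-likelihood units and is rejected by KH/RELL at p < 0.0001, so
vertical transmission does not explain the tree; median ω ≈ 0.8 is
consistent with neutral decay of dead copies; and the transfer caller
recovers the simulated event — `tel1` nested inside the `lampN`
cluster — together with its reciprocal donor-side call, the
directionality ambiguity such nesting always carries.

With a host tree and a presence/absence survey, `tehgt losses` counts
the independent losses a single vertical origin would imply.  On the
built-in vertebrate phylogeny and PCR survey
(`tehgt.datasets`), the family's absence from hagfishes, southern
lampreys, cartilaginous fishes, sturgeon, gar and sarcopterygians
forces **6 independent losses outside the teleosts** — the parsimony
argument against vertical transmission.

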