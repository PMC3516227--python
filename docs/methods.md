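# Methods

This note documents the models, defaults and numerical choices behind
`tehgt`, and what the simulated validation does and does not show.

## The simulator (`tehgt.simulate`)

The simulator is the package's experimental substrate: it produces TE
families whose full history (genealogy, transfers, disruptions) is
known, so every downstream stage can be scored against truth.

**Master element.** `make_master` draws a random 1,610-nt element with
a single intact ORF of 1,020 nt (ATG, 338 sense codons, one stop) —
the size class of a Tc1 transposase element.  Coordinates are 0-based,
half-open everywhere in the package.

**Copy process.** One founder copy descends from the root of a host
species tree whose branch lengths are in expected substitutions per
site.  On each terminal branch the family burst-amplifies to
`burst_size` copies (default 30) at fraction `prolif_time` (default
0.8) along the branch.  This burst-dominated model encodes the study
condition the package targets: a family whose intragenomic
proliferation is recent and roughly coincident across carrier species,
so each genome's copies form a within-species cluster.  Background
copy births are a Poisson process at `birth_rate` (default 0.2 per
copy per unit branch length) — rare, but enough to create occasional
older paralog lineages, which is exactly the confounder the transfer
caller must reject.

**Mutation.** Substitutions follow K80 with transition/transversion
rate ratio κ = 2.0 (typical vertebrate nuclear bias; the closed-form
transition matrix is used, so expected divergences are analytic).
Indels occur at `indel_rate` (default 0.005 events per site per unit
branch length) with lengths 1–3 under a truncated geometric — enough
to produce the frameshifts that disrupt most real copies without
making alignment ambiguous.  Premature stops arise naturally from
substitutions; there is no separate disruption event.

**Transfers.** A `TransferEvent(donor, recipient, time)` copies one
randomly chosen extant donor-lineage copy at the stated time point
(checked for contemporaneity against node depths) and burst-amplifies
it to `burst_size` copies in the recipient, which then evolve
normally.  A single copy seeding the recipient mirrors the single-
element founder effect inferred for real transfers; burst timing is a
parameter because the data do not pin it down.

**What the simulator does not model:** selection on transposase
activity, within-host population dynamics, excision footprints,
horizontal transfer vectors, and genome assembly artifacts.  Passing
the validation therefore shows the *inference machinery* is sound
under the stated generative model, not that real data are this clean.

## Harvesting and consensus (`tehgt.harvest`)

The similarity search is seed-and-extend: exact 11-mers nominate
subject windows, and an affine Smith–Waterman–Gotoh kernel (match +1,
mismatch −2, gap open −5, extend −2; N is always a mismatch) produces
the gapped local alignment on both strands.  Percent identity is
computed over aligned columns excluding gap columns.  Repeated copies
on one subject are found by masking matched stretches and re-aligning.

The consensus stacks hits on query coordinates and takes the
per-column majority; ties break by the fixed residue order
A < C < G < T, with the gap losing every tie, and columns where the
gap is the strict majority are deleted.  Positions a hit does not
cover count as gaps, so the consensus spans the well-supported core.
With fewer hits than the requested top-n (default 300) all hits are
used, with a warning.

Fragment assembly is greedy single-linkage merging of end-spanning
overlaps (defaults ≥99% identity over ≥40 bp), taking the
first-listed record's bases in the overlap; it replaces a full
assembler because inputs are desk-scale.

Dedup clustering is single-linkage within each species (≥95% nt /
≥80% aa), with the longest member (ties by id) as representative.
Identity for dedup penalizes terminal gaps (a true global alignment);
otherwise unrelated sequences can score near-100% over a tiny
coincidental core.

In-silico PCR requires the forward primer on the plus strand and the
reverse primer's reverse complement downstream, each with ≤2
mismatches and an exact 3′-terminal 3 nt, products ≤2,000 bp, both
orientations tried.

## ORF handling (`tehgt.orf`)

The reading frame of a copy is defined by the consensus, not by
re-scanning the copy: the copy is globally aligned (free end gaps;
match +1, mismatch −1, gap open −4, extend −1) to the consensus ORF,
and indel runs are classified whole.  A run whose length is divisible
by 3 is a clean codon indel (inserted residues dropped, straddled
codons re-read as consensus-frame triplets); any other run is a
frameshift and every codon it touches is excised.  Codons translating
to a premature stop are excised as nonsense; the ORF's own terminator
is not a disruption.  Only the standard genetic code is supported.
Codons adjacent to a frameshift are kept — the alignment, not a
fixed window, decides what is disrupted.

## Alignment filters (`tehgt.msa`)

Multiple alignment delegates to MAFFT (default progressive settings,
deterministic), the aligner practitioners use for this job; the
package's own contribution is the filter semantics: gap-heavy columns
(gap fraction ≥0.15) are removed first, then rows with residues for
<75% of the remaining width (inclusive thresholds), in that fixed
order, with row completeness measured against the post-column-filter
width.  Alignment never edits residues.

## Phylogenetics (`tehgt.phylo`, `tehgt.likelihood`)

*Distances.* p-distances use pairwise deletion; the Poisson correction
d = −ln(1−p) errors at p ≥ 1 ("saturated").

*Neighbor joining.* Saitou–Nei Q-criterion agglomeration; ties break
on the smallest index pair; negative branch lengths are clamped to
zero with the deficit moved to the sister branch; the result carries a
trifurcating root.  On additive matrices NJ provably recovers the
generating topology — the test suite checks this against an exhaustive
enumeration-plus-least-squares oracle on ≤6 taxa.

*Likelihood.* GTR+Γ via Felsenstein pruning over compressed site
patterns; gaps and Ns are missing data (partial likelihood 1).  Γ uses
equal-weight discrete categories with mean-of-quantile rates (default
4; α = ∞ or one category recovers the homogeneous model).  The
transition matrix comes from the symmetrized eigendecomposition, so
likelihoods are exactly reversible (re-rooting invariant).  Full ML
tree search is deliberately out of scope: the inference the package
supports compares the likelihoods of given topologies (NJ trees and
constrained variants), which is what the vertical-vs-horizontal
question needs.  Branch lengths are optimized one at a time by
bounded Brent (bounds 10⁻⁹–10, a few sweeps); GTR parameters can be
estimated by Nelder–Mead from empirical base frequencies with the GT
rate fixed at 1.

*Constrained topologies.* To force a subset monophyletic, the subset
is pruned, its induced subtree rebuilt by NJ on the induced distance
submatrix, and the subtree tried on every backbone branch; each
placement's three junction branches are Brent-optimized and the best
placement then gets a full optimization pass.

*Topology test.* Kishino–Hasegawa with RELL: per-site log-likelihoods
per topology, the best tree as reference (Δ = 0, p = 1), and a
one-sided p-value for each alternative from the centered bootstrap
distribution of its per-site log-likelihood deficit (default 1,000
resamples, seeded).

## Transfer evidence (`tehgt.hgt`)

*Identity distributions.* Identity to the consensus is computed over
gap-excluded columns of a free-end-gap global alignment; records with
fewer than 150 comparable sites are dropped (logged).  Histogram bins
are right-closed with 0.5-point width.  Group classification uses an
inclusive floor of 92.5% for the recent family and a ceiling of 90%
for divergent background copies; the zone between is reported
"unassigned" rather than forced into a group.

*Ka/Ks.* Nei–Gojobori (1986) unweighted pathway counting with
Jukes–Cantor correction.  Synonymous site fractions treat
stop-producing changes as nonsynonymous; multi-difference codons
average over all minimal pathways, excluding pathways through stops
when a stop-free one exists; codons with gaps, Ns or stops are
skipped pairwise (counted).  ω is reported missing when dS = 0 or a
class saturates (p ≥ 3/4) so summary medians stay finite.

*Dollo losses.* With a single gain at the origin and unlimited losses,
the minimum loss count equals the number of maximal all-absent
subtrees below the origin; unknown-state taxa are pruned first, and a
present taxon outside the origin's subtree is an error.  The package
ships the vertebrate host phylogeny and PCR survey pattern in
`tehgt.datasets`; on it, six losses fall outside the teleost clade.

*Transfer calls.* On a midpoint-rooted copy gene tree (rooting makes
the ancestor walk independent of the arbitrary NJ trifurcation), a
maximal single-species clade is called a recipient when it sits
strictly inside a cluster of donor-species copies: its sisters belong
to the donor set and at least one further ancestor adds only donor
(or more recipient) copies.  Two guards keep the caller specific:
nesting inside "all other species" carries no directional signal and
is ignored, and a nesting whose recipient-donor distance exceeds
twice the donor cluster's own mean pairwise distance is discarded —
that is the signature of an old intragenomic duplication, not of a
recent transfer, which leaves recipient copies at donor-level
identity.  Donor-vs-recipient direction is genuinely ambiguous from
topology alone; the reciprocal call is emitted rather than hidden.
Mosaicism is summarized by Fitch parsimony: true when the species
character needs more than (species − 1) changes.

## Validation scenarios (`tehgt.validation`)

The acceptance script and test suite recompute these from scratch:

- **Dollo**: the built-in vertebrate survey → 6 losses outside the
  teleosts (plus further losses inside).
- **Consensus recovery**: 300 copies independently diverged 2% from
  the master; the majority consensus matches the master at ≥99.5% of
  positions.
- **Neutral ω**: 100 ORF pairs, each side 0.08 substitutions/site
  under K80 — long enough that per-pair noise is modest, within the
  divergence range a recent family spans; the median ω lands near
  but slightly below 1, the known small downward bias of
  equal-pathway counting under transition bias.
- **Family split**: a 2%-divergence family (50 copies, two species)
  plus a 30%-divergence within-species family (25 copies): every
  recent copy scores ≥92.5% to the recent consensus, every old copy
  <90% — the empirical identity gap that separates a recent
  horizontally spread family from resident background copies.
- **Transfer detection**: 20 replicates of one late (time 0.9)
  lampN → tel1 transfer with 30-copy bursts on a five-species host
  tree; the caller must name recipient and donor in ≥80% of
  replicates, with at most one spurious call across 20 transfer-free
  replicates.
- **Topology test**: 20 replicates of 1,020 K80 sites simulated on a
  fixed mosaic gene tree (teleost clades nested inside the lamprey
  cluster); the lamprey-monophyly constraint must score a lower
  likelihood and be rejected by KH/RELL at p < 0.05 in ≥90% of
  replicates.

Problem sizes (copy counts, replicate counts, site counts) are chosen
as the smallest at which each statistic is stable; they are stated
above and in the code, and the single `--seed` drives every random
stream.

## Known limitations

- The transfer caller reports nesting-based evidence only; it does not
  date events or resolve donor-vs-recipient direction.
- Peptide deduction trusts the pairwise alignment; in low-complexity
  regions the excised codon can shift by one relative to the true
  edit position (alignment ambiguity, not an error in excision).
- The likelihood machinery evaluates given topologies; it is not a
  tree-search program.
- E-value statistics and translated (protein-vs-nucleotide) search
  are not implemented; the harvest is nucleotide-only.
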