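# Methods

## Assay model

The toolkit models a targeted short-read assay for circular RNAs. A circRNA is
defined by its back-splice junction (BSJ): the 3′ end of the circle's last
exon (the splice donor) joined to the 5′ end of its first exon (the splice
acceptor). A target-specific first-strand-synthesis (FSS) primer anneals to
the acceptor exon ("3′ BSJ exon" in read orientation); reverse transcription
extends toward the transcript 5′ end, across the acceptor-exon start, into
either the circle's donor exon (circular template) or the exon spliced to the
acceptor exon in the linear transcript. Random-primed second-strand synthesis
places each read's 5′ end at a random upstream position, while the 3′ end is
anchored at the primer site. Every informative read therefore spans exactly
one of two junctions per target, and the per-target circular-to-linear ratio

    CLR = n_chimeric / (n_chimeric + n_linear)

is estimated directly from junction-spanning read counts. Expression is
reported as reads per million uniquely assigned reads (RPM).

Single-end reads up to 300 nt are assumed (the default flank and read length);
all coordinates are 0-based half-open, and all sequence operations are
strand-aware, returning transcript-sense sequence.

## Panels

A panel row carries the circle span (BED6) plus `host_gene` and three exon
intervals: `donor_exon`, `acceptor_exon`, `upstream_linear_exon`. The donor
exon is an explicit column because junction references take their 5′ flank
from it (and truncate to its length); inferring it from annotation would drag
in isoform-selection ambiguity that is better resolved by the panel author.
For hosts with multiple linear isoforms, the upstream linear exon is likewise
an explicit user choice. Circles from one host gene that share the acceptor
exon form one *acceptor-exon group* served by a single FSS primer; the group
count is the primer count. Panels larger than 110 targets trigger a warning
(a multiplexing recommendation), not an error.

## Melting temperatures

The Tm engine implements unified DNA/DNA nearest-neighbor thermodynamics
(SantaLucia, PNAS 1998): ΔH and ΔS are sums over the 10 distinct stacked
pairs plus terminal-base-pair initiation terms, and

    Tm(1 M Na+) = 1000·ΔH / (ΔS + R·ln(C_T / x)),

with x = 4 for a non-self-complementary duplex at comparable strand
concentrations (x = 1 selectable for primer excess). Salt effects use the
Owczarzy et al. (Biochemistry 2008) inverse-Tm correction with the
monovalent/divalent decision tree (ratio √[Mg²⁺]/[Mon⁺]) and free Mg²⁺
computed from total Mg²⁺ and dNTPs via the published association constant
(Ka = 3×10⁴ M⁻¹); conditions with [dNTP] > [Mg²⁺] (fully chelated divalent)
are rejected. Default conditions are the reverse-transcription reaction:
75 mM Na⁺, 3 mM Mg²⁺, 0.5 mM dNTPs, 0.0125 µM oligo, target 50 ± 2 °C.

DNA/DNA parameters are used although the FSS primer anneals to RNA — the
standard simplification of the common oligo calculators whose model this
reproduces. A test suite cross-checks the engine against the independent
Biopython implementation of the same published model (agreement ≤ 0.1 °C on
random 18–30-mers; observed agreement is at machine precision).

## Primer design

For each acceptor-exon group, every candidate window (start offset ×
specific-portion length) on the transcript-sense acceptor exon is scanned.
The specific-portion length range is derived from the accepted full-oligo
length range (default 43–48 nt) minus the adapter length (default 24 nt
placeholder partial P7 — the kit's exact sequence is proprietary, so it is
configurable). Admissible windows have Tm within the reaction window; among
them the design minimizes |Tm − 50 °C|, breaking ties by |GC − 0.5|, then by
preference for a BSJ distance of 30–50 nt, then by the smallest distance. The
scan order is deterministic, so tie-breaking is reproducible, and an
exhaustive-enumeration oracle in the tests confirms the search is exact. The
binding site must start ≥ 20 nt from the BSJ: that distance bounds the
junction flank available to a read, hence the classifiability of its target.
Design failures report the best near-miss and do not abort other groups.

qPCR primers (assay side-data) are chosen as 20-mers closest to 50 % GC with
Tm 55–57 °C, lengthening up to 30 nt for low-GC regions.

Specificity is checked within the panel only (exact occurrence of each
primer's binding site in other targets' references); a genome-wide off-target
screen is out of scope and should be run separately if needed.

## Junction references

Per target: `bsj_seq = donor 3′-flank (F nt) ++ acceptor prefix (D nt)` and
`linear_seq = upstream-exon 3′-flank (F) ++ acceptor prefix (D)`, with the
junction at offset F in both. F defaults to the read length (300 nt) so any
read 5′ end can be placed, truncated to the shorter of the two 5′-side exons
so the two references share the offset. D runs from the acceptor exon start
through the primer's 3′ terminus, i.e. the reference 3′ end is the anchored
read 3′ end. Targets whose donor-side and linear-side flanks coincide over
the min-anchor bases next to the junction are flagged unclassifiable and
excluded from junction calls (no read could distinguish them); they are
reported with a warning.

## Classification

Reads are preprocessed minimally: 3′ adapter removal (exact match anywhere,
else suffix overlap of ≥ 5 nt with the adapter prefix), 3′ clipping of bases
below Q20, and a 30-nt length floor. Classification is seed-and-extend:
exact 12-mer seeds against an index of all classifiable references propose
diagonals; a read must lie fully within a reference (ungapped), and mismatches
are counted against a budget of 5 % of read length (a rate, not a fixed count,
because trimmed read lengths vary). Indels are not modeled — targeted reads
against known references rarely need them, and gapped alignment would buy
little for its cost; such reads fall to `unassigned`.

The best admissible hits (within a 1-mismatch tie slack) are canonicalized:
a hit spanning the junction with ≥ min_anchor nt (default 10) on both sides is
`chimeric` (bsj reference) or `linear`; any other hit — confined to the shared
acceptor suffix, junction-overlapping with a short anchor, or confined to a 5′
flank — is group-level `non_junction` evidence. Distinct surviving assignments
make the read `ambiguous`. Because grouped targets share one linear junction,
their identical linear references are collapsed and a linear read is credited
to every member target — shared evidence of the one linear transcript — so
per-sample label totals are over reads, not per-target rows. Raising
min_anchor can only demote junction calls to `non_junction`, never create
them (monotonicity).

The default CLR denominator uses junction-spanning linear reads only
(symmetric evidence classes); a switch adds `non_junction` reads to linear
support for compatibility with "all uniquely aligned reads" definitions, and
every output records which denominator was used. For workflows that map with
a spliced aligner instead, a STAR `Chimeric.out.junction` parser counts
chimeric records whose breakpoints match a panel BSJ within a coordinate
tolerance (default 5 nt) on the correct strand.

## Quantification and comparison

CLR is undefined (reported missing, never imputed) when a target has no
junction reads. Targets with fewer than `min_junction_reads` (default 10 — a
conservative, configurable choice; no canonical cutoff exists) are flagged
low-expression and excluded from condition-comparison candidate lists while
remaining in all tables. Replicate agreement uses the Pearson coefficient
(scipy), with an optional exclusion list to re-test after removing a dominant
target. Condition comparison reports per-target mean CLR per condition, the
delta versus a reference condition, and the underlying RPM pairs for
inspecting reciprocal isoform changes; no multiple-testing machinery is
applied because the deltas are descriptive, not inferential. qPCR side-data
are reduced with the ΔΔCt model, fold change = 2^(−ΔΔCt), normalized to a
reference gene and the mean of the control samples.

## Simulator

The simulator draws, per read: target ∝ (circ + lin abundance) × primer pool
weight; circular vs linear template ∝ the two abundances; 3′ end fixed at the
reference 3′ end (the primer terminus); 5′ start uniform over a window
(default 30–300 nt upstream, truncated at the reference start and capped at
the read length); iid substitutions at the error rate (default 0.001);
constant Q30 qualities. The seed is mandatory. Ground truth (per-read
provenance and per-target realized counts) accompanies every FASTQ.

What it emulates: the primer-anchored/random-end read geometry, per-target
abundance and pool-weighting (including 1 % down-weighting of a dominant
target), and sequencing substitutions. What it does not: position-biased
random priming (the real hexamer process is biased; no published bias model
exists for this protocol, so starts are uniform), indels, quality decay along
the read, PCR duplicates, or off-panel background transcripts. Passing tests
therefore demonstrate correctness of the computational pipeline under the
assay's idealized geometry, not robustness to every artifact of real
libraries.

The synthetic panel generator plants three-exon genes (upstream, acceptor,
donor) in random sequence on alternating strands. `make_synthetic_heart_panel`
is a *synthetic* structural stand-in for a conserved cardiac panel: 63
circRNAs from 50 host genes collapsing to 52 acceptor-exon groups (37
single-circle genes, 11 genes with two circles sharing the 3′ BSJ exon, 2
genes with two circles on distinct acceptor exons), exon lengths 150–350 nt
at a genome-like 42 % GC. Sequence content is random, not real loci.

## Numerical and design notes

- Deterministic everywhere: fixed scan order in design, seeded RNG in
  simulation, order-stable counting in classification; identical inputs give
  byte-identical outputs.
- Problem sizes in the test and acceptance runs — 10,000 reads per simulated
  target, 100 random oligos for the Tm cross-check — were chosen so binomial
  sampling error is small against the checked tolerances (3 binomial standard
  errors on recovered CLR) while runs finish in seconds.
- Degenerate inputs are errors, not silent defaults: empty reference sets,
  zero total abundance, fully chelated Mg²⁺, zero-variance correlation
  vectors, RPM with a zero denominator.
- Known limitations: no hairpin/dimer screening of primers, no RNA/DNA hybrid
  thermodynamic parameters, no gapped alignment, no genome-wide primer
  specificity screen, no differential-expression inference across replicates.
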