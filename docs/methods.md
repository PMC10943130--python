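# Methods

## The BSJ-ORF model

A circRNA is represented by its linear spliced sense sequence of length *L*;
the back-splice junction (BSJ) is the wrap point between the last and first
nucleotide.  Translation is modeled with the standard genetic code on the
forward strand only (circBase-style sequences are already sense-spliced),
with ATG as the only accepted initiator and TAA/TAG/TGA as stops.  Codons
containing N translate to X and terminate ORF extension like a stop — a
conservative choice that avoids fabricating peptide sequence from ambiguous
bases.

Reading through the junction, the frame relation between codons and the
junction depends on *L* mod 3:

- *L* mod 3 = 0: the frame is invariant across the junction; two
  concatenated copies ("2x") expose the junction once per fixed frame.
- *L* mod 3 ≠ 0: the frame shifts at every junction passage; four copies
  ("4x") contain three internal junctions that realize all three phase
  relations in a single linear scan.

Each scan (three start frames per circRNA) is reduced to a sorted element
list of ATG/stop/junction coordinates.  Ties at one coordinate order
stop < junction < ATG: a stop ending exactly at the junction closes its
interval first, and an ATG starting at the junction is not upstream of it.
Every junction inside a stop-to-stop interval with at least one ATG strictly
between the preceding stop and the junction becomes a translatable span;
residues N-terminal to the first Met are removed.  Translated spans are
trimmed to at most W residues on each side of the junction residue(s), with
W = 24 when the junction falls inside a codon (one junction residue, window
≤ 49 aa) and W = 23 when it falls between two codons (two junction
residues, window ≤ 48 aa).  The flank of 24 is chosen so that any 25-mer
(the upper HLA-II reporting bound) with at least one junction residue is a
substring of some window; the same reference therefore serves HLA-I and
HLA-II searches.

### Boundary handling

A stop-to-stop interval truncated by a scan boundary can misstate the first
ATG or a flank (the true stop or Met may lie before the scan start or after
its end).  Windows are therefore emitted only from spans whose two bounding
stops are both real codons inside the scan.  Because start frames are free,
every junction phase is realized at junction positions *L*, 2*L* and 3*L*
across the three 4x scans, and for any non-infinite ORF (length < 3*L*) at
least one of these occurrences is fully stop-bounded — so the restriction
loses nothing.  This is what makes the builder provably identical to the
exhaustive unrolled-circle oracle (below), and it is verified as a test.

### Rolling-circle (infinite) translation

A reading frame of the circle with no stop codon supports rolling-circle
translation.  For *L* mod 3 = 0 each fixed frame is tested on one rotation;
otherwise the frames cycle and one test over all *L* codon offsets decides
all three phases at once.  On an infinite reading the "first Met" is
ill-defined (a Met recurs every rotation upstream), so infinite windows are
built directly off the unrolled circle with full W flanks on both sides,
requiring only that the rotation contains at least one ATG.  The infinite
flag is carried as window metadata (`INF=1` in the FASTA header); trimming
is the same as for finite windows.

### Window identity and deduplication

A window id is `<circ_id>_<phase>` where phase ∈ {0,1,2} is the junction
position within its codon (0 = between codons, i.e. the width-2 case).
Within one circRNA at most one window exists per phase — the three start
frames re-observe the same phases, and fully stop-bounded observations of a
phase are identical — so ids are unique.  Identical windows from different
circRNAs are deliberately kept per source: one peptide may be encoded by
several circRNAs of the same host gene, and that multi-source evidence is
reported downstream.

## Search database

Windows are appended to a UniProt-style proteome in one FASTA.  The Protein
Existence (PE) header field is repurposed as the group tag: `PE=1` for
canonical entries (any pre-existing PE token is overridden), `PE=4` for
windows, whose headers follow
`>circ|<id>|<id> BSJ=<start>-<end> INF=<0|1> PE=4` with 1-based window
coordinates of the junction residues.  The triple-bar shape mimics UniProt
so downstream tools parse the accession.

## Group-specific FDR

Canonical and circRNA-derived PSMs have different score distributions;
pooling them underestimates the error in the small circRNA group.  q-values
are computed per (engine, group): sort by score descending (decoys before
targets at score ties — conservative), estimate FDR at a threshold as
#decoys / max(1, #targets) among PSMs at or above it, let tied scores share
the worse estimate, and monotonize by a running minimum from the permissive
end.  No π0 correction is applied.  A peptide is retained when its best
target q-value is ≤ α (default 0.03) in both engines; a union mode exists
for single-engine use.  Per-engine q-values are reported; the combined FDR
of the intersection is not characterized analytically, but on simulated
data it is far below α (independent engine noise makes joint false passes
rare), which the calibration test quantifies.

## Classification and screens

Identified peptides (modifications such as `(Ox)` stripped for matching and
uniqueness) are located as exact substrings in all windows; a match
overlapping the window's BSJ span by one or two residues makes the peptide
circRNA-BSJ, otherwise circRNA-not-BSJ.  Each junction hit is documented as
`UP- > pre[BSJ]suf < -DOWN`, brackets around the junction residues covered
by the peptide; window, peptide and junction span reconstruct exactly from
this string.  The canonical screen re-annotates to PC any peptide occurring
verbatim inside a user-supplied proteome — for short peptides, "100%
similarity" in a BLAST-style search is exactly substring identity, so
pointing the screen at a larger FASTA reproduces a reference-proteome BLAST
step without a network dependency.  Ile/Leu equivalence (indistinguishable
by MS) is available behind a flag, off by default.  Identifications that a
modified canonical peptide explains with equal or better score are dropped
(strict inequality required to keep).  Entries whose accession carries the
contaminant prefix (default `CON__`) are removed from the analysis together
with the peptides matching them.  Reporting length windows are 8–15 aa
(HLA-I) and 9–25 aa (HLA-II); binder annotation consumes precomputed %rank
tables with the conventional strict <2 threshold and best-allele = lowest
rank.

## Tumor-specificity rule

CircRNAs are assumed to co-exist with their linear counterparts, so the
rule operates on host-gene TPM: a gene qualifies when ≥ 2.5 TPM at the 99th
percentile in at least one tumor cohort and ≤ 1 TPM at the 90th percentile
in every normal cohort, excluding testis and sun-exposed skin.  Percentiles
use the nearest-rank definition (ceil(p/100·n)-th order statistic): exact
on small cohorts and free of interpolation ambiguity.  Genes absent from
either reference are reported unknown, not negative.

## Synthetic data and oracles

The circRNA generator draws uniform random sequences in a length range
(defaults 300–900 nt with 30% frame-invariant lengths when exercising the
trimming cap; smaller ranges in the equivalence tests) and can plant a
junction-spanning ORF: a within-codon junction whose rolling reading
carries non-stop codons with an ATG exactly 40 codons upstream and its
first stop 41 codons downstream — enough reach on both sides that trimmed
windows attain the 49-aa cap.  The PSM generator emulates the two-engine
setting: each target peptide is truly present with probability π1 = 0.5;
true targets draw scores from Normal(3, 1) in each engine independently
(shared truth, independent noise), false targets and one decoy per target
from Normal(0, 1).  These defaults give realistically overlapping score
distributions (neither trivially separable nor hopeless) at sizes — 20,000
canonical and 1,000 circRNA-group targets, 20 replicates — where the
Monte-Carlo error of the realized false-discovery proportion is small and a
run still takes seconds.

The window oracle is an independent code path: it unrolls the circle far
enough that every junction phase has a fully-contexted occurrence, then
finds the nearest stops and first ATG by direct codon stepping with its own
codon table.  Builder/oracle window-set equality over hundreds of random
circRNAs per seed is the central correctness property.

What the simulations do not emulate: real spectra and engine score
distributions, correlated engine errors, homology between circRNAs and the
proteome, and circRNA expression levels.  Passing tests therefore establish
the combinatorial and statistical correctness of the reference construction
and filtering, not MS identification performance on real data.

## Numerical and design choices

- Coordinates are 0-based half-open internally, 1-based inclusive in every
  report and FASTA flag.
- Flanks are 24/23 with the 49-aa cap (the published methods text), not the
  alternative figure-legend reading of 25.
- The `_0/_1/_2` window-id suffix is reconstructed as the junction phase
  class; the between-codon case is phase 0, which reproduces the published
  frame-invariant width-2 examples carrying suffix `_0`.
- The packaged worked-example tables store windows reconstructed from the
  printed context columns; where a printed flank is truncated, the stored
  window is the truncated one, and tests assert on exactly what is printed.
- All generators are seeded (`numpy.random.default_rng`); identical inputs
  and configuration give byte-identical pipeline outputs.

## Known limitations

- Non-ATG initiation (near-cognate starts), IRES/m6A-driven start
  prediction and intron-retention reconstruction are out of scope; input is
  the spliced sequence.
- The FDR module operates on generic score columns; engine-specific score
  recalibration of the cited search tools is not re-implemented.
- The tumor-specificity rule depends on the upstream expression pipeline's
  percentile conventions; results on real cohorts will vary with those
  choices.
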