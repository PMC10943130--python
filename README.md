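# circbsj

Proteogenomic discovery of HLA-presented peptides derived from circular RNAs.

Circular RNAs (circRNAs) arise by back-splicing: the 3' end of a downstream
exon is joined to the 5' end of an upstream exon, producing a covalently
closed transcript.  The resulting back-splice junction (BSJ) can be
translated into peptide sequence that exists in no reading frame of the
linear transcript — a potential source of shared, non-mutated tumor
antigens.  `circbsj` builds the protein search space needed to find such
peptides by MS immunopeptidomics and implements the downstream
classification and filtering:

- **Reference building** — from each circRNA's spliced sequence (length
  *L*), the sequence is concatenated 2× (when *L* mod 3 = 0, the reading
  frame is invariant across the junction) or 4× (otherwise, so every
  junction/codon phase relation is visited).  In each of three start frames,
  all ATG codons, stop codons and junction coordinates are listed, sorted,
  and traversed; every junction inside a stop-to-stop interval with an ATG
  upstream yields an ORF, which is trimmed to at most 24 residues on each
  side of the junction residue (23 when the junction falls between two
  codons), i.e. windows of ≤ 49 aa — enough to host any 8–25-mer HLA-I/II
  peptide touching the junction.  Reading frames of the circle with no stop
  codon at all are flagged as rolling-circle ("infinite") translation
  candidates.
- **Search-database export** — windows are concatenated with a UniProt-style
  proteome into one FASTA whose headers carry `PE=1` (canonical) or `PE=4`
  (circRNA) so that group-aware FDR tools can separate the two search
  spaces.
- **Group-specific FDR** — per-group (canonical vs circRNA), per-engine
  target-decoy q-values with a 0.03 default threshold and two-engine
  intersection: the small non-canonical group gets its own error control
  instead of borrowing the canonical score distribution.
- **Classification** — identified peptides are mapped back onto the windows
  and split into canonical (PC), circRNA-BSJ (≥1 residue on the junction)
  and circRNA-not-BSJ; exact-substring screening against a proteome
  reassigns anything canonical; bracketed BSJ-context strings
  (`UP- > pre[BSJ]suf < -DOWN`) document each junction hit.
- **Annotation** — HLA binder calls from precomputed %rank tables
  (binder ⇔ %rank < 2, best allele = argmin), HLA-I/II length windows
  (8–15 / 9–25 aa), and a tumor-specificity rule on host-gene TPM
  percentiles (≥ 2.5 TPM at the 99th percentile in some tumor cohort, ≤ 1
  TPM at the 90th percentile in every non-excluded normal tissue).

A seed-deterministic simulator (synthetic circRNAs with optionally planted
junction-spanning ORFs; two-engine PSM scores with ground truth) and a
brute-force unrolled-circle oracle make the whole pipeline testable offline.

## Worked example

```python
from circbsj import CircRNARecord, build_reference
from circbsj.classify import classify_peptides

# 79-nt circRNA; the junction is the wrap point between sequence end and start
S = ("GA" "GTTTTCGAAGTTTACCACACCACTGTTCTGAAGATTCAACGTTAA"
     "CCCCCCCCCC" "TAG" "ATGGCTACCAAGAAAGCT" "A")
circ = CircRNARecord("hsa_circ_demo", S)

for w in build_reference([circ]):
    print(w.window_id, "len", len(w.aa_seq), "bsj", w.bsj_span, "inf", w.infinite)
    print("   ", w.aa_seq)

for c in classify_peptides(["RVFEVYHTTVLK", "EVYHTTVLK"], build_reference([circ])):
    print(c.sequence, c.group.value, "BSJ-overlap:", c.bsj_overlap, "n:", c.n_bsj_residues)
    for _, _, _, ctx in c.matches:
        if ctx:
            print("   ", ctx)
```

prints

```
hsa_circ_demo_1 len 21 bsj (7, 7) inf False
    MATKKARVFEVYHTTVLKIQR
RVFEVYHTTVLK CIRC BSJ-overlap: True n: 1
    MATKKA- > [R]VFEVYHTTVLK < -IQR
EVYHTTVLK CIRC BSJ-overlap: False n: 0
```

One trimmed window was found (id suffix `_1`: the junction falls inside a
codon, so a single residue — the R at window position 7 — is encoded across
the junction).  The 12-mer that includes that R is a circRNA-BSJ peptide and
gets its bracketed context; its shorter version misses the junction and is
circRNA-not-BSJ, i.e. it could equally derive from out-of-frame translation
of the linear transcript.

The same steps are available from the shell:

```bash
circbsj build-ref --circ-fasta circs.fa --out windows.fa --report report.tsv
circbsj concat-ref --windows windows.fa --proteome uniprot.fa --out search.fa
circbsj fdr --psms-a a.tsv --psms-b b.tsv --alpha 0.03 --out retained.tsv
circbsj classify --windows windows.fa --proteome uniprot.fa \
    --peptides retained.tsv --mode hla1 --ranks ranks.tsv --out classified.tsv
circbsj run-all --circ-fasta circs.fa --proteome uniprot.fa \
    --psms-a a.tsv --psms-b b.tsv --out-dir results/
```

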