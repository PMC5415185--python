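# Methods

## The classification model

taxomap assigns metagenomic reads to reference sequences from externally
produced alignments and reports which taxonomic clades are confidently
present.  The procedure has four stages.

**1. Alignment filtering.**  Candidate records are selected with the
standard samtools flag masks: paired data keeps non-secondary, properly
paired records (`-F 256 -f 2`); single-end data keeps mapped, non-secondary
records (`-F 260`).  Supplementary alignments (0x800) are dropped as well by
default, since split hits are shorter partial matches of the same read; the
bare mask semantics remain available (`drop_supplementary=False`).  Each
surviving record must then meet two inclusive thresholds:

- **MAS** (minimum alignment score, default 30) on the aligner-reported
  AS-tag score, and
- **FMM** (minimum matched fraction, default 0.8): the fraction of the
  *full* read length — clipped bases included in the denominator — covered
  by CIGAR `M`/`=`/`X` operations.

In paired mode a fragment is kept only if both mates pass; one failing mate
removes the pair.

**2. Best-hit resolution.**  A fragment's score against a reference is the
sum of its mates' alignment scores (SAS).  Databases are declared in either
*bestmode* or *fullmode*.  Across all bestmode databases a fragment receives
exactly one assignment: the highest-SAS reference, ties broken first by
database priority (the order the user listed them), then by position in the
alignment file — arbitrary but deterministic, mirroring aligner behaviour.
Each fullmode database is resolved independently, so a read can be assigned
both a genome (bestmode) and, say, a resistance gene (fullmode) that is a
subsequence of that genome.  A fragment is *uniquely mapped* when its chosen
SAS strictly exceeds the SAS of every other reference in the resolution
scope; a tie genuinely leaves the origin ambiguous, so ties are not unique.

**3. Per-reference statistics.**  For each reference with ≥ 1 assignment a
14-column record is computed.  ReadCount counts mates individually (a pair
contributes 2); this is what makes the paired abundance formula coherent:

- `S_Abundance = 100 · ReadCount / Size` (single-end),
  `100 · ReadCount / (2 · Size)` (paired) — the size normalization removes
  the bias that large genomes accumulate more reads at equal copy number;
- `R_Abundance(%) = 100 · ReadCount / total_clean_reads`, where the
  denominator is the cleaned (trimmed, control-free) read count supplied by
  the user and set to 100 %;
- Nucleotides counts aligned bases (`M`/`=`/`X`) only — insertions exist in
  the read but not on the reference; Covered positions is the union of the
  resulting reference intervals (deletions advance the reference without
  contributing), computed by interval merging and verified against a
  per-position tally oracle in tests;
- Depth = Nucleotides/Size, Coverage = Covered/Size, Mismatches = summed
  NM edit distance.

**4. Clade collapsing and post-processing.**  Statistics are summed over
references sharing a taxid at each requested rank (strain, species, genus,
family, order, class, phylum, superkingdom); references lacking a taxid are
grouped by the rank's name, then under "unclassified", so read conservation
holds.  Coverage and Depth are summed like every other identifier (an
aggregate coverage can exceed 1); recomputed ratios
(sum covered / sum size, sum nucleotides / sum size) are emitted alongside,
explicitly labelled.  Four criteria then separate confident annotations from
likely false positives:

| criterion | test | default |
|---|---|---|
| I | ReadCount ≥ threshold (inclusive: "minimum of 10") | 10 |
| II | Mismatches/Nucleotides < threshold (strict) | 0.01 |
| III | S_Abundance > threshold (strict) | 0.01 |
| IV | ReadCount uniq / ReadCount > threshold (strict) | 0.005 |

Strain level imposes all four.  Species level runs a two-pass procedure:
pass 1 selects species passing all four criteria and takes T = the minimum
S_Abundance among them (falling back to the configured criterion-III floor
when nothing is selected — accepting everything would invert the filter's
purpose); pass 2 accepts species meeting I, II and S_Abundance ≥ T, with IV
dropped.  The comparison with T is inclusive because T is itself the
abundance of an accepted species.  Genus level and above use I–III only.
Both accepted and rejected sets are reported, the latter with the violated
criteria, so thresholds can be re-tuned from saved tables without
re-mapping (the `postprocess` subcommand).

The pre-cycle wording admits a second reading (selection on IV alone); that
would let a single high-uniqueness, low-abundance row drag T arbitrarily
low, so the all-criteria reading is the default and the alternative is
exposed as `CriteriaConfig(precycle_all_criteria=False)`.

## Synthetic communities

The `synthetic` module generates complete inputs (reference FASTA, taxonomy
TSV, one SAM per database, sample context) from a declarative community
spec, together with a closed-form truth table computed from the spec's
arithmetic alone — fragment counts, mismatch schedules, genome sizes — and
never from the pipeline, so end-to-end tests compare two independent routes.

Reads are placed uniformly on their genome with an exact scheduled number of
substitutions per mate (positions uniform within the read); alignment scores
are synthesized as `read_length − 5·mismatches`.  Only the relative order of
scores matters to the method, so any monotone scoring emulates an aligner
adequately.  Multi-mapping is emulated by emitting an equal-score alignment
of the same fragment onto a decoy reference in a lower-priority database:
the planted reference keeps the assignment via the priority tie-break while
the fragment loses uniqueness.

Two stock designs are provided:

- `default_community`: eight species (two with two strains each, ten strains
  total, ~4.5k reads) plus four contaminants engineered to violate exactly
  one criterion each — ReadCount 9, mismatch ratio 0.015, S_Abundance 0.009,
  unique fraction 0.004.  It is generated single-end so that odd read counts
  are realizable (paired mate counting is always even).  Genome sizes sit in
  the 10–200 kb range: abundances only depend on the read-count/size ratio,
  so scaled-down genomes preserve every margin while keeping generation and
  classification fast (the whole fixture runs in well under a second).
- `paired_community`: a small paired-end sample with a genome database, a
  decoy database and a fullmode gene database whose reference receives hits
  independently of the bestmode assignment.

What the generator does **not** emulate: indels and clipping in reads (all
CIGARs are full-length matches; the CIGAR arithmetic is instead covered
directly by unit and property tests), positional coverage bias, quality
scores, chimeric fragments, improper pairs, and real sequence homology —
decoy "multi-mapping" is declared, not discovered by an aligner.  Passing
the planted-recovery test therefore shows the bookkeeping and criteria are
exact, not that the method separates real species from relatives whose
genomes share sequence.

## Numerical choices

- Threshold comparisons follow the printed wording: criterion I inclusive,
  II–IV strict; MAS/FMM inclusive ("minimum").
- A mismatch ratio with zero nucleotides is 0 when there are no mismatches,
  otherwise the row fails criterion II.
- Clade collapsing sorts group members canonically (by reference name)
  before summing so float sums are independent of input order; output rows
  sort by descending S_Abundance with a name tie-break, making every output
  file byte-stable.
- Reals are written with 6 significant digits; round-tripping a table
  preserves all integer fields exactly and reals to print precision.
- Missing AS/NM tags, absent CIGARs, or unrecoverable read lengths reject
  the record into a per-reason diagnostics tally rather than aborting the
  run; paired fragments with a mate count other than 2 on a reference are
  tallied as improper.

## Limitations

- Assignment is per-reference, not lowest-common-ancestor: reads from a
  genome region shared by two references in the database are attributed by
  tie-break, and only the uniqueness statistic exposes the ambiguity.
- The cleaned-read denominator for R_Abundance is taken on trust from the
  caller; trimming and control-read removal are outside this package.
- The taxdump converter keeps only the eight standard ranks; intermediate
  ranks (subspecies, species group, ...) are skipped.
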