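# Methods

## The molecular model

A coligo is a circularized synthetic single-stranded DNA oligonucleotide
used as a promoter-less RNA polymerase III transcription template. It
contains only the template strand; positions are 1-based on the written
5′→3′ sequence and all arithmetic is modular. Because the polymerase reads
its template 3′→5′, a transcript's 5′→3′ sequence corresponds to walking
the written strand in **descending** index order: `start_pos` is the
template position pairing with the transcript's first base, `stop_pos` the
position pairing with its last, and the monomer length is
`(start − stop) mod L + 1`. Failure to terminate on a lap adds a whole
template length per extra lap (circumtranscription multimers). Start and
stop sites are sampled independently — an explicit modeling assumption,
which the analysis itself can interrogate (the mutual information between
mapped start and stop bins on simulated data is ~0).

The library preparation is simulated step by step in sense-strand DNA
space (transcript U written as T):

1. **3′-adapter ligation.** The 22-nt adapter (a 5′ dC plus the 21-mer
   core `AGATCGGAAGAGCACACGTCT`) is appended with probability
   `adapter3_ligation_efficiency`. The adapter must carry a 3′ amino
   blocker. Transcripts carry a 5′ triphosphate, which precludes
   self-ligation; in the 5′-monophosphate + ATP chemistry, self-circle and
   multimer side reactions compete first at absolute rates
   (`side_reaction_rates`), and in the pre-adenylylated-adapter (no ATP)
   chemistry they are forced to zero.
2. **Reverse transcription.** The RT primer's 3′-terminal segment must be
   the reverse complement of the chimera's 3′ end (validated by suffix
   matching, minimum 12 nt — a failed match models failed priming). The
   cDNA is the full primer followed by the complement of the remaining
   template; the primer's single ribonucleotide position is carried as an
   index. For the 47-nt primer the cDNA is `48 + L` nt; for the 43-nt
   primer whose 3′ 17-mer covers the entire 17-nt adapter it is `43 + L`,
   which for an 83-nt transcript composes to the expected 126-bp amplicon.
3. **Circularization / re-linearization.** With probability
   `circularization_efficiency` (default 0.9, the ligase's characteristic
   intramolecular yield) the cDNA circularizes; RNase A then cuts 3′ of the
   ribonucleotide, producing the rotation that begins at `ribo_index + 1`
   and ends with the retained ribo base (2′,3′-cyclic phosphate). Because
   both PCR primers span the cut, the amplicon regenerates the full circle
   and the retained base never appears truncated in reads. Uncircularized
   molecules are also cut, into two unamplifiable fragments, and are
   dropped.
4. **Sequencing.** Read1 is the reverse complement of the re-linearized
   molecule starting after the 26 bases covered by the sequencing primer
   (the riboC complement plus the 25-nt forward primer site), continuing
   into the reverse complement of the PCR reverse-primer tail when the
   insert is shorter than the read, then padded. For an error-free
   monomer this composes to `transcript_DNA + "C" + adapter core + tail`.
   Defaults: 110 cycles; per-base Phred from a normal with linear mean
   decay (mean 36, 0.05/cycle, SD 4, clipped to [2, 40]) — deliberately
   simple, since the analysis only thresholds at a per-base minimum;
   substitution errors i.i.d. per base at `substitution_error_rate`; the
   rare non-templated first transcript base is modeled as a read-level
   substitution of the first base at `nontemplated_first_base_rate`
   (mechanism-agnostic, matching what is observable).

The randomized-junction bias substrate is the packaged 61-nt LBprimer:
seven hand-mixed N positions on each side of the eventual junction (5′
acceptor block N7a, 3′ donor block N7b), divergent PCR sites separated by
one riboC. A molecule is accepted for circularization with probability
proportional to `bias_model[(donor, acceptor)]` — donor = last base of
N7b (3′-OH side), acceptor = first base of N7a (5′-p side). Composing
circularization, re-linearization and sense-strand sequencing places
`revcomp(N7a)` at read bases 1–7, `revcomp(N7b)` at 8–14 and the adapter
anchor at 15–35; the analysis inverts exactly this mapping.

## Analysis parameters

| parameter | default | rationale |
|---|---|---|
| adapter anchor | 21-mer core, first 12 bases, ≤ 1 mismatch | deterministic leftmost-match trimming; adequate for short known layouts |
| size selection | 60–71 nt (inclusive), after dC strip | the monomer transcript range of the 82-nt template |
| end k-mer | k = 20 | long enough to be unique on an ≤ 89-nt circle, short enough to dodge mid-read errors |
| quality filter | every base Phred ≥ 20 | per-base rule; raising it can only shrink the retained set |
| report threshold | 1.0 % of the reference total | sites below it are summed into an excluded-mass figure |
| top reads | 10 | whole-insert collapsed reads with summed coverage |
| uniform junction null | 6.25 % = 100/16 | analytic |

Percentages are computed against the quality-filtered reference totals
(the 5′ and 3′ sides have their own denominators); raw counts ride along
so any other denominator can be recomputed. Collapsed tables sort by count
descending with lexicographic tie-break. 5′ mapping demands exact identity
at k-mer positions 2..k and classifies a position-1 mismatch as
non-templated with the observed base; 3′ mapping is exact over all k.
Multi-position matches are reported as ambiguous/unmapped rather than
assigned. Exact-match mapping drops reads whose k-mer carries a
substitution error (~1.9 % at the 0.1 % error rate) uniformly across
sites, so site *percentages of the reference total* are uniformly deflated
by that factor while the *normalized* site distribution is unbiased; the
parameter-recovery check therefore normalizes over mapped mass.

The chi-square uniformity test (Pearson goodness-of-fit, df = categories −
1) is an addition on top of the descriptive percentage tables, kept
separate from them in the report. Its type-I error is calibrated (5 % ± 2 %
over 1,000 uniform replicates at n = 10,000) and a 2-fold
single-dinucleotide bias is detected with power > 0.95 at the 70,000-read
scale.

## What the simulator does and does not emulate

Emulated: the complete strand bookkeeping of every step (base conservation
is testable end to end), efficiency losses as independent Bernoulli
events, circumtranscription multimers, ligation side products, per-base
quality decay, uniform substitution errors, the non-templated first base,
and a truth channel in every read id that makes any downstream percentage
exactly recomputable.

Not emulated: ligation/circularization efficiency as a function of RNA
secondary structure (per-species 5′-ligation efficiencies in the protocol
comparison are user-supplied, never predicted), PCR amplification bias and
duplicates, paired-end reads, instrument-specific error profiles, and
sequence-dependent quality artifacts. Passing tests therefore demonstrate
correctness of the analysis pipeline and of the protocol's structural
logic — not that real libraries are free of those unmodeled effects.

## Numerical and design choices

- One seeded generator (`numpy.random.default_rng`) per simulation call;
  a fixed seed makes FASTQ/TSV/JSON outputs byte-identical across runs.
- Probability distributions must sum to 1 within 1e-9; positions are
  validated against template length.
- Oligo notation is NFC-normalized and both apostrophe forms accepted;
  stray single characters in a printed sequence body are skipped with a
  logged warning (the packaged catalog contains one such typographic
  artifact), while unknown multi-character tokens are hard errors naming
  the offset. Two house tokens (`ppp`, `-cP`) make render∘parse total over
  the 5′/3′ end-state enums.
- The read-length histogram is taken after adapter trimming and before dC
  stripping. Multimer transcripts longer than the read never show the
  adapter and drop at the trimming stage, which is the physically correct
  fate for a 110-cycle read.
- Reporting orientation for the bias analysis is the original substrate
  orientation (donor −7..−1, acceptor +1..+7; junction written donor →
  acceptor 5′→3′ across the seal), with the read-space mapping documented
  above.

## Problem sizes

The analysis drivers use 20,000 transcripts (end mapping) and 70,000
junction molecules (bias), the latter matching the scale of the real
experiment's accepted-read count; the verification suite uses 100,000
molecules for frequency-recovery checks, 1,000 replicates for test
calibration, and exhaustive enumeration (every template rotation, all 16
junctions) for the oracle-equivalence checks.

## Known limitations

- The adapter trimmer tolerates one mismatch in a 12-base anchor probe and
  no indels; indel-containing reads are counted as adapter-less.
- End mapping is exact-match (position 1 aside): at high substitution
  rates the unmapped mass grows and only the normalized site distribution
  remains unbiased.
- The quality model is a truncated normal with linear decay; it reproduces
  threshold behavior, not real quality-score correlation structure.
- The non-templated first-base model is site-agnostic, whereas the real
  phenomenon was observed at one initiation site; only the rate, not the
  mechanism, is representable.
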