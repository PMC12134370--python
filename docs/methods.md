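# Methods

## Coordinate model

Reference coordinates are 0-based and half-open throughout; nick coordinates
are between-base integers (nick *k* lies between reference indices *k−1* and
*k*). A SpacerSite records the protospacer interval by its lowest reference
index regardless of strand. SpCas9 is assumed to cut bluntly 3 bp 5′ of the
PAM — HNH and RuvC at the same duplex position — which is the canonical
SpCas9 geometry; the nick-offset logic is therefore SpCas9-specific even
though the PAM pattern is configurable (non-NGG nickases are out of scope).

Editing positions are labelled from the nick: 0 is the nick itself, +*k* the
*k*-th base along the edited strand in the editing direction. For a + strand
site with protospacer at `[p, p+20)` the nick is `p+17`; the **reverse**
window runs `+1, +2, …` through reference indices `p+16, p+15, …`
(protospacer positions 17..1 and on into the upstream flank), and the
**canonical** window runs through `p+17, p+18, …` (positions 18–20, PAM,
downstream). The two windows are disjoint by construction. Labels continue
uninterrupted past the protospacer 5′ boundary; windows are truncated with a
warning at the reference edge.

## rpegRNA construction

A guide is `5′-spacer-scaffold-RTT-PBS[-linker-motif]-3′`. For a reverse
design:

* **PBS** — the reverse complement of the targeted-strand primer's
  3′-terminal `L_PBS` bases, which equals the non-targeted-strand sequence
  of the `L_PBS` reference positions on the PAM side of the nick, as RNA.
* **RTT** — the edited non-targeted-strand sequence of the `L_RTT`
  edited-coordinate positions on the PAM-distal side of the nick, as RNA.
  `L_RTT` counts RTT nucleotides; for insertions/deletions the covered
  reference span is `L_RTT − (len(alt) − len(ref))`.

This yields the extension identity asserted on every assembled design: for
substitutions, `RTT+PBS` equals the edited non-targeted-strand window
`[nick − span_RTT, nick + L_PBS)` transcribed to RNA. Canonical comparison
designs are the mirror image (extension = reverse complement of the edited
window `[nick − L_PBS, nick + span_RTT)`). Assembly always re-validates by
rebuilding the edited amplicon from (reference, flap) and comparing with the
EditSpec applied directly; a mismatch is a fatal internal error, never a
warning.

Defaults, all configurable through `RunConfig`:

| parameter | default | rationale |
| --- | --- | --- |
| PBS length range | 10–16 nt | the range efficient rPE designs used; the narrower 10–15 report is reachable by flag |
| RTT length range | 10–16 nt | as above |
| GC bounds | 40–60 %, PBS and RTT independently | standard design guidance; GC = (G+C)/len×100, no ambiguity codes |
| post-edit homology | 5 nt | minimum distal annealing arm beyond the edit; no published requirement exists, 5 nt is a conservative common choice |
| scaffold | standard SpCas9 sgRNA scaffold | configuration data, not printed by the design rules themselves |
| 3′ motif | trimmed evopreQ1 pseudoknot + 4-nt linker | the widely used pegRNA 3′-protection motif; both sequences are config entries |
| 5′-G prepending | off | affects cloning oligos only, never the genomic spacer match |

Design enumeration emits one row per (L_PBS, L_RTT) pair (49 rows for the
default 7×7 grid); GC-out-of-bounds rows are flagged rather than dropped,
and ranking puts GC-pass rows first, then ascending `|pbs_gc−50| +
|rtt_gc−50|`, ties by smaller L_PBS then L_RTT (stable sort, so output is
deterministic).

The split-circular representation is a declared simplification: part 1 is
the spacer+scaffold guide, part 2 a cassette holding RTT+PBS between
user-configured ligation/ribozyme elements, because the exact split point
of published circular rpegRNAs is not specified at sequence level. With no
elements configured the cassette is the bare extension (warned).

## Nicking guides

An rPE3 ngRNA must direct Cas9-D10A to the strand the rpegRNA does **not**
edit, so candidates live on the protospacer strand opposite the primary
site. `nick_offset` is signed, positive meaning the ngRNA nick sits at a
larger reference coordinate than the rpegRNA nick; this sign convention is
ours (published figures print magnitudes like "+41" without defining the
sign) and is declared in output headers. Default offset bounds are
20 ≤ |offset| ≤ 120, typical PE3 practice.

rPE3b candidates are enumerated on the *edited* sequence;
`post_edit_only` is set when the candidate's protospacer+PAM 23-mer
mismatches the pre-edit sequence in at least one spacer base or its PAM is
broken pre-edit — i.e. the nick can only occur after flap resolution.
`suggest_pam_insertion` searches the RTT-coverable window (on the edited
sequence, so PAM bases contributed by the primary edit itself count) for
placements where at most `max_extra_subs` additional substitutions complete
an opposite-strand PAM, returning the extra edits, a combined EditSpec
(expressed as a single multi-base substitution when the primary edit is a
substitution; `None` for indel primaries, where the extra substitutions are
returned as a separate list) and the enabled candidate, ranked by fewest
extra substitutions.

Off-target scanning is an exhaustive both-strand Hamming scan (no bulges),
matching the basic mode of the usual candidate-site finders; mismatch
positions are reported 1-based from the PAM-distal end.

## Quantification

Reads are globally aligned to the wild-type amplicon under an affine-gap
model (defaults match +2, mismatch −3, gap open −5, gap extend −2; a
length-k gap scores `open + (k−1)·extend`). These scores are our declared
defaults, stated in every output header. The aligner is Biopython's
`PairwiseAligner`; among co-optimal alignments the library's deterministic
first alignment is used. Both the read and its reverse complement are
aligned and the higher score kept (ties go forward). For equal-length pairs
a provable shortcut skips the DP: any gapped alignment of equal-length
sequences scores at most `(L−1)·match + 2·gap_open`, so when the gapless
score exceeds that bound the gapless alignment is optimal; this settles
both the alignment and the orientation choice for the vast majority of
substitution-only reads without changing any result.

Classification (defaults; window = full amplicon because the defining
formulas are unqualified, a CRISPResso2-style flank is available):

1. **indel** — any gap column overlapping the window; indels take
   precedence over the desired edit.
2. **desired_no_indel** — no qualifying indel and every edited position
   carries the alt allele (stray substitutions elsewhere are tolerated).
3. **unedited** — reference alleles at all edited positions, no indel.
4. **other_substitution** — everything else.

For insertion/deletion EditSpecs the desired outcome is itself a gap
against the wild-type amplicon, so the classifier additionally aligns
against the edited amplicon and recognises the desired outcome there
first; the programmed edit is never counted as an indel. Reads shorter than
50 % of the amplicon are excluded and counted separately. Efficiency and
indel percentages recompute exactly from the category counts, which always
partition the total.

Flap conversion places the design's 3′ DNA flap (reverse complement of the
RTT) at its best ungapped position on the off-target amplicon, in either
orientation, ties resolved toward the forward orientation and the leftmost
offset. Positions where flap and amplicon differ are informative; a read is
converted when all informative positions carry the flap allele (strict
mode, default) or at least one does (loose). No informative position is an
error, not a zero.

## Simulators

`synthdata` emulates a 200–300 bp amplicon-seq editing experiment: class
counts (edited / indel byproduct / wild-type) follow the largest-remainder
rule so stated fractions are met exactly at error 0; indel byproducts are
random 1–5 nt insertions or deletions within ±10 nt of the nick, mimicking
nuclease lesions; sequencing noise is i.i.d. per-base substitution at a
stated rate. Base qualities are uniform Q30 since nothing downstream
consumes them. Deliberately absent: quality-dependent error profiles, PCR
chimeras, adapter read-through, paired-end structure. Passing tests
therefore demonstrate correctness of the classification arithmetic and
estimator recovery under substitution noise, not robustness to real
library artifacts.

Problem sizes in the test suite and acceptance script (120 design
problems, 10 000-read libraries, a 100 kb off-target subject, 1000-variant
selection tables) were chosen as the smallest sizes at which the binomial
noise bands quoted in the tests are meaningful.

## Variant selection

Round 1 inner-joins the per-model score tables on (pos, wt, mut), ranks
within each model (higher score = rank 1, ties share the minimum rank) and
keeps `ceil(fraction·N)` variants by mean rank (`rank_mean`, default) or
the union of per-model top fractions (`union`). How published screens
combined their three models is not stated at this level of detail, so both
modes are provided and the mode used is recorded in output metadata;
neither is claimed as canonical. Round 2 passes a variant when the PSSM
scores the mutant residue strictly higher than the wild-type residue at
that position ("baseline" = the wild-type residue's own score) and the
positional information value strictly exceeds 0.1. Candidates at positions
missing from the PSSM are excluded as unevaluable and logged, never
silently passed. Raising `info_min` can only shrink the passed set;
raising `fraction` can only grow round 1 — both monotonicities are tested.

## Determinism and reproducibility

Every generator and every CLI subcommand is a pure function of (inputs,
RunConfig, seed). The configuration — scaffold/motif/linker sequences,
overhangs, alignment scores, design bounds — serializes to a canonical JSON
whose SHA-256 prefix is embedded in every TSV/JSON output header, so
byte-identical reruns are guaranteed and checked by test.

## Known limitations

* SpCas9/NGG nick geometry only; no bulge-tolerant off-target search and no
  CFD/MIT-style off-target scoring.
* No thermodynamic or learned efficiency prediction — enumeration ranks by
  GC proximity to 50 %, not by predicted editing rate.
* The circular-cassette layout and the PSSM information values for
  POSSUM-style inputs must be supplied by the user where their sources do
  not provide them.
* No wrapping of external pipelines (CRISPResso2, Cas-OFFinder); the
  corresponding computations are re-implemented natively and validated
  against independent oracles instead.
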