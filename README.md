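# rpekit

Design and quantification toolkit for **reverse prime editing (rPE)**.

Canonical prime editors pair SpCas9-H840A with a reverse transcriptase: RuvC
nicks the non-targeted strand and the pegRNA's 3′ extension (RTT then PBS)
writes edits downstream of the nick, across protospacer positions 18–20, the
PAM and beyond. Reverse prime editing flips this geometry: SpCas9-D10A nicks
the **targeted** strand through HNH, and the reverse pegRNA (rpegRNA) is
designed against the targeted strand, its PBS annealing on the PAM side of
the nick. The new DNA flap then grows in the opposite direction, so the
editable window shifts to protospacer positions 17..1 and the upstream
flank — sequence that canonical editors reach poorly.

`rpekit` covers the dry-lab work around such editors:

| module | what it does |
| --- | --- |
| `rpekit.geometry` | SpCas9 site enumeration (NGG), blunt-nick coordinates, reverse vs canonical editing windows |
| `rpekit.design` | rpegRNA / comparison-pegRNA assembly, PBS/RTT enumeration with GC filters, erpegRNA 3′ motifs, split-circular cassettes, Golden-Gate oligos |
| `rpekit.nicking` | rPE3 ngRNA candidates, rPE3b post-edit-only nicking with PAM insertion, mismatch-tolerant off-target scanning |
| `rpekit.quantify` | affine-gap read alignment, editing-efficiency / indel statistics, per-position nucleotide tables, off-target flap-conversion rates |
| `rpekit.synthdata` | seeded simulators for loci, amplicon libraries and off-target reads |
| `rpekit.plm` | two-round protein-variant selection: ensemble top-10 % of language-model scores, then PSSM filtering |

## The statistics at the core

For an amplicon read set aligned to the wild-type reference:

```
editing efficiency (%) = 100 × #(reads with the desired edit and no indel) / #reads
indel frequency (%)    = 100 × #(reads containing an indel)               / #reads
```

An indel anywhere in the quantification window (default: the whole amplicon)
takes precedence over the desired edit. At candidate off-target loci the
**flap conversion** rate is the fraction of reads carrying, at every position
where the designed 3′ DNA flap differs from the off-target amplicon, the
flap's allele.

Design constraints follow common rPE practice: PBS and RTT lengths 10–16 nt,
GC content 40–60 % for each, and a configurable post-edit homology arm
(default 5 nt) beyond the edited bases.

## Worked example

```python
from rpekit import (EditSpec, find_spacer_sites, assemble_rpegrna,
                    quantify_amplicon)
from rpekit.synthdata import SimTruth, random_locus, simulate_reads

locus = random_locus(7, 200, ensure_site=True, name="demo_amplicon")
site = next(s for s in find_spacer_sites(locus)
            if s.strand == "+" and s.proto_start == locus.planted_proto_start)

pos = site.nick - 4                         # reverse-window position +4
edit = EditSpec.substitution(pos, locus.seq[pos], "A")
design = assemble_rpegrna(site, edit, L_PBS=13, L_RTT=14)
print("PBS:", design.pbs_rna, "RTT:", design.rtt_rna)
print("flap:", design.flap_dna)

truth = SimTruth(seed=11, amplicon=locus.seq, edit=edit, frac_edited=0.25,
                 frac_indel=0.05, error_rate=0.002, n_reads=2000,
                 nick=site.nick)
res = quantify_amplicon(simulate_reads(truth), locus.seq, edit)
print(f"efficiency {res.efficiency_pct:.2f}%  indel {res.indel_pct:.2f}%")
```

prints

```
PBS: GCGUGGUAUUACU RTT: GCUACAAUGCAUCG
flap: CGATGCATTGTAGC
efficiency 25.05%  indel 5.00%
```

The PBS is the 13 reference bases on the PAM side of the nick (as RNA); the
RTT templates a 14-nt targeted-strand flap carrying the G→A substitution
4 nt upstream of the nick; the recovered efficiency and indel rate match the
simulated 25 % / 5 % ground truth to within sequencing-error noise (every
assembled design is additionally re-validated by reconstructing the edited
amplicon from its flap).

The same operations are available from the shell:

```bash
rpekit design ref.fasta --edit sub:104:G>A          # PBS/RTT design table
rpekit ngrna ref.fasta --edit sub:104:G>A --proto-start 90 --strand +
rpekit offtarget-scan subject.fasta --spacer ATCGCTACAATGCGTCGGCG --max-mismatch 3
rpekit simulate --amplicon ref.fasta --edit sub:104:G>A --n-reads 1000
rpekit quantify sim.fastq --amplicon ref.fasta --edit sub:104:G>A
rpekit plm-filter --scores esm1v=scores.tsv --pssm pssm.tsv
```

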