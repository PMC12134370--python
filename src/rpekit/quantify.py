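"""Amplicon-read classification and editing-outcome statistics.

Reads are globally aligned to the wild-type amplicon (affine gap model,
both orientations, higher score kept) and classified into four categories:

* ``desired_no_indel`` -- every edited position carries the alt allele and no
  qualifying indel is present,
* ``indel`` -- any insertion/deletion within the quantification window
  (default: the whole amplicon); an indel takes precedence over the edit,
* ``unedited`` -- reference alleles at all edited positions, no indel,
* ``other_substitution`` -- anything else.

Editing efficiency is ``100 * desired_no_indel / total`` and indel frequency
``100 * indel / total``.  For insertion/deletion edits the desired outcome is
itself a gap against the wild-type amplicon, so the classifier additionally
aligns against the edited amplicon to recognise it (two-reference logic, as
amplicon-seq pipelines do); the programmed edit never counts as an indel.

The off-target metric is *flap conversion*: the designed 3' DNA flap is
placed against the off-target amplicon, and a read is "converted" when it
carries the flap allele at every position where flap and amplicon differ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from ._seq import revcomp
from .config import DEFAULT_CONFIG, RunConfig
from .geometry import EditSpec

logger = logging.getLogger(__name__)

LABELS = ("desired_no_indel", "indel", "unedited", "other_substitution")


@dataclass(frozen=True)
class AlignmentResult:
    """A global read-vs-amplicon alignment as gapped strings plus score."""

    read: str
    amplicon: str
    aligned_read: str
    aligned_amplicon: str
    score: float

    @property
    def ops(self) -> str:
        """Per-column operations: M(match) X(mismatch) I(read ins) D(read del)."""
        out = []
        for r, a in zip(self.aligned_read, self.aligned_amplicon):
            if a == "-":
                out.append("I")
            elif r == "-":
                out.append("D")
            else:
                out.append("M" if r == a else "X")
        return "".join(out)


@dataclass
class QuantResult:
    n_total: int
    n_desired_no_indel: int
    n_indel: int
    n_unedited: int
    n_other_substitution: int
    n_excluded_short: int = 0

    @property
    def efficiency_pct(self) -> float:
        return 100.0 * self.n_desired_no_indel / self.n_total

    @property
    def indel_pct(self) -> float:
        return 100.0 * self.n_indel / self.n_total

    def as_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_desired_no_indel": self.n_desired_no_indel,
            "n_indel": self.n_indel,
            "n_unedited": self.n_unedited,
            "n_other_substitution": self.n_other_substitution,
            "n_excluded_short": self.n_excluded_short,
            "efficiency_pct": self.efficiency_pct,
            "indel_pct": self.indel_pct,
        }


@dataclass
class FlapConversionResult:
    table: pd.DataFrame
    flap_positions: list[int]
    informative_positions: list[int]
    n_reads: int
    n_converted: int

    @property
    def conversion_pct(self) -> float:
        return 100.0 * self.n_converted / self.n_reads


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def _make_aligner(match: int, mismatch: int, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def global_align(
    read: str,
    amplicon: str,
    match: int = DEFAULT_CONFIG.match,
    mismatch: int = DEFAULT_CONFIG.mismatch,
    gap_open: int = DEFAULT_CONFIG.gap_open,
    gap_extend: int = DEFAULT_CONFIG.gap_extend,
) -> AlignmentResult:
    """Optimal global alignment under the affine-gap model.

    A length-k gap scores ``gap_open + (k-1)*gap_extend``.  Among co-optimal
    alignments a fixed deterministic one is returned.
    """
    if not read or not amplicon:
        raise ValueError("sequences must be non-empty")
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    aln = aligner.align(amplicon, read)[0]
    return AlignmentResult(
        read=read,
        amplicon=amplicon,
        aligned_read=str(aln[1]),
        aligned_amplicon=str(aln[0]),
        score=float(aln.score),
    )


def _gapless_score(read: str, amplicon: str, match: int, mismatch: int) -> tuple[int, int]:
    h = sum(1 for a, b in zip(read, amplicon) if a != b)
    return len(read) * match - h * (match - mismatch), h


def _align_fast(read: str, amplicon: str, cfg: RunConfig) -> AlignmentResult:
    """global_align with a provable gapless shortcut for equal-length pairs.

    Any alignment of equal-length sequences containing a gap has at least one
    insertion and one deletion segment, so its score is bounded by
    ``(L-1)*match + 2*gap_open``; when the gapless score beats that bound the
    gapless alignment is optimal and the DP can be skipped.
    """
    if len(read) == len(amplicon):
        s0, _ = _gapless_score(read, amplicon, cfg.match, cfg.mismatch)
        if s0 > (len(read) - 1) * cfg.match + 2 * cfg.gap_open:
            return AlignmentResult(read, amplicon, read, amplicon, float(s0))
    return global_align(read, amplicon, cfg.match, cfg.mismatch, cfg.gap_open, cfg.gap_extend)


def align_oriented(read: str, amplicon: str, cfg: RunConfig = DEFAULT_CONFIG) -> AlignmentResult:
    """Align read and its reverse complement; keep the higher score (tie: forward).

    For equal-length pairs the same bound as in :func:`_align_fast` also
    settles the orientation choice without running the DP: an orientation
    whose gapless score beats both the gapped bound and the other
    orientation's score ceiling is optimal overall.
    """
    rc = revcomp(read)
    if len(read) == len(amplicon):
        L = len(read)
        b_gap = (L - 1) * cfg.match + 2 * cfg.gap_open
        s_f, _ = _gapless_score(read, amplicon, cfg.match, cfg.mismatch)
        s_r, _ = _gapless_score(rc, amplicon, cfg.match, cfg.mismatch)
        if s_f > b_gap and s_f >= max(s_r, b_gap):
            return AlignmentResult(read, amplicon, read, amplicon, float(s_f))
        if s_r > b_gap and s_r > max(s_f, b_gap):
            return AlignmentResult(rc, amplicon, rc, amplicon, float(s_r))
    fwd = _align_fast(read, amplicon, cfg)
    rev = _align_fast(rc, amplicon, cfg)
    return fwd if fwd.score >= rev.score else rev


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _column_map(aln: AlignmentResult):
    """Yield (ref_pos_or_None, read_char_or_'-') events.

    Deletion columns give (ref_pos, '-'); insertion columns give
    (None, base) and are recorded separately with the between-base reference
    coordinate where they occur.
    """
    ref_bases: dict[int, str] = {}
    insertions: list[int] = []
    pos = 0
    for r, a in zip(aln.aligned_read, aln.aligned_amplicon):
        if a == "-":
            insertions.append(pos)  # between-base coordinate
        else:
            ref_bases[pos] = r  # '-' when deleted in the read
            pos += 1
    return ref_bases, insertions


def _window(edit_span: tuple[int, int], flank, amplicon_len: int) -> tuple[int, int]:
    if flank == "full":
        return (0, amplicon_len)
    a, b = edit_span
    return (max(0, a - flank), min(amplicon_len, b + flank))


def _has_indel_in_window(aln: AlignmentResult, window: tuple[int, int]) -> bool:
    ref_bases, insertions = _column_map(aln)
    wa, wb = window
    if any(ref_bases.get(p) == "-" for p in range(wa, wb)):
        return True
    return any(wa <= c <= wb for c in insertions)


def classify_read(
    aln: AlignmentResult,
    amplicon: str,
    edit: EditSpec,
    window_flank="full",
    cfg: RunConfig = DEFAULT_CONFIG,
) -> str:
    """Classify one read-vs-wild-type alignment (see module docstring).

    ``window_flank`` is ``"full"`` (whole amplicon, the default) or an integer
    flank around the edit span.
    """
    edit.validate(amplicon)
    span = edit.ref_span
    win = _window(span, window_flank, len(amplicon))
    read = aln.read

    if edit.kind == "substitution":
        if _has_indel_in_window(aln, win):
            return "indel"
        ref_bases, _ = _column_map(aln)
        obs = [ref_bases.get(p) for p in range(*span)]
        if None in obs:
            return "other_substitution"  # read does not cover the edit span
        if "".join(obs) == edit.alt_allele:
            return "desired_no_indel"
        if "".join(obs) == edit.ref_allele:
            return "unedited"
        return "other_substitution"

    # insertion/deletion edits: the desired outcome is itself a gap vs the
    # wild-type amplicon, so test against the edited amplicon first.
    edited = edit.apply(amplicon)
    aln_ed = _align_fast(read, edited, cfg)
    alt_span = (edit.start, edit.start + len(edit.alt_allele))
    win_ed = _window(alt_span, window_flank, len(edited))
    if not _has_indel_in_window(aln_ed, win_ed):
        ref_bases_ed, _ = _column_map(aln_ed)
        obs = [ref_bases_ed.get(p) for p in range(*alt_span)]
        if None not in obs and "".join(obs) == edit.alt_allele:
            return "desired_no_indel"
    if _has_indel_in_window(aln, win):
        return "indel"
    ref_bases, _ = _column_map(aln)
    obs = [ref_bases.get(p) for p in range(*span)]
    if all(o == amplicon[p] for o, p in zip(obs, range(*span))):
        return "unedited"
    return "other_substitution"


def quantify_amplicon(
    reads: Iterable,
    amplicon: str,
    edit: EditSpec,
    cfg: RunConfig = DEFAULT_CONFIG,
    window_flank="full",
    min_len_frac: float = 0.5,
) -> QuantResult:
    """Classify every read and aggregate the editing statistics.

    *reads* may be plain strings or Biopython SeqRecords.  Reads shorter than
    ``min_len_frac`` of the amplicon are excluded and counted separately.
    """
    counts = dict.fromkeys(LABELS, 0)
    n_excluded = 0
    n_total = 0
    for rec in reads:
        seq = str(rec.seq) if hasattr(rec, "seq") else str(rec)
        seq = seq.upper()
        if len(seq) < min_len_frac * len(amplicon):
            n_excluded += 1
            continue
        aln = align_oriented(seq, amplicon, cfg)
        counts[classify_read(aln, amplicon, edit, window_flank, cfg)] += 1
        n_total += 1
    if n_total == 0:
        raise ValueError("no usable reads")
    return QuantResult(
        n_total=n_total,
        n_desired_no_indel=counts["desired_no_indel"],
        n_indel=counts["indel"],
        n_unedited=counts["unedited"],
        n_other_substitution=counts["other_substitution"],
        n_excluded_short=n_excluded,
    )


def nucleotide_frequency_table(
    reads: Iterable, amplicon: str, cfg: RunConfig = DEFAULT_CONFIG
) -> pd.DataFrame:
    """Per-amplicon-position counts of A/C/G/T/- across aligned reads.

    Read insertions are excluded from positional counts; column totals equal
    the number of reads aligned across each position.
    """
    idx = {b: i for i, b in enumerate("ACGT-")}
    mat = np.zeros((len(amplicon), 5), dtype=int)
    for rec in reads:
        seq = str(rec.seq) if hasattr(rec, "seq") else str(rec)
        aln = align_oriented(seq.upper(), amplicon, cfg)
        ref_bases, _ = _column_map(aln)
        for p, b in ref_bases.items():
            mat[p, idx.get(b, idx["-"])] += 1
    return pd.DataFrame(mat, columns=list("ACGT-"), index=pd.RangeIndex(len(amplicon), name="pos"))


# ---------------------------------------------------------------------------
# off-target flap conversion
# ---------------------------------------------------------------------------

def best_flap_placement(flap: str, amplicon: str) -> tuple[int, str, int]:
    """Best ungapped placement of the flap (either orientation) on *amplicon*.

    Returns (offset, oriented_flap, n_matches); forward orientation and the
    leftmost offset win ties.
    """
    best = (-1, 0, "")
    for oriented in (flap, revcomp(flap)):
        for off in range(0, len(amplicon) - len(oriented) + 1):
            m = sum(
                1 for a, b in zip(oriented, amplicon[off : off + len(oriented)]) if a == b
            )
            if m > best[0]:
                best = (m, off, oriented)
    if best[0] < 0:
        raise ValueError("flap longer than amplicon")
    return best[1], best[2], best[0]


def flap_conversion_rate(
    reads: Sequence,
    ot_amplicon: str,
    design,
    mode: str = "strict",
    cfg: RunConfig = DEFAULT_CONFIG,
) -> FlapConversionResult:
    """Fraction of reads carrying the designed flap alleles at an off-target.

    The design's 3' DNA flap is placed at its best ungapped position on the
    off-target amplicon; positions where flap and amplicon differ are
    *informative*.  In ``strict`` mode (default) a read is converted when all
    informative positions carry the flap allele; in ``loose`` mode when at
    least one does.
    """
    if mode not in ("strict", "loose"):
        raise ValueError("mode must be 'strict' or 'loose'")
    flap = design.flap_dna if hasattr(design, "flap_dna") else str(design)
    off, oriented, _ = best_flap_placement(flap, ot_amplicon)
    flap_positions = list(range(off, off + len(oriented)))
    informative = [
        p for p in flap_positions if oriented[p - off] != ot_amplicon[p]
    ]
    if not informative:
        raise ValueError("no informative position: flap indistinguishable from amplicon")
    idx = {b: i for i, b in enumerate("ACGT-")}
    mat = np.zeros((len(flap_positions), 5), dtype=int)
    n_reads = 0
    n_converted = 0
    for rec in reads:
        seq = str(rec.seq) if hasattr(rec, "seq") else str(rec)
        aln = align_oriented(seq.upper(), ot_amplicon, cfg)
        ref_bases, _ = _column_map(aln)
        for i, p in enumerate(flap_positions):
            b = ref_bases.get(p)
            if b is not None:
                mat[i, idx.get(b, idx["-"])] += 1
        hits = [ref_bases.get(p) == oriented[p - off] for p in informative]
        converted = all(hits) if mode == "strict" else any(hits)
        n_converted += converted
        n_reads += 1
    if n_reads == 0:
        raise ValueError("no reads")
    table = pd.DataFrame(
        mat, columns=list("ACGT-"), index=pd.Index(flap_positions, name="pos")
    )
    return FlapConversionResult(table, flap_positions, informative, n_reads, n_converted)
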