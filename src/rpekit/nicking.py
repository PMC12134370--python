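"""Nicking-guide (ngRNA) design and mismatch-tolerant off-target scanning.

rPE3 adds a second guide directing Cas9-D10A to nick the *non-edited* strand,
biasing mismatch repair toward the edit.  Because D10A cuts the strand paired
with the guide, an ngRNA for a given primary site must sit on the opposite
protospacer strand.  rPE3b delays that nick until the edited flap has
resolved: its ngRNA protospacer/PAM must match the *edited* sequence but not
the pre-edit one.  When no such sequence difference exists naturally, a PAM
can be created by adding silent substitutions to the RTT-covered window
("PAM insertion").

Off-target candidates are found by an exhaustive Hamming-distance scan of
both strands (Cas-OFFinder's basic, bulge-free mode).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._seq import IUPAC_SETS, revcomp
from .config import DEFAULT_CONFIG
from .geometry import (
    PAM_LEN,
    PROTOSPACER_LEN,
    EditSpec,
    ReferenceLocus,
    SpacerSite,
    find_spacer_sites,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NgRNACandidate:
    """A nicking-guide placement relative to a primary rpegRNA site.

    ``nick_offset`` is signed: positive means the ngRNA nick lies at a larger
    reference coordinate than the rpegRNA nick (declared in output headers).
    """

    site: SpacerSite
    nick_offset: int
    overlaps_edit: bool
    post_edit_only: bool = False


@dataclass(frozen=True)
class OffTargetSite:
    """A mismatch-tolerant protospacer+PAM match on a subject sequence."""

    subject_name: str
    strand: str
    proto_start: int
    matched: str  # 23-nt protospacer+PAM in guide orientation
    mismatch_count: int
    mismatch_positions: tuple[int, ...]  # 1-based from the PAM-distal end


def _interval_overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _edit_ref_interval(edit: EditSpec) -> tuple[int, int]:
    a, b = edit.ref_span
    if edit.kind == "insertion":
        return (a, a)  # zero-width junction at the insertion point
    return (a, b)


def _site_footprint(site: SpacerSite) -> tuple[int, int]:
    a, b = site.proto_interval
    pa, pb = site.pam_interval
    return (min(a, pa), max(b, pb))


def _footprint_overlaps_edit(site: SpacerSite, edit: EditSpec) -> bool:
    fa, fb = _site_footprint(site)
    ea, eb = _edit_ref_interval(edit)
    if ea == eb:  # insertion junction: overlaps if strictly inside the footprint
        return fa < ea < fb
    return _interval_overlaps((fa, fb), (ea, eb))


def find_ngrna(
    locus: ReferenceLocus,
    primary: SpacerSite,
    edit: EditSpec,
    min_offset: int = DEFAULT_CONFIG.min_nick_offset,
    max_offset: int = DEFAULT_CONFIG.max_nick_offset,
    rpe3b: bool = False,
    pam_pattern: str = "NGG",
) -> list[NgRNACandidate]:
    """Enumerate ngRNA candidates for rPE3 on the strand opposite *primary*.

    Candidates whose protospacer/PAM footprint overlaps the edited positions
    are excluded unless ``rpe3b`` (then retained with ``overlaps_edit`` set).
    Sorted by ``|nick_offset|`` ascending, ties by proto_start.
    """
    other = "-" if primary.strand == "+" else "+"
    out = []
    for site in find_spacer_sites(locus, pam_pattern):
        if site.strand != other:
            continue
        offset = site.nick - primary.nick
        if not (min_offset <= abs(offset) <= max_offset):
            continue
        overlaps = _footprint_overlaps_edit(site, edit)
        if overlaps and not rpe3b:
            continue
        out.append(NgRNACandidate(site, offset, overlaps))
    out.sort(key=lambda c: (abs(c.nick_offset), c.site.proto_start))
    return out


def rpe3b_candidates(
    locus: ReferenceLocus,
    edit: EditSpec,
    primary: SpacerSite,
    min_offset: int = DEFAULT_CONFIG.min_nick_offset,
    max_offset: int = DEFAULT_CONFIG.max_nick_offset,
    pam_pattern: str = "NGG",
) -> list[NgRNACandidate]:
    """ngRNA candidates enumerated on the *edited* reference (rPE3b logic).

    ``post_edit_only`` marks candidates whose protospacer+PAM exist only
    after the edit resolves: their 23-mer mismatches the pre-edit sequence in
    at least one spacer position, or their PAM is broken pre-edit.
    """
    edit.validate(locus)
    edited_locus = ReferenceLocus(locus.name + "|edited", edit.apply(locus.seq))
    # primary site coordinates on the edited sequence: reverse-mode edits lie
    # on the PAM-distal side of the nick, so the protospacer/PAM may shift by
    # the edit's length change when it lies left of the site.
    shift = edit.delta if _edit_ref_interval(edit)[1] <= _site_footprint(primary)[0] else 0
    primary_e = SpacerSite(edited_locus, primary.strand, primary.proto_start + shift)
    # a zero-delta edit keeps coordinates aligned between pre and post; for
    # indel edits candidate coordinates refer to the edited sequence.
    out = []
    other = "-" if primary.strand == "+" else "+"
    for site in find_spacer_sites(edited_locus, pam_pattern):
        if site.strand != other:
            continue
        offset = site.nick - primary_e.nick
        if not (min_offset <= abs(offset) <= max_offset):
            continue
        overlaps = _candidate_overlaps_edited_region(site, edit)
        post_only = _post_edit_only(locus.seq, edited_locus.seq, site, edit, pam_pattern)
        out.append(NgRNACandidate(site, offset, overlaps, post_only))
    out.sort(key=lambda c: (abs(c.nick_offset), c.site.proto_start))
    return out


def _candidate_overlaps_edited_region(site: SpacerSite, edit: EditSpec) -> bool:
    fa, fb = _site_footprint(site)
    a = edit.start
    b = edit.start + len(edit.alt_allele)  # alt footprint in edited coords
    if a == b:
        return fa < a < fb
    return _interval_overlaps((fa, fb), (a, b))


def _post_edit_only(
    pre: str, post: str, site: SpacerSite, edit: EditSpec, pam_pattern: str
) -> bool:
    """Does the candidate's 23-mer match only the edited sequence?"""
    fa, fb = _site_footprint(site)
    # map the edited-coordinate footprint back to pre-edit coordinates,
    # anchoring on whichever side of the edit the footprint starts.
    if fa >= edit.start + len(edit.alt_allele):
        pa = fa - edit.delta
    else:
        pa = fa
    pre_seg = pre[pa : pa + (fb - fa)]
    post_seg = post[fa:fb]
    if len(pre_seg) < fb - fa:
        return True  # footprint runs off the pre-edit sequence
    if pre_seg == post_seg:
        return False
    # orient both segments to the candidate's guide strand and check whether
    # the pre-edit version still presents the same spacer and a valid PAM
    if site.strand == "-":
        pre_seg = revcomp(pre_seg)
        post_seg = revcomp(post_seg)
    pre_pam, post_pam = pre_seg[-PAM_LEN:], post_seg[-PAM_LEN:]
    pam_ok_pre = all(c in IUPAC_SETS[p] for c, p in zip(pre_pam, pam_pattern))
    spacer_same = pre_seg[:-PAM_LEN] == post_seg[:-PAM_LEN]
    return (not pam_ok_pre) or (not spacer_same)


def suggest_pam_insertion(
    locus: ReferenceLocus,
    primary: SpacerSite,
    edit: EditSpec,
    max_extra_subs: int = 2,
    max_rtt: int = DEFAULT_CONFIG.rtt_range[1],
    min_post_edit_homology: int = DEFAULT_CONFIG.min_post_edit_homology,
    pam_pattern: str = "NGG",
) -> list[dict]:
    """Extra substitutions in the RTT-covered window that create an ngRNA PAM.

    Enumerates candidate opposite-strand PAM placements whose PAM bases lie
    inside the reverse editing window of *primary* and which can be completed
    with at most ``max_extra_subs`` substitutions, yielding a
    ``post_edit_only`` candidate.  Each suggestion carries the extra edits,
    the combined EditSpec (single multi-base substitution; ``None`` when the
    primary edit is an indel) and the enabled candidate, ranked by fewest
    extra substitutions.
    """
    edit.validate(locus)
    reach = max_rtt - min_post_edit_homology
    edited = edit.apply(locus.seq)
    nick = primary.nick
    # window of RTT-coverable positions in *edited* coordinates: the primary
    # edit itself sits inside it, so its PAM-contributing bases count too
    if primary.strand == "+":
        nick_e = nick + edit.delta
        win = range(max(0, nick_e - reach), nick_e)
    else:
        win = range(nick, min(len(edited), nick + reach))
    win_pos = set(win)
    alt_region = set(range(edit.start, edit.start + len(edit.alt_allele)))
    other = "-" if primary.strand == "+" else "+"
    pam_plus = pam_pattern if other == "+" else revcomp(pam_pattern)
    n = len(edited)
    suggestions = []
    for ps in range(0, n - PROTOSPACER_LEN + 1):
        # opposite-strand candidate geometry, edited coordinates
        if other == "-":
            pam_iv = (ps - PAM_LEN, ps)
        else:
            pam_iv = (ps + PROTOSPACER_LEN, ps + PROTOSPACER_LEN + PAM_LEN)
        if pam_iv[0] < 0 or pam_iv[1] > n:
            continue
        subs_e: list[tuple[int, str, str]] = []  # (edited pos, from, to)
        feasible = True
        for k, code in enumerate(pam_plus):
            pos = pam_iv[0] + k
            allowed = IUPAC_SETS[code]
            base = edited[pos]
            if base in allowed:
                continue
            # substitution needed: must lie in the RTT window, outside the
            # primary edit's own bases, and the code must be concrete
            if pos not in win_pos or pos in alt_region or len(allowed) != 1:
                feasible = False
                break
            subs_e.append((pos, base, next(iter(allowed))))
        if not feasible or len(subs_e) > max_extra_subs:
            continue
        combined_seq = edited
        for pos, _, to in subs_e:
            combined_seq = combined_seq[:pos] + to + combined_seq[pos + 1 :]
        combined_locus = ReferenceLocus(locus.name + "|edited", combined_seq)
        try:
            cand_site = SpacerSite(combined_locus, other, ps)
        except ValueError:
            continue
        if not _post_edit_only(locus.seq, combined_seq, cand_site, edit, pam_pattern):
            continue
        # express extra substitutions in reference coordinates
        subs = []
        ok = True
        for pos, frm, to in subs_e:
            pos_ref = pos if pos < edit.start else pos - edit.delta
            if locus.seq[pos_ref] != frm:
                ok = False
                break
            subs.append(EditSpec.substitution(pos_ref, frm, to))
        if not ok:
            continue
        combined = _combine_edits(locus.seq, edit, subs)
        cand = NgRNACandidate(
            cand_site,
            cand_site.nick - (nick + (edit.delta if primary.strand == "+" else 0)),
            _candidate_overlaps_edited_region(cand_site, edit),
            post_edit_only=True,
        )
        suggestions.append(
            {"extra_edits": subs, "combined": combined, "candidate": cand, "n_extra": len(subs)}
        )
    suggestions.sort(key=lambda s: (s["n_extra"], s["candidate"].site.proto_start))
    return suggestions


def _combine_edits(ref: str, edit: EditSpec, subs: list[EditSpec]) -> EditSpec | None:
    """Merge a substitution edit with extra substitutions into one EditSpec."""
    if edit.kind != "substitution":
        return None
    positions = list(range(*edit.ref_span)) + [s.start for s in subs]
    lo, hi = min(positions), max(positions) + 1
    ref_allele = ref[lo:hi]
    alt = list(ref_allele)
    for i, b in enumerate(edit.alt_allele):
        alt[edit.start - lo + i] = b
    for s in subs:
        alt[s.start - lo] = s.alt_allele
    return EditSpec.substitution(lo, ref_allele, "".join(alt))


# ---------------------------------------------------------------------------
# off-target scanning
# ---------------------------------------------------------------------------

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _pam_mask(arr: np.ndarray, pattern: str, offset: int, n_windows: int) -> np.ndarray:
    """Boolean mask over window starts whose PAM (at window+offset) matches."""
    mask = np.ones(n_windows, dtype=bool)
    for k, code in enumerate(pattern):
        allowed = np.array([ord(b) for b in IUPAC_SETS[code]], dtype=np.uint8)
        col = arr[offset + k : offset + k + n_windows]
        mask &= np.isin(col, allowed)
    return mask


def scan_offtargets(
    subject: str | ReferenceLocus,
    spacer: str,
    max_mismatch: int,
    pam_pattern: str = "NGG",
    subject_name: str | None = None,
) -> list[OffTargetSite]:
    """Exhaustive both-strand scan for spacer matches within *max_mismatch*.

    Mismatch positions are 1-based from the PAM-distal end of the
    protospacer.  Results are ordered by proto_start ascending, ``+`` before
    ``-``.
    """
    if isinstance(subject, ReferenceLocus):
        subject_name = subject_name or subject.name
        subject = subject.seq
    subject = subject.upper()
    subject_name = subject_name or "subject"
    spacer = spacer.upper()
    L = len(spacer)
    plen = len(pam_pattern)
    n = len(subject)
    if n < L + plen:
        return []
    hits: list[OffTargetSite] = []
    arr = _encode(subject)
    spacer_arr = _encode(spacer)
    n_windows = n - (L + plen) + 1
    windows = np.lib.stride_tricks.sliding_window_view(arr, L)

    # + strand: spacer at w, PAM at w+L
    mism_fw = (windows[:n_windows] != spacer_arr).sum(axis=1)
    pam_fw = _pam_mask(arr, pam_pattern, L, n_windows)
    for w in np.nonzero(pam_fw & (mism_fw <= max_mismatch))[0]:
        seg = subject[w : w + L + plen]
        pos = tuple(i + 1 for i in range(L) if seg[i] != spacer[i])
        hits.append(OffTargetSite(subject_name, "+", int(w), seg, len(pos), pos))

    # - strand: reference shows revcomp(PAM)+revcomp(spacer); protospacer
    # occupies [w+plen, w+plen+L) with proto_start = w+plen
    rc_spacer = revcomp(spacer)
    rc_spacer_arr = _encode(rc_spacer)
    mism_rv = (windows[plen : plen + n_windows] != rc_spacer_arr).sum(axis=1)
    pam_rv = _pam_mask(arr, revcomp(pam_pattern), 0, n_windows)
    for w in np.nonzero(pam_rv & (mism_rv <= max_mismatch))[0]:
        seg = revcomp(subject[w : w + L + plen])
        pos = tuple(i + 1 for i in range(L) if seg[i] != spacer[i])
        hits.append(OffTargetSite(subject_name, "-", int(w) + plen, seg, len(pos), pos))

    hits.sort(key=lambda h: (h.proto_start, 0 if h.strand == "+" else 1))
    return hits
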