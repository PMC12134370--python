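"""Coordinate model of SpCas9 target sites and the reverse editing window.

SpCas9 binds a 20-nt protospacer followed by an NGG PAM on the non-targeted
strand and cuts bluntly 3 bp 5' of the PAM.  The strand nicked depends on the
nickase used: Cas9-H840A (canonical prime editing) nicks the non-targeted
strand through RuvC, Cas9-D10A (reverse prime editing, rPE) nicks the
targeted strand through HNH.  Both nicks sit at the same duplex position, so
a single between-base *nick coordinate* describes either.

Editing proceeds from the nick in opposite directions in the two systems:

* ``canonical`` -- from the nick across protospacer positions 18-20, the PAM
  and downstream (the classic PE window);
* ``reverse`` -- from the nick back across protospacer positions 17..1 and
  into the upstream flank (the rPE window).

Positions are labelled ``+1..+k`` counting along the edited strand in the
editing direction, with 0 being the nick itself.  Reference coordinates are
0-based, half-open throughout; nick coordinates are between-base integers
(nick ``k`` lies between reference indices ``k-1`` and ``k``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

from ._seq import IUPAC_SETS, revcomp

logger = logging.getLogger(__name__)

PROTOSPACER_LEN = 20
PAM_LEN = 3
#: distance of the blunt SpCas9 cut from the PAM-proximal protospacer end
NICK_OFFSET_FROM_PAM = 3

_VALID = set("ACGTN")


@dataclass(frozen=True)
class ReferenceLocus:
    """A named reference sequence (uppercase A/C/G/T, N tolerated)."""

    name: str
    seq: str
    #: protospacer start recorded by generators that plant a guaranteed site
    planted_proto_start: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        bad = set(self.seq) - _VALID
        if bad:
            raise ValueError(f"locus {self.name!r}: invalid characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class EditSpec:
    """A desired edit in reference coordinates.

    ``start`` is a 0-based reference index.  For substitutions and deletions
    ``ref_allele`` must match the reference at ``[start, start+len(ref_allele))``;
    for insertions ``ref_allele`` is empty and ``alt_allele`` is inserted
    *before* index ``start``.
    """

    kind: str  # substitution | insertion | deletion
    start: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.kind not in ("substitution", "insertion", "deletion"):
            raise ValueError(f"unknown edit kind {self.kind!r}")
        object.__setattr__(self, "ref_allele", self.ref_allele.upper())
        object.__setattr__(self, "alt_allele", self.alt_allele.upper())
        if self.kind == "insertion" and (self.ref_allele or not self.alt_allele):
            raise ValueError("insertion requires empty ref_allele and non-empty alt_allele")
        if self.kind == "deletion" and (self.alt_allele or not self.ref_allele):
            raise ValueError("deletion requires non-empty ref_allele and empty alt_allele")
        if self.kind == "substitution":
            if not self.ref_allele or not self.alt_allele:
                raise ValueError("substitution requires both alleles")
        if self.ref_allele == self.alt_allele:
            raise ValueError("alleles must differ")
        if self.start < 0:
            raise ValueError("start must be >= 0")

    # -- convenience constructors -------------------------------------------------
    @classmethod
    def substitution(cls, start: int, ref: str, alt: str) -> "EditSpec":
        return cls("substitution", start, ref, alt)

    @classmethod
    def insertion(cls, start: int, alt: str) -> "EditSpec":
        return cls("insertion", start, "", alt)

    @classmethod
    def deletion(cls, start: int, ref: str) -> "EditSpec":
        return cls("deletion", start, ref, "")

    # -- geometry helpers ---------------------------------------------------------
    @property
    def ref_span(self) -> tuple[int, int]:
        """Half-open reference interval replaced by the edit (empty for insertions)."""
        return (self.start, self.start + len(self.ref_allele))

    @property
    def delta(self) -> int:
        """Length change: len(alt) - len(ref)."""
        return len(self.alt_allele) - len(self.ref_allele)

    def validate(self, seq: str | ReferenceLocus) -> None:
        s = seq.seq if isinstance(seq, ReferenceLocus) else seq
        a, b = self.ref_span
        if b > len(s) or (self.kind == "insertion" and self.start > len(s)):
            raise ValueError("edit extends past the reference end")
        if s[a:b] != self.ref_allele:
            raise ValueError(
                f"ref allele mismatch at {a}: expected {self.ref_allele!r}, found {s[a:b]!r}"
            )

    def apply(self, seq: str | ReferenceLocus) -> str:
        """Return the edited sequence."""
        s = seq.seq if isinstance(seq, ReferenceLocus) else seq
        self.validate(s)
        a, b = self.ref_span
        return s[:a] + self.alt_allele + s[b:]


@dataclass(frozen=True)
class SpacerSite:
    """A protospacer + PAM placement on a reference locus.

    ``proto_start`` is the lowest reference index of the 20-nt protospacer
    interval regardless of strand.  On the ``+`` strand the PAM occupies
    ``[proto_start+20, proto_start+23)`` and the nick is ``proto_start+17``;
    on the ``-`` strand the PAM occupies ``[proto_start-3, proto_start)`` and
    the nick is ``proto_start+3``.
    """

    locus: ReferenceLocus
    strand: str
    proto_start: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        a, b = self.proto_interval
        pa, pb = self.pam_interval
        if a < 0 or pa < 0 or b > len(self.locus) or pb > len(self.locus):
            raise ValueError("site extends outside the reference")

    @property
    def proto_interval(self) -> tuple[int, int]:
        return (self.proto_start, self.proto_start + PROTOSPACER_LEN)

    @property
    def pam_interval(self) -> tuple[int, int]:
        if self.strand == "+":
            return (self.proto_start + PROTOSPACER_LEN, self.proto_start + PROTOSPACER_LEN + PAM_LEN)
        return (self.proto_start - PAM_LEN, self.proto_start)

    @property
    def spacer(self) -> str:
        """Protospacer sequence (non-targeted-strand orientation, 5'->3')."""
        a, b = self.proto_interval
        s = self.locus.seq[a:b]
        return s if self.strand == "+" else revcomp(s)

    @property
    def pam(self) -> str:
        a, b = self.pam_interval
        s = self.locus.seq[a:b]
        return s if self.strand == "+" else revcomp(s)

    @property
    def nick(self) -> int:
        """Between-base coordinate of the blunt cut, 3 bp 5' of the PAM."""
        if self.strand == "+":
            return self.proto_start + PROTOSPACER_LEN - NICK_OFFSET_FROM_PAM
        return self.proto_start + NICK_OFFSET_FROM_PAM


@dataclass(frozen=True)
class EditingWindow:
    """Editable positions of a site in one editing mode.

    ``positions`` maps each reference index to its signed editing-position
    label (+1 is the first base in the editing direction from the nick).
    """

    site: SpacerSite
    mode: str  # reverse | canonical
    interval: tuple[int, int]
    positions: dict[int, int]


def _pam_matches(seq: str, pattern: str) -> bool:
    return len(seq) == len(pattern) and all(
        c in IUPAC_SETS[p] for c, p in zip(seq, pattern)
    )


def nick_coordinate(site: SpacerSite) -> int:
    """Between-base coordinate of the Cas9 blunt cut for *site*."""
    return site.nick


def find_spacer_sites(
    locus: ReferenceLocus, pam_pattern: str = "NGG"
) -> list[SpacerSite]:
    """Enumerate every protospacer+PAM placement on both strands.

    Returns sites ordered by ascending ``proto_start`` with ``+`` before
    ``-`` at equal coordinates.  Placements containing ``N`` in the
    protospacer or PAM are skipped with a logged warning.
    """
    seq = locus.seq
    n = len(seq)
    span = PROTOSPACER_LEN + len(pam_pattern)
    rc_pattern = revcomp(pam_pattern)
    sites: list[SpacerSite] = []
    n_skipped = 0
    for ps in range(0, n - PROTOSPACER_LEN + 1):
        proto = seq[ps : ps + PROTOSPACER_LEN]
        # + strand: PAM immediately 3' of the protospacer
        if ps + span <= n:
            pam = seq[ps + PROTOSPACER_LEN : ps + span]
            if _pam_matches(pam, pam_pattern):
                if "N" in proto or "N" in pam:
                    n_skipped += 1
                else:
                    sites.append(SpacerSite(locus, "+", ps))
        # - strand: reference holds revcomp(PAM) immediately 5' of the interval
        if ps - len(pam_pattern) >= 0:
            pam_rc = seq[ps - len(pam_pattern) : ps]
            if _pam_matches(pam_rc, rc_pattern):
                if "N" in proto or "N" in pam_rc:
                    n_skipped += 1
                else:
                    sites.append(SpacerSite(locus, "-", ps))
    if n_skipped:
        logger.warning("%s: skipped %d site(s) containing N", locus.name, n_skipped)
    return sites


def editing_window(site: SpacerSite, mode: str, max_reach: int) -> EditingWindow:
    """Editable reference positions of *site* in the given mode.

    ``reverse`` proceeds from the nick toward the PAM-distal protospacer end
    and beyond; ``canonical`` proceeds from the nick across protospacer
    positions 18-20, the PAM, and downstream.  The window is truncated with a
    warning at the reference boundary.
    """
    if mode not in ("reverse", "canonical"):
        raise ValueError(f"unknown mode {mode!r}")
    if max_reach < 1:
        raise ValueError("max_reach must be >= 1")
    n = len(site.locus)
    nick = site.nick
    # editing direction along the reference: reverse mode moves away from the
    # PAM, canonical toward/through it.
    if (site.strand == "+") == (mode == "reverse"):
        idx = [nick - k for k in range(1, max_reach + 1)]
    else:
        idx = [nick + k - 1 for k in range(1, max_reach + 1)]
    positions = {}
    for label, i in enumerate(idx, start=1):
        if 0 <= i < n:
            positions[i] = label
    if len(positions) < max_reach:
        warnings.warn(
            f"{mode} window of site {site.strand}{site.proto_start} truncated at "
            f"reference boundary ({len(positions)}/{max_reach} positions)",
            stacklevel=2,
        )
    lo, hi = min(positions), max(positions)
    return EditingWindow(site, mode, (lo, hi + 1), positions)


def edit_labels(site: SpacerSite, edit: EditSpec, mode: str) -> list[int]:
    """Editing-position labels of every edited base (insertion: the junction).

    Labels are positive inside the *mode* window; non-positive labels mean the
    edit lies at or beyond the nick on the wrong side.
    """
    nick = site.nick
    reverse_sense = (site.strand == "+") == (mode == "reverse")
    if edit.kind == "insertion":
        # distance of the insertion point (a between-base coordinate) from the
        # nick, in window direction; 0 = insertion exactly at the nick.
        d = nick - edit.start if reverse_sense else edit.start - nick
        return [d]
    a, b = edit.ref_span
    if reverse_sense:
        return [nick - i for i in range(a, b)]
    return [i - nick + 1 for i in range(a, b)]


def sites_covering_edit(
    locus: ReferenceLocus,
    edit: EditSpec,
    mode: str = "reverse",
    max_rtt: int = 16,
    min_post_edit_homology: int = 5,
    pam_pattern: str = "NGG",
) -> list[SpacerSite]:
    """Sites whose *mode* editing window can reach every edited position.

    The usable reach is ``max_rtt - min_post_edit_homology``.  Sites are
    ranked by the distance of the edit's farthest position from the nick
    (ascending), ties broken by ``proto_start`` then strand (``+`` first).
    Sites for which the edit would fall in the PBS region (wrong side of the
    nick) can never host a valid design and are reported per-site via the
    logger, not returned.
    """
    edit.validate(locus)
    reach = max_rtt - min_post_edit_homology
    scored: list[tuple[int, int, int, SpacerSite]] = []
    for site in find_spacer_sites(locus, pam_pattern):
        labels = edit_labels(site, edit, mode)
        far = max(labels)
        if min(labels) < 0 or (edit.kind != "insertion" and min(labels) < 1):
            logger.info(
                "site %s%d: edit overlaps the PBS side of the nick; no valid %s design",
                site.strand, site.proto_start, mode,
            )
            continue
        if far > reach:
            continue
        scored.append((far, site.proto_start, 0 if site.strand == "+" else 1, site))
    scored.sort(key=lambda t: t[:3])
    return [t[3] for t in scored]


def sites_to_bed(sites: list[SpacerSite]) -> str:
    """BED6 text (0-based half-open) for a list of sites; name = spacer."""
    lines = []
    for s in sites:
        a, b = s.proto_interval
        pa, pb = s.pam_interval
        start, end = min(a, pa), max(b, pb)
        lines.append(f"{s.locus.name}\t{start}\t{end}\t{s.spacer}\t0\t{s.strand}")
    return "\n".join(lines) + ("\n" if lines else "")
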