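"""rpegRNA and comparison pegRNA construction.

A prime-editing guide is ``5'-spacer-scaffold-RTT-PBS[-linker-motif]-3'``.
The two geometries differ only in which nicked strand primes reverse
transcription:

* **reverse (rPE, rpegRNA)** -- Cas9-D10A nicks the targeted strand; the PBS
  anneals to the 3' fragment of the targeted strand (the side of the nick
  carrying the PAM), and the RTT templates a new targeted-strand flap growing
  *away* from the PAM, so the edit lands on the PAM-distal side of the nick.
* **canonical (PE, pegRNA)** -- Cas9-H840A nicks the non-targeted strand; the
  flap grows across protospacer positions 18-20, the PAM and downstream.

A convenient identity follows from the geometry and is asserted on every
assembled design: for substitution edits the concatenated ``RTT+PBS``
extension equals the *edited* non-targeted-strand sequence of the reference
window ``[nick - span_RTT, nick + L_PBS)`` (reverse) or its reverse
complement over ``[nick - L_PBS, nick + span_RTT)`` (canonical), transcribed
to RNA.  For insertions/deletions ``L_RTT`` counts RTT nucleotides and the
covered reference span adjusts by the length change of the edit.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import pandas as pd

from ._seq import gc_percent, revcomp, to_dna, to_rna
from .config import DEFAULT_CONFIG, RunConfig
from .geometry import EditSpec, ReferenceLocus, SpacerSite, edit_labels

logger = logging.getLogger(__name__)


class DesignError(ValueError):
    """A requested design violates the site/edit geometry."""


@dataclass(frozen=True)
class RpegRNADesign:
    """A fully assembled reverse prime-editing guide."""

    site: SpacerSite
    edit: EditSpec
    spacer_rna: str
    scaffold_rna: str
    rtt_rna: str
    pbs_rna: str
    linker_rna: str | None = None
    motif_rna: str | None = None

    mode = "reverse"

    @property
    def L_RTT(self) -> int:
        return len(self.rtt_rna)

    @property
    def L_PBS(self) -> int:
        return len(self.pbs_rna)

    @property
    def extension_rna(self) -> str:
        return self.rtt_rna + self.pbs_rna

    @property
    def full_sequence(self) -> str:
        tail = ""
        if self.motif_rna is not None:
            tail = (self.linker_rna or "") + self.motif_rna
        return self.spacer_rna + self.scaffold_rna + self.extension_rna + tail

    @property
    def pbs_gc(self) -> float:
        return gc_percent(to_dna(self.pbs_rna))

    @property
    def rtt_gc(self) -> float:
        return gc_percent(to_dna(self.rtt_rna))

    @property
    def flap_dna(self) -> str:
        """The new edited-strand DNA flap the RT synthesizes, 5'->3'."""
        return revcomp(to_dna(self.rtt_rna))

    @property
    def edit_distance_from_nick(self) -> int:
        return max(edit_labels(self.site, self.edit, self.mode))

    @property
    def post_edit_homology(self) -> int:
        return _post_edit_homology(self.site, self.edit, self.L_RTT, self.mode)


@dataclass(frozen=True)
class PegRNADesign(RpegRNADesign):
    """Canonical-orientation comparison design (same fields, RuvC geometry)."""

    mode = "canonical"


# ---------------------------------------------------------------------------
# component operations
# ---------------------------------------------------------------------------

def design_pbs(site: SpacerSite, locus: ReferenceLocus, L_PBS: int) -> str:
    """PBS of an rpegRNA: anneals to the targeted-strand primer's 3' terminus.

    The primer is the targeted-strand fragment whose 3' end sits at the nick
    on the PAM side; its terminal ``L_PBS`` bases are reverse-complemented,
    which equals the non-targeted-strand sequence of the ``L_PBS`` reference
    positions on the PAM side of the nick, as RNA.
    """
    if L_PBS < 1:
        raise DesignError("L_PBS must be >= 1")
    nick = site.nick
    if site.strand == "+":
        if nick + L_PBS > len(locus):
            raise DesignError(
                f"PBS overruns reference 3' boundary by {nick + L_PBS - len(locus)} nt"
            )
        return to_rna(locus.seq[nick : nick + L_PBS])
    if nick - L_PBS < 0:
        raise DesignError(f"PBS overruns reference boundary by {L_PBS - nick} nt")
    return to_rna(revcomp(locus.seq[nick - L_PBS : nick]))


def _reverse_edit_bounds(site: SpacerSite, edit: EditSpec) -> None:
    """Reject edits on the PBS side of the nick for reverse designs."""
    labels = edit_labels(site, edit, "reverse")
    lo = min(labels)
    if (edit.kind == "insertion" and lo < 0) or (edit.kind != "insertion" and lo < 1):
        raise DesignError(
            "edit overlaps the PBS side of the nick; no reverse design exists"
        )


def _post_edit_homology(site: SpacerSite, edit: EditSpec, L_RTT: int, mode: str) -> int:
    """RTT bases beyond the far end of the edit (the distal homology arm)."""
    nick = site.nick
    reverse_sense = (site.strand == "+") == (mode == "reverse")
    if reverse_sense:
        # flap grows toward lower coordinates; edited coords shift by delta
        nick_e = nick + edit.delta
        far = edit.start  # lowest edited coordinate (edited coords == ref coords here)
        return far - (nick_e - L_RTT)
    far = edit.start + len(edit.alt_allele)  # highest edited coordinate, edited coords
    return (nick + L_RTT) - far


def design_rtt(
    site: SpacerSite,
    locus: ReferenceLocus,
    edit: EditSpec,
    L_RTT: int,
    min_post_edit_homology: int = DEFAULT_CONFIG.min_post_edit_homology,
) -> str:
    """RTT of an rpegRNA: templates the edited targeted-strand flap.

    Returns the edited non-targeted-strand sequence of the ``L_RTT``
    (edited-coordinate) positions on the PAM-distal side of the nick, as RNA.
    ``L_RTT`` counts RTT nucleotides; for insertions/deletions the covered
    reference span is ``L_RTT - edit.delta``.
    """
    if L_RTT < 1:
        raise DesignError("L_RTT must be >= 1")
    edit.validate(locus)
    _reverse_edit_bounds(site, edit)
    edited = edit.apply(locus.seq)
    nick = site.nick
    if site.strand == "+":
        nick_e = nick + edit.delta
        start = nick_e - L_RTT
        if start < 0:
            raise DesignError(f"RTT overruns reference boundary by {-start} nt")
        hom = edit.start - start
        if hom < min_post_edit_homology:
            raise DesignError(
                f"post-edit homology {hom} < required {min_post_edit_homology}"
                if hom >= 0
                else f"edit outside RTT reach (needs {min_post_edit_homology - hom} more nt)"
            )
        return to_rna(edited[start:nick_e])
    # '-' strand: flap grows toward higher coordinates; coords right of the
    # nick are edited coords, the nick itself is unshifted.
    end = nick + L_RTT
    if end > len(edited):
        raise DesignError(f"RTT overruns reference boundary by {end - len(edited)} nt")
    hom = end - (edit.start + len(edit.alt_allele))
    if hom < min_post_edit_homology:
        raise DesignError(
            f"post-edit homology {hom} < required {min_post_edit_homology}"
            if hom >= 0
            else f"edit outside RTT reach (needs {min_post_edit_homology - hom} more nt)"
        )
    return to_rna(revcomp(edited[nick:end]))


def _reconstruct_edited(site: SpacerSite, edit: EditSpec, rtt_rna: str, pbs_rna: str) -> None:
    """Validation: re-derive the edited amplicon from (reference, flap) and
    assert it equals applying the EditSpec directly."""
    ref = site.locus.seq
    nick = site.nick
    rtt_dna = to_dna(rtt_rna)
    span_ref = len(rtt_dna) - edit.delta
    if site.strand == "+":
        rebuilt = ref[: nick - span_ref] + rtt_dna + ref[nick:]
        pbs_ok = to_dna(pbs_rna) == ref[nick : nick + len(pbs_rna)]
    else:
        rebuilt = ref[:nick] + revcomp(rtt_dna) + ref[nick + span_ref :]
        pbs_ok = to_dna(pbs_rna) == revcomp(ref[nick - len(pbs_rna) : nick])
    if not pbs_ok or rebuilt != edit.apply(ref):
        raise RuntimeError(
            "internal design validation failed: flap does not reproduce the edit"
        )


def assemble_rpegrna(
    site: SpacerSite,
    edit: EditSpec,
    L_PBS: int,
    L_RTT: int,
    config: RunConfig = DEFAULT_CONFIG,
    motif: bool = False,
) -> RpegRNADesign:
    """Assemble a complete rpegRNA; validates flap->edit round-trip."""
    pbs = design_pbs(site, site.locus, L_PBS)
    rtt = design_rtt(site, site.locus, edit, L_RTT, config.min_post_edit_homology)
    _reconstruct_edited(site, edit, rtt, pbs)
    design = RpegRNADesign(
        site=site,
        edit=edit,
        spacer_rna=to_rna(site.spacer),
        scaffold_rna=config.scaffold_rna,
        rtt_rna=rtt,
        pbs_rna=pbs,
    )
    if motif:
        design = append_motif(design, config.linker_rna, config.motif_rna)
    return design


def design_canonical_pegrna(
    site: SpacerSite,
    edit: EditSpec,
    L_PBS: int,
    L_RTT: int,
    config: RunConfig = DEFAULT_CONFIG,
) -> PegRNADesign:
    """Canonical-orientation pegRNA for the same site (comparison mode).

    The extension is the reverse complement of the edited non-targeted-strand
    window ``[nick - L_PBS, nick + span_RTT)``, as RNA, ordered RTT-then-PBS.
    """
    if L_PBS < 1 or L_RTT < 1:
        raise DesignError("lengths must be >= 1")
    edit.validate(site.locus)
    labels = edit_labels(site, edit, "canonical")
    lo = min(labels)
    if (edit.kind == "insertion" and lo < 0) or (edit.kind != "insertion" and lo < 1):
        raise DesignError("edit overlaps the PBS side of the nick; not in canonical window")
    ref = site.locus.seq
    edited = edit.apply(ref)
    nick = site.nick
    if site.strand == "+":
        end = nick + L_RTT  # edited coords; nick unshifted (edit right of nick)
        if end > len(edited):
            raise DesignError("RTT overruns reference boundary")
        hom = end - (edit.start + len(edit.alt_allele))
        if hom < config.min_post_edit_homology:
            raise DesignError(f"post-edit homology {hom} < {config.min_post_edit_homology}")
        if nick - L_PBS < 0:
            raise DesignError("PBS overruns reference boundary")
        rtt = to_rna(revcomp(edited[nick:end]))
        pbs = to_rna(revcomp(ref[nick - L_PBS : nick]))
    else:
        nick_e = nick + edit.delta
        start = nick_e - L_RTT
        if start < 0:
            raise DesignError("RTT overruns reference boundary")
        hom = edit.start - start
        if hom < config.min_post_edit_homology:
            raise DesignError(f"post-edit homology {hom} < {config.min_post_edit_homology}")
        if nick + L_PBS > len(ref):
            raise DesignError("PBS overruns reference boundary")
        rtt = to_rna(edited[start:nick_e])
        pbs = to_rna(ref[nick : nick + L_PBS])
    design = PegRNADesign(
        site=site,
        edit=edit,
        spacer_rna=to_rna(site.spacer),
        scaffold_rna=config.scaffold_rna,
        rtt_rna=rtt,
        pbs_rna=pbs,
    )
    _validate_canonical(design)
    return design


def _validate_canonical(design: PegRNADesign) -> None:
    """Flap->edit round-trip for canonical designs."""
    ref = design.site.locus.seq
    nick = design.site.nick
    rtt_dna = to_dna(design.rtt_rna)
    span_ref = len(rtt_dna) - design.edit.delta
    if design.site.strand == "+":
        rebuilt = ref[:nick] + revcomp(rtt_dna) + ref[nick + span_ref :]
    else:
        rebuilt = ref[: nick - span_ref] + rtt_dna + ref[nick:]
    if rebuilt != design.edit.apply(ref):
        raise RuntimeError("internal design validation failed (canonical)")


def append_motif(
    design: RpegRNADesign,
    linker: str | None = None,
    motif: str | None = None,
) -> RpegRNADesign:
    """Return a copy with a structured 3' motif (erpegRNA); original unchanged."""
    if design.motif_rna is not None:
        raise DesignError("design already carries a 3' motif")
    if motif is None:
        motif = DEFAULT_CONFIG.motif_rna
    if not motif:
        raise DesignError("no 3' motif configured")
    if linker is None:
        linker = DEFAULT_CONFIG.linker_rna
    return dataclasses.replace(design, linker_rna=linker, motif_rna=motif)


def enumerate_designs(
    site: SpacerSite,
    edit: EditSpec,
    pbs_range: tuple[int, int] = DEFAULT_CONFIG.pbs_range,
    rtt_range: tuple[int, int] = DEFAULT_CONFIG.rtt_range,
    gc_bounds: tuple[float, float] = DEFAULT_CONFIG.gc_bounds,
    config: RunConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """One row per (L_PBS, L_RTT) pair with GC flags and a deterministic rank.

    GC-out-of-bounds rows are flagged, not dropped; rows whose RTT cannot be
    designed carry ``error``.  Ranking: GC-pass rows first, then ascending
    ``|pbs_gc-50| + |rtt_gc-50|``, ties by smaller L_PBS then L_RTT.
    """
    lo_gc, hi_gc = gc_bounds
    rows = []
    for L_PBS in range(pbs_range[0], pbs_range[1] + 1):
        for L_RTT in range(rtt_range[0], rtt_range[1] + 1):
            row = {
                "design_id": f"{site.locus.name}_{site.strand}{site.proto_start}_P{L_PBS}R{L_RTT}",
                "locus": site.locus.name,
                "strand": site.strand,
                "proto_start": site.proto_start,
                "nick": site.nick,
                "L_PBS": L_PBS,
                "L_RTT": L_RTT,
            }
            try:
                d = assemble_rpegrna(site, edit, L_PBS, L_RTT, config)
            except (DesignError, RuntimeError) as exc:
                row.update(
                    pbs_gc=float("nan"), rtt_gc=float("nan"),
                    gc_pass=False, error=str(exc),
                    edit_offset=None, full_sequence=None,
                )
            else:
                row.update(
                    pbs_gc=round(d.pbs_gc, 2),
                    rtt_gc=round(d.rtt_gc, 2),
                    gc_pass=(lo_gc <= d.pbs_gc <= hi_gc) and (lo_gc <= d.rtt_gc <= hi_gc),
                    error="",
                    edit_offset=d.edit_distance_from_nick,
                    full_sequence=d.full_sequence,
                )
            rows.append(row)
    df = pd.DataFrame(rows)
    dev = (df["pbs_gc"] - 50).abs() + (df["rtt_gc"] - 50).abs()
    order = pd.DataFrame(
        {
            "err": df["error"] != "",
            "fail": ~df["gc_pass"],
            "dev": dev.fillna(float("inf")),
            "L_PBS": df["L_PBS"],
            "L_RTT": df["L_RTT"],
        }
    ).sort_values(["err", "fail", "dev", "L_PBS", "L_RTT"], kind="mergesort")
    df = df.loc[order.index].reset_index(drop=True)
    df["rank"] = df.index + 1
    return df


def circular_parts(
    design: RpegRNADesign, elements: dict | None = None
) -> list[tuple[str, str]]:
    """Split circular-rpegRNA representation as (role, sequence) parts.

    Part 1 is the spacer+scaffold guide; part 2 the circularization cassette
    holding RTT+PBS between user-configured ligation/ribozyme elements.  With
    no elements configured the cassette is the bare extension (warned).
    """
    if not elements:
        logger.warning("no circularization elements configured; emitting bare extension cassette")
        elements = {}
    five = elements.get("five_prime", "")
    three = elements.get("three_prime", "")
    return [
        ("guide", design.spacer_rna + design.scaffold_rna),
        ("cassette", five + design.extension_rna + three),
    ]


def cloning_oligos(
    design: RpegRNADesign,
    overhangs: dict | None = None,
    prepend_g: bool = DEFAULT_CONFIG.prepend_g,
) -> dict[str, tuple[str, str]]:
    """Golden-Gate top/bottom oligo pairs (DNA) for spacer and extension.

    The optional 5'-G (U6 expression) affects oligos only, never the genomic
    spacer match.  Bottom oligos are reverse complements of the insert with
    the configured 4-nt overhangs.
    """
    ov = dict(DEFAULT_CONFIG.overhangs)
    if overhangs:
        ov.update(overhangs)
    spacer = to_dna(design.spacer_rna)
    if prepend_g and not spacer.startswith("G"):
        spacer = "G" + spacer
    ext = to_dna(design.extension_rna)
    return {
        "spacer": (ov["spacer_top"] + spacer, ov["spacer_bottom"] + revcomp(spacer)),
        "extension": (ov["extension_top"] + ext, ov["extension_bottom"] + revcomp(ext)),
    }


def designs_to_tsv_rows(designs: list[RpegRNADesign]) -> pd.DataFrame:
    """Flat table of assembled designs for TSV export."""
    return pd.DataFrame(
        {
            "design_id": [
                f"{d.site.locus.name}_{d.site.strand}{d.site.proto_start}_P{d.L_PBS}R{d.L_RTT}"
                for d in designs
            ],
            "locus": [d.site.locus.name for d in designs],
            "strand": [d.site.strand for d in designs],
            "proto_start": [d.site.proto_start for d in designs],
            "nick": [d.site.nick for d in designs],
            "L_PBS": [d.L_PBS for d in designs],
            "L_RTT": [d.L_RTT for d in designs],
            "pbs_gc": [round(d.pbs_gc, 2) for d in designs],
            "rtt_gc": [round(d.rtt_gc, 2) for d in designs],
            "edit_offset": [d.edit_distance_from_nick for d in designs],
            "full_sequence": [d.full_sequence for d in designs],
        }
    )
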