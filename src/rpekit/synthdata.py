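"""Deterministic generators for test loci, amplicons and reads.

These emulate the study conditions of an amplicon-seq editing experiment:
200-300 bp on-target amplicons, a mixture of correctly edited reads, indel
byproducts near the nick, and wild-type reads, each overlaid with i.i.d.
substitution sequencing errors.  Base qualities are uniform (Q30) because no
downstream step consumes them.  Class counts follow the largest-remainder
rule so stated fractions are met exactly at error rate 0.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .geometry import EditSpec, ReferenceLocus

BASES = np.array(list("ACGT"))


@dataclass
class SimTruth:
    """Ground truth of a simulated amplicon library."""

    seed: int
    amplicon: str
    edit: EditSpec
    frac_edited: float
    frac_indel: float
    error_rate: float
    n_reads: int
    #: between-base coordinate near which indel byproducts are placed
    nick: int | None = None
    indel_halfwidth: int = 10

    def __post_init__(self) -> None:
        if self.frac_edited < 0 or self.frac_indel < 0:
            raise ValueError("fractions must be >= 0")
        if self.frac_edited + self.frac_indel > 1:
            raise ValueError("fractions must sum to <= 1")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["edit"] = {
            "kind": self.edit.kind,
            "start": self.edit.start,
            "ref_allele": self.edit.ref_allele,
            "alt_allele": self.edit.alt_allele,
        }
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        d = json.loads(text)
        d["edit"] = EditSpec(**d["edit"])
        return cls(**d)


def largest_remainder(fractions: list[float], n: int) -> list[int]:
    """Integer allocation of n items to fractions, largest remainder first.

    Remainder ties break toward the earlier class; totals always sum to n.
    """
    raw = [f * n for f in fractions]
    base = [int(x) for x in raw]
    short = n - sum(base)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - base[i]), i))
    for i in order[:short]:
        base[i] += 1
    return base


def random_locus(
    seed: int,
    length: int,
    gc_target: float = 0.5,
    ensure_site: bool = False,
    name: str | None = None,
) -> ReferenceLocus:
    """Seeded random locus; optionally plants a guaranteed NGG site.

    With ``ensure_site`` a GG dinucleotide is written at the PAM position of
    a central protospacer placement; the planted ``proto_start`` is recorded
    on the returned locus.
    """
    if length < 60:
        raise ValueError("length must be >= 60")
    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_target) / 2, gc_target / 2, gc_target / 2, (1 - gc_target) / 2]
    )
    seq = rng.choice(BASES, size=length, p=p)
    planted = None
    if ensure_site:
        planted = length // 2 - 10
        seq[planted + 21] = "G"
        seq[planted + 22] = "G"
    return ReferenceLocus(
        name or f"locus_{seed}", "".join(seq), planted_proto_start=planted
    )


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def _random_indel(amplicon: str, nick: int, halfwidth: int, rng: np.random.Generator) -> str:
    """A 1-5 nt deletion or insertion within +-halfwidth of the nick."""
    size = int(rng.integers(1, 6))
    lo = max(0, nick - halfwidth)
    hi = min(len(amplicon) - size, nick + halfwidth)
    pos = int(rng.integers(lo, max(lo + 1, hi)))
    if rng.random() < 0.5:
        return amplicon[:pos] + amplicon[pos + size :]
    ins = "".join(rng.choice(BASES, size=size))
    return amplicon[:pos] + ins + amplicon[pos:]


def simulate_reads(truth: SimTruth) -> list[SeqRecord]:
    """Simulate an amplicon library from *truth* (fully seed-deterministic).

    Class counts are largest-remainder exact; edited reads are the amplicon
    with the EditSpec applied, indel reads carry a random 1-5 nt lesion near
    the nick, and every read is then perturbed by i.i.d. substitution errors.
    """
    rng = np.random.default_rng(truth.seed)
    truth.edit.validate(truth.amplicon)
    edited = truth.edit.apply(truth.amplicon)
    nick = truth.nick if truth.nick is not None else len(truth.amplicon) // 2
    counts = largest_remainder(
        [truth.frac_edited, truth.frac_indel, 1 - truth.frac_edited - truth.frac_indel],
        truth.n_reads,
    )
    labels = np.repeat(np.array(["edited", "indel", "wt"]), counts)
    rng.shuffle(labels)
    records = []
    for i, lab in enumerate(labels):
        if lab == "edited":
            template = edited
        elif lab == "indel":
            template = _random_indel(truth.amplicon, nick, truth.indel_halfwidth, rng)
        else:
            template = truth.amplicon
        seq = _apply_errors(template, truth.error_rate, rng)
        rec = SeqRecord(Seq(seq), id=f"read_{i}|{lab}", description="")
        rec.letter_annotations["phred_quality"] = [30] * len(seq)
        records.append(rec)
    return records


def simulate_offtarget_reads(
    ot_amplicon: str,
    flap: str,
    conversion_frac: float,
    error_rate: float,
    n_reads: int,
    seed: int,
) -> tuple[list[SeqRecord], dict]:
    """Reads at an off-target locus with a known flap-conversion fraction.

    Converted reads carry the flap alleles at every informative position of
    the flap's best placement on the amplicon; the rest are wild-type.
    Returns (records, truth dict).
    """
    from .quantify import best_flap_placement

    off, oriented, _ = best_flap_placement(flap, ot_amplicon)
    informative = [
        off + i for i, b in enumerate(oriented) if b != ot_amplicon[off + i]
    ]
    if not informative:
        raise ValueError("flap has no informative position vs the amplicon")
    converted_seq = list(ot_amplicon)
    for p in informative:
        converted_seq[p] = oriented[p - off]
    converted_seq = "".join(converted_seq)
    rng = np.random.default_rng(seed)
    counts = largest_remainder([conversion_frac, 1 - conversion_frac], n_reads)
    labels = np.repeat(np.array(["conv", "wt"]), counts)
    rng.shuffle(labels)
    records = []
    for i, lab in enumerate(labels):
        template = converted_seq if lab == "conv" else ot_amplicon
        seq = _apply_errors(template, error_rate, rng)
        rec = SeqRecord(Seq(seq), id=f"otread_{i}|{lab}", description="")
        rec.letter_annotations["phred_quality"] = [30] * len(seq)
        records.append(rec)
    truth = {
        "seed": seed,
        "conversion_frac": conversion_frac,
        "error_rate": error_rate,
        "n_reads": n_reads,
        "informative_positions": informative,
    }
    return records, truth
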