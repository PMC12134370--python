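"""File formats and the edit-specification grammar.

Human-facing positions (CLI, edit grammar) are 1-based; everything internal
is 0-based, half-open.  The conversion happens here, in ``parse_edit_spec``,
and nowhere else.  All readers are gzip-transparent; TSV outputs carry a
versioned header comment with the tool version, config hash and seed so
identical invocations are byte-identical.
"""

from __future__ import annotations

import gzip
import re
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .config import RunConfig
from .geometry import EditSpec, ReferenceLocus, SpacerSite, sites_to_bed

_EDIT_RE = {
    "sub": re.compile(r"^sub:(\d+):([ACGTacgt]+)>([ACGTacgt]+)$"),
    "ins": re.compile(r"^ins:(\d+):([ACGTacgt]+)$"),
    "del": re.compile(r"^del:(\d+)-(\d+)$"),
}


def parse_edit_spec(text: str, reference: str | ReferenceLocus | None = None) -> EditSpec:
    """Parse the edit grammar into an internal 0-based EditSpec.

    Grammar (positions 1-based):
      ``sub:<pos>:<ref>><alt>`` | ``ins:<pos>:<seq>`` | ``del:<start>-<end>``

    Insertion places <seq> before 1-based position <pos>; deletion removes
    the closed 1-based range, i.e. 0-based ``[start-1, end)``.  When a
    reference is supplied the ref allele is validated against it.
    """
    text = text.strip()
    m = _EDIT_RE["sub"].match(text)
    if m:
        pos, ref, alt = int(m.group(1)), m.group(2).upper(), m.group(3).upper()
        edit = EditSpec.substitution(pos - 1, ref, alt)
    else:
        m = _EDIT_RE["ins"].match(text)
        if m:
            edit = EditSpec.insertion(int(m.group(1)) - 1, m.group(2).upper())
        else:
            m = _EDIT_RE["del"].match(text)
            if not m:
                raise ValueError(
                    f"malformed edit spec {text!r}; expected sub:<pos>:<ref>><alt> | "
                    "ins:<pos>:<seq> | del:<start>-<end>"
                )
            start, end = int(m.group(1)), int(m.group(2))
            if end < start:
                raise ValueError(f"deletion end {end} before start {start}")
            if reference is None:
                raise ValueError("deletions need a reference to resolve the deleted allele")
            seq = reference.seq if isinstance(reference, ReferenceLocus) else reference
            edit = EditSpec.deletion(start - 1, seq[start - 1 : end])
    if reference is not None:
        edit.validate(reference if isinstance(reference, str) else reference.seq)
    return edit


def xopen(path: str | Path, mode: str = "rt"):
    """open() that is transparent to .gz suffixes."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[ReferenceLocus]:
    with xopen(path) as fh:
        return [ReferenceLocus(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]


def read_fastq(path: str | Path) -> Iterator[SeqRecord]:
    with xopen(path) as fh:
        yield from SeqIO.parse(fh, "fastq")


def write_fasta(records: Iterable, path: str | Path) -> None:
    """Write (name, seq) pairs or SeqRecords as FASTA."""
    recs = []
    for r in records:
        if isinstance(r, SeqRecord):
            recs.append(r)
        else:
            name, seq = r
            recs.append(SeqRecord(Seq(seq), id=name, description=""))
    with xopen(path, "wt") as fh:
        SeqIO.write(recs, fh, "fasta")


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> None:
    with xopen(path, "wt") as fh:
        SeqIO.write(records, fh, "fastq")


def output_header(config: RunConfig, seed: int | None = None) -> str:
    seed_part = f" seed={seed}" if seed is not None else ""
    return f"#rpekit={__version__} config={config.config_hash}{seed_part}\n"


def write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    config: RunConfig | None = None,
    seed: int | None = None,
) -> None:
    """TSV with a versioned header comment (reproducibility stamp)."""
    with xopen(path, "wt") as fh:
        if config is not None:
            fh.write(output_header(config, seed))
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_bed(sites: list[SpacerSite], path: str | Path) -> None:
    with xopen(path, "wt") as fh:
        fh.write(sites_to_bed(sites))
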