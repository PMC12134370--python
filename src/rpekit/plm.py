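"""Two-round protein-variant selection from language-model score tables.

Round 1 combines per-model scores (e.g. ESM-1v, ESM-MSA-1b, ESM-IF1 zero-shot
scores over a saturation-mutagenesis library) and keeps the top 10 % of
variants.  Two combination modes are provided, since either is a defensible
reading of "combining" several models:

* ``rank_mean`` (default) -- per-model ranks (1 = best) averaged; the
  ``ceil(fraction * N)`` best mean ranks are kept;
* ``union`` -- a variant is kept if it is in the top fraction of *any* model.

Round 2 filters against a position-specific scoring matrix (PSSM): a variant
passes when the mutant residue scores strictly higher than the wild-type
residue at that position and the positional information value exceeds
``info_min`` (default 0.1).

Model inference itself is out of scope here; scores are inputs (TSV with
columns ``pos``, ``wt``, ``mut``, ``score``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AMINO_ACIDS = list("ACDEFGHIKLMNPQRSTVWY")

VARIANT_COLUMNS = ["pos", "wt", "mut"]


@dataclass
class PSSMMatrix:
    """Per-position amino-acid scores plus an information value per position.

    ``scores`` is indexed by 1-based residue position with the 20 standard
    amino acids as columns; ``info`` is a Series on the same index.
    """

    scores: pd.DataFrame
    info: pd.Series

    def __post_init__(self) -> None:
        missing = [a for a in AMINO_ACIDS if a not in self.scores.columns]
        if missing:
            raise ValueError(f"PSSM missing amino-acid columns: {missing}")
        self.scores = self.scores[AMINO_ACIDS]
        self.info = self.info.reindex(self.scores.index)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PSSMMatrix":
        """Read the native format: columns ``pos``, 20 amino acids, ``info``."""
        df = pd.read_csv(path, sep="\t")
        df = df.set_index("pos")
        return cls(df[AMINO_ACIDS], df["info"])

    @classmethod
    def from_possum(cls, path: str | Path, info: str | Path | None = None) -> "PSSMMatrix":
        """Read a POSSUM-style profile export (20 columns, rows = positions).

        POSSUM exports carry no information column; pass a separate
        one-column file or leave ``info`` absent (rows then fail the
        information criterion as unevaluable rather than receiving an
        invented value).
        """
        df = pd.read_csv(path)
        if df.shape[1] != 20:
            raise ValueError(f"expected 20 columns, found {df.shape[1]}")
        df.columns = AMINO_ACIDS
        df.index = pd.RangeIndex(1, len(df) + 1, name="pos")
        if info is not None:
            iv = pd.read_csv(info, header=None).iloc[:, 0]
            iv.index = df.index
        else:
            iv = pd.Series(np.nan, index=df.index)
        return cls(df, iv)

    def to_tsv(self, path: str | Path) -> None:
        out = self.scores.copy()
        out["info"] = self.info
        out.to_csv(path, sep="\t", index_label="pos")


def read_score_table(path: str | Path) -> pd.DataFrame:
    """Read one model's variant scores (TSV: pos, wt, mut, score)."""
    df = pd.read_csv(path, sep="\t")
    required = set(VARIANT_COLUMNS + ["score"])
    if not required <= set(df.columns):
        raise ValueError(f"score table needs columns {sorted(required)}")
    return df


def _variant_key(df: pd.DataFrame) -> pd.Series:
    return df["wt"] + df["pos"].astype(str) + df["mut"]


def ensemble_rank(
    tables: dict[str, pd.DataFrame],
    fraction: float = 0.10,
    combine: str = "rank_mean",
) -> pd.DataFrame:
    """Round-1 selection: top *fraction* of the shared variant universe.

    Tables are inner-joined on (pos, wt, mut); dropped keys are logged.
    Higher score = better, rank 1 = best.  ``rank_mean`` returns exactly
    ``ceil(fraction * N)`` variants ordered by mean rank (ties by variant key
    lexicographic); ``union`` returns the union of per-model top fractions.
    """
    if not tables:
        raise ValueError("no score tables supplied")
    if combine not in ("rank_mean", "union"):
        raise ValueError("combine must be 'rank_mean' or 'union'")
    merged = None
    for name, df in tables.items():
        part = df[VARIANT_COLUMNS + ["score"]].rename(columns={"score": f"score_{name}"})
        merged = part if merged is None else merged.merge(part, on=VARIANT_COLUMNS, how="inner")
    n_union = max(len(df) for df in tables.values())
    if len(merged) == 0:
        raise ValueError("empty intersection of variant universes")
    if len(merged) < n_union:
        logger.warning(
            "inner join dropped %d variant key(s) absent from some model", n_union - len(merged)
        )
    merged = merged.copy()
    merged["variant"] = _variant_key(merged)
    score_cols = [c for c in merged.columns if c.startswith("score_")]
    for c in score_cols:
        merged[c.replace("score_", "rank_")] = (
            merged[c].rank(ascending=False, method="min").astype(int)
        )
    rank_cols = [c for c in merged.columns if c.startswith("rank_")]
    merged["mean_rank"] = merged[rank_cols].mean(axis=1)
    n = len(merged)
    k = math.ceil(fraction * n)
    if k < 1:
        raise ValueError("fraction selects fewer than 1 variant")
    if combine == "rank_mean":
        out = merged.sort_values(["mean_rank", "variant"], kind="mergesort").head(k)
    else:
        keep = pd.Series(False, index=merged.index)
        for c in rank_cols:
            keep |= merged[c] <= math.ceil(fraction * n)
        out = merged[keep].sort_values(["mean_rank", "variant"], kind="mergesort")
    return out.reset_index(drop=True)


def pssm_filter(
    candidates: pd.DataFrame,
    pssm: PSSMMatrix,
    info_min: float = 0.1,
) -> pd.DataFrame:
    """Round-2 PSSM filter with per-criterion flags, input order preserved.

    A candidate passes when ``pssm[pos][mut] > pssm[pos][wt]`` (strict) and
    ``info[pos] > info_min``.  Candidates at positions absent from the PSSM
    are flagged unevaluable, excluded from the output and logged.
    """
    rows = []
    n_unevaluable = 0
    for _, row in candidates.iterrows():
        pos = row["pos"]
        if pos not in pssm.scores.index or row["mut"] not in pssm.scores.columns:
            n_unevaluable += 1
            continue
        mut_score = pssm.scores.at[pos, row["mut"]]
        wt_score = pssm.scores.at[pos, row["wt"]]
        info = pssm.info.at[pos]
        pass_score = bool(mut_score > wt_score)
        pass_info = bool(info > info_min) if pd.notna(info) else False
        d = dict(row)
        d.update(
            mut_pssm=mut_score, wt_pssm=wt_score, info=info,
            pass_score=pass_score, pass_info=pass_info,
            passed=pass_score and pass_info,
        )
        rows.append(d)
    if n_unevaluable:
        logger.warning("%d candidate(s) at positions absent from the PSSM; excluded", n_unevaluable)
    return pd.DataFrame(rows)


@dataclass
class SelectionReport:
    round1: pd.DataFrame
    round2: pd.DataFrame
    final: pd.DataFrame
    combine: str
    fraction: float
    info_min: float

    @property
    def round1_size(self) -> int:
        return len(self.round1)

    @property
    def round2_size(self) -> int:
        return len(self.final)


def select_variants(
    tables: dict[str, pd.DataFrame],
    pssm: PSSMMatrix,
    fraction: float = 0.10,
    info_min: float = 0.1,
    combine: str = "rank_mean",
) -> SelectionReport:
    """Full two-round selection: ensemble top fraction, then PSSM filter."""
    round1 = ensemble_rank(tables, fraction, combine)
    round2 = pssm_filter(round1, pssm, info_min)
    final = round2[round2["passed"]].reset_index(drop=True) if len(round2) else round2
    return SelectionReport(round1, round2, final, combine, fraction, info_min)
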