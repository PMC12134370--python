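"""Independent oracles used by the test suite.

Everything here re-derives expected results by a different route from the
implementation: naive window scans, simulated primer extension, memoized
recursion over all alignments, exhaustive neighborhood search.
"""

from __future__ import annotations

from functools import lru_cache

COMP = str.maketrans("ACGTN", "TGCAN")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def rc(s: str) -> str:
    return s.translate(COMP)[::-1]


def naive_site_scan(seq: str, pam: str = "NGG") -> list[tuple[str, int]]:
    """All-windows protospacer+PAM scan; returns (strand, proto_start) sorted."""
    hits = []
    n = len(seq)
    for i in range(n):
        if i + 23 <= n:
            window = seq[i : i + 23]
            if "N" not in window and all(window[20 + k] in IUPAC[pam[k]] for k in range(3)):
                hits.append(("+", i))
        if i - 3 >= 0 and i + 20 <= n:
            window = rc(seq[i - 3 : i + 20])
            if "N" not in window and all(window[20 + k] in IUPAC[pam[k]] for k in range(3)):
                hits.append(("-", i))
    hits.sort(key=lambda h: (h[1], 0 if h[0] == "+" else 1))
    return hits


def simulate_primer_extension(design) -> bool:
    """Flap-simulation oracle for the rpegRNA extension identity.

    Builds the targeted-strand primer, verifies PBS annealing, polymerizes
    the flap off the RTT base-by-base, and checks the extended primer equals
    the corresponding targeted-strand prefix of the directly edited sequence.
    """
    ref = design.site.locus.seq
    nick = design.site.nick
    ext = (design.rtt_rna + design.pbs_rna).replace("U", "T")
    L_pbs, L_rtt = len(design.pbs_rna), len(design.rtt_rna)
    edited = design.edit.apply(ref)

    if design.site.strand == "+":
        primer = rc(ref[nick:])  # TS 3' fragment, 5'->3'
        expected_ts = rc(edited)
    else:
        primer = ref[:nick]
        expected_ts = edited

    # PBS annealing: primer 3'-terminal L_pbs bases pair the extension's
    # 3'-terminal L_pbs bases antiparallel
    if primer[-L_pbs:] != rc(ext[-L_pbs:]):
        return False

    # reverse transcription: read the RTT 3'->5', append complements
    flap = "".join(ext[L_rtt - 1 - k].translate(COMP) for k in range(L_rtt))
    product = primer + flap
    return product == expected_ts[: len(product)]


def brute_affine_score(a: str, b: str, match: int, mism: int, open_: int, ext: int) -> int:
    """Optimal global affine-gap score by memoized recursion over all
    alignment paths (gap of length k costs open + (k-1)*ext)."""

    @lru_cache(maxsize=None)
    def f(i: int, j: int, state: int) -> int:
        if i == len(a) and j == len(b):
            return 0
        best = -(10**9)
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mism
            best = max(best, s + f(i + 1, j + 1, 0))
        if i < len(a):
            g = ext if state == 1 else open_
            best = max(best, g + f(i + 1, j, 1))
        if j < len(b):
            g = ext if state == 2 else open_
            best = max(best, g + f(i, j + 1, 2))
        return best

    return f(0, 0, 0)


def naive_offtarget_scan(subject: str, spacer: str, max_mm: int, pam: str = "NGG"):
    """Plain-Python rescan; returns (strand, proto_start, n_mismatch) sorted."""
    hits = []
    n, L = len(subject), len(spacer)
    for i in range(n - L - 3 + 1):
        seg = subject[i : i + L]
        pamseg = subject[i + L : i + L + 3]
        if all(pamseg[k] in IUPAC[pam[k]] for k in range(3)):
            mm = sum(1 for x, y in zip(seg, spacer) if x != y)
            if mm <= max_mm:
                hits.append(("+", i, mm))
    for i in range(3, n - L + 1):
        seg = rc(subject[i : i + L])
        pamseg = rc(subject[i - 3 : i])
        if all(pamseg[k] in IUPAC[pam[k]] for k in range(3)):
            mm = sum(1 for x, y in zip(seg, spacer) if x != y)
            if mm <= max_mm:
                hits.append(("-", i, mm))
    hits.sort(key=lambda h: (h[1], 0 if h[0] == "+" else 1))
    return hits


def mean_rank_top(tables: dict[str, list[tuple[str, float]]], fraction: float) -> list[str]:
    """Brute-force round-1 oracle on tiny hand-built tables.

    *tables* maps model -> [(variant_key, score)]; returns the ceil(f*N)
    variants with smallest mean rank (rank 1 = best, ties share the min
    rank), ordered by (mean_rank, key).
    """
    import math

    keys = set.intersection(*(set(k for k, _ in t) for t in tables.values()))
    mean_ranks = {}
    for key in keys:
        ranks = []
        for t in tables.values():
            scores = {k: s for k, s in t if k in keys}
            better = sum(1 for v in scores.values() if v > scores[key])
            ranks.append(better + 1)
        mean_ranks[key] = sum(ranks) / len(ranks)
    k = math.ceil(fraction * len(keys))
    return sorted(mean_ranks, key=lambda v: (mean_ranks[v], v))[:k]
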