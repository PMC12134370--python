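import numpy as np
import pytest

from rpekit import EditSpec, ReferenceLocus, find_spacer_sites
from rpekit.synthdata import random_locus


@pytest.fixture
def toy_locus():
    """30-nt locus with a single + strand site at proto_start 0 (nick 17)."""
    return ReferenceLocus("toy", "ACGTACGTACGTACGTAACC" + "AGG" + "TACGTCA")


@pytest.fixture
def toy_site(toy_locus):
    return next(
        s for s in find_spacer_sites(toy_locus) if s.strand == "+" and s.proto_start == 0
    )


@pytest.fixture
def toy_sub(toy_locus):
    """Substitution at reference index 10, inside the reverse window."""
    ref = toy_locus.seq[10]
    alt = "A" if ref != "A" else "C"
    return EditSpec.substitution(10, ref, alt)


def random_site_and_edit(seed, length=140, mode="reverse", edit_kind="substitution"):
    """A random locus with a planted site plus a random window edit."""
    rng = np.random.default_rng(seed)
    locus = random_locus(seed, length, ensure_site=True)
    site = next(
        s
        for s in find_spacer_sites(locus)
        if s.strand == "+" and s.proto_start == locus.planted_proto_start
    )
    # ranges keep every edit reachable with L_RTT >= 13 and 5 nt homology
    nick = site.nick
    if mode == "reverse":
        pos = int(rng.integers(nick - 7, nick - 1))  # labels +2..+7
    else:
        pos = int(rng.integers(nick + 1, nick + 7))
    if edit_kind == "substitution":
        n_sub = int(rng.integers(1, 3))
        if mode == "reverse":
            pos = min(pos, nick - n_sub)
        ref = locus.seq[pos : pos + n_sub]
        alt = "".join(
            rng.choice([b for b in "ACGT" if b != c]) for c in ref
        )
        edit = EditSpec.substitution(pos, ref, alt)
    elif edit_kind == "insertion":
        ins = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 4))))
        if mode == "reverse":
            pos = max(pos, nick - 6)
        edit = EditSpec.insertion(pos, ins)
    else:
        n_del = int(rng.integers(1, 3))
        if mode == "reverse":
            pos = min(max(pos, nick - 7 + n_del), nick - n_del)
        edit = EditSpec.deletion(pos, locus.seq[pos : pos + n_del])
    return locus, site, edit
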