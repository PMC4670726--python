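import numpy as np
import pytest

from dmotif.io_formats import ProteinRecord, read_tree_string
from dmotif.motif_patterns import MotifClassDef, default_class_definitions


@pytest.fixture(scope="session")
def loose_classes():
    return default_class_definitions("loose")


@pytest.fixture(scope="session")
def tight_classes():
    return default_class_definitions("tight")


@pytest.fixture(scope="session")
def toy_tree():
    """The printed toy tree: d(B,C)=5, d(A,B)=4, d(A,C)=5."""
    return read_tree_string("(A:1,(B:2,C:3):1);")


def random_protein(rng: np.random.Generator, length: int, pid: str = "RND") -> ProteinRecord:
    """Random sequence enriched in basic/hydrophobic residues so motifs occur."""
    letters = np.array(list("ACDEFGHIKLMNPQRSTVWYRKLIVMFP"))
    return ProteinRecord(pid, "".join(rng.choice(letters, size=length)))


def oracle_scan(sequence: str, cdef: MotifClassDef) -> set[tuple[int, int]]:
    """Brute-force enumeration of all (start, theta-count, linker) parses.

    Checks every window directly against the class definition with plain
    loops and set membership, then applies the same reporting rule as the
    scanner: one hit per (class, phiB end), minimal start.  Independent of
    the regex-based implementation.
    """
    seq = sequence.upper()
    n = len(seq)
    by_end: dict[int, list[int]] = {}
    for start in range(1, n + 1):
        for tc in range(cdef.theta_range[0], cdef.theta_range[1] + 1):
            for lk in range(cdef.linker_range[0], cdef.linker_range[1] + 1):
                length = tc + lk + cdef.spacing + 4
                end = start + length - 1
                if end > n:
                    continue
                w = seq[start - 1 : end]
                lo = tc + lk
                ao = lo + 1 + cdef.spacing
                ok = (
                    all(w[i] in cdef.theta_alphabet for i in range(tc))
                    and w[lo] in cdef.phi_l
                    and w[ao] in cdef.phi_a
                    and w[ao + 2] in cdef.phi_b
                )
                for off, allowed in cdef.extra_constraints:
                    if not ok:
                        break
                    if off < 0:
                        p = start + off
                        ok = p >= 1 and seq[p - 1] in allowed
                    else:
                        ok = off < length and w[off] in allowed
                if ok:
                    by_end.setdefault(end, []).append(start)
    return {(min(starts), end) for end, starts in by_end.items()}
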