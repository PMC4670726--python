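"""The seven MAPK docking-motif classes and consensus scanning.

Every class instantiates the generic D-motif scheme

    theta(1,2) - x(0-5) - phiL - x(spacing) - phiA - x - phiB

with class-specific parameter choices: the spacing between the lower-pocket
residue (phiL) and pocket A (phiA) is 1 or 2, the theta-to-phiL linker is
short (0-2) or longer (3-5), and subtypes add positional context
constraints (e.g. an upstream hydrophobic phiU for the helical HePTP-class
N-terminus, or an S/T preference preceding the basic block in MKK6-type
motifs).  Classes are fully parameterized and can be overridden from YAML;
the shipped defaults are documented heuristics.

Hit coordinates are 1-based inclusive and cover the core motif only
(first theta residue through phiB).  Scanning reports every (class, core
span) combination, including overlapping hits and the same span matching
several classes.  Where one phi-core admits several theta/linker parses,
the minimal-start and then maximal-theta-count parse is reported once;
alternative parses are retained in a detail field.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from dmotif.io_formats import HIT_TABLE_COLUMNS, ProteinRecord

CLASS_NAMES = (
    "JIP1",
    "NFAT4",
    "MEF2A_MEF2A",
    "MEF2A_MKK6",
    "DCC",
    "HePTP_Ste7",
    "HePTP_HePTP",
)

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

# default residue classes; theta contacts the acidic CD groove, the phi
# positions fill the hydrophobic docking groove (phiL tolerates proline,
# as in the JIP1 and DCC lower pockets)
THETA_DEFAULT = frozenset("RK")
PHI_L_LOOSE = frozenset("LIVMFP")
PHI_A_LOOSE = frozenset("LIVMF")
PHI_B_LOOSE = frozenset("LIVMF")
PHI_U_LOOSE = frozenset("LIVMF")

PHI_L_TIGHT = frozenset("LIP")
PHI_A_TIGHT = frozenset("LIV")
PHI_B_TIGHT = frozenset("LIVF")
PHI_U_TIGHT = frozenset("LIV")
ST = frozenset("ST")


@dataclass(frozen=True)
class MotifClassDef:
    """One parameterized D-motif class.

    ``extra_constraints`` maps a position offset relative to the first theta
    residue (negative = upstream context outside the core) to an allowed
    residue set; a hit is valid only if the offset exists in the protein
    and carries an allowed residue.
    """

    name: str
    theta_range: tuple[int, int] = (1, 2)
    linker_range: tuple[int, int] = (0, 2)
    spacing: int = 1
    theta_alphabet: frozenset[str] = THETA_DEFAULT
    phi_l: frozenset[str] = PHI_L_LOOSE
    phi_a: frozenset[str] = PHI_A_LOOSE
    phi_b: frozenset[str] = PHI_B_LOOSE
    strictness: str = "loose"
    extra_constraints: tuple[tuple[int, frozenset[str]], ...] = ()

    def __post_init__(self) -> None:
        if self.spacing not in (1, 2):
            raise ValueError(f"spacing must be 1 or 2, got {self.spacing}")
        if not (1 <= self.theta_range[0] <= self.theta_range[1] <= 2):
            raise ValueError(f"theta_range {self.theta_range} outside the generic scheme")
        if not (0 <= self.linker_range[0] <= self.linker_range[1] <= 5):
            raise ValueError(f"linker_range {self.linker_range} outside the generic x(0-5)")
        for aset in (self.theta_alphabet, self.phi_l, self.phi_a, self.phi_b):
            if not aset <= STANDARD_AA:
                raise ValueError("residue alphabets must be subsets of the 20-letter alphabet")

    def core_length(self, theta_count: int, linker: int) -> int:
        """Length of the core span for one parse: theta block through phiB."""
        return theta_count + linker + 1 + self.spacing + 1 + 1 + 1

    def canonical_geometry(self) -> tuple[int, int]:
        """(theta_count, linker) of the fixed-length canonical instance."""
        return (1, self.linker_range[0])

    def canonical_length(self) -> int:
        return self.core_length(*self.canonical_geometry())

    def phi_offsets(self, theta_count: int, linker: int) -> tuple[int, int, int]:
        """0-based offsets of (phiL, phiA, phiB) within the core span."""
        l_off = theta_count + linker
        a_off = l_off + 1 + self.spacing
        return l_off, a_off, a_off + 2


def default_class_definitions(strictness: str = "loose") -> list[MotifClassDef]:
    """The seven shipped D-motif class definitions.

    JNK-binding classes use a short theta-to-phiL linker: NFAT4 (1-spacing)
    and JIP1 (2-spacing).  ERK/p38-binding classes use a longer linker:
    greater MEF2A (1-spacing; the MKK6 subtype prefers S/T just before the
    basic block), greater DCC (2-spacing), and the greater HePTP class
    (1-spacing with a helical N-terminal extension placing an upstream
    hydrophobic phiU; the HePTP subtype has the longer extension).
    Every tight definition matches a subset of what its loose counterpart
    matches.
    """
    if strictness not in ("loose", "tight"):
        raise ValueError(f"strictness must be 'loose' or 'tight', got {strictness!r}")
    tight = strictness == "tight"
    phi_l = PHI_L_TIGHT if tight else PHI_L_LOOSE
    phi_a = PHI_A_TIGHT if tight else PHI_A_LOOSE
    phi_b = PHI_B_TIGHT if tight else PHI_B_LOOSE
    phi_u = PHI_U_TIGHT if tight else PHI_U_LOOSE
    short, longer = (0, 2), (3, 5)
    common = dict(
        theta_range=(1, 2),
        theta_alphabet=THETA_DEFAULT,
        phi_l=phi_l,
        phi_a=phi_a,
        phi_b=phi_b,
        strictness=strictness,
    )
    return [
        MotifClassDef(name="JIP1", linker_range=short, spacing=2, **common),
        MotifClassDef(name="NFAT4", linker_range=short, spacing=1, **common),
        MotifClassDef(name="MEF2A_MEF2A", linker_range=longer, spacing=1, **common),
        MotifClassDef(
            name="MEF2A_MKK6",
            linker_range=longer,
            spacing=1,
            extra_constraints=((-1, ST),),
            **common,
        ),
        MotifClassDef(name="DCC", linker_range=longer, spacing=2, **common),
        MotifClassDef(
            name="HePTP_Ste7",
            linker_range=longer,
            spacing=1,
            extra_constraints=((-2, phi_u),),
            **common,
        ),
        MotifClassDef(
            name="HePTP_HePTP",
            linker_range=longer,
            spacing=1,
            extra_constraints=((-4, phi_u),),
            **common,
        ),
    ]


@dataclass
class MotifHit:
    """One consensus match (core span, 1-based inclusive)."""

    protein_id: str
    class_name: str
    start: int
    end: int
    matched_sequence: str
    theta_positions: tuple[int, ...]
    phi_positions: tuple[int, int, int]
    filter_status: dict[str, tuple[str, str]] = field(default_factory=dict)  # step -> (status, reason)
    pssm_score: float | None = None
    external_score: float | None = None
    alt_parses: list[tuple[int, int]] = field(default_factory=list)  # (theta_count, linker)

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.matched_sequence):
            raise ValueError("span length disagrees with matched sequence")
        for p in (*self.theta_positions, *self.phi_positions):
            if not self.start <= p <= self.end:
                raise ValueError("theta/phi positions must lie within the core span")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


# ---------------------------------------------------------------------------
# scanning


def _char_class(allowed: frozenset[str] | None) -> str:
    if allowed is None:
        return "."
    return "[" + "".join(sorted(allowed)) + "]"


def _parse_patterns(cdef: MotifClassDef):
    """Compile one lookahead regex per (theta_count, linker) parse geometry."""
    compiled = []
    for tc in range(cdef.theta_range[0], cdef.theta_range[1] + 1):
        for lk in range(cdef.linker_range[0], cdef.linker_range[1] + 1):
            core: list[frozenset[str] | None] = (
                [cdef.theta_alphabet] * tc
                + [None] * lk
                + [cdef.phi_l]
                + [None] * cdef.spacing
                + [cdef.phi_a, None, cdef.phi_b]
            )
            lookbehind = ""
            ok = True
            neg = [(off, aset) for off, aset in cdef.extra_constraints if off < 0]
            if neg:
                depth = -min(off for off, _ in neg)
                pre: list[frozenset[str] | None] = [None] * depth
                for off, aset in neg:
                    pre[depth + off] = aset
                lookbehind = "(?<=" + "".join(_char_class(a) for a in pre) + ")"
            for off, aset in cdef.extra_constraints:
                if off < 0:
                    continue
                if off >= len(core):
                    ok = False
                    break
                cur = core[off]
                merged = aset if cur is None else (cur & aset)
                if not merged:
                    ok = False
                    break
                core[off] = merged
            if not ok:
                continue
            body = "".join(_char_class(a) for a in core)
            rx = re.compile(lookbehind + "(?=(" + body + "))")
            compiled.append((tc, lk, rx))
    return compiled


def scan_sequence(record: ProteinRecord, classes: Sequence[MotifClassDef]) -> list[MotifHit]:
    """Enumerate all D-motif consensus matches of ``classes`` in one protein.

    Returns one hit per (class, core span), ordered by start position, then
    class name, then end.  Overlapping spans and multi-class matches of the
    same span are all reported.
    """
    if not classes:
        raise ValueError("classes must be non-empty")
    seq = record.sequence.upper()
    hits: list[MotifHit] = []
    for cdef in classes:
        # parses keyed by phiB position; the phi core is determined by
        # (class, end), so this collapses duplicate spans per class
        by_end: dict[int, list[tuple[int, int, int]]] = {}
        for tc, lk, rx in _parse_patterns(cdef):
            core_len = cdef.core_length(tc, lk)
            for m in rx.finditer(seq):
                start = m.start() + 1
                end = start + core_len - 1
                by_end.setdefault(end, []).append((start, tc, lk))
        for end, parses in by_end.items():
            best_start = min(p[0] for p in parses)
            at_start = [p for p in parses if p[0] == best_start]
            start, tc, lk = max(at_start, key=lambda p: p[1])
            l_off, a_off, b_off = cdef.phi_offsets(tc, lk)
            hits.append(
                MotifHit(
                    protein_id=record.id,
                    class_name=cdef.name,
                    start=start,
                    end=end,
                    matched_sequence=seq[start - 1 : end],
                    theta_positions=tuple(range(start, start + tc)),
                    phi_positions=(start + l_off, start + a_off, start + b_off),
                    alt_parses=sorted((p[1], p[2]) for p in parses),
                )
            )
    hits.sort(key=lambda h: (h.start, h.class_name, h.end))
    return hits


def scan_proteome(
    records: Iterable[ProteinRecord], classes: Sequence[MotifClassDef]
) -> list[MotifHit]:
    """Concatenate scan_sequence over records, ordered by protein id."""
    hits: list[MotifHit] = []
    for rec in sorted(records, key=lambda r: r.id):
        hits.extend(scan_sequence(rec, classes))
    return hits


def hits_to_table(hits: Sequence[MotifHit]) -> pd.DataFrame:
    """Flatten hits into the documented TSV-ready table."""
    rows = []
    for h in hits:
        status = ";".join(f"{step}:{st}" + (f"({why})" if why else "") for step, (st, why) in h.filter_status.items())
        rows.append(
            (
                h.protein_id,
                h.class_name,
                h.start,
                h.end,
                h.matched_sequence,
                ",".join(map(str, h.theta_positions)),
                ",".join(map(str, h.phi_positions)),
                status,
                h.pssm_score,
                h.external_score,
            )
        )
    return pd.DataFrame(rows, columns=HIT_TABLE_COLUMNS)


# ---------------------------------------------------------------------------
# YAML class-definition schema


def classes_to_yaml(classes: Sequence[MotifClassDef], path: str | Path) -> None:
    payload = []
    for c in classes:
        payload.append(
            {
                "name": c.name,
                "theta_range": list(c.theta_range),
                "linker_range": list(c.linker_range),
                "spacing": c.spacing,
                "theta_alphabet": "".join(sorted(c.theta_alphabet)),
                "phi_l": "".join(sorted(c.phi_l)),
                "phi_a": "".join(sorted(c.phi_a)),
                "phi_b": "".join(sorted(c.phi_b)),
                "strictness": c.strictness,
                "extra_constraints": {
                    int(off): "".join(sorted(aset)) for off, aset in c.extra_constraints
                },
            }
        )
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def classes_from_yaml(path: str | Path) -> list[MotifClassDef]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    classes = []
    for item in payload:
        classes.append(
            MotifClassDef(
                name=item["name"],
                theta_range=tuple(item["theta_range"]),
                linker_range=tuple(item["linker_range"]),
                spacing=int(item["spacing"]),
                theta_alphabet=frozenset(item["theta_alphabet"]),
                phi_l=frozenset(item["phi_l"]),
                phi_a=frozenset(item["phi_a"]),
                phi_b=frozenset(item["phi_b"]),
                strictness=item.get("strictness", "loose"),
                extra_constraints=tuple(
                    (int(off), frozenset(aset))
                    for off, aset in sorted(item.get("extra_constraints", {}).items())
                ),
            )
        )
    return classes


def class_by_name(classes: Sequence[MotifClassDef], name: str) -> MotifClassDef:
    for c in classes:
        if c.name == name:
            return c
    raise KeyError(f"unknown motif class {name!r}")
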