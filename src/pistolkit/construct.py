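"""Assembly of trans-acting pistol ribozyme constructs.

A construct is the scaffold core flanked by two substrate-binding arms
computed as exact reverse complements of the target flanks around the
chosen GU site: the P3 arm binds the ``p3_len`` nucleotides ending at the
G, the P1 arm the ``p1_len`` nucleotides starting at the U, so the GU sits
at the junction between the two intermolecular duplexes and the assembled
ribozyme strand reads ``p1_arm + core + p3_arm`` (5'->3', antiparallel to
the substrate).  Constructs are named ``PS<position>-<p3_len>`` after the
lead-variant convention.  The catalytically dead M5 control differs from
its parent at exactly the two catalytic core positions (G -> U, C -> A)
and binds the substrate identically.

Cleavage is simulated 3' of the G by default (configurable), annotating
the products with the pistol chemistry: the 5' fragment ends in a
2',3'-cyclic phosphate, the 3' fragment starts with a 5'-hydroxyl.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from .errors import ConfigError, CoordinateError, NoSiteError, ScaffoldIntegrityError
from .scaffold import PistolScaffold
from .scanner import CleavageSite, _frame_sequence, binding_footprint
from .seq_io import Transcript, reverse_complement

__all__ = [
    "RibozymeConstruct",
    "CleavageProducts",
    "CleavageOutcome",
    "build_construct",
    "arm_length_series",
    "make_inactive_mutant",
    "simulate_cleavage",
    "render_dot_bracket",
    "parse_dot_bracket",
]

MIN_ARM_LEN = 4
MAX_ARM_LEN = 40

_COMPLEMENTARY = {("G", "C"), ("C", "G"), ("A", "U"), ("U", "A")}


@dataclass(frozen=True)
class RibozymeConstruct:
    name: str
    target_id: str
    site: CleavageSite
    p1_arm: str
    p3_arm: str
    full_sequence: str
    variant: str = "active"  # "active" | "M5"
    scaffold_name: str = ""
    predicted_duplex: str = ""

    @property
    def p3_length(self) -> int:
        return len(self.p3_arm)

    @property
    def p1_length(self) -> int:
        return len(self.p1_arm)

    @property
    def core(self) -> str:
        return self.full_sequence[self.p1_length : len(self.full_sequence) - self.p3_length]

    def footprint(self) -> str:
        """Substrate-strand segment the arms hybridise to (GU at the junction)."""
        return binding_footprint(self.p1_arm, self.p3_arm)


@dataclass(frozen=True)
class CleavageProducts:
    fragment5: str
    fragment3: str
    cut_after: int  # 1-based substrate index of the last base of fragment5
    end5_chemistry: str = "2',3'-cyclic phosphate"
    end3_chemistry: str = "5'-hydroxyl"


@dataclass(frozen=True)
class CleavageOutcome:
    """Explicit result of a simulated cleavage; M5 yields cleaved=False."""

    cleaved: bool
    products: Optional[CleavageProducts] = None
    reason: str = ""


def build_construct(scaffold: PistolScaffold, target: Transcript, site: CleavageSite,
                    p1_len: int | None = None, p3_len: int = 16,
                    name_prefix: str = "PS") -> RibozymeConstruct:
    """Design a construct against one GU site; deterministic in its inputs."""
    p1_len = scaffold.default_p1_len if p1_len is None else p1_len
    for label, val in (("p1_len", p1_len), ("p3_len", p3_len)):
        if not MIN_ARM_LEN <= val <= MAX_ARM_LEN:
            raise ConfigError(f"{label}={val} outside configured range "
                              f"[{MIN_ARM_LEN}, {MAX_ARM_LEN}]")
    seq = _frame_sequence(target, site.frame)
    p = site.position
    if not (p >= 1 and p + 1 <= len(seq) and seq[p - 1 : p + 1] == "GU"):
        raise NoSiteError(f"no GU dinucleotide at {site.frame} position {p} of {target.id!r}")
    if p - p3_len < 0 or p + p1_len > len(seq):
        raise CoordinateError(
            f"arm footprint [{p - p3_len + 1}, {p + p1_len}] beyond sequence ends (1..{len(seq)})"
        )
    upstream = seq[p - p3_len : p]          # ends at the G
    downstream = seq[p : p + p1_len]        # starts at the U
    p3_arm = reverse_complement(upstream)
    p1_arm = reverse_complement(downstream)
    full = p1_arm + scaffold.core + p3_arm
    construct = RibozymeConstruct(
        name=f"{name_prefix}{p}-{p3_len}",
        target_id=target.id,
        site=site,
        p1_arm=p1_arm,
        p3_arm=p3_arm,
        full_sequence=full,
        scaffold_name=scaffold.name,
    )
    duplex = render_dot_bracket(construct, upstream + downstream, scaffold)
    return replace(construct, predicted_duplex=duplex)


def arm_length_series(scaffold: PistolScaffold, target: Transcript, site: CleavageSite,
                      p3_range: tuple[int, int] = (14, 18),
                      p1_len: int | None = None) -> list[RibozymeConstruct]:
    """One construct per P3 arm length in the inclusive range, name-suffixed."""
    lo, hi = p3_range
    return [
        build_construct(scaffold, target, site, p1_len=p1_len, p3_len=L)
        for L in range(lo, hi + 1)
    ]


def make_inactive_mutant(construct: RibozymeConstruct,
                         scaffold: PistolScaffold) -> RibozymeConstruct:
    """The M5 catalytic-dead control: G -> U and C -> A at the catalytic core
    positions, everything else (arms included) byte-identical."""
    if construct.variant != "active":
        raise ConfigError(f"construct {construct.name} is already an inactive variant")
    seq = list(construct.full_sequence)
    offset = construct.p1_length
    for core_pos, expected, mutant in ((scaffold.catalytic_g, "G", "U"),
                                       (scaffold.catalytic_c, "C", "A")):
        idx = offset + core_pos - 1
        if seq[idx] != expected:
            raise ScaffoldIntegrityError(
                f"position {core_pos} of scaffold {scaffold.name!r} carries "
                f"{seq[idx]}, expected {expected}"
            )
        seq[idx] = mutant
    return replace(construct, full_sequence="".join(seq), variant="M5",
                   name=construct.name + "-M5")


def simulate_cleavage(construct: RibozymeConstruct, substrate: str,
                      cut_offset: int = 0) -> CleavageOutcome:
    """Split a substrate at the construct's scissile position.

    ``cut_offset`` shifts the cut relative to the default (3' of the G):
    0 cuts between G and U, 1 cuts 3' of the U.  The substrate must
    contain the construct's binding footprint; an M5 construct binds but
    returns an explicit no-cleavage outcome.
    """
    footprint = construct.footprint()
    idx = substrate.find(footprint)
    if idx == -1:
        raise NoSiteError(
            f"substrate does not contain the binding footprint of {construct.name}"
        )
    if construct.variant != "active":
        return CleavageOutcome(False, reason=f"{construct.variant} variant is catalytically dead")
    cut_after = idx + construct.p3_length + cut_offset  # 1-based index of last 5'-fragment base
    if not 0 < cut_after < len(substrate):
        raise CoordinateError(f"scissile position {cut_after} outside substrate")
    return CleavageOutcome(
        True,
        CleavageProducts(
            fragment5=substrate[:cut_after],
            fragment3=substrate[cut_after:],
            cut_after=cut_after,
        ),
    )


def render_dot_bracket(construct: RibozymeConstruct, substrate: str,
                       scaffold: PistolScaffold) -> str:
    """Dot-bracket of the ribozyme-substrate complex, strands joined by '&'.

    Arm positions are shown paired only where the substrate base is
    Watson-Crick complementary (a mismatched, e.g. poly-A, region renders
    unpaired); scaffold P2 pairs use parentheses and pseudoknot pairs
    square brackets.  The footprint is registered on the substrate at the
    offset with the fewest mismatches (leftmost on ties).
    """
    ribo = construct.full_sequence
    footprint = construct.footprint()
    f_idx = _best_alignment(substrate, footprint)
    n_r, n_s = len(ribo), len(substrate)
    rb, sb = ["."] * n_r, ["."] * n_s
    p1, p3 = construct.p1_length, construct.p3_length

    def try_pair(ri: int, si: int) -> None:
        if 0 <= si < n_s and (ribo[ri], substrate[si]) in _COMPLEMENTARY:
            rb[ri], sb[si] = "(", ")"

    for a in range(p1):  # P1 arm vs downstream footprint, antiparallel
        try_pair(a, f_idx + p3 + p1 - 1 - a)
    for b in range(p3):  # P3 arm vs upstream footprint
        try_pair(n_r - p3 + b, f_idx + p3 - 1 - b)
    for i, j in scaffold.p2_pairs:
        rb[p1 + i - 1], rb[p1 + j - 1] = "(", ")"
    for i, j in scaffold.pseudoknot_pairs:
        rb[p1 + i - 1], rb[p1 + j - 1] = "[", "]"
    return f"{ribo}&{substrate}\n{''.join(rb)}&{''.join(sb)}"


def _best_alignment(substrate: str, footprint: str) -> int:
    if len(substrate) < len(footprint):
        raise NoSiteError("substrate shorter than the binding footprint")
    best_idx, best_matches = 0, -1
    for idx in range(len(substrate) - len(footprint) + 1):
        matches = sum(a == b for a, b in zip(substrate[idx:], footprint))
        if matches > best_matches:
            best_idx, best_matches = idx, matches
    return best_idx


def parse_dot_bracket(text: str) -> set[tuple[int, int]]:
    """Pair set from a (possibly multi-strand) dot-bracket annotation.

    Accepts the two-line ``sequence\\n structure`` form emitted by
    :func:`render_dot_bracket`; returns 0-based position pairs on the
    concatenated coordinates with '&' separators excluded.
    """
    line = text.splitlines()[-1]
    stacks: dict[str, list[int]] = {"(": [], "[": []}
    closers = {")": "(", "]": "["}
    pairs = set()
    pos = 0
    for ch in line:
        if ch == "&":
            continue
        if ch in stacks:
            stacks[ch].append(pos)
        elif ch in closers:
            if not stacks[closers[ch]]:
                raise ConfigError(f"unbalanced {ch!r} in dot-bracket")
            pairs.add((stacks[closers[ch]].pop(), pos))
        pos += 1
    if any(s for s in stacks.values()):
        raise ConfigError("unbalanced opening bracket in dot-bracket")
    return pairs
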