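"""Pistol scaffold definitions loaded from structured text files.

The scaffold is configuration data, not code: a file declares the core
sequence (the catalytic strand between the two substrate-binding arm
slots), the intramolecular P2 stem and pseudoknot pair lists, conserved
positions, and — crucially — its own numbering for the two catalytic
positions whose mutation (G -> U, C -> A) yields the inactive M5 control.
The bundled default is a synthetic pistol-like core (see
``data/scaffold_synthetic.txt``); users supply their own file for a real
construct.

File format: ``key: value`` lines, ``#`` comments.  Pair lists are comma
separated ``i-j`` entries; conserved positions are ``i=BASE`` entries.
All indices are 1-based within ``core``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .errors import FormatError, ScaffoldIntegrityError
from .seq_io import normalize_rna

__all__ = ["PistolScaffold", "load_scaffold", "default_scaffold"]

_WC_AND_WOBBLE = {("G", "C"), ("C", "G"), ("A", "U"), ("U", "A"), ("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class PistolScaffold:
    """A trans-pistol catalytic core with arm slots at both ends.

    The assembled ribozyme is ``p1_arm + core + p3_arm`` (5'->3'), so the
    P1 arm pairs with the substrate segment 3' of the cleavage site and
    the P3 arm with the segment 5' of it, antiparallel.  ``catalytic_g``
    and ``catalytic_c`` are 1-based core positions.
    """

    name: str
    core: str
    p2_pairs: tuple[tuple[int, int], ...]
    pseudoknot_pairs: tuple[tuple[int, int], ...]
    conserved: tuple[tuple[int, str], ...]
    catalytic_g: int
    catalytic_c: int
    default_p1_len: int = 8

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        n = len(self.core)
        for idx, expected in ((self.catalytic_g, "G"), (self.catalytic_c, "C")):
            if not 1 <= idx <= n:
                raise ScaffoldIntegrityError(f"catalytic position {idx} outside core (1..{n})")
            if self.core[idx - 1] != expected:
                raise ScaffoldIntegrityError(
                    f"core position {idx} carries {self.core[idx-1]}, expected {expected}"
                )
        for idx, base in self.conserved:
            if self.core[idx - 1] != base:
                raise ScaffoldIntegrityError(
                    f"conserved position {idx} carries {self.core[idx-1]}, expected {base}"
                )
        seen: set[int] = set()
        for i, j in self.p2_pairs + self.pseudoknot_pairs:
            if not (1 <= i < j <= n):
                raise ScaffoldIntegrityError(f"pair {i}-{j} outside core")
            if i in seen or j in seen:
                raise ScaffoldIntegrityError(f"position in pair {i}-{j} used by more than one pair")
            seen.update((i, j))
            if (self.core[i - 1], self.core[j - 1]) not in _WC_AND_WOBBLE:
                raise ScaffoldIntegrityError(
                    f"pair {i}-{j} ({self.core[i-1]}-{self.core[j-1]}) is not WC or GU wobble"
                )

    @property
    def stems(self) -> dict[str, tuple[tuple[int, int], ...]]:
        """Named intramolecular stems; P1/P3 are intermolecular, built per target."""
        return {"P2": self.p2_pairs}


def _parse_pairs(text: str) -> tuple[tuple[int, int], ...]:
    pairs = []
    for item in filter(None, (p.strip() for p in text.split(","))):
        i, j = item.split("-")
        pairs.append((int(i), int(j)))
    return tuple(pairs)


def load_scaffold(path: str | Path) -> PistolScaffold:
    """Parse a scaffold file; structural declarations are validated on load."""
    fields: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if ":" not in stripped:
            raise FormatError(f"{path}:{lineno}: expected 'key: value'")
        key, _, value = stripped.partition(":")
        fields[key.strip()] = value.strip()
    try:
        conserved = tuple(
            (int(item.split("=")[0]), item.split("=")[1])
            for item in filter(None, (c.strip() for c in fields.get("conserved", "").split(",")))
        )
        return PistolScaffold(
            name=fields["name"],
            core=normalize_rna(fields["core"]),
            p2_pairs=_parse_pairs(fields.get("p2_pairs", "")),
            pseudoknot_pairs=_parse_pairs(fields.get("pseudoknot_pairs", "")),
            conserved=conserved,
            catalytic_g=int(fields["catalytic_g"]),
            catalytic_c=int(fields["catalytic_c"]),
            default_p1_len=int(fields.get("default_p1_len", 8)),
        )
    except KeyError as exc:
        raise FormatError(f"scaffold file {path} missing required key {exc}") from exc


def default_scaffold() -> PistolScaffold:
    """The bundled synthetic pistol-like scaffold."""
    ref = resources.files("pistolkit.data").joinpath("scaffold_synthetic.txt")
    with resources.as_file(ref) as path:
        return load_scaffold(path)
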