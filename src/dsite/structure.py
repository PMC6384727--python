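"""Secondary-structure prediction and dot-bracket handling.

The structure encoder consumes a dot-bracket string for each window.  Two
engines produce it:

* ``"vienna"`` — minimum-free-energy fold from the ViennaRNA thermodynamic
  engine at default parameters (requires the ``RNA`` python bindings).
* ``"nussinov"`` — a builtin maximum base-pairing folder (Watson-Crick + GU
  wobble, minimum hairpin loop 3) with deterministic traceback; it keeps the
  test suite free of external binaries while preserving the dot-bracket
  contract.

For the encoder, opening and closing brackets are not distinguished: a
"collapsed" structure rewrites every ``)`` as ``(``, so each position is
simply paired or unpaired.

Pseudoknots are never produced; structures are strictly nested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

logger = logging.getLogger("dsite")

RNA_ALPHABET = frozenset("ACGU")

#: canonical pairs admitted by the builtin folder
CANONICAL_PAIRS = frozenset({"AU", "UA", "GC", "CG", "GU", "UG"})

#: engine version the original protocol pinned; a mismatch only warns
REFERENCE_VIENNA_VERSION = "2.1.9"

_version_warned = False


class StructureError(ValueError):
    pass


@dataclass(frozen=True)
class DotBracket:
    """A nested secondary structure over {'(', ')', '.'} with provenance."""

    text: str
    engine: str

    def __post_init__(self) -> None:
        depth = 0
        for ch in self.text:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
            elif ch != ".":
                raise StructureError(f"invalid dot-bracket character {ch!r}")
            if depth < 0:
                raise StructureError(f"unbalanced brackets in {self.text!r}")
        if depth != 0:
            raise StructureError(f"unbalanced brackets in {self.text!r}")

    @property
    def n_pairs(self) -> int:
        return self.text.count("(")

    def __len__(self) -> int:
        return len(self.text)


@dataclass(frozen=True)
class CollapsedStructure:
    """Dot-bracket with ')' rewritten as '(' — paired/unpaired only."""

    text: str

    def __post_init__(self) -> None:
        bad = set(self.text) - {"(", "."}
        if bad:
            raise StructureError(f"invalid collapsed character(s) {sorted(bad)!r}")

    def __len__(self) -> int:
        return len(self.text)


def collapse_brackets(db: DotBracket) -> CollapsedStructure:
    """Rewrite every closing bracket as an opening one; dots unchanged."""
    return CollapsedStructure(db.text.replace(")", "("))


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise StructureError("empty sequence")
    bad = set(sequence) - RNA_ALPHABET
    if bad:
        raise StructureError(f"invalid character(s) {sorted(bad)!r} in sequence")


def nussinov_fold(sequence: str, min_loop: int = 3) -> DotBracket:
    """Maximum base-pairing fold (Nussinov dynamic program).

    Maximizes the number of Watson-Crick + GU wobble pairs subject to
    nesting and a minimum hairpin loop of ``min_loop`` unpaired bases
    (``|i - j| > min_loop``).  Traceback is deterministic: among optimal
    structures it pairs the smallest available 5' index first, with the
    smallest admissible partner.
    """
    _check_sequence(sequence)
    return DotBracket(_nussinov_text(sequence, min_loop), engine="builtin-nussinov")


@lru_cache(maxsize=16384)  # jackknife refolds the same windows n times
def _nussinov_text(sequence: str, min_loop: int) -> str:
    n = len(sequence)
    can_pair = lambda i, j: sequence[i] + sequence[j] in CANONICAL_PAIRS

    # N[i][j] = max pairs within i..j inclusive
    N = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = N[i + 1][j]  # i unpaired
            for k in range(i + min_loop + 1, j + 1):
                if can_pair(i, k):
                    left = N[i + 1][k - 1] if k - i > 1 else 0
                    right = N[k + 1][j] if k < j else 0
                    best = max(best, 1 + left + right)
            N[i][j] = best

    struct = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or N[i][j] == 0:
            continue
        paired = False
        for k in range(i + min_loop + 1, j + 1):  # smallest partner first
            if can_pair(i, k):
                left = N[i + 1][k - 1] if k - i > 1 else 0
                right = N[k + 1][j] if k < j else 0
                if 1 + left + right == N[i][j]:
                    struct[i], struct[k] = "(", ")"
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    paired = True
                    break
        if not paired:
            stack.append((i + 1, j))
    return "".join(struct)


def vienna_fold(sequence: str) -> DotBracket:
    """Minimum-free-energy fold via the ViennaRNA bindings, default params."""
    _check_sequence(sequence)
    try:
        import RNA
    except ImportError as exc:  # pragma: no cover - bindings present in CI env
        raise StructureError(
            "ViennaRNA python bindings not available; use engine='nussinov' "
            "or install the 'RNA' package"
        ) from exc
    global _version_warned
    version = getattr(RNA, "__version__", "unknown")
    if version != REFERENCE_VIENNA_VERSION and not _version_warned:
        logger.warning(
            "ViennaRNA version %s differs from the reference protocol's %s; "
            "folds may differ slightly", version, REFERENCE_VIENNA_VERSION,
        )
        _version_warned = True
    db, _mfe = RNA.fold(sequence)
    return DotBracket(db, engine=f"external-thermodynamic (ViennaRNA {version})")


def fold(sequence: str, engine: str = "nussinov", min_loop: int = 3) -> DotBracket:
    """Fold a sequence with the chosen engine; see module docstring."""
    if engine in ("nussinov", "builtin", "builtin-nussinov"):
        return nussinov_fold(sequence, min_loop=min_loop)
    if engine in ("vienna", "external", "external-thermodynamic"):
        return vienna_fold(sequence)
    raise StructureError(f"unknown folding engine {engine!r}")


def to_ct(sequence: str, db: DotBracket) -> str:
    """Connect-table (CT) export, mainly for debugging structures."""
    if len(sequence) != len(db):
        raise StructureError("sequence/structure length mismatch")
    partner = [0] * len(sequence)
    stack: list[int] = []
    for i, ch in enumerate(db.text):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            j = stack.pop()
            partner[i], partner[j] = j + 1, i + 1
    lines = [f"{len(sequence)}\tdsite"]
    for i, base in enumerate(sequence, start=1):
        lines.append(f"{i}\t{base}\t{i-1}\t{i+1 if i < len(sequence) else 0}\t{partner[i-1]}\t{i}")
    return "\n".join(lines) + "\n"
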