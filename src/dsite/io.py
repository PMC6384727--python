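"""Sequence and label I/O for dihydrouridine-site candidate windows.

A candidate is a 41-nt RNA window with a uridine at the center (position 21,
1-based): the putative D site.  This module reads/writes FASTA and sidecar
label TSVs, extracts windows from transcripts, validates them, and samples
negative (non-modified center-U) windows.

Coordinates are 1-based, closed intervals throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

logger = logging.getLogger("dsite")

WINDOW_LENGTH = 41
FLANK = 20
CENTER = FLANK + 1  # position 21 of 41, 1-based

RNA_ALPHABET = frozenset("ACGU")

POSITIVE = "positive"
NEGATIVE = "negative"
_LABELS = (POSITIVE, NEGATIVE)

# header-token fallback when no sidecar label TSV is given
_HEADER_TOKENS = {"|pos": POSITIVE, "|neg": NEGATIVE}


class WindowError(ValueError):
    """A sequence fails the candidate-window contract."""


@dataclass(frozen=True)
class RnaWindow:
    """A 41-nt candidate sequence with a center uridine.

    Parameters
    ----------
    id : str
        Unique identifier of the window.
    sequence : str
        41-nt RNA sequence over {A, C, G, U}; position 21 is ``U``.
    label : str, optional
        ``"positive"`` (experimentally verified D site) or ``"negative"``.
    source : (str, int), optional
        Transcript id and 1-based center position the window was cut from.
    """

    id: str
    sequence: str
    label: Optional[str] = None
    source: Optional[tuple[str, int]] = None


@dataclass
class Dataset:
    """An ordered collection of :class:`RnaWindow` with provenance metadata."""

    windows: list[RnaWindow]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [w.id for w in self.windows]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise WindowError(f"duplicate window id {dup!r} in dataset")

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def labels(self) -> list[Optional[str]]:
        return [w.label for w in self.windows]


def read_fasta(path: str | Path, normalize: bool = True) -> list[tuple[str, str]]:
    """Read a FASTA file into ``(id, sequence)`` pairs, order preserved.

    Sequences are uppercased; with ``normalize`` (default) DNA-style ``T`` is
    converted to ``U``.  Any other non-ACGU character raises, naming the
    record and the offending character — ambiguity codes are rejected rather
    than silently encoded.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise WindowError(f"no FASTA records found in {path}")
    out: list[tuple[str, str]] = []
    for rec in records:
        seq = str(rec.seq).upper()
        if normalize:
            seq = seq.replace("T", "U")
        bad = set(seq) - RNA_ALPHABET
        if bad:
            raise WindowError(
                f"record {rec.id!r}: invalid character(s) {sorted(bad)!r} "
                "(expected A/C/G/U" + ("/T" if normalize else "") + ")"
            )
        out.append((rec.id, seq))
    return out


def validate_window(
    id: str,
    sequence: str,
    label: Optional[str] = None,
    source: Optional[tuple[str, int]] = None,
) -> RnaWindow:
    """Check the window contract (length 41, center U, ACGU alphabet)."""
    if label is not None and label not in _LABELS:
        raise WindowError(f"window {id!r}: unknown label {label!r}")
    if len(sequence) != WINDOW_LENGTH:
        raise WindowError(
            f"window {id!r}: length {len(sequence)}, expected {WINDOW_LENGTH}"
        )
    bad = set(sequence) - RNA_ALPHABET
    if bad:
        raise WindowError(f"window {id!r}: invalid character(s) {sorted(bad)!r}")
    if sequence[CENTER - 1] != "U":
        raise WindowError(
            f"window {id!r}: center position {CENTER} is "
            f"{sequence[CENTER - 1]!r}, expected 'U'"
        )
    return RnaWindow(id=id, sequence=sequence, label=label, source=source)


def extract_window(
    transcript: tuple[str, str],
    center: int,
    flank: int = FLANK,
    label: Optional[str] = None,
) -> Optional[RnaWindow]:
    """Cut the window ``center-flank .. center+flank`` (1-based, closed).

    Returns ``None`` (with a logged warning) when the window would run off
    either transcript end — boundary windows are skipped, never padded.
    Raises if the centered base is not U.
    """
    tid, seq = transcript
    if not 1 <= center <= len(seq):
        raise WindowError(f"{tid}: center {center} outside transcript (len {len(seq)})")
    if seq[center - 1] != "U":
        raise WindowError(
            f"{tid}: position {center} is {seq[center - 1]!r}, expected 'U'"
        )
    lo, hi = center - flank, center + flank
    if lo < 1 or hi > len(seq):
        logger.warning(
            "%s: window %d..%d overlaps transcript boundary (len %d); skipped",
            tid, lo, hi, len(seq),
        )
        return None
    window = seq[lo - 1 : hi]
    return validate_window(
        f"{tid}:{center}", window, label=label, source=(tid, center)
    )


def sample_negatives(
    transcripts: Iterable[tuple[str, str]],
    known_sites: set[tuple[str, int]],
    n: int,
    seed: int,
) -> list[RnaWindow]:
    """Sample ``n`` center-U windows whose centers are not known D sites.

    Candidates are every full-flank window with a centered U whose
    ``(transcript id, center)`` is absent from ``known_sites``; ``n`` of them
    are drawn uniformly without replacement.  Identical seed, identical output.
    """
    import numpy as np

    if n < 1:
        raise WindowError(f"n must be >= 1, got {n}")
    pool: list[tuple[str, str, int]] = []
    for tid, seq in transcripts:
        for pos in range(CENTER, len(seq) - FLANK + 1):  # full flanks only
            if seq[pos - 1] == "U" and (tid, pos) not in known_sites:
                pool.append((tid, seq, pos))
    if len(pool) < n:
        raise WindowError(
            f"only {len(pool)} eligible negative windows available, need {n}"
        )
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(pool), size=n, replace=False)
    out = []
    for k in picks:
        tid, seq, pos = pool[int(k)]
        w = extract_window((tid, seq), pos, label=NEGATIVE)
        assert w is not None  # pool guarantees full flanks
        out.append(w)
    return out


# ---------------------------------------------------------------------------
# Dataset round-trip: FASTA (60-col wrap) + sidecar TSVs
# ---------------------------------------------------------------------------

def write_dataset(
    dataset: Dataset,
    fasta_path: str | Path,
    labels_path: Optional[str | Path] = None,
    sources_path: Optional[str | Path] = None,
) -> None:
    """Write windows as FASTA plus optional label / provenance TSVs."""
    with open(fasta_path, "w") as fh:
        for w in dataset:
            fh.write(f">{w.id}\n")
            for i in range(0, len(w.sequence), 60):
                fh.write(w.sequence[i : i + 60] + "\n")
    if labels_path is not None:
        with open(labels_path, "w") as fh:
            fh.write("id\tlabel\n")
            for w in dataset:
                if w.label is not None:
                    fh.write(f"{w.id}\t{w.label}\n")
    if sources_path is not None:
        with open(sources_path, "w") as fh:
            fh.write("id\ttranscript\tcenter\n")
            for w in dataset:
                if w.source is not None:
                    fh.write(f"{w.id}\t{w.source[0]}\t{w.source[1]}\n")


def read_labels(labels_path: str | Path) -> dict[str, str]:
    labels: dict[str, str] = {}
    with open(labels_path) as fh:
        header = fh.readline()
        if not header.rstrip("\n").split("\t")[:2] == ["id", "label"]:
            raise WindowError(f"{labels_path}: expected header 'id<TAB>label'")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise WindowError(f"{labels_path}: malformed line {line!r}")
            wid, label = fields
            if label not in _LABELS:
                raise WindowError(f"{labels_path}: unknown label {label!r} for {wid!r}")
            labels[wid] = label
    return labels


def read_dataset(
    fasta_path: str | Path,
    labels_path: Optional[str | Path] = None,
    normalize: bool = True,
) -> Dataset:
    """Read windows from FASTA, labels from a sidecar TSV.

    Without a TSV, a trailing ``|pos`` / ``|neg`` token in the record id is
    honored as a fallback label encoding (and stripped from the id).
    """
    labels = read_labels(labels_path) if labels_path is not None else None
    windows = []
    for rid, seq in read_fasta(fasta_path, normalize=normalize):
        label = None
        if labels is not None:
            label = labels.get(rid)
        else:
            for token, lab in _HEADER_TOKENS.items():
                if rid.endswith(token):
                    rid, label = rid[: -len(token)], lab
                    break
        windows.append(validate_window(rid, seq, label=label))
    return Dataset(windows, metadata={"fasta": str(fasta_path)})
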