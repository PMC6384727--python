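"""The three feature encodings feeding the base predictors.

NPCP — nucleotide physicochemical property.  Each base maps to a 3-bit code
(ring count, hydrogen-bond strength, amino/keto class):
A=(1,1,1), C=(0,0,1), G=(1,0,0), U=(0,1,0).  A 41-nt window becomes a
123-dimensional binary vector.

PseDNC — pseudo dinucleotide composition.  16 dinucleotide frequencies f_u
plus lambda correlation tiers theta_j, combined as

    d_u = f_u / (sum f + w * sum theta)          for u <= 16
    d_u = w * theta_{u-16} / (sum f + w * sum theta)  otherwise

where theta_j averages the coupling factor C between dinucleotides j apart,
and C is the mean squared difference of their standardized physicochemical
property values.  At the defaults (w=0.5, lambda=4) the vector has 20 entries
and always sums to 1.

SSC — secondary structure component.  The window is folded, brackets are
collapsed (paired/unpaired only), and every overlapping trinucleotide yields
a mode = (first-nucleotide identity, 3-character structure status): 4 x 8 =
32 modes, counted and normalized to frequencies.

Mode ordering is fixed (nucleotide-major A,C,G,U; statuses from all-paired
to all-unpaired) so feature matrices and trained models are portable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .io import RnaWindow
from .physchem import DINUCLEOTIDES, DinucleotidePropertyTable, load_property_table
from .structure import CollapsedStructure, collapse_brackets, fold

#: 3-bit code per base: (ring structure, hydrogen bond, amino/keto)
NPCP_CODE: dict[str, tuple[int, int, int]] = {
    "A": (1, 1, 1),
    "C": (0, 0, 1),
    "G": (1, 0, 0),
    "U": (0, 1, 0),
}

#: the 8 collapsed trinucleotide structure statuses, canonical order
SSC_STATUSES: tuple[str, ...] = (
    "(((", "((.", "(..", "(.(", ".((", ".(.", "..(", "...",
)

#: the 32 sequence-structure modes, nucleotide-major
SSC_MODES: tuple[str, ...] = tuple(
    f"{nt}-{st}" for nt in "ACGU" for st in SSC_STATUSES
)

FEATURE_KINDS = ("NPCP", "PseDNC", "SSC")

_DINUC_INDEX = {d: i for i, d in enumerate(DINUCLEOTIDES)}
_STATUS_INDEX = {s: i for i, s in enumerate(SSC_STATUSES)}


class EncodingError(ValueError):
    pass


def _seq(window: Union[RnaWindow, str]) -> str:
    return window.sequence if isinstance(window, RnaWindow) else window


@dataclass
class EncoderContext:
    """Everything needed to encode windows reproducibly.

    Bundled so that a trained model can be applied to new windows with the
    exact encoding it was trained with (same property table, same folding
    engine, same parameters).
    """

    table: DinucleotidePropertyTable = field(default_factory=load_property_table)
    w: float = 0.5
    lam: int = 4
    freq_mode: str = "overlapping"
    engine: str = "nussinov"
    min_loop: int = 3

    def provenance(self) -> dict:
        return {
            "property_table_hash": self.table.content_hash(),
            "w": self.w,
            "lambda": self.lam,
            "freq_mode": self.freq_mode,
            "engine": self.engine,
            "min_loop": self.min_loop,
        }


# ---------------------------------------------------------------------------
# NPCP
# ---------------------------------------------------------------------------

def encode_npcp(window: Union[RnaWindow, str]) -> np.ndarray:
    """Per position, the 3-bit physicochemical code; length 3L (123 for 41)."""
    seq = _seq(window)
    try:
        bits = [b for ch in seq for b in NPCP_CODE[ch]]
    except KeyError as exc:
        raise EncodingError(f"invalid character {exc.args[0]!r} in sequence") from None
    return np.array(bits, dtype=float)


# ---------------------------------------------------------------------------
# PseDNC
# ---------------------------------------------------------------------------

def dinucleotide_frequencies(
    sequence: Union[RnaWindow, str], mode: str = "overlapping"
) -> np.ndarray:
    """Normalized frequencies of the 16 dinucleotides (sum 1).

    ``overlapping`` counts the L-1 adjacent pairs; ``nonoverlapping`` counts
    the floor(L/2) pairs starting at odd (1-based) positions.
    """
    seq = _seq(sequence)
    if len(seq) < 2:
        raise EncodingError(f"need length >= 2 for dinucleotides, got {len(seq)}")
    if mode == "overlapping":
        starts: Iterable[int] = range(len(seq) - 1)
    elif mode == "nonoverlapping":
        starts = range(0, len(seq) - 1, 2)
    else:
        raise EncodingError(f"unknown frequency mode {mode!r}")
    counts = np.zeros(16)
    for i in starts:
        try:
            counts[_DINUC_INDEX[seq[i : i + 2]]] += 1
        except KeyError:
            raise EncodingError(f"invalid dinucleotide {seq[i:i+2]!r}") from None
    return counts / counts.sum()


def coupling_factor(
    table: DinucleotidePropertyTable, d1: str, d2: str
) -> float:
    """Mean squared difference of standardized property values (symmetric, >=0)."""
    try:
        p1, p2 = table.standardized[d1], table.standardized[d2]
    except KeyError as exc:
        raise EncodingError(f"unknown dinucleotide {exc.args[0]!r}") from None
    return float(np.mean((p1 - p2) ** 2))


def theta_correlation(
    sequence: Union[RnaWindow, str], j: int, table: DinucleotidePropertyTable
) -> float:
    """j-tier sequence-order correlation: mean coupling factor at lag j.

    Averages C(D_i, D_{i+j}) over the L-j-1 positions where both
    dinucleotides exist.
    """
    seq = _seq(sequence)
    n_terms = len(seq) - j - 1
    if j < 1 or n_terms < 1:
        raise EncodingError(
            f"tier j={j} invalid for sequence length {len(seq)} (need 1 <= j <= L-2)"
        )
    total = 0.0
    for i in range(n_terms):
        total += coupling_factor(table, seq[i : i + 2], seq[i + j : i + j + 2])
    return total / n_terms


def encode_psednc(
    window: Union[RnaWindow, str],
    table: Optional[DinucleotidePropertyTable] = None,
    w: float = 0.5,
    lam: int = 4,
    mode: str = "overlapping",
) -> np.ndarray:
    """Pseudo dinucleotide composition vector of length 16 + lambda."""
    seq = _seq(window)
    if table is None:
        table = load_property_table()
    if not 0 <= w <= 1:
        raise EncodingError(f"weight w must be in [0, 1], got {w}")
    if lam < 1 or lam > len(seq) - 2:
        raise EncodingError(
            f"lambda={lam} out of range for sequence length {len(seq)}"
        )
    f = dinucleotide_frequencies(seq, mode=mode)
    theta = np.array([theta_correlation(seq, j, table) for j in range(1, lam + 1)])
    denom = f.sum() + w * theta.sum()
    return np.concatenate([f / denom, w * theta / denom])


# ---------------------------------------------------------------------------
# SSC
# ---------------------------------------------------------------------------

def encode_ssc(
    window: Union[RnaWindow, str], collapsed: CollapsedStructure
) -> np.ndarray:
    """Frequencies of the 32 sequence-structure modes over the L-2 windows."""
    seq = _seq(window)
    if len(collapsed) != len(seq):
        raise EncodingError(
            f"structure length {len(collapsed)} != sequence length {len(seq)}"
        )
    if len(seq) < 3:
        raise EncodingError("need length >= 3 for trinucleotide modes")
    counts = np.zeros(32)
    nt_index = {"A": 0, "C": 1, "G": 2, "U": 3}
    for i in range(len(seq) - 2):
        try:
            nt = nt_index[seq[i]]
        except KeyError:
            raise EncodingError(f"invalid character {seq[i]!r}") from None
        counts[nt * 8 + _STATUS_INDEX[collapsed.text[i : i + 3]]] += 1
    return counts / (len(seq) - 2)


def encode_ssc_window(window: Union[RnaWindow, str], ctx: EncoderContext) -> np.ndarray:
    """Fold the window with the context's engine, collapse, and encode."""
    seq = _seq(window)
    db = fold(seq, engine=ctx.engine, min_loop=ctx.min_loop)
    return encode_ssc(seq, collapse_brackets(db))


# ---------------------------------------------------------------------------
# Feature matrices
# ---------------------------------------------------------------------------

def encode_window(
    window: Union[RnaWindow, str], kind: str, ctx: EncoderContext
) -> np.ndarray:
    if kind == "NPCP":
        return encode_npcp(window)
    if kind == "PseDNC":
        return encode_psednc(
            window, table=ctx.table, w=ctx.w, lam=ctx.lam, mode=ctx.freq_mode
        )
    if kind == "SSC":
        return encode_ssc_window(window, ctx)
    raise EncodingError(f"unknown feature kind {kind!r} (choose from {FEATURE_KINDS})")


def feature_matrix(
    windows: Sequence[Union[RnaWindow, str]], kind: str, ctx: EncoderContext
) -> np.ndarray:
    """Stack per-window encodings into an (n_windows, n_features) matrix."""
    if not windows:
        kind_dim = {"NPCP": 123, "PseDNC": 16 + ctx.lam, "SSC": 32}[kind]
        return np.empty((0, kind_dim))
    return np.vstack([encode_window(w, kind, ctx) for w in windows])


def feature_names(kind: str, ctx: Optional[EncoderContext] = None) -> list[str]:
    if kind == "NPCP":
        return [
            f"pos{p:02d}_{prop}"
            for p in range(1, 42)
            for prop in ("ring", "hbond", "aminoketo")
        ]
    if kind == "PseDNC":
        lam = ctx.lam if ctx is not None else 4
        return [f"f_{d}" for d in DINUCLEOTIDES] + [
            f"theta_{j}" for j in range(1, lam + 1)
        ]
    if kind == "SSC":
        return list(SSC_MODES)
    raise EncodingError(f"unknown feature kind {kind!r}")


def write_feature_tsv(
    path: str | Path,
    ids: Sequence[str],
    X: np.ndarray,
    kind: str,
    ctx: Optional[EncoderContext] = None,
) -> None:
    """Export a feature matrix as TSV with one named column per feature."""
    names = feature_names(kind, ctx)
    if X.shape[1] != len(names):
        raise EncodingError(
            f"matrix has {X.shape[1]} columns, {kind} expects {len(names)}"
        )
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(names) + "\n")
        for wid, row in zip(ids, X):
            fh.write(wid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
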