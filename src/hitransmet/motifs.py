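"""Motif cassette design: PFM scoring, CpG-preserving scrambling, PWM scanning.

A transcription-factor binding motif is summarised by a position frequency
matrix (PFM).  For the methylation assay each wild-type (WT) motif gets a
scrambled (Sc) control that keeps every CG dinucleotide in place (so both
loci expose the same CpGs to the methylation machinery) while destroying the
binding site, plus a pair of 6 bp barcodes whose top or bottom strand is
cytosine-free and therefore invariant under bisulfite conversion.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class MotifDesignError(ValueError):
    """Raised when a design constraint cannot be satisfied."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def cpg_positions(seq: str) -> list[int]:
    """0-based start indices of every CG dinucleotide in ``seq``."""
    return [i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"]


# ---------------------------------------------------------------------------
# PFM


@dataclass(frozen=True)
class PFM:
    """Position frequency matrix with per-column base probabilities.

    ``probs`` has shape (width, 4) with columns ordered A, C, G, T; every
    row sums to 1.
    """

    name: str
    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4 or p.shape[0] < 1:
            raise MotifDesignError(f"PFM {self.name!r}: need a (width, 4) matrix")
        if (p < 0).any():
            raise MotifDesignError(f"PFM {self.name!r}: negative probabilities")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise MotifDesignError(f"PFM {self.name!r}: columns do not sum to 1")
        object.__setattr__(self, "probs", p)

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    def reverse_complement(self) -> "PFM":
        return PFM(self.name, self.probs[::-1, ::-1])


def normalize_pfm(name: str, counts: np.ndarray, pseudocount: float = 0.0) -> PFM:
    """Turn a per-position base-count table into a probability PFM.

    ``counts`` is (width, 4) in A,C,G,T order.  An all-zero column is a
    malformed matrix and raises :class:`MotifDesignError`.
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 2 or c.shape[1] != 4:
        raise MotifDesignError("counts must be a (width, 4) table in A,C,G,T order")
    if (c < 0).any():
        raise MotifDesignError("negative counts")
    totals = c.sum(axis=1)
    if (totals == 0).any():
        raise MotifDesignError(f"PFM {name!r}: all-zero column")
    c = c + pseudocount
    return PFM(name, c / c.sum(axis=1, keepdims=True))


def read_jaspar(path: str | Path) -> list[PFM]:
    """Read a minimal JASPAR-style PFM text file.

    Format: ``>name`` header followed by four rows ``A [ 1 2 ... ]`` (the
    brackets are optional), in any base order.  Counts are normalised to
    probabilities per column.
    """
    pfms: list[PFM] = []
    name = None
    rows: dict[str, list[float]] = {}

    def _flush() -> None:
        if name is None:
            return
        if set(rows) != set(BASES):
            raise MotifDesignError(f"PFM {name!r}: missing base rows")
        counts = np.array([rows[b] for b in BASES], dtype=float).T
        pfms.append(normalize_pfm(name, counts))

    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            _flush()
            name = line[1:].split()[0]
            rows = {}
        else:
            fields = line.replace("[", " ").replace("]", " ").split()
            base = fields[0].upper()
            if base not in _BASE_INDEX:
                raise MotifDesignError(f"unexpected row {line!r}")
            rows[base] = [float(x) for x in fields[1:]]
    _flush()
    return pfms


def write_jaspar(pfms: list[PFM], path: str | Path, scale: int = 100) -> None:
    """Write PFMs in the minimal JASPAR text format (probabilities x scale)."""
    with open(path, "w") as fh:
        for pfm in pfms:
            fh.write(f">{pfm.name}\n")
            for i, b in enumerate(BASES):
                row = " ".join(f"{scale * p:.0f}" for p in pfm.probs[:, i])
                fh.write(f"{b} [ {row} ]\n")


# ---------------------------------------------------------------------------
# Scoring


def _encode(seq: str) -> np.ndarray:
    seq = seq.upper()
    try:
        return np.array([_BASE_INDEX[b] for b in seq], dtype=int)
    except KeyError as exc:
        raise MotifDesignError(f"ambiguous or non-DNA base {exc.args[0]!r}") from exc


def normalized_score(seq: str, pfm: PFM) -> float:
    """Mean over positions of the PFM probability of the observed base.

    The match score at position *i* is the probability the PFM assigns to
    ``seq[i]``; the normalized score is the average over all positions, a
    value in [0, 1].  Consensus sequences of sharp matrices score near 1.
    """
    idx = _encode(seq)
    if len(idx) != pfm.width:
        raise MotifDesignError(
            f"sequence length {len(idx)} != PFM width {pfm.width}"
        )
    return float(pfm.probs[np.arange(pfm.width), idx].mean())


@dataclass(frozen=True)
class ScoredMotif:
    sequence: str
    normalized_score: float
    cpg_positions: tuple[int, ...]

    @classmethod
    def score(cls, seq: str, pfm: PFM) -> "ScoredMotif":
        return cls(seq, normalized_score(seq, pfm), tuple(cpg_positions(seq)))


# ---------------------------------------------------------------------------
# CpG-preserving scrambling


def validate_scramble(wt: str, sc: str) -> bool:
    """True iff ``sc`` is a CpG-preserving permutation of ``wt``.

    Requirements: equal length; identical CG dinucleotide positions (none
    lost, none gained); the bases outside the CG-locked positions are a
    permutation of the WT's bases at those positions.
    """
    if len(wt) != len(sc):
        return False
    if cpg_positions(wt) != cpg_positions(sc):
        return False
    locked = set()
    for i in cpg_positions(wt):
        locked.update((i, i + 1))
    free_wt = sorted(wt[i] for i in range(len(wt)) if i not in locked)
    free_sc = sorted(sc[i] for i in range(len(sc)) if i not in locked)
    return free_wt == free_sc


def scramble_preserving_cpgs(
    wt: str, rng: np.random.Generator, max_iter: int = 10_000
) -> str:
    """Random shuffle of ``wt`` that keeps every CG dinucleotide in place.

    Bases at CG-locked positions stay fixed; the remaining bases are
    permuted.  Draws are rejected (and redrawn) if the permutation creates a
    CG dinucleotide absent from the WT, so CpG number and position are
    conserved exactly.
    """
    wt = wt.upper()
    locked = set()
    for i in cpg_positions(wt):
        locked.update((i, i + 1))
    free_idx = [i for i in range(len(wt)) if i not in locked]
    free_bases = [wt[i] for i in free_idx]
    if not free_idx:
        return wt
    for _ in range(max_iter):
        perm = rng.permutation(len(free_bases))
        out = list(wt)
        for j, i in enumerate(free_idx):
            out[i] = free_bases[perm[j]]
        cand = "".join(out)
        if validate_scramble(wt, cand):
            return cand
    raise MotifDesignError(
        f"no CpG-preserving scramble of {wt!r} found in {max_iter} draws"
    )


def design_scrambled(
    wt: str,
    pfm: PFM,
    rng: np.random.Generator,
    max_iter: int = 10_000,
    min_gap: float = 0.3,
) -> ScoredMotif:
    """Scramble ``wt`` until the normalized score drops by at least ``min_gap``.

    Returns the first accepted draw under the seeded generator (reproducible).
    Raises :class:`MotifDesignError` with the best candidate seen if no
    scramble achieves the gap within ``max_iter`` draws.
    """
    wt_score = normalized_score(wt, pfm)
    best: ScoredMotif | None = None
    for _ in range(max_iter):
        cand = scramble_preserving_cpgs(wt, rng, max_iter=max_iter)
        scored = ScoredMotif.score(cand, pfm)
        if scored.normalized_score <= wt_score - min_gap:
            return scored
        if best is None or scored.normalized_score < best.normalized_score:
            best = scored
    assert best is not None
    raise MotifDesignError(
        f"no scramble with score gap >= {min_gap} found for {wt!r}; best "
        f"candidate {best.sequence!r} scores {best.normalized_score:.3f} "
        f"(WT {wt_score:.3f}, gap {wt_score - best.normalized_score:.3f})"
    )


# ---------------------------------------------------------------------------
# PWM scanning


def _log_odds(pfm: PFM, epsilon: float = 0.01) -> np.ndarray:
    # pseudocount enters the log-odds only; normalized_score uses raw probs
    return np.log2((pfm.probs + epsilon) / 0.25)


def _scan_scores(seq: str, lo: np.ndarray) -> np.ndarray:
    idx = _encode(seq)
    w = lo.shape[0]
    if len(idx) < w:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(idx, w)
    return lo[np.arange(w), windows].sum(axis=1)


def pwm_scan_count(
    seq: str,
    pfm: PFM,
    mode: str = "fractional",
    threshold: float = 0.9,
    both_strands: bool = True,
    epsilon: float = 0.01,
) -> int:
    """Count windows of ``seq`` scoring above a PWM log-odds threshold.

    Log-odds score of a window: sum over positions of
    ``log2((p_i(base) + eps) / 0.25)``.  In ``fractional`` mode the cutoff is
    ``S_min + threshold * (S_max - S_min)`` (the Biostrings ``countPWM``
    min.score convention; ``threshold`` in [0, 1], e.g. 0.9 for "90%").  In
    ``absolute`` mode the cutoff is ``threshold`` itself (the HOMER-style
    screen uses 6).  Both strands are scanned by default; a sequence shorter
    than the matrix width counts zero windows.
    """
    lo = _log_odds(pfm, epsilon)
    if mode == "fractional":
        if not 0.0 <= threshold <= 1.0:
            raise MotifDesignError("fractional threshold must be in [0, 1]")
        s_min = lo.min(axis=1).sum()
        s_max = lo.max(axis=1).sum()
        cutoff = s_min + threshold * (s_max - s_min)
    elif mode == "absolute":
        cutoff = threshold
    else:
        raise MotifDesignError(f"unknown scan mode {mode!r}")
    n = int((_scan_scores(seq, lo) >= cutoff - 1e-12).sum())
    if both_strands:
        n += int((_scan_scores(reverse_complement(seq), lo) >= cutoff - 1e-12).sum())
    return n


# ---------------------------------------------------------------------------
# Cassettes and barcodes


@dataclass(frozen=True)
class MotifCassette:
    """A barcoded motif unit: arm5 + barcode5 + motif + barcode3 + arm3.

    ``variant`` is ``"WT"`` or ``"Sc"``.  Each 6 bp barcode has a
    cytosine-free strand (top strand with no C, or no G so the bottom strand
    carries no C), making it invariant under bisulfite conversion on that
    strand and usable as a recognition anchor after conversion.
    """

    motif_name: str
    variant: str
    barcode5: str
    barcode3: str
    motif: str
    arm5: str = ""
    arm3: str = ""
    normalized_score: float = field(default=float("nan"), compare=False)

    def __post_init__(self) -> None:
        for bc in (self.barcode5, self.barcode3):
            if len(bc) != 6:
                raise MotifDesignError(f"barcode {bc!r} is not 6 bp")
            if not barcode_has_c_free_strand(bc):
                raise MotifDesignError(f"barcode {bc!r} has no cytosine-free strand")
        if self.variant not in ("WT", "Sc"):
            raise MotifDesignError(f"variant must be WT or Sc, got {self.variant!r}")

    @property
    def sequence(self) -> str:
        return self.arm5 + self.barcode5 + self.motif + self.barcode3 + self.arm3

    @property
    def core(self) -> str:
        """barcode5 + motif + barcode3 — the read-classification anchor."""
        return self.barcode5 + self.motif + self.barcode3

    @property
    def label(self) -> str:
        return f"{self.motif_name}_{self.variant}"


def barcode_has_c_free_strand(bc: str) -> bool:
    """One strand cytosine-free: top has no C, or top has no G (bottom C-free)."""
    return "C" not in bc or "G" not in bc


def random_c_free_barcode(rng: np.random.Generator, length: int = 6) -> str:
    """Draw a barcode over {A,G,T} (top strand cytosine-free), no CG possible."""
    return "".join(rng.choice(list("AGT"), size=length))


def design_barcode_pair(
    rng: np.random.Generator,
    pfm_library: list[PFM],
    motif: str,
    motif_name: str,
    arm5: str = "",
    arm3: str = "",
    max_iter: int = 1000,
    threshold: float = 0.9,
) -> tuple[str, str]:
    """Pick 6 bp cytosine-free-strand barcodes passing the cross-motif screen.

    The assembled cassette (arms + barcodes + motif) must contain zero PWM
    hits at the fractional 90% cutoff for every library PFM other than the
    cassette's own; candidate pairs failing the screen are redrawn.
    """
    for _ in range(max_iter):
        b5 = random_c_free_barcode(rng)
        b3 = random_c_free_barcode(rng)
        cassette = arm5 + b5 + motif + b3 + arm3
        if cassette_cross_hits(cassette, pfm_library, motif_name, threshold) == 0:
            return b5, b3
    raise MotifDesignError(
        f"no barcode pair for {motif_name!r} passed the cross-motif screen "
        f"in {max_iter} draws"
    )


def cassette_cross_hits(
    cassette: str,
    pfm_library: list[PFM],
    own_name: str,
    threshold: float = 0.9,
) -> int:
    """Total PWM hits of the cassette against every library PFM except its own."""
    return sum(
        pwm_scan_count(cassette, pfm, "fractional", threshold)
        for pfm in pfm_library
        if pfm.name != own_name
    )


def design_cassette_pair(
    pfm: PFM,
    pfm_library: list[PFM],
    rng: np.random.Generator,
    wt: str | None = None,
    arm5: str = "GCATGC",
    arm3: str = "GCTAGC",
    min_wt_score: float = 0.7,
    min_gap: float = 0.3,
    max_iter: int = 10_000,
) -> tuple[MotifCassette, MotifCassette]:
    """Design the WT and Sc cassettes for one motif.

    The WT sequence defaults to the PFM consensus and must score above
    ``min_wt_score``; the scramble must score at least ``min_gap`` lower.
    Barcodes are shared between the WT and Sc cassettes of a motif, and both
    assembled cassettes must pass the cross-motif collision screen.
    """
    wt = (wt or pfm.consensus()).upper()
    wt_scored = ScoredMotif.score(wt, pfm)
    if wt_scored.normalized_score <= min_wt_score:
        raise MotifDesignError(
            f"WT motif {wt!r} scores {wt_scored.normalized_score:.3f} "
            f"<= {min_wt_score} against {pfm.name}"
        )
    sc_scored = design_scrambled(wt, pfm, rng, max_iter=max_iter, min_gap=min_gap)
    for _ in range(max_iter):
        b5, b3 = design_barcode_pair(
            rng, pfm_library, wt, pfm.name, arm5, arm3, max_iter=max_iter
        )
        sc_cassette = arm5 + b5 + sc_scored.sequence + b3 + arm3
        if cassette_cross_hits(sc_cassette, pfm_library, pfm.name) == 0:
            break
    else:
        raise MotifDesignError(f"no shared barcode pair works for {pfm.name}")
    mk = lambda variant, seq, score: MotifCassette(
        pfm.name, variant, b5, b3, seq, arm5, arm3, normalized_score=score
    )
    return (
        mk("WT", wt, wt_scored.normalized_score),
        mk("Sc", sc_scored.sequence, sc_scored.normalized_score),
    )


# ---------------------------------------------------------------------------
# Manifest I/O


MANIFEST_COLUMNS = [
    "motif_name",
    "variant",
    "barcode5",
    "motif",
    "barcode3",
    "arm5",
    "arm3",
    "normalized_score",
]


def write_manifest(cassettes: list[MotifCassette], path: str | Path) -> None:
    import pandas as pd

    rows = [
        {
            "motif_name": c.motif_name,
            "variant": c.variant,
            "barcode5": c.barcode5,
            "motif": c.motif,
            "barcode3": c.barcode3,
            "arm5": c.arm5,
            "arm3": c.arm3,
            "normalized_score": c.normalized_score,
        }
        for c in cassettes
    ]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> list[MotifCassette]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        MotifCassette(
            r.motif_name,
            r.variant,
            r.barcode5,
            r.barcode3,
            r.motif,
            r.arm5,
            r.arm3,
            normalized_score=float(r.normalized_score or "nan"),
        )
        for r in df.itertuples()
    ]


def enumerate_sequences(width: int):
    """All DNA sequences of the given width (for brute-force oracles)."""
    for tup in itertools.product(BASES, repeat=width):
        yield "".join(tup)
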