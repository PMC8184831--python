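"""Bisulfite alignment, per-cytosine methylation calls, conversion
filtering, UMI deduplication, and per-CpG aggregation.

Alignment works in three-letter (C-to-T collapsed) space against the known
amplicon: with both read and reference collapsed, a bisulfite-converted
read matches its origin exactly regardless of methylation state, and the
original read base at each reference cytosine then gives the call
(C = methylated, T = unmethylated).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .demux import TaggedRead
from .simulate import AmpliconReference, revcomp

_C, _T = ord("C"), ord("T")


@dataclass
class RefIndex:
    """Precomputed arrays for aligning reads to one amplicon."""

    ref: AmpliconReference
    seq: np.ndarray = field(init=False)
    collapsed: np.ndarray = field(init=False)
    c_positions: np.ndarray = field(init=False)
    c_is_cpg: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.seq = np.frombuffer(self.ref.sequence.encode(), dtype=np.uint8).copy()
        self.collapsed = self.seq.copy()
        self.collapsed[self.collapsed == _C] = _T
        self.c_positions = self.ref.c_positions
        self.c_is_cpg = self.ref.c_is_cpg


def _collapse(arr: np.ndarray) -> np.ndarray:
    out = arr.copy()
    out[out == _C] = _T
    return out


def align_bisulfite(
    seq: str,
    qual: str,
    index: RefIndex,
    min_identity: float = 0.9,
    min_base_q: int = 20,
) -> dict[int, str] | None:
    """Semi-global alignment in collapsed space; per-cytosine calls.

    Both orientations of the read are C-to-T collapsed and slid along the
    collapsed reference; the best-identity placement wins.  If identity
    falls below ``min_identity`` the read is rejected (returns None).  At
    each reference cytosine inside the aligned span, the original read base
    yields the call: C -> "M", T -> "U", anything else (or base quality
    below ``min_base_q``) is missing.
    """
    n_ref = len(index.collapsed)
    best = (-1.0, 0, None, None)  # identity, offset, oriented seq, oriented qual
    for oriented_seq, oriented_qual in ((seq, qual), (revcomp(seq), qual[::-1])):
        arr = np.frombuffer(oriented_seq.encode(), dtype=np.uint8)
        if len(arr) == 0 or len(arr) > n_ref:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(index.collapsed, len(arr))
        identity = (windows == _collapse(arr)).mean(axis=1)
        i = int(identity.argmax())
        if identity[i] > best[0]:
            best = (float(identity[i]), i, arr, oriented_qual)
    identity, offset, arr, oriented_qual = best
    if arr is None or identity < min_identity:
        return None
    quals = np.frombuffer(oriented_qual.encode(), dtype=np.uint8) - 33
    calls: dict[int, str] = {}
    span = (index.c_positions >= offset) & (index.c_positions < offset + len(arr))
    for pos in index.c_positions[span]:
        j = pos - offset
        if quals[j] < min_base_q:
            continue
        base = arr[j]
        if base == _C:
            calls[int(pos)] = "M"
        elif base == _T:
            calls[int(pos)] = "U"
    return calls


@dataclass
class PairCalls:
    """Per-cytosine calls of one read pair (mates kept separate)."""

    read_id: str
    umi: str
    motif: str
    mate_calls: list[dict[int, str]]

    def noncg_fraction(self, index: RefIndex) -> float | None:
        """Methylated fraction of observed non-CpG cytosines, or None."""
        cpg = dict(zip(index.c_positions.tolist(), index.c_is_cpg.tolist()))
        n_m = n_obs = 0
        for calls in self.mate_calls:
            for pos, call in calls.items():
                if not cpg[pos]:
                    n_obs += 1
                    n_m += call == "M"
        return n_m / n_obs if n_obs else None


def call_pair(
    read: TaggedRead,
    index: RefIndex,
    min_identity: float = 0.9,
    min_base_q: int = 20,
) -> PairCalls | None:
    """Align both mates; drop the pair only if neither mate aligns."""
    mate_calls = []
    for seq, qual in ((read.seq1, read.qual1), (read.seq2, read.qual2)):
        calls = align_bisulfite(seq, qual, index, min_identity, min_base_q)
        if calls is not None:
            mate_calls.append(calls)
    if not mate_calls:
        return None
    return PairCalls(read.read_id, read.umi, read.motif, mate_calls)


def conversion_filter(
    pair: PairCalls,
    index: RefIndex,
    max_noncg: float = 0.02,
    tet_tko: bool = False,
) -> bool:
    """Keep reads whose non-CpG methylation stays below ``max_noncg``.

    Retained non-CpG cytosines flag incomplete bisulfite conversion, so a
    pair with a non-CpG methylated fraction >= ``max_noncg`` is discarded.
    Pairs with no observed non-CpG cytosine cannot be assessed and are
    kept.  In TET-TKO mode the filter is bypassed entirely, because those
    libraries carry genuine non-CG methylation well above the threshold.
    """
    if tet_tko:
        return True
    frac = pair.noncg_fraction(index)
    return frac is None or frac < max_noncg


# ---------------------------------------------------------------------------
# UMI deduplication


@dataclass
class MoleculeCall:
    """Consensus per-cytosine calls of one deduplicated molecule."""

    umi: str
    motif: str
    calls: dict[int, str]
    n_reads: int


def _hamming1(a: str, b: str) -> bool:
    if len(a) != len(b):
        return False
    diff = 0
    for x, y in zip(a, b):
        if x != y:
            diff += 1
            if diff > 1:
                return False
    return diff == 1


def cluster_umis_directional(counts: dict[str, int]) -> dict[str, str]:
    """UMI -> cluster-representative map under the directional rule.

    UMI ``b`` merges into ``a`` when hamming(a, b) == 1 and
    ``count(a) >= 2 * count(b) - 1``; merging proceeds from the most
    abundant UMI outwards (ties broken lexicographically for determinism).
    """
    order = sorted(counts, key=lambda u: (-counts[u], u))
    rep: dict[str, str] = {}
    for root in order:
        if root in rep:
            continue
        rep[root] = root
        frontier = [root]
        while frontier:
            node = frontier.pop()
            for other in order:
                if other in rep:
                    continue
                if _hamming1(node, other) and counts[node] >= 2 * counts[other] - 1:
                    rep[other] = root
                    frontier.append(other)
    return rep


def consensus_calls(pairs: list[PairCalls]) -> dict[int, str]:
    """Majority vote per coordinate over every mate of every pair; ties missing."""
    votes: dict[int, Counter] = defaultdict(Counter)
    for pair in pairs:
        for calls in pair.mate_calls:
            for pos, call in calls.items():
                votes[pos][call] += 1
    out = {}
    for pos, counter in votes.items():
        m, u = counter.get("M", 0), counter.get("U", 0)
        if m > u:
            out[pos] = "M"
        elif u > m:
            out[pos] = "U"
    return out


def dedup_umi(pairs: list[PairCalls], mode: str = "exact") -> list[MoleculeCall]:
    """Collapse PCR duplicates sharing a UMI into consensus molecules.

    ``exact`` groups identical UMIs; ``directional`` additionally merges
    1-mismatch UMI satellites into their abundant neighbour (the standard
    sequencing-error-tolerant rule).  Consensus per cytosine is the
    majority over all reads of the group.
    """
    if mode not in ("exact", "directional"):
        raise ValueError(f"unknown dedup mode {mode!r}")
    by_umi: dict[str, list[PairCalls]] = defaultdict(list)
    for pair in pairs:
        by_umi[pair.umi].append(pair)
    if mode == "directional":
        counts = {u: len(v) for u, v in by_umi.items()}
        rep = cluster_umis_directional(counts)
        merged: dict[str, list[PairCalls]] = defaultdict(list)
        for umi, group in by_umi.items():
            merged[rep[umi]].extend(group)
        by_umi = merged
    molecules = []
    for umi in sorted(by_umi):
        group = by_umi[umi]
        motif = group[0].motif
        molecules.append(
            MoleculeCall(umi, motif, consensus_calls(group), len(group))
        )
    return molecules


# ---------------------------------------------------------------------------
# Aggregation


def aggregate(
    molecules: list[MoleculeCall],
    index: RefIndex,
    min_coverage: int = 10,
    context: str = "CpG",
) -> pd.DataFrame:
    """Per-cytosine methylation table over deduplicated molecules.

    Restricted to cytosines of the requested context (``CpG`` or
    ``nonCpG``) inside the reporting window.  Coordinates are reported as
    signed bp offsets from the motif 5' end; positions covered by fewer
    than ``min_coverage`` molecules are flagged ``masked``.
    """
    if context == "CpG":
        keep = index.c_is_cpg
    elif context == "nonCpG":
        keep = ~index.c_is_cpg
    else:
        raise ValueError(f"unknown context {context!r}")
    keep = keep & index.ref.in_window(index.c_positions)
    positions = index.c_positions[keep]
    n_meth = {int(p): 0 for p in positions}
    n_total = {int(p): 0 for p in positions}
    for mol in molecules:
        for pos, call in mol.calls.items():
            if pos in n_total:
                n_total[pos] += 1
                n_meth[pos] += call == "M"
    bin_name = molecules[0].motif if molecules else ""
    df = pd.DataFrame(
        {
            "bin": bin_name,
            "offset": index.ref.offsets(positions),
            "ref_pos": positions,
            "n_meth": [n_meth[int(p)] for p in positions],
            "n_total": [n_total[int(p)] for p in positions],
        }
    )
    df["pct"] = np.where(
        df["n_total"] > 0, 100.0 * df["n_meth"] / df["n_total"].clip(lower=1), np.nan
    )
    df["masked"] = df["n_total"] < min_coverage
    return df


def weighted_mean_pct(table: pd.DataFrame) -> float:
    """Coverage-weighted mean methylation (%) over unmasked positions."""
    ok = table[~table["masked"]]
    if ok.empty or ok["n_total"].sum() == 0:
        return float("nan")
    return float(100.0 * ok["n_meth"].sum() / ok["n_total"].sum())


def call_molecules(
    reads: list[TaggedRead],
    index: RefIndex,
    min_identity: float = 0.9,
    min_base_q: int = 20,
    max_noncg: float = 0.02,
    tet_tko: bool = False,
    dedup_mode: str = "exact",
) -> tuple[list[MoleculeCall], dict[str, int]]:
    """align -> conversion filter -> dedup for the reads of one motif bin.

    Returns the consensus molecules and a drop-reason tally
    (align_fail / conversion_fail / bad_umi).
    """
    drops = {"align_fail": 0, "conversion_fail": 0, "bad_umi": 0}
    kept: list[PairCalls] = []
    for read in reads:
        if not read.umi_ok:
            drops["bad_umi"] += 1
            continue
        pair = call_pair(read, index, min_identity, min_base_q)
        if pair is None:
            drops["align_fail"] += 1
            continue
        if not conversion_filter(pair, index, max_noncg, tet_tko):
            drops["conversion_fail"] += 1
            continue
        kept.append(pair)
    return dedup_umi(kept, dedup_mode), drops


def write_bedgraph(table: pd.DataFrame, amplicon: str, path) -> None:
    """bedGraph-style per-CpG methylation (0-based half-open intervals)."""
    with open(path, "w") as fh:
        for row in table.itertuples():
            if row.masked:
                continue
            fh.write(f"{amplicon}\t{row.ref_pos}\t{row.ref_pos + 1}\t{row.pct:.2f}\n")
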