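"""Quality filtering, barcode demultiplexing, UMI extraction, and
bisulfite-aware motif classification of paired reads.

Demultiplexing keys on the 6 bp library barcode plus 4 bp of the
neighbouring adaptor at zero mismatches; the 8-nt UMI follows that block.
Reads are then assigned to their motif cassette by exact substring search
with an IUPAC pattern that tolerates the methylation-dependent C/T state of
CpG cytosines inside the motif.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from .motifs import MotifCassette
from .simulate import ReadPair, revcomp

BARCODE_LEN = 6
ADAPTOR_LEN = 4
UMI_LEN = 8
PREFIX_LEN = BARCODE_LEN + ADAPTOR_LEN + UMI_LEN  # 18 bp


class ConfigError(ValueError):
    pass


_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class Sample:
    name: str
    barcode: str
    adaptor: str

    @property
    def key(self) -> str:
        return self.barcode + self.adaptor


def load_sample_sheet(rows) -> dict[str, Sample]:
    """Validate a sample sheet (name, 6 bp barcode, 4 bp adaptor).

    ``rows`` is an iterable of (name, barcode, adaptor) or a path to a TSV
    with those columns.  Keys must be mutually distinct at 0 mismatches.
    """
    if isinstance(rows, (str, bytes)) or hasattr(rows, "read_text") or (
        isinstance(rows, str)
    ):
        rows = pd.read_csv(rows, sep="\t").itertuples(index=False)
    samples: dict[str, Sample] = {}
    seen_keys: dict[str, str] = {}
    for name, barcode, adaptor in rows:
        if len(barcode) != BARCODE_LEN or len(adaptor) != ADAPTOR_LEN:
            raise ConfigError(f"sample {name}: barcode must be 6 bp, adaptor 4 bp")
        s = Sample(str(name), barcode.upper(), adaptor.upper())
        if s.key in seen_keys:
            raise ConfigError(
                f"duplicate demux key {s.key} for samples {seen_keys[s.key]} and {name}"
            )
        seen_keys[s.key] = s.name
        samples[s.name] = s
    return samples


# ---------------------------------------------------------------------------
# Quality filter


def mean_phred(qualities: str) -> float:
    if not qualities:
        raise ConfigError("empty quality string")
    return sum(ord(c) - 33 for c in qualities) / len(qualities)


def quality_filter(pair: ReadPair, min_q: float = 20.0) -> bool:
    """Keep the pair unless either mate's mean Phred is strictly below min_q."""
    return mean_phred(pair.qual1) >= min_q and mean_phred(pair.qual2) >= min_q


# ---------------------------------------------------------------------------
# Demultiplexing and UMI extraction


def demultiplex(pair: ReadPair, samples: dict[str, Sample]) -> str | None:
    """Sample name whose barcode+adaptor key exactly matches the R1 prefix."""
    if len(pair.seq1) < PREFIX_LEN:
        return None
    prefix = pair.seq1[: BARCODE_LEN + ADAPTOR_LEN].upper()
    for sample in samples.values():
        if prefix == sample.key:
            return sample.name
    return None


@dataclass
class TaggedRead:
    """A demultiplexed pair: UMI extracted, prefix trimmed from R1."""

    read_id: str
    sample: str
    umi: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str
    motif: str | None = None  # cassette label, filled by classification
    umi_ok: bool = True


def extract_umi(pair: ReadPair, sample: str) -> TaggedRead:
    """Slice the 8-nt UMI following the barcode+adaptor block off R1.

    The UMI and the 18 bp prefix are removed from the sequence passed
    downstream; R2 inherits R1's UMI.  A UMI containing N is flagged so the
    read is excluded from deduplication groups.
    """
    umi = pair.seq1[BARCODE_LEN + ADAPTOR_LEN : PREFIX_LEN].upper()
    return TaggedRead(
        read_id=pair.read_id,
        sample=sample,
        umi=umi,
        seq1=pair.seq1[PREFIX_LEN:],
        qual1=pair.qual1[PREFIX_LEN:],
        seq2=pair.seq2,
        qual2=pair.qual2,
        umi_ok="N" not in umi,
    )


# ---------------------------------------------------------------------------
# Bisulfite-aware motif patterns


def build_bisulfite_pattern(cassette: MotifCassette, strict: bool = False) -> str:
    """IUPAC search pattern for a cassette after bisulfite conversion.

    Built over barcode5+motif+barcode3 on the strand whose barcodes are
    cytosine-free: a C in CpG context becomes Y (reads as C when methylated,
    T when converted); a C outside CpG context becomes T (full conversion
    assumed — ``strict=True`` renders it Y instead, tolerating conversion
    failure inside the motif at the cost of specificity).
    """
    core = cassette.core.upper()
    out = []
    for i, b in enumerate(core):
        if b != "C":
            out.append(b)
        elif core[i + 1 : i + 2] == "G":
            out.append("Y")
        else:
            out.append("Y" if strict else "T")
    return "".join(out)


def _pattern_regex(pattern: str) -> re.Pattern:
    return re.compile("".join(
        b if len(_IUPAC[b]) == 1 else f"[{_IUPAC[b]}]" for b in pattern.upper()
    ))


def patterns_collide(a: str, b: str) -> bool:
    """True if some DNA string matches ``a`` while containing a match of ``b``.

    Checked by sliding the shorter pattern along the longer and requiring a
    non-empty IUPAC intersection at every overlapping position.
    """
    if len(a) < len(b):
        a, b = b, a
    for start in range(len(a) - len(b) + 1):
        if all(
            set(_IUPAC[a[start + i]]) & set(_IUPAC[b[i]]) for i in range(len(b))
        ):
            return True
    return False


class PatternSet:
    """Compiled cassette patterns with a load-time collision check."""

    def __init__(self, cassettes: list[MotifCassette], strict: bool = False):
        self.labels: list[str] = []
        self._regex: list[tuple[str, re.Pattern, re.Pattern]] = []
        raw: list[tuple[str, str]] = []
        for cassette in cassettes:
            pat = build_bisulfite_pattern(cassette, strict=strict)
            for other_label, other in raw:
                if patterns_collide(pat, other):
                    raise ConfigError(
                        f"cassette patterns for {cassette.label} and {other_label} "
                        "collide under IUPAC expansion"
                    )
            raw.append((cassette.label, pat))
            self.labels.append(cassette.label)
            self._regex.append(
                (cassette.label, _pattern_regex(pat), _pattern_regex(revcomp_pattern(pat)))
            )

    def hits(self, seq: str) -> set[str]:
        seq = seq.upper()
        found = set()
        for label, fwd, rev in self._regex:
            if fwd.search(seq) or rev.search(seq):
                found.add(label)
        return found


_IUPAC_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp_pattern(pattern: str) -> str:
    return pattern.translate(_IUPAC_COMP)[::-1]


def classify_pair(read: TaggedRead, patterns: PatternSet) -> str | None:
    """Assign a pair to the unique cassette pattern found in either mate.

    Hits are collected from both mates (forward and reverse complement, 0
    mismatches).  Exactly one distinct cassette across the mates gives an
    assignment; zero hits, or conflicting hits between or within mates,
    leave the pair unassigned.
    """
    found = patterns.hits(read.seq1) | patterns.hits(read.seq2)
    return found.pop() if len(found) == 1 else None


# ---------------------------------------------------------------------------
# Driver


def demux_and_classify(
    pairs: list[ReadPair],
    samples: dict[str, Sample],
    patterns: PatternSet,
    min_q: float = 20.0,
) -> tuple[list[TaggedRead], pd.DataFrame]:
    """Run filter -> demux -> UMI -> classify over a batch of read pairs.

    Returns the assigned reads and a per-(sample, motif) summary that also
    tallies quality-discarded, unassigned-sample and unassigned-motif reads;
    every input pair lands in exactly one bin of the summary.
    """
    tagged: list[TaggedRead] = []
    counts: dict[tuple[str, str], int] = {}

    def bump(sample: str, motif: str) -> None:
        counts[(sample, motif)] = counts.get((sample, motif), 0) + 1

    for pair in pairs:
        if not quality_filter(pair, min_q):
            bump("*", "low_quality")
            continue
        sample = demultiplex(pair, samples)
        if sample is None:
            bump("*", "unassigned_sample")
            continue
        read = extract_umi(pair, sample)
        read.motif = classify_pair(read, patterns)
        if read.motif is None:
            bump(sample, "unassigned_motif")
            continue
        bump(sample, read.motif)
        tagged.append(read)
    summary = pd.DataFrame(
        [
            {"sample": s, "motif": m, "n_pairs": n}
            for (s, m), n in sorted(counts.items())
        ],
        columns=["sample", "motif", "n_pairs"],
    )
    return tagged, summary
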