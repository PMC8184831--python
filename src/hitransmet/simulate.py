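"""End-to-end simulator for targeted bisulfite amplicon experiments.

Builds a neutral amplicon (a TFBS-free backbone carrying one
barcode-motif-barcode cassette), draws per-molecule methylation states,
applies bisulfite chemistry, PCR duplication under 8-nt UMIs, and sequencing
error, and emits paired-end FASTQ with a ground-truth table.  Every
downstream stage of the pipeline can therefore be exercised — and its
estimates compared with known truth — without any external data.

The default condition profiles encode the assay's experimental arms: an
unmethylated construct gains methylation after insertion (−SssI), an in
vitro methylated one keeps it (+SssI), methylation rises further after
neural-progenitor differentiation, and in TET triple-knockout cells both CG
and non-CG methylation are elevated.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .motifs import MotifCassette, cpg_positions

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class SimulationError(ValueError):
    pass


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Backbone and amplicon reference


def build_backbone(
    length: int,
    target_cpg_ratio: float,
    rng: np.random.Generator,
    forbidden: list[str] | None = None,
    max_iter: int = 100,
) -> str:
    """Random DNA backbone with a controlled CpG ratio.

    The CpG ratio is the number of CG dinucleotides divided by the sequence
    length (the neutral bacterial fragment used by the assay sits at 3.6%,
    i.e. intermediate CpG content).  The sequence is first drawn CG-free,
    then the exact number of CG dinucleotides is planted at non-overlapping
    positions, so the realised ratio matches the target to within rounding.
    Substrings listed in ``forbidden`` (e.g. cassette barcodes) never occur.
    """
    if length < 600:
        raise SimulationError("backbone must be >= 600 bp to host the reporting window")
    if not 0.0 <= target_cpg_ratio <= 0.25:
        raise SimulationError(f"CpG ratio {target_cpg_ratio} unattainable (max 0.25)")
    n_cpg = round(target_cpg_ratio * length)
    forbidden = forbidden or []
    for _ in range(max_iter):
        # draw with no CG anywhere: never put G right after C
        seq = []
        prev = ""
        for _ in range(length):
            choices = "ACT" if prev == "C" else BASES
            prev = choices[rng.integers(len(choices))]
            seq.append(prev)
        # plant CGs at non-overlapping positions (pairwise distance >= 2);
        # planting C at i and G at i+1 cannot create a CG elsewhere
        if n_cpg > 0:
            positions = _spaced_positions(length - 1, n_cpg, rng)
            if positions is None:
                continue
            for i in positions:
                seq[i] = "C"
                seq[i + 1] = "G"
        out = "".join(seq)
        realized = len(cpg_positions(out))
        if realized != n_cpg:
            continue
        if any(f in out for f in forbidden):
            continue
        return out
    raise SimulationError("could not build a backbone satisfying the constraints")


def _spaced_positions(
    high: int, k: int, rng: np.random.Generator, min_dist: int = 2
) -> np.ndarray | None:
    """k positions in [0, high) with pairwise distance >= min_dist, or None."""
    if k * min_dist > high:
        return None
    # classic stars-and-bars trick: draw sorted positions in a shrunk range
    base = np.sort(rng.choice(high - (k - 1) * (min_dist - 1), size=k, replace=False))
    return base + np.arange(k) * (min_dist - 1)


@dataclass(frozen=True)
class AmpliconReference:
    """Backbone + cassette with coordinate maps for methylation reporting.

    ``motif_anchor`` (the motif's 5' end) is the origin for reported CpG
    offsets; the reporting window spans 300 bp upstream to 250 bp downstream
    of it, clipped to the sequence.
    """

    name: str
    sequence: str
    cassette_offset: int
    motif_anchor: int
    cassette: MotifCassette
    window_upstream: int = 300
    window_downstream: int = 250

    @property
    def cpg_positions(self) -> np.ndarray:
        return np.array(cpg_positions(self.sequence), dtype=int)

    @property
    def c_positions(self) -> np.ndarray:
        """Top-strand cytosine positions (both CpG and non-CpG context)."""
        return np.array([i for i, b in enumerate(self.sequence) if b == "C"], dtype=int)

    @property
    def c_is_cpg(self) -> np.ndarray:
        seq = self.sequence
        return np.array(
            [seq[i + 1 : i + 2] == "G" for i in self.c_positions], dtype=bool
        )

    @property
    def window(self) -> tuple[int, int]:
        lo = max(0, self.motif_anchor - self.window_upstream)
        hi = min(len(self.sequence), self.motif_anchor + self.window_downstream + 1)
        return lo, hi

    def in_window(self, positions: np.ndarray) -> np.ndarray:
        lo, hi = self.window
        positions = np.asarray(positions)
        return (positions >= lo) & (positions < hi)

    def offsets(self, positions: np.ndarray) -> np.ndarray:
        """Signed bp offsets from the motif 5' end (negative = upstream)."""
        return np.asarray(positions) - self.motif_anchor


def make_amplicon(
    backbone: str, cassette: MotifCassette, cassette_offset: int | None = None
) -> AmpliconReference:
    """Insert a cassette into the backbone and index the result."""
    if cassette_offset is None:
        cassette_offset = 150
    if not 0 <= cassette_offset <= len(backbone):
        raise SimulationError("cassette offset outside the backbone")
    seq = backbone[:cassette_offset] + cassette.sequence + backbone[cassette_offset:]
    anchor = cassette_offset + len(cassette.arm5) + len(cassette.barcode5)
    return AmpliconReference(cassette.label, seq, cassette_offset, anchor, cassette)


# ---------------------------------------------------------------------------
# Condition profiles


@dataclass(frozen=True)
class HMREffect:
    """Localised WT-only reduction of CpG methylation around the motif."""

    delta: float  # reduction of the methylation probability, in [0, 1]
    n_cpgs: int = 4
    span_bp: int = 80


@dataclass(frozen=True)
class ConditionProfile:
    """Per-condition methylation and chemistry parameters.

    ``mean_cg_meth`` is the expected per-CpG methylation fraction around a
    control (scrambled) motif; ``cg_overdispersion`` is the inverse of the
    Beta "sample size" governing molecule-to-molecule variability;
    ``noncg_meth_rate`` is the genuine non-CpG methylation fraction (high
    only in TET-TKO cells); ``conversion_rate`` is the probability an
    unmethylated cytosine reads as T after bisulfite treatment.
    """

    name: str
    mean_cg_meth: float
    cg_overdispersion: float = 0.02
    noncg_meth_rate: float = 0.002
    conversion_rate: float = 0.995
    hmr_effect: HMREffect | None = None
    tet_tko: bool = False

    def __post_init__(self) -> None:
        for v in (self.mean_cg_meth, self.noncg_meth_rate, self.conversion_rate):
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"fraction {v} outside [0, 1]")
        if self.cg_overdispersion < 0:
            raise SimulationError("overdispersion must be >= 0")
        if self.hmr_effect is not None and self.hmr_effect.delta > self.mean_cg_meth:
            raise SimulationError("hmr_effect.delta exceeds the baseline mean")


#: Condition means around scrambled motifs, as estimated by the assay:
#: de novo methylation of the unmethylated construct in ESCs (52.4%),
#: maintained methylation of the pre-methylated construct (79.1%), the same
#: two arms after NP differentiation (81.7% / 85.9%), and the TET
#: triple-knockout +SssI arm (88.6% CG, 6.3% non-CG, conversion filter off).
PRESETS: dict[str, ConditionProfile] = {
    "ESC_minusSssI": ConditionProfile("ESC_minusSssI", 0.524),
    "ESC_plusSssI": ConditionProfile("ESC_plusSssI", 0.791),
    "NP_minusSssI": ConditionProfile("NP_minusSssI", 0.817),
    "NP_plusSssI": ConditionProfile("NP_plusSssI", 0.859),
    "TETTKO_plusSssI": ConditionProfile(
        "TETTKO_plusSssI", 0.886, noncg_meth_rate=0.063, tet_tko=True
    ),
    # siRNA knockdown experiment around the OCT4SOX2 WT motif (+SssI):
    # 16% without siRNA, 38-40% (midpoint 39%) after SOX2/OCT4 knockdown.
    "OS_WT_noSiRNA": ConditionProfile("OS_WT_noSiRNA", 0.16),
    "OS_WT_siRNA": ConditionProfile("OS_WT_siRNA", 0.39),
}


def get_preset(name: str, **overrides) -> ConditionProfile:
    try:
        profile = PRESETS[name]
    except KeyError:
        raise SimulationError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None
    return replace(profile, **overrides) if overrides else profile


# ---------------------------------------------------------------------------
# Molecules


@dataclass
class TrueMolecule:
    """Ground-truth methylation states of one DNA molecule.

    ``c_states`` aligns one-to-one with the reference's top-strand cytosine
    coordinates (``AmpliconReference.c_positions``); True = methylated.
    """

    molecule_id: str
    amplicon: str
    umi: str
    c_states: np.ndarray


def draw_molecules(
    ref: AmpliconReference,
    profile: ConditionProfile,
    variant: str,
    n: int,
    rng: np.random.Generator,
) -> list[TrueMolecule]:
    """Draw n molecules with per-CpG Bernoulli methylation.

    Each molecule gets its own CpG methylation probability drawn from a
    Beta distribution with mean ``mean_cg_meth`` and sample size
    ``1/cg_overdispersion`` (molecule-to-molecule heterogeneity); per-CpG
    states are then independent Bernoulli draws.  For a WT variant with an
    ``hmr_effect``, the probability is reduced by ``delta`` at the CpGs
    nearest the motif (at least ``n_cpgs`` of them, extended until they span
    ``span_bp``).  Non-CpG cytosines methylate at ``noncg_meth_rate``.
    """
    if n < 1:
        raise SimulationError("need n >= 1 molecules")
    is_cpg = ref.c_is_cpg
    c_pos = ref.c_positions
    n_c = len(c_pos)
    m, phi = profile.mean_cg_meth, profile.cg_overdispersion

    hmr_mask = np.zeros(n_c, dtype=bool)
    if variant == "WT" and profile.hmr_effect is not None:
        eff = profile.hmr_effect
        cg_idx = np.flatnonzero(is_cpg)
        if len(cg_idx) < eff.n_cpgs:
            raise SimulationError(
                f"reference has {len(cg_idx)} CpGs, fewer than hmr_effect.n_cpgs"
            )
        order = cg_idx[np.argsort(np.abs(ref.offsets(c_pos[cg_idx])), kind="stable")]
        chosen = list(order[: eff.n_cpgs])
        extra = iter(order[eff.n_cpgs :])
        while c_pos[chosen].max() - c_pos[chosen].min() < eff.span_bp:
            try:
                chosen.append(next(extra))
            except StopIteration:
                raise SimulationError(
                    f"CpGs available cannot span {eff.span_bp} bp for the HMR effect"
                ) from None
        hmr_mask[chosen] = True

    molecules = []
    for i in range(n):
        if phi > 0:
            s = 1.0 / phi
            p_mol = rng.beta(max(m * s, 1e-9), max((1 - m) * s, 1e-9))
        else:
            p_mol = m
        p = np.where(is_cpg, p_mol, profile.noncg_meth_rate)
        if profile.hmr_effect is not None and variant == "WT":
            p = np.where(hmr_mask, np.clip(p - profile.hmr_effect.delta, 0, 1), p)
        states = rng.random(n_c) < p
        umi = "".join(BASES[j] for j in rng.integers(4, size=8))
        molecules.append(TrueMolecule(f"{ref.name}:mol{i:05d}", ref.name, umi, states))
    return molecules


# ---------------------------------------------------------------------------
# Bisulfite chemistry


def bisulfite_convert(
    mol: TrueMolecule,
    ref: AmpliconReference,
    rng: np.random.Generator,
    conversion_rate: float = 0.995,
    over_conversion: float = 0.0,
) -> str:
    """Top-strand sequence after bisulfite treatment.

    Unmethylated cytosines deaminate to T with probability
    ``conversion_rate`` (a retained C is a conversion failure); methylated
    cytosines are protected, except for a rare over-conversion to T.
    """
    seq = list(ref.sequence)
    c_pos = ref.c_positions
    u = rng.random(len(c_pos))
    for pos, methylated, r in zip(c_pos, mol.c_states, u):
        if methylated:
            if r < over_conversion:
                seq[pos] = "T"
        else:
            if r < conversion_rate:
                seq[pos] = "T"
    return "".join(seq)


# ---------------------------------------------------------------------------
# Sequencing


@dataclass
class ReadPair:
    read_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = list(seq)
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        alternatives = [b for b in BASES if b != arr[i]]
        arr[i] = alternatives[rng.integers(3)]
    return "".join(arr)


def emit_reads(
    molecules: list[TrueMolecule],
    converted: list[str],
    library_barcode: str,
    adaptor: str,
    rng: np.random.Generator,
    read_len: int = 300,
    pcr_dup_mean: float = 2.0,
    seq_error_rate: float = 0.002,
    base_quality: int = 37,
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Paired reads from converted molecules, plus the read->molecule truth.

    R1 carries the 6 bp library barcode, 4 bp of the neighbouring adaptor
    and the 8-nt UMI, followed by the amplicon 5' segment; R2 is the
    reverse complement of the amplicon 3' segment.  Each molecule is
    sequenced ``1 + Poisson(pcr_dup_mean)`` times (PCR duplicates share the
    molecule's UMI exactly); substitution errors hit every base at
    ``seq_error_rate``.
    """
    if len(library_barcode) != 6 or len(adaptor) != 4:
        raise SimulationError("library barcode must be 6 bp and adaptor 4 bp")
    prefix_len = len(library_barcode) + len(adaptor) + 8
    reads: list[ReadPair] = []
    truth_rows = []
    qual = chr(33 + base_quality)
    for mol, conv in zip(molecules, converted):
        if read_len > len(conv):
            raise SimulationError("read length exceeds the amplicon length")
        n_copies = 1 + rng.poisson(pcr_dup_mean)
        payload1 = conv[: read_len - prefix_len]
        r2 = revcomp(conv[-read_len:])
        template1 = library_barcode + adaptor + mol.umi + payload1
        for copy in range(n_copies):
            rid = f"{mol.molecule_id}:c{copy}"
            s1 = _apply_errors(template1, seq_error_rate, rng)
            s2 = _apply_errors(r2, seq_error_rate, rng)
            reads.append(ReadPair(rid, s1, qual * len(s1), s2, qual * len(s2)))
            truth_rows.append(
                {"read_id": rid, "molecule_id": mol.molecule_id, "umi": mol.umi}
            )
    truth = pd.DataFrame(truth_rows, columns=["read_id", "molecule_id", "umi"])
    return reads, truth


def simulate_library(
    ref: AmpliconReference,
    profile: ConditionProfile,
    variant: str,
    n_molecules: int,
    rng: np.random.Generator,
    library_barcode: str = "ACGTCA",
    adaptor: str = "AGAT",
    read_len: int = 300,
    pcr_dup_mean: float = 2.0,
    seq_error_rate: float = 0.002,
    over_conversion: float = 0.0,
) -> tuple[list[ReadPair], pd.DataFrame, list[TrueMolecule]]:
    """Molecules -> bisulfite conversion -> paired reads, in one call."""
    molecules = draw_molecules(ref, profile, variant, n_molecules, rng)
    converted = [
        bisulfite_convert(m, ref, rng, profile.conversion_rate, over_conversion)
        for m in molecules
    ]
    reads, truth = emit_reads(
        molecules,
        converted,
        library_barcode,
        adaptor,
        rng,
        read_len=read_len,
        pcr_dup_mean=pcr_dup_mean,
        seq_error_rate=seq_error_rate,
    )
    return reads, truth, molecules


def truth_cpg_means(ref: AmpliconReference, molecules: list[TrueMolecule]) -> pd.DataFrame:
    """Empirical per-CpG methylation of the true molecules (window CpGs)."""
    c_pos = ref.c_positions
    keep = ref.c_is_cpg & ref.in_window(c_pos)
    states = np.array([m.c_states for m in molecules])
    rows = pd.DataFrame(
        {
            "offset": ref.offsets(c_pos[keep]),
            "ref_pos": c_pos[keep],
            "n_meth": states[:, keep].sum(axis=0),
            "n_total": len(molecules),
        }
    )
    rows["pct"] = 100.0 * rows["n_meth"] / rows["n_total"]
    return rows


# ---------------------------------------------------------------------------
# FASTQ I/O (plain or gzip by extension)


def _open_text(path: str | Path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, mode + "b"))
    return open(path, mode)


def write_fastq_pair(
    reads: list[ReadPair], r1_path: str | Path, r2_path: str | Path
) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    def records(mate: int):
        for rp in reads:
            seq = rp.seq1 if mate == 1 else rp.seq2
            qual = rp.qual1 if mate == 1 else rp.qual2
            rec = SeqRecord(Seq(seq), id=rp.read_id, description=f"/{mate}")
            rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
            yield rec

    for mate, path in ((1, r1_path), (2, r2_path)):
        with _open_text(path, "w") as fh:
            SeqIO.write(records(mate), fh, "fastq")


def read_fastq_pair(r1_path: str | Path, r2_path: str | Path) -> list[ReadPair]:
    from Bio import SeqIO

    def load(path):
        with _open_text(path, "r") as fh:
            return [
                (r.id, str(r.seq), "".join(chr(q + 33) for q in r.letter_annotations["phred_quality"]))
                for r in SeqIO.parse(fh, "fastq")
            ]

    r1, r2 = load(r1_path), load(r2_path)
    if len(r1) != len(r2):
        raise SimulationError("R1/R2 FASTQ files differ in read count")
    pairs = []
    for (id1, s1, q1), (id2, s2, q2) in zip(r1, r2):
        if id1 != id2:
            raise SimulationError(f"mate ids out of sync: {id1} vs {id2}")
        pairs.append(ReadPair(id1, s1, q1, s2, q2))
    return pairs
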