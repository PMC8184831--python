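"""End-to-end orchestration: design -> simulate -> demux -> call -> diff.

Every run is driven by one integer seed; each stage and condition draws
from a named substream derived from it, so re-running a configuration
reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import motifs as mo
from . import simulate as sim
from . import demux as dx
from . import methcall as mc
from . import diffmeth as dm


def rng_for(seed: int, *tokens) -> np.random.Generator:
    """Named, reproducible substream of the run seed."""
    key = [int(seed) % (2**31)]
    key += [zlib.crc32(str(t).encode()) % (2**31) for t in tokens]
    return np.random.default_rng(key)


@dataclass
class RunConfig:
    """Thresholds and modes of one pipeline run (assay defaults)."""

    seed: int = 7
    presets: tuple[str, ...] = ("ESC_minusSssI",)
    n_molecules: int = 500
    read_len: int = 300
    pcr_dup_mean: float = 2.0
    seq_error_rate: float = 0.002
    min_q: float = 20.0  # mean-Phred read filter
    max_noncg: float = 0.02  # conversion filter threshold
    min_coverage: int = 10  # molecules per CpG
    min_delta: float = 10.0  # HMR Δmet threshold (percentage points)
    max_q: float = 0.05  # HMR corrected-p threshold
    smooth_window: float = 50.0  # bp
    hmr_min_span: float = 50.0  # bp
    hmr_min_cpgs: int = 3
    dedup_mode: str = "exact"
    tet_tko: bool = False
    backbone_length: int = 600
    cpg_ratio: float = 0.036
    cassette_offset: int = 150
    library_barcode: str = "ACGTCA"
    adaptor: str = "AGAT"

    def __post_init__(self) -> None:
        positive = {
            "n_molecules": self.n_molecules,
            "read_len": self.read_len,
            "min_coverage": self.min_coverage,
            "min_delta": self.min_delta,
            "max_q": self.max_q,
            "smooth_window": self.smooth_window,
            "hmr_min_span": self.hmr_min_span,
            "hmr_min_cpgs": self.hmr_min_cpgs,
        }
        for name, value in positive.items():
            if value <= 0:
                raise dx.ConfigError(f"{name} must be positive, got {value}")
        for p in self.presets:
            if p not in sim.PRESETS:
                raise dx.ConfigError(f"unknown preset {p!r}")


# ---------------------------------------------------------------------------
# Building blocks reused by the CLI, the acceptance script and the tests


def toy_pfm_library() -> list[mo.PFM]:
    """A small synthetic PFM library with sharp, CpG-containing motifs.

    The matrices are constructed for testing (consensus-dominated columns
    with probability 0.85 on the consensus base), not taken from any
    database; names indicate the family whose consensus inspired them.
    """
    consensi = {
        "CTCFL1": "CCACCAGGTGGCGC",
        "SOXF1": "CATTGTTC",
        "OCSX1": "TTTGCATAACAATG",
        "KLFX1": "GGGGTGGGGC",
        "RESTL1": "TTCAGCACCACGGACAG",
        "EBOXN1": "CACGTGAC",
    }
    library = []
    for name, cons in consensi.items():
        probs = np.full((len(cons), 4), 0.05)
        for i, b in enumerate(cons):
            probs[i, mo.BASES.index(b)] = 0.85
        library.append(mo.PFM(name, probs))
    return library


def design_cassettes(
    pfm_library: list[mo.PFM],
    seed: int,
    motif_names: list[str] | None = None,
) -> list[mo.MotifCassette]:
    """WT + Sc cassette pairs for the selected library motifs."""
    cassettes = []
    for pfm in pfm_library:
        if motif_names is not None and pfm.name not in motif_names:
            continue
        rng = rng_for(seed, "design", pfm.name)
        wt, sc = mo.design_cassette_pair(pfm, pfm_library, rng)
        cassettes.extend([wt, sc])
    return cassettes


def build_references(
    cassettes: list[mo.MotifCassette], config: RunConfig
) -> dict[str, sim.AmpliconReference]:
    """One shared backbone; each cassette inserted at the same offset.

    Sharing the backbone reproduces the assay's design: WT and Sc loci
    differ only inside the motif, so flanking CpG offsets match exactly.
    """
    forbidden = sorted({c.barcode5 for c in cassettes} | {c.barcode3 for c in cassettes})
    rng = rng_for(config.seed, "backbone")
    backbone = sim.build_backbone(
        config.backbone_length, config.cpg_ratio, rng, forbidden=forbidden
    )
    return {
        c.label: sim.make_amplicon(backbone, c, config.cassette_offset)
        for c in cassettes
    }


def run_condition(
    ref: sim.AmpliconReference,
    profile: sim.ConditionProfile,
    variant: str,
    config: RunConfig,
    seed_tokens: tuple = (),
) -> dict:
    """Simulate one (condition, cassette) library and push it through
    demux -> align -> filter -> dedup -> aggregate.

    Returns the CpG and non-CpG methylation tables, their coverage-weighted
    means, the drop log, and the ground truth for comparison.
    """
    rng = rng_for(config.seed, "simulate", profile.name, ref.name, *seed_tokens)
    reads, truth, molecules = sim.simulate_library(
        ref,
        profile,
        variant,
        config.n_molecules,
        rng,
        library_barcode=config.library_barcode,
        adaptor=config.adaptor,
        read_len=config.read_len,
        pcr_dup_mean=config.pcr_dup_mean,
        seq_error_rate=config.seq_error_rate,
    )
    samples = dx.load_sample_sheet(
        [(profile.name, config.library_barcode, config.adaptor)]
    )
    patterns = dx.PatternSet([ref.cassette])
    tagged, summary = dx.demux_and_classify(reads, samples, patterns, config.min_q)
    index = mc.RefIndex(ref)
    tet_tko = config.tet_tko or profile.tet_tko
    mols, drops = mc.call_molecules(
        tagged,
        index,
        max_noncg=config.max_noncg,
        tet_tko=tet_tko,
        dedup_mode=config.dedup_mode,
    )
    cg = mc.aggregate(mols, index, config.min_coverage, context="CpG")
    noncg = mc.aggregate(mols, index, config.min_coverage, context="nonCpG")
    return {
        "reads": reads,
        "truth": truth,
        "molecules": molecules,
        "tagged": tagged,
        "demux_summary": summary,
        "molecule_calls": mols,
        "drops": drops,
        "cg_table": cg,
        "noncg_table": noncg,
        "cg_mean": mc.weighted_mean_pct(cg),
        "noncg_mean": mc.weighted_mean_pct(noncg),
        "index": index,
    }


def estimate_condition_mean(
    preset: str,
    seed: int,
    n_molecules: int = 500,
    variant: str = "Sc",
    config: RunConfig | None = None,
    **profile_overrides,
) -> dict:
    """Single-cassette parameter-recovery run for one condition preset.

    Designs one cassette, simulates ``n_molecules`` molecules of the given
    variant under the preset, runs the full read pipeline and reports the
    coverage-weighted mean CpG (and non-CpG) methylation percentages.
    """
    config = config or RunConfig(seed=seed, presets=(preset,), n_molecules=n_molecules)
    library = toy_pfm_library()
    cassettes = design_cassettes(library, seed, motif_names=[library[0].name])
    refs = build_references(cassettes, config)
    cassette = next(c for c in cassettes if c.variant == variant)
    profile = sim.get_preset(preset, **profile_overrides)
    return run_condition(refs[cassette.label], profile, variant, config)


# ---------------------------------------------------------------------------
# Full pipeline with file outputs


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run design -> simulate -> demux -> call -> diff, writing a run
    directory with stage outputs, drop logs, and a checksummed manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    library = toy_pfm_library()
    cassettes = design_cassettes(library, config.seed)
    mo.write_manifest(cassettes, outdir / "cassettes.tsv")
    refs = build_references(cassettes, config)
    with open(outdir / "amplicons.fasta", "w") as fh:
        for ref in refs.values():
            fh.write(f">{ref.name} anchor={ref.motif_anchor}\n{ref.sequence}\n")

    motif_names = sorted({c.motif_name for c in cassettes})
    all_tables = []
    all_profiles = []
    all_hmrs = []
    drop_log = []
    for preset_name in config.presets:
        profile = sim.get_preset(preset_name)
        per_variant: dict[tuple[str, str], pd.DataFrame] = {}
        for cassette in cassettes:
            ref = refs[cassette.label]
            result = run_condition(ref, profile, cassette.variant, config)
            table = result["cg_table"].assign(
                condition=preset_name, motif=cassette.motif_name, variant=cassette.variant
            )
            all_tables.append(table)
            per_variant[(cassette.motif_name, cassette.variant)] = result["cg_table"]
            drop_log.append(
                {"condition": preset_name, "bin": cassette.label, **result["drops"]}
            )
        for name in motif_names:
            profile_df = dm.delta_met(
                per_variant[(name, "WT")], per_variant[(name, "Sc")], name
            )
            profile_df = dm.add_statistics(profile_df)
            profile_df.insert(0, "condition", preset_name)
            all_profiles.append(profile_df)
            hmrs = dm.call_hmrs(
                profile_df,
                min_span=config.hmr_min_span,
                min_cpgs=config.hmr_min_cpgs,
                min_delta=config.min_delta,
                max_q=config.max_q,
            )
            frame = dm.hmrs_to_frame(hmrs)
            frame.insert(0, "condition", preset_name)
            all_hmrs.append(frame)

    files = {
        "cpg_tables.tsv": pd.concat(all_tables, ignore_index=True),
        "delta_profiles.tsv": pd.concat(all_profiles, ignore_index=True),
        "hmrs.tsv": pd.concat(all_hmrs, ignore_index=True),
        "drop_log.tsv": pd.DataFrame(drop_log),
    }
    for name, frame in files.items():
        frame.to_csv(outdir / name, sep="\t", index=False, float_format="%.6g")

    # cluster motifs on the first preset's Δmet matrix when possible
    first = pd.concat(all_profiles, ignore_index=True)
    first = first[first["condition"] == config.presets[0]]
    matrix = first.pivot_table(index="motif", columns="offset", values="delta")
    if len(matrix) >= 2:
        linkage, order = dm.cluster_motifs(matrix)
        (outdir / "dendrogram.nwk").write_text(
            dm.linkage_to_newick(linkage, list(matrix.sort_index().index)) + "\n"
        )

    manifest = {
        "seed": config.seed,
        "config": asdict(config),
        "checksums": {
            p.name: _sha256(p)
            for p in sorted(outdir.iterdir())
            if p.name != "manifest.json" and p.is_file()
        },
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True, default=str).encode()
    ).hexdigest()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
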