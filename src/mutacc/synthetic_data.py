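"""Synthetic inputs with the statistical structure the analyses assume.

Two generators produce complete stand-ins for the study's data:

* :func:`simulate_ma` — mutation-accumulation catalogs.  Single-colony
  bottlenecking makes the per-lineage mutation count for each class very
  nearly Poisson with mean ``rate * N * T`` (within-colony genealogy is not
  simulated), so each lineage draws class counts from Poisson and then
  places mutations on the genome: substitutions on focal-base-eligible
  sites with a configurable clockwise:counter-clockwise odds (the strand
  bias the spectrum tests look for), structural variants with macrodomain
  enrichment weights (a Ter-proximal excess, as observed for SVs) and an
  insertion-sequence element drawn proportionally to copy number × relative
  activity, and indels with a configurable slippage fraction.

* :func:`simulate_fluctuation` — Luria-Delbrück cultures: discrete
  generations of synchronous doubling from ``n0`` to ``n_final`` cells,
  mutations Poisson per division, mutant clones expanding deterministically
  by doubling with wild-type fitness.

:func:`make_toy_genome` writes small FASTA/GFF3/geometry bundles for unit
tests, and :func:`synthetic_study_genome` builds a full-size (4.6 Mb)
random genome on the packaged replichore geometry so every genome-aware
analysis can run at study scale without external data.

All generators are pure functions of (configuration, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .genome_model import CLOCKWISE, GenomeModel, build_genome_model, rel4536_geometry
from .mutation_catalog import (
    AEROBIC,
    ANAEROBIC,
    MutationRecord,
    MutationSet,
    PAIR_CLASSES,
    SV_TYPES,
)
from .rate_estimation import STUDY_DESIGNS, ExperimentDesign
from .fluctuation import FluctuationExperiment

__all__ = [
    "ISElement",
    "EnvironmentConfig",
    "SimulationConfig",
    "ToyGenomeSpec",
    "default_simulation_config",
    "simulate_ma",
    "simulate_fluctuation",
    "make_toy_genome",
    "synthetic_study_genome",
]

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class ISElement:
    """One insertion-sequence element type: genomic copies and how actively
    it transposes (relative units; the SV simulator draws the mediating
    element with probability proportional to copies × activity)."""

    name: str
    copies: int
    activity: float = 1.0


@dataclass
class EnvironmentConfig:
    """Per-environment generative parameters.

    Rates are per genome per generation; ``strand_odds`` maps a pair class
    to the clockwise:counter-clockwise placement odds relative to the
    length-proportional expectation (1.0 = no strand bias);
    ``sv_macrodomain_weights`` up- or down-weights SV placement per
    macrodomain (missing names default to 1).
    """

    design: ExperimentDesign
    bps_rates: dict[str, float]
    indel_rate: float
    sv_rates: dict[str, float]
    strand_odds: dict[str, float] = field(default_factory=dict)
    is_elements: list[ISElement] = field(default_factory=list)
    sv_macrodomain_weights: dict[str, float] = field(default_factory=dict)
    slippage_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name, rate in {**self.bps_rates, **self.sv_rates, "indel": self.indel_rate}.items():
            if rate < 0:
                raise ValueError(f"rate for {name!r} must be non-negative")
        for pc, odds in self.strand_odds.items():
            if odds <= 0:
                raise ValueError(f"strand odds for {pc!r} must be positive")
        if not 0 <= self.slippage_fraction <= 1:
            raise ValueError("slippage_fraction must lie in [0, 1]")


@dataclass
class SimulationConfig:
    """Seeded configuration for the MA catalog generator."""

    seed: int
    environments: dict[str, EnvironmentConfig]


#: REL4536's nine IS element types.  Copy numbers are synthetic but keep the
#: published ordering (IS1 over four times as abundant as IS150); activities
#: make IS150 strongly elevated anaerobically while IS2/IS30/IS600/IS911
#: stay silent, mirroring which elements actually produced mutations.
_IS_TABLE_AEROBIC = [
    ISElement("IS1", 24, 1.0),
    ISElement("IS2", 6, 0.0),
    ISElement("IS3", 5, 1.0),
    ISElement("IS4", 2, 1.0),
    ISElement("IS30", 2, 0.0),
    ISElement("IS150", 5, 1.0),
    ISElement("IS186", 3, 1.0),
    ISElement("IS600", 1, 0.0),
    ISElement("IS911", 5, 0.0),
]
_IS_TABLE_ANAEROBIC = [
    replace(e, activity=10.0) if e.name == "IS150" else e for e in _IS_TABLE_AEROBIC
]


def _rates_from_counts(counts: Mapping[str, float], design: ExperimentDesign) -> dict[str, float]:
    denom = design.L * design.N * design.T
    return {k: v / denom for k, v in counts.items()}


def default_simulation_config(seed: int = 0) -> SimulationConfig:
    """The study's conditions as generative defaults.

    Class rates are set so the expected catalog reproduces the observed
    class totals (124 aerobic / 158 anaerobic mutations; 74/73 BPSs with
    ts:tv 2.08/1.09, 33/65 SVs, 17/20 indels) under the published designs.
    SVs are Ter-enriched threefold; the aerobic catalog carries a modest
    clockwise bias for A:T>G:C and the predominant transition classes, the
    anaerobic for G:C>A:T, qualitatively matching the observed strand
    asymmetries.
    """
    aero = STUDY_DESIGNS[AEROBIC]
    anae = STUDY_DESIGNS[ANAEROBIC]
    aerobic = EnvironmentConfig(
        design=aero,
        bps_rates=_rates_from_counts(
            {"A:T>G:C": 16, "G:C>A:T": 34, "A:T>C:G": 4,
             "G:C>T:A": 10, "A:T>T:A": 5, "G:C>C:G": 5},
            aero,
        ),
        indel_rate=17 / (aero.L * aero.N * aero.T),
        sv_rates=_rates_from_counts(
            {"IS_insertion": 22, "IS_mediated_deletion": 6,
             "IS_mediated_inversion": 2, "IS_mediated_translocation": 1,
             "repeat_mediated": 1, "other": 1},
            aero,
        ),
        strand_odds={"A:T>G:C": 2.5, "G:C>A:T": 0.5},
        is_elements=_IS_TABLE_AEROBIC,
        sv_macrodomain_weights={"Ter": 3.0},
        slippage_fraction=0.514,
    )
    anaerobic = EnvironmentConfig(
        design=anae,
        bps_rates=_rates_from_counts(
            {"A:T>G:C": 5, "G:C>A:T": 33, "A:T>C:G": 14,
             "G:C>T:A": 9, "A:T>T:A": 6, "G:C>C:G": 6},
            anae,
        ),
        indel_rate=20 / (anae.L * anae.N * anae.T),
        sv_rates=_rates_from_counts(
            {"IS_insertion": 53, "IS_mediated_deletion": 7,
             "IS_mediated_inversion": 2, "IS_mediated_translocation": 1,
             "repeat_mediated": 1, "other": 1},
            anae,
        ),
        strand_odds={"G:C>A:T": 0.5, "A:T>C:G": 2.0},
        is_elements=_IS_TABLE_ANAEROBIC,
        sv_macrodomain_weights={"Ter": 3.0},
        slippage_fraction=0.514,
    )
    return SimulationConfig(seed=seed, environments={AEROBIC: aerobic, ANAEROBIC: anaerobic})


# -- MA catalog simulation -------------------------------------------------


def _class_targets(pair_class: str) -> dict[str, str]:
    """ref base -> alt base for both orientations of a pair class."""
    left, right = pair_class.split(">")
    r1, r2 = left.split(":")
    a1, a2 = right.split(":")
    return {r1: a1, r2: a2}


def _site_weights(
    model: GenomeModel, eligible: np.ndarray, cw_mask: np.ndarray, odds: float
) -> np.ndarray:
    w = np.where(cw_mask[eligible], odds, 1.0)
    return w / w.sum()


def simulate_ma(config: SimulationConfig, model: GenomeModel) -> MutationSet:
    """Generate a mutation catalog under the configured generative model."""
    rng = np.random.default_rng(config.seed)
    seq = np.frombuffer(model.sequence.encode("ascii"), dtype="S1")
    positions_1based = np.arange(1, model.length + 1)
    ori, ter, L = model.ori_position, model.ter_position, model.length
    arc = (ter - ori) % L or L
    cw_mask = ((positions_1based - ori) % L) < arc

    base_indices = {
        b: np.flatnonzero(seq == b.encode()) for b in "ACGT"
    }

    records: list[MutationRecord] = []
    lineages: dict[str, list[str]] = {}
    for env_name, env in config.environments.items():
        design = env.design
        lineage_ids = design.lineage_ids()
        lineages[env_name] = lineage_ids
        gens = design.N * design.T

        # cached per-class eligible-site distributions
        class_sites: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for pc in PAIR_CLASSES:
            targets = _class_targets(pc)
            eligible = np.concatenate([base_indices[b] for b in targets])
            eligible.sort()
            if eligible.size == 0:
                continue
            odds = env.strand_odds.get(pc, 1.0)
            probs = _site_weights(model, eligible, cw_mask, odds) if odds != 1.0 else None
            class_sites[pc] = (eligible, probs)

        sv_probs = None
        if model.macrodomains is not None and env.sv_macrodomain_weights:
            w = np.ones(model.length)
            for name, start, end in model.macrodomains:
                if name in env.sv_macrodomain_weights:
                    idx = (np.arange((end - start) % L or L) + start - 1) % L
                    w[idx] = env.sv_macrodomain_weights[name]
            sv_probs = w / w.sum()

        is_table = [e for e in env.is_elements if e.copies * e.activity > 0]
        is_p = None
        if is_table:
            is_w = np.array([e.copies * e.activity for e in is_table], dtype=float)
            is_p = is_w / is_w.sum()

        for lid in lineage_ids:
            # substitutions
            for pc, rate in env.bps_rates.items():
                if pc not in class_sites or rate == 0:
                    continue
                n = rng.poisson(rate * gens)
                if n == 0:
                    continue
                eligible, probs = class_sites[pc]
                idx = rng.choice(eligible, size=n, p=probs)
                targets = _class_targets(pc)
                for i in idx:
                    ref = model.sequence[i]
                    records.append(
                        MutationRecord(
                            lineage_id=lid,
                            environment=env_name,
                            position=int(i) + 1,
                            mclass="BPS",
                            ref_base=ref,
                            alt_base=targets[ref],
                        )
                    )
            # indels
            n = rng.poisson(env.indel_rate * gens)
            for _ in range(n):
                pos = int(rng.integers(1, model.length + 1))
                length = int(rng.integers(1, 5)) * (1 if rng.random() < 0.5 else -1)
                records.append(
                    MutationRecord(
                        lineage_id=lid,
                        environment=env_name,
                        position=pos,
                        mclass="INDEL",
                        indel_length=length,
                        slippage_flag=bool(rng.random() < env.slippage_fraction),
                    )
                )
            # structural variants
            for sv_type, rate in env.sv_rates.items():
                if sv_type not in SV_TYPES:
                    raise ValueError(f"unknown SV type {sv_type!r} in configuration")
                n = rng.poisson(rate * gens)
                if n == 0:
                    continue
                if sv_probs is not None:
                    pos_idx = rng.choice(model.length, size=n, p=sv_probs)
                else:
                    pos_idx = rng.integers(0, model.length, size=n)
                for i in pos_idx:
                    if sv_type.startswith("IS_") and is_table:
                        element = is_table[int(rng.choice(len(is_table), p=is_p))].name
                    elif sv_type == "repeat_mediated":
                        element = "rhs"
                    else:
                        element = None
                    records.append(
                        MutationRecord(
                            lineage_id=lid,
                            environment=env_name,
                            position=int(i) + 1,
                            mclass="SV",
                            sv_type=sv_type,
                            element=element,
                        )
                    )
    return MutationSet(records=records, lineages=lineages)


# -- Luria-Delbrück culture simulation ------------------------------------


def simulate_fluctuation(
    mu_per_division: float,
    n0: int,
    n_final: int,
    n_cultures: int,
    seed: int,
) -> FluctuationExperiment:
    """Simulate parallel cultures under the classic Luria-Delbrück model.

    Growth from ``n0`` to ``n_final`` cells comprises ``n_final - n0``
    divisions; each division mutates with probability ``mu_per_division``,
    so the number of mutational events per culture is Poisson with mean
    ``m = mu * (n_final - n0)``.  Divisions are asynchronous — they occur
    at population sizes uniform on ``(n0, n_final)`` — and a mutant clone
    born when the population has ``n`` cells expands deterministically with
    the culture to ``floor(n_final / n)`` cells (equal fitness, perfect
    plating).  In the ``n_final >> n0`` limit this yields the classic
    clone-size law ``P(size = k) = 1/(k(k+1))`` and hence the
    Luria-Delbrück mutant-count distribution of :func:`mutacc.fluctuation.ld_pmf`.
    """
    if not 0 <= mu_per_division <= 1e-4:
        raise ValueError("mu_per_division must lie in [0, 1e-4]")
    if n0 < 1 or n_final < n0:
        raise ValueError("need 1 <= n0 <= n_final")
    rng = np.random.default_rng(seed)
    n_divisions = n_final - n0
    events = rng.poisson(mu_per_division * n_divisions, size=n_cultures)
    counts = np.zeros(n_cultures, dtype=np.int64)
    total = int(events.sum())
    if total:
        birth_sizes = rng.uniform(n0, n_final, size=total)
        clone_sizes = np.floor(n_final / birth_sizes).astype(np.int64)
        owners = np.repeat(np.arange(n_cultures), events)
        np.add.at(counts, owners, clone_sizes)
    return FluctuationExperiment(
        mutant_counts=counts,
        final_cells=float(n_final),
        metadata={
            "mu_per_division": mu_per_division,
            "n0": n0,
            "generations": math.log2(n_final / n0),
        },
    )


# -- toy genomes -----------------------------------------------------------


@dataclass(frozen=True)
class ToyGenomeSpec:
    """Shape of a generated test genome."""

    length: int = 10_000
    coding_fraction: float = 0.5
    gc_content: float = 0.5
    ori: int = 1
    ter: int | None = None
    n_macrodomains: int = 4

    def __post_init__(self) -> None:
        if self.length < 100:
            raise ValueError("toy genomes need at least 100 bp")
        if not 0 <= self.coding_fraction <= 1:
            raise ValueError("coding fraction must lie in [0, 1]")
        if not 0 < self.gc_content < 1:
            raise ValueError("GC content must lie in (0, 1)")


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


def _tile_genes(
    rng: np.random.Generator, length: int, coding_fraction: float
) -> list[tuple[int, int, int]]:
    """Non-overlapping (start, end, strand) CDS tiling ~coding_fraction."""
    if coding_fraction == 0:
        return []
    genes = []
    pos = 1
    coding = 0
    while pos < length - 60:
        gene_len = 3 * int(rng.integers(60, 140))
        end = pos + gene_len
        if end > length + 1:
            gene_len = 3 * ((length + 1 - pos) // 3)
            if gene_len < 60:
                break
            end = pos + gene_len
        strand = 1 if rng.random() < 0.5 else -1
        genes.append((pos, end, strand))
        coding += gene_len
        # steer the running coding fraction toward the target
        gap = max(0, round(coding / coding_fraction - end))
        if gap:
            gap = int(rng.integers(max(1, gap // 2), 2 * gap))
        pos = end + gap
    # absorb any systematic trailing deficit with one final gene
    deficit = int(coding_fraction * length - coding)
    tail_room = length + 1 - pos
    if deficit >= 60 and tail_room >= 60:
        gene_len = 3 * (min(deficit, tail_room) // 3)
        genes.append((pos, pos + gene_len, 1))
    return genes


def make_toy_genome(
    spec: ToyGenomeSpec, seed: int, out_dir: str | Path
) -> tuple[GenomeModel, dict[str, Path]]:
    """Write a FASTA + GFF3 + geometry bundle and return the round-tripped model.

    The files are byte-deterministic given (spec, seed); the realized
    coding fraction tracks the spec to within a couple of percent for
    genomes of a few kb and up.
    """
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    genes = _tile_genes(rng, spec.length, spec.coding_fraction)
    seq = list(_random_sequence(rng, spec.length, spec.gc_content))
    # gene starts get ATG / stops get TAA on the annotated strand so the
    # files look like real annotation; effects tests use genuine codons
    for start, end, strand in genes:
        if strand > 0:
            seq[start - 1 : start + 2] = "ATG"
            seq[end - 4 : end - 1] = "TAA"
        else:
            seq[end - 4 : end - 1] = "CAT"
            seq[start - 1 : start + 2] = "TTA"
    sequence = "".join(seq)

    ter = spec.ter if spec.ter is not None else spec.length // 2 + 1
    fasta = out_dir / "toy_genome.fasta"
    with open(fasta, "w") as fh:
        fh.write(">toy_genome synthetic test genome\n")
        for i in range(0, spec.length, 70):
            fh.write(sequence[i : i + 70] + "\n")

    gff = out_dir / "toy_genome.gff3"
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for k, (start, end, strand) in enumerate(genes, 1):
            fh.write(
                "\t".join(
                    [
                        "toy_genome", "mutacc_sim", "CDS",
                        str(start), str(end - 1),
                        ".", "+" if strand > 0 else "-", "0",
                        f"ID=gene{k:04d}",
                    ]
                )
                + "\n"
            )

    md_size = spec.length // spec.n_macrodomains
    macrodomains = []
    for k in range(spec.n_macrodomains):
        start = 1 + k * md_size
        end = spec.length + 1 if k == spec.n_macrodomains - 1 else 1 + (k + 1) * md_size
        macrodomains.append({"name": f"MD{k + 1}", "start": start, "end": end})
    geometry = out_dir / "toy_geometry.yaml"
    with open(geometry, "w") as fh:
        yaml.safe_dump(
            {"ori": spec.ori, "ter": ter, "macrodomains": macrodomains},
            fh,
            sort_keys=False,
        )

    model = build_genome_model(fasta, gff, geometry)
    return model, {"fasta": fasta, "annotation": gff, "geometry": geometry}


def synthetic_study_genome(seed: int = 0, coding_ratio: float = 7.83) -> GenomeModel:
    """A full-size random genome on the packaged REL4536-like geometry.

    4.6 Mb, ~50% GC, protein-coding:non-coding ratio targeting the
    published genome-wide value.  Entirely synthetic sequence: positions
    and composition are realistic in aggregate but individual loci mean
    nothing.
    """
    geometry = rel4536_geometry()
    length = 4_600_000
    rng = np.random.default_rng(seed)
    sequence = _random_sequence(rng, length, 0.508)
    genes = _tile_genes(rng, length, coding_ratio / (1 + coding_ratio))
    from .genome_model import CodingInterval

    intervals = [
        CodingInterval(start, end, strand, f"sgene{k:05d}")
        for k, (start, end, strand) in enumerate(genes, 1)
    ]
    return GenomeModel(
        sequence=sequence,
        ori_position=geometry["ori"],
        ter_position=geometry["ter"],
        macrodomains=geometry.get("macrodomains"),
        coding_intervals=intervals,
    )
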