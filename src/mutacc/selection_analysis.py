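"""Null-model selection diagnostics for MA substitution data.

An MA experiment is designed so that selection barely filters mutations;
two diagnostics check that claim:

* **dN/dS against a neutral expectation.**  The observed nonsynonymous to
  synonymous count ratio among coding substitutions is compared to the
  ratio expected with *no* selection, given the genome's codon usage and
  the observed transition:transversion ratio ``R``.  The expectation
  enumerates, for every sense codon (weighted by usage), its nine
  single-nucleotide neighbours, weighting each transition ``2R`` and each
  transversion ``1`` — each codon position offers one transition and two
  transversions, so the implied event-level ts:tv equals ``R`` — and
  returns total nonsynonymous weight over total synonymous weight.
  Stop-gaining changes count as nonsynonymous.

* **Coding vs non-coding placement.**  Under neutrality substitutions land
  in coding sequence in proportion to the genome's coding:non-coding ratio;
  a deficit in coding sequence indicates purifying selection (or
  preferential repair of coding DNA).

Both comparisons use the 1-df Pearson chi-square of
:func:`mutacc.spectrum_analysis.chi_square_gof`.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .genome_model import GenomeModel
from .mutation_catalog import MutationSet
from .spectrum_analysis import chi_square_gof

__all__ = [
    "CodonUsage",
    "SelectionSummary",
    "codon_usage_from_annotation",
    "ecoli_codon_usage",
    "expected_dnds",
    "observed_dnds",
    "dnds_test",
    "coding_test",
    "coding_counts_test",
]

_BACTERIAL_TABLE = CodonTable.unambiguous_dna_by_id[11]
_STOPS = set(_BACTERIAL_TABLE.stop_codons)
_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

SENSE_CODONS = tuple(
    a + b + c
    for a in "TCAG"
    for b in "TCAG"
    for c in "TCAG"
    if a + b + c not in _STOPS
)


@dataclass(frozen=True)
class CodonUsage:
    """Genome-wide counts of the 61 sense codons, coding-strand orientation."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(SENSE_CODONS)
        if unknown:
            raise ValueError(f"non-sense codons in usage table: {sorted(unknown)}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("codon counts must be non-negative")
        if sum(self.counts.values()) <= 0:
            raise ValueError("codon usage is empty")

    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"codon": list(SENSE_CODONS), "count": [self.counts.get(c, 0) for c in SENSE_CODONS]}
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "CodonUsage":
        frame = pd.read_csv(path, sep="\t", comment="#")
        return cls(dict(zip(frame["codon"], frame["count"].astype(int))))


def codon_usage_from_annotation(model: GenomeModel) -> CodonUsage:
    """Count codons over all annotated CDS, coding-strand orientation.

    CDS whose length is not a multiple of three are skipped with a warning;
    stop codons are excluded from the table.
    """
    if not model.coding_intervals:
        raise ValueError("genome model carries no CDS annotation")
    counts: dict[str, int] = dict.fromkeys(SENSE_CODONS, 0)
    L = model.length
    for iv in model.coding_intervals:
        n = (iv.end - iv.start) % L or L
        if n % 3:
            warnings.warn(
                f"CDS {iv.gene_id!r} length {n} not divisible by 3; skipped",
                stacklevel=2,
            )
            continue
        idx = [(iv.start - 1 + k) % L for k in range(n)]
        seq = "".join(model.sequence[i] for i in idx)
        if iv.strand < 0:
            seq = str(Seq(seq).reverse_complement())
        for k in range(0, n, 3):
            codon = seq[k : k + 3]
            if codon in counts:
                counts[codon] += 1
    if sum(counts.values()) == 0:
        raise ValueError("annotation yielded no sense codons")
    return CodonUsage(counts)


def ecoli_codon_usage() -> CodonUsage:
    """Packaged stand-in genomic codon-usage table for E. coli.

    Synthetic fixture: constructed from published E. coli genomic codon
    usage frequencies, not counted from the study strain's annotation.
    """
    ref = importlib.resources.files("mutacc.fixtures") / "codon_usage_ecoli_synthetic.tsv"
    with importlib.resources.as_file(ref) as path:
        return CodonUsage.read(path)


def _neighbor_changes(codon: str):
    """Yield (alt_codon, is_transition) for the 9 single-base neighbours."""
    for pos in range(3):
        ref = codon[pos]
        for alt in "ACGT":
            if alt == ref:
                continue
            yield codon[:pos] + alt + codon[pos + 1 :], alt == _TRANSITION[ref]


def expected_dnds(usage: CodonUsage, R: float, weighting: str = "event") -> float:
    """Expected nonsynonymous:synonymous ratio in the absence of selection.

    See the module docstring for the default ``weighting="event"`` (each
    transition weighted ``2R``, each transversion ``1``, making the implied
    event-level ts:tv equal ``R``); ``R`` is the observed
    transition:transversion ratio.  ``weighting="uniform"`` is an
    exploratory alternative that ignores ``R`` and weights all nine
    neighbour changes equally.
    """
    if R <= 0:
        raise ValueError("ts/tv ratio R must be positive")
    if weighting not in {"event", "uniform"}:
        raise ValueError(f"unknown weighting {weighting!r}")
    ts_weight = 2 * R if weighting == "event" else 1.0
    forward = _BACTERIAL_TABLE.forward_table
    nonsyn = syn = 0.0
    for codon, n in usage.counts.items():
        if n == 0:
            continue
        aa = forward[codon]
        for alt_codon, is_ts in _neighbor_changes(codon):
            weight = n * (ts_weight if is_ts else 1.0)
            if alt_codon in _STOPS or forward[alt_codon] != aa:
                nonsyn += weight
            else:
                syn += weight
    if syn == 0:
        raise ZeroDivisionError("usage admits no synonymous changes")
    return nonsyn / syn


@dataclass(frozen=True)
class SelectionSummary:
    """Observed/expected dN/dS (or coding/non-coding) comparison."""

    nonsyn: int
    syn: int
    observed_ratio: float
    expected_ratio: float | None = None
    chi_square: float | None = None
    df: int | None = None
    p: float | None = None


def observed_dnds(
    mset: MutationSet, environment: str | None = None
) -> SelectionSummary:
    """Observed nonsynonymous:synonymous count ratio over coding BPSs.

    Requires an annotated catalog (:func:`mutacc.mutation_catalog.annotate_mutations`).
    """
    sub = mset.filter(environment=environment, mclass="BPS")
    nonsyn = sum(1 for r in sub if r.effect == "nonsynonymous")
    syn = sum(1 for r in sub if r.effect == "synonymous")
    if any(r.effect == "unset" for r in sub):
        raise ValueError("catalog has unannotated BPS effects; annotate first")
    if nonsyn + syn == 0:
        raise ValueError("no coding BPSs observed; dN/dS undefined")
    if syn == 0:
        raise ZeroDivisionError(
            f"no synonymous substitutions observed ({nonsyn} nonsynonymous); "
            "ratio undefined"
        )
    return SelectionSummary(nonsyn=nonsyn, syn=syn, observed_ratio=nonsyn / syn)


def dnds_test(nonsyn: int, syn: int, expected_ratio: float) -> SelectionSummary:
    """1-df chi-square of observed (nonsyn, syn) counts against an expected ratio.

    The total is split ``expected_ratio : 1`` to form expected counts.
    """
    if nonsyn < 0 or syn < 0 or nonsyn + syn == 0:
        raise ValueError("need non-negative counts with a positive total")
    total = nonsyn + syn
    exp_nonsyn = total * expected_ratio / (1 + expected_ratio)
    exp_syn = total / (1 + expected_ratio)
    statistic, df, p = chi_square_gof([nonsyn, syn], [exp_nonsyn, exp_syn])
    return SelectionSummary(
        nonsyn=nonsyn,
        syn=syn,
        observed_ratio=nonsyn / syn if syn else float("inf"),
        expected_ratio=expected_ratio,
        chi_square=statistic,
        df=df,
        p=p,
    )


def coding_counts_test(
    n_coding: int, n_noncoding: int, coding_ratio: float
) -> SelectionSummary:
    """Chi-square of a (coding, noncoding) split against the genome's ratio."""
    summary = dnds_test(n_coding, n_noncoding, coding_ratio)
    return summary


def coding_test(
    mset: MutationSet,
    model: GenomeModel | None = None,
    environment: str | None = None,
    coding_ratio: float | None = None,
) -> SelectionSummary:
    """Coding vs non-coding BPS placement against the genome expectation.

    The expected split is proportional to ``(coding_ratio, 1)``; the ratio
    is taken from ``model.coding_noncoding_ratio()`` unless supplied
    explicitly (useful when only the published genome-wide ratio is known).
    """
    if coding_ratio is None:
        if model is None:
            raise ValueError("supply a genome model or an explicit coding_ratio")
        coding_ratio = model.coding_noncoding_ratio()
    sub = mset.filter(environment=environment, mclass="BPS")
    if any(r.coding_status == "unset" for r in sub):
        raise ValueError("catalog has unannotated coding status; annotate first")
    n_coding = sum(1 for r in sub if r.coding_status == "coding")
    n_noncoding = sum(1 for r in sub if r.coding_status == "noncoding")
    return coding_counts_test(n_coding, n_noncoding, coding_ratio)
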