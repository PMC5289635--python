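"""Chromosome replication geometry, base composition and coding annotation.

The bacterial chromosome is circular and replicated bidirectionally from a
single origin (*oriC*) to the terminus (*ter*), which splits it into two
arms, the *replichores*.  On the clockwise replichore the conventional top
strand templates lagging-strand synthesis; on the counter-clockwise
replichore it templates the leading strand.  Large-scale chromosome
structure is further organised into *macrodomains* (Ori, Ter, Left, Right
and two non-structured arms) that constrain recombination.

:class:`GenomeModel` bundles this geometry with the genome sequence and the
annotated protein-coding intervals, and answers the position → context
queries (which replichore? which macrodomain? coding or not?) that the
mutation-spectrum and selection analyses rely on.

Coordinate conventions
----------------------
All coordinates are 1-based.  Intervals are closed on the left and open on
the right, ``[start, end)``, and may wrap past the end of the circular
chromosome; a boundary position belongs to the interval that starts at it.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from Bio import SeqIO

__all__ = [
    "CLOCKWISE",
    "COUNTER_CLOCKWISE",
    "GeometryError",
    "AnnotationError",
    "CodingInterval",
    "GenomeModel",
    "load_geometry",
    "rel4536_geometry",
    "build_genome_model",
    "replichore_of",
    "macrodomain_of",
    "coding_noncoding_ratio",
]

CLOCKWISE = "clockwise"
COUNTER_CLOCKWISE = "counter_clockwise"

BASES = ("A", "C", "G", "T")


class GeometryError(ValueError):
    """Raised when replication-geometry configuration is absent or invalid."""


class AnnotationError(ValueError):
    """Raised when an annotation feature is inconsistent with the sequence."""


@dataclass(frozen=True)
class CodingInterval:
    """One annotated CDS: 1-based ``[start, end)`` on ``strand`` (+1/-1)."""

    start: int
    end: int
    strand: int
    gene_id: str


def _arc_length(start: int, end: int, length: int) -> int:
    """Length of the wrapping arc ``[start, end)`` on a circle of ``length``."""
    return (end - start) % length or length


def _in_arc(position: int, start: int, end: int, length: int) -> bool:
    return (position - start) % length < _arc_length(start, end, length)


@dataclass
class GenomeModel:
    """Circular genome with replication geometry and coding annotation.

    Parameters
    ----------
    sequence
        Top-strand sequence, upper-case A/C/G/T (other letters are allowed
        but never count as a focal base).
    ori_position, ter_position
        1-based origin and terminus of replication.  The clockwise
        replichore is the arc ``[ori, ter)`` in increasing coordinates,
        the counter-clockwise replichore is ``[ter, ori)``.
    macrodomains
        Ordered ``(name, start, end)`` intervals tiling the chromosome,
        or ``None`` when macrodomain coordinates are not configured.
    coding_intervals
        Annotated CDS features.
    """

    sequence: str
    ori_position: int
    ter_position: int
    macrodomains: list[tuple[str, int, int]] | None = None
    coding_intervals: list[CodingInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        L = len(self.sequence)
        if L == 0:
            raise GeometryError("genome sequence is empty")
        if self.ori_position == self.ter_position:
            raise GeometryError("ori and ter must differ")
        for pos, name in ((self.ori_position, "ori"), (self.ter_position, "ter")):
            if not 1 <= pos <= L:
                raise GeometryError(f"{name} position {pos} outside genome of {L} bp")
        if self.macrodomains is not None:
            covered = sum(_arc_length(s, e, L) for _, s, e in self.macrodomains)
            if covered != L:
                raise GeometryError(
                    f"macrodomain intervals cover {covered} bp, genome is {L} bp"
                )
        for iv in self.coding_intervals:
            if not (1 <= iv.start <= L and 1 <= iv.end <= L + 1):
                raise AnnotationError(
                    f"CDS {iv.gene_id!r} [{iv.start}, {iv.end}) outside genome of {L} bp"
                )
        self._seq_array = np.frombuffer(self.sequence.encode("ascii"), dtype="S1")

    # -- basic geometry ---------------------------------------------------

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def replichores(self) -> dict[str, tuple[int, int, int]]:
        """``label -> (start, end, length_bp)`` for the two replichores."""
        L = self.length
        return {
            CLOCKWISE: (
                self.ori_position,
                self.ter_position,
                _arc_length(self.ori_position, self.ter_position, L),
            ),
            COUNTER_CLOCKWISE: (
                self.ter_position,
                self.ori_position,
                _arc_length(self.ter_position, self.ori_position, L),
            ),
        }

    def _check_position(self, position: int) -> None:
        if not 1 <= position <= self.length:
            raise ValueError(
                f"position {position} outside genome of {self.length} bp"
            )

    def replichore_of(self, position: int) -> str:
        self._check_position(position)
        ori, ter, L = self.ori_position, self.ter_position, self.length
        return CLOCKWISE if _in_arc(position, ori, ter, L) else COUNTER_CLOCKWISE

    def macrodomain_of(self, position: int) -> str:
        if self.macrodomains is None:
            raise GeometryError(
                "macrodomain coordinates are not configured for this genome; "
                "supply them in the geometry configuration"
            )
        self._check_position(position)
        L = self.length
        for name, start, end in self.macrodomains:
            if _in_arc(position, start, end, L):
                return name
        raise GeometryError(f"position {position} not covered by any macrodomain")

    def macrodomain_lengths(self) -> dict[str, int]:
        if self.macrodomains is None:
            raise GeometryError("macrodomain coordinates are not configured")
        return {
            name: _arc_length(s, e, self.length) for name, s, e in self.macrodomains
        }

    # -- composition ------------------------------------------------------

    def _positions_of_arc(self, start: int, end: int) -> np.ndarray:
        """0-based indices of the wrapping arc ``[start, end)``."""
        n = _arc_length(start, end, self.length)
        return (np.arange(n) + start - 1) % self.length

    def base_counts(self, replichore: str | None = None) -> dict[str, int]:
        """Top-strand A/C/G/T counts, genome-wide or within one replichore."""
        if replichore is None:
            arr = self._seq_array
        else:
            start, end, _ = self.replichores[replichore]
            arr = self._seq_array[self._positions_of_arc(start, end)]
        return {b: int(np.count_nonzero(arr == b.encode())) for b in BASES}

    def base_pair_counts(self) -> dict[str, int]:
        """Counts of A:T and G:C base *pairs* (each top-strand base is one pair)."""
        counts = self.base_counts()
        return {"A:T": counts["A"] + counts["T"], "G:C": counts["G"] + counts["C"]}

    def base_at(self, position: int) -> str:
        self._check_position(position)
        return self.sequence[position - 1]

    # -- coding annotation ------------------------------------------------

    def coding_mask(self) -> np.ndarray:
        """Boolean array of length ``length``; index ``pos-1`` is True iff coding."""
        mask = np.zeros(self.length, dtype=bool)
        for iv in self.coding_intervals:
            mask[self._positions_of_arc(iv.start, iv.end)] = True
        return mask

    def is_coding(self, position: int) -> bool:
        self._check_position(position)
        L = self.length
        return any(
            _in_arc(position, iv.start, iv.end, L) for iv in self.coding_intervals
        )

    def cds_at(self, position: int) -> CodingInterval | None:
        """First annotated CDS containing ``position`` (annotation order)."""
        L = self.length
        for iv in self.coding_intervals:
            if _in_arc(position, iv.start, iv.end, L):
                return iv
        return None

    def coding_noncoding_ratio(self) -> float:
        """(bp covered by ≥1 CDS) / (bp covered by none); overlaps counted once."""
        if not self.coding_intervals:
            raise AnnotationError("no coding intervals annotated")
        mask = self.coding_mask()
        coding = int(mask.sum())
        noncoding = self.length - coding
        if noncoding == 0:
            raise ZeroDivisionError("genome is entirely coding; ratio undefined")
        return coding / noncoding


# -- geometry configuration ----------------------------------------------


def load_geometry(source: str | Path) -> dict:
    """Read a geometry configuration (YAML: ``ori``, ``ter``, ``macrodomains``)."""
    with open(source) as fh:
        geometry = yaml.safe_load(fh)
    return _validate_geometry(geometry)


def _validate_geometry(geometry: Mapping) -> dict:
    if geometry is None or "ori" not in geometry or "ter" not in geometry:
        raise GeometryError(
            "geometry configuration must define 'ori' and 'ter' coordinates"
        )
    out = {"ori": int(geometry["ori"]), "ter": int(geometry["ter"])}
    mds = geometry.get("macrodomains")
    if mds:
        out["macrodomains"] = [
            (str(md["name"]), int(md["start"]), int(md["end"])) for md in mds
        ]
    return out


def rel4536_geometry() -> dict:
    """Packaged REL4536-like geometry (synthetic coordinates).

    The published arc lengths are reproduced exactly — a 2.06 Mb clockwise
    and a 2.54 Mb counter-clockwise replichore — but the origin is placed at
    coordinate 1 and the macrodomain boundaries are synthetic placeholders,
    since the study strain's exact coordinates are not published.  Override
    with :func:`load_geometry` for a genuinely annotated genome.
    """
    ref = importlib.resources.files("mutacc.fixtures") / "rel4536_geometry_synthetic.yaml"
    with importlib.resources.as_file(ref) as path:
        return load_geometry(path)


# -- construction ---------------------------------------------------------


def _read_sequence(source: str | Path) -> str:
    records = list(SeqIO.parse(str(source), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {source}")
    if len(records) > 1:
        raise ValueError("expected a single-replicon FASTA")
    return str(records[0].seq).upper()


def _cds_from_genbank(source: str | Path) -> list[CodingInterval]:
    record = SeqIO.read(str(source), "genbank")
    intervals = []
    for feat in record.features:
        if feat.type != "CDS":
            continue
        gene = feat.qualifiers.get("locus_tag", feat.qualifiers.get("gene", ["?"]))[0]
        intervals.append(
            CodingInterval(
                start=int(feat.location.start) + 1,
                end=int(feat.location.end) + 1,
                strand=feat.location.strand or 1,
                gene_id=gene,
            )
        )
    return intervals


def _cds_from_gff(source: str | Path) -> list[CodingInterval]:
    intervals = []
    with open(source) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8 or fields[2] != "CDS":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            ) if len(fields) > 8 else {}
            gene = attrs.get("ID", attrs.get("Parent", "?"))
            intervals.append(
                CodingInterval(
                    start=int(fields[3]),
                    end=int(fields[4]) + 1,  # GFF end is inclusive
                    strand=-1 if fields[6] == "-" else 1,
                    gene_id=gene,
                )
            )
    return intervals


def build_genome_model(
    sequence: str | Path,
    annotation: str | Path | None,
    geometry: Mapping | str | Path,
) -> GenomeModel:
    """Assemble a :class:`GenomeModel` from FASTA + annotation + geometry.

    ``annotation`` may be a GenBank flat file (``.gb``/``.gbk``/``.gbff``)
    or GFF3; ``geometry`` is a configuration mapping or path (see
    :func:`load_geometry`).  There are no silent geometry defaults: a
    genome other than the packaged fixture must bring its own coordinates.
    """
    seq = _read_sequence(sequence)
    if isinstance(geometry, (str, Path)):
        geometry = load_geometry(geometry)
    else:
        geometry = _validate_geometry(geometry)

    intervals: list[CodingInterval] = []
    if annotation is not None:
        suffix = Path(str(annotation)).suffix.lower()
        if suffix in {".gb", ".gbk", ".gbff", ".genbank"}:
            intervals = _cds_from_genbank(annotation)
        else:
            intervals = _cds_from_gff(annotation)
        for iv in intervals:
            if not (1 <= iv.start <= len(seq) and iv.end <= len(seq) + 1):
                raise AnnotationError(
                    f"feature {iv.gene_id!r} [{iv.start}, {iv.end}) lies outside "
                    f"the {len(seq)} bp sequence"
                )

    return GenomeModel(
        sequence=seq,
        ori_position=geometry["ori"],
        ter_position=geometry["ter"],
        macrodomains=geometry.get("macrodomains"),
        coding_intervals=intervals,
    )


# -- functional aliases matching the analysis vocabulary -------------------


def replichore_of(model: GenomeModel, position: int) -> str:
    """Replichore label (:data:`CLOCKWISE` or :data:`COUNTER_CLOCKWISE`)."""
    return model.replichore_of(position)


def macrodomain_of(model: GenomeModel, position: int) -> str:
    return model.macrodomain_of(position)


def coding_noncoding_ratio(model: GenomeModel) -> float:
    return model.coding_noncoding_ratio()
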