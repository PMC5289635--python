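"""Typed mutation catalog: the tabular record of every mutation detected
across the mutation-accumulation (MA) lineages.

One row per mutation, one of three classes:

* ``BPS`` — base-pair substitution, recorded on the conventional top strand.
  Because the two strands are complementary, the 12 ordered base changes
  collapse into 6 strand-symmetric *pair classes* (e.g. an A→G on the top
  strand and a T→C on the top strand are the same A:T>G:C event).
* ``INDEL`` — insertion or deletion of one to a few nucleotides, frequently
  replication slippage within repeats (``slippage_flag``).
* ``SV`` — structural variant: insertion-sequence (IS) transpositions and
  IS/repeat-mediated deletions, inversions and translocations; anchored by
  the left-most breakpoint on the top strand.

The on-disk dialect is tab-delimited with a fixed header
(:data:`CATALOG_COLUMNS`); unset fields are written as ``"."``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .genome_model import GenomeModel

__all__ = [
    "AEROBIC",
    "ANAEROBIC",
    "ENVIRONMENTS",
    "MUTATION_CLASSES",
    "SV_TYPES",
    "PAIR_CLASSES",
    "TRANSITION_CLASSES",
    "TRANSVERSION_CLASSES",
    "CATALOG_COLUMNS",
    "CatalogError",
    "MutationRecord",
    "MutationSet",
    "classify_bps",
    "annotate_mutations",
    "read_mutation_table",
    "write_mutation_table",
]

AEROBIC = "aerobic"
ANAEROBIC = "anaerobic"
ENVIRONMENTS = (AEROBIC, ANAEROBIC)

MUTATION_CLASSES = ("BPS", "INDEL", "SV")
SV_TYPES = (
    "IS_insertion",
    "IS_mediated_deletion",
    "IS_mediated_inversion",
    "IS_mediated_translocation",
    "repeat_mediated",
    "other",
)

#: The six strand-symmetric substitution classes.
PAIR_CLASSES = (
    "A:T>G:C",
    "G:C>A:T",
    "A:T>C:G",
    "G:C>T:A",
    "A:T>T:A",
    "G:C>C:G",
)
TRANSITION_CLASSES = ("A:T>G:C", "G:C>A:T")
TRANSVERSION_CLASSES = ("A:T>C:G", "G:C>T:A", "A:T>T:A", "G:C>C:G")

CATALOG_COLUMNS = [
    "lineage_id",
    "environment",
    "position",
    "mclass",
    "ref_base",
    "alt_base",
    "indel_length",
    "slippage_flag",
    "sv_type",
    "element",
    "coding_status",
    "effect",
]

UNSET = "."
_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


class CatalogError(ValueError):
    """Raised on malformed catalog rows or inconsistent records."""


def classify_bps(ref_base: str, alt_base: str) -> tuple[str, str]:
    """Collapse a top-strand substitution into its pair class.

    Returns ``(pair_class, focal_top_strand_base)`` where the focal base is
    the literal top-strand reference base.  Complementary substitutions map
    to the same class: ``(A, G)`` and ``(T, C)`` are both ``A:T>G:C``.
    """
    ref = ref_base.upper()
    alt = alt_base.upper()
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        raise CatalogError(
            f"ambiguous or invalid nucleotide in substitution {ref_base}>{alt_base}"
        )
    if ref == alt:
        raise CatalogError(f"reference and alternate base are both {ref}")
    # orient so the purine of the reference pair leads the label
    if ref in "AT":
        a = alt if ref == "A" else _COMPLEMENT[alt]
        label = f"A:T>{a}:{_COMPLEMENT[a]}"
    else:
        g = alt if ref == "G" else _COMPLEMENT[alt]
        label = f"G:C>{g}:{_COMPLEMENT[g]}"
    return label, ref


@dataclass
class MutationRecord:
    """A single mutation.  Class-specific fields are ``None`` unless the
    class matches (``ref_base``/``alt_base`` for BPS, ``indel_length`` and
    ``slippage_flag`` for INDEL, ``sv_type``/``element`` for SV)."""

    lineage_id: str
    environment: str
    position: int
    mclass: str
    ref_base: str | None = None
    alt_base: str | None = None
    indel_length: int | None = None
    slippage_flag: bool | None = None
    sv_type: str | None = None
    element: str | None = None
    coding_status: str = "unset"
    effect: str = "unset"
    replichore: str | None = None
    macrodomain: str | None = None

    def __post_init__(self) -> None:
        if self.environment not in ENVIRONMENTS:
            raise CatalogError(f"unknown environment {self.environment!r}")
        if self.mclass not in MUTATION_CLASSES:
            raise CatalogError(f"unknown mutation class {self.mclass!r}")
        if self.position < 1:
            raise CatalogError(f"position must be a positive integer, got {self.position}")
        if self.mclass == "BPS":
            if self.ref_base is None or self.alt_base is None:
                raise CatalogError("BPS records require ref_base and alt_base")
            classify_bps(self.ref_base, self.alt_base)  # validates
            self.ref_base = self.ref_base.upper()
            self.alt_base = self.alt_base.upper()
            if self.indel_length is not None or self.sv_type is not None:
                raise CatalogError("BPS records must not carry indel or SV fields")
        elif self.mclass == "INDEL":
            if self.indel_length is None or self.indel_length == 0:
                raise CatalogError("INDEL records require a nonzero indel_length")
            if self.slippage_flag is None:
                self.slippage_flag = False
            if self.ref_base is not None or self.sv_type is not None:
                raise CatalogError("INDEL records must not carry BPS or SV fields")
        else:  # SV
            if self.sv_type not in SV_TYPES:
                raise CatalogError(f"unknown sv_type {self.sv_type!r}")
            if self.ref_base is not None or self.indel_length is not None:
                raise CatalogError("SV records must not carry BPS or indel fields")

    @property
    def pair_class(self) -> str | None:
        if self.mclass != "BPS":
            return None
        return classify_bps(self.ref_base, self.alt_base)[0]

    @property
    def focal_base(self) -> str | None:
        if self.mclass != "BPS":
            return None
        return self.ref_base


@dataclass
class MutationSet:
    """An ordered collection of :class:`MutationRecord`.

    ``lineages`` optionally declares, per environment, the full set of
    lineage identifiers in the experiment so that lineages with zero
    mutations still enter rate denominators.
    """

    records: list[MutationRecord] = field(default_factory=list)
    lineages: dict[str, list[str]] | None = None

    def __post_init__(self) -> None:
        if self.lineages is not None:
            declared = {
                (env, lid) for env, lids in self.lineages.items() for lid in lids
            }
            for rec in self.records:
                if (rec.environment, rec.lineage_id) not in declared:
                    raise CatalogError(
                        f"lineage {rec.lineage_id!r} ({rec.environment}) is not "
                        "declared in the experiment design"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MutationRecord]:
        return iter(self.records)

    def filter(
        self,
        environment: str | None = None,
        mclass: str | None = None,
        predicate: Callable[[MutationRecord], bool] | None = None,
    ) -> "MutationSet":
        recs = [
            r
            for r in self.records
            if (environment is None or r.environment == environment)
            and (mclass is None or r.mclass == mclass)
            and (predicate is None or predicate(r))
        ]
        return MutationSet(records=recs, lineages=self.lineages)

    def class_totals(self, environment: str | None = None) -> dict[str, int]:
        totals = dict.fromkeys(MUTATION_CLASSES, 0)
        for rec in self.records:
            if environment is None or rec.environment == environment:
                totals[rec.mclass] += 1
        return totals

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "lineage_id": r.lineage_id,
                    "environment": r.environment,
                    "position": r.position,
                    "mclass": r.mclass,
                    "ref_base": r.ref_base or UNSET,
                    "alt_base": r.alt_base or UNSET,
                    "indel_length": UNSET if r.indel_length is None else r.indel_length,
                    "slippage_flag": UNSET
                    if r.slippage_flag is None
                    else str(bool(r.slippage_flag)),
                    "sv_type": r.sv_type or UNSET,
                    "element": r.element or UNSET,
                    "coding_status": r.coding_status,
                    "effect": r.effect,
                }
            )
        return pd.DataFrame(rows, columns=CATALOG_COLUMNS)


# -- I/O -------------------------------------------------------------------


def write_mutation_table(mset: MutationSet, path: str | Path) -> None:
    """Write the tab-delimited catalog dialect (fixed column order)."""
    mset.to_frame().to_csv(path, sep="\t", index=False)


def _parse_row(row: Mapping, row_number: int) -> MutationRecord:
    def opt(key):
        val = row[key]
        return None if (pd.isna(val) or val == UNSET) else val

    try:
        position = int(row["position"])
    except (TypeError, ValueError):
        raise CatalogError(
            f"row {row_number}: position {row['position']!r} is not an integer"
        ) from None
    indel_length = opt("indel_length")
    if indel_length is not None:
        try:
            indel_length = int(indel_length)
        except (TypeError, ValueError):
            raise CatalogError(
                f"row {row_number}: indel_length {indel_length!r} is not an integer"
            ) from None
    slippage = opt("slippage_flag")
    if slippage is not None:
        slippage = str(slippage).strip().lower() in {"true", "1", "yes"}
    try:
        return MutationRecord(
            lineage_id=str(row["lineage_id"]),
            environment=str(row["environment"]),
            position=position,
            mclass=str(row["mclass"]),
            ref_base=opt("ref_base"),
            alt_base=opt("alt_base"),
            indel_length=indel_length,
            slippage_flag=slippage,
            sv_type=opt("sv_type"),
            element=opt("element"),
            coding_status=str(row.get("coding_status", "unset") or "unset"),
            effect=str(row.get("effect", "unset") or "unset"),
        )
    except CatalogError as exc:
        raise CatalogError(f"row {row_number}: {exc}") from None


def read_mutation_table(
    source: str | Path, lineages: dict[str, list[str]] | None = None
) -> MutationSet:
    """Read a tab-delimited catalog; every row is validated on the way in."""
    frame = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False, na_values=[])
    missing = [c for c in CATALOG_COLUMNS if c not in frame.columns]
    if missing:
        raise CatalogError(f"catalog is missing required columns: {missing}")
    records = [
        _parse_row(row, i + 2)  # +2: 1-based with header line
        for i, row in enumerate(frame.to_dict("records"))
    ]
    return MutationSet(records=records, lineages=lineages)


# -- annotation ------------------------------------------------------------


def _bps_effect(rec: MutationRecord, model: GenomeModel) -> str:
    cds = model.cds_at(rec.position)
    if cds is None:
        return "intergenic"
    if cds.strand >= 0:
        offset = (rec.position - cds.start) % model.length
    else:
        offset = (cds.end - 1 - rec.position) % model.length
    codon_index, within = divmod(offset, 3)
    codon_positions = []
    for k in range(3):
        off = codon_index * 3 + k
        if cds.strand >= 0:
            pos = (cds.start - 1 + off) % model.length + 1
        else:
            pos = (cds.end - 2 - off) % model.length + 1
        codon_positions.append(pos)
    ref_codon = "".join(
        model.base_at(p) if cds.strand >= 0 else _COMPLEMENT[model.base_at(p)]
        for p in codon_positions
    )
    alt = rec.alt_base if cds.strand >= 0 else _COMPLEMENT[rec.alt_base]
    alt_codon = ref_codon[:within] + alt + ref_codon[within + 1 :]
    ref_aa = str(Seq(ref_codon).translate(table=11))
    alt_aa = str(Seq(alt_codon).translate(table=11))
    return "synonymous" if ref_aa == alt_aa else "nonsynonymous"


def annotate_mutations(mset: MutationSet, model: GenomeModel) -> MutationSet:
    """Fill coding status, codon-level effect and replichore/macrodomain labels.

    BPS reference bases are checked against the genome sequence; a mismatch
    rejects the whole set, naming the offending record.  Annotation is
    idempotent: re-annotating an annotated set is a no-op.
    """
    out = []
    for rec in mset.records:
        if rec.position > model.length:
            raise CatalogError(
                f"record at position {rec.position} exceeds genome length {model.length}"
            )
        if rec.mclass == "BPS" and model.base_at(rec.position) != rec.ref_base:
            raise CatalogError(
                f"BPS at {rec.position} ({rec.lineage_id}): catalog ref_base "
                f"{rec.ref_base} does not match genome base {model.base_at(rec.position)}"
            )
        coding = model.is_coding(rec.position)
        if rec.mclass == "BPS":
            effect = _bps_effect(rec, model) if coding else "intergenic"
        else:
            effect = "unset"
        out.append(
            replace(
                rec,
                coding_status="coding" if coding else "noncoding",
                effect=effect,
                replichore=model.replichore_of(rec.position),
                macrodomain=model.macrodomain_of(rec.position)
                if model.macrodomains is not None
                else None,
            )
        )
    return MutationSet(records=out, lineages=mset.lineages)
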