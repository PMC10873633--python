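"""Data model and I/O for germline segment libraries, AIRR rearrangement
tables, and per-cell metadata.

The germline library stores annotated V/D/J nucleotide segments. FASTA
headers use a pipe-delimited dialect defined by this package::

    >IGHV1-1*01|IGH|V|285

i.e. ``segment_id|locus|segment_type|cdr3_anchor``, where the anchor is the
0-based offset of the conserved junction-boundary codon (the V-gene
cysteine or the J-gene tryptophan/phenylalanine) within the segment. D
segments carry no anchor (empty fourth field, or a three-field header).

Receptor data flow through AIRR Rearrangement TSVs (one row per chain)
grouped into :class:`ReceptorCell` objects, optionally merged with a
per-cell metadata CSV carrying surface-marker intensities, donor, tested
reactivity and endpoint concentrations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._utils import check_nucleotides

logger = logging.getLogger(__name__)

LOCI = frozenset({"IGH", "IGK", "IGL", "TRA", "TRB"})
SEGMENT_TYPES = frozenset({"V", "D", "J"})
HEAVY_LOCI = frozenset({"IGH", "TRB"})
CELL_STATES = frozenset({"MBC", "prePB", "PB", "PC", "unknown"})
REACTIVITIES = frozenset({"LGI1", "CASPR2", "other_CNS", "negative", "untested"})
MARKERS = ("CD3", "CD4", "CD8", "CD14", "CD19", "CD20", "CD27", "CD38", "CD138")

#: Genomic order of the IgG constant genes on the IGH locus; class-switch
#: recombination deletes intervening DNA, so switching is only ever to a
#: gene further downstream in this order.
IGG_SUBCLASS_ORDER = ("IGHG3", "IGHG1", "IGHG2", "IGHG4")

AIRR_COLUMNS = (
    "cell_id",
    "locus",
    "sequence",
    "v_call",
    "d_call",
    "j_call",
    "junction",
    "junction_aa",
    "c_call",
    "n_region_mask",
)
MANDATORY_AIRR = ("cell_id", "locus", "sequence", "junction", "c_call")


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(ValueError):
    """In-memory data violate a domain invariant."""


@dataclass(frozen=True)
class Segment:
    segment_id: str
    locus: str
    segment_type: str
    sequence: str
    cdr3_anchor: int | None = None

    def __post_init__(self) -> None:
        if self.locus not in LOCI:
            raise ValidationError(f"{self.segment_id}: unknown locus {self.locus!r}")
        if self.segment_type not in SEGMENT_TYPES:
            raise ValidationError(
                f"{self.segment_id}: unknown segment type {self.segment_type!r}"
            )
        check_nucleotides(self.sequence, f"segment {self.segment_id}")
        if self.segment_type in ("V", "J"):
            if self.cdr3_anchor is None:
                raise ValidationError(
                    f"{self.segment_id}: {self.segment_type} segment requires a cdr3_anchor"
                )
            if not 0 <= self.cdr3_anchor <= len(self.sequence) - 3:
                raise ValidationError(
                    f"{self.segment_id}: cdr3_anchor {self.cdr3_anchor} outside sequence"
                )


@dataclass
class SegmentLibrary:
    """An ordered collection of germline segments with unique ids."""

    segments: list[Segment]

    def __post_init__(self) -> None:
        ids = [s.segment_id for s in self.segments]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise ValidationError(f"duplicate segment ids: {sorted(dup)}")
        self._by_id = {s.segment_id: s for s in self.segments}

    def __len__(self) -> int:
        return len(self.segments)

    def __getitem__(self, segment_id: str) -> Segment:
        return self._by_id[segment_id]

    def __contains__(self, segment_id: str) -> bool:
        return segment_id in self._by_id

    def select(self, locus: str, segment_type: str) -> list[Segment]:
        return [
            s
            for s in self.segments
            if s.locus == locus and s.segment_type == segment_type
        ]


@dataclass
class ChainRecord:
    """One assembled V(D)J chain of one cell."""

    cell_id: str
    locus: str
    sequence: str
    junction: str
    c_call: str | None = None
    v_call: str | None = None
    d_call: str | None = None
    j_call: str | None = None
    junction_aa: str | None = None
    #: 0-based positions of non-templated (N-region) nucleotides; available
    #: for simulated or pre-annotated data only.
    n_region_mask: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.junction_aa and len(self.junction) % 3 != 0:
            raise ValidationError(
                f"{self.cell_id}/{self.locus}: junction length {len(self.junction)} "
                "not a multiple of 3 despite junction_aa"
            )
        if self.n_region_mask and (
            min(self.n_region_mask) < 0 or max(self.n_region_mask) >= len(self.sequence)
        ):
            raise ValidationError(
                f"{self.cell_id}/{self.locus}: n_region_mask outside sequence bounds"
            )


@dataclass
class ReceptorCell:
    """One cell with a heavy chain, optional light chain and metadata."""

    cell_id: str
    heavy: ChainRecord
    light: ChainRecord | None = None
    donor: str = "unknown"
    markers: dict[str, float] = field(default_factory=dict)
    cell_state: str = "unknown"
    reactivity: str = "untested"
    endpoint_conc: float | None = None

    def __post_init__(self) -> None:
        if self.cell_state not in CELL_STATES:
            raise ValidationError(f"{self.cell_id}: unknown cell_state {self.cell_state!r}")
        if self.reactivity not in REACTIVITIES:
            raise ValidationError(f"{self.cell_id}: unknown reactivity {self.reactivity!r}")
        if self.endpoint_conc is not None and not self.endpoint_conc > 0:
            raise ValidationError(f"{self.cell_id}: endpoint_conc must be positive")


# ---------------------------------------------------------------------------
# germline FASTA


def _parse_header(header: str) -> tuple[str, str, str, int | None]:
    parts = header.split("|")
    if len(parts) not in (3, 4):
        raise FormatError(
            f"malformed FASTA header {header!r}: expected id|locus|type|anchor"
        )
    segment_id, locus, segment_type = parts[:3]
    anchor: int | None = None
    if len(parts) == 4 and parts[3] not in ("", "-"):
        try:
            anchor = int(parts[3])
        except ValueError as exc:
            raise FormatError(f"malformed anchor in header {header!r}") from exc
    return segment_id, locus, segment_type, anchor


def read_segment_fasta(path: str | Path) -> SegmentLibrary:
    """Read a germline segment library from FASTA (header dialect above)."""
    segments = []
    for rec in SeqIO.parse(str(path), "fasta"):
        segment_id, locus, segment_type, anchor = _parse_header(rec.description)
        try:
            segments.append(
                Segment(segment_id, locus, segment_type, str(rec.seq).upper(), anchor)
            )
        except ValidationError as exc:
            raise FormatError(f"record {rec.description!r}: {exc}") from exc
    return SegmentLibrary(segments)


def write_segment_fasta(library: SegmentLibrary, path: str | Path) -> None:
    records = []
    for s in library.segments:
        anchor = "" if s.cdr3_anchor is None else str(s.cdr3_anchor)
        header = f"{s.segment_id}|{s.locus}|{s.segment_type}|{anchor}"
        records.append(SeqRecord(Seq(s.sequence), id=header, description=""))
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# AIRR rearrangement TSV


def _mask_to_str(mask: frozenset[int]) -> str:
    return ",".join(str(i) for i in sorted(mask))


def _str_to_mask(text: str) -> frozenset[int]:
    if not text or pd.isna(text):
        return frozenset()
    return frozenset(int(tok) for tok in str(text).split(","))


def write_airr(cells: Sequence[ReceptorCell], path: str | Path) -> None:
    """Write cells as an AIRR Rearrangement TSV, one row per chain."""
    rows = []
    for cell in cells:
        chains = [cell.heavy] + ([cell.light] if cell.light else [])
        for ch in chains:
            rows.append(
                {
                    "cell_id": ch.cell_id,
                    "locus": ch.locus,
                    "sequence": ch.sequence,
                    "v_call": ch.v_call or "",
                    "d_call": ch.d_call or "",
                    "j_call": ch.j_call or "",
                    "junction": ch.junction,
                    "junction_aa": ch.junction_aa or "",
                    "c_call": ch.c_call or "",
                    "n_region_mask": _mask_to_str(ch.n_region_mask),
                }
            )
    pd.DataFrame(rows, columns=list(AIRR_COLUMNS)).to_csv(path, sep="\t", index=False)


def write_metadata(cells: Sequence[ReceptorCell], path: str | Path) -> None:
    """Write per-cell metadata (donor, markers, state, reactivity) as CSV."""
    rows = []
    for cell in cells:
        row: dict[str, object] = {
            "cell_id": cell.cell_id,
            "donor": cell.donor,
            "cell_state": cell.cell_state,
            "reactivity": cell.reactivity,
            "endpoint_conc": cell.endpoint_conc,
        }
        for m in MARKERS:
            if m in cell.markers:
                row[m] = cell.markers[m]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def _row_to_chain(row: pd.Series) -> ChainRecord:
    def get(col: str) -> str | None:
        val = row.get(col)
        if val is None or (isinstance(val, float) and pd.isna(val)) or val == "":
            return None
        return str(val)

    return ChainRecord(
        cell_id=str(row["cell_id"]),
        locus=str(row["locus"]),
        sequence=str(row["sequence"]),
        junction=get("junction") or "",
        junction_aa=get("junction_aa"),
        c_call=get("c_call"),
        v_call=get("v_call"),
        d_call=get("d_call"),
        j_call=get("j_call"),
        n_region_mask=_str_to_mask(row.get("n_region_mask", "")),
    )


def read_airr(
    path: str | Path,
    metadata: str | Path | None = None,
) -> tuple[list[ReceptorCell], list[str]]:
    """Read an AIRR Rearrangement TSV into :class:`ReceptorCell` objects.

    Chains are grouped by ``cell_id``. Cells with more than one heavy-locus
    chain are excluded (logged); the excluded ids are returned alongside the
    kept cells. A metadata CSV (cell_id keyed) merges donor, marker, state,
    reactivity and endpoint-concentration columns.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty and df.columns.size == 0:
        warnings.warn(f"{path}: empty AIRR file", stacklevel=2)
        return [], []
    missing = [c for c in MANDATORY_AIRR if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory AIRR columns {missing}")
    if df.empty:
        warnings.warn(f"{path}: AIRR file has no rows", stacklevel=2)
        return [], []

    meta_df = None
    if metadata is not None:
        meta_df = pd.read_csv(metadata).set_index("cell_id")

    cells: list[ReceptorCell] = []
    excluded: list[str] = []
    for cell_id, group in df.groupby("cell_id", sort=False):
        heavies = group[group["locus"].isin(HEAVY_LOCI)]
        lights = group[~group["locus"].isin(HEAVY_LOCI)]
        if len(heavies) > 1:
            excluded.append(str(cell_id))
            logger.warning("cell %s: %d heavy chains, excluded", cell_id, len(heavies))
            continue
        if heavies.empty:
            excluded.append(str(cell_id))
            logger.warning("cell %s: no heavy chain, excluded", cell_id)
            continue
        heavy = _row_to_chain(heavies.iloc[0])
        light = _row_to_chain(lights.iloc[0]) if not lights.empty else None
        cell = ReceptorCell(cell_id=str(cell_id), heavy=heavy, light=light)
        if meta_df is not None and cell_id in meta_df.index:
            row = meta_df.loc[cell_id]
            markers = {m: float(row[m]) for m in MARKERS if m in row and pd.notna(row[m])}
            conc = row.get("endpoint_conc")
            cell = replace(
                cell,
                donor=str(row.get("donor", cell.donor)),
                cell_state=str(row.get("cell_state", cell.cell_state)),
                reactivity=str(row.get("reactivity", cell.reactivity)),
                markers=markers,
                endpoint_conc=None if conc is None or pd.isna(conc) else float(conc),
            )
        cells.append(cell)
    return cells, excluded


# ---------------------------------------------------------------------------
# surface-phenotype gating


DEFAULT_THRESHOLDS = {m: 0.5 for m in MARKERS}


def gate_phenotype(
    markers: Mapping[str, float],
    thresholds: Mapping[str, float] | None = None,
) -> str:
    """Assign a FACS-style phenotype class from surface-marker intensities.

    Antibody-secreting cells (ASC) are CD3- CD138+ or CD3- CD19+ CD20- CD38+;
    B cells are CD3- CD19+ non-ASCs; CD4 T cells are CD3+ CD4+ CD138-.
    Everything else is ``other``. Positivity is intensity strictly above the
    per-marker threshold (default 0.5 on a normalized 0-1 scale).
    """
    thresholds = dict(DEFAULT_THRESHOLDS, **(thresholds or {}))
    missing = [m for m in MARKERS if m not in markers]
    if missing:
        raise ValidationError(f"missing markers: {missing}")
    pos = {m: markers[m] > thresholds[m] for m in MARKERS}
    if not pos["CD3"]:
        if pos["CD138"] or (pos["CD19"] and not pos["CD20"] and pos["CD38"]):
            return "ASC"
        if pos["CD19"]:
            return "B"
    elif pos["CD4"] and not pos["CD138"]:
        return "CD4T"
    return "other"


def validate_cells(cells: Iterable[ReceptorCell]) -> None:
    """Check dataset-level invariants (unique cell ids, valid sequences)."""
    seen: set[str] = set()
    for cell in cells:
        if cell.cell_id in seen:
            raise ValidationError(f"duplicate cell_id {cell.cell_id}")
        seen.add(cell.cell_id)
        check_nucleotides(cell.heavy.sequence, f"{cell.cell_id} heavy")
        if cell.light is not None:
            check_nucleotides(cell.light.sequence, f"{cell.cell_id} light")
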