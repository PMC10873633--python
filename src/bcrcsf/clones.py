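"""Germline assignment, clonal clustering, founder identification and
clonality summaries.

Clones follow the Immcantation-style definition used throughout: cells
share a clone when their heavy chains use the same V gene and J gene
(allele-stripped), have identical junction length, and their junction
nucleotide sequences fall within Hamming distance < 6 under single-linkage
clustering.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from ._utils import decode, encode
from .germline import ChainRecord, ReceptorCell, SegmentLibrary, ValidationError
from .sim import size_category

#: Hamming-distance threshold (strict upper bound) for junction linkage.
DEFAULT_CLONE_THRESHOLD = 6

#: Minimum identity for a germline call to be accepted.
MIN_ASSIGN_IDENTITY = 0.5

#: Alignment ends are clipped back to the nearest run of this many
#: consecutive matches, so exonuclease-trimmed / N-region overhangs are
#: not reported as templated positions.
_CLIP_RUN = 4


@dataclass
class GermlineAssignment:
    """Best V/J germline call for one chain with a templated-position map."""

    chain: ChainRecord
    v_call: str | None
    j_call: str | None
    v_identity: float
    j_identity: float
    d_call: str | None = None
    #: observed positions with a germline template (V- or J-covered)
    positions: np.ndarray | None = None
    #: germline base (uint8 byte code) for each entry of ``positions``
    germline_bases: np.ndarray | None = None
    #: reading frame of the observed sequence (offset of the V alignment
    #: modulo 3, germline V segments being frame 0)
    frame: int = 0
    failed: bool = False

    @property
    def templated(self) -> set[int]:
        return set() if self.positions is None else set(int(p) for p in self.positions)


def _best_segment(seq_arr: np.ndarray, segments) -> tuple[object, int, float]:
    """Sliding ungapped alignment; returns (segment, offset, identity).

    Identity is matches / segment length over every full-containment
    offset; ties break to the lexicographically smallest segment_id.
    """
    best: tuple[float, str, int, object] | None = None
    n = seq_arr.size
    for seg in segments:
        g = encode(seg.sequence)
        m = g.size
        if m > n:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(seq_arr, m)
        matches = (windows == g).sum(axis=1)
        off = int(matches.argmax())
        ident = float(matches[off]) / m
        key = (-ident, seg.segment_id, off, seg)
        if best is None or key[:2] < best[:2]:
            best = key
    if best is None:
        return None, 0, 0.0
    return best[3], best[2], -best[0]


def _clip_alignment(match: np.ndarray) -> tuple[int, int]:
    """Return [start, end) columns of the alignment after clipping both
    ends back to the nearest run of ``_CLIP_RUN`` consecutive matches."""
    m = match.size
    if m < _CLIP_RUN:
        return (0, m) if match.all() else (0, 0)
    runs = np.convolve(match.astype(int), np.ones(_CLIP_RUN, dtype=int), "valid")
    full = np.nonzero(runs == _CLIP_RUN)[0]
    if full.size == 0:
        return (0, 0)
    return int(full[0]), int(full[-1]) + _CLIP_RUN


def assign_germline(chain: ChainRecord, library: SegmentLibrary) -> GermlineAssignment:
    """Assign best-matching germline V and J segments to a chain.

    V and J are chosen to maximize ungapped identity over sliding offsets;
    the templated-position map covers the clipped V and J alignments
    (junction-interior N/D positions carry no template). Chains where
    either call falls below 50% identity are flagged failed and excluded
    downstream.
    """
    if len(chain.sequence) < 50:
        raise ValidationError(f"{chain.cell_id}: sequence shorter than 50 nt")
    seq_arr = encode(chain.sequence)
    vs = library.select(chain.locus, "V")
    js = library.select(chain.locus, "J")
    v_seg, v_off, v_ident = _best_segment(seq_arr, vs)
    j_seg, j_off, j_ident = _best_segment(seq_arr, js)

    if v_seg is None or j_seg is None or v_ident < MIN_ASSIGN_IDENTITY \
            or j_ident < MIN_ASSIGN_IDENTITY:
        return GermlineAssignment(
            chain,
            v_call=v_seg.segment_id if v_seg else None,
            j_call=j_seg.segment_id if j_seg else None,
            v_identity=v_ident,
            j_identity=j_ident,
            failed=True,
        )

    positions: list[np.ndarray] = []
    bases: list[np.ndarray] = []
    v_arr = encode(v_seg.sequence)
    match_v = seq_arr[v_off:v_off + v_arr.size] == v_arr
    s, e = _clip_alignment(match_v)
    v_end = v_off + e
    positions.append(np.arange(v_off + s, v_off + e))
    bases.append(v_arr[s:e])

    j_arr = encode(j_seg.sequence)
    match_j = seq_arr[j_off:j_off + j_arr.size] == j_arr
    s, e = _clip_alignment(match_j)
    # the J map must not reach into the V-covered prefix
    j_lo = max(j_off + s, v_end)
    sel = np.arange(j_off + s, j_off + e)
    keep = sel >= j_lo
    positions.append(sel[keep])
    bases.append(j_arr[s:e][keep])

    return GermlineAssignment(
        chain,
        v_call=v_seg.segment_id,
        j_call=j_seg.segment_id,
        v_identity=v_ident,
        j_identity=j_ident,
        positions=np.concatenate(positions),
        germline_bases=np.concatenate(bases),
        frame=v_off % 3,
    )


def strip_allele(call: str) -> str:
    """IGHV3-23*01 -> IGHV3-23 (gene-level, not allele-level, identity)."""
    return call.split("*")[0]


@dataclass
class Clone:
    clone_id: str
    members: list[str]
    v_gene: str
    j_gene: str
    junction_length: int
    founder: str | None = None

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def size_category(self) -> str:
        return size_category(self.size)


def _clone_id(members: Sequence[str]) -> str:
    digest = hashlib.sha1("|".join(sorted(members)).encode()).hexdigest()
    return f"clone_{digest[:12]}"


def cluster_clones(
    cells: Sequence[ReceptorCell],
    assignments: Mapping[str, GermlineAssignment],
    threshold: int = DEFAULT_CLONE_THRESHOLD,
    junction_on: str = "nt",
) -> list[Clone]:
    """Partition cells into clones by heavy V gene, J gene, junction length
    and single-linkage junction Hamming distance < ``threshold`` (strict).

    ``junction_on`` selects nucleotide (``"nt"``, default, Immcantation
    convention) or amino-acid (``"aa"``) junctions for the distance.
    """
    if junction_on not in ("nt", "aa"):
        raise ValidationError(f"junction_on must be 'nt' or 'aa', got {junction_on!r}")

    groups: dict[tuple[str, str, int], list[tuple[str, str]]] = {}
    for cell in cells:
        asg = assignments.get(cell.cell_id)
        if asg is None or asg.failed:
            continue
        if cell.heavy.locus != cells[0].heavy.locus:
            raise ValidationError("mixed heavy-chain loci in one clustering run")
        junction = cell.heavy.junction if junction_on == "nt" else (
            cell.heavy.junction_aa or ""
        )
        key = (strip_allele(asg.v_call), strip_allele(asg.j_call), len(cell.heavy.junction))
        groups.setdefault(key, []).append((cell.cell_id, junction))

    clones: list[Clone] = []
    for (v_gene, j_gene, jlen), pairs in groups.items():
        pairs = sorted(pairs)
        ids = [p[0] for p in pairs]
        if len(pairs) == 1:
            labels = [1]
        else:
            mat = np.vstack([encode(p[1]) for p in pairs])
            dist = pdist(mat, metric="hamming") * mat.shape[1]
            z = linkage(dist, method="single")
            labels = fcluster(z, t=threshold - 0.5, criterion="distance")
        by_label: dict[int, list[str]] = {}
        for cid, lab in zip(ids, labels):
            by_label.setdefault(int(lab), []).append(cid)
        for members in by_label.values():
            members = sorted(members)
            clones.append(
                Clone(
                    clone_id=_clone_id(members),
                    members=members,
                    v_gene=v_gene,
                    j_gene=j_gene,
                    junction_length=jlen,
                )
            )
    clones.sort(key=lambda c: c.clone_id)
    return clones


def cluster_tcr_clones(cells: Sequence[ReceptorCell]) -> list[Clone]:
    """TCR clones: identical junction nucleotide sequences of all recovered
    chains (the stricter rule appropriate to unmutated TCRs)."""
    groups: dict[tuple[str, str], list[str]] = {}
    for cell in cells:
        key = (cell.heavy.junction, cell.light.junction if cell.light else "")
        groups.setdefault(key, []).append(cell.cell_id)
    clones = []
    for (jh, _jl), members in groups.items():
        members = sorted(members)
        clones.append(
            Clone(
                clone_id=_clone_id(members),
                members=members,
                v_gene="",
                j_gene="",
                junction_length=len(jh),
            )
        )
    clones.sort(key=lambda c: c.clone_id)
    return clones


def identify_founder(clone: Clone, mutation_counts: Mapping[str, int]) -> str:
    """The clone member with the fewest mutations (heavy + light summed);
    ties break to the lexicographically smallest cell_id."""
    missing = [m for m in clone.members if m not in mutation_counts]
    if missing:
        raise ValidationError(f"clone {clone.clone_id}: missing mutation counts {missing}")
    return min(clone.members, key=lambda m: (mutation_counts[m], m))


def clonality_fraction(
    cells: Sequence[ReceptorCell] | int,
    clones: Sequence[Clone] | None = None,
    n_clonal: int | None = None,
) -> float:
    """Fraction of cells lying within clones of size >= 2.

    Either pass cells and clones, or raw counts
    (``clonality_fraction(343, n_clonal=37)``).
    """
    if isinstance(cells, int):
        total = cells
        clonal = int(n_clonal or 0)
    else:
        if not cells:
            raise ValidationError("clonality_fraction undefined on empty input")
        total = len(cells)
        clonal = sum(c.size for c in (clones or []) if c.size >= 2)
    if total == 0:
        raise ValidationError("clonality_fraction undefined on empty input")
    return clonal / total
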