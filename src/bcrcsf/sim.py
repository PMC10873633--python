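"""Synthetic V(D)J repertoire generator with full ground truth.

Emulates the statistical structure of a clonally expanded IgG CSF
repertoire from autoimmune encephalitis: a small number of donors, clones
drawn from a size distribution dominated by singletons, a large
germline-to-founder (peripheral) mutation load versus a small intraclonal
(intrathecal) one, clone-level autoantigen reactivity whose probability
rises with clone size, downstream-only IgG subclass switching, an
ASC-dominated cell-state composition, and endpoint concentrations that
fall (binding strengthens) with total mutation count.

The model is substitution-only: somatic hypermutation introduces no
indels, so every member of a clone has the same sequence length as its
naive ancestor and germline reversion is a per-position operation. This
matches the assumption of the downstream UCA algorithm and is a documented
limitation (no SHM hotspot targeting, no insertions/deletions, no
selection).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._utils import NUCLEOTIDES, decode, encode, hamming
from .germline import (
    IGG_SUBCLASS_ORDER,
    MARKERS,
    ChainRecord,
    ReceptorCell,
    Segment,
    SegmentLibrary,
)


class ConfigurationError(ValueError):
    """The simulation configuration or library cannot produce a repertoire."""


#: Size-category labels shared with clonal inference.
SIZE_CATEGORIES = ("singleton", "small", "large")


def size_category(size: int) -> str:
    """singleton (1), small (2-3), large (>=4)."""
    if size <= 1:
        return "singleton"
    return "small" if size <= 3 else "large"


@dataclass
class SimConfig:
    """Parameters of the synthetic repertoire.

    Defaults emulate the study conditions: ~200 clones with mean size ~1.9
    (≈380 cells, matching the scale of a deeply sampled CSF repertoire),
    a heavy peripheral mutation load (mu_peripheral = 0.05 per site,
    germline→founder) against a light intrathecal one (mu_intrathecal =
    0.002 per branching), reactivity probabilities rising 0.6 → 0.8 → 1.0
    across singleton / 2-3-member / >=4-member clones, plasmablast-dominated
    cell states, and an IgG4-skewed subclass distribution with rare
    downstream-only switching.
    """

    n_clones: int = 200
    clone_size_weights: dict[int, float] = field(
        default_factory=lambda: {1: 0.60, 2: 0.16, 3: 0.10, 4: 0.05,
                                 5: 0.04, 6: 0.02, 7: 0.02, 8: 0.01}
    )
    mu_peripheral: float = 0.05
    mu_intrathecal: float = 0.002
    n_insertion_mean: float = 4.0
    trim_max: int = 3
    p_reactive_by_size: dict[str, float] = field(
        default_factory=lambda: {"singleton": 0.6, "small": 0.8, "large": 1.0}
    )
    state_weights: dict[str, float] = field(
        default_factory=lambda: {"MBC": 0.10, "prePB": 0.04, "PB": 0.60, "PC": 0.26}
    )
    subclass_start_weights: dict[str, float] = field(
        default_factory=lambda: {"IGHG3": 0.05, "IGHG1": 0.30,
                                 "IGHG2": 0.05, "IGHG4": 0.60}
    )
    p_switch: float = 0.10
    p_test_singleton: float = 0.5
    n_donors: int = 3
    seed: int = 42
    #: Reject a new clone whose founder junction lies within this Hamming
    #: distance of an existing same-V/J/length clone, so distinct simulated
    #: clones are identifiable by the <6 clustering rule.
    min_clone_junction_distance: int = 10

    def __post_init__(self) -> None:
        for name in ("mu_peripheral", "mu_intrathecal"):
            mu = getattr(self, name)
            if not 0.0 <= mu <= 0.2:
                raise ConfigurationError(f"{name}={mu} outside [0, 0.2]")
        for name in ("p_switch", "p_test_singleton"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p} outside [0, 1]")
        for key, p in self.p_reactive_by_size.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"p_reactive_by_size[{key}]={p} outside [0, 1]")
        for name in ("clone_size_weights", "state_weights", "subclass_start_weights"):
            w = getattr(self, name)
            if not w or any(v < 0 for v in w.values()) or sum(w.values()) <= 0:
                raise ConfigurationError(f"{name}: weights must be nonnegative, not all zero")
        if self.n_clones < 1:
            raise ConfigurationError("n_clones must be >= 1")


@dataclass
class SimTruth:
    """Ground truth for one simulated cell."""

    cell_id: str
    true_clone_id: str
    naive_heavy: str
    naive_light: str
    n_region_mask_heavy: frozenset[int]
    n_region_mask_light: frozenset[int]
    #: half-open span of junction-interior (N+D) positions on each chain;
    #: positions outside it are V/J germline-templated
    untemplated_span_heavy: tuple[int, int]
    untemplated_span_light: tuple[int, int]
    true_mut_peripheral: int
    true_mut_intrathecal: int
    true_reactivity: str
    true_state: str
    true_subclass_path: tuple[str, ...]


@dataclass
class RecombinedChain:
    chain: ChainRecord
    v_end: int            # end of the V-templated prefix in the assembled sequence
    j_start: int          # start of the J-templated suffix
    junction_start: int   # position of the V anchor codon (junction start)


# ---------------------------------------------------------------------------
# toy germline library


def _random_coding(rng: np.random.Generator, n_codons: int) -> str:
    """Random in-frame sequence without stop codons."""
    stops = {"TAA", "TAG", "TGA"}
    codons = []
    while len(codons) < n_codons:
        codon = "".join(rng.choice(list(NUCLEOTIDES), 3))
        if codon not in stops:
            codons.append(codon)
    return "".join(codons)


def toy_library(seed: int = 7) -> SegmentLibrary:
    """A small bundled germline library (5 V, 2 D, 3 J for IGH; 4 V, 2 J
    for IGK), generated deterministically. V anchors carry the conserved
    cysteine codon (TGT), J anchors the conserved tryptophan (TGG), in the
    positions real IMGT segments place them; sequences are otherwise random
    coding DNA. Not real germline genes — a synthetic stand-in for tests
    and simulation."""
    rng = np.random.default_rng(seed)
    segments: list[Segment] = []

    def make_v(gene: str, locus: str, n_codons: int) -> None:
        # anchor codon (Cys) sits two codons before the 3' end, leaving a
        # short germline tail that exonuclease trimming can chew back
        seq = _random_coding(rng, n_codons - 3) + "TGT" + _random_coding(rng, 2)
        anchor = 3 * (n_codons - 3)
        segments.append(Segment(f"{gene}*01", locus, "V", seq, anchor))

    def make_j(gene: str, locus: str, anchor_codons: int, tail_codons: int) -> None:
        # anchor codon sits after `anchor_codons` leading codons; tail keeps
        # the assembled sequence codon-complete
        head = _random_coding(rng, anchor_codons)
        tail = _random_coding(rng, tail_codons)
        seq = head + "TGG" + tail
        segments.append(Segment(f"{gene}*01", locus, "J", seq, len(head)))

    for i, gene in enumerate(["IGHV1-2", "IGHV2-5", "IGHV3-23", "IGHV4-34", "IGHV5-51"]):
        make_v(gene, "IGH", 98 + i)  # 294-306 nt
    for gene, length in [("IGHD2-2", 21), ("IGHD3-10", 24)]:
        seq = "".join(rng.choice(list(NUCLEOTIDES), length))
        segments.append(Segment(f"{gene}*01", "IGH", "D", seq, None))
    for gene in ["IGHJ4", "IGHJ5", "IGHJ6"]:
        make_j(gene, "IGH", anchor_codons=5, tail_codons=11)

    for i, gene in enumerate(["IGKV1-5", "IGKV2-28", "IGKV3-20", "IGKV4-1"]):
        make_v(gene, "IGK", 95 + i)
    for gene in ["IGKJ1", "IGKJ2"]:
        make_j(gene, "IGK", anchor_codons=3, tail_codons=9)

    return SegmentLibrary(segments)


# ---------------------------------------------------------------------------
# generative operations


def mutate(
    seq: str,
    mu: float,
    protected: frozenset[int] | set[int] = frozenset(),
    rng: np.random.Generator | None = None,
    *,
    spare_protected: bool = False,
) -> str:
    """Point-mutate each position independently with probability ``mu``.

    Substitutions go to a uniformly chosen *different* base; length never
    changes. By default N-region (``protected``) positions mutate like any
    other — real SHM does not spare them; pass ``spare_protected=True`` to
    exempt them.
    """
    if not 0.0 <= mu <= 0.2 and mu != 1.0:  # mu=1 allowed for forced-mutation tests
        raise ConfigurationError(f"mu={mu} outside [0, 0.2]")
    if rng is None:
        rng = np.random.default_rng()
    arr = encode(seq).copy()
    hit = rng.random(len(arr)) < mu
    if spare_protected and protected:
        hit[list(protected)] = False
    idx = np.nonzero(hit)[0]
    if idx.size == 0:
        return seq
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in idx:
        choices = bases[bases != arr[i]]
        arr[i] = rng.choice(choices)
    return decode(arr)


def _trim_amount(rng: np.random.Generator, trim_max: int, cap: int) -> int:
    cap = max(0, min(trim_max, cap))
    return int(rng.integers(0, cap + 1)) if cap > 0 else 0


def recombine(
    library: SegmentLibrary,
    cfg: SimConfig,
    rng: np.random.Generator,
    locus: str = "IGH",
) -> RecombinedChain:
    """Draw one naive V(D)J recombination event for ``locus``.

    sequence = trimmed V + N1 + (trimmed D + N2, heavy loci only) + trimmed J.
    The junction runs from the V anchor codon through the J anchor codon
    inclusive; N1 is padded so its length is a multiple of 3, preserving the
    reading frame. The returned mask covers exactly the inserted N positions.
    """
    vs = library.select(locus, "V")
    js = library.select(locus, "J")
    ds = library.select(locus, "D")
    use_d = locus in ("IGH", "TRB")
    if not vs or not js or (use_d and not ds):
        raise ConfigurationError(f"library lacks V/D/J segments for locus {locus}")

    v = vs[rng.integers(len(vs))]
    j = js[rng.integers(len(js))]
    tv = _trim_amount(rng, cfg.trim_max, len(v.sequence) - (v.cdr3_anchor + 3))
    v_kept = v.sequence[: len(v.sequence) - tv]

    d_kept = ""
    d_call = None
    if use_d:
        d = ds[rng.integers(len(ds))]
        t5 = _trim_amount(rng, cfg.trim_max, len(d.sequence) // 2 - 2)
        t3 = _trim_amount(rng, cfg.trim_max, len(d.sequence) // 2 - 2)
        d_kept = d.sequence[t5: len(d.sequence) - t3]
        d_call = d.segment_id

    tj = _trim_amount(rng, cfg.trim_max, j.cdr3_anchor)
    j_kept = j.sequence[tj:]
    j_anchor_in_kept = j.cdr3_anchor - tj

    def draw_n() -> str:
        n = int(rng.poisson(cfg.n_insertion_mean))
        return "".join(rng.choice(list(NUCLEOTIDES), n)) if n else ""

    n1, n2 = draw_n(), (draw_n() if use_d else "")

    # pad N1 until the junction (V anchor .. J anchor codon, inclusive) is
    # in frame, so junction_aa is always defined
    junction_start = v.cdr3_anchor
    while (len(v_kept) + len(n1) + len(d_kept) + len(n2) + j_anchor_in_kept + 3
           - junction_start) % 3 != 0:
        n1 += str(rng.choice(list(NUCLEOTIDES)))

    seq = v_kept + n1 + d_kept + n2 + j_kept
    v_end = len(v_kept)
    j_start = len(v_kept) + len(n1) + len(d_kept) + len(n2)
    junction_end = j_start + j_anchor_in_kept + 3
    junction = seq[junction_start:junction_end]

    mask = set(range(v_end, v_end + len(n1)))
    mask |= set(range(v_end + len(n1) + len(d_kept), j_start))

    from Bio.Seq import Seq

    chain = ChainRecord(
        cell_id="",
        locus=locus,
        sequence=seq,
        junction=junction,
        junction_aa=str(Seq(junction).translate()),
        v_call=v.segment_id,
        d_call=d_call,
        j_call=j.segment_id,
        n_region_mask=frozenset(mask),
    )
    return RecombinedChain(chain, v_end=v_end, j_start=j_start,
                           junction_start=junction_start)


def _templated_hamming(a: str, b: str, mask: frozenset[int]) -> int:
    """Hamming distance restricted to templated (non-N) positions."""
    arr_a, arr_b = encode(a), encode(b)
    diff = arr_a != arr_b
    if mask:
        diff[list(mask)] = False
    return int(np.count_nonzero(diff))


def _draw_markers(state: str, rng: np.random.Generator) -> dict[str, float]:
    """Surface-marker intensities consistent with the FACS gate rules."""
    positive = {
        "MBC": {"CD19", "CD20", "CD27"},
        "prePB": {"CD19", "CD38", "CD27"},
        "PB": {"CD19", "CD38", "CD27"},
        "PC": {"CD138", "CD38", "CD27"},
    }[state]
    return {
        m: float(rng.uniform(0.7, 1.0)) if m in positive else float(rng.uniform(0.0, 0.3))
        for m in MARKERS
    }


def _weighted_choice(rng: np.random.Generator, weights: dict) -> object:
    keys = list(weights.keys())
    w = np.asarray([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=w / w.sum())]


def simulate_repertoire(
    library: SegmentLibrary,
    cfg: SimConfig,
) -> tuple[list[ReceptorCell], list[SimTruth]]:
    """Simulate a full repertoire: cells plus per-cell ground truth.

    Per clone: one recombined naive ancestor (heavy + light), a founder
    obtained by mutating the naive at ``mu_peripheral``, and members grown
    along a random branching tree with ``mu_intrathecal`` per branch.
    Reactivity is drawn once per clone (clone members share reactivities);
    subclass switching only ever moves downstream on the constant-gene
    order IGHG3 < IGHG1 < IGHG2 < IGHG4.
    """
    rng = np.random.default_rng(cfg.seed)
    sizes = [int(_weighted_choice(rng, cfg.clone_size_weights))
             for _ in range(cfg.n_clones)]

    donor_antigen = {f"donor{i + 1}": ("CASPR2" if (i + 1) % 3 == 0 else "LGI1")
                     for i in range(cfg.n_donors)}
    donors = list(donor_antigen)

    # registry of founder junctions per (v, j, length) for the separation guard
    junction_registry: dict[tuple[str, str, int], list[str]] = {}

    cells: list[ReceptorCell] = []
    truths: list[SimTruth] = []
    cell_counter = 0

    for ci, size in enumerate(sizes):
        clone_id = f"simclone{ci:04d}"
        donor = donors[int(rng.integers(len(donors)))]

        for _attempt in range(200):
            rh = recombine(library, cfg, rng, "IGH")
            rl = recombine(library, cfg, rng, "IGK")
            founder_h = mutate(rh.chain.sequence, cfg.mu_peripheral, rng=rng)
            founder_l = mutate(rl.chain.sequence, cfg.mu_peripheral, rng=rng)
            jun_lo = rh.junction_start
            jun_hi = jun_lo + len(rh.chain.junction)
            founder_junction = founder_h[jun_lo:jun_hi]
            key = (rh.chain.v_call, rh.chain.j_call, len(founder_junction))
            neighbours = junction_registry.get(key, [])
            if all(hamming(founder_junction, other) >= cfg.min_clone_junction_distance
                   for other in neighbours):
                junction_registry.setdefault(key, []).append(founder_junction)
                break
        else:  # pragma: no cover - would need a pathological library
            raise ConfigurationError("could not draw a separable clone junction")

        start_subclass = str(_weighted_choice(rng, cfg.subclass_start_weights))
        order = list(IGG_SUBCLASS_ORDER)

        def maybe_switch(path: tuple[str, ...]) -> tuple[str, ...]:
            pos = order.index(path[-1])
            if pos < len(order) - 1 and rng.random() < cfg.p_switch:
                return path + (order[int(rng.integers(pos + 1, len(order)))],)
            return path

        # intraclonal branching: member 0 is the founder itself; subclass
        # switches are inherited by descendants (class-switch recombination
        # is irreversible and clonal)
        member_seqs: list[tuple[str, str, tuple[str, ...]]] = [
            (founder_h, founder_l, maybe_switch((start_subclass,)))
        ]
        for _ in range(size - 1):
            ph, pl, ppath = member_seqs[int(rng.integers(len(member_seqs)))]
            member_seqs.append(
                (mutate(ph, cfg.mu_intrathecal, rng=rng),
                 mutate(pl, cfg.mu_intrathecal, rng=rng),
                 maybe_switch(ppath))
            )

        cat = size_category(size)
        reactive = rng.random() < cfg.p_reactive_by_size.get(cat, 0.0)
        clone_label = donor_antigen[donor] if reactive else "negative"
        tested_member = int(rng.integers(size)) if size > 1 else (
            0 if rng.random() < cfg.p_test_singleton else -1
        )

        mut_p = (
            _templated_hamming(rh.chain.sequence, founder_h, rh.chain.n_region_mask)
            + _templated_hamming(rl.chain.sequence, founder_l, rl.chain.n_region_mask)
        )

        for mi, (hseq, lseq, path) in enumerate(member_seqs):
            cell_id = f"simcell{cell_counter:05d}"
            cell_counter += 1
            subclass = path[-1]

            state = str(_weighted_choice(rng, cfg.state_weights))
            markers = _draw_markers(state, rng)

            label = clone_label if mi == tested_member else "untested"
            mut_i = (
                _templated_hamming(founder_h, hseq, rh.chain.n_region_mask)
                + _templated_hamming(founder_l, lseq, rl.chain.n_region_mask)
            )

            conc = None
            if label in ("LGI1", "CASPR2"):
                log10c = 1.5 - 0.06 * (mut_p + mut_i) + rng.normal(0.0, 0.25)
                conc = float(10.0 ** log10c)

            heavy = ChainRecord(
                cell_id=cell_id,
                locus="IGH",
                sequence=hseq,
                junction=hseq[jun_lo:jun_hi],
                junction_aa=_translate(hseq[jun_lo:jun_hi]),
                v_call=rh.chain.v_call,
                d_call=rh.chain.d_call,
                j_call=rh.chain.j_call,
                c_call=subclass,
                n_region_mask=rh.chain.n_region_mask,
            )
            ljun_lo = rl.junction_start
            ljun_hi = ljun_lo + len(rl.chain.junction)
            light = ChainRecord(
                cell_id=cell_id,
                locus="IGK",
                sequence=lseq,
                junction=lseq[ljun_lo:ljun_hi],
                junction_aa=_translate(lseq[ljun_lo:ljun_hi]),
                v_call=rl.chain.v_call,
                j_call=rl.chain.j_call,
                c_call="IGKC",
                n_region_mask=rl.chain.n_region_mask,
            )
            cells.append(
                ReceptorCell(
                    cell_id=cell_id,
                    heavy=heavy,
                    light=light,
                    donor=donor,
                    markers=markers,
                    cell_state=state,
                    reactivity=label,
                    endpoint_conc=conc,
                )
            )
            truths.append(
                SimTruth(
                    cell_id=cell_id,
                    true_clone_id=clone_id,
                    naive_heavy=rh.chain.sequence,
                    naive_light=rl.chain.sequence,
                    n_region_mask_heavy=rh.chain.n_region_mask,
                    n_region_mask_light=rl.chain.n_region_mask,
                    untemplated_span_heavy=(rh.v_end, rh.j_start),
                    untemplated_span_light=(rl.v_end, rl.j_start),
                    true_mut_peripheral=mut_p,
                    true_mut_intrathecal=mut_i,
                    true_reactivity=clone_label,
                    true_state=state,
                    true_subclass_path=tuple(path),
                )
            )
    return cells, truths


def _translate(junction: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(junction).translate())


# ---------------------------------------------------------------------------
# truth I/O


def write_truth(truths: Sequence[SimTruth], path: str | Path) -> None:
    rows = []
    for t in truths:
        rows.append(
            {
                "cell_id": t.cell_id,
                "true_clone_id": t.true_clone_id,
                "naive_heavy": t.naive_heavy,
                "naive_light": t.naive_light,
                "n_region_mask_heavy": ",".join(map(str, sorted(t.n_region_mask_heavy))),
                "n_region_mask_light": ",".join(map(str, sorted(t.n_region_mask_light))),
                "untemplated_span_heavy": f"{t.untemplated_span_heavy[0]}-{t.untemplated_span_heavy[1]}",
                "untemplated_span_light": f"{t.untemplated_span_light[0]}-{t.untemplated_span_light[1]}",
                "true_mut_peripheral": t.true_mut_peripheral,
                "true_mut_intrathecal": t.true_mut_intrathecal,
                "true_reactivity": t.true_reactivity,
                "true_state": t.true_state,
                "true_subclass_path": ">".join(t.true_subclass_path),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> list[SimTruth]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    def mask(text: str) -> frozenset[int]:
        return frozenset(int(x) for x in text.split(",")) if text else frozenset()

    def span(text: str) -> tuple[int, int]:
        lo, hi = text.split("-")
        return int(lo), int(hi)

    return [
        SimTruth(
            cell_id=r["cell_id"],
            true_clone_id=r["true_clone_id"],
            naive_heavy=r["naive_heavy"],
            naive_light=r["naive_light"],
            n_region_mask_heavy=mask(r["n_region_mask_heavy"]),
            n_region_mask_light=mask(r["n_region_mask_light"]),
            untemplated_span_heavy=span(r["untemplated_span_heavy"]),
            untemplated_span_light=span(r["untemplated_span_light"]),
            true_mut_peripheral=int(r["true_mut_peripheral"]),
            true_mut_intrathecal=int(r["true_mut_intrathecal"]),
            true_reactivity=r["true_reactivity"],
            true_state=r["true_state"],
            true_subclass_path=tuple(r["true_subclass_path"].split(">")),
        )
        for _, r in df.iterrows()
    ]
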