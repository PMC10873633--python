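"""Unmutated-common-ancestor reconstruction, mutation counting, lineage
distances, and the peripheral-versus-intrathecal compartment contrast.

The UCA of a chain is obtained by germline reversion: every templated
position where the observed base differs from its germline template is
restored to the germline base. In the default ``revert_nonsilent`` mode
only substitutions that change the encoded amino acid are reverted;
``revert_all`` (the conventional UCA definition) reverts every templated
mismatch. N-region positions are never modified — they are non-templated
random insertions with no germline counterpart.

The compartment contrast compares, per clone, the distance from UCA to
founder (peripheral maturation, acquired before CNS entry) against the
distance from the founder to its furthest intraclonal member (intrathecal
maturation). Distances are normalized Hamming distances on the heavy
V(D)J — a documented proxy for phylogenetic (IgPhyML-style) distances, so
contrasts and orderings are comparable but absolute scales are not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

from ._utils import decode, encode, translate_codon
from .clones import Clone, GermlineAssignment
from .germline import ChainRecord, ValidationError

logger = logging.getLogger(__name__)

UCA_MODES = ("revert_nonsilent", "revert_all")


@dataclass
class UCAResult:
    """Reverted (UCA) sequence for one chain."""

    cell_id: str
    locus: str
    sequence: str
    n_positions_reverted: int
    n_region_positions_preserved: int
    mode: str


def reconstruct_uca(
    chain: ChainRecord,
    assignment: GermlineAssignment,
    mode: str = "revert_nonsilent",
    n_region_mask: frozenset[int] | None = None,
) -> UCAResult | None:
    """Backmutate a chain to its inferred naive (UCA) sequence.

    ``n_region_mask`` defaults to the chain's own mask (simulator /
    annotation truth) when present; positions without a germline template
    (outside the assignment's position map) are never touched either way.
    Returns None (logged) for chains whose germline assignment failed.
    """
    if mode not in UCA_MODES:
        raise ValidationError(f"unknown UCA mode {mode!r}")
    if assignment.failed:
        logger.warning("%s/%s: germline assignment failed; UCA skipped",
                       chain.cell_id, chain.locus)
        return None
    if assignment.positions is None:
        raise ValidationError(f"{chain.cell_id}: assignment has no position map; "
                              "frame cannot be established")
    mask = n_region_mask if n_region_mask is not None else chain.n_region_mask

    seq = encode(chain.sequence).copy()
    frame = assignment.frame
    n_reverted = 0
    # iterate to a fixed point: reverting one base of a multiply mutated
    # codon can change whether its neighbours are silent, so passes repeat
    # until nothing more reverts (monotone toward germline, so terminates);
    # this makes the reversion idempotent
    changed = True
    while changed:
        changed = False
        for p, g in zip(assignment.positions, assignment.germline_bases):
            p = int(p)
            if p in mask or seq[p] == g:
                continue
            if mode == "revert_nonsilent":
                start = p - ((p - frame) % 3)
                codon_obs = seq[start:start + 3].tobytes().decode()
                if len(codon_obs) == 3:
                    codon_rev = bytearray(codon_obs.encode())
                    codon_rev[p - start] = g
                    if translate_codon(codon_obs) == translate_codon(codon_rev.decode()):
                        continue  # silent substitution: left in place
            seq[p] = g
            n_reverted += 1
            changed = True

    return UCAResult(
        cell_id=chain.cell_id,
        locus=chain.locus,
        sequence=decode(seq),
        n_positions_reverted=n_reverted,
        n_region_positions_preserved=len(mask),
        mode=mode,
    )


def count_mutations(
    observed: str,
    uca: str,
    n_region_mask: frozenset[int] = frozenset(),
    templated: Sequence[int] | None = None,
) -> int:
    """Hamming distance between observed and UCA over templated positions.

    ``templated`` restricts to an explicit position set (e.g. the
    assignment map); otherwise every position outside the N-region mask
    counts.
    """
    if len(observed) != len(uca):
        raise ValidationError(
            f"length mismatch: observed {len(observed)} vs UCA {len(uca)}")
    diff = encode(observed) != encode(uca)
    if templated is not None:
        keep = np.zeros(len(observed), dtype=bool)
        keep[list(templated)] = True
        diff &= keep
    if n_region_mask:
        diff[list(n_region_mask)] = False
    return int(np.count_nonzero(diff))


def lineage_distance(seq_a: str, seq_b: str) -> float:
    """Normalized Hamming distance (mismatches / length) in [0, 1]."""
    if len(seq_a) != len(seq_b):
        raise ValidationError(
            f"length mismatch: {len(seq_a)} vs {len(seq_b)}")
    if not seq_a:
        raise ValidationError("empty sequences")
    return float(np.count_nonzero(encode(seq_a) != encode(seq_b))) / len(seq_a)


@dataclass
class CompartmentContrast:
    """Per-clone peripheral vs intrathecal distances with a paired test."""

    table: pd.DataFrame  # clone_id, size, size_category, d_peripheral, d_intrathecal
    median_peripheral: float
    median_intrathecal: float
    range_peripheral: tuple[float, float]
    range_intrathecal: tuple[float, float]
    p_value: float  # NaN when the paired test is not applicable
    n_clones: int
    p_value_small: float  # clones with < 4 members
    p_value_large: float  # clones with >= 4 members


def _paired_wilcoxon(d_p: np.ndarray, d_i: np.ndarray) -> float:
    """Two-sided paired Wilcoxon signed-rank p; NaN when undefined
    (fewer than one non-zero difference)."""
    if d_p.size == 0 or np.allclose(d_p, d_i):
        return float("nan")
    try:
        return float(wilcoxon(d_p, d_i, alternative="two-sided").pvalue)
    except ValueError:
        return float("nan")


def compartment_contrast(
    clones: Sequence[Clone],
    ucas: Mapping[str, str],
    sequences: Mapping[str, str],
) -> CompartmentContrast:
    """Per clone: d_peripheral = distance(UCA, founder) and d_intrathecal =
    max over members of distance(founder, member), on heavy chains.

    ``ucas`` maps founder cell_id -> UCA heavy sequence; ``sequences`` maps
    cell_id -> observed heavy sequence. Every clone must have its founder
    set. Singleton clones have d_intrathecal = 0 by construction.
    """
    if not clones:
        raise ValidationError("compartment contrast requires at least one clone")
    rows = []
    for clone in clones:
        if clone.founder is None:
            raise ValidationError(f"clone {clone.clone_id}: founder not identified")
        founder_seq = sequences[clone.founder]
        d_p = lineage_distance(ucas[clone.founder], founder_seq)
        d_i = max(
            (lineage_distance(founder_seq, sequences[m]) for m in clone.members),
            default=0.0,
        )
        rows.append(
            {
                "clone_id": clone.clone_id,
                "size": clone.size,
                "size_category": clone.size_category,
                "d_peripheral": d_p,
                "d_intrathecal": d_i,
            }
        )
    table = pd.DataFrame(rows)
    d_p = table["d_peripheral"].to_numpy()
    d_i = table["d_intrathecal"].to_numpy()
    small = table["size"] < 4
    return CompartmentContrast(
        table=table,
        median_peripheral=float(np.median(d_p)),
        median_intrathecal=float(np.median(d_i)),
        range_peripheral=(float(d_p.min()), float(d_p.max())),
        range_intrathecal=(float(d_i.min()), float(d_i.max())),
        p_value=_paired_wilcoxon(d_p, d_i),
        n_clones=len(clones),
        p_value_small=_paired_wilcoxon(d_p[small], d_i[small]),
        p_value_large=_paired_wilcoxon(d_p[~small], d_i[~small]),
    )
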