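"""Reactivity propagation, clone-size-stratified specificity enrichment,
exact contingency testing, antibody index, subclass-switch summaries, BCR
feature statistics, and closest-identity ("privacy") search.

The clone-size enrichment question: do larger clonal expansions carry
autoantigen-reactive receptors more often? Because testing every receptor
as a monoclonal antibody is infeasible, reactivity observed for one clone
member is propagated to all members (clone members empirically share
reactivities), and the rates per size category are compared. The
"adjusted" rate extrapolates the observed singleton reactivity rate to
the untested singletons:

    adjusted = (n_reactive + rate_singleton * n_untested_singletons)
               / (n_tested + n_untested_singletons)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom, spearmanr

from .clones import Clone
from .germline import IGG_SUBCLASS_ORDER, ReceptorCell, ValidationError

REACTIVE_LABELS = frozenset({"LGI1", "CASPR2"})

#: relative tolerance of the point-probability rule for the two-sided
#: Fisher p-value (tables whose probability exceeds the observed one by
#: less than this are still counted)
_FISHER_RTOL = 1e-7


class ConflictError(ValueError):
    """Tested members of one clone disagree on reactivity."""


# ---------------------------------------------------------------------------
# reactivity propagation and enrichment


def propagate_reactivity(
    clone: Clone,
    labels: Mapping[str, str],
) -> tuple[dict[str, str], bool]:
    """Propagate the tested members' shared reactivity to untested members.

    Returns the per-member labels and a flag marking whether the clone had
    any tested member (clones without one are returned unchanged, flagged
    False). Conflicting tested labels raise :class:`ConflictError` — the
    underlying biology (members of a clone share specificity) makes a
    conflict a data problem, not a result.
    """
    tested = {m: labels[m] for m in clone.members if labels.get(m, "untested") != "untested"}
    if not tested:
        return {m: labels.get(m, "untested") for m in clone.members}, False
    distinct = set(tested.values())
    if len(distinct) > 1:
        raise ConflictError(
            f"clone {clone.clone_id}: conflicting tested labels {sorted(distinct)}")
    shared = distinct.pop()
    return {m: shared for m in clone.members}, True


@dataclass
class ContingencyResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    p_two_sided: float
    odds_ratio: float


def fisher_exact(table: Sequence[Sequence[int]]) -> ContingencyResult:
    """Two-sided Fisher exact test on a 2x2 table.

    The p-value sums hypergeometric probabilities of every table with the
    same margins whose point probability is <= that of the observed table
    (the common "minimum-likelihood" two-sided rule), with relative
    tolerance 1e-7 on the comparison. Odds ratio is (a*d)/(b*c), infinite
    when b*c = 0 and a*d > 0.
    """
    (a, b), (c, d) = table
    cells = [a, b, c, d]
    if any(x < 0 or x != int(x) for x in cells):
        raise ValidationError(f"table entries must be nonnegative integers: {cells}")
    a, b, c, d = (int(x) for x in cells)
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValidationError("all margins of the 2x2 table must be positive")
    n = r1 + r2
    # P(A = k) for tables with these margins: A ~ Hypergeom(n, r1, c1)
    k_min, k_max = max(0, c1 - r2), min(r1, c1)
    ks = np.arange(k_min, k_max + 1)
    pmf = hypergeom.pmf(ks, n, r1, c1)
    p_obs = float(hypergeom.pmf(a, n, r1, c1))
    included = pmf <= p_obs * (1.0 + _FISHER_RTOL)
    p = 1.0 if included.all() else min(float(pmf[included].sum()), 1.0)
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    return ContingencyResult(((a, b), (c, d)), p, odds)


@dataclass
class EnrichmentSummary:
    """Reactivity rates per clone-size category with adjustment."""

    per_category: dict[str, dict[str, float | int | None]]
    adjusted_by_donor: dict[str, float]
    adjusted_pooled: float | None
    overall: ContingencyResult | None  # singleton-vs-clonal 2x2 exact test


def stratify_by_clone_size(
    cells: Sequence[ReceptorCell],
    clones: Sequence[Clone],
    labels: Mapping[str, str],
    reactive_labels: frozenset[str] = REACTIVE_LABELS,
) -> EnrichmentSummary:
    """Reactivity rates in singleton / 2-3-member / >=4-member clones.

    ``labels`` are post-propagation per-cell reactivities; cells still
    ``untested`` are excluded from the rates. The overall association is
    tested by Fisher exact on the singleton-vs-clonal collapse of the
    category table. Adjusted rates extrapolate each donor's singleton rate
    to that donor's untested singletons.
    """
    cat_of: dict[str, str] = {}
    for clone in clones:
        for m in clone.members:
            cat_of[m] = clone.size_category
    donor_of = {c.cell_id: c.donor for c in cells}

    per_category: dict[str, dict[str, float | int | None]] = {}
    for cat in ("singleton", "small", "large"):
        members = [cid for cid, c in cat_of.items() if c == cat]
        tested = [m for m in members if labels.get(m, "untested") != "untested"]
        reactive = [m for m in tested if labels[m] in reactive_labels]
        rate = len(reactive) / len(tested) if tested else None
        per_category[cat] = {
            "n_cells": len(members),
            "n_tested": len(tested),
            "n_reactive": len(reactive),
            "rate": rate,
        }

    # adjusted rates: per donor, dilute by untested singletons at the
    # donor's own singleton rate
    adjusted_by_donor: dict[str, float] = {}
    for donor in sorted({c.donor for c in cells}):
        ids = [cid for cid in cat_of if donor_of.get(cid) == donor]
        tested = [m for m in ids if labels.get(m, "untested") != "untested"]
        reactive = [m for m in tested if labels[m] in reactive_labels]
        singles = [m for m in ids if cat_of[m] == "singleton"]
        tested_singles = [m for m in singles if labels.get(m, "untested") != "untested"]
        untested_singles = len(singles) - len(tested_singles)
        if not tested:
            continue
        s_rate = (
            sum(labels[m] in reactive_labels for m in tested_singles) / len(tested_singles)
            if tested_singles
            else 0.0
        )
        adjusted_by_donor[donor] = adjusted_specificity(
            len(reactive), len(tested), untested_singles, s_rate
        )

    singleton = per_category["singleton"]
    clonal_tested = per_category["small"]["n_tested"] + per_category["large"]["n_tested"]
    clonal_reactive = per_category["small"]["n_reactive"] + per_category["large"]["n_reactive"]
    overall = None
    tbl = (
        (int(singleton["n_reactive"]), int(singleton["n_tested"]) - int(singleton["n_reactive"])),
        (int(clonal_reactive), int(clonal_tested) - int(clonal_reactive)),
    )
    margins_ok = all(sum(row) > 0 for row in tbl) and all(
        tbl[0][j] + tbl[1][j] > 0 for j in (0, 1)
    )
    if margins_ok:
        overall = fisher_exact(tbl)

    n_tested_all = sum(int(v["n_tested"]) for v in per_category.values())
    n_reactive_all = sum(int(v["n_reactive"]) for v in per_category.values())
    n_untested_singles = int(singleton["n_cells"]) - int(singleton["n_tested"])
    adjusted_pooled = None
    if n_tested_all and singleton["rate"] is not None:
        adjusted_pooled = adjusted_specificity(
            n_reactive_all, n_tested_all, n_untested_singles, float(singleton["rate"])
        )
    return EnrichmentSummary(per_category, adjusted_by_donor, adjusted_pooled, overall)


def adjusted_specificity(
    n_reactive_total: int,
    n_tested_total: int,
    n_untested_singletons: int,
    singleton_rate: float,
) -> float:
    """(n_reactive + rate*n_untested) / (n_tested + n_untested)."""
    if min(n_reactive_total, n_tested_total, n_untested_singletons) < 0:
        raise ValidationError("counts must be nonnegative")
    if not 0.0 <= singleton_rate <= 1.0:
        raise ValidationError(f"singleton_rate {singleton_rate} outside [0, 1]")
    denom = n_tested_total + n_untested_singletons
    if denom == 0:
        raise ValidationError("adjusted specificity undefined: zero denominator")
    return (n_reactive_total + singleton_rate * n_untested_singletons) / denom


# ---------------------------------------------------------------------------
# antibody index and subclass statistics


@dataclass
class AntibodyIndexResult:
    value: float
    intrathecal: bool


def antibody_index(
    auto_csf: float,
    auto_serum: float,
    igg_csf: float,
    igg_serum: float,
    cutoff: float = 4.0,
) -> AntibodyIndexResult:
    """AI = (autoantibody CSF/serum) / (total IgG CSF/serum); the
    intrathecal-synthesis flag is strict (AI > cutoff)."""
    for name, v in [("auto_csf", auto_csf), ("auto_serum", auto_serum),
                    ("igg_csf", igg_csf), ("igg_serum", igg_serum)]:
        if not v > 0:
            raise ValidationError(f"{name} must be strictly positive, got {v}")
    ai = (auto_csf / auto_serum) / (igg_csf / igg_serum)
    return AntibodyIndexResult(ai, ai > cutoff)


def igg4_ratio(subclass_levels: Mapping[str, float]) -> float:
    """IGHG4 / (IGHG1 + IGHG2 + IGHG3 + IGHG4)."""
    levels = {g: float(subclass_levels.get(g, 0.0)) for g in IGG_SUBCLASS_ORDER}
    if any(v < 0 for v in levels.values()):
        raise ValidationError("subclass levels must be nonnegative")
    total = sum(levels.values())
    if total <= 0:
        raise ValidationError("igg4_ratio undefined: all subclass levels zero")
    return levels["IGHG4"] / total


@dataclass
class SubclassSwitchSummary:
    n_one_subclass: int
    n_two_subclasses: int
    n_more_than_two: int
    violations: list[tuple[str, str, str]]  # (clone_id, founder subclass, member subclass)


def subclass_switch_summary(
    clones: Sequence[Clone],
    c_calls: Mapping[str, str],
) -> SubclassSwitchSummary:
    """Count clones expressing 1, 2, or >2 IgG subclasses, and flag
    upstream switches (member subclass upstream of the founder's on the
    genomic order IGHG3 < IGHG1 < IGHG2 < IGHG4) — biologically impossible
    events under class-switch recombination."""
    order = {g: i for i, g in enumerate(IGG_SUBCLASS_ORDER)}
    counts = [0, 0, 0]
    violations: list[tuple[str, str, str]] = []
    for clone in clones:
        subs = []
        for m in clone.members:
            call = c_calls.get(m)
            if call is None or call not in order:
                raise ValidationError(f"clone {clone.clone_id}: unknown c_call {call!r} "
                                      f"for member {m}")
            subs.append(call)
        distinct = len(set(subs))
        counts[min(distinct, 3) - 1] += 1
        if clone.founder is not None:
            f_sub = c_calls[clone.founder]
            for m, s in zip(clone.members, subs):
                if order[s] < order[f_sub]:
                    violations.append((clone.clone_id, f_sub, s))
    return SubclassSwitchSummary(counts[0], counts[1], counts[2], violations)


# ---------------------------------------------------------------------------
# BCR features and correlations


_POSITIVE_AA = frozenset("KR")
_NEGATIVE_AA = frozenset("DE")
_VALID_AA = frozenset("ACDEFGHIKLMNPQRSTVWY*X")


def cdr3_charge(junction_aa: str, histidine_weight: float = 0.0) -> float:
    """Net charge: +1 per K/R, -1 per D/E; histidine counts
    ``histidine_weight`` (0 by default, 0.1 optionally)."""
    bad = set(junction_aa) - _VALID_AA
    if bad:
        raise ValidationError(f"junction_aa has invalid characters: {sorted(bad)}")
    charge = 0.0
    for aa in junction_aa:
        if aa in _POSITIVE_AA:
            charge += 1
        elif aa in _NEGATIVE_AA:
            charge -= 1
        elif aa == "H":
            charge += histidine_weight
    return charge


def gene_family(call: str | None) -> str | None:
    """IGHV3-23*01 -> IGHV3 (family = prefix before the hyphen)."""
    if call is None:
        return None
    gene = call.split("*")[0]
    return gene.split("-")[0]


def bcr_features(
    cells: Sequence[ReceptorCell],
    mutation_counts: Mapping[str, int] | None = None,
    histidine_weight: float = 0.0,
):
    """Per-cell feature table: subclass, CDR3 aa length/charge, light-chain
    locus, VH/VL family, total mutations."""
    import pandas as pd

    rows = []
    for cell in cells:
        jaa = cell.heavy.junction_aa
        if jaa is None:
            raise ValidationError(f"{cell.cell_id}: junction_aa required for features")
        rows.append(
            {
                "cell_id": cell.cell_id,
                "donor": cell.donor,
                "subclass": cell.heavy.c_call,
                "cdr3_length_aa": len(jaa),
                "cdr3_charge": cdr3_charge(jaa, histidine_weight),
                "light_locus": cell.light.locus if cell.light else None,
                "vh_family": gene_family(cell.heavy.v_call),
                "vl_family": gene_family(cell.light.v_call) if cell.light else None,
                "total_mutations": (mutation_counts or {}).get(cell.cell_id),
                "reactivity": cell.reactivity,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CorrelationResult:
    coefficient: float
    p_value: float
    n: int
    applicable: bool = True


def correlate_mutations_affinity(
    cells: Sequence[ReceptorCell],
    mutation_counts: Mapping[str, int],
    clones: Sequence[Clone] | None = None,
) -> CorrelationResult:
    """Spearman rank correlation between total (heavy+light) mutations and
    log10 endpoint concentration, one cell (the founder) per clone.

    Lower endpoint concentrations mean stronger binding, so affinity
    maturation appears as a negative coefficient.
    """
    keep: set[str] | None = None
    if clones is not None:
        keep = {c.founder for c in clones if c.founder is not None}
    xs, ys = [], []
    for cell in cells:
        if cell.endpoint_conc is None or cell.cell_id not in mutation_counts:
            continue
        if keep is not None and cell.cell_id not in keep:
            continue
        xs.append(mutation_counts[cell.cell_id])
        ys.append(np.log10(cell.endpoint_conc))
    if len(xs) < 3:
        raise ValidationError("need >= 3 cells with endpoint concentrations")
    if len(set(xs)) == 1 or len(set(ys)) == 1:
        return CorrelationResult(float("nan"), float("nan"), len(xs), applicable=False)
    rho, p = spearmanr(xs, ys)
    return CorrelationResult(float(rho), float(p), len(xs))


# ---------------------------------------------------------------------------
# privacy / closest-identity search


@dataclass
class IdentityResult:
    max_identity_pct: float | None
    private: bool | None  # closest identity < 80% (strict)
    n_compared: int


def closest_identity(
    query_cdrs: str,
    reference: Iterable[str],
    private_threshold: float = 80.0,
) -> IdentityResult:
    """Maximum percent identity of a concatenated heavy-CDR string against
    a reference set; length-mismatched references are skipped. The
    ``private`` flag marks identities strictly below the threshold."""
    q = np.frombuffer(query_cdrs.encode("ascii"), dtype=np.uint8)
    best = None
    n = 0
    for ref in reference:
        if len(ref) != q.size:
            continue
        r = np.frombuffer(ref.encode("ascii"), dtype=np.uint8)
        ident = 100.0 * float(np.count_nonzero(q == r)) / q.size
        n += 1
        if best is None or ident > best:
            best = ident
    if n == 0:
        return IdentityResult(None, None, 0)
    return IdentityResult(best, best < private_threshold, n)


def synthetic_cdr_reference(
    n: int,
    length: int,
    seed: int = 0,
    alphabet: str = "ACDEFGHIKLMNPQRSTVWY",
) -> list[str]:
    """Random amino-acid reference set standing in for a large public
    repertoire database in tests (synthetic; not real antibody data)."""
    rng = np.random.default_rng(seed)
    letters = list(alphabet)
    return ["".join(rng.choice(letters, length)) for _ in range(n)]
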