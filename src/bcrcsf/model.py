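"""Top-level modelling interface.

:class:`RepertoireAnalysis` is built from a set of receptor cells plus a
germline segment library; :meth:`RepertoireAnalysis.fit` runs the full
inference chain — germline assignment, clonal clustering, founder
identification, UCA reconstruction, the peripheral-vs-intrathecal
compartment contrast, reactivity propagation and clone-size specificity
enrichment, subclass-switch accounting, BCR features and the
mutation-affinity correlation — and returns a :class:`RepertoireResults`
carrying the estimates, their tests and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._utils import encode
from .cellstate import ClassificationResult
from .clones import (
    Clone,
    GermlineAssignment,
    assign_germline,
    clonality_fraction,
    cluster_clones,
    identify_founder,
)
from .germline import (
    ReceptorCell,
    SegmentLibrary,
    ValidationError,
    gate_phenotype,
    read_airr,
    read_segment_fasta,
    validate_cells,
)
from .lineage import CompartmentContrast, compartment_contrast, reconstruct_uca
from .specificity import (
    CorrelationResult,
    EnrichmentSummary,
    SubclassSwitchSummary,
    bcr_features,
    correlate_mutations_affinity,
    propagate_reactivity,
    stratify_by_clone_size,
    subclass_switch_summary,
)


@dataclass
class AnalysisConfig:
    """Tunable knobs of the pipeline (all defaults follow the conventions
    documented in the methods note)."""

    clone_threshold: int = 6           # strict junction Hamming bound
    junction_on: str = "nt"            # "nt" | "aa"
    uca_mode: str = "revert_nonsilent"  # | "revert_all"
    mutation_scope: str = "heavy_light"  # | "heavy"
    paired_only: bool = False          # drop cells lacking a light chain
    histidine_weight: float = 0.0      # CDR3 charge contribution of H


class RepertoireAnalysis:
    """Model object: a repertoire dataset plus a germline library.

    Parameters
    ----------
    cells
        Receptor cells (heavy chain mandatory, light optional).
    library
        Germline V/D/J segment library used for assignment and reversion.
    config
        Pipeline options; defaults reproduce the standard analysis.
    """

    def __init__(
        self,
        cells: Sequence[ReceptorCell],
        library: SegmentLibrary,
        config: AnalysisConfig | None = None,
    ) -> None:
        if not cells:
            raise ValidationError("RepertoireAnalysis requires at least one cell")
        validate_cells(cells)
        self.config = config or AnalysisConfig()
        if self.config.paired_only:
            cells = [c for c in cells if c.light is not None]
            if not cells:
                raise ValidationError("paired_only filter removed every cell")
        self.cells = list(cells)
        self.library = library

    @classmethod
    def from_airr(
        cls,
        airr_path: str | Path,
        library: SegmentLibrary | str | Path,
        metadata: str | Path | None = None,
        config: AnalysisConfig | None = None,
    ) -> "RepertoireAnalysis":
        if not isinstance(library, SegmentLibrary):
            library = read_segment_fasta(library)
        cells, _excluded = read_airr(airr_path, metadata=metadata)
        return cls(cells, library, config=config)

    # -- fitting -----------------------------------------------------------

    def _mutation_count(self, cell: ReceptorCell,
                        assignments: Mapping[tuple[str, str], GermlineAssignment]) -> int:
        total = 0
        chains = [cell.heavy]
        if self.config.mutation_scope == "heavy_light" and cell.light is not None:
            chains.append(cell.light)
        for ch in chains:
            asg = assignments.get((cell.cell_id, ch.locus))
            if asg is None or asg.failed or asg.positions is None:
                continue
            obs = encode(ch.sequence)[asg.positions]
            diff = obs != asg.germline_bases
            if ch.n_region_mask:
                in_mask = np.isin(asg.positions, list(ch.n_region_mask))
                diff &= ~in_mask
            total += int(np.count_nonzero(diff))
        return total

    def fit(self) -> "RepertoireResults":
        cfg = self.config
        assignments: dict[tuple[str, str], GermlineAssignment] = {}
        heavy_assignments: dict[str, GermlineAssignment] = {}
        kept: list[ReceptorCell] = []
        failed: list[str] = []
        for cell in self.cells:
            asg_h = assign_germline(cell.heavy, self.library)
            if asg_h.failed:
                failed.append(cell.cell_id)
                continue
            assignments[(cell.cell_id, cell.heavy.locus)] = asg_h
            heavy_assignments[cell.cell_id] = asg_h
            if cell.light is not None:
                asg_l = assign_germline(cell.light, self.library)
                if not asg_l.failed:
                    assignments[(cell.cell_id, cell.light.locus)] = asg_l
            kept.append(cell)
        if not kept:
            raise ValidationError("germline assignment failed for every cell")

        clones = cluster_clones(
            kept, heavy_assignments,
            threshold=cfg.clone_threshold, junction_on=cfg.junction_on,
        )

        mutation_counts = {c.cell_id: self._mutation_count(c, assignments) for c in kept}
        for clone in clones:
            clone.founder = identify_founder(clone, mutation_counts)

        # founder UCAs (heavy chain) for the compartment contrast
        ucas: dict[str, str] = {}
        sequences = {c.cell_id: c.heavy.sequence for c in kept}
        by_id = {c.cell_id: c for c in kept}
        for clone in clones:
            founder = by_id[clone.founder]
            res = reconstruct_uca(
                founder.heavy, heavy_assignments[founder.cell_id], mode=cfg.uca_mode
            )
            if res is not None:
                ucas[founder.cell_id] = res.sequence
        contrast = compartment_contrast(
            [c for c in clones if c.founder in ucas], ucas, sequences
        )

        observed_labels = {c.cell_id: c.reactivity for c in kept}
        resolved: dict[str, str] = dict(observed_labels)
        for clone in clones:
            labels, _had_tested = propagate_reactivity(clone, observed_labels)
            resolved.update(labels)

        enrichment = stratify_by_clone_size(kept, clones, resolved)

        c_calls = {c.cell_id: c.heavy.c_call for c in kept}
        igg_clones = [
            cl for cl in clones
            if all((c_calls.get(m) or "").startswith("IGHG") for m in cl.members)
        ]
        switches = subclass_switch_summary(igg_clones, c_calls)

        features = bcr_features(kept, mutation_counts,
                                histidine_weight=cfg.histidine_weight)
        try:
            correlation = correlate_mutations_affinity(kept, mutation_counts, clones)
        except ValidationError:
            correlation = None

        phenotypes = {}
        for cell in kept:
            if len(cell.markers) >= 9:
                phenotypes[cell.cell_id] = gate_phenotype(cell.markers)

        return RepertoireResults(
            model=self,
            cells=kept,
            excluded_cells=failed,
            assignments=assignments,
            clones=clones,
            mutation_counts=mutation_counts,
            ucas=ucas,
            contrast=contrast,
            resolved_reactivity=resolved,
            enrichment=enrichment,
            subclass_switches=switches,
            features=features,
            mutation_affinity=correlation,
            phenotypes=phenotypes,
        )


@dataclass
class RepertoireResults:
    """Fitted repertoire analysis: estimates, tests and summaries."""

    model: RepertoireAnalysis
    cells: list[ReceptorCell]
    excluded_cells: list[str]
    assignments: dict[tuple[str, str], GermlineAssignment]
    clones: list[Clone]
    mutation_counts: dict[str, int]
    ucas: dict[str, str]
    contrast: CompartmentContrast
    resolved_reactivity: dict[str, str]
    enrichment: EnrichmentSummary
    subclass_switches: SubclassSwitchSummary
    features: pd.DataFrame
    mutation_affinity: CorrelationResult | None
    phenotypes: dict[str, str]
    cell_state_classification: ClassificationResult | None = None

    # -- derived tables ----------------------------------------------------

    @property
    def clone_table(self) -> pd.DataFrame:
        rows = []
        for clone in self.clones:
            for m in clone.members:
                rows.append(
                    {
                        "cell_id": m,
                        "clone_id": clone.clone_id,
                        "v_gene": clone.v_gene,
                        "j_gene": clone.j_gene,
                        "junction_length": clone.junction_length,
                        "clone_size": clone.size,
                        "size_category": clone.size_category,
                        "founder_flag": m == clone.founder,
                        "total_mutations": self.mutation_counts.get(m),
                        "reactivity": self.resolved_reactivity.get(m, "untested"),
                    }
                )
        return pd.DataFrame(rows).sort_values("cell_id").reset_index(drop=True)

    @property
    def clonality(self) -> float:
        return clonality_fraction(self.cells, self.clones)

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        e = self.enrichment
        c = self.contrast
        lines = [
            "              Repertoire Analysis Results",
            "=" * 58,
            f"Cells analysed:            {len(self.cells)}"
            + (f"  (excluded: {len(self.excluded_cells)})" if self.excluded_cells else ""),
            f"Clones:                    {len(self.clones)}"
            f"  (clonality fraction {self.clonality:.3f})",
            "",
            "Specificity by clone size (post-propagation)",
            "-" * 58,
        ]
        for cat, label in [("singleton", "singletons"), ("small", "2-3 members"),
                           ("large", ">=4 members")]:
            row = e.per_category[cat]
            rate = "   --" if row["rate"] is None else f"{100 * row['rate']:5.1f}%"
            lines.append(
                f"  {label:<12} reactive {row['n_reactive']:>4}/{row['n_tested']:<4} {rate}"
            )
        if e.adjusted_pooled is not None:
            lines.append(f"  adjusted (pooled):      {100 * e.adjusted_pooled:5.1f}%")
        if e.overall is not None:
            lines.append(f"  singleton-vs-clonal Fisher p = {e.overall.p_two_sided:.3g}")
        lines += [
            "",
            "Compartment contrast (normalized heavy-chain distance)",
            "-" * 58,
            f"  median UCA->founder (peripheral):    {c.median_peripheral:.4f}",
            f"  median founder->furthest (CNS):      {c.median_intrathecal:.4f}",
            f"  paired Wilcoxon p:                   "
            + ("n/a" if np.isnan(c.p_value) else f"{c.p_value:.3g}"),
            "",
            "Subclass switching",
            "-" * 58,
            f"  clones with one subclass:  {self.subclass_switches.n_one_subclass}",
            f"  clones with two:           {self.subclass_switches.n_two_subclasses}",
            f"  clones with more than two: {self.subclass_switches.n_more_than_two}",
            f"  order violations:          {len(self.subclass_switches.violations)}",
        ]
        if self.mutation_affinity is not None and self.mutation_affinity.applicable:
            lines += [
                "",
                "Mutations vs endpoint concentration (founders)",
                "-" * 58,
                f"  Spearman rho = {self.mutation_affinity.coefficient:.3f}"
                f"  (p = {self.mutation_affinity.p_value:.3g},"
                f" n = {self.mutation_affinity.n})",
            ]
        lines.append("=" * 58)
        return "\n".join(lines)

    # -- plotting ----------------------------------------------------------

    def plot_enrichment(self, ax=None):
        """Bar plot of reactive rates per clone-size category."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        cats = ["singleton", "small", "large"]
        rates = [self.enrichment.per_category[c]["rate"] or 0.0 for c in cats]
        ax.bar(["1", "2-3", ">=4"], [100 * r for r in rates], color="#b8860b")
        ax.set_ylabel("% LGI1/CASPR2 reactive")
        ax.set_xlabel("clone size")
        ax.set_ylim(0, 105)
        return ax

    def plot_contrast(self, ax=None):
        """Paired peripheral vs intrathecal distances per clone."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.contrast.table
        for _, row in t.iterrows():
            ax.plot([0, 1], [row["d_peripheral"], row["d_intrathecal"]],
                    "-o", color="gray", alpha=0.5, markersize=3)
        ax.set_xticks([0, 1])
        ax.set_xticklabels(["UCA → founder", "founder → furthest"])
        ax.set_ylabel("normalized Hamming distance")
        return ax
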