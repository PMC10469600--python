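"""Reporter gene panel and dual-reporter experimental design.

A panel is a list of genes (each tagged with the phenotype its promoter
reports on) with optional exclusion flags.  The dual-reporter design over
the active genes enumerates every unordered gene pair, and for each pair
the two strain configurations obtained by swapping which gene drives the
yellow (YPet) versus the cyan (mTurq) fluorophore.  With 14 active genes
this yields 91 pairs and 182 strain configurations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

FLUOROPHORES = ("YPet", "mTurq")

#: Common alternate spellings seen in strain tables mapped to the gene
#: names used throughout the package.
DEFAULT_ALIASES: Mapping[str, str] = {
    "aprF": "aprE",
    "comG": "comGA",
    "comQ": "comQX",
    "skf": "skfA",
    "skfAA": "srfAA",
}

#: The 15-gene reporter panel (gene, associated phenotype).  *sunA*
#: (sublancin) is conventionally excluded because its reporter strain shows
#: an altered colony morphology, leaving 14 genes in the active panel.
DEFAULT_PANEL: Sequence[tuple[str, str]] = (
    ("aprE", "Protease"),
    ("bacA", "Bacilysin"),
    ("comGA", "Competence"),
    ("comQX", "Pheromone"),
    ("dhbA", "Bacillibactin"),
    ("hag", "Motility"),
    ("pksC", "Bacillaene"),
    ("ppsA", "Plipastatin"),
    ("sboA", "Subtilosin"),
    ("sdpA", "Cannibal (SDP)"),
    ("skfA", "Cannibal (SKF)"),
    ("srfAA", "Surfactin"),
    ("sspB", "Sporulation"),
    ("sunA", "Sublancin"),
    ("tapA", "Biofilm"),
)

DEFAULT_EXCLUSIONS: Sequence[str] = ("sunA",)


class PanelError(ValueError):
    """Invalid panel table or exclusion list."""


class DesignError(ValueError):
    """Design cannot be enumerated (fewer than two active genes)."""


@dataclass(frozen=True)
class PanelEntry:
    gene: str
    phenotype: str
    excluded: bool = False
    exclusion_reason: str = ""


@dataclass(frozen=True)
class GenePanel:
    """Reporter panel with exclusion flags.

    ``active_genes`` preserves the input row order; design enumeration
    sorts lexicographically so it does not depend on table order.
    """

    entries: tuple[PanelEntry, ...]

    @property
    def active_genes(self) -> tuple[str, ...]:
        return tuple(e.gene for e in self.entries if not e.excluded)

    @property
    def n_active(self) -> int:
        return len(self.active_genes)

    def phenotype(self, gene: str) -> str:
        for e in self.entries:
            if e.gene == gene:
                return e.phenotype
        raise KeyError(gene)


@dataclass(frozen=True)
class DualReporterDesign:
    """All unordered pairs of active genes, each in both color orientations.

    ``configurations`` rows are ``(pair_id, geneA, geneB, orientation,
    ypet_gene, mturq_gene)`` with geneA < geneB lexicographically;
    orientation 1 assigns geneA to YPet, orientation 2 swaps.
    """

    pairs: tuple[tuple[str, str], ...]
    configurations: tuple[tuple[str, str, str, int, str, str], ...] = field(repr=False)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_configurations(self) -> int:
        return len(self.configurations)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.configurations,
            columns=["pair_id", "geneA", "geneB", "orientation", "ypet_gene", "mturq_gene"],
        )


def default_panel(exclusions: Iterable[str] = DEFAULT_EXCLUSIONS) -> GenePanel:
    """The built-in 15-gene panel with the given exclusions applied."""
    table = pd.DataFrame(DEFAULT_PANEL, columns=["gene", "phenotype"])
    return load_panel(table, exclusions=exclusions)


def load_panel(
    table: pd.DataFrame | str | Path,
    exclusions: Iterable[str] = (),
    aliases: Mapping[str, str] | None = None,
    exclusion_reason: str = "excluded by configuration",
) -> GenePanel:
    """Load a gene panel from a gene/phenotype table and apply exclusions.

    Parameters
    ----------
    table:
        DataFrame with columns ``gene`` and ``phenotype``, or a path to a
        CSV/TSV file with those columns.
    exclusions:
        Gene names to flag as excluded.  Naming a gene absent from the
        table raises :class:`PanelError`.
    aliases:
        Optional mapping applied to gene names before validation; defaults
        to :data:`DEFAULT_ALIASES`.  Pass ``{}`` to disable.
    """
    if not isinstance(table, pd.DataFrame):
        path = Path(table)
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
        table = pd.read_csv(path, sep=sep)
    missing_cols = {"gene", "phenotype"} - set(table.columns)
    if missing_cols:
        raise PanelError(f"panel table missing columns: {sorted(missing_cols)}")

    alias_map = DEFAULT_ALIASES if aliases is None else aliases
    genes = [alias_map.get(str(g).strip(), str(g).strip()) for g in table["gene"]]
    if any(not g for g in genes):
        raise PanelError("empty gene name in panel table")
    dupes = {g for g in genes if genes.count(g) > 1}
    if dupes:
        raise PanelError(f"duplicate gene names in panel table: {sorted(dupes)}")

    exclusions = [alias_map.get(g, g) for g in exclusions]
    unknown = sorted(set(exclusions) - set(genes))
    if unknown:
        raise PanelError(f"exclusions name genes absent from the panel: {unknown}")

    entries = tuple(
        PanelEntry(
            gene=g,
            phenotype=str(p),
            excluded=g in exclusions,
            exclusion_reason=exclusion_reason if g in exclusions else "",
        )
        for g, p in zip(genes, table["phenotype"])
    )
    return GenePanel(entries=entries)


def enumerate_design(panel: GenePanel) -> DualReporterDesign:
    """Enumerate all dual-reporter pairs and color-orientation configurations.

    For ``n`` active genes the design holds ``n(n-1)/2`` unordered pairs and
    twice as many strain configurations.  Ordering is deterministic:
    pairs are lexicographic by (geneA, geneB); orientation 1 puts the
    lexicographically smaller gene on YPet.
    """
    genes = sorted(panel.active_genes)
    if len(genes) < 2:
        raise DesignError(f"need at least 2 active genes, got {len(genes)}")
    pairs = tuple(itertools.combinations(genes, 2))
    configurations = []
    for a, b in pairs:
        pair_id = f"{a}-{b}"
        for orientation, (ypet, mturq) in enumerate(((a, b), (b, a)), start=1):
            configurations.append((pair_id, a, b, orientation, ypet, mturq))
    return DualReporterDesign(pairs=pairs, configurations=tuple(configurations))
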