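"""Dual-reporter flow-cytometry gating, quadrant analysis and co-expression.

Each sample is a table of per-event (YPet, mTurq) fluorescence intensities
from a strain carrying two promoter-fluorophore fusions.  Detection gates
come from a non-fluorescent wild-type control: the per-channel threshold
is an upper empirical quantile (default 99.9%) of the control's
intensities, so events above the gate are called expressing.  Events are
classified into four quadrants — neither, mTurq-only, YPet-only, both —
by strict comparison against both thresholds (an event sitting exactly on
a threshold is negative; empirical quantiles land on observed values, so
the tie rule matters).  No spectral compensation or transform is applied:
thresholding is scale-equivariant, and the YPet/mTurquoise2 pair has
minimal spectral overlap.

Pairwise co-expression is the percent of double-positive events; because
every gene pair is measured in both color orientations, the matrix entry
for a pair is the maximum over its orientations, recording which
orientation supplied it.  Per-gene percent-expressing uses the YPet
channel only (its sensitivity exceeds mTurq's against cellular background)
averaged over every strain in which the gene carries the YPet reporter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Quadrant order used everywhere: indices into counts/fractions.
QUADRANTS = ("neither", "mturq_only", "ypet_only", "both")

#: Minimum events per strain for the QC flag.
DEFAULT_MIN_EVENTS = 24_000

DEFAULT_GATE_QUANTILE = 0.999


class FlowError(ValueError):
    """Invalid flow sample, gate or summary input."""


@dataclass(frozen=True)
class FlowSample:
    """Per-event two-channel intensities plus strain metadata."""

    ypet: np.ndarray
    mturq: np.ndarray
    gene_ypet: str | None = None
    gene_mturq: str | None = None
    orientation: int | None = None
    true_labels: np.ndarray | None = None
    is_control: bool = False
    sample_id: str | None = None

    def __post_init__(self) -> None:
        y = np.asarray(self.ypet, dtype=float)
        m = np.asarray(self.mturq, dtype=float)
        if y.ndim != 1 or y.shape != m.shape:
            raise FlowError("ypet and mturq must be 1D arrays of equal length")
        if y.size < 1:
            raise FlowError("sample must contain at least one event")
        if not (np.isfinite(y).all() and np.isfinite(m).all()):
            raise FlowError("intensities must be finite")
        object.__setattr__(self, "ypet", y)
        object.__setattr__(self, "mturq", m)

    @property
    def n(self) -> int:
        return int(self.ypet.size)

    @property
    def pair(self) -> tuple[str, str] | None:
        if self.gene_ypet is None or self.gene_mturq is None:
            return None
        return tuple(sorted((self.gene_ypet, self.gene_mturq)))


@dataclass(frozen=True)
class GateSet:
    """Per-channel detection thresholds derived from a control sample."""

    ypet_threshold: float
    mturq_threshold: float
    quantile: float
    control_id: str | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.ypet_threshold) and np.isfinite(self.mturq_threshold)):
            raise FlowError("thresholds must be finite")
        if not 0.0 < self.quantile < 1.0:
            raise FlowError(f"quantile must be in (0, 1), got {self.quantile}")


@dataclass(frozen=True)
class QuadrantSummary:
    """Four-population decomposition of one sample."""

    counts: tuple[int, int, int, int]   # order: QUADRANTS
    n: int
    qc_pass: bool
    gates: GateSet
    gene_ypet: str | None = None
    gene_mturq: str | None = None
    orientation: int | None = None
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if sum(self.counts) != self.n:
            raise FlowError("quadrant counts must sum to n")
        if any(c < 0 for c in self.counts):
            raise FlowError("quadrant counts must be non-negative")

    @property
    def fractions(self) -> tuple[float, float, float, float]:
        return tuple(c / self.n for c in self.counts)

    @property
    def percent_both(self) -> float:
        return 100.0 * self.counts[3] / self.n

    @property
    def pair(self) -> tuple[str, str] | None:
        if self.gene_ypet is None or self.gene_mturq is None:
            return None
        return tuple(sorted((self.gene_ypet, self.gene_mturq)))


@dataclass(frozen=True)
class CoexpressionMatrix:
    """Gene-by-gene percent co-expressing, aggregated over color orientations.

    ``matrix`` is symmetric with NaN on the diagonal and for unmeasured
    pairs; ``provenance`` records, per measured pair, which orientation
    supplied the maximum and both orientation values.
    """

    matrix: pd.DataFrame
    provenance: pd.DataFrame
    missing_pairs: tuple[tuple[str, str], ...] = ()

    @property
    def genes(self) -> list[str]:
        return list(self.matrix.index)


def fit_gates(
    control: FlowSample,
    quantile: float = DEFAULT_GATE_QUANTILE,
    min_control_events: int = 1000,
) -> GateSet:
    """Set per-channel detection thresholds from a non-fluorescent control.

    The threshold is the empirical ``quantile`` of the control intensities
    in each channel, taken as an order statistic: the smallest observed
    value v with at least ``quantile * n`` events <= v (inverted-CDF
    definition), so thresholds are always observed intensities.
    """
    if not 0.0 < quantile < 1.0:
        raise FlowError(f"quantile must be in (0, 1), got {quantile}")
    if control.n < min_control_events:
        raise FlowError(
            f"control has {control.n} events; need >= {min_control_events} for a stable gate"
        )
    ypet_thr = float(np.quantile(control.ypet, quantile, method="inverted_cdf"))
    mturq_thr = float(np.quantile(control.mturq, quantile, method="inverted_cdf"))
    return GateSet(ypet_threshold=ypet_thr, mturq_threshold=mturq_thr,
                   quantile=quantile, control_id=control.sample_id)


def classify_quadrants(
    sample: FlowSample,
    gates: GateSet,
    min_events: int = DEFAULT_MIN_EVENTS,
) -> QuadrantSummary:
    """Assign every event to a quadrant by strict comparison against both gates.

    An event is positive in a channel only when its intensity is strictly
    above that channel's threshold.  Samples under ``min_events`` still
    produce a summary but carry ``qc_pass=False``.
    """
    ypet_pos = sample.ypet > gates.ypet_threshold
    mturq_pos = sample.mturq > gates.mturq_threshold
    both = int(np.sum(ypet_pos & mturq_pos))
    ypet_only = int(np.sum(ypet_pos & ~mturq_pos))
    mturq_only = int(np.sum(~ypet_pos & mturq_pos))
    neither = sample.n - both - ypet_only - mturq_only
    return QuadrantSummary(
        counts=(neither, mturq_only, ypet_only, both),
        n=sample.n,
        qc_pass=sample.n >= min_events,
        gates=gates,
        gene_ypet=sample.gene_ypet,
        gene_mturq=sample.gene_mturq,
        orientation=sample.orientation,
        sample_id=sample.sample_id,
    )


def percent_expressing(summary: QuadrantSummary, channel: str = "YPet") -> float:
    """Percent of events expressing the YPet reporter (YPet-only + both).

    Only the YPet channel is supported: per-gene expression totals use the
    YPet signal exclusively because its sensitivity is superior to mTurq
    against cellular background fluorescence.
    """
    if channel != "YPet":
        raise FlowError("percent_expressing supports only the YPet channel by design")
    return 100.0 * (summary.counts[2] + summary.counts[3]) / summary.n


def percent_expressing_by_gene(
    summaries: Iterable[QuadrantSummary],
) -> pd.DataFrame:
    """Aggregate per-gene percent expressing over all YPet-carrying strains.

    For each gene, every summary in which that gene drives the YPet
    reporter contributes its percent-expressing value; the mean is
    reported with the min/max range and the number of strains.
    """
    rows: dict[str, list[float]] = {}
    for s in summaries:
        if s.gene_ypet is None:
            continue
        rows.setdefault(s.gene_ypet, []).append(percent_expressing(s))
    if not rows:
        raise FlowError("no summaries carry YPet gene metadata")
    records = [
        {"gene": gene, "percent_expressing": float(np.mean(vals)),
         "min": float(np.min(vals)), "max": float(np.max(vals)), "n_strains": len(vals)}
        for gene, vals in sorted(rows.items())
    ]
    return pd.DataFrame(records)


def build_coexpression_matrix(
    summaries: Sequence[QuadrantSummary],
    genes: Sequence[str] | None = None,
) -> CoexpressionMatrix:
    """Aggregate per-strain double-positive percentages into a gene-pair matrix.

    Each summary contributes ``100 * both / n`` for its (geneA, geneB)
    pair; the matrix entry is the maximum over the pair's color
    orientations (the orientation with the better-detected overlap), and
    the provenance table records both orientations' values.  Pairs of the
    requested gene set with no summary are reported as missing (NaN), not
    zero.
    """
    tagged = [s for s in summaries if s.pair is not None]
    if not tagged:
        raise FlowError("no summaries carry gene-pair metadata")
    if genes is None:
        genes = sorted({g for s in tagged for g in s.pair})

    per_pair: dict[tuple[str, str], list[QuadrantSummary]] = {}
    for s in tagged:
        per_pair.setdefault(s.pair, []).append(s)

    matrix = pd.DataFrame(np.nan, index=list(genes), columns=list(genes))
    prov_rows = []
    missing = []
    for i, a in enumerate(genes):
        for b in genes[i + 1:]:
            pair = tuple(sorted((a, b)))
            group = per_pair.get(pair)
            if not group:
                missing.append(pair)
                continue
            values = {s.orientation: s.percent_both for s in group}
            best = max(group, key=lambda s: s.percent_both)
            entry = best.percent_both
            matrix.loc[a, b] = matrix.loc[b, a] = entry
            prov_rows.append({
                "geneA": pair[0], "geneB": pair[1],
                "percent_coexpressing": entry,
                "max_orientation": best.orientation,
                "orientation_1": values.get(1, np.nan),
                "orientation_2": values.get(2, np.nan),
                "n_orientations": len(group),
            })
    provenance = pd.DataFrame(
        prov_rows,
        columns=["geneA", "geneB", "percent_coexpressing", "max_orientation",
                 "orientation_1", "orientation_2", "n_orientations"],
    )
    return CoexpressionMatrix(matrix=matrix, provenance=provenance,
                              missing_pairs=tuple(missing))


@dataclass(frozen=True)
class RelationshipThresholds:
    """Cutoffs for naming a pair's expression relationship.

    ``r = p_both / (pA * pB)`` compares the observed double-positive
    fraction with the independence expectation; ``c = p_both / min(pA, pB)``
    is the coverage of the rarer population.  The category names are
    standard; the numeric cutoffs are this package's configurable defaults.
    """

    anticorrelated_r: float = 0.5
    distinct_c: float = 0.1
    overlapping_c: float = 0.8


def classify_relationship(
    p_a: float,
    p_b: float,
    p_both: float,
    n: int | None = None,
    thresholds: RelationshipThresholds = RelationshipThresholds(),
) -> str:
    """Label a gene pair's co-expression relationship.

    Returns one of ``distinct`` (the overlap covers under
    ``distinct_c`` of the rarer population, or one gene is never
    expressed), ``anticorrelated`` (overlap below ``anticorrelated_r``
    times the independence expectation), ``overlapping`` (coverage above
    ``overlapping_c``) or ``partial``.  Coverage is tested before the
    independence ratio so a vanishing overlap reads as distinct rather
    than anticorrelated.
    """
    for name, p in (("p_a", p_a), ("p_b", p_b), ("p_both", p_both)):
        if not 0.0 <= p <= 1.0:
            raise FlowError(f"{name} must be a fraction in [0, 1], got {p}")
    if p_a * p_b == 0.0:
        return "distinct"
    coverage = p_both / min(p_a, p_b)
    if coverage < thresholds.distinct_c:
        return "distinct"
    ratio = p_both / (p_a * p_b)
    if ratio < thresholds.anticorrelated_r:
        return "anticorrelated"
    if coverage > thresholds.overlapping_c:
        return "overlapping"
    return "partial"


def load_flow_csv(
    path: str | Path,
    gene_ypet: str | None = None,
    gene_mturq: str | None = None,
    orientation: int | None = None,
    is_control: bool = False,
    sample_id: str | None = None,
) -> FlowSample:
    """Read a CSV event table with columns ``ypet`` and ``mturq``.

    An optional ``true_label`` column (from the synthetic generator) is
    carried along as ground truth.
    """
    df = pd.read_csv(Path(path))
    missing = {"ypet", "mturq"} - set(df.columns)
    if missing:
        raise FlowError(f"flow CSV missing columns: {sorted(missing)}")
    labels = df["true_label"].to_numpy() if "true_label" in df.columns else None
    return FlowSample(
        ypet=df["ypet"].to_numpy(dtype=float),
        mturq=df["mturq"].to_numpy(dtype=float),
        gene_ypet=gene_ypet, gene_mturq=gene_mturq, orientation=orientation,
        true_labels=labels, is_control=is_control,
        sample_id=sample_id or Path(path).stem,
    )


def summary_frame(summaries: Iterable[QuadrantSummary]) -> pd.DataFrame:
    """Tabulate quadrant summaries (one row per sample) for CSV output."""
    rows = []
    for s in summaries:
        row = {
            "sample_id": s.sample_id, "gene_ypet": s.gene_ypet,
            "gene_mturq": s.gene_mturq, "orientation": s.orientation,
            "n": s.n, "qc_pass": s.qc_pass,
        }
        row.update({f"count_{q}": c for q, c in zip(QUADRANTS, s.counts)})
        row.update({f"frac_{q}": f for q, f in zip(QUADRANTS, s.fractions)})
        rows.append(row)
    return pd.DataFrame(rows)
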