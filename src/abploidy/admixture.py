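"""Expected-ploidy calculus for admixed individuals and validation helpers.

An individual whose ancestry splits across source lineages of known
ploidy has a null expectation under simple additive inheritance: the
weighted arithmetic mean of the lineage ploidies, with the F1 of two
parental lineages as the equal-weight special case.  An observed ploidy
exceeding that expectation indicates recent whole-genome doubling
(a neoploid); falling below it indicates genome reduction.

The module also houses the flow-cytometry side of validation — nearest
reference-class assignment of 2C genome sizes (picograms) to cytotypes —
a concordance summary between any two per-individual ploidy mappings,
and the polyploid inbreeding coefficient F = 1 - H*p/(p-1) for observed
heterozygosity H at ploidy p.

Reference tables transcribed from the study's flow-cytometry panel and
admixed-individual panel ship with the package and load by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "AdmixtureRecord",
    "FlowClassifierConfig",
    "expected_f1_ploidy",
    "expected_admixture_ploidy",
    "classify_neoploidy",
    "classify_flow_cytometry",
    "concordance",
    "inbreeding_coefficient",
    "load_admixture_table",
    "load_flow_table",
    "evaluate_admixture_table",
    "flow_concordance_report",
]

_PROPORTION_SUM_TOL = 0.02  # published tables round proportions to 2 dp


def _round1(x: float) -> float:
    """Round to one decimal, half away from zero (0.77*8+0.23*4=7.08 -> 7.1)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class AdmixtureRecord:
    """One admixed individual: ancestry proportions and lineage ploidies."""

    individual_id: str
    lineage_labels: tuple[str, ...]
    proportions: tuple[float, ...]
    lineage_ploidies: tuple[int, ...]
    predicted_ploidy: int | None = None
    flow_ploidy: int | None = None

    def __post_init__(self) -> None:
        if not (
            len(self.lineage_labels)
            == len(self.proportions)
            == len(self.lineage_ploidies)
        ):
            raise ValueError("lineage labels, proportions and ploidies must align")
        if any(not (0.0 < p <= 1.0) for p in self.proportions):
            raise ValueError("proportions must lie in (0, 1]")
        if abs(sum(self.proportions) - 1.0) > _PROPORTION_SUM_TOL:
            raise ValueError("proportions must sum to 1 (within rounding)")


def expected_f1_ploidy(p1: int, p2: int) -> float:
    """Expected ploidy of a first-generation cross: the parental midpoint."""
    if p1 < 2 or p2 < 2:
        raise ValueError("parental ploidies must be >= 2")
    return _round1((p1 + p2) / 2.0)


def expected_admixture_ploidy(record: AdmixtureRecord) -> float:
    """Weighted arithmetic mean of lineage ploidies, to one decimal.

    Proportions are used as given (not renormalised): published ancestry
    vectors may sum slightly below 1 after rounding, and the residual is
    unassigned ancestry contributing no ploidy expectation.
    """
    value = sum(p * q for p, q in zip(record.proportions, record.lineage_ploidies))
    return _round1(value)


def classify_neoploidy(
    expected: float, predicted: int, epsilon: float = 0.05
) -> str:
    """'increased' / 'decreased' / 'consistent' vs the admixture expectation.

    The band is a tiny numerical epsilon, not a +-0.5 class width: an
    individual predicted 8x against an expectation of 7.5 counts as
    increased.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if predicted > expected + epsilon:
        return "increased"
    if predicted < expected - epsilon:
        return "decreased"
    return "consistent"


@dataclass(frozen=True)
class FlowClassifierConfig:
    """Reference 2C genome sizes (pg) per cytotype.

    Defaults are the medians of the study panel's flow-cytometry groups
    for the observed cytotypes 4x / 6x / 8x.
    """

    class_means: Mapping[int, float] = field(
        default_factory=lambda: {4: 1.99, 6: 3.09, 8: 3.99}
    )

    def __post_init__(self) -> None:
        ploidies = sorted(self.class_means)
        means = [self.class_means[p] for p in ploidies]
        if any(b <= a for a, b in zip(means, means[1:])):
            raise ValueError("class means must increase strictly with ploidy")


def classify_flow_cytometry(
    size_pg: float, config: FlowClassifierConfig | None = None
) -> int:
    """Nearest-class cytotype for a 2C genome size; ties go to lower ploidy."""
    if size_pg <= 0:
        raise ValueError("genome size must be positive")
    config = config or FlowClassifierConfig()
    return min(
        sorted(config.class_means),
        key=lambda p: (abs(size_pg - config.class_means[p]), p),
    )


def concordance(
    predicted: Mapping[str, int], reference: Mapping[str, int]
) -> tuple[float, list[str]]:
    """Fraction of shared individuals with matching ploidy, plus mismatches.

    Returns ``(matches / shared, sorted mismatching ids)``; raises on an
    empty intersection.
    """
    shared = sorted(set(predicted) & set(reference))
    if not shared:
        raise ValueError("no shared individual ids between the two mappings")
    mismatches = [i for i in shared if predicted[i] != reference[i]]
    return (len(shared) - len(mismatches)) / len(shared), mismatches


def inbreeding_coefficient(hindhe: float, ploidy: int) -> float:
    """Polyploid inbreeding coefficient F = 1 - H*p/(p-1).

    ``hindhe`` is the observed heterozygosity-related statistic H; the
    result is <= 1, and negative values indicate excess heterozygosity.
    """
    if ploidy < 2:
        raise ValueError("ploidy must be >= 2")
    if not (0.0 <= hindhe <= 1.0):
        raise ValueError("hindhe must lie in [0, 1]")
    return 1.0 - hindhe * ploidy / (ploidy - 1)


# ---------------------------------------------------------------------------
# packaged reference tables


def _data_path(name: str) -> Path:
    return Path(str(resources.files("abploidy").joinpath("data", name)))


def load_admixture_table(path: str | Path | None = None) -> pd.DataFrame:
    """Admixed-individual panel: ancestry proportions, lineage ploidies,
    the published expected/predicted ploidies, and flow estimates."""
    return pd.read_csv(path or _data_path("admixture_panel.tsv"), sep="\t")


def load_flow_table(path: str | Path | None = None) -> pd.DataFrame:
    """Flow-cytometry panel: predicted ploidy, 2C size (pg) where measured,
    and the per-individual inbreeding coefficient."""
    return pd.read_csv(path or _data_path("flow_panel.tsv"), sep="\t")


def record_from_row(row: pd.Series) -> AdmixtureRecord:
    """Build an AdmixtureRecord from one admixture-table row."""
    return AdmixtureRecord(
        individual_id=str(row["individual_id"]),
        lineage_labels=tuple(str(row["lineages"]).split("/")),
        proportions=tuple(float(x) for x in str(row["proportions"]).split("/")),
        lineage_ploidies=tuple(
            int(x) for x in str(row["lineage_ploidies"]).split("/")
        ),
        predicted_ploidy=int(row["predicted_ploidy"]),
    )


def evaluate_admixture_table(
    table: pd.DataFrame | None = None, epsilon: float = 0.05
) -> pd.DataFrame:
    """Expected ploidies and neoploidy verdicts for an admixture panel.

    Adds ``expected_f1`` (midpoint of the extreme parental ploidies),
    ``expected_ploidy`` (weighted mean, one decimal) and ``verdict``
    columns to the panel.
    """
    table = table if table is not None else load_admixture_table()
    rows = []
    for _, row in table.iterrows():
        rec = record_from_row(row)
        f1 = expected_f1_ploidy(min(rec.lineage_ploidies), max(rec.lineage_ploidies))
        expected = expected_admixture_ploidy(rec)
        rows.append(
            {
                "individual_id": rec.individual_id,
                "expected_f1": f1,
                "expected_ploidy": expected,
                "predicted_ploidy": rec.predicted_ploidy,
                "verdict": classify_neoploidy(
                    expected, rec.predicted_ploidy, epsilon
                ),
            }
        )
    return pd.DataFrame(rows)


def flow_concordance_report(
    table: pd.DataFrame | None = None,
    config: FlowClassifierConfig | None = None,
) -> dict:
    """Concordance between read-based predictions and flow classifications.

    Individuals without a measured genome size are excluded; the report
    carries the concordance fraction and the discrepant ids (surfaced,
    not resolved).
    """
    table = table if table is not None else load_flow_table()
    measured = table.dropna(subset=["genome_size_pg", "predicted_ploidy"])
    predicted = {
        str(r.sample_id): int(r.predicted_ploidy) for r in measured.itertuples()
    }
    flow = {
        str(r.sample_id): classify_flow_cytometry(float(r.genome_size_pg), config)
        for r in measured.itertuples()
    }
    frac, mismatches = concordance(predicted, flow)
    return {
        "n_measured": len(predicted),
        "concordance": frac,
        "discrepant_ids": mismatches,
    }
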