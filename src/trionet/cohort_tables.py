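"""Validated-variant table parsing and cohort summary statistics.

The package ships the published list of 88 Sanger-validated de novo
mutations from three schizophrenia trio cohorts (75 Algerian, 45 French and
61 Japanese families) as a TSV fixture.  This module parses that schema,
triages variants by PolyPhen-2 score into probably damaging / possibly
damaging / benign, and reproduces the cohort summary tables: mutation counts
per cohort, chromosomes hit, per-chromosome multiplicity percentages (of 23
chromosomes: 22 autosomes + X) and per-patient percentages.

PolyPhen-2 triage thresholds default to ``score > 0.94`` for probably
damaging and ``score > 0.446`` for possibly damaging.  These are the tightest
cut points consistent with the published score/label pairs (0.929 is labelled
possibly, 0.947 probably; 0.414 benign, 0.478 possibly) — neither the
standard HumDiv nor HumVar cutoffs reproduce the published labels.  Both are
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, IO, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

import pandas as pd

COHORTS = ("Algerian", "French", "Japanese")
CHROMOSOMES = tuple(str(i) for i in range(1, 23)) + ("X",)
PP2_CLASSES = ("probably_damaging", "possibly_damaging", "benign")

#: published family counts per cohort
DEFAULT_FAMILY_COUNTS: Dict[str, int] = {"Algerian": 75, "French": 45, "Japanese": 61}

_REQUIRED_COLUMNS = (
    "Cohort", "Gene", "Chromosome", "Position",
    "Father", "Mother", "Patient", "PPH2 Score", "PPH2 Prediction",
)

_PREDICTION_MAP = {
    "probably damaging": "probably_damaging",
    "possibly damaging": "possibly_damaging",
    "benign": "benign",
}

__all__ = [
    "TrioVariantRecord",
    "CohortSummary",
    "parse_variant_table",
    "packaged_variant_table",
    "write_variant_table",
    "pp2_classify",
    "tally_mutations",
    "chromosome_distribution",
    "patient_distribution",
    "pp2_tally",
    "DEFAULT_FAMILY_COUNTS",
]


@dataclass(frozen=True)
class TrioVariantRecord:
    """One validated de novo variant row."""

    cohort: str
    gene: str
    chrom: str
    pos: int
    father: str
    mother: str
    patient: str
    pph2_score: float
    pph2_class: str
    patient_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValueError(f"unknown cohort {self.cohort!r}")
        if self.chrom not in CHROMOSOMES:
            raise ValueError(f"unknown chromosome {self.chrom!r}")
        if not 0.0 <= self.pph2_score <= 1.0:
            raise ValueError(f"PPH2 score {self.pph2_score} outside [0, 1]")
        if self.pph2_class not in PP2_CLASSES:
            raise ValueError(f"unknown PPH2 class {self.pph2_class!r}")


@dataclass
class CohortSummary:
    """Per-cohort mutation/chromosome tallies (the published Table-3 shape)."""

    n_families: Dict[str, int]
    n_mutations: Dict[str, int]
    n_chromosomes_with: Dict[str, int]
    chromosome_histogram: Dict[str, Dict[str, int]]  # cohort -> chrom -> count
    n_mutations_total: int = 0
    n_chromosomes_total: int = 0

    def to_frame(self) -> pd.DataFrame:
        cols = list(COHORTS) + ["Total"]
        data = {
            "Number Of Families": [self.n_families.get(c, 0) for c in COHORTS]
            + [sum(self.n_families.values())],
            "Number Of Mutations": [self.n_mutations[c] for c in COHORTS]
            + [self.n_mutations_total],
            "Number Of Chromosomes With Mutation(s)": [
                self.n_chromosomes_with[c] for c in COHORTS
            ]
            + [self.n_chromosomes_total],
        }
        return pd.DataFrame(data, index=cols).T


def normalize_chromosome(label: str) -> str:
    """Normalize a chromosome label: "chr10" and "10" are the same."""
    lab = str(label).strip()
    if lab.lower().startswith("chr"):
        lab = lab[3:]
    return lab.upper() if lab.lower() == "x" else lab


def _parse_position(value: str) -> int:
    """Positions appear either bare ("102489584") or as "chr5:102489584"."""
    text = str(value).strip()
    if ":" in text:
        text = text.rsplit(":", 1)[1]
    return int(text)


def parse_variant_table(
    source: Union[str, Path, IO[str]]
) -> List[TrioVariantRecord]:
    """Parse a validated-variant TSV into records, rejecting malformed rows.

    The expected header matches the published table: Cohort, Gene,
    Chromosome, Position, Father, Mother, Patient, PPH2 Score,
    PPH2 Prediction (an optional Patient ID column is carried through).
    Malformed rows are reported with their line numbers.
    """
    df = pd.read_csv(source, sep="\t", dtype=str, comment="#")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s): {missing}")
    records: List[TrioVariantRecord] = []
    errors: List[str] = []
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        try:
            pred = str(row["PPH2 Prediction"]).strip().lower()
            if pred not in _PREDICTION_MAP:
                raise ValueError(f"unknown PPH2 prediction {pred!r}")
            records.append(
                TrioVariantRecord(
                    cohort=str(row["Cohort"]).strip(),
                    gene=str(row["Gene"]).strip(),
                    chrom=normalize_chromosome(row["Chromosome"]),
                    pos=_parse_position(row["Position"]),
                    father=str(row["Father"]).strip(),
                    mother=str(row["Mother"]).strip(),
                    patient=str(row["Patient"]).strip(),
                    pph2_score=float(row["PPH2 Score"]),
                    pph2_class=_PREDICTION_MAP[pred],
                    patient_id=(
                        str(row["Patient ID"]).strip()
                        if "Patient ID" in df.columns
                        and pd.notna(row.get("Patient ID"))
                        else None
                    ),
                )
            )
        except (ValueError, KeyError) as exc:
            errors.append(f"line {line_no}: {exc}")
    if errors:
        raise ValueError("malformed variant rows:\n" + "\n".join(errors))
    return records


def packaged_variant_table() -> List[TrioVariantRecord]:
    """The packaged list of 88 Sanger-validated de novo mutations."""
    ref = resources.files("trionet").joinpath("data/validated_mutations.tsv")
    with resources.as_file(ref) as path:
        return parse_variant_table(path)


def write_variant_table(
    records: Sequence[TrioVariantRecord], path: Union[str, Path]
) -> None:
    """Write records back to the same TSV schema."""
    rows = [
        {
            "Cohort": r.cohort,
            "Gene": r.gene,
            "Chromosome": r.chrom,
            "Position": f"chr{r.chrom}:{r.pos}",
            "Father": r.father,
            "Mother": r.mother,
            "Patient": r.patient,
            "PPH2 Score": r.pph2_score,
            "PPH2 Prediction": r.pph2_class.replace("_", " "),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(_REQUIRED_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def pp2_classify(
    score: float, t_probably: float = 0.94, t_benign: float = 0.446
) -> str:
    """Triage a PolyPhen-2 score into the three damage classes."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"PPH2 score {score} outside [0, 1]")
    if score > t_probably:
        return "probably_damaging"
    if score > t_benign:
        return "possibly_damaging"
    return "benign"


def _round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (as in the tables)."""
    return int(x + 0.5) if x >= 0 else -int(-x + 0.5)


def tally_mutations(
    records: Iterable[TrioVariantRecord],
    n_families: Optional[Mapping[str, int]] = None,
) -> CohortSummary:
    """Per-cohort mutation counts and distinct chromosomes hit.

    The overall chromosome count is the size of the union across cohorts,
    not the sum (the same chromosome may be hit in several cohorts).
    """
    fams = dict(n_families if n_families is not None else DEFAULT_FAMILY_COUNTS)
    n_mut = {c: 0 for c in COHORTS}
    hist: Dict[str, Dict[str, int]] = {c: {} for c in COHORTS}
    for r in records:
        if r.cohort not in n_mut:
            raise ValueError(f"unknown cohort {r.cohort!r}")
        n_mut[r.cohort] += 1
        hist[r.cohort][r.chrom] = hist[r.cohort].get(r.chrom, 0) + 1
    chrom_union: Set[str] = set()
    n_chrom = {}
    for c in COHORTS:
        n_chrom[c] = len(hist[c])
        chrom_union |= set(hist[c])
    return CohortSummary(
        n_families=fams,
        n_mutations=n_mut,
        n_chromosomes_with=n_chrom,
        chromosome_histogram=hist,
        n_mutations_total=sum(n_mut.values()),
        n_chromosomes_total=len(chrom_union),
    )


def chromosome_distribution(
    records: Iterable[TrioVariantRecord], denominator: int = 23
) -> Dict[str, Dict[str, int]]:
    """Percent of chromosomes carrying 1 / 2 / >=3 / any mutations, per cohort.

    Percentages are of ``denominator`` chromosomes (22 autosomes + X by
    default) rounded half away from zero; the "any" percentage is rounded
    from the unrounded sum of the three components, so rounded components
    may disagree with the rounded total by one point.
    """
    if denominator < 1:
        raise ValueError("denominator must be positive")
    summary = tally_mutations(records)
    out: Dict[str, Dict[str, int]] = {}
    for c in COHORTS:
        mult = list(summary.chromosome_histogram[c].values())
        n1 = sum(1 for m in mult if m == 1)
        n2 = sum(1 for m in mult if m == 2)
        n3 = sum(1 for m in mult if m >= 3)
        out[c] = {
            "1": _round_half_away(100.0 * n1 / denominator),
            "2": _round_half_away(100.0 * n2 / denominator),
            "3+": _round_half_away(100.0 * n3 / denominator),
            "any": _round_half_away(100.0 * (n1 + n2 + n3) / denominator),
        }
    return out


def patient_distribution(
    patient_counts: Mapping[str, Union[int, Tuple[int, int]]],
    n_families: Optional[Mapping[str, int]] = None,
) -> Dict[str, Dict[str, int]]:
    """Percent of patients carrying mutations, per cohort.

    ``patient_counts`` maps a cohort to either the number of patients with at
    least one mutation, or a pair ``(n_with, n_with_two_or_more)``.  The
    published variant list carries no patient identifiers, so these counts
    come from the published per-cohort tallies rather than from records.
    """
    fams = dict(n_families if n_families is not None else DEFAULT_FAMILY_COUNTS)
    out: Dict[str, Dict[str, int]] = {}
    for cohort, counts in patient_counts.items():
        if cohort not in fams:
            raise ValueError(f"no family count for cohort {cohort!r}")
        families = fams[cohort]
        if isinstance(counts, tuple):
            n_with, n_multi = counts
        else:
            n_with, n_multi = counts, None
        if n_with > families:
            raise ValueError(
                f"{cohort}: {n_with} patients with mutations exceeds "
                f"{families} families"
            )
        row = {"any": _round_half_away(100.0 * n_with / families)}
        if n_multi is not None:
            if n_multi > n_with:
                raise ValueError(f"{cohort}: multi-mutation count exceeds total")
            row["1"] = _round_half_away(100.0 * (n_with - n_multi) / families)
            row["2+"] = _round_half_away(100.0 * n_multi / families)
        out[cohort] = row
    return out


def pp2_tally(
    records: Iterable[TrioVariantRecord],
) -> pd.DataFrame:
    """Counts of probably/possibly damaging and benign mutations per cohort.

    Rows are the three cohorts plus a Total row; row sums equal the cohort
    mutation counts.
    """
    counts = {c: {k: 0 for k in PP2_CLASSES} for c in COHORTS}
    for r in records:
        if r.cohort not in counts:
            raise ValueError(f"unknown cohort {r.cohort!r}")
        counts[r.cohort][r.pph2_class] += 1
    rows = []
    for c in COHORTS:
        row = [counts[c][k] for k in PP2_CLASSES]
        rows.append(row + [sum(row)])
    total = [sum(r[i] for r in rows) for i in range(4)]
    rows.append(total)
    return pd.DataFrame(
        rows,
        index=list(COHORTS) + ["Total"],
        columns=list(PP2_CLASSES) + ["total"],
    )
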